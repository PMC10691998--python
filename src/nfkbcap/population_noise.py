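"""Lognormal cell-to-cell variability and the Monte Carlo population engine.

Across a population, each protein's total abundance is sampled from a
lognormal distribution whose median equals the nominal (accepted) value
and whose scale parameter sigma — the "noise level" — is shared by all
variable proteins.  A per-protein boolean mask selects which proteins
vary; the "fixed pools" scenario of the capacity experiments fixes NFkB
and IkBa at their nominal values while the upstream proteins vary.

Each sampled cell is first equilibrated to its own pre-stimulation steady
state (so the sampled totals are the cell's conserved quantities), then
stimulated with its assigned antigen concentration.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import PopulationRunError
from .signaling_model import (
    KineticParameterSet,
    ResponseMetrics,
    PROTEINS,
    response_metrics,
    simulate_response,
    steady_state_fast,
)

logger = logging.getLogger(__name__)

#: Extreme-tail guard: sampled totals are clipped to this many decades
#: around nominal (keeps the stiff solver stable at sigma = 2).
CLIP_DECADES = 3.0

#: Replicates per simulation regime used for converging population samples.
DEFAULT_N_CELLS = 2000


@dataclass(frozen=True)
class NoiseModel:
    """Shared-scale lognormal variability across the population."""

    noise_level: float
    nominal_totals: Mapping[str, float]
    variability_mask: Mapping[str, bool] = field(
        default_factory=lambda: {p: True for p in PROTEINS}
    )
    seed: int = 0

    def __post_init__(self):
        if self.noise_level < 0:
            raise ValueError("noise level (lognormal sigma) must be >= 0")
        for p, m in self.nominal_totals.items():
            if m <= 0:
                raise ValueError(f"nominal total for {p!r} must be > 0")
        missing = set(self.nominal_totals) - set(self.variability_mask)
        if missing:
            raise ValueError(f"variability mask does not cover: {sorted(missing)}")


@dataclass(frozen=True)
class CellSample:
    """One cell's sampled protein totals and the antigen it encounters."""

    totals: Mapping[str, float]
    antigen: float | None = None

    def with_antigen(self, antigen: float) -> "CellSample":
        return CellSample(totals=self.totals, antigen=float(antigen))


@dataclass(frozen=True)
class ResponseSample:
    cell: CellSample
    metrics: ResponseMetrics


def _protein_stream(seed: int, protein: str) -> np.random.Generator:
    """Independent substream per protein, keyed by a stable name hash.

    Adding or removing a protein therefore does not perturb the draws of
    the others.
    """
    key = zlib.crc32(protein.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def sample_population(noise: NoiseModel, n_cells: int = DEFAULT_N_CELLS) -> list[CellSample]:
    """Draw ``n_cells`` independent cells (antigen left unset).

    Variable proteins: ``total = exp(Normal(ln median, sigma^2))`` so the
    population median equals the nominal value.  Fixed proteins are set to
    nominal exactly.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    columns: dict[str, np.ndarray] = {}
    n_clipped = 0
    for protein in sorted(noise.nominal_totals):
        median = noise.nominal_totals[protein]
        if noise.variability_mask.get(protein, False) and noise.noise_level > 0:
            rng = _protein_stream(noise.seed, protein)
            draws = np.exp(rng.normal(np.log(median), noise.noise_level, size=n_cells))
            lo, hi = median * 10.0 ** -CLIP_DECADES, median * 10.0 ** CLIP_DECADES
            n_clipped += int(np.sum((draws < lo) | (draws > hi)))
            draws = np.clip(draws, lo, hi)
        else:
            draws = np.full(n_cells, median)
        columns[protein] = draws
    if n_clipped:
        logger.info(
            "clipped %d of %d lognormal draws (%.3f%%) at +/-%g decades",
            n_clipped, n_cells * len(columns), 100 * n_clipped / (n_cells * len(columns)),
            CLIP_DECADES,
        )
    names = list(noise.nominal_totals)
    return [
        CellSample(totals={p: float(columns[p][i]) for p in names})
        for i in range(n_cells)
    ]


def run_population(
    params: KineticParameterSet,
    cells: Sequence[CellSample],
    t_end: float = 300.0,
    max_failure_fraction: float = 0.01,
) -> list[ResponseSample | None]:
    """Simulate every (cell, antigen) pair and extract response metrics.

    Each cell is re-equilibrated from its own sampled totals before
    stimulation.  Output order matches input; a failed cell yields
    ``None`` (and the whole run fails if more than 1% of cells fail).
    Results are deterministic functions of the inputs.
    """
    out: list[ResponseSample | None] = []
    failures: list[tuple[int, str]] = []
    for i, cell in enumerate(cells):
        if cell.antigen is None or cell.antigen < 0:
            raise ValueError(f"cell {i} has no valid antigen concentration")
        try:
            ss, _ = steady_state_fast(params, cell.totals)
            traj = simulate_response(params, ss, cell.antigen, t_end=t_end, totals=cell.totals)
            out.append(ResponseSample(cell=cell, metrics=response_metrics(traj)))
        except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
            failures.append((i, repr(exc)))
            out.append(None)
    if failures:
        frac = len(failures) / len(cells)
        logger.warning("%d/%d cells failed (%.2f%%); first: %s",
                       len(failures), len(cells), 100 * frac, failures[0][1])
        if frac > max_failure_fraction:
            raise PopulationRunError(
                f"{len(failures)}/{len(cells)} cell simulations failed; first: {failures[0][1]}"
            )
    return out


def metric_array(samples: Sequence[ResponseSample | None], metric: str) -> np.ndarray:
    """Extract one response metric ('absolute' or 'fold_change') as an array.

    Failed cells (``None``) are dropped.
    """
    key = {"absolute": "peak_nuclear_nfkb", "fold_change": "fold_change"}[metric]
    return np.array([getattr(s.metrics, key) for s in samples if s is not None])
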