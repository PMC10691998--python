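"""Information-theoretic estimators and the channel-capacity heuristic.

Mutual information between continuous samples is estimated with the
Kraskov-Stogbauer-Grassberger (KSG) k-nearest-neighbor estimator
(algorithm 1, max-norm):

    I(X;Y) ~= psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) >

where n_x, n_y count neighbors within the k-th joint-space distance.
Mixed discrete/continuous pairs (the equiprobable probe levels against a
continuous response) use the nearest-neighbor estimator of Ross, which
replaces the joint-space ball by the k-th neighbor within the same
discrete class.

Channel capacity is estimated with an iterative heuristic: probe the
channel with n equiprobable input levels whose elicited activations are
evenly spaced (maximizing prior entropy while minimizing response
overlap), increase n while the estimated mutual information keeps
increasing, and report the maximum as capacity.  A discretized
Blahut-Arimoto solver is provided as an independent oracle for testing.

Discrimination error rates follow a likelihood rule: a response from the
"high"-stimulated population counts as a false negative when its
estimated density is strictly greater under the "low" response
distribution (and conversely for false positives), with each sample's own
value excluded from its class's kernel density fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import digamma

from .antigen_distributions import ProbeDesign, make_probe
from .exceptions import DegenerateInputError, InvalidDistributionError
from .signaling_model import DoseResponseCurve

LN2 = np.log(2.0)


@dataclass(frozen=True)
class MIEstimate:
    """A mutual-information estimate in bits (clipped at 0 from below)."""

    value: float
    k: int
    n_samples: int
    estimator_variant: str
    raw_value: float = None

    def __post_init__(self):
        if self.raw_value is None:
            object.__setattr__(self, "raw_value", self.value)
        object.__setattr__(self, "value", max(0.0, self.value))


@dataclass(frozen=True)
class CapacityEstimate:
    """Output of the iterative capacity heuristic."""

    capacity: float
    mi_by_n: Mapping[int, MIEstimate]
    n_at_max: int
    stopping_reason: str  # "plateau" | "max_n"
    #: per-n diagnostic: MI within epsilon of log2(n), i.e. H(S|R) ~ 0,
    #: which is what licenses incrementing n.
    saturated: Mapping[int, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class ErrorRates:
    false_positive_pct: float
    false_negative_pct: float
    n_low: int
    n_high: int


# ---------------------------------------------------------------------------
# entropies and MI

def discrete_entropy(probabilities) -> float:
    """Shannon entropy -sum p log2 p of a discrete distribution, in bits."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise InvalidDistributionError("probabilities must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidDistributionError(f"probabilities sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _ksg_continuous(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """KSG algorithm 1 for scalar margins, in nats."""
    n = len(x)
    xs = np.sort(x)
    ys = np.sort(y)
    # k-th joint Chebyshev neighbor distance, excluding self
    from scipy.spatial import cKDTree

    z = np.column_stack([x, y])
    tree = cKDTree(z)
    dist, _ = tree.query(z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    nx = (np.searchsorted(xs, x + eps, side="left")
          - np.searchsorted(xs, x - eps, side="right"))
    ny = (np.searchsorted(ys, y + eps, side="left")
          - np.searchsorted(ys, y - eps, side="right"))
    # counts are strictly-within-eps and include the point itself; the
    # estimator wants n_x + 1 with self excluded, which is the same number
    return float(digamma(k) + digamma(n) - np.mean(digamma(nx) + digamma(ny)))


def _ross_discrete_continuous(labels: np.ndarray, y: np.ndarray, k: int) -> float:
    """Ross nearest-neighbor MI between a discrete X and continuous Y, nats.

    Exactly tied responses (e.g. a shared resting level across
    non-responding cells) would give zero neighbor radii; they are broken
    by a deterministic, negligibly small jitter, as is standard for
    nearest-neighbor MI estimators.
    """
    n = len(y)
    if len(np.unique(y)) < n:
        scale = np.std(y)
        if scale == 0:
            return 0.0
        y = y + np.random.default_rng(981273).normal(0.0, 1e-9 * scale, size=n)
    order = np.argsort(y)
    ys = y[order]
    ls = labels[order]
    radius = np.empty(n)
    k_used = np.empty(n, dtype=int)
    label_count = np.empty(n, dtype=int)
    for lab in np.unique(ls):
        idx = np.flatnonzero(ls == lab)
        m = len(idx)
        if m < 2:
            raise DegenerateInputError(f"class {lab!r} has fewer than 2 samples")
        yc = ys[idx]
        kk = min(k, m - 1)
        # k-th nearest neighbor within the class, via the sorted order
        d = np.empty(m)
        for j in range(m):
            lo, hi = max(0, j - kk), min(m, j + kk + 1)
            dd = np.sort(np.abs(yc[lo:hi] - yc[j]))
            d[j] = dd[kk]  # dd[0] == 0 is the point itself
        radius[idx] = d
        k_used[idx] = kk
        label_count[idx] = m
    # count points of the full sample strictly within the class radius;
    # compare computed distances (not shifted values) so the k-th
    # neighbor itself is reliably excluded despite float rounding
    from scipy.spatial import cKDTree

    tree = cKDTree(ys[:, None])
    m_i = tree.query_ball_point(ys[:, None], np.nextafter(radius, 0.0),
                                return_length=True)
    m_i = np.maximum(m_i, 1)
    return float(digamma(n) - np.mean(digamma(label_count))
                 + np.mean(digamma(k_used)) - np.mean(digamma(m_i)))


def knn_mutual_information(
    x, y, k: int = 3, variant: str = "continuous-continuous"
) -> MIEstimate:
    """k-NN mutual information between two scalar samples, in bits.

    ``variant="continuous-continuous"`` is the KSG estimator (symmetric,
    invariant within sampling error under strictly monotone marginal
    transforms).  ``variant="discrete-continuous"`` treats ``x`` as class
    labels and uses the Ross estimator.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 50:
        raise ValueError("need at least 50 samples")
    if k < 1 or k >= len(x):
        raise ValueError("need n_samples > k >= 1")
    if variant == "continuous-continuous":
        for name, v in (("x", x), ("y", y)):
            if len(np.unique(v)) < k + 1:
                raise DegenerateInputError(f"margin {name} has fewer than k+1 distinct values")
        nats = _ksg_continuous(x, y, k)
    elif variant == "discrete-continuous":
        nats = _ross_discrete_continuous(x.astype(np.int64), y, k)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    bits = nats / LN2
    return MIEstimate(value=bits, raw_value=bits, k=k,
                      n_samples=len(x), estimator_variant=variant)


# ---------------------------------------------------------------------------
# channel capacity

DEFAULT_CAPACITY_CONFIG = {
    "k": 3,
    "n_per_level": 500,
    "epsilon": 0.05,
    "max_n": 32,
    "seed": 0,
}

Channel = Callable[[ProbeDesign, int, np.random.Generator], tuple[np.ndarray, np.ndarray]]


def estimate_channel_capacity(
    channel: Channel,
    curve: DoseResponseCurve,
    config: Mapping | None = None,
) -> CapacityEstimate:
    """Iterative equal-activation-spacing capacity heuristic.

    Starting from two probe levels (the low/high anchors), the number of
    equiprobable input levels is incremented as long as the estimated
    mutual information keeps increasing by more than ``epsilon`` bits;
    the maximum MI observed is reported as the capacity of a single
    activation event.

    ``channel(probe, n_per_level, rng)`` must return paired arrays
    ``(level_indices, responses)``.
    """
    cfg = dict(DEFAULT_CAPACITY_CONFIG)
    if config:
        cfg.update(config)
    total = cfg.pop("total_cells", None)
    if total is not None:
        # keep the whole-population budget roughly constant as n grows
        per_level = lambda n: max(100, int(round(total / n)))  # noqa: E731
    else:
        per_level = lambda n: cfg["n_per_level"]  # noqa: E731
    if per_level(2) < 100:
        raise ValueError("n_per_level must be >= 100")
    rng = np.random.default_rng(cfg["seed"])
    mi_by_n: dict[int, MIEstimate] = {}
    saturated: dict[int, bool] = {}
    prev = None
    stopping = "max_n"
    n_final = 2
    for n in range(2, cfg["max_n"] + 1):
        probe = make_probe(n, curve)
        labels, responses = channel(probe, per_level(n), rng)
        est = knn_mutual_information(labels, responses, k=cfg["k"],
                                     variant="discrete-continuous")
        mi_by_n[n] = est
        saturated[n] = est.value >= np.log2(n) - cfg["epsilon"]
        n_final = n
        if prev is not None and est.value <= prev + cfg["epsilon"]:
            stopping = "plateau"
            break
        prev = est.value
    values = {n: e.value for n, e in mi_by_n.items()}
    n_at_max = max(values, key=values.get)
    return CapacityEstimate(
        capacity=values[n_at_max],
        mi_by_n=mi_by_n,
        n_at_max=n_at_max,
        stopping_reason=stopping if n_final < cfg["max_n"] else "max_n",
        saturated=saturated,
    )


def blahut_arimoto(transition_matrix, tol: float = 1e-9, max_iter: int = 10000) -> float:
    """Capacity (bits) of a discrete memoryless channel by alternating
    maximization.  Rows of ``transition_matrix`` are p(y|x).  Test oracle
    for the heuristic; not part of the estimation pipeline."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise InvalidDistributionError("rows must be valid conditional distributions")
    m = P.shape[0]
    p = np.full(m, 1.0 / m)
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(P), 0.0)
    for _ in range(max_iter):
        q = p @ P  # output distribution
        with np.errstate(divide="ignore", invalid="ignore"):
            D = np.where(P > 0, logP - np.log(q), 0.0)
        c = np.exp((P * D).sum(axis=1))
        p_new = p * c
        p_new /= p_new.sum()
        # capacity bounds for the stopping rule
        il = np.log((p * c).sum())
        iu = np.log(c.max())
        p = p_new
        if iu - il < tol:
            break
    return float(il / LN2) if np.isfinite(il) else 0.0


# ---------------------------------------------------------------------------
# discrimination error rates

def _silverman_bandwidth(z: np.ndarray) -> float:
    """Silverman's rule with the sample standard deviation as the scale
    (the convention of scipy's gaussian_kde).  On the natural response
    scale the standard deviation of a strongly right-skewed class is
    dominated by its upper tail, which flattens that class's density —
    the effect underlying the false-negative/false-positive asymmetry."""
    n = len(z)
    sd = np.std(z, ddof=1)
    if sd <= 0:
        raise DegenerateInputError("class has zero variance; density undefined")
    return 0.9 * sd * n ** (-0.2)


def _kde_matrix(points: np.ndarray, data: np.ndarray, h: float) -> np.ndarray:
    """Gaussian kernel contributions, summed over data, at each point."""
    d = (points[:, None] - data[None, :]) / h
    K = np.exp(-0.5 * d * d)
    return K.sum(axis=1) / (h * np.sqrt(2 * np.pi))


def discrimination_error_rates(
    low_responses,
    high_responses,
    bandwidth_rule: str = "silverman",
    seed: int = 0,
) -> ErrorRates:
    """Likelihood-based confusion between 'low' and 'high' stimulation.

    Class densities are estimated by Gaussian KDE with Silverman's
    bandwidth on the natural response scale (``"silverman"``, default) or
    on log responses (``"silverman-log"``).  The natural scale matters:
    under strong lognormal protein noise the high-stimulated responses
    spread over orders of magnitude, so their density is everywhere low,
    while weak responses concentrate near the resting level in a tall
    narrow mode — which is what drives the characteristic asymmetry of
    large false-negative but near-zero false-positive rates.  A sample's
    own value is left out of its own class's density.  Likelihood ties
    are broken toward the correct class with probability 1/2.
    """
    low = np.asarray(low_responses, dtype=float).ravel()
    high = np.asarray(high_responses, dtype=float).ravel()
    if len(low) < 100 or len(high) < 100:
        raise ValueError("need at least 100 samples per class")
    if bandwidth_rule not in ("silverman", "silverman-log"):
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if bandwidth_rule == "silverman-log":
        if np.any(low <= 0) or np.any(high <= 0):
            raise ValueError("responses must be positive for the log transform")
        zl, zh = np.log(low), np.log(high)
    else:
        zl, zh = low, high
    for name, z in (("low", zl), ("high", zh)):
        if np.std(z) == 0:
            raise DegenerateInputError(f"{name} class has zero variance; density undefined")
    # one smoothing scale for the likelihood comparison, from the pooled
    # sample: per-class bandwidths would tilt every comparison by the
    # sampling noise of the two scale estimates
    h = _silverman_bandwidth(np.concatenate([zl, zh]))
    norm = np.sqrt(2 * np.pi)
    rng = np.random.default_rng(seed)

    # low samples: own-class LOO density vs cross density under 'high'
    own_low = (_kde_matrix(zl, zl, h) - 1.0 / (h * norm)) / (len(zl) - 1)
    cross_low = _kde_matrix(zl, zh, h) / len(zh)
    fp = cross_low > own_low
    ties = cross_low == own_low
    if ties.any():
        fp = fp | (ties & (rng.random(len(zl)) < 0.5))

    own_high = (_kde_matrix(zh, zh, h) - 1.0 / (h * norm)) / (len(zh) - 1)
    cross_high = _kde_matrix(zh, zl, h) / len(zl)
    fn = cross_high > own_high
    ties = cross_high == own_high
    if ties.any():
        fn = fn | (ties & (rng.random(len(zh)) < 0.5))

    return ErrorRates(
        false_positive_pct=100.0 * float(np.mean(fp)),
        false_negative_pct=100.0 * float(np.mean(fn)),
        n_low=len(low),
        n_high=len(high),
    )
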