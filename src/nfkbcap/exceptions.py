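"""Exception hierarchy for nfkbcap."""


class NfkbcapError(Exception):
    """Base class for all package errors."""


class CalibrationError(NfkbcapError):
    """The stored kinetic parameter set fails its calibration guard."""


class SteadyStateError(NfkbcapError):
    """Pre-stimulation steady state could not be reached."""


class SolverError(NfkbcapError):
    """The ODE integrator reported a failure."""


class NegativeConcentrationError(NfkbcapError):
    """A species concentration fell below the negativity tolerance."""


class NonMonotoneDoseResponseError(NfkbcapError):
    """Dose-response activation decreased beyond tolerance (mis-calibration)."""


class DoseResponseRangeError(NfkbcapError):
    """Requested activation target is unreachable on the dose-response grid."""


class UnknownPerturbationError(NfkbcapError):
    """Perturbation name is not recognized."""


class UndefinedFoldChangeError(NfkbcapError):
    """Fold change undefined because the baseline is zero."""


class InvalidDistributionError(NfkbcapError):
    """A probability vector is not a valid distribution."""


class DegenerateInputError(NfkbcapError):
    """Input sample is degenerate for the requested estimator."""


class PopulationRunError(NfkbcapError):
    """Too many per-cell simulations failed in a population run."""
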