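"""Exception hierarchy for model construction, validation and solving."""


class ModelError(Exception):
    """Base class for all carecost errors."""


class StructuralError(ModelError):
    """A matrix or mapping has the wrong shape, labels or coverage."""


class InvalidMatrixError(ModelError):
    """A probability matrix failed validation in strict mode."""


class DegenerateRowError(ModelError):
    """An effective-transition row has zero total accuracy-weighted mass.

    This signals an unmodelable state: no admissible treatment/transition
    combination carries probability, so the renormalised row is undefined.
    """


class NonErgodicError(ModelError):
    """The chain has no unique stationary distribution.

    Raised when more than one closed recurrent class exists, so the
    long-run state occupancy depends on the starting state.
    """


class InfeasiblePerturbationError(ModelError):
    """A sensitivity perturbation pushed the absorbing probability outside [0, 1]."""


class ConfigError(ModelError):
    """A configuration file or cost schedule is missing or inconsistent."""


class SampleSizeError(ModelError):
    """Too few clinician reports for the requested statistical test."""


class EnumerationSizeError(ModelError):
    """Pure-policy enumeration would exceed the desk-scale guard."""
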