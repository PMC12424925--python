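"""Exception hierarchy shared across the pipeline."""


class AgearchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AgearchError, ValueError):
    """A numeric argument is outside its admissible range."""


class ConfigurationError(AgearchError, ValueError):
    """A config block references unknown columns, traits or flags."""


class DegenerateInputError(AgearchError, ValueError):
    """Input carries no usable variation (constant phenotype, all-equal ranks, ...)."""


class MatchingInfeasibleError(AgearchError, ValueError):
    """Age-matched resampling cannot proceed (disjoint supports, oversized request)."""


class EmptySetError(AgearchError, ValueError):
    """A case or control set came out empty."""


class InsufficientVisitsError(AgearchError, ValueError):
    """Longitudinal operation requested with too few visits per individual."""


class UnstableRatioError(AgearchError, ValueError):
    """Denominator correlation too close to zero for the ratio estimator."""


class UndefinedEstimateError(AgearchError, ValueError):
    """Estimate undefined (non-positive heritability in a correlation, zero denominator...)."""
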