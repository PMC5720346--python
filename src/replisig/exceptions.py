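"""Exception hierarchy shared across the package."""


class ReplisigError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ReplisigError, ValueError):
    """Invalid user-supplied data (malformed tables, misaligned ids, bad values)."""


class ParameterError(ReplisigError, ValueError):
    """Invalid parameter value (negative counts, infeasible configurations)."""


class DesignError(ReplisigError, ValueError):
    """A design matrix cannot be built or is rank deficient."""


class EstimationError(ReplisigError, RuntimeError):
    """A model or hyperparameter estimate cannot be computed."""


class ConfigError(ReplisigError, ValueError):
    """Inconsistent pipeline or permutation configuration."""
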