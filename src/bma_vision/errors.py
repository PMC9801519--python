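"""Exception hierarchy for the package."""


class BmaVisionError(Exception):
    """Base class for all package errors."""


class DataValidationError(BmaVisionError, ValueError):
    """A study table violates a structural invariant."""


class ModelSpaceError(BmaVisionError, ValueError):
    """Invalid model-space request (bad covariate count, bad index)."""


class SingularModelError(BmaVisionError, ValueError):
    """The design matrix restricted to one model is rank deficient."""


class ConfigError(BmaVisionError, ValueError):
    """Invalid run configuration."""


class ScenarioError(BmaVisionError, ValueError):
    """Infeasible or malformed synthetic-data scenario."""
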