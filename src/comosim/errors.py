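"""Exception hierarchy shared across the package."""


class ComosimError(Exception):
    """Base class for all errors raised by comosim."""


class ValidationError(ComosimError):
    """Input data or parameter object violates a stated invariant."""


class DegenerateFitError(ComosimError):
    """An outcome has a single level, so the model cannot be estimated."""


class StratumError(ComosimError):
    """A required fitting stratum contains no usable observations."""


class EstimationError(ComosimError):
    """Maximum-likelihood estimation failed to converge."""


class ParseError(ComosimError):
    """A delimited input file is malformed; the message names the row."""


class ConfigError(ComosimError):
    """A run-configuration document is invalid."""
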