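"""Exception hierarchy for colonyquant."""


class ColonyQuantError(Exception):
    """Base class for all colonyquant errors."""


class FormatError(ColonyQuantError):
    """An input file could not be read or has an unsupported format."""


class ConfigurationError(ColonyQuantError):
    """Required configuration (e.g. scan resolution) is missing or inconsistent."""


class ValidationError(ColonyQuantError):
    """Input data violates a precondition of an operation."""


class FitError(ColonyQuantError):
    """A nonlinear fit failed to converge or the data are degenerate."""


class GenerationError(ColonyQuantError):
    """A synthetic image could not be generated under the requested constraints."""
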