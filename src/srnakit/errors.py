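"""Exception hierarchy shared across the toolkit."""


class SrnakitError(Exception):
    """Base class for all srnakit errors."""


class ParseError(SrnakitError):
    """A sequence or table file could not be parsed."""


class FormatError(SrnakitError):
    """A record violates the expected dialect (e.g. a collapsed-FASTA header)."""


class ValidationError(SrnakitError):
    """Input data violates a documented precondition or invariant."""


class ConfigError(SrnakitError):
    """A configuration document contains unknown or invalid entries."""


class CapacityError(SrnakitError):
    """An input exceeds a documented size bound (e.g. fold length limit)."""


class PipelineError(SrnakitError):
    """A pipeline stage failed; the message names the stage."""
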