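"""Exception hierarchy shared across the package."""


class RpfamError(Exception):
    """Base class for all errors raised by rpfam."""


class ParseError(RpfamError, ValueError):
    """An input file violates the expected tabular/annotation format."""


class ConfigurationError(RpfamError, ValueError):
    """A parameter or simulation scenario is invalid; the message names the field."""


class PipelineError(RpfamError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
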