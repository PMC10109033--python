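"""Exception hierarchy shared across the pipeline."""


class ProteodxError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ProteodxError):
    """Malformed input file (ragged TSV, duplicate ids, bad GMT line...)."""


class ConfigError(ProteodxError):
    """Inconsistent or invalid configuration."""


class ValidationError(ProteodxError):
    """Input violates an operation's contract (wrong layer/scale, bad value)."""


class InputError(ProteodxError):
    """Too little data to run an operation (e.g. <3 samples)."""


class PipelineError(ProteodxError):
    """A stage refuses to continue (e.g. every sample flagged as outlier)."""
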