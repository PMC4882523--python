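"""Exception hierarchy for the pipeline."""


class SweepscanError(Exception):
    """Base class for all package errors."""


class ParseError(SweepscanError):
    """A malformed input file; message carries the file and line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(SweepscanError):
    """A contract violation on inputs (bad config, inconsistent tables)."""


class ConfigError(ValidationError):
    """An invalid configuration value."""
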