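"""Package-wide exception types."""


class EstSurveyError(Exception):
    """Base class for all errors raised by estsurvey."""


class ConfigError(EstSurveyError):
    """Invalid configuration value or combination."""


class FormatError(EstSurveyError):
    """Malformed input record (e.g. quality/sequence length mismatch)."""


class ParseError(EstSurveyError):
    """Malformed tabular input; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class PipelineError(EstSurveyError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
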