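"""Exception hierarchy shared across the package."""


class MethMirNetError(Exception):
    """Base class for all package errors."""


class ConfigError(MethMirNetError):
    """Invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ParameterError(MethMirNetError):
    """A statistical parameter is outside its admissible range."""


class ZeroCoverageError(MethMirNetError):
    """Methylation level requested at a site with no reads."""


class NormalizationError(MethMirNetError):
    """A sample cannot be depth-normalized (e.g. zero total counts)."""


class AnnotationError(MethMirNetError):
    """Required feature annotation (e.g. exon length) is missing."""


class DesignError(MethMirNetError):
    """The sample design cannot support the requested test."""


class CoordinateError(MethMirNetError):
    """A genomic coordinate falls outside its chromosome."""


class SequenceError(MethMirNetError):
    """A sequence is too short or contains characters outside ACGU/ACGT."""


class ParseError(MethMirNetError):
    """A text input file is malformed; the message carries the line number."""


class UndefinedCorrelationError(MethMirNetError):
    """Correlation undefined because one vector has zero variance."""


class AlignmentError(MethMirNetError):
    """Sample identifiers of two tables do not align."""


class PipelineError(MethMirNetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
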