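"""Exception hierarchy shared across the pipeline stages."""


class StethosimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StethosimError, ValueError):
    """A synthesis or analysis parameter is out of its admissible range."""


class FormatError(StethosimError, ValueError):
    """An input file is not in a supported audio/metadata format."""


class DegenerateInputError(StethosimError, ValueError):
    """An input is structurally valid but degenerate (e.g. all-zero audio)."""


class DegenerateReferenceError(StethosimError, ValueError):
    """A reference label set has no positives or no negatives, so agreement
    metrics at varying cutoffs are undefined."""


class PipelineStageError(StethosimError, RuntimeError):
    """Wraps a failure inside one named stage of the end-to-end pipeline."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
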