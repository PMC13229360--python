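"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (usage 2, data quality 3,
low-confidence detection 4) so batch callers can triage failures.
"""


class FgaError(Exception):
    """Base class for all fgakit errors."""


class FormatError(FgaError):
    """Malformed input file (bad header, non-uniform timestamps, ...)."""


class MissingKeypointError(FormatError):
    """A keypoint required by the dialect or operation is absent."""

    def __init__(self, name: str, context: str = ""):
        self.keypoint = name
        msg = f"required keypoint {name!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class DataQualityError(FgaError):
    """Input is structurally valid but unusable (long gaps, bad scales...)."""


class LowConfidenceError(FgaError):
    """A detection step produced a result below its confidence floor."""


class DegenerateFrameError(DataQualityError):
    """Walkway calibration points do not span a plane."""
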