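"""Exception hierarchy.

Per-frame algorithm failures (segmentation, identification) are recoverable:
the pipeline catches them and marks the frame failed. Input errors
(:class:`ValueError` subclasses) indicate caller mistakes and propagate.
"""


class FlagtraceError(Exception):
    """Base class for recoverable per-frame analysis failures."""


class SegmentationError(FlagtraceError):
    """Binarization could not produce a plausible single-cell mask."""


class IdentificationError(FlagtraceError):
    """Width analysis could not isolate a flagellar region."""


class BranchedSkeletonError(ValueError):
    """A simple-path operation was handed a branched skeleton.

    Callers should resolve junctions first (``tracing.resolve_branches``).
    """
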