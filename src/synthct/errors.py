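"""Exception hierarchy.

Every failure mode the pipeline can signal deliberately derives from
:class:`SynthCTError`, so callers can distinguish pipeline errors from
programming bugs.
"""


class SynthCTError(Exception):
    """Base class for all deliberate pipeline errors."""


class ConstraintError(SynthCTError):
    """A geometric or anatomical invariant was violated (names the invariant)."""


class ParameterError(SynthCTError):
    """Invalid parameter combination (e.g. window lo >= hi)."""


class DataError(SynthCTError):
    """Malformed or mismatched data (shape mismatch, out-of-range labels)."""


class SegmentationFailure(SynthCTError):
    """Algorithmic segmentation could not find a body on the slice."""


class NotFoundError(SynthCTError):
    """A referenced object (e.g. nodule id) does not exist."""


class MetadataError(SynthCTError):
    """Required file metadata is missing (e.g. DICOM rescale tags)."""


class SizeError(SynthCTError):
    """A requested subset size cannot be satisfied by the available data."""


class ConfigError(SynthCTError):
    """Inconsistent model configuration."""


class TrainingDivergenceError(SynthCTError):
    """A loss became non-finite during training."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class BundleFormatError(SynthCTError):
    """A model bundle file is corrupt or from an incompatible version."""


class DegenerateStatisticError(SynthCTError):
    """A statistical test was handed data with no usable variance."""
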