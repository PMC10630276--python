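"""Annotation-map label encoding.

Annotation maps are ``uint8`` rasters with six codes: the five anatomical
labels that condition the synthesis network (body, soft tissue, dense
tissue, lung area, nodule area) plus an explicit exterior code 0 so that
one-hot conditioning covers every pixel.  Claims about "five labels"
always exclude the exterior.
"""

from __future__ import annotations

import numpy as np

EXTERIOR = 0
BODY = 1
SOFT = 2
DENSE = 3
LUNG = 4
NODULE = 5

N_LABELS = 6

LABEL_NAMES = {
    EXTERIOR: "exterior",
    BODY: "body",
    SOFT: "soft tissue",
    DENSE: "dense tissue",
    LUNG: "lung area",
    NODULE: "nodule area",
}

# Fixed 8-bit palette for indexed-PNG export (exterior, body, soft, dense,
# lung, nodule) — one distinct colour per label.
PALETTE = np.array(
    [
        [0, 0, 0],
        [128, 96, 64],
        [220, 160, 120],
        [240, 240, 240],
        [64, 128, 192],
        [200, 40, 40],
    ],
    dtype=np.uint8,
)


def validate_map(labels: np.ndarray) -> np.ndarray:
    """Check an annotation map's basic invariants; return it as uint8."""
    from .errors import DataError

    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise DataError(f"annotation map must be 2D, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() >= N_LABELS:
        raise DataError(
            f"annotation map labels must lie in 0..{N_LABELS - 1}, "
            f"found range [{arr.min()}, {arr.max()}]"
        )
    return arr.astype(np.uint8, copy=False)
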