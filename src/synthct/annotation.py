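"""Annotation maps: algorithmic segmentation and nodule-label editing.

An annotation map carries one integer label per pixel (see
:mod:`synthct.labels`): an explicit exterior code plus the five anatomical
labels that condition the synthesis network — full body, soft tissue,
dense tissue, total lung area, and nodule area.  The first four are
obtained by HU thresholding with connected-component and morphological
cleanup on the *raw* (unwindowed) slice, because the display window's
150 HU ceiling saturates bone and would destroy dense-tissue contrast.
The nodule label comes from a supplied mask (manual delineation in real
data, ground truth for phantoms) and is the one label the editing
operations manipulate: removal, insertion, relocation and resizing, all
under the anatomical constraint that a nodule stays attached to lung.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import labels as L
from .errors import (
    ConstraintError,
    DataError,
    NotFoundError,
    ParameterError,
    SegmentationFailure,
    SizeError,
)
from .geometry import NoduleSpec, nodule_mask

__all__ = [
    "NoduleSpec",
    "SegmentationParams",
    "segment_slice",
    "attach_nodule_mask",
    "remove_nodule",
    "insert_nodule",
    "relocate_nodule",
    "resize_nodule",
    "one_hot",
    "dice",
    "nodule_components",
    "save_map",
    "load_map",
    "save_map_png",
]

# 8-connectivity for all connected-component work
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the algorithmic five-label segmentation.

    HU thresholds follow standard CT practice: the body is everything
    above fat-ish ``body_threshold`` (largest component, holes filled);
    air-filled lung sits below ``lung_threshold``; calcified/bony dense
    tissue above ``dense_threshold``; soft tissue occupies the band above
    ``soft_threshold``; the body label keeps the remaining fat/skin band.
    ``min_lung_area`` is specified at 512x512 scale and rescaled by
    ``(side/512)**2`` internally.
    """

    body_threshold: float = -500.0
    lung_threshold: float = -320.0
    soft_threshold: float = -120.0
    dense_threshold: float = 150.0
    min_lung_area: float = 50.0
    hole_fill: bool = True

    def validate(self) -> None:
        if not (
            self.body_threshold
            < self.lung_threshold
            < self.soft_threshold
            < self.dense_threshold
        ):
            raise ParameterError(
                "thresholds must satisfy body < lung < soft < dense, got "
                f"{self.body_threshold}, {self.lung_threshold}, "
                f"{self.soft_threshold}, {self.dense_threshold}"
            )
        if self.min_lung_area < 0:
            raise ParameterError("min_lung_area must be >= 0")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    # ndimage.label assigns ids in raster order, so ties resolve to the
    # component whose first pixel comes earliest (lowest top-left index)
    best = int(np.argmax(sizes)) + 1
    return lab == best


def segment_slice(
    pixels: np.ndarray,
    params: SegmentationParams | None = None,
    nodule_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Segment a raw-HU slice into the five anatomical labels.

    Label priority on overlap is nodule > lung > dense > soft > body.
    Raises :class:`SegmentationFailure` when no body is found (e.g. an
    all-air slice).
    """
    params = params or SegmentationParams()
    params.validate()
    hu = np.asarray(pixels, dtype=np.float32)
    if hu.ndim != 2:
        raise DataError(f"slice must be 2D, got shape {hu.shape}")

    body = _largest_component(hu > params.body_threshold)
    if params.hole_fill:
        body = ndimage.binary_fill_holes(body)
    if not body.any():
        raise SegmentationFailure(
            f"no body component above {params.body_threshold} HU on this slice"
        )

    side = hu.shape[0]
    min_area = max(1.0, params.min_lung_area * (side / 512.0) ** 2)

    lung_raw = (hu < params.lung_threshold) & body
    # close over thin bright structures (vessels) and fill enclosed holes
    close_r = max(1, side // 256)
    lung = ndimage.binary_closing(
        lung_raw, structure=_STRUCT8, iterations=close_r
    )
    if params.hole_fill:
        lung = ndimage.binary_fill_holes(lung)
    lung &= body
    lab, n = ndimage.label(lung, structure=_STRUCT8)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area) + 1
        lung = np.isin(lab, keep)

    dense = (hu > params.dense_threshold) & body
    soft = (hu > params.soft_threshold) & body

    out = np.zeros(hu.shape, dtype=np.uint8)
    out[body] = L.BODY
    out[soft] = L.SOFT
    out[dense] = L.DENSE
    out[lung] = L.LUNG
    if nodule_mask is not None:
        m = np.asarray(nodule_mask, dtype=bool)
        if m.shape != out.shape:
            raise DataError("nodule mask shape does not match slice shape")
        out[m] = L.NODULE
    return out


def attach_nodule_mask(
    labels: np.ndarray,
    mask: np.ndarray,
    require_lung_overlap: float = 0.5,
) -> np.ndarray:
    """Stamp a manual nodule mask onto a map as the fifth label.

    Rejected (with the measured fraction) when less than
    ``require_lung_overlap`` of the mask lies on lung-or-nodule pixels —
    a nodule annotation that mostly misses the lungs is anatomically
    implausible and usually signals misregistration.
    """
    arr = L.validate_map(labels)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise DataError("mask shape does not match map shape")
    if not m.any():
        raise DataError("nodule mask is empty")
    overlap = float(np.isin(arr[m], (L.LUNG, L.NODULE)).mean())
    if overlap < require_lung_overlap:
        raise ConstraintError(
            f"nodule mask overlaps lung by {overlap:.2f} < "
            f"required {require_lung_overlap:.2f}"
        )
    out = arr.copy()
    out[m] = L.NODULE
    return out


def nodule_components(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected components of the nodule label, ids in raster order."""
    arr = L.validate_map(labels)
    return ndimage.label(arr == L.NODULE, structure=_STRUCT8)


def remove_nodule(labels: np.ndarray, id: int | str = "all") -> np.ndarray:
    """Relabel one nodule component (or all of them) back to lung."""
    arr = L.validate_map(labels)
    comp, n = nodule_components(arr)
    out = arr.copy()
    if id == "all":
        out[comp > 0] = L.LUNG
        return out
    if not isinstance(id, (int, np.integer)) or not 1 <= id <= n:
        raise NotFoundError(f"nodule id {id!r} not present (map has {n})")
    out[comp == id] = L.LUNG
    return out


def _clip_to_lung_contiguous(
    arr: np.ndarray, candidate: np.ndarray
) -> np.ndarray:
    """Clip a candidate nodule mask to the body, keeping only the parts
    connected to lung (pleura contact allowed; free-floating islands in
    soft tissue are dropped)."""
    cand = candidate & (arr != L.EXTERIOR)
    if not cand.any():
        return cand
    comp, n = ndimage.label(cand, structure=_STRUCT8)
    lungish = np.isin(arr, (L.LUNG, L.NODULE))
    keep = [
        i for i in range(1, n + 1) if bool(lungish[comp == i].any())
    ]
    return np.isin(comp, keep) if keep else np.zeros_like(cand)


def insert_nodule(
    labels: np.ndarray, spec: NoduleSpec, seed: int = 0
) -> np.ndarray:
    """Insert a new nodule label region rasterized from ``spec``.

    The center must sit on a lung pixel; the rasterized (irregular) disk
    is clipped to the body and any part not contiguous with lung is
    discarded.
    """
    arr = L.validate_map(labels)
    spec.validate(arr.shape)
    ri, ci = int(round(spec.center[0])), int(round(spec.center[1]))
    if arr[ri, ci] != L.LUNG:
        raise ConstraintError(
            f"nodule center {spec.center} must be on a lung pixel; found "
            f"{L.LABEL_NAMES[int(arr[ri, ci])]}"
        )
    rng = np.random.default_rng(seed)
    disk = nodule_mask(arr.shape, spec, rng)
    final = _clip_to_lung_contiguous(arr, disk)
    out = arr.copy()
    out[final] = L.NODULE
    return out


def relocate_nodule(
    labels: np.ndarray, id: int, new_center: tuple[float, float]
) -> np.ndarray:
    """Rigidly translate one nodule component to a new lung position.

    The component's pixel set is shifted by the integer offset that moves
    its centroid onto ``new_center``, clipped by the same contiguity rules
    as insertion; the vacated pixels become lung.
    """
    arr = L.validate_map(labels)
    comp, n = nodule_components(arr)
    if not isinstance(id, (int, np.integer)) or not 1 <= id <= n:
        raise NotFoundError(f"nodule id {id!r} not present (map has {n})")
    rr, cc = np.nonzero(comp == id)
    centroid = (rr.mean(), cc.mean())
    dr = int(np.round(new_center[0] - centroid[0]))
    dc = int(np.round(new_center[1] - centroid[1]))

    tri = int(round(new_center[0]))
    tci = int(round(new_center[1]))
    if not (0 <= tri < arr.shape[0] and 0 <= tci < arr.shape[1]):
        raise ConstraintError(f"target {new_center} outside image bounds")

    out = arr.copy()
    out[comp == id] = L.LUNG
    if out[tri, tci] != L.LUNG:
        raise ConstraintError(
            f"relocation target {new_center} is not on lung (found "
            f"{L.LABEL_NAMES[int(out[tri, tci])]})"
        )
    nr, nc = rr + dr, cc + dc
    inb = (nr >= 0) & (nr < arr.shape[0]) & (nc >= 0) & (nc < arr.shape[1])
    cand = np.zeros(arr.shape, dtype=bool)
    cand[nr[inb], nc[inb]] = True
    final = _clip_to_lung_contiguous(out, cand)
    if not final.any():
        raise ConstraintError("relocated nodule has no valid lung-attached pixels")
    out[final] = L.NODULE
    return out


def resize_nodule(labels: np.ndarray, id: int, scale: float) -> np.ndarray:
    """Rescale one nodule component about its centroid.

    Nearest-neighbour inverse mapping on the binary component mask, then
    the usual clipping rules.  Shrinking below an equivalent diameter of
    2 px raises :class:`SizeError`.
    """
    arr = L.validate_map(labels)
    if scale <= 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    comp, n = nodule_components(arr)
    if not isinstance(id, (int, np.integer)) or not 1 <= id <= n:
        raise NotFoundError(f"nodule id {id!r} not present (map has {n})")
    if scale == 1.0:
        return arr.copy()
    mask = comp == id
    rr, cc = np.nonzero(mask)
    gr, gc = rr.mean(), cc.mean()

    # inverse mapping: output pixel p samples the source mask at
    # g + (p - g)/scale; bilinear interpolation with a 0.5 threshold gives
    # half-pixel boundary accuracy, which matters for few-pixel nodules
    R, C = np.meshgrid(
        np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij"
    )
    sr = gr + (R - gr) / scale
    sc = gc + (C - gc) / scale
    vals = ndimage.map_coordinates(
        mask.astype(np.float32), [sr, sc], order=1, mode="constant", cval=0.0
    )
    scaled = vals >= 0.5

    eq_diam = 2.0 * np.sqrt(scaled.sum() / np.pi)
    if eq_diam < 2.0:
        raise SizeError(
            f"resized nodule equivalent diameter {eq_diam:.2f} px < 2 px minimum"
        )
    out = arr.copy()
    out[mask] = L.LUNG
    final = _clip_to_lung_contiguous(out, scaled)
    out[final] = L.NODULE
    return out


def one_hot(labels: np.ndarray) -> np.ndarray:
    """Expand a map to a (6, H, W) binary float32 stack (one channel hot)."""
    arr = L.validate_map(labels)
    stack = np.zeros((L.N_LABELS,) + arr.shape, dtype=np.float32)
    for k in range(L.N_LABELS):
        stack[k] = arr == k
    return stack


def dice(a: np.ndarray, b: np.ndarray, label: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of one label; 1.0 when both empty."""
    aa, bb = np.asarray(a), np.asarray(b)
    if aa.shape != bb.shape:
        raise DataError(f"shape mismatch {aa.shape} vs {bb.shape}")
    ma, mb = aa == label, bb == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def save_map(labels: np.ndarray, path: str | Path) -> None:
    np.savez_compressed(path, labels=L.validate_map(labels))


def load_map(path: str | Path) -> np.ndarray:
    with np.load(path) as npz:
        if "labels" not in npz:
            raise DataError(f"{path} is not an annotation-map archive")
        return L.validate_map(npz["labels"])


def save_map_png(labels: np.ndarray, path: str | Path) -> None:
    """Export as an 8-bit indexed PNG with the fixed label palette."""
    from PIL import Image

    arr = L.validate_map(labels)
    img = Image.fromarray(arr, mode="P")
    img.putpalette(L.PALETTE.flatten().tolist())
    img.save(str(path))
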