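"""Slice preprocessing: volume I/O, lung-window harmonization, data splits.

All slices are harmonized by clipping Hounsfield units to the lung display
window [-1350, 150] HU and mapped affinely to [0, 1] for the network.
Data splits are made at the *scan* level so that near-duplicate neighbouring
slices of one scan can never straddle a train/test boundary; the degraded
control subsets (defaults 2% and 0.3% of the training slice pool) are drawn
at the slice level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, MetadataError, ParameterError, SizeError
from .phantom import PhantomCorpus

logger = logging.getLogger(__name__)

#: The lung display window (lo, hi) in HU used to harmonize all slices.
LUNG_WINDOW: tuple[float, float] = (-1350.0, 150.0)


@dataclass
class HUVolume:
    """A 3D stack of slices in Hounsfield units."""

    voxels: np.ndarray
    scan_id: str
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[self.slice_axis] < 1:
            raise DataError("volume must be 3D with at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("volume contains non-finite HU values")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]

    def slice_at(self, index: int) -> np.ndarray:
        return np.take(self.voxels, index, axis=self.slice_axis)


def read_volume(path: str | Path, format: str | None = None) -> HUVolume:
    """Read a CT volume from a DICOM series directory, NIfTI file, or NPZ.

    DICOM stored values are converted to HU with the per-file rescale
    slope/intercept; missing rescale tags raise :class:`MetadataError`
    rather than silently assuming identity.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "dicom-series"
        elif path.suffix == ".npz":
            format = "npz"
        elif path.suffix in (".nii", ".gz"):
            format = "nifti"
        else:
            raise ParameterError(f"cannot infer volume format from {path}")

    if format == "npz":
        with np.load(path) as npz:
            if "voxels" not in npz:
                raise DataError(f"{path} has no 'voxels' array")
            scan_id = str(npz["scan_id"]) if "scan_id" in npz else path.stem
            return HUVolume(voxels=npz["voxels"].astype(np.float32), scan_id=scan_id)

    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        if data.ndim == 2:
            data = data[None]
        # NIfTI stores (x, y, z); slices index the last axis
        return HUVolume(voxels=data, scan_id=path.stem, slice_axis=data.ndim - 1)

    if format == "dicom-series":
        import pydicom

        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
        if not files:
            raise DataError(f"no .dcm files in {path}")
        slices = []
        for f in files:
            ds = pydicom.dcmread(str(f))
            if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
                raise MetadataError(
                    f"{f} lacks RescaleSlope/RescaleIntercept; cannot convert to HU"
                )
            hu = ds.pixel_array.astype(np.float32) * float(ds.RescaleSlope) + float(
                ds.RescaleIntercept
            )
            key = getattr(ds, "InstanceNumber", len(slices))
            slices.append((int(key), hu))
        slices.sort(key=lambda kv: kv[0])
        return HUVolume(
            voxels=np.stack([hu for _, hu in slices]), scan_id=path.name
        )

    raise ParameterError(f"unsupported volume format: {format!r}")


def window_hu(
    pixels: np.ndarray,
    lo: float = LUNG_WINDOW[0],
    hi: float = LUNG_WINDOW[1],
) -> np.ndarray:
    """Clip a slice to an HU display window (defaults: the lung window)."""
    if lo >= hi:
        raise ParameterError(f"window lo must be < hi, got [{lo}, {hi}]")
    return np.clip(np.asarray(pixels, dtype=np.float32), lo, hi)


def normalize(
    pixels: np.ndarray,
    window: tuple[float, float] = LUNG_WINDOW,
) -> np.ndarray:
    """Affinely map a windowed slice to [0, 1] (lo -> 0, hi -> 1)."""
    lo, hi = window
    if lo >= hi:
        raise ParameterError(f"window lo must be < hi, got [{lo}, {hi}]")
    return ((np.asarray(pixels, dtype=np.float32) - lo) / (hi - lo)).astype(np.float32)


def denormalize(
    image: np.ndarray,
    window: tuple[float, float] = LUNG_WINDOW,
) -> np.ndarray:
    """Inverse of :func:`normalize`: map [0, 1] back to HU."""
    lo, hi = window
    return (np.asarray(image, dtype=np.float32) * (hi - lo) + lo).astype(np.float32)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class DataSplit:
    """Scan-level train/val/test partition plus slice-level control subsets.

    ``control_indices`` maps each control fraction to the corpus slice
    indices (into the full corpus) of that degraded-training subset; both
    subsets are drawn uniformly without replacement from the training pool.
    """

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    control_fractions: tuple[float, ...]
    control_indices: dict[float, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def slice_indices(self, corpus: PhantomCorpus, which: str) -> np.ndarray:
        ids = {"train": self.train_ids, "val": self.val_ids, "test": self.test_ids}[
            which
        ]
        idset = set(ids)
        return np.array(
            [i for i, sid in enumerate(corpus.scan_ids) if sid in idset], dtype=int
        )


def split_dataset(
    corpus: PhantomCorpus,
    test_fraction: float = 0.15,
    val_fraction: float = 0.0,
    control_fractions: tuple[float, ...] = (0.02, 0.003),
    seed: int = 0,
) -> DataSplit:
    """Partition a corpus by scan and draw control subsets from training.

    Subset sizes use round-half-away-from-zero with a floor of one item
    (a warning is logged when the floor engages).
    """
    if not (0.0 < test_fraction < 1.0) or not (0.0 <= val_fraction < 1.0):
        raise ParameterError("fractions must lie in (0,1) (val may be 0)")
    if test_fraction + val_fraction >= 1.0:
        raise ParameterError("test_fraction + val_fraction must be < 1")
    for f in control_fractions:
        if not 0.0 < f < 1.0:
            raise ParameterError(f"control fraction {f} outside (0,1)")

    scan_order: list[str] = []
    for sid in corpus.scan_ids:
        if sid not in scan_order:
            scan_order.append(sid)
    n_scans = len(scan_order)
    if n_scans < 2:
        raise SizeError("need at least 2 scans for a scan-level split")

    rng = np.random.default_rng(seed)
    perm = [scan_order[i] for i in rng.permutation(n_scans)]

    def take(fraction: float, pool_size: int) -> int:
        if fraction <= 0:
            return 0
        n = _round_half_away(fraction * pool_size)
        if n == 0:
            logger.warning(
                "fraction %.4f of %d rounds to 0; clamped to 1", fraction, pool_size
            )
            n = 1
        return n

    n_test = take(test_fraction, n_scans)
    n_val = take(val_fraction, n_scans)
    if n_test + n_val >= n_scans:
        raise SizeError(
            f"test+val scans ({n_test}+{n_val}) leave no training scans of {n_scans}"
        )
    test_ids = perm[:n_test]
    val_ids = perm[n_test : n_test + n_val]
    train_ids = perm[n_test + n_val :]

    split = DataSplit(
        train_ids=train_ids,
        val_ids=val_ids,
        test_ids=test_ids,
        control_fractions=tuple(control_fractions),
        seed=seed,
    )
    train_slices = split.slice_indices(corpus, "train")
    for f in control_fractions:
        n = take(f, len(train_slices))
        if n > len(train_slices):
            raise SizeError(f"control fraction {f} needs more slices than available")
        chosen = rng.choice(train_slices, size=n, replace=False)
        split.control_indices[f] = np.sort(chosen)
    return split
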