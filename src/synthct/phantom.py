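"""Procedural chest-CT phantoms.

Generates 2D chest-like slices in Hounsfield units together with
ground-truth annotation maps, so the whole pipeline — segmentation,
synthesis, evaluation — can be exercised without any external imaging
data.  A phantom slice has the label-vs-HU structure of an axial chest
slice: an elliptical body with a subcutaneous fat/skin rim, soft-tissue
interior, a dense vertebral body, two air-filled lungs carrying bright
curvilinear "vessels", and optionally a soft-tissue-density nodule inside
a lung.

Phantoms are statistical stand-ins, not physical simulations: there is no
projection geometry, beam hardening or partial-volume averaging.  Their
purpose is that every pixel's true label is known by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import labels as L
from .errors import ConstraintError, DataError
from .geometry import NoduleSpec, bezier_stroke, ellipse_mask, nodule_mask

#: Default HU distribution per label: mean, sd.  Chosen to sit correctly
#: inside/outside the lung display window [-1350, 150]: air-like lungs,
#: fat-like body rim, water/muscle-like soft tissue, bone-like dense
#: tissue, and soft-tissue-density nodules that stand out against lung.
DEFAULT_HU_TABLE: dict[int, tuple[float, float]] = {
    L.EXTERIOR: (-1000.0, 0.0),
    L.BODY: (-200.0, 25.0),
    L.SOFT: (40.0, 20.0),
    L.DENSE: (700.0, 150.0),
    L.LUNG: (-800.0, 60.0),
    L.NODULE: (-50.0, 40.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one phantom slice.

    ``body_axes`` / ``lung_axes`` are (row, col) semi-axes in pixels;
    ``None`` selects anatomy-proportional defaults for ``image_side``.
    """

    image_side: int = 64
    body_axes: tuple[float, float] | None = None
    lung_axes: tuple[float, float] | None = None
    n_vessels: int = 3
    nodule: NoduleSpec | None = None
    hu_table: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HU_TABLE)
    )
    noise_sd: float = 20.0
    seed: int = 0

    def resolved_body_axes(self) -> tuple[float, float]:
        s = self.image_side
        return self.body_axes if self.body_axes is not None else (0.34 * s, 0.44 * s)

    def resolved_lung_axes(self) -> tuple[float, float]:
        s = self.image_side
        return self.lung_axes if self.lung_axes is not None else (0.17 * s, 0.11 * s)

    def validate(self) -> None:
        if self.image_side < 16:
            raise ConstraintError("image_side must be >= 16 px")
        mu = {k: v[0] for k, v in self.hu_table.items()}
        if not (
            mu[L.LUNG] < mu[L.NODULE] <= mu[L.SOFT] < mu[L.DENSE]
        ):
            raise ConstraintError(
                "hu_table means must be ordered lung < nodule <= soft < dense, "
                f"got lung={mu[L.LUNG]}, nodule={mu[L.NODULE]}, "
                f"soft={mu[L.SOFT]}, dense={mu[L.DENSE]}"
            )
        if self.noise_sd < 0:
            raise ConstraintError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScannerStyle:
    """Acquisition-style appearance knobs (scanner look, not anatomy)."""

    intensity_offset: float = 0.0
    gantry_ring: bool = False
    table_pad: bool = False
    extra_noise_sd: float = 0.0

    def validate(self) -> None:
        if abs(self.intensity_offset) > 100:
            raise ConstraintError(
                f"intensity_offset must be within +/-100 HU, got {self.intensity_offset}"
            )
        if self.extra_noise_sd < 0:
            raise ConstraintError("extra_noise_sd must be >= 0")


def _lung_centers(spec: PhantomSpec) -> list[tuple[float, float]]:
    s = spec.image_side
    cr, cc = 0.50 * s, 0.50 * s
    dc = 0.165 * s
    return [(cr - 0.02 * s, cc - dc), (cr - 0.02 * s, cc + dc)]


def _build_label_map(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the ground-truth label map; also return the vessel mask."""
    s = spec.image_side
    shape = (s, s)
    center = (0.50 * s, 0.50 * s)
    body = ellipse_mask(shape, center, spec.resolved_body_axes())

    rim_width = max(1, int(round(0.05 * s)))
    interior = ndimage.binary_erosion(body, iterations=rim_width)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[body] = L.BODY
    labels[interior] = L.SOFT

    # vertebral body: dense ellipse at the posterior midline
    vert = ellipse_mask(
        shape, (center[0] + 0.62 * spec.resolved_body_axes()[0], center[1]),
        (0.07 * s, 0.09 * s),
    )
    labels[vert & interior] = L.DENSE

    lung_axes = spec.resolved_lung_axes()
    vessels = np.zeros(shape, dtype=bool)
    for lc in _lung_centers(spec):
        lung = ellipse_mask(shape, lc, lung_axes)
        if not np.all(interior[lung]):
            raise ConstraintError(
                "lung ellipse extends outside the body interior; shrink "
                "lung_axes or grow body_axes"
            )
        labels[lung] = L.LUNG
        # vessels: bright strokes fanning out from the hilum (medial edge)
        hilum = (lc[0], lc[1] + (0.7 * lung_axes[1] if lc[1] < center[1] else -0.7 * lung_axes[1]))
        width = 1 if s < 256 else 2
        for _ in range(spec.n_vessels):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.4, 0.9)
            p2 = (
                lc[0] + rad * lung_axes[0] * np.sin(ang),
                lc[1] + rad * lung_axes[1] * np.cos(ang),
            )
            mid = (
                (hilum[0] + p2[0]) / 2 + rng.uniform(-0.1, 0.1) * lung_axes[0],
                (hilum[1] + p2[1]) / 2 + rng.uniform(-0.1, 0.1) * lung_axes[1],
            )
            vessels |= bezier_stroke(shape, hilum, mid, p2, width=width) & lung

    if spec.nodule is not None:
        r, c = spec.nodule.center
        ri, ci = int(round(r)), int(round(c))
        if labels[ri, ci] != L.LUNG:
            raise ConstraintError(
                f"nodule center {spec.nodule.center} is not inside a lung "
                f"(label there is {L.LABEL_NAMES[int(labels[ri, ci])]})"
            )
        nod = nodule_mask(shape, spec.nodule, rng) & (labels == L.LUNG)
        labels[nod] = L.NODULE
        vessels &= labels == L.LUNG

    return labels, vessels


def generate_phantom_slice(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom slice.

    Returns
    -------
    pixels : float32 array (side, side)
        Raw HU values: per-label Gaussian draws from ``hu_table`` plus
        global Gaussian noise of sd ``noise_sd``.
    labels : uint8 array (side, side)
        Ground-truth annotation map.

    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels, vessels = _build_label_map(spec, rng)

    pixels = np.empty(labels.shape, dtype=np.float64)
    for lab, (mu, sd) in spec.hu_table.items():
        mask = labels == lab
        n = int(mask.sum())
        if n == 0:
            continue
        pixels[mask] = mu if sd == 0 else rng.normal(mu, sd, size=n)
    # vessels render at soft-tissue HU but remain part of the lung label
    nv = int(vessels.sum())
    if nv:
        mu, sd = spec.hu_table[L.SOFT]
        pixels[vessels] = mu if sd == 0 else rng.normal(mu, sd, size=nv)
    if spec.noise_sd > 0:
        pixels += rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    return pixels.astype(np.float32), labels


def apply_scanner_style(
    pixels: np.ndarray,
    style: ScannerStyle,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Re-render a raw HU slice under a different scanner appearance.

    The intensity offset shifts pixels inside the body only; the gantry
    ring and patient table are drawn in the exterior; extra noise applies
    everywhere.  With ``labels`` the ground-truth body/exterior partition
    is used, otherwise the body is taken as HU > -500.
    """
    style.validate()
    rng = np.random.default_rng(seed)
    out = np.asarray(pixels, dtype=np.float32).copy()
    if labels is not None:
        body = np.asarray(labels) != L.EXTERIOR
    else:
        body = ndimage.binary_fill_holes(out > -500.0)
    exterior = ~body

    if style.intensity_offset:
        out[body] += style.intensity_offset
    s = out.shape[0]
    if style.gantry_ring:
        rr, cc = np.ogrid[: out.shape[0], : out.shape[1]]
        dist = np.hypot(rr - s / 2, cc - out.shape[1] / 2)
        ring = (np.abs(dist - 0.48 * s) <= max(1.0, 0.008 * s)) & exterior
        out[ring] = -200.0
    if style.table_pad:
        pad = np.zeros_like(exterior)
        pad[int(0.92 * s) : int(0.97 * s), int(0.25 * s) : int(0.75 * s)] = True
        out[pad & exterior] = 100.0
    if style.extra_noise_sd > 0:
        out += rng.normal(0.0, style.extra_noise_sd, size=out.shape).astype(np.float32)
    return out


@dataclass
class PhantomCorpus:
    """An ordered collection of phantom slices with ground truth.

    Scans share a per-scan base geometry (slices of one scan resemble each
    other, jittered <= 5% per slice) and a per-scan scanner style, so
    scan-level data splits and style encoding are both meaningful.
    """

    slices: np.ndarray  # float32 (n, side, side), raw HU
    maps: np.ndarray  # uint8 (n, side, side)
    scan_ids: list[str]
    slice_indices: list[int]
    has_nodule: np.ndarray  # bool (n,)
    nodule_prevalence: float
    seed: int

    def __len__(self) -> int:
        return self.slices.shape[0]

    @property
    def image_side(self) -> int:
        return self.slices.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize as one NPZ archive with an embedded JSON manifest."""
        manifest = {
            "scan_ids": self.scan_ids,
            "slice_indices": self.slice_indices,
            "has_nodule": [bool(b) for b in self.has_nodule],
            "nodule_prevalence": self.nodule_prevalence,
            "seed": self.seed,
        }
        np.savez_compressed(
            path,
            slices=self.slices,
            maps=self.maps,
            manifest=np.frombuffer(
                json.dumps(manifest).encode("utf-8"), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PhantomCorpus":
        with np.load(path) as npz:
            if "manifest" not in npz or "slices" not in npz:
                raise DataError(f"{path} is not a phantom corpus archive")
            manifest = json.loads(bytes(npz["manifest"].tobytes()).decode("utf-8"))
            return cls(
                slices=npz["slices"],
                maps=npz["maps"],
                scan_ids=list(manifest["scan_ids"]),
                slice_indices=list(manifest["slice_indices"]),
                has_nodule=np.asarray(manifest["has_nodule"], dtype=bool),
                nodule_prevalence=float(manifest["nodule_prevalence"]),
                seed=int(manifest["seed"]),
            )


def _sample_nodule(
    spec: PhantomSpec, rng: np.random.Generator
) -> NoduleSpec:
    """Sample a nodule placed safely inside one of the lungs."""
    s = spec.image_side
    diameter = float(np.clip(rng.uniform(0.08, 0.16) * s, 3.0, 0.16 * s))
    lung_axes = spec.resolved_lung_axes()
    lc = _lung_centers(spec)[int(rng.integers(0, 2))]
    # keep the whole disk inside the lung ellipse: shrink placement axes
    ar = max(1.0, lung_axes[0] - diameter / 2 - 1)
    ac = max(1.0, lung_axes[1] - diameter / 2 - 1)
    while True:
        u, v = rng.uniform(-1, 1, size=2)
        if u * u + v * v <= 1:
            break
    return NoduleSpec(
        center=(lc[0] + u * ar, lc[1] + v * ac),
        diameter=diameter,
        roughness=float(rng.uniform(0.1, 0.5)),
    )


def generate_phantom_corpus(
    n_scans: int,
    slices_per_scan: int,
    nodule_prevalence: float = 0.17,
    seed: int = 0,
    image_side: int = 64,
    scanner_variation: bool = True,
) -> PhantomCorpus:
    """Generate a corpus of phantom scans.

    Nodule presence is Bernoulli(``nodule_prevalence``) per slice — the
    default matches the fraction of nodule-bearing slices in typical
    screening chest-CT collections (~17%).  With ``scanner_variation``
    each scan receives a random intensity offset (+/-60 HU) and sometimes
    a visible gantry ring, giving the style encoder genuine appearance
    variation to learn.
    """
    if n_scans * slices_per_scan < 1:
        raise ConstraintError("corpus must contain at least one slice")
    if not 0.0 <= nodule_prevalence <= 1.0:
        raise ConstraintError("nodule_prevalence must be in [0, 1]")

    rng = np.random.default_rng(seed)
    s = image_side
    slices, maps, scan_ids, slice_idx, has_nod = [], [], [], [], []
    for i_scan in range(n_scans):
        scan_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        base_body = (
            0.34 * s * scan_rng.uniform(0.95, 1.08),
            0.44 * s * scan_rng.uniform(0.95, 1.08),
        )
        base_lung = (
            0.17 * s * scan_rng.uniform(0.90, 1.05),
            0.11 * s * scan_rng.uniform(0.90, 1.05),
        )
        n_vessels = int(scan_rng.integers(2, 5))
        style = ScannerStyle(
            intensity_offset=float(scan_rng.uniform(-60, 60)),
            gantry_ring=bool(scan_rng.uniform() < 0.3),
            table_pad=bool(scan_rng.uniform() < 0.3),
            extra_noise_sd=float(scan_rng.uniform(0, 10)),
        ) if scanner_variation else ScannerStyle()
        for i_slice in range(slices_per_scan):
            jitter = lambda ax: tuple(  # noqa: E731 - local helper
                a * scan_rng.uniform(0.97, 1.03) for a in ax
            )
            spec = PhantomSpec(
                image_side=s,
                body_axes=jitter(base_body),
                lung_axes=jitter(base_lung),
                n_vessels=n_vessels,
                seed=int(scan_rng.integers(0, 2**31 - 1)),
            )
            nodule_here = bool(scan_rng.uniform() < nodule_prevalence)
            if nodule_here:
                spec = replace(spec, nodule=_sample_nodule(spec, scan_rng))
            pixels, lab = generate_phantom_slice(spec)
            pixels = apply_scanner_style(
                pixels, style, seed=int(scan_rng.integers(0, 2**31 - 1)), labels=lab
            )
            slices.append(pixels)
            maps.append(lab)
            scan_ids.append(f"scan{i_scan:04d}")
            slice_idx.append(i_slice)
            has_nod.append(nodule_here)

    return PhantomCorpus(
        slices=np.stack(slices),
        maps=np.stack(maps),
        scan_ids=scan_ids,
        slice_indices=slice_idx,
        has_nodule=np.asarray(has_nod, dtype=bool),
        nodule_prevalence=nodule_prevalence,
        seed=seed,
    )
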