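"""Raster geometry shared by the phantom generator and the annotation editor.

Coordinates are 0-based ``(row, col)``.  All randomness is funnelled through
an explicit :class:`numpy.random.Generator` so callers own determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConstraintError


@dataclass(frozen=True)
class NoduleSpec:
    """Parametric description of a nodule label region.

    Parameters
    ----------
    center : (row, col)
        0-based pixel coordinates of the nodule centroid.
    diameter : float
        Nominal diameter in pixels (>= 2).
    roughness : float
        Boundary irregularity in [0, 1]; 0 is a perfect disk, larger values
        perturb the radius with smooth angular harmonics, mimicking the
        spiculated margins of real pulmonary nodules.
    id : int
        Caller-assigned identifier.
    """

    center: tuple[float, float]
    diameter: float
    roughness: float = 0.0
    id: int = 1

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if self.diameter < 2:
            raise ConstraintError(
                f"nodule diameter must be >= 2 px, got {self.diameter}"
            )
        if not 0.0 <= self.roughness <= 1.0:
            raise ConstraintError(f"roughness must be in [0, 1], got {self.roughness}")
        if shape is not None:
            r, c = self.center
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ConstraintError(
                    f"nodule center {self.center} outside image bounds {shape}"
                )


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
) -> np.ndarray:
    """Boolean mask of a filled axis-aligned ellipse."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    ar, ac = semi_axes
    return ((rr - center[0]) / ar) ** 2 + ((cc - center[1]) / ac) ** 2 <= 1.0


def nodule_mask(
    shape: tuple[int, int],
    spec: NoduleSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize an (optionally irregular) nodule disk as a boolean mask.

    The boundary radius is ``r0 * (1 + roughness * f(theta))`` where ``f`` is
    a seeded sum of low-order angular harmonics with zero mean and unit peak
    scale, so the expected area stays close to the perfect-disk area.
    """
    spec.validate(shape)
    r0 = spec.diameter / 2.0
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    dist = np.hypot(dr, dc)
    if spec.roughness == 0.0:
        return dist <= r0
    theta = np.arctan2(dr, dc)
    # 3 harmonics, orders 2..4: smooth lobulated outline
    radius = np.full(theta.shape, r0)
    amp = spec.roughness * r0 * 0.35
    for k, order in enumerate(range(2, 5)):
        phase = rng.uniform(0, 2 * np.pi)
        weight = rng.uniform(0.3, 1.0)
        radius = radius + amp * weight / (k + 1) * np.cos(order * theta + phase)
    return dist <= radius


def bezier_stroke(
    shape: tuple[int, int],
    p0: tuple[float, float],
    p1: tuple[float, float],
    p2: tuple[float, float],
    width: int = 1,
) -> np.ndarray:
    """Boolean mask of a quadratic Bezier stroke of the given pixel width."""
    n = int(4 * (abs(p2[0] - p0[0]) + abs(p2[1] - p0[1])) + 8)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (
        (1 - t) ** 2 * np.asarray(p0)
        + 2 * (1 - t) * t * np.asarray(p1)
        + t**2 * np.asarray(p2)
    )
    mask = np.zeros(shape, dtype=bool)
    radius = max(0, (width - 1))
    for r, c in pts:
        ri, ci = int(round(r)), int(round(c))
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, cc = ri + dr, ci + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    mask[rr, cc] = True
    return mask
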