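"""Image-similarity metrics and per-model evaluation reports.

SSIM is the primary metric, computed on [0, 1]-normalized windowed slices
with the literature-standard parameterization (11x11 Gaussian window,
sigma 1.5, K1=0.01, K2=0.03, L=1).  MSE and PSNR accompany it as generic
secondary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from ..errors import DataError, ParameterError
from ..preprocess import LUNG_WINDOW, normalize, window_hu
from ..synthesis import ModelBundle, synthesize


@dataclass(frozen=True)
class SSIMParams:
    window_side: int = 11
    window_sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def validate(self, image_side: int) -> None:
        if self.window_side % 2 == 0 or self.window_side > image_side:
            raise ParameterError(
                f"SSIM window must be odd and <= image side, got "
                f"{self.window_side} for side {image_side}"
            )
        if self.k1 <= 0 or self.k2 <= 0:
            raise ParameterError("k1 and k2 must be > 0")


def ssim(
    a: np.ndarray, b: np.ndarray, params: SSIMParams | None = None
) -> tuple[float, np.ndarray]:
    """Mean structural similarity and the local SSIM map."""
    params = params or SSIMParams()
    aa = np.asarray(a, dtype=np.float64)
    bb = np.asarray(b, dtype=np.float64)
    if aa.shape != bb.shape:
        raise DataError(f"shape mismatch {aa.shape} vs {bb.shape}")
    params.validate(min(aa.shape))
    score, local = structural_similarity(
        aa,
        bb,
        win_size=params.window_side,
        gaussian_weights=True,
        sigma=params.window_sigma,
        K1=params.k1,
        K2=params.k2,
        data_range=params.data_range,
        use_sample_covariance=False,
        full=True,
    )
    return float(score), local


def mse(a: np.ndarray, b: np.ndarray) -> float:
    aa, bb = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if aa.shape != bb.shape:
        raise DataError(f"shape mismatch {aa.shape} vs {bb.shape}")
    return float(np.mean((aa - bb) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / err))


@dataclass
class MetricReport:
    """Per-pair metric rows plus recomputable aggregates."""

    per_pair: pd.DataFrame  # columns: pair_id, ssim, mse, psnr

    def aggregates(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        n = len(self.per_pair)
        for metric in ("ssim", "mse", "psnr"):
            vals = self.per_pair[metric].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            m = float(finite.mean())
            sd = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
            half = 1.96 * sd / np.sqrt(max(1, len(finite)))
            out[metric] = {
                "mean": m,
                "sd": sd,
                "ci95": (m - half, m + half),
                "n": n,
            }
        return out


def evaluate_model(
    bundle: ModelBundle,
    maps: np.ndarray,
    originals_hu: np.ndarray,
    pair_ids: list | None = None,
    ssim_params: SSIMParams | None = None,
    window: tuple[float, float] = LUNG_WINDOW,
    seed: int = 0,
) -> MetricReport:
    """Synthesize one image per test map and score it against the original.

    Style is paired: each test original guides its own synthetic image
    (posterior-mean latent), which is what makes pairwise SSIM meaningful.
    """
    maps = np.asarray(maps)
    originals_hu = np.asarray(originals_hu, dtype=np.float32)
    if maps.ndim != 3 or maps.shape != originals_hu.shape:
        raise DataError("maps and originals must align as (N, H, W)")
    if maps.shape[0] == 0:
        raise DataError("empty test set")
    if maps.shape[1] != bundle.config.image_side:
        raise DataError(
            f"test side {maps.shape[1]} != bundle side {bundle.config.image_side}"
        )
    ids = pair_ids if pair_ids is not None else list(range(maps.shape[0]))
    rows = []
    for i, pid in enumerate(ids):
        orig_n = normalize(window_hu(originals_hu[i], *window), window)
        synth_hu = synthesize(bundle, maps[i], style=orig_n, seed=seed + i,
                              window=window)
        synth_n = normalize(synth_hu, window)
        s, _ = ssim(orig_n, synth_n, ssim_params)
        rows.append(
            {
                "pair_id": pid,
                "ssim": s,
                "mse": mse(orig_n, synth_n),
                "psnr": psnr(orig_n, synth_n),
            }
        )
    return MetricReport(per_pair=pd.DataFrame(rows))
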