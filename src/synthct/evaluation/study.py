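"""Blinded reader-study harness: quartet construction and scoring.

A quartet presents one original test image alongside the three synthetic
renderings of the *same* annotation map (primary set, control set 1,
control set 2), in uniformly random positions.  Readers pick the image
they believe is the original and score every image from 1 (unrealistic)
to 4 (almost indistinguishable from an original).  The blinding key is
stored separately from the exported images and is only consulted at
scoring time; partial completion (a reader answering only some quartets)
is handled naturally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import DataError, SizeError
from ..preprocess import LUNG_WINDOW, normalize, window_hu

SET_NAMES = ("original", "primary", "control1", "control2")


@dataclass
class QuartetRecord:
    quartet_id: int
    pair_id: object
    positions: dict[str, int]  # set name -> position 1..4
    seed: int

    def __post_init__(self) -> None:
        if sorted(self.positions.keys()) != sorted(SET_NAMES):
            raise DataError(f"quartet needs exactly the sets {SET_NAMES}")
        if sorted(self.positions.values()) != [1, 2, 3, 4]:
            raise DataError("positions must be a bijection onto 1..4")

    def set_at(self, position: int) -> str:
        for name, pos in self.positions.items():
            if pos == position:
                return name
        raise DataError(f"invalid position {position}")


@dataclass
class ReaderResponse:
    reader_id: str
    quartet_id: int
    chosen_position: int
    scores: dict[int, int] = field(default_factory=dict)  # position -> 1..4

    def __post_init__(self) -> None:
        if self.chosen_position not in (1, 2, 3, 4):
            raise DataError(f"chosen_position must be 1..4, got {self.chosen_position}")
        for pos, sc in self.scores.items():
            if pos not in (1, 2, 3, 4) or not 1 <= sc <= 4:
                raise DataError(f"score {sc} at position {pos} outside scale")


def build_quartets(
    originals: dict,
    primary: dict,
    control1: dict,
    control2: dict,
    n_quartets: int,
    seed: int = 0,
    export_dir: str | Path | None = None,
    window: tuple[float, float] = LUNG_WINDOW,
) -> list[QuartetRecord]:
    """Assemble blinded quartets from four image sets keyed by pair id.

    Originals are sampled without replacement; all four images of a
    quartet must exist for the sampled pair id (same annotation-map
    provenance).  With ``export_dir``, windowed 8-bit PNGs are written
    under ``export_dir/images`` with opaque names (``q017_p3.png``) and
    the unblinding key as ``export_dir/key.csv``.
    """
    sets = {"original": originals, "primary": primary,
            "control1": control1, "control2": control2}
    common = set(originals)
    for name, d in sets.items():
        missing = common - set(d)
        if missing:
            raise DataError(f"set {name} lacks pair ids {sorted(missing)[:5]} ...")
    if n_quartets > len(originals):
        raise SizeError(
            f"requested {n_quartets} quartets but only {len(originals)} originals"
        )

    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(sorted(originals), dtype=object),
                        size=n_quartets, replace=False)
    records = []
    for qid, pid in enumerate(chosen):
        perm = rng.permutation(4) + 1
        records.append(
            QuartetRecord(
                quartet_id=qid,
                pair_id=pid,
                positions={name: int(p) for name, p in zip(SET_NAMES, perm)},
                seed=seed,
            )
        )

    if export_dir is not None:
        from PIL import Image

        export_dir = Path(export_dir)
        img_dir = export_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            for name, pos in rec.positions.items():
                hu = np.asarray(sets[name][rec.pair_id], dtype=np.float32)
                u8 = (normalize(window_hu(hu, *window), window) * 255).astype(
                    np.uint8
                )
                Image.fromarray(u8, mode="L").save(
                    img_dir / f"q{rec.quartet_id:03d}_p{pos}.png"
                )
        with open(export_dir / "key.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["quartet_id", "pair_id", "position", "set"])
            for rec in records:
                for name, pos in rec.positions.items():
                    writer.writerow([rec.quartet_id, rec.pair_id, pos, name])
    return records


def score_study(
    records: list[QuartetRecord], responses: list[ReaderResponse]
) -> pd.DataFrame:
    """Aggregate reader responses into the study summary table.

    One row per set with the percentage of responses in which that set's
    image was chosen as the original, and the mean +/- sd of its 1-4
    scores.  Responses referencing unknown quartets raise
    :class:`DataError`; an empty response list is an error, never a table
    of silent zeros.
    """
    if not responses:
        raise DataError("no reader responses to score")
    by_id = {rec.quartet_id: rec for rec in records}
    orphans = [r.quartet_id for r in responses if r.quartet_id not in by_id]
    if orphans:
        raise DataError(f"responses reference unknown quartet ids {sorted(set(orphans))}")

    chosen_counts = {name: 0 for name in SET_NAMES}
    scores: dict[str, list[int]] = {name: [] for name in SET_NAMES}
    for resp in responses:
        rec = by_id[resp.quartet_id]
        chosen_counts[rec.set_at(resp.chosen_position)] += 1
        for pos, sc in resp.scores.items():
            scores[rec.set_at(pos)].append(sc)

    n = len(responses)
    rows = []
    for name in SET_NAMES:
        vals = np.asarray(scores[name], dtype=float)
        rows.append(
            {
                "set": name,
                "pct_identified_original": 100.0 * chosen_counts[name] / n,
                "mean_score": float(vals.mean()) if len(vals) else float("nan"),
                "sd_score": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_responses": n,
                "n_scores": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
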