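"""Training of the primary / degraded-control model family.

The two control models are deliberate negative controls: identical
architecture, config and seed discipline, but trained on only 2% and
0.3% of the training slice pool, yielding images of visibly lower
quality against which the primary model's realism is judged.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np

from ..phantom import PhantomCorpus
from ..preprocess import DataSplit, LUNG_WINDOW, normalize, window_hu
from ..synthesis import GeneratorConfig, ModelBundle, build_models, train

logger = logging.getLogger(__name__)

FAMILY_NAMES = ("primary", "control1", "control2")


def _corpus_hash(corpus: PhantomCorpus) -> str:
    return hashlib.sha1(np.ascontiguousarray(corpus.slices).tobytes()).hexdigest()[
        :16
    ]


def train_model_family(
    corpus: PhantomCorpus,
    split: DataSplit,
    config: GeneratorConfig,
    window: tuple[float, float] = LUNG_WINDOW,
) -> dict[str, ModelBundle]:
    """Train primary + two degraded controls, differing only in data subset.

    Returns bundles keyed ``primary`` / ``control1`` / ``control2`` whose
    manifests record the subset fraction actually used (1.0, then the
    split's control fractions, by default 0.02 and 0.003).
    """
    chash = _corpus_hash(corpus)
    train_idx = split.slice_indices(corpus, "train")
    subsets: dict[str, tuple[float, np.ndarray]] = {
        "primary": (1.0, train_idx)
    }
    for name, frac in zip(FAMILY_NAMES[1:], split.control_fractions):
        subsets[name] = (frac, split.control_indices[frac])

    bundles: dict[str, ModelBundle] = {}
    for name, (frac, idx) in subsets.items():
        if len(idx) < config.batch_size:
            logger.warning(
                "%s subset (%d slices) smaller than batch size %d; "
                "batch adjusted down",
                name,
                len(idx),
                config.batch_size,
            )
        bundle = build_models(config)
        maps = corpus.maps[idx]
        images = normalize(window_hu(corpus.slices[idx], *window), window)
        train(bundle, maps, images, config)
        bundle.training_manifest = {
            "corpus_hash": chash,
            "subset_fraction": frac,
            "n_slices": int(len(idx)),
            "seed": config.seed,
        }
        bundles[name] = bundle
    return bundles
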