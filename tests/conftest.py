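"""Shared fixtures.

``desk_experiment`` is the expensive one: the full miniature synthesis
study (phantom corpus -> scan-level split -> primary + two degraded
control models -> held-out SSIM reports) repeated for three seeds.  It is
session-scoped and shared by the acceptance tests and the stochastic
synthesis property tests so training happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from synthct import phantom, preprocess, synthesis
from synthct.evaluation import evaluate_model, train_model_family

SEEDS = (0, 1, 2)
N_TEST_PAIRS = 50


@pytest.fixture(scope="session")
def small_corpus():
    """A quick 100-slice corpus for cheap structural tests."""
    return phantom.generate_phantom_corpus(
        n_scans=10, slices_per_scan=10, nodule_prevalence=0.2, seed=7
    )


@pytest.fixture(scope="session")
def desk_experiment():
    """Miniature synthesis study at 64x64: 300 slices, 3 seeds.

    Per seed: model family at training fractions (1.0, 0.02, 0.003),
    an untrained baseline, and SSIM reports on 50 held-out pairs.
    """
    out = {}
    for seed in SEEDS:
        corpus = phantom.generate_phantom_corpus(
            n_scans=20, slices_per_scan=15, nodule_prevalence=0.17, seed=seed
        )
        split = preprocess.split_dataset(corpus, test_fraction=0.2, seed=seed)
        config = synthesis.desk_profile(epochs=3, seed=seed)
        bundles = train_model_family(corpus, split, config)
        bundles["untrained"] = synthesis.build_models(config)
        test_idx = split.slice_indices(corpus, "test")[:N_TEST_PAIRS]
        reports = {
            name: evaluate_model(
                b, corpus.maps[test_idx], corpus.slices[test_idx], seed=seed
            )
            for name, b in bundles.items()
        }
        out[seed] = {
            "corpus": corpus,
            "split": split,
            "config": config,
            "bundles": bundles,
            "test_idx": test_idx,
            "reports": reports,
        }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
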