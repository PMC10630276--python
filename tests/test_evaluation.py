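"""Metrics, reader-study harness, and statistical tests."""

import numpy as np
import pytest
from scipy import stats as sps

from synthct import phantom, synthesis
from synthct.errors import (
    DataError,
    DegenerateStatisticError,
    ParameterError,
    SizeError,
)
from synthct.evaluation import (
    QuartetRecord,
    ReaderResponse,
    anova_oneway,
    build_quartets,
    evaluate_model,
    mse,
    ordinal_fit,
    psnr,
    score_study,
    ssim,
    tukey_hsd,
)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(0, 1, size=(64, 64))
        score, local = ssim(x, x)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert local.shape == x.shape

    def test_constant_images_closed_form(self):
        # zero-variance images: only the luminance term remains,
        # (2*mu_a*mu_b + C1) / (mu_a^2 + mu_b^2 + C1) with C1 = 1e-4
        a = np.full((32, 32), 0.5)
        b = np.full((32, 32), 0.25)
        expected = (2 * 0.5 * 0.25 + 1e-4) / (0.5**2 + 0.25**2 + 1e-4)
        score, _ = ssim(a, b)
        assert score == pytest.approx(expected, abs=1e-3)

    def test_symmetry_and_upper_bound(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 1, size=(32, 32))
            b = np.clip(a + rng.normal(0, 0.1, size=a.shape), 0, 1)
            sab, _ = ssim(a, b)
            sba, _ = ssim(b, a)
            assert sab == pytest.approx(sba, abs=1e-12)
            assert sab <= 1.0 + 1e-12

    def test_monotone_degradation_under_noise(self, rng):
        px, _ = phantom.generate_phantom_slice(phantom.PhantomSpec(seed=8))
        base = (px - px.min()) / (px.max() - px.min())
        sds = np.linspace(0.01, 0.5, 10)
        scores = []
        for sd in sds:
            noisy = np.clip(base + rng.normal(0, sd, base.shape), 0, 1)
            scores.append(ssim(base, noisy)[0])
        rho = sps.spearmanr(sds, scores).statistic
        assert rho < -0.9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            ssim(np.zeros((8, 8)), np.zeros((9, 9)))


class TestMSEPSNR:
    def test_identical_images(self):
        x = np.ones((8, 8)) * 0.3
        assert mse(x, x) == 0.0
        assert psnr(x, x) == float("inf")

    def test_hand_arithmetic(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)
        assert mse(a, b) == pytest.approx(0.01, abs=1e-12)
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8))
        assert mse(a, b) == mse(b, a)


class TestEvaluateModel:
    def test_report_rows_and_aggregate_consistency(self):
        corpus = phantom.generate_phantom_corpus(2, 4, 0.25, seed=13)
        bundle = synthesis.build_models(synthesis.desk_profile(seed=13))
        report = evaluate_model(bundle, corpus.maps, corpus.slices, seed=0)
        assert len(report.per_pair) == len(corpus)
        agg = report.aggregates()
        assert agg["ssim"]["mean"] == pytest.approx(
            report.per_pair["ssim"].mean(), abs=1e-9
        )
        assert agg["ssim"]["sd"] == pytest.approx(
            report.per_pair["ssim"].std(ddof=1), abs=1e-9
        )

    def test_empty_test_set_rejected(self):
        bundle = synthesis.build_models(synthesis.desk_profile(seed=13))
        with pytest.raises(DataError):
            evaluate_model(
                bundle,
                np.zeros((0, 64, 64), dtype=np.uint8),
                np.zeros((0, 64, 64), dtype=np.float32),
            )


class TestQuartets:
    @staticmethod
    def image_sets(n=70, side=16, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"pair{i}" for i in range(n)]
        mk = lambda: {i: rng.normal(-500, 300, (side, side)) for i in ids}  # noqa: E731
        return mk(), mk(), mk(), mk()

    def test_sixty_quartets_export_240_images_and_key(self, tmp_path):
        o, p, c1, c2 = self.image_sets()
        records = build_quartets(o, p, c1, c2, 60, seed=1, export_dir=tmp_path)
        assert len(records) == 60
        images = list((tmp_path / "images").glob("*.png"))
        assert len(images) == 240
        key_lines = (tmp_path / "key.csv").read_text().strip().splitlines()
        assert len(key_lines) == 1 + 240
        # opaque filenames: position only, never the set name
        assert not any("original" in f.name or "primary" in f.name for f in images)

    def test_every_record_has_one_original_per_position_bijection(self):
        o, p, c1, c2 = self.image_sets()
        for rec in build_quartets(o, p, c1, c2, 30, seed=2):
            assert sorted(rec.positions.values()) == [1, 2, 3, 4]

    def test_original_position_uniform(self):
        o, p, c1, c2 = self.image_sets(n=10)
        counts = np.zeros(4)
        # many independent small batches to accumulate position draws
        for seed in range(500):
            for rec in build_quartets(o, p, c1, c2, 4, seed=seed):
                counts[rec.positions["original"] - 1] += 1
        chi2 = sps.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_more_quartets_than_originals_rejected(self):
        o, p, c1, c2 = self.image_sets(n=5)
        with pytest.raises(SizeError):
            build_quartets(o, p, c1, c2, 6, seed=0)


class TestScoreStudy:
    @staticmethod
    def perfect_responses(records, reader="r1"):
        out = []
        for rec in records:
            scores = {pos: 1 for pos in (1, 2, 3, 4)}
            scores[rec.positions["original"]] = 4
            out.append(
                ReaderResponse(
                    reader_id=reader,
                    quartet_id=rec.quartet_id,
                    chosen_position=rec.positions["original"],
                    scores=scores,
                )
            )
        return out

    def test_perfect_readers(self):
        o, p, c1, c2 = TestQuartets.image_sets(n=30)
        records = build_quartets(o, p, c1, c2, 30, seed=3)
        table = score_study(records, self.perfect_responses(records))
        row = table.set_index("set").loc["original"]
        assert row["pct_identified_original"] == 100.0
        assert row["mean_score"] == 4.0
        assert table["pct_identified_original"].sum() == pytest.approx(100.0)

    def test_random_readers_near_quarter(self):
        o, p, c1, c2 = TestQuartets.image_sets(n=50)
        records = build_quartets(o, p, c1, c2, 50, seed=4)
        rng = np.random.default_rng(0)
        responses = [
            ReaderResponse(
                reader_id=f"r{k}",
                quartet_id=rec.quartet_id,
                chosen_position=int(rng.integers(1, 5)),
                scores={pos: int(rng.integers(1, 5)) for pos in (1, 2, 3, 4)},
            )
            for k in range(100)
            for rec in records
        ]
        table = score_study(records, responses).set_index("set")
        for name in table.index:
            assert table.loc[name, "pct_identified_original"] == pytest.approx(
                25.0, abs=2.0
            )

    def test_partial_completion_supported(self):
        o, p, c1, c2 = TestQuartets.image_sets(n=30)
        records = build_quartets(o, p, c1, c2, 30, seed=5)
        # a fifth reader answering only 21 of the quartets
        responses = self.perfect_responses(records[:21], reader="r5")
        table = score_study(records, responses).set_index("set")
        assert table.loc["original", "n_responses"] == 21

    def test_empty_responses_error(self):
        o, p, c1, c2 = TestQuartets.image_sets(n=5)
        records = build_quartets(o, p, c1, c2, 5, seed=6)
        with pytest.raises(DataError):
            score_study(records, [])

    def test_orphan_responses_listed(self):
        o, p, c1, c2 = TestQuartets.image_sets(n=5)
        records = build_quartets(o, p, c1, c2, 5, seed=7)
        bad = ReaderResponse("r1", 999, 1, {1: 1, 2: 1, 3: 1, 4: 1})
        with pytest.raises(DataError, match="999"):
            score_study(records, [bad])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_f(self):
        # groups {0,1} and {2,3}: SSB = 4 (df 1), SSW = 1 (df 2) -> F = 8
        f, p = anova_oneway([[0, 1], [2, 3]])
        assert f == pytest.approx(8.0, abs=1e-9)

    def test_degenerate_variance_flagged(self):
        with pytest.raises(DegenerateStatisticError):
            anova_oneway([[1, 1, 1], [2, 2, 2]])

    def test_tukey_identical_groups_p_near_one(self, rng):
        g = rng.normal(size=30)
        p = tukey_hsd([g, g.copy()])
        assert p[0, 1] > 0.99

    def test_tukey_flags_only_shifted_group(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        c = rng.normal(5, 1, 30)  # 5 sd shift
        p = tukey_hsd([a, b, c])
        assert np.allclose(p, p.T)
        assert p[0, 2] < 0.001 and p[1, 2] < 0.001
        assert p[0, 1] > 0.05


class TestOrdinalRegression:
    def test_single_set_rejected(self):
        with pytest.raises(ParameterError):
            ordinal_fit([1, 2, 3, 4], ["a", "a", "a", "a"])

    def test_recovers_generating_order(self, rng):
        # three sets with increasingly favourable score distributions
        sets, scores = [], []
        probs = {
            "s1_low": [0.7, 0.2, 0.08, 0.02],
            "s2_mid": [0.2, 0.4, 0.3, 0.1],
            "s3_high": [0.02, 0.08, 0.3, 0.6],
        }
        for name, pr in probs.items():
            draws = rng.choice([1, 2, 3, 4], size=120, p=pr)
            scores.extend(draws.tolist())
            sets.extend([name] * 120)
        fit = ordinal_fit(scores, sets)
        # reference is s1_low: both effects positive, s3 above s2
        assert fit.coefficients["s2_mid"] > 0
        assert fit.coefficients["s3_high"] > fit.coefficients["s2_mid"]
        assert fit.p_values["s3_high"] < 0.001

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        reps = 100
        for _ in range(reps):
            scores = rng.integers(1, 5, size=80)
            sets = np.repeat(["a", "b"], 40)
            try:
                fit = ordinal_fit(scores.tolist(), sets.tolist())
            except DegenerateStatisticError:
                continue
            rejections += fit.p_values["b"] < 0.05
        assert rejections / reps < 0.15
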