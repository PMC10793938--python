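import dataclasses
import math

import numpy as np
import pytest

from summr import uvmr
from summr.harmonize import HarmonizedInstrument, HarmonizedSet
from summr.synthetic_data import PleiotropyConfig, SimConfig, generate_univariable
from summr.synthetic_data import as_harmonized_set as harmonized_from_study


def inst(bx=0.1, sx=0.02, by=0.05, sy=0.02, vid="v"):
    return HarmonizedInstrument(vid, bx, sx, by, sy)


class TestWaldRatio:
    def test_arithmetic(self):
        e = uvmr.wald_ratio(inst(bx=0.1, by=0.05, sy=0.02))
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert uvmr.wald_ratio(inst(by=0.0)).beta == 0.0

    def test_zero_exposure_effect_hard_error(self):
        with pytest.raises(ValueError):
            uvmr.wald_ratio(inst(bx=0.0))

    def test_delta_se_against_monte_carlo(self):
        # strong instrument (|z_exp| > 10): delta SE within 5% of the SD of
        # simulated ratios
        bx, sx, by, sy = 0.2, 0.008, 0.08, 0.02
        e = uvmr.wald_ratio(inst(bx=bx, sx=sx, by=by, sy=sy))
        rng = np.random.default_rng(42)
        draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        assert e.se == pytest.approx(draws.std(), rel=0.05)


class TestIVW:
    def test_consensus_of_identical_ratios(self):
        hs = HarmonizedSet("e", "o", [inst(vid="a"), inst(vid="b")])
        assert uvmr.ivw(hs).beta == pytest.approx(0.5)

    def test_matches_closed_form_normal_equations(self, paper_like_set):
        bx, _, by, sy = paper_like_set.arrays()
        w = 1.0 / sy**2
        expected = np.sum(w * bx * by) / np.sum(w * bx**2)
        e = uvmr.ivw(paper_like_set)
        assert e.beta == pytest.approx(expected, abs=1e-10)
        assert e.se == pytest.approx(np.sum(w * bx**2) ** -0.5, abs=1e-12)

    def test_single_snp_hard_error(self):
        with pytest.raises(ValueError, match="wald"):
            uvmr.ivw(HarmonizedSet("e", "o", [inst()]))

    def test_fixed_se_never_exceeds_random_se(self, paper_like_set, tiny_set):
        for hs in (paper_like_set, tiny_set):
            assert uvmr.ivw(hs, "fixed").se <= uvmr.ivw(hs, "random").se + 1e-15

    def test_auto_switches_on_heterogeneity(self):
        study = generate_univariable(
            SimConfig(seed=21, pleiotropy=PleiotropyConfig("balanced", 0, 0.05, 0.5))
        )
        hs = harmonized_from_study(study)
        e = uvmr.ivw(hs, "auto")
        assert e.notes["q_pval"] < 0.05
        assert e.method == "ivw_random"

    def test_ci_is_beta_pm_196_se(self, tiny_set):
        e = uvmr.ivw(tiny_set)
        assert e.ci_low == pytest.approx(e.beta - 1.96 * e.se, abs=1e-9)
        assert e.ci_high == pytest.approx(e.beta + 1.96 * e.se, abs=1e-9)


class TestEgger:
    def test_two_points_hard_error(self):
        with pytest.raises(ValueError):
            uvmr.egger(HarmonizedSet("e", "o", [inst(vid="a"), inst(vid="b")]))

    def test_agrees_with_ivw_without_pleiotropy(self):
        # zero-intercept data: slope close to IVW (within simulation error)
        diffs = []
        for seed in range(20):
            hs = harmonized_from_study(generate_univariable(SimConfig(seed=300 + seed)))
            diffs.append(uvmr.egger(hs).beta - uvmr.ivw(hs).beta)
        assert abs(np.mean(diffs)) < 0.02

    def test_recovers_injected_directional_pleiotropy(self):
        # constant pleiotropic offset on every SNP: the intercept estimates it
        hits = 0
        for seed in range(20):
            study = generate_univariable(
                SimConfig(
                    seed=400 + seed, k_snps=200,
                    pleiotropy=PleiotropyConfig("directional", 0.02, 1e-6, 1.0),
                )
            )
            e = uvmr.egger(harmonized_from_study(study))
            hits += abs(e.intercept - 0.02) < 1.96 * e.intercept_se
        assert hits >= 17  # ~95% coverage over 20 replicates


class TestWeightedMedian:
    def test_equal_ratios_any_weights(self):
        hs = HarmonizedSet("e", "o", [inst(bx=b, by=0.5 * b, sy=s, vid=f"v{i}")
                                      for i, (b, s) in enumerate([(0.1, 0.01), (0.2, 0.05), (0.3, 0.02)])])
        assert uvmr.weighted_median(hs, seed=0).beta == pytest.approx(0.5)

    def test_equal_weights_simple_median(self):
        hs = HarmonizedSet(
            "e", "o",
            [inst(bx=1.0, sx=1e-6, by=r, sy=1.0, vid=f"v{i}") for i, r in enumerate([1.0, 2.0, 9.0])],
        )
        assert uvmr.weighted_median(hs, seed=0).beta == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_interpolation(self, tiny_set):
        bx, sx, by, sy = tiny_set.arrays()
        theta = by / bx
        w = 1.0 / (sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        # independent brute-force cumulative-weight interpolation
        order = np.argsort(theta)
        t, ww = theta[order], w[order] / w.sum()
        s = np.cumsum(ww) - 0.5 * ww
        i = int(np.searchsorted(s, 0.5))
        expected = t[i - 1] + (0.5 - s[i - 1]) * (t[i] - t[i - 1]) / (s[i] - s[i - 1])
        assert uvmr.weighted_median(tiny_set, seed=3).beta == pytest.approx(expected, abs=1e-12)

    def test_too_few_snps_hard_error(self):
        with pytest.raises(ValueError):
            uvmr.weighted_median(HarmonizedSet("e", "o", [inst(vid="a"), inst(vid="b")]))


class TestMRPresso:
    def test_too_few_snps_hard_error(self, tiny_set):
        hs = HarmonizedSet("e", "o", tiny_set.instruments[:3])
        with pytest.raises(ValueError):
            uvmr.mr_presso(hs)

    def test_corrected_equals_ivw_without_outliers(self, paper_like_set):
        res = uvmr.mr_presso(paper_like_set, seed=5)
        assert res.outlier_ids == []
        assert res.corrected.beta == pytest.approx(uvmr.ivw(paper_like_set).beta, abs=1e-12)

    def test_detects_injected_outlier(self):
        hits = 0
        for seed in range(25):
            study = generate_univariable(SimConfig(seed=600 + seed, k_snps=50))
            hs = harmonized_from_study(study)
            instruments = list(hs.instruments)
            tgt = instruments[3]
            instruments[3] = dataclasses.replace(tgt, beta_out=tgt.beta_out + 8 * tgt.se_out)
            res = uvmr.mr_presso(HarmonizedSet("e", "o", instruments), seed=seed)
            hits += tgt.variant_id in res.outlier_ids
        assert hits >= 23  # >= 90% power

    def test_determinism(self, paper_like_set):
        a = uvmr.mr_presso(paper_like_set, seed=9)
        b = uvmr.mr_presso(paper_like_set, seed=9)
        assert a.global_pval == b.global_pval and a.outlier_ids == b.outlier_ids


class TestBWMR:
    def test_agrees_with_ivw_without_pleiotropy(self, paper_like_set):
        e = uvmr.bwmr(paper_like_set, seed=13)
        ref = uvmr.ivw(paper_like_set)
        assert abs(e.beta - ref.beta) < 0.05
        assert e.ci_low < e.beta < e.ci_high

    def test_tau2_concentrates_near_zero_on_clean_data(self, paper_like_set):
        e = uvmr.bwmr(paper_like_set, seed=13)
        # clean data: posterior pleiotropy variance negligible relative to the
        # causal-signal scale
        assert e.notes["tau2_q975"] < 1e-3

    def test_seeded_runs_are_bit_identical(self, paper_like_set):
        a = uvmr.bwmr(paper_like_set, seed=17)
        b = uvmr.bwmr(paper_like_set, seed=17)
        assert a.beta == b.beta and a.se == b.se and a.ci_low == b.ci_low

    def test_too_few_snps_hard_error(self):
        with pytest.raises(ValueError):
            uvmr.bwmr(HarmonizedSet("e", "o", [inst(vid="a"), inst(vid="b")]))


class TestOddsRatio:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.3980, 1.489), (0.0, 1.0), (0.3195, 1.376)],
    )
    def test_printed_odds_ratios(self, beta, expected):
        e = uvmr.MREstimate("ivw_fixed", beta, 0.07, beta - 0.14, beta + 0.14, 0.006, 100)
        orr, lo, hi = uvmr.to_odds_ratio(e)
        assert round(orr, 3) == pytest.approx(expected, abs=5e-4)
        assert lo < orr < hi  # monotone


from hypothesis import given, settings
from hypothesis import strategies as st


def _finite(lo, hi):
    return st.floats(lo, hi, allow_nan=False, allow_infinity=False)


class TestProperties:
    @given(
        bx=st.lists(_finite(0.01, 1.0), min_size=3, max_size=12),
        by=st.lists(_finite(-1.0, 1.0), min_size=12, max_size=12),
        sy=st.lists(_finite(0.01, 0.5), min_size=12, max_size=12),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_weighted_median_bounded_by_ratio_range(self, bx, by, sy):
        k = len(bx)
        hs = HarmonizedSet.from_arrays(bx, [0.01] * k, by[:k], sy[:k])
        ratios = np.array(by[:k]) / np.array(bx)
        est = uvmr.weighted_median(hs, n_boot=10, seed=0).beta
        assert ratios.min() - 1e-9 <= est <= ratios.max() + 1e-9

    @given(
        bx=st.lists(_finite(0.01, 1.0), min_size=2, max_size=12),
        by=st.lists(_finite(-1.0, 1.0), min_size=12, max_size=12),
        sy=st.lists(_finite(0.01, 0.5), min_size=12, max_size=12),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ivw_closed_form_property(self, bx, by, sy):
        k = len(bx)
        hs = HarmonizedSet.from_arrays(bx, [0.01] * k, by[:k], sy[:k])
        w = 1.0 / np.array(sy[:k]) ** 2
        expected = np.sum(w * np.array(bx) * np.array(by[:k])) / np.sum(w * np.array(bx) ** 2)
        assert uvmr.ivw(hs).beta == pytest.approx(expected, abs=1e-10)


class TestEquivariance:
    def test_joint_sign_flip(self, tiny_set):
        """Negating both betas flips IVW's sign and leaves the oriented
        estimators (Egger, weighted median) unchanged."""
        bx, sx, by, sy = tiny_set.arrays()
        flipped = HarmonizedSet.from_arrays(-bx, sx, -by, sy)
        assert uvmr.ivw(flipped).beta == pytest.approx(uvmr.ivw(tiny_set).beta, abs=1e-12)
        assert uvmr.egger(flipped).beta == pytest.approx(uvmr.egger(tiny_set).beta, abs=1e-12)
        assert uvmr.weighted_median(flipped, seed=2).beta == pytest.approx(
            uvmr.weighted_median(tiny_set, seed=2).beta, abs=1e-12
        )

    def test_outcome_sign_flip_negates_estimates(self, tiny_set):
        bx, sx, by, sy = tiny_set.arrays()
        neg = HarmonizedSet.from_arrays(bx, sx, -by, sy)
        assert uvmr.ivw(neg).beta == pytest.approx(-uvmr.ivw(tiny_set).beta, abs=1e-12)
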