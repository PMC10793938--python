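import dataclasses

import numpy as np
import pytest

from summr import harmonize
from summr.gwas_io import ExclusionList, SummaryStatRecord
from summr.harmonize import (
    HarmonizedInstrument,
    HarmonizedSet,
    apply_exclusions,
    clump,
    compute_f_statistics,
    filter_genome_wide,
    harmonize_pair,
    screen_outcome_associated,
    variance_explained,
)
from summr.synthetic_data import LDBlockConfig, SimConfig, generate_ld_blocks, generate_univariable


def rec(vid, ea="A", oa="G", beta=0.1, se=0.02, pval=1e-9, eaf=0.3, chrom="1", pos=100):
    return SummaryStatRecord(
        variant_id=vid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, eaf=eaf, chrom=chrom, pos=pos,
    )


class TestGenomeWideFilter:
    def test_strict_boundary(self):
        records = [rec("a", pval=1e-9), rec("b", pval=5e-8), rec("c", pval=1e-7)]
        assert [r.variant_id for r in filter_genome_wide(records)] == ["a"]

    def test_all_pass_is_identity(self):
        records = [rec("a", pval=1e-9), rec("b", pval=1e-10)]
        assert filter_genome_wide(records) == records

    def test_count_matches_direct_scan(self):
        study = generate_univariable(SimConfig(seed=5, k_snps=200, n_exposure=20_000))
        records = study.exposure_stats
        expected = sum(1 for r in records if r.pval < 5e-8)
        assert len(filter_genome_wide(records)) == expected
        assert 0 < expected < 200  # the weak-n regime actually exercises the filter


class TestClump:
    def test_pairwise_keeps_smaller_p(self):
        ld = harmonize.LDInfo(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        records = [rec("a", pval=1e-10), rec("b", pval=1e-9, pos=200)]
        assert [r.variant_id for r in clump(records, ld)] == ["a"]

    def test_identity_ld_is_identity(self):
        ld = harmonize.LDInfo(["a", "b"], np.eye(2))
        records = [rec("a", pval=1e-10), rec("b", pval=1e-9, pos=200)]
        assert clump(records, ld) == records

    def test_block_panel_keeps_per_block_minimum(self):
        # 3 blocks x 5 SNPs at within-block r2=0.9: exactly the per-block
        # minimum-p SNP survives
        cfg = SimConfig(seed=9, k_snps=15, ld=LDBlockConfig(n_blocks=3, within_r2=0.9))
        ld = generate_ld_blocks(cfg)
        rng = np.random.default_rng(0)
        pvals = 10.0 ** -rng.uniform(9, 20, 15)
        records = [
            rec(ld.variant_ids[j], pval=pvals[j], pos=(j + 1) * 1000) for j in range(15)
        ]
        kept = clump(records, ld)
        expected = {
            min(records[b * 5:(b + 1) * 5], key=lambda r: r.pval).variant_id
            for b in range(3)
        }
        assert {r.variant_id for r in kept} == expected

    def test_deterministic_tie_break_by_id(self):
        ld = harmonize.LDInfo(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        records = [rec("b", pval=1e-9, pos=200), rec("a", pval=1e-9)]
        assert [r.variant_id for r in clump(records, ld)] == ["a"]


class TestHarmonizePair:
    def test_allele_swap_flips_beta(self):
        hs = harmonize_pair(
            [rec("v", ea="A", oa="G", beta=0.1)],
            [rec("v", ea="G", oa="A", beta=0.05, eaf=0.7)],
        )
        (inst,) = hs.instruments
        assert inst.beta_out == pytest.approx(-0.05)
        assert inst.eaf_out == pytest.approx(0.3)
        assert "flipped" in inst.flags

    def test_intermediate_palindrome_dropped(self):
        hs = harmonize_pair(
            [rec("v", ea="A", oa="T", eaf=0.50)],
            [rec("v", ea="A", oa="T", eaf=0.50)],
        )
        assert hs.instruments == []
        assert ("palindromic_intermediate", 1, ["v"]) in hs.provenance_log

    def test_palindrome_aligned_by_frequency(self):
        # exposure eaf 0.10, outcome eaf 0.88: the outcome's listed effect
        # allele must be the other strand's partner, so beta flips
        hs = harmonize_pair(
            [rec("v", ea="A", oa="T", eaf=0.10, beta=0.1)],
            [rec("v", ea="A", oa="T", eaf=0.88, beta=0.05)],
        )
        (inst,) = hs.instruments
        assert inst.beta_out == pytest.approx(-0.05)
        assert "palindromic_kept" in inst.flags

    def test_palindrome_missing_eaf_dropped(self):
        hs = harmonize_pair(
            [rec("v", ea="A", oa="T", eaf=None)],
            [rec("v", ea="A", oa="T", eaf=0.1)],
        )
        assert hs.instruments == []

    def test_incompatible_alleles_dropped(self):
        hs = harmonize_pair(
            [rec("v", ea="A", oa="G")],
            [rec("v", ea="A", oa="C")],
        )
        assert hs.instruments == []
        assert ("incompatible_alleles", 1, ["v"]) in hs.provenance_log

    def test_absent_in_outcome_logged(self):
        hs = harmonize_pair([rec("v")], [rec("w")])
        assert ("absent_in_outcome", 1, ["v"]) in hs.provenance_log

    def test_duplicate_ids_hard_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            harmonize_pair([rec("v"), rec("v", pos=200)], [rec("v")])

    def test_conservation(self):
        """Every input SNP lands in the final set or in exactly one removal."""
        exp = [
            rec("a"),
            rec("b", ea="A", oa="T", eaf=0.5),
            rec("c", ea="A", oa="C"),
            rec("d"),
        ]
        out = [rec("a"), rec("b", ea="A", oa="T", eaf=0.5), rec("c", ea="G", oa="T")]
        hs = harmonize_pair(exp, out)
        survivors = {i.variant_id for i in hs.instruments}
        removed = {v for _, _, ids in hs.provenance_log for v in ids}
        assert survivors | removed == {"a", "b", "c", "d"}
        assert survivors & removed == set()

    def test_idempotent(self):
        exp = [rec("a", beta=0.1), rec("b", ea="C", oa="T", beta=-0.2, pos=300)]
        out = [rec("a", ea="G", oa="A", beta=0.05, eaf=0.7), rec("b", ea="C", oa="T", beta=0.01, pos=300)]
        hs1 = harmonize_pair(exp, out)
        # re-wrap the harmonized set as records: both sides now share alleles
        exp2 = [rec(i.variant_id, beta=i.beta_exp, se=i.se_exp, eaf=i.eaf_exp) for i in hs1.instruments]
        out2 = [rec(i.variant_id, beta=i.beta_out, se=i.se_out, eaf=i.eaf_out) for i in hs1.instruments]
        hs2 = harmonize_pair(exp2, out2)
        assert [(i.variant_id, i.beta_out) for i in hs2.instruments] == [
            (i.variant_id, i.beta_out) for i in hs1.instruments
        ]

    def test_flip_symmetry(self):
        """Swapping outcome alleles (negating beta, complementing EAF)
        yields the identical harmonized set."""
        exp = [rec("a", beta=0.1), rec("b", ea="C", oa="T", beta=-0.2, pos=300)]
        out = [rec("a", beta=0.05, eaf=0.3), rec("b", ea="C", oa="T", beta=0.01, eaf=0.4, pos=300)]
        flipped = [
            dataclasses.replace(
                r,
                effect_allele=r.other_allele,
                other_allele=r.effect_allele,
                beta=-r.beta,
                eaf=1 - r.eaf,
            )
            for r in out
        ]
        hs1 = harmonize_pair(exp, out)
        hs2 = harmonize_pair(exp, flipped)
        for i1, i2 in zip(hs1.instruments, hs2.instruments):
            assert i1.beta_out == pytest.approx(i2.beta_out)
            assert i1.eaf_out == pytest.approx(i2.eaf_out)


class TestFStatistics:
    def make_set(self, pairs):
        return HarmonizedSet(
            "e", "o",
            [
                HarmonizedInstrument(f"v{i}", bx, sx, 0.01, 0.01)
                for i, (bx, sx) in enumerate(pairs)
            ],
        )

    def test_strong_kept_weak_removed(self):
        hs = self.make_set([(0.1, 0.02), (0.01, 0.01)])
        assert hs.instruments[0].f_stat == pytest.approx(25.0)
        assert hs.instruments[1].f_stat == pytest.approx(1.0)
        out = compute_f_statistics(hs)
        assert [i.variant_id for i in out.instruments] == ["v0"]
        assert ("weak_instrument_f", 1, ["v1"]) in out.provenance_log

    def test_mean_f_matches_direct_average(self):
        rng = np.random.default_rng(4)
        pairs = [(b, s) for b, s in zip(rng.uniform(0.05, 0.2, 100), rng.uniform(0.005, 0.02, 100))]
        hs = self.make_set(pairs)
        out = compute_f_statistics(hs, f_threshold=10)
        direct = np.mean([(b / s) ** 2 for b, s in pairs if (b / s) ** 2 > 10])
        logged = next(s for s, _, _ in out.provenance_log if s.startswith("mean_f="))
        assert float(logged.split("=")[1]) == pytest.approx(direct, abs=0.01)


class TestVarianceExplained:
    def test_single_snp(self):
        total, per = variance_explained([rec("v", eaf=0.5, beta=0.1, pval=0.05)])
        assert total == pytest.approx(0.005)

    def test_zero_betas(self):
        recs = [rec(f"v{i}", beta=0.0, pval=1.0) for i in range(3)]
        total, per = variance_explained(recs)
        assert total == 0.0 and np.all(per == 0)

    def test_matches_independent_sum(self):
        study = generate_univariable(SimConfig(seed=8, k_snps=50))
        total, per = variance_explained(study.exposure_stats)
        manual = sum(
            2 * r.eaf * (1 - r.eaf) * r.beta**2 for r in study.exposure_stats
        )
        assert total == pytest.approx(manual, rel=1e-12)
        assert len(per) == 50

    def test_construction_hits_target_h2(self):
        # realized true-effect R2 is exact by construction (within 1%);
        # the estimated betas add sampling noise on top
        study = generate_univariable(SimConfig(seed=8))
        true_r2 = sum(
            2 * p * (1 - p) * g**2
            for p, g in zip(study.truth["mafs"], study.truth["gamma"])
        )
        assert true_r2 == pytest.approx(0.18, rel=0.01)
        total, _ = variance_explained(study.exposure_stats)
        assert total == pytest.approx(0.18, rel=0.05)

    def test_missing_eaf_names_snp(self):
        with pytest.raises(ValueError, match="vX"):
            variance_explained([rec("vX", eaf=None)])


class TestScreensAndExclusions:
    def make_set(self):
        return HarmonizedSet(
            "e", "o",
            [
                HarmonizedInstrument(f"v{i}", 0.1, 0.01, 0.01, 0.01, pval_out=p)
                for i, p in enumerate([1e-9, 1e-3, 0.5])
            ],
        )

    def test_outcome_associated_removed(self):
        out = screen_outcome_associated(self.make_set())
        assert [i.variant_id for i in out.instruments] == ["v1", "v2"]
        assert ("outcome_associated", 1, ["v0"]) in out.provenance_log

    def test_empty_exclusion_is_identity(self):
        hs = self.make_set()
        out = apply_exclusions(hs, ExclusionList(set(), "manual"))
        assert [i.variant_id for i in out.instruments] == [i.variant_id for i in hs.instruments]

    def test_all_listed_empties_set(self):
        out = apply_exclusions(self.make_set(), ExclusionList({"v0", "v1", "v2"}, "confounder"))
        assert out.instruments == []
        assert ("exclusion_confounder", 3, ["v0", "v1", "v2"]) in out.provenance_log

    def test_partial_exclusion(self):
        hs = HarmonizedSet(
            "e", "o",
            [HarmonizedInstrument(f"v{i}", 0.1, 0.01, 0.01, 0.01) for i in range(10)],
        )
        out = apply_exclusions(hs, ExclusionList({"v0", "v5", "v9"}, "outcome"))
        assert len(out.instruments) == 7
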