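"""Instrument selection and exposure-outcome harmonization.

The selection chain mirrors standard two-sample MR practice: keep
genome-wide-significant SNPs (p < 5e-8), prune to mutual linkage
equilibrium (greedy clumping at r² < 0.001), align outcome effects to the
exposure's effect allele (dropping unresolvable palindromes), drop weak
instruments (F <= 10), screen out SNPs associated with the outcome, and
apply confounder exclusion lists.  Every removal is recorded in a
provenance log so that input = survivors + removals always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gwas_io import ExclusionList, LDInfo, SummaryStatRecord

logger = logging.getLogger("summr")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-SNP exposure and outcome effects on a common effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    pval_exp: float | None = None
    pval_out: float | None = None
    chrom: str = ""
    pos: int = 0
    n_exp: int | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.variant_id}: standard errors must be positive")

    @property
    def f_stat(self) -> float:
        return (self.beta_exp / self.se_exp) ** 2


@dataclass
class HarmonizedSet:
    """Analysis-ready instruments for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    provenance_log: list[tuple[str, int, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i.variant_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_id in harmonized set")

    def log(self, step: str, removed_ids: list[str]) -> None:
        self.provenance_log.append((step, len(removed_ids), sorted(removed_ids)))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([i.beta_exp for i in self.instruments])
        sx = np.array([i.se_exp for i in self.instruments])
        by = np.array([i.beta_out for i in self.instruments])
        sy = np.array([i.se_out for i in self.instruments])
        return bx, sx, by, sy

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        variant_ids=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        k = len(beta_exp)
        ids = variant_ids if variant_ids is not None else [f"snp{i}" for i in range(k)]
        instruments = [
            HarmonizedInstrument(
                variant_id=str(ids[j]),
                beta_exp=float(beta_exp[j]),
                se_exp=float(se_exp[j]),
                beta_out=float(beta_out[j]),
                se_out=float(se_out[j]),
            )
            for j in range(k)
        ]
        return cls(exposure_name, outcome_name, instruments)


# ---------------------------------------------------------------------------
# selection steps on raw records


def filter_genome_wide(
    records: list[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep SNPs with p strictly below the genome-wide threshold."""
    if not records:
        raise ValueError("no records supplied")
    kept = [r for r in records if r.pval < p_threshold]
    if not kept:
        logger.info("filter_genome_wide: no SNP passes p < %g", p_threshold)
    return kept


def clump(
    records: list[SummaryStatRecord],
    ld: LDInfo | None = None,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: scan SNPs by ascending p (ties broken by
    variant_id) and accept a SNP iff its r² with every already-accepted SNP
    within ``window_bp`` is below ``r2_threshold``.

    SNPs absent from the LD matrix are treated as independent (warned once).
    The returned list preserves the input ordering.
    """
    order = sorted(range(len(records)), key=lambda i: (records[i].pval, records[i].variant_id))
    accepted: list[int] = []
    warned = False
    for i in order:
        r = records[i]
        ok = True
        for j in accepted:
            a = records[j]
            if r.chrom and a.chrom and r.chrom != a.chrom:
                continue
            if r.pos and a.pos and abs(r.pos - a.pos) > window_bp:
                continue
            r2 = ld.pairwise(r.variant_id, a.variant_id) if ld is not None else None
            if r2 is None:
                if ld is not None and not warned:
                    logger.warning(
                        "clump: SNP pair missing from LD matrix; treating as independent"
                    )
                    warned = True
                continue
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
    keep = set(accepted)
    return [r for i, r in enumerate(records) if i in keep]


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize_pair(
    exposure_records: list[SummaryStatRecord],
    outcome_records: list[SummaryStatRecord],
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    SNPs absent from the outcome are dropped; swapped alleles flip the
    outcome beta and EAF; palindromic (A/T, C/G) SNPs are dropped when
    either EAF is missing or intermediate (inside the band), otherwise
    aligned by frequency; allele sets matching neither orientation are
    dropped as incompatible.
    """

    def index(records: list[SummaryStatRecord], side: str):
        idx: dict[str, SummaryStatRecord] = {}
        for r in records:
            if r.variant_id in idx:
                raise ValueError(f"duplicate variant_id on {side} side: {r.variant_id}")
            idx[r.variant_id] = r
        return idx

    out_idx = index(outcome_records, "outcome")
    index(exposure_records, "exposure")

    lo, hi = palindrome_eaf_band
    instruments: list[HarmonizedInstrument] = []
    missing, palindromic, incompatible = [], [], []

    for ex in exposure_records:
        out = out_idx.get(ex.variant_id)
        if out is None:
            missing.append(ex.variant_id)
            continue

        flags: set[str] = set()
        beta_out, eaf_out = out.beta, out.eaf

        if _is_palindromic(ex.effect_allele, ex.other_allele):
            if {out.effect_allele, out.other_allele} != {
                ex.effect_allele,
                ex.other_allele,
            }:
                incompatible.append(ex.variant_id)
                continue
            if ex.eaf is None or out.eaf is None:
                palindromic.append(ex.variant_id)
                continue
            if lo <= ex.eaf <= hi or lo <= out.eaf <= hi:
                palindromic.append(ex.variant_id)
                continue
            # strand is unresolvable from alleles; use frequency: the outcome's
            # effect allele matches the exposure's iff the frequencies agree in
            # direction relative to 0.5
            same_side = (ex.eaf < 0.5) == (out.eaf < 0.5)
            aligned_same = out.effect_allele == ex.effect_allele
            if same_side != aligned_same:
                beta_out = -out.beta
                eaf_out = 1.0 - out.eaf
                flags.add("flipped")
            flags.add("palindromic_kept")
        else:
            ex_pair = (ex.effect_allele, ex.other_allele)
            out_pair = (out.effect_allele, out.other_allele)
            comp_pair = (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele])
            if out_pair == ex_pair or comp_pair == ex_pair:
                pass  # already aligned (possibly reported on the other strand)
            elif out_pair == ex_pair[::-1] or comp_pair == ex_pair[::-1]:
                beta_out = -out.beta
                eaf_out = None if out.eaf is None else 1.0 - out.eaf
                flags.add("flipped")
            else:
                incompatible.append(ex.variant_id)
                continue

        instruments.append(
            HarmonizedInstrument(
                variant_id=ex.variant_id,
                beta_exp=ex.beta,
                se_exp=ex.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=ex.eaf,
                eaf_out=eaf_out,
                pval_exp=ex.pval,
                pval_out=out.pval,
                chrom=ex.chrom,
                pos=ex.pos,
                n_exp=ex.n,
                flags=frozenset(flags),
            )
        )

    hs = HarmonizedSet(exposure_name, outcome_name, instruments)
    hs.log("absent_in_outcome", missing)
    hs.log("palindromic_intermediate", palindromic)
    hs.log("incompatible_alleles", incompatible)
    return hs


# ---------------------------------------------------------------------------
# post-harmonization screens


def compute_f_statistics(hs: HarmonizedSet, f_threshold: float = 10.0) -> HarmonizedSet:
    """Drop weak instruments (per-SNP F = (beta/se)² <= threshold)."""
    kept = [i for i in hs.instruments if i.f_stat > f_threshold]
    removed = [i.variant_id for i in hs.instruments if i.f_stat <= f_threshold]
    out = HarmonizedSet(hs.exposure_name, hs.outcome_name, kept, list(hs.provenance_log))
    out.log("weak_instrument_f", removed)
    if kept:
        mean_f = float(np.mean([i.f_stat for i in kept]))
        out.provenance_log.append((f"mean_f={mean_f:.2f}", 0, []))
    return out


def screen_outcome_associated(hs: HarmonizedSet, p_threshold: float = 5e-8) -> HarmonizedSet:
    """Drop SNPs genome-wide associated with the outcome itself."""
    removed, kept = [], []
    for i in hs.instruments:
        if i.pval_out is not None and i.pval_out < p_threshold:
            removed.append(i.variant_id)
        else:
            kept.append(i)
    out = HarmonizedSet(hs.exposure_name, hs.outcome_name, kept, list(hs.provenance_log))
    out.log("outcome_associated", removed)
    return out


def apply_exclusions(hs: HarmonizedSet, *lists: ExclusionList) -> HarmonizedSet:
    """Remove SNPs named on exclusion lists (confounder screens etc.)."""
    out = HarmonizedSet(
        hs.exposure_name, hs.outcome_name, list(hs.instruments), list(hs.provenance_log)
    )
    for lst in lists:
        removed = [i.variant_id for i in out.instruments if i.variant_id in lst.variant_ids]
        out.instruments = [
            i for i in out.instruments if i.variant_id not in lst.variant_ids
        ]
        out.log(f"exclusion_{lst.reason}", removed)
    return out


def variance_explained(records) -> tuple[float, np.ndarray]:
    """Exposure variance explained by the instruments.

    For standardized per-SD betas, each SNP contributes 2·p·(1−p)·beta²;
    the total is their sum.  Accepts SummaryStatRecords or
    HarmonizedInstruments (using the exposure side).  A missing EAF is a
    hard error naming the SNP.
    """
    per_snp = []
    for r in records:
        eaf = getattr(r, "eaf", None)
        beta = getattr(r, "beta", None)
        if beta is None:
            eaf, beta = r.eaf_exp, r.beta_exp
        if eaf is None:
            raise ValueError(f"{r.variant_id}: missing EAF, cannot compute R²")
        per_snp.append(2.0 * eaf * (1.0 - eaf) * beta**2)
    per_snp = np.asarray(per_snp)
    return float(per_snp.sum()), per_snp
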