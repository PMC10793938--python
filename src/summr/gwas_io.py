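"""Reading and writing GWAS summary statistics and companion files.

Summary statistics travel as flat TSV/CSV tables with one row per variant.
Two header dialects are recognised out of the box: a GWAS-SSF-style header
(``beta``, ``standard_error``, ``p_value``, ``effect_allele_frequency``) and
a legacy header (``BETA``, ``SE``, ``P``, ``EAF``); anything else can be
mapped explicitly via ``column_map``.  LD information is a labelled square
r-squared matrix, exclusion lists are one variant id per line.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("summr")

VALID_BASES = frozenset("ACGT")

#: canonical field -> accepted column names, tried in order (case-insensitive)
_DIALECTS: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "rsid", "snp", "id", "markername"),
    "chrom": ("chromosome", "chrom", "chr"),
    "pos": ("base_pair_location", "pos", "position", "bp"),
    "effect_allele": ("effect_allele", "ea", "a1", "alt"),
    "other_allele": ("other_allele", "oa", "a2", "ref"),
    "eaf": ("effect_allele_frequency", "eaf", "af", "freq"),
    "beta": ("beta", "b", "effect"),
    "se": ("standard_error", "se", "stderr"),
    "pval": ("p_value", "p", "pval", "p_val"),
    "n": ("n", "sample_size", "samplesize"),
}

_REQUIRED = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is on the per-SD scale for continuous exposures and the
    log-odds scale for binary outcomes; ``eaf`` is the effect-allele
    frequency and may be missing (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not (self.se > 0):
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval outside (0, 1]: {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf outside (0, 1): {self.eaf}")
        # p should roughly match the two-sided normal p of beta/se; warn only,
        # since published files round both.  Skip once p underflows double
        # precision territory: nothing to compare there.
        z = abs(self.beta / self.se)
        if z > 0 and self.pval > 1e-250:
            from scipy.stats import norm

            p_implied = 2.0 * norm.sf(z)
            if p_implied > 0:
                if abs(math.log10(p_implied) - math.log10(self.pval)) > 1.0:
                    logger.warning(
                        "%s: reported p=%.3g differs from |beta/se|-implied p=%.3g",
                        self.variant_id,
                        self.pval,
                        p_implied,
                    )

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class LDInfo:
    """Pairwise r-squared between variants, with an optional bp window."""

    variant_ids: list[str]
    r2: np.ndarray
    window_bp: int = 10_000_000

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} does not match {k} ids")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if np.abs(self.r2 - self.r2.T).max() > 1e-8:
            raise ValueError("r2 matrix is not symmetric")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def pairwise(self, a: str, b: str) -> float | None:
        """r² between two variants, or None if either is unknown."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


@dataclass
class ExclusionList:
    """Variants to drop, with a reason tag (confounder / outcome / manual)."""

    variant_ids: set[str]
    reason: str = "manual"


# ---------------------------------------------------------------------------
# summary statistics


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, aliases in _DIALECTS.items():
        if column_map and canon in column_map:
            if column_map[canon] not in columns:
                raise ValueError(
                    f"column_map names column {column_map[canon]!r} for "
                    f"{canon!r} but the file has no such column"
                )
            resolved[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise ValueError(f"required column(s) not found: {', '.join(missing)}")
    return resolved


def read_summary_stats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SummaryStatRecord]:
    """Read a summary-statistic TSV/CSV into records, preserving row order.

    Rows whose beta or se fail to parse as numbers are dropped; the drop
    count is logged.  A missing required column or an empty file is a hard
    error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, comment=None)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = _resolve_columns(list(df.columns), column_map)

    records: list[SummaryStatRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()

        def get(canon: str) -> str | None:
            col = cols.get(canon)
            if col is None:
                return None
            v = row[col]
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        try:
            beta = float(get("beta"))
            se = float(get("se"))
            pval = float(get("pval"))
        except (TypeError, ValueError):
            dropped += 1
            continue
        if math.isnan(beta) or math.isnan(se):
            dropped += 1
            continue
        eaf_raw = get("eaf")
        try:
            eaf = float(eaf_raw) if eaf_raw is not None else None
            if eaf is not None and math.isnan(eaf):
                eaf = None
        except ValueError:
            eaf = None
        n_raw = get("n")
        n = int(float(n_raw)) if n_raw not in (None, "") else None
        records.append(
            SummaryStatRecord(
                variant_id=str(get("variant_id")),
                chrom=str(get("chrom") or ""),
                pos=int(float(get("pos") or 0)),
                effect_allele=str(get("effect_allele")),
                other_allele=str(get("other_allele")),
                eaf=eaf,
                beta=beta,
                se=se,
                pval=pval,
                n=n,
            )
        )
    if dropped:
        logger.info("%s: dropped %d row(s) with non-numeric beta/se", path, dropped)
    if not records:
        raise ValueError(f"{path}: no parseable data rows")
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records in the GWAS-SSF-style dialect (TSV)."""
    rows = [
        {
            "variant_id": r.variant_id,
            "chromosome": r.chrom,
            "base_pair_location": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "effect_allele_frequency": "" if r.eaf is None else repr(r.eaf),
            "beta": repr(r.beta),
            "standard_error": repr(r.se),
            "p_value": repr(r.pval),
            "n": "" if r.n is None else r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results


def write_results_table(estimates: Sequence, path: str | Path) -> None:
    """Write MR estimates as a TSV (6 significant digits) plus a JSON mirror.

    Column order is fixed: method, n_snp, beta, se, ci_low, ci_high, pval,
    odds ratio and its CI.  Raises on an empty list.
    """
    if not estimates:
        raise ValueError("no estimates to write")
    path = Path(path)
    rows = []
    for e in estimates:
        rows.append(
            {
                "method": e.method,
                "n_snp": e.n_snp,
                "beta": _sig6(e.beta),
                "se": _sig6(e.se),
                "ci_low": _sig6(e.ci_low),
                "ci_high": _sig6(e.ci_high),
                "pval": _sig6(e.pval),
                "or": _sig6(math.exp(e.beta)),
                "or_ci_low": _sig6(math.exp(e.ci_low)),
                "or_ci_high": _sig6(math.exp(e.ci_high)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    mirror = path.with_suffix(path.suffix + ".json")
    with open(mirror, "w") as fh:
        json.dump(rows, fh, indent=1)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sig6(x: float) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.6g}")


# ---------------------------------------------------------------------------
# LD matrices and exclusion lists


def read_ld_matrix(path: str | Path, window_bp: int = 10_000_000) -> LDInfo:
    """Read a labelled square r² matrix (TSV, ids in header and first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    return LDInfo(variant_ids=[str(v) for v in df.index], r2=df.to_numpy(float),
                  window_bp=window_bp)


def write_ld_matrix(ld: LDInfo, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


def read_exclusion_list(path: str | Path, reason: str = "manual") -> ExclusionList:
    """One variant id per line; '#' starts a comment."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ExclusionList(variant_ids=ids, reason=reason)
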