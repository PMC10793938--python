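"""Multivariable two-sample MR.

Joint estimation of direct (conditional) causal effects of m exposures on
one outcome from a k×m matrix of per-SNP exposure effects, with:

- ``mv_ivw`` / ``mv_egger``: weighted least squares extensions of IVW and
  Egger with multiplicative overdispersion;
- ``qmin``: minimisation of the heteroscedasticity-corrected Q statistic,
  robust to weak instruments, with profile-Q confidence intervals;
- ``conditional_f``: per-exposure two-sample conditional instrument
  strength (below 10 signals weak instruments);
- ``validity_q``: the instrument-validity Q test at a given effect vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .gwas_io import SummaryStatRecord
from .harmonize import clump, filter_genome_wide

Z95 = 1.96


@dataclass
class MVMRInput:
    """k SNPs × m exposures effect matrix with SEs, plus the outcome vector."""

    snp_ids: list[str]
    bx: np.ndarray  # (k, m)
    sx: np.ndarray  # (k, m)
    by: np.ndarray  # (k,)
    sy: np.ndarray  # (k,)
    exposure_names: list[str]

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, float)
        self.sx = np.asarray(self.sx, float)
        if self.bx.ndim == 1:  # m=1 degenerates to univariable IVW
            self.bx = self.bx[:, None]
        if self.sx.ndim == 1:
            self.sx = self.sx[:, None]
        self.by = np.asarray(self.by, float)
        self.sy = np.asarray(self.sy, float)
        k, m = self.bx.shape
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("duplicate SNP ids in MVMR input")
        if self.sx.shape != (k, m) or self.by.shape != (k,) or self.sy.shape != (k,):
            raise ValueError("inconsistent MVMR input shapes")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("standard errors must be positive")
        if np.isnan(self.bx).any() or np.isnan(self.by).any():
            raise ValueError("missing cells in MVMR input (fill by proxy upstream)")
        if not k > m:
            raise ValueError(f"need more SNPs than exposures (k={k}, m={m})")

    @property
    def k(self) -> int:
        return self.bx.shape[0]

    @property
    def m(self) -> int:
        return self.bx.shape[1]


@dataclass(frozen=True)
class MVMREstimate:
    method: str  # mv_ivw | mv_egger | qmin
    exposure_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pval: np.ndarray
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    notes: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# input assembly


def build_mvmr_input(
    exposure_records: dict[str, list[SummaryStatRecord]],
    outcome_records: list[SummaryStatRecord],
    proxy_table: dict[str, tuple[str, int]] | None = None,
    ld=None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> MVMRInput:
    """Assemble the k×m exposure matrix from per-exposure summary stats.

    Instruments are the clumped union of SNPs genome-wide significant for
    at least one exposure.  A SNP missing from some exposure may be filled
    through ``proxy_table`` (missing id -> (proxy id, orientation sign);
    unsigned proxies are refused).  Palindromic-ambiguous and unfillable
    SNPs are dropped.
    """
    names = list(exposure_records)
    if len(names) < 2:
        raise ValueError("MVMR needs >= 2 exposures")
    if proxy_table:
        for snp, entry in proxy_table.items():
            if len(entry) != 2 or entry[1] not in (-1, 1):
                raise ValueError(f"proxy for {snp} lacks an orientation sign")

    # union of genome-wide-significant, clumped instruments
    union: dict[str, SummaryStatRecord] = {}
    for name in names:
        try:
            sig = filter_genome_wide(exposure_records[name], p_threshold)
        except ValueError:
            sig = []
        for r in sig:
            prev = union.get(r.variant_id)
            if prev is None or r.pval < prev.pval:
                union[r.variant_id] = r
    selected = clump(sorted(union.values(), key=lambda r: r.variant_id), ld, r2_threshold)

    lo, hi = palindrome_eaf_band
    exp_idx = [
        {r.variant_id: r for r in exposure_records[name]} for name in names
    ]
    out_idx = {r.variant_id: r for r in outcome_records}

    ids, bx_rows, sx_rows, by_l, sy_l = [], [], [], [], []
    for r in sorted(selected, key=lambda r: r.variant_id):
        vid = r.variant_id
        out = out_idx.get(vid)
        if out is None:
            continue
        ref = None  # reference orientation: first exposure carrying the SNP
        row_b, row_s = [], []
        ok = True
        for idx in exp_idx:
            rec, sign = idx.get(vid), 1
            if rec is None and proxy_table and vid in proxy_table:
                proxy_id, sign = proxy_table[vid]
                rec = idx.get(proxy_id)
            if rec is None:
                ok = False
                break
            if rec.is_palindromic and (
                rec.eaf is None or lo <= rec.eaf <= hi
            ):
                ok = False  # ambiguous palindrome
                break
            if ref is None:
                ref = rec
            elif {rec.effect_allele, rec.other_allele} == {
                ref.effect_allele,
                ref.other_allele,
            } and rec.effect_allele != ref.effect_allele:
                sign *= -1
            row_b.append(sign * rec.beta)
            row_s.append(rec.se)
        if not ok:
            continue
        out_sign = 1
        if ref is not None and {out.effect_allele, out.other_allele} == {
            ref.effect_allele,
            ref.other_allele,
        } and out.effect_allele != ref.effect_allele:
            out_sign = -1
        ids.append(vid)
        bx_rows.append(row_b)
        sx_rows.append(row_s)
        by_l.append(out_sign * out.beta)
        sy_l.append(out.se)

    if len(ids) <= len(names):
        raise ValueError(
            f"only {len(ids)} usable SNPs for {len(names)} exposures"
        )
    return MVMRInput(ids, np.array(bx_rows), np.array(sx_rows),
                     np.array(by_l), np.array(sy_l), names)


# ---------------------------------------------------------------------------
# estimators


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, exposure_names=None):
    XtW = X.T * w
    gram = XtW @ X
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError(
            "exposure-effect matrix is rank deficient (collinear exposures"
            + (f": {exposure_names}" if exposure_names else "") + ")"
        )
    cov_unit = np.linalg.inv(gram)
    coef = cov_unit @ (XtW @ y)
    return coef, cov_unit


def _package(method, names, coef, cov_unit, resid_q, k, p, intercept_block=False, notes=None):
    dispersion = max(1.0, math.sqrt(resid_q / (k - p)))
    se_all = np.sqrt(np.diag(cov_unit)) * dispersion
    if intercept_block:
        icpt, icpt_se = float(coef[0]), float(se_all[0])
        icpt_p = float(2 * stats.norm.sf(abs(icpt / icpt_se)))
        beta, se = coef[1:], se_all[1:]
    else:
        icpt = icpt_se = icpt_p = None
        beta, se = coef, se_all
    pv = 2 * stats.norm.sf(np.abs(beta / se))
    return MVMREstimate(
        method=method,
        exposure_names=list(names),
        beta=np.asarray(beta, float),
        se=np.asarray(se, float),
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=np.asarray(pv, float),
        n_snp=k,
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_pval=icpt_p,
        notes=notes or {},
    )


def mv_ivw(inp: MVMRInput) -> MVMREstimate:
    """Multivariable IVW: WLS of by on the columns of bx without intercept,
    weights 1/sy²; SEs carry multiplicative dispersion
    max(1, sqrt(Q_A/(k−m)))."""
    w = 1.0 / inp.sy**2
    coef, cov_unit = _wls(inp.bx, inp.by, w, inp.exposure_names)
    q = float(np.sum(w * (inp.by - inp.bx @ coef) ** 2))
    return _package("mv_ivw", inp.exposure_names, coef, cov_unit, q, inp.k, inp.m,
                    notes={"q": q})


def mv_egger(inp: MVMRInput) -> MVMREstimate:
    """Multivariable MR-Egger: mv_ivw plus a common intercept.

    Rows are signed so the first exposure's effects are positive; the
    intercept p-value tests directional pleiotropy.
    """
    if not inp.k > inp.m + 1:
        raise ValueError(f"MV-Egger needs k > m+1 (k={inp.k}, m={inp.m})")
    s = np.where(inp.bx[:, 0] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(inp.k), inp.bx * s[:, None]])
    y = inp.by * s
    w = 1.0 / inp.sy**2
    coef, cov_unit = _wls(X, y, w, inp.exposure_names)
    q = float(np.sum(w * (y - X @ coef) ** 2))
    return _package("mv_egger", inp.exposure_names, coef, cov_unit, q, inp.k,
                    inp.m + 1, intercept_block=True, notes={"q": q})


# ---------------------------------------------------------------------------
# Q-statistic machinery


def q_statistic(inp: MVMRInput, theta: np.ndarray) -> float:
    """Heteroscedasticity-corrected Q at effect vector theta:
    Σ_j (by_j − bx_j·θ)² / (sy_j² + Σ_a θ_a² sx_ja²)."""
    theta = np.asarray(theta, float)
    resid = inp.by - inp.bx @ theta
    var = inp.sy**2 + (inp.sx**2) @ (theta**2)
    return float(np.sum(resid**2 / var))


def validity_q(inp: MVMRInput, theta: np.ndarray) -> tuple[float, float]:
    """Instrument-validity test: Q_A at theta against chi-square(k−m).

    p > 0.05 means no evidence of heterogeneity/pleiotropy at that effect
    vector.
    """
    q = q_statistic(inp, theta)
    return q, float(stats.chi2.sf(q, inp.k - inp.m))


def qmin(inp: MVMRInput, starts: int = 8, seed: int = 0) -> MVMREstimate:
    """Direct effects by Q-statistic minimisation.

    Robust to weak instruments because the denominator propagates the
    exposure-effect measurement error at the candidate theta.  Multi-start
    Nelder-Mead seeded around the mv_ivw solution ± 2 SE; per-coordinate
    95% CIs from the profile Q (Q difference <= chi-square(1) 0.95
    quantile).
    """
    base = mv_ivw(inp)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(starts):
        x0 = base.beta if s == 0 else rng.normal(base.beta, 2.0 * base.se)
        res = optimize.minimize(
            lambda t: q_statistic(inp, t), x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("Q-minimisation failed to converge from any start")
    theta = best.x
    q_min = float(best.fun)
    # qmin point can never sit above the mv_ivw point of the same objective
    if q_min > q_statistic(inp, base.beta) + 1e-9:
        raise RuntimeError("Q-minimisation ended above the mv_ivw point")

    crit = stats.chi2.ppf(0.95, 1)
    lo = np.empty(inp.m)
    hi = np.empty(inp.m)
    se = np.empty(inp.m)
    for a in range(inp.m):
        def profile(v: float) -> float:
            def obj(rest: np.ndarray) -> float:
                t = np.insert(rest, a, v)
                return q_statistic(inp, t)
            if inp.m == 1:
                return q_statistic(inp, np.array([v]))
            r0 = np.delete(theta, a)
            r = optimize.minimize(obj, r0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10})
            return float(r.fun)

        def root(v: float) -> float:
            return profile(v) - (q_min + crit)

        step = max(2.0 * base.se[a], 1e-3)
        vlo, vhi = theta[a] - step, theta[a] + step
        for _ in range(40):
            if root(vlo) > 0:
                break
            vlo -= step
        for _ in range(40):
            if root(vhi) > 0:
                break
            vhi += step
        lo[a] = optimize.brentq(root, vlo, theta[a]) if root(vlo) > 0 else vlo
        hi[a] = optimize.brentq(root, theta[a], vhi) if root(vhi) > 0 else vhi
        se[a] = (hi[a] - lo[a]) / (2 * Z95)

    pv = 2 * stats.norm.sf(np.abs(theta / se))
    return MVMREstimate(
        method="qmin",
        exposure_names=list(inp.exposure_names),
        beta=theta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        pval=pv,
        n_snp=inp.k,
        notes={"q_min": q_min, "q_ivw": q_statistic(inp, base.beta)},
    )


# ---------------------------------------------------------------------------
# conditional instrument strength


def conditional_f(inp: MVMRInput, n_iter: int = 5) -> np.ndarray:
    """Two-sample conditional F-statistic per exposure.

    For exposure a, its SNP effects are regressed on the other exposures'
    effects; the conditional Q is the variance-scaled residual sum, and
    F_a = Q_xa / (k − m + 1).  Weights are updated iteratively from the
    current delta coefficients (measurement error of the regressors
    propagates into the residual variance).  Values below 10 flag weak
    conditional instruments; perfectly collinear exposures drive F to 0.
    """
    k, m = inp.k, inp.m
    f = np.empty(m)
    for a in range(m):
        xa = inp.bx[:, a]
        sxa2 = inp.sx[:, a] ** 2
        others = [b for b in range(m) if b != a]
        if not others:
            q = float(np.sum(xa**2 / sxa2))
            f[a] = q / (k - m + 1)
            continue
        Xo = inp.bx[:, others]
        so2 = inp.sx[:, others] ** 2
        delta = np.zeros(len(others))
        var = sxa2.copy()
        for _ in range(n_iter):
            coef, _ = _wls(Xo, xa, 1.0 / var)
            delta = coef
            var = sxa2 + so2 @ (delta**2)
        resid = xa - Xo @ delta
        q = float(np.sum(resid**2 / var))
        f[a] = q / (k - m + 1)
    return f
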