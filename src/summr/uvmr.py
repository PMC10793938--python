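"""Univariable two-sample MR estimators.

All estimators consume a :class:`~summr.harmonize.HarmonizedSet` whose
exposure effects are per-SD and whose outcome effects are log-odds, and
return an :class:`MREstimate` on the log-odds-per-SD scale.

Methods
-------
wald_ratio        single-SNP ratio with first-order delta SE
ivw               inverse-variance-weighted regression through the origin,
                  with fixed or multiplicative-random-effects SEs
egger             weighted regression with an unconstrained intercept; the
                  intercept estimates average directional pleiotropy
weighted_median   consistent when valid instruments carry >= 50% of weight;
                  parametric-bootstrap SE
mr_presso         residual-sum-of-squares global pleiotropy test, per-SNP
                  outlier detection, distortion test, and outlier-corrected
                  IVW estimate
bwmr              Bayesian weighted MR: pleiotropy as a normal random
                  effect, outlier down-weighting, seeded MCMC inference
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

Z95 = 1.96  # normal-theory 95% CIs throughout


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds-per-SD scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    notes: dict = field(default_factory=dict, compare=False)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    corrected: MREstimate
    n_sim: int
    seed: int


def _normal_estimate(method: str, beta: float, se: float, n_snp: int, **kw) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snp=n_snp,
        **kw,
    )


# ---------------------------------------------------------------------------
# Wald ratio and IVW


def wald_ratio(instrument) -> MREstimate:
    """Single-instrument ratio estimate beta_out/beta_exp.

    SE by the first-order delta method, |se_out/beta_exp|; the exposure
    effect must be nonzero.
    """
    if instrument.beta_exp == 0:
        raise ValueError(f"{instrument.variant_id}: beta_exp is 0, Wald ratio undefined")
    beta = instrument.beta_out / instrument.beta_exp
    se = abs(instrument.se_out / instrument.beta_exp)
    return _normal_estimate("wald", beta, se, 1)


def cochran_q_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, int]:
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return q, len(bx) - 1


def ivw(hs: HarmonizedSet, mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of outcome on exposure effects through the
    origin with weights 1/se_out²; closed form Σwxy / Σwx².  ``mode``:

    - ``fixed``: SE = (Σ w·bx²)^{-1/2}
    - ``random``: multiplicative random effects, SE inflated by
      max(1, sqrt(Q/(k−1)))
    - ``auto``: random iff Cochran's Q has p < 0.05 (choice recorded)
    """
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    if k < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for a single SNP")
    if mode not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(np.sum(w * bx**2) ** -0.5)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_pval = float(stats.chi2.sf(q, k - 1))
    inflation = max(1.0, math.sqrt(q / (k - 1)))

    chosen = mode
    if mode == "auto":
        chosen = "random" if q_pval < 0.05 else "fixed"
    se = se_fixed * inflation if chosen == "random" else se_fixed
    method = "ivw_random" if chosen == "random" else "ivw_fixed"
    return _normal_estimate(
        method, beta, se, k,
        notes={"q": q, "q_pval": q_pval, "mode_requested": mode, "mode_used": chosen},
    )


# ---------------------------------------------------------------------------
# MR-Egger


def _orient_positive(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sign rows so every exposure effect is positive (jointly negating
    outcome effects); required for Egger/weighted-median invariance."""
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s, s


def egger(hs: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Instruments are oriented so beta_exp > 0.  The slope is the causal
    estimate; the intercept estimates average directional pleiotropy.  Both
    SEs are inflated by max(1, sqrt(Q'/(k−2))) (Rücker heterogeneity).
    """
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    bx, by, _ = _orient_positive(bx, by)
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    cov_unit = np.linalg.inv(XtW @ X)
    coef = cov_unit @ (XtW @ by)
    resid = by - X @ coef
    q_prime = float(np.sum(w * resid**2))
    inflation = max(1.0, math.sqrt(q_prime / (k - 2)))
    se = np.sqrt(np.diag(cov_unit)) * inflation
    intercept, slope = coef
    ip = float(2 * stats.norm.sf(abs(intercept / se[0])))
    est = _normal_estimate(
        "egger", slope, se[1], k,
        intercept=float(intercept),
        intercept_se=float(se[0]),
        intercept_pval=ip,
        notes={"q_prime": q_prime},
    )
    return est


# ---------------------------------------------------------------------------
# weighted median


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(theta)
    t = theta[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight of each ratio
    return float(np.interp(0.5, s, t))


def _weighted_median_rows(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians (vectorised bootstrap helper)."""
    order = np.argsort(theta, axis=1)
    t = np.take_along_axis(theta, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    n, k = t.shape
    # first index with cumulative weight >= 0.5, then linear interpolation
    hi = np.clip((s < 0.5).sum(axis=1), 1, k - 1)
    lo = hi - 1
    rows = np.arange(n)
    s_lo, s_hi = s[rows, lo], s[rows, hi]
    t_lo, t_hi = t[rows, lo], t[rows, hi]
    frac = np.clip((0.5 - s_lo) / np.where(s_hi > s_lo, s_hi - s_lo, 1.0), 0.0, 1.0)
    return t_lo + frac * (t_hi - t_lo)


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    Weights are inverse delta-method variances of the ratios.  The SE is
    the SD of the estimate over ``n_boot`` parametric bootstrap draws of
    (beta_exp, beta_out) from their normal sampling distributions.
    """
    bx, sx, by, sy = hs.arrays()
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    theta = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    w = 1.0 / var
    est = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_boot, k))
    by_s = rng.normal(by, sy, size=(n_boot, k))
    theta_s = by_s / bx_s
    var_s = sy**2 / bx_s**2 + by_s**2 * sx**2 / bx_s**4
    boots = _weighted_median_rows(theta_s, 1.0 / var_s)
    se = float(boots.std(ddof=1))
    return _normal_estimate("weighted_median", est, se, k)


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every SNP, in O(k)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    hs: HarmonizedSet, n_sim: int = 1000, sig: float = 0.05, seed: int = 0
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier search, distortion test.

    The observed residual sum of squares (each SNP against the IVW fit that
    leaves it out, weighted by 1/se_out²) is compared with ``n_sim``
    simulated RSS values drawn under the no-pleiotropy model; p-values use
    the add-one estimator so they are never zero.  Per-SNP outliers are
    flagged by Bonferroni-adjusted simulated residual p-values, and the
    corrected estimate is IVW on the outlier-free set.
    """
    bx, sx, by, sy = hs.arrays()
    k = len(bx)
    if k < 4:
        raise ValueError("MR-PRESSO needs >= 4 instruments")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    loo = _loo_ivw_betas(bx, by, w)
    obs_resid2 = w * (by - loo * bx) ** 2
    rss_obs = float(obs_resid2.sum())

    # simulate under the no-pleiotropy model: expected outcome effect of SNP j
    # is its leave-one-out prediction, with the SNP's own sampling noise
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(loo * bx, sy, size=(n_sim, k))
    wk = w[None, :]
    sxy = np.sum(wk * bx_s * by_s, axis=1, keepdims=True)
    sxx = np.sum(wk * bx_s**2, axis=1, keepdims=True)
    loo_s = (sxy - wk * bx_s * by_s) / (sxx - wk * bx_s**2)
    sim_resid2 = wk * (by_s - loo_s * bx_s) ** 2
    rss_sim = sim_resid2.sum(axis=1)
    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (1.0 + n_sim)

    # per-SNP outlier test, Bonferroni over k; the reported p uses the
    # add-one estimator, the flagging decision the raw empirical count (an
    # observed residual beyond every simulated one must remain flaggable)
    exceed = np.sum(sim_resid2 >= obs_resid2, axis=0)
    p_raw = (1.0 + exceed) / (1.0 + n_sim)
    p_adj = np.minimum(1.0, p_raw * k)
    ids = hs.variant_ids
    outlier_mask = (np.minimum(1.0, exceed / n_sim * k) < sig) & (global_pval < sig)
    outlier_ids = [ids[j] for j in range(k) if outlier_mask[j]]
    outlier_pvals = {ids[j]: float(p_adj[j]) for j in range(k)}

    full = ivw(hs, mode="fixed")
    if outlier_ids and k - len(outlier_ids) >= 2:
        kept = [i for i in hs.instruments if i.variant_id not in outlier_ids]
        sub = HarmonizedSet(hs.exposure_name, hs.outcome_name, kept)
        corrected = ivw(sub, mode="fixed")
        # distortion: compare the observed shift against shifts from random
        # removals of the same number of SNPs
        n_out = len(outlier_ids)
        obs_shift = abs(corrected.beta - full.beta)
        u = rng.random((n_sim, k))
        drop = np.argpartition(u, n_out - 1, axis=1)[:, :n_out]
        keep_mask = np.ones((n_sim, k), dtype=bool)
        np.put_along_axis(keep_mask, drop, False, axis=1)
        num = ((w * bx * by)[None, :] * keep_mask).sum(axis=1)
        den = ((w * bx**2)[None, :] * keep_mask).sum(axis=1)
        shifts = np.abs(num / den - full.beta)
        distortion_pval = float((1.0 + np.sum(shifts >= obs_shift)) / (1.0 + n_sim))
        corrected = MREstimate(
            "presso_corrected", corrected.beta, corrected.se, corrected.ci_low,
            corrected.ci_high, corrected.pval, corrected.n_snp,
        )
    else:
        distortion_pval = None
        corrected = MREstimate(
            "presso_corrected", full.beta, full.se, full.ci_low, full.ci_high,
            full.pval, full.n_snp,
        )
    return PressoResult(
        global_rss=rss_obs,
        global_pval=float(global_pval),
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals,
        distortion_pval=distortion_pval,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bayesian weighted MR


def _bwmr_logpost(theta, log_tau2, bx, sx, by, sy, weights):
    tau2 = np.exp(log_tau2)
    var = tau2 + sy**2 + theta**2 * sx**2
    ll = -0.5 * np.sum(weights * ((by - theta * bx) ** 2 / var + np.log(var)))
    # priors: theta ~ N(0, 10^2); tau ~ half-N(0, 0.5^2) with the log-tau2
    # Jacobian folded in
    lp = -0.5 * theta**2 / 100.0
    lp += -0.5 * tau2 / 0.25 + 0.5 * log_tau2
    return ll + lp


def _bwmr_chain(rng, n_iter, init, bx, sx, by, sy, weights):
    theta, lt2 = init
    step_t, step_l = 0.05, 0.5
    draws = np.empty((n_iter, 2))
    lp = _bwmr_logpost(theta, lt2, bx, sx, by, sy, weights)
    n_accept = 0
    n_adapt = n_iter // 3
    for i in range(n_iter):
        prop_t = theta + rng.normal(0, step_t)
        prop_l = lt2 + rng.normal(0, step_l)
        lp_prop = _bwmr_logpost(prop_t, prop_l, bx, sx, by, sy, weights)
        if np.log(rng.uniform()) < lp_prop - lp:
            theta, lt2, lp = prop_t, prop_l, lp_prop
            n_accept += 1
        draws[i] = theta, lt2
        if i < n_adapt and (i + 1) % 100 == 0:  # crude step adaptation in burn-in
            rate = n_accept / (i + 1)
            scale = 1.25 if rate > 0.35 else (0.8 if rate < 0.15 else 1.0)
            step_t *= scale
            step_l *= scale
    return draws


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat over post-burn-in chains (n_chain, n_draw)."""
    halves = np.concatenate(np.split(chains, 2, axis=1), axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    b = n * means.var(ddof=1)
    wv = variances.mean()
    var_hat = (n - 1) / n * wv + b / n
    return float(np.sqrt(var_hat / wv))


def bwmr(
    hs: HarmonizedSet,
    n_iter: int = 4000,
    seed: int = 0,
    rhat_max: float = 1.1,
    outlier_z: float = 3.0,
) -> MREstimate:
    """Bayesian weighted MR by seeded MCMC.

    Generative model: by_j ~ N(theta*gamma_j + alpha_j, se_out_j²) with
    pleiotropy alpha_j ~ N(0, tau²) and gamma_j ~ N(beta_exp_j, se_exp_j²).
    Marginalising gamma and alpha gives by_j ~ N(theta*bx_j,
    tau² + se_out_j² + theta²·se_exp_j²), which is sampled by
    random-walk Metropolis on (theta, log tau²) in two chains.  SNPs with
    posterior standardized residuals beyond ``outlier_z`` are down-weighted
    by (outlier_z/|z|)² and the chains re-run once.  Non-convergence
    (split-R-hat above ``rhat_max``) is a hard error.

    Returns the posterior mean, SD, and central 95% interval.
    """
    bx, sx, by, sy = hs.arrays()
    k = len(bx)
    if k < 3:
        raise ValueError("BWMR needs >= 3 instruments")
    rng = np.random.default_rng(seed)
    burn = n_iter // 2

    # IVW starting point
    w0 = 1.0 / sy**2
    theta0 = float(np.sum(w0 * bx * by) / np.sum(w0 * bx**2))

    weights = np.ones(k)
    for sweep in range(2):
        chains = []
        for c in range(2):
            init = (theta0 + 0.1 * (c - 0.5), np.log(1e-4) + c)
            chains.append(
                _bwmr_chain(rng, n_iter, init, bx, sx, by, sy, weights)[burn:]
            )
        post = np.stack(chains)  # (2, n_iter-burn, 2)
        if sweep == 0:
            # residual-based outlier down-weighting
            t_hat = post[..., 0].mean()
            tau2_hat = np.exp(post[..., 1]).mean()
            z = (by - t_hat * bx) / np.sqrt(tau2_hat + sy**2 + t_hat**2 * sx**2)
            new_w = np.minimum(1.0, (outlier_z / np.maximum(np.abs(z), 1e-12)) ** 2)
            if np.allclose(new_w, weights):
                break
            weights = new_w

    rhat = _split_rhat(post[..., 0])
    if rhat > rhat_max:
        raise RuntimeError(f"BWMR MCMC did not converge: split-R-hat = {rhat:.3f}")

    theta_draws = post[..., 0].ravel()
    mean = float(theta_draws.mean())
    sd = float(theta_draws.std(ddof=1))
    lo, hi = np.quantile(theta_draws, [0.025, 0.975])
    z = mean / sd
    return MREstimate(
        method="bwmr",
        beta=mean,
        se=sd,
        ci_low=float(lo),
        ci_high=float(hi),
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snp=k,
        notes={"rhat": rhat, "tau2_mean": float(np.exp(post[..., 1]).mean()),
               "tau2_q975": float(np.quantile(np.exp(post[..., 1]), 0.975))},
    )


# ---------------------------------------------------------------------------


def to_odds_ratio(estimate: MREstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate and its CI bounds to odds ratios."""
    return (
        math.exp(estimate.beta),
        math.exp(estimate.ci_low),
        math.exp(estimate.ci_high),
    )


def run_all(hs: HarmonizedSet, seed: int = 0) -> list[MREstimate]:
    """The standard five-method battery (IVW auto, BWMR, MR-PRESSO,
    weighted median, MR-Egger)."""
    out = [ivw(hs, mode="auto")]
    if len(hs.instruments) >= 3:
        out.append(bwmr(hs, seed=seed))
        out.append(weighted_median(hs, seed=seed + 1))
        out.append(egger(hs))
    if len(hs.instruments) >= 4:
        out.append(mr_presso(hs, seed=seed + 2).corrected)
    return out
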