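"""Heterogeneity, pleiotropy, influence, power, and reverse-causation checks.

These are the sensitivity analyses that accompany a UVMR battery: Cochran's
Q under the IVW and Egger fits, the I²_GX check of the NOME assumption,
leave-one-out influence, funnel-plot coordinates, an analytic power
calculation for a binary outcome, and a bidirectional (reverse-direction)
run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet
from .uvmr import MREstimate, ivw, run_all


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "ivw_q" | "egger_q"
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PowerInput:
    """Inputs for the binary-outcome MR power approximation."""

    n_outcome: int
    case_fraction: float
    r2_exposure: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        if not (0 < self.r2_exposure < 1):
            raise ValueError("r2_exposure must be in (0, 1)")


def cochran_q(hs: HarmonizedSet, method: str = "ivw_q") -> HeterogeneityResult:
    """Cochran's Q (IVW fit) or Rücker's Q' (Egger fit).

    Q = Σ_j w_j (beta_out_j − fitted_j)² with w_j = 1/se_out_j²; the
    p-value is the upper tail of chi-square with k−1 (IVW) or k−2 (Egger)
    degrees of freedom.
    """
    bx, _, by, sy = hs.arrays()
    k = len(bx)
    w = 1.0 / sy**2
    if method == "ivw_q":
        if k < 2:
            raise ValueError("Cochran's Q (IVW) needs >= 2 instruments")
        beta = np.sum(w * bx * by) / np.sum(w * bx**2)
        fitted = beta * bx
        df = k - 1
    elif method == "egger_q":
        if k < 3:
            raise ValueError("Rücker's Q' (Egger) needs >= 3 instruments")
        s = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * s, by * s
        X = np.column_stack([np.ones(k), bxo])
        XtW = X.T * w
        coef = np.linalg.solve(XtW @ X, XtW @ byo)
        fitted = (X @ coef) * s
        df = k - 2
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    q = float(np.sum(w * (by - fitted) ** 2))
    return HeterogeneityResult(method, q, df, float(stats.chi2.sf(q, df)))


def i2_gx(hs: HarmonizedSet) -> float:
    """I²_GX: fraction of variance in exposure-effect estimates not due to
    measurement error.  Values near 1 mean the NOME assumption of MR-Egger
    is safe; below ~0.9 Egger estimates are attenuated.
    """
    bx, sx, _, _ = hs.arrays()
    k = len(bx)
    if k < 2:
        raise ValueError("I²GX needs >= 2 instruments")
    w = 1.0 / sx**2
    b_bar = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum(w * (bx - b_bar) ** 2))
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (k - 1)) / q_gx)


def leave_one_out(hs: HarmonizedSet) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each SNP removed in turn."""
    k = len(hs.instruments)
    if k < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    out = []
    for j in range(k):
        sub = HarmonizedSet(
            hs.exposure_name,
            hs.outcome_name,
            hs.instruments[:j] + hs.instruments[j + 1:],
        )
        out.append((hs.instruments[j].variant_id, ivw(sub, mode="fixed")))
    return out


def funnel_data(hs: HarmonizedSet) -> list[tuple[str, float, float]]:
    """Per-SNP (variant_id, Wald ratio, precision = 1/SE(ratio)) for a
    funnel plot; no inference."""
    rows = []
    for i in hs.instruments:
        if i.beta_exp == 0:
            raise ValueError(f"{i.variant_id}: beta_exp is 0, ratio undefined")
        ratio = i.beta_out / i.beta_exp
        se = abs(i.se_out / i.beta_exp)
        rows.append((i.variant_id, ratio, 1.0 / se))
    return rows


def power_binary(inp: PowerInput) -> float:
    """Approximate power of two-sample MR with a binary outcome.

    Uses the standard non-centrality approximation: the IVW estimate of
    b = log(or_alt) has variance ≈ 1/(n·R²·cf·(1−cf)), giving
    NCP = n·R²·cf·(1−cf)·b² and
    power = Φ(−z_{1−α/2} + √NCP) + Φ(−z_{1−α/2} − √NCP).
    """
    b = math.log(inp.or_alt)
    ncp = inp.n_outcome * inp.r2_exposure * inp.case_fraction * (1 - inp.case_fraction) * b**2
    z = stats.norm.ppf(1 - inp.alpha / 2)
    return float(stats.norm.cdf(-z + math.sqrt(ncp)) + stats.norm.cdf(-z - math.sqrt(ncp)))


def bidirectional(
    forward: HarmonizedSet, reverse: HarmonizedSet, seed: int = 0
) -> dict[str, list[MREstimate]]:
    """Run the full UVMR battery in both causal directions.

    ``forward`` instruments the exposure against the outcome; ``reverse``
    instruments the outcome against the exposure.  Evidence of an effect in
    the reverse direction warns of reverse causation.
    """
    return {
        "forward": run_all(forward, seed=seed),
        "reverse": run_all(reverse, seed=seed + 1),
    }
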