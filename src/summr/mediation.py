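"""Network (two-step) MR mediation.

Three univariable IVW fits give the total effect c (exposure → outcome),
the a-path (exposure → mediator) and the b-path (mediator → outcome).  The
indirect effect is the product of coefficients a·b with a Monte Carlo
confidence interval (independent normal draws of a and b), and the
mediation proportion is a·b/c with its CI truncated below at 0.  When the
indirect effect and the total effect disagree in sign the proportion is
not interpretable and is reported as NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonize import (
    HarmonizedSet,
    compute_f_statistics,
    filter_genome_wide,
    harmonize_pair,
    screen_outcome_associated,
)
from .uvmr import MREstimate, ivw


@dataclass(frozen=True)
class MediationResult:
    total: MREstimate  # c: exposure -> outcome, log-odds per SD
    a_path: MREstimate  # exposure -> mediator, SD per SD
    b_path: MREstimate  # mediator -> outcome, log-odds per SD
    indirect: float  # a*b
    indirect_ci: tuple[float, float]
    proportion: float | None  # a*b / c, None when NA
    proportion_ci: tuple[float, float] | None
    status: str  # "ok" | "na_sign_conflict"
    n_draws: int
    seed: int


def indirect_effect(
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Product-of-coefficients indirect effect with a Monte Carlo CI.

    Point estimate a·b; the CI is the empirical 2.5%/97.5% quantiles of
    a*·b* with a* ~ N(a, se_a²) and b* ~ N(b, se_b²) drawn independently.
    Returns the draws too, so the proportion CI can reuse them.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.normal(a, se_a, n_draws) * rng.normal(b, se_b, n_draws)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return a * b, (float(lo), float(hi)), draws


def mediation_proportion(
    indirect: float,
    indirect_draws: np.ndarray,
    total: float,
) -> tuple[float | None, tuple[float, float] | None, str]:
    """Mediation proportion a·b/c with CI from the same Monte Carlo draws.

    The total effect is held at its point estimate; the CI is truncated
    below at 0.  A sign conflict between the indirect and total effect
    yields status ``na_sign_conflict`` and NA proportions.
    """
    if total == 0:
        raise ValueError("total effect is 0, proportion undefined")
    if indirect != 0 and np.sign(indirect) != np.sign(total):
        return None, None, "na_sign_conflict"
    prop = indirect / total
    lo, hi = np.quantile(indirect_draws / total, [0.025, 0.975])
    return prop, (float(max(lo, 0.0)), float(max(hi, 0.0))), "ok"


def _ivw_leg(
    exposure_records,
    outcome_records,
    p_threshold: float = 5e-8,
    f_threshold: float = 10.0,
    names: tuple[str, str] = ("exposure", "outcome"),
) -> MREstimate:
    sig = filter_genome_wide(exposure_records, p_threshold)
    hs = harmonize_pair(sig, outcome_records, exposure_name=names[0], outcome_name=names[1])
    hs = compute_f_statistics(hs, f_threshold)
    hs = screen_outcome_associated(hs, p_threshold)
    if len(hs.instruments) < 2:
        raise ValueError(f"leg {names[0]} -> {names[1]}: fewer than 2 instruments")
    return ivw(hs, mode="auto")


def run_network_mr(
    exposure_records,
    mediator_records,
    outcome_records,
    p_threshold: float = 5e-8,
    f_threshold: float = 10.0,
    n_draws: int = 100_000,
    seed: int = 0,
) -> MediationResult:
    """Full network-MR mediation from three summary-statistic datasets.

    Each leg runs the standard instrument pipeline (genome-wide filter,
    harmonization, weak-instrument and outcome-association screens) and an
    IVW fit; the IVW estimates feed the product-of-coefficients machinery.
    """
    total = _ivw_leg(exposure_records, outcome_records, p_threshold, f_threshold,
                     ("exposure", "outcome"))
    a_path = _ivw_leg(exposure_records, mediator_records, p_threshold, f_threshold,
                      ("exposure", "mediator"))
    b_path = _ivw_leg(mediator_records, outcome_records, p_threshold, f_threshold,
                      ("mediator", "outcome"))
    ab, ci, draws = indirect_effect(
        a_path.beta, a_path.se, b_path.beta, b_path.se, n_draws, seed
    )
    prop, prop_ci, status = mediation_proportion(ab, draws, total.beta)
    return MediationResult(
        total=total,
        a_path=a_path,
        b_path=b_path,
        indirect=ab,
        indirect_ci=ci,
        proportion=prop,
        proportion_ci=prop_ci,
        status=status,
        n_draws=n_draws,
        seed=seed,
    )
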