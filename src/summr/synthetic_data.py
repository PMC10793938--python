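"""Synthetic two-sample GWAS summary statistics.

The generator emulates the statistical structure the estimators assume: a
continuous exposure measured in SD units with per-SNP effects scaled to a
target variance explained, a binary outcome whose per-SNP log-odds effects
carry the causal signal plus optional pleiotropy, and independent sampling
noise on the two sides (non-overlapping samples).  Exposure-side SEs follow
1/sqrt(2p(1-p)·n) and outcome-side SEs the case-control analogue
1/sqrt(2p(1-p)·n·cf·(1-cf)).

The default configuration mirrors the regime of a large biobank exposure
GWAS against a registry case-control outcome: ~100 instruments explaining
~18% of exposure variance in ~440,000 samples, an outcome sample of
~307,000 with 1.36% cases, and a true effect of 0.398 log-odds per SD
(odds ratio 1.489).

Pleiotropy modes
----------------
``none``              all instruments valid
``balanced``          pleiotropic effects with mean 0 (InSIDE holds)
``directional``       pleiotropic effects with a nonzero mean (InSIDE holds)
``inside_violating``  pleiotropic effects correlated with instrument
                      strength, which is what the Egger intercept test is
                      most sensitive to
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .gwas_io import LDInfo, SummaryStatRecord


@dataclass(frozen=True)
class PleiotropyConfig:
    mode: str = "none"  # none | balanced | directional | inside_violating
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    prop_invalid: float = 0.0


@dataclass(frozen=True)
class MediatorConfig:
    a: float = 0.3  # exposure -> mediator, SD per SD
    b: float = 0.5  # mediator -> outcome, log-odds per SD
    direct: float = 0.2  # exposure -> outcome not via mediator
    k_mediator: int = 100  # mediator-specific instruments
    n_mediator: int = 100_000
    h2_mediator: float = 0.18


@dataclass(frozen=True)
class LDBlockConfig:
    n_blocks: int = 20
    within_r2: float = 0.9


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic two-sample MR dataset."""

    seed: int
    k_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.18
    n_exposure: int = 440_000
    n_outcome: int = 307_452
    case_fraction: float = 0.0136
    theta: float = math.log(1.489)  # true causal log-odds per SD
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    m_exposures: int = 1
    rho: float = 0.0  # correlation of per-SNP effects across exposures
    direct_effects: tuple[float, ...] | None = None  # MVMR truth, default (theta, 0, ...)
    mediator: MediatorConfig | None = None
    ld: LDBlockConfig | None = None

    def __post_init__(self) -> None:
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if not (0 < self.exposure_h2 < 1):
            raise ValueError("exposure_h2 must be in (0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.pleiotropy.mode not in (
            "none", "balanced", "directional", "inside_violating",
        ):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy.mode!r}")


@dataclass
class SyntheticStudy:
    exposure_stats: list[SummaryStatRecord]
    outcome_stats: list[SummaryStatRecord]
    mediator_stats: list[SummaryStatRecord] | None
    extra_exposure_stats: dict[str, list[SummaryStatRecord]]
    ld_info: LDInfo | None
    truth: dict


def paper_like_config(seed: int, **overrides) -> SimConfig:
    """The default biobank-versus-registry scenario (see module docstring)."""
    return SimConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# helpers


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, 1e-300)


def _records(ids, mafs, beta, se, n, prefix_pos=0) -> list[SummaryStatRecord]:
    p = _pvals(beta, se)
    return [
        SummaryStatRecord(
            variant_id=ids[j],
            chrom="1",
            pos=prefix_pos + (j + 1) * 50_000,
            effect_allele="A",
            other_allele="G",
            eaf=float(mafs[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(p[j]),
            n=int(n),
        )
        for j in range(len(ids))
    ]


def _scaled_effects(rng, mafs, h2) -> np.ndarray:
    """Per-SNP standardized effects with Σ 2p(1-p)γ² = h2 exactly."""
    gamma = rng.normal(0.0, 1.0, len(mafs))
    var = 2.0 * mafs * (1.0 - mafs)
    scale = math.sqrt(h2 / float(np.sum(var * gamma**2)))
    return gamma * scale


def _pleiotropy(rng, cfg: SimConfig, gamma: np.ndarray) -> np.ndarray:
    pc = cfg.pleiotropy
    k = len(gamma)
    alpha = np.zeros(k)
    if pc.mode == "none" or pc.prop_invalid <= 0:
        return alpha
    n_invalid = max(1, int(round(pc.prop_invalid * k)))
    idx = rng.choice(k, size=n_invalid, replace=False)
    # "directional" is defined in the oriented frame (exposure effect
    # positive), so the offset is applied along sign(gamma)
    sgn = np.sign(gamma[idx])
    if pc.mode == "balanced":
        alpha[idx] = rng.normal(0.0, pc.alpha_sd, n_invalid)
    elif pc.mode == "directional":
        alpha[idx] = sgn * rng.normal(pc.alpha_mean, pc.alpha_sd, n_invalid)
    elif pc.mode == "inside_violating":
        # pleiotropy proportional to instrument strength plus noise: breaks
        # the InSIDE independence the Egger intercept relies on
        g = np.abs(gamma[idx])
        scale = pc.alpha_sd / max(float(np.std(g)), 1e-12)
        alpha[idx] = sgn * (
            pc.alpha_mean + scale * (g - g.mean()) + rng.normal(0.0, pc.alpha_sd / 2, n_invalid)
        )
    return alpha


def _truth_base(cfg: SimConfig) -> dict:
    t = asdict(cfg)
    t["maf_range"] = list(cfg.maf_range)
    return t


# ---------------------------------------------------------------------------
# generators


def generate_univariable(cfg: SimConfig) -> SyntheticStudy:
    """One exposure, one binary outcome, independent sampling noise."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_snps
    mafs = rng.uniform(*cfg.maf_range, k)
    var = 2.0 * mafs * (1.0 - mafs)
    gamma = _scaled_effects(rng, mafs, cfg.exposure_h2)
    se_x = 1.0 / np.sqrt(var * cfg.n_exposure)
    if np.any(gamma**2 / se_x**2 < 1e-12):
        raise ValueError("exposure_h2 too small for k_snps: degenerate instruments")
    alpha = _pleiotropy(rng, cfg, gamma)
    beta_out_true = cfg.theta * gamma + alpha
    se_y = 1.0 / np.sqrt(
        var * cfg.n_outcome * cfg.case_fraction * (1.0 - cfg.case_fraction)
    )
    rng_x = np.random.default_rng(rng.integers(2**31))  # independent streams:
    rng_y = np.random.default_rng(rng.integers(2**31))  # two-sample design
    bx_hat = gamma + rng_x.normal(0.0, se_x)
    by_hat = beta_out_true + rng_y.normal(0.0, se_y)

    ids = [f"rs{j + 1:06d}" for j in range(k)]
    truth = _truth_base(cfg)
    truth.update(
        gamma=gamma.tolist(), alpha=alpha.tolist(), mafs=mafs.tolist(),
        beta_out_true=beta_out_true.tolist(),
    )
    ld_info = generate_ld_blocks(cfg, ids) if cfg.ld else None
    return SyntheticStudy(
        exposure_stats=_records(ids, mafs, bx_hat, se_x, cfg.n_exposure),
        outcome_stats=_records(ids, mafs, by_hat, se_y, cfg.n_outcome),
        mediator_stats=None,
        extra_exposure_stats={},
        ld_info=ld_info,
        truth=truth,
    )


def generate_mvmr(cfg: SimConfig) -> SyntheticStudy:
    """m correlated exposures sharing instruments, one binary outcome.

    Per-SNP effect vectors are multivariate normal with cross-exposure
    correlation ``rho``; each exposure's effects are scaled to
    ``exposure_h2``.  The outcome carries the configured direct effects
    (default: full effect for the first exposure, zero for the rest).
    """
    if cfg.m_exposures < 2:
        raise ValueError("generate_mvmr needs m_exposures >= 2")
    m = cfg.m_exposures
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_snps
    mafs = rng.uniform(*cfg.maf_range, k)
    var = 2.0 * mafs * (1.0 - mafs)

    corr = np.full((m, m), cfg.rho)
    np.fill_diagonal(corr, 1.0)
    raw = rng.multivariate_normal(np.zeros(m), corr, size=k)  # (k, m)
    gammas = np.empty_like(raw)
    for a in range(m):
        scale = math.sqrt(cfg.exposure_h2 / float(np.sum(var * raw[:, a] ** 2)))
        gammas[:, a] = raw[:, a] * scale

    direct = (
        np.asarray(cfg.direct_effects, float)
        if cfg.direct_effects is not None
        else np.concatenate([[cfg.theta], np.zeros(m - 1)])
    )
    if direct.shape != (m,):
        raise ValueError("direct_effects length must equal m_exposures")
    beta_out_true = gammas @ direct + _pleiotropy(rng, cfg, gammas[:, 0])

    se_x = 1.0 / np.sqrt(var * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(
        var * cfg.n_outcome * cfg.case_fraction * (1.0 - cfg.case_fraction)
    )
    ids = [f"rs{j + 1:06d}" for j in range(k)]
    exposures: dict[str, list[SummaryStatRecord]] = {}
    for a in range(m):
        rng_a = np.random.default_rng(rng.integers(2**31))
        bx_hat = gammas[:, a] + rng_a.normal(0.0, se_x)
        exposures[f"exposure_{a + 1}"] = _records(ids, mafs, bx_hat, se_x, cfg.n_exposure)
    rng_y = np.random.default_rng(rng.integers(2**31))
    by_hat = beta_out_true + rng_y.normal(0.0, se_y)

    truth = _truth_base(cfg)
    truth.update(
        gammas=gammas.tolist(), direct_effects=direct.tolist(), mafs=mafs.tolist(),
    )
    first = "exposure_1"
    return SyntheticStudy(
        exposure_stats=exposures[first],
        outcome_stats=_records(ids, mafs, by_hat, se_y, cfg.n_outcome),
        mediator_stats=None,
        extra_exposure_stats={n: r for n, r in exposures.items() if n != first},
        ld_info=generate_ld_blocks(cfg, ids) if cfg.ld else None,
        truth=truth,
    )


def generate_mediation(cfg: SimConfig) -> SyntheticStudy:
    """X -> M -> Y chain with mediator-specific instruments.

    Exposure SNPs affect the mediator through the a-path and the outcome
    through direct + a·b; mediator-specific SNPs affect the mediator
    directly and the outcome through the b-path.  The total effect
    direct + a·b is recorded in the truth block.
    """
    if cfg.mediator is None:
        raise ValueError("mediator config required")
    med = cfg.mediator
    rng = np.random.default_rng(cfg.seed)
    kx, km = cfg.k_snps, med.k_mediator
    k = kx + km
    mafs = rng.uniform(*cfg.maf_range, k)
    var = 2.0 * mafs * (1.0 - mafs)

    gamma = np.zeros(k)  # exposure effects (exposure SNPs only)
    gamma[:kx] = _scaled_effects(rng, mafs[:kx], cfg.exposure_h2)
    delta = np.zeros(k)  # mediator-specific effects
    delta[kx:] = _scaled_effects(rng, mafs[kx:], med.h2_mediator)

    beta_med_true = med.a * gamma + delta
    beta_out_true = (med.direct + med.a * med.b) * gamma + med.b * delta

    se_x = 1.0 / np.sqrt(var * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(var * med.n_mediator)
    se_y = 1.0 / np.sqrt(
        var * cfg.n_outcome * cfg.case_fraction * (1.0 - cfg.case_fraction)
    )
    rng_x = np.random.default_rng(rng.integers(2**31))
    rng_m = np.random.default_rng(rng.integers(2**31))
    rng_y = np.random.default_rng(rng.integers(2**31))
    bx_hat = gamma + rng_x.normal(0.0, se_x)
    bm_hat = beta_med_true + rng_m.normal(0.0, se_m)
    by_hat = beta_out_true + rng_y.normal(0.0, se_y)

    ids = [f"rs{j + 1:06d}" for j in range(k)]
    truth = _truth_base(cfg)
    truth.update(
        gamma=gamma.tolist(), delta=delta.tolist(), mafs=mafs.tolist(),
        a=med.a, b=med.b, direct=med.direct,
        indirect=med.a * med.b, total=med.direct + med.a * med.b,
    )
    return SyntheticStudy(
        exposure_stats=_records(ids, mafs, bx_hat, se_x, cfg.n_exposure),
        outcome_stats=_records(ids, mafs, by_hat, se_y, cfg.n_outcome),
        mediator_stats=_records(ids, mafs, bm_hat, se_m, med.n_mediator),
        extra_exposure_stats={},
        ld_info=None,
        truth=truth,
    )


def as_harmonized_set(study: SyntheticStudy) -> "HarmonizedSet":
    """Wrap a study's raw stats as an analysis-ready harmonized set.

    The generator emits both sides pre-aligned to the same effect allele,
    so no allele harmonization is needed.
    """
    from .harmonize import HarmonizedSet

    return HarmonizedSet.from_arrays(
        [r.beta for r in study.exposure_stats],
        [r.se for r in study.exposure_stats],
        [r.beta for r in study.outcome_stats],
        [r.se for r in study.outcome_stats],
        variant_ids=[r.variant_id for r in study.exposure_stats],
    )


def as_mvmr_input(study: SyntheticStudy) -> "MVMRInput":
    """Assemble the full k x m effect matrix of a multi-exposure study,
    bypassing instrument selection (for estimator-isolation experiments)."""
    from .mvmr import MVMRInput

    exposures = {"exposure_1": study.exposure_stats, **study.extra_exposure_stats}
    names = sorted(exposures)
    bx = np.array([[r.beta for r in exposures[n]] for n in names]).T
    sx = np.array([[r.se for r in exposures[n]] for n in names]).T
    return MVMRInput(
        [r.variant_id for r in study.outcome_stats],
        bx,
        sx,
        np.array([r.beta for r in study.outcome_stats]),
        np.array([r.se for r in study.outcome_stats]),
        names,
    )


def generate_ld_blocks(cfg: SimConfig, variant_ids: list[str] | None = None) -> LDInfo:
    """Block-diagonal r² panel: ``within_r2`` inside blocks, 0 between."""
    if cfg.ld is None:
        raise ValueError("ld config required")
    k = cfg.k_snps
    ids = variant_ids if variant_ids is not None else [f"rs{j + 1:06d}" for j in range(k)]
    n_blocks = min(cfg.ld.n_blocks, k)
    r2 = np.zeros((k, k))
    bounds = np.linspace(0, k, n_blocks + 1).astype(int)
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        r2[lo:hi, lo:hi] = cfg.ld.within_r2
    np.fill_diagonal(r2, 1.0)
    return LDInfo(variant_ids=list(ids), r2=r2)
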