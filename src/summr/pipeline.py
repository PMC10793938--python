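"""Config-driven end-to-end driver.

Runs the whole workflow on summary-statistic files: instrument selection
and harmonization, the five-method UVMR battery, the sensitivity suite,
and optional MVMR / mediation / bidirectional stages.  Every estimate is
labelled against a Bonferroni-adjusted threshold alpha/n_tests:
``significant`` below it, ``suggestive`` between it and alpha, ``null``
otherwise.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import diagnostics, gwas_io, harmonize, mediation, mvmr, uvmr

logger = logging.getLogger("summr")


@dataclass
class RunConfig:
    exposure: str
    outcome: str
    mediator: str | None = None
    covariates: list[str] = field(default_factory=list)
    ld_matrix: str | None = None
    exclusion_lists: list[str] = field(default_factory=list)
    p_instrument: float = 5e-8
    r2_threshold: float = 0.001
    f_min: float = 10.0
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)
    p_outcome_screen: float = 5e-8
    alpha: float = 0.05
    n_tests: int = 1
    run_mvmr: bool = False
    run_mediation: bool = False
    run_bidirectional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tests

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "palindrome_eaf_band" in raw:
            raw["palindrome_eaf_band"] = tuple(raw["palindrome_eaf_band"])
        return cls(**raw)


def classify_pvalue(p: float, alpha: float = 0.05, n_tests: int = 1) -> str:
    """Label a p-value: ``significant`` (p < alpha/n_tests), ``suggestive``
    (alpha/n_tests <= p < alpha), or ``null``."""
    if not (0 < p <= 1):
        raise ValueError(f"p-value outside (0, 1]: {p}")
    if p < alpha / n_tests:
        return "significant"
    if p < alpha:
        return "suggestive"
    return "null"


def _select_instruments(cfg: RunConfig, exposure_records, outcome_records, ld, exclusions):
    """The standard selection chain; returns the harmonized set."""
    sig = harmonize.filter_genome_wide(exposure_records, cfg.p_instrument)
    clumped = harmonize.clump(sig, ld, cfg.r2_threshold)
    hs = harmonize.harmonize_pair(
        clumped, outcome_records, cfg.palindrome_eaf_band
    )
    hs = harmonize.compute_f_statistics(hs, cfg.f_min)
    hs = harmonize.screen_outcome_associated(hs, cfg.p_outcome_screen)
    if exclusions:
        hs = harmonize.apply_exclusions(hs, *exclusions)
    return hs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the report bundle.

    The bundle maps stage name to results and includes the provenance log,
    significance labels, and all seeds, so a run is reproducible and
    auditable.
    """
    t0 = time.time()
    report: dict = {"config": {**cfg.__dict__}, "stages": {}}

    exposure = gwas_io.read_summary_stats(cfg.exposure)
    outcome = gwas_io.read_summary_stats(cfg.outcome)
    ld = gwas_io.read_ld_matrix(cfg.ld_matrix) if cfg.ld_matrix else None
    exclusions = [
        gwas_io.read_exclusion_list(p, reason="confounder") for p in cfg.exclusion_lists
    ]

    hs = _select_instruments(cfg, exposure, outcome, ld, exclusions)
    report["stages"]["harmonize"] = {
        "n_instruments": len(hs.instruments),
        "provenance": [list(step) for step in hs.provenance_log],
    }
    logger.info("harmonize: %d instruments (%.2fs)", len(hs.instruments), time.time() - t0)

    estimates = uvmr.run_all(hs, seed=cfg.seed)
    report["stages"]["uvmr"] = [
        {
            "method": e.method,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pval": e.pval,
            "n_snp": e.n_snp,
            "or": uvmr.to_odds_ratio(e)[0],
            "label": classify_pvalue(e.pval, cfg.alpha, cfg.n_tests),
        }
        for e in estimates
    ]

    diag: dict = {}
    if len(hs.instruments) >= 2:
        q = diagnostics.cochran_q(hs, "ivw_q")
        diag["heterogeneity_ivw"] = {"q": q.q, "df": q.df, "pval": q.pval}
        diag["i2_gx"] = diagnostics.i2_gx(hs)
    if len(hs.instruments) >= 3:
        q = diagnostics.cochran_q(hs, "egger_q")
        diag["heterogeneity_egger"] = {"q": q.q, "df": q.df, "pval": q.pval}
        eg = next((e for e in estimates if e.method == "egger"), None)
        if eg is not None:
            diag["egger_intercept_pval"] = eg.intercept_pval
        diag["leave_one_out"] = [
            {"dropped": vid, "beta": e.beta, "ci_low": e.ci_low, "ci_high": e.ci_high}
            for vid, e in diagnostics.leave_one_out(hs)
        ]
        diag["funnel"] = [
            {"variant_id": v, "ratio": r, "precision": p}
            for v, r, p in diagnostics.funnel_data(hs)
        ]
    if len(hs.instruments) >= 4:
        pres = uvmr.mr_presso(hs, seed=cfg.seed + 2)
        diag["presso_global_pval"] = pres.global_pval
        diag["presso_outliers"] = pres.outlier_ids
    report["stages"]["diagnostics"] = diag

    if cfg.run_mvmr and cfg.covariates:
        exposures = {"exposure": exposure}
        for i, path in enumerate(cfg.covariates):
            exposures[f"covariate_{i + 1}"] = gwas_io.read_summary_stats(path)
        inp = mvmr.build_mvmr_input(
            exposures, outcome, ld=ld,
            p_threshold=cfg.p_instrument, r2_threshold=cfg.r2_threshold,
        )
        est = mvmr.mv_ivw(inp)
        q, qp = mvmr.validity_q(inp, est.beta)
        report["stages"]["mvmr"] = {
            "exposures": est.exposure_names,
            "beta": est.beta.tolist(),
            "se": est.se.tolist(),
            "pval": est.pval.tolist(),
            "labels": [
                classify_pvalue(p, cfg.alpha, cfg.n_tests) for p in est.pval
            ],
            "conditional_f": mvmr.conditional_f(inp).tolist(),
            "validity_q": q,
            "validity_pval": qp,
        }

    if cfg.run_mediation and cfg.mediator:
        med_records = gwas_io.read_summary_stats(cfg.mediator)
        med = mediation.run_network_mr(
            exposure, med_records, outcome,
            p_threshold=cfg.p_instrument, f_threshold=cfg.f_min, seed=cfg.seed + 3,
        )
        report["stages"]["mediation"] = {
            "total": med.total.beta,
            "a_path": med.a_path.beta,
            "b_path": med.b_path.beta,
            "indirect": med.indirect,
            "indirect_ci": list(med.indirect_ci),
            "proportion": med.proportion,
            "proportion_ci": None if med.proportion_ci is None else list(med.proportion_ci),
            "status": med.status,
        }

    if cfg.run_bidirectional:
        # reverse direction: instrument the outcome against the exposure
        try:
            rev = _select_instruments(cfg, outcome, exposure, ld, exclusions)
            if len(rev.instruments) >= 2:
                report["stages"]["bidirectional_reverse"] = [
                    {"method": e.method, "beta": e.beta, "pval": e.pval}
                    for e in uvmr.run_all(rev, seed=cfg.seed + 4)
                ]
            else:
                report["stages"]["bidirectional_reverse"] = "insufficient instruments"
        except ValueError as exc:
            report["stages"]["bidirectional_reverse"] = f"not estimable: {exc}"

    report["bonferroni_threshold"] = cfg.bonferroni_threshold
    report["elapsed_s"] = time.time() - t0
    return report
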