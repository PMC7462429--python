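"""End-to-end orchestration of the analysis pipeline.

``run_all`` chains the full inference sequence on a cohort (real files or
the synthetic generator): thought-pattern decomposition, NBS component
discovery for every score contrast, signed graph metrics on the masked
connectomes, test-retest reliability when a second session is available,
and mediation of brain -> thought -> well-being for every significant
component.  The result is a plain JSON-serializable report with a config
and seed echo so that identical inputs reproduce identical numbers.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import decomposition as dec
from . import mediation as med
from . import nbs
from .connectome import mean_connectivity
from .metrics import compute_metrics, group_metrics
from .reliability import change_correlation, icc
from .synthetic import SyntheticCohort, simulate_retest

logger = logging.getLogger(__name__)

WELLBEING_DOMAINS = ("psychological", "social")
MEDIATION_COVARIATES = ("age", "gender", "motion_fraction")


@dataclass
class PipelineConfig:
    """Analysis settings; defaults reproduce the reference pipeline
    (T = 3.2, alpha = 0.05, 5,000 permutations, 5,000 bootstrap samples)."""

    T_threshold: float = 3.2
    n_permutations: int = 5000
    alpha: float = 0.05
    sidedness: str = "two_sided"
    scheme: str = "permute_interest"
    n_boot: int = 5000
    component_rule: str = "fixed:3"
    icc_form: str = "icc2_1"
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def log_fractional_strength_over_edges(stack: np.ndarray, edges) -> np.ndarray:
    """Per-subject natural log of pos/neg strength over a fixed edge set."""
    i = np.array([e[0] for e in edges])
    j = np.array([e[1] for e in edges])
    w = stack[:, i, j]
    pos = np.clip(w, 0, None).sum(axis=1)
    neg = np.clip(-w, 0, None).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where((pos > 0) & (neg > 0), np.log(pos) - np.log(neg), np.nan)


def _select_components(evals_by_cluster, rule: str):
    if rule.startswith("fixed:"):
        k = dec.select_n_components(evals_by_cluster[0], rule)
        return (k, dec.select_n_components(evals_by_cluster[1], rule))
    return tuple(dec.select_n_components(ev, rule) for ev in evals_by_cluster)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_all(cohort: SyntheticCohort, retest: SyntheticCohort | None = None,
            config: PipelineConfig | None = None) -> dict:
    """Run the full pipeline and return the run report.

    Parameters
    ----------
    cohort
        Session-1 data (any :class:`SyntheticCohort`-shaped object: tables
        sharing a subject index plus a connectome per subject).
    retest
        Optional session-2 data for a subset of subjects; enables the
        reliability stage.
    """
    cfg = config or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2 ** 31)
    report: dict = {"provenance": {
        "config": asdict(cfg),
        "stage_seeds": {"nbs": int(seeds[0]), "icc": int(seeds[1]),
                        "mediation": int(seeds[2])},
        "n_subjects": len(cohort.ratings),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }, "stages": {}}
    timings = {}

    # --- 1. thought-pattern decomposition -------------------------------
    t0 = time.perf_counter()
    linkage = dec.cluster_items(cohort.ratings)
    # eigenvalues per cluster for the component-count rule
    probe = dec.fit_pca_varimax(cohort.ratings, linkage, n_components=1)
    evals = [probe.clusters[c].eigenvalues for c in (0, 1)]
    k_ab = _select_components(evals, cfg.component_rule)
    model = dec.fit_pca_varimax(cohort.ratings, linkage, n_components=k_ab)
    scores = dec.score_components(model, cohort.ratings)
    report["stages"]["decomposition"] = {
        "cluster_of_item": linkage.cluster_of_item.to_dict(),
        "n_components": list(k_ab),
        "variance_explained": model.variance_explained,
        "eigenvalues": {dec.CLUSTER_NAMES[c]: evals[c].tolist() for c in (0, 1)},
        "loadings": {dec.CLUSTER_NAMES[c]: pd.DataFrame(
            model.clusters[c].loadings, index=model.clusters[c].items
        ).round(6).to_dict() for c in (0, 1)},
    }
    timings["decomposition"] = time.perf_counter() - t0

    # --- 2. connectomes and design --------------------------------------
    t0 = time.perf_counter()
    stack = cohort.connectome_stack()
    mean_conn = np.array([mean_connectivity(c) for c in cohort.connectomes])
    design = nbs.make_design(scores, cohort.covariates, mean_conn)
    timings["design"] = time.perf_counter() - t0

    # --- 3. NBS per contrast --------------------------------------------
    t0 = time.perf_counter()
    nbs_results = {}
    nbs_report = {}
    for ci, contrast in enumerate(scores.columns):
        res = nbs.nbs_test(stack, design, contrast, T=cfg.T_threshold,
                           n_perm=cfg.n_permutations,
                           seed=int(seeds[0]) + ci, scheme=cfg.scheme,
                           sidedness=cfg.sidedness, alpha=cfg.alpha)
        nbs_results[contrast] = res
        nbs_report[contrast] = {
            "components": [
                {"size": c.size, "n_nodes": len(c.nodes),
                 "fwe_p": float(p), "significant": bool(s)}
                for c, p, s in zip(res.components, res.fwe_p, res.significant)],
            "null_max_quantiles": {
                q: float(np.quantile(res.null_max_sizes, float(q)))
                for q in ("0.5", "0.95", "0.99")},
        }
        logger.info("NBS %s: %d components, %d significant", contrast,
                    len(res.components), int(res.significant.sum()))
    report["stages"]["nbs"] = nbs_report
    timings["nbs"] = time.perf_counter() - t0

    # --- 4. graph metrics on significant components ---------------------
    t0 = time.perf_counter()
    significant = []  # (contrast, component_index, edges)
    for contrast, res in nbs_results.items():
        for k, sig in enumerate(res.significant):
            if sig:
                significant.append((contrast, k, res.components[k].edges))
    metrics_report = {}
    logfs = {}
    for contrast, k, edges in significant:
        key = f"{contrast}/comp{k}"
        masked = [nbs.mask_connectome(c, nbs_results[contrast], k)
                  for c in cohort.connectomes]
        per_subject = [compute_metrics(m, component_index=k) for m in masked]
        logfs[key] = log_fractional_strength_over_edges(stack, edges)
        n_undefined = int(np.isnan(logfs[key]).sum())
        metrics_report[key] = {
            "n_edges": len(edges),
            "group_mean_nodes": group_metrics(masked).round(6).to_dict(),
            "mean_fractional_strength": float(np.nanmean(
                [m.fractional_strength for m in per_subject])),
            "mean_log_fractional_strength": float(np.nanmean(logfs[key])),
            "n_undefined_fractional_strength": n_undefined,
        }
    report["stages"]["metrics"] = metrics_report
    timings["metrics"] = time.perf_counter() - t0

    # --- 5. test-retest reliability -------------------------------------
    if retest is not None:
        t0 = time.perf_counter()
        retest_ids = [s for s in retest.ratings.index
                      if s in cohort.ratings.index]
        scores2 = dec.project_session(model, retest.ratings.loc[retest_ids])
        scores1 = scores.loc[retest_ids]
        stack2 = retest.connectome_stack()
        rel_report = {"n_retest": len(retest_ids), "scores": {}, "brain": {},
                      "change_correlation": {}}
        for col in scores.columns:
            r = icc(scores1[col].to_numpy(), scores2[col].to_numpy(),
                    n_boot=cfg.n_boot, seed=int(seeds[1]), form=cfg.icc_form)
            rel_report["scores"][col] = {
                "icc": r.icc, "ci": [r.ci_low, r.ci_high], "p": r.p}
        pos1 = [cohort.ratings.index.get_loc(s) for s in retest_ids]
        for contrast, k, edges in significant:
            key = f"{contrast}/comp{k}"
            x1 = log_fractional_strength_over_edges(stack[pos1], edges)
            x2 = log_fractional_strength_over_edges(stack2, edges)
            ok = np.isfinite(x1) & np.isfinite(x2)
            if ok.sum() >= 5:
                r = icc(x1[ok], x2[ok], n_boot=cfg.n_boot,
                        seed=int(seeds[1]) + 1, form=cfg.icc_form)
                rel_report["brain"][key] = {
                    "icc": r.icc, "ci": [r.ci_low, r.ci_high], "p": r.p}
                dm = (scores2[contrast].to_numpy()
                      - scores1[contrast].to_numpy())[ok]
                cr, cp = change_correlation(dm, (x2 - x1)[ok])
                rel_report["change_correlation"][key] = {"r": cr, "p": cp}
        report["stages"]["reliability"] = rel_report
        timings["reliability"] = time.perf_counter() - t0

    # --- 6. regressions and mediation -----------------------------------
    t0 = time.perf_counter()
    cov = cohort.covariates[list(MEDIATION_COVARIATES)]
    med_report = {}
    for contrast, k, edges in significant:
        key = f"{contrast}/comp{k}"
        x = logfs[key]
        entry = {}
        raw_p = {}
        for domain in WELLBEING_DOMAINS:
            y = cohort.wellbeing[domain].to_numpy(dtype=float)
            predictors = cov.copy()
            predictors.insert(0, "log_fractional_strength", x)
            reg = med.fit_linear(y, predictors)
            raw_p[domain] = float(reg.pvalues["log_fractional_strength"])
            m_res = med.mediate(
                x, scores[contrast].to_numpy(), y, covariates=cov,
                n_boot=cfg.n_boot, seed=int(seeds[2]))
            entry[domain] = {
                "regression": {
                    "beta": float(reg.params["log_fractional_strength"]),
                    "t": float(reg.tvalues["log_fractional_strength"]),
                    "p": raw_p[domain], "df_resid": reg.df_resid,
                    "n_used": reg.n_used},
                "mediation": {
                    "a": m_res.a, "b": m_res.b, "c": m_res.c,
                    "c_prime": m_res.c_prime, "indirect": m_res.indirect,
                    "se_indirect": m_res.se_indirect,
                    "ci": [m_res.ci_low, m_res.ci_high],
                    "significant": m_res.significant,
                    "n_used": m_res.n_used},
            }
        adj = med.bonferroni_domains(
            [raw_p[d] for d in WELLBEING_DOMAINS], k=len(WELLBEING_DOMAINS))
        for d, pa in zip(WELLBEING_DOMAINS, np.atleast_1d(adj)):
            entry[d]["regression"]["p_bonferroni"] = float(pa)
        med_report[key] = entry
    report["stages"]["mediation"] = med_report
    timings["mediation"] = time.perf_counter() - t0

    report["provenance"]["timings_s"] = {k: round(v, 3)
                                         for k, v in timings.items()}
    for stage, dt in timings.items():
        logger.info("stage %-14s %6.2f s", stage, dt)
    return _jsonable(report)


def run_all_synthetic(seed: int = 11, n_subjects: int = 200,
                      n_nodes: int = 60, n_permutations: int = 1000,
                      n_boot: int = 2000, with_retest: bool = True,
                      config: PipelineConfig | None = None) -> dict:
    """Simulate the default desk-scale cohort and run the full pipeline.

    Returns ``(report)`` with the generator's ground truth echoed under
    ``provenance.truth`` so recovery can be checked downstream.
    """
    from .synthetic import CohortConfig, simulate_cohort

    cc = CohortConfig.desk(seed=seed, n_subjects=n_subjects, n_nodes=n_nodes)
    cohort = simulate_cohort(cc)
    retest = simulate_retest(cohort) if with_retest else None
    cfg = config or PipelineConfig(n_permutations=n_permutations,
                                   n_boot=n_boot, seed=seed)
    report = run_all(cohort, retest, cfg)
    report["provenance"]["truth"] = {
        "planted_components": [
            {"edges": [list(e) for e in comp.edges],
             "target_factor": comp.target_factor}
            for comp in cc.planted_components],
        "mediation": asdict(cc.mediation) if cc.mediation else None,
        "retest": asdict(cc.retest),
        "cohort_seed": cc.seed,
    }
    return _jsonable(report)
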