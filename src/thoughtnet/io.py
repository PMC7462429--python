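"""On-disk formats for cohorts and stage outputs.

All formats are plain text:

* ratings: CSV, rows = subjects, columns = item labels, values 1-4;
* covariates / well-being: CSV keyed by ``subject_id``;
* parcellation: CSV with ``node_id, label, network, x, y, z``;
* connectomes: one square TSV per subject (header = node labels) plus a
  manifest CSV (``subject_id, path``);
* NBS output: edge-list TSV, mask matrix TSV, and a JSON summary;
* metrics: tidy TSV (``subject_id, component_id, node_id, metric, value``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, read_connectome, write_connectome
from .synthetic import SyntheticCohort


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    out = Path(outdir)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    cohort.ratings.rename_axis("subject_id").to_csv(out / "ratings.csv")
    cohort.covariates.rename_axis("subject_id").to_csv(out / "covariates.csv")
    cohort.wellbeing.rename_axis("subject_id").to_csv(out / "wellbeing.csv")
    cohort.parcellation.to_csv(out / "parcellation.csv", index=False)
    labels = cohort.parcellation["label"].tolist()
    rows = []
    for c in cohort.connectomes:
        path = out / "connectomes" / f"{c.subject_id}.tsv"
        write_connectome(c, path, labels=labels)
        rows.append({"subject_id": c.subject_id,
                     "path": str(path.relative_to(out))})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def read_tables(indir):
    """Read ratings/covariates/wellbeing/parcellation, aligned on subjects.

    Raises a descriptive error when the tables disagree on the subject set.
    """
    ind = Path(indir)
    ratings = pd.read_csv(ind / "ratings.csv", index_col="subject_id")
    covariates = pd.read_csv(ind / "covariates.csv", index_col="subject_id")
    wellbeing = pd.read_csv(ind / "wellbeing.csv", index_col="subject_id")
    parcellation = pd.read_csv(ind / "parcellation.csv")
    for name, df in (("covariates", covariates), ("wellbeing", wellbeing)):
        extra = set(df.index) ^ set(ratings.index)
        if extra:
            raise ValueError(
                f"subject index mismatch between ratings.csv and {name}.csv: "
                f"{sorted(extra)[:5]} ...")
        df = df.loc[ratings.index]
    return ratings, covariates.loc[ratings.index], \
        wellbeing.loc[ratings.index], parcellation


def read_connectome_dir(indir, subject_ids=None):
    """Load connectomes listed in ``manifest.csv`` in subject order."""
    ind = Path(indir)
    manifest = pd.read_csv(ind / "manifest.csv")
    by_id = {r.subject_id: ind / r.path for r in manifest.itertuples()}
    order = list(subject_ids) if subject_ids is not None else list(by_id)
    missing = [s for s in order if s not in by_id]
    if missing:
        raise ValueError(f"manifest.csv lacks connectomes for subjects: "
                         f"{missing[:5]} ...")
    return [read_connectome(by_id[s], subject_id=s) for s in order]


def read_cohort(indir) -> SyntheticCohort:
    ratings, covariates, wellbeing, parcellation = read_tables(indir)
    connectomes = read_connectome_dir(indir, subject_ids=ratings.index)
    from .synthetic import CohortConfig
    cfg = CohortConfig(n_subjects=len(ratings),
                       n_nodes=len(parcellation),
                       n_items=ratings.shape[1],
                       n_networks=parcellation["network"].nunique(),
                       planted_components=(), mediation=None)
    return SyntheticCohort(parcellation=parcellation, connectomes=connectomes,
                           ratings=ratings, covariates=covariates,
                           wellbeing=wellbeing, truth=cfg)


def write_nbs_result(result, outdir, prefix: str = "nbs") -> None:
    """Edge-list TSV + mask matrix TSV + JSON summary for one contrast."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    iu = result.edge_stats.edge_index()
    n = result.edge_stats.n_nodes
    pos_of = {}
    for e, (i, j) in enumerate(zip(iu[0], iu[1])):
        pos_of[(int(i), int(j))] = e
    rows = []
    for k, comp in enumerate(result.components):
        for (i, j), s in zip(comp.edges, comp.signs):
            rows.append({"node_i": i, "node_j": j,
                         "t": float(result.edge_stats.t[pos_of[(i, j)]]),
                         "sign": s, "component_id": k})
    pd.DataFrame(rows, columns=["node_i", "node_j", "t", "sign",
                                "component_id"]).to_csv(
        out / f"{prefix}_edges.tsv", sep="\t", index=False)
    pd.DataFrame(result.mask).to_csv(out / f"{prefix}_mask.tsv", sep="\t",
                                     index=False, header=False)
    summary = {
        "contrast": result.contrast, "T_threshold": result.T_threshold,
        "n_permutations": result.n_permutations, "scheme": result.scheme,
        "alpha": result.alpha, "seed": result.seed,
        "component_sizes": [c.size for c in result.components],
        "fwe_p": [float(p) for p in result.fwe_p],
        "significant": [bool(s) for s in result.significant],
        "null_max_quantiles": {q: float(np.quantile(result.null_max_sizes, q))
                               for q in (0.5, 0.95, 0.99)},
    }
    (out / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))


def write_metrics_tidy(metrics_list, path) -> None:
    """Tidy TSV of per-node and graph-level ("GRAPH") metric values."""
    rows = []
    for gm in metrics_list:
        cid = gm.component_index if gm.component_index is not None else 0
        for rec in gm.nodes.itertuples():
            for metric in ("pos_strength", "neg_strength", "total_strength",
                           "fractional_strength", "betweenness"):
                rows.append({"subject_id": gm.subject_id, "component_id": cid,
                             "node_id": int(rec.node_id), "metric": metric,
                             "value": getattr(rec, metric)})
        for metric, value in (("pos_sum", gm.pos_sum), ("neg_sum", gm.neg_sum),
                              ("total_sum", gm.total_sum),
                              ("fractional_strength", gm.fractional_strength),
                              ("log_fractional_strength",
                               gm.log_fractional_strength)):
            rows.append({"subject_id": gm.subject_id, "component_id": cid,
                         "node_id": "GRAPH", "metric": metric, "value": value})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, allow_nan=False))
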