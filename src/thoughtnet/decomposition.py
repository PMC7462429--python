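"""Decomposition of experience-sampling ratings into thought patterns.

The items of a retrospective thought questionnaire (Likert 1-4) are first
hierarchically clustered into two groups (Ward linkage on item response
profiles), and each group is then reduced to a small number of
varimax-rotated principal components of the item correlation matrix.
Per-subject component scores (the "thought patterns", six by default) are
computed by the regression method and can be projected onto new sessions
without refitting, which is what the test-retest analysis requires.

No step is stochastic; component sign indeterminacy is resolved by making
the largest-magnitude loading of each rotated component positive, so that
fits, scores and projections are exactly reproducible.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

CLUSTER_NAMES = ("clusterA", "clusterB")


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check a participants x items Likert table (values in {1,2,3,4})."""
    if ratings.isna().any().any():
        raise ValueError("ratings contain missing cells; exclude incomplete "
                         "subjects upstream")
    vals = ratings.to_numpy()
    if not np.isin(vals, [1, 2, 3, 4]).all():
        raise ValueError("ratings must be Likert values in {1, 2, 3, 4}")
    return ratings


@dataclass
class ItemLinkage:
    """Ward agglomeration of items with the 2-cluster cut.

    ``merge_history`` is the scipy linkage matrix (heights on the
    Euclidean scale; the Ward objective, and therefore the partition, is
    the squared-Euclidean one).  ``cluster_of_item`` maps item label to
    cluster 0/1; cluster 0 is the cluster containing the first item, so
    the labelling is deterministic.
    """

    merge_history: np.ndarray
    cluster_of_item: pd.Series

    @property
    def heights(self) -> np.ndarray:
        return self.merge_history[:, 2]

    def items_in(self, cluster: int) -> list:
        return list(self.cluster_of_item.index[self.cluster_of_item == cluster])


def cluster_items(ratings: pd.DataFrame) -> ItemLinkage:
    """Ward-link items on their response profiles and cut into two clusters.

    Items are the observations and subjects the features, so two items
    with identical response profiles merge first at height zero.
    Constant (zero-variance) items are allowed here but flagged, since
    they will break the standardization step of the PCA later.
    """
    validate_ratings(ratings)
    if ratings.shape[1] < 4:
        raise ValueError(f"need >= 4 items to cluster, got {ratings.shape[1]}")
    if ratings.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    X = ratings.to_numpy(dtype=float).T  # items x subjects
    constant = ratings.columns[ratings.std(axis=0) == 0]
    if len(constant):
        logger.warning("constant items (zero variance): %s", list(constant))
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    # relabel so that the first item's cluster is 0
    labels = (labels != labels[0]).astype(int)
    if labels.min() == labels.max():
        raise ValueError("2-cluster cut produced a single cluster")
    return ItemLinkage(merge_history=Z,
                       cluster_of_item=pd.Series(labels, index=ratings.columns))


def select_n_components(eigenvalues, rule: str = "fixed:3") -> int:
    """Number of components to retain under an eigenvalue rule.

    ``rule`` is either ``"eigenvalue_gt_1"`` (Kaiser criterion, strict
    inequality) or ``"fixed:k"``.  Eigenvalues must be sorted descending,
    as produced by a correlation-matrix PCA.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    if rule == "eigenvalue_gt_1":
        return int((ev > 1.0).sum())
    m = re.fullmatch(r"fixed:(\d+)", rule)
    if not m:
        raise ValueError(f"unknown rule {rule!r}")
    k = int(m.group(1))
    if k > ev.size:
        raise ValueError(f"fixed:{k} exceeds the number of items ({ev.size})")
    return k


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal; SVD algorithm).

    With ``kaiser_normalize`` the rows are scaled to unit communality
    before rotation and rescaled after, the convention of the classic
    implementation.  Communalities (row sums of squares) are preserved
    exactly up to floating point because the rotation is orthogonal.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy()
    h = np.sqrt((L ** 2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    Ln = L / h[:, None] if kaiser_normalize else L.copy()
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = Ln @ R
        u, s, vt = np.linalg.svd(
            Ln.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    out = (Ln @ R)
    if kaiser_normalize:
        out = out * h[:, None]
    return out


def _fix_sign_and_order(L: np.ndarray) -> np.ndarray:
    """Deterministic component convention: order by explained SS, sign by
    the largest-magnitude loading."""
    order = np.argsort(-(L ** 2).sum(axis=0), kind="stable")
    L = L[:, order]
    for c in range(L.shape[1]):
        j = np.argmax(np.abs(L[:, c]))
        if L[j, c] < 0:
            L[:, c] = -L[:, c]
    return L


@dataclass
class ClusterFit:
    """PCA/varimax fit of one item cluster."""

    items: list
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray          # all item eigenvalues, descending
    loadings_unrotated: np.ndarray   # items x k
    loadings: np.ndarray             # varimax-rotated, sign/order fixed
    weights: np.ndarray              # items x k score weights (regression method)
    variance_explained: float        # proportion, retained set


@dataclass
class ComponentModel:
    """Two per-cluster fits plus bookkeeping for scoring new sessions."""

    clusters: dict = field(default_factory=dict)  # cluster id -> ClusterFit
    component_names: list = field(default_factory=list)

    @property
    def variance_explained(self) -> dict:
        return {CLUSTER_NAMES[c]: f.variance_explained
                for c, f in self.clusters.items()}


def _fit_cluster(X: pd.DataFrame, n_components: int) -> ClusterFit:
    items = list(X.columns)
    vals = X.to_numpy(dtype=float)
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    dead = [items[i] for i in np.flatnonzero(sds == 0)]
    if dead:
        raise ValueError(f"zero-variance items cannot be standardized: {dead}")
    Z = (vals - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    ev, V = np.linalg.eigh(R)
    ev, V = ev[::-1], V[:, ::-1]
    if ev[-1] < 1e-10:
        # identify (near-)collinear item pairs for the error message
        pairs = [(items[i], items[j])
                 for i in range(len(items)) for j in range(i + 1, len(items))
                 if abs(R[i, j]) > 1 - 1e-8]
        raise ValueError(f"singular item correlation matrix; collinear items: {pairs}")
    if n_components > len(items):
        raise ValueError("more components requested than items in cluster")
    L0 = V[:, :n_components] * np.sqrt(ev[:n_components])
    L = _fix_sign_and_order(varimax(L0))
    W = np.linalg.solve(R, L)
    return ClusterFit(items=items, means=means, sds=sds, eigenvalues=ev,
                      loadings_unrotated=L0, loadings=L, weights=W,
                      variance_explained=float(ev[:n_components].sum() / len(items)))


def fit_pca_varimax(ratings: pd.DataFrame, item_linkage: ItemLinkage,
                    n_components=3) -> ComponentModel:
    """Per-cluster correlation-matrix PCA with varimax rotation.

    Items are standardized within cluster; the top ``n_components``
    eigenvectors (scaled to loadings) are varimax-rotated with Kaiser
    normalization; score weights use the regression method
    ``W = R^{-1} L``.  ``n_components`` may be a single integer or a pair
    (one per cluster), as produced by an eigenvalue rule applied to each
    cluster separately.
    """
    validate_ratings(ratings)
    per_cluster = ((n_components, n_components)
                   if np.isscalar(n_components) else tuple(n_components))
    model = ComponentModel()
    for c in (0, 1):
        items = item_linkage.items_in(c)
        k_c = int(per_cluster[c])
        if len(items) < k_c:
            raise ValueError(
                f"cluster {CLUSTER_NAMES[c]} has {len(items)} items, "
                f"fewer than n_components={k_c}")
        model.clusters[c] = _fit_cluster(ratings[items], k_c)
        model.component_names += [f"{CLUSTER_NAMES[c]}_pc{k + 1}"
                                  for k in range(k_c)]
    return model


def score_components(model: ComponentModel,
                     ratings: pd.DataFrame) -> pd.DataFrame:
    """Thought-pattern scores for each participant.

    Standardizes with the *model's* stored item means/sds and applies the
    stored regression weights; in-sample this yields zero-mean scores.
    Accepts any real-valued table over the fitted items (Likert validation
    happens at fit time), so hypothetical profiles such as a subject at
    the item means can be scored.
    """
    if ratings.isna().any().any():
        raise ValueError("ratings contain missing cells")
    blocks = []
    for c in (0, 1):
        fit = model.clusters[c]
        missing = [it for it in fit.items if it not in ratings.columns]
        if missing:
            raise ValueError(f"ratings lack fitted items: {missing}")
        Z = (ratings[fit.items].to_numpy(dtype=float) - fit.means) / fit.sds
        S = Z @ fit.weights
        blocks.append(pd.DataFrame(
            S, index=ratings.index,
            columns=[f"{CLUSTER_NAMES[c]}_pc{k + 1}" for k in range(S.shape[1])]))
    return pd.concat(blocks, axis=1)


def project_session(model: ComponentModel,
                    new_ratings: pd.DataFrame) -> pd.DataFrame:
    """Score a new session through a previously fitted model.

    Identical computation to :func:`score_components` — the point of a
    separate entry is the contract: session-1 standardization parameters
    and weights are imposed on the new ratings, never refit, so that
    session-to-session score changes reflect the subjects and not a new
    rotation.
    """
    return score_components(model, new_ratings)
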