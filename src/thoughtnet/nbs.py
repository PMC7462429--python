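"""Network-based statistic (NBS) with permutation FWE control.

Mass-univariate GLMs relate every connectome edge to a covariate of
interest (a thought-pattern score) while adjusting for nuisance terms
(intercept, mean connectivity, age, gender, motion).  Edges whose
t-statistic exceeds a primary threshold T are assembled into connected
components; the family-wise error of each observed component is assessed
against a permutation null distribution of the *maximal* component size
(edge count), obtained by re-randomizing the interest block of the design
across subjects.

Two permutation schemes are available: joint row shuffling of the interest
block (default; preserves the correlation among the six scores and the
pairing of nuisance variables with connectomes) and Freedman-Lane residual
permutation.  For tiny samples the full permutation group can be
enumerated, in which case the reported p-value is the exact one.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

logger = logging.getLogger(__name__)

T_CAP = 1e6  # cap for degenerate (zero-residual) edge fits


@dataclass
class DesignMatrix:
    """Subjects x regressors design with named interest and nuisance blocks."""

    data: pd.DataFrame
    interest: tuple
    nuisance: tuple

    def __post_init__(self):
        self.interest = tuple(self.interest)
        self.nuisance = tuple(self.nuisance)
        cols = set(self.data.columns)
        missing = [c for c in self.interest + self.nuisance if c not in cols]
        if missing:
            raise ValueError(f"design lacks columns: {missing}")
        X = self.values
        if np.linalg.matrix_rank(X) < X.shape[1]:
            _, r = np.linalg.qr(X)
            dep = [self.columns[i] for i in
                   np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(r).max())]
            raise ValueError(f"design is rank deficient; dependent columns: {dep}")

    @property
    def columns(self) -> list:
        return list(self.interest) + list(self.nuisance)

    @property
    def values(self) -> np.ndarray:
        return self.data[self.columns].to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return len(self.data)


def make_design(scores: pd.DataFrame, covariates: pd.DataFrame,
                mean_conn) -> DesignMatrix:
    """Assemble the standard NBS design.

    Interest block: the thought-pattern scores.  Nuisance block:
    intercept, per-subject mean connectivity, and the covariate columns.
    Rows are aligned on the scores index, which must match the order of
    the connectome stack.
    """
    if not scores.index.equals(covariates.index):
        raise ValueError("scores and covariates subject indices differ")
    df = scores.copy()
    df["intercept"] = 1.0
    df["mean_connectivity"] = np.asarray(mean_conn, dtype=float)
    for c in covariates.columns:
        df[c] = covariates[c].to_numpy(dtype=float)
    return DesignMatrix(data=df, interest=tuple(scores.columns),
                        nuisance=("intercept", "mean_connectivity",
                                  *covariates.columns))


@dataclass
class EdgeStats:
    """Per-edge t-statistics over the strict upper triangle."""

    t: np.ndarray
    df: int
    contrast: str
    n_nodes: int

    def edge_index(self):
        return np.triu_indices(self.n_nodes, k=1)


@dataclass
class SuprathresholdComponent:
    """One connected component of suprathreshold edges."""

    edges: tuple          # ((i, j), ...) with i < j
    nodes: tuple
    signs: tuple          # sign of t per edge
    size: int             # EDGE count ("extent")


@dataclass
class NBSResult:
    contrast: str
    T_threshold: float
    sidedness: str
    components: list
    fwe_p: np.ndarray
    null_max_sizes: np.ndarray
    n_permutations: int
    seed: int | None
    alpha: float
    scheme: str
    significant: np.ndarray = field(default=None)
    mask: np.ndarray = field(default=None)   # N x N in {-1, 0, +1}
    edge_stats: EdgeStats = field(default=None)

    def significant_components(self) -> list:
        return [c for c, s in zip(self.components, self.significant) if s]


# ---------------------------------------------------------------------------
# Edgewise GLM
# ---------------------------------------------------------------------------

def _edge_matrix(stack) -> tuple:
    """(n_subjects x n_edges) upper-triangle matrix from a connectome stack."""
    if isinstance(stack, np.ndarray):
        arr = stack
    else:
        from .connectome import as_stack
        arr = as_stack(stack)
    n, N, _ = arr.shape
    iu = np.triu_indices(N, k=1)
    return arr[:, iu[0], iu[1]], N


def _tstats(X: np.ndarray, Y: np.ndarray, ci: int, xtxi=None) -> np.ndarray:
    """OLS t-statistics of column ``ci`` of X for every column of Y."""
    n, p = X.shape
    if xtxi is None:
        xtxi = np.linalg.inv(X.T @ X)
    beta = xtxi @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid * resid).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtxi[ci, ci], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[ci] / np.where(se > 0, se, 1.0),
                     np.sign(beta[ci]) * T_CAP)
    return np.clip(t, -T_CAP, T_CAP)


def edgewise_glm(stack, design: DesignMatrix, contrast: str) -> EdgeStats:
    """Ordinary least squares of every edge weight on the full design.

    Returns the t-statistic of the ``contrast`` column at each
    upper-triangle edge.  Degenerate zero-residual edges are reported with
    a capped finite t (|t| = 1e6) and a log note.
    """
    Y, N = _edge_matrix(stack)
    X = design.values
    if contrast not in design.columns:
        raise ValueError(f"unknown contrast {contrast!r}")
    if Y.shape[0] != X.shape[0]:
        raise ValueError("connectome stack and design have different n_subjects")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least rank(design)+2 subjects")
    t = _tstats(X, Y, design.columns.index(contrast))
    n_capped = int((np.abs(t) >= T_CAP).sum())
    if n_capped:
        logger.warning("%d edges had zero-residual fits; t capped at %g",
                       n_capped, T_CAP)
    return EdgeStats(t=t, df=X.shape[0] - X.shape[1], contrast=contrast,
                     n_nodes=N)


# ---------------------------------------------------------------------------
# Component extraction
# ---------------------------------------------------------------------------

def _select_edges(t: np.ndarray, T: float, sidedness: str) -> np.ndarray:
    if T <= 0:
        raise ValueError("T threshold must be positive")
    if sidedness == "two_sided":
        return np.abs(t) >= T
    if sidedness == "positive":
        return t >= T
    if sidedness == "negative":
        return t <= -T
    raise ValueError(f"unknown sidedness {sidedness!r}")


def _component_labels(sel: np.ndarray, iu, N: int):
    """Connected-component label per selected edge (scipy csgraph)."""
    i, j = iu[0][sel], iu[1][sel]
    g = coo_matrix((np.ones(i.size), (i, j)), shape=(N, N))
    _, node_labels = _cc(g, directed=False)
    return node_labels[i], i, j


def _max_component_size(t, T, sidedness, iu, N) -> int:
    sel = _select_edges(t, T, sidedness)
    if not sel.any():
        return 0
    lab, _, _ = _component_labels(sel, iu, N)
    return int(np.bincount(lab).max())


def suprathreshold_components(stats: EdgeStats, T: float,
                              sidedness: str = "two_sided") -> list:
    """Connected components of edges with |t| >= T, sorted by size desc."""
    iu = stats.edge_index()
    sel = _select_edges(stats.t, T, sidedness)
    if not sel.any():
        return []
    lab, i, j = _component_labels(sel, iu, stats.n_nodes)
    signs = np.sign(stats.t[sel]).astype(int)
    comps = []
    for label in np.unique(lab):
        m = lab == label
        edges = tuple(sorted(zip(i[m].tolist(), j[m].tolist())))
        comps.append(SuprathresholdComponent(
            edges=edges,
            nodes=tuple(sorted(set(i[m].tolist()) | set(j[m].tolist()))),
            signs=tuple(int(s) for s, (a, b) in
                        sorted(zip(signs[m], zip(i[m], j[m])),
                               key=lambda z: z[1])),
            size=int(m.sum())))
    comps.sort(key=lambda c: (-c.size, c.edges))
    return comps


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def nbs_test(stack, design: DesignMatrix, contrast: str, T: float = 3.2,
             n_perm: int = 5000, seed: int | None = 0,
             scheme: str = "permute_interest", sidedness: str = "two_sided",
             alpha: float = 0.05, exhaustive: bool = False,
             smoothing: bool = True) -> NBSResult:
    """NBS inference for one contrast.

    The observed suprathreshold components are compared against a null
    distribution of the maximal component size obtained by ``n_perm``
    random permutations (or the full permutation group when
    ``exhaustive``).  The FWE-corrected p-value of a component of size s
    is ``(#{null_max >= s} + 1) / (n_perm + 1)`` by default; with
    ``smoothing=False`` the unsmoothed ``#{null_max >= s} / n_perm`` is
    reported, and exhaustive enumeration always reports the exact
    ``#{null_max >= s} / n_total`` (the identity permutation is included
    in the enumeration, so the exact p is already never zero).
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("permute_interest", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    Y, N = _edge_matrix(stack)
    X = design.values
    n = X.shape[0]
    ci = design.columns.index(contrast)
    iu = np.triu_indices(N, k=1)

    obs_stats = edgewise_glm(stack, design, contrast)
    components = suprathreshold_components(obs_stats, T, sidedness)

    interest_idx = [design.columns.index(c) for c in design.interest]
    nuis_idx = [design.columns.index(c) for c in design.nuisance]

    if scheme == "freedman_lane":
        Z = X[:, nuis_idx]
        Hz = Z @ np.linalg.pinv(Z)
        Yhat_z = Hz @ Y
        Rz = Y - Yhat_z

    if exhaustive:
        if math.factorial(n) > 500_000:
            raise ValueError("exhaustive enumeration only supported for small n")
        perms = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    null_max = np.empty(len(perms), dtype=int)
    xtxi_obs = None
    for k, perm in enumerate(perms):
        perm = np.asarray(perm)
        if scheme == "permute_interest":
            Xp = X.copy()
            Xp[:, interest_idx] = X[perm][:, interest_idx]
            t = _tstats(Xp, Y, ci)
        else:  # freedman_lane: permute reduced-model residuals of the outcome
            if xtxi_obs is None:
                xtxi_obs = np.linalg.inv(X.T @ X)
            Ystar = Yhat_z + Rz[perm]
            t = _tstats(X, Ystar, ci, xtxi=xtxi_obs)
        null_max[k] = _max_component_size(t, T, sidedness, iu, N)

    sizes = np.array([c.size for c in components], dtype=int)
    counts = np.array([(null_max >= s).sum() for s in sizes], dtype=float)
    if exhaustive:
        fwe_p = counts / len(perms)
    elif smoothing:
        fwe_p = (counts + 1.0) / (len(perms) + 1.0)
    else:
        fwe_p = counts / len(perms)
    significant = fwe_p < alpha if sizes.size else np.zeros(0, dtype=bool)

    mask = np.zeros((N, N), dtype=np.int8)
    for comp, sig in zip(components, significant):
        if sig:
            for (i, j), s in zip(comp.edges, comp.signs):
                mask[i, j] = mask[j, i] = s

    return NBSResult(contrast=contrast, T_threshold=T, sidedness=sidedness,
                     components=components, fwe_p=fwe_p, null_max_sizes=null_max,
                     n_permutations=len(perms),
                     seed=None if exhaustive else seed, alpha=alpha,
                     scheme="exhaustive" if exhaustive else scheme,
                     significant=significant, mask=mask, edge_stats=obs_stats)


def mask_connectome(connectome, result: NBSResult, component_index: int):
    """Keep a subject's weights on one component's edges, zero elsewhere."""
    from .connectome import Connectome
    if not 0 <= component_index < len(result.components):
        raise IndexError(
            f"component {component_index} out of range "
            f"({len(result.components)} components)")
    comp = result.components[component_index]
    w = connectome.weights if isinstance(connectome, Connectome) \
        else np.asarray(connectome, dtype=float)
    out = np.zeros_like(w)
    for i, j in comp.edges:
        out[i, j] = out[j, i] = w[i, j]
    return Connectome(out,
                      subject_id=getattr(connectome, "subject_id", ""),
                      component_nodes=np.array(comp.nodes))
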