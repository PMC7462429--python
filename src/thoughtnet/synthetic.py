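"""Synthetic resting-state cohort generator with planted ground truth.

Emulates the data model of a study in which ~200 participants undergo a
resting-state scan followed by retrospective experience sampling: each
subject contributes a signed fully connected correlation connectome on a
fixed parcellation, Likert (1-4) ratings of ongoing thought with a
two-cluster / six-factor latent structure, demographic and motion
covariates, and psychological/social well-being domain scores.  A subset
returns for a second session, with separable trait-like and state-like
reliability of the thought factors.

Everything the downstream pipeline is supposed to discover is planted and
echoed back as ground truth:

* item ratings are generated from six latent factors (three per item
  cluster, factors within a cluster correlated) through simple-structure
  loadings, then discretized at fixed quartile cutpoints;
* each planted edge component shifts a connected set of connectome edges
  in proportion to its target factor score;
* well-being is generated from a mediation model
  brain (log fractional strength of the planted component) -> thought
  factor -> well-being, with covariate effects;
* the retest arm reproduces configured intraclass correlations for the
  trait-like and state-like factors and a configured change-change
  coupling for the state-like component.

The generator is fully deterministic given the config seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .connectome import Connectome

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Study conditions (fixed generator constants; see docs/methods.md)
# ---------------------------------------------------------------------------

#: primary loading of each rating item on its target factor
ITEM_LOADING = 0.95
#: correlation between latent factors belonging to the same item cluster
FACTOR_COR_WITHIN_CLUSTER = 0.25
#: sd of the subject-level offset added to every edge ("mean connectivity" variation)
SUBJECT_OFFSET_SD = 0.05
#: per-edge noise sd as a multiple of CohortConfig.noise_sd
EDGE_NOISE_SCALE = 0.3
#: magnitude of the base weight put on planted edges
BASE_EDGE_MAG = 0.25
#: reference noise_sd at which the item residual sd equals sqrt(1 - ITEM_LOADING**2)
REFERENCE_NOISE_SD = 0.2

#: canonical large-scale network names used for synthetic parcellation labels
NETWORK_NAMES = (
    "DMN", "FPN", "DAN", "VAN", "SAN", "CON", "VIS", "AUD",
    "SMN-hand", "SMN-mouth", "SCN", "MEM", "CBN",
)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedComponent:
    """A connected set of edges whose weights track a latent thought factor.

    ``base_weights`` are the population-mean weights written onto the
    planted edges (positive entries feed the positive strength of the
    component, negative entries its negative strength); ``sign_pattern``
    gives the direction of the per-edge association with the target
    factor.  The per-unit-score shift of edge ``e`` is
    ``effect_per_edge * sign_pattern[e]`` in correlation units.
    """

    edges: tuple
    effect_per_edge: float
    target_factor: int
    sign_pattern: tuple | None = None
    base_weights: tuple | None = None

    def __post_init__(self):
        edges = tuple((int(i), int(j)) for i, j in self.edges)
        if any(i >= j for i, j in edges):
            raise ValueError("planted edges must be (i, j) pairs with i < j")
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate planted edges")
        if self.effect_per_edge < 0:
            raise ValueError("effect_per_edge must be >= 0")
        g = nx.Graph(edges)
        if len(edges) and not nx.is_connected(g):
            raise ValueError("planted edge set must form a connected graph")
        object.__setattr__(self, "edges", edges)
        sign = self.sign_pattern
        if sign is None:
            sign = tuple(1 for _ in edges)
        sign = tuple(int(s) for s in sign)
        if len(sign) != len(edges) or any(s not in (-1, 1) for s in sign):
            raise ValueError("sign_pattern must be +-1, one per edge")
        object.__setattr__(self, "sign_pattern", sign)
        base = self.base_weights
        if base is None:
            # 60/40 split: first 60% of edges positive, rest negative
            n_pos = int(round(0.6 * len(edges)))
            base = tuple(BASE_EDGE_MAG if k < n_pos else -BASE_EDGE_MAG
                         for k in range(len(edges)))
        base = tuple(float(b) for b in base)
        if len(base) != len(edges):
            raise ValueError("base_weights must have one entry per edge")
        object.__setattr__(self, "base_weights", base)

    @property
    def node_set(self) -> tuple:
        return tuple(sorted({n for e in self.edges for n in e}))


@dataclass(frozen=True)
class MediationTruth:
    """Ground-truth path coefficients of the brain -> thought -> well-being model.

    ``a_path`` is the standardized association between the log fractional
    strength of the mediated component and its target thought factor; the
    generator calibrates the planted edge coupling so that this value is
    realized (see :func:`calibrate_edge_coupling`).  ``target_component``
    indexes into ``CohortConfig.planted_components``; ``domain`` names the
    well-being column that carries the mediated effect.
    """

    a_path: float = 0.5
    b_path: float = 0.4
    c_prime: float = 0.2
    covariate_effects: tuple = (("age", -0.1), ("gender", 0.1),
                                ("motion_fraction", -0.2))
    target_component: int = 0
    domain: str = "psychological"

    def __post_init__(self):
        for v in (self.a_path, self.b_path, self.c_prime):
            if not np.isfinite(v):
                raise ValueError("mediation paths must be finite")
        if not -1 < self.a_path < 1:
            raise ValueError("a_path is a standardized correlation; need |a_path| < 1")

    @property
    def indirect(self) -> float:
        return self.a_path * self.b_path


@dataclass(frozen=True)
class RetestTruth:
    """Session-2 structure: trait vs state reliability and change coupling."""

    n_retest: int = 40
    trait_icc: float = 0.7
    state_icc: float = 0.15
    change_coupling: float = 0.4
    trait_factor: int = 3
    state_factor: int = 0
    other_icc: float = 0.4

    def __post_init__(self):
        if self.n_retest < 1:
            raise ValueError("n_retest must be positive")
        for name in ("trait_icc", "state_icc", "other_icc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.change_coupling <= 1.0:
            raise ValueError("change_coupling must be in [-1, 1]")


def default_planted_components(n_nodes: int) -> tuple:
    """Two 10-edge components on disjoint node sets.

    Component 0 ("state-like") targets factor 0 and carries the mediation;
    its coupling is calibrated from the mediation a-path at simulation
    time.  Component 1 ("trait-like") targets factor 3 with a fixed
    per-edge effect.
    """
    template = ((0, 1), (0, 2), (1, 2), (1, 3), (2, 4),
                (3, 4), (3, 5), (4, 6), (5, 7), (6, 7))
    if n_nodes < 28:
        raise ValueError("default planted components need n_nodes >= 28")
    state = PlantedComponent(edges=template, effect_per_edge=0.031, target_factor=0)
    trait = PlantedComponent(edges=tuple((i + 20, j + 20) for i, j in template),
                             effect_per_edge=0.035, target_factor=3)
    return (state, trait)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    Defaults mirror the emulated study: 211 subjects, a 264-node
    parcellation in 13 networks, 25 Likert items with a two-cluster /
    six-factor structure, a 40-subject retest arm.  ``desk()`` returns the
    reduced configuration used throughout the test suite (200 subjects,
    60 nodes).
    """

    n_subjects: int = 211
    n_nodes: int = 264
    n_items: int = 25
    n_networks: int = 13
    planted_components: tuple | None = None
    mediation: MediationTruth | None = field(default_factory=MediationTruth)
    retest: RetestTruth = field(default_factory=RetestTruth)
    noise_sd: float = REFERENCE_NOISE_SD
    seed: int = 0
    #: direct (non-mediated) effect of the trait component on social well-being
    social_direct_component: int | None = 1
    social_direct_coef: float = 0.3

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.n_items < 6:
            raise ValueError("need at least 6 items for a 2x3 factor structure")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        comps = self.planted_components
        if comps is None:
            comps = default_planted_components(self.n_nodes)
        comps = tuple(comps)
        for comp in comps:
            if comp.node_set and max(comp.node_set) >= self.n_nodes:
                raise ValueError("planted component nodes outside [0, n_nodes)")
            if not 0 <= comp.target_factor < 6:
                raise ValueError("target_factor must index one of the 6 factors")
        object.__setattr__(self, "planted_components", comps)
        if self.mediation is not None:
            if not 0 <= self.mediation.target_component < len(comps):
                raise ValueError("mediation.target_component out of range")
        if self.retest.n_retest > self.n_subjects:
            raise ValueError("retest arm larger than the cohort")

    @classmethod
    def desk(cls, seed: int = 11, **overrides) -> "CohortConfig":
        """Desk-scale default: 200 subjects, 60 nodes, everything else as-is."""
        kw = dict(n_subjects=200, n_nodes=60, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @property
    def edge_noise_sd(self) -> float:
        return EDGE_NOISE_SCALE * self.noise_sd

    @property
    def item_noise_sd(self) -> float:
        base = math.sqrt(1.0 - ITEM_LOADING ** 2)
        return base * (self.noise_sd / REFERENCE_NOISE_SD)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it.

    All tables share the subject index.  ``latents`` holds generator
    internals (factor scores, base matrix, calibrated couplings, ...)
    needed by :func:`simulate_retest` and by recovery tests; it is not
    part of the public data contract.
    """

    parcellation: pd.DataFrame
    connectomes: list
    ratings: pd.DataFrame
    covariates: pd.DataFrame
    wellbeing: pd.DataFrame
    truth: CohortConfig
    session: int = 1
    latents: dict = field(default_factory=dict, repr=False)

    @property
    def subject_ids(self) -> list:
        return list(self.ratings.index)

    def connectome_stack(self) -> np.ndarray:
        return np.stack([c.weights for c in self.connectomes], axis=0)


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def make_parcellation(n_nodes: int, n_networks: int, seed: int) -> pd.DataFrame:
    """Synthetic parcellation: node ids, labels, network assignment, coordinates.

    Every network is guaranteed non-empty; coordinates are points on a
    70 mm sphere (used only for reports). Deterministic given the seed.
    """
    if n_networks < 1 or n_nodes < 1:
        raise ValueError("n_nodes and n_networks must be positive")
    if n_networks > n_nodes:
        raise ValueError(
            f"n_networks ({n_networks}) cannot exceed n_nodes ({n_nodes})")
    rng = np.random.default_rng(seed)
    names = [NETWORK_NAMES[k] if k < len(NETWORK_NAMES) else f"NET{k:02d}"
             for k in range(n_networks)]
    # first one node per network, remainder assigned uniformly
    assignment = np.concatenate([
        np.arange(n_networks),
        rng.integers(0, n_networks, size=n_nodes - n_networks),
    ])
    rng.shuffle(assignment)
    # ensure the shuffle kept all networks non-empty (it must, but be safe)
    missing = set(range(n_networks)) - set(assignment.tolist())
    for k, net in enumerate(sorted(missing)):
        assignment[k] = net
    xyz = rng.normal(size=(n_nodes, 3))
    xyz *= 70.0 / np.linalg.norm(xyz, axis=1, keepdims=True)
    return pd.DataFrame({
        "node_id": np.arange(n_nodes),
        "label": [f"ROI_{i:04d}" for i in range(n_nodes)],
        "network": [names[a] for a in assignment],
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })


# ---------------------------------------------------------------------------
# Calibration helpers
# ---------------------------------------------------------------------------

def _log_fs_sensitivities(comp: PlantedComponent):
    """Linearized sensitivities of log fractional strength over the component.

    Returns ``(g, q, P0, N0)`` where ``g`` is d(log FS)/d(factor) per unit
    per-edge coupling (also the sensitivity to the common subject offset)
    and ``q`` scales the per-edge noise variance into log-FS variance.
    """
    base = np.asarray(comp.base_weights)
    sign = np.asarray(comp.sign_pattern)
    pos = base > 0
    P0 = base[pos].sum()
    N0 = -base[~pos].sum()
    if P0 <= 0 or N0 <= 0:
        raise ValueError("planted component needs positive and negative base weight")
    g = sign[pos].sum() / P0 + sign[~pos].sum() / N0
    q = pos.sum() / P0 ** 2 + (~pos).sum() / N0 ** 2
    return g, q, P0, N0


def calibrate_edge_coupling(comp: PlantedComponent, a_path: float,
                            noise_sd: float) -> float:
    """Per-edge coupling realizing corr(log FS, factor) = ``a_path``.

    Derived from a first-order expansion of log(P/N) around the planted
    base weights: the factor moves log FS through ``g * beta``, the
    subject offset contributes variance ``(g * SUBJECT_OFFSET_SD)**2`` and
    the edge noise ``q * sigma_e**2``; solving
    ``a = g b / sqrt(g^2 b^2 + V0)`` for ``b`` gives the coupling.
    """
    if a_path == 0:
        return 0.0
    g, q, _, _ = _log_fs_sensitivities(comp)
    sigma_e = EDGE_NOISE_SCALE * noise_sd
    v0 = (g * SUBJECT_OFFSET_SD) ** 2 + q * sigma_e ** 2
    return abs(a_path) / (abs(g) * math.sqrt(1 - a_path ** 2)) * math.sqrt(v0)


def planted_edge_score_correlation(beta: float, noise_sd: float) -> float:
    """Expected marginal corr(edge weight, target factor) for a planted edge.

    Closed form from the generative variances: the edge is
    ``base + beta*f + delta + eps`` with ``Var(f)=1``,
    ``sd(delta)=SUBJECT_OFFSET_SD`` and ``sd(eps)=EDGE_NOISE_SCALE*noise_sd``.
    """
    var = beta ** 2 + SUBJECT_OFFSET_SD ** 2 + (EDGE_NOISE_SCALE * noise_sd) ** 2
    return beta / math.sqrt(var) if var > 0 else 0.0


def component_log_fractional_strength(stack: np.ndarray,
                                      comp: PlantedComponent) -> np.ndarray:
    """log(sum positive / sum |negative|) over the planted edges, per subject.

    Returns NaN for subjects with no negative (or no positive) weight on
    the component; these are excluded from downstream regressions.
    """
    i = np.array([e[0] for e in comp.edges])
    j = np.array([e[1] for e in comp.edges])
    w = stack[:, i, j]
    pos = np.clip(w, 0, None).sum(axis=1)
    neg = np.clip(-w, 0, None).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((pos > 0) & (neg > 0), np.log(pos) - np.log(neg), np.nan)
    n_bad = int(np.isnan(out).sum())
    if n_bad:
        logger.warning("log fractional strength undefined for %d subjects", n_bad)
    return out


# ---------------------------------------------------------------------------
# Generation internals
# ---------------------------------------------------------------------------

def _factor_correlation() -> np.ndarray:
    """6x6 factor correlation: blocks of 3 with within-block correlation."""
    sigma = np.eye(6)
    for block in (range(0, 3), range(3, 6)):
        for a, b in itertools.combinations(block, 2):
            sigma[a, b] = sigma[b, a] = FACTOR_COR_WITHIN_CLUSTER
    return sigma


def _item_assignment(n_items: int):
    """Split items into two clusters and assign each to one of 3 factors.

    Cluster A takes the first ceil(n/2) items; within a cluster items are
    dealt round-robin across its three factors.
    """
    n_a = (n_items + 1) // 2
    cluster = np.array([0] * n_a + [1] * (n_items - n_a))
    factor = np.empty(n_items, dtype=int)
    factor[:n_a] = np.arange(n_a) % 3
    factor[n_a:] = 3 + np.arange(n_items - n_a) % 3
    return cluster, factor


def _discretize_ratings(latent: np.ndarray, marginal_sd: float) -> np.ndarray:
    """Threshold latent item values at fixed quartile cutpoints -> 1..4.

    Cutpoints are the standard-normal quartiles scaled to the marginal sd
    of the latent items, giving roughly balanced response categories
    (item-specific endorsement rates are not emulated).
    """
    cuts = marginal_sd * np.array([-0.6744897501960817, 0.0, 0.6744897501960817])
    return (np.searchsorted(cuts, latent.ravel(), side="right")
            .reshape(latent.shape) + 1)


def _planted_couplings(config: CohortConfig) -> np.ndarray:
    """Per-component per-edge coupling, with mediation calibration applied."""
    betas = np.array([c.effect_per_edge for c in config.planted_components])
    med = config.mediation
    if med is not None:
        betas[med.target_component] = calibrate_edge_coupling(
            config.planted_components[med.target_component], med.a_path,
            config.noise_sd)
    return betas


def _build_stack(config: CohortConfig, base: np.ndarray, delta: np.ndarray,
                 drivers: np.ndarray, betas: np.ndarray,
                 rng: np.random.Generator):
    """Assemble per-subject connectome matrices.

    ``drivers`` is ``(n_subjects, n_components)``: the latent value that
    moves each planted component's edges for each subject (usually the
    target factor score).  Returns the ``(n, N, N)`` stack and the
    fraction of planted edge values clipped at +-1.
    """
    n, N = delta.shape[0], config.n_nodes
    iu0, iu1 = np.triu_indices(N, k=1)
    edge_vals = base[iu0, iu1][None, :] + delta[:, None]
    edge_vals = edge_vals + rng.normal(0.0, config.edge_noise_sd,
                                       size=(n, iu0.size))
    # map (i, j) -> position in the upper-triangle vector
    pos_of = -np.ones((N, N), dtype=np.int64)
    pos_of[iu0, iu1] = np.arange(iu0.size)
    n_planted = n_clipped = 0
    for k, comp in enumerate(config.planted_components):
        if not comp.edges:
            continue
        idx = pos_of[[e[0] for e in comp.edges], [e[1] for e in comp.edges]]
        shift = np.outer(drivers[:, k] * betas[k], np.asarray(comp.sign_pattern))
        edge_vals[:, idx] += shift
        n_planted += idx.size * n
        n_clipped += int((np.abs(edge_vals[:, idx]) > 1.0).sum())
    if n_planted and n_clipped / n_planted > 0.05:
        logger.warning("clipping saturates %.1f%% of planted edge values",
                       100.0 * n_clipped / n_planted)
    np.clip(edge_vals, -1.0, 1.0, out=edge_vals)
    stack = np.zeros((n, N, N))
    stack[:, iu0, iu1] = edge_vals
    stack += stack.transpose(0, 2, 1)
    if not np.isfinite(stack).all():
        raise RuntimeError("non-finite connectome values generated")
    return stack


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


# ---------------------------------------------------------------------------
# Public generation API
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a session-1 cohort with the configured planted structure."""
    n = config.n_subjects
    root = np.random.SeedSequence([int(config.seed) % (2 ** 31), 1])
    streams = [np.random.default_rng(s) for s in root.spawn(6)]
    rng_f, rng_items, rng_base, rng_edges, rng_cov, rng_y = streams

    # latent thought factors (blocks of 3 correlated within cluster)
    chol = np.linalg.cholesky(_factor_correlation())
    factors = rng_f.standard_normal((n, 6)) @ chol.T

    # ratings
    cluster_of_item, factor_of_item = _item_assignment(config.n_items)
    resid_sd = config.item_noise_sd
    latent_items = (ITEM_LOADING * factors[:, factor_of_item]
                    + rng_items.normal(0.0, resid_sd, size=(n, config.n_items)))
    marginal_sd = math.sqrt(ITEM_LOADING ** 2 + resid_sd ** 2)
    values = _discretize_ratings(latent_items, marginal_sd)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    item_labels = [f"item_{k:02d}" for k in range(config.n_items)]
    ratings = pd.DataFrame(values, index=subject_ids, columns=item_labels)

    # parcellation and base connectivity
    parcellation = make_parcellation(config.n_nodes, config.n_networks,
                                     int(config.seed) % (2 ** 31))
    G = rng_base.normal(0.0, 0.3, size=(config.n_nodes, 5))
    base = np.clip(G @ G.T, -0.8, 0.8)
    np.fill_diagonal(base, 0.0)
    for comp in config.planted_components:
        for (i, j), b in zip(comp.edges, comp.base_weights):
            base[i, j] = base[j, i] = b

    betas = _planted_couplings(config)
    delta = rng_base.normal(0.0, SUBJECT_OFFSET_SD, size=n)
    drivers = np.stack(
        [factors[:, comp.target_factor] for comp in config.planted_components],
        axis=1) if config.planted_components else np.zeros((n, 0))
    stack = _build_stack(config, base, delta, drivers, betas, rng_edges)
    connectomes = [Connectome(stack[i], subject_id=subject_ids[i])
                   for i in range(n)]

    # covariates: age (years), gender (1 = female, Bernoulli 0.61 as in the
    # emulated cohort's 129/82 split), motion fraction in [0, 0.15]
    age = np.clip(rng_cov.normal(20.85, 2.44, size=n), 18, 31)
    gender = (rng_cov.random(n) < 129 / 211).astype(int)
    motion = np.clip(rng_cov.beta(2.0, 30.0, size=n), 0.0, 0.15)
    covariates = pd.DataFrame(
        {"age": age, "gender": gender, "motion_fraction": motion},
        index=subject_ids)

    # well-being from the planted mediation model (standardized latent scale,
    # then mapped to a WHOQOL-like 0-100 domain score)
    zcov = {"age": _standardize(age),
            "gender": gender - gender.mean(),
            "motion_fraction": _standardize(motion)}
    domains = {}
    for domain in ("psychological", "social"):
        y = np.zeros(n)
        used_var = 0.0
        med = config.mediation
        if med is not None and med.domain == domain:
            comp = config.planted_components[med.target_component]
            x = component_log_fractional_strength(stack, comp)
            x = _standardize(np.nan_to_num(x, nan=np.nanmean(x)))
            m = factors[:, comp.target_factor]
            y += med.c_prime * x + med.b_path * m
            used_var += (med.c_prime ** 2 + med.b_path ** 2
                         + 2 * med.a_path * med.b_path * med.c_prime)
            for name, gamma in med.covariate_effects:
                y += gamma * zcov[name]
                used_var += gamma ** 2
        if (domain == "social" and config.social_direct_component is not None
                and config.social_direct_component < len(config.planted_components)):
            comp = config.planted_components[config.social_direct_component]
            x = component_log_fractional_strength(stack, comp)
            x = _standardize(np.nan_to_num(x, nan=np.nanmean(x)))
            y += config.social_direct_coef * x
            used_var += config.social_direct_coef ** 2
            for name, gamma in (("age", -0.1), ("motion_fraction", -0.1)):
                y += gamma * zcov[name]
                used_var += gamma ** 2
        noise_var = max(0.05, 1.0 - used_var)
        y = y + rng_y.normal(0.0, math.sqrt(noise_var), size=n)
        domains[domain] = 60.0 + 10.0 * y
    wellbeing = pd.DataFrame(domains, index=subject_ids)

    latents = {
        "factors": factors,
        "base": base,
        "delta": delta,
        "betas": betas,
        "chol": chol,
        "cluster_of_item": cluster_of_item,
        "factor_of_item": factor_of_item,
        "marginal_sd": marginal_sd,
    }
    return SyntheticCohort(parcellation=parcellation, connectomes=connectomes,
                           ratings=ratings, covariates=covariates,
                           wellbeing=wellbeing, truth=config, latents=latents)


def _solve_change_coupling_mix(a_real: float, rho: float, v_fresh: float,
                               target: float) -> float:
    """Mixing weight mu of the session-2 brain driver.

    The session-2 planted edges of the state component are driven by
    ``h2 = mu * f2 + sqrt(1 - mu^2) * xi``; session 1 uses ``h1 = f1``.
    ``a_real`` is the standardized brain-score coupling, ``rho`` the factor
    ICC, ``v_fresh`` the fresh (per-session) share of log-FS variance.
    Solves corr(delta x, delta f) = target on mu in [-1, 1]; returns 1 with
    a warning when the target exceeds the attainable maximum.
    """

    def c_of(mu: float) -> float:
        num = a_real * (1 - rho) * (1 + mu)
        den = math.sqrt(2 * (1 - rho)) * math.sqrt(
            a_real ** 2 * (2 - 2 * mu * rho) + 2 * v_fresh)
        return num / den

    if target >= c_of(1.0):
        if target > c_of(1.0) + 1e-9:
            logger.warning(
                "change_coupling %.2f above attainable maximum %.2f; using mu=1",
                target, c_of(1.0))
        return 1.0
    if target <= c_of(-1.0):
        return -1.0
    return float(brentq(lambda mu: c_of(mu) - target, -1.0, 1.0, xtol=1e-10))


def simulate_retest(cohort: SyntheticCohort,
                    truth: RetestTruth | None = None) -> SyntheticCohort:
    """Generate a session-2 cohort for the retest subjects.

    Factor k evolves as ``f2 = rho_k * f1 + sqrt(1 - rho_k^2) * e`` with
    ``rho_k`` the configured ICC (trait/state/other), which makes the
    population ICC(2,1) of each factor equal to ``rho_k``.  Session-2
    connectomes reuse the subject's base connectivity and offset (the
    trait-like part of the brain measure) with fresh edge noise; the
    state component's edges are driven by a partially decoupled session-2
    brain state calibrated to the configured change-change coupling.
    """
    config = cohort.truth
    if truth is None:
        truth = config.retest
    if truth.n_retest > config.n_subjects:
        raise ValueError("n_retest exceeds cohort size")
    n = truth.n_retest
    idx = np.arange(n)  # retest arm = first n_retest subjects
    subject_ids = cohort.subject_ids[:n]

    root = np.random.SeedSequence([int(config.seed) % (2 ** 31), 2])
    rng_f, rng_items, rng_edges, rng_mix = [
        np.random.default_rng(s) for s in root.spawn(4)]

    rho = np.full(6, truth.other_icc)
    rho[truth.trait_factor] = truth.trait_icc
    rho[truth.state_factor] = truth.state_icc

    f1 = cohort.latents["factors"][idx]
    resid = rng_f.standard_normal((n, 6)) @ cohort.latents["chol"].T
    f2 = rho * f1 + np.sqrt(1.0 - rho ** 2) * resid

    # session-2 ratings through the same loadings and cutpoints
    factor_of_item = cohort.latents["factor_of_item"]
    resid_sd = config.item_noise_sd
    latent_items = (ITEM_LOADING * f2[:, factor_of_item]
                    + rng_items.normal(0.0, resid_sd, size=(n, config.n_items)))
    values = _discretize_ratings(latent_items, cohort.latents["marginal_sd"])
    ratings = pd.DataFrame(values, index=subject_ids,
                           columns=list(cohort.ratings.columns))

    # session-2 planted-edge drivers
    betas = cohort.latents["betas"]
    drivers = np.zeros((n, len(config.planted_components)))
    mu_used = {}
    for k, comp in enumerate(config.planted_components):
        driver = f2[:, comp.target_factor]
        if comp.target_factor == truth.state_factor and betas[k] > 0:
            g, q, _, _ = _log_fs_sensitivities(comp)
            s_f = g * betas[k]
            var_x = (s_f ** 2 + (g * SUBJECT_OFFSET_SD) ** 2
                     + q * config.edge_noise_sd ** 2)
            a_real = s_f / math.sqrt(var_x)
            v_fresh = q * config.edge_noise_sd ** 2 / var_x
            mu = _solve_change_coupling_mix(a_real, rho[comp.target_factor],
                                            v_fresh, truth.change_coupling)
            xi = rng_mix.standard_normal(n)
            driver = mu * driver + math.sqrt(max(0.0, 1 - mu ** 2)) * xi
            mu_used[k] = mu
        drivers[:, k] = driver

    stack = _build_stack(config, cohort.latents["base"],
                         cohort.latents["delta"][idx], drivers, betas,
                         rng_edges)
    connectomes = [Connectome(stack[i], subject_id=subject_ids[i])
                   for i in range(n)]

    latents = dict(cohort.latents)
    latents.update({"factors": f2, "factors_session1": f1,
                    "delta": cohort.latents["delta"][idx], "mu": mu_used})
    return SyntheticCohort(
        parcellation=cohort.parcellation, connectomes=connectomes,
        ratings=ratings, covariates=cohort.covariates.iloc[:n].copy(),
        wellbeing=cohort.wellbeing.iloc[:n].copy(), truth=config,
        session=2, latents=latents)
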