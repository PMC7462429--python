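"""Edgewise GLM, suprathreshold components, and permutation FWE."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from thoughtnet import (DesignMatrix, EdgeStats, edgewise_glm, make_design,
                        mask_connectome, nbs_test, suprathreshold_components)
from thoughtnet.connectome import Connectome


def _random_stack(rng, n=40, N=10):
    w = rng.uniform(-0.5, 0.5, size=(n, N, N))
    w = (w + w.transpose(0, 2, 1)) / 2
    for k in range(n):
        np.fill_diagonal(w[k], 0.0)
    return w


def _simple_design(rng, n, n_scores=1):
    scores = pd.DataFrame(rng.standard_normal((n, n_scores)),
                          columns=[f"s{k}" for k in range(n_scores)],
                          index=[f"S{i}" for i in range(n)])
    df = scores.copy()
    df["intercept"] = 1.0
    return DesignMatrix(data=df, interest=tuple(scores.columns),
                        nuisance=("intercept",))


class TestEdgewiseGlm:
    def test_toy_regression_matches_statsmodels(self):
        """Fixed 8-subject single-edge toy agrees with an independent OLS."""
        weights = np.array([0.11, -0.30, 0.42, 0.05, -0.17, 0.33, 0.25, -0.08])
        score = np.array([0.9, -1.2, 1.5, 0.1, -0.7, 1.1, 0.4, -0.6])
        motion = np.array([0.02, 0.05, 0.01, 0.08, 0.03, 0.02, 0.06, 0.04])
        stack = np.zeros((8, 2, 2))
        stack[:, 0, 1] = stack[:, 1, 0] = weights
        df = pd.DataFrame({"s0": score, "intercept": 1.0, "motion": motion})
        design = DesignMatrix(df, interest=("s0",),
                              nuisance=("intercept", "motion"))
        stats = edgewise_glm(stack, design, "s0")
        X = sm.add_constant(np.column_stack([score, motion]))
        t_ref = sm.OLS(weights, X).fit().tvalues[1]
        assert stats.t[0] == pytest.approx(t_ref, abs=1e-10)
        assert stats.df == 5

    def test_null_scores_rarely_exceed_three(self, rng):
        """A score orthogonal to the edges by construction yields |t| < 3
        for ~99% of edges at n=100."""
        stack = _random_stack(rng, n=100, N=25)
        design = _simple_design(rng, 100)
        stats = edgewise_glm(stack, design, "s0")
        assert (np.abs(stats.t) < 3).mean() > 0.98

    def test_perfect_fit_is_capped_not_infinite(self, rng, caplog):
        import logging
        n = 20
        score = rng.standard_normal(n)
        stack = np.zeros((n, 2, 2))
        stack[:, 0, 1] = stack[:, 1, 0] = 0.5 * score
        df = pd.DataFrame({"s0": score, "intercept": 1.0})
        design = DesignMatrix(df, interest=("s0",), nuisance=("intercept",))
        with caplog.at_level(logging.WARNING, logger="thoughtnet.nbs"):
            stats = edgewise_glm(stack, design, "s0")
        assert np.isfinite(stats.t).all()
        assert np.abs(stats.t[0]) == 1e6
        assert any("capped" in r.message for r in caplog.records)

    def test_rank_deficient_design_names_columns(self, rng):
        df = pd.DataFrame({"s0": rng.standard_normal(20)})
        df["s1"] = 2 * df["s0"]
        df["intercept"] = 1.0
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(df, interest=("s0", "s1"), nuisance=("intercept",))


class TestSuprathresholdComponents:
    def _stats_from_tmap(self, tmap: dict, N=10):
        iu = np.triu_indices(N, k=1)
        t = np.zeros(iu[0].size)
        for k, (i, j) in enumerate(zip(iu[0], iu[1])):
            t[k] = tmap.get((int(i), int(j)), 0.0)
        return EdgeStats(t=t, df=50, contrast="s0", n_nodes=N)

    def test_hand_checkable_graph(self):
        stats = self._stats_from_tmap({(0, 1): 4.0, (1, 2): 3.5, (0, 2): -3.3,
                                       (5, 6): 3.6, (6, 7): 4.2})
        comps = suprathreshold_components(stats, T=3.2)
        assert [c.size for c in comps] == [3, 2]
        assert comps[0].edges == ((0, 1), (0, 2), (1, 2))
        assert comps[0].signs == (1, -1, 1)
        assert comps[1].nodes == (5, 6, 7)

    def test_no_suprathreshold_edges_gives_empty_list(self):
        stats = self._stats_from_tmap({(0, 1): 2.0})
        assert suprathreshold_components(stats, T=3.2) == []

    def test_sidedness(self):
        stats = self._stats_from_tmap({(0, 1): 4.0, (2, 3): -4.0})
        pos = suprathreshold_components(stats, T=3.2, sidedness="positive")
        neg = suprathreshold_components(stats, T=3.2, sidedness="negative")
        assert [c.edges for c in pos] == [((0, 1),)]
        assert [c.edges for c in neg] == [((2, 3),)]

    def test_matches_union_find_oracle(self, rng):
        """Component decomposition equals a brute-force union-find oracle
        on 50 random t-maps."""
        for _ in range(50):
            N = 12
            iu = np.triu_indices(N, k=1)
            t = rng.standard_normal(iu[0].size) * 2
            stats = EdgeStats(t=t, df=30, contrast="s0", n_nodes=N)
            comps = suprathreshold_components(stats, T=2.5)
            # oracle: union-find over suprathreshold edges
            parent = list(range(N))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            sel = np.abs(t) >= 2.5
            edges = list(zip(iu[0][sel], iu[1][sel]))
            for i, j in edges:
                parent[find(i)] = find(j)
            groups = {}
            for i, j in edges:
                groups.setdefault(find(i), set()).add((int(i), int(j)))
            expected = sorted((sorted(g) for g in groups.values()),
                              key=lambda g: (-len(g), g))
            got = [sorted(c.edges) for c in comps]
            assert got == [list(map(tuple, g)) for g in expected]


class TestNbsTest:
    def test_exhaustive_matches_enumeration_oracle(self, rng):
        """For n=6 with no nuisance beyond the intercept, the permutation p
        over all 720 enumerated shuffles equals an independently coded
        exhaustive-enumeration oracle exactly."""
        n, N, T = 6, 5, 1.5
        stack = _random_stack(rng, n=n, N=N)
        # make one edge strongly score-coupled so a component exists
        score = rng.standard_normal(n)
        stack[:, 0, 1] = stack[:, 1, 0] = np.clip(0.6 * score, -1, 1)
        stack[:, 1, 2] = stack[:, 2, 1] = np.clip(0.5 * score, -1, 1)
        design = _simple_design(rng, n)
        design.data["s0"] = score
        res = nbs_test(stack, design, "s0", T=T, exhaustive=True, n_perm=0)
        assert res.n_permutations == 720

        # oracle: simple regression t per edge, pure-python components
        iu = np.triu_indices(N, k=1)

        def tmap(s):
            out = []
            for i, j in zip(iu[0], iu[1]):
                y = stack[:, i, j]
                slope, intercept = np.polyfit(s, y, 1)
                resid = y - slope * s - intercept
                se = np.sqrt((resid ** 2).sum() / (n - 2)
                             / ((s - s.mean()) ** 2).sum())
                out.append(slope / se if se > 0 else np.sign(slope) * 1e6)
            return np.array(out)

        def max_comp(t):
            sel = np.abs(t) >= T
            parent = list(range(N))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            edges = [(i, j) for i, j, s in zip(iu[0], iu[1], sel) if s]
            for i, j in edges:
                parent[find(i)] = find(j)
            sizes = {}
            for i, j in edges:
                sizes[find(i)] = sizes.get(find(i), 0) + 1
            return max(sizes.values(), default=0)

        obs_t = tmap(score)
        obs_sizes = sorted((c.size for c in res.components), reverse=True)
        null = [max_comp(tmap(score[list(p)]))
                for p in itertools.permutations(range(n))]
        null = np.array(null)
        for comp, p in zip(res.components, res.fwe_p):
            assert p == pytest.approx((null >= comp.size).mean(), abs=1e-12)
        assert sorted(res.null_max_sizes.tolist()) == sorted(null.tolist())
        assert obs_sizes[0] == max_comp(obs_t)

    def test_seeded_determinism(self, rng):
        stack = _random_stack(rng, n=30, N=8)
        design = _simple_design(rng, 30)
        a = nbs_test(stack, design, "s0", T=2.0, n_perm=200, seed=42)
        b = nbs_test(stack, design, "s0", T=2.0, n_perm=200, seed=42)
        assert np.array_equal(a.null_max_sizes, b.null_max_sizes)
        assert np.array_equal(a.fwe_p, b.fwe_p)

    def test_raising_threshold_never_grows_components(self, rng):
        stack = _random_stack(rng, n=40, N=10)
        design = _simple_design(rng, 40)
        stats = edgewise_glm(stack, design, "s0")
        prev = None
        for T in (1.5, 2.0, 2.5, 3.0):
            comps = suprathreshold_components(stats, T)
            largest = comps[0].size if comps else 0
            total = sum(c.size for c in comps)
            if prev is not None:
                assert largest <= prev[0]
                assert total <= prev[1]
            prev = (largest, total)

    def test_unsmoothed_p_reproduces_count_over_n(self, rng):
        stack = _random_stack(rng, n=25, N=8)
        score = rng.standard_normal(25)
        stack[:, 0, 1] = stack[:, 1, 0] = np.clip(0.7 * score, -1, 1)
        design = _simple_design(rng, 25)
        design.data["s0"] = score
        smooth = nbs_test(stack, design, "s0", T=2.5, n_perm=99, seed=0)
        strict = nbs_test(stack, design, "s0", T=2.5, n_perm=99, seed=0,
                          smoothing=False)
        counts = strict.fwe_p * 99
        assert np.allclose(smooth.fwe_p, (counts + 1) / 100)

    def test_freedman_lane_scheme_runs(self, rng):
        stack = _random_stack(rng, n=30, N=8)
        design = _simple_design(rng, 30)
        res = nbs_test(stack, design, "s0", T=2.0, n_perm=100, seed=1,
                       scheme="freedman_lane")
        assert res.n_permutations == 100
        assert ((res.fwe_p > 0) & (res.fwe_p <= 1)).all()

    def test_zero_permutations_rejected(self, rng):
        stack = _random_stack(rng, n=20, N=6)
        design = _simple_design(rng, 20)
        with pytest.raises(ValueError, match="n_perm"):
            nbs_test(stack, design, "s0", T=2.0, n_perm=0)


class TestMaskConnectome:
    @pytest.fixture()
    def result(self, rng):
        stack = _random_stack(rng, n=40, N=10)
        score = rng.standard_normal(40)
        for (i, j) in [(0, 1), (1, 2), (2, 3)]:
            stack[:, i, j] = stack[:, j, i] = np.clip(0.8 * score, -1, 1)
        design = _simple_design(rng, 40)
        design.data["s0"] = score
        return stack, nbs_test(stack, design, "s0", T=3.2, n_perm=100, seed=0)

    def test_retained_edges_equal_component_edges(self, result):
        stack, res = result
        comp = res.components[0]
        masked = mask_connectome(Connectome(stack[0]), res, 0)
        nz = {(i, j) for i, j in zip(*np.nonzero(np.triu(masked.weights)))}
        assert nz == set(comp.edges)
        for i, j in comp.edges:
            assert masked.weights[i, j] == stack[0][i, j]

    def test_non_component_weight_sums_to_zero(self, result):
        stack, res = result
        masked = mask_connectome(Connectome(stack[0]), res, 0)
        outside = np.abs(masked.weights).sum() - sum(
            2 * abs(masked.weights[i, j]) for i, j in res.components[0].edges)
        assert outside == pytest.approx(0.0, abs=1e-15)

    def test_component_index_out_of_range(self, result):
        stack, res = result
        with pytest.raises(IndexError):
            mask_connectome(Connectome(stack[0]), res, len(res.components))

    def test_mask_marks_exactly_significant_edges(self, result):
        stack, res = result
        expected = set()
        for comp, sig in zip(res.components, res.significant):
            if sig:
                expected |= set(comp.edges)
        marked = {(i, j) for i, j in zip(*np.nonzero(np.triu(res.mask)))}
        assert marked == expected


def test_make_design_alignment_checked(rng):
    scores = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"],
                          index=[f"S{i}" for i in range(10)])
    cov = pd.DataFrame({"age": np.arange(10)},
                       index=[f"X{i}" for i in range(10)])
    with pytest.raises(ValueError, match="indices differ"):
        make_design(scores, cov, np.zeros(10))
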