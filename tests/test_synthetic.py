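"""Ground-truth properties of the synthetic cohort generator."""

import logging
import math

import numpy as np
import pytest

from thoughtnet import (CohortConfig, MediationTruth, PlantedComponent,
                        RetestTruth, component_log_fractional_strength,
                        default_planted_components, make_parcellation,
                        planted_edge_score_correlation, simulate_cohort,
                        simulate_retest)
from thoughtnet.mediation import mediate
from thoughtnet.synthetic import EDGE_NOISE_SCALE, SUBJECT_OFFSET_SD


def _null_components(n_nodes):
    return tuple(PlantedComponent(edges=c.edges, effect_per_edge=0.0,
                                  target_factor=c.target_factor)
                 for c in default_planted_components(n_nodes))


class TestParcellation:
    @pytest.mark.parametrize("n_nodes,n_networks,seed", [(264, 13, 1), (60, 13, 7)])
    def test_all_networks_populated(self, n_nodes, n_networks, seed):
        p = make_parcellation(n_nodes, n_networks, seed)
        assert len(p) == n_nodes
        assert p["network"].nunique() == n_networks
        assert p["label"].is_unique
        assert np.allclose(np.linalg.norm(p[["x", "y", "z"]], axis=1), 70.0)

    def test_single_network(self):
        p = make_parcellation(10, 1, 0)
        assert p["network"].nunique() == 1

    def test_seed_determinism(self):
        a = make_parcellation(60, 13, 7)
        b = make_parcellation(60, 13, 7)
        assert a.equals(b)

    def test_too_many_networks_rejected(self):
        with pytest.raises(ValueError, match="cannot exceed"):
            make_parcellation(5, 6, 0)


class TestCohortGeneration:
    def test_generative_determinism(self):
        cfg = CohortConfig.desk(seed=5, n_subjects=40, n_nodes=30)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.ratings.equals(b.ratings)
        assert np.array_equal(a.connectome_stack(), b.connectome_stack())
        assert a.wellbeing.equals(b.wellbeing)
        assert a.covariates.equals(b.covariates)

    def test_connectome_invariants(self, desk_cohort):
        w = desk_cohort.connectomes[0].weights
        assert np.abs(w - w.T).max() < 1e-12
        assert np.abs(np.diagonal(w)).max() == 0
        assert np.abs(w).max() <= 1.0
        assert desk_cohort.ratings.to_numpy().min() >= 1
        assert desk_cohort.ratings.to_numpy().max() <= 4

    def test_null_effect_leaves_planted_edges_uncorrelated(self):
        cfg = CohortConfig.desk(seed=2, planted_components=_null_components(60),
                                mediation=None)
        cohort = simulate_cohort(cfg)
        stack = cohort.connectome_stack()
        f = cohort.latents["factors"]
        for comp in cfg.planted_components:
            for i, j in comp.edges:
                r = np.corrcoef(stack[:, i, j], f[:, comp.target_factor])[0, 1]
                assert abs(r) < 0.2

    def test_edge_score_correlation_matches_closed_form(self, desk_cohort):
        """Sample corr(planted edge, target factor) agrees with the analytic
        value r = beta / sqrt(beta^2 + sigma_delta^2 + sigma_edge^2)."""
        cfg = desk_cohort.truth
        stack = desk_cohort.connectome_stack()
        f = desk_cohort.latents["factors"]
        betas = desk_cohort.latents["betas"]
        for k, comp in enumerate(cfg.planted_components):
            expected = planted_edge_score_correlation(betas[k], cfg.noise_sd)
            # independent closed form from the generative variances
            check = betas[k] / math.sqrt(
                betas[k] ** 2 + SUBJECT_OFFSET_SD ** 2
                + (EDGE_NOISE_SCALE * cfg.noise_sd) ** 2)
            assert expected == pytest.approx(check, abs=1e-12)
            observed = np.mean([
                np.corrcoef(stack[:, i, j] * s, f[:, comp.target_factor])[0, 1]
                for (i, j), s in zip(comp.edges, comp.sign_pattern)])
            assert observed == pytest.approx(expected, abs=0.1)

    def test_variance_bookkeeping(self):
        """Var(planted edge) decomposes into effect^2*Var(score) + noise
        variance (subject offset + edge noise) within 5% at n=2000."""
        cfg = CohortConfig.desk(seed=9, n_subjects=2000, n_nodes=30)
        cohort = simulate_cohort(cfg)
        stack = cohort.connectome_stack()
        betas = cohort.latents["betas"]
        for k, comp in enumerate(cfg.planted_components):
            expected = (betas[k] ** 2 + SUBJECT_OFFSET_SD ** 2
                        + (EDGE_NOISE_SCALE * cfg.noise_sd) ** 2)
            var = np.mean([stack[:, i, j].var() for i, j in comp.edges])
            assert var == pytest.approx(expected, rel=0.05)

    def test_zero_a_path_breaks_indirect_effect(self):
        cfg = CohortConfig.desk(seed=3, n_subjects=300,
                                mediation=MediationTruth(a_path=0.0))
        cohort = simulate_cohort(cfg)
        comp = cfg.planted_components[0]
        stack = cohort.connectome_stack()
        # planted edges uncorrelated with the score
        f = cohort.latents["factors"][:, comp.target_factor]
        for i, j in comp.edges:
            assert abs(np.corrcoef(stack[:, i, j], f)[0, 1]) < 0.2
        x = component_log_fractional_strength(stack, comp)
        res = mediate(x, f, cohort.wellbeing["psychological"].to_numpy(),
                      covariates=cohort.covariates, n_boot=500, seed=0)
        assert abs(res.indirect) <= 2 * res.se_indirect

    def test_saturating_effect_logs_warning(self, caplog):
        comp = PlantedComponent(edges=((0, 1), (1, 2)), effect_per_edge=2.0,
                                target_factor=0)
        cfg = CohortConfig.desk(seed=0, n_subjects=50, n_nodes=30,
                                planted_components=(comp,), mediation=None)
        with caplog.at_level(logging.WARNING, logger="thoughtnet.synthetic"):
            simulate_cohort(cfg)
        assert any("saturates" in r.message for r in caplog.records)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_nodes=5)
        with pytest.raises(ValueError):
            PlantedComponent(edges=((0, 1), (4, 5)), effect_per_edge=0.1,
                             target_factor=0)  # disconnected
        with pytest.raises(ValueError):
            PlantedComponent(edges=((1, 0),), effect_per_edge=0.1,
                             target_factor=0)  # i >= j


class TestRetest:
    def test_perfect_trait_reliability_with_zero_noise(self):
        cfg = CohortConfig.desk(seed=6, n_subjects=60, n_nodes=30, noise_sd=0.0,
                                retest=RetestTruth(n_retest=40, trait_icc=1.0))
        cohort = simulate_cohort(cfg)
        rt = simulate_retest(cohort)
        k = cfg.retest.trait_factor
        f1 = rt.latents["factors_session1"][:, k]
        f2 = rt.latents["factors"][:, k]
        assert np.allclose(f1, f2)
        # trait-factor items reproduce exactly when item noise is zero
        items = np.flatnonzero(cohort.latents["factor_of_item"] == k)
        assert rt.ratings.iloc[:, items].equals(
            cohort.ratings.iloc[:40, items])

    def test_state_icc_zero_monte_carlo(self):
        cfg = CohortConfig.desk(seed=7, n_subjects=1000, n_nodes=30,
                                retest=RetestTruth(n_retest=1000, state_icc=0.0))
        rt = simulate_retest(simulate_cohort(cfg))
        k = cfg.retest.state_factor
        r = np.corrcoef(rt.latents["factors_session1"][:, k],
                        rt.latents["factors"][:, k])[0, 1]
        assert abs(r) < 0.1

    def test_trait_icc_converges(self):
        cfg = CohortConfig.desk(seed=8, n_subjects=1000, n_nodes=30,
                                retest=RetestTruth(n_retest=1000))
        rt = simulate_retest(simulate_cohort(cfg))
        k = cfg.retest.trait_factor
        r = np.corrcoef(rt.latents["factors_session1"][:, k],
                        rt.latents["factors"][:, k])[0, 1]
        assert abs(r - cfg.retest.trait_icc) < 0.05

    def test_change_coupling_realized(self):
        """corr(delta score, delta log fractional strength) lands in the
        configured band for the state-like component."""
        cfg = CohortConfig.desk(seed=3, n_subjects=600,
                                retest=RetestTruth(n_retest=500,
                                                   change_coupling=0.4))
        cohort = simulate_cohort(cfg)
        rt = simulate_retest(cohort)
        comp = cfg.planted_components[0]
        x1 = component_log_fractional_strength(
            cohort.connectome_stack()[:500], comp)
        x2 = component_log_fractional_strength(rt.connectome_stack(), comp)
        dm = (rt.latents["factors"][:, comp.target_factor]
              - rt.latents["factors_session1"][:, comp.target_factor])
        r = np.corrcoef(dm, x2 - x1)[0, 1]
        assert 0.3 <= r <= 0.5

    def test_retest_larger_than_cohort_rejected(self):
        cfg = CohortConfig.desk(seed=0, n_subjects=30, n_nodes=30,
                                retest=RetestTruth(n_retest=20))
        cohort = simulate_cohort(cfg)
        with pytest.raises(ValueError):
            simulate_retest(cohort, RetestTruth(n_retest=50))
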