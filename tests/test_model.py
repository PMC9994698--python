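"""Likelihood engine: parameter counting, recursions, history probabilities,
oracle equivalence, and maximum-likelihood fitting."""

import numpy as np
import pytest

import jspopan as jp
from jspopan.model import _group_history_logprobs, resolve_cell_probs

from conftest import all_histories, brute_group_loglik, brute_history_prob


# Structural parameter counts on the 23-group design.  Published k values
# agree for every one-hot and t*acc row; the p(t+acc) rows were counted
# differently by the original software (see the k-discrepancy test below).
STRUCTURAL_K = [
    ("Phi(t+acc2019) p(t)", 9),
    ("Phi(t+acc2019) p(t*acc)", 12),
    ("Phi(acc2019) p(t)", 5),
    ("Phi(acc+t2019) p(t)", 6),
    ("Phi(t*acc) p(t)", 12),
    ("Phi(t*acc) p(t*acc)", 15),
    ("Phi(cohort) p(t)", 8),
    ("Phi(cohort) p(t*acc)", 11),
    ("Phi(t) p(t)", 8),
    ("Phi(t) p(t*acc)", 11),
    ("Phi(2019) p(t*acc)", 8),
    ("Phi(constant) p(t)", 4),
]


class TestParameterIndex:
    @pytest.mark.parametrize("name,k", STRUCTURAL_K)
    def test_structural_parameter_counts(self, design, name, k):
        pim = jp.build_parameter_index(design, jp.ModelSpec.parse(name))
        assert pim.n_params == k

    def test_additive_detection_counts_are_structural(self, design):
        # t+acc detection: 3 realized survey occasions + 1 acclimation effect
        pim = jp.build_parameter_index(design, jp.ModelSpec.parse("Phi(acc2019) p(t+acc)"))
        assert pim.k_p == 4 and pim.n_params == 6

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            jp.ModelSpec("nonsense", "t")

    def test_survival_only_model_single_parameter(self):
        # fully tracked group: every detection cell fixed, only survival free
        d = jp.build_design([jp.CohortGroup(2015, 6, 10)])
        pim = jp.build_parameter_index(d, jp.ModelSpec("constant", "t"))
        assert pim.n_params == 1

    def test_acclimation_level_definition(self, design):
        pim = jp.build_parameter_index(design, jp.ModelSpec.parse("Phi(acc) p(t)"))
        # the New column is hit exactly once per group: its first interval
        new_col = pim.phi_labels.index("New")
        for g, grp in enumerate(design.groups):
            rows = [i for i, (gi, _) in enumerate(pim.phi_cells) if gi == g]
            hits = [i for i in rows if pim.X_phi[i, new_col] == 1.0]
            if grp.release_occasion < 5:
                (hit,) = hits
                assert pim.phi_cells[hit] == (g, grp.release_occasion)

    def test_pim_export_contiguous_ids(self, design):
        pim = jp.build_parameter_index(design, jp.ModelSpec.parse("Phi(acc2019) p(t)"))
        df = pim.to_frame(design)
        ids = set()
        for s in df["parameter_ids"]:
            ids.update(int(x) for x in s.split("+") if x)
        assert ids == set(range(1, pim.n_params + 1))


class TestRecursions:
    def test_certain_detection_forbids_all_zero(self):
        zeta, _, _ = jp.nonencounter_recursion([0.9] * 5, [1, 0.5, 0.5, 0, 0, 0], start=0)
        assert zeta == 0.0

    def test_immortal_invisible(self):
        zeta, _, _ = jp.nonencounter_recursion([1.0] * 5, [0.0] * 6, start=0)
        assert zeta == 1.0

    def test_two_occasion_enumeration(self):
        # start at occasion 4: die (0.2) or survive undetected (0.8 * 0.5)
        phi = [0.0] * 4 + [0.8]
        p = [0.0] * 4 + [0.0, 0.5]
        zeta, _, _ = jp.nonencounter_recursion(phi, p, start=4)
        assert zeta == pytest.approx(0.6, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            jp.nonencounter_recursion([1.2] * 5, [0.5] * 6, start=0)

    def test_chi_final_occasion_is_one(self):
        _, _, chi = jp.nonencounter_recursion([0.7] * 5, [0.3] * 6, start=0)
        assert chi[-1] == 1.0


class TestHistoryProbability:
    def test_telemetered_death_sequence(self):
        # tracked throughout from occasion 3: seen, seen, vanished => died
        phi = [0.0] * 3 + [0.9, 0.8]
        p = [0.0] * 3 + [1.0, 1.0, 1.0]
        P = jp.history_probability([0, 0, 0, 1, 1, 0], 3, phi, p)
        assert P == pytest.approx(0.9 * 0.2, abs=1e-12)

    def test_two_occasion_certain_detection(self):
        phi = [0.0] * 4 + [0.75]
        p = [0.0] * 4 + [1.0, 1.0]
        assert jp.history_probability([0, 0, 0, 0, 1, 1], 4, phi, p) == pytest.approx(0.75)

    def test_all_zero_equals_zeta(self):
        phi = [0.8] * 5
        p = [0.0, 0.0, 0.0, 0.3, 0.2, 0.1]
        zeta, _, _ = jp.nonencounter_recursion(phi, p, 1)
        assert jp.history_probability([0] * 6, 1, phi, p) == pytest.approx(zeta)

    @pytest.mark.parametrize("release", [0, 2, 4])
    def test_matches_latent_death_enumeration(self, release):
        rng = np.random.default_rng(42 + release)
        for _ in range(50):
            phi = rng.uniform(0.05, 0.95, size=5)
            p = rng.uniform(0.05, 0.95, size=6)
            for h in all_histories(release):
                got = jp.history_probability(h, release, phi, p)
                want = brute_history_prob(h, release, phi, p)
                assert got == pytest.approx(want, abs=1e-12)

    def test_completeness_over_history_space(self, design):
        rng = np.random.default_rng(7)
        for _ in range(20):
            phi = rng.uniform(0.02, 0.98, size=5)
            for g, grp in enumerate(design.groups):
                p = np.array(
                    [1.0 if design.detection_mask[g, t] is jp.MaskState.FIXED_1
                     else (rng.uniform(0.02, 0.98)
                           if design.detection_mask[g, t] is jp.MaskState.FREE else 0.0)
                     for t in range(6)]
                )
                total = sum(
                    jp.history_probability(h, grp.release_occasion, phi, p)
                    for h in all_histories(grp.release_occasion)
                )
                assert total == pytest.approx(1.0, abs=1e-10)


class TestLikelihood:
    def _toy_group(self):
        # 2-occasion group: released 2019, n=10, 6 observed
        grp = jp.CohortGroup(2019, 0, 10)
        H = np.array([[0, 0, 0, 0, 1, 0]] * 1 + [[0, 0, 0, 0, 1, 1]] * 2
                     + [[0, 0, 0, 0, 0, 1]] * 3, dtype=np.int8)
        items = {}
        for row in H:
            items[tuple(row)] = items.get(tuple(row), 0) + 1
        hist = np.array(sorted(items), dtype=np.int8)
        counts = np.array([items[tuple(r)] for r in hist], dtype=float)
        return jp.GroupData(group=grp, histories=hist, counts=counts, n_unobserved=4)

    def test_group_loglik_matches_enumeration_oracle(self):
        gd = self._toy_group()
        phi = np.array([np.nan] * 4 + [0.7])
        p = np.array([0, 0, 0, 0, 0.4, 0.3])
        got = jp.group_loglik(gd, phi, p)
        want = brute_group_loglik(gd, [0.0] * 4 + [0.7], p)
        assert got == pytest.approx(want, abs=1e-10)

    def test_degenerate_certainty(self):
        # all tracked, nobody dies: lnL = n * log(prod phi)
        grp = jp.CohortGroup(2018, 3, 5)
        H = np.tile(np.array([0, 0, 0, 1, 1, 1], dtype=np.int8), (1, 1))
        gd = jp.GroupData(grp, H, np.array([5.0]), 0)
        phi = np.array([np.nan] * 3 + [0.9, 0.8])
        p = np.array([0, 0, 0, 1.0, 1.0, 1.0])
        assert jp.group_loglik(gd, phi, p) == pytest.approx(5 * np.log(0.9 * 0.8))

    def test_total_loglik_single_group_reduces(self, design, best_spec, sim_dataset):
        _, _, data, _ = sim_dataset
        pim = jp.build_parameter_index(design, best_spec)
        theta = np.random.default_rng(0).normal(size=pim.n_params)
        lv = jp.total_loglik(data, design, pim, theta)
        assert lv.loglik == pytest.approx(sum(lv.per_group_loglik.values()))
        assert lv.dropped_constant

    def test_total_loglik_group_order_invariant(self, design, best_spec, sim_dataset):
        _, _, data, _ = sim_dataset
        pim = jp.build_parameter_index(design, best_spec)
        theta = np.linspace(-1, 1, pim.n_params)
        a = jp.total_loglik(data, design, pim, theta).loglik
        b = jp.total_loglik(data[::-1], design, pim, theta).loglik
        assert a == pytest.approx(b, abs=1e-12)

    def test_total_loglik_matches_brute_force(self, design, best_spec, sim_dataset):
        _, _, data, _ = sim_dataset
        pim = jp.build_parameter_index(design, best_spec)
        rng = np.random.default_rng(11)
        for _ in range(5):
            theta = rng.normal(size=pim.n_params)
            Phi, P = resolve_cell_probs(design, pim, theta)
            want = sum(
                brute_group_loglik(gd, np.nan_to_num(Phi[g]), P[g])
                for g, gd in enumerate(data)
            )
            got = jp.total_loglik(data, design, pim, theta).loglik
            assert got == pytest.approx(want, abs=1e-10)

    def test_non_finite_theta_rejected(self, design, best_spec, sim_dataset):
        _, _, data, _ = sim_dataset
        pim = jp.build_parameter_index(design, best_spec)
        with pytest.raises(ValueError):
            jp.total_loglik(data, design, pim, np.full(pim.n_params, np.nan))

    def test_detection_at_fixed_zero_occasion_rejected(self, design):
        bad = jp.EncounterHistory("bad", 2017, 0, (0, 0, 1, 0, 0, 0))
        with pytest.raises(jp.ValidationError, match="bad"):
            jp.prepare_data([bad], design)

    def test_observed_exceeding_release_rejected(self):
        d = jp.build_design([jp.CohortGroup(2020, 0, 2)])
        hs = [jp.EncounterHistory(f"x{i}", 2020, 0, (0, 0, 0, 0, 0, 1)) for i in range(3)]
        with pytest.raises(jp.ValidationError, match="exceed"):
            jp.prepare_data(hs, d)


class TestFitting:
    def test_fixed_cells_inviolable(self, design, best_spec, sim_dataset):
        _, _, data, _ = sim_dataset
        fit = jp.fit_mle(data, design, best_spec)
        _, P = fit.cell_probs()
        for g in range(design.n_groups):
            for t in range(6):
                st = design.detection_mask[g, t]
                if st is jp.MaskState.FIXED_1:
                    assert P[g, t] == 1.0
                elif st is jp.MaskState.FIXED_0:
                    assert P[g, t] == 0.0

    def test_recovers_truth_at_scale(self, best_spec):
        scenario = jp.SimulationScenario(seed=17, scale=10)
        d = jp.scenario_design(scenario)
        histories, _ = jp.simulate_histories(scenario)
        fit = jp.fit_mle(jp.prepare_data(histories, d), d, best_spec)
        est = dict(zip(fit.param_labels, fit.estimates))
        assert est["phi:baseline"] == pytest.approx(0.89, abs=0.04)
        assert est["phi:2019 New"] == pytest.approx(0.43, abs=0.12)
        assert est["p:2018"] == pytest.approx(0.34, abs=0.08)
        assert est["p:2019"] == pytest.approx(0.10, abs=0.05)
        assert est["p:2020"] == pytest.approx(0.04, abs=0.03)

    def test_boundary_flagged_when_no_deaths(self):
        scenario = jp.SimulationScenario(
            release_schedule={2015: 20}, telemetry_plan={(2015, 6): 20},
            phi_baseline=1.0, phi_first_year={}, seed=3)
        d = jp.scenario_design(scenario)
        histories, _ = jp.simulate_histories(scenario)
        fit = jp.fit_mle(jp.prepare_data(histories, d), d, jp.ModelSpec("constant", "t"))
        assert fit.estimates[0] == pytest.approx(1.0, abs=1e-4)
        assert fit.boundary_flags[0]

    def test_wald_ci_closed_form(self, design, best_spec, sim_dataset):
        import dataclasses
        _, _, data, _ = sim_dataset
        fit = jp.fit_mle(data, design, best_spec)
        k = fit.k
        fake = dataclasses.replace(
            fit, beta=np.zeros(k), covariance=np.eye(k),
            boundary_flags=np.zeros(k, dtype=bool))
        ci = jp.wald_ci(fake, level=0.95)
        assert np.allclose(ci["lo"], 0.123, atol=1e-3)
        assert np.allclose(ci["hi"], 0.877, atol=1e-3)
        # zero covariance degenerates to the estimate
        fake0 = dataclasses.replace(fake, covariance=np.zeros((k, k)))
        ci0 = jp.wald_ci(fake0)
        assert np.allclose(ci0["lo"], ci0["estimate"])

    def test_telemetry_never_increases_survival_variance(self):
        """Expected Fisher information: an extra certain-detection occasion
        cannot make the shared survival estimate less precise."""
        from scipy.special import logit

        def expected_var_phi(d_telem):
            grp = jp.CohortGroup(2018, d_telem, 200)
            d = jp.build_design([grp])
            pim = jp.build_parameter_index(d, jp.ModelSpec("constant", "t"))
            theta0 = np.concatenate([[logit(0.85)], logit(np.full(pim.k_p, 0.3))])

            def logp(h, theta):
                Phi, P = resolve_cell_probs(d, pim, theta)
                return np.log(jp.history_probability(h, 3, np.nan_to_num(Phi[0]), P[0]))

            info = np.zeros((pim.n_params, pim.n_params))
            eps = 1e-6
            for h in all_histories(3):
                Phi, P = resolve_cell_probs(d, pim, theta0)
                ph = jp.history_probability(h, 3, np.nan_to_num(Phi[0]), P[0])
                if ph <= 0:
                    continue
                g = np.zeros(pim.n_params)
                for j in range(pim.n_params):
                    e = np.zeros(pim.n_params); e[j] = eps
                    g[j] = (logp(h, theta0 + e) - logp(h, theta0 - e)) / (2 * eps)
                info += 200 * ph * np.outer(g, g)
            return np.linalg.inv(info)[0, 0]

        variances = [expected_var_phi(d) for d in (0, 1, 2, 3)]
        assert all(b <= a + 1e-10 for a, b in zip(variances, variances[1:]))
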