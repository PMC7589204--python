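import numpy as np
import pytest

from microclust import mixture as mx
from microclust.mixture import GAMMA, HIGH, ZERO, Component, ComponentGrid


def make_grid(components, cutoff):
    return ComponentGrid(tuple(components), cutoff=cutoff)


class TestRelativeResolution:
    def test_equal_totals(self):
        assert np.allclose(mx.compute_relative_resolution([100, 100, 100]), 1.0)

    def test_proportional(self):
        assert np.allclose(mx.compute_relative_resolution([50, 150]), [0.5, 1.5])

    def test_mean_exactly_one(self, rng):
        t = mx.compute_relative_resolution(rng.integers(1, 1000, size=50))
        assert abs(t.mean() - 1.0) < 1e-12

    def test_zero_total_errors_by_default(self):
        with pytest.raises(ValueError, match="zero total"):
            mx.compute_relative_resolution([0, 200])

    def test_zero_total_floor_option(self):
        t = mx.compute_relative_resolution([0, 200], zero_total="floor")
        assert t[0] > 0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            mx.compute_relative_resolution([0, 0])


class TestBuildComponentGrid:
    def test_high_range_knots(self):
        # C=150, C_mid=10, 5 knots: rounded exp(linspace(log10, log150, 5))
        # = (10, 20, 39, 76, 150) -> shapes 11..151 in the high range
        g = mx.build_component_grid(np.array([0, 5, 200]), cutoff=150, c_mid=10,
                                    n_high_knots=5)
        shapes = {c.shape for c in g.gamma_components()}
        assert {11.0, 21.0, 40.0, 77.0, 151.0} <= shapes
        assert max(shapes) == 151.0

    def test_structure_and_order(self):
        g = mx.build_component_grid(np.array([1, 2, 50]), cutoff=40, c_mid=5)
        assert g.components[0].kind == ZERO and g.components[-1].kind == HIGH
        means = [c.mean for c in g.gamma_components()]
        assert means == sorted(means)
        # dedup: no repeated (shape, rate)
        keys = [(c.shape, c.rate) for c in g.gamma_components()]
        assert len(keys) == len(set(keys))

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="positive"):
            mx.build_component_grid(np.zeros(10, dtype=int))

    def test_cmid_must_be_below_cutoff(self):
        with pytest.raises(ValueError):
            mx.build_component_grid(np.array([1, 2]), cutoff=10, c_mid=10)


class TestComponentPmf:
    def test_geometric_case(self):
        # Gamma(1,1) at t=1 is geometric with p=1/2
        assert mx.component_count_pmf(Component(GAMMA, 1, 1), 0, 1.0) == pytest.approx(0.5)
        assert mx.component_count_pmf(Component(GAMMA, 1, 1), 3, 1.0) == pytest.approx(0.5**4)

    def test_shape_two(self):
        assert mx.component_count_pmf(Component(GAMMA, 2, 1), 0, 1.0) == pytest.approx(0.25)

    def test_point_masses(self):
        assert mx.component_count_pmf(Component(ZERO), 0, 1.0) == 1.0
        assert mx.component_count_pmf(Component(ZERO), 3, 1.0) == 0.0
        assert mx.component_count_pmf(Component(HIGH), 5, 1.0) == 0.0

    def test_matches_scipy_nbinom(self, rng):
        from scipy.stats import nbinom

        for _ in range(10):
            a = rng.uniform(0.3, 20)
            b = rng.uniform(0.1, 5)
            t = rng.uniform(0.5, 2)
            k = np.arange(0, 30)
            ours = mx.component_count_pmf(Component(GAMMA, a, b), k, t)
            ref = nbinom.pmf(k, a, b / (t + b))
            assert np.allclose(ours, ref, atol=1e-12)


class TestExpectedAggregatedCounts:
    def test_pure_zero_mass(self):
        g = make_grid([Component(ZERO), Component(GAMMA, 1, 1), Component(HIGH)], 5)
        y = mx.expected_aggregated_counts(g, [1, 0, 0], np.ones(7))
        assert y[0] == pytest.approx(7.0)
        assert np.allclose(y[1:], 0.0)

    def test_geometric_with_tail(self):
        g = make_grid([Component(ZERO), Component(GAMMA, 1, 1), Component(HIGH)], 2)
        y = mx.expected_aggregated_counts(g, [0, 1, 0], np.array([1.0]))
        assert np.allclose(y, [0.5, 0.25, 0.125, 0.125])

    def test_conservation_for_random_weights(self, rng):
        g = mx.build_component_grid(np.array([0, 3, 12, 40]), cutoff=30, c_mid=6)
        t = rng.uniform(0.5, 1.5, size=11)
        for _ in range(5):
            w = rng.dirichlet(np.ones(g.n_components))
            y = mx.expected_aggregated_counts(g, w, t)
            assert y.sum() == pytest.approx(11.0, abs=1e-6)


class TestEstimateWeights:
    def test_pure_zero_data(self):
        g = mx.build_component_grid(np.array([0, 1, 2, 3]), cutoff=10, c_mid=3)
        counts = np.zeros(50, dtype=int)
        y = mx.aggregate_counts(counts, g.cutoff)
        pop = mx.estimate_weights(g, y, np.ones(50))
        assert pop.weights[0] == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_large_sample(self, rng):
        # data from zero mass + Gamma(3,1) + Gamma(8,1), all inside the grid
        I = 2000
        truth = {0: 0.3, 3.0: 0.4, 8.0: 0.3}
        comp = rng.choice(3, p=[0.3, 0.4, 0.3], size=I)
        t = rng.uniform(2 / 3, 4 / 3, I)
        rates = np.zeros(I)
        rates[comp == 1] = rng.gamma(3, 1, (comp == 1).sum())
        rates[comp == 2] = rng.gamma(8, 1, (comp == 2).sum())
        counts = rng.poisson(rates * t)
        g = mx.build_component_grid(counts, c_mid=10, n_high_knots=5)
        y = mx.aggregate_counts(counts, g.cutoff)
        pop = mx.estimate_weights(g, y, t)
        w_z = pop.weights[0]
        assert abs(w_z - 0.3) < 0.05
        # total recovered gamma mass
        assert abs(pop.weights.sum() - 1) < 1e-8

    def test_solution_beats_random_simplex_points(self, rng):
        g = mx.build_component_grid(np.array([0, 1, 4, 9, 20]), cutoff=15, c_mid=5)
        counts = rng.poisson(3.0, size=60)
        t = rng.uniform(0.8, 1.2, 60)
        y = mx.aggregate_counts(counts, g.cutoff)
        tensor = mx.component_pmf_tensor(g, t)
        pop = mx.estimate_weights(g, y, t, pmf_tensor=tensor)
        A = 60 * mx._design_matrix(tensor)
        for _ in range(100):
            w = rng.dirichlet(np.ones(g.n_components))
            r = A @ w - y
            assert pop.objective <= r @ r + 1e-9

    def test_recovery_error_shrinks_with_sample_size(self):
        # L1 weight-recovery error decreases from I=200 to I=2000 (mean over
        # seeds), for data generated inside the grid
        def fit_err(I, seed):
            rng = np.random.default_rng(seed)
            comp = rng.choice(3, p=[0.3, 0.4, 0.3], size=I)
            t = rng.uniform(2 / 3, 4 / 3, I)
            rates = np.zeros(I)
            rates[comp == 1] = rng.gamma(3, 1, (comp == 1).sum())
            rates[comp == 2] = rng.gamma(8, 1, (comp == 2).sum())
            counts = rng.poisson(rates * t)
            g = mx.build_component_grid(counts, c_mid=10, n_high_knots=5)
            pop = mx.estimate_weights(g, mx.aggregate_counts(counts, g.cutoff), t)
            cat = mx.category_matrix(g, t)
            k = np.arange(g.cutoff + 1)
            p3 = np.mean([mx.component_count_pmf(Component(GAMMA, 3, 1), k, ti)
                          for ti in t[:100]], axis=0)
            p8 = np.mean([mx.component_count_pmf(Component(GAMMA, 8, 1), k, ti)
                          for ti in t[:100]], axis=0)
            true_cat = np.zeros(g.cutoff + 3)
            true_cat[0] = 0.3
            true_cat[1:-1] = 0.4 * p3 + 0.3 * p8
            true_cat[-1] = max(0.0, 1.0 - true_cat.sum())
            return np.abs(pop.weights @ cat - true_cat).sum()

        small = np.mean([fit_err(200, s) for s in range(6)])
        large = np.mean([fit_err(2000, s) for s in range(6)])
        assert large < small

    def test_active_set_agrees_with_penalized_nnls(self, rng):
        g = mx.build_component_grid(np.array([0, 2, 5, 11]), cutoff=12, c_mid=4)
        counts = rng.poisson(2.0, size=80)
        t = np.ones(80)
        y = mx.aggregate_counts(counts, g.cutoff)
        a = mx.estimate_weights(g, y, t, method="active-set")
        b = mx.estimate_weights(g, y, t, method="penalized-nnls")
        assert abs(a.objective - b.objective) < 1e-4 * max(a.objective, 1.0)

    def test_objective_invariant_to_subject_permutation(self, rng):
        counts = rng.poisson(4.0, size=40)
        t = rng.uniform(0.5, 1.5, 40)
        g = mx.build_component_grid(counts, c_mid=6)
        perm = rng.permutation(40)
        y = mx.aggregate_counts(counts, g.cutoff)
        p1 = mx.estimate_weights(g, y, t)
        p2 = mx.estimate_weights(g, mx.aggregate_counts(counts[perm], g.cutoff), t[perm])
        assert p1.objective == pytest.approx(p2.objective, rel=1e-9)
        assert np.allclose(p1.weights, p2.weights, atol=1e-7)


class TestBootstrapSelectModel:
    def test_identity_resample_reduces_to_plain_fit(self, rng, monkeypatch):
        counts = rng.poisson(3.0, size=50)
        t = np.ones(50)
        g = mx.build_component_grid(counts, c_mid=5)

        class IdentityRng:
            def integers(self, lo, hi, size):
                return np.arange(size)

        monkeypatch.setattr(np.random, "default_rng", lambda *_: IdentityRng())
        pop = mx.bootstrap_select_model(counts, t, candidate_grids=[g], B=1)
        y = mx.aggregate_counts(counts, g.cutoff)
        ref = mx.estimate_weights(g, y, t)
        assert np.allclose(pop.weights, ref.weights, atol=1e-8)
        assert pop.objective == pytest.approx(ref.objective, rel=1e-9)

    def test_true_model_selected_majority(self):
        # candidate A contains the generating components, candidate B is a
        # deliberately coarse grid missing the low range
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            I = 2000
            comp = rng.choice(3, p=[0.4, 0.35, 0.25], size=I)
            t = rng.uniform(2 / 3, 4 / 3, I)
            rates = np.zeros(I)
            rates[comp == 1] = rng.gamma(2, 1, (comp == 1).sum())
            rates[comp == 2] = rng.gamma(9, 1, (comp == 2).sum())
            counts = rng.poisson(rates * t)
            good = mx.build_component_grid(counts, c_mid=10, n_high_knots=5)
            bad_comps = [Component(ZERO), Component(GAMMA, 30.0, 1.0), Component(HIGH)]
            bad = ComponentGrid(tuple(bad_comps), cutoff=good.cutoff)
            pop = mx.bootstrap_select_model(counts, t, candidate_grids=[bad, good],
                                            B=5, rng=seed)
            if pop.grid is good:
                hits += 1
        assert hits > n_runs / 2

    def test_weights_on_simplex(self, rng):
        counts = rng.poisson(2.0, size=60)
        t = rng.uniform(0.5, 1.5, 60)
        pop = mx.bootstrap_select_model(counts, t, B=4, rng=0)
        assert (pop.weights >= 0).all()
        assert pop.weights.sum() == pytest.approx(1.0, abs=1e-8)


class TestSubjectMixture:
    def _grid(self, C=30):
        return make_grid(
            [Component(ZERO), Component(GAMMA, 1, 1), Component(GAMMA, 10, 1), Component(HIGH)],
            C,
        )

    def test_pure_zero_population(self):
        g = self._grid()
        pop = mx.PopulationMixture(g, np.array([1.0, 0, 0, 0]), 0.0)
        sm = mx.subject_mixture(g, pop, n_i=0, t_i=1.0)
        assert sm.weights[0] == pytest.approx(1.0)
        assert sm.category_pdf[0] == pytest.approx(1.0)  # P_i(z) = 1

    def test_high_count_goes_to_high_mass(self):
        g = self._grid(C=80)  # gamma tails beyond 80 are negligible
        pop = mx.PopulationMixture(g, np.array([0.25, 0.25, 0.25, 0.25]), 0.0)
        sm = mx.subject_mixture(g, pop, n_i=100, t_i=1.0)
        assert sm.weights[-1] == pytest.approx(1.0, abs=1e-6)
        assert sm.category_pdf[-1] == pytest.approx(1.0, abs=1e-6)

    def test_bayes_rule_closed_form(self):
        # two gammas G(1,1), G(10,1) with equal weights, n=0, t=1:
        # posterior on G(1,1) = 0.5 / (0.5 + (1/2)^10)
        g = make_grid([Component(ZERO), Component(GAMMA, 1, 1), Component(GAMMA, 10, 1),
                       Component(HIGH)], 30)
        pop = mx.PopulationMixture(g, np.array([0.0, 0.5, 0.5, 0.0]), 0.0)
        sm = mx.subject_mixture(g, pop, n_i=0, t_i=1.0)
        expected = 0.5 / (0.5 + 0.5**10)
        assert sm.weights[1] == pytest.approx(expected, rel=1e-9)

    def test_category_pdf_sums_to_one_cdf_monotone(self, rng):
        counts = rng.poisson(3.0, size=40)
        t = mx.compute_relative_resolution(np.maximum(rng.poisson(100, 40), 1))
        g = mx.build_component_grid(counts, c_mid=5)
        pop = mx.bootstrap_select_model(counts, t, candidate_grids=[g], B=3, rng=1)
        cat = mx.category_matrix(g, t)
        for i in range(10):
            sm = mx.subject_mixture(g, pop, counts[i], t[i], cat_matrix=cat)
            assert sm.category_pdf.sum() == pytest.approx(1.0, abs=1e-8)
            assert (np.diff(sm.category_cdf) >= -1e-12).all()
            assert sm.category_cdf[-1] == pytest.approx(1.0, abs=1e-8)

    def test_incompatible_observation_errors(self):
        g = self._grid()
        pop = mx.PopulationMixture(g, np.array([1.0, 0, 0, 0]), 0.0)
        with pytest.raises(ValueError, match="compatible"):
            mx.subject_mixture(g, pop, n_i=5, t_i=1.0)
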