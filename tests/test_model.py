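"""Refuge-model unit and property tests.

The independent oracle for the dynamics is the closed-form logistic
solution: with r = R + mu - s(1 + mu) and K = q r / (R + mu) the model is
exactly logistic, so N(t) = K / (1 + (K/N0 - 1) e^{-rt}).
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refugia.model import (
    ModelParams,
    UndefinedEquilibriumError,
    VariantParams,
    classify_outcome,
    critical_nutrient,
    eigenvalue_extinct,
    eigenvalue_interior,
    equilibrium_report,
    growth_rate,
    integrate_ode,
    interior_equilibrium,
    mixing_effect,
    phase_diagram,
    variant_growth_rate,
    variant_persistence_threshold,
)

rates = st.floats(0.0, 5.0, allow_nan=False)
capacities = st.floats(0.1, 100.0, allow_nan=False)


def logistic_solution(params, n0, t):
    """Closed-form oracle, independent of the numerical integrator."""
    r = params.R + params.mu - params.s * (1.0 + params.mu)
    K = params.q * r / (params.R + params.mu)
    with np.errstate(over="ignore"):
        return K / (1.0 + (K / n0 - 1.0) * np.exp(-r * np.asarray(t)))


def random_params(rng, lambda_min=0.05):
    """Draw parameters with the low-density eigenvalue away from zero."""
    while True:
        p = ModelParams(
            R=rng.uniform(0.05, 3.0),
            s=rng.uniform(0.0, 2.0),
            mu=rng.uniform(0.0, 1.5),
            q=rng.uniform(0.5, 50.0),
        )
        if abs(eigenvalue_extinct(p)) >= lambda_min:
            return p


class TestGrowthRate:
    @pytest.mark.parametrize(
        "params,N,expected",
        [
            (ModelParams(R=1.3, s=0.7, mu=0.4, q=3.0), 0.0, 0.0),
            # N at the interior equilibrium q(R-s)/R = 5: bracket vanishes
            (ModelParams(R=2, s=1, mu=0, q=10), 5.0, 0.0),
            # direct substitution: 2 * [2 * (1 - 0.5) - 2] = -2
            (ModelParams(R=1, s=1, mu=1, q=4), 2.0, -2.0),
        ],
    )
    def test_examples(self, params, N, expected):
        assert growth_rate(params, N) == pytest.approx(expected, abs=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(ModelParams(R=1, s=0, q=1), -0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(R=-1, s=0, q=1)
        with pytest.raises(ValueError):
            ModelParams(R=1, s=0, q=0)
        with pytest.raises(ValueError):
            ModelParams(R=float("nan"), s=0, q=1)


class TestEquilibria:
    @pytest.mark.parametrize(
        "params,expected",
        [
            (ModelParams(R=1.7, s=0.0, mu=0.0, q=7.5), 7.5),  # stressor-free
            (ModelParams(R=2, s=1, mu=1, q=10), 10.0 / 3.0),
            (ModelParams(R=1, s=1, mu=1, q=5), 0.0),  # boundary case
        ],
    )
    def test_interior_equilibrium(self, params, expected):
        assert interior_equilibrium(params) == pytest.approx(expected)

    def test_undefined_when_no_growth_terms(self):
        with pytest.raises(UndefinedEquilibriumError):
            interior_equilibrium(ModelParams(R=0, s=1, mu=0, q=1))

    @pytest.mark.parametrize(
        "params,expected",
        [
            (ModelParams(R=1.9, s=0, mu=0, q=1), 1.9),
            (ModelParams(R=1, s=1, mu=1, q=1), 0.0),
            (ModelParams(R=0.25, s=0.5, mu=1, q=1), 0.25),
        ],
    )
    def test_eigenvalue_extinct(self, params, expected):
        assert eigenvalue_extinct(params) == pytest.approx(expected)

    @given(R=rates, s=rates, mu=rates, q=capacities)
    def test_eigenvalues_are_exact_negations(self, R, s, mu, q):
        p = ModelParams(R=R, s=s, mu=mu, q=q)
        assert eigenvalue_interior(p) == -eigenvalue_extinct(p)

    def test_growth_rate_vanishes_at_equilibrium(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = random_params(rng)
            n_star = interior_equilibrium(p)
            if n_star > 0:
                assert growth_rate(p, n_star) == pytest.approx(0.0, abs=1e-12 * p.q)

    def test_report_states_are_mutually_exclusive(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            rep = equilibrium_report(random_params(rng))
            if rep.stable_state == "persistence":
                assert rep.lambda_extinct > 0 and rep.N_star > 0
            else:
                assert rep.lambda_extinct <= 0


class TestBoundary:
    @pytest.mark.parametrize(
        "s,mu,expected",
        [(0.8, 0.0, 0.8), (2.0, 1.0, 3.0), (0.5, 1.0, 0.0)],
    )
    def test_critical_nutrient(self, s, mu, expected):
        assert critical_nutrient(s, mu) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "params,expected",
        [
            (ModelParams(R=2, s=1, mu=0, q=10), "persist"),
            (ModelParams(R=1, s=1, mu=1, q=10), "extinct"),  # boundary
            (ModelParams(R=0.25, s=0.5, mu=0, q=10), "extinct"),
        ],
    )
    def test_classify_outcome(self, params, expected):
        assert classify_outcome(params) == expected

    @pytest.mark.parametrize(
        "R,s,expected",
        [
            (0.25, 0.5, "rescued_by_mixing"),
            (2.5, 2.0, "extinguished_by_mixing"),
            (1.0, 0.0, "persist_both"),
            (0.1, 2.0, "extinct_both"),
        ],
    )
    def test_mixing_effect(self, R, s, expected):
        assert mixing_effect(R, s) == expected

    def test_classification_consistent_with_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            R, s, mu = rng.uniform(0, 3, 3)
            p = ModelParams(R=R, s=s, mu=mu, q=1.0)
            persists = classify_outcome(p) == "persist"
            assert persists == (R > critical_nutrient(s, mu))


class TestIntegrator:
    def test_zero_start_stays_zero(self):
        traj = integrate_ode(ModelParams(R=2, s=0.5, mu=1, q=10), 0.0, 20.0)
        assert np.all(traj.N == 0.0)

    def test_matches_logistic_oracle_at_reference_point(self):
        p = ModelParams(R=2, s=1, mu=1, q=10)
        t = np.linspace(0, 30, 40)
        traj = integrate_ode(p, 0.1, 30.0, t_eval=t)
        expected = logistic_solution(p, 0.1, t)
        assert np.max(np.abs(traj.N - expected) / expected) < 1e-6

    def test_decays_to_extinction_when_unstable(self):
        p = ModelParams(R=0.1, s=2, mu=1, q=10)
        traj = integrate_ode(p, 5.0, 50.0)
        assert traj.final < 1e-6 * p.q

    def test_oracle_agreement_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = random_params(rng)
            n0 = p.q * 10 ** rng.uniform(-3, -0.5)
            r = eigenvalue_extinct(p)
            t_end = min(10.0 / abs(r), 100.0)
            t = np.linspace(0, t_end, 15)[1:]
            traj = integrate_ode(p, n0, t_end, t_eval=t)
            expected = logistic_solution(p, n0, t)
            scale = np.maximum(np.abs(expected), 1e-9 * p.q)
            assert np.max(np.abs(traj.N - expected) / scale) < 1e-6

    def test_classification_predicts_long_run_fate(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = random_params(rng)
            r = eigenvalue_extinct(p)
            traj = integrate_ode(p, p.q * 1e-3, 30.0 / abs(r))
            if classify_outcome(p) == "persist":
                assert traj.final == pytest.approx(
                    interior_equilibrium(p), rel=1e-2
                )
            else:
                assert traj.final < 1e-2 * p.q * 1e-3

    def test_invalid_inputs(self):
        p = ModelParams(R=1, s=0, q=1)
        with pytest.raises(ValueError):
            integrate_ode(p, -1.0, 1.0)
        with pytest.raises(ValueError):
            integrate_ode(p, 1.0, 0.0)


class TestPhaseDiagram:
    def test_no_stressor_row_all_persist(self):
        d = phase_diagram([0.5, 1.0, 2.0], [0.0])
        assert (d.region == "persist_both").all()

    def test_partition_matches_threshold_algebra(self):
        axis = np.linspace(0.0, 3.0, 60)
        d = phase_diagram(axis, axis)
        rr, ss = np.meshgrid(axis, axis, indexing="ij")
        rescued = d.region == "rescued_by_mixing"
        extinguished = d.region == "extinguished_by_mixing"
        # mixing with (0, 1) rescues only below s = 1, extinguishes only above
        assert np.all(ss[rescued] < 1.0)
        assert np.all(ss[extinguished] > 1.0)
        # boundaries are the lines R = s (static) and R = 2s - 1 (mixed)
        assert np.array_equal(rescued, (rr <= ss) & (rr + 1 > 2 * ss))
        assert np.array_equal(extinguished, (rr > ss) & (rr + 1 <= 2 * ss))

    def test_labels_are_exclusive_and_complete(self):
        d = phase_diagram(np.linspace(0, 2, 20), np.linspace(0, 2, 20))
        assert set(np.unique(d.region)) <= {
            "persist_both", "extinct_both",
            "rescued_by_mixing", "extinguished_by_mixing",
        }

    def test_tidy_frame_round_trip(self):
        d = phase_diagram([0.0, 1.0], [0.0, 1.0])
        frame = d.to_frame()
        assert len(frame) == 4
        assert set(frame.columns) == {"R", "s", "region"}

    def test_bad_axes_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram([], [0.0])
        with pytest.raises(ValueError):
            phase_diagram([1.0, 0.5], [0.0])
        with pytest.raises(ValueError):
            phase_diagram([-1.0, 0.5], [0.0])


class TestVariants:
    def test_baseline_reduces_to_model(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = random_params(rng)
            vp = VariantParams("baseline", p)
            n = rng.uniform(0, p.q)
            assert variant_growth_rate(vp, n) == growth_rate(p, n)

    def test_extinction_is_fixed_point_for_all_variants(self):
        p = ModelParams(R=1.5, s=0.5, mu=0.5, q=2.0)
        for v in ("baseline", "capacity_mixing", "growth_stressor"):
            assert variant_growth_rate(VariantParams(v, p), 0.0) == 0.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            VariantParams("spatial", ModelParams(R=1, s=0, q=1))

    @pytest.mark.parametrize(
        "variant,extra",
        [
            ("baseline", {}),
            ("capacity_mixing", {}),
            ("growth_stressor", {"delta": 0.5}),
        ],
    )
    def test_threshold_unique_and_growth_monotone(self, variant, extra):
        R, mu, q = 2.0, 1.0, 1.0
        s_star = variant_persistence_threshold(variant, R, mu, q, extra)
        eps = 1e-9
        lam = lambda s: variant_growth_rate(
            VariantParams(variant, ModelParams(R=R, s=s, mu=mu, q=q), extra), eps
        ) / eps
        # single sign change: positive strictly below, negative strictly above
        for frac in (0.2, 0.5, 0.9):
            assert lam(s_star * frac) > 0
        for s in (s_star * 1.1, s_star * 2, s_star * 5):
            assert lam(s) < 0

    def test_baseline_threshold_matches_closed_form(self):
        # boundary R = mu(s-1)+s inverted: s* = (R + mu)/(1 + mu)
        s_star = variant_persistence_threshold("baseline", 2.0, 1.0)
        # bisection evaluates the rate at N = 1e-9 q, shifting the root O(1e-9)
        assert s_star == pytest.approx(1.5, abs=1e-7)

    def test_growth_stressor_without_turnover_never_goes_extinct(self):
        with pytest.raises(ValueError):
            variant_persistence_threshold("growth_stressor", 2.0, 1.0, extra={})
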