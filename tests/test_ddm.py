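import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from coged.cohort import exp3_spec, generate_agents
from coged.ddm import (
    DDMParams,
    HierarchicalDDM,
    choice_probability_closed_form,
    compare_dic,
    compute_dic,
    compute_rhat,
    generate_choice_rt_table,
    mean_decision_time_closed_form,
    simulate_wiener,
    wfpt_logdensity,
)


def signed_rt_ks(sim, params, t_max=60.0, n_grid=12000):
    """KS distance between simulated (boundary, rt) pairs and the
    density-implied distribution of signed RTs (lower-boundary passages
    negated), using every simulated trial."""
    grid = np.linspace(1e-4, t_max, n_grid)
    dt = grid[1] - grid[0]
    cdf_up = np.cumsum(np.exp(wfpt_logdensity(grid, "effortful", params))) * dt
    cdf_dn = np.cumsum(np.exp(wfpt_logdensity(grid, "effortless", params))) * dt
    p_dn = cdf_dn[-1]
    signed = np.where(
        sim.boundary.to_numpy() == "effortful", sim.rt.to_numpy(), -sim.rt.to_numpy()
    )
    signed = np.sort(signed)
    # F(x) = p_dn - CDF_dn(-x) for x < 0, p_dn + CDF_up(x) for x >= 0
    theo = np.where(
        signed < 0,
        p_dn - np.interp(-signed, grid, cdf_dn),
        p_dn + np.interp(signed, grid, cdf_up),
    )
    total = p_dn + cdf_up[-1]
    emp = np.arange(1, signed.size + 1) / signed.size
    return float(np.abs(emp - theo / total).max())


class TestSimulator:
    def test_symmetric_null_is_unbiased(self):
        p = DDMParams(v=0.0, a=1.5, z=0.5)
        sim = simulate_wiener(p, 6000, np.random.default_rng(1))
        frac = (sim.boundary == "effortful").mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 6000)

    def test_choice_probability_matches_logistic_form(self):
        """For z = 1/2 the absorption probability is 1/(1+exp(-v a))."""
        p = DDMParams(v=0.5, a=2.0, z=0.5)
        target = 1 / (1 + np.exp(-1.0))
        assert choice_probability_closed_form(p) == pytest.approx(target, abs=1e-12)
        sim = simulate_wiener(p, 6000, np.random.default_rng(2))
        frac = (sim.boundary == "effortful").mean()
        assert abs(frac - target) < 3 * np.sqrt(target * (1 - target) / 6000)

    def test_mean_decision_time_matches_tanh_form(self):
        p = DDMParams(v=0.5, a=2.0, z=0.5, t0=0.0)
        target = (p.a / (2 * p.v)) * np.tanh(p.v * p.a / 2)
        assert mean_decision_time_closed_form(p) == pytest.approx(target, abs=1e-12)
        sim = simulate_wiener(p, 6000, np.random.default_rng(3))
        se = sim.rt.std() / np.sqrt(len(sim))
        assert abs(sim.rt.mean() - target) < 3 * se

    def test_t0_shifts_rt(self):
        p = DDMParams(v=1.0, a=1.0, z=0.5, t0=0.3)
        sim = simulate_wiener(p, 500, np.random.default_rng(4))
        assert sim.rt.min() > 0.3

    def test_coarse_dt_triggers_refinement_warning(self):
        p = DDMParams(v=0.0, a=0.2, z=0.5)
        with pytest.warns(UserWarning, match="refin"):
            sim = simulate_wiener(p, 50, np.random.default_rng(5), dt=1e-3)
        assert len(sim) == 50

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(v=0.1, a=-1.0)
        with pytest.raises(ValueError):
            DDMParams(v=0.1, a=1.0, z=1.2)
        with pytest.raises(ValueError):
            DDMParams(v=0.1, a=1.0, t0=-0.1)


class TestDensity:
    @pytest.mark.parametrize("v,a,z", [(0.5, 2.0, 0.5), (-0.8, 1.2, 0.3), (0.0, 1.0, 0.6)])
    def test_integral_equals_absorption_probability(self, v, a, z):
        p = DDMParams(v=v, a=a, z=z)
        p_up = choice_probability_closed_form(p)
        for bnd, target in (("effortful", p_up), ("effortless", 1 - p_up)):
            val, _ = integrate.quad(
                lambda t: np.exp(wfpt_logdensity(t, bnd, p)), 1e-9, 200, limit=300
            )
            assert val == pytest.approx(target, abs=1e-4)

    def test_reflection_symmetry(self):
        rts = np.linspace(0.05, 5.0, 40)
        p = DDMParams(v=0.7, a=1.6, z=0.35)
        p_ref = DDMParams(v=-0.7, a=1.6, z=0.65)
        np.testing.assert_allclose(
            wfpt_logdensity(rts, "effortful", p),
            wfpt_logdensity(rts, "effortless", p_ref),
            rtol=1e-9,
        )

    def test_rt_before_t0_has_zero_density(self):
        p = DDMParams(v=0.5, a=1.0, z=0.5, t0=0.4)
        assert wfpt_logdensity(0.3, "effortful", p) == -np.inf

    def test_simulator_density_consistency_grid(self):
        """KS distance between simulated first passages and the
        density-implied joint (boundary, rt) distribution stays below
        0.02 across a (v, a, z) grid at n = 10,000.  Both boundaries
        enter one statistic through the signed-RT representation
        (effortless passages count negative)."""
        rng = np.random.default_rng(10)
        for v in (-0.5, 0.0, 0.5):
            for a in (1.0, 1.5, 2.0):
                for z in (0.4, 0.5):
                    p = DDMParams(v=v, a=a, z=z)
                    sim = simulate_wiener(p, 10000, rng)
                    ks = signed_rt_ks(sim, p)
                    assert ks < 0.02, (v, a, z, ks)


class TestRhat:
    def test_identical_distribution_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000).reshape(4, 1000)
        assert compute_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 5.0
        assert compute_rhat(np.stack([a, b])) > 1.5

    def test_never_below_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.standard_normal((3, 60))
            assert compute_rhat(x) >= 1.0 - 1e-9

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 500)) + rng.standard_normal((4, 1))
        ours = compute_rhat(x)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(x[:, :, None]))["x"]).ravel()[0])
        # arviz rank-normalizes; agreement is approximate but close
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_degenerate_chains_rejected(self):
        with pytest.raises(ValueError):
            compute_rhat(np.ones((2, 100)))


class TestDic:
    def _toy_posterior(self, n=40, sigma=1.0, tau=100.0, n_draws=40000, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.normal(0.3, sigma, n)
        post_var = 1.0 / (n / sigma**2 + 1.0 / tau**2)
        post_mean = post_var * y.sum() / sigma**2
        theta = rng.normal(post_mean, np.sqrt(post_var), n_draws)

        def deviance(th, data=y):
            th = np.atleast_1d(th)[:, None]
            ll = stats.norm.logpdf(data[None, :], th, sigma).sum(axis=1)
            return -2 * ll

        return y, theta, deviance, n * post_var / sigma**2

    def test_pd_matches_conjugate_effective_parameters(self):
        """Normal-mean model with a flat prior: pD is the effective
        number of parameters, here n * Var_post / sigma^2 ~ 1."""
        _, theta, deviance, expected_pd = self._toy_posterior()
        dic, p_d, dbar = compute_dic(deviance(theta), float(deviance(theta.mean())[0]))
        assert p_d == pytest.approx(expected_pd, rel=0.05)
        assert dic == pytest.approx(dbar + p_d)

    def test_deviance_additivity_on_duplicated_data(self):
        y, theta, deviance, _ = self._toy_posterior(n_draws=2000)
        d1 = deviance(theta)
        d2 = deviance(theta, np.concatenate([y, y]))
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)

    def test_nonfinite_deviance_rejected(self):
        with pytest.raises(ValueError):
            compute_dic([1.0, np.inf], 1.0)

    def test_compare_flags_substantial_difference(self):
        out = compare_dic(100.0, 110.0)
        assert out["substantial"] and out["preferred"] == "a"
        assert not compare_dic(100.0, 103.0)["substantial"]


@pytest.fixture(scope="module")
def small_fit():
    spec = exp3_spec(n_per_group=6, seed=5)
    agents = generate_agents(spec)
    table = generate_choice_rt_table(
        agents, spec, np.random.default_rng(6), n_trials_per_cell=20
    )
    fit = HierarchicalDDM(n_chains=2, n_iter=500, burn_in=100, seed=7).fit(table)
    return spec, table, fit


class TestHierarchicalFit:

    def test_posterior_shapes_and_diagnostics(self, small_fit):
        _, _, fit = small_fit
        assert all(arr.shape == (2, 400) for arr in fit.posterior_.values())
        assert set(fit.group_drift_["group"]) == {"depressed", "nondepressed"}
        assert len(fit.group_drift_) == 12
        d = fit.diagnostics_
        assert d.dic == pytest.approx(d.mean_deviance + d.p_d)
        assert all(r >= 1.0 - 1e-6 for r in d.rhat.values())

    def test_identical_seed_identical_draws(self, small_fit):
        spec, table, fit = small_fit
        refit = HierarchicalDDM(n_chains=2, n_iter=500, burn_in=100, seed=7).fit(table)
        for p in fit.posterior_:
            np.testing.assert_array_equal(fit.posterior_[p], refit.posterior_[p])

    def test_group_separation_recovered(self, small_fit):
        """Nondepressed drift exceeds depressed drift at the lowest load
        (generating gap ~0.66) even in a small fit."""
        _, _, fit = small_fit
        gd = fit.group_drift_.set_index(["group", "effort_level"])["mean"]
        assert gd["nondepressed", "1-back"] > gd["depressed", "1-back"]

    def test_true_model_beats_drift_constant_by_dic(self, small_fit):
        """Data generated with drift varying by group x effort prefer
        the cell-drift model over a single-drift model by more than the
        substantial-improvement margin."""
        _, table, fit = small_fit
        flat = HierarchicalDDM(
            drift_by=("group",), n_chains=2, n_iter=500, burn_in=100, seed=8
        ).fit(table)
        out = compare_dic(fit.diagnostics_.dic, flat.diagnostics_.dic)
        assert out["preferred"] == "a"
        assert out["delta_dic"] > 5

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            HierarchicalDDM().fit(pd.DataFrame({"subject_id": [1], "rt_s": [0.5]}))
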