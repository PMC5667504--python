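import numpy as np
import pytest
import scipy.stats

from quadnb import (
    GroupNBParams,
    LocalGammaSurface,
    MeripDataset,
    NormalizationFactors,
    QNBConfig,
    SimulationConfig,
    VarianceModel,
    compute_estimates,
    estimate_size_factors,
    fit_variance_model,
    group_nb_params,
    joint_conditional_probability,
    nb_pmf,
    odds_ratio,
    qnb_pvalue,
    risk_ratio,
    run_qnb,
    simulate,
)
from quadnb.estimation import BLIND
from quadnb.simulate import sample_nb


def scipy_pmf(k, mean, variance):
    """Independent NB/Poisson mass via scipy.stats distributions."""
    if mean <= 0:
        return 1.0 if k == 0 else 0.0
    if k < 0:
        return 0.0
    if variance <= mean:
        return float(scipy.stats.poisson.pmf(k, mean))
    r = mean**2 / (variance - mean)
    return float(scipy.stats.nbinom.pmf(k, r, mean / variance))


def brute_force_pvalue(params):
    """Exhaustive enumeration oracle built on scipy.stats only."""
    lo, hi = params.support()
    probs = []
    for t in range(lo, hi + 1):
        probs.append(
            scipy_pmf(t, params.mu[("ip", "A")], params.var[("ip", "A")])
            * scipy_pmf(params.t_total - t, params.mu[("ip", "B")],
                        params.var[("ip", "B")])
            * scipy_pmf(params.n_a - t, params.mu[("input", "A")],
                        params.var[("input", "A")])
            * scipy_pmf(params.n_b - params.t_total + t, params.mu[("input", "B")],
                        params.var[("input", "B")])
        )
    probs = np.array(probs)
    total = probs.sum()
    if total == 0:
        return 1.0
    p_obs = probs[params.t_a - lo]
    return float(probs[probs <= p_obs * (1 + 1e-8)].sum() / total)


def random_small_params(rng):
    """A random feature with t_i <= 50 and loosely matched NB parameters."""
    t_a, t_b = rng.integers(0, 26, size=2)
    c_a, c_b = rng.integers(0, 26, size=2)
    if t_a + t_b == 0:
        t_a = 1
    mu, var = {}, {}
    for key, obs in ((("ip", "A"), t_a), (("ip", "B"), t_b),
                     (("input", "A"), c_a), (("input", "B"), c_b)):
        m = max(obs, 1) * rng.uniform(0.5, 2.0)
        mu[key] = m
        var[key] = m * rng.uniform(1.0, 4.0)
    return GroupNBParams(mu=mu, var=var, t_a=int(t_a), t_b=int(t_b),
                         c_a=int(c_a), c_b=int(c_b))


class TestNBPmf:
    def test_poisson_limit(self):
        for mu in (0.5, 4.0, 20.0):
            assert nb_pmf(0, mu, mu) == pytest.approx(np.exp(-mu), rel=1e-12)
            ks = np.arange(0, 50)
            np.testing.assert_allclose(
                nb_pmf(ks, mu, mu), scipy.stats.poisson.pmf(ks, mu), rtol=1e-10
            )

    def test_normalization(self):
        mean, var = 10.0, 30.0
        kmax = int(mean + 50 * np.sqrt(var))
        total = nb_pmf(np.arange(kmax + 1), mean, var).sum()
        assert abs(total - 1.0) < 1e-12

    def test_moment_recovery_by_summation(self):
        mean, var = 10.0, 30.0
        ks = np.arange(0, 2000)
        pmf = nb_pmf(ks, mean, var)
        m1 = (ks * pmf).sum()
        m2 = (ks**2 * pmf).sum()
        assert m1 == pytest.approx(mean, abs=1e-8)
        assert m2 - m1**2 == pytest.approx(var, abs=1e-8)

    def test_negative_count_gets_zero_mass(self):
        assert nb_pmf(-1, 10.0, 30.0) == 0.0

    def test_matches_scipy_parameterization(self):
        ks = np.arange(0, 100)
        np.testing.assert_allclose(
            nb_pmf(ks, 12.0, 40.0),
            [scipy_pmf(k, 12.0, 40.0) for k in ks],
            rtol=1e-10,
        )


class TestJointConditionalProbability:
    def _params(self):
        mu = {("ip", "A"): 3.0, ("ip", "B"): 3.0,
              ("input", "A"): 2.0, ("input", "B"): 2.0}
        var = {k: v * 2 for k, v in mu.items()}
        return GroupNBParams(mu=mu, var=var, t_a=4, t_b=2, c_a=1, c_b=3)

    def test_zero_outside_support(self):
        params = self._params()
        lo, hi = params.support()
        assert joint_conditional_probability(params, lo - 1) == 0.0
        assert joint_conditional_probability(params, hi + 1) == 0.0

    def test_matches_four_pmf_product_oracle(self):
        params = self._params()
        lo, hi = params.support()
        assert (lo, hi) == (1, 5)  # t_i=6, n_A=n_B=5
        for t in range(lo, hi + 1):
            direct = (
                scipy_pmf(t, 3.0, 6.0) * scipy_pmf(6 - t, 3.0, 6.0)
                * scipy_pmf(5 - t, 2.0, 4.0) * scipy_pmf(t - 1, 2.0, 4.0)
            )
            assert joint_conditional_probability(params, t) == pytest.approx(
                direct, rel=1e-12
            )

    def test_symmetry_with_identical_groups(self):
        params = self._params()  # A and B params identical, n_A == n_B
        ti = params.t_total
        for t in range(*params.support()):
            assert joint_conditional_probability(params, t) == pytest.approx(
                joint_conditional_probability(params, ti - t), rel=1e-12
            )


class TestPvalue:
    def test_equals_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            params = random_small_params(rng)
            assert qnb_pvalue(params) == pytest.approx(
                brute_force_pvalue(params), abs=1e-10
            )

    def test_observed_at_mode_gives_one(self):
        # balanced observation at the conditional mode: every other split is
        # no more likely, so the whole mass is summed
        mu = {("ip", "A"): 10.0, ("ip", "B"): 10.0,
              ("input", "A"): 10.0, ("input", "B"): 10.0}
        var = {k: 15.0 for k in mu}
        params = GroupNBParams(mu=mu, var=var, t_a=10, t_b=10, c_a=10, c_b=10)
        probs = joint_conditional_probability(
            params, np.arange(*[s + o for s, o in zip(params.support(), (0, 1))])
        )
        assert np.argmax(probs) + params.support()[0] == params.t_a
        assert qnb_pvalue(params) == pytest.approx(1.0)

    def test_observed_at_unique_minimum(self):
        # grossly unbalanced observation: the observed split is the least
        # likely one, so p = P(t_obs) / sum P(t)
        mu = {("ip", "A"): 5.0, ("ip", "B"): 5.0,
              ("input", "A"): 5.0, ("input", "B"): 5.0}
        var = {k: 8.0 for k in mu}
        params = GroupNBParams(mu=mu, var=var, t_a=10, t_b=0, c_a=0, c_b=14)
        lo, hi = params.support()
        probs = joint_conditional_probability(params, np.arange(lo, hi + 1))
        i_obs = params.t_a - lo
        others = np.delete(probs, i_obs)
        assert np.all(probs[i_obs] < others * (1 - 1e-10))  # unique minimum
        assert qnb_pvalue(params) == pytest.approx(
            probs[i_obs] / probs.sum(), rel=1e-10
        )


class TestEffectSizes:
    def test_identical_conditions_give_unit_ratios(self):
        ds = MeripDataset(("f",), np.array([[4, 4]]), np.array([[6, 6]]),
                          ("A", "B"))
        f = NormalizationFactors(np.ones(2), np.ones(2))
        assert risk_ratio(ds, f, 0) == pytest.approx(1.0)
        assert odds_ratio(ds, f, 0) == pytest.approx(1.0)

    def test_risk_ratio_arithmetic(self):
        # p_A = 0.6, p_B = 0.3 -> RR = 2
        ds = MeripDataset(("f",), np.array([[6, 3]]), np.array([[4, 7]]),
                          ("A", "B"))
        f = NormalizationFactors(np.ones(2), np.ones(2))
        assert risk_ratio(ds, f, 0) == pytest.approx(2.0)

    def test_odds_ratio_arithmetic(self):
        # A: t=4, c=1; B: t=1, c=4 -> OR = (4/1)/(1/4) = 16
        ds = MeripDataset(("f",), np.array([[4, 1]]), np.array([[1, 4]]),
                          ("A", "B"))
        f = NormalizationFactors(np.ones(2), np.ones(2))
        assert odds_ratio(ds, f, 0) == pytest.approx(16.0)

    def test_zero_control_rate_is_missing(self):
        ds = MeripDataset(("f",), np.array([[4, 0]]), np.array([[1, 4]]),
                          ("A", "B"))
        f = NormalizationFactors(np.ones(2), np.ones(2))
        assert np.isnan(risk_ratio(ds, f, 0))
        assert np.isnan(odds_ratio(ds, f, 0))

    def test_match_direct_formula_on_simulation(self, sim_seed7,
                                                sim_seed7_factors):
        dataset, _ = sim_seed7
        f = sim_seed7_factors
        rr = risk_ratio(dataset, f)
        or_ = odds_ratio(dataset, f)
        ia = dataset.replicates_of("A")
        ib = dataset.replicates_of("B")
        for i in range(0, dataset.n_features, 149):
            ta = sum(dataset.ip_counts[i, j] / f.s_ip[j] for j in ia)
            ca = sum(dataset.input_counts[i, j] / f.s_input[j] for j in ia)
            tb = sum(dataset.ip_counts[i, j] / f.s_ip[j] for j in ib)
            cb = sum(dataset.input_counts[i, j] / f.s_input[j] for j in ib)
            pa, pb = ta / (ta + ca), tb / (tb + cb)
            if pb > 0:
                assert rr[i] == pytest.approx(pa / pb, abs=1e-10)
            if min(ta, ca, tb, cb) > 0:
                assert or_[i] == pytest.approx((ta / ca) / (tb / cb), abs=1e-10)


class TestGroupParams:
    def test_match_direct_formula(self, sim_seed7, sim_seed7_factors):
        from quadnb import raw_variance

        dataset, _ = sim_seed7
        f = sim_seed7_factors
        est = compute_estimates(dataset, f, "auto")
        model = fit_variance_model(est, "auto")
        rng = np.random.default_rng(13)
        for i in rng.integers(0, dataset.n_features, 10):
            gp = group_nb_params(dataset, f, est, model, int(i))
            p_o = est.p_hat["pooled"][i]
            for label, cond in (("A", "A"), ("B", "B")):
                idx = dataset.replicates_of(cond)
                e = est.e_hat[cond][i]
                for stype, s in (("ip", f.s_ip), ("input", f.s_input)):
                    rate = p_o if stype == "ip" else 1 - p_o
                    mu_direct = rate * est.q_hat[i] * e * s[idx].sum()
                    v = raw_variance(model, est, cond, stype, p_o)[i]
                    var_direct = mu_direct + v * e**2 * (s[idx] ** 2).sum()
                    assert gp.mu[(stype, label)] == pytest.approx(mu_direct,
                                                                  rel=1e-10)
                    assert gp.var[(stype, label)] == pytest.approx(var_direct,
                                                                   rel=1e-10)

    def test_zero_variance_surface_gives_poisson_limit(self, sim_seed7,
                                                       sim_seed7_factors):
        # with the variance surface pinned (numerically) at zero, w - z
        # clamps to 0 and the null variance collapses to the mean
        dataset, _ = sim_seed7
        f = sim_seed7_factors
        est = compute_estimates(dataset, f, "auto")
        flat = LocalGammaSurface(p_grid=np.array([0.0, 1.0]),
                                 u_grid=np.array([-5.0, 20.0]),
                                 log_w=np.full((2, 2), -46.0),
                                 n_points=0, span=0.7)
        model = VarianceModel(
            mode="per-condition", resolved_mode="per-condition",
            surfaces={(st, c): flat for st in ("ip", "input")
                      for c in ("A", "B")},
            z_group_of={"A": "A", "B": "B"},
        )
        gp = group_nb_params(dataset, f, est, model, 3)
        for key in gp.mu:
            assert gp.var[key] == pytest.approx(gp.mu[key], rel=1e-9)

    def test_doubling_size_factors_doubles_means(self, sim_seed7):
        dataset, _ = sim_seed7
        f1 = NormalizationFactors(np.ones(dataset.n_replicates),
                                  np.ones(dataset.n_replicates))
        f2 = NormalizationFactors(2 * np.ones(dataset.n_replicates),
                                  2 * np.ones(dataset.n_replicates))
        est1 = compute_estimates(dataset, f1, "auto")
        est2 = compute_estimates(dataset, f2, "auto")
        m1 = fit_variance_model(est1, "auto")
        m2 = fit_variance_model(est2, "auto")
        g1 = group_nb_params(dataset, f1, est1, m1, 5)
        g2 = group_nb_params(dataset, f2, est2, m2, 5)
        for key in g1.mu:
            # factors are relative: doubling both vectors halves q_hat and
            # doubles sum(s), leaving every null mean exactly unchanged
            assert g2.mu[key] == pytest.approx(g1.mu[key], rel=1e-9)


class TestRunQnb:
    def test_result_contract(self):
        dataset, truth = simulate(SimulationConfig(n_features=400, seed=21))
        res = run_qnb(dataset)
        assert len(res) == 400
        assert list(res["feature_id"]) == list(dataset.feature_ids)
        tested = res["status"] == "tested"
        assert tested.sum() > 300
        p = res.loc[tested, "p_value"]
        assert ((p >= 0) & (p <= 1)).all()
        padj = res.loc[tested, "p_adjusted"]
        assert (padj >= p - 1e-12).all()

    def test_batch_path_matches_per_feature_path(self):
        dataset, _ = simulate(SimulationConfig(n_features=300, seed=22))
        factors = estimate_size_factors(dataset)
        est = compute_estimates(dataset, factors, "auto")
        model = fit_variance_model(est, "auto")
        res = run_qnb(dataset)
        for i in (0, 17, 100, 250):
            gp = group_nb_params(dataset, factors, est, model, i)
            if gp.t_total == 0:
                continue
            assert res["p_value"][i] == pytest.approx(qnb_pvalue(gp), abs=1e-9)

    def test_row_permutation_permutes_results(self):
        dataset, _ = simulate(SimulationConfig(n_features=300, seed=23))
        perm = np.random.default_rng(0).permutation(300)
        res1 = run_qnb(dataset)
        res2 = run_qnb(dataset.subset(perm))
        np.testing.assert_allclose(
            res1["p_value"].to_numpy()[perm], res2["p_value"].to_numpy(),
            rtol=1e-9, equal_nan=True,
        )

    def test_label_swap_preserves_pvalues_inverts_ratios(self):
        # exchanging the labels while keeping "B" as the control means the
        # two conditions trade treated/control roles
        dataset, _ = simulate(SimulationConfig(n_features=400, seed=24))
        swapped = dataset.with_conditions(
            ["B" if c == "A" else "A" for c in dataset.conditions]
        )
        res1 = run_qnb(dataset)
        res2 = run_qnb(swapped, QNBConfig(control="B"))
        np.testing.assert_allclose(res1["p_value"], res2["p_value"],
                                   rtol=1e-9, equal_nan=True)
        ok = (~res1["rr"].isna()) & (res1["rr"] > 0)
        np.testing.assert_allclose(res2.loc[ok, "rr"], 1 / res1.loc[ok, "rr"],
                                   rtol=1e-9)
        ok = (~res1["or_"].isna()) & (res1["or_"] > 0)
        np.testing.assert_allclose(res2.loc[ok, "or_"], 1 / res1.loc[ok, "or_"],
                                   rtol=1e-9)

    def test_mean_pvalue_decreases_with_effect_size(self):
        """Fixed abundance and dispersion: larger |p_A - p_B| means smaller
        p-values on average."""
        rng = np.random.default_rng(31)
        mean_p = []
        for delta in (0.0, 0.1, 0.2, 0.3):
            n, reps = 500, 3
            q = np.exp(rng.uniform(np.log(100), np.log(2000), n))
            # random shift direction per feature so the global IP/input
            # composition stays balanced and size factors stay honest
            sign = rng.choice([-1.0, 1.0], n)
            pa = 0.5 - sign * delta / 2
            pb = 0.5 + sign * delta / 2
            ip = np.empty((n, 2 * reps), dtype=np.int64)
            inp = np.empty((n, 2 * reps), dtype=np.int64)
            d = 1.0
            for j in range(2 * reps):
                p = pa if j < reps else pb
                mu_t, mu_c = q * p, q * (1 - p)
                ip[:, j] = sample_nb(rng, mu_t, mu_t + d)
                inp[:, j] = sample_nb(rng, mu_c, mu_c + d)
            ds = MeripDataset(tuple(f"f{i}" for i in range(n)), ip, inp,
                              ("A",) * reps + ("B",) * reps)
            res = run_qnb(ds, QNBConfig(size_factor_method="total"))
            mean_p.append(res["p_value"].mean())
        assert all(a > b for a, b in zip(mean_p, mean_p[1:]))

    def test_control_option_flips_effect_direction(self):
        dataset, _ = simulate(SimulationConfig(n_features=300, seed=25))
        res_default = run_qnb(dataset)  # control = B (second label)
        res_flipped = run_qnb(dataset, QNBConfig(control="A"))
        ok = (~res_default["rr"].isna()) & (res_default["rr"] > 0)
        np.testing.assert_allclose(
            res_flipped.loc[ok, "rr"], 1 / res_default.loc[ok, "rr"], rtol=1e-9
        )
        np.testing.assert_allclose(res_default["p_value"],
                                   res_flipped["p_value"],
                                   rtol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("mode", ["pooled", "blind"])
    def test_alternative_variance_modes_run_end_to_end(self, mode):
        dataset, truth = simulate(SimulationConfig(n_features=400, seed=27))
        res = run_qnb(dataset, QNBConfig(mode=mode))
        tested = res["status"] == "tested"
        assert tested.sum() > 300
        assert res.loc[tested, "p_value"].between(0, 1).all()

    def test_all_zero_feature_flagged_skipped(self):
        dataset, _ = simulate(SimulationConfig(n_features=300, seed=26))
        ip = dataset.ip_counts.copy()
        inp = dataset.input_counts.copy()
        ip[7] = 0
        inp[7] = 0
        ds = MeripDataset(dataset.feature_ids, ip, inp, dataset.conditions)
        res = run_qnb(ds)
        assert res["status"][7] == "skipped-zero"
        assert np.isnan(res["p_value"][7])
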