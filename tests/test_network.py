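"""Master-equation network model: rates, steady states, mutants, fitting."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from wormdecode.config import Genotype, OptimizerSettings
from wormdecode import network as nw
from wormdecode import synthetic as syn


def _random_matrix(rng, span=1.5):
    return nw.RegulatoryMatrix(np.exp(rng.uniform(-span, span, (3, 3))))


class TestRateMatrix:
    def test_all_ones_network_has_unit_rates_everywhere(self):
        W = nw.build_rate_matrix(nw.RegulatoryMatrix.ones())
        assert set(np.unique(W[W > 0])) == {1.0}
        # 24 single-flip transitions on the 3-cube
        assert (W > 0).sum() == 24

    def test_printed_entries_reproduced(self):
        """The two worked entries: the ADF OFF-switch rate out of state 2 is
        w_xx, and the ASI OFF-switch out of state 4 is w_xy * w_yy."""
        w = nw.RegulatoryMatrix(
            np.array([[1.5, 2.0, 1.1], [0.7, 3.0, 0.9], [1.3, 0.8, 2.2]])
        )
        W = nw.build_rate_matrix(w)
        assert W[0, 1] == pytest.approx(1.5)  # W12 = wxx
        assert W[1, 3] == pytest.approx(2.0 * 3.0)  # W24 = wxy wyy

    def test_full_matrix_against_bitwise_oracle(self, rng):
        """Every entry matches an independently coded rule: ON switches at
        kon, OFF switch of neuron b at w[b,b] times w[a,b] for each other
        active neuron a; anything changing != 1 neuron has rate 0."""
        w = _random_matrix(rng)
        W = nw.build_rate_matrix(w)
        bits = [(i & 1, (i >> 1) & 1, (i >> 2) & 1) for i in range(8)]
        for i in range(8):
            for j in range(8):
                diff = [n for n in range(3) if bits[i][n] != bits[j][n]]
                if len(diff) != 1 or i == j:
                    assert W[i, j] == 0.0
                    continue
                (n,) = diff
                if bits[j][n] == 1:  # j has n ON, i is the OFF state
                    expected = w.w[n, n]
                    for a in range(3):
                        if a != n and bits[j][a] == 1:
                            expected *= w.w[a, n]
                else:
                    expected = w.kon
                assert W[i, j] == pytest.approx(expected)

    def test_nonpositive_entries_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nw.RegulatoryMatrix(np.zeros((3, 3)))


class TestSteadyState:
    def test_all_ones_network_is_uniform(self):
        p = nw.steady_state(nw.build_rate_matrix(nw.RegulatoryMatrix.ones()))
        np.testing.assert_allclose(p, 1 / 8, atol=1e-12)
        np.testing.assert_allclose(nw.marginals(p), 0.5, atol=1e-12)

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_self_regulation_closed_form(self, n):
        """With all cross terms at 1 the neurons decouple and each activity
        is kon / (kon + w_nn)."""
        flat = np.ones(9)
        flat[4 * n] = 3.0  # diagonal entry of neuron n
        p = nw.steady_state(
            nw.build_rate_matrix(nw.RegulatoryMatrix.from_flat(flat))
        )
        Q = nw.marginals(p)
        expected = np.full(3, 0.5)
        expected[n] = 1.0 / (1.0 + 3.0)
        np.testing.assert_allclose(Q, expected, atol=1e-10)

    def test_agrees_with_ode_integration(self, rng):
        """The linear-solve stationary distribution matches long-time
        integration of the Master equation on random matrices."""
        for _ in range(20):
            w = _random_matrix(rng)
            W = nw.build_rate_matrix(w)
            A = nw._generator(W)
            sol = solve_ivp(
                lambda t, p: A @ p,
                (0.0, 200.0),
                np.full(8, 1 / 8),
                rtol=1e-10,
                atol=1e-12,
            )
            assert np.abs(sol.y[:, -1] - nw.steady_state(W)).max() < 1e-8

    def test_probability_simplex_and_balance(self, rng):
        for _ in range(50):
            W = nw.build_rate_matrix(_random_matrix(rng, span=2.3))
            p = nw.steady_state(W)
            assert np.all(p >= 0)
            assert abs(p.sum() - 1.0) < 1e-10
            assert np.abs(nw._generator(W) @ p).max() < 1e-10


class TestMarginals:
    def test_point_masses(self):
        p = np.zeros(8)
        p[7] = 1.0  # state 8 = (1,1,1)
        np.testing.assert_allclose(nw.marginals(p), [1, 1, 1])
        p = np.zeros(8)
        p[1] = 1.0  # state 2 = (1,0,0): only ADF active
        np.testing.assert_allclose(nw.marginals(p), [1, 0, 0])


class TestApplyMutant:
    def test_double_mutant_resets_everything(self):
        w = nw.RegulatoryMatrix(np.full((3, 3), 2.0))
        out = nw.apply_mutant(w, Genotype.double_minus)
        np.testing.assert_allclose(out.w, 1.0)

    def test_daf7_removes_asi_row_keeps_incoming(self):
        w = nw.RegulatoryMatrix.from_flat([2, 3, 4, 5, 6, 7, 8, 9, 10])
        out = nw.apply_mutant(w, Genotype.daf7_minus)
        np.testing.assert_allclose(out.flat, [2, 3, 4, 1, 1, 1, 8, 9, 10])

    def test_tph1_removes_adf_and_nsm_rows(self):
        w = nw.RegulatoryMatrix.from_flat([2, 3, 4, 5, 6, 7, 8, 9, 10])
        out = nw.apply_mutant(w, Genotype.tph1_minus)
        np.testing.assert_allclose(out.flat, [1, 1, 1, 5, 6, 7, 1, 1, 1])

    def test_wild_type_is_identity(self, rng):
        w = _random_matrix(rng)
        out = nw.apply_mutant(w, Genotype.wild_type)
        np.testing.assert_allclose(out.w, w.w)


class TestPredictedRatios:
    def test_all_ones_gives_unit_ratios(self):
        np.testing.assert_allclose(
            nw.predicted_ratios(nw.RegulatoryMatrix.ones()), 1.0, atol=1e-12
        )

    def test_double_mutant_row_is_uniform_over_wildtype(self, rng):
        w = _random_matrix(rng)
        R = nw.predicted_ratios(w)
        Qwt = nw.marginals(nw.steady_state(nw.build_rate_matrix(w)))
        np.testing.assert_allclose(R[2], 0.5 / Qwt, rtol=1e-9)

    def test_asi_self_regulation_example(self):
        w = nw.RegulatoryMatrix.from_flat([1, 1, 1, 1, 3, 1, 1, 1, 1])
        R = nw.predicted_ratios(w)
        np.testing.assert_allclose(R[0], [1.0, 2.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(R[1], 1.0, atol=1e-10)  # tph-1(-) unchanged


class TestObservedRatios:
    def _frame(self, batch_means):
        rows = []
        for b, per_geno in batch_means.items():
            for geno, mu in per_geno.items():
                for i in range(4):
                    rows.append(
                        dict(
                            batch=b,
                            genotype=geno,
                            f_nsm=mu[0],
                            f_adf=mu[1],
                            f_asi=mu[2],
                        )
                    )
        return pd.DataFrame(rows)

    def test_mutant_identical_to_wildtype_gives_unit_ratios(self):
        mu = [100.0, 150.0, 200.0]
        frame = self._frame(
            {b: {g.value: mu for g in Genotype} for b in (0, 1, 2)}
        )
        obs = nw.observed_ratios(frame)
        np.testing.assert_allclose(obs.R, 1.0)
        np.testing.assert_allclose(obs.sigma, 0.0, atol=1e-12)

    def test_two_pair_mean_and_sd(self):
        """Per-pair ratios 2.0 and 2.2 give mean 2.1 and SD 0.1414."""
        wt = [100.0, 100.0, 100.0]
        frame = self._frame(
            {
                0: {"wild_type": wt, "daf7_minus": [200.0] * 3,
                    "tph1_minus": wt, "double_minus": wt},
                1: {"wild_type": wt, "daf7_minus": [220.0] * 3,
                    "tph1_minus": wt, "double_minus": wt},
            }
        )
        obs = nw.observed_ratios(frame)
        np.testing.assert_allclose(obs.R[0], 2.1)
        np.testing.assert_allclose(obs.sigma[0], 0.14142, atol=1e-4)

    def test_roundtrip_from_generated_expression(self, rng):
        """Ratios measured from a generated expression table recover the
        Master-equation truth within the sampling noise."""
        from wormdecode.config import EnvironmentCondition, StudyConfig
        from wormdecode import expression as ex

        cond = EnvironmentCondition(food=2e7, temperature=15.0)
        cfg = StudyConfig(
            conditions=[cond], n_animals_per_cell=100, n_batches=6, seed=31
        )
        expr, beads, truth = syn.generate_expression(cfg)
        cal = {
            ch: ex.fit_bead_regression(beads, ch) for ch in ("green", "red")
        }
        obs = nw.observed_ratios(ex.normalize_expression(expr, cal))
        np.testing.assert_allclose(
            obs.R, nw.predicted_ratios(truth.network_w[cond]), rtol=0.15
        )

    def test_too_few_pairs_rejected(self):
        mu = [1.0, 1.0, 1.0]
        frame = self._frame({0: {g.value: mu for g in Genotype}})
        with pytest.raises(ValueError, match="paired batches"):
            nw.observed_ratios(frame)


class TestCost:
    def _obs(self, R, sigma):
        return nw.RatioObservations(R=R, sigma=sigma, n_pairs=3)

    def test_exact_match_is_zero(self):
        w = nw.RegulatoryMatrix.from_flat([2, 1, 1, 1, 0.5, 1, 1, 1, 1])
        obs = self._obs(nw.predicted_ratios(w), np.full((3, 3), 0.1))
        assert nw.cost(w, obs) == pytest.approx(0.0, abs=1e-15)

    def test_single_standardized_residual(self):
        w = nw.RegulatoryMatrix.ones()
        R = np.ones((3, 3))
        R[0, 1] = 0.5  # prediction 1 vs observation 0.5 with sigma 0.25
        obs = self._obs(R, np.full((3, 3), 0.25))
        assert nw.cost(w, obs) == pytest.approx(4.0)

    def test_zero_sigma_with_match_contributes_nothing(self):
        w = nw.RegulatoryMatrix.ones()
        obs = self._obs(np.ones((3, 3)), np.zeros((3, 3)))
        assert nw.cost(w, obs) == 0.0

    def test_zero_sigma_with_mismatch_raises(self):
        w = nw.RegulatoryMatrix.ones()
        R = np.ones((3, 3))
        R[1, 1] = 2.0
        with pytest.raises(ValueError, match="infinite"):
            nw.cost(w, obs=self._obs(R, np.zeros((3, 3))))

    def test_invariant_under_matched_relabeling(self):
        w = nw.RegulatoryMatrix.from_flat([2, 1, 1, 1, 3, 1, 1, 1, 0.5])
        R = nw.predicted_ratios(w) * 1.1
        s = np.full((3, 3), 0.2)
        h1 = nw.cost(w, self._obs(R, s))
        h2 = nw.cost(w, self._obs(R[::-1][[2, 1, 0]], s))  # same rows
        assert h1 == pytest.approx(h2)


class TestFitNetwork:
    def test_recovers_noiseless_observations(self, rng):
        """With exact ratio observations from the default cold-temperature
        truth network the fit drives H below 1e-3 and recovers every sign.

        Magnitudes are checked on the identifiable entries only: the pair
        (t3, t7) trades off along a cost-flat direction (both edges connect
        ADF and NSM, which the two knockouts delete or keep together), so
        only its signs, not its magnitudes, are pinned by the ratios."""
        true = nw.RegulatoryMatrix.from_flat(
            [2.5, 3.0, 0.45, 2.2, 2.5, 0.4, 2.8, 0.35, 0.5]
        )
        R = nw.predicted_ratios(true)
        obs = nw.RatioObservations(R=R, sigma=0.1 * R, n_pairs=3)
        fit = nw.fit_network(obs, rng=rng)
        assert fit.cost < 1e-3
        assert fit.sign_model == nw.SignModel.from_log_sign(np.log(true.flat))
        identifiable = [0, 1, 3, 4, 5, 7, 8]
        np.testing.assert_allclose(
            fit.w_hat.flat[identifiable], true.flat[identifiable], rtol=0.2
        )

    def test_unit_ratio_observations_reach_zero_cost(self, rng):
        obs = nw.RatioObservations(
            R=np.ones((3, 3)), sigma=np.full((3, 3), 0.1), n_pairs=3
        )
        fit = nw.fit_network(obs, rng=rng)
        assert fit.cost < 1e-4

    def test_deterministic_under_fixed_seed(self, fast_opt):
        w = nw.RegulatoryMatrix.from_flat([2, 1, 1, 1, 3, 1, 1, 1, 0.5])
        obs = syn.simulate_ratio_observations(w, 0.1, 6, seed=9)
        f1 = nw.fit_network(obs, opt=fast_opt, rng=np.random.default_rng(1))
        f2 = nw.fit_network(obs, opt=fast_opt, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(f1.w_hat.flat, f2.w_hat.flat)
        assert f1.cost == f2.cost

    def test_sign_constraint_is_respected(self, rng, fast_opt):
        w = nw.RegulatoryMatrix.from_flat([2, 1, 1, 1, 3, 1, 1, 1, 0.5])
        obs = syn.simulate_ratio_observations(w, 0.1, 6, seed=10)
        sm = nw.SignModel(("negative",) * 9)
        fit = nw.fit_network(obs, sign_model=sm, opt=fast_opt, rng=rng)
        assert np.all(fit.w_hat.flat >= 1.0)

    def test_accepted_cost_sequence_is_monotone(self, rng):
        w = nw.RegulatoryMatrix.from_flat([2, 1, 1, 1, 3, 1, 1, 1, 0.5])
        obs = syn.simulate_ratio_observations(w, 0.1, 6, seed=11)
        x0 = rng.uniform(-1, 1, (5, 9))
        lo = np.full((5, 9), -np.log(100))
        hi = np.full((5, 9), np.log(100))
        _, _, _, trace = nw._descend(
            x0, lo, hi, obs, 1.0, 200, 0.1, rng, return_trace=True
        )
        assert np.all(np.diff(trace, axis=0) <= 1e-12)


@pytest.fixture(scope="module")
def scan():
    true = nw.RegulatoryMatrix.from_flat(
        [2.5, 3.0, 0.45, 2.2, 2.5, 0.4, 2.8, 0.35, 0.5]
    )
    obs = syn.simulate_ratio_observations(true, 0.05, 24, seed=12)
    fits = nw.enumerate_sign_models(
        obs,
        opt=OptimizerSettings(n_restarts=2, n_iter=250, seed=1),
        rng=np.random.default_rng(3),
    )
    return true, fits


class TestEnumeration:
    def test_covers_all_512_architectures(self, scan):
        _, fits = scan
        assert len(fits) == 512
        assert len({f.sign_model.signs for f in fits}) == 512

    def test_costs_sorted_non_decreasing(self, scan):
        _, fits = scan
        costs = [f.cost for f in fits]
        assert costs == sorted(costs)

    def test_true_architecture_near_minimum(self, scan):
        true, fits = scan
        tsigns = nw.SignModel.from_log_sign(np.log(true.flat))
        rank = next(i for i, f in enumerate(fits) if f.sign_model == tsigns)
        assert rank < 10


class TestClassifyEdges:
    def test_strong_negative(self):
        w = nw.RegulatoryMatrix.from_flat([5, 1, 1, 1, 1, 1, 1, 1, 1])
        cats = nw.classify_edges(w, 2.0)
        assert cats.loc["t1", "sign"] == "negative"
        assert cats.loc["t1", "strength"] == "strong"

    def test_weak_positive(self):
        w = nw.RegulatoryMatrix.from_flat([0.9, 1, 1, 1, 1, 1, 1, 1, 1])
        cats = nw.classify_edges(w, 2.0)
        assert cats.loc["t1", "sign"] == "positive"
        assert cats.loc["t1", "strength"] == "weak"

    def test_unit_entry_is_neutral(self):
        cats = nw.classify_edges(nw.RegulatoryMatrix.ones(), 2.0)
        assert (cats["sign"] == "neutral").all()

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            nw.classify_edges(nw.RegulatoryMatrix.ones(), 1.0)


class TestAggregation:
    def _fit(self, flat, cost):
        return nw.NetworkFit(
            w_hat=nw.RegulatoryMatrix.from_flat(flat),
            cost=cost,
            sign_model=nw.SignModel.from_log_sign(np.log(np.asarray(flat))),
            n_restarts=1,
            n_iter=1,
            n_accepted=1,
            restart_costs=np.array([cost]),
        )

    def test_single_model_under_every_scheme(self):
        f = self._fit([2.0] * 9, 1.0)
        for scheme in ("best", "gof_weighted_geomean", "top_likelihood_set"):
            np.testing.assert_allclose(
                nw.aggregate_models([f], scheme).flat, 2.0
            )

    def test_equal_costs_give_geometric_mean(self):
        fits = [self._fit([2.0] * 9, 1.0), self._fit([8.0] * 9, 1.0)]
        agg = nw.aggregate_models(fits, "gof_weighted_geomean")
        np.testing.assert_allclose(agg.flat, 4.0)

    def test_weights_concentrate_on_minimum(self):
        fits = [self._fit([2.0] * 9, 0.0), self._fit([8.0] * 9, 200.0)]
        agg = nw.aggregate_models(fits, "gof_weighted_geomean")
        np.testing.assert_allclose(agg.flat, 2.0, rtol=1e-6)

    def test_likelihood_cutoff_excludes_poor_fits(self):
        fits = [self._fit([2.0] * 9, 0.0), self._fit([8.0] * 9, 10.0)]
        agg = nw.aggregate_models(fits, "top_likelihood_set")
        np.testing.assert_allclose(agg.flat, 2.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            nw.aggregate_models([self._fit([2.0] * 9, 0.0)], "median")


def _sign_table(columns, data):
    table = pd.DataFrame(data, index=list(nw.EDGE_NAMES), columns=columns)
    table.columns = pd.MultiIndex.from_tuples(
        columns, names=["food", "temperature"]
    )
    return table


class TestShuffleSignificance:
    def _columns(self, foods=(0.0, 1.0, 2.0), temps=(15.0, 20.0, 25.0)):
        return [(f, t) for t in temps for f in foods]

    def test_constant_table_has_zero_statistic_and_no_passes(self):
        cols = self._columns()
        table = _sign_table(cols, [["negative"] * 9] * 9)
        res = nw.shuffle_significance(table, n_shuffles=500, seed=0)
        assert res.observed_statistic == 0
        assert res.n_passing == 0
        assert res.p_hat == 0.0

    def test_engineered_four_edge_flip_counts_four(self):
        """Four edges switch sign monotonically from 15 to 25 degrees in
        every food column; the other five never change."""
        cols = self._columns()
        data = []
        for e in range(9):
            row = []
            for f, t in cols:
                if e < 4:
                    row.append("positive" if t < 20 else "negative")
                else:
                    row.append("positive")
            data.append(row)
        table = _sign_table(cols, data)
        res = nw.shuffle_significance(table, n_shuffles=2000, seed=1)
        assert res.observed_statistic == 4
        assert 0.0 <= res.p_hat <= 1.0
        assert res.n_passing <= res.n_shuffles

    def test_small_p_for_consistent_rewiring(self):
        """Four edges flip with distinct monotone profiles (two flip already
        at 20 degrees, two only at 25, in opposite directions); reassembling
        all four flips simultaneously by a chance column permutation is
        rare."""
        cols = self._columns(foods=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0))
        data = []
        for e in range(9):
            row = []
            for f, t in cols:
                if e in (0, 1):
                    row.append("positive" if t < 20 else "negative")
                elif e == 2:
                    row.append("positive" if t < 25 else "negative")
                elif e == 3:
                    row.append("negative" if t < 25 else "positive")
                else:
                    row.append("negative" if e % 2 else "positive")
            data.append(row)
        table = _sign_table(cols, data)
        res = nw.shuffle_significance(table, n_shuffles=20_000, seed=2)
        assert res.observed_statistic == 4
        assert res.p_hat < 0.05

    def test_requires_two_temperatures(self):
        cols = [(0.0, 20.0), (1.0, 20.0)]
        table = _sign_table(cols, [["positive"] * 2] * 9)
        with pytest.raises(ValueError, match="two temperatures"):
            nw.shuffle_significance(table, n_shuffles=10)
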