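"""pRL eligibility/update machinery and the pCOV covariance rule."""

import numpy as np
import pytest

import popgrad as pg
from popgrad.spiking import psp_matrix


def _episode_traces(w, pat, ker, esc, seed):
    rng = np.random.default_rng(seed)
    train, tr = pg.simulate_neuron(w, pat, ker, esc, rng)
    elig = pg.eligibility_trace(tr["psp"], train, tr["u"], esc)
    return train, tr, elig


class TestEligibility:
    def test_silent_channel_has_zero_eligibility(self, toy_setup):
        ker, esc, _, _ = toy_setup
        pat = pg.SpikePattern(2, 20.0, [np.array([3.0, 9.0]), np.empty(0)])
        w = np.array([0.5, 0.5])
        train, tr, elig = _episode_traces(w, pat, ker, esc, seed=4)
        assert elig[1] == 0.0

    def test_matches_numerical_loglik_gradient(self, toy_setup):
        # duality: e_j == d log_likelihood / d w_j (neg_term_factor = 1)
        ker, esc, pat, w = toy_setup
        found_spiking = False
        for seed in range(6):
            train, tr, elig = _episode_traces(w, pat, ker, esc, seed)
            found_spiking = found_spiking or train.fired
            h = 1e-5
            for j in range(3):
                wp, wm = w.copy(), w.copy()
                wp[j] += h
                wm[j] -= h
                fd = (pg.log_likelihood(wp, pat, train, ker, esc)
                      - pg.log_likelihood(wm, pat, train, ker, esc)) / (2 * h)
                assert elig[j] == pytest.approx(fd, rel=1e-4, abs=1e-10)
        assert found_spiking  # the check covered spike-containing outputs

    def test_zero_mean_under_model_sampling(self, toy_setup):
        # score-function identity: E[e_j] = 0 when outputs are drawn from
        # the model itself (balanced positive and negative terms)
        ker, esc, pat, w = toy_setup
        rng = np.random.default_rng(8)
        n = 10**4
        es = np.empty((n, 3))
        for k in range(n):
            train, tr = pg.simulate_neuron(w, pat, ker, esc, rng)
            es[k] = pg.eligibility_trace(tr["psp"], train, tr["u"], esc)
        se = es.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(es.mean(axis=0)) < 3 * se + 1e-12)

    def test_grid_mismatch_raises(self, toy_setup):
        ker, esc, pat, w = toy_setup
        _, psp = psp_matrix(pat, ker, esc.dt)
        with pytest.raises(ValueError):
            pg.eligibility_trace(psp, pg.SpikeTrain(), np.zeros(5), esc)


class TestRewardPredictionError:
    def test_arithmetic(self):
        cfg = pg.LearnConfig(eta=0.1)
        est = pg.RewardEstimator()
        rp, est = pg.reward_prediction_error(1.0, "s", est, cfg)
        assert rp == pytest.approx(0.1)

    def test_constant_stream_geometric_fixed_point(self):
        cfg = pg.LearnConfig(eta=1.0, gamma_rbar=0.2)
        est = pg.RewardEstimator()
        c = 3.0
        for k in range(60):
            rp, est = pg.reward_prediction_error(c, "s", est, cfg)
        # rbar -> c geometrically at rate (1 - gamma)
        assert est.get("s", cfg) == pytest.approx(c, abs=c * (1 - 0.2) ** 60 + 1e-9)
        assert abs(rp) < 1e-4

    def test_running_mean_unbiased(self):
        cfg = pg.LearnConfig(eta=1.0, gamma_rbar=0.05)
        est = pg.RewardEstimator()
        rng = np.random.default_rng(2)
        errs = []
        for _ in range(20000):
            r = rng.normal(1.7, 0.5)
            rp, est = pg.reward_prediction_error(r, "s", est, cfg)
            errs.append(rp)
        assert abs(np.mean(errs[1000:])) < 0.02

    def test_per_state_scope_is_independent(self):
        cfg = pg.LearnConfig(gamma_rbar=1.0)
        est = pg.RewardEstimator()
        pg.reward_prediction_error(1.0, "a", est, cfg)
        assert est.get("b", cfg) == cfg.rbar_init
        assert est.get("a", cfg) == 1.0


class TestPRLUpdate:
    def _record(self, n=2, m=3, sigma=(1.0, 1.0)):
        return {
            "f_prime": 0.25,
            "sigma": np.array(sigma),
            "elig": np.arange(n * m, dtype=float).reshape(n, m) + 1.0,
        }

    def test_zero_reward_factor_no_change(self):
        w = np.ones((2, 3))
        out = pg.prl_update(w, [self._record()], r_prime=0.0)
        np.testing.assert_array_equal(out, w)

    def test_silent_neuron_row_unchanged(self):
        w = np.ones((2, 3))
        out = pg.prl_update(w, [self._record(sigma=(0.0, 1.0))], r_prime=0.5)
        np.testing.assert_array_equal(out[0], w[0])
        assert not np.allclose(out[1], w[1])

    def test_mask_protects_absent_synapses(self):
        w = np.ones((2, 3))
        mask = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        out = pg.prl_update(w, [self._record()], r_prime=0.5, mask=mask)
        np.testing.assert_array_equal(out[mask == 0], w[mask == 0])

    def test_missing_record_fields_raise(self):
        with pytest.raises(ValueError):
            pg.prl_update(np.ones((2, 3)), [{"f_prime": 0.1}], r_prime=1.0)
        with pytest.raises(ValueError):
            pg.prl_update(np.ones((2, 3)), [], r_prime=1.0)


class TestBinaryNeuron:
    def test_zero_drive_is_chance(self):
        _, mean = pg.binary_forward(np.zeros(4), np.ones(4), seed=0)
        assert mean == pytest.approx(0.5)

    def test_large_drive_saturates(self):
        _, mean = pg.binary_forward(np.full(4, 10.0), np.ones(4), seed=0)
        assert mean > 0.9999

    def test_empirical_mean_matches(self):
        w, x = np.array([0.7, -0.2]), np.array([1.0, 1.0])
        rng = np.random.default_rng(3)
        draws = [pg.binary_forward(w, x, rng)[0] for _ in range(10**4)]
        _, p = pg.binary_forward(w, x, seed=0)
        assert abs(np.mean(draws) - p) < 3 * np.sqrt(p * (1 - p) / 10**4)


class TestPCOV:
    def test_centered_response_no_change(self):
        cfg = pg.LearnConfig()
        w = np.array([0.1, 0.2])
        out = pg.pcov_update(w, np.ones(2), sigma=1, sigma_center=1.0,
                             f_prime=0.3, r_prime=0.5, cfg=cfg)
        np.testing.assert_array_equal(out, w)

    def test_no_subtraction_variant_silent_neuron_no_change(self):
        cfg = pg.LearnConfig()
        w = np.array([0.1, 0.2])
        out = pg.pcov_update(w, np.ones(2), sigma=0, sigma_center=0.0,
                             f_prime=0.3, r_prime=0.5, cfg=cfg)
        np.testing.assert_array_equal(out, w)

    def test_reward_independent_of_response_is_fixed_point(self):
        # reward drawn independently of sigma: expected update vanishes
        cfg = pg.LearnConfig(nu=1.0, eta=1.0, gamma_rbar=0.05, rbar_scope="global")
        pop = pg.PopulationConfig(n_neurons=1)
        w = np.array([0.3, -0.4])
        x = np.array([1.0, 1.0])
        rng = np.random.default_rng(9)
        est = pg.RewardEstimator()
        updates = []
        for _ in range(20000):
            sigma, mean = pg.binary_forward(w, x, rng)
            a = sigma
            p1 = pg.decision_prob(a, pop)
            d = int(rng.random() < p1)
            fp = pg.decision_feedback(d, a, pop)
            r = rng.normal(1.0, 0.3)  # independent of everything
            rp, est = pg.reward_prediction_error(r, "s", est, cfg)
            updates.append(pg.pcov_update(w, x, sigma, mean, fp, rp, cfg) - w)
        upd = np.array(updates)[1000:]
        se = upd.std(axis=0) / np.sqrt(len(upd))
        assert np.all(np.abs(upd.mean(axis=0)) < 3 * se + 1e-4)


class TestGradientAscent:
    def test_batch_updates_increase_expected_reward(self):
        # tiny population (2 neurons, 3 afferents, 10-step grid, R = D):
        # E[R] evaluated in closed form; pRL batch updates must climb it
        from scipy.stats import wilcoxon

        ker = pg.KernelParams()
        esc = pg.EscapeParams(rho0=0.05, theta=0.3, delta_u=0.3, dt=1.0)
        pat = pg.generate_frozen_pattern(3, 250.0, 10.0, seed=42)
        pop = pg.PopulationConfig(n_neurons=2, connect_prob=1.0)
        _, psp = psp_matrix(pat, ker, esc.dt)

        def p_fire(w_row):
            u = ker.u_rest + w_row @ psp
            p = np.minimum(1.0, esc.rate(u) * esc.dt)
            return 1.0 - np.prod(1.0 - p)

        def exp_reward(W):
            p1, p2 = p_fire(W[0]), p_fire(W[1])
            pa = {0: (1 - p1) * (1 - p2), 1: p1 * (1 - p2) + (1 - p1) * p2,
                  2: p1 * p2}
            return sum(pa[a] * pg.decision_prob(a, pop) for a in pa)

        rng = np.random.default_rng(7)
        W = rng.normal(0, 0.3, (2, 3))
        lr, batch = 0.8, 150
        values = [exp_reward(W)]
        for _ in range(200):
            acc = np.zeros_like(W)
            for _ in range(batch):
                recs = {"sigma": np.zeros(2), "elig": np.zeros_like(W)}
                trains = []
                for i in range(2):
                    tr, traces = pg.simulate_neuron(W[i], pat, ker, esc, rng, psp=psp)
                    trains.append(tr)
                    recs["sigma"][i] = tr.fired
                    recs["elig"][i] = pg.eligibility_trace(
                        traces["psp"], tr, traces["u"], esc)
                a = pg.population_activity(trains)
                d = int(rng.random() < pg.decision_prob(a, pop))
                recs["f_prime"] = pg.decision_feedback(d, a, pop)
                acc += pg.prl_update(np.zeros_like(W), [recs], float(d))
            W = W + lr * acc / batch
            values.append(exp_reward(W))
        inc = np.diff(values)
        assert values[-1] > values[0] + 0.05
        assert wilcoxon(inc, alternative="greater").pvalue < 0.01
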