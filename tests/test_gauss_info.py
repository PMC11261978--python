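"""State-space engine: Riccati posteriors, information rates, causal filters."""

import dataclasses

import numpy as np
import pytest

from chemosense import (KinaseParams, PhysicalConstants, SwimSignalParams,
                        gauss_info, theory)
from chemosense.gauss_info import (arrival_rho2_closed_form,
                                   build_arrival_channel,
                                   build_kinase_channel, causal_estimate,
                                   discretize, error_propagation, eta,
                                   info_summary, predictive_info_rate_from_rho2,
                                   simulate_channel, stationary_discrete_filter,
                                   stationary_posterior)

from conftest import gamma_r_to_g


class TestArrivalChannel:
    def test_prior_variance_is_signal_variance(self, swim_1uM, constants):
        ch = build_arrival_channel(swim_1uM, constants)
        assert ch.sigma_s2 == pytest.approx(swim_1uM.sigma_s2)
        # OU stationary variance Q_ss*tau_v/2 reproduces sigma_s2 exactly
        assert (ch.process_noise[0, 0] * swim_1uM.tau_v / 2
                == pytest.approx(swim_1uM.sigma_s2))

    def test_no_gradient_channel_uninformative(self, constants):
        swim = SwimSignalParams(g=0.0, c0=1.0)
        post = stationary_posterior(build_arrival_channel(swim, constants))
        assert post.P_ss == 0.0 and post.rho2 == 0.0 and post.info_rate == 0.0

    def test_zero_background_rejected(self, constants):
        with pytest.raises(ValueError):
            build_arrival_channel(SwimSignalParams(g=0.05, c0=0.0), constants)

    def test_low_count_warning(self):
        const = PhysicalConstants(kD=1.2e5)
        with pytest.warns(UserWarning, match="Gaussian"):
            build_arrival_channel(SwimSignalParams(g=0.05, c0=5e-5), const)

    def test_simulated_signal_autocorrelation(self, constants):
        # the latent s of the state-space model is the OU signal
        swim = SwimSignalParams(sigma_v2=146.0, tau_v=1.19, g=0.4, c0=1.0)
        ch = build_arrival_channel(swim, constants)
        rng = np.random.default_rng(11)
        dt = swim.tau_v / 50
        x, _ = simulate_channel(ch, dt, 200_000, rng)
        s = x[:, ch.s_index]
        var = np.var(s)
        assert var == pytest.approx(swim.sigma_s2, rel=0.05)
        lag = int(round(swim.tau_v / dt))
        acf1 = np.mean(s[:-lag] * s[lag:]) / var
        assert acf1 == pytest.approx(np.exp(-1.0), abs=0.03)


class TestStationaryPosterior:
    @pytest.mark.parametrize("gamma_r", [1e-4, 1e-3, 1e-2])
    def test_engine_matches_exact_closed_form(self, constants, gamma_r):
        # independent hand solution of the 2-state Riccati system
        swim = SwimSignalParams(sigma_v2=146, tau_v=1.19,
                                g=gamma_r_to_g(gamma_r), c0=1.0)
        post = stationary_posterior(build_arrival_channel(swim, constants))
        exact = arrival_rho2_closed_form(theory.gamma_r(swim, constants))
        assert post.rho2 == pytest.approx(exact, rel=1e-3)

    def test_convergence_to_quarter_gamma_asymptote(self, constants):
        # rho2 -> gamma_r/4 as gamma_r -> 0, with relative deviation
        # bounded by the leading correction 2*sqrt(gamma_r)
        devs = []
        for gamma_r in (1e-2, 1e-4, 1e-6):
            swim = SwimSignalParams(sigma_v2=146, tau_v=1.19,
                                    g=gamma_r_to_g(gamma_r), c0=1.0)
            post = stationary_posterior(build_arrival_channel(swim, constants))
            dev = abs(post.rho2 / (gamma_r / 4.0) - 1.0)
            assert dev < 2.0 * np.sqrt(gamma_r) + 1e-3
            devs.append(dev)
        assert devs[0] > devs[1] > devs[2]
        assert devs[1] < 0.021  # within ~2% by gamma_r = 1e-4

    def test_uninformative_limit_large_observation_noise(self, constants):
        swim = SwimSignalParams(g=0.05, c0=1.0)
        ch = build_arrival_channel(swim, constants)
        noisy = dataclasses.replace(ch, obs_noise=ch.obs_noise * 1e12)
        post = stationary_posterior(noisy)
        assert post.P_ss == pytest.approx(swim.sigma_s2, rel=1e-4)
        assert post.rho2 < 1e-4

    @pytest.mark.parametrize("channel", ["arrival", "kinase"])
    def test_brute_force_discrete_filter_agreement(self, constants, kinase_1uM,
                                                   channel):
        # plain fixed-point Riccati recursion on a fine grid as the arbiter
        # (run in rescaled units; rho2 is invariant under the rescaling)
        swim = SwimSignalParams(sigma_v2=146, tau_v=1.19, g=0.05, c0=1.0)
        if channel == "arrival":
            ch = build_arrival_channel(swim, constants)
        else:
            ch = build_kinase_channel(swim, kinase_1uM, constants)
        scaled = gauss_info.rescaled_channel(ch)
        dt = ch.tau_v * 1e-3
        _, _, _, P_filt = stationary_discrete_filter(
            discretize(scaled, dt), min_iter=int(100.0 / dt))
        rho2_brute = 1.0 - P_filt[scaled.s_index, scaled.s_index] / scaled.sigma_s2
        rho2_engine = stationary_posterior(ch).rho2
        assert rho2_brute == pytest.approx(rho2_engine, rel=5e-3)
        # posterior variances agree to <0.5% as well
        assert ((1 - rho2_brute) * ch.sigma_s2
                == pytest.approx(stationary_posterior(ch).P_ss, rel=5e-3))


class TestKinaseChannel:
    def test_ideal_sensor_limit(self, constants, swim_1uM):
        kin = KinaseParams(G_r=2.28 / 1.2e5, D_n=8.1e-10, tau_n=8.7)
        post_a = stationary_posterior(build_kinase_channel(swim_1uM, kin, constants))
        post_r = stationary_posterior(build_arrival_channel(swim_1uM, constants))
        assert post_a.info_rate == pytest.approx(post_r.info_rate, rel=0.01)

    def test_zero_internal_noise_needs_flag(self, constants, swim_1uM):
        kin = KinaseParams(G_r=2.28 / 1.2e5, D_n=0.0)
        with pytest.raises(ValueError):
            build_kinase_channel(swim_1uM, kin, constants)
        ch = build_kinase_channel(swim_1uM, kin, constants,
                                  allow_zero_internal_noise=True)
        post_r = stationary_posterior(build_arrival_channel(swim_1uM, constants))
        assert (stationary_posterior(ch).info_rate
                == pytest.approx(post_r.info_rate, rel=1e-6))

    def test_zero_gain_carries_no_information(self, constants, swim_1uM):
        kin = KinaseParams(G_r=0.0, D_n=8.1e-4, tau_n=8.7)
        post = stationary_posterior(build_kinase_channel(swim_1uM, kin, constants))
        assert post.rho2 < 1e-10

    def test_finite_tau1_not_representable(self, constants, swim_1uM):
        kin = KinaseParams(G_r=2.28 / 1.2e5, tau_1=0.2, tau_2=7.4)
        with pytest.raises(NotImplementedError):
            build_kinase_channel(swim_1uM, kin, constants)


class TestPredictiveRate:
    def test_zero_correlation(self):
        assert predictive_info_rate_from_rho2(0.0, 1.19) == 0.0

    def test_small_rho2_expansion(self):
        rho2 = 1e-5
        rate = predictive_info_rate_from_rho2(rho2, 2.0)
        assert rate == pytest.approx(rho2 / 2.0, rel=2e-5)

    def test_finite_difference_of_gaussian_information(self):
        # I(tau) = -1/2 ln(sigma^2(tau)/sigma_s^2) differentiated at tau=0
        sigma_s2, P, tau_v = 2.3, 0.9, 1.19
        rho2 = 1 - P / sigma_s2

        def info(tau):
            var = sigma_s2 - (sigma_s2 - P) * np.exp(-2 * tau / tau_v)
            return -0.5 * np.log(var / sigma_s2)

        h = 1e-6
        fd = (info(0.0) - info(h)) / h
        assert fd == pytest.approx(
            predictive_info_rate_from_rho2(rho2, tau_v), rel=1e-3)

    def test_invalid_rho2_guarded(self):
        with pytest.raises(ValueError):
            predictive_info_rate_from_rho2(1.0, 1.0)


class TestEta:
    def test_ideal_sensor_eta_one(self, constants, swim_1uM):
        kin = KinaseParams(G_r=2.28 / 1.2e5, D_n=8.1e-12, tau_n=8.7)
        assert eta(swim_1uM, kin, constants) == pytest.approx(1.0, abs=1e-3)

    def test_gradient_independence_in_the_shallow_limit(self, constants,
                                                        kinase_1uM):
        # both rates scale as g^2; the ratio plateaus (residual g-dependence
        # from the sqrt(gamma_r) correction stays below 2% at g <= 1e-3/mm)
        vals = [eta(SwimSignalParams(sigma_v2=146, tau_v=1.19, g=g, c0=1.0),
                    kinase_1uM, constants) for g in (1e-3, 1e-4)]
        assert vals[0] == pytest.approx(vals[1], rel=0.02)

    def test_summary_fields_consistent(self, constants, kinase_1uM, swim_1uM):
        s = info_summary(swim_1uM, kinase_1uM, constants)
        assert 0 < s.eta < 1
        assert s.I_a == pytest.approx(s.eta * s.I_r)
        assert s.r0 == pytest.approx(1.2e5)
        assert 0 < s.rho2_as < s.rho2_rs < 1


class TestDataProcessingAndMonotonicity:
    def test_kinase_never_beats_arrivals_on_grid(self, constants):
        for c0 in np.geomspace(0.05, 20, 5):
            for g in np.geomspace(1e-3, 0.4, 5):
                for dn in np.geomspace(8.1e-6, 8.1e-2, 5):
                    swim = SwimSignalParams(sigma_v2=146, tau_v=1.19, g=g, c0=c0)
                    kin = KinaseParams(G_r=2.28 / 1.2e5, D_n=dn, tau_n=8.7)
                    s = info_summary(swim, kin, constants)
                    assert s.I_a <= s.I_r + 1e-12

    def test_monotone_in_gain_noise_background_gradient(self, constants):
        swim = SwimSignalParams(sigma_v2=146, tau_v=1.19, g=0.1, c0=1.0)
        base = dict(tau_2=7.4, D_n=8.1e-4, tau_n=8.7)
        rates_gain = [stationary_posterior(build_kinase_channel(
            swim, KinaseParams(G_r=gr, **base), constants)).info_rate
            for gr in np.array([0.5, 1.0, 2.0, 4.0]) * 2.28 / 1.2e5]
        assert all(b >= a for a, b in zip(rates_gain, rates_gain[1:]))
        rates_dn = [stationary_posterior(build_kinase_channel(
            swim, KinaseParams(G_r=2.28 / 1.2e5, tau_2=7.4, D_n=dn, tau_n=8.7),
            constants)).info_rate for dn in (1e-4, 1e-3, 1e-2)]
        assert all(b <= a for a, b in zip(rates_dn, rates_dn[1:]))
        for param, values in (("c0", [0.1, 1.0, 10.0]), ("g", [0.05, 0.1, 0.4])):
            rates = []
            for v in values:
                sw = dataclasses.replace(swim, **{param: v})
                rates.append(stationary_posterior(
                    build_arrival_channel(sw, constants)).info_rate)
            assert rates[0] < rates[1] < rates[2]


class TestCausalEstimate:
    def test_zero_observations_give_prior_mean(self, constants, swim_1uM):
        ch = build_arrival_channel(swim_1uM, constants)
        t = np.arange(500) * (swim_1uM.tau_v / 100)
        np.testing.assert_allclose(causal_estimate(ch, t, np.zeros(500)), 0.0)

    def test_nan_rejected_and_nonuniform_rejected(self, constants, swim_1uM):
        ch = build_arrival_channel(swim_1uM, constants)
        t = np.arange(10) * 0.01
        y = np.zeros(10)
        y[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            causal_estimate(ch, t, y)
        with pytest.raises(ValueError, match="uniform"):
            causal_estimate(ch, t ** 1.5, np.zeros(10))

    def test_coarse_sampling_warns(self, constants, swim_1uM):
        ch = build_arrival_channel(swim_1uM, constants)
        t = np.arange(100) * (swim_1uM.tau_v / 10)
        with pytest.warns(UserWarning, match="coarse"):
            causal_estimate(ch, t, np.zeros(100))

    @pytest.mark.parametrize("channel", ["arrival", "kinase"])
    def test_empirical_correlation_matches_engine(self, constants, kinase_1uM,
                                                  channel):
        # long model-generated series: empirical rho2 of the causal estimate
        # against the true latent signal converges to the engine value
        swim = SwimSignalParams(sigma_v2=146, tau_v=1.19, g=0.4, c0=1.0)
        if channel == "arrival":
            ch = build_arrival_channel(swim, constants)
        else:
            ch = build_kinase_channel(swim, kinase_1uM, constants)
        dt = swim.tau_v / 50
        n = 400_000  # ~ 8e3 correlation times
        rng = np.random.default_rng(202)
        x, y = simulate_channel(ch, dt, n, rng)
        t = np.arange(n) * dt
        s_hat = causal_estimate(ch, t, y)
        s_true = x[:, ch.s_index]
        rho2_emp = np.corrcoef(s_hat, s_true)[0, 1] ** 2
        rho2_eng = stationary_posterior(ch).rho2
        # standard error of rho2 over ~n*dt/(2 tau_v) effective samples
        n_eff = n * dt / (2 * swim.tau_v)
        se = 4 * rho2_eng * (1 - rho2_eng) / np.sqrt(n_eff)
        assert abs(rho2_emp - rho2_eng) < 3 * se + 0.02 * rho2_eng


class TestErrorPropagation:
    def test_identity_map(self):
        var = error_propagation(lambda th: th[0], np.array([2.0, 3.0]),
                                np.array([0.1, 0.7]))
        assert var == pytest.approx(0.01, rel=1e-6)

    def test_product_rule(self):
        theta = np.array([2.0, 5.0])
        sig = np.array([0.1, 0.2])
        var = error_propagation(lambda th: th[0] * th[1], theta, sig)
        assert var == pytest.approx(5.0 ** 2 * 0.01 + 2.0 ** 2 * 0.04, rel=1e-6)

    def test_nonfinite_function_reported(self):
        with pytest.raises(ValueError, match="finite"):
            error_propagation(lambda th: np.nan, np.array([1.0]),
                              np.array([0.1]))

    def test_eta_uncertainty_order_of_magnitude(self, constants):
        # propagate the printed parameter SEMs into eta at 1 uM, g -> 0;
        # expect an uncertainty of order 2e-3
        def eta_of(th):
            sv2, tv, kdgr, t2, dn, tn = th
            swim = SwimSignalParams(sigma_v2=sv2, tau_v=tv, g=1e-3, c0=1.0)
            kin = KinaseParams(G_r=kdgr / 1.2e5, tau_2=t2, D_n=dn, tau_n=tn)
            return eta(swim, kin, constants)

        theta = np.array([146.0, 1.19, 2.28, 7.4, 8.1e-4, 8.7])
        sigma = np.array([5.0, 0.01, 0.05, 0.3, 0.9e-4, 0.9])
        sd = np.sqrt(error_propagation(eta_of, theta, sigma, rel_step=1e-3))
        assert 5e-4 < sd < 8e-3
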