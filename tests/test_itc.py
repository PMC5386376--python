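import numpy as np
import pytest

from bclkit import itc


def _params(kd_nM=100.0, n=1.0, dh=-12000.0, baseline=0.0):
    return itc.ITCModelParams(N=n, Ka=1e9 / kd_nM, dH=dh, baseline=baseline)


class TestModel:
    def test_zero_enthalpy_gives_baseline_only(self):
        p = _params(dh=0.0, baseline=0.25)
        exp = itc.simulate_titration(p, itc.ITCExperiment(), noise_sd=0.0)
        assert np.allclose(exp.heats, 0.25)

    def test_saturation_limit_conserves_total_heat(self):
        # huge Ka, large ligand excess: everything in the cell ends up bound
        p = itc.ITCModelParams(N=1.0, Ka=1e12, dH=-10000.0)
        protocol = itc.ITCExperiment()
        q = itc._cumulative_heats(p, protocol)
        dV = np.asarray(protocol.injection_volumes)
        v0 = protocol.cell_volume
        cum = dV.sum()
        mt_final = protocol.cell_conc * (1 - cum / (2 * v0)) / (1 + cum / (2 * v0))
        expect = p.N * p.dH * mt_final * v0
        assert q[-1] == pytest.approx(expect, rel=0.005)

    def test_heat_conservation_identity(self):
        p = _params()
        protocol = itc.ITCExperiment()
        q = itc._cumulative_heats(p, protocol)
        heats = itc.injection_heats(p, protocol)
        dV = np.asarray(protocol.injection_volumes)
        q_prev = np.concatenate([[0.0], q[:-1]])
        corrections = dV / protocol.cell_volume * (q + q_prev) / 2
        assert (heats - corrections - p.baseline).sum() == pytest.approx(
            q[-1], abs=1e-9
        )

    def test_c_value_for_reported_protocol(self):
        # 20 μM cell at the tight sponge-Bak affinity: strongly sigmoidal regime
        p = _params(kd_nM=65.0)
        c = itc.c_value(p, itc.ITCExperiment())
        assert c == pytest.approx(20e-6 / 65e-9, rel=1e-12)
        assert c > 100

    def test_simulation_deterministic_given_seed(self):
        p = _params()
        e1 = itc.simulate_titration(p, itc.ITCExperiment(), noise_fraction=0.02, seed=7)
        e2 = itc.simulate_titration(p, itc.ITCExperiment(), noise_fraction=0.02, seed=7)
        assert e1.heats == e2.heats

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            itc.ITCExperiment(cell_conc=-1.0)
        with pytest.raises(ValueError):
            itc.ITCModelParams(N=1.0, Ka=-5.0, dH=0.0)


class TestFit:
    def test_noiseless_refit_recovers_parameters(self):
        p = _params(kd_nM=100.0, n=1.0, dh=-12000.0)
        exp = itc.simulate_titration(p, itc.ITCExperiment(), noise_sd=0.0)
        fit = itc.fit_single_site(exp)
        assert fit.converged and not fit.no_binding
        assert fit.kd_nM == pytest.approx(100.0, rel=1e-3)
        assert fit.params.N == pytest.approx(1.0, rel=1e-3)
        assert fit.params.dH == pytest.approx(-12000.0, rel=1e-3)

    def test_flat_thermogram_yields_no_binding_verdict(self):
        p = _params(dh=0.0)
        exp = itc.simulate_titration(p, itc.ITCExperiment(), noise_sd=0.05, seed=3)
        fit = itc.fit_single_site(exp)
        assert fit.no_binding
        assert not fit.converged
        assert np.isnan(fit.kd_nM)

    def test_weak_binding_carries_much_wider_kd_uncertainty(self):
        # c = 0.2 (Kd = 100 μM at a 20 μM cell) vs c ≈ 308 (Kd = 65 nM):
        # the shallow low-c curve should leave Kd far less determined
        def rel_err(kd_nM, seed):
            p = _params(kd_nM=kd_nM, dh=-10000.0)
            exp = itc.simulate_titration(p, itc.ITCExperiment(),
                                         noise_fraction=0.02, seed=seed)
            fit = itc.fit_single_site(exp)
            assert fit.converged
            return fit.stderr["kd_nM"] / fit.kd_nM

        weak = rel_err(100_000.0, seed=11)
        tight = rel_err(65.0, seed=11)
        assert weak > 5 * tight

    def test_too_few_injections_rejected(self):
        p = _params()
        protocol = itc.ITCExperiment(injection_volumes=[2.0] * 5)
        exp = itc.simulate_titration(p, protocol, noise_sd=0.0)
        with pytest.raises(ValueError, match="8"):
            itc.fit_single_site(exp)

    def test_replicate_spread_consistent_with_noise(self):
        p = _params(kd_nM=65.0, dh=-10000.0)
        kds = []
        for seed in range(1, 7):
            exp = itc.simulate_titration(p, itc.ITCExperiment(),
                                         noise_fraction=0.02, seed=seed)
            fit = itc.fit_single_site(exp)
            assert fit.converged
            kds.append(fit.kd_nM)
        sd_kd = np.std(kds, ddof=1)
        # order-of-magnitude check: spread far below the mean, not zero
        assert 0.0 < sd_kd < 0.5 * np.mean(kds)


class TestAggregate:
    def test_mean_and_sample_sd(self):
        fits = [
            itc.FitResult(params=_params(kd_nM=kd), kd_nM=kd, stderr={},
                          residual_norm=0.0, converged=True)
            for kd in (60.0, 65.0, 70.0)
        ]
        mean, sd = itc.aggregate_replicates(fits)
        assert mean == pytest.approx(65.0)
        assert sd == pytest.approx(5.0)

    def test_single_fit_rejected(self):
        fit = itc.FitResult(params=_params(), kd_nM=100.0, stderr={},
                            residual_norm=0.0, converged=True)
        with pytest.raises(ValueError, match="2"):
            itc.aggregate_replicates([fit])

    def test_unconverged_fits_ignored(self):
        good = [
            itc.FitResult(params=_params(kd_nM=kd), kd_nM=kd, stderr={},
                          residual_norm=0.0, converged=True)
            for kd in (60.0, 70.0)
        ]
        bad = itc.FitResult(params=_params(), kd_nM=float("nan"), stderr={},
                            residual_norm=0.0, converged=False, no_binding=True)
        mean, _ = itc.aggregate_replicates(good + [bad])
        assert mean == pytest.approx(65.0)
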