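"""Trace cleaning, decay-weighted integration, gap-loss bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from ac225rims import (
    CampaignTruth,
    CurrentTrace,
    estimate_gap_loss,
    fit_background,
    generate_current_trace,
    integrate_to_activity,
    subtract_background,
)
from ac225rims.beam_current import E_CHARGE, BackgroundModel, BeamCurrentError

PA = 1e-12
HOUR = 3600.0


def _trace(t, current, fc_in=False, collecting=True, laser_on=True, heater=602.0):
    n = len(t)

    def col(x):
        return np.full(n, x) if np.isscalar(x) else np.asarray(x)

    return CurrentTrace(
        pd.DataFrame(
            {
                "time_s": np.asarray(t, float),
                "current_a": col(current).astype(float),
                "fc_in": col(fc_in).astype(bool),
                "laser_on": col(laser_on).astype(bool),
                "collecting": col(collecting).astype(bool),
                "heater_current_a": col(heater).astype(float),
            }
        )
    )


class TestBackground:
    def test_constant_blocked_samples_degenerate_flat(self):
        t = np.arange(0, 6000.0, 600.0)
        tr = _trace(t, -0.05 * PA, fc_in=True)
        model = fit_background(tr)
        assert model.b0 == pytest.approx(-0.05 * PA)
        assert model.b1 == pytest.approx(-0.05 * PA)

    def test_too_few_blocked_samples_rejected(self):
        t = np.arange(0, 600.0, 60.0)
        tr = _trace(t, 1 * PA, fc_in=False)
        with pytest.raises(BeamCurrentError, match="blocked"):
            fit_background(tr)

    def test_sigmoid_parameter_recovery(self):
        """Seeded noise on sigmoid truth: asymptotes recovered within 10%."""
        rng = np.random.default_rng(5)
        truth = BackgroundModel(b0=0.0, b1=-0.06 * PA, t0=36000.0, w=5000.0)
        t = np.arange(0.0, 72000.0, 300.0)
        cur = truth(t) + rng.normal(0, 0.002 * PA, len(t))
        model = fit_background(_trace(t, cur, fc_in=True))
        assert model.b1 == pytest.approx(truth.b1, rel=0.10)
        assert abs(model.b0 - truth.b0) < 0.1 * abs(truth.b1)

    def test_subtract_zero_background_is_identity(self):
        t = np.arange(0, 3600.0, 60.0)
        tr = _trace(t, 2 * PA)
        net = subtract_background(tr, BackgroundModel(0.0, 0.0, 1800.0, 100.0))
        assert np.allclose(net.current_a, tr.current_a)

    def test_subtracting_background_from_itself_zeroes(self):
        model = BackgroundModel(-0.01 * PA, -0.05 * PA, 1800.0, 400.0)
        t = np.arange(0, 3600.0, 60.0)
        tr = _trace(t, model(t))
        net = subtract_background(tr, model)
        assert np.allclose(net.current_a, 0.0, atol=1e-25)

    def test_generator_truth_recovered_through_subtraction(self, truth):
        trace = generate_current_trace(truth, 9)
        net = subtract_background(trace, fit_background(trace))
        live = net.data[~net.data.fc_in & net.data.laser_on]
        signal = truth.signal_current(live.time_s.to_numpy())
        resid = live.current_a.to_numpy() - signal
        assert abs(np.mean(resid)) < truth.current_noise_a
        assert np.std(resid) < 1.5 * truth.current_noise_a


class TestIntegrateToActivity:
    def test_constant_current_closed_form(self, chain):
        """1 pA of ²²⁵Ac⁺ for 1 h → (I/e)(1−e^{−λΔt}) ≈ 18.2 kBq at EOC."""
        t = np.arange(0.0, 3600.0 + 1, 10.0)
        tr = _trace(t, 1 * PA)
        lam = chain["Ac-225"].lam
        act, _ = integrate_to_activity(tr, chain["Ac-225"], noise_sigma_a=0.0)
        expected = (1e-12 / E_CHARGE) * (1.0 - math.exp(-lam * 3600.0))
        assert act == pytest.approx(expected, rel=1e-9)
        assert act == pytest.approx(18.2e3, rel=0.01)

    def test_zero_current_zero_activity(self, chain):
        t = np.arange(0.0, 3600.0, 60.0)
        act, sig = integrate_to_activity(_trace(t, 0.0), chain["Ac-225"], noise_sigma_a=0.0)
        assert act == 0.0 and sig == 0.0

    def test_distant_t_ref_decays_everything(self, chain):
        t = np.arange(0.0, 3600.0, 60.0)
        act, _ = integrate_to_activity(
            _trace(t, 1 * PA), chain["Fr-221"], t_ref=t[-1] + 100 * 288.0,
            noise_sigma_a=0.0,
        )
        assert act < 1e-20  # ~30 orders below the undecayed equivalent

    def test_fc_in_samples_excluded(self, chain):
        t = np.arange(0.0, 7200.0 + 1, 10.0)
        fc = (t >= 3600.0)
        a_half, _ = integrate_to_activity(
            _trace(t, 1 * PA, fc_in=fc), chain["Ac-225"], noise_sigma_a=0.0
        )
        a_full, _ = integrate_to_activity(
            _trace(t, 1 * PA), chain["Ac-225"], noise_sigma_a=0.0
        )
        assert a_half < 0.52 * a_full

    def test_linear_in_lambda_for_small_lambda(self, chain):
        """λ→0: equivalent activity → λ × (ions delivered), linear over
        three decades of λ."""
        t = np.arange(0.0, 3600.0 + 1, 10.0)
        tr = _trace(t, 1 * PA)
        ions = 1e-12 * 3600.0 / E_CHARGE
        for half_life in (1e9, 1e10, 1e11):
            nuc = type(chain["Ac-225"])(
                name="X", half_life_s=half_life,
                decay_modes=(type(chain["Ac-225"].decay_modes[0])("alpha", 1.0, "X"),),
            )
            lam = math.log(2) / half_life
            act, _ = integrate_to_activity(tr, nuc, noise_sigma_a=0.0)
            assert act == pytest.approx(lam * ions, rel=1e-3)

    def test_additive_over_disjoint_subtraces(self, chain):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 7200.0 + 1, 10.0)
        cur = rng.normal(1.0, 0.1, len(t)) * PA
        tr = _trace(t, cur)
        t_ref = float(t[-1])
        k = len(t) // 2
        a_full, _ = integrate_to_activity(tr, chain["Ac-225"], t_ref=t_ref, noise_sigma_a=0.0)
        a_1, _ = integrate_to_activity(
            CurrentTrace(tr.data.iloc[: k + 1].reset_index(drop=True)),
            chain["Ac-225"], t_ref=t_ref, noise_sigma_a=0.0,
        )
        a_2, _ = integrate_to_activity(
            CurrentTrace(tr.data.iloc[k:].reset_index(drop=True)),
            chain["Ac-225"], t_ref=t_ref, noise_sigma_a=0.0,
        )
        assert a_1 + a_2 == pytest.approx(a_full, rel=1e-9)


class TestGapLoss:
    def _trace_with_gap(self, donor_current, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 7200.0 + 1, 60.0)
        gap = (t >= 3000.0) & (t <= 4200.0)
        cur = np.full(len(t), donor_current)
        if noise:
            cur = rng.normal(donor_current, noise, len(t))
        cur[gap] = 0.0
        return _trace(t, cur, fc_in=gap, collecting=~gap), (3000.0, 4200.0)

    def test_constant_donor_pool_deterministic(self, chain):
        tr, gap = self._trace_with_gap(1 * PA)
        loss = estimate_gap_loss(tr, gap, chain["Ac-225"], n_resamples=50)
        lam = chain["Ac-225"].lam
        expected = lam * (1e-12 / E_CHARGE) * (gap[1] - gap[0])
        assert loss.activity == pytest.approx(expected, rel=0.05)
        assert loss.sigma <= 1e-12 * loss.activity  # identical draws: only float jitter

    def test_single_resample_sigma_indeterminate(self, chain):
        tr, gap = self._trace_with_gap(1 * PA)
        loss = estimate_gap_loss(tr, gap, chain["Ac-225"], n_resamples=1)
        assert math.isnan(loss.sigma)

    def test_noisy_donor_pool_unbiased(self, chain):
        tr, gap = self._trace_with_gap(1 * PA, noise=0.1 * PA, seed=4)
        loss = estimate_gap_loss(tr, gap, chain["Ac-225"], n_resamples=1000, seed=12)
        lam = chain["Ac-225"].lam
        expected = lam * (1e-12 / E_CHARGE) * (gap[1] - gap[0])
        assert abs(loss.activity - expected) < 3 * loss.sigma + 0.02 * expected

    def test_empty_donor_pool_suggests_wider_tolerance(self, chain):
        tr, gap = self._trace_with_gap(1 * PA)
        df = tr.data.copy()
        df.loc[~df.fc_in, "heater_current_a"] = 700.0  # donors far from gap's heater
        with pytest.raises(BeamCurrentError, match="tolerance"):
            estimate_gap_loss(CurrentTrace(df), gap, chain["Ac-225"])

    def test_bootstrap_convergence_rate(self, chain):
        """sd of the mean of the loss estimate shrinks ~1/√n_resamples."""
        tr, gap = self._trace_with_gap(1 * PA, noise=0.2 * PA, seed=8)
        means = {n: [] for n in (25, 400)}
        for rep in range(12):
            for n in means:
                loss = estimate_gap_loss(
                    tr, gap, chain["Ac-225"], n_resamples=n, seed=100 + rep
                )
                means[n].append(loss.activity)
        sd25 = np.std(means[25], ddof=1)
        sd400 = np.std(means[400], ddof=1)
        assert sd400 < sd25  # 4× fewer: expect ≈ 4× smaller sd of the mean
        assert sd25 / sd400 == pytest.approx(4.0, rel=0.8)
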