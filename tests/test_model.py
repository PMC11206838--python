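import numpy as np
import pytest

from balancefb import model as mdl
from balancefb import synthetic as syn
from balancefb.model import (
    ROLE_PF,
    ROLE_TA,
    FeedbackGains,
    ModelConfig,
    RoleError,
    baseline_activity,
    cost_improvement,
    fit_both_variants,
    fit_gains,
    gate_stiction,
    goodness_of_fit,
    identifiable_gains,
    model_cost,
    reconstruct_emg,
)
from .conftest import make_com


@pytest.fixture
def grid():
    return np.arange(-60, 151) * 0.01


class TestGateStiction:
    def test_constant_ankle_gate_never_closes(self, grid, rng):
        a = rng.normal(size=grid.size)
        out = gate_stiction(grid, a, np.zeros(grid.size), 0.5)
        np.testing.assert_array_equal(out[grid >= 0], a[grid >= 0])
        np.testing.assert_array_equal(out[grid < 0], 0.0)

    def test_ramp_closes_at_expected_time(self, grid):
        # 5 deg/s ramp, 0.5 deg threshold -> gate closes at t = 0.1 s
        ankle = np.where(grid >= 0, 5.0 * grid, 0.0)
        a = np.ones(grid.size)
        out = gate_stiction(grid, a, ankle, 0.5)
        assert np.all(out[(grid >= 0) & (grid < 0.1 - 1e-12)] == 1.0)
        assert np.all(out[grid >= 0.1 - 1e-12] == 0.0)

    def test_zero_threshold_all_zero(self, grid, rng):
        out = gate_stiction(grid, rng.normal(size=grid.size),
                            np.zeros(grid.size), 0.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_negative_threshold_rejected(self, grid):
        with pytest.raises(ValueError):
            gate_stiction(grid, np.zeros(grid.size), np.zeros(grid.size), -1.0)


class TestReconstruct:
    def test_zero_gains_returns_e0(self, grid, level2):
        _, com, _ = level2
        g = FeedbackGains(e0=0.1)
        res = reconstruct_emg(g, com, ModelConfig(), ROLE_PF)
        np.testing.assert_allclose(res.emg_recon, 0.1, atol=1e-14)

    def test_constant_displacement(self, grid):
        com = make_com(grid, d=np.full(grid.size, 0.05),
                       v=np.zeros(grid.size), a=np.zeros(grid.size))
        g = FeedbackGains(k_d=1.0, e0=0.0)
        res = reconstruct_emg(g, com, ModelConfig(), ROLE_PF)
        # constant channel: delayed copy + quiet-stance fill are both 0.05
        np.testing.assert_allclose(res.emg_recon, 0.05, atol=1e-14)

    def test_antagonistic_sign_bookkeeping(self, grid):
        com = make_com(grid, d=np.zeros(grid.size),
                       v=np.full(grid.size, -0.2), a=np.zeros(grid.size))
        g = FeedbackGains(k_vp=1.0, e0=0.03)
        res = reconstruct_emg(g, com, ModelConfig(), ROLE_PF)
        np.testing.assert_allclose(res.antagonistic, 0.2, atol=1e-14)
        np.testing.assert_allclose(res.balance_correcting, 0.03, atol=1e-14)

    def test_ks_for_ta_rejected(self, grid, level2):
        _, com, _ = level2
        g = FeedbackGains(k_s=0.5)
        with pytest.raises(RoleError):
            reconstruct_emg(g, com, ModelConfig(), ROLE_TA)

    def test_delay_is_exact_ten_sample_shift(self, level2, rng):
        _, com, _ = level2
        g = FeedbackGains(k_d=1.5, k_v=0.7, k_a=0.1, k_s=0.2, e0=0.05)
        res = reconstruct_emg(g, com, ModelConfig(tau=0.1), ROLE_PF)
        # shift oracle: build the linear combination, shift by 10 samples
        lin = (g.e0 + g.k_d * com.d + g.k_v * com.v + g.k_a * com.a
               + g.k_s * com.a_init)
        shifted = np.empty_like(lin)
        fill = np.mean(lin[com.t < 0])
        shifted[:10] = fill
        shifted[10:] = lin[:-10]
        np.testing.assert_allclose(res.emg_recon, np.maximum(shifted, 0.0),
                                   atol=1e-12)

    def test_pathway_exclusivity_monotone_inputs(self, grid):
        # all kinematics >= 0 -> TA balance-correcting (beyond e0) is 0
        pos = np.clip(np.sin(np.linspace(0, np.pi, grid.size)), 0, None)
        com = make_com(grid, d=pos * 0.05, v=pos * 0.2, a=pos)
        g = FeedbackGains(k_d=2.0, k_v=2.0, k_a=2.0, k_s=None, e0=0.0)
        res = reconstruct_emg(g, com, ModelConfig(), ROLE_TA)
        np.testing.assert_allclose(res.balance_correcting, 0.0, atol=1e-14)

    def test_contributions_nonnegative_and_sum(self, level2, cp_gains):
        _, com, _ = level2
        res = reconstruct_emg(cp_gains.gains["LG"], com, ModelConfig(), ROLE_PF)
        assert np.all(res.balance_correcting >= 0)
        assert np.all(res.antagonistic >= 0)
        np.testing.assert_allclose(
            res.emg_recon, res.balance_correcting + res.antagonistic)


class TestCost:
    def test_perfect_fit_no_primes_zero_cost(self, level2, td_gains):
        _, com, _ = level2
        g = FeedbackGains(k_d=1.0, k_v=0.5, k_a=0.1, k_s=0.2, e0=0.05)
        measured = reconstruct_emg(g, com, ModelConfig(), ROLE_PF).emg_recon
        assert model_cost(g, measured, com, ModelConfig(), ROLE_PF) == \
            pytest.approx(0.0, abs=1e-18)

    def test_penalty_only_case(self, grid):
        # antagonist input never positive: PF prime gains see -d,-v,-a
        # with all-positive kinematics, so ANT == 0 and only the
        # quadratic penalty remains
        pos = np.full(grid.size, 0.1)
        com = make_com(grid, d=pos, v=pos, a=pos)
        base = FeedbackGains(e0=0.02)
        measured = reconstruct_emg(base, com, ModelConfig(), ROLE_PF).emg_recon
        g = FeedbackGains(k_vp=2.0, e0=0.02)
        cost = model_cost(g, measured, com, ModelConfig(), ROLE_PF)
        assert cost == pytest.approx(1e-4 * 4.0, rel=1e-12)

    def test_matches_bruteforce_sum(self, level2, cp_gains, rng):
        _, com, _ = level2
        cfg = ModelConfig()
        g = cp_gains.gains["MG"]
        measured = rng.uniform(0, 0.5, com.t.size)
        cost = model_cost(g, measured, com, cfg, ROLE_PF)
        recon = reconstruct_emg(g, com, cfg, ROLE_PF).emg_recon
        mask = (com.t >= cfg.fit_window[0] - 1e-9) & \
               (com.t <= cfg.fit_window[1] + 1e-9)
        brute = sum((recon[i] - measured[i]) ** 2
                    for i in range(com.t.size) if mask[i])
        brute += 1e-4 * (g.k_dp**2 + g.k_vp**2 + g.k_ap**2)
        assert cost == pytest.approx(brute, rel=1e-12)


class TestFit:
    def test_noiseless_recovery(self, level2):
        _, com, _ = level2
        cfg = ModelConfig()
        truth = syn.archetype_gains("CP_like").gains["LG"]
        measured = reconstruct_emg(truth, com, cfg, ROLE_PF).emg_recon
        fit, rec = fit_gains(measured, com, cfg, ROLE_PF)
        ident = identifiable_gains(truth, com, cfg, ROLE_PF)
        for name, val in truth.as_dict().items():
            if name == "e0" or val is None or not ident.get(name, False):
                continue
            if val > 1e-6:
                assert abs(fit.as_dict()[name] - val) / val < 0.01, name

    def test_constant_measured_gains_to_zero(self, level2):
        _, com, _ = level2
        measured = np.full(com.t.size, 0.07)
        fit, _ = fit_gains(measured, com, ModelConfig(), ROLE_PF)
        assert fit.e0 == pytest.approx(0.07)
        for name, val in fit.as_dict().items():
            if name != "e0" and val is not None:
                assert abs(val) < 1e-3, name

    def test_extended_never_worse_than_simple(self, level2, rng):
        _, com, _ = level2
        cfg = ModelConfig(n_starts=5)
        truth = syn.archetype_gains("CP_like").gains["SOL"]
        measured = np.clip(
            reconstruct_emg(truth, com, cfg, ROLE_PF).emg_recon
            + rng.normal(0, 0.02, com.t.size), 0, None)
        (_, r_s), (_, r_e), improvement = fit_both_variants(
            measured, com, cfg, ROLE_PF)
        assert r_e.cost <= r_s.cost + 1e-12
        assert improvement >= -1e-9

    def test_grid_search_two_gain_oracle(self, level2):
        # restrict to (k_d, k_v): fitter matches exhaustive 0.01 grid
        _, com, _ = level2
        cfg = ModelConfig()
        truth = FeedbackGains(k_d=1.30, k_v=0.70, e0=0.05)
        measured = reconstruct_emg(truth, com, cfg, ROLE_PF).emg_recon
        reg = mdl._Regressors(com, cfg)
        mask = reg.fit_mask
        kds = np.arange(0.0, 3.0 + 1e-9, 0.01)
        kvs = np.arange(0.0, 3.0 + 1e-9, 0.01)
        best = (np.inf, None, None)
        meas = measured[mask]
        for kd in kds:
            base = truth.e0 + kd * reg.d
            recs = np.maximum(base[None, :] + kvs[:, None] * reg.v[None, :], 0)
            sse = np.sum((recs[:, mask] - meas[None, :]) ** 2, axis=1)
            j = int(np.argmin(sse))
            if sse[j] < best[0]:
                best = (sse[j], kd, kvs[j])
        fit, _ = fit_gains(measured, com, cfg, ROLE_PF)
        assert abs(fit.k_d - best[1]) <= 0.01 + 1e-9
        assert abs(fit.k_v - best[2]) <= 0.01 + 1e-9

    def test_bound_flags(self):
        g = FeedbackGains(k_d=10.0, k_v=0.5, k_s=1e-7, e0=0.1)
        flags = g.bound_flags((0.0, 10.0))
        assert flags["k_d"] and flags["k_s"] and not flags["k_v"]


class TestGoodnessOfFit:
    def test_perfect(self, grid, rng):
        m = rng.uniform(0, 1, grid.size)
        r2, vaf, rmse = goodness_of_fit(m, m, grid)
        assert (r2, vaf, rmse) == (pytest.approx(1.0), pytest.approx(1.0),
                                   pytest.approx(0.0))

    def test_shifted(self, grid, rng):
        m = rng.uniform(0, 1, grid.size)
        r2, vaf, rmse = goodness_of_fit(m, m + 0.1, grid)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert vaf < 1.0
        assert rmse == pytest.approx(0.1, abs=1e-12)

    def test_textbook_oracle(self, grid, rng):
        m = rng.uniform(0, 1, grid.size)
        r = rng.uniform(0, 1, grid.size)
        r2, vaf, rmse = goodness_of_fit(m, r, grid, window=(0.0, 1.5))
        mask = (grid >= -1e-9) & (grid <= 1.5 + 1e-9)
        mm, rr = m[mask], r[mask]
        r2_ref = (np.sum((mm - mm.mean()) * (rr - rr.mean())) /
                  np.sqrt(np.sum((mm - mm.mean())**2)
                          * np.sum((rr - rr.mean())**2)))**2
        vaf_ref = 1 - np.sum((mm - rr)**2) / np.sum(mm**2)
        rmse_ref = np.sqrt(np.mean((mm - rr)**2))
        assert r2 == pytest.approx(r2_ref, abs=1e-12)
        assert vaf == pytest.approx(vaf_ref, abs=1e-12)
        assert rmse == pytest.approx(rmse_ref, abs=1e-12)

    def test_constant_measured_warns(self, grid):
        with pytest.warns(UserWarning):
            r2, vaf, rmse = goodness_of_fit(np.full(grid.size, 0.5),
                                            np.full(grid.size, 0.4), grid)
        assert np.isnan(r2)
        assert rmse == pytest.approx(0.1)


class TestCostImprovement:
    def test_equal_costs(self):
        assert cost_improvement(1.0, 1.0) == 0.0

    def test_twenty_percent(self):
        assert cost_improvement(1.0, 0.8) == pytest.approx(20.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cost_improvement(0.0, 0.0)


class TestBaseline:
    def test_pre_onset_mean(self, grid):
        env = np.where(grid < 0, 0.2, 0.9)
        assert baseline_activity(grid, env, (-0.5, 0.0)) == pytest.approx(0.2)
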