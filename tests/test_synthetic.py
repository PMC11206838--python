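import os

import numpy as np
import pytest

from balancefb import model as mdl
from balancefb import synthetic as syn
from balancefb.dataio import MUSCLES, load_manifest
from balancefb.model import FeedbackGains, ModelConfig, ROLE_PF, reconstruct_emg
from balancefb.synthetic import (
    NoiseModel,
    ParameterError,
    archetype_gains,
    draw_subject_gains,
    generate_cohort,
    generate_emg,
    load_ground_truth,
    make_com_ankle,
    make_profile,
    raised_cosine_step,
    raised_cosine_step_vel,
)


class TestProfiles:
    def test_velocity_monotone_in_level(self):
        profiles = [make_profile(lv) for lv in (1, 2, 3, 4)]
        speeds = [p.peak_trans_speed for p in profiles]
        assert speeds == sorted(speeds) and len(set(speeds)) == 4
        rot = [p.peak_rot_speed for p in profiles]
        assert rot == sorted(rot) and len(set(rot)) == 4

    def test_profiles_start_and_end_at_rest(self):
        for lv in (1, 2, 3, 4):
            p = make_profile(lv)
            assert p.trans_vel[0] == 0 and abs(p.trans_vel[-1]) < 1e-12
            assert p.rot_vel[0] == 0 and abs(p.rot_vel[-1]) < 1e-12

    def test_zero_amplitudes_zero_profile(self):
        p = make_profile(1, params={"trans_amp_m": (0, 0, 0, 0),
                                    "rot_amp_deg": (0, 0, 0, 0)})
        assert np.all(p.trans_disp == 0) and np.all(p.rot_angle == 0)

    def test_closed_form_derivative_oracle(self):
        h = 1e-4
        t = np.arange(0, 1, h)
        disp = raised_cosine_step(t, 0.1, 0.3, 0.06)
        vel = raised_cosine_step_vel(t, 0.1, 0.3, 0.06)
        num = np.gradient(disp, h)
        # the step is C^1 only at its end points; compare away from them
        smooth = (np.abs(t - 0.1) > 2 * h) & (np.abs(t - 0.4) > 2 * h)
        assert np.max(np.abs(num[smooth] - vel[smooth])) < 1e-6

    def test_invalid_level(self):
        with pytest.raises(ParameterError):
            make_profile(5)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            make_profile(1, params={"trans_amp_m": (-0.1, 0, 0, 0)})


class TestComAnkle:
    @pytest.mark.parametrize("level", [1, 2, 3, 4])
    def test_single_velocity_reversal(self, level):
        t, com, _ = syn.level_kinematics(level)
        post = (t > 0) & (t <= 1.5)
        v = com.v[post]
        signs = np.sign(v[np.abs(v) > 1e-12])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1
        assert v[np.abs(v) > 1e-12][0] > 0  # forward first

    def test_zero_profile_zero_response(self):
        p = make_profile(1, params={"trans_amp_m": (0, 0, 0, 0),
                                    "rot_amp_deg": (0, 0, 0, 0)})
        t, com_pos, ankle = make_com_ankle(p)
        np.testing.assert_allclose(com_pos, com_pos[0])
        np.testing.assert_allclose(ankle, ankle[0])

    def test_doubled_translation_larger_peak(self):
        p1 = make_profile(2)
        p2 = make_profile(2, params={"trans_amp_m": (0.12, 0.12, 0.16, 0.16)})
        _, d1, _ = make_com_ankle(p1)
        _, d2, _ = make_com_ankle(p2)
        assert np.max(d2 - d2[0]) > np.max(d1 - d1[0])

    def test_ankle_crosses_threshold_early(self):
        for level in (1, 2, 3, 4):
            t, _, ankle_change = syn.level_kinematics(level)
            crossed = t[(t >= 0) & (np.abs(ankle_change) >= 0.5)]
            assert crossed.size and crossed[0] < 0.15

    def test_ankle_monotone_early(self):
        t, _, ankle = syn.level_kinematics(3)
        early = ankle[(t >= 0) & (t <= 0.2)]
        assert np.all(np.diff(early) >= -1e-12)


class TestGenerateEmg:
    def test_zero_gains_constant_envelope(self, level2):
        _, com, _ = level2
        gt = syn.GroundTruthGains(
            gains={m: FeedbackGains(k_s=None if m == "TA" else 0.0, e0=0.1)
                   for m in MUSCLES})
        env = generate_emg(com, gt, NoiseModel(sd=0.0))
        for m in MUSCLES:
            np.testing.assert_allclose(env[m], 0.1, atol=1e-14)

    def test_ta_silent_forward_active_after_reversal(self, level2):
        _, com, _ = level2
        t = com.t
        gains = archetype_gains("TD_like")
        # pure balance-correcting TA (primes zero), no baseline
        ta = FeedbackGains(k_d=0.8, k_v=0.6, k_a=0.0, k_s=None, e0=0.0)
        gt = syn.GroundTruthGains(gains={**gains.gains, "TA": ta})
        env = generate_emg(com, gt, NoiseModel(sd=0.0))["TA"]
        reversal = t[(t > 0) & (com.v <= 0)][0]
        tau = 0.1
        forward = (t > 0) & (t < reversal + tau - 1e-9)
        assert np.max(env[forward]) < 1e-9
        assert np.max(env[t > reversal + tau]) > 0.01

    def test_cp_persistence_and_higher_cci(self, level2):
        _, com, _ = level2
        t = com.t
        envs = {}
        for arch in ("TD_like", "CP_like"):
            envs[arch] = generate_emg(com, archetype_gains(arch),
                                      NoiseModel(sd=0.01),
                                      np.random.default_rng(7))
        reversal = t[(t > 0) & (com.v <= 0)][0]
        late = t > reversal + 0.2
        # PF activity persists after reversal in the CP-like archetype
        assert np.mean(envs["CP_like"]["LG"][late]) > \
            np.mean(envs["TD_like"]["LG"][late])
        from balancefb.cci import cci
        for pf in ("LG", "MG", "SOL"):
            c_cp = cci(envs["CP_like"][pf], envs["CP_like"]["TA"], t, (0, 0.4))
            c_td = cci(envs["TD_like"][pf], envs["TD_like"]["TA"], t, (0, 0.4))
            assert c_cp.cci > c_td.cci

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ParameterError):
            NoiseModel(sd=-0.1)

    def test_true_gains_are_noiseless_optimum(self, level2):
        _, com, _ = level2
        cfg = ModelConfig()
        truth = archetype_gains("TD_like").gains["LG"]
        measured = reconstruct_emg(truth, com, cfg, ROLE_PF).emg_recon
        c0 = mdl.model_cost(truth, measured, com, cfg, ROLE_PF)
        rng = np.random.default_rng(3)
        x = truth.vector(ROLE_PF)
        for _ in range(25):
            pert = np.clip(x + rng.normal(0, 0.05, x.size), 0, 10)
            g = FeedbackGains.from_vector(pert, ROLE_PF, truth.e0)
            # compare data terms only (penalty excluded): the truth is a
            # global optimum of the SSE
            sse0 = c0 - cfg.penalty_weight * (truth.k_dp**2 + truth.k_vp**2
                                              + truth.k_ap**2)
            sse = mdl.model_cost(g, measured, com, cfg, ROLE_PF) \
                - cfg.penalty_weight * (g.k_dp**2 + g.k_vp**2 + g.k_ap**2)
            assert sse >= sse0 - 1e-12


class TestDrawGains:
    def test_within_bounds(self, rng):
        for arch in ("TD_like", "CP_like"):
            gt = draw_subject_gains(arch, rng)
            for m, g in gt.gains.items():
                for name, val in g.as_dict().items():
                    if val is not None:
                        assert 0.0 <= val <= 10.0

    def test_identifiability_report_covers_all(self, td_gains):
        report = syn.identifiability_report(td_gains, level=2)
        assert set(report) == set(MUSCLES)
        # BC velocity gain must be identifiable on every default trajectory
        assert all(report[m]["k_v"] for m in MUSCLES)


class TestCohort:
    def test_seeded_determinism(self, tmp_path):
        kw = dict(n_per_group=1, trials_per_level=2, levels=(1,),
                  noise=NoiseModel(sd=0.02), seed=7)
        generate_cohort(str(tmp_path / "a"), **kw)
        generate_cohort(str(tmp_path / "b"), **kw)
        files_a = sorted(os.listdir(tmp_path / "a" / "trials"))
        files_b = sorted(os.listdir(tmp_path / "b" / "trials"))
        assert files_a == files_b
        for f in files_a:
            assert (tmp_path / "a" / "trials" / f).read_bytes() == \
                (tmp_path / "b" / "trials" / f).read_bytes()

    def test_counts(self, tmp_path):
        manifest = generate_cohort(str(tmp_path), n_per_group=2,
                                   trials_per_level=2, levels=(1, 2), seed=1)
        assert len(manifest) == 2 * 2 * 2 * 2
        loaded = load_manifest(str(tmp_path / "manifest.yaml"))
        assert len(loaded) == len(manifest)

    def test_ground_truth_sidecar_roundtrip(self, tmp_path):
        generate_cohort(str(tmp_path), n_per_group=1, trials_per_level=1,
                        levels=(1,), seed=3)
        truth = load_ground_truth(str(tmp_path / "ground_truth.yaml"))
        assert set(truth) == {"CP01", "TD01"}
        assert truth["CP01"].archetype == "CP_like"
        assert truth["TD01"].gains["TA"].k_s is None

    def test_stepped_flags_never_whole_level(self, tmp_path):
        manifest = generate_cohort(str(tmp_path), n_per_group=1,
                                   trials_per_level=4, levels=(1, 2),
                                   seed=5, step_prob=0.7)
        for subject in ("CP01", "TD01"):
            for level in (1, 2):
                flags = [e.stepped for e in manifest.entries
                         if e.subject_id == subject and e.level == level]
                assert not all(flags)

    def test_prime_velocity_ordering_recovered(self):
        # 2 subjects per group, one level, light noise: median fitted
        # k_v' preserves the CP > TD ordering of the generator
        cfg = ModelConfig()
        _, com, _ = syn.level_kinematics(2)
        fitted = {"CP_like": [], "TD_like": []}
        rng = np.random.default_rng(11)
        for arch in fitted:
            for _ in range(2):
                gt = draw_subject_gains(arch, rng, cv=0.1)
                env = generate_emg(com, gt, NoiseModel(sd=0.005), rng)
                g, _ = mdl.fit_gains(env["LG"], com, cfg, ROLE_PF)
                fitted[arch].append(g.k_vp)
        assert np.median(fitted["CP_like"]) > np.median(fitted["TD_like"])

    def test_raw_emg_mode_survives_filter_chain(self, tmp_path):
        # raw-style 1000 Hz interference signals, demodulated by the
        # preprocessing chain, keep the CP > TD co-contraction ordering
        from balancefb.config import load_config
        from balancefb.pipeline import analyze_dataset, emg_mode_of

        manifest = generate_cohort(str(tmp_path), n_per_group=1,
                                   trials_per_level=2, levels=(1,),
                                   seed=3, raw_emg=True)
        assert emg_mode_of(str(tmp_path / "manifest.yaml")) == "raw"
        out = analyze_dataset(manifest, load_config(None), emg_mode="raw",
                              fit_models=False)
        cci_rows = out.cohort_table[out.cohort_table["outcome"] == "cci"]
        means = cci_rows.groupby("subject_id")["value"].mean()
        assert means["CP01"] > means["TD01"]
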