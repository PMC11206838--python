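"""Synthetic perturbation trials with known ground-truth gains.

The study's recordings are emulated at the signal level: platform
profiles are smooth raised-cosine pulses (backward translation followed
by an overlapping toe-up rotation), the induced CoM velocity is built
from two opposing unimodal pulses whose overlap guarantees exactly one
forward-to-backward reversal in (0, 1.5] s, the ankle dorsiflexes early
and monotonically (crossing the 0.5 deg stiction threshold well before
150 ms), and muscle envelopes are produced by forward evaluation of the
same delayed-feedback equations the fitter estimates, plus seeded
Gaussian envelope noise clipped at zero.

Two group archetypes are provided: ``TD_like`` with near-zero
antagonistic (prime) gains and ``CP_like`` with elevated
balance-correcting velocity gains and prime-velocity gains 5x the
TD-like mean, so that co-contraction separates the groups.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import dataio
from .dataio import (
    MUSCLES,
    DatasetManifest,
    ManifestEntry,
    TrialRecording,
    entry_for,
    save_manifest,
    write_trial,
)
from .model import (
    ROLE_PF,
    ROLE_TA,
    FeedbackGains,
    ModelConfig,
    identifiable_gains,
    reconstruct_emg,
    role_of,
)
from .preprocess import (
    ANALYSIS_RATE,
    ANALYSIS_WINDOW,
    ComKinematics,
    analysis_grid,
    com_kinematics,
)

# ---------------------------------------------------------------------------
# smooth pulse primitives (closed forms used as oracles in tests)


def raised_cosine_step(t: np.ndarray, t0: float, dur: float, amp: float) -> np.ndarray:
    """Smooth step from 0 to ``amp`` over [t0, t0 + dur] (C^1, zero
    velocity at both ends)."""
    t = np.asarray(t, dtype=float)
    x = np.clip((t - t0) / dur, 0.0, 1.0)
    return amp * 0.5 * (1.0 - np.cos(np.pi * x))


def raised_cosine_step_vel(t, t0, dur, amp):
    t = np.asarray(t, dtype=float)
    x = (t - t0) / dur
    inside = (x > 0) & (x < 1)
    out = np.zeros_like(t)
    out[inside] = amp * np.pi / (2.0 * dur) * np.sin(np.pi * x[inside])
    return out


def raised_cosine_step_acc(t, t0, dur, amp):
    t = np.asarray(t, dtype=float)
    x = (t - t0) / dur
    inside = (x > 0) & (x < 1)
    out = np.zeros_like(t)
    out[inside] = amp * np.pi**2 / (2.0 * dur**2) * np.cos(np.pi * x[inside])
    return out


def raised_cosine_bump(t: np.ndarray, t0: float, dur: float) -> np.ndarray:
    """Unimodal non-negative pulse on [t0, t0 + dur], peak 1 at the
    midpoint, zero (with zero slope) at both ends."""
    t = np.asarray(t, dtype=float)
    x = (t - t0) / dur
    inside = (x > 0) & (x < 1)
    out = np.zeros_like(t)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    return out


# ---------------------------------------------------------------------------
# perturbation profiles

#: per-level platform amplitudes: displacement grows only from L2 to L3,
#: peak velocity and acceleration grow with every level (durations shrink)
DEFAULT_PROFILE_PARAMS = {
    "trans_amp_m": (0.06, 0.06, 0.08, 0.08),
    "trans_dur_s": (0.30, 0.26, 0.24, 0.20),
    "rot_amp_deg": (5.0, 6.0, 7.0, 8.0),
    "rot_dur_s": (0.35, 0.30, 0.28, 0.25),
    "rot_delay_s": 0.15,
    "duration_s": 1.5,
}


class ParameterError(ValueError):
    pass


@dataclass
class PerturbationProfile:
    """Platform kinematics for one level (translation negative =
    backward; rotation positive = toe-up)."""

    level: int
    t: np.ndarray
    trans_disp: np.ndarray
    trans_vel: np.ndarray
    trans_acc: np.ndarray
    rot_angle: np.ndarray
    rot_vel: np.ndarray
    rot_acc: np.ndarray
    duration: float
    params: dict = field(default_factory=dict)

    @property
    def peak_trans_speed(self) -> float:
        return float(np.max(np.abs(self.trans_vel)))

    @property
    def peak_rot_speed(self) -> float:
        return float(np.max(np.abs(self.rot_vel)))


def make_profile(
    level: int,
    params: Optional[dict] = None,
    rate: float = ANALYSIS_RATE,
) -> PerturbationProfile:
    """Raised-cosine platform pulses for one perturbation level."""
    if level not in (1, 2, 3, 4):
        raise ParameterError(f"level must be 1-4, got {level}")
    p = dict(DEFAULT_PROFILE_PARAMS)
    if params:
        p.update(params)
    i = level - 1
    ta, td = p["trans_amp_m"][i], p["trans_dur_s"][i]
    ra, rd = p["rot_amp_deg"][i], p["rot_dur_s"][i]
    delay = p["rot_delay_s"]
    if ta < 0 or ra < 0 or td <= 0 or rd <= 0:
        raise ParameterError("profile amplitudes/durations must be non-negative")
    t = np.arange(0.0, p["duration_s"] + 0.5 / rate, 1.0 / rate)
    return PerturbationProfile(
        level=level,
        t=t,
        trans_disp=-raised_cosine_step(t, 0.0, td, ta),
        trans_vel=-raised_cosine_step_vel(t, 0.0, td, ta),
        trans_acc=-raised_cosine_step_acc(t, 0.0, td, ta),
        rot_angle=raised_cosine_step(t, delay, rd, ra),
        rot_vel=raised_cosine_step_vel(t, delay, rd, ra),
        rot_acc=raised_cosine_step_acc(t, delay, rd, ra),
        duration=p["duration_s"],
        params=p,
    )


# ---------------------------------------------------------------------------
# induced CoM / ankle trajectories

DEFAULT_RESPONSE_PARAMS = {
    # CoM forward velocity pulse (response to backward translation)
    "fwd_gain": 0.35,       # peak fwd CoM speed / peak platform speed
    "fwd_onset_s": 0.05,
    "fwd_dur_s": 0.35,
    # CoM backward velocity pulse (response to toe-up rotation)
    "bwd_gain": 0.30,       # peak bwd CoM speed / peak rot speed (rad/s)
    "bwd_onset_s": 0.30,
    "bwd_dur_s": 0.70,
    # ankle dorsiflexion (deg) driven by the rotation
    "ankle_gain": 0.8,      # peak ankle change / rotation amplitude
    "ankle_rise_s": 0.30,
    # quiet-stance offsets
    "com_offset_m": 0.05,
    "ankle_offset_deg": 2.0,
}


def make_com_ankle(
    profile: PerturbationProfile,
    response_params: Optional[dict] = None,
    window: Tuple[float, float] = ANALYSIS_WINDOW,
    rate: float = ANALYSIS_RATE,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Induced CoM position and ankle angle on the onset-referenced grid.

    The CoM velocity is the difference of a forward pulse (translation
    response) and a delayed, longer backward pulse (rotation response);
    on their overlap the forward pulse is strictly decreasing and the
    backward pulse strictly increasing, so the velocity changes sign
    exactly once in (0, 1.5] s.  Ankle dorsiflexion rises monotonically
    from onset, crossing 0.5 deg within ~70 ms.

    Returns ``(t, com_pos, ankle_angle)`` in absolute units (offsets
    included); both series are flat before onset.
    """
    rp = dict(DEFAULT_RESPONSE_PARAMS)
    if response_params:
        rp.update(response_params)
    t = analysis_grid(window, rate)
    v_fwd_peak = rp["fwd_gain"] * profile.peak_trans_speed
    v_bwd_peak = rp["bwd_gain"] * np.deg2rad(profile.peak_rot_speed)
    v = v_fwd_peak * raised_cosine_bump(t, rp["fwd_onset_s"], rp["fwd_dur_s"]) \
        - v_bwd_peak * raised_cosine_bump(t, rp["bwd_onset_s"], rp["bwd_dur_s"])
    dt = 1.0 / rate
    d = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    d -= d[np.argmin(np.abs(t))]  # zero displacement at onset
    ankle_amp = rp["ankle_gain"] * float(np.max(profile.rot_angle))
    ankle = raised_cosine_step(t, 0.0, rp["ankle_rise_s"], ankle_amp)
    ankle[t < 0] = 0.0
    com_pos = rp["com_offset_m"] + d
    ankle_angle = rp["ankle_offset_deg"] + ankle
    return t, com_pos, ankle_angle


_KINEMATICS_CACHE: Dict[tuple, Tuple[np.ndarray, ComKinematics, np.ndarray]] = {}


def level_kinematics(
    level: int,
    stiction_threshold: float = 0.5,
    rate: float = ANALYSIS_RATE,
    window: Tuple[float, float] = ANALYSIS_WINDOW,
) -> Tuple[np.ndarray, ComKinematics, np.ndarray]:
    """Default-parameter CoM kinematics and ankle change for one level
    on the analysis grid (cached; the construction is deterministic).

    Returns ``(t, com, ankle_change)``.
    """
    key = (level, stiction_threshold, rate, window)
    if key not in _KINEMATICS_CACHE:
        profile = make_profile(level, rate=rate)
        t, com_pos, ankle_angle = make_com_ankle(profile, window=window, rate=rate)
        onset_idx = int(np.argmin(np.abs(t)))
        ankle_change = ankle_angle - ankle_angle[onset_idx]
        d_rel = com_pos - DEFAULT_RESPONSE_PARAMS["com_offset_m"]
        com = com_kinematics(t, d_rel, ankle_change, stiction_threshold)
        _KINEMATICS_CACHE[key] = (t, com, ankle_change)
    return _KINEMATICS_CACHE[key]


# ---------------------------------------------------------------------------
# ground-truth gains and noise

#: archetype mean gains; prime-velocity mean is 5x higher in CP_like
ARCHETYPES: Dict[str, Dict[str, Dict[str, float]]] = {
    "TD_like": {
        "PF": dict(k_d=1.2, k_v=0.8, k_a=0.12, k_s=0.3,
                   k_dp=0.05, k_vp=0.2, k_ap=0.05, e0=0.05),
        "TA": dict(k_d=0.8, k_v=0.6, k_a=0.08,
                   k_dp=0.05, k_vp=0.2, k_ap=0.05, e0=0.05),
    },
    "CP_like": {
        "PF": dict(k_d=2.2, k_v=2.0, k_a=0.20, k_s=0.5,
                   k_dp=0.15, k_vp=1.0, k_ap=0.15, e0=0.08),
        "TA": dict(k_d=1.2, k_v=1.8, k_a=0.15,
                   k_dp=0.15, k_vp=1.0, k_ap=0.15, e0=0.08),
    },
}


@dataclass
class GroundTruthGains:
    """Per-muscle feedback gains used to generate one subject."""

    gains: Dict[str, FeedbackGains]
    archetype: str = "TD_like"

    def __post_init__(self):
        for muscle, g in self.gains.items():
            g.validate(role_of(muscle))


@dataclass
class NoiseModel:
    """Additive Gaussian envelope noise (clipped at 0) plus a tonic
    baseline offset."""

    sd: float = 0.02
    tonic: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError("noise sd must be >= 0")
        if self.tonic < 0:
            raise ParameterError("tonic baseline must be >= 0")


def archetype_gains(archetype: str, scale: Optional[Dict[str, float]] = None
                    ) -> GroundTruthGains:
    """Mean gains of a group archetype as a GroundTruthGains object."""
    spec = ARCHETYPES[archetype]
    gains = {}
    for muscle in MUSCLES:
        src = spec["TA"] if muscle == "TA" else spec["PF"]
        src = dict(src)
        if scale:
            for k, s in scale.items():
                if k in src:
                    src[k] = src[k] * s
        if muscle == "TA":
            src.setdefault("k_s", None)
            gains[muscle] = FeedbackGains(**{**src, "k_s": None})
        else:
            gains[muscle] = FeedbackGains(**src)
    return GroundTruthGains(gains=gains, archetype=archetype)


def draw_subject_gains(
    archetype: str, rng: np.random.Generator, cv: float = 0.2
) -> GroundTruthGains:
    """Draw per-subject gains around the archetype means (normal with
    coefficient of variation ``cv``, clipped into the model bounds)."""
    mean = archetype_gains(archetype)
    gains = {}
    for muscle, g in mean.gains.items():
        vals = {}
        for name, v in g.as_dict().items():
            if name == "e0":
                vals[name] = max(float(rng.normal(v, cv * v)), 0.005)
            else:
                vals[name] = float(np.clip(rng.normal(v, cv * max(v, 1e-3)), 0.0, 10.0))
        if muscle == "TA":
            vals["k_s"] = None
        gains[muscle] = FeedbackGains(**vals)
    return GroundTruthGains(gains=gains, archetype=archetype)


# ---------------------------------------------------------------------------
# EMG generation

def generate_emg(
    com: ComKinematics,
    gains: GroundTruthGains,
    noise: NoiseModel = NoiseModel(),
    rng: Optional[np.random.Generator] = None,
    config: ModelConfig = ModelConfig(),
    muscles: Sequence[str] = MUSCLES,
) -> Dict[str, np.ndarray]:
    """Per-muscle envelopes: forward model + tonic + Gaussian noise,
    clipped at zero."""
    if rng is None:
        rng = np.random.default_rng(0)
    out = {}
    for muscle in muscles:
        g = gains.gains[muscle]
        recon = reconstruct_emg(g, com, config, role_of(muscle)).emg_recon
        env = recon + noise.tonic
        if noise.sd > 0:
            env = env + rng.normal(0.0, noise.sd, size=env.shape)
        out[muscle] = np.clip(env, 0.0, None)
    return out


def identifiability_report(
    gains: GroundTruthGains,
    level: int,
    config: ModelConfig = ModelConfig(),
) -> Dict[str, Dict[str, bool]]:
    """Which gains are identifiable per muscle for the level's default
    trajectory (rectification can hide gains whose pathway input never
    goes positive in the fit window)."""
    _, com, _ = level_kinematics(level, config.stiction_threshold)
    return {
        muscle: identifiable_gains(gains.gains[muscle], com, config,
                                   role_of(muscle))
        for muscle in MUSCLES
    }


def emg_envelope_to_raw(
    t_env: np.ndarray,
    env: np.ndarray,
    fs_out: float,
    rng: np.random.Generator,
    band: Tuple[float, float] = (20.0, 400.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Amplitude-modulate band-limited noise by an envelope, producing a
    raw-style interference signal whose filtered envelope approximates
    the input (for exercising the preprocessing chain)."""
    from scipy import signal as _signal

    t = np.arange(t_env[0], t_env[-1] + 0.5 / fs_out, 1.0 / fs_out)
    carrier = rng.standard_normal(t.size)
    sos = _signal.butter(4, band, btype="bandpass", fs=fs_out, output="sos")
    carrier = _signal.sosfiltfilt(sos, carrier)
    carrier /= np.mean(np.abs(carrier))  # unit rectified mean
    env_up = np.interp(t, t_env, env)
    return t, env_up * carrier


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(
    out_dir: str,
    n_per_group: int = 20,
    trials_per_level: int = 8,
    levels: Sequence[int] = (1, 2, 3, 4),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    step_prob: float = 0.0,
    raw_emg: bool = False,
    gain_cv: float = 0.2,
    archetype_scale: Optional[Dict[str, Dict[str, float]]] = None,
) -> DatasetManifest:
    """Write a full synthetic dataset (trial files + manifest + ground
    truth sidecar) and return the manifest.

    Deterministic given ``seed``.  Groups: CP subjects draw from the
    CP_like archetype, TD subjects from TD_like (means optionally
    rescaled per archetype via ``archetype_scale``).  ``step_prob``
    randomly flags trials as stepped (never all trials of a level).
    With ``raw_emg`` the EMG columns hold 1000 Hz interference-style
    signals; otherwise they hold 100 Hz envelopes and the manifest
    records ``emg_mode: envelope``.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    entries: List[ManifestEntry] = []
    truth: Dict[str, dict] = {}
    onset = 0.6
    fs = 1000.0 if raw_emg else ANALYSIS_RATE
    for group, archetype in (("CP", "CP_like"), ("TD", "TD_like")):
        for s in range(n_per_group):
            subject = f"{group}{s + 1:02d}"
            sub_rng = np.random.default_rng(rng.integers(0, 2**63 - 1))
            gt = draw_subject_gains(archetype, sub_rng, cv=gain_cv)
            if archetype_scale and archetype in archetype_scale:
                for muscle in MUSCLES:
                    vals = gt.gains[muscle].as_dict()
                    for k, fac in archetype_scale[archetype].items():
                        if k in vals:
                            vals[k] = float(np.clip(vals[k] * fac, 0.0, 10.0))
                    if muscle == "TA":
                        vals["k_s"] = None
                    gt.gains[muscle] = FeedbackGains(**vals)
            truth[subject] = {
                "archetype": archetype,
                "gains": {m: {k: (None if v is None else float(v))
                              for k, v in g.as_dict().items()}
                          for m, g in gt.gains.items()},
            }
            for level in levels:
                t, com, ankle_change = level_kinematics(level)
                stepped_flags = sub_rng.random(trials_per_level) < step_prob
                if stepped_flags.all():
                    stepped_flags[0] = False
                for trial_idx in range(trials_per_level):
                    env = generate_emg(com, gt, noise, sub_rng)
                    rec = _build_recording(
                        subject, group, level, trial_idx,
                        bool(stepped_flags[trial_idx]), onset, t, com,
                        ankle_change, env, raw_emg, sub_rng,
                    )
                    rel = os.path.join(
                        "trials", f"{subject}_L{level}_T{trial_idx:02d}.tsv"
                    )
                    write_trial(rec, os.path.join(out_dir, rel))
                    entries.append(entry_for(rec, rel))
    manifest = DatasetManifest(entries=entries, root=out_dir)
    save_manifest(manifest, os.path.join(out_dir, "manifest.yaml"))
    if not raw_emg:  # annotate envelope mode next to the manifest
        with open(os.path.join(out_dir, "manifest.yaml")) as fh:
            doc = yaml.safe_load(fh)
        doc["emg_mode"] = "envelope"
        with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    with open(os.path.join(out_dir, "ground_truth.yaml"), "w") as fh:
        yaml.safe_dump({"seed": seed, "subjects": truth}, fh, sort_keys=True)
    return manifest


def _build_recording(subject, group, level, trial_idx, stepped, onset,
                     t, com: ComKinematics, ankle_change, env, raw_emg,
                     rng) -> TrialRecording:
    com_pos = com.d + DEFAULT_RESPONSE_PARAMS["com_offset_m"]
    ankle_angle = ankle_change + DEFAULT_RESPONSE_PARAMS["ankle_offset_deg"]
    if raw_emg:
        fs = 1000.0
        t_raw = None
        emg = {}
        for m in MUSCLES:
            t_raw, sig = emg_envelope_to_raw(t, env[m], fs, rng)
            emg[m] = sig
        time = t_raw + onset
        com_w = np.interp(t_raw, t, com_pos)
        ankle_w = np.interp(t_raw, t, ankle_angle)
        return TrialRecording(
            subject_id=subject, group=group, level=level,
            trial_index=trial_idx, stepped=stepped, onset_time=onset,
            time=time, emg_raw=emg, com_pos=com_w, ankle_angle=ankle_w,
            emg_rate_hz=fs, kin_rate_hz=ANALYSIS_RATE,
        )
    return TrialRecording(
        subject_id=subject, group=group, level=level,
        trial_index=trial_idx, stepped=stepped, onset_time=onset,
        time=t + onset, emg_raw=env, com_pos=com_pos,
        ankle_angle=ankle_angle,
        emg_rate_hz=ANALYSIS_RATE, kin_rate_hz=ANALYSIS_RATE,
    )


def load_ground_truth(path: str) -> Dict[str, GroundTruthGains]:
    """Re-read the ground-truth sidecar written by :func:`generate_cohort`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for subject, entry in doc["subjects"].items():
        gains = {}
        for muscle, vals in entry["gains"].items():
            vals = dict(vals)
            if muscle == "TA":
                vals["k_s"] = None
            else:
                vals.setdefault("k_s", 0.0)
            gains[muscle] = FeedbackGains(**vals)
        out[subject] = GroundTruthGains(gains=gains, archetype=entry["archetype"])
    return out


def simulate_cci_cohort(
    n_per_group: int,
    seed: int,
    levels: Sequence[int] = (1, 2, 3, 4),
    trials_per_level: int = 8,
    noise: NoiseModel = NoiseModel(),
    group_archetypes: Optional[Dict[str, str]] = None,
    pairs: Sequence[Tuple[str, str]] = (("LG", "TA"),),
    windows: Sequence[Tuple[float, float]] = ((0.0, 0.4),),
    gain_cv: float = 0.2,
):
    """In-memory cohort -> long-format CCI table (no files written).

    For each subject, per-level envelopes are averaged over
    ``trials_per_level`` noisy trials (as the analysis pipeline does)
    and the co-contraction index is computed for the requested muscle
    pairs and windows.  Used for power/type-I simulations where writing
    trial files would dominate the runtime.  Deterministic given
    ``seed``.
    """
    import pandas as pd

    from .cci import cci as _cci

    if group_archetypes is None:
        group_archetypes = {"CP": "CP_like", "TD": "TD_like"}
    muscles = sorted({m for pair in pairs for m in pair})
    rng = np.random.default_rng(seed)
    rows = []
    for group, archetype in sorted(group_archetypes.items()):
        for s in range(n_per_group):
            subject = f"{group}{s + 1:02d}"
            gt = draw_subject_gains(archetype, rng, cv=gain_cv)
            for level in levels:
                t, com, _ = level_kinematics(level)
                acc = {m: np.zeros(t.size) for m in muscles}
                for _trial in range(trials_per_level):
                    env = generate_emg(com, gt, noise, rng, muscles=muscles)
                    for m in muscles:
                        acc[m] += env[m]
                avg = {m: acc[m] / trials_per_level for m in muscles}
                for pair in pairs:
                    for window in windows:
                        val = _cci(avg[pair[0]], avg[pair[1]], t, window).cci
                        rows.append(dict(
                            subject_id=subject, group=group, level=level,
                            condition=level, pair="-".join(pair),
                            window=f"{window[0]:g}:{window[1]:g}",
                            value=val))
    return pd.DataFrame(rows)
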