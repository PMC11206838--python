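"""EMG and kinematic conditioning.

EMG chain: 4th-order Butterworth band-pass (10-450 Hz), full-wave
rectification, 4th-order Butterworth low-pass (40 Hz); both stages are
applied forward-backward (zero phase) so the envelope is not delayed
relative to the 100 ms analysis bins.  Envelopes are scaled per subject
and muscle by the maximum filtered value over all of that subject's
trials.  CoM velocity comes from numerical differentiation of position;
acceleration from a first-derivative Savitzky-Golay filter (polynomial
order 5, window 11).  Everything is then put on a uniform analysis grid
(default 100 Hz) re-referenced so perturbation onset is t = 0, and
averaged across the non-stepping trials of each subject x level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import signal

from .dataio import MUSCLES, TrialRecording


class SamplingError(ValueError):
    """Sampling rate incompatible with the requested filter."""


class ScalingError(ValueError):
    """Degenerate (all-zero) channel cannot be scaled."""


class WindowError(ValueError):
    """Series does not cover the requested analysis window."""


class ExclusionError(ValueError):
    """No usable (non-stepping) trials for a subject x level."""


#: default analysis window around onset, seconds
ANALYSIS_WINDOW = (-0.6, 1.5)
#: default analysis rate, Hz (kinematic acquisition rate)
ANALYSIS_RATE = 100.0


@dataclass
class ComKinematics:
    """CoM feedback inputs on the analysis grid (onset = 0).

    ``a_init`` is the stiction-gated copy of ``a``: equal to ``a`` from
    onset until the ankle-angle change first reaches the stiction
    threshold, zero elsewhere.
    """

    t: np.ndarray
    d: np.ndarray
    v: np.ndarray
    a: np.ndarray
    a_init: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class AnkleKinematics:
    t: np.ndarray
    angle: np.ndarray  # change relative to onset, deg, dorsiflexion +
    vel: np.ndarray
    acc: np.ndarray


@dataclass
class ProcessedTrial:
    """One conditioned trial (or trial average) on the analysis grid."""

    t: np.ndarray
    emg_env: Dict[str, np.ndarray]
    com: ComKinematics
    ankle: AnkleKinematics
    subject_id: str = ""
    group: str = ""
    level: int = 0
    stepped: bool = False
    trial_index: int = -1
    n_trials: int = 1


def filter_emg(
    raw: np.ndarray,
    fs: float,
    band: Tuple[float, float] = (10.0, 450.0),
    lowpass: float = 40.0,
    order: int = 4,
) -> np.ndarray:
    """Band-pass, rectify and low-pass one raw EMG channel.

    Requires ``fs`` > 2x the upper band edge (900 Hz at defaults).
    Filtering is zero-phase (``filtfilt``); the stated order is the
    design order per pass.  Negative low-pass undershoot is floored at
    zero since a rectified signal is non-negative by meaning.
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * band[1]:
        raise SamplingError(
            f"fs={fs} Hz too low for band edge {band[1]} Hz (need fs > {2 * band[1]})"
        )
    sos_bp = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    sos_lp = signal.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    bandpassed = signal.sosfiltfilt(sos_bp, raw)
    rectified = np.abs(bandpassed)
    env = signal.sosfiltfilt(sos_lp, rectified)
    return np.clip(env, 0.0, None)


def scale_emg(envelopes: Sequence[np.ndarray]) -> Tuple[List[np.ndarray], float]:
    """Scale one subject's envelopes of one muscle by their common maximum.

    Returns the scaled envelopes (same order) and the scale factor; the
    maximum over the union of all provided trials becomes exactly 1.
    """
    if len(envelopes) == 0:
        raise ScalingError("need at least one trial to scale")
    peak = max(float(np.nanmax(env)) for env in envelopes)
    if not peak > 0:
        raise ScalingError("all-zero muscle channel cannot be scaled")
    return [np.asarray(env, dtype=float) / peak for env in envelopes], peak


def differentiate(pos: np.ndarray, fs: float) -> np.ndarray:
    """First derivative on a uniform grid: central differences in the
    interior, one-sided at the ends."""
    pos = np.asarray(pos, dtype=float)
    if pos.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(pos, 1.0 / fs)


def sg_acceleration(
    vel: np.ndarray, fs: float, polyorder: int = 5, window: int = 11
) -> np.ndarray:
    """Savitzky-Golay first derivative of velocity (default order 5,
    frame length 11), scaled to physical units by ``fs``."""
    vel = np.asarray(vel, dtype=float)
    if vel.size < window:
        raise ValueError(f"need at least {window} samples, got {vel.size}")
    return signal.savgol_filter(
        vel, window_length=window, polyorder=polyorder, deriv=1, delta=1.0 / fs,
        mode="interp",
    )


def analysis_grid(
    window: Tuple[float, float] = ANALYSIS_WINDOW, rate: float = ANALYSIS_RATE
) -> np.ndarray:
    """Uniform onset-referenced time axis; onset (t = 0) is a grid point."""
    dt = 1.0 / rate
    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    return np.arange(-n_pre, n_post + 1) * dt


def _interp(t_new: np.ndarray, t_old: np.ndarray, y: np.ndarray) -> np.ndarray:
    eps = 1e-9
    if t_old[0] > t_new[0] + eps or t_old[-1] < t_new[-1] - eps:
        raise WindowError(
            f"series covers [{t_old[0]:.3f}, {t_old[-1]:.3f}] s; "
            f"analysis window needs [{t_new[0]:.3f}, {t_new[-1]:.3f}] s"
        )
    return np.interp(t_new, t_old, y)


def com_kinematics(
    t: np.ndarray,
    com_pos: np.ndarray,
    ankle_change: np.ndarray,
    stiction_threshold: float = 0.5,
) -> ComKinematics:
    """Derive d/v/a and the stiction-gated initial acceleration from CoM
    position on the analysis grid."""
    from .model import gate_stiction  # local import to avoid a cycle

    fs = 1.0 / float(np.median(np.diff(t)))
    d = np.asarray(com_pos, dtype=float)
    v = differentiate(d, fs)
    a = sg_acceleration(v, fs)
    a_init = gate_stiction(t, a, ankle_change, stiction_threshold)
    return ComKinematics(t=t, d=d, v=v, a=a, a_init=a_init)


def resample_common_grid(
    trial: TrialRecording,
    envelopes: Dict[str, np.ndarray],
    rate: float = ANALYSIS_RATE,
    window: Tuple[float, float] = ANALYSIS_WINDOW,
    stiction_threshold: float = 0.5,
) -> ProcessedTrial:
    """Interpolate envelopes + kinematics onto the analysis grid.

    Linear interpolation (signals are already low-passed; avoids
    overshoot).  The output grid is onset-referenced; ankle angle is
    re-expressed as change relative to its value at onset.
    """
    t = analysis_grid(window, rate)
    t_rel = trial.time - trial.onset_time
    env = {m: _interp(t, t_rel, envelopes[m]) for m in MUSCLES}
    com_pos = _interp(t, t_rel, trial.com_pos)
    ankle_abs = _interp(t, t_rel, trial.ankle_angle)
    onset_idx = int(np.argmin(np.abs(t)))
    ankle_change = ankle_abs - ankle_abs[onset_idx]
    fs = 1.0 / float(np.median(np.diff(t)))
    ankle = AnkleKinematics(
        t=t,
        angle=ankle_change,
        vel=differentiate(ankle_change, fs),
        acc=sg_acceleration(differentiate(ankle_change, fs), fs),
    )
    com = com_kinematics(t, com_pos, ankle_change, stiction_threshold)
    return ProcessedTrial(
        t=t,
        emg_env=env,
        com=com,
        ankle=ankle,
        subject_id=trial.subject_id,
        group=trial.group,
        level=trial.level,
        stepped=trial.stepped,
        trial_index=trial.trial_index,
    )


def average_trials(
    trials: Sequence[ProcessedTrial], stiction_threshold: float = 0.5
) -> ProcessedTrial:
    """Pointwise mean of non-stepping trials on identical grids.

    The stiction-gated acceleration is re-derived from the *averaged*
    ankle trace rather than averaged across trials, so the gate closes
    at a single well-defined time for the subject x level.
    """
    usable = [tr for tr in trials if not tr.stepped]
    if not usable:
        raise ExclusionError("no non-stepping trials to average")
    t0 = usable[0].t
    for tr in usable[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0):
            raise ValueError("trials must share an identical analysis grid")
    from .model import gate_stiction

    env = {
        m: np.mean([tr.emg_env[m] for tr in usable], axis=0) for m in MUSCLES
    }
    ankle = AnkleKinematics(
        t=t0,
        angle=np.mean([tr.ankle.angle for tr in usable], axis=0),
        vel=np.mean([tr.ankle.vel for tr in usable], axis=0),
        acc=np.mean([tr.ankle.acc for tr in usable], axis=0),
    )
    d = np.mean([tr.com.d for tr in usable], axis=0)
    v = np.mean([tr.com.v for tr in usable], axis=0)
    a = np.mean([tr.com.a for tr in usable], axis=0)
    com = ComKinematics(
        t=t0, d=d, v=v, a=a,
        a_init=gate_stiction(t0, a, ankle.angle, stiction_threshold),
    )
    first = usable[0]
    return ProcessedTrial(
        t=t0,
        emg_env=env,
        com=com,
        ankle=ankle,
        subject_id=first.subject_id,
        group=first.group,
        level=first.level,
        stepped=False,
        trial_index=-1,
        n_trials=len(usable),
    )
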