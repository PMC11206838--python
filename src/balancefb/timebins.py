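"""Time-binned reactive activity and kinematics.

EMG bins: Z1 = [0, 150) ms, Z2 = [150, 250) ms, Z3 = [250, 400) ms after
perturbation onset.  Kinematic bins are the same bins shifted 100 ms
earlier ([0, 50), [50, 150), [150, 300) ms), since the kinematic
disturbance provides the sensory input for the later muscle response.
Bins are half-open so no sample is counted twice, and membership is by
time stamp, so non-canonical grid rates work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataio import MUSCLES
from .preprocess import ProcessedTrial, WindowError

EMG_BINS: Tuple[Tuple[float, float], ...] = ((0.0, 0.150), (0.150, 0.250), (0.250, 0.400))
KIN_BINS: Tuple[Tuple[float, float], ...] = ((0.0, 0.050), (0.050, 0.150), (0.150, 0.300))
BIN_LABELS = ("Z1", "Z2", "Z3")

#: baseline window for reactive EMG, seconds relative to onset
BASELINE_WINDOW = (-0.100, 0.0)


class BinError(ValueError):
    """A bin contains no samples on this grid."""


def reactive_emg(env: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Envelope minus its scalar pre-onset baseline.

    Baseline = mean envelope over the 100 ms preceding onset,
    [-0.1, 0) s.  The result may be negative (activity below baseline).
    """
    env = np.asarray(env, dtype=float)
    t = np.asarray(t, dtype=float)
    eps = 1e-9
    mask = (t >= BASELINE_WINDOW[0] - eps) & (t < BASELINE_WINDOW[1] - eps)
    if not np.any(mask):
        raise WindowError("grid does not cover the [-0.1, 0) s baseline window")
    return env - float(np.mean(env[mask]))


def bin_means(
    series: np.ndarray, t: np.ndarray, edges: Sequence[Tuple[float, float]]
) -> np.ndarray:
    """Arithmetic mean of samples with t in [start, end) for each bin."""
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    eps = 1e-9
    out = np.empty(len(edges))
    for i, (start, end) in enumerate(edges):
        mask = (t >= start - eps) & (t < end - eps)
        if not np.any(mask):
            raise BinError(f"bin [{start}, {end}) contains no samples")
        out[i] = float(np.mean(series[mask]))
    return out


@dataclass
class TimeBinSummary:
    """Per-muscle reactive-EMG bin means and per-channel kinematic bin
    means for one processed (usually trial-averaged) response."""

    emg: Dict[str, np.ndarray]        # muscle -> (Z1, Z2, Z3)
    kinematics: Dict[str, np.ndarray]  # channel -> shifted-bin means
    emg_edges: Tuple[Tuple[float, float], ...] = EMG_BINS
    kin_edges: Tuple[Tuple[float, float], ...] = KIN_BINS


KINEMATIC_CHANNELS = (
    "com_d", "com_v", "com_a", "ankle_angle", "ankle_vel", "ankle_acc"
)


def summarize_bins(
    trial: ProcessedTrial,
    emg_edges: Sequence[Tuple[float, float]] = EMG_BINS,
    kin_edges: Sequence[Tuple[float, float]] = KIN_BINS,
) -> TimeBinSummary:
    """Bin-average the reactive EMG (EMG bins) and the kinematic
    channels (100 ms-shifted bins) of one processed response."""
    t = trial.t
    emg = {
        m: bin_means(reactive_emg(trial.emg_env[m], t), t, emg_edges)
        for m in MUSCLES
    }
    kin_series = {
        "com_d": trial.com.d,
        "com_v": trial.com.v,
        "com_a": trial.com.a,
        "ankle_angle": trial.ankle.angle,
        "ankle_vel": trial.ankle.vel,
        "ankle_acc": trial.ankle.acc,
    }
    kin = {name: bin_means(s, t, kin_edges) for name, s in kin_series.items()}
    return TimeBinSummary(emg=emg, kinematics=kin,
                          emg_edges=tuple(emg_edges), kin_edges=tuple(kin_edges))


def bins_to_rows(trial: ProcessedTrial, summary: TimeBinSummary) -> pd.DataFrame:
    """Long-format rows (subject, group, level, channel, bin, value) for
    the cohort table."""
    rows: List[dict] = []
    for m, vals in summary.emg.items():
        for label, v in zip(BIN_LABELS, vals):
            rows.append(
                dict(subject_id=trial.subject_id, group=trial.group,
                     level=trial.level, outcome="emg_bin", channel=m,
                     condition=label, value=float(v))
            )
    for ch, vals in summary.kinematics.items():
        for label, v in zip(BIN_LABELS, vals):
            rows.append(
                dict(subject_id=trial.subject_id, group=trial.group,
                     level=trial.level, outcome="kin_bin", channel=ch,
                     condition=label, value=float(v))
            )
    return pd.DataFrame(rows)
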