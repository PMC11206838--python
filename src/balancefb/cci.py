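"""Co-contraction index (CCI) between tibialis anterior and each
plantar flexor.

CCI over a window is the mean across frames of the pointwise minimum of
two scaled EMG envelopes:

    CCI = sum_frames min(EMG_PF, EMG_TA) / #frames

computed on the filtered and *scaled* envelopes without baseline
subtraction.  Two standard windows are evaluated per trial: [0, 0.4) s
after onset (spanning the EMG time bins) and [-0.5, 1.5) s (the model
fit interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .preprocess import ProcessedTrial, WindowError

#: the two analysis windows, seconds relative to onset
WINDOW_SHORT = (0.0, 0.400)
WINDOW_LONG = (-0.5, 1.5)

PAIRS = (("LG", "TA"), ("MG", "TA"), ("SOL", "TA"))


class AlignmentError(ValueError):
    """Input series are not on a common grid."""


@dataclass
class CciResult:
    cci: float
    pair: Tuple[str, str]
    window: Tuple[float, float]


def cci(
    emg_a: np.ndarray,
    emg_b: np.ndarray,
    t: np.ndarray,
    window: Tuple[float, float],
    pair: Tuple[str, str] = ("A", "B"),
) -> CciResult:
    """Mean of the elementwise minimum over frames with t in
    [start, end)."""
    emg_a = np.asarray(emg_a, dtype=float)
    emg_b = np.asarray(emg_b, dtype=float)
    t = np.asarray(t, dtype=float)
    if emg_a.shape != emg_b.shape or emg_a.shape != t.shape:
        raise AlignmentError(
            f"series shapes differ: {emg_a.shape}, {emg_b.shape}, grid {t.shape}"
        )
    eps = 1e-9
    mask = (t >= window[0] - eps) & (t < window[1] - eps)
    if not np.any(mask):
        raise WindowError(f"window [{window[0]}, {window[1]}) not covered by grid")
    value = float(np.mean(np.minimum(emg_a, emg_b)[mask]))
    return CciResult(cci=value, pair=tuple(pair), window=tuple(window))


def cci_battery(trial: ProcessedTrial) -> List[CciResult]:
    """All three PF-TA pairs x both windows (6 results)."""
    out: List[CciResult] = []
    for window in (WINDOW_SHORT, WINDOW_LONG):
        for pf, ta in PAIRS:
            out.append(
                cci(trial.emg_env[pf], trial.emg_env[ta], trial.t, window,
                    pair=(pf, ta))
            )
    return out


def cci_to_rows(trial: ProcessedTrial, results: List[CciResult]) -> pd.DataFrame:
    rows = [
        dict(subject_id=trial.subject_id, group=trial.group, level=trial.level,
             outcome="cci", channel="-".join(r.pair),
             condition="short" if r.window == WINDOW_SHORT else "long",
             value=r.cci)
        for r in results
    ]
    return pd.DataFrame(rows)
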