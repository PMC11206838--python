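"""Trial time-series and dataset-manifest I/O.

A trial is one perturbation of one subject: four raw EMG channels
(LG, MG, SOL, TA), anterior-posterior CoM position relative to the ankle
(meters, anterior positive) and ankle angle (degrees, dorsiflexion
positive), all sampled on one common time axis stored as a
delimiter-separated text file with a single header line.  A dataset is a
set of such files indexed by a YAML manifest.

Conventions: ``onset_time`` is the perturbation onset in the trial's
absolute time axis; every downstream analysis re-references time so that
onset = 0.  Canonical acquisition rates are 1000 Hz for EMG and 100 Hz
for kinematics; files written by this package store all channels on the
finer grid and record both native rates in the manifest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MUSCLES = ("LG", "MG", "SOL", "TA")
GROUPS = ("CP", "TD")
LEVELS = (1, 2, 3, 4)

#: minimum coverage around onset required of every trial, seconds
REQUIRED_WINDOW = (-0.6, 1.5)

SCHEMA_VERSION = "1"

TRIAL_COLUMNS = (
    "time_s",
    "com_pos_m",
    "ankle_angle_deg",
    "emg_LG",
    "emg_MG",
    "emg_SOL",
    "emg_TA",
)


class FormatError(ValueError):
    """Malformed trial file (missing column, bad header)."""


class DataError(ValueError):
    """Well-formed file with invalid content (e.g. non-monotonic time)."""


class ManifestError(ValueError):
    """Invalid dataset manifest."""


@dataclass
class TrialRecording:
    """One perturbation trial: raw channels + metadata.

    All series share ``time`` (seconds, strictly increasing, uniform).
    ``emg_rate_hz`` / ``kin_rate_hz`` record the native acquisition
    rates; the stored grid rate equals ``fs``.
    """

    subject_id: str
    group: str
    level: int
    trial_index: int
    stepped: bool
    onset_time: float
    time: np.ndarray
    emg_raw: Dict[str, np.ndarray]
    com_pos: np.ndarray
    ankle_angle: np.ndarray
    emg_rate_hz: float = 1000.0
    kin_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.com_pos = np.asarray(self.com_pos, dtype=float)
        self.ankle_angle = np.asarray(self.ankle_angle, dtype=float)
        self.emg_raw = {m: np.asarray(v, dtype=float) for m, v in self.emg_raw.items()}
        self.validate()

    @property
    def fs(self) -> float:
        """Sampling rate of the stored grid, Hz."""
        return 1.0 / float(np.median(np.diff(self.time)))

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.level not in LEVELS:
            raise DataError(f"level must be in {LEVELS}, got {self.level!r}")
        if set(self.emg_raw) != set(MUSCLES):
            raise DataError(
                f"EMG channels must be exactly {MUSCLES}, got {sorted(self.emg_raw)}"
            )
        if self.time.size < 2:
            raise DataError("trial needs at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise DataError("time_s must be strictly increasing")
        n = self.time.size
        for name, series in self.channels().items():
            if series.size != n:
                raise DataError(
                    f"channel {name} has {series.size} samples, expected {n}"
                )
        if self.emg_rate_hz <= 0 or self.kin_rate_hz <= 0:
            raise DataError("sampling rates must be strictly positive")
        if self.emg_rate_hz < self.kin_rate_hz:
            raise DataError("EMG rate must be >= kinematic rate")
        lo = self.onset_time + REQUIRED_WINDOW[0]
        hi = self.onset_time + REQUIRED_WINDOW[1]
        eps = 0.5 / self.fs
        if self.time[0] > lo + eps or self.time[-1] < hi - eps:
            raise DataError(
                f"trial must cover [{lo:.3f}, {hi:.3f}] s around onset; "
                f"covers [{self.time[0]:.3f}, {self.time[-1]:.3f}]"
            )

    def channels(self) -> Dict[str, np.ndarray]:
        """All data channels keyed by trial-file column name."""
        out = {"com_pos_m": self.com_pos, "ankle_angle_deg": self.ankle_angle}
        for m in MUSCLES:
            out[f"emg_{m}"] = self.emg_raw[m]
        return out


@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    group: str
    level: int
    trial: int
    onset_time_s: float
    stepped: bool
    emg_rate_hz: float = 1000.0
    kin_rate_hz: float = 100.0

    @property
    def key(self):
        return (self.subject_id, self.level, self.trial)


@dataclass
class DatasetManifest:
    entries: List[ManifestEntry]
    schema_version: str = SCHEMA_VERSION
    root: str = "."

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.key in seen:
                raise ManifestError(
                    f"duplicate subject/level/trial entry {e.key}"
                )
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, entry: ManifestEntry) -> str:
        return os.path.join(self.root, entry.path)


def read_trial(path: str, entry: ManifestEntry) -> TrialRecording:
    """Read one trial file and validate it against its manifest metadata."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"trial file {path} is missing column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(time) > 0):
        raise DataError(f"non-monotonic time_s in {path}")
    return TrialRecording(
        subject_id=entry.subject_id,
        group=entry.group,
        level=int(entry.level),
        trial_index=int(entry.trial),
        stepped=bool(entry.stepped),
        onset_time=float(entry.onset_time_s),
        time=time,
        emg_raw={m: df[f"emg_{m}"].to_numpy(dtype=float) for m in MUSCLES},
        com_pos=df["com_pos_m"].to_numpy(dtype=float),
        ankle_angle=df["ankle_angle_deg"].to_numpy(dtype=float),
        emg_rate_hz=float(entry.emg_rate_hz),
        kin_rate_hz=float(entry.kin_rate_hz),
    )


def write_trial(rec: TrialRecording, path: str) -> str:
    """Write a trial to a tab-separated file readable by :func:`read_trial`.

    Values are written with ``repr``-level precision; the round trip is
    lossless well below 1e-9.  NaN samples are preserved (permitted for
    gaps).
    """
    rec.validate()
    data = {"time_s": rec.time}
    data.update(rec.channels())
    df = pd.DataFrame(data, columns=list(TRIAL_COLUMNS))
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def entry_for(rec: TrialRecording, path: str) -> ManifestEntry:
    """Manifest entry describing an in-memory recording written at ``path``."""
    return ManifestEntry(
        path=path,
        subject_id=rec.subject_id,
        group=rec.group,
        level=rec.level,
        trial=rec.trial_index,
        onset_time_s=rec.onset_time,
        stepped=rec.stepped,
        emg_rate_hz=rec.emg_rate_hz,
        kin_rate_hz=rec.kin_rate_hz,
    )


def save_manifest(manifest: DatasetManifest, path: str) -> str:
    doc = {
        "schema_version": manifest.schema_version,
        "entries": [
            {
                "path": e.path,
                "subject_id": e.subject_id,
                "group": e.group,
                "level": int(e.level),
                "trial": int(e.trial),
                "onset_time_s": float(e.onset_time_s),
                "stepped": bool(e.stepped),
                "emg_rate_hz": float(e.emg_rate_hz),
                "kin_rate_hz": float(e.kin_rate_hz),
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def load_manifest(path: str) -> DatasetManifest:
    """Load and validate a dataset manifest.

    Referenced trial files must exist (paths are resolved relative to
    the manifest's directory); duplicated subject/level/trial triples
    are rejected.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "entries" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with 'entries'")
    root = os.path.dirname(os.path.abspath(path))
    entries = []
    for raw in doc["entries"]:
        try:
            entries.append(
                ManifestEntry(
                    path=str(raw["path"]),
                    subject_id=str(raw["subject_id"]),
                    group=str(raw["group"]),
                    level=int(raw["level"]),
                    trial=int(raw["trial"]),
                    onset_time_s=float(raw["onset_time_s"]),
                    stepped=bool(raw["stepped"]),
                    emg_rate_hz=float(raw.get("emg_rate_hz", 1000.0)),
                    kin_rate_hz=float(raw.get("kin_rate_hz", 100.0)),
                )
            )
        except KeyError as exc:
            raise ManifestError(f"{path}: entry missing field {exc}") from exc
    manifest = DatasetManifest(
        entries=entries,
        schema_version=str(doc.get("schema_version", SCHEMA_VERSION)),
        root=root,
    )
    for e in manifest.entries:
        p = manifest.resolve(e)
        if not os.path.exists(p):
            raise ManifestError(f"manifest references missing file: {p}")
    return manifest
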