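"""End-to-end analysis: manifest -> cohort outcome table + fit results.

Per subject: read all trials, condition EMG (filter raw signals, or use
stored envelopes directly for envelope-mode datasets), scale each muscle
by the subject's maximum over *all* trials, resample to the analysis
grid, average the non-stepping trials of each level, then compute time
bins, co-contraction indices and both feedback-model variants per
muscle.  Stepped trials are excluded from averaging (and logged);
subject x level cells with no usable trial are skipped and reported as
missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .dataio import MUSCLES, DatasetManifest, read_trial
from .preprocess import (
    ProcessedTrial,
    average_trials,
    filter_emg,
    resample_common_grid,
    scale_emg,
)
from .timebins import bins_to_rows, summarize_bins
from .cci import cci_battery, cci_to_rows
from .model import (
    ModelConfig,
    fit_both_variants,
    role_of,
)

logger = logging.getLogger(__name__)

GAIN_PARAMS = ("k_d", "k_v", "k_a", "k_s", "k_dp", "k_vp", "k_ap")


@dataclass
class AnalysisOutput:
    cohort_table: pd.DataFrame
    fits: Dict[Tuple[str, int, str], dict]  # (subject, level, muscle) -> fit info
    excluded_stepped: Dict[Tuple[str, int], int]
    missing_levels: List[Tuple[str, int]]


def model_config_from(cfg: dict) -> ModelConfig:
    m = cfg["model"]
    return ModelConfig(
        tau=m["tau_s"],
        gain_bounds=tuple(m["gain_bounds"]),
        penalty_weight=m["penalty_weight"],
        stiction_threshold=m["stiction_threshold_deg"],
        fit_window=tuple(m["fit_window_s"]),
        gof_window=tuple(m["gof_window_s"]),
        n_starts=m["n_starts"],
        seed=cfg["seed"],
    )


def analyze_dataset(
    manifest: DatasetManifest,
    cfg: dict,
    emg_mode: str = "raw",
    fit_models: bool = True,
) -> AnalysisOutput:
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    pp = cfg["preprocess"]
    mcfg = model_config_from(cfg)
    rate = pp["analysis_rate_hz"]
    window = tuple(pp["window_s"])

    by_subject: Dict[str, list] = {}
    for entry in manifest.entries:
        by_subject.setdefault(entry.subject_id, []).append(entry)

    rows: List[pd.DataFrame] = []
    fits: Dict[Tuple[str, int, str], dict] = {}
    excluded: Dict[Tuple[str, int], int] = {}
    missing: List[Tuple[str, int]] = []

    for subject, entries in sorted(by_subject.items()):
        recs = [read_trial(manifest.resolve(e), e) for e in entries]
        # envelopes per trial (same order as recs)
        envs: List[Dict[str, np.ndarray]] = []
        for rec in recs:
            if emg_mode == "envelope":
                envs.append({m: rec.emg_raw[m] for m in MUSCLES})
            else:
                envs.append({
                    m: filter_emg(rec.emg_raw[m], rec.fs,
                                  band=tuple(pp["band_hz"]),
                                  lowpass=pp["lowpass_hz"])
                    for m in MUSCLES
                })
        # subject-wide scaling per muscle across all trials
        for m in MUSCLES:
            scaled, _ = scale_emg([env[m] for env in envs])
            for env, s in zip(envs, scaled):
                env[m] = s
        processed = [
            resample_common_grid(rec, env, rate=rate, window=window,
                                 stiction_threshold=mcfg.stiction_threshold)
            for rec, env in zip(recs, envs)
        ]
        levels = sorted({p.level for p in processed})
        for level in levels:
            at_level = [p for p in processed if p.level == level]
            n_stepped = sum(p.stepped for p in at_level)
            if n_stepped:
                excluded[(subject, level)] = n_stepped
            usable = [p for p in at_level if not p.stepped]
            if not usable:
                missing.append((subject, level))
                logger.warning("%s level %d: no non-stepping trials; skipped",
                               subject, level)
                continue
            avg = average_trials(at_level, mcfg.stiction_threshold)
            rows.append(bins_to_rows(avg, summarize_bins(
                avg, emg_edges=[tuple(e) for e in cfg["bins"]["emg_edges"]],
                kin_edges=[tuple(e) for e in cfg["bins"]["kin_edges"]])))
            rows.append(cci_to_rows(avg, cci_battery(avg)))
            if fit_models:
                rows.append(_fit_rows(avg, mcfg, fits))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if excluded:
        total = sum(excluded.values())
        logger.info("excluded %d stepped trial(s) over %d subject-level cell(s)",
                    total, len(excluded))
    return AnalysisOutput(cohort_table=table, fits=fits,
                          excluded_stepped=excluded, missing_levels=missing)


def _fit_rows(avg: ProcessedTrial, mcfg: ModelConfig,
              fits: Dict[Tuple[str, int, str], dict]) -> pd.DataFrame:
    out = []
    for muscle in MUSCLES:
        role = role_of(muscle)
        (g_s, r_s), (g_e, r_e), improvement = fit_both_variants(
            avg.emg_env[muscle], avg.com, mcfg, role)
        fits[(avg.subject_id, avg.level, muscle)] = dict(
            simple=dict(gains=g_s.as_dict(), cost=r_s.cost,
                        r2=r_s.r2, vaf=r_s.vaf, rmse=r_s.rmse),
            extended=dict(gains=g_e.as_dict(), cost=r_e.cost,
                          r2=r_e.r2, vaf=r_e.vaf, rmse=r_e.rmse,
                          bound_flags=g_e.bound_flags(mcfg.gain_bounds)),
            improvement_pct=improvement,
        )
        base = dict(subject_id=avg.subject_id, group=avg.group,
                    level=avg.level, channel=muscle, condition=avg.level)
        for name, val in g_e.as_dict().items():
            if name == "e0" or val is None:
                continue
            out.append(dict(base, outcome=f"gain:{name}", value=float(val)))
        out.append(dict(base, outcome="improvement", value=float(improvement)))
        out.append(dict(base, outcome="gof:r2", value=float(r_e.r2)))
        out.append(dict(base, outcome="gof:vaf", value=float(r_e.vaf)))
        out.append(dict(base, outcome="gof:rmse", value=float(r_e.rmse)))
    return pd.DataFrame(out)


def emg_mode_of(manifest_path: str) -> str:
    """Read the optional ``emg_mode`` annotation from a manifest file."""
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    return str(doc.get("emg_mode", "raw"))


def run_stats(table: pd.DataFrame, cfg: dict) -> Dict[str, pd.DataFrame]:
    """Run the configured weighted-mixed-model families on a cohort table.

    Family layout mirrors the outcome types: bin outcomes test the
    group x time-bin interaction per muscle/channel and level; CCI,
    gains, goodness of fit and cost improvement test the group main
    effect with perturbation level as the ordinal condition.  Holm
    correction is applied within each family.
    """
    from . import stats as st

    alpha = cfg["stats"]["alpha"]
    out: Dict[str, pd.DataFrame] = {}
    outcomes = set(table["outcome"].unique())
    for family, effect in cfg["stats"]["families"].items():
        if family in ("emg_bin", "kin_bin"):
            members = [family] if family in outcomes else []
            sub_all = table[table["outcome"] == family]
            results = {}
            for (channel, level), sub in sub_all.groupby(["channel", "level"]):
                sub = st.compute_weights(sub)
                try:
                    results[f"{channel}@L{level}"] = st.fit_group_model(
                        sub, effect=effect, alpha=alpha)
                except st.UsageError as exc:
                    logger.warning("%s %s L%s: %s", family, channel, level, exc)
            if results:
                out[family] = st.results_table(results, alpha)
        else:
            if family == "gain":
                members = sorted(o for o in outcomes if o.startswith("gain:"))
            elif family == "gof":
                members = sorted(o for o in outcomes if o.startswith("gof:"))
            else:
                members = [family] if family in outcomes else []
            results = {}
            for outcome in members:
                sub_all = table[table["outcome"] == outcome].copy()
                sub_all["condition"] = sub_all["level"]
                group_cols = ["channel"]
                if outcome == "cci":
                    # rows carry the window label in 'condition' originally
                    sub_all = table[table["outcome"] == outcome].copy()
                    sub_all["window"] = sub_all["condition"]
                    sub_all["condition"] = sub_all["level"]
                    group_cols = ["channel", "window"]
                for key, sub in sub_all.groupby(group_cols):
                    key_str = key if isinstance(key, str) else "/".join(map(str, key))
                    sub = st.compute_weights(sub)
                    try:
                        results[f"{outcome}:{key_str}"] = st.fit_group_model(
                            sub, effect=effect, alpha=alpha)
                    except st.UsageError as exc:
                        logger.warning("%s %s: %s", outcome, key_str, exc)
            if results:
                out[family] = st.results_table(results, alpha)
    return out
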