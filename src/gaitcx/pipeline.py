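"""End-to-end orchestration: recordings → events → bouts → measures.

``run_pipeline`` processes a batch of recordings with a single
:class:`PipelineConfig`, producing a :class:`RunReport` with a
per-participant measure table, a bout frequency table, an optional group
descriptive summary, and a warnings log.  Linear measures are computed on
filtered-stream bouts and nonlinear measures on raw-stream bouts;
everything is deterministic given the configured seed (per-participant
surrogate seeds are derived from it by index).

Participant-level aggregation: linear and the bout-wise nonlinear measures
(FSI, ApEn, SaEn) are computed per qualifying bout and averaged within a
participant; the participant COV is recomputed as 100·SD/xISI from the
averaged SD and mean so the COV identity always holds.  MSE, CI, SPD and
EnHL use exactly the first 800 strides of the participant's longest
raw-stream bout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bouts as bouts_mod
from . import decay as decay_mod
from . import events as events_mod
from . import measures as measures_mod
from .measures import EntropyParams, MeasureSet
from .preprocess import (AccelRecording, correct_orientation_and_gravity,
                         lowpass_filter, read_recording_csv, resample_uniform)

__all__ = ["PipelineConfig", "RunReport", "process_recording", "run_pipeline",
           "group_summary"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline tunables, defaulting to the standard protocol values."""

    fs: float = 100.0
    lowpass_cutoff_hz: float = 16.0
    filter_order: int = 4
    invert: bool = True
    vertical_axis: str = "az"
    hp_cutoff_hz: float = 0.1
    cwt_scale: float = 12.0
    min_separation_s: float = 0.8
    threshold_fraction: float = 0.4
    offset_frames: int = 3
    gap_s: float = 1.8
    min_raw_strides: int = 24
    trim_strides: int = 2
    min_strides: int = 20
    dfa_box_min: int = 10
    dfa_box_max: int = 40
    entropy_m: int = 2
    entropy_r_fraction: float = 0.15
    mse_scales: tuple = (1, 2, 3, 4)
    mse_required_strides: int = 800
    nonlinear_min_strides: int = 256    # "> 255 strides"
    n_reshapes: int = 100
    n_surrogates: int = 100
    max_separation: int = 100
    seed: int = 0
    inputs: list = field(default_factory=list)  # dicts: path, participant_id, group
    output_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.mse_scales, list):
            cfg.mse_scales = tuple(cfg.mse_scales)
        return cfg


@dataclass
class RunReport:
    """Batch result: measure table, frequency table, summary, warnings."""

    measures: pd.DataFrame
    frequency: pd.DataFrame
    group_summary: pd.DataFrame | None
    warnings: list

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measures.to_csv(outdir / "measures.csv", index=False)
        self.frequency.to_csv(outdir / "bout_frequency.csv", index=False)
        if self.group_summary is not None:
            self.group_summary.to_csv(outdir / "group_summary.csv")
        (outdir / "warnings.log").write_text("\n".join(self.warnings) + "\n"
                                             if self.warnings else "")


def _mean_or_none(values: list) -> float | None:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.mean(vals)) if vals else None


def process_recording(rec: AccelRecording, config: PipelineConfig,
                      participant_id: str | None = None,
                      seed: int | None = None,
                      ) -> tuple[MeasureSet, dict, list]:
    """Run all stages on one recording.

    Returns the participant's :class:`MeasureSet`, a dict with the
    raw- and filtered-stream bout lists, and a list of warning strings.
    """
    warnings_log: list[str] = []
    ms = MeasureSet(participant_id=participant_id)

    sig = resample_uniform(rec, fs=config.fs)
    sig = correct_orientation_and_gravity(sig, invert=config.invert)
    sig_f = lowpass_filter(sig, cutoff=config.lowpass_cutoff_hz,
                           order=config.filter_order)
    ev_f, ev_r = events_mod.detect_heel_contacts(
        sig, sig_f,
        hp_cutoff=config.hp_cutoff_hz, cwt_scale=config.cwt_scale,
        min_separation=config.min_separation_s,
        threshold_fraction=config.threshold_fraction,
        offset_frames=config.offset_frames)

    seg_kwargs = dict(gap_s=config.gap_s, min_raw_strides=config.min_raw_strides,
                      trim=config.trim_strides, min_strides=config.min_strides,
                      participant_id=participant_id)
    bouts_f = bouts_mod.segment_bouts(ev_f, **seg_kwargs)
    bouts_r = bouts_mod.segment_bouts(ev_r, **seg_kwargs)
    all_bouts = {"filtered": bouts_f, "raw": bouts_r}

    # -- linear measures: filtered-stream bouts, averaged across bouts
    if bouts_f:
        lin = [measures_mod.linear_measures(b) for b in bouts_f]
        ms.xisi = _mean_or_none([v[0] for v in lin])
        ms.sd = _mean_or_none([v[1] for v in lin])
        ms.cov = 100.0 * ms.sd / ms.xisi
        for name in ("xisi", "sd", "cov"):
            ms.eligibility[name] = None
    else:
        reason = f"no bouts with >= {config.min_strides} strides"
        for name in ("xisi", "sd", "cov"):
            ms.eligibility[name] = reason

    # -- bout-wise nonlinear measures: raw-stream bouts above 255 strides
    long_bouts = [b for b in bouts_r
                  if b.n_strides >= config.nonlinear_min_strides]
    if long_bouts:
        fsi_vals, apen_vals, saen_vals = [], [], []
        for b in long_bouts:
            fsi_vals.append(measures_mod.dfa(
                b.isi, box_min=config.dfa_box_min, box_max=config.dfa_box_max,
                min_length=config.nonlinear_min_strides).alpha)
            params = EntropyParams.from_series(
                b.isi, m=config.entropy_m, r_fraction=config.entropy_r_fraction)
            apen_vals.append(measures_mod.apen(b.isi, params))
            se = measures_mod.saen(b.isi, params)
            if se is None:
                warnings_log.append(
                    f"{participant_id}: SaEn undefined on bout at {b.start_s:.1f}s")
            saen_vals.append(se)
        ms.fsi = _mean_or_none(fsi_vals)
        ms.apen = _mean_or_none(apen_vals)
        ms.saen = _mean_or_none(saen_vals)
        for name in ("fsi", "apen", "saen"):
            ms.eligibility[name] = None
    else:
        reason = (f"no raw-stream bouts with > "
                  f"{config.nonlinear_min_strides - 1} strides")
        for name in ("fsi", "apen", "saen"):
            ms.eligibility[name] = reason

    # -- fixed-length measures: first 800 strides of the longest raw bout
    longest = max(bouts_r, key=lambda b: b.n_strides, default=None)
    need = config.mse_required_strides
    if longest is not None and longest.n_strides >= need:
        series = longest.isi[:need]
        params = EntropyParams.from_series(
            series, m=config.entropy_m, r_fraction=config.entropy_r_fraction)
        mse_res = measures_mod.mse(series, scales=config.mse_scales,
                                   params=params, n_required=need)
        ms.mse = dict(mse_res.values)
        try:
            ms.ci = measures_mod.complexity_index(mse_res)
            ms.eligibility["ci"] = None
        except ValueError as exc:
            ms.eligibility["ci"] = str(exc)
            warnings_log.append(f"{participant_id}: {exc}")
        dec = decay_mod.persistence_decay(
            series, n_surrogates=config.n_surrogates, seed=seed,
            params=params, max_s=config.max_separation,
            box_min=config.dfa_box_min, box_max=config.dfa_box_max)
        ms.spd = dec.spd
        ms.enhl = dec.enhl
        if dec.spd_censored:
            warnings_log.append(f"{participant_id}: SPD censored at "
                                f"{config.max_separation}")
        if dec.enhl_censored:
            warnings_log.append(f"{participant_id}: EnHL censored at "
                                f"{config.max_separation}")
        for name in ("mse", "spd", "enhl"):
            ms.eligibility[name] = None
    else:
        have = longest.n_strides if longest is not None else 0
        reason = f"longest raw bout has {have} strides; needs {need}"
        for name in ("mse", "ci", "spd", "enhl"):
            ms.eligibility[name] = reason

    return ms, all_bouts, warnings_log


def run_pipeline(config: PipelineConfig, recordings=None) -> RunReport:
    """Process a batch of recordings.

    ``recordings`` is a list of ``(participant_id, group, AccelRecording)``
    tuples; if omitted, recordings are read from ``config.inputs`` (each a
    dict with ``path`` and optional ``participant_id``/``group``).  A stage
    error flags the participant and is logged, never fatal to the batch.
    """
    if recordings is None:
        recordings = []
        for i, item in enumerate(config.inputs):
            rec = read_recording_csv(item["path"],
                                     vertical_axis=config.vertical_axis,
                                     fs_nominal=config.fs)
            recordings.append((item.get("participant_id", f"P{i + 1}"),
                               item.get("group"), rec))

    rows, groups, warnings_log = [], {}, []
    bouts_by_participant: dict[str, list] = {}
    for idx, (pid, group, rec) in enumerate(recordings):
        part_seed = (int(config.seed) + idx) % (2 ** 31)
        try:
            ms, all_bouts, wlog = process_recording(
                rec, config, participant_id=pid, seed=part_seed)
            warnings_log.extend(wlog)
            bouts_by_participant[pid] = all_bouts["raw"]
        except Exception as exc:
            log.exception("participant %s failed", pid)
            warnings_log.append(f"{pid}: stage error: {exc}")
            ms = MeasureSet(participant_id=pid,
                            eligibility={"all": f"stage error: {exc}"})
            bouts_by_participant[pid] = []
        row = ms.as_dict()
        row["group"] = group
        rows.append(row)
        groups[pid] = group

    measures_df = pd.DataFrame(rows)
    freq = bouts_mod.bout_frequency_table(bouts_by_participant)
    summary = None
    if measures_df["group"].notna().any():
        try:
            summary = group_summary(measures_df)
        except ValueError as exc:
            warnings_log.append(f"group summary skipped: {exc}")
    return RunReport(measures=measures_df, frequency=freq,
                     group_summary=summary, warnings=warnings_log)


def group_summary(measures_df: pd.DataFrame, group_col: str = "group",
                  group_order: list | None = None) -> pd.DataFrame:
    """Descriptive mean ± SD per measure per group, plus a difference column.

    With exactly two groups the difference is first-listed minus
    second-listed group mean (pass ``group_order`` to fix the convention,
    e.g. older minus young).
    """
    df = measures_df.dropna(subset=[group_col])
    labels = group_order or sorted(df[group_col].unique())
    unknown = set(df[group_col]) - set(labels)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    numeric = [c for c in df.columns
               if c not in ("participant_id", group_col)
               and pd.api.types.is_numeric_dtype(df[c])]
    out = {}
    for g in labels:
        sub = df[df[group_col] == g][numeric]
        out[f"{g}_mean"] = sub.mean()
        out[f"{g}_sd"] = sub.std(ddof=1)
    summary = pd.DataFrame(out)
    if len(labels) == 2:
        summary["difference"] = (summary[f"{labels[0]}_mean"]
                                 - summary[f"{labels[1]}_mean"])
    return summary
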