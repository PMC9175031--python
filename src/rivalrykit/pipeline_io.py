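"""File I/O, run configuration, and end-to-end report generation.

File schemas (delimited UTF-8 text, '.' decimal separator, header row;
lines starting with '#' are provenance comments):

* event logs — ``participant_id,trial_id,condition_id,button,t_on,t_off,trial_duration``
  (one row per press interval; ``button`` is ``LEFT`` or ``RIGHT``);
* cohort metadata — ``participant_id,group,age`` (optional ``seed``);
* per-condition metrics — one row per participant x condition with every
  trial-metric field.

The report bundle mirrors the study's summary shapes: a group x condition
table of grouped/ungrouped/mixed dominance times, a group x condition table
of rivalry rates (central and the two same-eye conditions), a five-number
summary per group of the within/between-hemifield epoch difference, and the
statistical battery (mixed ANOVAs, pairwise comparisons, t-tests,
Mann-Whitney U).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .event_stream import (
    Button,
    ButtonIntervalLog,
    aggregate_by_condition,
    compute_trial_metrics,
    epoch_differences_frame,
    metrics_frame,
)
from .stats_engine import (
    independent_t,
    mann_whitney_u,
    mixed_anova,
    pairwise_comparisons,
)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "LOG_COLUMNS",
    "META_COLUMNS",
    "read_event_logs",
    "read_metadata",
    "write_event_logs",
    "write_metadata",
    "analyze_logs",
    "run_pipeline",
]

logger = logging.getLogger("rivalrykit")

LOG_COLUMNS = [
    "participant_id", "trial_id", "condition_id",
    "button", "t_on", "t_off", "trial_duration",
]
META_COLUMNS = ["participant_id", "group", "age"]

GROUPING_CONDITIONS = ["MO_SE_SH", "MO_SE_DH", "MO_DE_SH", "MO_DE_DH"]
RATE_CONDITIONS = ["CENTRAL", "MO_SE_SH", "MO_SE_DH"]


@dataclass
class RunConfig:
    """End-to-end run parameters."""

    tau_overlap: float = 0.4          # s, transition-wave threshold
    tau_gap: float = math.inf         # s, optional switch-run break
    trial_duration: float = 60.0      # s
    seed: int = 0
    logs_path: str | None = None
    metadata_path: str | None = None
    output_dir: str | None = None
    use_age_covariate: bool = True
    pairwise_method: str = "bonferroni"
    report_precision: int = 6

    def __post_init__(self) -> None:
        if self.tau_overlap < 0:
            raise ValueError("tau_overlap must be >= 0")
        if self.tau_gap < 0:
            raise ValueError("tau_gap must be >= 0")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.pairwise_method not in ("bonferroni", "lsd"):
            raise ValueError("pairwise_method must be 'bonferroni' or 'lsd'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_gap"] = "inf" if math.isinf(self.tau_gap) else self.tau_gap
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "tau_gap" in raw and raw["tau_gap"] in ("inf", ".inf", None):
            raw["tau_gap"] = math.inf
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = self.to_dict()
        for key in ("logs_path", "metadata_path", "output_dir"):
            d.pop(key, None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers / writers


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{what}: missing required column {col!r}")


def read_event_logs(path) -> list[ButtonIntervalLog]:
    """Load and validate an event-log file into per-trial logs."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _check_columns(df, LOG_COLUMNS, f"event log {path}")
    dup = df.duplicated(subset=["participant_id", "trial_id", "button", "t_on", "t_off"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"event log {path}: duplicate interval row at index {i}")
    logs: list[ButtonIntervalLog] = []
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=False):
        if grp["condition_id"].nunique() > 1 or grp["trial_duration"].nunique() > 1:
            raise ValueError(
                f"event log {path}: trial ({pid!r}, {tid!r}) has inconsistent "
                "condition_id or trial_duration"
            )
        from .event_stream import validate_log  # local to avoid cycle noise
        raw = ButtonIntervalLog(
            participant_id=str(pid),
            trial_id=str(tid),
            condition_id=str(grp["condition_id"].iloc[0]),
            trial_duration=float(grp["trial_duration"].iloc[0]),
            intervals=[
                (Button(str(b)), float(a), float(o))
                for b, a, o in zip(grp["button"], grp["t_on"], grp["t_off"])
            ],
        )
        logs.append(validate_log(raw))
    return logs


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, META_COLUMNS, f"metadata {path}")
    if df["participant_id"].duplicated().any():
        raise ValueError(f"metadata {path}: duplicate participant_id")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def logs_frame(logs: Sequence[ButtonIntervalLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for button, a, b in log.intervals:
            rows.append({
                "participant_id": log.participant_id,
                "trial_id": log.trial_id,
                "condition_id": log.condition_id,
                "button": button.value,
                "t_on": a,
                "t_off": b,
                "trial_duration": log.trial_duration,
            })
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _write_csv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
            fh.write(f"# {items}\n")
        # shortest round-trip float formatting so write->read->write is stable
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def write_event_logs(logs: Sequence[ButtonIntervalLog], path,
                     provenance: dict | None = None) -> None:
    _write_csv(logs_frame(logs), path, provenance)


def write_metadata(metadata: pd.DataFrame, path,
                   provenance: dict | None = None) -> None:
    _write_csv(metadata, path, provenance)


# ---------------------------------------------------------------------------
# analysis stages


def analyze_logs(
    logs: Sequence[ButtonIntervalLog],
    tau_overlap: float = 0.4,
    tau_gap: float = math.inf,
) -> pd.DataFrame:
    """Per-trial metrics table for a collection of logs."""
    if not logs:
        raise ValueError("no logs found")
    return metrics_frame(
        compute_trial_metrics(log, tau_overlap=tau_overlap, tau_gap=tau_gap)
        for log in logs
    )


def _summary_table(
    per_condition: pd.DataFrame, value_cols: Sequence[str],
    conditions: Sequence[str],
) -> pd.DataFrame:
    sub = per_condition[per_condition["condition_id"].isin(conditions)]
    out = (
        sub.groupby(["condition_id", "group"], sort=False)[list(value_cols)]
        .agg(["mean", "std"])
    )
    out.columns = [f"{v}_{s}" for v, s in out.columns]
    order = pd.MultiIndex.from_product(
        [conditions, list(pd.unique(sub["group"]))],
        names=["condition_id", "group"],
    )
    return out.reindex(order).reset_index()


def _five_number(values: np.ndarray) -> dict:
    v = values[~np.isnan(values)]
    if len(v) == 0:
        return {k: np.nan for k in ("min", "q1", "median", "q3", "max", "mean", "n")}
    return {
        "min": float(np.min(v)),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "q3": float(np.percentile(v, 75)),
        "max": float(np.max(v)),
        "mean": float(np.mean(v)),
        "n": int(len(v)),
    }


@dataclass
class ReportBundle:
    per_trial: pd.DataFrame
    per_condition: pd.DataFrame
    dominance_summary: pd.DataFrame
    rate_summary: pd.DataFrame
    epoch_differences: pd.DataFrame
    epoch_diff_summary: pd.DataFrame
    anova_tables: dict[str, pd.DataFrame]
    pairwise_grouped: pd.DataFrame
    ttest_central_rate: dict
    mwu_epoch_diff: dict
    provenance: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = self.provenance
        _write_csv(self.per_trial, outdir / "per_trial_metrics.csv", prov)
        _write_csv(self.per_condition, outdir / "per_condition_metrics.csv", prov)
        _write_csv(self.dominance_summary, outdir / "dominance_summary.csv", prov)
        _write_csv(self.rate_summary, outdir / "rate_summary.csv", prov)
        _write_csv(self.epoch_differences, outdir / "epoch_differences.csv", prov)
        _write_csv(self.epoch_diff_summary, outdir / "epoch_diff_summary.csv", prov)
        _write_csv(self.pairwise_grouped, outdir / "pairwise_grouped.csv", prov)
        for name, table in self.anova_tables.items():
            _write_csv(table, outdir / f"anova_{name}.csv", prov)
        scalars = {
            "ttest_central_rate": self.ttest_central_rate,
            "mwu_epoch_diff": self.mwu_epoch_diff,
            "provenance": prov,
        }
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(scalars, fh, indent=2, sort_keys=True, default=float)


def _audit_summary(bundle_summary: pd.DataFrame, per_condition: pd.DataFrame,
                   value_cols: Sequence[str], conditions: Sequence[str]) -> None:
    recomputed = _summary_table(per_condition, value_cols, conditions)
    a = bundle_summary.drop(columns=["condition_id", "group"]).to_numpy(dtype=float)
    b = recomputed.drop(columns=["condition_id", "group"]).to_numpy(dtype=float)
    if not np.allclose(a, b, equal_nan=True):
        raise RuntimeError("report self-consistency audit failed")


def run_pipeline(
    config: RunConfig,
    logs: Sequence[ButtonIntervalLog] | None = None,
    metadata: pd.DataFrame | None = None,
) -> ReportBundle:
    """Execute validate -> resolve -> metrics -> aggregate -> stats -> report.

    Inputs may be given in memory; otherwise they are read from the paths in
    ``config``.  Deterministic for fixed inputs and config.
    """
    if logs is None:
        if not config.logs_path:
            raise ValueError("run_pipeline: no logs given and no logs_path configured")
        logs = read_event_logs(config.logs_path)
    if metadata is None:
        if not config.metadata_path:
            raise ValueError("run_pipeline: no metadata given and no metadata_path configured")
        metadata = read_metadata(config.metadata_path)
    logger.info("stage=load n_logs=%d n_participants=%d", len(logs), len(metadata))

    per_trial = analyze_logs(logs, tau_overlap=config.tau_overlap,
                             tau_gap=config.tau_gap)
    logger.info("stage=metrics n_trials=%d", len(per_trial))

    per_condition = aggregate_by_condition(per_trial)
    per_condition = per_condition.merge(
        metadata[["participant_id", "group", "age"]], on="participant_id",
        how="left", validate="many_to_one",
    )
    if per_condition["group"].isna().any():
        missing = per_condition.loc[per_condition["group"].isna(),
                                    "participant_id"].unique()
        raise ValueError(f"participants missing from metadata: {list(missing)[:5]}")
    logger.info("stage=aggregate n_rows=%d", len(per_condition))

    dominance_summary = _summary_table(
        per_condition, ["t_grouped", "t_ungrouped", "t_mixed"],
        GROUPING_CONDITIONS + ["CENTRAL"],
    )
    rate_summary = _summary_table(
        per_condition, ["rivalry_rate"], RATE_CONDITIONS,
    )

    epoch_diffs = epoch_differences_frame(per_condition).merge(
        metadata[["participant_id", "group"]], on="participant_id", how="left"
    )
    epoch_diff_summary = pd.DataFrame([
        {"group": grp, **_five_number(sub["d_epoch"].to_numpy(dtype=float))}
        for grp, sub in epoch_diffs.groupby("group", sort=False)
    ])

    # ----- statistical battery
    grouping = per_condition[
        per_condition["condition_id"].isin(GROUPING_CONDITIONS)
    ]
    anovas: dict[str, pd.DataFrame] = {}
    for dv, name in (("t_grouped", "grouped_time"),
                     ("t_ungrouped", "ungrouped_time"),
                     ("t_mixed", "mixed_time")):
        anovas[name] = mixed_anova(
            grouping, dv=dv, subject="participant_id",
            within="condition_id", between="group",
        )
    percept_long = pd.concat([
        grouping.assign(percept="grouped", time=grouping["t_grouped"]),
        grouping.assign(percept="ungrouped", time=grouping["t_ungrouped"]),
    ], ignore_index=True)
    anovas["percept_by_condition"] = mixed_anova(
        percept_long, dv="time", subject="participant_id",
        within=["condition_id", "percept"], between="group",
    )
    covariate = "age" if config.use_age_covariate else None
    rate_se = per_condition[
        per_condition["condition_id"].isin(["MO_SE_SH", "MO_SE_DH"])
    ]
    anovas["rate_grouped"] = mixed_anova(
        rate_se, dv="rivalry_rate", subject="participant_id",
        within="condition_id", between="group", covariate=covariate,
    )
    rate_3 = per_condition[per_condition["condition_id"].isin(RATE_CONDITIONS)]
    anovas["rate_with_central"] = mixed_anova(
        rate_3, dv="rivalry_rate", subject="participant_id",
        within="condition_id", between="group", covariate=covariate,
    )
    logger.info("stage=stats n_models=%d", len(anovas))

    pairwise_grouped = pairwise_comparisons(
        grouping, dv="t_grouped", within="condition_id",
        subject="participant_id", method=config.pairwise_method,
    )

    central = per_condition[per_condition["condition_id"] == "CENTRAL"]
    groups = list(pd.unique(per_condition["group"]))
    if set(groups) == {"control", "glaucoma"}:
        groups = ["control", "glaucoma"]  # report control-minus-patient
    rates = [
        central.loc[central["group"] == grp, "rivalry_rate"].to_numpy(dtype=float)
        for grp in groups
    ]
    tt = independent_t(rates[0], rates[1])
    ttest_central_rate = {
        "groups": groups, "t": tt.t, "df": tt.df, "p": tt.p, "d": tt.d,
    }
    d_by_group = [
        epoch_diffs.loc[epoch_diffs["group"] == grp, "d_epoch"]
        .dropna().to_numpy(dtype=float)
        for grp in groups
    ]
    U, p_u = mann_whitney_u(d_by_group[0], d_by_group[1])
    mwu_epoch_diff = {"groups": groups, "U": U, "p": p_u}

    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "n_logs": len(logs),
        "n_participants": int(metadata["participant_id"].nunique()),
    }

    bundle = ReportBundle(
        per_trial=per_trial,
        per_condition=per_condition,
        dominance_summary=dominance_summary,
        rate_summary=rate_summary,
        epoch_differences=epoch_diffs,
        epoch_diff_summary=epoch_diff_summary,
        anova_tables=anovas,
        pairwise_grouped=pairwise_grouped,
        ttest_central_rate=ttest_central_rate,
        mwu_epoch_diff=mwu_epoch_diff,
        provenance=provenance,
    )
    _audit_summary(bundle.dominance_summary, per_condition,
                   ["t_grouped", "t_ungrouped", "t_mixed"],
                   GROUPING_CONDITIONS + ["CENTRAL"])
    _audit_summary(bundle.rate_summary, per_condition,
                   ["rivalry_rate"], RATE_CONDITIONS)
    if config.output_dir:
        bundle.write(config.output_dir)
        logger.info("stage=report outdir=%s", config.output_dir)
    return bundle
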