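"""Long-format I/O, run configuration, and the end-to-end pipeline.

The canonical input is a long-format CSV with one row per subject x
occasion and the eight columns ``subject_id, unit_id, group_id,
occasion, week, sccs, ks2, kon``; KON-2006 is recorded at occasion 1
only, KS-II at least at the first (pre) and last (post) occasion.

:func:`run_pipeline` executes the stages in order — per-subject log
trend + fluctuation + shape, disposition categorization, then the
inferential battery — and returns a :class:`RunReport` that can write a
per-subject CSV, a markdown report, CSV tables, and a schema-versioned
JSON summary of every statistic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import outcome_stats as ost
from .cohort import (
    SubjectRecord,
    categorize_disposition,
    kon_cutoff_from_integrated,
    validate_dispositions_kmeans,
)
from .errors import (
    IntegrityError,
    InvalidArgumentError,
    InvalidCohortError,
    SchemaError,
)
from .psychometrics import KON, KS2, SCCS
from .trajectory import MeasurementSeries, classify_shape, fit_log_trajectory

__all__ = [
    "RunConfig",
    "LongTable",
    "RunReport",
    "read_long_csv",
    "build_records",
    "build_cohort_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "subject_id", "unit_id", "group_id", "occasion", "week", "sccs", "ks2", "kon",
)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (flat, YAML-compatible)."""

    sccs_rci: float = 3.48
    ks2_rci: float = 56.6
    scc_cutoff: float = 34.0
    kon_cutoff: Union[str, float] = "auto"   # "auto" = integrated-group median
    run_gtests: bool = True
    run_anova: bool = True
    run_interaction: bool = True
    run_multilevel: bool = True
    run_kmeans: bool = True
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sccs_rci <= 0 or self.ks2_rci <= 0:
            raise InvalidArgumentError("reliable-change thresholds must be > 0")
        if isinstance(self.kon_cutoff, str) and self.kon_cutoff != "auto":
            raise InvalidArgumentError("kon_cutoff must be 'auto' or a number")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class LongTable:
    """Validated long-format repeated-measures table."""

    data: pd.DataFrame
    warnings: List[str] = field(default_factory=list)
    rejected: Dict[str, str] = field(default_factory=dict)  # subject -> reason

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()


def read_long_csv(path: Union[str, Path]) -> LongTable:
    """Read and validate the long-format CSV.

    Raises :class:`SchemaError` for missing columns,
    :class:`IntegrityError` for duplicate (subject, occasion) pairs or
    non-increasing occasions, and :class:`InvalidArgumentError` (listing
    1-based data row numbers) for out-of-range scores.  Subjects with
    fewer than two occasions are excluded and listed in ``rejected``;
    subjects with fewer than four occasions are kept with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    dup = df.duplicated(subset=["subject_id", "occasion"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "occasion"]].drop_duplicates()
        raise IntegrityError(
            f"duplicate (subject, occasion) pairs: {pairs.to_dict('records')}"
        )
    bad_rows: List[int] = []
    sccs_bad = ~df["sccs"].apply(SCCS.in_range)
    ks2_bad = df["ks2"].notna() & ~df["ks2"].apply(KS2.in_range)
    kon_bad = df["kon"].notna() & ~df["kon"].apply(KON.in_range)
    for mask in (sccs_bad, ks2_bad, kon_bad):
        bad_rows.extend((df.index[mask] + 1).tolist())
    if bad_rows:
        raise InvalidArgumentError(
            f"score(s) outside instrument range at data row(s) {sorted(set(bad_rows))}"
        )
    warnings: List[str] = []
    rejected: Dict[str, str] = {}
    keep_parts = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("occasion")
        occ = sub["occasion"].to_numpy()
        if occ[0] != 1:
            raise IntegrityError(f"{sid}: occasions must start at 1 (got {occ[0]})")
        if np.any(np.diff(occ) <= 0):
            raise IntegrityError(f"{sid}: occasions must be strictly increasing")
        k = len(sub)
        if k < 2:
            rejected[sid] = f"only {k} occasion(s); at least 2 required"
            continue
        if k < 4 or k > 9:
            warnings.append(f"{sid}: {k} occasions is outside the study range 4-9")
        if sub["ks2"].isna().iloc[0] or sub["ks2"].isna().iloc[-1]:
            rejected[sid] = "KS-II missing at the first or last occasion"
            continue
        if sub["kon"].isna().iloc[0]:
            rejected[sid] = "KON-2006 missing at occasion 1"
            continue
        keep_parts.append(sub)
    if not keep_parts:
        raise InvalidCohortError("no usable subjects in the input file")
    out = pd.concat(keep_parts, ignore_index=True)
    for msg in warnings:
        log.warning(msg)
    for sid, reason in rejected.items():
        log.warning("rejected %s: %s", sid, reason)
    return LongTable(data=out, warnings=warnings, rejected=rejected)


def build_records(table: LongTable) -> List[SubjectRecord]:
    """Assemble one :class:`SubjectRecord` per subject from the long table."""
    records: List[SubjectRecord] = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        for sid, sub in table.data.groupby("subject_id", sort=False):
            sub = sub.sort_values("occasion")
            series = MeasurementSeries(
                subject_id=str(sid),
                scores=tuple(float(v) for v in sub["sccs"]),
                occasions=tuple(int(o) for o in sub["occasion"]),
                weeks=tuple(float(w) for w in sub["week"]),
            )
            records.append(SubjectRecord(
                subject_id=str(sid),
                unit_id=str(sub["unit_id"].iloc[0]),
                group_id=str(sub["group_id"].iloc[0]),
                scc_t1=float(sub["sccs"].iloc[0]),
                kon_t1=float(sub["kon"].iloc[0]),
                ks2_pre=float(sub["ks2"].iloc[0]),
                ks2_post=float(sub["ks2"].iloc[-1]),
                series=series,
            ))
    for w in caught:
        table.warnings.append(str(w.message))
    return records


def build_cohort_table(
    records: List[SubjectRecord], config: Optional[RunConfig] = None
) -> Tuple[pd.DataFrame, float]:
    """Per-subject analysis table and the KON cutoff actually applied.

    Columns: identifiers, baselines, log-trend slope/intercept,
    fluctuation rmse, shape, disposition, change, improved.
    """
    config = config or RunConfig()
    if isinstance(config.kon_cutoff, str):
        kon_cutoff = kon_cutoff_from_integrated(records, config.scc_cutoff)
    else:
        kon_cutoff = float(config.kon_cutoff)
    rows = []
    for r in records:
        fit = fit_log_trajectory(r.series)
        shape = classify_shape(r.series, rci=config.sccs_rci)
        disp = categorize_disposition(r, config.scc_cutoff, kon_cutoff)
        change = ost.change_score(r.ks2_pre, r.ks2_post)
        rows.append({
            "subject_id": r.subject_id,
            "unit_id": r.unit_id,
            "group_id": r.group_id,
            "scc_t1": r.scc_t1,
            "kon_t1": r.kon_t1,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "rmse": fit.rmse,
            "shape": shape.value,
            "disposition": disp.value,
            "ks2_pre": r.ks2_pre,
            "ks2_post": r.ks2_post,
            "change": change,
            "improved": ost.improvement_flag(change, config.ks2_rci),
        })
    return pd.DataFrame(rows), kon_cutoff


@dataclass
class RunReport:
    """All pipeline outputs: per-subject table, statistics, warnings."""

    config: RunConfig
    per_subject: pd.DataFrame
    stats: Dict
    warnings: List[str] = field(default_factory=list)
    rejected: Dict[str, str] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_subjects": int(len(self.per_subject)),
            "n_rejected": len(self.rejected),
            "warnings": list(self.warnings),
            **self.stats,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        (out / "tables").mkdir(parents=True, exist_ok=True)
        self.per_subject.to_csv(out / "subjects.csv", index=False)
        (out / "report.json").write_text(self.to_json())
        (out / "report.md").write_text(self._markdown())
        if "g_tests" in self.stats:
            pd.DataFrame(self.stats["g_tests"]).to_csv(
                out / "tables" / "g_tests.csv", index=False)
        if "anova" in self.stats:
            pd.DataFrame(self.stats["anova"]["table"]).to_csv(
                out / "tables" / "anova.csv")
            pd.DataFrame(self.stats["anova"]["cells"]).to_csv(
                out / "tables" / "anova_cells.csv", index=False)
        if "variance_components" in self.stats:
            pd.DataFrame(self.stats["variance_components"]["wald"]).T.to_csv(
                out / "tables" / "variance_components.csv")

    def _markdown(self) -> str:
        s = self.stats
        lines = ["# SCC trajectory pipeline report", ""]
        lines.append(f"Subjects analyzed: {len(self.per_subject)}; "
                     f"rejected: {len(self.rejected)}; "
                     f"warnings: {len(self.warnings)}")
        lines.append("")
        lines.append("## Cohort")
        lines.append("")
        lines.append(f"- KON-2006 cutoff applied: {s['kon_cutoff']:.1f} "
                     f"(SCC cutoff {s['scc_cutoff']:.0f})")
        lines.append(f"- Dispositions: {s['disposition_counts']}")
        lines.append(f"- Shapes: {s['shape_counts']}")
        if "kmeans_cramers_v" in s:
            lines.append(f"- k-means validation Cramér's V = "
                         f"{s['kmeans_cramers_v']:.2f}")
        lines.append("")
        if "variance_components" in s:
            vc = s["variance_components"]
            lines += ["## Variance components (null model)", "",
                      "| Parameter | Estimate | Wald z | p |",
                      "| --- | --- | --- | --- |"]
            for name in ("residual", "var_group", "var_unit"):
                w = vc["wald"].get(name)
                if w:
                    lines.append(f"| {name} | {w['estimate']:.2f} | "
                                 f"{w['z']:.2f} | {w['p']:.3g} |")
            lines.append("")
        if "interaction" in s:
            it = s["interaction"]
            lines += ["## Fluctuation x disposition moderation", "",
                      "| Term | Estimate | t | p | incr. R² |",
                      "| --- | --- | --- | --- | --- |"]
            for term in ("Intercept", "rmse", "pd_fi", "rmse:pd_fi"):
                inc = it["incremental_r2"].get(term)
                inc_s = f"{inc:.3f}" if inc is not None else "-"
                lines.append(f"| {term} | {it['params'][term]:.2f} | "
                             f"{it['tvalues'][term]:.2f} | "
                             f"{it['pvalues'][term]:.3g} | {inc_s} |")
            lines.append(f"\nTotal R² = {it['total_r2']:.3f}")
            lines.append("")
        if "anova" in s:
            an = s["anova"]
            lines += ["## Shape x disposition ANOVA", "",
                      "| Term | df | F | p | partial η² |",
                      "| --- | --- | --- | --- | --- |"]
            for term, row in an["table"].items():
                if term == "Residual":
                    continue
                lines.append(f"| {term} | {row['df']:.0f} | {row['F']:.2f} | "
                             f"{row['p']:.3g} | {row['partial_eta2']:.2f} |")
            lines.append("")
        if "g_tests" in s:
            lines += ["## Improvement x shape likelihood-ratio tests", "",
                      "| Stratum | Shape | a/b/c/d | G | p |",
                      "| --- | --- | --- | --- | --- |"]
            for t in s["g_tests"]:
                if t["skipped"]:
                    lines.append(f"| {t['stratum']} | {t['shape']} | - | "
                                 f"skipped ({t['note']}) | - |")
                else:
                    lines.append(
                        f"| {t['stratum']} | {t['shape']} | "
                        f"{t['a']}/{t['b']}/{t['c']}/{t['d']} | "
                        f"{t['statistic']:.2f} | {t['p']:.3g} |")
            lines.append("")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: RunConfig, table: LongTable) -> RunReport:
    """Execute trajectory -> cohort -> outcome statistics on a table."""
    timings: Dict[str, float] = {}
    t0 = time.perf_counter()
    records = build_records(table)
    cohort, kon_cutoff = build_cohort_table(records, config)
    timings["trajectory_cohort"] = time.perf_counter() - t0

    stats: Dict = {
        "scc_cutoff": config.scc_cutoff,
        "kon_cutoff": kon_cutoff,
        "kon_cutoff_mode": ("auto" if isinstance(config.kon_cutoff, str)
                            else "fixed"),
        "shape_counts": cohort["shape"].value_counts().to_dict(),
        "disposition_counts": cohort["disposition"].value_counts().to_dict(),
        "n_improved": int(cohort["improved"].sum()),
    }
    if config.run_kmeans:
        t = time.perf_counter()
        try:
            cv = validate_dispositions_kmeans(
                records, seed=config.seed, scc_cutoff=config.scc_cutoff,
                kon_cutoff=kon_cutoff)
            stats["kmeans_cramers_v"] = cv.cramers_v
        except InvalidCohortError as exc:
            table.warnings.append(f"kmeans validation skipped: {exc}")
        timings["kmeans"] = time.perf_counter() - t
    if config.run_gtests:
        t = time.perf_counter()
        stats["g_tests"] = [
            {
                "stratum": r.stratum, "shape": r.shape,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "statistic": r.result.statistic if r.result else None,
                "p": r.result.p if r.result else None,
                "skipped": r.skipped, "note": r.note,
            }
            for r in ost.shape_frequency_tests(cohort)
        ]
        corrs = {}
        for stratum in ("whole", "integrated_functional", "other_three"):
            try:
                r, n, p = ost.subgroup_correlation(cohort, stratum)
                corrs[stratum] = {"r": r, "n": n, "p": p}
            except Exception as exc:  # degenerate stratum: recorded, not fatal
                corrs[stratum] = {"error": str(exc)}
        stats["correlations"] = corrs
        timings["g_tests"] = time.perf_counter() - t
    if config.run_interaction:
        t = time.perf_counter()
        fit = ost.fit_interaction_model(cohort)
        stats["interaction"] = {
            "params": fit.params, "tvalues": fit.tvalues,
            "pvalues": fit.pvalues, "incremental_r2": fit.incremental_r2,
            "total_r2": fit.total_r2, "n": fit.n,
        }
        timings["interaction"] = time.perf_counter() - t
    if config.run_anova:
        t = time.perf_counter()
        an = ost.two_way_anova(cohort)
        stats["anova"] = {
            "table": an.table.to_dict(orient="index"),
            "cells": an.cell_stats.reset_index().to_dict(orient="records"),
            "dropped_levels": list(an.dropped_levels),
        }
        timings["anova"] = time.perf_counter() - t
    if config.run_multilevel:
        t = time.perf_counter()
        vc = ost.variance_components_null(cohort)
        stats["variance_components"] = {
            "residual": vc.residual, "var_group": vc.var_group,
            "var_unit": vc.var_unit, "intercept": vc.intercept,
            "method": vc.method, "notes": list(vc.notes),
            "wald": {k: dataclasses.asdict(w) for k, w in vc.wald.items()},
        }
        timings["multilevel"] = time.perf_counter() - t
    for stage, dt in timings.items():
        log.info("stage %-18s %.3f s", stage, dt)
    report = RunReport(config=config, per_subject=cohort, stats=stats,
                       warnings=list(table.warnings), rejected=dict(table.rejected),
                       timings=timings)
    if config.out_dir:
        report.write(config.out_dir)
    return report
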