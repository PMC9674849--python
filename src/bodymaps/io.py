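"""File formats: event tables, map grids, reports.

Event files are CSV with header ``subject_id,stimulus,panel,col,row``
(panel is ``activation`` or ``deactivation``; ``col`` is x, ``row`` is
y, 0-based from the top-left), or JSON-lines with one record per line.
Grids are plain CSV (one row per canvas row); reports are JSON.
Stimulus labels are free text, matched case-insensitively downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .preprocess import QCReport, SubjectBSM
from .simulate import Cohort, CohortConfig, PaintRecord
from .similarity import SimilarityMatrix
from .stats import GroupMap
from .template import BodyTemplate

__all__ = [
    "events_to_dataframe",
    "write_events_csv",
    "read_events_csv",
    "write_cohort_jsonl",
    "read_cohort_jsonl",
    "write_truth_registry",
    "write_grid_csv",
    "read_grid_csv",
    "write_group_map",
    "read_group_map",
    "write_qc_report",
    "write_similarity_csv",
    "read_similarity_csv",
    "write_classification_report",
]

PANELS = ("activation", "deactivation")


def events_to_dataframe(records: list[PaintRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for r, c in rec.events:
            rows.append((rec.subject_id, rec.stimulus, rec.panel, int(c), int(r)))
    return pd.DataFrame(rows, columns=["subject_id", "stimulus", "panel", "col", "row"])


def write_events_csv(records: list[PaintRecord], path: str | Path) -> None:
    events_to_dataframe(records).to_csv(path, index=False)


def read_events_csv(path: str | Path, template: BodyTemplate | None = None) -> list[PaintRecord]:
    """Read an event CSV back into PaintRecords (one per subject/stimulus/panel).

    ``completed`` is recomputed from the events if a template is given
    (at least one in-mask pixel touched), else set True for any
    non-empty record.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "stimulus", "panel", "col", "row"}
    if not required.issubset(df.columns):
        raise ValueError(f"event CSV must have columns {sorted(required)}")
    bad = set(df["panel"].unique()) - set(PANELS)
    if bad:
        raise ValueError(f"unknown panel values {sorted(bad)}")
    records = []
    for (sid, stim), group in df.groupby(["subject_id", "stimulus"], sort=True):
        panel_events = {}
        for panel in PANELS:
            sub = group[group["panel"] == panel]
            panel_events[panel] = np.column_stack(
                [sub["row"].to_numpy(int), sub["col"].to_numpy(int)]
            ) if len(sub) else np.empty((0, 2), dtype=int)
        if template is not None:
            completed = any(
                len(ev) and template.mask[ev[:, 0], ev[:, 1]].any()
                for ev in panel_events.values()
            )
        else:
            completed = any(len(ev) for ev in panel_events.values())
        for panel in PANELS:
            records.append(PaintRecord(str(sid), str(stim), panel, panel_events[panel], completed))
    return records


def write_cohort_jsonl(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in cohort.records:
            fh.write(json.dumps({
                "subject_id": rec.subject_id,
                "stimulus": rec.stimulus,
                "panel": rec.panel,
                "completed": rec.completed,
                "events": rec.events.tolist(),
            }) + "\n")


def read_cohort_jsonl(path: str | Path) -> list[PaintRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            records.append(PaintRecord(
                d["subject_id"], d["stimulus"], d["panel"],
                np.array(d["events"], dtype=int).reshape(-1, 2), d["completed"],
            ))
    return records


def write_truth_registry(cohort: Cohort, path: str | Path) -> None:
    payload = {
        "stimuli": list(cohort.config.stimuli),
        "anomalous_subjects": sorted(cohort.anomalous_subjects),
        "truths": {k: np.asarray(v).tolist() for k, v in cohort.truths.items()},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def write_grid_csv(grid: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(grid, float), delimiter=",", fmt="%.10g")


def read_grid_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_group_map(gm: GroupMap, out_dir: str | Path, slug: str) -> list[Path]:
    """Serialize a GroupMap as t/p/sig CSV grids plus JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in (("t", gm.t), ("p", gm.p), ("sig", gm.sig_mask.astype(float))):
        p = out_dir / f"{slug}_{name}.csv"
        write_grid_csv(grid, p)
        paths.append(p)
    meta = {
        "stimulus": gm.stimulus,
        "n_subjects": gm.n_subjects,
        "df": gm.df,
        "alpha": gm.alpha,
        "fdr_critical_p": gm.fdr_critical_p,
        "min_sig_abs_t": None if np.isnan(gm.min_sig_abs_t) else gm.min_sig_abs_t,
        "n_significant": int(gm.sig_mask.sum()),
    }
    meta_path = out_dir / f"{slug}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths.append(meta_path)
    return paths


def read_group_map(out_dir: str | Path, slug: str) -> GroupMap:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{slug}_meta.json").read_text())
    t = read_grid_csv(out_dir / f"{slug}_t.csv")
    p = read_grid_csv(out_dir / f"{slug}_p.csv")
    sig = read_grid_csv(out_dir / f"{slug}_sig.csv") > 0.5
    mst = meta["min_sig_abs_t"]
    return GroupMap(
        stimulus=meta["stimulus"], n_subjects=meta["n_subjects"], t=t, p=p,
        alpha=meta["alpha"], fdr_critical_p=meta["fdr_critical_p"], sig_mask=sig,
        min_sig_abs_t=float("nan") if mst is None else float(mst),
    )


def write_qc_report(report: QCReport, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    payload = {
        "mean": report.mean,
        "sd": report.sd,
        "k": report.k,
        "threshold": report.threshold,
        "excluded": sorted(report.excluded),
        "kept": sorted(report.kept),
        "reasons": dict(sorted(report.reasons.items())),
        "counts": dict(sorted(report.counts.items())),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if csv_path is not None:
        df = pd.DataFrame(
            [(sid, cnt, sid in set(report.excluded)) for sid, cnt in sorted(report.counts.items())],
            columns=["subject_id", "completed_maps", "excluded"],
        )
        df.to_csv(csv_path, index=False)


def write_similarity_csv(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.r, index=sim.labels, columns=sim.labels).to_csv(path, float_format="%.10g")


def read_similarity_csv(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(labels=list(df.columns), r=df.to_numpy(float), n_pixels_used=0)


def write_classification_report(
    report: ClassificationReport, json_path: str | Path, confusion_csv: str | Path | None = None
) -> None:
    payload = {
        "mean": report.mean_accuracy,
        "sd": report.sd_accuracy,
        "sem": report.sem_accuracy,
        "chance": report.chance,
        "n_components": report.n_components,
        "folds": report.folds,
        "iterations": report.iterations,
        "labels": report.labels,
        "per_iteration": report.accuracies.tolist(),
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if confusion_csv is not None:
        pd.DataFrame(report.confusion_pct, index=report.labels, columns=report.labels).to_csv(
            confusion_csv, float_format="%.6g"
        )
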