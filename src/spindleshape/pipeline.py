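"""Orchestration: load per-cell records, predict, score, summarize.

The unit of analysis is one mitotic division of one blastomere: a cell
outline (apical-plane contour), the observed spindle poles, and labels
(lineage, stage, mitotic phase, experimental group).  ``run_analysis``
predicts the spindle for every record, scores centering and orienting
deviations, and aggregates pooled and per-lineage statistics.
``run_mesh_stage`` turns labeled 3D blastomere meshes into shape metrics
and extracted apical-plane contours that feed the same analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .geometry import (
    Contour2D,
    InvalidShapeError,
    LabeledMesh,
    SpindleAxis,
    apical_surface_ratio,
    extract_apical_plane,
    principal_axes,
    sphericity,
)
from .metrics import centering_deviation, orienting_deviation
from .spindle_model import (
    InfeasiblePlacementError,
    ModelParams,
    predict_spindle,
)
from .stats import (
    THRESHOLDS_DEG,
    DeviationSummary,
    group_compare,
    summarize_deviations,
)

logger = logging.getLogger("spindleshape")

#: germ-line precursors undergoing CAB-driven unequal cleavage; their
#: spindles are positioned by a cortical cue the geometric model does not
#: capture, so they are excluded from pooled deviation statistics.
DEFAULT_EXCLUDED_LINEAGES = ("B4.1", "B5.2", "B6.3")

TABLE_COLUMNS = [
    "cell_id",
    "lineage",
    "stage",
    "phase",
    "group",
    "centering_pct",
    "orienting_deg",
    "degenerate",
    "status",
]


class CellValidationError(ValueError):
    """One or more cell records violate the input schema."""


@dataclass
class CellRecord:
    """One analyzed division: labels, contour and observed spindle."""

    cell_id: str
    lineage: str
    stage: int
    phase: str
    group: str
    contour: Contour2D
    observed: SpindleAxis
    entry_time_min: float | None = None
    reference_axis_deg: float | None = None

    def validate(self) -> list[str]:
        """Return a list of human-readable problems (empty if valid)."""
        problems = []
        poles = np.array([self.observed.pole_a, self.observed.pole_b])
        if not self.contour.contains(poles).all():
            problems.append(
                f"cell {self.cell_id!r}: observed spindle pole outside contour"
            )
        return problems


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    model: ModelParams = field(default_factory=ModelParams)
    thresholds: tuple[float, ...] = THRESHOLDS_DEG
    misorientation_threshold: float = 45.0
    exclude_lineages: tuple[str, ...] = DEFAULT_EXCLUDED_LINEAGES
    phase_filter: str | None = "metaphase"
    tests: list[dict] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if list(t) != sorted(t):
            raise ValueError("thresholds must be sorted ascending")
        self.thresholds = t

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelParams(**d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "model": {
                "beta": self.model.beta,
                "n_rays": self.model.n_rays,
                "dtheta": self.model.dtheta,
                "spindle_length_mode": self.model.spindle_length_mode,
                "spindle_fraction": self.model.spindle_fraction,
                "center_mode": self.model.center_mode,
                "relief_tol": self.model.relief_tol,
            },
            "thresholds": list(self.thresholds),
            "misorientation_threshold": self.misorientation_threshold,
            "exclude_lineages": list(self.exclude_lineages),
            "phase_filter": self.phase_filter,
            "tests": self.tests,
            "seed": self.seed,
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------------
# cells.json I/O
# --------------------------------------------------------------------------

def _record_from_entry(entry: dict, base_dir: Path) -> CellRecord:
    if "contour_um" in entry:
        contour = Contour2D(np.asarray(entry["contour_um"], dtype=float))
    elif "contour_csv" in entry:
        contour = Contour2D.from_csv(base_dir / entry["contour_csv"])
    else:
        raise KeyError("contour_um")
    poles = np.asarray(entry["poles_um"], dtype=float).reshape(2, 2)
    return CellRecord(
        cell_id=str(entry["cell_id"]),
        lineage=str(entry["lineage"]),
        stage=int(entry["stage"]),
        phase=str(entry["phase"]),
        group=str(entry.get("group", "control")),
        contour=contour,
        observed=SpindleAxis(tuple(poles[0]), tuple(poles[1])),
        entry_time_min=entry.get("entry_time_min"),
        reference_axis_deg=entry.get("reference_axis_deg"),
    )


def load_cells(path: str | Path) -> list[CellRecord]:
    """Load and validate a cells.json file.

    All per-record problems are collected and reported together; any
    problem aborts the load.
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    entries = payload.get("cells", [])
    if not entries:
        raise CellValidationError(f"{path}: no cell records")
    records, problems, seen = [], [], set()
    for i, entry in enumerate(entries):
        cid = entry.get("cell_id", f"<entry {i}>")
        try:
            rec = _record_from_entry(entry, path.parent)
        except (KeyError, TypeError) as exc:
            problems.append(f"cell {cid!r}: missing/invalid field {exc}")
            continue
        except InvalidShapeError as exc:
            problems.append(f"cell {cid!r}: {exc}")
            continue
        if rec.cell_id in seen:
            problems.append(f"cell {rec.cell_id!r}: duplicate cell_id")
        seen.add(rec.cell_id)
        problems.extend(rec.validate())
        records.append(rec)
    if problems:
        raise CellValidationError(
            f"{path}: {len(problems)} invalid record(s):\n  " + "\n  ".join(problems)
        )
    return records


def save_cells(records: list[CellRecord], path: str | Path) -> None:
    """Write records to the cells.json schema (round-trips load_cells)."""
    cells = []
    for r in records:
        entry = {
            "cell_id": r.cell_id,
            "lineage": r.lineage,
            "stage": r.stage,
            "phase": r.phase,
            "group": r.group,
            "contour_um": np.asarray(r.contour.vertices).tolist(),
            "poles_um": [list(r.observed.pole_a), list(r.observed.pole_b)],
        }
        if r.entry_time_min is not None:
            entry["entry_time_min"] = r.entry_time_min
        if r.reference_axis_deg is not None:
            entry["reference_axis_deg"] = r.reference_axis_deg
        cells.append(entry)
    with open(path, "w") as fh:
        json.dump({"cells": cells}, fh, indent=1)


# --------------------------------------------------------------------------
# Analysis
# --------------------------------------------------------------------------

def _select(table: pd.DataFrame, sel: dict) -> pd.Series:
    mask = pd.Series(True, index=table.index)
    if "group" in sel:
        mask &= table["group"] == sel["group"]
    if "lineages" in sel:
        mask &= table["lineage"].isin(sel["lineages"])
    if "invert_lineages" in sel:
        mask &= ~table["lineage"].isin(sel["invert_lineages"])
    return mask


def run_analysis(
    cells: list[CellRecord], config: RunConfig | None = None
) -> tuple[pd.DataFrame, DeviationSummary, dict]:
    """Predict every spindle and aggregate deviation statistics.

    Returns (per-cell table, pooled summary, report).  Pooled statistics
    use non-degenerate records of the configured phase, excluding the
    unequal-cleavage lineages in ``config.exclude_lineages``; every input
    record appears in the table exactly once with a status of analyzed,
    degenerate or skipped.
    """
    config = config or RunConfig()
    if not cells:
        raise ValueError("no cells to analyze")
    rows = []
    predictions = {}
    for rec in cells:
        row = {
            "cell_id": rec.cell_id,
            "lineage": rec.lineage,
            "stage": rec.stage,
            "phase": rec.phase,
            "group": rec.group,
            "centering_pct": np.nan,
            "orienting_deg": np.nan,
            "degenerate": False,
            "status": "analyzed",
        }
        try:
            pred = predict_spindle(rec.contour, rec.observed, config.model)
        except (InfeasiblePlacementError, InvalidShapeError) as exc:
            logger.warning("cell %s skipped: %s", rec.cell_id, exc)
            row["status"] = "skipped"
            rows.append(row)
            continue
        predictions[rec.cell_id] = pred
        row["degenerate"] = pred.degenerate
        row["orienting_deg"] = orienting_deviation(rec.observed, pred.axis)
        try:
            row["centering_pct"] = centering_deviation(
                rec.observed, pred.axis, rec.contour
            )
        except InvalidShapeError:
            pass  # isotropic contour: centering denominator undefined
        if pred.degenerate:
            row["status"] = "degenerate"
        rows.append(row)
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)

    pool = table[table["status"] == "analyzed"]
    if config.phase_filter:
        pool = pool[pool["phase"] == config.phase_filter]
    pool = pool[~pool["lineage"].isin(config.exclude_lineages)]
    report: dict = {
        "provenance": {
            "package": "spindleshape",
            "version": _pkg_version,
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_input": len(cells),
        },
        "config": config.to_dict(),
    }
    if len(pool) == 0:
        logger.warning("no analyzable records after filtering; tests skipped")
        summary = DeviationSummary(n=0, fractions={}, ks_D=None, ks_p=None)
        report["summary"] = {"flag": "all_degenerate_or_skipped"}
        report["tests"] = []
        return table, summary, report

    summary = summarize_deviations(
        pool["orienting_deg"].to_numpy(),
        lineages=pool["lineage"],
        thresholds=config.thresholds,
    )
    report["summary"] = summary.to_dict()

    test_results = []
    for sel in config.tests:
        name = sel.get("name", sel.get("test", "test"))
        metric = sel.get("metric", "orienting_deg")
        a = pool.loc[_select(pool, sel.get("a", {})), metric].dropna()
        b = pool.loc[_select(pool, sel.get("b", {})), metric].dropna()
        try:
            stat, p = group_compare(a, b, test=sel.get("test", "rank_sum"))
            test_results.append(
                {"name": name, "test": sel.get("test", "rank_sum"),
                 "n_a": int(a.size), "n_b": int(b.size),
                 "statistic": stat, "p": p}
            )
        except ValueError as exc:
            logger.warning("test %s skipped: %s", name, exc)
            test_results.append({"name": name, "skipped": str(exc)})
    report["tests"] = test_results
    return table, summary, report


def run_mesh_stage(
    items: list[tuple[str, LabeledMesh, np.ndarray]],
) -> tuple[pd.DataFrame, dict[str, tuple[Contour2D, SpindleAxis]]]:
    """3D shape metrics and apical-plane extraction per blastomere.

    ``items`` holds (cell_id, labeled mesh, 3D spindle poles (2, 3)).
    Returns a per-cell table (sphericity, apical ratio, separation score,
    contour aspect ratio) and the extracted 2D contours + projected poles
    keyed by cell id, ready for :func:`run_analysis`.  Cells whose mesh
    fails validation are skipped with a logged reason.
    """
    rows = []
    extracted: dict[str, tuple[Contour2D, SpindleAxis]] = {}
    for cell_id, lm, poles3d in items:
        row = {
            "cell_id": cell_id,
            "sphericity": np.nan,
            "apical_ratio": np.nan,
            "separation_score": np.nan,
            "contour_aspect": np.nan,
            "status": "ok",
        }
        try:
            row["sphericity"] = sphericity(lm)
            row["apical_ratio"] = apical_surface_ratio(lm)
            plane, contour, poles2d = extract_apical_plane(lm, poles3d)
            row["separation_score"] = plane.separation_score
            row["contour_aspect"] = principal_axes(contour).aspect_ratio
            extracted[cell_id] = (contour, poles2d)
        except (InvalidShapeError, ValueError) as exc:
            logger.warning("mesh stage: cell %s skipped: %s", cell_id, exc)
            row["status"] = f"skipped: {exc}"
        rows.append(row)
    return pd.DataFrame(rows), extracted


def write_outputs(
    out_dir: str | Path,
    table: pd.DataFrame,
    report: dict,
    prefix: str = "deviations",
) -> tuple[Path, Path]:
    """Write the per-cell table (CSV) and the run report (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / f"{prefix}.csv"
    report_path = out_dir / f"{prefix}_report.json"
    table.to_csv(table_path, index=False, float_format="%.6f")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return table_path, report_path
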