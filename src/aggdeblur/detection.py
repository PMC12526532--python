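"""Detection-metric reporting: F1, false-negative rate and relative
improvements between sharp / blurred / restored evaluation conditions.

This module consumes printed detection-metric tables (it never runs a
detector).  A reference table with per-class metrics under the three
conditions ships with the package and feeds the worked examples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

__all__ = [
    "DetectionRow", "ImprovementReport", "f1_score", "false_negative_rate",
    "relative_change", "improvement_report", "load_reference_detection_table",
    "REFERENCE_TABLE_PATH", "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("map50", "map5095", "precision", "recall", "f1", "fnr", "mconf")
CONDITIONS = ("sharp", "blur", "restore")

REFERENCE_TABLE_PATH = Path(__file__).parent / "data" / "detection_metrics.csv"

#: tolerance for printed-vs-recomputed F1/FNR agreement; 3-d.p. rounding of
#: precision/recall/F1 can move the harmonic mean by at most ~0.002, so 0.005
#: separates rounding noise from genuine inconsistencies
CONSISTENCY_TOL = 0.005


@dataclass
class DetectionRow:
    source: str
    class_name: str
    map50: float
    map5095: float
    precision: float
    recall: float
    f1: float
    fnr: float
    mconf: float

    def __post_init__(self):
        if self.source not in CONDITIONS:
            raise ValueError(f"source must be one of {CONDITIONS}")
        for col in METRIC_COLUMNS:
            v = getattr(self, col)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{col}={v} outside [0, 1]")


@dataclass
class ImprovementReport:
    """Per-class, per-metric relative changes (percent) between conditions."""

    changes: Dict[Tuple[str, str, str], float]  # (class, metric, transition) -> %
    flags: List[str] = field(default_factory=list)
    warnings_: List[str] = field(default_factory=list)

    def change(self, class_name: str, metric: str,
               transition: str = "blur->restore") -> float:
        return self.changes[(class_name, metric, transition)]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c, "metric": m, "transition": t, "percent": round(v, 1)}
                for (c, m, t), v in sorted(self.changes.items())]
        return pd.DataFrame(rows)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean ``2PR / (P + R)``; defined as 0 (with a warning) when
    both inputs are zero."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        warnings.warn("F1 undefined for precision = recall = 0; returning 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def false_negative_rate(recall: float) -> float:
    """Miss rate, ``1 - recall``."""
    if not 0.0 <= recall <= 1.0:
        raise ValueError("recall must lie in [0, 1]")
    return 1.0 - recall


def relative_change(before: float, after: float) -> float:
    """Signed percent change ``100 * (after - before) / before``."""
    if before == 0:
        raise ZeroDivisionError("relative change undefined for a zero baseline")
    return 100.0 * (after - before) / before


def improvement_report(rows: Sequence[DetectionRow]) -> ImprovementReport:
    """Relative blur->restore and blur->sharp changes per class and metric.

    Printed F1/FNR cells are checked against recomputation from precision
    and recall; discrepancies beyond the rounding tolerance are flagged,
    never silently corrected.
    """
    by_class: Dict[str, Dict[str, DetectionRow]] = {}
    for r in rows:
        by_class.setdefault(r.class_name, {})[r.source] = r

    changes: Dict[Tuple[str, str, str], float] = {}
    flags: List[str] = []
    warns: List[str] = []
    for cls, conds in by_class.items():
        if len(conds) < 2:
            warns.append(f"class {cls!r}: fewer than two conditions; skipped")
            continue
        for cond, r in conds.items():
            f1_re = f1_score(r.precision, r.recall)
            if abs(f1_re - r.f1) > CONSISTENCY_TOL:
                flags.append(
                    f"{cond}/{cls}: stored F1 {r.f1:.3f} disagrees with "
                    f"2PR/(P+R) = {f1_re:.3f}")
            if abs((1.0 - r.recall) - r.fnr) > CONSISTENCY_TOL:
                flags.append(
                    f"{cond}/{cls}: stored FNR {r.fnr:.3f} disagrees with "
                    f"1 - recall = {1.0 - r.recall:.3f}")
        if "blur" not in conds:
            warns.append(f"class {cls!r}: no blurred condition; partial report")
            continue
        base = conds["blur"]
        for target_name, transition in (("restore", "blur->restore"),
                                        ("sharp", "blur->sharp")):
            if target_name not in conds:
                warns.append(f"class {cls!r}: missing {target_name} condition")
                continue
            tgt = conds[target_name]
            for metric in METRIC_COLUMNS:
                before = getattr(base, metric)
                after = getattr(tgt, metric)
                if before == 0:
                    warns.append(
                        f"class {cls!r} {metric}: zero baseline, change undefined")
                    continue
                changes[(cls, metric, transition)] = relative_change(before, after)
    for w in warns:
        warnings.warn(w)
    return ImprovementReport(changes=changes, flags=flags, warnings_=warns)


def load_detection_table(path) -> List[DetectionRow]:
    """Read a CSV/JSON detection table with the standard column names."""
    path = Path(path)
    df = pd.read_json(path) if path.suffix == ".json" else pd.read_csv(path)
    required = {"source", "class_name", *METRIC_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    return [DetectionRow(**{k: row[k] for k in required}) for _, row in df.iterrows()]


def load_reference_detection_table() -> List[DetectionRow]:
    """The packaged sharp/blur/restore reference table (citrus and tree)."""
    return load_detection_table(REFERENCE_TABLE_PATH)
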