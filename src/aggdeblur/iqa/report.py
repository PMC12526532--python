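"""Composite IQA scoring: normalization of the seven metrics to [0, 1]
(1 = best), their arithmetic-mean composite score, blur-severity bands and
paired group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .metrics import METRIC_NAMES, compute_raw_metric

__all__ = [
    "SIMILARITY_METRICS", "DISTANCE_CAPS", "MetricResult", "IQAReport",
    "GroupComparison", "normalize_metric", "composite_score", "severity_band",
    "paired_comparison", "score_pair",
]

#: similarity-type metrics whose raw value already lives in [0, 1]
SIMILARITY_METRICS = ("VSI", "FSIM", "MS-SSIM")

#: distance-type metrics mapped to [0, 1] via 1 - clip(raw / cap).  The caps
#: are a reconstruction (the normalization behind the published score table
#: is unstated) and are deliberately configuration-exposed.
DISTANCE_CAPS: Dict[str, float] = {
    "LPIPS": 1.0, "DISTS": 1.0, "GMSD": 0.35, "NLPD": 1.0,
}

_BANDS = (  # left-closed bands; the top band includes 1.0
    (0.0, 0.6, "severe"),
    (0.6, 0.7, "moderate"),
    (0.7, 0.8, "mild"),
    (0.8, 1.0 + 1e-12, "sharp"),
)


@dataclass
class MetricResult:
    name: str
    raw: float
    normalized: float

    def __post_init__(self):
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}")
        if not 0.0 <= self.normalized <= 1.0:
            raise ValueError("normalized score must lie in [0, 1]")


@dataclass
class IQAReport:
    per_metric: List[MetricResult]
    composite: float
    severity: str

    def as_dict(self) -> dict:
        return {
            "metrics": {m.name: {"raw": m.raw, "normalized": m.normalized}
                        for m in self.per_metric},
            "composite": self.composite,
            "severity": self.severity,
        }


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    ci95_a: float            # half-widths (t-distribution)
    ci95_b: float
    t_stat: float
    p_value: float
    n: int
    degenerate: bool = False


def normalize_metric(name: str, raw: float, caps: Optional[Dict[str, float]] = None
                     ) -> float:
    """Map a raw metric value to [0, 1] with 1 meaning best quality."""
    if not np.isfinite(raw):
        raise ValueError(f"non-finite raw value for {name}")
    key = name.upper()
    if key in SIMILARITY_METRICS:
        return float(np.clip(raw, 0.0, 1.0))
    all_caps = dict(DISTANCE_CAPS)
    if caps:
        all_caps.update({k.upper(): v for k, v in caps.items()})
    if key in all_caps:
        return float(1.0 - np.clip(raw / all_caps[key], 0.0, 1.0))
    raise ValueError(f"unknown metric {name!r}")


def composite_score(normalized: Sequence[float]) -> float:
    """Arithmetic mean of the seven normalized metric scores."""
    vals = np.asarray(list(normalized), dtype=float)
    if vals.shape != (7,):
        raise ValueError(f"composite score needs exactly 7 values, got {vals.shape}")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("normalized scores must lie in [0, 1]")
    return float(vals.mean())


def severity_band(score: float) -> str:
    """Blur-severity band for a composite score: severe below 0.6, moderate
    in [0.6, 0.7), mild in [0.7, 0.8), sharp from 0.8 up."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"composite score must lie in [0, 1], got {score}")
    for lo, hi, label in _BANDS:
        if lo <= score < hi:
            return label
    return "sharp"  # score == 1.0 + fp edge


def paired_comparison(scores_a: Sequence[float], scores_b: Sequence[float]
                      ) -> GroupComparison:
    """Per-group means with 95% t-CIs and a two-sided paired t-test.

    Zero-variance differences are reported as degenerate (p = nan) rather
    than as spuriously perfect significance.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    tcrit = stats.t.ppf(0.975, n - 1)

    def half_width(x):
        return float(tcrit * x.std(ddof=1) / np.sqrt(n))

    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return GroupComparison(float(a.mean()), float(b.mean()),
                               half_width(a), half_width(b),
                               t_stat=0.0, p_value=float("nan"), n=n,
                               degenerate=True)
    t_stat, p = stats.ttest_rel(a, b)
    return GroupComparison(float(a.mean()), float(b.mean()),
                           half_width(a), half_width(b),
                           float(t_stat), float(p), n)


def score_pair(ref: np.ndarray, test: np.ndarray,
               metrics: Sequence[str] = METRIC_NAMES,
               caps: Optional[Dict[str, float]] = None) -> IQAReport:
    """Score ``test`` against the reference image on the listed metrics.

    The composite is only defined for the full seven-metric set; learned
    metrics raise :class:`~.metrics.MetricUnavailableError` unless a
    backend is registered (tests mock them).
    """
    results = []
    for name in metrics:
        raw = compute_raw_metric(name, ref, test)
        results.append(MetricResult(name=name.upper(), raw=float(raw),
                                    normalized=normalize_metric(name, raw, caps)))
    comp = composite_score([m.normalized for m in results])
    return IQAReport(per_metric=results, composite=comp,
                     severity=severity_band(comp))
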