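"""Scoring per-nerve decisions, cutoff sweeps, and diagnostic-time analysis.

Nerve-level scoring matches detected nerve structures to ground-truth nerves
greedily by pixel overlap, then fills a confusion matrix: a matched pair
contributes TP/TN/FP/FN from its (predicted, true) PNI classes, an unmatched
truth-PNI nerve is a miss (FN), an unmatched PNI-positive detection is a
false alarm (FP), and an unmatched truth-normal nerve counts as a correct
rejection (it was never flagged).

Display conventions differ between published confusion-matrix reports:
percentages are shown either truncated to two decimals or rounded half-up;
``metrics`` supports both ("truncate" is the default).  Diagnostic-time
changes are rounded half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .postprocess import DecisionConfig, NerveStructure, ProbabilityMap, run_decision_flow

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SweepResult",
    "TimingRecord",
    "TimingAnalysis",
    "TruthNerve",
    "truth_from_scene",
    "match_structures",
    "match_annotations",
    "metrics",
    "mean_accuracy",
    "cutoff_sweep",
    "time_reduction",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def _display(pct: float | None, convention: str) -> float | None:
    if pct is None:
        return None
    if convention == "truncate":
        return math.floor(pct * 100.0 + 1e-9) / 100.0
    if convention == "half_up":
        return math.floor(pct * 100.0 + 0.5) / 100.0
    raise ValidationError(f"unknown display convention {convention!r}")


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity / specificity / accuracy as displayed percentages.

    A metric whose denominator is zero is reported as None (undefined), never
    as 0.  ``convention`` records how the raw percentages were brought to two
    decimals.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    cm: ConfusionMatrix
    convention: str = "truncate"


def metrics(cm: ConfusionMatrix, convention: str = "truncate") -> MetricsReport:
    """sensitivity = 100 tp/(tp+fn); specificity = 100 tn/(tn+fp);
    accuracy = 100 (tp+tn)/total; displayed to 2 decimals per convention."""
    if cm.total < 1:
        raise ValidationError("confusion matrix must hold at least one count")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return MetricsReport(
        sensitivity=_display(sens, convention),
        specificity=_display(spec, convention),
        accuracy=_display(acc, convention),
        cm=cm,
        convention=convention,
    )


def mean_accuracy(reports: Sequence[MetricsReport], convention: str = "truncate") -> float:
    """Arithmetic mean of the displayed accuracies, displayed the same way."""
    if not reports:
        raise ValidationError("need at least one report")
    if any(r.accuracy is None for r in reports):
        raise ValidationError("cannot average undefined accuracies")
    value = sum(r.accuracy for r in reports) / len(reports)
    return _display(value, convention)


# ---------------------------------------------------------------------------
# nerve-structure matching


@dataclass(frozen=True)
class TruthNerve:
    """Ground truth for one nerve: its pixels and whether PNI was planted."""

    id: int
    pixels: np.ndarray  # (k, 2) int coordinates
    is_pni: bool


def truth_from_scene(scene) -> list[TruthNerve]:
    """Build the truth list from a synthetic scene's label image + records."""
    out = []
    for rec in scene.nerve_records:
        coords = np.argwhere(scene.nerve_labels == rec.id)
        out.append(TruthNerve(id=rec.id, pixels=coords, is_pni=rec.truth_class == "PNI"))
    return out


def _pixel_set(coords: np.ndarray, width: int) -> np.ndarray:
    return coords[:, 0].astype(np.int64) * width + coords[:, 1]


def match_structures(
    predicted: Sequence[NerveStructure],
    truth: Sequence[TruthNerve],
    min_overlap_frac: float = 0.1,
) -> ConfusionMatrix:
    """Greedy overlap matching followed by confusion-matrix filling.

    Candidate (prediction, truth) pairs whose intersection covers at least
    ``min_overlap_frac`` of the truth region are matched greedily in order of
    descending overlap; each side is used at most once.
    """
    if not (0.0 < min_overlap_frac <= 1.0):
        raise ValidationError("min_overlap_frac must lie in (0, 1]")
    width = predicted[0].region.mask_shape[1] if predicted else (
        max((t.pixels[:, 1].max() + 1 for t in truth if t.pixels.size), default=1)
    )
    pred_sets = [np.sort(_pixel_set(p.region.pixels, width)) for p in predicted]
    truth_sets = [np.sort(_pixel_set(t.pixels, width)) for t in truth]
    candidates = []
    for pi, pset in enumerate(pred_sets):
        for ti, tset in enumerate(truth_sets):
            overlap = np.intersect1d(pset, tset, assume_unique=True).size
            if tset.size and overlap / tset.size >= min_overlap_frac:
                candidates.append((overlap, pi, ti))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    matched_p, matched_t = set(), set()
    tp = fp = fn = tn = 0
    for overlap, pi, ti in candidates:
        if pi in matched_p or ti in matched_t:
            continue
        matched_p.add(pi)
        matched_t.add(ti)
        pred_pni = predicted[pi].predicted_class == "PNI"
        true_pni = truth[ti].is_pni
        if pred_pni and true_pni:
            tp += 1
        elif pred_pni and not true_pni:
            fp += 1
        elif not pred_pni and true_pni:
            fn += 1
        else:
            tn += 1
    for ti, t in enumerate(truth):
        if ti not in matched_t:
            if t.is_pni:
                fn += 1  # missed PNI nerve
            else:
                tn += 1  # undetected normal nerve was never flagged
    for pi, p in enumerate(predicted):
        if pi not in matched_p and p.predicted_class == "PNI":
            fp += 1  # PNI called on something that is not a truth nerve
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def match_annotations(
    predicted, truth, min_overlap_frac: float = 0.1
) -> ConfusionMatrix:
    """Rectangle-level variant of :func:`match_structures` for serialized
    annotation records: overlap is bbox intersection area over truth bbox
    area, and the class is ``label == "PNI"``."""
    if not (0.0 < min_overlap_frac <= 1.0):
        raise ValidationError("min_overlap_frac must lie in (0, 1]")

    def _area(b):
        return max(b[2] - b[0], 0) * max(b[3] - b[1], 0)

    def _inter(a, b):
        h = max(min(a[2], b[2]) - max(a[0], b[0]), 0)
        w = max(min(a[3], b[3]) - max(a[1], b[1]), 0)
        return h * w

    candidates = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth):
            ov = _inter(p.bbox, t.bbox)
            if _area(t.bbox) and ov / _area(t.bbox) >= min_overlap_frac:
                candidates.append((ov, pi, ti))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    matched_p, matched_t = set(), set()
    tp = fp = fn = tn = 0
    for ov, pi, ti in candidates:
        if pi in matched_p or ti in matched_t:
            continue
        matched_p.add(pi)
        matched_t.add(ti)
        pred_pni = predicted[pi].label == "PNI"
        true_pni = truth[ti].label == "PNI"
        tp += pred_pni and true_pni
        fp += pred_pni and not true_pni
        fn += (not pred_pni) and true_pni
        tn += (not pred_pni) and not true_pni
    for ti, t in enumerate(truth):
        if ti not in matched_t:
            if t.label == "PNI":
                fn += 1
            else:
                tn += 1
    for pi, p in enumerate(predicted):
        if pi not in matched_p and p.label == "PNI":
            fp += 1
    return ConfusionMatrix(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))


# ---------------------------------------------------------------------------
# cutoff sweep


@dataclass(frozen=True)
class SweepResult:
    cutoffs_px2: tuple[float, ...]
    reports: tuple[MetricsReport, ...]

    def __post_init__(self):
        cuts = self.cutoffs_px2
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValidationError("cutoffs must be strictly increasing")


def cutoff_sweep(
    inputs: Sequence[tuple[ProbabilityMap, ProbabilityMap, Sequence[TruthNerve]]],
    cfg: DecisionConfig,
    cutoffs: Sequence[float],
    min_overlap_frac: float = 0.1,
    convention: str = "truncate",
) -> SweepResult:
    """Re-run the decision flow at each cutoff (all else fixed), aggregate the
    per-scene confusion matrices, and report metrics per cutoff."""
    if len(inputs) < 1:
        raise ValidationError("need at least one (nerve map, pni map, truth) input")
    if len(cutoffs) < 2:
        raise ValidationError("need at least two cutoffs")
    reports = []
    for cutoff in cutoffs:
        cm = ConfusionMatrix()
        cut_cfg = dc_replace(cfg, size_cutoff_px2=cutoff)
        for nerve_map, pni_map, truth in inputs:
            result = run_decision_flow(nerve_map, pni_map, cut_cfg)
            cm = cm + match_structures(result.nerves, truth, min_overlap_frac)
        reports.append(metrics(cm, convention))
    return SweepResult(cutoffs_px2=tuple(float(c) for c in cutoffs), reports=tuple(reports))


# ---------------------------------------------------------------------------
# diagnostic-time analysis


@dataclass(frozen=True)
class TimingRecord:
    slide_id: str
    t_without_sec: float
    t_with_sec: float

    def __post_init__(self):
        if self.t_without_sec <= 0 or self.t_with_sec <= 0:
            raise ValidationError("diagnostic times must be positive")


def _round_half_up_1dp(x: float) -> float:
    return math.floor(x * 10.0 + 0.5) / 10.0


@dataclass(frozen=True)
class TimingAnalysis:
    per_slide_pct: dict
    total_pct: float
    total_without_sec: float
    total_with_sec: float


def time_reduction(records: Iterable[TimingRecord]) -> TimingAnalysis:
    """Percent change in diagnostic time per slide and in total.

    change = 100 (t_without - t_with) / t_without, rounded half-up to one
    decimal (negative values mean the reading got slower).  The total uses
    summed times, not the mean of per-slide percentages.
    """
    records = list(records)
    if not records:
        raise ValidationError("need at least one timing record")
    per_slide = {
        r.slide_id: _round_half_up_1dp(
            100.0 * (r.t_without_sec - r.t_with_sec) / r.t_without_sec
        )
        for r in records
    }
    t_without = sum(r.t_without_sec for r in records)
    t_with = sum(r.t_with_sec for r in records)
    total = _round_half_up_1dp(100.0 * (t_without - t_with) / t_without)
    return TimingAnalysis(
        per_slide_pct=per_slide,
        total_pct=total,
        total_without_sec=t_without,
        total_with_sec=t_with,
    )
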