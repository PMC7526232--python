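"""Agreement evaluation: confusion tables, PPA/NPA, ROC cutoff optimization,
Cohen's kappa and cohort summaries.

Because the reference standard here is expert annotation rather than a gold
standard, accuracy is reported as positive and negative percent agreement
(PPA, NPA) — the sensitivity/specificity analogs.  Presence calls use a
strict ">" cutoff on the continuous per-recording score; the ROC enumerates
every achievable operating point (one per distinct score value, plus a
call-everything-positive point below the minimum score), and the "optimal"
cutoff is reported as the maximal *interval* of cutoffs yielding the winning
confusion table, since any cutoff between two adjacent distinct scores is
observationally identical.

Two readings of "true positive rate" coexist in this literature; the default
here is tp/(tp+fn) (identical to PPA), with the precision-style tp/(tp+fp)
available via ``tpr_definition="precision"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import DegenerateReferenceError, InvalidParameterError

__all__ = [
    "ConfusionTable",
    "OperatingPoint",
    "ThresholdInterval",
    "CohortSummary",
    "confusion",
    "ppa_npa",
    "roc",
    "optimal_cutoff_interval",
    "cohen_kappa",
    "cohort_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class OperatingPoint:
    """A cutoff with its confusion table and agreement metrics.

    ``cutoff`` may be slightly below 0 for the sentinel point that calls
    every recording positive (reachable only with a cutoff below the minimum
    score under strict ">" labelling).
    """

    cutoff: float
    table: ConfusionTable
    ppa: float | None
    npa: float | None
    tpr: float | None


@dataclass(frozen=True)
class ThresholdInterval:
    """A maximal contiguous cutoff interval with identical behaviour."""

    cutoff_lo: float
    cutoff_hi: float
    ppa: float | None
    npa: float | None
    table: ConfusionTable


def confusion(pred: Mapping[str, bool] | pd.Series,
              ref: Mapping[str, bool] | pd.Series) -> ConfusionTable:
    """Per-recording confusion table; positive = reference label present.

    ``pred`` and ``ref`` are keyed by recording id and must cover the same
    set of recordings (excluded recordings must be removed beforehand).
    """
    pred = pd.Series(pred, dtype=bool)
    ref = pd.Series(ref, dtype=bool)
    if set(pred.index) != set(ref.index):
        raise InvalidParameterError("prediction and reference recording sets differ")
    ref = ref.reindex(pred.index)
    tp = int(((pred) & (ref)).sum())
    fp = int(((pred) & (~ref)).sum())
    tn = int(((~pred) & (~ref)).sum())
    fn = int(((~pred) & (ref)).sum())
    return ConfusionTable(tp, fp, tn, fn)


def ppa_npa(ct: ConfusionTable, tpr_definition: str = "agreement",
            ) -> tuple[float | None, float | None, float | None]:
    """PPA = tp/(tp+fn), NPA = tn/(tn+fp).

    ``tpr_definition``: ``"agreement"`` reports TPR as tp/(tp+fn) (same as
    PPA); ``"precision"`` reports tp/(tp+fp).  A metric with a zero
    denominator is returned as ``None`` (undefined), never 0.
    """
    ppa = ct.tp / (ct.tp + ct.fn) if ct.tp + ct.fn else None
    npa = ct.tn / (ct.tn + ct.fp) if ct.tn + ct.fp else None
    if tpr_definition == "agreement":
        tpr = ppa
    elif tpr_definition == "precision":
        tpr = ct.tp / (ct.tp + ct.fp) if ct.tp + ct.fp else None
    else:
        raise InvalidParameterError(f"unknown tpr_definition {tpr_definition!r}")
    return ppa, npa, tpr


def roc(scores: Mapping[str, float] | pd.Series,
        ref: Mapping[str, bool] | pd.Series,
        tpr_definition: str = "agreement") -> list[OperatingPoint]:
    """Enumerate every achievable operating point over score cutoffs.

    Cutoffs are the sorted distinct score values (labelling is strict ">"),
    plus one sentinel cutoff below the minimum score at which everything is
    called positive.  Points are returned in increasing cutoff order;
    ``(1 - npa, ppa)`` pairs trace the ROC curve.
    """
    scores = pd.Series(scores, dtype=float)
    ref = pd.Series(ref, dtype=bool)
    if set(scores.index) != set(ref.index):
        raise InvalidParameterError("score and reference recording sets differ")
    ref = ref.reindex(scores.index)
    n_pos = int(ref.sum())
    if n_pos == 0 or n_pos == len(ref):
        raise DegenerateReferenceError(
            "reference labels must include at least one positive and one negative"
        )
    distinct = np.unique(scores.to_numpy())
    gaps = np.diff(distinct)
    delta = float(gaps.min()) / 2 if gaps.size else max(distinct[0] / 2, 0.01)
    cutoffs = np.concatenate([[distinct[0] - delta], distinct])
    points = []
    for c in cutoffs:
        pred = scores > c
        ct = confusion(pred, ref)
        ppa, npa, tpr = ppa_npa(ct, tpr_definition)
        points.append(OperatingPoint(float(c), ct, ppa, npa, tpr))
    return points


def optimal_cutoff_interval(points: Sequence[OperatingPoint],
                            criterion: str = "ppa_plus_npa",
                            ) -> ThresholdInterval:
    """Select the best operating point and its maximal cutoff interval.

    The default criterion maximizes PPA + NPA (Youden-style balance); ties
    are broken toward higher NPA, then lower cutoff.  The returned interval
    [cutoff_lo, cutoff_hi) spans every cutoff producing the winning point's
    confusion table — cutoff_hi is the next distinct cutoff (or 1.0 for the
    last point); a single candidate yields a degenerate lo == hi interval.
    """
    if not points:
        raise InvalidParameterError("no operating points supplied")
    if criterion != "ppa_plus_npa":
        raise InvalidParameterError(f"unknown criterion {criterion!r}")
    pts = sorted(points, key=lambda p: p.cutoff)

    def score(p: OperatingPoint) -> tuple:
        ppa = p.ppa if p.ppa is not None else -1.0
        npa = p.npa if p.npa is not None else -1.0
        return (ppa + npa, npa, -p.cutoff)

    best_idx = max(range(len(pts)), key=lambda i: score(pts[i]))
    best = pts[best_idx]
    if len(pts) == 1:
        return ThresholdInterval(best.cutoff, best.cutoff, best.ppa, best.npa,
                                 best.table)
    hi = pts[best_idx + 1].cutoff if best_idx + 1 < len(pts) else 1.0
    return ThresholdInterval(best.cutoff, hi, best.ppa, best.npa, best.table)


def cohen_kappa(tags_a: Sequence, tags_b: Sequence) -> float:
    """Chance-corrected inter-rater agreement, kappa = (p_o - p_e)/(1 - p_e).

    When both raters produce the same constant vector, expected agreement
    p_e equals 1 and kappa is defined as 1.0 by convention (logged).
    """
    a = np.asarray(tags_a)
    b = np.asarray(tags_b)
    if a.shape != b.shape or a.size == 0:
        raise InvalidParameterError("tag vectors must be equal-length and non-empty")
    if np.unique(a).size == 1 and np.array_equal(a, b):
        log.info("both raters constant and identical; kappa = 1.0 by convention")
        return 1.0
    return float(cohen_kappa_score(a, b))


@dataclass(frozen=True)
class CohortSummary:
    n_participants: int
    n_recordings: int
    age_median: float
    age_iqr: float
    weight_median: float
    weight_kg_iqr: float
    percent_female: int
    group_counts: dict[str, int]
    group_percents: dict[str, int]


def cohort_summary(manifest: pd.DataFrame,
                   participants: pd.DataFrame) -> CohortSummary:
    """Participant-characteristics summary in study-table style.

    Medians are standard (midpoint of central order statistics), IQR is
    Q3 - Q1 with linear interpolation, and all percentages are reported as
    integers (100 × count / n participants, rounded half away from zero).
    """
    if participants.empty:
        raise InvalidParameterError("empty cohort")
    n = len(participants)
    counts = participants["group"].value_counts().to_dict()

    def pct(c: int) -> int:
        return int(math.floor(100.0 * c / n + 0.5))

    age = participants["age_years"].to_numpy(dtype=float)
    wt = participants["weight_kg"].to_numpy(dtype=float)
    return CohortSummary(
        n_participants=n,
        n_recordings=int((~manifest["excluded"]).sum()),
        age_median=float(np.median(age)),
        age_iqr=float(np.percentile(age, 75) - np.percentile(age, 25)),
        weight_median=float(np.median(wt)),
        weight_kg_iqr=float(np.percentile(wt, 75) - np.percentile(wt, 25)),
        percent_female=pct(int((participants["sex"] == "F").sum())),
        group_counts={g: int(counts.get(g, 0)) for g in counts},
        group_percents={g: pct(int(c)) for g, c in counts.items()},
    )
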