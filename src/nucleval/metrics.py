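"""Object matching by IoU and the challenge's segmentation metrics.

Evaluation is object-level. Predicted objects are matched one-to-one to
target objects whenever their intersection-over-union,

    IoU(A, B) = |A ∩ B| / |A ∪ B|,

exceeds a threshold t (strict ``>`` by default). Matched pairs are true
positives TP(t); unmatched predictions are false positives FP(t) and
unmatched targets false negatives FN(t). From these we compute

    P(t)  = TP / (TP + FP)
    R(t)  = TP / (TP + FN)
    F1(t) = 2 TP / (2 TP + FP + FN)

and the official competition score for one image,

    S = (1/|T|) Σ_{t ∈ T} TP(t) / (TP(t) + FP(t) + FN(t)),

with T = {0.10, 0.15, ..., 0.95}. Dataset-level summaries follow the
benchmark's reporting: mean S and threshold-averaged F1 across images,
plus pooled object-count percentages (Recall / Missed / Extra) at
IoU 0.7.

Matching is greedy in descending IoU with a deterministic tie-break;
for t ≥ 0.5 each predicted object can exceed IoU t with at most one
target (the pixel counts forbid two such overlaps), so the greedy
result is the unique maximal matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .mask_io import LabelMask

__all__ = [
    "ThresholdSet",
    "default_thresholds",
    "IouMatrix",
    "MatchResult",
    "ConfusionAtThreshold",
    "ImageReport",
    "DatasetReport",
    "iou",
    "iou_matrix",
    "match_at_threshold",
    "precision_recall_f1",
    "image_score",
    "evaluate_dataset",
    "f1_curve",
]

REFERENCE_IOU = 0.7  # threshold used for the Recall/Missed/Extra breakdown


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing IoU thresholds in (0, 1)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if len(v) == 0:
            raise ContractError("threshold set must be nonempty")
        if any(not (0.0 < t < 1.0) for t in v):
            raise ContractError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ContractError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @classmethod
    def from_spec(cls, spec: str) -> "ThresholdSet":
        """Parse a ``lo:hi:step`` string in integer hundredths (e.g. ``0.10:0.95:0.05``)."""
        try:
            lo, hi, step = (round(float(x) * 100) for x in spec.split(":"))
        except ValueError as exc:
            raise ContractError(f"bad threshold spec {spec!r}; expected lo:hi:step") from exc
        if step <= 0 or lo > hi:
            raise ContractError(f"bad threshold spec {spec!r}")
        return cls(tuple(h / 100.0 for h in range(lo, hi + 1, step)))


def default_thresholds() -> ThresholdSet:
    """T = {0.10, 0.15, ..., 0.95}, built from integer hundredths (18 values)."""
    return ThresholdSet(tuple(h / 100.0 for h in range(10, 100, 5)))


# ---------------------------------------------------------------------------
# IoU


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU between two binary regions on one grid; 0 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ContractError(f"region shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


@dataclass
class IouMatrix:
    """All-pairs IoU between the objects of two label masks."""

    values: np.ndarray  # (n_targets, n_preds)

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_preds(self) -> int:
        return self.values.shape[1]


def iou_matrix(targets: LabelMask, preds: LabelMask) -> IouMatrix:
    """IoU between every (target, prediction) object pair.

    Only co-occurring label pairs are enumerated (sparse discovery); the
    result is identical to the dense all-pairs computation because
    non-co-occurring pairs have IoU exactly 0.
    """
    if targets.shape != preds.shape:
        raise ContractError(f"mask shapes differ: {targets.shape} vs {preds.shape}")
    nt, np_ = targets.n_objects, preds.n_objects
    values = np.zeros((nt, np_), dtype=np.float64)
    if nt == 0 or np_ == 0:
        return IouMatrix(values)
    t = targets.labels.ravel()
    p = preds.labels.ravel()
    both = (t > 0) & (p > 0)
    if both.any():
        key = t[both].astype(np.int64) * (np_ + 1) + p[both]
        pair_keys, inter = np.unique(key, return_counts=True)
        ti = (pair_keys // (np_ + 1)) - 1
        pi = (pair_keys % (np_ + 1)) - 1
        t_area = targets.areas()
        p_area = preds.areas()
        union = t_area[ti] + p_area[pi] - inter
        values[ti, pi] = inter / union
    return IouMatrix(values)


# ---------------------------------------------------------------------------
# matching


@dataclass
class MatchResult:
    """One-to-one object matching at a single IoU threshold."""

    threshold: float
    pairs: list[tuple[int, int, float]]  # (target_label, pred_label, iou)
    unmatched_targets: list[int]
    unmatched_preds: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_targets)

    @property
    def fp(self) -> int:
        return len(self.unmatched_preds)


def match_at_threshold(
    m: IouMatrix, t: float, inclusive: bool = False
) -> MatchResult:
    """Greedily match targets to predictions among pairs with IoU > t.

    Candidate pairs are taken in descending IoU, ties broken by lower
    target label then lower prediction label. The greedy pass is then
    completed by deterministic augmenting paths so the matching always
    has maximum cardinality (for t >= 0.5 the greedy result is already
    the unique maximal matching and augmentation is a no-op; below 0.5
    a purely greedy pass can strand a matchable pair). The result is
    unique. With ``inclusive=True`` pairs at exactly IoU = t also
    qualify.
    """
    if not (0.0 <= t < 1.0):
        raise ContractError(f"threshold must be in [0, 1); got {t}")
    values = m.values
    if inclusive and t > 0.0:
        cand = values >= t
    else:
        cand = values > t
    ti, pi = np.nonzero(cand)
    ious = values[ti, pi]
    order = np.lexsort((pi, ti, -ious))
    match_of_t = np.full(m.n_targets, -1)  # target index -> pred index
    match_of_p = np.full(m.n_preds, -1)
    for k in order:
        i, j = int(ti[k]), int(pi[k])
        if match_of_t[i] >= 0 or match_of_p[j] >= 0:
            continue
        match_of_t[i] = j
        match_of_p[j] = i
    # Kuhn augmentation from unmatched targets, ascending label order
    adj: dict[int, list[int]] = {}
    for i, j in zip(ti.tolist(), pi.tolist()):
        adj.setdefault(i, []).append(j)

    def _augment(i: int, visited: set[int]) -> bool:
        for j in adj.get(i, ()):
            if j in visited:
                continue
            visited.add(j)
            if match_of_p[j] < 0 or _augment(int(match_of_p[j]), visited):
                match_of_t[i] = j
                match_of_p[j] = i
                return True
        return False

    for i in range(m.n_targets):
        if match_of_t[i] < 0:
            _augment(i, set())
    pairs = [
        (i + 1, int(j) + 1, float(values[i, j]))
        for i, j in enumerate(match_of_t)
        if j >= 0
    ]
    return MatchResult(
        threshold=t,
        pairs=pairs,
        unmatched_targets=[i + 1 for i in range(m.n_targets) if match_of_t[i] < 0],
        unmatched_preds=[j + 1 for j in range(m.n_preds) if match_of_p[j] < 0],
    )


@dataclass
class ConfusionAtThreshold:
    """Object-level confusion counts at one IoU threshold.

    True negatives are undefined at object level and carried as 0.
    """

    t: float
    tp: int
    fp: int
    fn: int
    tn: int = 0

    @classmethod
    def from_match(cls, match: MatchResult) -> "ConfusionAtThreshold":
        return cls(t=match.threshold, tp=match.tp, fp=match.fp, fn=match.fn)


def precision_recall_f1(c: ConfusionAtThreshold) -> tuple[float, float, float]:
    """P, R and F1 from a confusion; all-empty images count as perfect.

    A quotient with a zero denominator is 0, except when
    TP = FP = FN = 0 (nothing to find, nothing predicted) where all
    three metrics are defined as 1.
    """
    tp, fp, fn = c.tp, c.fp, c.fn
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return p, r, f1


def _score_term(c: ConfusionAtThreshold) -> float:
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else 1.0


# ---------------------------------------------------------------------------
# per-image and dataset reports


@dataclass
class ImageReport:
    """Per-threshold metrics and the competition score S for one image."""

    image_id: str
    thresholds: tuple[float, ...]
    confusions: list[ConfusionAtThreshold]
    group: str = "unknown"

    @property
    def precision(self) -> np.ndarray:
        return np.array([precision_recall_f1(c)[0] for c in self.confusions])

    @property
    def recall(self) -> np.ndarray:
        return np.array([precision_recall_f1(c)[1] for c in self.confusions])

    @property
    def f1(self) -> np.ndarray:
        return np.array([precision_recall_f1(c)[2] for c in self.confusions])

    @property
    def score_terms(self) -> np.ndarray:
        return np.array([_score_term(c) for c in self.confusions])

    @property
    def score(self) -> float:
        return float(self.score_terms.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": list(self.thresholds),
                "tp": [c.tp for c in self.confusions],
                "fp": [c.fp for c in self.confusions],
                "fn": [c.fn for c in self.confusions],
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "score_term": self.score_terms,
            }
        )


def image_score(
    targets: LabelMask,
    preds: LabelMask,
    thresholds: ThresholdSet | None = None,
    inclusive: bool = False,
    group: str = "unknown",
) -> ImageReport:
    """Evaluate one image: confusions, P/R/F1 per threshold and score S."""
    thresholds = thresholds or default_thresholds()
    m = iou_matrix(targets, preds)
    confusions = [
        ConfusionAtThreshold.from_match(match_at_threshold(m, t, inclusive))
        for t in thresholds
    ]
    return ImageReport(
        image_id=targets.image_id or preds.image_id,
        thresholds=tuple(thresholds),
        confusions=confusions,
        group=group,
    )


@dataclass
class DatasetReport:
    """Dataset-level summary with a per-group breakdown.

    ``mean_score`` and ``average_f1`` average per-image values first
    (the challenge scored each image independently); Recall, Missed and
    Extra at IoU 0.7 pool object counts over all images and are
    reported as percentages, so Recall + Missed = 100 by construction.
    Extra is normalized by predicted-object count.
    """

    image_reports: list[ImageReport]
    mean_score: float
    average_f1: float
    recall_at_07: float
    missed_at_07: float
    extra_at_07: float
    pooled_confusion_07: ConfusionAtThreshold
    per_group: dict[str, "DatasetReport"] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        """Summary dict mirroring the benchmark's reported column names."""
        return {
            "n_images": len(self.image_reports),
            "score": self.mean_score,
            "average_f1": self.average_f1,
            "recall_at_0.7": self.recall_at_07,
            "missed_at_0.7": self.missed_at_07,
            "extra_at_0.7": self.extra_at_07,
        }

    def per_image_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.image_reports:
            rows.append(
                {
                    "image_id": rep.image_id,
                    "group": rep.group,
                    "score": rep.score,
                    "mean_f1": float(rep.f1.mean()),
                }
            )
        return pd.DataFrame(rows)


def _evaluate_flat(
    triples: list[tuple[LabelMask, LabelMask, str]],
    thresholds: ThresholdSet,
    inclusive: bool,
    aggregate: str,
) -> DatasetReport:
    reports = []
    pooled = np.zeros(3, dtype=np.int64)  # tp, fp, fn at the reference threshold
    for tgt, prd, grp in triples:
        rep = image_score(tgt, prd, thresholds, inclusive, group=grp)
        reports.append(rep)
        m = iou_matrix(tgt, prd)
        c = ConfusionAtThreshold.from_match(
            match_at_threshold(m, REFERENCE_IOU, inclusive)
        )
        pooled += (c.tp, c.fp, c.fn)
    tp, fp, fn = (int(x) for x in pooled)
    recall = 100.0 * tp / (tp + fn) if tp + fn else 100.0
    missed = 100.0 * fn / (tp + fn) if tp + fn else 0.0
    extra = 100.0 * fp / (tp + fp) if tp + fp else 0.0
    if aggregate == "mean":
        mean_score = float(np.mean([r.score for r in reports]))
        f1_by_t = np.mean([r.f1 for r in reports], axis=0)
        average_f1 = float(f1_by_t.mean())
    elif aggregate == "pooled":
        tps = np.sum([[c.tp for c in r.confusions] for r in reports], axis=0)
        fps = np.sum([[c.fp for c in r.confusions] for r in reports], axis=0)
        fns = np.sum([[c.fn for c in r.confusions] for r in reports], axis=0)
        terms, f1s = [], []
        for tpk, fpk, fnk in zip(tps, fps, fns):
            ck = ConfusionAtThreshold(t=0.0, tp=int(tpk), fp=int(fpk), fn=int(fnk))
            terms.append(_score_term(ck))
            f1s.append(precision_recall_f1(ck)[2])
        mean_score = float(np.mean(terms))
        average_f1 = float(np.mean(f1s))
    else:
        raise ContractError(f"unknown aggregate mode {aggregate!r}")
    return DatasetReport(
        image_reports=reports,
        mean_score=mean_score,
        average_f1=average_f1,
        recall_at_07=recall,
        missed_at_07=missed,
        extra_at_07=extra,
        pooled_confusion_07=ConfusionAtThreshold(REFERENCE_IOU, tp, fp, fn),
    )


def evaluate_dataset(
    pairs: Sequence[tuple[LabelMask, LabelMask] | tuple[LabelMask, LabelMask, str]],
    thresholds: ThresholdSet | None = None,
    inclusive: bool = False,
    aggregate: str = "mean",
) -> DatasetReport:
    """Evaluate target/prediction mask pairs and summarize per group.

    Each pair is ``(target, prediction)`` or ``(target, prediction,
    group)``. ``aggregate`` selects per-image-first averaging (``mean``,
    the default and the challenge's convention for S) or pooled-count
    aggregation (``pooled``) for S and average F1.
    """
    if len(pairs) == 0:
        raise ContractError("evaluate_dataset requires at least one mask pair")
    thresholds = thresholds or default_thresholds()
    triples = [
        (p[0], p[1], p[2] if len(p) > 2 else "unknown") for p in pairs  # type: ignore[misc]
    ]
    report = _evaluate_flat(triples, thresholds, inclusive, aggregate)
    groups = sorted({g for _, _, g in triples})
    if len(groups) > 1:
        for g in groups:
            sub = [trip for trip in triples if trip[2] == g]
            report.per_group[g] = _evaluate_flat(sub, thresholds, inclusive, aggregate)
    return report


def f1_curve(
    pairs: Sequence[tuple[LabelMask, LabelMask]],
    thresholds: ThresholdSet | None = None,
    inclusive: bool = False,
) -> np.ndarray:
    """Mean-over-images F1 at each threshold; non-increasing in t."""
    if len(pairs) == 0:
        raise ContractError("f1_curve requires at least one mask pair")
    thresholds = thresholds or default_thresholds()
    curves = [
        image_score(t, p, thresholds, inclusive).f1 for t, p, *_ in pairs
    ]
    return np.mean(curves, axis=0)
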