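"""Object-level agreement between two segmentations of the same images.

Used to compare annotators with each other or a model with an
annotator. Objects are matched one-to-one by the same greedy IoU
matcher as the evaluation metrics, but at threshold 0 — any strictly
positive overlap qualifies — so boundary disagreement is captured even
for weakly overlapping objects. The matched pairs' IoUs form the
per-object agreement distribution (summarized by its median); accuracy
agreement is the F1 score of a re-match at the fixed 0.7 IoU
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .mask_io import LabelMask
from .metrics import (
    ConfusionAtThreshold,
    iou_matrix,
    match_at_threshold,
    precision_recall_f1,
)

__all__ = ["AgreementReport", "pairwise_agreement", "agreement_table"]


@dataclass
class AgreementReport:
    """Agreement between two segmentations (one image or pooled)."""

    pair_label: str
    per_object_ious: list[float]
    median_iou: float
    f1_at_07: float
    n_matched: int
    n_only_a: int
    n_only_b: int


def pairwise_agreement(
    a: LabelMask, b: LabelMask, pair_label: str = "a vs b"
) -> AgreementReport:
    """Match objects of two masks (IoU > 0) and summarize their agreement.

    The matched-IoU multiset is symmetric in the two masks; F1 at 0.7
    treats ``a`` as the target.
    """
    if a.shape != b.shape:
        raise ContractError(f"mask shapes differ: {a.shape} vs {b.shape}")
    m = iou_matrix(a, b)
    overlap = match_at_threshold(m, 0.0)
    ious = [iou for _, _, iou in overlap.pairs]
    median = float(np.median(ious)) if ious else 0.0
    strict = match_at_threshold(m, 0.7)
    _, _, f1 = precision_recall_f1(ConfusionAtThreshold.from_match(strict))
    return AgreementReport(
        pair_label=pair_label,
        per_object_ious=ious,
        median_iou=median,
        f1_at_07=f1,
        n_matched=overlap.tp,
        n_only_a=overlap.fn,
        n_only_b=overlap.fp,
    )


def agreement_table(
    masksets: Mapping[str, Mapping[str, LabelMask]],
) -> tuple[pd.DataFrame, list[AgreementReport]]:
    """All-pairs agreement across named mask collections.

    ``masksets`` maps a collection name (annotator or model) to a
    mapping ``image_id -> LabelMask``. Returns a per-(pair, image)
    table and pooled reports per pair; pooled medians are taken over
    the concatenated per-object IoU list (object-weighted) and pooled
    F1 over summed confusion counts.
    """
    names = sorted(masksets)
    if len(names) < 2:
        raise ContractError("agreement_table requires at least two collections")
    shared = set.intersection(*(set(masksets[n]) for n in names))
    if not shared:
        raise ContractError("collections share no image ids")
    rows = []
    pooled: list[AgreementReport] = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            label = f"{na} vs {nb}"
            all_ious: list[float] = []
            tp = fp = fn = 0
            n_matched = n_only_a = n_only_b = 0
            for image_id in sorted(shared):
                rep = pairwise_agreement(
                    masksets[na][image_id], masksets[nb][image_id], label
                )
                m = iou_matrix(masksets[na][image_id], masksets[nb][image_id])
                strict = match_at_threshold(m, 0.7)
                tp += strict.tp
                fp += strict.fp
                fn += strict.fn
                n_matched += rep.n_matched
                n_only_a += rep.n_only_a
                n_only_b += rep.n_only_b
                all_ious.extend(rep.per_object_ious)
                rows.append(
                    {
                        "pair": label,
                        "image_id": image_id,
                        "median_iou": rep.median_iou,
                        "f1_at_0.7": rep.f1_at_07,
                        "n_matched": rep.n_matched,
                        "n_only_a": rep.n_only_a,
                        "n_only_b": rep.n_only_b,
                    }
                )
            _, _, pooled_f1 = precision_recall_f1(
                ConfusionAtThreshold(0.7, tp, fp, fn)
            )
            pooled.append(
                AgreementReport(
                    pair_label=label,
                    per_object_ious=all_ious,
                    median_iou=float(np.median(all_ious)) if all_ious else 0.0,
                    f1_at_07=pooled_f1,
                    n_matched=n_matched,
                    n_only_a=n_only_a,
                    n_only_b=n_only_b,
                )
            )
    return pd.DataFrame(rows), pooled
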