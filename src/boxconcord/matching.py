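"""Correspondence relation, greedy matching and pairwise agreement metrics.

Two boxes are deemed to denote the same lesion when either contains the
other's centroid — a reflexive, symmetric but non-transitive relation.  A
matching between two annotators' boxes on one image is built greedily,
seeding from the largest box; each box is used at most once.  Agreement
between two annotators over a dataset is summarised by

* the number of errors ``e`` — unmatched boxes of both sides summed over
  images (missed lesions and spurious detections alike), and
* the pooled mean IoU over all matched pairs across the dataset (unmatched
  boxes do not enter this mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .geometry_io import BoundingBox, Dataset, intersection_area, iou

__all__ = [
    "boxes_correspond",
    "greedy_match",
    "count_errors",
    "MatchResult",
    "PairwiseAgreement",
    "pairwise_agreement",
    "pairwise_matrix",
    "combined_agreement_table",
]


def boxes_correspond(b: BoundingBox, b2: BoundingBox) -> bool:
    """True iff centroid(b) lies in b2 or centroid(b2) lies in b (inclusive)."""
    return b2.contains_point(*b.centroid) or b.contains_point(*b2.centroid)


@dataclass
class MatchResult:
    """A matching between two box collections on one image.

    ``pairs`` are oriented (box from side a, box from side b) regardless of
    which side seeded the match.  Boxes of either side not covered by any
    pair are the errors: ``e = |unmatched_a| + |unmatched_b|``.
    """

    pairs: list[tuple[BoundingBox, BoundingBox]] = field(default_factory=list)
    unmatched_a: list[BoundingBox] = field(default_factory=list)
    unmatched_b: list[BoundingBox] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return len(self.unmatched_a) + len(self.unmatched_b)

    @property
    def ious(self) -> list[float]:
        return [iou(a, b) for a, b in self.pairs]


def count_errors(m: MatchResult) -> int:
    """Number of unmatched boxes on both sides."""
    return m.n_errors


def _seed_key(box: BoundingBox, side: int) -> tuple:
    # Largest area first; lexicographic coordinates, then side a before side b
    # (the side component can only matter for coordinate-identical twins and
    # cannot change e or the pooled IoU).
    return (-box.area, box.as_tuple(), side)


def greedy_match(
    boxes_a: Sequence[BoundingBox],
    boxes_b: Sequence[BoundingBox],
) -> MatchResult:
    """Greedy largest-box-first matching between two collections.

    Boxes from both sides are processed in order of decreasing area (ties:
    lexicographic coordinates, then side).  Each seed looks for a
    corresponding box among the other side's still-unmatched boxes; among
    candidates the one maximising the intersection area wins, then the
    largest, then the lexicographically smallest.  A seed with no candidate
    stays unmatched but remains available as a candidate for later seeds
    from the other side — boxes leave the pool only when matched, which
    makes the result maximal: no unmatched cross-pair corresponds.
    """
    a = list(boxes_a)
    b = list(boxes_b)
    entries = sorted(
        [(i, 0) for i in range(len(a))] + [(j, 1) for j in range(len(b))],
        key=lambda e: _seed_key((a, b)[e[1]][e[0]], e[1]),
    )
    matched_a: dict[int, int] = {}  # index in a -> index in b
    matched_b: dict[int, int] = {}

    for idx, side in entries:
        if side == 0:
            if idx in matched_a:
                continue
            seed, others, taken = a[idx], b, matched_b
        else:
            if idx in matched_b:
                continue
            seed, others, taken = b[idx], a, matched_a
        best = None
        best_key = None
        for j, cand in enumerate(others):
            if j in taken or not boxes_correspond(seed, cand):
                continue
            key = (-intersection_area(seed, cand), -cand.area, cand.as_tuple())
            if best_key is None or key < best_key:
                best, best_key = j, key
        if best is None:
            continue
        if side == 0:
            matched_a[idx] = best
            matched_b[best] = idx
        else:
            matched_b[idx] = best
            matched_a[best] = idx

    pairs = [(a[i], b[j]) for i, j in sorted(matched_a.items())]
    unmatched_a = [a[i] for i in range(len(a)) if i not in matched_a]
    unmatched_b = [b[j] for j in range(len(b)) if j not in matched_b]
    return MatchResult(pairs, unmatched_a, unmatched_b)


@dataclass
class PairwiseAgreement:
    """Dataset-level agreement between two annotators.

    ``iou_mean`` is the pooled mean — all matched-pair IoUs across all
    images divided by the total match count, not a mean of per-image means;
    it is ``None`` when the two annotators share no match anywhere.
    """

    annotator_a: str
    annotator_b: str
    e_total: int
    iou_mean: float | None
    per_image: dict[str, tuple[int, list[float]]]

    @property
    def n_matches(self) -> int:
        return sum(len(ious) for _, ious in self.per_image.values())


def pairwise_agreement(dataset: Dataset, a: str, b: str) -> PairwiseAgreement:
    """Match annotators a and b on every image and pool the metrics."""
    per_image: dict[str, tuple[int, list[float]]] = {}
    e_total = 0
    iou_sum = 0.0
    n_matches = 0
    for image_id in dataset.image_ids:
        m = greedy_match(dataset.boxes(a, image_id), dataset.boxes(b, image_id))
        ious = m.ious
        per_image[image_id] = (m.n_errors, ious)
        e_total += m.n_errors
        iou_sum += sum(ious)
        n_matches += len(ious)
    iou_mean = iou_sum / n_matches if n_matches else None
    return PairwiseAgreement(a, b, e_total, iou_mean, per_image)


def pairwise_matrix(
    dataset: Dataset,
    annotators: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Square tables of e (diagonal 0) and pooled IoU (diagonal 1).

    Both matrices are symmetric; an undefined IoU cell (no matches at all
    between a pair) is NaN.
    """
    ids = list(annotators) if annotators is not None else dataset.annotator_ids
    if len(ids) < 2:
        raise ValueError("pairwise_matrix needs at least 2 annotators")
    e = pd.DataFrame(0.0, index=ids, columns=ids)
    io = pd.DataFrame(1.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            agg = pairwise_agreement(dataset, a, b)
            e.loc[a, b] = e.loc[b, a] = agg.e_total
            v = float("nan") if agg.iou_mean is None else agg.iou_mean
            io.loc[a, b] = io.loc[b, a] = v
    return e, io


def combined_agreement_table(e: pd.DataFrame, iou_m: pd.DataFrame) -> pd.DataFrame:
    """One table with pooled IoU above the diagonal and e below it."""
    ids = list(e.index)
    out = pd.DataFrame("", index=ids, columns=ids, dtype=object)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                v = iou_m.loc[a, b]
                out.loc[a, b] = "" if pd.isna(v) else f"{v:.2f}"
            elif i > j:
                out.loc[a, b] = str(int(e.loc[a, b]))
    return out
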