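"""Majority consensus standards and evaluation against them.

When no gold standard exists, the annotations of an expert panel E can be
fused into a consensus standard: lesions supported by a strict majority of
the panel (|supporters| > |E|/2) form the majority set S, each represented
by the coordinate-wise mean of its supporting boxes; lesions proposed
without majority support form the tentative (minority) set S'.  Tentative
lesions count as neither true positives nor false positives when an
annotator is scored against the standard.

To avoid self-confirmation bias, an annotator is evaluated only against
standards built without them (leave-one-out), and a designated reference
annotator can be excluded from every panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .geometry_io import AnnotationSet, BoundingBox, Dataset, intersection_area
from .matching import greedy_match

__all__ = [
    "ConsensusStandard",
    "ConsensusEvaluation",
    "ReferenceComparison",
    "build_consensus",
    "leave_one_out_standards",
    "evaluate_against_consensus",
    "evaluate_all_against_standards",
    "compare_to_reference",
    "f1_score",
    "classification_error_percent",
]


def _mean_box(boxes: Sequence[BoundingBox]) -> BoundingBox:
    n = len(boxes)
    return BoundingBox(
        sum(b.xmin for b in boxes) / n,
        sum(b.ymin for b in boxes) / n,
        sum(b.xmax for b in boxes) / n,
        sum(b.ymax for b in boxes) / n,
    )


@dataclass
class ConsensusStandard:
    """Per-image majority set S and tentative minority set S' of a panel.

    ``support`` holds, for each S box, how many panel members contributed to
    its mean (always > |panel|/2).  ``minority_supported`` audits the rare
    events where a minority seed still had supporters that were consumed
    with it (possible only for even panels)."""

    expert_ids: tuple[str, ...]
    per_image: dict[str, tuple[list[BoundingBox], list[BoundingBox]]] = field(default_factory=dict)
    support: dict[str, list[int]] = field(default_factory=dict)
    minority_supported: list[tuple[str, BoundingBox, int]] = field(default_factory=list)

    @property
    def majority_threshold(self) -> float:
        return len(self.expert_ids) / 2.0

    def majority(self, image_id: str) -> list[BoundingBox]:
        return self.per_image.get(image_id, ([], []))[0]

    def minority(self, image_id: str) -> list[BoundingBox]:
        return self.per_image.get(image_id, ([], []))[1]

    @property
    def n_majority(self) -> int:
        return sum(len(s) for s, _ in self.per_image.values())

    @property
    def n_minority(self) -> int:
        return sum(len(sp) for _, sp in self.per_image.values())

    def to_dict(self) -> dict:
        return {
            "experts": list(self.expert_ids),
            "images": {
                image_id: {
                    "majority": [list(b.as_tuple()) for b in s],
                    "minority": [list(b.as_tuple()) for b in sp],
                }
                for image_id, (s, sp) in self.per_image.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ConsensusStandard":
        std = cls(tuple(doc["experts"]))
        for image_id, sec in doc["images"].items():
            std.per_image[image_id] = (
                [BoundingBox(*b) for b in sec["majority"]],
                [BoundingBox(*b) for b in sec["minority"]],
            )
        return std


def build_consensus(dataset: Dataset, panel: Sequence[str]) -> ConsensusStandard:
    """Fuse a panel's annotations into majority / minority sets per image.

    Greedy procedure per image: take the globally largest remaining box b
    (area, then lexicographic coordinates, then panel order) and remove it;
    from each OTHER panel member take at most one corresponding box
    (max intersection with b, then largest, then lexicographic) into the
    supporter set B'; remove the supporters too.  If |B'|+1 > |panel|/2 the
    coordinate-wise mean of B' ∪ {b} joins S, otherwise b joins S'.  Repeat
    until every member's set is empty.  With a panel of two, unanimity is
    required for S.
    """
    panel = list(panel)
    if len(panel) < 2:
        raise ValueError(f"consensus panel needs >= 2 experts, got {len(panel)}")
    for a in panel:
        if a not in dataset.annotations:
            raise ValueError(f"panel member {a!r} has no annotations in dataset")

    std = ConsensusStandard(tuple(panel))
    half = len(panel) / 2.0
    for image_id in dataset.image_ids:
        working: dict[str, list[BoundingBox]] = {
            a: list(dataset.boxes(a, image_id)) for a in panel
        }
        s_boxes: list[BoundingBox] = []
        s_support: list[int] = []
        sp_boxes: list[BoundingBox] = []
        while any(working.values()):
            # globally largest remaining box; panel order is the residual tie-break
            seed_a, seed_i = min(
                (
                    (a, i)
                    for rank, a in enumerate(panel)
                    for i in range(len(working[a]))
                ),
                key=lambda t: (
                    -working[t[0]][t[1]].area,
                    working[t[0]][t[1]].as_tuple(),
                    panel.index(t[0]),
                ),
            )
            b = working[seed_a].pop(seed_i)
            supporters: list[BoundingBox] = []
            for a2 in panel:
                if a2 == seed_a:
                    continue
                best = None
                best_key = None
                for j, cand in enumerate(working[a2]):
                    inter = intersection_area(b, cand)
                    if not (
                        cand.contains_point(*b.centroid) or b.contains_point(*cand.centroid)
                    ):
                        continue
                    key = (-inter, -cand.area, cand.as_tuple())
                    if best_key is None or key < best_key:
                        best, best_key = j, key
                if best is not None:
                    supporters.append(working[a2].pop(best))
            if len(supporters) + 1 > half:
                s_boxes.append(_mean_box(supporters + [b]))
                s_support.append(len(supporters) + 1)
            else:
                sp_boxes.append(b)
                if supporters:
                    std.minority_supported.append((image_id, b, len(supporters)))
        std.per_image[image_id] = (s_boxes, sp_boxes)
        std.support[image_id] = s_support
    return std


def leave_one_out_standards(
    dataset: Dataset,
    experts: Sequence[str],
    exclude_always: str | None = None,
) -> dict[str, ConsensusStandard]:
    """One consensus standard per left-out expert.

    ``exclude_always`` names an annotator (typically the reference whose
    annotations trained an automatic method) kept out of every panel.
    Returns a mapping left-out expert id -> standard built from the others.
    """
    experts = [e for e in experts if e != exclude_always]
    if len(experts) < 3:
        raise ValueError(
            "leave-one-out needs >= 3 experts after exclusions "
            f"(got {len(experts)}: panels would fall below 2)"
        )
    return {
        left_out: build_consensus(dataset, [e for e in experts if e != left_out])
        for left_out in experts
    }


@dataclass
class ConsensusMatchSummary:
    """e and pooled IoU of one annotator against one standard."""

    annotator_id: str
    e: int
    iou_mean: float | None
    n_matches: int
    n_tentative_matches: int


def evaluate_against_consensus(
    annotator: AnnotationSet,
    std: ConsensusStandard,
) -> ConsensusMatchSummary:
    """Score an annotator against a consensus standard.

    Per image the annotator's boxes are matched against S first; the
    leftovers are then matched against S', and any that match a tentative
    lesion are discarded — they count as neither true nor false positives
    and contribute nothing to the IoU.  Errors are unmatched S boxes
    (missed confirmed lesions) plus annotator boxes matching neither S nor
    S' (spurious detections).
    """
    if annotator.annotator_id in std.expert_ids:
        raise ValueError(
            f"annotator {annotator.annotator_id!r} is in the standard's panel; "
            "evaluate only against leave-one-out standards"
        )
    e = 0
    iou_sum = 0.0
    n_matches = 0
    n_tentative = 0
    for image_id, (s_boxes, sp_boxes) in std.per_image.items():
        m1 = greedy_match(annotator.boxes_for(image_id), s_boxes)
        iou_sum += sum(m1.ious)
        n_matches += len(m1.pairs)
        m2 = greedy_match(m1.unmatched_a, sp_boxes)
        n_tentative += len(m2.pairs)
        e += len(m1.unmatched_b) + len(m2.unmatched_a)
    iou_mean = iou_sum / n_matches if n_matches else None
    return ConsensusMatchSummary(annotator.annotator_id, e, iou_mean, n_matches, n_tentative)


@dataclass
class ConsensusEvaluation:
    """Per-standard and averaged scores for one annotator."""

    annotator_id: str
    per_standard: dict[str, ConsensusMatchSummary]

    @property
    def e_avg(self) -> float:
        return sum(s.e for s in self.per_standard.values()) / len(self.per_standard)

    @property
    def iou_avg(self) -> float | None:
        vals = [s.iou_mean for s in self.per_standard.values() if s.iou_mean is not None]
        return sum(vals) / len(vals) if vals else None


def evaluate_all_against_standards(
    dataset: Dataset,
    experts: Sequence[str],
    others: Sequence[str],
    exclude_always: str | None = None,
) -> dict[str, ConsensusEvaluation]:
    """Leave-one-out evaluation of a whole annotator roster.

    Panel experts are scored only on the one standard that excludes them;
    every annotator in ``others`` (and ``exclude_always`` if given) is
    scored on all standards and the results averaged.
    """
    standards = leave_one_out_standards(dataset, experts, exclude_always)
    evals: dict[str, ConsensusEvaluation] = {}
    panel_experts = [e for e in experts if e != exclude_always]
    for a in panel_experts:
        summary = evaluate_against_consensus(dataset.annotations[a], standards[a])
        evals[a] = ConsensusEvaluation(a, {a: summary})
    roster = list(others)
    if exclude_always is not None and exclude_always not in roster:
        roster.append(exclude_always)
    for a in roster:
        per_std = {
            left_out: evaluate_against_consensus(dataset.annotations[a], std)
            for left_out, std in standards.items()
        }
        evals[a] = ConsensusEvaluation(a, per_std)
    return evals


def consensus_table(evals: dict[str, ConsensusEvaluation]) -> pd.DataFrame:
    """Tabulate evaluations: one row per annotator, per-standard IoU/e plus averages.

    Cells for standards not applicable to a panel expert are NaN (rendered
    as dashes in CSV exports).
    """
    std_names = sorted({k for ev in evals.values() for k in ev.per_standard})
    rows = {}
    for aid, ev in evals.items():
        row = {}
        for name in std_names:
            s = ev.per_standard.get(name)
            row[f"iou_excl_{name}"] = float("nan") if s is None or s.iou_mean is None else s.iou_mean
            row[f"e_excl_{name}"] = float("nan") if s is None else s.e
        row["iou_avg"] = float("nan") if ev.iou_avg is None else ev.iou_avg
        row["e_avg"] = ev.e_avg
        rows[aid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Comparison with a designated reference annotator
# ---------------------------------------------------------------------------


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def classification_error_percent(e: int, n_images: int, surfaces_per_image: float) -> float:
    """Detection errors as a percentage of examined surfaces, 1 decimal.

    Treats each image as carrying ``surfaces_per_image`` decision sites
    (default elsewhere: 13 proximal surfaces per bitewing), so e errors over
    n images correspond to an equivalent surface-classification error rate.
    """
    return round(100.0 * e / (n_images * surfaces_per_image), 1)


@dataclass
class ReferenceComparison:
    """Detection-style scores of one annotator against a reference annotator."""

    annotator_id: str
    reference_id: str
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    e: int
    iou_mean: float | None
    classification_error: float


def compare_to_reference(
    dataset: Dataset,
    annotator: str,
    reference: str,
    surfaces_per_image: float = 13.0,
) -> ReferenceComparison:
    """Score an annotator treating another annotator's boxes as ground truth.

    Matches per image: matched pairs are true positives, the annotator's
    unmatched boxes false positives, the reference's unmatched boxes false
    negatives; e = fp + fn.  The classification error expresses e as a
    percentage of (n_images x surfaces_per_image) decision sites.
    """
    if annotator == reference:
        raise ValueError("annotator and reference must differ")
    tp = fp = fn = 0
    iou_sum = 0.0
    for image_id in dataset.image_ids:
        m = greedy_match(dataset.boxes(annotator, image_id), dataset.boxes(reference, image_id))
        tp += len(m.pairs)
        fp += len(m.unmatched_a)
        fn += len(m.unmatched_b)
        iou_sum += sum(m.ious)
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = f1_score(precision, recall) if precision is not None and recall is not None else None
    e = fp + fn
    iou_mean = iou_sum / tp if tp else None
    cls_err = classification_error_percent(e, len(dataset.image_ids), surfaces_per_image)
    return ReferenceComparison(
        annotator, reference, tp, fp, fn, precision, recall, f1, e, iou_mean, cls_err
    )
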