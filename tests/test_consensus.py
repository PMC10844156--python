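import itertools
import random

import pytest

from conftest import make_dataset, random_box

from boxconcord.consensus import (
    build_consensus,
    classification_error_percent,
    compare_to_reference,
    evaluate_against_consensus,
    evaluate_all_against_standards,
    f1_score,
    leave_one_out_standards,
)
from boxconcord.geometry_io import AnnotationSet, BoundingBox
from boxconcord.matching import boxes_correspond


def _site_box(k: int, side: float = 10.0) -> BoundingBox:
    """Well-separated lesion sites on a grid: no two correspond."""
    x, y = 40.0 * (k % 5), 40.0 * (k // 5)
    return BoundingBox(x, y, x + side, y + side)


class TestBuildConsensus:
    def test_unanimous_identical_boxes(self):
        box = BoundingBox(10, 10, 30, 30)
        ds = make_dataset({e: {"i": [box]} for e in ("E1", "E2", "E3")})
        std = build_consensus(ds, ["E1", "E2", "E3"])
        s, sp = std.per_image["i"]
        assert s == [box] and sp == []

    def test_single_proposer_goes_to_minority(self):
        ds = make_dataset(
            {
                "E1": {"i": [BoundingBox(10, 10, 30, 30)]},
                "E2": {"i": []},
                "E3": {"i": []},
                "E4": {"i": []},
            }
        )
        std = build_consensus(ds, ["E1", "E2", "E3", "E4"])
        s, sp = std.per_image["i"]
        assert s == [] and sp == [BoundingBox(10, 10, 30, 30)]

    def test_coordinate_wise_mean_of_three_supporters(self):
        ds = make_dataset(
            {
                "E1": {"i": [BoundingBox(0, 0, 10, 10)]},
                "E2": {"i": [BoundingBox(2, 0, 12, 10)]},
                "E3": {"i": [BoundingBox(1, 3, 11, 13)]},
                "E4": {"i": []},
            }
        )
        std = build_consensus(ds, ["E1", "E2", "E3", "E4"])
        s, sp = std.per_image["i"]
        assert s == [BoundingBox(1, 1, 11, 11)]
        assert sp == []

    def test_two_expert_panel_requires_unanimity(self):
        ds = make_dataset(
            {
                "E1": {"i": [_site_box(0), _site_box(1)]},
                "E2": {"i": [_site_box(0)]},
            }
        )
        std = build_consensus(ds, ["E1", "E2"])
        s, sp = std.per_image["i"]
        assert s == [_site_box(0)]
        assert sp == [_site_box(1)]

    def test_panel_too_small(self):
        ds = make_dataset({"E1": {"i": []}})
        with pytest.raises(ValueError):
            build_consensus(ds, ["E1"])

    def test_box_accounting_conserved(self, rng):
        """Every panel box is consumed exactly once: into an S mean, as an S'
        seed, or as a discarded supporter of an S' seed."""
        for _ in range(30):
            panel = ["E1", "E2", "E3", "E4"]
            data = {
                e: {"i": [random_box(rng, span=40) for _ in range(rng.randint(0, 5))]}
                for e in panel
            }
            ds = make_dataset(data)
            std = build_consensus(ds, panel)
            total_in = sum(len(data[e]["i"]) for e in panel)
            s, sp = std.per_image["i"]
            consumed_by_s = sum(std.support["i"])
            minority_supporters = sum(
                n for img, _, n in std.minority_supported if img == "i"
            )
            assert consumed_by_s + len(sp) + minority_supporters == total_in

    @pytest.mark.parametrize("n_experts", [2, 3, 4, 5])
    def test_majority_voting_semantics(self, n_experts):
        """On separated sites, a site lands in S iff supported by a strict
        majority of the panel — unanimity when the panel has two members."""
        experts = [f"E{j}" for j in range(n_experts)]
        rnd = random.Random(7 + n_experts)
        sites = list(range(8))
        supporters = {k: set(rnd.sample(experts, rnd.randint(0, n_experts))) for k in sites}
        data = {
            e: {"i": [_site_box(k) for k in sites if e in supporters[k]]}
            for e in experts
        }
        ds = make_dataset(data)
        std = build_consensus(ds, experts)
        s, sp = std.per_image["i"]
        for k in sites:
            n_sup = len(supporters[k])
            in_s = any(boxes_correspond(b, _site_box(k)) for b in s)
            in_sp = any(boxes_correspond(b, _site_box(k)) for b in sp)
            if n_sup > n_experts / 2:
                assert in_s and not in_sp
            elif n_sup > 0:
                assert in_sp and not in_s
            else:
                assert not in_s and not in_sp


class TestLeaveOneOut:
    def _panel_dataset(self, experts):
        return make_dataset({e: {"i": [_site_box(0)]} for e in experts})

    def test_four_experts_four_standards(self):
        experts = ["E1", "E2", "E3", "E4"]
        stds = leave_one_out_standards(self._panel_dataset(experts), experts)
        assert set(stds) == set(experts)
        for left_out, std in stds.items():
            assert left_out not in std.expert_ids
            assert len(std.expert_ids) == 3

    def test_always_excluded_reference_shrinks_panels(self):
        experts = ["E1", "E2", "E3", "E4"]
        stds = leave_one_out_standards(self._panel_dataset(experts), experts, exclude_always="E1")
        assert set(stds) == {"E2", "E3", "E4"}
        assert all(len(std.expert_ids) == 2 for std in stds.values())

    def test_three_experts_pairs(self):
        experts = ["E1", "E2", "E3"]
        stds = leave_one_out_standards(self._panel_dataset(experts), experts)
        assert all(len(std.expert_ids) == 2 for std in stds.values())

    def test_too_few_experts_rejected(self):
        experts = ["E1", "E2"]
        with pytest.raises(ValueError):
            leave_one_out_standards(self._panel_dataset(experts), experts)


class TestEvaluateAgainstConsensus:
    def _standard(self):
        ds = make_dataset(
            {
                "E1": {"i": [_site_box(0), _site_box(1)]},
                "E2": {"i": [_site_box(0), _site_box(1)]},
                "E3": {"i": [_site_box(0), _site_box(2)]},
            }
        )
        return build_consensus(ds, ["E1", "E2", "E3"])  # S = sites 0,1; S' = site 2

    def test_identical_to_majority_is_perfect(self):
        std = self._standard()
        annot = AnnotationSet("M", {"i": [_site_box(0), _site_box(1)]})
        res = evaluate_against_consensus(annot, std)
        assert res.e == 0 and res.iou_mean == pytest.approx(1.0)

    def test_tentative_match_is_neither_tp_nor_fp(self):
        std = self._standard()
        annot = AnnotationSet("M", {"i": [_site_box(0), _site_box(1), _site_box(2)]})
        res = evaluate_against_consensus(annot, std)
        assert res.e == 0
        assert res.n_tentative_matches == 1
        assert res.n_matches == 2  # tentative match contributes nothing to IoU pool

    def test_spurious_box_is_one_error(self):
        std = self._standard()
        annot = AnnotationSet("M", {"i": [_site_box(0), _site_box(1), _site_box(7)]})
        res = evaluate_against_consensus(annot, std)
        assert res.e == 1

    def test_panel_member_rejected(self):
        std = self._standard()
        with pytest.raises(ValueError, match="panel"):
            evaluate_against_consensus(AnnotationSet("E1"), std)

    def test_tentative_exclusion_never_increases_errors(self, rng):
        for _ in range(25):
            panel = ["E1", "E2", "E3"]
            ds = make_dataset(
                {
                    e: {"i": [random_box(rng, span=40) for _ in range(rng.randint(0, 5))]}
                    for e in panel
                }
            )
            std = build_consensus(ds, panel)
            std_no_sp = type(std)(std.expert_ids)
            std_no_sp.per_image = {k: (s, []) for k, (s, _) in std.per_image.items()}
            annot = AnnotationSet("M", {"i": [random_box(rng, span=40) for _ in range(4)]})
            with_sp = evaluate_against_consensus(annot, std).e
            without_sp = evaluate_against_consensus(annot, std_no_sp).e
            assert with_sp <= without_sp


class TestEvaluateAll:
    def _dataset(self):
        experts = ["E1", "E2", "E3", "E4"]
        data = {e: {"i": [_site_box(0), _site_box(1)]} for e in experts}
        data["M"] = {"i": [_site_box(0), _site_box(1)]}
        data["E0"] = {"i": [_site_box(0), _site_box(1)]}
        return make_dataset(data), experts

    def test_expert_scored_on_own_leave_one_out_only(self):
        ds, experts = self._dataset()
        evals = evaluate_all_against_standards(ds, experts, ["M", "E0"])
        assert list(evals["E2"].per_standard) == ["E2"]
        assert len(evals["M"].per_standard) == 4

    def test_identical_annotators_all_zero_errors(self):
        ds, experts = self._dataset()
        evals = evaluate_all_against_standards(ds, experts, ["M", "E0"])
        for ev in evals.values():
            assert ev.e_avg == 0
            assert ev.iou_avg == pytest.approx(1.0)


class TestReferenceComparison:
    def test_f1_from_printed_precision_recall(self):
        assert round(f1_score(0.78, 0.73), 2) == 0.75

    def test_classification_error_arithmetic(self):
        assert classification_error_percent(83, 100, 13) == 6.4

    def test_perfect_agreement(self):
        ds = make_dataset(
            {
                "M": {f"i{k}": [_site_box(0)] for k in range(4)},
                "E0": {f"i{k}": [_site_box(0)] for k in range(4)},
            }
        )
        r = compare_to_reference(ds, "M", "E0")
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)
        assert r.classification_error == 0.0

    def test_count_identities(self, rng):
        data = {
            aid: {f"i{k}": [random_box(rng, span=40) for _ in range(rng.randint(0, 4))] for k in range(5)}
            for aid in ("M", "E0")
        }
        ds = make_dataset(data)
        r = compare_to_reference(ds, "M", "E0")
        n_m = sum(len(v) for v in data["M"].values())
        n_e0 = sum(len(v) for v in data["E0"].values())
        assert r.tp + r.fp == n_m
        assert r.tp + r.fn == n_e0
        assert r.e == r.fp + r.fn

    def test_self_comparison_rejected(self):
        ds = make_dataset({"M": {"i": []}, "E0": {"i": []}})
        with pytest.raises(ValueError):
            compare_to_reference(ds, "M", "M")


def test_parameter_recovery_perfect_panel():
    """Perfect simulated experts reproduce the ground truth exactly: S equals
    the true sites, S' is empty, and a designated annotator's recall against
    S equals its simulated sensitivity up to binomial error."""
    from boxconcord.synthetic import AnnotatorProfile, generate_layout, simulate_panel

    layout = generate_layout(n_images=40, lesion_rate=3.0, seed=11)
    profiles = [AnnotatorProfile(f"E{j}", sensitivity=1.0) for j in range(1, 4)]
    target_sens = 0.8
    profiles.append(AnnotatorProfile("M", sensitivity=target_sens, center_jitter_sd=1.0))
    ds = simulate_panel(layout, profiles)
    std = build_consensus(ds, ["E1", "E2", "E3"])
    import numpy as np

    for image_id, truth in layout.lesions.items():
        s, sp = std.per_image[image_id]
        assert sp == []
        got = sorted(b.as_tuple() for b in s)
        exp = sorted(b.as_tuple() for b in truth)
        assert len(got) == len(exp)
        # coordinate-wise means of identical boxes agree up to float rounding
        if got:
            assert np.allclose(np.array(got), np.array(exp), atol=1e-9)
    res = evaluate_against_consensus(ds.annotations["M"], std)
    n_truth = layout.n_lesions
    recall = res.n_matches / n_truth
    sd = (target_sens * (1 - target_sens) / n_truth) ** 0.5
    assert abs(recall - target_sens) < 4 * sd
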