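"""Seeded simulator of lesion layouts and multi-annotator panels.

Real multi-reader annotation studies have no observable gold standard; the
simulator provides one.  A :class:`GroundTruthLayout` places lesions (boxes)
in image frames — by default the lesions are mutually non-corresponding, so
each box unambiguously identifies one site.  An :class:`AnnotatorProfile`
then degrades the truth the way a human reader would: missing lesions
(sensitivity < 1), inventing spurious ones (Poisson false positives),
displacing box centers (Gaussian jitter) and mis-sizing boxes (a systematic
scale factor times log-normal noise).

Everything is reproducible: per-annotator streams are derived from a master
seed and a stable hash of the annotator id, so adding an annotator never
perturbs the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry_io import AnnotationSet, BoundingBox, Dataset, ImageFrame
from .matching import boxes_correspond

__all__ = [
    "GroundTruthLayout",
    "AnnotatorProfile",
    "LayoutError",
    "generate_layout",
    "simulate_annotator",
    "simulate_panel",
    "bitewing_panel_profiles",
]

DEFAULT_FRAME = (896.0, 1024.0)
DEFAULT_SIDE_BOUNDS = (8.0, 160.0)
# log-normal side distribution: median 52 px, sigma 0.45 -> mean ~57 px
DEFAULT_SIDE_MEDIAN = 52.0
DEFAULT_SIDE_SIGMA = 0.45


class LayoutError(RuntimeError):
    """Raised when rejection sampling cannot place the requested lesions."""


@dataclass
class GroundTruthLayout:
    """Ground-truth lesion boxes per image, plus the generating parameters."""

    frames: dict[str, ImageFrame]
    lesions: dict[str, list[BoundingBox]]
    seed: int
    side_median: float = DEFAULT_SIDE_MEDIAN
    side_sigma: float = DEFAULT_SIDE_SIGMA
    side_bounds: tuple[float, float] = DEFAULT_SIDE_BOUNDS

    @property
    def n_lesions(self) -> int:
        return sum(len(v) for v in self.lesions.values())

    def as_annotation_set(self, annotator_id: str = "truth") -> AnnotationSet:
        return AnnotationSet(
            annotator_id, {i: list(boxes) for i, boxes in self.lesions.items()}
        )


def _draw_side(rng: np.random.Generator, median: float, sigma: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    for _ in range(1000):
        s = median * math.exp(rng.normal(0.0, sigma))
        if lo <= s <= hi:
            return s
    return min(max(median, lo), hi)


def generate_layout(
    n_images: int = 100,
    frame_dims: tuple[float, float] = DEFAULT_FRAME,
    lesion_rate: float = 3.0,
    side_median: float = DEFAULT_SIDE_MEDIAN,
    side_sigma: float = DEFAULT_SIDE_SIGMA,
    side_bounds: tuple[float, float] = DEFAULT_SIDE_BOUNDS,
    min_separation: bool = True,
    seed: int = 0,
    rejection_budget: int = 500,
) -> GroundTruthLayout:
    """Place Poisson(lesion_rate) lesions per image with log-normal sides.

    With ``min_separation`` (default) no two lesions in an image satisfy the
    centroid-correspondence relation, so each lesion is a distinct site for
    voting and recovery experiments.  Placement uses rejection sampling;
    exhausting the budget raises :class:`LayoutError` suggesting a lower
    rate.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if lesion_rate < 0:
        raise ValueError("lesion_rate must be >= 0")
    w, h = frame_dims
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6C6179]))
    frames: dict[str, ImageFrame] = {}
    lesions: dict[str, list[BoundingBox]] = {}
    for k in range(n_images):
        image_id = f"img_{k:04d}"
        frames[image_id] = ImageFrame(image_id, w, h)
        n = int(rng.poisson(lesion_rate))
        boxes: list[BoundingBox] = []
        for _ in range(n):
            placed = False
            for _ in range(rejection_budget):
                bw = _draw_side(rng, side_median, side_sigma, side_bounds)
                bh = _draw_side(rng, side_median, side_sigma, side_bounds)
                x = rng.uniform(0.0, w - bw)
                y = rng.uniform(0.0, h - bh)
                cand = BoundingBox(x, y, x + bw, y + bh)
                if min_separation and any(boxes_correspond(cand, b) for b in boxes):
                    continue
                boxes.append(cand)
                placed = True
                break
            if not placed:
                raise LayoutError(
                    f"could not place lesion {len(boxes) + 1} in {image_id} after "
                    f"{rejection_budget} tries; lower lesion_rate or loosen separation"
                )
        lesions[image_id] = boxes
    return GroundTruthLayout(frames, lesions, seed, side_median, side_sigma, side_bounds)


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioural parameters of one simulated annotator.

    sensitivity
        Probability that a true lesion is annotated at all.
    fp_per_image
        Expected number of spurious boxes per image (Poisson).
    center_jitter_sd
        Std dev (px) of the Gaussian displacement of each kept box center.
    scale_factor
        Systematic multiplicative bias on box sides (2.0 = draws boxes
        twice as big as the truth).
    size_noise_sd
        Log-scale std dev of the random per-box size multiplier.
    """

    annotator_id: str
    sensitivity: float = 1.0
    fp_per_image: float = 0.0
    center_jitter_sd: float = 0.0
    scale_factor: float = 1.0
    size_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.fp_per_image < 0:
            raise ValueError("fp_per_image must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")


def _annotator_rng(master_seed: int, annotator_id: str) -> np.random.Generator:
    # crc32 gives a stable, platform-independent per-annotator stream key
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(annotator_id.encode())])
    )


def _clip_to_frame(
    cx: float, cy: float, bw: float, bh: float, frame: ImageFrame
) -> BoundingBox:
    bw = min(bw, frame.width)
    bh = min(bh, frame.height)
    x = min(max(cx - bw / 2.0, 0.0), frame.width - bw)
    y = min(max(cy - bh / 2.0, 0.0), frame.height - bh)
    return BoundingBox(x, y, x + bw, y + bh)


def simulate_annotator(
    layout: GroundTruthLayout,
    profile: AnnotatorProfile,
    master_seed: int | None = None,
    fp_avoid_lesions: bool = True,
) -> AnnotationSet:
    """Produce one annotator's boxes by degrading the ground truth.

    Per true lesion: kept with probability ``sensitivity``; the kept box's
    center is jittered by N(0, center_jitter_sd) per axis and each side is
    multiplied by ``scale_factor · exp(N(0, size_noise_sd))``, then clipped
    to the frame.  False positives (Poisson per image) draw their sizes
    from the layout's side distribution and are placed uniformly, by
    default avoiding correspondence with any true lesion so that the error
    accounting stays identifiable.
    """
    rng = _annotator_rng(layout.seed if master_seed is None else master_seed, profile.annotator_id)
    aset = AnnotationSet(profile.annotator_id)
    for image_id, frame in layout.frames.items():
        out: list[BoundingBox] = []
        truths = layout.lesions[image_id]
        undistorted = (
            profile.center_jitter_sd == 0
            and profile.scale_factor == 1.0
            and profile.size_noise_sd == 0
        )
        for b in truths:
            if rng.uniform() >= profile.sensitivity:
                continue
            if undistorted:
                out.append(b)  # bit-exact passthrough
                continue
            cx, cy = b.centroid
            cx += rng.normal(0.0, profile.center_jitter_sd) if profile.center_jitter_sd else 0.0
            cy += rng.normal(0.0, profile.center_jitter_sd) if profile.center_jitter_sd else 0.0
            mult = profile.scale_factor * (
                math.exp(rng.normal(0.0, profile.size_noise_sd)) if profile.size_noise_sd else 1.0
            )
            out.append(_clip_to_frame(cx, cy, b.width * mult, b.height * mult, frame))
        n_fp = int(rng.poisson(profile.fp_per_image)) if profile.fp_per_image else 0
        for _ in range(n_fp):
            for _ in range(200):
                bw = _draw_side(rng, layout.side_median, layout.side_sigma, layout.side_bounds)
                bh = _draw_side(rng, layout.side_median, layout.side_sigma, layout.side_bounds)
                x = rng.uniform(0.0, frame.width - bw)
                y = rng.uniform(0.0, frame.height - bh)
                cand = BoundingBox(x, y, x + bw, y + bh)
                if fp_avoid_lesions and any(boxes_correspond(cand, t) for t in truths):
                    continue
                out.append(cand)
                break
        aset.boxes_by_image[image_id] = out
    return aset


def simulate_panel(
    layout: GroundTruthLayout,
    profiles: Sequence[AnnotatorProfile],
    master_seed: int | None = None,
) -> Dataset:
    """Simulate every profile independently and bundle the panel as a Dataset."""
    ids = [p.annotator_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate annotator ids in profiles: {ids}")
    ds = Dataset(frames=dict(layout.frames))
    for p in profiles:
        ds.add_annotator(simulate_annotator(layout, p, master_seed=master_seed))
    return ds


def bitewing_panel_profiles() -> list[AnnotatorProfile]:
    """A 9-reader bitewing-style panel preset.

    On 100 images with 3 lesions/image the expected per-annotator counts
    span roughly 240–425: one over-caller (E1), one reader drawing boxes
    twice as big as the others (E4), three noisier novices (N1–N3) with
    elevated false-positive rates, an automatic-method-like reader (M)
    close to the reference reader (E0).
    """
    return [
        AnnotatorProfile("M", sensitivity=0.80, fp_per_image=0.20, center_jitter_sd=3.0, scale_factor=0.90, size_noise_sd=0.10),
        AnnotatorProfile("E0", sensitivity=0.84, fp_per_image=0.20, center_jitter_sd=3.0, scale_factor=1.00, size_noise_sd=0.12),
        AnnotatorProfile("E1", sensitivity=0.97, fp_per_image=1.30, center_jitter_sd=5.0, scale_factor=1.15, size_noise_sd=0.15),
        AnnotatorProfile("E2", sensitivity=0.82, fp_per_image=0.20, center_jitter_sd=6.0, scale_factor=0.95, size_noise_sd=0.18),
        AnnotatorProfile("E3", sensitivity=0.90, fp_per_image=0.25, center_jitter_sd=5.0, scale_factor=1.30, size_noise_sd=0.15),
        AnnotatorProfile("E4", sensitivity=0.75, fp_per_image=0.15, center_jitter_sd=6.0, scale_factor=2.00, size_noise_sd=0.15),
        AnnotatorProfile("N1", sensitivity=0.95, fp_per_image=1.00, center_jitter_sd=8.0, scale_factor=1.00, size_noise_sd=0.20),
        AnnotatorProfile("N2", sensitivity=0.93, fp_per_image=0.90, center_jitter_sd=9.0, scale_factor=1.10, size_noise_sd=0.20),
        AnnotatorProfile("N3", sensitivity=0.90, fp_per_image=0.70, center_jitter_sd=8.0, scale_factor=1.00, size_noise_sd=0.22),
    ]


def profiles_from_config(doc: dict) -> list[AnnotatorProfile]:
    """Build profiles from a parsed YAML/JSON mapping.

    Expected shape: ``{"annotators": [{"annotator_id": ..., "sensitivity":
    ..., ...}, ...]}`` — unknown keys are rejected by the dataclass.
    """
    return [AnnotatorProfile(**entry) for entry in doc["annotators"]]
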