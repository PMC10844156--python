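# boxconcord

Inter-annotator agreement evaluation for bounding-box detection
annotations when no gold standard exists.

In detection tasks such as marking carious lesions in dental bitewing
radiographs, several readers (and possibly an automatic detector) each
produce a set of boxes per image — and they disagree, both about which
lesions exist and about box placement. With no reference standard
available, performance can only be assessed relative to the panel itself.
`boxconcord` implements that methodology:

* **Correspondence.** Two boxes b, b′ denote the same lesion iff
  `centroid(b) ∈ b′ ∨ centroid(b′) ∈ b` — reflexive and symmetric, robust
  to the large box-size differences between annotators.
* **Greedy matching.** For each image, a matching Ω ⊆ B × B′ is built
  greedily from the largest box down; candidates are ranked by
  intersection area, then size, then a deterministic coordinate order.
* **Agreement metrics.** The number of errors
  `e_aa′ = Σ_i (|B_ia| + |B_ia′| − 2|Ω_i|)` counts missed and spurious
  detections; the pooled mean IoU
  `IoU_aa′ = Σ_i Σ_{(b,b′)∈Ω_i} IoU(b,b′) / Σ_i |Ω_i|` measures
  localisation quality over matched pairs only.
* **Consensus standards.** An expert panel E is fused by greedy majority
  voting: a lesion supported by more than |E|/2 members enters the
  majority set S as the coordinate-wise mean of its supporting boxes;
  singletons become *tentative* lesions (S′) that count as neither true
  nor false positives. Leave-one-out standards avoid self-confirmation
  bias.
* **Significance.** Whether annotator a agrees with a reference group
  better than annotator b is tested with a two-sided Wilcoxon signed-rank
  test on the per-image paired differences
  `Δ^i = Σ_c [e(B_ia, B_ic) − e(B_ib, B_ic)]`, reported as the signed
  score `q = ±(1 − p)`.
* **Reference comparison.** Against a designated reference annotator,
  matched pairs are true positives, yielding precision/recall/F1 and a
  surface-level classification error `e / (n_images · surfaces_per_image)`.
* **Simulator.** A seeded generator of ground-truth lesion layouts and
  annotator panels with controllable sensitivity, false-positive rate,
  center jitter and box-scale bias, for validating the whole pipeline.

Input formats: CVAT "for images 1.1" XML (one task per annotator),
COCO detection JSON, and a canonical JSON dataset dump.

## Worked example

Simulate a 9-reader panel (4 experts E1–E4, a reference reader E0, three
novices N1–N3 and an automatic-method-like reader M) on 10 images:

```sh
$ boxconcord simulate demo --n-images 10 --seed 3
wrote panel of 9 annotators on 10 images (29 true lesions) to demo

$ boxconcord stats demo/panel.json
annotator  num  mean_side  std_side
M          21   53.57      23.30
E0         26   62.85      28.02
E1         38   60.71      28.70
E2         22   56.48      29.32
...
```

Build a consensus standard from experts E2–E4 (leaving out E1, the
over-caller) and score M against it:

```sh
$ boxconcord consensus build demo/panel.json --experts E1,E2,E3,E4 \
      --exclude E1 --out demo/s234.json
wrote demo/s234.json: |S|=23, |S'|=13 (panel E2,E3,E4)

$ boxconcord consensus eval demo/panel.json --standard demo/s234.json --annotator M
M vs S(E2,E3,E4): e=7, iou=0.411, matches=16, tentative-matches=5
```

23 lesions had majority support; 13 were tentative. M disagreed with the
standard on 7 confirmed lesions, matched 16 with a mean overlap of 0.41,
and 5 further boxes hit tentative lesions only — those count neither way.

Treating E0 as ground truth:

```sh
$ boxconcord compare-ref demo/panel.json --annotator M --reference E0
M vs E0: tp=18 fp=3 fn=8 P=0.86 R=0.69 F1=0.77 e=11 IoU=0.664 classification_error=8.5%
```

i.e. 18 of M's boxes match E0's, 3 are spurious and 8 of E0's lesions are
missed; the 11 disagreements over 10 images × 13 proximal surfaces
correspond to an 8.5% surface classification error.

The same operations are available as library calls
(`boxconcord.greedy_match`, `pairwise_matrix`, `build_consensus`,
`significance_matrix`, …); see the docstrings and `docs/methods.md`.

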