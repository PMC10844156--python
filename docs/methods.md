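# Methods

## Setting

A detection-annotation study: each annotator a ∈ A examines each image i
and produces a possibly empty set of axis-aligned boxes B_ia in continuous
pixel coordinates (origin top-left). The task is single-class (one lesion
type); there is no observable gold standard, so every evaluation is
relative — pairwise between annotators, against a panel consensus, or
against one designated reference annotator.

## Box correspondence and matching

Two boxes correspond when either contains the other's centroid. Intervals
are treated as closed and containment is boundary-inclusive; coordinates
are continuous, so no pixel-raster convention is needed. Degenerate
(zero-area) boxes are rejected at ingest because both the correspondence
relation and IoU are ill-defined for them.

The per-image matching is greedy:

1. take the largest unprocessed box b from the union of both sides —
   "largest" means largest **area** (the natural magnitude for 2-D boxes;
   longest-side ordering would change very little but area is the
   documented choice), ties broken by lexicographic (xmin, ymin, xmax,
   ymax), then side a before side b;
2. among the other side's still-unmatched boxes, keep those corresponding
   to b; choose the one maximising |b ∩ b′|, then the largest, then the
   lexicographically smallest;
3. a matched pair is removed from further consideration; a seed with no
   candidate is set aside as unmatched but **remains eligible** as a
   candidate for later seeds — boxes leave the pool only on match.

Because the relation is symmetric, rule 3 makes the result *maximal*: if
an unmatched box of one side corresponded to an unmatched box of the
other, the later-processed of the two would have matched it. The
side-independent ordering makes e and the pooled IoU invariant under
swapping the two annotators; the residual side-a-first tie-break can only
fire for coordinate-identical twins and cannot affect either metric. Both
properties, and exact agreement with an independent literal enumeration
of the steps, are checked by the test suite on randomized instances
drawn on an integer grid specifically to provoke area and intersection
ties.

Errors and pooled IoU: e_aa′ sums unmatched boxes of both sides over
images (equivalently |B|+|B′|−2|Ω| per image); IoU_aa′ divides the sum of
all matched-pair IoUs across the dataset by the total number of matches —
deliberately *not* a mean of per-image means, so images with many matches
weigh more. A pair with no matches anywhere has undefined IoU, reported
as None/NaN, never 0.

An annotator with no recorded boxes for an image is treated as having
examined it and found nothing; absence of boxes is a negative finding in
a detection task.

## Consensus standards

For a panel E, per image: repeatedly seed with the globally largest
remaining box (same ordering as above, panel order as final tie-break),
remove it, and collect **at most one** corresponding box from each other
panel member (max intersection, then largest, then lexicographic).
One-per-member matters: the vote count |B′|+1 is compared with |E|/2 and
counts supporting *experts*, so letting one expert contribute two boxes
would corrupt the majority rule. If |B′|+1 > |E|/2 the coordinate-wise
mean of B′ ∪ {b} joins the majority set S; otherwise b joins the
tentative set S′. Supporters consumed alongside a minority seed are
discarded rather than re-seeded — the procedure removes all collected
boxes unconditionally; with the one-per-member rule such an event is only
possible for even panels (e.g. a 2-of-4 lesion) and is recorded in
`minority_supported` for audit. With |E| = 2, S requires unanimity.

Scoring an annotator against a standard: match against S first, then
match the leftovers against S′ and discard any hits — a tentative lesion
is neither a true nor a false positive, and S′ matches contribute nothing
to the IoU numerator or denominator. Matching S before S′ means a
detection overlapping both a confirmed and a tentative lesion scores as a
true detection of the confirmed one. Errors are unmatched S boxes plus
annotator boxes matching neither set; consequently scoring against
(S, S′) can never yield more errors than against (S, ∅).

Leave-one-out standards exclude the annotator under evaluation from the
panel, and optionally a designated reference annotator from every panel
(to avoid rewarding a detector for reproducing its own trainer). Panel
experts are scored only on the one standard that excludes them; everyone
else on all standards, with arithmetic means over standards.

## Reference comparison

Against a designated reference annotator, per-image matches are true
positives; precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = 2PR/(P+R);
e = fp + fn. The classification error converts e into a percentage of
decision sites, e / (n_images · surfaces_per_image), rounded to one
decimal; `surfaces_per_image` defaults to 13, the typical number of
proximal surfaces visible on a bitewing radiograph, and is a user
parameter.

## Significance testing

Per-image paired differences Δ^i = Σ_c [m_i(a,c) − m_i(b,c)] over a
reference group c ∉ {a, b} (a singleton group for comparison with one
reference annotator) feed a **two-sided** Wilcoxon signed-rank test. The
sign display q = ±(1−p) needs both directions, which rules out a
one-sided test. Conventions, all switchable:

* zeros discarded before ranking (Wilcoxon's original treatment; the
  Pratt variant — rank with zeros, drop their ranks — is behind
  `zero_method="pratt"`);
* ties get average ranks;
* the exact null distribution is computed whenever ≤ 25 nonzero values
  remain, by dynamic programming over the doubled (hence integral) ranks
  — full enumeration at desk scale, valid also with ties;
* beyond that, the normal approximation with continuity correction and
  the tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48.

For the IoU metric the per-image pooled matched IoU is used, and images
where any involved pairing has zero matches are dropped from the series
(their ids are recorded) — the difference is undefined there, and
dropping is the minimal-assumption choice. Degenerate all-zero series
report p = 1, q = 0. In significance grids, positive q always means the
row annotator is closer to the reference (fewer errors / higher IoU), so
for the error metric the raw signed-rank direction is negated. Grids are
antisymmetric by construction; no multiple-testing correction is applied.

## Synthetic panels

The generator emulates the *annotation* process, not the images: per
image a Poisson(lesion_rate) number of lesions with log-normally
distributed sides (default median 52 px, σ = 0.45, bounded to [8, 160] px
in a 896×1024 frame — producing mean sides near 55–60 px, the scale of
real bitewing lesion boxes), placed uniformly with rejection sampling so
that, by default, no two same-image lesions correspond. The separation
default makes each lesion an identifiable voting site; it can be turned
off. An annotator profile degrades the truth: each lesion kept with
probability `sensitivity`; kept boxes get Gaussian center jitter and a
`scale_factor · lognormal(0, size_noise_sd)` size multiplier, clipped to
the frame; Poisson(`fp_per_image`) spurious boxes are placed uniformly,
by default avoiding true lesions so sensitivity and false-positive
accounting remain identifiable. A profile with no distortion passes boxes
through bit-exactly.

Per-annotator RNG streams are seeded by (master seed, CRC-32 of the
annotator id), so adding an annotator never perturbs the others' draws,
and identical seeds give bit-identical serialized outputs.

The bundled 9-reader preset mimics a real bitewing panel qualitatively:
on 100 images at 3 lesions/image the expected counts span ~240–430, with
one over-caller (E1), one reader drawing boxes twice as large (E4,
scale_factor 2.0), and three novices with elevated jitter and
false-positive rates.

What passing simulator-based tests does **not** show: real annotators
disagree for structured reasons (lesion depth, image quality, anatomy)
that are not independent across readers or images; real false positives
cluster at plausible sites rather than uniformly; and real box-size
variation is lesion-dependent. The simulator validates the *machinery* —
matching, voting, metrics, test calibration — not claims about real
reader behaviour.

## Numerical choices and problem sizes

* Side-length statistics pool widths and heights into one sample
  (2·n_boxes values), yielding a single mean/std per annotator; the
  standard deviation uses the population (divide-by-n) convention by
  default, with `ddof=1` available — both conventions are reported in the
  result object's metadata.
* Undefined quantities (mean side of an empty set, IoU with no matches,
  precision with no detections) are explicit None/NaN markers, never 0.
* File round-trips are bit-exact: coordinates are written with shortest
  float repr in XML/JSON and re-parsed to the identical doubles.
* The acceptance script uses 3000 random instances for the
  matcher-vs-enumeration agreement rate, 600 panels for symmetry, 300
  replicates for the null rejection rate and 10 seeds for consensus
  recovery; the test suite runs the heavier versions (10,000 instances,
  500 replicates). These sizes give negligible Monte-Carlo error for the
  deterministic rates and a ±0.025-wide 99% band for the rejection rate.

## Known limitations

* Single label class; no confidence scores or graded (5-point) ratings.
* The greedy matcher is faithful to the documented procedure and is not
  a maximum-cardinality matcher; an optimal matcher exists in the test
  suite only as an upper-bound comparator.
* Majority voting is deterministic; probabilistic label fusion
  (STAPLE-style) is out of scope.
* κ-type chance-corrected agreement is not computable in a pure
  detection formulation (absence of a lesion is never explicitly
  labelled), and is deliberately absent.
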