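"""Paired significance testing and agreement summaries.

Whether annotator a agrees with a reference group better than annotator b
is tested on the per-image paired differences

    Δ^i = Σ_{c in ref, c != a, c != b} [ m_i(a, c) − m_i(b, c) ]

where m_i is either the per-image error count e or the per-image pooled
matched IoU.  The two-sided Wilcoxon signed-rank test on the series gives a
p-value; the signed score q = ±(1−p) packs direction and significance into
one number (|q| > 1−α means significant; the sign says which annotator is
closer to the reference).

The exact null distribution of the signed-rank statistic is computed by
dynamic programming over the (average, tie-aware) ranks whenever the number
of nonzero differences is small; beyond that a normal approximation with
continuity and tie corrections is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .matching import greedy_match

__all__ = [
    "PairedDifferenceSeries",
    "SignificanceCell",
    "MeanAgreement",
    "delta_error_series",
    "wilcoxon_signed_rank",
    "significance_matrix",
    "mean_agreement",
]


@dataclass
class PairedDifferenceSeries:
    """Per-image paired differences between annotators a and b.

    For the IoU metric, images where any of the involved pairings had no
    matched boxes are dropped (the per-image pooled IoU is undefined
    there); their ids are recorded in ``dropped_images``.
    """

    annotator_a: str
    annotator_b: str
    reference_set: tuple[str, ...]
    metric: str
    values: np.ndarray
    image_ids: list[str]
    dropped_images: list[str]


def _per_image_metrics(dataset, a: str, c: str, metric: str) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for image_id in dataset.image_ids:
        m = greedy_match(dataset.boxes(a, image_id), dataset.boxes(c, image_id))
        if metric == "errors":
            out[image_id] = float(m.n_errors)
        else:
            ious = m.ious
            out[image_id] = sum(ious) / len(ious) if ious else None
    return out


def delta_error_series(
    dataset,
    a: str,
    b: str,
    reference_set: Sequence[str],
    metric: str = "errors",
) -> PairedDifferenceSeries:
    """Build the paired per-image difference series for a vs b.

    ``reference_set`` is the group of annotators c used as the yardstick;
    a and b must not belong to it (a single-annotator reference, e.g. the
    original annotator of a training set, is the degenerate case).  With
    ``metric="errors"`` values are error-count differences; with
    ``metric="iou"`` they are pooled per-image matched-IoU differences and
    matchless images are dropped.
    """
    refs = [c for c in reference_set]
    if not refs:
        raise ValueError("reference_set must be nonempty")
    if a in refs or b in refs:
        raise ValueError("a and b must not be in the reference set (they are excluded from the sum)")
    if metric not in ("errors", "iou"):
        raise ValueError(f"unknown metric {metric!r}")

    per_ref_a = {c: _per_image_metrics(dataset, a, c, metric) for c in refs}
    per_ref_b = {c: _per_image_metrics(dataset, b, c, metric) for c in refs}

    values: list[float] = []
    kept: list[str] = []
    dropped: list[str] = []
    for image_id in dataset.image_ids:
        vals_a = [per_ref_a[c][image_id] for c in refs]
        vals_b = [per_ref_b[c][image_id] for c in refs]
        if any(v is None for v in vals_a + vals_b):
            dropped.append(image_id)
            continue
        values.append(sum(vals_a) - sum(vals_b))
        kept.append(image_id)
    return PairedDifferenceSeries(
        a, b, tuple(refs), metric, np.asarray(values, dtype=float), kept, dropped
    )


@dataclass
class SignificanceCell:
    """Outcome of one two-sided signed-rank test.

    ``direction`` is the sign of (W+ − n(n+1)/4): +1 when the positive
    differences dominate.  ``q = direction · (1 − p)`` so that p = 1 − |q|
    whenever q != 0.  ``degenerate`` flags an all-zero series (p = 1 by
    convention).
    """

    p_value: float
    direction: int
    q: float
    significant: bool
    n_nonzero: int
    w_plus: float
    method: str
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by DP over all sign assignments of the ranks.

    Average ranks may be half-integers; doubling makes them integral so the
    distribution of 2·W+ fits an integer-indexed count array.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    series: PairedDifferenceSeries | Sequence[float] | np.ndarray,
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
    alpha: float = 0.05,
) -> SignificanceCell:
    """Two-sided Wilcoxon signed-rank test on a paired-difference series.

    Zeros are discarded before ranking (``zero_method="wilcox"``, the
    classical treatment) or kept in the ranking with their ranks dropped
    from both sums (``"pratt"``).  The exact null distribution is used when
    the number of nonzero values is at most ``exact_max_n``; otherwise the
    normal approximation with continuity correction and the tie correction
    of the variance.
    """
    d = np.asarray(series.values if isinstance(series, PairedDifferenceSeries) else series, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference series")
    nonzero = d[d != 0]
    n = nonzero.size
    if n == 0:
        return SignificanceCell(1.0, 0, 0.0, False, 0, 0.0, "degenerate", degenerate=True)

    if zero_method == "pratt":
        ranks_all = _sps.rankdata(np.abs(d))
        mask = d != 0
        ranks = ranks_all[mask]
        signs = np.sign(d[mask])
    elif zero_method == "wilcox":
        ranks = _sps.rankdata(np.abs(nonzero))
        signs = np.sign(nonzero)
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    w_plus = float(ranks[signs > 0].sum())
    mu = float(ranks.sum()) / 2.0  # n(n+1)/4 when ranks are 1..n
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        # variance with tie correction: n(n+1)(2n+1)/24 − Σ(t³−t)/48
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, t = np.unique(ranks, return_counts=True)
        var -= (t**3 - t).sum() / 48.0
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var) if var > 0 else 0.0
        p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
        method = "approx"
    direction = int(np.sign(w_plus - mu))
    q = direction * (1.0 - p)
    return SignificanceCell(p, direction, q, p < alpha, n, w_plus, method)


def significance_matrix(
    dataset,
    rows: Sequence[str],
    cols: Sequence[str] | None = None,
    mode: str = "experts",
    metric: str = "errors",
    experts: Sequence[str] | None = None,
    reference: str | None = None,
    alpha: float = 0.05,
    zero_method: str = "wilcox",
) -> tuple[pd.DataFrame, dict[tuple[str, str], SignificanceCell]]:
    """Grid of signed significance scores q between annotator pairs.

    ``mode="experts"`` uses the expert group (minus the two annotators under
    comparison) as the reference set; ``mode="reference"`` uses a single
    designated annotator.  Positive q always means the ROW annotator is
    closer to the reference — lower errors or higher IoU — so the e-metric
    direction is flipped relative to the raw signed-rank direction.
    The grid is antisymmetric (q(a,b) = −q(b,a)); the diagonal is NaN.
    """
    cols = list(cols) if cols is not None else list(rows)
    if mode == "experts":
        if not experts:
            raise ValueError("mode='experts' requires the experts list")
    elif mode == "reference":
        if reference is None:
            raise ValueError("mode='reference' requires a reference annotator")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    better_sign = -1 if metric == "errors" else 1
    grid = pd.DataFrame(float("nan"), index=list(rows), columns=cols)
    cells: dict[tuple[str, str], SignificanceCell] = {}
    for a in rows:
        for b in cols:
            if a == b:
                continue
            if mode == "experts":
                refs = [c for c in experts if c not in (a, b)]
            else:
                if reference in (a, b):
                    continue
                refs = [reference]
            series = delta_error_series(dataset, a, b, refs, metric=metric)
            if series.values.size == 0:
                continue
            cell = wilcoxon_signed_rank(series, zero_method=zero_method, alpha=alpha)
            cells[(a, b)] = cell
            grid.loc[a, b] = better_sign * cell.direction * (1.0 - cell.p_value)
    return grid, cells


@dataclass
class MeanAgreement:
    """Pairwise e and pooled IoU of one annotator averaged over a peer group."""

    annotator_id: str
    e_mean: float
    iou_mean_over_peers: float | None
    peers: tuple[str, ...]
    undefined_iou_peers: tuple[str, ...]


def mean_agreement(dataset, a: str, peer_set: Sequence[str]) -> MeanAgreement:
    """Average the pairwise agreement of annotator a over peers other than a.

    Peers whose pairwise IoU with a is undefined (no matches anywhere) are
    excluded from the IoU mean and reported in ``undefined_iou_peers``.
    """
    from .matching import pairwise_agreement

    peers = [p for p in peer_set if p != a]
    if not peers:
        raise ValueError(f"peer_set for {a!r} contains no annotator other than {a!r}")
    e_vals = []
    iou_vals = []
    undefined = []
    for p in peers:
        agg = pairwise_agreement(dataset, a, p)
        e_vals.append(agg.e_total)
        if agg.iou_mean is None:
            undefined.append(p)
        else:
            iou_vals.append(agg.iou_mean)
    iou_mean = sum(iou_vals) / len(iou_vals) if iou_vals else None
    return MeanAgreement(a, sum(e_vals) / len(e_vals), iou_mean, tuple(peers), tuple(undefined))


def render_significance_heatmap(grid: pd.DataFrame, path, alpha: float = 0.05):
    """Render a q-value grid as a green/red heatmap (saturated when significant)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "qmap", [(0.7, 0.1, 0.1), (1.0, 1.0, 1.0), (0.1, 0.6, 0.1)]
    )
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(grid.columns), 1 + 0.6 * len(grid.index)))
    im = ax.imshow(grid.to_numpy(dtype=float), cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(len(grid.columns)), grid.columns, rotation=45)
    ax.set_yticks(range(len(grid.index)), grid.index)
    fig.colorbar(im, ax=ax, label="q = ±(1−p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
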