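"""Effect-variant calling from per-cell-type variant effect scores.

Each variant that falls inside a cell type's accessible-chromatin peaks
carries a signed score: the Jensen-Shannon divergence (JSD) between the
predicted chromatin-accessibility profiles of the reference and alternate
alleles, signed by the direction of the predicted accessibility change.
Within each cell type the ranked positive and negative score tails are
thresholded independently at their inflection point (the "elbow" of the
positive tail, the "knee" of the negative tail); variants strictly beyond
either threshold are called effect variants.

The module also provides the companion cohort-level statistics: Fisher
enrichment of rare variants among top-scoring variants, rank-sum comparison
of rare versus common score distributions, and an exact binomial check for
allelic imbalance at a heterozygous site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InflectionUndefinedError",
    "DegenerateScoresError",
    "InsufficientDepthError",
    "ScoreThresholds",
    "detect_inflection",
    "classify_effect_variants",
    "fisher_rare_enrichment",
    "compare_score_distributions",
    "allelic_imbalance_check",
]


class InflectionUndefinedError(ValueError):
    """Fewer than three points in a tail: no inflection point exists."""


class DegenerateScoresError(ValueError):
    """Ranked scores lie on the chord (e.g. all equal or perfectly linear)."""


class InsufficientDepthError(ValueError):
    """Zero total reads at the queried site."""


@dataclass(frozen=True)
class ScoreThresholds:
    """Per-cell-type inflection thresholds on the signed score axis.

    ``pos_elbow``/``neg_knee`` are score values; a tail that could not be
    thresholded (too few points, or degenerate) is recorded as ``nan`` with
    rank ``-1`` and produces no effect calls in that direction.
    """

    cell_type: str
    pos_elbow: float
    neg_knee: float
    pos_elbow_rank: int
    neg_knee_rank: int


def detect_inflection(scores, tail: str = "positive") -> tuple[float, int]:
    """Locate the elbow/knee of a ranked score tail.

    ``scores`` must hold same-sign values sorted by decreasing magnitude.
    Both axes are normalized to [0, 1] (rank by index/(n-1), score by
    min-max), and the returned rank maximizes the perpendicular distance
    from the chord joining the first and last normalized points.  Ties are
    broken toward the larger magnitude (earlier rank), which yields the
    more conservative effect set.

    Returns ``(threshold, rank)`` where ``threshold = scores[rank]``.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise InflectionUndefinedError(
            f"need >=3 {tail} scores to locate an inflection point, got {s.size}"
        )
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    mag = np.abs(s)
    if np.any(np.diff(mag) > 1e-12):
        raise ValueError("scores must be sorted by decreasing magnitude")

    lo, hi = mag[-1], mag[0]
    if hi - lo <= 0.0:
        raise DegenerateScoresError("all scores equal; inflection undefined")
    x = np.arange(s.size) / (s.size - 1)
    y = (mag - lo) / (hi - lo)
    # Chord runs (0,1)->(1,0); perpendicular distance is |x + y - 1| / sqrt(2).
    dist = np.abs(x + y - 1.0)
    if np.max(dist) <= 1e-12:
        raise DegenerateScoresError("ranked scores lie on the chord; no inflection")
    rank = int(np.argmax(dist))  # argmax takes the first (largest-magnitude) tie
    return float(s[rank]), rank


def _threshold_tail(values: np.ndarray, tail: str) -> tuple[float, int]:
    """Threshold one signed tail, mapping degenerate tails to (nan, -1)."""
    if tail == "positive":
        ordered = np.sort(values)[::-1]
    else:
        ordered = np.sort(values)
    try:
        thr, rank = detect_inflection(ordered, tail=tail)
    except (InflectionUndefinedError, DegenerateScoresError):
        return float("nan"), -1
    return thr, rank


def classify_effect_variants(
    table: pd.DataFrame,
) -> tuple[dict[str, ScoreThresholds], pd.DataFrame]:
    """Call effect variants per cell type from a signed score table.

    ``table`` needs columns ``variant_id``, ``cell_type``, ``score``.
    Positive and negative tails are thresholded independently; a variant is
    an effect variant when its score is strictly beyond the tail threshold
    (score > elbow, or score < knee).  All rows are retained in the returned
    call set with ``is_effect`` and ``direction`` columns.
    """
    if table.empty:
        raise ValueError("score table is empty")
    dup = table.duplicated(subset=["variant_id", "cell_type"])
    if dup.any():
        raise ValueError("duplicate (variant, cell type) rows in score table")

    thresholds: dict[str, ScoreThresholds] = {}
    out = table.copy()
    out["direction"] = np.where(out["score"] >= 0, "increase", "decrease")
    out["is_effect"] = False

    for ct, sub in table.groupby("cell_type", sort=True):
        sc = sub["score"].to_numpy(dtype=float)
        pos_thr, pos_rank = _threshold_tail(sc[sc > 0], "positive")
        neg_thr, neg_rank = _threshold_tail(sc[sc < 0], "negative")
        thresholds[str(ct)] = ScoreThresholds(
            cell_type=str(ct),
            pos_elbow=pos_thr,
            neg_knee=neg_thr,
            pos_elbow_rank=pos_rank,
            neg_knee_rank=neg_rank,
        )
        mask = out["cell_type"] == ct
        if np.isfinite(pos_thr):
            out.loc[mask & (out["score"] > pos_thr), "is_effect"] = True
        if np.isfinite(neg_thr):
            out.loc[mask & (out["score"] < neg_thr), "is_effect"] = True
    return thresholds, out


def fisher_rare_enrichment(
    calls: pd.DataFrame,
    maf: pd.Series,
    top_fraction: float = 0.01,
    rare_cutoff: float = 0.01,
) -> tuple[float, tuple[float, float], float]:
    """Fisher enrichment of rare variants among the top |score| fraction.

    Builds the 2x2 table (rare/common) x (top/rest), where "top" is the top
    ``top_fraction`` of |score| within the supplied call set, and returns
    the sample odds ratio, its Woolf-logit 95% CI (with 0.5 continuity
    correction when any cell is zero), and the two-sided Fisher exact p.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    df = calls[["variant_id", "score"]].copy()
    df["maf"] = df["variant_id"].map(maf)
    df = df.dropna(subset=["maf"])
    if df.empty:
        raise ValueError("no variants with allele frequencies")
    cut = np.quantile(np.abs(df["score"]), 1.0 - top_fraction)
    top = np.abs(df["score"].to_numpy()) >= cut
    rare = df["maf"].to_numpy() < rare_cutoff
    a = int(np.sum(rare & top))
    b = int(np.sum(rare & ~top))
    c = int(np.sum(~rare & top))
    d = int(np.sum(~rare & ~top))
    return fisher_exact_2x2(a, b, c, d)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int
) -> tuple[float, tuple[float, float], float]:
    """Two-sided Fisher exact test for a 2x2 table ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, (ci_low, ci_high), p)``.  The odds ratio is the
    sample OR ``a*d / (b*c)``; the CI is Woolf's logit interval, applying a
    0.5 continuity correction to every cell when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("undefined table: an entire margin is zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (a * d) / (b * c) if b * c > 0 else (aa * dd) / (bb * cc)
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (float(np.exp(log_or - 1.959964 * se)), float(np.exp(log_or + 1.959964 * se)))
    return float(or_), ci, float(p)


def compare_score_distributions(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two score samples.

    Uses exact enumeration when ``n*m <= 100`` and there are no ties across
    the pooled sample, otherwise the normal approximation with tie
    correction and continuity correction.  Returns ``(U statistic, p)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= 100 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def allelic_imbalance_check(
    ref_count: int, alt_count: int, expected_alt_fraction: float = 0.5
) -> tuple[float, str]:
    """Exact binomial test for allele-specific read imbalance.

    Compares the observed alternate-allele read fraction at a heterozygous
    site against its expectation; returns the two-sided p-value and the
    direction of the deviation (``'ref'``, ``'alt'`` or ``'balanced'``).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total < 1:
        raise InsufficientDepthError("zero reads covering the site")
    if not 0 < expected_alt_fraction < 1:
        raise ValueError("expected_alt_fraction must be in (0, 1)")
    p = stats.binomtest(alt_count, total, expected_alt_fraction).pvalue
    obs = alt_count / total
    if obs > expected_alt_fraction:
        direction = "alt"
    elif obs < expected_alt_fraction:
        direction = "ref"
    else:
        direction = "balanced"
    return float(p), direction
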