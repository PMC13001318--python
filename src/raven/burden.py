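"""Per-gene effect-variant burden and cell-type specificity statistics.

After effect variants are collapsed to unique (gene, variant, cell type)
triplets, two questions are asked of each gene: does it concentrate its
effect variants in particular cell types more than chance would allow
(specificity, measured by top-share and the tau index against per-gene
permutation nulls), and does it carry more effect variants than expected
given how many peaks map to it (burden, against a variant-to-peak shuffling
null)?

tau = (1/(k-1)) * sum_i (1 - x_i / max_j x_j), where x_i is the number of
unique effect variants of the gene in cell type i and k the number of cell
types evaluated; tau = 1 when all variants sit in a single cell type and 0
when they are spread evenly.  top-share = max_i x_i / sum_i x_i.  Genes are
evaluated only in cell types where their pseudobulk expression reaches
CPM >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpecificityStats",
    "BurdenResult",
    "compute_tau",
    "compute_top_share",
    "specificity_null",
    "specificity_scan",
    "gene_burden_enrichment",
    "expression_gate",
    "summarize_specific_fraction",
]


@dataclass
class SpecificityStats:
    gene_id: str
    x: np.ndarray
    k: int
    top_share: float
    tau: float
    null_cutoff_top_share: float
    null_cutoff_tau: float
    specific: bool


@dataclass
class BurdenResult:
    gene_id: str
    cell_type: str
    observed_count: int
    n_peaks: int
    normalized_burden: float
    empirical_p: float
    fdr: float


def compute_tau(x) -> float:
    """Tau specificity index of a per-cell-type count vector."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires counts over k >= 2 cell types")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined for an all-zero count vector")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def compute_top_share(x) -> float:
    """Largest single-cell-type fraction of a gene's effect variants."""
    x = np.asarray(x, dtype=float)
    s = x.sum()
    if s <= 0:
        raise ValueError("top-share undefined for an all-zero count vector")
    return float(x.max() / s)


def specificity_null(
    total: int,
    k: int,
    n_perm: int = 10_000,
    rng=None,
    percentile: float = 95.0,
) -> tuple[float, float]:
    """Permutation-null 95th-percentile cutoffs for top-share and tau.

    Each permutation scatters the gene's ``total`` effect variants uniformly
    over the ``k`` evaluated cell types (equivalent to shuffling cell-type
    labels while preserving the per-gene variant count) and recomputes both
    statistics; the cutoffs are the requested percentile of the null draws.
    """
    if total < 1:
        raise ValueError("need at least one effect variant")
    if k < 2:
        raise ValueError("need k >= 2 cell types")
    rng = np.random.default_rng(rng)
    assign = rng.integers(0, k, size=(n_perm, total))
    counts = np.zeros((n_perm, k), dtype=np.int32)
    np.add.at(counts, (np.repeat(np.arange(n_perm), total), assign.ravel()), 1)
    m = counts.max(axis=1).astype(float)
    top = m / total
    tau = (k - total / m) / (k - 1)
    return (
        float(np.percentile(top, percentile)),
        float(np.percentile(tau, percentile)),
    )


def specificity_scan(
    triplets: pd.DataFrame,
    cell_types=None,
    n_perm: int = 10_000,
    seed: int = 0,
    cpm: pd.DataFrame | None = None,
) -> list[SpecificityStats]:
    """Per-gene specificity statistics with per-gene permutation cutoffs.

    ``triplets`` holds unique (gene_id, variant_id, cell_type) rows.  When a
    CPM table (gene x cell type) is supplied, each gene is evaluated only in
    cell types where CPM >= 1 (genes absent from the table are skipped).
    A gene is flagged specific when its observed top-share or tau strictly
    exceeds the matching null cutoff.
    """
    if cell_types is None:
        cell_types = sorted(triplets["cell_type"].unique())
    cell_types = list(cell_types)
    rng = np.random.default_rng(seed)
    results: list[SpecificityStats] = []
    for gene, sub in triplets.groupby("gene_id", sort=True):
        evaluated = cell_types
        if cpm is not None:
            if gene not in cpm.index:
                continue
            evaluated = expression_gate(gene, cell_types, cpm)
        if len(evaluated) < 2:
            continue
        counts = (
            sub[sub["cell_type"].isin(evaluated)]
            .groupby("cell_type")["variant_id"]
            .nunique()
        )
        x = np.array([counts.get(ct, 0) for ct in evaluated], dtype=float)
        total = int(x.sum())
        if total == 0:
            continue
        top = compute_top_share(x)
        tau = compute_tau(x)
        cut_top, cut_tau = specificity_null(total, len(evaluated), n_perm, rng)
        results.append(
            SpecificityStats(
                gene_id=str(gene),
                x=x,
                k=len(evaluated),
                top_share=top,
                tau=tau,
                null_cutoff_top_share=cut_top,
                null_cutoff_tau=cut_tau,
                specific=bool(top > cut_top or tau > cut_tau),
            )
        )
    return results


def expression_gate(gene_id, cell_types, cpm: pd.DataFrame, min_cpm: float = 1.0):
    """Cell types in which a gene is expressed at CPM >= ``min_cpm``."""
    row = cpm.loc[gene_id]
    return [ct for ct in cell_types if ct in row.index and row[ct] >= min_cpm]


def gene_burden_enrichment(
    triplets: pd.DataFrame,
    links: pd.DataFrame,
    n_perm: int = 100_000,
    fdr_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Peak-normalized effect-variant burden with a shuffling null.

    ``links`` maps peaks to genes per cell type (columns ``peak_id``,
    ``gene_id``, ``cell_type``); ``triplets`` additionally carries the peak
    each effect variant fell in (``peak_id``).  Within each cell type the
    observed statistic per gene is its number of unique effect variants;
    the null reassigns every effect variant to a peak uniformly at random
    (preserving per-gene peak counts) and recounts.  Empirical p-values use
    the add-one estimator (#{null >= obs} + 1)/(n_perm + 1); BH FDR is
    applied within cell type and rows at ``fdr <= fdr_threshold`` are
    flagged enriched.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for ct, ct_links in links.groupby("cell_type", sort=True):
        ct_links = ct_links.drop_duplicates(subset=["peak_id"])
        peak_gene = ct_links.set_index("peak_id")["gene_id"]
        genes = pd.Index(sorted(peak_gene.unique()))
        gene_idx = pd.Series(np.arange(len(genes)), index=genes)
        peak_gene_codes = gene_idx[peak_gene.to_numpy()].to_numpy()
        n_peaks_per_gene = np.bincount(peak_gene_codes, minlength=len(genes))

        trip = triplets[triplets["cell_type"] == ct]
        trip = trip[trip["gene_id"].isin(genes)]
        n_var = trip["variant_id"].nunique()
        observed = trip.groupby("gene_id")["variant_id"].nunique()
        obs = np.zeros(len(genes), dtype=int)
        obs[gene_idx[observed.index].to_numpy()] = observed.to_numpy()

        # Null: each of the n_var effect variants lands in a random peak of
        # this cell type; count per gene.  Vectorized over permutations.
        n_peaks = len(peak_gene)
        exceed = np.zeros(len(genes), dtype=np.int64)
        chunk = max(1, int(5e6 // max(n_var, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            draws = rng.integers(0, n_peaks, size=(b, n_var))
            gene_hits = peak_gene_codes[draws]  # (b, n_var) of gene codes
            null_counts = np.zeros((b, len(genes)), dtype=np.int32)
            row_ix = np.repeat(np.arange(b), n_var)
            np.add.at(null_counts, (row_ix, gene_hits.ravel()), 1)
            exceed += (null_counts >= obs[None, :]).sum(axis=0)
            done += b
        emp_p = (exceed + 1) / (n_perm + 1)
        fdr = multipletests(emp_p, method="fdr_bh")[1]
        for g, o, npk, p, q in zip(genes, obs, n_peaks_per_gene, emp_p, fdr):
            rows.append(
                {
                    "gene_id": g,
                    "cell_type": ct,
                    "observed_count": int(o),
                    "n_peaks": int(npk),
                    "normalized_burden": float(o / npk) if npk else np.nan,
                    "empirical_p": float(p),
                    "fdr": float(q),
                    "enriched": bool(q <= fdr_threshold),
                }
            )
    return pd.DataFrame(rows)


def summarize_specific_fraction(
    n_specific: int, n_total: int
) -> tuple[float, float, float]:
    """Percentage of specific genes with a normal-approximation 95% CI.

    Returns ``(percent, ci_low, ci_high)`` on the percent scale, with the
    interval clamped to [0, 100].
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_specific <= n_total:
        raise ValueError("n_specific must lie in [0, n_total]")
    p = n_specific / n_total
    half = 1.959964 * np.sqrt(p * (1 - p) / n_total)
    return (
        100 * p,
        float(max(0.0, 100 * (p - half))),
        float(min(100.0, 100 * (p + half))),
    )
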