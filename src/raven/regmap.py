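"""Tiered regulatory-element-to-gene mapping.

Each accessible-chromatin peak is assigned to at most one putative target
gene per cell type through a three-tier hierarchy:

1. **ABC** — the activity-by-contact model.  ABC(E, G) = A_E * C_{E,G} /
   sum_e A_e * C_{e,G} over candidate peaks within a window around the
   gene's TSS, where A is the pseudobulk accessibility signal in the peak
   and C the normalized 3D contact frequency with the gene promoter.
   Links with score >= threshold (default 0.02) qualify; a peak takes its
   highest-scoring ABC gene.
2. **Correlation** — peak-to-gene links from Pearson correlation of peak
   accessibility with gene expression across samples, gated at r >= 0.4
   and BH FDR <= 0.01.  A peak without ABC links takes the gene of the
   correlation-linked peak with greatest physical overlap (intersection
   bp), breaking ties by strongest r.
3. **Proximity** — otherwise the nearest TSS within 25 kb.

Peaks failing all three tiers are left unassigned and their variants are
excluded downstream.  Effect variants inherit the assignment of their
containing peak, collapsed to unique (gene, variant, cell type) triplets.

Coordinates are BED-style 0-based half-open throughout; distances are
measured between variant position / peak midpoint and the TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "abc_scores",
    "compute_abc_links",
    "correlation_links",
    "assign_target_genes",
    "map_variants_to_genes",
]

ABC_WINDOW_BP = 5_000_000
ABC_THRESHOLD = 0.02
CORR_WINDOW_BP = 250_000
PROXIMITY_MAX_BP = 25_000
POWERLAW_OFFSET_BP = 5_000


def abc_scores(activity, contact) -> np.ndarray:
    """Normalized activity-by-contact scores over one gene's candidates."""
    a = np.asarray(activity, dtype=float)
    c = np.asarray(contact, dtype=float)
    if a.shape != c.shape:
        raise ValueError("activity and contact must align")
    if np.any(a < 0) or np.any(c < 0):
        raise ValueError("activity and contact must be non-negative")
    prod = a * c
    total = prod.sum()
    if total <= 0:
        return np.zeros_like(prod)
    return prod / total


def powerlaw_contact(distance_bp) -> np.ndarray:
    """Distance power-law fallback contact, 1 at distance 0.

    contact = offset / (|d| + offset) with a 5-kb offset — the standard
    fallback when no measured contact entry exists for a peak-gene pair.
    """
    d = np.abs(np.asarray(distance_bp, dtype=float))
    return POWERLAW_OFFSET_BP / (d + POWERLAW_OFFSET_BP)


def compute_abc_links(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    contacts: pd.DataFrame | None = None,
    threshold: float = ABC_THRESHOLD,
    window_bp: int = ABC_WINDOW_BP,
    use_powerlaw_fallback: bool = True,
    use_second_activity: bool = False,
) -> pd.DataFrame:
    """ABC links for every (gene, cell type) with a positive candidate.

    ``peaks``: peak_id, chrom, start, end, cell_type, activity (plus,
    optionally, ``activity2`` — e.g. an H3K27ac track; with
    ``use_second_activity`` the effective activity is the geometric mean
    of the two, off by default).
    ``genes``: gene_id, chrom, tss.
    ``contacts``: peak_id, gene_id, contact (optional; missing pairs fall
    back to the distance power law when enabled, else contact 0).

    Candidates for a gene are that cell type's peaks whose midpoint lies
    within ``window_bp`` of the TSS.  Scores are normalized within the
    candidate set; rows with score >= threshold are emitted with
    tier='ABC'.  A gene whose candidate products are all zero simply emits
    no links.
    """
    contact_lut: dict[tuple[str, str], float] = {}
    if contacts is not None and len(contacts):
        contact_lut = {
            (r.peak_id, r.gene_id): float(r.contact)
            for r in contacts.itertuples(index=False)
        }
    out = []
    if use_second_activity and "activity2" not in peaks.columns:
        raise ValueError("use_second_activity requires an 'activity2' column")
    for ct, ct_peaks in peaks.groupby("cell_type", sort=True):
        mid = ((ct_peaks["start"] + ct_peaks["end"]) // 2).to_numpy()
        pk_ids = ct_peaks["peak_id"].to_numpy()
        pk_chrom = ct_peaks["chrom"].to_numpy()
        act = ct_peaks["activity"].to_numpy(dtype=float)
        if use_second_activity:
            act = np.sqrt(act * ct_peaks["activity2"].to_numpy(dtype=float))
        for g in genes.itertuples(index=False):
            near = (pk_chrom == g.chrom) & (np.abs(mid - g.tss) <= window_bp)
            if not near.any():
                continue
            cand_ids = pk_ids[near]
            cand_act = act[near]
            cand_mid = mid[near]
            contact = np.empty(len(cand_ids))
            for i, pid in enumerate(cand_ids):
                key = (pid, g.gene_id)
                if key in contact_lut:
                    contact[i] = contact_lut[key]
                elif use_powerlaw_fallback:
                    contact[i] = powerlaw_contact(cand_mid[i] - g.tss)
                else:
                    contact[i] = 0.0
            score = abc_scores(cand_act, contact)
            keep = score >= threshold
            for pid, s, m in zip(cand_ids[keep], score[keep], cand_mid[keep]):
                out.append(
                    {
                        "peak_id": pid,
                        "gene_id": g.gene_id,
                        "cell_type": ct,
                        "tier": "ABC",
                        "score": float(s),
                        "tss_distance": int(abs(m - g.tss)),
                    }
                )
    return pd.DataFrame(
        out,
        columns=["peak_id", "gene_id", "cell_type", "tier", "score", "tss_distance"],
    )


def correlation_links(
    peak_signal: pd.DataFrame,
    expression: pd.DataFrame,
    peak_coords: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = CORR_WINDOW_BP,
    r_min: float = 0.4,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Correlation-based peak-to-gene links across matched samples.

    ``peak_signal`` (peaks x samples) and ``expression`` (genes x samples)
    must share sample columns (>= 3).  Pearson r is computed for every
    peak-gene pair whose TSS lies within ``window_bp`` of the peak
    midpoint; p-values come from the t distribution on n-2 df and are BH
    adjusted across all tested pairs.  Pairs with r >= r_min (signed) and
    FDR <= fdr_max are emitted with tier='correlation'.  Zero-variance
    vectors are skipped.
    """
    samples = peak_signal.columns.intersection(expression.columns)
    n = len(samples)
    if n < 3:
        raise ValueError(f"need >= 3 shared samples, got {n}")
    ps = peak_signal[samples]
    ex = expression[samples]
    coords = peak_coords.set_index("peak_id")
    gene_pos = genes.set_index("gene_id")

    tested = []
    for pid in ps.index:
        if pid not in coords.index:
            continue
        pk = coords.loc[pid]
        mid = (pk["start"] + pk["end"]) // 2
        x = ps.loc[pid].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        for gid in ex.index:
            if gid not in gene_pos.index:
                continue
            gn = gene_pos.loc[gid]
            if gn["chrom"] != pk["chrom"] or abs(gn["tss"] - mid) > window_bp:
                continue
            y = ex.loc[gid].to_numpy(dtype=float)
            if np.std(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            t = r * np.sqrt((n - 2) / max(1e-300, 1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
            tested.append((pid, gid, r, p))
    if not tested:
        return pd.DataFrame(
            columns=["peak_id", "gene_id", "tier", "score", "fdr"]
        )
    df = pd.DataFrame(tested, columns=["peak_id", "gene_id", "score", "p"])
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[(df["score"] >= r_min) & (df["fdr"] <= fdr_max)].copy()
    df["tier"] = "correlation"
    return df[["peak_id", "gene_id", "tier", "score", "fdr"]].reset_index(drop=True)


def _overlap_bp(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_target_genes(
    peaks: pd.DataFrame,
    abc_links: pd.DataFrame,
    corr_links: pd.DataFrame,
    corr_peak_coords: pd.DataFrame,
    genes: pd.DataFrame,
    max_tss_bp: int = PROXIMITY_MAX_BP,
) -> pd.DataFrame:
    """One target gene (or none) per (peak, cell type), by tier hierarchy.

    Returns rows (peak_id, cell_type, gene_id, tier, score); unassignable
    peaks carry gene_id = NA and tier = 'none'.  ABC ties on score break to
    the nearest TSS; correlation-tier candidates are the peaks of the
    correlation link set that physically overlap the query peak, ranked by
    overlap bp then by r.
    """
    gene_pos = genes.set_index("gene_id")
    corr = corr_links.merge(
        corr_peak_coords[["peak_id", "chrom", "start", "end"]], on="peak_id"
    ) if len(corr_links) else pd.DataFrame(
        columns=["peak_id", "gene_id", "score", "chrom", "start", "end"]
    )
    abc_by_peak = (
        dict(tuple(abc_links.groupby(["peak_id", "cell_type"])))
        if len(abc_links)
        else {}
    )

    rows = []
    for pk in peaks.itertuples(index=False):
        assigned = None
        # Tier 1: ABC
        key = (pk.peak_id, pk.cell_type)
        if key in abc_by_peak:
            cand = abc_by_peak[key].sort_values(
                ["score", "tss_distance"], ascending=[False, True]
            )
            best = cand.iloc[0]
            assigned = (best["gene_id"], "ABC", float(best["score"]))
        # Tier 2: overlap with correlation-linked peaks
        if assigned is None and len(corr):
            same = corr[corr["chrom"] == pk.chrom].copy()
            if len(same):
                same["overlap"] = [
                    _overlap_bp(pk.start, pk.end, s, e)
                    for s, e in zip(same["start"], same["end"])
                ]
                same = same[same["overlap"] > 0]
                if len(same):
                    best = same.sort_values(
                        ["overlap", "score"], ascending=[False, False]
                    ).iloc[0]
                    assigned = (best["gene_id"], "correlation", float(best["score"]))
        # Tier 3: nearest TSS within the gate
        if assigned is None:
            mid = (pk.start + pk.end) // 2
            same_chrom = gene_pos[gene_pos["chrom"] == pk.chrom]
            if len(same_chrom):
                d = (same_chrom["tss"] - mid).abs()
                gid = d.idxmin()
                if d.loc[gid] <= max_tss_bp:
                    assigned = (gid, "proximity", float(d.loc[gid]))
        if assigned is None:
            rows.append(
                {
                    "peak_id": pk.peak_id,
                    "cell_type": pk.cell_type,
                    "gene_id": pd.NA,
                    "tier": "none",
                    "score": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "peak_id": pk.peak_id,
                    "cell_type": pk.cell_type,
                    "gene_id": assigned[0],
                    "tier": assigned[1],
                    "score": assigned[2],
                }
            )
    return pd.DataFrame(rows)


def map_variants_to_genes(
    calls: pd.DataFrame,
    variants: pd.DataFrame,
    peaks: pd.DataFrame,
    assignments: pd.DataFrame,
    effect_only: bool = True,
    collapse: bool = True,
) -> pd.DataFrame:
    """Collapse effect variants to unique (gene, variant, cell type) triplets.

    Each effect call inherits the gene assignment of every peak (of its
    scored cell type) containing the variant; rows through peaks that map
    to the same gene collapse to one triplet (``collapse=False`` keeps the
    per-peak rows, as peak-level testing units need them).  Variants whose
    containing peaks are all unassigned are excluded.  A scored variant
    lying in no peak of its cell type violates the scoring contract and
    raises.
    """
    pos = variants.set_index("variant_id")[["chrom", "pos"]]
    assign = assignments.dropna(subset=["gene_id"]).set_index(
        ["peak_id", "cell_type"]
    )["gene_id"]
    use = calls[calls["is_effect"]] if effect_only else calls
    triplets = []
    peaks_by_ct = dict(tuple(peaks.groupby("cell_type")))
    for row in use.itertuples(index=False):
        if row.variant_id not in pos.index:
            raise KeyError(f"variant {row.variant_id} missing from catalog")
        chrom, p = pos.loc[row.variant_id]
        ct_peaks = peaks_by_ct.get(row.cell_type)
        hit = (
            ct_peaks[
                (ct_peaks["chrom"] == chrom)
                & (ct_peaks["start"] <= p)
                & (p < ct_peaks["end"])
            ]
            if ct_peaks is not None
            else None
        )
        if hit is None or hit.empty:
            raise ValueError(
                f"scored variant {row.variant_id} lies in no "
                f"{row.cell_type} peak; scores only exist within peaks"
            )
        for pid in hit["peak_id"]:
            key = (pid, row.cell_type)
            if key in assign.index:
                triplets.append(
                    {
                        "gene_id": assign.loc[key],
                        "variant_id": row.variant_id,
                        "cell_type": row.cell_type,
                        "peak_id": pid,
                        "score": row.score,
                    }
                )
    if not triplets:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "cell_type", "peak_id", "score"]
        )
    df = pd.DataFrame(triplets)
    if collapse:
        df = df.sort_values("peak_id").drop_duplicates(
            subset=["gene_id", "variant_id", "cell_type"]
        )
    return df.reset_index(drop=True)
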