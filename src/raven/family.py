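"""Noncoding variant prioritization in multiplex pedigrees.

Workflow for families with several affected members: per-genotype quality
control (GQ >= 20, DP >= 10, heterozygous allele balance in [0.2, 0.8],
then variant call rate >= 0.95), segregation filtering under dominant or
recessive inheritance with population-frequency gates (dominant: maximum
population AF <= 0.01; recessive: reference homozygote count <= 1),
intersection of the segregating variants with per-cell-type accessibility
peaks, and ranking by the magnitude of the ML effect score among variants
beyond the cell type's effect-calling thresholds.

Genotypes are dosages 0/1/2 with -1 for missing.  Missing genotypes after
QC neither satisfy nor violate carrier requirements unless ``strict`` is
set, which additionally demands a non-missing genotype in every affected.
Non-autosomal variants are passed through with a warning (X-linked
inheritance is not modeled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "apply_genotype_qc",
    "segregate_dominant",
    "segregate_recessive",
    "prioritize_candidates",
]

MISSING = -1


@dataclass(frozen=True)
class QCThresholds:
    min_gq: int = 20
    min_dp: int = 10
    het_ab_low: float = 0.2
    het_ab_high: float = 0.8
    min_call_rate: float = 0.95

    def __post_init__(self):
        if not (0 <= self.het_ab_low < self.het_ab_high <= 1):
            raise ValueError("het AB bounds must satisfy 0 <= low < high <= 1")


def apply_genotype_qc(
    genotypes: pd.DataFrame,
    gq: pd.DataFrame,
    dp: pd.DataFrame,
    ad_alt: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> pd.DataFrame:
    """Mask low-quality genotypes and drop low-call-rate variants.

    All tables are variants x samples.  A genotype becomes missing when
    GQ < min_gq, DP < min_dp, or — for heterozygotes — the alternate
    allele fraction (AD_alt / DP) falls outside [low, high]; bounds are
    inclusive.  Variants whose post-masking call rate drops below
    ``min_call_rate`` (inclusive retain) are removed entirely.
    """
    gt = genotypes.to_numpy(dtype=float).copy()
    gq_a = gq.reindex_like(genotypes).to_numpy(dtype=float)
    dp_a = dp.reindex_like(genotypes).to_numpy(dtype=float)
    ad_a = ad_alt.reindex_like(genotypes).to_numpy(dtype=float)

    bad = np.isnan(gq_a) | np.isnan(dp_a)
    if bad.any():
        warnings.warn("missing FORMAT fields; affected genotypes set missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        mask = bad | (gq_a < thresholds.min_gq) | (dp_a < thresholds.min_dp)
        het = gt == 1
        ab = np.where(dp_a > 0, ad_a / dp_a, np.nan)
        mask |= het & (
            np.isnan(ab)
            | (ab < thresholds.het_ab_low)
            | (ab > thresholds.het_ab_high)
        )
    gt[mask] = MISSING
    out = pd.DataFrame(gt, index=genotypes.index, columns=genotypes.columns).astype(
        int
    )
    call_rate = (out.to_numpy() != MISSING).mean(axis=1)
    return out[call_rate >= thresholds.min_call_rate]


def _check_autosomal(variant_ids) -> None:
    flagged = [v for v in variant_ids if str(v).split(":")[0] in ("chrX", "chrY", "X", "Y")]
    if flagged:
        warnings.warn(
            f"{len(flagged)} non-autosomal variants pass through unmodeled"
        )


def segregate_dominant(
    pedigree: pd.DataFrame,
    genotypes: pd.DataFrame,
    max_pop_af: pd.Series,
    max_af: float = 0.01,
    strict: bool = False,
) -> list[str]:
    """Variants consistent with dominant transmission in the family.

    Retained iff every genotyped affected member carries at least one
    alternate allele, no genotyped unaffected member carries any, and the
    maximum population allele frequency is <= ``max_af``.  Missing
    genotypes do not disqualify a variant unless ``strict`` is set.
    """
    ped = pedigree.set_index("id") if "id" in pedigree.columns else pedigree
    members = [m for m in ped.index if m in genotypes.columns]
    affected = [m for m in members if ped.loc[m, "affected"] and ped.loc[m, "genotyped"]]
    unaffected = [
        m for m in members if not ped.loc[m, "affected"] and ped.loc[m, "genotyped"]
    ]
    if not affected:
        raise ValueError("no genotyped affected individuals in pedigree")
    _check_autosomal(genotypes.index)

    out = []
    aff = genotypes[affected].to_numpy()
    una = genotypes[unaffected].to_numpy() if unaffected else None
    for i, vid in enumerate(genotypes.index):
        ga = aff[i]
        if strict and np.any(ga == MISSING):
            continue
        known = ga != MISSING
        if not np.all(ga[known] >= 1) or not known.any():
            continue
        if una is not None:
            gu = una[i]
            if np.any(gu[gu != MISSING] >= 1):
                continue
        af = max_pop_af.get(vid, np.nan)
        if np.isnan(af) or af > max_af:
            continue
        out.append(vid)
    return out


def _transmitting_parent(
    child_gt: int, father_gt: int, mother_gt: int
) -> str | None:
    """Which parent transmitted the (single) alternate allele of a het child.

    Returns 'father'/'mother' when unambiguous, None when phase is unknown
    (both parents carry it, or a parent genotype is missing).
    """
    f_car = father_gt >= 1
    m_car = mother_gt >= 1
    if father_gt == MISSING or mother_gt == MISSING:
        return None
    if f_car and not m_car:
        return "father"
    if m_car and not f_car:
        return "mother"
    return None


def segregate_recessive(
    pedigree: pd.DataFrame,
    genotypes: pd.DataFrame,
    hom_counts: pd.Series,
    max_hom: int = 1,
    gene_map: pd.Series | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Variants consistent with recessive inheritance.

    Two branches: *homozygous* — all genotyped affected are hom-alt, no
    genotyped unaffected is, and the reference-population homozygote count
    is <= ``max_hom``; *compound heterozygous* — two distinct variants in
    one gene (``gene_map``: variant -> gene, required for this branch),
    each heterozygous in all genotyped affected, with parental genotypes
    (when available) excluding a cis configuration (both alternate alleles
    from the same parent).  Returns rows (variant_id, mode, phase).
    """
    ped = pedigree.set_index("id") if "id" in pedigree.columns else pedigree
    members = [m for m in ped.index if m in genotypes.columns]
    affected = [m for m in members if ped.loc[m, "affected"] and ped.loc[m, "genotyped"]]
    unaffected = [
        m for m in members if not ped.loc[m, "affected"] and ped.loc[m, "genotyped"]
    ]
    if not affected:
        raise ValueError("no genotyped affected individuals in pedigree")

    rows = []
    aff = genotypes[affected]
    una = genotypes[unaffected] if unaffected else None
    # Homozygous branch
    for vid in genotypes.index:
        ga = aff.loc[vid].to_numpy()
        known = ga != MISSING
        if strict and not known.all():
            continue
        if not known.any() or not np.all(ga[known] == 2):
            continue
        if una is not None:
            gu = una.loc[vid].to_numpy()
            if np.any(gu[gu != MISSING] == 2):
                continue
        if hom_counts.get(vid, np.inf) > max_hom:
            continue
        rows.append({"variant_id": vid, "mode": "recessive_hom", "phase": "n/a"})

    # Compound-het branch
    het_in_all = []
    for vid in genotypes.index:
        ga = aff.loc[vid].to_numpy()
        known = ga != MISSING
        if known.any() and np.all(ga[known] == 1) and (not strict or known.all()):
            het_in_all.append(vid)
    if len(het_in_all) >= 2:
        if gene_map is None:
            raise ValueError("compound-het analysis requires a variant->gene map")
        by_gene: dict[str, list[str]] = {}
        for vid in het_in_all:
            g = gene_map.get(vid)
            if g is not None and not pd.isna(g):
                by_gene.setdefault(g, []).append(vid)
        for gene, vids in by_gene.items():
            if len(vids) < 2:
                continue
            for i in range(len(vids)):
                for j in range(i + 1, len(vids)):
                    v1, v2 = vids[i], vids[j]
                    phase = _pair_phase(ped, genotypes, affected, v1, v2)
                    if phase == "cis":
                        continue
                    for v in (v1, v2):
                        rows.append(
                            {
                                "variant_id": v,
                                "mode": "recessive_comphet",
                                "phase": phase,
                                "gene_id": gene,
                                "partner": v2 if v == v1 else v1,
                            }
                        )
    return pd.DataFrame(rows, columns=["variant_id", "mode", "phase", "gene_id", "partner"])


def _pair_phase(ped, genotypes, affected, v1, v2) -> str:
    """Phase of a candidate compound-het pair across the affected set.

    'trans' when some affected shows the two variants transmitted by
    different parents, 'cis' when every phasable affected received both
    from the same parent, 'unknown' otherwise.
    """
    verdicts = []
    for child in affected:
        fa, mo = ped.loc[child, "father_id"], ped.loc[child, "mother_id"]
        if fa not in genotypes.columns or mo not in genotypes.columns:
            continue
        p1 = _transmitting_parent(
            genotypes.loc[v1, child], genotypes.loc[v1, fa], genotypes.loc[v1, mo]
        )
        p2 = _transmitting_parent(
            genotypes.loc[v2, child], genotypes.loc[v2, fa], genotypes.loc[v2, mo]
        )
        if p1 is None or p2 is None:
            continue
        verdicts.append("trans" if p1 != p2 else "cis")
    if not verdicts:
        return "unknown"
    if "trans" in verdicts:
        return "trans"
    return "cis"


def prioritize_candidates(
    segregating: list[str],
    variants: pd.DataFrame,
    peaks: pd.DataFrame,
    thresholds: dict,
    scores: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    mode: str = "dominant",
) -> pd.DataFrame:
    """Rank segregating variants by ML effect score within peaks.

    ``variants`` gives chrom/pos per variant; ``peaks`` the per-cell-type
    peak set; ``thresholds`` maps cell type -> ScoreThresholds from effect
    calling; ``scores`` is the (variant_id, cell_type, score) table.  A
    variant qualifies in a cell type when it lies in one of that cell
    type's peaks and its score is strictly beyond the cell type's
    elbow/knee.  One row per (variant, cell type), ranked by descending
    |score|; the containing peak and (optionally) the peak's target gene
    are annotated.
    """
    pos = variants.set_index("variant_id")[["chrom", "pos"]]
    score_lut = scores.set_index(["variant_id", "cell_type"])["score"]
    assign_lut = (
        assignments.dropna(subset=["gene_id"]).set_index(["peak_id", "cell_type"])[
            "gene_id"
        ]
        if assignments is not None
        else None
    )
    rows = []
    for vid in segregating:
        if vid not in pos.index:
            continue
        chrom, p = pos.loc[vid]
        inside = peaks[
            (peaks["chrom"] == chrom) & (peaks["start"] <= p) & (p < peaks["end"])
        ]
        for pk in inside.itertuples(index=False):
            key = (vid, pk.cell_type)
            if key not in score_lut.index:
                continue
            s = float(score_lut.loc[key])
            thr = thresholds.get(pk.cell_type)
            if thr is None:
                continue
            beyond = (np.isfinite(thr.pos_elbow) and s > thr.pos_elbow) or (
                np.isfinite(thr.neg_knee) and s < thr.neg_knee
            )
            if not beyond:
                continue
            gene = (
                assign_lut.get((pk.peak_id, pk.cell_type))
                if assign_lut is not None
                else None
            )
            rows.append(
                {
                    "variant_id": vid,
                    "mode": mode,
                    "cell_type": pk.cell_type,
                    "score": s,
                    "peak_id": pk.peak_id,
                    "gene_id": gene,
                }
            )
    out = pd.DataFrame(
        rows, columns=["variant_id", "mode", "cell_type", "score", "peak_id", "gene_id"]
    ).drop_duplicates(subset=["variant_id", "cell_type"])
    out = out.sort_values("score", key=lambda s: -s.abs()).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
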