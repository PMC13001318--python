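"""Synthetic cohort generator with planted ground truth.

Every input the pipeline consumes can be generated here with known truth:
a toy genome scaffold (one chromosome, genes, per-cell-type accessibility
peaks), a rare-variant catalog with Hardy-Weinberg genotypes, per-cell-type
signed effect scores with a near-zero bulk and a heavy outlier tail,
case/control phenotypes from a logistic risk model over carriers of effect
variants in designated "spiked" genes, negative-binomial pseudobulk counts
with planted differentially expressed and stage-monotonic genes, and a
multiplex pedigree carrying one planted segregating causal variant.

The generative choices are deliberate stand-ins — no public generative
model exists for the cohorts this emulates — and are documented in the
methods note.  Defaults: allele frequencies from a mixture concentrated
below 0.01 (90% rare), score magnitudes from an exponential bulk
(scale 0.01) plus a shifted exponential tail (0.15 + Exp(0.05)), one 10-Mb
chromosome.  Every generator is a pure function of its configuration and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GenomeScaffold",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_scaffold",
    "generate_variants_and_genotypes",
    "generate_effect_scores",
    "generate_case_control",
    "generate_pseudobulk",
    "generate_pedigree",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    n_cases: int = 500
    n_controls: int = 500
    n_variants: int = 4000
    n_genes: int = 60
    n_peaks: int = 240
    n_cell_types: int = 4
    chrom_name: str = "chr1"
    chrom_length: int = 10_000_000
    peak_width: int = 500
    orphan_peaks: float = 0.1
    # AF mixture: P(rare) plus Beta shapes for each component; rare
    # frequencies are scaled into (0, 0.01], common into (0.01, 0.5].
    maf_rare_prop: float = 0.9
    rare_beta: tuple[float, float] = (0.8, 3.0)
    common_beta: tuple[float, float] = (1.2, 3.0)
    # Signed score mixture.
    score_tail_fraction: float = 0.05
    bulk_scale: float = 0.01
    tail_loc: float = 0.15
    tail_scale: float = 0.05
    # Phenotype model.
    n_spiked_genes: int = 1
    spiked_beta: float = 2.0
    gamma_sex: float = 0.25
    gamma_pc: float = 0.1
    case_fraction: float = 0.5
    # Pseudobulk.
    n_pb_cases: int = 30
    n_pb_controls: int = 30
    n_pb_genes: int = 300
    n_de_genes: int = 20
    de_logfc: float = 1.0
    n_stage_genes: int = 10
    stage_step: float = 0.5
    pb_dispersion: float = 0.15
    pb_lib_size: float = 2e5
    stage_labels: tuple[str, ...] = ("I", "IIa", "III", "IV")
    # Pedigree.
    n_affected: int = 3
    n_unaffected_sibs: int = 1
    genotype_corruption: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_cases", "n_controls", "n_variants", "n_genes", "n_peaks",
            "n_cell_types", "chrom_length", "peak_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("maf_rare_prop", "score_tail_fraction", "orphan_peaks",
                     "case_fraction", "genotype_corruption"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ValueError("stage labels must be unique")
        if self.n_affected < 3:
            raise ValueError("pedigree requires >= 3 affected individuals")

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass
class GenomeScaffold:
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    peaks: pd.DataFrame  # peak_id, chrom, start, end, cell_type, activity
    cell_types: list[str]


@dataclass
class SyntheticTruth:
    effect_variants: dict[str, list[str]] = field(default_factory=dict)
    spiked_risk_genes: dict[str, float] = field(default_factory=dict)
    spiked_gene_variants: dict[str, list[str]] = field(default_factory=dict)
    planted_de_genes: dict[str, float] = field(default_factory=dict)
    stage_trajectory_genes: dict[str, float] = field(default_factory=dict)
    pedigree_causal_variant: str | None = None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    scaffold: GenomeScaffold
    variants: pd.DataFrame
    genotypes: pd.DataFrame
    scores: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SyntheticTruth


def _rng(config: CohortConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def generate_scaffold(config: CohortConfig) -> GenomeScaffold:
    """Toy genome: one chromosome, genes, per-cell-type peaks.

    A gene-free desert occupies the last 15% of the chromosome so that a
    configurable fraction of peaks has no TSS within 25 kb (exercising the
    proximity fallback's drop rule); the remaining peaks are placed within
    20 kb of a random gene's TSS.
    """
    rng = _rng(config, 1)
    L = config.chrom_length
    desert_start = int(L * 0.85)
    cell_types = [f"ct{i+1}" for i in range(config.n_cell_types)]

    tss = np.sort(
        rng.integers(30_000, desert_start - 30_000, size=config.n_genes)
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i+1:04d}" for i in range(config.n_genes)],
            "chrom": config.chrom_name,
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=config.n_genes),
        }
    )

    n_orphan = int(round(config.orphan_peaks * config.n_peaks))
    n_near = config.n_peaks - n_orphan
    anchor = rng.choice(tss, size=n_near)
    near_start = anchor + rng.integers(-20_000, 20_000 - config.peak_width, n_near)
    orphan_start = rng.integers(
        desert_start + 26_000, L - config.peak_width - 1, size=n_orphan
    )
    start = np.concatenate([near_start, orphan_start])
    start = np.clip(start, 0, L - config.peak_width - 1)
    peaks = pd.DataFrame(
        {
            "peak_id": [f"P{i+1:05d}" for i in range(config.n_peaks)],
            "chrom": config.chrom_name,
            "start": start,
            "end": start + config.peak_width,
            "cell_type": rng.choice(cell_types, size=config.n_peaks),
            "activity": np.round(rng.lognormal(1.0, 0.6, size=config.n_peaks), 4),
        }
    ).sort_values("start", ignore_index=True)
    return GenomeScaffold(
        chrom_names=[config.chrom_name],
        chrom_lengths={config.chrom_name: L},
        genes=genes,
        peaks=peaks,
        cell_types=cell_types,
    )


def generate_variants_and_genotypes(
    config: CohortConfig, scaffold: GenomeScaffold
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant catalog with reference AFs and Hardy-Weinberg genotypes.

    Two thirds of variants are placed inside random peaks (so they can be
    scored), the rest uniformly; allele frequencies come from the rare /
    common Beta mixture, and genotype dosages are Binomial(2, AF) per
    sample.  The ``af`` column plays the role of the reference-population
    (gnomAD-style) frequency lookup.
    """
    rng = _rng(config, 2)
    n = config.n_variants
    n_in_peak = int(n * 2 / 3)
    pk = scaffold.peaks.sample(
        n=n_in_peak, replace=True, random_state=int(rng.integers(2**31))
    )
    pos_in = pk["start"].to_numpy() + rng.integers(
        0, config.peak_width, size=n_in_peak
    )
    pos_out = rng.integers(0, config.chrom_length, size=n - n_in_peak)
    pos = np.concatenate([pos_in, pos_out])

    rare = rng.random(n) < config.maf_rare_prop
    a_r, b_r = config.rare_beta
    a_c, b_c = config.common_beta
    af = np.where(
        rare,
        rng.beta(a_r, b_r, size=n) * 0.0099 + 0.0001,
        0.01 + rng.beta(a_c, b_c, size=n) * 0.49,
    )
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    af = af[order]
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n)
    alt = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
    )
    variants = pd.DataFrame(
        {
            "variant_id": [
                f"{config.chrom_name}:{p}:{r}:{a}" for p, r, a in zip(pos, ref, alt)
            ],
            "chrom": config.chrom_name,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "af": af,
        }
    ).drop_duplicates(subset="variant_id", ignore_index=True)

    n_samples = config.n_cases + config.n_controls
    dosage = rng.binomial(
        2, variants["af"].to_numpy()[None, :], size=(n_samples, len(variants))
    ).astype(np.int8)
    genotypes = pd.DataFrame(
        dosage,
        index=[f"S{i+1:05d}" for i in range(n_samples)],
        columns=variants["variant_id"],
    )
    return variants, genotypes


def generate_effect_scores(
    config: CohortConfig,
    scaffold: GenomeScaffold,
    variants: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Signed per-cell-type scores for variants inside that cell type's peaks.

    Magnitudes mix a near-zero exponential bulk with a shifted-exponential
    outlier tail (probability ``score_tail_fraction`` per scored variant);
    the sign encodes the direction of the predicted accessibility change
    and is drawn symmetrically.  Tail memberships are recorded in truth.
    """
    rng = _rng(config, 3)
    truth = truth or SyntheticTruth()
    rows = []
    pos = variants.set_index("variant_id")["pos"]
    for ct in scaffold.cell_types:
        ct_peaks = scaffold.peaks[scaffold.peaks["cell_type"] == ct]
        starts = ct_peaks["start"].to_numpy()
        ends = ct_peaks["end"].to_numpy()
        p = pos.to_numpy()
        inside = (p[:, None] >= starts[None, :]) & (p[:, None] < ends[None, :])
        scored = pos.index[inside.any(axis=1)]
        m = len(scored)
        if m == 0:
            truth.effect_variants[ct] = []
            continue
        is_tail = rng.random(m) < config.score_tail_fraction
        if config.score_tail_fraction > 0 and not is_tail.any():
            # Guarantee >= 1 planted outlier per scored cell type so the
            # truth always closes, even for very small catalogs.
            is_tail[rng.integers(0, m)] = True
        mag = np.where(
            is_tail,
            config.tail_loc + rng.exponential(config.tail_scale, size=m),
            rng.exponential(config.bulk_scale, size=m),
        )
        sign = rng.choice([-1.0, 1.0], size=m)
        truth.effect_variants[ct] = list(scored[is_tail])
        rows.append(
            pd.DataFrame(
                {
                    "variant_id": scored,
                    "cell_type": ct,
                    "score": sign * mag,
                }
            )
        )
    scores = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["variant_id", "cell_type", "score"])
    )
    return scores, truth


def _tail_variant_gene_map(
    scaffold: GenomeScaffold,
    variants: pd.DataFrame,
    truth: SyntheticTruth,
    max_af: float = 0.01,
) -> dict[str, list[str]]:
    """Gene -> rare tail variants, through the default regulatory map.

    Risk is carried by *rare* effect variants only (the premise of the
    framework).  Gene assignment uses the same deterministic ABC +
    power-law-contact hierarchy the analysis applies, so planted truth and
    pipeline reconstruction agree on which gene a risk variant belongs to.
    """
    from . import regmap

    vi = variants.set_index("variant_id")
    rows = []
    for ct, vids in truth.effect_variants.items():
        for v in vids:
            if float(vi.loc[v, "af"]) < max_af:
                rows.append({"variant_id": v, "cell_type": ct, "score": 1.0,
                             "is_effect": True})
    if not rows:
        return {}
    calls = pd.DataFrame(rows)
    abc = regmap.compute_abc_links(scaffold.peaks, scaffold.genes, None)
    empty_corr = pd.DataFrame(columns=["peak_id", "gene_id", "tier", "score", "fdr"])
    assignment = regmap.assign_target_genes(
        scaffold.peaks, abc, empty_corr, scaffold.peaks, scaffold.genes
    )
    triplets = regmap.map_variants_to_genes(
        calls, variants, scaffold.peaks, assignment
    )
    out: dict[str, list[str]] = {}
    for gene, sub in triplets.groupby("gene_id"):
        out[str(gene)] = sorted(sub["variant_id"].unique())
    return out


def generate_case_control(
    config: CohortConfig,
    scaffold: GenomeScaffold,
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Phenotypes from a logistic model over spiked-gene carrier status.

    logit P(case) = b0 + sum_g beta_g carrier_g + gamma_sex sex +
    sum_k gamma_k PC_k, with b0 tuned by bisection so the mean case
    probability matches ``case_fraction``.  Spiked genes are chosen (if
    not preset in truth) among genes with the most tail variants within
    25 kb; a spiked gene without mapped effect variants is a
    configuration error.
    """
    rng = _rng(config, 4)
    samples = genotypes.index
    n = len(samples)

    gene_map = _tail_variant_gene_map(scaffold, variants, truth)
    if not truth.spiked_risk_genes:
        ranked = sorted(gene_map, key=lambda g: -len(gene_map[g]))
        for g in ranked[: config.n_spiked_genes]:
            truth.spiked_risk_genes[g] = config.spiked_beta
    truth.spiked_gene_variants = {
        g: gene_map.get(g, []) for g in truth.spiked_risk_genes
    }
    for g, vids in truth.spiked_gene_variants.items():
        if not vids:
            raise ValueError(f"spiked gene {g} has no mapped effect variants")

    sex = rng.integers(0, 2, size=n)
    pcs = rng.normal(size=(n, 5))
    risk = np.zeros(n)
    for g, beta in truth.spiked_risk_genes.items():
        carrier = (genotypes[truth.spiked_gene_variants[g]].to_numpy() > 0).any(
            axis=1
        )
        risk += beta * carrier
    lin = risk + config.gamma_sex * sex + config.gamma_pc * pcs.sum(axis=1)

    lo, hi = -20.0, 20.0
    for _ in range(60):
        b0 = (lo + hi) / 2
        if np.mean(1 / (1 + np.exp(-(b0 + lin)))) < config.case_fraction:
            lo = b0
        else:
            hi = b0
    prob = 1 / (1 + np.exp(-(b0 + lin)))
    pheno = rng.binomial(1, prob)
    table = pd.DataFrame(
        {
            "sample_id": samples,
            "phenotype": pheno,
            "sex": sex,
            **{f"PC{k+1}": pcs[:, k] for k in range(5)},
            "age": np.round(rng.normal(65, 8, size=n), 1),
        }
    ).set_index("sample_id")
    return table, truth


def generate_pseudobulk(
    config: CohortConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """NB pseudobulk counts with planted DE and stage-trajectory genes.

    counts_gs ~ NB(mean = lib_s * softmax-ish relative expression *
    exp(disease*logFC + stage_slope*(stage-1)), dispersion phi).  Disease
    samples receive a Lewy stage uniformly over the configured labels;
    controls sit at the first stage.  Returns (counts, sample metadata,
    truth).
    """
    rng = _rng(config, 5)
    n_s = config.n_pb_cases + config.n_pb_controls
    sample_ids = [f"PB{i+1:03d}" for i in range(n_s)]
    disease = np.array([1] * config.n_pb_cases + [0] * config.n_pb_controls)
    stages = np.where(
        disease == 1,
        rng.choice(config.stage_labels, size=n_s),
        config.stage_labels[0],
    )
    stage_num = pd.Series(stages).map(
        {s: i + 1 for i, s in enumerate(config.stage_labels)}
    ).to_numpy(dtype=float)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "disease": np.where(disease == 1, "PD", "control"),
            "sex": rng.integers(0, 2, size=n_s),
            "age": np.round(rng.normal(70, 7, size=n_s), 1),
            "pmi": np.round(rng.gamma(6, 1.5, size=n_s), 1),
            "stage": stages,
        }
    ).set_index("sample_id")

    g = config.n_pb_genes
    gene_ids = [f"PBG{i+1:04d}" for i in range(g)]
    base = rng.lognormal(1.5, 1.0, size=g)
    rel = base / base.sum()
    logfc = np.zeros(g)
    de_idx = rng.choice(g, size=config.n_de_genes, replace=False)
    sgn = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    logfc[de_idx] = sgn * config.de_logfc
    remaining = np.setdiff1d(np.arange(g), de_idx)
    stage_idx = rng.choice(remaining, size=config.n_stage_genes, replace=False)
    slope = np.zeros(g)
    slope[stage_idx] = rng.choice([-1.0, 1.0], size=config.n_stage_genes) * (
        config.stage_step
    )
    truth.planted_de_genes = {
        gene_ids[i]: float(logfc[i] / np.log(2)) for i in de_idx
    }
    truth.stage_trajectory_genes = {
        gene_ids[i]: float(slope[i]) for i in stage_idx
    }

    lib = rng.lognormal(np.log(config.pb_lib_size), 0.25, size=n_s)
    eta = (
        np.log(rel)[:, None]
        + logfc[:, None] * disease[None, :]
        + slope[:, None] * (stage_num[None, :] - 1.0)
    )
    mean = lib[None, :] * np.exp(eta)
    r = 1.0 / config.pb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    return (
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        meta,
        truth,
    )


def generate_pedigree(
    config: CohortConfig,
    variants: pd.DataFrame,
    truth: SyntheticTruth,
    scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], SyntheticTruth]:
    """Nuclear pedigree with a planted dominant causal variant.

    Two ungenotyped-by-default founders (here genotyped, carrying the
    causal variant heterozygously in the father), ``n_affected`` affected
    children forced to inherit the causal allele, and unaffected siblings
    forced not to.  Other variants gene-drop independently from founder
    genotypes (no linkage, matching the generator's no-LD scope).
    Per-genotype GQ/DP/AD fields are emitted, with a configurable fraction
    corrupted below the QC thresholds.

    Returns (pedigree table, {'genotypes','gq','dp','ad_alt'} tables, truth).
    """
    rng = _rng(config, 6)
    causal = truth.pedigree_causal_variant
    if causal is None:
        tail = sorted(set().union(*truth.effect_variants.values()))
        in_tail = variants[variants["variant_id"].isin(tail)]
        if in_tail.empty:
            raise ValueError("no tail variant available as pedigree causal")
        rare = in_tail[in_tail["af"] < 0.005]
        if rare.empty:  # tiny catalogs: fall back to the rarest tail variant
            rare = in_tail.nsmallest(1, "af")
        if scores is not None:
            # Plant the causal at the top synthetic tail score so that the
            # downstream ML ranking has an unambiguous truth.
            mx = (
                scores[scores["variant_id"].isin(rare["variant_id"])]
                .assign(mag=lambda d: d["score"].abs())
                .groupby("variant_id")["mag"]
                .max()
            )
            causal = mx.idxmax()
        else:
            best = rare.sample(1, random_state=int(rng.integers(2**31)))
            causal = best["variant_id"].iloc[0]
        truth.pedigree_causal_variant = causal

    n_kids = config.n_affected + config.n_unaffected_sibs
    members = ["father", "mother"] + [f"child{i+1}" for i in range(n_kids)]
    affected = [False, False] + [i < config.n_affected for i in range(n_kids)]
    ped = pd.DataFrame(
        {
            "id": members,
            "father_id": ["0", "0"] + ["father"] * n_kids,
            "mother_id": ["0", "0"] + ["mother"] * n_kids,
            "sex": [1, 2] + [int(rng.integers(1, 3)) for _ in range(n_kids)],
            "affected": affected,
            # Founders are not genotyped in the emitted pedigree (the
            # affected-only family situation); their genotypes still exist
            # in the tables for phase logic.
            "genotyped": [False, False] + [True] * n_kids,
        }
    )

    vids = variants["variant_id"].to_numpy()
    af = variants["af"].to_numpy()
    n_v = len(vids)
    founders = {
        m: rng.binomial(1, af, size=(2, n_v)).astype(np.int8)
        for m in ("father", "mother")
    }
    ci = int(np.where(vids == causal)[0][0])
    founders["father"][:, ci] = [1, 0]  # het father carries the causal allele
    founders["mother"][:, ci] = [0, 0]

    geno = {}
    geno["father"] = founders["father"].sum(axis=0)
    geno["mother"] = founders["mother"].sum(axis=0)
    for i in range(n_kids):
        pick_f = rng.integers(0, 2, size=n_v)
        pick_m = rng.integers(0, 2, size=n_v)
        # Force transmission of the causal haplotype to affected children
        # and the reference haplotype to unaffected siblings.
        pick_f[ci] = 0 if i < config.n_affected else 1
        child = (
            founders["father"][pick_f, np.arange(n_v)]
            + founders["mother"][pick_m, np.arange(n_v)]
        )
        geno[f"child{i+1}"] = child
    gt = pd.DataFrame(geno, index=vids).astype(np.int8)

    shape = gt.shape
    gq = rng.integers(40, 99, size=shape).astype(float)
    dp = rng.integers(20, 60, size=shape).astype(float)
    ad_alt = np.where(
        gt.to_numpy() == 1,
        np.round(dp * np.clip(rng.normal(0.5, 0.05, size=shape), 0.25, 0.75)),
        np.where(gt.to_numpy() == 2, dp, 0),
    )
    corrupt = rng.random(shape) < config.genotype_corruption
    gq[corrupt] = rng.integers(0, 20, size=int(corrupt.sum()))
    fmt = {
        "genotypes": gt,
        "gq": pd.DataFrame(gq, index=vids, columns=gt.columns),
        "dp": pd.DataFrame(dp, index=vids, columns=gt.columns),
        "ad_alt": pd.DataFrame(ad_alt, index=vids, columns=gt.columns),
    }
    return ped, fmt, truth


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Run all generators in order and bundle the cohort."""
    scaffold = generate_scaffold(config)
    variants, genotypes = generate_variants_and_genotypes(config, scaffold)
    scores, truth = generate_effect_scores(config, scaffold, variants)
    phenotypes, truth = generate_case_control(
        config, scaffold, variants, genotypes, truth
    )
    return SyntheticCohort(
        config=config,
        scaffold=scaffold,
        variants=variants,
        genotypes=genotypes,
        scores=scores,
        phenotypes=phenotypes,
        truth=truth,
    )
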