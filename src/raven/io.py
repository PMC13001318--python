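"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats only: VCF v4.2 (genotypes, with optional per-genotype
GQ/DP/AD), BED3+1 peaks (0-based half-open, column 4 = cell type), TSV
score/sample/link tables, PED pedigrees, and TSV count matrices.  VCFs are
read back through cyvcf2.  Positions are 0-based inside the package and
converted to 1-based on VCF export.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

VCF_HEADER = """##fileformat=VCFv4.2
##source=raven
##INFO=<ID=AF,Number=A,Type=Float,Description="Reference allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    path,
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    gq: pd.DataFrame | None = None,
    dp: pd.DataFrame | None = None,
    ad_alt: pd.DataFrame | None = None,
) -> None:
    """Write variants + sample genotypes as VCF v4.2.

    ``genotypes`` is samples x variants (dosage 0/1/2, -1 missing) or
    variants x samples when GQ/DP/AD tables are supplied (pedigree
    convention, where rows align with the variant catalog).
    """
    path = Path(path)
    contigs = variants.groupby("chrom")["pos"].max()
    with_fmt = gq is not None
    if with_fmt:
        samples = list(genotypes.columns)
        gt_by_variant = genotypes
    else:
        samples = list(genotypes.index)
        gt_by_variant = genotypes.T
    with path.open("w") as fh:
        fh.write(VCF_HEADER)
        for chrom, mx in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={int(mx) + 10}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        fmt = "GT:GQ:DP:AD" if with_fmt else "GT"
        for v in variants.itertuples(index=False):
            row = gt_by_variant.loc[v.variant_id]
            fields = []
            for s in samples:
                g = int(row[s])
                cell = _GT_CODE.get(g, "./.")
                if with_fmt:
                    q = int(gq.loc[v.variant_id, s])
                    d = int(dp.loc[v.variant_id, s])
                    aa = int(ad_alt.loc[v.variant_id, s])
                    cell = f"{cell}:{q}:{d}:{d - aa},{aa}"
                fields.append(cell)
            fh.write(
                f"{v.chrom}\t{int(v.pos) + 1}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\tAF={v.af:.6g}\t{fmt}\t" + "\t".join(fields) + "\n"
            )


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (variant catalog, samples x variants dosage table)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta, rows = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS - 1}:{rec.REF}:{rec.ALT[0]}"
        af = rec.INFO.get("AF")
        meta.append(
            {
                "variant_id": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS - 1,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "af": float(af) if af is not None else np.nan,
            }
        )
        gt = rec.gt_types  # 0=hom_ref,1=het,2=unknown,3=hom_alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        rows.append(dosage)
    variants = pd.DataFrame(meta)
    geno = pd.DataFrame(
        np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=variants["variant_id"] if len(variants) else [],
    )
    return variants, geno


def read_family_vcf(path) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Read a multi-sample VCF with GQ/DP/AD into variant x sample tables."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta = []
    gt_rows, gq_rows, dp_rows, ad_rows = [], [], [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS - 1}:{rec.REF}:{rec.ALT[0]}"
        af = rec.INFO.get("AF")
        meta.append(
            {
                "variant_id": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS - 1,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "af": float(af) if af is not None else np.nan,
            }
        )
        gtt = rec.gt_types
        gt_rows.append(
            np.select([gtt == 0, gtt == 1, gtt == 3], [0, 1, 2], default=-1)
        )
        gq_rows.append(rec.gt_quals.astype(float))
        try:
            dp_arr = rec.format("DP").astype(float).ravel()
        except Exception:
            dp_arr = np.full(len(samples), np.nan)
        dp_rows.append(dp_arr)
        try:
            ad = rec.format("AD").astype(float)
            ad_rows.append(ad[:, 1])
        except Exception:
            ad_rows.append(np.full(len(samples), np.nan))
    variants = pd.DataFrame(meta)
    idx = variants["variant_id"]
    tables = {
        "genotypes": pd.DataFrame(gt_rows, index=idx, columns=samples).astype(int),
        "gq": pd.DataFrame(gq_rows, index=idx, columns=samples),
        "dp": pd.DataFrame(dp_rows, index=idx, columns=samples),
        "ad_alt": pd.DataFrame(ad_rows, index=idx, columns=samples),
    }
    return variants, tables


def write_bed(path, peaks: pd.DataFrame) -> None:
    """BED3+1: chrom, start, end, cell type (plus peak_id, activity)."""
    peaks[["chrom", "start", "end", "cell_type", "peak_id", "activity"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "cell_type", "peak_id", "activity"],
    )
    if df["peak_id"].isna().any():
        df["peak_id"] = [f"P{i+1:05d}" for i in range(len(df))]
    return df


def write_ped(path, pedigree: pd.DataFrame, family_id: str = "FAM1") -> None:
    """Six-column PED: family, id, father, mother, sex, phenotype (2=affected)."""
    out = pd.DataFrame(
        {
            "family_id": family_id,
            "id": pedigree["id"],
            "father_id": pedigree["father_id"],
            "mother_id": pedigree["mother_id"],
            "sex": pedigree["sex"],
            "phenotype": np.where(pedigree["affected"], 2, 1),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_ped(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["family_id", "id", "father_id", "mother_id", "sex", "phenotype"],
        dtype={"id": str, "father_id": str, "mother_id": str},
    )
    df["affected"] = df["phenotype"] == 2
    df["genotyped"] = True
    return df[["id", "father_id", "mother_id", "sex", "affected", "genotyped"]]


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
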