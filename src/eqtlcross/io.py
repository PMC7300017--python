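"""Readers and writers for the formats the pipeline touches.

PLINK ped/map and VCF carry genotypes; plain TSV carries expression, pedigree,
gene positions and every result table.  All readers validate on load and all
reader/writer pairs are exact round-trips (covered by tests).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GenePositions,
    GenotypeMatrix,
    Pedigree,
    SNPMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

_PED_SEX = {"1": "M", "2": "F"}
_SEX_PED = {"M": "1", "F": "2"}


# ---------------------------------------------------------------------------
# PLINK ped/map
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> SNPMap:
    rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValidationError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
        chrom, snp_id, _cm, pos = parts
        rows.append((snp_id, chrom, int(pos)))
    return SNPMap(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"]))


def read_plink(ped_path: str | Path, map_path: str | Path):
    """Read a PLINK text fileset.

    Dosages count the alphabetically-first allele observed at each SNP; "0 0"
    genotypes become missing.  Returns ``(GenotypeMatrix, SNPMap, Pedigree)``
    where the pedigree carries whatever the .ped family columns contain.

    Raises :class:`ValidationError` naming the offending line for malformed
    rows and for SNPs with more than two observed alleles.
    """
    snp_map = read_map(map_path)
    m = len(snp_map)

    individuals: list[str] = []
    fam_rows = []
    allele_rows: list[list[tuple[str, str]]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ValidationError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for {m} SNPs, got {len(parts)}"
            )
        _fid, iid, sire, dam, sex_code, _pheno = parts[:6]
        individuals.append(iid)
        fam_rows.append((iid, sire, dam, _PED_SEX.get(sex_code, "M"), _fid))
        allele_rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        )

    n = len(individuals)
    dosage = np.full((n, m), np.nan)
    allele_pairs: list[tuple[str, str]] = []
    for j in range(m):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise ValidationError(
                f"{ped_path}: SNP {snp_map.snp_ids[j]!r} has >2 alleles: {observed}"
            )
        counted = observed[0] if observed else "0"
        other = observed[1] if len(observed) > 1 else counted
        allele_pairs.append((counted, other))
        for i in range(n):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == counted) + (a2 == counted)

    ped = Pedigree(
        pd.DataFrame(fam_rows, columns=["individual", "sire", "dam", "sex", "backcross"])
    )
    return GenotypeMatrix(individuals, dosage, allele_pairs), snp_map, ped


def write_plink(
    geno: GenotypeMatrix,
    snp_map: SNPMap,
    pedigree: Pedigree | None,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    with open(map_path, "w") as fh:
        for r in snp_map.table.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")

    alleles = geno.alleles or [("A", "B")] * geno.n_snps
    fam = None
    if pedigree is not None:
        fam = pedigree.table.set_index("individual")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(geno.individuals):
            if fam is not None and iid in fam.index:
                r = fam.loc[iid]
                head = [str(r["backcross"]), iid, str(r["sire"]), str(r["dam"]),
                        _SEX_PED.get(r["sex"], "0"), "-9"]
            else:
                head = ["FAM", iid, "0", "0", "0", "-9"]
            fields = list(head)
            for j in range(geno.n_snps):
                d = geno.dosage[i, j]
                counted, other = alleles[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    k = int(d)
                    fields += [counted] * k + [other] * (2 - k)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, snp_map: SNPMap, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT only; ALT is the counted allele."""
    alleles = geno.alleles or [("A", "B")] * geno.n_snps
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in snp_map.table["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individuals)
            + "\n"
        )
        for j, r in enumerate(snp_map.table.itertuples()):
            counted, other = alleles[j]
            ref = other if other != counted else "N"
            gts = [
                "./." if np.isnan(d) else gt_codes[d] for d in geno.dosage[:, j]
            ]
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.snp_id}\t{ref}\t{counted}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, SNPMap]:
    """Read genotypes from a VCF; dosage counts the ALT allele.

    GT 0/0, 0/1, 1/1 map to 0, 1, 2; ./. is missing.  Multiallelic records are
    skipped with a logged warning; a VCF without a GT field is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    if not individuals:
        raise ValidationError(f"{path}: no samples / GT field in VCF")
    rows, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping non-biallelic record %s:%s", variant.CHROM, variant.POS
            )
            continue
        if "GT" not in (variant.FORMAT or []):
            raise ValidationError(f"{path}: record without GT at {variant.CHROM}:{variant.POS}")
        gt = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown with gts012
        gt[gt == 3] = np.nan
        columns.append(gt)
        rows.append((variant.ID or f"{variant.CHROM}_{variant.POS}", variant.CHROM, variant.POS))
    snp_map = SNPMap(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"]))
    dosage = np.column_stack(columns) if columns else np.empty((len(individuals), 0))
    return GenotypeMatrix(individuals, dosage), snp_map


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    long = (
        expr.values.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="individual", value_name="value")
    )
    long["log2"] = long["gene"].map(expr.log2).astype(int)
    long.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "individual", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expression TSV needs columns {sorted(required)}")
    if df.duplicated(["gene", "individual"]).any():
        raise ValidationError(f"{path}: duplicate (gene, individual) pair")
    flags = {}
    if "log2" in df.columns:
        per_gene = df.groupby("gene")["log2"].nunique()
        if (per_gene > 1).any():
            raise ValidationError(f"{path}: inconsistent log2 flag within a gene")
        flags = df.groupby("gene")["log2"].first().astype(bool).to_dict()
    wide = df.pivot(index="gene", columns="individual", values="value")
    wide.columns.name = None
    wide.index.name = None
    for gene in wide.index:
        if not flags.get(gene, False) and (wide.loc[gene] <= 0).any():
            raise ValidationError(f"{path}: non-positive NQ for gene {gene!r}")
    return ExpressionMatrix(wide, {g: bool(flags.get(g, False)) for g in wide.index})


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree(df)


def write_gene_positions(gp: GenePositions, path: str | Path) -> None:
    gp.table.to_csv(path, sep="\t", index=False)


def read_gene_positions(path: str | Path) -> GenePositions:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    return GenePositions(df)
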