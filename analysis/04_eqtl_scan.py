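"""Genome scan of every gene's expression with the kinship-aware mixed model.

SNP QC (MAF >= 5%, missingness <= 5%), genomic relationship matrix, per-gene
mixed-model scan with Wald tests and per-scan BH q-values.  Writes the
pooled scan table and a Manhattan-plot export (chr, pos, -log10 p).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from eqtlcross import assoc, io
from eqtlcross.experiments import design_covariates


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/simulated"))
    ap.add_argument("--expr", type=Path, default=Path("results/expression_nq.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--loco", action="store_true",
                    help="leave-one-chromosome-out kinship (recommended at "
                    "reduced panel sizes)")
    args = ap.parse_args()

    geno, snp_map, _ = io.read_plink(args.sim / "genotypes.ped", args.sim / "genotypes.map")
    ped = io.read_pedigree(args.sim / "pedigree.tsv")
    expr = io.read_expression(args.expr)

    geno, snp_map, report = assoc.snp_qc(geno, snp_map)
    print(f"QC: kept {report.n_kept}/{report.n_input} SNPs "
          f"({report.n_removed_maf} failed MAF, {report.n_removed_missing} missingness)")

    off = ped.table[ped.table["individual"].isin(expr.individuals)]
    off = off.set_index("individual").loc[expr.individuals].reset_index()
    keep = [i for i, ind in enumerate(geno.individuals) if ind in set(expr.individuals)]
    order = {ind: k for k, ind in enumerate(expr.individuals)}
    keep.sort(key=lambda i: order[geno.individuals[i]])
    geno = assoc.GenotypeMatrix(
        [geno.individuals[i] for i in keep], geno.dosage[keep], geno.alleles
    )
    W = design_covariates(off)
    K = assoc.compute_grm(geno)

    scans = []
    for gene in expr.genes:
        y = expr.gene_values(gene)
        if args.loco:
            scan = assoc.scan_gene_loco(y, W, geno, snp_map, gene=gene)
        else:
            scan = assoc.scan_gene(y, W, geno, snp_map, K, gene=gene)
        n_sig = int((scan["q"] < 0.05).sum())
        if n_sig:
            top = scan.loc[scan["p"].idxmin()]
            print(f"{gene}: {n_sig} eSNPs (q<0.05); top {top.snp_id} "
                  f"chr{top.chrom}:{top.pos} p={top.p:.2e}")
        scans.append(scan)
    pooled = pd.concat(scans, ignore_index=True)
    pooled.to_csv(args.out / "scans.tsv", sep="\t", index=False)

    manhattan = pooled[["gene", "chrom", "pos"]].copy()
    manhattan["neglog10p"] = -np.log10(pooled["p"].clip(lower=1e-300))
    manhattan.to_csv(args.out / "manhattan.tsv", sep="\t", index=False)
    print(f"wrote {args.out}/scans.tsv and {args.out}/manhattan.tsv")


if __name__ == "__main__":
    main()
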