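"""Quantify raw Cq tables and produce the normalized expression matrix.

Fits per-assay relative standard curves, screens candidate reference genes
for stability (geNorm-style M), normalizes targets to NQ by the geometric
mean of the two most stable references, and applies the per-gene
Shapiro-Wilk-driven log2 transform.  Writes results/expression_nq.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqtlcross import io, qpcr

REFERENCE_CANDIDATES = ["REF1", "REF2", "HPRT1L"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cq = pd.read_csv(args.sim / "qpcr_cq.tsv", sep="\t")
    quantities, curves = qpcr.quantify_assays(cq)
    effs = {a: c.efficiency for a, c in curves.items()}
    print(f"fitted {len(curves)} standard curves; efficiency range "
          f"{min(effs.values()):.3f}-{max(effs.values()):.3f}")

    candidates = [g for g in REFERENCE_CANDIDATES if g in quantities.index]
    stability = qpcr.reference_stability(quantities, candidates)
    print("reference stability (geNorm M, lower = stabler):")
    for g, m in stability.items():
        print(f"  {g}: {m:.3f}")
    refs = list(stability.index[:2])
    dropped = [g for g in candidates if g not in refs]
    print(f"normalizing with {refs}; discarded {dropped}")

    targets = quantities.drop(index=candidates)
    nq = qpcr.normalize_nq(targets, quantities.loc[refs])
    expr = qpcr.normality_transform(nq)
    n_log = sum(expr.log2.values())
    print(f"log2-transformed {n_log}/{len(expr.genes)} genes after Shapiro-Wilk")

    args.out.mkdir(parents=True, exist_ok=True)
    io.write_expression(expr, args.out / "expression_nq.tsv")
    print(f"wrote {args.out}/expression_nq.tsv")


if __name__ == "__main__":
    main()
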