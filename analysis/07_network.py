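"""PCIT co-expression network of the target genes.

Pairwise Pearson correlations on the analysis scale, PCIT
partial-correlation significance filter, |r| >= 0.6 display threshold;
writes the signed edge list and a GraphML with node degrees.
"""

import argparse
from pathlib import Path

from eqtlcross import io, pcit


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--expr", type=Path, default=Path("results/expression_nq.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--rmin", type=float, default=0.6)
    args = ap.parse_args()

    expr = io.read_expression(args.expr)
    corr = pcit.correlation_matrix(expr)
    kept = pcit.pcit_filter(corr)
    n_pairs = len(corr) * (len(corr) - 1) // 2
    n_kept = int(kept.to_numpy().sum() // 2)
    print(f"PCIT: {n_kept}/{n_pairs} gene pairs significant")

    net = pcit.threshold_and_export(
        corr, kept, r_min=args.rmin,
        edge_tsv=args.out / "network_edges.tsv",
        graphml=args.out / "network.graphml",
    )
    print(f"display network (|r| >= {args.rmin}): {net.graph.number_of_nodes()} genes, "
          f"{net.graph.number_of_edges()} edges")
    for gene, deg in sorted(net.degrees.items(), key=lambda kv: -kv[1]):
        print(f"  {gene}: degree {deg}")
    print(f"wrote {args.out}/network_edges.tsv, network.graphml")


if __name__ == "__main__":
    main()
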