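"""Screen sex and backcross effects on per-gene expression.

Per gene: two-factor additive linear model on the analysis scale, marginal
F-test per term, group means with SEM and significance stars.  Writes
results/sex_effects.tsv and results/backcross_effects.tsv.
"""

import argparse
from pathlib import Path

from eqtlcross import effects, io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/simulated"))
    ap.add_argument("--expr", type=Path, default=Path("results/expression_nq.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    expr = io.read_expression(args.expr)
    ped = io.read_pedigree(args.sim / "pedigree.tsv")

    for term, fname in (("sex", "sex_effects.tsv"), ("backcross", "backcross_effects.tsv")):
        summary = effects.group_summary(expr, ped, term)
        summary.to_csv(args.out / fname, sep="\t", index=False)
        sig = summary[summary["p"] <= 0.05]["gene"].nunique()
        print(f"{term}: {sig}/{len(expr.genes)} genes significant at 0.05 "
              f"-> {args.out}/{fname}")


if __name__ == "__main__":
    main()
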