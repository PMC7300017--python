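"""Map significant eSNPs to eQTL intervals, label cis/trans, find hotspots.

Applies the 10 Mb merge rule per gene and chromosome, the >=2 SNP interval
filter (joint-backcross mode), the 1 Mb cis rule, the +/-1 Mb annotation
window, and trans-hotspot detection by interval overlap.  Writes the
interval table, hotspot table and a karyotype-plot export.
"""

import argparse
from pathlib import Path

import pandas as pd

from eqtlcross import io, mapper


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/simulated"))
    ap.add_argument("--scans", type=Path, default=Path("results/scans.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--mode", choices=["3BCs", "single"], default="3BCs")
    args = ap.parse_args()

    scans = pd.read_csv(args.scans, sep="\t", dtype={"chrom": str})
    gene_pos = io.read_gene_positions(args.sim / "gene_positions.tsv")
    _, snp_map, _ = io.read_plink(args.sim / "genotypes.ped", args.sim / "genotypes.map")

    intervals = []
    for gene, scan in scans.groupby("gene", sort=False):
        esnps = mapper.call_esnps(scan)
        merged = mapper.merge_intervals(esnps)
        kept = mapper.filter_intervals(merged, args.mode)
        for iv in kept:
            mapper.classify_cis_trans(iv, gene_pos, snp_map)
        intervals.extend(kept)

    table = mapper.intervals_table(intervals)
    windows = [mapper.annotation_window(iv) for iv in intervals]
    table["window_start"] = [w[1] for w in windows]
    table["window_end"] = [w[2] for w in windows]
    table.to_csv(args.out / "eqtl_intervals.tsv", sep="\t", index=False)
    print(f"{len(intervals)} eQTL intervals "
          f"({sum(iv.label == 'cis' for iv in intervals)} cis, "
          f"{sum(iv.label == 'trans' for iv in intervals)} trans, "
          f"{sum(iv.label == 'cis/trans' for iv in intervals)} cis/trans)")

    hotspots = mapper.detect_hotspots(intervals)
    mapper.hotspots_table(hotspots).to_csv(args.out / "hotspots.tsv", sep="\t", index=False)
    for h in hotspots:
        print(f"hotspot chr{h.chrom}:{h.start_bp / 1e6:.1f}-{h.end_bp / 1e6:.1f} Mb "
              f"regulating {len(h.genes)} genes: {', '.join(h.genes)}")

    mapper.phenogram_table(intervals, args.mode).to_csv(
        args.out / "phenogram.tsv", sep="\t", index=False
    )
    print(f"wrote {args.out}/eqtl_intervals.tsv, hotspots.tsv, phenogram.tsv")


if __name__ == "__main__":
    main()
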