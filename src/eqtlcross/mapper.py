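"""From significant eSNPs to eQTL intervals, cis/trans labels and hotspots.

Interval rule: per gene and chromosome, significant SNPs less than 10 Mb
apart belong to the same interval (a gap of exactly 10 Mb splits); interval
bounds are the member min/max positions and size = end - start (no +1, the
convention the published interval tables follow).  A member SNP is cis when
it lies within 1 Mb of the analyzed gene's nearest edge on the same
chromosome; an interval is labeled cis, trans, or cis/trans accordingly.
Hotspots are connected components (>=1 bp overlap) of trans intervals from
two or more distinct genes on one chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import GenePositions, SNPMap, ValidationError, bp_distance

GAP_BP = 10_000_000
CIS_BP = 1_000_000
WINDOW_BP = 1_000_000


@dataclass
class EqtlInterval:
    gene: str
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    top_snp: str | None = None
    top_p: float | None = None
    pve: float | None = None
    label: str | None = None  # cis | trans | cis/trans

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError("interval start must be <= end")

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class Hotspot:
    chrom: str
    start_bp: int
    end_bp: int
    genes: list[str]
    intervals: list[EqtlInterval] = field(default_factory=list)


def interval_size(start_bp: int, end_bp: int) -> int:
    """Published convention: size = end - start (two co-located SNPs span 0)."""
    if start_bp > end_bp:
        raise ValidationError("start must be <= end")
    return end_bp - start_bp


def call_esnps(scan: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Significant eSNPs at strict q < threshold (FDR < 0.05 convention)."""
    if scan.empty:
        return scan.copy()
    return scan[scan["q"] < q_threshold].reset_index(drop=True)


def merge_intervals(esnps: pd.DataFrame, gap_bp: int = GAP_BP) -> list[EqtlInterval]:
    """Cluster each gene's eSNPs into intervals: gaps < 10 Mb merge.

    ``esnps`` needs columns gene, snp_id, chrom, pos (scan output after
    :func:`call_esnps`); p/q and PVE columns are carried onto the interval's
    top SNP when present.
    """
    intervals: list[EqtlInterval] = []
    if esnps.empty:
        return intervals
    for (gene, chrom), sub in esnps.groupby(["gene", "chrom"], sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp) + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            members = sub.iloc[chunk]
            iv = EqtlInterval(
                gene=gene,
                chrom=str(chrom),
                start_bp=int(members["pos"].min()),
                end_bp=int(members["pos"].max()),
                snp_ids=list(members["snp_id"]),
            )
            if "p" in members.columns:
                top = members.loc[members["p"].idxmin()]
                iv.top_snp = top["snp_id"]
                iv.top_p = float(top["p"])
                if "pve" in members.columns:
                    iv.pve = float(top["pve"])
            intervals.append(iv)
    return intervals


def filter_intervals(intervals: list[EqtlInterval], mode: str) -> list[EqtlInterval]:
    """Annotation filter: keep >=2 SNPs in the joint (3BCs) analysis, >=3 in a
    single-backcross analysis."""
    if mode not in ("3BCs", "single"):
        raise ValidationError("mode must be '3BCs' or 'single'")
    min_snps = 2 if mode == "3BCs" else 3
    return [iv for iv in intervals if iv.n_snps >= min_snps]


def classify_cis_trans(
    interval: EqtlInterval,
    gene_positions: GenePositions,
    snp_map: SNPMap,
    cis_bp: int = CIS_BP,
) -> str:
    """Label an interval cis / trans / cis-and-trans by its member SNPs."""
    chrom, start, end = gene_positions.locus(interval.gene)
    t = snp_map.table.set_index("snp_id")
    flags = []
    for snp in interval.snp_ids:
        r = t.loc[snp]
        flags.append(snp_is_cis(str(r["chrom"]), int(r["pos"]), chrom, start, end, cis_bp))
    if all(flags):
        label = "cis"
    elif not any(flags):
        label = "trans"
    else:
        label = "cis/trans"
    interval.label = label
    return label


def snp_is_cis(
    snp_chrom: str, snp_pos: int, gene_chrom: str, gene_start: int, gene_end: int,
    cis_bp: int = CIS_BP,
) -> bool:
    """A SNP is cis when it sits within 1 Mb of the gene's nearest edge on the
    same chromosome (inside the gene counts as distance 0)."""
    return snp_chrom == gene_chrom and bp_distance(snp_pos, gene_start, gene_end) <= cis_bp


def annotation_window(interval: EqtlInterval, window_bp: int = WINDOW_BP) -> tuple[str, int, int]:
    """(chromosome, start - 1 Mb floored at 1, end + 1 Mb) for external
    annotation tools."""
    return interval.chrom, max(1, interval.start_bp - window_bp), interval.end_bp + window_bp


def detect_hotspots(
    intervals: list[EqtlInterval], adjacency_bp: int = 0
) -> list[Hotspot]:
    """Trans-eQTL hotspots: overlapping trans intervals hitting >=2 genes.

    Intervals must already be labeled.  Overlap means a nonempty bp
    intersection (configurable adjacency tolerance, default 0).
    """
    trans = [iv for iv in intervals if iv.label == "trans"]
    g = nx.Graph()
    g.add_nodes_from(range(len(trans)))
    for i in range(len(trans)):
        for j in range(i + 1, len(trans)):
            a, b = trans[i], trans[j]
            if a.chrom != b.chrom:
                continue
            if a.start_bp <= b.end_bp + adjacency_bp and b.start_bp <= a.end_bp + adjacency_bp:
                g.add_edge(i, j)
    hotspots = []
    for comp in nx.connected_components(g):
        members = [trans[i] for i in comp]
        genes = sorted({iv.gene for iv in members})
        if len(genes) < 2:
            continue
        hotspots.append(
            Hotspot(
                chrom=members[0].chrom,
                start_bp=min(iv.start_bp for iv in members),
                end_bp=max(iv.end_bp for iv in members),
                genes=genes,
                intervals=members,
            )
        )
    hotspots.sort(key=lambda h: (h.chrom, h.start_bp))
    return hotspots


def intervals_table(intervals: list[EqtlInterval]) -> pd.DataFrame:
    """Result-table export mirroring the published interval table layout."""
    rows = [
        (
            k + 1, iv.gene, iv.chrom, iv.start_bp, iv.end_bp, iv.size_bp,
            iv.n_snps, iv.label, iv.top_snp, iv.top_p, iv.pve,
        )
        for k, iv in enumerate(intervals)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "interval", "gene", "chrom", "start_bp", "end_bp", "size_bp",
            "n_snps", "label", "top_snp", "top_p", "pve",
        ],
    )


def hotspots_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = [
        (h.chrom, h.start_bp, h.end_bp, len(h.genes), ",".join(h.genes))
        for h in hotspots
    ]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_genes", "genes"])


def phenogram_table(intervals: list[EqtlInterval], cohort: str) -> pd.DataFrame:
    """Per-SNP (chr, pos placeholder by interval bounds) export for
    karyotype-style plots of associated regions."""
    rows = []
    for iv in intervals:
        rows.append((iv.chrom, iv.start_bp, iv.gene, cohort))
        if iv.end_bp != iv.start_bp:
            rows.append((iv.chrom, iv.end_bp, iv.gene, cohort))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene", "cohort"])
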