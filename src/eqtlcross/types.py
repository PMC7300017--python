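"""Shared domain containers for the backcross eQTL pipeline.

Coordinates are 1-based and inclusive everywhere; :func:`bp_distance` is the
single place where base-pair distances to a feature are computed, so any
off-by-one convention lives (and is tested) in exactly one spot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

SEX_LEVELS = ("M", "F")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass
class SNPMap:
    """Marker map: one row per SNP with chromosome label and 1-based bp position.

    Chromosome labels are opaque strings ("1".."18", "X"); no numeric ordering
    is assumed beyond lexical grouping.
    """

    table: pd.DataFrame  # columns: snp_id, chrom, pos

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(t.columns):
            raise ValidationError(f"SNP map needs columns {sorted(required)}")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValidationError(f"duplicate snp_id {dup!r}")
        if (t["pos"] <= 0).any():
            raise ValidationError("SNP positions must be strictly positive (1-based)")
        self.table = t.reset_index(drop=True).assign(
            chrom=t["chrom"].astype(str).values, pos=t["pos"].astype(np.int64).values
        )

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Per-individual dosage of the counted allele, in {0, 1, 2, NaN}.

    ``alleles`` stores the (counted, other) allele letters per SNP when known;
    the counted allele is the alphabetically first observed one for PLINK input
    and the ALT allele for VCF input.  Orientation only flips effect signs.
    """

    individuals: list[str]
    dosage: np.ndarray  # float array, shape (n_individuals, n_snps)
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.individuals):
            raise ValidationError("dosage shape does not match individual list")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("dosages must be 0/1/2 or missing")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return np.isnan(self.dosage).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency, ignoring missing entries."""
        p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class Pedigree:
    """Individual / sire / dam / sex / backcross table.

    Unknown parents are recorded as "0".  Sex and backcross must be non-missing
    for phenotyped animals (enforced on load for every row present).
    """

    table: pd.DataFrame  # columns: individual, sire, dam, sex, backcross

    def __post_init__(self) -> None:
        t = self.table
        required = {"individual", "sire", "dam", "sex", "backcross"}
        if not required.issubset(t.columns):
            raise ValidationError(f"pedigree needs columns {sorted(required)}")
        if t["individual"].duplicated().any():
            raise ValidationError("duplicate individual in pedigree")
        bad_sex = ~t["sex"].isin(SEX_LEVELS)
        if bad_sex.any():
            raise ValidationError(f"sex must be one of {SEX_LEVELS}")
        self._check_no_ancestor_cycles(t)
        self.table = t.reset_index(drop=True)

    @staticmethod
    def _check_no_ancestor_cycles(t: pd.DataFrame) -> None:
        parents = {
            r.individual: {r.sire, r.dam} - {"0"} for r in t.itertuples()
        }
        for start in parents:
            seen, frontier = set(), {start}
            while frontier:
                frontier = {
                    p for ind in frontier for p in parents.get(ind, ())
                } - seen
                if start in frontier:
                    raise ValidationError(f"{start} is its own ancestor")
                seen |= frontier

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.set_index("individual").loc[individual]
        return str(row["sire"]), str(row["dam"])


@dataclass
class ExpressionMatrix:
    """Normalized quantity (NQ) values, genes x individuals.

    ``log2`` flags genes whose values have been replaced by log2(NQ); raw NQ is
    strictly positive, so the flag fully determines the analysis scale.
    """

    values: pd.DataFrame  # index: gene, columns: individual
    log2: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.values.index:
            self.log2.setdefault(g, False)
        raw = self.values.loc[[g for g in self.values.index if not self.log2[g]]]
        if (raw.to_numpy() <= 0).any():
            raise ValidationError("NQ values must be > 0 before log transform")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.values.columns)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


@dataclass
class GenePositions:
    """Gene coordinates (1-based, inclusive) used for cis/trans classification."""

    table: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(t.columns):
            raise ValidationError(f"gene positions need columns {sorted(required)}")
        if (t["start"] > t["end"]).any():
            raise ValidationError("gene start must be <= end")
        if t["gene"].duplicated().any():
            raise ValidationError("duplicate gene in gene positions")
        self.table = t.reset_index(drop=True).assign(
            chrom=t["chrom"].astype(str).values,
            start=t["start"].astype(np.int64).values,
            end=t["end"].astype(np.int64).values,
        )

    def locus(self, gene: str) -> tuple[str, int, int]:
        sub = self.table[self.table["gene"] == gene]
        if sub.empty:
            raise ValidationError(f"no position recorded for gene {gene!r}")
        r = sub.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])


def bp_distance(pos: int, start: int, end: int) -> int:
    """Distance in bp from a point to the nearest edge of [start, end].

    A position inside the (inclusive) interval has distance 0.
    """
    if start > end:
        raise ValueError("start must be <= end")
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0
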