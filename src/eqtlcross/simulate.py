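"""Synthetic three-backcross populations with planted eQTL architecture.

Emulates an experimental pig design: purebred Iberian boars crossed to sows of
three commercial breeds give F1 sires, which are backcrossed to purebred sows
of the same maternal breed, so every BC1 animal is on average 25% Iberian.
Founder haplotypes are drawn per breed from Beta-distributed allele
frequencies; gametes recombine under a Haldane model (no interference) on a
uniform 1 cM/Mb map.  Expression is generated on the natural-log scale as

    log NQ = mu + sex + backcross + sum(beta * dosage) + beta_imp * 1[paternal A]
             + polygenic + block factor + residual

with planted effect sizes solved back from the requested fraction of variance
explained (PVE) given the realized genotype variance.  Raw qPCR Cq values and
dilution-series standards are derived from the abundances through per-assay
standard curves, so the quantification module can be exercised end to end.

A machine-readable :class:`TruthSet` records phased transmissions, parental
breed origin, realized effect sizes, and co-expression block membership for
parameter-recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
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
from . import io as _io

CM_PER_MB = 1.0  # uniform genetic map


@dataclass
class PlantedEffect:
    """A genetic effect planted on one gene's expression.

    mode is one of ``additive_cis``, ``additive_trans``, ``imprinted_paternal``;
    ``pve`` is the intended fraction of (log-scale) phenotypic variance.
    """

    gene: str
    snp_id: str
    mode: str
    pve: float

    def __post_init__(self) -> None:
        if self.mode not in ("additive_cis", "additive_trans", "imprinted_paternal"):
            raise ValidationError(f"unknown effect mode {self.mode!r}")
        if not 0.0 < self.pve < 1.0:
            raise ValidationError("pve must be in (0, 1)")


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic population.

    The default is the desk profile (3 x 60 animals, 3 chromosomes x 500 SNPs,
    12 target genes); :meth:`study_scale` restores the real cohort sizes
    (114/122/119) and :meth:`full_scale` additionally mirrors the genotyping
    density (18 autosomes, ~38,426 SNPs, 45 target + 3 reference genes).
    """

    n_per_backcross: tuple[int, ...] = (60, 60, 60)
    backcross_names: tuple[str, ...] = ("BC1_LD", "BC1_DU", "BC1_PI")
    dam_breeds: tuple[str, ...] = ("LD", "DU", "PI")
    n_sires_per_backcross: int = 6
    litter_size: int = 3
    n_chromosomes: int = 3
    chromosome_lengths_bp: tuple[int, ...] = (120_000_000, 100_000_000, 80_000_000)
    snps_per_chromosome: int = 500
    # Beta(a, b) allele-frequency spectrum per breed (Iberian + dam breeds)
    breed_allele_freq_spec: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "IB": (0.7, 0.7), "LD": (0.7, 0.7), "DU": (0.7, 0.7), "PI": (0.7, 0.7)
        }
    )
    shared_freqs: bool = False  # one frequency vector for all breeds (testing aid)
    forced_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    n_genes: int = 12
    n_reference: int = 3  # 2 stable candidates + 1 unstable (HPRT1-like)
    effects: list[PlantedEffect] | None = None  # None -> default architecture
    sex_effect_size: float = 0.25  # log-scale shift for sex-affected genes
    sex_affected_fraction: float = 2 / 3
    backcross_effect_sd: float = 0.25
    backcross_affected_fraction: float = 0.8
    residual_sd: float = 0.30
    polygenic_h2: float = 0.10
    block_var_frac: float = 0.55
    coexpression_blocks: tuple[tuple[int, ...], ...] | None = None  # gene indices
    qpcr_noise_sd: float = 0.15
    qpcr_efficiency_range: tuple[float, float] = (0.85, 1.05)
    seed: int = 20240

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_backcross):
            raise ValidationError("backcross sizes must be positive")
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValidationError("polygenic_h2 must be in [0, 1)")
        if self.snps_per_chromosome <= 0 or self.n_chromosomes <= 0:
            raise ValidationError("need positive SNP and chromosome counts")
        if len(self.chromosome_lengths_bp) != self.n_chromosomes:
            raise ValidationError("chromosome_lengths_bp length mismatch")
        for spec in self.breed_allele_freq_spec.values():
            if any(v <= 0 for v in spec):
                raise ValidationError("Beta parameters must be positive")

    @classmethod
    def study_scale(cls, **kw) -> "SimConfig":
        kw.setdefault("n_per_backcross", (114, 122, 119))
        return cls(**kw)

    @classmethod
    def full_scale(cls, **kw) -> "SimConfig":
        kw.setdefault("n_per_backcross", (114, 122, 119))
        kw.setdefault("n_chromosomes", 18)
        kw.setdefault(
            "chromosome_lengths_bp",
            tuple(int(l) for l in np.linspace(270e6, 60e6, 18)),
        )
        kw.setdefault("snps_per_chromosome", 2135)  # 18 * 2135 = 38,430 ~ study panel
        kw.setdefault("n_genes", 45)
        return cls(**kw)


@dataclass
class RealizedEffect:
    gene: str
    snp_id: str
    mode: str
    pve: float
    beta: float


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic files."""

    individuals: list[str]
    snp_ids: list[str]
    paternal_hap: np.ndarray  # (n, m) 0/1 copies of the counted "A" allele
    maternal_hap: np.ndarray
    paternal_is_iberian: np.ndarray  # (n, m) bool: paternal allele of Iberian origin
    sire_phase: np.ndarray  # (n, m) which sire haplotype was transmitted (0/1)
    dam_phase: np.ndarray
    sire_haps: dict[str, np.ndarray]  # sire id -> (2, m); row 0 Iberian-origin
    dam_haps: dict[str, np.ndarray]
    effects: list[RealizedEffect]
    gene_mu: dict[str, float]
    sex_coef: dict[str, float]
    backcross_coef: dict[str, dict[str, float]]
    blocks: list[list[str]]
    log_transform_expected: dict[str, bool]
    seed: int

    def iberian_fraction(self) -> np.ndarray:
        """Per-individual genome fraction of Iberian origin (maternal side is 0)."""
        return self.paternal_is_iberian.mean(axis=1) / 2.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "individuals": self.individuals,
            "snp_ids": self.snp_ids,
            "paternal_hap": self.paternal_hap.astype(int).tolist(),
            "maternal_hap": self.maternal_hap.astype(int).tolist(),
            "paternal_is_iberian": self.paternal_is_iberian.astype(int).tolist(),
            "sire_phase": self.sire_phase.astype(int).tolist(),
            "dam_phase": self.dam_phase.astype(int).tolist(),
            "sire_haps": {k: v.astype(int).tolist() for k, v in self.sire_haps.items()},
            "dam_haps": {k: v.astype(int).tolist() for k, v in self.dam_haps.items()},
            "effects": [asdict(e) for e in self.effects],
            "gene_mu": self.gene_mu,
            "sex_coef": self.sex_coef,
            "backcross_coef": self.backcross_coef,
            "blocks": self.blocks,
            "log_transform_expected": self.log_transform_expected,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            individuals=d["individuals"],
            snp_ids=d["snp_ids"],
            paternal_hap=np.array(d["paternal_hap"], dtype=np.int8),
            maternal_hap=np.array(d["maternal_hap"], dtype=np.int8),
            paternal_is_iberian=np.array(d["paternal_is_iberian"], dtype=bool),
            sire_phase=np.array(d["sire_phase"], dtype=np.int8),
            dam_phase=np.array(d["dam_phase"], dtype=np.int8),
            sire_haps={k: np.array(v, dtype=np.int8) for k, v in d["sire_haps"].items()},
            dam_haps={k: np.array(v, dtype=np.int8) for k, v in d["dam_haps"].items()},
            effects=[RealizedEffect(**e) for e in d["effects"]],
            gene_mu=d["gene_mu"],
            sex_coef=d["sex_coef"],
            backcross_coef=d["backcross_coef"],
            blocks=d["blocks"],
            log_transform_expected=d["log_transform_expected"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# Marker map and allele frequencies
# ---------------------------------------------------------------------------

def forced_window(
    snp_map: SNPMap,
    snp_id: str,
    per_breed: dict[str, float],
    halfwidth: int = 2,
) -> dict[str, dict[str, float]]:
    """Breed-divergent frequency window around a planted SNP.

    Allele-level LD in the cross arises only where breed frequencies diverge
    (segment origin is near-perfectly correlated along a gamete, but an
    uninformative marker hides it); planting the same divergent frequencies
    on the flanking SNPs makes the region behave like a breed-differentiated
    haplotype, which is what makes the planted loci segregate in these
    crosses in the first place.
    """
    t = snp_map.table
    j = int(np.flatnonzero(t["snp_id"] == snp_id)[0])
    chrom = t["chrom"].iloc[j]
    out = {}
    for k in range(max(0, j - halfwidth), min(len(t), j + halfwidth + 1)):
        if t["chrom"].iloc[k] == chrom:
            out[t["snp_id"].iloc[k]] = dict(per_breed)
    return out


def build_snp_map(config: SimConfig) -> SNPMap:
    rows = []
    for c in range(config.n_chromosomes):
        length = config.chromosome_lengths_bp[c]
        pos = np.linspace(1_000_000, length - 1_000_000, config.snps_per_chromosome)
        for k, p in enumerate(pos):
            rows.append((f"snp_c{c + 1}_{k:05d}", str(c + 1), int(round(p))))
    return SNPMap(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"]))


def draw_breed_frequencies(
    config: SimConfig, snp_map: SNPMap, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-breed allele frequencies of the counted allele, clipped to (0.02, 0.98)."""
    m = len(snp_map)
    freqs: dict[str, np.ndarray] = {}
    shared = None
    for breed, (a, b) in config.breed_allele_freq_spec.items():
        if config.shared_freqs:
            if shared is None:
                shared = np.clip(rng.beta(a, b, size=m), 0.02, 0.98)
            freqs[breed] = shared.copy()
        else:
            freqs[breed] = np.clip(rng.beta(a, b, size=m), 0.02, 0.98)
    snp_index = {s: j for j, s in enumerate(snp_map.snp_ids)}
    for snp_id, per_breed in config.forced_freqs.items():
        j = snp_index[snp_id]
        for breed, p in per_breed.items():
            freqs[breed][j] = p
    return freqs


# ---------------------------------------------------------------------------
# Meiosis (Haldane, 1 cM/Mb)
# ---------------------------------------------------------------------------

def simulate_meiosis(
    parent_haps: np.ndarray,
    snp_pos_bp: np.ndarray,
    chrom_labels: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a pair of parental haplotypes.

    Crossover counts per chromosome are Poisson(length in Morgans) with
    positions uniform along the chromosome (Haldane, no interference); the
    starting haplotype is chosen at random per chromosome.  Returns the gamete
    and the phase vector (which parental haplotype supplied each locus).
    """
    parent_haps = np.asarray(parent_haps)
    if parent_haps.shape[0] != 2:
        raise ValidationError("parent_haps must have shape (2, n_snps)")
    m = parent_haps.shape[1]
    phase = np.zeros(m, dtype=np.int8)
    for chrom in pd.unique(chrom_labels):
        idx = np.flatnonzero(chrom_labels == chrom)
        pos = snp_pos_bp[idx]
        length_bp = pos.max() if len(pos) else 0
        morgans = length_bp * CM_PER_MB * 1e-8
        n_co = rng.poisson(morgans)
        start = rng.integers(0, 2)
        if n_co == 0:
            phase[idx] = start
            continue
        co_pos = np.sort(rng.uniform(0, length_bp, size=n_co))
        crossings = np.searchsorted(co_pos, pos)
        phase[idx] = (start + crossings) % 2
    gamete = parent_haps[phase, np.arange(m)]
    return gamete, phase


# ---------------------------------------------------------------------------
# Founders and backcross structure
# ---------------------------------------------------------------------------

@dataclass
class Founders:
    """F1 sires (Iberian x dam-breed) and purebred dams, with haplotypes.

    Sire haplotype row 0 is always the Iberian-origin haplotype.
    """

    sire_haps: dict[str, np.ndarray]  # id -> (2, m)
    dam_haps: dict[str, np.ndarray]
    sire_backcross: dict[str, str]
    dam_backcross: dict[str, str]

    def f1_dosage(self) -> pd.DataFrame:
        data = {sid: h.sum(axis=0) for sid, h in self.sire_haps.items()}
        return pd.DataFrame(data).T


def simulate_founders(
    config: SimConfig, snp_map: SNPMap, rng: np.random.Generator
) -> tuple[Founders, Pedigree]:
    """Draw founder haplotypes breed by breed and assemble the founder pedigree.

    Iberian boars contribute one haplotype to each F1 sire; dams are purebred
    for their backcross's maternal breed.  Because allele frequencies are drawn
    independently per breed, some loci segregate in only a subset of
    backcrosses — the study's "different allelic frequencies among the breeds".
    """
    freqs = draw_breed_frequencies(config, snp_map, rng)
    m = len(snp_map)
    sire_haps, dam_haps = {}, {}
    sire_bc, dam_bc = {}, {}
    ped_rows = []
    for b, bc_name in enumerate(config.backcross_names):
        dam_breed = config.dam_breeds[b]
        n_off = config.n_per_backcross[b]
        n_dams = int(np.ceil(n_off / config.litter_size))
        for s in range(config.n_sires_per_backcross):
            sid = f"{bc_name}_S{s:02d}"
            hap_ib = (rng.random(m) < freqs["IB"]).astype(np.int8)
            hap_dm = (rng.random(m) < freqs[dam_breed]).astype(np.int8)
            sire_haps[sid] = np.vstack([hap_ib, hap_dm])
            sire_bc[sid] = bc_name
            ped_rows.append((sid, "0", "0", "M", bc_name))
        for d in range(n_dams):
            did = f"{bc_name}_D{d:03d}"
            dam_haps[did] = (
                rng.random((2, m)) < freqs[dam_breed][None, :]
            ).astype(np.int8)
            dam_bc[did] = bc_name
            ped_rows.append((did, "0", "0", "F", bc_name))
    ped = Pedigree(
        pd.DataFrame(ped_rows, columns=["individual", "sire", "dam", "sex", "backcross"])
    )
    return Founders(sire_haps, dam_haps, sire_bc, dam_bc), ped


# ---------------------------------------------------------------------------
# Population assembly
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genotypes: GenotypeMatrix
    snp_map: SNPMap
    pedigree: Pedigree  # founders + offspring; offspring have sire/dam filled
    abundance: pd.DataFrame  # true NQ per gene x offspring
    gene_positions: GenePositions
    truth: TruthSet
    cq: pd.DataFrame | None = None

    @property
    def offspring(self) -> list[str]:
        return self.genotypes.individuals

    def offspring_pedigree(self) -> Pedigree:
        t = self.pedigree.table
        return Pedigree(t[t["individual"].isin(self.offspring)].reset_index(drop=True))

    def all_genotypes(self) -> GenotypeMatrix:
        """Founders (sires, dams) and offspring in one matrix — progenitors
        are genotyped too, which is what parent-of-origin deduction needs."""
        ids = list(self.truth.sire_haps) + list(self.truth.dam_haps) + self.offspring
        founder_dosage = [
            haps.sum(axis=0).astype(float)
            for haps in list(self.truth.sire_haps.values()) + list(self.truth.dam_haps.values())
        ]
        dosage = np.vstack(founder_dosage + [self.genotypes.dosage])
        return GenotypeMatrix(ids, dosage, self.genotypes.alleles)

    def write_all(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        everyone = self.all_genotypes()
        _io.write_plink(
            everyone, self.snp_map, self.pedigree,
            outdir / "genotypes.ped", outdir / "genotypes.map",
        )
        _io.write_vcf(everyone, self.snp_map, outdir / "genotypes.vcf")
        _io.write_pedigree(self.pedigree, outdir / "pedigree.tsv")
        _io.write_gene_positions(self.gene_positions, outdir / "gene_positions.tsv")
        _io.write_expression(
            ExpressionMatrix(self.abundance.copy()), outdir / "abundance_true.tsv"
        )
        if self.cq is not None:
            self.cq.to_csv(outdir / "qpcr_cq.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


def _default_architecture(config: SimConfig, snp_map: SNPMap):
    """Plant the study-like architecture on the desk genome.

    One major imprinted cis-eQTL (IGF2-like, PVE 0.70), one additive promoter
    cis-eQTL (ACSM5-like, PVE 0.40), a shared trans-regulator hitting a block
    of four genes, and one backcross-private trans effect.  Remaining genes are
    background, two of them forming a second co-expression block.
    """
    t = snp_map.table
    genes = [f"G{k:02d}" for k in range(1, config.n_genes + 1)]

    def snp_at(chrom: str, frac: float) -> tuple[str, int]:
        sub = t[t["chrom"] == chrom]
        row = sub.iloc[int(frac * (len(sub) - 1))]
        return row["snp_id"], int(row["pos"])

    imp_snp, imp_pos = snp_at("1", 0.5)
    cis_snp, cis_pos = snp_at("2", 0.5)
    reg_snp, reg_pos = snp_at("3", 0.5)
    prv_snp, prv_pos = snp_at("3", 0.15)

    effects = [
        PlantedEffect(genes[0], imp_snp, "imprinted_paternal", 0.70),
        PlantedEffect(genes[1], cis_snp, "additive_cis", 0.40),
    ]
    for g in genes[2:6]:
        effects.append(PlantedEffect(g, reg_snp, "additive_trans", 0.25))
    if config.n_genes >= 7:
        effects.append(PlantedEffect(genes[6], prv_snp, "additive_trans", 0.20))

    # gene placement: cis targets sit on their SNP; trans targets live elsewhere
    pos_rows = [
        (genes[0], "1", imp_pos - 10_000, imp_pos + 10_000),
        (genes[1], "2", cis_pos - 10_000, cis_pos + 10_000),
    ]
    chroms = ["1", "2"]
    for k, g in enumerate(genes[2:], start=2):
        chrom = chroms[k % 2]
        length = config.chromosome_lengths_bp[int(chrom) - 1]
        start = int(length * (0.12 + 0.055 * k))
        pos_rows.append((g, chrom, start, start + 20_000))
    gene_positions = GenePositions(
        pd.DataFrame(pos_rows, columns=["gene", "chrom", "start", "end"])
    )

    blocks: tuple[tuple[int, ...], ...]
    if config.coexpression_blocks is not None:
        blocks = config.coexpression_blocks
    else:
        second = tuple(range(7, min(11, config.n_genes)))
        blocks = (tuple(range(2, 6)), second) if len(second) >= 2 else (tuple(range(2, 6)),)

    forced = {}
    # IGF2-like allele: near-fixed in Iberian, common in the dam breeds too
    # (the four ordered-genotype groups all populate, with maternal-A the
    # larger side); flanking SNPs share the frequencies so the region
    # carries allele-level LD
    forced.update(forced_window(snp_map, imp_snp, {"IB": 0.92, "LD": 0.70, "DU": 0.70, "PI": 0.70}))
    forced.update(forced_window(snp_map, cis_snp, {"IB": 0.85, "LD": 0.15, "DU": 0.15, "PI": 0.15}))
    forced.update(forced_window(snp_map, reg_snp, {"IB": 0.85, "LD": 0.15, "DU": 0.15, "PI": 0.15}))
    # private trans effect: segregates only in the second backcross's dams
    forced.update(forced_window(snp_map, prv_snp, {"IB": 0.02, "LD": 0.02, "DU": 0.50, "PI": 0.02}))
    forced.update(config.forced_freqs)
    return genes, effects, gene_positions, blocks, forced


def simulate_expression(
    dosage: np.ndarray,
    paternal_hap: np.ndarray,
    sex: np.ndarray,
    backcross: np.ndarray,
    genes: list[str],
    effects: list[PlantedEffect],
    snp_index: dict[str, int],
    config: SimConfig,
    blocks: tuple[tuple[int, ...], ...],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[RealizedEffect], dict, dict, dict]:
    """Generate true NQ abundances from genotypes and planted effects.

    Effect sizes are solved from the requested PVE against the realized
    genotype (or paternal-indicator) variance; the per-gene log-scale variance
    budget is ``residual_sd**2 / (1 - sum(pve) - h2 - block fraction)``.
    """
    n = dosage.shape[0]
    by_gene: dict[str, list[PlantedEffect]] = {}
    for e in effects:
        by_gene.setdefault(e.gene, []).append(e)

    block_of: dict[int, int] = {}
    for bi, members in enumerate(blocks):
        for gi in members:
            block_of[gi] = bi
    block_factors = rng.standard_normal((len(blocks), n))

    is_female = (sex == "F").astype(float)
    bc_levels = list(dict.fromkeys(backcross))

    realized: list[RealizedEffect] = []
    gene_mu: dict[str, float] = {}
    sex_coef: dict[str, float] = {}
    bc_coef: dict[str, dict[str, float]] = {}
    values = np.zeros((len(genes), n))

    for gi, gene in enumerate(genes):
        planted = by_gene.get(gene, [])
        pve_sum = sum(e.pve for e in planted)
        h2 = config.polygenic_h2
        bfrac = config.block_var_frac if gi in block_of else 0.0
        if pve_sum + h2 + bfrac >= 0.98:
            raise ValidationError(
                f"gene {gene}: planted PVE {pve_sum:.2f} + h2 {h2:.2f} + block "
                f"{bfrac:.2f} leaves no residual variance"
            )
        total_var = config.residual_sd**2 / (1.0 - pve_sum - h2 - bfrac)

        mu = float(rng.normal(0.5, 0.4))
        gene_mu[gene] = mu
        y = np.full(n, mu)

        if rng.random() < config.sex_affected_fraction:
            sign = 1.0 if rng.random() < 0.7 else -1.0  # more genes up in females
            sc = sign * config.sex_effect_size
        else:
            sc = 0.0
        sex_coef[gene] = sc
        y += sc * is_female

        if rng.random() < config.backcross_affected_fraction:
            shifts = {lv: float(rng.normal(0.0, config.backcross_effect_sd)) for lv in bc_levels}
        else:
            shifts = {lv: 0.0 for lv in bc_levels}
        bc_coef[gene] = shifts
        y += np.array([shifts[b] for b in backcross])

        predictors = []
        for e in planted:
            j = snp_index[e.snp_id]
            if e.mode == "imprinted_paternal":
                x = paternal_hap[:, j].astype(float)
            else:
                x = dosage[:, j].astype(float)
            vx = x.var()
            if vx <= 0:
                raise ValidationError(
                    f"planted SNP {e.snp_id} is monomorphic in the realized population"
                )
            beta = float(np.sqrt(e.pve * total_var / vx))
            realized.append(RealizedEffect(gene, e.snp_id, e.mode, e.pve, beta))
            y += beta * x
            predictors.append(x)

        if h2 > 0:
            gamma = rng.standard_normal(dosage.shape[1])
            u = (dosage - dosage.mean(axis=0)) @ gamma
            # h2 and PVE are defined net of the model's fixed effects: remove
            # the polygenic term's backcross-level means (breed allele
            # frequencies differ systematically) and its projection onto the
            # planted predictors (backcross LD is long-range) before scaling,
            # so the requested fractions are the realized ones
            P_cols = [np.ones(n)] + [
                (backcross == lv).astype(float) for lv in bc_levels[1:]
            ] + predictors
            P = np.column_stack(P_cols)
            coef, *_ = np.linalg.lstsq(P, u, rcond=None)
            u = u - P @ coef
            su = u.std()
            if su > 0:
                y += u * np.sqrt(h2 * total_var) / su

        if gi in block_of:
            y += np.sqrt(bfrac * total_var) * block_factors[block_of[gi]]

        y += rng.normal(0.0, config.residual_sd, size=n)
        values[gi] = np.exp(y)

    abundance = pd.DataFrame(values, index=genes)
    return abundance, realized, gene_mu, sex_coef, bc_coef


def simulate_qpcr(
    abundance: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Raw Cq tables with 5-point 4-fold dilution standards per assay.

    Cq = intercept - log_{1+E}(quantity) + Gaussian technical noise, with E the
    per-assay amplification efficiency.  Standard quantities are relative
    (1, 1/4, ..., 1/256), matching a relative-standard-curve design.
    """
    if noise_sd is None:
        noise_sd = config.qpcr_noise_sd
    lo, hi = config.qpcr_efficiency_range
    if not (0.8 < hi <= 1.1 and 0.8 < lo <= 1.1):
        raise ValidationError("qPCR efficiencies must lie in (0.8, 1.1]")
    rows = []
    for assay in abundance.index:
        eff = float(rng.uniform(lo, hi))
        intercept = float(rng.uniform(22.0, 28.0))
        base = np.log(1.0 + eff)
        for q in (4.0 ** -np.arange(5)):
            cq = intercept - np.log(q) / base + rng.normal(0.0, noise_sd)
            rows.append((f"std_{q:g}", assay, cq, 1, True, q))
        for sample, quantity in abundance.loc[assay].items():
            cq = intercept - np.log(quantity) / base + rng.normal(0.0, noise_sd)
            rows.append((sample, assay, cq, 1, False, np.nan))
    return pd.DataFrame(
        rows, columns=["sample", "assay", "Cq", "replicate", "is_standard", "standard_quantity"]
    )


def simulate_population(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Full pipeline input: genotypes, pedigree, expression, qPCR, truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    snp_map = build_snp_map(config)
    m = len(snp_map)
    snp_index = {s: j for j, s in enumerate(snp_map.snp_ids)}
    pos = snp_map.table["pos"].to_numpy()
    chroms = snp_map.table["chrom"].to_numpy()

    if config.effects is None:
        genes, effects, gene_positions, blocks, forced = _default_architecture(config, snp_map)
        config = dataclasses.replace(config, forced_freqs=forced)
    else:
        genes, effects, gene_positions, blocks, _ = _custom_architecture(config, snp_map)

    _check_cis_placement(effects, gene_positions, snp_map)

    founders, founder_ped = simulate_founders(config, snp_map, rng)

    individuals, off_rows = [], []
    pat_hap = np.zeros((sum(config.n_per_backcross), m), dtype=np.int8)
    mat_hap = np.zeros_like(pat_hap)
    sire_phase = np.zeros_like(pat_hap)
    dam_phase = np.zeros_like(pat_hap)
    sexes, bcs = [], []
    i = 0
    for b, bc_name in enumerate(config.backcross_names):
        sires = [s for s, v in founders.sire_backcross.items() if v == bc_name]
        dams = [d for d, v in founders.dam_backcross.items() if v == bc_name]
        for k in range(config.n_per_backcross[b]):
            iid = f"{bc_name}_O{k:03d}"
            # litter-mates share sire and dam (full sibs); sires rotate
            # across litters, giving paternal half-sib families too
            litter = k // config.litter_size
            sire = sires[litter % len(sires)]
            dam = dams[litter]
            g_p, ph_p = simulate_meiosis(founders.sire_haps[sire], pos, chroms, rng)
            g_m, ph_m = simulate_meiosis(founders.dam_haps[dam], pos, chroms, rng)
            pat_hap[i], mat_hap[i] = g_p, g_m
            sire_phase[i], dam_phase[i] = ph_p, ph_m
            sex = "M" if rng.random() < 0.5 else "F"
            individuals.append(iid)
            off_rows.append((iid, sire, dam, sex, bc_name))
            sexes.append(sex)
            bcs.append(bc_name)
            i += 1

    dosage = (pat_hap + mat_hap).astype(float)
    alleles = [("A", "G")] * m  # "A" is the counted allele, alphabetically first
    geno = GenotypeMatrix(individuals, dosage, alleles)
    pedigree = Pedigree(
        pd.concat(
            [
                founder_ped.table,
                pd.DataFrame(
                    off_rows, columns=["individual", "sire", "dam", "sex", "backcross"]
                ),
            ],
            ignore_index=True,
        )
    )

    abundance, realized, gene_mu, sex_coef, bc_coef = simulate_expression(
        dosage, pat_hap, np.array(sexes), np.array(bcs), genes, effects,
        snp_index, config, blocks, rng,
    )
    abundance.columns = individuals

    cq = simulate_qpcr(_with_reference_genes(abundance, config, rng), config, rng)

    truth = TruthSet(
        individuals=individuals,
        snp_ids=list(snp_map.snp_ids),
        paternal_hap=pat_hap,
        maternal_hap=mat_hap,
        paternal_is_iberian=(sire_phase == 0),
        sire_phase=sire_phase,
        dam_phase=dam_phase,
        sire_haps=founders.sire_haps,
        dam_haps=founders.dam_haps,
        effects=realized,
        gene_mu=gene_mu,
        sex_coef=sex_coef,
        backcross_coef=bc_coef,
        blocks=[[genes[gi] for gi in members] for members in blocks],
        log_transform_expected={g: True for g in genes},  # log-normal by construction
        seed=int(config.seed),
    )
    return SimResult(config, geno, snp_map, pedigree, abundance, gene_positions, truth, cq)


def _with_reference_genes(
    abundance: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Append stable reference genes plus one unstable pseudo-reference."""
    n = abundance.shape[1]
    refs = {}
    names = ["REF1", "REF2", "HPRT1L"][: config.n_reference]
    for k, name in enumerate(names):
        sd = 0.05 if k < 2 else 0.5  # the last candidate drifts (HPRT1-like)
        refs[name] = np.exp(rng.normal(1.0, sd, size=n))
    ref_df = pd.DataFrame(refs, index=abundance.columns).T
    return pd.concat([abundance, ref_df])


def _custom_architecture(config: SimConfig, snp_map: SNPMap):
    genes = [f"G{k:02d}" for k in range(1, config.n_genes + 1)]
    effects = list(config.effects or [])
    # place cis targets on their SNP, everything else deterministically spread
    t = snp_map.table.set_index("snp_id")
    pos_rows = []
    cis_genes = {
        e.gene: e.snp_id
        for e in effects
        if e.mode in ("additive_cis", "imprinted_paternal")
    }
    trans_regulators = {
        e.gene: str(t.loc[e.snp_id, "chrom"])
        for e in effects
        if e.mode == "additive_trans"
    }
    for k, g in enumerate(genes):
        if g in cis_genes:
            r = t.loc[cis_genes[g]]
            pos_rows.append((g, str(r["chrom"]), int(r["pos"]) - 10_000, int(r["pos"]) + 10_000))
        else:
            candidates = [
                str(c + 1)
                for c in range(config.n_chromosomes)
                if str(c + 1) != trans_regulators.get(g)
            ] or [str(1 + (k % config.n_chromosomes))]
            chrom = candidates[k % len(candidates)]  # trans targets live elsewhere
            length = config.chromosome_lengths_bp[int(chrom) - 1]
            start = int(length * (0.1 + 0.06 * (k % 12)))
            pos_rows.append((g, chrom, start, start + 20_000))
    gene_positions = GenePositions(
        pd.DataFrame(pos_rows, columns=["gene", "chrom", "start", "end"])
    )
    blocks = config.coexpression_blocks or ()
    return genes, effects, gene_positions, blocks, config.forced_freqs


def _check_cis_placement(effects, gene_positions: GenePositions, snp_map: SNPMap) -> None:
    from .types import bp_distance

    t = snp_map.table.set_index("snp_id")
    for e in effects:
        if e.mode not in ("additive_cis", "imprinted_paternal"):
            continue
        chrom, start, end = gene_positions.locus(e.gene)
        r = t.loc[e.snp_id]
        if str(r["chrom"]) != chrom or bp_distance(int(r["pos"]), start, end) > 1_000_000:
            raise ValidationError(
                f"cis effect for {e.gene} references SNP {e.snp_id} farther than 1 Mb"
            )
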