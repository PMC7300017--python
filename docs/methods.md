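# Methods

`eqtlcross` implements an expression-GWAS (eQTL) pipeline for experimental
pig backcross populations, together with a synthetic-population generator
that plants known effects so every stage can be tested for parameter
recovery. This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic benchmark does and
does not establish about real data.

## Study design being modeled

Three BC1 backcrosses: purebred Iberian boars are crossed to sows of a
commercial breed (Landrace, Duroc or Pietrain); their F1 sons are
backcrossed to purebred sows of the same maternal breed. Every BC1 animal
is therefore 25% Iberian in expectation, carries one gamete from an F1 sire
(a mosaic of one Iberian and one commercial haplotype) and one gamete from
a purebred dam. Muscle expression of a panel of lipid-metabolism candidate
genes is measured by qPCR and scanned against a genome-wide SNP panel.

## qPCR quantification (`qpcr`)

Relative standard-curve method. Per assay, Cq is regressed on
log10(relative quantity) over a dilution series (>= 3 points); the
amplification efficiency is `E = 10^(-1/slope) - 1` and samples are
interpolated as `q = 10^((Cq - intercept)/slope)`. Technical replicates are
averaged on the quantity scale. Candidate reference genes are screened with
a geNorm-style stability statistic: `M_j` is the mean, over the other
candidates, of the SD across samples of `log2(q_j/q_k)`; the two most
stable references are retained and targets are normalized by their
geometric mean to give NQ. NQ is defined up to a per-gene multiplicative
constant (no calibrator sample); nothing downstream depends on that
constant. Per gene, a Shapiro-Wilk test at alpha = 0.05 decides an
all-or-none log2 transform; a constant gene (test undefined) is left
untransformed.

## Fixed-effect screen (`effects`)

Per gene, the additive two-factor linear model `expression ~ sex +
backcross` on the post-transform scale; the reported p-value per term is
the marginal (type-II) F test, so each factor is adjusted for the other but
no interaction is fitted. With a single backcross the sex test reduces
exactly to the equal-variance two-sample t-test (F = t^2). Group summaries
report mean, SEM (SD/sqrt(n)) and stars at 0.05/0.01/0.001. A response with
zero sum of squares for a term yields F = 0 and p = 1.

## Mixed-model association scan (`assoc`)

SNP QC keeps markers with MAF >= 0.05 and missingness <= 0.05 (both
inclusive). The genomic relationship matrix is VanRaden-type:
`K = W W' / sum_j 2 p_j (1-p_j)` with W the mean-imputed, mean-centered
dosage matrix — this scaling makes full sibs average ~0.5, which the tests
assert; K's scale is otherwise irrelevant because the variance ratio
absorbs it. Eigenvalues are clipped at zero (tolerance -1e-8) to guarantee
PSD.

The per-SNP model is `y = W a + x b + u + e`, `u ~ N(0, sg2 K)`,
`e ~ N(0, se2 I)`, fitted by maximum likelihood with everything profiled
out except `lambda = sg2/se2`. K is eigendecomposed once per scan; after
rotation each likelihood evaluation costs two small mat-vecs against
precomputed row outer-products. The profile likelihood in log(lambda) can
be bimodal (a boundary mode near lambda = 0 plus an interior mode), so the
search evaluates a 41-point coarse grid over [1e-5, 1e5] and polishes the
bracket around the best point with bounded Brent (xatol 1e-10 on
log-lambda). The SNP is tested with the Wald statistic `b^2/se^2` against
chi-square(1), with the ML residual variance (RSS/n). Missing dosages are
mean-imputed at scan time, matching the GRM construction; SNPs with > 5%
missingness at scan time are skipped with a warning. Covariates are
intercept + sex, plus backcross dummies when several backcrosses are
present.

FDR control is Benjamini-Hochberg per gene scan (the most conservative
reading of a per-scan q-value); Storey's q is available behind
`storey_qvalues`. eSNPs are called at strict `q < 0.05` (a q exactly at the
threshold is excluded), with 0.10 as the conventional suggestive tier.

Variance explained by one SNP is the partial R^2:
`(RSS_reduced - RSS_full)/RSS_reduced`, reduced = covariates only. The
alternative `beta^2 2pq / var(y)` is not the default because the headline
"variance explained" figures this pipeline reproduces are single-SNP
regression R^2 values.

**LOCO option.** `scan_gene_loco` tests chromosome c against a GRM built
from the other chromosomes. At genome-wide panel sizes the plain and LOCO
scans agree closely, but at the reduced desk panels used in simulation a
single strong region carries a large share of the GRM and partially absorbs
its own signal (proximal contamination); LOCO restores full-panel behavior
and is used in the hotspot-recovery benchmark.

## eQTL intervals and hotspots (`mapper`)

Per gene and chromosome, significant SNPs less than 10 Mb apart belong to
one interval; a gap of exactly 10 Mb splits. Interval bounds are the member
min/max positions and the size is `end - start` with no +1 — the convention
the published interval table follows (a co-located SNP pair spans 0).
Merging precedes the SNP-count filter (>= 2 SNPs in the joint analysis,
>= 3 in a single-backcross analysis). A member SNP is cis when it lies on
the gene's chromosome within 1 Mb of the nearest gene edge (inclusive;
inside the gene is distance 0); intervals are labeled cis, trans or
cis/trans by their members. Annotation windows extend intervals by 1 Mb on
each side, floored at position 1. Hotspots are connected components (>= 1
bp overlap; adjacency tolerance configurable, default 0) of pure-trans
intervals from >= 2 distinct genes on one chromosome.

## Parent-of-origin analysis (`imprint`)

At a biallelic focal SNP, homozygous offspring are trivially phased; a
heterozygous offspring is resolved when either parent is homozygous;
the triple-heterozygous case stays ambiguous (no grandparental phasing —
the resulting attrition, ~7% of offspring at the simulated frequencies,
mirrors what a real pedigree shows). Offspring carrying an allele absent
from both parents are flagged as Mendelian errors and excluded. The
expression test is a one-way model on the four ordered genotypes with the
primary contrast paternal-A {AA, ApGm} versus paternal-G {AmGp, GG} tested
against the pooled residual; compact letters come from pairwise Welch tests
at 0.05 (unadjusted), and an AIC comparison of the paternal-indicator model
against the additive-dosage model flags purely additive signals that would
otherwise masquerade as parent-of-origin effects.

## PCIT co-expression networks (`pcit`)

For every gene trio the three first-order partial correlations are
computed; the trio tolerance is the mean of the three absolute
partial-to-direct ratios, and the x-y edge is flagged for that trio when
`|r_xy| < eps|r_xz|` and `|r_xy| < eps|r_yz|`. An edge survives only if no
trio flags it. Trios containing a perfect correlation are skipped. The
tolerance is deliberately local: for the family `r_xz = r_yz = a, r_xy =
a^2` (partial exactly zero) the edge is removed only for `a < 1/sqrt(3)`.
Display networks keep PCIT-significant edges with `|r| >= 0.6` (applied to
the magnitude; the sign is preserved and negative edges are labeled), drop
isolated nodes and carry node degree. On a two-block benchmark the raw
filter removes ~74% of chance cross-block edges — the 10-gene fixture has
no trio in which all three correlations are weak, which caps the local
rule — while the display network separates the blocks essentially
perfectly; both numbers are reported.

## Synthetic generator (`simulate`)

Founder haplotypes are drawn per breed from Beta(0.7, 0.7) allele
frequencies clipped to (0.02, 0.98), independently per breed, so loci can
segregate in only a subset of backcrosses. Planted loci override these
frequencies; because founders carry no within-breed LD, allele-level LD in
the cross exists only where breeds diverge, so planted regions force a
divergent window over a few flanking SNPs (a breed-differentiated
haplotype, which is also why such loci segregate in these crosses at all).
Meiosis is Haldane on a uniform 1 cM/Mb map: Poisson crossover counts,
uniform positions, no interference; parental origin is carried through, and
litters share sire and dam (full sibs) with sires rotating across litters.

Expression is generated on the natural-log scale as
`mu + sex + backcross + sum(beta*dosage) + beta_imp*[paternal A] +
polygenic + block factor + residual`, then exponentiated (so raw NQ is
log-normal and the Shapiro-Wilk step fires). Planted effect sizes are
solved from the requested PVE against the realized predictor variance with
total variance `residual_sd^2 / (1 - sum(PVE) - h2 - block fraction)`. The
polygenic term is orthogonalized against the backcross factor and the
planted predictors before scaling: breed allele-frequency differences put
group-mean structure into it that the backcross covariate would absorb, and
backcross long-range LD couples it to planted dosages — without the
orthogonalization the realized regression R^2 overshoots the requested PVE
by ~0.02. This makes the generator contract exact: requested PVE equals
realized single-SNP regression R^2 net of the model covariates.
Co-expression blocks are induced by shared latent factors (default variance
fraction 0.55). qPCR simulation draws per-assay efficiency in [0.85, 1.05]
and intercepts in [22, 28], emits five-point four-fold dilution standards,
two stable reference genes and one drifting pseudo-reference, with Gaussian
technical noise (SD 0.15 cycles).

Defaults: the desk profile is 3 x 60 animals, 3 chromosomes x 500 SNPs and
12 genes (chosen for test speed); `SimConfig.study_scale()` restores
114/122/119 animals and `SimConfig.full_scale()` the full panel
(18 autosomes, ~38,430 SNPs, 45 + 3 genes). The default planted
architecture mirrors the study: one major imprinted cis locus (PVE 0.70,
near-fixed in Iberian, common in the dam breeds so all four ordered
genotype groups populate), one additive promoter-like cis locus (PVE 0.40),
a shared trans-regulator driving a four-gene block (PVE 0.25 each), one
backcross-private trans effect, and a second co-expression block. All
randomness flows from the single config seed.

**What the benchmark does not emulate.** Within-breed LD and realistic
haplotype panels (LD arises only from the cross and the planted divergent
windows); genotyping error; array-platform differences; X-chromosome
dosage; selection. Passing recovery tests therefore demonstrates the
statistics and the interval logic under the cross design's LD, not
performance under commercial-panel LD structure.

## Verification experiment sizes

Chosen as the package's own benchmark conditions: mixed-model oracle at
n = 40 with 200 SNPs (grid oracle: 1,000-point log-spaced grid per round,
three zoom rounds, explicit Cholesky GLS); calibration with 1,000 null
replicates (permuted structured phenotypes — an unpermuted polygenic null
leaks ~n*h2/m noncentrality per test at desk panel sizes, an artifact that
vanishes at genome-wide m); cis recovery with 200 replicates of the
355-animal design on a 300-SNP panel; imprinting with 200 replicates;
interval-merge oracle on 1,000 random sets; hotspot recovery with 100
replicates (LOCO scan); PCIT block recovery with 100 replicates at n = 355.

## Known limitations

- ML (not REML) variance ratios make the Wald test mildly anticonservative
  at small n (factor n/(n-k) on the statistic); calibration is asserted at
  the cohort sizes actually used.
- Near-zero Wald statistics cannot be compared to an oracle in purely
  relative terms: profile-likelihood flatness near the optimum bounds any
  optimizer's lambda localization at ~sqrt(machine epsilon), so the oracle
  comparison floors its denominator at 0.01 (absolute agreement there is
  still ~1e-9).
- The cross-platform SNP harmonization of the original design is modeled as
  a single pre-harmonized panel.
- NQ's per-gene constant is arbitrary; only within-gene contrasts are
  meaningful.
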