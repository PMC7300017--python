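"""Parent-of-origin deduction at a focal SNP and the paternal-expression test.

For a biallelic SNP the parental origin of an offspring's alleles follows
from the trio genotypes alone in all but the triple-heterozygous case:
homozygous offspring are trivially phased; a heterozygous offspring is
resolved when either parent is homozygous.  No grandparental phasing is
attempted, mirroring the attrition a real pedigree shows (e.g. 327 of 355
animals resolvable).

The expression test is a one-way linear model on the four ordered genotype
groups with the primary contrast paternal-A {AA, ApGm} versus paternal-G
{AmGp, GG}; pairwise Welch comparisons at 0.05 yield a compact letter
display, and an additive-versus-imprinting AIC comparison is reported to
flag purely additive signals masquerading as parent-of-origin effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import Pedigree, ValidationError

GROUPS = ("AA", "ApGm", "AmGp", "GG")


@dataclass
class OrderedGenotype:
    individual: str
    paternal: str  # allele letter or "?"
    maternal: str
    group: str  # AA | ApGm | AmGp | GG | ambiguous
    mendelian_error: bool = False


def _group(paternal: str, maternal: str, a: str, b: str) -> str:
    if paternal == "?" or maternal == "?":
        return "ambiguous"
    if paternal == a and maternal == a:
        return "AA"
    if paternal == a and maternal == b:
        return "ApGm"
    if paternal == b and maternal == a:
        return "AmGp"
    return "GG"


def deduce_parental_origin(
    genotypes: dict[str, tuple[str, str]],
    pedigree: Pedigree,
    alleles: tuple[str, str] = ("A", "G"),
) -> list[OrderedGenotype]:
    """Deduce each offspring's paternal/maternal allele from trio genotypes.

    ``genotypes`` maps individual -> unordered allele pair at the focal SNP.
    Offspring whose alleles are incompatible with both parents are flagged as
    Mendelian errors and grouped ambiguous.  Group names use the first allele
    as "A" (the expressed-when-paternal allele in the motivating example).
    """
    a, b = alleles
    ped = pedigree.table.set_index("individual")
    out: list[OrderedGenotype] = []
    for ind, pair in genotypes.items():
        if ind not in ped.index:
            continue
        sire, dam = str(ped.loc[ind, "sire"]), str(ped.loc[ind, "dam"])
        if sire == "0" and dam == "0":
            continue  # founder: nothing to deduce
        g = tuple(sorted(pair))
        sire_g = tuple(sorted(genotypes.get(sire, ("?", "?"))))
        dam_g = tuple(sorted(genotypes.get(dam, ("?", "?"))))

        if _mendel_violation(g, sire_g, dam_g):
            out.append(OrderedGenotype(ind, "?", "?", "ambiguous", mendelian_error=True))
            continue

        if g[0] == g[1]:  # homozygote: both origins forced
            pat = mat = g[0]
        else:
            if "?" not in sire_g and sire_g[0] == sire_g[1]:
                pat = sire_g[0]
                mat = g[0] if g[1] == pat else g[1]
            elif "?" not in dam_g and dam_g[0] == dam_g[1]:
                mat = dam_g[0]
                pat = g[0] if g[1] == mat else g[1]
            else:
                pat = mat = "?"
        out.append(OrderedGenotype(ind, pat, mat, _group(pat, mat, a, b)))
    return out


def _mendel_violation(off, sire_g, dam_g) -> bool:
    """True when no assignment of offspring alleles to parents is possible."""
    if "?" in sire_g or "?" in dam_g:
        return False
    for pat, mat in ((off[0], off[1]), (off[1], off[0])):
        if pat in sire_g and mat in dam_g:
            return False
    return True


@dataclass
class ImprintingResult:
    summary: pd.DataFrame  # group, n, mean, sem, letter
    contrast_p: float  # paternal-A vs paternal-G
    contrast_estimate: float
    aic_imprinting: float
    aic_additive: float

    @property
    def prefers_imprinting(self) -> bool:
        return self.aic_imprinting < self.aic_additive


def imprinting_test(
    values: pd.Series, ordered: list[OrderedGenotype], alpha: float = 0.05
) -> ImprintingResult:
    """Test paternal-allele expression across the four ordered genotype groups.

    ``values`` maps individual -> expression on the analysis scale; ambiguous
    individuals are excluded.  The contrast compares the paternal-A groups
    {AA, ApGm} against the paternal-G groups {AmGp, GG} inside the one-way
    group model; per-group means/SEM and compact letters come from pairwise
    Welch tests at ``alpha``.
    """
    groups = {
        o.individual: o.group
        for o in ordered
        if o.group != "ambiguous" and o.individual in values.index
    }
    df = pd.DataFrame(
        {"y": values.loc[list(groups)], "group": [groups[i] for i in groups]}
    )
    present = [g for g in GROUPS if g in set(df["group"])]
    pat_a = [g for g in present if g in ("AA", "ApGm")]
    pat_g = [g for g in present if g in ("AmGp", "GG")]
    if not pat_a or not pat_g:
        raise ValidationError("one side of the paternal contrast is empty")

    # one-way model: group means; contrast tested with the pooled residual
    samples = {g: df.loc[df["group"] == g, "y"].to_numpy() for g in present}
    n_tot = len(df)
    k = len(present)
    rss = sum(((x - x.mean()) ** 2).sum() for x in samples.values())
    df_resid = n_tot - k
    mse = rss / df_resid if df_resid > 0 else np.nan
    est = np.mean([samples[g].mean() for g in pat_a]) - np.mean(
        [samples[g].mean() for g in pat_g]
    )
    var_est = mse * (
        sum(1.0 / len(samples[g]) for g in pat_a) / len(pat_a) ** 2
        + sum(1.0 / len(samples[g]) for g in pat_g) / len(pat_g) ** 2
    )
    tstat = est / np.sqrt(var_est)
    contrast_p = float(2.0 * stats.t.sf(abs(tstat), df_resid))

    letters = _compact_letters(samples, alpha)
    summary = pd.DataFrame(
        [
            (
                g,
                len(samples[g]),
                float(samples[g].mean()),
                float(samples[g].std(ddof=1) / np.sqrt(len(samples[g])))
                if len(samples[g]) > 1
                else 0.0,
                letters[g],
            )
            for g in present
        ],
        columns=["group", "n", "mean", "sem", "letter"],
    )

    y = df["y"].to_numpy()
    x_pat = df["group"].isin(("AA", "ApGm")).to_numpy(dtype=float)
    x_add = df["group"].map({"AA": 2.0, "ApGm": 1.0, "AmGp": 1.0, "GG": 0.0}).to_numpy()
    return ImprintingResult(
        summary=summary,
        contrast_p=contrast_p,
        contrast_estimate=float(est),
        aic_imprinting=_ols_aic(y, x_pat),
        aic_additive=_ols_aic(y, x_add),
    )


def _ols_aic(y: np.ndarray, x: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(y), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = len(y)
    rss = float(resid @ resid)
    return n * np.log(rss / n) + 2 * (X.shape[1] + 1)


def _compact_letters(samples: dict[str, np.ndarray], alpha: float) -> dict[str, str]:
    """Compact letter display via insert-and-absorb over pairwise Welch tests."""
    names = sorted(samples, key=lambda g: -samples[g].mean())
    differ = {
        frozenset((a, b)): _welch_p(samples[a], samples[b]) < alpha
        for a, b in combinations(names, 2)
    }
    letter_sets: list[set[str]] = [set(names)]
    for pair, sig in differ.items():
        if not sig:
            continue
        a, b = tuple(pair)
        for ls in list(letter_sets):
            if a in ls and b in ls:
                letter_sets.remove(ls)
                for dropped in (a, b):
                    new = ls - {dropped}
                    if new and not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    # absorb redundant subsets
    letter_sets = [
        ls for ls in letter_sets
        if not any(ls < other for other in letter_sets)
    ]
    letter_sets.sort(key=lambda ls: min(names.index(g) for g in ls))
    out = {g: "" for g in names}
    for letter, ls in zip("abcdefgh", letter_sets):
        for g in names:
            if g in ls:
                out[g] += letter
    return out


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or len(y) < 2:
        return 1.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def ordered_genotype_table(ordered: list[OrderedGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.individual, o.paternal, o.maternal, o.group, o.mendelian_error) for o in ordered],
        columns=["individual", "paternal", "maternal", "group", "mendelian_error"],
    )
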