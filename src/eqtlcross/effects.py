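"""Sex and backcross effect screening on per-gene expression.

Per-gene two-factor additive linear model (no interaction); the reported
p-value for a term is the marginal (type-II) F test.  Group summaries carry
mean, SEM and significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, Pedigree, ValidationError

TERMS = ("sex", "backcross")


def stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _aligned_factors(expr: ExpressionMatrix, pedigree: Pedigree) -> pd.DataFrame:
    ped = pedigree.table.set_index("individual")
    missing = [i for i in expr.individuals if i not in ped.index]
    if missing:
        raise ValidationError(f"individuals missing from pedigree: {missing[:3]}")
    return ped.loc[expr.individuals, ["sex", "backcross"]]


def group_summary(
    expr: ExpressionMatrix, pedigree: Pedigree, grouping: str
) -> pd.DataFrame:
    """Per-gene, per-level mean and SEM on the analysis scale, with the
    omnibus p-value for the grouping term and its significance stars."""
    if grouping not in TERMS:
        raise ValidationError(f"grouping must be one of {TERMS}")
    fac = _aligned_factors(expr, pedigree)[grouping]
    levels = list(pd.unique(fac))
    pvals = effect_test(expr, pedigree, grouping)
    rows = []
    for gene in expr.genes:
        y = expr.gene_values(gene)
        for lv in levels:
            x = y[(fac == lv).to_numpy()]
            if len(x) < 2:
                raise ValidationError(f"{gene}: level {lv!r} has <2 observations")
            mean = float(np.mean(x))
            sem = float(np.std(x, ddof=1) / np.sqrt(len(x)))
            p = float(pvals[gene])
            rows.append((gene, grouping, lv, len(x), mean, sem, p, stars(p)))
    return pd.DataFrame(
        rows, columns=["gene", "grouping", "level", "n", "mean", "sem", "p", "stars"]
    )


def _design(fac: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(fac))]
    for term in terms:
        dummies = pd.get_dummies(fac[term], drop_first=True)
        cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def effect_test(
    expr: ExpressionMatrix, pedigree: Pedigree, term: str
) -> pd.Series:
    """Marginal F-test p-value for ``term`` in NQ ~ sex + backcross, per gene.

    With a single backcross present the model degrades to NQ ~ sex and the
    sex test equals an equal-variance two-sample t-test (F = t^2).
    """
    if term not in TERMS:
        raise ValidationError(f"term must be one of {TERMS}")
    fac = _aligned_factors(expr, pedigree)
    active = [t for t in TERMS if fac[t].nunique() > 1]
    if term not in active:
        raise ValidationError(f"term {term!r} has a single level in these data")
    X_full = _design(fac, tuple(active))
    X_red = _design(fac, tuple(t for t in active if t != term))
    n, p_full = X_full.shape
    df_term = p_full - X_red.shape[1]
    if np.linalg.matrix_rank(X_full) < p_full:
        raise ValidationError(f"design matrix rank-deficient including term {term!r}")
    out = {}
    for gene in expr.genes:
        y = expr.gene_values(gene)
        rss_full, _ = _rss(X_full, y)
        rss_red, _ = _rss(X_red, y)
        df_resid = n - p_full
        num = max(rss_red - rss_full, 0.0) / df_term
        den = rss_full / df_resid
        if den == 0.0:
            out[gene] = 1.0 if num == 0.0 else 0.0
            continue
        f = num / den
        out[gene] = float(stats.f.sf(f, df_term, df_resid))
    return pd.Series(out, name=f"p_{term}")
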