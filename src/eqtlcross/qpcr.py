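"""Relative-standard-curve qPCR quantification and NQ normalization.

The quantification chain is: fit a per-assay standard curve (Cq on
log10 relative quantity) from the dilution series, interpolate sample Cq
values back to relative quantities, screen candidate reference genes for
stability (geNorm-style M value), and divide each target quantity by the
geometric mean of the accepted references to obtain the normalized quantity
(NQ).  Per-gene normality is then checked with a Shapiro-Wilk test and a
log2 transform applied where it fails.

NQ is defined up to a per-gene multiplicative constant (no calibrator sample
is used); none of the downstream inference depends on that constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, ValidationError


@dataclass
class StandardCurve:
    """Least-squares line of Cq on log10(relative quantity).

    Efficiency E = 10^(-1/slope) - 1; a perfect doubling per cycle gives
    slope -3.3219 and E = 1.
    """

    assay: str
    slope: float
    intercept: float
    efficiency: float
    r2: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError(f"{self.assay}: standard-curve slope must be negative")
        if not 0.0 < self.efficiency <= 1.5:
            raise ValidationError(f"{self.assay}: implausible efficiency {self.efficiency:.3f}")


def fit_standard_curve(dilutions: pd.DataFrame, assay: str = "") -> StandardCurve:
    """Fit the relative standard curve from a dilution series.

    ``dilutions`` needs columns ``Cq`` and ``standard_quantity`` (relative
    quantities, e.g. 1, 1/4, ... ).  At least three points are required.
    """
    d = dilutions.dropna(subset=["Cq", "standard_quantity"])
    if len(d) < 3:
        raise ValidationError(f"{assay}: need >=3 dilution points, got {len(d)}")
    x = np.log10(d["standard_quantity"].to_numpy(dtype=float))
    y = d["Cq"].to_numpy(dtype=float)
    slope, intercept, r, _, _ = stats.linregress(x, y)
    eff = 10.0 ** (-1.0 / slope) - 1.0 if slope < 0 else np.inf
    return StandardCurve(assay, float(slope), float(intercept), float(eff), float(r**2))


def quantify(cq: np.ndarray | float, curve: StandardCurve) -> np.ndarray | float:
    """Relative quantity from Cq: 10**((Cq - intercept)/slope), monotone
    decreasing in Cq."""
    cq = np.asarray(cq, dtype=float)
    if not np.isfinite(cq).all():
        raise ValidationError("Cq values must be finite")
    q = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return float(q) if q.ndim == 0 else q


def reference_stability(quantities: pd.DataFrame, candidates: list[str]) -> pd.Series:
    """geNorm-style stability M per candidate reference gene (lower = stabler).

    M_j is the mean, over the other candidates k, of the standard deviation
    across samples of log2(q_j / q_k).  Two perfectly proportional references
    have M = 0.
    """
    if len(candidates) < 2:
        raise ValidationError("need >=2 candidate reference genes")
    logq = np.log2(quantities.loc[candidates].to_numpy(dtype=float))
    m_values = {}
    for i, g in enumerate(candidates):
        sds = [
            np.std(logq[i] - logq[k], ddof=1)
            for k in range(len(candidates))
            if k != i
        ]
        m_values[g] = float(np.mean(sds))
    return pd.Series(m_values).sort_values()


def normalize_nq(
    targets: pd.DataFrame, references: pd.DataFrame
) -> ExpressionMatrix:
    """NQ = target quantity / geometric mean of the reference quantities.

    Both frames are genes x samples on the quantity scale; columns must align.
    """
    refs = references.to_numpy(dtype=float)
    if (refs <= 0).any():
        raise ValidationError("reference quantities must be > 0")
    if list(targets.columns) != list(references.columns):
        raise ValidationError("target/reference sample columns do not align")
    geo = np.exp(np.log(refs).mean(axis=0))
    nq = targets.to_numpy(dtype=float) / geo[None, :]
    return ExpressionMatrix(pd.DataFrame(nq, index=targets.index, columns=targets.columns))


def quantify_assays(cq_table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Run the full per-assay quantification from a raw Cq table.

    The table follows the simulator layout (sample, assay, Cq, replicate,
    is_standard, standard_quantity).  Technical replicates are averaged on the
    quantity scale.  Returns the assay x sample quantity matrix and the fitted
    curves.
    """
    curves: dict[str, StandardCurve] = {}
    frames = []
    for assay, sub in cq_table.groupby("assay", sort=False):
        std = sub[sub["is_standard"].astype(bool)]
        curve = fit_standard_curve(std, assay)
        curves[assay] = curve
        samples = sub[~sub["is_standard"].astype(bool)]
        q = quantify(samples["Cq"].to_numpy(dtype=float), curve)
        df = pd.DataFrame({"sample": samples["sample"].values, "q": q})
        frames.append(df.groupby("sample", sort=False)["q"].mean().rename(assay))
    quantities = pd.DataFrame(frames)
    quantities.columns.name = None
    return quantities, curves


def normality_transform(expr: ExpressionMatrix, alpha: float = 0.05) -> ExpressionMatrix:
    """Per-gene Shapiro-Wilk screen; log2-transform genes that fail.

    Genes with Shapiro-Wilk p < ``alpha`` have their values replaced by
    log2(NQ) and the per-gene flag set; already-transformed genes are left
    alone.  A constant gene (Shapiro-Wilk undefined) is left untransformed and
    flagged degenerate via the returned matrix's ``log2`` dict (False).
    """
    values = expr.values.copy()
    flags = dict(expr.log2)
    for gene in values.index:
        if flags.get(gene, False):
            continue
        x = values.loc[gene].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValidationError(f"{gene}: need >=3 observations for normality check")
        if np.ptp(x) == 0.0:
            continue  # degenerate: SW undefined, leave as is
        p = stats.shapiro(x).pvalue
        if p < alpha:
            if (x <= 0).any():
                raise ValidationError(f"{gene}: non-positive NQ, cannot log-transform")
            values.loc[gene] = np.log2(x)
            flags[gene] = True
    return ExpressionMatrix(values, flags)
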