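"""PCIT co-expression networks: partial-correlation + information-theory filter.

For every gene trio (x, y, z) the three first-order partial correlations are
computed; the trio's tolerance epsilon is the mean of the three absolute
partial-to-direct ratios (a magnitude, as in the reference implementation of
the algorithm), and the x-y association is flagged non-significant for that
trio when |r_xy| < eps * |r_xz| and |r_xy| < eps * |r_yz|.  An edge survives
only if no trio flags it.  Display edges additionally require |r| >= 0.6
(sign preserved; negative correlations are reported distinctly).

Note the tolerance is local: an edge whose partial correlation given z is
exactly zero is only discarded when its direct correlation also falls below
the trio tolerance (for the family r_xz = r_yz = a, r_xy = a^2 this happens
for a < 1/sqrt(3) ~ 0.577; a stronger trio keeps the edge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

R_DISPLAY = 0.6


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation across samples; zero-variance genes are
    dropped with a warning."""
    if len(expr.individuals) < 3:
        raise ValidationError("need >=3 samples for correlations")
    values = expr.values
    sd = values.std(axis=1, ddof=1)
    dropped = list(values.index[sd == 0])
    if dropped:
        logger.warning("dropping zero-variance genes: %s", dropped)
        values = values.drop(index=dropped)
    r = np.corrcoef(values.to_numpy(dtype=float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


def pcit_filter(corr: pd.DataFrame) -> pd.DataFrame:
    """Boolean kept-edge mask over the correlation matrix.

    Trios containing a perfect correlation (|r| = 1 off-diagonal) have
    undefined partials and are skipped with a warning.  With fewer than three
    genes the condition is vacuous and every edge is kept.
    """
    r = corr.to_numpy(dtype=float)
    m = r.shape[0]
    if r.shape[0] != r.shape[1] or not np.allclose(r, r.T, atol=1e-12):
        raise ValidationError("correlation matrix must be square and symmetric")
    keep = np.ones((m, m), dtype=bool)
    np.fill_diagonal(keep, False)
    if m < 3:
        return pd.DataFrame(keep, index=corr.index, columns=corr.columns)

    eye = np.eye(m, dtype=bool)
    warned = False
    for z in range(m):
        rz = r[:, z]
        denom_sq = (1.0 - rz[:, None] ** 2) * (1.0 - rz[None, :] ** 2)
        degenerate = np.abs(rz) >= 1.0 - 1e-12
        degenerate[z] = False
        if degenerate.any() and not warned:
            logger.warning("perfect correlation with gene %s; trios skipped", corr.index[z])
            warned = True
        with np.errstate(divide="ignore", invalid="ignore"):
            # partial of every pair given z, and of each pair member with z given the other
            p_xy_z = (r - rz[:, None] * rz[None, :]) / np.sqrt(denom_sq)
            p_xz_y = (rz[:, None] - r * rz[None, :]) / np.sqrt(
                (1.0 - r**2) * (1.0 - rz[None, :] ** 2)
            )
            p_yz_x = (rz[None, :] - r * rz[:, None]) / np.sqrt(
                (1.0 - r**2) * (1.0 - rz[:, None] ** 2)
            )
            eps = (
                np.abs(p_xy_z / r)
                + np.abs(p_xz_y / rz[:, None])
                + np.abs(p_yz_x / rz[None, :])
            ) / 3.0
            flag = (np.abs(r) < eps * np.abs(rz[:, None])) & (
                np.abs(r) < eps * np.abs(rz[None, :])
            )
        flag &= ~np.isnan(eps)
        flag[np.abs(r) >= 1.0 - 1e-12] = False  # perfect pair: trio undefined
        flag[degenerate, :] = False
        flag[:, degenerate] = False
        flag[z, :] = False
        flag[:, z] = False
        flag[eye] = False
        keep &= ~flag
    keep = keep & keep.T
    return pd.DataFrame(keep, index=corr.index, columns=corr.columns)


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph  # nodes: genes; edge attrs: r, sign; node attr: degree

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["r"], d["sign"]) for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "sign"])


def threshold_and_export(
    corr: pd.DataFrame,
    kept: pd.DataFrame,
    r_min: float = R_DISPLAY,
    edge_tsv: str | Path | None = None,
    graphml: str | Path | None = None,
) -> CoexpressionNetwork:
    """Build the display network: PCIT-kept edges with |r| >= r_min.

    Isolated nodes are dropped; node degree is stored as an attribute; signed
    correlations are preserved so negative edges can be drawn distinctly.
    Optionally writes an edge-list TSV and GraphML.
    """
    genes = list(corr.index)
    g = nx.Graph()
    rk = kept.to_numpy()
    rv = corr.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rk[i, j] and abs(rv[i, j]) >= r_min:
                g.add_edge(
                    genes[i],
                    genes[j],
                    r=float(rv[i, j]),
                    sign="negative" if rv[i, j] < 0 else "positive",
                )
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    net = CoexpressionNetwork(g)
    if edge_tsv is not None:
        net.edge_table().to_csv(edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(g, graphml)
    return net


def pcit_filter_naive(corr: pd.DataFrame) -> pd.DataFrame:
    """Reference triple-loop implementation used as a cross-check in tests."""
    r = corr.to_numpy(dtype=float)
    m = r.shape[0]
    keep = np.ones((m, m), dtype=bool)
    np.fill_diagonal(keep, False)

    def partial(a, b, c):
        den = (1.0 - r[a, c] ** 2) * (1.0 - r[b, c] ** 2)
        return (r[a, b] - r[a, c] * r[b, c]) / np.sqrt(den)

    for x in range(m):
        for y in range(m):
            if x == y:
                continue
            for z in range(m):
                if z in (x, y):
                    continue
                if (
                    abs(r[x, z]) >= 1.0 - 1e-12
                    or abs(r[y, z]) >= 1.0 - 1e-12
                    or abs(r[x, y]) >= 1.0 - 1e-12
                ):
                    continue
                eps = (
                    abs(partial(x, y, z) / r[x, y])
                    + abs(partial(x, z, y) / r[x, z])
                    + abs(partial(y, z, x) / r[y, z])
                ) / 3.0
                if abs(r[x, y]) < eps * abs(r[x, z]) and abs(r[x, y]) < eps * abs(
                    r[y, z]
                ):
                    keep[x, y] = False
                    break
    keep = keep & keep.T
    return pd.DataFrame(keep, index=corr.index, columns=corr.columns)
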