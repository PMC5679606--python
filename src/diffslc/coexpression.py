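"""Pairwise gene-coexpression measures and edge annotation.

Three measures of association between two expression profiles are supported:
Pearson (linear), Spearman (monotone, rank-based, average ranks on ties), and
distance correlation (dCor), which detects non-monotone dependence and is
zero in population only under independence. dCor is the default edge weight:
it is non-negative by construction, so it never reduces the degree bias the
way a negative Pearson or Spearman weight would.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
import networkx as nx

from diffslc.io import IdMap
from diffslc.network import edge_key

__all__ = [
    "pearson",
    "spearman",
    "distance_correlation",
    "edge_coexpression",
    "COEXPRESSION_METHODS",
]

log = logging.getLogger(__name__)


class ConstantInputError(ValueError):
    """Correlation is undefined for a constant vector; the caller decides the fallback."""


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return x, y


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient, in [-1, 1]."""
    x, y = _validate_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Pearson correlation undefined for constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman rank correlation, average ranks on ties, in [-1, 1]."""
    x, y = _validate_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman correlation undefined for constant input")
    return float(scipy.stats.spearmanr(x, y).statistic)


def distance_correlation(x, y) -> float:
    """Empirical distance correlation dCor(x, y) in [0, 1].

    The standard univariate estimator: pairwise Euclidean distance matrices
    |x_i - x_j| are double-centered, dCov^2 is the mean of their elementwise
    product, and dCor = dCov / sqrt(dVar(x) * dVar(y)). If either distance
    variance is zero (a constant vector), returns 0 by convention.
    """
    x, y = _validate_pair(x, y)
    ax = _centered_distances(x)
    ay = _centered_distances(y)
    dcov2 = float(np.mean(ax * ay))
    dvar_x = float(np.mean(ax * ax))
    dvar_y = float(np.mean(ay * ay))
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        return 0.0
    # rounding can push dcov2 a hair negative for near-independent data
    dcor2 = max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)
    return float(min(np.sqrt(dcor2), 1.0))


def _centered_distances(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


COEXPRESSION_METHODS = {
    "pearson": pearson,
    "spearman": spearman,
    "dcor": distance_correlation,
}


def edge_coexpression(
    net: nx.Graph,
    expr: pd.DataFrame,
    idmap: IdMap,
    method: str = "dcor",
    absolute: bool = False,
    missing_value: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Coexpression of the two endpoint expression profiles, per edge.

    For each edge whose endpoints both map to probesets present in ``expr``,
    computes the chosen measure of their profiles. Edges with an unmapped
    endpoint (or a constant profile, for pearson/spearman) receive
    ``missing_value`` and are counted in a logged summary. ``absolute`` takes
    |r| for the signed measures, so anticorrelation also counts as bias.
    """
    if method not in COEXPRESSION_METHODS:
        raise ValueError(
            f"unknown coexpression method {method!r}; valid: {sorted(COEXPRESSION_METHODS)}"
        )
    fn = COEXPRESSION_METHODS[method]
    values: dict[tuple[str, str], float] = {}
    n_missing = 0
    for u, v in net.edges():
        key = edge_key(u, v)
        pu, pv = idmap.get(u), idmap.get(v)
        if pu is None or pv is None or pu not in expr.index or pv not in expr.index:
            values[key] = missing_value
            n_missing += 1
            continue
        try:
            r = fn(expr.loc[pu].to_numpy(), expr.loc[pv].to_numpy())
        except ConstantInputError:
            values[key] = missing_value
            n_missing += 1
            continue
        values[key] = abs(r) if absolute else r
    if n_missing:
        log.info("%d/%d edges had no usable expression pair; default %.3g used",
                 n_missing, net.number_of_edges(), missing_value)
    return values
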