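"""Ranking evaluation against an essential-gene label set.

A centrality ranking is treated as a binary classifier of essentiality:
every gene not on the essential list is assumed non-essential, giving a
conservative estimate of success. The layer computes confusion matrices at
a top-k cutoff, ROC and precision-recall curves with trapezoid AUC, top-k%
(and uniquely-found) essential counts across methods, pairwise overlap of
top slices, and the AUC landscape over the (beta, omega) grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from diffslc.centrality import (
    CentralityScores,
    biased_degree_centrality,
    diffslc,
    eigenvector_centrality,
    rank_nodes,
)
from diffslc.io import EssentialSet
from diffslc.network import EdgeWeights

__all__ = [
    "ConfusionMatrix",
    "EvalCurve",
    "label_nodes",
    "confusion_at_top_k",
    "roc_curve",
    "pr_curve",
    "auc_roc",
    "top_percent_hits",
    "ranking_overlap",
    "parameter_sweep",
    "bootstrap_auc_ci",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    recall = tpr


@dataclass
class EvalCurve:
    """An ROC ((FPR, TPR) points, with AUC) or PR ((recall, precision)) curve."""

    kind: str
    points: list[tuple[float, float]]
    auc: float | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = ("fpr", "tpr") if self.kind == "roc" else ("recall", "precision")
        return pd.DataFrame(self.points, columns=list(cols))


def label_nodes(
    net: nx.Graph,
    essentials: EssentialSet,
    node_to_gene: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Binary essentiality labels: 1 iff the node's gene is on the list.

    Every unlisted gene is labeled 0 — there is no "unknown" class, which
    makes the evaluation a conservative lower bound on true performance.
    ``node_to_gene`` defaults to the identity map.
    """
    labels = {}
    for node in net.nodes():
        gene = node_to_gene[node] if node_to_gene is not None else node
        labels[node] = 1 if gene in essentials else 0
    return labels


def _ordered_labels(scores: CentralityScores | Mapping[str, float],
                    labels: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels aligned in ranked order (desc score, asc node ID)."""
    mapping = scores.scores if isinstance(scores, CentralityScores) else scores
    order = rank_nodes(mapping)
    y = np.array([labels[n] for n in order], dtype=int)
    s = np.array([mapping[n] for n in order], dtype=float)
    return s, y


def confusion_at_top_k(
    scores: CentralityScores | Mapping[str, float],
    labels: Mapping[str, int],
    k: int,
) -> ConfusionMatrix:
    """Confusion matrix when the top-k ranked nodes are called positive."""
    _, y = _ordered_labels(scores, labels)
    if not 0 <= k <= y.size:
        raise ValueError(f"k must be in [0, {y.size}]")
    pos = int(y.sum())
    tp = int(y[:k].sum())
    fp = k - tp
    fn = pos - tp
    tn = (y.size - pos) - fp
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def roc_curve(scores, labels: Mapping[str, int]) -> EvalCurve:
    """ROC curve over all score thresholds, with trapezoid AUC.

    Nodes sharing a score cross each threshold together, so tie order cannot
    inflate the curve; the trapezoid over a tied block equals the Mann-Whitney
    convention of counting tied positive-negative pairs as 1/2. The AUC is
    the probability that a random essential node outranks a random
    non-essential one.
    """
    s, y = _ordered_labels(scores, labels)
    pos = int(y.sum())
    neg = y.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires at least one positive and one negative label")
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # last index of each distinct-score block: the whole block crosses together
    block_ends = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    tpr = np.concatenate(([0.0], tps[block_ends] / pos))
    fpr = np.concatenate(([0.0], fps[block_ends] / neg))
    auc = float(np.trapezoid(tpr, fpr))
    return EvalCurve("roc", list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


def auc_roc(scores, labels: Mapping[str, int]) -> float:
    return roc_curve(scores, labels).auc


def pr_curve(scores, labels: Mapping[str, int]) -> EvalCurve:
    """Precision-recall curve at every threshold.

    The zero-prediction point is omitted: precision is undefined there and
    is not imputed.
    """
    s, y = _ordered_labels(scores, labels)
    pos = int(y.sum())
    if pos == 0:
        raise ValueError("PR curve requires at least one positive label")
    tps = np.cumsum(y)
    ks = np.arange(1, y.size + 1)
    block_ends = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    recall = tps[block_ends] / pos
    precision = tps[block_ends] / ks[block_ends]
    return EvalCurve("pr", list(zip(recall.tolist(), precision.tolist())))


def top_percent_hits(
    scores_list: Sequence[CentralityScores],
    labels: Mapping[str, int],
    percents: Iterable[float] = (1, 5, 10, 15, 20, 25),
) -> pd.DataFrame:
    """Essential-gene counts in each method's top p% slice, plus unique counts.

    The slice size is floor(p * N / 100). "unique" is the number of essential
    nodes found in that method's slice and in no other method's slice at the
    same p — the statistic that shows what each variant contributes beyond
    the rest.
    """
    percents = list(percents)
    if any(not 0 < p <= 100 for p in percents):
        raise ValueError("percents must lie in (0, 100]")
    n = len(labels)
    rankings = {s.method: s.ranking() for s in scores_list}
    rows = []
    for p in percents:
        k = int(np.floor(p * n / 100))
        slices = {
            m: {node for node in ranking[:k] if labels[node] == 1}
            for m, ranking in rankings.items()
        }
        for method, hits in slices.items():
            others = set().union(*(s for m, s in slices.items() if m != method)) if len(slices) > 1 else set()
            rows.append({
                "method": method,
                "percent": p,
                "k": k,
                "hits": len(hits),
                "unique": len(hits - others),
            })
    return pd.DataFrame(rows)


def ranking_overlap(
    scores_a: CentralityScores,
    scores_b: CentralityScores,
    labels: Mapping[str, int],
    percent: float,
) -> tuple[int, int, int]:
    """Venn partition (shared, only_a, only_b) of essentials in two top slices."""
    if set(scores_a.scores) != set(scores_b.scores):
        raise ValueError("rankings must cover the same node universe")
    k = int(np.floor(percent * len(labels) / 100))
    hits_a = {n for n in scores_a.ranking()[:k] if labels[n] == 1}
    hits_b = {n for n in scores_b.ranking()[:k] if labels[n] == 1}
    return len(hits_a & hits_b), len(hits_a - hits_b), len(hits_b - hits_a)


def parameter_sweep(
    net: nx.Graph,
    weights: EdgeWeights,
    labels: Mapping[str, int],
    beta_grid: Iterable[float],
    omega_grid: Iterable[float],
    normalization: str = "ec_max",
) -> pd.DataFrame:
    """ROC AUC of DiffSLC over every (beta, omega) grid pair.

    EC and the per-node coexpression / ECC sums are computed once; each grid
    cell is then a linear remix, identical to an independent full DiffSLC
    evaluation at that pair.
    """
    beta_grid = list(beta_grid)
    omega_grid = list(omega_grid)
    if not beta_grid or not omega_grid:
        raise ValueError("grids must be non-empty")
    ec = eigenvector_centrality(net)
    # BDC(beta) = beta * coexpr_sum + (1 - beta) * ecc_sum per node
    bdc0 = biased_degree_centrality(net, weights, beta=0.0)  # ecc sums
    bdc1 = biased_degree_centrality(net, weights, beta=1.0)  # coexpr sums
    rows = []
    for beta in beta_grid:
        bdc = CentralityScores(
            "bdc",
            {n: beta * bdc1[n] + (1 - beta) * bdc0[n] for n in net.nodes()},
            {"beta": beta},
        )
        for omega in omega_grid:
            scores = diffslc(net, weights, beta=beta, omega=omega,
                             normalization=normalization,
                             ec_scores=ec, bdc_scores=bdc)
            rows.append({"beta": beta, "omega": omega, "auc": auc_roc(scores, labels)})
    return pd.DataFrame(rows)


def bootstrap_auc_ci(
    scores,
    labels: Mapping[str, int],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the ROC AUC (off by default in pipelines)."""
    mapping = scores.scores if isinstance(scores, CentralityScores) else scores
    nodes = sorted(mapping)
    rng = np.random.default_rng(seed)
    s = np.array([mapping[n] for n in nodes])
    y = np.array([labels[n] for n in nodes])
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(nodes), size=len(nodes))
        ys = y[idx]
        if ys.min() == ys.max():
            continue
        aucs.append(_auc_mann_whitney(s[idx], ys))
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _auc_mann_whitney(s: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    ranks = rankdata(s)
    pos = y == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
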