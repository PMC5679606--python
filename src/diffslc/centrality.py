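"""Node centralities for essential-protein ranking.

Implements the classical centralities used as baselines under the
centrality-lethality hypothesis — degree (DC), closeness (CC, harmonic
form), betweenness (BC), eigenvector (EC), subgraph (SC) — and the
coexpression-biased scores:

    BDC(u)     = sum over incident edges of [beta * coexpr + (1 - beta) * ECC]
    DiffSLC(u) = omega * EC(u) + (1 - omega) * BDC(u)

EC rewards nodes attached to other high-scoring nodes, so DiffSLC can
recover essential proteins of low degree that sit next to hubs; the BDC
term pulls in interactions that are both coexpressed and embedded in
triangles. beta and omega each live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import scipy.linalg

from diffslc.network import EdgeWeights, edge_key

__all__ = [
    "CentralityScores",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "subgraph_centrality",
    "biased_degree_centrality",
    "diffslc",
    "compute_centrality",
    "CENTRALITY_METHODS",
    "rank_nodes",
]

# full eigendecomposition guard for subgraph centrality
_SC_DENSE_LIMIT = 6000


@dataclass
class CentralityScores:
    """Per-node scores for one method, with the parameters that produced them."""

    method: str
    scores: dict[str, float]
    params: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.array(list(self.scores.values()), dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError(f"{self.method}: non-finite scores")

    def __getitem__(self, node: str) -> float:
        return self.scores[node]

    def ranking(self) -> list[str]:
        """Nodes by descending score, ties broken by ascending node ID."""
        return rank_nodes(self.scores)


def rank_nodes(scores: Mapping[str, float]) -> list[str]:
    return [n for n, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]


def degree_centrality(net: nx.Graph) -> CentralityScores:
    """DC(u): the number of edges incident to u."""
    return CentralityScores("dc", {n: float(d) for n, d in net.degree()})


def closeness_centrality(net: nx.Graph, mode: str = "harmonic") -> CentralityScores:
    """CC(u) = sum over v != u of 1 / d(u, v), unreachable pairs contributing 0.

    This harmonic form handles disconnected interaction graphs gracefully.
    ``mode="classic"`` instead returns 1 / sum(d(u, v)) over u's own
    component (Sabidussi's inverse farness).
    """
    if mode == "harmonic":
        return CentralityScores("cc", {n: float(s) for n, s in nx.harmonic_centrality(net).items()},
                                {"mode": mode})
    if mode == "classic":
        scores = {}
        for n in net.nodes():
            dists = nx.single_source_shortest_path_length(net, n)
            total = sum(d for v, d in dists.items() if v != n)
            scores[n] = 1.0 / total if total > 0 else 0.0
        return CentralityScores("cc", scores, {"mode": mode})
    raise ValueError(f"unknown closeness mode {mode!r}")


def betweenness_centrality(net: nx.Graph) -> CentralityScores:
    """BC(u) = sum over unordered pairs i != u != j of sigma_ij(u) / sigma_ij."""
    raw = nx.betweenness_centrality(net, normalized=False)
    return CentralityScores("bc", {n: float(s) for n, s in raw.items()})


def eigenvector_centrality(
    net: nx.Graph,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    weights: Mapping[tuple[str, str], float] | None = None,
) -> CentralityScores:
    """EC(u): principal eigenvector of the adjacency matrix, max entry 1.

    Computed by power iteration from a deterministic uniform start vector so
    results are bit-reproducible. Iteration runs on A + I, which shares A's
    eigenvectors but cannot oscillate on bipartite components. Nodes outside
    the dominant component converge to ~0. With ``weights``, A holds the
    given edge weights instead of 0/1 entries.

    Raises if the iteration has not converged (successive normalized vectors
    within ``tol`` in the max norm) after ``max_iter`` steps.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if weights is None:
        adj = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csr", dtype=float)
    else:
        g = net.copy()
        for u, v in g.edges():
            g[u][v]["weight"] = float(weights[edge_key(u, v)])
        adj = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr", dtype=float)

    x = np.full(n, 1.0 / np.sqrt(n))
    residual = np.inf
    for _ in range(max_iter):
        y = adj @ x + x  # (A + I) x : spectral shift, same eigenvectors
        norm = np.linalg.norm(y)
        if norm == 0.0:  # edgeless graph: every vector is an eigenvector
            break
        y /= norm
        residual = np.max(np.abs(y - x))
        x = y
        if residual <= tol:
            break
    else:
        raise RuntimeError(f"power iteration did not converge: residual {residual:.3e}")
    x = np.abs(x)
    top = x.max()
    if top > 0:
        x = x / top
    return CentralityScores("ec", {node: float(x[index[node]]) for node in nodes},
                            {"tol": tol, "weighted": weights is not None})


def subgraph_centrality(net: nx.Graph, dense_limit: int = _SC_DENSE_LIMIT) -> CentralityScores:
    """SC(u) = sum_j (v_j^u)^2 exp(lambda_j): diagonal of expm(A).

    Counts closed walks from u weighted by 1/length!, so short cycles (network
    motifs) dominate. Computed by full symmetric eigendecomposition; graphs
    above ``dense_limit`` nodes are refused rather than silently swapping to
    an approximation.
    """
    n = net.number_of_nodes()
    if n == 0:
        return CentralityScores("sc", {})
    if n > dense_limit:
        raise ValueError(
            f"subgraph centrality needs a full eigendecomposition; {n} nodes exceeds "
            f"the {dense_limit}-node guard (raise dense_limit to override)"
        )
    nodes = sorted(net.nodes())
    adj = nx.to_numpy_array(net, nodelist=nodes, dtype=float)
    eigvals, eigvecs = scipy.linalg.eigh(adj)
    diag = (eigvecs ** 2) @ np.exp(eigvals)
    return CentralityScores("sc", {node: float(diag[i]) for i, node in enumerate(nodes)})


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return value


def biased_degree_centrality(
    net: nx.Graph, weights: EdgeWeights, beta: float = 0.8
) -> CentralityScores:
    """BDC(u): degree centrality biased by coexpression and edge clustering.

    Each incident edge contributes beta * coexpr + (1 - beta) * ECC; beta = 1
    reduces to a coexpression-sum, beta = 0 to an ECC-weighted degree.
    """
    beta = _check_unit("beta", beta)
    scores: dict[str, float] = {}
    for u in net.nodes():
        total = 0.0
        for v in net[u]:
            key = edge_key(u, v)
            total += beta * weights.coexpr[key] + (1.0 - beta) * weights.ecc[key]
        scores[u] = total
    return CentralityScores("bdc", scores, {"beta": beta})


def diffslc(
    net: nx.Graph,
    weights: EdgeWeights,
    beta: float = 0.8,
    omega: float = 0.1,
    normalization: str = "ec_max",
    ec_scores: CentralityScores | None = None,
    bdc_scores: CentralityScores | None = None,
) -> CentralityScores:
    """DiffSLC(u) = omega * EC(u) + (1 - omega) * BDC(u).

    omega = 1 reduces to eigenvector centrality, omega = 0 to BDC. Under the
    default ``normalization="ec_max"`` EC is rescaled to max 1 (its usual
    scale) and BDC enters raw; ``"minmax"`` min-max scales both terms to
    [0, 1] before mixing, making omega a true convex mixture weight.
    Precomputed ``ec_scores``/``bdc_scores`` may be supplied to avoid
    recomputation across a parameter sweep; BDC's beta must then match.
    """
    beta = _check_unit("beta", beta)
    omega = _check_unit("omega", omega)
    if normalization not in ("ec_max", "minmax"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ec = ec_scores if ec_scores is not None else eigenvector_centrality(net)
    bdc = bdc_scores if bdc_scores is not None else biased_degree_centrality(net, weights, beta)
    if bdc.params.get("beta") != beta:
        raise ValueError("supplied bdc_scores were computed with a different beta")

    ec_vals = {n: ec[n] for n in net.nodes()}
    bdc_vals = {n: bdc[n] for n in net.nodes()}
    if normalization == "minmax":
        ec_vals = _minmax(ec_vals)
        bdc_vals = _minmax(bdc_vals)
    scores = {n: omega * ec_vals[n] + (1.0 - omega) * bdc_vals[n] for n in net.nodes()}
    return CentralityScores(
        "diffslc", scores, {"beta": beta, "omega": omega, "normalization": normalization}
    )


def _minmax(scores: dict[str, float]) -> dict[str, float]:
    values = np.array(list(scores.values()))
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {n: 0.0 for n in scores}
    return {n: (s - lo) / (hi - lo) for n, s in scores.items()}


CENTRALITY_METHODS: dict[str, Callable] = {
    "dc": degree_centrality,
    "cc": closeness_centrality,
    "bc": betweenness_centrality,
    "ec": eigenvector_centrality,
    "sc": subgraph_centrality,
}


def compute_centrality(
    method: str,
    net: nx.Graph,
    weights: EdgeWeights | None = None,
    **params,
) -> CentralityScores:
    """Dispatch a centrality computation by method name.

    ``"bdc"`` and ``"diffslc"`` require ``weights``; the five classical
    centralities ignore them.
    """
    if method in CENTRALITY_METHODS:
        return CENTRALITY_METHODS[method](net, **params)
    if method in ("bdc", "diffslc"):
        if weights is None:
            raise ValueError(f"{method} requires edge weights")
        fn = biased_degree_centrality if method == "bdc" else diffslc
        return fn(net, weights, **params)
    valid = sorted(CENTRALITY_METHODS) + ["bdc", "diffslc"]
    raise ValueError(f"unknown centrality method {method!r}; valid: {valid}")
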