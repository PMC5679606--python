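"""End-to-end workflows: build the network, rank nodes, evaluate rankings.

Each step is a plain function over the library modules so that anything the
command line can do is equally available (and identical) from Python. A
`RunConfig` captures every knob of a run; it is echoed into output headers
so results are traceable to their parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from diffslc import centrality, coexpression, evaluation, io, network

__all__ = ["RunConfig", "BuildResult", "run_build", "run_rank", "run_evaluate", "run_sweep"]

log = logging.getLogger(__name__)

DEFAULT_PERCENTS = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    mitab: str | None = None
    expression: str | None = None
    annotations: str | None = None
    essential: str | None = None
    synonyms: str | None = None
    taxon: int | None = None
    coexpr_method: str | None = "dcor"    # None -> no coexpression (an unweighted run)
    abs_coexpr: bool = False
    beta: float = 0.8
    omega: float = 0.1
    methods: tuple[str, ...] = ("dc", "cc", "bc", "ec", "sc", "diffslc")
    percents: tuple[float, ...] = DEFAULT_PERCENTS
    normalization: str = "ec_max"
    ecc_denominator: str = "degree"
    min_component_size: int = 4           # components smaller than this are dropped
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.beta <= 1 or not 0 <= self.omega <= 1:
            raise ValueError("beta and omega must lie in [0, 1]")
        if self.coexpr_method is not None and \
                self.coexpr_method not in coexpression.COEXPRESSION_METHODS:
            raise ValueError(f"unknown coexpression method {self.coexpr_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("methods", "percents"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BuildResult:
    net: nx.Graph
    weights: network.EdgeWeights
    idmap: io.IdMap
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_build(config: RunConfig) -> BuildResult:
    """MITAB -> cleaned network + ID map + edge weights, with stage counts.

    Stages mirror the curation pipeline: taxon filter, dedup/self-loop
    removal, small-component removal, then edge annotation with ECC and
    (optionally) coexpression.
    """
    if config.mitab is None:
        raise FileNotFoundError("config.mitab is required for build")
    records = io.read_mitab(config.mitab, taxon_filter=config.taxon)
    net = network.build_network(records)
    counts = {
        "records": len(records),
        "nodes_raw": net.number_of_nodes(),
        "edges_raw": net.number_of_edges(),
    }
    net = network.filter_small_components(net, max_size=config.min_component_size - 1)
    counts["nodes_filtered"] = net.number_of_nodes()
    counts["edges_filtered"] = net.number_of_edges()
    log.info("network: %(nodes_raw)d/%(edges_raw)d raw -> "
             "%(nodes_filtered)d/%(edges_filtered)d after component filter", counts)

    idmap = io.IdMap()
    coexpr_map = None
    if config.coexpr_method is not None and config.expression and config.annotations:
        expr = io.read_expression_matrix(config.expression)
        annotations = pd.read_csv(config.annotations, sep=None, engine="python")
        idmap = io.build_id_map(records, annotations, expr)
        counts["unmapped_interactors"] = len(idmap.unmapped)
        coexpr_map = coexpression.edge_coexpression(
            net, expr, idmap, method=config.coexpr_method, absolute=config.abs_coexpr
        )
    weights = network.all_edge_weights(net, coexpr_map, denominator=config.ecc_denominator)
    return BuildResult(net=net, weights=weights, idmap=idmap, stage_counts=counts)


def run_rank(config: RunConfig, build: BuildResult) -> dict[str, centrality.CentralityScores]:
    """Compute every requested centrality on the built network."""
    results = {}
    for method in config.methods:
        if method == "diffslc":
            scores = centrality.diffslc(build.net, build.weights,
                                        beta=config.beta, omega=config.omega,
                                        normalization=config.normalization)
        elif method == "bdc":
            scores = centrality.biased_degree_centrality(build.net, build.weights,
                                                         beta=config.beta)
        else:
            scores = centrality.compute_centrality(method, build.net)
        results[method] = scores
    return results


def run_evaluate(
    config: RunConfig,
    build: BuildResult,
    rankings: dict[str, centrality.CentralityScores],
) -> dict:
    """ROC/PR curves, AUCs, and top-k% tables for every ranking."""
    if config.essential is None:
        raise FileNotFoundError("config.essential is required for evaluate")
    essentials = io.read_essential_list(config.essential, synonyms=config.synonyms)
    labels = evaluation.label_nodes(build.net, essentials)
    out = {"labels": labels, "auc": {}, "roc": {}, "pr": {}}
    for method, scores in rankings.items():
        curve = evaluation.roc_curve(scores, labels)
        out["auc"][method] = curve.auc
        out["roc"][method] = curve
        out["pr"][method] = evaluation.pr_curve(scores, labels)
    out["top_percent"] = evaluation.top_percent_hits(
        list(rankings.values()), labels, config.percents
    )
    return out


def run_sweep(
    config: RunConfig,
    build: BuildResult,
    beta_grid,
    omega_grid,
) -> pd.DataFrame:
    """AUC landscape of DiffSLC over the (beta, omega) grid."""
    if config.essential is None:
        raise FileNotFoundError("config.essential is required for sweep")
    essentials = io.read_essential_list(config.essential, synonyms=config.synonyms)
    labels = evaluation.label_nodes(build.net, essentials)
    return evaluation.parameter_sweep(build.net, build.weights, labels,
                                      beta_grid, omega_grid,
                                      normalization=config.normalization)
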