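"""Coupled synthetic fixtures: PPI network, essentiality, expression, ID map.

The generator emulates the statistical structure asserted by the
centrality-lethality hypothesis: a scale-free-like interaction graph
(preferential attachment) in which hubs are more likely to be essential,
and expression profiles in which interacting partners — especially those of
essential proteins — are coexpressed through shared latent factors. All
artifacts can be written in the exact on-disk formats the readers consume
(MITAB 2.5, expression TSV, annotation table, gene list), so every pipeline
stage is testable without downloads.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from diffslc.io import (
    EssentialSet,
    IdMap,
    InteractionRecord,
    write_expression_matrix,
    write_mitab,
)

__all__ = [
    "FixtureSpec",
    "simulate_ppi",
    "plant_essentiality",
    "simulate_expression",
    "simulate_all",
    "write_fixture",
    "SYNTHETIC_TAXON",
]

# taxon id stamped on synthetic MITAB records (budding yeast)
SYNTHETIC_TAXON = 4932


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a mid-sized interactome snapshot: 2000 proteins grown
    by preferential attachment with 3 edges per arrival, ~20% of genes
    essential (the approximate essential fraction of the curated yeast
    interactome), a clear but not deterministic degree-essentiality link,
    and 36 expression samples as in a dense yeast time-course.
    """

    n_nodes: int = 2000
    attachment_edges: int = 3
    essential_fraction: float = 0.2
    degree_bias: float = 1.5
    n_samples: int = 36
    edge_coexpr_boost: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0
    n_satellites: int = 0          # extra 2-3 node components, to exercise filtering
    unmapped_fraction: float = 0.0  # nodes left without a probeset
    decoy_fraction: float = 0.0     # nodes given a second, higher-expression probeset

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.attachment_edges < 0:
            raise ValueError("attachment_edges must be >= 0")
        if not 0 < self.essential_fraction < 1:
            raise ValueError("essential_fraction must be in (0, 1)")
        if self.degree_bias < 0:
            raise ValueError("degree_bias must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.edge_coexpr_boost <= 1:
            raise ValueError("edge_coexpr_boost must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def simulate_ppi(spec: FixtureSpec) -> nx.Graph:
    """Scale-free-like undirected simple graph by preferential attachment.

    Deterministic under ``spec.seed``. ``n_satellites`` appends that many
    disconnected 2-3-node components (alternating edges and paths) so the
    small-component filter has something to remove.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_nodes == 1 or spec.attachment_edges == 0:
        net: nx.Graph = nx.empty_graph(spec.n_nodes)
    else:
        m = min(spec.attachment_edges, spec.n_nodes - 1)
        net = nx.barabasi_albert_graph(spec.n_nodes, m, seed=int(rng.integers(2**31)))
    net = nx.relabel_nodes(net, {i: _node_name(i) for i in net.nodes()})
    offset = spec.n_nodes
    for s in range(spec.n_satellites):
        size = 2 + s % 2
        members = [_node_name(offset + j) for j in range(size)]
        nx.add_path(net, members)
        offset += size
    return net


def plant_essentiality(net: nx.Graph, spec: FixtureSpec) -> EssentialSet:
    """Mark nodes essential with probability logistic in (standardized) degree.

    P(essential | degree k) = sigmoid(a + degree_bias * z(k)) with the
    intercept a solved so the expected essential fraction matches the spec.
    degree_bias = 0 therefore gives essentiality independent of topology.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nodes = sorted(net.nodes())
    degrees = np.array([net.degree(n) for n in nodes], dtype=float)
    sd = degrees.std()
    z = (degrees - degrees.mean()) / sd if sd > 0 else np.zeros_like(degrees)

    def excess(a: float) -> float:
        return float(np.mean(expit(a + spec.degree_bias * z))) - spec.essential_fraction

    intercept = brentq(excess, -50, 50)
    p = expit(intercept + spec.degree_bias * z)
    essential = rng.random(len(nodes)) < p
    return EssentialSet(genes={EssentialSet.normalize(n) for n, e in zip(nodes, essential) if e})


def simulate_expression(
    net: nx.Graph, essentials: EssentialSet, spec: FixtureSpec
) -> tuple[pd.DataFrame, IdMap, pd.DataFrame]:
    """Expression profiles coupled along edges, plus the probeset ID map.

    Each edge carries a shared latent factor (a Gaussian sample path over the
    ``n_samples`` conditions). A node's profile is its own Gaussian noise plus
    ``edge_coexpr_boost`` times the variance-normalized weighted sum of its
    incident edge factors; edges touching an essential node carry four times
    the relative weight of other edges. The per-node normalization keeps the
    factor component at unit variance regardless of degree, so hubs are not
    drowned in their own factors. With the boost at 0 profiles are pure noise
    and edges carry no coexpression signal.

    One probeset per node by default. ``unmapped_fraction`` of nodes get no
    probeset (exercising the missing-data rule); ``decoy_fraction`` get a
    second probeset with strictly higher mean expression, so the
    lowest-expression mapping rule is observable. Returns the expression
    matrix, the ID map, and the annotation table (probeset_id, uniprot_acc,
    ensembl_id) linking them.
    """
    rng = np.random.default_rng(spec.seed + 2)
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    m = spec.n_samples
    profiles = rng.normal(0.0, spec.noise_sd, size=(len(nodes), m))
    factor_sum = np.zeros_like(profiles)
    loading_ss = np.zeros(len(nodes))  # sum of squared loadings per node
    for u, v in sorted(net.edges()):
        factor = rng.normal(0.0, 1.0, size=m)
        touches_essential = (u in essentials) or (v in essentials)
        loading = 1.0 if touches_essential else 0.25
        for node in (u, v):
            factor_sum[index[node]] += loading * factor
            loading_ss[index[node]] += loading ** 2
    active = loading_ss > 0
    if spec.edge_coexpr_boost > 0 and active.any():
        scale = spec.edge_coexpr_boost * spec.noise_sd / np.sqrt(loading_ss[active])
        profiles[active] += scale[:, None] * factor_sum[active]

    n = len(nodes)
    n_unmapped = int(round(spec.unmapped_fraction * n))
    n_decoy = int(round(spec.decoy_fraction * n))
    shuffled = list(rng.permutation(nodes))
    unmapped = set(shuffled[:n_unmapped])
    decoys = set(shuffled[n_unmapped:n_unmapped + n_decoy])

    rows, ann_rows, idmap = [], [], IdMap()
    probeset_names = []
    for node in nodes:
        if node in unmapped:
            idmap.provenance[node] = "unmapped"
            continue
        probeset = f"{node}_at"
        probeset_names.append(probeset)
        rows.append(profiles[index[node]])
        ann_rows.append({"probeset_id": probeset, "uniprot_acc": f"U_{node}",
                         "ensembl_id": f"ENS_{node}"})
        idmap.entries[node] = probeset
        idmap.provenance[node] = "uniprot"
        if node in decoys:
            decoy_name = f"{node}_x_at"
            probeset_names.append(decoy_name)
            # strictly higher mean: shift the true profile upward
            rows.append(profiles[index[node]] + 3.0 * spec.noise_sd)
            ann_rows.append({"probeset_id": decoy_name, "uniprot_acc": f"U_{node}",
                             "ensembl_id": f"ENS_{node}"})
    expr = pd.DataFrame(
        np.array(rows), index=probeset_names,
        columns=[f"sample_{j:02d}" for j in range(m)],
    )
    annotations = pd.DataFrame(ann_rows, columns=["probeset_id", "uniprot_acc", "ensembl_id"])
    return expr, idmap, annotations


def simulate_all(spec: FixtureSpec):
    """Generate the full coupled fixture: (net, essentials, expr, idmap, annotations)."""
    net = simulate_ppi(spec)
    essentials = plant_essentiality(net, spec)
    expr, idmap, annotations = simulate_expression(net, essentials, spec)
    return net, essentials, expr, idmap, annotations


def _records_from_network(net: nx.Graph) -> list[InteractionRecord]:
    records = []
    for u, v in sorted(net.edges()):
        records.append(InteractionRecord(
            interactor_a=u, interactor_b=v,
            taxon_a=SYNTHETIC_TAXON, taxon_b=SYNTHETIC_TAXON,
            xrefs_a=(("dip", u), ("uniprotkb", f"U_{u}"), ("ensembl", f"ENS_{u}")),
            xrefs_b=(("dip", v), ("uniprotkb", f"U_{v}"), ("ensembl", f"ENS_{v}")),
        ))
    return records


def write_fixture(directory: str | Path, spec: FixtureSpec) -> dict:
    """Write a complete fixture to ``directory`` and return its manifest.

    Emits ``interactions.mitab``, ``expression.tsv``, ``annotations.tsv``,
    ``essential_genes.txt`` and ``manifest.yaml``. Reading the files back
    through the io layer reproduces the in-memory objects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net, essentials, expr, idmap, annotations = simulate_all(spec)

    write_mitab(_records_from_network(net), directory / "interactions.mitab")
    write_expression_matrix(expr, directory / "expression.tsv")
    annotations.to_csv(directory / "annotations.tsv", sep="\t", index=False)
    with open(directory / "essential_genes.txt", "w") as handle:
        handle.write("# synthetic essential-gene list\n")
        for gene in sorted(essentials.genes):
            handle.write(gene + "\n")
    manifest = {
        "spec": asdict(spec),
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_essential": len(essentials),
        "n_probesets": int(expr.shape[0]),
        "files": {
            "mitab": "interactions.mitab",
            "expression": "expression.tsv",
            "annotations": "annotations.tsv",
            "essential": "essential_genes.txt",
        },
    }
    with open(directory / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return manifest
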