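"""Compound-target-disease network construction and key-target screening.

The screening funnel mirrors the classical network-pharmacology workflow:

1. compounds pass at oral bioavailability >= ``ob_min`` AND drug-likeness
   >= ``dl_min`` (both inclusive), with an allow-list for
   literature-supported compounds that fail the gate;
2. compound->target predictions pass at probability strictly greater than
   ``prob_min``, deduplicated per (compound, target) keeping the maximum;
3. disease genes pass at relevance strictly greater than the median of
   all input relevance scores;
4. an undirected simple tripartite graph is built, each target node
   labelled drug-only / disease-only / common;
5. key targets are the nodes whose degree exceeds ``multiplier`` x the
   median degree (strict) and whose betweenness and closeness centralities
   are not lower than their medians.

Centrality conventions match Cytoscape's NetworkAnalyzer: betweenness is
normalised by (n-1)(n-2)/2 and closeness uses the component-scaled form
(r-1)/(n-1) x (r-1)/sum(d), so disconnected graphs still yield values
in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger("tcqe")

ROLE_COMPOUND = "compound"
ROLE_DRUG = "drug_target"
ROLE_DISEASE = "disease_target"
ROLE_COMMON = "common_target"
TARGET_ROLES = {ROLE_DRUG, ROLE_DISEASE, ROLE_COMMON}


def filter_compounds(
    compounds: pd.DataFrame,
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    allow_list: set[str] | None = None,
) -> pd.DataFrame:
    """Keep compounds with ob >= ob_min and dl >= dl_min (inclusive).

    ``allow_list`` force-includes compounds by id regardless of their
    scores (e.g. pharmacopoeia index compounds added from the literature).
    """
    allow = set(allow_list or ())
    keep = ((compounds["ob"] >= ob_min) & (compounds["dl"] >= dl_min)) | compounds[
        "id"
    ].isin(allow)
    out = compounds.loc[keep].reset_index(drop=True)
    log.info(
        "filter_compounds: %d -> %d (ob>=%g, dl>=%g, %d allow-listed)",
        len(compounds), len(out), ob_min, dl_min, len(allow),
    )
    return out


def filter_predictions(predictions: pd.DataFrame, prob_min: float = 0.1) -> pd.DataFrame:
    """Keep predictions with probability strictly greater than prob_min.

    Duplicate (compound, target) pairs collapse to one row carrying the
    maximum probability.
    """
    probs = predictions["probability"]
    if ((probs < 0) | (probs > 1)).any():
        bad = probs[(probs < 0) | (probs > 1)].iloc[0]
        raise ValidationError(f"prediction probability outside [0, 1]: {bad}")
    out = (
        predictions.loc[probs > prob_min]
        .sort_values("probability", kind="stable")
        .drop_duplicates(subset=["compound_id", "target_id"], keep="last")
        .sort_index()
        .reset_index(drop=True)
    )
    log.info(
        "filter_predictions: %d -> %d (probability > %g, deduplicated)",
        len(predictions), len(out), prob_min,
    )
    return out


def screen_disease_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Keep genes whose relevance strictly exceeds the median relevance.

    The median is computed over *all* input scores (even count -> mean of
    the central pair), so at most half the genes can survive.
    """
    if len(genes) == 0:
        raise ValidationError("screen_disease_genes: empty gene table")
    cutoff = float(np.median(genes["relevance"].to_numpy(dtype=float)))
    out = genes.loc[genes["relevance"] > cutoff].reset_index(drop=True)
    log.info(
        "screen_disease_genes: %d -> %d (relevance > median %g)",
        len(genes), len(out), cutoff,
    )
    return out


def build_network(
    compounds: pd.DataFrame,
    predictions: pd.DataFrame,
    disease_genes: pd.DataFrame,
) -> nx.Graph:
    """Assemble the undirected simple compound-target-disease graph.

    Compound-target edges come from the (filtered) prediction table;
    disease genes enter as nodes even when no compound targets them.
    Node attribute ``role`` is one of compound / drug_target /
    disease_target / common_target; a target is common iff it is both a
    predicted drug target and a screened disease gene.
    """
    if len(compounds) == 0:
        raise ValidationError("build_network: no active compounds")
    compound_ids = set(compounds["id"])
    edges = predictions[predictions["compound_id"].isin(compound_ids)]
    drug_targets = set(edges["target_id"])
    disease = set(disease_genes["gene_id"])

    g = nx.Graph()
    for cid in compounds["id"]:
        g.add_node(cid, role=ROLE_COMPOUND)
    for t in sorted(drug_targets | disease):
        if t in drug_targets and t in disease:
            role = ROLE_COMMON
        elif t in drug_targets:
            role = ROLE_DRUG
        else:
            role = ROLE_DISEASE
        g.add_node(t, role=role)
    for _, row in edges.iterrows():
        c, t = row["compound_id"], row["target_id"]
        if c != t:  # no self-loops
            g.add_edge(c, t, probability=float(row["probability"]))
    log.info(
        "build_network: %d compounds, %d drug targets, %d disease genes, "
        "%d common targets, %d edges",
        len(compound_ids), len(drug_targets), len(disease),
        len(drug_targets & disease), g.number_of_edges(),
    )
    return g


def compute_topology(graph: nx.Graph) -> pd.DataFrame:
    """Degree, normalised betweenness and component-scaled closeness per node.

    Isolated nodes get betweenness 0 and closeness 0.  Returns a frame
    indexed by node id with columns degree / betweenness / closeness / role.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("compute_topology: empty network")
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    rows = []
    for node in graph.nodes:
        rows.append(
            {
                "node_id": node,
                "degree": graph.degree[node],
                "betweenness": betweenness[node],
                "closeness": closeness[node],
                "role": graph.nodes[node].get("role", ""),
            }
        )
    return pd.DataFrame(rows).set_index("node_id")


@dataclass
class KeyTargetScreen:
    """Outcome of the topological key-target screen."""

    median_degree: float
    median_betweenness: float
    median_closeness: float
    degree_threshold: float
    targets: pd.DataFrame = field(repr=False)  # survivors ranked by degree

    @property
    def target_ids(self) -> list[str]:
        return list(self.targets.index)


def screen_key_targets(
    topology: pd.DataFrame,
    multiplier: float = 2.0,
    scope: str = "targets",
    include_isolated: bool = False,
) -> KeyTargetScreen:
    """Screen key targets by degree and centrality against scope medians.

    ``scope`` selects the nodes over which medians are computed and from
    which survivors may be drawn: ``"targets"`` (default) restricts to
    target-role nodes, ``"all"`` uses every node.  Isolated nodes are
    excluded from the scope unless ``include_isolated`` is set.

    Survivors need degree strictly greater than ``multiplier`` x median
    degree AND betweenness >= its median AND closeness >= its median;
    they are ranked by degree descending, ties broken by closeness
    descending then node id.
    """
    if scope == "targets":
        pool = topology[topology["role"].isin(TARGET_ROLES)]
    elif scope == "all":
        pool = topology
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    if not include_isolated:
        pool = pool[pool["degree"] > 0]
    if len(pool) == 0:
        raise ValidationError("screen_key_targets: scope selects no nodes")

    med_deg = float(pool["degree"].median())
    med_bet = float(pool["betweenness"].median())
    med_clo = float(pool["closeness"].median())
    threshold = multiplier * med_deg
    keep = pool[
        (pool["degree"] > threshold)
        & (pool["betweenness"] >= med_bet)
        & (pool["closeness"] >= med_clo)
    ]
    ranked = keep.sort_values(
        by=["degree", "closeness", "node_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    log.info(
        "screen_key_targets: %d in scope -> %d key targets "
        "(degree > %g, betweenness >= %g, closeness >= %g)",
        len(pool), len(ranked), threshold, med_bet, med_clo,
    )
    return KeyTargetScreen(
        median_degree=med_deg,
        median_betweenness=med_bet,
        median_closeness=med_clo,
        degree_threshold=threshold,
        targets=ranked,
    )


def export_sif(graph: nx.Graph, path) -> None:
    """Write the network as a simple-interaction-format (SIF) file."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(graph.edges):
            fh.write(f"{u}\ttargets\t{v}\n")
        for node in sorted(n for n in graph.nodes if graph.degree[n] == 0):
            fh.write(f"{node}\n")


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
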