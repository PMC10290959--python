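"""Reaction-step distances between genes and metabolites.

A gene and a metabolite participating in the same reaction are at distance
1; a pair in consecutive reactions (reactions sharing a non-currency
metabolite) is at distance 2, and so on. Traversal is undirected and
reversibility annotations are ignored. Currency metabolites (water, ATP,
NAD...) are removed from connectivity entirely: they create no
reaction-to-reaction edges, and distances to a currency metabolite are
reported undefined. Pairs beyond ``distance_cap`` (default 10), or with a
gene/metabolite absent from the network, have undefined distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig, ReactionNetwork

DEFAULT_CURRENCY = frozenset({
    "h2o", "h", "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
    "co2", "pi", "ppi", "o2", "coa",
})


@dataclass
class ReactionGraph:
    """Reaction-adjacency view of a :class:`ReactionNetwork`."""

    reaction_graph: nx.Graph
    gene_reactions: dict[str, set[str]] = field(default_factory=dict)
    metabolite_reactions: dict[str, set[str]] = field(default_factory=dict)


def build_graph(
    network: ReactionNetwork, currency: set[str] | None = None
) -> ReactionGraph:
    """Build the reaction graph: two reactions are adjacent when they share
    at least one non-currency metabolite. Genes attach to the reactions
    they catalyze, metabolites to the reactions they participate in."""
    currency = set(
        network.currency_metabolites if currency is None else currency
    )
    g = nx.Graph()
    met_to_rxn: dict[str, set[str]] = {}
    gene_reactions: dict[str, set[str]] = {}
    for r in network.reactions:
        g.add_node(r.reaction_id)
        for m in r.metabolites:
            if m in currency:
                continue
            met_to_rxn.setdefault(m, set()).add(r.reaction_id)
        for gene in r.genes:
            gene_reactions.setdefault(gene, set()).add(r.reaction_id)
    for m, rxns in met_to_rxn.items():
        rxns = sorted(rxns)
        for i in range(len(rxns)):
            for j in range(i + 1, len(rxns)):
                g.add_edge(rxns[i], rxns[j])
    return ReactionGraph(
        reaction_graph=g,
        gene_reactions=gene_reactions,
        metabolite_reactions=met_to_rxn,
    )


def gene_metabolite_distance(
    graph: ReactionGraph, gene: str, metabolite: str, cap: int = 10
) -> int | None:
    """Reaction-step distance: 1 + minimum reaction-to-reaction hops from
    any reaction catalyzed by the gene to any reaction containing the
    metabolite. None when either endpoint is absent or no path exists
    within ``cap``."""
    sources = graph.gene_reactions.get(gene)
    targets = graph.metabolite_reactions.get(metabolite)
    if not sources or not targets:
        return None
    if sources & targets:
        return 1
    hops = nx.multi_source_dijkstra_path_length(
        graph.reaction_graph, sources, cutoff=cap - 1, weight=None
    )
    best = min((hops[t] for t in targets if t in hops), default=None)
    if best is None:
        return None
    d = int(best) + 1
    return d if d <= cap else None


def classify_proximal(
    distance: int | None, config: AnalysisConfig | None = None
) -> bool:
    """Proximal = defined distance of at most ``proximal_max_distance``
    (default 2: same reaction or consecutive reactions)."""
    max_d = (config or AnalysisConfig()).proximal_max_distance
    return distance is not None and distance <= max_d


def compute_distances(
    graph: ReactionGraph,
    genes,
    metabolites,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Distance table for a gene x metabolite grid.

    One breadth-first pass per gene, reused for all metabolites. Columns:
    gene, metabolite, distance (NaN when undefined), proximal.
    """
    config = config or AnalysisConfig()
    cap = config.distance_cap
    rows = []
    for gene in sorted(genes):
        sources = graph.gene_reactions.get(gene)
        hops = (
            nx.multi_source_dijkstra_path_length(
                graph.reaction_graph, sources, cutoff=cap - 1, weight=None
            )
            if sources
            else {}
        )
        for met in sorted(metabolites):
            targets = graph.metabolite_reactions.get(met)
            d: int | None = None
            if sources and targets:
                best = min(
                    (hops[t] for t in targets if t in hops), default=None
                )
                if best is not None and best + 1 <= cap:
                    d = int(best) + 1
            rows.append({
                "gene": gene,
                "metabolite": met,
                "distance": np.nan if d is None else d,
                "proximal": classify_proximal(d, config),
            })
    return pd.DataFrame(rows, columns=["gene", "metabolite", "distance",
                                       "proximal"])


def proximal_enrichment(
    gmi_table: pd.DataFrame,
    distance_table: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict:
    """Fisher's exact test of significant x proximal over the pairs with a
    defined network distance.

    ``gmi_table`` needs columns x_id (metabolite), y_id (gene) and
    significant; ``distance_table`` is the output of
    :func:`compute_distances`. Returns the 2x2 table, sample odds ratio
    (NaN when a margin is zero) and the two-sided p-value.
    """
    dist = distance_table.dropna(subset=["distance"])
    dist_idx = dist.set_index(["gene", "metabolite"])["proximal"]
    merged = gmi_table.copy()
    keys = list(zip(merged["y_id"], merged["x_id"]))
    merged["proximal"] = [dist_idx.get(k, None) for k in keys]
    merged = merged.dropna(subset=["proximal"])
    sig = merged["significant"].astype(bool)
    prox = merged["proximal"].astype(bool)
    table = np.array([
        [int((sig & prox).sum()), int((sig & ~prox).sum())],
        [int((~sig & prox).sum()), int((~sig & ~prox).sum())],
    ])
    a, b = table[0]
    c, d = table[1]
    undefined = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if undefined:
        odds, p = float("nan"), float("nan")
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    # Haldane-Anscombe +0.5 keeps the reported effect finite when a single
    # cell (not a margin) is empty
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return {
        "table": table,
        "odds_ratio": float(odds),
        "odds_ratio_haldane": float(haldane) if not undefined else float("nan"),
        "p": float(p),
        "n_pairs_with_distance": int(len(merged)),
    }
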