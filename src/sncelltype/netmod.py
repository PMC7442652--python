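"""Cell-type PPI networks, module detection, and GO over-representation.

A cell type's network is the node-induced subgraph of a global PPI graph
on that type's specificity gene set. Modules are found by multi-level
modularity optimization (Louvain) on the unweighted graph; modules with
more than ``min_module_size`` genes (default 30, exclusive) are retained
and labelled ``<celltype>_M1``, ``<celltype>_M2``, ... by decreasing
size. GO over-representation is the one-sided Fisher exact
(hypergeometric upper-tail) test of each term against a gene universe.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def induce_celltype_network(
    network: igraph.Graph, gene_set: list[str] | set[str], set_name: str = "set"
) -> igraph.Graph:
    """Node-induced subgraph on the gene set's intersection with the graph.

    Isolated nodes stay in the node list (community detection ignores
    them); an empty intersection is an error naming the set.
    """
    names = set(network.vs["name"])
    members = [g for g in gene_set if g in names]
    if not members:
        raise ValueError(f"gene set {set_name!r} shares no genes with the network")
    return network.induced_subgraph(
        [v.index for v in network.vs if v["name"] in set(members)]
    )


@dataclass
class ModuleSet:
    """Retained modules of one cell-type network plus partition metadata."""

    cell_type: str
    modules: dict[str, list[str]]  # id -> genes, only modules > min size
    all_modules: list[list[str]]  # every community, unfiltered
    modularity: float
    min_module_size: int

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)


def detect_modules(
    network: igraph.Graph,
    seed: int = 0,
    cell_type: str = "celltype",
    min_module_size: int = 30,
) -> ModuleSet:
    """Louvain modules of an unweighted network; > min_module_size kept.

    Isolated nodes are excluded before optimization. Node order is
    shuffled under the seed (the greedy sweep is order-dependent); the
    returned partition's modularity refers to the non-isolated subgraph.
    """
    if network.ecount() == 0:
        raise ValueError("cannot detect modules in an edgeless network")
    if "weight" in network.es.attributes():
        log.info("edge weights present; ignored (modules use unweighted edges)")
    core = network.induced_subgraph(
        [v.index for v in network.vs if network.degree(v.index) > 0]
    )
    rng = random.Random(seed)
    order = list(range(core.vcount()))
    rng.shuffle(order)
    shuffled = core.permute_vertices(order)
    igraph.set_random_number_generator(random.Random(seed))
    part = shuffled.community_multilevel()
    comms = [
        [shuffled.vs[i]["name"] for i in comm] for comm in part
    ]
    comms.sort(key=lambda c: (-len(c), c))
    retained = {
        f"{cell_type}_M{i + 1}": sorted(c)
        for i, c in enumerate(c for c in comms if len(c) > min_module_size)
    }
    return ModuleSet(
        cell_type=cell_type,
        modules=retained,
        all_modules=[sorted(c) for c in comms],
        modularity=float(shuffled.modularity(part.membership)),
        min_module_size=min_module_size,
    )


def go_overrepresentation(
    query_genes: list[str] | set[str],
    terms: dict[str, list[str]],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """One-sided Fisher over-representation of each term in the query.

    p = P[X >= overlap] with X ~ Hypergeom(|universe|, |term ∩ universe|,
    |query|). Terms with no universe overlap are skipped; results are
    ranked by p. ``top_hits`` of the result frame gives the usual top-100
    reporting slice.
    """
    universe = set(universe)
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    M, n_query = len(universe), len(query)
    rows = []
    for term, genes in terms.items():
        term_in = set(genes) & universe
        if not term_in:
            continue
        k = len(query & term_in)
        p = float(stats.hypergeom.sf(k - 1, M, len(term_in), n_query))
        rows.append((term, len(term_in), k, p))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def top_hits(enrichment: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    return enrichment.head(n)
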