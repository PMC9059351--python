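"""Coherent association networks, module detection, cross-cohort overlap.

Coherent same-class pairs form a simple undirected graph per subtype;
modules are communities found by greedy modularity maximization with
deterministic node-ID tie-breaking.  Communities below ``min_size`` are
relabeled 0 (unassigned); surviving modules are numbered 1, 2, ... by
decreasing size.  Cross-subtype comparison tabulates, for every
non-empty combination of cohorts, the nodes present in exactly that
combination (the cells of a Venn diagram).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ModuleAssignment:
    """node -> module ID partition; 0 means unassigned."""

    labels: dict[str, int]
    subtype: str | None = None

    @property
    def module_sizes(self) -> pd.Series:
        ser = pd.Series(self.labels, name="module")
        sizes = ser[ser > 0].value_counts().sort_index()
        sizes.index.name = "module"
        return sizes

    @property
    def n_modules(self) -> int:
        return int(len(self.module_sizes))

    def members(self, module: int) -> list[str]:
        return sorted(n for n, m in self.labels.items() if m == module)

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.labels)
        return pd.DataFrame(
            {
                "node": nodes,
                "subtype": self.subtype or "",
                "module": [self.labels[n] for n in nodes],
            }
        )


def build_coherent_network(coherent_pairs) -> nx.Graph:
    """Simple undirected graph over the endpoints of coherent pairs.

    Accepts a DataFrame with ``node_a``/``node_b`` columns or any
    iterable of 2-tuples; duplicates collapse, self-loops are dropped.
    """
    if isinstance(coherent_pairs, pd.DataFrame):
        pairs = list(
            coherent_pairs[["node_a", "node_b"]].itertuples(index=False, name=None)
        )
    else:
        pairs = [tuple(p) for p in coherent_pairs]
    g = nx.Graph()
    for a, b in sorted(set(tuple(sorted(p)) for p in pairs)):
        if a == b:
            continue
        g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        log.warning("empty coherent pair list: returning empty graph")
    return g


def detect_modules(
    graph: nx.Graph, min_size: int = 3, seed: int = 0, method: str = "greedy"
) -> ModuleAssignment:
    """Community detection with size filtering and stable numbering.

    ``greedy`` (default) is modularity maximization via the CNM greedy
    agglomeration, which is deterministic given the graph;
    ``label_propagation`` is available as a faster stochastic
    alternative seeded by ``seed``.  Ties in module numbering break on
    the smallest member node ID.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    # rebuild with sorted insertion so iteration order never depends on
    # how the caller assembled the graph
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes()))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges()))

    if g.number_of_edges() == 0:
        communities: list[set] = [{n} for n in g.nodes()]
    elif method == "greedy":
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    elif method == "label_propagation":
        communities = [
            set(c)
            for c in nx.community.asyn_lpa_communities(g, seed=seed)
        ]
    else:
        raise ValueError(f"unknown method {method!r}")

    kept = [c for c in communities if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    labels = {n: 0 for n in g.nodes()}
    for module_id, community in enumerate(kept, start=1):
        for n in community:
            labels[n] = module_id
    log.info(
        "%d modules (min_size=%d), %d/%d nodes unassigned",
        len(kept), min_size, sum(1 for v in labels.values() if v == 0), len(labels),
    )
    return ModuleAssignment(labels=labels)


def intersect_across_cohorts(cohort_sets: dict[str, set]) -> pd.DataFrame:
    """Venn-cell membership counts across >= 2 named cohorts.

    One row per non-empty cohort combination with the nodes present in
    exactly that combination; cell counts sum to the union size.
    """
    if len(cohort_sets) < 2:
        raise ValueError("need at least 2 cohorts")
    names = sorted(cohort_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(cohort_sets[c]) for c in combo))
            outside = set.union(
                set(), *(set(cohort_sets[c]) for c in names if c not in combo)
            )
            exact = sorted(inside - outside)
            rows.append(
                {
                    "combination": "&".join(combo),
                    "n_cohorts": r,
                    "count": len(exact),
                    "nodes": ",".join(exact),
                }
            )
    return pd.DataFrame(rows)


def write_modules(assignment: ModuleAssignment, path: str | Path) -> None:
    assignment.to_frame().to_csv(path, sep="\t", index=False)


def read_modules(path: str | Path) -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    subtype = str(df["subtype"].iloc[0]) if len(df) and df["subtype"].notna().any() else None
    return ModuleAssignment(
        labels=dict(zip(df["node"], df["module"].astype(int))), subtype=subtype
    )
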