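"""Functional characterization: PPI overlap, ontology similarity, enrichment.

Term similarity follows the relevance measure: for terms t1, t2 with
annotation probabilities p(t1), p(t2), the score over common ancestors
c is

    simRel(t1, t2) = max_c  [2 ln p(c) / (ln p(t1) + ln p(t2))] * (1 - p(c))

i.e. Lin's information-content ratio damped by (1 - p(MICA)) so that
similarity through near-root ancestors counts for little.  Gene-level
similarity funSim aggregates simRel by best-match averaging over the
two genes' term sets per namespace (biological process and molecular
function) and combines namespaces as the mean of squared scores.

Enrichment of a gene set against an annotated background uses the
one-sided hypergeometric upper tail on ancestor-propagated annotations
with Benjamini-Hochberg FDR control across tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import false_discovery_control, hypergeom

from .bipartite import BipartiteNetwork

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function")


def ppi_fraction(pairs, ppi_edges: pd.DataFrame, score_min: float = 0.95) -> float:
    """Percentage of gene pairs found among high-confidence PPI edges.

    Only PPI edges with confidence score strictly above ``score_min``
    count.  Pairs are unordered.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    high = ppi_edges[ppi_edges["score"] > score_min]
    edge_set = {frozenset((a, b)) for a, b in zip(high["gene_a"], high["gene_b"])}
    hits = sum(frozenset(p) in edge_set for p in pairs)
    return 100.0 * hits / len(pairs)


@dataclass
class OntologyStats:
    """Per-namespace term probabilities, information content, ancestors.

    ``p[c]`` is the fraction of annotated genes carrying c or any of its
    descendants (after propagation); IC(c) = -ln p(c).  ``gene_terms``
    holds each gene's ancestor-propagated term set, ``direct_terms`` its
    directly annotated terms; both are restricted to this namespace.
    """

    namespace: str
    root: str
    p: dict[str, float]
    ancestors: dict[str, frozenset]
    gene_terms: dict[str, frozenset]
    direct_terms: dict[str, frozenset]
    term_names: dict[str, str] = field(default_factory=dict)

    def ic(self, term: str) -> float:
        return -np.log(self.p[term])

    @property
    def n_genes(self) -> int:
        return len(self.gene_terms)


def _namespace_subgraph(ontology: nx.MultiDiGraph, namespace: str) -> nx.MultiDiGraph:
    nodes = [
        n for n, d in ontology.nodes(data=True) if d.get("namespace") == namespace
    ]
    return ontology.subgraph(nodes)


def information_content(
    ontology: nx.MultiDiGraph, annotations: pd.DataFrame
) -> dict[str, OntologyStats]:
    """Propagate annotations and compute p(c), IC per namespace.

    ``ontology`` is an obonet-style graph (edges point from each term
    to its parents); ``annotations`` has columns gene, term, namespace.
    Terms with zero propagated annotations are excluded (logged) from
    the similarity universe.
    """
    stats: dict[str, OntologyStats] = {}
    for ns in NAMESPACES:
        sub = _namespace_subgraph(ontology, ns)
        if sub.number_of_nodes() == 0:
            continue
        roots = [n for n in sub.nodes if sub.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"namespace {ns} must have exactly one root, found {roots}")
        root = roots[0]
        # obonet edges run child -> parent, so ancestors are descendants
        # in graph direction
        ancestors = {
            t: frozenset(nx.descendants(sub, t)) for t in sub.nodes
        }
        ann = annotations[annotations["namespace"] == ns]
        gene_terms: dict[str, set] = {}
        direct: dict[str, set] = {}
        for gene, term in zip(ann["gene"], ann["term"]):
            if term not in sub.nodes:
                continue
            direct.setdefault(gene, set()).add(term)
            gene_terms.setdefault(gene, set()).update(ancestors[term] | {term})
        n_genes = len(gene_terms)
        if n_genes == 0:
            raise ValueError(f"no annotated genes in namespace {ns}")
        counts: dict[str, int] = {}
        for terms in gene_terms.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        p = {t: counts[t] / n_genes for t in counts}
        unannotated = sub.number_of_nodes() - len(p)
        if unannotated:
            log.info("namespace %s: %d terms without propagated annotations excluded",
                     ns, unannotated)
        stats[ns] = OntologyStats(
            namespace=ns,
            root=root,
            p=p,
            ancestors=ancestors,
            gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
            direct_terms={g: frozenset(t) for g, t in direct.items()},
            term_names={
                n: d.get("name", n) for n, d in sub.nodes(data=True)
            },
        )
    if not stats:
        raise ValueError("ontology contains no recognized namespace")
    return stats


def sim_rel(term1: str, term2: str, stats: OntologyStats) -> float:
    """Relevance similarity of two terms of one namespace, in [0, 1).

    Zero whenever the only common ancestor is the root (its p is 1, so
    the (1 - p) relevance factor vanishes).
    """
    for t in (term1, term2):
        if t not in stats.p:
            raise ValueError(f"term {t!r} has no annotation probability in "
                             f"{stats.namespace}")
    common = (stats.ancestors[term1] | {term1}) & (stats.ancestors[term2] | {term2})
    common = {c for c in common if c in stats.p}
    if not common:
        return 0.0
    denom = np.log(stats.p[term1]) + np.log(stats.p[term2])
    best = 0.0
    for c in common:
        pc = stats.p[c]
        if pc >= 1.0:
            continue  # root-like ancestor: relevance factor is zero
        lin = 1.0 if denom == 0 else 2.0 * np.log(pc) / denom
        best = max(best, lin * (1.0 - pc))
    return float(best)


def _best_match_average(terms_a, terms_b, stats: OntologyStats) -> float:
    sims = np.array(
        [[sim_rel(ta, tb, stats) for tb in terms_b] for ta in terms_a]
    )
    row_max = sims.max(axis=1)
    col_max = sims.max(axis=0)
    return float((row_max.sum() + col_max.sum()) / (len(terms_a) + len(terms_b)))


def funsim(gene_a: str, gene_b: str, stats: dict[str, OntologyStats]) -> float:
    """Gene-level functional similarity in [0, 1].

    Per namespace: best-match average of simRel over the two genes'
    directly annotated terms.  funSim is the mean of the squared
    namespace scores over the namespaces where both genes are
    annotated.
    """
    scores = []
    for ns, st in stats.items():
        ta = st.direct_terms.get(gene_a)
        tb = st.direct_terms.get(gene_b)
        if not ta or not tb:
            continue
        ta = sorted(t for t in ta if t in st.p)
        tb = sorted(t for t in tb if t in st.p)
        if ta and tb:
            scores.append(_best_match_average(ta, tb, st))
    if not scores:
        raise ValueError(f"no shared annotated namespace for {gene_a}/{gene_b}")
    return float(np.mean([s**2 for s in scores]))


def area_functional_report(
    records: pd.DataFrame,
    ppi_edges: pd.DataFrame | None,
    stats: dict[str, OntologyStats] | None,
    score_min: float = 0.95,
    max_pairs_per_cell: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (index, area): PPI percentage and mean pairwise funSim.

    ``records`` are area-labeled similarity rows for mRNA pairs.  Empty
    cells are reported as missing (NaN), not zero.  funSim is averaged
    over at most ``max_pairs_per_cell`` pairs per cell (seeded
    subsample) since cells can hold 10^5 pairs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (index, area), sub in records.groupby(["index", "area"], observed=True):
        pairs = list(zip(sub["node_a"], sub["node_b"]))
        row = {"index": index, "area": area, "n_pairs": len(pairs),
               "ppi_pct": np.nan, "mean_funsim": np.nan}
        if pairs:
            if ppi_edges is not None:
                row["ppi_pct"] = ppi_fraction(pairs, ppi_edges, score_min)
            if stats is not None:
                if len(pairs) > max_pairs_per_cell:
                    idx = rng.choice(len(pairs), max_pairs_per_cell, replace=False)
                    sample = [pairs[i] for i in idx]
                else:
                    sample = pairs
                vals = []
                for a, b in sample:
                    try:
                        vals.append(funsim(a, b, stats))
                    except ValueError:
                        continue
                row["mean_funsim"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    columns = ["index", "area", "n_pairs", "ppi_pct", "mean_funsim"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(rows)[columns]
        .sort_values(["index", "area"])
        .reset_index(drop=True)
    )


def module_target_mrnas(
    module_lncrnas, network: BipartiteNetwork, min_links: int = 1
) -> set:
    """mRNAs co-expressed with a module: union of bipartite neighborhoods.

    ``network`` is the lncRNA-mRNA bipartite network with lncRNAs on
    the X side.  With ``min_links`` > 1 only mRNAs connected to at
    least that many module lncRNAs are kept.
    """
    module_lncrnas = list(module_lncrnas)
    if not module_lncrnas:
        raise ValueError("empty module")
    counts: dict[str, int] = {}
    for lnc in module_lncrnas:
        for m in network.neighbors(lnc, "x"):
            counts[m] = counts.get(m, 0) + 1
    return {m for m, c in counts.items() if c >= min_links}


def go_enrichment(
    gene_set,
    background,
    stats: dict[str, OntologyStats],
    namespace: str = "biological_process",
) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini-Hochberg FDR.

    Uses ancestor-propagated annotations.  For each term with at least
    one annotated background gene: p = P(X >= k) with X hypergeometric
    (N = background size, K = annotated background genes, n = gene-set
    size, k = annotated gene-set genes).  Rows sorted by p.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    st = stats[namespace]
    bg_terms: dict[str, set] = {}
    for g in background:
        for t in st.gene_terms.get(g, ()):
            bg_terms.setdefault(t, set()).add(g)
    n_bg = len(background)
    n_set = len(gene_set)
    rows = []
    for term in sorted(bg_terms):
        annotated = bg_terms[term]
        k = len(annotated & gene_set)
        p = float(hypergeom.sf(k - 1, n_bg, len(annotated), n_set))
        rows.append(
            {
                "term": term,
                "name": st.term_names.get(term, term),
                "overlap": k,
                "annotated": len(annotated),
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = false_discovery_control(df["p_value"], method="bh")
    return df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)


def cluster_enrichment_profiles(
    q_matrix: pd.DataFrame,
    k: int | None = None,
    q_threshold: float = 0.05,
    cap: float = 10.0,
) -> tuple[np.ndarray, pd.Series, pd.DataFrame]:
    """Hierarchically cluster modules by their enrichment profiles.

    ``q_matrix`` is modules x terms of FDR q-values.  Terms significant
    (q < ``q_threshold``, strict) in at least one module are kept; the
    profile is -log10(q) capped at ``cap``; modules are clustered by
    average-linkage Euclidean hierarchy.  Returns (linkage matrix,
    cluster labels as a Series indexed by module — all ones unless
    ``k`` is given — and the transformed profile matrix).
    """
    if q_matrix.shape[0] < 2:
        raise ValueError("need at least 2 modules")
    keep = (q_matrix < q_threshold).any(axis=0)
    if not keep.any():
        raise ValueError(f"no term reaches q < {q_threshold} in any module")
    profile = -np.log10(q_matrix.loc[:, keep].clip(lower=10.0 ** (-cap)))
    profile = profile.clip(upper=cap)
    linkage = hierarchy.linkage(profile.to_numpy(), method="average", metric="euclidean")
    if k is not None:
        labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    else:
        labels = np.ones(profile.shape[0], dtype=int)
    return linkage, pd.Series(labels, index=profile.index, name="cluster"), profile
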