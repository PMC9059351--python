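"""Interaction-profile association indices and coherent-pair selection.

Given a bipartite network, two same-class (X-side) nodes A and B are
compared through their neighborhoods N(A), N(B) on the opposite side
with five association indices:

    jaccard   |N(A) ∩ N(B)| / |N(A) ∪ N(B)|
    simpson   |N(A) ∩ N(B)| / min(|N(A)|, |N(B)|)
    geometric |N(A) ∩ N(B)|^2 / (|N(A)| · |N(B)|)
    cosine    |N(A) ∩ N(B)| / sqrt(|N(A)| · |N(B)|)
    pcc       Pearson correlation of the two 0/1 incidence profiles
              over the n_y Y-type nodes

Each same-class pair gets one value per index in each of two bipartite
contexts (e.g. lncRNA pairs via shared mRNAs and via shared miRNAs).
The two-context plane is split per index into quadrants A (low/low),
B (high/low), C (low/high) and D (high/high) by per-axis quantile
thresholds; a pair is a *coherent association* when, for enough
indices, it falls in area D with both context values in the extreme
top fraction of their per-axis distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .bipartite import BipartiteNetwork

log = logging.getLogger(__name__)

INDICES = ("jaccard", "simpson", "geometric", "cosine", "pcc")


class UndefinedIndexError(ValueError):
    """Association index undefined for the given neighborhoods."""


class AreaError(ValueError):
    """Quadrant labeling impossible (degenerate axis)."""


def association_index(
    neighborhood_a, neighborhood_b, method: str, n_y: int | None = None
) -> float:
    """One association index between two Y-side neighborhood sets.

    ``n_y`` (the total number of Y-type nodes in the network) is
    required only by ``pcc``.
    """
    na = set(neighborhood_a)
    nb = set(neighborhood_b)
    ka, kb = len(na), len(nb)
    inter = len(na & nb)
    if method == "jaccard":
        union = ka + kb - inter
        if union == 0:
            raise UndefinedIndexError("jaccard undefined for two empty sets")
        return inter / union
    if ka == 0 or kb == 0:
        raise UndefinedIndexError(f"{method} undefined for an empty neighborhood")
    if method == "simpson":
        return inter / min(ka, kb)
    if method == "geometric":
        return inter**2 / (ka * kb)
    if method == "cosine":
        return inter / np.sqrt(ka * kb)
    if method == "pcc":
        if n_y is None:
            raise ValueError("pcc requires n_y")
        if n_y < max(ka, kb):
            raise ValueError("n_y smaller than a neighborhood size")
        denom = ka * kb * (n_y - ka) * (n_y - kb)
        if denom == 0:
            raise UndefinedIndexError("pcc undefined when a profile is constant")
        return (inter * n_y - ka * kb) / np.sqrt(denom)
    raise ValueError(f"unknown method {method!r}; expected one of {INDICES}")


def pairwise_profile_similarity(
    network: BipartiteNetwork, side: str = "x"
) -> pd.DataFrame:
    """All five indices for every unordered same-side node pair.

    Returns one row per pair (``node_a`` < ``node_b`` lexicographically)
    with a column per index; undefined values are NaN.  Computed
    vectorized from the 0/1 incidence matrix.
    """
    nodes = network.x_nodes if side == "x" else network.y_nodes
    if len(nodes) < 2:
        raise ValueError(f"need at least 2 nodes on side {side!r}")
    other = network.y_nodes if side == "x" else network.x_nodes
    n_other = len(other)
    col = {y: j for j, y in enumerate(other)}
    m = np.zeros((len(nodes), n_other), dtype=float)
    for i, v in enumerate(nodes):
        for y in network.neighbors(v, side):
            m[i, col[y]] = 1.0

    sizes = m.sum(axis=1)
    inter = m @ m.T
    iu, ju = np.triu_indices(len(nodes), k=1)
    ka, kb = sizes[iu], sizes[ju]
    ov = inter[iu, ju]

    with np.errstate(divide="ignore", invalid="ignore"):
        union = ka + kb - ov
        jaccard = np.where(union > 0, ov / union, np.nan)
        prod = ka * kb
        simpson = np.where(prod > 0, ov / np.minimum(ka, kb), np.nan)
        geometric = np.where(prod > 0, ov**2 / prod, np.nan)
        cosine = np.where(prod > 0, ov / np.sqrt(prod), np.nan)
        pdenom = prod * (n_other - ka) * (n_other - kb)
        pcc = np.where(pdenom > 0, (ov * n_other - prod) / np.sqrt(pdenom), np.nan)

    arr = np.asarray(nodes)
    return pd.DataFrame(
        {
            "node_a": arr[iu], "node_b": arr[ju],
            "jaccard": jaccard, "simpson": simpson,
            "geometric": geometric, "cosine": cosine, "pcc": pcc,
        }
    )


def combine_contexts(
    sim_context1: pd.DataFrame, sim_context2: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-pair similarities from two bipartite contexts.

    Long format: one row per (pair, index) with ``value_c1`` and
    ``value_c2``.  Only pairs measurable in both contexts are kept.
    """
    def melt(df: pd.DataFrame, name: str) -> pd.DataFrame:
        out = df.melt(
            id_vars=["node_a", "node_b"], value_vars=list(INDICES),
            var_name="index", value_name=name,
        )
        # node/index columns repeat heavily; categoricals keep large
        # cohorts (10^5-10^6 pairs) affordable
        for col in ("node_a", "node_b", "index"):
            out[col] = out[col].astype("category")
        return out

    merged = melt(sim_context1, "value_c1").merge(
        melt(sim_context2, "value_c2"), on=["node_a", "node_b", "index"],
        how="inner",
    )
    return merged


def assign_areas(records: pd.DataFrame, area_quantile: float = 0.95) -> pd.DataFrame:
    """Label each (pair, index) row with its quadrant A/B/C/D.

    Per index and per axis the high/low boundary is the
    ``area_quantile`` quantile of that axis's (defined) values; a value
    at or above the boundary counts as high.  A = low/low, B =
    high/low, C = low/high, D = high/high.  Rows with a missing value
    get a missing label.
    """
    records = records.copy()
    records["area"] = pd.NA
    for index, sub in records.groupby("index", observed=True):
        for axis in ("value_c1", "value_c2"):
            vals = sub[axis].dropna()
            if len(vals) and vals.nunique() == 1:
                raise AreaError(f"degenerate axis {axis} for index {index!r}")
        thr1 = np.nanquantile(sub["value_c1"].to_numpy(dtype=float), area_quantile)
        thr2 = np.nanquantile(sub["value_c2"].to_numpy(dtype=float), area_quantile)
        hi1 = sub["value_c1"] >= thr1
        hi2 = sub["value_c2"] >= thr2
        label = np.select(
            [hi1 & hi2, hi1 & ~hi2, ~hi1 & hi2, ~hi1 & ~hi2],
            ["D", "B", "C", "A"],
            default=None,
        )
        defined = sub["value_c1"].notna() & sub["value_c2"].notna()
        label = pd.array(label, dtype="string")
        label[~defined.to_numpy()] = pd.NA
        records.loc[sub.index, "area"] = label
    return records


@dataclass
class CoherenceConfig:
    """How many indices must agree, and how extreme the pair must rank."""

    min_indices: int = 3
    top_frac: float = 0.0005
    area_quantile: float = 0.95

    def validate(self) -> None:
        if not 1 <= self.min_indices <= len(INDICES):
            raise ValueError("min_indices must be in [1, 5]")
        if not 0.0 < self.top_frac < 1.0:
            raise ValueError("top_frac must be in (0, 1)")
        if not 0.0 < self.area_quantile < 1.0:
            raise ValueError("area_quantile must be in (0, 1)")


def select_coherent_pairs(
    records: pd.DataFrame, config: CoherenceConfig | None = None
) -> pd.DataFrame:
    """Coherent associations: area-D pairs of extreme rank, by vote.

    A pair qualifies under one index when its area label is D and both
    context values reach the top ``top_frac`` fraction of that index's
    per-axis distribution (ties at the boundary included).  Pairs
    qualifying under at least ``min_indices`` indices are returned with
    their supporting-index count.  Undefined (NaN) values never
    qualify.
    """
    config = config or CoherenceConfig()
    config.validate()
    if "area" not in records.columns:
        records = assign_areas(records, config.area_quantile)

    support: dict[tuple, int] = {}
    for index, sub in records.groupby("index", observed=True):
        t1 = np.nanquantile(sub["value_c1"].to_numpy(dtype=float), 1 - config.top_frac)
        t2 = np.nanquantile(sub["value_c2"].to_numpy(dtype=float), 1 - config.top_frac)
        ok = (
            (sub["area"] == "D")
            & (sub["value_c1"] >= t1)
            & (sub["value_c2"] >= t2)
        )
        for a, b in sub.loc[ok.fillna(False), ["node_a", "node_b"]].itertuples(index=False):
            support[(a, b)] = support.get((a, b), 0) + 1

    rows = [
        {"node_a": a, "node_b": b, "n_supporting": c}
        for (a, b), c in sorted(support.items())
        if c >= config.min_indices
    ]
    out = pd.DataFrame(rows, columns=["node_a", "node_b", "n_supporting"])
    log.info("%d coherent pairs (min_indices=%d, top_frac=%g)",
             len(out), config.min_indices, config.top_frac)
    return out
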