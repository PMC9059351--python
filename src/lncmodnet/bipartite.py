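"""Bipartite co-expression networks and scale-free cutoff selection.

An edge connects a feature of class A to a feature of class B whenever
the absolute Fisher z of their Spearman correlation reaches a cutoff.
The cutoff is chosen by the scale-free topology criterion: over a grid
of candidate cutoffs, keep those whose thresholded network has a degree
distribution p(k) that is approximately linear in log10 p(k) vs
log10 k with fit index R^2 above ``r2_min`` and slope inside
``slope_range``; among passing cutoffs the smallest (densest passing
network) is returned, since pushing R^2 toward 1 tends to leave very
few connections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import ZTable

log = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Fewer than 3 distinct positive degrees: no regression possible."""


class NoCutoffError(RuntimeError):
    """No candidate cutoff satisfied the scale-free criterion."""

    def __init__(self, message: str, scan: pd.DataFrame):
        super().__init__(message)
        self.scan = scan


@dataclass
class ScaleFreeFit:
    """Log-log degree-distribution regression result at one cutoff."""

    r_squared: float
    slope: float
    degree_dist: pd.Series  # index k, value p(k); sums to 1 over observed k
    cutoff: float | None = None
    scan: pd.DataFrame | None = field(default=None, repr=False)


def scale_free_fit(degrees) -> ScaleFreeFit:
    """OLS of log10 p(k) on log10 k over the observed positive degrees.

    ``degrees`` is the degree multiset of the network's nodes (both
    sides pooled); zero degrees are ignored.  p(k) is the fraction of
    (positive-degree) nodes with degree exactly k.
    """
    degrees = np.asarray(list(degrees), dtype=int)
    degrees = degrees[degrees > 0]
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise DegenerateFitError(
            f"{len(ks)} distinct positive degrees; need at least 3"
        )
    pk = counts / counts.sum()
    x = np.log10(ks)
    y = np.log10(pk)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ScaleFreeFit(
        r_squared=float(r2),
        slope=float(slope),
        degree_dist=pd.Series(pk, index=ks, name="p_k"),
    )


def _degrees_at(ztable: ZTable, cutoff: float) -> np.ndarray:
    mask = ztable.records["z"].abs() >= cutoff
    sub = ztable.records[mask]
    deg_a = sub["feature_a"].value_counts().to_numpy()
    deg_b = sub["feature_b"].value_counts().to_numpy()
    return np.concatenate([deg_a, deg_b])


def default_grid(ztable: ZTable, n_candidates: int = 50) -> np.ndarray:
    """Candidate cutoffs evenly spaced in |z| from the median to the max.

    Cutoffs below the median |z| keep more than half of all pairs and
    never yield sparse, heterogeneous-degree networks, so the scan
    starts at the median; spacing in the statistic (rather than in
    quantiles) keeps the sparse upper tail, where scale-free-like
    networks live, densely covered.
    """
    absz = ztable.records["z"].abs().to_numpy()
    return np.linspace(np.median(absz), absz.max(), n_candidates, endpoint=False)


def select_cutoff(
    ztable: ZTable,
    candidate_grid=None,
    r2_min: float = 0.8,
    slope_range: tuple[float, float] = (-2.0, -0.5),
) -> ScaleFreeFit:
    """Scan candidate |z| cutoffs and return the smallest passing fit.

    A candidate passes when its thresholded network fits the scale-free
    criterion: R^2 > ``r2_min`` and slope strictly inside
    ``slope_range``.  The full scan table (cutoff, n_edges, r_squared,
    slope, passed) is attached to the returned fit and to the
    :class:`NoCutoffError` raised when nothing passes.
    """
    if candidate_grid is None:
        candidate_grid = default_grid(ztable)
    candidate_grid = np.sort(np.asarray(candidate_grid, dtype=float))

    rows = []
    best: ScaleFreeFit | None = None
    for cutoff in candidate_grid:
        mask = ztable.records["z"].abs() >= cutoff
        n_edges = int(mask.sum())
        try:
            fit = scale_free_fit(_degrees_at(ztable, cutoff))
        except DegenerateFitError:
            rows.append((cutoff, n_edges, np.nan, np.nan, False))
            continue
        passed = fit.r_squared > r2_min and slope_range[0] < fit.slope < slope_range[1]
        rows.append((cutoff, n_edges, fit.r_squared, fit.slope, passed))
        if passed and best is None:
            fit.cutoff = float(cutoff)
            best = fit

    scan = pd.DataFrame(
        rows, columns=["cutoff", "n_edges", "r_squared", "slope", "passed"]
    )
    if best is None:
        raise NoCutoffError(
            "no candidate cutoff satisfied the scale-free criterion "
            f"(R^2 > {r2_min}, slope in {slope_range})",
            scan,
        )
    best.scan = scan
    log.info(
        "selected cutoff %.4g (R^2=%.3f, slope=%.3f, %d/%d candidates passed)",
        best.cutoff, best.r_squared, best.slope, int(scan["passed"].sum()), len(scan),
    )
    return best


@dataclass
class BipartiteNetwork:
    """Thresholded cross-class network with typed X and Y node sets.

    Edges connect only X-type to Y-type nodes; each edge keeps its
    signed z-value.  ``neighbors`` gives the interaction profile N(v)
    of any node; ``n_y`` is the number of retained Y-type nodes, the
    universe size used by the profile-correlation association index.
    """

    edges: pd.DataFrame  # columns: x, y, z
    x_class: str
    y_class: str

    def __post_init__(self) -> None:
        self._nx: dict[str, set] = {}
        self._ny: dict[str, set] = {}
        for x, y in zip(self.edges["x"], self.edges["y"]):
            self._nx.setdefault(x, set()).add(y)
            self._ny.setdefault(y, set()).add(x)

    @property
    def x_nodes(self) -> list:
        return sorted(self._nx)

    @property
    def y_nodes(self) -> list:
        return sorted(self._ny)

    @property
    def n_y(self) -> int:
        return len(self._ny)

    @property
    def n_x(self) -> int:
        return len(self._nx)

    def neighbors(self, node, side: str = "x") -> set:
        table = self._nx if side == "x" else self._ny
        return set(table.get(node, set()))

    def degree(self, node, side: str = "x") -> int:
        table = self._nx if side == "x" else self._ny
        return len(table.get(node, set()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for x in self.x_nodes:
            g.add_node(x, bipartite=0, rna_class=self.x_class)
        for y in self.y_nodes:
            g.add_node(y, bipartite=1, rna_class=self.y_class)
        for x, y, z in self.edges.itertuples(index=False):
            g.add_edge(x, y, z=float(z))
        return g

    def to_tsv(self, path: str | Path) -> None:
        df = self.edges.copy()
        df.insert(1, "class_x", self.x_class)
        df.insert(3, "class_y", self.y_class)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BipartiteNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"x": str, "y": str})
        x_class = str(df["class_x"].iloc[0]) if len(df) else ""
        y_class = str(df["class_y"].iloc[0]) if len(df) else ""
        return cls(edges=df[["x", "y", "z"]], x_class=x_class, y_class=y_class)


def build_bipartite(
    ztable: ZTable, cutoff: float, min_degree: int = 1
) -> BipartiteNetwork:
    """Threshold a z-table at |z| >= cutoff into a bipartite network.

    Sparsely connected nodes (degree < ``min_degree`` after
    thresholding) are removed in a single pass together with their
    incident edges.
    """
    rec = ztable.records
    sub = rec[rec["z"].abs() >= cutoff]
    if min_degree > 0 and len(sub):
        deg_a = sub["feature_a"].value_counts()
        deg_b = sub["feature_b"].value_counts()
        keep_a = set(deg_a[deg_a >= min_degree].index)
        keep_b = set(deg_b[deg_b >= min_degree].index)
        sub = sub[sub["feature_a"].isin(keep_a) & sub["feature_b"].isin(keep_b)]
    if not len(sub):
        raise ValueError(f"empty network at cutoff {cutoff}")
    edges = pd.DataFrame(
        {"x": sub["feature_a"].to_numpy(), "y": sub["feature_b"].to_numpy(),
         "z": sub["z"].to_numpy()}
    )
    return BipartiteNetwork(edges=edges, x_class=ztable.class_a, y_class=ztable.class_b)
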