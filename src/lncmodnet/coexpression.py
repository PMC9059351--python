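"""Cross-class co-expression: Spearman rank correlation and its Fisher z.

For each pair of features drawn from two different RNA classes we compute
the Spearman rank correlation rs (midranks on ties, Pearson on the rank
vectors), its Fisher transform F(rs) = arctanh(rs), and the variance-
corrected z-score

    z = sqrt((n - 3) / 1.06) * F(rs)

which is approximately standard normal under independence.  The 1.06
constant is the classical variance correction for the Fisher transform of
a *rank* correlation (the plain Pearson version uses 1.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

#: variance correction for Fisher-transformed Spearman correlations
SPEARMAN_VARIANCE_CORRECTION = 1.06


class ConstantInputError(ValueError):
    """A vector with zero rank variance has no defined correlation."""


class DivergenceError(ValueError):
    """|rs| = 1 makes the Fisher transform infinite."""


def spearman_rho(x, y) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Ties receive midranks; the statistic is the Pearson correlation of
    the two rank vectors, which coincides with the classical
    1 - 6*sum(d_i^2)/(n(n^2-1)) formula when there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        raise ConstantInputError("constant input vector: correlation undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def fisher_z(rs: float, n: int) -> tuple[float, float]:
    """Fisher transform of rs and the corrected z-score at sample size n.

    Returns ``(fisher_f, z)`` with ``fisher_f = arctanh(rs)`` and
    ``z = sqrt((n-3)/1.06) * fisher_f``.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if abs(rs) >= 1.0:
        raise DivergenceError(f"|rs| = {abs(rs)} >= 1: Fisher transform diverges")
    f = float(np.arctanh(rs))
    z = float(np.sqrt((n - 3) / SPEARMAN_VARIANCE_CORRECTION) * f)
    return f, z


@dataclass
class ZTable:
    """All cross-pair correlation records for one pair of matrices.

    ``records`` has one row per unordered cross pair with columns
    feature_a, class_a, feature_b, class_b, rs, z; every row shares the
    sample count ``n`` (the size of the two matrices' sample
    intersection).
    """

    records: pd.DataFrame
    class_a: str
    class_b: str
    n: int

    COLUMNS = ("feature_a", "class_a", "feature_b", "class_b", "rs", "z", "n")

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        df = self.records.copy()
        df["n"] = self.n
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ZTable":
        df = pd.read_csv(path, sep="\t", dtype={"feature_a": str, "feature_b": str})
        n = int(df["n"].iloc[0]) if len(df) else 0
        return cls(
            records=df.drop(columns=["n"]),
            class_a=str(df["class_a"].iloc[0]) if len(df) else "",
            class_b=str(df["class_b"].iloc[0]) if len(df) else "",
            n=n,
        )


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise midranks, centered and scaled to unit norm.

    Returns the standardized rank matrix and a boolean mask of rows with
    zero rank variance (constant features), whose rows are left as zero.
    """
    ranks = rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms[:, None], constant


def pairwise_z_table(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    clip: bool = False,
    eps: float = 1e-7,
) -> ZTable:
    """Spearman rs and Fisher z for every cross pair of two matrices.

    Correlations are computed over the (sorted) intersection of the two
    sample sets.  Pairs involving a constant feature are dropped (their
    correlation is undefined); |rs| = 1 raises unless ``clip`` is set,
    in which case rs is clipped to ``1 - eps``.
    """
    shared = sorted(set(matrix_a.samples) & set(matrix_b.samples))
    n = len(shared)
    if n < 4:
        raise ValueError(f"shared-sample count {n} < 4")
    a = matrix_a.values[shared].to_numpy(dtype=float)
    b = matrix_b.values[shared].to_numpy(dtype=float)
    za, const_a = _rank_standardize(a)
    zb, const_b = _rank_standardize(b)
    if const_a.any() or const_b.any():
        log.warning(
            "dropping pairs with constant features: %d (%s) / %d (%s)",
            const_a.sum(), matrix_a.rna_class, const_b.sum(), matrix_b.rna_class,
        )
    rho = np.clip(za @ zb.T, -1.0, 1.0)

    at_unity = np.abs(rho) >= 1.0 - 1e-15
    # constant rows produce rho == 0; mark them invalid instead
    valid = ~(const_a[:, None] | const_b[None, :])
    if (at_unity & valid).any():
        if not clip:
            raise DivergenceError(
                f"{int((at_unity & valid).sum())} pairs with |rs| = 1; "
                "pass clip=True to clip toward 1 - eps"
            )
        log.warning("clipping %d pairs with |rs| = 1 to 1 - %g",
                    int((at_unity & valid).sum()), eps)
        rho = np.clip(rho, -1.0 + eps, 1.0 - eps)

    scale = np.sqrt((n - 3) / SPEARMAN_VARIANCE_CORRECTION)
    z = scale * np.arctanh(rho)

    ia, ib = np.nonzero(valid)
    records = pd.DataFrame(
        {
            "feature_a": matrix_a.features.to_numpy()[ia],
            "class_a": matrix_a.rna_class,
            "feature_b": matrix_b.features.to_numpy()[ib],
            "class_b": matrix_b.rna_class,
            "rs": rho[ia, ib],
            "z": z[ia, ib],
        }
    )
    return ZTable(records=records, class_a=matrix_a.rna_class,
                  class_b=matrix_b.rna_class, n=n)
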