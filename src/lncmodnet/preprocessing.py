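"""Expression preprocessing: filters, normalization, transform, splitting.

The fixed stage order for a cohort matrix is

    non-zero-fraction filter -> upper-quartile normalization
    -> biotype partition (gene matrices) -> subtype split
    -> per-subtype median-FPKM filter (mRNA/lncRNA only)
    -> log2 shift transform -> outlier-sample removal

The median-FPKM filter runs on the normalized FPKM scale, before the
log transform, because its threshold (default 0.7) is an FPKM value.
Every filter logs before/after counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .matrix import ExpressionMatrix, MatrixError

log = logging.getLogger(__name__)

#: Ensembl biotypes mapped onto the two gene-level RNA classes
MRNA_BIOTYPES = frozenset({"protein_coding"})
LNCRNA_BIOTYPES = frozenset({"lincRNA", "antisense", "antisense_RNA"})


def filter_nonzero_features(
    m: ExpressionMatrix, min_frac: float = 0.8
) -> ExpressionMatrix:
    """Keep features whose non-zero sample fraction is >= ``min_frac``."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if m.n_features == 0 or m.n_samples == 0:
        raise MatrixError("empty matrix")
    frac = (m.values != 0).sum(axis=1) / m.n_samples
    kept = m.values.loc[frac >= min_frac]
    log.info("non-zero filter (%s, >=%.0f%%): %d -> %d features",
             m.rna_class, 100 * min_frac, m.n_features, len(kept))
    return m.with_values(kept.copy())


def upper_quartile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample by the 75th percentile of its non-zero values.

    Samples are rescaled by the geometric mean of the per-sample upper
    quartiles so the output stays on the input's magnitude; afterwards
    every sample's non-zero upper quartile is identical.
    """
    if m.scale != "fpkm":
        raise MatrixError("upper-quartile normalization expects FPKM scale")
    values = m.values.to_numpy(dtype=float)
    uq = np.empty(m.n_samples)
    for j in range(m.n_samples):
        nz = values[:, j][values[:, j] > 0]
        if nz.size == 0:
            raise MatrixError(f"sample {m.samples[j]!r} has no non-zero values")
        uq[j] = np.percentile(nz, 75)
    ref = gmean(uq)
    out = values * (ref / uq)[None, :]
    return m.with_values(pd.DataFrame(out, index=m.features, columns=m.samples))


def log2_shift_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + m_min) with m_min the matrix-wide minimum non-zero value."""
    if m.scale != "fpkm":
        raise MatrixError("matrix already log-transformed")
    values = m.values.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise MatrixError("all-zero matrix: no minimum non-zero element")
    m_min = float(nonzero.min())
    out = np.log2(values + m_min)
    log.info("log2 shift (%s): pseudo-value %.3g", m.rna_class, m_min)
    return m.with_values(
        pd.DataFrame(out, index=m.features, columns=m.samples), scale="log2"
    )


def remove_outlier_samples(m: ExpressionMatrix, k_sd: float = 2.0) -> ExpressionMatrix:
    """Drop samples whose mean expression is > ``k_sd`` SDs from the mean.

    The per-sample summary is the mean log2 expression; the boundary is
    strict (a sample at exactly ``k_sd`` SDs is kept).
    """
    if m.scale != "log2":
        raise MatrixError("outlier removal expects log2 scale")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if m.n_samples < 3:
        raise MatrixError(f"need >= 3 samples, got {m.n_samples}")
    means = m.values.mean(axis=0)
    center = means.mean()
    sd = means.std(ddof=1)
    if sd == 0:
        return m.with_values(m.values.copy())
    keep = (means - center).abs() <= k_sd * sd
    log.info("outlier removal (%s, %.1f SD): %d -> %d samples",
             m.rna_class, k_sd, m.n_samples, int(keep.sum()))
    return m.with_values(m.values.loc[:, keep].copy())


def partition_by_biotype(
    m: ExpressionMatrix, biotype_table: pd.Series
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split a gene matrix into (mRNA, lncRNA) by annotated biotype.

    ``biotype_table`` maps feature ID -> biotype string.  Protein-coding
    features go to the mRNA matrix; lincRNA and antisense features to
    the lncRNA matrix.  Features with other or missing biotypes are
    dropped (count logged), never guessed.
    """
    biotype = biotype_table.reindex(m.features)
    is_mrna = biotype.isin(MRNA_BIOTYPES)
    is_lnc = biotype.isin(LNCRNA_BIOTYPES)
    dropped = int((~(is_mrna | is_lnc)).sum())
    if dropped:
        log.info("biotype partition: dropped %d unannotated/other features", dropped)
    mrna = ExpressionMatrix(
        values=m.values.loc[is_mrna].copy(), rna_class="mRNA", scale=m.scale
    )
    lncrna = ExpressionMatrix(
        values=m.values.loc[is_lnc].copy(), rna_class="lncRNA", scale=m.scale
    )
    return mrna, lncrna


def subtype_expression_filter(
    m: ExpressionMatrix,
    labels: pd.Series,
    threshold: float = 0.7,
    median_filter: bool = True,
) -> dict[str, ExpressionMatrix]:
    """Split samples by subtype; drop low-median features per subtype.

    Within each subtype, features whose median FPKM is <= ``threshold``
    are removed (gene classes only; pass ``median_filter=False`` for
    miRNA matrices, which are split but not filtered).  Feature sets of
    different subtypes are independent.
    """
    if m.scale != "fpkm":
        raise MatrixError("median-FPKM filter runs on the FPKM scale")
    labels = labels.reindex(m.samples)
    if labels.isna().any():
        missing = labels.index[labels.isna()][:5].tolist()
        raise MatrixError(f"samples without subtype label, e.g. {missing}")
    out: dict[str, ExpressionMatrix] = {}
    for subtype, cols in sorted(labels.groupby(labels).groups.items()):
        if len(cols) == 0:
            raise MatrixError(f"subtype {subtype!r} has zero samples")
        sub = m.values[list(cols)]
        before = len(sub)
        if median_filter:
            sub = sub.loc[sub.median(axis=1) > threshold]
        log.info("subtype %s (%s): %d samples, %d -> %d features",
                 subtype, m.rna_class, sub.shape[1], before, len(sub))
        out[str(subtype)] = m.with_values(sub.copy())
    return out
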