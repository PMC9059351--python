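"""Shared fixtures: synthetic cohorts, pipeline runs, toy ontologies."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from lncmodnet.matrix import ExpressionMatrix
from lncmodnet.pipeline import PipelineConfig, run_pipeline
from lncmodnet.synthetic import (
    SyntheticConfig,
    generate_cohort,
    generate_toy_ontology,
    generate_toy_ppi,
    write_cohort,
)

logging.getLogger("lncmodnet").setLevel(logging.WARNING)


SMALL_CONFIG = SyntheticConfig(
    n_subtypes=2,
    samples_per_subtype=100,
    n_mrna=250,
    n_lncrna=120,
    n_mirna=50,
    n_groups=3,
    group_size_mrna=8,
    group_size_lncrna=6,
    group_size_mirna=4,
    seed=7,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 200 samples, 5 planted groups."""
    return generate_cohort(SyntheticConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A light two-subtype cohort for fast structural tests."""
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_cohort):
    """Full pipeline run on the default cohort, with its ground truth."""
    base = tmp_path_factory.mktemp("default_run")
    cohort = default_cohort
    ontology, annotations = generate_toy_ontology(cohort.config, cohort.truth)
    ppi = generate_toy_ppi(cohort.truth, seed=cohort.config.seed + 1)
    paths = write_cohort(
        cohort, base / "data", ppi=ppi, ontology=ontology, annotations=annotations
    )
    config = PipelineConfig(
        genes_path=str(paths["genes"]),
        mirna_path=str(paths["mirna"]),
        biotypes_path=str(paths["biotypes"]),
        labels_path=str(paths["labels"]),
        ppi_path=str(paths["ppi"]),
        ontology_path=str(paths["ontology"]),
        annotations_path=str(paths["annotations"]),
        outdir=str(base / "run"),
    )
    manifest = run_pipeline(config)
    return {
        "cohort": cohort,
        "rundir": base / "run" / "subtype1",
        "outdir": base / "run",
        "manifest": manifest,
        "paths": paths,
    }


@pytest.fixture(scope="session")
def toy_functional():
    """Small cohort truth + toy ontology + information-content stats."""
    from lncmodnet.functional import information_content

    config = SyntheticConfig(
        n_mrna=60, n_lncrna=30, n_mirna=20, n_groups=4,
        group_size_mrna=6, group_size_lncrna=4, group_size_mirna=3,
        samples_per_subtype=50, seed=5,
    )
    cohort = generate_cohort(config)
    ontology, annotations = generate_toy_ontology(config, cohort.truth)
    stats = information_content(ontology, annotations)
    return {
        "config": config,
        "truth": cohort.truth,
        "ontology": ontology,
        "annotations": annotations,
        "stats": stats,
    }


def toy_matrix(values, rna_class="mRNA", scale="fpkm", prefix="f", samples=None):
    """Build a small ExpressionMatrix from a nested list."""
    arr = np.asarray(values, dtype=float)
    features = [f"{prefix}{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=features, columns=samples),
        rna_class=rna_class,
        scale=scale,
    )
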