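"""Seeded synthetic cohorts with planted ceRNA structure.

The generator emulates a multi-subtype tumor expression cohort in which
groups of mRNAs and lncRNAs act as competing endogenous RNAs: members of
one group are positively co-expressed with each other and negatively
co-expressed with the group's miRNAs.  Each group g carries a latent
per-sample activity a_g ~ N(0, 1); mRNA/lncRNA members load on it with
+beta, miRNA members with -beta, on the log2 scale, on top of a
feature-specific baseline and i.i.d. Gaussian noise.  Values are
exponentiated to an FPKM-like positive scale (log-normal), zeros are
injected completely at random, and a small fraction of dropout-heavy
background features is added so that the non-zero-fraction filter has
something to remove.  Subtypes differ by which planted groups are
active, which creates subtype-specific modules downstream.

A toy two-namespace ontology and a scored protein-interaction list with
group-aware edge probabilities accompany the cohort so that functional
evaluation is testable without external databases.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

NAMESPACES = ("biological_process", "molecular_function")


class ConfigError(ValueError):
    """Inconsistent synthetic-cohort configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the planted-ceRNA cohort generator.

    Defaults describe a 200-sample single-subtype cohort with five
    planted groups at loading beta = 1.2 against unit noise — strong
    enough that within-group co-expression dominates, weak enough that
    thresholding is non-trivial.  Class sizes keep roughly the
    mRNA : lncRNA : miRNA proportions of a tumor transcriptome cohort
    at about one-tenth scale, so that rank-based selection rules (top
    fractions of pairwise association values) operate in the same
    regime as on real data, where within-group pairs are a sub-percent
    minority of all candidate pairs.
    """

    n_subtypes: int = 1
    samples_per_subtype: int = 200
    n_mrna: int = 1200
    n_lncrna: int = 800
    n_mirna: int = 100
    n_groups: int = 5
    group_size_mrna: int = 12
    group_size_lncrna: int = 8
    group_size_mirna: int = 6
    loading: float = 1.2          # beta, log2-scale effect of group activity
    loading_jitter: float = 0.3   # member loadings drawn from beta*U(1-j, 1+j)
    noise_sd: float = 1.0         # log2-scale residual SD
    n_confounders: int = 2        # weak global factors (purity/batch-like)
    confounder_sd: float = 0.25   # SD of per-feature confounder loadings
    baseline_mean: float = 2.0    # log2-FPKM feature baseline mean
    baseline_sd: float = 1.5
    zero_rate: float = 0.1        # MCAR zero-injection fraction
    dropout_feature_frac: float = 0.05  # background features with heavy dropout
    dropout_zero_rate: float = 0.85
    seed: int = 42

    def validate(self) -> None:
        counts = (
            self.n_subtypes, self.samples_per_subtype, self.n_mrna,
            self.n_lncrna, self.n_mirna, self.n_groups,
            self.group_size_mrna, self.group_size_lncrna, self.group_size_mirna,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("counts must be non-negative")
        if self.n_subtypes == 0 or self.samples_per_subtype == 0:
            raise ConfigError("need at least one subtype and one sample")
        for size, total, cls in (
            (self.group_size_mrna, self.n_mrna, "mRNA"),
            (self.group_size_lncrna, self.n_lncrna, "lncRNA"),
            (self.group_size_mirna, self.n_mirna, "miRNA"),
        ):
            if self.n_groups * size > total:
                raise ConfigError(
                    f"{self.n_groups} groups x {size} {cls} members exceed "
                    f"the {total} {cls} features"
                )
        if self.loading_jitter < 0 or self.loading_jitter > 1:
            raise ConfigError("loading_jitter must be in [0, 1]")
        if self.n_confounders < 0:
            raise ConfigError("n_confounders must be non-negative")
        if not 0.0 <= self.zero_rate <= 1.0:
            raise ConfigError("zero_rate must be in [0, 1]")
        if not 0.0 <= self.dropout_feature_frac <= 1.0:
            raise ConfigError("dropout_feature_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure: which feature belongs to which ceRNA group.

    ``group_of`` maps every feature ID to its group (0 = background);
    ``sign_of`` is +1 for mRNA/lncRNA members and -1 for miRNA members;
    ``active_groups`` lists the groups switched on in each subtype.
    """

    group_of: dict[str, int]
    sign_of: dict[str, int]
    class_of: dict[str, str]
    active_groups: dict[str, list[int]]
    n_groups: int

    def members(self, group: int, rna_class: str | None = None) -> list[str]:
        return sorted(
            f for f, g in self.group_of.items()
            if g == group and (rna_class is None or self.class_of[f] == rna_class)
        )

    def grouped_features(self, rna_class: str | None = None) -> list[str]:
        return sorted(
            f for f, g in self.group_of.items()
            if g > 0 and (rna_class is None or self.class_of[f] == rna_class)
        )

    def to_frame(self) -> pd.DataFrame:
        feats = sorted(self.group_of)
        return pd.DataFrame(
            {
                "feature": feats,
                "rna_class": [self.class_of[f] for f in feats],
                "group": [self.group_of[f] for f in feats],
                "sign": [self.sign_of[f] for f in feats],
            }
        )


@dataclass
class SyntheticCohort:
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    labels: pd.Series  # sample -> subtype
    truth: GroundTruth
    config: SyntheticConfig


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _active_groups(n_subtypes: int, n_groups: int) -> dict[str, list[int]]:
    """Subtype s carries all groups except the (s mod n_groups)-th.

    A single-subtype cohort keeps every group active; with several
    subtypes each drops one rotating group, yielding shared and
    subtype-specific modules.
    """
    names = [f"subtype{s + 1}" for s in range(n_subtypes)]
    if n_subtypes == 1 or n_groups == 0:
        return {names[0] if names else "subtype1": list(range(1, n_groups + 1))}
    out = {}
    for s, name in enumerate(names):
        dropped = (s % n_groups) + 1
        out[name] = [g for g in range(1, n_groups + 1) if g != dropped]
    return out


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the three FPKM-scale class matrices plus ground truth.

    Deterministic for a fixed config (including seed): two calls return
    bit-identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_subtypes * config.samples_per_subtype
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    labels = pd.Series(
        np.repeat(
            [f"subtype{s + 1}" for s in range(config.n_subtypes)],
            config.samples_per_subtype,
        ),
        index=pd.Index(sample_ids, name="sample"),
        name="subtype",
    )
    active = _active_groups(config.n_subtypes, config.n_groups)

    # latent group activities; zeroed where the group is inactive
    a = rng.standard_normal((config.n_groups, n_samples))
    # weak global factors shared by all classes (tumor-purity/batch-like);
    # they give background correlations a realistic continuum so that
    # thresholded networks decay smoothly instead of splitting into
    # pure noise plus planted bicliques
    confounders = rng.standard_normal((config.n_confounders, n_samples))
    for s, subtype in enumerate(sorted(active)):
        cols = slice(s * config.samples_per_subtype, (s + 1) * config.samples_per_subtype)
        for g in range(1, config.n_groups + 1):
            if g not in active[subtype]:
                a[g - 1, cols] = 0.0

    class_defs = [
        ("mRNA", "MRNA", config.n_mrna, config.group_size_mrna, +1),
        ("lncRNA", "LNC", config.n_lncrna, config.group_size_lncrna, +1),
        ("miRNA", "MIR", config.n_mirna, config.group_size_mirna, -1),
    ]
    group_of: dict[str, int] = {}
    sign_of: dict[str, int] = {}
    class_of: dict[str, str] = {}
    matrices: dict[str, ExpressionMatrix] = {}

    for rna_class, prefix, n_feat, gsize, sign in class_defs:
        feats = _feature_ids(prefix, n_feat)
        # random group membership, deterministic under the seed
        order = rng.permutation(n_feat)
        membership = np.zeros(n_feat, dtype=int)
        for g in range(config.n_groups):
            membership[order[g * gsize:(g + 1) * gsize]] = g + 1
        for f, g in zip(feats, membership):
            group_of[f] = int(g)
            sign_of[f] = sign if g else 0
            class_of[f] = rna_class

        baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_feat)
        conf_load = rng.normal(
            0.0, config.confounder_sd, size=(n_feat, config.n_confounders)
        )
        member_load = config.loading * rng.uniform(
            1.0 - config.loading_jitter, 1.0 + config.loading_jitter, size=n_feat
        )
        noise = rng.normal(0.0, config.noise_sd, size=(n_feat, n_samples))
        signal = np.zeros((n_feat, n_samples))
        grouped = membership > 0
        if grouped.any() and config.n_groups:
            signal[grouped] = (
                sign * member_load[grouped, None] * a[membership[grouped] - 1]
            )
        log2_expr = baseline[:, None] + conf_load @ confounders + signal + noise
        fpkm = np.exp2(log2_expr)

        # MCAR zero injection; a slice of background features is dropout-heavy
        zero_p = np.full(n_feat, config.zero_rate)
        bg = np.flatnonzero(~grouped)
        n_drop = int(round(config.dropout_feature_frac * len(bg)))
        if n_drop:
            drop_idx = rng.choice(bg, size=n_drop, replace=False)
            zero_p[drop_idx] = config.dropout_zero_rate
        fpkm[rng.random((n_feat, n_samples)) < zero_p[:, None]] = 0.0

        matrices[rna_class] = ExpressionMatrix(
            values=pd.DataFrame(fpkm, index=pd.Index(feats, name="feature"),
                                columns=sample_ids),
            rna_class=rna_class,
            scale="fpkm",
        )

    truth = GroundTruth(
        group_of=group_of, sign_of=sign_of, class_of=class_of,
        active_groups=active, n_groups=config.n_groups,
    )
    return SyntheticCohort(
        mrna=matrices["mRNA"], lncrna=matrices["lncRNA"], mirna=matrices["miRNA"],
        labels=labels, truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------

def _obo_stanza(term_id: str, name: str, namespace: str, parents: list[str]) -> str:
    lines = ["[Term]", f"id: {term_id}", f"name: {name}", f"namespace: {namespace}"]
    lines += [f"is_a: {p}" for p in parents]
    return "\n".join(lines) + "\n"


def generate_toy_ontology(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple["object", pd.DataFrame]:
    """Build a small two-namespace DAG plus gene-to-term annotations.

    Per namespace: one root, two branch terms, one specific term per
    planted group (annotating all and only that group's mRNA members;
    some group terms have two parents so the DAG is not a tree), and two
    generic terms that soak up background mRNAs.  Every mRNA is
    annotated to both roots.  Returns an obonet-style networkx graph and
    a (gene, term, namespace) DataFrame.
    """
    import obonet

    rng = np.random.default_rng(config.seed + 1)
    mrnas = sorted(f for f, c in truth.class_of.items() if c == "mRNA")
    stanzas: list[str] = []
    annotations: list[tuple[str, str, str]] = []

    for ns_idx, ns in enumerate(NAMESPACES):
        tag = "BP" if ns == "biological_process" else "MF"
        root = f"GO:{tag}0000"
        branches = [f"GO:{tag}0001", f"GO:{tag}0002"]
        generic = [f"GO:{tag}0003", f"GO:{tag}0004"]
        stanzas.append(_obo_stanza(root, f"{ns} root", ns, []))
        for b in branches:
            stanzas.append(_obo_stanza(b, f"{ns} branch {b[-1]}", ns, [root]))
        for t, b in zip(generic, branches):
            stanzas.append(_obo_stanza(t, f"{ns} generic {t[-1]}", ns, [b]))

        for g in range(1, truth.n_groups + 1):
            term = f"GO:{tag}{100 + g:04d}"
            parents = [branches[g % 2]]
            if g % 3 == 0:  # a few multi-parent terms keep the DAG non-tree
                parents.append(branches[(g + 1) % 2])
            stanzas.append(_obo_stanza(term, f"{ns} planted group {g}", ns, parents))
            for gene in truth.members(g, "mRNA"):
                annotations.append((gene, term, ns))

        for gene in mrnas:
            annotations.append((gene, root, ns))
            if truth.group_of[gene] == 0 and rng.random() < 0.6:
                annotations.append((gene, str(rng.choice(generic)), ns))

    obo_text = "format-version: 1.2\nontology: toy\n\n" + "\n".join(stanzas)
    graph = obonet.read_obo(io.StringIO(obo_text))
    graph.graph["obo_text"] = obo_text
    ann = pd.DataFrame(annotations, columns=["gene", "term", "namespace"])
    ann = ann.drop_duplicates().sort_values(["gene", "namespace", "term"])
    return graph, ann.reset_index(drop=True)


# ---------------------------------------------------------------------------
# toy PPI
# ---------------------------------------------------------------------------

def generate_toy_ppi(
    truth: GroundTruth,
    p_within: float = 0.8,
    p_between: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Scored protein-interaction list over the cohort's mRNAs.

    Same-group mRNA pairs are connected with probability ``p_within``,
    all other pairs with ``p_between``; every edge carries a confidence
    score drawn uniformly from [0.9, 1.0].
    """
    if not 0.0 <= p_between <= p_within <= 1.0:
        raise ValueError("require 0 <= p_between <= p_within <= 1")
    rng = np.random.default_rng(seed)
    mrnas = sorted(f for f, c in truth.class_of.items() if c == "mRNA")
    groups = np.array([truth.group_of[f] for f in mrnas])
    n = len(mrnas)
    iu, ju = np.triu_indices(n, k=1)
    same = (groups[iu] == groups[ju]) & (groups[iu] > 0)
    p = np.where(same, p_within, p_between)
    keep = rng.random(len(p)) < p
    scores = rng.uniform(0.9, 1.0, size=int(keep.sum()))
    arr = np.array(mrnas)
    return pd.DataFrame(
        {"gene_a": arr[iu[keep]], "gene_b": arr[ju[keep]],
         "score": np.round(scores, 6)}
    )


# ---------------------------------------------------------------------------
# writers for the pipeline's standard text inputs
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 ppi: pd.DataFrame | None = None,
                 ontology=None, annotations: pd.DataFrame | None = None) -> dict:
    """Write the cohort as the pipeline's standard delimited-text inputs.

    The mRNA and lncRNA matrices are stacked into one gene matrix with a
    matching biotype table (protein_coding / lincRNA / antisense), which
    is how annotated expression data arrive in practice.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    genes = pd.concat([cohort.mrna.values, cohort.lncrna.values])
    paths["genes"] = outdir / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index_label="feature")

    paths["mirna"] = outdir / "mirna.tsv"
    cohort.mirna.to_tsv(paths["mirna"])

    biotype = pd.DataFrame(
        {
            "feature": list(cohort.mrna.features) + list(cohort.lncrna.features),
            "biotype": ["protein_coding"] * cohort.mrna.n_features
            + ["lincRNA" if i % 2 == 0 else "antisense"
               for i in range(cohort.lncrna.n_features)],
        }
    )
    paths["biotypes"] = outdir / "biotypes.tsv"
    biotype.to_csv(paths["biotypes"], sep="\t", index=False)

    paths["labels"] = outdir / "labels.tsv"
    cohort.labels.to_frame().reset_index().to_csv(paths["labels"], sep="\t", index=False)

    paths["truth"] = outdir / "ground_truth.tsv"
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    paths["active_groups"] = outdir / "active_groups.json"
    with open(paths["active_groups"], "w") as fh:
        json.dump(cohort.truth.active_groups, fh, indent=1, sort_keys=True)

    if ppi is not None:
        paths["ppi"] = outdir / "ppi.tsv"
        ppi.to_csv(paths["ppi"], sep="\t", index=False)
    if ontology is not None:
        paths["ontology"] = outdir / "ontology.obo"
        Path(paths["ontology"]).write_text(ontology.graph["obo_text"])
    if annotations is not None:
        paths["annotations"] = outdir / "annotations.tsv"
        annotations.to_csv(paths["annotations"], sep="\t", index=False)
    return paths
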