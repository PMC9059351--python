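"""End-to-end per-subtype workflow with persisted intermediates.

Stages: preprocess -> correlate -> network -> associate -> modules ->
functional.  Every stage reads the previous stage's files from the run
directory and writes its own, so any stage can be re-run in isolation
with identical results.  A JSON manifest records parameters, per-stage
counts and output checksums; runs with identical configuration and
seeds are byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AreaError,
    CoherenceConfig,
    assign_areas,
    combine_contexts,
    pairwise_profile_similarity,
    select_coherent_pairs,
)
from .bipartite import BipartiteNetwork, NoCutoffError, build_bipartite, select_cutoff
from .coexpression import ZTable, pairwise_z_table
from .functional import (
    area_functional_report,
    cluster_enrichment_profiles,
    go_enrichment,
    information_content,
    module_target_mrnas,
)
from .matrix import ExpressionMatrix, read_two_column_table
from .module_analysis import (
    build_coherent_network,
    detect_modules,
    intersect_across_cohorts,
)
from .preprocessing import (
    filter_nonzero_features,
    log2_shift_transform,
    partition_by_biotype,
    remove_outlier_samples,
    subtype_expression_filter,
    upper_quartile_normalize,
)

log = logging.getLogger(__name__)

CLASS_PAIRS = (
    ("lncRNA", "mRNA"),
    ("mRNA", "miRNA"),
    ("lncRNA", "miRNA"),
)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run."""

    genes_path: str
    mirna_path: str
    biotypes_path: str
    labels_path: str
    outdir: str
    ppi_path: str | None = None
    ontology_path: str | None = None
    annotations_path: str | None = None

    min_frac: float = 0.8               # non-zero-fraction filter
    median_fpkm_threshold: float = 0.7  # per-subtype low-expression filter
    outlier_sd: float = 2.0
    r2_min: float = 0.8                 # scale-free criterion
    slope_min: float = -2.0
    slope_max: float = -0.5
    min_degree: int = 3                 # sparse-node removal after thresholding
    area_quantile: float = 0.95
    min_indices: int = 3
    top_frac: float = 0.0005
    min_module_size: int = 3
    module_min_links: int = 1
    ppi_score_min: float = 0.95
    enrichment_q_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("genes_path", "mirna_path", "biotypes_path", "labels_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for name in ("ppi_path", "ontology_path", "annotations_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    def coherence(self) -> CoherenceConfig:
        return CoherenceConfig(
            min_indices=self.min_indices,
            top_frac=self.top_frac,
            area_quantile=self.area_quantile,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _pair_name(xc: str, yc: str) -> str:
    return f"{xc}-{yc}"


class Pipeline:
    """Stage-wise runner; see :func:`run_pipeline` for the one-shot API."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "parameters": {
                k: v for k, v in asdict(config).items() if not k.endswith("path")
            },
            "stages": {},
            "checksums": {},
        }

    # -- helpers ---------------------------------------------------------
    def _subdir(self, subtype: str) -> Path:
        d = self.outdir / subtype
        d.mkdir(exist_ok=True)
        return d

    def _record(self, stage: str, **counts) -> None:
        self.manifest["stages"].setdefault(stage, {}).update(counts)

    def _subtypes(self) -> list[str]:
        labels = read_two_column_table(self.config.labels_path, "subtype")
        return sorted(labels.unique())

    # -- stage 1: preprocessing ------------------------------------------
    def stage_preprocess(self) -> None:
        cfg = self.config
        genes = ExpressionMatrix.from_tsv(cfg.genes_path, rna_class="gene")
        mirna = ExpressionMatrix.from_tsv(cfg.mirna_path, rna_class="miRNA")
        biotypes = read_two_column_table(cfg.biotypes_path, "biotype")
        labels = read_two_column_table(cfg.labels_path, "subtype")

        genes = upper_quartile_normalize(filter_nonzero_features(genes, cfg.min_frac))
        mirna = upper_quartile_normalize(filter_nonzero_features(mirna, cfg.min_frac))
        mrna, lncrna = partition_by_biotype(genes, biotypes)
        self._record(
            "preprocess",
            n_mrna=mrna.n_features, n_lncrna=lncrna.n_features,
            n_mirna=mirna.n_features, n_samples=genes.n_samples,
        )

        per_class = {"mRNA": mrna, "lncRNA": lncrna, "miRNA": mirna}
        for rna_class, m in per_class.items():
            split = subtype_expression_filter(
                m, labels, cfg.median_fpkm_threshold,
                median_filter=rna_class != "miRNA",
            )
            for subtype, sm in split.items():
                sm = remove_outlier_samples(log2_shift_transform(sm), cfg.outlier_sd)
                sm.to_tsv(self._subdir(subtype) / f"preprocessed_{rna_class}.tsv")
                self._record(
                    "preprocess",
                    **{f"{subtype}.{rna_class}": [sm.n_features, sm.n_samples]},
                )

    # -- stage 2: correlation --------------------------------------------
    def stage_correlate(self) -> None:
        for subtype in self._subtypes():
            d = self._subdir(subtype)
            mats = {
                c: ExpressionMatrix.from_tsv(
                    d / f"preprocessed_{c}.tsv", rna_class=c, scale="log2"
                )
                for c in ("mRNA", "lncRNA", "miRNA")
            }
            for xc, yc in CLASS_PAIRS:
                zt = pairwise_z_table(mats[xc], mats[yc], clip=True)
                zt.to_tsv(d / f"ztable_{_pair_name(xc, yc)}.tsv")
                self._record("correlate", **{f"{subtype}.{_pair_name(xc, yc)}": len(zt)})

    # -- stage 3: networks -----------------------------------------------
    def stage_network(self) -> None:
        cfg = self.config
        for subtype in self._subtypes():
            d = self._subdir(subtype)
            for xc, yc in CLASS_PAIRS:
                name = _pair_name(xc, yc)
                zt = ZTable.from_tsv(d / f"ztable_{name}.tsv")
                try:
                    fit = select_cutoff(
                        zt, r2_min=cfg.r2_min,
                        slope_range=(cfg.slope_min, cfg.slope_max),
                    )
                except NoCutoffError as exc:
                    # signal-free inputs legitimately yield no scale-free
                    # cutoff; record the scan, emit an empty network and
                    # let downstream stages produce empty results
                    log.warning("subtype %s %s: %s", subtype, name, exc)
                    exc.scan.to_csv(d / f"scan_{name}.tsv", sep="\t", index=False)
                    empty = BipartiteNetwork(
                        edges=pd.DataFrame(columns=["x", "y", "z"]),
                        x_class=xc, y_class=yc,
                    )
                    empty.to_tsv(d / f"network_{name}.tsv")
                    self.manifest.setdefault("warnings", []).append(
                        f"{subtype}.{name}: no scale-free cutoff"
                    )
                    continue
                fit.scan.to_csv(d / f"scan_{name}.tsv", sep="\t", index=False)
                net = build_bipartite(zt, fit.cutoff, cfg.min_degree)
                net.to_tsv(d / f"network_{name}.tsv")
                self._record(
                    "network",
                    **{
                        f"{subtype}.{name}": {
                            "cutoff": fit.cutoff,
                            "r_squared": fit.r_squared,
                            "slope": fit.slope,
                            "n_edges": len(net.edges),
                            "n_x": net.n_x,
                            "n_y": net.n_y,
                        }
                    },
                )

    # -- stage 4: association --------------------------------------------
    def stage_associate(self) -> None:
        cfg = self.config
        for subtype in self._subtypes():
            d = self._subdir(subtype)
            net_lm = BipartiteNetwork.from_tsv(d / "network_lncRNA-mRNA.tsv")
            net_lr = BipartiteNetwork.from_tsv(d / "network_lncRNA-miRNA.tsv")
            net_mr = BipartiteNetwork.from_tsv(d / "network_mRNA-miRNA.tsv")

            def records_for(net1, side1, net2, side2):
                n1 = net1.n_x if side1 == "x" else net1.n_y
                n2 = net2.n_x if side2 == "x" else net2.n_y
                empty = pd.DataFrame(
                    columns=["node_a", "node_b", "index",
                             "value_c1", "value_c2", "area"]
                )
                if n1 < 2 or n2 < 2:
                    return empty
                try:
                    return assign_areas(
                        combine_contexts(
                            pairwise_profile_similarity(net1, side1),
                            pairwise_profile_similarity(net2, side2),
                        ),
                        cfg.area_quantile,
                    )
                except AreaError as exc:
                    log.warning("subtype %s: %s", subtype, exc)
                    self.manifest.setdefault("warnings", []).append(
                        f"{subtype}: {exc}"
                    )
                    return empty

            # lncRNA pairs: shared mRNAs (context 1) vs shared miRNAs (2)
            rec_lnc = records_for(net_lm, "x", net_lr, "x")
            rec_lnc.to_csv(d / "similarity_lncRNA.tsv", sep="\t", index=False)

            # mRNA pairs: shared lncRNAs vs shared miRNAs (the proxy class
            # used to benchmark the area definition)
            rec_mrna = records_for(net_lm, "y", net_mr, "x")
            rec_mrna.to_csv(d / "similarity_mRNA.tsv", sep="\t", index=False)

            if len(rec_lnc):
                pairs = select_coherent_pairs(rec_lnc, cfg.coherence())
            else:
                pairs = pd.DataFrame(columns=["node_a", "node_b", "n_supporting"])
            pairs.to_csv(d / "coherent.tsv", sep="\t", index=False)
            self._record(
                "associate",
                **{
                    f"{subtype}.lncRNA_pairs": int(len(rec_lnc) // 5),
                    f"{subtype}.mRNA_pairs": int(len(rec_mrna) // 5),
                    f"{subtype}.coherent_pairs": int(len(pairs)),
                },
            )

    # -- stage 5: modules -------------------------------------------------
    def stage_modules(self) -> None:
        cfg = self.config
        node_sets: dict[str, set] = {}
        for subtype in self._subtypes():
            d = self._subdir(subtype)
            pairs = pd.read_csv(d / "coherent.tsv", sep="\t", dtype=str)
            graph = build_coherent_network(pairs)
            if graph.number_of_nodes() == 0:
                log.warning("subtype %s: empty coherent network", subtype)
                assignment_frame = pd.DataFrame(columns=["node", "subtype", "module"])
            else:
                assignment = detect_modules(
                    graph, min_size=cfg.min_module_size, seed=cfg.seed
                )
                assignment.subtype = subtype
                assignment_frame = assignment.to_frame()
            assignment_frame.to_csv(d / "modules.tsv", sep="\t", index=False)
            node_sets[subtype] = set(assignment_frame["node"])
            self._record(
                "modules",
                **{
                    f"{subtype}.n_nodes": int(graph.number_of_nodes()),
                    f"{subtype}.n_modules": int(
                        assignment_frame.loc[
                            assignment_frame["module"].astype(int) > 0, "module"
                        ].nunique()
                        if len(assignment_frame)
                        else 0
                    ),
                },
            )
        if len(node_sets) >= 2:
            venn = intersect_across_cohorts(node_sets)
            venn.to_csv(self.outdir / "venn.tsv", sep="\t", index=False)

    # -- stage 6: functional ----------------------------------------------
    def stage_functional(self) -> None:
        cfg = self.config
        ppi = (
            pd.read_csv(cfg.ppi_path, sep="\t", dtype={"gene_a": str, "gene_b": str})
            if cfg.ppi_path
            else None
        )
        stats = None
        if cfg.ontology_path and cfg.annotations_path:
            import obonet

            ontology = obonet.read_obo(cfg.ontology_path)
            annotations = pd.read_csv(cfg.annotations_path, sep="\t", dtype=str)
            stats = information_content(ontology, annotations)
        if ppi is None and stats is None:
            log.info("no PPI or ontology inputs: functional stage skipped")
            return

        for subtype in self._subtypes():
            d = self._subdir(subtype)
            rec_mrna = pd.read_csv(
                d / "similarity_mRNA.tsv", sep="\t",
                dtype={"node_a": str, "node_b": str},
            )
            report = area_functional_report(
                rec_mrna.dropna(subset=["area"]), ppi, stats,
                score_min=cfg.ppi_score_min, seed=cfg.seed,
            )
            report.to_csv(d / "area_report.tsv", sep="\t", index=False)

            if stats is None:
                continue
            modules = pd.read_csv(d / "modules.tsv", sep="\t", dtype={"node": str})
            if not len(modules):
                continue
            net_lm = BipartiteNetwork.from_tsv(d / "network_lncRNA-mRNA.tsv")
            background = set(net_lm.y_nodes)
            q_rows = {}
            for module_id, sub in modules[modules["module"] > 0].groupby("module"):
                targets = module_target_mrnas(
                    sub["node"], net_lm, cfg.module_min_links
                )
                targets &= background
                if not targets:
                    continue
                enr = go_enrichment(targets, background, stats)
                enr.to_csv(d / f"enrichment_module{module_id}.tsv", sep="\t", index=False)
                q_rows[f"module{module_id}"] = enr.set_index("term")["q_value"]
            if len(q_rows) >= 2:
                q_matrix = pd.DataFrame(q_rows).T.fillna(1.0)
                try:
                    _, clusters, profile = cluster_enrichment_profiles(
                        q_matrix, q_threshold=cfg.enrichment_q_threshold
                    )
                    clusters.to_frame().to_csv(
                        d / "module_clusters.tsv", sep="\t", index_label="module"
                    )
                except ValueError as exc:
                    log.warning("subtype %s: %s", subtype, exc)
            self._record("functional", **{f"{subtype}.n_enriched_modules": len(q_rows)})

    # -- orchestration -----------------------------------------------------
    STAGES = (
        "preprocess", "correlate", "network", "associate", "modules", "functional",
    )

    def run_all(self) -> dict:
        t_start = time.time()
        for stage in self.STAGES:
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                self.manifest["failed_stage"] = stage
                self.manifest["error"] = f"{type(exc).__name__}: {exc}"
                self._write_manifest(t_start)
                raise
            self._record(stage, seconds=round(time.time() - t0, 2))
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
        self._write_manifest(t_start)
        return self.manifest

    def _write_manifest(self, t_start: float | None = None) -> None:
        for path in sorted(self.outdir.rglob("*.tsv")):
            self.manifest["checksums"][str(path.relative_to(self.outdir))] = _sha256(path)
        if t_start is not None:
            self.manifest["elapsed_seconds"] = round(time.time() - t_start, 2)
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    return Pipeline(config).run_all()
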