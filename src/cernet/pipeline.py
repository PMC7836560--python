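"""End-to-end orchestration: simulate/ingest -> normalize -> DE -> ceRNA -> survival.

``run_pipeline`` executes the stages in order under one configuration, writes
every intermediate and final table to the output directory, and records a
manifest (seed, thresholds, row counts, SHA-256 of every file) so identical
configurations are verifiably reproducible.  ``summarize_by_cluster``
provides the single-cell per-cluster expression summary on log2(x+1)
normalized values (cluster labels are consumed as input, never computed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineStageError, UsageError
from .cerna_network import (
    CeRNAThresholds,
    build_network,
    infer_cerna_pairs,
    network_stats,
    pairs_table,
)
from .differential_expression import CLASS_NS, moderated_t, volcano_table
from .io_formats import (
    GRAPHML,
    LNCRNA,
    MIRNA,
    PROTEIN_CODING,
    SIF,
    TUMOUR,
    ClinicalTable,
    CountMatrix,
    GeneAnnotation,
    InteractionTable,
    read_clinical_table,
    read_count_matrix,
    read_gene_annotation,
    read_interaction_table,
    write_clinical_table,
    write_count_matrix,
    write_gene_annotation,
    write_interaction_table,
    write_network,
)
from .normalization import ExprMatrix, cpm, filter_low_expression, tmm_factors
from .survival_analysis import gene_survival_screen
from .synthetic_data import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class InputPaths:
    """Paths to an externally provided dataset (alternative to simulation)."""

    rna_counts: str
    rna_groups: str
    mir_counts: str
    mir_groups: str
    annotation: str
    interactions: str
    clinical: str


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``sim`` (synthetic-data configuration) or ``inputs``
    (paths to existing tables) must be set.
    """

    sim: SimConfig | None = None
    inputs: InputPaths | None = None
    out_dir: str = "cernet_out"
    filter_threshold: float = 1.0
    max_low_fraction: float = 0.5
    prior_count: float = 0.5
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    use_adjusted: bool = True
    cerna: CeRNAThresholds = field(default_factory=CeRNAThresholds)
    volcano_cap: float = 320.0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'sim' or 'inputs' must be configured"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim")) if "sim" in raw else None
        inputs = InputPaths(**raw.pop("inputs")) if "inputs" in raw else None
        cerna = CeRNAThresholds(**raw.pop("cerna", {}))
        return cls(sim=sim, inputs=inputs, cerna=cerna, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def _truth_table(truth) -> pd.DataFrame:
    rows = []
    for gene, lfc in sorted(truth.de_genes.items()):
        rows.append({"record": "de", "gene": gene, "value": lfc,
                     "lncrna": "", "mirnas": "", "mrna": ""})
    for tri in truth.triples:
        rows.append({"record": "triple", "gene": "", "value": np.nan,
                     "lncrna": tri.lncrna, "mirnas": ";".join(tri.mirnas),
                     "mrna": tri.mrna})
    for gene, beta in sorted(truth.surv_effects.items()):
        rows.append({"record": "survival", "gene": gene, "value": beta,
                     "lncrna": "", "mirnas": "", "mrna": ""})
    return pd.DataFrame(
        rows, columns=["record", "gene", "value", "lncrna", "mirnas", "mrna"]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the in-memory results plus the manifest.

    Outputs are grouped per stage under ``out_dir``; any stage failure raises
    :class:`PipelineStageError` naming the stage, leaving earlier outputs on
    disk for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.sim.seed if config.sim else None,
        "config": config.to_dict(),
        "stages": {},
        "files": {},
    }
    results: dict = {}

    def _record(stage: str, paths: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p.relative_to(out)) for k, p in paths.items()},
            "row_counts": counts,
        }
        for p in paths.values():
            manifest["files"][str(p.relative_to(out))] = _sha256(p)

    # ------------------------------------------------------------------ data
    stage = "data"
    try:
        if config.sim is not None:
            rna, mir, annotation, interactions, clinical, truth = simulate_dataset(
                config.sim
            )
        else:
            paths = config.inputs
            annotation = read_gene_annotation(paths.annotation)
            rna = read_count_matrix(paths.rna_counts, paths.rna_groups, annotation)
            mir = read_count_matrix(paths.mir_counts, paths.mir_groups)
            interactions = read_interaction_table(paths.interactions)
            clinical = read_clinical_table(paths.clinical)
            truth = None
        stage_dir = out / "01_data"
        stage_dir.mkdir(exist_ok=True)
        files = {
            "rna_counts": stage_dir / "rna_counts.tsv",
            "rna_groups": stage_dir / "rna_groups.tsv",
            "mir_counts": stage_dir / "mir_counts.tsv",
            "mir_groups": stage_dir / "mir_groups.tsv",
            "annotation": stage_dir / "annotation.tsv",
            "interactions": stage_dir / "interactions.tsv",
            "clinical": stage_dir / "clinical.tsv",
        }
        write_count_matrix(rna, files["rna_counts"], files["rna_groups"])
        write_count_matrix(mir, files["mir_counts"], files["mir_groups"])
        write_gene_annotation(annotation, files["annotation"])
        write_interaction_table(interactions, files["interactions"])
        write_clinical_table(clinical, files["clinical"])
        if truth is not None:
            files["ground_truth"] = stage_dir / "ground_truth.tsv"
            _write_table(_truth_table(truth), files["ground_truth"])
        _record(stage, files, {
            "rna_genes": len(rna.gene_ids),
            "mir_genes": len(mir.gene_ids),
            "samples": rna.n_samples,
            "interactions": len(interactions),
            "clinical": len(clinical),
        })
        results.update(
            rna=rna, mir=mir, annotation=annotation,
            interactions=interactions, clinical=clinical, truth=truth,
        )
    except Exception as exc:  # noqa: BLE001 - stage wrapper
        raise PipelineStageError(stage, exc) from exc

    # ------------------------------------------------------------- normalize
    stage = "normalize"
    try:
        stage_dir = out / "02_normalize"
        stage_dir.mkdir(exist_ok=True)
        files = {}
        logcpms: dict[str, ExprMatrix] = {}
        for label, matrix in (("rna", rna), ("mir", mir)):
            factors = tmm_factors(matrix)
            logcpm = cpm(matrix, factors, log=True, prior_count=config.prior_count)
            kept = filter_low_expression(
                logcpm, config.filter_threshold, config.max_low_fraction
            )
            logcpm = ExprMatrix(
                logcpm.values.loc[kept], log=True, prior_count=config.prior_count
            )
            logcpms[label] = logcpm
            f_path = stage_dir / f"{label}_factors.tsv"
            e_path = stage_dir / f"{label}_logcpm.tsv"
            _write_table(
                pd.DataFrame(
                    {"lib_size": factors.lib_size, "factor": factors.factor}
                ).rename_axis("sample_id"),
                f_path,
                index=True,
            )
            _write_table(logcpm.values.rename_axis("gene_id"), e_path, index=True)
            files[f"{label}_factors"] = f_path
            files[f"{label}_logcpm"] = e_path
        _record(stage, files, {
            "rna_genes_kept": len(logcpms["rna"].gene_ids),
            "mir_genes_kept": len(logcpms["mir"].gene_ids),
        })
        results["logcpm"] = logcpms["rna"]
        results["mir_logcpm"] = logcpms["mir"]
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # -------------------------------------------------------------------- de
    stage = "de"
    try:
        stage_dir = out / "03_de"
        stage_dir.mkdir(exist_ok=True)
        groups = rna.sample_groups
        de_rna = moderated_t(
            results["logcpm"], groups,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
        )
        de_mir = moderated_t(
            results["mir_logcpm"], mir.sample_groups,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
            use_adjusted=config.use_adjusted,
        )
        files = {
            "rna_de": stage_dir / "rna_de.tsv",
            "mir_de": stage_dir / "mir_de.tsv",
            "rna_volcano": stage_dir / "rna_volcano.tsv",
            "mir_volcano": stage_dir / "mir_volcano.tsv",
        }
        _write_table(de_rna, files["rna_de"], index=True)
        _write_table(de_mir, files["mir_de"], index=True)
        _write_table(
            volcano_table(de_rna, config.volcano_cap), files["rna_volcano"],
            index=True,
        )
        _write_table(
            volcano_table(de_mir, config.volcano_cap), files["mir_volcano"],
            index=True,
        )
        n_de_rna = int((de_rna["de_class"] != CLASS_NS).sum())
        n_de_mir = int((de_mir["de_class"] != CLASS_NS).sum())
        _record(stage, files, {"de_rna": n_de_rna, "de_mir": n_de_mir})
        results["de_rna"] = de_rna
        results["de_mir"] = de_mir
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ----------------------------------------------------------------- cerna
    stage = "cerna"
    try:
        stage_dir = out / "04_cerna"
        stage_dir.mkdir(exist_ok=True)
        de_rna, de_mir = results["de_rna"], results["de_mir"]
        sig_rna = de_rna.index[de_rna["de_class"] != CLASS_NS]
        de_lnc = [g for g in sig_rna if annotation.biotype_of(g) == LNCRNA]
        de_mrna = [g for g in sig_rna if annotation.biotype_of(g) == PROTEIN_CODING]
        sig_mir = list(de_mir.index[de_mir["de_class"] != CLASS_NS])
        tumour_samples = [
            s for s in results["logcpm"].sample_ids
            if rna.sample_groups[s] == TUMOUR
        ]
        pairs = infer_cerna_pairs(
            de_lnc, de_mrna, sig_mir,
            results["logcpm"], results["mir_logcpm"], interactions,
            thresholds=config.cerna, samples=tumour_samples,
        )
        network = build_network(pairs)
        n_nodes, n_edges, degrees = network_stats(network)
        files = {
            "pairs": stage_dir / "pairs.tsv",
            "network_sif": stage_dir / "network.sif",
            "network_graphml": stage_dir / "network.graphml",
            "degrees": stage_dir / "degrees.tsv",
        }
        _write_table(pairs_table(pairs), files["pairs"])
        write_network(network, files["network_sif"], SIF)
        write_network(network, files["network_graphml"], GRAPHML)
        _write_table(degrees, files["degrees"])
        _record(stage, files, {
            "pairs_evaluated": len(pairs),
            "pairs_passed": sum(p.passed for p in pairs),
            "network_nodes": n_nodes,
            "network_edges": n_edges,
        })
        results["pairs"] = pairs
        results["network"] = network
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # -------------------------------------------------------------- survival
    stage = "survival"
    try:
        stage_dir = out / "05_survival"
        stage_dir.mkdir(exist_ok=True)
        network = results["network"]
        panel = sorted(
            set(network.nodes_of(LNCRNA)) | set(network.nodes_of(PROTEIN_CODING))
        )
        if truth is not None:
            panel = sorted(set(panel) | set(truth.surv_effects))
        panel = [g for g in panel if g in results["logcpm"].values.index]
        surv = gene_survival_screen(results["logcpm"], clinical, panel)
        files = {"survival": stage_dir / "survival.tsv"}
        _write_table(surv, files["survival"])
        _record(stage, files, {"genes_screened": len(surv)})
        results["survival"] = surv
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # -------------------------------------------------------------- manifest
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
    results["manifest"] = manifest
    results["manifest_path"] = manifest_path
    logger.info(
        "pipeline finished: %d DE genes, %d passed pairs, %d-node network",
        manifest["stages"]["de"]["row_counts"]["de_rna"],
        manifest["stages"]["cerna"]["row_counts"]["pairs_passed"],
        manifest["stages"]["cerna"]["row_counts"]["network_nodes"],
    )
    return results


def summarize_by_cluster(
    expr: pd.DataFrame,
    clusters: pd.Series,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-(gene, cluster) summary of log2(x + 1) expression.

    ``expr`` is cells x genes (raw filtered values); ``clusters`` maps every
    cell to its cluster label.  Returns n_cells, mean, median and quartiles
    per gene and cluster; clusters with no cells do not appear.
    """
    clusters = pd.Series(clusters)
    missing = set(expr.index) - set(clusters.index)
    if missing:
        raise UsageError(f"cluster label missing for cell(s) {sorted(missing)[:3]}")
    clusters = clusters.reindex(expr.index)
    if genes is None:
        genes = list(expr.columns)
    rows = []
    for gene in genes:
        if gene not in expr.columns:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        values = np.log2(expr[gene].astype(float) + 1.0)
        for cluster, idx in clusters.groupby(clusters).groups.items():
            v = values.loc[idx]
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "n_cells": len(v),
                    "mean": float(v.mean()),
                    "median": float(v.median()),
                    "q25": float(v.quantile(0.25)),
                    "q75": float(v.quantile(0.75)),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "cluster", "n_cells", "mean", "median", "q25", "q75"]
    )
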