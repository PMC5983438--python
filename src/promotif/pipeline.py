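"""Stagewise orchestration over a data directory of study files.

Each stage reads the study inputs plus the previous stage's persisted
outputs from ``out_dir``, so a run can be resumed or inspected between
stages; ``run_pipeline`` executes the whole chain through the model object.
Gene and site counts are logged after each filtering step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import enrichment, expression, io as pio
from .clustering import (
    classify_pattern,
    group_mean_profiles,
    kmeans_cluster,
    select_reversal_clusters,
    standardize,
)
from .config import PipelineConfig
from .model import (
    PromoterOverrepresentationModel,
    PromoterOverrepresentationResults,
)

log = logging.getLogger("promotif")

STUDY_FILES = {
    "expression": "expression.tsv",
    "design": "design.tsv",
    "orthologs": "orthologs.tsv",
    "ref_fasta": "promoters_rat.fasta",
    "orth_fasta": "promoters_mouse.fasta",
    "matrices": "matrices.transfac",
}


def model_from_dir(
    data_dir: str | Path, config: PipelineConfig | None = None
) -> PromoterOverrepresentationModel:
    d = Path(data_dir)
    missing = [n for n in STUDY_FILES.values() if not (d / n).exists()]
    if missing:
        raise FileNotFoundError(f"study files missing from {d}: {missing}")
    return PromoterOverrepresentationModel.from_files(
        expression=d / STUDY_FILES["expression"],
        design=d / STUDY_FILES["design"],
        orthologs=d / STUDY_FILES["orthologs"],
        ref_fasta=d / STUDY_FILES["ref_fasta"],
        orth_fasta=d / STUDY_FILES["orth_fasta"],
        matrices=d / STUDY_FILES["matrices"],
        config=config,
    )


@dataclass
class ReportBundle:
    """A fitted results object plus the files it was persisted to."""

    results: PromoterOverrepresentationResults
    paths: dict[str, Path]
    out_dir: Path


def run_pipeline(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> ReportBundle:
    """Run the whole chain and persist every report under ``out_dir``."""
    model = model_from_dir(data_dir, config)
    log.info("loaded %d genes x %d samples", *model.expression.shape)
    results = model.fit()
    log.info("DE universe: %d genes", len(results.de_genes))
    log.info(
        "selected reversal clusters: %s (sizes %s)",
        results.selected_clusters,
        [len(cs.genes) for cs in results.cluster_scans],
    )
    for cs in results.cluster_scans:
        c = cs.status_counts
        log.info(
            "cluster %d: %d genes -> %d no_ortholog, %d no_tfbs, %d analysis_ready; "
            "%d matrices flagged",
            cs.cluster_id,
            len(cs.genes),
            c["no_ortholog"],
            c["no_tfbs"],
            c["analysis_ready"],
            len(cs.flagged_matrices),
        )
    paths = results.save(out_dir)
    return ReportBundle(results=results, paths=paths, out_dir=Path(out_dir))


# -- incremental stages ----------------------------------------------------


def stage_de(config: PipelineConfig, data_dir: str | Path, out_dir: str | Path) -> Path:
    """Normalize, fit the variance prior, test the three contrasts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model_from_dir(data_dir, config)
    de = model.differential_expression()
    genes = expression.select_de_genes(de, config.alpha, config.de_use_adjusted)
    pio.write_expression_tsv(model._normalized, out / "normalized.tsv")
    frames = []
    for (a, b), res in de.items():
        f = res[["log2fc", "t", "p", "q"]].copy()
        f.insert(0, "contrast", f"{a}_vs_{b}")
        f.insert(0, "gene_id", f.index)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "de_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (out / "de_genes.txt").write_text("\n".join(genes) + "\n")
    log.info("DE stage: %d of %d genes selected", len(genes), len(model.expression))
    return out / "de_genes.txt"


def stage_cluster(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> Path:
    """Profile, standardize and k-means cluster the DE universe."""
    out = Path(out_dir)
    normalized = pio.read_expression_tsv(out / "normalized.tsv")
    design = pio.read_design_tsv(Path(data_dir) / STUDY_FILES["design"])
    genes = (out / "de_genes.txt").read_text().split()
    profiles = standardize(group_mean_profiles(normalized, design, genes))
    assert profiles.standardized is not None
    assignment = kmeans_cluster(
        profiles.standardized, config.k, config.cluster_seed, config.kmeans_restarts
    )
    labels = {
        cid: classify_pattern(assignment.centroids.loc[cid], config.delta, config.rho)
        for cid in assignment.centroids.index
    }
    selected = select_reversal_clusters(assignment, labels, config.min_cluster_size)
    pd.DataFrame(
        {
            "gene_id": assignment.labels.index,
            "cluster": assignment.labels.to_numpy(),
            "pattern": [labels[c].label for c in assignment.labels],
        }
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    assignment.centroids.to_csv(
        out / "centroids.tsv", sep="\t", index_label="cluster", float_format="%.6f"
    )
    (out / "selected_clusters.txt").write_text(
        "\n".join(str(c) for c in selected) + ("\n" if selected else "")
    )
    log.info("cluster stage: selected %s of %d clusters", selected, config.k)
    return out / "clusters.tsv"


def stage_scan(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> list[Path]:
    """Conservation + MATCH scan of the selected clusters' promoters."""
    out = Path(out_dir)
    model = model_from_dir(data_dir, config)
    from .conservation import ConservationParams

    model._conservation = ConservationParams(evalue_max=config.evalue_max)
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    selected = [int(x) for x in (out / "selected_clusters.txt").read_text().split()]
    from .motifs import classify_gene_status

    written = []
    cache: dict = {}
    for cid in selected:
        genes = list(clusters.loc[clusters["cluster"] == cid, "gene_id"])
        hits_by_gene = {
            g: model._scan_gene(g, cache)
            for g in genes
            if model.orthologs.get(g) is not None
        }
        statuses = classify_gene_status(genes, model.orthologs, hits_by_gene)
        ready = {s.gene_id for s in statuses if s.status == "analysis_ready"}
        all_hits = [h for g in sorted(ready) for h in hits_by_gene[g]]
        pio.write_hits_tsv(all_hits, out / f"cluster{cid}_hits.tsv")
        pd.DataFrame(
            [(s.gene_id, s.status) for s in statuses], columns=["gene_id", "status"]
        ).to_csv(out / f"cluster{cid}_status.tsv", sep="\t", index=False)
        written.append(out / f"cluster{cid}_hits.tsv")
        log.info(
            "scan stage: cluster %d, %d genes, %d analysis-ready, %d hits",
            cid,
            len(genes),
            len(ready),
            len(all_hits),
        )
    return written


def stage_enrich(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> list[Path]:
    """Mann-Whitney over-representation of each scanned cluster."""
    out = Path(out_dir)
    model = model_from_dir(data_dir, config)
    from .conservation import ConservationParams
    from .motifs import GeneScanStatus

    model._conservation = ConservationParams(evalue_max=config.evalue_max)
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    selected = [int(x) for x in (out / "selected_clusters.txt").read_text().split()]
    de_genes = (out / "de_genes.txt").read_text().split()
    universe = [g for g in de_genes if model.orthologs.get(g) is not None]
    matrix_ids = [p.id for p in model.pwms]
    cache: dict = {}
    written = []
    for cid in selected:
        genes = list(clusters.loc[clusters["cluster"] == cid, "gene_id"])
        statuses = [
            GeneScanStatus(gene_id=r.gene_id, status=r.status)
            for r in pd.read_csv(out / f"cluster{cid}_status.tsv", sep="\t").itertuples()
        ]
        hits = pio.read_hits_tsv(out / f"cluster{cid}_hits.tsv")
        table = enrichment.build_count_table(hits, statuses, matrix_ids)
        controls = enrichment.sample_control_sets(
            universe,
            genes,
            n_sets=config.n_control_sets,
            set_size=max(len(table), 1),
            seed=config.control_seed + cid,
        )
        control_tables = [
            pd.DataFrame.from_dict(
                {g: model._count_row(g, cache, matrix_ids) for g in cset},
                orient="index",
                columns=matrix_ids,
            )
            for cset in controls.sets
        ]
        overrep = enrichment.test_overrepresentation(table, control_tables, config.mw_alpha)
        summary = enrichment.summarize_tf_table(table, overrep)
        summary.to_csv(
            out / f"cluster{cid}_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        written.append(out / f"cluster{cid}_summary.tsv")
        log.info(
            "enrich stage: cluster %d, flagged %s",
            cid,
            [r.matrix_id for r in overrep if r.over_represented] or "none",
        )
    return written
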