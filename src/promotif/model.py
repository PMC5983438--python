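"""Model / Results objects for the promoter over-representation analysis.

``PromoterOverrepresentationModel`` holds the study inputs (expression
matrix, group design, promoter pairs, ortholog table, PWM set) and a
``PipelineConfig``; ``fit()`` runs the full inference chain —

    quantile normalization -> moderated-t differential expression (3 pairwise
    contrasts, BH-adjusted) -> group-mean profiles, standardization, k-means
    (k = 10) -> reversal-cluster classification and selection -> conserved-
    region detection and MATCH scanning of cluster and control promoters ->
    per-matrix Mann-Whitney tests against 17 random control sets

— and returns a ``PromoterOverrepresentationResults`` carrying every
intermediate (DE tables, cluster assignment, scan statuses, count tables,
over-representation results) plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import enrichment, expression, io as pio
from .clustering import (
    ClusterAssignment,
    PatternLabel,
    classify_pattern,
    group_mean_profiles,
    kmeans_cluster,
    select_reversal_clusters,
    standardize,
)
from .config import PipelineConfig
from .conservation import ConservationParams, find_conserved_regions
from .enrichment import ControlSets, OverrepResult
from .motifs import (
    PWM,
    GeneScanStatus,
    PromoterRecord,
    SiteHit,
    classify_gene_status,
    scan_promoter,
)


@dataclass
class ClusterScan:
    """Promoter-stage outputs for one selected reversal cluster."""

    cluster_id: int
    genes: list[str]
    statuses: list[GeneScanStatus]
    hits: dict[str, list[SiteHit]]
    count_table: pd.DataFrame
    control_sets: ControlSets
    control_tables: list[pd.DataFrame]
    overrep: list[OverrepResult]
    summary: pd.DataFrame

    @property
    def status_counts(self) -> dict[str, int]:
        out = {"no_ortholog": 0, "no_tfbs": 0, "analysis_ready": 0}
        for s in self.statuses:
            out[s.status] += 1
        return out

    @property
    def analysis_ready_genes(self) -> list[str]:
        return [s.gene_id for s in self.statuses if s.status == "analysis_ready"]

    @property
    def flagged_matrices(self) -> list[str]:
        return [r.matrix_id for r in self.overrep if r.over_represented]


class PromoterOverrepresentationModel:
    """Three-group expression study analysed for over-represented promoter TFBS."""

    def __init__(
        self,
        expression_matrix: pd.DataFrame,
        design: Mapping[str, str],
        ref_promoters: Mapping[str, PromoterRecord],
        orth_promoters: Mapping[str, PromoterRecord],
        orthologs: Mapping[str, str | None],
        pwms: Sequence[PWM],
        config: PipelineConfig | None = None,
    ) -> None:
        self.expression = expression_matrix
        self.design = dict(design)
        self.ref_promoters = dict(ref_promoters)
        self.orth_promoters = dict(orth_promoters)
        self.orthologs = dict(orthologs)
        self.pwms = list(pwms)
        self.config = config or PipelineConfig()

    @classmethod
    def from_bundle(cls, bundle, config: PipelineConfig | None = None):
        """Build from a ``simulate.StudyBundle`` (or any object with the same
        attributes)."""
        return cls(
            expression_matrix=bundle.expression,
            design=bundle.design,
            ref_promoters=bundle.ref_promoters,
            orth_promoters=bundle.orth_promoters,
            orthologs=bundle.orthologs,
            pwms=bundle.pwms,
            config=config,
        )

    @classmethod
    def from_files(
        cls,
        expression: str | Path,
        design: str | Path,
        orthologs: str | Path,
        ref_fasta: str | Path,
        orth_fasta: str | Path,
        matrices: str | Path,
        config: PipelineConfig | None = None,
    ):
        return cls(
            expression_matrix=pio.read_expression_tsv(expression),
            design=pio.read_design_tsv(design),
            ref_promoters=pio.read_promoter_fasta(ref_fasta),
            orth_promoters=pio.read_promoter_fasta(orth_fasta),
            orthologs=pio.read_ortholog_tsv(orthologs),
            pwms=pio.read_transfac_file(matrices),
            config=config,
        )

    # -- stage methods -----------------------------------------------------

    def differential_expression(self) -> dict[tuple[str, str], pd.DataFrame]:
        normalized = expression.normalize_quantile(self.expression)
        params = expression.fit_prior(normalized, self.design)
        self._normalized = normalized
        self._prior = params
        return {
            contrast: expression.moderated_t(normalized, self.design, contrast, params)
            for contrast in expression.CONTRASTS
        }

    def _scan_gene(self, gene: str, cache: dict) -> list[SiteHit]:
        """Conserved regions + MATCH scan for one gene (memoized)."""
        if gene in cache:
            return cache[gene]
        cfg = self.config
        ref = self.ref_promoters[gene]
        orth = self.orth_promoters.get(gene)
        if cfg.restrict_to_conserved:
            if orth is None:
                cache[gene] = []
                return []
            regions = [
                r.interval
                for r in find_conserved_regions(ref, orth, self._conservation)
            ]
        else:
            regions = None
        hits = scan_promoter(self.pwms, ref, regions, cfg.mss_min, cfg.css_min)
        cache[gene] = hits
        return hits

    def fit(self) -> "PromoterOverrepresentationResults":
        cfg = self.config
        self._conservation = ConservationParams(evalue_max=cfg.evalue_max)
        de_results = self.differential_expression()
        de_genes = expression.select_de_genes(
            de_results, cfg.alpha, use_adjusted=cfg.de_use_adjusted
        )

        profiles = group_mean_profiles(self._normalized, self.design, de_genes)
        profiles = standardize(profiles)
        assert profiles.standardized is not None
        assignment = kmeans_cluster(
            profiles.standardized, cfg.k, cfg.cluster_seed, cfg.kmeans_restarts
        )
        labels = {
            cid: classify_pattern(
                assignment.centroids.loc[cid], cfg.delta, cfg.rho
            )
            for cid in assignment.centroids.index
        }
        selected = select_reversal_clusters(assignment, labels, cfg.min_cluster_size)

        scan_cache: dict[str, list[SiteHit]] = {}
        matrix_ids = [p.id for p in self.pwms]
        cluster_scans: list[ClusterScan] = []
        universe_with_orth = [
            g for g in de_genes if self.orthologs.get(g) is not None
        ]
        for cid in selected:
            genes = assignment.members(cid)
            hits_by_gene = {
                g: self._scan_gene(g, scan_cache)
                for g in genes
                if self.orthologs.get(g) is not None
            }
            statuses = classify_gene_status(genes, self.orthologs, hits_by_gene)
            ready = [s.gene_id for s in statuses if s.status == "analysis_ready"]
            cluster_hits = [h for g in ready for h in hits_by_gene[g]]
            table = enrichment.build_count_table(cluster_hits, statuses, matrix_ids)

            controls = enrichment.sample_control_sets(
                universe_with_orth,
                genes,
                n_sets=cfg.n_control_sets,
                set_size=max(len(ready), 1),
                seed=cfg.control_seed + cid,
            )
            control_tables = []
            for cset in controls.sets:
                rows = {g: self._count_row(g, scan_cache, matrix_ids) for g in cset}
                control_tables.append(
                    pd.DataFrame.from_dict(rows, orient="index", columns=matrix_ids)
                )
            overrep = enrichment.test_overrepresentation(
                table, control_tables, cfg.mw_alpha
            )
            summary = enrichment.summarize_tf_table(table, overrep)
            cluster_scans.append(
                ClusterScan(
                    cluster_id=cid,
                    genes=genes,
                    statuses=statuses,
                    hits=hits_by_gene,
                    count_table=table,
                    control_sets=controls,
                    control_tables=control_tables,
                    overrep=overrep,
                    summary=summary,
                )
            )
        return PromoterOverrepresentationResults(
            model=self,
            prior=self._prior,
            de_results=de_results,
            de_genes=de_genes,
            profiles=profiles,
            assignment=assignment,
            pattern_labels=labels,
            selected_clusters=selected,
            cluster_scans=cluster_scans,
        )

    def _count_row(self, gene: str, cache: dict, matrix_ids: list[str]) -> list[int]:
        hits = self._scan_gene(gene, cache)
        counts = {m: 0 for m in matrix_ids}
        for h in hits:
            counts[h.matrix_id] += 1
        return [counts[m] for m in matrix_ids]


@dataclass
class PromoterOverrepresentationResults:
    """Everything the fitted chain computed, stage by stage."""

    model: PromoterOverrepresentationModel
    prior: expression.ModeratedTParams
    de_results: dict[tuple[str, str], pd.DataFrame]
    de_genes: list[str]
    profiles: object
    assignment: ClusterAssignment
    pattern_labels: dict[int, PatternLabel]
    selected_clusters: list[int]
    cluster_scans: list[ClusterScan] = field(default_factory=list)

    def scan_for(self, cluster_id: int) -> ClusterScan:
        for cs in self.cluster_scans:
            if cs.cluster_id == cluster_id:
                return cs
        raise KeyError(f"cluster {cluster_id} was not scanned")

    def de_table(self) -> pd.DataFrame:
        """Long-format DE table: gene, contrast, log2fc, t, p, q."""
        frames = []
        for (a, b), res in self.de_results.items():
            f = res[["log2fc", "t", "p", "q"]].copy()
            f.insert(0, "contrast", f"{a}_vs_{b}")
            f.insert(0, "gene_id", f.index)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def cluster_table(self) -> pd.DataFrame:
        """Per-gene cluster id with the cluster's pattern label."""
        lab = self.assignment.labels
        return pd.DataFrame(
            {
                "gene_id": lab.index,
                "cluster": lab.to_numpy(),
                "pattern": [self.pattern_labels[c].label for c in lab],
            }
        )

    def summary(self) -> str:
        """Human-readable account of the fitted chain."""
        cfg = self.model.config
        sizes = self.assignment.sizes()
        lines = [
            "Promoter TFBS over-representation analysis",
            "=" * 44,
            f"samples: {len(self.model.design)}  genes: {len(self.model.expression)}",
            f"variance prior: d0 = {self.prior.d0:.4g}, s0^2 = {self.prior.s0_sq:.4g}",
            f"DE universe (union of pairwise contrasts, "
            f"{'BH' if cfg.de_use_adjusted else 'raw'} p < {cfg.alpha}): "
            f"{len(self.de_genes)} genes",
            f"k-means (k = {cfg.k}) objective: {self.assignment.objective:.4f}",
            "",
            "cluster  size  pattern        effect  recovery  selected",
        ]
        for cid in self.assignment.centroids.index:
            pl = self.pattern_labels[cid]
            mark = "*" if cid in self.selected_clusters else ""
            lines.append(
                f"{cid:>7}  {int(sizes[cid]):>4}  {pl.label:<13} "
                f"{pl.effect:>7.2f}  {pl.recovery:>8.2f}  {mark}"
            )
        for cs in self.cluster_scans:
            counts = cs.status_counts
            lines += [
                "",
                f"cluster {cs.cluster_id}: {len(cs.genes)} genes -> "
                f"{counts['no_ortholog']} without ortholog, "
                f"{counts['no_tfbs']} without TFBS, "
                f"{counts['analysis_ready']} analysis-ready",
                f"over-represented matrices (p <= {self.model.config.mw_alpha} "
                f"against all {self.model.config.n_control_sets} control sets): "
                f"{', '.join(cs.flagged_matrices) or 'none'}",
            ]
            if len(cs.summary):
                lines.append(cs.summary.drop(columns="genes").to_string(index=False))
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Persist all report tables; returns the path map (the manifest
        records config digest and seeds sufficient to reproduce bitwise)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.model.config
        paths: dict[str, Path] = {}

        paths["de"] = out / "de_results.tsv"
        self.de_table().to_csv(paths["de"], sep="\t", index=False, float_format="%.6g")
        paths["clusters"] = out / "clusters.tsv"
        self.cluster_table().to_csv(paths["clusters"], sep="\t", index=False)
        paths["centroids"] = out / "centroids.tsv"
        self.assignment.centroids.to_csv(
            paths["centroids"], sep="\t", index_label="cluster", float_format="%.6f"
        )
        matrix_lengths = {p.id: len(p) for p in self.model.pwms}
        for cs in self.cluster_scans:
            tag = f"cluster{cs.cluster_id}"
            paths[f"{tag}_status"] = out / f"{tag}_status.tsv"
            pd.DataFrame(
                [(s.gene_id, s.status) for s in cs.statuses],
                columns=["gene_id", "status"],
            ).to_csv(paths[f"{tag}_status"], sep="\t", index=False)
            all_hits = [h for hits in cs.hits.values() for h in hits]
            paths[f"{tag}_hits"] = out / f"{tag}_hits.tsv"
            pio.write_hits_tsv(all_hits, paths[f"{tag}_hits"])
            paths[f"{tag}_bed"] = out / f"{tag}_hits.bed"
            pio.write_hits_bed(all_hits, "rat", paths[f"{tag}_bed"], matrix_lengths)
            paths[f"{tag}_counts"] = out / f"{tag}_counts.tsv"
            cs.count_table.to_csv(
                paths[f"{tag}_counts"], sep="\t", index_label="gene_id"
            )
            paths[f"{tag}_overrep"] = out / f"{tag}_overrep.tsv"
            rows = []
            for r in cs.overrep:
                row = {
                    "matrix": r.matrix_id,
                    "n_sites": r.n_sites,
                    "n_genes_with_site": r.n_genes_with_site,
                    "pct_genes": r.pct_genes,
                    "max_p": r.max_p,
                    "over_represented": r.over_represented,
                }
                row.update({f"p_set{i + 1}": p for i, p in enumerate(r.p_values)})
                rows.append(row)
            pd.DataFrame(rows).to_csv(
                paths[f"{tag}_overrep"], sep="\t", index=False, float_format="%.6g"
            )
            paths[f"{tag}_overrep_json"] = out / f"{tag}_overrep.json"
            pio.write_json(
                {
                    "cluster": cs.cluster_id,
                    "n_analysis_ready": len(cs.count_table),
                    "alpha": cfg.mw_alpha,
                    "n_control_sets": cfg.n_control_sets,
                    "results": rows,
                },
                paths[f"{tag}_overrep_json"],
            )
            paths[f"{tag}_summary"] = out / f"{tag}_summary.tsv"
            cs.summary.to_csv(
                paths[f"{tag}_summary"], sep="\t", index=False, float_format="%.6g"
            )
        import promotif

        paths["manifest"] = out / "manifest.json"
        pio.write_json(
            {
                "config": cfg.to_dict(),
                "config_digest": cfg.digest(),
                "version": promotif.__version__,
                "n_genes": len(self.model.expression),
                "selected_clusters": list(self.selected_clusters),
            },
            paths["manifest"],
        )
        paths["summary"] = out / "summary.txt"
        paths["summary"].write_text(self.summary() + "\n")
        return paths
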