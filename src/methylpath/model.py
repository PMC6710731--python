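"""Model/Results interface for the methylation pathway analysis.

:class:`MethylationPathwayModel` bundles the four study inputs -- a
probes x samples beta matrix with case/control labels, a probe manifest
and a GMT pathway collection -- and :meth:`~MethylationPathwayModel.fit`
runs the full procedure:

    probe QC filter -> CpG differential screen -> gene aggregation ->
    overlap weights -> Fisher x weighted-MWU enrichment -> FPCA ->
    functional-F hub-gene ranking

returning a :class:`PathwayAnalysisResults` that carries every stage
table, a recomputable run report, a ``summary()`` text block and
``save()`` for writing all result tables to disk.  All stages are
deterministic given the inputs; randomness only enters through the
synthetic-study generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import fpca as fp
from . import preprocess as pp
from .simulate import SimulationConfig, SyntheticStudy, generate_study, read_study_inputs

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


class MethylationPathwayModel:
    """Pathway-level analysis of a two-group methylation study.

    Parameters
    ----------
    betas : DataFrame
        Probes x samples beta values in [0, 1], probe ids as index.
    groups : Series
        Sample id -> 'case' / 'control', at least two samples per group.
    manifest : DataFrame
        Probe annotation with columns probe_id, chrom, gene,
        snp_distance, snp_maf, crossreactive.
    gene_sets : GeneSetCollection
        The pathway collection to test.
    seed : int, optional
        Recorded in the run report when the inputs were simulated.
    """

    def __init__(
        self,
        betas: pd.DataFrame,
        groups: pd.Series,
        manifest: pd.DataFrame,
        gene_sets: enr.GeneSetCollection,
        seed: int | None = None,
    ):
        values = betas.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("beta matrix contains missing values")
        if values.min() < 0.0 or values.max() > 1.0:
            raise ValueError("beta values must lie in [0, 1]")
        pp._require_columns(manifest, pp.REQUIRED_MANIFEST_COLUMNS, "manifest")
        missing = set(betas.index) - set(manifest["probe_id"])
        if missing:
            logger.warning("%d beta-matrix probe(s) absent from manifest", len(missing))
        self.betas = betas
        self.groups = groups
        self.manifest = manifest
        self.gene_sets = gene_sets
        self.seed = seed

    @classmethod
    def from_files(cls, betas_path, groups_path, manifest_path, gmt_path) -> "MethylationPathwayModel":
        """Build the model from the TSV/GMT files of a study directory layout."""
        manifest = pd.read_csv(manifest_path, sep="\t")
        betas = pd.read_csv(betas_path, sep="\t", index_col=0)
        grp = pd.read_csv(groups_path, sep="\t")
        groups = pd.Series(
            grp["group"].to_numpy(), index=grp["sample_id"].to_numpy(), name="group"
        )
        gene_sets = enr.read_gmt(gmt_path)
        return cls(betas, groups, manifest, gene_sets)

    @classmethod
    def from_directory(cls, directory) -> "MethylationPathwayModel":
        inputs = read_study_inputs(directory)
        return cls(inputs["betas"], inputs["groups"], inputs["manifest"], inputs["gene_sets"])

    @classmethod
    def from_study(cls, study: SyntheticStudy) -> "MethylationPathwayModel":
        return cls(
            study.betas, study.groups, study.manifest, study.gene_sets,
            seed=study.config.seed,
        )

    @classmethod
    def from_simulation(cls, config: SimulationConfig) -> tuple["MethylationPathwayModel", SyntheticStudy]:
        study = generate_study(config)
        return cls.from_study(study), study

    def fit(
        self,
        p_threshold: float = 0.01,
        s_threshold: float = 0.1,
        enrich_p: float = 0.05,
        min_count: int = 1,
        variance_target: float = 0.9,
        top_k: int = 3,
        delta: float | None = None,
        maf_removes: str = "lt",
        test_method: str = "welch",
        dm_tier: str = "tier1",
        alternative: str = "greater",
        order_rule: str = "group_mean",
        order: list[str] | None = None,
        basis_size: int | None = None,
        background: list[str] | None = None,
    ) -> "PathwayAnalysisResults":
        """Run all stages and return the results object.

        ``dm_tier`` selects which DM gene list feeds enrichment
        ('tier1', the p-screen survivors, or 'tier2', additionally
        |S| >= s_threshold).  ``background`` optionally replaces the
        collection universe as the Fisher/MWU background.
        """
        if dm_tier not in {"tier1", "tier2"}:
            raise ValueError(f"dm_tier must be 'tier1' or 'tier2', got {dm_tier!r}")
        params = {
            "p_threshold": p_threshold,
            "s_threshold": s_threshold,
            "enrich_p": enrich_p,
            "min_count": min_count,
            "variance_target": variance_target,
            "top_k": top_k,
            "delta": delta,
            "maf_removes": maf_removes,
            "test_method": test_method,
            "dm_tier": dm_tier,
            "alternative": alternative,
            "order_rule": order_rule,
            "basis_size": basis_size,
            "seed": self.seed,
        }

        def stage(name, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc

        filt = stage("filter", pp.filter_probes, self.manifest, maf_removes)
        retained = [p for p in self.betas.index if p in set(filt.retained)]
        betas_f = self.betas.loc[retained]
        manifest_f = self.manifest[self.manifest["probe_id"].isin(set(retained))]

        cpg_results = stage("dmp", pp.test_differential_cpgs, betas_f, self.groups, test_method)
        dm = stage(
            "dmp", pp.select_dm_cpgs, cpg_results, p_threshold, s_threshold, manifest_f
        )
        volcano = stage("dmp", pp.volcano_table, cpg_results)

        gene_meth = stage("aggregate", pp.aggregate_to_genes, betas_f, manifest_f)

        weights = stage("weights", enr.compute_gene_weights, self.gene_sets)
        dm_genes = dm.genes_tier1 if dm_tier == "tier1" else dm.genes_tier2
        enrichment_table = stage(
            "enrichment", enr.run_enrichment, dm_genes, self.gene_sets,
            universe=background, alternative=alternative,
        )
        enriched = stage("enrichment", enr.select_enriched, enrichment_table, enrich_p, min_count)
        enrichment_table = enrichment_table.copy()
        enrichment_table["enriched"] = enrichment_table["pathway_id"].isin(
            set(enriched["pathway_id"])
        )

        grid = None
        decomposition = None
        f_table = pd.DataFrame(columns=["rss0", "rss1", "f_value", "delta", "pathways"])
        hub_rows: list[pd.DataFrame] = []
        scored: list[str] = []
        if len(enriched) and gene_meth.matrix.shape[0] >= 2 and gene_meth.matrix.shape[1] >= 4:
            member_map = {
                pid: self.gene_sets[pid].members for pid in enriched["pathway_id"]
            }
            scored = sorted(
                set().union(*member_map.values()) & set(gene_meth.matrix.index)
            )
            if len(scored) >= 2:
                grid = stage(
                    "fpca", fp.build_pseudotime, gene_meth.matrix, self.groups,
                    order_rule, order,
                )
                smoothed = stage(
                    "fpca", fp.smooth_curves, gene_meth.matrix.loc[scored], grid, basis_size
                )
                centered = smoothed.sub(smoothed.mean(axis=1), axis=0)
                decomposition = stage("fpca", fp.fit_fpca, centered, variance_target)
                f_table = stage("fpca", fp.compute_f_table, smoothed, decomposition, delta)
                f_table = f_table.copy()
                f_table["pathways"] = [
                    ";".join(sorted(p for p, mem in member_map.items() if g in mem))
                    for g in f_table.index
                ]
                for pid in enriched["pathway_id"]:
                    ranked = stage("ranking", fp.rank_genes, f_table, member_map[pid], top_k)
                    ranked.insert(0, "pathway_id", pid)
                    hub_rows.append(ranked)
        hub_genes = (
            pd.concat(hub_rows, ignore_index=True)
            if hub_rows
            else pd.DataFrame(columns=["pathway_id", "rank", "gene", "f_value"])
        )

        return PathwayAnalysisResults(
            model=self,
            params=params,
            filter_result=filt,
            cpg_results=cpg_results,
            volcano=volcano,
            dm=dm,
            gene_methylation=gene_meth,
            weights=weights,
            enrichment=enrichment_table,
            enriched=enriched,
            pseudotime=grid,
            fpca=decomposition,
            f_table=f_table,
            hub_genes=hub_genes,
            n_genes_scored=len(scored),
        )


@dataclass
class PathwayAnalysisResults:
    """All stage outputs of one pipeline run.

    Every count in :attr:`report` is recomputable from the tables this
    object writes with :meth:`save`; nothing lives only in memory.
    """

    model: MethylationPathwayModel
    params: dict[str, Any]
    filter_result: pp.FilterResult
    cpg_results: pd.DataFrame
    volcano: pd.DataFrame
    dm: pp.DMSelection
    gene_methylation: pp.GeneMethylation
    weights: pd.DataFrame
    enrichment: pd.DataFrame
    enriched: pd.DataFrame
    pseudotime: fp.PseudoTimeGrid | None
    fpca: fp.FPCADecomposition | None
    f_table: pd.DataFrame
    hub_genes: pd.DataFrame
    n_genes_scored: int

    @property
    def report(self) -> dict[str, Any]:
        """Per-stage counts of the run (the run report)."""
        grp = self.model.groups
        return {
            "version": __version__,
            "seed": self.params.get("seed"),
            "samples_case": int((grp == "case").sum()),
            "samples_control": int((grp == "control").sum()),
            "probes_total": int(len(self.model.manifest)),
            "probes_retained": self.filter_result.rule_counts["retained"],
            "filter_rule_counts": {
                k: self.filter_result.rule_counts[k]
                for k in ("snp_distance", "snp_maf", "crossreactive", "sex_chromosome")
            },
            "tier1_cpgs": self.dm.n_tier1,
            "tier1_genes": len(self.dm.genes_tier1 or ()),
            "tier1_up": self.dm.n_up,
            "tier1_down": self.dm.n_down,
            "tier2_cpgs": self.dm.n_tier2,
            "tier2_genes": len(self.dm.genes_tier2 or ()),
            "genes_aggregated": int(self.gene_methylation.matrix.shape[0]),
            "pathways_tested": int(len(self.enrichment)),
            "pathways_enriched": int(len(self.enriched)),
            "genes_scored": self.n_genes_scored,
            "hub_genes": int(len(self.hub_genes)),
            "pseudotime_rule": self.pseudotime.rule if self.pseudotime else None,
        }

    def summary(self) -> str:
        """Human-readable run summary mirroring the stage reports."""
        r = self.report
        lines = [
            "Methylation pathway analysis",
            "=" * 60,
            f"samples            {r['samples_case']} case / {r['samples_control']} control",
            f"probes             {r['probes_total']} total, {r['probes_retained']} retained "
            f"(maf rule: {self.filter_result.maf_rule})",
            "filter removals    "
            + ", ".join(f"{k}={v}" for k, v in r["filter_rule_counts"].items()),
            f"tier-1 DM CpGs     {r['tier1_cpgs']} (p < {self.params['p_threshold']}) "
            f"covering {r['tier1_genes']} genes; {r['tier1_up']} up / {r['tier1_down']} down",
            f"tier-2 DM CpGs     {r['tier2_cpgs']} (|S| >= {self.params['s_threshold']}) "
            f"covering {r['tier2_genes']} genes",
            f"pathways           {r['pathways_tested']} tested, "
            f"{r['pathways_enriched']} enriched "
            f"(p_combined < {self.params['enrich_p']}, count > {self.params['min_count']})",
        ]
        if len(self.enriched):
            lines.append("")
            lines.append("Enriched pathways (ascending combined p):")
            cols = ["pathway_id", "name", "count", "total", "p_fisher", "p_mwu", "p_combined"]
            lines.append(
                self.enriched[cols].to_string(
                    index=False, float_format=lambda v: f"{v:.4g}"
                )
            )
        else:
            lines.append("")
            lines.append("No enriched pathways at the configured thresholds.")
        if len(self.hub_genes):
            lines.append("")
            lines.append(
                f"Hub genes (top {self.params['top_k']} by functional F per enriched pathway, "
                f"pseudo-time rule: {r['pseudotime_rule']}):"
            )
            lines.append(
                self.hub_genes.to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines) + "\n"

    def save(self, directory) -> dict[str, Path]:
        """Write every stage table plus summary.txt and run_manifest.json."""
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        dm_table = self.cpg_results.copy()
        dm_table["tier1"] = dm_table.index.isin(self.dm.tier1)
        dm_table["tier2"] = dm_table.index.isin(self.dm.tier2)
        paths["dm_cpgs"] = out / "dm_cpgs.tsv"
        dm_table.rename_axis("probe_id").to_csv(paths["dm_cpgs"], sep="\t")

        paths["volcano"] = out / "volcano.tsv"
        self.volcano.rename_axis("probe_id").to_csv(paths["volcano"], sep="\t")

        paths["gene_methylation"] = out / "gene_methylation.tsv"
        self.gene_methylation.matrix.rename_axis("gene").to_csv(
            paths["gene_methylation"], sep="\t"
        )

        paths["weights"] = out / "weights.tsv"
        self.weights.rename_axis("gene").to_csv(paths["weights"], sep="\t")

        paths["enrichment"] = out / "enrichment.tsv"
        self.enrichment.to_csv(paths["enrichment"], sep="\t", index=False)

        paths["fvalues"] = out / "fvalues.tsv"
        self.f_table.rename_axis("gene").to_csv(paths["fvalues"], sep="\t")

        paths["hub_genes"] = out / "hub_genes.tsv"
        self.hub_genes.to_csv(paths["hub_genes"], sep="\t", index=False)

        paths["summary"] = out / "summary.txt"
        paths["summary"].write_text(self.summary())

        manifest = {"parameters": self.params, "report": self.report}
        paths["run_manifest"] = out / "run_manifest.json"
        paths["run_manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return paths
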