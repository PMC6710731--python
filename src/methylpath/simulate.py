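"""Seeded synthetic case/control methylation studies with planted signal.

Emulates the inputs of a two-group 450K-style study: a probe manifest
with filterable probe classes (SNP-proximal, cross-reactive, sex
chromosome), a probes x samples beta-value matrix, and a GMT pathway
collection with controlled gene overlap and one planted differentially
methylated pathway.  A fraction of the planted pathway's members (the
"truth" genes) receive a +effect_size mean shift in the case group, so
every downstream stage can be checked against known ground truth.

Noise model: beta values are generated as expit(logit(baseline) + e)
with e ~ Normal(0, noise_sd) on the logit scale, which keeps values
strictly inside (0, 1) without truncating the noise; the planted effect
is then added on the beta scale and clipped to [0.01, 0.99], so the
case-control delta of truth probes equals effect_size whenever the clip
is inactive.  One integer seed drives separate hierarchical streams for
the manifest, the betas, the gene sets and the truth-gene draw, so
enlarging one component does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .enrichment import GeneSet, GeneSetCollection, read_gmt, write_gmt

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SyntheticStudy",
    "generate_manifest",
    "generate_betas",
    "generate_gene_sets",
    "generate_study",
    "write_study",
    "read_study",
]

# spawn order of the per-component random streams
_STREAMS = {"manifest": 0, "betas": 1, "sets": 2, "truth": 3}

#: SNP distance recorded for probes with no annotated SNP.
NO_SNP_DISTANCE = 1000


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic methylation cohort.

    Defaults describe the package's reference study: 10 pathways of
    25-35 genes drawn from a pool of 280 genes with 30% overlapping
    genes, 3 probes per gene, 20 cases vs 20 controls, baseline beta 0.5
    with logit-scale noise SD 0.2, and a planted pathway in which 70% of
    the members gain +0.15 mean beta in cases.  The pool is sized so any
    draw of pathway sizes is feasible.
    """

    n_genes: int = 280
    probes_per_gene: int | tuple[int, int] = 3
    n_probes: int | None = None
    n_cases: int = 20
    n_controls: int = 20
    n_pathways: int = 10
    pathway_size: tuple[int, int] = (25, 35)
    overlap_fraction: float = 0.3
    planted_pathway_index: int = 0
    planted_gene_fraction: float = 0.7
    effect_size: float = 0.15
    baseline_beta_mean: float = 0.5
    noise_sd: float = 0.2
    frac_snp_probes: float = 0.05
    frac_crossreactive: float = 0.05
    frac_sex_chromosome: float = 0.05
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "overlap_fraction": self.overlap_fraction,
            "planted_gene_fraction": self.planted_gene_fraction,
            "baseline_beta_mean": self.baseline_beta_mean,
            "frac_snp_probes": self.frac_snp_probes,
            "frac_crossreactive": self.frac_crossreactive,
            "frac_sex_chromosome": self.frac_sex_chromosome,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes={self.n_genes} must be >= 1")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigError(
                f"n_cases={self.n_cases}, n_controls={self.n_controls}: need >= 2 per group"
            )
        if not (0.0 <= self.effect_size < 1.0):
            raise ConfigError(f"effect_size={self.effect_size} outside [0, 1)")
        if self.effect_size + self.baseline_beta_mean > 1.0:
            raise ConfigError("effect_size + baseline_beta_mean must be <= 1")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd={self.noise_sd} must be >= 0")
        if self.n_pathways < 1:
            raise ConfigError(f"n_pathways={self.n_pathways} must be >= 1")
        if not (0 <= self.planted_pathway_index < self.n_pathways):
            raise ConfigError(
                f"planted_pathway_index={self.planted_pathway_index} outside [0, {self.n_pathways})"
            )
        lo, hi = self.pathway_size
        if lo < 1 or hi < lo:
            raise ConfigError(f"pathway_size={self.pathway_size} must satisfy 1 <= lo <= hi")
        if isinstance(self.probes_per_gene, tuple):
            plo, phi = self.probes_per_gene
            if plo < 1 or phi < plo:
                raise ConfigError(f"probes_per_gene={self.probes_per_gene} invalid range")
            if self.n_probes is not None:
                raise ConfigError("n_probes cannot be fixed when probes_per_gene is a range")
        elif self.probes_per_gene < 1:
            raise ConfigError(f"probes_per_gene={self.probes_per_gene} must be >= 1")
        if self.n_probes is not None and self.n_probes < self.n_genes:
            raise ConfigError(f"n_probes={self.n_probes} must be >= n_genes={self.n_genes}")

    def stream(self, name: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[name]])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _probe_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Probes owned by each gene (many-to-one probe->gene map)."""
    if isinstance(config.probes_per_gene, tuple):
        lo, hi = config.probes_per_gene
        return rng.integers(lo, hi + 1, size=config.n_genes)
    if config.n_probes is None:
        return np.full(config.n_genes, config.probes_per_gene, dtype=int)
    base, extra = divmod(config.n_probes, config.n_genes)
    counts = np.full(config.n_genes, base, dtype=int)
    counts[:extra] += 1
    return counts


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Probe annotation table with seeded filterable probe classes.

    A ``frac_snp_probes`` share of probes gets an annotated SNP within
    2 bp (violating the SNP-distance rule); other probes carry no SNP
    annotation (distance :data:`NO_SNP_DISTANCE`, MAF missing).
    Cross-reactive and sex-chromosome flags are drawn independently, so
    flag classes may overlap.
    """
    rng = config.stream("manifest")
    counts = _probe_counts(config, rng)
    genes = np.repeat(_gene_ids(config.n_genes), counts)
    n = genes.size

    probe_ids = [f"cg{i + 1:08d}" for i in range(n)]
    autosome = rng.integers(1, 23, size=n)
    chrom = np.array([f"chr{a}" for a in autosome], dtype=object)
    sex_mask = rng.random(n) < config.frac_sex_chromosome
    sex_label = np.where(rng.random(n) < 0.5, "chrX", "chrY")
    chrom[sex_mask] = sex_label[sex_mask]

    snp_mask = rng.random(n) < config.frac_snp_probes
    snp_distance = np.full(n, NO_SNP_DISTANCE, dtype=int)
    snp_distance[snp_mask] = rng.integers(0, 3, size=int(snp_mask.sum()))
    snp_maf = np.full(n, np.nan)
    snp_maf[snp_mask] = rng.uniform(0.01, 0.5, size=int(snp_mask.sum()))

    crossreactive = (rng.random(n) < config.frac_crossreactive).astype(int)

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "gene": genes,
            "snp_distance": snp_distance,
            "snp_maf": snp_maf,
            "crossreactive": crossreactive,
        }
    )


def generate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Pathway collection with a controlled share of overlapping genes.

    An ``overlap_fraction`` share of the resulting gene universe belongs
    to exactly two pathways (weights 1/2); the remainder to exactly one
    (weight 1).  Overlapping genes are placed greedily into the two
    pathways with the most remaining capacity, which keeps the target
    sizes feasible.
    """
    rng = config.stream("sets")
    lo, hi = config.pathway_size
    if hi > config.n_genes:
        raise ConfigError(
            f"pathway_size upper bound {hi} exceeds n_genes={config.n_genes}"
        )
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    total_slots = int(sizes.sum())

    n_overlap = int(round(config.overlap_fraction * total_slots / (1.0 + config.overlap_fraction)))
    n_overlap = min(n_overlap, total_slots // 2)
    if config.n_pathways < 2:
        n_overlap = 0
    n_singles = total_slots - 2 * n_overlap
    n_universe = n_overlap + n_singles
    if n_universe > config.n_genes:
        raise ConfigError(
            f"pathway_size range {config.pathway_size} needs {n_universe} genes, "
            f"only n_genes={config.n_genes} available"
        )

    pool = np.array(_gene_ids(config.n_genes), dtype=object)
    rng.shuffle(pool)
    overlap_genes = pool[:n_overlap]
    single_genes = pool[n_overlap : n_overlap + n_singles]

    capacity = sizes.astype(int).copy()
    members: list[list[str]] = [[] for _ in range(config.n_pathways)]
    # random tie-break among equal capacities, then greedy largest-capacity
    for g in overlap_genes:
        jitter = rng.random(config.n_pathways)
        order = np.lexsort((jitter, -capacity))
        a, b = order[0], order[1]
        if capacity[b] < 1:
            raise ConfigError("cannot place overlapping genes: pathway capacity exhausted")
        members[a].append(g)
        members[b].append(g)
        capacity[a] -= 1
        capacity[b] -= 1
    cursor = 0
    for j in range(config.n_pathways):
        take = capacity[j]
        members[j].extend(single_genes[cursor : cursor + take])
        cursor += take

    width = max(2, len(str(config.n_pathways)))
    sets = [
        GeneSet(f"PW{j + 1:0{width}d}", f"pathway_{j + 1:0{width}d}", tuple(members[j]))
        for j in range(config.n_pathways)
    ]
    return GeneSetCollection(sets)


def _truth_genes(config: SimulationConfig, gene_sets: GeneSetCollection) -> tuple[str, ...]:
    planted = list(gene_sets)[config.planted_pathway_index]
    n_truth = int(round(config.planted_gene_fraction * len(planted)))
    rng = config.stream("truth")
    chosen = rng.choice(np.array(sorted(planted.genes), dtype=object), size=n_truth, replace=False)
    return tuple(sorted(chosen))


def generate_betas(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    truth_genes: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Probes x samples beta matrix with the planted case-group shift.

    Returns ``(betas, groups)`` where groups maps sample id to
    'case'/'control'.  When ``truth_genes`` is not given it is derived
    from the seeded gene-set stream, so manifest, betas and gene sets
    generated from the same config agree on the planted signal.
    """
    if truth_genes is None:
        truth_genes = _truth_genes(config, generate_gene_sets(config))
    rng = config.stream("betas")
    n_probes = len(manifest)
    sample_ids = [f"control_{i + 1:02d}" for i in range(config.n_controls)] + [
        f"case_{i + 1:02d}" for i in range(config.n_cases)
    ]
    groups = pd.Series(
        ["control"] * config.n_controls + ["case"] * config.n_cases,
        index=sample_ids,
        name="group",
    )

    baseline = np.clip(
        rng.normal(config.baseline_beta_mean, 0.05, size=n_probes), 0.05, 0.95
    )
    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, len(sample_ids)))
    values = expit(logit(baseline)[:, None] + noise)

    truth_probe_mask = manifest["gene"].isin(truth_genes).to_numpy()
    case_cols = np.array([groups[s] == "case" for s in sample_ids])
    if config.effect_size > 0 and truth_probe_mask.any():
        block = values[np.ix_(truth_probe_mask, case_cols)] + config.effect_size
        values[np.ix_(truth_probe_mask, case_cols)] = np.clip(block, 0.01, 0.99)

    betas = pd.DataFrame(values, index=manifest["probe_id"].to_numpy(), columns=sample_ids)
    betas.index.name = "probe_id"
    return betas, groups


@dataclass
class SyntheticStudy:
    """A complete simulated study plus its planted-signal ledger."""

    config: SimulationConfig
    manifest: pd.DataFrame
    betas: pd.DataFrame
    groups: pd.Series
    gene_sets: GeneSetCollection
    truth_genes: tuple[str, ...]
    truth_probes: tuple[str, ...]

    @property
    def planted_pathway_id(self) -> str:
        return list(self.gene_sets)[self.config.planted_pathway_index].set_id


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate manifest, betas and gene sets from one seeded config."""
    manifest = generate_manifest(config)
    gene_sets = generate_gene_sets(config)
    truth_genes = _truth_genes(config, gene_sets)
    betas, groups = generate_betas(config, manifest, truth_genes=truth_genes)
    truth_probes = tuple(manifest.loc[manifest["gene"].isin(truth_genes), "probe_id"])
    return SyntheticStudy(
        config=config,
        manifest=manifest,
        betas=betas,
        groups=groups,
        gene_sets=gene_sets,
        truth_genes=truth_genes,
        truth_probes=truth_probes,
    )


def write_study(study: SyntheticStudy, directory) -> dict[str, Path]:
    """Write manifest/betas/groups TSVs, the GMT file and the truth ledger."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": out / "manifest.tsv",
        "betas": out / "betas.tsv",
        "groups": out / "groups.tsv",
        "gmt": out / "pathways.gmt",
        "truth": out / "truth.tsv",
    }
    study.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    study.betas.to_csv(paths["betas"], sep="\t")
    study.groups.rename_axis("sample_id").reset_index().to_csv(
        paths["groups"], sep="\t", index=False
    )
    write_gmt(study.gene_sets, paths["gmt"])
    pd.DataFrame(
        {
            "gene": list(study.truth_genes),
            "pathway_id": study.planted_pathway_id,
            "effect_size": study.config.effect_size,
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_study_inputs(directory) -> dict:
    """Re-read the study files written by :func:`write_study`."""
    d = Path(directory)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t")
    betas = pd.read_csv(d / "betas.tsv", sep="\t", index_col=0)
    grp = pd.read_csv(d / "groups.tsv", sep="\t")
    groups = pd.Series(grp["group"].to_numpy(), index=grp["sample_id"].to_numpy(), name="group")
    gene_sets = read_gmt(d / "pathways.gmt")
    return {"manifest": manifest, "betas": betas, "groups": groups, "gene_sets": gene_sets}


# backwards-friendly alias used by the CLI
read_study = read_study_inputs
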