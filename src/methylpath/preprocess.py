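"""Probe QC filtering, CpG differential screening and gene-level aggregation.

Implements the 450K-style screen used upstream of pathway analysis:

1. drop probes near SNPs (distance <= 2 bp), probes failing the
   minor-allele-frequency rule, cross-reactive probes and probes on the
   sex chromosomes;
2. test every retained CpG for a case/control difference in mean beta
   value (Welch t-test by default), recording the delta-beta
   S = mean(case) - mean(control);
3. select differentially methylated CpGs in two tiers -- tier 1 at
   p < 0.01, tier 2 additionally requiring |S| >= 0.1;
4. aggregate probe betas to gene methylation levels by the arithmetic
   mean of each gene's CpGs.

Beta values are methylated fractions in [0, 1].  No normalisation or
M-value transform is applied; inputs are assumed to be preprocessed
beta matrices.  The raw-p tier selection is deliberate (no multiplicity
correction is used for selection); a Benjamini-Hochberg FDR column is
emitted for information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REQUIRED_MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "gene",
    "snp_distance",
    "snp_maf",
    "crossreactive",
)

_SEX_CHROMS = {"x", "y", "chrx", "chry"}


class SchemaError(ValueError):
    """Raised when an input table lacks a required column."""


@dataclass
class FilterResult:
    """Outcome of probe QC filtering with a per-rule audit.

    ``rule_counts`` counts each rule independently: a probe tripping
    several rules is counted under each of them but removed once.
    """

    retained: pd.Index
    removed: pd.Index
    rule_counts: dict[str, int]
    maf_rule: str


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def filter_probes(manifest: pd.DataFrame, maf_removes: str = "lt") -> FilterResult:
    """Apply the four probe-removal rules and return retained probe ids.

    Rules (a probe is removed if it trips any):

    * ``snp_distance`` -- an annotated SNP within 2 bp (<= 2);
    * ``snp_maf`` -- the annotated SNP's MAF fails the configured rule:
      ``maf_removes='lt'`` removes MAF < 0.05 (the published rule as
      stated), ``'ge'`` removes MAF >= 0.05 (the common-SNP convention);
    * ``crossreactive`` -- cross-hybridising probes;
    * ``sex_chromosome`` -- chrom in {X, Y} (case-insensitive, with or
      without a ``chr`` prefix).

    SNP rules apply only to probes with an annotated SNP (non-missing
    ``snp_maf``).
    """
    _require_columns(manifest, REQUIRED_MANIFEST_COLUMNS, "manifest")
    if maf_removes not in {"lt", "ge"}:
        raise ValueError(f"maf_removes must be 'lt' or 'ge', got {maf_removes!r}")

    maf = pd.to_numeric(manifest["snp_maf"], errors="coerce")
    dist = pd.to_numeric(manifest["snp_distance"], errors="coerce")
    has_snp = maf.notna() & dist.notna()

    rule_snp_distance = has_snp & (dist <= 2)
    if maf_removes == "lt":
        rule_snp_maf = has_snp & (maf < 0.05)
    else:
        rule_snp_maf = has_snp & (maf >= 0.05)
    rule_crossreactive = manifest["crossreactive"].astype(bool)
    chrom = manifest["chrom"].astype(str).str.strip().str.lower()
    rule_sex = chrom.isin(_SEX_CHROMS)

    removed_mask = (
        rule_snp_distance.to_numpy()
        | rule_snp_maf.to_numpy()
        | rule_crossreactive.to_numpy()
        | rule_sex.to_numpy()
    )
    probe_ids = pd.Index(manifest["probe_id"])
    counts = {
        "snp_distance": int(rule_snp_distance.sum()),
        "snp_maf": int(rule_snp_maf.sum()),
        "crossreactive": int(rule_crossreactive.sum()),
        "sex_chromosome": int(rule_sex.sum()),
        "removed": int(removed_mask.sum()),
        "retained": int((~removed_mask).sum()),
    }
    logger.info(
        "probe filter (maf_removes=%s): %d/%d retained, per-rule %s",
        maf_removes,
        counts["retained"],
        len(probe_ids),
        {k: counts[k] for k in ("snp_distance", "snp_maf", "crossreactive", "sex_chromosome")},
    )
    return FilterResult(
        retained=probe_ids[~removed_mask],
        removed=probe_ids[removed_mask],
        rule_counts=counts,
        maf_rule=maf_removes,
    )


def _split_groups(betas: pd.DataFrame, groups: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    labels = set(groups.unique())
    if not labels <= {"case", "control"}:
        raise ValueError(f"group labels must be 'case'/'control', got {sorted(labels)}")
    case_ids = [s for s in betas.columns if groups.get(s) == "case"]
    ctrl_ids = [s for s in betas.columns if groups.get(s) == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_ids)} case / {len(ctrl_ids)} control"
        )
    return betas[case_ids], betas[ctrl_ids]


def test_differential_cpgs(
    betas: pd.DataFrame, groups: pd.Series, method: str = "welch"
) -> pd.DataFrame:
    """Per-probe two-group differential methylation test.

    ``method='welch'`` (default) uses the two-sided Welch two-sample
    t-test on beta values; ``'wilcoxon'`` uses the two-sided
    Mann-Whitney rank-sum test.  Returns a DataFrame indexed by probe
    with columns ``p_value``, ``mean_case``, ``mean_control``, ``S``
    (delta-beta, case minus control), ``direction`` and an informational
    ``fdr`` (Benjamini-Hochberg) column.

    Degenerate probes with zero variance in both groups get p = 1.0 when
    S = 0 and p = 0.0 otherwise.
    """
    case, ctrl = _split_groups(betas, groups)
    mean_case = case.mean(axis=1).to_numpy()
    mean_ctrl = ctrl.mean(axis=1).to_numpy()
    s = mean_case - mean_ctrl

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(case.to_numpy(), ctrl.to_numpy(), axis=1, equal_var=False)
        p = np.asarray(p, dtype=float)
    elif method == "wilcoxon":
        cv, kv = case.to_numpy(), ctrl.to_numpy()
        p = np.empty(betas.shape[0])
        for i in range(betas.shape[0]):
            p[i] = stats.mannwhitneyu(
                cv[i], kv[i], alternative="two-sided", method="asymptotic"
            ).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")

    # constant-row detection must be exact; sample variance of identical
    # values can round to a nonzero float
    both_flat = (case.max(axis=1) == case.min(axis=1)).to_numpy() & (
        ctrl.max(axis=1) == ctrl.min(axis=1)
    ).to_numpy()
    p[both_flat & (s == 0)] = 1.0
    p[both_flat & (s != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)

    direction = np.where(s > 0, "up", np.where(s < 0, "down", "none"))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "p_value": p,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "S": s,
            "direction": direction,
            "fdr": fdr,
        },
        index=betas.index,
    )


# the function is library API, not a pytest case, despite the test_ prefix
test_differential_cpgs.__test__ = False  # type: ignore[attr-defined]


@dataclass
class DMSelection:
    """Two-tier differentially methylated CpG selection.

    Tier 1 passes the p-value screen; tier 2 additionally requires
    |S| >= s_threshold, so tier 2 is always a subset of tier 1.
    """

    tier1: pd.Index
    tier2: pd.Index
    p_threshold: float
    s_threshold: float
    n_up: int
    n_down: int
    genes_tier1: frozenset[str] | None = None
    genes_tier2: frozenset[str] | None = None

    @property
    def n_tier1(self) -> int:
        return len(self.tier1)

    @property
    def n_tier2(self) -> int:
        return len(self.tier2)


def _probe_gene_map(manifest: pd.DataFrame) -> pd.Series:
    """probe_id -> list of gene symbols (multi-gene fields split on ';')."""
    genes = manifest["gene"].astype("string")
    out = {}
    for pid, g in zip(manifest["probe_id"], genes):
        if pd.isna(g) or not str(g).strip():
            out[pid] = []
        else:
            out[pid] = [x.strip() for x in str(g).split(";") if x.strip()]
    return pd.Series(out)


def select_dm_cpgs(
    results: pd.DataFrame,
    p_threshold: float = 0.01,
    s_threshold: float = 0.1,
    manifest: pd.DataFrame | None = None,
) -> DMSelection:
    """Select DM CpGs in two tiers and report the up/down split.

    Tier 1 = {p < p_threshold}; tier 2 = tier 1 and {|S| >= s_threshold}.
    When a manifest is given, the covered gene sets for both tiers are
    reported as well.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if not (0.0 <= s_threshold < 1.0):
        raise ValueError(f"s_threshold must be in [0, 1), got {s_threshold}")

    tier1_mask = results["p_value"] < p_threshold
    tier2_mask = tier1_mask & (results["S"].abs() >= s_threshold)
    tier1 = results.index[tier1_mask]
    tier2 = results.index[tier2_mask]
    n_up = int((results.loc[tier1, "S"] > 0).sum())
    n_down = int((results.loc[tier1, "S"] < 0).sum())

    genes1 = genes2 = None
    if manifest is not None:
        gmap = _probe_gene_map(manifest)
        genes1 = frozenset(g for pid in tier1 for g in gmap.get(pid, []))
        genes2 = frozenset(g for pid in tier2 for g in gmap.get(pid, []))
    return DMSelection(
        tier1=tier1,
        tier2=tier2,
        p_threshold=p_threshold,
        s_threshold=s_threshold,
        n_up=n_up,
        n_down=n_down,
        genes_tier1=genes1,
        genes_tier2=genes2,
    )


@dataclass
class GeneMethylation:
    """Gene x sample methylation with provenance of contributing probes."""

    matrix: pd.DataFrame
    provenance: dict[str, list[str]]
    n_unmapped: int


def aggregate_to_genes(betas: pd.DataFrame, manifest: pd.DataFrame) -> GeneMethylation:
    """Gene methylation level = arithmetic mean of the gene's probes.

    Probes mapping to several genes (``;``-separated in the manifest)
    contribute to each; probes with no gene annotation are skipped with a
    logged count.  Genes with no probe in ``betas`` are absent.
    """
    _require_columns(manifest, ("probe_id", "gene"), "manifest")
    gmap = _probe_gene_map(manifest)
    pairs: list[tuple[str, str]] = []
    n_unmapped = 0
    for pid in betas.index:
        genes = gmap.get(pid, [])
        if len(genes) == 0:
            n_unmapped += 1
            continue
        pairs.extend((pid, g) for g in genes)
    if n_unmapped:
        logger.info("aggregate_to_genes: %d probe(s) without gene annotation skipped", n_unmapped)
    if not pairs:
        return GeneMethylation(
            matrix=pd.DataFrame(columns=betas.columns), provenance={}, n_unmapped=n_unmapped
        )
    link = pd.DataFrame(pairs, columns=["probe_id", "gene"])
    expanded = betas.loc[link["probe_id"]].to_numpy()
    mat = (
        pd.DataFrame(expanded, index=link["gene"].to_numpy(), columns=betas.columns)
        .groupby(level=0)
        .mean()
        .sort_index()
    )
    provenance = {g: sub["probe_id"].tolist() for g, sub in link.groupby("gene")}
    return GeneMethylation(matrix=mat, provenance=provenance, n_unmapped=n_unmapped)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano table: log2(mean_case/mean_control) vs -log10 p.

    Rows with zero control mean are flagged and their fold change
    omitted (NaN).
    """
    mc = results["mean_case"].to_numpy(dtype=float)
    mk = results["mean_control"].to_numpy(dtype=float)
    flagged = mk == 0
    log2fc = np.full(mc.shape, np.nan)
    ok = ~flagged & (mc > 0)
    with np.errstate(divide="ignore"):
        log2fc[ok] = np.log2(mc[ok] / mk[ok])
        neg_log10_p = -np.log10(results["p_value"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"log2_fc": log2fc, "neg_log10_p": neg_log10_p, "flagged": flagged},
        index=results.index,
    )
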