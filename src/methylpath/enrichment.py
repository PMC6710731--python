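"""Overlap-weighted competitive pathway enrichment.

Genes that belong to several pathways are double-counted by naive
over-representation tests.  This module down-weights each gene by the
number of gene sets it belongs to (w = 1/n), then scores every pathway
with two complementary tests:

* a one-sided Fisher/hypergeometric over-representation test of the
  differentially methylated (DM) gene list against a gene universe, and
* a one-sided Mann-Whitney U test asking whether the overlap weights of
  the pathway's DM members are larger than the weights of the background
  (all universe genes outside the pathway) -- the competitive part.

The two p-values are combined as ``p = (p_mwu * p_fisher) / 2`` and
pathways with combined p below threshold and more than ``min_count`` DM
members are reported as enriched.  Note the product combination is not a
calibrated meta-analytic statistic (contrast Fisher's method); it is
used here as the published selection rule and is bounded above by 0.5.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Largest per-group size for which the weighted MWU p-value is computed
#: by exhaustive enumeration of group-label assignments.
EXACT_MWU_LIMIT = 8


class GMTParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """One named pathway: identifier, description, ordered unique members."""

    set_id: str
    name: str
    genes: tuple[str, ...]

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """A GMT-backed collection of gene sets over a shared gene universe."""

    def __init__(self, gene_sets: Sequence[GeneSet]):
        ids = [gs.set_id for gs in gene_sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway ids in collection")
        self._sets = list(gene_sets)
        self._by_id = {gs.set_id: gs for gs in self._sets}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    @property
    def ids(self) -> list[str]:
        return [gs.set_id for gs in self._sets]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self._sets:
            out.update(gs.genes)
        return frozenset(out)

    def membership_counts(self) -> pd.Series:
        """Number of pathways containing each universe gene."""
        counts: dict[str, int] = {}
        for gs in self._sets:
            for g in gs.genes:
                counts[g] = counts.get(g, 0) + 1
        return pd.Series(counts, name="n_pathways").sort_index()

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        return read_gmt(path)

    def to_gmt(self, path) -> None:
        write_gmt(self, path)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated member genes).

    Duplicate members within a line are dropped with a warning; a line
    with fewer than three fields raises :class:`GMTParseError` naming the
    line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                members.append(g)
            if dups:
                logger.warning(
                    "GMT line %d (%s): %d duplicate member(s) dropped", lineno, set_id, dups
                )
            sets.append(GeneSet(set_id, name, tuple(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name, *gs.genes]) + "\n")


def compute_gene_weights(collection: GeneSetCollection) -> pd.DataFrame:
    """Per-gene overlap weights w = 1/n over the collection universe.

    Returns a DataFrame indexed by gene with columns ``n_pathways`` (the
    number of containing gene sets) and ``weight`` (exactly ``1/n``).
    Genes absent from the collection receive no row.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    counts = collection.membership_counts()
    return pd.DataFrame(
        {"n_pathways": counts.astype(int), "weight": 1.0 / counts.to_numpy()}
    )


def fisher_overrepresentation(
    dm_genes: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided (enrichment) hypergeometric tail p for a 2x2 table.

    The table is [in-pathway x in-DM-list] over ``universe``; both gene
    lists are intersected with the universe before tabulation.  Returns
    P(X >= observed overlap).
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    path_set = frozenset(pathway) & uni
    dm = frozenset(dm_genes) & uni
    k = len(dm & path_set)
    return hypergeom_tail(k, len(uni), len(path_set), len(dm))


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def weighted_mwu(
    pathway_dm_weights: Sequence[float],
    background_weights: Sequence[float],
    alternative: str = "greater",
) -> float:
    """Mann-Whitney U p-value comparing in-pathway DM gene weights to background.

    ``alternative='greater'`` tests whether the first group's weights are
    stochastically larger.  When both groups have at most
    :data:`EXACT_MWU_LIMIT` elements the p-value is computed by exhaustive
    enumeration of all group-label assignments (exact under ties);
    otherwise the tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(pathway_dm_weights, dtype=float)
    y = np.asarray(background_weights, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both weight groups must be nonempty")
    if alternative not in {"greater", "less", "two-sided"}:
        raise ValueError(f"unknown alternative: {alternative!r}")
    if x.size <= EXACT_MWU_LIMIT and y.size <= EXACT_MWU_LIMIT:
        return _exact_mwu(x, y, alternative)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def _exact_mwu(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    # Permutation distribution via rank sums: U and the group-1 rank sum
    # differ by a constant, so tail counts agree.  Midranks are half-integers;
    # doubling makes every comparison exact in integer arithmetic.
    pooled = np.concatenate([x, y])
    n1, n = x.size, x.size + y.size
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    obs = int(ranks2[:n1].sum())
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    sums = ranks2[idx].sum(axis=1)
    p_greater = float(np.mean(sums >= obs))
    p_less = float(np.mean(sums <= obs))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def combine_pvalues(p_mwu: float, p_fisher: float) -> float:
    """Combined pathway p-value: (p_mwu * p_fisher) / 2.

    Symmetric in its arguments, monotone in each, bounded above by 0.5.
    """
    for name, p in (("p_mwu", p_mwu), ("p_fisher", p_fisher)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}={p} outside [0, 1]")
    return (p_mwu * p_fisher) / 2.0


def run_enrichment(
    dm_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Score every pathway in ``collection`` against a DM gene list.

    ``universe`` defaults to the collection universe (the largest gene
    space in which both table margins are well defined); an explicit
    background list may be supplied instead.  The MWU background for a
    pathway is every weighted universe gene outside that pathway.

    Returns one row per pathway with columns ``pathway_id``, ``name``,
    ``count`` (DM members), ``total`` (pathway size), ``p_fisher``,
    ``p_mwu`` and ``p_combined``.
    """
    weights = compute_gene_weights(collection)
    uni = frozenset(universe) if universe is not None else collection.universe
    if not uni:
        raise ValueError("empty universe")
    dm = frozenset(dm_genes) & uni
    w = weights["weight"]
    weighted_genes = frozenset(w.index) & uni

    rows = []
    for gs in collection:
        members = gs.members & uni
        hits = sorted(dm & members)
        p_fisher = fisher_overrepresentation(dm, members, uni)
        bg = sorted(weighted_genes - gs.members)
        if hits and bg:
            p_mwu = weighted_mwu(
                w.loc[hits].to_numpy(), w.loc[bg].to_numpy(), alternative=alternative
            )
        else:
            p_mwu = 1.0
        rows.append(
            {
                "pathway_id": gs.set_id,
                "name": gs.name,
                "count": len(hits),
                "total": len(gs),
                "p_fisher": p_fisher,
                "p_mwu": p_mwu,
                "p_combined": combine_pvalues(p_mwu, p_fisher),
            }
        )
    return pd.DataFrame(rows)


def select_enriched(
    results: pd.DataFrame, p_threshold: float = 0.05, min_count: int = 1
) -> pd.DataFrame:
    """Enriched pathways: p_combined < threshold and count > min_count.

    Both inequalities are strict.  The result is sorted ascending by
    combined p, ties broken by pathway id (stable).
    """
    mask = (results["p_combined"] < p_threshold) & (results["count"] > min_count)
    out = results.loc[mask].sort_values(
        ["p_combined", "pathway_id"], kind="mergesort"
    )
    return out.reset_index(drop=True)
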