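"""Functional PCA of gene methylation profiles and the functional F-statistic.

Each gene's methylation levels across samples are treated as a curve
X_i(t) over a pseudo-time grid t in [0, 1].  The study design is
cross-sectional (two groups), so a deterministic pseudo-time ordering is
imposed: controls first, then cases, each group ordered by sample-wise
mean methylation (the rule is recorded in the grid and can be overridden
with an explicit order).  Curves are smoothed with least-squares cubic
B-splines, centred per gene, and decomposed as

    X_i(t) = mu_i + sum_l  xi_il * Phi_l(t)

where Phi_l are the orthonormal eigenfunctions of the across-gene
covariance of the centred curves and xi_il the FPC scores.  Each gene is
then scored by the functional F-statistic

    F_i = (RSS0_i - RSS1_i) / (RSS1_i + delta)

with RSS0 the residual sum of squares around the gene's constant mean
(the null model), RSS1 around the truncated FPCA reconstruction, and
delta a signal-to-noise offset (default: the median RSS1 across scored
genes).  Because the reconstruction is an orthogonal projection that
includes the gene mean, RSS0 >= RSS1 and F >= 0.  Genes with a higher F
carry more structure along the pseudo-time axis; pathway members are
ranked by F to nominate hub genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoTimeGrid:
    """Ordered samples mapped to equispaced positions on [0, 1]."""

    sample_ids: tuple[str, ...]
    positions: np.ndarray
    rule: str

    def __post_init__(self):
        if len(self.sample_ids) != len(self.positions):
            raise ValueError("one position per sample required")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def build_pseudotime(
    gene_matrix: pd.DataFrame,
    groups: pd.Series,
    rule: str = "group_mean",
    order: list[str] | None = None,
) -> PseudoTimeGrid:
    """Order samples on a pseudo-time axis and map them to [0, 1].

    ``rule='group_mean'`` (default): controls first, then cases, each
    group sorted ascending by sample-wise mean methylation (ties broken
    by sample id).  ``rule='given'`` preserves the explicit ``order``.
    The ordering depends only on the data, so permuting input columns
    does not change it.
    """
    samples = list(gene_matrix.columns)
    if len(samples) < 4:
        raise ValueError(f"need >=4 samples, got {len(samples)}")
    if rule == "group_mean":
        means = gene_matrix.mean(axis=0)
        ctrl = sorted(
            (s for s in samples if groups.get(s) == "control"), key=lambda s: (means[s], s)
        )
        case = sorted(
            (s for s in samples if groups.get(s) == "case"), key=lambda s: (means[s], s)
        )
        ordered = ctrl + case
        if len(ordered) != len(samples):
            raise ValueError("every sample needs a case/control label")
    elif rule == "given":
        if order is None or sorted(order) != sorted(samples):
            raise ValueError("rule='given' requires an explicit permutation of the samples")
        ordered = list(order)
    else:
        raise ValueError(f"unknown ordering rule {rule!r}")
    positions = np.linspace(0.0, 1.0, len(ordered))
    return PseudoTimeGrid(sample_ids=tuple(ordered), positions=positions, rule=rule)


def _bspline_design(x: np.ndarray, basis_size: int, degree: int = 3) -> np.ndarray:
    """Design matrix of ``basis_size`` B-splines of ``degree`` on [x0, x1]."""
    n_interior = basis_size - degree - 1
    interior = np.linspace(x[0], x[-1], n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.repeat(x[0], degree + 1), interior, np.repeat(x[-1], degree + 1)]
    )
    return BSpline.design_matrix(x, knots, degree).toarray()


def smooth_curves(
    gene_matrix: pd.DataFrame, grid: PseudoTimeGrid, basis_size: int | None = None
) -> pd.DataFrame:
    """Least-squares cubic B-spline smoothing of every gene's profile.

    Default ``basis_size`` is min(8, n_samples - 1).  Because the spline
    space contains constants, the fit reproduces any curve already in the
    space and preserves each gene's mean exactly (orthogonal projection).
    Returns the smoothed curves evaluated on the grid, columns in
    pseudo-time order.
    """
    n = len(grid.sample_ids)
    if basis_size is None:
        basis_size = min(8, n - 1)
    if basis_size < 4 or basis_size > n:
        raise ValueError(f"basis_size must be in [4, {n}], got {basis_size}")
    x = np.asarray(grid.positions, dtype=float)
    design = _bspline_design(x, basis_size)
    y = gene_matrix[list(grid.sample_ids)].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    smoothed = (design @ coef).T
    return pd.DataFrame(smoothed, index=gene_matrix.index, columns=list(grid.sample_ids))


@dataclass
class FPCADecomposition:
    """Eigenfunctions, scores and retained dimension of an FPCA fit.

    ``eigenfunctions`` has one row per component (orthonormal under the
    plain grid inner product); ``scores`` one row per gene.  ``L`` is the
    number of components needed to reach the variance target; components
    beyond L are kept so a full-rank reconstruction remains available.
    """

    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    scores: pd.DataFrame
    L: int
    variance_target: float

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    def reconstruct(self, n_components: int | None = None) -> pd.DataFrame:
        """Reconstruction of the centred curves from the first components."""
        m = self.L if n_components is None else n_components
        m = min(m, self.n_components)
        if m == 0:
            values = np.zeros((len(self.scores), self.eigenfunctions.shape[1]))
        else:
            values = self.scores.to_numpy()[:, :m] @ self.eigenfunctions[:m]
        return pd.DataFrame(values, index=self.scores.index)


def fit_fpca(centered_curves: pd.DataFrame, variance_target: float = 0.9) -> FPCADecomposition:
    """Eigendecomposition of the across-gene covariance of centred curves.

    The covariance is C(s, t) = sum_i x_i(s) x_i(t) / (n_genes - 1) with
    x_i already centred per gene, so eigenvectors span the curves and a
    full-component reconstruction is exact.  Eigenfunction signs are
    fixed by requiring a nonnegative grid sum (first nonzero coordinate
    positive when the sum vanishes), making repeated fits identical.
    Degenerate input (all centred curves numerically zero) yields L = 0.
    """
    if not (0.0 < variance_target <= 1.0):
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    xc = centered_curves.to_numpy(dtype=float)
    n_genes, n_grid = xc.shape
    if n_genes < 2:
        raise ValueError("need >=2 genes")
    if n_grid < 3:
        raise ValueError("need >=3 grid points")

    cov = xc.T @ xc / (n_genes - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(evals.max(initial=0.0), 0.0) * 1e-12
    keep = evals > tol
    if not keep.any():
        logger.warning("degenerate covariance (all centred curves ~0): L = 0")
        return FPCADecomposition(
            eigenfunctions=np.zeros((0, n_grid)),
            eigenvalues=np.zeros(0),
            variance_explained=np.zeros(0),
            scores=pd.DataFrame(
                np.zeros((n_genes, 0)), index=centered_curves.index
            ),
            L=0,
            variance_target=variance_target,
        )
    evals, evecs = evals[keep], evecs[:, keep]

    phi = evecs.T.copy()
    for l in range(phi.shape[0]):
        s = phi[l].sum()
        if s < 0 or (s == 0 and phi[l][np.flatnonzero(phi[l])[0]] < 0):
            phi[l] = -phi[l]

    total = evals.sum()
    varexp = evals / total
    cum = np.cumsum(varexp)
    reached = np.flatnonzero(cum >= variance_target - 1e-12)
    L = int(reached[0]) + 1 if reached.size else len(evals)

    scores = pd.DataFrame(xc @ phi.T, index=centered_curves.index)
    return FPCADecomposition(
        eigenfunctions=phi,
        eigenvalues=evals,
        variance_explained=varexp,
        scores=scores,
        L=L,
        variance_target=variance_target,
    )


@dataclass(frozen=True)
class GeneFStatistic:
    """Functional F-statistic of a single gene curve."""

    rss0: float
    rss1: float
    f_value: float
    delta: float


def f_statistic(curve, reconstruction, delta: float) -> GeneFStatistic:
    """F = (RSS0 - RSS1) / (RSS1 + delta) for one gene.

    RSS0 measures the curve around its own constant mean (null model);
    RSS1 around the FPCA reconstruction.  ``delta > 0`` acts as a
    signal-to-noise offset keeping the ratio finite for near-perfect
    fits.  The difference is floored at 0 against rounding, since the
    projection guarantees RSS0 >= RSS1 in exact arithmetic.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    x = np.asarray(curve, dtype=float)
    r = np.asarray(reconstruction, dtype=float)
    rss0 = float(((x - x.mean()) ** 2).sum())
    rss1 = float(((x - r) ** 2).sum())
    f = max(rss0 - rss1, 0.0) / (rss1 + delta)
    return GeneFStatistic(rss0=rss0, rss1=rss1, f_value=f, delta=delta)


def compute_f_table(
    smoothed: pd.DataFrame, decomposition: FPCADecomposition, delta: float | None = None
) -> pd.DataFrame:
    """Per-gene RSS0, RSS1 and F over a common decomposition.

    ``delta`` defaults to the median RSS1 across the scored genes
    (floored at 1e-12), an adaptive signal-to-noise scale.
    """
    means = smoothed.mean(axis=1).to_numpy()
    recon = decomposition.reconstruct().to_numpy() + means[:, None]
    x = smoothed.to_numpy(dtype=float)
    rss0 = ((x - means[:, None]) ** 2).sum(axis=1)
    rss1 = ((x - recon) ** 2).sum(axis=1)
    if delta is None:
        delta = max(float(np.median(rss1)), 1e-12)
    elif delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    f = np.maximum(rss0 - rss1, 0.0) / (rss1 + delta)
    return pd.DataFrame(
        {"rss0": rss0, "rss1": rss1, "f_value": f, "delta": delta}, index=smoothed.index
    )


def rank_genes(f_table: pd.DataFrame, members, top_k: int = 3) -> pd.DataFrame:
    """Top-k pathway members by F value (ties broken by gene symbol).

    Members missing from the F table are logged and skipped.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    members = list(members)
    present = [g for g in members if g in f_table.index]
    missing = len(members) - len(present)
    if missing:
        logger.info("rank_genes: %d pathway member(s) absent from F table skipped", missing)
    sub = f_table.loc[sorted(present)]
    ranked = sub.sort_values("f_value", ascending=False, kind="mergesort").head(top_k)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "gene": ranked.index.to_numpy(),
            "f_value": ranked["f_value"].to_numpy(),
        }
    )
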