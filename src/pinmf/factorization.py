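"""Pseudotime-informed non-negative matrix factorization (piNMF).

The expression matrix Y (genes x cells) is approximated by a low-rank
non-negative product: Y^T ~ A X, where the columns of A (cells x r) are
temporal activation patterns and the rows of X (r x genes) hold per-gene
loadings on each pattern. In piNMF mode every temporal pattern is
constrained to be a non-negative spline function of pseudotime,
A = Phi C^T, with Phi a clamped B-spline design matrix evaluated at the
cells' pseudotimes and C >= 0 the spline coefficients. Because B-splines
are non-negative and sum to one at every point, non-negative coefficients
are sufficient for non-negative patterns. In stdNMF mode A is a free
non-negative matrix, so the two modes differ only by the temporal
constraint.

Fitting is by Hierarchical Alternating Least Squares (HALS): blocks of
the problem (one spline-coefficient row, one pattern column, one loading
row) are minimized exactly in turn under non-negativity, which makes the
squared-Frobenius objective non-increasing by construction. Stability
against the non-uniqueness of NMF is obtained by refitting from many
random restarts and clustering the pooled components (consensus NMF).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment, nnls
from scipy.spatial.distance import squareform, pdist
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_EPS = 1e-12


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Raised when an input is structurally unable to support the fit."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryDataset:
    """Non-negative expression matrix with per-cell pseudotime and branch.

    ``expr`` is genes x cells (normalized log expression), ``pseudotime``
    and ``branch`` are per cell. Identifiers must be unique.
    """

    expr: np.ndarray
    pseudotime: np.ndarray
    branch: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        self.branch = np.asarray(self.branch)
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        n_genes, n_cells = self.expr.shape
        if self.pseudotime.shape != (n_cells,) or self.branch.shape != (n_cells,):
            raise ValidationError("pseudotime/branch length must match cell count")
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValidationError("identifier lengths must match matrix shape")
        if not np.all(np.isfinite(self.expr)):
            raise ValidationError("expression matrix contains NaN/Inf")
        if np.any(self.expr < 0):
            i, j = np.argwhere(self.expr < 0)[0]
            raise ValidationError(
                f"negative expression at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValidationError("pseudotime contains NaN/Inf")
        if len(set(self.gene_ids.tolist())) != n_genes:
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids.tolist())) != n_cells:
            raise ValidationError("cell_ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    def subset_branch(self, branches) -> "TrajectoryDataset":
        """Cells whose branch label is in ``branches``, pseudotime order."""
        branches = {branches} if isinstance(branches, str) else set(branches)
        mask = np.isin(self.branch, list(branches))
        if not mask.any():
            raise ValidationError(f"no cells on branch(es) {sorted(branches)}")
        order = np.argsort(self.pseudotime[mask], kind="stable")
        idx = np.flatnonzero(mask)[order]
        return TrajectoryDataset(
            expr=self.expr[:, idx],
            pseudotime=self.pseudotime[idx],
            branch=self.branch[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
        )


@dataclass
class SplineBasis:
    """Clamped B-spline design matrix evaluated at the cells' pseudotimes.

    ``phi`` is cells x K with K = n_knots + degree + 1; rows sum to one
    (partition of unity) and all entries are non-negative.
    """

    degree: int
    n_knots: int
    knots: np.ndarray  # full (clamped) knot vector
    phi: np.ndarray

    @property
    def n_basis(self) -> int:
        return self.phi.shape[1]


@dataclass
class FactorizationConfig:
    rank: int
    mode: str = "pinmf"  # "pinmf" | "stdnmf"
    max_iter: int = 10_000
    tol: float = 1e-10
    n_replicates: int = 750
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError("rank must be >= 1")
        if self.mode not in ("pinmf", "stdnmf"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class ReplicateFactorization:
    """One HALS solution.

    ``A`` (cells x r) holds temporal patterns, ``X`` (r x genes) the gene
    coefficients; in piNMF mode ``C`` (r x K) holds spline coefficients
    with A = Phi C^T. ``objective_trace`` is the squared Frobenius
    residual after each sweep and is non-increasing.
    """

    A: np.ndarray
    X: np.ndarray
    C: np.ndarray | None
    objective_trace: np.ndarray
    converged: bool
    seed: int

    @property
    def rank(self) -> int:
        return self.X.shape[0]


@dataclass
class ConsensusResult:
    consensus_A: np.ndarray  # cells x r
    consensus_X: np.ndarray  # r x genes
    replicate_cluster_labels: np.ndarray
    silhouette: float
    frobenius_error: float
    activations: np.ndarray  # cells x r in [0, 1]
    program_distance: np.ndarray  # r x r
    pseudotime: np.ndarray = field(default=None, repr=False)

    @property
    def rank(self) -> int:
        return self.consensus_X.shape[0]


@dataclass
class GeneModuleAssignment:
    """Per-gene regression of z-scored expression on program activations."""

    gene_ids: np.ndarray
    coefficients: np.ndarray  # genes x r
    pvalues: np.ndarray  # genes x r
    qvalues: np.ndarray  # genes x r
    membership: np.ndarray  # genes x r boolean
    alpha: float
    dropped_genes: np.ndarray  # zero-variance genes excluded from testing

    def module_genes(self, program: int) -> set[str]:
        return set(self.gene_ids[self.membership[:, program]].tolist())


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------


def build_spline_basis(
    pseudotime: np.ndarray, n_knots: int = 4, degree: int = 3
) -> SplineBasis:
    """Clamped B-spline basis with interior knots at pseudotime quantiles.

    ``n_knots`` counts interior breakpoints, so the basis has
    K = n_knots + degree + 1 functions. Quantile placement keeps roughly
    equal numbers of cells per inter-knot interval, which is robust to
    uneven cell density along the trajectory.
    """
    t = np.asarray(pseudotime, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("pseudotime must be a non-empty 1-D array")
    if not np.all(np.isfinite(t)):
        raise ValidationError("pseudotime contains NaN/Inf")
    if n_knots < 1 or degree < 1:
        raise ValidationError("n_knots and degree must be >= 1")
    k_basis = n_knots + degree + 1
    distinct = np.unique(t)
    if distinct.size < k_basis:
        raise DegenerateInputError(
            f"need >= {k_basis} distinct pseudotime values, got {distinct.size}"
        )
    lo, hi = distinct[0], distinct[-1]
    interior = np.quantile(t, np.linspace(0.0, 1.0, n_knots + 2)[1:-1])
    if np.any(interior <= lo) or np.any(interior >= hi):
        # heavily tied pseudotimes: fall back to quantiles of distinct values
        interior = np.quantile(distinct, np.linspace(0.0, 1.0, n_knots + 2)[1:-1])
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    phi = BSpline.design_matrix(t, knots, degree, extrapolate=False).toarray()
    return SplineBasis(degree=degree, n_knots=n_knots, knots=knots, phi=phi)


# ---------------------------------------------------------------------------
# HALS fitting
# ---------------------------------------------------------------------------


def _update_X(A: np.ndarray, Yt: np.ndarray, X: np.ndarray) -> tuple:
    """Exact sequential non-negative row updates of X. Returns (AtA, AtY)."""
    AtA = A.T @ A
    AtY = A.T @ Yt
    r = X.shape[0]
    for j in range(r):
        d = AtA[j, j]
        if d < _EPS:
            X[j] = 0.0
            continue
        X[j] = np.maximum(0.0, X[j] + (AtY[j] - AtA[j] @ X) / d)
    return AtA, AtY


def _update_A_free(A: np.ndarray, Yt: np.ndarray, X: np.ndarray) -> None:
    """Exact sequential non-negative column updates of a free A (stdNMF)."""
    S = X @ X.T
    P = Yt @ X.T
    for j in range(A.shape[1]):
        beta = S[j, j]
        if beta < _EPS:
            A[:, j] = 0.0
            continue
        A[:, j] = np.maximum(0.0, A[:, j] + (P[:, j] - A @ S[:, j]) / beta)


def _update_C(
    C: np.ndarray, phi: np.ndarray, R_chol: np.ndarray, Yt: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Exact per-component NNLS updates of the spline coefficients C.

    For component j the subproblem min_{c>=0} S_jj c'Gc - 2 c'v with
    G = Phi'Phi = R'R is rewritten as an ordinary NNLS in the Cholesky
    coordinates. Returns the implied A = Phi C^T.
    """
    S = X @ X.T
    PhiT_P = phi.T @ (Yt @ X.T)  # K x r
    G = R_chol.T @ R_chol
    r = C.shape[0]
    for j in range(r):
        beta = S[j, j]
        if beta < _EPS:
            C[j] = 0.0
            continue
        v = PhiT_P[:, j] - G @ (C.T @ S[:, j] - beta * C[j])
        z = solve_triangular(R_chol.T, v, lower=True) / np.sqrt(beta)
        C[j], _ = nnls(np.sqrt(beta) * R_chol, z)
    return phi @ C.T


def fit_replicate(
    data: TrajectoryDataset,
    basis: SplineBasis | None,
    config: FactorizationConfig,
    seed: int,
) -> ReplicateFactorization:
    """One HALS fit from a uniform(0, 1] random initialization.

    The objective ||Y^T - A X||_F^2 is minimized block-wise under
    non-negativity; every block update is an exact constrained minimizer,
    so the per-sweep objective trace never increases. After convergence
    each temporal pattern is rescaled to unit maximum with the
    compensating inverse rescale applied to the corresponding row of X,
    leaving the product A X unchanged.
    """
    Yt = np.ascontiguousarray(data.expr.T, dtype=float)
    n_cells, n_genes = Yt.shape
    r = config.rank
    if r > min(n_cells, n_genes):
        raise ValidationError(f"rank {r} exceeds min(cells, genes)")
    pinmf = config.mode == "pinmf"
    if pinmf:
        if basis is None:
            raise ValidationError("piNMF mode requires a spline basis")
        if basis.phi.shape[0] != n_cells:
            raise ValidationError("basis rows must align with cells")

    rng = np.random.default_rng(seed)
    if not Yt.any():
        warnings.warn("all-zero expression matrix; returning zero factors")
        K = basis.n_basis if pinmf else 0
        return ReplicateFactorization(
            A=np.zeros((n_cells, r)),
            X=np.zeros((r, n_genes)),
            C=np.zeros((r, K)) if pinmf else None,
            objective_trace=np.zeros(1),
            converged=True,
            seed=seed,
        )

    X = 1.0 - rng.random((r, n_genes))  # uniform (0, 1]
    if pinmf:
        K = basis.n_basis
        C = 1.0 - rng.random((r, K))
        G = basis.phi.T @ basis.phi
        # tiny jitter keeps Cholesky stable if the design is near-singular
        R_chol = cholesky(G + _EPS * np.eye(K), lower=False)
        A = basis.phi @ C.T
    else:
        C = None
        A = 1.0 - rng.random((n_cells, r))

    yy = float(np.dot(Yt.ravel(), Yt.ravel()))
    trace = []
    prev = np.inf
    converged = False
    for _ in range(config.max_iter):
        if pinmf:
            A = _update_C(C, basis.phi, R_chol, Yt, X)
        else:
            _update_A_free(A, Yt, X)
        AtA, AtY = _update_X(A, Yt, X)
        obj = yy - 2.0 * float(np.sum(AtY * X)) + float(np.sum(AtA * (X @ X.T)))
        obj = max(obj, 0.0)
        trace.append(obj)
        if prev < np.inf and prev - obj < config.tol * max(prev, _EPS):
            converged = True
            break
        prev = obj

    # unit-maximum convention for temporal patterns; A X is unchanged
    for j in range(r):
        m = A[:, j].max()
        if m > 0:
            A[:, j] /= m
            X[j] *= m
            if pinmf:
                C[j] /= m
    return ReplicateFactorization(
        A=A, X=X, C=C, objective_trace=np.asarray(trace),
        converged=converged, seed=seed,
    )


def run_ensemble(
    data: TrajectoryDataset,
    basis: SplineBasis | None,
    config: FactorizationConfig,
) -> list[ReplicateFactorization]:
    """``n_replicates`` independent fits, replicate i seeded base_seed + i."""
    out = []
    for i in range(config.n_replicates):
        try:
            out.append(fit_replicate(data, basis, config, seed=config.base_seed + i))
        except Exception as exc:  # annotate which replicate failed
            raise RuntimeError(f"replicate {i} failed: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _l2_normalize_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def _refit_temporal(
    Yt: np.ndarray, X: np.ndarray, basis: SplineBasis | None,
    max_sweeps: int = 500, tol: float = 1e-12,
) -> np.ndarray:
    """Non-negative least-squares refit of A given fixed X (convex)."""
    n_cells = Yt.shape[0]
    r = X.shape[0]
    if basis is not None:
        K = basis.n_basis
        C = np.full((r, K), 0.5)
        G = basis.phi.T @ basis.phi
        R_chol = cholesky(G + _EPS * np.eye(K), lower=False)
        A = basis.phi @ C.T
    else:
        A = np.full((n_cells, r), 0.5)
    prev = np.inf
    for _ in range(max_sweeps):
        if basis is not None:
            A = _update_C(C, basis.phi, R_chol, Yt, X)
        else:
            _update_A_free(A, Yt, X)
        obj = float(np.linalg.norm(Yt - A @ X) ** 2)
        if prev - obj < tol * max(prev, _EPS):
            break
        prev = obj
    return A


def consensus_programs(
    data: TrajectoryDataset,
    basis: SplineBasis | None,
    replicates: list[ReplicateFactorization],
    rank: int,
    kmeans_seed: int = 0,
    outlier_filter_frac: float | None = None,
) -> ConsensusResult:
    """Cluster pooled replicate components into ``rank`` stable programs.

    The r gene-coefficient rows of every replicate's X are L2-normalized
    and pooled; K-means with k = rank (Euclidean distance) groups
    recurring components, the cluster centroids become consensus_X, and
    consensus_A is a single constrained non-negative least-squares refit
    of the temporal factor against consensus_X. Silhouette on the
    clustered vectors quantifies stability; the Frobenius norm of
    Y^T - A X quantifies reconstruction error. Programs are ordered by
    the pseudotime at which their consensus pattern peaks.
    """
    if len(replicates) < 2:
        raise ValidationError("need >= 2 replicates for consensus")
    ranks = {rep.rank for rep in replicates}
    if ranks != {rank}:
        raise ValidationError(f"replicate ranks {sorted(ranks)} != requested {rank}")
    n_genes = {rep.X.shape[1] for rep in replicates}
    if len(n_genes) != 1:
        raise ValidationError("replicates have mismatched gene sets")

    comps = np.vstack([_l2_normalize_rows(rep.X) for rep in replicates])
    live = np.linalg.norm(comps, axis=1) > 0
    n_dead = int((~live).sum())
    if n_dead:
        # dead components carry no program information and would form a
        # spurious zero-vector cluster; excluded from the pooling
        logger.info("excluding %d dead (all-zero) components from consensus", n_dead)
        comps = comps[live]
    if comps.shape[0] < rank + 1:
        raise ValidationError("too few live components to form a consensus")
    km = KMeans(n_clusters=rank, n_init=10, random_state=kmeans_seed)
    labels = km.fit_predict(comps)
    if outlier_filter_frac:
        if not 0.0 < outlier_filter_frac < 1.0:
            raise ValidationError("outlier_filter_frac must be in (0, 1)")
        # drop the components farthest from their centroid and recluster
        dist = np.linalg.norm(comps - km.cluster_centers_[labels], axis=1)
        keep = dist <= np.quantile(dist, 1.0 - outlier_filter_frac)
        if keep.sum() < rank + 1:
            raise ValidationError("outlier filtering left too few components")
        comps = comps[keep]
        km = KMeans(n_clusters=rank, n_init=10, random_state=kmeans_seed)
        labels = km.fit_predict(comps)
    if len(np.unique(labels)) < rank:
        raise RuntimeError("empty K-means cluster; resampling failed")
    consensus_X = km.cluster_centers_.copy()
    consensus_X[consensus_X < 0] = 0.0  # numerical guard; centroids of >=0 rows

    Yt = np.ascontiguousarray(data.expr.T, dtype=float)
    A = _refit_temporal(Yt, consensus_X, basis)

    # order programs by pseudotime of peak activation
    peak_t = [data.pseudotime[np.argmax(A[:, j])] for j in range(rank)]
    order = np.argsort(peak_t, kind="stable")
    A = A[:, order]
    consensus_X = consensus_X[order]
    relabel = np.empty(rank, dtype=int)
    relabel[order] = np.arange(rank)
    labels = relabel[labels]

    for j in range(rank):
        m = A[:, j].max()
        if m > 0:
            A[:, j] /= m
            consensus_X[j] *= m

    sil = float(silhouette_score(comps, labels, metric="euclidean"))
    frob = float(np.linalg.norm(Yt - A @ consensus_X))
    result = ConsensusResult(
        consensus_A=A,
        consensus_X=consensus_X,
        replicate_cluster_labels=labels,
        silhouette=sil,
        frobenius_error=frob,
        activations=np.zeros_like(A),
        program_distance=program_distance_matrix(consensus_X),
        pseudotime=data.pseudotime.copy(),
    )
    result.activations = activation_scale(result)
    return result


def activation_scale(consensus: ConsensusResult) -> np.ndarray:
    """Min-max scale each program's temporal pattern across cells to [0, 1]."""
    A = consensus.consensus_A
    out = np.zeros_like(A)
    for j in range(A.shape[1]):
        col = A[:, j]
        rng_ = col.max() - col.min()
        if rng_ <= 0:
            warnings.warn(f"program {j} has a constant pattern; activation set to 0")
            continue
        out[:, j] = (col - col.min()) / rng_
    return out


def program_distance_matrix(consensus_X: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between L2-normalized program vectors."""
    normed = _l2_normalize_rows(np.asarray(consensus_X, dtype=float))
    if normed.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(normed, metric="euclidean"))


def program_distance(consensus: ConsensusResult) -> np.ndarray:
    return program_distance_matrix(consensus.consensus_X)


def rank_sweep(
    data: TrajectoryDataset,
    basis: SplineBasis | None,
    ranks: list[int],
    config: FactorizationConfig,
) -> pd.DataFrame:
    """Ensemble + consensus per rank; silhouette and error guide selection.

    ``frobenius_error`` is the consensus reconstruction error;
    ``best_replicate_error`` is the smallest final objective (square
    root) across the ensemble, which decreases with rank when fits are
    near-optimal.
    """
    rows = []
    for r in ranks:
        if r < 2:
            raise ValidationError("rank sweep requires ranks >= 2 (silhouette needs k >= 2)")
        cfg = replace(config, rank=r)
        reps = run_ensemble(data, basis, cfg)
        cons = consensus_programs(data, basis, reps, rank=r)
        best = float(np.sqrt(min(rep.objective_trace[-1] for rep in reps)))
        rows.append(
            {
                "rank": r,
                "silhouette": cons.silhouette,
                "frobenius_error": cons.frobenius_error,
                "best_replicate_error": best,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene-module assignment
# ---------------------------------------------------------------------------


def assign_gene_modules(
    data: TrajectoryDataset,
    consensus: ConsensusResult,
    alpha: float = 0.05,
) -> GeneModuleAssignment:
    """OLS of z-scored expression on program activations, BH-corrected.

    Each gene's expression is z-scored across cells and regressed on the
    r activation columns (plus intercept). A gene belongs to every
    program whose coefficient is positive with BH-adjusted q < alpha;
    genes may belong to several modules. Zero-variance genes are
    excluded and reported.
    """
    act = consensus.activations
    n_cells, r = act.shape
    if n_cells != data.n_cells:
        raise ValidationError("consensus activations do not match the dataset cells")
    D = np.column_stack([np.ones(n_cells), act])
    if np.linalg.matrix_rank(D) < r + 1:
        raise ValidationError("collinear program activations: design is rank-deficient")

    mu = data.expr.mean(axis=1, keepdims=True)
    sd = data.expr.std(axis=1, keepdims=True)
    keep = sd.ravel() > 0
    dropped = data.gene_ids[~keep]
    if dropped.size:
        logger.info("excluding %d zero-variance genes from module assignment", dropped.size)
    Z = ((data.expr[keep] - mu[keep]) / sd[keep]).T  # cells x genes

    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ D.T @ Z  # (r+1) x genes
    resid = Z - D @ beta
    dof = n_cells - (r + 1)
    if dof <= 0:
        raise ValidationError("not enough cells for the regression degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(DtD_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    coef = beta[1:].T  # genes x r
    pv = pvals[1:].T
    qv = multipletests(pv.ravel(), method="fdr_bh")[1].reshape(pv.shape)
    membership = (qv < alpha) & (coef > 0)
    return GeneModuleAssignment(
        gene_ids=data.gene_ids[keep],
        coefficients=coef,
        pvalues=pv,
        qvalues=qv,
        membership=membership,
        alpha=alpha,
        dropped_genes=dropped,
    )


def match_programs(patterns_a: np.ndarray, patterns_b: np.ndarray) -> list[tuple[int, int]]:
    """Pair programs across two fits by maximal Pearson correlation.

    ``patterns_*`` are cells x r temporal patterns over the same cells;
    the Hungarian assignment maximizes total correlation.
    """
    ra, rb = patterns_a.shape[1], patterns_b.shape[1]
    corr = np.zeros((ra, rb))
    for i in range(ra):
        for j in range(rb):
            sa, sb = patterns_a[:, i].std(), patterns_b[:, j].std()
            if sa > 0 and sb > 0:
                corr[i, j] = np.corrcoef(patterns_a[:, i], patterns_b[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return list(zip(rows.tolist(), cols.tolist()))


def module_overlap(
    assign_a: GeneModuleAssignment,
    assign_b: GeneModuleAssignment,
    matching: list[tuple[int, int]],
) -> pd.DataFrame:
    """Percent of each reference module recovered in the matched module.

    For matched pair (i, j): 100 * |A_i intersect B_j| / |A_i|, where A_i
    is the reference module (from ``assign_a``). Asymmetric by design.
    """
    shared = set(assign_a.gene_ids.tolist()) & set(assign_b.gene_ids.tolist())
    rows = []
    for i, j in matching:
        a = assign_a.module_genes(i) & shared
        b = assign_b.module_genes(j) & shared
        if not a:
            warnings.warn(f"reference module {i} is empty; overlap set to 0")
            pct = 0.0
        else:
            pct = 100.0 * len(a & b) / len(a)
        rows.append({"program_a": i, "program_b": j, "overlap_pct": pct})
    return pd.DataFrame(rows)
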