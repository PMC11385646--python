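"""Unit tests for the spline basis, HALS fits, consensus and modules."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

import pinmf as P
from pinmf.factorization import DegenerateInputError, ValidationError

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------


class TestSplineBasis:
    @pytest.mark.parametrize("n_knots,degree", [(4, 3), (1, 1), (2, 2), (6, 3)])
    def test_basis_dimension_and_partition_of_unity(self, rng, n_knots, degree):
        t = rng.random(60)
        basis = P.build_spline_basis(t, n_knots=n_knots, degree=degree)
        assert basis.phi.shape == (60, n_knots + degree + 1)
        assert np.all(basis.phi >= 0)
        assert np.abs(basis.phi.sum(axis=1) - 1.0).max() < 1e-12

    def test_matches_reference_bspline_evaluation(self, rng):
        """Each column equals direct evaluation of the corresponding B-spline."""
        t = np.sort(rng.random(40))
        basis = P.build_spline_basis(t, n_knots=4, degree=3)
        for j in range(basis.n_basis):
            coef = np.zeros(basis.n_basis)
            coef[j] = 1.0
            ref = BSpline(basis.knots, coef, 3)(t)
            assert np.allclose(basis.phi[:, j], ref, atol=1e-12)

    def test_too_few_distinct_pseudotimes_rejected(self):
        with pytest.raises(DegenerateInputError):
            P.build_spline_basis(np.linspace(0, 1, 5), n_knots=4, degree=3)

    def test_nan_pseudotime_rejected(self):
        t = np.linspace(0, 1, 30)
        t[3] = np.nan
        with pytest.raises(ValidationError):
            P.build_spline_basis(t)


# ---------------------------------------------------------------------------
# HALS fitting
# ---------------------------------------------------------------------------


def _mu_nmf_from_same_init(Y_cells_by_genes, rank, seed, iters=50_000, tol=1e-13):
    """Lee-Seung multiplicative-update oracle, mirroring the HALS init."""
    rng = np.random.default_rng(seed)
    X = 1.0 - rng.random((rank, Y_cells_by_genes.shape[1]))
    A = 1.0 - rng.random((Y_cells_by_genes.shape[0], rank))
    prev = np.inf
    for _ in range(iters):
        X *= (A.T @ Y_cells_by_genes) / np.maximum(A.T @ A @ X, 1e-300)
        A *= (Y_cells_by_genes @ X.T) / np.maximum(A @ (X @ X.T), 1e-300)
        obj = float(np.linalg.norm(Y_cells_by_genes - A @ X) ** 2)
        if prev - obj < tol * max(prev, 1e-300):
            break
        prev = obj
    return obj


class TestFitReplicate:
    def test_exact_rank_one_factorization(self, rng):
        Y = np.outer(rng.random(30), rng.random(20))
        data = make_dataset(Y)
        config = P.FactorizationConfig(rank=1, mode="stdnmf", max_iter=2000, tol=1e-14)
        best = min(
            P.fit_replicate(data, None, config, seed=s).objective_trace[-1]
            for s in range(20)
        )
        assert np.sqrt(best) / np.linalg.norm(Y) <= 1e-6

    def test_final_objective_matches_multiplicative_update_oracle(self):
        rng = np.random.default_rng(123)
        Y = rng.random((6, 5))  # genes x cells
        data = make_dataset(Y)
        config = P.FactorizationConfig(rank=2, mode="stdnmf", max_iter=50_000, tol=1e-14)
        hals = P.fit_replicate(data, None, config, seed=7).objective_trace[-1]
        mu = _mu_nmf_from_same_init(Y.T, rank=2, seed=7)
        assert abs(hals - mu) / mu < 1e-6

    @pytest.mark.parametrize("mode", ["pinmf", "stdnmf"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_trace_non_increasing(self, small_sim, mode, seed):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=3, mode=mode, max_iter=60, tol=1e-12)
        rep = P.fit_replicate(branch_a, basis if mode == "pinmf" else None, config, seed)
        trace = rep.objective_trace
        assert np.all(np.diff(trace) <= 1e-10 * trace[:-1])
        assert np.all(rep.A >= 0) and np.all(rep.X >= 0)

    def test_pinmf_structural_constraint_and_unit_max(self, small_sim):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=3, mode="pinmf", max_iter=80, tol=1e-10)
        rep = P.fit_replicate(branch_a, basis, config, seed=4)
        assert np.allclose(rep.A, basis.phi @ rep.C.T, atol=1e-12)
        assert np.all(rep.C >= 0)
        for j in range(3):
            if rep.A[:, j].any():
                assert rep.A[:, j].max() == pytest.approx(1.0, abs=1e-12)

    def test_unit_max_rescaling_preserves_product(self, small_sim):
        """A X after rescaling still reproduces the final objective."""
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=3, mode="pinmf", max_iter=80, tol=1e-10)
        rep = P.fit_replicate(branch_a, basis, config, seed=4)
        obj = float(np.linalg.norm(branch_a.expr.T - rep.A @ rep.X) ** 2)
        assert obj == pytest.approx(rep.objective_trace[-1], rel=1e-8)

    def test_seeded_determinism_bitwise(self, small_sim):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=3, mode="pinmf", max_iter=30, tol=1e-12)
        a = P.fit_replicate(branch_a, basis, config, seed=9)
        b = P.fit_replicate(branch_a, basis, config, seed=9)
        assert np.array_equal(a.A, b.A) and np.array_equal(a.X, b.X)

    def test_all_zero_matrix_returns_zero_factors_with_warning(self):
        data = make_dataset(np.zeros((10, 12)))
        config = P.FactorizationConfig(rank=2, mode="stdnmf")
        with pytest.warns(UserWarning, match="all-zero"):
            rep = P.fit_replicate(data, None, config, seed=0)
        assert not rep.A.any() and not rep.X.any()

    def test_rank_too_large_rejected(self):
        data = make_dataset(np.ones((4, 5)))
        config = P.FactorizationConfig(rank=6, mode="stdnmf")
        with pytest.raises(ValidationError, match="rank"):
            P.fit_replicate(data, None, config, seed=0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            P.FactorizationConfig(rank=2, n_replicates=0)
        with pytest.raises(ValidationError):
            P.FactorizationConfig(rank=0)
        with pytest.raises(ValidationError):
            P.FactorizationConfig(rank=2, tol=0.0)


class TestRunEnsemble:
    def test_ensemble_determinism_and_seeding(self, small_sim):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(
            rank=2, mode="pinmf", max_iter=25, tol=1e-12, n_replicates=3, base_seed=42
        )
        first = P.run_ensemble(branch_a, basis, config)
        second = P.run_ensemble(branch_a, basis, config)
        assert [r.seed for r in first] == [42, 43, 44]
        for a, b in zip(first, second):
            assert np.array_equal(a.X, b.X) and np.array_equal(a.A, b.A)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _silhouette_oracle(points, labels):
    """Direct pairwise-distance silhouette (mean over samples)."""
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = d[i, same].mean() if same else 0.0
        b = min(
            d[i, [j for j in range(n) if labels[j] == lab]].mean()
            for lab in set(labels) if lab != labels[i]
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))


class TestConsensus:
    def test_identical_replicates_give_perfect_silhouette(self, small_sim):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=3, mode="pinmf", max_iter=100, tol=1e-10)
        rep = P.fit_replicate(branch_a, basis, config, seed=1)
        # three copies whose components are permuted
        reps = []
        for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            clone = P.ReplicateFactorization(
                A=rep.A[:, perm].copy(), X=rep.X[perm].copy(), C=rep.C[perm].copy(),
                objective_trace=rep.objective_trace, converged=True, seed=rep.seed,
            )
            reps.append(clone)
        cons = P.consensus_programs(branch_a, basis, reps, rank=3)
        assert cons.silhouette == pytest.approx(1.0, abs=1e-6)
        # centroids equal the shared components up to ordering
        normed = rep.X / np.linalg.norm(rep.X, axis=1, keepdims=True)
        got = np.sort(cons.consensus_X / np.linalg.norm(cons.consensus_X, axis=1, keepdims=True), axis=0)
        assert np.allclose(np.sort(normed, axis=0), got, atol=1e-8)

    def test_planted_program_recovery(self, small_sim, small_consensus):
        _, truth, branch_a, _ = small_sim
        _, cons = small_consensus
        true_pat = truth.evaluate(branch_a.pseudotime, branch_a.branch)
        pairs = dict(P.match_programs(true_pat.T, cons.consensus_A))
        corrs = [
            np.corrcoef(true_pat[i], cons.consensus_A[:, pairs[i]])[0, 1]
            for i in range(4)
        ]
        assert len(set(pairs.values())) == 4  # distinct consensus programs
        assert min(corrs) >= 0.9

    def test_silhouette_matches_pairwise_oracle_on_separated_clouds(self, small_sim):
        _, _, branch_a, basis = small_sim
        rng = np.random.default_rng(0)
        n_genes = branch_a.n_genes
        # clouds separated in direction: support on disjoint coordinate halves
        half = n_genes // 2
        cloud1 = np.abs(rng.normal(1.0, 0.05, size=(2, n_genes)))
        cloud1[:, half:] = 0.0
        cloud2 = np.abs(rng.normal(1.0, 0.05, size=(2, n_genes)))
        cloud2[:, :half] = 0.0
        reps = []
        for k in range(2):
            X = np.vstack([cloud1[k], cloud2[k]])
            reps.append(
                P.ReplicateFactorization(
                    A=np.abs(rng.random((branch_a.n_cells, 2))), X=X, C=None,
                    objective_trace=np.array([1.0]), converged=True, seed=k,
                )
            )
        cons = P.consensus_programs(branch_a, None, reps, rank=2)
        assert cons.silhouette > 0.5
        comps = np.vstack([r.X / np.linalg.norm(r.X, axis=1, keepdims=True) for r in reps])
        oracle = _silhouette_oracle(comps, list(cons.replicate_cluster_labels))
        assert cons.silhouette == pytest.approx(oracle, abs=1e-9)

    def test_mismatched_ranks_rejected(self, small_sim):
        _, _, branch_a, basis = small_sim
        c2 = P.FactorizationConfig(rank=2, mode="pinmf", max_iter=10)
        c3 = P.FactorizationConfig(rank=3, mode="pinmf", max_iter=10)
        reps = [
            P.fit_replicate(branch_a, basis, c2, 0),
            P.fit_replicate(branch_a, basis, c3, 1),
        ]
        with pytest.raises(ValidationError, match="rank"):
            P.consensus_programs(branch_a, basis, reps, rank=2)

    def test_needs_at_least_two_replicates(self, small_sim):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=2, mode="pinmf", max_iter=10)
        rep = P.fit_replicate(branch_a, basis, config, 0)
        with pytest.raises(ValidationError):
            P.consensus_programs(branch_a, basis, [rep], rank=2)


class TestActivationScale:
    def test_minmax_example(self, small_consensus):
        _, cons = small_consensus
        import copy

        c = copy.deepcopy(cons)
        c.consensus_A = np.array([[2.0], [4.0], [6.0]])
        assert np.allclose(P.activation_scale(c), [[0.0], [0.5], [1.0]])

    def test_constant_column_warns_and_zeroes(self, small_consensus):
        import copy

        _, cons = small_consensus
        c = copy.deepcopy(cons)
        c.consensus_A = np.full((5, 1), 3.0)
        with pytest.warns(UserWarning, match="constant"):
            out = P.activation_scale(c)
        assert not out.any()

    def test_range_invariant(self, small_consensus):
        _, cons = small_consensus
        act = cons.activations
        assert act.min() >= 0.0 and act.max() <= 1.0


class TestProgramDistance:
    def test_closed_forms_and_bruteforce(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        d = P.program_distance_matrix(X)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        # brute force on random programs
        rng = np.random.default_rng(1)
        X = rng.random((4, 30))
        d = P.program_distance_matrix(X)
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        for i in range(4):
            for j in range(4):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((Xn[i] - Xn[j]) ** 2).sum()), abs=1e-12
                )


class TestRankSweep:
    def test_rank_one_rejected(self, small_sim):
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(rank=2, mode="pinmf", max_iter=10, n_replicates=2)
        with pytest.raises(ValidationError):
            P.rank_sweep(branch_a, basis, [1], config)

    def test_best_replicate_error_decreases_with_rank(self, small_sim):
        """Higher rank can only improve the best achievable reconstruction."""
        _, _, branch_a, basis = small_sim
        config = P.FactorizationConfig(
            rank=2, mode="pinmf", max_iter=150, tol=1e-8, n_replicates=8, base_seed=0
        )
        table = P.rank_sweep(branch_a, basis, [2, 3, 4, 5], config)
        errors = table["best_replicate_error"].to_numpy()
        violations = int((np.diff(errors) > 1e-9 * errors[:-1]).sum())
        assert violations <= 1  # stochastic fits allow at most one inversion


class TestOutlierFilter:
    def test_outliers_removed_before_clustering(self, small_sim, small_consensus):
        _, _, branch_a, basis = small_sim
        reps, _ = small_consensus
        # corrupt one replicate with a wildly different component
        import copy

        bad = copy.deepcopy(reps[0])
        rng = np.random.default_rng(0)
        bad.X[0] = rng.random(bad.X.shape[1]) * 50
        filtered = P.consensus_programs(
            branch_a, basis, [bad] + list(reps[1:]), rank=4, outlier_filter_frac=0.05
        )
        plain = P.consensus_programs(branch_a, basis, list(reps), rank=4)
        # filtering restores the clean-consensus stability
        assert filtered.silhouette >= plain.silhouette - 0.05
        with pytest.raises(ValidationError):
            P.consensus_programs(branch_a, basis, list(reps), rank=4, outlier_filter_frac=1.5)


# ---------------------------------------------------------------------------
# Gene modules
# ---------------------------------------------------------------------------


class TestGeneModules:
    def test_self_regression_identifies_own_program(self, small_sim, small_consensus):
        _, truth, branch_a, _ = small_sim
        _, cons = small_consensus
        expr = branch_a.expr.copy()
        expr[0] = cons.activations[:, 2] + 1e-9  # gene 0 IS program 2's activation
        data = P.TrajectoryDataset(
            expr, branch_a.pseudotime, branch_a.branch, branch_a.gene_ids, branch_a.cell_ids
        )
        assignment = P.assign_gene_modules(data, cons, alpha=0.05)
        coefs = assignment.coefficients[0]
        assert coefs[2] > 0
        assert coefs[2] > 10 * np.abs(np.delete(coefs, 2)).max()
        assert assignment.pvalues[0].argmin() == 2

    def test_type_one_error_control_on_noise_genes(self, small_consensus, small_sim):
        _, _, branch_a, _ = small_sim
        _, cons = small_consensus
        raw_rates, post_bh = [], []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            noise = rng.lognormal(0.0, 1.0, size=(400, branch_a.n_cells))
            data = P.TrajectoryDataset(
                noise, branch_a.pseudotime, branch_a.branch,
                np.array([f"n{i}" for i in range(400)]), branch_a.cell_ids,
            )
            assignment = P.assign_gene_modules(data, cons, alpha=0.05)
            raw_rates.append((assignment.pvalues < 0.05).mean())
            post_bh.append(assignment.membership.mean())
        assert np.mean(raw_rates) < 0.08  # ~5% nominal
        assert np.mean(post_bh) < 0.005  # essentially none survive BH

    def test_zero_variance_genes_dropped(self, small_sim, small_consensus):
        _, _, branch_a, _ = small_sim
        _, cons = small_consensus
        expr = branch_a.expr.copy()
        expr[5] = 1.0
        data = P.TrajectoryDataset(
            expr, branch_a.pseudotime, branch_a.branch, branch_a.gene_ids, branch_a.cell_ids
        )
        assignment = P.assign_gene_modules(data, cons, alpha=0.05)
        assert branch_a.gene_ids[5] in assignment.dropped_genes
        assert branch_a.gene_ids[5] not in assignment.gene_ids

    def test_qvalues_bound_pvalues(self, small_sim, small_consensus):
        _, _, branch_a, _ = small_sim
        _, cons = small_consensus
        assignment = P.assign_gene_modules(branch_a, cons, alpha=0.05)
        assert np.all(assignment.qvalues >= assignment.pvalues - 1e-15)
        assert np.all((assignment.qvalues >= 0) & (assignment.qvalues <= 1))
        assert np.all(assignment.coefficients[assignment.membership] > 0)


class TestModuleOverlap:
    @staticmethod
    def _assignment(member_sets, r, genes):
        membership = np.zeros((len(genes), r), dtype=bool)
        gidx = {g: i for i, g in enumerate(genes)}
        for j, s in enumerate(member_sets):
            for g in s:
                membership[gidx[g], j] = True
        return P.GeneModuleAssignment(
            gene_ids=np.asarray(genes),
            coefficients=np.ones((len(genes), r)),
            pvalues=np.zeros((len(genes), r)),
            qvalues=np.zeros((len(genes), r)),
            membership=membership,
            alpha=0.05,
            dropped_genes=np.array([]),
        )

    def test_overlap_conventions(self):
        genes = [f"g{i}" for i in range(6)]
        a = self._assignment([{"g0", "g1", "g2", "g3"}, {"g4"}], 2, genes)
        b = self._assignment([{"g0", "g1"}, {"g5"}], 2, genes)
        table = P.module_overlap(a, b, [(0, 0), (1, 1)])
        assert table.loc[0, "overlap_pct"] == pytest.approx(50.0)  # 2 of 4 recovered
        assert table.loc[1, "overlap_pct"] == pytest.approx(0.0)  # disjoint
        same = P.module_overlap(a, a, [(0, 0), (1, 1)])
        assert (same["overlap_pct"] == 100.0).all()

    def test_empty_reference_module_warns(self):
        genes = ["g0", "g1"]
        a = self._assignment([set(), {"g0"}], 2, genes)
        b = self._assignment([{"g0"}, {"g0"}], 2, genes)
        with pytest.warns(UserWarning, match="empty"):
            table = P.module_overlap(a, b, [(0, 0)])
        assert table.loc[0, "overlap_pct"] == 0.0
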