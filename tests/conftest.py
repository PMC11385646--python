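import numpy as np
import pytest

import pinmf as P


@pytest.fixture(scope="session")
def small_sim():
    """A small bifurcating dataset with planted programs (branch A subset)."""
    data, truth = P.simulate_bifurcating_expression(
        n_cells=300, n_genes=500, n_programs=4, seed=11
    )
    branch_a = data.subset_branch("A")
    basis = P.build_spline_basis(branch_a.pseudotime)
    return data, truth, branch_a, basis


@pytest.fixture(scope="session")
def small_consensus(small_sim):
    _, truth, branch_a, basis = small_sim
    config = P.FactorizationConfig(
        rank=4, mode="pinmf", max_iter=300, tol=1e-8, n_replicates=20, base_seed=5
    )
    replicates = P.run_ensemble(branch_a, basis, config)
    consensus = P.consensus_programs(branch_a, basis, replicates, rank=4)
    return replicates, consensus


@pytest.fixture(scope="session")
def toy_landscape():
    return P.simulate_regulatory_landscape(
        chrom_sizes={"chr1": 60_000, "chr2": 40_000},
        n_peaks=25,
        n_variants=60,
        seed=3,
        n_motifs=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_dataset(Y, seed=0):
    """Wrap a genes x cells matrix in a TrajectoryDataset with random times."""
    Y = np.asarray(Y, dtype=float)
    n_genes, n_cells = Y.shape
    t = np.random.default_rng(seed).random(n_cells)
    return P.TrajectoryDataset(
        expr=Y,
        pseudotime=t,
        branch=np.array(["A"] * n_cells),
        gene_ids=np.array([f"g{i}" for i in range(n_genes)]),
        cell_ids=np.array([f"c{i}" for i in range(n_cells)]),
    )
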