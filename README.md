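# pinmf

Pseudotime-informed consensus non-negative matrix factorization of gene
expression programs, plus a companion pipeline for calling archaic-clean
"regulatory islands" and scoring allele-specific transcription-factor
binding at the variants inside them.

The package is aimed at researchers studying cell differentiation with
single-cell transcriptomics — for example the progression of ventricular
radial glia toward outer radial glia or intermediate progenitors in the
developing cortex — who want temporally coherent gene expression
programs along a pseudotime trajectory, and at groups annotating
modern-human-derived regulatory variation against archaic hominin
genomes.

## The model

Given a non-negative expression matrix Y (genes × cells) and a per-cell
pseudotime t, standard NMF seeks non-negative factors minimizing
‖Yᵀ − A X‖²_F, where the columns of A (cells × r) are program activation
patterns and the rows of X (r × genes) are gene loadings. piNMF
additionally constrains every temporal pattern to be a smooth
non-negative function of pseudotime,

    A = Φ Cᵀ,   C ≥ 0,

with Φ the design matrix of a clamped cubic B-spline basis evaluated at
the cells' pseudotimes (degree 3, 4 interior knots at pseudotime
quantiles → 8 basis functions). Because B-splines are non-negative and
sum to one everywhere, C ≥ 0 suffices for non-negative patterns. The
problem is solved by Hierarchical Alternating Least Squares (HALS):
exact non-negative block updates of C (or A) and X, giving a provably
non-increasing objective. Because NMF solutions are not unique, the fit
is repeated from many random restarts (750 by default) and the pooled,
L2-normalized gene-coefficient vectors are clustered with K-means
(k = r); cluster centroids are the consensus programs, stability is
measured by the silhouette score and accuracy by the Frobenius norm of
the reconstruction. Genes are assigned to programs by ordinary least
squares of z-scored expression on the program activations with
Benjamini–Hochberg correction across all gene × program tests; a gene
may belong to several modules.

The genomic pipeline defines a **regulatory island** as a centered
window of at least 3 kb around a derived single-nucleotide variant that
(i) has derived-allele frequency ≥ 0.9, (ii) shows the ancestral allele
in archaic genomes, (iii) lies inside an open-chromatin atlas peak (a
reference peak set filtered at ≥ 50% overlap with supporting peak
sets), and (iv) contains no archaic lineage-specific derived position;
overlapping windows merge. Islands are linked to genes through
basal-plus-extension regulatory domains, enrichment against target
region sets (selection scans, introgression deserts) is tested with a
length- and chromosome-matched permutation null, and binding effects of
island variants are scored per motif as min-max-scaled probability sums
with exact grid-convolution match p-values, a top-quartile strength
filter, and per-TF direction classes.

## Worked example

```python
import numpy as np
import pinmf as P

# simulate a bifurcating trajectory with 4 planted programs
data, truth = P.simulate_bifurcating_expression(n_cells=1000, n_genes=2000, seed=0)
branch = data.subset_branch("A")                       # root + one branch
basis = P.build_spline_basis(branch.pseudotime, n_knots=4, degree=3)
config = P.FactorizationConfig(rank=4, mode="pinmf", max_iter=300, tol=1e-8,
                               n_replicates=100, base_seed=0)
replicates = P.run_ensemble(branch, basis, config)
cons = P.consensus_programs(branch, basis, replicates, rank=4)
print(f"silhouette: {cons.silhouette:.3f}")
print(f"frobenius error: {cons.frobenius_error:.1f}")
assign = P.assign_gene_modules(branch, cons, alpha=0.05)
print("module sizes:", [len(assign.module_genes(j)) for j in range(4)])
```

prints

```
silhouette: 0.987
frobenius error: 1537.4
module sizes: [506, 536, 525, 475]
```

A silhouette of 0.99 says the hundred random restarts keep finding the
same four components; the Frobenius error is the remaining reconstruction
residual (the simulated data carry strong multiplicative noise and
dropout); the four modules of ~500 genes each recover the planted gene
sets. Matching the consensus patterns against the simulator's ground
truth gives Pearson correlations of 0.997–0.999 per program.

The same analyses are available from the shell:

```bash
pinmf simulate-traj --seed 1 --outdir sim
pinmf fit --expr sim/expr.mtx --meta sim/meta.tsv --branch A --rank 4 --outdir fit
pinmf assign --expr sim/expr.mtx --meta sim/meta.tsv --branch A \
      --activations fit/activations.tsv --out fit/modules.tsv
pinmf simulate-landscape --seed 1 --outdir land
pinmf islands --variants land/variants.tsv --archaic land/archaic_derived.bed \
      --atlas land/peaks.bed --chrom-sizes land/chrom.sizes --outdir isl
pinmf enrich --query isl/islands.bed --target land/target_selection_scan.bed \
      --chrom-sizes land/chrom.sizes --out isl/enrich.json
```

All outputs are byte-identical on rerun with the same seed.

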