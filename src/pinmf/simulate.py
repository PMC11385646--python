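"""Ground-truthed synthetic inputs for both analysis engines.

Two generators:

* :func:`simulate_bifurcating_expression` builds a bifurcating
  differentiation trajectory: cells get a pseudotime in [0, 1] and one of
  two branch labels; a small set of smooth non-negative temporal programs
  (sigmoid onsets plus at least one transient bump) activates
  sequentially along pseudotime and diverges between branches after the
  bifurcation point; genes load sparsely and non-negatively on the
  programs; multiplicative lognormal noise and Bernoulli dropout corrupt
  the product. The planted patterns, loadings and module memberships are
  returned as ground truth.

* :func:`simulate_regulatory_landscape` builds a toy genome: chromosomes
  with open-chromatin peaks, modern derived variants with allele
  frequencies and archaic-state flags, scattered archaic
  lineage-specific derived positions, target region sets, random motifs
  and a random reference sequence. The exact set of regulatory islands
  implied by the island definition is computed internally by a
  brute-force scan that is independent of the production island caller,
  so callers can be validated against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .factorization import TrajectoryDataset, ValidationError
from .islands import IntervalSet, VariantRecord
from .tfbs import BASES, PWMRecord

DEFAULT_N_CELLS = 1000
DEFAULT_N_GENES = 2000
DEFAULT_BIFURCATION = 0.5


@dataclass
class GroundTruthPrograms:
    """Planted truth for a simulated bifurcating trajectory."""

    centers: np.ndarray  # per-program onset/peak positions in [0, 1]
    loadings: np.ndarray  # genes x r, sparse non-negative
    membership: np.ndarray  # genes x r boolean
    transient_programs: list  # indices of bump-shaped (transient) programs
    bifurcation: float
    dropout_rate: float
    noise_sd: float
    seed: int

    def evaluate(self, pseudotime: np.ndarray, branch: np.ndarray) -> np.ndarray:
        """True temporal patterns (r x cells) at the given cells."""
        return _program_patterns(
            np.asarray(pseudotime, float), np.asarray(branch), self.centers, self.bifurcation
        )


def _program_patterns(
    t: np.ndarray, branch: np.ndarray, centers: np.ndarray, bifurcation: float
) -> np.ndarray:
    """Smooth non-negative program curves, branch-specific after bifurcation.

    Program 0 is a decreasing sigmoid (root identity), the last program
    an increasing sigmoid (terminal identity), intermediate programs are
    Gaussian bumps (transient activation). On branch "B", programs
    peaking after the bifurcation are shifted and damped so the two
    branches share early programs but diverge late.
    """
    # widths chosen so the curves are representable by the default
    # 4-knot cubic spline basis (noiseless reconstruction within a few %)
    r = len(centers)
    width = 0.16
    steep = 0.09
    out = np.zeros((r, len(t)))
    is_b = np.asarray(branch) == "B"
    for j, c in enumerate(centers):
        c_eff = np.full(len(t), float(c))
        amp = np.ones(len(t))
        if c > bifurcation:
            c_eff[is_b] = c + 0.06
            amp[is_b] = 0.75
        if j == 0:
            val = 1.0 / (1.0 + np.exp((t - c_eff) / steep))
        elif j == r - 1:
            val = 1.0 / (1.0 + np.exp(-(t - c_eff) / steep))
        else:
            val = np.exp(-((t - c_eff) ** 2) / (2.0 * width**2))
        out[j] = amp * val
    return out


def simulate_bifurcating_expression(
    n_cells: int = DEFAULT_N_CELLS,
    n_genes: int = DEFAULT_N_GENES,
    n_programs: int = 4,
    dropout_rate: float = 0.2,
    noise_sd: float = 0.8,
    seed: int = 0,
    bifurcation: float = DEFAULT_BIFURCATION,
    shared_gene_frac: float = 0.1,
) -> tuple[TrajectoryDataset, GroundTruthPrograms]:
    """Simulate a bifurcating trajectory with planted temporal programs.

    Expression is loadings x patterns with multiplicative lognormal
    noise (sd ``noise_sd`` on the log scale) and Bernoulli dropout to
    zero. A fraction ``shared_gene_frac`` of genes belongs to two
    modules. Defaults are 1000 cells and 2000 genes.
    """
    if n_programs < 2:
        raise ValidationError("need at least 2 programs")
    if n_cells <= 0 or n_genes <= 0:
        raise ValidationError("n_cells and n_genes must be positive")
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValidationError("dropout_rate must be in [0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    t = rng.random(n_cells)
    branch = np.where(rng.random(n_cells) < 0.5, "A", "B")
    centers = np.linspace(0.12, 0.88, n_programs)
    patterns = _program_patterns(t, branch, centers, bifurcation)

    primary = rng.integers(0, n_programs, size=n_genes)
    loadings = np.zeros((n_genes, n_programs))
    loadings[np.arange(n_genes), primary] = rng.gamma(2.0, 1.0, size=n_genes) + 0.2
    shared = rng.random(n_genes) < shared_gene_frac
    second = (primary + rng.integers(1, n_programs, size=n_genes)) % n_programs
    loadings[shared, second[shared]] = rng.gamma(2.0, 0.5, size=int(shared.sum())) + 0.2

    expr = loadings @ patterns
    if noise_sd > 0:
        expr = expr * rng.lognormal(0.0, noise_sd, size=expr.shape)
    if dropout_rate > 0:
        expr[rng.random(expr.shape) < dropout_rate] = 0.0

    data = TrajectoryDataset(
        expr=expr,
        pseudotime=t,
        branch=branch,
        gene_ids=np.array([f"gene{i:05d}" for i in range(n_genes)]),
        cell_ids=np.array([f"cell{i:05d}" for i in range(n_cells)]),
    )
    truth = GroundTruthPrograms(
        centers=centers,
        loadings=loadings,
        membership=loadings > 0,
        transient_programs=list(range(1, n_programs - 1)),
        bifurcation=bifurcation,
        dropout_rate=dropout_rate,
        noise_sd=noise_sd,
        seed=seed,
    )
    return data, truth


# ---------------------------------------------------------------------------
# Toy regulatory landscape
# ---------------------------------------------------------------------------


@dataclass
class ToyRegulatoryLandscape:
    chrom_sizes: dict
    peaks: IntervalSet
    variants: list
    archaic_derived: dict  # chrom -> sorted int positions
    targets: dict  # name -> IntervalSet
    true_islands: list  # (chrom, start, end, tuple of member variant ids)
    pwms: list = field(default_factory=list)
    reference_sequence: dict = field(default_factory=dict)
    af_threshold: float = 0.9
    window: int = 3000
    seed: int = 0


def _brute_force_islands(
    variants, archaic_derived, peaks: IntervalSet, chrom_sizes, af_threshold, window
):
    """Reference island scan by direct looping over the definition.

    Deliberately naive (O(variants x peaks) membership checks, per-base
    window scans against archaic positions) and shares no code with the
    production caller, so it can serve as its oracle.
    """
    half = window // 2
    qualifying = []
    peak_list = list(peaks.df.itertuples(index=False))
    for v in variants:
        if v.chrom not in chrom_sizes:
            continue
        if v.frequency < af_threshold or v.archaic_state != "ancestral":
            continue
        in_peak = False
        for p in peak_list:
            if p.chrom == v.chrom and p.start <= v.pos < p.end:
                in_peak = True
                break
        if not in_peak:
            continue
        lo, hi = v.pos - half, v.pos + half
        if lo < 0 or hi > chrom_sizes[v.chrom]:
            continue
        clean = True
        for pos in archaic_derived.get(v.chrom, ()):
            if lo <= pos < hi:
                clean = False
                break
        if clean:
            qualifying.append((v.chrom, lo, hi, v))
    islands = []
    for chrom in sorted({q[0] for q in qualifying}):
        windows = sorted([q for q in qualifying if q[0] == chrom], key=lambda q: q[1])
        cur = [windows[0][1], windows[0][2], [windows[0][3]]]
        for _, lo, hi, v in windows[1:]:
            if lo <= cur[1]:
                cur[1] = max(cur[1], hi)
                cur[2].append(v)
            else:
                islands.append((chrom, cur[0], cur[1], tuple(x.variant_id for x in cur[2])))
                cur = [lo, hi, [v]]
        islands.append((chrom, cur[0], cur[1], tuple(x.variant_id for x in cur[2])))
    return islands


def _random_pwms(rng, n_motifs: int) -> list[PWMRecord]:
    pwms = []
    for m in range(n_motifs):
        L = int(rng.integers(6, 11))
        counts = rng.dirichlet(np.full(4, 0.3), size=L) * 100.0
        mat = (counts + 0.2) / (counts.sum(axis=1, keepdims=True) + 0.8)
        pwms.append(PWMRecord(f"MOTIF{m:03d}", f"TF{m:03d}", mat))
    return pwms


def simulate_regulatory_landscape(
    chrom_sizes: dict | None = None,
    n_peaks: int = 60,
    n_variants: int = 200,
    frac_high_freq: float = 0.5,
    frac_archaic_ancestral: float = 0.7,
    archaic_derived_density: float = 2e-4,
    seed: int = 0,
    af_threshold: float = 0.9,
    window: int = 3000,
    n_motifs: int = 5,
    with_sequence: bool = True,
) -> ToyRegulatoryLandscape:
    """Toy genome with peaks, variants and planted regulatory islands.

    Roughly 70% of variants are placed inside peaks so that islands are
    plentiful; allele frequencies are drawn above or below the threshold
    according to ``frac_high_freq``; archaic-derived positions are
    scattered at ``archaic_derived_density`` per bp. The truth set of
    islands is computed by the internal brute-force scan.
    """
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 200_000, "chr2": 150_000}
    if n_peaks <= 0 or n_variants <= 0:
        raise ValidationError("n_peaks and n_variants must be positive")
    for frac in (frac_high_freq, frac_archaic_ancestral):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if min(chrom_sizes.values()) < window:
        warnings.warn("chromosomes shorter than the island window; truth set may be empty")

    # peaks
    probs = sizes / sizes.sum()
    peak_rows = []
    for _ in range(n_peaks):
        c = chroms[rng.choice(len(chroms), p=probs)]
        length = min(int(rng.integers(200, 801)), chrom_sizes[c])
        start = int(rng.integers(0, max(chrom_sizes[c] - length, 1)))
        peak_rows.append((c, start, start + length))
    peaks = IntervalSet.from_records(peak_rows, chrom_sizes)

    # variants: most inside peaks so the filter chain has positives
    variants = []
    seen_pos = set()
    base_idx = np.arange(4)
    while len(variants) < n_variants:
        if rng.random() < 0.7 and len(peaks):
            row = peaks.df.iloc[int(rng.integers(0, len(peaks)))]
            c = row["chrom"]
            pos = int(rng.integers(row["start"], row["end"]))
        else:
            c = chroms[rng.choice(len(chroms), p=probs)]
            pos = int(rng.integers(0, chrom_sizes[c]))
        if (c, pos) in seen_pos:
            continue
        seen_pos.add((c, pos))
        anc, der = rng.choice(base_idx, size=2, replace=False)
        if rng.random() < frac_high_freq:
            freq = float(af_threshold + (1.0 - af_threshold) * rng.random())
        else:
            freq = float(af_threshold * rng.random() * 0.999)
        u = rng.random()
        if u < frac_archaic_ancestral:
            state = "ancestral"
        elif u < frac_archaic_ancestral + (1 - frac_archaic_ancestral) * 0.7:
            state = "derived"
        else:
            state = "missing"
        variants.append(
            VariantRecord(c, pos, BASES[anc], BASES[der], freq, state)
        )
    variants.sort(key=lambda v: (v.chrom, v.pos))

    # archaic lineage-specific derived positions
    archaic = {}
    for c in chroms:
        k = rng.poisson(archaic_derived_density * chrom_sizes[c])
        archaic[c] = np.sort(rng.choice(chrom_sizes[c], size=min(k, chrom_sizes[c]), replace=False)).astype(int)

    # a target region set (stand-in for selection scans / introgression deserts)
    target_rows = []
    for _ in range(max(3, n_peaks // 10)):
        c = chroms[rng.choice(len(chroms), p=probs)]
        length = min(int(rng.integers(2000, 10001)), chrom_sizes[c])
        start = int(rng.integers(0, max(chrom_sizes[c] - length, 1)))
        target_rows.append((c, start, start + length))
    targets = {"selection_scan": IntervalSet.from_records(target_rows, chrom_sizes)}

    true_islands = _brute_force_islands(
        variants, archaic, peaks, chrom_sizes, af_threshold, window
    )
    if not true_islands:
        warnings.warn("no regulatory island is attainable under these settings")

    sequence = {}
    if with_sequence:
        for c in chroms:
            seq = rng.integers(0, 4, size=chrom_sizes[c])
            sequence[c] = "".join(BASES[i] for i in seq)
        # make the reference agree with each variant's ancestral allele
        for v in variants:
            s = sequence[v.chrom]
            sequence[v.chrom] = s[: v.pos] + v.ancestral + s[v.pos + 1 :]

    return ToyRegulatoryLandscape(
        chrom_sizes=dict(chrom_sizes),
        peaks=peaks,
        variants=variants,
        archaic_derived=archaic,
        targets=targets,
        true_islands=true_islands,
        pwms=_random_pwms(rng, n_motifs),
        reference_sequence=sequence,
        af_threshold=af_threshold,
        window=window,
        seed=seed,
    )
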