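"""Regulatory-island calling over an open-chromatin atlas.

A regulatory island is a genomic window of at least 3 kb centered on a
high-frequency derived variant (modern lineage) for which the archaic
genomes carry the ancestral allele, anchored inside an open-chromatin
peak, and clean of archaic lineage-specific derived changes. Overlapping
qualifying windows are merged, so islands can exceed the window size.

Coordinates are 0-based half-open throughout (BED semantics); variant
input files use 1-based positions and are converted on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factorization import GeneModuleAssignment, ValidationError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_ARCHAIC_STATES = ("ancestral", "derived", "missing")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide derived variant; ``pos`` is stored 0-based."""

    chrom: str
    pos: int
    ancestral: str
    derived: str
    frequency: float
    archaic_state: str

    def __post_init__(self) -> None:
        if self.ancestral not in _BASES or self.derived not in _BASES:
            raise ValidationError(
                f"alleles must be single nucleotides in ACGT: "
                f"{self.ancestral!r}>{self.derived!r}"
            )
        if self.ancestral == self.derived:
            raise ValidationError("ancestral and derived alleles must differ")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(f"derived-allele frequency {self.frequency} not in [0, 1]")
        if self.archaic_state not in _ARCHAIC_STATES:
            raise ValidationError(f"unknown archaic_state {self.archaic_state!r}")
        if self.pos < 0:
            raise ValidationError("position must be non-negative")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ancestral}>{self.derived}"


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Union of sorted-by-start intervals on one chromosome."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.asarray(m_starts), np.asarray(m_ends)


class IntervalSet:
    """Sorted genomic intervals, 0-based half-open, with optional names.

    Thin container over a DataFrame with columns chrom/start/end(/name);
    provides merging, overlap queries and BED round-trip.
    """

    def __init__(self, df: pd.DataFrame, chrom_sizes: dict | None = None):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValidationError(f"interval table needs columns {sorted(required)}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(f"empty/inverted interval {bad.chrom}:{bad.start}-{bad.end}")
        if (df["start"] < 0).any():
            raise ValidationError("negative interval start")
        if chrom_sizes is not None:
            for chrom, sub in df.groupby("chrom"):
                if chrom not in chrom_sizes:
                    raise ValidationError(f"interval on unknown chromosome {chrom!r}")
                if (sub["end"] > chrom_sizes[chrom]).any():
                    raise ValidationError(f"interval beyond end of {chrom}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records, chrom_sizes: dict | None = None) -> "IntervalSet":
        rows = []
        for rec in records:
            if len(rec) == 3:
                rows.append({"chrom": rec[0], "start": rec[1], "end": rec[2]})
            else:
                rows.append({"chrom": rec[0], "start": rec[1], "end": rec[2], "name": rec[3]})
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"][: max(map(len, records)) if records else 3])
        if not rows:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        return cls(df, chrom_sizes)

    @classmethod
    def read_bed(cls, path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(f"{path}: line {ln}: fewer than 3 BED fields")
                try:
                    row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
                except ValueError as exc:
                    raise ValidationError(f"{path}: line {ln}: {exc}") from exc
                if len(parts) > 3:
                    row["name"] = parts[3]
                rows.append(row)
        cols = ["chrom", "start", "end"] + (["name"] if rows and "name" in rows[0] else [])
        return cls(pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols))

    def to_bed(self, path) -> None:
        cols = ["chrom", "start", "end"] + (["name"] if "name" in self.df.columns else [])
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def merged_by_chrom(self) -> dict:
        """chrom -> (starts, ends) of the merged union."""
        out = {}
        for chrom, sub in self.df.groupby("chrom"):
            out[chrom] = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def overlap_bp(self, chrom: str, start: int, end: int, merged: dict | None = None) -> int:
        """Base pairs of [start, end) covered by this set's union."""
        merged = merged if merged is not None else self.merged_by_chrom()
        if chrom not in merged:
            return 0
        s, e = merged[chrom]
        k = np.searchsorted(s, end, side="left")
        if k == 0:
            return 0
        lo = np.searchsorted(e, start, side="right")
        chunk = np.minimum(e[lo:k], end) - np.maximum(s[lo:k], start)
        return int(np.clip(chunk, 0, None).sum())


def _point_in_union(pos: int, merged_chrom) -> bool:
    s, e = merged_chrom
    k = np.searchsorted(s, pos, side="right")
    return k > 0 and e[k - 1] > pos


def _window_overlaps_union(start: int, end: int, merged_chrom) -> bool:
    s, e = merged_chrom
    k = np.searchsorted(s, end, side="left")
    return k > 0 and e[k - 1] > start


@dataclass
class PeakAtlas:
    """Open-chromatin atlas: reference peaks supported by replicate sets.

    ``intervals.df`` carries a ``support`` column naming the support sets
    that covered each autosomal peak at the required fraction, and a
    ``from_sex_source`` flag for X/Y peaks imported verbatim.
    """

    intervals: IntervalSet
    min_frac: float

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class RegulatoryIsland:
    chrom: str
    start: int
    end: int
    variants: list
    peaks: list = field(default_factory=list)
    genes: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_tuple(self):
        return (self.chrom, self.start, self.end)


@dataclass
class PermutationResult:
    observed: int
    null_mean: float
    null_sd: float
    n_perm: int
    pvalue: float
    zscore: float
    alternative: str
    seed: int


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------


def build_peak_atlas(
    reference: IntervalSet,
    supports: list,
    min_frac: float = 0.5,
    sex_chrom_sources: list | None = None,
    support_names: list | None = None,
) -> PeakAtlas:
    """Retain reference peaks covered >= ``min_frac`` by any support set.

    Coverage is computed against the union of each support set
    separately; a peak stays if at least one set reaches the fraction.
    X/Y peaks from ``sex_chrom_sources`` are appended verbatim and
    flagged, mirroring atlases whose reference lacks sex chromosomes.
    """
    if len(reference) == 0:
        raise ValidationError("empty reference peak set")
    if not 0.0 < min_frac <= 1.0:
        raise ValidationError("min_frac must be in (0, 1]")
    names = support_names or [f"support_{i}" for i in range(len(supports))]
    merged = [s.merged_by_chrom() for s in supports]
    rows = []
    for rec in reference:
        length = rec.end - rec.start
        passed = [
            names[i]
            for i, m in enumerate(merged)
            if supports[i].overlap_bp(rec.chrom, rec.start, rec.end, m) >= min_frac * length
        ]
        if passed:
            rows.append(
                {
                    "chrom": rec.chrom, "start": rec.start, "end": rec.end,
                    "support": ",".join(passed), "from_sex_source": False,
                }
            )
    for k, src in enumerate(sex_chrom_sources or []):
        for rec in src:
            rows.append(
                {
                    "chrom": rec.chrom, "start": rec.start, "end": rec.end,
                    "support": f"sex_source_{k}", "from_sex_source": True,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "support", "from_sex_source"])
    return PeakAtlas(intervals=IntervalSet(df), min_frac=min_frac)


# ---------------------------------------------------------------------------
# Island calling
# ---------------------------------------------------------------------------


def _archaic_union(archaic_derived) -> dict:
    """Normalize archaic-derived input to chrom -> merged (starts, ends)."""
    if isinstance(archaic_derived, IntervalSet):
        return archaic_derived.merged_by_chrom()
    if isinstance(archaic_derived, dict):
        out = {}
        for chrom, positions in archaic_derived.items():
            p = np.sort(np.asarray(positions, dtype=int))
            out[chrom] = _merge_intervals(p, p + 1)
        return out
    raise ValidationError("archaic_derived must be an IntervalSet or a chrom->positions dict")


def call_regulatory_islands(
    variants: list,
    archaic_derived,
    atlas: PeakAtlas,
    chrom_sizes: dict,
    af_threshold: float = 0.9,
    window: int = 3000,
) -> list:
    """Call regulatory islands from a derived-variant catalog.

    A variant qualifies when its derived-allele frequency is >=
    ``af_threshold``, the archaic genomes carry the ancestral allele, it
    lies inside an atlas peak, and its centered window
    [pos - window/2, pos + window/2) fits inside the chromosome and
    contains no archaic lineage-specific derived position. Overlapping
    windows merge into single islands with pooled member variants.
    """
    if window % 2 != 0 or window <= 0:
        raise ValidationError("window must be a positive even integer")
    if not 0.0 <= af_threshold <= 1.0:
        raise ValidationError("af_threshold must be in [0, 1]")
    half = window // 2
    peak_union = atlas.intervals.merged_by_chrom()
    arch = _archaic_union(archaic_derived)
    empty = (np.array([], dtype=int), np.array([], dtype=int))

    windows: dict[str, list] = {}
    for v in variants:
        if v.chrom not in chrom_sizes:
            logger.info("variant %s on unknown chromosome; skipped", v.variant_id)
            continue
        if v.archaic_state == "missing":
            logger.debug("variant %s has missing archaic state; non-qualifying", v.variant_id)
            continue
        if v.archaic_state != "ancestral" or v.frequency < af_threshold:
            continue
        if v.chrom not in peak_union or not _point_in_union(v.pos, peak_union[v.chrom]):
            continue
        start, end = v.pos - half, v.pos + half
        if start < 0 or end > chrom_sizes[v.chrom]:
            continue
        if _window_overlaps_union(start, end, arch.get(v.chrom, empty)):
            continue
        windows.setdefault(v.chrom, []).append((start, end, v))

    islands = []
    for chrom in sorted(windows):
        items = sorted(windows[chrom], key=lambda w: w[0])
        cur_start, cur_end, members = items[0][0], items[0][1], [items[0][2]]
        for s, e, v in items[1:]:
            if s <= cur_end:
                cur_end = max(cur_end, e)
                members.append(v)
            else:
                islands.append(RegulatoryIsland(chrom, cur_start, cur_end, members))
                cur_start, cur_end, members = s, e, [v]
        islands.append(RegulatoryIsland(chrom, cur_start, cur_end, members))

    # annotate overlapping atlas peaks
    peaks_by_chrom = {c: sub for c, sub in atlas.intervals.df.groupby("chrom")}
    for isl in islands:
        sub = peaks_by_chrom.get(isl.chrom)
        if sub is not None:
            hit = sub[(sub["start"] < isl.end) & (sub["end"] > isl.start)]
            isl.peaks = list(hit[["start", "end"]].itertuples(index=False, name=None))
    return islands


# ---------------------------------------------------------------------------
# Gene linkage (basal-plus-extension regulatory domains)
# ---------------------------------------------------------------------------


def _basal_domain(pos: int, strand: str, basal_up: int, basal_down: int):
    if strand == "+":
        return pos - basal_up, pos + basal_down
    return pos - basal_down, pos + basal_up


def build_regulatory_domains(
    tss_table: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension: int = 1_000_000,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains from a TSS table.

    Each gene gets a basal domain (basal_up upstream, basal_down
    downstream of the TSS, strand-aware) extended in both directions to
    the nearest neighboring basal domain, capped at ``extension``.
    """
    req = {"gene", "chrom", "pos", "strand"}
    if not req.issubset(tss_table.columns):
        raise ValidationError(f"TSS table needs columns {sorted(req)}")
    rows = []
    for chrom, sub in tss_table.groupby("chrom"):
        sub = sub.sort_values("pos", kind="stable")
        basal = []
        for rec in sub.itertuples(index=False):
            strand = rec.strand
            if strand not in ("+", "-"):
                logger.info("gene %s has unknown strand %r; treated as '+'", rec.gene, strand)
                strand = "+"
            b0, b1 = _basal_domain(int(rec.pos), strand, basal_up, basal_down)
            basal.append((rec.gene, int(rec.pos), max(b0, 0), b1))
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        for i, (gene, pos, b0, b1) in enumerate(basal):
            left = max((b[3] for b in basal[:i]), default=0)
            right = min((b[2] for b in basal[i + 1:]), default=np.inf)
            start = min(b0, max(pos - extension, left, 0))
            end = max(b1, min(pos + extension, right))
            if size is not None:
                end = min(end, size)
                start = min(start, end - 1)
            rows.append({"gene": gene, "chrom": chrom, "start": int(start), "end": int(end)})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def link_islands_to_genes(
    islands: list,
    tss_table: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    extension: int = 1_000_000,
    curated_domains: IntervalSet | None = None,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Associate islands with genes whose regulatory domain they overlap.

    Curated domains (an IntervalSet whose ``name`` column carries gene
    symbols) take precedence over computed domains for their genes.
    Also fills each island's ``genes`` set in place. Returns one row per
    (island, gene) association.
    """
    domains = build_regulatory_domains(tss_table, basal_up, basal_down, extension, chrom_sizes)
    if curated_domains is not None and len(curated_domains):
        if "name" not in curated_domains.df.columns:
            raise ValidationError("curated_domains needs a 'name' column with gene symbols")
        cur = curated_domains.df.rename(columns={"name": "gene"})[["gene", "chrom", "start", "end"]]
        domains = pd.concat(
            [domains[~domains["gene"].isin(cur["gene"])], cur], ignore_index=True
        )
    rows = []
    by_chrom = {c: sub.sort_values("start", kind="stable") for c, sub in domains.groupby("chrom")}
    for idx, isl in enumerate(islands):
        isl.genes = set()
        sub = by_chrom.get(isl.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] < isl.end) & (sub["end"] > isl.start)]
        for gene in hit["gene"]:
            isl.genes.add(gene)
            rows.append(
                {
                    "island_index": idx, "chrom": isl.chrom,
                    "start": isl.start, "end": isl.end, "gene": gene,
                }
            )
    return pd.DataFrame(rows, columns=["island_index", "chrom", "start", "end", "gene"])


# ---------------------------------------------------------------------------
# Permutation enrichment
# ---------------------------------------------------------------------------


def _count_overlapping(starts, ends, merged_chrom) -> np.ndarray:
    """Boolean per region: overlaps the merged union on this chromosome."""
    s, e = merged_chrom
    if len(s) == 0:
        return np.zeros(np.shape(starts), dtype=bool)
    k = np.searchsorted(s, ends, side="left")
    prev_end = np.where(k > 0, e[np.maximum(k - 1, 0)], -np.inf)
    return (k > 0) & (prev_end > starts)


def permutation_enrichment(
    query: IntervalSet,
    target: IntervalSet,
    chrom_sizes: dict,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Permutation test of query-target overlap.

    The statistic is the number of query regions overlapping at least
    one target region. Each permutation redraws every query region
    uniformly at random on its own chromosome with its own length, so
    the null preserves region lengths and the per-chromosome count.
    The empirical p-value uses the +1 correction, p = (1 + #extreme) /
    (1 + n_perm), and is therefore never zero.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    merged = target.merged_by_chrom()
    empty = (np.array([], dtype=int), np.array([], dtype=int))
    rng = np.random.default_rng(seed)

    observed = 0
    null = np.zeros(n_perm, dtype=int)
    for chrom, sub in query.df.groupby("chrom"):
        if chrom not in chrom_sizes:
            raise ValidationError(f"query region on unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        if (lengths > size).any():
            raise ValidationError(f"query region longer than chromosome {chrom}")
        m = merged.get(chrom, empty)
        observed += int(
            _count_overlapping(sub["start"].to_numpy(), sub["end"].to_numpy(), m).sum()
        )
        max_start = size - lengths + 1  # exclusive upper bound per region
        draws = rng.integers(0, max_start[None, :], size=(n_perm, len(lengths)))
        null += _count_overlapping(draws, draws + lengths[None, :], m).sum(axis=1)

    if alternative == "greater":
        p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    elif alternative == "less":
        p = (1 + int(np.sum(null <= observed))) / (1 + n_perm)
    else:
        pg = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
        pl = (1 + int(np.sum(null <= observed))) / (1 + n_perm)
        p = min(1.0, 2.0 * min(pg, pl))
    sd = float(null.std())
    z = (observed - float(null.mean())) / sd if sd > 0 else 0.0
    return PermutationResult(
        observed=observed, null_mean=float(null.mean()), null_sd=sd,
        n_perm=n_perm, pvalue=float(p), zscore=float(z),
        alternative=alternative, seed=seed,
    )


def module_island_fraction(
    assignment: GeneModuleAssignment, island_gene_links
) -> dict:
    """Per module, the fraction of member genes linked to >= 1 island."""
    if isinstance(island_gene_links, pd.DataFrame):
        linked = set(island_gene_links["gene"].tolist())
    else:
        linked = set(island_gene_links)
    out = {}
    for j in range(assignment.membership.shape[1]):
        genes = assignment.module_genes(j)
        if not genes:
            warnings.warn(f"module {j} is empty; island fraction set to 0")
            out[j] = 0.0
        else:
            out[j] = len(genes & linked) / len(genes)
    return out
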