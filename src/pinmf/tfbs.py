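"""Allele-specific transcription-factor binding scores at island variants.

Motifs are position probability matrices (PWMs). A sequence's match
score is the sum of per-position probabilities, min-max scaled to [0, 1]
so that the consensus sequence scores exactly 1 and the anti-consensus
exactly 0. Match significance is the exact tail probability of that
score under a background nucleotide distribution, computed by
dynamic-programming convolution of the per-position score distributions
on a fixed grid. For each variant the motif window maximizing the better
allele's score (over offsets and strands) is retained, the score
difference alt - ref quantifies the predicted binding change, and
effects in the top quartile of |difference| are labelled strong.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .factorization import ValidationError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_PSEUDOCOUNT = 0.8  # per position, split evenly across the 4 bases
DEFAULT_GRID = 1e-4  # p-value DP bin width, as a fraction of the score range


@dataclass
class PWMRecord:
    """A motif: L x 4 per-position base probabilities (columns A, C, G, T)."""

    motif_id: str
    tf: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"{self.motif_id}: matrix must be L x 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError(f"{self.motif_id}: rows must sum to 1")
        if np.any(self.matrix <= 0):
            raise ValidationError(f"{self.motif_id}: probabilities must be > 0 (pseudocounted)")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWMRecord":
        return PWMRecord(self.motif_id, self.tf, self.matrix[::-1, ::-1].copy())


@dataclass
class TFBSEffect:
    variant_id: str
    motif_id: str
    tf: str
    strand: str
    offset: int  # variant position within the motif window
    ref_score: float
    alt_score: float
    delta: float
    pvalue: float
    qvalue: float = np.nan
    strength: str | None = None


@dataclass
class TFEffectSummary:
    tf: str
    n_strong_positive: int
    n_strong_negative: int
    n_total: int
    tf_class: str  # increased | reduced | both | none
    frequency_score: float


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _normalize_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    return (counts + pseudocount / 4.0) / (totals + pseudocount)


def parse_pwms(text: str, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWMRecord]:
    """Parse a JASPAR- or HOCOMOCO-style motif collection.

    Two layouts are recognized per motif block: four base-labelled rows
    ("A [ 1 2 3 ]") or L position rows of four numbers (A C G T order).
    Count and frequency matrices are both accepted; every matrix is
    pseudocount-regularized (``pseudocount`` split evenly over bases,
    relative to each position's total) and renormalized.
    """
    records: list[PWMRecord] = []
    blocks: list[tuple[str, list[str]]] = []
    header = None
    lines: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                blocks.append((header, lines))
            header, lines = line[1:].strip(), []
        elif header is not None:
            lines.append(line)
    if header is not None:
        blocks.append((header, lines))
    if not blocks:
        warnings.warn("no motifs found in PWM input")
        return []

    for header, lines in blocks:
        parts = header.split(None, 1)
        motif_id = parts[0]
        tf = parts[1].strip() if len(parts) > 1 else motif_id.split("_")[0]
        base_rows = {}
        position_rows = []
        for line in lines:
            stripped = line.replace("[", " ").replace("]", " ")
            fields = stripped.split()
            if fields and fields[0].upper() in _BASE_INDEX and len(fields) > 1:
                try:
                    base_rows[fields[0].upper()] = [float(x) for x in fields[1:]]
                    continue
                except ValueError:
                    pass
            try:
                position_rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValidationError(f"motif {motif_id}: unparseable line {line!r}") from exc
        if base_rows:
            if set(base_rows) != set(BASES):
                raise ValidationError(f"motif {motif_id}: needs rows for all of A, C, G, T")
            lens = {len(v) for v in base_rows.values()}
            if len(lens) != 1:
                raise ValidationError(f"motif {motif_id}: ragged matrix (unequal row lengths)")
            counts = np.array([base_rows[b] for b in BASES]).T
        else:
            lens = {len(r) for r in position_rows}
            if lens != {4}:
                raise ValidationError(f"motif {motif_id}: ragged matrix (rows must have 4 values)")
            counts = np.array(position_rows)
        if counts.size == 0:
            raise ValidationError(f"motif {motif_id}: empty matrix")
        records.append(PWMRecord(motif_id, tf, _normalize_counts(counts, pseudocount)))
    return records


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValidationError(f"ambiguous base {exc.args[0]!r} in sequence") from exc


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_sequence(pwm: PWMRecord, seq: str) -> float:
    """Min-max-scaled probability-sum match score in [0, 1]."""
    if len(seq) != pwm.length:
        raise ValidationError(f"sequence length {len(seq)} != motif length {pwm.length}")
    try:
        idx = [_BASE_INDEX[b] for b in seq.upper()]
    except KeyError as exc:
        raise ValidationError(f"ambiguous base {exc.args[0]!r}; mask before scoring") from exc
    raw = float(pwm.matrix[np.arange(pwm.length), idx].sum())
    lo = float(pwm.matrix.min(axis=1).sum())
    hi = float(pwm.matrix.max(axis=1).sum())
    if hi - lo <= 0:
        return 1.0  # constant-score motif: every sequence attains the maximum
    return (raw - lo) / (hi - lo)


def match_pvalue(
    pwm: PWMRecord,
    scaled_score: float,
    background: np.ndarray | None = None,
    grid: float = DEFAULT_GRID,
) -> float:
    """P(scaled score of a random background L-mer >= ``scaled_score``).

    Exact up to score-grid discretization: per-position contributions are
    rounded to a grid of width ``grid`` times the score range and the
    score distribution is built by convolution across positions.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValidationError("background must be 4 probabilities summing to 1")
    if scaled_score <= 0.0:
        return 1.0
    if scaled_score > 1.0:
        return 0.0
    lo = pwm.matrix.min(axis=1)
    hi = pwm.matrix.max(axis=1)
    span = float((hi - lo).sum())
    if span <= 0:
        return 1.0  # constant-score motif: the whole mass sits at the maximum
    binw = grid * span
    # per-position contributions above the positional minimum, in bins
    contrib = np.rint((pwm.matrix - lo[:, None]) / binw).astype(int)
    top_total = int(contrib.max(axis=1).sum())
    dist = np.zeros(top_total + 1)
    dist[0] = 1.0
    top = 0
    for i in range(pwm.length):
        new = np.zeros(top_total + 1)
        for b in range(4):
            k = contrib[i, b]
            new[k : top + k + 1] += bg[b] * dist[: top + 1]
        dist = new
        top += int(contrib[i].max())
    # map the scaled threshold onto the realized bin range (0 .. top_total)
    cut = int(np.ceil(scaled_score * top_total - 1e-9))
    return float(dist[cut:].sum())


# ---------------------------------------------------------------------------
# Variant evaluation
# ---------------------------------------------------------------------------


def evaluate_variant(
    variant,
    context_sequence: str,
    pwms: list[PWMRecord],
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    adjust: bool = True,
) -> list[TFBSEffect]:
    """Score ref/alt binding for every motif window covering a variant.

    ``context_sequence`` must be centered on the variant position and
    carry the ancestral (reference) allele at its center; it must span
    at least max motif length - 1 bases on each side. For each motif all
    offsets on both strands are scanned and the single placement with
    the best better-allele score is kept; an effect is emitted when that
    allele's match p-value is <= ``p_threshold``. Per TF only the best
    effect per variant survives (redundant motifs dropped); BH
    adjustment is applied across the emitted set when ``adjust`` is
    true (use :func:`bh_adjust_effects` to re-adjust jointly across
    variants instead).
    """
    context = context_sequence.upper()
    center = len(context) // 2
    if context[center] != variant.ancestral:
        raise ValidationError(
            f"context center base {context[center]!r} does not match "
            f"ancestral allele {variant.ancestral!r}"
        )
    max_len = max((p.length for p in pwms), default=1)
    if center < max_len - 1 or len(context) - center - 1 < max_len - 1:
        raise ValidationError(
            f"context too short: need {max_len - 1} bases on each side of the variant"
        )
    alt_context = context[:center] + variant.derived + context[center + 1 :]

    effects = []
    for pwm in pwms:
        L = pwm.length
        rc = pwm.reverse_complement()
        best = None  # (max_score, ref, alt, strand, offset, scoring_pwm)
        for offset in range(L):
            start = center - offset
            ref_win = context[start : start + L]
            alt_win = alt_context[start : start + L]
            for strand, mat in (("+", pwm), ("-", rc)):
                s_ref = score_sequence(mat, ref_win)
                s_alt = score_sequence(mat, alt_win)
                key = max(s_ref, s_alt)
                if best is None or key > best[0]:
                    best = (key, s_ref, s_alt, strand, offset, mat)
        key, s_ref, s_alt, strand, offset, mat = best
        p = match_pvalue(mat, key, background=background)
        if p <= p_threshold:
            effects.append(
                TFBSEffect(
                    variant_id=variant.variant_id,
                    motif_id=pwm.motif_id,
                    tf=pwm.tf,
                    strand=strand,
                    offset=offset,
                    ref_score=s_ref,
                    alt_score=s_alt,
                    delta=s_alt - s_ref,
                    pvalue=p,
                )
            )

    effects = _drop_redundant(effects)
    if adjust and effects:
        bh_adjust_effects(effects)
    return effects


def _drop_redundant(effects: list[TFBSEffect]) -> list[TFBSEffect]:
    """Keep, per (TF, variant), the single effect with the best match."""
    best: dict[tuple, TFBSEffect] = {}
    for eff in effects:
        key = (eff.tf, eff.variant_id)
        cur = best.get(key)
        if cur is None:
            best[key] = eff
            continue
        eff_match = max(eff.ref_score, eff.alt_score)
        cur_match = max(cur.ref_score, cur.alt_score)
        if (eff_match, abs(eff.delta)) > (cur_match, abs(cur.delta)):
            best[key] = eff
    return sorted(best.values(), key=lambda e: (e.variant_id, e.tf, e.motif_id))


def bh_adjust_effects(effects: list[TFBSEffect]) -> list[TFBSEffect]:
    """Benjamini-Hochberg adjustment across all effects, in place."""
    if not effects:
        return effects
    qvals = multipletests([e.pvalue for e in effects], method="fdr_bh")[1]
    for eff, q in zip(effects, qvals):
        eff.qvalue = float(q)
    return effects


def classify_tf_effects(effects: list[TFBSEffect]) -> list[TFEffectSummary]:
    """Top-quartile strength filter and per-TF direction classes.

    An effect is strong when |delta| is at or above the 75th percentile
    of |delta| over all effects. A TF's class is ``increased`` if all of
    its strong effects raise affinity, ``reduced`` if all lower it,
    ``both`` if mixed, ``none`` without strong effects. The frequency
    score is strong hits / total hits.
    """
    if not effects:
        raise ValidationError("no effects to classify")
    abs_delta = np.array([abs(e.delta) for e in effects])
    cutoff = float(np.quantile(abs_delta, 0.75))
    for eff in effects:
        eff.strength = "strong" if abs(eff.delta) >= cutoff else "weak"
    summaries = []
    tfs = sorted({e.tf for e in effects})
    for tf in tfs:
        own = [e for e in effects if e.tf == tf]
        pos = sum(1 for e in own if e.strength == "strong" and e.delta > 0)
        neg = sum(1 for e in own if e.strength == "strong" and e.delta < 0)
        if pos and neg:
            cls = "both"
        elif pos:
            cls = "increased"
        elif neg:
            cls = "reduced"
        else:
            cls = "none"
        summaries.append(
            TFEffectSummary(
                tf=tf,
                n_strong_positive=pos,
                n_strong_negative=neg,
                n_total=len(own),
                tf_class=cls,
                frequency_score=(pos + neg) / len(own),
            )
        )
    return summaries
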