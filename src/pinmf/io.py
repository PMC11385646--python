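"""Readers and writers for the toolkit's file formats.

Expression matrices travel as MatrixMarket (.mtx) with gene/cell TSV
sidecars or as dense TSV (genes x cells); cell metadata as TSV with
columns cell_id, pseudotime, branch. Genomic intervals are BED (0-based
half-open); variant tables are TSV with 1-based positions converted on
load; motif collections are JASPAR/HOCOMOCO-style text. Every writer has
a matching reader that round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .factorization import (
    ConsensusResult,
    GeneModuleAssignment,
    TrajectoryDataset,
    ValidationError,
)
from .islands import IntervalSet, PermutationResult, VariantRecord
from .tfbs import TFBSEffect, TFEffectSummary

VARIANT_HEADER = ["chrom", "pos_1based", "ancestral", "derived", "frequency", "archaic_state"]


# ---------------------------------------------------------------------------
# Trajectory data
# ---------------------------------------------------------------------------


def _sidecar_paths(expr_path: Path) -> tuple[Path, Path]:
    stem = expr_path.with_suffix("")
    return Path(f"{stem}.genes.tsv"), Path(f"{stem}.cells.tsv")


def save_trajectory(data: TrajectoryDataset, expr_path, meta_path) -> None:
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        sio.mmwrite(str(expr_path), sparse.csr_matrix(data.expr))
        genes_path, cells_path = _sidecar_paths(expr_path)
        pd.Series(data.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
        pd.Series(data.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)
    else:
        pd.DataFrame(data.expr, index=data.gene_ids, columns=data.cell_ids).to_csv(
            expr_path, sep="\t"
        )
    pd.DataFrame(
        {"cell_id": data.cell_ids, "pseudotime": data.pseudotime, "branch": data.branch}
    ).to_csv(meta_path, sep="\t", index=False)


def load_trajectory(expr_path, meta_path) -> TrajectoryDataset:
    """Load and validate an expression matrix plus per-cell metadata.

    Cells present in the matrix but absent from the metadata (or vice
    versa) are a validation error naming the missing identifiers.
    """
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        expr = np.asarray(sio.mmread(str(expr_path)).todense())
        genes_path, cells_path = _sidecar_paths(expr_path)
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).to_numpy()
        cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).to_numpy()
    else:
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        expr = df.to_numpy(dtype=float)
        gene_ids = df.index.astype(str).to_numpy()
        cell_ids = df.columns.astype(str).to_numpy()
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"cell_id", "pseudotime", "branch"}
    if not required.issubset(meta.columns):
        raise ValidationError(f"metadata needs columns {sorted(required)}")
    meta = meta.set_index(meta["cell_id"].astype(str))
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        shown = ", ".join(missing[:5])
        raise ValidationError(
            f"{len(missing)} matrix cells missing from metadata: {shown}"
            + ("..." if len(missing) > 5 else "")
        )
    meta = meta.loc[cell_ids]
    return TrajectoryDataset(
        expr=expr,
        pseudotime=meta["pseudotime"].to_numpy(dtype=float),
        branch=meta["branch"].astype(str).to_numpy(),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
    )


# ---------------------------------------------------------------------------
# Factorization outputs
# ---------------------------------------------------------------------------


def save_consensus(consensus: ConsensusResult, data: TrajectoryDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r = consensus.rank
    prog = [f"program{j + 1}" for j in range(r)]
    pd.DataFrame(consensus.consensus_A, index=data.cell_ids, columns=prog).to_csv(
        outdir / "consensus_A.tsv", sep="\t", float_format="%.10g"
    )
    pd.DataFrame(consensus.consensus_X.T, index=data.gene_ids, columns=prog).to_csv(
        outdir / "consensus_X.tsv", sep="\t", float_format="%.10g"
    )
    pd.DataFrame(consensus.activations, index=data.cell_ids, columns=prog).to_csv(
        outdir / "activations.tsv", sep="\t", float_format="%.10g"
    )


def save_replicate_components(replicates, data: TrajectoryDataset, path) -> None:
    """Pooled gene-coefficient rows of every replicate, one row per component."""
    rows = []
    index = []
    for rep in replicates:
        for j in range(rep.rank):
            index.append(f"rep{rep.seed}_comp{j}")
            rows.append(rep.X[j])
    pd.DataFrame(np.asarray(rows), index=index, columns=data.gene_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def load_replicate_components(path):
    """Rebuild minimal replicate stubs from a pooled-component table.

    Returns objects sufficient for consensus clustering (X and rank);
    temporal factors are refit by the consensus step itself.
    """
    from .factorization import ReplicateFactorization

    df = pd.read_csv(path, sep="\t", index_col=0)
    groups: dict[str, list] = {}
    for name in df.index:
        rep_id = name.rsplit("_comp", 1)[0]
        groups.setdefault(rep_id, []).append(name)
    replicates = []
    for rep_id, names in groups.items():
        X = df.loc[names].to_numpy(dtype=float)
        replicates.append(
            ReplicateFactorization(
                A=np.zeros((0, X.shape[0])), X=X, C=None,
                objective_trace=np.array([np.nan]), converged=True,
                seed=int(rep_id.replace("rep", "")),
            )
        )
    return replicates, df.columns.to_numpy()


def save_assignment(assignment: GeneModuleAssignment, path) -> None:
    rows = []
    r = assignment.coefficients.shape[1]
    for g, gene in enumerate(assignment.gene_ids):
        for j in range(r):
            rows.append(
                {
                    "gene": gene,
                    "program": j + 1,
                    "coefficient": assignment.coefficients[g, j],
                    "p": assignment.pvalues[g, j],
                    "q": assignment.qvalues[g, j],
                    "member": int(assignment.membership[g, j]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def save_diagnostics(path, **payload) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Variants, chromosome sizes, TSS tables
# ---------------------------------------------------------------------------


def save_variants(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("# positions are 1-based; converted to 0-based on load\n")
        fh.write("\t".join(VARIANT_HEADER) + "\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.ancestral}\t{v.derived}"
                f"\t{v.frequency:.6g}\t{v.archaic_state}\n"
            )


def load_variants(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(VARIANT_HEADER) - set(df.columns)
    if missing:
        raise ValidationError(f"variant table missing columns {sorted(missing)}")
    return [
        VariantRecord(
            chrom=str(r.chrom),
            pos=int(r.pos_1based) - 1,
            ancestral=str(r.ancestral),
            derived=str(r.derived),
            frequency=float(r.frequency),
            archaic_state=str(r.archaic_state),
        )
        for r in df.itertuples(index=False)
    ]


def load_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return {str(r.chrom): int(r.size) for r in df.itertuples(index=False)}


def save_chrom_sizes(chrom_sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def load_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "pos", "strand"}
    if not required.issubset(df.columns):
        raise ValidationError(f"TSS table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# FASTA and motifs
# ---------------------------------------------------------------------------


def load_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def save_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def save_pwms(pwms, path) -> None:
    """Write motifs as position rows of probabilities (A C G T columns)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.tf}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.8f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Islands / effects tables
# ---------------------------------------------------------------------------


def save_islands(islands, bed_path, variants_path=None) -> None:
    with open(bed_path, "w") as fh:
        for i, isl in enumerate(islands):
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland{i + 1}\n")
    if variants_path is not None:
        rows = []
        for i, isl in enumerate(islands):
            for v in isl.variants:
                rows.append({"island": f"island{i + 1}", "variant_id": v.variant_id})
        pd.DataFrame(rows, columns=["island", "variant_id"]).to_csv(
            variants_path, sep="\t", index=False
        )


def save_permutation_result(result: PermutationResult, path) -> None:
    save_diagnostics(
        path,
        observed=result.observed,
        null_mean=result.null_mean,
        null_sd=result.null_sd,
        n_perm=result.n_perm,
        pvalue=result.pvalue,
        zscore=result.zscore,
        alternative=result.alternative,
        seed=result.seed,
    )


def save_effects(effects, path) -> None:
    rows = [
        {
            "variant_id": e.variant_id,
            "motif_id": e.motif_id,
            "tf": e.tf,
            "strand": e.strand,
            "offset": e.offset,
            "ref_score": e.ref_score,
            "alt_score": e.alt_score,
            "delta": e.delta,
            "p": e.pvalue,
            "q": e.qvalue,
            "strength": e.strength if e.strength is not None else "",
        }
        for e in effects
    ]
    pd.DataFrame(
        rows,
        columns=[
            "variant_id", "motif_id", "tf", "strand", "offset",
            "ref_score", "alt_score", "delta", "p", "q", "strength",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_effects(path) -> list:
    df = pd.read_csv(path, sep="\t")
    effects = []
    for r in df.itertuples(index=False):
        strength = r.strength if isinstance(r.strength, str) and r.strength else None
        effects.append(
            TFBSEffect(
                variant_id=str(r.variant_id),
                motif_id=str(r.motif_id),
                tf=str(r.tf),
                strand=str(r.strand),
                offset=int(r.offset),
                ref_score=float(r.ref_score),
                alt_score=float(r.alt_score),
                delta=float(r.delta),
                pvalue=float(r.p),
                qvalue=float(r.q) if not pd.isna(r.q) else np.nan,
                strength=strength,
            )
        )
    return effects


def save_tf_summaries(summaries, path) -> None:
    pd.DataFrame(
        [
            {
                "tf": s.tf,
                "n_strong_positive": s.n_strong_positive,
                "n_strong_negative": s.n_strong_negative,
                "n_total": s.n_total,
                "class": s.tf_class,
                "frequency_score": s.frequency_score,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Landscape bundle
# ---------------------------------------------------------------------------


def save_landscape(landscape, outdir) -> None:
    """Write a simulated landscape in exactly the formats the callers read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_chrom_sizes(landscape.chrom_sizes, outdir / "chrom.sizes")
    landscape.peaks.to_bed(outdir / "peaks.bed")
    save_variants(landscape.variants, outdir / "variants.tsv")
    with open(outdir / "archaic_derived.bed", "w") as fh:
        for chrom in sorted(landscape.archaic_derived):
            for pos in landscape.archaic_derived[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
    for name, target in landscape.targets.items():
        target.to_bed(outdir / f"target_{name}.bed")
    with open(outdir / "true_islands.bed", "w") as fh:
        for chrom, start, end, members in landscape.true_islands:
            fh.write(f"{chrom}\t{start}\t{end}\t{';'.join(members)}\n")
    if landscape.pwms:
        save_pwms(landscape.pwms, outdir / "pwms.txt")
    if landscape.reference_sequence:
        save_fasta(landscape.reference_sequence, outdir / "reference.fa")
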