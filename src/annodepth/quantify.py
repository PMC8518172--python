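"""Read assignment (EM over compatibility sets) and tpm computation.

tpm follows the standard definition

    tpm_i = 10^6 * (x_i / y_i) / S,      S = sum_j x_j / y_j

with x_i the (possibly fractional) mapped-read count, y_i the raw
transcript length in nucleotides, and the sum running over the transcripts
of the quantified annotation only.  Unmapped reads contribute to neither
x nor S — that exclusion is what shrinks S when annotations are reduced.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import QuantificationError, ValidationError
from .synthetic_data import Annotation, ReadSet

__all__ = [
    "SampleQuant",
    "GeneQuant",
    "assign_reads",
    "compute_tpm",
    "quantify_sample",
    "summarize_to_gene",
]

EM_MAX_ITER_DEFAULT = 1000
EM_TOL_DEFAULT = 1e-8


@dataclass(frozen=True)
class SampleQuant:
    """Per-transcript quantification of one sample against one annotation.

    ``table`` is indexed by transcript_id with columns
    ``reads_mapped`` (x), ``length`` (y) and ``tpm``.
    """

    table: pd.DataFrame
    S: float            # sum_j x_j / y_j  (reads per nucleotide)
    n_mapped: float

    @property
    def n_transcripts(self) -> int:
        return len(self.table)

    @property
    def tpm(self) -> pd.Series:
        return self.table["tpm"]

    @property
    def reads_mapped(self) -> pd.Series:
        return self.table["reads_mapped"]


@dataclass(frozen=True)
class GeneQuant:
    """Gene-level summary: summed counts/tpm plus represented length fraction."""

    table: pd.DataFrame  # index gene_id; columns reads_mapped, tpm, represented_length_fraction

    @property
    def tpm(self) -> pd.Series:
        return self.table["tpm"]

    @property
    def reads_mapped(self) -> pd.Series:
        return self.table["reads_mapped"]


# ---------------------------------------------------------------------------
# EM assignment
# ---------------------------------------------------------------------------

def _compatibility_classes(reads: ReadSet, annotation: Annotation):
    """Collapse reads into equivalence classes keyed by block id.

    Returns (class_counts, member_class_idx, member_tx_idx, n_unmapped):
    flattened membership lists mapping each class to the indices of the
    annotation transcripts compatible with it.
    """
    counts_per_block = np.bincount(reads.block_codes, minlength=len(reads.block_vocab))
    tx_pos = {tid: i for i, tid in enumerate(annotation.transcript_ids)}
    index = annotation.block_index

    class_counts: list[int] = []
    member_class: list[int] = []
    member_tx: list[int] = []
    n_unmapped = 0
    for code in np.nonzero(counts_per_block)[0]:
        block = reads.block_vocab[code]
        compat = [tx_pos[t] for t in index.get(block, ()) if t in tx_pos]
        if not compat:
            n_unmapped += int(counts_per_block[code])
            continue
        ci = len(class_counts)
        class_counts.append(int(counts_per_block[code]))
        member_class.extend([ci] * len(compat))
        member_tx.extend(compat)
    return (np.array(class_counts, dtype=float),
            np.array(member_class, dtype=np.int64),
            np.array(member_tx, dtype=np.int64),
            n_unmapped)


def assign_reads(
    reads: ReadSet,
    annotation: Annotation,
    em_max_iter: int = EM_MAX_ITER_DEFAULT,
    em_tol: float = EM_TOL_DEFAULT,
) -> np.ndarray:
    """Fractionally allocate reads to ``annotation`` transcripts by EM.

    Reads whose compatibility set does not intersect the annotation are
    unmapped and excluded entirely.  Uniquely compatible reads count 1.0 to
    their transcript; ambiguous reads are split by EM on the per-length
    relative abundances v_t (responsibility of t for a class ∝ v_t,
    M-step v_t ∝ x_t / y_t) until the abundance change drops below
    ``em_tol`` or ``em_max_iter`` iterations.

    Returns the count vector x aligned with ``annotation.transcripts``;
    x.sum() equals the number of mapped reads (up to float rounding).
    """
    if em_max_iter < 1:
        raise QuantificationError("em_max_iter must be >= 1")
    n_tx = annotation.n_transcripts
    class_counts, member_class, member_tx, _ = _compatibility_classes(reads, annotation)
    if class_counts.size == 0:
        return np.zeros(n_tx)

    n_classes = class_counts.size
    y = annotation.lengths()
    v = np.full(n_tx, 1.0 / n_tx)
    x = np.zeros(n_tx)
    for _ in range(em_max_iter):
        contrib = v[member_tx]
        denom = np.bincount(member_class, weights=contrib, minlength=n_classes)
        # divide before scaling so uniquely compatible reads count exactly
        resp = (contrib / denom[member_class]) * class_counts[member_class]
        x = np.bincount(member_tx, weights=resp, minlength=n_tx)
        v_new = x / y
        v_new /= v_new.sum()
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < em_tol:
            break
    return x


def compute_tpm(x, y, transcript_ids=None) -> SampleQuant:
    """Apply the tpm formula to count vector ``x`` and length vector ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise QuantificationError("x and y must be 1-d vectors of equal length")
    if (y <= 0).any():
        raise QuantificationError("all transcript lengths must be positive")
    if (x < 0).any():
        raise QuantificationError("negative read counts")
    if x.sum() <= 0:
        raise QuantificationError("no mapped reads: tpm undefined")

    rate = x / y
    S = rate.sum()
    tpm = 1e6 * rate / S
    if transcript_ids is None:
        transcript_ids = [f"t{i}" for i in range(x.size)]
    table = pd.DataFrame(
        {"reads_mapped": x, "length": y, "tpm": tpm},
        index=pd.Index(transcript_ids, name="transcript_id"),
    )
    return SampleQuant(table=table, S=float(S), n_mapped=float(x.sum()))


def quantify_sample(
    reads: ReadSet,
    annotation: Annotation,
    em_max_iter: int = EM_MAX_ITER_DEFAULT,
    em_tol: float = EM_TOL_DEFAULT,
) -> SampleQuant:
    """assign_reads + compute_tpm against one annotation."""
    x = assign_reads(reads, annotation, em_max_iter=em_max_iter, em_tol=em_tol)
    return compute_tpm(x, annotation.lengths(), transcript_ids=annotation.transcript_ids)


def summarize_to_gene(
    quant: SampleQuant,
    annotation: Annotation,
    full_annotation: Annotation | None = None,
) -> GeneQuant:
    """Sum transcript counts and tpm to the gene level.

    ``represented_length_fraction`` is the fraction of each gene's
    full-annotation transcript length present in ``annotation``; when
    ``full_annotation`` is omitted the quantified annotation is its own
    reference (fraction 1 everywhere).
    """
    full = annotation if full_annotation is None else full_annotation
    quant_ids = set(quant.table.index)
    ann_ids = set(annotation.transcript_ids)
    if not quant_ids <= ann_ids:
        raise ValidationError("quantified transcripts not all present in the annotation")
    if not ann_ids <= set(full.transcript_ids):
        raise ValidationError("annotation is not a subset of the full annotation")

    gene_of = {t.transcript_id: t.gene_id for t in annotation.transcripts}
    genes = quant.table.groupby(quant.table.index.map(gene_of))[["reads_mapped", "tpm"]].sum()
    genes.index.name = "gene_id"

    sub_len = {g: sum(annotation.by_id[t].length for t in members)
               for g, members in annotation.gene_members.items()}
    full_len = {g: sum(full.by_id[t].length for t in members)
                for g, members in full.gene_members.items()}
    genes["represented_length_fraction"] = [
        sub_len[g] / full_len.get(g, sub_len[g]) for g in genes.index
    ]
    return GeneQuant(table=genes)
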