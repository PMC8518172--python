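"""Plain-text (TSV / FASTA) serialization of the pipeline's tables.

Dialects (column names are fixed):

* annotation TSV: transcript_id, gene_id, family_id, length, blocks
  (blocks encoded as ``id:len;id:len;...``; length must equal the block sum)
* quant TSV: transcript_id, reads_mapped, length, tpm
* gene quant TSV: gene_id, reads_mapped, tpm, represented_length_fraction
* ortholog TSV: gene_id_ref, gene_id_other
* FASTA: one record per transcript; the sequence of a block is a
  deterministic function of its id, so shared blocks share sequence.

Every writer can stamp metadata (config hash, seed, ...) as ``#``-prefixed
header comments; readers skip them.  Malformed rows are rejected with
their line number.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import SchemaError
from .quantify import GeneQuant, SampleQuant
from .synthetic_data import Annotation, Block, Transcript

__all__ = [
    "write_annotation", "read_annotation",
    "write_quant", "read_quant",
    "write_gene_quant", "read_gene_quant",
    "write_ortholog_map", "read_ortholog_map",
    "write_fasta", "read_fasta",
]

_ANNOTATION_COLS = ["transcript_id", "gene_id", "family_id", "length", "blocks"]
_QUANT_COLS = ["transcript_id", "reads_mapped", "length", "tpm"]
_GENE_COLS = ["gene_id", "reads_mapped", "tpm", "represented_length_fraction"]
_ORTHO_COLS = ["gene_id_ref", "gene_id_other"]


def _write_tsv(df: pd.DataFrame, path, meta: Mapping[str, str] | None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path, expected_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype=str)
    if list(df.columns) != expected_cols:
        raise SchemaError(
            f"{path}: expected columns {expected_cols}, found {list(df.columns)}")
    return df


def _row_number(df_index: int, path: Path) -> str:
    # +2: 1-based plus header row (comment lines not counted; close enough to locate)
    return f"{path} row {df_index + 2}"


# -- annotations -----------------------------------------------------------

def write_annotation(annotation: Annotation, path,
                     meta: Mapping[str, str] | None = None) -> None:
    rows = [{
        "transcript_id": t.transcript_id,
        "gene_id": t.gene_id,
        "family_id": t.family_id,
        "length": t.length,
        "blocks": ";".join(f"{b.block_id}:{b.length}" for b in t.blocks),
    } for t in annotation.transcripts]
    stamped = {"label": annotation.label, "version_tag": annotation.version_tag,
               **(meta or {})}
    _write_tsv(pd.DataFrame(rows, columns=_ANNOTATION_COLS), path, stamped)


def read_annotation(path, label: str | None = None) -> Annotation:
    path = Path(path)
    df = _read_tsv(path, _ANNOTATION_COLS)
    header_meta = _read_meta(path)
    transcripts = []
    for i, row in df.iterrows():
        try:
            pieces = [p.split(":") for p in row["blocks"].split(";")]
            blocks = tuple(Block(bid, int(ln)) for bid, ln in pieces)
            length = int(row["length"])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{_row_number(i, path)}: malformed blocks/length ({exc})")
        if sum(b.length for b in blocks) != length:
            raise SchemaError(
                f"{_row_number(i, path)}: length {length} != sum of block lengths")
        transcripts.append(Transcript(
            transcript_id=row["transcript_id"], gene_id=row["gene_id"],
            family_id=row["family_id"], blocks=blocks))
    return Annotation(
        label=label or header_meta.get("label", path.stem),
        transcripts=tuple(transcripts),
        version_tag=header_meta.get("version_tag", ""),
    )


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


# -- quantifications -------------------------------------------------------

def write_quant(quant: SampleQuant, path, meta: Mapping[str, str] | None = None) -> None:
    df = quant.table.reset_index()[_QUANT_COLS]
    _write_tsv(df, path, meta)


def read_quant(path) -> SampleQuant:
    path = Path(path)
    df = _read_tsv(path, _QUANT_COLS)
    try:
        x = df["reads_mapped"].astype(float).to_numpy()
        y = df["length"].astype(float).to_numpy()
        tpm = df["tpm"].astype(float).to_numpy()
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric quant values ({exc})")
    for i in np.nonzero(x < 0)[0]:
        raise SchemaError(f"{_row_number(int(i), path)}: negative read count {x[i]}")
    for i in np.nonzero(y <= 0)[0]:
        raise SchemaError(f"{_row_number(int(i), path)}: non-positive length {y[i]}")
    table = pd.DataFrame(
        {"reads_mapped": x, "length": y, "tpm": tpm},
        index=pd.Index(df["transcript_id"], name="transcript_id"))
    S = float((x / y).sum())
    return SampleQuant(table=table, S=S, n_mapped=float(x.sum()))


def write_gene_quant(gene: GeneQuant, path, meta: Mapping[str, str] | None = None) -> None:
    df = gene.table.reset_index()[_GENE_COLS]
    _write_tsv(df, path, meta)


def read_gene_quant(path) -> GeneQuant:
    path = Path(path)
    df = _read_tsv(path, _GENE_COLS)
    try:
        out = df.assign(
            reads_mapped=df["reads_mapped"].astype(float),
            tpm=df["tpm"].astype(float),
            represented_length_fraction=df["represented_length_fraction"].astype(float),
        ).set_index("gene_id")
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric gene quant values ({exc})")
    if (out["reads_mapped"] < 0).any():
        i = int(np.nonzero(out["reads_mapped"].to_numpy() < 0)[0][0])
        raise SchemaError(f"{_row_number(i, path)}: negative read count")
    return GeneQuant(table=out)


# -- ortholog maps ---------------------------------------------------------

def write_ortholog_map(mapping: Mapping[str, str], path,
                       meta: Mapping[str, str] | None = None) -> None:
    """``mapping`` is other-species gene -> reference gene."""
    df = pd.DataFrame(
        {"gene_id_ref": list(mapping.values()), "gene_id_other": list(mapping.keys())},
        columns=_ORTHO_COLS)
    _write_tsv(df, path, meta)


def read_ortholog_map(path) -> dict[str, str]:
    path = Path(path)
    df = _read_tsv(path, _ORTHO_COLS)
    if df["gene_id_other"].duplicated().any() or df["gene_id_ref"].duplicated().any():
        raise SchemaError(f"{path}: ortholog map is not one-to-one")
    return dict(zip(df["gene_id_other"], df["gene_id_ref"]))


# -- FASTA (interoperability only) ----------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _block_sequence(block: Block) -> str:
    seed = int.from_bytes(hashlib.sha256(block.block_id.encode()).digest()[:8], "little")
    rng = np.random.default_rng(seed)
    return b"".join(_BASES[rng.integers(0, 4, size=block.length)]).decode()


def write_fasta(annotation: Annotation, path, width: int = 70) -> None:
    """Synthetic sequence per transcript; shared blocks share sequence."""
    with Path(path).open("w") as fh:
        for t in annotation.transcripts:
            seq = "".join(_block_sequence(b) for b in t.blocks)
            fh.write(f">{t.transcript_id} gene={t.gene_id} family={t.family_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> list[tuple[str, int]]:
    """(transcript_id, length) pairs from a FASTA file."""
    return [(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
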