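"""Readers and writers for the pipeline's tables and alignment files.

All tables are headered TSV; residue positions are 1-based on ungapped
sequences.  Alignments are aligned FASTA, one file per ortholog cluster,
with record ids of the form ``<genome_code><delimiter><protein_id>``.
Readers fail loudly on malformed input; writers sort rows on fixed keys and
format floats to six significant digits so identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    GenomeSet,
    InteractionEdge,
    KinaseRecord,
    KinaseSubstrateEdge,
    MalformedAlignmentError,
    OrthologFamily,
    Phosphosite,
)

__all__ = [
    "read_alignment_family",
    "read_alignment_families",
    "write_alignment_family",
    "read_fasta_sequences",
    "write_fasta_sequences",
    "read_site_table",
    "write_site_table",
    "read_motif_table",
    "read_kinase_table",
    "write_kinase_table",
    "read_kinase_substrate_table",
    "write_kinase_substrate_table",
    "read_interaction_table",
    "write_interaction_table",
    "read_annotation_table",
    "write_table",
]

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# alignments and sequences

def read_alignment_family(
    path: str | os.PathLike,
    genomes: Optional[GenomeSet] = None,
    delimiter: str = "|",
) -> OrthologFamily:
    """Read one per-cluster aligned FASTA file into an :class:`OrthologFamily`.

    The cluster id is the file stem.  Record ids must look like
    ``genome|protein``; records with a genome code outside *genomes* are
    skipped with a warning.  ``.`` gap characters are normalised to ``-``
    and sequences are upper-cased.
    """
    path = Path(path)
    members: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if delimiter not in rec.id:
            raise MalformedAlignmentError(
                f"{path.name}: record id {rec.id!r} lacks delimiter {delimiter!r}"
            )
        genome, protein_id = rec.id.split(delimiter, 1)
        if genomes is not None and genome not in genomes:
            log.warning("%s: skipping unknown genome code %r", path.name, genome)
            continue
        row = str(rec.seq).upper().replace(".", "-")
        members.setdefault(genome, []).append((protein_id, row))
    if not members:
        raise MalformedAlignmentError(f"{path.name}: no alignment records")
    lengths = {len(row) for mem in members.values() for _, row in mem}
    if len(lengths) != 1:
        raise MalformedAlignmentError(
            f"{path.name}: unequal aligned row lengths {sorted(lengths)}"
        )
    return OrthologFamily(cluster_id=path.stem, members=members)


def read_alignment_families(
    paths: Iterable[str | os.PathLike],
    genomes: Optional[GenomeSet] = None,
    delimiter: str = "|",
) -> list[OrthologFamily]:
    """Read many per-cluster alignment files, sorted by cluster id."""
    fams = [read_alignment_family(p, genomes, delimiter) for p in paths]
    return sorted(fams, key=lambda f: f.cluster_id)


def write_alignment_family(
    family: OrthologFamily, directory: str | os.PathLike, delimiter: str = "|"
) -> Path:
    """Write a family as ``<directory>/<cluster_id>.afa`` (aligned FASTA)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{family.cluster_id}.afa"
    with open(path, "w") as fh:
        for genome in sorted(family.members):
            for protein_id, row in sorted(family.members[genome]):
                fh.write(f">{genome}{delimiter}{protein_id}\n{row}\n")
    return path


def read_fasta_sequences(path: str | os.PathLike) -> dict[str, str]:
    """Read an ungapped FASTA file as ``{id: sequence}``, upper-cased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_sequences(sequences: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n{sequences[name]}\n")


# ---------------------------------------------------------------------------
# generic deterministic TSV plumbing

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def write_table(
    df: pd.DataFrame, path: str | os.PathLike, sort_by: Optional[Sequence[str]] = None
) -> None:
    """Write a TSV deterministically: sorted rows, %.6g floats, no index."""
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# phosphosites

def read_site_table(path: str | os.PathLike) -> list[Phosphosite]:
    """Read a phosphosite TSV (protein_id, position, residue, status)."""
    df = _read_tsv(path)
    _require_columns(df, ["protein_id", "position", "residue", "status"], path)
    sites = []
    for rec in df.itertuples(index=False):
        try:
            pos = int(rec.position)
        except ValueError:
            raise ValueError(
                f"{path}: non-integer position {rec.position!r} for {rec.protein_id}"
            ) from None
        sites.append(Phosphosite(rec.protein_id, pos, rec.residue, rec.status))
    return sites


def write_site_table(sites: Iterable[Phosphosite], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.position, s.residue, s.status) for s in sites],
        columns=["protein_id", "position", "residue", "status"],
    )
    write_table(df, path, sort_by=["protein_id", "position", "status"])


# ---------------------------------------------------------------------------
# motifs

def read_motif_table(path: str | os.PathLike):
    """Read the motif TSV (motif_id, pattern, optional acceptor_index).

    Returns a list of :class:`~phosmoca.motifs.MotifPattern`.
    """
    from .motifs import parse_motif_pattern

    df = _read_tsv(path)
    _require_columns(df, ["motif_id", "pattern"], path)
    patterns = []
    for rec in df.itertuples(index=False):
        acc = None
        if "acceptor_index" in df.columns and str(getattr(rec, "acceptor_index", "")).strip():
            acc = int(rec.acceptor_index)
        patterns.append(parse_motif_pattern(rec.pattern, rec.motif_id, acc))
    return patterns


def write_motif_table(patterns, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(p.motif_id, p.raw, p.acceptor_offset) for p in patterns],
        columns=["motif_id", "pattern", "acceptor_index"],
    )
    write_table(df, path, sort_by=["motif_id"])


# ---------------------------------------------------------------------------
# kinases

def read_kinase_table(
    path: str | os.PathLike, genomes: Optional[GenomeSet] = None
) -> list[KinaseRecord]:
    """Read the kinase TSV (kinase_id, group, family, one 0/1 column per genome)."""
    df = _read_tsv(path)
    _require_columns(df, ["kinase_id", "group"], path)
    genome_cols = [c for c in df.columns if c not in ("kinase_id", "group", "family")]
    if genomes is not None:
        genome_cols = [c for c in genome_cols if c in genomes]
    records = []
    for rec in df.itertuples(index=False):
        presence = {g: getattr(rec, g) in ("1", "True", "true") for g in genome_cols}
        records.append(
            KinaseRecord(
                kinase_id=rec.kinase_id,
                group=rec.group,
                family=getattr(rec, "family", ""),
                presence=presence,
            )
        )
    return records


def write_kinase_table(
    kinases: Iterable[KinaseRecord], path: str | os.PathLike, genomes: GenomeSet
) -> None:
    rows = []
    for k in kinases:
        row = {"kinase_id": k.kinase_id, "group": k.group, "family": k.family}
        for g in genomes:
            row[g] = int(k.present_in(g))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["kinase_id", "group", "family", *genomes.codes])
    write_table(df, path, sort_by=["kinase_id"])


def read_kinase_substrate_table(path: str | os.PathLike) -> list[KinaseSubstrateEdge]:
    df = _read_tsv(path)
    _require_columns(df, ["kinase_id", "protein_id", "position", "residue"], path)
    return [
        KinaseSubstrateEdge(r.kinase_id, r.protein_id, int(r.position), r.residue)
        for r in df.itertuples(index=False)
    ]


def write_kinase_substrate_table(
    edges: Iterable[KinaseSubstrateEdge], path: str | os.PathLike
) -> None:
    df = pd.DataFrame(
        [(e.kinase_id, e.protein_id, e.position, e.residue) for e in edges],
        columns=["kinase_id", "protein_id", "position", "residue"],
    )
    write_table(df, path, sort_by=["kinase_id", "protein_id", "position"])


# ---------------------------------------------------------------------------
# interactions and annotations

def read_interaction_table(path: str | os.PathLike) -> list[InteractionEdge]:
    """Read an interaction edge list; drops self-loops, collapses duplicates."""
    df = _read_tsv(path)
    _require_columns(df, ["protein_a", "protein_b"], path)
    seen: dict[tuple[str, str], InteractionEdge] = {}
    for rec in df.itertuples(index=False):
        if rec.protein_a == rec.protein_b:
            continue
        edge = InteractionEdge.canonical(
            rec.protein_a, rec.protein_b, getattr(rec, "source", "")
        )
        seen.setdefault(edge.key, edge)
    return [seen[k] for k in sorted(seen)]


def write_interaction_table(
    edges: Iterable[InteractionEdge], path: str | os.PathLike
) -> None:
    df = pd.DataFrame(
        [(e.protein_a, e.protein_b, e.source) for e in edges],
        columns=["protein_a", "protein_b", "source"],
    )
    write_table(df, path, sort_by=["protein_a", "protein_b"])


def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a protein→term annotation TSV (protein_id, term)."""
    df = _read_tsv(path)
    _require_columns(df, ["protein_id", "term"], path)
    return df.drop_duplicates().reset_index(drop=True)


def write_annotation_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    write_table(df[["protein_id", "term"]], path, sort_by=["protein_id", "term"])
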