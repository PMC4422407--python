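"""Shared data model: genomes, phosphosites, ortholog families, kinase tables.

The study set spans nine eukaryote genomes ordered from yeast to human, with
human (``hsa``) as the reference genome in which phosphosites are observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .motifs import GAP

__all__ = [
    "STUDY_GENOME_CODES",
    "GenomeSet",
    "Phosphosite",
    "OrthologFamily",
    "KinaseRecord",
    "KinaseSubstrateEdge",
    "InteractionEdge",
    "KNOWN",
    "POTENTIAL",
]

#: KEGG three-letter codes of the nine study genomes, yeast → human.
STUDY_GENOME_CODES: tuple[str, ...] = (
    "sce", "spo", "cel", "dme", "dre", "cfa", "mmu", "ptr", "hsa",
)

KNOWN = "known"
POTENTIAL = "potential"


@dataclass(frozen=True)
class GenomeSet:
    """An ordered set of genome codes with one designated reference genome."""

    codes: tuple[str, ...] = STUDY_GENOME_CODES
    reference: str = "hsa"

    def __post_init__(self) -> None:
        if self.reference not in self.codes:
            raise ValueError(
                f"reference genome {self.reference!r} not among codes {self.codes}"
            )
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("duplicate genome codes")

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(c for c in self.codes if c != self.reference)

    def __iter__(self):
        return iter(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class Phosphosite:
    """One S/T/Y residue of a human protein, known or potential phosphosite.

    Positions are 1-based on the ungapped protein sequence.
    """

    protein_id: str
    position: int
    residue: str
    status: str = POTENTIAL

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(
                f"{self.protein_id}:{self.position}: residue must be S/T/Y, "
                f"got {self.residue!r}"
            )
        if self.status not in (KNOWN, POTENTIAL):
            raise ValueError(f"status must be 'known' or 'potential', got {self.status!r}")


class MalformedAlignmentError(ValueError):
    """An alignment whose rows are not all the same length, or an empty one."""


@dataclass
class OrthologFamily:
    """An ortholog cluster with one multiple sequence alignment.

    ``members`` maps a genome code to the list of that genome's members as
    ``(protein_id, aligned_row)`` pairs; a genome may contribute several
    in-paralogs.  All aligned rows share one length.
    """

    cluster_id: str
    members: dict[str, list[tuple[str, str]]]
    alignment_length: int = field(default=0)

    def __post_init__(self) -> None:
        rows = [row for mem in self.members.values() for _, row in mem]
        if not rows:
            raise MalformedAlignmentError(f"{self.cluster_id}: family has no members")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"{self.cluster_id}: unequal aligned row lengths {sorted(lengths)}"
            )
        self.alignment_length = lengths.pop()

    @property
    def genomes(self) -> tuple[str, ...]:
        return tuple(self.members)

    def n_genomes(self) -> int:
        return len(self.members)

    def rows_for(self, genome: str) -> list[tuple[str, str]]:
        return self.members.get(genome, [])

    def row_of(self, genome: str, protein_id: str) -> str:
        for pid, row in self.members.get(genome, []):
            if pid == protein_id:
                return row
        raise KeyError(f"{self.cluster_id}: no member {protein_id!r} in genome {genome!r}")

    @staticmethod
    def ungap(row: str) -> str:
        return row.replace(GAP, "")


@dataclass(frozen=True)
class KinaseRecord:
    """A protein kinase with its kinome classification and genome presence."""

    kinase_id: str
    group: str
    family: str = ""
    presence: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError(f"{self.kinase_id}: kinase group must be non-empty")

    def present_in(self, genome: str) -> bool:
        return bool(self.presence.get(genome, False))


@dataclass(frozen=True)
class KinaseSubstrateEdge:
    """One kinase → substrate-site relationship."""

    kinase_id: str
    protein_id: str
    position: int
    residue: str


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected protein–protein interaction; endpoints stored sorted."""

    protein_a: str
    protein_b: str
    source: str = ""

    @classmethod
    def canonical(cls, a: str, b: str, source: str = "") -> "InteractionEdge":
        a, b = sorted((a, b))
        return cls(a, b, source)

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)
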