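"""Phosphorylation-motif grammar: parsing, matching, and structural classification.

Kinase recognition motifs are written in the field's positional shorthand:
dash-separated positions, ``/`` for alternative residues, ``X`` (or ``x``)
for a wildcard, e.g. ``R-X-X-S/T`` (a basophilic motif with arginine three
residues upstream of the phospho-acceptor) or ``S/T-P`` (the proline-directed
motif targeted by CMGC kinases).  One position of every motif is the
phospho-acceptor, a serine/threonine/tyrosine that carries the phosphate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

__all__ = [
    "AMINO_ACIDS",
    "ACCEPTOR_RESIDUES",
    "GAP",
    "MotifPattern",
    "MotifStructure",
    "MotifParseError",
    "parse_motif_pattern",
    "match_at",
    "scan_sequence",
    "classify_pattern",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ACCEPTOR_RESIDUES = frozenset("STY")
GAP = "-"

#: Wildcard marker inside ``MotifPattern.positions``.
WILDCARD = None


class MotifParseError(ValueError):
    """Raised when a motif pattern string cannot be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed positional motif.

    Parameters
    ----------
    motif_id:
        Label used in tables and outputs.
    raw:
        The original pattern text, e.g. ``"R-X-X-S/T"``.
    positions:
        One entry per motif position, in N→C order.  Each entry is either
        ``None`` (wildcard: any non-gap residue) or a non-empty frozenset of
        one-letter residue codes.
    acceptor_offset:
        0-based index into ``positions`` of the phospho-acceptor.
    """

    motif_id: str
    raw: str
    positions: tuple[Optional[frozenset[str]], ...]
    acceptor_offset: int

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise MotifParseError(f"{self.motif_id}: motif has no positions")
        if not 0 <= self.acceptor_offset < len(self.positions):
            raise MotifParseError(
                f"{self.motif_id}: acceptor offset {self.acceptor_offset} "
                f"outside pattern of length {len(self.positions)}"
            )
        acc = self.positions[self.acceptor_offset]
        if acc is WILDCARD or not acc or not acc <= ACCEPTOR_RESIDUES:
            raise MotifParseError(
                f"{self.motif_id}: acceptor position must be a non-empty "
                f"subset of S/T/Y, got {acc!r}"
            )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def acceptor_residues(self) -> frozenset[str]:
        rs = self.positions[self.acceptor_offset]
        assert rs is not None
        return rs

    def window_offsets(self) -> range:
        """Sequence offsets of the motif window relative to the acceptor."""
        return range(-self.acceptor_offset, len(self.positions) - self.acceptor_offset)


def _parse_token(token: str, motif_id: str) -> Optional[frozenset[str]]:
    if not token:
        raise MotifParseError(f"{motif_id}: empty token in pattern")
    if token.upper() == "X":
        return WILDCARD
    residues = set()
    for part in token.split("/"):
        part = part.strip().upper()
        if len(part) != 1 or part not in AMINO_ACIDS:
            raise MotifParseError(
                f"{motif_id}: unknown residue code {part!r} in token {token!r}"
            )
        residues.add(part)
    return frozenset(residues)


def parse_motif_pattern(
    text: str, motif_id: str = "", acceptor_index: Optional[int] = None
) -> MotifPattern:
    """Parse a pattern string such as ``"R-X-X-S/T"`` into a :class:`MotifPattern`.

    If *acceptor_index* is not given, the acceptor is the first position whose
    residue set is a non-empty subset of {S, T, Y}.  Parsing is
    case-insensitive.  Raises :class:`MotifParseError` for empty tokens,
    unknown residue letters, or when no acceptor can be identified.
    """
    motif_id = motif_id or text
    tokens = text.strip().split("-")
    positions = tuple(_parse_token(tok, motif_id) for tok in tokens)
    if acceptor_index is None:
        for i, rs in enumerate(positions):
            if rs is not WILDCARD and rs <= ACCEPTOR_RESIDUES:
                acceptor_index = i
                break
        else:
            raise MotifParseError(
                f"{motif_id}: no S/T/Y acceptor position found in {text!r}"
            )
    return MotifPattern(motif_id, text.strip(), positions, acceptor_index)


def match_at(pattern: MotifPattern, sequence: str, acceptor_pos: int) -> bool:
    """True iff *pattern* matches *sequence* with its acceptor at 1-based *acceptor_pos*.

    Every pattern position must fall inside the sequence, be a non-gap
    residue, and satisfy the position's residue set (wildcards accept any
    non-gap residue).  Windows running off either end return False.
    """
    start = acceptor_pos - 1 - pattern.acceptor_offset
    if start < 0 or start + len(pattern.positions) > len(sequence):
        return False
    for i, rs in enumerate(pattern.positions):
        ch = sequence[start + i]
        if ch == GAP:
            return False
        if rs is not WILDCARD and ch not in rs:
            return False
    return True


def scan_sequence(pattern: MotifPattern, sequence: str) -> list[int]:
    """All 1-based acceptor positions where *pattern* matches *sequence*, sorted."""
    acc = pattern.acceptor_residues
    return [
        p
        for p in range(1, len(sequence) + 1)
        if sequence[p - 1] in acc and match_at(pattern, sequence, p)
    ]


@dataclass(frozen=True)
class MotifStructure:
    """Structural flags of a motif relative to its acceptor.

    ``proline_directed``: proline immediately C-terminal of the acceptor
    (the S/T-P class).  ``basic_minus2/3/4``: arginine/lysine 2, 3, or 4
    positions N-terminal of the acceptor (the basophilic classes).
    """

    proline_directed: bool
    basic_minus2: bool
    basic_minus3: bool
    basic_minus4: bool

    @property
    def basic(self) -> bool:
        return self.basic_minus2 or self.basic_minus3 or self.basic_minus4


_BASIC = frozenset("RK")
_PRO = frozenset("P")


def classify_pattern(pattern: MotifPattern) -> MotifStructure:
    """Classify a motif as proline-directed and/or basophilic."""
    off = pattern.acceptor_offset
    pos = pattern.positions

    def _constrained(idx: int, allowed: frozenset[str]) -> bool:
        if not 0 <= idx < len(pos):
            return False
        rs = pos[idx]
        return rs is not WILDCARD and rs <= allowed

    return MotifStructure(
        proline_directed=_constrained(off + 1, _PRO),
        basic_minus2=_constrained(off - 2, _BASIC),
        basic_minus3=_constrained(off - 3, _BASIC),
        basic_minus4=_constrained(off - 4, _BASIC),
    )
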