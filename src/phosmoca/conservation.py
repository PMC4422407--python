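"""Conservation calls, rates, and the conservation index (CI).

The central statistic compares how often a motif's human phosphosites are
conserved in each non-human genome against the background conservation of
the acceptor residue type.  For a genome ``q``, the motif conservation rate
``C_q`` is the fraction of the motif's human sites whose motif window is
precisely matched in ``q`` through the ortholog-cluster alignment, and the
reference rate ``R_q`` is the corresponding fraction for single S/T/Y
residues across the phosphoprotein background.  The conservation index is

    CI = sum over genomes q of (C_q - R_q)

A positive CI means motif sites are retained above residue background; the
reference genome contributes exactly zero (C = R = 1 there).

Conservation is called by strict alignment-column matching: the ortholog's
residues in the alignment columns of the human motif window must all be
non-gap and satisfy the motif's residue sets.  An optional mode instead
re-matches the motif against the ortholog's degapped local window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .model import GenomeSet, OrthologFamily, Phosphosite
from .motifs import GAP, MotifPattern, match_at

__all__ = [
    "match_sites",
    "ungapped_to_column",
    "column_to_ungapped",
    "FamilyIndex",
    "index_families",
    "ConservationCall",
    "ConservationProfile",
    "ReferenceRates",
    "CIRecord",
    "UndefinedRateError",
    "call_site_conservation",
    "motif_conservation_rates",
    "site_set_conservation",
    "reference_rates",
    "conservation_index",
    "single_residue_pattern",
]

log = logging.getLogger(__name__)

CONSERVED = "conserved"
NOT_CONSERVED = "not_conserved"
NO_ORTHOLOG = "no_ortholog"

Denominator = Literal["all", "aligned_only"]
Rematch = Literal["strict_columns", "degapped_window"]


class UndefinedRateError(ValueError):
    """A conservation rate was requested for an empty site set."""


def match_sites(
    pattern: MotifPattern,
    sites: Sequence[Phosphosite],
    sequences: Mapping[str, str],
) -> list[Phosphosite]:
    """Filter *sites* to those whose human window matches *pattern*.

    Sites of proteins absent from *sequences* are dropped (they cannot be
    matched).
    """
    out = []
    for s in sites:
        seq = sequences.get(s.protein_id)
        if seq is not None and match_at(pattern, seq, s.position):
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# alignment coordinate mapping

def ungapped_to_column(aligned_row: str, position: int) -> int:
    """1-based alignment column holding the *position*-th non-gap residue."""
    if position < 1:
        raise IndexError(f"ungapped position must be >= 1, got {position}")
    seen = 0
    for col, ch in enumerate(aligned_row, start=1):
        if ch != GAP:
            seen += 1
            if seen == position:
                return col
    raise IndexError(
        f"ungapped position {position} exceeds ungapped length {seen}"
    )


def column_to_ungapped(aligned_row: str, column: int) -> int:
    """1-based ungapped position of the residue in *column* (error on a gap)."""
    if not 1 <= column <= len(aligned_row):
        raise IndexError(f"column {column} outside alignment of length {len(aligned_row)}")
    if aligned_row[column - 1] == GAP:
        raise IndexError(f"column {column} is a gap")
    return sum(1 for ch in aligned_row[:column] if ch != GAP)


def _position_columns(aligned_row: str) -> np.ndarray:
    """0-based column index of each ungapped position (vectorised map)."""
    arr = np.frombuffer(aligned_row.encode("ascii"), dtype="S1")
    return np.flatnonzero(arr != GAP.encode("ascii"))


# ---------------------------------------------------------------------------
# family index (reference protein -> its ortholog family)

@dataclass
class _Entry:
    family: OrthologFamily
    row: str                     # the reference member's aligned row
    sequence: str                # its ungapped sequence
    pos_cols: np.ndarray         # ungapped position (0-based) -> column (0-based)


class FamilyIndex:
    """Maps each reference-genome protein to the ortholog family used for it.

    A protein present in several clusters is assigned the cluster covering
    the most genomes, ties broken by lexicographic cluster id.
    """

    def __init__(self, genomes: GenomeSet):
        self.genomes = genomes
        self._entries: dict[str, _Entry] = {}

    def add_family(self, family: OrthologFamily) -> None:
        for protein_id, row in family.rows_for(self.genomes.reference):
            old = self._entries.get(protein_id)
            if old is not None:
                better = (family.n_genomes(), ) > (old.family.n_genomes(), ) or (
                    family.n_genomes() == old.family.n_genomes()
                    and family.cluster_id < old.family.cluster_id
                )
                if not better:
                    continue
                log.info(
                    "protein %s in clusters %s and %s; keeping %s",
                    protein_id, old.family.cluster_id, family.cluster_id,
                    family.cluster_id if better else old.family.cluster_id,
                )
            self._entries[protein_id] = _Entry(
                family=family,
                row=row,
                sequence=OrthologFamily.ungap(row),
                pos_cols=_position_columns(row),
            )

    def get(self, protein_id: str) -> Optional[_Entry]:
        return self._entries.get(protein_id)

    def sequence(self, protein_id: str) -> Optional[str]:
        e = self._entries.get(protein_id)
        return e.sequence if e else None

    def sequences(self) -> dict[str, str]:
        return {pid: e.sequence for pid, e in self._entries.items()}

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)


def index_families(
    families: Iterable[OrthologFamily], genomes: GenomeSet
) -> FamilyIndex:
    index = FamilyIndex(genomes)
    for fam in families:
        index.add_family(fam)
    return index


# ---------------------------------------------------------------------------
# conservation calls

@dataclass(frozen=True)
class ConservationCall:
    site: Phosphosite
    genome: str
    verdict: str  # conserved | not_conserved | no_ortholog


def _window_columns(entry: _Entry, site: Phosphosite, pattern: MotifPattern) -> np.ndarray:
    """0-based alignment columns of the human motif window around *site*."""
    start = site.position - 1 - pattern.acceptor_offset
    stop = start + len(pattern.positions)
    if start < 0 or stop > len(entry.sequence):
        raise ValueError(
            f"{site.protein_id}:{site.position}: motif window [{start + 1}, {stop}] "
            f"outside sequence of length {len(entry.sequence)}"
        )
    return entry.pos_cols[start:stop]


def _ortholog_matches(
    row: str, cols: np.ndarray, pattern: MotifPattern, rematch: Rematch
) -> bool:
    if rematch == "strict_columns":
        for rs, c in zip(pattern.positions, cols):
            ch = row[c]
            if ch == GAP or (rs is not None and ch not in rs):
                return False
        return True
    # degapped_window: re-match the motif against the ortholog's local window,
    # anchored at the residue aligned to the human acceptor column.
    acc_col = int(cols[pattern.acceptor_offset])
    if row[acc_col] == GAP:
        return False
    pos = column_to_ungapped(row, acc_col + 1)
    return match_at(pattern, OrthologFamily.ungap(row), pos)


def call_site_conservation(
    family: OrthologFamily,
    human_member: str,
    site: Phosphosite,
    pattern: MotifPattern,
    genome: str,
    genomes: GenomeSet = GenomeSet(),
    rematch: Rematch = "strict_columns",
) -> ConservationCall:
    """Call conservation of one human motif site in one genome.

    The human member's window must match the pattern (error otherwise).  The
    verdict is ``conserved`` if ANY member of *genome* satisfies the motif at
    the human window's alignment columns, ``no_ortholog`` if the genome has
    no member in the family.
    """
    row = family.row_of(genomes.reference, human_member)
    entry = _Entry(family, row, OrthologFamily.ungap(row), _position_columns(row))
    if not match_at(pattern, entry.sequence, site.position):
        raise ValueError(
            f"{human_member}:{site.position}: human window does not match "
            f"motif {pattern.motif_id}"
        )
    if genome == genomes.reference:
        return ConservationCall(site, genome, CONSERVED)
    members = family.rows_for(genome)
    if not members:
        return ConservationCall(site, genome, NO_ORTHOLOG)
    cols = _window_columns(entry, site, pattern)
    for _, orow in members:
        if _ortholog_matches(orow, cols, pattern, rematch):
            return ConservationCall(site, genome, CONSERVED)
    return ConservationCall(site, genome, NOT_CONSERVED)


# ---------------------------------------------------------------------------
# rates

@dataclass
class ConservationProfile:
    """Per-genome conservation counts and rates for one motif × site class."""

    motif_id: str
    site_class: str
    n_sites: int
    conserved: dict[str, int]
    denominator: dict[str, int]

    def rate(self, genome: str) -> float:
        den = self.denominator[genome]
        if den == 0:
            raise UndefinedRateError(
                f"{self.motif_id}/{self.site_class}: empty denominator for {genome}"
            )
        return self.conserved[genome] / den

    @property
    def rates(self) -> dict[str, float]:
        return {g: self.rate(g) for g in self.denominator}


_STY = ("S", "T", "Y")

_SINGLE_CACHE: dict[str, MotifPattern] = {}


def single_residue_pattern(residue: str) -> MotifPattern:
    """A one-position motif matching exactly *residue* (acceptor-only matching)."""
    if residue not in _SINGLE_CACHE:
        _SINGLE_CACHE[residue] = MotifPattern(
            motif_id=f"residue:{residue}",
            raw=residue,
            positions=(frozenset({residue}),),
            acceptor_offset=0,
        )
    return _SINGLE_CACHE[residue]


def _accumulate_conservation(
    index: FamilyIndex,
    site_patterns: Sequence[tuple[Phosphosite, MotifPattern]],
    genomes: GenomeSet,
    denominator: Denominator,
    rematch: Rematch,
    per_site: Optional[list[ConservationCall]] = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Shared counting loop.

    A site whose protein has no ortholog family at all stays in every
    denominator and counts as not conserved under ``denominator='all'``;
    under ``'aligned_only'`` a site leaves genome q's denominator whenever q
    lacks an ortholog (including the no-family case).
    """
    ref = genomes.reference
    conserved = {g: 0 for g in genomes}
    denom = {g: 0 for g in genomes}
    n = len(site_patterns)
    conserved[ref] = denom[ref] = n

    for site, pattern in site_patterns:
        entry = index.get(site.protein_id)
        if entry is None:
            for q in genomes.non_reference:
                if denominator == "all":
                    denom[q] += 1
                if per_site is not None:
                    per_site.append(ConservationCall(site, q, NO_ORTHOLOG))
            continue
        if not match_at(pattern, entry.sequence, site.position):
            raise ValueError(
                f"{site.protein_id}:{site.position}: human window does not "
                f"match motif {pattern.motif_id}"
            )
        cols = _window_columns(entry, site, pattern)
        for q in genomes.non_reference:
            members = entry.family.rows_for(q)
            if not members:
                if denominator == "all":
                    denom[q] += 1
                if per_site is not None:
                    per_site.append(ConservationCall(site, q, NO_ORTHOLOG))
                continue
            denom[q] += 1
            hit = any(
                _ortholog_matches(row, cols, pattern, rematch) for _, row in members
            )
            if hit:
                conserved[q] += 1
            if per_site is not None:
                per_site.append(
                    ConservationCall(site, q, CONSERVED if hit else NOT_CONSERVED)
                )
    return conserved, denom


def motif_conservation_rates(
    index: FamilyIndex,
    sites: Sequence[Phosphosite],
    pattern: MotifPattern,
    genomes: GenomeSet,
    site_class: str = "known",
    denominator: Denominator = "all",
    rematch: Rematch = "strict_columns",
    calls_out: Optional[list[ConservationCall]] = None,
) -> ConservationProfile:
    """Per-genome motif conservation rates C_q over motif-matching human sites.

    *sites* must already be filtered to those whose human window matches
    *pattern*.  Raises :class:`UndefinedRateError` on an empty site list.
    """
    if not sites:
        raise UndefinedRateError(f"{pattern.motif_id}: no sites; rate undefined")
    conserved, denom = _accumulate_conservation(
        index, [(s, pattern) for s in sites], genomes, denominator, rematch, calls_out
    )
    return ConservationProfile(
        motif_id=pattern.motif_id,
        site_class=site_class,
        n_sites=len(sites),
        conserved=conserved,
        denominator=denom,
    )


def site_set_conservation(
    index: FamilyIndex,
    sites: Sequence[Phosphosite],
    genomes: GenomeSet,
    label: str = "site_set",
    site_class: str = "known",
    denominator: Denominator = "all",
) -> ConservationProfile:
    """Conservation of an arbitrary site set with acceptor-residue-only matching.

    Each site is evaluated as a one-residue motif of its own residue type;
    used for kinase-group substrate pools, where sites of many motifs mix.
    """
    if not sites:
        raise UndefinedRateError(f"{label}: no sites; rate undefined")
    pairs = [(s, single_residue_pattern(s.residue)) for s in sites]
    conserved, denom = _accumulate_conservation(
        index, pairs, genomes, denominator, "strict_columns"
    )
    return ConservationProfile(label, site_class, len(sites), conserved, denom)


@dataclass
class ReferenceRates:
    """Background conservation R_q per genome and acceptor residue type."""

    conserved: dict[tuple[str, str], int]
    denominator: dict[tuple[str, str], int]
    genomes: GenomeSet

    def available(self, residue: str) -> bool:
        return any(self.denominator.get((q, residue), 0) > 0 for q in self.genomes)

    def rate(self, genome: str, residue: str) -> float:
        den = self.denominator.get((genome, residue), 0)
        if den == 0:
            raise UndefinedRateError(
                f"reference rate unavailable for genome {genome}, residue {residue}"
            )
        return self.conserved[(genome, residue)] / den


def reference_rates(
    index: FamilyIndex,
    background_sites: Sequence[Phosphosite],
    genomes: GenomeSet,
    denominator: Denominator = "all",
) -> ReferenceRates:
    """Background conservation rates of single S/T/Y residues.

    *background_sites* are all STY residues of the phosphoprotein set; each
    residue type is scored as a one-residue motif under the same gap and
    missing-ortholog rules as motif conservation.  A residue type with no
    background sites is flagged unavailable (rate lookups then raise).
    """
    conserved: dict[tuple[str, str], int] = {}
    denom: dict[tuple[str, str], int] = {}
    for r in _STY:
        subset = [s for s in background_sites if s.residue == r]
        if not subset:
            log.warning("no background sites of type %s; rate unavailable", r)
            continue
        c, d = _accumulate_conservation(
            index,
            [(s, single_residue_pattern(r)) for s in subset],
            genomes,
            denominator,
            "strict_columns",
        )
        for q in genomes:
            conserved[(q, r)] = c[q]
            denom[(q, r)] = d[q]
    return ReferenceRates(conserved, denom, genomes)


# ---------------------------------------------------------------------------
# the conservation index

@dataclass
class CIRecord:
    """CI value with its per-genome (C_q − R_q) terms."""

    motif_id: str
    site_class: str
    ci: float
    terms: dict[str, float]
    c_rates: dict[str, float]
    r_rates: dict[str, float]
    n_sites: int = 0

    def __post_init__(self) -> None:
        assert abs(self.ci - sum(self.terms.values())) < 1e-9


def conservation_index(
    profile: ConservationProfile,
    refs: ReferenceRates,
    acceptor_mix: Mapping[str, int],
) -> CIRecord:
    """CI = Σ_q (C_q − R_q) with a count-weighted motif-level reference rate.

    *acceptor_mix* gives the motif's human site counts per acceptor residue
    type; the motif-level R_q is the count-weighted mixture of the per-type
    background rates, so an S/T-ambiguous acceptor draws its reference from
    the motif's actual residue composition.
    """
    total = sum(acceptor_mix.values())
    if total <= 0:
        raise UndefinedRateError(f"{profile.motif_id}: empty acceptor mix")
    weights = {r: n / total for r, n in acceptor_mix.items() if n > 0}
    genomes = refs.genomes
    terms: dict[str, float] = {}
    c_rates: dict[str, float] = {}
    r_rates: dict[str, float] = {}
    for q in genomes:
        if q not in profile.denominator:
            raise UndefinedRateError(
                f"{profile.motif_id}: genome {q} missing from profile"
            )
        c_q = profile.rate(q)
        r_q = sum(w * refs.rate(q, r) for r, w in weights.items())
        c_rates[q] = c_q
        r_rates[q] = r_q
        terms[q] = c_q - r_q
    return CIRecord(
        motif_id=profile.motif_id,
        site_class=profile.site_class,
        ci=sum(terms.values()),
        terms=terms,
        c_rates=c_rates,
        r_rates=r_rates,
        n_sites=profile.n_sites,
    )
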