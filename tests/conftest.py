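"""Shared fixtures and independent brute-force oracles.

The oracle functions re-derive conservation calls, rates, and the CI by
direct iteration over alignment characters — no shared code with the
package's vectorised implementation — so equivalence tests genuinely
cross-check two routes.
"""

from __future__ import annotations

import pytest

from phosmoca import GenomeSet, SimConfig, parse_motif_pattern, simulate_families
from phosmoca.model import KNOWN


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def stp():
    return parse_motif_pattern("S/T-P", "stp")


@pytest.fixture(scope="session")
def rxxst():
    return parse_motif_pattern("R-X-X-S/T", "rxxst")


@pytest.fixture(scope="session")
def genomes():
    return GenomeSet()


@pytest.fixture(scope="session")
def small_sim(stp, rxxst):
    """Fifteen families with two planted motifs, indels, mixed labels."""
    cfg = SimConfig(
        seed=20240611,
        n_families=15,
        length_range=(120, 200),
        motifs=(stp, rxxst),
        sites_per_protein=1,
        p_bg=0.5,
        p_mot=0.8,
        known_rate=0.8,
        indel_rate=0.4,
        loss_prob=0.1,
    )
    return simulate_families(cfg)


# ---------------------------------------------------------------------------
# brute-force oracles (string-walking, no numpy, no shared helpers)

GAP = "-"


def bf_ungapped_to_col0(row: str, pos: int) -> int:
    """0-based column of the pos-th (1-based) non-gap character."""
    seen = 0
    for i, ch in enumerate(row):
        if ch != GAP:
            seen += 1
            if seen == pos:
                return i
    raise IndexError(pos)


def bf_verdict(family, reference, human_pid, position, pattern, genome) -> str:
    """Re-derive one conservation call by walking alignment strings."""
    hrow = dict(family.members[reference])[human_pid]
    cols = [
        bf_ungapped_to_col0(hrow, position + off) for off in pattern.window_offsets()
    ]
    members = family.members.get(genome, [])
    if not members:
        return "no_ortholog"
    for _, row in members:
        ok = True
        for rs, c in zip(pattern.positions, cols):
            ch = row[c]
            if ch == GAP or (rs is not None and ch not in rs):
                ok = False
                break
        if ok:
            return "conserved"
    return "not_conserved"


def bf_pick_family(families, reference, protein_id):
    """Most-genomes family holding the protein, ties by cluster id."""
    best = None
    for fam in families:
        if protein_id in dict(fam.members.get(reference, [])):
            key = (-len(fam.members), fam.cluster_id)
            if best is None or key < best[0]:
                best = (key, fam)
    return best[1] if best else None


def bf_rates(families, sites, pattern, gset):
    """Per-genome conservation rate of motif-matching sites, D1 rule."""
    rates = {}
    for q in gset.codes:
        if q == gset.reference:
            rates[q] = 1.0
            continue
        hit = 0
        for s in sites:
            fam = bf_pick_family(families, gset.reference, s.protein_id)
            if fam is None:
                continue
            if bf_verdict(fam, gset.reference, s.protein_id, s.position, pattern, q) == "conserved":
                hit += 1
        rates[q] = hit / len(sites)
    return rates


def bf_reference_rates(families, background, gset):
    """Single-residue background rates per genome and residue type."""
    out = {}
    for r in "STY":
        subset = [s for s in background if s.residue == r]
        if not subset:
            continue
        pat = parse_motif_pattern(r, f"bf:{r}")
        for q, rate in bf_rates(families, subset, pat, gset).items():
            out[(q, r)] = rate
    return out


def bf_ci(c_rates, ref_rates, mix, gset) -> float:
    """Independently coded sum of (C_q − R_q) with mixture weights."""
    total = sum(mix.values())
    ci = 0.0
    for q in gset.codes:
        r_q = sum((n / total) * ref_rates[(q, r)] for r, n in mix.items())
        ci += c_rates[q] - r_q
    return ci


def known_sites_of(result, motif_id):
    return [s for m, s in result.truth.planted if m == motif_id and s.status == KNOWN]
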