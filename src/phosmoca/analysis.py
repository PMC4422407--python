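"""Derived analyses over conservation indices, kinases, annotations, networks.

Covers the study's downstream comparisons: known-vs-potential CI pairing,
CI-rank binning by motif structure, kinase group/family substrate fractions,
kinase-group substrate CIs, kinome expansion across genomes, hypergeometric
term enrichment with Benjamini–Hochberg control, and a permutation statistic
for motif-sharing interaction subnetworks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .conservation import (
    CIRecord,
    FamilyIndex,
    ReferenceRates,
    conservation_index,
    site_set_conservation,
)
from .model import (
    GenomeSet,
    InteractionEdge,
    KinaseRecord,
    KinaseSubstrateEdge,
    Phosphosite,
)
from .motifs import MotifStructure

__all__ = [
    "ComparisonResult",
    "compare_known_vs_potential",
    "CIBin",
    "bin_ci_distribution",
    "KinaseFractionResult",
    "kinase_fractions",
    "kinase_group_substrate_ci",
    "kinase_expansion_table",
    "EnrichmentResult",
    "term_enrichment",
    "NetworkStatistic",
    "motif_network_statistic",
]

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# known vs potential CI comparison

@dataclass
class ComparisonResult:
    """Paired CI table with its Pearson correlation and diagonal tallies."""

    table: pd.DataFrame  # motif_id, ci_known, ci_potential
    pearson_r: Optional[float]
    n_above: int   # known CI > potential CI (above the y = x line)
    n_below: int
    n_on: int

    @property
    def n_pairs(self) -> int:
        return len(self.table)


def compare_known_vs_potential(
    ci_known: Iterable[CIRecord], ci_potential: Iterable[CIRecord]
) -> ComparisonResult:
    """Pair motif CIs of known sites against those of all STY residues.

    The Pearson correlation is computed over motifs present in both sets;
    with fewer than 3 pairs it is flagged unavailable (None).
    """
    known = {r.motif_id: r.ci for r in ci_known}
    pot = {r.motif_id: r.ci for r in ci_potential}
    shared = sorted(known.keys() & pot.keys())
    if not shared:
        raise ValueError("no motifs shared between known and potential CI sets")
    table = pd.DataFrame(
        {
            "motif_id": shared,
            "ci_known": [known[m] for m in shared],
            "ci_potential": [pot[m] for m in shared],
        }
    )
    diff = table["ci_known"] - table["ci_potential"]
    if len(shared) >= 3:
        r = float(stats.pearsonr(table["ci_known"], table["ci_potential"])[0])
    else:
        log.warning("only %d paired motifs; correlation unavailable", len(shared))
        r = None
    return ComparisonResult(
        table=table,
        pearson_r=r,
        n_above=int((diff > 0).sum()),
        n_below=int((diff < 0).sum()),
        n_on=int((diff == 0).sum()),
    )


# ---------------------------------------------------------------------------
# CI-rank binning

@dataclass
class CIBin:
    """One rank class of the CI-ordered motif list."""

    index: int
    motif_ids: list[str]
    mean_ci: float
    n_proline_directed: int
    n_basic: int


def bin_ci_distribution(
    ci_records: Sequence[CIRecord],
    structures: Mapping[str, MotifStructure],
    class_size: int = 10,
) -> list[CIBin]:
    """Chunk motifs ordered by descending CI into successive rank classes.

    Each class holds *class_size* motifs (the last may be smaller) and counts
    its proline-directed and basophilic members.  Ties in CI are broken by
    motif id so the binning is deterministic.
    """
    missing = [r.motif_id for r in ci_records if r.motif_id not in structures]
    if missing:
        raise KeyError(f"motifs without a structural classification: {missing}")
    ranked = sorted(ci_records, key=lambda r: (-r.ci, r.motif_id))
    bins = []
    for b, start in enumerate(range(0, len(ranked), class_size)):
        chunk = ranked[start : start + class_size]
        ids = [r.motif_id for r in chunk]
        bins.append(
            CIBin(
                index=b,
                motif_ids=ids,
                mean_ci=float(np.mean([r.ci for r in chunk])),
                n_proline_directed=sum(
                    structures[m].proline_directed for m in ids
                ),
                n_basic=sum(structures[m].basic for m in ids),
            )
        )
    return bins


# ---------------------------------------------------------------------------
# kinase fractions (Table-1 style)

@dataclass
class KinaseFractionResult:
    """Top classification fractions among a motif's kinase-substrate edges."""

    level: str                   # "group" or "family"
    table: pd.DataFrame          # label, count, fraction (descending)
    n_edges: int
    n_substrates: int            # distinct substrate proteins


def kinase_fractions(
    edges: Sequence[KinaseSubstrateEdge],
    kinases: Mapping[str, KinaseRecord],
    level: str = "group",
    top_k: int = 3,
    unit: str = "edges",
) -> KinaseFractionResult:
    """Fractions of kinase groups (or families) among a motif's substrate edges.

    The counting unit is kinase-substrate EDGES by default; ``unit='proteins'``
    counts distinct (label, substrate) pairs instead.  Kinases without a
    classification fall under ``unclassified`` with a warning.  An empty edge
    set is an error, never a silent zero table.
    """
    if level not in ("group", "family"):
        raise ValueError(f"level must be 'group' or 'family', got {level!r}")
    if not edges:
        raise ValueError("no kinase-substrate edges for this motif")

    def _label(e: KinaseSubstrateEdge) -> str:
        rec = kinases.get(e.kinase_id)
        if rec is None:
            log.warning("kinase %s has no classification record", e.kinase_id)
            return UNCLASSIFIED
        lab = rec.group if level == "group" else rec.family
        return lab or UNCLASSIFIED

    if unit == "edges":
        counts: dict[str, int] = {}
        for e in edges:
            lab = _label(e)
            counts[lab] = counts.get(lab, 0) + 1
        total = len(edges)
    elif unit == "proteins":
        pairs = {(_label(e), e.protein_id) for e in edges}
        counts = {}
        for lab, _ in pairs:
            counts[lab] = counts.get(lab, 0) + 1
        total = len(pairs)
    else:
        raise ValueError(f"unit must be 'edges' or 'proteins', got {unit!r}")

    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["label", "count"],
    )
    table["fraction"] = table["count"] / total
    return KinaseFractionResult(
        level=level,
        table=table.head(top_k).reset_index(drop=True),
        n_edges=len(edges),
        n_substrates=len({e.protein_id for e in edges}),
    )


# ---------------------------------------------------------------------------
# kinase-group substrate CI (Fig-3A style)

def kinase_group_substrate_ci(
    edges: Sequence[KinaseSubstrateEdge],
    kinases: Mapping[str, KinaseRecord],
    site_index: Mapping[tuple[str, int], Phosphosite],
    index: FamilyIndex,
    refs: ReferenceRates,
    genomes: GenomeSet,
    min_sites: int = 10,
) -> tuple[dict[str, CIRecord], dict[str, bool]]:
    """CI of each kinase group's pooled substrate sites.

    Substrate sites are resolved against the phosphosite table and scored
    with acceptor-residue-only matching (a site set, not a motif).  Returns
    ``(records, low_support)`` where low_support flags groups with fewer
    than *min_sites* resolvable sites; groups with none are omitted with a
    warning.  The CI is a function of the substrate site set only.
    """
    pools: dict[str, dict[tuple[str, int], Phosphosite]] = {}
    seen_groups: set[str] = set()
    for e in edges:
        rec = kinases.get(e.kinase_id)
        group = rec.group if rec else UNCLASSIFIED
        seen_groups.add(group)
        site = site_index.get((e.protein_id, e.position))
        if site is None:
            continue
        pools.setdefault(group, {})[(site.protein_id, site.position)] = site
    for group in sorted(seen_groups - set(pools)):
        log.warning("kinase group %s: no resolvable substrate sites; omitted", group)

    records: dict[str, CIRecord] = {}
    low_support: dict[str, bool] = {}
    for group in sorted(pools):
        sites = [pools[group][k] for k in sorted(pools[group])]
        if not sites:
            log.warning("kinase group %s: no resolvable substrate sites; omitted", group)
            continue
        profile = site_set_conservation(
            index, sites, genomes, label=group, site_class="substrates"
        )
        mix: dict[str, int] = {}
        for s in sites:
            mix[s.residue] = mix.get(s.residue, 0) + 1
        records[group] = conservation_index(profile, refs, mix)
        low_support[group] = len(sites) < min_sites
    return records, low_support


# ---------------------------------------------------------------------------
# kinome expansion (Fig-3B style)

def kinase_expansion_table(
    kinases: Sequence[KinaseRecord], genomes: GenomeSet
) -> pd.DataFrame:
    """Per-genome kinase totals and group fractions.

    For each genome: the number of kinases present and, per group, that
    group's fraction of the genome's kinase complement.
    """
    rows = []
    groups = sorted({k.group for k in kinases})
    for g in genomes:
        present = [k for k in kinases if k.present_in(g)]
        total = len(present)
        for grp in groups:
            count = sum(1 for k in present if k.group == grp)
            rows.append(
                {
                    "genome": g,
                    "group": grp,
                    "count": count,
                    "fraction": count / total if total else 0.0,
                    "total": total,
                }
            )
    return pd.DataFrame(rows, columns=["genome", "group", "count", "fraction", "total"])


# ---------------------------------------------------------------------------
# term enrichment

@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int
    background_size: int
    term_size: int
    p_value: float
    fdr: float
    significant: bool


def term_enrichment(
    motif_proteins: Iterable[str],
    annotations: pd.DataFrame,
    background: Iterable[str],
    alpha_p: float = 0.01,
    alpha_fdr: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of terms in a motif's protein set.

    For each term the upper-tail hypergeometric p-value of the overlap is
    computed given (background size, term size, set size), then adjusted
    across terms with Benjamini–Hochberg.  A term is significant when both
    raw p < *alpha_p* and FDR < *alpha_fdr*.  Terms with no annotated
    protein in the background are skipped with a warning.
    """
    background = set(background)
    motif_proteins = set(motif_proteins)
    if not motif_proteins <= background:
        raise ValueError("motif protein set must be a subset of the background")
    M, N = len(background), len(motif_proteins)

    term_members: dict[str, set[str]] = {}
    for rec in annotations.itertuples(index=False):
        term_members.setdefault(rec.term, set()).add(rec.protein_id)

    rows = []
    for term in sorted(term_members):
        members = term_members[term] & background
        if not members:
            log.warning("term %s has no annotated protein in background; skipped", term)
            continue
        K = len(members)
        k = len(members & motif_proteins)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((term, k, K, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term,
            overlap=k,
            set_size=N,
            background_size=M,
            term_size=K,
            p_value=p,
            fdr=float(q),
            significant=bool(p < alpha_p and q < alpha_fdr),
        )
        for (term, k, K, p), q in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


# ---------------------------------------------------------------------------
# motif-sharing network statistic

@dataclass
class NetworkStatistic:
    observed: int
    p_value: float
    n_perm: int
    subnetwork: list[InteractionEdge]


def motif_network_statistic(
    interactions: Sequence[InteractionEdge],
    motif_proteins: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
    degree_preserving: bool = False,
) -> NetworkStatistic:
    """Permutation test for excess interactions among same-motif proteins.

    ``observed`` counts edges with both endpoints in the motif set.  The
    null resamples node sets of the same size uniformly without replacement
    from the network's nodes (or degree-weighted when *degree_preserving*),
    and p = (1 + #{null >= observed}) / (1 + n_perm).  The same-motif
    subnetwork edge list is returned alongside.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    nodes = sorted({p for e in interactions for p in (e.protein_a, e.protein_b)})
    motif_set = set(motif_proteins)
    if not motif_set <= set(nodes):
        raise ValueError("motif protein set contains nodes absent from the network")
    if len(motif_set) > len(nodes):
        raise ValueError("motif set larger than the network's node set")

    def _inside(members: set[str]) -> int:
        return sum(1 for e in interactions if e.protein_a in members and e.protein_b in members)

    observed = _inside(motif_set)
    subnetwork = [
        e for e in interactions if e.protein_a in motif_set and e.protein_b in motif_set
    ]

    rng = np.random.default_rng(seed)
    node_arr = np.array(nodes)
    if degree_preserving:
        deg = {n: 0 for n in nodes}
        for e in interactions:
            deg[e.protein_a] += 1
            deg[e.protein_b] += 1
        weights = np.array([deg[n] for n in nodes], dtype=float)
        weights /= weights.sum()
    else:
        weights = None
    k = len(motif_set)
    exceed = 0
    for _ in range(n_perm):
        sample = set(rng.choice(node_arr, size=k, replace=False, p=weights))
        if _inside(sample) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return NetworkStatistic(
        observed=observed, p_value=p, n_perm=n_perm, subnetwork=subnetwork
    )
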