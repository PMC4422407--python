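"""Synthetic ortholog families and study tables with planted ground truth.

The generator emulates the study's inputs: ortholog clusters over the nine
genomes with one MAFFT-style alignment each, known/potential phosphosite
labels, kinase-substrate edges with chosen group composition, interaction
networks, and protein→term annotations.  Human sequences are drawn with
uniform residue frequencies; motif windows are planted at a configured rate
and each planted window is conserved in an ortholog as a single Bernoulli
event with probability ``p_mot`` (conserved windows are copied verbatim;
non-conserved windows get a non-S/T/Y residue at the acceptor, which
guarantees both a motif mismatch and an acceptor-residue mismatch).  All
other positions are retained independently with the background probability
``p_bg``, else substituted by a uniformly chosen different residue.

Because planted acceptors and in-window S/T/Y residues conserve at
motif-level rates, the background reference rate is a mixture; the returned
:class:`SimTruth` computes the exact expected CI in closed form from the
realized sequence composition, alongside the ideal value
``sum_q (p_mot(q) - p_bg(q))`` that holds in the no-contamination limit.

Everything is reproducible from the mandatory seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model import (
    KNOWN,
    POTENTIAL,
    GenomeSet,
    InteractionEdge,
    KinaseRecord,
    KinaseSubstrateEdge,
    OrthologFamily,
    Phosphosite,
)
from .motifs import ACCEPTOR_RESIDUES, MotifPattern

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_families",
    "simulate_kinase_data",
    "simulate_interactions",
    "simulate_annotations",
]

log = logging.getLogger(__name__)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_STY_IDX = np.array([_AA_INDEX[r] for r in "STY"])
_NON_STY_IDX = np.array([i for i, a in enumerate(_AA) if a not in "STY"])

ProbLike = Union[float, Mapping[str, float]]


def _per_genome(value: ProbLike, genomes: GenomeSet, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        probs = {q: float(value[q]) for q in genomes.non_reference}
    else:
        probs = {q: float(value) for q in genomes.non_reference}
    for q, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}[{q}] = {p} outside [0, 1]")
    return probs


@dataclass
class SimConfig:
    """Study conditions for the ortholog-family generator.

    ``p_mot`` governs known-labeled planted sites, ``p_mot_potential``
    (default: same as ``p_mot``) the planted sites labeled potential, and
    ``p_bg`` every other position.  ``loss_prob`` removes a genome from a
    family entirely (ortholog loss).  ``known_rate`` is the probability a
    planted acceptor is labeled a known phosphosite.  ``indel_rate`` is the
    per-genome chance of one insertion block per family, placed strictly
    outside planted motif windows so planted truth is never disturbed.
    """

    seed: int
    n_families: int = 50
    length_range: tuple[int, int] = (200, 400)
    genomes: GenomeSet = field(default_factory=GenomeSet)
    motifs: tuple[MotifPattern, ...] = ()
    sites_per_protein: int = 1
    p_bg: ProbLike = 0.5
    p_mot: ProbLike = 0.8
    p_mot_potential: Optional[ProbLike] = None
    loss_prob: ProbLike = 0.0
    known_rate: float = 1.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (no implicit entropy)")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length range {self.length_range}")
        for m in self.motifs:
            if len(m) > lo:
                raise ValueError(
                    f"motif {m.motif_id} (length {len(m)}) exceeds minimum "
                    f"protein length {lo}"
                )
        if not 0.0 <= self.known_rate <= 1.0:
            raise ValueError(f"known_rate {self.known_rate} outside [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError(f"indel_rate {self.indel_rate} outside [0, 1]")

    def bg(self) -> dict[str, float]:
        return _per_genome(self.p_bg, self.genomes, "p_bg")

    def mot_known(self) -> dict[str, float]:
        return _per_genome(self.p_mot, self.genomes, "p_mot")

    def mot_potential(self) -> dict[str, float]:
        src = self.p_mot if self.p_mot_potential is None else self.p_mot_potential
        return _per_genome(src, self.genomes, "p_mot_potential")

    def loss(self) -> dict[str, float]:
        return _per_genome(self.loss_prob, self.genomes, "loss_prob")


@dataclass
class SimTruth:
    """Planted parameters plus exact closed-form expectations.

    Composition counts are per acceptor residue type r: ``n_bg[r]`` plain
    background STY residues (including wildcard positions inside planted
    windows, which follow the background process), ``n_acc[(motif, status,
    r)]`` planted acceptors, and ``n_win[(status, r)]`` STY residues at
    constrained non-acceptor window positions (these are retained on the
    window-conservation event or, failing that, at background).
    """

    config: SimConfig
    planted: list[tuple[str, Phosphosite]]  # (motif_id, site)
    n_bg: dict[str, int]
    n_acc: dict[tuple[str, str, str], int]
    n_win: dict[tuple[str, str], int]

    # -- expectations under denominator='all' ------------------------------

    def expected_c(self, motif_id: str, status: str = KNOWN) -> dict[str, float]:
        cfg = self.config
        p = cfg.mot_known() if status == KNOWN else cfg.mot_potential()
        loss = cfg.loss()
        return {q: (1.0 - loss[q]) * p[q] for q in cfg.genomes.non_reference}

    def expected_r(self) -> dict[tuple[str, str], float]:
        """Exact expected background rate per (genome, residue type)."""
        cfg = self.config
        bg, loss = cfg.bg(), cfg.loss()
        pk, pp = cfg.mot_known(), cfg.mot_potential()
        out: dict[tuple[str, str], float] = {}
        for q in cfg.genomes.non_reference:
            scale = 1.0 - loss[q]
            for r in "STY":
                num = self.n_bg.get(r, 0) * bg[q]
                den = self.n_bg.get(r, 0)
                for (mid, status, rr), n in self.n_acc.items():
                    if rr != r:
                        continue
                    p = pk[q] if status == KNOWN else pp[q]
                    num += n * p
                    den += n
                for (status, rr), n in self.n_win.items():
                    if rr != r:
                        continue
                    p = pk[q] if status == KNOWN else pp[q]
                    num += n * (p + (1.0 - p) * bg[q])
                    den += n
                out[(q, r)] = scale * num / den if den else float("nan")
        return out

    def acceptor_mix(self, motif_id: str, status: str = KNOWN) -> dict[str, int]:
        mix: dict[str, int] = {}
        for mid, site in self.planted:
            if mid == motif_id and site.status == status:
                mix[site.residue] = mix.get(site.residue, 0) + 1
        return mix

    def expected_ci(self, motif_id: str, status: str = KNOWN) -> float:
        """Exact expected CI of the planted (known) sites of one motif."""
        mix = self.acceptor_mix(motif_id, status)
        total = sum(mix.values())
        if total == 0:
            raise ValueError(f"no planted {status} sites for motif {motif_id}")
        weights = {r: n / total for r, n in mix.items()}
        ec = self.expected_c(motif_id, status)
        er = self.expected_r()
        return sum(
            ec[q] - sum(w * er[(q, r)] for r, w in weights.items())
            for q in self.config.genomes.non_reference
        )

    def expected_ci_ideal(self, status: str = KNOWN) -> float:
        """The no-contamination closed form sum_q (1-loss_q)(p_mot - p_bg)."""
        cfg = self.config
        p = cfg.mot_known() if status == KNOWN else cfg.mot_potential()
        bg, loss = cfg.bg(), cfg.loss()
        return sum(
            (1.0 - loss[q]) * (p[q] - bg[q]) for q in cfg.genomes.non_reference
        )

    def ci_standard_error(self, motif_id: str, status: str = KNOWN) -> float:
        """Conservative binomial standard error of the CI estimator.

        Sums per-genome variances of C and the mixture R; the positive
        covariance between the two (planted acceptors sit in both counts)
        is ignored, so the bound errs wide.
        """
        mix = self.acceptor_mix(motif_id, status)
        n_sites = sum(mix.values())
        weights = {r: n / n_sites for r, n in mix.items()}
        n_r = {
            r: self.n_bg.get(r, 0)
            + sum(n for (m, s, rr), n in self.n_acc.items() if rr == r)
            + sum(n for (s, rr), n in self.n_win.items() if rr == r)
            for r in "STY"
        }
        ec = self.expected_c(motif_id, status)
        er = self.expected_r()
        var = 0.0
        for q in self.config.genomes.non_reference:
            c = ec[q]
            var += c * (1.0 - c) / n_sites
            for r, w in weights.items():
                rq = er[(q, r)]
                if n_r[r]:
                    var += (w**2) * rq * (1.0 - rq) / n_r[r]
        return sqrt(var)


@dataclass
class SimResult:
    families: list[OrthologFamily]
    sites: list[Phosphosite]
    truth: SimTruth
    sequences: dict[str, str]  # human protein id -> ungapped sequence


def _mutate(rng: np.random.Generator, idx: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Retain residues where *keep*; elsewhere substitute a different residue."""
    out = idx.copy()
    n_mut = int((~keep).sum())
    if n_mut:
        out[~keep] = (idx[~keep] + rng.integers(1, 20, size=n_mut)) % 20
    return out


def simulate_families(config: SimConfig) -> SimResult:
    """Generate ortholog families, a phosphosite table, and planted truth."""
    rng = np.random.default_rng(config.seed)
    genomes = config.genomes
    ref = genomes.reference
    bg, pk, pp, loss = config.bg(), config.mot_known(), config.mot_potential(), config.loss()
    lo, hi = config.length_range

    families: list[OrthologFamily] = []
    sites: list[Phosphosite] = []
    sequences: dict[str, str] = {}
    planted_truth: list[tuple[str, Phosphosite]] = []
    n_bg: dict[str, int] = {r: 0 for r in "STY"}
    n_acc: dict[tuple[str, str, str], int] = {}
    n_win: dict[tuple[str, str], int] = {}

    for i in range(config.n_families):
        L = int(rng.integers(lo, hi + 1))
        seq_idx = rng.integers(0, 20, size=L)
        occupied = np.zeros(L, dtype=bool)
        planted: list[tuple[MotifPattern, int, str]] = []  # (motif, start0, status)

        for motif in config.motifs:
            wlen = len(motif)
            for _ in range(config.sites_per_protein):
                start = None
                for _attempt in range(100):
                    cand = int(rng.integers(0, L - wlen + 1))
                    if not occupied[cand : cand + wlen].any():
                        start = cand
                        break
                if start is None:
                    log.warning(
                        "family %d: could not place motif %s", i, motif.motif_id
                    )
                    continue
                occupied[start : start + wlen] = True
                for j, rs in enumerate(motif.positions):
                    if rs is not None:
                        choices = sorted(rs)
                        pick = choices[int(rng.integers(0, len(choices)))]
                        seq_idx[start + j] = _AA_INDEX[pick]
                status = KNOWN if rng.random() < config.known_rate else POTENTIAL
                planted.append((motif, start, status))

        protein_id = f"HSA{i:05d}"
        human_seq = "".join(_AA[seq_idx])
        sequences[protein_id] = human_seq

        # bookkeeping for truth and the site table
        acceptor_pos0 = set()
        window_pos0 = set()
        for motif, start, status in planted:
            acc0 = start + motif.acceptor_offset
            acceptor_pos0.add(acc0)
            res = human_seq[acc0]
            site = Phosphosite(protein_id, acc0 + 1, res, status)
            sites.append(site)
            planted_truth.append((motif.motif_id, site))
            key = (motif.motif_id, status, res)
            n_acc[key] = n_acc.get(key, 0) + 1
            for j in range(len(motif)):
                p0 = start + j
                if p0 == acc0 or motif.positions[j] is None:
                    continue  # wildcard positions follow the background process
                window_pos0.add(p0)
                ch = human_seq[p0]
                if ch in ACCEPTOR_RESIDUES:
                    k = (status, ch)
                    n_win[k] = n_win.get(k, 0) + 1
        for p0, ch in enumerate(human_seq):
            if ch in ACCEPTOR_RESIDUES and p0 not in acceptor_pos0:
                sites.append(Phosphosite(protein_id, p0 + 1, ch, POTENTIAL))
                if p0 not in window_pos0:
                    n_bg[ch] += 1

        # orthologs
        rows_idx: dict[str, np.ndarray] = {}
        for q in genomes.non_reference:
            if rng.random() < loss[q]:
                continue
            keep = rng.random(L) < bg[q]
            ortho = _mutate(rng, seq_idx, keep)
            for motif, start, status in planted:
                wlen = len(motif)
                p = pk[q] if status == KNOWN else pp[q]
                acc0 = start + motif.acceptor_offset
                if rng.random() < p:
                    # copy the constrained positions; wildcards match any
                    # residue, so they keep their background-process draw
                    for j, rs in enumerate(motif.positions):
                        if rs is not None:
                            ortho[start + j] = seq_idx[start + j]
                else:
                    ortho[acc0] = _NON_STY_IDX[int(rng.integers(0, len(_NON_STY_IDX)))]
            rows_idx[q] = ortho

        # aligned rows: gap-free stack, optionally decorated with insertions
        rows: dict[str, str] = {q: "".join(_AA[v]) for q, v in rows_idx.items()}
        rows[ref] = human_seq
        if config.indel_rate > 0:
            rows = _decorate_indels(rng, rows, ref, planted, L, config.indel_rate)

        members = {
            q: [(protein_id if q == ref else f"{q.upper()}{i:05d}", row)]
            for q, row in rows.items()
        }
        families.append(OrthologFamily(cluster_id=f"OC{i:05d}", members=members))

    truth = SimTruth(
        config=config, planted=planted_truth, n_bg=n_bg, n_acc=n_acc, n_win=n_win
    )
    return SimResult(families=families, sites=sites, truth=truth, sequences=sequences)


def _decorate_indels(
    rng: np.random.Generator,
    rows: dict[str, str],
    ref: str,
    planted: Sequence[tuple[MotifPattern, int, str]],
    L: int,
    indel_rate: float,
) -> dict[str, str]:
    """Insert per-genome residue blocks at points outside planted windows.

    An insertion in genome g adds k residues to g's row and k gap columns to
    every other row; planted windows keep contiguous, unshifted contents, so
    truth is untouched while column mapping gets exercised.
    """
    forbidden: list[tuple[int, int]] = [
        (start + 1, start + len(m) - 1) for m, start, _ in planted if len(m) > 1
    ]

    def _ok(point: int) -> bool:
        return all(not (a <= point <= b) for a, b in forbidden)

    insertions: list[tuple[int, str, str]] = []  # (point, genome, residues)
    for q in sorted(rows):
        if q == ref or rng.random() >= indel_rate:
            continue
        for _attempt in range(50):
            point = int(rng.integers(0, L + 1))
            if _ok(point):
                k = int(rng.integers(1, 4))
                res = "".join(_AA[rng.integers(0, 20, size=k)])
                insertions.append((point, q, res))
                break
    for point, genome, res in sorted(insertions, key=lambda t: -t[0]):
        k = len(res)
        out = {}
        for q, row in rows.items():
            ins = res if q == genome else "-" * k
            out[q] = row[:point] + ins + row[point:]
        rows = out
    return rows


# ---------------------------------------------------------------------------
# kinase tables

def simulate_kinase_data(
    group_probs: Mapping[str, float],
    n_edges: int,
    genomes: GenomeSet,
    seed: int,
    n_kinases_per_group: int = 4,
    presence_prob: ProbLike = 1.0,
    substrate_sites: Optional[Sequence[Phosphosite]] = None,
) -> tuple[list[KinaseRecord], list[KinaseSubstrateEdge]]:
    """Multinomial kinase-substrate edges plus a kinase classification table.

    Edges are assigned to kinase groups by one multinomial draw over
    *group_probs*; each group owns ``n_kinases_per_group`` kinases (two
    families per group) and presence flags drawn per genome.  If
    *substrate_sites* is given, edges attach to those sites (cycled in a
    seeded shuffle); otherwise synthetic substrate ids are fabricated.
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    total = sum(group_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"group probabilities sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    ref = genomes.reference

    kinases: list[KinaseRecord] = []
    by_group: dict[str, list[str]] = {}
    if isinstance(presence_prob, Mapping):
        pres = {q: float(presence_prob[q]) for q in genomes}
    else:
        pres = {q: float(presence_prob) for q in genomes}
    for group in group_probs:
        for j in range(n_kinases_per_group):
            kid = f"KIN_{group}_{j}"
            presence = {
                q: True if q == ref else bool(rng.random() < pres[q]) for q in genomes
            }
            kinases.append(
                KinaseRecord(
                    kinase_id=kid,
                    group=group,
                    family=f"{group}_fam{j % 2}",
                    presence=presence,
                )
            )
            by_group.setdefault(group, []).append(kid)

    groups = list(group_probs)
    counts = rng.multinomial(n_edges, [group_probs[g] for g in groups])
    if substrate_sites:
        order = rng.permutation(len(substrate_sites))
    edges: list[KinaseSubstrateEdge] = []
    e = 0
    for group, count in zip(groups, counts):
        pool = by_group[group]
        for _ in range(count):
            kid = pool[int(rng.integers(0, len(pool)))]
            if substrate_sites:
                s = substrate_sites[int(order[e % len(substrate_sites)])]
                edges.append(KinaseSubstrateEdge(kid, s.protein_id, s.position, s.residue))
            else:
                res = "S" if rng.random() < 0.8 else "T"
                edges.append(
                    KinaseSubstrateEdge(kid, f"SUB{e:05d}", int(rng.integers(1, 500)), res)
                )
            e += 1
    return kinases, edges


# ---------------------------------------------------------------------------
# interaction networks and annotations

def simulate_interactions(
    proteins: Sequence[str],
    seed: int,
    mean_degree: float = 4.0,
    clique: Sequence[str] = (),
) -> list[InteractionEdge]:
    """An Erdős–Rényi edge list, optionally with a planted clique."""
    rng = np.random.default_rng(seed)
    n = len(proteins)
    if n < 2:
        raise ValueError("need at least two proteins")
    p = min(1.0, mean_degree / max(n - 1, 1))
    edges: dict[tuple[str, str], InteractionEdge] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                e = InteractionEdge.canonical(proteins[i], proteins[j], "sim")
                edges[e.key] = e
    clique = sorted(set(clique))
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            e = InteractionEdge.canonical(clique[i], clique[j], "clique")
            edges.setdefault(e.key, e)
    return [edges[k] for k in sorted(edges)]


def simulate_annotations(
    proteins: Sequence[str],
    seed: int,
    n_terms: int = 10,
    term_prob: float = 0.15,
    enriched_term: str = "T_ENRICHED",
    enriched_proteins: Sequence[str] = (),
):
    """Random protein→term table, optionally with one term planted on a set."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        term = f"T{t:03d}"
        for p in proteins:
            if rng.random() < term_prob:
                rows.append((p, term))
    for p in sorted(set(enriched_proteins)):
        rows.append((p, enriched_term))
    return pd.DataFrame(rows, columns=["protein_id", "term"]).drop_duplicates()
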