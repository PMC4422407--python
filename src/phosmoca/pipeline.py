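"""End-to-end pipeline: stage orchestration, config, and run manifest.

Stages run in a fixed order (match → conserve → ci → compare → bin →
kinases → enrich → network); each stage reads its inputs from files — the
raw input tables and its predecessors' written outputs — and writes its
results before the next stage starts, so any stage can be re-run in
isolation and reproduces the full-pipeline result.  Reruns with an
identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

from . import io as pio
from .analysis import (
    bin_ci_distribution,
    compare_known_vs_potential,
    kinase_expansion_table,
    kinase_fractions,
    kinase_group_substrate_ci,
    motif_network_statistic,
    term_enrichment,
)
from .conservation import (
    CIRecord,
    ConservationProfile,
    ReferenceRates,
    UndefinedRateError,
    conservation_index,
    index_families,
    motif_conservation_rates,
    reference_rates,
)
from .model import KNOWN, POTENTIAL, GenomeSet, Phosphosite
from .motifs import classify_pattern, match_at
from .simulate import (
    SimConfig,
    simulate_annotations,
    simulate_families,
    simulate_interactions,
    simulate_kinase_data,
)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_stage", "run_pipeline",
           "write_simulated_dataset", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("match", "conserve", "ci", "compare", "bin", "kinases", "enrich", "network")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (usually loaded from YAML).

    Input paths may live anywhere; stage outputs all go to ``out_dir``.
    The switches mirror the documented analysis decisions: ``denominator``
    (``all`` keeps ortholog-less sites in every denominator;
    ``aligned_only`` drops them per genome), ``rematch`` (``strict_columns``
    or ``degapped_window``), and ``fraction_unit`` (``edges`` or
    ``proteins``).
    """

    motifs: str = ""
    sites: str = ""
    families_dir: str = ""
    proteome: str = ""
    kinases: str = ""
    kinase_substrates: str = ""
    interactions: str = ""
    annotations: str = ""
    out_dir: str = "results"
    genome_codes: tuple[str, ...] = GenomeSet().codes
    reference: str = "hsa"
    denominator: str = "all"
    rematch: str = "strict_columns"
    fraction_unit: str = "edges"
    class_size: int = 10
    top_k: int = 3
    min_sites: int = 10
    alpha_p: float = 0.01
    alpha_fdr: float = 0.01
    n_perm: int = 999
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "genome_codes" in raw:
            raw["genome_codes"] = tuple(raw["genome_codes"])
        return cls(**raw)

    @property
    def genomes(self) -> GenomeSet:
        return GenomeSet(codes=tuple(self.genome_codes), reference=self.reference)

    def canonical(self) -> dict:
        d = asdict(self)
        d["genome_codes"] = list(self.genome_codes)
        return d

    def config_hash(self) -> str:
        # the output location does not change what is computed
        d = {k: v for k, v in self.canonical().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def out(self, name: str) -> Path:
        return Path(self.out_dir) / name

    def validate(self, stage: Optional[str] = None) -> None:
        """Fail fast on missing inputs before any computation starts."""
        required = {"motifs": self.motifs, "sites": self.sites,
                    "families_dir": self.families_dir}
        for key, path in required.items():
            if not path:
                raise ConfigError(f"config field {key!r} is required")
            if not Path(path).exists():
                raise ConfigError(f"{key}: path does not exist: {path}")
        for key in ("proteome", "kinases", "kinase_substrates", "interactions",
                    "annotations"):
            path = getattr(self, key)
            if path and not Path(path).exists():
                raise ConfigError(f"{key}: path does not exist: {path}")
        if self.denominator not in ("all", "aligned_only"):
            raise ConfigError(f"denominator must be all|aligned_only, got {self.denominator}")
        if self.rematch not in ("strict_columns", "degapped_window"):
            raise ConfigError(f"rematch must be strict_columns|degapped_window")
        self.genomes  # raises on a bad genome set


# ---------------------------------------------------------------------------
# shared loaders

def _load_families(cfg: PipelineConfig):
    paths = sorted(Path(cfg.families_dir).glob("*.afa")) or sorted(
        Path(cfg.families_dir).glob("*.fasta")
    )
    if not paths:
        raise StageError(f"no alignment files (*.afa) in {cfg.families_dir}")
    return pio.read_alignment_families(paths, cfg.genomes)


def _human_sequences(cfg: PipelineConfig, index) -> dict[str, str]:
    seqs = index.sequences()
    if cfg.proteome:
        seqs.update(pio.read_fasta_sequences(cfg.proteome))
    return seqs


def _read_matched(cfg: PipelineConfig) -> pd.DataFrame:
    path = cfg.out("matched_sites.tsv")
    if not path.exists():
        raise StageError("match stage output missing; run 'match' first")
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    return df


def _matched_to_sites(df: pd.DataFrame) -> list[Phosphosite]:
    return [
        Phosphosite(r.protein_id, int(r.position), r.residue, r.status)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# stages

def _stage_match(cfg: PipelineConfig) -> dict[str, int]:
    """Identify which known/potential sites carry each motif in human."""
    patterns = pio.read_motif_table(cfg.motifs)
    sites = pio.read_site_table(cfg.sites)
    index = index_families(_load_families(cfg), cfg.genomes)
    seqs = _human_sequences(cfg, index)
    missing = {s.protein_id for s in sites if s.protein_id not in seqs}
    if missing:
        log.warning("match: %d proteins in the site table have no sequence", len(missing))
    rows = []
    for pat in patterns:
        for s in sites:
            seq = seqs.get(s.protein_id)
            if seq is None:
                continue
            if s.position <= len(seq) and seq[s.position - 1] != s.residue:
                raise StageError(
                    f"match: {s.protein_id}:{s.position} residue {s.residue} "
                    f"does not match sequence"
                )
            if match_at(pat, seq, s.position):
                rows.append((pat.motif_id, s.protein_id, s.position, s.residue, s.status))
    df = pd.DataFrame(
        rows, columns=["motif_id", "protein_id", "position", "residue", "status"]
    )
    pio.write_table(df, cfg.out("matched_sites.tsv"),
                    sort_by=["motif_id", "protein_id", "position", "status"])
    return {"matched_sites": len(df)}


def _stage_conserve(cfg: PipelineConfig) -> dict[str, int]:
    """Call per-site, per-genome conservation and tabulate rates."""
    patterns = {p.motif_id: p for p in pio.read_motif_table(cfg.motifs)}
    sites = pio.read_site_table(cfg.sites)
    index = index_families(_load_families(cfg), cfg.genomes)
    matched = _read_matched(cfg)

    prof_rows, call_rows = [], []
    for (motif_id, status), grp in matched.groupby(["motif_id", "status"], sort=True):
        pat = patterns[motif_id]
        msites = _matched_to_sites(grp)
        calls = []
        try:
            profile = motif_conservation_rates(
                index, msites, pat, cfg.genomes, site_class=status,
                denominator=cfg.denominator, rematch=cfg.rematch, calls_out=calls,
            )
        except UndefinedRateError as exc:
            log.warning("conserve: %s", exc)
            continue
        for g in cfg.genomes:
            prof_rows.append(
                (motif_id, status, g, profile.conserved[g], profile.denominator[g])
            )
        for c in calls:
            call_rows.append(
                (motif_id, status, c.site.protein_id, c.site.position, c.genome, c.verdict)
            )

    # background reference rates over every STY residue in the site table
    refs = reference_rates(index, sites, cfg.genomes, denominator=cfg.denominator)
    ref_rows = [
        (q, r, refs.conserved[(q, r)], refs.denominator[(q, r)])
        for (q, r) in sorted(refs.denominator)
    ]

    pio.write_table(
        pd.DataFrame(prof_rows, columns=["motif_id", "site_class", "genome",
                                         "conserved", "denominator"]),
        cfg.out("profiles.tsv"),
        sort_by=["motif_id", "site_class", "genome"],
    )
    pio.write_table(
        pd.DataFrame(call_rows, columns=["motif_id", "site_class", "protein_id",
                                         "position", "genome", "verdict"]),
        cfg.out("calls.tsv"),
        sort_by=["motif_id", "site_class", "protein_id", "position", "genome"],
    )
    pio.write_table(
        pd.DataFrame(ref_rows, columns=["genome", "residue", "conserved", "denominator"]),
        cfg.out("reference_rates.tsv"),
        sort_by=["genome", "residue"],
    )
    return {"profiles": len(prof_rows), "calls": len(call_rows)}


def _load_profiles(cfg: PipelineConfig) -> dict[tuple[str, str], ConservationProfile]:
    df = pd.read_csv(cfg.out("profiles.tsv"), sep="\t")
    out = {}
    for (motif_id, status), grp in df.groupby(["motif_id", "site_class"]):
        conserved = dict(zip(grp["genome"], grp["conserved"].astype(int)))
        denom = dict(zip(grp["genome"], grp["denominator"].astype(int)))
        out[(motif_id, status)] = ConservationProfile(
            motif_id=motif_id, site_class=status,
            n_sites=denom[cfg.reference], conserved=conserved, denominator=denom,
        )
    return out


def _load_refs(cfg: PipelineConfig) -> ReferenceRates:
    df = pd.read_csv(cfg.out("reference_rates.tsv"), sep="\t")
    conserved = {(r.genome, r.residue): int(r.conserved) for r in df.itertuples()}
    denom = {(r.genome, r.residue): int(r.denominator) for r in df.itertuples()}
    return ReferenceRates(conserved, denom, cfg.genomes)


def _stage_ci(cfg: PipelineConfig) -> dict[str, int]:
    """Combine rates into per-motif, per-class conservation indices."""
    profiles = _load_profiles(cfg)
    refs = _load_refs(cfg)
    matched = _read_matched(cfg)
    mixes = {
        key: dict(grp["residue"].value_counts())
        for key, grp in matched.groupby(["motif_id", "status"])
    }
    rows = []
    genomes = list(cfg.genomes)
    for (motif_id, status), profile in sorted(profiles.items()):
        mix = {r: int(n) for r, n in mixes.get((motif_id, status), {}).items()}
        try:
            rec = conservation_index(profile, refs, mix)
        except UndefinedRateError as exc:
            raise StageError(f"ci: {exc}") from exc
        row = {"motif_id": motif_id, "site_class": status,
               "n_sites": profile.n_sites, "ci": rec.ci}
        for g in genomes:
            row[f"c_{g}"] = rec.c_rates[g]
            row[f"r_{g}"] = rec.r_rates[g]
        rows.append(row)
    cols = ["motif_id", "site_class", "n_sites", "ci"]
    cols += [f"c_{g}" for g in genomes] + [f"r_{g}" for g in genomes]
    pio.write_table(pd.DataFrame(rows, columns=cols), cfg.out("ci.tsv"),
                    sort_by=["motif_id", "site_class"])
    return {"ci_records": len(rows)}


def _load_ci(cfg: PipelineConfig) -> list[CIRecord]:
    df = pd.read_csv(cfg.out("ci.tsv"), sep="\t")
    genomes = list(cfg.genomes)
    recs = []
    for r in df.itertuples(index=False):
        c = {g: getattr(r, f"c_{g}") for g in genomes}
        rr = {g: getattr(r, f"r_{g}") for g in genomes}
        terms = {g: c[g] - rr[g] for g in genomes}
        recs.append(
            CIRecord(motif_id=r.motif_id, site_class=r.site_class,
                     ci=sum(terms.values()), terms=terms, c_rates=c, r_rates=rr,
                     n_sites=int(r.n_sites))
        )
    return recs


def _stage_compare(cfg: PipelineConfig) -> dict[str, int]:
    """Pair known vs potential CIs per motif (scatter + correlation)."""
    recs = _load_ci(cfg)
    known = [r for r in recs if r.site_class == KNOWN]
    pot = [r for r in recs if r.site_class == POTENTIAL]
    result = compare_known_vs_potential(known, pot)
    pio.write_table(result.table, cfg.out("compare.tsv"), sort_by=["motif_id"])
    stats = {
        "pearson_r": result.pearson_r,
        "n_pairs": result.n_pairs,
        "n_above_diagonal": result.n_above,
        "n_below_diagonal": result.n_below,
        "n_on_diagonal": result.n_on,
    }
    with open(cfg.out("compare_stats.json"), "w") as fh:
        json.dump(stats, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return {"pairs": result.n_pairs}


def _stage_bin(cfg: PipelineConfig) -> dict[str, int]:
    """CI-rank classes of known-site CIs with structural composition."""
    patterns = pio.read_motif_table(cfg.motifs)
    structures = {p.motif_id: classify_pattern(p) for p in patterns}
    recs = [r for r in _load_ci(cfg) if r.site_class == KNOWN]
    bins = bin_ci_distribution(recs, structures, class_size=cfg.class_size)
    df = pd.DataFrame(
        [
            (b.index, len(b.motif_ids), b.mean_ci, b.n_basic, b.n_proline_directed,
             ";".join(b.motif_ids))
            for b in bins
        ],
        columns=["bin", "n_motifs", "mean_ci", "n_basic", "n_STP", "motif_ids"],
    )
    pio.write_table(df, cfg.out("bins.tsv"))
    return {"bins": len(bins)}


def _stage_kinases(cfg: PipelineConfig) -> dict[str, int]:
    """Kinase group/family fractions, group substrate CIs, kinome expansion."""
    if not cfg.kinases or not cfg.kinase_substrates:
        log.warning("kinases: inputs not configured; stage skipped")
        return {"skipped": 1}
    kin_list = pio.read_kinase_table(cfg.kinases, cfg.genomes)
    kinases = {k.kinase_id: k for k in kin_list}
    edges = pio.read_kinase_substrate_table(cfg.kinase_substrates)
    matched = _read_matched(cfg)
    known = matched[matched["status"] == KNOWN]

    frac_rows = []
    for motif_id, grp in known.groupby("motif_id", sort=True):
        keys = {(r.protein_id, int(r.position)) for r in grp.itertuples()}
        medges = [e for e in edges if (e.protein_id, e.position) in keys]
        if not medges:
            log.warning("kinases: motif %s has no substrate edges", motif_id)
            continue
        for level in ("group", "family"):
            res = kinase_fractions(medges, kinases, level=level, top_k=cfg.top_k,
                                   unit=cfg.fraction_unit)
            for rank, r in enumerate(res.table.itertuples(index=False), start=1):
                frac_rows.append(
                    (motif_id, res.n_substrates, res.n_edges, level, rank,
                     r.label, r.count, r.fraction)
                )
    pio.write_table(
        pd.DataFrame(frac_rows, columns=["motif_id", "n_substrates", "n_edges",
                                         "level", "rank", "label", "count", "fraction"]),
        cfg.out("kinase_fractions.tsv"),
        sort_by=["motif_id", "level", "rank"],
    )

    # group substrate CIs need the conservation machinery
    sites = pio.read_site_table(cfg.sites)
    site_index = {(s.protein_id, s.position): s for s in sites}
    index = index_families(_load_families(cfg), cfg.genomes)
    refs = _load_refs(cfg)
    records, low = kinase_group_substrate_ci(
        edges, kinases, site_index, index, refs, cfg.genomes, min_sites=cfg.min_sites
    )
    gci = pd.DataFrame(
        [(g, r.n_sites, r.ci, int(low[g])) for g, r in sorted(records.items())],
        columns=["group", "n_sites", "ci", "low_support"],
    )
    pio.write_table(gci, cfg.out("kinase_group_ci.tsv"), sort_by=["group"])

    expansion = kinase_expansion_table(kin_list, cfg.genomes)
    pio.write_table(expansion, cfg.out("kinase_expansion.tsv"),
                    sort_by=["genome", "group"])
    return {"fractions": len(frac_rows), "group_ci": len(gci), "expansion": len(expansion)}


def _stage_enrich(cfg: PipelineConfig) -> dict[str, int]:
    """Per-motif term over-representation among motif-bearing proteins."""
    if not cfg.annotations:
        log.warning("enrich: annotations not configured; stage skipped")
        return {"skipped": 1}
    annotations = pio.read_annotation_table(cfg.annotations)
    sites = pio.read_site_table(cfg.sites)
    background = {s.protein_id for s in sites}
    matched = _read_matched(cfg)
    known = matched[matched["status"] == KNOWN]
    rows = []
    for motif_id, grp in known.groupby("motif_id", sort=True):
        proteins = set(grp["protein_id"]) & background
        if not proteins:
            continue
        for res in term_enrichment(proteins, annotations, background,
                                   alpha_p=cfg.alpha_p, alpha_fdr=cfg.alpha_fdr):
            rows.append(
                (motif_id, res.term, res.overlap, res.set_size, res.term_size,
                 res.background_size, res.p_value, res.fdr, int(res.significant))
            )
    pio.write_table(
        pd.DataFrame(rows, columns=["motif_id", "term", "overlap", "set_size",
                                    "term_size", "background_size", "p_value",
                                    "fdr", "significant"]),
        cfg.out("enrichment.tsv"),
        sort_by=["motif_id", "p_value", "term"],
    )
    return {"enrichment_rows": len(rows)}


def _stage_network(cfg: PipelineConfig) -> dict[str, int]:
    """Same-motif interaction subnetworks with permutation p-values."""
    if not cfg.interactions:
        log.warning("network: interactions not configured; stage skipped")
        return {"skipped": 1}
    interactions = pio.read_interaction_table(cfg.interactions)
    nodes = {p for e in interactions for p in (e.protein_a, e.protein_b)}
    matched = _read_matched(cfg)
    known = matched[matched["status"] == KNOWN]
    stat_rows, edge_rows = [], []
    for k, (motif_id, grp) in enumerate(known.groupby("motif_id", sort=True)):
        proteins = set(grp["protein_id"]) & nodes
        if len(proteins) < 2:
            log.warning("network: motif %s has <2 proteins in the network", motif_id)
            continue
        stat = motif_network_statistic(
            interactions, proteins, n_perm=cfg.n_perm, seed=cfg.seed + k
        )
        stat_rows.append(
            (motif_id, len(proteins), stat.observed, stat.n_perm, stat.p_value)
        )
        for e in stat.subnetwork:
            edge_rows.append((motif_id, e.protein_a, e.protein_b))
    pio.write_table(
        pd.DataFrame(stat_rows, columns=["motif_id", "n_proteins", "observed",
                                         "n_perm", "p_value"]),
        cfg.out("network_stats.tsv"), sort_by=["motif_id"],
    )
    pio.write_table(
        pd.DataFrame(edge_rows, columns=["motif_id", "protein_a", "protein_b"]),
        cfg.out("subnetworks.tsv"), sort_by=["motif_id", "protein_a", "protein_b"],
    )
    return {"networks": len(stat_rows), "subnetwork_edges": len(edge_rows)}


_STAGE_FUNCS = {
    "match": _stage_match,
    "conserve": _stage_conserve,
    "ci": _stage_ci,
    "compare": _stage_compare,
    "bin": _stage_bin,
    "kinases": _stage_kinases,
    "enrich": _stage_enrich,
    "network": _stage_network,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict[str, int]:
    """Run one stage; raises :class:`StageError` naming the stage on failure."""
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r}; stages are {STAGES}")
    cfg.validate(name)
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[name](cfg)
    except (StageError, ConfigError):
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order and write ``manifest.json``."""
    cfg.validate()
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package": "phosmoca",
        "stages": [],
    }
    for name in STAGES:
        counts = run_stage(name, cfg)
        manifest["stages"].append({"name": name, "rows": counts})
    with open(cfg.out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# simulated dataset writer (the 'simulate' subcommand)

_DEFAULT_SIM = {
    "n_families": 60,
    "length_range": [150, 250],
    "motif_patterns": ["S/T-P", "R-X-X-S/T", "R-X-S/T"],
    "sites_per_protein": 1,
    "p_bg": 0.5,
    "p_mot": 0.8,
    "loss_prob": 0.0,
    "known_rate": 1.0,
    "indel_rate": 0.2,
    "kinase_group_probs": {"CMGC": 0.55, "AGC": 0.25, "CAMK": 0.15, "Other": 0.05},
    "n_kinase_edges": 400,
}


def write_simulated_dataset(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, int]:
    """Generate a full synthetic study dataset under *out_dir*.

    Writes per-cluster alignments, the phosphosite and motif tables, the
    human proteome, kinase and interaction and annotation tables, and a
    ``truth.tsv`` sidecar with the planted parameters and expected CIs.
    """
    from .motifs import parse_motif_pattern

    params = dict(_DEFAULT_SIM)
    params.update(cfg.simulate or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patterns = [
        parse_motif_pattern(p, f"M{i:03d}")
        for i, p in enumerate(params["motif_patterns"])
    ]
    sim_cfg = SimConfig(
        seed=cfg.seed,
        n_families=int(params["n_families"]),
        length_range=tuple(params["length_range"]),
        genomes=cfg.genomes,
        motifs=tuple(patterns),
        sites_per_protein=int(params["sites_per_protein"]),
        p_bg=params["p_bg"],
        p_mot=params["p_mot"],
        loss_prob=params["loss_prob"],
        known_rate=float(params["known_rate"]),
        indel_rate=float(params["indel_rate"]),
    )
    result = simulate_families(sim_cfg)

    fam_dir = out / "families"
    for fam in result.families:
        pio.write_alignment_family(fam, fam_dir)
    pio.write_site_table(result.sites, out / "sites.tsv")
    pio.write_fasta_sequences(result.sequences, out / "proteome.fasta")
    pio.write_motif_table(patterns, out / "motifs.tsv")

    truth_rows = [
        {
            "motif_id": p.motif_id,
            "expected_ci_known": result.truth.expected_ci(p.motif_id, KNOWN),
            "expected_ci_ideal": result.truth.expected_ci_ideal(KNOWN),
            "n_planted_known": sum(result.truth.acceptor_mix(p.motif_id).values()),
        }
        for p in patterns
    ]
    pio.write_table(pd.DataFrame(truth_rows), out / "truth.tsv", sort_by=["motif_id"])

    known_sites = [s for s in result.sites if s.status == KNOWN]
    kinases, edges = simulate_kinase_data(
        params["kinase_group_probs"], int(params["n_kinase_edges"]), cfg.genomes,
        seed=cfg.seed + 1, substrate_sites=known_sites,
    )
    pio.write_kinase_table(kinases, out / "kinases.tsv", cfg.genomes)
    pio.write_kinase_substrate_table(edges, out / "kinase_substrates.tsv")

    proteins = sorted(result.sequences)
    motif_proteins = sorted({s.protein_id for s in known_sites})
    interactions = simulate_interactions(
        proteins, seed=cfg.seed + 2, clique=motif_proteins[: max(4, len(motif_proteins) // 4)]
    )
    pio.write_interaction_table(interactions, out / "interactions.tsv")
    annotations = simulate_annotations(
        proteins, seed=cfg.seed + 3, enriched_proteins=motif_proteins[:20]
    )
    pio.write_annotation_table(annotations, out / "annotations.tsv")
    return {
        "families": len(result.families),
        "sites": len(result.sites),
        "kinase_edges": len(edges),
        "interactions": len(interactions),
    }
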