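"""Conservation core: coordinate mapping, calls, rates, and the CI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bf_ci, bf_rates, bf_reference_rates, bf_verdict, known_sites_of
from phosmoca import (
    GenomeSet,
    Phosphosite,
    conservation_index,
    index_families,
    motif_conservation_rates,
    reference_rates,
    site_set_conservation,
)
from phosmoca.conservation import (
    CONSERVED,
    NO_ORTHOLOG,
    NOT_CONSERVED,
    UndefinedRateError,
    call_site_conservation,
    column_to_ungapped,
    match_sites,
    ungapped_to_column,
)
from phosmoca.model import KNOWN, OrthologFamily


class TestCoordinateMapping:
    def test_gapped_row(self):
        assert ungapped_to_column("AC-DE", 3) == 4

    def test_identity_without_gaps(self):
        for k in range(1, 6):
            assert ungapped_to_column("ACDEF", k) == k

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            ungapped_to_column("AC-DE", 5)

    def test_column_on_gap_rejected(self):
        with pytest.raises(IndexError):
            column_to_ungapped("AC-DE", 3)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from("ACDEF-"), min_size=1, max_size=40))
    def test_round_trip_identity(self, chars):
        """Mapping position→column→position is the identity on valid positions."""
        row = "".join(chars)
        n = sum(1 for c in row if c != "-")
        for pos in range(1, n + 1):
            assert column_to_ungapped(row, ungapped_to_column(row, pos)) == pos


def _family(**rows):
    members = {g: [(f"{g}_p", row)] for g, row in rows.items()}
    return OrthologFamily(cluster_id="oc", members=members)


class TestCallSiteConservation:
    def test_identical_rows_conserved(self, rxxst, genomes):
        fam = _family(hsa="AR--PGSAP", mmu="AR--PGSAP")
        site = Phosphosite("hsa_p", 5, "S", "known")  # ungapped ARPGSAP
        call = call_site_conservation(fam, "hsa_p", site, rxxst, "mmu", genomes)
        assert call.verdict == CONSERVED

    def test_gap_in_motif_column_not_conserved(self, rxxst, genomes):
        fam = _family(hsa="AR--PGSAP", mmu="A---PGSAP")
        site = Phosphosite("hsa_p", 5, "S", "known")
        call = call_site_conservation(fam, "hsa_p", site, rxxst, "mmu", genomes)
        assert call.verdict == NOT_CONSERVED

    def test_degapped_rematch_mode_recovers_shifted_motif(self, rxxst, genomes):
        # mouse carries an intact motif whose arginine sits in a column where
        # the human row has a gap, so strict column matching misses it
        fam = _family(hsa="AR--PGSAP", mmu="AQ-RCGSAP")
        site = Phosphosite("hsa_p", 5, "S", "known")
        strict = call_site_conservation(fam, "hsa_p", site, rxxst, "mmu", genomes)
        loose = call_site_conservation(
            fam, "hsa_p", site, rxxst, "mmu", genomes, rematch="degapped_window"
        )
        assert strict.verdict == NOT_CONSERVED  # wrong residues in human columns
        assert loose.verdict == CONSERVED

    def test_missing_genome_is_no_ortholog(self, rxxst, genomes):
        fam = _family(hsa="ARPGSAP")
        site = Phosphosite("hsa_p", 5, "S", "known")
        assert (
            call_site_conservation(fam, "hsa_p", site, rxxst, "cel", genomes).verdict
            == NO_ORTHOLOG
        )

    def test_reference_genome_always_conserved(self, rxxst, genomes):
        fam = _family(hsa="ARPGSAP")
        site = Phosphosite("hsa_p", 5, "S", "known")
        assert (
            call_site_conservation(fam, "hsa_p", site, rxxst, "hsa", genomes).verdict
            == CONSERVED
        )

    def test_non_matching_human_window_is_an_error(self, rxxst, genomes):
        fam = _family(hsa="AAPGSAP", mmu="AAPGSAP")
        site = Phosphosite("hsa_p", 5, "S", "known")
        with pytest.raises(ValueError, match="does not match"):
            call_site_conservation(fam, "hsa_p", site, rxxst, "mmu", genomes)

    def test_any_member_match_suffices(self, rxxst, genomes):
        fam = OrthologFamily(
            cluster_id="oc",
            members={
                "hsa": [("hp", "ARPGSAP")],
                "mmu": [("m1", "AAPGAAP"), ("m2", "ARPGSAP")],
            },
        )
        site = Phosphosite("hp", 5, "S", "known")
        assert (
            call_site_conservation(fam, "hp", site, rxxst, "mmu", genomes).verdict
            == CONSERVED
        )

    def test_verdicts_equal_brute_force_on_simulation(self, small_sim, rxxst, genomes):
        """Hundreds of simulated calls equal an independent re-implementation."""
        index = index_families(small_sim.families, genomes)
        sites = known_sites_of(small_sim, "rxxst")
        fam_by_protein = {
            pid: fam
            for fam in small_sim.families
            for pid, _ in fam.members.get("hsa", [])
        }
        checked = 0
        for site in sites:
            fam = fam_by_protein[site.protein_id]
            for q in genomes.non_reference:
                got = call_site_conservation(
                    fam, site.protein_id, site, rxxst, q, genomes
                )
                want = bf_verdict(fam, "hsa", site.protein_id, site.position, rxxst, q)
                assert got.verdict == want
                checked += 1
        assert checked >= 80


class TestRates:
    def test_simple_ratio(self, stp, genomes):
        fams = [
            _family(hsa="ASPA", mmu="ASPA"),
        ]
        # build 4 copies of the site over 4 families, 3 conserved in mmu
        families, sites = [], []
        for i, mrow in enumerate(["ASPA", "ASPA", "ASPA", "AAPA"]):
            fam = OrthologFamily(
                cluster_id=f"oc{i}",
                members={"hsa": [(f"P{i}", "ASPA")], "mmu": [(f"m{i}", mrow)]},
            )
            families.append(fam)
            sites.append(Phosphosite(f"P{i}", 2, "S", "known"))
        index = index_families(families, genomes)
        prof = motif_conservation_rates(index, sites, stp, genomes)
        assert prof.rate("mmu") == pytest.approx(0.75)
        assert prof.rate("hsa") == 1.0
        assert prof.rate("cel") == 0.0  # no ortholog anywhere counts not conserved

    def test_aligned_only_denominator_drops_missing(self, stp, genomes):
        fams = [
            OrthologFamily(
                cluster_id="a",
                members={"hsa": [("P0", "ASPA")], "mmu": [("m", "ASPA")]},
            ),
            OrthologFamily(
                cluster_id="b", members={"hsa": [("P1", "ASPA")]}
            ),
        ]
        sites = [Phosphosite("P0", 2, "S"), Phosphosite("P1", 2, "S")]
        index = index_families(fams, genomes)
        all_mode = motif_conservation_rates(index, sites, stp, genomes)
        aligned = motif_conservation_rates(
            index, sites, stp, genomes, denominator="aligned_only"
        )
        assert all_mode.rate("mmu") == pytest.approx(0.5)
        assert aligned.rate("mmu") == pytest.approx(1.0)
        assert aligned.denominator["mmu"] == 1

    def test_empty_sites_error(self, stp, genomes):
        index = index_families([_family(hsa="ASPA")], genomes)
        with pytest.raises(UndefinedRateError):
            motif_conservation_rates(index, [], stp, genomes)

    def test_binomial_recovery_of_planted_rate(self, genomes, rxxst):
        """Estimated C_q lies within 3·sqrt(p(1-p)/n) of the planted p."""
        from phosmoca import SimConfig, simulate_families

        cfg = SimConfig(
            seed=5, n_families=500, length_range=(60, 90), motifs=(rxxst,),
            p_bg=0.5, p_mot=0.8,
        )
        res = simulate_families(cfg)
        index = index_families(res.families, genomes)
        sites = known_sites_of(res, "rxxst")
        prof = motif_conservation_rates(index, sites, rxxst, genomes)
        n = len(sites)
        tol = 3 * math.sqrt(0.8 * 0.2 / n)
        for q in genomes.non_reference:
            assert abs(prof.rate(q) - 0.8) < tol

    def test_reference_rates_identical_rows(self, genomes):
        fam = _family(hsa="ASTYA", mmu="ASTYA")
        index = index_families([fam], genomes)
        background = [
            Phosphosite("hsa_p", 2, "S"),
            Phosphosite("hsa_p", 3, "T"),
            Phosphosite("hsa_p", 4, "Y"),
        ]
        refs = reference_rates(index, background, genomes)
        for r in "STY":
            assert refs.rate("mmu", r) == 1.0
            assert refs.rate("hsa", r) == 1.0

    def test_reference_rate_unavailable_type(self, genomes):
        fam = _family(hsa="ASA", mmu="ASA")
        index = index_families([fam], genomes)
        refs = reference_rates(index, [Phosphosite("hsa_p", 2, "S")], genomes)
        assert refs.available("S") and not refs.available("Y")
        with pytest.raises(UndefinedRateError):
            refs.rate("mmu", "Y")


class TestConservationIndex:
    def _refs(self, genomes, value):
        from phosmoca.conservation import ReferenceRates

        conserved = {(q, r): int(value * 1000) for q in genomes for r in "STY"}
        denom = {(q, r): 1000 for q in genomes for r in "STY"}
        for r in "STY":
            conserved[(genomes.reference, r)] = 1000
        return ReferenceRates(conserved, denom, genomes)

    def test_direct_sum_two_genomes(self):
        from phosmoca.conservation import ConservationProfile, ReferenceRates

        gset = GenomeSet(codes=("mmu", "cel", "hsa"), reference="hsa")
        prof = ConservationProfile(
            "m", "known", 10,
            conserved={"mmu": 8, "cel": 6, "hsa": 10},
            denominator={"mmu": 10, "cel": 10, "hsa": 10},
        )
        refs = ReferenceRates(
            {(q, "S"): n for q, n in [("mmu", 5), ("cel", 5), ("hsa", 10)]},
            {(q, "S"): 10 for q in gset},
            gset,
        )
        rec = conservation_index(prof, refs, {"S": 10})
        assert rec.ci == pytest.approx(0.4)
        assert rec.terms["hsa"] == pytest.approx(0.0)

    def test_null_when_c_equals_r(self, genomes):
        from phosmoca.conservation import ConservationProfile

        prof = ConservationProfile(
            "m", "known", 1000,
            conserved={q: 500 if q != "hsa" else 1000 for q in genomes},
            denominator={q: 1000 for q in genomes},
        )
        rec = conservation_index(prof, self._refs(genomes, 0.5), {"S": 7, "T": 3})
        assert rec.ci == pytest.approx(0.0)

    def test_reference_genome_term_is_zero(self, genomes):
        from phosmoca.conservation import ConservationProfile

        prof = ConservationProfile(
            "m", "known", 100,
            conserved={q: 70 if q != "hsa" else 100 for q in genomes},
            denominator={q: 100 for q in genomes},
        )
        rec = conservation_index(prof, self._refs(genomes, 0.5), {"T": 100})
        assert rec.terms["hsa"] == 0.0
        assert -8 <= rec.ci <= 8

    def test_matches_arithmetic_oracle_on_random_profiles(self, genomes):
        """CI equals an independently coded sum of differences to 1e-12."""
        from phosmoca.conservation import ConservationProfile, ReferenceRates

        rng = np.random.default_rng(3)
        for _ in range(20):
            den = 100
            conserved = {
                q: int(rng.integers(0, den + 1)) if q != "hsa" else den
                for q in genomes
            }
            prof = ConservationProfile(
                "m", "known", den, conserved, {q: den for q in genomes}
            )
            rc = {(q, r): int(rng.integers(0, 1001)) for q in genomes for r in "STY"}
            for r in "STY":
                rc[("hsa", r)] = 1000
            refs = ReferenceRates(rc, {(q, r): 1000 for q in genomes for r in "STY"}, genomes)
            mix = {"S": 5, "T": 3, "Y": 2}
            rec = conservation_index(prof, refs, mix)
            want = bf_ci(
                {q: conserved[q] / den for q in genomes},
                {(q, r): rc[(q, r)] / 1000 for q in genomes for r in "STY"},
                mix,
                genomes,
            )
            assert rec.ci == pytest.approx(want, abs=1e-12)

    def test_strictly_increasing_in_any_single_rate(self, genomes):
        from phosmoca.conservation import ConservationProfile

        base = {q: 50 if q != "hsa" else 100 for q in genomes}
        refs = self._refs(genomes, 0.5)
        prof = ConservationProfile("m", "known", 100, dict(base), {q: 100 for q in genomes})
        ci0 = conservation_index(prof, refs, {"S": 1}).ci
        for q in genomes.non_reference:
            bumped = dict(base)
            bumped[q] += 10
            prof2 = ConservationProfile(
                "m", "known", 100, bumped, {q: 100 for q in genomes}
            )
            assert conservation_index(prof2, refs, {"S": 1}).ci > ci0


class TestPipelineEqualsBruteForce:
    def test_full_recomputation_on_small_families(self, small_sim, rxxst, stp, genomes):
        """C_q, R_q and CI on ≤20 families equal a from-scratch recomputation."""
        index = index_families(small_sim.families, genomes)
        background = small_sim.sites
        refs = reference_rates(index, background, genomes)
        bf_refs = bf_reference_rates(small_sim.families, background, genomes)
        for (q, r), want in bf_refs.items():
            assert refs.rate(q, r) == pytest.approx(want, abs=1e-12)
        for pat in (rxxst, stp):
            sites = known_sites_of(small_sim, pat.motif_id)
            prof = motif_conservation_rates(index, sites, pat, genomes)
            want_rates = bf_rates(small_sim.families, sites, pat, genomes)
            for q in genomes:
                assert prof.rate(q) == pytest.approx(want_rates[q], abs=1e-12)
            mix = small_sim.truth.acceptor_mix(pat.motif_id)
            rec = conservation_index(prof, refs, mix)
            want_ci = bf_ci(want_rates, bf_refs, mix, genomes)
            assert rec.ci == pytest.approx(want_ci, abs=1e-12)


class TestSiteSetConservation:
    def test_extensionality(self, genomes, small_sim):
        """Identical site sets give identical profiles regardless of label."""
        index = index_families(small_sim.families, genomes)
        sites = [s for s in small_sim.sites if s.status == KNOWN][:30]
        a = site_set_conservation(index, sites, genomes, label="A")
        b = site_set_conservation(index, list(sites), genomes, label="B")
        assert a.conserved == b.conserved and a.denominator == b.denominator


class TestMatchSites:
    def test_filters_by_window(self, stp):
        seqs = {"P1": "ASPA", "P2": "ASAA"}
        sites = [Phosphosite("P1", 2, "S"), Phosphosite("P2", 2, "S"),
                 Phosphosite("P3", 1, "S")]
        out = match_sites(stp, sites, seqs)
        assert [(s.protein_id, s.position) for s in out] == [("P1", 2)]
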