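"""Unit and property tests for the deamidation kinetics module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngome import (
    AsnSite,
    HalfLifeTable,
    Weights,
    classify_site,
    find_asn_sites,
    hypothetical_scan,
    intrinsic_half_time,
    is_sequon,
    percent_deamidated,
    predict_protein,
    predict_site,
    protection_factor,
    protein_half_time,
)
from conftest import uniform_profile


class TestSiteDiscovery:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("MNGK", [(2, "G")]),                 # single internal Asn
            ("NGGN", []),                          # both Asn terminal
            ("MANGSANAK", [(3, "G"), (7, "A")]),  # two internal sites
            ("MAGK", []),                           # no Asn at all
        ],
    )
    def test_internal_asn_positions(self, sequence, expected):
        sites = find_asn_sites(sequence, "p")
        assert [(s.position, s.n_plus_1) for s in sites] == expected

    def test_sequon_flags_from_scan(self):
        # N-G-S completes the N[^P][ST] motif; N-A-K does not
        sites = find_asn_sites("MANGSANAK", "p")
        assert [s.is_sequon for s in sites] == [True, False]

    def test_sites_ascending_and_consistent(self):
        seq = "MNGNGNAK"
        sites = find_asn_sites(seq, "p")
        assert [s.position for s in sites] == sorted(s.position for s in sites)
        for s in sites:
            assert seq[s.position - 1] == "N"
            assert seq[s.position] == s.n_plus_1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            find_asn_sites("", "p")

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_asn_sites("MN1K", "p")

    def test_nonstandard_residue_is_not_a_site_but_may_be_n_plus_1(self):
        sites = find_asn_sites("MXNXK", "p")
        assert [(s.position, s.n_plus_1) for s in sites] == [(3, "X")]

    @pytest.mark.parametrize(
        "sequence, position, expected",
        [
            ("ANGT", 2, True),    # N-G-T
            ("ANPT", 2, False),   # Pro at N+1 blocks glycosylation
            ("ANG", 2, False),    # motif cannot complete at the terminus
            ("ANGS", 2, True),
            ("ANGA", 2, False),
        ],
    )
    def test_sequon_motif(self, sequence, position, expected):
        assert is_sequon(sequence, position) is expected

    def test_sequon_position_out_of_range(self):
        with pytest.raises(ValueError):
            is_sequon("ANGT", 9)


class TestHalfLifeTable:
    def test_lookup(self, tiny_table):
        site_g = AsnSite("p", 2, "G", False)
        site_a = AsnSite("p", 2, "A", False)
        assert intrinsic_half_time(site_g, tiny_table) == 1.0
        assert intrinsic_half_time(site_a, tiny_table) == 20.0

    def test_missing_residue_raises_naming_it(self, tiny_table):
        with pytest.raises(KeyError, match="'X'"):
            intrinsic_half_time(AsnSite("p", 2, "X", False), tiny_table)

    def test_gly_is_fastest_in_packaged_table(self, table):
        assert table["G"] == min(table.entries.values())
        assert all(v > 0 for v in table.entries.values())

    def test_packaged_table_covers_standard_residues_except_pro(self, table):
        assert "P" not in table
        assert set(table.entries) == set("ACDEFGHIKLMNQRSTVWY")

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            HalfLifeTable({"G": 0.0})

    def test_gly_must_be_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            HalfLifeTable({"G": 5.0, "A": 1.0})


class TestProtectionFactor:
    def test_fully_disordered_coil_unprotected(self, published_weights):
        assert protection_factor(0, 1.0, published_weights) == 1.0

    def test_helix_plus_full_order(self, published_weights):
        # exp(0.571 + 2.989) evaluated directly
        assert protection_factor(1, 0.0, published_weights) == pytest.approx(
            math.exp(3.560), rel=1e-12
        )

    def test_half_order_no_helix(self, published_weights):
        assert protection_factor(0, 0.5, published_weights) == pytest.approx(
            math.exp(1.4945), rel=1e-12
        )

    def test_disorder_out_of_range(self, published_weights):
        with pytest.raises(ValueError):
            protection_factor(0, 1.5, published_weights)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            Weights(helix=-0.1, order=1.0)

    @given(
        h=st.integers(0, 1),
        d=st.floats(0, 1),
        wh=st.floats(0, 5),
        wo=st.floats(0, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_protection_at_least_one(self, h, d, wh, wo):
        assert protection_factor(h, d, Weights(wh, wo)) >= 1.0

    @given(d1=st.floats(0, 1), d2=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_disorder(self, d1, d2, published_weights):
        # more disorder, less protection
        lo, hi = sorted((d1, d2))
        assert protection_factor(0, hi, published_weights) <= protection_factor(
            0, lo, published_weights
        )

    @given(d=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_helix_never_decreases_protection(self, d, published_weights):
        assert protection_factor(1, d, published_weights) >= protection_factor(
            0, d, published_weights
        )


class TestPercentDeamidated:
    def test_half_time_gives_fifty_percent(self):
        for t50 in (0.5, 1.0, 37.0, 1e4):
            assert percent_deamidated(t50, t50) == pytest.approx(50.0)

    def test_zero_time_zero_percent(self):
        assert percent_deamidated(3.0, 0.0) == 0.0

    def test_two_half_times(self):
        assert percent_deamidated(1.0, 2.0) == pytest.approx(75.0)

    def test_invalid_t50(self):
        with pytest.raises(ValueError):
            percent_deamidated(0.0, 1.0)

    @given(
        t50=st.floats(1e-3, 1e6),
        r1=st.floats(0, 50),
        r2=st.floats(0, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, t50, r1, r2):
        # times as multiples of t50; beyond ~53 half-times the double just
        # below 1 is unrepresentable and the percent rounds to exactly 100
        lo, hi = sorted((r1, r2))
        p_lo, p_hi = percent_deamidated(t50, lo * t50), percent_deamidated(t50, hi * t50)
        assert 0.0 <= p_lo <= p_hi < 100.0


class TestProteinHalfTime:
    def test_single_site_passthrough(self):
        assert protein_half_time([7.3]) == pytest.approx(7.3)

    def test_two_equal_clocks_halve(self):
        assert protein_half_time([10.0, 10.0]) == pytest.approx(5.0)

    def test_dominated_by_fast_site(self):
        assert protein_half_time([1.0, 1000.0]) == pytest.approx(1000.0 / 1001.0)

    def test_empty_list_is_no_sites_signal(self):
        assert protein_half_time([]) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            protein_half_time([1.0, -2.0])

    @given(st.lists(st.floats(1e-3, 1e5), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_never_exceeds_fastest_site(self, t50s):
        combined = protein_half_time(t50s)
        assert combined <= min(t50s) * (1 + 1e-12)

    @given(
        st.lists(st.floats(1e-3, 1e5), min_size=1, max_size=8),
        st.floats(1e-3, 1e5),
    )
    @settings(max_examples=100, deadline=None)
    def test_adding_a_site_never_slows_the_protein(self, t50s, extra):
        assert protein_half_time(t50s + [extra]) <= protein_half_time(t50s) * (1 + 1e-12)

    def test_matches_exponential_first_event_simulation(self):
        """Composition law vs a direct simulation of competing exponential
        clocks: the median first-event time over 10^5 draws."""
        rng = np.random.default_rng(20240917)
        t50s = [3.0, 11.0, 40.0]
        rates = np.log(2) / np.array(t50s)
        draws = rng.exponential(1.0 / rates, size=(100_000, len(t50s))).min(axis=1)
        simulated_median = float(np.median(draws))
        expected = protein_half_time(t50s)
        # Monte-Carlo error of a median at n=1e5 is ~0.6% here
        assert simulated_median == pytest.approx(expected, rel=0.02)


class TestClassification:
    @pytest.mark.parametrize(
        "t50, threshold, expected",
        [(1.0, 10.0, "positive"), (10.0, 10.0, "positive"), (11.0, 10.0, "negative")],
    )
    def test_threshold_rule_tie_positive(self, t50, threshold, expected):
        assert classify_site(t50, threshold) == expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_site(1.0, 0.0)


class TestPredictSite:
    def test_unprotected_site(self, tiny_table, published_weights):
        site = AsnSite("p", 2, "G", False)
        profile = uniform_profile(4, h=0, d=1.0)
        pred = predict_site(site, profile, published_weights, tiny_table)
        assert pred.t50_ngome == pytest.approx(1.0)
        assert pred.protection == pytest.approx(1.0)

    def test_helix_ordered_site(self, tiny_table, published_weights):
        site = AsnSite("p", 2, "G", False)
        profile = uniform_profile(4, h=1, d=0.0)
        pred = predict_site(site, profile, published_weights, tiny_table)
        assert pred.t50_ngome == pytest.approx(math.exp(3.560), rel=1e-12)

    def test_product_invariant(self, tiny_table, published_weights):
        site = AsnSite("p", 2, "A", False)
        profile = uniform_profile(4, h=1, d=0.25)
        pred = predict_site(site, profile, published_weights, tiny_table)
        assert pred.t50_ngome == pytest.approx(pred.t50_sequence * pred.protection)

    def test_missing_n_plus_1_reported_not_raised(self, tiny_table, published_weights):
        site = AsnSite("p", 2, "P", False)
        pred = predict_site(site, uniform_profile(4), published_weights, tiny_table)
        assert pred.t50_sequence is None and pred.t50_ngome is None
        assert pred.label is None

    def test_position_outside_profile(self, tiny_table, published_weights):
        site = AsnSite("p", 9, "G", False)
        with pytest.raises(ValueError, match="position 9"):
            predict_site(site, uniform_profile(4), published_weights, tiny_table)


class TestPredictProtein:
    def test_protein_half_time_bounded_by_fastest_site(self, table, published_weights):
        seq = "MNGANGSNAK"
        profile = uniform_profile(len(seq), h=0, d=0.9)
        pred = predict_protein(seq, "p", profile, published_weights, table)
        t50s = [s.t50_ngome for s in pred.site_predictions]
        assert pred.t50_protein <= min(t50s)
        assert pred.t50_protein == pytest.approx(protein_half_time(t50s))

    def test_no_internal_asn_marker(self, table, published_weights):
        pred = predict_protein("NAAN", "p", uniform_profile(4), published_weights, table)
        assert pred.site_predictions == ()
        assert pred.t50_protein is None

    def test_profile_length_mismatch(self, table, published_weights):
        with pytest.raises(ValueError, match="length"):
            predict_protein("MNGK", "p", uniform_profile(3), published_weights, table)


class TestHypotheticalScan:
    def test_substitution_uses_wild_type_n_plus_1(self, tiny_table, published_weights):
        # "MAGK": position 2 hypothetically N, N+1 is the real G at position 3
        scan = hypothetical_scan("MAGK", uniform_profile(4), published_weights, tiny_table)
        by_pos = {p.site.position: p for p in scan}
        assert by_pos[2].t50_ngome == pytest.approx(1.0)
        assert not by_pos[2].native

    def test_terminal_positions_never_scanned(self, tiny_table, published_weights):
        seq = "MAGKAG"
        scan = hypothetical_scan(seq, uniform_profile(len(seq)), published_weights, tiny_table)
        positions = {p.site.position for p in scan}
        assert 1 not in positions and len(seq) not in positions
        assert positions == set(range(2, len(seq)))

    def test_scan_agrees_with_predict_at_real_asn(self, table, published_weights):
        seq = "MANGSANAK"
        profile = uniform_profile(len(seq), h=0, d=0.4)
        scan = {p.site.position: p for p in
                hypothetical_scan(seq, profile, published_weights, table)}
        for site in find_asn_sites(seq, ""):
            direct = predict_site(site, profile, published_weights, table)
            assert scan[site.position].native
            assert scan[site.position].t50_ngome == pytest.approx(direct.t50_ngome)
            assert scan[site.position].site.is_sequon == site.is_sequon

    def test_strand_and_coil_equivalent(self, table, published_weights):
        """E never protects: profiles differing only by E/C at some positions
        give identical predictions (both map to H=0)."""
        from ngome import build_profile, DisorderTrack, SecondaryStructureTrack

        seq = "MANGSANAK"
        dis = DisorderTrack(scores=(0.4,) * len(seq), source="file")
        a = build_profile(seq, SecondaryStructureTrack("CCCCCCCCC"), dis)
        b = build_profile(seq, SecondaryStructureTrack("CEECCEECC"), dis)
        pa = hypothetical_scan(seq, a, published_weights, table)
        pb = hypothetical_scan(seq, b, published_weights, table)
        assert [p.t50_ngome for p in pa] == [p.t50_ngome for p in pb]
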