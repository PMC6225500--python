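import pytest

from barcodekit import (
    build_all_consensus,
    build_consensus,
    count_consensus_differences,
    find_species_specific_sites,
    identify_query,
    load_uncaria_reference,
    read_consensus_table,
    write_consensus_table,
)
from barcodekit.consensus import ConsensusError, ConsensusProfile, differing_positions
from barcodekit.seqio import SequenceRecord, build_alignment


def profile(species, codes, positions=None):
    from barcodekit.alphabet import expand

    positions = positions or tuple(range(1, len(codes) + 1))
    states = tuple(
        frozenset() if c == "-" else expand(c) for c in codes
    )
    return ConsensusProfile(species=species, positions=tuple(positions), states=states)


def aln_of(*specs):
    recs = [SequenceRecord(id=i, species=s, residues=r) for i, s, r in specs]
    return build_alignment(recs, {r.id: r.species for r in recs})


class TestBuildConsensus:
    def test_single_sequence_is_identity(self):
        aln = aln_of(("a1", "A", "ACGT"))
        p = build_consensus(aln, {"a1": "A"}, "A")
        assert p.codes() == ["A", "C", "G", "T"]

    @pytest.mark.parametrize(
        "residues,code",
        [(("ACGT", "GCGT"), "R"), (("GCGT", "TCGT"), "K"), (("ACGT", "CCGT"), "M")],
    )
    def test_polymorphism_becomes_degenerate_code(self, residues, code):
        aln = aln_of(("a1", "A", residues[0]), ("a2", "A", residues[1]))
        p = build_consensus(aln, {"a1": "A", "a2": "A"}, "A")
        assert p.code(0) == code

    def test_degenerate_inputs_expand_before_union(self):
        aln = aln_of(("a1", "A", "RCGT"), ("a2", "A", "GCGT"))
        p = build_consensus(aln, {"a1": "A", "a2": "A"}, "A")
        assert p.states[0] == frozenset("AG")

    def test_all_gap_column_is_gap(self):
        aln = aln_of(("a1", "A", "-CGT"), ("a2", "A", "-CGT"))
        p = build_consensus(aln, {"a1": "A", "a2": "A"}, "A")
        assert p.code(0) == "-"

    def test_mixed_gap_base_keeps_bases_with_flag(self):
        aln = aln_of(("a1", "A", "-CGT"), ("a2", "A", "ACGT"))
        p = build_consensus(aln, {"a1": "A", "a2": "A"}, "A")
        assert p.states[0] == frozenset("A")
        assert p.gap_seen[0] is True

    def test_unknown_species_errors(self):
        aln = aln_of(("a1", "A", "ACGT"))
        with pytest.raises(ConsensusError):
            build_consensus(aln, {"a1": "A"}, "Z")


class TestSpeciesSpecificSites:
    def test_disjoint_singletons_specific_for_both(self):
        table = find_species_specific_sites(
            [profile("A", "ACGT"), profile("B", "GCGT")]
        )
        assert ("A", 1, "A") in table.rows
        assert ("B", 1, "G") in table.rows

    def test_overlapping_degenerate_is_not_specific(self):
        table = find_species_specific_sites(
            [profile("A", "ACGT"), profile("B", "RCGT")]  # {A} vs {A,G}
        )
        assert table.rows == []

    def test_gap_vs_base_counts_as_specific(self):
        table = find_species_specific_sites(
            [profile("A", "-CGT"), profile("B", "ACGT")]
        )
        positions = {(sp, pos) for sp, pos, _ in table.rows}
        assert ("A", 1) in positions and ("B", 1) in positions

    def test_column_count_mismatch_errors(self):
        with pytest.raises(ConsensusError):
            find_species_specific_sites([profile("A", "ACGT"), profile("B", "ACG")])


class TestCountDifferences:
    def test_identical_profiles_zero(self):
        p = profile("A", "ACGTR")
        assert count_consensus_differences(p, profile("B", "ACGTR")) == 0

    def test_symmetry(self):
        p1, p2 = profile("A", "ACGT-"), profile("B", "GCGTA")
        assert count_consensus_differences(p1, p2) == count_consensus_differences(
            p2, p1
        )

    def test_degenerate_overlap_is_compatible(self):
        # Y = {C,T} overlaps {T}: no difference
        assert count_consensus_differences(
            profile("A", "YCGT"), profile("B", "TCGT")
        ) == 0

    def test_gap_vs_base_is_a_difference(self):
        assert count_consensus_differences(
            profile("A", "-CGT"), profile("B", "TCGT")
        ) == 1


class TestUncariaReferenceTable:
    """The packaged genus-wide ITS diagnostic-position database."""

    @pytest.fixture(scope="class")
    def profiles(self):
        return {p.species: p for p in load_uncaria_reference()}

    def test_shape(self, profiles):
        assert len(profiles) == 12
        assert all(len(p.positions) == 31 for p in profiles.values())
        ref = profiles["U. rhynchophylloides"]
        assert ref.positions[0] == 75 and ref.code(0) == "T"

    def test_degenerate_codes_decode(self, profiles):
        mac = profiles["U. macrophylla"]
        i = mac.positions.index(445)
        assert mac.states[i] == frozenset("GC")  # S

    def test_six_site_separation_of_sinensis(self, profiles):
        """A query matching C-118, G-152, A-247, T-447, T-493, C-580 against
        the reference consensus is U. sinensis."""
        a, b = profiles["U. sinensis"], profiles["U. rhynchophylloides"]
        assert count_consensus_differences(a, b) == 6
        assert differing_positions(a, b) == [118, 152, 247, 447, 493, 580]

    def test_single_insertion_separates_yunnanensis_from_lanosa(self, profiles):
        a, b = profiles["U. yunnanensis"], profiles["U. lanosa"]
        assert count_consensus_differences(a, b) == 1
        assert differing_positions(a, b) == [602]

    def test_roundtrip_write_read_identity(self, profiles, tmp_path):
        original = load_uncaria_reference()
        out = tmp_path / "table.tsv"
        write_consensus_table(original, out)
        again = read_consensus_table(out)
        assert [(p.species, p.positions, p.states) for p in again] == [
            (p.species, p.positions, p.states) for p in original
        ]

    def test_identify_sinensis_query(self, profiles):
        all_profiles = load_uncaria_reference()
        sin = profiles["U. sinensis"]
        query = "".join(sin.codes())
        ranking = identify_query(query, all_profiles)
        top_species, n_bad, matched = ranking[0]
        assert top_species == "U. sinensis"
        assert n_bad == 0
        # every lower rank is strictly or equally worse
        assert all(n_bad <= r[1] for r in ranking[1:])


class TestIdentifyQuery:
    def test_query_equal_to_consensus_ranks_first(self):
        profiles = [profile("A", "ACGT"), profile("B", "GCTT")]
        ranking = identify_query("ACGT", profiles)
        assert ranking[0][0] == "A" and ranking[0][1] == 0

    def test_far_query_has_deterministic_ranking(self):
        profiles = [profile("A", "AAAA"), profile("B", "CCCC"),
                    profile("C", "GGGG")]
        r1 = identify_query("TTTT", profiles)
        r2 = identify_query("TTTT", profiles)
        assert r1 == r2
        assert all(n == 4 for _, n, _ in r1)
        assert [s for s, _, _ in r1] == ["A", "B", "C"]  # alphabetic tie-break

    def test_length_mismatch_errors(self):
        with pytest.raises(ConsensusError):
            identify_query("ACG", [profile("A", "ACGT"), profile("B", "GCGT")])
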