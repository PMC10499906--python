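"""In silico proteolysis, peptide masses and disulphide-connected fragments."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltpdigest.core import DisulphideTopology, EMPTY_TOPOLOGY, PHOSPHO_S, ProteinIsoform
from ltpdigest.digest import (
    CHYMOTRYPSIN,
    TRYPSIN,
    CleavageRule,
    TheoreticalPeptide,
    build_fragment_components,
    digest,
    interbridge_free_intervals,
    nonreduced_observable,
    peptide_mass,
    predict_cleavage_sites,
)

WATER_MONO = 18.0105646863


def brute_force_full_digest(sequence, rules, max_missed, length_range):
    """Independent oracle: enumerate every (boundary_i, boundary_j) window."""
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if any(
            sequence[i] in r.p1_residues
            and sequence[i + 1] not in r.blocked_p1prime
            for r in rules
        )
    ]
    bounds = [0] + sites + [len(sequence)]
    out = set()
    for i, j in itertools.combinations(range(len(bounds)), 2):
        missed = j - i - 1
        length = bounds[j] - bounds[i]
        if missed <= max_missed and length_range[0] <= length <= length_range[1]:
            out.add((bounds[i] + 1, bounds[j]))
    return out


class TestPredictCleavageSites:
    def test_proline_blocks_tryptic_cleavage(self):
        iso = ProteinIsoform("X", "AKPGRG")
        sites = predict_cleavage_sites(iso, TRYPSIN)
        assert [s.position for s in sites] == [5]

    def test_prup3_tryptic_sites(self, isoform):
        sites = predict_cleavage_sites(isoform, TRYPSIN)
        assert len(sites) == 7
        assert [s.position for s in sites] == [18, 32, 39, 44, 52, 72, 80]

    def test_prup3_chymotryptic_sites_include_L10(self, isoform):
        sites = predict_cleavage_sites(isoform, CHYMOTRYPSIN)
        positions = [s.position for s in sites]
        assert len(positions) == 6
        assert 10 in positions

    def test_terminal_residue_never_a_site(self):
        iso = ProteinIsoform("X", "AGK")
        assert predict_cleavage_sites(iso, TRYPSIN) == []

    def test_sites_unique_and_ascending(self, isoform):
        for rule in (TRYPSIN, CHYMOTRYPSIN):
            pos = [s.position for s in predict_cleavage_sites(isoform, rule)]
            assert pos == sorted(set(pos))


class TestDigest:
    def test_akrg_no_missed(self):
        iso = ProteinIsoform("X", "AKRG")
        peps = digest(iso, [TRYPSIN], max_missed=0, specificity="full")
        assert {(p.start, p.end) for p in peps} == {(1, 2), (3, 3), (4, 4)}

    def test_akrg_one_missed_adds_windows(self):
        iso = ProteinIsoform("X", "AKRG")
        peps = digest(iso, [TRYPSIN], max_missed=1, specificity="full")
        assert {(p.start, p.end) for p in peps} == {
            (1, 2), (3, 3), (4, 4), (1, 3), (3, 4),
        }

    def test_prup3_full_digest_contains_key_products(self, isoform):
        peps = digest(isoform, max_missed=2, specificity="full")
        intervals = {(p.start, p.end) for p in peps}
        assert (53, 72) in intervals  # dominant non-reduced peptide Q53-K72
        assert (80, 91) in intervals

    def test_semi_relaxes_one_terminus(self):
        iso = ProteinIsoform("X", "AKRG")
        semi = {
            (p.start, p.end)
            for p in digest(iso, [TRYPSIN], max_missed=0, specificity="semi")
        }
        assert (1, 1) in semi  # ragged C-terminus inside the first product
        assert (2, 3) not in semi  # both termini non-specific

    def test_nonspecific_requires_length_bound_on_long_chains(self, isoform):
        with pytest.raises(ValueError, match="length bound"):
            digest(isoform, specificity="none")

    def test_deterministic_order(self, isoform):
        peps = digest(isoform, max_missed=2, specificity="full")
        assert [(p.start, p.end) for p in peps] == sorted(
            (p.start, p.end) for p in peps
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
        max_missed=st.integers(0, 3),
    )
    def test_full_digest_matches_brute_force_oracle(self, seq, max_missed):
        iso = ProteinIsoform("X", seq)
        got = {
            (p.start, p.end)
            for p in digest(
                iso, max_missed=max_missed, specificity="full",
                length_range=(1, 99),
            )
        }
        expected = brute_force_full_digest(
            seq, [TRYPSIN, CHYMOTRYPSIN], max_missed, (1, 99)
        )
        assert got == expected

    def test_missed_cleavage_counts(self, isoform):
        peps = digest(isoform, max_missed=2, specificity="full")
        sites = {
            s.position
            for rule in (TRYPSIN, CHYMOTRYPSIN)
            for s in predict_cleavage_sites(isoform, rule)
        }
        for p in peps:
            internal = [x for x in sites if p.start <= x <= p.end - 1]
            assert p.missed_cleavages == len(internal)


class TestPeptideMass:
    def test_glycine_monoisotopic(self):
        assert peptide_mass("G") == pytest.approx(75.0320, abs=1e-3)

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    def test_phospho_additivity(self):
        base = peptide_mass("S")
        assert peptide_mass("S", [(1, PHOSPHO_S)]) == pytest.approx(
            base + 79.9663, abs=1e-4
        )

    def test_mod_on_disallowed_residue_rejected(self):
        with pytest.raises(ValueError, match="not allowed"):
            peptide_mass("G", [(1, PHOSPHO_S)])

    def test_average_exceeds_monoisotopic(self):
        seq = "ITCGQVSSALAPCIPYVR"
        assert peptide_mass(seq, kind="avg") > peptide_mass(seq, kind="mono")


class TestFragmentComponents:
    def test_single_cut_bridged_into_one_component(self, isoform, topology):
        comps = build_fragment_components(isoform, {52}, topology)
        assert len(comps) == 1
        assert comps[0].intervals == ((1, 52), (53, 91))
        assert set(comps[0].bridges) == {(3, 50), (13, 27), (28, 73), (48, 87)}

    def test_central_peptide_freed_by_two_cuts(self, isoform, topology):
        comps = build_fragment_components(isoform, {52, 72}, topology)
        by_intervals = {c.intervals: c for c in comps}
        assert ((53, 72),) in by_intervals
        assert ((1, 52), (73, 91)) in by_intervals
        free = by_intervals[((53, 72),)]
        assert free.bridges == ()

    @pytest.mark.parametrize("cuts", [set(), {52}, {52, 72}, {10, 30, 60, 85}])
    def test_hydrolysis_mass_conservation(self, isoform, cuts):
        comps = build_fragment_components(isoform, cuts, EMPTY_TOPOLOGY)
        assert len(comps) == len(cuts) + 1
        for kind, water in (("mono", WATER_MONO), ("avg", 18.0153)):
            total = sum(
                peptide_mass(m.sequence, kind=kind)
                for c in comps
                for m in c.members
            )
            parent = peptide_mass(isoform.sequence, kind=kind)
            expected = parent + len(cuts) * water
            assert total == pytest.approx(expected, rel=1e-6)

    def test_disulphides_remove_two_hydrogens_each(self, isoform, topology):
        comps = build_fragment_components(isoform, {52}, topology)
        raw = sum(peptide_mass(m.sequence) for m in comps[0].members)
        assert comps[0].mass_mono == pytest.approx(raw - 8 * 1.007825, abs=1e-4)

    def test_components_partition_fragments(self, isoform, topology):
        comps = build_fragment_components(isoform, {20, 52, 72, 85}, topology)
        intervals = sorted(iv for c in comps for iv in c.intervals)
        assert intervals == [(1, 20), (21, 52), (53, 72), (73, 85), (86, 91)]

    def test_component_mass_invariant_to_bridge_order(self, isoform, topology):
        reversed_topo = DisulphideTopology(tuple(reversed(topology.pairs)))
        a = build_fragment_components(isoform, {52, 72}, topology)
        b = build_fragment_components(isoform, {52, 72}, reversed_topo)
        assert sorted(c.mass_mono for c in a) == pytest.approx(
            sorted(c.mass_mono for c in b)
        )


class TestNonreducedObservable:
    def test_interbridge_peptide_observable(self, isoform, topology):
        pep = TheoreticalPeptide(53, 72, isoform.slice(53, 72))
        assert nonreduced_observable(pep, topology)

    def test_bridge_spanning_peptide_not_observable(self, isoform, topology):
        pep = TheoreticalPeptide(1, 26, isoform.slice(1, 26))
        assert not nonreduced_observable(pep, topology)

    def test_everything_observable_without_bridges(self, isoform):
        pep = TheoreticalPeptide(1, 26, isoform.slice(1, 26))
        assert nonreduced_observable(pep, EMPTY_TOPOLOGY)


class TestInterbridgeFreeIntervals:
    def test_central_free_region_between_cys50_and_cys73(self, isoform, topology):
        assert (51, 72) in interbridge_free_intervals(isoform, topology)

    def test_tail_after_last_paired_cys(self, isoform, topology):
        assert (88, 91) in interbridge_free_intervals(isoform, topology)

    def test_empty_topology_gives_whole_chain(self, isoform):
        assert interbridge_free_intervals(isoform, EMPTY_TOPOLOGY) == [(1, 91)]
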