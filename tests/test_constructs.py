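"""Mutant design: compensatory quartets, lock mutants, label round trips."""

import pytest
from hypothesis import given, settings, strategies as st

from lm2r.constructs import (
    BasePair,
    Construct,
    Helix,
    MutantSpec,
    MutationError,
    Substitution,
    apply_mutations,
    design_compensatory_quartet,
    design_double_pair_lock,
    helix_from_span,
    is_watson_crick,
    can_pair,
)


@pytest.fixture
def toy():
    return Construct(name="toy", sequence="GGGGAAAACCCC")


class TestApplyMutations:
    def test_empty_spec_is_identity(self, toy):
        assert apply_mutations(toy, MutantSpec()).sequence == toy.sequence

    def test_stabilizer_mutant_changes_exactly_four_positions(self, add_bundle):
        """The published P2-stabilizing variant substitutes four nucleotides."""
        construct, _, locks = add_bundle
        mutant = apply_mutations(construct, MutantSpec.from_label(locks["MutP2"]))
        diffs = [
            p
            for p in construct.positions()
            if construct.base_at(p) != mutant.base_at(p)
        ]
        assert diffs == [29, 30, 40, 41]
        assert mutant.base_at(29) == "C" and mutant.base_at(30) == "G"
        assert mutant.base_at(40) == "C" and mutant.base_at(41) == "G"

    def test_wild_type_mismatch_is_rejected_with_context(self, toy):
        spec = MutantSpec((Substitution(5, "G", "C"),))  # position 5 holds A
        with pytest.raises(MutationError, match=r"position 5.*expected 'G'"):
            apply_mutations(toy, spec)


class TestCompensatoryQuartet:
    def test_gc_pair_design_matches_published_labels(self):
        """A G-C pair yields G->C, C->G singles and the swapped double."""
        seq = "A" * 200 + "G" + "A" * 15 + "C" + "A" * 20
        construct = Construct(name="junction", sequence=seq)
        mut_a, mut_b, mut_ab = design_compensatory_quartet(construct, BasePair(201, 217))
        assert (mut_a.label, mut_b.label, mut_ab.label) == (
            "G201C",
            "C217G",
            "G201C-C217G",
        )

    def test_au_pair_on_riboswitch(self, add_bundle):
        construct, helices, _ = add_bundle
        mut_a, mut_b, mut_ab = design_compensatory_quartet(
            construct, helices["P1"].pairs[0]
        )
        assert (mut_a.label, mut_b.label, mut_ab.label) == ("A19U", "U77A", "A19U-U77A")

    def test_single_then_single_equals_double(self, add_bundle):
        construct, helices, _ = add_bundle
        mut_a, mut_b, mut_ab = design_compensatory_quartet(
            construct, helices["P4B"].pairs[1]
        )
        via_singles = apply_mutations(apply_mutations(construct, mut_a), mut_b)
        assert via_singles.sequence == apply_mutations(construct, mut_ab).sequence

    def test_gu_wobble_resolves_to_watson_crick_double(self):
        construct = Construct(name="gu", sequence="GAAAAU" + "A" * 6)
        mut_a, mut_b, mut_ab = design_compensatory_quartet(construct, BasePair(1, 6))
        mutant = apply_mutations(construct, mut_ab)
        assert is_watson_crick(mutant.base_at(1), mutant.base_at(6))

    def test_singles_break_pair_double_restores(self, add_bundle):
        construct, helices, _ = add_bundle
        for helix in helices.values():
            for pair in helix.pairs:
                mut_a, mut_b, mut_ab = design_compensatory_quartet(construct, pair)
                for single in (mut_a, mut_b):
                    mutant = apply_mutations(construct, single)
                    assert not can_pair(mutant.base_at(pair.i), mutant.base_at(pair.j))
                double = apply_mutations(construct, mut_ab)
                assert is_watson_crick(double.base_at(pair.i), double.base_at(pair.j))

    def test_unpairable_bases_rejected(self, toy):
        with pytest.raises(MutationError, match="not a pairable"):
            design_compensatory_quartet(toy, BasePair(1, 5))  # G-A


class TestDoublePairLock:
    def test_lock_labels_match_published_designs(self, add_bundle):
        """Strand-swap locks reproduce the printed lock-P1 and lock-P4B."""
        construct, helices, locks = add_bundle
        assert design_double_pair_lock(construct, helices["P1"]).label == locks["lock-P1"]
        assert design_double_pair_lock(construct, helices["P4B"]).label == locks["lock-P4B"]

    @pytest.mark.parametrize("style", ["swap", "transversion"])
    def test_lock_preserves_watson_crick_pairing(self, add_bundle, style):
        construct, helices, _ = add_bundle
        for helix in helices.values():
            spec = design_double_pair_lock(construct, helix, style=style)
            locked = apply_mutations(construct, spec)
            for pair in helix.pairs[:2]:
                assert is_watson_crick(locked.base_at(pair.i), locked.base_at(pair.j))
                # the pair identity actually changed
                assert (locked.base_at(pair.i), locked.base_at(pair.j)) != (
                    construct.base_at(pair.i),
                    construct.base_at(pair.j),
                )

    def test_too_short_helix_rejected(self, add_bundle):
        construct, helices, _ = add_bundle
        short = Helix("short", helices["P1"].pairs[:1])
        with pytest.raises(ValueError, match="no two consecutive pairs"):
            design_double_pair_lock(construct, short)


@st.composite
def mutant_specs(draw):
    n = draw(st.integers(1, 5))
    positions = draw(
        st.lists(st.integers(-20, 300), min_size=n, max_size=n, unique=True)
    )
    subs = []
    for p in positions:
        wt, new = draw(
            st.tuples(st.sampled_from("ACGU"), st.sampled_from("ACGU")).filter(
                lambda t: t[0] != t[1]
            )
        )
        subs.append(Substitution(p, wt, new))
    return MutantSpec(tuple(subs))


class TestLabels:
    @settings(max_examples=200, deadline=None)
    @given(mutant_specs())
    def test_label_round_trip(self, spec):
        assert MutantSpec.from_label(spec.label) == spec

    def test_wt_label(self):
        assert MutantSpec().label == "WT"
        assert MutantSpec.from_label("WT") == MutantSpec()

    def test_labels_use_biological_numbering(self, add_bundle):
        """A construct offset shifts labels to biological coordinates."""
        construct, _, _ = add_bundle
        assert construct.numbering_offset != 0
        mut_a, _, _ = design_compensatory_quartet(construct, BasePair(19, 77))
        assert mut_a.label == "A19U"


class TestInvariants:
    def test_construct_rejects_bad_sequence(self):
        with pytest.raises(ValueError, match="non-RNA"):
            Construct(name="bad", sequence="ACGT")
        with pytest.raises(ValueError):
            Construct(name="empty", sequence="")

    def test_probed_region_bounds_checked(self):
        with pytest.raises(ValueError, match="probed_region"):
            Construct(name="x", sequence="ACGU", probed_region=(1, 99))

    def test_reference_loops_disjoint_from_probed(self):
        with pytest.raises(ValueError, match="overlap"):
            Construct(
                name="x",
                sequence="ACGUACGU",
                probed_region=(1, 9),
                reference_loops=((2, 3), ()),
            )

    def test_helix_requires_stacked_pairs(self):
        with pytest.raises(ValueError, match="stacked"):
            Helix("bad", (BasePair(1, 10), BasePair(3, 8)))
        assert helix_from_span("ok", 1, 10, 3).pairs == (
            BasePair(1, 10),
            BasePair(2, 9),
            BasePair(3, 8),
        )
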