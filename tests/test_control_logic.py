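import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_min_covers
from petrirec.control_logic import (
    GROUP_I,
    GROUP_II,
    GROUP_III,
    ControlFunction,
    ControlledReaction,
    classify,
    derive_controls,
    minimize_boolean,
    to_subnet,
)
from petrirec.decomposition import is_applicable
from petrirec.errors import (
    MultiValuedControlError,
    NoSeparationError,
    ValidationError,
)
from petrirec.petri_core import enabled_transitions

PLACES4 = ["A", "B", "C", "D"]


def cf(terms, places=PLACES4):
    return ControlFunction.of(terms, places)


class TestControlFunction:
    def test_always(self):
        f = ControlFunction.always()
        assert f.is_always and f.evaluate((0, 0), {"A": 0, "B": 1})
        assert f.infix() == "1"

    def test_evaluation(self):
        f = cf([[("A", True), ("B", False)]])
        idx = {p: i for i, p in enumerate(PLACES4)}
        assert f.evaluate((1, 0, 0, 0), idx)
        assert not f.evaluate((1, 1, 0, 0), idx)
        assert not f.evaluate((0, 0, 0, 0), idx)

    def test_infix_uses_dash_for_not(self):
        f = cf([[("A", True), ("D", False)], [("B", True)]])
        assert f.infix() == "B ∨ (A ∧ -D)"

    def test_duplicate_place_in_term_rejected(self):
        with pytest.raises(ValidationError):
            cf([[("A", True), ("A", False)]])

    def test_superset_term_rejected(self):
        with pytest.raises(ValidationError):
            cf([[("A", True)], [("A", True), ("B", True)]])


class TestClassify:
    caps = (1, 1, 1, 1)

    def test_group_i_when_no_applicable_terminal(self):
        r = (-1, 1, 0, 0)
        assert classify(r, [(1, 0, 0, 0)], [(0, 1, 1, 1)], self.caps) == GROUP_I

    def test_group_ii_when_on_state_equals_terminal(self):
        r = (-1, 1, 0, 0)
        assert classify(r, [(1, 0, 0, 0)], [(1, 0, 0, 0)], self.caps) == GROUP_II

    def test_group_iii_otherwise(self, toy):
        r4 = toy.expected["r4"]
        x0 = toy.expected["states"][0]
        x4 = toy.expected["states"][4]
        assert classify(r4, [x0], [x4], (1,) * 6) == GROUP_III

    def test_empty_on_states_rejected(self):
        with pytest.raises(ValidationError):
            classify((-1, 0, 0, 0), [], [], self.caps)


class TestMinimizeBoolean:
    def test_toy_r4_case_yields_exactly_two_single_literals(self, toy):
        x0 = toy.expected["states"][0]
        x4 = toy.expected["states"][4]
        places = toy.expected["components"]
        covers = minimize_boolean([x0], [x4], places)
        got = {f.terms for f in covers}
        assert got == {((("A", True),),), ((("F", False),),)}

    def test_empty_off_set_gives_constant_true(self):
        covers = minimize_boolean([(1, 0, 0, 0)], [], PLACES4)
        assert len(covers) == 1 and covers[0].is_always

    def test_overlap_raises(self):
        with pytest.raises(NoSeparationError):
            minimize_boolean([(1, 0, 0, 0)], [(1, 0, 0, 0)], PLACES4)

    def test_two_term_cover_forced(self):
        # on-states disagree everywhere relevant: no single term covers both
        on = [(1, 0, 0, 0), (0, 1, 0, 0)]
        off = [(0, 0, 0, 0)]
        covers = minimize_boolean(on, off, PLACES4)
        assert all(len(f.terms) == 2 for f in covers)
        oracle = oracle_min_covers(on, off, PLACES4)
        assert {frozenset(map(frozenset, f.terms)) for f in covers} == oracle

    def test_separation_always_holds(self):
        on = [(1, 1, 0, 1), (1, 0, 0, 1)]
        off = [(0, 1, 1, 1), (1, 1, 1, 0)]
        idx = {p: i for i, p in enumerate(PLACES4)}
        for f in minimize_boolean(on, off, PLACES4):
            assert all(f.evaluate(m, idx) for m in on)
            assert not any(f.evaluate(m, idx) for m in off)


@settings(max_examples=120, deadline=None)
@given(data=st.data())
def test_minimize_matches_exhaustive_search(data):
    n = data.draw(st.integers(min_value=2, max_value=4))
    places = PLACES4[:n]
    markings = list(itertools.product((0, 1), repeat=n))
    chosen = data.draw(
        st.lists(st.sampled_from(markings), min_size=2, max_size=6, unique=True)
    )
    split = data.draw(st.integers(min_value=1, max_value=len(chosen) - 1))
    on, off = chosen[:split], chosen[split:]
    ours = {frozenset(map(frozenset, f.terms)) for f in minimize_boolean(on, off, places)}
    assert ours == oracle_min_covers(on, off, places)


class TestDeriveControls:
    def test_toy_r4_two_alternatives(self, toy):
        x0 = toy.expected["states"][0]
        x4 = toy.expected["states"][4]
        crs = derive_controls(
            toy.expected["r4"], [x0], [x4], (1,) * 6, toy.expected["components"]
        )
        assert [cr.f.terms for cr in crs] == toy.expected["r4_controls"]

    def test_group_i_single_constant_true(self):
        crs = derive_controls((-1, 1, 0, 0), [(1, 0, 0, 0)], [(0, 1, 1, 1)],
                              (1, 1, 1, 1), PLACES4)
        assert len(crs) == 1 and crs[0].f.is_always

    def test_group_ii_empty(self):
        crs = derive_controls((-1, 1, 0, 0), [(1, 0, 0, 0)], [(1, 0, 0, 0)],
                              (1, 1, 1, 1), PLACES4)
        assert crs == []

    def test_forced_two_term_cover(self):
        # the reaction is applied at two states whose only consistent
        # literals cannot exclude both terminals with one term
        r = (0, 0, 0, 1)
        on = [(1, 0, 0, 0), (0, 1, 0, 0)]
        terminals = [(0, 0, 0, 0)]
        crs = derive_controls(r, on, terminals, (1, 1, 1, 1), PLACES4)
        assert crs and all(len(cr.f.terms) == 2 for cr in crs)

    def test_multivalued_group_iii_rejected(self):
        with pytest.raises(MultiValuedControlError):
            derive_controls((1, 0, 0, 0), [(0, 0, 0, 1)], [(1, 0, 0, 1)],
                            (2, 1, 1, 1), PLACES4)


class TestToSubnet:
    places = ["A", "B", "C", "F"]
    caps = (1, 1, 1, 1)

    def test_read_arc_from_positive_literal(self):
        cr = ControlledReaction(
            r=(0, -1, 1, 0), f=ControlFunction.of([[("A", True)]], self.places)
        )
        net = to_subnet(cr, self.places, self.caps)
        (t,) = net.transitions
        assert net.inputs(t) == {"B": 1}
        assert net.outputs(t) == {"C": 1}
        assert net.reads(t) == ["A"] and net.inhibitors(t) == []

    def test_inhibitory_arc_from_negative_literal(self):
        cr = ControlledReaction(
            r=(0, -1, 1, 0), f=ControlFunction.of([[("F", False)]], self.places)
        )
        net = to_subnet(cr, self.places, self.caps)
        (t,) = net.transitions
        assert net.inhibitors(t) == ["F"] and net.reads(t) == []

    def test_two_terms_two_transitions_same_standard_arcs(self):
        cr = ControlledReaction(
            r=(-1, 1, 0, 0),
            f=ControlFunction.of([[("C", True)], [("F", False)]], self.places),
        )
        net = to_subnet(cr, self.places, self.caps)
        assert len(net.transitions) == 2
        for t in net.transitions:
            assert net.inputs(t) == {"A": 1} and net.outputs(t) == {"B": 1}
        controls = {
            (tuple(net.reads(t)), tuple(net.inhibitors(t))) for t in net.transitions
        }
        assert controls == {(("C",), ()), ((), ("F",))}

    def test_constant_true_single_uncontrolled_transition(self):
        cr = ControlledReaction(r=(-1, 1, 0, 0), f=ControlFunction.always())
        net = to_subnet(cr, self.places, self.caps)
        (t,) = net.transitions
        assert net.reads(t) == [] and net.inhibitors(t) == []

    def test_subnet_faithfulness(self):
        # some transition enabled  <=>  r applicable and f true
        cr = ControlledReaction(
            r=(0, -1, 1, 0),
            f=ControlFunction.of([[("A", True)], [("F", False)]], self.places),
        )
        net = to_subnet(cr, self.places, self.caps)
        idx = {p: i for i, p in enumerate(self.places)}
        for m in itertools.product((0, 1), repeat=4):
            expected = is_applicable(cr.r, m, self.caps) and cr.f.evaluate(m, idx)
            assert bool(enabled_transitions(net, m)) == expected


def test_literal_redundancy_property(phosphate_sm):
    """A place whose presence is already implied by the reaction's own
    applicability never shows up as the sole distinguishing literal."""
    from petrirec.timeseries import difference_matrix

    caps = phosphate_sm.capacities
    terminals = phosphate_sm.terminal_states()
    for d in difference_matrix(phosphate_sm):
        on = [phosphate_sm.states[w] for w in d.witnesses]
        crs = derive_controls(d.entries, on, terminals, caps, phosphate_sm.components)
        for cr in crs:
            for term in cr.f.terms:
                if len(term) != 1:
                    continue
                ((place, positive),) = term
                i = phosphate_sm.components.index(place)
                if positive and d.entries[i] < 0:
                    # input place under boolean capacity: present at every
                    # applicable marking, cannot separate on from off
                    pytest.fail(
                        f"input place {place} used as sole control literal"
                    )
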