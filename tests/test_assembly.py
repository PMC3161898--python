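import random

import pytest

from petrirec.assembly import (
    build_catalog,
    compose_net,
    enumerate_nets,
    verify_replay,
    wiring_signature,
)
from petrirec.control_logic import ControlFunction
from petrirec.decomposition import Caps
from petrirec.errors import (
    CapsExceededError,
    InfeasibleError,
    ValidationError,
)
from petrirec.fixtures import random_instance
from petrirec.petri_core import INPUT, OUTPUT, Arc, ExtendedPetriNet, Place, reaction_vector_of
from petrirec.timeseries import Experiment, compile_state_matrix


def generating_selection(cat, net, controls=None):
    """Per-column index of the alternative matching `net`, or None.

    `controls` maps transition id -> literal frozenset; defaults to the
    net's read/inhibitory arcs.
    """
    net_pairs = set()
    for t in net.transitions:
        r = reaction_vector_of(net, t)
        if controls is not None:
            term = tuple(sorted(controls[t]))
        else:
            term = tuple(
                sorted(
                    [(p, True) for p in net.reads(t)]
                    + [(p, False) for p in net.inhibitors(t)]
                )
            )
        net_pairs.add((r, term))
    selection = []
    for col in cat.columns:
        match = None
        for i, alt in enumerate(col.alternatives):
            pairs = set()
            for cr in alt.sequence:
                for term in (cr.f.terms or ((),)):
                    pairs.add((cr.r, tuple(sorted(term))))
            if pairs <= net_pairs:
                match = i
                break
        selection.append(match)
    return selection


class TestBuildCatalog:
    def test_toy_d1_column_contents(self, toy, toy_catalog):
        col = toy_catalog.columns[0]
        assert col.difference.entries == toy.expected["d1"]
        keys = {
            tuple(sorted((cr.r, cr.f.terms) for cr in alt.sequence))
            for alt in col.alternatives
        }
        d1, r4, r5 = toy.expected["d1"], toy.expected["r4"], toy.expected["r5"]
        always = ControlFunction.always().terms
        # the single-reaction alternative
        assert ((d1, always),) in keys
        # the r4 + r5 alternatives, controlled by A or by absence of F
        fa, fnf = toy.expected["r4_controls"]
        assert tuple(sorted([(r5, always), (r4, fa)])) in keys
        assert tuple(sorted([(r5, always), (r4, fnf)])) in keys

    def test_phosphate_reaction_matrix_matches_published(self, phosphate, phosphate_catalog):
        got = set()
        for col in phosphate_catalog.columns:
            for alt in col.alternatives:
                for cr in alt.sequence:
                    got.add(cr.r)
        comps = phosphate_catalog.components
        published = {
            tuple(d.get(c, 0) for c in comps)
            for d in phosphate.expected["printed_reactions"]
        }
        assert got == published
        assert len(got) == 19

    def test_single_state_matrix_gives_zero_columns(self):
        sm = compile_state_matrix(
            [Experiment(id="e", series=[(0, (1, 0)), (1, (1, 0))])]
        )
        cat = build_catalog(sm)
        assert cat.columns == [] and cat.n_nets == 0

    def test_infeasible_column_reported(self):
        # the only realising reaction is applied at a marking identical to
        # a declared terminal state: group II everywhere -> empty column
        exps = [
            Experiment(id="a", series=[(0, (1,)), (1, (0,))]),
            Experiment(id="b", series=[(0, (1,)), (1, (1,))]),
        ]
        sm = compile_state_matrix(exps)
        with pytest.raises(InfeasibleError):
            build_catalog(sm)

    def test_cap_overflow_propagates(self, toy_sm):
        with pytest.raises(CapsExceededError):
            build_catalog(toy_sm, caps=Caps(max_decompositions=2))

    def test_ordering_dedup_keeps_order_insensitive_alternatives(self, toy_catalog):
        for col in toy_catalog.columns:
            keys = [alt.key for alt in col.alternatives]
            assert len(keys) == len(set(keys))


class TestComposeNet:
    def test_toy_original_wiring_from_singleton_selection(self, toy, toy_catalog):
        sel = generating_selection(toy_catalog, toy.net)
        assert all(s is not None for s in sel)
        rnet = compose_net(toy_catalog, sel)
        assert rnet.report.ok
        assert wiring_signature(rnet.net) == wiring_signature(toy.net)

    def test_phosphate_original_wiring_recovered(self, phosphate, phosphate_catalog):
        sel = generating_selection(phosphate_catalog, phosphate.net)
        assert all(s is not None for s in sel)
        rnet = compose_net(phosphate_catalog, sel)
        assert rnet.report.ok
        assert wiring_signature(rnet.net) == wiring_signature(phosphate.net)

    def test_out_of_range_selection(self, toy_catalog):
        bad = [0] * len(toy_catalog.columns)
        bad[0] = 10**6
        with pytest.raises(ValidationError):
            compose_net(toy_catalog, bad)

    def test_wrong_selection_length(self, toy_catalog):
        with pytest.raises(ValidationError):
            compose_net(toy_catalog, [0])

    def test_identical_pairs_merge_across_columns(self):
        # two experiments exhibiting the same difference in two distinct
        # columns is impossible (columns are distinct differences), so
        # merging is exercised with a repeated-part decomposition instead:
        # d = (2,) decomposes into (1,) + (1,), one transition after merge
        exps = [Experiment(id="e", series=[(0, (0,)), (1, (2,)), (2, (2,))])]
        sm = compile_state_matrix(exps)
        cat = build_catalog(sm)
        col = cat.columns[0]
        split = next(
            i
            for i, alt in enumerate(col.alternatives)
            if len(alt.sequence) == 2
        )
        rnet = compose_net(cat, [split])
        assert len(rnet.net.transitions) == 1  # identical (r, f) pair merged


class TestEnumerate:
    def test_count_is_product_of_column_sizes(self, toy_catalog):
        sizes = [len(c.alternatives) for c in toy_catalog.columns]
        expected = 1
        for s in sizes:
            expected *= s
        assert enumerate_nets(toy_catalog, limit=0).total == expected

    def test_limit_zero_returns_no_nets(self, toy_catalog):
        res = enumerate_nets(toy_catalog, limit=0)
        assert res.nets == []

    def test_limit_honoured(self, toy_catalog):
        res = enumerate_nets(toy_catalog, limit=5)
        assert len(res.nets) == 5

    def test_all_singleton_columns_give_unique_net(self):
        fx = random_instance(3)
        sm = compile_state_matrix(
            fx.experiments, components=fx.expected["components"]
        )
        cat = build_catalog(sm)
        if all(len(c.alternatives) == 1 for c in cat.columns):
            res = enumerate_nets(cat)
            assert res.total == 1 and len(res.nets) == 1

    def test_every_toy_net_passes_replay(self, toy_catalog):
        res = enumerate_nets(toy_catalog)
        assert res.total == len(res.nets) + res.duplicates
        assert all(r.report.ok for r in res.nets)


class TestVerifyReplay:
    def test_phosphate_fixture_net_replays_cleanly(self, phosphate, phosphate_sm, phosphate_catalog):
        sel = generating_selection(phosphate_catalog, phosphate.net)
        rnet = compose_net(phosphate_catalog, sel)
        report = verify_replay(rnet, phosphate_sm, phosphate_catalog)
        assert report.violations == []

    def test_sampled_phosphate_selections_replay(self, phosphate_catalog):
        rng = random.Random(7)
        sizes = [len(c.alternatives) for c in phosphate_catalog.columns]
        for _ in range(25):
            sel = [rng.randrange(s) for s in sizes]
            rnet = compose_net(phosphate_catalog, sel)
            assert rnet.report.ok, rnet.report.violations

    def test_transition_enabled_at_terminal_is_reported(self, phosphate_sm):
        # a lone uncontrolled transition that stays enabled at terminals
        comps = phosphate_sm.components
        net = ExtendedPetriNet(
            places=[Place(c) for c in comps],
            transitions=["bad"],
            arcs=[
                Arc("PhoB-P", "bad", INPUT),
                Arc("PhoB", "bad", OUTPUT),
            ],
        )
        from petrirec.assembly import ReconstructedNet, ReplayReport

        rnet = ReconstructedNet(net=net, selection=(), report=ReplayReport())
        report = verify_replay(rnet, phosphate_sm)
        assert any("terminal state" in v for v in report.violations)

    def test_empty_net_on_terminal_only_matrix_passes(self):
        sm = compile_state_matrix(
            [Experiment(id="e", series=[(0, (1,)), (1, (1,))])]
        )
        net = ExtendedPetriNet(places=[Place("x")], transitions=[], arcs=[])
        from petrirec.assembly import ReconstructedNet, ReplayReport

        rnet = ReconstructedNet(net=net, selection=(), report=ReplayReport())
        assert verify_replay(rnet, sm).ok


class TestRoundTripCompleteness:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_generating_net_recovered(self, seed):
        fx = random_instance(seed)
        sm = compile_state_matrix(
            fx.experiments, components=fx.expected["components"]
        )
        cat = build_catalog(sm)
        sel = generating_selection(cat, fx.net, controls=fx.expected["controls"])
        assert all(s is not None for s in sel), "generating (r, f) not in catalog"
        rnet = compose_net(cat, sel)
        assert rnet.report.ok
        assert wiring_signature(rnet.net) == wiring_signature(fx.net)
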