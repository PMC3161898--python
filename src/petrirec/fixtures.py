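"""Bundled example nets and data sets, plus a seeded random-instance
generator, so every pipeline stage is testable without external data.

Three hand-built fixtures ship with the package:

* :func:`water_net` — the classic 2 H2 + O2 -> 2 H2O stoichiometry net;
* :func:`toy_example` — a six-place cascade (A..F) whose first observed
  difference decomposes ambiguously; the standard worked example for the
  reconstruction stages;
* :func:`phosphate_regulon` — the phosphate regulatory network of enteric
  bacteria: a 16-component extended Petri net with negative feedback, and
  discrete time-series observations from 11 in-silico experiments
  (wild-type and deletion/site-directed mutants, 46 compiled states).

The phosphate net is transcribed from the published network diagram; the
state vectors and experiment design are the published observation tables
verbatim.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .control_logic import ControlFunction
from .decomposition import is_applicable
from .errors import ValidationError
from .petri_core import (
    INHIBITORY,
    INPUT,
    OUTPUT,
    READ,
    Arc,
    ExtendedPetriNet,
    Place,
    reaction_vector_of,
    simulate,
)
from .timeseries import Experiment

__all__ = [
    "FixtureSet",
    "water_net",
    "toy_example",
    "phosphate_regulon",
    "random_instance",
    "brute_force_minimum_covers",
]


@dataclass
class FixtureSet:
    """A named bundle: an optional generating net, its experiments, the
    explicit firing sequences that replay them, and documented expected
    outputs for tests."""

    name: str
    experiments: list[Experiment]
    net: ExtendedPetriNet | None = None
    firing_sequences: dict = field(default_factory=dict)  # exp id -> [t ids]
    expected: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# water synthesis
# ---------------------------------------------------------------------------

def water_net() -> FixtureSet:
    """2 H + 1 O -> 2 W with initial marking (3, 1, 0)."""
    net = ExtendedPetriNet(
        places=[Place("H", capacity=3), Place("O", capacity=1), Place("W", capacity=2)],
        transitions=["T"],
        arcs=[
            Arc("H", "T", INPUT, weight=2),
            Arc("O", "T", INPUT, weight=1),
            Arc("W", "T", OUTPUT, weight=2),
        ],
        name="water",
    )
    exp = Experiment(
        id="synthesis",
        label="water synthesis from the elements",
        series=[(0, (3, 1, 0)), (1, (1, 0, 2)), (2, (1, 0, 2))],
    )
    return FixtureSet(
        name="water",
        net=net,
        experiments=[exp],
        firing_sequences={"synthesis": ["T"]},
        expected={
            "initial": (3, 1, 0),
            "after_firing": (1, 0, 2),
            "reaction_vector": (-2, -1, 2),
        },
    )


# ---------------------------------------------------------------------------
# six-place toy cascade
# ---------------------------------------------------------------------------

def toy_example() -> FixtureSet:
    """Six places A..F; A and B react to C, which decays via D and E back
    to B while producing F.  The observed run x0..x4 ends dead.

    The first difference, (-1, -1, 1, 0, 0, 0), is the standard worked
    example: it decomposes into 7 candidate reaction vectors and 5
    decompositions, and the candidate (0, -1, 1, 0, 0, 0) applied at x0
    admits exactly two alternative controls, presence of A or absence of F.
    """
    places = ["A", "B", "C", "D", "E", "F"]
    net = ExtendedPetriNet(
        places=[Place(p) for p in places],
        transitions=["tAB_C", "tC_D", "tD_E", "tE_BF"],
        arcs=[
            Arc("A", "tAB_C", INPUT),
            Arc("B", "tAB_C", INPUT),
            Arc("C", "tAB_C", OUTPUT),
            Arc("C", "tC_D", INPUT),
            Arc("D", "tC_D", OUTPUT),
            Arc("D", "tD_E", INPUT),
            Arc("E", "tD_E", OUTPUT),
            Arc("E", "tE_BF", INPUT),
            Arc("B", "tE_BF", OUTPUT),
            Arc("F", "tE_BF", OUTPUT),
        ],
        name="toy",
    )
    states = [
        (1, 1, 0, 0, 0, 0),
        (0, 0, 1, 0, 0, 0),
        (0, 0, 0, 1, 0, 0),
        (0, 0, 0, 0, 1, 0),
        (0, 1, 0, 0, 0, 1),
    ]
    exp = Experiment(
        id="run",
        label="single observed run to the dead state",
        series=[(t, s) for t, s in enumerate(states)] + [(len(states), states[-1])],
    )
    return FixtureSet(
        name="toy",
        net=net,
        experiments=[exp],
        firing_sequences={"run": ["tAB_C", "tC_D", "tD_E", "tE_BF"]},
        expected={
            "components": places,
            "states": states,
            "terminal_index": 4,
            "d1": (-1, -1, 1, 0, 0, 0),
            "n_candidates_d1": 7,
            "n_decompositions_d1": 5,
            "r4": (0, -1, 1, 0, 0, 0),
            "r5": (-1, 0, 0, 0, 0, 0),
            "y1": (1, 0, 1, 0, 0, 0),  # x0 + r4
            "y2": (0, 1, 0, 0, 0, 0),  # x0 + r5
            "r4_controls": [((("A", True),),), ((("F", False),),)],
        },
    )


# ---------------------------------------------------------------------------
# phosphate regulon case study
# ---------------------------------------------------------------------------

PHOSPHATE_COMPONENTS = [
    "pi-pp", "pi-cp", "po-pp", "Pst-P", "Pst", "PhoU-I", "PhoU-A",
    "PhoR", "PhoR-P", "PhoR-S", "PhoB", "PhoB-P", "PhoB-S",
    "PhoA-T", "PhoA", "PhoA-pp",
]

# 46 compiled state vectors (one row per state, one digit per component in
# the order above), concatenated over the 11 experiments.
_PHOSPHATE_STATES = """
1011010101101100
0111010101101100
0110110101101100
0110101101101100
0110101011101100
0110101101011100
0110101101011110
0110101101011101
1100101101011101
1101001101011101
1101010101011101
1101010101101101
0001010101101100
0000110101101100
0000101101101100
0000101011101100
0000101101011100
0000101101011110
0000101101011101
0000101101011111
0000101011011111
0011010101101000
0010110101101000
0010101101101000
0010101011101000
0010101101011000
0010101011011000
0000010101101100
0010010101101100
1010010101101100
0001000101101100
0000100101101100
0001010001101100
0000110001101100
0000101001101100
0001010101001100
0000110101001100
0000101101001100
0000101011001100
0001010100101100
0000110100101100
0000101100101100
0001010101100100
0000110101100100
0000101101100100
0000101011100100
""".split()

# experiment id, half-open state range, terminal?, genetic background,
# experimental perturbation
_PHOSPHATE_EXPERIMENTS = [
    ("exp1", 0, 12, False, "wild-type", "addition of organic and inorganic phosphate"),
    ("exp2", 12, 21, True, "wild-type", "absence of organic and inorganic phosphate"),
    ("exp3", 21, 27, True, "wild-type", "inhibition of transcription/translation"),
    ("exp4", 27, 28, True, "delta-pstSCAB", "absence of organic and inorganic phosphate"),
    ("exp5", 28, 29, True, "delta-pstSCAB", "addition of organic phosphate"),
    ("exp6", 29, 30, True, "delta-pstSCAB", "addition of organic and inorganic phosphate"),
    ("exp7", 30, 32, True, "delta-phoU", "absence of organic and inorganic phosphate"),
    ("exp8", 32, 35, True, "delta-phoR", "absence of organic and inorganic phosphate"),
    ("exp9", 35, 39, True, "delta-phoB", "absence of organic and inorganic phosphate"),
    ("exp10", 39, 42, True, "phoR delta-P-site", "absence of organic and inorganic phosphate"),
    ("exp11", 42, 46, True, "phoB delta-P-site", "absence of organic and inorganic phosphate"),
]

_PHOSPHATE_SEQUENCES = {
    "exp1": [
        "pi_uptake", "pstP_dephosphorylation", "phoU_activation",
        "phoR_phosphorylation", "phosphotransfer", "phoA_synthesis",
        "phoA_export", "po_degradation", "pst_phosphorylation",
        "phoU_deactivation", "phoBP_dephosphorylation",
    ],
    "exp2": [
        "pstP_dephosphorylation", "phoU_activation", "phoR_phosphorylation",
        "phosphotransfer", "phoA_synthesis", "phoA_export", "phoA_synthesis",
        "phoR_phosphorylation",
    ],
    "exp3": [
        "pstP_dephosphorylation", "phoU_activation", "phoR_phosphorylation",
        "phosphotransfer", "phoR_phosphorylation",
    ],
    "exp4": [],
    "exp5": [],
    "exp6": [],
    "exp7": ["pstP_dephosphorylation"],
    "exp8": ["pstP_dephosphorylation", "phoU_activation"],
    "exp9": ["pstP_dephosphorylation", "phoU_activation", "phoR_phosphorylation"],
    "exp10": ["pstP_dephosphorylation", "phoU_activation"],
    "exp11": ["pstP_dephosphorylation", "phoU_activation", "phoR_phosphorylation"],
}

# the 11 distinct difference vectors plus the 8 additional reaction vectors
# that survive exhaustive decomposition, as published (sparse name -> entry)
PHOSPHATE_PRINTED_REACTIONS = [
    {"pi-pp": -1, "pi-cp": 1},
    {"Pst-P": -1, "Pst": 1},
    {"PhoU-I": -1, "PhoU-A": 1},
    {"PhoR": -1, "PhoR-P": 1},
    {"PhoR": 1, "PhoR-P": -1, "PhoB": -1, "PhoB-P": 1},
    {"PhoA": 1},
    {"PhoA": -1, "PhoA-pp": 1},
    {"pi-pp": 1, "po-pp": -1},
    {"Pst-P": 1, "Pst": -1},
    {"PhoU-I": 1, "PhoU-A": -1},
    {"PhoB": 1, "PhoB-P": -1},
    {"pi-pp": -1},
    {"pi-cp": 1},
    {"PhoR": 1, "PhoR-P": -1},
    {"PhoB": -1, "PhoB-P": 1},
    {"PhoA": -1},
    {"PhoA-pp": 1},
    {"po-pp": -1},
    {"pi-pp": 1},
]


def _phosphate_net() -> ExtendedPetriNet:
    """The predefined phosphate-regulon model (diagram-transcribed).

    Read arcs encode catalysis by protein forms (e.g. PhoU-A catalyses
    PhoR autophosphorylation); the phospho-site places PhoR-S/PhoB-S gate
    the corresponding phosphorylation steps so that site-directed mutants
    are expressible as initial markings.
    """
    t = {
        "pi_uptake": dict(inputs={"pi-pp": 1}, outputs={"pi-cp": 1}, reads=["Pst-P"]),
        "pstP_dephosphorylation": dict(inputs={"Pst-P": 1}, outputs={"Pst": 1}, reads=[]),
        "phoU_activation": dict(inputs={"PhoU-I": 1}, outputs={"PhoU-A": 1}, reads=["Pst"]),
        "phoR_phosphorylation": dict(
            inputs={"PhoR": 1}, outputs={"PhoR-P": 1}, reads=["PhoU-A", "PhoR-S"]
        ),
        "phosphotransfer": dict(
            inputs={"PhoR-P": 1, "PhoB": 1},
            outputs={"PhoR": 1, "PhoB-P": 1},
            reads=["PhoB-S"],
        ),
        "phoA_synthesis": dict(
            inputs={}, outputs={"PhoA": 1}, reads=["PhoB-P", "PhoA-T"]
        ),
        "phoA_export": dict(inputs={"PhoA": 1}, outputs={"PhoA-pp": 1}, reads=[]),
        "po_degradation": dict(
            inputs={"po-pp": 1}, outputs={"pi-pp": 1}, reads=["PhoA-pp"]
        ),
        "pst_phosphorylation": dict(
            inputs={"Pst": 1}, outputs={"Pst-P": 1}, reads=["pi-pp"]
        ),
        "phoU_deactivation": dict(
            inputs={"PhoU-A": 1}, outputs={"PhoU-I": 1}, reads=["Pst-P"]
        ),
        "phoBP_dephosphorylation": dict(
            inputs={"PhoB-P": 1}, outputs={"PhoB": 1}, reads=["PhoU-I"]
        ),
    }
    arcs = []
    for name, spec in t.items():
        for p, w in spec["inputs"].items():
            arcs.append(Arc(p, name, INPUT, weight=w))
        for p, w in spec["outputs"].items():
            arcs.append(Arc(p, name, OUTPUT, weight=w))
        for p in spec["reads"]:
            arcs.append(Arc(p, name, READ))
    return ExtendedPetriNet(
        places=[Place(p) for p in PHOSPHATE_COMPONENTS],
        transitions=list(t),
        arcs=arcs,
        name="phosphate-regulon",
    )


def phosphate_regulon() -> FixtureSet:
    """The phosphate-regulon case study: 16 components, 11 experiments,
    46 compiled state vectors with the published terminal flags."""
    states = [tuple(int(c) for c in row) for row in _PHOSPHATE_STATES]
    assert len(states) == 46
    experiments = []
    for exp_id, start, stop, terminal, background, perturbation in _PHOSPHATE_EXPERIMENTS:
        rows = [(k, states[i]) for k, i in enumerate(range(start, stop))]
        if terminal:
            # the run was observed until it stopped changing
            rows.append((len(rows), rows[-1][1]))
        experiments.append(
            Experiment(
                id=exp_id,
                label=f"{background}; {perturbation}",
                series=rows,
            )
        )
    terminal_indices = [
        stop - 1
        for _, start, stop, terminal, _, _ in _PHOSPHATE_EXPERIMENTS
        if terminal
    ]
    return FixtureSet(
        name="phosphate-regulon",
        net=_phosphate_net(),
        experiments=experiments,
        firing_sequences=dict(_PHOSPHATE_SEQUENCES),
        expected={
            "components": list(PHOSPHATE_COMPONENTS),
            "n_states": 46,
            "terminal_indices": terminal_indices,
            "segments": [
                (exp_id, start, stop)
                for exp_id, start, stop, _, _, _ in _PHOSPHATE_EXPERIMENTS
            ],
            "n_difference_vectors": 11,
            "printed_reactions": [dict(d) for d in PHOSPHATE_PRINTED_REACTIONS],
            "n_ambiguous_reported": 4,
            "invariant_pairs": [
                ("Pst-P", "Pst"),
                ("PhoU-I", "PhoU-A"),
                ("PhoR", "PhoR-P"),
                ("PhoB", "PhoB-P"),
            ],
        },
    )


# ---------------------------------------------------------------------------
# random instances for the small-scale completeness oracle
# ---------------------------------------------------------------------------

def brute_force_minimum_covers(on, off, places):
    """Reference enumeration of all minimum DNF covers, by sheer force.

    Enumerates every conjunctive term over the places (3^P - 1), keeps the
    implicants (false on every off-state), and searches term subsets of
    increasing size for covers of the on-set; among the covers with the
    fewest terms, those with the fewest literals are returned as sets of
    literal-frozensets.  Intended as an independent oracle for small P.
    """
    on = sorted({tuple(x) for x in on})
    off = sorted({tuple(x) for x in off})
    if not off:
        return [frozenset()]  # constant true
    index = {p: i for i, p in enumerate(places)}

    def true_at(term, m):
        return all((m[index[p]] >= 1) == pos for p, pos in term)

    terms = []
    for r in range(1, len(places) + 1):
        for combo in itertools.combinations(places, r):
            for signs in itertools.product((True, False), repeat=r):
                term = frozenset(zip(combo, signs))
                if not any(true_at(term, o) for o in off) and any(
                    true_at(term, s) for s in on
                ):
                    terms.append(term)
    covers = []
    for k in range(1, len(on) + 1):
        for combo in itertools.combinations(terms, k):
            if all(any(true_at(t, s) for t in combo) for s in on):
                covers.append(frozenset(combo))
        if covers:
            break
    if not covers:
        return []
    best = min(sum(len(t) for t in c) for c in covers)
    return sorted(
        {c for c in covers if sum(len(t) for t in c) == best},
        key=lambda c: sorted(sorted(t) for t in c),
    )


def random_instance(
    seed: int,
    n_places: int = 5,
    n_transitions: int = 3,
    control_density: float = 0.4,
    max_attempts: int = 2000,
) -> FixtureSet:
    """A reproducible random extended net plus a deadlock-terminated
    trajectory from a random initial marking.

    Instances are rejection-sampled until (a) the deterministic token game
    reaches a dead state after at least two steps with every transition
    firing at least once, and (b) each transition's control-arc term is a
    *minimum* cover of the on/off sets it induces on its own trajectory.
    Condition (b) matters for round-trip tests: a net whose control arcs
    are redundant with respect to the data it generates cannot be returned
    by any minimal-model reconstruction.
    """
    if not 2 <= n_places <= 6:
        raise ValidationError("random_instance supports 2..6 places (oracle bounds)")
    if not 1 <= n_transitions <= 4:
        raise ValidationError("random_instance supports 1..4 transitions (oracle bounds)")
    rng = random.Random(seed)
    places = [f"P{i}" for i in range(n_places)]

    for _ in range(max_attempts):
        arcs = []
        controls = {}
        vectors = set()
        ok = True
        for k in range(n_transitions):
            t = f"T{k}"
            n_in = rng.randint(0, 2)
            n_out = rng.randint(0 if n_in else 1, 2)
            shuffled = rng.sample(places, n_places)
            ins, outs = shuffled[:n_in], shuffled[n_in : n_in + n_out]
            vec = tuple(
                -1 if p in ins else (1 if p in outs else 0) for p in places
            )
            if vec in vectors or not any(vec):
                ok = False
                break
            vectors.add(vec)
            term = []
            for p in shuffled[n_in + n_out :]:
                if rng.random() < control_density:
                    positive = rng.random() < 0.5
                    term.append((p, positive))
                    arcs.append(Arc(p, t, READ if positive else INHIBITORY))
            controls[t] = frozenset(term)
            for p in ins:
                arcs.append(Arc(p, t, INPUT))
            for p in outs:
                arcs.append(Arc(p, t, OUTPUT))
        if not ok:
            continue
        net = ExtendedPetriNet(
            places=[Place(p) for p in places],
            transitions=[f"T{k}" for k in range(n_transitions)],
            arcs=arcs,
            name=f"random-{seed}",
        )
        m0 = tuple(rng.randint(0, 1) for _ in places)
        traj = simulate(net, m0, policy="deterministic", max_steps=30)
        if not traj.terminal or len(traj.markings) < 3:
            continue
        fired = set(traj.fired)
        if not fired:
            continue
        # transitions that never fired are unobservable: drop them (their
        # wiring cannot be recovered from the emitted data); deadness at
        # the final marking is unaffected by removing transitions
        if fired != set(net.transitions):
            keep = [t for t in net.transitions if t in fired]
            net = ExtendedPetriNet(
                places=[Place(p) for p in places],
                transitions=keep,
                arcs=[a for a in arcs if a.transition in fired],
                name=f"random-{seed}",
            )
        final = traj.markings[-1]
        recoverable = True
        for t in net.transitions:
            r = reaction_vector_of(net, t)
            on = {m for m, f in zip(traj.markings, traj.fired) if f == t}
            off = {final} if is_applicable(r, final, net.capacities) else set()
            minima = brute_force_minimum_covers(on, off, places)
            if controls[t] not in minima:
                recoverable = False
                break
        if not recoverable:
            continue
        series = [(i, m) for i, m in enumerate(traj.markings)]
        series.append((len(series), traj.markings[-1]))
        exp = Experiment(id="sim", label="deterministic run to deadlock", series=series)
        return FixtureSet(
            name=f"random-{seed}",
            net=net,
            experiments=[exp],
            firing_sequences={"sim": list(traj.fired)},
            expected={
                "components": places,
                "controls": {t: controls[t] for t in net.transitions},
                "markings": list(traj.markings),
            },
        )
    raise ValidationError(
        f"random_instance: no acceptable instance found for seed {seed} "
        f"within {max_attempts} attempts"
    )
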