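# petrirec

Exact reconstruction of **extended Petri nets** — place/transition nets
with read (test) arcs and inhibitory arcs — from discrete time-series
data.

Given one or more experiments (wild-type and perturbed/mutant), each a
table of integer-valued (typically boolean) component measurements over
time, petrirec returns **all** minimal extended Petri nets consistent
with the data:

1. **compile** — per experiment, consecutive duplicate measurements are
   collapsed; the experiments are concatenated into one state matrix with
   terminal-state flags (a terminal state is one at which nothing changes
   any more, so every reconstructed net must be dead there);
2. **decompose** — every distinct difference between consecutive states
   is split exhaustively into all candidate reaction vectors, all
   multiset decompositions, and all orderings; orderings whose
   intermediate states leave the token bounds are discarded.
   P-invariants (token-conservation constraints detected in the data or
   nominated by the user) prune the candidate set;
3. **control** — each reaction is classified against the terminal states:
   never applicable there (always enabled, no control arcs), applied at a
   marking identical to a terminal marking (contradictory, deleted), or
   controllable.  For controllable reactions, *all* minimum DNF control
   functions separating application states (value 1) from applicable
   terminal states (value 0) are derived by exact two-level minimisation
   (Quine–McCluskey discipline: prime terms + exhaustive minimum-cover
   selection; every other marking is a don't-care).  Each DNF term maps
   to one transition; positive literals become read arcs, negative
   literals inhibitory arcs;
4. **assemble** — the surviving controlled-reaction sequences form a
   *solution catalog* (one column per difference vector, the implicit
   representation of all solutions).  Explicit nets are composed by
   picking one alternative per column; every composed net is verified by
   replaying the state matrix and checking deadness at all terminals.

Token-game dialect: enabling is capacity-respecting on the output side
(a transition that would overfill a place is disabled).  Per-place
capacities default to the maximum value observed for that component
(1 for boolean data).  Discretisation is deliberately out of scope: the
readers reject non-integer values.

## CLI

```sh
# compile experiment tables into state + difference matrices
petrirec compile phosphate.tsv --out-prefix out

# build the complete solution catalog
petrirec reconstruct phosphate.tsv --out catalog.json --table catalog.txt

# enumerate composed nets (PNML or DOT)
petrirec enumerate catalog.json --limit 10 --out-dir nets --fmt pnml

# token-game simulation on a PNML net
petrirec simulate water.pnml --marking 3,1,0 --out traj.csv

# convert PNML to GraphViz DOT
petrirec export water.pnml --fmt dot --out water.dot
```

Exit codes: `0` ok, `2` validation error, `3` reconstruction infeasible
(some difference vector admits no controlled-reaction sequence), `4`
combinatorial-guard overflow (raise the caps in the YAML config).

Input format: CSV/TSV (delimiter sniffed from the header, `#` comments),
either one file per experiment (optional `# terminal: yes` line) or one
long-format file with an `experiment` column and optional `time` /
`terminal` columns; the remaining header names are the components, in
declaration order.  Configuration (capacities, nominated invariants,
caps, …) is YAML; see `petrirec.io_formats.RunConfig`.

PNML dialect: standard place/transition PNML plus a `<capacity>` child
on places and an `<arctype>` child (`read` / `inhibitory`) on control
arcs; unknown arc types fall back to standard arcs with a warning.
Round-trips are lossless for this dialect.

## Bundled fixtures

`petrirec.fixtures` ships three hand-built example sets (no downloads):

* `water_net()` — 2 H + O → 2 W stoichiometry net;
* `toy_example()` — six-place cascade whose first difference vector
  decomposes into 7 candidate reactions and admits alternative controls
  (presence of A / absence of F);
* `phosphate_regulon()` — the phosphate regulatory network of enteric
  bacteria: 16 components, 11 in-silico experiments (wild-type, deletion
  and phospho-site mutants), 46 compiled state vectors with terminal
  flags, plus the transcribed reference net.  The reconstruction
  recovers the reference wiring as one of its solutions and reproduces
  the published 19-column reaction-vector matrix exactly.
* `random_instance(seed, …)` — seeded random extended nets with
  deadlock-terminated trajectories for round-trip testing.

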