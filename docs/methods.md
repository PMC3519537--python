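# Methods

## Model and semantics

`signet` treats a signalling pathway as a signed directed graph
G = (V, E) with E ⊆ V × V × {activates, inhibits}, one optional terminal
phenotype node, and qualitative node states s ∈ {active, inactive}.
An experiment contributes a partial assignment of *fixed* states:

| evidence                     | fixed state |
|------------------------------|-------------|
| knockout / heterozygous knockout / dominant negative | inactive |
| overexpression               | active      |
| transcript up-regulated      | active      |
| transcript down-regulated    | inactive    |

The transcript rules rest on the premise that mRNA levels are a usable
qualitative proxy for protein availability — defensible for signalling
molecules, whose transcripts and proteins turn over quickly, but a
proxy nonetheless (see *Limitations*). A gene that is both perturbed
and differentially expressed keeps only the perturbation: the genetic
intervention is the stronger statement about the protein's state.

Inference is the least fixpoint of a single propagation rule over the
(node, state) product space. From every achievable pair (x, s) and edge
(x, y, σ), the conferred state is s′ = s if σ = activates, else ¬s;
if y is fixed to ¬s′ the chain is *blocked* and (y, s′) is recorded as
an impairment point; otherwise the relation atom — `activates(x,y)`
when s′ = active, `inactivates(x,y)` otherwise — is derived and
(y, s′) becomes achievable. The fixpoint exists and is unique because
the operator is monotone on a finite lattice (≤ 2·|V| achievable
pairs), so the answer set is deterministic, independent of propagation
order and loop-safe; every solvable experiment has exactly one
consistent answer set. These are *per-route* (signal-flow) semantics,
not steady state: a free node may legitimately be achievable in both
states through different routes (in the Lnk null, PI3K is inactive via
the broken adaptor yet active via the up-regulated insulin-like
peptides), and only fixed nodes are single-valued.

Two deliberate semantic choices, both of which reproduce every
reported shortest-path block:

* **OR-logic across regulators.** One achievable upstream state
  suffices to extend a chain; complex assembly is not modelled as an
  AND-gate. Loss of LNK alone silences PI3K in the model even though
  CHICO remains — consistent with the reported routes, but a known
  simplification.
* **Hard DE constraints.** DE-derived states are integrity
  constraints, not soft seeds; this is what makes *impaired effects*
  derivable (a down-regulated ILP chain in the foxo null is blocked at
  the knocked-out factor, which it would need active).

## Path analysis

Within the answer set, all *simple* paths (no repeated node) from each
perturbed or DE node — seeded with its fixed state — to the phenotype
node are enumerated by depth-first search; a step (x → y) is taken only
if its relation atom was derived. Simple paths keep the enumeration
finite in a cyclic pathway without losing information: a loop's edges
still appear, distributed over different simple paths. The phenotype
node's end state predicts lifespan (active → long-lived, inactive →
short-lived) and classification is a total function of (path, facts):

* start perturbed, prediction matches observation → **primary**;
* start perturbed, contradiction → **inconsistent_primary** (never
  produced by the four built-in experiments; surfacing it flags
  model/data inconsistency rather than silently dropping the path);
* start DE-only → **positive_feedback** on match, else
  **negative_feedback**;
* chain stopped at a contradicting fixed node → **impaired** (reported
  only on request, ending at the blocking node with the state the
  signal would have conferred).

Shortest paths are taken per (start, class) with all ties retained.
Enumeration carries a configurable cap (`max_paths`, default 100 000)
with an explicit truncation flag; reports are sorted lexicographically
so identical runs are byte-identical.

## Sub-path mining

Paths are tokenised as `node:state` sequences; every unordered pair is
compared by longest-common-substring dynamic programming *over tokens*,
keeping all tied maxima; each collected run (minimum two tokens = one
relation) is counted as the number of input paths containing it
contiguously, and results are sorted by frequency, then length, then
lexicographically. Token-level matching forecloses spurious overlaps
between node names sharing prefixes (Ilp2 vs Ilp25) that a
character-level matcher would admit; keeping all tied maxima (rather
than one arbitrary winner) makes the output deterministic and
complete. The frequency convention — number of *containing paths*, not
pair hits — is the more interpretable of the two and they coincide on
the built-in cascade example.

## Fixtures and the random generator

`build_iis_tor_core()` is a curated, validated sub-network of the
hand-compiled IIS/TOR diagram: 26 nodes and 28 signed edges, exactly
the interactions needed so that every reported shortest signalling
path of the four experiments is realisable (ILPs → INR → CHICO/LNK →
PI3K → PDK1 → AKT1 ⊣ FOXO → longevity; the JNK branch; the
S6K–CHICO, TOR-C1/TOR-C2 and TSC–RHEB couplings; the IMP-L2, WDB,
PTEN and HPO modulators). A direct PI3K → AKT1 edge coexists with the
PI3K → PDK1 → AKT1 route because the IIS-core shortest paths traverse
one step while the foxo-null feedback enters through PDK1. Extra edges
of the full diagram are deliberately excluded: they would add routes
that nothing in the packaged experiments can verify.

`build_experiment(name)` encodes the four experiments' perturbations,
pathway-component DE calls and observed phenotypes. DE genes reported
for an experiment but outside the core network (Thor, myc, Tor, Sin1)
are available behind `extended=True` and are dropped — with a warning —
during fact building against the core graph, keeping the regression
surface exact.

`random_signed_graph(seed, n_nodes, edge_probability,
inhibit_fraction)` drives the property suites: independent Bernoulli
edges, Bernoulli signs, one terminal phenotype node, fully determined
by the seed. It emulates only the structural features the engine cares
about (signed directed edges, cycles, a terminal phenotype); it does
not emulate degree heterogeneity, motif structure or biological
plausibility of real pathways, so passing property tests demonstrates
algorithmic correctness, not biological validity on real networks.

## Verification strategy

Three independent oracles cross-check the implementation on small
random inputs: a bounded-iteration walk closure (states reachable by
walks of length ≤ 2·|V|, recomputed naively over the full edge set)
against the worklist fixpoint; networkx simple-path enumeration plus
parity filtering against the guided DFS; and exhaustive substring
enumeration against the dynamic-programming sub-path matcher. The
four experiments' shortest-path blocks are frozen as checked-in
expected files and compared string-exactly. Problem sizes — graphs of
≤ 10 nodes, 200 seeds for oracle equivalence, 200 seeds for the
generator's binomial calibration — were chosen so the whole suite runs
in a few seconds while exercising every branch of the propagation and
blocking logic.

## Numerical and edge-case choices

* DE cutoff: adjusted P < 0.005, strict inequality at the boundary
  (exposed as `strict=False` for non-strict), threshold configurable in
  (0, 1].
* A gene passing the cutoff with zero or non-finite log fold-change is
  rejected as non-informative; conflicting directions for one gene are
  an error (ambiguous evidence), not a silent overwrite.
* Rows with missing adjusted P are dropped with a logged warning;
  a missing mandatory column is an error naming the column.
* Parallel opposite-sign edges between one ordered pair are permitted
  (context-dependent dual regulation); duplicate same-sign edges are
  rejected.
* GraphML signs live in a first-class `sign` attribute; files from the
  yEd editor that encode signs graphically are handled by a best-effort
  arrow-style fallback (plain arrowhead → activates, T-bar → inhibits),
  with unmappable styles reported per edge. The exact style vocabulary
  of any given yEd export is not standardised, hence "best effort".
* The phenotype node must be terminal; validation reports all
  violations as data rather than failing on the first.

## Limitations

* Qualitative only: no kinetics, no dosage, no tissue or localisation
  information; transcript direction stands in for protein activity.
* OR-logic may overestimate reachability where complex assembly truly
  requires all subunits.
* The core network is a verified sub-network; analyses on it cannot
  surface routes that exist only in the full diagram.
* Microarray preprocessing and differential-expression fitting are out
  of scope: the DE table (moderated t-statistics, adjusted P-values)
  is trusted as produced by standard tooling.
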