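# signet

Qualitative inference of how genetic perturbations and transcriptional
changes modulate a signed signalling network — built around the
insulin/insulin-like signalling (IIS) pathway of *Drosophila
melanogaster*, its cross-talk with the TOR pathway, and the
FOXO-mediated longevity phenotype.

## The problem

Longevity experiments in the fly perturb one IIS component (a *chico*
heterozygous knockout, a *Lnk* null, a dominant-negative *InR*, a *foxo*
null), measure genome-wide transcription, and record whether the mutant
is long- or short-lived. Transcript changes on pathway components hint
at how the pathway re-wires in the mutant — but reading those hints
requires propagating them through the pathway's activation/inhibition
structure. `signet` does that propagation symbolically and answers:

* which signalling routes does the intervention open, and do they
  explain the observed lifespan change (*primary effects*)?
* which routes are opened by differential expression of *other*
  components, and do they oppose (*negative feedback*) or reinforce
  (*positive feedback*) the observed phenotype?
* where is a would-be signal *impaired* — disrupted because a
  component's experimentally fixed state contradicts the state the
  signal would need?
* which sub-routes recur across the inferred paths of one or several
  experiments (*longest common sub-paths*)?

## The model

The pathway is a signed directed graph: nodes are proteins, complexes
(ids prefixed `c_`), transcription factors, processes, and one terminal
phenotype node; edges are `activates` or `inhibits`. Each experiment
fixes node states: loss-of-function perturbations and down-regulated
genes fix a node *inactive*, overexpression and up-regulated genes fix
it *active* (adjusted-P cutoff 0.005 for calling differential
expression). Signals then propagate by sign parity,

```
state(target) = state(source)         if source —activates→ target
state(target) = ¬ state(source)       if source —inhibits→  target
```

subject to one integrity constraint: no signal may confer on a fixed
node the opposite of its fixed state — such chains stop and are
recorded as impairment points. The closure of this rule over the
(node, state) product space is a least fixpoint: unique, order
independent, loop-safe, and every solvable experiment yields exactly
one consistent answer set of `activates(x,y)` / `inactivates(x,y)`
relations. Simple paths from each perturbed or differentially
expressed node to the phenotype node are enumerated inside that answer
set, the phenotype node's end state predicts lifespan (active →
long-lived, inactive → short-lived), and each path is classified
against the observation. Finally, paths are tokenised as
`node:state` sequences and mined pairwise for maximal common
contiguous runs, counted across all paths.

## Worked example

The built-in fixtures reproduce the *chico¹/+* experiment (CHICO fixed
inactive; Ilp2, Ilp3, Ilp5 up-regulated; observed long-lived) on the
curated IIS/TOR core network:

```sh
signet fixture iis-tor-core --out-dir demo
signet fixture chico --out-dir demo
signet -v paths --graph demo/iis-tor-core.graphml --experiment demo/chico.yaml --out demo/chico
cat demo/chico.shortest.tsv
```

```
chico  Ilp2   negative_feedback  short_lived  7  Ilp2(active) -> InR(active) -> Lnk(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
chico  Ilp3   negative_feedback  short_lived  7  Ilp3(active) -> InR(active) -> Lnk(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
chico  Ilp5   negative_feedback  short_lived  7  Ilp5(active) -> InR(active) -> Lnk(active) -> Pi3K(active) -> Akt1(active) -> foxo(inactive) -> longevity(inactive)
chico  chico  primary            long_lived   5  chico(inactive) -> Pi3K(inactive) -> Akt1(inactive) -> foxo(active) -> longevity(active)
```

(The columns are experiment, start node, class, predicted phenotype,
path length, and the path itself.) The primary effect reads: losing
CHICO silences PI3K and AKT1, de-represses FOXO, and extends lifespan —
matching the observation. The three up-regulated insulin-like peptides
each open a route that would *inactivate* FOXO and shorten lifespan:
transcriptional negative feedback pushing back against the mutation.

Mining the path report for shared sub-routes:

```sh
signet subpaths demo/chico.paths.tsv --out demo/chico.subpaths.tsv
head -2 demo/chico.subpaths.tsv
```

```
6  3  Akt1(active) -> foxo(inactive) -> longevity(inactive)
6  3  InR(active) -> Lnk(active) -> Pi3K(active)
```

i.e. six of the eight inferred paths funnel through active AKT1
inhibiting FOXO, and six share the receptor-to-PI3K cascade. Applying
the miner to just the three ILP feedback routes returns their full
common cascade `InR -> Lnk -> Pi3K -> Akt1 -> foxo -> longevity` with
frequency 3 — the routes differ only in which peptide triggers them.

The same library surface is available programmatically:

```python
from signet import solve, enumerate_signal_paths, shortest_paths
from signet.fixtures import build_iis_tor_core, build_experiment

graph = build_iis_tor_core()
facts = build_experiment("Lnk")
answer = solve(graph, facts)
paths = [p for p in enumerate_signal_paths(graph, answer, facts) if not p.impaired]
for (start, cls), group in shortest_paths(paths, facts).items():
    print(start, cls.value, group[0].render())
```

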