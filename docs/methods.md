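# Methods

This note documents the models, algorithms and numerical choices behind
`kegg2net`, and what its synthetic fixtures can and cannot say about real
KEGG data.

## From KGML to a heterogeneous graph

A KGML document contributes three element families. *Entries* become typed
nodes: `gene`, `compound`, `map` (a link to another pathway), `group` (a
complex), `ortholog`, `enzyme`; unknown `type` attributes are retained as
`other` with a warning rather than dropped. *Relations* become directed
edges between the two entries; a subtype of `activation`/`expression` marks
the edge activating, `inhibition`/`repression` inhibiting, anything else
unknown. Two cases get special handling: a `compound` (or `hidden
compound`) subtype names an explicit intermediate, so the relation is
decomposed into entry1→compound and compound→entry2 — this is what makes
indirect gene–gene routes through metabolites recoverable later — and
`binding/association`/`dissociation` relations assert no direction, so they
emit edges both ways. *Reactions* connect substrates to the catalysing gene
entry and the gene entry to products; reversible reactions also emit the
mirrored edges.

Expansion to concrete identifiers follows three rules. Group entries
flatten: their links lift to every member and the group node itself is not
emitted (a synthetic complex node would pollute the gene-only collapse).
Entries carrying several identifiers expand to one node each, all
inheriting the entry's links; this is stated in the KGML ecosystem for gene
entries and applied uniformly to all kinds for consistency. Duplicate
directed edges merge, with conflicting signs collapsing to `unknown`, since
the downstream adjacency representation admits one edge per ordered pair.
Ortholog entries count as genes only under the `orthologs_as_genes` flag
(default off); `map` entries are ordinary traversable non-gene nodes.

## Gene-only collapse

The gene network contains an edge g₁→g₂ (g₁≠g₂) exactly when the
heterogeneous graph has a directed path from g₁ to g₂ whose internal nodes
are all non-gene; paths through a third gene do not create an edge, because
that dependency is already represented by the two shorter edges. Self-loops
(a gene returning to itself through compounds) are suppressed: the DAG
conversion and BN scoring both forbid them.

Existence is decided without path enumeration: from each gene, a traversal
expands only non-gene intermediates and records every gene reached, O(|V|·
(|V|+|E|)) overall. Signs need more care. The sign of an indirect edge is
the product of edge signs along the path, when every hop is signed and all
paths agree — but propagating signs along *walks* is wrong: a sign-flipping
cycle among compounds can manufacture a sign that no simple path realises.
Signs are therefore resolved per discovered pair by a depth-first
enumeration of simple paths restricted to non-gene nodes lying both
downstream of the source and upstream of the target, terminating early as
soon as the sign set saturates (two signs, or any unknown, already force
`unknown`). In pathway-sized graphs the restriction plus early exit keeps
this cheap; a brute-force all-simple-paths oracle checks the collapse
exactly on hundreds of random 12-node instances in the test suite.

Parallel indirect routes collapse to a single edge (presence, not
multiplicity), matching an adjacency-matrix representation.

## Cycle removal

All four methods return the partition (kept DAG, ordered removed edges) and
share two conventions: hierarchy scores increase along edge direction (an
edge u→v means v outranks u — the agony formula forces this orientation, and
using it uniformly keeps the methods comparable), and every tie anywhere is
broken lexicographically on gene name, so all outputs are reproducible.

**DFS.** Depth-first search from every node in lexicographic order with
lexicographic neighbour expansion; edges onto the current traversal stack
(back edges) are removed, tree/forward/cross edges kept. Removing all back
edges of any DFS leaves an acyclic graph; acyclic inputs lose nothing.

**MFAS (Eades–Lin–Smyth).** Builds a vertex sequence by repeatedly moving
sinks to the right end, sources to the left end, and otherwise the vertex
maximising out-degree − in-degree to the left end; edges pointing
right-to-left in the final sequence form the feedback set. On connected
digraphs without 2-cycles the removed set respects the classical
m/2 − n/6 guarantee (2-cycles break the bound for any algorithm: a single
a↔b pair needs one removal but the bound allows ⅔). The greedy is a
heuristic, not an exact solver — exhaustive enumeration shows it misses the
optimum on 60 of the 4096 labelled 4-node digraphs, a gap the test suite
records rather than hides; exact MFAS is NP-hard and exists here only as a
small-instance testing oracle.

**PageRank.** Power iteration with damping 0.85, uniform teleport, uniform
redistribution of dangling mass, iterated until the maximum score change
falls below 1e-10. Whether high PageRank should sit at the top or bottom of
a regulatory hierarchy is genuinely ambiguous, so both orientations of the
score order are evaluated and the one removing fewer edges wins (ties →
ascending). Removal deletes every edge pointing backwards in the chosen
total order, which guarantees acyclicity outright. An already-acyclic input
is returned untouched: a DAG may well contain order-violating edges, but
they carry no cycle and repairing them would delete information for no
benefit.

**Ensemble (TrueSkill + agony).** TrueSkill treats each edge u→v as a
two-player, no-draw match won by v, with the canonical priors μ₀=25,
σ₀=25/3, β=σ₀/2, τ=σ₀/100; the edge list is replayed for 10 epochs in an
order shuffled by a seeded generator, and the final means are the scores.
The agony ranking minimises Σ_{u→v} max(0, r(u)−r(v)+1) over integer rank
levels by deterministic multi-start local search: single-node moves (each
gene to the level minimising its incident agony) run to convergence (≤100
sweeps) from several starts — longest-path levels of the DFS-debacked DAG
(agony 0 on any DAG, so acyclic inputs are exact), the all-equal ranking,
sink-depth levels, and five fixed-seed random rank vectors — keeping the
lowest-agony result. Single-start descent stalls on plateaus of dense
cyclic graphs (observed worst case 2× the exhaustive optimum on 5-node
instances); with the multi-start it matched the exhaustive optimum on all
200 random ≤5-node instances in the development checks, and the test suite
bounds it at 1.5× with ≥90% exact. The exact primal–dual agony algorithm
from the hierarchy literature is intentionally not implemented; the
ensemble only needs a low-agony ranking. Each edge then receives one vote
per hierarchy it violates and a violation magnitude (summed score gaps);
while cycles remain, the edge on a cycle with most votes (then largest
magnitude, then lexicographic) is removed. Re-checking cycle membership
after every removal keeps the feedback set lean — this is why the ensemble
usually removes the fewest edges.

## Expression simulation

The simulator emulates the SynTReN family rather than wrapping the Java
tool: Hill-kinetics transfer functions, uniform external conditions on
regulator-free genes, additive Gaussian noise. Per edge, a Hill coefficient
n ∈ {1,…,10}, half-saturation K ∈ [0.05, 1.0] and a role (activator
x^n/(K^n+x^n), repressor K^n/(K^n+x^n)) are sampled with a seeded
generator; signed edges keep their sign's role. Per gene, a basal level
b ∈ [0.01, 0.2]. A regulated gene's level is

    x_v = clip₀₁( b_v + (1 − b_v) · mean_e h_e(x_u) )

— the mean of edge-wise Hill terms replaces SynTReN's combinatorial AND/OR
input logic. This keeps the monotone dependence on each regulator (which
is what BIC scoring can detect) with far fewer parameters; it is a
documented divergence from SynTReN's internals.

Steady states are found by damped synchronous iteration x ← (1−α)x + αf(x)
(α = 0.5) from 0.5, stopping when the largest change drops below 1e-8 or
after 500 iterations; this also handles cyclic networks, where a
closed-form topological evaluation does not exist. Non-converged samples
are kept and flagged (dropping them would bias the data); the pipeline
warns when more than half the samples fail to converge. Per sample, root
inputs are uniform(0,1), the steady state is solved, Gaussian noise
(default sd 0.05) is added and values are clipped to [0,1].

Discretization for multinomial scoring is per-gene equal-frequency binning
into 3 levels (configurable): cutpoints at the k/levels quantiles, a value
landing in the number of cutpoints strictly below it, so boundary ties go
down and constant rows map to level 0 throughout. Three quantile levels is
the conventional choice for expression-to-multinomial-BN pipelines.

### What the simulator does not capture

- **Rootless networks.** A strongly feedback-dominated network can have no
  regulator-free genes; with external variation applied only to roots, its
  pre-noise steady state is identical across samples and the data carries
  no topological signal — BIC comparisons on such networks are essentially
  noise (visible in the benchmark's random-DAG beat counts for some cyclic
  fixtures). Real experiments perturb conditions network-wide.
- No time courses, no SynTReN subnetwork sampling from source organisms, no
  microarray-specific noise model, no saturating combinatorial regulation.

Passing tests therefore demonstrate correctness of the machinery and
recovery of *identifiable* structure, not that any particular real pathway
would be recovered from real expression data.

## BIC scoring and the random-DAG null

The score is the decomposable multinomial BIC in the higher-is-better,
natural-log convention: per gene, Σ_{jk} N_jk ln(N_jk/N_j) minus
(ln N)/2 · q (r−1), where r counts *observed* target states and q observed
parent configurations (1 when parentless) — counting observed rather than
declared states matches quantile-binned data, where all levels occur by
construction, and keeps degenerate constant genes harmless (r = 1
contributes exactly 0). Cyclic inputs are rejected naming a cycle.

Random DAGs matched in node and edge count are drawn by sampling a uniform
permutation and then the requested number of distinct ordered pairs
uniformly among its forward pairs. This sampler is not uniform over DAGs
but is simple, seedable, and covers the support (verified exhaustively for
small cases). Method comparison uses dense descending ranks (ties share
the better rank); the random-DAG comparison counts randoms *strictly*
beating the method's score.

An identifiability remark that shaped the test fixtures: a node with k
3-level parents has 3^k parent configurations, so its penalty grows as
(ln N)/2 · 3^k · 2 ≈ 5.3·3^k at N = 200 — beyond ~3 parents no achievable
likelihood gain repays it. Data-generating DAG fixtures for the recovery
study therefore cap in-degree at 3 (`random_true_dag`), which also matches
the sparse regulator structure of pathway-derived networks.

## Pipeline and determinism

Every stage seeds its generator from the single run seed via stable
CRC-derived sub-seeds tagged by pathway, method and stage, so two runs with
the same configuration are byte-identical (asserted down to file hashes in
the tests). Output files carry no timestamps; the manifest records the
seed, all knobs and the package version. Pathways under the non-isolated
threshold (default 6, as in the benchmark design) still get their network
files but are recorded as skipped; acyclic networks are converted (all
methods trivially remove nothing) but not scored, since the scoring
exercise only discriminates cycle-removal choices.

## Problem sizes used by the shipped studies

The acceptance study runs 24 generated pathways (7–14 genes each before
collapse), 100 expression samples and 100 matched random DAGs per method
DAG; the test suite uses exhaustive enumeration up to 4–5 nodes where an
oracle exists, 500-instance randomized sweeps for graph properties, and
200-sample simulations for the statistical ones. These sizes were chosen to
make every property checkable by brute force or repetition at a desk;
nothing in the algorithms depends on them.
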