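# Methods

`epiclust` implements a fully simulation-based study asking whether the
level of clustering in a contact network — the propensity for triangles,
with the degree of every node held fixed — leaves a detectable signal in
the data an epidemic produces: the epidemic curve and the transmission
tree. This note records the models, the numerical choices, and what the
package's tests do and do not establish.

## Network models (the synthetic-data generator)

All networks are undirected simple graphs on integer-labelled nodes
(`networkx.Graph`), validated against the structural invariants (no
self-loops, binary adjacency, degree sum = twice the edge count).

**Bernoulli model** (N = 500, p = 7/N = 0.014 by default). Sampled by the
two-step construction: edge count `|Y| ~ Binomial(N(N-1)/2, p)`, then `|Y|`
distinct unordered pairs uniformly at random. This is distributionally
identical to independent per-edge coin flips.

**Approximate power-law model** (N = 600, α = 1.8 by default). Degrees are
drawn i.i.d. with `P(d = k) ∝ k^-α` on `k = 1 .. max_degree`. A cutoff is
mandatory — for α < 2 the raw law has divergent mean — and defaults to
N − 1, the largest degree a simple graph admits. Degree 0 is excluded:
zero-degree nodes can never join the component an epidemic runs on. If the
degree total is odd, one uniformly chosen node's degree is redrawn until
the total is even (unbiased, and independent of the other nodes). The graph
is then assembled by uniform stub pairing (configuration model) with loops
removed and parallel edges collapsed, so realized degrees never exceed
requested ones. With α = 1.8 the cutoff is often hit: near-cap hubs lose
roughly half their requested stubs to collapse (requested mean degree ≈ 9.5
shrinks to a realized ≈ 4.5). This is a property of the model as specified,
and the realized degree sequence — not the requested one — is what the
rewiring stage preserves exactly.

**Clustering** is measured as the mean over *all* nodes of the local
coefficient `C_i = 2 n_i / (d_i (d_i − 1))`, with `C_i = 0` when
`d_i ≤ 1` and 0 for the empty graph by convention.

## Degree-preserving rewiring

From each base network `Y` the pipeline produces a high-clustering arm
`Y^hi` and a low-clustering arm `Y^lo` by Metropolis–Hastings over
double-edge swaps, targeting the exponential-family density
`π(Y) ∝ exp(θ · u(Y; τ))` restricted to graphs with `Y`'s exact per-node
degrees, where `u` is the geometrically weighted edgewise-shared-partner
statistic

    u(Y; τ) = e^τ · Σ_{i≥1} [1 − (1 − e^{−τ})^i] · EP_i(Y),

`EP_i` counting edges whose endpoints share exactly `i` partners. Defaults:
decay τ = 0.2, coefficient θ = +5 (hi) or −5 (lo), burn-in 5×10⁵ proposals.

Numerical and design choices:

* **Proposals.** Two distinct edges uniformly, then one of the two
  rewirings with probability 1/2. Proposals that would create a loop or
  duplicate an existing edge are rejected and still count toward burn-in.
  Duplication is checked against the pre-removal graph, so degenerate
  proposals that would merely recreate the removed edges (no-ops on the
  state) are also classed invalid; rejecting a state-preserving move leaves
  the chain's law unchanged. Forward and reverse of any swap are proposed
  with equal probability, so the acceptance ratio is `min(1, exp(θ·Δu))`.
* **Exact incremental deltas.** Removing edge (a,b) changes
  shared-partner counts only for pairs involving a or b: `sp(a,y)` drops by
  one exactly for neighbours y of b, and symmetrically. The compiled kernel
  maintains a dense all-pairs shared-partner matrix plus fixed-capacity
  neighbour lists (degrees never change under swapping) and returns exact
  deltas; the pure-Python `delta_gwesp` implements the same identity and is
  tested against full recomputation to 10⁻⁹.
* **Connectivity is not constrained.** The largest component may — and
  under θ = +5 does — shrink as triangle-rich clumps detach. This is a
  feature of the model being studied, not an artifact.
* **Burn-in semantics.** Burn-in counts proposals, valid or not, matching
  the study conditions. The output is the single state after burn-in; no
  thinning or convergence diagnostics are required, though
  `return_stats=True` exposes acceptance counts and the running statistic,
  and a debug-level log line is emitted every 10⁴ proposals.

**Burn-in for attained-range measurements.** Monitoring the running
clustering level shows that at these network sizes the θ = +5 chain is
still climbing at 5×10⁵ proposals and flattens out only after a few
million (e.g. Bernoulli chains move from ≈ 0.275 at 5×10⁵ to ≈ 0.30 at
2–4×10⁶ and are stable thereafter). The paired experiment uses the study's
5×10⁵; the measurements whose point is the *attainable range of clustering*
(the acceptance script and the range checks in the test suite) run each
chain for 4×10⁶ proposals so that they measure the stationary range rather
than a transient. Attained ranges under this sampler: Bernoulli hi ≈
0.27–0.32 (lo exactly 0, triangle-free); power-law hi ≈ 0.30–0.40, lo ≈ 0.

## SEIR epidemics

Event-driven simulation with a priority queue; ties break on (time, event
kind with exposure < onset < recovery, insertion order), so runs are
deterministic given (network, parameters, index, seed). Defaults:
per-edge transmission rate β = 0.1/day; latent and infectious periods
gamma-distributed with shapes k_E = k_I = 1 and scales θ_E = θ_I = 3 days.
The source text prints "θ_E = β_I = 3"; `β_I` is read as a typographical
slip for θ_I — θ_I is otherwise undefined and the symmetric reading matches
k_E = k_I.

Since re-infection is impossible, only the first potential transmission
along each infectious–susceptible edge matters, so a single
`Exponential(β)` first-contact time is drawn per pair when the infector
becomes infectious; the contact succeeds iff it precedes the infector's
recovery and the neighbour is still susceptible at that time. With
k_I = 1 this yields the closed-form per-neighbour transmission probability
`β/(β + 1/θ_I) ≈ 0.2308`, which the test suite verifies by Monte Carlo.

**Conditioning.** Outbreaks are conditioned on infecting ≥ 20 nodes by
re-running with fresh randomness and the *index fixed*; only when a
configurable attempt budget is exhausted is a new index drawn, and then
both members of a pair restart. The index of a pair is drawn uniformly
from the node ids lying in the largest component of *both* arms (outbreaks
are confined to the index's component, so this is equivalent to
restricting each arm to its giant component before pairing). Both rules
are package choices where the study description is silent.

## Transmission trees

Each infected individual's timeline runs from their infection event
through the transmissions they cause to their recovery; branches join
consecutive events on a timeline. An internal node (t, u, v) — v infects
u at t — therefore has two children (the continuation of v's timeline and
the start of u's), the root one, leaves none; a tree on L infected hosts
has L − 1 internal nodes, 2L − 1 branches, and total branch length equal
to the summed infected durations (asserted to 10⁻⁹ on every simulated
tree). Branch means are classified by the child endpoint: internal-child
branches measure times between successive secondary infections,
leaf-child branches the time from last transmission to removal; a
single-host tree has no internal branches and reports NaN.

Infective descendants are computed by the recursion (an individual's
infectees, their infectees, and so on), which makes the index's count
exactly L − 1. The equivalent leaf-ancestor characterisation used as a
test oracle must exclude each leaf's own individual: the transmission
nodes on an individual's own timeline are ancestors of its own leaf, and
counting it would inflate every transmitter's count by one.

Cherries are internal nodes whose two children are both leaves; the
cherry ratio divides by the maximum possible `floor(L/2)` and is NaN for
single-host trees. Trees serialize to rooted Newick (leaf labels are host
ids; round-trips through a standard parser are tested to 10⁻⁶) and to a
TSV of node triples.

## Curve summaries

The epidemic curve counts hosts that are exposed *or* infectious by
default (the total-ever-infected reading of "infected"); counting
infectious only is available via `include_exposed=False`. Prevalence is
piecewise constant, changing only at events, so final size, epidemic
length (first infection to last recovery), peak prevalence and peak time
are computed exactly from event times — the daily grid is output-only.
At an instant where one infection ends exactly as another starts the
ending host is not counted (intervals are half-open at recovery); peak
ties resolve to the earliest attaining time.

## The paired experiment

Per replicate: sample `Y_i`, rewire to both arms, run paired conditioned
epidemics from a shared index, summarise both trees. The master seed
spawns one `SeedSequence` substream per replicate (and per stage within a
replicate), so any replicate is individually reproducible and results are
independent of execution order. Failed replicates (conditioning exhausted
across index redraws) are reported in the output table with
`failed=True`, never silently resampled. Arm comparisons report per-arm
mean/min/max and a range-overlap coefficient
`|range intersection| / |range union|`; NaN entries (failed replicates,
single-host trees) are dropped per statistic, and degenerate zero-width
unions count as overlap 1.

## Problem sizes used by the test suite and acceptance script

The original study runs 500 replicates per model. The packaged checks use
10 replicates for the attained-clustering ranges, 100 Bernoulli and 50
power-law paired replicates for the direction-of-means checks, and
2×10⁴ runs for the two-node transmission probability — sizes chosen so a
single-core run of the whole suite completes in minutes while the
direction and range statements remain stable across seeds. The full
500-replicate experiment is reproducible with the `epiclust experiment`
command overnight on one core.

## What the generator does and does not emulate

The synthetic networks reproduce the study conditions exactly as stated
(sizes, edge probability, exponent, rewiring coefficients and burn-in,
epidemic parameters). They do not emulate features of real contact
networks outside those models: degree assortativity is uncontrolled,
there is no household or spatial structure, and edges are static over the
epidemic. Passing tests therefore support claims about these model
classes, not about any empirical network.

## Known limitations

* The rewiring sampler targets the same density family as the original
  study's tool but is not the same program; only the target density, not
  the draw-for-draw distribution at a finite burn-in, is claimed. Attained
  clustering ranges agree closely for the Bernoulli model and for the
  power-law bounds, but this sampler fragments the high-clustering
  power-law giant component more strongly (giants ≈ 290–370 of 600 nodes)
  than the original runs appear to have, and its low-clustering power-law
  epidemics infect a somewhat smaller fraction of the giant; the
  proportion-of-giant overlap between arms is correspondingly weaker than
  originally reported. The corresponding end-to-end check is left failing
  rather than weakened.
* With α = 1.8 and cutoff N − 1, multi-edge collapse at hubs is heavy, so
  the realized power-law degree distribution depends materially on the
  cutoff choice, which the study text does not pin down.
* `mean_secondary` is derived from the tree and equals (L−1)/L by
  construction; it is reported for completeness, not as an estimate of a
  reproduction number.
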