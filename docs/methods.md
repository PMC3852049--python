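# Methods

## Model

All computations assume the multispecies coalescent on a rooted phylogeny:
within each branch, every pair of gene lineages coalesces independently at
rate 1 per coalescent unit (time divided by population size), so `u` lineages
drop to `v` with the classical probability `p_{u,v}(λ)` (an alternating sum
with coefficients computed here as exact rationals and cached; lineage counts
are capped at 30, far above anything the algorithms are practical for).  A
species network is a rooted DAG: tree nodes have one parent, reticulation
(hybridization) nodes have two, and each in-edge of a reticulation carries an
inheritance probability γ, the chance that a lineage at the node follows that
parent; the γ over each node's in-edges sum to 1.  Only gene-tree
*topologies* are modeled — gene-tree branch lengths never enter, matching the
common situation where per-locus trees are reliable in shape but not in
depth.  An implicit branch of infinite length sits above the root, where any
remaining lineages finish coalescing; it contributes ordering fractions but,
by construction, no extra-lineage cost, which is also why parsimony scores
exclude it.

## Coalescent histories and the oracle

A coalescent history assigns every gene-tree node to the network edge where
that coalescence happens (leaves to their species' terminal edges, ancestors
never below descendants).  On a network a history additionally fixes the
parent edge taken by each gene lineage at each reticulation it crosses; the
oracle enumerates assignments and routings exhaustively, multiplies per-edge
factors `(w_b/d_b) γ^{u_b} p_{u_b,v_b}(λ_b)`, and sums (probability) or
minimizes extra lineages (parsimony).  This is exponential and used only on
small instances, as the independent check for the fast algorithms — every
fast result in the test suite is validated against it.

The ordering fraction `w_b/d_b` is computed exactly: `d` is the product of
pair counts `C(k,2)`, and `w` counts linear extensions of the forest of
required coalescence events by the hook-length formula `r!/Π(subtree sizes)`;
an explicit sequence-enumeration oracle confirms it in the tests.

## Weighted ancestral configurations

The production algorithms propagate sets of configurations `(B, a, w)`
bottom-up: `B` the lineages present, `a` a vector of per-reticulation split
indices, `w` a weight (extra-lineage count, or accumulated probability).  At
a reticulation every configuration is split into all `2^|B|` ordered
bipartitions; **each bipartition receives its own fresh index**, stamped on
both halves, so that exactly the two halves of one bipartition can recombine
at the tree node above (the compatibility rule: vectors must agree wherever
both are nonzero).  Sharing one index across bipartitions of a configuration
would let mismatched halves merge and double-count lineages; the per-pair
stamping is forced by the compatibility rule and verified against the oracle.
In probability mode each side's weight is multiplied by γ^(lineages sent that
way) — note `γ^0 = 1`, so a zero-γ edge only kills configurations that
actually route lineages through it, which is what makes γ ∈ {0,1} reduce the
network exactly to a displayed tree.

Along every edge (including reticulation in-edges) configurations coalesce:
in probability mode each reachable outcome `B⁺` of `Coal(B, g)` gets weight
`w · p_{|B|,|B⁺|}(λ) · w_b/d_b`, identical outcomes summing; in parsimony
mode each configuration coalesces maximally (greedy merging is confluent and
early coalescence can never hurt the cost) and pays `max(|B⁺| − 1, 0)`.
Parsimony keeps only the minimum-weight configuration per distinct `(B, a)`,
which is safe because later updates add weight independently of `w`.  The
per-distinct-`B` (rather than single global) minimum is likewise kept when
vectors are reset, since configurations with different lineage sets are not
interchangeable above the reset point.

**Articulation reduction.**  At a node whose rooted subnetwork is connected
to the rest of the graph only through the node itself, all reticulation
bookkeeping below is resolved, so vectors are reset to zero: probability mode
sums weights of now-identical configurations, parsimony keeps the per-`B`
minimum.  The precise criterion — every in-edge of every strict descendant
originates inside the descendant set — matters: an undirected cut vertex is
*not* sufficient (a node separating only a pendant leaf still shares its
reticulation with the outside, and resetting there corrupts the computation).
The reduction changes results by nothing (checked to 1e-12, and exactly for
parsimony) while shrinking configuration sets.

Both traversals cap the number of live configurations (default 500,000) and
raise a capacity error beyond it; the underlying problems are conjectured
intractable in general, and the cap turns a silent blow-up into a diagnosis.
Probabilities are accumulated with compensated summation in linear space;
instances deep enough to underflow double precision are outside the intended
scale.

## The LCH heuristic (trees)

Exact probability on a species tree is the reticulation-free special case
(every node is a reduction point and all vectors stay zero).  The heuristic
first builds a *limiting coalescent history*: walking the tree in post-order,
each branch with `u` entering lineages commits `u − x` topology-consistent
coalescences, where `x ∈ [minL, numL]` maximizes `p_{u,x}(λ)`; which eligible
events are committed when there is slack is chosen uniformly at random from a
seeded generator (ties in `x` go to the larger value, i.e. fewer events).
Initially every clade coalesces above the root, so short branches leave the
assignment at the root and the heuristic degenerates to the exact sum.  The
probability is then the sum over histories *under* the LCH — each clade must
form no higher than its assigned branch — implemented by discarding, at the
top of each assigned branch, configurations in which the clade has not yet
formed.  The result is always in `(0, exact]`, is deterministic given the
seed, and on a three-taxon tree with internal branch `T` commits the cherry
below the root exactly when `T > ln 2`.

## Simulator

Gene trees are simulated backward in time within the network's edges (the
role an external coalescent simulator would play): exponential waiting times
at rate `C(k,2)` per branch, truncation at branch length, independent
γ-weighted parent choice per lineage at reticulations, and unconstrained
coalescence above the root.  Random ultrametric species trees use sequential
uniform joins with `n − 2` interior join times uniform on `(0, height)` — a
simple stand-in for a pure-birth generator; the `height` parameter is the
tree age in coalescent units.  Random networks grow by midpoint attachment:
two distinct edges are drawn, their midpoints (in depth from the root along
branch lengths) are connected from shallower to deeper, and the deeper
midpoint becomes a reticulation with γ ~ Uniform(0,1), the neutral choice in
the absence of any biological prior.  Because every
edge runs from a shallower to a strictly deeper node, the construction can
never create a directed cycle; equal-depth draws are rejected and redrawn.

What the simulator does *not* emulate: mutation, recombination, gene flow
continuous in time, population-size variation across branches, or gene-tree
estimation error.  Tests passing on simulated data therefore certify the
coalescent machinery, not robustness to misestimated input trees.

## Inference driver

The species-tree search is a deliberately compact stand-in for a full ML
program: likelihood = Σ log P(g_i | S) over loci (identical topologies are
collapsed and weighted), engine either exact or heuristic; branch lengths by
per-branch bounded scalar search (coordinate ascent, sweep tolerance 1e-4
log-units, branch lengths bounded to [1e-3, 15]; terminal branches are only
optimized when a species contributes more than one allele, since otherwise
they cannot affect topology probabilities); topology moves are rooted NNI
from a greedy clade-frequency consensus start, with neighbors screened at
inherited branch lengths and only the best two re-optimized.  Restarts
perturb the start with seeded random NNI moves.  On four taxa the search
provably matches exhaustive enumeration in the tests; on eight taxa it
recovers the true tree from ~100 loci at height 7.  Differences from any
particular published search implementation are expected; only the ML
objective is shared.

## Numerical and design choices

- Branch lengths are coalescent units throughout; no rescaling by population
  size is performed or supported.
- Newick dialect: hybrid nodes `#Hk`, annotations `:length:support:gamma`
  with support left empty; γ may be given on one in-edge (the sibling gets
  `1 − γ`).  Reticulation indices follow first appearance of tags and the
  writer renumbers by output order, making serialization canonical and
  round-trips exact.  Parallel edges are rejected.
- Missing branch lengths parse fine and are fatal only for probability use;
  parsimony ignores λ and γ entirely.
- Internal tree nodes with out-degree > 2 are accepted in species phylogenies
  (merged pairwise in traversal order); gene trees must be binary.
- Deterministic iteration everywhere: configuration sets iterate in canonical
  (sorted lineage set, vector) order, so split-index assignment and all
  tie-breaks are reproducible run to run.
- The acceptance battery uses 3–6 taxa and 0–2 reticulations with branch
  lengths drawn from [0.2, 5]: large enough to exercise deep coalescence and
  reticulation interplay, small enough that the exponential history oracle
  stays exact and fast.  The inference experiment uses ten 8-taxon trees of
  height 7 with 10–100 loci, a scaled-down version of the regime where more
  loci should monotonically improve accuracy.

## Known limitations

- Exponential worst case in taxa and reticulations (inherent to the
  problems); the capacity guard reports rather than fights it.
- The heuristic is defined for species trees only, as is the inference
  driver; network *inference* (searching network space) is out of scope.
- Gene trees must be rooted and binary; unrooted input is not interpreted.
- No time-consistency check of networks beyond acyclicity (a reticulation may
  join branches whose time spans do not overlap; the coalescent on edges is
  still well-defined).
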