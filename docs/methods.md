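# Methods

## Model and procedure

The package treats a conserved protein complex as a group of proteins that
is (i) dense and well separated inside each species' PPI network and
(ii) rich in cross-species sequence homology.  Detection is local: each
cross-species spine (one protein per network) is processed independently,
so cost scales with neighborhood size rather than network size, and the
result is invariant to processing order and worker count.

Per spine protein the pipeline runs three stages.

**Personalized PageRank neighborhood.**  Scores are computed by the local
push scheme: an approximation vector p and residual vector r start with
all mass on the seed, and any node whose residual reaches `tolerance`
times its degree transfers `restart` of it to its own score and spreads
the rest over its neighbors.  On termination every residual is below
`tolerance · degree`, so each score is within `tolerance · vol(touched
nodes)` of the exact random-walk-with-restart solution, and only the
seed's neighborhood is ever touched.  The seed plus the m−1 top-scoring
proteins form the candidate set H (ties: higher degree, then protein ID).
A degree-0 seed keeps unit mass on itself.

**Exact minimum-conductance subset.**  Within H the subset S containing
the seed minimizing φ(S) = cut(S)/vol(S) is found exactly.  Degrees and
cuts are those of the **full host network**: vol(S) counts all
interactions of the selected proteins and cut(S) all interactions leaving
S, including edges to proteins of H not selected and to the rest of the
network.  This is a deliberate design choice: if both the adjacency and
the degree matrix were restricted to the subgraph induced by H, selecting
all of H would always give a numerator of zero and the optimization would
be vacuous.  Charging the selection for its full-network boundary keeps
the problem meaningful and matches the intent of "separated from the rest
of the network" — an isolated module still scores φ = 0, while a
neighborhood that merely ran out of PageRank mass does not.

The fractional program is solved as a MILP (HiGHS via
`scipy.optimize.milp`): minimize a level variable z subject to
cut(S) ≤ z·vol(S), with products z·x_i and x_i·x_j linearized by McCormick
envelopes (exact here because z ∈ [0,1] and x is binary) and vol(S) ≥ 1 to
exclude the degenerate zero-volume selections that satisfy the level
constraint vacuously.  The returned selection's conductance is re-evaluated
in exact arithmetic, so solver tolerances cannot leak into reported values.
`mip_rel_gap` is set to 0.  An exhaustive enumerator over all
seed-containing subsets provides the independent oracle (and the fallback
when the solver fails on instances within `exhaustive_cap`); beyond the
cap a PageRank sweep cut is the last-resort fallback, logged as a warning.
Zero-volume selections score 1 (the worst possible value); exact ties go
to the larger subset, then the lexicographically smallest member list.

**Greedy pruning of the merged candidate.**  The k minimum-conductance
sets are merged and scored by

    F = −( Σ_j  2·E_j(S) / |S_j|  +  λ · 2·Sim(S) / |S| ),

with E_j(S) the selected interactions in network j, Sim(S) the similarity
sum over selected cross-network pairs, and |S| the total selection.  Both
numerators follow the ordered-pair convention (each unordered pair counted
in both orientations, hence the factors 2): the adjacency form Σ_{a,b}
A(a,b)δ_aδ_b naturally sums both orientations, and keeping similarity on
the same convention makes λ weigh homology against topology on a
consistent scale — a selected triangle contributes density 2, and one
homolog pair at similarity 1 in a 2-protein selection contributes λ·1.
Pruning is steepest descent: every selected protein's removal is evaluated
(O(1) each via cached per-protein selected-degree and similarity sums, so
one prune is O((km)²) evaluations in total) and the best strictly
improving removal (margin 1e-12, ties by network index then protein ID) is
applied until none remains.  A network whose selection empties contributes
0 to the density sum.  Steepest descent is a heuristic; tests verify it
never beats the exhaustive optimum and reaches it in ≥ 70% of small random
instances.

**Post-processing.**  Exact duplicates (all k protein sets equal) keep
their first occurrence; complexes whose internal similarity sum (stored
once per unordered pair) is below β are dropped; a minimum per-species
size can be enforced.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| m | 20 | neighborhood size; complexes rarely exceed ~20 subunits, and the MILP stays small |
| restart | 0.15 | classic PageRank restart probability |
| tolerance | 1e-4 | per-degree residual bound of the push scheme |
| λ | 10 | homology weight in F; 1/10/100 span the useful range, 10 is the middle |
| β | 0.1 | minimum internal similarity sum of a reported complex |
| min_size_per_species | 3 | evaluation-grade complexes need ≥3 proteins per species |
| exhaustive_cap | 15 | largest neighborhood enumerated when the solver fails (2^14 subsets) |
| similarity threshold | 0.1 | normalized bit scores below this are treated as noise and dropped |
| τ | 0.25 | affinity level at which a prediction matches a reference |
| IC threshold | 2 (natural log) | "high-level" GO terms; −ln(|term|/|root|) > 2 ≈ term covers <13.5% of its namespace |

Similarity scores are normalized bit scores
s(p,q) = blast(p,q)/√(blast(p,p)·blast(q,q)) ∈ [0,1]; the highest bit
score per pair is used, and lookups are symmetric.

## Evaluation metrics

Pairwise (two-species) scores: matched fraction at affinity
w(X,Y)=|X∩Y|²/(|X||Y|) ≥ τ in both species simultaneously; complex-wise
Sn = Σ_j max_i t_ij / Σ_j w_j and PPV = Σ_i max_j t_ij / Σ_iΣ_j t_ij with
t_ij the per-species overlap counts summed and w_j the reference size
(species namespaced, so cross-species unions are disjoint);
Acc = √(Sn·PPV); MMRC — maximum-weight one-to-one matching (solved by
`linear_sum_assignment`) of harmonic-mean affinities
o(A,B) = 2w₁w₂/(w₁+w₂), edges below τ dropped, divided by the number of
references; composite = fraction + Acc + MMRC ∈ [0,3].  Guards: PPV = 0
when there is no overlap at all; o = 0 when both affinities are 0; NE = 0
for a single term; a complex with no annotated protein is skipped in MNE
with a warning.  MNE uses assignment fractions (a protein carrying several
terms contributes one count per term) and natural logs, which cancel in
NE; coverage counts distinct proteins (union over qualifying complexes),
namespaced by species.  Reference pairs are built by the shared-GO-term
rule: a species-2 complex pairs with a labeled species-1 complex when at
least half its proteins carry that term.

## Noise injection and parameter grids

Topological noise is Maslov–Sneppen double-edge swapping — (a,b),(c,d) →
(a,d),(c,b), rejecting self-loops and duplicates — continued until the
requested fraction of the *original* edge set has been displaced, so
"10% noise" is measured in edges no longer present, not in swap count.
Degree sequences are preserved exactly; graphs too rigid to reach the
target return best effort with a warning.  No connectivity constraint is
imposed.  The same swap applied to the similarity bipartite graph
perturbs homology; each rewired pair inherits the score of the original
entry with the same first-species protein (the paper-style procedure does
not pin this down; any consistent rule preserves the semantics, and the
left-inheritance rule keeps every first-species protein's total similarity
mass unchanged).  The grid sampler spreads a budget N over k parameters
with n = ⌊N^(1/k)⌋ evenly spaced values per parameter including both
endpoints (the k-th root is computed in integer arithmetic to avoid
floating-point rounding); the default even grid keeps sweeps reproducible
without bookkeeping, and a seeded uniform-random mode is available for
when grid alignment with round parameter values is undesirable.

## Synthetic worlds

The generator plants `n_complexes` modules of `size` proteins in each of
k networks: module edges with probability p_in, module-to-background edges
with probability p_out, an Erdős–Rényi background (default 200 proteins,
mean degree ~2), index-aligned orthologs with similarity drawn from
Normal(0.6, 0.15) clipped to [0.1, 1], and decoy similarities at rate
5·10⁻⁴ per cross-network pair drawn uniformly from [0.1, 0.5].  Modules
are disjoint within a network, so ground truth is unambiguous; spines are
the first protein of each module counterpart.  The defaults are the
package's benchmark conditions: strong but imperfect modules (p_in = 0.9),
light leakage (p_out = 0.02 gives each module protein ~4 background
interactions, conductance ≈ 0.5 — separable but not trivial), and
homology well above threshold.

What the generator does **not** emulate: scale-free degree distributions,
overlapping or partially conserved complexes, many-to-many ortholog
groups (decoys aside), missing orthologs, or correlated noise between
species.  Passing the recovery tests therefore shows the pipeline is
correct and robust under the planted-partition model of complex
conservation, not that it attains any particular score on real
interactomes, where evaluation additionally depends on reference-set
completeness.

In the idealized noiseless condition (p_in = 1, p_out = 0, no decoys)
every planted module is an isolated clique and recovery is required to be
exact (composite = 3).  p_in = 1 is used there because a G(5, 0.9) module
has a small chance of being generated disconnected, in which case no
seed-local method can see the whole module and exactness is impossible by
construction rather than by algorithmic failure.

## Problem sizes

The test suite and the reproduction script run the full pipeline on
two-species worlds of ~225 proteins per network (10 planted complexes,
200-protein background), averaging over 10 seeds for recovery bounds, 10
replicates for the noise protocol, and 5 worlds in the reproduction
script — sizes chosen so the whole suite completes in minutes on one CPU
while every stage (PageRank, MILP, pruning, matching) is exercised at
realistic neighborhood sizes.

## Known limitations

* The pairwise prediction metrics are defined for k = 2; for k > 2 runs
  only MNE and coverage apply (pairwise projections of the truth are
  provided for per-pair evaluation).
* The built-in spine builder is a deterministic reciprocal-best-hit
  chainer, not a full multiple network aligner; it is one-to-one by
  construction (many-to-many homology still enters through the cost
  function).  Spines from an external aligner can be loaded from file.
* "Duplicate" complexes means exact equality of all k protein sets;
  highly overlapping near-duplicates are all reported.
* Parallelism is a thread pool over spines with deterministic reassembly;
  it guarantees order-invariance rather than linear speed-up.
* Networks are unweighted simple graphs; interaction confidence scores
  are ignored.
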