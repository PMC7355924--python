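# Methods

## Model and assumptions

The analysis treats two layers of evidence about a gene pair as
independent measurements of one relationship. The causal layer is a
directed graph with edge signs s ∈ {+1 activation, −1 inhibition},
assembled by merging edge lists from one or more curated sources. The
observational layer is a set of expression matrices (genes × samples),
each from an independent study. The central assumption is that if a
causal edge is active at the transcript level, the source and target
profiles correlate with the edge's sign *within* a dataset; samples are
never pooled across datasets, because platform and tissue heterogeneity
can fabricate or mask correlations.

A pair's verdict is three-valued: *coherent* (significant correlation,
sign matches), *incoherent* (significant, sign contradicts), or
*non-significant* (no call at the chosen confidence). Verdicts are
compared across structural contexts — simple activation/inhibition edges,
two-node loops, multi-edge feedback and feed-forward loops — against
unconnected gene pairs (UGPs), the null class.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `min_n` | 3 | minimum shared complete samples per dataset ("more than two"); eligibility is per dataset, never pooled |
| `method` | pearson | correlation; spearman and kendall (tau-b, tie-corrected) give the same sign structure on monotone data |
| `alpha` | 0.05 | significance cutoff applied to BH-adjusted p-values |
| `aggregation` | weighted_mean | per-dataset → edge-level rule; alternative `max_n` uses only the largest dataset |
| `conflict_policy` | ambiguous | ordered pairs carrying both signs after merge are excluded and recorded; `keep_both` and `drop` available |
| `ugp_m`, `ugp_replicates` | 1000, 10 | UGP sample size and replicate count |

Aggregation is a genuinely open design point: dataset-level correlations
must become one edge-level call, and nothing in the method's definition
fixes the rule. The default combines homogeneous datasets with an
n-weighted mean of r and Fisher's method on the two-sided p-values; a
single eligible dataset keeps its own p. Both choices are conservative in
the sense that they never manufacture a sign the datasets disagree on,
because heterogeneous pairs are removed first (r = 0 is sign-neutral in
that test). One BH family spans all homogeneous eligible edges of a run;
each UGP replicate forms its own family, mirroring its role as an
independently drawn null set.

Missing values are handled complete-case within each pair (correlation
needs paired observations); a constant vector makes that dataset's
correlation undefined and the dataset is skipped with a logged reason.
Expression values are used as provided — preprocessing is declared
upstream — with an optional log2(x+1) flag.

## Subgraph census

Matrix self-multiplication is the census instrument, so *walks* (which
may revisit nodes), not simple paths, are counted: the k-th power of the
signed adjacency sums sign products over all length-k walks, the unsigned
power counts them, and |S^k| = B^k certifies that every length-k walk
carries the same net sign. For each direct edge the shortest indirect
walk with k ∈ [2, radius] is used; pairs whose walks disagree in sign at
that length are excluded from the class tallies (a class label needs one
net sign, and no mixing rule is defined). The (direct, indirect) sign →
class map follows loop-sign logic — negative loops MNFBL/MNFFL, positive
or coherent ones MPFBL/MFFL, suffix 1/2 for an activating/inhibiting
direct edge — and lives in a configuration table (`DEFAULT_CLASS_MAP`) so
an alternative convention can be swapped in without code changes. Dual
pairs are read directly off the edge list (cheap and equivalent; tested
against the sign logic). Classes deliberately overlap: a dual-loop pair
still counts under Act/Inh through its constituent edges.

UGP candidates are unordered pairs with no directed walk in either
orientation. Connectivity is judged on the directed transitive closure
(boolean powers iterated to a fixpoint) rather than a fixed
diameter-bounded horizon: the undirected diameter does not bound directed
path lengths, and the null class must contain no path of any length. The
closure is reached at or before n−1 multiplications, which always exceeds
the diameter, so this is the bounded-horizon prescription taken to its
safe limit. Candidates are further screened for expression eligibility so
every sampled pair can be correlated. Replicate RNG streams are spawned
from the master seed (`numpy` `SeedSequence`), making every draw
reproducible.

Adjacency powers use int64 arithmetic; walk counts grow like
(mean degree)^k, so extremely dense graphs powered to large radii could
overflow — irrelevant at the sparse, radius ≤ ~15 scales this analysis
targets, but worth knowing.

## Proportion comparisons

"Binomial proportion test" is implemented as the pooled two-sample
z-test, z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)), no continuity correction
by default (a flag adds the prop.test-style half-unit correction, which
R's `prop.test` applies by default — the uncorrected statistic is the
classical pooled z). A degenerate pooled proportion (0 or 1) forces
p̂₁ = p̂₂ and returns p = 1. All pairwise class comparisons form one BH
family; which proportion is tested (positive, negative, or coherent) is
an explicit option, defaulting to positive, since the method definition
leaves both the tested proportion and the multiplicity handling open. The
UGP row enters with counts pooled over replicates; with equal replicate
sizes pooling and averaging coincide.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes:
several independent datasets (default 5 × 20 samples), a signed network
(default 150 genes, 200 edges; activation probability 0.72, matching the
activation share of curated human signaling networks), per-dataset gene
missingness (10%), and a planted coherent fraction φ (default 0.8). Edges
are linear-Gaussian: target = Σ (effect sign)·β·parent + N(0, σ²), with
β = 1 and σ = 0.5, giving a single-parent coherent edge a population
correlation of β/√(β²+σ²) ≈ 0.89. Incoherent edges flip the effect sign
(`anti_sign`); the `independent` mode instead leaves targets unlinked,
emulating null-like edges. Multiple parents contribute additively; cycles
(dual pairs, feedback loops) are resolved by one deterministic
Gauss–Seidel-style pass in node order. A configurable number of dual
pairs and signed triangles is injected so every census class is
populated. n_genes = 150 keeps the giant component large enough to supply
1000 unconnected pairs to the UGP sampler at the default density.

What the generator does *not* emulate: platform noise models, batch
effects, probe-level artifacts, heavy-tailed expression, or confounded
sampling. Passing recovery tests therefore show that the pipeline's
inference machinery is correct and calibrated under its own model — not
that real signaling networks are coherent, nor that real-data verdicts
are unbiased under violations of these assumptions. Indirect paths and
shared sources make even "null" unconnected pairs weakly dependent, which
is realistic and visible as a UGP significant rate slightly above α.

DEG labels propagate directions along edges: sources are random, each
still-unlabeled target receives the direction the truth table dictates
(inverted for incoherent edges). On node-disjoint edges the planted
fraction is recovered exactly; shared targets dilute it toward 0.5, which
is why recovery tests use disjoint constructions.

## Problem sizes and numerical choices

Tests and the acceptance script run at the planted-recovery sizes (200
edges, five 20-sample datasets, UGP 1000 × 10) and reduced sizes for
smoke and property checks; oracle-equivalence checks use 100 random
graphs of ≤ 15 nodes with walks up to length 5, where exhaustive walk
enumeration is instant. Output tables are sorted and written with fixed
float formatting (`%.12g`), so identical config + seed reproduces every
file byte for byte. Ties in the giant component and in `max_n`
aggregation break lexicographically. Eccentricities are computed on the
undirected projection of the giant weakly connected component by default
(the maximal reachability horizon; a directed variant is available).

## Known limitations

- No partial correlation or conditioning: indirect co-regulation is
  interpreted, as in the underlying method, through the subgraph census
  rather than removed.
- The homogeneity filter is sharp (any sign flip discards the pair);
  a sign flip in one tiny noisy dataset suffices to drop an edge.
- Snapshot-dependent quantities of any particular database export
  (edge counts, diameters, DEG tallies) are inputs, not outputs: the
  package analyzes whatever edge lists and matrices it is given.
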