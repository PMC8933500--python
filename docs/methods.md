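# Methods

This note documents the models implemented in `replinet`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions a user should know before trusting
or extending the results.

## The experimental system being modeled

The package targets serial-transfer evolution experiments of an RNA that
replicates via a self-encoded replicase. Two molecular classes matter: a
**host RNA** (~2,125 nt) encoding the catalytic replicase subunit, and
**parasitic RNAs** — deletion variants (retained length ~500 nt here) that
keep only the 5'/3' terminal recognition sequences and replicate by
exploiting replicases translated from host RNAs. Populations are propagated
in micro-compartments through rounds of replication, dilution with fresh
medium, and compartment mixing; long-read amplicon sequencing of host and
parasite size classes tracks the genetic composition per round, and
pairwise biochemical assays measure who replicates whom.

## Consensus genotyping

Reads are globally aligned to the ancestral host reference with affine gap
penalties (defaults: match +1, mismatch −1, gap open −4, gap extend −0.5;
a gap of length L costs `open + (L−1)·extend`). The defaults were chosen so
that one long structural deletion plus sparse substitutions is always
preferred over alternatives at realistic error rates; they are exposed as
parameters. The engine is Biopython's `PairwiseAligner`; an independent
pure-Python Gotoh dynamic program in the test suite cross-checks optimal
scores on small instances.

Conventions:

* Coordinates are 1-based; deletions are anchored at the first deleted
  reference base.
* **Deletions are left-normalized**: a gap inside a repeat admits several
  equal-scoring placements, so every deletion is shifted to its lowest
  equivalent coordinate (the convention VCF normalizers use). This makes
  calls canonical regardless of which co-optimal alignment the engine
  enumerates first, and the synthetic truth tables apply the same
  normalization.
* Insertions relative to the reference are called but never eligible for
  the dominant panel, which lists point mutations and deletions only.
* Host and parasite reads are processed as separate classes (split by
  length midpoint — the two classes differ by a 1,625 nt deletion, so the
  split is unambiguous for full-length reads) with separate panels and
  separate per-round frequency denominators. Both classes are aligned to
  the host reference, so the parasite panel contains the shared structural
  deletion in host coordinates.

A mutation is **dominant** when its within-round read frequency strictly
exceeds the threshold (default 10%) in at least one round; strictness is
configurable because the boundary case (exactly 10%) is convention, not
biology. Each read is then projected onto the panel — non-panel mutations
discarded — and identical projections merge into one consensus genotype
with per-round counts and frequencies. Projection is idempotent, and reads
carrying only sub-threshold noise collapse into the ancestor-like genotype.

Full-length reads are assumed; reads spanning only part of a deletion are
out of scope, as is sequencing-quality filtering (the synthetic reads carry
no quality model).

## Lineage analysis

Distances between genotypes are Hamming counts over the panel. Lineages
are **single-linkage threshold components**: two genotypes share a lineage
iff they are connected through pairs at distance ≤ cutoff. The cutoff is a
required analysis parameter; the bundled scenario separates cleanly at
cutoff 3 because planted lineages differ by ≥ 4 private mutations.
Clustering runs on the raw distances; the 2-D PCoA map is for
visualization only, since clustering in a projection would depend on how
much variance the plane happens to capture. Lineage labels are ordered by
each cluster's earliest round of appearance.

PCoA is classical (Torgerson) scaling: eigendecomposition of the
double-centered squared-distance matrix. Axis orientation is fixed by
making the largest-magnitude loading positive, so embeddings are identical
run to run. One caveat worth stating precisely: Hamming distance between
binary vectors equals *squared* Euclidean distance, so classical scaling
of a raw Hamming matrix can legitimately produce negative eigenvalues
(√Hamming is the exactly embeddable metric). Negative eigenvalues are
reported in the result object, never silently dropped, and contribute
zero coordinates.

Neighbor joining follows the Saitou–Nei agglomeration with two pinned
conventions: Q-matrix ties select the lexicographically smallest index
pair, and negative branch-length estimates are clamped to zero with the
total clamped deficit reported. On additive matrices no clamping occurs
and path lengths are recovered exactly (the suite checks ≤ 1e−9 against
constructed trees and against scikit-bio's NJ). Trees are unrooted
(trifurcating root) and serialized as Newick.

Per-round lineage frequencies are sums of member-genotype frequencies
renormalized over all analyzed genotypes; a presence flag marks lineages
strictly above 0.1% of a round's analyzed reads.

## Replication networks

Fold replication is `conc(t2)/conc(t0)` per template; a fold of 0 is legal
but flagged as degradation. Measurements of a co-incubated second RNA are
normalized by its template-only negative control. The directed replicator
graph draws an edge from replicase source *j* to template *i* iff the mean
fold over replicates strictly exceeds 1.5; edge widths store log2 of the
fold, and sub-threshold pairs are kept as an "undetected" annotation
rather than edges. Rendering is the caller's concern (GraphML via
networkx; a minimal in-repo DOT writer, since no DOT library is a
dependency).

Treating the assay as a first-order reaction over reaction time T gives
`k_ij = ln(mean fold)/T`. Folds in (0, 1] map to k = 0 with a warning: the
growth model has no decay term, so apparent shrinkage carries no rate
information. Columns for sources that encode no replicase (parasites) are
structurally zero regardless of measured values. The effective replication
factor is taken to be the normalized mean fold itself; the transform is a
single pluggable point (`reaction_time`, pre-normalized tables) should a
different definition be needed.

## Bahadur decomposition

The four presence/absence combinations of two partners form an orthogonal
2² design, so the expansion of `y = log10(fold_i)`,

    y = f0 + w_j z_j + w_k z_k + w_jk z_j z_k,   z ∈ {−1, +1},

is exactly determined: `f0 = mean(y)`, `w_x = mean(z_x·y)`. Per-term
`R²_x = w_x²/(Σ(y−f0)²/4)`; orthogonality makes the three terms sum to 1
whenever the responses vary, which the suite asserts to 1e−9. A
first-order sum below `1 − tolerance` (default tolerance 0.05) flags a
higher-order interaction; zero-variance designs return an indeterminate
result rather than dividing by zero. Replicate folds are averaged **in log
space** before fitting — the expansion is linear in log responses, and
averaging raw folds would bias `f0` upward by Jensen's inequality. The
design is deliberately limited to two partners; the statistic's value here
is the pairwise-within-triplet decomposition, not a general ANOVA.

## Serial-transfer simulator

State is an M × S array of per-compartment copy numbers; compartment
volume is 1, so counts equal concentrations. One round applies:

1. **Replication.** Each compartment follows
   `dx_i/dt = x_i Σ_j k_ij x_j (1 − Σ_i x_i / C)` for reaction time T
   (default 1, with T absorbed into k = ln(fold)). Compartments are
   independent, so the whole batch is integrated jointly with adaptive
   RK45 (`scipy.integrate.solve_ivp`; defaults rtol 1e−6/atol 1e−8 for
   population runs, tightenable to oracle precision). Totals never exceed
   C beyond solver tolerance; a species whose accessible k entries are all
   zero (a parasite without its host) cannot grow.
2. **Stochastic rounding.** ODE output is continuous; counts are
   integerized by floor plus a Bernoulli draw on the fractional part —
   unbiased, and exact on integers — so the discrete steps act on whole
   molecules.
3. **Dilution.** Each compartment independently survives with probability
   1/D and is emptied otherwise (M fixed). This reading of "diluted D-fold
   with vacant compartments" preserves the compartment count and the
   expected D-fold drop; redistributing into D·M compartments would be an
   alternative reading with different bookkeeping but the same expected
   decay.
4. **Fusion–division.** `round(M·F)` events; each pools two distinct
   uniformly chosen compartments and splits every molecule Binomial(n, ½).
   Per-species totals are conserved exactly. Partners are drawn without
   replacement within an event, with replacement across events.

Defaults are the study conditions: C = 300, D = 5, F = 1.3, Poisson
seeding with mean 10 copies per species per compartment. The compartment
count defaults to M = 10,000 — a desk-scale choice; the experimental value
300,000 is reachable via config, and summary statistics agree across M up
to Monte-Carlo error. A species is flagged extinct when its population
total falls below the extinction threshold (default: fewer than 1
molecule, i.e. zero copies). The full trajectory is a pure function of
(config, seed); knockout experiments zero one species' initial counts
while keeping its rate-matrix rows and columns in place, and consume the
RNG stream identically to the baseline run, so removing an absent species
reproduces the baseline exactly.

One stochastic subtlety: the deterministic-decay bound
⌈log_D(initial/threshold)⌉ bounds the round at which the *expected* total
of a non-replicating species crosses the threshold. Actual extinction —
losing the last few molecules — is a tail event that exceeds that bound in
a substantial minority of runs (measured ~25% at M = 10,000); analyses
that need a hard deadline should either add a round of slack or use a
higher extinction threshold, where the bound is sharp.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the analysis pipeline
consumes: a random (GC 0.5) host reference with a parasite derived by one
internal deletion that preserves both termini; nested lineages
(sublineages inherit ancestral mutations) with per-round frequency
trajectories that drift and then stabilize; i.i.d. per-base substitution
errors (default 1e−3); and fold tables as `exp(k)` under multiplicative
log-normal noise. Defaults: 1,000 reads per round (real per-round depths
vary roughly 10²–10⁴; depth is configurable) over 5 rounds, five lineages
(three host — one a sublineage, two parasite — one a sublineage), each
with 4–6 private substitutions placed away from the deletion boundaries.

It deliberately does **not** model: indel sequencing errors or quality
scores (substitution-only errors keep alignment-based calling unambiguous
at desk scale, and the 10% dominance threshold makes rare error calls
irrelevant), chimeric reads, recombination as a process (the parasite
deletion is given, not evolved), or real secondary-structure-driven
replication biases. Consequently, green tests on synthetic data certify
the *pipeline machinery* — exact panel recovery, frequency estimation
within binomial error, partition and phylogeny reconstruction — not
robustness to the full error structure of real long-read data.

The bundled five-species rate matrix mirrors the structure of the evolved
replicator network: HL2's replicase is a generalist replicating all five
members; HL1 replicates itself and accepts help from HL2; HL3 depends
mostly on HL2; PL2 is an HL2-specific parasite (its only nonzero entry)
that out-replicates its host within shared compartments; PL3 is a general
parasite that hits HL1 hardest. Values (template × source, hosts only;
parasite columns zero):

|     | HL1 | HL2 | HL3 |
|-----|-----|-----|-----|
| HL1 | 2.0 | 0.7 | 0   |
| HL2 | 0   | 2.0 | 0   |
| HL3 | 0.2 | 0.8 | 0.3 |
| PL2 | 0   | 2.4 | 0   |
| PL3 | 2.2 | 1.0 | 1.5 |

The published rate constants derive from assay figures that are not
machine-readable, so these values are the package's own: they were chosen
once so that the network's qualitative behavior matches the reported
endpoint — HL3 is diluted out early while the other four members sustain
co-replication for at least 22 rounds at desk scale, and knocking out HL2
forces PL2 extinct. Oscillation troughs at small M can extinguish members
that would persist at the experimental M; that is a property of
demographic noise, not of the network.

## Numerical choices and degenerate inputs

* Alignment tie-breaks: the engine's first optimal alignment (stable) plus
  deletion left-normalization; panel order is (position, kind, alt,
  length); genotype rank ties break toward the earlier panel mutation.
* Zero-variance Bahadur designs: flagged, never an exception; interaction
  verdict indeterminate (`None`).
* All-zero distance matrices embed at the origin; PCoA axes with
  non-positive eigenvalues contribute zero coordinates.
* NJ requires ≥ 3 taxa; the 3-taxon case uses the closed-form star
  branch lengths.
* Fold tables must be positive to infer rates; folds ≤ 1 give k = 0 with
  a warning; a zero control fold is an error, not a silent NaN.
* ODE failure raises with the offending compartment state; it does not
  silently continue.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the pipeline splits one master seed into
  per-stage seeds via `SeedSequence`.

## Known limitations

* The aligner is global: partial or chimeric reads would accumulate
  spurious terminal deletions rather than being rejected.
* Single-linkage clustering chains through intermediate genotypes; with
  dense low-frequency strays the planted partition is only recovered when
  clustering the dominant genotypes (as the source experiments did with
  their top-100 sets), not every singleton.
* The simulator has no mutation or recombination: the species set is
  fixed, so it models ecology of an existing network, not its evolution.
* The replicase is implicit in k_ij; an explicit-replicase extension is
  out of scope.
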