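# Methods

## Problem

Group studies of structural brain connectivity need a single
group-representative network, but every thresholding recipe for building
one trades off false-positive against false-negative connections and
changes the network's topology — and therefore the dynamics any model
run on it will produce.  This package selects the group network by its
*dynamics*: among a ladder of uniform consensus-thresholded candidates,
it keeps the one whose simulated synchronisation behaviour is closest to
that of the individual subjects.  We call that network the
dynamics-based consensus (DBC).

## Model

Each of the N parcellation regions is a Kuramoto phase oscillator on the
binary adjacency A:

    dθ_i/dt = ω_i + λ Σ_j A_ij sin(θ_j − θ_i),         λ = K / (N d)

with no noise and no conduction delays.  `d = Σ_ij A_ij / N²` is the
density of the adjacency matrix, so λ = K / ⟨degree⟩ up to the N/(N−1)
diagonal correction: the summed coupling a typical node receives is ~K
regardless of network density, which makes networks of different density
comparable under one coupling constant and puts the entire
incoherence-to-synchrony transition inside the default sweep K ∈ [0, 3]
for frequency spreads of order 1 rad/s.  (A normalisation by the edge
*count* instead of the mean degree would scale the transition with N and
push it far outside that range — we verified on an 82-node,
density-0.59 network that the chosen normalisation drives mean coherence
from ≈0.14 at K = 0 to ≈0.92 at K = 3.)

Instantaneous coherence is the Kuramoto order parameter
`r e^{iΨ} = (1/N) Σ_j e^{iθ_j}`, r ∈ [0, 1].  **Metastability** is the
standard deviation of r over the post-transient window; the
**metastability profile** is metastability as a function of K over the
sweep.  The profile is the dynamical signature: it captures how network
structure shapes the whole pathway to synchronisation rather than a
single operating point.

For candidate group network G_T at consensus threshold T, the deviation
from the n subjects is

    MSE_T = (1/n) Σ_i mean_K ( MP_{G_T}(K) − MP_{s_i}(K) )²

and the DBC is the argmin over T.  The reduction over grid points is a
mean so MSE values are comparable across grids of different length
(`grid_reduction="sum"` preserves the additive convention).  Exact MSE
ties break toward the threshold nearest 50% consensus, then lower —
mid-range thresholds are least likely to distort density.

## Simulation protocol

| parameter | default | notes |
|---|---|---|
| total time | 100 s | long enough for r to reach a statistical steady state |
| transient discarded | 50 s | removes initial-condition dependence |
| integration | explicit Euler, dt = 1 ms | fixed points of the locked dynamics are preserved exactly by the Euler map; halving dt changes profile values by < 2% |
| natural frequencies | Normal(2π·40 rad/s, 1 rad/s) | mean sets only the rotating frame and does not affect the profile; small spread keeps the transition structure-driven (zero spread would abolish it) |
| initial phases | uniform in (−π, π) | |
| coupling grid | K = 0 … 3, step 0.125 (25 values) | spans incoherence to near-full synchrony |
| realisations | 1 | configurable; profiles report the across-realisation SD |

Implementation notes: the integrator advances all K values of the sweep
simultaneously (one batched phase state per coupling), which is what
makes cohort-scale profile computation cheap; phases are integrated
unwrapped (sin of differences is wrap-invariant) and wrapped only for
reporting; r is recorded at every Euler step of the retained window
(50 000 samples at defaults); metastability uses the population SD —
with that many samples the sample/population distinction is negligible.
Initial phases and frequencies are drawn from a stream keyed by
`(rng_seed, realisation)` only, never by the network, so candidate
networks compared under one config share identical draws (common random
numbers, reducing between-network variance in profile comparisons).
A reduced preset (`SimulationConfig.smoke`: 10 s, 5 s transient,
dt = 5 ms) exists for fast experimentation; the validation suite uses it
for whole-cohort replicate runs.

## Group-network builders

**Uniform consensus ladder.** An edge survives threshold T iff present
in ≥ ⌈T·n/100⌉ subjects; thresholds are the multiples of 100/n, so an
n-subject cohort yields exactly n nested candidates from the union
(T = 100/n) down to the intersection (T = 100).  Thresholds are treated
as quoted to one decimal place so that displayed rungs (66.7% for 2/3)
map back to their exact counts.

**Distance-dependent consensus.** Node pairs are split into intra- and
inter-hemispheric classes; each class's pairs are binned into 41
linearly spaced Euclidean-distance bins spanning the class's observed
range (last bin right-closed).  Per bin, m = the rounded (half away from
zero) mean number of that-class edges per subject, and the m most
prevalent pairs are kept — ties broken by shorter distance, then
lexicographic (i, j).  The class split keeps long inter-hemispheric
connections from being crowded out; the output density tracks the mean
subject density to within binning/rounding slack (≤ 0.5 edge per class
× bin).

**Consistency thresholding.** Pairs with nonzero mean weight are ranked
by ascending coefficient of variation of the weight across subjects
(sample SD / mean; absences count as weight 0 by default —
`cv_include_zeros=False` restricts to subjects possessing the edge) and
the top ⌊target_density · N(N−1)/2⌋ pairs are kept, ties broken by
higher mean weight then lexicographic.  The pipeline sets the target
density to the DBC's density so the two are comparable.  When the cohort
has no streamline weights (purely binary input), the binary adjacencies
serve as weights, under which CV ranking reduces to prevalence ranking.

All tie-breaks are deterministic, so a cohort maps to bit-identical
group networks on every run.

## Synthetic cohort generator

The generator provides ground truth that real cohorts cannot: a seed
binary network (by default Erdős–Rényi with an exact edge count at
density 0.59, typical of an 82-node binary tractography cohort), from
which each subject is derived by toggling k distinct upper-triangle
entries (additions and deletions), k ~ round(Normal(80, 10)) clipped to
the feasible range.  A fixed 30% of the seed's *edges* is exempt from
toggling (the immutable core), so every subject retains a conserved
backbone and the 100% consensus network stays non-trivial.  Toggling
without replacement makes a subject's Manhattan distance to the seed
equal its draw exactly, so the noise level is directly interpretable.

The toggle mean/SD would, for an empirical cohort, be estimated from the
pairwise Manhattan-distance statistics (`pairwise_flip_statistics`).
For the shipped defaults we chose 80 ± 10 so that roughly 40–45% of node
pairs are identical across all 40 members — the conserved-topology
fraction typical of binary connectome cohorts at this resolution — while
per-subject perturbations stay large enough (≈2.4% of pairs) that
recovery is a non-trivial test.

What the generator does **not** model: real between-subject variability
is not independent random edge flips around a blueprint — it is spatially
structured, distance- and degree-dependent, and partly systematic.
Passing the recovery experiment therefore shows that the selection
machinery finds a known planted consensus under unstructured noise; it
does not certify behaviour under anatomically structured variability.

## Validation experiments (what the suite computes)

* **Two-oscillator oracle**: for a connected pair the phase difference
  obeys dΔθ/dt = Δω − c·sinΔθ with c = 2λ = 2K; locking iff |Δω| ≤ c
  with locked r = cos(arcsin(Δω/c)/2).  Simulated locked r matches the
  closed form to < 1e-3 at dt = 1e-4 across 20 (Δω, K) pairs.
* **Metastability oracle**: the SD of a sinusoidal r series over whole
  periods is amplitude/√2; constant series give 0.
* **Ground-truth recovery**: on 10 replicate default cohorts (N = 82,
  n = 40, smoke preset), the selected DBC must be strictly nearer (in
  upper-triangle Manhattan distance) to the seed than to any member in
  ≥ 9/10 replicates; the MSE curve must exceed its minimum at both the
  lowest and highest threshold (U-shape) in each.  The smoke preset and
  replicate count are the package's validation problem size; full
  protocol settings scale the same code by a constant factor.
* **Statistics oracles**: KS, Welch t (with Satterthwaite df), ANOVA F
  and η² agree with direct ECDF/sum-of-squares formula implementations
  to 1e-10 on randomised datasets; canonical graphs (K₄, C₅, two
  disjoint K₃) match hand-derived metric values.

## Statistical comparison conventions

Nodal metrics (degree, clustering, betweenness, eigenvector centrality)
are compared per group network by the mean over subjects of the
two-sample KS statistic; lower = closer.  Betweenness is unnormalised
(raw shortest-path counts, endpoints excluded) and eigenvector
centrality is the principal eigenvector of A (largest component,
non-negative, unit Euclidean norm) — KS comparisons only need the
convention to be identical on both sides.  Global metrics (density,
Louvain modularity as best-of-100 seeded repeats at resolution 1, mean
nodal clustering, characteristic path length over connected pairs) are
compared by z-score against the subject distribution (sample SD).
Families of per-subject squared profile distances are tested by one-way
ANOVA with η² = SS_between/SS_total and pairwise Welch post-hocs,
Bonferroni-corrected over the contrasts actually tested (m = C(g, 2) for
g group networks), at α = 0.01.

## Degenerate inputs and edge cases

Edgeless networks get λ = 0 (free rotation) with a warning; empty
post-transient series are rejected.  Disconnected graphs: betweenness is
per-component, eigenvector centrality is computed on the largest
component with zeros elsewhere, path length excludes disconnected pairs
— each with a warning.  A two-member cohort's pairwise-distance SD is
reported as 0 with a warning.  A consistency target density requesting
more pairs than have nonzero mean weight keeps all such pairs and warns.
Zero subject SD makes a z-score signed infinity (flagged).  Matrix reads
symmetrise asymmetries within an absolute tolerance (default 1e-8) and
reject larger ones with the offending indices.

## Reproducibility

Every stochastic stage takes an explicit seed.  The pipeline derives
per-stage seeds from one master seed via `numpy.random.SeedSequence` and
records them, along with every parameter, in the run manifest;
re-running a config reproduces all numeric outputs bit-identically.

## Known limitations

* Binary networks only; weighted coupling is out of scope.
* No noise or delay terms in the oscillator model; metastability here is
  deterministic-model variability, not an empirical BOLD statistic.
* The profile is insensitive to some structural differences (the flat
  bottom of the MSE curve is wide), so the selected threshold can wander
  within the flat region between runs at reduced simulation settings;
  the selected *network* stays close to the planted consensus regardless.
* Euclidean centroid distances understate true fibre lengths; they are
  used for consistency with the distance-dependent builder's definition.
* The node tables shipped by the synthetic module carry synthetic
  placeholder coordinates, not real atlas centroids.
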