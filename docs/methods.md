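# Methods

## Model and assumptions

A cryo-EM helical dataset is reduced to a particle table: one row per
extracted filament segment, carrying a micrograph identifier, a helical
tube ID within the micrograph, and a 1-based 2D class assignment. The pair
(micrograph, tube) identifies a filament; tube IDs are never assumed unique
across micrographs. The method's single statistical assumption is that
filaments of the same polymorph distribute their particles similarly over
2D classes, while different polymorphs use (largely) different classes. No
image content is modelled anywhere in the package.

Each filament becomes one observation: its normalised class-assignment
distribution (a probability vector over the K classes of the current
classification round). Filaments are *not* weighted by length at the
clustering stage; particle counts enter only in small-cluster merging and
in abundances. Particles whose class assignment is marked unusable
(non-positive class ID — e.g. picking false positives removed by an initial
classification) are excluded from profiles but retained in picked-particle
totals.

## Clustering procedure

1. **Distance.** Cosine distance `1 − u·v/(‖u‖‖v‖)` between profiles. It is
   invariant to positive rescaling, so raw count vectors and normalised
   distributions cluster identically; values are clipped into [0, 1] to
   absorb roundoff on parallel vectors.
2. **Linkage.** UPGMA: the inter-cluster distance is the arithmetic mean of
   distances over all leaf pairs, maintained via the size-weighted update
   `d(A∪B, C) = (|A|·d(A,C) + |B|·d(B,C)) / (|A|+|B|)`. Merge heights are
   therefore non-decreasing. Ties break on the lowest index pair, making
   the dendrogram deterministic. The implementation is O(n²) per merge with
   vectorised row updates; tests verify exact (1e−12) agreement with an
   independent O(n³) brute-force oracle and with standard average-linkage
   library output.
3. **Flattening.** Flat clusters are the connected components induced by
   all merges at height ≤ the threshold (default 0.3 cosine distance).
   Labels are numbered by each cluster's smallest leaf index. Partitions at
   higher thresholds are coarsenings of those at lower thresholds.
4. **Small-cluster merging.** Clusters below `min_particles` (default
   1,000 — the conventional floor for a usable helical reconstruction) are
   absorbed by the surviving large cluster whose particle-weighted centroid
   profile is nearest by cosine distance; ties go to the lowest cluster id.
   If no cluster reaches the floor, everything pools into one remainder
   cluster, flagged by `remainder_id`. Total particle counts are conserved.
5. **Iteration.** Homogeneity of a cluster is its mean pairwise cosine
   distance (0 for singletons). Clusters above `homogeneity_epsilon`
   (default 0.1) have their particles re-classified through a pluggable
   callback — in real use an external 2D classification of just that
   cluster's particles — and are re-clustered on the new profiles. Because
   re-classification changes the class inventory, each such cluster is
   re-clustered in its own class space; profiles from different rounds are
   never mixed in one distance matrix. The loop stops when every cluster
   passes or after `max_iterations` rounds (default 5). With
   `max_iterations = 0` the base cluster→flatten→merge pass still runs and
   the audit log is empty. "Interactive" cluster curation is deliberately
   not implemented; determinism and an explicit audit log (cluster count,
   sizes, particle totals, homogeneities, re-classified ids per round) take
   its place.

## Abundances

For one dataset (condition × replicate × time point), a cluster's abundance
is `100 × particle_count / total_picked`, where the denominator counts
*every* picked particle — including unusable particles and filaments in no
cluster. The shortfall appears as an explicit `unassigned` row, so each
per-dataset table sums to 100% within 1e−6. Percentages are stored at full
precision; rounding (1 decimal) is presentation-only. These are
particle-count abundances on micrographs; they need not equal the
solution-state amounts of each filament type.

## Helical geometry

Twist (degrees per β-rung; negative = left-handed) and rise (Å per β-rung)
convert to crossover distance as `c = 180 · rise / |twist|`, exactly
invertible given the handedness. The rise used in worked examples is the
4.7 Å cross-β rung spacing; every routine takes rise explicitly. Converting
a −6.3°/rung twist at 4.7 Å gives 134.3 Å; at the 0.5-nm rounding used for
reported crossover distances this is 13.5 nm, and the residual <1%
discrepancy is absorbed by that rounding. For pseudo-2₁ filaments (two
alternating subunits per rung pair), the subunit operator is
`(twist/2 + 180°` wrapped into (−180°, 180°], `rise/2)`; applying it twice
reproduces the rung operator.

## Ordered-core arithmetic

The tau(297–391) construct sequence (95 residues, numbered per the
441-residue 2N4R isoform) is embedded as package data and validated at
import against two independently printed subsequences — 302–316
`GGGSVQIVYKPVDLS` and the PHF6 motif 306–311 `VQIVYK` — so a transcription
error cannot silently become ground truth. `core_stats` reports
(ordered, disordered, % disordered rounded to integer) for a core span
inside a construct span; all spans are 1-based inclusive and no 0-based
span crosses a module boundary.

## Synthetic data generator

The generator emulates exactly the structure the clustering assumes, and
nothing else:

* **True profiles.** Each polymorph's class-usage profile is a symmetric
  Dirichlet draw (α = 0.2 over K = 24 classes by default; small α gives the
  sparse, peaked usage a polymorph shows over a handful of characteristic
  class averages). Profile sets are redrawn until all pairwise cosine
  distances reach `min_profile_separation` (default 0.5), making "well
  separated" an explicit, testable property instead of a lucky draw.
* **Filaments.** Default 60 per polymorph, each contributing a
  uniform-random 30–120 segments (overlapping extraction along a tube),
  laid out 5 tubes per synthetic micrograph so grouping is exercised.
* **Noise.** With probability `assignment_noise` (default 0.1) a particle's
  class is drawn uniformly over all K classes instead of from its
  polymorph's profile — a crude but serviceable model of classifier
  misassignment.
* **Unassignable particles.** An optional fraction of picked particles
  carries class ID −1 on its own filaments, standing in for picking false
  positives and unsolved filament types (the grey abundance segments).
* **Re-classifier.** `simulated_reclassify` redraws a cluster's particle
  classes from the true profiles with noise scaled by
  `noise_reduction^round` (default 0.5/round): a model of the *effect* of
  re-classifying a more homogeneous subset, not of 2D classification
  itself, which the package intentionally does not implement.
* **Time courses.** A schedule maps (condition, replicate, time_min) to
  polymorph mixture weights (optionally plus an unassignable fraction);
  filament counts are multinomial in the weights. Every dataset derives its
  seed from the config seed via `SeedSequence`, so tables are distinct but
  byte-reproducible.

What passing tests show — and what they do not: recovery at ARI ≥ 0.95
across seeds demonstrates the pipeline separates polymorphs whose class
usage differs at cosine distance ≥ 0.5 under 10% uniform noise, at desk
scale (2–6 polymorphs, 50–60 filaments each, tens of particles per
filament). Real datasets have orders of magnitude more particles, class
inventories of 150+ classes, correlated (not uniform) misassignment, and
filament-length biases; none of these are emulated, so test results bound
the algorithmic behaviour, not real-data performance.

## Numerical choices and degenerate inputs

* Cosine similarities are clipped into [−1, 1] territory by clipping the
  distance into [0, 1]; zero vectors are a domain error, never a NaN.
* All tie-breaks (merge pair, absorbing cluster, label order) are by lowest
  index; all randomness flows through explicit seeds, and per-dataset /
  per-round seeds derive from `numpy.random.SeedSequence` spawn keys.
* Single-profile inputs skip the distance matrix (trivial single cluster);
  empty inputs return empty assignments; empty STAR tables are written as
  header-only loops (only on request) and read back as empty collections.
* Class IDs are 1-based at every public boundary and converted to 0-based
  indices at exactly one point (profile construction), preventing
  off-by-one drift.

## Problem sizes

Default test and acceptance runs use 2–6 polymorphs × 50–60 filaments ×
30–120 particles (≈10⁴–10⁵ particles per dataset), 30-dataset time courses
at reduced filament counts, and 100 random matrices of n ≤ 12 for the
linkage oracle — sizes chosen so the whole suite runs in seconds on one
CPU while still exercising every code path at realistic shape.

## Known limitations

* 2D classification is out of scope by design; the iterate step needs a
  user-supplied re-classification callback for real data.
* UPGMA is quadratic in memory over filaments (the distance matrix);
  datasets beyond ~10⁵ filaments would need a chunked or approximate
  linkage, which is not provided.
* The uniform-contamination noise model understates the structured
  confusion between visually similar polymorphs; the homogeneity threshold
  (0.1) was chosen for sparse Dirichlet-like profiles and may need
  retuning for flat class usage.
* Abundance percentages inherit every bias of picking and extraction; the
  package reports them as particle-count shares only.
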