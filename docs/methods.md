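# Methods

## The problem

Two institutions hold tabular clinical records over overlapping feature
sets. One holds a small but *complete* table (the **reference**, `D_r`); the
other a larger table with a whole attribute column — and possibly the class
label — absent (the **incomplete** table, `D_i`). The goal is to produce,
for every incomplete record, plausible values of the missing feature `x`
(and, when needed, the label `y`) without ever moving row-level data between
the institutions. The output is *partially synthetic*: real known features
combined with generated values, `D_g = (X^K, X̂^U, Y)`.

## The procedure

1. **Alignment and setup.** The incomplete table's known features must match
   the reference by name, kind and unit (declared unit equivalences such as
   cc ≡ mL are accepted). Features are reordered known-first. The finite
   candidate set for `x` is derived from the reference: discrete kinds are
   enumerated (integers over the closed observed range — ages observed from
   35 to 92 give M = 58 candidates regardless of interior gaps), continuous
   kinds are quantized into `M` uniform bins whose midpoints form the grid.
2. **Candidate expansion.** Every incomplete row is replicated once per
   candidate value: `|D_g| = N_i · M`, ordered row-major then by ascending
   value so downstream outputs are byte-reproducible.
3. **Embedding.** The reference features (standardized; label excluded) are
   embedded into a 2D Euclidean plane with UMAP under a mandatory fixed
   seed. The fitted model projects candidate rows out-of-sample into the
   same plane.
4. **Reliability scoring.** For each projected candidate, the mean of `x`
   over its `k` nearest reference points (Euclidean distance in the plane,
   ties broken by ascending reference id) gives the neighborhood mean `x̄`.
   The disparity `f = |x̂ − x̄|`, measured on the original feature scale, is
   banded in multiples of a width `ε` into a score
   `r_c ∈ {1, 0.9, 0.8, 0.7, 0.6, 0.5, 0}`; each band is closed on the
   right (`f = 2ε` scores 0.9) and anything beyond `6ε` scores 0 and can
   never validate. Candidates with `r_c ≥ r_min` form the validated set
   `D_v`. Several candidates of one source row may validate simultaneously;
   that multiplicity is the data-augmentation half of the method and is
   deliberately kept.
5. **Cluster validation** (when `y` is missing). Reference points of each
   class define a centroid (coordinate mean) and a radius: the largest
   radius on an explicit grid at which the same-class point density
   `count/(πr²)` still meets a threshold. Projected candidates inside an
   area take its label; inside several, the nearest centroid wins (ties to
   the lexicographically smallest label); outside all, the candidate is
   dropped.

Two derived modes reuse the same machinery. **Full synthesis** applies the
pipeline iteratively, one missing feature per round (by default in order of
descending |correlation with the label|); each round's validated rows become
the next round's incomplete input and the newly generated attribute joins
the reference feature set, so the embedding is refit every round.
**Imputation** partitions a mixed-missingness table by missing pattern, runs
the pipeline per single-feature pattern, and keeps exactly one value per
cell: the highest-scoring validated candidate (ties to the smallest
disparity, then the smallest value). Returning the top-n candidates per cell
instead is supported for multiple-imputation style workflows; Rubin-style
combination rules are out of scope.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_neighbors`, `min_dist` | 15, 0.1 | UMAP locality/packing (backend defaults; the method prescribes none) |
| `seed` | required | fixes the embedding; there is no unseeded mode |
| `k` | 10 | neighborhood size for the reliability mean; also the k-NN baseline's k, keeping the comparison symmetric |
| `ε` | grid default | band width on the original feature scale: 1 for integer/ordinal kinds, the bin width for quantized continuous kinds, half the minimum level gap for categorical/binary |
| `r_min` | 1.0 | minimum score to validate; validated sets are nested as it decreases |
| `density_threshold` | 1.0 | points per unit area required inside a cluster radius; larger ⇒ smaller areas |
| radius grid | start 0.05, step 0.05, max = farthest member + step | makes the "largest radius still meeting the threshold" rule deterministic |

On `ε` for binary/categorical features: a band width of 1 on a 0/1 encoding
would validate every candidate, so the grid default is half the minimum
level gap (0.5 for 0/1), and disparity is always computed on the original
encoded scale rather than the standardized one. Callers can force any `ε`
explicitly when reproducing a protocol that used 1 throughout.

On *density*: the threshold is interpreted per unit area, not as a raw
count, because only the per-area reading makes larger thresholds shrink the
validated area (the behavior the method's threshold sweeps display). The raw
count reading is available behind `density_mode="count"` for comparison.

## Numerical and design choices

- Standardization uses the population (divide-by-N) standard deviation;
  constant columns are an error at fit time.
- The label column never enters the embedding: generated rows in the
  label-missing cases must pass through the same projection, so class
  structure has to emerge from features alone. On the built-in fixtures the
  class centroids separate label-free (tested).
- Neighbor ties are broken by ascending reference id, and distances are
  compared exactly as stored floats, so scoring is fully deterministic.
- The missing marker is NaN in memory and the empty string in CSV; a feature
  missing in only *some* rows is rejected by the core data model (strict
  mode) and handled only by the imputation pipeline's pattern partitioning.
- Candidate expansion may be consumed in chunks; results are independent of
  the chunking, which keeps million-row expansions memory-safe.
- Cluster validation runs *after* reliability filtering when both apply.
- Two-party exchanges are pure file-based operations: either side can score
  (the reference holder from received candidate values — option 1 — or the
  counterpart from released neighborhood means — option 2); both produce
  identical scores, and the model file carries a plain-text header
  (hyperparameters, seed, feature order, normalizer stats) for audit.

## What the synthetic fixtures emulate — and what they don't

`FixtureSpec` generates a registry-like table: a Gaussian mixture over 2–5
visible features whose classes sit `class_separation` within-class standard
deviations apart (default 4, comfortably separable), plus a hidden feature
that is affine in the latent position with additive noise, clipped and
rounded to a declared range (default: an integer age-like feature on
35–92). Because the hidden value is tied to the latent position it varies
smoothly across the fitted embedding — exactly the regularity the
neighborhood-mean validation exploits, and the reason parameter recovery is
possible at all.

Real registries are not Gaussian mixtures: they carry skewed marginals,
heteroscedastic noise, missingness that correlates with outcomes, and
hidden features only weakly tied to the observed ones. Passing tests on
these fixtures therefore demonstrate that the machinery is correct and that
the method's qualitative behaviors (nesting in `r_min`, shrinkage in the
density threshold, dominance over mean/k-NN imputation when the smoothness
assumption holds) emerge as designed — not that comparable accuracy would be
obtained on any particular real dataset.

## Evaluation harness

The rotation harness splits a complete table into `n` equal groups (seeded
shuffle; remainder rows dropped with a warning), holds each group out in
turn as the reference, blanks the evaluation feature in the rest, and runs
the pipeline down the `r_min` ladder {0.5, …, 1.0}. A validated candidate is
*correctly imputed* iff its value equals the held-out truth after grid
mapping (bin midpoint for quantized features); every other validated
candidate is synthetic. Counts are averaged across rotations; mean and k-NN
baselines (the latter measured in the standardized known-feature space) run
per rotation with the same correctness rule. Range tables report per-bin
percentages with empty bins left blank, not zero.

Problem sizes used by the test suite and the acceptance script — chosen to
exercise every protocol shape at desk scale — are: 1,500-row fixtures for
the 5×300 rotation shape and the monotonicity sweeps (3 seeds), 500-row
fixtures for the baseline-dominance comparison (3 seeds), 240–300-row
fixtures for unit and determinism checks, and the full 24,728×58 and
1,058×3 expansions for the counting identities.

## Known limitations

- UMAP's out-of-sample transform is deterministic but not continuous at
  fine scales: input nudges around 1e-6 can flip neighbor-graph entries and
  move a projected point a few tenths of an embedding unit. Projection
  continuity holds below that granularity.
- Only one feature is expanded per round; joint expansion of two
  simultaneously missing features is unsupported (rows with multi-feature
  missing patterns are reported, not imputed).
- Cluster areas are circles; elongated or non-convex class regions will
  validate conservatively.
- The method presumes the hidden feature varies smoothly over the embedding
  of the remaining features; where it does not, validated candidates
  concentrate near the reference mean of `x` and the method degrades toward
  mean imputation.
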