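# Methods notes

This note records the models, defaults and design decisions behind
`msnpipe`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
establish.

## Similarity estimation

Per region, vertex-wise cortical thickness is summarised as a discrete
probability distribution on a fixed shared grid, and region pairs are
compared with the Jensen–Shannon similarity estimate JSSE = 1 − JS.

* **Grid.**  All PDFs share one grid, 0–6 mm × 256 points.  A shared
  support is required for the divergence sums to be well defined; 6 mm
  exceeds physiological cortical thickness, so no mass is clipped.
  256 points keeps the discretisation error of the KDE far below
  sampling noise while keeping the 68×68×256 pairwise broadcast cheap.
* **KDE.**  Gaussian kernel with Silverman's rule-of-thumb bandwidth
  (`scipy.stats.gaussian_kde`), configurable per transformer.  The
  density is evaluated at the grid points and renormalised to unit
  mass; because cell widths are uniform, this equals the cell-integral
  approximation up to the common factor.
* **Log base.**  Base-2 logarithms, so JS ∈ [0, 1] and JSSE lands in
  [0, 1] without rescaling.  Identical PDFs give exactly 1; PDFs with
  disjoint support give exactly 0 (the two bounds are analytically
  forced and asserted in the acceptance suite).
* **Degenerate samples.**  A region whose vertices are all identical
  has no finite bandwidth; the estimator falls back to a single-bin
  spike at the nearest grid point and warns.  A pair of such spikes at
  different bins correctly scores JSSE = 0.
* **Diagonal.**  Self-similarity is fixed to 1 and never enters
  thresholding.

## Graph features

* **Thresholding.**  At sparsity level s the `k = round(s·n(n−1)/2)`
  highest-similarity edges are kept (round half to even).  Ties at the
  cutoff are broken by ascending (i, j) node-index order — an arbitrary
  but deterministic rule, so reruns and tied matrices are reproducible.
* **Measures.**  CC, DC, BC, LE per node; SW, GE, AST, CPL per graph.
  BC is left unnormalised: any affine normalisation cancels in
  group-difference regressions.  Nodal measures are not normalised
  against null networks (only the global measures are).
* **Disconnected graphs.**  At low sparsity the thresholded graph may
  fragment.  CPL is averaged over connected pairs only and the subject
  is flagged in a QC log rather than dropped; GE uses 1/∞ = 0 for
  disconnected pairs.  AST is undefined (NaN, with a warning) for
  graphs with zero endpoint-degree variance, e.g. regular graphs.
* **Null model.**  Degree-preserving Maslov–Sneppen rewiring with 10·E
  attempted double-edge swaps per network, 100 networks per sparsity
  level by default.  Each global measure is divided by its
  null-ensemble mean; SW = (C/⟨C_rand⟩)/(L/⟨L_rand⟩).  A zero or
  undefined null mean propagates as a flagged missing value.  The AST
  ratio can be numerically large when the null mean is near zero; it is
  reported as defined rather than clipped.
* **Normalise-then-integrate.**  Global measures are normalised per
  sparsity level and then integrated across levels (trapezoid rule over
  the level axis).  Integrating first and normalising the AUCs is a
  defensible alternative; per-level normalisation was chosen because
  the null ensembles are level-specific.  The AUC of a constant curve
  over the default sweep equals 0.45 × the constant.
* **Implementation.**  Distance-based quantities run on adjacency
  matrices via `scipy.sparse.csgraph` (BFS all-pairs shortest paths),
  which gives explicit control over disconnected pairs and the
  throughput needed for 100 nulls × 10 levels per subject; BC uses
  networkx's Brandes algorithm; the swap loop is numba-compiled.  All
  measures are verified exhaustively against an independent brute-force
  oracle (Floyd–Warshall, explicit triangle counting, shortest-path
  enumeration) on every connected graph with ≤ 7 nodes, and
  cross-checked against networkx on random graphs.

## Association screens

Classical OLS with two-sided t tests; no robust or clustered standard
errors (the design is a single-visit cross-section).  The practice
covariate (count of prior test completions) enters only the cognitive
models; network-feature and thickness models adjust for age, sex and
education.  Significance thresholds are strict inequalities at
0.05 / 0.01 / 0.005; the 0.005 tier defines mediator candidates among
the 272 local tests.  Benjamini–Hochberg q-values are reported next to
the raw p-values for transparency, but candidate selection deliberately
uses uncorrected p-values, matching the screening character of the
analysis.  Rows with missing values are dropped listwise with a logged
count.

## Mediation

Single-mediator product-of-coefficients model.  Paths a (M ~ X + C) and
b, c′ (Y ~ X + M + C) are OLS estimates; the indirect effect is a·b and
c = c′ + a·b holds to machine precision whenever all models share one
covariate set (asserted at 1e-10).  Inference is by case resampling:
whole rows are redrawn with replacement, n_boot = 10,000 by default,
95% percentile CI; a bias-corrected variant is available
(`method="bias-corrected"`).  Replicates with singular designs are
redrawn with a capped retry count and tallied.  In the wired pipeline,
age, sex and education enter both sides of the model and practice
additionally enters the outcome-side models (mirroring its role in the
cognitive screens); with that asymmetric covariate set the c = c′ + a·b
identity is only approximate, which is the standard trade-off when the
outcome model has its own covariates.  The bootstrap is vectorised
(batched normal equations), which makes the 10,000-replicate default
interactive-speed at cohort sizes in the hundreds.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis
assumes, not any individual-level data:

* **Demographics.**  450 low-ADI / 74 high-ADI subjects; age
  62.96 ± 8.37 y shared across groups; education 16.63 ± 2.38 vs
  15.33 ± 2.45 y; female fraction 0.637 vs 0.757; practice counts
  geometric (p = 0.5) clipped to 0–7, giving the observed median of 0 —
  a uniform distribution over the configured range cannot produce that
  median, hence the skewed choice.
* **Cognitive scores.**  Linear in ADI, age, sex (male = 1), education
  and practice.  The default coefficients are the published association
  estimates, and each score's residual SD is back-derived from the
  published standard error of its ADI coefficient at the 450/74 split
  (SE ≈ σ√(1/450 + 1/74)), so simulated screens operate at realistic
  effect-to-noise ratios.  `CohortConfig.null_cognition()` zeroes the
  ADI effects for calibration studies.
* **Thickness.**  Per-region Gaussian vertex samples truncated at
  0.1 mm.  The Gaussian shape is a modelling choice (the empirical
  vertex distribution within a region is not documented); it is also
  the easiest shape for the KDE stage to recover, so end-to-end tests
  are conservative about pipeline noise rather than distributional
  mismatch.  Baseline means/SDs per region are a frozen deterministic
  table (means ≈ 2.1–3.1 mm, SDs ≈ 0.18–0.30 mm).  In the high-ADI
  group, designated regions (defaults: left lateral orbitofrontal,
  left fusiform — the regions the local screen is meant to flag)
  receive location and/or scale changes.
* **Two tiers.**  Thickness-level simulation feeds end-to-end tests;
  a separate feature-level generator (ADI, mediator, outcome,
  covariates with known a, b, c′) supports mediation-recovery tests,
  because a mediator that is itself a computed network feature would
  confound parameter-recovery checks.
* **Seeding.**  One root seed, spawned into named substreams per
  subject and stage (`numpy.random.SeedSequence`), so any subset of the
  simulation is bitwise reproducible and reruns of the pipeline are
  byte-identical.

What passing on synthetic data shows: the pipeline recovers effects it
is pointed at, is calibrated under the null, and is deterministic.
What it cannot show: robustness to real cortical geometry (spatially
correlated vertices, hemispheric asymmetry, scanner effects), to
non-Gaussian thickness distributions, or to covariate structures beyond
the linear model used for generation.

## Problem sizes in the validation suite

Simulation sizes were chosen to make the statistical checks sharp while
staying desk-scale: type-I calibration uses 1,000 null cohorts of
n = 524; mediation bias/decomposition uses 200 replications at
n = 5,000; bootstrap coverage uses 1,000 replications at n = 500 with
n_boot = 1,000; the determinism check runs a 20-subject cohort twice
with 15 nulls per level and 300 bootstrap iterations (determinism does
not depend on these sizes; the analysis defaults remain 100 and
10,000).

## Known limitations

* KDE bandwidth, grid and log base are unspecified in toolbox
  conventions and are exposed as parameters; results are stable to
  reasonable alternatives but no sensitivity sweep is automated.
* The AST null-normalisation is ill-conditioned when the null-mean
  assortativity is near zero; interpret the normalised AST with care.
* One practice column is shared across outcomes (per-test practice
  counts would need six columns).
* No FDR-corrected inference, multiple mediators, longitudinal
  structure, or weighted-graph measures.
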