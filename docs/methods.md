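# Methods

This note records the model behind `conemosaic`, the choices made where the
procedure admitted more than one reasonable reading, and what the synthetic
closed loop does and does not demonstrate.

## Coordinates and scaling

Cone selections live in continuous micrometer coordinates with the origin
at the ROI's top-left corner, x rightward, y downward — the raster
convention of AOSLO ROIs. Pixel-unit files are converted by multiplying by
the ROI's µm/px scale, with pixel centers at integer coordinates. The
lateral scale itself is modeled as proportional to ocular axial length
relative to a 24.0 mm reference eye (`scale = base · AL/AL_ref`); the
reference and base scale are parameters of `scale_factor`, never baked into
stored data. More elaborate retinal-magnification models (e.g. adjusted
Bennett schematic eyes) can be substituted by computing the scale outside
and writing it into the manifest. Bit-identical duplicate selections within
one annotator's file are collapsed (a double-click artifact) and counted;
rows outside the ROI rectangle are dropped with a logged count, with a
1 nm-scale tolerance at the border so edge-clipped clicks survive text
round-trips.

## Matching

The per-ROI threshold is the mean nearest-neighbor distance of the pooled
master list plus two standard deviations. Two conventions had to be fixed:

* **SD denominator** — sample SD (n−1), matching common statistical
  software defaults.
* **Neighbor pool** — the nearest neighbor excludes the point itself but
  includes same-annotator neighbors, since the master list pools all
  selections without distinction.

Matching accepts candidate pairs (distance ≤ t, inclusive, so coincident
points still match at t = 0) in a single global ascending-distance greedy
pass, skipping pairs whose endpoint is taken; exact ties break on (lower
ground-truth index, lower comparison index). The per-cone "closer of the
two" rule is ambiguous when one comparison cone is nearest to two
ground-truth cones; the global pass reduces to that rule in unambiguous
cases, is deterministic, and makes the true-positive count symmetric in
the two sets. On well-separated mosaics it attains the maximum-cardinality
matching of the threshold graph (checked against a Hopcroft–Karp oracle in
the tests; the greedy solution is always maximal by construction).

Multi-annotator clustering uses the same greedy pass over cross-annotator
pairs with a union-find merge that only joins clusters whose annotator
sets are disjoint — at most one selection per annotator per cluster, every
selection in exactly one cluster. With two annotators this provably
reproduces pairwise matching. The threshold is computed per ROI — per
comparison for pairwise analyses, across all annotators for clustering —
never pooled across ROIs. Note that pooling more annotators shrinks the
mean nearest-neighbor distance (several marks per cone), so clustered
k-annotator rates are systematically somewhat stricter than two-set
pairwise rates; the closed-loop recovery checks therefore use the pairwise
route, mirroring a two-grading repeatability comparison.

## Bound density

A cone is "bound" iff its Voronoi cell is closed and every vertex lies
inside or on the ROI rectangle (inclusive within 1e-9 µm, which keeps
lattice configurations exact). Cells are never clipped; a partially
outside cell is excluded entirely. Density is n_bound / Σ areas × 10⁶
(cones/mm²). Areas use the shoelace formula on the cell's angularly sorted
vertices (cells are convex). Fewer than 4 points or collinear input is a
degenerate-geometry error; a tessellation with no bound cell is a distinct
no-bound-cells error. Square and hexagonal lattices reproduce 1/s² and
2/(√3 s²) analytically, and random configurations agree with an
independent half-plane-intersection construction to 1e-6 µm² in the tests.

## Statistics

* **Bland–Altman**: differences are comparison − reference; Shapiro–Wilk
  on the raw differences at α = 0.05 (configurable) decides the automatic
  log₁₀ transform of both series; limits of agreement are bias ± 1.96 SD.
  Constant difference series (nothing to test) stay on the identity scale.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — the standard form when every target is rated by every rater;
  computed via `pingouin.intraclass_corr` with its F-based 95 % CI and
  cross-checked in the tests against the closed-form mean-squares
  expression (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) to 1e-9. Qualitative
  bands use Cicchetti's cut points 0.40/0.60/0.75.
* **Repeated-measures ANOVA**: within-subject one-way omnibus (pingouin),
  post hoc paired t-tests over all condition pairs, Bonferroni-adjusted
  with m = number of pairs actually tested. Zero-variance input is flagged
  degenerate and reported with p = 1 rather than NaN.
* **CoV**: sample SD over mean of one ROI's per-annotator densities.

## Synthetic data

The generator emulates the statistical structure of a multi-grader AOSLO
study of a degenerative cone mosaic; its defaults are the study
conditions, fixed once:

* 17 subjects, 5–16 ROIs each (~200 ROIs in total), square ROIs with
  sides ~N(70, 22) µm truncated at 25 µm, eccentricities uniform on
  135–2210 µm, axial lengths ~N(23.71, 0.98) mm.
* True mosaics: hexagonal lattice with spacing from a log-normal bound
  density (mean 30,600, SD 14,200 cones/mm² on the natural scale —
  log-normal for positivity and the right skew), positional jitter with
  SD = 0.12 × spacing, random lattice phase.
* Annotators: independent Bernoulli misses; Gaussian localization error;
  spurious marks as a Poisson count with mean `false/(1−false) × retained`
  so the expected spurious fraction equals the nominal false rate, placed
  uniformly outside a half-spacing exclusion zone around true cones (so a
  spurious mark is not trivially absorbed as a match). Defaults:
  (miss, false, jitter µm) = (0.06, 0.18, 1.0), (0.12, 0.16, 1.2),
  (0.12, 0.23, 1.5) for the three simulated graders.
* Eccentricity is carried as metadata only; density is not functionally
  tied to it (the emulated design reports a range, not a profile).

What the closed loop shows: the pipeline recovers the generating miss and
false rates (mean TPR ≈ 1 − miss, mean FPR ≈ false over ~200 ROIs) and
produces intergrader density ICCs in the excellent band under these noise
regimes. What it does not show: real gradings have spatially structured,
image-quality- and eccentricity-dependent errors, correlated across
graders, and systematic annotator biases in ambiguous regions — none of
which the independent-noise model emulates. Passing the closed loop
validates the bookkeeping and the statistics, not grader behavior.

## Problem sizes and numerics

The bundled analyses and acceptance checks use ~200-ROI studies with
70 µm-scale ROIs (~50–300 cones each), 500–1,000 random matching problems
for the identity and oracle checks, 100 random matrices for the ICC
cross-check and 10,000 paired values for Bland–Altman coverage — sizes at
which every Monte-Carlo estimate above is stable to well inside its
tolerance while the whole suite runs in seconds. All randomness flows from
explicit integer seeds (`numpy.random.default_rng`); spawned sub-seeds
stay below 2³¹. Degenerate inputs (coincident points, zero-variance
matrices, constant difference series) are defined behaviors, not errors,
wherever a sensible value exists, and named errors otherwise.

## Known limitations

* The axial-length scaling is a linear stand-in; studies with biometry
  should compute subject-specific scales externally.
* Whether cells exactly touching the ROI border count as bound is a
  convention (inclusive here); real-data densities can shift by a border
  cell or two under the exclusive reading.
* The greedy matcher can, in principle, fall short of the maximum-
  cardinality matching on pathologically dense configurations (observed
  rate 0 on well-separated mosaics in the oracle check).
* Figures are not generated; all outputs are delimited tables and JSON,
  which plot readily with any standard tooling.
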