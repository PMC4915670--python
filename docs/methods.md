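# Methods

## The comparison design

All statistics operate on a crossed repeated-measurement design: `S` species
× `P` sites (populations) × `N` individuals per population, every individual
measured by `M` measurers, `R` times each.  The canonical configuration is
S = P = M = R = 3, N = 30, giving 2430 records per method and, counting each
landmark or distance variable once per record, 26 730 measurements for the
11-landmark body method (GMB), 17 010 for the 7-landmark scale method (GMS)
and 38 880 for each of the 16-variable distance methods (TRU, TRU's caliper
analogue TRA).

Four method datasets are analysed with the same engine but different size
corrections: geometric methods carry 2-D landmark coordinates, distance
methods carry linear measurements plus standard length SL.

## Size removal

**Landmarks.**  Generalized Procrustes analysis: configurations are centred,
scaled to unit centroid size, and iteratively rotated to the consensus by
planar orthogonal least squares (closed-form rotation angle
θ = atan2(S₁₀ − S₀₁, S₀₀ + S₁₁) with S = Xᵀm; reflections are disallowed by
default because all specimens are digitized from the same side, and a silent
reflection would absorb digitization inversions).  Convergence is declared
when the consensus moves by less than 1e-8 (Frobenius), with a 100-iteration
budget; the objective Σᵢ‖Xᵢ − m‖² is non-increasing by construction.  After
convergence the consensus is put into a canonical orientation (major
principal axis along x, 180° ambiguity resolved by the first landmark's
sign), which makes the whole fit invariant to a common similarity transform
of the input.  Aligned shapes are orthogonally projected onto the tangent
plane at the consensus so subsequent statistics are linear.  Centroid size
is computed on the raw coordinates; shape is then regressed coordinate-wise
on log CS (natural log; the base only rescales slopes) within pooling
groups — per species by default, since every analysis is run per species —
and the residuals are the shape variables used downstream.

**Distances.**  Allometric standardization to the common mean standard
length: `M_adj = M · (Ls/L0)^b`, with `b` per variable the slope of
log₁₀ M on log₁₀ L0, estimated within pooling groups (per site by default)
and averaged with df weights, and `Ls` the arithmetic mean SL of the
analysis set.  The ratio form is the classical correction: it is
dimensionless in the correction factor, exact at `L0 = Ls`, and idempotent
(refitting `b` on standardized data gives ≈ 0).  A frequently reproduced
typographical variant `M · (Ls − L0)^b` is available behind
`literal_subtraction=True` for forensic comparison only; it is dimensionally
inconsistent and undefined for `L0 > Ls` with fractional `b`.  After
standardization every variable is re-correlated against SL (Pearson,
two-sided); variables standardized from exact power laws become constant and
are reported "not-applicable".

## Repeatability and reproducibility

Each (species, site, measurer, repeat) dataset, reduced to its size-corrected
variables and sorted canonically by individual, is converted to a Euclidean
distance matrix over the 30 individuals.  Agreement between two datasets of
the same individuals is the Mantel correlation R of the off-diagonal
triangles; significance is one-sided for positive association with
p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm) under joint row/column
permutation.  For n ≤ 8 individuals all n! permutations are enumerated and
the p-value is exact.  R is reported as computed and can be negative; no
clamping to [0, 1].

Pairing: repeatability compares the repeats of one measurer
(C(R,2) pairs per measurer per population: 3 × C(3,2) × 9 populations = 81
per method, 324 over four methods); reproducibility compares different
measurers' datasets in **all** repeat pairings (C(M,2) × R² = 27 per
population, 243 per method, 972 in total) — the all-pairings reading is
forced by the per-species group size of 81.

Group comparisons at consecutive levels (measurer within method × species;
species within method; method) use Kruskal–Wallis with midranks and the
standard tie correction; pairwise two-group Kruskal–Wallis tests at
α = 0.05, uncorrected by default (Holm/Bonferroni would be a caller-side
p-adjustment on the returned table), summarized with a greedy insert–absorb
compact letter display over the non-significance graph.

## Separative power and measurer effect

One repeat per (individual, measurer) is chosen uniformly at random
(seeded; the chosen repeat is recorded), giving P·N·M = 270 rows per
species and method.

**CVA.**  Shape residuals are rank-deficient (at most 2K − 4 informative
dimensions), so the data are first projected onto principal components with
eigenvalue > 1e-10 of the largest, capped at n − g components; the
generalized eigenproblem between/within is then solved densely on the
reduced space.  At most g − 1 axes are retained; per-axis variance
percentages are eigenvalue shares; axis signs are fixed by making the
largest-magnitude loading positive.  Pairwise population detachment is a
two-group one-way PERMANOVA on the Euclidean distance matrix at α = 0.05,
uncorrected; with three populations the count of significant pairs maps to
the classes all-three / two-of-three / one / none.

**PERMANOVA.**  The crossed two-way partition works on the Gower-centred
squared-distance matrix G (so SS_total = (1/n)Σ_{i<j}d²ᵢⱼ = tr G): main
effect SS are tr(H G) for the centred factor projectors, the interaction SS
is the cell-means SS minus both main effects, the residual the remainder;
the identity SS_site + SS_measurer + SS_interaction + SS_residual = SS_total
is asserted on every run.  df are (a−1, b−1, (a−1)(b−1), n−ab, n−1) — for
the canonical design (2, 2, 4, 261, 269).  Pseudo-F uses the residual mean
square; p-values come from unrestricted permutation of specimen rows
(the simplest scheme, also used for the interaction; restricted schemes are
deliberately out of scope), recomputing every F.  The design must be
balanced, as the study design is.

## The synthetic generator

The generator emulates exactly the features the statistics measure:

* **Shape hierarchy.**  Each species is the unit-size template displaced by
  0.08 shape units along a fixed direction; population means are displaced
  from their species template by `population_shift` (default 0.012) along
  fixed orthonormal directions; individuals scatter isotropically around
  their population mean with per-coordinate SD `individual_sd` = 0.02.
  These magnitudes make populations overlap substantially (detachment is a
  statistical question, not a foregone conclusion) while species are
  trivially distinct.
* **Measurer bias** is one fixed landmark-offset vector per measurer (norm
  `measurer_bias`), added to every record of that measurer — the mean-shift
  that drives the PERMANOVA measurer effect and the centroid "ghosting" in
  CVA plots.
* **Repeat noise** is iid Gaussian per coordinate per record (SD
  `repeat_noise`) — the digitization error that degrades Mantel R.
* **Size.**  SL is drawn log-uniformly from 60–135 mm (the span of
  mid-sized cyprinids) once per individual; landmark records are the shape
  times SL, so centroid size carries the size signal.  Distance variables
  are 16 inter-landmark distances of the perturbed body configuration times
  SL^b (b default 1.1, mild positive allometry); caliper mode multiplies
  measurer bias ×6 and repeat noise ×2 relative to truss mode, emulating
  measurement on the fish itself rather than on a static image.

Per-method error profiles (shape units) are fixed once:

| method | measurer_bias | repeat_noise |
|--------|---------------|--------------|
| GMB    | 0.004         | 0.005        |
| GMS    | 0.020         | 0.010        |
| TRU    | 0.012         | 0.014        |
| TRA    | 0.072 (×6)    | 0.028 (×2)   |

The magnitudes were calibrated once so that the noise ordering
TRA ≫ TRU ≳ GMS ≫ GMB — the defining condition of the comparison — yields
the mean-repeatability ordering GMB > GMS > TRU > TRA, and then frozen; no
attempt is made to reproduce any particular published mean.

**What the generator does not emulate.**  Real measurers disagree
*individual-dependently* (hard specimens are hard for everyone differently);
the generator's bias is a constant offset, which largely cancels in
between-individual distances, so synthetic reproducibility barely drops
below repeatability — unlike real scale-landmark data, where the drop is
marked.  It also produces no outliers, no clerical data-entry errors, no
specimen degradation between repeats, and no species-specific scale-shape
difficulty (a "characteristic" scale template exists but maps to geometry,
not to measurer behaviour).  Passing tests therefore demonstrate that the
machinery measures what it should under a controlled error model, not that
any particular real dataset will show these magnitudes.

## Numerical choices and degenerate inputs

* GPA: tolerance 1e-8, 100 iterations; zero-centroid-size specimens raise an
  error naming the specimen; non-convergence raises with the final change.
* Constant logCS within a pooling group: slope 0 with a warning (error in
  strict mode).
* Zero measurements are excluded from that variable's allometric slope with
  a warning; constant SL in all groups is an error.
* Mantel: zero-variance triangles raise; exact mode auto-activates at n ≤ 8;
  permutation exceedance comparisons use a 1e-12 slack against ties.
* Kruskal–Wallis p from the χ² approximation (groups here have n ≥ 9).
* All permutation p-values are seeded; every pipeline stage draws from a
  named substream of the single run seed, so adding a stage does not shift
  existing streams.

## Problem sizes used in the test suite

The default test run exercises the full canonical design (2430 records per
method) for the bookkeeping, concordance-mean and PERMANOVA-structure
checks; statistical calibration uses 2000 null replicates (Mantel, n = 10,
99 permutations) and 1000 null replicates (two-way PERMANOVA, 3 × 3 × 3
design); the qualitative ordering and subjectivity patterns use 20 generator
seeds with sign tests.  Permutation counts in tests (99–999) are chosen for
the quantity under test (F statistics and R are permutation-free; only
p-values consume permutations); the CLI default remains 9999.

## Known limitations

* Exact published F/p values from any real study are not recoverable without
  the identical random repeat selection and specimens; only structural
  quantities (counts, df) and qualitative patterns are asserted.
* Whether pairwise detachment in the original software stack came from
  CVA-associated MANOVA or permutation tests is not determinable; the
  permutation choice here is documented, not asserted as anyone else's.
* The allometric pooling ("each analysis") is configurable because the
  canonical grouping is ambiguous; per-species with within-site slope
  pooling is the default.
* One-sided Mantel p matches the use of R as a similarity score; a two-sided
  variant would halve nothing for the high-R comparisons that dominate here
  but would change null calibration.
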