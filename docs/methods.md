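# Methods

## The measurement and its model

A multicolor lineage-tracing experiment labels single embryonic radial
glial progenitors with up to 12 heritable reporters: six spectrally
separable fluorescent proteins (YFP, mKO, mCerulean, mCherry, mT-Sapphire,
EGFP), each existing in a cytoplasmic and a nuclear (H2B-fused) plasmid
form that a piggyBac transposase integrates independently and
stochastically. At analysis time each labeled cell in serial 50-µm coronal
sections is measured in six channels and two compartments, giving a
12-value intensity vector. The analysis asks three things of that vector:

1. **Which reporters are present** (the 12-digit color code);
2. **Which cells are siblings** (same code, similar intensities);
3. **What the resulting clones look like** (size, rostro-caudal extent,
   glial composition, laminar spread).

## Barcoding

Presence is a fixed-threshold call (default 40 intensity units on the
package's 0–255-like scale), with the boundary convention that a value at
the threshold counts as present. The code's layout is positional: the
cytoplasm block occupies digits 1–6 and the nucleus block digits 7–12;
within a block position *i* holds digit *i* or 0. The encode/decode pair
is exercised exhaustively over all 4095 labeled presence patterns in the
tests. No probabilistic or mixture-model calling is attempted: a
supervised-threshold stand-in keeps the decision auditable, and the
threshold is exposed in every config.

## Clone calling

Cells sharing a color code within an animal are candidate siblings.
Two guards refine the grouping:

* **Intensity consistency.** Integrated copy number scales fluorescence,
  so true siblings agree in brightness. A group is consistent when, for
  every reporter named in the barcode, the maximum pairwise difference of
  member intensities is strictly below 80 units. Inconsistent groups are
  split by single-linkage clustering under the Chebyshev distance
  restricted to present reporters, cut at the same 80-unit threshold —
  the deterministic analogue of the manual "same intensity ⇒ same clone"
  judgement. Comparing only barcode-present reporters is deliberate:
  absent-reporter readings are background noise and carry no copy-number
  signal. A clone-mean comparison mode exists as an option but does not
  split.
* **Rarity filter.** Independent progenitors can draw the same
  integration pattern by chance, and common codes are the likely
  collisions. A clone may only be classified as mixed (two glial types)
  when its code occurs in strictly less than 1% of all labeled cells in
  the loaded dataset (the denominator is configurable to per-animal).
  Ineligible multi-type groups are reported as "ambiguous" rather than
  dropped, keeping cohort counts auditable.

Groups below 4 cells — the smallest clone the method is credited with
resolving — are flagged `fragment` and excluded from cohort summaries by
default. Clones never span animals.

`CloneCaller` presents this as a scikit-learn cluster estimator
(`fit`, `labels_`, `fit_predict`, `get_params`/`set_params`) so it
composes with sklearn model-selection tooling; `call_clones` is the thin
functional wrapper.

## Clone metrics

Rostro-caudal dispersion uses the inclusive-span convention:
`(max − min section index + 1) × thickness`, with the first labeled
section as index 0 ("0 µm"). A single-section clone therefore disperses
50 µm — which is why the convention is inclusive: an exclusive difference
would report 0 µm, a value the measurement (one physical 50-µm section)
cannot produce — and a seven-section clone 350 µm. Composition follows
glial lineage logic: Ast, NG2, OL and NG2+OL clones are uniform (NG2-glia
act as oligodendrocyte precursors, so an NG2+OL clone is one lineage),
Ast+OL and Ast+NG2 are mixed, and mixed labels additionally require
rarity eligibility. Laminar spread is binary: restricted to lower layers
(V–VI) iff every member's region is LL, else spread (upper layers and/or
corpus callosum involvement).

Cohort percentages are rounded half-up to integers, matching how clonal
pie charts are conventionally printed; they can sum to 100 ± 1.
Uncertainty is printed as SEM (= SD/√n) by default with SD retained in
the same table, because published clonal reports mix the two
conventions.

## Statistics

The gate is the Lilliefors-corrected Kolmogorov–Smirnov test against the
normal family, with the Dallal–Wilkinson p-value approximation
(statsmodels' `lilliefors`, `pvalmethod="approx"`). It is informative
only — the pipeline always reports the nonparametric comparisons, as
appropriate for small, skewed clonal samples. Samples with n < 4 or zero
variance are "not assessable" and default to the nonparametric branch.

Mann–Whitney U is exact (full null distribution) when both groups have
≤ 8 observations and no ties, otherwise normal approximation with tie and
continuity correction; the flag on every result records which branch ran.
Kruskal–Wallis H uses the χ² approximation with k−1 df, or exhaustive
permutation of group assignments when the pooled sample is ≤ 10. Both
tests default to two-sided; no multiple-testing correction is applied —
a known limitation, kept to match standard practice in this assay rather
than silently changed. Tests are validated against a brute-force
enumeration oracle (all rank arrangements for n₁, n₂ ≤ 6) and by type-I
calibration at 10³ null replicates.

## Synthetic cohorts

The generator is the package's study-condition definition, not a tuning
surface. Defaults:

| parameter | default | rationale |
|---|---|---|
| `p_integration` | 0.5 per reporter | maximizes code diversity (collision probability per progenitor pair (q²+(1−q)²)¹² ≈ 2.4·10⁻⁴); not an empirically reported rate |
| copy-number law | 1 + Poisson(λ=1) | small-count integration with mode 1 copy; only "a variable number of copies" is known |
| `gain` | 100 units/copy | one copy-number step (100) clearly exceeds the 80-point sibling rule |
| `noise_sd` | 8 units | 6σ of a sibling intensity difference (6·8·√2 ≈ 68) stays below 80, so true clones pass the rule |
| `background_level` | 5 units | well below the 40-unit presence threshold |
| fate-class probs | 0.26, 0.34, 0.17, 0.11, 0.06, 0.06 | the reported uniform/mixed clonal proportions |
| clone-size law | truncated negative binomial on [4, 49], per-class means 11.58 / 16.58 / 11.88 / 14.40 / 32 / 12.67, shape 6 | means match the reported per-class averages; the distributional form is a stand-in — only ranges and means are known |
| span law | 1 + Binomial(6, 0.27) sections | support 1–7 (50–350 µm), mean ≈ 2.6 sections ≈ 130 µm, the scale of reported uniform-clone dispersion |
| region placement | per-class UL/LL/CC probabilities, LL-dominant | qualitative: astrocyte clones reach upper layers, oligodendrocyte clones the corpus callosum, mixed clones both |
| mixed split | 50/50 | astrocyte+oligodendrocyte clones carry equal type counts; the Ast+NG2 ratio is exposed because equality is *not* expected there |

Present-reporter intensity is `copies × gain + N(0, noise_sd)` floored at
0; absent reporters read `background_level + N(0, noise_sd)`. Each clone
occupies a run of consecutive sections whose endpoints are always
occupied, so ground-truth dispersion equals span × thickness exactly.
All-zero integration draws are resampled (an invisible progenitor cannot
appear in the analyzed table), and only labeled cells are generated.

What the generator does **not** emulate: electroporation efficiency,
tamoxifen-dependent removal of episomal copies, neuronal progeny,
bleed-through between channels, real glial morphology, or spatial
correlation of sibling positions within a section. Passing tests
therefore demonstrate correctness of the *analysis* under the stated
generative assumptions, not robustness to every failure mode of real
microscopy.

## Imaging forward model

Sections are 2-D (the assay analyzes 50-µm physical sections as mosaics);
cells are concentric disk (nucleus, radius 4 px) + annulus (cytoplasm,
outer radius 8 px) renderings with additive Gaussian pixel noise.
Detection thresholds the across-channel maximum projection at median +
5σ with a 5-px minimum area — the maximum projection ensures
single-channel cells are found, and the annulus centroid coincides with
the cell center, so hollow (cytoplasm-only) cells detect correctly.
Quantification averages the same disk/annulus masks and subtracts the
per-channel image median (robust, parameter-free background). Cells whose
cytoplasm mask would leave the image are flagged, never silently cropped.
On noiseless, non-overlapping renderings the render → detect → quantify →
barcode roundtrip reproduces every generating barcode exactly, and
recovery is linear in rendered intensity (slope 1, R² > 0.99 on a
100-cell sweep).

## Numerical and procedural choices

* Threshold boundaries are fixed conventions: presence is `≥ threshold`;
  sibling consistency and rarity are strict `<`. A pairwise difference of
  exactly 80 splits; a code frequency of exactly 1% is ineligible.
* Single-linkage cutting uses `t = tolerance·(1 − 10⁻¹²)` so that exact-
  tolerance distances do not link (scipy's cut is ≤ t).
* Clone calling is invariant to input row order (groups are keyed and
  ordered by animal and barcode; membership comes from connected
  components at a fixed cut).
* TSV round-trips are bit-exact: floats are written with `%.17g` and read
  with pandas' `round_trip` parser; barcodes are read as strings to
  preserve leading zeros.
* Degenerate inputs fail loudly: empty tables, all-zero barcodes,
  negative intensities, malformed digits, unknown fate classes and
  missing region labels all raise with the offending row or value named.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo bands
tight relative to the asserted effect: 10⁴ draws for integration-profile
binomial checks, 10³ replicates for type-I calibration (3σ band
0.029–0.071 around α = 0.05), 200 progenitors (~3·10³ cells) for
partition-recovery ARI, 10³ progenitors for the clone-consistency
probability, and 2·10³ progenitors for fate-class convergence. All
stochastic tests are seeded.

## Known limitations

* Cell-type labels are consumed as given (marker-based typing is a wet-lab
  input); no typing errors are modeled.
* The intensity-consistency rule compares raw units; no normalization
  across sections or animals is attempted, so section-to-section staining
  drift would need upstream correction.
* The rarity filter's denominator choice (whole dataset vs per animal)
  changes eligibility in small cohorts; the default (whole dataset) suits
  pooled analyses.
* Headline cohort quantities of the motivating assay (specific clone
  counts and dispersion means) depend on undeposited specimen data and are
  not recomputable; the package instead verifies the conventions and
  properties those quantities rest on.
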