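# Methods

This note documents the models, scoring rules, parameter choices and
numerical conventions implemented in `sterol4d`, and what the synthetic
test fixtures do and do not establish.

## Derivatization mass arithmetic

Sterol hydroxyls are esterified with picolinic acid (PA, C6H5NO2,
123.0320 Da). Each ester bond adds a picolinoyl group C6H3NO
(Δ = 105.0215 Da = PA − H2O) to the molecule, so the derivatized neutral
mass is `M + n_OH · Δ` with `n_OH ∈ 1..5` (sterols with no or more than
five hydroxyls are outside the derivatizable class and are rejected at
library curation). Element masses are hard-coded monoisotopic values to
6 decimals; the proton is 1.007276 Da and the sodium cation
22.989220 Da (Na − e⁻). Supported precursor adducts are [M+H]+, [M+Na]+,
[M+H−H2O]+ and [M+H−2H2O]+. By default monohydroxysterols are keyed as
[M+H]+ and di-/polyhydroxysterols as [M+Na]+; this follows the hydroxyl
classes of the fragmentation rules, since instrument practice does not
pin a precursor adduct per compound.

Feature ids encode rounded coordinates as `M<mz>T<rt_s>C<ccs>`; rounding
is half-up, which matches the printed examples (528.38 → M528).

## Four-dimensional match scoring

Candidates must pass a hard MS1 gate of 25 ppm. The three soft scores are:

* **RT** — trapezoid on absolute error in seconds: plateau at 1 inside
  `rt_min`, linear ramp to 0 at `rt_max` (0/12 s against the standard
  library, 0/30 s against the extended library). At the degenerate edge
  `tol_min = tol_max` the score is 0 (strict maximum).
* **CCS** — the same trapezoid on the percent error relative to the
  library CCS (1/1.5 % standard, 1/3 % extended).
* **MS/MS** — against measured standard spectra, the reverse dot product:
  the squared cosine of √-intensity vectors restricted to library peaks
  (measured peaks matching no library peak are ignored; unmatched library
  peaks contribute zero). This is the classic NIST-style dot product with
  intensity weighting `intensity^0.5 · mz^0`; it is scale-invariant in
  both spectra. Fragment m/z matching uses 25 ppm with a 0.01 Th floor,
  mirroring the MS1 gate. Against the rule-predicted extended library,
  the two-ion rule score: 1.0 when both the skeleton ion
  (precursor − PA) and the derivate ion [PA+Na]+ (146.0212 Th) are
  detected, 0.5 for exactly one, 0 otherwise.

The integrated score is `0.2·RT + 0.4·CCS + 0.4·MS/MS`. An identification
is kept when the integrated score strictly exceeds 0.6 ("larger than"
read as strict) and the MS/MS score reaches the tier cutoff (0.6
standard, 0.5 extended). Features without a fragment spectrum are scored
but never kept. Standard-library matches are MSI level 1 and take
precedence over extended-library (level 2) matches for the same feature;
within a tier the highest integrated score wins, ties broken by smaller
|ppm error| and then name, so output is deterministic.

A consequence of the published weighting worth knowing: with perfect CCS
and MS/MS scores the integrated score is 0.8 regardless of RT, so an RT
outlier alone can never reject a candidate. The RT dimension only
discriminates among candidates that already disagree elsewhere.

RT calibration against RTQC reference pairs is piecewise-linear
interpolation with linear end-segment extrapolation, applied to library
RTs before matching; observed RTs must be strictly increasing.

## Decoy FDR

The published workflow reports an identification FDR but not its decoy
construction, so the implementation provides a synthetic stand-in
(flagged as such in its output): the decoy library copies the target with
identities relabeled and CCS displaced by ±2 × the extended CCS tolerance
(sign random per entry, seeded); `rt-shuffle` and `mass-shift` strategies
are alternatives. FDR% = 100 · decoy hits / target hits at each CCS
tolerance of a grid, all other dimensions at extended-library settings.
Absolute FDR values from this scheme depend on the decoy design and
should be read as relative (tolerance-to-tolerance, dataset-to-dataset)
comparisons.

## Isomer separability and the chemical space

Two library compounds sharing an exact mass key (within 5 mDa; the
source text says "same exact mass" without a tolerance) form an isomer
pair. In derivatized mode the key is the derivatized neutral mass; in
underivatized mode the keys are the detected-ion m/z values [M+H]+ plus
water-loss adducts up to the hydroxyl count, because in-source water loss
can collapse distinct masses onto one detected ion — this is why
underivatized libraries have more pairs than derivatized ones.

Pair metrics: percent CCS difference `|CCS_A − CCS_B| / CCS_A × 100`
with A chosen as the smaller CCS (the conservative, larger percentage —
the source does not fix the ordering); one-dimensional peak resolution
`2|Δposition| / (W_A + W_B)` with full base widths (4σ for Gaussian
peaks when only a σ is known; file-supplied widths take precedence); and
the two-dimensional LC-IM resolution `sqrt(R_LC² + R_IM²)`.

The class trend line is `CCS = a·mz^b`, fitted by nonlinear least
squares from the starting point (a=1, b=0.05). The 99% predictive
interval half-width is `Δy = z·s_yx·sqrt(1 + 1/n + (x − x̄)²/SS_x)` with
z = 2.576 (a normal quantile, as printed, rather than a t-quantile),
`s_yx` the standard error of the estimate and `SS_x` the x
sum-of-squares computed from the data. A printed `SS_x` constant can be
supplied as an override (`ss_x_override`) because the published constant
(98.71926) is inconsistent with the raw m/z spread of a ~100-compound
library (~10⁵–10⁶), suggesting an undocumented x-scaling; the package
does not guess that scaling. A point is inside the chemical space when
its CCS residual from the trend is at most Δy(mz).

## Predictor (extended-library curation)

Descriptors are either loaded from file (first column compound name) or
computed from SMILES with RDKit's 2-D descriptor set; descriptor sets
from different toolkits differ in membership, so reproduction of
published selection sizes requires the original descriptor matrix.
Missing values are imputed with training-set medians. LASSO selects
descriptors with nonzero coefficients at the minimum-CV-MSE lambda
(10-fold); an empty selection falls back, with a warning, to the largest
lambda with at least one nonzero coefficient. The SVR uses an RBF
kernel with C = 23, γ = 0.1/12 for CCS and C = 29, γ = 0.25/24 for RT
(the published optima used directly; the original 77-combination search
grid is not enumerated) and ε = 0.1, a conventional default not stated
in the source. Features are standardized with training statistics
carried by the fitted predictor.

Validation reports R² as the squared Pearson correlation between
predicted and observed (the coefficient of determination is also
reported for transparency; the source's "R²" is not defined precisely),
the median relative error (MRE, %) for CCS, and "median error"
interpreted as the median absolute error in seconds for RT.
Leave-one-out validation refits the full pipeline n times.

## Quantification

Calibration points (known amount ng, peak-area ratio analyte/IS) from
all injections are pooled into one unweighted OLS line per analyte
(bracketing injections are not averaged separately — the source does not
say; 1/x weighting is available). Curves with non-positive slope or
fewer than three distinct levels are rejected. Level-1 analytes use
their own curve; level-2 analytes the curve of a same-subclass standard.
Concentration = inverse-interpolated amount × dilution factor / tissue
mass (ng per mg wet weight); readings outside the calibrated range are
flagged, not extrapolated silently, and below-LOQ values are expected to
be excluded from downstream statistics by the caller.

## Region and aging statistics

The concentration matrix is sterols × (region, age, replicate). The
spatial screen is a per-sterol one-way ANOVA across regions within one
age (6-week by default; pooling is an option — the source is ambiguous),
with raw p < 0.05 as quoted; a BH-adjusted variant is behind a flag.
Altered sterols are standardized to row Z-scores on per-region means and
clustered with WPGMC (median) linkage on a 1 − Pearson correlation
distance. Centroid-family linkage on a non-Euclidean distance is a
heuristic — merge heights are not guaranteed monotone — but it is the
field's practice and is used deliberately. Constant rows are dropped
with a warning.

Age contrasts are two-sided two-sample t-tests per (sterol, region) with
log2 fold changes of group means and Benjamini–Hochberg adjustment
within each region. The coregulation network connects dysregulated
sterols whose per-region fold-change profiles have |Pearson r| ≥ 0.85
over at least 3 shared regions; zero-variance profiles are excluded, and
nodes carry per-region log2 fold changes for export (edge list CSV and
GraphML).

## Synthetic data generators

The fixtures module emulates the study's data shapes with planted,
seeded ground truth; every generator is a pure function of (spec, seed).

* **Libraries** — 97 standard + 2068 extended compounds by default.
  Formulas are drawn from a sterol-like elemental space (C18–32
  skeletons, 3–8 double-bond equivalents, 1–3 hydroxyls plus 0–2 other
  oxygens) wide enough that isomer groups stay small, matching the LMSD
  sterol statistics (most sterols have isomers; large groups are rare).
  CCS is `22.2·mz^0.38` plus Gaussian scatter of 18 Å², the class-level
  residual scatter implied by the published trend-line standard error;
  RT ramps with m/z over a 20-min-gradient-like range (120–1020 s, 60 s
  scatter). Standard entries carry measured-style spectra (rule ions at
  realistic intensities plus low-intensity noise peaks); extended
  entries carry rule-predicted spectra.
* **Feature tables** — true features jitter library coordinates well
  inside the match tolerances (5 ppm, 3 s, 0.3 %); decoy features
  displace CCS beyond the widest tolerance (6 %), displace RT and CCS
  jointly, or strip the spectrum. A pure RT displacement is not used as
  a decoy because the published weighting cannot reject it (see above).
* **Brain matrices** — 197 sterols × 10 regions × 2 ages × 6 replicates;
  per-sterol baselines log-uniform over 8 orders of magnitude
  (10⁻⁴–10⁴ ng/mg, the published dynamic range); 149 sterols carry one
  of three orthogonalized region-archetype profiles (amplitude
  2 in log2); 102 sterols carry age fold-change profiles (amplitude 1.5
  in log2), organized into positively coupled modules of 21 and 5 plus
  3 anti-correlated pairs so the planted coregulation structure is
  known; replicate noise is log-normal with 20 % CV.

What passing these fixtures shows: the scoring, screening and network
machinery recovers structure it was told to plant, at the study's scale
and noise levels. What it does not show: performance on real LC-IM-MS
data, where CCS/RT errors are structured rather than independent,
spectra contain chimeric and in-source fragments, isomer CCS values
cluster by scaffold, and missingness is not random. Paper-level numbers
(external-validation R², isomer-pair counts, separability fractions)
depend on the real compound set and require the original supplementary
tables, which are not redistributable with the package.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the generators at the study
scale (97/2068 libraries, 100-feature tables, 197×120 brain matrices;
400 sterols for the null ANOVA calibration and 20 seeds × 40 sterols for
the FDR calibration) — sizes chosen to pin the statistics without waste.
Delimited text is comma-separated UTF-8 with a header (TSV accepted by
sniffing); m/z serializes to 4 decimals, RT/CCS to 4 decimals; RT is
always seconds, CCS Å², m/z Th. Spectra round-trip through MSP/MGF via
matchms; rule-predicted spectra carry a `predicted=rule` field and
per-peak role annotations. Nonlinear fits use scipy `curve_fit`
(max 20000 evaluations); a non-converged trend line raises rather than
returning garbage. All RNGs are numpy `default_rng` seeded explicitly.
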