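# Methods

## Scope and data model

`seroprofiler` analyses two linked data sets from a single atopic cohort:
an allergen-component sIgE panel (patients × 26 storage-protein
components, concentrations in kUA/L) and linear-mode MALDI-TOF serum
spectra (m/z 1000–10,000 Da, three technical replicates per sample).
The panel side produces sensitisation calls and summaries; the spectra
side produces a samples × peak-clusters matrix, per-cluster discriminant
statistics and validated classifiers; a mass matcher links discriminant
peaks to catalogued peptide identifications.

## Panel analysis

The packaged catalog holds the 26 components with their family
(vicilins, legumins, 2S albumins, cereal prolamins) and superfamily
(Cupins, Prolamins) assignments; family sizes are 6/6/13/1.

* **Positivity** is `concentration >= threshold`, inclusive, with a
  default of 0.35 kUA/L. The threshold is a config parameter because
  published cohort descriptions are not always internally consistent
  about it; 0.35 kUA/L is the conventional assay cut-off.
* **Family calls**: a patient is family-positive when positive to at
  least one member component; the allergy group is every patient positive
  to any storage protein, controls are all others.
* **Summaries**: prevalence = 100·count/n, reported to one decimal (full
  precision retained). Concentration statistics use the sample SD
  (n−1 denominator; configurable). The "allergy group" concentration
  columns are computed over the patients *positive to that component* —
  the convention that makes single-positive components show SD 0 — not
  over all allergy-group members. Not-measured cells ("-") are distinct
  from the 0.1 kUA/L detection floor and are excluded from statistics;
  empty groups report absent (NaN), never zero.

## Synthetic cohort generator

The generator's defaults are the study conditions used by every test:
n = 76, 22 allergic, family-positive counts 19 (2S albumins),
15 (vicilins), 10 (legumins), 1 (cereal prolamins), and 9 patients
positive to all of Ara h 1/2/3 (the co-sensitisation structure of peanut
allergy). Family and component counts are planted *exactly*: family
membership is assigned by a feasible random covering (every allergic
patient belongs to at least one family), the nine triple-positive
patients are placed first, and per-component positives are drawn inside
each family so that the configured counts (Ara h 1: 14, Ara h 2: 13,
Ara h 6: 12, Ara h 3: 9, …) are hit exactly. A probabilistic mode
(independent Bernoulli positives with a triple-sensitisation coupling
probability, default 9/17) is available for non-deterministic cohorts.

Concentrations: negatives sit at the 0.1 kUA/L detection floor (a point
mass, no imputation); positives are log-normal truncated at the
positivity threshold. Per-component (µ, σ) are derived from published
allergy-group medians and means via µ = ln(median),
σ = √(2·ln(mean/median)) (fallback σ = 0.3 when the printed mean does not
exceed the median, which happens for small positive counts). Truncation
raises the realised mean slightly above the configured log-normal mean;
`truncated_lognormal_mean` gives the exact expectation used by the tests.
One component (rTri a 19) has a printed allergy-group concentration of
0.3 kUA/L, *below* the 0.35 positivity cut-off — an inconsistency of the
source summary; its generator location is ln(0.4) so that a truncated
positive draw exists.

## Synthetic spectra

Each spectrum is baseline + Gaussian peaks + noise, clipped at zero:

* baseline: A·exp(−(m/z − 1000)/τ) + c with A = 30, τ = 1200 Da, c = 2
  (arbitrary units) — a typical chemical-background shape;
* peaks: Gaussian with FWHM = 3 + 0.002·m/z Da (linear-mode widths grow
  with mass); 16 class-shared background peaks plus discriminant peaks at
  the 15 published genetic-algorithm positions with class-conditional
  amplitude ratio 2 (allergy : control = 48 : 24, against noise SD 1);
* biology: per-sample, per-peak log-normal amplitude multipliers
  (CV 0.25), shared by that sample's replicates;
* replicates: a multiplicative intensity jitter (CV 0.08) and a small
  linear m/z miscalibration (slope within ±5·10⁻⁵, offset within
  ±0.3 Da, i.e. ≤ ~0.8 Da at 10,000 Da) per technical replicate.
  Additive detector noise is drawn once per biological sample and shared
  by its replicates, so replicate-level variation is exactly the jitter
  plus miscalibration: with both at zero, replicates are identical.

What the generator does *not* emulate: isotope structure, detector
saturation, matrix cluster ions, heteroscedastic detector noise, or any
relationship between a patient's sIgE titres and their spectrum beyond
the class label. Passing tests therefore demonstrate that the pipeline
recovers signals of the planted form at the study's sample sizes — not
that it would recover the specific biology of real sera.

## Spectrum processing

Canonical order (enforced; overriding requires an explicit flag):
resample → recalibrate → TIC-normalize → smooth → top-hat baseline →
group replicates → total mean spectrum.

* **Resampling**: linear interpolation onto a uniform grid over
  1000–10,000 Da; default step 1 Da (2 Da in the packaged demo — linear
  mode peaks are many Da wide, so either step oversamples every peak).
* **Recalibration**: the 15 most prominent peaks per spectrum are pooled
  and clustered at a coarse 0.2% tolerance; positions shared by ≥ 80% of
  spectra define consensus masses; each spectrum gets a least-squares
  linear axis correction. Corrections implying shifts beyond 3 Da flag
  the spectrum instead of warping it; fewer than 3 consensus peaks skip
  the step with a warning.
* **TIC normalization** divides by the intensity sum (Σ = 1 afterwards).
  Classifier results are scale-invariant under this choice.
* **Smoothing**: Savitzky–Golay, window 5, order 2 (moving average
  available); edges handled by the truncated-window polynomial fit.
* **Top-hat baseline**: output = input − greyscale opening with a flat
  structuring element spanning 10% of the processed span ("minimum
  baseline width"); the result is pointwise ≥ 0 and exact against a
  brute-force sliding-window erosion/dilation oracle.
* **Grouping** averages the replicates of each sample pointwise;
  grouping precedes peak picking.

## Peak picking and clusters

Local noise is a sliding-window median absolute deviation × 1.4826
(window 250 Da). Because the top-hat of a noisy trace rides on a small
positive pedestal (noise minus its lower envelope), S/N rates an apex by
its height *above the local median background*, divided by the local
noise; the threshold is S/N ≥ 5 on the total mean spectrum. A retained
peak must be the tallest local maximum within one FWHM (the larger of
the pair) — this rule is applied before the S/N filter so that raising
the threshold can only remove peaks. Apexes are refined by parabolic
interpolation; bounds sit at the nearest local minima. Each peak defines
a cluster window of width max(FWHM, 0.1% of m/z) — the relative term
reflecting linear-mode mass precision (~100 ppm calibration accuracy) —
with overlaps split at the midpoint. Per-sample cluster intensity is the
windowed maximum (trapezoid area optional). An epsilon noise floor of
10⁻¹² × max intensity guards the S/N division.

## Discriminant statistics

Per cluster: two-sided Wilcoxon rank-sum p (exact permutation null when
n₁+n₂ ≤ 20 and tie-free, else normal approximation with tie and
continuity corrections — validated against full enumeration and, for the
large-sample path, calibrated to a 5.0% type-I rate on null data), and
ROC AUC computed from rank sums (ties count one half). The AUC is stored
both oriented ("allergy scores higher") and as max(AUC, 1−AUC) for
ranking. Significance is raw p ≤ 0.05 with no multiple-testing
correction, matching profiling practice; a Benjamini–Hochberg option
exists but is off by default. Constant clusters report p = 1, AUC = 0.5
and a degenerate flag.

## Classifiers

The three model families are explicit, literature-standard constructions;
the commercial profiling software whose workflow they mirror does not
document its internals, so numerical equality with it is out of reach by
design — the report metrics (cross-validation %, recognition capability
%, per-class correct %) are the comparable surface.

* **QC** ranks clusters by Wilcoxon p, keeps the best `top_k` (default
  10) and classifies by weighted vote: each kept cluster votes for the
  class with the nearer training centroid, weight −log₁₀(p); the class
  score is the normalized weight share.
* **SNN** is LVQ1: per-class prototypes (default 3) initialised by
  class-stratified k-means on z-scored intensities, updated by
  attract/repel steps with a linearly decaying rate (0.3 → 0.01 over 200
  epochs). Repelled prototypes are clipped to the training-data bounding
  box: plain LVQ1 diverges on non-separable data (repulsion ratchets
  prototypes outward), and the clip removes the runaway without touching
  separable problems.
* **GA** selects cluster subsets (size 3–15 by default). Fitness is the
  stratified 3-fold CV accuracy of a nearest-centroid classifier on the
  subset, with standardization fitted on training folds only; evolution
  uses tournament selection (size 3), uniform crossover (p = 0.8),
  per-gene mutation (p = 0.05), size-repair, and one elite. Fitness
  values are memoized per chromosome; folds are fixed per training call
  so fitness is deterministic given the seed.

Ties in prediction scores resolve to the first class of the label
encoding (allergy first). LOOCV retrains the entire model — including
feature selection — in each fold, so selection cannot leak; recognition
capability is the training-set accuracy of the final model. Reports
serialize to JSON losslessly.

## Peptide mass matching

[M+H]⁺ = Σ residue monoisotopic (or average) masses + H₂O (18.0105647)
+ H⁺ (1.0072765), plus modification deltas from a fixed dictionary
(carbamidomethyl +57.02146 applied per cysteine; acetyl +42.01057;
oxidation +15.99491; amidation −0.98402). Flanked peptide strings
(X.PEPTIDE.Y, "-" = terminus) follow the search-engine convention. The
matcher assigns each peak the record/modification combination minimizing
|Δ| within a ppm or Da tolerance (default ±50 ppm, the original search
setting) and lists unmatched peaks separately. Reported linear-mode
precursor masses do not generally equal unmodified theoretical masses
(e.g. the catalogued 1419.92 Da peak sits ≈ 152 ppm above the
carbamidomethylated EACTWGSLALGVR mass, and 1077.88 is ≈ 42.4 Da above
bare NSSNTADITI — an acetylation-sized, but unassigned, gap); the module
therefore surfaces deltas rather than asserting identity.

## Problem sizes and numerical choices

Multi-run experiments derive their streams from `numpy.random.SeedSequence`
spawning — the recommended scheme for independent substreams — and every
stochastic routine takes an explicit seed. Sizes used by the test suite
and acceptance script, chosen to make each check statistically decisive:

* planted-signal recovery: 100 (tests) / 50 (script) full pipeline runs
  at 22 + 54 samples × 3 replicates, grid step 2 Da;
* null calibration: 200 matrices × 30 clusters (6000 tests);
* classifier sanity: 40-sample cohorts with a 5σ class-centroid margin
  (the two informative clusters each shifted by margin/√2); permutation
  nulls use 40 samples — large enough that the known pessimistic bias of
  leave-one-out on chance-level data stays within a few points;
* GA subset recovery: 100-sample cohorts at a 4σ margin, where the
  planted pair is the modal optimum of the exhaustive C(20,2) search; at
  larger margins a single informative cluster saturates the fitness and
  the optimum is no longer unique, so the margin is deliberately partial
  per feature;
* peptide properties: 1000 random sequences.

## Known limitations

* mzML is read (via pyteomics) but spectra are written as two-column
  text; no vendor binary formats.
* The recalibration consensus requires peaks shared by 80% of spectra;
  cohorts with grossly mis-set axes (> 3 Da) are flagged, not corrected.
* External validation on an independent cohort is exposed only as the
  shared prediction interface — no held-out cohort is defined.
* The classifiers are stand-ins with documented semantics, not
  re-implementations of any proprietary tool; their reported percentages
  on synthetic data characterise the pipeline, not any published cohort.
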