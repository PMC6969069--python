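# Methods

## Imaging model and segmentation

Fields are single-channel 16-bit images of Hoechst-like counterstain with a
micrometre calibration (default 0.323 μm/pixel, plausible for a 20× objective
on a 16-bit CCD; every filter is denominated in μm, so any calibration works).
Coordinates are 0-based pixel indices × pixel size; "diameter" always means
the equivalent circular diameter √(4·area/π), which is rotation-invariant and
lets a geometric oracle predict filter decisions exactly.

Segmentation is deliberately simple and reproducible: global Otsu threshold,
per-object hole filling, then a distance-transform watershed seeded at peaks
at least `watershed_min_distance` (default 6 μm) apart to split touching
nuclei. Foreground objects with equivalent diameter below
`min_nucleus_diameter` (default 7 μm) are not nuclei but micronucleus
candidates; a floor of `mn_min_diameter` (default 1 μm) discards noise
specks. No attempt is made to model a vendor segmentation stack; the
contribution quantified here is the filter scheme downstream of any
reasonable segmentation.

The cell-body (secondary) mask is `expand_labels` on the nuclear labels by
`cell_mask_dilation` (default 10 μm): a fixed-radius dilation whose overlaps
are partitioned by nearest nucleus, so labels never merge. No cytoplasmic
stain exists in this assay, so a true cell-body segmentation is not possible;
the fixed-radius convention is stated rather than hidden.

### Micronucleus filters

A candidate is a foreground component outside all primary regions and inside
a secondary region (a candidate spanning two regions is assigned to the
nearest nucleus centroid and logged). Retention requires all of:

1. equivalent diameter ≤ min(`mn_relative_diameter_cap` × owner diameter,
   `mn_absolute_diameter_cap`) — defaults ⅓ and 5 μm, combined as a minimum
   because the absolute cap reads as a ceiling layered on the relative rule;
   both comparisons are inclusive (≤), indistinguishable from a strict rule
   at pixel quantization;
2. mean intensity ≤ `intensity_cap` (default 58,000 a.u.), which removes
   uniformly bright apoptotic/mitotic bodies;
3. a retained owner: centroid more than `border_margin` (default 30 μm,
   inclusive at the boundary) from every image edge, mean intensity at most
   the cap, area inside `nucleus_area_band` (default 40–1500 μm²). The
   border rule applies to centroids, not bounding boxes — unambiguous and
   directly testable.

The nuclear-area assay returns areas of retained nuclei only and flags (not
raises) a QC failure below `min_nuclei_per_condition` = 200; orchestration
refuses to run downstream comparisons on failed conditions unless overridden.

## Statistics

* Micronucleus frequency is micronuclei per 100 retained nuclei. The
  alternative reading — percent of nuclei owning ≥ 1 micronucleus — is
  provided as `micronucleus_frequency_per_cell`; the per-100 convention is
  the default because multiple micronuclei per cell are informative.
* Fold changes are tested with a two-sided, equal-variance Student t-test on
  replicate means (typically n = 3 per group). Zero-variance degeneracies
  resolve to p = 1 (equal means) or p = 0. Significance codes: * < 0.05,
  ** < 0.01, *** < 0.001, **** < 0.0001, NS otherwise.
* KS comparisons use the exact two-sample null when min(n) < 50 and the
  asymptotic one otherwise; direction is the sign of the median shift.
  Samples under 10 observations carry a warning flag.
* No multiple-testing correction is applied across conditions or genes; the
  workflow mirrors exploratory screening practice and says so.

## PCG grading

A spread with the severe flag (cohesion lost, chromatids scattered) is
PCG_III regardless of counts. Otherwise grading is count-dominant: ≥ 6
defective chromosomes → PCG_II, 1–5 → PCG_I, 0 → NORMAL. The mild/moderate
adjectives attached to defect annotations are treated as descriptive because
the category boundary is the chromosome count; a spread with "moderate"
defects in fewer than six chromosomes is therefore PCG_I by default. This
corner of the taxonomy is a convention, not a fact of the assay, so the
`severity` rule (moderate promotes to PCG_II) is switchable per call. Defect
frequency is 1 − P(NORMAL); modal chromosome counts break ties toward the
smaller value; near-tetraploid means a count above 1.5 × the control mode.

## Survival cutpoint

Candidates are percentiles of the observed expression values from the 20th to
the 80th in 1-percentile steps (a grid rather than all observed values: the
candidate set is then deterministic and independent of ties). "Low
expression" is strictly below the threshold. Each split is scored with the
standard 1-df log-rank test (lifelines); the minimizing percentile wins, ties
to the lower percentile. The minimal-p selection is optimistically biased and
is reported as exploratory — no correction for the search is applied, and the
result object retains the whole (percentile, p) grid so users can see the
profile. Groups with zero events leave the test undefined and flagged rather
than silently producing a number.

## Synthetic generators: what they emulate, and what they do not

`generate_field` renders elliptical nuclei (diameter ~N(15, 1.5²) μm
truncated at ±3σ, axis ratio uniform on [0.85, 1]) with Gaussian-soft edges
(σ = 0.5 px), Poisson-distributed micronuclei per cell placed 1–6 μm outside
the owner boundary, nucleus-sized apoptotic bodies at 63,000 a.u. (above the
intensity cap), and an optional border-placed fraction. Background/foreground
are 3,000/30,000 a.u. with configurable Gaussian noise. Placement is
rejection sampling with a bounded retry budget and an explicit failure naming
the limiting parameter. The micronucleus offset tops out at 6 μm so that a
maximal spot stays inside the 10 μm cell-body band of its owner — the
generator guarantees ownership is geometrically unambiguous, which is what
makes the detection oracle exact. Ground-truth diameters/centroids are
measured from the rendered pixel set and intensities from the noise-free
render, so a brute-force pixel scan of the image reproduces the table.

Not modelled: PSF/illumination fields, multi-channel staining, 3-D stacks,
overlapping or touching nuclei in the default generator (the watershed path
is exercised by dedicated scenes instead), chromatin texture, and real
segmentation ambiguity. Passing the exact-oracle tests therefore shows the
filter chain and bookkeeping are correct, not that segmentation is robust to
the full messiness of real micrographs.

`generate_spread_set` draws counts as modal ± a user distribution with a
tetraploid-shifted subpopulation at 2× modal; defects follow a per-spread
rate with zero-truncated-Poisson defective counts and a severe-spread
probability (severe spreads record defective = count, since per-chromosome
scoring is unreliable once chromatids scatter). `generate_cna_matrix` draws
independent per-gene code probabilities over {−2…2}. `generate_survival_cohort`
uses standard-normal expression, exponential event times whose hazard is
multiplied by the hazard ratio strictly below the chosen expression
percentile (baseline 0.03/month ≈ 23-month median), and independent
exponential censoring calibrated by root-finding so the expected censored
fraction matches the requested rate.

## Problem sizes and numerical choices

Default test and demonstration scales: fields of 80–100 cells at 900–1200 px,
3 replicates × 3 fields per condition; 100–1000 spreads; 10 × 200–600 CNA
matrices; cohorts of 120–300 patients; 100–500 simulation replicates for
calibration checks — sizes at which the binomial/Poisson acceptance
intervals are informative while a full run stays in the minutes range on one
core. All randomness flows from `numpy.random.default_rng` seeds; the
orchestrator derives per-stage child seeds by a fixed integer hash (< 2³¹),
so identical configs give byte-identical JSON reports. Degenerate inputs are
defined, not accidental: blank images yield empty tables, empty masks stay
empty, zero retained nuclei make the frequency an error, all-censored
cohorts refuse the cutpoint search.

## Known limitations

* The intensity/area exclusion defaults for the nuclear-area assay are
  configuration choices, not measured constants of any instrument.
* The cell-body radius is a convention; micronuclei farther than the
  dilation from their owner are invisible to the detector by construction.
* The minimal-p cutpoint is biased toward small p-values; downstream use
  should treat it as hypothesis-generating.
* Replicate t-tests assume equal variance and n ≈ 3; no mixed-effects
  modelling of field-level clustering is attempted.
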