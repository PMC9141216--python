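# Methods

## Measurement model

A sealing event is recorded as a time-ordered stack of 2-D temperature grids
with an isotropic spatial calibration (µm/pixel) and a declared *branch band*
— the row interval occupied by the closed instrument jaws.  Row 0 is the top
of the image; "above the branches" means rows < `r_top`, "below" means rows
> `r_bottom`.  The band geometry and calibration always come from the
recording's sidecar: the package performs no automatic band detection and no
radiometric/emissivity correction (temperatures are taken as the camera
reports them).

The recording is reduced to its **per-pixel peak map** (max over frames).
Tissue damage integrates peak exposure, and the reduction makes the extent
measurement independent of frame rate; it is also idempotent — appending
frames colder than the running maximum changes nothing.  The alternative
(a single chosen frame) would tie results to frame timing.

**Transects.**  Per side, `n_transects` columns (default 15, mirroring the
15 histology measurements per section) are taken evenly across the declared
column ROI, endpoints included (a single transect sits at the ROI centre;
columns that collide after rounding to the pixel grid are merged).  Each
transect is a profile of peak temperature versus lateral distance, with
distance 0 at the centre of the first off-band pixel row — the operational
"edge of the branches" reference.  Whether the original protocol's 15
measurements were spatial transects or repeated readings is not documented;
transects are this package's choice.

**Critical extent.**  The extent of the >50 °C zone is the length of the
contiguous supra-threshold run starting at distance 0, with the boundary
linearly interpolated between the last supra- and first sub-threshold pixel.
Conventions, fixed and tested:

- strictly-greater comparison: a pixel at exactly 50.0 °C terminates the
  zone (boundary-exclusive);
- first-crossing rule: an isolated distal hot pixel (noise speckle) cannot
  re-open the zone;
- a profile that never crosses the threshold is truncated by the field of
  view and returns its last distance — size grids generously;
- a side whose band touches the image edge is reported *absent*, not zero.

The per-side extent is the mean over transects; per-transect values are kept
for dispersion.  Reading the temperature at a stated distance (e.g. the
histological necrosis margin) uses linear interpolation on the same profile,
so frontier-temperature lookup and extent measurement are mutually
consistent: inverting any temperature above the threshold always lands
inside the critical zone.

## Risk index

`RILATE = necrosis extent / critical extent × 100 %`, classified
low ≤ 30 < moderate ≤ 60 < high (closed rule; the published class wording
leaves 30–31 and 60–61 unassigned, and the closed rule reproduces every
published assignment).  Group-level indices are the **ratio of group means**,
which is how the published group values were derived; the mean of per-sample
ratios is computed alongside because the two genuinely differ (18.5 % vs
17.8 % for one group).  Indices are carried at full precision; rounding to
1–2 decimals is presentation only.  Group SDs use the sample (n−1)
denominator, confirmed by digit-for-digit agreement with the published SDs.

## Statistics

The two-sample comparison is the two-sided Mann–Whitney U test.

- **Exact path** (both n ≤ 25, no value shared *between* samples): the null
  distribution of U is enumerated with the counting recurrence
  `N(n1,n2,u) = N(n1−1,n2,u−n2) + N(n1,n2−1,u)`; the two-sided p doubles the
  smaller tail, capped at 1.  Ties entirely within one sample do not alter U
  or its null distribution, so they keep the exact path.
- **Approximate path** (cross-sample ties or larger n): mid-ranks,
  tie-corrected variance `n1·n2/12·((N+1) − Σ(t³−t)/(N(N−1)))`, continuity
  correction 0.5, doubled normal tail.
- Degenerate input (all values identical in both samples) returns p = 1 with
  the tie flag set.

The doubling rule (vs. summing more-extreme outcomes) matters for asymmetric
discrete nulls and is fixed deliberately.  At n₁ = n₂ = 15 the exact test's
attainable level just below 0.05 is 0.0453, which is what a permutation
calibration of the rejection rate converges to.

The eight reference comparisons (critical, necrosis, frontier, per-sample
index; above vs below; two instruments) run in a fixed order, each tagged
with the published p-value for side-by-side reporting.  The published source
does not state which test variant produced its p-values; where the computed
value disagrees with the printed one the report marks it DISCREPANT instead
of suppressing it, and the index comparison whose printed p sat exactly at
the 0.05 level is flagged borderline and judged by its computed value.  No
multiple-testing correction is applied (none was in the source), and no
shift confidence intervals are produced.

## Synthetic data

Noiseless field: `T(d,t) = T_amb + (T_peak − T_amb)·exp(−d/λ_side)·s(t)`,
with `s(t)` a linear ramp (default 2 s) followed by a plateau (3 s), and
i.i.d. Gaussian sensor noise per pixel per frame.  The exponential is the
simplest monotone profile consistent with published temperature curves and
gives closed-form oracles:

    critical_side = λ_side · ln((T_peak − T_amb)/(50 − T_amb))
    necrosis_side = λ_side · ln((T_peak − T_amb)/(T_f − T_amb))

The frontier temperature `T_f` is drawn per side from a normal distribution
truncated strictly inside (50 °C, T_peak), so necrosis < critical by
construction.  Between-sample variability is log-normal on λ (extents are
positive and right-skewed) and normal on `T_f`.  One integer seed governs
everything; per-sample streams are spawned with `numpy.random.SeedSequence`,
making cohorts reproducible element-wise.

Defaults (tissue 22 °C, band plateau 110 °C, λ chosen so the noiseless
extents equal the published group means 2315/1700 µm, frontier
64.93 ± 4.1 °C, 50 µm/pixel, 160 × 48 grid, 8 frames, noise 0.5 °C) emulate
the published study conditions; `paper_cohort_specs()` parameterises both
instruments' sides from the published group statistics, with the log-normal
σ matched to each group's coefficient of variation.  Peak temperature and
ramp/plateau times are free parameters — the source reports no temporal
trace.

**What the generator does not emulate.**  (1) Real lateral profiles fall
steeply near the band and flatten beyond; a single-λ exponential cannot
jointly reproduce the published (critical, necrosis, frontier) triple —
matching critical extents and frontier temperatures forces synthetic
necrosis/critical ratios near 0.6, far above the published 0.18–0.55.
Synthetic cohorts therefore validate estimator correctness and comparison
behaviour, not the realism of the index distribution.  (2) No heat
conduction, perfusion, or tissue heterogeneity (the reference preparations
were ex vivo and unperfused); the temporal profile is a stand-in.
(3) The pathologist's necrosis marking is replaced by profile inversion at
the sampled frontier temperature.  Passing tests on synthetic data show the
pipeline measures what the model generates to stated tolerances; they do not
validate the 50 °C threshold or the class boundaries biologically.

## Numerical behaviour and tolerances

- Noiseless oracle equivalence: measured extent within half a pixel of the
  closed form over random valid parameters (interpolation error on the
  convex exponential is ≪ half a pixel for λ ≫ pixel size); frontier
  inversion within 0.5 °C.
- **Peak-detection bias under noise**: max projection over k noisy plateau
  frames lifts the peak map by ≈ E[max of k N(0,σ)] ≈ 1.2σ for k ≈ 5, which
  the shallow gradient at the crossing, `(50 − T_amb)/λ` °C/µm, converts
  into a strictly positive extent bias (≈ +170 µm at σ = 2 °C with default
  geometry).  This is inherent to peak-over-time reduction, not an
  implementation artefact; the suite asserts the noisy mean extent is
  unbiased *up to* this analytically derived bound.  Keep it small with low
  sensor noise, few plateau frames, or steeper gradients.
- Frame CSVs are written at 6 decimals; round trips are exact to 1e-6 °C.
- Temperatures outside −50…400 °C are rejected on load as corrupt data.
- Test problem sizes — 100 random oracle events, 2 000 permutations,
  200-sample calibration cohorts (tables only, no frame synthesis) — keep the
  full suite a few seconds long while giving Monte-Carlo errors well inside
  the asserted tolerances.

## Known limitations

- 1-D lateral extents only; no 2-D isotherm areas.
- Exact-with-ties enumeration is not implemented; cross-sample ties use the
  approximate path even at small n (flagged in the result).
- The measurement-table necrosis/critical containment check uses exact
  comparisons; equality at the boundary is allowed.
- Calibration is a single isotropic scalar; anisotropic optics are out of
  scope.
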