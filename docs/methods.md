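# Methods

`voxdose` implements an individualized CT dosimetry chain: voxel phantom →
per-voxel dose map → organ doses → effective dose → lifetime risk, next to
the conventional DLP-based estimate, plus the cohort statistics used to
compare the two. This note records the models, the defaults and why they
were chosen, and what the synthetic data can and cannot show.

## Synthetic cohort

No imaging data accompanies the reference cohort, so the generator emulates
its statistical structure rather than its pixels.

**Demographics.** Patients are drawn from a truncated-normal model: female
fraction 0.227; age 57.3 ± 14.3 y on [18, 90]; sex-specific BMI
(female 21.2 ± 2.5, male 27.4 ± 5.88 kg/m², truncated to [15, 45]); height
163 ± 6 cm (female) / 176 ± 7 cm (male). Weight follows from BMI and
height, so the three are mutually consistent by construction (the record
validator tolerates 0.5 kg/m² of slack for externally supplied data).

**Tube-current modulation.** Effective mAs is modelled as
`86 * exp(b * (BMI - 21.6))` with `b = ln(165/86)/18.4 ≈ 0.0354`, anchored
to the two reference rows of the packaged cohort table (86 mAs at BMI 21.6
and 165 mAs at BMI 40.0), with multiplicative log-normal noise
(σ = 0.05) representing modulation and positioning variability. The
reference data state only that mAs rises roughly linearly with BMI over the
observed range; the exponential form extrapolates more sensibly at the
extremes and is nearly linear in between.

**CTDIvol and DLP.** CTDIvol = 0.0713 mGy/mAs × effective mAs at 120 kV
(least-squares through the origin on the packaged table). The table's own
CTDIvol/mAs ratio is *not* constant (5.8/86 vs 17.36/165); the scanner's
internal normalization is unknown, so a single constant is used and the
residual (SD 1.28 mGy) is accepted as emulator error. DLP = CTDIvol × scan
length, with scan length 0.64 × height (head to mid-femur, fit from
DLP/CTDIvol against the height implied by weight and BMI).

**Air kerma.** The free-in-air kerma at the isocenter is 18.3 mGy at the
reference technique and scales linearly with effective mAs (kerma is
proportional to tube output at fixed kV); the reference technique is taken
as the cohort-mean 112.6 mAs.

**Phantoms.** Stylized geometry: a body ellipse (lateral half-axis
`3.6 * sqrt(BMI)` cm, AP 0.72 of that) with head, neck and thigh sections,
and 27 organ classes as ellipsoids, tubes and shells at anatomically
plausible stations. Hollow organs (stomach, colon, small intestine,
bladder, gall bladder) are labelled on wall voxels only. Organ linear
dimensions scale with `(BMI/26)^(1/3)`; per-seed jitter (±5 % size, small
center offsets, ±10 % HU) varies geometry without changing the class
inventory. HU values are nominal tissue values (lung ≈ −700, soft tissue
30–95, cortical bone 1100, marrow 140) with contrast-enhanced kidneys and
thyroid set high (180/200 HU) so the radiodensity-driven dose enhancement
seen in contrast-enhanced scans is reproducible. Breast/uterus/ovaries
appear only in female phantoms, prostate/testes only in male ones; any
organ can be omitted to emulate aplasia or resection. On coarse grids an
organ whose analytic shape captures no voxel center is repaired to its
center voxel (stealing only from background or from organs that keep other
voxels); if even that fails, phantom construction raises an explicit
resolution error. The minimum supported resolution is 16 voxels per axis.

What the generator does **not** emulate: real anatomy (organ shapes,
postural variation), beam-hardening and reconstruction artifacts, metal
implants, and the scanner's true modulation law. Tests that pass on this
cohort therefore validate the *pipeline arithmetic and its statistical
structure* (dose aggregation, weighting, risk conversion, BMI–DLP
coupling, the sign pattern of the conventional method's bias), not
patient-level dosimetric accuracy on clinical images.

## Monte Carlo transport

A deliberately simple, verifiable model standing in for a commercial dose
engine whose algorithms are not public.

* **Physics**: photons only; photoelectric absorption and incoherent
  (Klein–Nishina) scatter; kerma approximation (energy deposited at the
  interaction site, no electron transport); no coherent scatter, bowtie
  filter or heel effect. These choices keep the model checkable against
  closed forms.
* **Beam**: monoenergetic 64 keV effective energy standing in for a
  120 kVp spectrum (keeps the analytic oracle exact); an optional 3-bin
  spectrum (45/64/90 keV, weights 0.25/0.5/0.25) is provided.
* **Cross-sections**: NIST mass attenuation tables for water and cortical
  bone and mass energy-absorption for air at 10–150 keV, interpolated
  log-log. The Compton component uses the analytic Klein–Nishina total
  cross-section with electron densities 3.343 × 10²³ /g (water-like) and
  3.192 × 10²³ /g (bone); the photoelectric component is the remainder of
  the total attenuation (clamped at zero).
* **HU model**: below HU 100 a voxel is water with density `1 + HU/1000`;
  above, density and composition ramp linearly to cortical bone at HU 1800
  and 1.92 g/cm³. `mu(-1000) = 0` and `mu(0) = mu_water` hold exactly.
* **Source**: point source on a helix of radius 60 cm; table feed = pitch ×
  collimation (19.2 mm); source z uniform over the scan range; photon
  targets uniform over a fan rectangle at the isocenter plane wide enough
  to cover the phantom. Overranging is not modelled: the intended use is a
  single spiral covering the whole imaged anatomy, where it is negligible.
* **Tracking**: Woodcock (delta) tracking against an energy-dependent
  majorant; Compton scattering angles by Kahn's rejection method; photons
  below 10 keV (the table floor) deposit locally.
* **Normalization**: relative dose 1 equals the free-in-air air kerma at
  the isocenter. For a helical source with uniform z coverage the planar
  photon fluence at the isocenter is `N / (2 w Z)` (fan half-width `w`,
  scan range `Z`), so the reference is `sum(E * mu_en_air(E)) / (2 w Z)`.
  Multiplying the relative map by the scanner's air kerma (mGy) yields
  absorbed dose.
* **Uncertainty**: batch method over 10 batches; per-voxel relative
  standard error of the batch mean.
* **Verification**: a homogeneous water cylinder with rotational symmetry
  admits a closed-form primary-only dose: the angular average of
  `exp(-mu * pathlength)` with the inverse-square fluence factor, times
  `(mu/rho)_water / (mu_en/rho)_air`. The transport in absorption-only
  mode matches this oracle within Monte Carlo error, and the RMS deviation
  over a central region contracts as `1/sqrt(n_histories)` across
  10⁴–10⁶ histories. A scatter-transport run can only add deposition
  relative to a run that deposits Compton recoil but discards the
  scattered photon (`follow_scatter=False`).

## Organ dosimetry

Absorbed organ dose is the arithmetic mean of the absorbed-dose grid over
the organ's labelled voxels. Equivalent dose applies `W_R = 1` (photons);
effective organ dose applies the ICRP-103 tissue weighting factor. The
whole-body `ED_MC` is the sum of effective organ doses over organs
*present* in the label map: a missing organ (aplasia, resection, sex)
contributes nothing and is reported as absent — requesting it raises an
explicit error rather than returning zero, because absence is a meaningful
anatomical state.

Conventions follow the reference organ table rather than the strict
ICRP-103 formalism where the two differ:

* each of the 13 remainder tissues carries its own `W_T = 0.0092` instead
  of a collective remainder term, and thymus is not in the vocabulary;
* testes and ovaries are both subsumed under one "gonads" entry,
  `W_T = 0.08`;
* `W_T` is sex- and age-averaged (a stated limitation of the formalism).

Organ contributions `C = ED_organ / ED_MC` sum to 1 to 1e-9 by
construction and are undefined (explicit error) when `ED_MC = 0`. Report
output rounds doses to 1 decimal and contributions to 3; JSON output keeps
full precision.

## Conventional dose and method comparison

`ED_DLP = DLP × k_body` with `k_body = 0.015 mSv/(mGy cm)`;
`k_MC = ED_MC / DLP`; deviations are `100 (alt - ref)/ref` percent. The
count of patients with `k_MC` within ±10 % of `k_body` uses the closed
interval [0.0135, 0.0165].

**Report rounding.** All arithmetic is double precision; rounding is a
reporting-layer concern. The convention is round-half-away-from-zero with
one guard digit (quantize at `nd+1` decimals, then at `nd`). The guard
digit matches the rounding chain of the packaged reference table, whose
derived cells were evidently produced from values carried at higher
intermediate precision (e.g. 783 × 0.015 = 11.745 printed as 11.8). Two
derived cells of the packaged table (and one ERR cell) are not
reproducible from their own printed inputs under any rounding and are
traceable to unrounded source values; the acceptance tests pin these down
explicitly rather than loosening the comparison for all rows. The printed
`k_MC` of one row (0.001 where the quotient gives 0.009) is treated as a
typesetting error and excluded from exact-cell assertions.

## Risk model

The packaged coefficient table holds BEIR VII cancer-mortality LAR
coefficients (per 100,000 per 100 mGy) on a 20–80 y decennial anchor grid,
by sex and site. Ages outside the grid are clamped to the nearest anchor
with a warning (policy switchable to an error). LAR is piecewise-linear in
age (exact at anchors, continuous in between) and exactly linear in dose;
doses are accepted in mSv, numerically equal to mGy for photons.

Two genuinely open design points, and how they were resolved:

* **Coefficient variant for the whole body.** Reconstructing the reference
  cohort's printed LAR column constrains the choice: the all-solid-cancer
  mortality table reproduces every male row within ±1 per 100,000, while
  adding leukemia overshoots all of them by ~+8. The default is therefore
  the all-solid mortality table (site `all_solid`), switchable per call.
  The female rows sit ~10 % below any BEIR VII variant; the residual is
  documented rather than fitted away, and the acceptance check counts rows
  within ±2 per 100,000 (18 of 22) instead of asserting exact equality.
* **Dose quantity per estimate.** The whole-body estimate uses `ED_MC`;
  per-site estimates use the organ's *equivalent* dose by default (the
  magnitudes of the printed per-site risks are only consistent with
  equivalent, not effective, organ dose). Both choices are switchable
  (`whole_body_dose=`, `dose_quantity=`).

Organs map to BEIR VII sites where one exists (colon, lung, stomach,
breast, liver, bladder, prostate, uterus, ovary for female gonads,
leukemia for red bone marrow); unmapped organs yield no per-site estimate,
mirroring the blank cells of the reference table. ERR = LAR / baseline
(17,500 ♀ / 22,100 ♂ per 100,000), reported as a 2-decimal percentage; LAR
reports round to whole persons per 100,000.

## Cohort statistics

Mean ± sample SD (n−1), min/max/range; Bland-Altman mean difference with
1.96-SD limits of agreement; tie-corrected Spearman correlation (average
ranks; two-sided p by the t-approximation, reported descriptively); BMI
bins <20, 20–25, >25, >30 (nested) and age bins <40, 40–55, 55–70, >70.
Matched pairs are user-specified by patient id — the reference pairs were
selected manually, so no automatic matching is attempted.

## Problem sizes

The test and acceptance runs use sizes chosen to make Monte Carlo error
negligible relative to the asserted tolerances while staying lightweight:
the water-cylinder benchmark at 33³ voxels with 10⁴–10⁶ histories, and the
end-to-end synthetic cohort at 20 patients, 64³ voxels and 2 × 10⁴
histories per patient (per-organ dose SE of a few percent, well below the
between-patient spread the assertions concern).

## Known limitations

* The transport is validated against closed forms, not against a clinical
  dose engine; absolute synthetic `ED_MC` values are plausible (≈ 11–12 mSv
  at the cohort's technique) but carry the stylized-anatomy approximation.
* One effective energy ignores spectral hardening; the 3-bin option only
  coarsely probes spectral sensitivity.
* The per-organ remainder weighting and the gonads convention follow the
  reference tables, not ICRP-103 verbatim; swap `WeightingTables` for
  strict ICRP work.
* BEIR VII subjective confidence intervals, cancer incidence (vs
  mortality) and competing-risk life tables are out of scope.
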