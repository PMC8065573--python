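# Methods

## The locked-calibration model

The central quantity is the relative peak area (RPA): the integrated area
of a target's quantifier ion divided by the area of the response internal
standard IS1 (d10-phenanthrene, quantifier m/z 188, 53.1 µmol/L in the
derivatized vial). Each library entry carries a line

    RPA = slope · C + intercept,   C in µmol/L (vial)

fitted once by unweighted ordinary least squares over the calibration
levels 0, 5, 50, 100, 200 µmol/L (glucose additionally 500/1000/1500 to
cover plasma). Quantification inverts this line. The model's validity rests
on two instrument-side assumptions that the toolkit emulates rather than
controls:

1. **Fixed relative sensitivity.** Target tuning (DFTPP: relative
   abundances 100/55/2 % at m/z 69/219/502) pins the sensitivity *ratios*
   across the mass range, so a global sensitivity factor multiplies every
   area equally and cancels in the RPA. The pipeline is exactly invariant
   to scaling all raw intensities by k > 0; this is asserted by tests.
2. **Locked retention times.** Every run is anchored on
   d27-TMS-myristic acid at reference RT 16.727 min. Because a single
   anchor determines one degree of freedom, the default correction is a
   constant offset (measured → reference); a proportional model is
   available for method translation. The correction is applied to detected
   peak RTs, never by resampling scans. Note the vial IS1 concentration:
   10 µg/mL at 188.29 g/mol is 53.1 µmol/L (some method sheets print the
   unit inconsistently; the arithmetically consistent µmol/L value is used).

All intercepts in the packaged library are negative, so a blank inverts
below zero; negative concentrations are clamped to 0 and flagged
(`negative_clamped`). Values below the entry's LOQ or above its highest
calibration level are reported but flagged (`below_loq`,
`above_uloq`/`extrapolated`).

## Identification

A target is *identified* when three orthogonal checks pass:

- **RT window** — a deconvolved component carrying the quantifier m/z lies
  within ±0.1 min of the locked RT (10× the library's reported RT SD of
  ±0.01 min; deliberately forgiving, since the next two checks
  discriminate).
- **Qualifier ratios** — each qualifier's area ratio to the quantifier must
  fall within ±20 % (relative) of the library ratio, a conventional
  targeted-screening tolerance.
- **Spectral similarity** — a cosine between the component spectrum and the
  library spectrum with weights intensity × m/z² (the classic
  high-mass-emphasizing weighting), threshold 0.7.

The similarity is computed in **reverse-search mode**: only m/z present in
the library spectrum enter the comparison. This matters because several
library targets co-elute exactly (three entries share RT 16.55 min, two
pairs share an RT to the 0.01 min print precision); the deconvolution step
groups their fragments into one component, and a forward cosine against the
mixture spectrum would penalize every member (three comparable compounds
score ≈ 1/√3 each). With disjoint ion sets — which the library's
quantifier/qualifier selections provide — reverse matching scores each
co-eluting target on its own fragments. Statuses: `identified`,
`failed_qualifier` (RT hit, ratio out), `rt_only` (RT and ratios pass,
similarity below threshold), `not_found`.

## Peak processing

Runs are held on a contiguous nominal-mass grid (default m/z 50–650;
unit-resolution quadrupole data), with profile/centroid peaks binned to the
nearest integer (ties round half up) — binning conserves total ion current
exactly. Peaks in an EIC are local maxima of a 5-scan moving-average
smoothed trace exceeding baseline + 3 × noise; the baseline is the trace
median, so detection is invariant to a constant offset. Integration bounds
sit at the nearest flanking descent stops of the smoothed trace; windows
that touch across a valley shallower than half the smaller maximum are
merged (noise can split one apex into a double maximum). The apex is
refined by three-point parabolic interpolation and the area is the
trapezoid above a straight baseline between the bounds, in counts·s.

Noise is 1.4826 × MAD of peak-free residuals around a 21-scan running
median — robust to residual peaks — and S/N = height/noise. Vendor software
defines S/N differently (often peak-to-peak/5), so users comparing LOQs
against vendor values must recalibrate thresholds; the LOQ *rule* (lowest
calibration level with S/N > 10) is independent of the estimator choice.

Deconvolution is deliberately simplified to apex co-elution grouping:
single-linkage clustering of apex RTs with a 0.01 min tolerance (matching
the library's RT SD), each m/z contributing its peak nearest the
height-weighted consensus apex. Model-peak least-squares deconvolution is
out of scope; for targeted quantification against a locked library,
grouping is sufficient and fully testable.

## QC procedures

- **Calibration averaging** across replicate batches (3 replicates × 3 days
  = 9 curve sets by default) is the arithmetic mean of slopes, intercepts
  and R² — the batch curves remain first-class records for RSD analysis. A
  pooled refit is available as an option; on noiseless data both agree.
- **Slope stability**: intra-day RSD (sd/mean of slopes within a day,
  averaged over days) and inter-day RSD (on day-mean slopes).
- **Tune checks** normalize ion abundances to the base target ion and pass
  when every ion is within ±30 % (relative to its target) — an EPA-625-style
  window; the check is scale-invariant. **Tune stability** reports per-ion
  RSDs of absolute and base-normalized abundances; common-mode drift
  cancels exactly in the relative series, which is precisely why an
  RPA-based locked calibration survives sensitivity drift.
- **Addition-recovery** is 100 × (spiked − unspiked)/added on vial
  concentrations *without* IS2 correction, because the spike enters the
  extract after extraction.

## The simulator

The generator's response model is the library's own locked line: a target
at vial concentration C yields a quantifier area max(0, slope·C +
intercept) × IS1 area, with every other fragment scaled by its spectrum
ratio; a negative modelled response renders no peak. Peaks are Gaussians of
σ = 0.008 min on a 1.3 scans/s grid (the instrument's 781 u/s scan rate
over a 600-bin range), 37.5 min acquisition with a 5.9 min solvent delay.
Extraction efficiency attenuates targets and IS2 alike (both pass through
extraction); IS1 is added at derivatization and is unaffected. Noise is
composable: multiplicative log-normal noise on areas (CV) and additive
Gaussian noise on scans over a constant detector offset. Fixed seeds give
byte-identical output.

For calibration-series simulation the RPA itself is drawn from the line
(unclamped — it is the regression observable, so a noiseless series refits
the generating line exactly, negative blank included). Chromatogram-level
refits have no blank datum (no peak exists at 0 µM), so pipeline-level
curve refitting uses the detected levels only.

Because the generator *is* the calibration model, round-trip tests
demonstrate the correctness and invariances of the processing chain — RT
locking, integration, normalization, inversion — not the physics of
chromatography: no tailing, column bleed, matrix effects, spectral overlap
beyond shared nominal ions, or derivatization kinetics are modelled.
Synthetic spectra (quantifier 100, qualifiers 60/30, five unique filler
fragments per entry, assigned so no two co-eluting targets share a
fragment) stand in for licensed library spectra; real-data performance
depends on the actual spectra and matrix.

## Numerical choices and scales

- Trapezoidal integration on the 1.3 scans/s grid reproduces analytic
  Gaussian areas to ≈ 0.1 % (σ/Δt ≈ 0.62); the end-to-end concentration
  identity is asserted at 2 %, the pipeline slope refit at 1 %.
- OLS is checked against a brute-force normal-equations solve at 1e-10.
- Ties in candidate matching break on smallest RT deviation; the tallest
  peak wins the locking-compound and IS searches.
- Test and acceptance simulations use 15–37.5 min acquisitions and panels
  of 1–52 targets — full-scale single runs, sized so the whole suite runs
  in well under a minute on one CPU.
- The packaged plasma panel stores the printed concentrations in µmol/L
  (the source table's mmol/L unit label is internally inconsistent with
  reference plasma values by three orders of magnitude).

## Known limitations

- Post-hoc RT correction emulates the *effect* of instrument-side RT
  locking; equivalence to flow-adjustment locking is not claimed.
- One anchor cannot correct nonlinear RT distortions; no retention-index
  (multi-anchor) calibration.
- The MAD noise estimator needs ≥ 20 peak-free scans and differs from
  vendor S/N definitions.
- No non-target annotation, isotope-pattern handling, or matrix-effect
  modelling beyond the IS2 scale factor.
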