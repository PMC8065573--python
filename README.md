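# ccldkit

A calibration-curve-locking database (CCLD) toolkit for semi-quantitative
GC/EI-MS metabolomics.

## The problem

Quantitative metabolomics by GC/MS normally requires fresh calibration
curves for every batch, because the absolute detector sensitivity of a mass
spectrometer drifts from day to day. A CCLD removes that burden. It bundles,
per target metabolite, everything needed to identify and quantify it in any
later run acquired under locked instrument conditions:

- a **locked retention time** (the chromatography is anchored so a reference
  compound, d27-TMS-myristic acid, always elutes at 16.727 min),
- an **EI mass spectrum** with a quantifier ion and one or two qualifier
  ions whose area ratios confirm identity,
- a **locked calibration line** fitted once on the *relative peak area*
  (RPA) — the quantifier area divided by the area of an internal standard
  (IS1, d10-phenanthrene, m/z 188, 53.1 µmol/L in the vial).

Under target (DFTPP) tuning the *relative* sensitivity across m/z is held
fixed (targets 100 % / 55 % / 2 % at m/z 69/219/502), so even when absolute
sensitivity drifts by a factor k, both the target and IS1 areas scale by k
and the RPA is unchanged. The locked line

```
RPA = slope · C + intercept          ⇒          C = (RPA − intercept) / slope
```

therefore converts RPAs measured in *any* batch directly to vial
concentrations C (µmol/L) — no per-batch standards. The packaged library
covers 52 central-carbon-metabolism targets (TMS/methoxime derivatives)
with printed slopes, intercepts, R², locked RTs and LOQs; the glucose curve
extends to 1500 µmol/L to span plasma levels. An extraction internal
standard (IS2, adipic acid, m/z 111) optionally rescales plasma results for
sample-prep recovery, and a configurable dilution factor maps vial
concentrations back to the original sample.

The packaged spectra are deterministic synthetic stand-ins (the method's
real EI spectra come from a licensed commercial library); importing real
MSP spectra is supported.

## What's in the package

| module | purpose |
| --- | --- |
| `ccldkit.library` | CCLD format (one-file JSON), validation, MSP and method-sheet import/export, the packaged 52-target library |
| `ccldkit.msdata` | mzML reading onto a nominal-mass grid, EICs, CSV peak tables |
| `ccldkit.peaks` | peak detection/integration, MAD-based noise and S/N, apex-co-elution component grouping |
| `ccldkit.rtlock` | locking-compound search and post-hoc RT correction |
| `ccldkit.quantify` | identification (RT window + qualifier ratios + weighted-cosine match), RPA, calibration inversion, IS2/dilution, recovery |
| `ccldkit.qc` | calibration fitting/averaging, slope RSDs, LOQ rule, DFTPP tune checks |
| `ccldkit.simulate` | ground-truth simulator (runs, calibration series, tune logs) and a minimal mzML writer |
| `ccldkit.cli` | `ccld build / simulate / quantify / qc` |

## Worked example

Simulate a run containing alanine (150 µM), glucose (800 µM) and leucine
(60 µM) with 3 % area noise, then quantify it against the locked library:

```python
import ccldkit as ck
from ccldkit.simulate import SimulationConfig, simulate_run
from ccldkit.quantify import quantify_run

lib = ck.load_packaged_library()
config = SimulationConfig(
    ccld=lib,
    vial_concentrations={"M004": 150.0, "M014": 800.0, "M026": 60.0},
    area_cv=0.03, seed=11,
)
run, truth = simulate_run(config)
report = quantify_run(lib, run)
print(report.to_frame().query("status == 'identified'"))
```

```
entry_id               name     status  similarity      rpa  conc_vial_uM
    M004     Alanine (2TMS) identified    0.999893 2.816879    158.595524
    M014 Glucose-syn (5TMS) identified    0.999637 6.848428    886.747522
    M026     Leucine (2TMS) identified    0.999747 1.490509     62.931528
```

Each identified target reports the spectral match score (1.0 = perfect),
the measured RPA, and the vial concentration obtained by inverting its
locked line — here within the scatter expected from 3 % area noise on a
single injection. The other 49 library targets appear as `not_found`.

The same workflow from the shell:

```sh
ccld simulate lib.json concs.csv run.mzML --seed 11 --area-cv 0.03
ccld quantify lib.json run.mzML report.csv
```

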