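"""Synthetic GC/EI-MS data with known ground truth.

The generating response model is the library's own locked calibration line:
a target at vial concentration C produces a quantifier peak whose area,
relative to the IS1 area, is slope·C + intercept (clamped at zero — a
negative modelled response means the compound is below its blank level and
no peak is rendered). Every other fragment in the entry's spectrum scales
with the quantifier by its relative intensity. Peaks are rendered as
Gaussians (default σ 0.008 min) on the nominal-mass scan grid (default
1.3 scans/s, from the instrument's 781 u/s scan rate over a 600-bin range).
Noise enters in two composable ways: multiplicative log-normal noise on
areas (CV) and additive Gaussian baseline noise on raw scans. RT drift is
an affine map applied to every true RT, locking compound included.

Because the simulator generates from the calibration line itself, a
noiseless simulate→quantify round trip recovers concentrations exactly up
to numerical integration error; this is the intended test surface, not a
physical chromatography model.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import CCLD, TargetEntry
from .msdata import MZ_HI_DEFAULT, MZ_LO_DEFAULT, PeakTable, Run
from .qc import CalibrationBatch, TuneRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_run",
    "simulate_peak_table",
    "simulate_calibration_series",
    "simulate_tune_log",
    "write_mzml",
]

SCAN_RATE_DEFAULT = 1.3       # scans/s
PEAK_SIGMA_DEFAULT = 0.008    # min
ACQ_LENGTH_DEFAULT = 37.5     # min
SOLVENT_DELAY_DEFAULT = 5.9   # min
IS1_AREA_DEFAULT = 1.0e6      # counts·s reference response
LOCK_AREA_FACTOR = 2.0        # locking peak area relative to IS1
IS2_RPA_DEFAULT = 0.5         # IS2/IS1 area ratio at 100% extraction


class SimulationError(Exception):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic acquisition."""

    ccld: CCLD
    vial_concentrations: dict[str, float] = field(default_factory=dict)  # id -> µmol/L
    is1_area: float = IS1_AREA_DEFAULT
    is2_expected_rpa: float = IS2_RPA_DEFAULT
    extraction_efficiency: float = 1.0
    rt_drift_offset: float = 0.0      # min, added to every true RT
    rt_drift_scale: float = 1.0
    area_cv: float = 0.0              # log-normal CV on areas
    baseline_sd: float = 0.0          # counts, additive scan noise
    baseline_level: float = 0.0       # counts, constant detector offset
    peak_sigma: float = PEAK_SIGMA_DEFAULT   # min
    scan_rate: float = SCAN_RATE_DEFAULT     # scans/s
    acquisition_length: float = ACQ_LENGTH_DEFAULT  # min
    solvent_delay: float = SOLVENT_DELAY_DEFAULT    # min
    mz_lo: int = MZ_LO_DEFAULT
    mz_hi: int = MZ_HI_DEFAULT
    include_is: bool = True
    include_lock: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.vial_concentrations.values()):
            raise SimulationError("vial concentrations must be non-negative")
        if not 0 < self.extraction_efficiency <= 1:
            raise SimulationError("extraction efficiency must be in (0, 1]")
        if self.area_cv < 0 or self.baseline_sd < 0:
            raise SimulationError("noise parameters must be non-negative")
        unknown = [eid for eid in self.vial_concentrations
                   if not any(e.id == eid for e in self.ccld.entries)]
        if unknown:
            raise SimulationError(f"vial_concentrations reference unknown entry id(s) {unknown}")

    def drifted(self, rt: float) -> float:
        return rt * self.rt_drift_scale + self.rt_drift_offset


@dataclass
class GroundTruth:
    """True per-compound state behind a simulated acquisition."""

    per_entry: dict[str, dict]  # id -> {conc, apex_rt, quant_area, fragment_areas}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eid, d in self.per_entry.items():
            rows.append(
                {
                    "entry_id": eid,
                    "conc_uM": d.get("conc", float("nan")),
                    "apex_rt_min": d["apex_rt"],
                    "quant_area": d["quant_area"],
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _noisy(area: float, cv: float, rng: np.random.Generator) -> float:
    if cv <= 0:
        return area
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return area * float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _model_peaks(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[tuple[int, float, float]], GroundTruth]:
    """Analytic peak list [(mz, apex_rt, area)] plus ground truth."""
    ccld = config.ccld
    peaks: list[tuple[int, float, float]] = []
    truth: dict[str, dict] = {}

    for eid, conc in sorted(config.vial_concentrations.items()):
        entry = ccld.get(eid)
        # extraction losses hit targets and IS2 alike; IS1 is added at
        # derivatization and is unaffected
        rpa_model = entry.calibration.predict(conc * config.extraction_efficiency)
        quant_area = max(0.0, rpa_model) * config.is1_area
        apex = config.drifted(entry.rt)
        frag_areas: dict[int, float] = {}
        if quant_area > 0:
            for mz, inten in entry.spectrum.peaks:
                area = _noisy(quant_area * inten / 100.0, config.area_cv, rng)
                frag_areas[mz] = area
                peaks.append((mz, apex, area))
        truth[eid] = {
            "conc": conc,
            "apex_rt": apex,
            "quant_area": frag_areas.get(entry.quantifier.mz, 0.0),
            "fragment_areas": frag_areas,
        }

    if config.include_is:
        is1 = ccld.is1
        if is1 is not None:
            a = _noisy(config.is1_area, config.area_cv, rng)
            peaks.append((is1.mz, config.drifted(is1.rt), a))
            truth["IS1"] = {"apex_rt": config.drifted(is1.rt), "quant_area": a,
                            "fragment_areas": {is1.mz: a}}
        is2 = ccld.is2
        if is2 is not None:
            a = _noisy(
                config.is2_expected_rpa * config.is1_area * config.extraction_efficiency,
                config.area_cv, rng,
            )
            peaks.append((is2.mz, config.drifted(is2.rt), a))
            truth["IS2"] = {"apex_rt": config.drifted(is2.rt), "quant_area": a,
                            "fragment_areas": {is2.mz: a}}
    if config.include_lock:
        a = _noisy(LOCK_AREA_FACTOR * config.is1_area, config.area_cv, rng)
        apex = config.drifted(ccld.locking.reference_rt)
        peaks.append((ccld.locking.mz, apex, a))
        truth["LOCK"] = {"apex_rt": apex, "quant_area": a,
                         "fragment_areas": {ccld.locking.mz: a}}
    return peaks, GroundTruth(per_entry=truth)


def simulate_run(config: SimulationConfig) -> tuple[Run, GroundTruth]:
    """Render a full scan map (time × nominal m/z) with Gaussian peaks."""
    rng = np.random.default_rng(config.seed)
    peaks, truth = _model_peaks(config, rng)

    dt = 1.0 / (config.scan_rate * 60.0)  # min between scans
    n_scans = int(round(config.acquisition_length / dt))
    times = (np.arange(n_scans) + 1) * dt
    n_bins = config.mz_hi - config.mz_lo + 1
    intensities = np.zeros((n_scans, n_bins))

    sigma = config.peak_sigma
    sigma_s = sigma * 60.0
    norm = 1.0 / (sigma_s * np.sqrt(2.0 * np.pi))
    for mz, apex, area in peaks:
        j = int(mz) - config.mz_lo
        if not 0 <= j < n_bins:
            continue
        lo = np.searchsorted(times, apex - 6 * sigma)
        hi = np.searchsorted(times, apex + 6 * sigma)
        window = times[lo:hi]
        intensities[lo:hi, j] += area * norm * np.exp(
            -0.5 * ((window - apex) / sigma) ** 2
        )

    if config.baseline_level > 0:
        intensities += config.baseline_level
    if config.baseline_sd > 0:
        intensities += rng.normal(0.0, config.baseline_sd, size=intensities.shape)
        np.clip(intensities, 0.0, None, out=intensities)

    run = Run(
        times=times,
        mz_lo=config.mz_lo,
        intensities=intensities,
        meta={
            "source": "ccldkit.simulate",
            "solvent_delay": config.solvent_delay,
            "acquisition_length": config.acquisition_length,
            "seed": config.seed,
        },
    )
    return run, truth


def simulate_peak_table(config: SimulationConfig) -> tuple[PeakTable, GroundTruth]:
    """The same model emitted as a pre-integrated peak table (no rendering)."""
    rng = np.random.default_rng(config.seed)
    peaks, truth = _model_peaks(config, rng)
    sigma_s = config.peak_sigma * 60.0
    height = 1.0 / (sigma_s * np.sqrt(2.0 * np.pi))
    df = pd.DataFrame(
        {
            "mz": [mz for mz, _, _ in peaks],
            "rt_min": [rt for _, rt, _ in peaks],
            "area": [a for _, _, a in peaks],
            "height": [a * height for _, _, a in peaks],
        }
    )
    return PeakTable(df=df), truth


def simulate_calibration_series(
    entry: TargetEntry,
    levels: list[float] | None = None,
    replicates: int = 3,
    days: int = 3,
    cv: float = 0.0,
    day_effect_cv: float = 0.0,
    seed: int = 0,
) -> list[CalibrationBatch]:
    """Replicate × day calibration batches of RPAs drawn from the entry's line.

    With ``cv = 0`` every batch lies exactly on the generating line
    (including a negative blank-level RPA — the regression observable, not a
    clamped peak). ``day_effect_cv`` adds a common multiplicative day factor.
    """
    if levels is None:
        levels = list(entry.calibration.levels)
    if not levels:
        raise SimulationError("levels must be non-empty")
    rng = np.random.default_rng(seed)
    batches: list[CalibrationBatch] = []
    for d in range(days):
        day_factor = _noisy(1.0, day_effect_cv, rng)
        for r in range(replicates):
            rpas = {
                float(c): [_noisy(1.0, cv, rng) * day_factor * entry.calibration.predict(c)
                           if cv > 0 or day_effect_cv > 0
                           else entry.calibration.predict(c)]
                for c in levels
            }
            batches.append(
                CalibrationBatch(batch_id=f"day{d + 1}_rep{r + 1}", day=f"day{d + 1}", rpas=rpas)
            )
    return batches


def simulate_tune_log(
    days: int,
    targets: dict[int, float] | None = None,
    common_cv: float = 0.0,
    per_ion_cv: float = 0.0,
    base_abundance: float = 2.0e5,
    seed: int = 0,
) -> list[TuneRecord]:
    """A per-day tune log around DFTPP-style targets.

    ``common_cv`` drifts all ions together (cancels in relative abundance);
    ``per_ion_cv`` is independent per-ion noise (does not cancel).
    """
    if days < 1:
        raise SimulationError("days must be >= 1")
    from .library import DEFAULT_TUNE_TARGETS

    targets = dict(targets if targets is not None else DEFAULT_TUNE_TARGETS)
    rng = np.random.default_rng(seed)
    records = []
    for d in range(days):
        common = _noisy(1.0, common_cv, rng)
        abundance = {
            mz: base_abundance * (pct / 100.0) * common * _noisy(1.0, per_ion_cv, rng)
            for mz, pct in sorted(targets.items())
        }
        records.append(TuneRecord(timestamp=f"day{d + 1}", abundance=abundance))
    return records


# ---------------------------------------------------------------------------
# Minimal mzML writer (MS1-only, centroid rows of the nominal grid)
# ---------------------------------------------------------------------------

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a Run as a minimal valid MS1-only mzML document.

    Only non-zero bins are written per scan (centroid style); reading the
    file back through the nominal-mass binning reader reproduces the scan
    map exactly at float64 precision.
    """
    out = []
    out.append('<?xml version="1.0" encoding="utf-8"?>')
    out.append('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">')
    out.append('<cvList count="2">')
    out.append('<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>')
    out.append('<cv id="UO" fullName="UNIT-ONTOLOGY" URI="http://ontologies.berkeleybop.org/uo.obo"/>')
    out.append('</cvList>')
    out.append('<run id="run1">')
    out.append(f'<spectrumList count="{run.times.size}">')
    bins = run.mz_bins.astype(float)
    for i, (t, row) in enumerate(zip(run.times, run.intensities)):
        nz = row > 0
        mzs = bins[nz]
        ints = row[nz]
        mz_b64 = _b64(mzs)
        int_b64 = _b64(ints)
        out.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mzs.size}">'
        )
        out.append('<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
        out.append('<scanList count="1">')
        out.append('<scan>')
        out.append(
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{float(t)!r}" '
            'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
        )
        out.append('</scan>')
        out.append('</scanList>')
        out.append('<binaryDataArrayList count="2">')
        out.append(f'<binaryDataArray encodedLength="{len(mz_b64)}">')
        out.append('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>')
        out.append(f'<binary>{mz_b64}</binary>')
        out.append('</binaryDataArray>')
        out.append(f'<binaryDataArray encodedLength="{len(int_b64)}">')
        out.append('<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>')
        out.append('<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>')
        out.append(f'<binary>{int_b64}</binary>')
        out.append('</binaryDataArray>')
        out.append('</binaryDataArrayList>')
        out.append('</spectrum>')
    out.append('</spectrumList>')
    out.append('</run>')
    out.append('</mzML>')
    Path(path).write_text("\n".join(out), encoding="utf-8")
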