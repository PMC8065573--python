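"""Target identification and semi-quantification against a CCLD.

Identification combines three orthogonal checks per target: the corrected
component apex must fall inside an RT window around the locked RT; the
observed qualifier/quantifier area ratios must agree with the library
ratios within a relative tolerance; and the component spectrum must match
the library spectrum with an m/z²·intensity-weighted cosine (NIST-style
weighting). The match score is computed in reverse-search mode — restricted
to the m/z present in the library spectrum — so that a target remains
identifiable when it co-elutes with another target inside the deconvolution
tolerance and the composite spectrum is a mixture.

Quantification is the calibration-curve-locking step: the quantifier area
is normalized by the IS1 (d10-phenanthrene, m/z 188) area to a relative
peak area (RPA), which the locked line converts to a vial concentration,
conc = (RPA − intercept)/slope. Because both the target and IS1 respond to
the same detector-sensitivity factor, RPA — and hence the reported
concentration — is invariant to global sensitivity drift, which is what
makes a locked calibration transferable across batches. IS2 (adipic acid,
m/z 111) optionally rescales sample concentrations for extraction
efficiency, and a configurable dilution factor maps vial concentration back
to the original sample.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import CCLD, CalibrationLine, Spectrum, TargetEntry, ccld_to_dict
from .msdata import PeakTable, Run, extract_eic
from .peaks import Component, Peak, build_components, detect_peaks
from .rtlock import (RTCorrection, apply_correction, compute_correction,
                     find_locking_compound, identity_correction)

__all__ = [
    "IdentificationResult",
    "QuantRecord",
    "RecoveryResult",
    "QuantifyError",
    "MissingIS1Error",
    "weighted_cosine",
    "match_target",
    "compute_rpa",
    "apply_calibration",
    "apply_is2_correction",
    "vial_to_sample",
    "dilution_factor_from_steps",
    "mass_to_molar",
    "compute_recovery",
    "QuantConfig",
    "quantify_run",
    "QuantReport",
]


class QuantifyError(Exception):
    pass


class MissingIS1Error(QuantifyError):
    """IS1 is absent or has zero area: no quantification is possible."""


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

@dataclass
class QualifierCheck:
    mz: int
    expected_ratio: float
    observed_ratio: float
    passed: bool


@dataclass
class IdentificationResult:
    entry_id: str
    status: str  # identified | rt_only | failed_qualifier | not_found
    component: Component | None = None
    rt_delta: float = float("nan")
    qualifier_checks: list[QualifierCheck] = field(default_factory=list)
    similarity: float = float("nan")


def weighted_cosine(
    library: Spectrum,
    observed: Spectrum,
    mz_power: float = 2.0,
    reverse: bool = True,
) -> float:
    """Cosine similarity of two nominal-mass spectra with w = I · m/z^p.

    With ``reverse=True`` only the m/z present in the library spectrum are
    compared (reverse-search mode), so extra fragments contributed by a
    co-eluting compound do not penalize the match.
    """
    lib = {mz: inten * mz**mz_power for mz, inten in library.peaks}
    obs = {mz: inten * mz**mz_power for mz, inten in observed.peaks}
    if reverse:
        obs = {mz: v for mz, v in obs.items() if mz in lib}
    num = sum(w * obs.get(mz, 0.0) for mz, w in lib.items())
    na = np.sqrt(sum(w * w for w in lib.values()))
    nb = np.sqrt(sum(w * w for w in obs.values()))
    if na == 0 or nb == 0:
        return 0.0
    return float(num / (na * nb))


def match_target(
    entry: TargetEntry,
    components: list[Component],
    rt_tol: float = 0.1,
    q_tol: float = 0.2,
    similarity_threshold: float = 0.7,
) -> IdentificationResult:
    """Match one library entry against deconvolved components.

    Candidates are components carrying the quantifier m/z within
    ``rt_tol`` of the locked RT; the candidate with the highest spectral
    similarity wins (ties broken by smallest RT deviation). A qualifier
    check passes when observed/expected ∈ [1 − q_tol, 1 + q_tol].
    """
    qmz = entry.quantifier.mz
    candidates = [
        c
        for c in components
        if qmz in c.fragment_peaks and abs(c.apex_rt - entry.rt) <= rt_tol
    ]
    if not candidates:
        return IdentificationResult(entry_id=entry.id, status="not_found")

    scored = [
        (weighted_cosine(entry.spectrum, c.composite_spectrum), -abs(c.apex_rt - entry.rt), c)
        for c in candidates
    ]
    sim, _, comp = max(scored, key=lambda s: (s[0], s[1]))
    rt_delta = comp.apex_rt - entry.rt

    checks: list[QualifierCheck] = []
    quant_area = comp.area(qmz)
    for q in entry.qualifiers:
        if q.expected_ratio is None:
            continue
        observed = comp.area(q.mz) / quant_area if quant_area > 0 else 0.0
        rel = observed / q.expected_ratio
        checks.append(
            QualifierCheck(
                mz=q.mz,
                expected_ratio=q.expected_ratio,
                observed_ratio=observed,
                passed=bool(1 - q_tol <= rel <= 1 + q_tol),
            )
        )

    if not all(c.passed for c in checks):
        status = "failed_qualifier"
    elif sim < similarity_threshold:
        status = "rt_only"
    else:
        status = "identified"
    return IdentificationResult(
        entry_id=entry.id,
        status=status,
        component=comp,
        rt_delta=rt_delta,
        qualifier_checks=checks,
        similarity=sim,
    )


# ---------------------------------------------------------------------------
# Semi-quantification
# ---------------------------------------------------------------------------

@dataclass
class QuantRecord:
    entry_id: str
    name: str
    status: str
    rt_obs: float = float("nan")
    rt_delta: float = float("nan")
    similarity: float = float("nan")
    rpa: float = float("nan")
    conc_vial: float = float("nan")     # µmol/L in the derivatized vial
    conc_sample: float = float("nan")   # µmol/L in the original sample
    flags: list[str] = field(default_factory=list)


@dataclass
class RecoveryResult:
    entry_id: str
    recovery_pct: float
    rsd_pct: float = float("nan")


def compute_rpa(quant_area: float, is1_area: float) -> float:
    """Relative peak area: quantifier area / IS1 area."""
    if not is1_area > 0:
        raise MissingIS1Error("IS1 area must be positive; no quantification without IS1")
    return quant_area / is1_area


def apply_calibration(rpa: float, cal: CalibrationLine) -> tuple[float, list[str]]:
    """Invert the locked line: conc_vial = (RPA − intercept)/slope.

    Concentrations below the LOQ or above the ULOQ are still reported but
    flagged; negative inversions are clamped to 0 (all library intercepts
    are negative, so blank-level RPAs invert below zero).
    """
    if not cal.slope > 0:
        raise QuantifyError("calibration slope must be positive")
    conc = (rpa - cal.intercept) / cal.slope
    flags: list[str] = []
    if conc < 0:
        conc = 0.0
        flags.append("negative_clamped")
    if cal.loq is not None and conc < cal.loq:
        flags.append("below_loq")
    if cal.levels and conc > cal.uloq:
        flags.extend(["above_uloq", "extrapolated"])
    return conc, flags


def apply_is2_correction(
    conc: float, is2_observed_rpa: float, is2_expected_rpa: float
) -> float:
    """Rescale a concentration for extraction efficiency via IS2."""
    if not (is2_observed_rpa > 0 and is2_expected_rpa > 0):
        raise QuantifyError("IS2 observed and expected RPAs must be positive")
    return conc * (is2_expected_rpa / is2_observed_rpa)


def vial_to_sample(conc_vial: float, dilution_factor: float) -> float:
    """Back-calculate the original-sample concentration from the vial."""
    if not dilution_factor > 0:
        raise QuantifyError("dilution factor must be positive")
    return conc_vial * dilution_factor


def dilution_factor_from_steps(steps: list[tuple[float, float]]) -> float:
    """Compose a dilution factor from (aliquot volume, total volume) steps.

    Each step carries ``aliquot`` out of ``total`` forward, diluting the
    analyte by total/aliquot; the overall factor is the product.
    """
    factor = 1.0
    for aliquot, total in steps:
        if not (aliquot > 0 and total > 0):
            raise QuantifyError("step volumes must be positive")
        factor *= total / aliquot
    return factor


def mass_to_molar(mass_conc: float, molar_mass: float) -> float:
    """Convert µg/mL to µmol/L (×1000/M)."""
    if not molar_mass > 0:
        raise QuantifyError("molar mass must be positive")
    return mass_conc * 1000.0 / molar_mass


def compute_recovery(
    conc_spiked: float, conc_unspiked: float, conc_added: float
) -> float:
    """Addition-recovery: 100 × (spiked − unspiked)/added (%)."""
    if not conc_added > 0:
        raise QuantifyError("added concentration must be positive")
    return 100.0 * (conc_spiked - conc_unspiked) / conc_added


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class QuantConfig:
    """Thresholds and policies for the quantification pipeline."""

    rt_tol: float = 0.1               # min; identification window
    q_tol: float = 0.2                # relative qualifier-ratio tolerance
    similarity_threshold: float = 0.7
    min_snr: float = 3.0
    smoothing_width: int = 5          # scans
    coelute_tol: float = 0.01         # min; deconvolution grouping
    lock_search_window: float = 0.5   # min
    rt_model: str = "offset"
    dilution_factor: float = 1.0
    is2_expected_rpa: float | None = None  # enables IS2 correction
    apply_rt_locking: bool = True


@dataclass
class QuantReport:
    """One row per target plus a provenance header."""

    records: list[QuantRecord]
    header: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry_id": [r.entry_id for r in self.records],
                "name": [r.name for r in self.records],
                "status": [r.status for r in self.records],
                "rt_obs": [r.rt_obs for r in self.records],
                "rt_delta": [r.rt_delta for r in self.records],
                "similarity": [r.similarity for r in self.records],
                "rpa": [r.rpa for r in self.records],
                "conc_vial_uM": [r.conc_vial for r in self.records],
                "conc_sample_uM": [r.conc_sample for r in self.records],
                "flags": [";".join(r.flags) for r in self.records],
            }
        )

    def write(self, path: str | Path) -> None:
        lines = [f"# {k}: {v}" for k, v in self.header.items()]
        body = self.to_frame().to_csv(index=False)
        Path(path).write_text("\n".join(lines) + "\n" + body, encoding="utf-8")

    def record(self, entry_id: str) -> QuantRecord:
        return next(r for r in self.records if r.entry_id == entry_id)

    def count(self, status: str) -> int:
        return sum(1 for r in self.records if r.status == status)


def library_hash(ccld: CCLD) -> str:
    doc = json.dumps(ccld_to_dict(ccld), sort_keys=True).encode()
    return hashlib.sha256(doc).hexdigest()[:16]


def _detect_run_peaks(run: Run, mzs: set[int], config: QuantConfig) -> dict[int, list[Peak]]:
    peaks_by_mz: dict[int, list[Peak]] = {}
    for mz in sorted(mzs):
        if not run.mz_lo <= mz <= run.mz_hi:
            continue
        eic = extract_eic(run, mz)
        found = detect_peaks(
            eic,
            min_snr=config.min_snr,
            smoothing_width=config.smoothing_width,
            min_rt=run.solvent_delay,
        )
        if found:
            peaks_by_mz[mz] = found
    return peaks_by_mz


def _peaktable_peaks(table: PeakTable) -> dict[int, list[Peak]]:
    peaks_by_mz: dict[int, list[Peak]] = {}
    for _, row in table.df.iterrows():
        p = Peak(
            mz=int(row["mz"]),
            apex_rt=float(row["rt_min"]),
            left_rt=float(row["rt_min"]) - 0.02,
            right_rt=float(row["rt_min"]) + 0.02,
            area=float(row["area"]),
            height=float(row["height"]),
            snr=float("inf"),
        )
        peaks_by_mz.setdefault(p.mz, []).append(p)
    return peaks_by_mz


def _nearest_peak(peaks: list[Peak], rt: float, tol: float) -> Peak | None:
    inside = [p for p in peaks if abs(p.apex_rt - rt) <= tol]
    if not inside:
        return None
    return max(inside, key=lambda p: p.height)


def quantify_run(
    ccld: CCLD,
    data: Run | PeakTable,
    config: QuantConfig | None = None,
) -> QuantReport:
    """Run the full locked-library pipeline on one acquisition.

    Steps: detect fragment peaks on every library m/z → locate the locking
    compound and correct all peak RTs → group co-eluting peaks into
    components → identify each target (RT + qualifiers + similarity) →
    normalize quantifier areas by IS1 → invert the locked calibration →
    optional IS2 and dilution mapping to the sample concentration.
    """
    config = config or QuantConfig()

    mzs: set[int] = {ccld.locking.mz}
    for s in ccld.internal_standards:
        mzs.add(s.mz)
    for e in ccld.entries:
        mzs.update(e.spectrum.mzs)

    if isinstance(data, Run):
        peaks_by_mz = _detect_run_peaks(data, mzs, config)
    else:
        peaks_by_mz = _peaktable_peaks(data)

    # RT locking: anchor the locking compound at its reference RT.
    corr = identity_correction()
    if config.apply_rt_locking:
        lock_peaks = peaks_by_mz.get(ccld.locking.mz, [])
        anchor = _nearest_peak(lock_peaks, ccld.locking.reference_rt, config.lock_search_window)
        if isinstance(data, Run) and anchor is None:
            # fall back to a direct EIC search so the error message is uniform
            anchor = find_locking_compound(
                data, ccld.locking, search_window=config.lock_search_window,
                min_snr=config.min_snr,
            )
        if anchor is None:
            from .rtlock import LockingError

            raise LockingError(
                f"locking compound (m/z {ccld.locking.mz}) not found within "
                f"{ccld.locking.reference_rt} ± {config.lock_search_window} min"
            )
        corr = compute_correction(
            anchor.apex_rt, ccld.locking.reference_rt, model=config.rt_model
        )
        for plist in peaks_by_mz.values():
            for p in plist:
                p.apex_rt = apply_correction(p.apex_rt, corr)
                p.left_rt = apply_correction(p.left_rt, corr)
                p.right_rt = apply_correction(p.right_rt, corr)

    components = build_components(peaks_by_mz, coelute_tol=config.coelute_tol)

    # IS1 area (run-level fatal if absent).
    is1 = ccld.is1
    if is1 is None:
        raise MissingIS1Error("library defines no response internal standard")
    is1_peak = _nearest_peak(peaks_by_mz.get(is1.mz, []), is1.rt, config.rt_tol)
    if is1_peak is None or not is1_peak.area > 0:
        raise MissingIS1Error(
            f"IS1 ({is1.name}, m/z {is1.mz}) not found near {is1.rt} min"
        )
    is1_area = is1_peak.area

    # IS2 (optional extraction correction).
    is2 = ccld.is2
    is2_rpa = None
    is2_warn = None
    if config.is2_expected_rpa is not None:
        if is2 is None:
            is2_warn = "is2_missing"
        else:
            is2_peak = _nearest_peak(peaks_by_mz.get(is2.mz, []), is2.rt, config.rt_tol)
            if is2_peak is None:
                is2_warn = "is2_missing"
            else:
                is2_rpa = compute_rpa(is2_peak.area, is1_area)

    records: list[QuantRecord] = []
    for entry in ccld.entries:
        ident = match_target(
            entry,
            components,
            rt_tol=config.rt_tol,
            q_tol=config.q_tol,
            similarity_threshold=config.similarity_threshold,
        )
        rec = QuantRecord(entry_id=entry.id, name=entry.name, status=ident.status)
        if ident.component is not None:
            rec.rt_obs = ident.component.apex_rt
            rec.rt_delta = ident.rt_delta
            rec.similarity = ident.similarity
            if ident.status == "failed_qualifier":
                rec.flags.append("qualifier_fail")
            rpa = compute_rpa(ident.component.area(entry.quantifier.mz), is1_area)
            rec.rpa = rpa
            conc, flags = apply_calibration(rpa, entry.calibration)
            rec.conc_vial = conc
            rec.flags.extend(flags)
            sample_conc = conc
            if is2_rpa is not None and config.is2_expected_rpa is not None:
                sample_conc = apply_is2_correction(
                    sample_conc, is2_rpa, config.is2_expected_rpa
                )
                rec.flags.append("is2_corrected")
            elif is2_warn:
                rec.flags.append(is2_warn)
            rec.conc_sample = vial_to_sample(sample_conc, config.dilution_factor)
        records.append(rec)

    header = {
        "library_hash": library_hash(ccld),
        "rt_model": corr.model,
        "rt_offset_min": corr.offset,
        "rt_scale": corr.scale,
        "anchor_measured_min": corr.anchor_measured,
        "anchor_reference_min": corr.anchor_reference,
        "is1_area": is1_area,
        "is2_observed_rpa": is2_rpa if is2_rpa is not None else "",
        "dilution_factor": config.dilution_factor,
        "rt_tol_min": config.rt_tol,
        "q_tol": config.q_tol,
        "similarity_threshold": config.similarity_threshold,
    }
    return QuantReport(records=records, header=header)


def recovery_table(
    spiked: QuantReport,
    unspiked: QuantReport,
    added_uM: float,
) -> list[RecoveryResult]:
    """Addition-recovery per target from a spiked/unspiked report pair.

    Recovery is computed on IS1-normalized vial concentrations (the spike
    is added to the extract after extraction, so IS2 correction does not
    apply) and only where both quantifications succeeded.
    """
    out: list[RecoveryResult] = []
    unspiked_by_id = {r.entry_id: r for r in unspiked.records}
    for rs in spiked.records:
        ru = unspiked_by_id.get(rs.entry_id)
        if ru is None:
            continue
        if rs.status != "identified" or ru.status not in ("identified", "not_found"):
            continue
        base = ru.conc_vial if ru.status == "identified" else 0.0
        out.append(
            RecoveryResult(
                entry_id=rs.entry_id,
                recovery_pct=compute_recovery(rs.conc_vial, base, added_uM),
            )
        )
    return out
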