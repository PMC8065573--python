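"""Calibration-curve-locking database (CCLD): types, validation and I/O.

A CCLD bundles, for each target metabolite, the locked retention time, the
EI mass spectrum, the quantifier/qualifier ion scheme and a pre-established
calibration line (RPA per µmol/L), together with the internal-standard and
retention-time-locking compound definitions. The native on-disk format is a
single human-readable JSON document so that a whole locked method travels as
one file. MSP (NIST text format) import/export and tabular (CSV) import are
provided for interoperability with spectral libraries and method sheets.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IonSpec",
    "Spectrum",
    "CalibrationLine",
    "TargetEntry",
    "InternalStandardSpec",
    "LockingCompoundSpec",
    "CCLD",
    "CCLDError",
    "SchemaError",
    "load_ccld",
    "save_ccld",
    "import_target_table",
    "export_msp",
    "parse_msp",
    "write_msp",
    "load_packaged_library",
    "packaged_table_path",
    "packaged_plasma_panel",
    "synthesize_spectrum",
    "DEFAULT_LEVELS",
    "DEFAULT_TUNE_TARGETS",
]

SCHEMA_VERSION = "1.0"

#: Calibration levels of the standard series (µmol/L); glucose extends this
#: with 500/1000/1500 to cover the plasma concentration range.
DEFAULT_LEVELS = (0.0, 5.0, 50.0, 100.0, 200.0)

#: DFTPP target relative abundances (%) that fix relative MS sensitivity.
DEFAULT_TUNE_TARGETS = {69: 100.0, 219: 55.0, 502: 2.0}

#: IS1 vial concentration: 10 µg/mL d10-phenanthrene / 188.29 g/mol.
IS1_CONCENTRATION_UM = 53.1


class CCLDError(Exception):
    """Base error for CCLD parsing and validation."""


class SchemaError(CCLDError):
    """Raised when a document violates the CCLD schema.

    Collects every offending (entry id, field, message) triple so a broken
    library is reported in one pass.
    """

    def __init__(self, violations: Sequence[tuple[str, str, str]]):
        self.violations = list(violations)
        lines = [f"{eid}.{fld}: {msg}" for eid, fld, msg in self.violations]
        super().__init__("CCLD schema violations:\n" + "\n".join(lines))


@dataclass
class IonSpec:
    """A quantifier or qualifier ion at nominal (unit) mass resolution."""

    mz: int
    role: str  # "quantifier" | "qualifier"
    expected_ratio: float | None = None  # qualifier/quantifier area ratio

    def _check(self, eid: str, out: list) -> None:
        if int(self.mz) != self.mz or self.mz < 1:
            out.append((eid, "ions", f"mz must be a positive integer, got {self.mz}"))
        if self.role not in ("quantifier", "qualifier"):
            out.append((eid, "ions", f"unknown ion role {self.role!r}"))
        if self.expected_ratio is not None and not self.expected_ratio > 0:
            out.append((eid, "ions", f"expected_ratio must be > 0, got {self.expected_ratio}"))


@dataclass
class Spectrum:
    """An EI spectrum as (nominal m/z, relative intensity) with base peak 100."""

    peaks: list[tuple[int, float]]

    @property
    def mzs(self) -> list[int]:
        return [mz for mz, _ in self.peaks]

    def intensity_at(self, mz: int) -> float:
        for pmz, inten in self.peaks:
            if pmz == mz:
                return inten
        return 0.0

    @staticmethod
    def from_arrays(mzs: Iterable[float], intensities: Iterable[float]) -> "Spectrum":
        """Build a base-100-normalized spectrum, binning m/z to nearest integer."""
        acc: dict[int, float] = {}
        for mz, inten in zip(mzs, intensities):
            b = int(mz + 0.5)  # round half up, matching the scan binning rule
            acc[b] = acc.get(b, 0.0) + float(inten)
        if not acc:
            raise CCLDError("spectrum has no peaks")
        base = max(acc.values())
        if base <= 0:
            raise CCLDError("spectrum base peak intensity must be positive")
        peaks = sorted((mz, 100.0 * i / base) for mz, i in acc.items() if i > 0)
        return Spectrum(peaks=peaks)

    def _check(self, eid: str, out: list) -> None:
        mzs = self.mzs
        if sorted(set(mzs)) != mzs:
            out.append((eid, "spectrum", "m/z values must be strictly increasing and unique"))
        for mz, inten in self.peaks:
            if not 0 < inten <= 100:
                out.append((eid, "spectrum", f"intensity at m/z {mz} outside (0, 100]: {inten}"))
        if self.peaks and max(i for _, i in self.peaks) != 100.0:
            out.append((eid, "spectrum", "base peak intensity must be exactly 100"))


@dataclass
class CalibrationLine:
    """A locked calibration line: RPA = slope · conc + intercept.

    slope is RPA per µmol/L; levels are the calibration concentrations
    (µmol/L, ascending, blank allowed); loq is the lowest level with S/N > 10
    and uloq the highest calibration level. Concentrations outside
    [loq, uloq] are still reported but flagged by the quantifier.
    """

    slope: float
    intercept: float
    r_squared: float
    levels: list[float] = field(default_factory=lambda: list(DEFAULT_LEVELS))
    loq: float | None = None

    @property
    def uloq(self) -> float:
        return max(self.levels) if self.levels else float("nan")

    def predict(self, conc: float) -> float:
        """Forward-evaluate the line: expected RPA at a vial concentration."""
        return self.slope * conc + self.intercept

    def _check(self, eid: str, out: list) -> None:
        if not self.slope > 0:
            out.append((eid, "calibration", f"slope must be > 0, got {self.slope}"))
        if not 0 <= self.r_squared <= 1:
            out.append((eid, "calibration", f"r_squared outside [0, 1]: {self.r_squared}"))
        if self.levels != sorted(self.levels):
            out.append((eid, "calibration", "levels must be sorted ascending"))
        if any(l < 0 for l in self.levels):
            out.append((eid, "calibration", "levels must be non-negative"))
        if self.loq is not None and self.loq not in self.levels:
            out.append((eid, "calibration", f"loq {self.loq} is not one of the levels"))


@dataclass
class TargetEntry:
    """One CCLD record: metabolite derivative + RT + ions + spectrum + line."""

    id: str
    name: str
    rt: float
    rt_sd: float
    ions: list[IonSpec]
    spectrum: Spectrum
    calibration: CalibrationLine
    notes: str = ""

    @property
    def quantifier(self) -> IonSpec:
        return next(i for i in self.ions if i.role == "quantifier")

    @property
    def qualifiers(self) -> list[IonSpec]:
        return [i for i in self.ions if i.role == "qualifier"]

    def _check(self, out: list) -> None:
        eid = self.id
        if not self.rt > 0:
            out.append((eid, "rt", f"rt must be > 0, got {self.rt}"))
        nq = sum(1 for i in self.ions if i.role == "quantifier")
        if nq != 1:
            out.append((eid, "ions", f"exactly one quantifier required, found {nq}"))
        for i in self.ions:
            i._check(eid, out)
        if nq == 1:
            qmz = self.quantifier.mz
            for q in self.qualifiers:
                if q.mz == qmz:
                    out.append((eid, "ions", f"qualifier m/z {q.mz} equals the quantifier m/z"))
        self.spectrum._check(eid, out)
        spec_mzs = set(self.spectrum.mzs)
        for i in self.ions:
            if i.mz not in spec_mzs:
                out.append((eid, "spectrum", f"ion m/z {i.mz} missing from the spectrum"))
        self.calibration._check(eid, out)


@dataclass
class InternalStandardSpec:
    """An internal standard: response (IS1) or extraction (IS2)."""

    name: str
    role: str  # "response" | "extraction"
    mz: int
    rt: float
    nominal_concentration: float  # µmol/L in the derivatized vial / spiked
    notes: str = ""

    def _check(self, out: list) -> None:
        if self.role not in ("response", "extraction"):
            out.append((self.name, "role", f"unknown IS role {self.role!r}"))
        if not self.rt > 0:
            out.append((self.name, "rt", f"rt must be > 0, got {self.rt}"))
        if self.mz < 1:
            out.append((self.name, "mz", f"mz must be positive, got {self.mz}"))


@dataclass
class LockingCompoundSpec:
    """The RT-locking compound and its reference elution time."""

    name: str
    reference_rt: float
    mz: int

    def _check(self, out: list) -> None:
        if not self.reference_rt > 0:
            out.append((self.name, "reference_rt", "reference_rt must be > 0"))


@dataclass
class CCLD:
    """A complete calibration-curve-locking database."""

    entries: list[TargetEntry]
    internal_standards: list[InternalStandardSpec]
    locking: LockingCompoundSpec
    tune_targets: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_TUNE_TARGETS))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- lookups ----------------------------------------------------------
    def get(self, entry_id: str) -> TargetEntry:
        try:
            return next(e for e in self.entries if e.id == entry_id)
        except StopIteration:
            raise KeyError(f"no CCLD entry with id {entry_id!r}") from None

    def internal_standard(self, role: str) -> InternalStandardSpec | None:
        for s in self.internal_standards:
            if s.role == role:
                return s
        return None

    @property
    def is1(self) -> InternalStandardSpec | None:
        return self.internal_standard("response")

    @property
    def is2(self) -> InternalStandardSpec | None:
        return self.internal_standard("extraction")

    def subset(self, entry_ids: Sequence[str]) -> "CCLD":
        """A new CCLD restricted to the given entry ids (ISs/locking kept)."""
        return CCLD(
            entries=[self.get(eid) for eid in entry_ids],
            internal_standards=list(self.internal_standards),
            locking=self.locking,
            tune_targets=dict(self.tune_targets),
            metadata=dict(self.metadata),
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        out: list[tuple[str, str, str]] = []
        ids = [e.id for e in self.entries]
        for dup in sorted({i for i in ids if ids.count(i) > 1}):
            out.append((dup, "id", "duplicate entry id"))
        names = [e.name for e in self.entries]
        for dup in sorted({n for n in names if names.count(n) > 1}):
            out.append((dup, "name", "duplicate entry name"))
        for e in self.entries:
            e._check(out)
        roles = [s.role for s in self.internal_standards]
        for role in ("response", "extraction"):
            if roles.count(role) > 1:
                out.append(("internal_standards", role, f"more than one {role} IS"))
        for s in self.internal_standards:
            s._check(out)
        self.locking._check(out)
        if self.tune_targets and max(self.tune_targets.values()) != 100.0:
            out.append(("tune_targets", "base", "tune targets must contain the base ion at 100%"))
        if out:
            raise SchemaError(out)


# ---------------------------------------------------------------------------
# Native JSON document
# ---------------------------------------------------------------------------

def _entry_to_dict(e: TargetEntry) -> dict:
    return {
        "id": e.id,
        "name": e.name,
        "rt": e.rt,
        "rt_sd": e.rt_sd,
        "ions": [
            {"mz": i.mz, "role": i.role, "expected_ratio": i.expected_ratio}
            for i in e.ions
        ],
        "spectrum": [[mz, inten] for mz, inten in e.spectrum.peaks],
        "calibration": {
            "slope": e.calibration.slope,
            "intercept": e.calibration.intercept,
            "r_squared": e.calibration.r_squared,
            "levels": e.calibration.levels,
            "loq": e.calibration.loq,
        },
        "notes": e.notes,
    }


def _entry_from_dict(d: Mapping) -> TargetEntry:
    cal = d["calibration"]
    return TargetEntry(
        id=d["id"],
        name=d["name"],
        rt=d["rt"],
        rt_sd=d["rt_sd"],
        ions=[
            IonSpec(mz=i["mz"], role=i["role"], expected_ratio=i.get("expected_ratio"))
            for i in d["ions"]
        ],
        spectrum=Spectrum(peaks=[(int(mz), float(i)) for mz, i in d["spectrum"]]),
        calibration=CalibrationLine(
            slope=cal["slope"],
            intercept=cal["intercept"],
            r_squared=cal["r_squared"],
            levels=list(cal["levels"]),
            loq=cal.get("loq"),
        ),
        notes=d.get("notes", ""),
    )


def ccld_to_dict(ccld: CCLD) -> dict:
    return {
        "format": "ccld",
        "schema_version": SCHEMA_VERSION,
        "metadata": ccld.metadata,
        "locking": {
            "name": ccld.locking.name,
            "reference_rt": ccld.locking.reference_rt,
            "mz": ccld.locking.mz,
        },
        "internal_standards": [
            {
                "name": s.name,
                "role": s.role,
                "mz": s.mz,
                "rt": s.rt,
                "nominal_concentration": s.nominal_concentration,
                "notes": s.notes,
            }
            for s in ccld.internal_standards
        ],
        "tune_targets": {str(mz): pct for mz, pct in ccld.tune_targets.items()},
        "entries": [_entry_to_dict(e) for e in ccld.entries],
    }


def ccld_from_dict(doc: Mapping) -> CCLD:
    if doc.get("format") != "ccld":
        raise CCLDError("not a CCLD document (missing format marker)")
    lock = doc["locking"]
    return CCLD(
        entries=[_entry_from_dict(d) for d in doc["entries"]],
        internal_standards=[
            InternalStandardSpec(
                name=s["name"],
                role=s["role"],
                mz=s["mz"],
                rt=s["rt"],
                nominal_concentration=s["nominal_concentration"],
                notes=s.get("notes", ""),
            )
            for s in doc["internal_standards"]
        ],
        locking=LockingCompoundSpec(
            name=lock["name"], reference_rt=lock["reference_rt"], mz=lock["mz"]
        ),
        tune_targets={int(mz): float(pct) for mz, pct in doc["tune_targets"].items()},
        metadata=dict(doc.get("metadata", {})),
    )


def load_ccld(path: str | Path) -> CCLD:
    """Load and validate a native CCLD JSON document."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CCLDError(f"cannot parse {path}: {exc}") from exc
    return ccld_from_dict(doc)


def save_ccld(ccld: CCLD, path: str | Path) -> None:
    """Write a CCLD as its native JSON document (round-trips exactly)."""
    Path(path).write_text(
        json.dumps(ccld_to_dict(ccld), ensure_ascii=False, indent=1), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# MSP (NIST text) import/export
# ---------------------------------------------------------------------------

def parse_msp(source: str | Path | io.TextIOBase) -> dict[str, Spectrum]:
    """Parse an MSP document into {record name: Spectrum}.

    Uses matchms when given a file path; parses inline text directly.
    Intensities are renormalized to base peak 100 and m/z binned to nominal
    integers.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        from matchms.importing import load_from_msp

        out: dict[str, Spectrum] = {}
        for sp in load_from_msp(str(source), metadata_harmonization=False):
            if sp is None:
                continue
            name = sp.metadata.get("name") or sp.metadata.get("compound_name")
            out[name] = Spectrum.from_arrays(sp.peaks.mz, sp.peaks.intensities)
        return out
    text = source if isinstance(source, str) else source.read()
    return _parse_msp_text(text)


def _parse_msp_text(text: str) -> dict[str, Spectrum]:
    out: dict[str, Spectrum] = {}
    name = None
    mzs: list[float] = []
    ints: list[float] = []

    def flush():
        if name is not None:
            out[name] = Spectrum.from_arrays(mzs, ints)

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        low = line.lower()
        if low.startswith("name:"):
            flush()
            name = line.split(":", 1)[1].strip()
            mzs, ints = [], []
        elif ":" in line and not line[0].isdigit():
            continue  # other metadata fields (MW, Num Peaks, ...)
        else:
            tokens = line.replace(";", " ").split()
            for mz, inten in zip(tokens[0::2], tokens[1::2]):
                mzs.append(float(mz))
                ints.append(float(inten))
    flush()
    return out


def write_msp(spectra: Mapping[str, Spectrum], path: str | Path | None = None) -> str:
    """Serialize spectra as MSP text (Name / Num Peaks / m/z–intensity pairs)."""
    buf = io.StringIO()
    for name, sp in spectra.items():
        buf.write(f"Name: {name}\n")
        buf.write(f"Num Peaks: {len(sp.peaks)}\n")
        for mz, inten in sp.peaks:
            buf.write(f"{mz} {inten:g}\n")
        buf.write("\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def export_msp(ccld: CCLD, path: str | Path | None = None) -> str:
    """Export every target, IS and locking-compound spectrum as MSP text."""
    spectra: dict[str, Spectrum] = {e.name: e.spectrum for e in ccld.entries}
    for s in ccld.internal_standards:
        spectra[s.name] = Spectrum(peaks=[(s.mz, 100.0)])
    spectra[ccld.locking.name] = Spectrum(peaks=[(ccld.locking.mz, 100.0)])
    return write_msp(spectra, path)


# ---------------------------------------------------------------------------
# Tabular (method-sheet) import
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "id", "name", "rt", "rt_sd", "quantifier", "qualifier1", "qualifier2",
    "slope", "intercept", "r_squared",
}


def _default_internal_standards() -> list[InternalStandardSpec]:
    return [
        InternalStandardSpec(
            name="d10-Phenanthrene (IS1)",
            role="response",
            mz=188,
            rt=15.50,
            nominal_concentration=IS1_CONCENTRATION_UM,
            notes=(
                "Response IS; 10 ug/mL in the vial = 53.1 umol/L at "
                "188.29 g/mol. Source method sheets disagree on the unit "
                "(mmol/L vs umol/L); umol/L is the arithmetically "
                "consistent value and is used throughout."
            ),
        ),
        InternalStandardSpec(
            name="Adipic acid (IS2)",
            role="extraction",
            mz=111,
            rt=12.20,
            nominal_concentration=10.0,
            notes="Extraction IS spiked into the sample before extraction.",
        ),
    ]


def _default_locking() -> LockingCompoundSpec:
    return LockingCompoundSpec(
        name="d27-TMS-Myristic acid (lock)", reference_rt=16.727, mz=312
    )


def import_target_table(
    table: str | Path | pd.DataFrame,
    spectra: Mapping[str, Spectrum] | str | Path,
    internal_standards: list[InternalStandardSpec] | None = None,
    locking: LockingCompoundSpec | None = None,
    metadata: dict | None = None,
) -> CCLD:
    """Build a CCLD from a method sheet (CSV/DataFrame) plus MSP spectra.

    The sheet needs columns id, name, rt, rt_sd, quantifier, qualifier1,
    qualifier2, slope, intercept, r_squared, and optionally loq and levels
    (semicolon-separated µmol/L list for extended series). A qualifier value
    of 0 means "no qualifier" and is dropped. Expected qualifier ratios are
    computed from the spectrum as intensity(qualifier)/intensity(quantifier).
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = table.copy()
    missing = _TABLE_COLUMNS - set(df.columns)
    if missing:
        raise CCLDError(f"target table missing columns: {sorted(missing)}")
    if not isinstance(spectra, Mapping):
        spectra = parse_msp(spectra)

    violations: list[tuple[str, str, str]] = []
    entries: list[TargetEntry] = []
    for _, row in df.iterrows():
        eid = str(row["id"])
        name = str(row["name"])
        if name not in spectra:
            violations.append((eid, "spectrum", f"no MSP record named {name!r}"))
            continue
        sp = spectra[name]
        slope = float(row["slope"])
        if not slope > 0:
            violations.append((eid, "slope", f"non-positive slope {slope}"))
            continue
        quant = int(row["quantifier"])
        ions = [IonSpec(mz=quant, role="quantifier")]
        q_int = sp.intensity_at(quant)
        for col in ("qualifier1", "qualifier2"):
            qmz = int(row[col])
            if qmz == 0:
                continue  # 0 encodes "no qualifier"
            ratio = sp.intensity_at(qmz) / q_int if q_int > 0 else None
            ions.append(IonSpec(mz=qmz, role="qualifier", expected_ratio=ratio))
        levels = list(DEFAULT_LEVELS)
        if "levels" in df.columns and isinstance(row.get("levels"), str) and row["levels"].strip():
            levels = sorted(float(x) for x in row["levels"].split(";"))
        loq = None
        if "loq" in df.columns and pd.notna(row.get("loq")):
            loq = float(row["loq"])
        entries.append(
            TargetEntry(
                id=eid,
                name=name,
                rt=float(row["rt"]),
                rt_sd=float(row["rt_sd"]),
                ions=ions,
                spectrum=sp,
                calibration=CalibrationLine(
                    slope=slope,
                    intercept=float(row["intercept"]),
                    r_squared=float(row["r_squared"]),
                    levels=levels,
                    loq=loq,
                ),
            )
        )
    if violations:
        raise SchemaError(violations)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "created": _dt.date.today().isoformat(),
        **(metadata or {}),
    }
    return CCLD(
        entries=entries,
        internal_standards=(
            internal_standards if internal_standards is not None else _default_internal_standards()
        ),
        locking=locking if locking is not None else _default_locking(),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Packaged library (synthetic spectra)
# ---------------------------------------------------------------------------

_FILLER_INTENSITIES = (15.0, 12.0, 10.0, 8.0, 5.0)
_QUALIFIER_INTENSITIES = (60.0, 30.0)


def _assign_fillers(df: pd.DataFrame, reserved: set[int]) -> dict[str, list[int]]:
    """Deterministically assign five unique filler m/z per entry.

    Fillers are drawn from high-mass bins, descending from 650, skipping
    every quantifier/qualifier/IS/locking ion and every filler already
    assigned, so no two co-eluting targets ever share a synthetic fragment.
    """
    pool = [mz for mz in range(650, 299, -1) if mz not in reserved]
    out: dict[str, list[int]] = {}
    k = 0
    for _, row in df.iterrows():
        own = {int(row["quantifier"]), int(row["qualifier1"]), int(row["qualifier2"])}
        fillers: list[int] = []
        while len(fillers) < len(_FILLER_INTENSITIES):
            mz = pool[k]
            k += 1
            if mz not in own:
                fillers.append(mz)
        out[str(row["id"])] = sorted(fillers)
    return out


def synthesize_spectrum(
    quantifier: int, qualifiers: Sequence[int], fillers: Sequence[int]
) -> Spectrum:
    """Synthetic EI spectrum: quantifier at base 100, qualifiers at 60/30,
    filler fragments at fixed minor intensities.

    These spectra are synthetic stand-ins: the method's real EI spectra come
    from a licensed commercial library that cannot be redistributed. They are
    deterministic and carry the quantifier/qualifier structure the pipeline
    needs, which is all the identification logic depends on.
    """
    peaks = {int(quantifier): 100.0}
    for mz, inten in zip(qualifiers, _QUALIFIER_INTENSITIES):
        peaks[int(mz)] = inten
    for mz, inten in zip(fillers, _FILLER_INTENSITIES):
        peaks.setdefault(int(mz), inten)
    return Spectrum(peaks=sorted(peaks.items()))


def packaged_table_path() -> Path:
    """Path of the packaged 52-target method sheet (CSV)."""
    return Path(str(resources.files("ccldkit.data") / "table1.csv"))


def packaged_plasma_panel() -> pd.DataFrame:
    """The 28-metabolite plasma panel with measured and reference
    concentrations (µmol/L in plasma)."""
    return pd.read_csv(str(resources.files("ccldkit.data") / "plasma_panel.csv"))


def packaged_spectra() -> dict[str, Spectrum]:
    """Deterministic synthetic spectra for the packaged 52-target sheet."""
    df = pd.read_csv(packaged_table_path())
    reserved: set[int] = set()
    for col in ("quantifier", "qualifier1", "qualifier2"):
        reserved.update(int(v) for v in df[col] if int(v) > 0)
    reserved.update({188, 111, 312})  # IS1, IS2, locking ions
    fillers = _assign_fillers(df, reserved)
    out: dict[str, Spectrum] = {}
    for _, row in df.iterrows():
        quals = [int(row[c]) for c in ("qualifier1", "qualifier2") if int(row[c]) > 0]
        out[str(row["name"])] = synthesize_spectrum(
            int(row["quantifier"]), quals, fillers[str(row["id"])]
        )
    return out


def load_packaged_library() -> CCLD:
    """The packaged 52-target CCLD (synthetic spectra, printed calibration
    lines, locked RTs)."""
    return import_target_table(
        packaged_table_path(),
        packaged_spectra(),
        metadata={
            "source": "packaged 52-target central-carbon-metabolism method sheet",
            "spectra": "synthetic (quantifier 100, qualifiers 60/30, 5 fillers)",
        },
    )
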