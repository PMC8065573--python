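"""GC/MS run containers and I/O: mzML reading, nominal-mass binning,
extracted ion chromatograms, and pre-integrated peak tables.

Single-quadrupole EI data are unit-resolution, so scans are held on a
contiguous nominal integer m/z grid (default 50–650); profile or centroid
peaks are binned to the nearest integer (ties round half up) with
intensities summed, which conserves the total ion current exactly.
Retention times are decimal minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Run", "EIC", "PeakTable", "MSDataError", "read_mzml", "extract_eic",
           "read_peak_table", "write_peak_table", "PEAK_TABLE_COLUMNS"]

MZ_LO_DEFAULT = 50
MZ_HI_DEFAULT = 650

PEAK_TABLE_COLUMNS = ["mz", "rt_min", "area", "height"]


class MSDataError(Exception):
    pass


@dataclass
class Run:
    """A GC/MS acquisition as a time × nominal-m/z intensity map."""

    times: np.ndarray            # scan times, minutes, strictly increasing
    mz_lo: int                   # first nominal m/z bin
    intensities: np.ndarray      # (n_scans, n_bins) counts
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.shape[0] != self.times.size:
            raise MSDataError("times and intensity map have inconsistent shapes")
        if np.any(np.diff(self.times) <= 0):
            raise MSDataError("scan times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise MSDataError("intensities must be non-negative")

    @property
    def mz_hi(self) -> int:
        return self.mz_lo + self.intensities.shape[1] - 1

    @property
    def mz_bins(self) -> np.ndarray:
        return np.arange(self.mz_lo, self.mz_hi + 1)

    @property
    def solvent_delay(self) -> float:
        return float(self.meta.get("solvent_delay", 0.0))

    def tic(self) -> np.ndarray:
        """Total ion current per scan."""
        return self.intensities.sum(axis=1)


@dataclass
class EIC:
    """Extracted ion chromatogram at one nominal m/z."""

    mz: int
    times: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.size != self.intensity.size:
            raise MSDataError("EIC times and intensity must have the same length")


def extract_eic(run: Run, mz: int) -> EIC:
    """The intensity trace of one nominal m/z bin."""
    if not run.mz_lo <= mz <= run.mz_hi:
        raise MSDataError(
            f"m/z {mz} outside the run's bin range {run.mz_lo}-{run.mz_hi}"
        )
    col = run.intensities[:, int(mz) - run.mz_lo]
    return EIC(mz=int(mz), times=run.times, intensity=col.copy())


def bin_nominal(mzs: np.ndarray, intensities: np.ndarray, mz_lo: int, mz_hi: int) -> np.ndarray:
    """Sum peak intensities into nominal integer bins (ties round half up)."""
    n_bins = mz_hi - mz_lo + 1
    out = np.zeros(n_bins)
    if len(mzs) == 0:
        return out
    idx = np.floor(np.asarray(mzs, dtype=float) + 0.5).astype(int) - mz_lo
    keep = (idx >= 0) & (idx < n_bins)
    np.add.at(out, idx[keep], np.asarray(intensities, dtype=float)[keep])
    return out


_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    accs = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
    node = bda.find("{*}binary")
    raw = base64.b64decode((node.text or "").encode())
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, mz_lo: int = MZ_LO_DEFAULT, mz_hi: int = MZ_HI_DEFAULT) -> Run:
    """Read an mzML file into a nominal-mass Run (MS1 scans only).

    Parses the mzML XML directly (indexed wrapper, 32/64-bit floats and
    zlib compression supported); each spectrum's peaks are summed into
    nearest-integer m/z bins.
    """
    from lxml import etree

    times: list[float] = []
    rows: list[np.ndarray] = []
    meta: dict = {"source": str(path)}
    for _, spec in etree.iterparse(str(path), tag="{*}spectrum"):
        level = 1
        for cv in spec.findall("{*}cvParam"):
            if cv.get("accession") == _ACC_MS_LEVEL:
                level = int(cv.get("value"))
        if level != 1:
            spec.clear()
            continue
        t = None
        for cv in spec.iter("{*}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                t = float(cv.get("value"))
                if cv.get("unitName", "minute").startswith("second"):
                    t /= 60.0
        if t is None:
            spec.clear()
            continue
        mz_arr = int_arr = None
        for bda in spec.iter("{*}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
            if _ACC_MZ_ARRAY in accs:
                mz_arr = _decode_binary_array(bda)
            elif _ACC_INT_ARRAY in accs:
                int_arr = _decode_binary_array(bda)
        if mz_arr is None or int_arr is None:
            spec.clear()
            continue
        times.append(t)
        rows.append(bin_nominal(mz_arr, int_arr, mz_lo, mz_hi))
        spec.clear()
    if not times:
        raise MSDataError(f"no MS1 scans found in {path}")
    order = np.argsort(times)
    run = Run(
        times=np.asarray(times)[order],
        mz_lo=mz_lo,
        intensities=np.vstack([rows[i] for i in order]),
        meta=meta,
    )
    return run


# ---------------------------------------------------------------------------
# Pre-integrated peak tables
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Pre-integrated peaks: rows of (mz, rt_min, area, height[, label]).

    Quantification can run directly on a PeakTable (e.g. exported from a
    vendor integrator), bypassing raw-scan peak processing. area is in
    counts·s, height in counts, rt in minutes.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PEAK_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise MSDataError(f"peak table missing columns: {missing}")
        for col in PEAK_TABLE_COLUMNS:
            bad = self.df.index[~np.isfinite(pd.to_numeric(self.df[col], errors="coerce"))]
            if len(bad):
                raise MSDataError(
                    f"non-numeric value in column {col!r} at row(s) {list(bad)}"
                )
        for col, msg in (("area", "area must be > 0"), ("height", "height must be > 0")):
            bad = self.df.index[self.df[col] <= 0].tolist()
            if bad:
                raise MSDataError(f"{msg} (row(s) {bad})")

    def __len__(self) -> int:
        return len(self.df)


def read_peak_table(path: str | Path) -> PeakTable:
    """Read the CSV peak-table dialect (header mz,rt_min,area,height[,label])."""
    df = pd.read_csv(path)
    return PeakTable(df=df)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
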