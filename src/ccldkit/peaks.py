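"""Chromatographic peak detection, integration, noise/S/N estimation, and
apex-co-elution component grouping (simplified deconvolution).

Peaks are local maxima of a moving-average-smoothed trace that rise more
than ``min_snr`` noise units above the local baseline; integration bounds
sit at the nearest flanking local minima, the apex is refined by three-point
parabolic interpolation, and the area is the trapezoid above a straight
baseline drawn between the bounds (counts·s).

Noise is the scaled median absolute deviation (×1.4826, consistent for a
Gaussian) of peak-free residuals around a running median — robust to any
residual peaks left in the trace. S/N = peak height / noise. Deconvolution
is deliberately simple: fragment peaks whose apexes co-elute within a
tolerance are grouped into one component by single linkage, which is
sufficient for targeted quantification against a locked library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import argrelmax

from .library import Spectrum
from .msdata import EIC, PeakTable

__all__ = [
    "Peak",
    "Component",
    "PeakProcError",
    "detect_peaks",
    "estimate_noise",
    "build_components",
    "peaks_to_table",
]


class PeakProcError(Exception):
    pass


@dataclass
class Peak:
    mz: int
    apex_rt: float          # min
    left_rt: float          # min
    right_rt: float         # min
    area: float             # counts·s
    height: float           # counts, above local baseline
    snr: float              # height / noise; inf when noise is zero


@dataclass
class Component:
    """A deconvolved feature: co-eluting fragment peaks + composite spectrum."""

    apex_rt: float
    fragment_peaks: dict[int, Peak]
    composite_spectrum: Spectrum = field(init=False)

    def __post_init__(self):
        areas = {mz: p.area for mz, p in self.fragment_peaks.items()}
        self.composite_spectrum = Spectrum.from_arrays(
            list(areas.keys()), list(areas.values())
        )

    def area(self, mz: int) -> float:
        p = self.fragment_peaks.get(mz)
        return p.area if p is not None else 0.0


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine apex position/height with a parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid apex
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
    apex_t = float(t[i] + delta * dt)
    apex_y = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_t, apex_y


def estimate_noise(
    eic: EIC,
    exclusion: list[tuple[float, float]] | None = None,
    window: int = 21,
    min_free_scans: int = 20,
) -> float:
    """Robust noise level of a trace (counts).

    MAD × 1.4826 of the residuals around a running median, computed on scans
    outside the given peak-bound exclusion windows.
    """
    x = eic.intensity
    free = np.ones(x.size, dtype=bool)
    for lo, hi in exclusion or []:
        free &= ~((eic.times >= lo) & (eic.times <= hi))
    if free.sum() < min_free_scans:
        raise PeakProcError(
            f"only {int(free.sum())} peak-free scans; need at least {min_free_scans}"
        )
    resid = (x - median_filter(x, size=window, mode="nearest"))[free]
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def _bounds(y: np.ndarray, i: int) -> tuple[int, int]:
    """Nearest flanking local minima (descent stops) around apex index i."""
    left = i
    while left > 0 and y[left - 1] < y[left]:
        left -= 1
    right = i
    while right < len(y) - 1 and y[right + 1] < y[right]:
        right += 1
    return left, right


def detect_peaks(
    eic: EIC,
    min_snr: float = 3.0,
    smoothing_width: int = 5,
    noise: float | None = None,
    min_rt: float | None = None,
) -> list[Peak]:
    """Detect and integrate peaks in one EIC.

    ``noise`` may be supplied (e.g. from a prior pass); otherwise it is
    estimated from the trace itself. ``min_rt`` excludes the solvent-delay
    region from detection. Returns an empty list when nothing rises above
    baseline + min_snr × noise.
    """
    t, x = eic.times, eic.intensity
    if x.size < 5:
        raise PeakProcError("need at least 5 scans for peak detection")
    smoothing_width = max(1, int(smoothing_width))
    smooth = uniform_filter1d(x, size=smoothing_width, mode="nearest")
    if noise is None:
        resid = x - median_filter(x, size=21, mode="nearest")
        noise = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    baseline = float(np.median(smooth))
    threshold = baseline + min_snr * noise

    (maxima,) = argrelmax(smooth, order=1)
    candidates: list[tuple[int, int, int]] = []
    for im in maxima:
        if smooth[im] <= threshold or smooth[im] <= 0:
            continue
        lo, hi = _bounds(smooth, im)
        candidates.append((im, lo, hi))

    # Noise can split one apex into two adjacent smoothed maxima separated
    # by a shallow valley; merge windows that touch across a valley deeper
    # than half the smaller maximum (baseline-relative), which leaves truly
    # resolved peaks (valley near baseline) separate.
    merged: list[tuple[int, int, int]] = []
    for im, lo, hi in candidates:
        if merged:
            pm, plo, phi = merged[-1]
            valley = smooth[phi:lo + 1].min() if lo >= phi else smooth[lo]
            shallow = (valley - baseline) > 0.5 * (
                min(smooth[pm], smooth[im]) - baseline
            )
            if lo <= phi and shallow:
                top = im if smooth[im] > smooth[pm] else pm
                merged[-1] = (top, plo, max(phi, hi))
                continue
        merged.append((im, lo, hi))

    peaks: list[Peak] = []
    for im, lo, hi in merged:
        if hi - lo < 2:
            continue
        seg = slice(lo, hi + 1)
        iraw = lo + int(np.argmax(x[seg]))
        apex_rt, _ = _parabolic_apex(t, x, iraw)
        if min_rt is not None and apex_rt < min_rt:
            continue
        base_line = np.interp(t[seg], [t[lo], t[hi]], [x[lo], x[hi]])
        corrected = x[seg] - base_line
        area = float(np.trapezoid(np.clip(corrected, 0, None), t[seg]) * 60.0)
        height = float(np.max(corrected))
        if area <= 0 or height <= 0:
            continue
        snr = height / noise if noise > 0 else float("inf")
        peaks.append(
            Peak(
                mz=eic.mz,
                apex_rt=apex_rt,
                left_rt=float(t[lo]),
                right_rt=float(t[hi]),
                area=area,
                height=height,
                snr=snr,
            )
        )
    return peaks


def build_components(
    peaks_by_mz: dict[int, list[Peak]], coelute_tol: float = 0.01
) -> list[Component]:
    """Group fragment peaks into components by apex co-elution.

    Single-linkage clustering of apex RTs with gap ≤ ``coelute_tol``; within
    a cluster each m/z contributes its single peak nearest the consensus
    apex (height-weighted mean of member apexes).
    """
    if not coelute_tol > 0:
        raise PeakProcError("coelute_tol must be positive")
    flat = [p for plist in peaks_by_mz.values() for p in plist]
    if not flat:
        return []
    flat.sort(key=lambda p: p.apex_rt)
    clusters: list[list[Peak]] = [[flat[0]]]
    for p in flat[1:]:
        if p.apex_rt - clusters[-1][-1].apex_rt <= coelute_tol:
            clusters[-1].append(p)
        else:
            clusters.append([p])

    components: list[Component] = []
    for cluster in clusters:
        w = np.array([p.height for p in cluster])
        apexes = np.array([p.apex_rt for p in cluster])
        consensus = float(np.average(apexes, weights=w)) if w.sum() > 0 else float(apexes.mean())
        chosen: dict[int, Peak] = {}
        for p in cluster:
            prev = chosen.get(p.mz)
            if prev is None or abs(p.apex_rt - consensus) < abs(prev.apex_rt - consensus):
                chosen[p.mz] = p
        components.append(Component(apex_rt=consensus, fragment_peaks=chosen))
    return components


def peaks_to_table(peaks: list[Peak], label: str | None = None) -> PeakTable:
    """Export detected peaks as the CSV peak-table dialect (lossless hand-off)."""
    df = pd.DataFrame(
        {
            "mz": [p.mz for p in peaks],
            "rt_min": [p.apex_rt for p in peaks],
            "area": [p.area for p in peaks],
            "height": [p.height for p in peaks],
        }
    )
    if label is not None:
        df["label"] = label
    return PeakTable(df=df)
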