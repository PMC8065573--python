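"""Retention-time locking emulated as a post-hoc correction.

The chromatographic method is locked on a single reference compound
(d27-TMS-myristic acid, reference elution 16.727 min): the locking peak is
located in the measured run, and a correction mapping its measured apex to
the reference RT is applied to every detected peak RT. A single anchor
determines one degree of freedom, so the default model is a constant
offset; a proportional (linear through the origin) model is offered for
method-translation scenarios. The raw scans are never resampled — only
peak RTs are corrected, which is lossless and sufficient for RT-window
matching against the library.
"""

from __future__ import annotations

from dataclasses import dataclass

from .library import LockingCompoundSpec
from .msdata import Run, extract_eic
from .peaks import Peak, detect_peaks

__all__ = ["RTCorrection", "LockingError", "find_locking_compound",
           "compute_correction", "apply_correction", "identity_correction"]


class LockingError(Exception):
    """The locking compound could not be found; the run is rejected for
    CCLD quantification."""


@dataclass
class RTCorrection:
    model: str                 # "offset" | "linear"
    offset: float = 0.0        # min
    scale: float = 1.0         # linear model only
    anchor_measured: float = 0.0
    anchor_reference: float = 0.0

    def __post_init__(self):
        if self.model not in ("offset", "linear"):
            raise ValueError(f"unknown RT correction model {self.model!r}")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


def identity_correction() -> RTCorrection:
    return RTCorrection(model="offset", offset=0.0)


def find_locking_compound(
    run: Run,
    lock: LockingCompoundSpec,
    search_window: float = 0.5,
    min_snr: float = 3.0,
) -> Peak:
    """Locate the locking compound: the highest peak of its EIC within
    reference_rt ± search_window."""
    if not search_window > 0:
        raise ValueError("search_window must be positive")
    eic = extract_eic(run, lock.mz)
    candidates = [
        p
        for p in detect_peaks(eic, min_snr=min_snr, min_rt=run.solvent_delay)
        if abs(p.apex_rt - lock.reference_rt) <= search_window
    ]
    if not candidates:
        raise LockingError(
            f"locking compound (m/z {lock.mz}) not found within "
            f"{lock.reference_rt} ± {search_window} min; run rejected"
        )
    return max(candidates, key=lambda p: p.height)


def compute_correction(
    measured_rt: float, reference_rt: float, model: str = "offset"
) -> RTCorrection:
    """Correction mapping the measured anchor RT onto the reference RT."""
    if not measured_rt > 0:
        raise ValueError("measured RT must be positive")
    if model == "offset":
        return RTCorrection(
            model="offset",
            offset=reference_rt - measured_rt,
            anchor_measured=measured_rt,
            anchor_reference=reference_rt,
        )
    if model == "linear":
        return RTCorrection(
            model="linear",
            scale=reference_rt / measured_rt,
            offset=0.0,
            anchor_measured=measured_rt,
            anchor_reference=reference_rt,
        )
    raise ValueError(f"unknown RT correction model {model!r}")


def apply_correction(rt: float, corr: RTCorrection) -> float:
    """Apply an RT correction to a single retention time (minutes)."""
    if corr.model == "offset":
        return rt + corr.offset
    return rt * corr.scale
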