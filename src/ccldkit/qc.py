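"""Calibration-curve building/averaging, LOQ assignment, slope stability,
and DFTPP-style tune checks.

Calibration lines are unweighted ordinary least squares of RPA on
concentration (a 1/x weighting is available for users who prefer it; off
by default, matching the registered method). The cross-batch "averaged"
curve is the arithmetic mean of per-batch parameters — not a pooled refit —
so the individual batch curves remain first-class records; a pooled refit
is offered as an option. The LOQ is the lowest calibration level whose
measured S/N exceeds a threshold (default 10). Tune checks normalize ion
abundances to the base target ion (m/z 69 for DFTPP: targets 100/55/2 % at
m/z 69/219/502) and pass when every ion sits within a relative window of
its target (default ±30% of target, an EPA-625-style window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .library import DEFAULT_TUNE_TARGETS, CalibrationLine

__all__ = [
    "CalibrationBatch",
    "AveragedCalibration",
    "TuneRecord",
    "TuneCheck",
    "QCError",
    "fit_calibration",
    "average_curves",
    "pooled_refit",
    "slope_rsd",
    "determine_loq",
    "check_tune",
    "tune_stability",
]


class QCError(Exception):
    pass


@dataclass
class CalibrationBatch:
    """Replicate RPAs per concentration level for one target in one batch."""

    batch_id: str
    day: str
    rpas: dict[float, list[float]]  # conc µmol/L -> replicate RPAs

    def points(self) -> list[tuple[float, float]]:
        return [(c, r) for c, reps in sorted(self.rpas.items()) for r in reps]

    def __post_init__(self):
        if len(self.rpas) < 2:
            raise QCError("a calibration batch needs at least 2 distinct levels")
        if any(c < 0 for c in self.rpas):
            raise QCError("concentrations must be non-negative")


@dataclass
class AveragedCalibration:
    """The cross-batch averaged line plus the per-batch lines it came from."""

    line: CalibrationLine
    batch_lines: list[CalibrationLine] = field(default_factory=list)

    @property
    def slopes(self) -> list[float]:
        return [b.slope for b in self.batch_lines]


def fit_calibration(
    levels_and_rpas: Sequence[tuple[float, float]],
    weighting: str | None = None,
) -> CalibrationLine:
    """Least-squares line RPA = slope·conc + intercept.

    ``weighting=None`` is ordinary (unweighted) least squares;
    ``weighting="1/x"`` weights each point by 1/conc (blank excluded).
    R² = 1 − SS_res/SS_tot.
    """
    pts = [(float(c), float(r)) for c, r in levels_and_rpas]
    x = np.array([c for c, _ in pts])
    y = np.array([r for _, r in pts])
    if np.unique(x).size < 2:
        raise QCError("need at least 2 distinct concentrations to fit a line")
    if weighting is None:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    elif weighting == "1/x":
        m = x > 0
        w = 1.0 / x[m]
        W = np.diag(w)
        A = np.column_stack([x[m], np.ones(m.sum())])
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ y[m])
        slope, intercept = float(beta[0]), float(beta[1])
    else:
        raise QCError(f"unknown weighting {weighting!r}")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationLine(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        levels=sorted(set(x.tolist())),
    )


def average_curves(batches: Sequence[CalibrationLine]) -> AveragedCalibration:
    """Mean-of-parameters average across replicate batch curves."""
    if not batches:
        raise QCError("need at least one curve to average")
    level_sets = {tuple(b.levels) for b in batches}
    if len(level_sets) > 1:
        raise QCError(f"mismatched level sets across batches: {sorted(level_sets)}")
    return AveragedCalibration(
        line=CalibrationLine(
            slope=float(np.mean([b.slope for b in batches])),
            intercept=float(np.mean([b.intercept for b in batches])),
            r_squared=float(np.mean([b.r_squared for b in batches])),
            levels=list(batches[0].levels),
        ),
        batch_lines=list(batches),
    )


def pooled_refit(batches: Sequence[CalibrationBatch]) -> CalibrationLine:
    """Alternative averaging: one OLS fit through all batches' points."""
    pts = [p for b in batches for p in b.points()]
    return fit_calibration(pts)


def slope_rsd(
    batches: Sequence[CalibrationBatch],
) -> tuple[float, float]:
    """Intra-day and inter-day slope RSDs (%) across calibration batches.

    Each batch is fitted; intra-day RSD is sd/mean of slopes within each
    day, averaged over days with ≥ 2 batches; inter-day RSD is sd/mean of
    the day-mean slopes. NaN where undefined (single batch / single day).
    """
    if not batches:
        raise QCError("no batches given")
    by_day: dict[str, list[float]] = {}
    for b in batches:
        by_day.setdefault(b.day, []).append(fit_calibration(b.points()).slope)

    def rsd(v: Sequence[float]) -> float:
        v = np.asarray(v, dtype=float)
        if v.size < 2 or v.mean() == 0:
            return float("nan")
        return float(100.0 * v.std(ddof=1) / v.mean())

    intra = [rsd(slopes) for slopes in by_day.values() if len(slopes) >= 2]
    intra_day = float(np.mean(intra)) if intra else float("nan")
    day_means = [float(np.mean(s)) for s in by_day.values()]
    inter_day = rsd(day_means)
    return intra_day, inter_day


def determine_loq(
    series: Sequence[tuple[float, float]], threshold: float = 10.0
) -> float | None:
    """Lowest concentration whose S/N exceeds the threshold.

    ``series`` is (concentration µmol/L, measured S/N); returns None when no
    level clears the threshold.
    """
    if not series:
        raise QCError("empty S/N series")
    for conc, snr in sorted(series):
        if snr > threshold:
            return float(conc)
    return None


# ---------------------------------------------------------------------------
# Tune checks
# ---------------------------------------------------------------------------

@dataclass
class TuneRecord:
    timestamp: str
    abundance: dict[int, float]  # m/z -> counts/s

    def __post_init__(self):
        if any(v <= 0 for v in self.abundance.values()):
            raise QCError("tune abundances must be positive")


@dataclass
class TuneCheck:
    relative_abundance: dict[int, float]  # %
    deviation: dict[int, float]           # percentage points from target
    passed: bool


def check_tune(
    record: TuneRecord,
    targets: Mapping[int, float] | None = None,
    tolerance: float = 0.30,
) -> TuneCheck:
    """Evaluate one tune record against target relative abundances.

    Abundances are normalized to the base ion (the ion with the largest
    target, 100%); the check passes when every ion's relative abundance is
    within ``tolerance`` (relative, fraction of target) of its target.
    Scale-invariant by construction.
    """
    targets = dict(targets if targets is not None else DEFAULT_TUNE_TARGETS)
    base_mz = max(targets, key=lambda mz: targets[mz])
    missing = [mz for mz in targets if mz not in record.abundance]
    if missing:
        raise QCError(f"tune record missing ion(s) {missing}")
    base = record.abundance[base_mz]
    rel = {mz: 100.0 * record.abundance[mz] / base for mz in targets}
    dev = {mz: rel[mz] - targets[mz] for mz in targets}
    passed = all(abs(dev[mz]) <= tolerance * targets[mz] for mz in targets)
    return TuneCheck(relative_abundance=rel, deviation=dev, passed=passed)


def tune_stability(
    records: Sequence[TuneRecord],
    base_mz: int = 69,
) -> dict[str, dict[int, float]]:
    """Per-ion RSDs (%) of absolute and base-normalized relative abundance.

    Summarizes a tuning log the way drift is assessed: absolute RSD tracks
    raw sensitivity drift, relative RSD (normalized to the base ion) is
    what the locked calibration actually depends on — common-mode drift
    cancels in the ratio.
    """
    if len(records) < 2:
        raise QCError("need at least 2 tune records")
    mzs = sorted(records[0].abundance)
    abs_mat = np.array([[r.abundance[mz] for mz in mzs] for r in records])
    base_idx = mzs.index(base_mz)
    rel_mat = abs_mat / abs_mat[:, [base_idx]]

    def rsd_cols(mat: np.ndarray) -> dict[int, float]:
        means = mat.mean(axis=0)
        sds = mat.std(axis=0, ddof=1)
        return {
            mz: float(100.0 * sd / mean) if mean != 0 else float("nan")
            for mz, sd, mean in zip(mzs, sds, means)
        }

    return {"absolute_rsd": rsd_cols(abs_mat), "relative_rsd": rsd_cols(rel_mat)}
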