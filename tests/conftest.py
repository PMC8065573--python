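import numpy as np
import pytest

from ccldkit.library import (CCLD, CalibrationLine, InternalStandardSpec, IonSpec,
                             LockingCompoundSpec, Spectrum, TargetEntry,
                             load_packaged_library, packaged_plasma_panel)


@pytest.fixture(scope="session")
def library():
    """The packaged 52-target CCLD with synthetic spectra."""
    return load_packaged_library()


@pytest.fixture(scope="session")
def plasma_panel():
    return packaged_plasma_panel()


def make_entry(
    eid="T001",
    name="Testine (2TMS)",
    rt=10.0,
    quantifier=200,
    qualifiers=((210, 0.6), (150, 0.3)),
    slope=0.01,
    intercept=-0.05,
    fillers=(420, 430),
) -> TargetEntry:
    """A minimal valid entry for unit tests."""
    peaks = {quantifier: 100.0}
    ions = [IonSpec(mz=quantifier, role="quantifier")]
    for (mz, ratio) in qualifiers:
        peaks[mz] = 100.0 * ratio
        ions.append(IonSpec(mz=mz, role="qualifier", expected_ratio=ratio))
    for i, mz in enumerate(fillers):
        peaks[mz] = 10.0 - i
    return TargetEntry(
        id=eid,
        name=name,
        rt=rt,
        rt_sd=0.01,
        ions=ions,
        spectrum=Spectrum(peaks=sorted(peaks.items())),
        calibration=CalibrationLine(slope=slope, intercept=intercept, r_squared=0.999),
    )


def make_ccld(entries=None) -> CCLD:
    if entries is None:
        entries = [make_entry()]
    return CCLD(
        entries=entries,
        internal_standards=[
            InternalStandardSpec(
                name="d10-Phenanthrene (IS1)", role="response", mz=188, rt=15.5,
                nominal_concentration=53.1,
            ),
            InternalStandardSpec(
                name="Adipic acid (IS2)", role="extraction", mz=111, rt=12.2,
                nominal_concentration=10.0,
            ),
        ],
        locking=LockingCompoundSpec(
            name="d27-TMS-Myristic acid (lock)", reference_rt=16.727, mz=312
        ),
    )


@pytest.fixture()
def tiny_ccld():
    return make_ccld()


def gaussian_eic(mz=200, apex=10.0, sigma=0.008, area=1.0e5, dt=1 / (1.3 * 60),
                 t_lo=8.0, t_hi=12.0, baseline=0.0, noise_sd=0.0, seed=0):
    """An analytic Gaussian trace on a realistic scan grid (area in counts·s)."""
    from ccldkit.msdata import EIC

    t = np.arange(t_lo, t_hi, dt)
    sigma_s = sigma * 60.0
    y = area / (sigma_s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    y = y + baseline
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return EIC(mz=mz, times=t, intensity=np.clip(y, 0, None))
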