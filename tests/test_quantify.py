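"""Identification logic, RPA normalization, calibration inversion,
IS2/dilution corrections, recovery, and pipeline invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccldkit.library import CalibrationLine, Spectrum
from ccldkit.peaks import Peak, build_components
from ccldkit.quantify import (MissingIS1Error, QuantConfig, QuantifyError,
                              apply_calibration, apply_is2_correction,
                              compute_recovery, compute_rpa,
                              dilution_factor_from_steps, mass_to_molar,
                              match_target, quantify_run, recovery_table,
                              vial_to_sample, weighted_cosine)
from ccldkit.simulate import SimulationConfig, simulate_peak_table, simulate_run

from conftest import make_ccld, make_entry


def component_for(entry, quant_area=1000.0, apex=None, ratios=None):
    """Build a component carrying the entry's fragments at given ratios."""
    apex = entry.rt if apex is None else apex
    ratios = ratios or {}
    by_mz = {}
    for mz, inten in entry.spectrum.peaks:
        ratio = ratios.get(mz, inten / 100.0)
        area = quant_area * ratio if mz != entry.quantifier.mz else quant_area
        if area > 0:
            by_mz[mz] = [Peak(mz=mz, apex_rt=apex, left_rt=apex - 0.02,
                              right_rt=apex + 0.02, area=area, height=area,
                              snr=np.inf)]
    (comp,) = build_components(by_mz)
    return comp


class TestMatchTarget:
    def test_clean_component_identified(self):
        entry = make_entry()
        res = match_target(entry, [component_for(entry)])
        assert res.status == "identified"
        assert res.similarity == pytest.approx(1.0)
        assert abs(res.rt_delta) < 1e-9

    def test_doubled_qualifier_ratio_fails(self):
        entry = make_entry()
        comp = component_for(entry, ratios={210: 1.2})  # expected 0.6, observed 1.2
        res = match_target(entry, [comp], q_tol=0.2)
        assert res.status == "failed_qualifier"
        failed = [c for c in res.qualifier_checks if not c.passed]
        assert [c.mz for c in failed] == [210]

    def test_no_component_in_window_is_not_found(self):
        entry = make_entry(rt=10.0)
        res = match_target(entry, [component_for(entry, apex=10.5)], rt_tol=0.1)
        assert res.status == "not_found"

    def test_low_similarity_is_rt_only(self):
        entry = make_entry()
        # fragments present at wildly wrong relative intensities but
        # qualifier ratios preserved: cosine drops, qualifiers pass
        comp = component_for(entry, ratios={420: 80.0, 430: 60.0})
        res = match_target(entry, [comp], similarity_threshold=0.99)
        assert res.status == "rt_only"

    def test_best_similarity_wins_among_candidates(self):
        entry = make_entry()
        good = component_for(entry, apex=entry.rt + 0.05)
        # decoy at the exact RT but missing qualifiers entirely
        decoy = component_for(entry, apex=entry.rt, ratios={210: 0.0, 150: 0.0})
        res = match_target(entry, [decoy, good])
        assert res.component is good


class TestWeightedCosine:
    def test_identical_spectra_score_one(self):
        sp = Spectrum(peaks=[(100, 50.0), (200, 100.0)])
        assert weighted_cosine(sp, sp) == pytest.approx(1.0)

    def test_reverse_mode_ignores_extra_fragments(self):
        lib = Spectrum(peaks=[(100, 50.0), (200, 100.0)])
        mixture = Spectrum(peaks=[(100, 50.0), (150, 90.0), (200, 100.0)])
        assert weighted_cosine(lib, mixture, reverse=True) == pytest.approx(1.0)
        assert weighted_cosine(lib, mixture, reverse=False) < 1.0

    def test_matches_matchms_weighted_cosine(self):
        # independent oracle: matchms CosineGreedy with the same weighting
        import matchms
        from matchms.similarity import CosineGreedy

        a = Spectrum(peaks=[(100, 30.0), (150, 100.0), (220, 55.0)])
        b = Spectrum(peaks=[(100, 45.0), (150, 100.0), (220, 20.0)])
        ours = weighted_cosine(a, b, reverse=False)
        ma = matchms.Spectrum(
            mz=np.array([float(m) for m, _ in a.peaks]),
            intensities=np.array([i for _, i in a.peaks]),
            metadata_harmonization=False,
        )
        mb = matchms.Spectrum(
            mz=np.array([float(m) for m, _ in b.peaks]),
            intensities=np.array([i for _, i in b.peaks]),
            metadata_harmonization=False,
        )
        score = CosineGreedy(tolerance=0.4, mz_power=2.0, intensity_power=1.0).pair(ma, mb)
        assert ours == pytest.approx(float(score["score"]), abs=1e-9)


class TestRPAAndCalibration:
    def test_rpa_is_area_ratio(self):
        assert compute_rpa(1000.0, 1000.0) == 1.0
        assert compute_rpa(3566.3, 1000.0) == pytest.approx(3.5663)

    def test_rpa_invariant_to_common_scale(self):
        assert compute_rpa(3.7 * 1000.0, 3.7 * 800.0) == compute_rpa(1000.0, 800.0)

    def test_zero_is1_is_fatal(self):
        with pytest.raises(MissingIS1Error):
            compute_rpa(1000.0, 0.0)

    def test_alanine_line_inverts_to_200(self):
        cal = CalibrationLine(slope=0.0181, intercept=-0.0537, r_squared=0.998,
                              loq=5.0)
        conc, flags = apply_calibration(3.5663, cal)
        assert conc == pytest.approx(200.0, rel=1e-9)
        assert flags == []

    def test_rpa_at_intercept_is_zero_below_loq(self):
        cal = CalibrationLine(slope=0.0181, intercept=-0.0537, r_squared=0.998,
                              loq=5.0)
        conc, flags = apply_calibration(-0.0537, cal)
        assert conc == 0.0
        assert "below_loq" in flags

    def test_above_uloq_flagged_but_reported(self):
        cal = CalibrationLine(
            slope=0.00777, intercept=-0.04160, r_squared=0.996,
            levels=[0, 5, 50, 100, 200, 500, 1000, 1500], loq=5.0,
        )
        rpa = cal.predict(1600.0)
        conc, flags = apply_calibration(rpa, cal)
        assert conc == pytest.approx(1600.0, rel=1e-9)
        assert "above_uloq" in flags and "extrapolated" in flags

    def test_negative_clamped(self):
        cal = CalibrationLine(slope=0.01, intercept=-0.05, r_squared=0.99)
        conc, flags = apply_calibration(-0.3, cal)
        assert conc == 0.0
        assert "negative_clamped" in flags

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(conc=st.floats(0.0, 1500.0))
    def test_inverse_consistency(self, conc):
        cal = CalibrationLine(
            slope=0.00777, intercept=-0.04160, r_squared=0.996,
            levels=[0, 5, 50, 100, 200, 500, 1000, 1500],
        )
        out, _ = apply_calibration(cal.predict(conc), cal)
        assert out == pytest.approx(conc, rel=1e-9, abs=1e-9)


class TestCorrections:
    def test_is2_unchanged_when_observed_equals_expected(self):
        assert apply_is2_correction(50.0, 0.5, 0.5) == 50.0

    def test_is2_half_recovery_doubles_concentration(self):
        assert apply_is2_correction(50.0, 0.25, 0.5) == pytest.approx(100.0)

    def test_is2_requires_positive_rpas(self):
        with pytest.raises(QuantifyError):
            apply_is2_correction(50.0, 0.0, 0.5)

    def test_simulated_70pct_extraction_recovered(self, library):
        panel = {"M004": 100.0}
        config = SimulationConfig(
            ccld=library, vial_concentrations=panel,
            extraction_efficiency=0.7, seed=9, acquisition_length=20.0,
        )
        run, _ = simulate_run(config)
        report = quantify_run(
            library, run, QuantConfig(is2_expected_rpa=config.is2_expected_rpa)
        )
        rec = report.record("M004")
        assert "is2_corrected" in rec.flags
        assert rec.conc_sample == pytest.approx(100.0, rel=0.02)

    def test_vial_to_sample_scaling(self):
        assert vial_to_sample(25.0, 1.0) == 25.0
        assert vial_to_sample(25.0, 4.0) == 100.0

    def test_dilution_chain_composes(self):
        # 50 µL into 1000 µL total, then 100 µL of that into 400 µL
        assert dilution_factor_from_steps([(50, 1000), (100, 400)]) == pytest.approx(80.0)

    def test_mass_to_molar_is1(self):
        assert mass_to_molar(10.0, 188.29) == pytest.approx(53.1, abs=0.05)
        assert mass_to_molar(0.0, 188.29) == 0.0
        assert mass_to_molar(188.29, 188.29) == pytest.approx(1000.0)


class TestRecovery:
    def test_arithmetic(self):
        assert compute_recovery(95.0, 50.0, 50.0) == pytest.approx(90.0)
        assert compute_recovery(50.0, 50.0, 50.0) == 0.0

    def test_added_must_be_positive(self):
        with pytest.raises(QuantifyError):
            compute_recovery(95.0, 50.0, 0.0)

    def test_noiseless_spike_in_recovers_100pct(self, library):
        base = {"M004": 40.0}
        spiked = {"M004": 50.0}
        cfgs = [
            SimulationConfig(ccld=library, vial_concentrations=c, seed=1,
                             acquisition_length=20.0)
            for c in (base, spiked)
        ]
        reports = [quantify_run(library, simulate_run(c)[0]) for c in cfgs]
        results = recovery_table(reports[1], reports[0], added_uM=10.0)
        (res,) = [r for r in results if r.entry_id == "M004"]
        assert res.recovery_pct == pytest.approx(100.0, abs=1.0)


class TestPipelineInvariants:
    def test_global_sensitivity_invariance(self, library):
        config = SimulationConfig(
            ccld=library, vial_concentrations={"M004": 100.0, "M018": 100.0},
            seed=11, acquisition_length=20.0,
        )
        run, _ = simulate_run(config)
        r1 = quantify_run(library, run)
        run.intensities *= 2.9  # detector sensitivity drift
        r2 = quantify_run(library, run)
        for eid in ("M004", "M018"):
            a, b = r1.record(eid), r2.record(eid)
            assert a.status == b.status == "identified"
            assert b.rpa == pytest.approx(a.rpa, rel=1e-9)
            assert b.conc_vial == pytest.approx(a.conc_vial, rel=1e-9)

    def test_quantify_from_peak_table_matches_truth(self, library):
        concs = {"M004": 150.0, "M026": 80.0}
        config = SimulationConfig(ccld=library, vial_concentrations=concs, seed=2)
        table, truth = simulate_peak_table(config)
        report = quantify_run(library, table)
        for eid, conc in concs.items():
            rec = report.record(eid)
            assert rec.status == "identified"
            assert rec.conc_vial == pytest.approx(conc, rel=1e-9)

    def test_run_without_is1_is_fatal(self, library):
        config = SimulationConfig(
            ccld=library, vial_concentrations={"M004": 100.0},
            include_is=False, seed=0, acquisition_length=20.0,
        )
        run, _ = simulate_run(config)
        with pytest.raises(MissingIS1Error):
            quantify_run(library, run)

    def test_report_round_trip_header_and_rows(self, library, tmp_path):
        config = SimulationConfig(ccld=library, vial_concentrations={"M004": 100.0},
                                  seed=0, acquisition_length=20.0)
        run, _ = simulate_run(config)
        report = quantify_run(library, run)
        p = tmp_path / "report.csv"
        report.write(p)
        text = p.read_text()
        assert "# library_hash:" in text
        assert "M004" in text
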