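"""MRM quantification arithmetic, table IO, and QC operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qconpath.mrm_quant import (
    QuantificationError,
    SampleMeta,
    SchemaError,
    copies_per_cell,
    cells_in_digest_from_od,
    digestion_plateau,
    fit_calibration,
    implied_molar_mass,
    protein_abundance,
    quantify_dataset,
    quantify_peptide,
    read_peak_table,
    read_sample_meta,
    subtract_negative_control,
)
from qconpath.synthetic_data import (
    NOISE_FREE,
    PEPTIDE_TO_PROTEIN,
    make_scenario,
    synth_calibration_points,
    synth_digestion_timecourse,
    synth_peak_table,
)

META = SampleMeta(sample_id="s1")


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "peptide", "channel", "area"])


class TestReaders:
    def test_minimal_table(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "sample_id,peptide,channel,area\ns1,AAAK,light,10\ns1,AAAK,heavy,20\n"
        )
        df = read_peak_table(path)
        assert len(df) == 2

    def test_missing_column_listed(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text("sample_id,peptide,area\ns1,AAAK,10\n")
        with pytest.raises(SchemaError, match="channel"):
            read_peak_table(path)

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "sample_id,peptide,channel,area\ns1,AAAK,light,10\ns1,AAAK,light,11\n"
        )
        with pytest.raises(SchemaError, match="duplicated"):
            read_peak_table(path)

    def test_negative_area_rejected(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text("sample_id,peptide,channel,area\ns1,AAAK,light,-1\n")
        with pytest.raises(SchemaError):
            read_peak_table(path)

    def test_synthetic_tables_roundtrip(self, tmp_path):
        dataset = synth_peak_table(make_scenario("MpaLc"), NOISE_FREE)
        dataset.write(tmp_path, stem="t")
        peaks = read_peak_table(tmp_path / "t.csv")
        meta = read_sample_meta(tmp_path / "t_meta.csv")
        pd.testing.assert_frame_equal(peaks, dataset.peaks)
        assert list(meta["sample_id"]) == list(dataset.meta["sample_id"])


class TestControlSubtraction:
    def test_zero_control_is_identity(self):
        samples = peak_frame([("s1", "AAAK", "light", 10.0), ("s1", "AAAK", "heavy", 5.0)])
        control = peak_frame([("c1", "AAAK", "light", 0.0), ("c1", "AAAK", "heavy", 5.0)])
        out = subtract_negative_control(samples, control)
        pd.testing.assert_frame_equal(out, samples)

    def test_control_exceeding_sample_clamps_to_zero(self):
        samples = peak_frame([("s1", "AAAK", "light", 10.0)])
        control = peak_frame([("c1", "AAAK", "light", 50.0)])
        out = subtract_negative_control(samples, control)
        assert out["area"].iloc[0] == 0.0

    def test_heavy_untouched(self):
        samples = peak_frame([("s1", "AAAK", "heavy", 10.0)])
        control = peak_frame([("c1", "AAAK", "light", 3.0), ("c1", "AAAK", "heavy", 9.0)])
        out = subtract_negative_control(samples, control)
        assert out["area"].iloc[0] == 10.0

    def test_missing_control_peptide_warns(self):
        samples = peak_frame([("s1", "GGGR", "light", 10.0)])
        control = peak_frame([("c1", "AAAK", "light", 3.0)])
        with pytest.warns(UserWarning, match="GGGR"):
            out = subtract_negative_control(samples, control)
        assert out["area"].iloc[0] == 10.0

    def test_known_background_removed_exactly(self):
        from qconpath.synthetic_data import NoiseModel

        noise = NoiseModel(cv=0.0, background_frac=0.01)
        dataset = synth_peak_table(make_scenario("MpaLc"), noise)
        b = dataset.truth["background"]
        assert b > 0
        control = dataset.peaks[
            dataset.peaks["sample_id"].str.startswith("control")
        ]
        samples = dataset.peaks[
            dataset.peaks["sample_id"].str.startswith("MpaLc")
        ]
        out = subtract_negative_control(samples, control)
        raw_light = samples[samples["channel"] == "light"]["area"].to_numpy()
        corrected = out[out["channel"] == "light"]["area"].to_numpy()
        assert corrected == pytest.approx(raw_light - b)


class TestQuantifyPeptide:
    def test_equal_areas_return_spike_amount(self):
        assert quantify_peptide(50.0, 50.0, META) == pytest.approx(100.9)

    def test_deficit_correction_inverts_generator_model(self):
        # heavy area is S * p^nC for spike S; correction recovers truth
        spike, pn, true_pmol, gain = 100.9, 0.63, 7.5, 1e4
        light, heavy = gain * true_pmol, gain * spike * pn
        assert quantify_peptide(light, heavy, META, deficit_correction=pn) == (
            pytest.approx(true_pmol)
        )

    def test_zero_light_gives_zero(self):
        assert quantify_peptide(0.0, 10.0, META) == 0.0

    def test_zero_heavy_flags_failure(self):
        assert np.isnan(quantify_peptide(10.0, 0.0, META))


class TestCopiesPerCell:
    def test_avogadro_scaling(self):
        assert copies_per_cell(1.0, 6.02214076e11) == pytest.approx(1.0)
        assert copies_per_cell(0.1, 6.022e8) == pytest.approx(100.0, rel=1e-4)
        assert copies_per_cell(0.0, 1e9) == 0.0

    def test_nonpositive_cells_rejected(self):
        with pytest.raises(QuantificationError):
            copies_per_cell(1.0, 0)

    def test_od_harvest_helper(self):
        assert cells_in_digest_from_od() == pytest.approx(4.0e9)


class TestProteinAbundance:
    def test_two_peptides_average(self):
        ab = protein_abundance("CYP71D18", {"A": 10.0, "B": 14.0})
        assert ab.copies_per_cell == 12.0

    def test_excluded_peptide_ignored(self):
        ab = protein_abundance(
            "ATR2", {"P1": 8.0, "VVDDILVEQGAQR": 99.0},
            exclusions={"VVDDILVEQGAQR": "miscleavage"},
        )
        assert ab.copies_per_cell == 8.0
        assert "VVDDILVEQGAQR" in ab.peptides_excluded

    def test_all_excluded_raises(self):
        with pytest.raises(QuantificationError, match="all peptides excluded"):
            protein_abundance("X", {"P": 1.0}, exclusions={"P": "r"})

    def test_identical_values_mean_unchanged(self):
        assert protein_abundance("X", {"A": 5.0, "B": 5.0}).copies_per_cell == 5.0


class TestQuantifyDataset:
    def test_linearity_in_light_areas(self, exclusions):
        dataset = synth_peak_table(make_scenario("MpaLc"), NOISE_FREE)
        base = quantify_dataset(
            dataset.peaks, dataset.meta, PEPTIDE_TO_PROTEIN, exclusions=exclusions
        )
        doubled_peaks = dataset.peaks.copy()
        light = doubled_peaks["channel"] == "light"
        doubled_peaks.loc[light, "area"] *= 2.0
        doubled = quantify_dataset(
            doubled_peaks, dataset.meta, PEPTIDE_TO_PROTEIN, exclusions=exclusions
        )
        assert doubled["copies_per_cell"].to_numpy() == pytest.approx(
            2.0 * base["copies_per_cell"].to_numpy()
        )

    def test_exclusion_does_not_affect_other_proteins(self, exclusions):
        dataset = synth_peak_table(make_scenario("MpaLc"), NOISE_FREE)
        with_excl = quantify_dataset(
            dataset.peaks, dataset.meta, PEPTIDE_TO_PROTEIN, exclusions=exclusions
        )
        without = quantify_dataset(
            dataset.peaks, dataset.meta, PEPTIDE_TO_PROTEIN, exclusions=None
        )
        for protein in ("CYP71D18", "ISPD"):
            a = with_excl[with_excl["protein"] == protein]["copies_per_cell"]
            b = without[without["protein"] == protein]["copies_per_cell"]
            assert a.to_numpy() == pytest.approx(b.to_numpy())


class TestCalibration:
    def test_noise_free_wide_range_is_linear(self):
        points = synth_calibration_points()
        curve = fit_calibration(points)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.validated_range == (0.25, 2500.0)

    def test_two_points_exact(self):
        curve = fit_calibration([(1.0, 2.0), (3.0, 8.0)])
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(3.0)

    def test_noisy_slope_recovered_within_5_percent(self):
        true_slope = 1.0 / 100.9
        points = synth_calibration_points(slope=true_slope, cv=0.02, seed=1)
        for weighting in ("none", "inverse-amount"):
            curve = fit_calibration(points, weighting=weighting)
            assert curve.slope == pytest.approx(true_slope, rel=0.05)

    def test_single_point_rejected(self):
        with pytest.raises(QuantificationError):
            fit_calibration([(1.0, 1.0)])


class TestDigestionPlateau:
    def test_first_order_release_plateaus_at_16h(self):
        # k=0.5/h: 8->16 h gain is ~1.8%, 4->8 h is ~13% -> plateau at 16 h
        course = synth_digestion_timecourse(k_per_h=0.5)
        result = digestion_plateau(course, rel_tol=0.05)
        assert result.time_h == 16.0
        assert result.plateau_reached

    def test_constant_signal_plateaus_immediately(self):
        result = digestion_plateau([(1.0, 5.0), (2.0, 5.0), (4.0, 5.0)])
        assert result.time_h == 2.0
        assert result.plateau_reached

    def test_linear_increase_never_plateaus(self):
        course = [(t, 10.0 * t) for t in (1.0, 2.0, 4.0, 8.0)]
        result = digestion_plateau(course)
        assert result.time_h == 8.0
        assert not result.plateau_reached

    def test_too_few_points_rejected(self):
        with pytest.raises(QuantificationError):
            digestion_plateau([(1.0, 1.0), (2.0, 2.0)])


class TestImpliedMolarMass:
    def test_standard_spike_implies_20_kda_band(self):
        kda = implied_molar_mass(2.0, 100.9)
        assert kda == pytest.approx(19.82, abs=0.005)
        assert round(kda) == 20

    def test_unit_case(self):
        assert implied_molar_mass(1.0, 1.0) == pytest.approx(1000.0)

    @given(
        m=st.floats(0.1, 100.0),
        molar_kda=st.floats(1.0, 500.0),
    )
    def test_inverse_consistency(self, m, molar_kda):
        amount_pmol = m / molar_kda * 1e3
        assert implied_molar_mass(m, amount_pmol) == pytest.approx(molar_kda)

    def test_nonpositive_rejected(self):
        with pytest.raises(QuantificationError):
            implied_molar_mass(0.0, 1.0)
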