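import pytest
from hypothesis import given
from hypothesis import strategies as st

from ventcal.errors import DomainError, InconsistentInputsError
from ventcal.gas_corrections import (
    GasReading,
    average_window,
    correct_co2_cross_sensitivity,
    correct_reading,
    interpolate_fio2,
    inverse_co2_cross_sensitivity,
    read_gas_timeseries,
    standardize_pressure,
    wet_to_dry_fraction,
    MMHG_TO_HPA,
)
from ventcal.psychrometry import PsychroState


class TestCo2CrossSensitivity:
    def test_identity_at_zero_o2(self):
        assert correct_co2_cross_sensitivity(4.0, 0.0) == 4.0

    def test_full_o2(self):
        # 4.0 / (1 - 0.072)
        assert correct_co2_cross_sensitivity(4.0, 100.0) == pytest.approx(4.310345, abs=1e-4)

    def test_intermediate(self):
        # 3.8 / (1 - 0.0216)
        assert correct_co2_cross_sensitivity(3.8, 30.0) == pytest.approx(3.883893, abs=1e-4)

    @pytest.mark.parametrize("co2,o2", [(4.0, -1.0), (4.0, 101.0), (-0.1, 50.0), (21.0, 50.0)])
    def test_precondition_violations(self, co2, o2):
        with pytest.raises(DomainError):
            correct_co2_cross_sensitivity(co2, o2)

    @given(co2=st.floats(0.0, 20.0), o2=st.floats(0.0, 100.0))
    def test_correction_never_decreases(self, co2, o2):
        corrected = correct_co2_cross_sensitivity(co2, o2)
        assert corrected >= co2
        if o2 == 0.0 or co2 == 0.0:
            assert corrected == co2

    @given(co2=st.floats(0.1, 19.0), o2=st.floats(0.0, 99.0), delta=st.floats(0.1, 1.0))
    def test_monotone_in_o2(self, co2, o2, delta):
        assert correct_co2_cross_sensitivity(co2, min(100.0, o2 + delta)) > \
            correct_co2_cross_sensitivity(co2, o2)

    @given(co2=st.floats(0.0, 18.0), o2=st.floats(0.0, 100.0))
    def test_inverse_round_trip(self, co2, o2):
        distorted = inverse_co2_cross_sensitivity(co2, o2)
        assert correct_co2_cross_sensitivity(distorted, o2) == pytest.approx(co2, rel=1e-12)


class TestStandardizePressure:
    def test_identity_when_pressures_equal(self):
        assert standardize_pressure(0.209, 1013.0, 1013.0) == 0.209

    def test_reference_values(self):
        assert standardize_pressure(0.209, 1000.0, 1016.0) == pytest.approx(0.205709, abs=1e-5)
        assert standardize_pressure(0.95, 1013.0, 1030.0) == pytest.approx(0.934320, abs=1e-5)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(DomainError):
            standardize_pressure(0.2, 0.0, 1013.0)
        with pytest.raises(DomainError):
            standardize_pressure(0.2, 1013.0, -5.0)

    @given(frac=st.floats(0.0, 1.0), p=st.floats(900.0, 1100.0))
    def test_identity_property(self, frac, p):
        assert standardize_pressure(frac, p, p) == pytest.approx(frac, rel=1e-15)

    @given(
        frac=st.floats(0.01, 1.0),
        p_calib=st.floats(900.0, 1100.0),
        p_circuit=st.floats(900.0, 1100.0),
    )
    def test_invertible(self, frac, p_calib, p_circuit):
        fwd = standardize_pressure(frac, p_calib, p_circuit)
        back = standardize_pressure(fwd, p_circuit, p_calib)
        assert back == pytest.approx(frac, rel=1e-12)


class TestWetToDryFraction:
    def test_dry_identity(self):
        assert wet_to_dry_fraction(0.16, None) == 0.16
        assert wet_to_dry_fraction(0.16, PsychroState.dry()) == 0.16

    def test_reference_values(self):
        # 0.16 * 1.0258141 and 0.04 * 1.0264708, frozen from the Buck oracle
        assert wet_to_dry_fraction(0.16, PsychroState(22.5, 0.925, 1002)) == \
            pytest.approx(0.1641303, abs=2e-6)
        assert wet_to_dry_fraction(0.04, PsychroState(23.3, 0.913, 1013)) == \
            pytest.approx(0.0410588, abs=2e-6)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(InconsistentInputsError):
            wet_to_dry_fraction(0.999, PsychroState(30.0, 0.95, 1000.0))

    @given(frac=st.floats(0.0, 0.9), rh=st.floats(0.0, 1.0))
    def test_never_decreases(self, frac, rh):
        state = PsychroState(23.0, rh, 1010.0)
        assert wet_to_dry_fraction(frac, state) >= frac


class TestInterpolateFio2:
    @pytest.mark.parametrize(
        "t_frac,expected", [(0.0, 0.300), (1.0, 0.302), (0.5, 0.301)]
    )
    def test_linear(self, t_frac, expected):
        assert interpolate_fio2(0.300, 0.302, t_frac) == pytest.approx(expected)

    @pytest.mark.parametrize("t_frac", [-0.01, 1.01])
    def test_out_of_range(self, t_frac):
        with pytest.raises(DomainError):
            interpolate_fio2(0.3, 0.31, t_frac)


def _reading(o2, co2, t=0.0):
    return GasReading(o2_frac=o2, co2_frac=co2, p_calib_hpa=1005.0,
                      p_circuit_hpa=1020.0, timestamp_s=t)


class TestAverageWindow:
    def test_constant_readings(self):
        readings = [_reading(0.21, 0.04, t=float(i)) for i in range(60)]
        avg = average_window(readings, 60.0)
        assert avg.o2_frac == pytest.approx(0.21)
        assert avg.co2_frac == pytest.approx(0.04)

    def test_alternating_readings(self):
        readings = [_reading(0.20 if i % 2 == 0 else 0.22, 0.0, t=float(i)) for i in range(60)]
        assert average_window(readings, 60.0).o2_frac == pytest.approx(0.21)

    def test_single_reading_is_itself(self):
        r = _reading(0.3, 0.05)
        avg = average_window([r], 60.0)
        assert avg.o2_frac == r.o2_frac and avg.co2_frac == r.co2_frac

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            average_window([], 60.0)

    def test_readings_outside_window_excluded(self):
        readings = [_reading(0.20, 0.0, t=0.0), _reading(0.40, 0.0, t=120.0)]
        assert average_window(readings, 60.0).o2_frac == pytest.approx(0.20)


class TestGasReadingValidation:
    def test_fraction_sum_invariant(self):
        with pytest.raises(DomainError):
            GasReading(o2_frac=0.8, co2_frac=0.3, p_calib_hpa=1000, p_circuit_hpa=1000)

    def test_negative_fraction(self):
        with pytest.raises(DomainError):
            GasReading(o2_frac=-0.1, co2_frac=0.0, p_calib_hpa=1000, p_circuit_hpa=1000)


class TestCorrectionChain:
    def test_correct_reading_dry_no_pressure_offset(self):
        r = GasReading(o2_frac=0.21, co2_frac=0.0, p_calib_hpa=1005, p_circuit_hpa=1005)
        o2, co2 = correct_reading(r)
        assert o2 == pytest.approx(0.21) and co2 == 0.0

    def test_forward_then_inverse_is_identity(self):
        # fabricate the raw reading from known dry fractions, then correct back
        feo2_dry, feco2_dry = 0.16, 0.045
        psychro = PsychroState(22.8, 0.92, 1020.0)
        from ventcal.psychrometry import water_mole_fraction

        x_w = water_mole_fraction(psychro)
        o2_wet, co2_wet = feo2_dry * (1 - x_w), feco2_dry * (1 - x_w)
        co2_distorted = inverse_co2_cross_sensitivity(co2_wet * 100, o2_wet * 100) / 100
        raw = GasReading(
            o2_frac=o2_wet * 1020.0 / 1005.0,
            co2_frac=co2_distorted * 1020.0 / 1005.0,
            p_calib_hpa=1005.0,
            p_circuit_hpa=1020.0,
            psychro=psychro,
        )
        o2, co2 = correct_reading(raw)
        assert o2 == pytest.approx(feo2_dry, rel=1e-12)
        assert co2 == pytest.approx(feco2_dry, rel=1e-12)


class TestTimeseriesReader:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "gas.csv"
        path.write_text(
            "t_s,o2_pct,co2_pct,p_circuit_mmhg_gauge,p_ambient_hpa,temp_c,rh_pct\n"
            "0,16.0,4.0,12.5,1005.0,22.8,92.0\n"
            "1,16.1,4.1,12.5,1005.0,22.8,92.0\n"
        )
        readings = read_gas_timeseries(path)
        assert len(readings) == 2
        assert readings[0].o2_frac == pytest.approx(0.16)
        assert readings[0].p_circuit_hpa == pytest.approx(1005.0 + 12.5 * MMHG_TO_HPA)
        assert readings[0].psychro.rh == pytest.approx(0.92)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_s,o2_pct\n0,16.0\n")
        with pytest.raises(DomainError):
            read_gas_timeseries(path)
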