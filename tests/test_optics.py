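import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirscpm.errors import ConfigurationError, InputError
from nirscpm.optics import (
    BeerLambertParams,
    HemoSeries,
    IntensityRecording,
    flag_artifacts,
    flagged_fraction,
    forward_od,
    interpolate_flagged,
    od_to_hemoglobin,
    trim_steady_state,
)


def _recording(od695, od830, fs=10.0):
    return IntensityRecording("p1", np.atleast_2d(od695), np.atleast_2d(od830), fs)


class TestBeerLambert:
    def test_default_effective_pathlength_is_distance_times_dpf(self):
        p = BeerLambertParams()
        assert p.effective_pathlength_mm() == pytest.approx(30.0 * 6.26)
        assert p.effective_pathlength_mm() == pytest.approx(187.8)

    def test_zero_od_gives_zero_hemoglobin(self):
        rec = _recording(np.zeros((3, 50)), np.zeros((3, 50)))
        out = od_to_hemoglobin(rec, BeerLambertParams())
        assert np.all(out.hbo == 0) and np.all(out.hbr == 0)

    def test_forward_inverse_round_trip(self):
        """Concentrations (1, -0.5) uM survive forward OD + inversion to 1e-10."""
        params = BeerLambertParams()
        hbo = np.full((2, 10), 1.0)
        hbr = np.full((2, 10), -0.5)
        od695, od830 = forward_od(hbo, hbr, params)
        out = od_to_hemoglobin(_recording(od695, od830), params)
        assert np.allclose(out.hbo, 1.0, rtol=1e-10)
        assert np.allclose(out.hbr, -0.5, rtol=1e-10)

    def test_round_trip_random_inputs(self, rng):
        params = BeerLambertParams()
        hbo, hbr = rng.normal(size=(2, 5, 200))
        od695, od830 = forward_od(hbo, hbr, params)
        out = od_to_hemoglobin(_recording(od695, od830), params)
        assert np.allclose(out.hbo, hbo, rtol=1e-10, atol=1e-12)
        assert np.allclose(out.hbr, hbr, rtol=1e-10, atol=1e-12)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_conversion_is_linear(self, a, b):
        params = BeerLambertParams()
        r = np.random.default_rng(7)
        x695, x830, y695, y830 = r.normal(size=(4, 2, 20))
        conv = lambda m695, m830: od_to_hemoglobin(_recording(m695, m830), params)
        mixed = conv(a * x695 + b * y695, a * x830 + b * y830)
        cx, cy = conv(x695, x830), conv(y695, y830)
        assert np.allclose(mixed.hbo, a * cx.hbo + b * cy.hbo, atol=1e-8)
        assert np.allclose(mixed.hbr, a * cx.hbr + b * cy.hbr, atol=1e-8)

    def test_extinction_table_loadable_from_file(self, tmp_path):
        from nirscpm.optics import load_extinction_table

        path = tmp_path / "ext.tsv"
        path.write_text(
            "wavelength_nm\teps_hbo\teps_hbr\n695\t300.0\t1900.0\n830\t970.0\t690.0\n"
        )
        table = load_extinction_table(path)
        params = BeerLambertParams(extinction=table)
        params.validate()
        assert params.extinction_matrix()[0, 0] == 300.0

    def test_singular_extinction_matrix_rejected(self):
        params = BeerLambertParams(extinction={695: (1.0, 2.0), 830: (2.0, 4.0)})
        with pytest.raises(ConfigurationError):
            params.validate()

    def test_shape_mismatch_and_nonfinite_rejected(self):
        with pytest.raises(InputError):
            od_to_hemoglobin(
                IntensityRecording("p", np.zeros((2, 5)), np.zeros((3, 5)), 10.0)
            )
        bad = np.zeros((2, 5))
        bad[0, 0] = np.nan
        with pytest.raises(InputError):
            od_to_hemoglobin(IntensityRecording("p", bad, np.zeros((2, 5)), 10.0))


class TestTrim:
    def test_seven_minutes_at_10hz_trims_to_4000_samples(self):
        s = HemoSeries("p", np.zeros((2, 4200)), np.zeros((2, 4200)), 10.0)
        assert trim_steady_state(s, 10.0).n_samples == 4000

    def test_zero_trim_is_identity(self, hemo_series):
        out = trim_steady_state(hemo_series, 0.0)
        assert np.array_equal(out.hbo, hemo_series.hbo)

    def test_too_short_series_rejected(self):
        s = HemoSeries("p", np.zeros((1, 150)), np.zeros((1, 150)), 10.0)
        with pytest.raises(InputError):
            trim_steady_state(s, 10.0)  # needs > 200 samples

    @given(
        n=st.integers(50, 400),
        trim=st.floats(0, 2.0),
        fs=st.sampled_from([5.0, 10.0, 12.5]),
    )
    def test_output_length_identity(self, n, trim, fs):
        cut = int(round(trim * fs))
        s = HemoSeries("p", np.zeros((1, n)), np.zeros((1, n)), fs)
        if n <= 2 * cut:
            with pytest.raises(InputError):
                trim_steady_state(s, trim)
        else:
            assert trim_steady_state(s, trim).n_samples == n - 2 * cut


class TestArtifactFlagging:
    def test_clean_signal_not_flagged(self, hemo_series):
        out = flag_artifacts(hemo_series)
        assert out.artifact_mask.sum() == 0

    def test_injected_spike_flagged_with_window(self, hemo_series):
        from nirscpm.synthetic_data import inject_spike

        spiked = inject_spike(hemo_series, channel=2, sample=1000, magnitude_sd=20.0)
        out = flag_artifacts(spiked, spike_z=7.0, shift_window=5)
        assert out.artifact_mask[2, 995:1006].all()
        assert not out.artifact_mask[[0, 1, 3, 4, 5, 6, 7]].any()
        assert flagged_fraction(out)[2] > 0

    def test_constant_channel_not_flagged(self):
        s = HemoSeries("p", np.ones((2, 500)), np.ones((2, 500)), 10.0)
        assert flag_artifacts(s).artifact_mask.sum() == 0

    def test_interpolation_repairs_spike_and_clears_mask(self, hemo_series):
        from nirscpm.synthetic_data import inject_spike

        spiked = inject_spike(hemo_series, channel=0, sample=500, magnitude_sd=30.0)
        repaired = interpolate_flagged(flag_artifacts(spiked))
        assert repaired.artifact_mask.sum() == 0
        assert abs(repaired.hbo[0, 500] - hemo_series.hbo[0, 500]) < 1.0
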