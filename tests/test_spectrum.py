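"""Core spectrum model: phase application, conversions, FID processing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrphaser import (
    FIDRecord,
    PhasePair,
    ProcessingParams,
    Spectrum1D,
    apply_phase,
    endpoint_to_phasepair,
    group_delay_correct,
    phasepair_to_endpoint,
    process_fid,
)


def random_spectrum(rng, n=257):
    pts = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    return Spectrum1D(points=pts)


def measure_fwhh(real: np.ndarray) -> float:
    """Full width at half height with linearly interpolated crossings."""
    k = int(np.argmax(real))
    half = real[k] / 2.0
    left = k
    while left > 0 and real[left] > half:
        left -= 1
    right = k
    while right < real.size - 1 and real[right] > half:
        right += 1
    xl = left + (half - real[left]) / (real[left + 1] - real[left])
    xr = right - 1 + (real[right - 1] - half) / (real[right - 1] - real[right])
    return xr - xl


class TestApplyPhase:
    def test_zero_phase_is_identity(self, rng):
        spec = random_spectrum(rng)
        out = apply_phase(spec, PhasePair(0.0, 0.0))
        np.testing.assert_array_equal(out.points, spec.points)

    def test_inverse_composition(self, rng):
        spec = random_spectrum(rng)
        p = PhasePair(37.2, -118.0)
        back = apply_phase(apply_phase(spec, p), -p)
        np.testing.assert_allclose(back.points, spec.points, rtol=1e-10)

    def test_constant_spectrum_ph0_90(self):
        spec = Spectrum1D(points=np.ones(64, complex))
        out = apply_phase(spec, PhasePair(90.0, 0.0))
        np.testing.assert_allclose(out.points, np.full(64, 1j), atol=1e-12)

    def test_ph1_ramp_endpoints_n3(self):
        # ramp k/(N-1): N=3 with PH1=180 gives phases 0, 90, 180 degrees
        spec = Spectrum1D(points=np.ones(3, complex))
        out = apply_phase(spec, PhasePair(0.0, 180.0))
        np.testing.assert_allclose(
            out.points, np.array([1.0, 1j, -1.0]), atol=1e-12
        )

    def test_magnitude_preserved_exactly(self, rng):
        spec = random_spectrum(rng, n=513)
        out = apply_phase(spec, PhasePair(-133.0, 287.5))
        np.testing.assert_allclose(
            np.abs(out.points), np.abs(spec.points), rtol=1e-12
        )

    def test_additive_composition(self, rng):
        spec = random_spectrum(rng)
        p1, p2 = PhasePair(12.0, -30.0), PhasePair(-45.5, 81.0)
        seq = apply_phase(apply_phase(spec, p1), p2)
        joint = apply_phase(spec, p1 + p2)
        np.testing.assert_allclose(seq.points, joint.points, rtol=1e-10)

    def test_matches_per_point_exponential_loop(self, rng):
        """Independent per-point complex-exponential oracle."""
        spec = random_spectrum(rng, n=101)
        p = PhasePair(23.0, -77.0)
        out = apply_phase(spec, p)
        n = len(spec)
        expected = np.array(
            [
                spec.points[k]
                * np.exp(1j * np.deg2rad(p.ph0 + p.ph1 * k / (n - 1)))
                for k in range(n)
            ]
        )
        np.testing.assert_allclose(out.points, expected, rtol=1e-10)

    def test_nonfinite_phase_rejected(self):
        with pytest.raises(ValueError):
            PhasePair(np.nan, 0.0)
        with pytest.raises(ValueError):
            PhasePair(0.0, np.inf)


class TestEndpointConversion:
    @pytest.mark.parametrize(
        "left,right,ph0,ph1",
        [(0.0, 0.0, 0.0, 0.0), (5.0, 5.0, 5.0, 0.0), (-3.0, 7.0, -3.0, 10.0)],
    )
    def test_examples(self, left, right, ph0, ph1):
        p = endpoint_to_phasepair(left, right)
        assert p.ph0 == ph0 and p.ph1 == ph1

    @settings(max_examples=1000, deadline=None)
    @given(
        left=st.floats(-720, 720, allow_nan=False),
        right=st.floats(-720, 720, allow_nan=False),
    )
    def test_round_trip(self, left, right):
        l2, r2 = phasepair_to_endpoint(endpoint_to_phasepair(left, right))
        assert l2 == pytest.approx(left, abs=1e-9)
        assert r2 == pytest.approx(right, abs=1e-9)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            endpoint_to_phasepair(np.inf, 0.0)


class TestProcessFid:
    def _single_oscillation_fid(self, n=1024, freq_cycles=96.0, r2=0.02):
        t = np.arange(n)
        samples = np.exp(2j * np.pi * freq_cycles * t / n) * np.exp(-r2 * t)
        return FIDRecord(samples=samples, dwell_time=1.0)

    def test_lorentzian_position_and_width(self):
        """Closed form: decay rate R gives FWHH = R*N/pi points."""
        n, r2 = 1024, 0.02
        fid = self._single_oscillation_fid(n=n, r2=r2)
        spec = process_fid(fid, ProcessingParams(apod_line_broadening=0.0))
        real = spec.real
        k = int(np.argmax(real))
        # peak must sit at the bin matching +96 cycles under the left=downfield order
        assert abs(real[k]) == np.max(np.abs(real))
        width = measure_fwhh(real)
        expected = r2 * n / np.pi
        assert width == pytest.approx(expected, rel=0.05)

    def test_group_delay_self_consistency(self):
        """A digitally delayed FID processes to the undelayed spectrum."""
        n = 1024
        fid0 = self._single_oscillation_fid(n=n)
        g = 7
        delayed = np.concatenate([np.zeros(g, complex), fid0.samples[: n - g]])
        fid_g = FIDRecord(samples=delayed, dwell_time=1.0, group_delay=g)
        s0 = process_fid(fid0, ProcessingParams(apod_line_broadening=0.0))
        sg = process_fid(fid_g, ProcessingParams(apod_line_broadening=0.0))
        # compare away from the spectral edges
        sl = slice(32, len(s0) - 32)
        scale = np.max(np.abs(s0.points))
        np.testing.assert_allclose(
            sg.points[sl] / scale, s0.points[sl] / scale, atol=0.02
        )

    def test_zero_fill_too_small_rejected(self):
        fid = self._single_oscillation_fid(n=1024)
        with pytest.raises(ValueError):
            process_fid(fid, ProcessingParams(zero_fill_target=512))

    def test_zero_fill_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            ProcessingParams(zero_fill_target=1000)


class TestGroupDelayCorrect:
    def test_identity_at_zero(self, rng):
        spec = random_spectrum(rng)
        out = group_delay_correct(spec, 0.0)
        np.testing.assert_array_equal(out.points, spec.points)

    def test_equivalent_to_minus_360_ph1(self):
        spec = Spectrum1D(points=np.ones(128, complex))
        out = group_delay_correct(spec, 1.0)
        ref = apply_phase(spec, PhasePair(0.0, -360.0))
        np.testing.assert_allclose(out.points, ref.points, rtol=1e-12)

    def test_inverse_composition(self, rng):
        spec = random_spectrum(rng)
        fwd = group_delay_correct(spec, 3.0)
        back = apply_phase(fwd, PhasePair(0.0, +360.0 * 3.0))
        np.testing.assert_allclose(back.points, spec.points, rtol=1e-10)

    def test_negative_rejected(self, rng):
        with pytest.raises(ValueError):
            group_delay_correct(random_spectrum(rng), -1.0)


def test_all_zero_fid_gives_all_zero_spectrum():
    fid = FIDRecord(samples=np.zeros(64, complex), dwell_time=1e-4)
    spec = process_fid(fid)
    assert np.all(spec.points == 0)


def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum1D(points=np.array([1.0 + 0j]))
    with pytest.raises(ValueError):
        Spectrum1D(points=np.array([np.nan + 0j, 1 + 0j]))
    with pytest.raises(ValueError):
        Spectrum1D(points=np.ones(4, complex), spectral_width=-5.0)
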