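"""Complex 1D spectrum / FID data model and phase application.

Conventions used throughout the package
---------------------------------------

* A :class:`Spectrum1D` stores complex frequency-domain points with index 0
  at the LEFT (downfield / high-ppm) end of the displayed spectrum.
* Phases are in degrees.  ``PH0`` is the frequency-independent zeroth-order
  phase; ``PH1`` is the *total* first-order phase change across the full
  spectral width.  Point ``k`` (0-based, ``k = 0..N-1``) is multiplied by
  ``exp(+i * deg2rad(PH0 + PH1 * k / (N - 1)))`` so that the left end
  receives exactly ``PH0`` and the right end exactly ``PH0 + PH1``.
* The phase-factor sign convention is ``e^{+i phi}`` (see
  :data:`PHASE_SIGN`); *correcting* a known phase error ``phi`` therefore
  means applying ``-phi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PHASE_SIGN",
    "Spectrum1D",
    "PhasePair",
    "FIDRecord",
    "ProcessingParams",
    "apply_phase",
    "phase_ramp",
    "endpoint_to_phasepair",
    "phasepair_to_endpoint",
    "wrap_degrees",
    "process_fid",
    "group_delay_correct",
]

#: Sign of the applied phase factor exponent: points are multiplied by
#: ``exp(PHASE_SIGN * 1j * phi_rad)``.  A single constant controls the
#: convention package-wide.
PHASE_SIGN = +1.0


def wrap_degrees(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped > 180.0:
        wrapped -= 360.0
    elif wrapped <= -180.0:
        wrapped += 360.0
    return wrapped


@dataclass(frozen=True)
class PhasePair:
    """Zeroth- and first-order phase, both in degrees.

    ``ph1`` is the total phase change across the full spectral width; the
    processing pipeline guarantees ``|ph1| < 360`` after group-delay
    correction, but the type itself does not restrict it.
    """

    ph0: float
    ph1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ph0) and math.isfinite(self.ph1)):
            raise ValueError(f"phase must be finite, got ({self.ph0}, {self.ph1})")

    def __add__(self, other: "PhasePair") -> "PhasePair":
        return PhasePair(self.ph0 + other.ph0, self.ph1 + other.ph1)

    def __neg__(self) -> "PhasePair":
        return PhasePair(-self.ph0, -self.ph1)

    def wrapped(self) -> "PhasePair":
        """Return the pair with ph0 wrapped to (-180, 180]; ph1 untouched."""
        return PhasePair(wrap_degrees(self.ph0), self.ph1)


@dataclass
class Spectrum1D:
    """Complex frequency-domain 1D spectrum.

    Parameters
    ----------
    points:
        Complex amplitudes, index 0 = left (downfield) end, length >= 2.
    spectral_width:
        Optional spectral width in Hz (> 0 if set).
    observe_freq:
        Optional observe frequency in MHz.
    ref_ppm:
        Optional ppm value of the first (leftmost) point.
    """

    points: np.ndarray
    spectral_width: Optional[float] = None
    observe_freq: Optional[float] = None
    ref_ppm: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if not np.iscomplexobj(pts):
            pts = pts.astype(np.complex128)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("spectrum needs a 1D complex array of length >= 2")
        if not np.all(np.isfinite(pts.view(float))):
            raise ValueError("spectrum contains non-finite values")
        if self.spectral_width is not None and not self.spectral_width > 0:
            raise ValueError("spectral_width must be > 0 when set")
        self.points = pts

    def __len__(self) -> int:
        return self.points.size

    @property
    def real(self) -> np.ndarray:
        return self.points.real

    @property
    def imag(self) -> np.ndarray:
        return self.points.imag

    def copy_with(self, points: np.ndarray) -> "Spectrum1D":
        return replace(self, points=points)


@dataclass
class FIDRecord:
    """Complex time-domain free induction decay.

    ``group_delay`` is the effective delay (in points, possibly fractional)
    introduced by the spectrometer's digital filter.  The processing
    pipeline assumes that after group-delay correction no residual
    first-order error larger than 360 degrees remains.
    """

    samples: np.ndarray
    dwell_time: float
    group_delay: float = 0.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if not np.iscomplexobj(s):
            s = s.astype(np.complex128)
        if s.ndim != 1 or s.size < 2:
            raise ValueError("FID needs a 1D complex array of length >= 2")
        if not self.dwell_time > 0:
            raise ValueError("dwell_time must be > 0")
        if self.group_delay < 0:
            raise ValueError("group_delay must be >= 0")
        self.samples = s


@dataclass
class ProcessingParams:
    """FID -> spectrum processing parameters.

    ``apod_line_broadening`` is the exponential line-broadening in Hz;
    ``zero_fill_target`` must be a power of two at least the FID length.
    """

    apod_line_broadening: float = 0.3
    zero_fill_target: Optional[int] = None

    def __post_init__(self) -> None:
        if self.apod_line_broadening < 0:
            raise ValueError("apod_line_broadening must be >= 0")
        if self.zero_fill_target is not None:
            n = self.zero_fill_target
            if n < 2 or (n & (n - 1)) != 0:
                raise ValueError("zero_fill_target must be a power of two >= 2")


def phase_ramp(n_points: int, phase: PhasePair) -> np.ndarray:
    """Per-point phase in radians for an ``n_points`` spectrum.

    Uses the endpoint parametrization: point ``k`` receives
    ``PH0 + PH1 * k / (N - 1)`` degrees, so the first point gets exactly
    PH0 and the last exactly PH0 + PH1.
    """
    k = np.arange(n_points)
    deg = phase.ph0 + phase.ph1 * k / (n_points - 1)
    return np.deg2rad(deg)


def apply_phase(spec: Spectrum1D, phase: PhasePair) -> Spectrum1D:
    """Multiply each spectral point by its phase factor.

    Point ``k`` is multiplied by ``exp(+i * deg2rad(PH0 + PH1*k/(N-1)))``.
    Magnitudes ``|S_k|`` are preserved exactly; the output length equals the
    input length.
    """
    if not isinstance(phase, PhasePair):
        phase = PhasePair(*phase)
    if phase.ph0 == 0.0 and phase.ph1 == 0.0:
        return spec.copy_with(spec.points.copy())
    factor = np.exp(PHASE_SIGN * 1j * phase_ramp(len(spec), phase))
    return spec.copy_with(spec.points * factor)


def endpoint_to_phasepair(phase_left: float, phase_right: float) -> PhasePair:
    """Convert (phase at left end, phase at right end) to a PhasePair.

    ``PH0 = phase_left`` and ``PH1 = phase_right - phase_left``; inverse of
    :func:`phasepair_to_endpoint`.
    """
    if not (math.isfinite(phase_left) and math.isfinite(phase_right)):
        raise ValueError("endpoint phases must be finite")
    return PhasePair(ph0=float(phase_left), ph1=float(phase_right - phase_left))


def phasepair_to_endpoint(phase: PhasePair) -> tuple[float, float]:
    """Phases received by the left and right spectrum ends."""
    return phase.ph0, phase.ph0 + phase.ph1


def group_delay_correct(spec: Spectrum1D, group_delay: float) -> Spectrum1D:
    """Compensate the digital-filter group delay.

    A delay of ``g`` points shows up as a linear phase ramp of ``360 * g``
    degrees across the spectral width; the correction applies a first-order
    phase of ``-360 * g`` (and no zeroth-order component).  ``g = 0`` is the
    identity.
    """
    if group_delay < 0:
        raise ValueError("group_delay must be >= 0 for correction")
    if group_delay == 0:
        return spec.copy_with(spec.points.copy())
    return apply_phase(spec, PhasePair(0.0, -360.0 * group_delay))


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def process_fid(fid: FIDRecord, params: Optional[ProcessingParams] = None) -> Spectrum1D:
    """Standard FID -> spectrum processing.

    Steps: exponential apodization, zero filling to a power of two, complex
    FFT with the output reordered so index 0 is the left (downfield,
    highest-frequency) end, then digital-filter group-delay correction.
    Deterministic for a fixed input.
    """
    if params is None:
        params = ProcessingParams()
    n_in = fid.samples.size
    target = params.zero_fill_target or _next_pow2(n_in)
    if target < n_in:
        raise ValueError(
            f"zero_fill_target {target} is smaller than the FID length {n_in}"
        )

    t = np.arange(n_in) * fid.dwell_time
    apod = np.exp(-math.pi * params.apod_line_broadening * t)
    s = fid.samples * apod
    # halve the first point to suppress the constant baseline offset of the
    # discrete FT of a signal that starts at t = 0
    s = s.copy()
    s[0] *= 0.5
    buf = np.zeros(target, dtype=np.complex128)
    buf[:n_in] = s

    ft = np.fft.fft(buf)
    if fid.group_delay:
        # exact compensation of the digital-filter time shift: a delay of g
        # samples multiplies fft bin k by exp(-2*pi*i*k*g/N); undo it bin-wise
        # (equivalent to group_delay_correct up to a constant 180*g offset,
        # and exact for fractional delays)
        k = np.fft.fftfreq(target) * target
        ft = ft * np.exp(2j * math.pi * k * fid.group_delay / target)
    # fftshift puts the most negative frequency first; reverse so that index 0
    # is the highest frequency (downfield, left end of the displayed spectrum)
    pts = np.fft.fftshift(ft)[::-1].copy()

    sw = 1.0 / fid.dwell_time
    return Spectrum1D(points=pts, spectral_width=sw)
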