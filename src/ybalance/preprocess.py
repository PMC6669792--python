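"""Signal conditioning for balance-trial channels.

The conditioning chain mirrors standard movement-analysis practice:

* joint angles — 4th-order Butterworth low-pass at 18 Hz;
* ground-reaction forces / CoP — 4th-order Butterworth low-pass at 50 Hz;
* surface EMG — band-pass 20-450 Hz (4th-order Butterworth), full-wave
  rectification, then a Chebyshev type-II low-pass (10 Hz) to obtain the
  linear envelope;
* all channels — resampled onto exactly 1001 equally spaced frames so
  trials of different durations are directly comparable.

All offline filters are applied zero-phase (forward-backward,
``filtfilt``) by default, which doubles the attenuation at the cutoff
(-6 dB instead of -3 dB for a single pass) but introduces no lag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import TrialSignal

__all__ = [
    "FilterSpec",
    "NormalizedTrial",
    "butter_lowpass",
    "emg_envelope",
    "compute_cop",
    "time_normalize",
    "preprocess_trial",
]

N_FRAMES = 1001

ANGLE_CUTOFF_HZ = 18.0
COP_CUTOFF_HZ = 50.0
EMG_BAND_HZ = (20.0, 450.0)
ENVELOPE_CUTOFF_HZ = 10.0


_design_cache: dict = {}


@dataclass(frozen=True)
class FilterSpec:
    """A filter recipe: family, order, kind and cutoff(s) in Hz."""

    family: str = "butterworth"  # or "chebyshev2"
    order: int = 4
    kind: str = "lowpass"  # lowpass | highpass | bandpass
    cutoffs: tuple = (18.0,)
    zero_phase: bool = True
    stop_atten_db: float = 40.0  # Chebyshev II stopband attenuation

    def design(self, rate: float):
        key = (self, rate)
        cached = _design_cache.get(key)
        if cached is not None:
            return cached
        nyq = rate / 2.0
        if any(c >= nyq for c in self.cutoffs) or any(c <= 0 for c in self.cutoffs):
            raise ValueError(f"cutoffs {self.cutoffs} must lie in (0, {nyq}) at rate {rate}")
        wn = self.cutoffs[0] if len(self.cutoffs) == 1 else list(self.cutoffs)
        if self.family == "butterworth":
            ba = sps.butter(self.order, wn, btype=self.kind, fs=rate)
        elif self.family == "chebyshev2":
            ba = sps.cheby2(self.order, self.stop_atten_db, wn, btype=self.kind, fs=rate)
        else:
            raise ValueError(f"unknown filter family {self.family!r}")
        _design_cache[key] = ba
        return ba

    def apply(self, values: np.ndarray, rate: float) -> np.ndarray:
        b, a = self.design(rate)
        if self.zero_phase:
            return sps.filtfilt(b, a, values)
        return sps.lfilter(b, a, values)


@dataclass
class NormalizedTrial:
    """A trial resampled to a fixed frame count (1001 by default); the
    frame index 0..n_frames-1 replaces time."""

    subject: str
    condition: str
    trial: int
    channel: str
    values: np.ndarray
    n_frames: int = N_FRAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_frames:
            raise ValueError(
                f"normalized trial must have {self.n_frames} frames, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values after normalization")


def butter_lowpass(
    signal: TrialSignal, cutoff_hz: float, order: int = 4, zero_phase: bool = True
) -> TrialSignal:
    """Butterworth low-pass of one trial channel (same length, zero-phase
    by default).  A single pass is -3 dB at the cutoff; the default
    forward-backward application squares the magnitude response."""
    spec = FilterSpec("butterworth", order, "lowpass", (cutoff_hz,), zero_phase)
    return replace(signal, values=spec.apply(signal.values, signal.rate))


def emg_envelope(
    signal: TrialSignal,
    band_hz: tuple = EMG_BAND_HZ,
    envelope_cutoff_hz: float = ENVELOPE_CUTOFF_HZ,
    zero_phase: bool = True,
    clip_negative: bool = True,
    rectify_only: bool = False,
) -> TrialSignal:
    """Linear envelope of a surface-EMG channel.

    Chain: band-pass (Butterworth, 20-450 Hz) -> full-wave rectification
    -> Chebyshev type-II low-pass smoothing.  The envelope approximates
    activation intensity; for a sine of amplitude A within the band, the
    steady-state envelope approaches the rectified mean 2A/pi.

    ``rectify_only=True`` skips the final smoothing stage, returning the
    rectified band-passed signal (an alternative complexity input).
    ``clip_negative`` zeroes the slight negative ringing the Chebyshev
    smoother can introduce.
    """
    if signal.rate < 2.0 * band_hz[1]:
        raise ValueError(f"rate {signal.rate} too low for band {band_hz}")
    bp = FilterSpec("butterworth", 4, "bandpass", tuple(band_hz), zero_phase)
    x = bp.apply(signal.values, signal.rate)
    x = np.abs(x)
    if not rectify_only:
        lp = FilterSpec("chebyshev2", 4, "lowpass", (envelope_cutoff_hz,), zero_phase)
        x = lp.apply(x, signal.rate)
        if clip_negative:
            x = np.clip(x, 0.0, None)
    return replace(signal, values=x)


def compute_cop(
    fz: np.ndarray,
    mx: np.ndarray,
    my: np.ndarray,
    contact_threshold_n: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Center of pressure from vertical force and plate moments.

    With the plate origin at its surface, ``cop_ap = -my / fz`` and
    ``cop_ml = mx / fz`` (meters).  Samples with |fz| below the contact
    threshold are returned as NaN; if no sample reaches the threshold a
    no-contact error is raised.
    """
    fz = np.asarray(fz, float)
    mx = np.asarray(mx, float)
    my = np.asarray(my, float)
    contact = np.abs(fz) >= contact_threshold_n
    if not contact.any():
        raise ValueError("no plate contact: |fz| below threshold throughout")
    with np.errstate(divide="ignore", invalid="ignore"):
        cop_ap = np.where(contact, -my / fz, np.nan)
        cop_ml = np.where(contact, mx / fz, np.nan)
    return cop_ap, cop_ml


def time_normalize(signal: TrialSignal, n_frames: int = N_FRAMES, method: str = "cubic") -> NormalizedTrial:
    """Resample a trial onto ``n_frames`` equally spaced points spanning
    [first, last] sample time; endpoints are preserved exactly.

    Cubic-spline interpolation by default (exact on polynomials up to
    degree 3); ``method='linear'`` is available.
    """
    x = signal.values
    if x.size < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    if x.size == n_frames:
        # the sampling grid is uniform, so the target knots coincide with the
        # original samples and interpolation is the identity
        return NormalizedTrial(
            signal.subject, signal.condition, signal.trial, signal.channel,
            x.copy(), n_frames=n_frames,
        )
    t = signal.times
    tn = np.linspace(t[0], t[-1], n_frames)
    if method == "cubic":
        y = CubicSpline(t, x)(tn)
    elif method == "linear":
        y = np.interp(tn, t, x)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    y[0], y[-1] = x[0], x[-1]
    return NormalizedTrial(
        signal.subject, signal.condition, signal.trial, signal.channel, y, n_frames=n_frames
    )


def preprocess_trial(
    signal: TrialSignal,
    angle_cutoff_hz: float = ANGLE_CUTOFF_HZ,
    cop_cutoff_hz: float = COP_CUTOFF_HZ,
    zero_phase: bool = True,
    emg_use_envelope: bool = True,
) -> TrialSignal:
    """Family-appropriate conditioning of one trial channel (no resampling)."""
    fam = signal.family
    if fam == "angle":
        return butter_lowpass(signal, angle_cutoff_hz, zero_phase=zero_phase)
    if fam == "cop":
        return butter_lowpass(signal, cop_cutoff_hz, zero_phase=zero_phase)
    return emg_envelope(signal, zero_phase=zero_phase, rectify_only=not emg_use_envelope)
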