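"""Synthetic balance-study generator with known ground truth.

The real quantity of interest downstream is the complexity (Higuchi
fractal dimension, SVD entropy) of joint-angle, center-of-pressure and
surface-EMG recordings from a single-leg balance test, compared across
three taping conditions (no tape NT, strapping tape ST, kinesiology tape
KT) in a repeated-measures design.  No public recordings exist, so this
module generates datasets with the statistical structure that analysis
assumes:

* kinematic and CoP channels are fractional Brownian motion (fBm) paths
  whose Hurst exponent ``H`` fixes the theoretical fractal dimension of
  the path at ``2 - H`` — a clean, known ground truth for the Higuchi
  estimator;
* EMG channels are band-limited (20-450 Hz) Gaussian noise under a
  slowly varying activation envelope, mimicking eccentric loading during
  a reach;
* condition effects are injected either as Hurst shifts (moves fractal
  dimension) or as changes in latent-source count / DC-offset scale
  (moves SVD entropy), with per-subject Gaussian random effects shared
  across that subject's trials so that the within-subject correlation a
  repeated-measures ANOVA relies on actually exists.

fBm synthesis uses exact circulant embedding (Davies-Harte) of the
fractional-Gaussian-noise covariance, falling back to a Cholesky
factorization when the circulant eigenvalues are not all nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ANGLE_CHANNELS, COP_CHANNELS, EMG_CHANNELS, TrialSignal, channel_family

__all__ = [
    "SyntheticStudySpec",
    "fgn_autocovariance",
    "generate_fbm",
    "generate_emg_like",
    "trapezoid_envelope",
    "generate_multisource",
    "generate_study",
]

CONDITIONS = ("NT", "ST", "KT")

#: samples per second for each channel family
FAMILY_RATES = {"angle": 100.0, "cop": 1000.0, "emg": 1000.0}


def fgn_autocovariance(hurst: float, lags) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fractional Gaussian noise.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)


def _check_hurst(hurst: float) -> None:
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must lie strictly in (0, 1), got {hurst}")


# circulant eigenvalues depend only on (hurst, n); generating many paths at
# the same parameters (Monte-Carlo sweeps, full studies) reuses them
_eig_cache: dict[tuple[float, int], np.ndarray] = {}


def _circulant_eigenvalues(hurst: float, n_incr: int) -> np.ndarray | None:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Returns None when any eigenvalue is negative (Davies-Harte
    inapplicable; caller falls back to Cholesky).
    """
    key = (round(hurst, 12), n_incr)
    if key in _eig_cache:
        return _eig_cache[key]
    gamma = fgn_autocovariance(hurst, np.arange(n_incr))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2*(n_incr-1)
    eig = np.fft.rfft(row).real
    out = None if np.any(eig < -1e-10) else np.clip(eig, 0.0, None)
    _eig_cache[key] = out
    return out


def _fgn(hurst: float, n_incr: int, rng: np.random.Generator) -> np.ndarray:
    """One exact sample of n_incr fractional-Gaussian-noise increments."""
    if hurst == 0.5 or n_incr == 1:
        return rng.standard_normal(n_incr)
    lam = _circulant_eigenvalues(hurst, n_incr)
    if lam is not None:
        # Davies-Harte: Hermitian complex spectrum with variance lam, then FFT
        m = 2 * (n_incr - 1)
        mid = m // 2
        w = np.zeros(m, dtype=complex)
        w[0] = np.sqrt(lam[0]) * rng.standard_normal()
        a = rng.standard_normal(mid - 1)
        b = rng.standard_normal(mid - 1)
        w[1:mid] = np.sqrt(lam[1:mid] / 2.0) * (a + 1j * b)
        w[mid] = np.sqrt(lam[mid]) * rng.standard_normal()
        w[mid + 1 :] = np.conj(w[1:mid][::-1])
        x = np.fft.fft(w) / np.sqrt(m)
        return x[:n_incr].real
    # Cholesky fallback (small n or numerically awkward H)
    cov = fgn_autocovariance(hurst, np.abs(np.subtract.outer(range(n_incr), range(n_incr))))
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_incr))
    return chol @ rng.standard_normal(n_incr)


def generate_fbm(hurst: float, n: int, seed) -> np.ndarray:
    """Exact fractional Brownian motion path of ``n`` points starting at 0.

    The path's theoretical fractal dimension is ``2 - hurst``; increments
    are stationary fractional Gaussian noise with unit variance.  ``seed``
    may be an int or a ``numpy.random.Generator``.
    """
    _check_hurst(hurst)
    if n < 2:
        raise ValueError(f"need n >= 2 points, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    incr = _fgn(hurst, n - 1, rng)
    return np.concatenate([[0.0], np.cumsum(incr)])


def trapezoid_envelope(n: int, ramp_frac: float = 0.2) -> np.ndarray:
    """Default activation profile: ramp up over the first ``ramp_frac`` of the
    trial, hold at 1, ramp down over the last ``ramp_frac``."""
    t = np.linspace(0.0, 1.0, n)
    up = np.clip(t / ramp_frac, 0.0, 1.0)
    down = np.clip((1.0 - t) / ramp_frac, 0.0, 1.0)
    return np.minimum(up, down)


def generate_emg_like(
    duration_s: float,
    rate: float,
    envelope_profile: np.ndarray | None = None,
    band: tuple[float, float] = (20.0, 450.0),
    seed=None,
) -> np.ndarray:
    """Band-limited Gaussian noise under a non-negative activation envelope.

    Emulates raw surface EMG whose usable band is 20-450 Hz: zero-mean
    white noise is band-passed (4th-order Butterworth, zero-phase) and
    multiplied by a slowly varying envelope in [0, 1].
    """
    from scipy.signal import butter, filtfilt

    low, high = band
    if not (0.0 < low < high < rate / 2.0):
        raise ValueError(f"band {band} must lie inside (0, {rate / 2})")
    n = int(round(duration_s * rate)) + 1
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = rng.standard_normal(n)
    b, a = butter(4, [low, high], btype="bandpass", fs=rate)
    x = filtfilt(b, a, noise)
    env = trapezoid_envelope(n) if envelope_profile is None else np.asarray(envelope_profile, float)
    if env.size != n:
        env = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, env.size), env)
    return x * env


def generate_multisource(
    n_sources: int,
    weights,
    n: int,
    hurst: float,
    seed=None,
    hurst_spread: float = 0.3,
) -> np.ndarray:
    """Weighted sum of independent fBm sources with fanned-out roughness.

    Source 1 has Hurst exponent ``hurst``; additional sources are
    progressively rougher (Hurst reduced by up to ``hurst_spread``,
    floored at 0.1), so that a mixture of more sources genuinely carries
    more distinguishable spectral structure — the ground truth that SVD
    entropy is meant to pick up.  The mixture is scaled to unit sample
    variance (fixed total variance regardless of source count).
    """
    if n_sources < 1:
        raise ValueError(f"n_sources must be >= 1, got {n_sources}")
    w = np.asarray(weights, dtype=float)
    if w.size != n_sources:
        raise ValueError(f"weights length {w.size} != n_sources {n_sources}")
    if np.all(w == 0.0):
        raise ValueError("weights must not be all zero")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.zeros(n)
    for j in range(n_sources):
        frac = j / max(n_sources - 1, 1)
        h_j = max(0.1, hurst - hurst_spread * frac) if n_sources > 1 else hurst
        out = out + w[j] * generate_fbm(h_j, n, rng)
    sd = out.std()
    return out / sd if sd > 0 else out


@dataclass(frozen=True)
class _ChannelLevels:
    """Baseline signal geometry for one channel: fluctuation amplitude and
    DC offset, in the channel's physical units."""

    amplitude: float
    dc: float


# baseline Hurst exponents per channel; kinematic values sit where the path
# fractal dimension 2 - H matches what balance-test recordings typically show
_DEFAULT_HURST = {
    "ankle_AP": 0.88,
    "ankle_ML": 0.51,
    "ankle_SI": 0.44,
    "knee_AP": 0.95,
    "knee_ML": 0.88,
    "knee_SI": 0.90,
    "cop_AP": 0.49,
    "cop_ML": 0.44,
}

# joint angles in degrees (fluctuation about a flexed working posture), CoP in
# meters (millimetre-scale sway about a stance offset from the plate origin)
_DEFAULT_LEVELS = {
    "ankle_AP": _ChannelLevels(amplitude=2.0, dc=110.0),
    "ankle_ML": _ChannelLevels(amplitude=2.0, dc=4.0),
    "ankle_SI": _ChannelLevels(amplitude=2.0, dc=30.0),
    "knee_AP": _ChannelLevels(amplitude=4.0, dc=45.0),
    "knee_ML": _ChannelLevels(amplitude=2.0, dc=8.0),
    "knee_SI": _ChannelLevels(amplitude=2.0, dc=12.0),
    "cop_AP": _ChannelLevels(amplitude=0.005, dc=0.08),
    "cop_ML": _ChannelLevels(amplitude=0.004, dc=0.03),
    "gastrocnemius": _ChannelLevels(amplitude=0.2, dc=0.0),
    "fibularis_longus": _ChannelLevels(amplitude=0.15, dc=0.0),
    "rectus_femoris": _ChannelLevels(amplitude=0.25, dc=0.0),
}


def _default_effects() -> dict[tuple[str, str], float]:
    # taping stiffens the ankle mediolaterally: rougher (lower-H) sway path,
    # i.e. higher fractal dimension under both tapes
    return {("ankle_ML", "ST"): -0.20, ("ankle_ML", "KT"): -0.20}


def _default_sources() -> dict[tuple[str, str], int]:
    # untaped ankle sagittal/transverse motion draws on more latent
    # physiological sources; tape collapses it toward a single source
    out: dict[tuple[str, str], int] = {}
    for ch in ("ankle_AP", "ankle_SI"):
        out[(ch, "NT")] = 3
        out[(ch, "ST")] = 1
        out[(ch, "KT")] = 1
    return out


def _default_dc_scale() -> dict[tuple[str, str], float]:
    # taped conditions hold the ankle closer to a fixed posture: larger DC
    # offset relative to fluctuation in the restricted directions
    out: dict[tuple[str, str], float] = {}
    for ch in ("ankle_AP", "ankle_SI"):
        out[(ch, "ST")] = 2.0
        out[(ch, "KT")] = 2.0
    return out


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full recipe for a ground-truth-known synthetic balance study.

    Defaults emulate the design the analysis targets: 41 subjects, three
    taping conditions (NT/ST/KT), five trials each, ~10 s trials sampled
    at 100 Hz (angles) and 1000 Hz (CoP, EMG).  ``effect`` maps
    (channel, condition) to a Hurst offset (drives fractal dimension);
    ``n_sources`` and ``dc_scale`` map (channel, condition) to a latent
    source count and a DC-offset multiplier (drive SVD entropy).
    """

    n_subjects: int = 41
    conditions: tuple[str, ...] = CONDITIONS
    n_trials: int = 5
    duration_s: float = 10.0
    rates: dict = field(default_factory=lambda: dict(FAMILY_RATES))
    channels: tuple[str, ...] = ANGLE_CHANNELS + COP_CHANNELS + EMG_CHANNELS
    hurst: dict = field(default_factory=lambda: dict(_DEFAULT_HURST))
    n_sources: dict = field(default_factory=_default_sources)
    effect: dict = field(default_factory=_default_effects)
    dc_scale: dict = field(default_factory=_default_dc_scale)
    noise_sd: float = 0.02
    subject_hurst_sd: float = 0.04
    subject_amp_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        for ch, h in self.hurst.items():
            if not (0.0 < h < 1.0):
                raise ValueError(f"hurst[{ch}]={h} outside (0, 1)")
        for key, k in self.n_sources.items():
            if k < 1:
                raise ValueError(f"n_sources[{key}]={k} must be >= 1")

    def with_zero_effects(self) -> "SyntheticStudySpec":
        """Copy of this spec with every condition effect removed (null study)."""
        return replace(self, effect={}, n_sources={}, dc_scale={})


def _n_samples(spec: SyntheticStudySpec, family: str) -> int:
    return int(round(spec.duration_s * spec.rates[family])) + 1


def generate_study(spec: SyntheticStudySpec) -> list[TrialSignal]:
    """Generate the complete long-format dataset for one synthetic study.

    Per-subject random effects (a Gaussian intercept on Hurst and a
    multiplicative amplitude factor) are drawn once per subject and
    shared across that subject's trials and conditions, inducing the
    within-subject correlation a repeated-measures analysis needs.
    Deterministic: a fixed spec (including seed) yields identical data.
    """
    rng = np.random.default_rng(spec.seed)
    signals: list[TrialSignal] = []
    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        dh_subj = rng.normal(0.0, spec.subject_hurst_sd)
        amp_subj = float(np.exp(rng.normal(0.0, spec.subject_amp_sd)))
        dc_subj = float(np.exp(rng.normal(0.0, 0.05)))
        for condition in spec.conditions:
            for trial in range(1, spec.n_trials + 1):
                for channel in spec.channels:
                    family = channel_family(channel)
                    rate = spec.rates[family]
                    n = _n_samples(spec, family)
                    lev = _DEFAULT_LEVELS[channel]
                    if family == "emg":
                        x = generate_emg_like(spec.duration_s, rate, seed=rng)
                        values = amp_subj * lev.amplitude * x
                    else:
                        h = spec.hurst[channel] + spec.effect.get((channel, condition), 0.0) + dh_subj
                        h = float(np.clip(h, 0.05, 0.95))
                        k = spec.n_sources.get((channel, condition), 1)
                        path = generate_multisource(k, np.ones(k), n, h, seed=rng)
                        dc = lev.dc * dc_subj * spec.dc_scale.get((channel, condition), 1.0)
                        values = amp_subj * lev.amplitude * path + dc
                    if spec.noise_sd > 0:
                        values = values + rng.normal(0.0, spec.noise_sd * lev.amplitude, values.size)
                    signals.append(
                        TrialSignal(
                            subject=subject,
                            condition=condition,
                            trial=trial,
                            channel=channel,
                            rate=rate,
                            values=values,
                        )
                    )
    return signals


def ground_truth(spec: SyntheticStudySpec) -> dict:
    """Per-(channel, condition) true generating parameters, for sidecar files."""
    truth = {}
    for channel in spec.channels:
        family = channel_family(channel)
        for condition in spec.conditions:
            entry = {"family": family, "rate": spec.rates[family]}
            if family != "emg":
                entry["hurst"] = spec.hurst[channel] + spec.effect.get((channel, condition), 0.0)
                entry["fractal_dimension"] = 2.0 - entry["hurst"]
                entry["n_sources"] = spec.n_sources.get((channel, condition), 1)
                entry["dc_scale"] = spec.dc_scale.get((channel, condition), 1.0)
            truth[f"{channel}/{condition}"] = entry
    return truth
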