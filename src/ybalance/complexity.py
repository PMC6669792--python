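"""Nonlinear complexity measures for short physiological time series.

Two estimators are implemented from scratch:

* :func:`higuchi_fd` — Higuchi's fractal dimension, the slope of
  ``ln L(k)`` versus ``ln(1/k)`` where ``L(k)`` is the mean normalized
  curve length at discrete time interval ``k``.  Values range from ~1
  (smooth, e.g. an affine trend) to ~2 (noise-like).

* :func:`svd_entropy` — Shannon entropy (base 2) of the sum-normalized
  singular values of a delay-embedding matrix.  With embedding dimension
  ``m`` the result lies in ``[0, log2 m]``; it is 0 for any rank-1
  embedding (constant or perfectly alternating series) and is invariant
  to amplitude scaling.

Both are designed for the short (1001-frame) series produced by
time-normalized balance-test trials; defaults (``k_max=8``, ``m=2``,
``tau=1``) are the standard choices for such recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingSpec",
    "HiguchiSpec",
    "ComplexityRecord",
    "embed",
    "svd_entropy",
    "higuchi_fd",
    "higuchi_curve_lengths",
    "measure_trial",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension ``m`` and delay ``tau`` (samples)."""

    m: int = 2
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"delay tau must be >= 1, got {self.tau}")

    def n_vectors(self, n: int) -> int:
        return n - (self.m - 1) * self.tau


@dataclass(frozen=True)
class HiguchiSpec:
    """Higuchi estimator parameters: maximal time interval ``k_max``."""

    k_max: int = 8

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError(f"k_max must be >= 2, got {self.k_max}")


@dataclass(frozen=True)
class ComplexityRecord:
    """Both complexity measures for one (subject, condition, channel) cell."""

    subject: str
    condition: str
    channel: str
    hdf: float
    svden: float


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    return x


def embed(series, spec: EmbeddingSpec = EmbeddingSpec()) -> np.ndarray:
    """Delay-coordinate embedding matrix.

    Row ``i`` (0-based) is ``[x[i], x[i+tau], ..., x[i+(m-1)*tau]]``; the
    matrix has ``N - (m-1)*tau`` rows and ``m`` columns.
    """
    x = _as_series(series)
    n_rows = spec.n_vectors(x.size)
    if n_rows < spec.m:
        raise ValueError(
            f"series of length {x.size} too short for m={spec.m}, tau={spec.tau}"
        )
    cols = [x[j * spec.tau : j * spec.tau + n_rows] for j in range(spec.m)]
    return np.column_stack(cols)


def svd_entropy(
    series,
    spec: EmbeddingSpec = EmbeddingSpec(),
    center: bool = False,
) -> float:
    """SVD entropy (bits) of the delay-embedded series.

    Singular values of the (by default uncentered) embedding matrix are
    normalized to sum to one and fed through Shannon entropy with the
    convention ``0*log 0 = 0``.  An uncentered embedding keeps the DC
    component of the signal as part of the description, which makes the
    entropy of offset-dominated signals (e.g. joint angles fluctuating
    around a large mean) very small; pass ``center=True`` to remove the
    mean first.
    """
    y = embed(series, spec)
    if center:
        y = y - y.mean(axis=0)
    sv = np.linalg.svd(y, compute_uv=False)
    # numerical-rank cutoff (same tolerance as matrix_rank): singular values
    # that are pure floating-point residue of a lower-rank embedding are zero
    sv[sv < sv.max(initial=0.0) * max(y.shape) * np.finfo(float).eps] = 0.0
    total = sv.sum()
    if total == 0.0:
        warnings.warn("all singular values are zero (all-zero series); entropy = 0")
        return 0.0
    p = sv / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)


def higuchi_curve_lengths(series, spec: HiguchiSpec = HiguchiSpec()) -> np.ndarray:
    """Mean normalized curve length ``L(k)`` for ``k = 1..k_max``.

    For interval ``k`` and offset ``m`` (1-based), the partial length is

        L(m, k) = [sum_{i=1}^{n} |x(m+ik) - x(m+(i-1)k)|] * (N-1) / (n*k) / k

    with ``n = floor((N-m)/k)``; ``L(k)`` averages over the ``k`` offsets.
    The ``(N-1)/(n*k)`` factor compensates for the unequal number of
    summed differences across offsets.
    """
    x = _as_series(series)
    n = x.size
    if spec.k_max > (n - 1) // 2:
        raise ValueError(f"series of length {n} too short for k_max={spec.k_max}")
    lk = np.empty(spec.k_max)
    for k in range(1, spec.k_max + 1):
        d = np.abs(x[k:] - x[:-k])
        # element d[i] belongs to offset m = (i mod k) + 1; folding k-wide
        # rows gives all per-offset sums at once (remainder handled apart)
        q, rem = divmod(d.size, k)
        sums = d[: q * k].reshape(q, k).sum(axis=0) if q else np.zeros(k)
        if rem:
            sums[:rem] += d[q * k :]
        counts = (n - 1 - np.arange(k)) // k
        lmk = sums * (n - 1) / (counts * k) / k
        lk[k - 1] = lmk.mean()
    return lk


def higuchi_fd(series, spec: HiguchiSpec = HiguchiSpec()) -> float:
    """Higuchi fractal dimension: slope of ``ln L(k)`` on ``ln(1/k)``.

    Uses an unweighted least-squares fit over all ``k = 1..k_max``.
    A series whose curve length vanishes at any scale (constant or affine
    degenerate to constant differences of zero) has dimension 1 by
    convention and returns 1.0 with a warning rather than raising, so
    batch runs never abort on flat channels.
    """
    lk = higuchi_curve_lengths(series, spec)
    if np.any(lk == 0.0):
        warnings.warn("curve length is zero at some scale (flat series); HDf = 1.0")
        return 1.0
    w = _slope_weights_cache.get(spec.k_max)
    if w is None:
        x = np.log(1.0 / np.arange(1, spec.k_max + 1))
        xc = x - x.mean()
        w = xc / (xc**2).sum()
        _slope_weights_cache[spec.k_max] = w
    return float(w @ np.log(lk))


_slope_weights_cache: dict[int, np.ndarray] = {}


def measure_trial(
    values,
    hspec: HiguchiSpec = HiguchiSpec(),
    espec: EmbeddingSpec = EmbeddingSpec(),
    center: bool = False,
) -> tuple[float, float]:
    """Compute (HDf, SvdEn) on the same series, as done per normalized trial."""
    return higuchi_fd(values, hspec), svd_entropy(values, espec, center=center)
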