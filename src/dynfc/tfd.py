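"""Complex time-frequency distributions for instantaneous phase estimation.

The Rihaczek distribution

    C(t, w) = (1/2pi) x(t) X*(w) e^{-jwt}

is a complex, bilinear time-frequency energy distribution whose argument
provides a time- and frequency-dependent phase estimate

    Phi(t, w) = arg[ C(t, w) / |C(t, w)| ].

For multicomponent signals the bilinear structure produces cross-terms that
bias both energy and phase.  The reduced-interference (RID) Rihaczek
distribution filters them in the ambiguity (Doppler theta, lag tau) domain
with a Choi-Williams kernel exp(-(theta*tau)^2 / sigma): the kernel is unity
on the theta and tau axes (where auto-terms concentrate) and decays away from
them (where cross-terms live), so smaller sigma means stronger cross-term
suppression at the price of more smoothing.

Discretization
--------------
All four domains (time, frequency, Doppler, lag) are L-point uniform DFT
grids.  The instantaneous autocorrelation uses the asymmetric circular lag

    R[n, l] = x[n] x*[(n - l) mod L],

whose DFT over n is the ambiguity function (so A[0, 0] is the signal energy)
and whose DFT over l is exactly the Rihaczek product form.  The asymmetric
lag absorbs the Rihaczek half-shift kernel e^{j theta tau / 2}: with no
Choi-Williams filtering the round trip through the ambiguity domain
reproduces (1/2pi) x[n] X*[k] e^{-j 2pi nk/L} to round-off.

Real-valued inputs are converted to their analytic form (negative-frequency
suppression) before the distribution is computed, so the phase is
single-sided; the returned frequency axis then spans [0, fs/2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "SignalEpoch",
    "TFDMatrix",
    "PhaseMatrix",
    "ambiguity",
    "choi_williams_kernel",
    "rid_rihaczek",
    "phase",
    "DEFAULT_KERNEL_SIGMA",
    "DEFAULT_FLOOR_REL",
]

#: Default Choi-Williams kernel parameter.  Small values strongly suppress
#: cross-terms of multicomponent signals.
DEFAULT_KERNEL_SIGMA = 0.01

#: Default magnitude floor for phase extraction, relative to max |C|.
DEFAULT_FLOOR_REL = 1e-12

_TWO_PI = 2.0 * np.pi


@dataclass
class SignalEpoch:
    """A single-channel epoch: samples, sampling rate and epoch start time.

    Parameters
    ----------
    samples
        Real (or already-analytic complex) vector, length >= 2, no NaNs.
    fs
        Sampling rate in Hz, > 0.
    t0
        Time of the first sample in ms relative to the event marker.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times in ms: t0 + k/fs * 1000, k = 0..L-1."""
        return self.t0 + np.arange(self.n_samples) / self.fs * 1000.0


@dataclass
class TFDMatrix:
    """Complex time-frequency distribution on a uniform (t, f) grid."""

    values: np.ndarray  # complex, [L_t x L_f]
    time_axis: np.ndarray  # ms
    freq_axis: np.ndarray  # Hz
    kernel_sigma: float = np.inf

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.values.shape != (self.time_axis.size, self.freq_axis.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.time_axis.size}, {self.freq_axis.size})"
            )
        if not self.kernel_sigma > 0:
            raise ValueError("kernel_sigma must be positive (inf allowed)")

    def same_grid(self, other: "TFDMatrix") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.time_axis, other.time_axis)
            and np.allclose(self.freq_axis, other.freq_axis)
        )


@dataclass
class PhaseMatrix:
    """Time-frequency phase in radians, wrapped to (-pi, pi].

    ``valid_mask`` is False wherever the distribution magnitude fell below
    the magnitude floor (phase undefined at zeros of C).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    time_axis: np.ndarray = field(default=None)
    freq_axis: np.ndarray = field(default=None)


def _as_complex_samples(signal, analytic: bool | None = None) -> np.ndarray:
    """Extract a complex sample vector, converting real input to analytic form."""
    if isinstance(signal, SignalEpoch):
        x = signal.samples
    else:
        x = np.asarray(signal)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("signal must be a 1-D vector of length >= 2")
    if np.iscomplexobj(x):
        return x.astype(np.complex128)
    if analytic is None:
        analytic = True
    x = x.astype(float)
    if analytic:
        return np.asarray(hilbert(x), dtype=np.complex128)
    return x.astype(np.complex128)


def _instantaneous_autocorr(x: np.ndarray) -> np.ndarray:
    """R[n, l] = x[n] x*[(n - l) mod L] on the circular lag grid."""
    L = x.size
    n = np.arange(L)
    idx = (n[:, None] - n[None, :]) % L  # [n, l]
    return x[:, None] * np.conj(x[idx])


def ambiguity(signal, analytic: bool | None = None) -> np.ndarray:
    """Discrete ambiguity function A[theta, tau] on an L x L DFT grid.

    Rows index Doppler (DFT bins over time), columns index circular lag.
    ``A[0, 0]`` equals the total signal energy sum |x[n]|^2.

    Real inputs are converted to their analytic form first unless
    ``analytic=False``.
    """
    x = _as_complex_samples(signal, analytic)
    if np.allclose(x, 0):
        warnings.warn("ambiguity of an all-zero signal is identically zero")
    R = _instantaneous_autocorr(x)
    return np.fft.fft(R, axis=0)


def choi_williams_kernel(L: int, sigma: float) -> np.ndarray:
    """Choi-Williams mask exp(-(theta*tau)^2/sigma) on the L x L (theta, tau) grid.

    theta is in radians/sample (signed DFT frequencies), tau in samples
    (signed circular lags); ``sigma=inf`` returns an all-ones mask (plain
    Rihaczek).
    """
    if not sigma > 0:
        raise ValueError(f"kernel sigma must be positive, got {sigma}")
    if np.isinf(sigma):
        return np.ones((L, L))
    theta = _TWO_PI * np.fft.fftfreq(L)  # rad/sample, signed
    tau = np.fft.fftfreq(L, d=1.0 / L)  # samples, signed
    return np.exp(-np.outer(theta, tau) ** 2 / sigma)


def rid_rihaczek(
    signal,
    sigma: float = DEFAULT_KERNEL_SIGMA,
    analytic: bool | None = None,
    one_sided: bool | None = None,
    fs: float | None = None,
    t0: float | None = None,
) -> TFDMatrix:
    """RID-Rihaczek distribution of a single-channel epoch.

    Parameters
    ----------
    signal
        A :class:`SignalEpoch`, or a plain vector (then ``fs``/``t0`` may be
        given; defaults fs=1, t0=0).
    sigma
        Choi-Williams kernel parameter; ``np.inf`` yields the plain Rihaczek
        distribution (exact product form).
    analytic
        Force or suppress analytic-signal conversion.  Default: convert
        real inputs, pass complex inputs through.
    one_sided
        Keep only the non-negative frequency half [0, fs/2].  Default: True
        for real inputs (analytic processing makes the negative half empty),
        False for complex inputs.

    Returns
    -------
    TFDMatrix
        Time x frequency complex matrix including the 1/2pi constant.
    """
    if isinstance(signal, SignalEpoch):
        fs = signal.fs if fs is None else fs
        t0 = signal.t0 if t0 is None else t0
        raw = signal.samples
    else:
        raw = np.asarray(signal)
    fs = 1.0 if fs is None else float(fs)
    t0 = 0.0 if t0 is None else float(t0)
    if one_sided is None:
        one_sided = not np.iscomplexobj(raw)

    x = _as_complex_samples(signal, analytic)
    L = x.size
    R = _instantaneous_autocorr(x)
    if np.isinf(sigma):
        # Kernel is identity: DFT over lag gives the exact product form.
        C = np.fft.fft(R, axis=1) / _TWO_PI
    else:
        A = np.fft.fft(R, axis=0)
        A *= choi_williams_kernel(L, sigma)
        C = np.fft.fft(np.fft.ifft(A, axis=0), axis=1) / _TWO_PI

    time_axis = t0 + np.arange(L) / fs * 1000.0
    freq_axis = np.arange(L) * fs / L
    if one_sided:
        keep = L // 2 + 1
        C = C[:, :keep]
        freq_axis = freq_axis[:keep]
    return TFDMatrix(values=C, time_axis=time_axis, freq_axis=freq_axis, kernel_sigma=sigma)


def phase(tfd: TFDMatrix, magnitude_floor: float | None = None) -> PhaseMatrix:
    """Time-frequency phase arg[C/|C|], masked where |C| is below the floor.

    ``magnitude_floor`` defaults to ``1e-12 * max|C|``; entries below it are
    marked invalid (phase of a vanishing complex number is undefined) and
    their value is set to 0.  Valid phases lie in (-pi, pi] with the
    convention arg(-1) = +pi.
    """
    C = tfd.values
    mag = np.abs(C)
    if magnitude_floor is None:
        magnitude_floor = DEFAULT_FLOOR_REL * mag.max() if mag.size else 0.0
    if magnitude_floor < 0:
        raise ValueError("magnitude_floor must be non-negative")
    valid = mag >= magnitude_floor
    if magnitude_floor == 0:
        valid &= mag > 0
    vals = np.where(valid, np.angle(C), 0.0)
    return PhaseMatrix(
        values=vals,
        valid_mask=valid,
        time_axis=tfd.time_axis,
        freq_axis=tfd.freq_axis,
    )
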