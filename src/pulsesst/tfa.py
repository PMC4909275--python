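"""Time-frequency analysis: Gaussian-window STFT, reassignment, synchrosqueezing.

The STFT used here is, for a window h,

    V(t, eta) = integral f(s) h(t - s) exp(-i 2 pi eta (t - s)) ds,

with the Gaussian window ``h(t) = (2 pi sigma)^(-1/2) exp(-t^2 / sigma^2)``.
Note the kernel's phase runs in ``t - s``; for a REAL signal this pairs the
positive-frequency axis with the conjugate analytic phase (a tone
``cos(2 pi xi0 t)`` produces coefficients proportional to
``exp(-i 2 pi xi0 t)`` near ``eta = +xi0``).  The demodulation layer undoes
this by conjugating the reconstructed component; within this module the
reassignment frequency

    omega(t, eta) = eta + Im(V_h'(t, eta) / V_h(t, eta)) / (2 pi)

is exact for tones (omega = +xi0) under this convention, with ``V_h'`` the
same transform taken with the differentiated window.

The synchrosqueezing transform (SST) reallocates each retained complex STFT
coefficient along the frequency axis into the output bin containing
``omega(t, eta)``, sharpening the representation while preserving per-time
invertibility: summing SST coefficients in a narrow band around a
component's instantaneous frequency and dividing by h(0) recovers the
component's analytic amplitude and phase.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import PulseSignal

__all__ = [
    "WindowSpec",
    "TFGrid",
    "STFTMatrix",
    "SSTMatrix",
    "gaussian_window",
    "stft",
    "reassignment_frequency",
    "synchrosqueeze",
    "sst_transform",
    "plot_tfr",
]

#: sentinel for "reassignment undefined" (magnitude below threshold)
OMEGA_UNDEFINED = -np.inf


@dataclass(frozen=True)
class WindowSpec:
    """Gaussian analysis window: kernel bandwidth sigma (s) and truncation."""

    sigma: float = 0.5
    half_width: float | None = None  # defaults to 4*sigma

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.half_width is None:
            object.__setattr__(self, "half_width", 4.0 * self.sigma)
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def h0(self) -> float:
        """Window value at 0: (2 pi sigma)^(-1/2)."""
        return 1.0 / math.sqrt(2.0 * math.pi * self.sigma)


@dataclass(frozen=True)
class TFGrid:
    """Uniform time/frequency grid of a TF representation."""

    times: np.ndarray
    freqs: np.ndarray
    dt: float
    df: float

    def __post_init__(self):
        for ax, step in ((self.times, self.dt), (self.freqs, self.df)):
            d = np.diff(ax)
            if ax.size > 1 and not np.allclose(d, step, rtol=1e-9, atol=1e-12):
                raise ValueError("grid axes must be uniform")


@dataclass(frozen=True)
class STFTMatrix:
    grid: TFGrid
    values: np.ndarray    # frames x frequency bins, complex
    dvalues: np.ndarray   # same, window derivative
    window: WindowSpec

    def __post_init__(self):
        shape = (self.grid.times.size, self.grid.freqs.size)
        if self.values.shape != shape or self.dvalues.shape != shape:
            raise ValueError("matrix shapes inconsistent with grid")


@dataclass(frozen=True)
class SSTMatrix:
    grid: TFGrid
    values: np.ndarray   # frames x output bins, complex
    omega: np.ndarray    # reassignment frequency (Hz), OMEGA_UNDEFINED sentinel
    window: WindowSpec

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def gaussian_window(spec: WindowSpec, fs: float):
    """Sample h and h' on [-half_width, half_width] at 1/fs spacing.

    Returns ``(t, h, dh)``.  The normalization ``(2 pi sigma)^(-1/2)`` is a
    fixed constant; it cancels in the band reconstruction through the
    ``h(0)^-1`` factor.
    """
    if spec.half_width < 2.0 / fs:
        raise ValueError("window too short for the sampling rate")
    L = int(math.floor(spec.half_width * fs))
    t = np.arange(-L, L + 1) / fs
    h = spec.h0() * np.exp(-(t ** 2) / spec.sigma ** 2)
    dh = -2.0 * t / spec.sigma ** 2 * h
    return t, h, dh


def stft(signal: PulseSignal, spec: WindowSpec | None = None,
         freq_max: float = 10.0, df: float = 0.02,
         hop: int = 1) -> STFTMatrix:
    """Discretized Gaussian-window STFT (and its derivative-window partner).

    Frames are centered on every ``hop``-th sample; the signal is
    zero-padded at the boundaries.  The frequency axis is
    ``0, df, ..., <= freq_max`` with ``df`` realized exactly as
    ``fs / nfft`` (``nfft = round(fs / df)``), so the transform is computed
    by a zero-padded FFT of each windowed segment.
    """
    spec = spec or WindowSpec()
    x = signal.samples
    fs = signal.fs
    if freq_max > fs / 2:
        raise ValueError("freq_max exceeds the Nyquist frequency")
    _, h, dh = gaussian_window(spec, fs)
    L = (h.size - 1) // 2
    if h.size > x.size:
        raise ValueError("window longer than the signal")
    nfft = int(round(fs / df))
    if nfft < h.size:
        raise ValueError("df too coarse for the window length")
    df_exact = fs / nfft
    nbins = int(math.floor(freq_max / df_exact + 1e-9)) + 1
    frame_idx = np.arange(0, x.size, hop)
    times = signal.t0 + frame_idx / fs

    xp = np.pad(x, L)
    # segments[m, j] = x[frame m + j - L]
    offs = np.arange(2 * L + 1)
    values = np.empty((frame_idx.size, nbins), dtype=complex)
    dvalues = np.empty_like(values)
    # wrap offsets u = k/fs, k = -L..L into FFT buffer positions (k mod nfft)
    cols = np.concatenate((np.arange(L, 2 * L + 1) - L,          # k = 0..L
                           nfft + np.arange(-L, 0)))             # k = -L..-1
    order = np.concatenate((np.arange(L, 2 * L + 1), np.arange(0, L)))
    dt = 1.0 / fs
    chunk = 256
    buf = np.zeros((min(chunk, frame_idx.size), nfft), dtype=float)
    for start in range(0, frame_idx.size, chunk):
        idx = frame_idx[start:start + chunk]
        segs = xp[idx[:, None] + offs[None, :]]
        b = buf[:idx.size]
        for win, out in ((h, values), (dh, dvalues)):
            b[:, :] = 0.0
            b[:, cols] = (segs * win)[:, order]
            # V[j] = dt * sum_k f h e^{+i 2 pi j k / nfft}  (Eq kernel in t-s)
            out[start:start + idx.size] = (
                dt * nfft * np.fft.ifft(b, axis=1)[:, :nbins])
    freqs = np.arange(nbins) * df_exact
    grid = TFGrid(times=times, freqs=freqs, dt=hop / fs, df=df_exact)
    return STFTMatrix(grid=grid, values=values, dvalues=dvalues, window=spec)


def reassignment_frequency(stft_mat: STFTMatrix,
                           threshold: float = 1e-4) -> np.ndarray:
    """Reassignment frequency omega(t, eta), sentinel where undefined.

    omega = eta + Im(V_h' / V_h) / (2 pi) wherever |V_h| >= threshold times
    the frame maximum; elsewhere the sentinel -inf (the "otherwise" branch).
    """
    mag = np.abs(stft_mat.values)
    frame_max = mag.max(axis=1, keepdims=True)
    keep = mag >= threshold * np.where(frame_max > 0, frame_max, 1.0)
    keep &= mag > 0
    omega = np.full(mag.shape, OMEGA_UNDEFINED)
    ratio = np.zeros_like(stft_mat.values)
    np.divide(stft_mat.dvalues, stft_mat.values, out=ratio, where=keep)
    om = stft_mat.grid.freqs[None, :] + ratio.imag / (2.0 * np.pi)
    omega[keep] = om[keep]
    return omega


def synchrosqueeze(stft_mat: STFTMatrix, omega: np.ndarray,
                   out_freqs: np.ndarray | None = None,
                   threshold: float = 1e-4) -> SSTMatrix:
    """Histogram-kernel synchrosqueezing of the STFT coefficients.

    Every STFT coefficient whose magnitude survives the threshold is added
    (complex, phase preserved) into the output bin containing its
    reassignment frequency, scaled by the input bin width.  Coefficients
    reassigned outside the output axis are dropped.
    """
    grid = stft_mat.grid
    if out_freqs is None:
        out_freqs = grid.freqs
    out_freqs = np.asarray(out_freqs, dtype=float)
    dfo = np.diff(out_freqs)
    if out_freqs.size < 2 or not np.allclose(dfo, dfo[0], rtol=1e-9):
        raise ValueError("output frequency axis must be uniform")
    dfo = dfo[0]
    mag = np.abs(stft_mat.values)
    frame_max = mag.max(axis=1, keepdims=True)
    keep = (mag >= threshold * np.where(frame_max > 0, frame_max, 1.0))
    keep &= np.isfinite(omega)

    nT, _ = stft_mat.values.shape
    nF = out_freqs.size
    om_safe = np.where(np.isfinite(omega), omega, out_freqs[0] - dfo)
    bins = np.round((om_safe - out_freqs[0]) / dfo).astype(np.int64)
    valid = keep & (bins >= 0) & (bins < nF)
    fr = np.broadcast_to(np.arange(nT)[:, None], bins.shape)
    flat = (fr[valid] * nF + bins[valid])
    # histogram kernel: each retained coefficient contributes V * d_eta,
    # normalized by the output bin width so S is a density in frequency
    w = stft_mat.values[valid] * (grid.df / dfo)
    acc = (np.bincount(flat, weights=w.real, minlength=nT * nF)
           + 1j * np.bincount(flat, weights=w.imag, minlength=nT * nF))
    values = acc.reshape(nT, nF)
    out_grid = TFGrid(times=grid.times, freqs=out_freqs, dt=grid.dt, df=dfo)
    return SSTMatrix(grid=out_grid, values=values, omega=omega,
                     window=stft_mat.window)


def sst_transform(signal: PulseSignal, spec: WindowSpec | None = None,
                  freq_max: float = 10.0, df: float = 0.02, hop: int = 1,
                  threshold: float = 1e-4) -> SSTMatrix:
    """Convenience: STFT -> reassignment -> synchrosqueeze in one call."""
    V = stft(signal, spec=spec, freq_max=freq_max, df=df, hop=hop)
    omega = reassignment_frequency(V, threshold=threshold)
    return synchrosqueeze(V, omega, threshold=threshold)


def plot_tfr(tfr: STFTMatrix | SSTMatrix, ax=None, floor_db: float = -60.0):
    """Log-magnitude image of a TF representation (matplotlib optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mag = np.abs(tfr.values).T
    ref = mag.max()
    db = 20.0 * np.log10(np.maximum(mag, 1e-300) / max(ref, 1e-300))
    g = tfr.grid
    im = ax.imshow(np.maximum(db, floor_db), origin="lower", aspect="auto",
                   extent=(g.times[0], g.times[-1], g.freqs[0], g.freqs[-1]))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return im
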