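"""Band-pass filter banks and envelope extraction.

Two banks drive the analysis: a cochlear-style acoustic bank (default 28
channels, 100-7250 Hz, spaced on the ERB_N number scale) and a modulation-rate
bank (default 24 channels, 0.9-40 Hz, log spaced) applied to amplitude
envelopes.  Channels are second-order Butterworth band-passes applied
forward-backward (zero phase); envelopes are Hilbert magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

__all__ = [
    "FilterBankSpec",
    "ChannelMatrix",
    "erb_number",
    "erb_number_to_hz",
    "design_bank",
    "apply_bank",
    "hilbert_env",
    "downsample_env",
]


def erb_number(f_hz):
    """ERB-number (Cam) of a frequency in Hz: 21.4*log10(0.00437*f + 1)."""
    return 21.4 * np.log10(0.00437 * np.asarray(f_hz, dtype=float) + 1.0)


def erb_number_to_hz(cam):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(cam, dtype=float) / 21.4) - 1.0) / 0.00437


@dataclass(frozen=True)
class FilterBankSpec:
    """Channel layout of a band-pass bank.

    ``edges`` has ``n_channels + 1`` strictly increasing entries from ``f_lo``
    to ``f_hi``; ``centers`` sit midway between their edges on the spacing
    scale.  ``order`` is the Butterworth order of each channel filter (applied
    forward-backward, so the effective magnitude order doubles).
    """

    n_channels: int
    f_lo: float
    f_hi: float
    spacing: str  # "erb_n" or "log"
    edges: tuple
    centers: tuple
    order: int = 2

    def __post_init__(self):
        edges = np.asarray(self.edges)
        if len(edges) != self.n_channels + 1:
            raise ValueError("edge count must be n_channels + 1")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("channel edges must be strictly increasing")
        for c, lo, hi in zip(self.centers, edges[:-1], edges[1:]):
            if not (lo < c < hi):
                raise ValueError("channel center outside its edges")

    def to_text(self) -> str:
        lines = [
            f"n_channels\t{self.n_channels}",
            f"f_lo\t{self.f_lo:.6g}",
            f"f_hi\t{self.f_hi:.6g}",
            f"spacing\t{self.spacing}",
            f"order\t{self.order}",
            "edges_hz\t" + "\t".join(f"{e:.6g}" for e in self.edges),
            "centers_hz\t" + "\t".join(f"{c:.6g}" for c in self.centers),
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FilterBankSpec":
        kv = {}
        for line in text.strip().splitlines():
            key, *vals = line.split("\t")
            kv[key] = vals
        return cls(
            n_channels=int(kv["n_channels"][0]),
            f_lo=float(kv["f_lo"][0]),
            f_hi=float(kv["f_hi"][0]),
            spacing=kv["spacing"][0],
            edges=tuple(float(v) for v in kv["edges_hz"]),
            centers=tuple(float(v) for v in kv["centers_hz"]),
            order=int(kv["order"][0]),
        )


@dataclass
class ChannelMatrix:
    """Time x channel array of band-passed signal or envelope samples."""

    values: np.ndarray  # shape (n_samples, n_channels)
    fs: float
    bank: FilterBankSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.bank.n_channels:
            raise ValueError("values must be (time, n_channels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite channel values")


def design_bank(f_lo: float, f_hi: float, n_channels: int, spacing: str = "erb_n",
                order: int = 2) -> FilterBankSpec:
    """Lay out ``n_channels`` contiguous band-pass channels over [f_lo, f_hi].

    ``spacing='erb_n'`` places edges uniformly on the ERB-number scale (the
    auditory-filter spacing used for the acoustic bank); ``spacing='log'``
    places them uniformly in log-frequency (used for the modulation bank).
    Centers are edge midpoints on the same scale.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if spacing == "erb_n":
        lo, hi = erb_number(f_lo), erb_number(f_hi)
        edges = erb_number_to_hz(np.linspace(lo, hi, n_channels + 1))
        centers = erb_number_to_hz((erb_number(edges[:-1]) + erb_number(edges[1:])) / 2)
    elif spacing == "log":
        edges = np.geomspace(f_lo, f_hi, n_channels + 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    # pin the outer edges exactly to the requested range
    edges[0], edges[-1] = f_lo, f_hi
    return FilterBankSpec(
        n_channels=n_channels, f_lo=f_lo, f_hi=f_hi, spacing=spacing,
        edges=tuple(edges), centers=tuple(centers), order=order,
    )


def _channel_sos(lo: float, hi: float, fs: float, order: int):
    nyq = fs / 2.0
    hi = min(hi, 0.999 * nyq)
    if lo >= hi:
        raise ValueError(f"channel [{lo}, {hi}] Hz collapses at fs={fs}")
    return butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def apply_bank(signal: np.ndarray, fs: float, spec: FilterBankSpec) -> ChannelMatrix:
    """Band-pass ``signal`` through every channel (zero-phase filtering)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if fs <= 2 * spec.f_hi:
        raise ValueError(f"fs={fs} too low for bank up to {spec.f_hi} Hz")
    out = np.empty((signal.size, spec.n_channels))
    for k, (lo, hi) in enumerate(zip(spec.edges[:-1], spec.edges[1:])):
        try:
            sos = _channel_sos(lo, hi, fs, spec.order)
            out[:, k] = sosfiltfilt(sos, signal)
        except ValueError as err:
            raise ValueError(f"channel {k} ({lo:.3g}-{hi:.3g} Hz): {err}") from err
        if not np.all(np.isfinite(out[:, k])):
            raise ValueError(f"unstable filter output in channel {k} ({lo:.3g}-{hi:.3g} Hz)")
    return ChannelMatrix(values=out, fs=fs, bank=spec)


def hilbert_env(x: np.ndarray) -> np.ndarray:
    """Hilbert envelope (magnitude of the analytic signal) along axis 0."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    nfft = next_fast_len(n)
    return np.abs(hilbert(x, N=nfft, axis=0)[:n])


def downsample_env(env: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-aliased resampling of an envelope to ``target_fs``.

    Uses polyphase resampling with the rational ratio closest to
    ``target_fs / fs``; envelopes are clipped at zero afterwards since the
    anti-aliasing filter can ring slightly negative.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == fs:
        return np.asarray(env, dtype=float)
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    out = resample_poly(np.asarray(env, dtype=float), frac.numerator, frac.denominator, axis=0)
    return np.clip(out, 0.0, None)
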