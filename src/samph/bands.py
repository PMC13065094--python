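"""Modulation-band discovery via PCA on channel envelopes.

Per speech file, PCA is run on the channel-envelope matrix (correlation
convention by default: channels standardized so the 1/f power tilt does not
swamp the loading shape).  Absolute component loadings are grand-averaged
across files; peaks in the averaged loading patterns mark co-modulated
channel clusters and flanking troughs mark band boundaries.  The spectral
domain retains five components and expects five bands; the temporal domain
retains three components and expects three bands.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences
from sklearn.decomposition import PCA

from .filterbank import (ChannelMatrix, FilterBankSpec, apply_bank, design_bank,
                         downsample_env, hilbert_env, _channel_sos)
from scipy.signal import sosfiltfilt

log = logging.getLogger(__name__)

__all__ = [
    "LoadingMatrix",
    "Band",
    "BandSet",
    "PeakCriteria",
    "SPECTRAL_CRITERIA",
    "TEMPORAL_CRITERIA",
    "pca_loadings",
    "grand_average",
    "detect_peaks_troughs",
    "infer_bands",
    "spectral_envelopes",
    "temporal_loadings",
    "temporal_pipeline",
]


@dataclass
class LoadingMatrix:
    """Absolute PCA loadings (channels x components) with variance fractions."""

    abs_loadings: np.ndarray
    variance_fraction: np.ndarray
    bank: FilterBankSpec | None = None

    def __post_init__(self):
        self.abs_loadings = np.asarray(self.abs_loadings, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.abs_loadings.ndim != 2:
            raise ValueError("abs_loadings must be channels x components")
        if self.abs_loadings.shape[1] != self.variance_fraction.size:
            raise ValueError("one variance fraction per component")

    @property
    def n_channels(self) -> int:
        return self.abs_loadings.shape[0]

    @property
    def n_components(self) -> int:
        return self.abs_loadings.shape[1]


@dataclass(frozen=True)
class Band:
    lo: float
    hi: float
    peak_channel: int
    components: tuple = ()

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("band hi must exceed lo")


@dataclass
class BandSet:
    """Contiguous, non-overlapping bands tiling the bank's [f_lo, f_hi]."""

    bands: list
    domain: str  # "spectral" or "temporal"

    def __post_init__(self):
        for a, b in zip(self.bands[:-1], self.bands[1:]):
            if abs(a.hi - b.lo) > 1e-9 * max(abs(a.hi), 1.0):
                raise ValueError("bands must be contiguous")

    def __len__(self):
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def edges(self) -> list:
        return [self.bands[0].lo] + [b.hi for b in self.bands]


@dataclass(frozen=True)
class PeakCriteria:
    """Peak/trough acceptance rules for loading patterns."""

    min_separation: int  # channels between retained peaks
    low_cycle_threshold: float = 0.10  # fraction of the mean excursion

    def __post_init__(self):
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if not (0 < self.low_cycle_threshold < 1):
            raise ValueError("low_cycle_threshold must lie in (0, 1)")


SPECTRAL_CRITERIA = PeakCriteria(min_separation=2)
TEMPORAL_CRITERIA = PeakCriteria(min_separation=5)


def pca_loadings(env: ChannelMatrix | np.ndarray, n_components: int,
                 bank: FilterBankSpec | None = None,
                 standardize: bool = False) -> LoadingMatrix:
    """PCA of the channel-envelope matrix of one speech file.

    The default is the covariance convention: channels enter with their
    actual envelope variance, so loadings reflect where co-modulated energy
    lives.  ``standardize=True`` selects the correlation convention
    (channels z-scored first); that equalizes channels regardless of energy,
    which lets near-empty channels between AM bands dominate the retained
    components, so it is not the default.  Constant channels are dropped
    with a warning and re-inserted as zero loadings so the channel axis is
    stable.  Returns unit-norm components as absolute loadings, ordered by
    explained variance.
    """
    if isinstance(env, ChannelMatrix):
        bank = env.bank
        x = env.values
    else:
        x = np.asarray(env, dtype=float)
    n_t, n_ch = x.shape
    if n_t < 10 * n_ch:
        raise ValueError(f"need >= 10x more time samples ({n_t}) than channels ({n_ch})")
    sd = x.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        log.warning("dropping %d constant channel(s) before PCA", int((~keep).sum()))
    xk = x[:, keep]
    if standardize:
        xk = (xk - xk.mean(axis=0)) / xk.std(axis=0)
    k = min(n_components, xk.shape[1])
    pca = PCA(n_components=k)
    pca.fit(xk)
    loadings = np.zeros((n_ch, k))
    loadings[keep, :] = np.abs(pca.components_.T)
    return LoadingMatrix(abs_loadings=loadings,
                         variance_fraction=pca.explained_variance_ratio_,
                         bank=bank)


def grand_average(loadings: list) -> LoadingMatrix:
    """Element-wise mean of absolute loadings (and variance fractions)."""
    if not loadings:
        raise ValueError("empty loading list")
    shapes = {lm.abs_loadings.shape for lm in loadings}
    if len(shapes) != 1:
        raise ValueError("loading matrices must share a shape")
    return LoadingMatrix(
        abs_loadings=np.mean([lm.abs_loadings for lm in loadings], axis=0),
        variance_fraction=np.mean([lm.variance_fraction for lm in loadings], axis=0),
        bank=loadings[0].bank,
    )


def detect_peaks_troughs(column: np.ndarray, criteria: PeakCriteria):
    """Find retained peaks and their flanking troughs in one loading column.

    Local maxima closer than ``min_separation`` channels keep only the larger;
    excursions whose prominence is below ``low_cycle_threshold`` of the mean
    prominence are treated as ripple and discarded.  Troughs are the minima
    between consecutive retained peaks.  Monotone input yields empty lists.
    """
    col = np.asarray(column, dtype=float)
    if col.size < 3:
        raise ValueError("need at least 3 channels")
    peaks, _ = find_peaks(col, distance=criteria.min_separation)
    if peaks.size:
        prom = peak_prominences(col, peaks)[0]
        mean_prom = prom.mean()
        if mean_prom > 0:
            peaks = peaks[prom >= criteria.low_cycle_threshold * mean_prom]
    troughs = []
    for p1, p2 in zip(peaks[:-1], peaks[1:]):
        troughs.append(p1 + int(np.argmin(col[p1:p2 + 1])))
    return list(peaks), troughs


def infer_bands(loading_matrices, bank: FilterBankSpec, criteria: PeakCriteria,
                target_bands: int | None = None, domain: str = "spectral",
                exclude_componentless_pc1: bool = True) -> BandSet:
    """Pool troughs across components (and corpora slices) into band boundaries.

    ``loading_matrices`` is a list of :class:`LoadingMatrix` (e.g. one per
    spectral band in the temporal domain, or a single grand average).  PC1 is
    excluded when it lacks interior troughs (it typically reflects global
    coherence rather than banded structure).  Boundaries are placed at the
    modal trough channels; ties break toward the lower-frequency channel.
    If the data support fewer boundaries than ``target_bands - 1``, the
    discovered count is returned with a warning.
    """
    trough_counts: Counter = Counter()
    peak_counts: Counter = Counter()
    peak_support: dict = {}
    for lm in loading_matrices:
        for comp in range(lm.n_components):
            peaks, troughs = detect_peaks_troughs(lm.abs_loadings[:, comp], criteria)
            if comp == 0 and exclude_componentless_pc1 and not troughs:
                continue
            for tr in troughs:
                trough_counts[tr] += 1
            for pk in peaks:
                peak_counts[pk] += 1
                peak_support.setdefault(pk, set()).add(comp + 1)

    n_boundaries = None if target_bands is None else target_bands - 1
    # modal trough channels, most frequent first; ties toward lower channel
    ranked = sorted(trough_counts, key=lambda c: (-trough_counts[c], c))
    chosen: list = []
    for c in ranked:
        if any(abs(c - o) < criteria.min_separation for o in chosen):
            continue
        chosen.append(c)
        if n_boundaries is not None and len(chosen) == n_boundaries:
            break
    if n_boundaries is not None and len(chosen) < n_boundaries:
        log.warning("%s domain: only %d of %d expected boundaries found",
                    domain, len(chosen), n_boundaries)
    chosen.sort()

    edges = np.asarray(bank.edges)
    bounds = [bank.f_lo] + [float(edges[c]) for c in chosen] + [bank.f_hi]
    bands = []
    lo_ch = 0
    for lo, hi, hi_ch in zip(bounds[:-1], bounds[1:], chosen + [bank.n_channels]):
        in_band = [p for p in peak_counts if lo_ch <= p < hi_ch]
        peak_ch = max(in_band, key=lambda p: peak_counts[p]) if in_band else lo_ch
        comps = sorted(set().union(set(), *(peak_support.get(p, set()) for p in in_band)))
        bands.append(Band(lo=lo, hi=hi, peak_channel=peak_ch, components=tuple(comps)))
        lo_ch = hi_ch
    return BandSet(bands=bands, domain=domain)


# ---------------------------------------------------------------------------
# Pipelines from a preprocessed speech file to loadings

def spectral_envelopes(file, bank: FilterBankSpec, env_fs: float = 1050.0) -> ChannelMatrix:
    """28-channel Hilbert envelopes of the waveform, downsampled for PCA."""
    cm = apply_bank(file.samples, file.fs, bank)
    env = hilbert_env(cm.values)
    env = downsample_env(env, file.fs, env_fs)
    return ChannelMatrix(values=env, fs=env_fs, bank=bank)


def _band_limited_envelope(file, lo: float, hi: float, env_fs: float) -> np.ndarray:
    """Hilbert envelope of the waveform restricted to one spectral band."""
    sos = _channel_sos(lo, hi, file.fs, order=2)
    band_sig = sosfiltfilt(sos, file.samples)
    env = hilbert_env(band_sig)
    return downsample_env(env, file.fs, env_fs)


def temporal_loadings(file, spectral_bands: BandSet, mod_bank: FilterBankSpec,
                      n_components: int = 3, env_fs: float = 120.0,
                      trim_pad_s: float | None = None,
                      standardize: bool = False) -> list:
    """Per-spectral-band temporal loading matrices for one file.

    For each spectral band: band-pass the raw signal, Hilbert envelope,
    downsample, pass through the modulation filter bank, envelope each
    modulation channel, trim the end pads, PCA.
    """
    pad_s = file.pad_s if trim_pad_s is None else trim_pad_s
    n_pad = int(round(pad_s * env_fs))
    out = []
    for band in spectral_bands:
        env = _band_limited_envelope(file, band.lo, band.hi, env_fs)
        mods = apply_bank(env, env_fs, mod_bank)
        menv = hilbert_env(mods.values)
        if n_pad:
            menv = menv[n_pad:-n_pad]
        out.append(pca_loadings(menv, n_components, bank=mod_bank,
                                standardize=standardize))
    return out


def temporal_pipeline(files, spectral_bands: BandSet,
                      mod_bank: FilterBankSpec | None = None,
                      n_components: int = 3, env_fs: float = 120.0,
                      criteria: PeakCriteria = TEMPORAL_CRITERIA,
                      target_bands: int = 3, standardize: bool = False):
    """Temporal-domain band discovery over a corpus of preprocessed files.

    Returns (per-spectral-band grand-average LoadingMatrix list, temporal
    BandSet inferred from loadings pooled over spectral bands).
    """
    if mod_bank is None:
        mod_bank = design_bank(0.9, 40.0, 24, spacing="log")
    per_band: list[list] = [[] for _ in spectral_bands]
    for f in files:
        for i, lm in enumerate(temporal_loadings(f, spectral_bands, mod_bank,
                                                 n_components, env_fs,
                                                 standardize=standardize)):
            per_band[i].append(lm)
    averages = [grand_average(lms) for lms in per_band]
    bands = infer_bands(averages, mod_bank, criteria,
                        target_bands=target_bands, domain="temporal")
    return averages, bands
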