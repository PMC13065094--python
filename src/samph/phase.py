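"""n:m phase synchronization between temporal AM bands.

The phase synchronization index (PSI) is the magnitude of the time-averaged
unit phasor of the generalized phase difference n*theta1 - m*theta2, where
theta1 and theta2 are the instantaneous Hilbert phases of the slower and
faster AM band modulators.  PSI = 1 means perfect n:m locking, PSI = 0 no
locking.  The n:m multipliers are determined from mean cycle lengths
(e.g. cycle lengths 2000 ms and 1500 ms give n:m = 4:3) snapped to a small
integer grid; the fixed grid ratios 1:2, 1:3 and 2:3 are also evaluated for
every file so register contrasts can be computed per ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import gcd

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.signal import find_peaks, hilbert, sosfiltfilt

from .filterbank import _channel_sos

log = logging.getLogger(__name__)

__all__ = [
    "PhaseSeries",
    "RatioPair",
    "PsiRecord",
    "MfpRecord",
    "DEFAULT_RATIO_LABELS",
    "ratio_from_label",
    "candidate_grid",
    "band_modulator",
    "inst_phase",
    "mean_cycle_length",
    "determine_ratio",
    "psi",
    "psi_profile",
    "mfp",
    "aggregate_by_age",
]


@dataclass(frozen=True)
class RatioPair:
    """n:m multipliers for a slow:fast cycle-count label.

    A label ``a:b`` (a slow cycles against b fast cycles) maps to multipliers
    ``(n, m) = (b, a)``: n scales the slower phase, m the faster, and under
    exact locking n/m = f_fast/f_slow.
    """

    label: str
    n: int
    m: int

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValueError("multipliers must be positive")
        if gcd(self.n, self.m) != 1:
            raise ValueError("multipliers must be coprime")

    @property
    def value(self) -> float:
        """f_fast / f_slow under exact locking."""
        return self.n / self.m


def ratio_from_label(label: str) -> RatioPair:
    a, b = (int(v) for v in label.split(":"))
    return RatioPair(label=label, n=b, m=a)


DEFAULT_RATIO_LABELS = ("1:2", "1:3", "2:3")


def candidate_grid(max_integer: int = 4) -> tuple:
    """All coprime slow:fast labels a:b with 1 <= a <= b <= max_integer."""
    out = []
    for a in range(1, max_integer + 1):
        for b in range(a, max_integer + 1):
            if gcd(a, b) == 1:
                out.append(RatioPair(label=f"{a}:{b}", n=b, m=a))
    return tuple(out)


@dataclass
class PhaseSeries:
    theta: np.ndarray  # unwrapped instantaneous phase, radians
    fs: float
    band: tuple | None = None  # (lo, hi) Hz of the source AM band

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite phases")


@dataclass(frozen=True)
class PsiRecord:
    psi: float
    ratio: RatioPair
    spectral_band: object
    temporal_bands: tuple = ()
    group: str = ""
    speaker: str = ""
    age_months: float = float("nan")
    file: str = ""

    def __post_init__(self):
        if not (0.0 <= self.psi <= 1.0 + 1e-12):
            raise ValueError("PSI must lie in [0, 1]")


@dataclass(frozen=True)
class MfpRecord:
    spectral_band: object
    mfp: float
    group: str = ""
    speaker: str = ""
    age_months: float = float("nan")
    file: str = ""

    def __post_init__(self):
        if self.mfp < 0:
            raise ValueError("mean frequency power must be >= 0")


def band_modulator(envelope: np.ndarray, fs: float, band: tuple,
                   trim_s: float = 0.0) -> np.ndarray:
    """Band-limit an envelope to one temporal AM band and remove its mean.

    ``trim_s`` seconds are cut from both ends afterwards (the silent pads
    absorb the filter transients and are excluded from all statistics).
    """
    lo, hi = band
    sos = _channel_sos(lo, hi, fs, order=2)
    x = sosfiltfilt(sos, np.asarray(envelope, dtype=float))
    n_trim = int(round(trim_s * fs))
    if n_trim:
        x = x[n_trim:-n_trim]
    return x - x.mean()


def inst_phase(series: np.ndarray, fs: float, band: tuple | None = None) -> PhaseSeries:
    """Unwrapped phase of the analytic signal."""
    x = np.asarray(series, dtype=float)
    nfft = next_fast_len(x.size)
    theta = np.unwrap(np.angle(hilbert(x, N=nfft)[: x.size]))
    return PhaseSeries(theta=theta, fs=fs, band=band)


def mean_cycle_length(series: np.ndarray, fs: float,
                      low_cycle_threshold: float = 0.10) -> float:
    """Mean cycle length in ms from successive envelope peaks.

    A cycle's peak-to-peak amplitude is taken as the peak's prominence.
    Cycles below ``low_cycle_threshold`` of the average cycle amplitude are
    treated as noise and excluded; the average itself is computed after
    discarding sub-threshold ripple relative to the largest cycle, so that
    superimposed fast ripple cannot drag the reference amplitude down.
    Excluded peaks stop being cycle boundaries (their spans merge into the
    neighboring cycles).  Fewer than two retained cycles is an error.
    """
    from scipy.signal import peak_prominences

    x = np.asarray(series, dtype=float)
    peaks, _ = find_peaks(x)
    if peaks.size < 3:
        raise ValueError("too few peaks to estimate a cycle length")
    prom = peak_prominences(x, peaks)[0]
    strong = prom >= low_cycle_threshold * prom.max()
    mean_amp = prom[strong].mean()
    kept = peaks[prom >= low_cycle_threshold * mean_amp]
    if kept.size < 3:
        raise ValueError("fewer than two retained cycles")
    return float(np.mean(np.diff(kept)) / fs * 1000.0)


def determine_ratio(t_slow_ms: float, t_fast_ms: float,
                    candidates: tuple | None = None) -> RatioPair:
    """Snap the cycle-length ratio to the nearest candidate n:m.

    ``t_slow / t_fast = n / m``; e.g. cycle lengths 2000 ms and 1500 ms give
    n:m = 4:3.  Ratios beyond the grid clamp to the nearest extreme with a
    warning.
    """
    if not (t_slow_ms >= t_fast_ms > 0):
        raise ValueError("need t_slow >= t_fast > 0")
    if candidates is None:
        candidates = candidate_grid()
    r = t_slow_ms / t_fast_ms
    lo, hi = min(c.value for c in candidates), max(c.value for c in candidates)
    if r < lo or r > hi:
        log.warning("cycle ratio %.3f outside candidate grid [%g, %g]", r, lo, hi)
    return min(candidates, key=lambda c: abs(c.value - r))


def psi(theta1: np.ndarray | PhaseSeries, theta2: np.ndarray | PhaseSeries,
        n: int, m: int) -> float:
    """Phase synchronization index |< exp(i*(n*theta1 - m*theta2)) >|.

    ``theta1`` is the slower band's phase, ``theta2`` the faster's.
    """
    t1 = theta1.theta if isinstance(theta1, PhaseSeries) else np.asarray(theta1, float)
    t2 = theta2.theta if isinstance(theta2, PhaseSeries) else np.asarray(theta2, float)
    if t1.shape != t2.shape:
        raise ValueError("phase series must have equal length")
    if t1.size < 100:
        raise ValueError("need at least 100 samples")
    return float(np.abs(np.mean(np.exp(1j * (n * t1 - m * t2)))))


def psi_profile(band_envelopes: dict, env_fs: float, temporal_bands,
                ratio_labels=DEFAULT_RATIO_LABELS, trim_s: float = 0.0,
                **provenance) -> list:
    """PSI records for one file: every spectral band x requested ratio.

    ``band_envelopes`` maps spectral-band id -> envelope series at ``env_fs``.
    PSI is computed between the two slowest entries of ``temporal_bands``.
    The cycle-length-determined ratio is reported per band under the label
    ``auto:<label>``, and spectral-band-averaged values are emitted under
    spectral band id ``"mean"``.
    """
    bands = sorted(temporal_bands, key=lambda b: b[0])[:2]
    slow_band, fast_band = bands[0], bands[1]
    records: list[PsiRecord] = []
    per_ratio: dict = {}
    for sb, env in band_envelopes.items():
        m_slow = band_modulator(env, env_fs, slow_band, trim_s=trim_s)
        m_fast = band_modulator(env, env_fs, fast_band, trim_s=trim_s)
        th1 = inst_phase(m_slow, env_fs, band=slow_band)
        th2 = inst_phase(m_fast, env_fs, band=fast_band)
        ratios = [ratio_from_label(lbl) for lbl in ratio_labels]
        try:
            t_slow = mean_cycle_length(m_slow, env_fs)
            t_fast = mean_cycle_length(m_fast, env_fs)
            auto = determine_ratio(t_slow, t_fast)
            ratios.append(RatioPair(label=f"auto:{auto.label}", n=auto.n, m=auto.m))
        except ValueError as err:
            log.warning("cycle-ratio determination failed for band %s: %s", sb, err)
        for rp in ratios:
            value = psi(th1, th2, rp.n, rp.m)
            records.append(PsiRecord(psi=value, ratio=rp, spectral_band=sb,
                                     temporal_bands=(tuple(slow_band), tuple(fast_band)),
                                     **provenance))
            if not rp.label.startswith("auto:"):
                per_ratio.setdefault(rp.label, []).append(value)
    for lbl, vals in per_ratio.items():
        records.append(PsiRecord(psi=float(np.mean(vals)), ratio=ratio_from_label(lbl),
                                 spectral_band="mean",
                                 temporal_bands=(tuple(slow_band), tuple(fast_band)),
                                 **provenance))
    return records


def mfp(envelope: np.ndarray, fs: float | None = None, trim_s: float = 0.0,
        **provenance) -> MfpRecord:
    """Mean frequency power: mean squared envelope over the trimmed interior."""
    x = np.asarray(envelope, dtype=float)
    n_trim = int(round(trim_s * fs)) if (trim_s and fs) else 0
    if n_trim:
        x = x[n_trim:-n_trim]
    return MfpRecord(mfp=float(np.mean(x ** 2)),
                     spectral_band=provenance.pop("spectral_band", None), **provenance)


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate PSI or MFP records (tab-friendly flat columns)."""
    rows = []
    for r in records:
        d = {"file": r.file, "group": r.group, "speaker": r.speaker,
             "age_months": r.age_months, "spectral_band": r.spectral_band}
        if isinstance(r, PsiRecord):
            d.update(ratio_label=r.ratio.label, n=r.ratio.n, m=r.ratio.m, psi=r.psi)
        else:
            d.update(mfp=r.mfp)
        rows.append(d)
    return pd.DataFrame(rows)


def aggregate_by_age(records: pd.DataFrame | list, value: str = "psi") -> pd.DataFrame:
    """Mean of ``value`` over children within each group x age-month cell.

    Missing cells are simply absent from the output, never imputed.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    keys = ["group", "age_months"]
    if "ratio_label" in df.columns:
        keys.append("ratio_label")
    return df.groupby(keys, dropna=False)[value].mean().reset_index()
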