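"""Pseudo-speech corpus generator with known hierarchical AM structure.

Generates audio whose amplitude envelope carries a nested hierarchy of
amplitude modulators (defaults near 1.5, 7 and 30 Hz — prosodic-, syllabic-
and phonetic-rate), riding on five acoustic carrier bands with a 1/f power
tilt.  Phase coupling between adjacent modulator levels is controlled by a
von Mises concentration ``kappa``: per slow-cycle phase offsets are drawn
from von Mises(0, kappa), so the n:m phase synchronization index of the pair
converges to the closed-form mean resultant length I1(kappa)/I0(kappa).

Corpus-level scenarios emulate the register and age structure of a
longitudinal infant/child/adult-directed speech study: higher coupling in
CDS than ADS, and coupling that declines with child age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SpeechFile, Utterance, write_annotations, write_wav
from .filterbank import _channel_sos
from scipy.signal import sosfiltfilt

log = logging.getLogger(__name__)

__all__ = [
    "ModulatorSpec",
    "CarrierSpec",
    "SessionPlan",
    "CorpusSpec",
    "ModulatorChain",
    "default_chain",
    "coupled_chain",
    "gen_modulator_chain",
    "gen_utterance",
    "gen_session",
    "gen_corpus",
    "gen_block_envelopes",
    "draw_session_plan",
]

#: spectral bands of the reference analysis, used as default carrier bands
DEFAULT_BAND_EDGES = (100.0, 370.0, 900.0, 2100.0, 4100.0, 7250.0)


@dataclass(frozen=True)
class ModulatorSpec:
    """One level of the AM hierarchy.

    ``coupling_ratio`` is a pair of positive integers (slow-cycles :
    fast-cycles) tying this level's phase to the next-slower level; ``None``
    for the slowest level or an uncoupled level.  ``coupling_kappa`` is the
    von Mises concentration of the per-slow-cycle phase offsets (0 = free
    phase, ``inf`` = rigid locking).
    """

    rate: float
    depth: float
    phase_offset: float = 0.0
    coupling_ratio: tuple | None = None
    coupling_kappa: float = 0.0
    #: relative strength of the slow random waxing/waning of this level's
    #: modulation depth (0 = strict cosine of constant depth).  Real prosodic
    #: and syllabic AM power fluctuates over a few cycles; this fluctuation is
    #: what makes modulation-rate channels near one level co-vary, so band
    #: discovery needs it > 0.
    amp_fluct: float = 0.5
    #: correlation time of the depth fluctuation, in cycles of this level
    coherence_cycles: float = 4.0
    #: relative (log-normal) SD of slow instantaneous-rate wander.  Speech AM
    #: rates are tempo-variable within a band rather than spectral lines;
    #: wander spreads each level's energy over its modulation band.  Coupled
    #: levels inherit the parent's wander through the phase relation.
    rate_jitter: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError("depth must lie in [0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        if not (0.0 <= self.amp_fluct <= 1.0):
            raise ValueError("amp_fluct must lie in [0, 1]")
        if self.rate_jitter < 0:
            raise ValueError("rate_jitter must be >= 0")
        if self.coupling_ratio is not None:
            a, b = self.coupling_ratio
            if a < 1 or b < 1 or int(a) != a or int(b) != b:
                raise ValueError("coupling_ratio must be positive integers")


@dataclass(frozen=True)
class CarrierSpec:
    """Acoustic carrier layout: harmonic complex in the low (pitch) bands,
    band-passed Gaussian noise in the high (formant/consonant) bands, with
    per-band power falling as f**(-band_tilt)."""

    f0: float = 300.0
    band_edges: tuple = DEFAULT_BAND_EDGES
    band_tilt: float = 1.0
    n_harmonic_bands: int = 2  # lowest bands carried by harmonics of f0

    def __post_init__(self):
        edges = np.asarray(self.band_edges)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("band_edges must be strictly increasing")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.band_edges) - 1

    def band_powers(self) -> np.ndarray:
        """Relative per-band power: f_center**(-tilt), normalized to band 1."""
        centers = np.sqrt(np.asarray(self.band_edges[:-1]) * np.asarray(self.band_edges[1:]))
        p = centers ** (-self.band_tilt)
        return p / p[0]


@dataclass(frozen=True)
class SessionPlan:
    """Planned utterance/gap structure of one recording session."""

    utterance_durations: tuple
    gap_durations: tuple  # one gap between each pair of consecutive utterances
    speaker: str = "mother"
    addressee: str = "CDS"
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.utterance_durations):
            raise ValueError("utterance durations must be positive")
        if any(g <= 0 for g in self.gap_durations):
            raise ValueError("gap durations must be positive")
        n = len(self.utterance_durations)
        if n and len(self.gap_durations) != n - 1:
            raise ValueError("need exactly one gap between consecutive utterances")

    @property
    def total_duration(self) -> float:
        return sum(self.utterance_durations) + sum(self.gap_durations)


def draw_session_plan(n_utterances: int, seed: int, speaker: str = "mother",
                      addressee: str = "CDS",
                      log_mean: float = math.log(2.5), log_sd: float = 0.35,
                      short_gap: tuple = (0.1, 0.45), long_gap: tuple = (0.55, 2.0),
                      p_short: float = 0.5) -> SessionPlan:
    """Draw a session plan: log-normal utterance durations and a gap mixture
    straddling the 500 ms merge threshold (short gaps merge, long gaps split)."""
    rng = np.random.default_rng(seed)
    durs = tuple(np.exp(rng.normal(log_mean, log_sd, n_utterances)))
    gaps = []
    for _ in range(max(n_utterances - 1, 0)):
        lo, hi = short_gap if rng.random() < p_short else long_gap
        gaps.append(float(rng.uniform(lo, hi)))
    return SessionPlan(durs, tuple(gaps), speaker=speaker, addressee=addressee, seed=seed)


@dataclass
class ModulatorChain:
    """Output of :func:`gen_modulator_chain`."""

    env_rate: float
    thetas: np.ndarray          # (n_levels, n_samples) instantaneous phases
    specs: tuple                # the ModulatorSpec list actually used
    offsets: list               # per level: drawn per-slow-cycle offsets (rad)
    gains: np.ndarray | None = None  # (n_levels, n_samples) depth gains in [0, 1]

    @property
    def mods(self) -> np.ndarray:
        """Unit-amplitude modulator series cos(theta) per level."""
        return np.cos(self.thetas)

    @property
    def duration(self) -> float:
        return self.thetas.shape[1] / self.env_rate

    def envelope(self) -> np.ndarray:
        """Product envelope prod_i (1 + depth_i * g_i(t) * cos theta_i) >= 0."""
        e = np.ones(self.thetas.shape[1])
        gains = self.gains if self.gains is not None else np.ones_like(self.thetas)
        for spec, m, g in zip(self.specs, self.mods, gains):
            e *= 1.0 + spec.depth * g * m
        return e


def default_chain(kappa: float = 2.0, depths=(0.9, 0.5, 0.3)) -> tuple:
    """Band-discovery chain: independent modulators at 1.5 / 7 / 30 Hz."""
    return (
        ModulatorSpec(rate=1.5, depth=depths[0]),
        ModulatorSpec(rate=7.0, depth=depths[1]),
        ModulatorSpec(rate=30.0, depth=depths[2]),
    )


def coupled_chain(kappa: float, ratio: tuple = (1, 2), slow_rate: float = 1.5,
                  depths=(0.9, 0.5, 0.3), fast_free_rate: float = 30.0) -> tuple:
    """Coupling chain: a slow prosodic-rate modulator, a ratio-locked
    syllabic-rate modulator with jitter concentration ``kappa``, and a free
    phonetic-rate modulator."""
    a, b = ratio
    return (
        ModulatorSpec(rate=slow_rate, depth=depths[0]),
        ModulatorSpec(rate=slow_rate * b / a, depth=depths[1],
                      coupling_ratio=(a, b), coupling_kappa=kappa),
        ModulatorSpec(rate=fast_free_rate, depth=depths[2]),
    )


def _depth_gain(spec: ModulatorSpec, n: int, env_rate: float, rng) -> np.ndarray:
    """Slowly varying depth gain in [0, 1] for one modulator level.

    A Gaussian process low-passed at rate/coherence_cycles is squashed through
    the normal CDF (uniform marginal on [0, 1]) and mixed with the constant 1
    according to ``amp_fluct``; the result keeps depth*gain <= depth, so the
    product envelope stays non-negative.
    """
    from scipy.special import ndtr

    z = _slow_gauss(n, env_rate, spec.rate / spec.coherence_cycles, rng)
    u = ndtr(z)
    return (1.0 - spec.amp_fluct) + spec.amp_fluct * u


def _slow_gauss(n: int, env_rate: float, cutoff_hz: float, rng) -> np.ndarray:
    """Standardized Gaussian series low-passed at ``cutoff_hz``."""
    from scipy.signal import butter, sosfiltfilt

    x = rng.standard_normal(n)
    if 0 < cutoff_hz < env_rate / 2:
        sos = butter(2, cutoff_hz / (env_rate / 2), btype="lowpass", output="sos")
        x = sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else np.zeros(n)


def _offset_series(theta_slow: np.ndarray, offsets: np.ndarray,
                   transition: float) -> np.ndarray:
    """Per-sample offset: constant within each slow cycle, linear ramp to the
    next cycle's value over the final ``transition`` fraction of the cycle."""
    cycle = theta_slow / (2 * np.pi)  # fractional slow-cycle count
    k = np.floor(cycle).astype(int)
    k -= k.min()
    k = np.clip(k, 0, len(offsets) - 2)
    frac = cycle - np.floor(cycle)
    ramp = np.clip((frac - (1.0 - transition)) / transition, 0.0, 1.0)
    return offsets[k] * (1.0 - ramp) + offsets[k + 1] * ramp


def gen_modulator_chain(specs, duration: float, env_rate: float,
                        seed: int = 0, transition: float = 0.1) -> ModulatorChain:
    """Generate instantaneous phases for a nested modulator hierarchy.

    The slowest phase advances uniformly at its rate.  A coupled level with
    ratio a:b (slow:fast cycles) follows theta_fast = (b/a)*theta_slow +
    delta(t)/a, where delta(t) interpolates per-slow-cycle offsets drawn from
    von Mises(0, kappa); the generalized phase difference
    b*theta_slow - a*theta_fast then equals -delta(t) exactly, so its mean
    resultant length has the closed form I1(kappa)/I0(kappa).
    """
    specs = tuple(specs)
    if duration <= 0:
        raise ValueError("duration must be positive")
    rates = [s.rate for s in specs]
    if any(r2 <= r1 for r1, r2 in zip(rates[:-1], rates[1:])):
        raise ValueError("modulator rates must be ordered slow to fast")
    if env_rate <= 2 * rates[-1]:
        raise ValueError(f"env_rate {env_rate} Hz too low for a {rates[-1]} Hz modulator")

    rng = np.random.default_rng(seed)
    n = int(round(duration * env_rate))
    t = np.arange(n) / env_rate
    thetas = np.empty((len(specs), n))
    gains = np.ones((len(specs), n))
    all_offsets: list = []
    for i, spec in enumerate(specs):
        if spec.amp_fluct > 0:
            gains[i] = _depth_gain(spec, n, env_rate, rng)
        if spec.coupling_ratio is None or i == 0:
            if spec.rate_jitter > 0:
                z = _slow_gauss(n, env_rate, spec.rate / spec.coherence_cycles, rng)
                inst_rate = spec.rate * np.exp(spec.rate_jitter * z
                                               - spec.rate_jitter ** 2 / 2)
                thetas[i] = (2 * np.pi * np.cumsum(inst_rate) / env_rate
                             + spec.phase_offset)
            else:
                thetas[i] = 2 * np.pi * spec.rate * t + spec.phase_offset
            all_offsets.append(np.empty(0))
            continue
        a, b = spec.coupling_ratio
        slow = specs[i - 1]
        implied = slow.rate * b / a
        if abs(spec.rate - implied) > 1e-9 * implied:
            raise ValueError(
                f"rate {spec.rate} inconsistent with coupling {a}:{b} on a "
                f"{slow.rate} Hz parent (implies {implied} Hz)")
        n_cycles = int(np.ceil((thetas[i - 1].max() - thetas[i - 1].min())
                               / (2 * np.pi))) + 2
        if np.isinf(spec.coupling_kappa):
            offsets = np.zeros(n_cycles)
        else:
            offsets = rng.vonmises(0.0, spec.coupling_kappa, n_cycles)
        delta = _offset_series(thetas[i - 1] - specs[i - 1].phase_offset, offsets, transition)
        thetas[i] = (b / a) * thetas[i - 1] + spec.phase_offset + delta / a
        all_offsets.append(offsets)
    return ModulatorChain(env_rate=env_rate, thetas=thetas, specs=specs,
                          offsets=all_offsets, gains=gains)


def _band_carrier(lo, hi, fs, n, carrier: CarrierSpec, band_index, rng) -> np.ndarray:
    """Unit-RMS carrier for one acoustic band."""
    t = np.arange(n) / fs
    if band_index < carrier.n_harmonic_bands:
        ks = [k for k in range(1, int(hi / carrier.f0) + 1) if lo <= k * carrier.f0 < hi]
        if ks:
            x = sum(np.cos(2 * np.pi * k * carrier.f0 * t + rng.uniform(0, 2 * np.pi))
                    for k in ks)
        else:  # no harmonic falls in the band; fall back to noise
            x = None
    else:
        x = None
    if x is None:
        sos = _channel_sos(lo, hi, fs, order=4)
        x = sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def gen_utterance(carrier: CarrierSpec, chain: ModulatorChain,
                  fs: float = 16000.0, seed: int = 0, **provenance) -> SpeechFile:
    """Render one pseudo-speech utterance: sum over acoustic bands of
    (tilt-scaled carrier) x (shared product envelope)."""
    rng = np.random.default_rng(seed)
    duration = chain.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    t_env = np.arange(chain.thetas.shape[1]) / chain.env_rate
    env = np.interp(t, t_env, chain.envelope())
    amps = np.sqrt(carrier.band_powers())
    x = np.zeros(n)
    for b, (lo, hi) in enumerate(zip(carrier.band_edges[:-1], carrier.band_edges[1:])):
        x += amps[b] * _band_carrier(lo, hi, fs, n, carrier, b, rng)
    x *= env
    peak = np.max(np.abs(x))
    scale = 0.3 / peak if peak > 0 else 1.0  # headroom for 16-bit output
    if peak * scale > 1.0:
        log.info("utterance rescaled to avoid clipping")
    return SpeechFile(samples=x * scale, fs=fs, **provenance)


def gen_session(plan: SessionPlan, carrier: CarrierSpec, chain_specs,
                fs: float = 16000.0, env_rate: float = 240.0):
    """Concatenate planned utterances with silent gaps.

    Returns the session audio as a :class:`SpeechFile` and an annotation
    table (one :class:`Utterance` per rendered utterance) whose rows exactly
    match the nonzero-signal spans.
    """
    rng = np.random.default_rng(plan.seed)
    pieces, annotations = [], []
    cursor = 0.0
    for i, dur in enumerate(plan.utterance_durations):
        if i:
            gap = plan.gap_durations[i - 1]
            pieces.append(np.zeros(int(round(gap * fs))))
            cursor += gap
        chain = gen_modulator_chain(chain_specs, dur, env_rate,
                                    seed=int(rng.integers(2 ** 31)))
        utt = gen_utterance(carrier, chain, fs=fs, seed=int(rng.integers(2 ** 31)),
                            speaker=plan.speaker)
        pieces.append(utt.samples)
        annotations.append(Utterance(cursor, cursor + utt.duration,
                                     plan.speaker, plan.addressee))
        cursor += utt.duration
    samples = np.concatenate(pieces) if pieces else np.empty(0)
    audio = SpeechFile(samples=samples, fs=fs, speaker=plan.speaker)
    return audio, annotations


def gen_block_envelopes(bank, block_edges, n_samples: int, seed: int = 0,
                        common_weight: float = 0.5, noise: float = 0.3,
                        edge_weight: float = 0.2,
                        block_scales=None) -> np.ndarray:
    """Synthetic channel envelopes with correlated blocks at known boundaries.

    Each filter-bank channel mixes a common broadband source, its block's
    private source, and independent noise.  The private-source weight follows
    a raised-cosine bump across the block (band energy concentrates toward
    band centers, as pitch/formant energy does in speech), falling to
    ``edge_weight`` at the block edges, so absolute PCA loadings show peaks
    inside blocks and troughs at the planted boundaries.  ``block_scales``
    optionally scales each block's private source (distinct scales separate
    the component eigenvalues, emulating the 1/f power ordering of natural
    bands and stabilizing component order across files).  Ground truth for
    spectral band-discovery tests.
    """
    from scipy.signal import butter, sosfiltfilt

    from .filterbank import erb_number

    block_edges = np.asarray(block_edges, dtype=float)
    if block_edges[0] > bank.f_lo or block_edges[-1] < bank.f_hi:
        raise ValueError("block edges must cover the bank range")
    rng = np.random.default_rng(seed)
    sos = butter(2, 0.1, btype="lowpass", output="sos")

    def slow(n):
        return sosfiltfilt(sos, rng.standard_normal(n))

    n_blocks = len(block_edges) - 1
    if block_scales is None:
        block_scales = np.ones(n_blocks)
    block_scales = np.asarray(block_scales, dtype=float)
    s0 = slow(n_samples)
    srcs = [block_scales[j] * slow(n_samples) for j in range(n_blocks)]
    cam_edges = erb_number(block_edges)
    env = np.empty((n_samples, bank.n_channels))
    for c, f_c in enumerate(bank.centers):
        j = int(np.clip(np.searchsorted(block_edges, f_c) - 1, 0, n_blocks - 1))
        pos = (erb_number(f_c) - cam_edges[j]) / (cam_edges[j + 1] - cam_edges[j])
        w = edge_weight + (1 - edge_weight) * 0.5 * (1 - np.cos(2 * np.pi * pos))
        env[:, c] = (common_weight * s0 + w * srcs[j]
                     + noise * rng.standard_normal(n_samples))
    return env


DEFAULT_GROUPS = ("ADSm", "ADSf", "CDSm", "CDSf")


def _default_kappa(group: str, age_months: float, kappa_ads: float = 1.0,
                   kappa_cds0: float = 2.5, kappa_cds_floor: float = 1.0,
                   decline_months: float = 60.0) -> float:
    """Default coupling scenario: CDS > ADS, CDS declining linearly with age."""
    if group.startswith("ADS"):
        return kappa_ads
    frac = min(max(age_months, 0.0), decline_months) / decline_months
    return kappa_cds0 + frac * (kappa_cds_floor - kappa_cds0)


@dataclass(frozen=True)
class CorpusSpec:
    """Design of a synthetic corpus: group x age grid with per-cell coupling.

    ``kappa_by_group_age`` maps (group, age_months) -> von Mises kappa; the
    default implements both study scenarios (CDS coupling above ADS, and a
    monotone decline of CDS coupling with child age).
    """

    groups: tuple = DEFAULT_GROUPS
    ages_months: tuple = tuple(range(3, 63, 6))
    n_files: int = 50
    master_seed: int = 0
    kappa_by_group_age: object = None  # callable (group, age) -> kappa
    carrier: CarrierSpec = CarrierSpec()
    ratio: tuple = (1, 2)
    duration_range: tuple = (10.0, 12.5)
    fs: float = 16000.0
    env_rate: float = 240.0
    children: tuple = ("A", "B", "C", "D", "E")

    def kappa(self, group: str, age_months: float) -> float:
        fn = self.kappa_by_group_age or _default_kappa
        return float(fn(group, age_months))


METADATA_COLUMNS = ["path", "group", "speaker", "child_id", "age_months", "kappa", "seed"]


def gen_corpus(spec: CorpusSpec, out_dir) -> pd.DataFrame:
    """Render the corpus to ``out_dir``: one WAV + one metadata row per file.

    The metadata table is also written to ``out_dir/metadata.tsv``.  The same
    ``CorpusSpec`` (including master seed) reproduces a byte-identical corpus.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(spec.master_seed)
    rows = []
    cells = [(g, a) for g in spec.groups for a in spec.ages_months]
    child_seeds = ss.spawn(len(cells))
    for (group, age), cell_ss in zip(cells, child_seeds):
        kappa = spec.kappa(group, age)
        speaker = "mother" if group.endswith("m") else "father"
        file_seeds = cell_ss.spawn(spec.n_files)
        for j, fss in enumerate(file_seeds):
            rng = np.random.default_rng(fss)
            seed = int(rng.integers(2 ** 31))
            dur = float(rng.uniform(*spec.duration_range))
            chain = gen_modulator_chain(
                coupled_chain(kappa, ratio=spec.ratio), dur, spec.env_rate, seed=seed)
            child = spec.children[j % len(spec.children)]
            sf = gen_utterance(spec.carrier, chain, fs=spec.fs, seed=seed,
                               group=group, speaker=speaker, child_id=child,
                               age_months=age)
            name = f"{group}_age{age:03d}_{j:03d}.wav"
            write_wav(out_dir / name, sf.samples, int(spec.fs))
            rows.append((name, group, speaker, child, age, kappa, seed))
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return meta
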