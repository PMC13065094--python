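"""Raw-recording preprocessing: segmentation, merging, padding, normalization.

Session recordings come with utterance annotations (start/end seconds,
speaker, addressee).  Adjacent same-speaker utterances separated by less than
the 500 ms gap threshold are merged into one speech file (the short silence is
retained); longer gaps split files.  Files shorter than 10 s are concatenated
with temporally adjacent files from the same session, inserting 1 s of silence
at each join, so every analysis file clears the 10 s floor needed for reliable
0.9 Hz modulation estimates.  Finally 3 s of silence is padded onto both ends
and the waveform is z-score normalized (mean 0, SD 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

__all__ = [
    "Utterance",
    "SpeechFile",
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "segment_by_gaps",
    "enforce_min_length",
    "pad_ends",
    "znormalize",
    "preprocess_session",
]


@dataclass(frozen=True)
class Utterance:
    start: float
    end: float
    speaker: str = ""
    addressee: str = ""  # "ADS" or "CDS"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"utterance end {self.end} <= start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SpeechFile:
    """A mono waveform plus provenance and processing flags."""

    samples: np.ndarray
    fs: float = 16000.0
    group: str = ""
    speaker: str = ""
    child_id: str = ""
    age_months: float = float("nan")
    merged: bool = False
    padded: bool = False
    normalized: bool = False
    pad_s: float = 0.0
    notes: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be mono (1-D)")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def interior(self) -> np.ndarray:
        """Samples with the end pads trimmed off."""
        n_pad = int(round(self.pad_s * self.fs))
        if n_pad == 0:
            return self.samples
        return self.samples[n_pad:-n_pad]


# ---------------------------------------------------------------------------
# I/O (RIFF PCM 16-bit mono WAV; UTF-8 tab-delimited annotation tables)

def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV, returning float samples in [-1, 1] and fs."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    else:
        data = data.astype(float)
    return data, int(fs)


def write_wav(path, samples: np.ndarray, fs: int = 16000) -> None:
    """Write float samples (clipped to [-1, 1]) as 16-bit PCM mono WAV."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(fs), (x * 32767.0).astype(np.int16))


ANNOTATION_COLUMNS = ["start", "end", "speaker", "addressee"]


def read_annotations(path) -> list[Utterance]:
    df = pd.read_csv(path, sep="\t")
    return [Utterance(float(r.start), float(r.end), str(r.speaker), str(r.addressee))
            for r in df.itertuples()]


def write_annotations(path, utterances) -> None:
    df = pd.DataFrame(
        [(f"{u.start:.3f}", f"{u.end:.3f}", u.speaker, u.addressee) for u in utterances],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segmentation and assembly rules

def _check_sorted_nonoverlapping(utterances) -> None:
    for a, b in zip(utterances[:-1], utterances[1:]):
        if b.start < a.start:
            raise ValueError("utterances must be sorted by start time")
        if a.speaker == b.speaker and b.start < a.end:
            raise ValueError(f"overlapping utterances at {b.start:.3f} s")


def segment_by_gaps(samples: np.ndarray, fs: float, utterances,
                    gap_threshold_ms: float = 500.0, **provenance) -> list[SpeechFile]:
    """Cut a session into speech files at silent gaps.

    Consecutive utterances from the same speaker whose silent gap is strictly
    shorter than ``gap_threshold_ms`` are merged into one file with the gap
    silence retained; gaps of the threshold or longer (or a speaker change)
    split files.
    """
    if gap_threshold_ms <= 0:
        raise ValueError("gap threshold must be positive")
    utterances = list(utterances)
    if not utterances:
        return []
    _check_sorted_nonoverlapping(utterances)
    samples = np.asarray(samples, dtype=float)
    thr_s = gap_threshold_ms / 1000.0

    runs: list[list[Utterance]] = [[utterances[0]]]
    for u in utterances[1:]:
        prev = runs[-1][-1]
        gap = u.start - prev.end
        if u.speaker == prev.speaker and gap < thr_s:
            runs[-1].append(u)
        else:
            runs.append([u])

    out = []
    for run in runs:
        i0 = int(round(run[0].start * fs))
        i1 = int(round(run[-1].end * fs))
        sf = SpeechFile(samples=samples[i0:i1].copy(), fs=fs,
                        speaker=run[0].speaker, merged=len(run) > 1, **provenance)
        if len(run) > 1:
            sf.notes.append(f"merged {len(run)} utterances (gaps < {gap_threshold_ms:g} ms)")
        out.append(sf)
    return out


def enforce_min_length(files, min_s: float = 10.0,
                       joiner_silence_s: float = 1.0) -> list[SpeechFile]:
    """Merge time-ordered files until every output is at least ``min_s`` long.

    Adjacent files from the session are concatenated with ``joiner_silence_s``
    of silence inserted at each join.  A short leftover tail is merged into
    the nearest (preceding) output; if the whole session falls short of
    ``min_s`` the material is dropped with a logged warning.
    """
    files = list(files)
    if not files:
        return []
    fs = files[0].fs
    joiner = np.zeros(int(round(joiner_silence_s * fs)))

    def join(group):
        parts = []
        for i, f in enumerate(group):
            if i:
                parts.append(joiner)
            parts.append(f.samples)
        sf = replace(group[0], samples=np.concatenate(parts) if len(parts) > 1 else parts[0].copy())
        sf.merged = sf.merged or len(group) > 1
        if len(group) > 1:
            sf.notes = sum((g.notes for g in group), []) + [
                f"joined {len(group)} files with {joiner_silence_s:g} s silence"]
        return sf

    out: list[SpeechFile] = []
    pending: list[SpeechFile] = []
    pending_dur = 0.0
    for f in files:
        if f.fs != fs:
            raise ValueError("mixed sample rates within a session")
        pending.append(f)
        pending_dur += f.duration + (joiner_silence_s if len(pending) > 1 else 0.0)
        if pending_dur >= min_s:
            out.append(join(pending))
            pending, pending_dur = [], 0.0
    if pending:
        if out:
            # merge the short tail into the nearest (previous) output
            out[-1] = join([out[-1], *pending])
        else:
            log.warning("session total %.2f s < %.1f s floor; dropped", pending_dur, min_s)
    return out


def pad_ends(file: SpeechFile, pad_s: float = 3.0) -> SpeechFile:
    """Add ``pad_s`` seconds of silence to both ends of the file."""
    if pad_s < 0:
        raise ValueError("pad_s must be >= 0")
    if pad_s == 0:
        return file
    pad = np.zeros(int(round(pad_s * file.fs)))
    out = replace(file, samples=np.concatenate([pad, file.samples, pad]))
    out.padded = True
    out.pad_s = file.pad_s + pad_s
    return out


def znormalize(file: SpeechFile) -> SpeechFile:
    """z-score the waveform to mean 0, SD 1 (population SD, divide by N)."""
    x = file.samples
    sd = x.std()
    if sd == 0:
        raise ValueError("all-silent file cannot be z-normalized")
    out = replace(file, samples=(x - x.mean()) / sd)
    out.normalized = True
    return out


def preprocess_session(samples, fs, utterances, gap_threshold_ms=500.0,
                       min_s=10.0, joiner_silence_s=1.0, pad_s=3.0,
                       **provenance) -> list[SpeechFile]:
    """Full preprocessing chain for one annotated session recording."""
    files = segment_by_gaps(samples, fs, utterances, gap_threshold_ms, **provenance)
    files = enforce_min_length(files, min_s=min_s, joiner_silence_s=joiner_silence_s)
    out = []
    for f in files:
        f = pad_ends(f, pad_s=pad_s)
        try:
            out.append(znormalize(f))
        except ValueError:
            log.warning("skipping all-silent file (%s)", f.notes)
    return out
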