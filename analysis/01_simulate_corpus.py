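"""Generate the synthetic pseudo-speech corpus used by the downstream steps.

Writes WAV audio + metadata under scratch/corpus (audio is bulky scratch
material) and a session-level demo (one annotated session recording) under
scratch/session for the preprocessing step.  The corpus design: four
registers (ADSm, ADSf, CDSm, CDSf) x ages 3-57 months, child-directed
coupling above adult-directed, and a monotone decline of child-directed
coupling with age.
"""

import sys
from pathlib import Path

import numpy as np

from samph import (CarrierSpec, CorpusSpec, coupled_chain, draw_session_plan,
                   gen_corpus, gen_session)
from samph.preprocess import write_annotations, write_wav

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    corpus_dir = ROOT / "scratch" / "corpus"
    spec = CorpusSpec(ages_months=(6, 18, 30), n_files=3, master_seed=seed)
    meta = gen_corpus(spec, corpus_dir)
    print(f"corpus: {len(meta)} files -> {corpus_dir}")
    print(meta.groupby(["group", "age_months"]).kappa.first().unstack().round(2))

    session_dir = ROOT / "scratch" / "session"
    session_dir.mkdir(parents=True, exist_ok=True)
    plan = draw_session_plan(12, seed=seed + 1, speaker="mother", addressee="CDS")
    audio, anns = gen_session(plan, CarrierSpec(), coupled_chain(2.0))
    write_wav(session_dir / "session.wav", audio.samples, int(audio.fs))
    write_annotations(session_dir / "session.tsv", anns)
    gaps = np.diff([(a.start, a.end) for a in anns], axis=0)
    print(f"session: {len(anns)} utterances, {audio.duration:.1f} s -> {session_dir}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
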