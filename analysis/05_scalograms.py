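"""Qualitative scalograms of representative synthetic utterances.

Renders continuous-wavelet scalograms (0.1-40 Hz modulation rates, 0 dB at
the amplitude maximum) for one strongly coupled (CDS-like) and one weakly
coupled (ADS-like) utterance.  Figures go to scratch/figures (binary
artifacts); this step is illustrative only.
"""

import sys
from pathlib import Path

from samph import (CarrierSpec, coupled_chain, gen_modulator_chain, gen_utterance,
                   render_scalogram)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for name, kappa in (("cds_like", 2.5), ("ads_like", 1.0)):
        chain = gen_modulator_chain(coupled_chain(kappa), 6.0, 240.0, seed=seed)
        sf = gen_utterance(CarrierSpec(), chain, seed=seed)
        out = fig_dir / f"scalogram_{name}.png"
        render_scalogram(sf.samples, sf.fs, out)
        print(f"wrote {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
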