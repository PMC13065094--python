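"""Band discovery: spectral blocks from constructed envelopes, temporal AM
bands from the rendered corpus.

Spectral-band discovery is demonstrated on block-correlated channel
envelopes with planted boundaries at the reference band edges (the rendered
corpus shares one envelope across carrier bands, so its spectral PCA shows
global coherence rather than banded structure — see docs/methods.md).
Temporal-band discovery runs on the corpus audio from step 01 and should
place loading peaks near the planted 1.5/7/30 Hz modulator rates.
Writes band tables under results/.
"""

import sys
from pathlib import Path

from samph import (PipelineConfig, design_bank, export_band_tables,
                   gen_block_envelopes, grand_average, infer_bands, pca_loadings,
                   temporal_pipeline)
from samph.bands import SPECTRAL_CRITERIA
from samph.pipeline import load_corpus
from samph.reference import REFERENCE_SPECTRAL_BANDS

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    cfg = PipelineConfig(seed=seed)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    # spectral: constructed block-envelope corpus with planted boundaries
    bank = design_bank(cfg.spectral_f_lo, cfg.spectral_f_hi, cfg.spectral_channels)
    planted = [b.lo for b in REFERENCE_SPECTRAL_BANDS] + [7250.0]
    lms = [pca_loadings(gen_block_envelopes(bank, planted, 2000, seed=seed + i),
                        cfg.spectral_components, bank=bank) for i in range(10)]
    spectral = infer_bands([grand_average(lms)], bank, SPECTRAL_CRITERIA,
                           target_bands=cfg.spectral_target_bands, domain="spectral")
    df = export_band_tables(spectral, results / "spectral_bands.tsv", cfg)
    print("spectral bands (planted at 370/900/2100/4100 Hz):")
    print(df.to_string(index=False))

    # temporal: corpus audio through the acoustic front end
    corpus_dir = ROOT / "scratch" / "corpus"
    if not (corpus_dir / "metadata.tsv").exists():
        raise SystemExit("run 01_simulate_corpus.py first")
    _, files, _ = load_corpus(corpus_dir, cfg)
    files = [sf for _, sf in files[:12]]
    mod_bank = design_bank(cfg.temporal_f_lo, cfg.temporal_f_hi,
                           cfg.temporal_channels, cfg.temporal_spacing)
    _, temporal = temporal_pipeline(files, REFERENCE_SPECTRAL_BANDS, mod_bank,
                                    env_fs=cfg.temporal_env_fs)
    df = export_band_tables(temporal, results / "temporal_bands.tsv", cfg)
    print("\ntemporal bands (modulators planted at 1.5/7/30 Hz):")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
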