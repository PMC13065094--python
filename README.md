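# samph

Speech-rhythm analysis via the spectral-amplitude modulation phase
hierarchy (S-AMPH): demodulate a speech waveform's amplitude envelope into
hierarchical spectral and temporal modulation bands, quantify n:m phase
synchronization between amplitude-modulation (AM) bands, and run the
register/age statistics used in research on infant- and child-directed
speech (IDS/CDS).

## Who this is for

Researchers in auditory neuroscience and developmental speech science who
model the amplitude envelope (AE) of speech: the slow intensity profile
tracked by cortical oscillations.  Natural speech carries nested AM bands
near ~1.5 Hz (prosodic), ~5–10 Hz (syllabic/moraic) and ~30 Hz
(phonetic-rate); the phase relation between the two slowest bands carries
the perceptual "beat" of speech and is stronger in speech directed to
infants and children than to adults.  The longitudinal corpora such
analyses target are licensed, so this package pairs the full analysis
pipeline with a synthetic pseudo-speech corpus generator whose coupling
structure is known in closed form, making every stage testable end to end.

## The model

1. **Preprocessing** — annotated session recordings are segmented at
   silent gaps (< 500 ms merges, ≥ 500 ms splits), merged to a 10 s floor
   with 1 s silence at joins, padded with 3 s of silence at both ends, and
   z-scored (M = 0, SD = 1).
2. **Spectral analysis** — a 28-channel ERB_N-spaced filter bank
   (100–7250 Hz) models cochlear frequency decomposition; Hilbert
   envelopes per channel; PCA across channel envelopes; absolute
   component loadings, grand-averaged across files, reveal five
   co-modulated spectral bands via loading peaks and flanking troughs.
3. **Temporal analysis** — the signal is refiltered into the five spectral
   bands; each band envelope passes a 24-channel log-spaced modulation
   filter bank (0.9–40 Hz); temporal PCA reveals three AM bands.
4. **Phase synchronization** — for the two slowest AM bands,

   PSI = | ⟨ exp(i·(n·θ₁ − m·θ₂)) ⟩ |

   with θ₁, θ₂ the instantaneous Hilbert phases of the slower and faster
   band and n:m set from mean cycle lengths (2000 ms against 1500 ms gives
   4:3) or fixed to the grid ratios 1:2, 1:3, 2:3.  PSI = 1 is perfect
   locking, PSI = 0 none.
5. **Statistics** — Shapiro–Wilk gating, Kruskal–Wallis omnibus with η²,
   prespecified pairwise register contrasts with Cohen's d,
   Benjamini–Hochberg FDR, TOST log-scale equivalence of durations
   (±10% geometric-mean margin), Spearman age trends, and a
   repeated-measures ANOVA over band mean frequency power.

The generator plants ground truth for all of this: von Mises phase jitter
with concentration κ between coupled modulators gives a closed-form PSI
target I₁(κ)/I₀(κ); register and age scenarios set κ(CDS) > κ(ADS) and κ
declining with child age.  See `docs/methods.md` for the full model and
design rationale.

## Worked example

```python
from samph import (CorpusSpec, compare_groups, run_envelope_study)

spec = CorpusSpec(groups=("ADSf", "CDSf"), ages_months=(12,), n_files=50,
                  master_seed=0,
                  kappa_by_group_age=lambda g, a: 2.5 if g.startswith("CDS") else 1.0)
df = run_envelope_study(spec)             # per-file PSI at the 1:2 ratio
print(df.groupby("group").psi.mean())
for r in compare_groups(df.psi.to_numpy(), df.group.to_numpy(),
                        pairs=(("CDSf", "ADSf"),)):
    print(r.test, round(r.statistic, 2), r.p_fdr, r.significant)
```

Output:

```
group
ADSf    0.445709
CDSf    0.691899
Name: psi, dtype: float64
kruskal-wallis 55.95 None None
W:CDSf-ADSf 7.48 7.44388828444204e-14 True
```

The CDS-like group (κ = 2.5, PSI ≈ 0.69, close to the analytic target
I₁(2.5)/I₀(2.5) ≈ 0.74 measured through the demodulation path) shows
substantially stronger 1:2 phase coupling than the ADS-like group
(κ = 1.0, PSI ≈ 0.45 against a target of ≈ 0.45).  Normality gating
routed to the nonparametric path (rank-sum W reported), and the
prespecified contrast is FDR-significant.

The numbered drivers under `analysis/` run the same steps as a narrative:
`01_simulate_corpus.py` (WAV corpus + annotated session),
`02_discover_bands.py` (spectral/temporal band tables → `results/`),
`03_phase_sync.py` (PSI by register and age), `04_group_stats.py`
(contrast/trend/equivalence report), `05_scalograms.py` (wavelet
scalograms).  A `samph` CLI wraps the pipeline (`samph synth`,
`samph preprocess`, `samph bands`, `samph psi`, `samph stats`,
`samph all`, `samph scalogram`).

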