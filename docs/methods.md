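# Methods

`samph` implements a spectral-amplitude modulation phase hierarchy (S-AMPH)
analysis of speech rhythm: demodulation of the amplitude envelope (AE) into
hierarchical spectral and temporal modulation bands, n:m phase
synchronization between AM bands, and the register/age statistics used in
infant- and child-directed speech (IDS/CDS) research.  Because the natural
longitudinal corpora this kind of analysis targets are licensed and large,
the package is driven by a synthetic pseudo-speech generator whose coupling
structure is known in closed form; this note records the model, the
defaults, and the design choices that were genuinely open.

## Preprocessing model

Session recordings arrive with utterance annotations (start/end seconds,
speaker, addressee).  Assembly rules:

* **Merge/split at 500 ms.**  Temporally adjacent utterances from the same
  speaker separated by silence strictly shorter than 500 ms are merged into
  one speech file, retaining the silence; gaps of 500 ms or more (or a
  speaker change) split files.  The comparison is strict (`< 500` merges),
  so a gap of exactly 500 ms splits.
* **10 s floor with 1 s joiners.**  Files shorter than 10 s are merged with
  temporally adjacent files of the same session, inserting 1.0 s of silence
  at each join, until the result clears 10 s.  A leftover short tail is
  merged into the preceding output; a session whose total falls below the
  floor is dropped with a logged warning.  Files are never truncated: the
  10.0–12.5 s range seen in natural corpora is an empirical outcome of the
  merge rule, not a rule itself.
* **3 s end pads, then z-normalization.**  3 s of silence are added to both
  ends (they absorb filter transients and are trimmed before all
  statistics), after which the waveform is z-scored to mean 0, SD 1.
  Population SD (divide by N) is used; at these file lengths the difference
  from the sample convention is < 1e-4.  Normalizing after padding keeps
  the whole stored waveform at exactly (M = 0, SD = 1), which is the
  contract tests enforce at 1e-6.

## Filter banks and envelopes

* Acoustic bank: 28 band-pass channels spanning 100–7250 Hz with edges
  uniform on the ERB-number scale Cam(f) = 21.4·log10(0.00437·f + 1).
* Modulation bank: 24 channels spanning 0.9–40 Hz with log-spaced edges.
  The literature's phrase "logarithmically spaced ERB_N" is ambiguous below
  ~1 Hz (the ERB scale is essentially linear there), so both spacings are
  implemented and selectable; defaults are ERB_N for the acoustic bank and
  log for the modulation bank.
* Channels are 2nd-order Butterworth band-passes applied forward–backward
  (zero phase, `sosfiltfilt`); the order is part of the bank spec.  The
  choice favors stability across the 0.9–40 Hz range at the envelope rates
  used.
* Envelopes are Hilbert magnitudes.  Acoustic-channel envelopes are
  decimated to 1050 Hz before spectral PCA; spectral-band envelopes are
  decimated to 120 Hz before the modulation bank and temporal PCA (both
  Nyquist-safe for 40 Hz content and keep the matrices small).

## Band discovery

PCA runs per speech file on the channel-envelope matrix; absolute component
loadings are averaged across files (grand average); peaks in the averaged
loading pattern mark co-modulated channel clusters and flanking troughs
mark band boundaries.  Spectral analysis retains five components and
expects five bands; temporal analysis retains three components and expects
three bands, with temporal loadings pooled over the five spectral bands.

Decisions that were genuinely open:

* **Covariance- vs correlation-convention PCA.**  Both are implemented;
  the default is covariance (no channel standardization).  Standardizing
  gives unit weight to channels that carry almost no envelope energy — the
  gaps between AM bands — and their phase-incoherent noise then dominates
  the retained components: on generator corpora the loading peak/trough
  structure collapses (boundaries recovered several channels off).  With
  the covariance convention, loadings reflect where co-modulated energy
  actually lives and the planted structure is recovered to within one
  channel.  The 1/f tilt concern that motivates standardization in the
  spectral domain is mitigated here because temporal PCA operates within a
  spectral band, where the tilt across modulation channels is mild.
* **Peak criteria.**  Minimum peak separation is 2 channels (spectral) and
  5 channels (temporal); on conflict the larger peak wins.  Excursions with
  prominence below 10% of the mean prominence are treated as ripple.  The
  same 10% low-amplitude threshold is reused when estimating mean cycle
  lengths (cycles below 10% of the average peak-to-peak amplitude are
  excluded); the two uses share one config parameter.
* **PC1 exclusion.**  A first component without interior troughs reflects
  global coherence rather than banded structure and is excluded from
  boundary pooling.
* **Boundary placement.**  Trough channels are pooled across components
  (and, temporally, across spectral bands); boundaries sit at the modal
  trough channels, ties breaking toward the lower-frequency channel
  (conservatively widening the slow band).  The boundary frequency is the
  lower edge of the trough channel.  If the data support fewer boundaries
  than requested, the discovered count is returned with a warning.

## Phase synchronization

For each spectral band, the band envelope is filtered into the two slowest
temporal AM bands; instantaneous phases come from the analytic signal; and

    PSI = | < exp(i·(n·theta1 − m·theta2)) > |

with theta1 the slower band's phase.  PSI is computed on full band-limited
modulator phases at every time point (not per-cycle discretization).  The
n:m multipliers follow the slow:fast cycle-count label a:b as (n, m) =
(b, a); under exact locking n/m = f_fast/f_slow, so cycle lengths of
2000 ms and 1500 ms give n:m = 4:3.  Cycle lengths are mean intervals
between retained envelope peaks; the ratio snaps to the nearest candidate
on the coprime grid up to max integer 4 (1:1, 1:2, 1:3, 1:4, 2:3, 3:4),
clamping with a warning beyond the grid.  Because register contrasts are
reported per integer ratio while the data-driven ratio varies per file,
the fixed ratios 1:2, 1:3 and 2:3 are evaluated for every file alongside
the cycle-length-determined ratio, and spectral-band-averaged values are
emitted next to per-band values.  PSI is computed per file (matching the
per-sample definition); concatenation across a session is available as an
option.  Mean frequency power (MFP) is the mean squared band envelope over
the pad-trimmed interior.

## Synthetic corpus generator

The generator emulates the structure, not the phonetics, of a longitudinal
IDS/CDS corpus: 16-bit 16 kHz mono WAV, utterance/silence alternation with
gaps straddling the 500 ms merge threshold, processed-file durations of
10.0–12.5 s, five carrier bands with a 1/f power tilt, and a nested AM
hierarchy.

* **Modulator hierarchy.**  Default rates 1.5/7/30 Hz (prosodic-,
  syllabic-, phonetic-rate) at depths 0.9/0.5/0.3.  The product envelope
  e(t) = Π (1 + depth_i·g_i(t)·cos θ_i(t)) is non-negative by construction.
* **Phase coupling.**  A coupled level with ratio a:b (slow:fast cycles)
  follows θ_fast = (b/a)·θ_slow + δ(t)/a, where δ(t) carries per-slow-cycle
  offsets drawn from von Mises(0, κ).  The generalized phase difference
  b·θ_slow − a·θ_fast equals −δ(t) exactly, so the PSI target is the von
  Mises mean resultant length I1(κ)/I0(κ) for every ratio, not only 1:2.
  Offsets are piecewise constant within a cycle with a linear ramp over the
  final 10% of the cycle: interpolating linearly across whole cycles would
  spend most of each cycle between two independent draws, biasing PSI well
  above the Bessel-ratio target (≈ +0.19 at κ = 0.5), while the narrow ramp
  keeps the phase continuous at a bias below 0.025.
* **Within-band variability.**  Each level's depth waxes and wanes (a
  low-passed Gaussian squashed to [0, 1], correlation time four cycles,
  mixed in at 50%), and each free level's instantaneous rate wanders
  log-normally (SD 0.2) around its nominal rate.  Real prosodic/syllabic AM
  power and tempo fluctuate this way, and both features are what give the
  modulation-rate channels of one band coherent co-fluctuation; without
  them the generator produces line spectra and there is no co-modulation
  structure for PCA to find.  Coupled levels inherit the parent's wander
  through the phase relation, leaving the PSI target untouched (measured
  deviation ≤ 0.035 across κ = 0.5–8).
* **Carriers.**  Bands 1–2 carry harmonics of F0 = 300 Hz (the pitch
  region); bands 3–5 carry band-passed Gaussian noise (formant/consonant
  energy).  Per-band power falls as f_center^(−1), normalized to band 1.
  All carrier bands share the same product envelope, so the synthetic
  audio's spectral PCA shows global coherence rather than banded structure;
  spectral band discovery is therefore validated on constructed
  block-correlated channel envelopes (`gen_block_envelopes`) with planted
  boundaries and band-centered energy bumps, emulating how pitch/formant
  energy concentrates inside natural spectral bands.
* **Session/corpus structure.**  Utterance durations are log-normal
  (median 2.5 s, log-SD 0.35); gaps mix uniform draws from 0.10–0.45 s and
  0.55–2.0 s in equal proportion, straddling the merge threshold.  No
  distributional facts about natural utterance/gap durations were available
  to fit, so these are stated defaults, not estimates.  The corpus design
  crosses four registers (ADSm, ADSf, CDSm, CDSf) with child ages; the
  default coupling scenario sets κ = 1.0 for ADS and κ declining linearly
  from 2.5 (birth) to 1.0 (60 months) for CDS, implementing both the
  register contrast (CDS > ADS) and the developmental decline.  A master
  seed makes the corpus byte-identical across runs.

What passing tests on this generator do **not** show: phonetic realism
(no formant transitions, no F0 contours, no lexical content), natural
per-band envelope differences (a shared envelope across carrier bands),
or the corpus-dependent values of a natural-speech analysis (variance
percentages, PSI group means, H/rho statistics).  Published full-scale
band layouts are shipped in `samph.reference` as comparison fixtures only
and are never asserted against synthetic output.

## Statistics

Shapiro–Wilk normality gating (any group p < 0.05 routes nonparametric);
omnibus Kruskal–Wallis with η² = (H − k + 1)/(n − k) (a common convention;
floored at 0); four prespecified pairwise register contrasts (Welch t with
pooled-SD Cohen's d and a normal-approximation CI on the parametric path;
rank-sum tests whose standardized statistic is reported as W on the
nonparametric path), Benjamini–Hochberg corrected at α = 0.05 within the
contrast family.  The effect-size sign convention is CDS − ADS.  Where a
published design describes a two-factor Kruskal–Wallis, two separate
one-way tests (by register; by participant) are run and both reported,
since the Kruskal–Wallis statistic is one-way.  Duration equivalence uses
ratio-based TOST on the log scale: the 90% Welch CI of the mean
log-difference is exponentiated to a geometric-mean-ratio CI, concluding
equivalence when it lies within [0.90, 1.10].  Age trends are Spearman
correlations (Pearson if gated normal) of per-age mean PSI against age in
months; PSI is averaged across children within each group × age-month cell
first, and missing cells stay absent rather than being imputed.  MFP band
effects use a repeated-measures ANOVA (file as subject, spectral band as
the within factor) with Tukey post hocs.

## Problem sizes and numerical choices

Desk-scale defaults keep every check cheap: coupling-oracle runs use 600 s
modulator hierarchies at a 120 Hz envelope rate (20 seeds per κ);
register-contrast studies use 50 files per group of 10.0–12.5 s each;
developmental studies use 10 ages × 10 files; band-recovery corpora use
6–12 files of 12 s audio.  The coupling oracle measures PSI from the
band-filtered modulator series: the product envelope additionally carries
intermodulation terms (e.g. at f2 ± f1) that are themselves phase-locked to
the pair and bias the slow band's phase at weak coupling — a real property
of multiplicative AM hierarchies, noted as a limitation, and the reason the
envelope-based route is reserved for group contrasts where both groups
share the bias.  Degenerate inputs fail loudly: all-silent files cannot be
z-normalized, fewer than two retained cycles cannot yield a cycle length,
PSI requires at least 100 samples, and repeated-measures ANOVA requires at
least two files.  Resampled envelopes are clipped at zero (anti-aliasing
ripple), and unstable filter designs raise with the offending channel
named.
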