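"""Reference band layouts from published S-AMPH corpus analyses.

These are expected-output fixtures for full-scale natural-speech corpora:
the canonical five spectral bands and three temporal AM bands (with the
elongated 2.5-17 Hz syllabic band reported for Japanese infant- and
child-directed speech).  They are corpus-dependent results, shipped for
comparison, table layout, and as default carrier-band edges for the
synthetic generator — they are never asserted against synthetic corpora.
"""

from .bands import Band, BandSet

#: Five spectral bands (Hz) with their supporting components.
REFERENCE_SPECTRAL_BANDS = BandSet(
    bands=[
        Band(100.0, 370.0, peak_channel=3, components=(2, 3, 4, 5)),
        Band(370.0, 900.0, peak_channel=8, components=(2, 3)),
        Band(900.0, 2100.0, peak_channel=14, components=(4, 5)),
        Band(2100.0, 4100.0, peak_channel=20, components=(1,)),
        Band(4100.0, 7250.0, peak_channel=25, components=(2, 3, 4, 5)),
    ],
    domain="spectral",
)

#: Three temporal AM bands (Hz): prosodic-, syllabic- (elongated to 17 Hz),
#: and phonetic-rate.
REFERENCE_TEMPORAL_BANDS = BandSet(
    bands=[
        Band(0.9, 2.5, peak_channel=3, components=(2, 3)),
        Band(2.5, 17.0, peak_channel=13, components=(1, 3)),
        Band(17.0, 40.0, peak_channel=22, components=(2, 3)),
    ],
    domain="temporal",
)

#: Variance fractions of retained components at corpus scale (spectral PCA
#: top five, temporal PCA top three).
REFERENCE_SPECTRAL_VARIANCE = (0.4616, 0.1045, 0.0632, 0.0478, 0.0386)
REFERENCE_TEMPORAL_VARIANCE = (0.7138, 0.1300, 0.0468)

#: Loading peaks (Hz) of the retained temporal components.
REFERENCE_TEMPORAL_PEAKS_HZ = (1.5, 7.0, 30.0)
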