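import numpy as np
import pytest

from samph import (LoadingMatrix, design_bank, detect_peaks_troughs,
                   gen_block_envelopes, grand_average, infer_bands, pca_loadings,
                   temporal_pipeline)
from samph.bands import SPECTRAL_CRITERIA, TEMPORAL_CRITERIA, PeakCriteria


class TestPcaLoadings:
    def test_two_block_structure_splits_components(self, rng):
        # channels 1-14 share one source, 15-28 another (independent)
        n = 3000
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        env = np.empty((n, 28))
        env[:, :14] = s1[:, None] + 0.05 * rng.standard_normal((n, 14))
        env[:, 14:] = s2[:, None] + 0.05 * rng.standard_normal((n, 14))
        lm = pca_loadings(env, 5)
        assert lm.variance_fraction[:2].sum() > 0.99
        # loadings are homogeneous within each block ...
        for c in range(2):
            assert lm.abs_loadings[:14, c].std() < 0.01
            assert lm.abs_loadings[14:, c].std() < 0.01
        # ... and the two retained components jointly separate the blocks
        block_means = np.array([[lm.abs_loadings[:14, c].mean(),
                                 lm.abs_loadings[14:, c].mean()] for c in range(2)])
        assert np.abs(np.linalg.det(block_means)) > 1e-3

    def test_identical_channels_one_component(self, rng):
        src = rng.standard_normal(2000)
        env = np.tile(src[:, None], (1, 10)) + 1e-9 * rng.standard_normal((2000, 10))
        lm = pca_loadings(env, 3)
        assert lm.variance_fraction[0] == pytest.approx(1.0, abs=1e-6)

    def test_independent_channels_flat_spectrum(self, rng):
        env = rng.standard_normal((20000, 28))
        lm = pca_loadings(env, 28)
        assert lm.variance_fraction.max() < 2.5 / 28

    def test_constant_channel_dropped_with_warning(self, rng, caplog):
        env = rng.standard_normal((1000, 5))
        env[:, 2] = 3.0
        lm = pca_loadings(env, 2)
        assert np.allclose(lm.abs_loadings[2], 0.0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="10x"):
            pca_loadings(rng.standard_normal((50, 28)), 5)


class TestGrandAverage:
    def _lm(self, vals):
        return LoadingMatrix(abs_loadings=np.asarray(vals, float),
                             variance_fraction=np.ones(np.shape(vals)[1]) / 2)

    def test_single_input_identity_and_permutation_invariance(self, rng):
        lms = [self._lm(rng.uniform(size=(6, 2))) for _ in range(4)]
        assert np.allclose(grand_average([lms[0]]).abs_loadings,
                           lms[0].abs_loadings)
        fwd = grand_average(lms).abs_loadings
        rev = grand_average(lms[::-1]).abs_loadings
        assert np.allclose(fwd, rev)

    def test_constant_list_mean_is_constant(self):
        lm = self._lm(np.full((6, 2), 0.3))
        assert np.allclose(grand_average([lm, lm, lm]).abs_loadings, 0.3)


class TestDetectPeaksTroughs:
    def test_constructed_two_peak_pattern(self):
        col = np.zeros(28)
        col[5], col[20] = 1.0, 0.8
        col[:5] = np.linspace(0, 0.9, 5)
        col[6:13] = np.linspace(0.9, 0.1, 7)
        col[13:20] = np.linspace(0.1, 0.75, 7)
        col[21:] = np.linspace(0.7, 0.1, 7)
        peaks, troughs = detect_peaks_troughs(col, SPECTRAL_CRITERIA)
        assert peaks == [5, 20]
        assert troughs == [12]

    def test_adjacent_maxima_keep_larger(self):
        col = np.zeros(12)
        col[5], col[6] = 0.8, 1.0
        peaks, _ = detect_peaks_troughs(col, SPECTRAL_CRITERIA)
        assert peaks == [6]

    def test_small_ripple_on_broad_peak_ignored(self):
        x = np.linspace(0, np.pi, 25)
        col = np.sin(x)  # one broad peak
        col[5] += 0.02   # 2% ripple
        col[6] -= 0.02
        peaks, troughs = detect_peaks_troughs(col, PeakCriteria(min_separation=2))
        assert len(peaks) == 1
        assert troughs == []

    def test_monotone_input_yields_nothing(self):
        peaks, troughs = detect_peaks_troughs(np.linspace(0, 1, 20),
                                              SPECTRAL_CRITERIA)
        assert peaks == [] and troughs == []


class TestInferBands:
    def test_block_corpus_recovers_planted_boundaries(self, spectral_bank):
        planted = [100.0, 370.0, 900.0, 2100.0, 4100.0, 7250.0]
        lms = [pca_loadings(gen_block_envelopes(spectral_bank, planted, 2000,
                                                seed=s), 5, bank=spectral_bank)
               for s in range(8)]
        bs = infer_bands([grand_average(lms)], spectral_bank, SPECTRAL_CRITERIA,
                         target_bands=5, domain="spectral")
        assert len(bs) == 5
        edges = np.asarray(spectral_bank.edges)
        for found, true in zip(bs.edges()[1:-1], planted[1:-1]):
            # recovered boundary within one channel of the planted one
            true_ch = np.searchsorted(edges, true) - 1
            found_ch = int(np.argmin(np.abs(edges - found)))
            assert abs(found_ch - true_ch) <= 1

    def test_bands_tile_bank_range(self, spectral_bank):
        planted = [100.0, 900.0, 7250.0]
        lms = [pca_loadings(gen_block_envelopes(spectral_bank, planted, 2000,
                                                seed=s), 4, bank=spectral_bank)
               for s in range(4)]
        bs = infer_bands([grand_average(lms)], spectral_bank, SPECTRAL_CRITERIA,
                         target_bands=2, domain="spectral")
        assert bs.edges()[0] == spectral_bank.f_lo
        assert bs.edges()[-1] == spectral_bank.f_hi
        for a, b in zip(bs.bands[:-1], bs.bands[1:]):
            assert a.hi == b.lo

    def test_grand_average_stability_between_corpus_halves(self, spectral_bank):
        # distinct block powers (1/f-like ordering) keep component order
        # stable across files, as in natural spectral bands
        planted = [100.0, 370.0, 900.0, 2100.0, 4100.0, 7250.0]
        scales = (1.0, 0.85, 0.72, 0.61, 0.52)
        lms = [pca_loadings(gen_block_envelopes(spectral_bank, planted, 2000,
                                                seed=s, block_scales=scales),
                            5, bank=spectral_bank)
               for s in range(100)]
        a = grand_average(lms[:50]).abs_loadings
        b = grand_average(lms[50:]).abs_loadings
        assert np.max(np.abs(a - b)) < 0.05


class TestTemporalPipeline:
    def test_recovers_planted_modulator_bands(self, small_audio_corpus,
                                              reference_spectral_bands, mod_bank):
        avgs, bands = temporal_pipeline(small_audio_corpus,
                                        reference_spectral_bands, mod_bank)
        assert len(avgs) == 5
        assert len(bands) == 3
        edges = bands.edges()
        # boundaries fall in the gaps between the 1.5/7/30 Hz modulators
        assert 1.5 < edges[1] < 7.0
        assert 7.0 < edges[2] < 30.0
        # retained-component loading peaks within one channel of each rate
        ga = grand_average(avgs)
        centers = np.asarray(mod_bank.centers)
        found = set()
        for c in range(ga.n_components):
            pks, _ = detect_peaks_troughs(ga.abs_loadings[:, c], TEMPORAL_CRITERIA)
            found.update(pks)
        for rate in (1.5, 7.0, 30.0):
            ch = int(np.argmin(np.abs(centers - rate)))
            assert any(abs(p - ch) <= 1 for p in found), f"no peak near {rate} Hz"
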