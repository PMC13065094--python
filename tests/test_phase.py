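import numpy as np
import pytest
from scipy.special import i0, i1

from samph import (CarrierSpec, aggregate_by_age, band_modulator, coupled_chain,
                   determine_ratio, gen_modulator_chain, gen_utterance, inst_phase,
                   mean_cycle_length, mfp, psi, psi_profile)
from samph.phase import RatioPair, candidate_grid, ratio_from_label, records_to_frame

FS = 120.0


def _tone(rate, dur=60.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return np.cos(2 * np.pi * rate * t + phase)


class TestBandModulator:
    def test_in_band_modulator_preserved(self):
        x = _tone(1.5)
        y = band_modulator(x, FS, (0.9, 2.5))
        sl = slice(int(5 * FS), -int(5 * FS))
        assert np.corrcoef(x[sl], y[sl])[0, 1] >= 0.99

    def test_out_of_band_modulator_attenuated(self):
        x = _tone(7.0)
        y = band_modulator(x, FS, (0.9, 2.5))
        atten = 10 * np.log10(np.mean(x ** 2) / np.mean(y ** 2))
        assert atten >= 20.0

    def test_dc_removed(self):
        y = band_modulator(np.full(int(30 * FS), 3.0), FS, (0.9, 2.5))
        assert np.abs(y).max() < 1e-6

    def test_trim_removes_requested_span(self):
        y = band_modulator(_tone(1.5, 20.0), FS, (0.9, 2.5), trim_s=3.0)
        assert y.size == int(20 * FS) - 2 * int(3 * FS)


class TestInstPhase:
    def test_phase_slope_matches_rate(self):
        ph = inst_phase(_tone(2.0), FS)
        slope = np.polyfit(np.arange(ph.theta.size) / FS, ph.theta, 1)[0]
        assert slope == pytest.approx(4 * np.pi, rel=0.01)

    def test_sin_lags_cos_by_quarter_cycle(self):
        t = np.arange(int(60 * FS)) / FS
        pc = inst_phase(np.cos(2 * np.pi * 2 * t), FS)
        ps = inst_phase(np.sin(2 * np.pi * 2 * t), FS)
        sl = slice(int(5 * FS), -int(5 * FS))
        diff = (pc.theta - ps.theta)[sl]
        assert np.allclose(diff, np.pi / 2, atol=0.02)

    def test_noise_free_harmonic_pair_locks(self):
        th1 = inst_phase(_tone(1.5), FS)
        th2 = inst_phase(_tone(3.0, phase=0.9), FS)
        sl = slice(int(5 * FS), -int(5 * FS))
        gpd = (2 * th1.theta - th2.theta)[sl]
        assert np.ptp(gpd) < 0.05


class TestMeanCycleLength:
    def test_pure_tone_cycle_length(self):
        assert mean_cycle_length(_tone(2.0), FS) == pytest.approx(500.0, rel=0.01)

    def test_small_ripple_cycles_excluded(self):
        x = _tone(2.0) + 0.05 * _tone(20.0)
        assert mean_cycle_length(x, FS) == pytest.approx(500.0, rel=0.02)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            mean_cycle_length(np.ones(1000), FS)


class TestDetermineRatio:
    def test_worked_cycle_length_example(self):
        # cycle lengths 2000 ms and 1500 ms -> n:m = 4:3
        rp = determine_ratio(2000.0, 1500.0)
        assert (rp.n, rp.m) == (4, 3)
        assert rp.label == "3:4"

    def test_exact_halving(self):
        rp = determine_ratio(2000.0, 1000.0)
        assert rp.label == "1:2" and (rp.n, rp.m) == (2, 1)

    def test_snap_matches_brute_force_over_grid(self):
        grid = candidate_grid()
        for t_fast in (1490.0, 1340.0, 990.0, 660.0, 510.0):
            best = min(grid, key=lambda c: abs(c.value - 2000.0 / t_fast))
            assert determine_ratio(2000.0, t_fast).label == best.label

    def test_out_of_grid_clamped_with_warning(self, caplog):
        rp = determine_ratio(9000.0, 1000.0)
        assert rp.label == "1:4"

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            determine_ratio(1000.0, 2000.0)

    def test_multipliers_coprime_and_label_mapping(self):
        for rp in candidate_grid():
            a, b = (int(v) for v in rp.label.split(":"))
            assert (rp.n, rp.m) == (b, a)
        with pytest.raises(ValueError):
            RatioPair(label="2:4", n=4, m=2)


class TestPsi:
    def test_perfect_lock_gives_one(self):
        n = int(60 * FS)
        th1 = 2 * np.pi * 2.0 * np.arange(n) / FS
        th2 = 2 * th1 + 0.7
        assert psi(th1, th2, 2, 1) == pytest.approx(1.0, abs=1e-12)

    def test_independent_phases_give_near_zero(self):
        rng = np.random.default_rng(0)
        value = psi(rng.uniform(0, 2 * np.pi, 10 ** 6),
                    rng.uniform(0, 2 * np.pi, 10 ** 6), 1, 1)
        assert value < 0.005

    def test_von_mises_phase_difference_matches_bessel_ratio(self):
        rng = np.random.default_rng(7)
        n = 200000
        th1 = np.cumsum(rng.uniform(0, 0.1, n))
        th2 = th1 + rng.vonmises(0.0, 2.0, n)
        assert psi(th1, th2, 1, 1) == pytest.approx(i1(2.0) / i0(2.0), abs=0.02)

    def test_invariance_to_time_shift_and_phase_offset(self):
        chain = gen_modulator_chain(coupled_chain(2.0), 120.0, FS, seed=4)
        m1 = band_modulator(chain.mods[0], FS, (0.9, 2.5))
        m2 = band_modulator(chain.mods[1], FS, (2.5, 17.0))
        th1, th2 = inst_phase(m1, FS).theta, inst_phase(m2, FS).theta
        base = psi(th1, th2, 2, 1)
        shifted = psi(th1[120:], th2[120:], 2, 1)
        offset = psi(th1 + 1.23, th2, 2, 1)
        assert shifted == pytest.approx(base, abs=0.02)
        assert offset == pytest.approx(base, abs=1e-12)

    def test_bounds_and_length_checks(self):
        with pytest.raises(ValueError):
            psi(np.zeros(50), np.zeros(50), 1, 1)
        with pytest.raises(ValueError):
            psi(np.zeros(200), np.zeros(100), 1, 1)

    def test_monotone_in_coupling_concentration(self):
        means = []
        for kappa in (8.0, 4.0, 2.0, 1.0, 0.5):
            vals = []
            for seed in range(8):
                chain = gen_modulator_chain(coupled_chain(kappa), 300.0, FS,
                                            seed=seed)
                m1 = band_modulator(chain.mods[0], FS, (0.9, 2.5))
                m2 = band_modulator(chain.mods[1], FS, (2.5, 17.0))
                vals.append(psi(inst_phase(m1, FS), inst_phase(m2, FS), 2, 1))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means[:-1], means[1:]))


class TestPsiProfile:
    def _profile(self, kappa, ratio, seed, dur=60.0):
        chain = gen_modulator_chain(coupled_chain(kappa, ratio=ratio), dur, FS,
                                    seed=seed)
        return psi_profile({1: chain.envelope()}, FS,
                           [(0.9, 2.5), (2.5, 17.0)], file=f"f{seed}")

    def test_coupled_ratio_dominates(self):
        wins = 0
        n = 12
        for seed in range(n):
            recs = {r.ratio.label: r.psi for r in self._profile(3.0, (1, 2), seed)
                    if r.spectral_band == 1}
            wins += recs["1:2"] > recs["1:3"]
        assert wins >= 0.9 * n

    def test_reverse_coupling_reverses_dominance(self):
        wins = 0
        n = 12
        for seed in range(n):
            recs = {r.ratio.label: r.psi for r in self._profile(3.0, (1, 3), seed)
                    if r.spectral_band == 1}
            wins += recs["1:3"] > recs["1:2"]
        assert wins >= 0.9 * n

    def test_uncoupled_corpus_near_zero(self):
        from samph import ModulatorSpec
        specs = (ModulatorSpec(rate=1.5, depth=0.9),
                 ModulatorSpec(rate=3.0, depth=0.5, coupling_ratio=(1, 2),
                               coupling_kappa=0.0))
        vals = []
        for seed in range(5):
            chain = gen_modulator_chain(specs, 60.0, FS, seed=seed)
            recs = psi_profile({1: chain.envelope()}, FS,
                               [(0.9, 2.5), (2.5, 17.0)])
            vals.extend(r.psi for r in recs if r.spectral_band == 1
                        and not r.ratio.label.startswith("auto"))
        assert np.mean(vals) < 0.1

    def test_band_average_rows_emitted(self):
        chain = gen_modulator_chain(coupled_chain(2.0), 30.0, FS, seed=0)
        env = chain.envelope()
        recs = psi_profile({1: env, 2: env}, FS, [(0.9, 2.5), (2.5, 17.0)])
        mean_rows = [r for r in recs if r.spectral_band == "mean"]
        assert {r.ratio.label for r in mean_rows} == {"1:2", "1:3", "2:3"}


class TestMfp:
    def test_silence_zero_and_quadratic_scaling(self):
        assert mfp(np.zeros(500)).mfp == 0.0
        x = np.abs(np.random.default_rng(0).standard_normal(500))
        assert mfp(2 * x).mfp == pytest.approx(4 * mfp(x).mfp)

    def test_tilted_utterance_mfp_decreases_across_bands(self):
        from samph.bands import _band_limited_envelope
        chain = gen_modulator_chain(coupled_chain(2.0), 8.0, 240.0, seed=3)
        sf = gen_utterance(CarrierSpec(), chain, seed=3)
        edges = CarrierSpec().band_edges
        mfps = [mfp(_band_limited_envelope(sf, lo, hi, FS)).mfp
                for lo, hi in zip(edges[:-1], edges[1:])]
        assert all(a > b for a, b in zip(mfps[:-1], mfps[1:]))


class TestAggregateByAge:
    def _frame(self):
        import pandas as pd
        return pd.DataFrame({
            "group": ["CDSf"] * 4, "age_months": [6, 6, 18, 18],
            "ratio_label": ["1:2"] * 4, "psi": [0.5, 0.7, 0.3, 0.5],
        })

    def test_cell_means_and_permutation_invariance(self):
        df = self._frame()
        out = aggregate_by_age(df)
        assert sorted(out.psi) == [0.4, 0.6]
        out2 = aggregate_by_age(df.iloc[::-1])
        assert sorted(out2.psi) == [0.4, 0.6]

    def test_single_row_identity(self):
        out = aggregate_by_age(self._frame().iloc[:1])
        assert len(out) == 1 and out.psi.iloc[0] == 0.5

    def test_missing_cells_absent(self):
        out = aggregate_by_age(self._frame())
        assert set(out.age_months) == {6, 18}
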