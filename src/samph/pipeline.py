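"""End-to-end orchestration: corpus in, band tables / PSI / stats out.

``run_pipeline`` drives the full analysis over a corpus directory (WAV files
plus a ``metadata.tsv`` as written by :func:`samph.synth.gen_corpus`, or
session WAVs with annotation tables): preprocessing, spectral and temporal
band discovery, phase synchronization and mean-frequency-power profiling,
and the group-statistics battery.  Every table carries the config hash so a
run is reproducible from its outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands as bd
from . import phase as ph
from . import stats as st
from .config import PipelineConfig
from .filterbank import design_bank
from .preprocess import SpeechFile, pad_ends, read_wav, znormalize
from .synth import CorpusSpec, gen_corpus

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "render_scalogram", "export_band_tables",
           "load_corpus", "run_envelope_study"]


def run_envelope_study(spec, temporal_bands=((0.9, 2.5), (2.5, 17.0)),
                       ratio_labels=("1:2",), env_rate: float = 120.0) -> pd.DataFrame:
    """Per-file PSI over a corpus design, computed at the envelope level.

    Renders each corpus cell's modulator hierarchy and measures PSI from the
    band-limited product envelope (the demodulation path), skipping audio
    rendering and the acoustic filter bank.  This is the desk-scale route for
    register-contrast and developmental studies, where the quantity under
    test is the PSI statistics, not the acoustic front end (which has its own
    tests).  Returns one row per file x ratio with group/age/kappa metadata.
    """
    from .synth import CorpusSpec, coupled_chain, gen_modulator_chain

    assert isinstance(spec, CorpusSpec)
    ss = np.random.SeedSequence(spec.master_seed)
    cells = [(g, a) for g in spec.groups for a in spec.ages_months]
    rows = []
    for (group, age), cell_ss in zip(cells, ss.spawn(len(cells))):
        kappa = spec.kappa(group, age)
        for j, fss in enumerate(cell_ss.spawn(spec.n_files)):
            rng = np.random.default_rng(fss)
            seed = int(rng.integers(2 ** 31))
            dur = float(rng.uniform(*spec.duration_range))
            chain = gen_modulator_chain(coupled_chain(kappa, ratio=spec.ratio),
                                        dur, env_rate, seed=seed)
            env = chain.envelope()
            mods = [ph.band_modulator(env, env_rate, b) for b in temporal_bands[:2]]
            th = [ph.inst_phase(m, env_rate) for m in mods]
            child = spec.children[j % len(spec.children)]
            for lbl in ratio_labels:
                rp = ph.ratio_from_label(lbl)
                rows.append({"file": f"{group}_{age}_{j}", "group": group,
                             "child_id": child, "age_months": age, "kappa": kappa,
                             "ratio_label": lbl,
                             "psi": ph.psi(th[0], th[1], rp.n, rp.m)})
    return pd.DataFrame(rows)


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha1={cfg.sha1()}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_corpus(corpus_dir, cfg: PipelineConfig):
    """Load (and preprocess) every corpus file listed in metadata.tsv."""
    corpus_dir = Path(corpus_dir)
    meta = pd.read_csv(corpus_dir / "metadata.tsv", sep="\t")
    files, failures = [], []
    for row in meta.itertuples():
        try:
            samples, fs = read_wav(corpus_dir / row.path)
            sf = SpeechFile(samples=samples, fs=fs, group=row.group,
                            speaker=row.speaker, child_id=str(row.child_id),
                            age_months=float(row.age_months))
            sf = znormalize(pad_ends(sf, pad_s=cfg.pad_s))
            sf.notes.append(row.path)
            files.append((row.path, sf))
        except Exception as err:  # noqa: BLE001 - per-file failures logged, run continues
            log.warning("failed to load %s: %s", row.path, err)
            failures.append((row.path, str(err)))
    return meta, files, failures


def export_band_tables(band_set: bd.BandSet, path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Write a band summary table (one row per band, lo-hi Hz, PC support)."""
    rows = []
    for i, b in enumerate(band_set, start=1):
        support = ", ".join(f"PC{c}" for c in b.components) if b.components else "-"
        rows.append({"band": f"Band {i}", "frequency_range_hz": f"{b.lo:.3g}-{b.hi:.3g}",
                     "peak_channel": b.peak_channel, "pc_support": support})
    df = pd.DataFrame(rows)
    if path is not None:
        _write_table(df, Path(path), cfg or PipelineConfig())
    return df


def render_scalogram(samples, fs, out_path, f_lo: float = 0.1, f_hi: float = 40.0,
                     env_fs: float = 120.0, n_freqs: int = 64):
    """Continuous-wavelet scalogram of the broadband amplitude envelope.

    Complex Morlet magnitudes over log-spaced modulation rates, normalized so
    the amplitude maximum sits at 0 dB.  Qualitative output only.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pywt

    from .filterbank import downsample_env, hilbert_env

    env = downsample_env(hilbert_env(np.asarray(samples, float)), fs, env_fs)
    freqs = np.geomspace(f_lo, f_hi, n_freqs)
    wavelet = "cmor1.5-1.0"
    scales = pywt.central_frequency(wavelet) * env_fs / freqs
    coeffs, _ = pywt.cwt(env - env.mean(), scales, wavelet, sampling_period=1 / env_fs)
    mag = np.abs(coeffs)
    mag_db = 20 * np.log10(np.maximum(mag / max(mag.max(), 1e-12), 1e-6))
    fig, ax = plt.subplots(figsize=(8, 4))
    t = np.arange(env.size) / env_fs
    pcm = ax.pcolormesh(t, freqs, mag_db, shading="auto", vmin=-40, vmax=0, cmap="magma")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("modulation rate (Hz)")
    fig.colorbar(pcm, ax=ax, label="dB (0 = max)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return mag_db, freqs


def run_pipeline(cfg: PipelineConfig, corpus, out_dir) -> dict:
    """Run the full analysis; returns a dict of result tables.

    ``corpus`` is either a directory holding WAVs + metadata.tsv or a
    :class:`samph.synth.CorpusSpec` (in which case the corpus is generated
    under ``out_dir/corpus`` first).  Outputs land in ``out_dir``:
    loading matrices, band tables, PSI/MFP tables, a stats report, and a
    per-file failure log.  Deterministic given config + seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(cfg.to_yaml())

    if isinstance(corpus, CorpusSpec):
        corpus_dir = out_dir / "corpus"
        gen_corpus(corpus, corpus_dir)
    else:
        corpus_dir = Path(corpus)
    meta, files, failures = load_corpus(corpus_dir, cfg)
    if failures:
        _write_table(pd.DataFrame(failures, columns=["path", "error"]),
                     out_dir / "failures.tsv", cfg)
    if not files:
        raise RuntimeError("no loadable corpus files")

    spec_bank = design_bank(cfg.spectral_f_lo, cfg.spectral_f_hi,
                            cfg.spectral_channels, cfg.spectral_spacing)
    mod_bank = design_bank(cfg.temporal_f_lo, cfg.temporal_f_hi,
                           cfg.temporal_channels, cfg.temporal_spacing)
    spec_criteria = bd.PeakCriteria(cfg.spectral_peak_separation, cfg.low_cycle_threshold)
    temp_criteria = bd.PeakCriteria(cfg.temporal_peak_separation, cfg.low_cycle_threshold)

    # --- spectral stage ---------------------------------------------------
    spec_loadings = []
    for _, sf in files:
        env = bd.spectral_envelopes(sf, spec_bank, env_fs=cfg.spectral_env_fs)
        n_pad = int(round(sf.pad_s * cfg.spectral_env_fs))
        vals = env.values[n_pad:-n_pad] if n_pad else env.values
        spec_loadings.append(bd.pca_loadings(vals, cfg.spectral_components,
                                             bank=spec_bank,
                                             standardize=cfg.pca_standardize))
    spec_avg = bd.grand_average(spec_loadings)
    spectral_bands = bd.infer_bands([spec_avg], spec_bank, spec_criteria,
                                    target_bands=cfg.spectral_target_bands,
                                    domain="spectral")
    _write_table(pd.DataFrame(spec_avg.abs_loadings,
                              columns=[f"PC{i+1}" for i in range(spec_avg.n_components)]),
                 out_dir / "spectral_loadings.tsv", cfg)
    spectral_table = export_band_tables(spectral_bands, out_dir / "spectral_bands.tsv", cfg)

    # --- temporal stage ---------------------------------------------------
    temp_avgs, temporal_bands = bd.temporal_pipeline(
        [sf for _, sf in files], spectral_bands, mod_bank,
        n_components=cfg.temporal_components, env_fs=cfg.temporal_env_fs,
        criteria=temp_criteria, target_bands=cfg.temporal_target_bands,
        standardize=cfg.pca_standardize)
    temporal_table = export_band_tables(temporal_bands, out_dir / "temporal_bands.tsv", cfg)

    # --- PSI / MFP stage --------------------------------------------------
    tbands = [(b.lo, b.hi) for b in temporal_bands]
    psi_records, mfp_records = [], []
    for name, sf in files:
        env_by_band = {}
        for i, b in enumerate(spectral_bands, start=1):
            env = bd._band_limited_envelope(sf, b.lo, b.hi, cfg.temporal_env_fs)
            env_by_band[i] = env
            mfp_records.append(ph.mfp(env, fs=cfg.temporal_env_fs, trim_s=sf.pad_s,
                                      spectral_band=i, file=name, group=sf.group,
                                      speaker=sf.speaker, age_months=sf.age_months))
        psi_records.extend(ph.psi_profile(env_by_band, cfg.temporal_env_fs, tbands,
                                          ratio_labels=cfg.ratio_labels,
                                          trim_s=sf.pad_s, file=name, group=sf.group,
                                          speaker=sf.speaker, age_months=sf.age_months))
    psi_df = ph.records_to_frame(psi_records)
    mfp_df = ph.records_to_frame(mfp_records)
    _write_table(psi_df, out_dir / "psi.tsv", cfg)
    _write_table(mfp_df, out_dir / "mfp.tsv", cfg)

    # --- statistics -------------------------------------------------------
    stats_rows = []
    mean_psi = psi_df[psi_df.spectral_band == "mean"]
    child_of = dict(zip(meta.path, meta.child_id.astype(str)))
    for lbl in cfg.ratio_labels:
        sub = mean_psi[mean_psi.ratio_label == lbl]
        if sub.group.nunique() >= 2 and sub.groupby("group").size().min() >= 3:
            for r in st.compare_groups(sub.psi.to_numpy(), sub.group.to_numpy()):
                stats_rows.append({"family": f"psi[{lbl}]", **_res_row(r)})
        # second one-way omnibus, by participant (two-factor designs are
        # reported as two separate one-way rank tests)
        children = sub.file.map(child_of)
        if children.nunique() >= 2 and children.value_counts().min() >= 3:
            for r in st.compare_groups(sub.psi.to_numpy(), children.to_numpy(),
                                       pairs=()):
                r.test = f"{r.test}:by-participant"
                stats_rows.append({"family": f"psi[{lbl}]", **_res_row(r)})
    try:
        for r in st.mfp_anova(mfp_df):
            stats_rows.append({"family": "mfp", **_res_row(r)})
    except ValueError as err:
        log.warning("MFP ANOVA skipped: %s", err)
    by_age = ph.aggregate_by_age(mean_psi)
    trend_ps = []
    for grp in ("CDSf", "CDSm"):
        for lbl in cfg.ratio_labels:
            cell = by_age[(by_age.group == grp) & (by_age.ratio_label == lbl)]
            if len(cell) >= 3:
                r = st.age_trend(cell.psi.to_numpy(), cell.age_months.to_numpy())
                r.test = f"{r.test}:{grp}[{lbl}]"
                trend_ps.append(r)
    if trend_ps:
        for r, q in zip(trend_ps, st.bh_fdr([r.p for r in trend_ps])):
            r.p_fdr = float(q)
            stats_rows.append({"family": "age-trend", **_res_row(r)})
    stats_df = pd.DataFrame(stats_rows)
    _write_table(stats_df, out_dir / "stats.tsv", cfg)

    return {"metadata": meta, "spectral_bands": spectral_bands,
            "temporal_bands": temporal_bands, "spectral_table": spectral_table,
            "temporal_table": temporal_table, "psi": psi_df, "mfp": mfp_df,
            "stats": stats_df, "failures": failures}


def _res_row(r: st.StatsResult) -> dict:
    return {"test": r.test, "statistic": r.statistic, "df": str(r.df),
            "p": r.p, "p_fdr": r.p_fdr, "effect": r.effect,
            "effect_name": r.effect_name, "ci": str(r.ci),
            "significant": r.significant, "notes": r.notes}
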