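"""Group statistics: normality gating, contrasts, FDR, equivalence, trends.

The battery mirrors common practice in corpus acoustics: Shapiro-Wilk
normality gating routes to parametric (t tests, Pearson) or nonparametric
(Kruskal-Wallis, rank-sum, Spearman) paths; pairwise p values are
Benjamini-Hochberg FDR corrected; segment-duration equivalence between
registers uses ratio-based TOST on the log scale with a +/-10% geometric-mean
margin; mean-frequency-power band effects use a repeated-measures ANOVA with
Tukey post hocs.  Effect-size sign convention for register contrasts is
CDS - ADS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "StatsResult",
    "EquivalenceResult",
    "normality_gate",
    "cohen_d",
    "compare_groups",
    "bh_fdr",
    "tost_log_equivalence",
    "age_trend",
    "mfp_anova",
    "DEFAULT_PAIRS",
]

DEFAULT_PAIRS = (("CDSf", "ADSf"), ("CDSm", "ADSm"), ("ADSf", "ADSm"), ("CDSf", "CDSm"))


@dataclass
class StatsResult:
    test: str
    statistic: float
    df: float | tuple | None = None
    p: float = float("nan")
    p_fdr: float | None = None
    effect: float | None = None
    effect_name: str = ""
    ci: tuple | None = None
    significant: bool | None = None
    notes: str = ""

    def __post_init__(self):
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p value outside [0, 1]")
        if self.p_fdr is not None and self.p_fdr < self.p - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


@dataclass
class EquivalenceResult:
    gm_ratio: float
    ci: tuple  # 90% CI of the GM ratio
    margin: tuple = (0.90, 1.10)
    equivalent: bool = False

    def __post_init__(self):
        lo, hi = self.ci
        if not (lo <= self.gm_ratio <= hi):
            raise ValueError("GM ratio must lie inside its CI")
        self.equivalent = bool(self.margin[0] <= lo and hi <= self.margin[1])


def normality_gate(groups: dict, alpha: float = 0.05):
    """Shapiro-Wilk per group; any p < alpha routes to the nonparametric path.

    Returns ("parametric" | "nonparametric", {label: StatsResult}).
    """
    results = {}
    path = "parametric"
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            raise ValueError(f"group {label!r}: need n >= 3 for a normality test")
        w, p = sps.shapiro(vals)
        results[label] = StatsResult(test="shapiro-wilk", statistic=float(w),
                                     df=vals.size, p=float(p))
        if p < alpha:
            path = "nonparametric"
    return path, results


def cohen_d(a: np.ndarray, b: np.ndarray, conf: float = 0.95):
    """Pooled-SD Cohen's d of a - b with a normal-approximation CI."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    if sp == 0:
        return 0.0, (0.0, 0.0)
    d = (a.mean() - b.mean()) / sp
    se = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    z = sps.norm.ppf(0.5 + conf / 2)
    return float(d), (float(d - z * se), float(d + z * se))


def kw_eta_squared(h: float, k: int, n: int) -> float:
    """eta^2 for Kruskal-Wallis: (H - k + 1) / (n - k), floored at 0."""
    return float(max(0.0, (h - k + 1) / (n - k)))


def compare_groups(values, labels, pairs=DEFAULT_PAIRS, path: str | None = None,
                   alpha: float = 0.05) -> list:
    """Omnibus Kruskal-Wallis plus prespecified pairwise register contrasts.

    On the parametric path pairwise contrasts are Welch t tests with Cohen's
    d and its CI; on the nonparametric path they are rank-sum tests whose
    standardized statistic is reported as W.  Pairwise p values are FDR
    corrected across the contrast family.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    if path is None:
        path, _ = normality_gate(groups, alpha=alpha)

    out: list[StatsResult] = []
    present = [g for g, v in groups.items() if v.size]
    if len(present) >= 2:
        h, p = sps.kruskal(*[groups[g] for g in present])
        out.append(StatsResult(test="kruskal-wallis", statistic=float(h),
                               df=len(present) - 1, p=float(p),
                               effect=kw_eta_squared(h, len(present), values.size),
                               effect_name="eta2", notes=f"path={path}"))

    pair_results = []
    for g1, g2 in pairs:
        if g1 not in groups or g2 not in groups:
            continue
        a, b = groups[g1], groups[g2]
        if path == "parametric":
            t, p = sps.ttest_ind(a, b, equal_var=False)
            d, ci = cohen_d(a, b)
            dof = a.size + b.size - 2
            pair_results.append(StatsResult(
                test=f"t:{g1}-{g2}", statistic=float(t), df=dof, p=float(p),
                effect=d, effect_name="cohens_d", ci=ci))
        else:
            w, p = sps.ranksums(a, b)
            d, ci = cohen_d(a, b)
            pair_results.append(StatsResult(
                test=f"W:{g1}-{g2}", statistic=float(w), p=float(p),
                effect=d, effect_name="cohens_d", ci=ci))
    if pair_results:
        adj = bh_fdr([r.p for r in pair_results])
        for r, q in zip(pair_results, adj):
            r.p_fdr = float(q)
            r.significant = bool(q < alpha)
    return out + pair_results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def tost_log_equivalence(a, b, margin=(0.90, 1.10), conf: float = 0.90) -> EquivalenceResult:
    """Ratio-based equivalence of two duration samples on the log scale.

    The ``conf`` CI of the mean log-difference (Welch) is exponentiated to a
    geometric-mean-ratio CI; equivalence holds iff that CI lies entirely
    within ``margin``.
    """
    la, lb = np.log(np.asarray(a, float)), np.log(np.asarray(b, float))
    diff = la.mean() - lb.mean()
    va, vb = la.var(ddof=1) / la.size, lb.var(ddof=1) / lb.size
    se = np.sqrt(va + vb)
    if se == 0:
        return EquivalenceResult(gm_ratio=float(np.exp(diff)),
                                 ci=(float(np.exp(diff)), float(np.exp(diff))),
                                 margin=margin)
    dof = (va + vb) ** 2 / (va ** 2 / (la.size - 1) + vb ** 2 / (lb.size - 1))
    tcrit = sps.t.ppf(0.5 + conf / 2, dof)
    lo, hi = diff - tcrit * se, diff + tcrit * se
    return EquivalenceResult(gm_ratio=float(np.exp(diff)),
                             ci=(float(np.exp(lo)), float(np.exp(hi))), margin=margin)


def age_trend(psi_means, ages_months, path: str = "nonparametric") -> StatsResult:
    """Correlation of PSI with child age (Spearman by default)."""
    x = np.asarray(ages_months, dtype=float)
    y = np.asarray(psi_means, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched series of length >= 3")
    if path == "parametric":
        r, p = sps.pearsonr(x, y)
        name = "pearson-r"
    else:
        r, p = sps.spearmanr(x, y)
        name = "spearman-rho"
    return StatsResult(test=name, statistic=float(r), df=x.size - 2, p=float(p),
                       effect=float(r), effect_name=name)


def mfp_anova(records: pd.DataFrame, alpha: float = 0.05) -> list:
    """Repeated-measures ANOVA of mean frequency power across spectral bands.

    ``records`` needs columns file, spectral_band, mfp; the file is the
    within-subject unit.  Tukey post hocs follow the omnibus test.
    """
    df = records[["file", "spectral_band", "mfp"]].copy()
    if df["file"].nunique() < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 files")
    res = AnovaRM(df, depvar="mfp", subject="file", within=["spectral_band"]).fit()
    row = res.anova_table.iloc[0]
    out = [StatsResult(test="rm-anova:spectral_band", statistic=float(row["F Value"]),
                       df=(float(row["Num DF"]), float(row["Den DF"])),
                       p=float(row["Pr > F"]))]
    tukey = pairwise_tukeyhsd(df["mfp"].to_numpy(), df["spectral_band"].astype(str).to_numpy(),
                              alpha=alpha)
    summ = pd.DataFrame(tukey._results_table.data[1:], columns=tukey._results_table.data[0])
    for _, r in summ.iterrows():
        out.append(StatsResult(test=f"tukey:{r['group1']}-{r['group2']}",
                               statistic=float(r["meandiff"]), p=float(r["p-adj"]),
                               significant=bool(r["reject"])))
    return out
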