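"""Statistical battery for motility metric tables.

Mirrors the analysis applied to the cohort metrics: Shapiro-Wilk normality
screening; Kruskal-Wallis with Dunn-Bonferroni post-hoc for the three-way
DVARS comparison (free-breathing vs motion-removed vs breath-hold); Welch's
two-sample t-test for lesser-vs-greater curvature contrasts; one-way ANOVA
with Tukey HSD post-hoc for the four GMI region groups; and distal-to-
proximal trend fits (degree-1 polynomial slope plus Spearman rank
correlation against region index).  Alpha is 0.05 throughout.

Standard tests are delegated to scipy; the Dunn post-hoc (rank-based
pairwise z-tests with tie correction) is implemented here because no
common scientific Python package ships it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatResult", "normality_screen", "compare_three_groups",
           "compare_two_groups", "compare_groups_anova", "dunn_posthoc",
           "trend_fit", "build_report"]

ALPHA = 0.05


@dataclass
class StatResult:
    test: str
    statistic: float
    pvalue: float
    groups: list = field(default_factory=list)
    direction: str = ""
    posthoc: object = None          # DataFrame of pairwise results or None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _as_groups(groups) -> dict:
    if isinstance(groups, dict):
        return {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"group{i + 1}": np.asarray(v, dtype=float)
            for i, v in enumerate(groups)}


def normality_screen(groups) -> StatResult:
    """Shapiro-Wilk per group; parametric tests indicated iff all pass at alpha.

    Constant samples have an undefined W; they are reported as non-normal
    (p = 0) with a warning.
    """
    gd = _as_groups(groups)
    per_group = {}
    all_normal = True
    for name, vals in gd.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r}: Shapiro-Wilk needs n >= 3")
        if np.ptp(vals) == 0:
            warnings.warn(f"group {name!r} is constant; normality undefined, "
                          "treated as non-normal", stacklevel=2)
            per_group[name] = (float("nan"), 0.0)
            all_normal = False
            continue
        w, p = sps.shapiro(vals)
        per_group[name] = (float(w), float(p))
        if p < ALPHA:
            all_normal = False
    worst = min(p for _, p in per_group.values())
    return StatResult(test="shapiro-wilk", statistic=float("nan"), pvalue=worst,
                      groups=list(gd), extra={"per_group": per_group,
                                              "parametric": all_normal})


def dunn_posthoc(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank test after Kruskal-Wallis, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) * (1/n_i + 1/n_j) )
    with tie term T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([groups[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, start = {}, 0
    for k in names:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "pvalue": float(p), "pvalue_adj": float(p_adj)})
    return pd.DataFrame(rows)


def compare_three_groups(a, b, c, labels=("a", "b", "c")) -> StatResult:
    """Kruskal-Wallis across three groups; Dunn-Bonferroni post-hoc if p < alpha."""
    gd = dict(zip(labels, [np.asarray(g, dtype=float) for g in (a, b, c)]))
    for k, v in gd.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    if all(np.array_equal(gd[labels[0]], v) for v in gd.values()):
        return StatResult(test="kruskal-wallis", statistic=0.0, pvalue=1.0,
                          groups=list(labels))
    h, p = sps.kruskal(*gd.values())
    posthoc = dunn_posthoc(gd) if p < ALPHA else None
    return StatResult(test="kruskal-wallis", statistic=float(h), pvalue=float(p),
                      groups=list(labels), posthoc=posthoc,
                      extra={"posthoc_test": "dunn-bonferroni"})


def compare_two_groups(a, b, equal_var: bool = False) -> StatResult:
    """Two-sample t-test (Welch by default; ``equal_var=True`` for pooled)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return StatResult(test="t-test", statistic=0.0, pvalue=1.0,
                          groups=["a", "b"], direction="equal")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    direction = "a>b" if a.mean() > b.mean() else ("a<b" if a.mean() < b.mean()
                                                  else "equal")
    return StatResult(test="t-test" + ("" if equal_var else " (welch)"),
                      statistic=float(t), pvalue=float(p),
                      groups=["a", "b"], direction=direction)


def compare_groups_anova(groups) -> StatResult:
    """One-way ANOVA; Tukey HSD post-hoc when p < alpha."""
    gd = _as_groups(groups)
    if len(gd) < 3:
        raise ValueError("ANOVA comparison needs >= 3 groups")
    for k, v in gd.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    vals = list(gd.values())
    if all(np.array_equal(vals[0], v) for v in vals):
        return StatResult(test="anova", statistic=0.0, pvalue=1.0,
                          groups=list(gd))
    f, p = sps.f_oneway(*vals)
    posthoc = None
    if p < ALPHA:
        res = sps.tukey_hsd(*vals)
        names = list(gd)
        rows = []
        for i, j in combinations(range(len(names)), 2):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(res.statistic[i, j]),
                         "pvalue_adj": float(res.pvalue[i, j])})
        posthoc = pd.DataFrame(rows)
    return StatResult(test="anova", statistic=float(f), pvalue=float(p),
                      groups=list(gd), posthoc=posthoc,
                      extra={"posthoc_test": "tukey-hsd"})


def trend_fit(region_means, indices=None, degree: int = 1) -> dict:
    """Distal-to-proximal trend: polynomial slope and Spearman correlation.

    Fits a degree-``degree`` polynomial of the metric against region index
    and reports the degree-1 coefficient with its p-value (from the linear
    term's t-test), plus the Spearman rank correlation with its p-value.
    A constant sequence reports slope 0 and r = 0 with a warning.
    """
    y = np.asarray(region_means, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if indices is None \
        else np.asarray(indices, dtype=float)
    if len(y) < 3:
        raise ValueError("trend fit needs >= 3 region means")
    if np.ptp(y) == 0:
        warnings.warn("constant region means: trend undefined, reporting "
                      "slope 0 and r 0", stacklevel=2)
        return {"slope": 0.0, "slope_p": 1.0, "spearman_r": 0.0,
                "spearman_p": 1.0, "degree": degree}
    if degree == 1:
        res = sps.linregress(x, y)
        slope, slope_p = float(res.slope), float(res.pvalue)
    else:
        coefs = np.polynomial.polynomial.polyfit(x, y, degree)
        slope = float(coefs[1])
        slope_p = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, rp = sps.spearmanr(x, y)
    if not np.isfinite(r):
        warnings.warn("Spearman correlation undefined; reporting 0", stacklevel=2)
        r, rp = 0.0, 1.0
    return {"slope": slope, "slope_p": slope_p,
            "spearman_r": float(r), "spearman_p": float(rp), "degree": degree}


def _fmt_mean_sd(vals) -> str:
    v = np.asarray(vals, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return "n/a"
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" if len(v) > 1 else f"{v.mean():.2f}"


def build_report(region_metrics: pd.DataFrame, gmi_table: pd.DataFrame,
                 out_dir) -> pd.DataFrame:
    """Run the standard battery on a metric table; write stats.csv and report.md.

    Curvature contrasts (speed, size, occlusion) use Welch's t-test on
    region values; per-curvature trends use the degree-1 fit against
    region index; GMI groups are compared by ANOVA (+ Tukey) when all four
    groups carry estimates.  Output is deterministic given the inputs.
    """
    import pathlib
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = region_metrics
    curvs = sorted(df["curvature"].unique())
    rows = []
    lines = ["# Gastric motility report", "",
             "## Regional metrics (mean ± SD over analyzed regions)", ""]
    lines.append("| curvature | speed (mm/s) | size (mm) | occlusion (%) | frequency (cpm) |")
    lines.append("|---|---|---|---|---|")
    for curv in curvs:
        sub = df[df["curvature"] == curv]
        lines.append(f"| {curv} | {_fmt_mean_sd(sub['speed_mm_s'])} | "
                     f"{_fmt_mean_sd(sub['size_mm'])} | "
                     f"{_fmt_mean_sd(sub['occlusion_pct'])} | "
                     f"{_fmt_mean_sd(sub['frequency_cpm'])} |")
    lines.append("")

    metric_cols = [("speed_mm_s", "speed"), ("size_mm", "size"),
                   ("occlusion_pct", "occlusion")]
    if len(curvs) == 2:
        lines += ["## Lesser vs greater curvature (Welch t-test)", ""]
        for col, name in metric_cols:
            a = df[df["curvature"] == curvs[0]][col].dropna().to_numpy()
            b = df[df["curvature"] == curvs[1]][col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                res = compare_two_groups(a, b)
                rows.append({"test": res.test, "metric": name,
                             "comparison": f"{curvs[0]} vs {curvs[1]}",
                             "statistic": res.statistic, "pvalue": res.pvalue})
                lines.append(f"- {name}: t = {res.statistic:.3f}, "
                             f"p = {res.pvalue:.4f}")
        lines.append("")

    lines += ["## Distal-to-proximal trends (slope vs region index; Spearman)", ""]
    for curv in curvs:
        sub = df[df["curvature"] == curv].sort_values("region")
        for col, name in metric_cols:
            vals = sub[col].to_numpy()
            idx = sub["region"].to_numpy()
            ok = np.isfinite(vals)
            if ok.sum() < 3:
                continue
            tr = trend_fit(vals[ok], indices=idx[ok])
            rows.append({"test": "trend", "metric": name,
                         "comparison": curv, "statistic": tr["slope"],
                         "pvalue": tr["slope_p"],
                         "spearman_r": tr["spearman_r"],
                         "spearman_p": tr["spearman_p"]})
            lines.append(f"- {curv} {name}: slope = {tr['slope']:.3f} "
                         f"(p = {tr['slope_p']:.4f}), r = {tr['spearman_r']:.3f} "
                         f"(p = {tr['spearman_p']:.4f})")
    lines.append("")

    lines += ["## GMI by region group", ""]
    lines.append("| group | mean speed (mm/s) | mean size (mm) | GMI (mm²/s) |")
    lines.append("|---|---|---|---|")
    for _, r in gmi_table.iterrows():
        lines.append(f"| {r['group']} | {r['mean_speed_mm_s']:.2f} | "
                     f"{r['mean_size_mm']:.2f} | {r['gmi_mm2_s']:.2f} |")
    lines.append("")

    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out_dir / "stats.csv", index=False, float_format="%.6g")
    (out_dir / "report.md").write_text("\n".join(lines))
    return stats_df
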