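"""Statistical layer: profile correlations, extrema/band concordance, zone
ANOVA + Tukey HSD, location Kruskal-Wallis and inter-fragment correlations.

All tests are thin, explicitly parameterized wrappers around scipy and
statsmodels that return tidy result records; nothing switches tests
silently — normality/homoscedasticity diagnostics are reported alongside,
never used as gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class CorrelationResult:
    method: str  # "spearman" | "pearson"
    coefficient: float
    p_value: float
    n: int
    pair: tuple[str, str] = ("", "")
    scope: str = ""


@dataclass
class ZoneStats:
    variable: str
    grouping: str
    per_zone: pd.DataFrame  # zone, n, mean, median
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    diagnostics: dict = field(default_factory=dict)


@dataclass
class GroupComparison:
    test: str  # "kruskal_wallis" | "anova_tukey"
    grouping: str
    variable: str
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    tukey: pd.DataFrame | None = None


def correlate_profiles(
    v1: np.ndarray,
    v2: np.ndarray,
    pair: tuple[str, str] = ("", ""),
) -> CorrelationResult:
    """Spearman rank correlation of two aligned per-Z series.

    Pairs with a missing value in either series are dropped; ties receive
    average ranks; the p-value is two-sided.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("series must be aligned (equal length)")
    keep = np.isfinite(v1) & np.isfinite(v2)
    v1, v2 = v1[keep], v2[keep]
    if len(v1) < 3:
        raise ValueError(f"need >= 3 aligned values, have {len(v1)}")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero variance in one of the series")
    rho, p = stats.spearmanr(v1, v2)
    return CorrelationResult(
        method="spearman", coefficient=float(rho), p_value=float(p),
        n=len(v1), pair=pair, scope="intra-colonial along Z",
    )


def concordance_extrema_band(
    extrema_mm: np.ndarray,
    band_midpoints_mm: np.ndarray,
) -> tuple[CorrelationResult, GroupComparison]:
    """Concordance of model extrema with the stereoscope green-band locations.

    Returns the Spearman correlation between the per-fragment extremum
    locations and band midpoints, together with a two-group one-way ANOVA
    asking whether the two sets of locations differ overall.
    """
    ext = np.asarray(extrema_mm, dtype=float)
    mid = np.asarray(band_midpoints_mm, dtype=float)
    if ext.shape != mid.shape:
        raise ValueError("extrema and band midpoints must pair up fragment-by-fragment")
    if len(ext) < 3:
        raise ValueError("need >= 3 fragments")
    if np.ptp(ext) == 0 or np.ptp(mid) == 0:
        raise ValueError("zero variance in locations")
    rho, p = stats.spearmanr(ext, mid)
    corr = CorrelationResult(
        method="spearman", coefficient=float(rho), p_value=float(p),
        n=len(ext), pair=("extremum_mm", "band_midpoint_mm"), scope="across fragments",
    )
    if np.ptp(np.concatenate([ext, mid])) == 0:
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p = stats.f_oneway(ext, mid)
        if not np.isfinite(f_stat):  # identical groups
            f_stat, f_p = 0.0, 1.0
    anova = GroupComparison(
        test="anova", grouping="method", variable="location_mm",
        statistic=float(f_stat), p_value=float(f_p),
        group_means={"extrema": float(ext.mean()), "band": float(mid.mean())},
        group_n={"extrema": len(ext), "band": len(mid)},
    )
    return corr, anova


def zone_anova(
    values: np.ndarray,
    zones: np.ndarray,
    variable: str = "",
    grouping: str = "overall",
    alpha: float = 0.05,
) -> ZoneStats:
    """One-way ANOVA across the three intra-colonial zones plus Tukey HSD.

    Shapiro-Wilk (per zone) and Levene diagnostics are attached to the result
    but do not alter which test runs.
    """
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    zone_names = [z for z in pd.unique(zones)]
    groups = [values[zones == z] for z in zone_names]
    for name, g in zip(zone_names, groups):
        if len(g) < 2:
            raise ValueError(f"zone {name!r} has fewer than 2 observations")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(values) == 0:
        raise ValueError("all zones constant and identical: F undefined")
    f_stat, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(values, zones, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    per_zone = pd.DataFrame(
        {
            "zone": zone_names,
            "n": [len(g) for g in groups],
            "mean": [float(g.mean()) for g in groups],
            "median": [float(np.median(g)) for g in groups],
        }
    )
    diagnostics = {}
    try:
        diagnostics["levene_p"] = float(stats.levene(*groups).pvalue)
        diagnostics["shapiro_p"] = {
            str(name): float(stats.shapiro(g).pvalue) if 3 <= len(g) <= 5000 else np.nan
            for name, g in zip(zone_names, groups)
        }
    except Exception:  # degenerate zones: diagnostics stay absent, test stands
        pass
    return ZoneStats(
        variable=variable, grouping=grouping, per_zone=per_zone,
        anova_f=float(f_stat), anova_p=float(p), tukey=tukey,
        diagnostics=diagnostics,
    )


def compare_groups(
    means: np.ndarray,
    groups: np.ndarray,
    grouping: str,
    variable: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare fragment means between locations or species.

    Locations (unbalanced, e.g. Caribbean n=10 vs Pacific n=20) are compared
    with the non-parametric Kruskal-Wallis test; species (balanced) with
    one-way ANOVA plus a full Tukey HSD pairwise table.
    """
    means = np.asarray(means, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    sets = [means[groups == g] for g in names]
    for name, g in zip(names, sets):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    group_means = {str(n): float(g.mean()) for n, g in zip(names, sets)}
    group_n = {str(n): len(g) for n, g in zip(names, sets)}

    if grouping == "location":
        if np.ptp(means) == 0:  # all identical: H defined as 0, no evidence
            return GroupComparison(
                test="kruskal_wallis", grouping=grouping, variable=variable,
                statistic=0.0, p_value=1.0, group_means=group_means, group_n=group_n,
            )
        h, p = stats.kruskal(*sets)
        return GroupComparison(
            test="kruskal_wallis", grouping=grouping, variable=variable,
            statistic=float(h), p_value=float(p),
            group_means=group_means, group_n=group_n,
        )
    if grouping == "species":
        f_stat, p = stats.f_oneway(*sets)
        tk = pairwise_tukeyhsd(means, groups, alpha=alpha)
        tukey = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
        return GroupComparison(
            test="anova_tukey", grouping=grouping, variable=variable,
            statistic=float(f_stat), p_value=float(p),
            group_means=group_means, group_n=group_n, tukey=tukey,
        )
    raise ValueError(f"unknown grouping {grouping!r} (expected 'location' or 'species')")


def interspecific_correlation(
    x: np.ndarray,
    y: np.ndarray,
    pair: tuple[str, str] = ("", ""),
) -> CorrelationResult:
    """Pearson correlation of per-fragment mean values across fragments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must pair up fragment-by-fragment")
    if len(x) < 3:
        raise ValueError(f"need >= 3 fragments, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        method="pearson", coefficient=float(r), p_value=float(p),
        n=len(x), pair=pair, scope="inter-specific across fragments",
    )
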