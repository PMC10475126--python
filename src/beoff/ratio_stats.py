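"""Specificity analytics over off:on-target ratio tables.

Coordinate convention used throughout the package: protospacer positions are
numbered 1-20 from the 5' end, with the PAM following position 20; the seed
region (1-9 nt proximal to the PAM) is therefore positions 12-20. A mean
off:on ratio at or below 0.8 marks a position as significantly reducing
off-target editing, anchored on the observation that single mismatches leave
the ratio near 0.85 on average.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANT_DECREASE_THRESHOLD = 0.8


def ratio_by_mutation_type(table: pd.DataFrame, value: str = "off_on_ratio") -> pd.DataFrame:
    """Per-mutation-type mean, sd and n, ordered by decreasing mean ratio."""
    out = (
        table.groupby("mutation_type")[value]
        .agg(mean="mean", sd="std", n="count")
        .sort_values("mean", ascending=False)
        .reset_index()
    )
    return out


def positional_effect(table: pd.DataFrame, mutation_type: str,
                      value: str = "off_on_ratio",
                      position: str = "position",
                      threshold: float = SIGNIFICANT_DECREASE_THRESHOLD) -> pd.DataFrame:
    """Per-position mean +/- sd for a single-event mutation type.

    Rows with mean ratio <= ``threshold`` are flagged as a significant
    decrease in off-target editing.
    """
    sub = table[table["mutation_type"] == mutation_type]
    out = (
        sub.groupby(position)[value]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values(position)
        .reset_index(drop=True)
    )
    out["significant_decrease"] = out["mean"] <= threshold
    return out


def zscore(values, ddof: int = 0) -> np.ndarray:
    """Population z-scores (ddof=0 by convention; set ddof=1 for sample sd)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if sd == 0 or np.isnan(sd):
        raise ValueError("z-score undefined for a constant group")
    return (v - v.mean()) / sd


def zscore_map(table: pd.DataFrame, value: str = "off_on_ratio",
               within: list[str] | None = None, over: str = "position",
               ddof: int = 0) -> pd.DataFrame:
    """Standardize per-``over`` mean values within each ``within`` group.

    For each group (for example mutation type x nucleotide), the mean ratio
    is computed per position and standardized across positions; |z| > 1
    singles out positions whose contribution departs from that group's
    average. Constant groups, whose sd is zero, are flagged and carry NaN.
    """
    within = within or ["mutation_type"]
    means = table.groupby(within + [over])[value].mean().reset_index(name="mean_value")

    def _z(g):
        sd = g["mean_value"].std(ddof=ddof)
        g = g.copy()
        if sd == 0 or np.isnan(sd):
            g["z"] = np.nan
            g["degenerate"] = True
        else:
            g["z"] = (g["mean_value"] - g["mean_value"].mean()) / sd
            g["degenerate"] = False
        return g

    out = means.groupby(within, group_keys=False)[means.columns].apply(_z)
    return out.reset_index(drop=True)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    n = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(1.0, p * n)


def position_tests(table: pd.DataFrame, mutation_type: str,
                   value: str = "off_on_ratio", position: str = "position",
                   equal_var: bool = False) -> pd.DataFrame:
    """All pairwise two-sample t-tests between positions, Bonferroni-adjusted.

    Welch's unequal-variance test by default; ``equal_var=True`` gives the
    pooled-variance Student test.
    """
    sub = table[table["mutation_type"] == mutation_type]
    groups = {p: g[value].to_numpy() for p, g in sub.groupby(position)}
    positions = sorted(groups)
    rows = []
    for i, a in enumerate(positions):
        for b in positions[i + 1:]:
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
            rows.append({"pos_a": a, "pos_b": b, "t": t, "p_raw": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p_raw"], len(out))
    return out


def correlation_metrics(predicted, observed) -> dict:
    """Spearman and Pearson correlation between two efficiency/ratio vectors."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("vectors must have equal length")
    return {
        "spearman": float(stats.spearmanr(predicted, observed).statistic),
        "pearson": float(stats.pearsonr(predicted, observed).statistic),
        "n": int(predicted.size),
    }


def stratified_correlations(table: pd.DataFrame, predicted: str, observed: str,
                            by: str = "mutation_type") -> pd.DataFrame:
    """Per-stratum Spearman/Pearson; strata partition the table exactly."""
    rows = []
    for key, g in table.groupby(by):
        if len(g) < 3 or g[observed].nunique() < 2 or g[predicted].nunique() < 2:
            rows.append({by: key, "spearman": np.nan, "pearson": np.nan, "n": len(g)})
            continue
        m = correlation_metrics(g[predicted], g[observed])
        rows.append({by: key, **m})
    out = pd.DataFrame(rows)
    assert out["n"].sum() == len(table)
    return out


def dataset_headline(table: pd.DataFrame, value: str = "off_on_ratio") -> dict:
    """Headline numbers of an efficiency table in the deposited-table dialect:
    valid off-target count, overall mean off:on ratio, and the 1-mismatch mean."""
    off = table[(table["mutation_type"] != "on") & table[value].notna()]
    one_mis = off[off["mutation_type"] == "1mis"]
    return {
        "n_offtarget_records": int(len(off)),
        "mean_off_on_ratio": float(off[value].mean()),
        "mean_1mis_ratio": float(one_mis[value].mean()) if len(one_mis) else float("nan"),
    }
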