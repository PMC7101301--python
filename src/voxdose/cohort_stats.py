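"""Patient- and cohort-level dose statistics.

Total tumor dose (TTD) is the volume-weighted mean of per-lesion doses,

    TTD = sum_i D_i V_i / sum_i V_i,

so it is invariant to rescaling all volumes and bounded by the min/max
lesion dose.  Cohort summaries use the population standard deviation
(n denominator) throughout.  Group comparisons use the two-sided
Wilcoxon rank-sum test (exact enumeration for small groups, tie-
corrected normal approximation otherwise); correlations are Pearson's.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .cohort import CohortTable


def total_tumor_dose(lesions) -> float:
    """Volume-weighted mean lesion dose; ``lesions`` is a sequence of
    (dose_gy, volume_ml) pairs."""
    if len(lesions) == 0:
        raise ValueError("no lesions")
    d = np.array([x[0] for x in lesions], dtype=np.float64)
    v = np.array([x[1] for x in lesions], dtype=np.float64)
    if np.any(v <= 0):
        raise ValueError("lesion volumes must be positive")
    return float((d * v).sum() / v.sum())


def dose_per_activity(dose_gy: float, activity_mbq: float) -> float:
    """Absorbed dose per injected activity in mGy/MBq."""
    if activity_mbq <= 0:
        raise ValueError("activity must be positive")
    return dose_gy * 1000.0 / activity_mbq


def summarize(values) -> tuple[float, float, float, float]:
    """(mean, population sd, min, max) of a value vector."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    return float(x.mean()), float(x.std()), float(x.min()), float(x.max())


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    w_obs = ranks[:n1].sum()
    expect = ranks.sum() * n1 / (n1 + n2)
    dev = abs(w_obs - expect)
    total = comb(n1 + n2, n1)
    count = 0
    for idx in combinations(range(n1 + n2), n1):
        if abs(ranks[list(idx)].sum() - expect) >= dev - 1e-12:
            count += 1
    return float(w_obs), count / total


def _ranksum_normal(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    _, t_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return float(w), 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    return float(w), float(2.0 * sps.norm.sf(abs(z)))


def ranksum(group1, group2, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank sum of group1, p).  ``method``: 'exact' enumerates all
    rank assignments (tie-aware, feasible for <= ~10 per group),
    'normal' uses the tie-corrected normal approximation, 'auto' picks
    exact for small groups.
    """
    x = np.asarray(group1, dtype=np.float64)
    y = np.asarray(group2, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if max(x.size, y.size) <= 10 else "normal"
    if method == "exact":
        return _ranksum_exact(x, y)
    if method == "normal":
        return _ranksum_normal(x, y)
    raise ValueError(f"unknown method {method!r}")


def cga_delta_correlation(table: CohortTable) -> tuple[float, float]:
    """Pearson correlation of (CgA_post - CgA_pre) with TTD.

    The difference is defined post minus pre, so a dose-driven decline
    of the tumor marker appears as a negative correlation.
    """
    p = table.patients
    if p["cga_pre_ug_l"].isna().any() or p["cga_post_ug_l"].isna().any():
        raise ValueError("missing CgA values")
    delta = p["cga_post_ug_l"] - p["cga_pre_ug_l"]
    return pearson(delta, p["ttd_gy"])


def cohort_report(table: CohortTable) -> dict:
    """All cohort summaries, correlations and tests in one dictionary."""
    p = table.patients
    mean_activity = float(p["activity_mbq"].mean())
    out: dict = {"n_patients": table.n_patients,
                 "total_lesions": table.total_lesions}
    for key, col in (("kidney", "kidney_dose_gy"),
                     ("spleen", "spleen_dose_gy"),
                     ("ttd", "ttd_gy")):
        mean, sd, lo, hi = summarize(p[col])
        out[key] = {"mean_gy": mean, "sd_gy": sd, "min_gy": lo, "max_gy": hi,
                    "per_activity_mgy_mbq": dose_per_activity(mean, mean_activity)}
    out["cga_pre_mean_ug_l"] = float(p["cga_pre_ug_l"].mean())
    out["cga_post_mean_ug_l"] = float(p["cga_post_ug_l"].mean())
    r, pv = pearson(p["cga_pre_ug_l"], p["ttd_gy"])
    out["pearson_cga_pre_ttd"] = {"rho": r, "p": pv}
    r, pv = cga_delta_correlation(table)
    out["pearson_cga_delta_ttd"] = {"rho": r, "p": pv}
    low = p.loc[p["grade"] < 3, "ttd_gy"].to_numpy()
    high = p.loc[p["grade"] == 3, "ttd_gy"].to_numpy()
    stat, pv = ranksum(low, high)
    out["ttd_by_grade"] = {"rank_sum_low_grade": stat, "p": pv,
                           "n_low_grade": int(low.size), "n_high_grade": int(high.size)}
    return out
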