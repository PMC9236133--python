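"""Hierarchical aggregation (growth cone -> animal -> genotype) and statistics.

Measurements are collected per growth cone, nested in animals, nested in
genotype x age groups.  Reported group values follow the published tables'
convention: each animal contributes its own mean (and SEM = sd/sqrt(n)),
and the genotype "total mean" is the *unweighted* arithmetic mean of the
per-animal means — weighting by per-animal N does not reproduce the printed
totals.  The genotype SEM column is likewise the unweighted mean of the
per-animal SEMs.

Group comparisons use the two-sided Mann-Whitney rank-sum test (exact when
sample sizes permit) or per-metric t-tests with Holm-Sidak multiplicity
adjustment across the metric family, mirroring the published analysis.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .track import classify_turning

__all__ = [
    "validate_table",
    "per_animal_summary",
    "grand_mean",
    "group_summary",
    "compare_groups",
    "holm_sidak_adjust",
    "angle_histogram",
    "round_half_away",
]

TABLE_COLUMNS = ["genotype", "age_months", "animal_id", "gc_id", "metric_name", "value"]


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the tables' convention, unlike banker's)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the measurement-table contract: required columns, finite values,
    no duplicate (animal_id, gc_id, metric_name)."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if not np.isfinite(table["value"]).all():
        raise ValueError("measurement values must be finite")
    dup = table.duplicated(subset=["animal_id", "gc_id", "metric_name"])
    if dup.any():
        raise ValueError("duplicate (animal_id, gc_id, metric_name) rows")
    return table


def per_animal_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean, SEM (sd/sqrt(n), ddof=1) and n for every metric.

    SEM is undefined (NaN) for single-measurement animals.
    """
    validate_table(table)
    g = table.groupby(["genotype", "age_months", "animal_id", "metric_name"])["value"]
    out = g.agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan, n="count")
    return out.reset_index()


def grand_mean(per_animal_means, decimals: int | None = None) -> float:
    """Unweighted arithmetic mean of per-animal means (the "Total mean" row).

    With ``decimals`` the result is rounded half away from zero, matching
    the printed tables (2 decimals generally, 3 for velocities in um/s).
    """
    vals = np.asarray(list(per_animal_means), dtype=float)
    if vals.size == 0:
        raise ValueError("empty list of per-animal means")
    m = float(vals.mean())
    return round_half_away(m, decimals) if decimals is not None else m


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Genotype x age x metric summary from per-animal summaries."""
    per_animal = per_animal_summary(table)
    rows = []
    for (gen, age, metric), sub in per_animal.groupby(
        ["genotype", "age_months", "metric_name"]
    ):
        rows.append(
            {
                "genotype": gen,
                "age_months": age,
                "metric_name": metric,
                "grand_mean": grand_mean(sub["mean"]),
                "sem": float(sub["sem"].mean()) if sub["sem"].notna().any() else np.nan,
                "n_animals": int(len(sub)),
                "n_gcs": int(sub["n"].sum()),
            }
        )
    return pd.DataFrame(rows)


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (smallest: 1-(1-p)^m)."""
    p = np.asarray(list(pvalues), dtype=float)
    return multipletests(p, method="holm-sidak")[1]


def compare_groups(a, b, method: str = "mann_whitney"):
    """Two-group comparison, mirroring the published statistics.

    * ``mann_whitney`` — two-sided rank-sum p-value, exact when sample sizes
      permit (no ties, small n), asymptotic otherwise.  ``a`` and ``b`` are
      value sequences; identical all-tied groups give p = 1.
    * ``holm_sidak_t`` — ``a`` and ``b`` are dicts {metric_name: values};
      per-metric two-sided t-tests adjusted with Holm-Sidak across the
      metric family; returns {metric_name: adjusted p}.
    """
    if method == "mann_whitney":
        a = np.asarray(list(a), dtype=float)
        b = np.asarray(list(b), dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 values")
        if np.all(a == a[0]) and np.all(b == a[0]):
            return 1.0  # degenerate all-tied case: no evidence of difference
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method == "holm_sidak_t":
        if not isinstance(a, dict) or not isinstance(b, dict):
            raise TypeError("holm_sidak_t expects dicts {metric_name: values}")
        if set(a) != set(b):
            raise ValueError("metric families of the two groups differ")
        metrics = sorted(a)
        raw = []
        for m in metrics:
            x = np.asarray(list(a[m]), dtype=float)
            y = np.asarray(list(b[m]), dtype=float)
            if x.size < 2 or y.size < 2:
                raise ValueError("each group needs at least 2 values")
            if np.all(x == x[0]) and np.all(y == x[0]):
                raw.append(1.0)
            else:
                raw.append(float(stats.ttest_ind(x, y).pvalue))
        adj = holm_sidak_adjust(raw)
        return dict(zip(metrics, adj))
    raise ValueError(f"unknown method: {method}")


def angle_histogram(mean_angles) -> pd.DataFrame:
    """Turning-class frequency table over per-track mean angles.

    Fractions over {horizontal, diagonal, vertical} sum to 1.
    """
    angles = list(mean_angles)
    if not angles:
        raise ValueError("empty list of mean angles")
    classes = [classify_turning(a) for a in angles]
    order = ["horizontal", "diagonal", "vertical"]
    frac = {c: classes.count(c) / len(classes) for c in order}
    return pd.DataFrame({"turning_class": order, "fraction": [frac[c] for c in order]})
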