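"""Assay-validation statistics for methylation titration experiments.

A titration series measures control DNA mixed to known methylation levels
(canonically 0/25/50/75/100%).  Linearity of the measured signal across
the series — summarised as the per-CpG R² of observed vs expected
methylation and its mean per amplicon — is the key evidence that an
amplicon quantifies methylation differences faithfully; amplicons with a
PCR bias show depressed R² or a slope away from 1.

All statistics operate on the percent scale (0–100).  Expected inputs are
long-format DataFrames with columns ``amplicon``, ``pos``, ``level``
(expected percent) and ``meth_pct`` (observed percent); the
:func:`calls_to_long` helper produces them from a :class:`CallTable` plus
a sample sheet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, InsufficientDesignError
from .meth_call import CallTable

DEFAULT_R2_THRESHOLD = 0.98
DEFAULT_SLOPE_RANGE = (0.9, 1.1)


@dataclass
class TitrationFit:
    """Per-CpG regression results and per-amplicon summaries."""

    per_cpg: pd.DataFrame  # amplicon, pos, slope, intercept, r_squared, n_levels
    per_amplicon: pd.DataFrame  # amplicon, mean_r_squared, mean_slope, n_cpgs, nonlinear


@dataclass
class ConditionComparison:
    """Absolute methylation differences between two measurement conditions."""

    per_level: pd.DataFrame | None  # amplicon, level, mean_abs_diff (pp)
    per_amplicon: pd.DataFrame  # amplicon, mean_abs_diff (pp), n_sites
    overall: float  # mean of per-amplicon means (pp)


@dataclass
class ReplicateStats:
    """Replicate standard deviations per CpG x level cell."""

    per_cell: pd.DataFrame  # amplicon, pos, level, n_replicates, sd (pp)
    mean_sd: float
    max_sd: float


def calls_to_long(calls: CallTable, sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """CpG calls as a long table on the percent scale.

    ``sheet`` is an optional sample sheet (columns ``sample`` plus any of
    ``condition``, ``level``, ``replicate``) merged on ``sample``.
    """
    df = calls.df
    out = df[df["context"] == "CpG"][
        ["sample", "amplicon", "pos", "is_reference_cpg", "coverage", "meth_fraction"]
    ].copy()
    out["meth_pct"] = out["meth_fraction"] * 100.0
    if sheet is not None:
        out = out.merge(sheet, on="sample", how="inner")
    return out.reset_index(drop=True)


def fit_titration(
    observed: pd.DataFrame,
    levels: tuple[float, ...] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
) -> TitrationFit:
    """Ordinary least squares of observed vs expected methylation per CpG.

    ``observed`` needs columns ``amplicon``, ``pos``, ``level`` and
    ``meth_pct``; ``levels`` optionally restricts to a subset of expected
    levels.  The design must span at least 3 distinct levels.  Degenerate
    CpGs (zero variance in the observations) get slope 0 and a missing R²
    and are excluded from the amplicon mean.  An amplicon is flagged
    ``nonlinear`` when its mean R² falls below ``r2_threshold`` or its mean
    slope leaves ``slope_range``.
    """
    df = observed
    if levels is not None:
        df = df[df["level"].isin(levels)]
    n_levels = df["level"].nunique()
    if n_levels < 3:
        raise InsufficientDesignError(
            f"titration design has {n_levels} level(s); at least 3 required"
        )
    cpg_rows = []
    dropped = 0
    for (amplicon, pos), grp in df.groupby(["amplicon", "pos"], sort=True):
        x = grp["level"].to_numpy(dtype=float)
        y = grp["meth_pct"].to_numpy(dtype=float)
        if len(np.unique(x)) < 3:
            dropped += 1
            continue
        if np.ptp(y) == 0.0:
            slope, intercept, r2 = 0.0, float(y[0]), np.nan
        else:
            res = stats.linregress(x, y)
            slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        cpg_rows.append(
            {
                "amplicon": amplicon,
                "pos": pos,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
                "n_levels": len(np.unique(x)),
            }
        )
    if dropped:
        warnings.warn(f"excluded {dropped} CpG(s) observed at fewer than 3 levels")
    per_cpg = pd.DataFrame(
        cpg_rows,
        columns=["amplicon", "pos", "slope", "intercept", "r_squared", "n_levels"],
    )
    amp_rows = []
    for amplicon, grp in per_cpg.groupby("amplicon", sort=True):
        mean_r2 = float(grp["r_squared"].mean())  # skips NaN
        mean_slope = float(grp["slope"].mean())
        nonlinear = bool(
            (not np.isnan(mean_r2) and mean_r2 < r2_threshold)
            or not slope_range[0] <= mean_slope <= slope_range[1]
        )
        amp_rows.append(
            {
                "amplicon": amplicon,
                "mean_r_squared": mean_r2,
                "mean_slope": mean_slope,
                "n_cpgs": int(grp["r_squared"].notna().sum()),
                "nonlinear": nonlinear,
            }
        )
    per_amplicon = pd.DataFrame(
        amp_rows,
        columns=["amplicon", "mean_r_squared", "mean_slope", "n_cpgs", "nonlinear"],
    )
    return TitrationFit(per_cpg=per_cpg, per_amplicon=per_amplicon)


def compare_conditions(
    test: pd.DataFrame, reference: pd.DataFrame
) -> ConditionComparison:
    """Mean absolute methylation difference of a test condition vs reference.

    Both inputs need columns ``amplicon``, ``pos`` and ``meth_pct``; a
    ``level`` column, when present in both, joins titration levels as well.
    Differences are reported in percentage points, aggregated per amplicon
    (mean over CpGs and levels) and overall (mean over amplicons).  The
    comparison is symmetric in its arguments.
    """
    keys = ["amplicon", "pos"]
    if "level" in test.columns and "level" in reference.columns:
        keys.append("level")
    merged = test.merge(
        reference, on=keys, suffixes=("_test", "_ref"), how="inner"
    )
    if merged.empty:
        raise ComparisonError("conditions share no sites to compare")
    merged["abs_diff"] = (merged["meth_pct_test"] - merged["meth_pct_ref"]).abs()
    per_level = None
    if "level" in keys:
        per_level = (
            merged.groupby(["amplicon", "level"], as_index=False)["abs_diff"]
            .mean()
            .rename(columns={"abs_diff": "mean_abs_diff"})
        )
    per_amplicon = (
        merged.groupby("amplicon", as_index=False)
        .agg(mean_abs_diff=("abs_diff", "mean"), n_sites=("abs_diff", "size"))
    )
    overall = float(per_amplicon["mean_abs_diff"].mean())
    return ConditionComparison(
        per_level=per_level, per_amplicon=per_amplicon, overall=overall
    )


def replicate_sd(replicates: pd.DataFrame) -> ReplicateStats:
    """Sample SD over replicate measurements per CpG x level cell.

    ``replicates`` needs columns ``amplicon``, ``pos``, ``level`` and
    ``meth_pct`` with one row per replicate measurement.  SDs use the n-1
    denominator; cells with fewer than 2 replicates are excluded with a
    warning.  The aggregate mean and max are taken over all cells — the
    most granular consistent aggregation.
    """
    rows = []
    n_excluded = 0
    for (amplicon, pos, level), grp in replicates.groupby(
        ["amplicon", "pos", "level"], sort=True
    ):
        if len(grp) < 2:
            n_excluded += 1
            continue
        rows.append(
            {
                "amplicon": amplicon,
                "pos": pos,
                "level": level,
                "n_replicates": len(grp),
                "sd": float(grp["meth_pct"].std(ddof=1)),
            }
        )
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} cell(s) with fewer than 2 replicates")
    per_cell = pd.DataFrame(
        rows, columns=["amplicon", "pos", "level", "n_replicates", "sd"]
    )
    if per_cell.empty:
        return ReplicateStats(per_cell=per_cell, mean_sd=float("nan"), max_sd=float("nan"))
    return ReplicateStats(
        per_cell=per_cell,
        mean_sd=float(per_cell["sd"].mean()),
        max_sd=float(per_cell["sd"].max()),
    )
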