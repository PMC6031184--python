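"""The three quality-control filters applied to methylation calls.

1. **Conversion**: a sample x amplicon unit whose bisulfite conversion rate
   (fraction of CHH observations read as T) is below 95% is excluded
   entirely — incomplete conversion inflates apparent methylation at every
   site of the unit.
2. **PCR artifacts**: a non-reference CpG presenting at very low coverage
   (below a configurable fraction of the amplicon's median reference-CpG
   coverage) *and* an extreme methylation level (~0 or ~100%) is removed
   as an amplification artifact.  Non-reference CpGs at substantial
   coverage are retained as candidate SNP-created CpGs — the analysis is
   deliberately not limited to reference CpGs.
3. **Coverage**: CpG sites supported by fewer than 1000 informative reads
   are removed; below that depth the sampling noise of the methylation
   estimate dominates the biological signal.

Boundary semantics are inclusive-pass: a rate of exactly 0.95 and a
coverage of exactly 1000 pass.  Filters are applied per sample, so an
amplicon dropped in one sample survives in the others.  All flags are
computed from the *input* table before any removal, which makes the three
filters commute.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .meth_call import CallTable, conversion_table

DEFAULT_MIN_CONVERSION = 0.95
DEFAULT_MIN_COVERAGE = 1000
DEFAULT_ARTIFACT_COV_FRAC = 0.05
DEFAULT_ARTIFACT_EXTREMITY = 0.05


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the three filters (inclusive-pass boundaries)."""

    min_conversion: float = DEFAULT_MIN_CONVERSION
    min_coverage: int = DEFAULT_MIN_COVERAGE
    artifact_cov_frac: float = DEFAULT_ARTIFACT_COV_FRAC
    artifact_extremity: float = DEFAULT_ARTIFACT_EXTREMITY


@dataclass(frozen=True)
class QCSummary:
    """Survival statistics over sample x amplicon units and CpG sites."""

    n_units: int
    n_units_passing: int
    fraction_passing: float
    n_units_failed_conversion: int
    n_artifact_sites: int
    n_cpg_sites_total: int
    n_cpg_sites_retained: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class QCResult:
    """Filtered calls plus the per-filter reports and the summary."""

    calls: CallTable
    conversion: pd.DataFrame
    artifacts: pd.DataFrame
    summary: QCSummary


def filter_conversion(
    calls: CallTable, threshold: float = DEFAULT_MIN_CONVERSION
) -> pd.DataFrame:
    """Per-unit conversion report: rate, pass flag and failure reason.

    A unit fails iff its rate is strictly below ``threshold``; a unit whose
    rate is undefined (no CHH coverage) fails with reason
    ``"no CHH coverage"`` rather than passing silently.
    """
    report = conversion_table(calls)
    rate = report["conversion_rate"]
    report["passed"] = rate >= threshold  # NaN compares False
    report["reason"] = np.select(
        [rate.isna(), rate < threshold],
        ["no CHH coverage", "conversion below threshold"],
        default="",
    )
    return report


def detect_artifacts(
    calls: CallTable,
    cov_frac: float = DEFAULT_ARTIFACT_COV_FRAC,
    extremity: float = DEFAULT_ARTIFACT_EXTREMITY,
) -> pd.DataFrame:
    """Flag PCR-artifact candidates among non-reference CpG sites.

    A non-reference CpG is flagged iff its coverage is below
    ``cov_frac x median reference-CpG coverage`` of its sample x amplicon
    unit *and* its methylation is ≤ ``extremity`` or ≥ ``1 - extremity``.
    Reference CpGs are never flagged.  Units without reference CpGs cannot
    provide a median and are skipped with a warning.
    """
    df = calls.df
    ref = df[(df["context"] == "CpG") & df["is_reference_cpg"]]
    medians = (
        ref.groupby(["sample", "amplicon"])["coverage"].median().rename("median_cov")
    )
    nonref = df[(df["context"] == "CpG") & ~df["is_reference_cpg"]].copy()
    nonref = nonref.merge(
        medians, left_on=["sample", "amplicon"], right_index=True, how="left"
    )
    skipped = nonref[nonref["median_cov"].isna()]
    if len(skipped):
        units = sorted(
            set(zip(skipped["sample"], skipped["amplicon"]))
        )
        warnings.warn(
            f"artifact detection skipped for unit(s) without reference CpGs: {units}"
        )
    low_cov = nonref["coverage"] < cov_frac * nonref["median_cov"]
    extreme = (nonref["meth_fraction"] <= extremity) | (
        nonref["meth_fraction"] >= 1 - extremity
    )
    nonref["is_artifact"] = (low_cov & extreme).fillna(False)
    cols = [
        "sample", "amplicon", "pos", "coverage", "meth_fraction",
        "median_cov", "is_artifact",
    ]
    return nonref[cols].reset_index(drop=True)


def filter_coverage(
    calls: CallTable, min_cov: int = DEFAULT_MIN_COVERAGE
) -> CallTable:
    """Remove CpG-context sites with coverage strictly below ``min_cov``.

    Non-CpG (CHH/CHG) records are retained: they carry the conversion-rate
    evidence, not methylation calls.
    """
    df = calls.df
    keep = (df["context"] != "CpG") | (df["coverage"] >= min_cov)
    return CallTable(df[keep].reset_index(drop=True))


def qc_summary(
    calls: CallTable,
    conversion: pd.DataFrame,
    artifacts: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> QCSummary:
    """Combine the per-filter reports into survival statistics.

    A unit passes iff its conversion passes and at least one of its CpG
    sites survives the artifact and coverage filters.
    """
    df = calls.df
    units = df[["sample", "amplicon"]].drop_duplicates()
    n_units = len(units)
    failed_conv = set(
        zip(
            conversion.loc[~conversion["passed"], "sample"],
            conversion.loc[~conversion["passed"], "amplicon"],
        )
    )
    artifact_keys = set(
        zip(
            artifacts.loc[artifacts["is_artifact"], "sample"],
            artifacts.loc[artifacts["is_artifact"], "amplicon"],
            artifacts.loc[artifacts["is_artifact"], "pos"],
        )
    )
    cpg = df[df["context"] == "CpG"]
    site_keys = list(zip(cpg["sample"], cpg["amplicon"], cpg["pos"]))
    unit_ok = np.array(
        [(s, a) not in failed_conv for s, a, _ in site_keys], dtype=bool
    )
    retained = (
        np.array([k not in artifact_keys for k in site_keys], dtype=bool)
        & (cpg["coverage"].to_numpy() >= min_coverage)
        & unit_ok
    )
    n_retained = int(retained.sum())
    passing_units = set(
        zip(cpg.loc[retained, "sample"], cpg.loc[retained, "amplicon"])
    )
    n_passing = len(passing_units)
    return QCSummary(
        n_units=n_units,
        n_units_passing=n_passing,
        fraction_passing=n_passing / n_units if n_units else float("nan"),
        n_units_failed_conversion=len(failed_conv & set(map(tuple, units.values))),
        n_artifact_sites=len(artifact_keys),
        n_cpg_sites_total=len(cpg),
        n_cpg_sites_retained=n_retained,
    )


def drop_failed_units(calls: CallTable, conversion: pd.DataFrame) -> CallTable:
    """Remove every record of units that failed the conversion filter."""
    failed = set(
        zip(
            conversion.loc[~conversion["passed"], "sample"],
            conversion.loc[~conversion["passed"], "amplicon"],
        )
    )
    df = calls.df
    keep = [
        (s, a) not in failed for s, a in zip(df["sample"], df["amplicon"])
    ]
    return CallTable(df[keep].reset_index(drop=True))


def drop_artifacts(calls: CallTable, artifacts: pd.DataFrame) -> CallTable:
    """Remove sites flagged as PCR artifacts."""
    flagged = set(
        zip(
            artifacts.loc[artifacts["is_artifact"], "sample"],
            artifacts.loc[artifacts["is_artifact"], "amplicon"],
            artifacts.loc[artifacts["is_artifact"], "pos"],
        )
    )
    df = calls.df
    keep = [
        not (ctx == "CpG" and not ref and (s, a, p) in flagged)
        for s, a, p, ctx, ref in zip(
            df["sample"], df["amplicon"], df["pos"],
            df["context"], df["is_reference_cpg"],
        )
    ]
    return CallTable(df[keep].reset_index(drop=True))


def run_qc(calls: CallTable, thresholds: QCThresholds = QCThresholds()) -> QCResult:
    """Apply all three filters and summarise survival.

    All flags are computed on the input table, then combined, so the
    retained set does not depend on filter order.
    """
    conv = filter_conversion(calls, thresholds.min_conversion)
    art = detect_artifacts(
        calls, thresholds.artifact_cov_frac, thresholds.artifact_extremity
    )
    summary = qc_summary(calls, conv, art, thresholds.min_coverage)
    filtered = drop_failed_units(calls, conv)
    filtered = drop_artifacts(filtered, art)
    filtered = filter_coverage(filtered, thresholds.min_coverage)
    return QCResult(calls=filtered, conversion=conv, artifacts=art, summary=summary)


def control_check(
    calls: CallTable,
    amplicon: str,
    expected: float = 0.5,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Check an internal control amplicon against its expected methylation.

    Intended for an imprinted-locus control (expected ~50% in genomic
    DNA).  Units whose mean reference-CpG methylation deviates from
    ``expected`` by more than ``tolerance`` are returned and warned about;
    deviation is advisory, not a hard failure.
    """
    df = calls.df
    ref = df[
        (df["amplicon"] == amplicon)
        & (df["context"] == "CpG")
        & df["is_reference_cpg"]
        & (df["coverage"] > 0)
    ]
    mean = ref.groupby("sample", as_index=False)["meth_fraction"].mean()
    mean["deviates"] = (mean["meth_fraction"] - expected).abs() > tolerance
    flagged = mean[mean["deviates"]]
    if len(flagged):
        warnings.warn(
            f"control amplicon {amplicon}: {len(flagged)} sample(s) deviate "
            f"more than {tolerance:.0%} from expected {expected:.0%} methylation"
        )
    return mean
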