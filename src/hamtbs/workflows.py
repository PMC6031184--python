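"""End-to-end study workflows built from the toolkit's modules.

These functions wire the simulator, overlap trimming, methylation calling,
QC and validation statistics into the two standard in-silico experiments:

* a **titration study** — one sample per expected methylation level,
  processed to a per-CpG linearity fit; and
* a **condition comparison** — the replicate-design contrast between a
  reference condition measured as the mean of three independent replicates
  and a pooled condition measured once at the combined depth.

They are the programmatic counterparts of the ``hamtbs simulate`` /
``hamtbs titrate`` command-line entry points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth_call import CallTable, call_sites
from .overlap_trim import trim_pairs
from .panel_model import Panel
from .qc_filters import QCResult, QCThresholds, run_qc
from .readsim import MethylationProfile, SimConfig, simulate_sample
from .titration import ConditionComparison, TitrationFit, calls_to_long, compare_conditions, fit_titration

DEFAULT_TITRATION_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)


def derive_seed(master: int | None, *key: int) -> int | None:
    """A reproducible child seed (< 2^31) for one sub-experiment."""
    if master is None:
        return None
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class TitrationStudy:
    """Everything produced by one simulated titration experiment."""

    calls: CallTable  # unfiltered calls, one sample per level
    sheet: pd.DataFrame  # sample, level (percent)
    qc: QCResult
    fit: TitrationFit


def simulate_titration_calls(
    panel: Panel,
    levels_pct: tuple[float, ...] = DEFAULT_TITRATION_LEVELS,
    depth: int = 2000,
    conversion_efficiency: float = 0.99,
    base_error_rate: float = 0.001,
    read_length: int = 300,
    seed: int | None = 0,
) -> tuple[CallTable, pd.DataFrame]:
    """Simulate, trim and call one sample per titration level.

    Returns the pooled call table (samples named ``L<level>``) and the
    matching sample sheet with expected levels in percent.
    """
    tables = []
    sheet_rows = []
    for idx, level in enumerate(levels_pct):
        profile = MethylationProfile.uniform(panel, level / 100.0)
        config = SimConfig(
            depth=depth,
            conversion_efficiency=conversion_efficiency,
            base_error_rate=base_error_rate,
            read_length=read_length,
            seed=derive_seed(seed, idx),
        )
        sim = simulate_sample(panel, profile, config)
        sample = f"L{level:g}"
        tables.append(call_sites(trim_pairs(sim.pairs), panel, sample=sample))
        sheet_rows.append({"sample": sample, "level": level})
    return CallTable.concat(tables), pd.DataFrame(sheet_rows)


def run_titration_study(
    panel: Panel,
    levels_pct: tuple[float, ...] = DEFAULT_TITRATION_LEVELS,
    depth: int = 2000,
    conversion_efficiency: float = 0.99,
    base_error_rate: float = 0.001,
    read_length: int = 300,
    seed: int | None = 0,
    thresholds: QCThresholds = QCThresholds(),
) -> TitrationStudy:
    """Simulated titration -> calling -> QC -> per-CpG linearity fit."""
    calls, sheet = simulate_titration_calls(
        panel,
        levels_pct=levels_pct,
        depth=depth,
        conversion_efficiency=conversion_efficiency,
        base_error_rate=base_error_rate,
        read_length=read_length,
        seed=seed,
    )
    qc = run_qc(calls, thresholds)
    observed = calls_to_long(qc.calls, sheet)
    fit = fit_titration(observed)
    return TitrationStudy(calls=calls, sheet=sheet, qc=qc, fit=fit)


def run_condition_comparison(
    panel: Panel,
    levels_pct: tuple[float, ...] = DEFAULT_TITRATION_LEVELS,
    replicate_depth: int = 1000,
    n_replicates: int = 3,
    pooled_depth: int = 3000,
    conversion_efficiency: float = 0.99,
    base_error_rate: float = 0.001,
    read_length: int = 300,
    seed: int | None = 0,
) -> ConditionComparison:
    """Replicate-design contrast on identically simulated control DNA.

    The reference condition measures each titration level as the mean of
    ``n_replicates`` independent simulations at ``replicate_depth`` each;
    the pooled condition measures the same truth once at ``pooled_depth``.
    Returns the per-amplicon mean absolute methylation difference between
    the two conditions in percentage points.
    """
    ref_rows = []
    pooled_rows = []
    for idx, level in enumerate(levels_pct):
        profile = MethylationProfile.uniform(panel, level / 100.0)
        rep_tables = []
        for rep in range(n_replicates):
            config = SimConfig(
                depth=replicate_depth,
                conversion_efficiency=conversion_efficiency,
                base_error_rate=base_error_rate,
                read_length=read_length,
                seed=derive_seed(seed, idx, rep),
            )
            sim = simulate_sample(panel, profile, config)
            rep_tables.append(
                call_sites(trim_pairs(sim.pairs), panel, sample=f"rep{rep}")
            )
        rep_long = calls_to_long(CallTable.concat(rep_tables))
        rep_long = rep_long[rep_long["is_reference_cpg"]]
        ref = (
            rep_long.groupby(["amplicon", "pos"], as_index=False)["meth_pct"].mean()
        )
        ref["level"] = level
        ref_rows.append(ref)

        config = SimConfig(
            depth=pooled_depth,
            conversion_efficiency=conversion_efficiency,
            base_error_rate=base_error_rate,
            read_length=read_length,
            seed=derive_seed(seed, idx, n_replicates),
        )
        sim = simulate_sample(panel, profile, config)
        pooled_long = calls_to_long(
            call_sites(trim_pairs(sim.pairs), panel, sample="pooled")
        )
        pooled_long = pooled_long[pooled_long["is_reference_cpg"]]
        pooled = pooled_long[["amplicon", "pos", "meth_pct"]].copy()
        pooled["level"] = level
        pooled_rows.append(pooled)

    reference = pd.concat(ref_rows, ignore_index=True)
    pooled = pd.concat(pooled_rows, ignore_index=True)
    return compare_conditions(pooled, reference)
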