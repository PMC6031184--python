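"""QC filters: boundary semantics, artifact signature, commutation, summary."""

import numpy as np
import pandas as pd
import pytest

from hamtbs import (
    CallTable,
    amplicon_contexts,
    MethylationProfile,
    QCThresholds,
    SimConfig,
    call_sites,
    detect_artifacts,
    filter_conversion,
    filter_coverage,
    inject_artifacts,
    inject_snp_cpg,
    run_qc,
    simulate_sample,
)
from hamtbs.meth_call import CALL_COLUMNS
from hamtbs.overlap_trim import trim_pairs
from hamtbs.qc_filters import drop_artifacts, drop_failed_units, qc_summary
from hamtbs.readsim import synthetic_panel


def _row(sample, amplicon, pos, context, is_ref, n_meth, n_unmeth):
    cov = n_meth + n_unmeth
    return {
        "sample": sample, "amplicon": amplicon, "pos": pos, "context": context,
        "is_reference_cpg": is_ref, "n_meth": n_meth, "n_unmeth": n_unmeth,
        "coverage": cov, "meth_fraction": n_meth / cov if cov else np.nan,
    }


def _table(rows):
    return CallTable(pd.DataFrame(rows, columns=CALL_COLUMNS))


def _unit(sample, amplicon, chh_unmeth=990, chh_meth=10, cpg_cov=2000, pos0=1):
    """One sample x amplicon unit: a CHH site (conversion) plus a CpG site."""
    return [
        _row(sample, amplicon, pos0, "CHH", False, chh_meth, chh_unmeth),
        _row(sample, amplicon, pos0 + 10, "CpG", True,
             int(cpg_cov * 0.3), cpg_cov - int(cpg_cov * 0.3)),
    ]


class TestConversionFilter:
    @pytest.mark.parametrize(
        "n_unmeth,n_meth,passes",
        [
            (990, 10, True),    # 0.99
            (950, 50, True),    # exactly 0.95 passes (strict "lower than" fails)
            (949, 51, False),   # 0.949
        ],
    )
    def test_boundary_semantics(self, n_unmeth, n_meth, passes):
        calls = _table(_unit("s", "a", chh_unmeth=n_unmeth, chh_meth=n_meth))
        report = filter_conversion(calls)
        assert report["passed"].iloc[0] == passes

    def test_no_chh_unit_fails_with_reason(self):
        calls = _table(
            [_row("s", "a", 11, "CpG", True, 500, 1500)]
        )
        report = filter_conversion(calls)
        assert not report["passed"].iloc[0]
        assert report["reason"].iloc[0] == "no CHH coverage"

    def test_empty_table_empty_report(self):
        assert filter_conversion(CallTable.empty()).empty


class TestArtifactFilter:
    def _calls_with_nonref(self, cov, meth_fraction, median_cov=2000):
        n_meth = int(round(cov * meth_fraction))
        rows = _unit("s", "a", cpg_cov=median_cov)
        rows.append(_row("s", "a", 50, "CpG", False, n_meth, cov - n_meth))
        return _table(rows)

    def test_low_coverage_extreme_site_flagged(self):
        report = detect_artifacts(self._calls_with_nonref(12, 1.0))
        nonref = report[report["pos"] == 50]
        assert nonref["is_artifact"].iloc[0]

    def test_full_coverage_intermediate_site_retained(self):
        """A SNP-created CpG at ~full coverage and ~50% methylation survives."""
        report = detect_artifacts(self._calls_with_nonref(1900, 0.47))
        assert not report[report["pos"] == 50]["is_artifact"].iloc[0]

    def test_low_coverage_intermediate_site_retained(self):
        report = detect_artifacts(self._calls_with_nonref(12, 0.5))
        assert not report[report["pos"] == 50]["is_artifact"].iloc[0]

    def test_reference_cpg_never_flagged(self):
        rows = _unit("s", "a", cpg_cov=2000)
        rows.append(_row("s", "a", 60, "CpG", True, 5, 0))  # cov 5, meth 1.0
        report = detect_artifacts(_table(rows))
        assert 60 not in set(report["pos"])

    def test_unit_without_reference_cpgs_warns_and_skips(self):
        rows = [
            _row("s", "a", 1, "CHH", False, 10, 990),
            _row("s", "a", 50, "CpG", False, 10, 0),
        ]
        with pytest.warns(UserWarning, match="without reference CpGs"):
            report = detect_artifacts(_table(rows))
        assert not report["is_artifact"].iloc[0]


class TestCoverageFilter:
    def test_boundary_semantics(self):
        rows = [
            _row("s", "a", 11, "CpG", True, 300, 700),   # 1000 retained
            _row("s", "a", 21, "CpG", True, 300, 699),   # 999 removed
            _row("s", "a", 1, "CHH", False, 1, 9),       # non-CpG kept
        ]
        out = filter_coverage(_table(rows), min_cov=1000)
        assert set(out.df["pos"]) == {11, 1}

    def test_all_above_threshold_unchanged(self):
        calls = _table(_unit("s", "a"))
        out = filter_coverage(calls, min_cov=1000)
        pd.testing.assert_frame_equal(out.df, calls.df)

    def test_empty_table(self):
        assert len(filter_coverage(CallTable.empty())) == 0

    def test_raising_min_cov_monotone(self):
        rows = [
            _row("s", "a", 10 * i + 1, "CpG", True, c, c) for i, c in enumerate(
                (100, 400, 500, 501, 700, 2000)
            )
        ]
        calls = _table(rows)
        counts = [
            len(filter_coverage(calls, min_cov=m)) for m in (0, 200, 800, 1001, 4001)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSummaryAndCommutation:
    def test_small_unit_arithmetic(self):
        rows = []
        for i in range(10):
            ok = i > 0  # unit 0 fails conversion
            rows.extend(
                _unit(f"s{i}", "a", chh_unmeth=990 if ok else 900,
                      chh_meth=10 if ok else 100)
            )
        calls = _table(rows)
        result = run_qc(calls)
        assert result.summary.n_units == 10
        assert result.summary.fraction_passing == pytest.approx(0.9)

    def test_plate_scale_survival_fraction(self):
        """95 samples x 29 amplicons with 9 failing units -> (2755-9)/2755."""
        rows = []
        failing = {("s0", "amp0")} | {(f"s{i}", "amp3") for i in range(1, 9)}
        for s in range(95):
            for a in range(29):
                sample, amp = f"s{s}", f"amp{a}"
                if (sample, amp) in failing:
                    rows.extend(_unit(sample, amp, chh_unmeth=940, chh_meth=60))
                else:
                    rows.extend(_unit(sample, amp))
        result = run_qc(_table(rows))
        assert result.summary.n_units == 2755
        assert result.summary.n_units_passing == 2755 - 9
        assert result.summary.fraction_passing == pytest.approx((2755 - 9) / 2755)

    def test_filters_commute(self, small_panel):
        """Any application order of the three filters retains the same sites."""
        profile = MethylationProfile.uniform(small_panel, 0.5)
        sim = simulate_sample(
            small_panel, profile,
            SimConfig(depth=1500, seed=31, read_length=150),
        )
        chh_pos = [
            s.pos for s in amplicon_contexts(small_panel["amp1"])
            if s.context == "CHH"
        ]
        pairs, _ = inject_artifacts(
            sim.pairs, small_panel, [("amp1", chh_pos[1])], n_reads=12,
            read_length=150,
        )
        calls = call_sites(trim_pairs(pairs), small_panel)
        thresholds = QCThresholds()
        conv = filter_conversion(calls, thresholds.min_conversion)
        art = detect_artifacts(
            calls, thresholds.artifact_cov_frac, thresholds.artifact_extremity
        )

        def key_set(table):
            df = table.df
            return set(zip(df["sample"], df["amplicon"], df["pos"], df["context"]))

        order1 = filter_coverage(
            drop_artifacts(drop_failed_units(calls, conv), art),
            thresholds.min_coverage,
        )
        order2 = drop_failed_units(
            drop_artifacts(filter_coverage(calls, thresholds.min_coverage), art),
            conv,
        )
        combined = run_qc(calls, thresholds).calls
        assert key_set(order1) == key_set(order2) == key_set(combined)


class TestEndToEndArtifactRecovery:
    def test_injected_artifacts_flagged_snp_retained(self):
        """Across seeds: injected artifacts are flagged, SNP-CpGs survive."""
        panel = synthetic_panel(n_amplicons=2, n_cpgs=3, n_chh=10, length=200, seed=5)
        chh = [
            s.pos
            for s in amplicon_contexts(panel["amp1"])
            if s.context == "CHH"
        ]
        for seed in (1, 2, 3):
            profile = MethylationProfile.uniform(panel, 0.5)
            sim = simulate_sample(
                panel, profile,
                SimConfig(depth=2000, conversion_efficiency=1.0,
                          base_error_rate=0.0, read_length=150, seed=seed),
            )
            pairs, truth = inject_artifacts(
                sim.pairs, panel, [("amp1", chh[0]), ("amp1", chh[4])],
                n_reads=10, read_length=150,
            )
            pairs = inject_snp_cpg(
                pairs, panel, "amp2", chh[2], meth_level=0.5, seed=seed
            )
            calls = call_sites(trim_pairs(pairs), panel)
            report = detect_artifacts(calls)
            flagged = set(
                zip(
                    report.loc[report["is_artifact"], "amplicon"],
                    report.loc[report["is_artifact"], "pos"],
                )
            )
            assert {("amp1", chh[0]), ("amp1", chh[4])} <= flagged
            snp = report[(report["amplicon"] == "amp2") & (report["pos"] == chh[2])]
            assert len(snp) == 1 and not snp["is_artifact"].iloc[0]
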