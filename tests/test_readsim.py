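"""Simulator: determinism, statistical recovery, artifact injection."""

import numpy as np
import pandas as pd
import pytest

from hamtbs import (
    ConfigurationError,
    MethylationProfile,
    SimConfig,
    amplicon_contexts,
    call_sites,
    inject_artifacts,
    mix_titration,
    simulate_sample,
    synthetic_panel,
    write_sam,
)
from hamtbs.overlap_trim import trim_pairs

_VALID = set(b"ACGTN")


def _amp_cpgs(panel, name):
    return [s.pos for s in amplicon_contexts(panel[name]) if s.is_reference_cpg]


class TestDeterminism:
    def test_fixed_seed_reproduces_sam_bytes(self, small_panel, tmp_path):
        profile = MethylationProfile.uniform(small_panel, 0.3)
        config = SimConfig(depth=50, seed=42, read_length=120)
        paths = []
        for i in (1, 2):
            sim = simulate_sample(small_panel, profile, config)
            p = tmp_path / f"run{i}.sam"
            write_sam(sim.pairs, small_panel, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self, small_panel):
        profile = MethylationProfile.uniform(small_panel, 0.5)
        sims = [
            simulate_sample(small_panel, profile, SimConfig(depth=20, seed=s))
            for s in (1, 2)
        ]
        seqs = [
            [p.mate1.seq for p in sim.pairs] for sim in sims
        ]
        assert seqs[0] != seqs[1]


class TestReadContent:
    def test_zero_depth_yields_nothing(self, small_panel):
        profile = MethylationProfile.uniform(small_panel, 0.5)
        sim = simulate_sample(small_panel, profile, SimConfig(depth=0, seed=0))
        assert sim.pairs == []
        assert (sim.truth["true_methylation"].dropna() >= 0).all()

    def test_bases_are_acgtn_and_coordinates_valid(self, small_panel):
        profile = MethylationProfile.uniform(small_panel, 0.5)
        sim = simulate_sample(
            small_panel, profile,
            SimConfig(depth=30, base_error_rate=0.01, seed=3, read_length=150),
        )
        for pair in sim.pairs:
            amp = small_panel[pair.amplicon]
            for mate in pair.mates():
                assert set(mate.bases.tolist()) <= {ord(c) for c in "ACGTN"}
                assert 1 <= mate.start and mate.end <= amp.length

    def test_mates_overlap_when_reads_exceed_half_length(self, small_panel):
        profile = MethylationProfile.uniform(small_panel, 0.0)
        sim = simulate_sample(
            small_panel, profile, SimConfig(depth=1, seed=0, read_length=150)
        )
        pair = sim.pairs[0]
        # 2 x 150 > 200, so the mates must intersect
        assert pair.mate2.start <= pair.mate1.end

    def test_profile_missing_cpg_rejected(self, small_panel):
        cpgs = {
            (a.name, s.pos): 0.5
            for a in small_panel
            for s in amplicon_contexts(a)
            if s.is_reference_cpg
        }
        cpgs.pop(next(iter(cpgs)))
        with pytest.raises(ConfigurationError):
            simulate_sample(
                small_panel, MethylationProfile(cpgs), SimConfig(depth=1, seed=0)
            )


class TestStatisticalRecovery:
    def test_cpg_methylation_matches_profile_binomially(self, small_panel):
        """At conversion 1, error 0, observed CpG fractions are Binomial(depth, p)."""
        depth, p = 5000, 0.5
        profile = MethylationProfile.uniform(small_panel, p)
        config = SimConfig(
            depth=depth, conversion_efficiency=1.0, base_error_rate=0.0,
            read_length=150, seed=5,
        )
        sim = simulate_sample(small_panel, profile, config)
        calls = call_sites(trim_pairs(sim.pairs), small_panel)
        cpg = calls.df[calls.df["context"] == "CpG"]
        assert (cpg["coverage"] == depth).all()
        # 99.9% central binomial interval
        from scipy.stats import binom
        lo, hi = binom.interval(0.999, depth, p)
        assert ((cpg["n_meth"] >= lo) & (cpg["n_meth"] <= hi)).all()

    def test_incomplete_conversion_leaves_chh_cytosines(self, small_panel):
        """With conversion 0.95 the retained-CHH fraction is ~5% (3 SE)."""
        depth, conv = 2000, 0.95
        profile = MethylationProfile.uniform(small_panel, 0.0)
        config = SimConfig(
            depth=depth, conversion_efficiency=conv, base_error_rate=0.0,
            read_length=150, seed=9,
        )
        sim = simulate_sample(small_panel, profile, config)
        calls = call_sites(trim_pairs(sim.pairs), small_panel)
        chh = calls.df[calls.df["context"] == "CHH"]
        n = chh["coverage"].sum()
        observed = chh["n_meth"].sum() / n
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(observed - 0.05) <= 3 * se


class TestTitrationProfiles:
    def test_five_level_series(self, small_panel):
        profiles = mix_titration(small_panel, (0, 0.25, 0.5, 0.75, 1.0))
        assert len(profiles) == 5
        cpgs = _amp_cpgs(small_panel, "amp1")
        for level, prof in zip((0, 0.25, 0.5, 0.75, 1.0), profiles):
            assert all(prof.level("amp1", pos) == level for pos in cpgs)

    def test_empty_and_single_level(self, small_panel):
        assert mix_titration(small_panel, ()) == []
        (prof,) = mix_titration(small_panel, (0.1,))
        assert prof.level("amp1", _amp_cpgs(small_panel, "amp1")[0]) == 0.1

    def test_out_of_range_level_rejected(self, small_panel):
        with pytest.raises(ConfigurationError):
            mix_titration(small_panel, (1.5,))


class TestArtifactInjection:
    @pytest.fixture()
    def base_sim(self, small_panel):
        profile = MethylationProfile.uniform(small_panel, 0.5)
        config = SimConfig(
            depth=2000, conversion_efficiency=1.0, base_error_rate=0.0,
            read_length=150, seed=13,
        )
        return simulate_sample(small_panel, profile, config)

    def _chh_pos(self, panel, name):
        return [s.pos for s in amplicon_contexts(panel[name]) if s.context == "CHH"]

    def test_artifact_site_presents_low_coverage_full_methylation(
        self, small_panel, base_sim
    ):
        pos = self._chh_pos(small_panel, "amp1")[2]
        pairs, truth = inject_artifacts(
            base_sim.pairs, small_panel, [("amp1", pos)], n_reads=10, read_length=150
        )
        calls = call_sites(trim_pairs(pairs), small_panel)
        site = calls.df[
            (calls.df["amplicon"] == "amp1")
            & (calls.df["pos"] == pos)
            & (calls.df["context"] == "CpG")
        ]
        assert len(site) == 1
        assert site["is_reference_cpg"].iloc[0] == False  # noqa: E712
        assert site["coverage"].iloc[0] == 10
        assert site["meth_fraction"].iloc[0] == 1.0
        assert truth["artifact"].all() and len(truth) == 1

    def test_zero_reads_is_identity(self, small_panel, base_sim):
        pos = self._chh_pos(small_panel, "amp1")[0]
        pairs, truth = inject_artifacts(
            base_sim.pairs, small_panel, [("amp1", pos)], n_reads=0
        )
        assert len(pairs) == len(base_sim.pairs)
        assert truth.empty

    def test_two_positions_two_truth_entries(self, small_panel, base_sim):
        pos = self._chh_pos(small_panel, "amp1")[:2]
        pairs, truth = inject_artifacts(
            base_sim.pairs, small_panel,
            [("amp1", p) for p in pos], n_reads=5, read_length=150,
        )
        assert len(pairs) == len(base_sim.pairs) + 10
        assert sorted(truth["pos"]) == sorted(pos)

    def test_reference_cpg_position_rejected(self, small_panel, base_sim):
        cpg = _amp_cpgs(small_panel, "amp1")[0]
        with pytest.raises(ConfigurationError):
            inject_artifacts(base_sim.pairs, small_panel, [("amp1", cpg)], n_reads=5)
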