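"""Cohort generator: determinism, planted structure and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cis_select.ris_processing import flag_expanded
from cis_select.synthetic_data import (
    DriverSpec,
    SimConfig,
    build_genome,
    default_screen_config,
    estimate_tss_weight,
    score_recovery,
    simulate_cohort,
)
from cis_select.selection_stats import tss_distance_profile
from cis_select.core import CIS


def _driver(chrom="chr1", locus=50_000_000, **kw):
    base = dict(
        driver_id="d0", chrom=chrom, locus=locus, window=10_000,
        orientation_prob=0.9, selection_prob=0.8,
    )
    base.update(kw)
    return DriverSpec(**base)


class TestSimulateCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = SimConfig(seed=11, n_samples=4, background_sites_per_sample=50, n_genes=100,
                        drivers=(_driver(),))
        a, ta = simulate_cohort(cfg)
        b, tb = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta.table, tb.table)

    def test_different_seeds_differ(self):
        kw = dict(n_samples=4, background_sites_per_sample=50, n_genes=100)
        a, _ = simulate_cohort(SimConfig(seed=1, **kw))
        b, _ = simulate_cohort(SimConfig(seed=2, **kw))
        assert not a.equals(b)

    def test_uniform_background_positions_pass_ks(self):
        cfg = SimConfig(seed=3, n_samples=10, background_sites_per_sample=500,
                        tss_weight=0.0, n_genes=10,
                        chrom_lengths={"chr1": 100_000_000})
        cohort, _ = simulate_cohort(cfg)
        u = cohort["pos"].to_numpy() / 100_000_000
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_degenerate_driver_hits_every_sample_forward(self):
        d = _driver(orientation_prob=1.0, selection_prob=1.0, window=5_000)
        cfg = SimConfig(seed=4, n_samples=28, background_sites_per_sample=0, n_genes=10,
                        drivers=(d,), passenger_mean=0.0)
        cohort, truth = simulate_cohort(cfg)
        assert len(cohort) == 28
        assert (cohort["strand"] == "+").all()
        assert cohort["pos"].between(d.locus - d.window, d.locus + d.window).all()
        assert truth.carriers["d0"] == cfg.sample_ids

    def test_genotype_restriction_respected(self):
        d = _driver(selection_prob=1.0, genotypes=("A",))
        cfg = SimConfig(seed=5, n_samples=6, genotypes=("A", "A", "A", "B", "B", "B"),
                        background_sites_per_sample=0, n_genes=10, drivers=(d,),
                        passenger_mean=0.0)
        cohort, truth = simulate_cohort(cfg)
        assert set(cohort["genotype"]) == {"A"}
        assert len(truth.carriers["d0"]) == 3

    def test_expansion_threshold_separates_clones_exactly(self):
        cfg = SimConfig(seed=6, n_samples=8, background_sites_per_sample=100, n_genes=50,
                        drivers=(_driver(),), passenger_mean=1.0)
        cohort, truth = simulate_cohort(cfg)
        expanded, _ = flag_expanded(cohort, threshold=100)
        planted = truth.table["role"] != "background"
        assert set(expanded.index) == set(np.flatnonzero(planted))

    def test_passengers_share_clone_read_count(self):
        cfg = SimConfig(seed=7, n_samples=10, background_sites_per_sample=0, n_genes=10,
                        drivers=(_driver(selection_prob=1.0),), passenger_mean=2.0)
        cohort, truth = simulate_cohort(cfg)
        t = truth.table.assign(reads=cohort["reads"])
        for clone, grp in t[t["clone_id"] != ""].groupby("clone_id"):
            assert grp["reads"].nunique() == 1


class TestTssPreference:
    @pytest.mark.parametrize("w", [0.0, 0.7])
    def test_mixture_weight_recovered_within_tolerance(self, w):
        cfg = SimConfig(seed=8, n_samples=28, background_sites_per_sample=358,
                        tss_weight=w, tss_decay=3_000.0, n_genes=20_000)
        cohort, _ = simulate_cohort(cfg)  # ~10,000 background sites
        genome = build_genome(cfg)
        prof, _ = tss_distance_profile(cohort, genome)
        w_hat = estimate_tss_weight(prof["distance"].to_numpy(), genome, tau=cfg.tss_decay)
        assert abs(w_hat - w) <= 0.05


class TestDefaultConfig:
    def test_matches_study_design(self):
        cfg = default_screen_config(seed=1)
        assert cfg.n_samples == 28
        assert len(cfg.drivers) == 50
        probs = [d.orientation_prob for d in cfg.drivers]
        assert probs.count(0.9) == 30 and probs.count(0.5) == 20  # 60/40 mix

    def test_cohort_size_near_nominal(self):
        sizes = [len(simulate_cohort(default_screen_config(seed=s))[0]) for s in (1, 2)]
        for n in sizes:
            assert abs(n - 12_485) < 300  # ~446 sites/sample on average

    def test_driver_loci_well_separated(self):
        cfg = default_screen_config(seed=9)
        by_chrom: dict = {}
        for d in cfg.drivers:
            by_chrom.setdefault(d.chrom, []).append(d.locus)
        for loci in by_chrom.values():
            loci = sorted(loci)
            assert all(b - a >= 5_000_000 for a, b in zip(loci, loci[1:]))


class TestScoreRecovery:
    def _perfect_calls(self, cohort, truth):
        calls = []
        for did, grp in truth.table[truth.table["role"] == "driver"].groupby("driver_id"):
            idx = grp.index.to_numpy()
            pos = cohort["pos"].iloc[idx]
            if len(idx) < 2:
                continue
            calls.append(
                CIS(cohort["chrom"].iloc[idx[0]], int(pos.min()), int(pos.max()),
                    int(pos.min()), 5.0, 10_000.0, idx)
            )
        return calls

    def test_perfect_calls_score_perfectly(self):
        # selection_prob 1 -> 10 members per driver, so spans cover the loci
        cfg = SimConfig(seed=10, n_samples=10, background_sites_per_sample=20, n_genes=50,
                        drivers=(_driver(selection_prob=1.0),
                                 _driver(driver_id="d1", chrom="chr2", locus=10_000_000,
                                         selection_prob=1.0)))
        cohort, truth = simulate_cohort(cfg)
        calls = self._perfect_calls(cohort, truth)
        s = score_recovery(calls, truth)
        assert s.sensitivity == 1.0
        assert s.false_cis_rate == 0.0

    def test_empty_call_set_scores_zero_sensitivity(self):
        cfg = SimConfig(seed=10, n_samples=10, background_sites_per_sample=20, n_genes=50,
                        drivers=(_driver(),))
        _, truth = simulate_cohort(cfg)
        s = score_recovery([], truth)
        assert s.sensitivity == 0.0 and s.false_cis_rate == 0.0

    def test_biased_metrics_use_flagged_subset(self):
        cfg = SimConfig(seed=12, n_samples=12, background_sites_per_sample=0, n_genes=10,
                        passenger_mean=0.0,
                        drivers=(_driver(selection_prob=1.0),
                                 _driver(driver_id="d1", chrom="chr2", locus=10_000_000,
                                         orientation_prob=0.5, selection_prob=1.0)))
        cohort, truth = simulate_cohort(cfg)
        calls = self._perfect_calls(cohort, truth)
        enh_idx = [i for i, c in enumerate(calls) if c.chrom == "chr1"]
        s = score_recovery(calls, truth, biased_indices=enh_idx)
        assert s.biased_recall == 1.0
        assert s.biased_false_flag == 0.0
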