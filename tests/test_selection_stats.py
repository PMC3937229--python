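"""Orientation bias, BH correction, enrichment and genotype comparisons."""

import numpy as np
import pandas as pd
import pytest

from cis_select.core import CIS, GenomeModel, RegionSet, ValidationError, toy_genome
from cis_select.selection_stats import (
    bh_adjust,
    biased_cis_set,
    bin_enrichment,
    bin_enrichment_from_counts,
    cis_overlap,
    geneset_enrichment,
    genotype_presence_test,
    genotype_reads_test,
    orientation_test,
    orientation_test_all,
    tss_distance_profile,
)

from conftest import make_cohort
from oracles import (
    bh_oracle,
    fisher_greater_oracle,
    hypergeom_sf_oracle,
    mwu_twosided_oracle,
)


def _cohort_with_cis(fwd_in, rev_in, fwd_out, rev_out):
    rows = []
    # CIS members clustered at 1 Mb, the rest spread far away
    for i in range(fwd_in):
        rows.append(("chr1", 1_000_000 + i, "+", f"T{i % 6}", 1))
    for i in range(rev_in):
        rows.append(("chr1", 1_000_500 + i, "-", f"T{i % 6}", 1))
    for i in range(fwd_out):
        rows.append(("chr1", 10_000_000 + 1_000 * i, "+", f"T{i % 6}", 1))
    for i in range(rev_out):
        rows.append(("chr1", 60_000_000 + 1_000 * i, "-", f"T{i % 6}", 1))
    df = make_cohort(rows)
    n_in = fwd_in + rev_in
    cis = CIS("chr1", 1_000_000, 1_000_500 + max(rev_in - 1, 0), 1_000_000, 5.0, 15_000.0,
              np.arange(n_in))
    return df.sort_values("pos", kind="mergesort").reset_index(drop=True), cis


class TestOrientation:
    def test_tie_gives_p_one(self):
        df, cis = _cohort_with_cis(5, 5, 100, 300)
        res = orientation_test(cis, df)
        assert res.p == 1.0
        assert res.bias == 0.5

    def test_one_sided_ten_vs_zero_matches_hypergeometric(self):
        df, cis = _cohort_with_cis(10, 0, 5_000, 5_000)
        res = orientation_test(cis, df)
        assert res.p == pytest.approx(9.7e-4, rel=2e-2)  # ~ (5010/10010)^10
        assert res.p == pytest.approx(fisher_greater_oracle(10, 0, 5_000, 5_000), rel=1e-9)

    def test_minority_forward_tests_reverse_tail(self):
        df, cis = _cohort_with_cis(1, 9, 5_000, 5_000)
        res = orientation_test(cis, df)
        assert res.bias == 0.9
        assert res.p == pytest.approx(fisher_greater_oracle(9, 1, 5_000, 5_000), rel=1e-9)

    def test_q_values_attached_and_filtered_strictly(self):
        df, cis = _cohort_with_cis(12, 0, 400, 400)
        results = orientation_test_all([cis], df)
        assert results[0].q == pytest.approx(results[0].p)  # single test
        fake = results[0]
        fake.q = 0.05
        assert biased_cis_set([fake], q_cut=0.05) == []  # strict <
        fake.q = 0.049999
        assert biased_cis_set([fake], q_cut=0.05) == [fake]

    def test_global_null_discovery_fraction_controlled(self):
        """Random strands: BH discoveries stay near zero on average."""
        rng = np.random.default_rng(5)
        rows = [("chr1", 1_000 + 200 * i, "+", f"T{i % 8}", 1) for i in range(600)]
        df = make_cohort(rows)
        cis_list = []
        for k in range(30):
            idx = np.arange(20 * k, 20 * k + int(rng.integers(5, 20)))
            sub = df.iloc[idx]
            cis_list.append(
                CIS("chr1", int(sub["pos"].min()), int(sub["pos"].max()),
                    int(sub["pos"].min()), 3.0, 15_000.0, idx)
            )
        frac = []
        for _ in range(200):
            shuf = df.copy()
            shuf["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
            res = orientation_test_all(cis_list, shuf)
            frac.append(np.mean([r.q < 0.05 for r in res]))
        assert np.mean(frac) <= 0.05


class TestVectorisedOrientation:
    def test_agrees_with_per_cis_fisher_test(self, rng):
        from cis_select.selection_stats import orientation_pvalues_vectorised

        n_total, fwd_total = 4_000, 2_113
        strands = np.array(["+"] * fwd_total + ["-"] * (n_total - fwd_total))
        rng.shuffle(strands)
        rows = [("chr1", 1_000 + i, s, f"T{i % 6}", 1) for i, s in enumerate(strands)]
        df = make_cohort(rows).sort_values("pos", kind="mergesort").reset_index(drop=True)
        fwd_ins, n_ins, expected = [], [], []
        for k in range(40):
            size = int(rng.integers(3, 30))
            idx = np.arange(50 * k, 50 * k + size)
            sub = df.iloc[idx]
            cis = CIS("chr1", int(sub["pos"].min()), int(sub["pos"].max()),
                      int(sub["pos"].min()), 3.0, 15_000.0, idx)
            res = orientation_test(cis, df)
            fwd_ins.append(res.fwd_in)
            n_ins.append(size)
            expected.append(res.p)
        fwd_total_obs = int((df["strand"] == "+").sum())
        got = orientation_pvalues_vectorised(
            np.array(fwd_ins), np.array(n_ins), fwd_total_obs, len(df)
        )
        np.testing.assert_allclose(got, expected, rtol=1e-9)


class TestBhAdjust:
    def test_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_permutation_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_reference_implementation(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)


class TestTssDistance:
    @pytest.fixture
    def genome(self):
        tss = pd.DataFrame(
            {
                "gene_id": ["aGene", "bGene", "cGene"],
                "chrom": ["chr1", "chr1", "chr1"],
                "tss_pos": [10_000, 50_000, 50_000],
                "strand": ["+", "-", "+"],
            }
        )
        return GenomeModel({"chr1": 1_000_000, "chr2": 1_000_000}, tss_table=tss)

    def test_ris_at_tss_has_zero_distance(self, genome):
        df = make_cohort([("chr1", 10_000, "+", "T1", 1)])
        prof, _ = tss_distance_profile(df, genome)
        assert prof["distance"].iloc[0] == 0
        assert prof["nearest_gene"].iloc[0] == "aGene"

    def test_sign_flips_for_minus_strand_gene(self, genome):
        # 500 bp left of a minus-strand TSS is downstream in gene coordinates
        df = make_cohort([("chr1", 49_500, "+", "T1", 1)])
        prof, _ = tss_distance_profile(df, genome)
        # tie between bGene(-) and cGene(+) at same coordinate -> bGene (lexicographic)
        assert prof["nearest_gene"].iloc[0] == "bGene"
        assert prof["distance"].iloc[0] == 500

    def test_chromosome_without_tss_is_flagged(self, genome):
        df = make_cohort([("chr2", 100, "+", "T1", 1)])
        prof, _ = tss_distance_profile(df, genome)
        assert prof["no_tss_on_chrom"].iloc[0]
        assert np.isnan(prof["distance"].iloc[0])


class TestCisOverlap:
    def _cis(self, chrom, start, end):
        return CIS(chrom, start, end, start, 3.0, 15_000.0, np.array([0, 1]))

    def test_abutting_extents_do_not_overlap(self):
        a = [self._cis("chr1", 100, 200)]
        b = [self._cis("chr1", 201, 300)]
        pairs, n = cis_overlap(a, b)
        assert pairs == [] and n == 0

    def test_identical_extents_overlap(self):
        a = [self._cis("chr1", 100, 200)]
        pairs, n = cis_overlap(a, a)
        assert pairs == [(0, 0)] and n == 1

    def test_single_shared_base_counts(self):
        a = [self._cis("chr1", 100, 200)]
        b = [self._cis("chr1", 200, 300)]
        assert cis_overlap(a, b)[1] == 1

    def test_matches_all_pairs_oracle(self, rng):
        from oracles import overlap_pairs_oracle

        def random_set(n):
            out = []
            for _ in range(n):
                chrom = f"chr{int(rng.integers(1, 4))}"
                s = int(rng.integers(1, 100_000))
                out.append(self._cis(chrom, s, s + int(rng.integers(1, 20_000))))
            return out

        for _ in range(20):
            A, B = random_set(15), random_set(15)
            pairs, _ = cis_overlap(A, B)
            expected = overlap_pairs_oracle(
                [(c.chrom, c.start, c.end) for c in A], [(c.chrom, c.start, c.end) for c in B]
            )
            assert sorted(pairs) == sorted(expected)


class TestBinEnrichment:
    def test_printed_syntenic_region_counts_are_significant(self):
        res = bin_enrichment_from_counts(43, 771, 2_613, 89_796)
        assert res.p < 1e-4

    def test_whole_genome_regions_give_p_one(self):
        genome = toy_genome(1, 300_000)
        regions = RegionSet("all", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [300_000]}))
        cis = [CIS("chr1", 1_000, 2_000, 1_500, 3.0, 15_000.0, np.array([0, 1]))]
        assert bin_enrichment(cis, regions, genome, bin_size=30_000).p == 1.0

    def test_small_case_matches_hypergeometric_enumeration(self):
        # 10 bins of 30 kb, 2 region bins, 3 CISs of which 2 peak in region bins
        genome = toy_genome(1, 300_000)
        regions = RegionSet("r", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60_000]}))
        cis = [
            CIS("chr1", 1_000, 2_000, 1_500, 3.0, 15_000.0, np.array([0, 1])),
            CIS("chr1", 31_000, 32_000, 31_500, 3.0, 15_000.0, np.array([2, 3])),
            CIS("chr1", 150_000, 152_000, 151_000, 3.0, 15_000.0, np.array([4, 5])),
        ]
        res = bin_enrichment(cis, regions, genome, bin_size=30_000)
        assert res.total_bins == 10 and res.region_bins == 2 and res.cis_in_region == 2
        assert res.p == pytest.approx(fisher_greater_oracle(2, 1, 0, 7), rel=1e-9)

    def test_region_outside_genome_rejected(self):
        genome = toy_genome(1, 100_000)
        regions = RegionSet("r", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200_000]}))
        with pytest.raises(ValidationError):
            bin_enrichment([], regions, genome)


def _genotype_cohort():
    rows = []
    # 4 MYC tumours with expanded insertions at the locus, 4 WT without
    for i in range(4):
        rows.append(("chr1", 1_000_000 + i, "+", f"M{i}", "MYC", 500))
        rows.append(("chr1", 5_000_000 + i, "+", f"W{i}", "WT", 500))
    for i in range(4):
        rows.append(("chr2", 1_000 + i, "+", f"M{i}", "MYC", 1))
        rows.append(("chr2", 1_000 + i, "-", f"W{i}", "WT", 1))
    return make_cohort(rows)


class TestGenotypeTests:
    def test_exclusive_presence_is_significant(self):
        df = _genotype_cohort()
        p = genotype_presence_test(df, ("chr1", 900_000, 1_100_000), "MYC", "WT")
        # 4/4 vs 0/4 two-sided Fisher
        assert p == pytest.approx(2 / 70, rel=1e-9)

    def test_identical_presence_gives_p_one(self):
        df = _genotype_cohort()
        p = genotype_presence_test(df, ("chr2", 1, 10_000), "MYC", "WT", expanded_threshold=1)
        assert p == 1.0

    def test_reads_test_matches_enumeration(self):
        rows = []
        for i, r in enumerate([10, 20, 30]):
            rows.append(("chr1", 1_000 + i, "+", f"A{i}", "gA", r))
        for i, r in enumerate([40, 50, 60]):
            rows.append(("chr1", 2_000 + i, "+", f"B{i}", "gB", r))
        df = make_cohort(rows)
        p = genotype_reads_test(df, ("chr1", 1, 10_000), "gA", "gB")
        assert p == pytest.approx(0.1, rel=1e-9)
        assert p == pytest.approx(mwu_twosided_oracle([10, 20, 30], [40, 50, 60]), rel=1e-9)

    def test_identical_groups_give_p_one(self):
        rows = [("chr1", 1_000 + i, "+", f"A{i}", "gA", 7) for i in range(3)]
        rows += [("chr1", 2_000 + i, "+", f"B{i}", "gB", 7) for i in range(3)]
        p = genotype_reads_test(make_cohort(rows), ("chr1", 1, 10_000), "gA", "gB")
        assert p == 1.0


class TestGenesetEnrichment:
    def test_whole_set_target_is_most_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"hit": universe[:5], "other": universe[5:12]}
        res = geneset_enrichment(universe[:5], sets, universe)
        p = res.set_index("geneset")["p"]
        assert p["hit"] < p["other"]
        assert p["hit"] == pytest.approx(hypergeom_sf_oracle(5, 20, 5, 5), rel=1e-9)

    def test_dropping_all_targets_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"s": universe[:5]}
        res = geneset_enrichment(universe[:4], sets, universe, drop_top_k=4)
        assert res["p"].iloc[0] == 1.0

    def test_toy_overlap_matches_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"s": universe[:5]}
        targets = universe[:3] + [universe[10]]  # 4 targets, 3 in set
        res = geneset_enrichment(targets, sets, universe)
        assert res["p"].iloc[0] == pytest.approx(hypergeom_sf_oracle(3, 20, 5, 4), rel=1e-9)

    def test_robustness_grid_over_k(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {"s": universe[:10]}
        res = geneset_enrichment(universe[:8], sets, universe, drop_top_k=[0, 2, 8])
        assert list(res["drop_top_k"]) == [0, 2, 8]
        assert res["p"].is_monotonic_increasing
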