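import math

import pytest

from mitocohort.io_formats import VcfRecordLite
from mitocohort.mt_variants import (
    MtVariantCall,
    SampleQc,
    aggregate_variants,
    annotate_region,
    classify_heteroplasmy,
    classify_mitotip,
    classify_variant_type,
    compute_mt_copy_number,
    compute_vaf,
    filter_samples,
    filter_variant_calls,
    frequency_category,
    region_enrichment,
)


def qc(sample="S0", mt=3000.0, auto=31.0, contam=0.0, flag=False, insert=400.0):
    return SampleQc(sample, mt, auto, contam, flag, insert)


def rec(pos=5000, ref="A", alt="C", filt="PASS", ad=50, dp=150, artifact=False):
    return VcfRecordLite("chrM", pos, ref, alt, frozenset(filt.split(";")), ad, dp, artifact)


class TestVafAndCopyNumber:
    @pytest.mark.parametrize("ad,dp,expect", [(50, 100, 0.5), (100, 100, 1.0), (9, 100, 0.09)])
    def test_vaf_is_exact_ratio(self, ad, dp, expect):
        assert compute_vaf(ad, dp) == expect

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            compute_vaf(0, 0)

    @pytest.mark.parametrize(
        "mt,auto,expect",
        [(3000, 31, 2 * 3000 / 31), (100, 100, 2.0), (775, 31, 50.0)],
    )
    def test_copy_number_formula(self, mt, auto, expect):
        assert compute_mt_copy_number(mt, auto) == pytest.approx(expect)


class TestFilterSamples:
    def test_copy_number_just_below_50_dropped(self):
        # CN = 49.9 sits just under the retention boundary
        kept, dropped = filter_samples([qc(mt=49.9 * 31 / 2, auto=31.0)])
        assert kept == [] and dropped[0][1] == "copy_number"

    def test_copy_number_exactly_50_kept(self):
        kept, dropped = filter_samples([qc(mt=775.0, auto=31.0)])
        assert len(kept) == 1

    def test_contamination_just_over_2pct_dropped(self):
        kept, dropped = filter_samples([qc(contam=0.021)])
        assert dropped[0][1] == "contamination"
        kept, dropped = filter_samples([qc(contam=0.02)])
        assert len(kept) == 1  # boundary retained (strictly greater drops)

    def test_phylogeny_flag_dropped(self):
        _, dropped = filter_samples([qc(flag=True)])
        assert dropped[0][1] == "mt_contamination"

    def test_numt_mode_only_insert_size(self):
        samples = [qc(insert=250.0, contam=0.5), qc(insert=249.9)]
        kept, dropped = filter_samples(samples, for_numt=True)
        assert len(kept) == 1 and kept[0].median_insert_size == 250.0
        assert dropped[0][1] == "insert_size"


class TestFilterVariantCalls:
    def test_clean_call_kept_with_level(self):
        calls = filter_variant_calls([rec(pos=5000, ad=18, dp=150)], "S0")
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.12)
        assert calls[0].level == "heteroplasmic"

    @pytest.mark.parametrize(
        "record",
        [
            rec(dp=100, ad=50),                  # DP must strictly exceed 100
            rec(pos=3107, ad=75, dp=150, artifact=True),  # artifact site
            rec(ad=14, dp=150),                  # VAF 0.093 < 0.1
            rec(filt="base_qual", ad=75, dp=150),
        ],
    )
    def test_each_filter_drops(self, record):
        assert filter_variant_calls([record], "S0") == []

    def test_dp_101_kept(self):
        assert len(filter_variant_calls([rec(dp=101, ad=50)], "S0")) == 1


class TestHeteroplasmyClassification:
    @pytest.mark.parametrize(
        "vaf,level",
        [(0.95, "homoplasmic"), (1.0, "homoplasmic"), (0.10, "heteroplasmic"),
         (0.949, "heteroplasmic"), (0.5, "heteroplasmic")],
    )
    def test_bins(self, vaf, level):
        assert classify_heteroplasmy(vaf) == level

    def test_below_filter_floor_is_error(self):
        with pytest.raises(ValueError):
            classify_heteroplasmy(0.05)


class TestVariantType:
    def test_snv_transition_with_both_strands(self):
        vtype, sub = classify_variant_type("G", "A")
        assert vtype == "SNV" and "transition" in sub
        assert "L:G>A" in sub and "H:C>T" in sub

    def test_transversion(self):
        assert "transversion" in classify_variant_type("G", "T")[1]

    def test_deletion_of_6bp(self):
        vtype, sub = classify_variant_type("CCCCTCT", "C")
        assert (vtype, sub) == ("deletion", "del_6bp")

    def test_insertion_of_1bp(self):
        assert classify_variant_type("A", "AT") == ("insertion", "ins_1bp")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_variant_type("N", "A")


class TestAggregate:
    def mk(self, sample, vaf, pos=4000):
        level = "homoplasmic" if vaf >= 0.95 else "heteroplasmic"
        return MtVariantCall(sample, pos, "A", "C", vaf, 500, level)

    def test_single_heteroplasmic_carrier(self):
        (s,) = aggregate_variants([self.mk("S0", 0.4)], 100)
        assert s.level_category == "heteroplasmic_only"
        assert s.singleton and s.n_carriers == 1
        assert s.max_het_level == 0.4

    def test_mixed_levels_give_both(self):
        (s,) = aggregate_variants([self.mk("S0", 0.3), self.mk("S1", 0.99)], 100)
        assert s.level_category == "both"
        assert s.max_het_level == 0.3

    def test_homoplasmic_only_popfreq(self):
        calls = [self.mk(f"S{i}", 1.0) for i in range(10)]
        (s,) = aggregate_variants(calls, 100)
        assert s.level_category == "homoplasmic_only"
        assert s.pop_freq == pytest.approx(0.1)
        assert s.max_het_level is None

    def test_level_categories_partition(self, rng):
        # property: the three categories are disjoint and exhaustive
        calls = [
            self.mk(f"S{i}", v, pos=100 + 10 * (i % 17))
            for i, v in enumerate(rng.uniform(0.1, 1.0, size=200))
        ]
        summaries = aggregate_variants(calls, 300)
        assert all(
            s.level_category in {"homoplasmic_only", "heteroplasmic_only", "both"}
            for s in summaries
        )

    def test_more_carriers_than_samples_is_error(self):
        with pytest.raises(ValueError):
            aggregate_variants([self.mk("S0", 1.0), self.mk("S1", 1.0)], 1)


class TestFrequencyCategory:
    @pytest.mark.parametrize(
        "carriers,n,expect",
        [
            (1, 7324, "private"),
            (74, 7324, "common"),     # F = 1.01%
            (73, 7324, "rare"),       # F = 0.997%
            (8, 7324, "rare"),        # F = 0.109%
            (7, 7324, "ultra_rare"),  # F = 0.0956%
            (2, 2000, "rare"),        # F = 0.1% exactly -> rare bin is closed below
        ],
    )
    def test_bins(self, carriers, n, expect):
        assert frequency_category(carriers, n) == expect

    def test_monotone_in_carriers(self):
        order = {"private": 0, "ultra_rare": 1, "rare": 2, "common": 3}
        n = 5000
        ranks = [order[frequency_category(c, n)] for c in range(1, n + 1)]
        assert ranks == sorted(ranks)

    def test_zero_carriers_error(self):
        with pytest.raises(ValueError):
            frequency_category(0, 10)


class TestRegions:
    @pytest.mark.parametrize(
        "pos,name,rclass",
        [
            (11778, "MT-ND4", "protein_coding"),
            (1555, "MT-RNR1", "rRNA"),
            (200, "MT-DLOOP", "D-loop"),
            (16100, "MT-DLOOP", "D-loop"),
            (600, "MT-TF", "tRNA"),
        ],
    )
    def test_known_positions(self, region_table, pos, name, rclass):
        assert annotate_region(pos, region_table) == (name, rclass)

    def test_out_of_range_error(self, region_table):
        with pytest.raises(ValueError):
            annotate_region(0, region_table)
        with pytest.raises(ValueError):
            annotate_region(16570, region_table)

    def test_table_tiles_genome(self, region_table):
        assert region_table[0].start == 1 and region_table[-1].end == 16569
        for a, b in zip(region_table, region_table[1:]):
            assert b.start == a.end + 1


class TestRegionEnrichment:
    def test_all_variants_in_small_region_matches_combinatorial_oracle(self):
        # 10 draws from a 1000 bp toy genome all landing in a 100 bp region:
        # upper tail p = P(X >= 10) = C(100,10)/C(1000,10)
        p = region_enrichment({"R": 10}, {"R": 100}, genome_len=1000)["R"]
        oracle = math.comb(100, 10) / math.comb(1000, 10)
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_observed_zero_gives_p_one(self):
        p = region_enrichment({"R": 0, "Q": 5}, {"R": 100, "Q": 500}, genome_len=1000)["R"]
        assert p == pytest.approx(1.0)

    def test_expected_count_not_significant(self):
        # observed equals expectation: upper-tail p sits in [0.4, 1]
        p = region_enrichment({"R": 10, "Q": 90}, {"R": 100, "Q": 900}, genome_len=1000)["R"]
        assert 0.4 <= p <= 1.0

    def test_zero_length_region_error(self):
        with pytest.raises(ValueError):
            region_enrichment({"R": 0}, {"R": 0})

    def test_exhaustive_enumeration_oracle_tiny(self):
        # exact oracle: enumerate all C(20, 4) draw sets on a 20 bp genome
        from itertools import combinations

        genome = range(1, 21)
        region = set(range(1, 6))  # 5 bp region
        draws = 4
        observed = 3
        total = hits = 0
        for combo in combinations(genome, draws):
            total += 1
            if sum(p in region for p in combo) >= observed:
                hits += 1
        p = region_enrichment({"R": observed, "other": draws - observed},
                              {"R": 5, "other": 15}, genome_len=20)["R"]
        assert p == pytest.approx(hits / total, rel=1e-12)


class TestMitotip:
    @pytest.mark.parametrize(
        "score,expect",
        [
            (17.0, "likely_pathogenic"),
            (16.25, "possibly_pathogenic"),  # boundary goes to the lower bin
            (13.0, "possibly_pathogenic"),
            (12.66, "possibly_benign"),
            (10.0, "possibly_benign"),
            (8.44, "likely_benign"),
            (5.0, "likely_benign"),
        ],
    )
    def test_bins(self, score, expect):
        assert classify_mitotip(score) == expect
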