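import numpy as np
import pandas as pd
import pytest

from gcircuits import (CnaConfig, apply_cnv_mask, build_alteration_matrix,
                       detect_recurrent_regions, extend_boundaries,
                       recurrent_arm_regions, resolve_mrd_hd_overlap,
                       suppress_arm_scale_mrds)
from gcircuits.calling import FocalEvent
from gcircuits.recurrence import RecurrentRegion, events_to_masks

from _oracles import brute_force_regions


def masks_from_intervals(intervals_by_sample, n):
    out = {}
    for sid, intervals in intervals_by_sample.items():
        m = np.zeros(n, dtype=bool)
        for lo, hi in intervals:
            m[lo:hi + 1] = True
        out[sid] = m
    return out


class TestDetect:
    def test_three_identical_fgas_one_region(self, small_map, config):
        masks = masks_from_intervals(
            {f"s{i}": [(10, 20)] for i in range(3)}, 100)
        (region,) = detect_recurrent_regions(masks, "FGA", small_map, config)
        assert region.core == (10, 20)
        assert region.max_support == 3
        assert region.members == frozenset({"s0", "s1", "s2"})

    def test_two_fgas_below_threshold(self, small_map, config):
        masks = masks_from_intervals({"a": [(10, 20)], "b": [(15, 25)]}, 100)
        assert detect_recurrent_regions(masks, "FGA", small_map, config) == []

    def test_two_hds_reach_threshold(self, small_map, config):
        masks = masks_from_intervals({"a": [(10, 20)], "b": [(15, 25)]}, 100)
        (region,) = detect_recurrent_regions(masks, "HD", small_map, config)
        assert region.core == (15, 20)   # shared stretch is the peak

    def test_empty_input(self, small_map, config):
        assert detect_recurrent_regions({}, "FGA", small_map, config) == []

    def test_core_support_invariants(self, small_map, config):
        rng = np.random.default_rng(3)
        masks = {f"s{i}": np.zeros(100, dtype=bool) for i in range(8)}
        for m in masks.values():
            for _ in range(rng.integers(1, 4)):
                lo = rng.integers(0, 95)
                m[lo:lo + rng.integers(2, 8)] = True
        counts = sum(m.astype(int) for m in masks.values())
        for kind in ("FGA", "HD"):
            for r in detect_recurrent_regions(masks, kind, small_map, config):
                assert r.ext_start <= r.core_start <= r.core_end <= r.ext_end
                assert np.all(counts[r.core_start:r.core_end + 1]
                              == r.max_support)
                slack = config.slack(kind)
                assert np.all(counts[r.ext_start:r.ext_end + 1]
                              >= r.max_support - slack)


class TestExtendBoundaries:
    def test_two_case_rule(self):
        counts = np.array([1, 2, 4, 5, 5, 3, 2])
        assert extend_boundaries(counts, (3, 4), "FGA") == (2, 5)

    def test_flat_chromosome_extends_fully(self):
        counts = np.array([5, 5, 5])
        assert extend_boundaries(counts, (0, 2), "FGA") == (0, 2)

    def test_hd_one_case_rule(self):
        counts = np.array([1, 3, 3, 2, 1])
        assert extend_boundaries(counts, (1, 2), "HD") == (1, 3)


class TestOracleEquivalence:
    """Peak-and-extend must match exhaustive interval enumeration."""

    def test_random_fixtures(self, two_chrom_map, config):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n_samples = rng.integers(2, 11)
            masks = {}
            for i in range(n_samples):
                m = np.zeros(100, dtype=bool)
                for _ in range(rng.integers(0, 4)):
                    lo = rng.integers(0, 95)
                    m[lo:lo + rng.integers(1, 12)] = True
                masks[f"s{i}"] = m
            for kind in ("FGA", "HD"):
                got = {(r.kind, r.chrom, r.core, r.extended)
                       for r in detect_recurrent_regions(
                           masks, kind, two_chrom_map, config)}
                want = brute_force_regions(masks, kind, two_chrom_map, config)
                assert got == want, f"trial {trial}, kind {kind}"


class TestCnvMask:
    def _region(self, lo=10, hi=19):
        # probes 10..19 on the 100kb grid: genomic 1.0-2.0 Mb
        return RecurrentRegion("FGA", "chr1", lo, hi, lo, hi, 5, frozenset())

    def test_heavy_overlap_removed(self, small_map):
        cnv = [("chr1", 1_000_000, 1_600_000, "cnv")]    # 60% of 1 Mb
        assert apply_cnv_mask([self._region()], cnv, small_map, 0.5) == []

    def test_light_overlap_kept(self, small_map):
        cnv = [("chr1", 1_000_000, 1_200_000, "cnv")]    # 20%
        assert len(apply_cnv_mask([self._region()], cnv, small_map, 0.5)) == 1

    def test_no_file_keeps_all(self, small_map):
        assert len(apply_cnv_mask([self._region()], None, small_map)) == 1

    def test_overlapping_cnvs_counted_once(self, small_map):
        cnv = [("chr1", 1_000_000, 1_400_000, "a"),
               ("chr1", 1_200_000, 1_600_000, "b")]      # union 60%
        assert apply_cnv_mask([self._region()], cnv, small_map, 0.5) == []


class TestMrdHdResolution:
    def test_overlap_replaced_by_hd(self):
        mrd = RecurrentRegion("MRD", "chr1", 5, 40, 5, 40, 20, frozenset())
        hd = RecurrentRegion("HD", "chr1", 10, 20, 10, 20, 4, frozenset())
        assert resolve_mrd_hd_overlap([mrd], [hd]) == [hd]

    def test_disjoint_both_kept(self):
        mrd = RecurrentRegion("MRD", "chr1", 5, 8, 5, 8, 20, frozenset())
        hd = RecurrentRegion("HD", "chr1", 30, 40, 30, 40, 4, frozenset())
        assert resolve_mrd_hd_overlap([mrd], [hd]) == [mrd]

    def test_mrd_over_two_hds_replaced_by_both(self):
        mrd = RecurrentRegion("MRD", "chr1", 5, 60, 5, 60, 20, frozenset())
        hd1 = RecurrentRegion("HD", "chr1", 10, 20, 10, 20, 4, frozenset())
        hd2 = RecurrentRegion("HD", "chr1", 40, 50, 40, 50, 3, frozenset())
        assert resolve_mrd_hd_overlap([mrd], [hd1, hd2]) == [hd1, hd2]


class TestArmScaleSuppression:
    def _mrd(self, lo, hi):
        return RecurrentRegion("MRD", "chr1", lo, hi, lo, hi, 20, frozenset())

    def test_arm_wide_mrd_dropped(self, small_map):
        # q arm is probes 40..99; 80% of it
        assert suppress_arm_scale_mrds([self._mrd(40, 87)], small_map) == []

    def test_small_mrd_kept(self, small_map):
        assert len(suppress_arm_scale_mrds([self._mrd(50, 55)], small_map)) == 1

    def test_exact_cutoff_kept(self, small_map):
        # exactly 50% of the 60-probe q arm (30 probes): strict inequality
        assert len(suppress_arm_scale_mrds([self._mrd(40, 69)], small_map)) == 1


class TestRecurrentArms:
    def _calls(self, n_loss, n):
        calls = {f"s{i}": {"9q": "loss" if i < n_loss else "none"}
                 for i in range(n)}
        return calls

    def test_11_percent_recurrent(self, config):
        regions = recurrent_arm_regions(self._calls(16, 146), config)
        assert [r.kind for r in regions] == ["ARM_LOSS"]

    def test_9_percent_not_recurrent(self, config):
        assert recurrent_arm_regions(self._calls(14, 146), config) == []

    def test_zero_carriers(self, config):
        assert recurrent_arm_regions(self._calls(0, 20), config) == []


class TestAlterationMatrix:
    def _setup(self, small_map):
        region = RecurrentRegion("FGA", "chr1", 10, 19, 10, 19, 3, frozenset())
        events = {
            "s1": [FocalEvent("s1", "chr1", 12, 16, "FGA", 1.0)],
            "s2": [FocalEvent("s2", "chr1", 60, 66, "FGA", 1.0)],
            "s3": [],
        }
        masks = {s: np.zeros(100, dtype=bool) for s in events}
        return region, events, masks

    def test_intersection_rule(self, small_map, config):
        region, events, masks = self._setup(small_map)
        mat = build_alteration_matrix([region], events, masks, [], None,
                                      small_map, config)
        col = mat.to_frame().iloc[:, 0]
        assert col["s1"] == 1 and col["s2"] == 0 and col["s3"] == 0

    def test_rare_feature_flagged_for_mds(self, small_map, config):
        region, events, masks = self._setup(small_map)
        # 25 samples, 1 carrier -> 4% < 5%
        events.update({f"x{i}": [] for i in range(22)})
        masks.update({f"x{i}": np.zeros(100, dtype=bool) for i in range(22)})
        mat = build_alteration_matrix([region], events, masks, [], None,
                                      small_map, config)
        assert mat.meta["excluded_for_mds"].iloc[0]

    def test_sample_mismatch_reported(self, small_map, config):
        region, events, masks = self._setup(small_map)
        del masks["s3"]
        with pytest.raises(ValueError, match="s3"):
            build_alteration_matrix([region], events, masks, [], None,
                                    small_map, config)

    def test_mutation_features_appended(self, small_map, config):
        region, events, masks = self._setup(small_map)
        muts = pd.DataFrame({"sample_id": ["s1", "s2", "s3"],
                             "gene": ["TP53"] * 3,
                             "status": ["mutated", "wildtype", "mutated"]})
        mat = build_alteration_matrix([region], events, masks, [], muts,
                                      small_map, config)
        assert mat.carriers("MUT:TP53") == frozenset({"s1", "s3"})
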