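"""SLR statistic: partitioning rules, per-sample ratios, group tests, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoswitch import apa_slr as slr
from isoswitch.io_formats import (
    IntensityMatrix,
    PolyASiteTable,
    ProbeAnnotation,
    ValidationError,
)
from isoswitch.synthetic_data import SwitchScenario, gen_probe_matrix


def _annotation(offsets, lengths=None, probeset="ps1"):
    n = len(offsets)
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "probeset_id": [probeset] * n,
        "transcript_position": offsets,
        "probe_length": lengths or [25] * n,
    }))


SITES = PolyASiteTable(pd.DataFrame(
    {"gene_id": ["G1"], "site_position": [100], "rank": [1]}
))


class TestPartition:
    def test_probes_split_at_site(self):
        ann = _annotation([10, 50, 300, 400])
        part = slr.partition_probes(ann, SITES, "G1", 1)
        assert part.proximal_probe_ids == ["p0", "p1"]
        assert part.distal_probe_ids == ["p2", "p3"]
        assert part.dropped_probe_ids == []

    def test_straddling_probe_dropped(self):
        ann = _annotation([10, 50, 95, 300, 400])  # 95+25=120 spans the site
        part = slr.partition_probes(ann, SITES, "G1", 1)
        assert part.dropped_probe_ids == ["p2"]
        assert "p2" not in part.proximal_probe_ids + part.distal_probe_ids

    def test_site_beyond_all_probes_rejected(self):
        ann = _annotation([10, 20, 40, 60])
        with pytest.raises(slr.PartitionError, match="distal"):
            slr.partition_probes(ann, SITES, "G1", 1)

    def test_min_probes_enforced(self):
        ann = _annotation([10, 300, 400])
        with pytest.raises(slr.PartitionError):
            slr.partition_probes(ann, SITES, "G1", 1, min_probes=2)
        part = slr.partition_probes(ann, SITES, "G1", 1, min_probes=1)
        assert part.proximal_probe_ids == ["p0"]


class TestComputeSlr:
    def test_arithmetic_example(self, simple_partition):
        values = pd.DataFrame(
            {"s1": [4.0, 4.0, 2.0, 2.0]},
            index=["p1", "p2", "d1", "d2"],
        )
        m = IntensityMatrix(values=values,
                            sample_groups=pd.Series(["a"], index=["s1"]))
        res = slr.compute_slr(m, simple_partition)
        assert res.slr["s1"] == pytest.approx(2.0)
        assert res.ln_slr["s1"] == pytest.approx(np.log(2), abs=1e-12)

    def test_all_equal_probes_give_slr_one(self, simple_partition):
        values = pd.DataFrame({"s1": [3.0] * 4}, index=["p1", "p2", "d1", "d2"])
        m = IntensityMatrix(values=values,
                            sample_groups=pd.Series(["a"], index=["s1"]))
        res = slr.compute_slr(m, simple_partition)
        assert res.ln_slr["s1"] == 0.0

    def test_matches_brute_force_oracle(self, random_intensity_matrix):
        part = slr.ProbePartition("ps", "G", 0, ["p1", "p2", "p3"],
                                  ["d1", "d2", "d3"])
        res = slr.compute_slr(random_intensity_matrix, part)
        v = random_intensity_matrix.values
        for s in v.columns:
            expect = np.log(
                (v.loc["p1", s] + v.loc["p2", s] + v.loc["p3", s]) /
                (v.loc["d1", s] + v.loc["d2", s] + v.loc["d3", s])
            )
            assert res.ln_slr[s] == pytest.approx(expect, rel=1e-12)

    def test_missing_probe_named(self, random_intensity_matrix):
        part = slr.ProbePartition("ps", "G", 0, ["p1", "ghost"], ["d1", "d2"])
        with pytest.raises(ValidationError, match="ghost"):
            slr.compute_slr(random_intensity_matrix, part)

    def test_nonpositive_distal_sample_excluded(self, simple_partition):
        values = pd.DataFrame({"s1": [4.0, 4.0, 0.0, 0.0],
                               "s2": [4.0, 4.0, 2.0, 2.0]},
                              index=["p1", "p2", "d1", "d2"])
        m = IntensityMatrix(values=values,
                            sample_groups=pd.Series(["a", "a"],
                                                    index=["s1", "s2"]))
        res = slr.compute_slr(m, simple_partition)
        assert res.excluded_samples == ["s1"]
        assert list(res.slr.index) == ["s2"]


class TestInvariants:
    @given(factor=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_per_sample(self, factor):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.lognormal(5, 0.4, size=(4, 3)),
                              index=["p1", "p2", "d1", "d2"],
                              columns=["s1", "s2", "s3"])
        groups = pd.Series(["a"] * 3, index=values.columns)
        part = slr.ProbePartition("ps", "G", 0, ["p1", "p2"], ["d1", "d2"])
        base = slr.compute_slr(IntensityMatrix(values, groups), part)
        scaled = values.copy()
        scaled["s2"] *= factor
        res = slr.compute_slr(IntensityMatrix(scaled, groups), part)
        assert np.allclose(res.ln_slr, base.ln_slr)

    def test_swapping_sides_negates_ln_slr(self, random_intensity_matrix):
        a = slr.ProbePartition("ps", "G", 0, ["p1", "p2"], ["d1", "d2"])
        b = slr.ProbePartition("ps", "G", 0, ["d1", "d2"], ["p1", "p2"])
        ra = slr.compute_slr(random_intensity_matrix, a)
        rb = slr.compute_slr(random_intensity_matrix, b)
        assert np.allclose(ra.ln_slr, -rb.ln_slr)

    def test_scaling_distal_by_c_divides_slr_by_c(self, random_intensity_matrix):
        part = slr.ProbePartition("ps", "G", 0, ["p1", "p2"], ["d1", "d2"])
        base = slr.compute_slr(random_intensity_matrix, part)
        c = 1.7
        scaled = random_intensity_matrix.values.copy()
        scaled.loc[["d1", "d2"]] *= c
        m = IntensityMatrix(scaled, random_intensity_matrix.sample_groups)
        res = slr.compute_slr(m, part)
        assert np.allclose(res.slr, base.slr / c)


class TestCompare:
    def test_identical_groups_give_null_result(self, simple_partition):
        rng = np.random.default_rng(1)
        col = rng.lognormal(5, 0.3, size=4)
        values = pd.DataFrame(
            np.column_stack([col] * 8),
            index=["p1", "p2", "d1", "d2"],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=values.columns)
        res = slr.compute_slr(IntensityMatrix(values, groups), simple_partition)
        cmp_ = slr.compare_slr(res, groups)
        assert cmp_.mean_difference == 0.0

    def test_strong_separation_gives_tiny_p(self, simple_partition):
        rng = np.random.default_rng(2)
        cols = []
        for i in range(12):
            base = np.array([2.0, 2.0, 2.0, 2.0]) if i < 6 else \
                np.array([6.0, 6.0, 2.0, 2.0])
            cols.append(base * (1 + rng.normal(0, 1e-3, 4)))
        values = pd.DataFrame(np.column_stack(cols),
                              index=["p1", "p2", "d1", "d2"],
                              columns=[f"s{i}" for i in range(12)])
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=values.columns)
        res = slr.compute_slr(IntensityMatrix(values, groups), simple_partition)
        assert slr.compare_slr(res, groups).p_value < 1e-6

    def test_noiseless_scenario_difference_is_ln_two(self, simple_partition):
        scen = SwitchScenario(noise_cv=0.0, short_long_ratio_normal=1.0,
                              short_long_ratio_tumor=3.0, seed=0)
        m = gen_probe_matrix(scen, simple_partition)
        res = slr.compute_slr(m, simple_partition)
        cmp_ = slr.compare_slr(res, m.sample_groups,
                               group_order=("normal", "tumor"))
        assert cmp_.mean_difference == pytest.approx(np.log(2), abs=1e-12)


class TestScreen:
    def test_empty_site_table_yields_only_rejections(self, random_intensity_matrix):
        ann = _annotation([10, 50, 300, 400], probeset="G1")
        empty_sites = PolyASiteTable(pd.DataFrame(
            columns=["gene_id", "site_position", "rank"]))
        results, rejected = slr.run_apa_screen(random_intensity_matrix, ann,
                                               empty_sites)
        assert len(results) == 0
        assert len(rejected) == 1
        assert "no poly(A) sites" in rejected["reason"].iloc[0]

    def test_results_sorted_by_p(self):
        from isoswitch.synthetic_data import gen_apa_panel

        m, probes, sites, truth = gen_apa_panel(n_genes=12, n_switch=3, seed=5)
        results, _ = slr.run_apa_screen(m, probes, sites)
        assert results["p_value"].is_monotonic_increasing
        assert set(results["gene_id"].head(3)) == set(truth)
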