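"""Composite arithmetic, ratio invariances, and genome encode/repair."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cvrsearch.composites import (
    CompositeConfig,
    InfeasibleConstraints,
    RatioSpec,
    SearchSpace,
    composite_value,
    compute_cvr,
    decode_genome,
    make_bilateral,
    repair_genome,
)
from cvrsearch.data_io import RegionalDataset

from conftest import make_long_frame


def scan_frame(values):
    return pd.DataFrame(
        [{"region_id": r, "suv": s, "volume": v} for r, s, v in values]
    )


class TestCompositeValue:
    @pytest.mark.parametrize(
        "records,regions,method,expected",
        [
            ([("a", 1.5, 100), ("b", 2.5, 100)], {"a", "b"}, "mean_suv", 2.0),
            ([("a", 1.2, 100), ("b", 1.8, 300)], {"a", "b"}, "volume_weighted", 1.65),
            ([("a", 1.7, 123)], {"a"}, "mean_suv", 1.7),
            ([("a", 1.7, 123)], {"a"}, "volume_weighted", 1.7),
        ],
    )
    def test_arithmetic(self, records, regions, method, expected):
        assert composite_value(scan_frame(records), regions, method) == pytest.approx(expected)

    def test_empty_or_missing_regions_error(self):
        scan = scan_frame([("a", 1.0, 1.0)])
        with pytest.raises(ValueError, match="empty"):
            composite_value(scan, set(), "mean_suv")
        with pytest.raises(ValueError, match="missing"):
            composite_value(scan, {"a", "zzz"}, "mean_suv")


class TestMakeBilateral:
    @pytest.mark.parametrize(
        "suv_l,suv_r,vol_l,vol_r,expected_suv",
        [(1.0, 2.0, 100, 100, 1.5), (1.2, 1.2, 70, 350, 1.2), (1.0, 3.0, 100, 300, 2.5)],
    )
    def test_volume_weighted_collapse(self, tiny_meta, suv_l, suv_r, vol_l, vol_r, expected_suv):
        frame = make_long_frame(n_subjects=1, n_visits=2)
        frame.loc[frame.region_id == "amygdala_L", ["suv", "volume"]] = (suv_l, vol_l)
        frame.loc[frame.region_id == "amygdala_R", ["suv", "volume"]] = (suv_r, vol_r)
        out = make_bilateral(RegionalDataset.from_frame(frame), tiny_meta)
        row = out.frame[out.frame.region_id == "amygdala"].iloc[0]
        assert row.suv == pytest.approx(expected_suv)
        assert row.volume == pytest.approx(vol_l + vol_r)

    def test_midline_and_unpaired_pass_through(self, tiny_dataset, tiny_meta):
        out = make_bilateral(tiny_dataset, tiny_meta)
        assert out.regions == {"amygdala", "postcentral_L", "cerebellum"}
        orig = tiny_dataset.frame[tiny_dataset.frame.region_id == "cerebellum"]["suv"].to_numpy()
        new = out.frame[out.frame.region_id == "cerebellum"]["suv"].to_numpy()
        np.testing.assert_allclose(np.sort(new), np.sort(orig))

    def test_missing_hemisphere_errors(self, tiny_meta):
        frame = make_long_frame(regions=("amygdala_L", "postcentral_L", "cerebellum"))
        with pytest.raises(ValueError, match="amygdala"):
            make_bilateral(RegionalDataset.from_frame(frame), tiny_meta)


class TestComputeCvr:
    def test_simple_ratio(self, tiny_meta):
        frame = make_long_frame(n_subjects=1, n_visits=2)
        frame.loc[frame.region_id == "postcentral_L", "suv"] = 2.0
        frame.loc[frame.region_id == "cerebellum", "suv"] = 1.0
        ds = RegionalDataset.from_frame(frame)
        spec = RatioSpec({"postcentral_L"}, {"cerebellum"})
        series = compute_cvr(ds, spec, CompositeConfig("mean_suv", "lateral"))
        assert np.allclose(series["value"], 2.0)
        assert np.allclose(series["log_value"], np.log(2.0))

    @pytest.mark.parametrize("laterality", ["lateral", "bilateral"])
    @pytest.mark.parametrize("method", ["mean_suv", "volume_weighted"])
    def test_per_scan_rescaling_cancels(self, tiny_dataset, tiny_meta, method, laterality):
        spec = RatioSpec({"amygdala_L", "amygdala_R"}, {"cerebellum"})
        config = CompositeConfig(method, laterality)
        base = compute_cvr(tiny_dataset, spec, config, tiny_meta)
        scaled_frame = tiny_dataset.frame.copy()
        rng = np.random.default_rng(1)
        for (sid, t), idx in scaled_frame.groupby(["subject_id", "scan_time"]).groups.items():
            scaled_frame.loc[idx, "suv"] *= rng.uniform(0.3, 3.7)
        scaled = compute_cvr(
            RegionalDataset.from_frame(scaled_frame), spec, config, tiny_meta
        )
        np.testing.assert_allclose(scaled["value"], base["value"], rtol=1e-12, atol=0)

    def test_suvr_inputs_give_identical_series(self, tiny_dataset, tiny_meta):
        # dividing every SUV by a common per-scan reference (SUVR) leaves CVR unchanged
        spec = RatioSpec({"amygdala_L", "amygdala_R"}, {"postcentral_L"})
        config = CompositeConfig("mean_suv", "lateral")
        base = compute_cvr(tiny_dataset, spec, config)
        suvr_frame = tiny_dataset.frame.copy()
        ref = suvr_frame[suvr_frame.region_id == "cerebellum"].set_index(
            ["subject_id", "scan_time"]
        )["suv"]
        keys = list(zip(suvr_frame["subject_id"], suvr_frame["scan_time"]))
        suvr_frame["suv"] = suvr_frame["suv"].to_numpy() / ref.loc[keys].to_numpy()
        suvr = compute_cvr(RegionalDataset.from_frame(suvr_frame), spec, config)
        np.testing.assert_allclose(suvr["value"], base["value"], rtol=1e-12)

    def test_bilateral_equals_union_under_volume_weighting(self, tiny_dataset, tiny_meta):
        # collapsing hemispheres first is an algebraic no-op for volume weighting
        spec = RatioSpec({"amygdala_L", "amygdala_R"}, {"cerebellum"})
        bil = compute_cvr(tiny_dataset, spec, CompositeConfig("volume_weighted", "bilateral"),
                          tiny_meta)
        lat = compute_cvr(tiny_dataset, spec, CompositeConfig("volume_weighted", "lateral"))
        np.testing.assert_allclose(bil["value"], lat["value"], atol=1e-12)

    def test_partial_pair_in_bilateral_mode_rejected(self, tiny_dataset, tiny_meta):
        spec = RatioSpec({"amygdala_L"}, {"cerebellum"})
        with pytest.raises(ValueError, match="partially"):
            compute_cvr(tiny_dataset, spec, CompositeConfig("mean_suv", "bilateral"), tiny_meta)


class TestRatioSpec:
    def test_rejects_empty_or_overlapping(self):
        with pytest.raises(ValueError):
            RatioSpec(frozenset(), {"a"})
        with pytest.raises(ValueError, match="overlap"):
            RatioSpec({"a", "b"}, {"b"})

    def test_json_round_trip(self):
        spec = RatioSpec({"a"}, {"b", "c"})
        config = CompositeConfig("mean_suv", "lateral")
        again, cfg = RatioSpec.from_json(spec.to_json(config))
        assert again == spec and cfg == config


def genome_space(tiny_meta, laterality="lateral", frozen=None):
    return SearchSpace.from_metadata(tiny_meta, laterality, frozen_assignments=frozen)


class TestGenome:
    def test_decode_maps_values_to_sides(self, tiny_meta):
        space = genome_space(tiny_meta)
        # units sorted: amygdala_L, amygdala_R, cerebellum, postcentral_L
        spec = decode_genome(np.array([0, 1, 2, 1]), space)
        assert spec == RatioSpec({"amygdala_L"}, {"cerebellum"})

    def test_bilateral_unit_expands_to_both_hemispheres(self, tiny_meta):
        space = genome_space(tiny_meta, "bilateral")
        # units sorted: amygdala, cerebellum, postcentral_L
        spec = decode_genome(np.array([0, 2, 1]), space)
        assert spec.numerator == {"amygdala_L", "amygdala_R"}

    def test_all_excluded_genome_invalid(self, tiny_meta):
        space = genome_space(tiny_meta)
        with pytest.raises(ValueError, match="invalid genome"):
            decode_genome(np.array([1, 1, 1, 1]), space)

    def test_repair_moves_early_tau_out_of_denominator(self, tiny_meta):
        space = genome_space(tiny_meta)
        rng = np.random.default_rng(0)
        g = repair_genome(np.array([2, 0, 2, 0]), space, rng)  # amygdala_L is Braak 3
        assert g[0] != 2
        assert space.is_valid(g)

    def test_repair_keeps_valid_genome_unchanged(self, tiny_meta):
        space = genome_space(tiny_meta)
        g = np.array([0, 1, 2, 1])
        np.testing.assert_array_equal(repair_genome(g, space, np.random.default_rng(0)), g)

    def test_repair_fills_empty_sides(self, tiny_meta):
        space = genome_space(tiny_meta)
        g = repair_genome(np.array([1, 1, 1, 1]), space, np.random.default_rng(3))
        assert (g == 0).sum() == 1 and (g == 2).sum() == 1
        assert space.is_valid(g)

    def test_frozen_assignments_pinned(self, tiny_meta):
        space = genome_space(tiny_meta, frozen={"postcentral_L": 0})
        g = repair_genome(np.array([1, 1, 1, 1]), space, np.random.default_rng(0))
        assert g[3] == 0

    def test_infeasible_pin_raises(self, tiny_meta):
        with pytest.raises(InfeasibleConstraints):
            genome_space(tiny_meta, frozen={"cerebellum": 0})  # reference in numerator

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=4), st.integers(0, 2**31 - 1))
    def test_repair_then_decode_never_raises(self, tiny_meta, values, seed):
        space = genome_space(tiny_meta)
        rng = np.random.default_rng(seed)
        g = repair_genome(np.array(values), space, rng)
        spec = decode_genome(g, space)
        assert spec.numerator and spec.denominator
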