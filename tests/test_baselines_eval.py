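"""Baseline grid enumeration, ablation, and parametric-bootstrap intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cvrsearch.baselines_eval import (
    REFERENCE_COMPOSITES,
    TARGET_COMPOSITES,
    ablate,
    best_baseline,
    bootstrap_ci,
    enumerate_baselines,
    evaluate_catalog,
)
from cvrsearch.composites import CompositeConfig, RatioSpec
from cvrsearch.data_io import default_region_metadata
from cvrsearch.trial_power import TrialDesign

from conftest import make_metadata


class TestEnumerateBaselines:
    def test_default_metadata_yields_full_literature_grid(self):
        catalog = enumerate_baselines(default_region_metadata())
        assert len(catalog) == 220
        assert len(catalog.usable) == 220
        names = [e.name for e in catalog.entries]
        assert len(set(names)) == 220

    def test_one_target_one_reference_gives_two_methods(self):
        meta = default_region_metadata()
        catalog = enumerate_baselines(
            meta, targets=["meta_temporal"], references=[REFERENCE_COMPOSITES[0]]
        )
        assert len(catalog) == 2
        assert {e.method for e in catalog.entries} == {"mean_suv", "volume_weighted"}

    @given(
        n_targets=st.integers(1, len(TARGET_COMPOSITES)),
        n_refs=st.integers(1, len(REFERENCE_COMPOSITES)),
    )
    def test_count_identity_for_any_grid(self, n_targets, n_refs):
        meta = default_region_metadata()
        catalog = enumerate_baselines(
            meta,
            targets=TARGET_COMPOSITES[:n_targets],
            references=REFERENCE_COMPOSITES[:n_refs],
        )
        assert len(catalog) == n_targets * n_refs * 2

    def test_empty_composite_marked_unusable_not_dropped(self):
        meta = make_metadata(
            [
                dict(region_id="x", hemisphere="midline", bilateral_pair_id=None,
                     braak_stage=1, reference_candidate=False, composites="braak1"),
                dict(region_id="cb", hemisphere="midline", bilateral_pair_id=None,
                     braak_stage=None, reference_candidate=True,
                     composites="whole_cerebellum"),
            ]
        )
        catalog = enumerate_baselines(meta)
        assert len(catalog) == 220
        unusable = [e for e in catalog.entries if not e.usable]
        assert unusable and all(e.reason for e in unusable)
        ok = [e for e in catalog.entries if e.usable]
        assert all(e.target == "braak1" and e.reference == "whole_cerebellum" for e in ok)


class TestEvaluateCatalog:
    def test_planted_signal_targets_outrank_stable_targets(self, discovery_cohort):
        dataset, meta, _ = discovery_cohort
        catalog = enumerate_baselines(
            meta,
            targets=["meta_temporal", "rest"],
            references=[("whole_cerebellum", ("whole_cerebellum",))],
        )
        table = evaluate_catalog(
            dataset, meta, catalog, {"e2": TrialDesign.preset("experiment2")}
        )
        by_target = table[table.usable].groupby("target")["separation"].mean()
        assert by_target["meta_temporal"] > by_target["rest"]

    def test_rows_are_order_independent_and_deterministic(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        refs = [("brainstem", ("brainstem",)), ("eroded_subcortical_wm", ("eroded_subcortical_wm",))]
        cat_a = enumerate_baselines(meta, targets=["meta_temporal"], references=refs)
        cat_b = enumerate_baselines(meta, targets=["meta_temporal"], references=refs[::-1])
        designs = {"e2": TrialDesign.preset("experiment2")}
        ta = evaluate_catalog(dataset, meta, cat_a, designs, laterality="lateral")
        tb = evaluate_catalog(dataset, meta, cat_b, designs, laterality="lateral")
        merged = ta.merge(tb, on="name", suffixes=("_a", "_b"))
        assert np.allclose(merged["fitness_a"], merged["fitness_b"], equal_nan=True)


class TestAblate:
    def test_row_count_and_skip_rules(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        spec = RatioSpec(
            {"entorhinal_L", "inferior_temporal_L", "postcentral_L"},
            {"brainstem", "eroded_subcortical_wm"},
        )
        table = ablate(
            dataset, meta, spec, CompositeConfig("mean_suv", "lateral"),
            TrialDesign.preset("experiment2"),
        )
        assert len(table) == 5
        assert not table["skipped"].any()

    def test_single_region_side_skipped_with_reason(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        spec = RatioSpec({"entorhinal_L", "inferior_temporal_L"}, {"brainstem"})
        table = ablate(
            dataset, meta, spec, CompositeConfig("mean_suv", "lateral"),
            TrialDesign.preset("experiment2"),
        )
        row = table[table.region == "brainstem"].iloc[0]
        assert row.skipped and "empty" in row.reason

    def test_removing_signal_region_hurts_separation_most(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        spec = RatioSpec(
            {"entorhinal_L", "postcentral_L"}, {"brainstem", "eroded_subcortical_wm"}
        )
        table = ablate(
            dataset, meta, spec, CompositeConfig("mean_suv", "lateral"),
            TrialDesign.preset("experiment2"),
        )
        sep = table.set_index("region")["separation"]
        # dropping the planted-signal region loses more separation than
        # dropping the flat region
        assert sep["entorhinal_L"] < sep["postcentral_L"]


class TestBootstrap:
    def test_near_zero_noise_collapses_interval(self, tiny_cohort):
        from dataclasses import replace

        from cvrsearch import synthetic

        config = replace(
            synthetic.preset("tiny_oracle"), seed=4,
            sigma_b0=0.0, sigma_b1=0.0, sigma_noise=1e-6, sigma_scale=0.0,
        )
        dataset, _ = synthetic.generate_cohort(config)
        meta = synthetic.metadata_for(config)
        cis = bootstrap_ci(
            dataset, meta, RatioSpec({"entorhinal_L"}, {"cerebellum_cortex_L"}),
            CompositeConfig("mean_suv", "lateral"), TrialDesign.preset("experiment2"),
            metrics=("sse", "repeatability"), B=50, seed=0,
        )
        # SSE and repeatability converge to their noise-free limits (both ~0);
        # the t-statistic instead diverges as noise vanishes, so it is not a
        # collapse witness
        assert cis["sse"].point < 1e-3 and cis["sse"].width < 1e-3
        assert cis["repeatability"].point < 1e-2 and cis["repeatability"].width < 1e-2

    def test_same_seed_identical_endpoints(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        args = (
            dataset, meta, RatioSpec({"entorhinal_L"}, {"brainstem"}),
            CompositeConfig("mean_suv", "lateral"), TrialDesign.preset("experiment2"),
        )
        a = bootstrap_ci(*args, B=40, seed=123)
        b = bootstrap_ci(*args, B=40, seed=123)
        for k in a:
            assert (a[k].lower, a[k].upper) == (b[k].lower, b[k].upper)

    def test_interval_brackets_point_estimate(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        cis = bootstrap_ci(
            dataset, meta, RatioSpec({"entorhinal_L", "inferior_temporal_L"}, {"brainstem"}),
            CompositeConfig("mean_suv", "lateral"), TrialDesign.preset("experiment2"),
            B=100, seed=5,
        )
        for k, ci in cis.items():
            assert ci.n_replicates + ci.n_failed == 100
            assert not ci.unreliable
            assert ci.lower <= ci.upper

    def test_unknown_metric_rejected(self, tiny_cohort):
        dataset, meta, _ = tiny_cohort
        with pytest.raises(ValueError, match="unknown metric"):
            bootstrap_ci(
                dataset, meta, RatioSpec({"entorhinal_L"}, {"brainstem"}),
                CompositeConfig("mean_suv", "lateral"), TrialDesign.preset("experiment2"),
                metrics=("sse", "zzz"), B=10,
            )


def test_best_baseline_requires_usable_rows():
    table = pd.DataFrame(
        [dict(design="e2", name="x", usable=False, converged=False, fitness=-math.inf)]
    )
    with pytest.raises(ValueError, match="usable"):
        best_baseline(table)
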