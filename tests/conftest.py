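"""Shared fixtures: tiny metadata/cohorts and hypothesis settings."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cvrsearch import synthetic
from cvrsearch.data_io import RegionalDataset, RegionMetadata

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_metadata(rows: list[dict]) -> RegionMetadata:
    return RegionMetadata.from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_meta() -> RegionMetadata:
    """Four regions: one bilateral pair, one early-tau region, one reference."""
    return make_metadata(
        [
            dict(region_id="amygdala_L", hemisphere="left", bilateral_pair_id="amygdala",
                 braak_stage=3, reference_candidate=False, composites="meta_temporal"),
            dict(region_id="amygdala_R", hemisphere="right", bilateral_pair_id="amygdala",
                 braak_stage=3, reference_candidate=False, composites="meta_temporal"),
            dict(region_id="postcentral_L", hemisphere="left", bilateral_pair_id=None,
                 braak_stage=6, reference_candidate=False, composites=""),
            dict(region_id="cerebellum", hemisphere="midline", bilateral_pair_id=None,
                 braak_stage=None, reference_candidate=True, composites="whole_cerebellum"),
        ]
    )


def make_long_frame(
    n_subjects: int = 2,
    n_visits: int = 3,
    regions: tuple[str, ...] = ("amygdala_L", "amygdala_R", "postcentral_L", "cerebellum"),
    seed: int = 0,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_subjects):
        group = "CI" if j % 2 else "CU"
        times = np.arange(n_visits) * 1.5
        for t in times:
            for r in regions:
                rows.append(
                    dict(subject_id=f"s{j}", group=group, scan_time=t, region_id=r,
                         suv=float(rng.uniform(0.8, 2.5)), volume=float(rng.uniform(900, 1100)))
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_dataset() -> RegionalDataset:
    return RegionalDataset.from_frame(make_long_frame())


@pytest.fixture(scope="session")
def tiny_cohort():
    """tiny_oracle synthetic cohort with its metadata and truth."""
    config = replace(synthetic.preset("tiny_oracle"), seed=11)
    dataset, truth = synthetic.generate_cohort(config)
    return dataset, synthetic.metadata_for(config), truth


@pytest.fixture(scope="session")
def discovery_cohort():
    """experiment2_like synthetic cohort (the clinical-trial discovery setting)."""
    config = replace(synthetic.preset("experiment2_like"), seed=7)
    dataset, truth = synthetic.generate_cohort(config)
    return dataset, synthetic.metadata_for(config), truth
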