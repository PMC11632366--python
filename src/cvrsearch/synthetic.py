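"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates an amyloid-positive tau PET cohort: per subject j in
group g, visit time t and region r,

    log suv = m_r + a_j + (s_{r,g} + c_j) * t + log g_j(t) + e_jrt

where (a_j, c_j) are correlated subject-level random intercept/slope,
g_j(t) is a lognormal per-scan global scale factor shared by every region of
that scan (the synthetic embodiment of instrumentation/uptake confounds that
ratios cancel), s_{r,g} is the planted group-dependent accumulation slope
(zero on stable and reference regions) and e_jrt is iid regional noise.
Visit counts and inter-visit intervals follow the observed cohort mix (most
intervals 0.7-1.5 years).  Volumes are region constants with subject-level
jitter.

Because a ratio of composites cancels exp(a_j + c_j t) and g_j(t) exactly,
group separation in a fitted CVR arises only from the planted slopes, and
residual variability only from regional noise - which is what makes planted-
signal recovery and ratio-cancellation tests sharp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import RegionalDataset, RegionMetadata

__all__ = [
    "SyntheticRegion",
    "SyntheticConfig",
    "SyntheticTruth",
    "bilateral_pair",
    "generate_cohort",
    "preset",
    "metadata_for",
]

# interval bins (years) and the cohort interval mix per group
INTERVAL_BINS = ((0.7, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 5.0))
INTERVAL_MIX_CU = (0.61, 0.22, 0.06, 0.11)
INTERVAL_MIX_CI = (0.72, 0.17, 0.06, 0.05)


@dataclass(frozen=True)
class SyntheticRegion:
    """One region's role in the generative model."""

    region_id: str
    hemisphere: str = "midline"
    bilateral_pair_id: str | None = None
    braak_stage: int | None = None
    reference_candidate: bool = False
    composites: tuple[str, ...] = ()
    base_log_suv: float = 0.25   # m_r
    slope_cu: float = 0.0        # s_{r,CU}, log units / year
    slope_ci: float = 0.0        # s_{r,CI}
    volume: float = 5000.0       # mm^3

    @property
    def role(self) -> str:
        if self.reference_candidate:
            return "reference"
        if self.slope_ci != 0.0 or self.slope_cu != 0.0:
            return "signal"
        return "stable"


def bilateral_pair(name: str, **kwargs) -> tuple[SyntheticRegion, SyntheticRegion]:
    """Left/right pair of regions sharing a role definition."""
    left = SyntheticRegion(
        region_id=f"{name}_L", hemisphere="left", bilateral_pair_id=name, **kwargs
    )
    right = SyntheticRegion(
        region_id=f"{name}_R", hemisphere="right", bilateral_pair_id=name, **kwargs
    )
    return left, right


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generative parameters.

    Defaults mirror the study conditions: ~200-subject amyloid-positive
    cohorts, 2-4 visits at 0.7-3.5+ year intervals, per-scan global scale SD
    0.05, small regional noise, correlated subject random effects.
    """

    n_cu: int = 76
    n_ci: int = 122
    regions: tuple[SyntheticRegion, ...] = ()
    visit_count_probs: tuple[float, ...] = (0.55, 0.30, 0.15)  # P(2,3,4 visits)
    interval_bins: tuple[tuple[float, float], ...] = INTERVAL_BINS
    interval_probs: tuple[float, ...] = INTERVAL_MIX_CU
    sigma_b0: float = 0.05
    sigma_b1: float = 0.01
    rho: float = 0.5
    sigma_noise: float = 0.02
    sigma_scale: float = 0.05
    volume_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cu < 0 or self.n_ci < 0 or self.n_cu + self.n_ci == 0:
            raise ValueError("need at least one subject")
        if not self.regions:
            raise ValueError("need at least one region")
        for probs, what in ((self.visit_count_probs, "visit_count_probs"),
                            (self.interval_probs, "interval_probs")):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{what} must sum to 1")
        if len(self.interval_probs) != len(self.interval_bins):
            raise ValueError("interval_probs/interval_bins length mismatch")
        for sd in (self.sigma_b0, self.sigma_b1, self.sigma_noise,
                   self.sigma_scale, self.volume_jitter):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Realized latent quantities of a generated cohort."""

    subjects: pd.DataFrame   # subject_id, group, a (intercept), c (slope)
    scans: pd.DataFrame      # subject_id, scan_time, scale
    regions: pd.DataFrame    # region_id, role, slope_cu, slope_ci, base_log_suv
    config: SyntheticConfig


def metadata_for(config: SyntheticConfig) -> RegionMetadata:
    """Region metadata matching a synthetic cohort."""
    rows = [
        {
            "region_id": r.region_id,
            "hemisphere": r.hemisphere,
            "bilateral_pair_id": r.bilateral_pair_id,
            "braak_stage": r.braak_stage,
            "reference_candidate": r.reference_candidate,
            "composites": ";".join(r.composites),
        }
        for r in config.regions
    ]
    return RegionMetadata.from_frame(pd.DataFrame(rows))


def generate_cohort(config: SyntheticConfig) -> tuple[RegionalDataset, SyntheticTruth]:
    """Draw one cohort; fully deterministic given ``config`` (incl. its seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cu + config.n_ci
    groups = np.array(["CU"] * config.n_cu + ["CI"] * config.n_ci)
    sids = np.array([f"S{i:04d}" for i in range(1, n + 1)])

    cov = np.array(
        [
            [config.sigma_b0**2, config.rho * config.sigma_b0 * config.sigma_b1],
            [config.rho * config.sigma_b0 * config.sigma_b1, config.sigma_b1**2],
        ]
    )
    re = rng.multivariate_normal(np.zeros(2), cov, size=n)

    regions = config.regions
    m = np.array([r.base_log_suv for r in regions])
    slope_cu = np.array([r.slope_cu for r in regions])
    slope_ci = np.array([r.slope_ci for r in regions])
    vols = np.array([r.volume for r in regions])
    k = len(regions)

    rows: list[pd.DataFrame] = []
    scan_rows: list[tuple[str, float, float]] = []
    bins = np.asarray(config.interval_bins)
    for j in range(n):
        n_visits = 2 + rng.choice(len(config.visit_count_probs), p=config.visit_count_probs)
        which = rng.choice(len(bins), size=n_visits - 1, p=np.asarray(config.interval_probs))
        intervals = rng.uniform(bins[which, 0], bins[which, 1])
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        slopes = slope_ci if groups[j] == "CI" else slope_cu
        subj_vol = vols * np.exp(rng.normal(0.0, config.volume_jitter, size=k))
        a, c = re[j]
        for t in times:
            log_g = rng.normal(0.0, config.sigma_scale)
            noise = rng.normal(0.0, config.sigma_noise, size=k)
            log_suv = m + a + (slopes + c) * t + log_g + noise
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sids[j],
                        "group": groups[j],
                        "scan_time": t,
                        "region_id": [r.region_id for r in regions],
                        "suv": np.exp(log_suv),
                        "volume": subj_vol,
                    }
                )
            )
            scan_rows.append((sids[j], float(t), float(np.exp(log_g))))

    dataset = RegionalDataset.from_frame(pd.concat(rows, ignore_index=True))
    truth = SyntheticTruth(
        subjects=pd.DataFrame(
            {"subject_id": sids, "group": groups, "a": re[:, 0], "c": re[:, 1]}
        ),
        scans=pd.DataFrame(scan_rows, columns=["subject_id", "scan_time", "scale"]),
        regions=pd.DataFrame(
            {
                "region_id": [r.region_id for r in regions],
                "role": [r.role for r in regions],
                "slope_cu": slope_cu,
                "slope_ci": slope_ci,
                "base_log_suv": m,
            }
        ),
        config=config,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# presets


def _cohort_regions() -> tuple[SyntheticRegion, ...]:
    """A compact region panel mirroring the real search problem: medial/lateral
    temporal signal regions (the meta-temporal constituents), late-stage
    stable cortex, and the conventional reference structures."""
    out: list[SyntheticRegion] = []
    signal = dict(base_log_suv=np.log(1.30), slope_cu=0.015, slope_ci=0.045)
    # meta-temporal constituents carry the disease signal
    out += bilateral_pair("entorhinal", braak_stage=1,
                          composites=("meta_temporal", "mesial_temporal", "braak1"),
                          volume=1800.0, **signal)
    out += bilateral_pair("hippocampus", braak_stage=2,
                          composites=("braak2",), volume=4200.0, **signal)
    out += bilateral_pair("amygdala", braak_stage=3,
                          composites=("meta_temporal", "mesial_temporal", "braak3"),
                          volume=1600.0, **signal)
    out += bilateral_pair("parahippocampal", braak_stage=3,
                          composites=("meta_temporal", "mesial_temporal", "braak3"),
                          volume=2100.0, **signal)
    out += bilateral_pair("fusiform", braak_stage=3,
                          composites=("meta_temporal", "mesial_temporal", "braak3"),
                          volume=9800.0, **signal)
    out += bilateral_pair("inferior_temporal", braak_stage=4,
                          composites=("meta_temporal", "temporoparietal", "braak4"),
                          volume=11000.0, **signal)
    out += bilateral_pair("middle_temporal", braak_stage=4,
                          composites=("meta_temporal", "temporoparietal", "braak4"),
                          volume=12000.0, **signal)
    # late-stage cortex: measured but flat over the study window
    stable = dict(base_log_suv=np.log(1.10))
    out += bilateral_pair("superior_frontal", braak_stage=5,
                          composites=("rest", "braak5"), volume=22000.0, **stable)
    out += bilateral_pair("precentral", braak_stage=6,
                          composites=("rest", "braak6"), volume=13000.0, **stable)
    out += bilateral_pair("postcentral", braak_stage=6,
                          composites=("rest", "braak6"), volume=10000.0, **stable)
    out += bilateral_pair("cuneus", braak_stage=6,
                          composites=("rest", "braak6"), volume=3200.0, **stable)
    out += bilateral_pair("pericalcarine", braak_stage=6,
                          composites=("rest", "braak6"), volume=2200.0, **stable)
    # conventional SUVR reference structures (numerator-excluded)
    ref = dict(reference_candidate=True)
    out += bilateral_pair("cerebellum_cortex", base_log_suv=0.0, volume=52000.0,
                          composites=("cerebellum_cortex", "whole_cerebellum",
                                      "composite_reference"), **ref)
    out += bilateral_pair("cerebellum_wm", base_log_suv=np.log(1.45), volume=14000.0,
                          composites=("whole_cerebellum", "composite_reference"), **ref)
    out += bilateral_pair("inferior_cerebellum_gm", base_log_suv=0.0, volume=21000.0,
                          composites=("inferior_cerebellum_gm",), **ref)
    out.append(SyntheticRegion("brainstem", base_log_suv=np.log(1.25), volume=21000.0,
                               composites=("brainstem", "composite_reference"), **ref))
    out.append(SyntheticRegion("eroded_subcortical_wm", base_log_suv=np.log(1.60),
                               volume=48000.0,
                               composites=("eroded_subcortical_wm", "composite_reference"),
                               **ref))
    return tuple(out)


def _tiny_regions() -> tuple[SyntheticRegion, ...]:
    """<= 6 searchable regions for brute-force oracle tests (lateral mode)."""
    return (
        SyntheticRegion("entorhinal_L", hemisphere="left", braak_stage=1,
                        composites=("meta_temporal", "braak1"), base_log_suv=np.log(1.3),
                        slope_cu=0.015, slope_ci=0.045, volume=1800.0),
        SyntheticRegion("inferior_temporal_L", hemisphere="left", braak_stage=4,
                        composites=("meta_temporal", "braak4"), base_log_suv=np.log(1.3),
                        slope_cu=0.015, slope_ci=0.045, volume=11000.0),
        SyntheticRegion("postcentral_L", hemisphere="left", braak_stage=6,
                        composites=("rest", "braak6"), base_log_suv=np.log(1.1),
                        volume=10000.0),
        SyntheticRegion("cerebellum_cortex_L", hemisphere="left",
                        reference_candidate=True, base_log_suv=0.0,
                        composites=("cerebellum_cortex", "whole_cerebellum"),
                        volume=52000.0),
        SyntheticRegion("brainstem", reference_candidate=True,
                        base_log_suv=np.log(1.25), composites=("brainstem",),
                        volume=21000.0),
        SyntheticRegion("eroded_subcortical_wm", reference_candidate=True,
                        base_log_suv=np.log(1.6), composites=("eroded_subcortical_wm",),
                        volume=48000.0),
    )


def preset(name: str) -> SyntheticConfig:
    """Named study-condition presets.

    * ``experiment1_like`` - 76 CU + 122 CI, CU-cohort interval mix
      (preclinical-trial discovery conditions);
    * ``experiment2_like`` - the same cohort weighted to the CI interval mix
      (clinical-trial discovery conditions);
    * ``tiny_oracle`` - <= 6 regions, 40 subjects, for exhaustive-search
      cross-checks.

    Presets are pure configuration: no randomness until ``generate_cohort``.
    """
    if name == "experiment1_like":
        return SyntheticConfig(
            n_cu=76, n_ci=122, regions=_cohort_regions(), interval_probs=INTERVAL_MIX_CU
        )
    if name == "experiment2_like":
        return SyntheticConfig(
            n_cu=76, n_ci=122, regions=_cohort_regions(), interval_probs=INTERVAL_MIX_CI
        )
    if name == "tiny_oracle":
        return SyntheticConfig(
            n_cu=20, n_ci=20, regions=_tiny_regions(), interval_probs=INTERVAL_MIX_CI,
            visit_count_probs=(0.5, 0.5, 0.0),
        )
    raise ValueError(f"unknown preset: {name!r}")
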