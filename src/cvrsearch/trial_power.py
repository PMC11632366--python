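"""Trial sample-size estimation and the search fitness.

The sample size estimate (SSE) is the per-arm count for a two-arm,
1:1-allocated trial powered to detect a fractional reduction of the trial
group's mean biomarker slope.  With a fitted random-slope model, the variance
of a subject's estimated slope over a visit schedule t_1..t_k is
sigma_b1^2 + sigma_eps^2 / sum_k (t_k - t_mean)^2, giving the per-arm count

    n = 2 (z_{1-alpha/2} + z_{power})^2 (sigma_b1^2 + sigma_eps^2/Sxx) / delta^2

with delta = pct_change x |group mean slope|.  The search fitness combines
trial efficiency with disease relevance: separation / SSE^2 (exponent
configurable), which also forces discovered biomarkers to increase faster in
the impaired group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .composites import CompositeConfig, RatioSpec, SearchSpace
from .data_io import RegionalDataset, RegionMetadata
from .longitudinal_model import (
    LMMFit,
    RandomSlopeModel,
    group_separation,
    repeatability_percent,
)

INVALID_FITNESS = -math.inf


@dataclass(frozen=True)
class TrialDesign:
    """A two-arm slope-reduction trial: population, schedule, power, effect."""

    group: str = "CI"
    visit_times: tuple[float, ...] = (0.0, 1.5)
    power: float = 0.80
    alpha: float = 0.05
    pct_change: float = 0.20

    def __post_init__(self) -> None:
        object.__setattr__(self, "visit_times", tuple(float(t) for t in self.visit_times))
        if self.group not in ("CU", "CI"):
            raise ValueError(f"unknown trial group: {self.group!r}")
        if len(set(self.visit_times)) < 2:
            raise ValueError("need at least 2 distinct visit times")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.pct_change <= 1:
            raise ValueError("pct_change must be in (0,1]")

    @classmethod
    def preset(cls, name: str) -> "TrialDesign":
        """Shipped designs: ``experiment1`` (CU, 4.5 y) / ``experiment2`` (CI, 1.5 y)."""
        from importlib.resources import files

        path = files("cvrsearch.presets").joinpath(f"{name}.yaml")
        if not path.is_file():
            raise ValueError(f"unknown design preset: {name!r}")
        return cls.from_yaml(path)

    @classmethod
    def from_yaml(cls, path) -> "TrialDesign":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            group=payload["group"],
            visit_times=tuple(payload["visit_times"]),
            power=float(payload.get("power", 0.80)),
            alpha=float(payload.get("alpha", 0.05)),
            pct_change=float(payload.get("pct_change", 0.20)),
        )

    @property
    def schedule_ssq(self) -> float:
        t = np.asarray(self.visit_times)
        return float(((t - t.mean()) ** 2).sum())


@dataclass(frozen=True)
class EvaluationResult:
    """Metric bundle for one candidate biomarker under one trial design."""

    sse: float                      # per-arm count after ceiling (inf if invalid)
    sse_raw: float                  # pre-ceiling value; used for fitness/tie-breaks
    separation: float
    repeatability: float
    fitness: float
    converged: bool
    spec: RatioSpec | None = None
    fit: LMMFit | None = field(repr=False, default=None)

    @property
    def valid(self) -> bool:
        return self.converged and math.isfinite(self.fitness)

    def to_dict(self) -> dict:
        return {
            "sse": self.sse if math.isfinite(self.sse) else None,
            "sse_raw": self.sse_raw if math.isfinite(self.sse_raw) else None,
            "separation": None if not math.isfinite(self.separation) else self.separation,
            "repeatability": None if not math.isfinite(self.repeatability) else self.repeatability,
            "fitness": None if not math.isfinite(self.fitness) else self.fitness,
            "converged": self.converged,
            "numerator": sorted(self.spec.numerator) if self.spec else None,
            "denominator": sorted(self.spec.denominator) if self.spec else None,
        }


def _group_slope(fit: LMMFit, group: str) -> float:
    if group == "CU" or not fit.two_group:
        return float(fit.beta[1])
    return float(fit.beta[1] + fit.beta[3])


def sample_size_raw(fit: LMMFit, design: TrialDesign) -> float:
    """Pre-ceiling per-arm sample size; ``inf`` when the group slope vanishes."""
    if not fit.converged:
        return math.inf
    slope = _group_slope(fit, design.group)
    delta = design.pct_change * abs(slope)
    if delta == 0:
        return math.inf
    z = stats.norm.ppf(1 - design.alpha / 2) + stats.norm.ppf(design.power)
    slope_var = fit.cov_re[1, 1] + fit.sigma_eps**2 / design.schedule_ssq
    return 2.0 * z**2 * slope_var / delta**2


def sample_size_estimate(fit: LMMFit, design: TrialDesign) -> float:
    """Per-arm sample size (ceiling of the raw estimate; ``inf`` sentinel)."""
    raw = sample_size_raw(fit, design)
    if not math.isfinite(raw):
        return math.inf
    return float(math.ceil(raw))


def fitness(separation: float, sse: float, sse_exponent: float = 2.0) -> float:
    """Search objective: separation / sse**sse_exponent.

    Invalid candidates (non-finite inputs, infinite SSE) rank below every
    valid candidate via a -inf sentinel.  Negative separation (signal
    decreasing in the impaired group) yields negative fitness.
    """
    if not (math.isfinite(separation) and math.isfinite(sse)) or sse <= 0:
        return INVALID_FITNESS
    return separation / sse**sse_exponent


class CandidateEvaluator:
    """Evaluate ratio specs against one dataset / pipeline / trial design.

    Pivots the dataset once (collapsing bilateral pairs when configured) and
    pre-factorizes the mixed-model design, so evaluating a candidate costs
    one composite computation plus one fast REML fit.  Results are memoized
    by genome key for search loops.
    """

    def __init__(
        self,
        dataset: RegionalDataset,
        meta: RegionMetadata,
        config: CompositeConfig,
        design: TrialDesign,
        sse_exponent: float = 2.0,
    ):
        from .composites import make_bilateral

        self.config = config
        self.design = design
        self.sse_exponent = sse_exponent
        self.meta = meta
        work = make_bilateral(dataset, meta) if config.laterality == "bilateral" else dataset
        self._suv = work.frame.pivot_table(
            index=["subject_id", "scan_time"], columns="region_id", values="suv", sort=True
        )
        self._vol = work.frame.pivot_table(
            index=["subject_id", "scan_time"], columns="region_id", values="volume", sort=True
        )
        self._columns = {rid: i for i, rid in enumerate(self._suv.columns)}
        self._suv_arr = self._suv.to_numpy()
        self._vol_arr = self._vol.to_numpy()
        scans = self._suv.index.to_frame(index=False)
        gm = work.group_map
        subj = scans["subject_id"].to_numpy()
        times = scans["scan_time"].to_numpy(dtype=float)
        dx = np.array([1.0 if gm[s] == "CI" else 0.0 for s in subj])
        mean_t = pd.Series(times).groupby(subj).transform("mean").to_numpy()
        self.model = RandomSlopeModel(subj, times - mean_t, dx)
        self._region_to_unit = (
            meta.region_to_unit("bilateral") if config.laterality == "bilateral" else None
        )
        self.cache: dict[tuple[int, ...], EvaluationResult] = {}
        self.n_evaluations = 0
        self.cache_hits = 0

    # -- composites ---------------------------------------------------------

    def _cols(self, regions: frozenset[str]) -> list[int]:
        if self._region_to_unit is not None:
            units = {self._region_to_unit.get(r, r) for r in regions}
            names = units
        else:
            names = set(regions)
        try:
            return sorted(self._columns[r] for r in names)
        except KeyError as exc:
            raise ValueError(f"region {exc.args[0]!r} absent from dataset") from None

    def series(self, spec: RatioSpec) -> np.ndarray:
        """Per-scan CVR values, in the evaluator's canonical scan order."""
        num, den = self._cols(spec.numerator), self._cols(spec.denominator)
        if self.config.method == "mean_suv":
            nv = self._suv_arr[:, num].mean(axis=1)
            dv = self._suv_arr[:, den].mean(axis=1)
        else:
            nv = (self._suv_arr[:, num] * self._vol_arr[:, num]).sum(axis=1) / self._vol_arr[
                :, num
            ].sum(axis=1)
            dv = (self._suv_arr[:, den] * self._vol_arr[:, den]).sum(axis=1) / self._vol_arr[
                :, den
            ].sum(axis=1)
        if np.any(dv <= 0):
            raise ValueError("non-positive denominator composite")
        return nv / dv

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, spec: RatioSpec) -> EvaluationResult:
        """Metrics for one spec; failures become an invalid-fitness sentinel."""
        self.n_evaluations += 1
        try:
            value = self.series(spec)
            fit = self.model.fit(np.log(value), reml=True)
            if not fit.converged:
                return self._sentinel(spec)
            sep = group_separation(fit) if fit.two_group else math.nan
            rep = repeatability_percent(fit)
            raw = sample_size_raw(fit, self.design)
            sse = math.ceil(raw) if math.isfinite(raw) else math.inf
            return EvaluationResult(
                sse=sse,
                sse_raw=raw,
                separation=sep,
                repeatability=rep,
                fitness=fitness(sep, raw, self.sse_exponent),
                converged=True,
                spec=spec,
                fit=fit,
            )
        except (ValueError, np.linalg.LinAlgError):
            return self._sentinel(spec)

    def evaluate_genome(self, values: np.ndarray, space: SearchSpace) -> EvaluationResult:
        key = tuple(int(v) for v in values)
        hit = self.cache.get(key)
        if hit is not None:
            self.cache_hits += 1
            return hit
        if not space.is_valid(np.asarray(values)):
            raise ValueError("invalid genome reached evaluation")
        result = self.evaluate(space.decode(np.asarray(values)))
        self.cache[key] = result
        return result

    @staticmethod
    def _sentinel(spec: RatioSpec | None) -> EvaluationResult:
        return EvaluationResult(
            sse=math.inf,
            sse_raw=math.inf,
            separation=math.nan,
            repeatability=math.nan,
            fitness=INVALID_FITNESS,
            converged=False,
            spec=spec,
        )


def evaluate_candidate(
    dataset: RegionalDataset,
    spec: RatioSpec,
    config: CompositeConfig,
    design: TrialDesign,
    meta: RegionMetadata | None = None,
    sse_exponent: float = 2.0,
) -> EvaluationResult:
    """One-shot candidate evaluation: CVR -> centred LMM -> metric bundle.

    A single joint two-group model is fitted; the SSE uses the design group's
    slope with the pooled variance components.
    """
    if meta is None:
        if config.laterality == "bilateral":
            raise ValueError("bilateral laterality requires region metadata")
        from .data_io import RegionMetadata as _RM

        rows = [
            {
                "region_id": rid,
                "hemisphere": "midline",
                "bilateral_pair_id": None,
                "braak_stage": None,
                "reference_candidate": False,
                "composites": "",
            }
            for rid in sorted(dataset.regions)
        ]
        meta = _RM.from_frame(pd.DataFrame(rows))
    return CandidateEvaluator(dataset, meta, config, design, sse_exponent).evaluate(spec)
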