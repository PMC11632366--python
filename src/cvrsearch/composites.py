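"""Composite signals, their ratio (CVR), and the search encoding.

A CVR biomarker is the ratio of two composite regional signals,

    CVR = f(numerator regions) / f(denominator regions),

where ``f`` combines regional SUV values either as a simple mean (``mean_suv``)
or volume-weighted (``volume_weighted``).  Any per-scan multiplicative factor
(instrumentation bias, global uptake scaling, or a common SUVR reference)
cancels in the ratio, which is the core rationale for this family of
biomarkers.

Candidate biomarkers are encoded as integer genomes over searchable units
(regions, or bilateral pairs): 0 = numerator, 1 = excluded, 2 = denominator.
Two biological priors restrict the space: early-tau (Braak 1-3) units may not
sit in the denominator, and conventional SUVR reference regions may not sit
in the numerator.  Constraint violations produced by crossover/mutation are
repaired, not rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import RegionalDataset, RegionMetadata

NUMERATOR, EXCLUDED, DENOMINATOR = 0, 1, 2

METHODS = ("mean_suv", "volume_weighted")
LATERALITIES = ("bilateral", "lateral")


@dataclass(frozen=True)
class CompositeConfig:
    """How composite signals are built: combination method and laterality."""

    method: str = "mean_suv"
    laterality: str = "bilateral"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method: {self.method!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality: {self.laterality!r}")

    @property
    def label(self) -> str:
        # mSUV-B / SUV-L style pipeline tag
        m = "mSUV" if self.method == "mean_suv" else "SUV"
        return f"{m}-{'B' if self.laterality == 'bilateral' else 'L'}"


@dataclass(frozen=True)
class RatioSpec:
    """A discovered or literature biomarker: numerator and denominator region sets."""

    numerator: frozenset[str]
    denominator: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "numerator", frozenset(self.numerator))
        object.__setattr__(self, "denominator", frozenset(self.denominator))
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator must be non-empty")
        if self.numerator & self.denominator:
            raise ValueError(
                f"numerator and denominator overlap: {sorted(self.numerator & self.denominator)}"
            )

    def to_json(self, config: CompositeConfig | None = None) -> str:
        payload: dict = {
            "numerator": sorted(self.numerator),
            "denominator": sorted(self.denominator),
        }
        if config is not None:
            payload["method"] = config.method
            payload["laterality"] = config.laterality
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> tuple["RatioSpec", CompositeConfig | None]:
        payload = json.loads(text)
        spec = cls(frozenset(payload["numerator"]), frozenset(payload["denominator"]))
        config = None
        if "method" in payload:
            config = CompositeConfig(payload["method"], payload.get("laterality", "bilateral"))
        return spec, config


# ---------------------------------------------------------------------------
# composite arithmetic


def make_bilateral(dataset: RegionalDataset, meta: RegionMetadata) -> RegionalDataset:
    """Collapse left/right pairs to single units.

    The collapsed SUV is the volume-weighted hemispheric average
    ``(suv_L*vol_L + suv_R*vol_R) / (vol_L + vol_R)`` with summed volume, so
    the unit behaves like the whole bilateral structure.  Midline and unpaired
    regions pass through unchanged.
    """
    unit_of = meta.region_to_unit("bilateral")
    unknown = dataset.regions - set(unit_of)
    if unknown:
        raise ValueError(f"dataset region(s) missing from metadata: {sorted(unknown)}")
    expected = {
        uid: members
        for uid, members in meta.units("bilateral")
        if set(members) & dataset.regions
    }
    for uid, members in expected.items():
        absent = set(members) - dataset.regions
        if absent:
            raise ValueError(
                f"bilateral pair {uid!r}: hemisphere region(s) {sorted(absent)} absent from dataset"
            )
    df = dataset.frame.copy()
    df["unit"] = df["region_id"].map(unit_of)
    df["sv"] = df["suv"] * df["volume"]
    agg = (
        df.groupby(["subject_id", "group", "scan_time", "unit"], sort=False)
        .agg(sv=("sv", "sum"), volume=("volume", "sum"), n=("suv", "size"))
        .reset_index()
    )
    sizes = {uid: len(m) for uid, m in expected.items()}
    bad = agg[agg["n"] != agg["unit"].map(sizes)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"pair {row['unit']!r} incomplete at scan ({row['subject_id']}, {row['scan_time']})"
        )
    agg["suv"] = agg["sv"] / agg["volume"]
    agg = agg.rename(columns={"unit": "region_id"})[
        ["subject_id", "group", "scan_time", "region_id", "suv", "volume"]
    ]
    return RegionalDataset.from_frame(agg)


def composite_value(scan: pd.DataFrame, regions: Iterable[str], method: str) -> float:
    """Combine one scan's regional records over ``regions`` into one signal.

    ``scan`` holds columns region_id, suv, volume for a single scan.
    """
    regions = set(regions)
    if not regions:
        raise ValueError("empty region set")
    sub = scan[scan["region_id"].isin(regions)]
    if len(sub) != len(regions):
        raise ValueError(f"region(s) missing at scan: {sorted(regions - set(sub['region_id']))}")
    if method == "mean_suv":
        return float(sub["suv"].mean())
    if method == "volume_weighted":
        return float((sub["suv"] * sub["volume"]).sum() / sub["volume"].sum())
    raise ValueError(f"unknown method: {method!r}")


def compute_cvr(
    dataset: RegionalDataset,
    spec: RatioSpec,
    config: CompositeConfig,
    meta: RegionMetadata | None = None,
) -> pd.DataFrame:
    """Per-scan CVR series for ``spec`` under ``config``.

    Returns a frame with columns subject_id, group, scan_time, value,
    log_value (natural log).  In bilateral mode the dataset is collapsed
    first (``meta`` required) and the spec's region ids are mapped onto
    bilateral units; each unit then contributes a single term to a mean-SUV
    composite.
    """
    work = dataset
    num, den = set(spec.numerator), set(spec.denominator)
    if config.laterality == "bilateral":
        if meta is None:
            raise ValueError("bilateral laterality requires region metadata")
        work = make_bilateral(dataset, meta)
        num = _to_units(num, meta)
        den = _to_units(den, meta)

    missing = (num | den) - work.regions
    if missing:
        raise ValueError(f"spec region(s) absent from dataset: {sorted(missing)}")

    suv = work.frame.pivot_table(
        index=["subject_id", "scan_time"], columns="region_id", values="suv", sort=True
    )
    vol = work.frame.pivot_table(
        index=["subject_id", "scan_time"], columns="region_id", values="volume", sort=True
    )
    numv = _composite_array(suv, vol, sorted(num), config.method)
    denv = _composite_array(suv, vol, sorted(den), config.method)
    if np.any(denv <= 0) or np.any(~np.isfinite(denv)):
        raise ValueError("non-positive denominator composite: corrupt input")
    value = numv / denv
    out = suv.index.to_frame(index=False)
    gm = work.group_map
    out["group"] = out["subject_id"].map(gm)
    out["value"] = value
    out["log_value"] = np.log(value)
    return out[["subject_id", "group", "scan_time", "value", "log_value"]]


def _composite_array(
    suv: pd.DataFrame, vol: pd.DataFrame, regions: Sequence[str], method: str
) -> np.ndarray:
    s = suv[list(regions)].to_numpy()
    if method == "mean_suv":
        return s.mean(axis=1)
    v = vol[list(regions)].to_numpy()
    return (s * v).sum(axis=1) / v.sum(axis=1)


def _to_units(regions: set[str], meta: RegionMetadata) -> set[str]:
    unit_of = meta.region_to_unit("bilateral")
    members: dict[str, set[str]] = {}
    for uid, mem in meta.units("bilateral"):
        members[uid] = set(mem)
    units: set[str] = set()
    for rid in regions:
        if rid not in unit_of:
            raise ValueError(f"region {rid!r} missing from metadata")
        units.add(unit_of[rid])
    for uid in units:
        partial = members[uid] - regions
        if partial:
            raise ValueError(
                f"bilateral unit {uid!r} only partially included; missing {sorted(partial)}"
            )
    return units


# ---------------------------------------------------------------------------
# genome encoding


class InfeasibleConstraints(ValueError):
    """The constraint set leaves one ratio side without any eligible unit."""


@dataclass(frozen=True)
class SearchSpace:
    """Searchable units with their constraint masks and optional pins.

    ``numerator_ok[i]`` is False when unit i contains a conventional reference
    region (kept out of the numerator); ``denominator_ok[i]`` is False when it
    contains an early-tau (Braak 1-3) region.  ``frozen`` pins gene values for
    restricted-search runs.
    """

    units: tuple[str, ...]
    unit_regions: tuple[tuple[str, ...], ...]
    numerator_ok: np.ndarray
    denominator_ok: np.ndarray
    frozen: Mapping[int, int] = field(default_factory=dict)

    @classmethod
    def from_metadata(
        cls,
        meta: RegionMetadata,
        laterality: str,
        frozen_assignments: Mapping[str, int] | None = None,
        restrict_to: Iterable[str] | None = None,
    ) -> "SearchSpace":
        units = meta.units(laterality)
        if restrict_to is not None:
            allowed = set(restrict_to)
            units = [(uid, mem) for uid, mem in units if uid in allowed]
        ids = tuple(uid for uid, _ in units)
        members = tuple(mem for _, mem in units)
        num_ok = np.array(
            [not any(meta.is_reference_candidate(r) for r in mem) for mem in members], dtype=bool
        )
        den_ok = np.array(
            [not any((meta.braak_stage(r) or 0) in (1, 2, 3) for r in mem) for mem in members],
            dtype=bool,
        )
        frozen: dict[int, int] = {}
        if frozen_assignments:
            index = {uid: i for i, uid in enumerate(ids)}
            for uid, value in frozen_assignments.items():
                if uid not in index:
                    raise ValueError(f"frozen assignment for unknown unit {uid!r}")
                if value not in (NUMERATOR, EXCLUDED, DENOMINATOR):
                    raise ValueError(f"frozen value for {uid!r} must be 0, 1 or 2")
                i = index[uid]
                if value == NUMERATOR and not num_ok[i]:
                    raise InfeasibleConstraints(f"unit {uid!r} pinned to numerator but ineligible")
                if value == DENOMINATOR and not den_ok[i]:
                    raise InfeasibleConstraints(f"unit {uid!r} pinned to denominator but ineligible")
                frozen[i] = value
        space = cls(ids, members, num_ok, den_ok, frozen)
        space._check_feasible()
        return space

    def _check_feasible(self) -> None:
        if not self._side_feasible(NUMERATOR):
            raise InfeasibleConstraints("no eligible unit for the numerator")
        if not self._side_feasible(DENOMINATOR):
            raise InfeasibleConstraints("no eligible unit for the denominator")

    def _side_feasible(self, side: int) -> bool:
        ok = self.numerator_ok if side == NUMERATOR else self.denominator_ok
        if any(v == side for v in self.frozen.values()):
            return True
        free = [i for i in range(len(self.units)) if i not in self.frozen]
        return any(ok[i] for i in free)

    def __len__(self) -> int:
        return len(self.units)

    @property
    def frozen_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.units), dtype=bool)
        for i in self.frozen:
            mask[i] = True
        return mask

    def is_valid(self, values: np.ndarray) -> bool:
        values = np.asarray(values)
        if values.shape != (len(self.units),):
            return False
        if not np.isin(values, (0, 1, 2)).all():
            return False
        if not (values == NUMERATOR).any() or not (values == DENOMINATOR).any():
            return False
        if ((values == NUMERATOR) & ~self.numerator_ok).any():
            return False
        if ((values == DENOMINATOR) & ~self.denominator_ok).any():
            return False
        return all(values[i] == v for i, v in self.frozen.items())

    def random_genome(self, rng: np.random.Generator) -> np.ndarray:
        return self.repair(rng.integers(0, 3, size=len(self.units)), rng)

    def repair(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Map an arbitrary {0,1,2} vector to the nearest valid genome.

        Ineligible assignments are excluded; pinned genes are restored; an
        emptied side receives one uniformly chosen eligible free unit.
        """
        g = np.asarray(values, dtype=np.int8).copy()
        if g.shape != (len(self.units),):
            raise ValueError("genome length mismatch")
        g[(g == DENOMINATOR) & ~self.denominator_ok] = EXCLUDED
        g[(g == NUMERATOR) & ~self.numerator_ok] = EXCLUDED
        for i, v in self.frozen.items():
            g[i] = v
        free = ~self.frozen_mask
        for side, ok in ((NUMERATOR, self.numerator_ok), (DENOMINATOR, self.denominator_ok)):
            if not (g == side).any():
                cand = np.flatnonzero(free & ok & (g == EXCLUDED))
                if cand.size == 0:
                    other = NUMERATOR + DENOMINATOR - side
                    # may steal from the other side only if it keeps a member
                    cand = np.flatnonzero(
                        free & ok & ~((g == other) & ((g == other).sum() == 1))
                    )
                if cand.size == 0:
                    raise InfeasibleConstraints(
                        f"no eligible unit available for side {side}"
                    )
                g[int(rng.choice(cand))] = side
        if not self.is_valid(g):
            raise InfeasibleConstraints("repair could not produce a valid genome")
        return g

    def decode(self, values: np.ndarray) -> RatioSpec:
        values = np.asarray(values)
        if not self.is_valid(values):
            raise ValueError("invalid genome: violates encoding invariants")
        num: set[str] = set()
        den: set[str] = set()
        for i, v in enumerate(values):
            if v == NUMERATOR:
                num.update(self.unit_regions[i])
            elif v == DENOMINATOR:
                den.update(self.unit_regions[i])
        return RatioSpec(frozenset(num), frozenset(den))


def decode_genome(values: np.ndarray, space: SearchSpace) -> RatioSpec:
    """Decode a valid {0,1,2} genome into its numerator/denominator region sets."""
    return space.decode(values)


def repair_genome(values: np.ndarray, space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Repair an arbitrary {0,1,2} vector into a constraint-satisfying genome."""
    return space.repair(values, rng)
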