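"""Reading, validation and reshaping of longitudinal regional PET tables.

Datasets are long-format tables of regional tracer uptake (SUV) and regional
volume per subject visit, with a cognitive-group label per subject.  This
module enforces the contracts every downstream computation relies on:

* each (subject, scan_time) pair carries one identical region panel;
* every retained subject has at least two distinct scan times;
* the cognitive group is constant within a subject;
* SUV and volume are strictly positive.

Rows or subjects that violate a contract are dropped with a logged reason;
no science happens here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("CU", "CI")
LONG_COLUMNS = ("subject_id", "group", "scan_time", "region_id", "suv", "volume")
METADATA_COLUMNS = (
    "region_id",
    "hemisphere",
    "bilateral_pair_id",
    "braak_stage",
    "reference_candidate",
    "composites",
)
HEMISPHERES = ("left", "right", "midline")


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


@dataclass(frozen=True)
class RegionalDataset:
    """Validated long-format table of (subject, visit, region) observations.

    ``frame`` has columns ``subject_id, group, scan_time, region_id, suv,
    volume`` in canonical sort order (subject, scan_time, region_id).
    """

    frame: pd.DataFrame

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionalDataset":
        """Validate and filter a raw long-format frame.

        Invalid rows (missing or non-positive suv/volume) are dropped, then
        subjects that violate the dataset invariants are dropped, each with a
        logged reason.  Raises :class:`FormatError` if required columns are
        missing and ``ValueError`` if nothing survives filtering.
        """
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = frame.loc[:, list(LONG_COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["region_id"] = df["region_id"].astype(str)
        df["group"] = df["group"].astype(str).str.upper()
        df["scan_time"] = pd.to_numeric(df["scan_time"], errors="coerce")
        df["suv"] = pd.to_numeric(df["suv"], errors="coerce")
        df["volume"] = pd.to_numeric(df["volume"], errors="coerce")

        n0 = len(df)
        bad = (
            df["suv"].isna()
            | df["volume"].isna()
            | df["scan_time"].isna()
            | (df["suv"] <= 0)
            | (df["volume"] <= 0)
        )
        if bad.any():
            logger.warning("dropping %d row(s) with missing or non-positive suv/volume", int(bad.sum()))
            df = df.loc[~bad]
        if df.empty:
            raise ValueError(f"empty dataset after filtering ({n0} input rows)")

        unknown = set(df["group"]) - set(GROUPS)
        if unknown:
            raise FormatError(f"unknown group label(s): {sorted(unknown)}; expected CU/CI")

        keep = []
        for sid, sub in df.groupby("subject_id", sort=True):
            grp = set(sub["group"])
            if len(grp) > 1:
                # diagnosis = maximum impairment across visits
                logger.warning("subject %s has mixed group labels; relabelled CI", sid)
                sub = sub.assign(group="CI")
            panels = sub.groupby("scan_time")["region_id"].apply(frozenset)
            if panels.nunique() > 1:
                logger.warning("subject %s dropped: inconsistent region panel across scans", sid)
                continue
            dup = sub.duplicated(subset=["scan_time", "region_id"])
            if dup.any():
                logger.warning("subject %s dropped: duplicate (scan_time, region) rows", sid)
                continue
            if sub["scan_time"].nunique() < 2:
                logger.warning("subject %s dropped: fewer than two distinct scan times", sid)
                continue
            keep.append(sub)
        if not keep:
            raise ValueError("empty dataset after filtering: no subject satisfies the invariants")
        df = pd.concat(keep, ignore_index=True)

        # one shared panel across subjects: required so every composite is
        # computable on every scan
        panels = df.groupby(["subject_id", "scan_time"])["region_id"].apply(frozenset)
        modal = panels.mode().iloc[0]
        off = panels[panels != modal]
        if len(off):
            bad_subjects = sorted({sid for sid, _ in off.index})
            logger.warning(
                "dropping %d subject(s) whose region panel differs from the modal panel: %s",
                len(bad_subjects),
                ", ".join(bad_subjects[:10]),
            )
            df = df.loc[~df["subject_id"].isin(bad_subjects)]
        if df.empty:
            raise ValueError("empty dataset after filtering: no common region panel")

        df = df.sort_values(["subject_id", "scan_time", "region_id"], kind="mergesort")
        return cls(df.reset_index(drop=True))

    # -- accessors ----------------------------------------------------------

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.frame["subject_id"].unique())

    @property
    def regions(self) -> frozenset[str]:
        return frozenset(self.frame["region_id"].unique())

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def group_map(self) -> dict[str, str]:
        sub = self.frame.drop_duplicates("subject_id")
        return dict(zip(sub["subject_id"], sub["group"]))

    def scans(self) -> pd.DataFrame:
        """Unique (subject_id, group, scan_time) rows, canonical order."""
        return self.frame.drop_duplicates(["subject_id", "scan_time"])[
            ["subject_id", "group", "scan_time"]
        ].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        """Write the canonical long CSV representation (round-trip exact)."""
        self.frame.to_csv(path, index=False, float_format="%.17g")

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, RegionalDataset):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))


@dataclass(frozen=True)
class RegionMetadata:
    """Region registry: hemisphere, bilateral pairing, Braak stage,
    reference-candidate flag and named-composite memberships.

    ``table`` is indexed by ``region_id``; ``composites`` maps a composite
    label to the frozenset of member region ids.
    """

    table: pd.DataFrame
    composites: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionMetadata":
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required metadata column(s): {', '.join(missing)}")
        df = frame.loc[:, list(METADATA_COLUMNS)].copy()
        df["region_id"] = df["region_id"].astype(str)
        if df["region_id"].duplicated().any():
            dups = sorted(df.loc[df["region_id"].duplicated(), "region_id"])
            raise FormatError(f"duplicate region_id(s): {dups}")
        df["hemisphere"] = df["hemisphere"].astype(str).str.lower()
        unknown = set(df["hemisphere"]) - set(HEMISPHERES)
        if unknown:
            raise FormatError(f"unknown hemisphere value(s): {sorted(unknown)}")

        def _pair(v: object) -> object:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            s = str(v).strip()
            return None if s.lower() in ("", "none", "nan") else s

        def _braak(v: object) -> object:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            s = str(v).strip().lower()
            if s in ("", "none", "nan"):
                return None
            stage = int(float(s))
            if not 1 <= stage <= 6:
                raise FormatError(f"braak_stage out of range 1..6: {v!r}")
            return stage

        def _bool(v: object) -> bool:
            if isinstance(v, (bool, np.bool_)):
                return bool(v)
            return str(v).strip().lower() in ("true", "1", "yes")

        def _labels(v: object) -> tuple[str, ...]:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return ()
            return tuple(s.strip() for s in str(v).split(";") if s.strip())

        df["bilateral_pair_id"] = df["bilateral_pair_id"].map(_pair).astype(object)
        df["bilateral_pair_id"] = df["bilateral_pair_id"].where(
            df["bilateral_pair_id"].notna(), None
        )
        df["braak_stage"] = df["braak_stage"].map(_braak).astype(object)
        df["braak_stage"] = df["braak_stage"].where(df["braak_stage"].notna(), None)
        df["reference_candidate"] = df["reference_candidate"].map(_bool)
        df["composites"] = df["composites"].map(_labels)

        midline_paired = df[(df["hemisphere"] == "midline") & df["bilateral_pair_id"].notna()]
        if len(midline_paired):
            raise FormatError(
                f"midline region(s) with a bilateral pair: {sorted(midline_paired['region_id'])}"
            )
        for pid, grp in df[df["bilateral_pair_id"].notna()].groupby("bilateral_pair_id"):
            hemis = sorted(grp["hemisphere"])
            if len(grp) != 2 or hemis != ["left", "right"]:
                raise FormatError(
                    f"asymmetric bilateral pairing for pair {pid!r}: "
                    f"regions {sorted(grp['region_id'])} (hemispheres {hemis})"
                )

        comps: dict[str, set[str]] = {}
        for rid, labels in zip(df["region_id"], df["composites"]):
            for lab in labels:
                comps.setdefault(lab, set()).add(rid)
        table = df.set_index("region_id", drop=False)
        return cls(table, {k: frozenset(v) for k, v in comps.items()})

    # -- accessors ----------------------------------------------------------

    @property
    def regions(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def composite_members(self, label: str) -> frozenset[str]:
        return self.composites.get(label, frozenset())

    def braak_stage(self, region_id: str) -> int | None:
        return self.table.at[region_id, "braak_stage"]

    def is_reference_candidate(self, region_id: str) -> bool:
        return bool(self.table.at[region_id, "reference_candidate"])

    def pair_of(self, region_id: str) -> str | None:
        return self.table.at[region_id, "bilateral_pair_id"]

    def units(self, laterality: str) -> list[tuple[str, tuple[str, ...]]]:
        """Searchable units: (unit_id, member region ids), sorted by unit id.

        ``lateral``: every region is its own unit.  ``bilateral``: left/right
        pairs collapse to their pair id; midline (and unpaired) regions stand
        alone.
        """
        if laterality == "lateral":
            return [(rid, (rid,)) for rid in sorted(self.table.index)]
        if laterality != "bilateral":
            raise ValueError(f"unknown laterality: {laterality!r}")
        units: dict[str, list[str]] = {}
        for rid, pid in zip(self.table["region_id"], self.table["bilateral_pair_id"]):
            units.setdefault(pid if pid is not None else rid, []).append(rid)
        return [(uid, tuple(sorted(members))) for uid, members in sorted(units.items())]

    def region_to_unit(self, laterality: str) -> dict[str, str]:
        return {rid: uid for uid, members in self.units(laterality) for rid in members}

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["bilateral_pair_id"] = out["bilateral_pair_id"].map(lambda v: v or "none")
        out["braak_stage"] = out["braak_stage"].map(lambda v: "none" if v is None else int(v))
        out["composites"] = out["composites"].map(";".join)
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class ValidationReport:
    """Result of cross-checking a dataset against region metadata."""

    fatal: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.fatal

    def to_json(self) -> str:
        return json.dumps({"fatal": list(self.fatal), "warnings": list(self.warnings)}, indent=2)

    def raise_if_fatal(self) -> None:
        if self.fatal:
            raise ValueError("cross-validation failed: " + "; ".join(self.fatal))


def load_regional_table(path: str | Path, format: str = "long") -> RegionalDataset:
    """Read a regional feature CSV in ``long`` or ``wide`` layout.

    Wide layout carries one ``suv_<region>`` / ``vol_<region>`` column pair
    per region next to ``subject_id, group, scan_time`` and is melted to the
    canonical long form.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, float_precision="round_trip")
    if format == "long":
        return RegionalDataset.from_frame(raw)
    if format != "wide":
        raise ValueError(f"unknown format: {format!r}")

    id_cols = ["subject_id", "group", "scan_time"]
    missing = [c for c in id_cols if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    suv_cols = [c for c in raw.columns if c.startswith("suv_")]
    if not suv_cols:
        raise FormatError("wide format requires suv_<region> columns")
    pieces = []
    for sc in suv_cols:
        region = sc[len("suv_"):]
        vc = f"vol_{region}"
        if vc not in raw.columns:
            raise FormatError(f"missing required column: {vc}")
        part = raw[id_cols].copy()
        part["region_id"] = region
        part["suv"] = raw[sc]
        part["volume"] = raw[vc]
        pieces.append(part)
    return RegionalDataset.from_frame(pd.concat(pieces, ignore_index=True))


def load_region_metadata(path: str | Path) -> RegionMetadata:
    """Read a region-metadata CSV (one row per region; ';'-separated composites)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return RegionMetadata.from_frame(pd.read_csv(path))


def default_region_metadata() -> RegionMetadata:
    """The packaged Desikan-Killiany-style region registry."""
    from importlib.resources import files

    with files("cvrsearch.data").joinpath("dk_regions.csv").open("r") as fh:
        return RegionMetadata.from_frame(pd.read_csv(fh))


def cross_validate(dataset: RegionalDataset, meta: RegionMetadata) -> ValidationReport:
    """Check dataset/metadata consistency.

    Dataset regions absent from the metadata are fatal (they cannot be
    constrained or composed); metadata regions absent from the dataset and
    named composites with incomplete coverage are warnings.
    """
    fatal = [
        f"dataset region {rid!r} missing from metadata"
        for rid in sorted(dataset.regions - meta.regions)
    ]
    warnings = [
        f"metadata region {rid!r} missing from dataset"
        for rid in sorted(meta.regions - dataset.regions)
    ]
    for label in sorted(meta.composites):
        gap = meta.composite_members(label) - dataset.regions
        if gap:
            warnings.append(
                f"composite {label!r} unusable: member(s) absent from dataset: {sorted(gap)}"
            )
    return ValidationReport(tuple(fatal), tuple(warnings))
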