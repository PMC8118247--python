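"""Data model and CSV input/output for stomach-content and stable-isotope tables.

The on-disk layout mirrors how diet studies typically deposit their raw data:
one CSV of per-fish prey *counts* (one row per fish, one column per prey
category), a parallel CSV of per-fish prey *weights* in grams, an optional
per-fish metadata CSV (location, year, month, longitude, depth, length, sex),
and a per-fish isotope CSV (δ13C, δ15N, %C, %N, C:N).

Prey taxonomies have two levels: the *lowest* identifiable taxon (e.g.
Salpidae, *Pyrosoma* spp.) and a *generalized* level of 8 broad categories
(Squids, Crustaceans, Amphipods, Euphausiids, Tunicates, Teleosts, Rockfishes,
Other).  Aggregation from lowest to generalized conserves per-fish totals
exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger("dietkit")

__all__ = [
    "PreyCategory",
    "StomachRecord",
    "DietDataset",
    "IsotopeRecord",
    "GENERALIZED_CODES",
    "default_taxonomy",
    "read_stomach_tables",
    "write_stomach_tables",
    "aggregate_to_generalized",
    "apply_exclusions",
    "read_isotope_table",
    "write_isotope_table",
    "isotope_records_to_frame",
]

#: Canonical order of the 8 generalized prey categories.
GENERALIZED_CODES = (
    "Squids",
    "Crustaceans",
    "Amphipods",
    "Euphausiids",
    "Tunicates",
    "Teleosts",
    "Rockfishes",
    "Other",
)

OTHER_CODE = "Other"

LOCATIONS = ("COR", "FAR", "HMB")


class FormatError(ValueError):
    """A table does not have the expected columns or layout."""


class ValidationError(ValueError):
    """A table parsed but contains invalid values."""


@dataclass(frozen=True)
class PreyCategory:
    """One prey taxon at either taxonomic level.

    ``trophic_level`` is the unitless trophic level of the prey itself (≥ 1),
    used when estimating the predator's trophic level from diet proportions;
    it may be left unset for categories not involved in that calculation.
    """

    code: str
    label: str = ""
    level: Literal["generalized", "lowest"] = "generalized"
    parent: str | None = None
    trophic_level: float | None = None

    def __post_init__(self) -> None:
        if self.level == "lowest" and not self.parent:
            raise ValidationError(f"lowest-level category {self.code!r} needs a generalized parent")
        if self.trophic_level is not None and self.trophic_level < 1:
            raise ValidationError(f"trophic_level of {self.code!r} must be >= 1")


def default_taxonomy() -> list[PreyCategory]:
    """Two-level taxonomy for the central-California rockfish prey spectrum.

    Lowest-level taxa map onto the 8 generalized categories; rare taxa
    (gastropods, polychaetes, isopods) fold into ``Other``.
    """
    gen = [PreyCategory(c, c, "generalized") for c in GENERALIZED_CODES]
    lowest = [
        ("Doryteuthis_opalescens", "Squids"),
        ("Crangon", "Crustaceans"),
        ("Unid_crustaceans", "Crustaceans"),
        ("Amphipoda", "Amphipods"),
        ("Hyperiidea", "Amphipods"),
        ("Vibilia", "Amphipods"),
        ("Caprellidae", "Amphipods"),
        ("Euphausiacea", "Euphausiids"),
        ("Salpidae", "Tunicates"),
        ("Pyrosoma", "Tunicates"),
        ("Thetys_vagina", "Tunicates"),
        ("Unid_fishes", "Teleosts"),
        ("Citharichthys_sordidus", "Teleosts"),
        ("Sebastes", "Rockfishes"),
        ("Sebastes_jordani", "Rockfishes"),
        ("Isopoda", "Other"),
        ("Polychaeta", "Other"),
        ("Pterotracheoida", "Other"),
        ("Gastropoda", "Other"),
    ]
    return gen + [PreyCategory(c, c.replace("_", " "), "lowest", parent=p) for c, p in lowest]


@dataclass
class StomachRecord:
    """Prey composition of a single stomach plus fish-level metadata.

    ``counts`` and ``weights_g`` share the same key set (prey codes); weights
    are grams at 0.001 g resolution.  Metadata fields may be None when the
    metadata table is absent.
    """

    fish_id: str
    counts: dict[str, float] = field(default_factory=dict)
    weights_g: dict[str, float] = field(default_factory=dict)
    location: str | None = None
    year: int | None = None
    month: int | None = None
    longitude: float | None = None
    depth_m: float | None = None
    total_length_cm: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if set(self.counts) != set(self.weights_g):
            raise ValidationError(f"fish {self.fish_id}: counts and weights key sets differ")
        for prey, c in self.counts.items():
            if c < 0 or self.weights_g[prey] < 0:
                raise ValidationError(f"fish {self.fish_id}: negative count/weight for {prey}")
        if self.depth_m is not None and not (10 <= self.depth_m <= 500):
            warnings.warn(
                f"fish {self.fish_id}: depth {self.depth_m} m outside the plausible shelf range",
                stacklevel=2,
            )

    @property
    def total_count(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def total_weight_g(self) -> float:
        return float(sum(self.weights_g.values()))

    def nonzero_prey(self) -> set[str]:
        """Prey codes present by count or by weight (digested items may lack one)."""
        return {
            p for p in self.counts if self.counts[p] > 0 or self.weights_g[p] > 0
        }

    @property
    def is_empty(self) -> bool:
        return not self.nonzero_prey()


@dataclass
class IsotopeRecord:
    """Per-fish muscle-tissue stable-isotope measurement (δ values in ‰)."""

    fish_id: str
    d13C: float
    d15N: float
    pctC: float | None = None
    pctN: float | None = None
    cn_ratio: float | None = None
    location: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if self.cn_ratio is None and self.pctC is not None and self.pctN is not None:
            self.cn_ratio = self.pctC / self.pctN
        if self.cn_ratio is not None:
            if self.cn_ratio <= 0:
                raise ValidationError(f"fish {self.fish_id}: C:N ratio must be positive")
            if self.pctC is not None and self.pctN is not None:
                implied = self.pctC / self.pctN
                if abs(implied - self.cn_ratio) > 0.05:
                    warnings.warn(
                        f"fish {self.fish_id}: C:N {self.cn_ratio:.3f} inconsistent with "
                        f"%C/%N {implied:.3f}",
                        stacklevel=2,
                    )

    @property
    def group(self) -> tuple[str | None, int | None]:
        return (self.location, self.year)


@dataclass
class DietDataset:
    """A validated collection of stomach records with its prey taxonomy.

    ``exclusion_flags`` maps fish_id to a subset of
    ``{"empty", "other_only", "other_partial"}``.
    """

    records: list[StomachRecord]
    taxonomy: list[PreyCategory]
    exclusion_flags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.fish_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate fish_id in dataset")
        if not self.exclusion_flags:
            self.exclusion_flags = {r.fish_id: self._flags_for(r) for r in self.records}

    @staticmethod
    def _flags_for(rec: StomachRecord) -> set[str]:
        flags: set[str] = set()
        prey = rec.nonzero_prey()
        if not prey:
            flags.add("empty")
        elif prey <= {OTHER_CODE}:
            flags.add("other_only")
        elif OTHER_CODE in prey:
            flags.add("other_partial")
        return flags

    # -- basic views -------------------------------------------------------

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_full(self) -> int:
        """Number of stomachs with at least one identifiable prey item."""
        return sum(not r.is_empty for r in self.records)

    @property
    def prey_codes(self) -> list[str]:
        return [c.code for c in self.taxonomy_for_level(self.level)]

    @property
    def level(self) -> str:
        """Taxonomic level the records are keyed at (generalized if no lowest keys)."""
        lowest = {c.code for c in self.taxonomy if c.level == "lowest"}
        used = set().union(*(set(r.counts) for r in self.records)) if self.records else set()
        return "lowest" if used & lowest else "generalized"

    def taxonomy_for_level(self, level: str) -> list[PreyCategory]:
        return [c for c in self.taxonomy if c.level == level]

    def full_records(self) -> list[StomachRecord]:
        return [r for r in self.records if not r.is_empty]

    def to_frames(self, full_only: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (counts, weights) DataFrames, fish_id index × prey columns."""
        recs = self.full_records() if full_only else self.records
        cols = self.prey_codes
        counts = pd.DataFrame(
            [[r.counts.get(c, 0.0) for c in cols] for r in recs],
            index=[r.fish_id for r in recs],
            columns=cols,
            dtype=float,
        )
        weights = pd.DataFrame(
            [[r.weights_g.get(c, 0.0) for c in cols] for r in recs],
            index=[r.fish_id for r in recs],
            columns=cols,
            dtype=float,
        )
        counts.index.name = weights.index.name = "fish_id"
        return counts, weights

    def metadata_frame(self, full_only: bool = False) -> pd.DataFrame:
        recs = self.full_records() if full_only else self.records
        return pd.DataFrame(
            {
                "fish_id": [r.fish_id for r in recs],
                "location": [r.location for r in recs],
                "year": [r.year for r in recs],
                "month": [r.month for r in recs],
                "longitude": [r.longitude for r in recs],
                "depth_m": [r.depth_m for r in recs],
                "total_length_cm": [r.total_length_cm for r in recs],
                "sex": [r.sex for r in recs],
            }
        ).set_index("fish_id")

    def strata(self, keys: Sequence[str] = ("location", "year")) -> dict[tuple, "DietDataset"]:
        """Split into per-stratum datasets on metadata keys (e.g. location, year)."""
        out: dict[tuple, DietDataset] = {}
        for rec in self.records:
            k = tuple(getattr(rec, key) for key in keys)
            out.setdefault(k, []).append(rec)  # type: ignore[arg-type]
        return {
            k: DietDataset(records=v, taxonomy=list(self.taxonomy))  # type: ignore[arg-type]
            for k, v in out.items()
        }


# ---------------------------------------------------------------------------
# readers / writers


def _read_prey_table(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "fish_id" not in df.columns:
        raise FormatError(f"{path}: missing fish_id column in {what} table")
    df = df.set_index(df["fish_id"].astype(str)).drop(columns="fish_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise ValidationError(f"{path}: non-numeric {what} for fish {bad}, prey {col}")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise ValidationError(f"{path}: negative {what} for fish {bad}, prey {col}")
        df[col] = vals.astype(float)
    return df


def read_stomach_tables(
    counts_path: str | Path,
    weights_path: str | Path,
    metadata_path: str | Path | None = None,
    taxonomy: list[PreyCategory] | None = None,
) -> DietDataset:
    """Read per-fish count and weight CSVs (plus optional metadata) into a dataset.

    Both prey tables must carry a ``fish_id`` column and one column per prey
    category; they are joined on fish_id.  Fish present in only one of the two
    tables are reported and get zeros on the missing side.  All-zero records
    are flagged ``empty``.
    """
    counts = _read_prey_table(counts_path, "count")
    weights = _read_prey_table(weights_path, "weight")

    only_c = set(counts.index) - set(weights.index)
    only_w = set(weights.index) - set(counts.index)
    if only_c or only_w:
        logger.warning(
            "unmatched fish_ids: %d only in counts, %d only in weights", len(only_c), len(only_w)
        )
    all_ids = list(counts.index) + [i for i in weights.index if i not in set(counts.index)]
    all_prey = list(counts.columns) + [c for c in weights.columns if c not in set(counts.columns)]
    counts = counts.reindex(index=all_ids, columns=all_prey, fill_value=0.0)
    weights = weights.reindex(index=all_ids, columns=all_prey, fill_value=0.0)

    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        if "fish_id" not in meta.columns:
            raise FormatError(f"{metadata_path}: missing fish_id column in metadata table")
        meta = meta.set_index(meta["fish_id"].astype(str)).drop(columns="fish_id")

    if taxonomy is None:
        taxonomy = _infer_taxonomy(all_prey)

    records = []
    for fid in all_ids:
        kwargs: dict = {}
        if meta is not None and fid in meta.index:
            row = meta.loc[fid]
            kwargs = {
                "location": row.get("location"),
                "year": int(row["year"]) if pd.notna(row.get("year")) else None,
                "month": int(row["month"]) if pd.notna(row.get("month")) else None,
                "longitude": float(row["longitude"]) if pd.notna(row.get("longitude")) else None,
                "depth_m": float(row["depth_m"]) if pd.notna(row.get("depth_m")) else None,
                "total_length_cm": (
                    float(row["total_length_cm"]) if pd.notna(row.get("total_length_cm")) else None
                ),
                "sex": row.get("sex"),
            }
        records.append(
            StomachRecord(
                fish_id=fid,
                counts=dict(zip(all_prey, counts.loc[fid])),
                weights_g=dict(zip(all_prey, weights.loc[fid])),
                **kwargs,
            )
        )
    ds = DietDataset(records=records, taxonomy=taxonomy)
    n_empty = ds.n_total - ds.n_full
    logger.info("read %d stomachs (%d full, %d empty)", ds.n_total, ds.n_full, n_empty)
    return ds


def _infer_taxonomy(prey_codes: Iterable[str]) -> list[PreyCategory]:
    """Use the shipped taxonomy for known codes; unknown codes become generalized."""
    known = {c.code: c for c in default_taxonomy()}
    out: dict[str, PreyCategory] = {}
    for code in prey_codes:
        if code in known:
            cat = known[code]
            out[code] = cat
            if cat.parent and cat.parent not in out:
                out[cat.parent] = known[cat.parent]
        else:
            out[code] = PreyCategory(code, code, "generalized")
    return list(out.values())


def write_stomach_tables(
    dataset: DietDataset,
    counts_path: str | Path,
    weights_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Inverse of :func:`read_stomach_tables`; weights written at 0.001 g precision."""
    counts, weights = dataset.to_frames()
    counts.to_csv(counts_path, float_format="%g")
    weights.round(3).to_csv(weights_path, float_format="%.3f")
    if metadata_path is not None:
        dataset.metadata_frame().to_csv(metadata_path)


def aggregate_to_generalized(dataset: DietDataset) -> DietDataset:
    """Collapse lowest-level prey categories onto their generalized parents.

    Per-record count and weight totals are conserved exactly (pure summation).
    Idempotent on already-generalized datasets.
    """
    if dataset.level == "generalized":
        return dataset
    parent: dict[str, str] = {}
    for cat in dataset.taxonomy:
        if cat.level == "lowest":
            if cat.parent is None or cat.parent not in {
                c.code for c in dataset.taxonomy if c.level == "generalized"
            }:
                raise ValidationError(f"prey code {cat.code!r} has no generalized parent")
            parent[cat.code] = cat.parent
        else:
            parent[cat.code] = cat.code

    records = []
    for rec in dataset.records:
        counts: dict[str, float] = {}
        weights: dict[str, float] = {}
        for code in rec.counts:
            if code not in parent:
                raise ValidationError(f"prey code {code!r} missing from taxonomy")
            p = parent[code]
            counts[p] = counts.get(p, 0.0) + rec.counts[code]
            weights[p] = weights.get(p, 0.0) + rec.weights_g[code]
        records.append(replace(rec, counts=counts, weights_g=weights))
    gen_taxonomy = dataset.taxonomy_for_level("generalized")
    return DietDataset(records=records, taxonomy=gen_taxonomy)


def apply_exclusions(dataset: DietDataset, drop_other: bool = True) -> DietDataset:
    """Remove empty stomachs and, when ``drop_other``, handle the Other category.

    Records containing exclusively Other prey are removed; records mixing Other
    with identifiable prey have their Other counts/weights zeroed so that diet
    proportions are recalculated over the remaining taxa.  Idempotent.
    """
    records = []
    for rec in dataset.records:
        flags = DietDataset._flags_for(rec)
        if "empty" in flags:
            continue
        if drop_other:
            if "other_only" in flags:
                continue
            if "other_partial" in flags:
                counts = dict(rec.counts)
                weights = dict(rec.weights_g)
                if OTHER_CODE in counts:
                    counts[OTHER_CODE] = 0.0
                    weights[OTHER_CODE] = 0.0
                rec = replace(rec, counts=counts, weights_g=weights)
        records.append(rec)
    if not records:
        warnings.warn("apply_exclusions produced an empty dataset", stacklevel=2)
    return DietDataset(records=records, taxonomy=list(dataset.taxonomy))


def read_isotope_table(path: str | Path) -> list[IsotopeRecord]:
    """Read a per-fish isotope CSV into records; empty file yields an empty list."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: isotope table is empty", stacklevel=2)
        return []
    if "fish_id" not in df.columns:
        raise FormatError(f"{path}: missing fish_id column in isotope table")
    for col in ("d13C", "d15N"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing {col} column in isotope table")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            raise ValidationError(f"{path}: non-numeric {col} in row {int(df.index[bad | df[col].isna()][0])}")
    out = []
    for _, row in df.iterrows():
        out.append(
            IsotopeRecord(
                fish_id=str(row["fish_id"]),
                d13C=float(row["d13C"]),
                d15N=float(row["d15N"]),
                pctC=float(row["pctC"]) if pd.notna(row.get("pctC")) else None,
                pctN=float(row["pctN"]) if pd.notna(row.get("pctN")) else None,
                cn_ratio=float(row["cn_ratio"]) if pd.notna(row.get("cn_ratio")) else None,
                location=row.get("location") if pd.notna(row.get("location")) else None,
                year=int(row["year"]) if pd.notna(row.get("year")) else None,
            )
        )
    return out


def isotope_records_to_frame(records: Sequence[IsotopeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in records],
            "d13C": [r.d13C for r in records],
            "d15N": [r.d15N for r in records],
            "pctC": [r.pctC for r in records],
            "pctN": [r.pctN for r in records],
            "cn_ratio": [r.cn_ratio for r in records],
            "location": [r.location for r in records],
            "year": [r.year for r in records],
        }
    )


def write_isotope_table(records: Sequence[IsotopeRecord], path: str | Path) -> None:
    isotope_records_to_frame(records).to_csv(path, index=False)
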