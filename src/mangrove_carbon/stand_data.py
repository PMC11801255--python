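"""Domain types, CSV schemas, validation, and exclusion filters for stand records.

A *stand* is one planted (restored/afforested) or intact mangrove forest
stand with location, geomorphic setting, age (planted only), species
composition, and per-compartment carbon stocks in MgC ha^-1.  Soil stocks
carry the depth over which they were sampled so they can later be rescaled
to the 1-m reference depth.

Units are fixed internally: stocks MgC ha^-1, depths cm, ages years,
coordinates decimal degrees WGS84.  Conversions happen only at the I/O
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GEOMORPHIC_CLASSES = frozenset(
    {"delta", "estuary", "lagoon", "open_coast", "oceanic_island"}
)
ROLES = frozenset({"planted", "intact"})
ORIGINS = frozenset({"afforested", "restored", "intact"})
COMPARTMENTS = ("agb", "bgb", "soil")

STANDS_COLUMNS = [
    "stand_id",
    "role",
    "origin",
    "latitude",
    "longitude",
    "site_id",
    "geomorphic_class",
    "age_yr",
    "composition",
    "agb_c_mgha",
    "bgb_c_mgha",
    "soil_c_mgha",
    "soil_depth_cm",
    "n_samples",
    "study_id",
]

PROFILES_COLUMNS = ["stand_id", "top_cm", "bottom_cm", "bulk_density_gcm3", "carbon_pct"]


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """A row or record violates a domain invariant."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.latitude) and math.isfinite(self.longitude)):
            raise ValidationError("coordinates must be finite")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class SoilLayer:
    """One sampled soil depth interval with bulk density and organic C content."""

    top_cm: float
    bottom_cm: float
    bulk_density: float  # g cm^-3
    carbon_pct: float  # percent of dry mass

    def __post_init__(self) -> None:
        if self.top_cm < 0:
            raise ValidationError("top_cm must be >= 0")
        if not self.bottom_cm > self.top_cm:
            raise ValidationError("bottom_cm must exceed top_cm")
        if not self.bulk_density > 0:
            raise ValidationError("bulk_density must be > 0")
        if not 0.0 <= self.carbon_pct <= 100.0:
            raise ValidationError("carbon_pct must be in [0, 100]")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm


@dataclass(frozen=True)
class SoilProfile:
    """An ordered, contiguous stack of soil layers from the surface downward."""

    stand_id: str
    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("profile must contain at least one layer")
        expected_top = 0.0
        for layer in self.layers:
            if not math.isclose(layer.top_cm, expected_top, abs_tol=1e-9):
                raise ValidationError(
                    f"layers of {self.stand_id} not contiguous from 0 cm: "
                    f"expected top {expected_top}, got {layer.top_cm}"
                )
            expected_top = layer.bottom_cm
        if not self.total_depth_cm > 0:
            raise ValidationError("total depth must be > 0")

    @property
    def total_depth_cm(self) -> float:
        return self.layers[-1].bottom_cm


@dataclass(frozen=True)
class StandRecord:
    """One planted or intact stand with location, class, age and stocks."""

    stand_id: str
    role: str
    origin: str
    location: GeoPoint
    site_id: str
    geomorphic_class: str
    composition: str
    study_id: str
    age_yr: float | None = None
    agb_c: float | None = None  # MgC ha^-1
    bgb_c: float | None = None
    soil_c: float | None = None
    soil_depth_cm: float | None = None
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.origin not in ORIGINS:
            raise ValidationError(f"unknown origin {self.origin!r}")
        if self.geomorphic_class not in GEOMORPHIC_CLASSES:
            raise ValidationError(
                f"unknown geomorphic class {self.geomorphic_class!r}"
            )
        if self.role == "planted" and self.age_yr is None:
            raise ValidationError("missing age")
        if self.age_yr is not None and self.age_yr < 0:
            raise ValidationError("age_yr must be >= 0")
        for name in ("agb_c", "bgb_c", "soil_c"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.stock("agb") is None and self.stock("bgb") is None and self.stock("soil") is None:
            raise ValidationError("at least one compartment stock required")
        if self.soil_c is not None and self.soil_depth_cm is None:
            raise ValidationError("soil_c requires soil_depth_cm")
        if self.soil_depth_cm is not None and not self.soil_depth_cm > 0:
            raise ValidationError("soil_depth_cm must be > 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")

    def stock(self, compartment: str) -> float | None:
        """Return the stock (MgC ha^-1) for a compartment, or None if absent."""
        return {"agb": self.agb_c, "bgb": self.bgb_c, "soil": self.soil_c}[compartment]

    def with_soil(self, soil_c: float, soil_depth_cm: float) -> "StandRecord":
        return replace(self, soil_c=soil_c, soil_depth_cm=soil_depth_cm)


@dataclass
class Dataset:
    """A validated collection of stand records plus its provenance log."""

    records: list[StandRecord]
    source: str = "<memory>"
    validation_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.stand_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate stand_id(s): {dupes}")
        site_class: dict[str, str] = {}
        for r in self.records:
            prev = site_class.setdefault(r.site_id, r.geomorphic_class)
            if prev != r.geomorphic_class:
                raise ValidationError(
                    f"site {r.site_id} maps to both {prev} and {r.geomorphic_class}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def planted(self) -> list[StandRecord]:
        return [r for r in self.records if r.role == "planted"]

    def intact(self) -> list[StandRecord]:
        return [r for r in self.records if r.role == "intact"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "stand_id": r.stand_id,
                    "role": r.role,
                    "origin": r.origin,
                    "latitude": r.location.latitude,
                    "longitude": r.location.longitude,
                    "site_id": r.site_id,
                    "geomorphic_class": r.geomorphic_class,
                    "age_yr": r.age_yr,
                    "composition": r.composition,
                    "agb_c_mgha": r.agb_c,
                    "bgb_c_mgha": r.bgb_c,
                    "soil_c_mgha": r.soil_c,
                    "soil_depth_cm": r.soil_depth_cm,
                    "n_samples": r.n_samples,
                    "study_id": r.study_id,
                }
            )
        return pd.DataFrame(rows, columns=STANDS_COLUMNS)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _record_from_row(row: Mapping) -> StandRecord:
    age = _opt_float(row["age_yr"])
    n_samples = _opt_float(row["n_samples"])
    return StandRecord(
        stand_id=str(row["stand_id"]),
        role=str(row["role"]),
        origin=str(row["origin"]),
        location=GeoPoint(float(row["latitude"]), float(row["longitude"])),
        site_id=str(row["site_id"]),
        geomorphic_class=str(row["geomorphic_class"]),
        age_yr=age,
        composition=str(row["composition"]),
        agb_c=_opt_float(row["agb_c_mgha"]),
        bgb_c=_opt_float(row["bgb_c_mgha"]),
        soil_c=_opt_float(row["soil_c_mgha"]),
        soil_depth_cm=_opt_float(row["soil_depth_cm"]),
        n_samples=int(n_samples) if n_samples is not None else 1,
        study_id=str(row["study_id"]),
    )


def read_dataset(path: str | Path, strict: bool = False) -> Dataset:
    """Read a stands CSV into a validated :class:`Dataset`.

    With ``strict=True`` any invalid row raises; otherwise invalid rows are
    dropped and the reason logged in ``Dataset.validation_log``.
    """
    df = pd.read_csv(path, dtype={"stand_id": str, "site_id": str, "study_id": str})
    missing = [c for c in STANDS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    records: list[StandRecord] = []
    log: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"row {idx}: {exc}") from exc
            log.append(f"row {idx} ({row.get('stand_id', '?')}): dropped: {exc}")
    return Dataset(records=records, source=str(path), validation_log=log)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset to CSV so that ``read_dataset`` round-trips it."""
    ds.to_frame().to_csv(path, index=False)


def read_profiles(path: str | Path, strict: bool = False) -> dict[str, SoilProfile]:
    """Read a soil-profiles CSV into per-stand :class:`SoilProfile` objects.

    Layers are sorted by depth per stand; invalid layers (or whole profiles
    failing contiguity) are dropped with a logged reason unless ``strict``.
    """
    df = pd.read_csv(path, dtype={"stand_id": str})
    missing = [c for c in PROFILES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    profiles: dict[str, SoilProfile] = {}
    for stand_id, group in df.groupby("stand_id", sort=True):
        layers: list[SoilLayer] = []
        for idx, row in group.sort_values("top_cm").iterrows():
            try:
                layers.append(
                    SoilLayer(
                        top_cm=float(row["top_cm"]),
                        bottom_cm=float(row["bottom_cm"]),
                        bulk_density=float(row["bulk_density_gcm3"]),
                        carbon_pct=float(row["carbon_pct"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                if strict:
                    raise ValidationError(f"row {idx}: {exc}") from exc
        if not layers:
            continue
        try:
            profiles[str(stand_id)] = SoilProfile(stand_id=str(stand_id), layers=tuple(layers))
        except ValidationError as exc:
            if strict:
                raise
            continue
    return profiles


#: Exclusion criteria applied to compiled records: stands without location,
#: composition, or (for planted stands) age are unusable for pairing or the
#: age model; single-sample records carry no replication.
EXCLUSION_CRITERIA = (
    "missing_location",
    "missing_composition",
    "missing_age",
    "no_replication",
)


def _exclusion_reason(r: StandRecord) -> str | None:
    if r.location is None:  # pragma: no cover - GeoPoint is required by the type
        return "missing_location"
    if not r.composition or r.composition.lower() in {"nan", "none", "unknown", ""}:
        return "missing_composition"
    if r.role == "planted" and r.age_yr is None:
        return "missing_age"
    if r.n_samples < 2:
        return "no_replication"
    return None


def apply_exclusion_filters(ds: Dataset) -> tuple[Dataset, dict[str, int]]:
    """Drop records failing the meta-analysis inclusion criteria.

    Returns the filtered dataset and a report counting removals per
    criterion; counts sum to ``len(ds) - len(filtered)``.  Idempotent.
    """
    report = {c: 0 for c in EXCLUSION_CRITERIA}
    kept: list[StandRecord] = []
    log = list(ds.validation_log)
    for r in ds.records:
        reason = _exclusion_reason(r)
        if reason is None:
            kept.append(r)
        else:
            report[reason] += 1
            log.append(f"{r.stand_id}: excluded: {reason}")
    return Dataset(records=kept, source=ds.source, validation_log=log), report
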