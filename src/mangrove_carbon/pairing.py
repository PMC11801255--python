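"""Match planted stands to intact references and form buildup ratios.

Each planted stand is compared against intact stands of the *same geomorphic
class*.  Matching is local first: every same-class intact stand within the
local distance threshold (default 10 km) is used, and the planted stock is
divided by the mean intact stock.  Stands with no local reference fall back
to a remote match: the nearest intact *site cluster* (stands sharing a
site_id, located at their centroid) in the same geomorphic class and the
same climatic band of absolute latitude, capped at a maximum remote
distance.  Stands that still have no reference are dropped.

Ratios are grouped into model strata by compartment x composition group
(mixed or genus); strata with too few observations or too few contributing
studies are excluded before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stand_data import COMPARTMENTS, Dataset, GeoPoint, StandRecord

EARTH_RADIUS_KM = 6371.0088

COMPOSITION_GROUPS = ("all", "mixed", "Avicennia", "Kandelia", "Rhizophora", "Sonneratia")


class UndefinedRatioError(ValueError):
    """The mean reference stock is zero or the planted stock is unusable."""


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lat1, lon1, lat2, lon2 = map(
        math.radians, (a.latitude, a.longitude, b.latitude, b.longitude)
    )
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass(frozen=True)
class StratumSpec:
    """A model stratum: ecosystem compartment x species-composition group."""

    compartment: str  # agb | bgb | soil
    composition_group: str  # all | mixed | genus name

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.composition_group not in COMPOSITION_GROUPS:
            raise ValueError(f"unknown composition group {self.composition_group!r}")

    @property
    def label(self) -> str:
        return f"{self.compartment}:{self.composition_group}"

    @classmethod
    def from_label(cls, label: str) -> "StratumSpec":
        compartment, _, group = label.partition(":")
        return cls(compartment, group or "all")


@dataclass(frozen=True)
class PairingConfig:
    """Distance, climate-band and stratum-size rules for reference matching."""

    local_threshold_km: float = 10.0
    remote_max_km: float = 400.0
    climatic_band_deg: float = 10.0
    min_stratum_obs: int = 30
    min_stratum_studies: int = 6
    remote_use_centroid: bool = True

    def __post_init__(self) -> None:
        for name in (
            "local_threshold_km",
            "remote_max_km",
            "climatic_band_deg",
            "min_stratum_obs",
            "min_stratum_studies",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def climatic_band(self, latitude: float) -> int:
        """Index of the |latitude| band this latitude falls into."""
        return int(abs(latitude) // self.climatic_band_deg)


@dataclass(frozen=True)
class MatchResult:
    references: tuple[StandRecord, ...]
    match_mode: str  # local | remote
    distance_km: float  # max used distance (local) or cluster distance (remote)


@dataclass(frozen=True)
class RatioObservation:
    """One planted stand's buildup ratio R for one compartment.

    R = planted stock / mean(reference intact stocks), dimensionless.
    """

    planted_id: str
    compartment: str
    ratio: float
    age_yr: float
    reference_ids: tuple[str, ...]
    reference_distance_km: float
    match_mode: str
    stratum: StratumSpec
    study_id: str

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("ratio must be > 0")
        if not self.reference_ids:
            raise ValueError("reference_ids must be non-empty")


def composition_group(composition: str) -> str:
    """Map a stand's composition to its model group (mixed or genus)."""
    if composition in COMPOSITION_GROUPS:
        return composition
    if composition.capitalize() in COMPOSITION_GROUPS:
        return composition.capitalize()
    return composition  # unknown genus -> StratumSpec rejects it


def match_references(
    planted: StandRecord,
    pool: Sequence[StandRecord],
    cfg: PairingConfig | None = None,
) -> MatchResult | None:
    """Find the intact reference set for one planted stand, or None.

    Local rule: all same-geomorphic-class intact stands within the local
    threshold.  Remote fallback: nearest same-class site cluster in the same
    climatic |latitude| band within the remote cap.  Deterministic: ties are
    broken by stand_id (local) / lexicographically smallest cluster site_id
    (remote), independent of pool ordering.
    """
    cfg = cfg or PairingConfig()
    candidates = sorted(
        (r for r in pool if r.role == "intact" and r.geomorphic_class == planted.geomorphic_class),
        key=lambda r: r.stand_id,
    )
    local = [
        (haversine_km(planted.location, r.location), r)
        for r in candidates
        if haversine_km(planted.location, r.location) <= cfg.local_threshold_km
    ]
    if local:
        return MatchResult(
            references=tuple(r for _, r in local),
            match_mode="local",
            distance_km=max(d for d, _ in local),
        )
    band = cfg.climatic_band(planted.location.latitude)
    remote = [r for r in candidates if cfg.climatic_band(r.location.latitude) == band]
    if not remote:
        return None
    clusters: dict[str, list[StandRecord]] = {}
    for r in remote:
        clusters.setdefault(r.site_id, []).append(r)
    best: tuple[float, str] | None = None
    for site_id in sorted(clusters):
        members = clusters[site_id]
        if cfg.remote_use_centroid:
            centroid = GeoPoint(
                float(np.mean([m.location.latitude for m in members])),
                float(np.mean([m.location.longitude for m in members])),
            )
            d = haversine_km(planted.location, centroid)
        else:
            d = min(haversine_km(planted.location, m.location) for m in members)
        if d <= cfg.remote_max_km and (best is None or d < best[0]):
            best = (d, site_id)
    if best is None:
        return None
    dist, site_id = best
    return MatchResult(
        references=tuple(sorted(clusters[site_id], key=lambda r: r.stand_id)),
        match_mode="remote",
        distance_km=dist,
    )


def compute_ratio(
    planted: StandRecord,
    refs: Sequence[StandRecord],
    compartment: str,
    match_mode: str = "local",
    distance_km: float = 0.0,
) -> RatioObservation | None:
    """Form R = planted stock / mean(reference stocks) for one compartment.

    References missing the compartment's stock are ignored (not zero-filled).
    Returns None when the planted stand or every reference lacks the stock;
    raises :class:`UndefinedRatioError` when the mean reference stock is 0
    or the planted stock is 0 (log-ratio undefined).
    """
    planted_stock = planted.stock(compartment)
    if planted_stock is None:
        return None
    ref_values = [(r.stand_id, r.stock(compartment)) for r in refs]
    ref_values = [(sid, v) for sid, v in ref_values if v is not None]
    if not ref_values:
        return None
    mean_ref = float(np.mean([v for _, v in ref_values]))
    if mean_ref == 0.0:
        raise UndefinedRatioError(
            f"{planted.stand_id}/{compartment}: mean reference stock is zero"
        )
    if planted_stock == 0.0:
        raise UndefinedRatioError(
            f"{planted.stand_id}/{compartment}: planted stock is zero; log ratio undefined"
        )
    return RatioObservation(
        planted_id=planted.stand_id,
        compartment=compartment,
        ratio=planted_stock / mean_ref,
        age_yr=float(planted.age_yr),
        reference_ids=tuple(sid for sid, _ in ref_values),
        reference_distance_km=distance_km,
        match_mode=match_mode,
        stratum=StratumSpec(compartment, composition_group(planted.composition)),
        study_id=planted.study_id,
    )


def pair_dataset(
    ds: Dataset, cfg: PairingConfig | None = None
) -> tuple[list[RatioObservation], dict[str, int]]:
    """Run matching + ratio formation over a whole harmonized dataset.

    Returns all ratio observations plus a report counting planted stands
    that were unmatched, and ratios skipped or undefined per compartment.
    """
    cfg = cfg or PairingConfig()
    pool = ds.intact()
    obs: list[RatioObservation] = []
    report = {"unmatched_stands": 0, "missing_compartment": 0, "undefined_ratio": 0}
    for planted in sorted(ds.planted(), key=lambda r: r.stand_id):
        match = match_references(planted, pool, cfg)
        if match is None:
            report["unmatched_stands"] += 1
            continue
        for compartment in COMPARTMENTS:
            try:
                o = compute_ratio(
                    planted,
                    match.references,
                    compartment,
                    match_mode=match.match_mode,
                    distance_km=match.distance_km,
                )
            except UndefinedRatioError:
                report["undefined_ratio"] += 1
                continue
            if o is None:
                report["missing_compartment"] += 1
            else:
                obs.append(o)
    return obs, report


def build_strata(
    obs: Iterable[RatioObservation], cfg: PairingConfig | None = None
) -> tuple[dict[StratumSpec, list[RatioObservation]], dict[str, dict[str, int]]]:
    """Group observations by stratum and drop under-sampled strata.

    A stratum is excluded when it has fewer than ``min_stratum_obs``
    observations or contributions from fewer than ``min_stratum_studies``
    distinct studies.  The report lists each excluded stratum with its
    observation and study counts; retained sizes + excluded sizes equal the
    input count.
    """
    cfg = cfg or PairingConfig()
    grouped: dict[StratumSpec, list[RatioObservation]] = {}
    for o in obs:
        grouped.setdefault(o.stratum, []).append(o)
    kept: dict[StratumSpec, list[RatioObservation]] = {}
    report: dict[str, dict[str, int]] = {}
    for stratum in sorted(grouped, key=lambda s: s.label):
        group = grouped[stratum]
        n_studies = len({o.study_id for o in group})
        if len(group) < cfg.min_stratum_obs or n_studies < cfg.min_stratum_studies:
            report[stratum.label] = {"n_obs": len(group), "n_studies": n_studies}
        else:
            kept[stratum] = group
    return kept, report


def pooled_stratum(
    obs: Iterable[RatioObservation], compartment: str
) -> tuple[StratumSpec, list[RatioObservation]]:
    """The pooled 'all' stratum for one compartment (all composition groups)."""
    spec = StratumSpec(compartment, "all")
    return spec, [o for o in obs if o.compartment == compartment]


def observations_to_frame(obs: Sequence[RatioObservation]):
    """Tabulate observations with the documented ratios.csv schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "planted_id": o.planted_id,
                "compartment": o.compartment,
                "ratio": o.ratio,
                "age_yr": o.age_yr,
                "composition_group": o.stratum.composition_group,
                "match_mode": o.match_mode,
                "reference_distance_km": o.reference_distance_km,
                "n_refs": len(o.reference_ids),
                "study_id": o.study_id,
            }
            for o in obs
        ],
        columns=[
            "planted_id",
            "compartment",
            "ratio",
            "age_yr",
            "composition_group",
            "match_mode",
            "reference_distance_km",
            "n_refs",
            "study_id",
        ],
    )


def observations_from_frame(df) -> list[RatioObservation]:
    """Rebuild observations from a ratios.csv table (reference ids not kept)."""
    out = []
    for _, row in df.iterrows():
        out.append(
            RatioObservation(
                planted_id=str(row["planted_id"]),
                compartment=str(row["compartment"]),
                ratio=float(row["ratio"]),
                age_yr=float(row["age_yr"]),
                reference_ids=("<unrecorded>",) * int(row.get("n_refs", 1)),
                reference_distance_km=float(row.get("reference_distance_km", 0.0)),
                match_mode=str(row.get("match_mode", "local")),
                stratum=StratumSpec(str(row["compartment"]), str(row["composition_group"])),
                study_id=str(row.get("study_id", "unknown")),
            )
        )
    return out
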