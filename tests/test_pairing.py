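import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mangrove_carbon.pairing import (
    EARTH_RADIUS_KM,
    PairingConfig,
    RatioObservation,
    StratumSpec,
    UndefinedRatioError,
    build_strata,
    compute_ratio,
    haversine_km,
    match_references,
    pair_dataset,
    pooled_stratum,
)
from mangrove_carbon.stand_data import Dataset, GeoPoint

from .test_stand_data import make_record


class TestHaversine:
    def test_identical_points(self):
        p = GeoPoint(5.0, 100.0)
        assert haversine_km(p, p) == 0.0

    def test_one_degree_at_equator(self):
        d = haversine_km(GeoPoint(0, 0), GeoPoint(0, 1))
        assert d == pytest.approx(EARTH_RADIUS_KM * math.radians(1), rel=1e-9)
        assert d == pytest.approx(111.195, abs=5e-4)

    def test_antipodal(self):
        d = haversine_km(GeoPoint(0, 0), GeoPoint(0, 180))
        assert d == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-9)

    @given(
        lat1=st.floats(-89, 89), lon1=st.floats(-179, 179),
        lat2=st.floats(-89, 89), lon2=st.floats(-179, 179),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_nonnegative(self, lat1, lon1, lat2, lon2):
        a, b = GeoPoint(lat1, lon1), GeoPoint(lat2, lon2)
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))
        assert haversine_km(a, b) >= 0.0


def intact(stand_id, lat, lon, gclass="delta", site_id=None, **kw):
    return make_record(
        stand_id, role="intact", location=GeoPoint(lat, lon),
        geomorphic_class=gclass, site_id=site_id or f"site_{stand_id}",
        composition="mixed", **kw,
    )


class TestMatchReferences:
    def setup_method(self):
        self.planted = make_record("p", location=GeoPoint(0.0, 100.0))

    def test_single_local_match(self):
        pool = [intact("u1", 0.0, 100.018)]  # ~2 km
        m = match_references(self.planted, pool)
        assert m.match_mode == "local"
        assert [r.stand_id for r in m.references] == ["u1"]
        assert m.distance_km <= 10.0

    def test_local_match_filters_by_class(self):
        pool = [
            intact("u_lagoon", 0.0, 100.045, gclass="lagoon"),  # ~5 km
            intact("u_delta", 0.0, 100.072, gclass="delta"),  # ~8 km
        ]
        m = match_references(self.planted, pool)
        assert m.match_mode == "local"
        assert [r.stand_id for r in m.references] == ["u_delta"]

    def test_remote_fallback_same_band_and_class(self):
        pool = [
            intact("far_same_band", 2.0, 100.0),  # ~222 km, band 0
            intact("far_other_band", 12.0, 100.0),  # band 1
        ]
        m = match_references(self.planted, pool)
        assert m.match_mode == "remote"
        assert [r.stand_id for r in m.references] == ["far_same_band"]
        assert m.distance_km <= 400.0

    def test_unmatched_beyond_cap(self):
        pool = [intact("veryfar", 5.0, 100.0)]  # ~556 km
        assert match_references(self.planted, pool) is None

    def test_invariant_to_pool_ordering(self):
        pool = [
            intact("b", 0.0, 100.02, site_id="sA"),
            intact("a", 0.0, 100.03, site_id="sA"),
        ]
        m1 = match_references(self.planted, pool)
        m2 = match_references(self.planted, list(reversed(pool)))
        assert [r.stand_id for r in m1.references] == [r.stand_id for r in m2.references]


class TestComputeRatio:
    def test_unit_ratio(self):
        p = make_record("p", agb_c=100.0)
        refs = [intact("u", 0, 100, agb_c=100.0)]
        assert compute_ratio(p, refs, "agb").ratio == pytest.approx(1.0)

    def test_mean_of_references(self):
        p = make_record("p", agb_c=50.0)
        refs = [intact("u1", 0, 100, agb_c=80.0), intact("u2", 0, 100.01, agb_c=120.0)]
        obs = compute_ratio(p, refs, "agb")
        assert obs.ratio == pytest.approx(0.5)
        assert obs.reference_ids == ("u1", "u2")

    def test_zero_reference_is_undefined(self):
        p = make_record("p", agb_c=50.0)
        refs = [intact("u", 0, 100, agb_c=0.0)]
        with pytest.raises(UndefinedRatioError):
            compute_ratio(p, refs, "agb")

    def test_missing_compartment_skipped(self):
        p = make_record("p", agb_c=50.0)
        refs = [intact("u", 0, 100, agb_c=80.0)]
        assert compute_ratio(p, refs, "soil") is None

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c):
        p = make_record("p", agb_c=50.0 * c)
        refs = [
            intact("u1", 0, 100, agb_c=80.0 * c),
            intact("u2", 0, 100.01, agb_c=120.0 * c),
        ]
        assert compute_ratio(p, refs, "agb").ratio == pytest.approx(0.5, rel=1e-12)

    def test_missing_reference_values_ignored_not_zero_filled(self):
        p = make_record("p", agb_c=50.0)
        refs = [
            intact("u1", 0, 100, agb_c=100.0),
            intact("u2", 0, 100.01, agb_c=None, soil_c=200.0, soil_depth_cm=100.0),
        ]
        assert compute_ratio(p, refs, "agb").ratio == pytest.approx(0.5)


def obs(i, stratum, study="st0", ratio=1.0):
    return RatioObservation(
        planted_id=f"p{i}", compartment=stratum.compartment, ratio=ratio,
        age_yr=10.0, reference_ids=("u",), reference_distance_km=1.0,
        match_mode="local", stratum=stratum, study_id=study,
    )


class TestBuildStrata:
    def test_documented_exclusion_threshold(self):
        # 27 observations from 5 studies: below both default minima
        s = StratumSpec("soil", "Avicennia")
        group = [obs(i, s, study=f"st{i % 5}") for i in range(27)]
        kept, report = build_strata(group)
        assert s not in kept
        assert report["soil:Avicennia"] == {"n_obs": 27, "n_studies": 5}

    def test_large_stratum_retained(self):
        s = StratumSpec("agb", "Rhizophora")
        group = [obs(i, s, study=f"st{i % 12}") for i in range(100)]
        kept, report = build_strata(group)
        assert len(kept[s]) == 100 and not report

    def test_empty_input(self):
        kept, report = build_strata([])
        assert kept == {} and report == {}

    def test_sizes_plus_exclusions_balance(self):
        s1 = StratumSpec("agb", "Rhizophora")
        s2 = StratumSpec("soil", "Avicennia")
        all_obs = [obs(i, s1, study=f"st{i % 12}") for i in range(40)] + [
            obs(100 + i, s2, study=f"st{i % 3}") for i in range(10)
        ]
        kept, report = build_strata(all_obs)
        n_kept = sum(len(v) for v in kept.values())
        n_excl = sum(r["n_obs"] for r in report.values())
        assert n_kept + n_excl == len(all_obs)

    def test_pooled_stratum_collects_compartment(self):
        s1 = StratumSpec("agb", "Rhizophora")
        s2 = StratumSpec("agb", "mixed")
        spec, pooled = pooled_stratum([obs(1, s1), obs(2, s2)], "agb")
        assert spec == StratumSpec("agb", "all")
        assert len(pooled) == 2


class TestPairDataset:
    def test_synthetic_assignments_recovered(self, default_dataset):
        ds, truth = default_dataset
        observations, report = pair_dataset(ds)
        assert report["unmatched_stands"] == 0
        by_id = {}
        for o in observations:
            by_id.setdefault(o.planted_id, o)
        for site_id, site in truth["sites"].items():
            for pid in site["planted"]:
                if pid in by_id:
                    assert set(by_id[pid].reference_ids) <= set(site["intact"])
                    assert by_id[pid].match_mode == "local"
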