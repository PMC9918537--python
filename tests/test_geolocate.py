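import numpy as np
import pandas as pd
import pytest

from migtime.geolocate import (
    ColonySite,
    PolarDayError,
    derive_arrival_date,
    estimate_daily_position,
    estimate_track,
    great_circle_km,
    simulate_twilights,
    solar_geometry,
)


def test_solar_geometry_landmarks():
    decl_solstice, _ = solar_geometry(172)  # ~June 21
    assert decl_solstice == pytest.approx(23.44, abs=0.5)
    decl_winter, _ = solar_geometry(355)
    assert decl_winter == pytest.approx(-23.44, abs=0.5)
    decl_equinox, _ = solar_geometry(80)
    assert abs(decl_equinox) < 1.0
    with pytest.raises(ValueError):
        solar_geometry(0)


def test_single_day_position_recovery():
    truth = pd.DataFrame({"day": [140], "latitude": [35.0], "longitude": [-80.0]})
    tw = simulate_twilights(truth)
    lat, lon, flag = estimate_daily_position(
        tw["rise_utc"].iloc[0], tw["set_utc"].iloc[0], 140, lat_hint=30.0
    )
    assert lat == pytest.approx(35.0, abs=0.01)
    assert lon == pytest.approx(-80.0, abs=0.01)
    assert flag == "ok"


def test_invalid_twilight_pairs():
    with pytest.raises(ValueError, match="sunset"):
        estimate_daily_position(12.0, 6.0, 100)
    with pytest.raises(PolarDayError):
        estimate_daily_position(0.0, 24.5, 172)


def test_polar_day_flagged_by_simulator_and_track():
    truth = pd.DataFrame({"day": [172], "latitude": [80.0], "longitude": [0.0]})
    tw = simulate_twilights(truth)
    assert bool(tw["polar"].iloc[0])
    track = estimate_track(tw)
    assert track["quality"].iloc[0] == "missing"


def test_great_circle_known_values():
    assert great_circle_km(0, 0, 0, 0) == 0.0
    # one degree of latitude is ~111 km
    assert great_circle_km(40, -75, 41, -75) == pytest.approx(111.2, rel=0.01)


def test_arrival_requires_persistence_and_quality():
    site = ColonySite(41.0, -77.0, radius_km=150.0, persistence_days=3)
    base = {"latitude": 41.0, "longitude": -77.0, "quality": "ok"}
    track = pd.DataFrame([{"day": d, **base} for d in range(120, 130)])
    assert derive_arrival_date(track, site) == 120
    # an equinox-flagged day breaks the run
    track.loc[track["day"] == 121, "quality"] = "equinox_unreliable"
    assert derive_arrival_date(track, site) == 122
    # too far away: no arrival
    far = track.assign(latitude=10.0)
    assert derive_arrival_date(far, site) is None
    with pytest.raises(ValueError):
        ColonySite(41.0, -77.0, radius_km=-1.0)


def test_noisy_track_stays_close():
    # early summer at mid-latitude: day length is sensitive to latitude, so
    # most days clear the equinox-reliability cutoff
    days = np.arange(130, 171)
    truth = pd.DataFrame(
        {"day": days, "latitude": np.full(days.size, 30.0),
         "longitude": np.full(days.size, -85.0)}
    )
    tw = simulate_twilights(truth, noise_sd_minutes=2.0, seed=4)
    track = estimate_track(tw, initial_lat_hint=25.0)
    ok = track[track["quality"] == "ok"]
    assert len(ok) >= 30
    assert np.abs(ok["longitude"] + 85.0).median() < 1.0
    assert np.abs(ok["latitude"] - 30.0).median() < 2.0
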