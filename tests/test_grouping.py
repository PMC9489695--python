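"""PCI, seasonality, MAT classes and ambient/warm pair construction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from soc_sft.grouping import (assign_mat_classes, build_pairs, classify_seasonality,
                              compute_pci, environments_frame, pairs_frame)
from soc_sft.profiles import SiteEnvironment


def _env(pid, mat, map_mm, monthly=None, landform="plains", soil="mollisols",
         hemisphere="N"):
    monthly = np.full(12, map_mm / 12.0) if monthly is None else np.asarray(monthly, float)
    return SiteEnvironment(profile_id=pid, mat=mat, monthly_precip=monthly,
                           map=float(monthly.sum()), landform=landform, soil_order=soil,
                           biome="grassland", elevation=100.0, npp=500.0,
                           aridity_index=1.0, hemisphere=hemisphere)


# ---------------------------------------------------------------------------
# PCI

def test_pci_uniform_lower_bound():
    assert compute_pci([50.0] * 12) == pytest.approx(100 / 12, abs=1e-9)


def test_pci_single_month_maximal():
    assert compute_pci([600.0] + [0.0] * 11) == pytest.approx(100.0)


def test_pci_two_level_example():
    assert compute_pci([10.0] * 6 + [90.0] * 6) == pytest.approx(13.67, abs=0.005)


def test_pci_multi_year_average_skips_void_years():
    years = np.array([[50.0] * 12, [600.0] + [0.0] * 11, [0.0] * 12])
    assert compute_pci(years) == pytest.approx((100 / 12 + 100.0) / 2)
    with pytest.raises(ValueError, match="non-zero"):
        compute_pci(np.zeros((2, 12)))


def test_pci_rejects_bad_input():
    with pytest.raises(ValueError):
        compute_pci([10.0] * 11)
    with pytest.raises(ValueError):
        compute_pci([-1.0] + [10.0] * 11)


# ---------------------------------------------------------------------------
# seasonality

def test_summer_rain_north():
    monthly = np.array([10] * 3 + [100] * 6 + [10] * 3, dtype=float)  # Apr-Sep heavy
    assert classify_seasonality(compute_pci(monthly), monthly, "N") == "summer"
    assert classify_seasonality(compute_pci(monthly), monthly, "S") == "winter"


def test_summer_rain_south_flips():
    monthly = np.array([100, 100, 10, 10, 10, 10, 10, 10, 10, 10, 100, 100], dtype=float)
    assert classify_seasonality(compute_pci(monthly), monthly, "S") == "summer"
    assert classify_seasonality(compute_pci(monthly), monthly, "N") == "winter"


def test_half_year_tie_breaks_to_winter():
    monthly = np.array([60, 0, 0, 60, 0, 0, 60, 0, 0, 60, 0, 0], dtype=float)
    assert np.sum(monthly[3:9]) == np.sum(monthly) / 2
    assert classify_seasonality(compute_pci(monthly), monthly, "N") == "winter"


def test_uniform_below_threshold_only():
    monthly = np.full(12, 50.0)
    pci = compute_pci(monthly)  # 8.333, above the customary 8.3 threshold
    assert classify_seasonality(pci, monthly, "N", threshold=8.3) != "uniform"
    assert classify_seasonality(pci, monthly, "N", threshold=8.34) == "uniform"


# ---------------------------------------------------------------------------
# MAT classes

@pytest.mark.parametrize("mat,lower", [(3.4, 3), (3.0, 3), (-0.5, -1), (24.999, 24)])
def test_mat_class_floor_convention(mat, lower):
    classes = assign_mat_classes([_env("p", mat, 480.0)])
    assert len(classes) == 1 and classes[0].lower == lower


def test_mat_classes_partition(small_world):
    classes = assign_mat_classes(small_world.environments)
    members = list(itertools.chain.from_iterable(c.members for c in classes))
    assert sorted(members) == sorted(e.profile_id for e in small_world.environments)
    for c, env in ((c, e) for c in classes for e in small_world.environments
                   if e.profile_id in c.members):
        assert c.lower <= env.mat < c.lower + 1


# ---------------------------------------------------------------------------
# pairing

def _harmonized(values):
    """values: {profile_id: topsoil stock}; single-layer tidy frame."""
    return pd.DataFrame([
        {"profile_id": pid, "layer": "0-0.3", "soc_c": v, "soc_s": v,
         "covered": True, "is_cropland": False}
        for pid, v in values.items()])


def test_toy_pairing_exhaustive_oracle():
    # two MAT classes, one shared key, |dMAP| = 10 mm -> exactly one pair
    envs = [_env("a1", 5.2, 500.0), _env("a2", 5.8, 500.0),
            _env("w1", 6.3, 510.0), _env("w2", 6.9, 510.0),
            _env("lone", 6.5, 510.0, landform="mountains")]  # no ambient partner
    harm = _harmonized({"a1": 10.0, "a2": 12.0, "w1": 9.0, "w2": 10.5, "lone": 7.0})
    pairs = build_pairs(envs, harm, "0-0.3", 1)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.ambient.n, p.warm.n) == (2, 2)
    assert p.ambient.mean == pytest.approx(11.0)
    assert p.warm.mean == pytest.approx(9.75)
    assert p.moderators["delta_t"] == pytest.approx(6.6 - 5.5)
    assert abs(p.moderators["delta_map"]) == pytest.approx(10.0)


def test_map_tolerance_excludes():
    envs = [_env("a1", 5.2, 500.0), _env("a2", 5.8, 500.0),
            _env("w1", 6.3, 549.0), _env("w2", 6.9, 549.0)]
    harm = _harmonized({"a1": 10.0, "a2": 12.0, "w1": 9.0, "w2": 10.5})
    # same 50 mm MAP bin but mean difference 49 mm: kept at tol 50, dropped at 25
    assert len(build_pairs(envs, harm, "0-0.3", 1, map_tolerance_mm=50)) == 1
    assert len(build_pairs(envs, harm, "0-0.3", 1, map_tolerance_mm=25)) == 0


def test_singleton_group_excluded():
    envs = [_env("a1", 5.2, 500.0), _env("a2", 5.8, 500.0), _env("w1", 6.3, 500.0)]
    harm = _harmonized({"a1": 10.0, "a2": 12.0, "w1": 9.0})
    assert build_pairs(envs, harm, "0-0.3", 1) == []


def test_emitted_pairs_satisfy_invariants(small_env_frame, small_harmonized):
    for dt in (1, 3):
        for p in build_pairs(small_env_frame, small_harmonized, "0-0.3", dt):
            assert p.warm.class_lower - p.ambient.class_lower == dt
            assert p.ambient.key == p.warm.key
            assert abs(p.warm.mean_map - p.ambient.mean_map) < 50.0
            assert p.ambient.n >= 2 and p.warm.n >= 2
            assert np.isfinite(p.ambient.sd) and np.isfinite(p.warm.sd)


def test_pair_count_monotonicity(small_env_frame, small_harmonized):
    args = (small_env_frame, small_harmonized, "0-0.3", 1)
    n_loose = len(build_pairs(*args, map_tolerance_mm=50))
    n_tight = len(build_pairs(*args, map_tolerance_mm=25))
    assert n_tight <= n_loose
    n_small = len(build_pairs(*args, min_group_n=None))
    n_big = len(build_pairs(*args, min_group_n=8))
    assert n_big <= n_small


def test_cropland_exclusion_noop_on_cropland_free_world(clean_world):
    from soc_sft.pipeline import prepare_profiles
    harm = prepare_profiles(clean_world.profiles, clean_world.environments, impute=False)
    env = environments_frame(clean_world.environments)
    with_flag = pairs_frame(build_pairs(env, harm, "0-0.3", 1, exclude_cropland=True))
    without = pairs_frame(build_pairs(env, harm, "0-0.3", 1, exclude_cropland=False))
    pd.testing.assert_frame_equal(with_flag, without)


def test_pairs_frame_columns(small_env_frame, small_harmonized):
    frame = pairs_frame(build_pairs(small_env_frame, small_harmonized, "0-0.3", 1))
    assert {"warming_level", "ambient_mean", "warm_mean", "mod_baseline_soc",
            "mod_biome", "mod_delta_t"} <= set(frame.columns)
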