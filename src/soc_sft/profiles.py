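"""Layered soil-profile ingestion, imputation, depth harmonization and stocks.

A soil profile is a stack of measured layers (depth interval, SOC content of
the <2 mm fine earth in g C/kg, bulk density in kg/m^3, volumetric gravel
fraction in %).  This module reads and validates such tables, fills missing
bulk density / gravel with a boosted regression-tree model trained on the
complete cases, harmonizes SOC content to the three standard depth intervals
0-0.3, 0.3-1 and 1-2 m with a mass-preserving spline, and converts content to
stock (kg C/m^2):

    SOC_s = SOC_c/1000 * D * BD * (1 - G/100)

with SOC_c in g C per kg fine earth, D the interval thickness in m, BD in
kg/m^3 and G the gravel volume percent.  (With these units the mass fraction
is SOC_c/1000; quoting BD in g/cm^3 or D in cm absorbs a factor 10 and yields
the /100 form seen elsewhere.)  Stocks are stored in kg C/m^2; multiply by 10
for Mg C/ha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.model_selection import train_test_split

from .spline import DEFAULT_LAMBDA, DepthSpline

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SiteEnvironment",
    "HarmonizedProfile",
    "STANDARD_LAYERS",
    "LAYER_LABELS",
    "read_profiles",
    "write_profiles",
    "read_environments",
    "write_environments",
    "impute_missing",
    "ImputationReport",
    "harmonize",
    "harmonize_profiles",
    "compute_soc_stock",
]

#: the three standard depth intervals (top, bottom) in m
STANDARD_LAYERS = ((0.0, 0.3), (0.3, 1.0), (1.0, 2.0))
LAYER_LABELS = ("0-0.3", "0.3-1", "1-2")
LAYER_THICKNESS = {"0-0.3": 0.3, "0.3-1": 0.7, "1-2": 1.0}

LANDFORMS = ("plains", "plateaus", "mountains")
USDA_ORDERS = (
    "alfisols", "andisols", "aridisols", "entisols", "gelisols", "histosols",
    "inceptisols", "mollisols", "oxisols", "spodosols", "ultisols", "vertisols",
)


@dataclass
class SoilLayer:
    """One measured depth interval; depths in m, positive downward."""

    top: float
    bottom: float
    soc_c: float  # g C / kg fine earth
    bd: float | None = None  # kg / m^3
    gravel: float | None = None  # volume %

    def validate(self) -> None:
        if not 0 <= self.top < self.bottom:
            raise ValueError(f"layer depths invalid: [{self.top}, {self.bottom})")
        if not np.isfinite(self.soc_c) or self.soc_c < 0:
            raise ValueError(f"soc_c invalid: {self.soc_c}")
        if self.bd is not None and not self.bd > 0:
            raise ValueError(f"bd invalid: {self.bd}")
        if self.gravel is not None and not 0 <= self.gravel <= 100:
            raise ValueError(f"gravel invalid: {self.gravel}")


@dataclass
class SoilProfile:
    id: str
    latitude: float
    longitude: float
    layers: list[SoilLayer] = field(default_factory=list)
    is_cropland: bool = False

    def validate(self) -> None:
        prev_bottom = 0.0
        for lay in self.layers:
            lay.validate()
            if lay.top < prev_bottom - 1e-9:
                raise ValueError(f"profile {self.id}: overlapping layers at {lay.top} m")
            prev_bottom = lay.bottom


@dataclass
class SiteEnvironment:
    """Climate, terrain and vegetation context at a profile location."""

    profile_id: str
    mat: float  # mean annual temperature, degC
    monthly_precip: np.ndarray  # 12 monthly totals, mm
    map: float  # mean annual precipitation, mm
    landform: str
    soil_order: str
    biome: str
    elevation: float  # m
    npp: float  # g C m^-2 yr^-1
    aridity_index: float
    hemisphere: str = "N"
    suborder: str | None = None

    def validate(self) -> None:
        mp = np.asarray(self.monthly_precip, dtype=float)
        if mp.shape[-1] != 12:
            raise ValueError("monthly_precip must have 12 values")
        if np.any(mp < 0):
            raise ValueError("negative monthly precipitation")
        if abs(float(np.sum(np.atleast_2d(mp).mean(axis=0))) - self.map) > max(1.0, 0.01 * self.map):
            raise ValueError("map inconsistent with monthly totals")
        if self.hemisphere not in ("N", "S"):
            raise ValueError(f"hemisphere must be N or S, got {self.hemisphere}")


@dataclass
class HarmonizedProfile:
    """SOC content/stock on the standard depth intervals for one profile."""

    id: str
    soc_c: dict  # label -> g C/kg (NaN if no observed overlap)
    soc_s: dict  # label -> kg C/m^2 (NaN if bd/gravel missing or no overlap)
    covered: dict  # label -> bool, observed layers fully span the interval
    is_cropland: bool = False


# ---------------------------------------------------------------------------
# I/O

_PROFILE_COLUMNS = ["profile_id", "latitude", "longitude", "is_cropland",
                    "top_m", "bottom_m", "soc_gkg", "bd_kgm3", "gravel_pct"]

_ENV_COLUMNS = ["profile_id", "mat_c", "map_mm", "landform", "soil_order",
                "suborder", "biome", "elevation_m", "npp", "aridity_index",
                "hemisphere"] + [f"precip_{m:02d}" for m in range(1, 13)]


def read_profiles(path) -> tuple[list[SoilProfile], pd.DataFrame]:
    """Read a layer table (one row per layer) into validated profiles.

    Returns (profiles, rejected) where ``rejected`` records every input row
    that violated an invariant (negative depths, inverted depth order,
    out-of-range gravel, ...) with the reason, mirroring the quality screen
    applied to global soil databases before analysis.
    """
    table = pd.read_csv(path)
    if table.empty:
        warnings.warn(f"{path}: empty profile table", stacklevel=2)
        return [], pd.DataFrame(columns=[*_PROFILE_COLUMNS, "reason"])
    missing = set(["profile_id", "top_m", "bottom_m", "soc_gkg"]) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")

    profiles: dict[str, SoilProfile] = {}
    rejected = []
    for idx, row in table.iterrows():
        pid = str(row["profile_id"])
        layer = SoilLayer(
            top=float(row["top_m"]),
            bottom=float(row["bottom_m"]),
            soc_c=float(row["soc_gkg"]),
            bd=None if pd.isna(row.get("bd_kgm3")) else float(row["bd_kgm3"]),
            gravel=None if pd.isna(row.get("gravel_pct")) else float(row["gravel_pct"]),
        )
        try:
            layer.validate()
        except ValueError as err:
            rejected.append({**row.to_dict(), "reason": str(err)})
            continue
        if pid not in profiles:
            profiles[pid] = SoilProfile(
                id=pid,
                latitude=float(row.get("latitude", np.nan)),
                longitude=float(row.get("longitude", np.nan)),
                is_cropland=bool(row.get("is_cropland", False)),
            )
        profiles[pid].layers.append(layer)

    result = []
    for prof in profiles.values():
        prof.layers.sort(key=lambda l: l.top)
        try:
            prof.validate()
            result.append(prof)
        except ValueError as err:
            rejected.append({"profile_id": prof.id, "reason": str(err)})
    return result, pd.DataFrame(rejected)


def write_profiles(profiles, path) -> None:
    rows = []
    for p in profiles:
        for lay in p.layers:
            rows.append({
                "profile_id": p.id, "latitude": p.latitude, "longitude": p.longitude,
                "is_cropland": p.is_cropland, "top_m": lay.top, "bottom_m": lay.bottom,
                "soc_gkg": lay.soc_c, "bd_kgm3": lay.bd, "gravel_pct": lay.gravel,
            })
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)


def read_environments(path) -> list[SiteEnvironment]:
    table = pd.read_csv(path)
    if table.empty:
        warnings.warn(f"{path}: empty environment table", stacklevel=2)
        return []
    envs = []
    for _, row in table.iterrows():
        env = SiteEnvironment(
            profile_id=str(row["profile_id"]),
            mat=float(row["mat_c"]),
            monthly_precip=np.array([row[f"precip_{m:02d}"] for m in range(1, 13)], dtype=float),
            map=float(row["map_mm"]),
            landform=str(row["landform"]),
            soil_order=str(row["soil_order"]),
            suborder=None if pd.isna(row.get("suborder")) else str(row["suborder"]),
            biome=str(row["biome"]),
            elevation=float(row["elevation_m"]),
            npp=float(row["npp"]),
            aridity_index=float(row["aridity_index"]),
            hemisphere=str(row.get("hemisphere", "N")),
        )
        env.validate()
        envs.append(env)
    return envs


def write_environments(envs, path) -> None:
    rows = []
    for e in envs:
        row = {
            "profile_id": e.profile_id, "mat_c": e.mat, "map_mm": e.map,
            "landform": e.landform, "soil_order": e.soil_order, "suborder": e.suborder,
            "biome": e.biome, "elevation_m": e.elevation, "npp": e.npp,
            "aridity_index": e.aridity_index, "hemisphere": e.hemisphere,
        }
        for m in range(1, 13):
            row[f"precip_{m:02d}"] = float(np.asarray(e.monthly_precip)[m - 1])
        rows.append(row)
    pd.DataFrame(rows, columns=_ENV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputation of missing bulk density / gravel

@dataclass
class ImputationReport:
    target: str
    n_missing: int
    n_complete: int
    rmse: float  # out-of-sample RMSE on a held-out fraction of complete cases


BD_PLAUSIBLE = (50.0, 2700.0)  # kg m^-3


def impute_missing(profiles, target, seed=0, environments=None, min_complete=30,
                   bd_range=BD_PLAUSIBLE):
    """Fill missing ``target`` ('bd' or 'gravel') with boosted-tree predictions.

    A gradient-boosted regression-tree model is trained on layers where the
    target is measured, using depth, thickness, SOC content, location and
    (when given) site climate as covariates, then applied to the layers where
    it is missing.  Observed values are never altered.  Imputed gravel is
    clamped to [0, 100] %, imputed BD to ``bd_range``.

    Returns (new_profiles, ImputationReport).  Deterministic given ``seed``.
    """
    if target not in ("bd", "gravel"):
        raise ValueError("target must be 'bd' or 'gravel'")
    env_by_id = {e.profile_id: e for e in environments} if environments else {}

    rows, values = [], []
    index = []  # (profile_idx, layer_idx)
    for i, p in enumerate(profiles):
        env = env_by_id.get(p.id)
        for j, lay in enumerate(p.layers):
            rows.append([
                (lay.top + lay.bottom) / 2, lay.bottom - lay.top, lay.soc_c,
                p.latitude, p.longitude,
                env.mat if env else np.nan, env.map if env else np.nan,
            ])
            values.append(getattr(lay, target))
            index.append((i, j))
    X = np.asarray(rows, dtype=float)
    keep = ~np.all(np.isnan(X), axis=0)  # drop covariates absent everywhere
    X = X[:, keep]
    y = np.array([np.nan if v is None else v for v in values], dtype=float)
    obs = np.isfinite(y)

    n_missing = int((~obs).sum())
    if n_missing == 0:
        return [replace(p, layers=[replace(l) for l in p.layers]) for p in profiles], \
            ImputationReport(target, 0, int(obs.sum()), float("nan"))
    if obs.sum() < min_complete:
        raise ValueError(
            f"imputation of {target} needs >= {min_complete} complete cases, have {int(obs.sum())}")

    Xtr, Xte, ytr, yte = train_test_split(X[obs], y[obs], test_size=0.2, random_state=seed)
    model = HistGradientBoostingRegressor(random_state=seed)
    model.fit(Xtr, ytr)
    rmse = float(np.sqrt(np.mean((model.predict(Xte) - yte) ** 2)))
    # refit on all complete cases for the actual fill
    model.fit(X[obs], y[obs])
    pred = model.predict(X[~obs])
    lo, hi = (0.0, 100.0) if target == "gravel" else bd_range
    pred = np.clip(pred, lo, hi)

    out = [replace(p, layers=[replace(l) for l in p.layers]) for p in profiles]
    for (i, j), v in zip(np.array(index)[~obs], pred):
        setattr(out[i].layers[j], target, float(v))
    return out, ImputationReport(target, n_missing, int(obs.sum()), rmse)


# ---------------------------------------------------------------------------
# Harmonization and stocks

def compute_soc_stock(soc_c, depth, bd, gravel):
    """SOC stock (kg C/m^2) from content (g C/kg), thickness (m), BD (kg/m^3)
    and gravel volume (%).  Vectorized over array inputs."""
    soc_c = np.asarray(soc_c, dtype=float)
    bd = np.asarray(bd, dtype=float)
    gravel = np.asarray(gravel, dtype=float)
    if np.any(soc_c < 0) or np.any(bd <= 0) or np.any((gravel < 0) | (gravel > 100)):
        raise ValueError("inputs outside valid ranges")
    out = soc_c / 1000.0 * depth * bd * (1.0 - gravel / 100.0)
    return float(out) if out.ndim == 0 else out


def _weighted_layer_value(layers, attr, top, bottom):
    """Overlap-thickness-weighted mean of a per-layer attribute over [top, bottom]."""
    num = den = 0.0
    for lay in layers:
        v = getattr(lay, attr)
        if v is None:
            continue
        w = min(lay.bottom, bottom) - max(lay.top, top)
        if w > 0:
            num += w * v
            den += w
    return num / den if den > 0 else float("nan")


def harmonize(profile: SoilProfile, lambda_smooth: float = DEFAULT_LAMBDA,
              gravel_default: float | None = None) -> HarmonizedProfile:
    """Harmonize one profile's SOC content to the standard depth intervals.

    Content is interpolated with the mass-preserving spline; BD and gravel
    (needed for the stock) are averaged over each interval weighted by layer
    overlap.  Stock is NaN wherever BD (or gravel, unless ``gravel_default``
    is given) is unavailable.  Intervals with no observed overlap are flagged
    uncovered and left NaN — never extrapolated to zero.
    """
    layers = [l for l in profile.layers if np.isfinite(l.soc_c)]
    if not layers:
        raise ValueError(f"profile {profile.id}: no layers with SOC content")
    spl = DepthSpline([(l.top, l.bottom) for l in layers], [l.soc_c for l in layers],
                      lam=lambda_smooth)
    soc_c, soc_s, covered = {}, {}, {}
    for (top, bottom), label in zip(STANDARD_LAYERS, LAYER_LABELS):
        c = spl.mean(top, bottom)
        soc_c[label] = c
        covered[label] = spl.covers(top, bottom)
        bd = _weighted_layer_value(layers, "bd", top, bottom)
        grav = _weighted_layer_value(layers, "gravel", top, bottom)
        if np.isnan(grav) and gravel_default is not None:
            grav = gravel_default
        if np.isfinite(c) and np.isfinite(bd) and np.isfinite(grav):
            soc_s[label] = compute_soc_stock(c, LAYER_THICKNESS[label], bd, grav)
        else:
            soc_s[label] = float("nan")
    return HarmonizedProfile(profile.id, soc_c, soc_s, covered, profile.is_cropland)


def harmonize_profiles(profiles, lambda_smooth: float = DEFAULT_LAMBDA,
                       gravel_default: float | None = None) -> pd.DataFrame:
    """Harmonize many profiles into a tidy frame: one row per (profile, layer)."""
    rows = []
    for p in profiles:
        try:
            h = harmonize(p, lambda_smooth, gravel_default)
        except ValueError:
            continue
        for label in LAYER_LABELS:
            rows.append({
                "profile_id": h.id, "layer": label, "soc_c": h.soc_c[label],
                "soc_s": h.soc_s[label], "covered": h.covered[label],
                "is_cropland": h.is_cropland,
            })
    return pd.DataFrame(rows)
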