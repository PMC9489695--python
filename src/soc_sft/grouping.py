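"""Space-for-time substitution: MAT classes, covariate groups, paired contrasts.

Profiles are binned into 1 degC mean-annual-temperature (MAT) classes and,
within each class, into groups sharing landform, soil type, precipitation
seasonality and a mean-annual-precipitation (MAP) bin.  For a warming level
dT, every group in class [i, i+1) is contrasted with the same group in class
[i+dT, i+dT+1): the cooler class stands for today's climate ("ambient"), the
warmer one for the future ("warm"), under the steady-state assumption that
otherwise-matched soils along a spatial temperature gradient represent the
equilibria the same soil would reach at those temperatures.

Seasonality comes from the precipitation concentration index

    PCI = 100 * sum(p_i^2) / (sum p_i)^2

over the 12 monthly totals (100/12 for perfectly uniform rain, 100 when all
rain falls in one month).  Below a threshold the regime is "uniform";
otherwise it is "summer" when the April-September total (October-March in the
southern hemisphere) exceeds the other half-year, else "winter".  Note the
analytic minimum of PCI is 100/12 = 8.333, so the customary threshold of 8.3
can only fire on multi-year averages where void years are excluded; the
threshold is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupKey",
    "MATClass",
    "GroupSummary",
    "PairedComparison",
    "compute_pci",
    "classify_seasonality",
    "summer_fraction",
    "assign_mat_classes",
    "environments_frame",
    "build_pairs",
    "pairs_frame",
    "PCI_THRESHOLD",
]

PCI_THRESHOLD = 8.3
_SUMMER_N = slice(3, 9)  # April..September (0-based months 3..8)


@dataclass(frozen=True)
class GroupKey:
    landform: str
    soil_order: str
    seasonality: str  # summer / winter / uniform
    map_bin: int


@dataclass
class MATClass:
    lower: int  # class is [lower, lower+1) degC
    members: list = field(default_factory=list)  # profile ids


@dataclass
class GroupSummary:
    key: GroupKey
    class_lower: int
    n: int
    mean: float
    sd: float  # NaN when n < 2
    mean_map: float
    mean_mat: float


@dataclass
class PairedComparison:
    warming_level: int
    layer: str
    ambient: GroupSummary
    warm: GroupSummary
    moderators: dict = field(default_factory=dict)


def compute_pci(monthly_precip) -> float:
    """Precipitation concentration index over 12 monthly totals.

    Accepts a single year (12 values) or a stack of years (k x 12); multiple
    years are averaged after computing PCI per year, skipping years with zero
    total.  Raises if no year has any precipitation.
    """
    p = np.atleast_2d(np.asarray(monthly_precip, dtype=float))
    if p.shape[1] != 12:
        raise ValueError("monthly precipitation must have 12 columns")
    if np.any(p < 0):
        raise ValueError("negative monthly precipitation")
    totals = p.sum(axis=1)
    ok = totals > 0
    if not ok.any():
        raise ValueError("no year with non-zero precipitation")
    pci = 100.0 * (p[ok] ** 2).sum(axis=1) / totals[ok] ** 2
    return float(pci.mean())


def summer_fraction(monthly_precip, hemisphere: str = "N") -> float:
    """Fraction of annual precipitation falling in the warm half-year."""
    p = np.atleast_2d(np.asarray(monthly_precip, dtype=float)).mean(axis=0)
    total = p.sum()
    if total <= 0:
        return float("nan")
    warm = p[_SUMMER_N].sum()
    if hemisphere == "S":
        warm = total - warm
    return float(warm / total)


def classify_seasonality(pci_mean, monthly_precip, hemisphere="N",
                         threshold=PCI_THRESHOLD) -> str:
    """Classify the precipitation regime as uniform / summer / winter.

    Ties between the two half-year totals resolve to "winter" (the rule is
    "summer only if strictly larger").
    """
    if hemisphere not in ("N", "S"):
        raise ValueError(f"hemisphere must be N or S, got {hemisphere!r}")
    if pci_mean < threshold:
        return "uniform"
    return "summer" if summer_fraction(monthly_precip, hemisphere) > 0.5 else "winter"


def assign_mat_classes(environments) -> list[MATClass]:
    """Half-open 1 degC MAT classes: MAT t joins class [floor(t), floor(t)+1)."""
    classes: dict[int, MATClass] = {}
    for env in environments:
        lower = math.floor(env.mat)
        classes.setdefault(lower, MATClass(lower)).members.append(env.profile_id)
    return [classes[k] for k in sorted(classes)]


def environments_frame(environments, pci_threshold=PCI_THRESHOLD,
                       map_bin_mm=50.0) -> pd.DataFrame:
    """Per-profile covariate frame with derived seasonality, PCI and keys."""
    rows = []
    for env in environments:
        pci = compute_pci(env.monthly_precip)
        rows.append({
            "profile_id": env.profile_id, "mat": env.mat, "map": env.map,
            "landform": env.landform, "soil_order": env.soil_order,
            "suborder": env.suborder, "biome": env.biome,
            "elevation": env.elevation, "npp": env.npp,
            "aridity_index": env.aridity_index, "pci": pci,
            "summer_frac": summer_fraction(env.monthly_precip, env.hemisphere),
            "seasonality": classify_seasonality(pci, env.monthly_precip,
                                                env.hemisphere, pci_threshold),
            "class_lower": math.floor(env.mat),
            "map_bin": int(env.map // map_bin_mm),
        })
    return pd.DataFrame(rows)


def _summarize(sub: pd.DataFrame, key: GroupKey, class_lower: int) -> GroupSummary:
    vals = sub["response"].to_numpy()
    return GroupSummary(
        key=key, class_lower=class_lower, n=len(vals),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan"),
        mean_map=float(sub["map"].mean()), mean_mat=float(sub["mat"].mean()),
    )


def build_pairs(environments, harmonized: pd.DataFrame, layer: str,
                warming_level: int, response: str = "soc_s",
                map_tolerance_mm: float = 50.0, map_bin_mm: float = 50.0,
                min_n: int = 2, exclude_cropland: bool = False,
                min_group_n: int | None = None,
                pci_threshold: float = PCI_THRESHOLD,
                soil_column: str = "soil_order") -> list[PairedComparison]:
    """Form all ambient/warm paired comparisons at one warming level.

    ``harmonized`` is the tidy frame from :func:`soc_sft.profiles.harmonize_profiles`;
    ``response`` selects SOC stock ("soc_s") or content ("soc_c").  Groups are
    keyed by landform, soil type (``soil_column`` picks the vocabulary, e.g.
    "suborder" for the finer USDA level), seasonality and a fixed-width MAP
    bin; a pair is emitted when both groups have at least ``min_n`` profiles
    (so a standard deviation exists) and their mean MAPs differ by less than
    ``map_tolerance_mm``.  ``min_group_n`` applies the stricter group-size
    floor used in sensitivity analysis; ``exclude_cropland`` drops cultivated
    profiles before grouping.
    """
    if warming_level < 1:
        raise ValueError("warming_level must be >= 1")
    if min_n < 2:
        raise ValueError("min_n must be >= 2 (a standard deviation must exist)")

    env = environments if isinstance(environments, pd.DataFrame) else \
        environments_frame(environments, pci_threshold, map_bin_mm)
    if map_bin_mm is not None and "map_bin" in env.columns:
        env = env.copy()
        env["map_bin"] = (env["map"] // map_bin_mm).astype(int)

    values = harmonized[harmonized["layer"] == layer][
        ["profile_id", "soc_c", "soc_s", "covered", "is_cropland"]]
    data = env.merge(values, on="profile_id", how="inner")
    data = data[np.isfinite(data[response])]
    if exclude_cropland:
        data = data[~data["is_cropland"].astype(bool)]
    data = data.rename(columns={response: "response"})
    data = data[data["response"] > 0]

    floor_n = max(min_n, min_group_n or 0)
    pairs: list[PairedComparison] = []
    grouped = {k: g for k, g in data.groupby(
        ["class_lower", "landform", soil_column, "seasonality", "map_bin"])}
    for (cl, lf, so, se, mb), amb in sorted(grouped.items()):
        warm = grouped.get((cl + warming_level, lf, so, se, mb))
        if warm is None or len(amb) < floor_n or len(warm) < floor_n:
            continue
        key = GroupKey(lf, so, se, int(mb))
        a = _summarize(amb, key, int(cl))
        w = _summarize(warm, key, int(cl + warming_level))
        if abs(w.mean_map - a.mean_map) >= map_tolerance_mm:
            continue
        both = pd.concat([amb, warm])
        pairs.append(PairedComparison(
            warming_level=warming_level, layer=layer, ambient=a, warm=w,
            moderators={
                "baseline_soc": a.mean, "layer": layer,
                "soil_order": so, "landform": lf, "seasonality": se,
                "biome": both["biome"].mode().iloc[0],
                "mat": a.mean_mat, "map": a.mean_map,
                "delta_t": w.mean_mat - a.mean_mat,
                "delta_map": w.mean_map - a.mean_map,
                "elevation": float(both["elevation"].mean()),
                "npp": float(both["npp"].mean()),
                "aridity_index": float(both["aridity_index"].mean()),
                "pci": float(both["pci"].mean()),
                "summer_frac": float(both["summer_frac"].mean()),
            }))
    return pairs


def pairs_frame(pairs) -> pd.DataFrame:
    """Flatten paired comparisons into one row per pair (all moderators as columns)."""
    rows = []
    for p in pairs:
        rows.append({
            "warming_level": p.warming_level, "layer": p.layer,
            "ambient_n": p.ambient.n, "ambient_mean": p.ambient.mean, "ambient_sd": p.ambient.sd,
            "warm_n": p.warm.n, "warm_mean": p.warm.mean, "warm_sd": p.warm.sd,
            **{f"mod_{k}": v for k, v in p.moderators.items()},
        })
    return pd.DataFrame(rows)
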