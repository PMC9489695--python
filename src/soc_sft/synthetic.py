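"""Synthetic global soil-profile generator with known warming response.

Builds a miniature "world" of layered soil profiles whose steady-state SOC
obeys a known one-pool temperature law, so that the full space-for-time
pipeline (harmonize -> pair -> meta-analyse -> model fit) can be exercised
against analytic ground truth.

For each profile at mean annual temperature T, the expected SOC stock of
standard layer L is

    C_L(T) = I_L / (k0_L * Q10_L^(T/10))

— steady state C = I/k of a one-pool model whose decay rate scales with the
layer's temperature sensitivity Q10_L — multiplied by lognormal noise with a
configured coefficient of variation.  Carbon inputs I_L and base decay k0_L
decline with depth by fixed factors, giving realistic depth-decaying SOC.
Content (g/kg) is then back-derived from stock through a drawn bulk density
and gravel fraction, and the observed table is degraded with configurable
missingness so the imputation stage has work to do.  Cropland profiles get a
fixed multiplicative SOC depletion, giving the cropland-exclusion sensitivity
switch a signal to find.

The analytic percentage response of layer L to warming by dT is therefore

    100 * (I_ratio * Q10_L^(-dT/10) - 1),

available from :func:`true_response` for any input-change scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .profiles import LAYER_LABELS, STANDARD_LAYERS, SiteEnvironment, SoilLayer, SoilProfile

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "true_response", "write_world"]

#: sub-layer breaks used for the observed (pre-harmonization) layer scheme;
#: nested within the standard intervals so layer-scheme conversion is exact
#: in expectation while the spline still does real work.
OBSERVED_BREAKS = (0.0, 0.15, 0.3, 0.6, 1.0, 1.5, 2.0)

ARCHETYPES = ("summer", "winter", "uniform")


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world.

    Defaults emulate a mid-latitude slice of a global profile compilation:
    MAT spanning -5..25 degC so every 1 degC class is populated, MAP within a
    200 mm band so the 50 mm pairing criterion bites without emptying groups,
    lognormal multiplicative SOC noise of CV 0.3, one fifth of bulk-density
    and gravel records missing, and Q10 declining with depth.
    """

    n_profiles: int = 2000
    seed: int = 0
    mat_range: tuple[float, float] = (-5.0, 25.0)
    map_range: tuple[float, float] = (400.0, 600.0)
    q10_true_by_layer: tuple[float, float, float] = (1.7, 1.4, 1.2)
    input_per_degree: float = 0.0  # fractional carbon-input change per degC
    noise_cv: float = 0.3
    missing_bd_rate: float = 0.2
    missing_gravel_rate: float = 0.2
    landform_levels: tuple[str, ...] = ("plains", "plateaus", "mountains")
    soil_order_levels: tuple[str, ...] = ("mollisols", "alfisols", "inceptisols")
    biome_levels: tuple[str, ...] = ("boreal_forest", "temperate_forest", "grassland", "tundra")
    precip_archetype_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)  # summer/winter/uniform
    cropland_rate: float = 0.1
    cropland_depletion: float = 0.8  # multiplicative SOC factor on cropland
    # surface carbon input (kg C m^-2 yr^-1), base decay rate (yr^-1) and their
    # fixed decline factors with depth
    i0: float = 0.4
    k0: float = 0.02
    input_depth_factors: tuple[float, float, float] = (1.0, 0.3, 0.12)
    k_depth_factors: tuple[float, float, float] = (1.0, 0.4, 0.25)
    mat_distribution: str = "uniform"  # or "bimodal" (latitudinal clustering)

    def validate(self) -> None:
        for name in ("missing_bd_rate", "missing_gravel_rate", "cropland_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(q < 1 for q in self.q10_true_by_layer):
            raise ValueError("q10_true_by_layer entries must be >= 1")
        if not self.mat_range[0] < self.mat_range[1]:
            raise ValueError("mat_range is degenerate")
        if not self.map_range[0] < self.map_range[1]:
            raise ValueError("map_range is degenerate")
        if abs(sum(self.precip_archetype_weights) - 1.0) > 1e-9:
            raise ValueError("precip_archetype_weights must sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.input_per_degree < -1:
            raise ValueError("input_per_degree must be >= -1")
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in self.__dict__.items()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fields = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**fields)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    profiles: list[SoilProfile]
    environments: list[SiteEnvironment]
    #: (layer label, warming level) -> true percentage response under the
    #: config's carbon-input scenario
    truth: dict = field(default_factory=dict)

    def true_response(self, layer, delta_t, input_ratio=None):
        return true_response(self, layer, delta_t, input_ratio)


def _monthly_weights(archetype: str) -> np.ndarray:
    """Relative monthly precipitation shape for one seasonality archetype."""
    months = np.arange(12)
    if archetype == "uniform":
        return np.full(12, 1 / 12)
    peak = 6 if archetype == "summer" else 0  # July vs January (N hemisphere)
    dist = np.minimum(np.abs(months - peak), 12 - np.abs(months - peak))
    w = np.exp(-0.5 * (dist / 2.0) ** 2)
    return w / w.sum()


def true_response(world: SyntheticWorld, layer, delta_t, input_ratio=None) -> float:
    """Analytic percentage SOC response of a standard layer to ``delta_t`` warming.

    ``input_ratio`` is the warm/ambient carbon-input ratio; by default the
    world's configured per-degree input change, compounded: (1+r)^dT.
    """
    if isinstance(layer, int):
        layer = LAYER_LABELS[layer]
    if layer not in LAYER_LABELS:
        raise KeyError(f"unknown layer {layer!r}; expected one of {LAYER_LABELS}")
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    q10 = world.config.q10_true_by_layer[LAYER_LABELS.index(layer)]
    if input_ratio is None:
        input_ratio = (1.0 + world.config.input_per_degree) ** delta_t
    return 100.0 * (input_ratio * q10 ** (-delta_t / 10.0) - 1.0)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a full synthetic world.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_profiles

    if config.mat_distribution == "bimodal":
        lo, hi = config.mat_range
        span = hi - lo
        comp = rng.random(n) < 0.5
        mat = np.where(comp,
                       rng.normal(lo + 0.25 * span, span / 8, n),
                       rng.normal(lo + 0.75 * span, span / 8, n))
        mat = np.clip(mat, lo, hi - 1e-6)
    elif config.mat_distribution == "uniform":
        mat = rng.uniform(*config.mat_range, n)
    else:
        raise ValueError(f"unknown mat_distribution {config.mat_distribution!r}")

    map_mm = rng.uniform(*config.map_range, n)
    arch = rng.choice(len(ARCHETYPES), size=n, p=config.precip_archetype_weights)
    landform = rng.choice(config.landform_levels, n)
    soil_order = rng.choice(config.soil_order_levels, n)
    biome = rng.choice(config.biome_levels, n)
    cropland = rng.random(n) < config.cropland_rate

    sigma2 = np.log1p(config.noise_cv ** 2)
    sigma = np.sqrt(sigma2)

    q10 = np.asarray(config.q10_true_by_layer)
    i_layer = config.i0 * np.asarray(config.input_depth_factors)
    k_layer = config.k0 * np.asarray(config.k_depth_factors)

    profiles, environments = [], []
    for idx in range(n):
        pid = f"syn{idx:05d}"
        # expected steady-state stock per standard layer, with mean-1
        # lognormal noise so group means stay on the analytic law
        expect = i_layer / (k_layer * q10 ** (mat[idx] / 10.0))
        noise = np.exp(rng.normal(-sigma2 / 2, sigma, 3)) if sigma > 0 else np.ones(3)
        stock = expect * noise
        if cropland[idx]:
            stock = stock * config.cropland_depletion

        bd = np.clip(rng.normal(1300.0, 150.0, 3), 800.0, 1800.0)
        gravel = 50.0 * rng.beta(2.0, 8.0, 3)

        layers = []
        for top, bottom in zip(OBSERVED_BREAKS[:-1], OBSERVED_BREAKS[1:]):
            li = next(j for j, (t, b) in enumerate(STANDARD_LAYERS) if t <= top < b)
            t_std, b_std = STANDARD_LAYERS[li]
            soc_c = 1000.0 * stock[li] / ((b_std - t_std) * bd[li] * (1 - gravel[li] / 100.0))
            layers.append(SoilLayer(
                top=top, bottom=bottom, soc_c=soc_c,
                bd=None if rng.random() < config.missing_bd_rate else float(bd[li]),
                gravel=None if rng.random() < config.missing_gravel_rate else float(gravel[li]),
            ))
        profiles.append(SoilProfile(
            id=pid, latitude=float(rng.uniform(-60, 70)), longitude=float(rng.uniform(-180, 180)),
            layers=layers, is_cropland=bool(cropland[idx]),
        ))

        monthly = map_mm[idx] * _monthly_weights(ARCHETYPES[arch[idx]])
        elev_range = {"plains": (0, 300), "plateaus": (300, 1500), "mountains": (500, 3000)}
        lo, hi = elev_range.get(str(landform[idx]), (0, 1000))
        pet = max(300.0 + 30.0 * mat[idx], 50.0)  # crude PET proxy for the aridity index
        environments.append(SiteEnvironment(
            profile_id=pid, mat=float(mat[idx]), monthly_precip=monthly,
            map=float(map_mm[idx]), landform=str(landform[idx]),
            soil_order=str(soil_order[idx]), biome=str(biome[idx]),
            elevation=float(rng.uniform(lo, hi)),
            npp=float(max(rng.normal(20 * mat[idx] + 0.5 * map_mm[idx], 50.0), 1.0)),
            aridity_index=float(map_mm[idx] / pet), hemisphere="N",
        ))

    world = SyntheticWorld(config, profiles, environments)
    world.truth = {(label, dt): world.true_response(label, dt)
                   for label in LAYER_LABELS for dt in range(1, 6)}
    return world


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write profiles, environments and config as text files under ``out_dir``."""
    from pathlib import Path

    from .profiles import write_environments, write_profiles

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_profiles(world.profiles, out / "profiles.csv")
    write_environments(world.environments, out / "environments.csv")
    world.config.to_yaml(out / "config.yml")
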