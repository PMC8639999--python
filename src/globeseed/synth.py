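"""Synthetic seed bank datasets, predictor tables and predictor grids.

The generator emulates the statistical structure of a compiled global seed
bank survey database: two response types (diversity = species per sample,
density = seeds per m2), stratification over the 14 TEOW biomes, mixed
sampling seasons / quadrat areas / soil depth slices, a hemispheric sampling
imbalance, and environmental effects with known shapes (e.g. a humped pH
response, a latitudinal trend).  Every latent quantity and true parameter is
written to a ground-truth ledger so downstream recovery can be tested.

Observed values are generated multiplicatively::

    observed = latent x season multiplier x (A / 0.01)^Z  [diversity]
                      x 10^(b1*u + b2*(l - 5))            [depth slice (u, l)]
                      x A                                  [density raw counts]
                      x lognormal(sigma) noise

which makes the ratio- and regression-based standardization corrections
exactly identifiable at ``sigma = 0`` under a balanced crossed design (see
``inversion_config``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    BIOMES,
    MEASURES,
    PREDICTOR_NAMES,
    SEASONS,
    SeedBankRecord,
    is_tropical,
)

__all__ = [
    "Effect",
    "GeneratorConfig",
    "default_config",
    "inversion_config",
    "species_area_config",
    "modeling_config",
    "generate_dataset",
    "generate_grid",
    "true_response",
    "PredictorGridBundle",
]

# Plausible generation range per covariate (units as in the covariate table).
PREDICTOR_RANGES: dict[str, tuple[float, float]] = {
    "abs.latit": (0.0, 90.0),
    "AMT": (-15.0, 30.0),
    "AP": (50.0, 3500.0),
    "ATR": (5.0, 60.0),
    "AVWAC": (2.0, 30.0),
    "BULK": (0.8, 1.8),
    "CEC": (2.0, 60.0),
    "CLAYC": (2.0, 60.0),
    "diversity": (0.1, 10.0),
    "HFP": (0.0, 50.0),
    "Isoth": (20.0, 95.0),
    "npp": (50.0, 2500.0),
    "ORGNC": (1.0, 120.0),
    "PCQ": (0.0, 900.0),
    "PDM": (0.0, 120.0),
    "PDQ": (0.0, 400.0),
    "pH": (3.5, 9.5),
    "Pseason": (5.0, 140.0),
    "PWeQ": (50.0, 1500.0),
    "PWM": (20.0, 600.0),
    "PWQ": (10.0, 1200.0),
    "SANDC": (5.0, 95.0),
    "SILTC": (2.0, 70.0),
    "TCM": (-40.0, 20.0),
    "TCQ": (-30.0, 25.0),
    "TDQ": (-25.0, 30.0),
    "TDR": (4.0, 20.0),
    "Tseason": (50.0, 1500.0),
    "TWeQ": (-10.0, 30.0),
    "TWM": (5.0, 45.0),
    "TWQ": (0.0, 35.0),
}

# Rough latitude band (absolute degrees) per biome, used to place records.
BIOME_LAT_BANDS: dict[str, tuple[float, float]] = {
    "TSMF": (0, 20), "TSDF": (5, 23), "TSCF": (10, 25), "MAN": (0, 25),
    "TSGS": (5, 25), "FGS": (0, 40), "MGS": (10, 50), "DXS": (15, 40),
    "MFWS": (30, 45), "TBMF": (30, 55), "TCF": (35, 55), "TGSS": (30, 55),
    "BFT": (50, 70), "TUN": (60, 80),
}


@dataclass
class Effect:
    """One environmental effect on the log latent response.

    shape: ``linear`` (coef * standardized x), ``humped``
    (coef * Gaussian bump at ``center`` with sd ``width``) or ``threshold``
    (coef where x > ``threshold``).
    """

    shape: str
    coef: float
    center: float | None = None
    width: float | None = None
    threshold: float | None = None

    def evaluate(self, name: str, x: np.ndarray) -> np.ndarray:
        lo, hi = PREDICTOR_RANGES[name]
        x = np.asarray(x, dtype=float)
        if self.shape == "linear":
            return self.coef * (x - lo) / (hi - lo)
        if self.shape == "humped":
            if not (lo <= self.center <= hi):
                raise ValueError(f"humped center for {name} outside its range")
            return self.coef * np.exp(-0.5 * ((x - self.center) / self.width) ** 2)
        if self.shape == "threshold":
            return self.coef * (x > self.threshold)
        raise ValueError(f"unknown effect shape {self.shape!r}")


def _default_biome_weights() -> dict[str, float]:
    w = {
        "TBMF": 0.18, "TCF": 0.10, "TGSS": 0.14, "MFWS": 0.08, "BFT": 0.06,
        "TUN": 0.04, "MGS": 0.05, "DXS": 0.06, "FGS": 0.03,
        "TSMF": 0.10, "TSDF": 0.05, "TSCF": 0.04, "TSGS": 0.05, "MAN": 0.02,
    }
    s = sum(w.values())
    return {k: v / s for k, v in w.items()}


def _default_effects() -> dict[str, dict[str, Effect]]:
    return {
        "diversity": {
            "pH": Effect("humped", coef=0.9, center=6.5, width=1.0),
            "AP": Effect("linear", coef=0.8),
            "abs.latit": Effect("humped", coef=0.6, center=40.0, width=25.0),
            "CEC": Effect("linear", coef=0.5),
            "SILTC": Effect("linear", coef=0.4),
        },
        "density": {
            "npp": Effect("linear", coef=1.0),
            "abs.latit": Effect("linear", coef=0.9),
            "BULK": Effect("linear", coef=-0.6),
            "ORGNC": Effect("linear", coef=0.5),
            "PDM": Effect("linear", coef=0.4),
        },
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world, with defaults at realistic survey scale."""

    n_records: int = 800  # per measure
    biome_weights: dict[str, float] = field(default_factory=_default_biome_weights)
    fraction_tropical: float | None = None  # if set, renormalizes biome groups
    hemisphere_north_fraction: float = 0.8
    season_weights: dict[str, float] = field(
        default_factory=lambda: {"spring": 0.3, "summer": 0.25, "autumn": 0.25, "winter": 0.2}
    )
    area_values: tuple[float, ...] = (0.0025, 0.005, 0.01, 0.02, 0.04, 0.1)
    area_weights: tuple[float, ...] = (0.1, 0.15, 0.4, 0.15, 0.1, 0.1)
    depth_slices: tuple[tuple[float, float], ...] = ((0, 5), (0, 10), (5, 10), (0, 2), (2, 5))
    depth_weights: tuple[float, ...] = (0.45, 0.2, 0.1, 0.1, 0.15)
    # True standardization parameters.
    season_multipliers: dict[str, float] = field(
        default_factory=lambda: {"winter": 1.0, "spring": 0.8, "summer": 0.6, "autumn": 0.75}
    )
    species_area_z: dict[str, float] = field(
        default_factory=lambda: {b: 0.2 + 0.01 * i for i, b in enumerate(sorted(BIOMES))}
    )
    depth_slopes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"diversity": (-0.03, 0.02), "density": (-0.04, 0.03)}
    )
    # Latent baselines: diversity = species per 0.01 m2, density = seeds m-2,
    # both at the 0-5 cm slice in winter.
    diversity_baseline: dict[str, float] = field(
        default_factory=lambda: {b: 4.0 + 0.4 * i for i, b in enumerate(sorted(BIOMES))}
    )
    density_baseline: dict[str, float] = field(
        default_factory=lambda: {b: 800.0 + 150.0 * i for i, b in enumerate(sorted(BIOMES))}
    )
    effects: dict[str, dict[str, Effect]] = field(default_factory=_default_effects)
    sigma: float = 0.3  # lognormal noise on responses (log scale, base e)
    predictor_noise: float = 0.05  # iid relative noise on coupled predictors
    # Sampling-time reporting mix: month only / season only / both / neither.
    time_reporting: tuple[float, float, float, float] = (0.5, 0.3, 0.18, 0.02)
    balanced_design: bool = False
    # Grid generation.
    grid_extent: tuple[float, float, float, float] = (25.0, 55.0, 0.0, 30.0)
    grid_resolution_arcmin: float = 30.0
    grid_correlation_cells: float = 4.0

    def validate(self) -> None:
        for name, mix in [
            ("biome_weights", self.biome_weights.values()),
            ("season_weights", self.season_weights.values()),
            ("area_weights", self.area_weights),
            ("depth_weights", self.depth_weights),
        ]:
            if abs(sum(mix) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if any(m <= 0 for m in self.season_multipliers.values()):
            raise ValueError("season multipliers must be positive")
        for measure, effs in self.effects.items():
            for pred, eff in effs.items():
                if pred not in PREDICTOR_NAMES:
                    raise ValueError(f"unknown predictor {pred!r} in effects")
                if eff.shape == "humped":
                    lo, hi = PREDICTOR_RANGES[pred]
                    if not (lo <= eff.center <= hi):
                        raise ValueError(f"humped center for {pred} outside range")


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def inversion_config(n_records: int = 400) -> GeneratorConfig:
    """Noise-free, balanced, biome-constant world where standardization is
    exactly invertible.

    Latent responses are constant within (and, for non-tropical biomes, across)
    biomes and season/area/depth assignments are fully crossed, so the fitted
    season ratios and area/depth regressions reproduce the generating
    distortions exactly and the standardization chain recovers the latent
    values elementwise.
    """
    biomes = {"TBMF": 0.5, "TSMF": 0.25, "TGSS": 0.25}
    cfg = GeneratorConfig(
        n_records=n_records,
        biome_weights=biomes,
        sigma=0.0,
        effects={"diversity": {}, "density": {}},
        diversity_baseline={b: 6.0 for b in BIOMES},
        density_baseline={b: 1500.0 for b in BIOMES},
        balanced_design=True,
        time_reporting=(0.0, 1.0, 0.0, 0.0),
    )
    cfg.validate()
    return cfg


def species_area_config(sigma: float = 0.2, n_records: int = 500) -> GeneratorConfig:
    """Species-area focused world: varied quadrat areas, single depth slice,
    winter sampling, constant latent baselines — isolates the power-law fit."""
    cfg = GeneratorConfig(
        n_records=n_records,
        biome_weights={"TBMF": 0.5, "TGSS": 0.5},
        sigma=sigma,
        effects={"diversity": {}, "density": {}},
        diversity_baseline={b: 6.0 for b in BIOMES},
        density_baseline={b: 1500.0 for b in BIOMES},
        season_weights={"winter": 1.0, "spring": 0.0, "summer": 0.0, "autumn": 0.0},
        depth_slices=((0, 5),),
        depth_weights=(1.0,),
        area_weights=(1 / 6,) * 6,
        time_reporting=(0.0, 1.0, 0.0, 0.0),
    )
    cfg.validate()
    return cfg


def modeling_config(
    effects: dict[str, dict[str, Effect]] | None = None,
    sigma: float = 0.2,
    n_records: int = 1000,
) -> GeneratorConfig:
    """World with degenerate sampling conventions (already standard: winter,
    0.01 m2, 0-5 cm) so observed = latent x noise; for modeling-stage tests."""
    cfg = GeneratorConfig(
        n_records=n_records,
        sigma=sigma,
        effects=effects if effects is not None else _default_effects(),
        season_weights={"winter": 1.0, "spring": 0.0, "summer": 0.0, "autumn": 0.0},
        area_values=(0.01,),
        area_weights=(1.0,),
        depth_slices=((0, 5),),
        depth_weights=(1.0,),
        time_reporting=(0.0, 1.0, 0.0, 0.0),
    )
    cfg.validate()
    return cfg


# month pools per (season, hemisphere); hemisphere-aware meteorological seasons
_SEASON_MONTHS_N = {"winter": (12, 1, 2), "spring": (3, 4, 5), "summer": (6, 7, 8), "autumn": (9, 10, 11)}
_SEASON_MONTHS_S = {"winter": (6, 7, 8), "spring": (9, 10, 11), "summer": (12, 1, 2), "autumn": (3, 4, 5)}


def _draw_predictors(rng: np.random.Generator, lat: np.ndarray, cfg: GeneratorConfig) -> pd.DataFrame:
    """Covariates: mostly independent uniforms in range; temperature, NPP and
    absolute latitude are coupled to latitude so the world has a climate
    gradient."""
    n = len(lat)
    data: dict[str, np.ndarray] = {}
    abslat = np.abs(lat)
    for name, (lo, hi) in PREDICTOR_RANGES.items():
        if name == "abs.latit":
            data[name] = abslat
            continue
        u = rng.uniform(lo, hi, size=n)
        data[name] = u
    # climate coupling
    amt = 27.0 - 0.45 * abslat
    amt = amt * (1 + cfg.predictor_noise * rng.standard_normal(n))
    data["AMT"] = np.clip(amt, *PREDICTOR_RANGES["AMT"])
    tcm = data["AMT"] - 10.0 - 0.2 * abslat
    data["TCM"] = np.clip(tcm + 2 * rng.standard_normal(n), *PREDICTOR_RANGES["TCM"])
    npp = 100.0 + 0.6 * data["AP"] + 25.0 * np.clip(data["AMT"], 0, None)
    npp = npp * (1 + cfg.predictor_noise * rng.standard_normal(n))
    data["npp"] = np.clip(npp, *PREDICTOR_RANGES["npp"])
    return pd.DataFrame(data, columns=list(PREDICTOR_NAMES))


def true_response(
    predictors: pd.DataFrame | Mapping[str, float],
    config: GeneratorConfig,
    measure: str,
    biome: str | None = None,
) -> np.ndarray:
    """Latent response (diversity per 0.01 m2 or density per m2, winter,
    0-5 cm) under the configured effect shapes; deterministic."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if isinstance(predictors, Mapping) and not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame([predictors])
    baselines = (
        config.diversity_baseline if measure == "diversity" else config.density_baseline
    )
    if biome is None:
        base = float(np.exp(np.mean(np.log(list(baselines.values())))))
    else:
        base = baselines[biome]
    log_effect = np.zeros(len(predictors))
    for name, eff in config.effects.get(measure, {}).items():
        if name not in predictors.columns:
            raise ValueError(f"predictor {name!r} missing from vector")
        col = predictors[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"predictor {name!r} has missing values")
        log_effect = log_effect + eff.evaluate(name, col)
    return base * np.exp(log_effect)


def _draw_design(rng, cfg: GeneratorConfig, weights: np.ndarray, biome_names: list[str]):
    """Assign (biome, season, area, depth slice) per record.

    Random mixtures by default.  With ``balanced_design`` the full cross
    biome x season x area x slice is tiled deterministically and n is rounded
    up to a whole number of crossings, which makes every stratum composition
    identical — the condition under which the ratio/regression corrections of
    the standardization stage are exactly identifiable at sigma = 0.
    """
    n = cfg.n_records
    seasons = [s for s in cfg.season_weights if cfg.season_weights[s] > 0]
    if cfg.balanced_design:
        cross = list(
            itertools.product(biome_names, seasons, cfg.area_values, cfg.depth_slices)
        )
        reps = max(1, math.ceil(n / len(cross)))
        picks = cross * reps
        n = len(picks)
        biomes = np.array([p[0] for p in picks])
        season = np.array([p[1] for p in picks])
        area = np.array([p[2] for p in picks])
        slc = [p[3] for p in picks]
    else:
        biomes = rng.choice(biome_names, size=n, p=weights)
        season = rng.choice(
            seasons, size=n, p=[cfg.season_weights[s] for s in seasons]
        )
        area = rng.choice(cfg.area_values, size=n, p=cfg.area_weights)
        idx = rng.choice(len(cfg.depth_slices), size=n, p=cfg.depth_weights)
        slc = [cfg.depth_slices[i] for i in idx]
    return n, biomes, season, area, slc


def generate_dataset(
    config: GeneratorConfig, seed: int
) -> tuple[list[SeedBankRecord], pd.DataFrame, dict]:
    """Generate records + predictor table + ground-truth ledger.

    Reproducible given (config, seed).  The ledger stores every latent
    standardized value, the true parameters and bookkeeping tallies; the
    tropical share, season composition etc. follow the configured mixtures.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    if len(config.area_values) < 2:
        warnings.append("single sampling area: species-area fit not identifiable")
    if len(config.depth_slices) < 2:
        warnings.append("single depth slice: depth regression not identifiable")

    biome_names = sorted(config.biome_weights)
    weights = np.array([config.biome_weights[b] for b in biome_names], dtype=float)
    if config.fraction_tropical is not None:
        trop = np.array([is_tropical(b) for b in biome_names])
        wt = weights * trop
        wn = weights * ~trop
        if wt.sum() == 0 or wn.sum() == 0:
            raise ValueError("fraction_tropical needs both biome groups in the mixture")
        weights = (
            config.fraction_tropical * wt / wt.sum()
            + (1 - config.fraction_tropical) * wn / wn.sum()
        )
    weights = weights / weights.sum()

    records: list[SeedBankRecord] = []
    pred_frames: list[pd.DataFrame] = []
    latents: dict[str, float] = {}
    biome_counts: dict[str, dict[str, int]] = {m: {} for m in MEASURES}

    for measure in MEASURES:
        n, biomes, season, area, slices = _draw_design(rng, config, weights, biome_names)
        north = rng.random(n) < config.hemisphere_north_fraction
        lat = np.empty(n)
        for i, b in enumerate(biomes):
            lo, hi = BIOME_LAT_BANDS[b]
            a = rng.uniform(lo, hi)
            lat[i] = a if north[i] else -a
        lon = rng.uniform(-180, 180, size=n)
        preds = _draw_predictors(rng, lat, config)
        trop_mask = np.array([is_tropical(b) for b in biomes])
        baselines = (
            config.diversity_baseline if measure == "diversity" else config.density_baseline
        )
        log_eff = np.zeros(n)
        for name, eff in config.effects.get(measure, {}).items():
            log_eff += eff.evaluate(name, preds[name].to_numpy())
        latent = np.array([baselines[b] for b in biomes]) * np.exp(log_eff)
        noise = (
            np.exp(config.sigma * rng.standard_normal(n)) if config.sigma > 0 else np.ones(n)
        )
        b1, b2 = config.depth_slopes[measure]
        rep_draw = rng.random(n)
        p_m, p_s, p_b, _ = config.time_reporting
        for i in range(n):
            u, low = slices[i]
            depth_factor = 10.0 ** (b1 * (u - 0.0) + b2 * (low - 5.0))
            m_s = 1.0 if trop_mask[i] else config.season_multipliers[season[i]]
            if measure == "diversity":
                z = config.species_area_z[biomes[i]]
                value = latent[i] * (area[i] / 0.01) ** z * depth_factor * m_s * noise[i]
            else:
                value = latent[i] * depth_factor * m_s * area[i] * noise[i]
            months = (_SEASON_MONTHS_N if lat[i] >= 0 else _SEASON_MONTHS_S)[season[i]]
            month = int(rng.choice(months))
            r = rep_draw[i]
            rec_month: int | None = month
            rec_season: str | None = season[i]
            if r < p_m:
                rec_season = None
            elif r < p_m + p_s:
                rec_month = None
            elif r >= p_m + p_s + p_b:
                rec_month = None
                rec_season = None
            rid = f"{measure[:3]}-{i:05d}"
            records.append(
                SeedBankRecord(
                    record_id=rid,
                    latitude=float(lat[i]),
                    longitude=float(lon[i]),
                    biome=str(biomes[i]),
                    measure=measure,
                    value=float(value),
                    sample_area_m2=float(area[i]),
                    depth_upper_cm=float(u),
                    depth_lower_cm=float(low),
                    sampling_month=rec_month,
                    season=rec_season,
                )
            )
            latents[rid] = float(latent[i])
            bc = biome_counts[measure]
            bc[str(biomes[i])] = bc.get(str(biomes[i]), 0) + 1
        pf = preds.copy()
        pf.insert(0, "record_id", [f"{measure[:3]}-{i:05d}" for i in range(n)])
        pred_frames.append(pf)

    predictor_table = pd.concat(pred_frames, ignore_index=True).set_index("record_id")
    truth = {
        "seed": seed,
        "params": {
            "season_multipliers": dict(config.season_multipliers),
            "season_ratios_true": {
                s: 1.0 / m for s, m in config.season_multipliers.items()
            },
            "species_area_z": dict(config.species_area_z),
            "depth_slopes": {k: list(v) for k, v in config.depth_slopes.items()},
            "diversity_baseline": dict(config.diversity_baseline),
            "density_baseline": dict(config.density_baseline),
            "sigma": config.sigma,
            "effects": {
                m: {p: vars(e) for p, e in effs.items()}
                for m, effs in config.effects.items()
            },
        },
        "latent": latents,
        "biome_counts": biome_counts,
        "warnings": warnings,
    }
    return records, predictor_table, truth


def grid_nominal_range_km(config: GeneratorConfig) -> float:
    """Variogram range implied by the grid smoothing.

    Gaussian smoothing with sd ``grid_correlation_cells`` gives a field with
    correlation exp(-h^2 / (4 sigma^2)); the semivariogram reaches 95% of its
    sill at h = 2 sqrt(ln 20) sigma ~ 3.46 sigma cells.
    """
    cell_km = config.grid_resolution_arcmin / 60.0 * 111.0
    return 2.0 * math.sqrt(math.log(20.0)) * config.grid_correlation_cells * cell_km


@dataclass
class PredictorGridBundle:
    """In-memory gridded covariate stack (one 2-D layer per covariate)."""

    layers: dict[str, np.ndarray]  # name -> (nrow, ncol), NaN = nodata
    lat: np.ndarray  # cell-center latitudes, length nrow, descending
    lon: np.ndarray  # cell-center longitudes, length ncol, ascending
    resolution_arcmin: float


def generate_grid(config: GeneratorConfig, seed: int) -> PredictorGridBundle:
    """Smooth random covariate fields on a lat/lon grid.

    Each layer is Gaussian-smoothed white noise (correlation length
    ``grid_correlation_cells`` cells) rescaled into the covariate's range;
    ``abs.latit`` is computed from the cell-center latitude, and temperature
    and NPP keep their latitudinal coupling.
    """
    config.validate()
    if config.grid_resolution_arcmin <= 0:
        raise ValueError("grid resolution must be positive")
    rng = np.random.default_rng(seed)
    lat_min, lat_max, lon_min, lon_max = config.grid_extent
    step = config.grid_resolution_arcmin / 60.0
    lat = np.arange(lat_max - step / 2, lat_min, -step)
    lon = np.arange(lon_min + step / 2, lon_max, step)
    nrow, ncol = len(lat), len(lon)
    abslat2d = np.tile(np.abs(lat)[:, None], (1, ncol))

    def smooth_field(lo: float, hi: float) -> np.ndarray:
        white = rng.standard_normal((nrow, ncol))
        f = ndimage.gaussian_filter(white, sigma=config.grid_correlation_cells, mode="reflect")
        f = (f - f.mean()) / (f.std() + 1e-12)
        # map ~N(0,1) through a logistic squashing into (lo, hi)
        return lo + (hi - lo) / (1.0 + np.exp(-1.2 * f))

    layers: dict[str, np.ndarray] = {}
    for name, (lo, hi) in PREDICTOR_RANGES.items():
        if name == "abs.latit":
            layers[name] = abslat2d.copy()
        else:
            layers[name] = smooth_field(lo, hi)
    # same latitudinal couplings as the tabular generator (one world)
    amt = 27.0 - 0.45 * abslat2d + 2.0 * (layers["AMT"] - np.mean(layers["AMT"])) / (
        np.std(layers["AMT"]) + 1e-12
    )
    layers["AMT"] = np.clip(amt, *PREDICTOR_RANGES["AMT"])
    tcm = layers["AMT"] - 10.0 - 0.2 * abslat2d + 2.0 * (
        layers["TCM"] - np.mean(layers["TCM"])
    ) / (np.std(layers["TCM"]) + 1e-12)
    layers["TCM"] = np.clip(tcm, *PREDICTOR_RANGES["TCM"])
    npp = 100.0 + 0.6 * layers["AP"] + 25.0 * np.clip(layers["AMT"], 0, None)
    layers["npp"] = np.clip(npp, *PREDICTOR_RANGES["npp"])
    return PredictorGridBundle(
        layers=layers, lat=lat, lon=lon, resolution_arcmin=config.grid_resolution_arcmin
    )
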