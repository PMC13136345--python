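"""Synthetic pipeline inputs with known ground truth.

The generator emulates the data a regional Earth-system experiment would
provide — categorical land-system maps for a reference and a scenario, a
land-system→habitat crosswalk with per-cell suitability scores, a
vegetation-plot table with species→PFT assignments, and multi-year gridded
climate fields for both runs — while planting a known linear
transition-response model so every downstream stage has an analytic
expectation.

Rather than running an atmosphere, the climate generator works backwards
from the target skin-temperature response: the multi-year mean scenario −
reference ΔTs per cell is drawn from Σ_p β_p·x_p + offset + spatial noise
(x_p the cell's net transition fractions), the implied flux perturbation
ΔF = ΔTs/λ is allocated across latent heat, sensible heat, albedo, and
downwelling short-/longwave radiation by configurable weights, and the
ground heat flux closes the surface energy balance exactly in every cell,
year, and run. Interannual temperature anomalies follow an AR(1) process
shared between runs (the paired-simulation analogy), daily 2 m maxima add a
seasonal cycle plus Gumbel excursions so the TXx extreme index is well
defined, and auxiliary variables (precipitation, soil moisture and
temperature, wind, GPP) are independent fields with configurable scenario
offsets.

All randomness flows from one root seed through named substreams, so any
individual output is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import transitions as tr
from .energy_balance import STEFAN_BOLTZMANN, SurfaceEnergyState, close_balance
from .pft import CATEGORIES, DEFAULT_SCHEMA, N_CATEGORIES
from .translate import (
    HabitatComposition,
    PftFractionGrid,
    habitat_composition_from_plots,
    translate_land_systems,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "LandSystemData",
    "AttributionFixture",
    "generate_land_systems",
    "generate_plot_table",
    "generate_pft_grids",
    "make_truth",
    "generate_climate_fields",
    "generate_recent_climate",
    "make_attribution_fixture",
    "ar1_series",
    "sensitivity_matrix",
    "delta_t_from_flows",
]

EULER_GAMMA = 0.5772156649015329


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _default_sensitivities() -> dict[tuple[str, str], float]:
    """Planted temperature sensitivities (°C per unit transition fraction).

    Keys are category pairs in canonical order; the value applies to the
    low-index → high-index direction (the reverse direction is its negation).
    Signs follow the qualitative behaviour of mid-latitude land-cover
    change experiments: conversion of forest to cropland cools in summer,
    cropland to grassland warms, loss of vegetation to bare ground warms.
    """
    c = CATEGORIES
    return {
        (c[0], c[1]): 0.2,
        (c[0], c[2]): 0.4,
        (c[0], c[3]): 0.6,
        (c[0], c[4]): -0.5,
        (c[0], c[5]): -0.8,
        (c[0], c[6]): 1.2,
        (c[1], c[2]): 0.3,
        (c[1], c[3]): 0.5,
        (c[1], c[4]): -0.3,
        (c[1], c[5]): -0.6,
        (c[1], c[6]): 1.0,
        (c[2], c[3]): 0.2,
        (c[2], c[4]): -0.4,
        (c[2], c[5]): -0.7,
        (c[2], c[6]): 0.8,
        (c[3], c[4]): -0.9,
        (c[3], c[5]): -1.2,
        (c[3], c[6]): 0.7,
        (c[4], c[5]): -0.3,
        (c[4], c[6]): 1.1,
        (c[5], c[6]): 1.5,
    }


def _default_allocation() -> dict[str, float]:
    # share of the required flux perturbation carried by each balance term
    return {
        "latent": 0.40,
        "sensible": 0.25,
        "albedo": 0.10,
        "sw_down": 0.15,
        "lw_down": 0.10,
    }


def _default_aux_offsets() -> dict[str, float]:
    # scenario offset per unit cell change fraction, in variable units
    return {
        "precip": -0.3,  # mm/day
        "soil_moisture": -0.01,  # m3/m3
        "soil_temp": 0.3,  # K
        "wind": 0.05,  # m/s
        "gpp": -0.8,  # gC/m2/day
    }


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic experiment.

    Defaults emulate a 15-year analysis window on a 120×120 fine grid
    coarsened ×3 to the 40×40 analysis grid, with roughly a third of fine
    cells changing land system between reference and scenario.
    """

    fine_grid_shape: tuple[int, int] = (120, 120)
    coarsen_factor: int = 3
    n_years: int = 15
    n_days_per_year: int = 365
    n_scenarios: int = 1
    scenario_change_fraction: float = 0.35
    true_sensitivities: dict[tuple[str, str], float] = field(
        default_factory=_default_sensitivities
    )
    nonlocal_offset: float = 0.08  # °C, spatially uniform
    noise_sd_space: float = 0.05  # °C, per-cell noise on mean ΔTs
    ar1_coefficient: float = 0.45
    noise_sd_year: float = 0.4  # °C, marginal sd of interannual anomalies
    seed: int = 0
    n_land_systems: int = 10
    n_habitats: int = 8
    n_species: int = 32
    n_plots: int = 80
    allocation_weights: dict[str, float] = field(default_factory=_default_allocation)
    aux_offsets: dict[str, float] = field(default_factory=_default_aux_offsets)
    daily_gumbel_scale: float = 2.0  # °C, daily excursion scale
    seasonal_amplitude: float = 8.0  # °C, annual cycle of daily maxima
    recent_offset: float = 0.6  # °C, warming of the future reference vs recent

    def __post_init__(self) -> None:
        ny, nx = self.fine_grid_shape
        if ny <= 0 or nx <= 0:
            raise ValueError("zero-area fine grid")
        if self.coarsen_factor < 1 or ny % self.coarsen_factor or nx % self.coarsen_factor:
            raise ValueError("coarsen factor must divide the fine grid shape")
        if self.noise_sd_space < 0 or self.noise_sd_year < 0:
            raise ValueError("noise scales must be non-negative")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|AR(1) coefficient| must be < 1")
        if not 0.0 <= self.scenario_change_fraction <= 1.0:
            raise ValueError("scenario change fraction must lie in [0, 1]")
        if self.n_plots < self.n_habitats:
            raise ValueError("need at least one plot per habitat")
        w = sum(self.allocation_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("allocation weights must sum to 1")

    @property
    def coarse_grid_shape(self) -> tuple[int, int]:
        f = self.coarsen_factor
        return self.fine_grid_shape[0] // f, self.fine_grid_shape[1] // f


@dataclass
class SyntheticTruth:
    """Hidden generator parameters, kept for recovery tests only.

    Analysis modules never read this object.
    """

    true_sensitivities: dict[tuple[str, str], float]
    realized_offset: float  # °C
    noise: np.ndarray  # (ny, nx) per-cell spatial noise, °C
    delta_ts_target: np.ndarray | None = None  # (ny, nx) planted mean ΔTs, °C

    def expected_coefficients(self, oriented: tr.OrientedTransitions) -> np.ndarray:
        """Planted β for each oriented transition type, sign-aligned."""
        out = np.empty(len(oriented.pairs))
        for k, (a, b) in enumerate(oriented.pairs):
            i, j = min(a, b), max(a, b)
            beta = self.true_sensitivities[(CATEGORIES[i], CATEGORIES[j])]
            out[k] = beta if (a, b) == (i, j) else -beta
        return out


def sensitivity_matrix(
    sensitivities: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """(7, 7) antisymmetric matrix B with B[i, j] = β for the i→j direction."""
    b = np.zeros((N_CATEGORIES, N_CATEGORIES))
    for (name_i, name_j), beta in sensitivities.items():
        i, j = CATEGORIES.index(name_i), CATEGORIES.index(name_j)
        b[i, j] = beta
        b[j, i] = -beta
    return b


def delta_t_from_flows(
    flows: np.ndarray, sensitivities: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """Planted linear temperature response Σ β_ij (flow_ij − flow_ji), °C."""
    b = sensitivity_matrix(sensitivities)
    return np.tensordot(b, flows, axes=2)


def ar1_series(
    n: int, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series with lag-1 coefficient rho and marginal sd."""
    a = np.empty(n)
    if sd == 0:
        return np.zeros(n)
    a[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        a[t] = rho * a[t - 1] + rng.normal(0.0, innov_sd)
    return a


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 3.0) -> np.ndarray:
    """Spatially correlated field in [0, 1] (smoothed uniform noise)."""
    raw = ndimage.gaussian_filter(rng.random(shape), sigma=sigma, mode="wrap")
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


# ---------------------------------------------------------------------------
# land systems, crosswalk, suitability

#: Habitat archetypes: name, land-unit tag, and PFT-slot weights used both
#: for species→PFT assignment and (through plots) habitat composition.
_ARCHETYPES: tuple[tuple[str, str, dict[int, float]], ...] = (
    ("needleleaf forest", "natural", {1: 0.5, 2: 0.3, 13: 0.2}),
    ("broadleaf forest", "natural", {5: 0.3, 7: 0.5, 13: 0.2}),
    ("shrubland", "natural", {9: 0.25, 10: 0.3, 11: 0.15, 13: 0.3}),
    ("grassland", "natural", {12: 0.2, 13: 0.6, 14: 0.2}),
    ("cropland", "cropland", {15: 0.9, 13: 0.1}),
    ("irrigated cropland", "cropland", {16: 0.9, 13: 0.1}),
    ("mixed forest", "natural", {1: 0.35, 7: 0.35, 10: 0.15, 13: 0.15}),
    ("arctic meadow", "natural", {12: 0.7, 11: 0.3}),
)


def habitat_archetype(code: int) -> tuple[str, str, dict[int, float]]:
    return _ARCHETYPES[code % len(_ARCHETYPES)]


@dataclass
class LandSystemData:
    """Fine-grid categorical maps plus the crosswalk and suitability inputs."""

    reference_map: np.ndarray  # (fy, fx) land-system codes
    scenario_map: np.ndarray
    crosswalk: dict[int, list[int]]  # land system -> candidate habitats
    suitability: dict[int, np.ndarray]  # habitat -> (fy, fx) score >= 0
    habitat_tags: dict[int, str]  # habitat -> natural/cropland/ice/urban


def generate_land_systems(config: SyntheticConfig) -> LandSystemData:
    """Reference and scenario land-system maps with crosswalk and suitability.

    The scenario map differs from the reference on an independent Bernoulli
    fraction of fine cells (``scenario_change_fraction``); changed cells get
    a different land-system code drawn uniformly from the others.
    """
    rng = substream(config.seed, "land_systems")
    fy, fx = config.fine_grid_shape
    n_ls = config.n_land_systems
    ref = rng.integers(0, n_ls, size=(fy, fx))

    change = rng.random((fy, fx)) < config.scenario_change_fraction
    shift = rng.integers(1, n_ls, size=(fy, fx)) if n_ls > 1 else np.zeros((fy, fx), int)
    scen = np.where(change, (ref + shift) % n_ls, ref)

    crosswalk: dict[int, list[int]] = {}
    for code in range(n_ls):
        primary = code % config.n_habitats
        extras = rng.choice(config.n_habitats, size=rng.integers(0, 3), replace=False)
        crosswalk[code] = sorted({int(primary), *map(int, extras)})

    suitability = {
        h: _smooth_field((fy, fx), substream(config.seed, f"suitability_{h}"))
        for h in range(config.n_habitats)
    }
    habitat_tags = {
        h: habitat_archetype(h)[1] for h in range(config.n_habitats)
    }
    return LandSystemData(
        reference_map=ref,
        scenario_map=scen,
        crosswalk=crosswalk,
        suitability=suitability,
        habitat_tags=habitat_tags,
    )


def generate_plot_table(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vegetation-plot table and species→PFT assignment table.

    Every habitat the crosswalk can emit receives at least one plot; each
    species belongs to exactly one vegetated (non-bare) PFT slot, drawn from
    its habitat archetype's weights. Species pools are disjoint between
    habitats, so habitat compositions differ and transitions carry signal.
    """
    rng = substream(config.seed, "plots")
    n_h = config.n_habitats
    if config.n_species < n_h:
        raise ValueError("need at least one species per habitat")
    schema = DEFAULT_SCHEMA

    species_rows = []
    pools: dict[int, list[str]] = {h: [] for h in range(n_h)}
    for s in range(config.n_species):
        habitat = s % n_h
        _, _, weights = habitat_archetype(habitat)
        slots = np.array(list(weights))
        probs = np.array(list(weights.values()))
        slot = int(rng.choice(slots, p=probs / probs.sum()))
        name = f"species_{s:03d}"
        species_rows.append({"species": name, "pft": schema.names[slot]})
        pools[habitat].append(name)
    species_to_pft = pd.DataFrame(species_rows)

    counts = np.full(n_h, config.n_plots // n_h)
    counts[: config.n_plots % n_h] += 1
    plot_rows = []
    plot_id = 0
    for habitat in range(n_h):
        pool = pools[habitat]
        for _ in range(counts[habitat]):
            k = int(rng.integers(1, len(pool) + 1))
            chosen = rng.choice(pool, size=k, replace=False)
            for sp in chosen:
                plot_rows.append(
                    {
                        "plot": plot_id,
                        "habitat": habitat,
                        "species": sp,
                        "cover": float(np.round(rng.uniform(5.0, 90.0), 1)),
                    }
                )
            plot_id += 1
    return pd.DataFrame(plot_rows), species_to_pft


def generate_pft_grids(
    config: SyntheticConfig,
    land: LandSystemData | None = None,
    composition: HabitatComposition | None = None,
) -> tuple[PftFractionGrid, PftFractionGrid, LandSystemData, HabitatComposition]:
    """Translate the generated land-system maps into coarse PFT grids."""
    if land is None:
        land = generate_land_systems(config)
    if composition is None:
        plots, species_to_pft = generate_plot_table(config)
        composition = habitat_composition_from_plots(plots, species_to_pft)
    grids = tuple(
        translate_land_systems(
            ls_map,
            land.crosswalk,
            land.suitability,
            composition,
            land.habitat_tags,
            config.coarsen_factor,
        )
        for ls_map in (land.reference_map, land.scenario_map)
    )
    return grids[0], grids[1], land, composition


def make_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw the realised hidden parameters (offset and spatial noise)."""
    rng = substream(config.seed, "space_noise")
    noise = rng.normal(0.0, config.noise_sd_space, size=config.coarse_grid_shape)
    return SyntheticTruth(
        true_sensitivities=dict(config.true_sensitivities),
        realized_offset=config.nonlocal_offset,
        noise=noise,
    )


def _require_sensitivities(
    flows: np.ndarray, sensitivities: Mapping[tuple[str, str], float]
) -> None:
    totals = flows.sum(axis=(2, 3))
    for i in range(N_CATEGORIES):
        for j in range(i + 1, N_CATEGORIES):
            if totals[i, j] + totals[j, i] > 0 and (
                (CATEGORIES[i], CATEGORIES[j]) not in sensitivities
            ):
                raise KeyError(
                    "no configured sensitivity for transition type "
                    f"({CATEGORIES[i]!r}, {CATEGORIES[j]!r})"
                )


def generate_climate_fields(
    config: SyntheticConfig,
    grid_ref: PftFractionGrid,
    grid_scen: PftFractionGrid,
    truth: SyntheticTruth,
) -> tuple[xr.Dataset, xr.Dataset]:
    """Multi-year gridded climate fields for the reference and scenario runs.

    Returns two datasets with dims (year, y, x) — skin temperature ``ts``,
    2 m air temperature ``t2m``, fluxes and radiation, plus auxiliary
    variables — and ``t2m_daily_max`` with dims (year, day, y, x). The
    surface energy balance closes exactly at every cell and year of both
    runs, and the ``n_years``-mean scenario − reference ``ts`` equals the
    planted transition-response model.
    """
    ny, nx = config.coarse_grid_shape
    cat_ref = tr.aggregate_categories(grid_ref)
    cat_scen = tr.aggregate_categories(grid_scen)
    field = tr.greedy_net_transitions(cat_ref, cat_scen)
    _require_sensitivities(field.flows, truth.true_sensitivities)

    delta_ts = (
        delta_t_from_flows(field.flows, truth.true_sensitivities)
        + truth.realized_offset
        + truth.noise
    )
    truth.delta_ts_target = delta_ts
    change_frac = np.abs(field.delta()).sum(axis=0) / 2.0

    rng = substream(config.seed, "base_climate")
    lat_gradient = np.linspace(3.0, -3.0, ny)[:, None]  # warmer south rows
    ts_ref = 286.0 + lat_gradient + 1.0 * _smooth_field((ny, nx), rng)
    albedo_ref = 0.15 + 0.10 * _smooth_field((ny, nx), rng)
    sw_ref = 160.0 + 60.0 * _smooth_field((ny, nx), rng)
    lw_ref = 300.0 + 30.0 * _smooth_field((ny, nx), rng)
    rnet = (1 - albedo_ref) * sw_ref + lw_ref - STEFAN_BOLTZMANN * ts_ref**4
    lh_ref = 0.6 * np.maximum(rnet, 10.0)
    sh_ref = 0.3 * np.maximum(rnet, 10.0)

    # allocate the flux perturbation implied by the target ΔTs
    dflux = 4.0 * STEFAN_BOLTZMANN * ts_ref**3 * delta_ts
    w = config.allocation_weights
    lh_scen = lh_ref - w["latent"] * dflux
    sh_scen = sh_ref - w["sensible"] * dflux
    albedo_scen = albedo_ref - w["albedo"] * dflux / sw_ref
    sw_scen = sw_ref + w["sw_down"] * dflux / (1.0 - albedo_ref)
    lw_scen = lw_ref + w["lw_down"] * dflux
    ts_scen = ts_ref + delta_ts

    anomalies = ar1_series(
        config.n_years,
        config.ar1_coefficient,
        config.noise_sd_year,
        substream(config.seed, "interannual"),
    )
    years = np.arange(config.n_years)
    n_days = config.n_days_per_year
    season = config.seasonal_amplitude * np.sin(
        2.0 * np.pi * (np.arange(n_days) + 0.5) / n_days - np.pi / 2.0
    )
    daily_rng = substream(config.seed, "daily")
    gum_scale = config.daily_gumbel_scale
    excursions = daily_rng.gumbel(
        -EULER_GAMMA * gum_scale, gum_scale, size=(config.n_years, n_days, ny, nx)
    ).astype(np.float32)

    aux_rng = substream(config.seed, "aux")
    aux_base = {
        "precip": 1.5 + 2.0 * _smooth_field((ny, nx), aux_rng),  # mm/day
        "soil_moisture": 0.15 + 0.2 * _smooth_field((ny, nx), aux_rng),
        "soil_temp": ts_ref - 1.0,  # K
        "wind": 2.0 + 3.0 * _smooth_field((ny, nx), aux_rng),  # m/s
        "gpp": 2.0 + 4.0 * _smooth_field((ny, nx), aux_rng),  # gC/m2/day
    }
    aux_year = {
        name: aux_rng.normal(0.0, 0.03 * np.mean(np.abs(base)), size=config.n_years)
        for name, base in aux_base.items()
    }

    def build_run(
        ts_m: np.ndarray,
        albedo: np.ndarray,
        sw: np.ndarray,
        lw: np.ndarray,
        lh: np.ndarray,
        sh: np.ndarray,
        aux_offset_scale: np.ndarray | float,
    ) -> xr.Dataset:
        ts_y = ts_m[None, :, :] + anomalies[:, None, None]
        state = close_balance(
            SurfaceEnergyState(
                albedo=np.broadcast_to(albedo, ts_y.shape),
                sw_down=np.broadcast_to(sw, ts_y.shape),
                lw_down=np.broadcast_to(lw, ts_y.shape),
                ts=ts_y,
                lh=np.broadcast_to(lh, ts_y.shape),
                sh=np.broadcast_to(sh, ts_y.shape),
            )
        )
        t2m = ts_y - 2.0
        daily = (
            (t2m - 273.15).astype(np.float32)[:, None, :, :]
            + season.astype(np.float32)[None, :, None, None]
            + excursions
        )
        data = {
            "ts": (("year", "y", "x"), ts_y),
            "t2m": (("year", "y", "x"), t2m),
            "albedo": (("year", "y", "x"), np.broadcast_to(albedo, ts_y.shape).copy()),
            "sw_down": (("year", "y", "x"), np.broadcast_to(sw, ts_y.shape).copy()),
            "lw_down": (("year", "y", "x"), np.broadcast_to(lw, ts_y.shape).copy()),
            "lh": (("year", "y", "x"), np.broadcast_to(lh, ts_y.shape).copy()),
            "sh": (("year", "y", "x"), np.broadcast_to(sh, ts_y.shape).copy()),
            "g": (("year", "y", "x"), state.g),
            "t2m_daily_max": (("year", "day", "y", "x"), daily),
        }
        for name, base in aux_base.items():
            offset = config.aux_offsets[name] * aux_offset_scale
            yearly = (
                base[None, :, :]
                + offset
                + aux_year[name][:, None, None]
            )
            data[name] = (("year", "y", "x"), yearly)
        return xr.Dataset(
            data, coords={"year": years, "day": np.arange(n_days)}
        )

    ds_ref = build_run(ts_ref, albedo_ref, sw_ref, lw_ref, lh_ref, sh_ref, 0.0)
    ds_scen = build_run(
        ts_scen, albedo_scen, sw_scen, lw_scen, lh_scen, sh_scen, change_frac
    )
    return ds_ref, ds_scen


def generate_recent_climate(config: SyntheticConfig, ds_ref: xr.Dataset) -> xr.Dataset:
    """Recent-climate temperatures for unpaired future-vs-recent comparisons.

    The recent run shares the reference run's mean state minus the
    configured background-warming offset, with its own independent AR(1)
    interannual anomalies (different boundary conditions, so no pairing
    with the scenario runs).
    """
    anomalies = ar1_series(
        config.n_years,
        config.ar1_coefficient,
        config.noise_sd_year,
        substream(config.seed, "recent_interannual"),
    )
    ts_mean = ds_ref["ts"].mean("year").values - config.recent_offset
    ts = ts_mean[None, :, :] + anomalies[:, None, None]
    return xr.Dataset(
        {
            "ts": (("year", "y", "x"), ts),
            "t2m": (("year", "y", "x"), ts - 2.0),
        },
        coords={"year": np.arange(config.n_years)},
    )


# ---------------------------------------------------------------------------
# controlled attribution fixture

#: Default active transition pairs (category indices) of the fixture.
_FIXTURE_PAIRS: tuple[tuple[int, int], ...] = ((0, 4), (3, 4), (1, 3), (2, 6), (0, 3))


@dataclass
class AttributionFixture:
    """Design matrix with planted sensitivities on a coarse grid."""

    X: np.ndarray  # (n_cells, n_pairs) signed transition fractions
    y: np.ndarray  # (n_cells,) planted response, °C
    names: list[str]
    true_beta: np.ndarray  # aligned with X columns / names
    true_intercept: float
    grid_shape: tuple[int, int]
    oriented: tr.OrientedTransitions


def make_attribution_fixture(
    grid_shape: tuple[int, int] = (40, 40),
    seed: int = 0,
    pairs: tuple[tuple[int, int], ...] = _FIXTURE_PAIRS,
    betas: np.ndarray | None = None,
    noise_sd: float = 0.1,
    intercept: float = 0.08,
    dominant_prob: float = 0.75,
) -> AttributionFixture:
    """Grid fixture with a known number of active transition types.

    Each cell transfers area along one or two category-disjoint pairs with
    continuous magnitudes, so the greedy matcher recovers the planted
    transitions exactly; a minority of cells run opposite to the dominant
    direction so the signed design has both signs. The response is the
    planted linear model plus iid noise.
    """
    rng = np.random.default_rng(seed)
    if betas is None:
        betas = rng.uniform(-3.0, 3.0, size=len(pairs))
    betas = np.asarray(betas, dtype=float)
    sens = {
        (CATEGORIES[i], CATEGORIES[j]): float(b) for (i, j), b in zip(pairs, betas)
    }

    ny, nx = grid_shape
    base = np.full(N_CATEGORIES, 1.0 / N_CATEGORIES)
    cat_ref = np.tile(base[:, None, None], (1, ny, nx))
    cat_scen = cat_ref.copy()
    for iy in range(ny):
        for ix in range(nx):
            p1 = int(rng.integers(len(pairs)))
            chosen = [p1]
            if rng.random() < 0.5:  # second, category-disjoint transfer
                partners = [
                    q
                    for q in range(len(pairs))
                    if q != p1 and not set(pairs[q]) & set(pairs[p1])
                ]
                if partners:
                    chosen.append(int(rng.choice(partners)))
            for p in chosen:
                i, j = pairs[p]
                if rng.random() >= dominant_prob:
                    i, j = j, i
                delta = rng.uniform(0.02, 0.12)
                cat_scen[i, iy, ix] -= delta
                cat_scen[j, iy, ix] += delta

    field = tr.greedy_net_transitions(cat_ref, cat_scen)
    oriented = tr.orient_by_dominant_direction(field)
    truth = SyntheticTruth(
        true_sensitivities=sens, realized_offset=intercept, noise=np.zeros(grid_shape)
    )
    y_grid = (
        delta_t_from_flows(field.flows, sens)
        + intercept
        + rng.normal(0.0, noise_sd, size=grid_shape)
    )
    return AttributionFixture(
        X=oriented.design_matrix(),
        y=y_grid.ravel(),
        names=oriented.names,
        true_beta=truth.expected_coefficients(oriented),
        true_intercept=intercept,
        grid_shape=grid_shape,
        oriented=oriented,
    )
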