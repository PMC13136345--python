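"""Shared readers/writers, configuration, and the end-to-end pipeline driver.

Gridded interchange uses NetCDF (classic format through the scipy backend of
xarray, so no binary compile-time dependencies); tables are CSV with a
``# config_hash=...`` comment header; the ground truth and the provenance
manifest are JSON. Every stage's outputs carry the configuration hash so a
rerun can be matched to its inputs, and all randomness flows from the config
seed, making reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from . import stats as st
from . import synth as sy
from . import transitions as tr
from .attribution import (
    RegressionSpec,
    bootstrap_attribution,
    filter_reported_transitions,
)
from .energy_balance import SurfaceEnergyState, decompose, summarize_region
from .translate import PftFractionGrid

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "save_dataset",
    "load_dataset",
    "write_table",
    "read_table",
    "default_regions",
    "config_hash",
]

logger = logging.getLogger(__name__)

STAGES = ("synth", "translate", "transitions", "decompose", "attribute", "stats")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    ``scenarios`` names the runs to compare against the reference;
    the synthetic generator realises one scenario per name from per-name
    seeds derived from the root seed.
    """

    out_dir: str = "landclim_out"
    reference: str = "SSP1"
    scenarios: tuple[str, ...] = ("NAC",)
    seed: int = 0
    response_variable: str = "t2m"  # or "ts" (skin temperature)
    alpha: float = 0.05
    synth: dict = field(default_factory=dict)  # SyntheticConfig overrides
    attribution: dict = field(default_factory=dict)  # RegressionSpec overrides

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("a reference scenario name is required")
        if not self.scenarios:
            raise ValueError("at least one non-reference scenario is required")
        if self.response_variable not in ("t2m", "ts"):
            raise ValueError("response variable must be 't2m' or 'ts'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        return d

    def synth_config(self, scenario_index: int = 0) -> sy.SyntheticConfig:
        kwargs = dict(self.synth)
        if "true_sensitivities" in kwargs:
            kwargs["true_sensitivities"] = {
                tuple(k.split("|")): v for k, v in kwargs["true_sensitivities"].items()
            }
        # keep derived seeds well inside the 32-bit range
        kwargs.setdefault("seed", (self.seed * 1009 + scenario_index) % (2**31 - 1))
        return sy.SyntheticConfig(**kwargs)

    def regression_spec(self) -> RegressionSpec:
        return RegressionSpec(**self.attribution)


def config_hash(config: PipelineConfig) -> str:
    """Short digest of the scientific configuration.

    The output location is excluded so reruns into different directories
    produce byte-identical tables.
    """
    d = config.to_dict()
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_dataset(ds: xr.Dataset, path: str | Path, chash: str = "") -> None:
    ds = ds.copy()
    ds.attrs["config_hash"] = chash
    ds.attrs["software"] = f"landclim {__version__}"
    ds.to_netcdf(path, engine="scipy")


def load_dataset(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_table(df: pd.DataFrame, path: str | Path, chash: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash} software=landclim-{__version__}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def default_regions(grid_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Full-domain mask plus four loosely geographic subregions.

    North is the top third of rows, South the bottom third, and the middle
    band splits into West (left half) and East (right half); the subregions
    partition the domain.
    """
    ny, nx = grid_shape
    full = np.ones((ny, nx), dtype=bool)
    north = np.zeros_like(full)
    north[: ny // 3] = True
    south = np.zeros_like(full)
    south[-(ny // 3):] = True
    middle = ~(north | south)
    west = middle.copy()
    west[:, nx // 2:] = False
    east = middle & ~west
    return {"EU+": full, "North": north, "West": west, "East": east, "South": south}


def _pft_grid_to_dataset(grid: PftFractionGrid) -> xr.Dataset:
    return xr.Dataset(
        {
            "natural": (("pft", "y", "x"), grid.natural),
            "crop": (("pft", "y", "x"), grid.crop),
            "natural_frac": (("y", "x"), grid.natural_frac),
            "crop_frac": (("y", "x"), grid.crop_frac),
            "unmodified_frac": (("y", "x"), grid.unmodified_frac),
        },
        coords={"pft": np.arange(grid.natural.shape[0])},
    )


def state_from_dataset(ds: xr.Dataset) -> SurfaceEnergyState:
    """Energy-balance state (year, y, x) from a run dataset."""
    return SurfaceEnergyState(
        albedo=ds["albedo"].values,
        sw_down=ds["sw_down"].values,
        lw_down=ds["lw_down"].values,
        ts=ds["ts"].values,
        lh=ds["lh"].values,
        sh=ds["sh"].values,
        g=ds["g"].values,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run synth → translate → transitions → decompose → attribute → stats.

    Writes every stage's outputs under ``config.out_dir`` and a manifest
    recording the config hash, seeds, software version, and completed
    stages. Returns the manifest dict. A stage failure aborts with the
    failing stage named; outputs already written stay in place under a
    ``failed/`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest: dict = {
        "software": f"landclim {__version__}",
        "config_hash": chash,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    current_stage = "synth"
    try:
        scen_name = config.scenarios[0]
        scfg = config.synth_config(0)

        # --- synth: raw inputs -------------------------------------------
        land = sy.generate_land_systems(scfg)
        plots, species_to_pft = sy.generate_plot_table(scfg)
        truth = sy.make_truth(scfg)
        ls_ds = xr.Dataset(
            {
                "reference": (("fy", "fx"), land.reference_map.astype(np.int32)),
                "scenario": (("fy", "fx"), land.scenario_map.astype(np.int32)),
            }
        )
        save_dataset(ls_ds, out / "land_systems.nc", chash)
        write_table(plots, out / "plots.csv", chash)
        write_table(species_to_pft, out / "species_to_pft.csv", chash)
        write_table(
            pd.DataFrame(
                [(ls, h) for ls, habs in land.crosswalk.items() for h in habs],
                columns=["land_system", "habitat"],
            ),
            out / "crosswalk.csv",
            chash,
        )
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "true_sensitivities": {
                        "|".join(k): v for k, v in truth.true_sensitivities.items()
                    },
                    "realized_offset": truth.realized_offset,
                    "noise_sd_space": scfg.noise_sd_space,
                },
                indent=2,
            )
        )
        manifest["stages"].append("synth")

        # --- translate ----------------------------------------------------
        current_stage = "translate"
        grid_ref, grid_scen, _, _ = sy.generate_pft_grids(scfg, land=land)
        save_dataset(_pft_grid_to_dataset(grid_ref), out / f"pft_{config.reference}.nc", chash)
        save_dataset(_pft_grid_to_dataset(grid_scen), out / f"pft_{scen_name}.nc", chash)
        manifest["stages"].append("translate")

        # --- transitions ----------------------------------------------------
        current_stage = "transitions"
        cat_ref = tr.aggregate_categories(grid_ref)
        cat_scen = tr.aggregate_categories(grid_scen)
        t_field = tr.greedy_net_transitions(cat_ref, cat_scen)
        oriented = tr.orient_by_dominant_direction(t_field)
        write_table(oriented.inventory(), out / f"transitions_{scen_name}.csv", chash)
        design = xr.Dataset(
            {"x": (("transition", "y", "x"), oriented.x)},
            coords={"transition": oriented.names},
        )
        save_dataset(design, out / f"design_{scen_name}.nc", chash)
        manifest["stages"].append("transitions")

        # --- climate fields + decomposition --------------------------------
        current_stage = "decompose"
        ds_ref, ds_scen = sy.generate_climate_fields(scfg, grid_ref, grid_scen, truth)
        regions = default_regions(scfg.coarse_grid_shape)
        result = decompose(state_from_dataset(ds_ref), state_from_dataset(ds_scen))
        comp = xr.Dataset(
            {k: (("year", "y", "x"), v) for k, v in result.contributions.items()}
            | {
                "total": (("year", "y", "x"), result.total),
                "simulated_delta_ts": (("year", "y", "x"), result.simulated_delta_ts),
                "residual": (("year", "y", "x"), result.residual),
            }
        )
        save_dataset(comp, out / f"decomposition_{scen_name}.nc", chash)
        rows = []
        for region, mask in regions.items():
            summary = summarize_region(result, mask)
            for component, vals in summary.items():
                rows.append({"region": region, "component": component, **vals})
        write_table(pd.DataFrame(rows), out / f"decomposition_summary_{scen_name}.csv", chash)
        manifest["stages"].append("decompose")

        # --- attribution ----------------------------------------------------
        current_stage = "attribute"
        response = (
            ds_scen[config.response_variable] - ds_ref[config.response_variable]
        ).mean("year").values
        spec = config.regression_spec()
        attr = bootstrap_attribution(
            response.ravel(),
            oriented.design_matrix(),
            scfg.coarse_grid_shape,
            spec,
            rng=sy.substream(config.seed, "attribution"),
            names=oriented.names,
            area_pct=100.0 * oriented.area_fraction,
            occupancy_pct=oriented.occupancy,
        )
        write_table(attr.to_frame(), out / f"attribution_{scen_name}.csv", chash)
        write_table(
            filter_reported_transitions(attr),
            out / f"attribution_reported_{scen_name}.csv",
            chash,
        )
        (out / f"attribution_samples_{scen_name}.json").write_text(
            json.dumps(
                {
                    "names": attr.names,
                    "samples": attr.coef_samples.tolist(),
                    "n_failed": attr.n_failed,
                },
            )
        )
        manifest["stages"].append("attribute")

        # --- stats ----------------------------------------------------------
        current_stage = "stats"
        txx_ref = st.txx(ds_ref["t2m_daily_max"].values)
        txx_scen = st.txx(ds_scen["t2m_daily_max"].values)
        diff_by_year = {
            "t2m": (ds_scen["t2m"] - ds_ref["t2m"]).values,
            "txx": txx_scen - txx_ref,
            "precip": (ds_scen["precip"] - ds_ref["precip"]).values,
            "soil_moisture": (ds_scen["soil_moisture"] - ds_ref["soil_moisture"]).values,
            "gpp": (ds_scen["gpp"] - ds_ref["gpp"]).values,
        }
        ds_recent = sy.generate_recent_climate(scfg, ds_ref)
        diff_by_year["t2m_vs_recent"] = (
            ds_ref["t2m"].values - ds_recent["t2m"].values
        )
        adjusted = {
            "t2m": st.adjust_fdr(
                st.paired_scenario_test(ds_scen["t2m"].values, ds_ref["t2m"].values)
            ),
            "txx": st.adjust_fdr(st.paired_scenario_test(txx_scen, txx_ref)),
            "t2m_vs_recent": st.adjust_fdr(
                st.unpaired_change_test(ds_ref["t2m"].values, ds_recent["t2m"].values)
            ),
        }
        summary = st.regional_summary(
            diff_by_year, regions, adjusted_p=adjusted, alpha=config.alpha
        )
        write_table(summary, out / f"stats_summary_{scen_name}.csv", chash)
        change_frac = st.pft_change_fraction(
            grid_ref.cell_cover(), grid_scen.cell_cover()
        )
        masks = st.masks_and_bins(
            change_frac,
            txx_ref.mean(axis=0),
            ds_ref["t2m"].values.mean(axis=0) - ds_recent["t2m"].values.mean(axis=0),
        )
        mask_ds = xr.Dataset(
            {
                "most_affected": (("y", "x"), masks.most_affected.astype(np.int8)),
                "most_extreme_reference": (
                    ("y", "x"),
                    masks.most_extreme_reference.astype(np.int8),
                ),
                "most_changing": (("y", "x"), masks.most_changing.astype(np.int8)),
                "perturbation_bin": (("y", "x"), masks.bins.astype(np.int8)),
            }
        )
        save_dataset(mask_ds, out / f"masks_{scen_name}.nc", chash)
        manifest["stages"].append("stats")
    except Exception as exc:
        (out / "failed").write_text(f"stage {current_stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
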