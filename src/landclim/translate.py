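"""Translate categorical land-system maps into fractional PFT maps.

The chain mirrors how land-surface model input is built from land-use
scenarios: each fine-grid cell holds one land system; a crosswalk restricts
which habitat types a land system can become, and per-cell suitability scores
pick one habitat per cell; vegetation-plot records give each habitat a mean
species composition, which species→PFT assignments turn into raw per-PFT
cover; a vertical-layer occlusion rule (tree over shrub over herb, remainder
bare) normalises raw cover to fractions summing to one; cropland and
(semi-)natural habitats are split into separate land units; and everything is
averaged onto the coarse analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pft import DEFAULT_SCHEMA, PftSchema

__all__ = [
    "HabitatComposition",
    "PftFractionGrid",
    "land_system_to_habitat",
    "habitat_composition_from_plots",
    "layer_adjust",
    "split_land_units",
    "aggregate_to_coarse",
    "translate_land_systems",
]

#: Habitat-tag vocabulary: cropland habitats feed the crop land unit, natural
#: habitats the natural-vegetation unit; ice/urban pass through unmodified.
HABITAT_TAGS = ("natural", "cropland", "ice", "urban")


@dataclass
class HabitatComposition:
    """Mean raw PFT cover (%) per habitat, from plot averaging."""

    covers: dict[int, np.ndarray]  # habitat code -> (17,) raw cover in %
    n_plots: dict[int, int]

    def __post_init__(self) -> None:
        for code, vec in self.covers.items():
            if np.any(np.asarray(vec) < 0):
                raise ValueError(f"negative raw cover for habitat {code}")
            if self.n_plots.get(code, 0) < 1:
                raise ValueError(f"habitat {code} has no plots")


@dataclass
class PftFractionGrid:
    """Coarse-grid PFT fractions split into natural and crop land units.

    ``natural`` and ``crop`` are (17, ny, nx) and each sums to 1 over the
    slot axis at every cell (a land unit with zero area carries the all-bare
    convention). ``natural_frac``/``crop_frac``/``unmodified_frac`` give the
    cell-area share of each land unit and sum to 1.
    """

    natural: np.ndarray
    crop: np.ndarray
    natural_frac: np.ndarray
    crop_frac: np.ndarray
    unmodified_frac: np.ndarray
    schema: PftSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def validate(self, tol: float = 1e-9) -> None:
        for name, unit in (("natural", self.natural), ("crop", self.crop)):
            if np.any(unit < -tol) or np.any(unit > 1 + tol):
                raise ValueError(f"{name} fractions outside [0, 1]")
            sums = unit.sum(axis=0)
            if np.max(np.abs(sums - 1.0)) > tol:
                raise ValueError(f"{name} land-unit fractions do not sum to 1")
        area = self.natural_frac + self.crop_frac + self.unmodified_frac
        if np.max(np.abs(area - 1.0)) > tol:
            raise ValueError("land-unit area shares do not sum to 1")

    def cell_cover(self) -> np.ndarray:
        """(17, ny, nx) PFT cover over the modifiable (non ice/urban) area.

        Cells with no modifiable area fall back to all-bare so sums stay 1.
        """
        modif = self.natural_frac + self.crop_frac
        cover = self.natural * self.natural_frac + self.crop * self.crop_frac
        out = np.zeros_like(cover)
        np.divide(cover, modif, out=out, where=modif > 0)
        bare = self.schema.bare_index
        out[bare] = np.where(modif > 0, out[bare], 1.0)
        return out


def land_system_to_habitat(
    ls_map: np.ndarray,
    crosswalk: Mapping[int, list[int]],
    suitability: Mapping[int, np.ndarray],
) -> np.ndarray:
    """Assign one habitat code per fine cell.

    Among the crosswalk candidates of the cell's land system, the habitat
    with the highest suitability at that cell wins; exact ties resolve to the
    lowest habitat code.
    """
    ls_map = np.asarray(ls_map)
    out = np.full(ls_map.shape, -1, dtype=int)
    for code in np.unique(ls_map):
        code = int(code)
        if code not in crosswalk or not crosswalk[code]:
            raise KeyError(f"land-system code {code} missing from crosswalk")
        candidates = sorted(crosswalk[code])
        for hab in candidates:
            if hab not in suitability:
                raise KeyError(f"no suitability grid for habitat {hab}")
            s = np.asarray(suitability[hab], dtype=float)
            if not np.all(np.isfinite(s)) or np.any(s < 0):
                raise ValueError(f"suitability for habitat {hab} must be finite and >= 0")
        stack = np.stack([suitability[hab] for hab in candidates])
        # argmax returns the first maximum; candidates sorted ascending, so
        # ties resolve to the lowest habitat code.
        best = np.argmax(stack, axis=0)
        mask = ls_map == code
        out[mask] = np.asarray(candidates)[best][mask]
    return out


def habitat_composition_from_plots(
    plot_table: pd.DataFrame,
    species_to_pft: Mapping[str, str] | pd.DataFrame,
    schema: PftSchema = DEFAULT_SCHEMA,
) -> HabitatComposition:
    """Average plot-level species cover into per-habitat raw PFT cover.

    ``plot_table`` needs columns plot, habitat, species, cover (% ground
    cover). Species cover is first summed per plot within each assigned PFT,
    then averaged across the habitat's plots with equal plot weights.
    """
    if isinstance(species_to_pft, pd.DataFrame):
        species_to_pft = dict(zip(species_to_pft["species"], species_to_pft["pft"]))
    missing = sorted(set(plot_table["species"]) - set(species_to_pft))
    if missing:
        raise KeyError(f"species without PFT assignment: {missing}")
    if np.any(plot_table["cover"].to_numpy() <= 0):
        raise ValueError("species covers must be positive")
    slot_index = {name: i for i, name in enumerate(schema.names)}
    bad = sorted({p for p in species_to_pft.values() if p not in slot_index})
    if bad:
        raise KeyError(f"unknown PFT names in assignment: {bad}")

    df = plot_table.copy()
    df["slot"] = df["species"].map(species_to_pft).map(slot_index)
    covers: dict[int, np.ndarray] = {}
    n_plots: dict[int, int] = {}
    for habitat, hab_df in df.groupby("habitat"):
        per_plot = (
            hab_df.groupby(["plot", "slot"])["cover"].sum().unstack(fill_value=0.0)
        )
        vec = np.zeros(len(schema))
        vec[per_plot.columns.to_numpy()] = per_plot.mean(axis=0).to_numpy()
        covers[int(habitat)] = vec
        n_plots[int(habitat)] = per_plot.shape[0]
    return HabitatComposition(covers=covers, n_plots=n_plots)


def layer_adjust(raw_cover: np.ndarray, schema: PftSchema = DEFAULT_SCHEMA) -> np.ndarray:
    """Collapse raw per-PFT cover (%) to top-layer fractions summing to 1.

    Only the highest vegetation layer is visible to the surface fluxes, so
    layers occlude top-down (tree > shrub > herb): the tree layer claims
    min(total tree cover, 100)% of the area, split among tree slots in
    proportion to raw cover; the shrub layer claims up to the residual, then
    herb; whatever remains is bare ground. All-zero input yields all bare.
    """
    raw = np.asarray(raw_cover, dtype=float)
    if raw.shape != (len(schema),):
        raise ValueError(f"expected ({len(schema)},) raw cover vector")
    if np.any(raw < 0):
        raise ValueError("raw covers must be non-negative")
    out = np.zeros_like(raw)
    residual = 1.0  # area fraction still unclaimed
    for layer in ("tree", "shrub", "herb"):
        idx = schema.layer_indices(layer)
        total = raw[idx].sum() / 100.0
        if total <= 0:
            continue
        claimed = min(total, residual)
        out[idx] = raw[idx] / 100.0 * (claimed / total)
        residual -= claimed
    out[schema.bare_index] = residual
    return out


def split_land_units(
    habitat_map: np.ndarray, habitat_tags: Mapping[int, str]
) -> np.ndarray:
    """Tag each fine cell by land unit: 0 natural, 1 crop, 2 unmodified.

    Cropland habitats feed the crop land unit; ice and urban habitats pass
    through unchanged; every other habitat is (semi-)natural vegetation.
    """
    habitat_map = np.asarray(habitat_map)
    out = np.empty(habitat_map.shape, dtype=int)
    for code in np.unique(habitat_map):
        tag = habitat_tags.get(int(code))
        if tag is None:
            raise KeyError(f"habitat code {int(code)} has no land-unit tag")
        if tag not in HABITAT_TAGS:
            raise ValueError(f"unknown habitat tag {tag!r} for code {int(code)}")
        out[habitat_map == code] = {"natural": 0, "cropland": 1}.get(tag, 2)
    return out


def aggregate_to_coarse(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-average the trailing two axes by an integer factor."""
    fine = np.asarray(fine, dtype=float)
    ny, nx = fine.shape[-2:]
    if factor < 1 or ny % factor or nx % factor:
        raise ValueError(f"coarsen factor {factor} does not divide grid {ny}x{nx}")
    shape = fine.shape[:-2] + (ny // factor, factor, nx // factor, factor)
    return fine.reshape(shape).mean(axis=(-3, -1))


def translate_land_systems(
    ls_map: np.ndarray,
    crosswalk: Mapping[int, list[int]],
    suitability: Mapping[int, np.ndarray],
    composition: HabitatComposition,
    habitat_tags: Mapping[int, str],
    coarsen_factor: int,
    schema: PftSchema = DEFAULT_SCHEMA,
) -> PftFractionGrid:
    """Full fine-grid land-system map → coarse-grid PftFractionGrid chain."""
    habitat_map = land_system_to_habitat(ls_map, crosswalk, suitability)
    units = split_land_units(habitat_map, habitat_tags)

    # Layer-adjusted fraction vector per habitat, via lookup table.
    hab_codes = np.unique(habitat_map)
    adjusted = {}
    for code in hab_codes:
        code = int(code)
        if code not in composition.covers:
            if habitat_tags.get(code) in ("ice", "urban"):
                continue  # unmodified cells never consult plot composition
            raise KeyError(f"habitat {code} has no plot-derived composition")
        adjusted[code] = layer_adjust(composition.covers[code], schema)

    ny, nx = habitat_map.shape
    fine_pft = np.zeros((len(schema), ny, nx))
    for code, vec in adjusted.items():
        mask = habitat_map == code
        fine_pft[:, mask] = vec[:, None]

    f = coarsen_factor
    natural_frac = aggregate_to_coarse((units == 0).astype(float), f)
    crop_frac = aggregate_to_coarse((units == 1).astype(float), f)
    unmodified_frac = aggregate_to_coarse((units == 2).astype(float), f)

    unit_grids = []
    for unit_id in (0, 1):
        sel = units == unit_id
        masked = fine_pft * sel  # zero outside the unit
        num = aggregate_to_coarse(masked, f)
        den = aggregate_to_coarse(sel.astype(float), f)
        unit = np.zeros_like(num)
        np.divide(num, den, out=unit, where=den > 0)
        # empty land unit: all-bare convention keeps per-unit sums at 1
        unit[schema.bare_index] = np.where(den > 0, unit[schema.bare_index], 1.0)
        unit_grids.append(unit)

    grid = PftFractionGrid(
        natural=unit_grids[0],
        crop=unit_grids[1],
        natural_frac=natural_frac,
        crop_frac=crop_frac,
        unmodified_frac=unmodified_frac,
        schema=schema,
    )
    grid.validate()
    return grid
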