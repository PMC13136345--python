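"""Net land-cover transitions between scenario pairs.

In fractional PFT maps the model does not track which vegetation replaced
which: only the per-cell change in each of the 7 aggregated categories is
known. Net transitions are reconstructed per cell by a greedy matching that
repeatedly pairs the most-increased with the most-decreased category until
all change is accounted for. Each unordered category pair is then oriented by
its dominant direction over the region (the direction covering more area),
which fixes the sign convention of the regression predictors x_p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pft import CATEGORIES, N_CATEGORIES
from .translate import PftFractionGrid

__all__ = [
    "TransitionField",
    "OrientedTransitions",
    "aggregate_categories",
    "greedy_net_transitions",
    "greedy_match",
    "orient_by_dominant_direction",
]

logger = logging.getLogger(__name__)

#: Residual below which a category's remaining change counts as exhausted.
RESIDUAL_TOL = 1e-12


@dataclass
class TransitionField:
    """Per-cell transition flows among the 7 categories.

    ``flows[i, j, y, x]`` is the cell-area fraction transitioned from
    category i (reference) to category j (scenario); both directions of a
    pair can be populated across different cells but never within one cell.
    """

    flows: np.ndarray  # (7, 7, ny, nx), non-negative, zero diagonal

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.flows.shape[2:]

    def total_area(self) -> float:
        """Mean transitioned cell-area fraction, Σ flows / n_cells."""
        return float(self.flows.sum() / np.prod(self.grid_shape))

    def delta(self) -> np.ndarray:
        """(7, ny, nx) net category change implied by the flows."""
        return self.flows.sum(axis=0) - self.flows.sum(axis=1)


@dataclass
class OrientedTransitions:
    """Signed design fractions per oriented transition type.

    ``x[p]`` is positive where the transition runs in the region-wide
    dominant direction and negative where it runs opposite.
    """

    pairs: list[tuple[int, int]]  # (from, to) category indices, dominant order
    names: list[str]
    x: np.ndarray  # (n_pairs, ny, nx), signed fractions
    area_fraction: np.ndarray  # (n_pairs,) mean |flow| area per cell, both directions
    occupancy: np.ndarray  # (n_pairs,) % of cells with nonzero x

    def inventory(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "from_category": [CATEGORIES[i] for i, _ in self.pairs],
                "to_category": [CATEGORIES[j] for _, j in self.pairs],
                "area_fraction": self.area_fraction,
                "occupancy_pct": self.occupancy,
            }
        )

    def design_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_pairs) design matrix over (masked) cells."""
        x = self.x.reshape(len(self.pairs), -1).T
        if mask is not None:
            x = x[np.asarray(mask).ravel()]
        return x


def aggregate_categories(grid: PftFractionGrid) -> np.ndarray:
    """(7, ny, nx) category fractions summing member slots over both land units.

    Fractions refer to the modifiable (non ice/urban) cell area, so they sum
    to 1 per cell regardless of the unmodified share.
    """
    m = grid.schema.category_matrix()
    cover = grid.cell_cover()
    return np.tensordot(m, cover, axes=(1, 0))


def greedy_match(delta: np.ndarray, tol: float = RESIDUAL_TOL) -> np.ndarray:
    """Greedy net-transition matching for one cell's category change vector.

    Repeatedly transfers min(largest remaining increase, largest remaining
    decrease) from the most-decreased to the most-increased category until
    residuals fall below ``tol``. Ties break on the fixed category order.
    Returns the (7, 7) flow matrix.
    """
    d = np.asarray(delta, dtype=float).copy()
    if abs(d.sum()) > 1e-9:
        raise ValueError(f"unbalanced category change (sum {d.sum():.3e}); fractions not conserved")
    flows = np.zeros((N_CATEGORIES, N_CATEGORIES))
    # each iteration exhausts at least one category, so <= 6 iterations
    for _ in range(N_CATEGORIES):
        inc = int(np.argmax(d))
        dec = int(np.argmin(d))
        amount = min(d[inc], -d[dec])
        if amount <= tol:
            break
        flows[dec, inc] += amount
        d[inc] -= amount
        d[dec] += amount
    return flows


def greedy_net_transitions(
    category_ref: np.ndarray, category_scen: np.ndarray, tol: float = RESIDUAL_TOL
) -> TransitionField:
    """Per-cell greedy net transitions between two category-fraction grids."""
    ref = np.asarray(category_ref, dtype=float)
    scen = np.asarray(category_scen, dtype=float)
    if ref.shape != scen.shape or ref.shape[0] != N_CATEGORIES:
        raise ValueError("category grids must share shape (7, ny, nx)")
    sums_ok = np.abs(ref.sum(axis=0) - scen.sum(axis=0)) <= 1e-9
    if not np.all(sums_ok):
        raise ValueError("per-cell fraction sums differ between scenario and reference")
    ny, nx = ref.shape[1:]
    flows = np.zeros((N_CATEGORIES, N_CATEGORIES, ny, nx))
    delta = scen - ref
    changed = np.abs(delta).sum(axis=0) > tol
    for iy, ix in zip(*np.nonzero(changed)):
        flows[:, :, iy, ix] = greedy_match(delta[:, iy, ix], tol)
    return TransitionField(flows=flows)


def orient_by_dominant_direction(
    field: TransitionField, region_mask: np.ndarray | None = None
) -> OrientedTransitions:
    """Orient each unordered pair by its region-wide dominant direction.

    For each pair, total transitioned area is compared between the two
    directions over the region; the larger one names the transition and
    defines positive sign. Pairs with zero total area are absent from the
    inventory. Exact ties orient by the fixed category order and are logged.
    """
    flows = field.flows
    if region_mask is not None:
        flows = flows * np.asarray(region_mask, dtype=bool)
    n_cells = int(np.prod(field.grid_shape)) if region_mask is None else int(
        np.asarray(region_mask).sum()
    )
    totals = flows.sum(axis=(2, 3))

    pairs: list[tuple[int, int]] = []
    names: list[str] = []
    xs: list[np.ndarray] = []
    areas: list[float] = []
    occ: list[float] = []
    for i in range(N_CATEGORIES):
        for j in range(i + 1, N_CATEGORIES):
            fwd, back = totals[i, j], totals[j, i]
            if fwd + back == 0.0:
                continue
            if fwd == back:
                logger.warning(
                    "transition %s<->%s area tie; orienting by category order",
                    CATEGORIES[i], CATEGORIES[j],
                )
            a, b = (i, j) if fwd >= back else (j, i)
            pairs.append((a, b))
            names.append(f"{CATEGORIES[a]} to {CATEGORIES[b]}")
            xs.append(flows[a, b] - flows[b, a])
            areas.append((fwd + back) / n_cells)
            occ.append(100.0 * np.count_nonzero(xs[-1]) / n_cells)
    x = np.stack(xs) if xs else np.zeros((0,) + field.grid_shape)
    return OrientedTransitions(
        pairs=pairs,
        names=names,
        x=x,
        area_fraction=np.asarray(areas),
        occupancy=np.asarray(occ),
    )
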