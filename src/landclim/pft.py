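"""Plant-functional-type (PFT) schema and land-cover category mapping.

The land model represents vegetation within each grid cell as fractions of
17 PFT slots, one of which is bare ground. Each slot carries a vertical-layer
tag (tree / shrub / herb / bare), used when collapsing plot-derived species
cover to the highest visible layer, and a land-cover category tag, used when
aggregating the 17 slots into the 7 categories on which net transitions are
computed (tree needleleaf, tree broadleaf, shrub, grass, crop rainfed, crop
irrigated, bare).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PftSlot",
    "PftSchema",
    "DEFAULT_SCHEMA",
    "CATEGORIES",
    "N_CATEGORIES",
]

#: The 7 aggregated land-cover categories, in canonical order. This order is
#: the deterministic tie-break everywhere a "largest" choice can tie.
CATEGORIES: tuple[str, ...] = (
    "tree needleleaf",
    "tree broadleaf",
    "shrub",
    "grass",
    "crop rainfed",
    "crop irrigated",
    "bare",
)
N_CATEGORIES = len(CATEGORIES)

_LAYERS = ("tree", "shrub", "herb", "bare")


@dataclass(frozen=True)
class PftSlot:
    """One PFT slot: name, vertical layer, and aggregated category."""

    name: str
    layer: str
    category: str

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


_SLOTS: tuple[PftSlot, ...] = (
    PftSlot("bare ground", "bare", "bare"),
    PftSlot("needleleaf evergreen temperate tree", "tree", "tree needleleaf"),
    PftSlot("needleleaf evergreen boreal tree", "tree", "tree needleleaf"),
    PftSlot("needleleaf deciduous boreal tree", "tree", "tree needleleaf"),
    PftSlot("broadleaf evergreen tropical tree", "tree", "tree broadleaf"),
    PftSlot("broadleaf evergreen temperate tree", "tree", "tree broadleaf"),
    PftSlot("broadleaf deciduous tropical tree", "tree", "tree broadleaf"),
    PftSlot("broadleaf deciduous temperate tree", "tree", "tree broadleaf"),
    PftSlot("broadleaf deciduous boreal tree", "tree", "tree broadleaf"),
    PftSlot("broadleaf evergreen temperate shrub", "shrub", "shrub"),
    PftSlot("broadleaf deciduous temperate shrub", "shrub", "shrub"),
    PftSlot("broadleaf deciduous boreal shrub", "shrub", "shrub"),
    PftSlot("C3 arctic grass", "herb", "grass"),
    PftSlot("C3 grass", "herb", "grass"),
    PftSlot("C4 grass", "herb", "grass"),
    PftSlot("rainfed crop", "herb", "crop rainfed"),
    PftSlot("irrigated crop", "herb", "crop irrigated"),
)


class PftSchema:
    """Ordered collection of the 17 PFT slots with layer/category lookups.

    Invariants: exactly 17 slots and exactly one bare slot. Tropical tree
    slots are part of the schema but may be identically zero in extratropical
    domains.
    """

    def __init__(self, slots: tuple[PftSlot, ...] = _SLOTS):
        if len(slots) != 17:
            raise ValueError(f"schema must hold exactly 17 slots, got {len(slots)}")
        bare = [s for s in slots if s.layer == "bare"]
        if len(bare) != 1:
            raise ValueError("schema must hold exactly one bare slot")
        self.slots = slots
        self.names = tuple(s.name for s in slots)
        self.layers = tuple(s.layer for s in slots)
        self.categories_per_slot = tuple(s.category for s in slots)
        self.bare_index = slots.index(bare[0])

    def __len__(self) -> int:
        return len(self.slots)

    def layer_indices(self, layer: str) -> np.ndarray:
        """Slot indices belonging to a vertical layer."""
        return np.array([i for i, s in enumerate(self.slots) if s.layer == layer])

    def category_matrix(self) -> np.ndarray:
        """(7, 17) indicator matrix mapping slots to categories.

        ``M @ pft_fractions`` yields category fractions; every slot maps to
        exactly one category so column sums are 1.
        """
        m = np.zeros((N_CATEGORIES, len(self.slots)))
        for j, s in enumerate(self.slots):
            m[CATEGORIES.index(s.category), j] = 1.0
        return m


DEFAULT_SCHEMA = PftSchema()
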