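"""Crop metadata: land-use classes and rotation categories.

Every crop code used by the pipeline is mapped to a land-use class
(``arable``, ``grassland`` or ``tree``) and, for arable crops, to one of
the ten rotation categories used when describing crop-rotation
composition: cereals, roots and tubers, dry pulses, sunflower, rapeseed,
other industrial crops, fodder legumes, maize, vegetables, and leys
(temporary grassland).
"""

from __future__ import annotations

from dataclasses import dataclass

ARABLE = "arable"
GRASSLAND = "grassland"
TREE = "tree"
LAND_USES = (ARABLE, GRASSLAND, TREE)

#: Rotation categories for arable land (order is the reporting order).
CATEGORIES = (
    "cereals",
    "roots_tubers",
    "dry_pulses",
    "sunflower",
    "rapeseed",
    "other_industrial",
    "fodder_legumes",
    "maize",
    "vegetables",
    "leys",
)


@dataclass(frozen=True)
class Crop:
    """A crop code with its land-use class and rotation category.

    ``category`` is ``None`` for non-arable crops (permanent grassland
    and tree crops), which do not enter rotation composition.
    """

    code: str
    land_use: str
    category: str | None = None

    def __post_init__(self) -> None:
        if self.land_use not in LAND_USES:
            raise ValueError(f"unknown land use {self.land_use!r} for crop {self.code!r}")
        if self.land_use == ARABLE:
            if self.category not in CATEGORIES:
                raise ValueError(
                    f"arable crop {self.code!r} needs a rotation category, got {self.category!r}"
                )
        elif self.category is not None:
            raise ValueError(f"non-arable crop {self.code!r} must not have a category")


#: Default crop list: a compact but structurally complete European mix.
DEFAULT_CROPS = (
    Crop("wheat", ARABLE, "cereals"),
    Crop("barley", ARABLE, "cereals"),
    Crop("rye", ARABLE, "cereals"),
    Crop("maize", ARABLE, "maize"),
    Crop("potato", ARABLE, "roots_tubers"),
    Crop("sugar_beet", ARABLE, "roots_tubers"),
    Crop("peas", ARABLE, "dry_pulses"),
    Crop("sunflower", ARABLE, "sunflower"),
    Crop("rapeseed", ARABLE, "rapeseed"),
    Crop("flax", ARABLE, "other_industrial"),
    Crop("lucerne", ARABLE, "fodder_legumes"),
    Crop("vegetables", ARABLE, "vegetables"),
    Crop("temp_grass", ARABLE, "leys"),
    Crop("perm_grass", GRASSLAND),
    Crop("olives", TREE),
    Crop("vines", TREE),
    Crop("orchard", TREE),
)


def category_map(crops: tuple[Crop, ...] = DEFAULT_CROPS) -> dict[str, str | None]:
    """Map crop code -> rotation category (``None`` for non-arable)."""
    return {c.code: c.category for c in crops}


def land_use_map(crops: tuple[Crop, ...] = DEFAULT_CROPS) -> dict[str, str]:
    """Map crop code -> land-use class."""
    return {c.code: c.land_use for c in crops}


def arable_codes(crops: tuple[Crop, ...] = DEFAULT_CROPS) -> list[str]:
    return [c.code for c in crops if c.land_use == ARABLE]
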