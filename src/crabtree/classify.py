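"""Crabtree phenotype categories from endpoint yields.

Species are sorted into three categories by how much glucose they spend
per gram of biomass and how much ethanol they make:

* ``STRONG_POSITIVE`` — over 5.5 g glucose per g biomass
  (Y_X/S < 0.18) while producing substantial ethanol (Y_E/S > 0.33);
* ``INTERMEDIATE`` — 3-5 g glucose per g biomass
  (0.18 <= Y_X/S <= 0.33);
* ``NEGATIVE_LIKE`` — under 3 g glucose per g biomass (Y_X/S > 0.33)
  with little or no ethanol (Y_E/S < 0.15).

The published bounds do not tile the yield plane (e.g. a low biomass
yield with modest ethanol, or a high biomass yield with Y_E/S >= 0.15);
such cases are assigned to the nearest category and flagged
``outside published bounds`` rather than silently forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = ["CrabtreeCategory", "CrabtreeClass", "classify_crabtree"]


class CrabtreeCategory(str, Enum):
    STRONG_POSITIVE = "STRONG_POSITIVE"
    INTERMEDIATE = "INTERMEDIATE"
    NEGATIVE_LIKE = "NEGATIVE_LIKE"


@dataclass(frozen=True)
class CrabtreeClass:
    category: CrabtreeCategory
    glucose_per_biomass: float   # g glucose per g biomass, 1 / Y_X/S
    flags: tuple[str, ...] = field(default=())


def _distance_to_category(
    category: CrabtreeCategory, ye: float, yx: float
) -> float:
    """How far (in yield units) the point lies outside a category's
    published bounds; 0 means inside."""
    if category is CrabtreeCategory.STRONG_POSITIVE:
        return max(yx - 0.18, 0.0) + max(0.33 - ye, 0.0)
    if category is CrabtreeCategory.NEGATIVE_LIKE:
        return max(0.33 - yx, 0.0) + max(ye - 0.15, 0.0)
    return max(0.18 - yx, 0.0) + max(yx - 0.33, 0.0)


def classify_crabtree(ethanol_yield: float, biomass_yield: float) -> CrabtreeClass:
    """Assign a Crabtree category from (Y_E/S, Y_X/S) in g/g.

    Deterministic, depends only on the two yields.  Points inside one of
    the published regions get that category; points in the gaps between
    regions get the nearest category plus an ``outside published
    bounds`` flag.
    """
    if biomass_yield <= 0:
        raise ValueError("biomass yield must be positive")
    ye, yx = ethanol_yield, biomass_yield

    if yx < 0.18 and ye > 0.33:
        category, flags = CrabtreeCategory.STRONG_POSITIVE, ()
    elif yx > 0.33 and ye < 0.15:
        category, flags = CrabtreeCategory.NEGATIVE_LIKE, ()
    elif 0.18 <= yx <= 0.33:
        category, flags = CrabtreeCategory.INTERMEDIATE, ()
    else:
        category = min(CrabtreeCategory,
                       key=lambda c: _distance_to_category(c, ye, yx))
        flags = ("outside published bounds",)
    return CrabtreeClass(category, 1.0 / yx, flags)
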