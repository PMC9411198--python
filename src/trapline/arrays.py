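"""Built-in fixture geometries for the three experimental arrays.

The study arrays are described by shape, not by printed coordinates, so the
fixtures below reconstruct each shape from its description:

* **Double Trapezoid** — six platforms forming two congruent trapezoids that
  share a long base; platforms 1 and 2 are the closest pair.  The fixture is
  scaled so that ``log(2 * L_min) = 4.78``, the prior centre used for the
  learning-curve intercept in this array, which pins the fixture to the
  coordinate scale of the original analysis.
* **Z array** — six platforms laid out along a Z stroke (two bar ends, two
  platforms on the diagonal, two bar ends).
* **Pentagon** — five platforms at the vertices of a regular pentagon, where
  walking the perimeter minus one edge is the optimal open path.

Distances are unitless; only relative geometry is meaningful.
"""

from __future__ import annotations

import math


from .geometry import PlatformArray, build_array, optimal_open_path

__all__ = [
    "double_trapezoid",
    "z_array",
    "pentagon",
    "get_array",
    "ARRAY_NAMES",
    "DOUBLE_TRAPEZOID_PRIOR_CENTER",
]

#: log(2 * L_min) for the Double Trapezoid at the original coordinate scale
DOUBLE_TRAPEZOID_PRIOR_CENTER = 4.78

# two congruent trapezoids sharing the base (0,0)-(4,0); labels follow the
# perimeter so that platforms 1 and 2 are the closest pair
_DT_BASE = {
    "1": (1.0, 2.0),
    "2": (3.0, 2.0),
    "3": (4.0, 0.0),
    "4": (3.0, -2.0),
    "5": (1.0, -2.0),
    "6": (0.0, 0.0),
}

# six platforms along a Z stroke: top bar, diagonal, bottom bar
_Z_BASE = {
    "1": (0.0, 3.0),
    "2": (4.0, 3.0),
    "3": (8.0 / 3.0, 2.0),
    "4": (4.0 / 3.0, 1.0),
    "5": (0.0, 0.0),
    "6": (4.0, 0.0),
}


def _scaled_from_base(name: str, base: dict, c: float) -> PlatformArray:
    return build_array(name, {k: (x * c, y * c) for k, (x, y) in base.items()})


def double_trapezoid() -> PlatformArray:
    """Double Trapezoid fixture, scaled so log(2·L_min) = 4.78."""
    unit = _scaled_from_base("double_trapezoid", _DT_BASE, 1.0)
    l_min = optimal_open_path(unit).length
    c = 0.5 * math.exp(DOUBLE_TRAPEZOID_PRIOR_CENTER) / l_min
    return _scaled_from_base("double_trapezoid", _DT_BASE, c)


def z_array() -> PlatformArray:
    """Z-array fixture (six platforms along a Z stroke)."""
    return _scaled_from_base("z_array", _Z_BASE, 4.0)


def pentagon(circumradius: float = 25.0) -> PlatformArray:
    """Regular-pentagon fixture; platform 1 at the top, labels clockwise."""
    coords = {}
    for k in range(5):
        theta = math.pi / 2 - 2 * math.pi * k / 5
        coords[str(k + 1)] = (
            circumradius * math.cos(theta),
            circumradius * math.sin(theta),
        )
    return build_array("pentagon", coords)


_BUILDERS = {
    "double_trapezoid": double_trapezoid,
    "z_array": z_array,
    "pentagon": pentagon,
}

ARRAY_NAMES = tuple(_BUILDERS)


def get_array(name: str) -> PlatformArray:
    """Look up a fixture array by name."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown array {name!r}; available: {sorted(_BUILDERS)}"
        ) from None
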