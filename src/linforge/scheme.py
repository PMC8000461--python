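"""LIN schemes: ordered ANI thresholds that define the positions of a LIN.

A LIN (Life Identification Number) scheme is an ordered, strictly increasing
list of ANI percentages. Position ``i`` of a LIN is shared between two genomes
exactly when their ANI reaches ``thresholds[i]``. Thresholds are kept on an
exact integer grid (units of 1e-6 %) so that schemes generated with decimal
steps such as 0.1 or 0.00001 never accumulate floating-point drift and
boundary ANI values classify deterministically.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: scale factor mapping ANI percent to the internal integer grid
GRID_SCALE = 10**6

#: advisory floor: ANI below 70% does not reflect evolutionary relationships
ADVISORY_MIN_ANI = 70.0

#: ANI thresholds of the primary 20-position scheme (positions A..T)
LIN20_THRESHOLDS = (
    70, 75, 80, 85, 90, 95, 96, 97, 98, 98.5,
    99, 99.25, 99.5, 99.75, 99.9, 99.925, 99.95, 99.975, 99.99, 99.999,
)


def _to_grid(value: float) -> int:
    """Round an ANI percentage onto the integer grid."""
    return int(round(float(value) * GRID_SCALE))


@dataclass(frozen=True)
class LINScheme:
    """An ordered set of ANI thresholds defining LIN positions.

    Parameters
    ----------
    name
        Text label for the scheme.
    grid
        Strictly increasing int64 array of thresholds in units of 1e-6 %.
    position_labels
        Optional per-position labels (``A``..``T`` for the 20-position scheme).
    """

    name: str
    grid: np.ndarray = field(repr=False)
    position_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.int64)
        object.__setattr__(self, "grid", grid)
        if grid.size == 0:
            raise ValueError("a LIN scheme needs at least one threshold")
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"scheme {self.name!r}: thresholds must be strictly increasing")
        if grid[0] <= 0 or grid[-1] > 100 * GRID_SCALE:
            raise ValueError(f"scheme {self.name!r}: thresholds must lie in (0, 100]")
        if self.position_labels is not None and len(self.position_labels) != grid.size:
            raise ValueError("position_labels length must match number of thresholds")

    def __len__(self) -> int:
        return int(self.grid.size)

    @property
    def thresholds(self) -> np.ndarray:
        """Thresholds as ANI percentages (float64)."""
        return self.grid / GRID_SCALE

    def threshold(self, position: int) -> float:
        return float(self.grid[position]) / GRID_SCALE

    def shared_depth(self, ani: float) -> int:
        """Number of leading positions whose threshold is <= ``ani``.

        An ANI exactly equal to a threshold shares that position. The ANI is
        snapped to the integer grid before comparison so that values like 99.9,
        which are not exactly representable in binary, land on their decimal
        grid point.
        """
        if not 0.0 <= ani <= 100.0:
            raise ValueError(f"ANI must be in [0, 100], got {ani}")
        return int(np.searchsorted(self.grid, _to_grid(ani), side="right"))

    def zeros(self) -> list[int]:
        """The all-zero LIN of this scheme (assigned to the first genome)."""
        return [0] * len(self)


def shared_depth(scheme: LINScheme, ani: float) -> int:
    """Module-level alias for :meth:`LINScheme.shared_depth`."""
    return scheme.shared_depth(ani)


def parse_scheme(
    thresholds: Sequence[float],
    name: str = "custom",
    position_labels: Sequence[str] | None = None,
) -> LINScheme:
    """Validate an explicit threshold list into a :class:`LINScheme`.

    Thresholds below 70% ANI are permitted but draw a warning: ANI loses its
    link to evolutionary relatedness below roughly that level.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold list is empty")
    grid = np.array([_to_grid(t) for t in thresholds], dtype=np.int64)
    scheme = LINScheme(
        name=name,
        grid=grid,
        position_labels=tuple(position_labels) if position_labels is not None else None,
    )
    if scheme.threshold(0) < ADVISORY_MIN_ANI:
        warnings.warn(
            f"scheme {name!r} has thresholds below {ADVISORY_MIN_ANI}% ANI; "
            "ANI is not a reliable relatedness measure down there",
            stacklevel=2,
        )
    return scheme


def build_scheme(start: float, stop: float, step: float, name: str | None = None) -> LINScheme:
    """Build an evenly spaced scheme from ``start`` to ``stop`` inclusive.

    The grid is computed from integer multiples of ``step``, never by repeated
    float addition, so position counts are exact: (70, 99.9, 0.1) yields 300
    positions and (70, 99.99, 0.01) yields 3,000.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if stop <= start:
        raise ValueError(f"stop ({stop}) must exceed start ({start})")
    start_g, stop_g, step_g = _to_grid(start), _to_grid(stop), _to_grid(step)
    if step_g == 0:
        raise ValueError(f"step {step} is below the {1 / GRID_SCALE}% grid resolution")
    span = stop_g - start_g
    if span % step_g != 0:
        raise ValueError(
            f"(stop - start) = {span / GRID_SCALE} is not an integer multiple of step {step}"
        )
    count = span // step_g + 1
    grid = start_g + step_g * np.arange(count, dtype=np.int64)
    if name is None:
        name = f"lin_{start}_{stop}_{step}"
    return LINScheme(name=name, grid=grid)


def _lin20() -> LINScheme:
    return parse_scheme(
        LIN20_THRESHOLDS, name="lin20", position_labels=tuple(string.ascii_uppercase[:20])
    )


# Built-in schemes. "lin_fine" is registered with the stated 70 -> 99.99999
# endpoints at 0.00001 intervals; that grid contains 3,000,000 points (see
# docs/methods.md for the position-count caveat). Constructed lazily: the fine
# grid is large and rarely activated.
_BUILTIN_FACTORIES = {
    "lin20": _lin20,
    "lin300": lambda: build_scheme(70, 99.9, 0.1, name="lin300"),
    "lin3000": lambda: build_scheme(70, 99.99, 0.01, name="lin3000"),
    "lin_fine": lambda: build_scheme(70, 99.99999, 0.00001, name="lin_fine"),
}

BUILTIN_SCHEME_NAMES = tuple(_BUILTIN_FACTORIES)


def get_scheme(name: str) -> LINScheme:
    """Look up a built-in scheme by name."""
    try:
        return _BUILTIN_FACTORIES[name]()
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; built-ins are {', '.join(BUILTIN_SCHEME_NAMES)}"
        ) from None


def scheme_from_config(doc: dict) -> LINScheme:
    """Build a scheme from a config mapping.

    Accepts either ``{"name": ..., "thresholds": [...]}`` or
    ``{"name": ..., "start": ..., "stop": ..., "step": ...}``.
    """
    name = doc.get("name", "custom")
    if "thresholds" in doc:
        return parse_scheme(doc["thresholds"], name=name, position_labels=doc.get("labels"))
    if {"start", "stop", "step"} <= doc.keys():
        return build_scheme(doc["start"], doc["stop"], doc["step"], name=name)
    raise ValueError("scheme config needs either 'thresholds' or 'start'/'stop'/'step'")
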