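"""Wavenumber grids for NIR spectra.

Instrument convention is a descending grid (high to low wavenumber); the
canonical default spans 10000 to 4000 cm^-1 in 1557 evenly spaced points,
i.e. a step of (10000 - 4000)/1556 ~ 3.86 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberGrid", "make_grid", "DEFAULT_N_POINTS"]

DEFAULT_N_POINTS = 1557


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly monotone vector of wavenumbers in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two wavenumber points")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite wavenumbers")
        diffs = np.diff(values)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("grid must be strictly monotone")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def is_descending(self) -> bool:
        return bool(self.values[0] > self.values[-1])

    @property
    def span(self) -> tuple[float, float]:
        """(low, high) wavenumber bounds in cm^-1."""
        lo = float(self.values.min())
        hi = float(self.values.max())
        return lo, hi

    @property
    def step(self) -> float:
        """Signed grid step in cm^-1 per index (negative when descending).

        Raises if spacing is not uniform; derivative filters require a
        uniform grid.
        """
        diffs = np.diff(self.values)
        mean = float(diffs.mean())
        if not np.allclose(diffs, mean, rtol=1e-6, atol=abs(mean) * 1e-6):
            raise ValueError("grid spacing is not uniform")
        return mean

    def contains(self, wavenumber: float) -> bool:
        lo, hi = self.span
        return lo <= wavenumber <= hi

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def reversed(self) -> "WavenumberGrid":
        return WavenumberGrid(self.values[::-1].copy())


def make_grid(start_cm1: float, end_cm1: float, n_points: int = DEFAULT_N_POINTS) -> WavenumberGrid:
    """Evenly spaced grid from ``start_cm1`` to ``end_cm1``, endpoints included.

    Descending when ``start_cm1 > end_cm1`` (the canonical orientation).
    """
    if not (np.isfinite(start_cm1) and np.isfinite(end_cm1)):
        raise ValueError("grid bounds must be finite")
    if start_cm1 == end_cm1:
        raise ValueError("grid bounds must differ")
    if n_points < 2:
        raise ValueError("a grid needs at least 2 points")
    return WavenumberGrid(np.linspace(float(start_cm1), float(end_cm1), int(n_points)))
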