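"""Spectral derivative preprocessing: Savitzky-Golay and Norris filters.

Five treatments are supported, named after the usual comparison table of an
NIR calibration study: raw, first or second derivative with Savitzky-Golay
smoothing (1d-sg, 2d-sg), and first or second derivative with the Norris
gap-segment filter (1d-no, 2d-no).  Derivatives are expressed per cm^-1
(grid-spacing aware), so results do not depend on sampling density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .spectra_io import SpectrumSet

__all__ = [
    "PreprocessSpec",
    "savitzky_golay",
    "norris_derivative",
    "apply_preprocessing",
    "TREATMENTS",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing treatment.

    ``derivative_order`` 0 with smoother ``none`` is the identity (raw
    spectra).  The Norris filter only defines first and second derivatives,
    so ``norris`` requires ``derivative_order`` in {1, 2}.
    """

    derivative_order: int = 0
    smoother: str = "none"  # none | savitzky_golay | norris
    sg_window: int = 11
    sg_polyorder: int = 3
    norris_segment: int = 5
    norris_gap: int = 5

    def __post_init__(self) -> None:
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.smoother not in ("none", "savitzky_golay", "norris"):
            raise ValueError(f"unknown smoother {self.smoother!r}")
        if self.smoother == "none" and self.derivative_order != 0:
            raise ValueError("derivatives require a smoother (savitzky_golay or norris)")
        if self.smoother == "norris" and self.derivative_order == 0:
            raise ValueError("the Norris filter is a derivative filter; use order 1 or 2")
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ValueError("sg_window must be odd and >= 3")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ValueError("sg_polyorder must satisfy 0 <= polyorder < window")
        if self.norris_segment % 2 == 0 or self.norris_segment < 1:
            raise ValueError("norris_segment must be odd and >= 1")
        if self.norris_gap < 1:
            raise ValueError("norris_gap must be >= 1")

    @property
    def label(self) -> str:
        if self.derivative_order == 0 and self.smoother == "none":
            return "raw"
        tag = {"savitzky_golay": "sg", "norris": "no"}[self.smoother]
        return f"{self.derivative_order}d-{tag}"

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "PreprocessSpec":
        """Parse treatment labels: raw, 1d-sg, 1d-no, 2d-sg, 2d-no."""
        label = label.lower().replace("+", "-").replace("_", "-")
        if label == "raw":
            return cls(0, "none", **kwargs)
        try:
            order_part, tag = label.split("-")
            order = int(order_part.rstrip("d"))
            smoother = {"sg": "savitzky_golay", "no": "norris"}[tag]
        except (ValueError, KeyError):
            raise ValueError(f"unknown preprocessing label {label!r}") from None
        return cls(order, smoother, **kwargs)


#: The five treatments of the standard comparison, in presentation order.
TREATMENTS: tuple[str, ...] = ("raw", "1d-sg", "1d-no", "2d-sg", "2d-no")


def savitzky_golay(s: SpectrumSet, window: int, polyorder: int, deriv: int = 0) -> SpectrumSet:
    """Per-row Savitzky-Golay derivative, scaled per cm^-1.

    Boundary points use polynomial extrapolation of the edge window fits.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if window > s.n_variables:
        raise ValueError("window larger than the number of spectral variables")
    step = s.grid.step  # signed; negative for descending grids
    out = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=abs(step), axis=1, mode="interp",
    )
    if step < 0 and deriv % 2 == 1:
        out = -out
    return s.with_absorbance(out)


def norris_derivative(s: SpectrumSet, segment: int, gap: int, deriv: int) -> SpectrumSet:
    """Norris gap-segment derivative per row.

    Segment-mean smoothing (moving average of odd width ``segment``), then
    for ``deriv=1`` the forward gap difference quotient
    ``(s[i+g] - s[i]) / (nu[i+g] - nu[i])`` and for ``deriv=2`` the
    symmetric second difference across two gaps.  Edge points whose stencil
    leaves the grid take the nearest valid value.
    """
    if deriv not in (1, 2):
        raise ValueError("the Norris filter defines deriv 1 or 2 only")
    if segment % 2 == 0 or segment < 1:
        raise ValueError("segment must be odd and >= 1")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    p = s.n_variables
    if segment > p or deriv * gap >= p:
        raise ValueError("stencil wider than the number of spectral variables")
    nu = s.grid.values
    smoothed = (
        uniform_filter1d(s.absorbance, size=segment, axis=1, mode="nearest")
        if segment > 1
        else s.absorbance
    )
    out = np.empty_like(smoothed)
    g = gap
    if deriv == 1:
        core = (smoothed[:, g:] - smoothed[:, :-g]) / (nu[g:] - nu[:-g])
        out[:, : p - g] = core
        out[:, p - g :] = core[:, -1:]
    else:
        denom = (nu[2 * g :] - nu[g:-g]) * (nu[g:-g] - nu[: -2 * g])
        core = (smoothed[:, 2 * g :] - 2.0 * smoothed[:, g:-g] + smoothed[:, : -2 * g]) / denom
        out[:, g : p - g] = core
        out[:, :g] = core[:, :1]
        out[:, p - g :] = core[:, -1:]
    return s.with_absorbance(out)


def apply_preprocessing(spec: PreprocessSpec, s: SpectrumSet) -> SpectrumSet:
    """Dispatch a :class:`PreprocessSpec` to the matching filter."""
    if spec.derivative_order == 0 and spec.smoother == "none":
        return s.with_absorbance(s.absorbance.copy())
    if spec.smoother == "savitzky_golay":
        return savitzky_golay(s, spec.sg_window, spec.sg_polyorder, spec.derivative_order)
    return norris_derivative(s, spec.norris_segment, spec.norris_gap, spec.derivative_order)
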