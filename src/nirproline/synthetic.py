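"""Serum-like synthetic NIR spectra with known ground truth.

The generator follows a Beer-Lambert mixture model.  Each absorbance
spectrum is

    A_i = s_i * (background + c_i * analyte + sum_j u_ij * interferent_j)
          + a_i + b_i * (nu - nu_center) + eps_i

where ``c_i`` is the true analyte concentration (mg/ml), ``s_i`` a
multiplicative scatter factor near 1, ``a_i + b_i * nu`` an affine baseline
drift and ``eps_i`` iid additive noise.  All pure-component spectra are sums
of Gaussian bands in wavenumber.  Serum is ~90% water, so the background is
dominated by two broad water-like bands (combination band near 5200 cm^-1,
first O-H overtone near 6900 cm^-1) whose amplitude dwarfs the analyte
signal.  The analyte's characteristic bands default to the proline regions
near 7352, 8620 and 5988 cm^-1.

Concentrations are drawn from a normal law truncated by rejection to the
cohort range; the reference (wet-chemistry) value adds an independent
Gaussian measurement error, emulating HPLC uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import WavenumberGrid, make_grid
from .spectra_io import SpectrumSet

__all__ = [
    "Band",
    "GeneratorConfig",
    "GroundTruth",
    "make_default_config",
    "sample_concentrations",
    "pure_component_spectrum",
    "simulate",
]

# (center cm^-1, width cm^-1, amplitude) — width is the Gaussian sigma
Band = tuple[float, float, float]

#: Characteristic analyte band centers (cm^-1) used by the defaults.
DEFAULT_ANALYTE_BANDS: list[Band] = [
    (7352.0, 50.0, 4.0),
    (8620.0, 40.0, 2.5),
    (5988.0, 45.0, 3.0),
]

#: Water-dominated broad background: combination band + first overtone.
DEFAULT_BACKGROUND_BANDS: list[Band] = [
    (5200.0, 400.0, 1.2),
    (6900.0, 300.0, 0.9),
]

#: Two unnamed co-solutes with bands away from the analyte regions.
DEFAULT_INTERFERENT_BANDS: list[list[Band]] = [
    [(4550.0, 150.0, 0.05)],
    [(6250.0, 120.0, 0.04), (8300.0, 100.0, 0.03)],
]


@dataclass
class GeneratorConfig:
    """Parameters of the serum-spectrum simulator.

    Defaults reproduce the study conditions: 207 samples on a 1557-point
    10000-4000 cm^-1 grid, analyte concentration 0.005234 +/- 0.001866 mg/ml
    truncated to [0.001917, 0.008198] mg/ml, and a reference-method error of
    2% of the mean concentration.
    """

    n_samples: int = 207
    grid: WavenumberGrid = field(default_factory=lambda: make_grid(10000.0, 4000.0, 1557))
    analyte_bands: list[Band] = field(default_factory=lambda: list(DEFAULT_ANALYTE_BANDS))
    interferent_bands: list[list[Band]] = field(
        default_factory=lambda: [list(b) for b in DEFAULT_INTERFERENT_BANDS]
    )
    background_bands: list[Band] = field(default_factory=lambda: list(DEFAULT_BACKGROUND_BANDS))
    conc_mean: float = 0.005234
    conc_sd: float = 0.001866
    conc_min: float = 0.001917
    conc_max: float = 0.008198
    baseline_slope_sd: float = 2e-6  # absorbance per cm^-1
    baseline_offset_sd: float = 0.01  # absorbance units
    scatter_sd: float = 0.01  # dimensionless multiplicative
    noise_sd: float = 0.001  # absorbance units
    reference_error_sd: float = 0.02 * 0.005234  # mg/ml
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (self.conc_min < self.conc_mean < self.conc_max):
            raise ValueError("require conc_min < conc_mean < conc_max")
        for name in (
            "conc_sd",
            "baseline_slope_sd",
            "baseline_offset_sd",
            "scatter_sd",
            "noise_sd",
            "reference_error_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for band_list in [self.analyte_bands, self.background_bands, *self.interferent_bands]:
            for center, width, _amp in band_list:
                if width <= 0:
                    raise ValueError(f"band width must be > 0, got {width}")
                if not self.grid.contains(center):
                    raise ValueError(f"band center {center} cm^-1 outside the grid span")


def make_default_config(**overrides) -> GeneratorConfig:
    """Default study-condition config with keyword overrides."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """What the simulator knows that a real experiment would not."""

    true_concentrations: np.ndarray  # mg/ml
    reference_concentrations: np.ndarray  # mg/ml, true + reference-method error
    informative_mask: np.ndarray  # bool per grid point: analyte band > 1% of its max


def sample_concentrations(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Truncated-normal analyte concentrations for the cohort.

    Rejection sampling from N(conc_mean, conc_sd) restricted to the closed
    interval [conc_min, conc_max].  With ``conc_sd == 0`` the law is a point
    mass at the mean, which must then lie inside the interval.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.conc_sd == 0.0:
        if not (cfg.conc_min <= cfg.conc_mean <= cfg.conc_max):
            raise ValueError("degenerate law: mean outside the truncation interval")
        return np.full(cfg.n_samples, cfg.conc_mean)
    out = np.empty(0)
    # acceptance probability under the defaults is ~0.9; cap defends against
    # configurations whose interval carries negligible mass
    for _ in range(1000):
        draw = rng.normal(cfg.conc_mean, cfg.conc_sd, size=cfg.n_samples)
        keep = draw[(draw >= cfg.conc_min) & (draw <= cfg.conc_max)]
        out = np.concatenate([out, keep])
        if out.size >= cfg.n_samples:
            return out[: cfg.n_samples]
    raise ValueError("truncation interval carries too little probability mass")


def pure_component_spectrum(bands: list[Band], grid: WavenumberGrid) -> np.ndarray:
    """Sum of Gaussian bands evaluated on the grid; non-negative."""
    nu = grid.values
    spectrum = np.zeros_like(nu)
    lo, hi = grid.span
    for center, width, amplitude in bands:
        if width <= 0:
            raise ValueError(f"band width must be > 0, got {width}")
        if not (lo <= center <= hi):
            raise ValueError(f"band center {center} cm^-1 outside grid span [{lo}, {hi}]")
        spectrum = spectrum + amplitude * np.exp(-0.5 * ((nu - center) / width) ** 2)
    return spectrum


def simulate(cfg: GeneratorConfig) -> tuple[SpectrumSet, GroundTruth]:
    """Generate a cohort of serum-like spectra with ground truth.

    Deterministic given ``cfg`` (including its seed).  Independent random
    streams are spawned per corruption source so that e.g. switching noise
    off does not shift the concentrations drawn.
    """
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_conc, rng_interf, rng_scatter, rng_base, rng_noise, rng_ref = (
        np.random.default_rng(s) for s in streams
    )

    n, p = cfg.n_samples, len(cfg.grid)
    nu = cfg.grid.values
    conc = sample_concentrations(cfg, rng_conc)

    analyte = pure_component_spectrum(cfg.analyte_bands, cfg.grid)
    background = pure_component_spectrum(cfg.background_bands, cfg.grid)

    chemistry = background[None, :] + conc[:, None] * analyte[None, :]
    for bands in cfg.interferent_bands:
        component = pure_component_spectrum(bands, cfg.grid)
        u = np.clip(rng_interf.normal(1.0, 0.2, size=n), 0.0, None)
        chemistry = chemistry + u[:, None] * component[None, :]

    scatter = 1.0 + rng_scatter.normal(0.0, cfg.scatter_sd, size=n)
    offsets = rng_base.normal(0.0, cfg.baseline_offset_sd, size=n)
    slopes = rng_base.normal(0.0, cfg.baseline_slope_sd, size=n)
    baseline = offsets[:, None] + slopes[:, None] * (nu - nu.mean())[None, :]
    noise = rng_noise.normal(0.0, cfg.noise_sd, size=(n, p)) if cfg.noise_sd > 0 else 0.0

    absorbance = scatter[:, None] * chemistry + baseline + noise

    reference = conc + rng_ref.normal(0.0, cfg.reference_error_sd, size=n)
    reference = np.clip(reference, np.finfo(float).tiny, None)  # concentrations stay positive

    if analyte.max() > 0:
        informative = analyte > 0.01 * analyte.max()
    else:
        informative = np.zeros(p, dtype=bool)

    width = max(3, len(str(n)))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    return (
        SpectrumSet(ids, cfg.grid, absorbance),
        GroundTruth(conc, reference, informative),
    )
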