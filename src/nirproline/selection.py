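"""Wavelength selection: stepwise MLR, interval PLS and simulated annealing.

Three strategies for trimming a redundant full spectrum down to the
variables that actually carry analyte signal:

* :func:`smlr` -- classical stepwise multiple linear regression (forward
  entry, backward removal, F-test p-value thresholds), restricted to a
  wavenumber window.
* :func:`ipls` -- interval PLS: partition the grid into equal-width
  intervals, fit a cross-validated PLS model per interval, keep the
  interval with the lowest RMSECV (the full-spectrum model is fitted
  alongside for comparison).
* :func:`anneal` -- simulated annealing over a binary feature-retention
  vector V with m retained variables.  Each proposal redraws a uniformly
  random mask of the current size m, scores it by the validation-set
  correlation of an inner PLS fit, and is accepted by the Metropolis
  criterion P = 1 if dE <= 0 else exp(-dE/T) with dE = R_prev - R_new.
  Whenever the global best improves, m shrinks by a configured fraction,
  steering the search toward sparser masks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .grid import WavenumberGrid
from .metrics import r_coefficient
from .pls import CvCurve, PlsModel, cross_validate, fit_pls

__all__ = [
    "RetentionVector",
    "AnnealConfig",
    "AnnealTrace",
    "StepwiseModel",
    "IntervalModelSet",
    "smlr",
    "ipls",
    "acceptance_probability",
    "metropolis_accept",
    "propose",
    "sa_objective",
    "anneal",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RetentionVector:
    """Binary mask over spectral variables; m = number retained."""

    V: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.V, dtype=bool)
        if v.ndim != 1:
            raise ValueError("retention vector must be 1-D")
        if v.sum() < 1:
            raise ValueError("retention vector must retain at least one variable")
        object.__setattr__(self, "V", v)

    @property
    def m(self) -> int:
        return int(self.V.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.nonzero(self.V)[0]


# ---------------------------------------------------------------------------
# Stepwise multiple linear regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseModel:
    """OLS model on a stepwise-selected set of wavenumber variables."""

    selected: np.ndarray  # column indices into the full grid
    intercept: float
    coef: np.ndarray  # one per selected variable
    window: tuple[float, float]
    n_lv: int = 0  # for report compatibility; MLR has no latent variables

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X[:, self.selected] @ self.coef


def _best_forward_candidate(
    X: np.ndarray, y: np.ndarray, selected: list[int], candidates: np.ndarray
) -> tuple[int, float]:
    """Candidate with the smallest entry p-value, via partial correlation.

    The t-statistic of a candidate's coefficient in the augmented OLS model
    equals the t-statistic of the correlation between y and the candidate,
    both residualized against the current design -- evaluated here for all
    candidates at once instead of refitting per candidate.
    """
    n = len(y)
    df = n - len(selected) - 2
    if df < 1:
        return -1, 1.0
    design = np.ones((n, 1)) if not selected else np.column_stack([np.ones(n), X[:, selected]])
    Q, _ = np.linalg.qr(design)
    ry = y - Q @ (Q.T @ y)
    ry_norm = np.linalg.norm(ry)
    pool = np.asarray([j for j in candidates if j not in selected], dtype=int)
    if pool.size == 0 or ry_norm <= 1e-12 * max(1.0, np.linalg.norm(y)):
        return -1, 1.0
    Xc = X[:, pool]
    Rx = Xc - Q @ (Q.T @ Xc)
    rx_norm = np.linalg.norm(Rx, axis=0)
    col_scale = np.maximum(np.linalg.norm(Xc, axis=0), 1.0)
    valid = rx_norm > 1e-10 * col_scale  # excludes columns collinear with the model
    if not np.any(valid):
        return -1, 1.0
    corr = np.zeros(pool.size)
    corr[valid] = (Rx[:, valid].T @ ry) / (rx_norm[valid] * ry_norm)
    corr = np.clip(corr, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = np.abs(corr) * np.sqrt(df / np.maximum(1.0 - corr**2, 1e-300))
    pvals = np.where(valid, 2.0 * stats.t.sf(tstat, df), 1.0)
    best = int(np.argmin(pvals))
    return int(pool[best]), float(pvals[best])


def smlr(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavenumberGrid,
    window: tuple[float, float] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_vars: int = 15,
) -> StepwiseModel:
    """Forward-entry / backward-removal stepwise OLS inside a window.

    A candidate enters when its coefficient's two-sided p-value in the
    augmented model is the smallest and below ``p_enter``; after each entry
    any retained variable whose p-value exceeds ``p_remove`` is dropped
    (largest first).  Stops when no entry or removal happens, or at
    ``max_vars`` variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not p_enter < p_remove:
        raise ValueError("require p_enter < p_remove")
    if window is None:
        lo, hi = grid.span
    else:
        lo, hi = min(window), max(window)
    candidates = np.nonzero((grid.values >= lo) & (grid.values <= hi))[0]
    if candidates.size == 0:
        raise ValueError(f"no grid variables inside window [{lo}, {hi}] cm^-1")

    selected: list[int] = []
    while len(selected) < max_vars:
        changed = False
        best_j, best_p = _best_forward_candidate(X, y, selected, candidates)
        if best_j >= 0 and best_p < p_enter:
            selected.append(best_j)
            changed = True
        # backward removal
        while len(selected) > 1:
            fit = sm.OLS(y, sm.add_constant(X[:, selected])).fit()
            pvals = np.asarray(fit.pvalues[1:])
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        # no variable met the entry threshold: intercept-only model
        return StepwiseModel(np.asarray([], dtype=int), float(y.mean()), np.asarray([]), (lo, hi))
    fit = sm.OLS(y, sm.add_constant(X[:, selected])).fit()
    return StepwiseModel(
        selected=np.asarray(selected, dtype=int),
        intercept=float(fit.params[0]),
        coef=np.asarray(fit.params[1:], dtype=float),
        window=(lo, hi),
    )


# ---------------------------------------------------------------------------
# Interval PLS
# ---------------------------------------------------------------------------


@dataclass
class IntervalModelSet:
    """Per-interval PLS models plus the full-spectrum comparison model."""

    boundaries: list[tuple[float, float]]  # wavenumber range per interval
    index_slices: list[tuple[int, int]]  # [start, stop) columns per interval
    models: list[PlsModel]
    cv_curves: list[CvCurve]
    rmsecv: np.ndarray  # best RMSECV per interval
    best_index: int
    full_model: PlsModel
    full_cv: CvCurve

    @property
    def best_model(self) -> PlsModel:
        return self.models[self.best_index]

    @property
    def best_range(self) -> tuple[float, float]:
        return self.boundaries[self.best_index]


def ipls(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavenumberGrid,
    n_intervals: int = 9,
    max_lv: int = 10,
    n_folds: int = 10,
    cv_seed: int | None = None,
) -> IntervalModelSet:
    """Equal-width interval PLS with cross-validated LV choice per interval."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if p // n_intervals < 2:
        raise ValueError("each interval must hold at least 2 variables")

    edges = np.linspace(0, p, n_intervals + 1).astype(int)
    slices = [(int(edges[i]), int(edges[i + 1])) for i in range(n_intervals)]

    models, curves, best_rmsecv, bounds = [], [], [], []
    for start, stop in slices:
        cols = np.arange(start, stop)
        width = cols.size
        lv_cap = min(max_lv, width)
        if lv_cap < max_lv:
            logger.info("interval [%d:%d): LVs reduced to %d (only %d variables)", start, stop, lv_cap, width)
        curve = cross_validate(X[:, cols], y, max_lv=lv_cap, n_folds=n_folds, seed=cv_seed)
        model = fit_pls(X[:, cols], y, curve.chosen_n_lv, variable_subset=cols)
        models.append(model)
        curves.append(curve)
        best_rmsecv.append(float(curve.rmsecv[curve.chosen_n_lv - 1]))
        seg = grid.values[start:stop]
        bounds.append((float(seg.min()), float(seg.max())))

    full_cv = cross_validate(X, y, max_lv=min(max_lv, p), n_folds=n_folds, seed=cv_seed)
    full_model = fit_pls(X, y, full_cv.chosen_n_lv)
    return IntervalModelSet(
        boundaries=bounds,
        index_slices=slices,
        models=models,
        cv_curves=curves,
        rmsecv=np.asarray(best_rmsecv),
        best_index=int(np.argmin(best_rmsecv)),
        full_model=full_model,
        full_cv=full_cv,
    )


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


@dataclass
class AnnealConfig:
    """Schedule and inner-model settings for the annealing search.

    ``t0=None`` calibrates the initial temperature on a short warm-up so
    that roughly 80% of worsening moves would be accepted.  ``initial_m``
    defaults to half the grid.  On every global improvement m shrinks to
    ``max(ceil(shrink * m), n_lv)``.
    """

    t0: float | None = None
    alpha: float = 0.95
    steps_per_temperature: int = 50
    max_iterations: int = 2000
    n_lv: int = 5
    shrink: float = 0.95
    initial_m: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be > 0 (or None to auto-calibrate)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.steps_per_temperature < 1:
            raise ValueError("steps_per_temperature must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        if not 0 < self.shrink <= 1:
            raise ValueError("shrink must lie in (0, 1]")


@dataclass
class AnnealTrace:
    """Per-iteration record of the annealing run."""

    iteration: list[int] = field(default_factory=list)
    delta_e: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    m: list[int] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    best_objective: list[float] = field(default_factory=list)

    def append(self, iteration, delta_e, temperature, accepted, m, objective, best) -> None:
        self.iteration.append(int(iteration))
        self.delta_e.append(float(delta_e))
        self.temperature.append(float(temperature))
        self.accepted.append(bool(accepted))
        self.m.append(int(m))
        self.objective.append(float(objective))
        self.best_objective.append(float(best))

    def __len__(self) -> int:
        return len(self.iteration)


def acceptance_probability(delta_e: float, temperature: float) -> float:
    """Metropolis acceptance probability: 1 if dE <= 0, else exp(-dE/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0:
        return 1.0
    return float(math.exp(-delta_e / temperature))


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """One Metropolis decision; consumes exactly one uniform draw."""
    p = acceptance_probability(delta_e, temperature)
    return bool(rng.random() < p)


def propose(V: RetentionVector, m: int, rng: np.random.Generator) -> RetentionVector:
    """A uniformly random retention mask with exactly ``m`` ones."""
    size = V.V.size
    if not 1 <= m <= size:
        raise ValueError(f"m must satisfy 1 <= m <= {size}")
    mask = np.zeros(size, dtype=bool)
    mask[rng.choice(size, size=m, replace=False)] = True
    return RetentionVector(mask)


def sa_objective(
    V: RetentionVector,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_lv: int,
) -> float:
    """Validation-set correlation Rp of a PLS fit on the retained columns.

    The LV count is lowered to m (and to n_cal - 1) when the mask is
    narrower than the requested complexity.
    """
    cols = V.indices
    lv = min(n_lv, cols.size, len(y_cal) - 1)
    model = fit_pls(X_cal[:, cols], y_cal, lv, variable_subset=cols)
    return r_coefficient(model.predict(X_val[:, cols]), y_val)


def _calibrate_t0(
    X_cal, y_cal, X_val, y_val, cfg: AnnealConfig, m: int, r_init: float, rng: np.random.Generator
) -> float:
    """Median worsening step scaled so ~80% of worsening moves are accepted."""
    worsenings = []
    base = RetentionVector(np.ones(X_cal.shape[1], dtype=bool))
    for _ in range(20):
        r = sa_objective(propose(base, m, rng), X_cal, y_cal, X_val, y_val, cfg.n_lv)
        de = r_init - r
        if de > 0:
            worsenings.append(de)
    if not worsenings:
        return 0.01
    return float(np.median(worsenings) / math.log(1.0 / 0.8))


def anneal(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: AnnealConfig,
) -> tuple[RetentionVector, PlsModel, AnnealTrace]:
    """Simulated-annealing search over retention masks.

    Iteration 1 scores the initial mask; each later iteration proposes a
    fresh uniformly random mask of the current size m, scores it, and
    applies the Metropolis rule with dE = R_current - R_proposed.  On every
    improvement of the global best, m shrinks by ``cfg.shrink`` (floored at
    ``cfg.n_lv``).  Temperature cools geometrically every
    ``cfg.steps_per_temperature`` proposals.  Returns the best-ever mask,
    its refit model, and the full trace.
    """
    cfg.validate()
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    p = X_cal.shape[1]
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng_warm, rng = (np.random.default_rng(s) for s in ss)

    m = cfg.initial_m if cfg.initial_m is not None else max(cfg.n_lv, math.ceil(0.5 * p))
    if not 1 <= m <= p:
        raise ValueError(f"initial_m must satisfy 1 <= m <= {p}")

    all_on = RetentionVector(np.ones(p, dtype=bool))
    current = propose(all_on, m, rng) if m < p else all_on
    r_current = sa_objective(current, X_cal, y_cal, X_val, y_val, cfg.n_lv)
    best_mask, r_best = current, r_current

    temperature = cfg.t0 if cfg.t0 is not None else _calibrate_t0(
        X_cal, y_cal, X_val, y_val, cfg, m, r_current, rng_warm
    )

    trace = AnnealTrace()
    trace.append(1, 0.0, temperature, True, m, r_current, r_best)

    for it in range(2, cfg.max_iterations + 1):
        candidate = propose(current, m, rng)
        r_new = sa_objective(candidate, X_cal, y_cal, X_val, y_val, cfg.n_lv)
        delta_e = r_current - r_new  # improvement => dE <= 0
        accepted = metropolis_accept(delta_e, temperature, rng)
        if accepted:
            current, r_current = candidate, r_new
        if r_new > r_best:
            best_mask, r_best = candidate, r_new
            m = max(math.ceil(cfg.shrink * m), cfg.n_lv)
        trace.append(it, delta_e, temperature, accepted, m, r_new, r_best)
        if it % cfg.steps_per_temperature == 0:
            temperature *= cfg.alpha

    cols = best_mask.indices
    lv = min(cfg.n_lv, cols.size, len(y_cal) - 1)
    best_model = fit_pls(X_cal[:, cols], y_cal, lv, variable_subset=cols)
    return best_mask, best_model, trace
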