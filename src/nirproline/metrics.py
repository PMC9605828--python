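"""Calibration figures of merit.

With C_i the reference (wet-chemistry) concentration, C_hat_i the NIR
prediction and C_bar the reference mean:

* RMSE  = sqrt( sum (C_hat_i - C_i)^2 / n )   -- RMSEC on the calibration
  set, RMSEP on the validation set, RMSECV over pooled out-of-fold
  residuals.
* R     = sqrt( max(0, 1 - SSE/SST) )         -- Rc / Rp; for least-squares
  calibrated predictions this equals |Pearson r| between predicted and
  reference values (both variants are reported).
* SEC/SEP = bias-corrected standard deviation of residuals (n-1).
* Offset  = mean residual (bias).
* RPD     = SD(reference) / SEP, the residual predictive deviation.

These satisfy RMSE^2 = SE^2 (n-1)/n + offset^2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["rmse", "r_coefficient", "sec_sep", "rpd", "offset", "ModelReport", "build_report"]


def _pair(predicted, reference) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.size != r.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {r.size} references")
    return p, r


def rmse(predicted, reference) -> float:
    """Root-mean-square error of prediction against reference values."""
    p, r = _pair(predicted, reference)
    if p.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def r_coefficient(predicted, reference) -> float:
    """R = sqrt(max(0, 1 - SSE/SST)); in [0, 1]."""
    p, r = _pair(predicted, reference)
    sst = float(np.sum((r - r.mean()) ** 2))
    if sst == 0:
        raise ValueError("reference values have zero variance")
    sse = float(np.sum((p - r) ** 2))
    return float(np.sqrt(max(0.0, 1.0 - sse / sst)))


def sec_sep(predicted, reference) -> float:
    """Bias-corrected standard deviation of the residuals (SEC or SEP)."""
    p, r = _pair(predicted, reference)
    if p.size < 2:
        raise ValueError("standard error needs n >= 2")
    d = p - r
    return float(np.sqrt(np.sum((d - d.mean()) ** 2) / (p.size - 1)))


def rpd(reference, sep: float) -> float:
    """Residual predictive deviation: SD(reference) / SEP."""
    r = np.asarray(reference, dtype=float).ravel()
    if sep <= 0:
        raise ValueError("RPD requires SEP > 0")
    return float(r.std(ddof=1) / sep)


def offset(predicted, reference) -> float:
    """Mean residual (prediction bias)."""
    p, r = _pair(predicted, reference)
    return float(np.mean(p - r))


@dataclass
class ModelReport:
    """Per-model row of the strategy-comparison table."""

    label: str
    n_lv: int
    rc: float
    rmsec: float
    rp: float
    rmsep: float
    rmsecv: float | None
    sec: float
    sep: float
    offset: float
    rpd: float
    rc_pearson: float
    rp_pearson: float
    n_variables: int | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _abs_pearson(predicted: np.ndarray, reference: np.ndarray) -> float:
    p, r = _pair(predicted, reference)
    if p.std() == 0 or r.std() == 0:
        return float("nan")
    return float(abs(np.corrcoef(p, r)[0, 1]))


def build_report(
    model,
    cal: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    cv_curve=None,
    label: str = "",
    n_variables: int | None = None,
) -> ModelReport:
    """Assemble all figures of merit for one fitted model.

    ``model`` is anything with a ``predict(X)`` method (and optionally
    ``n_lv``); ``cal`` and ``val`` are (X, y) pairs.
    """
    X_cal, y_cal = cal
    X_val, y_val = val
    if len(y_cal) == 0 or len(y_val) == 0:
        raise ValueError("calibration and validation sets must be non-empty")
    yhat_cal = np.asarray(model.predict(X_cal)).ravel()
    yhat_val = np.asarray(model.predict(X_val)).ravel()
    sep = sec_sep(yhat_val, y_val)
    return ModelReport(
        label=label,
        n_lv=int(getattr(model, "n_lv", 0)),
        rc=r_coefficient(yhat_cal, y_cal),
        rmsec=rmse(yhat_cal, y_cal),
        rp=r_coefficient(yhat_val, y_val),
        rmsep=rmse(yhat_val, y_val),
        rmsecv=(float(cv_curve.rmsecv[cv_curve.chosen_n_lv - 1]) if cv_curve is not None else None),
        sec=sec_sep(yhat_cal, y_cal),
        sep=sep,
        offset=offset(yhat_val, y_val),
        rpd=(rpd(y_val, sep) if sep > 0 else float("inf")),
        rc_pearson=_abs_pearson(yhat_cal, y_cal),
        rp_pearson=_abs_pearson(yhat_val, y_val),
        n_variables=n_variables,
    )
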