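"""Outlier screening and calibration/validation partitioning.

Screening ranks spectra by Mahalanobis distance in a PCA score space, then
tests the ranked distances with Dixon's Q test and Chauvenet's criterion; a
sample is excluded when either test flags it.  Partitioning uses the
Kennard-Stone max-min-distance algorithm (a seeded random split is also
available), and cohorts are summarised with the usual Number / Max / Min /
Mean +/- SD / CV statistics plus a Welch two-sample t-test between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .spectra_io import SpectrumSet

__all__ = [
    "OutlierReport",
    "SplitResult",
    "CohortStats",
    "mahalanobis_distances",
    "dixon_test",
    "chauvenet",
    "kennard_stone",
    "random_split",
    "cohort_stats",
    "compare_groups",
    "screen_outliers",
]

logger = logging.getLogger(__name__)

# Dixon's Q critical values (Rorabacher 1991, two-tailed), ratio variant by n:
# r10 for n=3..7, r11 for 8..10, r21 for 11..13, r22 for 14..30.
_DIXON_CRITICAL = {
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
        8: 0.615, 9: 0.570, 10: 0.534,
        11: 0.625, 12: 0.592, 13: 0.565,
        14: 0.590, 15: 0.568, 16: 0.548, 17: 0.531, 18: 0.516, 19: 0.503,
        20: 0.491, 21: 0.480, 22: 0.470, 23: 0.461, 24: 0.452, 25: 0.445,
        26: 0.438, 27: 0.432, 28: 0.426, 29: 0.419, 30: 0.414,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680,
        8: 0.717, 9: 0.672, 10: 0.635,
        11: 0.709, 12: 0.660, 13: 0.638,
        14: 0.670, 15: 0.647, 16: 0.633, 17: 0.611, 18: 0.594, 19: 0.580,
        20: 0.567, 21: 0.555, 22: 0.544, 23: 0.535, 24: 0.526, 25: 0.517,
        26: 0.510, 27: 0.502, 28: 0.495, 29: 0.489, 30: 0.483,
    },
}


@dataclass
class OutlierReport:
    """Screening outcome for one cohort."""

    sample_ids: list[str]
    distances: np.ndarray  # Mahalanobis distance per sample, same order as ids
    dixon_flag: bool
    dixon_statistic: float
    chauvenet_flags: np.ndarray  # bool per sample
    chauvenet_expected: np.ndarray  # n * P(|Z| > z) per sample
    excluded_ids: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "sample_id": sid,
                "mahalanobis_distance": float(d),
                "chauvenet_flag": bool(c),
                "excluded": sid in self.excluded_ids,
            }
            for sid, d, c in zip(self.sample_ids, self.distances, self.chauvenet_flags)
        ]


@dataclass
class SplitResult:
    calibration_ids: list[str]
    validation_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets overlap")


@dataclass
class CohortStats:
    n: int
    max: float
    min: float
    mean: float
    sd: float
    cv: float


def mahalanobis_distances(s: SpectrumSet, n_components: int) -> np.ndarray:
    """Mahalanobis distance of each spectrum in a PCA score space.

    Spectra are mean-centered and projected onto the leading
    ``n_components`` principal components; distances use the scores'
    (sample) covariance.  The full-dimensional spectral covariance is
    singular whenever variables outnumber samples, hence the projection.
    """
    n = s.n_samples
    if not 1 <= n_components < n:
        raise ValueError("require 1 <= n_components < n_samples")
    x = s.absorbance - s.absorbance.mean(axis=0)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    if sv[n_components - 1] <= sv[0] * 1e-12:
        raise ValueError("covariance singular in score space: n_components too large")
    scores = u[:, :n_components] * sv[:n_components]
    cov = np.cov(scores, rowvar=False).reshape(n_components, n_components)
    centered = scores - scores.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(cov), centered)
    return np.sqrt(np.clip(d2, 0.0, None))


def dixon_test(values: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """Dixon's Q test for a single outlying extreme.

    Computes the gap/range ratio appropriate for the sample size (both
    extremes are examined; the larger ratio is the suspect) and compares it
    with the tabulated critical value.  Valid for 3 <= n <= 30.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if not 3 <= n <= 30:
        raise ValueError("Dixon's test is tabulated for 3 <= n <= 30")
    if alpha not in _DIXON_CRITICAL:
        raise ValueError(f"no Dixon table for alpha={alpha}; use 0.05 or 0.01")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    if n <= 7:  # r10
        q_low = ratio(x[1] - x[0], x[-1] - x[0])
        q_high = ratio(x[-1] - x[-2], x[-1] - x[0])
    elif n <= 10:  # r11
        q_low = ratio(x[1] - x[0], x[-2] - x[0])
        q_high = ratio(x[-1] - x[-2], x[-1] - x[1])
    elif n <= 13:  # r21
        q_low = ratio(x[2] - x[0], x[-2] - x[0])
        q_high = ratio(x[-1] - x[-3], x[-1] - x[1])
    else:  # r22
        q_low = ratio(x[2] - x[0], x[-3] - x[0])
        q_high = ratio(x[-1] - x[-3], x[-1] - x[2])

    q = max(q_low, q_high)
    return q > _DIXON_CRITICAL[alpha][n], float(q)


def chauvenet(values: np.ndarray) -> np.ndarray:
    """Chauvenet's criterion: flag x when n * P(|Z| > |x - mean|/sd) < 1/2."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Chauvenet's criterion needs n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("Chauvenet: zero standard deviation, nothing flagged")
        return np.zeros(n, dtype=bool)
    z = np.abs(x - x.mean()) / sd
    return n * 2.0 * stats.norm.sf(z) < 0.5


def _chauvenet_expected(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.full(x.size, float(x.size))
    z = np.abs(x - x.mean()) / sd
    return x.size * 2.0 * stats.norm.sf(z)


def kennard_stone(s: SpectrumSet, n_cal: int) -> SplitResult:
    """Kennard-Stone max-min Euclidean-distance calibration subset.

    The first two picks are the maximum-distance pair; each later pick
    maximizes its minimum distance to the already-selected set.  Ties break
    toward the lower sample index.  The complement becomes the validation
    set.
    """
    n = s.n_samples
    if not 2 <= n_cal < n:
        raise ValueError("require 2 <= n_cal < n_samples")
    dist = squareform(pdist(s.absorbance, metric="euclidean"))
    # lexicographically smallest max-distance pair
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    first = (min(i, j), max(i, j))
    selected = [first[0], first[1]]
    remaining = [k for k in range(n) if k not in selected]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    while len(selected) < n_cal:
        cand = remaining[int(np.argmax(min_dist[remaining]))]  # argmax keeps lowest index on ties
        selected.append(cand)
        remaining.remove(cand)
        min_dist = np.minimum(min_dist, dist[cand])
    cal = [s.sample_ids[k] for k in sorted(selected)]
    val = [s.sample_ids[k] for k in sorted(remaining)]
    return SplitResult(cal, val)


def random_split(s: SpectrumSet, n_cal: int, seed: int) -> SplitResult:
    """Seeded uniformly random calibration/validation split."""
    n = s.n_samples
    if not 2 <= n_cal < n:
        raise ValueError("require 2 <= n_cal < n_samples")
    order = np.random.default_rng(seed).permutation(n)
    cal = sorted(order[:n_cal].tolist())
    val = sorted(order[n_cal:].tolist())
    return SplitResult([s.sample_ids[k] for k in cal], [s.sample_ids[k] for k in val])


def cohort_stats(concs: np.ndarray) -> CohortStats:
    """Number / Max / Min / Mean / SD / CV summary of a concentration cohort."""
    x = np.asarray(concs, dtype=float)
    if x.size < 2:
        raise ValueError("cohort statistics need n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        cv = 0.0
    elif mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    else:
        cv = sd / mean
    return CohortStats(n=int(x.size), max=float(x.max()), min=float(x.min()), mean=mean, sd=sd, cv=cv)


def compare_groups(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch two-sample t-test p-value between cohorts."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise ValueError("both groups have zero variance with unequal means")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def screen_outliers(
    s: SpectrumSet,
    variance_retained: float = 0.99,
    alpha: float = 0.05,
    n_components: int | None = None,
) -> OutlierReport:
    """Rank spectra by Mahalanobis distance and flag outliers.

    The PCA dimension defaults to the smallest number of components
    retaining ``variance_retained`` of the spectral variance.  Dixon's test
    examines the ranked distances (the 30 largest when the cohort exceeds
    the table's range) and flags the extreme distance if significant;
    Chauvenet's criterion flags any distance with expected count < 1/2.  A
    sample is excluded when either test flags it.
    """
    x = s.absorbance - s.absorbance.mean(axis=0)
    sv = np.linalg.svd(x, compute_uv=False)
    if n_components is None:
        frac = np.cumsum(sv**2) / np.sum(sv**2)
        n_components = int(np.searchsorted(frac, variance_retained) + 1)
        n_components = min(n_components, s.n_samples - 1)
    d = mahalanobis_distances(s, n_components)

    order = np.argsort(d)[::-1]
    top = d[order[: min(30, d.size)]] if d.size > 30 else d
    dixon_flag, dixon_q = dixon_test(top, alpha=alpha) if top.size >= 3 else (False, 0.0)
    ch_flags = chauvenet(d) if d.size >= 4 else np.zeros(d.size, dtype=bool)

    excluded = {s.sample_ids[i] for i in np.nonzero(ch_flags)[0]}
    if dixon_flag:
        excluded.add(s.sample_ids[int(np.argmax(d))])
    return OutlierReport(
        sample_ids=list(s.sample_ids),
        distances=d,
        dixon_flag=bool(dixon_flag),
        dixon_statistic=float(dixon_q),
        chauvenet_flags=ch_flags,
        chauvenet_expected=_chauvenet_expected(d),
        excluded_ids=sorted(excluded),
    )
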