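"""Colour-factor extraction, fWHR/BMI arithmetic, measurement quality gates,
rating aggregation and interrater reliability.

The interrater statistic is the two-way consistency, average-score
intraclass correlation ICC(3,k) = (MS_stimuli - MS_error) / MS_stimuli from
the stimuli x raters ANOVA layout (raters fixed). The colour factor is a
single-factor model of the standardised CIELab channels fitted by iterated
principal-axis factoring, with regression (Thurstone) factor scores; it is
extracted only when Horn's parallel analysis retains exactly one factor and
the channels are strongly collinear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RepeatabilityError, SchemaError

__all__ = [
    "RatingMatrix",
    "bmi",
    "fwhr",
    "repeatability_gate",
    "icc_3k",
    "mean_ratings",
    "parallel_analysis",
    "extract_colour_factor",
    "use_colour_factor",
]


@dataclass
class RatingMatrix:
    """Raters x stimuli integer ratings on the 1-7 scale (NaN = missing)."""

    values: np.ndarray            # (n_raters, n_stimuli) float with NaN
    rater_ids: list[str]
    stimulus_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("rating matrix must be 2-D")
        if self.values.shape[0] < 2:
            raise SchemaError("need >= 2 raters")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 1 or finite.max() > 7):
            raise SchemaError("ratings outside the 1-7 scale")
        rated = np.sum(np.isfinite(self.values), axis=0)
        if np.any(rated < 2):
            thin = [self.stimulus_ids[i] for i in np.flatnonzero(rated < 2)]
            raise SchemaError(f"stimuli rated by < 2 raters: {thin[:5]}")

    @property
    def n_raters(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.stimulus_ids)
        df.insert(0, "rater_id", self.rater_ids)
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight [kg] divided by squared height [m]."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m ** 2


def fwhr(width: float, height: float) -> float:
    """Facial width-to-height ratio (bizygomatic width / upper-face height)."""
    width = np.asarray(width, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(width <= 0) or np.any(height <= 0):
        raise ValueError("width and height must be positive")
    return width / height


def repeatability_gate(measure_1, measure_2) -> np.ndarray:
    """Accept two repeated measurements if they correlate at r > 0.9.

    Returns the element-wise mean when accepted; raises
    :class:`RepeatabilityError` (carrying the observed r) otherwise.
    """
    m1 = np.asarray(measure_1, dtype=float)
    m2 = np.asarray(measure_2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1 or m1.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if m1.std() == 0 or m2.std() == 0:
        raise ValueError("zero variance: repeatability undefined")
    r = float(np.corrcoef(m1, m2)[0, 1])
    if not r > 0.9:
        raise RepeatabilityError(r)
    return 0.5 * (m1 + m2)


def _complete_matrix(matrix: RatingMatrix) -> np.ndarray:
    """Drop stimuli with any missing rating (listwise by stimulus)."""
    keep = np.all(np.isfinite(matrix.values), axis=0)
    return matrix.values[:, keep]


def icc_3k(matrix: RatingMatrix) -> float:
    """Two-way consistency, average-score intraclass correlation ICC(3,k).

    Computed from the stimuli x raters two-way ANOVA:
    ``ICC(3,k) = (MS_stimuli - MS_error) / MS_stimuli``.
    """
    x = _complete_matrix(matrix).T  # stimuli x raters
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 stimuli and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    if ms_rows == 0:
        raise ValueError("no between-stimulus variance; ICC undefined")
    return float((ms_rows - ms_error) / ms_rows)


def mean_ratings(matrix: RatingMatrix) -> pd.Series:
    """Arithmetic mean rating per stimulus over non-missing raters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix.values, axis=0)
    if np.any(~np.isfinite(means)):
        raise ValueError("stimulus with zero ratings")
    return pd.Series(means, index=matrix.stimulus_ids, name="mean_rating")


def parallel_analysis(x: np.ndarray, n_random: int = 200,
                      seed: int | np.random.Generator = 0,
                      quantile: float | None = None) -> int:
    """Horn's parallel analysis: number of factors to retain.

    Eigenvalues of the observed correlation matrix are compared against the
    mean (or, if ``quantile`` is given, that quantile) of eigenvalues from
    ``n_random`` independent standard-normal matrices of the same shape; the
    retained count is the number of leading observed eigenvalues exceeding
    their random counterparts.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("parallel analysis needs n >= 10")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant column; correlation matrix undefined")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rand = np.empty((n_random, p))
    for i in range(n_random):
        z = rng.standard_normal((n, p))
        rand[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    ref = (rand.mean(axis=0) if quantile is None
           else np.quantile(rand, quantile, axis=0))
    retained = 0
    for lam_obs, lam_ref in zip(obs, ref):
        if lam_obs > lam_ref:
            retained += 1
        else:
            break
    return retained


def extract_colour_factor(x: np.ndarray, max_iter: int = 500,
                          tol: float = 1e-10):
    """Single-factor model of the (standardised) colour channels.

    Iterated principal-axis factoring on the correlation matrix; factor
    scores by the regression (Thurstone) method (mean 0, variance <= 1); the
    loading sign is oriented so the first channel (L*) loads positively.
    Returns ``(loadings, scores, r2)`` with ``r2_j`` the squared correlation
    between the score and channel j. A Heywood case (communality >= 1) is
    clipped at 0.995 with a warning.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant column; factor model undefined")
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    corr = np.corrcoef(z, rowvar=False)
    # start from squared multiple correlations
    inv = np.linalg.pinv(corr)
    comm = 1.0 - 1.0 / np.diag(inv)
    comm = np.clip(comm, 0.0, 0.995)
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, comm)
        eigval, eigvec = np.linalg.eigh(reduced)
        lam, v = eigval[-1], eigvec[:, -1]
        loadings = np.sqrt(max(lam, 0.0)) * v
        new_comm = loadings ** 2
        if np.any(new_comm >= 1.0):
            warnings.warn("Heywood case: communality clipped at 0.995",
                          stacklevel=2)
            new_comm = np.clip(new_comm, 0.0, 0.995)
            loadings = np.sign(loadings) * np.sqrt(new_comm)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            break
        comm = new_comm
    if loadings[0] < 0:
        loadings = -loadings
    # Thurstone regression scores: z @ R^{-1} @ loadings (pinv tolerates the
    # exactly-singular rank-one limit)
    weights = np.linalg.pinv(corr) @ loadings
    scores = z @ weights
    r2 = np.array([np.corrcoef(scores, z[:, j])[0, 1] ** 2 for j in range(p)])
    return loadings, scores, r2


def use_colour_factor(x: np.ndarray, n_random: int = 200,
                      seed: int | np.random.Generator = 0,
                      collinearity_threshold: float = 0.8) -> bool:
    """Decision rule for replacing the three channels by one factor.

    True when parallel analysis retains exactly one factor *and* the maximum
    pairwise channel correlation exceeds ``collinearity_threshold`` in
    absolute value — the strongly collinear regime in which separate channel
    slopes are unidentifiable in practice.
    """
    retained = parallel_analysis(x, n_random=n_random, seed=seed)
    corr = np.corrcoef(np.asarray(x, dtype=float), rowvar=False)
    max_r = np.max(np.abs(corr[np.triu_indices_from(corr, k=1)]))
    return retained == 1 and max_r > collinearity_threshold
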