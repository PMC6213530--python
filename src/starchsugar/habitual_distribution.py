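"""Habitual (usual) intake estimation via the best-power method.

Short multi-day records overstate between-person spread because each
person's few days carry day-to-day noise.  The procedure here: (1) pick a
power-transform exponent on a grid by minimising the absolute sample
skewness of person-day values, (2) decompose variance on the transformed
scale with a one-way random-effects ANOVA, (3) shrink person means toward
the grand mean, (4) back-transform with a second-order bias correction.

The published software implementing this method is not redistributable;
this module is a documented reimplementation with every choice (grid,
tie-break, zero offset, correction order) surfaced in the API.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EmptySetError, EstimationError

logger = logging.getLogger(__name__)

#: Grid of candidate exponents (lambda = 0 means log).
DEFAULT_LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)


def power_transform(x, lam: float):
    """Box-Cox style one-parameter power transform.

    ``(x**lam - 1)/lam`` for lam != 0, ``ln x`` for lam = 0; strictly
    increasing in x; defined for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("power transform requires strictly positive values")
    if abs(lam) < 1e-10:  # log limit; also avoids x**lam underflowing to 1
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def inverse_power_transform(t, lam: float):
    """Inverse of :func:`power_transform`."""
    t = np.asarray(t, dtype=float)
    if abs(lam) < 1e-10:
        return np.exp(t)
    base = lam * t + 1.0
    if np.any(base <= 0):
        raise DomainError("value outside the image of the power transform")
    return np.power(base, 1.0 / lam)


def _inverse_second_derivative(t, lam: float):
    """d2/dt2 of the inverse transform, used for bias correction."""
    t = np.asarray(t, dtype=float)
    if abs(lam) < 1e-10:
        return np.exp(t)
    base = lam * t + 1.0
    return (1.0 - lam) * np.power(base, 1.0 / lam - 2.0)


def zero_offset(values: Sequence[float]) -> float:
    """Offset added to handle zeros: half the smallest positive value."""
    arr = np.asarray(list(values), dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise DomainError("cannot offset an all-zero series")
    return float(positive.min() / 2.0)


def select_power(
    values: Sequence[float],
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    offset: float = 0.0,
) -> float:
    """Grid-search lambda minimising |sample skewness| of transformed values.

    Ties (including constant data, where skewness is undefined) resolve to
    the candidate closest to 1.
    """
    arr = np.asarray(list(values), dtype=float) + offset
    if arr.size < 2 or np.all(arr == arr[0]):
        return 1.0
    if np.any(arr <= 0):
        raise DomainError("non-positive values; apply a zero offset first")
    best_lam, best_score = 1.0, np.inf
    for lam in grid:
        transformed = power_transform(arr, float(lam))
        skew = stats.skew(transformed, bias=True)
        if not np.isfinite(skew):
            continue
        score = abs(skew)
        # strict improvement, or tie resolved toward lambda = 1
        if score < best_score - 1e-12 or (
            abs(score - best_score) <= 1e-12
            and abs(lam - 1.0) < abs(best_lam - 1.0)
        ):
            best_lam, best_score = float(lam), score
    return best_lam


@dataclass
class VarianceComponents:
    sigma2_between: float
    sigma2_within: float
    grand_mean: float


def variance_components(
    values: Sequence[float], person_ids: Sequence
) -> VarianceComponents:
    """One-way random-effects ANOVA on (already transformed) person-day data.

    sigma2_within = MSW; sigma2_between = max(0, (MSB - MSW)/n0) with
    n0 = (N - sum(n_i^2)/N) / (k - 1) for unbalanced designs.
    """
    y = np.asarray(list(values), dtype=float)
    ids = np.asarray(list(person_ids))
    if y.shape != ids.shape:
        raise ValueError("values and person_ids must align")
    unique, inverse = np.unique(ids, return_inverse=True)
    k = unique.size
    if k < 2:
        raise EstimationError("variance decomposition needs >= 2 persons")
    n_i = np.bincount(inverse).astype(float)
    if np.all(n_i < 2):
        raise EstimationError(
            "all persons have single-day data; habitual estimation impossible"
        )
    N = float(y.size)
    group_sums = np.bincount(inverse, weights=y)
    group_means = group_sums / n_i
    grand_mean = float(y.mean())
    ssb = float(np.sum(n_i * (group_means - grand_mean) ** 2))
    ssw = float(np.sum((y - group_means[inverse]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    sigma2_b = max(0.0, (msb - msw) / n0)
    return VarianceComponents(sigma2_b, msw, grand_mean)


@dataclass
class HabitualModel:
    """Fitted best-power model for one nutrient in one stratum."""

    lam: float
    sigma2_between: float
    sigma2_within: float
    grand_mean: float
    n_days: dict = field(default_factory=dict)  # person id -> recorded days
    offset: float = 0.0

    def shrink_factor(self, n_i: int) -> float:
        denom = self.sigma2_between + self.sigma2_within / n_i
        if denom == 0.0:
            return 0.0
        return float(np.sqrt(self.sigma2_between / denom))

    def back_transform(self, t: float) -> float:
        """Inverse transform with second-order bias correction for the
        within-person variance removed on the transformed scale."""
        value = inverse_power_transform(t, self.lam)
        correction = 0.5 * _inverse_second_derivative(t, self.lam) * self.sigma2_within
        return max(0.0, float(value + correction) - self.offset)


@dataclass
class HabitualEstimate:
    person_id: str
    habitual_intake: float  # original scale

    def __post_init__(self) -> None:
        if self.habitual_intake < 0:
            raise DomainError("habitual intake must be non-negative")


def fit_habitual_model(
    values: Sequence[float],
    person_ids: Sequence,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    handle_zeros: bool = True,
) -> HabitualModel:
    """Select lambda, transform, and decompose variance for person-day data."""
    arr = np.asarray(list(values), dtype=float)
    ids = list(person_ids)
    if arr.size == 0:
        raise EmptySetError("no person-day values")
    offset = 0.0
    if handle_zeros and np.any(arr <= 0):
        offset = zero_offset(arr)
        logger.info("zero offset %.6g applied before power selection", offset)
    lam = select_power(arr, grid=grid, offset=offset)
    transformed = power_transform(arr + offset, lam)
    vc = variance_components(transformed, ids)
    unique, inverse = np.unique(np.asarray(ids), return_inverse=True)
    n_days = {pid: int(c) for pid, c in zip(unique, np.bincount(inverse))}
    return HabitualModel(
        lam=lam,
        sigma2_between=vc.sigma2_between,
        sigma2_within=vc.sigma2_within,
        grand_mean=vc.grand_mean,
        n_days=n_days,
        offset=offset,
    )


def habitual_estimates(
    model: HabitualModel,
    values: Sequence[float],
    person_ids: Sequence,
) -> list[HabitualEstimate]:
    """Shrink each person's transformed mean toward the grand mean and
    back-transform; SD of the estimates never exceeds the SD of raw means."""
    arr = np.asarray(list(values), dtype=float) + model.offset
    ids = np.asarray(list(person_ids))
    transformed = power_transform(arr, model.lam)
    unique, inverse = np.unique(ids, return_inverse=True)
    n_i = np.bincount(inverse).astype(float)
    person_means = np.bincount(inverse, weights=transformed) / n_i
    out = []
    for pid, mean_t, n in zip(unique, person_means, n_i):
        c = model.shrink_factor(int(n))
        shrunk = model.grand_mean + c * (mean_t - model.grand_mean)
        out.append(HabitualEstimate(str(pid), model.back_transform(shrunk)))
    return out


def habitual_frame(
    person_days: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> tuple[pd.DataFrame, dict[str, HabitualModel]]:
    """Habitual estimates for each column of a (person_id, day)-indexed
    frame; returns the estimates frame and the fitted model per column.

    Columns where estimation is impossible (e.g. a stratum recorded a single
    day per person) are passed through as raw person means, with a log entry.
    """
    cols = list(columns) if columns is not None else list(person_days.columns)
    ids = person_days.index.get_level_values("person_id")
    result: dict[str, pd.Series] = {}
    models: dict[str, HabitualModel] = {}
    for col in cols:
        values = person_days[col]
        try:
            model = fit_habitual_model(values, ids, grid=grid)
            estimates = habitual_estimates(model, values, ids)
            result[col] = pd.Series(
                {e.person_id: e.habitual_intake for e in estimates}, name=col
            )
            models[col] = model
        except (EstimationError, DomainError) as exc:
            logger.warning("habitual estimation skipped for %r: %s", col, exc)
            raw = values.groupby(ids).mean()
            raw.index = raw.index.astype(str)
            result[col] = raw
    frame = pd.DataFrame(result)
    frame.index.name = "person_id"
    return frame, models
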