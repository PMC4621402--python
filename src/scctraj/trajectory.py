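"""Per-subject SCC trajectories: log-trend fit, fluctuation, shape class.

Each subject contributes an ordered series of SCCS scores over 4-9
measurement occasions.  Three statistics are derived per subject:

* an ordinary-least-squares fit of ``Y = a + b * ln(t)`` with ``t`` the
  1-based occasion index (:func:`fit_log_trajectory`);
* the *fluctuation* statistic: the root-mean-square of residuals around
  that log trend with denominator ``k`` (the number of occasions), i.e.
  the population SD of residuals (:func:`fluctuation_rmse`);
* one of five reliable-change *shape* labels (:func:`classify_shape`).

Shape classification works on lag-1 differences ``d_i = Y_{i+1} - Y_i``.
A difference is a reliable increase when ``d_i > rci`` and a reliable
decrease when ``d_i < -rci`` (strict: a change of exactly ``rci`` points
is noise).  The five labels form a total partition:

plateau
    no reliable change in either direction;
monotonic increase
    at least one reliable increase, no reliable decrease;
monotonic decrease
    at least one reliable decrease, no reliable increase;
"V" shape
    exactly one reliable decrease, not at the last transition, and the
    very next transition is a reliable increase (destabilisation with
    immediate re-integration);
discontinuous (other)
    both directions of reliable change occur but the "V" pattern does
    not hold.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DegenerateDesignError, InsufficientDataError, InvalidArgumentError

__all__ = [
    "MeasurementSeries",
    "LogTrendFit",
    "ShapeLabel",
    "fit_log_trajectory",
    "fluctuation_rmse",
    "classify_shape",
]

#: Occasion-count range observed in study-like data; outside it a
#: warning (not an error) is emitted.
STUDY_K_RANGE = (4, 9)


class ShapeLabel(enum.Enum):
    """The five reliable-change trajectory classes."""

    MONOTONIC_INCREASE = "monotonic_increase"
    V_SHAPE = "v_shape"
    DISCONTINUOUS_OTHER = "discontinuous_other"
    PLATEAU = "plateau"
    MONOTONIC_DECREASE = "monotonic_decrease"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MeasurementSeries:
    """One subject's ordered SCCS scores over measurement occasions.

    ``occasions`` are strictly increasing 1-based indices; ``weeks`` is
    optional calendar metadata (the default analysis keys on the
    occasion index).
    """

    subject_id: str
    scores: tuple
    occasions: tuple = None  # type: ignore[assignment]
    weeks: Optional[tuple] = None

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.scores)
        object.__setattr__(self, "scores", scores)
        k = len(scores)
        occ = self.occasions
        if occ is None:
            occ = tuple(range(1, k + 1))
        else:
            occ = tuple(int(o) for o in occ)
        object.__setattr__(self, "occasions", occ)
        if len(occ) != k:
            raise InvalidArgumentError(
                f"{self.subject_id}: {k} scores but {len(occ)} occasions"
            )
        if k and occ[0] < 1:
            raise InvalidArgumentError(f"{self.subject_id}: occasion indices start at 1")
        if any(b <= a for a, b in zip(occ, occ[1:])):
            raise InvalidArgumentError(
                f"{self.subject_id}: occasion indices must be strictly increasing"
            )
        if self.weeks is not None:
            wk = tuple(float(w) for w in self.weeks)
            object.__setattr__(self, "weeks", wk)
            if len(wk) != k:
                raise InvalidArgumentError(
                    f"{self.subject_id}: {k} scores but {len(wk)} weeks"
                )
        if k and not STUDY_K_RANGE[0] <= k <= STUDY_K_RANGE[1]:
            warnings.warn(
                f"{self.subject_id}: {k} occasions is outside the study-like "
                f"range {STUDY_K_RANGE[0]}-{STUDY_K_RANGE[1]}",
                stacklevel=2,
            )
        if any(b - a > 1 for a, b in zip(occ, occ[1:])):
            warnings.warn(
                f"{self.subject_id}: gap in occasion indices; differences are "
                "taken between successive observed occasions",
                stacklevel=2,
            )

    @property
    def k(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class LogTrendFit:
    """OLS fit of ``Y = a + b ln(t)`` plus the fluctuation RMSE."""

    intercept: float
    slope: float
    fitted: tuple
    rmse: float


def _as_series(series: Union[MeasurementSeries, Sequence[float]]) -> MeasurementSeries:
    if isinstance(series, MeasurementSeries):
        return series
    return MeasurementSeries(subject_id="<anonymous>", scores=tuple(series))


def fit_log_trajectory(
    series: Union[MeasurementSeries, Sequence[float]],
    time_from: str = "index",
) -> LogTrendFit:
    """Least-squares logarithmic trend of a score series.

    Fits ``Y_i = a + b * ln(t_i)`` where ``t_i`` is the 1-based occasion
    index by default (``time_from="week"`` uses the recorded week
    numbers instead, which must be positive).  The returned ``rmse``
    divides the residual sum of squares by ``k``, not ``k - 2``: it is
    the population SD of the residuals, matching the fluctuation
    statistic's definition.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = _as_series(series)
    if s.k < 2:
        raise InsufficientDataError(f"{s.subject_id}: need at least 2 occasions, got {s.k}")
    if time_from == "index":
        t = np.asarray(s.occasions, dtype=float)
    elif time_from == "week":
        if s.weeks is None:
            raise InvalidArgumentError("time_from='week' requires week metadata")
        t = np.asarray(s.weeks, dtype=float)
        if np.any(t <= 0):
            raise InvalidArgumentError("weeks must be positive for a log fit")
    else:
        raise InvalidArgumentError(f"unknown time_from {time_from!r}")
    if np.all(t == t[0]):
        raise DegenerateDesignError(f"{s.subject_id}: all time points identical")
    y = np.asarray(s.scores, dtype=float)
    x = np.log(t)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    rmse = math.sqrt(float(np.sum((y - fitted) ** 2)) / s.k)
    return LogTrendFit(
        intercept=float(coef[0]), slope=float(coef[1]),
        fitted=tuple(float(f) for f in fitted), rmse=rmse,
    )


def fluctuation_rmse(
    series: Union[MeasurementSeries, Sequence[float]],
    time_from: str = "index",
) -> float:
    """SCC fluctuation: RMS residual around the subject's log trend."""
    return fit_log_trajectory(series, time_from=time_from).rmse


def classify_shape(
    series: Union[MeasurementSeries, Sequence[float]],
    rci: float = 3.48,
) -> ShapeLabel:
    """Assign one of the five reliable-change shape labels.

    See the module docstring for the label definitions.  The function is
    total: every series with at least two occasions receives exactly one
    label.
    """
    if rci <= 0:
        raise InvalidArgumentError("rci must be > 0")
    if isinstance(series, MeasurementSeries):
        scores = series.scores
    else:
        scores = tuple(float(v) for v in series)
    k = len(scores)
    if k < 2:
        raise InsufficientDataError(f"need at least 2 occasions, got {k}")
    inc = []  # indices i (0-based into diffs) with a reliable increase
    dec = []
    for i in range(k - 1):
        d = scores[i + 1] - scores[i]
        if d > rci:
            inc.append(i)
        elif d < -rci:
            dec.append(i)
    if not inc and not dec:
        return ShapeLabel.PLATEAU
    if inc and not dec:
        return ShapeLabel.MONOTONIC_INCREASE
    if dec and not inc:
        return ShapeLabel.MONOTONIC_DECREASE
    # both directions present
    if len(dec) == 1:
        i = dec[0]
        if i + 1 <= k - 2 and (scores[i + 2] - scores[i + 1]) > rci:
            return ShapeLabel.V_SHAPE
    return ShapeLabel.DISCONTINUOUS_OTHER
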