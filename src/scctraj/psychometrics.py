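"""Reliable-change thresholds and clinical-significance cutoffs.

The pipeline flags a score change as *reliable* when it exceeds an
instrument-specific reliable-change threshold (RCI; Jacobson & Truax).
The study's configured constants are 3.48 raw points for the 12-item
Self-Concept Clarity Scale (SCCS) and 56.6 points for the KS-II symptom
questionnaire.  These constants are carried on :class:`InstrumentSpec`
and are configurable; :func:`reliable_change_threshold` exposes the
standard closed form ``z * sd * sqrt(2 * (1 - reliability))`` as a
utility for users who want to derive a threshold from psychometric
inputs instead.

Clinical-significance cutoffs between a dysfunctional and a healthy
reference distribution are computed by :func:`midpoint_cutoff`, either
as the simple midpoint of the two means or as the SD-weighted "c"
criterion.  The SCC integration cutoff used by the cohort module — the
midpoint 34 between a borderline-personality sample (mean 23.76, SD
7.44) and a healthy sample (mean 44.88, SD 11.28) — comes from the
simple-midpoint rule with nearest-integer rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .errors import InvalidArgumentError

__all__ = [
    "InstrumentSpec",
    "CutoffResult",
    "reliable_change_threshold",
    "midpoint_cutoff",
    "SCCS",
    "KS2",
    "KON",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """A measurement instrument with its reliable-change threshold.

    Parameters
    ----------
    name:
        Instrument label, e.g. ``"SCCS"``.
    score_min, score_max:
        Raw score range of the questionnaire total.
    rci_threshold:
        Configured reliable-change threshold in raw score points, or
        ``None`` when no reliable-change dichotomy is defined for the
        instrument.
    reliability:
        Test reliability in ``(0, 1]`` if known.
    norm_sd:
        Normative standard deviation if known.
    higher_is_better:
        Whether larger scores indicate better functioning (true for
        SCCS, false for the two symptom/trait questionnaires).
    """

    name: str
    score_min: float
    score_max: float
    rci_threshold: Optional[float] = None
    reliability: Optional[float] = None
    norm_sd: Optional[float] = None
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if not self.score_min < self.score_max:
            raise InvalidArgumentError(
                f"{self.name}: score_min must be < score_max "
                f"({self.score_min} >= {self.score_max})"
            )
        if self.rci_threshold is not None:
            if self.rci_threshold <= 0:
                raise InvalidArgumentError(f"{self.name}: rci_threshold must be > 0")
            if self.rci_threshold >= self.score_max - self.score_min:
                raise InvalidArgumentError(
                    f"{self.name}: rci_threshold {self.rci_threshold} exceeds the "
                    f"score range {self.score_max - self.score_min}"
                )
        if self.reliability is not None and not 0 < self.reliability <= 1:
            raise InvalidArgumentError(f"{self.name}: reliability must lie in (0, 1]")
        if self.norm_sd is not None and self.norm_sd < 0:
            raise InvalidArgumentError(f"{self.name}: norm_sd must be >= 0")

    def in_range(self, score: float) -> bool:
        return self.score_min <= score <= self.score_max


#: Self-Concept Clarity Scale: 12 items, totals 12-60, reliable change 3.48.
SCCS = InstrumentSpec("SCCS", 12, 60, rci_threshold=3.48, higher_is_better=True)

#: KS-II symptom questionnaire: 85 items scored 0/1/4/7, totals 0-595,
#: reliable change 56.6; lower is better.
KS2 = InstrumentSpec("KS-II", 0, 595, rci_threshold=56.6, higher_is_better=False)

#: KON-2006 neurotic personality questionnaire (trait measure; no
#: reliable-change dichotomy is used for it in this pipeline).
KON = InstrumentSpec("KON-2006", 0, 235, rci_threshold=None, higher_is_better=False)


def reliable_change_threshold(
    sd: float, reliability: float, confidence: float = 0.95
) -> float:
    """Jacobson-Truax reliable-change threshold.

    Returns ``z(confidence) * sd * sqrt(2 * (1 - reliability))`` with the
    two-sided z convention (0.95 -> 1.959964).  A pre-post difference
    larger than this value is unlikely (at the given confidence) to be
    measurement error alone.

    This is provided as a utility; the pipeline's defaults are the
    configured constants on :data:`SCCS` and :data:`KS2`.
    """
    if sd <= 0:
        raise InvalidArgumentError("sd must be > 0")
    if not 0 < reliability <= 1:
        raise InvalidArgumentError("reliability must lie in (0, 1]")
    if not 0 < confidence < 1:
        raise InvalidArgumentError("confidence must lie in (0, 1)")
    z = norm.ppf(0.5 + confidence / 2.0)
    return float(z * sd * math.sqrt(2.0 * (1.0 - reliability)))


@dataclass(frozen=True)
class CutoffResult:
    """A clinical-significance cutoff before and after rounding."""

    cutoff_raw: float
    cutoff_applied: int
    method: str
    rounding: str


_METHODS = ("simple_midpoint", "jacobson_c")
_ROUNDINGS = ("nearest", "floor")


def midpoint_cutoff(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    method: str = "simple_midpoint",
    rounding: str = "nearest",
) -> CutoffResult:
    """Cutoff between a clinical (a) and a reference (b) distribution.

    ``simple_midpoint`` returns ``(mean_a + mean_b) / 2``;
    ``jacobson_c`` returns the SD-weighted criterion
    ``(sd_a * mean_b + sd_b * mean_a) / (sd_a + sd_b)``, which lies
    strictly between the two means whenever both SDs are positive.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise InvalidArgumentError("standard deviations must be > 0")
    if method == "simple_midpoint":
        raw = (mean_a + mean_b) / 2.0
    elif method == "jacobson_c":
        raw = (sd_a * mean_b + sd_b * mean_a) / (sd_a + sd_b)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}; expected one of {_METHODS}")
    if rounding == "nearest":
        applied = int(math.floor(raw + 0.5))
    elif rounding == "floor":
        applied = int(math.floor(raw))
    else:
        raise InvalidArgumentError(f"unknown rounding {rounding!r}; expected one of {_ROUNDINGS}")
    return CutoffResult(cutoff_raw=float(raw), cutoff_applied=applied, method=method, rounding=rounding)
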