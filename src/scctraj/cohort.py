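"""Four personality dispositions and their cluster-based validation.

Subjects are crossed on two baseline dichotomies:

* *integrated* (first-occasion SCCS >= 34) vs *disintegrated* (<= 33);
  the cutoff 34 is the rounded midpoint of a borderline-personality and
  a healthy reference SCC distribution (see :mod:`scctraj.psychometrics`);
* *functional* (baseline KON-2006 strictly below the cutoff) vs
  *dysfunctional* (at or above it); the KON cutoff is the median
  KON-2006 score of the integrated subgroup (34 in the study), computed
  on the integrated subjects but applied to the whole cohort.

The resulting four dispositions are validated against an unsupervised
k-means partition of the standardized baseline (SCCS, KON-2006) plane;
agreement is summarized by Cramér's V on the 4 x 4 cross-tabulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

from .errors import InvalidCohortError
from .trajectory import MeasurementSeries

__all__ = [
    "SubjectRecord",
    "Disposition",
    "ClusterValidation",
    "kon_cutoff_from_integrated",
    "categorize_disposition",
    "validate_dispositions_kmeans",
    "cramers_v",
]


class Disposition(enum.Enum):
    """Cross of the integration and functionality dichotomies."""

    INTEGRATED_FUNCTIONAL = "integrated_functional"
    INTEGRATED_DYSFUNCTIONAL = "integrated_dysfunctional"
    DISINTEGRATED_FUNCTIONAL = "disintegrated_functional"
    DISINTEGRATED_DYSFUNCTIONAL = "disintegrated_dysfunctional"

    @property
    def integrated(self) -> bool:
        return self in (
            Disposition.INTEGRATED_FUNCTIONAL,
            Disposition.INTEGRATED_DYSFUNCTIONAL,
        )

    @property
    def functional(self) -> bool:
        return self in (
            Disposition.INTEGRATED_FUNCTIONAL,
            Disposition.DISINTEGRATED_FUNCTIONAL,
        )

    @classmethod
    def from_flags(cls, integrated: bool, functional: bool) -> "Disposition":
        return {
            (True, True): cls.INTEGRATED_FUNCTIONAL,
            (True, False): cls.INTEGRATED_DYSFUNCTIONAL,
            (False, True): cls.DISINTEGRATED_FUNCTIONAL,
            (False, False): cls.DISINTEGRATED_DYSFUNCTIONAL,
        }[(bool(integrated), bool(functional))]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's identifiers, baselines, outcome scores and series."""

    subject_id: str
    unit_id: str
    group_id: str
    scc_t1: float
    kon_t1: float
    ks2_pre: float
    ks2_post: float
    series: MeasurementSeries

    def __post_init__(self) -> None:
        if not self.unit_id or not self.group_id:
            raise InvalidCohortError(f"{self.subject_id}: empty unit/group id")
        if self.series.k and abs(self.scc_t1 - self.series.scores[0]) > 1e-9:
            raise InvalidCohortError(
                f"{self.subject_id}: scc_t1 ({self.scc_t1}) must equal the "
                f"first series score ({self.series.scores[0]})"
            )


def kon_cutoff_from_integrated(
    records: Sequence[SubjectRecord], scc_cutoff: float = 34
) -> float:
    """Median baseline KON-2006 among the integrated subjects.

    Integration is SCCS(t1) >= ``scc_cutoff``; the even-n median is the
    midpoint of the two central values.  Raises
    :class:`InvalidCohortError` when no subject is integrated.
    """
    kon = [r.kon_t1 for r in records if r.scc_t1 >= scc_cutoff]
    if not kon:
        raise InvalidCohortError("no subject reaches the integration cutoff")
    return float(np.median(kon))


def categorize_disposition(
    record: Union[SubjectRecord, tuple],
    scc_cutoff: float = 34,
    kon_cutoff: float = 34,
) -> Disposition:
    """Disposition of one subject from the two baseline cutoffs.

    Accepts a :class:`SubjectRecord` or a plain ``(scc_t1, kon_t1)``
    pair.  Integrated means SCCS >= ``scc_cutoff``; functional means
    KON strictly below ``kon_cutoff`` (a subject exactly at the KON
    cutoff is dysfunctional).
    """
    if isinstance(record, SubjectRecord):
        scc, kon = record.scc_t1, record.kon_t1
    else:
        scc, kon = record
    return Disposition.from_flags(scc >= scc_cutoff, kon < kon_cutoff)


@dataclass(frozen=True)
class ClusterValidation:
    """Cross-tabulation of k-means clusters against dispositions."""

    contingency: pd.DataFrame  # dispositions (rows) x clusters (columns)
    cramers_v: float
    n: int


def cramers_v(table: np.ndarray) -> float:
    """Cramér's V of a two-way count table: sqrt(chi2 / (n (min(r,c)-1)))."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise InvalidCohortError("Cramér's V needs at least a 2x2 table")
    chi2 = chi2_contingency(table, correction=False)[0]
    n = table.sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def validate_dispositions_kmeans(
    records: Sequence[SubjectRecord],
    k: int = 4,
    seed: int = 0,
    scc_cutoff: float = 34,
    kon_cutoff: Optional[float] = None,
    n_init: int = 10,
) -> ClusterValidation:
    """k-means validation of the cutoff-based disposition split.

    Runs k-means (``n_init`` restarts, fixed seed) on z-standardized
    baseline (SCCS, KON-2006), cross-tabulates the cluster labels
    against the cutoff dispositions, and returns Cramér's V.  When
    ``kon_cutoff`` is ``None`` it is derived from the integrated
    subgroup via :func:`kon_cutoff_from_integrated`.
    """
    n = len(records)
    if k < 2:
        raise InvalidCohortError("k must be >= 2 for a meaningful comparison")
    if n < k:
        raise InvalidCohortError(f"need at least k={k} subjects, got {n}")
    X = np.array([[r.scc_t1, r.kon_t1] for r in records], dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise InvalidCohortError("zero variance in a baseline feature")
    Z = (X - X.mean(axis=0)) / sd
    if kon_cutoff is None:
        kon_cutoff = kon_cutoff_from_integrated(records, scc_cutoff)
    labels = [categorize_disposition(r, scc_cutoff, kon_cutoff).value for r in records]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    clusters = km.fit_predict(Z)
    tab = pd.crosstab(pd.Series(labels, name="disposition"),
                      pd.Series(clusters, name="cluster"))
    # keep all four disposition rows even if empty in this cohort
    order = [d.value for d in Disposition]
    tab = tab.reindex([d for d in order if d in tab.index] +
                      [d for d in order if d not in tab.index], fill_value=0)
    return ClusterValidation(contingency=tab, cramers_v=cramers_v(tab.to_numpy()), n=n)
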