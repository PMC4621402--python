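"""Study-like synthetic cohorts with known ground truth.

The generator emulates the structure of the group-psychotherapy study
the pipeline is built for: 85 inpatients in three therapeutic units and
seven therapy groups, measured on the SCCS at 4-9 occasions, with
baseline SCCS / KON-2006 / KS-II distributions per personality
disposition, trajectory-shape archetypes for the five reliable-change
classes, and KS-II change distributions tied to shape x disposition.

Every subject is built from explicit ground truth (true disposition,
true shape, drawn change), returned alongside the records, so each
pipeline stage can be tested for recovery.  Generation is fully
deterministic given the seed.

Key defaults (all configurable on :class:`CohortConfig`):

* disposition sizes 22/21/10/32 (fixed, not sampled);
* baseline means/SDs per disposition for SCCS (45/8, 41/5, 28/3, 26/5),
  KON-2006 (17/11, 54/15, 18/10, 60/15) and KS-II pre (233/85, 315/99,
  260/104, 339/84), drawn as truncated normals on the
  disposition-consistent side of the cutoffs and within instrument
  ranges, then rounded to integer questionnaire totals;
* shape frequencies per disposition x improvement taken from the
  study's observed cross-tabulation;
* KS-II change drawn per shape x disposition-contrast cell
  (``by_shape`` mode, the default) or from the study's fitted
  moderation coefficients applied to the realized fluctuation
  (``linear`` mode);
* per-subject occasion-noise SD drawn from Gamma(4, 0.5) (mean 2,
  SD 1) — subjects must differ in fluctuation for the RMSE regression
  to be meaningful; a fixed value can be configured instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import Disposition, SubjectRecord
from .errors import InvalidConfigError
from .psychometrics import KON, KS2, SCCS
from .trajectory import MeasurementSeries, ShapeLabel, classify_shape, fluctuation_rmse

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "SyntheticCohort",
    "default_archetype",
    "generate_cohort",
    "generate_fixture",
    "FIXTURE_SEED",
]

_DISPOSITIONS = tuple(d.value for d in Disposition)
_SHAPES = tuple(s.value for s in ShapeLabel)

#: Step size used for reliable moves in the archetypes; comfortably
#: above the 3.48 reliable-change threshold so moderate occasion noise
#: rarely flips a step's category.
_STEP = 8.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """A base trajectory guaranteed to classify as its target shape.

    ``steps`` are the occasion-to-occasion increments of the noise-free
    curve; classification is shift-invariant, so the start level is
    supplied per subject.  Construction verifies self-consistency: the
    zero-noise curve must classify as ``shape`` at the 3.48 threshold.
    """

    shape: ShapeLabel
    steps: Tuple[float, ...]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        curve = np.concatenate([[0.0], np.cumsum(self.steps)])
        got = classify_shape(curve, rci=3.48)
        if got is not self.shape:
            raise InvalidConfigError(
                f"archetype steps {self.steps} classify as {got.value}, "
                f"not {self.shape.value}"
            )

    def curve(self, start: float) -> np.ndarray:
        return start + np.concatenate([[0.0], np.cumsum(self.steps)])


def default_archetype(shape: ShapeLabel, k: int) -> ArchetypeSpec:
    """Canonical step pattern of length ``k - 1`` for a shape class."""
    if k < 3:
        raise InvalidConfigError("archetypes need k >= 3 occasions")
    m = k - 1
    steps = [0.0] * m
    if shape is ShapeLabel.MONOTONIC_INCREASE:
        for i in range(min(2, m)):
            steps[i] = _STEP
    elif shape is ShapeLabel.MONOTONIC_DECREASE:
        for i in range(min(2, m)):
            steps[i] = -_STEP
    elif shape is ShapeLabel.V_SHAPE:
        dip = max(0, min(m - 2, (k - 2) // 2))
        steps[dip] = -_STEP
        steps[dip + 1] = _STEP + 1.0
    elif shape is ShapeLabel.DISCONTINUOUS_OTHER:
        if m >= 3:
            steps[0] = -_STEP
            steps[1] = -_STEP
            steps[2] = _STEP + 1.0
        else:  # a rise then an unrecovered drop
            steps[0] = _STEP + 1.0
            steps[1] = -_STEP
    # plateau: all zeros
    return ArchetypeSpec(shape=shape, steps=tuple(steps))


def _study_shape_counts() -> Dict[str, Dict[str, Tuple[int, int]]]:
    """(improved, not improved) counts per disposition x shape."""
    mi, v, do, pl, md = _SHAPES
    return {
        "integrated_functional": {mi: (3, 0), v: (4, 3), do: (2, 3), pl: (2, 0), md: (0, 5)},
        "integrated_dysfunctional": {mi: (1, 3), v: (6, 3), do: (1, 2), pl: (0, 2), md: (0, 3)},
        "disintegrated_functional": {mi: (0, 1), v: (1, 2), do: (2, 1), pl: (0, 1), md: (0, 2)},
        "disintegrated_dysfunctional": {mi: (6, 1), v: (9, 1), do: (2, 7), pl: (0, 1), md: (0, 5)},
    }


def _default_change_params() -> Dict[Tuple[str, str], Tuple[float, float]]:
    """KS-II change (mean, SD) per shape x disposition contrast.

    The four printed cells are used verbatim; the remaining cells are
    chosen so that P(change > 56.6) under the normal matches the
    observed improvement proportion of the cell (see docs/methods.md).
    """
    mi, v, do, pl, md = _SHAPES
    return {
        (mi, "if"): (150.0, 60.0), (mi, "other"): (75.0, 90.0),
        (v, "if"): (30.0, 116.0), (v, "other"): (103.0, 87.0),
        (do, "if"): (40.0, 90.0), (do, "other"): (20.0, 90.0),
        (pl, "if"): (129.0, 58.0), (pl, "other"): (-15.0, 68.0),
        (md, "if"): (-80.0, 70.0), (md, "other"): (-80.0, 70.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_per_disposition: Dict[str, int] = field(default_factory=lambda: {
        "integrated_functional": 22,
        "integrated_dysfunctional": 21,
        "disintegrated_functional": 10,
        "disintegrated_dysfunctional": 32,
    })
    k: int = 6
    scc_params: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "integrated_functional": (45.0, 8.0),
        "integrated_dysfunctional": (41.0, 5.0),
        "disintegrated_functional": (28.0, 3.0),
        "disintegrated_dysfunctional": (26.0, 5.0),
    })
    kon_params: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "integrated_functional": (17.0, 11.0),
        "integrated_dysfunctional": (54.0, 15.0),
        "disintegrated_functional": (18.0, 10.0),
        "disintegrated_dysfunctional": (60.0, 15.0),
    })
    ks2_params: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "integrated_functional": (233.0, 85.0),
        "integrated_dysfunctional": (315.0, 99.0),
        "disintegrated_functional": (260.0, 104.0),
        "disintegrated_dysfunctional": (339.0, 84.0),
    })
    shape_improvement_counts: Dict[str, Dict[str, Tuple[int, int]]] = field(
        default_factory=_study_shape_counts
    )
    change_params: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=_default_change_params
    )
    outcome_model: str = "by_shape"  # or "linear"
    #: intercept, rmse slope, pd_fi main effect, pd_fi x rmse
    #: interaction, residual SD — the study's fitted moderation model.
    linear_params: Tuple[float, float, float, float, float] = (
        1.92, 29.76, 61.25, -48.49, 85.26
    )
    #: fixed occasion-noise SD, or ("gamma", shape, scale) for a
    #: per-subject draw.
    noise_sd: Union[float, Tuple[str, float, float]] = ("gamma", 4.0, 0.5)
    var_group: float = 0.0
    var_unit: float = 0.0
    group_to_unit: Dict[str, str] = field(default_factory=lambda: {
        "G1": "U1", "G2": "U1", "G3": "U1",
        "G4": "U2", "G5": "U2",
        "G6": "U3", "G7": "U3",
    })
    scc_cutoff: float = 34.0
    kon_cutoff: float = 34.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_disposition) != set(_DISPOSITIONS):
            raise InvalidConfigError("n_per_disposition must cover the four dispositions")
        if any(n < 0 for n in self.n_per_disposition.values()):
            raise InvalidConfigError("disposition sizes must be >= 0")
        if self.k < 3:
            raise InvalidConfigError("k must be >= 3")
        for params in (self.scc_params, self.kon_params, self.ks2_params):
            for mean, sd in params.values():
                if sd < 0:
                    raise InvalidConfigError("SDs must be >= 0")
        for disp, counts in self.shape_improvement_counts.items():
            tot = sum(a + b for a, b in counts.values())
            if tot <= 0:
                raise InvalidConfigError(f"{disp}: shape frequencies sum to 0")
            if any(a < 0 or b < 0 for a, b in counts.values()):
                raise InvalidConfigError(f"{disp}: negative shape frequency")
        for (shape, _), (mean, sd) in self.change_params.items():
            if sd < 0:
                raise InvalidConfigError("change SDs must be >= 0")
        if self.outcome_model not in ("by_shape", "linear"):
            raise InvalidConfigError(f"unknown outcome_model {self.outcome_model!r}")
        if self.var_group < 0 or self.var_unit < 0:
            raise InvalidConfigError("variance components must be >= 0")
        if not self.group_to_unit:
            raise InvalidConfigError("group_to_unit must be non-empty")
        if isinstance(self.noise_sd, tuple):
            kind = self.noise_sd[0]
            if kind != "gamma" or len(self.noise_sd) != 3:
                raise InvalidConfigError("noise_sd tuple must be ('gamma', shape, scale)")
            if self.noise_sd[1] <= 0 or self.noise_sd[2] <= 0:
                raise InvalidConfigError("gamma parameters must be > 0")
        elif self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus their ground truth, one row per subject."""

    records: List[SubjectRecord]
    truth: pd.DataFrame
    config: CohortConfig


def _trunc_round(rng, mean, sd, lo, hi, score_lo, score_hi):
    """Truncated-normal draw rounded to an integer questionnaire total.

    Truncation happens at half-integer boundaries so the rounded value
    cannot cross out of [score_lo, score_hi].
    """
    lo = max(lo, score_lo)
    hi = min(hi, score_hi)
    if sd == 0:
        x = min(max(mean, lo), hi)
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        x = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return int(np.clip(np.floor(x + 0.5), np.ceil(score_lo), np.floor(score_hi)))


def generate_cohort(
    config: Optional[CohortConfig] = None, seed: Optional[int] = None
) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given config + seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    groups = list(config.group_to_unit)
    units = sorted(set(config.group_to_unit.values()))
    g_eff = {g: rng.normal(0.0, np.sqrt(config.var_group)) for g in groups}
    u_eff = {u: rng.normal(0.0, np.sqrt(config.var_unit)) for u in units}
    b0, b_rmse, b_if, b_int, resid_sd = config.linear_params

    records: List[SubjectRecord] = []
    truth_rows: List[dict] = []
    idx = 0
    for disp_name in _DISPOSITIONS:
        disp = Disposition(disp_name)
        counts = config.shape_improvement_counts[disp_name]
        probs = np.array([sum(counts[s]) for s in _SHAPES], dtype=float)
        probs /= probs.sum()
        scc_m, scc_s = config.scc_params[disp_name]
        kon_m, kon_s = config.kon_params[disp_name]
        ks2_m, ks2_s = config.ks2_params[disp_name]
        # disposition-consistent truncation windows (half-integer edges so
        # rounding stays on the right side of each cutoff)
        if disp.integrated:
            scc_lo, scc_hi = config.scc_cutoff - 0.5, SCCS.score_max
        else:
            scc_lo, scc_hi = SCCS.score_min, config.scc_cutoff - 0.5 - 1e-9
        if disp.functional:
            kon_lo, kon_hi = KON.score_min, config.kon_cutoff - 0.5 - 1e-9
        else:
            kon_lo, kon_hi = config.kon_cutoff - 0.5, KON.score_max

        for _ in range(config.n_per_disposition[disp_name]):
            idx += 1
            sid = f"S{idx:03d}"
            group = groups[(idx - 1) % len(groups)]
            unit = config.group_to_unit[group]
            shape = ShapeLabel(_SHAPES[rng.choice(len(_SHAPES), p=probs)])
            arch = default_archetype(shape, config.k)
            offsets = np.concatenate([[0.0], np.cumsum(arch.steps)])
            start_lo = max(SCCS.score_min - offsets.min(), scc_lo)
            start_hi = min(SCCS.score_max - offsets.max(), scc_hi)
            if start_lo > start_hi:
                raise InvalidConfigError(
                    f"{disp_name}/{shape.value}: no feasible start level"
                )
            if scc_s == 0:
                start = float(np.clip(scc_m, start_lo, start_hi))
            else:
                a, b = (start_lo - scc_m) / scc_s, (start_hi - scc_m) / scc_s
                start = float(truncnorm.rvs(a, b, loc=scc_m, scale=scc_s,
                                            random_state=rng))
            if isinstance(config.noise_sd, tuple):
                nsd = float(rng.gamma(config.noise_sd[1], config.noise_sd[2]))
            else:
                nsd = float(config.noise_sd)
            raw = start + offsets + rng.normal(0.0, nsd, size=config.k)
            scores = np.clip(np.floor(raw + 0.5), SCCS.score_min, SCCS.score_max)
            scores = tuple(int(s) for s in scores)
            series = MeasurementSeries(
                subject_id=sid, scores=scores,
                occasions=tuple(range(1, config.k + 1)),
                weeks=tuple(2.0 * i for i in range(config.k)),
            )
            kon = _trunc_round(rng, kon_m, kon_s, kon_lo, kon_hi,
                               KON.score_min, KON.score_max)
            ks2_pre = _trunc_round(rng, ks2_m, ks2_s, KS2.score_min,
                                   KS2.score_max, KS2.score_min, KS2.score_max)
            contrast = "if" if disp is Disposition.INTEGRATED_FUNCTIONAL else "other"
            if config.outcome_model == "by_shape":
                mean, sd = config.change_params[(shape.value, contrast)]
                change = float(rng.normal(mean, sd))
            else:
                rmse = fluctuation_rmse(series)
                fi = 1.0 if contrast == "if" else 0.0
                change = float(b0 + b_rmse * rmse + b_if * fi
                               + b_int * fi * rmse + rng.normal(0.0, resid_sd))
            change += g_eff[group] + u_eff[unit]
            ks2_post = int(np.clip(np.floor(ks2_pre - change + 0.5),
                                   KS2.score_min, KS2.score_max))
            records.append(SubjectRecord(
                subject_id=sid, unit_id=unit, group_id=group,
                scc_t1=float(scores[0]), kon_t1=float(kon),
                ks2_pre=float(ks2_pre), ks2_post=float(ks2_post),
                series=series,
            ))
            truth_rows.append({
                "subject_id": sid,
                "true_disposition": disp_name,
                "true_shape": shape.value,
                "noise_sd": nsd,
                "drawn_change": change,
                "start_level": start,
            })
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    return SyntheticCohort(records=records, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Bundled fixture
# ---------------------------------------------------------------------------

#: Seed of the small cohort shipped for I/O and CLI smoke tests.
FIXTURE_SEED = 2015

_FIXTURE_CONFIG_KW = dict(
    n_per_disposition={
        "integrated_functional": 6,
        "integrated_dysfunctional": 6,
        "disintegrated_functional": 3,
        "disintegrated_dysfunctional": 9,
    },
    k=5,
    noise_sd=0.5,
)


def cohort_to_long(cohort: SyntheticCohort) -> pd.DataFrame:
    """Long-format table for the pipeline's CSV dialect.

    KS-II appears at the first and last occasion only; KON-2006 at the
    first occasion only (matching the study's administration scheme).
    """
    rows = []
    for r in cohort.records:
        k = r.series.k
        for j, (occ, score) in enumerate(zip(r.series.occasions, r.series.scores)):
            rows.append({
                "subject_id": r.subject_id,
                "unit_id": r.unit_id,
                "group_id": r.group_id,
                "occasion": occ,
                "week": r.series.weeks[j] if r.series.weeks else 2.0 * (occ - 1),
                "sccs": int(score),
                "ks2": int(r.ks2_pre) if j == 0 else (int(r.ks2_post) if j == k - 1 else ""),
                "kon": int(r.kon_t1) if j == 0 else "",
            })
    return pd.DataFrame(rows)


def generate_fixture(seed: int = FIXTURE_SEED, path: Optional[Path] = None) -> str:
    """Small deterministic cohort (n = 24, k = 5) as long-format CSV text.

    Returns the CSV text; when ``path`` is given, also writes it (and a
    ``<stem>.truth.csv`` sidecar with the ground-truth labels) with
    ``\\n`` line endings so regeneration is byte-identical per seed.
    """
    config = CohortConfig(seed=seed, **_FIXTURE_CONFIG_KW)
    cohort = generate_cohort(config)
    long_df = cohort_to_long(cohort)
    buf = io.StringIO()
    long_df.to_csv(buf, index=False, lineterminator="\n")
    text = buf.getvalue()
    if path is not None:
        path = Path(path)
        path.write_text(text)
        truth_path = path.with_suffix(".truth.csv")
        tbuf = io.StringIO()
        cohort.truth.round(6).to_csv(tbuf, lineterminator="\n")
        truth_path.write_text(tbuf.getvalue())
    return text
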