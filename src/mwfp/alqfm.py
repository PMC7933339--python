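"""Averagely linear quantified fingerprint method (ALQFM).

Each sample's peak-area vector ``x`` is scored against a reference
fingerprint ``y`` over the shared (co-possessing) peaks.  With ratios
``r_i = x_i / y_i`` and ``n`` peaks:

* ``Sm`` — average linear qualitative similarity, the mean of the cosine
  similarity between ``x`` and ``y`` and the overlap of their
  area-fraction profiles: ``Sm = (S_cos + S_prof) / 2`` with
  ``S_cos = x.y / (|x||y|)`` and ``S_prof = sum_i min(p_i, q_i)``,
  ``p = x / sum(x)``, ``q = y / sum(y)``.  Scale-free: it measures
  whether the samples agree in the distribution of their constituents.
* ``Pm`` — average linear quantitative similarity in percent,
  ``Pm = 100 * mean(r)``: a linear measure of overall content relative
  to the reference.
* ``alpha`` — fingerprint variation coefficient, the coefficient of
  variation of the ratios, ``sd(r, ddof=1) / mean(r)``: the relative
  dispersion of the per-peak content ratios.

The three parameters combine into an eight-level similarity grade via a
nested threshold table; the returned grade is the worst of the three
component ratings (band boundaries inclusive).  Grade <= 5 is
conventionally read as "similar to the reference".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MWFPError, StudyError
from .peaks import FingerprintMatrix

_EPS = 1e-12


@dataclass(frozen=True)
class GradeCriteria:
    """Threshold table of the eight similarity grades.

    For grades 1..7: minimal ``Sm``, inclusive ``Pm`` band in percent,
    and maximal ``alpha``; grade 8 is "otherwise".  The defaults are the
    conventional ALQFM criteria.  (The published table's grade-8 alpha
    cell reads 0.05, an evident slip for 0.50 — with it, grades 2-7
    would be unreachable for alpha in (0.05, 0.50].)
    """

    sm_min: tuple = (0.95, 0.90, 0.85, 0.80, 0.70, 0.60, 0.50)
    pm_low: tuple = (95.0, 90.0, 80.0, 75.0, 70.0, 60.0, 50.0)
    pm_high: tuple = (105.0, 110.0, 120.0, 125.0, 130.0, 140.0, 150.0)
    alpha_max: tuple = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50)

    def __post_init__(self) -> None:
        for name in ("sm_min", "pm_low", "pm_high", "alpha_max"):
            if len(getattr(self, name)) != 7:
                raise MWFPError(f"{name} must list 7 thresholds (grades 1-7)")
        if np.any(np.diff(self.sm_min) >= 0):
            raise MWFPError("sm_min must be strictly decreasing")
        if np.any(np.diff(self.alpha_max) <= 0):
            raise MWFPError("alpha_max must be strictly increasing")
        if np.any(np.diff(self.pm_low) > 0) or np.any(np.diff(self.pm_high) < 0):
            raise MWFPError("Pm bands must be nested")


DEFAULT_CRITERIA = GradeCriteria()


@dataclass(frozen=True)
class ReferenceFingerprint:
    """The peak-area vector samples are scored against."""

    peak_rts: np.ndarray
    areas: np.ndarray
    provenance: str = "mean"

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_rts", np.asarray(self.peak_rts, float))
        object.__setattr__(self, "areas", np.asarray(self.areas, float))
        if self.areas.shape != self.peak_rts.shape:
            raise MWFPError("reference areas and peak_rts differ in length")
        if np.any(self.areas <= 0):
            raise MWFPError("reference fingerprint areas must all be positive")


@dataclass(frozen=True)
class ALQFMResult:
    sample_id: str
    channel: str
    sm: float
    pm: float
    alpha: float
    grade: int


def reference_fingerprint(
    matrix: FingerprintMatrix, mode: str = "mean"
) -> ReferenceFingerprint:
    """Build the reference fingerprint of a study.

    ``mode="mean"`` (default) takes arithmetic column means over all
    samples; ``mode="sample:<id>"`` designates one sample's row as the
    reference (e.g. a benchmark batch).
    """
    if matrix.n_samples == 0 or matrix.n_peaks == 0:
        raise MWFPError("cannot build a reference from an empty matrix")
    if mode == "mean":
        areas = matrix.areas.mean(axis=0)
    elif mode.startswith("sample:"):
        areas = matrix.row(mode.split(":", 1)[1])
    else:
        raise MWFPError(f"unknown reference mode {mode!r}")
    return ReferenceFingerprint(matrix.peak_rts, areas, provenance=mode)


def similarity_parameters(x, y) -> tuple:
    """Compute (Sm, Pm, alpha) of a sample vector against a reference.

    ``x`` must be element-wise non-negative with a positive sum; ``y``
    (a :class:`ReferenceFingerprint` or positive vector) strictly
    positive; both of equal length >= 2.  ``Sm`` and ``alpha`` are
    invariant to rescaling ``x``; ``Pm`` scales linearly.
    """
    if isinstance(y, ReferenceFingerprint):
        y = y.areas
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MWFPError(f"shape mismatch: x has {x.shape}, y has {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise MWFPError("similarity needs vectors of length >= 2")
    if np.any(y <= 0):
        raise MWFPError("reference vector must be strictly positive")
    if np.any(x < 0) or x.sum() <= 0:
        raise MWFPError("sample vector must be non-negative with positive sum")
    s_cos = float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    s_prof = float(np.minimum(x / x.sum(), y / y.sum()).sum())
    sm = (s_cos + s_prof) / 2.0
    r = x / y
    pm = 100.0 * float(r.mean())
    alpha = float(r.std(ddof=1) / r.mean())
    return sm, pm, alpha


def _component_grades(
    sm: float, pm: float, alpha: float, criteria: GradeCriteria
) -> tuple:
    g_s = next(
        (g + 1 for g in range(7) if sm >= criteria.sm_min[g] - _EPS), 8
    )
    g_p = next(
        (
            g + 1
            for g in range(7)
            if criteria.pm_low[g] - _EPS <= pm <= criteria.pm_high[g] + _EPS
        ),
        8,
    )
    g_a = next(
        (g + 1 for g in range(7) if alpha <= criteria.alpha_max[g] + _EPS), 8
    )
    return g_s, g_p, g_a


def assign_grade(
    sm: float, pm: float, alpha: float, criteria: GradeCriteria = DEFAULT_CRITERIA
) -> int:
    """Worst-of-three similarity grade (1 best ... 8 worst).

    Each parameter is rated by the smallest grade whose threshold it
    meets (band boundaries inclusive); the returned grade is the maximum
    of the three component ratings.
    """
    if pm < 0 or alpha < 0 or sm < 0:
        raise MWFPError("Sm, Pm and alpha must be non-negative")
    if sm > 1 + 1e-9:
        raise MWFPError(f"Sm must not exceed 1, got {sm}")
    return max(_component_grades(sm, pm, alpha, criteria))


def evaluate_sample(
    sample_id: str,
    x,
    reference: ReferenceFingerprint,
    channel: str = "unknown",
    criteria: GradeCriteria = DEFAULT_CRITERIA,
) -> ALQFMResult:
    sm, pm, alpha = similarity_parameters(x, reference)
    return ALQFMResult(
        sample_id, channel, sm, pm, alpha, assign_grade(sm, pm, alpha, criteria)
    )


def evaluate_study(
    matrices: dict,
    criteria: GradeCriteria = DEFAULT_CRITERIA,
    reference_mode: str = "mean",
) -> pd.DataFrame:
    """Score every sample of every channel against that channel's reference.

    Returns a long-format table with one row per (sample, channel):
    columns ``sample_id, channel, sm, pm, alpha, grade``.  The reference
    is rebuilt per channel with the requested mode (default: column
    mean).
    """
    orders = {tuple(m.sample_ids) for m in matrices.values()}
    if len(orders) != 1:
        raise MWFPError("all channel matrices must share the sample ordering")
    rows = []
    for ch, matrix in matrices.items():
        ref = reference_fingerprint(matrix, mode=reference_mode)
        for i, sid in enumerate(matrix.sample_ids):
            rows.append(
                evaluate_sample(sid, matrix.areas[i], ref, channel=ch, criteria=criteria)
            )
    return pd.DataFrame([vars(r) for r in rows])


def results_report(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format results to one row per sample (report layout)."""
    wide = results.pivot(index="sample_id", columns="channel")
    wide = wide.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
    wide.columns = [f"{p}_{ch}" for ch, p in wide.columns]
    return wide.loc[results["sample_id"].unique()]


@dataclass(frozen=True)
class DiscriminationCounts:
    """Confusion counts of grade-based origin discrimination."""

    similar_group: str
    other_group: str
    cutoff: int
    n_similar_correct: int  # similar-group samples with grade <= cutoff
    n_similar_total: int
    n_other_correct: int  # other-group samples with grade > cutoff
    n_other_total: int

    @property
    def errors(self) -> int:
        return (self.n_similar_total - self.n_similar_correct) + (
            self.n_other_total - self.n_other_correct
        )


def grade_discrimination(
    grades,
    labels,
    cutoff: int = 4,
    similar_group: str | None = None,
) -> DiscriminationCounts:
    """Count origin-discrimination errors of the similarity grades.

    ``grades`` maps sample_id -> grade (Series or dict) for one channel;
    ``labels`` maps sample_id -> origin, which must take exactly two
    values.  Samples of the ``similar_group`` are expected at grade
    <= ``cutoff`` and the other group above it; if ``similar_group`` is
    not given, the group with the lower mean grade is used.
    """
    grades = pd.Series(dict(grades) if not isinstance(grades, pd.Series) else grades)
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    labels = labels.loc[grades.index]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise StudyError(f"need exactly two origin groups, got {groups}")
    if similar_group is None:
        means = grades.groupby(labels).mean()
        similar_group = means.idxmin()
    if similar_group not in groups:
        raise StudyError(f"{similar_group!r} is not one of the groups {groups}")
    other_group = next(g for g in groups if g != similar_group)
    sim = grades[labels == similar_group]
    oth = grades[labels == other_group]
    return DiscriminationCounts(
        similar_group=similar_group,
        other_group=other_group,
        cutoff=cutoff,
        n_similar_correct=int((sim <= cutoff).sum()),
        n_similar_total=int(sim.size),
        n_other_correct=int((oth > cutoff).sum()),
        n_other_total=int(oth.size),
    )
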