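"""Intraclass correlation coefficients for measurement reliability.

The reliability design mirrors a typical radiographic study: three raters
each measure every shoulder twice, about a month apart.  Intrarater
reliability uses the one-way random-effects single-measure coefficient
ICC(1,1) on each rater's subjects × sessions table; interrater reliability
uses the two-way random-effects absolute-agreement single-measure
coefficient ICC(2,1) on the subjects × raters table.

Both estimates come from the classical ANOVA mean squares.  With n subjects
and k columns (sessions or raters):

    ICC(1,1) = (BMS − WMS) / (BMS + (k−1)·WMS)
    ICC(2,1) = (BMS − EMS) / (BMS + (k−1)·EMS + k·(JMS − EMS)/n)

where BMS is the between-subject mean square, WMS the within-subject mean
square, JMS the between-column (rater) mean square and EMS the residual mean
square of the two-way decomposition.  95% confidence intervals follow the
F-distribution-based formulation of Shrout & Fleiss (exact for ICC(1,1),
Satterthwaite-approximate degrees of freedom for ICC(2,1)).

Negative estimates are mathematically possible and are reported as computed,
with a warning, rather than truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedReliabilityError

__all__ = [
    "RatingMatrix",
    "ICCResult",
    "ReliabilityReport",
    "icc_1_1",
    "icc_2_1",
    "reliability_report",
]

_VAR_TOL = 1e-12


@dataclass(eq=False)
class RatingMatrix:
    """Complete (subject × rater × session) array of angle measurements.

    ``values`` has shape (n_subjects, n_raters, n_sessions) with no missing
    cells; degrees throughout.
    """

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError(
                f"rating matrix must be 3-dimensional (subjects × raters × "
                f"sessions), got shape {self.values.shape}"
            )
        n, r, s = self.values.shape
        if n < 2:
            raise InputError(f"need at least 2 subjects, got {n}")
        if r < 1 or s < 1:
            raise InputError(f"need at least 1 rater and 1 session, got {r} × {s}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("rating matrix contains missing or non-finite cells")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:04d}" for i in range(n)]
        if not self.rater_ids:
            self.rater_ids = [f"rater{j + 1}" for j in range(r)]
        if len(self.subject_ids) != n or len(self.rater_ids) != r:
            raise InputError("subject_ids / rater_ids lengths do not match values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class ICCResult:
    """A single intraclass correlation estimate with its 95% CI."""

    model: str  # "one_way_1_1" or "two_way_2_1"
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise InputError(
                f"inconsistent ICC interval: {self.ci_low} ≤ {self.estimate} "
                f"≤ {self.ci_high} violated"
            )
        if self.estimate > 1.0:
            raise InputError(f"ICC estimate cannot exceed 1, got {self.estimate}")

    def __str__(self) -> str:
        tag = f" [{self.label}]" if self.label else ""
        return (
            f"ICC({'1,1' if self.model == 'one_way_1_1' else '2,1'}){tag} = "
            f"{self.estimate:.3f} (95% CI, {self.ci_low:.3f}-{self.ci_high:.3f})"
        )


def _check_table(ratings, min_cols: int) -> np.ndarray:
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise InputError(f"ratings must be a 2D table, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InputError("ratings table has missing or non-finite cells (complete design required)")
    n, k = x.shape
    if n < 2:
        raise InputError(f"need at least 2 subjects, got {n}")
    if k < min_cols:
        raise InputError(f"need at least {min_cols} columns, got {k}")
    if float(np.var(x)) < _VAR_TOL:
        raise UndefinedReliabilityError(
            "all ratings are (numerically) identical; reliability is undefined"
        )
    return x


def _warn_if_negative(est: float) -> None:
    if est < 0:
        warnings.warn(
            f"negative ICC estimate ({est:.3f}); reported as computed, not truncated",
            stacklevel=3,
        )


def icc_1_1(ratings, alpha: float = 0.05, label: str = "") -> ICCResult:
    """One-way random-effects, single-measure ICC(1,1).

    ``ratings`` is a complete (subjects × repeated measurements) table; used
    here for intrarater reliability (one rater's two sessions).
    """
    x = _check_table(ratings, min_cols=2)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    bms = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    wss = float(((x - row_means[:, None]) ** 2).sum())
    wms = wss / (n * (k - 1))

    if wms < _VAR_TOL:
        # perfect repeatability: subjects differ, repeats identical
        return ICCResult("one_way_1_1", 1.0, 1.0, 1.0, n, k, label)

    est = (bms - wms) / (bms + (k - 1) * wms)
    fobs = bms / wms
    fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    _warn_if_negative(est)
    return ICCResult("one_way_1_1", est, lo, hi, n, k, label)


def icc_2_1(ratings, alpha: float = 0.05, label: str = "") -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC(2,1).

    ``ratings`` is a complete (subjects × raters) table.  Absolute agreement
    means a constant bias in one rater lowers the coefficient (unlike the
    consistency-type ICC(3,1)).
    """
    x = _check_table(ratings, min_cols=2)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    bms = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    jms = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ems = float((resid**2).sum()) / ((n - 1) * (k - 1))

    if ems < _VAR_TOL and jms < _VAR_TOL:
        return ICCResult("two_way_2_1", 1.0, 1.0, 1.0, n, k, label)

    denom = bms + (k - 1) * ems + k * (jms - ems) / n
    est = (bms - ems) / denom

    # Shrout–Fleiss CI with Satterthwaite degrees of freedom.
    a = k * est / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
    num = (a * jms + b * ems) ** 2
    den = (a * jms) ** 2 / (k - 1) + (b * ems) ** 2 / ((n - 1) * (k - 1))
    v = num / den
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (bms - f1 * ems) / (f1 * (k * jms + (k * n - k - n) * ems) + n * bms)
    hi = n * (f2 * bms - ems) / (k * jms + (k * n - k - n) * ems + n * f2 * bms)
    lo = min(lo, est)
    hi = max(hi, est)
    _warn_if_negative(est)
    return ICCResult("two_way_2_1", est, lo, hi, n, k, label)


@dataclass
class ReliabilityReport:
    """Per-rater intrarater ICC(1,1) plus pooled interrater ICC(2,1)."""

    intrarater: list[ICCResult]
    interrater: ICCResult

    def all_estimates(self) -> list[float]:
        return [r.estimate for r in self.intrarater] + [self.interrater.estimate]

    def to_text(self) -> str:
        lines = ["Reliability report", "------------------"]
        lines += [str(r) for r in self.intrarater]
        lines.append(str(self.interrater))
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "analysis": "intrarater",
                "label": r.label,
                "model": r.model,
                "icc": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_subjects": r.n_subjects,
                "k": r.n_raters,
            }
            for r in self.intrarater
        ]
        r = self.interrater
        rows.append(
            {
                "analysis": "interrater",
                "label": r.label,
                "model": r.model,
                "icc": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_subjects": r.n_subjects,
                "k": r.n_raters,
            }
        )
        return pd.DataFrame(rows)


def reliability_report(
    matrix: RatingMatrix, first_session_only: bool = False
) -> ReliabilityReport:
    """Full reliability analysis of a (subjects × raters × sessions) design.

    Intrarater: one ICC(1,1) per rater across that rater's sessions.
    Interrater: ICC(2,1) across raters, computed on each rater's session
    means (default, uses all data symmetrically) or on the first session only
    (``first_session_only=True``).
    """
    if matrix.n_sessions < 2 and not first_session_only:
        raise InputError(
            "intrarater ICC(1,1) needs at least 2 sessions; "
            f"got {matrix.n_sessions}"
        )
    intrarater = [
        icc_1_1(matrix.values[:, j, :], label=matrix.rater_ids[j])
        for j in range(matrix.n_raters)
    ]
    if matrix.n_raters < 2:
        raise InputError("interrater ICC(2,1) needs at least 2 raters")
    inter_table = (
        matrix.values[:, :, 0] if first_session_only else matrix.values.mean(axis=2)
    )
    label = "first session" if first_session_only else "session means"
    interrater = icc_2_1(inter_table, label=label)
    return ReliabilityReport(intrarater=intrarater, interrater=interrater)
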