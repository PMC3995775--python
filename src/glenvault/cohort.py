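"""Cohort-level comparisons of glenoid version values.

Implements the study-level statistics: per-group summaries (mean ± SD,
range), paired Wilcoxon signed-rank tests (vault vs conventional method, and
dominant vs nondominant side), and a two-sided variance-ratio F-test
comparing the spread of the two methods' distributions.

Before any comparison, per-shoulder values are averaged across raters and
sessions (:func:`average_measurements`), reflecting how multi-observer
measurement studies collapse their rating design to one value per shoulder.

Zeros in the Wilcoxon test (exactly tied pairs) are dropped before ranking
(Wilcoxon's original treatment, not Pratt's); the exact null distribution is
enumerated for ≤25 informative pairs, otherwise the normal approximation
with tie correction is used.  Significance level conventions: α = 0.05,
p-values printed to three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, InputError

__all__ = [
    "CohortSummary",
    "MethodComparison",
    "SideComparison",
    "summarize",
    "average_measurements",
    "paired_wilcoxon",
    "variance_f_test",
    "compare_methods",
    "compare_sides",
]

ALPHA = 0.05
_EXACT_MAX_N = 25


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of one stratum of version values (degrees)."""

    label: str
    n: int
    mean_deg: float
    sd_deg: float
    min_deg: float
    max_deg: float

    def __str__(self) -> str:
        return (
            f"{self.label}: n={self.n}, {self.mean_deg:.1f}° ± {self.sd_deg:.1f}° "
            f"(range, {self.min_deg:.1f}° to {self.max_deg:.1f}°)"
        )


def summarize(values: Sequence[float], label: str) -> CohortSummary:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError(f"cannot summarize empty group {label!r}")
    if not np.all(np.isfinite(x)):
        raise InputError(f"group {label!r} contains non-finite values")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return CohortSummary(
        label=label,
        n=int(x.size),
        mean_deg=float(x.mean()),
        sd_deg=sd,
        min_deg=float(x.min()),
        max_deg=float(x.max()),
    )


def average_measurements(results: pd.DataFrame) -> pd.DataFrame:
    """Average repeated measurements to one value per shoulder and method.

    Accepts a long results table with at least shoulder_id, method and
    version_deg (extra columns such as rater/session are averaged over;
    side/dominance/variant, if present, are carried through unchanged).
    """
    _require_columns(results, ("shoulder_id", "method", "version_deg"))
    keys = ["shoulder_id", "method"]
    carried = [c for c in ("side", "dominance", "variant") if c in results.columns]
    agg = {c: "first" for c in carried}
    agg["version_deg"] = "mean"
    return results.groupby(keys, as_index=False, sort=False).agg(agg)


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"results table is missing column(s) {missing}")


def paired_wilcoxon(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Pairs must be aligned by shoulder.  Zero differences are dropped; with
    ≤25 informative pairs (and untied magnitudes) the exact two-sided
    p-value is used, otherwise the tie-corrected normal approximation.
    Returns ``(W, p)`` where W is the smaller of the two signed-rank sums.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError(f"paired samples must be equal-length 1D, got {a.shape}, {b.shape}")
    if a.size < 5:
        raise InputError(f"need at least 5 pairs, got {a.size}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateTestError(
            "all paired differences are zero; the signed-rank test is degenerate"
        )
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= _EXACT_MAX_N and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def variance_f_test(a, b) -> tuple[float, float]:
    """Two-sided variance-ratio F-test comparing the spread of two groups.

    F is the larger sample variance over the smaller, with matching degrees
    of freedom; the two-sided p doubles the upper tail (capped at 1).  The
    test is symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    if va <= 0.0 or vb <= 0.0:
        raise DegenerateTestError("zero variance in one of the groups; F-test undefined")
    if va >= vb:
        F, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    p = min(1.0, 2.0 * float(stats.f.sf(F, dfn, dfd)))
    return F, p


@dataclass
class MethodComparison:
    """Vault-versus-conventional comparison on one cohort."""

    summary_conventional: CohortSummary
    summary_vault: CohortSummary
    mean_difference_deg: float  # vault − conventional
    wilcoxon_statistic: float
    wilcoxon_p: float
    f_statistic: float
    f_p: float
    n_pairs: int

    def to_text(self) -> str:
        w = (
            "degenerate (all paired differences zero)"
            if np.isnan(self.wilcoxon_p)
            else f"W={self.wilcoxon_statistic:.1f}, p={self.wilcoxon_p:.3f}"
        )
        return "\n".join(
            [
                "Method comparison (vault vs conventional)",
                "-----------------------------------------",
                str(self.summary_conventional),
                str(self.summary_vault),
                f"mean difference (vault − conventional): {self.mean_difference_deg:.1f}°",
                f"paired Wilcoxon signed-rank: {w}",
                f"variance-ratio F-test: F={self.f_statistic:.3f}, p={self.f_p:.3f}",
                "(zeros dropped in Wilcoxon; two-sided tests, α = 0.05)",
            ]
        )


def compare_methods(results: pd.DataFrame, label: str = "cohort") -> MethodComparison:
    """Compare vault and conventional version on a paired results table.

    ``results`` must contain one row per shoulder per method (average
    repeated measurements first with :func:`average_measurements`).  Every
    shoulder needs both methods; unpaired shoulders are reported by id.
    """
    _require_columns(results, ("shoulder_id", "method", "version_deg"))
    wide = results.pivot_table(
        index="shoulder_id", columns="method", values="version_deg", aggfunc="mean"
    )
    for m in ("conventional", "vault"):
        if m not in wide.columns:
            raise InputError(f"results table has no {m!r} rows")
    unpaired = sorted(wide.index[wide.isna().any(axis=1)])
    if unpaired:
        raise InputError(
            f"shoulders missing one method (unpaired): {unpaired}"
        )
    conv = wide["conventional"].to_numpy()
    vault = wide["vault"].to_numpy()
    stat, p = paired_wilcoxon(vault, conv)
    F, fp = variance_f_test(conv, vault)
    return MethodComparison(
        summary_conventional=summarize(conv, f"{label} conventional"),
        summary_vault=summarize(vault, f"{label} vault"),
        mean_difference_deg=float(np.mean(vault - conv)),
        wilcoxon_statistic=stat,
        wilcoxon_p=p,
        f_statistic=F,
        f_p=fp,
        n_pairs=int(wide.shape[0]),
    )


@dataclass
class SideComparison:
    """Dominant-versus-nondominant comparison, per method."""

    method: str
    summary_dominant: CohortSummary
    summary_nondominant: CohortSummary
    mean_difference_deg: float  # dominant − nondominant
    wilcoxon_statistic: float
    wilcoxon_p: float
    n_pairs: int

    def to_text(self) -> str:
        return "\n".join(
            [
                f"Side comparison ({self.method} method, dominant vs nondominant)",
                str(self.summary_dominant),
                str(self.summary_nondominant),
                f"mean side-to-side difference: {self.mean_difference_deg:.1f}°",
                f"paired Wilcoxon signed-rank: W={self.wilcoxon_statistic:.1f}, "
                f"p={self.wilcoxon_p:.3f}",
            ]
        )


def _default_subject_id(shoulder_id: str) -> str:
    if "-" not in shoulder_id:
        raise InputError(
            f"cannot derive a subject id from shoulder_id {shoulder_id!r}; "
            "pass subject_of= to compare_sides (expected '<subject>-<suffix>')"
        )
    return shoulder_id.rsplit("-", 1)[0]


def compare_sides(
    results: pd.DataFrame,
    subject_of: Callable[[str], str] | None = None,
) -> list[SideComparison]:
    """Paired dominant-versus-nondominant comparison, one per method.

    Shoulders are paired within subject; by default the subject id is the
    shoulder_id with its trailing ``-<suffix>`` removed (the simulator's
    convention, e.g. ``P0012-R`` / ``P0012-L``), or supply ``subject_of``.
    Every subject must contribute exactly one dominant and one nondominant
    shoulder per method.
    """
    _require_columns(results, ("shoulder_id", "dominance", "method", "version_deg"))
    df = results.copy()
    bad = sorted(set(df["dominance"]) - {"dominant", "nondominant"})
    if bad:
        raise InputError(
            f"side comparison needs dominance labels dominant/nondominant; found {bad}"
        )
    subject_of = subject_of or _default_subject_id
    df["subject_id"] = [subject_of(s) for s in df["shoulder_id"]]
    out: list[SideComparison] = []
    for method, sub in df.groupby("method", sort=True):
        wide = sub.pivot_table(
            index="subject_id", columns="dominance", values="version_deg", aggfunc="mean"
        )
        for col in ("dominant", "nondominant"):
            if col not in wide.columns:
                raise InputError(f"no {col} shoulders for method {method!r}")
        incomplete = sorted(wide.index[wide.isna().any(axis=1)])
        if incomplete:
            raise InputError(
                f"subjects lacking a side for method {method!r}: {incomplete}"
            )
        dom = wide["dominant"].to_numpy()
        nond = wide["nondominant"].to_numpy()
        stat, p = paired_wilcoxon(dom, nond)
        out.append(
            SideComparison(
                method=str(method),
                summary_dominant=summarize(dom, f"{method} dominant"),
                summary_nondominant=summarize(nond, f"{method} nondominant"),
                mean_difference_deg=float(np.mean(dom - nond)),
                wilcoxon_statistic=stat,
                wilcoxon_p=p,
                n_pairs=int(wide.shape[0]),
            )
        )
    return out
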