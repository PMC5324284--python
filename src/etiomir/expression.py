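"""miRNA quantification and de-etiolation expression dynamics.

Counts are normalized to TPQ (transcripts per quarter million): each tag's
count divided by the sample's total of clean genome-mapped reads, times
250,000 — so every per-tag TPQ column sums to exactly 250,000.  Family
expression is the sum of member TPQ vectors.  Fold-changes versus the control
sample are natural logarithms, substituting 0.001 for a TPQ that equals zero.
Time-course shapes are summarized by ordinary-least-squares cubic fits on raw
hours, and miRNA-target co-expression by Pearson correlation over the seven
de-etiolation time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import SAMPLES, TIME_POINTS_H

QUARTER_MILLION = 250_000.0
ZERO_SUBSTITUTE = 0.001


def compute_tpq(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Normalize a per-tag (or per-miRNA) count table to TPQ.

    `totals` defaults to the column sums of `counts`, i.e. the table is taken
    to already contain exactly the clean genome-mapped reads; pass explicit
    per-sample totals to normalize a subset of rows against the full library.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    for sample in counts.columns:
        if float(totals[sample]) <= 0:
            raise ValueError(f"sample {sample!r} has zero clean mapped reads")
    return counts.div(totals, axis=1) * QUARTER_MILLION


def fold_change(tpq_t, tpq_control):
    """ln fold-change of a time point versus control.

    A value of exactly 0 is replaced by 0.001 before taking the ratio (only
    then; nothing is added to nonzero values).  Accepts scalars or arrays.
    """
    t = np.asarray(tpq_t, dtype=float)
    c = np.asarray(tpq_control, dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValueError("TPQ values must be non-negative")
    t = np.where(t == 0, ZERO_SUBSTITUTE, t)
    c = np.where(c == 0, ZERO_SUBSTITUTE, c)
    out = np.log(t / c)
    return float(out) if out.ndim == 0 else out


@dataclass
class FamilyProfile:
    family_id: str
    members: list[str]
    tpq: np.ndarray  # length 8, SAMPLES order
    lnfc: np.ndarray  # length 7, vs control


def aggregate_family(
    matrix: pd.DataFrame, membership: dict[str, list[str]]
) -> dict[str, FamilyProfile]:
    """Family profiles as member-wise TPQ sums plus ln fold-changes."""
    profiles = {}
    for family_id in sorted(membership):
        members = membership[family_id]
        missing = [m for m in members if m not in matrix.index]
        if missing:
            raise KeyError(f"family {family_id!r}: members not in matrix: {missing}")
        tpq = matrix.loc[members].sum(axis=0).to_numpy(dtype=float)
        control = tpq[SAMPLES.index("control")]
        lnfc = fold_change(tpq[:7], control)
        profiles[family_id] = FamilyProfile(family_id, list(members), tpq, np.atleast_1d(lnfc))
    return profiles


def family_lnfc_table(profiles: dict[str, FamilyProfile]) -> pd.DataFrame:
    """Heatmap-ready long-format ln fold-change table (family, sample, lnfc)."""
    rows = []
    for fam, prof in profiles.items():
        for sample, value in zip(SAMPLES[:7], prof.lnfc):
            rows.append({"family": fam, "sample": sample, "lnfc": float(value)})
    return pd.DataFrame(rows)


@dataclass
class PolyFit:
    coefficients: np.ndarray  # ascending powers, length degree+1
    fitted: np.ndarray
    rss: float

    def predict(self, t) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), self.coefficients)


def fit_polynomial(times, values, degree: int = 3) -> PolyFit:
    """OLS polynomial fit of an expression series on raw hours."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(np.unique(t)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct time points for a degree-{degree} fit"
        )
    X = np.vander(t, degree + 1, increasing=True)
    coef, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    return PolyFit(coef, fitted, rss)


def fit_time_course(tpq_8vector, degree: int = 3) -> PolyFit:
    """Cubic fit over the 7 de-etiolation time points (control excluded)."""
    return fit_polynomial(TIME_POINTS_H, np.asarray(tpq_8vector, dtype=float)[:7], degree)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    defined: bool  # False when an input vector is constant


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p-value; constant input is flagged NA."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), defined=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), defined=True)
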