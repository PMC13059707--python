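"""Repeated-measures correlation (Bland-Altman) between feature pairs.

When every donor contributes many samples, a plain Pearson correlation
between two features conflates within-donor covariation with between-donor
composition differences.  The repeated-measures correlation removes the
latter by centering each variable within subject (donor) and correlating
the residuals; its error degrees of freedom are ``N - k - 1`` for ``N``
observations and ``k`` subjects, and significance comes from the usual
t transform ``t = r * sqrt(df / (1 - r^2))``.

A pair is *degenerate* when either variable has zero within-subject
variance: r is then undefined and reported as 0 with p = 1 and a flag, so
degenerate pairs never seed a network edge and sit at distance 1 in
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RmCorrResult", "RmCorrMatrix", "rmcorr_pair", "rmcorr_matrix"]

_EPS = 1e-12


@dataclass(frozen=True)
class RmCorrResult:
    r: float
    p: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class RmCorrMatrix:
    """All-pairs repeated-measures correlations over a feature table."""

    feature_ids: list[str]
    r: np.ndarray  # symmetric, unit diagonal
    p: np.ndarray  # symmetric, zero diagonal
    df: int
    degenerate: np.ndarray  # boolean, True where either feature lacks within-subject variance

    def to_long(self) -> pd.DataFrame:
        """Long-format table (feature_a, feature_b, r, p, degenerate), i < j pairs."""
        ids = self.feature_ids
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    (ids[i], ids[j], self.r[i, j], self.p[i, j], bool(self.degenerate[i, j]))
                )
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "degenerate"])


def _center_within(values: np.ndarray, subject: np.ndarray) -> np.ndarray:
    """Subtract each subject's mean from its observations (column-wise)."""
    centered = np.array(values, dtype=float)
    for s in np.unique(subject):
        mask = subject == s
        centered[mask] -= centered[mask].mean(axis=0)
    return centered


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - r**2, _EPS)
    t = r * np.sqrt(df / denom)
    return 2.0 * stats.t.sf(np.abs(t), df)


def rmcorr_pair(x, y, subject) -> RmCorrResult:
    """Repeated-measures correlation of two variables blocked by subject.

    Equivalent to the signed square root of the covariate partial eta
    squared from an ANCOVA of ``y`` on ``subject + x`` (a property the test
    suite verifies against an independent ANCOVA fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if not (len(x) == len(y) == len(subject)):
        raise ValueError("x, y and subject must have equal lengths")
    k = len(np.unique(subject))
    n = len(x)
    if k < 2:
        raise ValueError("at least 2 subjects are required")
    df = n - k - 1
    if df < 1:
        raise ValueError(f"not enough observations: df = N - k - 1 = {df} < 1")
    cx = _center_within(x[:, None], subject)[:, 0]
    cy = _center_within(y[:, None], subject)[:, 0]
    sx = np.sqrt(np.sum(cx**2))
    sy = np.sqrt(np.sum(cy**2))
    if sx < _EPS or sy < _EPS:
        return RmCorrResult(r=0.0, p=1.0, df=df, degenerate=True)
    r = float(np.dot(cx, cy) / (sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    p = float(_p_from_r(np.array(r), df))
    return RmCorrResult(r=r, p=p, df=df)


def rmcorr_matrix(table: pd.DataFrame, subjects) -> RmCorrMatrix:
    """All-pairs repeated-measures correlation over a samples x features table.

    ``subjects`` aligns with the table's rows (or is a mapping/Series over
    its index).  Implemented as one within-subject centering pass followed
    by a normalised cross-product, which is algebraically identical to
    calling :func:`rmcorr_pair` on every pair.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if isinstance(subjects, (pd.Series, dict)):
        subjects = pd.Series(subjects).loc[table.index].to_numpy()
    else:
        subjects = np.asarray(subjects)
        if len(subjects) != len(table):
            raise ValueError("subjects must align with table rows")
    n, m = table.shape
    k = len(np.unique(subjects))
    df = n - k - 1
    if df < 1:
        raise ValueError(f"not enough observations: df = N - k - 1 = {df} < 1")

    centered = _center_within(table.to_numpy(dtype=float), subjects)
    norms = np.sqrt(np.sum(centered**2, axis=0))
    zero_var = norms < _EPS
    safe = np.where(zero_var, 1.0, norms)
    unit = centered / safe
    r = unit.T @ unit
    np.clip(r, -1.0, 1.0, out=r)

    degenerate = zero_var[:, None] | zero_var[None, :]
    r[degenerate] = 0.0
    p = _p_from_r(r, df)
    p[degenerate] = 1.0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(degenerate, False)
    # exact symmetry despite float noise
    r = (r + r.T) / 2.0
    p = (p + p.T) / 2.0
    return RmCorrMatrix(
        feature_ids=[str(c) for c in table.columns], r=r, p=p, df=df, degenerate=degenerate
    )
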