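"""Regressor-quality check: ROI-level omnibus F over the boxcar bank.

For each region the BOLD trace is regressed on an intercept plus the eight
oscillatory boxcars (down-sampled to scan resolution, unconvolved by
default so that the GLM design equals the DCM drive).  The omnibus F tests
the joint null of all boxcar coefficients; its log is a variance-explained
measure whose group-level one-sample t-test (against the analytic null
mean of log F, not zero) checks that the drivers capture real variance
across subjects.

Null reference: under the null, F ~ F(df1, df2), and
E[log F] = ψ(df1/2) − log(df1/2) − ψ(df2/2) + log(df2/2) with ψ the
digamma function; the group t is centered on this value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special

from .generative import SubjectRecording

__all__ = [
    "RegressorFitResult",
    "omnibus_f",
    "group_log_f_test",
    "null_log_f_mean",
    "GroupLogFTest",
]


@dataclass(frozen=True)
class RegressorFitResult:
    """Per-region omnibus F over the oscillatory regressors."""

    region_labels: tuple[str, ...]
    f: np.ndarray
    log_f: np.ndarray
    df1: int
    df2: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"F": self.f, "log_F": self.log_f, "df1": self.df1, "df2": self.df2},
            index=list(self.region_labels),
        )


def omnibus_f(recording: SubjectRecording, regressors_at_scans: np.ndarray) -> RegressorFitResult:
    """Joint F-test of all oscillatory regressors, per region.

    ``regressors_at_scans`` is the scans × K boxcar matrix at scan
    resolution (see :meth:`RegressorSet.at_scans`).  The design is an
    intercept plus the K regressors and must be full rank — an all-zero or
    collinear column is rejected, never silently dropped.
    """
    y = np.asarray(recording.values, dtype=float)
    x = np.asarray(regressors_at_scans, dtype=float)
    n, k = x.shape
    if y.shape[0] != n:
        raise ValueError(f"recording has {y.shape[0]} scans but regressors have {n} rows")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (zero or collinear regressor column)")
    df1 = k
    df2 = n - k - 1
    if df2 <= 0:
        raise ValueError("not enough scans for the requested design")
    # full model residuals via least squares; reduced model = intercept only
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss1 = np.sum(resid ** 2, axis=0)
    rss0 = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
        f = np.where(rss1 <= 0, np.inf, f)
        log_f = np.log(f)
    return RegressorFitResult(
        region_labels=tuple(recording.region_labels),
        f=np.maximum(f, 0.0),
        log_f=log_f,
        df1=df1,
        df2=df2,
    )


def null_log_f_mean(df1: int, df2: int) -> float:
    """E[log F] under the null for an F(df1, df2) variate."""
    return float(
        special.digamma(df1 / 2.0) - np.log(df1 / 2.0)
        - special.digamma(df2 / 2.0) + np.log(df2 / 2.0)
    )


@dataclass(frozen=True)
class GroupLogFTest:
    region_labels: tuple[str, ...]
    t: np.ndarray
    df: int
    reference: float
    degenerate: np.ndarray  # True where the across-subject variance vanished

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "df": self.df, "reference": self.reference,
             "degenerate": self.degenerate},
            index=list(self.region_labels),
        )


def group_log_f_test(
    log_f: np.ndarray,
    df1: int,
    df2: int,
    region_labels: tuple[str, ...] | None = None,
) -> GroupLogFTest:
    """One-sample t of per-subject log F against the analytic null mean.

    ``log_f`` is subjects × regions.  df = n_subjects − 1.  A region where
    every subject has an identical log F has no estimable variance: if that
    common value differs from the reference, the t statistic is unbounded
    and the region is flagged ``degenerate``; if it equals the reference
    the test is undefined and an error is raised.
    """
    lf = np.atleast_2d(np.asarray(log_f, dtype=float))
    n = lf.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for the group test")
    ref = null_log_f_mean(df1, df2)
    sd = lf.std(axis=0, ddof=1)
    mean = lf.mean(axis=0)
    degenerate = sd == 0
    if np.any(degenerate & (mean == ref)):
        raise ValueError("zero variance across subjects at the null reference; t undefined")
    with np.errstate(divide="ignore"):
        t = (mean - ref) / (sd / np.sqrt(n))
        t = np.where(degenerate, np.sign(mean - ref) * np.inf, t)
    if region_labels is None:
        region_labels = tuple(f"region{i}" for i in range(lf.shape[1]))
    return GroupLogFTest(
        region_labels=tuple(region_labels),
        t=t,
        df=n - 1,
        reference=ref,
        degenerate=degenerate,
    )
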