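"""Pooled standard deviation and two-way fixed-effects ANOVA.

Replicate fermenters are summarised by a pooled standard deviation — the
square root of the variance-weighted-by-degrees-of-freedom average across
replicate groups.  Donor and matrix effects on a per-arm statistic (a rate
constant, a 48-h concentration, a peak concentration) are tested with a
two-way main-effects ANOVA.

The ANOVA is implemented from first principles via explicit design-matrix
least squares with Type II sums of squares: each factor's SS is the drop in
residual SS when that factor is added to a model already containing the
other.  On balanced data this coincides with the sequential (Type I)
decomposition; under mild imbalance (e.g. one lost fermenter) Type II keeps
each main effect adjusted for the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "FactorEffect",
    "AnovaResult",
    "pooled_sd",
    "two_way_anova",
    "stars",
]


@dataclass(frozen=True)
class GroupSummary:
    """Size and standard deviation of one replicate group."""

    label: str
    n: int
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def pooled_sd(groups: list[GroupSummary]) -> float:
    """Pooled standard deviation across replicate groups.

    sqrt( sum (n_i - 1) sd_i^2 / sum (n_i - 1) ); groups with n < 2
    contribute no degrees of freedom and are ignored.

    Raises
    ------
    ValueError
        No group with n >= 2.
    """
    dof = np.array([g.n - 1 for g in groups if g.n >= 2])
    var = np.array([g.sd**2 for g in groups if g.n >= 2])
    if dof.size == 0:
        raise ValueError("pooled SD needs at least one group with n >= 2")
    return float(np.sqrt(np.sum(dof * var) / np.sum(dof)))


def stars(p: float) -> str:
    """Significance stars: *** p<=0.001, ** p<=0.01, * p<=0.05, else ns."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class FactorEffect:
    """df, SS, MS, F, p and stars for one factor."""

    df: int
    ss: float
    ms: float
    F: float
    p: float

    @property
    def stars(self) -> str:
        return stars(self.p)


@dataclass(frozen=True)
class AnovaResult:
    """Two-way main-effects ANOVA summary (donor and matrix factors)."""

    donor: FactorEffect
    matrix: FactorEffect
    residual_df: int
    residual_ms: float


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Treatment-coded indicator columns (first level as reference)."""
    levels = np.unique(labels)
    cols = [(labels == lv).astype(float) for lv in levels[1:]]
    X = np.column_stack(cols) if cols else np.empty((len(labels), 0))
    return X, len(levels)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    values,
    donor_labels,
    matrix_labels,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with donor and matrix main effects.

    Type II sums of squares: SS(donor) = RSS(intercept + matrix) -
    RSS(full), and symmetrically for matrix.  F = MS_factor / MS_residual;
    p from the F distribution.

    Raises
    ------
    ValueError
        A factor with fewer than 2 levels, or zero residual degrees of
        freedom.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(donor_labels)
    m = np.asarray(matrix_labels)
    if not (len(y) == len(d) == len(m)):
        raise ValueError("values and label vectors must have equal length")

    Xd, n_d = _dummies(d)
    Xm, n_m = _dummies(m)
    if n_d < 2 or n_m < 2:
        raise ValueError("each factor needs at least 2 levels")

    ones = np.ones((len(y), 1))
    rss_full = _rss(y, np.hstack([ones, Xd, Xm]))
    df_resid = len(y) - 1 - (n_d - 1) - (n_m - 1)
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    ms_resid = rss_full / df_resid

    effects = {}
    for name, X_drop, X_keep, df in (
        ("donor", Xd, Xm, n_d - 1),
        ("matrix", Xm, Xd, n_m - 1),
    ):
        ss = max(_rss(y, np.hstack([ones, X_keep])) - rss_full, 0.0)
        ms = ss / df
        F = ms / ms_resid if ms_resid > 0 else np.inf
        p = float(sps.f.sf(F, df, df_resid)) if np.isfinite(F) else 0.0
        effects[name] = FactorEffect(df=df, ss=ss, ms=ms, F=F, p=p)

    return AnovaResult(
        donor=effects["donor"],
        matrix=effects["matrix"],
        residual_df=df_resid,
        residual_ms=ms_resid,
    )
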