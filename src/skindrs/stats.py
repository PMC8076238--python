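"""Cohort statistics: one-way ANOVA, Scheffé post hoc, Pearson r, box stats.

The four comparison groups are the measurement sites — psoriatic lesion,
adjacent uninvolved skin and uninvolved upper-inner-arm of the psoriasis
subjects, and the upper-inner-arm of the normal subjects.  ANOVA is the
classical equal-variance decomposition; when it rejects, all pairwise
contrasts are tested with the (conservative) Scheffé procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaResult",
    "ScheffeResult",
    "BoxStats",
    "SITE_LABELS",
    "one_way_anova",
    "scheffe_test",
    "pearson_correlation",
    "box_whisker_stats",
]

SITE_LABELS = ("lesion", "adjacent_uninvolved", "psoriasis_arm", "normal_arm")


@dataclass
class GroupSample:
    """One group's per-subject statistic values (e.g. rho, or mu_s' at a
    wavelength)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("group values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)


@dataclass
class ScheffeResult:
    """All pairwise Scheffé contrasts after a one-way ANOVA.

    ``p_values[i, j]`` is the Scheffé p for groups i vs j (diagonal 1);
    ``sig[i, j]`` is 1 when p < alpha, matching the Sig convention of the
    inset tables.
    """

    labels: list[str]
    p_values: np.ndarray
    sig: np.ndarray
    msw: float
    alpha: float = 0.05


def _validate_groups(groups: list[GroupSample], min_groups: int = 2) -> None:
    if len(groups) < min_groups:
        raise ValueError(f"need >= {min_groups} groups")
    for grp in groups:
        if grp.n < 2:
            raise ValueError(
                f"insufficient data: group {grp.label!r} has n={grp.n} < 2")


def one_way_anova(groups: list[GroupSample]) -> AnovaResult:
    """Classical equal-variance one-way ANOVA across k groups.

    F is the ratio of between- to within-group mean squares with
    (k-1, N-k) degrees of freedom.  All-equal data yields F = 0, p = 1.
    """
    _validate_groups(groups)
    arrays = [g.values for g in groups]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    f_stat, p = sps.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # zero within-group variance, equal means
        f_stat, p = 0.0, 1.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
        group_means={g.label: float(np.mean(g.values)) for g in groups},
    )


def scheffe_test(groups: list[GroupSample], alpha: float = 0.05) -> ScheffeResult:
    """Scheffé pairwise contrasts after one-way ANOVA.

    For groups i, j:  F_pair = (mean_i - mean_j)^2 / (MSW (1/n_i + 1/n_j));
    p is the upper tail of F_{k-1, N-k} at F_pair / (k-1).  The procedure
    is conservative: every Scheffé p is at least the unadjusted pooled-t p.
    """
    _validate_groups(groups)
    k = len(groups)
    n_total = sum(g.n for g in groups)
    df_w = n_total - k
    ssw = sum(float(np.sum((g.values - np.mean(g.values)) ** 2)) for g in groups)
    msw = ssw / df_w
    p_mat = np.ones((k, k))
    sig = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = float(np.mean(gi.values) - np.mean(gj.values))
            if msw == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                f_pair = diff**2 / (msw * (1.0 / gi.n + 1.0 / gj.n))
                p = float(sps.f.sf(f_pair / (k - 1), k - 1, df_w))
            p_mat[i, j] = p_mat[j, i] = p
            if p < alpha:
                sig[i, j] = sig[j, i] = 1
    return ScheffeResult(labels=[g.label for g in groups], p_values=p_mat,
                         sig=sig, msw=msw, alpha=alpha)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, _ = sps.pearsonr(x, y)
    return float(r)


@dataclass
class BoxStats:
    """Box-and-whisker summary: quartiles by linear interpolation, outliers
    beyond 1.5 IQR from the box, whiskers to the extreme non-outliers."""

    q25: float
    q75: float
    mean: float
    median: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def box_whisker_stats(values) -> BoxStats:
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"insufficient data: n={v.size} < 4")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_fence = q25 - 1.5 * iqr
    hi_fence = q75 + 1.5 * iqr
    out_mask = (v < lo_fence) | (v > hi_fence)
    inliers = v[~out_mask]
    return BoxStats(
        q25=float(q25), q75=float(q75), mean=float(np.mean(v)),
        median=float(med),
        whisker_low=float(np.min(inliers)),
        whisker_high=float(np.max(inliers)),
        outliers=np.sort(v[out_mask]),
    )
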