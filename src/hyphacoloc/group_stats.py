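"""Group-level statistics over per-image coefficients.

Strain-level summaries (mean ± SEM), one-way ANOVA from the classical
between/within sums of squares, and Dunnett's many-to-one multiple
comparisons with critical values obtained by seeded Monte-Carlo simulation
of the max-|t| null distribution (the contrasts share the control group and
are therefore correlated; the simulation reproduces that correlation
exactly under the pooled-variance normal model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "summarize_groups",
    "one_way_anova",
    "dunnett_mc",
    "dunnett_critical_value",
    "simulate_fwer_null",
    "significance_stars",
]


@dataclass
class GroupSummary:
    """Per-group sample mean and standard error (sd / sqrt(n), n-1 sd)."""

    group_label: str
    n: int
    mean: float
    sem: float
    qc_small_n: bool
    values: np.ndarray


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


def summarize_groups(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean and SEM per group; a singleton group gets SEM 0 with a QC flag."""
    out = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        if v.size < 2:
            sem, qc = 0.0, True
        else:
            sem, qc = float(v.std(ddof=1) / math.sqrt(v.size)), False
        out.append(GroupSummary(str(label), int(v.size), float(v.mean()), sem, qc, v))
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = (SSB / (k-1)) / (SSW / (N-k)); p from the F survival function.
    When every observation is identical, F = 0 and p = 1.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_values.size - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def significance_stars(p: float) -> str:
    """Significance tier labels at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _null_max_abs_t(
    group_sizes: Sequence[int], n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws of max_i |T_i| under H0 for many-to-one contrasts.

    ``group_sizes[0]`` is the control.  Each draw simulates standardized
    group means z_i ~ N(0,1) and a pooled-variance factor s with
    s^2 ~ chi2(df)/df, df = N - k, and forms
    T_i = (z_i/sqrt(n_i) - z_0/sqrt(n_0)) / (s * sqrt(1/n_i + 1/n_0)).
    """
    sizes = np.asarray(group_sizes, dtype=float)
    k = sizes.size
    df = int(sizes.sum()) - k
    z = rng.standard_normal((n_draws, k))
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    scale = np.sqrt(1.0 / sizes[1:] + 1.0 / sizes[0])
    t = (z[:, 1:] / np.sqrt(sizes[1:]) - z[:, [0]] / math.sqrt(sizes[0])) / (
        s[:, None] * scale[None, :]
    )
    return np.abs(t)


def dunnett_mc(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett's test of every treatment group against the control.

    Observed statistics use the variance pooled over all groups with
    df = N - k.  Adjusted p-values are Monte-Carlo exceedance probabilities
    of the simulated max-|t| null distribution (two-sided), estimated as
    (count + 1) / (n_draws + 1); unadjusted per-contrast p-values come from
    the same draws so that p_adj >= p_unadj holds sample-wise.  Reproducible
    given the seed.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10000 for a stable tail estimate")
    labels = [control_label] + [g for g in groups if g != control_label]
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    sizes = [a.size for a in arrays]
    n_total = sum(sizes)
    k = len(arrays)
    df = n_total - k
    pooled_var = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays) / df

    control_mean = arrays[0].mean()
    t_obs = np.array([
        (a.mean() - control_mean)
        / math.sqrt(pooled_var * (1.0 / a.size + 1.0 / sizes[0]))
        if pooled_var > 0 else (0.0 if a.mean() == control_mean else math.inf)
        for a in arrays[1:]
    ])

    rng = np.random.default_rng(seed)
    abs_t = _null_max_abs_t(sizes, n_draws, rng)
    max_abs = abs_t.max(axis=1)
    rows = []
    for i, label in enumerate(labels[1:]):
        stat = abs(t_obs[i])
        p_adj = (float(np.count_nonzero(max_abs >= stat)) + 1.0) / (n_draws + 1.0)
        p_unadj = (float(np.count_nonzero(abs_t[:, i] >= stat)) + 1.0) / (n_draws + 1.0)
        rows.append({
            "group": label,
            "control": control_label,
            "t": float(t_obs[i]),
            "df": df,
            "p_unadj": p_unadj,
            "p_adj": p_adj,
            "stars": significance_stars(p_adj),
        })
    return pd.DataFrame(rows)


def dunnett_critical_value(
    group_sizes: Sequence[int],
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value via Monte-Carlo.

    ``group_sizes[0]`` is the control group.  Returns the (1 - alpha)
    quantile of the simulated max-|t| null distribution.
    """
    rng = np.random.default_rng(seed)
    max_abs = _null_max_abs_t(group_sizes, n_draws, rng).max(axis=1)
    return float(np.quantile(max_abs, 1.0 - alpha))


def simulate_fwer_null(
    n_groups: int = 3,
    n_per_group: int = 10,
    n_experiments: int = 2000,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate of the Dunnett procedure under H0.

    Simulates ``n_experiments`` experiments where every group is drawn from
    the same normal distribution, applies the Monte-Carlo critical value,
    and returns the fraction of experiments with at least one rejection.
    Should be ~ alpha for a calibrated procedure.
    """
    rng = np.random.default_rng(seed)
    sizes = [n_per_group] * n_groups
    crit = dunnett_critical_value(
        sizes, alpha=alpha, n_draws=n_draws,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    data = rng.standard_normal((n_experiments, n_groups, n_per_group))
    means = data.mean(axis=2)
    ss = ((data - means[..., None]) ** 2).sum(axis=(1, 2))
    df = n_groups * n_per_group - n_groups
    pooled_var = ss / df
    scale = math.sqrt(2.0 / n_per_group)
    t = (means[:, 1:] - means[:, [0]]) / (
        np.sqrt(pooled_var)[:, None] * scale
    )
    rejected = np.abs(t).max(axis=1) > crit
    return float(rejected.mean())
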