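"""Statistical comparison of group networks against a cohort.

Nodal metric distributions are compared with two-sample
Kolmogorov-Smirnov statistics averaged over subjects (smaller mean KS =
closer correspondence); global metrics with z-scores against the
subject distribution (sample SD); families of mean distances with
Welch's t-test or one-way ANOVA plus the eta-squared effect size, with
Bonferroni correction over the pairwise contrasts actually tested.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .dbc import profile_sq_euclid
from .kuramoto import metastability_profile

__all__ = [
    "mean_ks", "global_zscore", "welch_t", "oneway_anova_eta",
    "bonferroni", "dynamical_anova",
]


def mean_ks(
    group_values: np.ndarray, cohort_values: Sequence[np.ndarray]
) -> tuple[float, float]:
    """Mean and sample SD over subjects of the two-sample KS statistic.

    The KS statistic (sup of absolute ECDF difference) is computed
    between the group network's per-node values and each subject's, then
    averaged.
    """
    group_values = np.asarray(group_values, dtype=float)
    if group_values.size == 0:
        raise ValueError("empty group value set")
    ks = []
    for vals in cohort_values:
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError("empty subject value set")
        ks.append(sps.ks_2samp(group_values, vals).statistic)
    ks = np.asarray(ks)
    sd = float(ks.std(ddof=1)) if ks.size > 1 else 0.0
    return float(ks.mean()), sd


def global_zscore(group_value: float, subject_values: Sequence[float]) -> float:
    """``(group - mean(subjects)) / sampleSD(subjects)``.

    Zero subject SD yields signed infinity (0 if the group matches the
    degenerate subject value exactly) with a warning.
    """
    vals = np.asarray(subject_values, dtype=float)
    if vals.size < 2:
        raise ValueError("z-score needs at least 2 subject values")
    sd = vals.std(ddof=1)
    diff = group_value - vals.mean()
    if sd == 0:
        warnings.warn("zero subject SD: z-score is infinite")
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / sd)


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Welch's unequal-variance t-test: ``(t, df, p)`` two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples degenerate with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def oneway_anova_eta(groups: Sequence[Sequence[float]]):
    """One-way ANOVA with effect size: ``(F, df_between, df_within, p, eta2)``.

    ``eta2 = SS_between / SS_total``; for g groups of sizes n_i the
    degrees of freedom are (g-1, sum(n_i)-g).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((all_vals - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ss_total == 0:
        return 0.0, df_b, df_w, 1.0, 0.0
    if ss_within == 0:
        return float("inf"), df_b, df_w, 0.0, 1.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    eta2 = ss_between / ss_total
    return float(f), df_b, df_w, p, float(eta2)


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.01, m: int | None = None
) -> list[bool]:
    """Flag ``p_i < alpha / m`` for ``m`` comparisons (default ``m = len(p)``)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    thr = alpha / m if m > 0 else alpha
    return [p < thr for p in p_values]


def dynamical_anova(
    group_networks: Sequence,
    subject_profiles: Sequence,
    grid=None,
    config=None,
    group_profiles: Sequence | None = None,
    alpha: float = 0.01,
) -> dict:
    """Compare group networks on profile distance to the subjects.

    For each group network the n per-subject squared Euclidean profile
    distances form one sample; a one-way ANOVA (with eta-squared) tests
    for differences across group networks, followed by pairwise Welch
    post-hocs with Bonferroni correction over the tested contrasts.
    ``group_profiles`` may be supplied to reuse precomputed profiles.
    """
    if len(group_networks) < 2:
        raise ValueError("need at least 2 group networks to compare")
    if group_profiles is None:
        group_profiles = [
            metastability_profile(g, grid, config) for g in group_networks
        ]
    distances = [
        np.array([profile_sq_euclid(gp, sp) for sp in subject_profiles])
        for gp in group_profiles
    ]
    f, df_b, df_w, p, eta2 = oneway_anova_eta(distances)
    pairs = list(itertools.combinations(range(len(distances)), 2))
    posthoc = []
    for i, j in pairs:
        t, df, pw = welch_t(distances[i], distances[j])
        posthoc.append({"pair": (i, j), "t": t, "df": df, "p": pw})
    flags = bonferroni([h["p"] for h in posthoc], alpha=alpha, m=len(pairs))
    for h, sig in zip(posthoc, flags):
        h["significant"] = sig
    return {
        "distances": distances,
        "anova": {"F": f, "df_between": df_b, "df_within": df_w, "p": p,
                  "eta_squared": eta2},
        "posthoc": posthoc,
        "n_comparisons": len(pairs),
        "alpha": alpha,
    }
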