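"""Statistical battery for NMJ- and animal-level tables.

One-way ANOVA (treatment fixed effect on per-NMJ morphometrics),
two-way ANOVA with interaction (treatment × denervation category on
per-animal proportions; Type-II sums of squares), Pearson chi-square on
the category contingency table, Tukey–Kramer HSD post hocs, matched
pre/post t-tests on body mass, derived effect sizes at reporting
precision, and a Monte-Carlo power check for the nested (NMJs within
animals) design.

All tests are two-sided at α = 0.05 by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class StatsResult:
    statistic_name: str
    statistic_value: float
    df_pair: tuple
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _summaries(values: np.ndarray, groups: np.ndarray) -> dict:
    out = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        out[str(g)] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }
    return out


def one_way_anova(values: Sequence[float], groups: Sequence) -> StatsResult:
    """Fixed-effect one-way ANOVA via the between/within decomposition.

    Returns F with (k−1, N−k) degrees of freedom.  Zero within-group
    variance with distinct means yields an infinite F (p = 0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("one_way_anova requires >= 2 groups")
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in labels:
        v = values[groups == g]
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df1, df2 = len(labels) - 1, values.size - len(labels)
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else float("inf")
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(F, df1, df2))
    return StatsResult(
        "one_way_anova_F",
        float(F),
        (df1, df2),
        p,
        _summaries(values, groups),
        extra={
            "ss_between": float(ss_between),
            "ss_within": float(ss_within),
            "ss_total": float(((values - grand) ** 2).sum()),
        },
    )


def _rss(y: np.ndarray, X: np.ndarray) -> Tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(np.linalg.matrix_rank(X))


def two_way_anova(
    response: Sequence[float], factor_a: Sequence, factor_b: Sequence
) -> Dict[str, Optional[StatsResult]]:
    """Two-factor fixed-effects ANOVA with interaction, Type-II sums of
    squares (each main effect adjusted for the other; the interaction
    adjusted for both).

    Returns a dict with keys ``factor_a``, ``factor_b``, ``interaction``
    (the latter ``None`` — with a warning — when empty cells make it
    inestimable).  Effects with zero sum of squares report F = 0.
    """
    y = np.asarray(response, dtype=float)
    a = pd.Categorical(np.asarray(factor_a))
    b = pd.Categorical(np.asarray(factor_b))
    if len(a.categories) < 2 or len(b.categories) < 2:
        raise ValueError("each factor needs >= 2 levels")

    cells = pd.crosstab(np.asarray(factor_a), np.asarray(factor_b))
    has_empty_cell = (cells.values == 0).any()
    if has_empty_cell:
        warnings.warn("empty cells in the two-factor layout; interaction omitted")

    A = pd.get_dummies(a, drop_first=True).to_numpy(float)
    B = pd.get_dummies(b, drop_first=True).to_numpy(float)
    ones = np.ones((y.size, 1))
    AB = np.einsum("ij,ik->ijk", A, B).reshape(y.size, -1)

    X_ab = np.hstack([ones, A, B])
    X_a = np.hstack([ones, A])
    X_b = np.hstack([ones, B])
    X_full = X_ab if has_empty_cell else np.hstack([X_ab, AB])

    rss_full, rank_full = _rss(y, X_full)
    rss_ab, rank_ab = _rss(y, X_ab)
    rss_a, rank_a = _rss(y, X_a)
    rss_b, rank_b = _rss(y, X_b)

    df_resid = y.size - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (need replicates per cell)")
    mse = rss_full / df_resid

    def effect(name, ss, df):
        ss = max(ss, 0.0)
        if df <= 0:
            return None
        if ss <= 1e-12 * max(1.0, float(y @ y)):
            F, p = 0.0, 1.0
        elif mse == 0.0:
            F, p = float("inf"), 0.0
        else:
            F = (ss / df) / mse
            p = float(sps.f.sf(F, df, df_resid))
        return StatsResult(
            name, float(F), (df, df_resid), p, extra={"ss": float(ss), "mse": float(mse)}
        )

    out = {
        "factor_a": effect("two_way_F_a", rss_b - rss_ab, rank_ab - rank_b),
        "factor_b": effect("two_way_F_b", rss_a - rss_ab, rank_ab - rank_a),
        "interaction": None
        if has_empty_cell
        else effect("two_way_F_interaction", rss_ab - rss_full, rank_full - rank_ab),
    }
    return out


def chi_square_independence(table) -> StatsResult:
    """Pearson chi-square test of independence on a counts table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if (table < 0).any() or not np.allclose(table, np.rint(table)):
        raise ValueError("table must hold nonnegative integer counts")
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    if (rows == 0).any():
        raise ValueError(f"degenerate margin: row sums {rows.tolist()} contain zero")
    if (cols == 0).any():
        raise ValueError(f"degenerate margin: column sums {cols.tolist()} contain zero")
    res = sps.chi2_contingency(table, correction=False)
    return StatsResult(
        "pearson_chi2",
        float(res.statistic),
        (int(res.dof),),
        float(res.pvalue),
        extra={"expected": res.expected_freq.tolist()},
    )


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float


def tukey_kramer(values: Sequence[float], groups: Sequence) -> list:
    """Tukey–Kramer HSD pairwise comparisons (studentized range with the
    unequal-n correction).  A single group yields an empty list."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        return []
    samples = [values[groups == g] for g in labels]
    res = sps.tukey_hsd(*samples)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                PairwiseComparison(
                    str(labels[i]),
                    str(labels[j]),
                    float(samples[i].mean() - samples[j].mean()),
                    float(res.pvalue[i, j]),
                )
            )
    return out


def paired_t_test(pre: Sequence[float], post: Sequence[float]) -> StatsResult:
    """Matched-pairs t-test on post − pre differences, df = n − 1,
    two-sided."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("paired_t_test needs two equal-length samples of size >= 2")
    d = post - pre
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else float("inf") * np.sign(d.mean())
        p = 1.0 if d.mean() == 0.0 else 0.0
        degenerate = True
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = float(2 * sps.t.sf(abs(t), n - 1))
        degenerate = False
    return StatsResult(
        "paired_t",
        float(t),
        (n - 1,),
        p,
        extra={"mean_difference": float(d.mean()), "degenerate": degenerate},
    )


@dataclass
class EffectSizes:
    """Derived between-group effect sizes, relative to the vehicle mean.

    Percent changes are 100 × (vehicle − treated) / vehicle; the
    partial-denervation fold change is treated / vehicle.  ``rounded``
    gives them at reporting precision (integer percent, one-decimal
    fold)."""

    pct_change_pre_volume: float = float("nan")
    pct_change_apposition: float = float("nan")
    pct_change_innervated: float = float("nan")
    fold_partial_denervation: float = float("nan")
    pct_sex_mass_difference: float = float("nan")

    def rounded(self) -> dict:
        out = {}
        for name in (
            "pct_change_pre_volume",
            "pct_change_apposition",
            "pct_change_innervated",
            "pct_sex_mass_difference",
        ):
            v = getattr(self, name)
            out[name] = int(round(v)) if np.isfinite(v) else None
        f = self.fold_partial_denervation
        out["fold_partial_denervation"] = round(f, 1) if np.isfinite(f) else None
        return out


def percent_change(reference_mean: float, treated_mean: float) -> float:
    """100 × (reference − treated) / reference."""
    if reference_mean == 0:
        raise ValueError("reference mean is 0; percent change undefined")
    return 100.0 * (reference_mean - treated_mean) / reference_mean


def percent_difference(larger_mean: float, smaller_mean: float) -> float:
    """100 × (larger − smaller) / smaller (e.g. male vs female mass)."""
    if smaller_mean == 0:
        raise ValueError("reference mean is 0; percent difference undefined")
    return 100.0 * (larger_mean - smaller_mean) / smaller_mean


def effect_sizes(group_summaries: dict) -> EffectSizes:
    """Compute the derived effect sizes from group means.

    ``group_summaries`` maps quantity name to a ``(vehicle_mean,
    treated_mean)`` pair for ``pre_volume``, ``apposition``,
    ``innervated_pct``, ``partial_pct``; optionally ``mass_by_sex`` as
    ``(male_mean, female_mean)``.
    """
    es = EffectSizes()
    if "pre_volume" in group_summaries:
        es.pct_change_pre_volume = percent_change(*group_summaries["pre_volume"])
    if "apposition" in group_summaries:
        es.pct_change_apposition = percent_change(*group_summaries["apposition"])
    if "innervated_pct" in group_summaries:
        es.pct_change_innervated = percent_change(*group_summaries["innervated_pct"])
    if "partial_pct" in group_summaries:
        veh, chl = group_summaries["partial_pct"]
        if veh == 0:
            raise ValueError("vehicle partial-denervation proportion is 0; fold undefined")
        es.fold_partial_denervation = chl / veh
    if "mass_by_sex" in group_summaries:
        es.pct_sex_mass_difference = percent_difference(*group_summaries["mass_by_sex"])
    return es


@dataclass(frozen=True)
class NestedVarianceProfile:
    """Variance components for the nested design: NMJs within animals.

    CVs are relative to the group mean; ``nmj_per_animal`` sets how much
    the within-animal component shrinks when averaging per animal."""

    mean: float = 1400.0
    between_animal_cv: float = 0.05
    within_animal_cv: float = 0.17
    nmj_per_animal: int = 40


def power_check(
    effect_pct: float,
    n_per_group: int = 4,
    profile: Optional[NestedVarianceProfile] = None,
    alpha: float = 0.05,
    reps: int = 500,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the one-way ANOVA on per-animal means for a
    two-group design under the nested variance model.

    ``effect_pct`` is the percent reduction in the treated group mean.
    Returns the achieved power (rejection fraction at ``alpha``).
    """
    if reps < 200:
        raise ValueError("reps must be >= 200 for a stable power estimate")
    profile = profile or NestedVarianceProfile()
    rng = np.random.default_rng(seed)
    mu = np.array([profile.mean, profile.mean * (1.0 - effect_pct / 100.0)])
    between_sd = profile.between_animal_cv * profile.mean
    within_se = profile.within_animal_cv * profile.mean / np.sqrt(profile.nmj_per_animal)
    animal_sd = np.sqrt(between_sd**2 + within_se**2)
    # vectorized two-group ANOVA on per-animal means (F = t² for k = 2)
    draws = rng.normal(
        mu[None, :, None], animal_sd, size=(reps, 2, n_per_group)
    )
    m = draws.mean(axis=2)
    v = draws.var(axis=2, ddof=1)
    # pooled two-sample t with equal n
    sp2 = v.mean(axis=1)
    t = (m[:, 0] - m[:, 1]) / np.sqrt(sp2 * 2.0 / n_per_group)
    F = t**2
    crit = sps.f.isf(alpha, 1, 2 * n_per_group - 2)
    return float(np.mean(F > crit))
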