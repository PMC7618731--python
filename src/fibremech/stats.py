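"""Group comparison and summary statistics across fibre cohorts.

The comparison policy is normality-gated: each variant's values are
tested with Shapiro–Wilk, and the omnibus comparison is one-way ANOVA if
every group passes, otherwise the nonparametric Kruskal–Wallis test.
Fold changes are reported as ratios of group means over a reference
group (typically wild type), and crosslinked and uncrosslinked cohorts
are never combined into one ratio for stress-valued metrics — absolute
stresses carry day-to-day calibration error that only cancels within a
measurement set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ComparisonPolicyError, GroupTooSmallError, InvalidParameterError


@dataclass
class GroupComparison:
    """Outcome of one normality-gated omnibus comparison."""

    metric: str
    groups: dict[str, np.ndarray]
    normality_p: dict[str, float]
    chosen_test: str  # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    p_value: float
    fold_changes: dict[str, float]
    reference: str
    alpha_norm: float = 0.05
    notes: dict = field(default_factory=dict)


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    metric: str = "",
    reference: str | None = None,
    alpha_norm: float = 0.05,
) -> GroupComparison:
    """Normality-gated omnibus comparison of ≥ 2 groups.

    Shapiro–Wilk per group at ``alpha_norm``; Kruskal–Wallis if any group
    fails, one-way ANOVA if all pass. Fold changes are group mean over
    reference mean (reference defaults to the first group; its own fold
    change is 1 by construction).
    """
    if len(values_by_group) < 2:
        raise InvalidParameterError("need at least 2 groups to compare")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, vals in groups.items():
        if len(vals) < 3:
            raise GroupTooSmallError(
                f"group {name!r} has only {len(vals)} values; need at least 3"
            )
    normality_p = {name: float(sps.shapiro(vals).pvalue) for name, vals in groups.items()}
    all_normal = all(p >= alpha_norm for p in normality_p.values())
    arrays = list(groups.values())
    if all_normal:
        stat, p = sps.f_oneway(*arrays)
        chosen = "ANOVA"
    else:
        stat, p = sps.kruskal(*arrays)
        chosen = "Kruskal-Wallis"
    reference = reference if reference is not None else next(iter(groups))
    if reference not in groups:
        raise InvalidParameterError(f"reference group {reference!r} not present")
    ref_mean = float(np.mean(groups[reference]))
    fold = {
        name: float(np.mean(vals)) / ref_mean if ref_mean != 0 else float("nan")
        for name, vals in groups.items()
    }
    return GroupComparison(
        metric=metric, groups=groups, normality_p=normality_p,
        chosen_test=chosen, statistic=float(stat), p_value=float(p),
        fold_changes=fold, reference=reference, alpha_norm=alpha_norm,
        notes={"normality_test": "shapiro-wilk"},
    )


def pairwise_tests(
    values_by_group: dict[str, np.ndarray],
    parametric: bool,
    correction: str = "holm",
) -> pd.DataFrame:
    """Optional pairwise follow-up (off the default path): Welch t-tests or
    Mann–Whitney U with Holm correction. Provided behind an explicit call
    because the omnibus test is the default report."""
    names = list(values_by_group)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(values_by_group[names[i]], float)
            b = np.asarray(values_by_group[names[j]], float)
            if parametric:
                stat, p = sps.ttest_ind(a, b, equal_var=False)
            else:
                stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(stat), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    if correction == "holm" and len(df):
        order = np.argsort(df["p_raw"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adjusted"] = adj
    return df


def fold_change_table(
    results: pd.DataFrame,
    metrics: list[str],
    variant_col: str = "variant",
    crosslinked_col: str = "crosslinked",
    reference: str = "WT",
    extra_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Ratio-over-reference table of group means, per crosslinking state.

    ``results`` holds one row per fibre with a variant label, a
    crosslinked flag and one column per metric. For each crosslinking
    state separately, every non-reference variant is reported as
    mean(variant)/mean(reference); ``extra_pairs`` adds ratios between two
    non-reference variants (e.g. the most truncated over the intermediate
    one). Columns are named ``"{num}{X|UX}/{den}{X|UX}"``. Ratios never
    mix crosslinked with uncrosslinked fibres; a zero reference mean
    yields NaN with a note in ``attrs['flags']``.
    """
    if reference not in set(results[variant_col]):
        raise InvalidParameterError(f"reference variant {reference!r} not in results")
    flags: list[str] = []
    table: dict[str, dict[str, float]] = {}
    for xlink, sub in results.groupby(crosslinked_col):
        suffix = "X" if xlink else "UX"
        means = {v: sub.loc[sub[variant_col] == v, metrics].mean() for v in sub[variant_col].unique()}
        pairs = [(v, reference) for v in means if v != reference]
        pairs += [p for p in (extra_pairs or []) if p[0] in means and p[1] in means]
        for num, den in pairs:
            if num == den:
                continue
            col = f"{num}{suffix}/{den}{suffix}"
            table[col] = {}
            for m in metrics:
                d = float(means[den][m])
                if d == 0:
                    table[col][m] = float("nan")
                    flags.append(f"zero_reference_mean:{col}:{m}")
                else:
                    table[col][m] = float(means[num][m]) / d
    out = pd.DataFrame(table).reindex(metrics)
    out.attrs["flags"] = flags
    out.attrs["policy"] = "crosslinked and uncrosslinked never combined in one ratio"
    return out


def assert_comparable(group_a_crosslinked: bool, group_b_crosslinked: bool,
                      metric_is_ratio: bool) -> None:
    """Guard for the pooling policy: stress-valued metrics may only be
    compared within one crosslinking state; ratio/time-constant metrics
    are calibration-free and may cross it."""
    if not metric_is_ratio and group_a_crosslinked != group_b_crosslinked:
        raise ComparisonPolicyError(
            "stress-valued metrics cannot be compared across crosslinked and "
            "uncrosslinked datasets (day-to-day calibration error does not cancel)"
        )
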