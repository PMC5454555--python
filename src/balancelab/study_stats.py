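"""Repeated-measures analysis of the transformed balance index.

The long table holds one transformed balance-index value (1/mean R, s²/m)
per (participant, condition) cell.  ``rm_anova`` fits the univariate
repeated-measures model with exercise condition as the within-subject factor
and, optionally, participant sex as a between-subject covariate.  Sums of
squares are sequential (Type I): sex first, then subjects within sex, then
condition, then the within-subject residual; the exercise F statistic tests
condition against that residual.  ``bonferroni_pairwise`` runs two-sided
paired t tests on every condition pair with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "reciprocal_transform",
    "validate_long_table",
    "rm_anova",
    "bonferroni_pairwise",
]

REQUIRED_COLUMNS = ("participant_id", "sex", "condition", "value")


@dataclass(frozen=True)
class AnovaResult:
    """Sequential sums-of-squares decomposition and the exercise-effect test."""

    ss_covariate: float
    ss_subject: float
    ss_exercise: float
    ss_residual: float
    ss_total: float
    df_covariate: int
    df_subject: int
    df_exercise: int
    df_residual: int
    f_exercise: float  # nan when the residual mean square is zero
    p_exercise: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sex", self.ss_covariate, self.df_covariate, np.nan, np.nan),
            ("subject", self.ss_subject, self.df_subject, np.nan, np.nan),
            ("exercise", self.ss_exercise, self.df_exercise, self.f_exercise, self.p_exercise),
            ("residual", self.ss_residual, self.df_residual, np.nan, np.nan),
            ("total", self.ss_total, self.df_covariate + self.df_subject
             + self.df_exercise + self.df_residual, np.nan, np.nan),
        ]
        return pd.DataFrame(rows, columns=["term", "SS", "df", "F", "p"])


def reciprocal_transform(values) -> np.ndarray:
    """Elementwise 1/x; every input must be strictly positive."""
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(
            f"reciprocal transform requires strictly positive values; "
            f"offending row index(es): {bad.tolist()[:10]}"
        )
    return 1.0 / arr


def validate_long_table(data: pd.DataFrame, covariate: str | None = "sex") -> pd.DataFrame:
    """Check balance and covariate constancy; returns the validated frame."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in data.columns and
                    not (c == "sex" and covariate is None)]
    if missing_cols:
        raise ValueError(f"long table missing column(s) {missing_cols}")
    if data.duplicated(subset=["participant_id", "condition"]).any():
        dupes = data[data.duplicated(subset=["participant_id", "condition"], keep=False)]
        raise ValueError(
            "duplicate (participant, condition) rows: "
            f"{sorted(set(map(tuple, dupes[['participant_id', 'condition']].values)))[:10]}"
        )
    participants = data["participant_id"].unique()
    conditions = data["condition"].unique()
    if len(participants) < 2 or len(conditions) < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    counts = data.pivot_table(
        index="participant_id", columns="condition", values="value", aggfunc="count"
    )
    if counts.isna().any().any():
        missing = [
            (p, c)
            for p in counts.index
            for c in counts.columns
            if pd.isna(counts.loc[p, c])
        ]
        raise ValueError(f"unbalanced design; missing cells: {missing[:20]}")
    if covariate is not None:
        per_subject = data.groupby("participant_id")[covariate].nunique()
        varying = per_subject[per_subject > 1]
        if len(varying):
            raise ValueError(
                f"covariate {covariate!r} varies within participant(s): {list(varying.index)}"
            )
    return data


def rm_anova(data: pd.DataFrame, covariate: str | None = "sex") -> AnovaResult:
    """Univariate repeated-measures ANOVA of the balance index.

    Balanced design required (every participant measured in every condition).
    Returns the sequential SS decomposition; F for the exercise effect uses
    the within-subject residual as the error term.
    """
    data = validate_long_table(data, covariate=covariate)
    wide = data.pivot(index="participant_id", columns="condition", values="value")
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=1)
    if covariate is not None:
        groups = data.groupby("participant_id")[covariate].first().reindex(wide.index)
        codes, uniques = pd.factorize(groups)
        n_groups = len(uniques)
        group_means = np.array([subj_means[codes == g].mean() for g in range(n_groups)])
        ss_cov = float(sum(k * (codes == g).sum() * (group_means[g] - grand) ** 2
                           for g in range(n_groups)))
        ss_subj = float(sum(k * (subj_means[i] - group_means[codes[i]]) ** 2
                            for i in range(n)))
        df_cov = n_groups - 1
        df_subj = n - n_groups
    else:
        ss_cov = 0.0
        df_cov = 0
        ss_subj = float((k * (subj_means - grand) ** 2).sum())
        df_subj = n - 1

    cond_means = y.mean(axis=0)
    ss_ex = float((n * (cond_means - grand) ** 2).sum())
    df_ex = k - 1
    ss_res = ss_total - ss_cov - ss_subj - ss_ex
    ss_res = max(ss_res, 0.0)  # guard tiny negative round-off
    df_res = (n - 1) * (k - 1)

    ms_res = ss_res / df_res
    if ms_res > 0:
        f = (ss_ex / df_ex) / ms_res
        p = float(stats.f.sf(f, df_ex, df_res))
    else:
        f = np.nan if ss_ex == 0 else np.inf
        p = 1.0 if ss_ex == 0 else 0.0
    return AnovaResult(
        ss_covariate=ss_cov,
        ss_subject=ss_subj,
        ss_exercise=ss_ex,
        ss_residual=ss_res,
        ss_total=ss_total,
        df_covariate=df_cov,
        df_subject=df_subj,
        df_exercise=df_ex,
        df_residual=df_res,
        f_exercise=float(f),
        p_exercise=p,
    )


def bonferroni_pairwise(data: pd.DataFrame) -> pd.DataFrame:
    """Paired t tests on every condition pair, Bonferroni-adjusted.

    Degenerate pairs (zero variance of the paired differences) get p = 1 when
    the common difference is zero and p = 0 otherwise.
    """
    data = validate_long_table(data, covariate=None)
    wide = data.pivot(index="participant_id", columns="condition", values="value")
    conditions = list(wide.columns)
    pairs = list(combinations(conditions, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        mean_diff = float(diff.mean())
        if np.allclose(diff, diff[0]):
            t_stat = np.nan
            p_raw = 1.0 if mean_diff == 0 else 0.0
        else:
            t_stat, p_raw = stats.ttest_rel(wide[a], wide[b])
            t_stat, p_raw = float(t_stat), float(p_raw)
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "mean_difference": mean_diff,
                "t": t_stat,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * m),
            }
        )
    return pd.DataFrame(rows)
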