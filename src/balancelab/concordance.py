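"""Difficulty rankings and weighted-kappa agreement between assessors.

A ranking assigns each balance condition a rank 1..K (1 = least difficult).
Agreement between two rankings is quantified with the weighted kappa
statistic on the K×K cross-tabulation of assigned ranks, with disagreement
weights w_ij = (i−j)² (quadratic, the default) or |i−j| (linear), and the
expected table taken from the product of the marginals:

    κ_w = 1 − Σ w·O / Σ w·E

For strict rank permutations the marginals are uniform and quadratic κ_w
coincides with the Spearman rank correlation 1 − 6Σd²/(K(K²−1)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankingTable",
    "KappaResult",
    "rank_by_difficulty",
    "weighted_kappa",
    "pairwise_kappa_matrix",
    "device_concordance",
    "read_ranking_csv",
    "write_kappa_report",
]

WEIGHT_SCHEMES = ("linear", "quadratic")
GOOD_AGREEMENT_THRESHOLD = 0.8


@dataclass(frozen=True)
class RankingTable:
    """One assessor's ranking of the conditions (1 = least difficult)."""

    assessor_id: str
    ranks: Mapping[str, float]
    strict: bool = True  # strict: ranks must be a permutation of 1..K

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))
        if len(self.ranks) < 2:
            raise ValueError("a ranking needs at least 2 conditions")
        if self.strict:
            k = len(self.ranks)
            if sorted(self.ranks.values()) != list(range(1, k + 1)):
                raise ValueError(
                    f"{self.assessor_id}: ranks must be a permutation of 1..{k}, "
                    f"got {sorted(self.ranks.values())}"
                )

    @property
    def k(self) -> int:
        return len(self.ranks)

    def conditions_in_rank_order(self) -> list[str]:
        return [c for c, _ in sorted(self.ranks.items(), key=lambda kv: kv[1])]


@dataclass(frozen=True)
class KappaResult:
    assessor_a: str
    assessor_b: str
    kappa: float
    weights: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError(f"kappa out of [-1, 1]: {self.kappa}")


def rank_by_difficulty(
    recip_by_condition: Mapping[str, float],
    *,
    assessor_id: str = "device",
    ties: str = "error",
) -> RankingTable:
    """Rank conditions by mean reciprocal R: the steadiest (largest reciprocal)
    condition is the easiest and gets rank 1.

    Exact ties are refused unless a policy is chosen: ``lexicographic`` breaks
    ties by condition label; ``mean-rank`` assigns tied conditions their
    average rank (the result is then not a strict permutation and cannot feed
    weighted kappa).
    """
    if len(recip_by_condition) < 2:
        raise ValueError("need at least 2 conditions to rank")
    for cond, v in recip_by_condition.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite reciprocal value for {cond!r}: {v}")

    values = list(recip_by_condition.values())
    has_ties = len(set(values)) != len(values)
    if has_ties and ties == "error":
        tied = sorted(
            {v for v in values if values.count(v) > 1}
        )
        raise ValueError(
            f"tied reciprocal values {tied}; pass ties='lexicographic' or ties='mean-rank'"
        )
    if ties not in ("error", "lexicographic", "mean-rank"):
        raise ValueError(f"unknown tie policy {ties!r}")

    if has_ties and ties == "mean-rank":
        s = pd.Series(recip_by_condition)
        ranks = s.rank(ascending=False, method="average")
        return RankingTable(assessor_id, ranks.to_dict(), strict=False)

    # descending by value; label breaks exact ties (no-op when values distinct)
    ordered = sorted(recip_by_condition.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankingTable(assessor_id, {cond: i + 1 for i, (cond, _) in enumerate(ordered)})


def _weight_matrix(k: int, weights: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weights == "quadratic":
        return ((i - j) ** 2).astype(float)
    if weights == "linear":
        return np.abs(i - j).astype(float)
    raise ValueError(f"weights must be one of {WEIGHT_SCHEMES}, got {weights!r}")


def weighted_kappa(a: RankingTable, b: RankingTable, weights: str = "quadratic") -> KappaResult:
    """Weighted kappa between two rankings over the same condition set."""
    if set(a.ranks) != set(b.ranks):
        raise ValueError(
            f"condition sets differ: {sorted(set(a.ranks) ^ set(b.ranks))}"
        )
    if not (a.strict and b.strict):
        raise ValueError("weighted kappa requires strict (untied) rank permutations")
    k = a.k
    observed = np.zeros((k, k))
    for cond in a.ranks:
        observed[int(a.ranks[cond]) - 1, int(b.ranks[cond]) - 1] += 1
    observed /= observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    w = _weight_matrix(k, weights)
    kappa = 1.0 - float((w * observed).sum() / (w * expected).sum())
    return KappaResult(a.assessor_id, b.assessor_id, kappa, weights)


def _summary(kappas: Sequence[float]) -> dict:
    return {
        "n_pairs": len(kappas),
        "min": min(kappas),
        "max": max(kappas),
    }


def pairwise_kappa_matrix(
    tables: Sequence[RankingTable], weights: str = "quadratic"
) -> tuple[list[KappaResult], dict]:
    """Kappa for every unordered pair of assessors (n·(n−1)/2 values)."""
    if len(tables) < 2:
        raise ValueError("need at least 2 ranking tables")
    results = [
        weighted_kappa(a, b, weights)
        for a, b in itertools.combinations(tables, 2)
    ]
    return results, _summary([r.kappa for r in results])


def device_concordance(
    device: RankingTable,
    raters: Sequence[RankingTable],
    weights: str = "quadratic",
) -> tuple[list[KappaResult], dict]:
    """Device-vs-rater kappas: one per rater, plus a validity verdict.

    Agreement above 0.8 with every rater is reported as "good agreement".
    """
    if not raters:
        raise ValueError("need at least one rater")
    results = [weighted_kappa(device, r, weights) for r in raters]
    summary = _summary([r.kappa for r in results])
    summary["verdict"] = (
        "good agreement" if summary["min"] > GOOD_AGREEMENT_THRESHOLD else "inadequate agreement"
    )
    return results, summary


def read_ranking_csv(path: str | Path) -> list[RankingTable]:
    """Read an assessor×condition rank table (rows = assessors, cells = rank 1..K)."""
    df = pd.read_csv(path, index_col=0)
    return [
        RankingTable(str(assessor), {str(c): int(v) for c, v in row.items()})
        for assessor, row in df.iterrows()
    ]


def write_kappa_report(results: Sequence[KappaResult], path: str | Path) -> Path:
    """Write pairwise kappa results as CSV (pair, kappa, weights)."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "assessor_a": r.assessor_a,
                "assessor_b": r.assessor_b,
                "kappa": r.kappa,
                "weights": r.weights,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False)
    return path
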