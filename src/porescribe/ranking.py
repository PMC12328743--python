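"""Ranking of multimer pore models from predictor confidence tables.

The stoichiometry of an oligomeric pore can be scanned by predicting every
n-mer over a range and ranking the models by the standard multimer
confidence score 0.8*ipTM + 0.2*pTM.  This module consumes such metric
tables (it never runs the predictor) and reproduces the two-round scan
logic: a broad first scan, then a template-seeded second scan around the
first winner, reporting whether the refined models improved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "IPTM_WEIGHT",
    "PTM_WEIGHT",
    "MultimerMetricsTable",
    "TwoRoundReport",
    "confidence_score",
    "plddt_band",
    "rank_models",
    "two_round_selection",
]

IPTM_WEIGHT = 0.8
PTM_WEIGHT = 0.2

REQUIRED_COLUMNS = ("n", "iptm", "ptm", "mean_plddt")


@dataclass(frozen=True)
class MultimerMetricsTable:
    """Stoichiometry-indexed confidence metrics.

    Wraps a DataFrame with columns n, iptm, ptm, mean_plddt and an optional
    round_label; n must be unique within each round, ipTM/pTM in [0, 1] and
    mean pLDDT in [0, 100].
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metrics table missing columns: {missing}")
        if "round_label" not in df.columns:
            df["round_label"] = "round1"
        if df.empty:
            raise ValueError("metrics table is empty")
        if df.groupby("round_label")["n"].apply(lambda s: s.duplicated().any()).any():
            raise ValueError("duplicate stoichiometry within a round")
        if ((df["iptm"] < 0) | (df["iptm"] > 1)).any() or (
            (df["ptm"] < 0) | (df["ptm"] > 1)
        ).any():
            raise ValueError("ipTM/pTM out of [0, 1]")
        if ((df["mean_plddt"] < 0) | (df["mean_plddt"] > 100)).any():
            raise ValueError("mean pLDDT out of [0, 100]")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def stoichiometries(self) -> tuple[int, ...]:
        return tuple(int(n) for n in self.frame["n"])


@dataclass(frozen=True)
class TwoRoundReport:
    round1_best_n: int
    round2_covers_round1_best: bool
    final_best_n: int
    score_improved: bool
    round1_best_score: float
    round2_best_score: float
    warnings: tuple[str, ...] = ()


def confidence_score(iptm: float, ptm: float) -> float:
    """Weighted multimer confidence: 0.8*ipTM + 0.2*pTM."""
    if not (0 <= iptm <= 1 and 0 <= ptm <= 1):
        raise ValueError("ipTM and pTM must lie in [0, 1]")
    return IPTM_WEIGHT * iptm + PTM_WEIGHT * ptm


def plddt_band(plddt: float) -> str:
    """Conventional per-residue confidence bands.

    The 'confident' band is the open interval (70, 90), matching the strict
    inequalities of the usual statement 70 < pLDDT < 90; 70 itself is
    'moderate' and 90 itself 'very-high'.
    """
    if not 0 <= plddt <= 100:
        raise ValueError("pLDDT must lie in [0, 100]")
    if plddt <= 50:
        return "low"
    if plddt <= 70:
        return "moderate"
    if plddt < 90:
        return "confident"
    return "very-high"


def rank_models(table: MultimerMetricsTable) -> tuple[pd.DataFrame, int]:
    """Rank by descending confidence score, ties broken toward lower n
    (parsimony).  Returns (ranked frame with a 'score' column, best n)."""
    df = table.frame.copy()
    df["score"] = IPTM_WEIGHT * df["iptm"] + PTM_WEIGHT * df["ptm"]
    ranked = df.sort_values(
        ["score", "n"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ranked, int(ranked.loc[0, "n"])


def two_round_selection(
    round1: MultimerMetricsTable,
    round2: MultimerMetricsTable,
    declared_round2_range: Optional[Sequence[int]] = None,
) -> TwoRoundReport:
    """Two-round stoichiometry scan: broad scan, then template-seeded rescan.

    Reports the round-1 winner, whether the round-2 scan covers it (a
    template-seeded rescan should), the final winner by round-2 scores, and
    whether the best confidence score improved between rounds.  If a
    declared round-2 range is given, stoichiometries outside it raise a
    warning in the report rather than an error.
    """
    r1_ranked, r1_best = rank_models(round1)
    r2_ranked, r2_best = rank_models(round2)
    warnings: list[str] = []
    r2_ns = set(round2.stoichiometries)
    if declared_round2_range is not None:
        declared = set(int(n) for n in declared_round2_range)
        stray = sorted(r2_ns - declared)
        if stray:
            warnings.append(
                f"round-2 stoichiometries {stray} outside declared range"
            )
    covers = r1_best in r2_ns
    if not covers:
        warnings.append(
            f"round-2 scan does not revisit round-1 best n={r1_best}; "
            "treat round 2 as template-seeded only"
        )
    r1_score = float(r1_ranked.loc[0, "score"])
    r2_score = float(r2_ranked.loc[0, "score"])
    return TwoRoundReport(
        round1_best_n=r1_best,
        round2_covers_round1_best=covers,
        final_best_n=r2_best,
        score_improved=r2_score > r1_score,
        round1_best_score=r1_score,
        round2_best_score=r2_score,
        warnings=tuple(warnings),
    )
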