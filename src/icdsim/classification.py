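"""Dichotomizing continuous similarity scores into similar/discrepant calls.

A cutoff rule turns each numeric score into a binary trigger decision.  For
distance-type measures (steps, weights) a pair is called discrepant when its
score is *larger or equal to* the threshold; for similarity-type measures
(Wu-Palmer, Li et al.) when it is *smaller or equal to* the threshold.  Both
comparisons are non-strict at the cutoff.

Candidate thresholds are the midpoints between consecutive distinct observed
scores, plus one sentinel below the minimum and one above the maximum so the
sweep runs all the way from "nothing is discrepant" to "everything is
discrepant".  :func:`cutoff_for_target` picks from this sweep the threshold
achieving a requested sensitivity or specificity, which is how the trigger
is tailored to its task — high sensitivity for safety review, high
specificity for high-stakes assessment decisions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import Algorithm, Orientation, ORIENTATION
from .taxonomy import TaxonomyError

__all__ = [
    "Direction",
    "CutoffRule",
    "classify",
    "candidate_cutoffs",
    "sweep_cutoffs",
    "cutoff_for_target",
    "cutoff_table",
    "SIMILAR",
    "DISCREPANT",
]

SIMILAR = "similar"
DISCREPANT = "discrepant"
SENTINEL_OFFSET = 1.0  # sentinels sit this far outside the observed range


class Direction(enum.Enum):
    DISCREPANT_IF_GE = "discrepant_if_ge"  # distance orientation
    DISCREPANT_IF_LE = "discrepant_if_le"  # similarity orientation


def direction_for(algorithm: Algorithm) -> Direction:
    """The comparison direction implied by an algorithm's orientation."""
    if ORIENTATION[algorithm] is Orientation.DISTANCE:
        return Direction.DISCREPANT_IF_GE
    return Direction.DISCREPANT_IF_LE


@dataclass(frozen=True)
class CutoffRule:
    """Threshold plus comparison direction for one algorithm."""

    algorithm: Algorithm
    threshold: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction is not direction_for(self.algorithm):
            raise TaxonomyError(
                f"direction {self.direction.value} inconsistent with "
                f"{self.algorithm.value} orientation"
            )

    def is_discrepant(self, score: float | np.ndarray) -> bool | np.ndarray:
        if self.direction is Direction.DISCREPANT_IF_GE:
            return score >= self.threshold
        return score <= self.threshold


def classify(scores: pd.DataFrame, rule: CutoffRule) -> pd.DataFrame:
    """Apply a cutoff rule to a score table.

    Parameters
    ----------
    scores
        Output of :func:`icdsim.similarity.score_pairs` (or any frame with a
        ``pair_id`` column and a numeric column named after the algorithm).

    Returns
    -------
    DataFrame with columns ``pair_id``, ``algorithm``, ``score``, ``call``;
    one call per scored pair (unresolved NaN rows keep a missing call).
    """
    col = rule.algorithm.value
    if col not in scores.columns:
        raise TaxonomyError(f"score table has no column {col!r}")
    vals = scores[col].to_numpy(dtype=float)
    calls = np.where(
        np.isnan(vals), None, np.where(rule.is_discrepant(vals), DISCREPANT, SIMILAR)
    )
    return pd.DataFrame(
        {
            "pair_id": scores["pair_id"].to_numpy(),
            "algorithm": col,
            "score": vals,
            "call": calls,
        }
    )


def candidate_cutoffs(observed: np.ndarray | list[float]) -> np.ndarray:
    """Candidate thresholds from observed scores, ascending.

    Midpoints of consecutive distinct observed values, bracketed by
    sentinels one unit below the minimum and one above the maximum.  Applied
    with either comparison direction, the candidates sweep the calls from
    none-discrepant to all-discrepant.
    """
    vals = np.unique(np.asarray(observed, dtype=float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise TaxonomyError("no observed scores to derive cutoffs from")
    mids = (vals[:-1] + vals[1:]) / 2.0
    return np.concatenate(([vals[0] - SENTINEL_OFFSET], mids, [vals[-1] + SENTINEL_OFFSET]))


def _sens_spec(
    scores: np.ndarray, is_discrepant_truth: np.ndarray, rule: CutoffRule
) -> tuple[float, float]:
    called = np.asarray(rule.is_discrepant(scores))
    n_disc = int(is_discrepant_truth.sum())
    n_sim = int((~is_discrepant_truth).sum())
    sens = float((called & is_discrepant_truth).sum() / n_disc) if n_disc else float("nan")
    spec = float((~called & ~is_discrepant_truth).sum() / n_sim) if n_sim else float("nan")
    return sens, spec


def _as_truth(labels: np.ndarray | pd.Series | list[str]) -> np.ndarray:
    arr = np.asarray(labels)
    truth = arr == DISCREPANT
    if not set(np.unique(arr)) <= {SIMILAR, DISCREPANT}:
        raise TaxonomyError(
            f"labels must be {SIMILAR!r}/{DISCREPANT!r}, got {sorted(set(arr))}"
        )
    return truth


def sweep_cutoffs(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    algorithm: Algorithm,
) -> pd.DataFrame:
    """Sensitivity and specificity at every candidate cutoff.

    Returns one row per candidate threshold with columns ``threshold``,
    ``sensitivity``, ``specificity``, ordered by descending sensitivity —
    the layout of a cutoff-choice table.
    """
    vals = np.asarray(scores, dtype=float)
    truth = _as_truth(labels)
    keep = ~np.isnan(vals)
    vals, truth = vals[keep], truth[keep]
    rows = []
    for t in candidate_cutoffs(vals):
        rule = CutoffRule(algorithm, float(t), direction_for(algorithm))
        sens, spec = _sens_spec(vals, truth, rule)
        rows.append({"threshold": float(t), "sensitivity": sens, "specificity": spec})
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["sensitivity", "specificity"], ascending=[False, True]
    ).reset_index(drop=True)


def cutoff_for_target(
    scores: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    algorithm: Algorithm,
    sensitivity: float | None = None,
    specificity: float | None = None,
) -> tuple[CutoffRule, float, float]:
    """Choose the cutoff achieving a requested sensitivity or specificity.

    Among all candidate cutoffs meeting the bound, the one with the smallest
    sensitivity >= target (resp. smallest specificity >= target) is chosen;
    ties are broken by maximizing the complementary metric, then by
    proximity to the midrange of the observed scores.  Returns the rule and
    the achieved (sensitivity, specificity).
    """
    if (sensitivity is None) == (specificity is None):
        raise TaxonomyError("specify exactly one of sensitivity or specificity")
    vals = np.asarray(scores, dtype=float)
    truth = _as_truth(labels)
    keep = ~np.isnan(vals)
    vals, truth = vals[keep], truth[keep]
    if truth.all() or not truth.any():
        raise TaxonomyError("labels must contain both similar and discrepant pairs")

    table = sweep_cutoffs(vals, np.where(truth, DISCREPANT, SIMILAR), algorithm)
    target_col, other_col = (
        ("sensitivity", "specificity") if sensitivity is not None else ("specificity", "sensitivity")
    )
    bound = sensitivity if sensitivity is not None else specificity
    assert bound is not None
    ok = table[table[target_col] >= bound - 1e-12]
    if ok.empty:  # bound of 1.0 is always attainable via a sentinel, so this
        raise TaxonomyError(f"requested {target_col} {bound} is not attainable")
    best_primary = ok[target_col].min()
    ok = ok[ok[target_col] <= best_primary + 1e-12]
    best_other = ok[other_col].max()
    ok = ok[ok[other_col] >= best_other - 1e-12]
    midrange = (np.nanmin(vals) + np.nanmax(vals)) / 2.0
    chosen = ok.loc[(ok["threshold"] - midrange).abs().idxmin()]
    rule = CutoffRule(algorithm, float(chosen["threshold"]), direction_for(algorithm))
    return rule, float(chosen["sensitivity"]), float(chosen["specificity"])


def cutoff_table(
    scored: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    algorithms: list[Algorithm] | None = None,
) -> pd.DataFrame:
    """Joint cutoff-choice table across algorithms.

    For every (sensitivity, specificity) operating point reached by any
    algorithm's candidate sweep, reports each algorithm's threshold at its
    own operating point of that sensitivity, mirroring the layout of a
    published cutoff-selection table: one row per operating point, one
    threshold column per algorithm (blank where an algorithm never attains
    that sensitivity exactly).
    """
    algorithms = algorithms or list(Algorithm)
    per_alg = {}
    for alg in algorithms:
        sweep = sweep_cutoffs(scored[alg.value], labels, alg)
        # keep one row per distinct sensitivity: the best specificity
        best = (
            sweep.sort_values(["sensitivity", "specificity"], ascending=[False, False])
            .groupby("sensitivity", as_index=False)
            .first()
        )
        per_alg[alg] = best
    all_sens = sorted(
        {round(s, 12) for best in per_alg.values() for s in best["sensitivity"]},
        reverse=True,
    )
    rows = []
    for s in all_sens:
        row: dict[str, float | None] = {"sensitivity": s}
        specs = []
        for alg, best in per_alg.items():
            match = best[np.isclose(best["sensitivity"], s)]
            if match.empty:
                row[alg.value] = None
            else:
                row[alg.value] = float(match["threshold"].iloc[0])
                specs.append(float(match["specificity"].iloc[0]))
        row["specificity"] = max(specs) if specs else float("nan")
        rows.append(row)
    cols = ["sensitivity", "specificity"] + [a.value for a in algorithms]
    return pd.DataFrame(rows)[cols]
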