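"""Validation of the automated trigger against a rater reference standard.

Pairs of diagnoses carry a dichotomous expert rating (similar vs discrepant)
used as reference standard.  Each algorithm's continuous scores are ranked
against that standard:

* empirical ROC curve and area under it (trapezoidal, equal to the
  Mann-Whitney statistic U / (n_D * n_S) with ties given half credit);
* 95% confidence interval for the AUC from the DeLong nonparametric
  variance estimate, with a normal approximation truncated to [0, 1];
* a two-sided z-test of the AUC against 0.5, i.e. against the null that the
  score ranks a random discrepant pair above a random similar pair no
  better than a coin flip;
* dataset summaries (class counts and error prevalence) and Cohen's kappa
  for the agreement of the two coders who assigned ICD codes.

Similarity-type scores (Wu-Palmer, Li et al.) are negated internally before
ranking so that "larger = more discrepant" holds for every algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .classification import DISCREPANT, SIMILAR, _as_truth
from .similarity import Algorithm, Orientation, ORIENTATION
from .taxonomy import TaxonomyError

__all__ = [
    "ROCResult",
    "DatasetSummary",
    "roc_curve",
    "auc_ci",
    "auc_test_vs_half",
    "summarize_dataset",
    "cohen_kappa",
    "validation_report",
]


@dataclass(frozen=True)
class ROCResult:
    algorithm: Algorithm
    fpr: np.ndarray  # 1 - specificity, ascending from 0 to 1
    tpr: np.ndarray  # sensitivity, ascending from 0 to 1
    auc: float
    ci_low: float
    ci_high: float
    p_value_vs_half: float
    n_similar: int
    n_discrepant: int


@dataclass(frozen=True)
class DatasetSummary:
    n_pairs: int
    n_similar: int
    n_discrepant: int
    prevalence_percent: float


def _oriented_scores(scores: np.ndarray, algorithm: Algorithm) -> np.ndarray:
    """Flip similarity-type scores so that larger always means more discrepant."""
    vals = np.asarray(scores, dtype=float)
    if ORIENTATION[algorithm] is Orientation.SIMILARITY:
        vals = -vals
    return vals


def _prepare(labeled: pd.DataFrame, algorithm: Algorithm) -> tuple[np.ndarray, np.ndarray]:
    col = algorithm.value
    if col not in labeled.columns:
        raise TaxonomyError(f"labeled table has no score column {col!r}")
    if "label" not in labeled.columns:
        raise TaxonomyError("labeled table has no 'label' column")
    vals = _oriented_scores(labeled[col].to_numpy(dtype=float), algorithm)
    truth = _as_truth(labeled["label"])
    keep = ~np.isnan(vals)
    vals, truth = vals[keep], truth[keep]
    if truth.all() or not truth.any():
        raise TaxonomyError("both similar and discrepant pairs are required")
    return vals, truth


# ---------------------------------------------------------------------------
# DeLong variance
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from discrepant (pos) and similar (neg) scores.

    Structural-component (placement-value) formulation: V10[i] is the
    fraction of negatives ranked below positive i (ties half), V01[j] the
    fraction of positives ranked above negative j.  The AUC variance is
    var(V10)/m + var(V01)/n with sample variances over m positives and n
    negatives.
    """
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rk_all = _midrank(allv)
    rk_pos = _midrank(pos)
    rk_neg = _midrank(neg)
    # placement values via midranks (Sun & Xu 2014 fast DeLong)
    v10 = (rk_all[:m] - rk_pos) / n
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def roc_curve(
    labeled: pd.DataFrame,
    algorithm: Algorithm,
    ci_level: float = 0.95,
) -> ROCResult:
    """Empirical ROC curve, AUC, DeLong CI and the test against AUC = 0.5.

    Parameters
    ----------
    labeled
        DataFrame with a ``label`` column (``similar``/``discrepant``) and a
        numeric score column named after the algorithm, e.g. the output of
        :func:`icdsim.similarity.score_pairs` on labeled pairs.
    """
    vals, truth = _prepare(labeled, algorithm)
    fpr, tpr, _ = _skm.roc_curve(truth, vals, drop_intermediate=False)
    pos, neg = vals[truth], vals[~truth]
    auc, var = _delong_auc_variance(pos, neg)
    lo, hi = _ci_from_variance(auc, var, ci_level)
    p = _p_from_variance(auc, var)
    return ROCResult(
        algorithm=algorithm,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        p_value_vs_half=p,
        n_similar=len(neg),
        n_discrepant=len(pos),
    )


def _ci_from_variance(auc: float, var: float, level: float) -> tuple[float, float]:
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def _p_from_variance(auc: float, var: float) -> float:
    se = np.sqrt(max(var, 0.0))
    if se == 0.0:
        return 1.0 if auc == 0.5 else 0.0
    z = (auc - 0.5) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def auc_ci(
    labeled: pd.DataFrame, algorithm: Algorithm, level: float = 0.95
) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, truncated to [0, 1]."""
    vals, truth = _prepare(labeled, algorithm)
    if truth.sum() < 2 or (~truth).sum() < 2:
        raise TaxonomyError("need at least two pairs in each class for a CI")
    auc, var = _delong_auc_variance(vals[truth], vals[~truth])
    return _ci_from_variance(auc, var, level)


def auc_test_vs_half(labeled: pd.DataFrame, algorithm: Algorithm) -> float:
    """Two-sided p-value for H0: AUC = 0.5 (the coin-flip null)."""
    vals, truth = _prepare(labeled, algorithm)
    if truth.sum() < 2 or (~truth).sum() < 2:
        raise TaxonomyError("need at least two pairs in each class for the test")
    auc, var = _delong_auc_variance(vals[truth], vals[~truth])
    return _p_from_variance(auc, var)


def summarize_dataset(labeled: pd.DataFrame) -> DatasetSummary:
    """Class counts and error prevalence (percent, 2 decimals, half-up)."""
    if labeled is None or len(labeled) == 0:
        raise TaxonomyError("empty labeled dataset")
    truth = _as_truth(labeled["label"])
    n = len(truth)
    n_disc = int(truth.sum())
    # round half-up at 2 decimals rather than banker's rounding
    prev = float(np.floor(100.0 * n_disc / n * 100.0 + 0.5) / 100.0)
    return DatasetSummary(
        n_pairs=n, n_similar=n - n_disc, n_discrepant=n_disc, prevalence_percent=prev
    )


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa for two raters: (p_o - p_e) / (1 - p_e).

    Raises when chance agreement p_e equals 1 (both raters constant with
    the same category), where kappa is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise TaxonomyError("ratings must be two equal-length vectors of length >= 2")
    cats = np.union1d(a, b)
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        raise TaxonomyError("kappa undefined: both raters are constant with one category")
    if len(cats) > 1:
        return float(_skm.cohen_kappa_score(a, b, labels=cats))
    p_o = float((a == b).mean())
    return (p_o - p_e) / (1.0 - p_e)


def validation_report(
    labeled: pd.DataFrame,
    algorithms: list[Algorithm] | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-algorithm summary: AUC, CI bounds, p-value, class sizes, prevalence."""
    algorithms = algorithms or list(Algorithm)
    summary = summarize_dataset(labeled)
    rows = []
    for alg in algorithms:
        r = roc_curve(labeled, alg, ci_level)
        rows.append(
            {
                "algorithm": alg.value,
                "auc": r.auc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value_vs_half": r.p_value_vs_half,
                "n_pairs": summary.n_pairs,
                "n_similar": summary.n_similar,
                "n_discrepant": summary.n_discrepant,
                "prevalence_percent": summary.prevalence_percent,
            }
        )
    return pd.DataFrame(rows)
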