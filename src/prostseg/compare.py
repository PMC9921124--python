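"""Statistical comparison of segmentation models.

Implements the study's analysis layer: per-model score tables, mean ranks,
worst-case analysis, coefficient of variation, volume-bias testing
(Wilcoxon signed-rank on signed relative volume differences), paired
significance tests against the best model, and clinical-covariate
associations (Kruskal-Wallis for categorical, Spearman for continuous
variables, Dice and MSD only). No multiplicity correction is applied
anywhere — an explicit choice to preserve power in an explorative analysis.

Small-sample p-values are exact (scipy's enumeration); larger samples use
the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ScoreRecord

__all__ = [
    "CohortResults",
    "BiasResult",
    "TestResult",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "spearman",
    "volume_bias",
    "rank_models",
    "coefficient_of_variation",
    "worst_cases",
    "covariate_association",
    "compare_to_best",
]

METRICS = ("dice", "arvd", "msd", "hd95")
HIGHER_IS_BETTER = {"dice": True, "arvd": False, "msd": False, "hd95": False}
CONTINUOUS_COVARIATES = ("age", "prostate_volume_ml", "ipsa")
CATEGORICAL_COVARIATES = ("isup", "ece", "pirads")


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class BiasResult:
    """Mean predicted/true volume ratio and the significance of the signed
    volume error (above one = systematic overestimation)."""

    mean_relative_volume: float
    p_value: float

    def __post_init__(self):
        if self.mean_relative_volume <= 0:
            raise ValueError("mean relative volume must be positive")


class CohortResults:
    """Score table keyed by (patient, model); one record per cell."""

    def __init__(self, records: dict[tuple[str, str], ScoreRecord] | None = None,
                 split_label: str = ""):
        self._records: dict[tuple[str, str], ScoreRecord] = {}
        self.split_label = split_label
        for (pid, model), rec in (records or {}).items():
            self.add(pid, model, rec)

    def add(self, patient_id: str, model: str, record: ScoreRecord) -> None:
        key = (patient_id, model)
        if key in self._records:
            raise ValueError(f"duplicate score record for {key}")
        self._records[key] = record

    @property
    def models(self) -> list[str]:
        return sorted({m for _, m in self._records})

    @property
    def patients(self) -> list[str]:
        return sorted({p for p, _ in self._records})

    def validate_complete(self) -> None:
        missing = [
            (p, m) for p in self.patients for m in self.models
            if (p, m) not in self._records
        ]
        if missing:
            raise ValueError(f"incomplete score table; missing cells: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p, "model": m, "dice": r.dice, "arvd": r.arvd,
             "msd": r.msd, "hd95": r.hd95}
            for (p, m), r in sorted(self._records.items())
        ]
        return pd.DataFrame(rows)

    def scores(self, model: str, metric: str) -> np.ndarray:
        """Per-patient scores for one model, in patient order."""
        return np.array([
            getattr(self._records[(p, model)], metric) for p in self.patients
        ])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, split_label: str = "") -> "CohortResults":
        out = cls(split_label=split_label)
        for _, row in df.iterrows():
            out.add(str(row["patient_id"]), str(row["model"]),
                    ScoreRecord(str(row["patient_id"]), float(row["dice"]),
                                float(row["arvd"]), float(row["msd"]), float(row["hd95"])))
        return out


# ---------------------------------------------------------------------------
# Elementary tests


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Identical pairs everywhere give a degenerate result (p = 1, flagged)
    rather than an exception.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        return TestResult(0.0, 1.0, degenerate=True)
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return TestResult(float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups) -> float:
    """Kruskal-Wallis H-test p-value (tie-corrected) across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    return float(stats.kruskal(*groups).pvalue)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return TestResult(np.nan, np.nan, degenerate=True)
    rho, p = stats.spearmanr(x, y)
    return TestResult(float(rho), float(p))


def volume_bias(pred_volumes, gt_volumes) -> BiasResult:
    """Systematic volume error: mean pred/true ratio plus Wilcoxon p-value
    of the signed volume differences against a zero median."""
    pred = np.asarray(pred_volumes, dtype=float)
    gt = np.asarray(gt_volumes, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("volume vectors must have equal length")
    if np.any(gt <= 0):
        raise ValueError("ground-truth volumes must be positive")
    ratio = float(np.mean(pred / gt))
    res = wilcoxon_signed_rank(pred, gt)
    return BiasResult(mean_relative_volume=ratio, p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# Cohort-level analyses


def rank_models(results: CohortResults) -> pd.Series:
    """Mean rank of each model across the four metrics (1 = best).

    Per metric, model mean scores are ranked (Dice descending, the error
    metrics ascending) with midranks for ties, then averaged over metrics.
    """
    results.validate_complete()
    models = results.models
    ranks = np.zeros(len(models))
    for metric in METRICS:
        means = np.array([results.scores(m, metric).mean() for m in models])
        keyed = -means if HIGHER_IS_BETTER[metric] else means
        ranks += stats.rankdata(keyed)
    return pd.Series(ranks / len(METRICS), index=models, name="mean_rank")


def coefficient_of_variation(scores) -> float:
    """Sample standard deviation divided by the mean."""
    x = np.asarray(scores, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return float(sd / mean)


def worst_cases(results: CohortResults, metric: str, k: int) -> pd.DataFrame:
    """The k worst patients per model (min Dice; max ARVD/MSD/HD95)."""
    results.validate_complete()
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(results.patients)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    rows = []
    for model in results.models:
        vals = results.scores(model, metric)
        order = np.argsort(vals if HIGHER_IS_BETTER[metric] else -vals, kind="stable")
        for rank, i in enumerate(order[:k], start=1):
            rows.append({"model": model, "rank": rank,
                         "patient_id": results.patients[i], metric: vals[i]})
    return pd.DataFrame(rows)


def compare_to_best(results: CohortResults, metric: str) -> pd.DataFrame:
    """Wilcoxon signed-rank of every model against the best mean performer."""
    results.validate_complete()
    models = results.models
    means = {m: results.scores(m, metric).mean() for m in models}
    best = (max if HIGHER_IS_BETTER[metric] else min)(means, key=means.get)
    rows = []
    for m in models:
        if m == best:
            continue
        res = wilcoxon_signed_rank(results.scores(best, metric), results.scores(m, metric))
        rows.append({"model": m, "best_model": best, "metric": metric,
                     "statistic": res.statistic, "p_value": res.pvalue,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def merge_sparse_categories(values, min_count: int = 3) -> np.ndarray:
    """Merge ordinal categories with fewer than ``min_count`` members into
    their nearest neighbouring category (ties toward the lower one)."""
    vals = np.asarray(values)
    out = vals.astype(float).copy()
    while True:
        cats, counts = np.unique(out, return_counts=True)
        if len(cats) < 2:
            break
        sparse = [c for c, n in zip(cats, counts) if n < min_count]
        if not sparse:
            break
        c = sparse[0]
        others = cats[cats != c]
        dist = np.abs(others - c)
        target = others[np.lexsort((others, dist))][0]
        out[out == c] = target
    return out


def covariate_association(
    results: CohortResults,
    covariates: pd.DataFrame,
    metrics: tuple[str, ...] = ("dice", "msd"),
) -> pd.DataFrame:
    """Associations between clinical covariates and per-patient scores.

    Kruskal-Wallis for the categorical covariates (after sparse-category
    merging), Spearman for the continuous ones; Dice and MSD only, per
    model, without multiplicity correction.
    """
    results.validate_complete()
    cov = covariates.set_index("patient_id") if "patient_id" in covariates else covariates
    missing = [p for p in results.patients if p not in cov.index]
    if missing:
        raise ValueError(f"covariates missing for patients: {missing}")
    cov = cov.loc[results.patients]
    rows = []
    for model in results.models:
        for metric in metrics:
            y = results.scores(model, metric)
            for var in CONTINUOUS_COVARIATES:
                if var not in cov:
                    continue
                res = spearman(cov[var].to_numpy(dtype=float), y)
                rows.append({"model": model, "metric": metric, "covariate": var,
                             "test": "spearman", "statistic": res.statistic,
                             "p_value": res.pvalue})
            for var in CATEGORICAL_COVARIATES:
                if var not in cov:
                    continue
                merged = merge_sparse_categories(cov[var].to_numpy())
                groups = [y[merged == c] for c in np.unique(merged)]
                if len(groups) < 2 or np.ptp(y) == 0:
                    p = np.nan  # a single category or constant scores
                else:
                    p = kruskal_wallis(groups)
                rows.append({"model": model, "metric": metric, "covariate": var,
                             "test": "kruskal", "statistic": np.nan, "p_value": p})
    return pd.DataFrame(rows)
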