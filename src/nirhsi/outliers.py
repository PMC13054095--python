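"""Consensus outlier detection on sample-level global features.

Five complementary detectors vote per sample — Z-score, Tukey-fence IQR,
chi-square-thresholded Mahalanobis distance in a PCA-reduced space,
Isolation Forest, and Local Outlier Factor. Votes are combined into
consensus categories: flagged by >= 3 methods = "strong" (removed from
analysis), exactly 2 = "moderate" (kept, reported for manual review),
<= 1 = "normal".

Defaults are chosen so each detector flags roughly 10% of a cohort,
keeping the 3-of-5 consensus selective; every threshold and seed is
echoed into :class:`OutlierReport.method_params`.

With 4*d features and only tens of samples the raw covariance is
singular, so the Mahalanobis detector always works in a PCA-reduced space
with Ledoit-Wolf shrinkage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf, MinCovDet
from sklearn.decomposition import PCA
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor

from .errors import (
    ConfigError,
    DegenerateCovarianceError,
    EmptyInputError,
    IdMismatchError,
)

__all__ = [
    "OutlierReport",
    "standardize_features",
    "zscore_flags",
    "iqr_flags",
    "mahalanobis_flags",
    "isolation_forest_flags",
    "lof_flags",
    "consensus",
    "detect_outliers",
    "remove_strong",
]

METHODS = ("zscore", "iqr", "mahalanobis", "isolation_forest", "lof")
CATEGORIES = ("normal", "moderate", "strong")


@dataclass
class OutlierReport:
    """Per-sample vote matrix and consensus categories."""

    sample_ids: list[str]
    votes: pd.DataFrame  # n x 5 boolean, columns = METHODS
    vote_count: pd.Series
    category: pd.Series  # {normal, moderate, strong}
    method_params: dict

    @property
    def strong_ids(self) -> list[str]:
        return list(self.category.index[self.category == "strong"])

    @property
    def moderate_ids(self) -> list[str]:
        return list(self.category.index[self.category == "moderate"])

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "votes": {m: self.votes[m].astype(bool).tolist() for m in METHODS},
            "vote_count": self.vote_count.astype(int).tolist(),
            "category": self.category.tolist(),
            "strong_ids": self.strong_ids,
            "moderate_ids": self.moderate_ids,
            "method_params": self.method_params,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def standardize_features(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Column-wise z-scoring (population SD).

    Returns (standardized table, means, SDs, zero-variance column names);
    zero-variance columns pass through as zeros.
    """
    if len(table) < 3:
        raise EmptyInputError("standardization needs >= 3 samples")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=0)
    zero_var = list(table.columns[sds == 0])
    safe = sds.replace(0, 1.0)
    z = (table - means) / safe
    z[zero_var] = 0.0
    return z, means, sds, zero_var


def zscore_flags(z_table: pd.DataFrame, z_max: float = 3.0) -> pd.Series:
    """Flag samples whose largest |z| over features exceeds ``z_max``."""
    return (z_table.abs().max(axis=1) > z_max).rename("zscore")


def iqr_flags(
    table: pd.DataFrame, fence_k: float = 1.5, feature_fraction: float = 0.10
) -> pd.Series:
    """Tukey fences per feature; flag samples with too many features outside.

    A sample is flagged iff the fraction of its features falling outside
    [q25 - k*IQR, q75 + k*IQR] exceeds ``feature_fraction``.
    """
    if len(table) < 4:
        raise EmptyInputError("IQR fences need >= 4 samples")
    q25 = table.quantile(0.25, interpolation="linear")
    q75 = table.quantile(0.75, interpolation="linear")
    iqr = q75 - q25
    lo = q25 - fence_k * iqr
    hi = q75 + fence_k * iqr
    outside = (table.lt(lo, axis=1) | table.gt(hi, axis=1)).mean(axis=1)
    return (outside > feature_fraction).rename("iqr")


#: fixed shrinkage intensity toward the spherical target
MAHALANOBIS_SHRINKAGE = 0.1


def mahalanobis_estimates(
    table: pd.DataFrame, n_components: int | None = None, robust: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """PCA scores plus the location/covariance the distances are built on.

    Features are projected to ``q = min(n_components, n - 2, 10)``
    principal directions. The center and scatter are estimated robustly
    (minimum covariance determinant) so that a block of gross outliers
    cannot mask itself by inflating the covariance; the scatter is then
    shrunk toward its spherical target, ``(1 - s) * Sigma + s *
    (tr(Sigma)/q) * I``, for numerical regularity. ``robust=False``
    substitutes the Ledoit-Wolf shrinkage estimate (location = mean).
    """
    n = len(table)
    if n < 5:
        raise EmptyInputError("Mahalanobis detector needs >= 5 samples")
    q = min(n_components or 10, n - 2, 10, table.shape[1])
    scores = PCA(n_components=q, random_state=0).fit_transform(table.to_numpy())
    if robust:
        est = MinCovDet(random_state=0).fit(scores)
        loc, cov = est.location_, est.covariance_
        cov = (1 - MAHALANOBIS_SHRINKAGE) * cov + MAHALANOBIS_SHRINKAGE * (
            np.trace(cov) / q
        ) * np.eye(q)
    else:
        est = LedoitWolf().fit(scores)
        loc, cov = est.location_, est.covariance_
    return scores, loc, cov, q


def mahalanobis_flags(
    table: pd.DataFrame,
    alpha: float = 0.001,
    n_components: int | None = None,
    robust: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Chi-square-thresholded Mahalanobis distance in PCA-reduced space.

    Squared distances ``(x - mu)^T Sigma^-1 (x - mu)`` under the
    shrinkage-regularized (robust by default) covariance from
    :func:`mahalanobis_estimates` are flagged when they exceed the
    chi-square ``1 - alpha`` quantile with q degrees of freedom.
    """
    scores, loc, cov, q = mahalanobis_estimates(table, n_components, robust)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateCovarianceError(str(exc)) from exc
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateCovarianceError(f"covariance condition number {cond:.3g}")
    centered = scores - loc
    d2 = np.einsum("ij,jk,ik->i", centered, prec, centered)
    cutoff = stats.chi2.ppf(1 - alpha, df=q)
    flags = pd.Series(d2 > cutoff, index=table.index, name="mahalanobis")
    return flags, pd.Series(d2, index=table.index, name="mahalanobis_d2")


def _rank_flags(scores: np.ndarray, k: int, index) -> np.ndarray:
    """Flag the k samples with the highest scores; ties broken by index order."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    flags = np.zeros(len(scores), dtype=bool)
    flags[order[:k]] = True
    return flags


def isolation_forest_flags(
    table: pd.DataFrame,
    contamination: float = 0.1,
    n_trees: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Isolation Forest: flag the round(contamination * n) most anomalous."""
    n = len(table)
    if n < 8:
        raise EmptyInputError("Isolation Forest needs >= 8 samples")
    model = IsolationForest(
        n_estimators=n_trees, contamination=contamination, random_state=seed
    ).fit(table.to_numpy())
    anomaly = -model.score_samples(table.to_numpy())  # higher = more anomalous
    k = int(round(contamination * n))
    return pd.Series(
        _rank_flags(anomaly, k, table.index), index=table.index, name="isolation_forest"
    )


def lof_flags(
    table: pd.DataFrame, n_neighbors: int = 20, contamination: float = 0.1
) -> pd.Series:
    """Local Outlier Factor: flag the round(contamination * n) highest LOF."""
    n = len(table)
    if n < 5:
        raise EmptyInputError("LOF needs >= 5 samples")
    k_nn = min(n_neighbors, n - 1)
    model = LocalOutlierFactor(n_neighbors=k_nn, contamination=contamination)
    model.fit(table.to_numpy())
    lof = -model.negative_outlier_factor_  # higher = more outlying
    k = int(round(contamination * n))
    return pd.Series(_rank_flags(lof, k, table.index), index=table.index, name="lof")


def consensus(votes: pd.DataFrame, method_params: dict | None = None) -> OutlierReport:
    """Combine the five vote columns into consensus categories.

    strong <=> >= 3 votes; moderate <=> exactly 2; normal <=> <= 1.
    """
    if tuple(votes.columns) != METHODS:
        raise ConfigError(
            f"vote matrix must have columns {METHODS}, got {tuple(votes.columns)}"
        )
    count = votes.sum(axis=1).astype(int)
    category = pd.Series(
        np.select([count >= 3, count == 2], ["strong", "moderate"], default="normal"),
        index=votes.index,
        name="category",
    )
    return OutlierReport(
        sample_ids=list(votes.index),
        votes=votes.astype(bool),
        vote_count=count.rename("vote_count"),
        category=category,
        method_params=method_params or {},
    )


def detect_outliers(
    table: pd.DataFrame,
    z_max: float = 3.0,
    fence_k: float = 1.5,
    feature_fraction: float = 0.10,
    alpha: float = 0.001,
    contamination: float = 0.1,
    n_neighbors: int = 20,
    seed: int = 0,
) -> OutlierReport:
    """Run all five detectors on a global-feature table and build the report.

    The Z-score detector sees the standardized table; IQR, Isolation
    Forest and LOF see raw features (they are scale-equivariant or
    fence-based); Mahalanobis standardizes internally via PCA.
    """
    z, _, _, zero_var = standardize_features(table)
    votes = pd.concat(
        [
            zscore_flags(z, z_max=z_max),
            iqr_flags(table, fence_k=fence_k, feature_fraction=feature_fraction),
            mahalanobis_flags(z, alpha=alpha)[0],
            isolation_forest_flags(z, contamination=contamination, seed=seed),
            lof_flags(z, n_neighbors=n_neighbors, contamination=contamination),
        ],
        axis=1,
    )
    params = {
        "z_max": z_max,
        "fence_k": fence_k,
        "feature_fraction": feature_fraction,
        "alpha": alpha,
        "contamination": contamination,
        "n_neighbors": n_neighbors,
        "seed": seed,
        "zero_variance_columns": zero_var,
    }
    return consensus(votes, method_params=params)


def remove_strong(cohort: list, report: OutlierReport) -> list:
    """Drop strong-consensus outliers from a cohort, preserving order.

    ``cohort`` items must expose ``sample_id``; every cohort id must be
    covered by the report.
    """
    covered = set(report.sample_ids)
    missing = [c.sample_id for c in cohort if c.sample_id not in covered]
    if missing:
        raise IdMismatchError(f"report does not cover ids: {missing}")
    strong = set(report.strong_ids)
    return [c for c in cohort if c.sample_id not in strong]
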