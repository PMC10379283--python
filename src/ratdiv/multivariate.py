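"""Descriptive statistics of the analysis table.

Four views of one species' complete-case table: Pearson screening of each
predictor against Ho, a standardized PCA over Ho plus the predictors,
Ward-linkage hierarchical clustering on the retained principal-component
scores (HCPC), and a Wilcoxon rank-sum comparison of island versus mainland
Ho.  These describe the data; inference about predictor importance is left
to the random-forest module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .grid import PREDICTORS, AnalysisTable


@dataclass
class CorrelationReport:
    """Pearson r of each predictor against Ho with two-sided t-test p-values."""

    table: pd.DataFrame  # index: predictor; columns: r, p, n

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass
class PcaResult:
    loadings: pd.DataFrame      # variable x component
    scores: np.ndarray          # observation x component
    explained: np.ndarray       # variance fraction per component, sums to 1
    variables: list[str]
    means: np.ndarray
    sds: np.ndarray


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    linkage_heights: np.ndarray
    n_components_used: int


def correlation_screen(table: AnalysisTable) -> CorrelationReport:
    """Pearson correlation of each predictor with Ho.

    A constant predictor column yields NaN r/p with a warning rather than a
    crash.  Requires at least three rows.
    """
    if table.n < 3:
        raise ValueError("need at least 3 rows for correlation screening")
    ho = table.ho
    rows = []
    for name in PREDICTORS:
        x = table.data[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(ho) == 0:
            warnings.warn(f"constant column; correlation undefined for {name}")
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, ho)
        rows.append({"predictor": name, "r": r, "p": p, "n": table.n})
    return CorrelationReport(table=pd.DataFrame(rows).set_index("predictor"))


def run_pca(table: AnalysisTable, include_ho: bool = True) -> PcaResult:
    """Standardized PCA over the predictors (and Ho, by default).

    Variables are centred and scaled to unit variance (population sd) before
    the decomposition, matching the correlation-matrix PCA convention.
    Loadings are orthonormal; explained fractions sum to 1 over all
    components.  Setting ``include_ho=False`` demotes Ho to a supplementary
    variable excluded from the decomposition.
    """
    variables = (["ho"] if include_ho else []) + list(PREDICTORS)
    X = table.data[variables].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [v for v, s in zip(variables, sds) if s == 0]
        raise ValueError(f"constant variables cannot be standardized: {bad}")
    Z = (X - means) / sds
    # SVD of the standardized matrix: right singular vectors are the loadings
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    var = S**2
    explained = var / var.sum()
    scores = U * S
    loadings = pd.DataFrame(
        Vt.T, index=variables,
        columns=[f"PC{i + 1}" for i in range(len(S))],
    )
    return PcaResult(loadings=loadings, scores=scores, explained=explained,
                     variables=variables, means=means, sds=sds)


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def hcpc(pca: PcaResult, k: Optional[int] = None, k_max: int = 10) -> ClusterAssignment:
    """Hierarchical clustering (Ward linkage) on retained PCA scores.

    Components with explained variance >= 1/p (the Kaiser-like rule on
    standardized data) are retained; at least one is always kept.  When
    ``k`` is not given, the cut is chosen over 2..k_max at the largest
    relative drop of within-cluster inertia between successive partitions
    (the elbow of the inertia curve).
    """
    n = pca.scores.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to cluster")
    p = len(pca.variables)
    retained = max(1, int(np.sum(pca.explained >= 1.0 / p)))
    scores = pca.scores[:, :retained]
    Z = linkage(scores, method="ward")
    heights = Z[:, 2].copy()
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError("k must be in 1..n")
        labels = (np.arange(n) + 1 if k == n
                  else fcluster(Z, t=k, criterion="maxclust"))
        return ClusterAssignment(labels=np.asarray(labels), k=k,
                                 linkage_heights=heights,
                                 n_components_used=retained)
    upper = min(k_max, n - 1)
    inertia = {kk: _within_inertia(scores, fcluster(Z, t=kk, criterion="maxclust"))
               for kk in range(1, upper + 2)}
    # gain(k): inertia explained by splitting k-1 -> k clusters; pick the k
    # whose gain dwarfs the next one (largest gain ratio)
    eps = 1e-12
    best_k, best_ratio = 2, -np.inf
    for kk in range(2, upper + 1):
        gain = inertia[kk - 1] - inertia[kk]
        nxt = inertia[kk] - inertia[kk + 1]
        ratio = gain / max(nxt, eps)
        if ratio > best_ratio:
            best_k, best_ratio = kk, ratio
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    return ClusterAssignment(labels=np.asarray(labels), k=best_k,
                             linkage_heights=heights,
                             n_components_used=retained)


def island_mainland_test(table: AnalysisTable) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) of island vs mainland Ho.

    Uses exact null enumeration when both groups have <= 10 records and the
    pooled values are tie-free; otherwise the normal approximation with tie
    correction.  Returns (U statistic, p).
    """
    ins = table.meta["insularity"].to_numpy()
    island = table.ho[ins == "island"]
    mainland = table.ho[ins == "mainland"]
    for name, grp in (("island", island), ("mainland", mainland)):
        if grp.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate([island, mainland])
    if np.ptp(pooled) == 0:  # all values identical: no evidence either way
        return float(island.size * mainland.size / 2), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (island.size <= 10 and mainland.size <= 10 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(island, mainland, alternative="two-sided",
                             method=method)
    return float(res.statistic), float(res.pvalue)
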