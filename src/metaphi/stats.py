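"""Multivariate analyses of expression matrices.

Rows of a Phi_bin matrix (functions with per-bin profiles) or its
transpose (bins with per-function profiles) are treated as observations:
k-means with an SSE-breakpoint choice of k, PCA with a fixed sign
convention, shrinkage LDA for class separation, and Welch's t-test for
per-function two-group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from metaphi.model import QuantMatrix

log = logging.getLogger(__name__)

MatrixLike = Union[QuantMatrix, pd.DataFrame]


def _frame(m: MatrixLike) -> pd.DataFrame:
    return m.data if isinstance(m, QuantMatrix) else m


@dataclass
class ClusterResult:
    """k-means outcome across a range of k, with the SSE-breakpoint k."""

    k: int
    labels: dict[str, int]
    sse_curve: dict[int, float]
    elbow_k: int


def kmeans_sse(
    m: MatrixLike,
    k_range: Sequence[int] = range(1, 7),
    restarts: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """Best-of-restarts k-means over ``k_range`` with breakpoint detection.

    The SSE (within-cluster sum of squared errors) curve is non-increasing
    in k; the breakpoint is the k maximizing the second difference
    SSE(k-1) - 2 SSE(k) + SSE(k+1), i.e. the sharpest bend in the curve.
    The full curve is returned so the choice can be inspected.
    """
    df = _frame(m)
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must span at least 3 values to locate a breakpoint")
    if max(ks) > len(df):
        raise ValueError(f"k_range max {max(ks)} exceeds the {len(df)} rows available")
    X = df.to_numpy(dtype=float)
    sse: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        km.fit(X)
        sse[k] = float(km.inertia_)
        models[k] = km
    curvature = {
        ks[i]: sse[ks[i - 1]] - 2 * sse[ks[i]] + sse[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    elbow_k = max(curvature, key=lambda k: (curvature[k], -k))
    labels = {row: int(lab) for row, lab in zip(df.index, models[elbow_k].labels_)}
    return ClusterResult(k=elbow_k, labels=labels, sse_curve=sse, elbow_k=elbow_k)


def pca(
    m: MatrixLike, n_components: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal component analysis of rows as observations.

    Columns are mean-centered (not scaled). Returns (scores, loadings,
    variance fractions); for reproducible axes each component's sign is
    fixed so its largest-magnitude loading is positive.
    """
    df = _frame(m)
    if len(df) < 2:
        raise ValueError("PCA needs at least 2 observations (rows)")
    model = PCA(n_components=n_components)
    scores = model.fit_transform(df.to_numpy(dtype=float))
    loadings = model.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    pcs = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    return (
        pd.DataFrame(scores, index=df.index, columns=pcs),
        pd.DataFrame(loadings, index=pcs, columns=df.columns),
        model.explained_variance_ratio_.copy(),
    )


def lda(
    m: MatrixLike, labels: Mapping[str, str], shrinkage: Union[str, float, None] = "auto"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Shrinkage linear discriminant analysis of rows as observations.

    ``labels`` maps row key -> class. Returns (discriminant scores,
    separation fractions), the latter being each discriminant's share of
    the between-class variance (they sum to 1, and there are at most
    n_classes - 1 of them). Within-class scatter is regularized by
    Ledoit-Wolf shrinkage, required when features outnumber observations
    (e.g. 141 Functional Groups vs a dozen bins per ecotype).
    """
    df = _frame(m)
    missing = [r for r in df.index if r not in labels]
    if missing:
        raise ValueError(f"rows without class labels: {missing[:5]}")
    y = np.array([labels[r] for r in df.index])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(
            f"class(es) {list(small)} have a single observation; "
            "pool them with a neighboring class or drop them"
        )
    model = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
    scores = model.fit_transform(df.to_numpy(dtype=float), y)
    fractions = model.explained_variance_ratio_[: scores.shape[1]].copy()
    fractions = fractions / fractions.sum()
    cols = [f"LD{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=df.index, columns=cols), fractions


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, Welch-Satterthwaite df, p). Requires two observations per
    group and nonzero variance in at least one group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t-test needs >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_tests(
    m: MatrixLike,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr_column: bool = True,
) -> pd.DataFrame:
    """Per-row Welch's t-tests between two column groups.

    Rows with zero variance in both groups and equal means are reported
    with t = 0, p = 1. P-values are reported raw, matching the published
    convention; the optional ``p_bh`` column adds Benjamini-Hochberg
    adjusted values as a clearly labeled extension.
    """
    df = _frame(m)
    rows = []
    for fn in df.index:
        x = df.loc[fn, list(group_a)].to_numpy(dtype=float)
        y = df.loc[fn, list(group_b)].to_numpy(dtype=float)
        try:
            t, dof, p = welch_t(x, y)
        except ValueError:
            t, dof, p = np.nan, np.nan, np.nan
        rows.append({"function": fn, "mean_a": x.mean(), "mean_b": y.mean(),
                     "t": t, "df": dof, "p": p})
    out = pd.DataFrame(rows).set_index("function")
    if fdr_column:
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = sps.false_discovery_control(out.loc[mask, "p"], method="bh")
        out["p_bh"] = adj
    return out
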