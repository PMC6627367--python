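"""Two-group comparison stack for lipidomic feature matrices.

The matrix convention throughout is species (rows) x samples (columns), the
shape the quantification step produces.  The stack mirrors standard
metabolomics practice: a generalized-log transform stabilises the variance
of percent-scale abundances, autoscaling gives low- and high-abundance
species equal weight, PCA explores group structure, an exact Mann-Whitney U
test with Benjamini-Hochberg control flags differential species, and
two-way Ward clustering drives the heatmap export.

glog: g(x) = log2((x + sqrt(x^2 + lambda)) / 2), defined at zero and
asymptotically log2(x).  With six samples per group, the exact U null
distribution (924 arrangements) is enumerable, so exact p-values are the
default at small n; mid-ranks with the normal tie correction are the
fallback when ties occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "glog",
    "autoscale",
    "TransformedMatrix",
    "pca",
    "PcaResult",
    "mwu_bh",
    "cluster_heatmap",
    "ClusterResult",
]

DEFAULT_GLOG_LAMBDA = 1.0


@dataclass
class TransformedMatrix:
    """A species x samples matrix after glog and/or autoscaling."""

    data: pd.DataFrame
    glog_lambda: float | None = None
    autoscaled: bool = False
    row_means: pd.Series | None = None
    row_sds: pd.Series | None = None
    dropped: list[str] = field(default_factory=list)


def glog(
    matrix: pd.DataFrame | np.ndarray,
    lam: float = DEFAULT_GLOG_LAMBDA,
    base: float = 2.0,
) -> TransformedMatrix:
    """Generalized logarithm, elementwise.

    ``g(x) = log_base((x + sqrt(x^2 + lam)) / 2)``; strictly increasing,
    finite at zero (g(0) = log(sqrt(lam)/2), exactly 0 at lam = 4) and
    asymptotically log(x) for x >> sqrt(lam).
    """
    if lam <= 0:
        raise ValueError("glog lambda must be positive")
    df = pd.DataFrame(matrix).astype(float)
    if (df.values < 0).any():
        raise ValueError("glog input must be non-negative")
    arr = df.values
    out = np.log((arr + np.sqrt(arr**2 + lam)) / 2.0) / np.log(base)
    return TransformedMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns), glog_lambda=lam
    )


def autoscale(matrix: pd.DataFrame | TransformedMatrix) -> TransformedMatrix:
    """Per-species (row) mean-centering and unit-variance scaling.

    Zero-variance species carry no contrast and are dropped with a warning;
    their labels are recorded on the result.
    """
    lam = None
    if isinstance(matrix, TransformedMatrix):
        lam = matrix.glog_lambda
        matrix = matrix.data
    df = pd.DataFrame(matrix).astype(float)
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    dropped = list(df.index[sds == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance species: {dropped[:5]}...",
            stacklevel=2,
        )
    keep = df.index[sds > 0]
    scaled = df.loc[keep].sub(means.loc[keep], axis=0).div(sds.loc[keep], axis=0)
    return TransformedMatrix(
        scaled,
        glog_lambda=lam,
        autoscaled=True,
        row_means=means.loc[keep],
        row_sds=sds.loc[keep],
        dropped=dropped,
    )


@dataclass
class PcaResult:
    """Scores (samples x PCs), loadings (species x PCs), variance shares."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_percent: np.ndarray
    column_means: pd.Series  # per-species mean removed before the SVD


def pca(matrix: pd.DataFrame | TransformedMatrix) -> PcaResult:
    """PCA of samples over species via SVD of the centered data.

    Input is species x samples; samples are the observations.  Deterministic
    sign convention: each component's largest-magnitude loading is positive.
    """
    if isinstance(matrix, TransformedMatrix):
        matrix = matrix.data
    df = pd.DataFrame(matrix).astype(float)
    X = df.T.values  # samples x species
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    means = X.mean(axis=0)
    Xc = X - means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign fix: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var = S**2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else var
    ncomp = len(S)
    pcs = [f"PC{i + 1}" for i in range(ncomp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=df.index, columns=pcs),
        explained_variance_percent=explained,
        column_means=pd.Series(means, index=df.index),
    )


def _exact_feasible(x: np.ndarray, y: np.ndarray, max_n: int = 8) -> bool:
    if len(x) > max_n or len(y) > max_n:
        return False
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) == len(pooled)  # no ties


def mwu_bh(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species two-sided Mann-Whitney U with BH step-up q-values.

    ``groups`` maps sample id -> one of exactly two labels, each with
    n >= 3.  The exact permutation null is used whenever both groups have
    n <= 8 and the pooled values are tie-free; otherwise the normal
    approximation with the mid-rank tie correction.  Significance flags
    ``sig_05``/``sig_01`` mark q < 0.05 and q < 0.01 (the conventional
    * and **).  Direction is the sign of (median first group - median
    second group), labels in sorted order.
    """
    groups = groups.loc[matrix.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga, gb = labels
    cols_a = groups.index[groups == ga]
    cols_b = groups.index[groups == gb]
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    records = []
    for label, row in matrix.iterrows():
        x = row[cols_a].to_numpy(dtype=float)
        y = row[cols_b].to_numpy(dtype=float)
        method = "exact" if _exact_feasible(x, y) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        med_a, med_b = float(np.median(x)), float(np.median(y))
        records.append(
            {
                "species": label,
                "U": float(res.statistic),
                "p": float(min(res.pvalue, 1.0)),
                f"median_{ga}": med_a,
                f"median_{gb}": med_b,
                "direction": int(np.sign(med_a - med_b)),
                "method": method,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("species")
    _, q, _, _ = multipletests(table["p"].values, method="fdr_bh")
    table["q"] = q
    table["sig_05"] = table["q"] < 0.05
    table["sig_01"] = table["q"] < 0.01
    return table


@dataclass
class ClusterResult:
    """Two-way hierarchical clustering plus the heatmap export matrix."""

    sample_linkage: np.ndarray
    species_linkage: np.ndarray
    heatmap: pd.DataFrame  # difference from the per-species mean
    species: list[str]
    samples: list[str]
    method: str


def _ward_linkage(X: np.ndarray, convention: str) -> np.ndarray:
    """Ward linkage under either distance convention.

    ``"ward.D"`` applies the Ward update to unsquared Euclidean distances
    (the historical convention of hclust); ``"ward.D2"`` to squared ones
    (scipy's native 'ward').  scipy internally squares the supplied
    condensed distances and reports sqrt of the criterion, so ward.D is
    obtained by feeding sqrt(d) and squaring the resulting heights.
    """
    d = pdist(X, metric="euclidean")
    if convention == "ward.D2":
        return sch.linkage(d, method="ward")
    if convention == "ward.D":
        Z = sch.linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z
    raise ValueError(f"unknown Ward convention {convention!r}")


def cluster_heatmap(
    matrix: pd.DataFrame,
    top_k: int | None = None,
    q_values: pd.Series | None = None,
    convention: str = "ward.D",
) -> ClusterResult:
    """Two-way Euclidean/Ward clustering with a fold-difference heatmap.

    ``matrix`` is species x samples on the transformed scale.  With
    ``top_k`` and ``q_values`` given, only the k smallest-q species are
    clustered (the "top 25" style display).  The heatmap matrix holds each
    value's difference from the species mean — the fold difference from the
    mean when the input is log-scale.
    """
    df = pd.DataFrame(matrix).astype(float)
    if top_k is not None:
        if q_values is None:
            raise ValueError("top_k selection needs q_values")
        chosen = q_values.loc[df.index].nsmallest(top_k).index
        df = df.loc[chosen]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("clustering needs >= 2 species and >= 2 samples")
    centered = df.sub(df.mean(axis=1), axis=0)
    return ClusterResult(
        sample_linkage=_ward_linkage(centered.T.values, convention),
        species_linkage=_ward_linkage(centered.values, convention),
        heatmap=centered,
        species=list(df.index),
        samples=list(df.columns),
        method=convention,
    )
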