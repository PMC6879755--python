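"""Cohort application of the cell-of-origin score.

Rank-sum comparison of the score between transcriptional subtypes,
Pearson-correlation ranking of pathway-activity (IPL) features against the
score, and Euclidean sample-distance hierarchical clustering.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from skbio.tree import TreeNode

from .datatypes import ValidationError

#: Sample-size bound below which the exact rank-sum null is enumerated.
EXACT_LIMIT = 12


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) with a two-sided p-value.

    ``method="auto"`` enumerates the exact null when ``n + m <= EXACT_LIMIT``
    and the pooled data are tie-free, otherwise uses the normal approximation
    with midranks, tie correction, and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    if np.unique(pooled).size == 1:
        # all observations identical: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    if method == "exact" and has_ties:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class SubtypeContrast:
    """One rank-sum contrast between two subtype groups."""

    group_high: str
    group_low: str
    n_high: int
    n_low: int
    u_statistic: float
    pvalue: float
    median_difference: float  # median(high) - median(low)

    @property
    def direction(self) -> int:
        return int(np.sign(self.median_difference))


def compare_subtypes(
    scores: pd.Series,
    subtypes: pd.Series,
    contrasts: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Rank-sum tests of the score between subtype pairs.

    ``scores`` is per-sample (e.g. ft_minus_o); each contrast is an ordered
    pair whose first label is reported as the putatively higher-scoring
    group; the sign of the median difference gives the observed direction.
    """
    known = set(subtypes.unique())
    rows = []
    for high, low in contrasts:
        for label in (high, low):
            if label not in known:
                raise ValidationError(f"unknown subtype label {label!r}")
        x = scores.loc[subtypes.index[subtypes == high]]
        y = scores.loc[subtypes.index[subtypes == low]]
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(
                f"contrast {high} vs {low}: both subtypes need >= 2 samples"
            )
        u, p = wilcoxon_rank_sum(x.to_numpy(), y.to_numpy())
        rows.append(
            SubtypeContrast(
                group_high=high,
                group_low=low,
                n_high=len(x),
                n_low=len(y),
                u_statistic=u,
                pvalue=p,
                median_difference=float(x.median() - y.median()),
            )
        )
    return pd.DataFrame(
        [
            {
                "group_high": c.group_high,
                "group_low": c.group_low,
                "n_high": c.n_high,
                "n_low": c.n_low,
                "U": c.u_statistic,
                "pvalue": c.pvalue,
                "median_difference": c.median_difference,
                "direction": c.direction,
            }
            for c in rows
        ]
    )


def correlate_ipl(
    ipl: pd.DataFrame, scores: pd.Series, top_n: int = 50
) -> pd.DataFrame:
    """Rank pathway features by |Pearson r| against the combined score.

    Returns the top_n features with columns feature, pearson_r (signed),
    rank, n; constant features are excluded and listed in
    ``result.attrs["constant_features"]``. Ties in |r| break by feature name.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    shared = [s for s in ipl.columns if s in scores.index]
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 3")
    mat = ipl[shared].to_numpy(dtype=float)
    vec = scores.loc[shared].to_numpy(dtype=float)
    constant = mat.std(axis=1) == 0
    if constant.all():
        raise ValidationError("all IPL features are constant")
    if vec.std() == 0:
        raise ValidationError("score vector is constant")

    centred = mat[~constant] - mat[~constant].mean(axis=1, keepdims=True)
    v = vec - vec.mean()
    r = centred @ v / (np.linalg.norm(centred, axis=1) * np.linalg.norm(v))
    table = (
        pd.DataFrame(
            {
                "feature": ipl.index[~constant],
                "pearson_r": r,
                "abs_r": np.abs(r),
            }
        )
        .sort_values("feature", kind="mergesort")
        .sort_values("abs_r", ascending=False, kind="mergesort")
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    table["n"] = len(shared)
    out = table.head(top_n).reset_index(drop=True)
    out.attrs["constant_features"] = list(ipl.index[constant])
    return out


@dataclass
class ClusteringResult:
    """Sample-distance clustering: distances, linkage, leaf order, tree."""

    distances: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    tree: TreeNode

    @property
    def newick(self) -> str:
        buf = _io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def sample_distance_clustering(
    log_expression: pd.DataFrame, linkage: str = "complete"
) -> ClusteringResult:
    """Euclidean sample distances over all genes + agglomerative clustering.

    Complete linkage by default (average available via ``linkage``); the
    leaf order is scipy's deterministic dendrogram order.
    """
    if log_expression.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    values = log_expression.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("expression matrix contains NaN")
    samples = list(log_expression.columns)
    condensed = scipy.spatial.distance.pdist(values.T, metric="euclidean")
    z = scipy.cluster.hierarchy.linkage(condensed, method=linkage)
    leaves = scipy.cluster.hierarchy.leaves_list(z)
    dist = pd.DataFrame(
        scipy.spatial.distance.squareform(condensed), index=samples, columns=samples
    )
    tree = TreeNode.from_linkage_matrix(z, samples)
    return ClusteringResult(
        distances=dist,
        linkage=z,
        leaf_order=[samples[i] for i in leaves],
        tree=tree,
    )


def subtree_purity(result: ClusteringResult, labels: pd.Series) -> bool:
    """True if every label's samples form one pure subtree of the dendrogram.

    Checked on the merge history: a label is pure if some merge node contains
    exactly its samples and each merge below the first mixed node is
    label-homogeneous.
    """
    samples = list(result.distances.index)
    n = len(samples)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    cluster_sets = []
    for step, (a, b, _, _) in enumerate(result.linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        cluster_sets.append(frozenset(merged))
    wanted = {
        label: frozenset(i for i, s in enumerate(samples) if labels[s] == label)
        for label in labels.unique()
    }
    return all(w in cluster_sets or len(w) == 1 for w in wanted.values())
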