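"""Profile-level comparisons: correlation, clustering, distribution tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import CondmapError, InsufficientDataError
from .differential_scoring import MeanScoreMatrix
from .types import DRUGS, UNTREATED

Linkage = Literal["average", "complete", "single"]

MIN_COMPLETE_PAIRS = 3


@dataclass
class CorrelationMatrix:
    """Pearson correlations between (query, condition) mean-score profiles.

    ``r`` is symmetric with unit diagonal; ``n`` records the
    pairwise-complete array-gene count behind each cell. Cells with fewer
    than three complete pairs (or a zero-variance profile) are NaN.
    """

    labels: list[tuple[str, str]]
    r: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        names = [f"{q}:{c}" for q, c in self.labels]
        return pd.DataFrame(self.r, index=names, columns=names)


@dataclass
class DistributionComparison:
    """Two-sided two-sample KS comparison of score distributions."""

    label_x: str
    label_y: str
    ks_stat: float
    p: float
    n_x: int
    n_y: int


@dataclass
class Dendrogram:
    """Agglomerative clustering result on 1 − r distances."""

    labels: list[tuple[str, str]]
    linkage_matrix: np.ndarray
    method: str

    @property
    def leaf_order(self) -> list[tuple[str, str]]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[tuple[str, str], int]:
        """Flat cluster assignment at k clusters."""
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                q, c = self.labels[node.id]
                return f"{q}:{c}".replace(":", "_")
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        return walk(tree) + ";"


def _profile_table(means: MeanScoreMatrix) -> pd.DataFrame:
    """Wide table: rows = array genes, columns = (query, drug) profiles."""
    return means.data.pivot_table(
        index="array", columns=["query", "drug"], values="S", aggfunc="first"
    )


def correlation_matrix(means: MeanScoreMatrix) -> CorrelationMatrix:
    """Pearson r over array genes for every pair of (query, condition) profiles.

    Uses pairwise-complete deletion; a cell with fewer than
    ``MIN_COMPLETE_PAIRS`` complete pairs, or involving a zero-variance
    profile, is missing (with a warning for the latter).
    """
    wide = _profile_table(means)
    labels = [tuple(c) for c in wide.columns]
    k = len(labels)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    values = wide.to_numpy()
    for i in range(k):
        r[i, i] = 1.0
        n[i, i] = int((~np.isnan(values[:, i])).sum())
        for j in range(i + 1, k):
            both = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            n[i, j] = n[j, i] = int(both.sum())
            if n[i, j] < MIN_COMPLETE_PAIRS:
                continue
            x, y = values[both, i], values[both, j]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"zero-variance profile in correlation {labels[i]} vs {labels[j]}",
                    stacklevel=2,
                )
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(x, y)[0, 1])
    return CorrelationMatrix(labels=labels, r=r, n=n)


def cluster_profiles(
    corr: CorrelationMatrix, linkage: Linkage = "average"
) -> Dendrogram:
    """Agglomerative clustering of profiles on distance d = 1 − r.

    Labels are ordered lexicographically first so that ties break
    deterministically regardless of input order.
    """
    order = np.argsort([f"{q}:{c}" for q, c in corr.labels], kind="mergesort")
    labels = [corr.labels[i] for i in order]
    r = corr.r[np.ix_(order, order)]
    if np.isnan(r).any():
        bad = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
            if np.isnan(r[i, j])
        ]
        raise CondmapError(f"missing correlation cells prevent clustering: {bad}")
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return Dendrogram(labels=labels, linkage_matrix=z, method=linkage)


def ks_two_sided(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> DistributionComparison:
    """Exact two-sample KS statistic with a two-sided p-value.

    Uses the exact small-sample distribution when n_x*n_y <= 10^4, the
    asymptotic formula otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("KS comparison needs >=2 observations per sample")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return DistributionComparison(
        label_x=label_x,
        label_y=label_y,
        ks_stat=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n_x=int(x.size),
        n_y=int(y.size),
    )


def condition_distribution_comparisons(
    means: MeanScoreMatrix,
) -> list[DistributionComparison]:
    """KS comparisons of each drug profile against untreated, per query."""
    out = []
    for query in means.queries:
        unt = means.profile(query, UNTREATED).dropna()
        for drug in means.drugs:
            s = means.profile(query, drug).dropna()
            if len(s) < 2 or len(unt) < 2:
                continue
            out.append(
                ks_two_sided(
                    s.to_numpy(), unt.to_numpy(),
                    label_x=f"{query}:{drug}", label_y=f"{query}:{UNTREATED}",
                )
            )
    return out
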