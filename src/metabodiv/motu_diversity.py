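"""Metabotype-OTU clustering and diversity statistics.

Strains measured in one cellular fraction are clustered by Ward's
minimum-variance method on their (preprocessed) metabolite intensity
profiles.  Cutting the dendrogram at a percentage of its maximal merge
distance partitions the strains into *metabotype OTUs* (m-OTUs), by analogy
with sequence-identity OTUs.  Per partition the module computes the
Shannon-Weiner index (natural log), Good's coverage C = 1 - n1/N (n1 =
singleton m-OTUs, N = strains), and the analytical (hypergeometric)
rarefaction curve.

Ward convention: merge heights are the *increase in within-cluster error sum
of squares* (ESS).  SciPy's ``ward`` linkage reports ``sqrt(2 * dESS)``, so
heights are transformed as h -> h^2 / 2; the transform is monotone, so tree
topology and percent cuts are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, log

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage

from .multivariate import Preprocessing, _as_X, preprocess

__all__ = [
    "WardDendrogram", "MOTUPartition", "DiversityStats",
    "ward_dendrogram", "cut_percent", "shannon", "goods_coverage",
    "rarefaction", "diversity_profile", "to_newick",
]


@dataclass
class WardDendrogram:
    """Ward merge tree with ESS-increase heights."""

    linkage: np.ndarray          # scipy linkage matrix, heights = dESS
    labels: list[str]            # strain ids, leaf order = input order

    @property
    def ward_max(self) -> float:
        """Maximal merge distance; the 100% clustering level."""
        return float(self.linkage[-1, 2]) if len(self.linkage) else 0.0

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class MOTUPartition:
    """Strain -> m-OTU assignment at one percent threshold."""

    threshold_pct: float
    labels: dict[str, int]       # strain id -> cluster id (1-based)
    ward_max: float

    @property
    def cluster_sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for c in self.labels.values():
            counts[c] = counts.get(c, 0) + 1
        return sorted(counts.values(), reverse=True)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain": list(self.labels),
                             "cluster": list(self.labels.values())})


@dataclass
class DiversityStats:
    shannon: float
    goods_coverage: float
    rarefaction: list[tuple[int, float]]


def ward_dendrogram(matrix, strain_ids: list[str] | None = None,
                    prep: Preprocessing | None = Preprocessing()
                    ) -> WardDendrogram:
    """Ward's minimum-variance dendrogram of strain profiles.

    ``matrix`` is a FeatureMatrix (features x samples) or samples x features
    array; profiles are centered/Pareto-scaled by default (``prep=None`` to
    cluster raw).  Heights are ESS increases.
    """
    X, ids = _as_X(matrix)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 strains to cluster")
    if strain_ids is None:
        strain_ids = ids if ids is not None else [str(i) for i in range(X.shape[0])]
    if prep is not None:
        X, _, _ = preprocess(X, prep)
    Z = _scipy_linkage(X, method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2 / 2.0   # sqrt(2*dESS) -> dESS
    return WardDendrogram(linkage=Z, labels=list(strain_ids))


def cut_percent(dendrogram: WardDendrogram, pct: float) -> MOTUPartition:
    """Cut at ``pct`` percent of the maximal Ward distance.

    Clusters are the connected subtrees whose merges all lie at or below the
    cut height ``pct/100 * ward_max``; pct=100 gives one cluster and pct -> 0+
    gives all singletons (up to exactly coincident strains).
    """
    if not 0 < pct <= 100:
        raise ValueError(f"pct must be in (0, 100], got {pct}")
    cut = pct / 100.0 * dendrogram.ward_max
    flat = fcluster(dendrogram.linkage, t=cut, criterion="distance")
    return MOTUPartition(threshold_pct=pct,
                         labels=dict(zip(dendrogram.labels,
                                         (int(c) for c in flat))),
                         ward_max=dendrogram.ward_max)


def shannon(partition: MOTUPartition | list[int]) -> float:
    """Shannon-Weiner index H = -sum p_i ln p_i over m-OTU relative sizes."""
    sizes = _sizes(partition)
    n = sum(sizes)
    if n == 0:
        raise ValueError("empty partition")
    return -sum((s / n) * log(s / n) for s in sizes if s > 0)


def goods_coverage(partition: MOTUPartition | list[int]) -> float:
    """Good's coverage C = 1 - n1/N (n1 singleton m-OTUs, N individuals)."""
    sizes = _sizes(partition)
    n = sum(sizes)
    if n < 1:
        raise ValueError("empty partition")
    singletons = sum(1 for s in sizes if s == 1)
    return 1.0 - singletons / n


def rarefaction(partition: MOTUPartition | list[int],
                subsample_sizes: list[int] | None = None
                ) -> list[tuple[int, float]]:
    """Analytical rarefaction: E[S_n] = sum_i [1 - C(N-N_i, n)/C(N, n)].

    Exact integer combinatorics, so endpoint identities hold to machine
    precision: E[S_1] = 1 (for N >= 1), E[S_N] = observed richness.
    """
    sizes = _sizes(partition)
    n_tot = sum(sizes)
    if subsample_sizes is None:
        subsample_sizes = list(range(1, n_tot + 1))
    curve = []
    for n in subsample_sizes:
        if not 1 <= n <= n_tot:
            raise ValueError(f"subsample size {n} outside [1, {n_tot}]")
        denom = comb(n_tot, n)
        # exact rational sum, floated once: endpoint identities hold exactly
        e_s = Fraction(0)
        for s in sizes:
            e_s += 1 - Fraction(comb(n_tot - s, n), denom)
        curve.append((n, float(e_s)))
    return curve


def diversity_profile(dendrogram: WardDendrogram,
                      pct_grid: list[float] | None = None) -> pd.DataFrame:
    """Diversity along a percent-threshold grid (default 5-100% by 5).

    Returns columns ``pct, n_motus, shannon, goods_coverage``.  By the nesting
    of dendrogram cuts, Shannon is non-increasing and coverage non-decreasing
    in pct; both are asserted on every call.
    """
    if pct_grid is None:
        pct_grid = [float(p) for p in range(5, 101, 5)]
    rows = []
    for pct in pct_grid:
        part = cut_percent(dendrogram, pct)
        rows.append({"pct": pct, "n_motus": part.n_clusters,
                     "shannon": shannon(part),
                     "goods_coverage": goods_coverage(part)})
    df = pd.DataFrame(rows).sort_values("pct", ignore_index=True)
    h = df["shannon"].to_numpy()
    c = df["goods_coverage"].to_numpy()
    assert np.all(np.diff(h) <= 1e-12), "Shannon must not increase with pct"
    assert np.all(np.diff(c) >= -1e-12), "coverage must not decrease with pct"
    return df


def diversity_stats(partition: MOTUPartition) -> DiversityStats:
    return DiversityStats(shannon=shannon(partition),
                          goods_coverage=goods_coverage(partition),
                          rarefaction=rarefaction(partition))


def _sizes(partition) -> list[int]:
    if isinstance(partition, MOTUPartition):
        return partition.cluster_sizes
    return [int(s) for s in partition]


def to_newick(dendrogram: WardDendrogram) -> str:
    """Newick string with branch lengths from ESS merge heights."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(dendrogram.linkage)
    labels = dendrogram.labels

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
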