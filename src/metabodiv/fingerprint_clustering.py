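"""Similarity dendrograms for binary fingerprints.

Covers the two classical typing fingerprints used alongside metabolomics:
genomic restriction band patterns resolved by pulsed-field gel
electrophoresis (PFGE; band sizes in kb, compared by the Dice coefficient and
clustered by UPGMA) and whole-cell MALDI-TOF peak lists (peak masses m/z,
compared by the matched-peak percentage and clustered by single linkage).

Two positions match when they agree within a relative tolerance (default 1%,
an FPQuest-style band-position tolerance).  Similarities are percentages;
dendrograms agglomerate the most similar pair first, with merge heights
expressed as dissimilarity 100 - S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

__all__ = [
    "BinaryFingerprint", "pairwise_similarity", "similarity_matrix",
    "similarity_dendrogram", "dendrogram_newick",
]


@dataclass
class BinaryFingerprint:
    """A sample's set of band sizes (kb) or peak masses (m/z)."""

    sample_id: str
    positions: list[float] = field(default_factory=list)
    match_tolerance: float = 0.01   # relative

    def __post_init__(self) -> None:
        for p in self.positions:
            if not (p > 0 and np.isfinite(p)):
                raise ValueError(f"fingerprint positions must be positive "
                                 f"finite, got {p}")
        self.positions = sorted(self.positions)


def _n_matched(a: list[float], b: list[float], tol: float) -> int:
    """Greedy one-to-one matching of sorted positions within relative tol."""
    i = j = matched = 0
    while i < len(a) and j < len(b):
        hi, lo = max(a[i], b[j]), min(a[i], b[j])
        if (hi - lo) <= tol * hi:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matched


def pairwise_similarity(a: BinaryFingerprint, b: BinaryFingerprint,
                        method: str = "dice") -> float:
    """Percent similarity between two fingerprints.

    ``dice`` = 2|A n B| / (|A| + |B|) x 100 (PFGE convention);
    ``matched_pct`` = |A n B| / max(|A|, |B|) x 100 (MALDI convention).
    """
    if not a.positions or not b.positions:
        raise ValueError("cannot compare an empty fingerprint")
    tol = max(a.match_tolerance, b.match_tolerance)
    m = _n_matched(a.positions, b.positions, tol)
    if method == "dice":
        return 200.0 * m / (len(a.positions) + len(b.positions))
    if method == "matched_pct":
        return 100.0 * m / max(len(a.positions), len(b.positions))
    raise ValueError(f"unknown method {method!r}; use 'dice' or 'matched_pct'")


def similarity_matrix(fingerprints: list[BinaryFingerprint],
                      method: str = "dice") -> np.ndarray:
    n = len(fingerprints)
    s = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = pairwise_similarity(fingerprints[i],
                                                    fingerprints[j], method)
    return s


def similarity_dendrogram(fingerprints: list[BinaryFingerprint],
                          linkage: str = "upgma",
                          method: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Agglomerate fingerprints on similarity; heights = 100 - similarity.

    ``linkage`` is 'upgma' (average; PFGE default, pairs with Dice) or
    'single' (MALDI default, pairs with matched_pct).  Returns a scipy
    linkage matrix and the leaf labels.
    """
    if len(fingerprints) < 2:
        raise ValueError("need >= 2 fingerprints")
    link_map = {"upgma": "average", "single": "single"}
    if linkage not in link_map:
        raise ValueError(f"unknown linkage {linkage!r}; use 'upgma' or 'single'")
    if method is None:
        method = "dice" if linkage == "upgma" else "matched_pct"
    s = similarity_matrix(fingerprints, method)
    d = 100.0 - s
    np.fill_diagonal(d, 0.0)
    z = _scipy_linkage(squareform(d, checks=False), method=link_map[linkage])
    return z, [f.sample_id for f in fingerprints]


def dendrogram_newick(z: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                f":{length:.6g}")

    return rec(tree, tree.dist) + ";"
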