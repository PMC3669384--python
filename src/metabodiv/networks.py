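"""Mass-difference and sample-correlation networks.

Two complementary graph views of a metabolomic dataset:

* **Mass-difference network** — nodes are formula-assigned mass peaks
  (assignment error < 0.5 ppm); an edge links two peaks whose exact mass
  difference matches a known biochemical transformation (H2, H2O, CH2, ...)
  within a very tight ppm window (default 0.1 ppm, relative to the larger of
  the two masses).  Edges are putative single-reaction relationships.

* **Correlation network** — nodes are samples; an edge links two samples
  whose intensity profiles have a positive Pearson correlation above a
  threshold (default 0.90).

The shipped transformation list (~50 entries) has deltas computed from exact
monoisotopic element masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import FeatureMatrix
from .formula_assignment import MASS_C, MASS_H, MASS_N, MASS_O, MASS_S

__all__ = [
    "MassDiffList", "DEFAULT_MASS_DIFFS",
    "build_mass_difference_network", "build_correlation_network",
    "module_composition", "class_specific_features",
    "write_edgelist", "write_graphml",
]


def _delta(c: int = 0, h: int = 0, n: int = 0, o: int = 0, s: int = 0) -> float:
    return c * MASS_C + h * MASS_H + n * MASS_N + o * MASS_O + s * MASS_S


@dataclass
class MassDiffList:
    """Named exact mass differences (biochemical transformations)."""

    records: list[tuple[str, float]]

    def __post_init__(self) -> None:
        names = [r[0] for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("mass-difference names must be unique")
        for name, d in self.records:
            if not d > 0:
                raise ValueError(f"mass difference {name!r} must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path) -> "MassDiffList":
        df = pd.read_csv(path)
        return cls(records=list(zip(df["name"], df["delta"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.records, columns=["name", "delta"]).to_csv(
            path, index=False)


# Common biochemical transformations; deltas from exact element masses.
_DEFAULT_DIFF_COMPOSITIONS: list[tuple[str, tuple[int, int, int, int, int]]] = [
    ("H2", (0, 2, 0, 0, 0)),                # (de)hydrogenation
    ("CH2", (1, 2, 0, 0, 0)),               # methylene / alkyl chain
    ("CH2O", (1, 2, 0, 1, 0)),              # formaldehyde / hydroxymethyl
    ("CH3N", (1, 3, 1, 0, 0)),              # methylamine
    ("CO", (1, 0, 0, 1, 0)),
    ("CO2", (1, 0, 0, 2, 0)),               # (de)carboxylation
    ("CHN", (1, 1, 1, 0, 0)),               # HCN
    ("C2H2", (2, 2, 0, 0, 0)),              # acetylene / unsaturated C2
    ("C2H4", (2, 4, 0, 0, 0)),
    ("C2H2O", (2, 2, 0, 1, 0)),             # ketene / acetylation - H2O
    ("C2H4O2", (2, 4, 0, 2, 0)),            # acetic acid
    ("C2H3NO", (2, 3, 1, 1, 0)),            # glycine residue
    ("C2H5N", (2, 5, 1, 0, 0)),
    ("C3H4O2", (3, 4, 0, 2, 0)),            # acrylic acid / malonyl - CO2
    ("C3H5NO", (3, 5, 1, 1, 0)),            # alanine residue
    ("C3H2O3", (3, 2, 0, 3, 0)),            # malonyl transfer
    ("C3H6O2", (3, 6, 0, 2, 0)),
    ("C4H4O2", (4, 4, 0, 2, 0)),
    ("C4H6O2", (4, 6, 0, 2, 0)),
    ("C4H8", (4, 8, 0, 0, 0)),
    ("C5H8", (5, 8, 0, 0, 0)),              # isoprene unit
    ("C5H7NO", (5, 7, 1, 1, 0)),            # proline residue
    ("C5H8O4", (5, 8, 0, 4, 0)),            # pentose (glycosylation - H2O)
    ("C6H10O4", (6, 10, 0, 4, 0)),          # deoxyhexose
    ("C6H10O5", (6, 10, 0, 5, 0)),          # hexose (glycosylation - H2O)
    ("C6H12O6", (6, 12, 0, 6, 0)),          # hexose condensation
    ("C6H11NO", (6, 11, 1, 1, 0)),          # leucine residue
    ("H2O", (0, 2, 0, 1, 0)),               # (de)hydration
    ("H2O2", (0, 2, 0, 2, 0)),
    ("NH", (0, 1, 1, 0, 0)),
    ("NH2", (0, 2, 1, 0, 0)),
    ("NH3", (0, 3, 1, 0, 0)),               # (de)amination
    ("HNO", (0, 1, 1, 1, 0)),
    ("NO2", (0, 0, 1, 2, 0)),
    ("O", (0, 0, 0, 1, 0)),                 # oxidation / hydroxylation
    ("O2", (0, 0, 0, 2, 0)),
    ("O3", (0, 0, 0, 3, 0)),
    ("S", (0, 0, 0, 0, 1)),
    ("SH2", (0, 2, 0, 0, 1)),               # hydrogen sulfide
    ("SO", (0, 0, 0, 1, 1)),
    ("SO2", (0, 0, 0, 2, 1)),
    ("SO3", (0, 0, 0, 3, 1)),               # sulfonation
    ("SO4H2", (0, 2, 0, 4, 1)),             # sulfate conjugation
    ("CH2S", (1, 2, 0, 0, 1)),
    ("C2H2S", (2, 2, 0, 0, 1)),
    ("CHNO", (1, 1, 1, 1, 0)),              # isocyanic acid
    ("CH3NO", (1, 3, 1, 1, 0)),
    ("C4H5NO3", (4, 5, 1, 3, 0)),           # aspartate residue
    ("C5H5N5", (5, 5, 5, 0, 0)),            # adenine
    ("C9H9NO", (9, 9, 1, 1, 0)),            # phenylalanine residue
]

DEFAULT_MASS_DIFFS = MassDiffList(
    records=[(name, _delta(*comp)) for name, comp in _DEFAULT_DIFF_COMPOSITIONS])


def build_mass_difference_network(assignments: pd.DataFrame,
                                  mdiffs: MassDiffList = DEFAULT_MASS_DIFFS,
                                  edge_ppm: float = 0.1,
                                  node_error_ppm: float = 0.5,
                                  node_attrs: pd.DataFrame | None = None,
                                  use_theoretical: bool = False) -> nx.Graph:
    """Build the mass-difference network over formula-assigned features.

    Nodes are rows of ``assignments`` with a formula and
    \\|error_ppm\\| < ``node_error_ppm``.  An undirected edge carries every
    transformation name whose delta matches the pair's mass difference within
    ``edge_ppm`` (ppm relative to the larger mass).  ``use_theoretical``
    switches node masses from measured to theoretical (noise-free mode).
    ``node_attrs`` (indexed like assignments) adds node attributes.
    """
    if len(mdiffs) == 0:
        raise ValueError("empty mass-difference list")
    ok = (assignments["formula"] != "") & (
        assignments["error_ppm"].abs() < node_error_ppm)
    sub = assignments[ok]
    masses = (sub["theoretical_mass"] if use_theoretical else sub["mz"]).to_numpy()
    idx = sub.index.to_numpy()

    g = nx.Graph()
    for i, row in sub.iterrows():
        attrs = {"mz": float(row["mz"]), "formula": row["formula"],
                 "error_ppm": float(row["error_ppm"])}
        if node_attrs is not None and i in node_attrs.index:
            attrs.update(node_attrs.loc[i].to_dict())
        g.add_node(i, **attrs)

    order = np.argsort(masses)
    m_sorted = masses[order]
    idx_sorted = idx[order]
    for name, d in mdiffs.records:
        # candidate window (generous); the exact ppm check below — relative to
        # the heavier mass of each pair — is authoritative
        tol = 2 * edge_ppm * (m_sorted + d) / 1e6
        lo = np.searchsorted(m_sorted, m_sorted + d - tol)
        hi = np.searchsorted(m_sorted, m_sorted + d + tol, side="right")
        for a in range(len(m_sorted)):
            for b in range(lo[a], hi[a]):
                if a == b:
                    continue
                heavier = max(m_sorted[a], m_sorted[b])
                err_ppm = abs(abs(m_sorted[b] - m_sorted[a]) - d) / heavier * 1e6
                if err_ppm <= edge_ppm:
                    u, v = int(idx_sorted[a]), int(idx_sorted[b])
                    if g.has_edge(u, v):
                        labels = set(g[u][v]["labels"])
                        labels.add(name)
                        g[u][v]["labels"] = sorted(labels)
                    else:
                        g.add_edge(u, v, labels=[name], delta=d)
    return g


def build_correlation_network(matrix: FeatureMatrix,
                              r_threshold: float = 0.90) -> nx.Graph:
    """Sample-correlation network: edge iff Pearson r > ``r_threshold`` (> 0).

    Samples with a zero-variance (or all-zero) profile stay isolated, with a
    warning.  Edge weight = r.
    """
    x = matrix.values  # features x samples
    if matrix.n_features < 3:
        raise ValueError("need >= 3 features per sample profile")
    g = nx.Graph()
    meta = matrix.sample_meta
    for s in matrix.sample_ids:
        attrs = meta.loc[s].to_dict() if meta is not None else {}
        g.add_node(s, **attrs)
    sd = x.std(axis=0)
    degenerate = sd == 0
    for j in np.nonzero(degenerate)[0]:
        warnings.warn(f"sample {matrix.sample_ids[j]} has a zero-variance "
                      "profile; left isolated", stacklevel=2)
    valid = np.nonzero(~degenerate)[0]
    if len(valid) >= 2:
        r = np.corrcoef(x[:, valid], rowvar=False)
        for a in range(len(valid)):
            for b in range(a + 1, len(valid)):
                if r[a, b] > r_threshold and r[a, b] > 0:
                    g.add_edge(matrix.sample_ids[valid[a]],
                               matrix.sample_ids[valid[b]],
                               weight=float(r[a, b]))
    return g


def module_composition(network: nx.Graph, attribute: str) -> list[dict]:
    """Per connected component, tally node values of ``attribute``.

    Returns a list (largest component first) of
    ``{"nodes": n, "composition": {value: count}}``.
    """
    out = []
    for comp in sorted(nx.connected_components(network), key=len, reverse=True):
        tally: dict = {}
        for node in comp:
            if attribute not in network.nodes[node]:
                raise KeyError(f"node {node!r} lacks attribute {attribute!r}")
            v = network.nodes[node][attribute]
            tally[v] = tally.get(v, 0) + 1
        out.append({"nodes": len(comp), "composition": tally})
    return out


def class_specific_features(matrix: FeatureMatrix, classes: pd.Series,
                            fold: float = 10.0) -> pd.Series:
    """Label features specific to one sample class (10x frequency rule).

    A feature is ``specific_to`` a class when its occurrence frequency there
    (fraction of that class's samples containing the peak) is at least
    ``fold`` times the mean frequency over the other classes; features present
    in only one class are specific to it.  Returns a Series of class labels
    ("" = unspecific) indexed by feature position.
    """
    classes = classes.reindex(matrix.sample_ids)
    labels = sorted(classes.dropna().unique())
    freq = {}
    for lab in labels:
        cols = np.array([s in set(classes[classes == lab].index)
                         for s in matrix.sample_ids])
        freq[lab] = (matrix.values[:, cols] > 0).mean(axis=1)
    out = np.full(matrix.n_features, "", dtype=object)
    for lab in labels:
        others = [freq[o] for o in labels if o != lab]
        other_mean = np.mean(others, axis=0) if others else np.zeros(matrix.n_features)
        with np.errstate(divide="ignore", invalid="ignore"):
            spec = np.where(other_mean > 0, freq[lab] >= fold * other_mean,
                            freq[lab] > 0)
        out[spec & (out == "")] = lab
    return pd.Series(out, name="specific_to")


def write_edgelist(network: nx.Graph, path) -> None:
    """Write edges as TSV: source, target, label, weight."""
    rows = []
    for u, v, data in network.edges(data=True):
        rows.append({"source": u, "target": v,
                     "label": ";".join(data.get("labels", [])) or "",
                     "weight": data.get("weight", "")})
    pd.DataFrame(rows, columns=["source", "target", "label", "weight"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(network: nx.Graph, path) -> None:
    g = network.copy()
    for _u, _v, data in g.edges(data=True):
        if "labels" in data:
            data["labels"] = ";".join(data["labels"])
    nx.write_graphml(g, path)
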