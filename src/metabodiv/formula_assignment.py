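"""Elemental-formula assignment for exact masses (CHNOS chemistry).

Sub-ppm mass accuracy makes the molecular formula of a small metabolite
recoverable from its exact mass alone.  This module converts observed m/z to
neutral monoisotopic masses ([M+H]+ / [M-H]- only), exhaustively enumerates
candidate CHNOS formulas within a ppm tolerance, validates them with the
standard chemical filters (nitrogen rule, O/C ratio, RDBE range, element
bounds, hydrogen valence cap), and strips 13C isotopologue satellites from an
aligned feature matrix before assignment.

Element bounds default to C <= 100, 0 <= O <= 80, N <= 5, S <= 1 with an
assignment tolerance of 0.5 ppm.

Enumeration strategy: loop over the (C, N, O, S) sub-lattice (vectorized) and
solve for the hydrogen count from the mass residual — at FT-ICR accuracy at
most one H count can land within tolerance for a given (C, N, O, S).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import FeatureMatrix
from .peaklist_io import formula_to_string

__all__ = [
    "MASS_C", "MASS_H", "MASS_N", "MASS_O", "MASS_S", "PROTON_MASS",
    "C13_C12_DELTA", "C13_ABUNDANCE",
    "FormulaCandidate", "ConstraintSet",
    "monoisotopic_mass", "nominal_mass", "rdbe",
    "neutralize_mz", "enumerate_formulas", "check_rules",
    "remove_isotopologues", "assign_matrix",
]

logger = logging.getLogger(__name__)

# Monoisotopic element masses (Da)
MASS_C = 12.0
MASS_H = 1.00782503
MASS_N = 14.00307401
MASS_O = 15.99491462
MASS_S = 31.97207069
PROTON_MASS = 1.007276466
#: 13C - 12C mass spacing and natural 13C abundance per carbon
C13_C12_DELTA = 1.0033548
C13_ABUNDANCE = 0.0107

_ELEMENT_MASSES = np.array([MASS_C, MASS_H, MASS_N, MASS_O, MASS_S])
_NOMINAL = np.array([12, 1, 14, 16, 32])


def monoisotopic_mass(counts) -> float:
    """Neutral monoisotopic mass (Da) of a (C, H, N, O, S) count vector."""
    return float(np.dot(np.asarray(counts, dtype=float), _ELEMENT_MASSES))


def nominal_mass(counts) -> int:
    """Integer (nominal) mass of a (C, H, N, O, S) count vector."""
    return int(np.dot(np.asarray(counts, dtype=int), _NOMINAL))


def rdbe(counts) -> float:
    """Rings + double-bond equivalents: C - H/2 + N/2 + 1 (O, S neutral)."""
    c, h, n, _o, _s = counts
    return c - h / 2 + n / 2 + 1


@dataclass(frozen=True)
class FormulaCandidate:
    """A candidate elemental composition for an observed neutral mass."""

    counts: tuple[int, int, int, int, int]   # (C, H, N, O, S)
    theoretical_mass: float
    error_ppm: float

    @property
    def formula(self) -> str:
        return formula_to_string(self.counts)

    @property
    def rdbe(self) -> float:
        return rdbe(self.counts)


@dataclass(frozen=True)
class ConstraintSet:
    """Chemical plausibility filters applied to enumerated formulas.

    ``max_h_factor`` caps H at ``2*C + N + 2`` (saturated-acyclic valence
    limit); ``rdbe_range`` requires an integral RDBE within the band, which
    together with the mass-parity check enforces the nitrogen rule.
    """

    max_C: int = 100
    O_range: tuple[int, int] = (0, 80)
    max_N: int = 5
    max_S: int = 1
    max_oc_ratio: float = 1.0
    require_nitrogen_rule: bool = True
    rdbe_range: tuple[float, float] = (0.0, 40.0)
    tol_ppm: float = 0.5

    def __post_init__(self) -> None:
        if min(self.max_C, self.O_range[0], self.max_N, self.max_S) < 0:
            raise ValueError("element bounds must be >= 0")
        if self.tol_ppm < 0:
            raise ValueError("tol_ppm must be >= 0")


def neutralize_mz(mz: float, mode: str = "positive",
                  adduct: str = "protonated") -> float:
    """Convert an observed ion m/z to the neutral monoisotopic mass.

    ``protonated`` ([M+H]+): neutral = mz - proton mass.
    ``deprotonated`` ([M-H]-): neutral = mz + proton mass.
    """
    if adduct == "protonated":
        if mode == "negative":
            raise ValueError("protonated adduct implies positive mode")
        if mz <= PROTON_MASS:
            raise ValueError(f"m/z {mz} is not above the proton mass")
        return mz - PROTON_MASS
    if adduct == "deprotonated":
        if mode == "positive":
            raise ValueError("deprotonated adduct implies negative mode")
        return mz + PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct!r}; "
                     "use 'protonated' or 'deprotonated'")


def check_rules(candidate: FormulaCandidate,
                constraints: ConstraintSet = ConstraintSet()) -> tuple[bool, str]:
    """Validate a formula against the constraint set.

    Returns ``(True, "ok")`` or ``(False, reason)`` where the reason names the
    first violated rule (element bound, O/C, RDBE, nitrogen rule).
    """
    c, h, n, o, s = candidate.counts
    if min(c, h, n, o, s) < 0:
        return False, "element bound: negative count"
    if c > constraints.max_C:
        return False, f"element bound: C={c} > {constraints.max_C}"
    if not constraints.O_range[0] <= o <= constraints.O_range[1]:
        return False, f"element bound: O={o} outside {constraints.O_range}"
    if n > constraints.max_N:
        return False, f"element bound: N={n} > {constraints.max_N}"
    if s > constraints.max_S:
        return False, f"element bound: S={s} > {constraints.max_S}"
    if c == 0:
        return False, "element bound: no carbon"
    if o / c > constraints.max_oc_ratio + 1e-12:
        return False, f"O/C ratio {o / c:.3f} > {constraints.max_oc_ratio}"
    r = rdbe(candidate.counts)
    lo, hi = constraints.rdbe_range
    if not lo <= r <= hi:
        return False, f"RDBE {r} outside [{lo}, {hi}]"
    if h > 2 * c + n + 2:
        return False, f"valence: H={h} > 2C+N+2={2 * c + n + 2}"
    if constraints.require_nitrogen_rule:
        # neutral molecule: parity of nominal mass must match parity of N
        if (nominal_mass(candidate.counts) % 2) != (n % 2):
            return False, "nitrogen rule: nominal-mass/N parity mismatch"
    return True, "ok"


def enumerate_formulas(neutral_mass: float,
                       constraints: ConstraintSet = ConstraintSet()
                       ) -> list[FormulaCandidate]:
    """All CHNOS formulas whose mass lies within ``tol_ppm`` of ``neutral_mass``
    and which pass :func:`check_rules`, sorted by \\|error_ppm\\| (ties by mass).

    An empty list means the mass is unassignable under the constraints.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    tol_da = constraints.tol_ppm * neutral_mass / 1e6

    c_max = min(constraints.max_C, int((neutral_mass + tol_da) // MASS_C))
    o_max = min(constraints.O_range[1], int((neutral_mass + tol_da) // MASS_O))
    n_max = min(constraints.max_N, int((neutral_mass + tol_da) // MASS_N))
    s_max = min(constraints.max_S, int((neutral_mass + tol_da) // MASS_S))

    c = np.arange(1, c_max + 1)
    o = np.arange(constraints.O_range[0], o_max + 1)
    n = np.arange(0, n_max + 1)
    s = np.arange(0, s_max + 1)
    C, O, N, S = np.meshgrid(c, o, n, s, indexing="ij")
    C, O, N, S = (a.ravel() for a in (C, O, N, S))

    residual = neutral_mass - (C * MASS_C + O * MASS_O + N * MASS_N + S * MASS_S)
    H = np.rint(residual / MASS_H).astype(int)
    # pre-filter with a hair of slack (ppm is defined against the theoretical
    # mass; the exact check below is authoritative)
    ok = (H >= 0) & (np.abs(residual - H * MASS_H) <= tol_da * (1 + 1e-9) + 1e-12)
    out: list[FormulaCandidate] = []
    for ci, hi_, ni, oi, si in zip(C[ok], H[ok], N[ok], O[ok], S[ok]):
        counts = (int(ci), int(hi_), int(ni), int(oi), int(si))
        theo = monoisotopic_mass(counts)
        err = (neutral_mass - theo) / theo * 1e6
        if abs(err) > constraints.tol_ppm:
            continue
        cand = FormulaCandidate(counts=counts, theoretical_mass=theo,
                                error_ppm=err)
        if check_rules(cand, constraints)[0]:
            out.append(cand)
    out.sort(key=lambda fc: (abs(fc.error_ppm), fc.theoretical_mass))
    return out


def remove_isotopologues(matrix: FeatureMatrix,
                         delta: float = C13_C12_DELTA,
                         delta_tol: float = 0.001,
                         constraints: ConstraintSet = ConstraintSet(),
                         assignments: pd.DataFrame | None = None,
                         ratio_factor: float = 1.2,
                         min_corr: float = 0.5,
                         ) -> tuple[FeatureMatrix, list[int]]:
    """Drop features consistent with the +1 13C satellite of a lighter feature.

    A feature is removed when (a) a lighter feature sits ``delta`` below it
    within ``delta_tol`` Da, (b) its median heavy/light intensity ratio over
    co-occurring samples is below ``ratio_factor * C * C13_ABUNDANCE`` (C from
    the light feature's assigned formula when ``assignments`` is given, else
    the constraint C bound), and (c) when >= 3 samples share both peaks, the
    two intensity patterns correlate positively (Pearson r >= ``min_corr``).

    Returns the filtered matrix and the removed feature indices (into the
    input matrix).
    """
    mzs = matrix.feature_mzs
    removed: list[int] = []
    removed_set: set[int] = set()
    c_by_feature = None
    if assignments is not None:
        c_by_feature = assignments["C"].to_numpy()
    for j in range(matrix.n_features):
        lo = np.searchsorted(mzs, mzs[j] - delta - delta_tol)
        hi = np.searchsorted(mzs, mzs[j] - delta + delta_tol, side="right")
        for i in range(lo, hi):
            if i == j or i in removed_set:
                continue
            light, heavy = matrix.values[i], matrix.values[j]
            both = (light > 0) & (heavy > 0)
            if not both.any():
                continue
            if c_by_feature is not None and c_by_feature[i] > 0:
                c_for_rule = float(c_by_feature[i])
            else:
                c_for_rule = float(constraints.max_C)
            max_ratio = ratio_factor * c_for_rule * C13_ABUNDANCE
            ratio = float(np.median(heavy[both] / light[both]))
            if ratio > max_ratio:
                continue
            if both.sum() >= 3:
                r = np.corrcoef(light[both], heavy[both])[0, 1]
                if np.isfinite(r) and r < min_corr:
                    continue
            removed.append(j)
            removed_set.add(j)
            logger.info("isotopologue filter: feature %.5f removed as 13C "
                        "satellite of %.5f (ratio %.3f)", mzs[j], mzs[i], ratio)
            break
    return matrix.drop_features(removed), removed


def assign_matrix(matrix: FeatureMatrix,
                  constraints: ConstraintSet = ConstraintSet(),
                  adduct: str = "protonated",
                  mode: str | None = None) -> pd.DataFrame:
    """Assign each feature its best formula (lowest \\|error_ppm\\|).

    Returns a DataFrame indexed like the matrix features with columns
    ``mz, neutral_mass, formula, C, H, N, O, S, theoretical_mass, error_ppm,
    n_candidates, ambiguous`` — ``formula`` empty for unassigned features,
    ``ambiguous`` True when >= 2 candidates fall within tolerance.
    """
    if mode is None:
        mode = "positive" if adduct == "protonated" else "negative"
    rows = []
    for mz in matrix.feature_mzs:
        neutral = neutralize_mz(float(mz), mode=mode, adduct=adduct)
        cands = enumerate_formulas(neutral, constraints)
        if cands:
            best = cands[0]
            c, h, n, o, s = best.counts
            rows.append({"mz": float(mz), "neutral_mass": neutral,
                         "formula": best.formula, "C": c, "H": h, "N": n,
                         "O": o, "S": s,
                         "theoretical_mass": best.theoretical_mass,
                         "error_ppm": best.error_ppm,
                         "n_candidates": len(cands),
                         "ambiguous": len(cands) >= 2})
        else:
            rows.append({"mz": float(mz), "neutral_mass": neutral,
                         "formula": "", "C": 0, "H": 0, "N": 0, "O": 0, "S": 0,
                         "theoretical_mass": np.nan, "error_ppm": np.nan,
                         "n_candidates": 0, "ambiguous": False})
    return pd.DataFrame(rows)
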