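"""Ground-truth generator emulating ESI(+) FT-ICR peak lists.

Every analysis stage in this package is exercised against data with known
truth: a lattice-valid set of CHNOS formulas (a shared *core* metabolome plus
*accessory* formulas whose mean intensity is shifted between strain groups),
per-strain peak lists with sub-ppm mass noise, log-normal intensities,
optional 13C isotopologue satellites, random noise peaks, and a synthetic
reference table for the annotation stage.

The default truth sizes mirror the old-vs-new contrast of the intracellular
(SN2) fraction of the Santa Pola experiment: 5742 formulas in total, of which
274 are elevated in old strains and 136 in new strains.  The default study
design is two salterns x (new isolates + 5 shared reference strains) x three
cellular fractions.  Mass noise defaults to 0.1 ppm (instrument calibration
below 100 ppb) and the intensity coefficient of variation to 5%.

All randomness flows from one ``numpy.random.default_rng`` seed; the same
seed reproduces the same truth set and peak lists bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .formula_assignment import (C13_ABUNDANCE, C13_C12_DELTA, ConstraintSet,
                                 FormulaCandidate, PROTON_MASS, check_rules,
                                 monoisotopic_mass)
from .peaklist_io import (Peak, PeakList, ReferenceRecord, ReferenceTable,
                          SampleDescriptor, formula_to_string)

__all__ = [
    "TruthConfig", "NoiseModel", "TruthSet",
    "generate_truth", "simulate_peaklists", "simulate_study",
]

# class -> example pathways, used to label annotable synthetic formulas
_CLASS_PATHWAYS: dict[str, list[str]] = {
    "Lipid metabolism": ["Fatty acid biosynthesis", "Ether lipid metabolism",
                         "Sphingolipid metabolism"],
    "Metabolism of other amino acids": ["Cyanoamino acid metabolism",
                                        "Glutathione metabolism"],
    "Biosynthesis of other secondary metabolites": [
        "Novobiocin biosynthesis", "Puromycin biosynthesis"],
    "Metabolism of terpenoids and polyketides": [
        "Biosynthesis of type II polyketide products",
        "Terpenoid backbone biosynthesis"],
    "Carbohydrate metabolism": ["Glycolysis", "Pentose phosphate pathway"],
    "Amino acid metabolism": ["Arginine and proline metabolism",
                              "Glycine, serine and threonine metabolism"],
}


@dataclass(frozen=True)
class TruthConfig:
    """Sizes and effect structure of the planted metabolome."""

    n_core: int = 5332
    accessory: dict = field(default_factory=lambda: {"old": 274, "new": 136})
    effect_size_sd: float = 2.0       # accessory mean shift, in noise SDs
    mass_window: tuple[float, float] = (150.0, 2000.0)  # observed m/z window
    annotable_fraction: float = 0.15  # share of formulas in the reference table
    mean_log10_intensity: float = 6.0
    sd_log10_intensity: float = 0.5
    class_weights: dict = field(default_factory=lambda: {
        "Lipid metabolism": 0.30,
        "Metabolism of other amino acids": 0.20,
        "Biosynthesis of other secondary metabolites": 0.18,
        "Metabolism of terpenoids and polyketides": 0.14,
        "Carbohydrate metabolism": 0.10,
        "Amino acid metabolism": 0.08,
    })

    def __post_init__(self) -> None:
        if self.n_core <= 0 or any(v <= 0 for v in self.accessory.values()):
            raise ValueError("truth sizes must be positive")
        if len(self.accessory) < 2:
            raise ValueError("need >= 2 groups of accessory formulas")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated acquisition."""

    mass_noise_ppm: float = 0.1
    intensity_cv: float = 0.05
    dropout_prob: float = 0.02
    n_noise_peaks: int = 50
    isotope_satellites: bool = False

    def __post_init__(self) -> None:
        if min(self.mass_noise_ppm, self.intensity_cv, self.dropout_prob,
               self.n_noise_peaks) < 0:
            raise ValueError("noise parameters must be >= 0")
        if not self.dropout_prob < 1:
            raise ValueError("dropout_prob must be < 1")


@dataclass
class TruthSet:
    """Planted formulas, group structure and annotation labels."""

    config: TruthConfig
    seed: int
    counts: np.ndarray               # (n_formulas, 5) CHNOS
    masses: np.ndarray               # neutral monoisotopic masses
    core_idx: np.ndarray
    accessory_idx: dict              # group -> indices into counts
    base_log_intensity: np.ndarray   # per-formula mean log10 intensity
    reference: ReferenceTable
    feature_class: list[str]         # "" = not annotable

    @property
    def n_formulas(self) -> int:
        return len(self.masses)

    def formula_strings(self) -> list[str]:
        return [formula_to_string(c) for c in self.counts]

    def group_of(self, idx: int) -> str:
        for g, ids in self.accessory_idx.items():
            if idx in set(ids.tolist()):
                return g
        return "core"


def _sample_formulas(n: int, rng: np.random.Generator,
                     mass_window: tuple[float, float],
                     constraints: ConstraintSet,
                     existing: set) -> list[tuple[int, int, int, int, int]]:
    """Rejection-sample distinct valid CHNOS formulas with protonated mass
    inside the acquisition window."""
    lo = mass_window[0] - PROTON_MASS
    hi = mass_window[1] - PROTON_MASS
    out: list[tuple[int, int, int, int, int]] = []
    misses = 0
    while len(out) < n:
        if misses > 20000:
            raise ValueError(
                f"could not draw {n} distinct valid formulas in the window "
                f"{mass_window}; lattice capacity exceeded under constraints")
        misses += 1
        # carbon counts follow a right-skewed small-metabolite profile:
        # median composition ~C20 (mass ~350-450 Da), with a lipid/oligomer
        # tail up to C70 (~2000 Da)
        c = 6 + int(rng.gamma(2.2, 8.0))
        if c > 70:
            continue
        dbe = int(rng.integers(0, min(c // 2 + 2, 20)))
        nn = int(rng.choice([0, 1, 2, 3, 4, 5],
                            p=[0.45, 0.22, 0.14, 0.09, 0.06, 0.04]))
        h = 2 * c + 2 + nn - 2 * dbe
        if h < 0:
            continue
        o = int(rng.integers(0, min(int(c * constraints.max_oc_ratio),
                                    constraints.O_range[1]) + 1))
        s = int(rng.random() < 0.08)
        counts = (c, h, nn, o, s)
        if counts in existing:
            continue
        m = monoisotopic_mass(counts)
        if not lo <= m <= hi:
            continue
        cand = FormulaCandidate(counts=counts, theoretical_mass=m, error_ppm=0.0)
        if not check_rules(cand, constraints)[0]:
            continue
        existing.add(counts)
        out.append(counts)
        misses = 0
    return out


def generate_truth(config: TruthConfig = TruthConfig(), seed: int = 0,
                   constraints: ConstraintSet = ConstraintSet()) -> TruthSet:
    """Draw the planted metabolome: core + per-group accessory formulas.

    Deterministic in ``seed``.  Every formula passes the default constraint
    set and sits inside the acquisition window after protonation.  A random
    ``annotable_fraction`` of formulas receives metabolite/pathway/class
    labels, which populate the synthetic reference table.
    """
    rng = np.random.default_rng(seed)
    existing: set = set()
    core = _sample_formulas(config.n_core, rng, config.mass_window,
                            constraints, existing)
    accessory: dict[str, list] = {}
    for group, size in config.accessory.items():
        accessory[group] = _sample_formulas(size, rng, config.mass_window,
                                            constraints, existing)

    all_counts = list(core)
    accessory_idx: dict[str, np.ndarray] = {}
    pos = len(core)
    for group, fs in accessory.items():
        accessory_idx[group] = np.arange(pos, pos + len(fs))
        all_counts.extend(fs)
        pos += len(fs)

    counts = np.array(all_counts, dtype=int)
    masses = np.array([monoisotopic_mass(c) for c in all_counts])
    base = rng.normal(config.mean_log10_intensity, config.sd_log10_intensity,
                      size=len(all_counts))

    classes = list(config.class_weights)
    weights = np.array([config.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()
    feature_class = [""] * len(all_counts)
    records: list[ReferenceRecord] = []
    annotable = rng.random(len(all_counts)) < config.annotable_fraction
    for i in np.nonzero(annotable)[0]:
        cls = classes[int(rng.choice(len(classes), p=weights))]
        pathway = _CLASS_PATHWAYS[cls][int(rng.integers(len(_CLASS_PATHWAYS[cls])))]
        feature_class[i] = cls
        records.append(ReferenceRecord(
            formula=formula_to_string(counts[i]),
            counts=tuple(int(v) for v in counts[i]),
            metabolite=f"synthetic_metabolite_{i:05d}",
            pathway=pathway, metabolic_class=cls))

    return TruthSet(config=config, seed=seed, counts=counts, masses=masses,
                    core_idx=np.arange(len(core)), accessory_idx=accessory_idx,
                    base_log_intensity=base,
                    reference=ReferenceTable(records=records),
                    feature_class=feature_class)


def _strain_groups(truth: TruthSet, n_strains_per_group: dict) -> list[tuple[str, str]]:
    strains = []
    for group, n in n_strains_per_group.items():
        if group not in truth.accessory_idx:
            raise ValueError(f"unknown strain group {group!r}; truth has "
                             f"{sorted(truth.accessory_idx)}")
        for k in range(n):
            strains.append((f"{group}_{k:03d}", group))
    return strains


def simulate_peaklists(truth: TruthSet,
                       noise: NoiseModel = NoiseModel(),
                       n_strains_per_group: dict | None = None,
                       seed: int = 0,
                       fraction: str = "intracellular_SN2",
                       site_of_group: dict | None = None,
                       ) -> tuple[list[PeakList], list[SampleDescriptor]]:
    """Simulate one fraction's peak lists for a set of strains.

    Per strain: protonated m/z = (M + m_p) * (1 + eps), eps ~ N(0, ppm*1e-6);
    intensity log-normal around the formula's base mean, shifted upward by
    ``effect_size_sd`` noise-SDs for the strain group's accessory formulas;
    core features drop out independently with ``dropout_prob``; noise peaks
    land uniformly in the window, at least 3 ppm away from any truth mass;
    optional 13C satellites carry intensity ratio 0.0107 x C.
    """
    if n_strains_per_group is None:
        n_strains_per_group = {g: 10 for g in truth.accessory_idx}
    rng = np.random.default_rng(seed)
    cfg = truth.config
    strains = _strain_groups(truth, n_strains_per_group)
    # log10-domain noise SD equivalent to the intensity CV
    sd_log = math.log10(1.0 + noise.intensity_cv) if noise.intensity_cv > 0 else 0.0
    shift = cfg.effect_size_sd * (sd_log if sd_log > 0 else 0.02)
    ion_masses = truth.masses + PROTON_MASS

    peaklists: list[PeakList] = []
    descriptors: list[SampleDescriptor] = []
    for strain_id, group in strains:
        mu = truth.base_log_intensity.copy()
        mu[truth.accessory_idx[group]] += shift
        present = np.ones(truth.n_formulas, dtype=bool)
        if noise.dropout_prob > 0:
            drop = rng.random(len(truth.core_idx)) < noise.dropout_prob
            present[truth.core_idx[drop]] = False

        idx = np.nonzero(present)[0]
        eps = rng.normal(0.0, noise.mass_noise_ppm * 1e-6, size=len(idx))
        mzs = ion_masses[idx] * (1.0 + eps)
        log_i = rng.normal(mu[idx], sd_log if sd_log > 0 else 0.0)
        intens = np.power(10.0, log_i)

        peaks = [Peak(mz=float(m), intensity=float(v), sn=float(v) / 1e3)
                 for m, v in zip(mzs, intens)]

        if noise.isotope_satellites:
            for m, v, i in zip(mzs, intens, idx):
                c_count = int(truth.counts[i][0])
                sat_i = v * C13_ABUNDANCE * c_count
                if sat_i > 0:
                    peaks.append(Peak(mz=float(m + C13_C12_DELTA),
                                      intensity=float(sat_i),
                                      sn=float(sat_i) / 1e3))

        if noise.n_noise_peaks > 0:
            lo, hi = cfg.mass_window
            added = 0
            while added < noise.n_noise_peaks:
                m = float(rng.uniform(lo, hi))
                if np.min(np.abs(ion_masses - m)) / m * 1e6 < 3.0:
                    continue
                v = float(np.power(10.0, rng.normal(
                    cfg.mean_log10_intensity - 1.5, 0.3)))
                peaks.append(Peak(mz=m, intensity=v, sn=v / 1e3))
                added += 1

        site = (site_of_group or {}).get(group, "SP")
        age = "old" if group == "old" else "new"
        sid = f"{strain_id}_{fraction}"
        peaklists.append(PeakList(
            sample_id=sid, strain_id=strain_id, fraction=fraction,
            site=site, age_class=age, peaks=peaks, mode="positive"))
        descriptors.append(SampleDescriptor(
            sample_id=sid, strain_id=strain_id, fraction=fraction,
            site=site, age_class=age, path=f"{sid}.tsv"))
    return peaklists, descriptors


def simulate_study(truth: TruthSet,
                   noise: NoiseModel = NoiseModel(),
                   n_strains_per_group: dict | None = None,
                   fractions: tuple[str, ...] = ("extracellular_SN1",
                                                 "intracellular_SN2",
                                                 "pellet"),
                   seed: int = 0,
                   ) -> tuple[list[PeakList], list[SampleDescriptor]]:
    """Simulate all cellular fractions (independent intensity structure per
    fraction via distinct per-fraction seeds derived from ``seed``)."""
    all_pl: list[PeakList] = []
    all_desc: list[SampleDescriptor] = []
    for k, fraction in enumerate(fractions):
        pls, descs = simulate_peaklists(
            truth, noise=noise, n_strains_per_group=n_strains_per_group,
            seed=(seed * 1000 + k) % (2 ** 31), fraction=fraction)
        all_pl.extend(pls)
        all_desc.extend(descs)
    return all_pl, all_desc
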