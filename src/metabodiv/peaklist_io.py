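"""Peak-list, manifest and reference-table I/O.

Direct-infusion FT-ICR spectra arrive as per-sample peak lists: one
``(m/z, intensity, S/N)`` triple per detected mass peak.  This module reads
and writes those lists together with the sample manifest (which strain, which
cellular fraction, which saltern, old or new isolate) and a local
formula -> metabolite reference table used for annotation.

Conventions
-----------
* Peak lists are TSV with a header ``mz  intensity  sn``; the ``sn`` column is
  optional (absent = already thresholded upstream, treated as +inf).
* Peaks below the configured signal-to-noise floor (default 1, the export
  threshold of the acquisition) or outside the acquisition window (default
  150-2000 m/z) are dropped on read.
* Manifests are CSV with columns
  ``sample_id, strain_id, fraction, site, age_class, path``.
* Reference tables are CSV with columns
  ``formula, metabolite, pathway, metabolic_class``.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Peak",
    "PeakList",
    "SampleDescriptor",
    "ReferenceRecord",
    "ReferenceTable",
    "FRACTIONS",
    "SITES",
    "AGE_CLASSES",
    "MODES",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_SN",
    "parse_formula",
    "formula_to_string",
    "read_peaklist",
    "write_peaklist",
    "read_manifest",
    "write_manifest",
    "read_reference_table",
    "write_reference_table",
]

#: Controlled vocabularies for sample metadata.
FRACTIONS = ("extracellular_SN1", "intracellular_SN2", "pellet")
SITES = ("SP", "RM", "reference")
AGE_CLASSES = ("old", "new")
MODES = ("positive", "negative")

#: Acquisition window (m/z) and peak-export S/N floor of the instrument method.
DEFAULT_WINDOW = (150.0, 2000.0)
DEFAULT_MIN_SN = 1.0

CHNOS = ("C", "H", "N", "O", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class PeakListError(ValueError):
    """Malformed peak list, manifest or reference table."""


@dataclass(frozen=True)
class Peak:
    """A single mass peak: m/z (Da), intensity (a.u.) and signal-to-noise."""

    mz: float
    intensity: float
    sn: float = math.inf

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise PeakListError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise PeakListError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class SampleDescriptor:
    """Metadata for one measured sample (one strain x fraction extract)."""

    sample_id: str
    strain_id: str
    fraction: str
    site: str
    age_class: str
    path: str | None = None

    def __post_init__(self) -> None:
        _check_enum("fraction", self.fraction, FRACTIONS)
        _check_enum("site", self.site, SITES)
        _check_enum("age_class", self.age_class, AGE_CLASSES)


@dataclass
class PeakList:
    """One sample's peaks, sorted ascending by m/z, plus its metadata."""

    sample_id: str
    strain_id: str
    fraction: str
    site: str
    age_class: str
    peaks: list[Peak] = field(default_factory=list)
    mode: str = "positive"

    def __post_init__(self) -> None:
        _check_enum("fraction", self.fraction, FRACTIONS)
        _check_enum("site", self.site, SITES)
        _check_enum("age_class", self.age_class, AGE_CLASSES)
        _check_enum("mode", self.mode, MODES)
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def filtered(self, min_sn: float = DEFAULT_MIN_SN,
                 window: tuple[float, float] = DEFAULT_WINDOW) -> "PeakList":
        """Return a copy with peaks below ``min_sn`` or outside ``window`` dropped."""
        lo, hi = window
        kept = [p for p in self.peaks if p.sn >= min_sn and lo <= p.mz <= hi]
        return replace(self, peaks=kept)

    @property
    def descriptor(self) -> SampleDescriptor:
        return SampleDescriptor(self.sample_id, self.strain_id, self.fraction,
                                self.site, self.age_class)


@dataclass(frozen=True)
class ReferenceRecord:
    """One row of the local annotation table."""

    formula: str
    counts: tuple[int, int, int, int, int]  # (C, H, N, O, S)
    metabolite: str
    pathway: str
    metabolic_class: str


@dataclass
class ReferenceTable:
    """Local formula -> metabolite/pathway/class lookup (MassTRIX surrogate)."""

    records: list[ReferenceRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (formula_to_string(rec.counts), rec.metabolite)
            if key in seen:
                raise PeakListError(f"duplicate (formula, metabolite) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def by_counts(self) -> dict[tuple[int, int, int, int, int], list[ReferenceRecord]]:
        out: dict[tuple[int, int, int, int, int], list[ReferenceRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.counts, []).append(rec)
        return out


def _check_enum(name: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise PeakListError(
            f"unknown {name} {value!r}; allowed values: {', '.join(allowed)}")


def parse_formula(formula: str) -> tuple[int, int, int, int, int]:
    """Parse a molecular-formula string into (C, H, N, O, S) counts.

    Only the five elements C, H, N, O, S are accepted; anything else (or an
    unparseable token) raises :class:`PeakListError` naming the offending token.
    """
    s = formula.strip()
    if not s:
        raise PeakListError("empty formula string")
    counts = dict.fromkeys(CHNOS, 0)
    pos = 0
    for m in _FORMULA_TOKEN.finditer(s):
        if m.start() != pos:
            raise PeakListError(
                f"unparseable formula {formula!r} at {s[pos:m.start()]!r}")
        elem, num = m.group(1), m.group(2)
        if elem not in counts:
            raise PeakListError(f"non-CHNOS element {elem!r} in formula {formula!r}")
        counts[elem] += int(num) if num else 1
        pos = m.end()
    if pos != len(s):
        raise PeakListError(f"unparseable formula {formula!r} at {s[pos:]!r}")
    return tuple(counts[e] for e in CHNOS)  # type: ignore[return-value]


def formula_to_string(counts: Sequence[int]) -> str:
    """Render (C, H, N, O, S) counts in Hill order (C, H, then alphabetical)."""
    c, h, n, o, s = counts
    parts = []
    for elem, k in (("C", c), ("H", h), ("N", n), ("O", o), ("S", s)):
        if k == 1:
            parts.append(elem)
        elif k > 1:
            parts.append(f"{elem}{k}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def read_peaklist(path: str | Path,
                  metadata: SampleDescriptor,
                  min_sn: float = DEFAULT_MIN_SN,
                  window: tuple[float, float] = DEFAULT_WINDOW,
                  mode: str = "positive") -> PeakList:
    """Read a TSV peak list, applying the S/N floor and acquisition window.

    The file must have a header line with columns ``mz`` and ``intensity``;
    an ``sn`` column is optional (treated as +inf when absent).  Rows that do
    not parse raise :class:`PeakListError` with the 1-based line number.
    An empty result (everything filtered away) is a warning, not an error.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PeakListError(f"{path}: empty file, header required") from None
        header = [h.strip().lower() for h in header]
        try:
            i_mz = header.index("mz")
            i_int = header.index("intensity")
        except ValueError:
            raise PeakListError(
                f"{path}: header must contain 'mz' and 'intensity', got {header}"
            ) from None
        i_sn = header.index("sn") if "sn" in header else None

        peaks: list[Peak] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                mz = float(row[i_mz])
                intensity = float(row[i_int])
                sn = float(row[i_sn]) if i_sn is not None else math.inf
            except (ValueError, IndexError) as exc:
                raise PeakListError(f"{path}: malformed row at line {lineno}: {row!r}"
                                    ) from exc
            peaks.append(Peak(mz=mz, intensity=intensity, sn=sn))

    pl = PeakList(sample_id=metadata.sample_id, strain_id=metadata.strain_id,
                  fraction=metadata.fraction, site=metadata.site,
                  age_class=metadata.age_class, peaks=peaks, mode=mode)
    pl = pl.filtered(min_sn=min_sn, window=window)
    if len(pl) == 0:
        warnings.warn(f"{path}: no peaks remain after S/N >= {min_sn} and "
                      f"window {window} filtering", stacklevel=2)
    return pl


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write a peak list as TSV (``mz intensity sn``) at full float precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["mz", "intensity", "sn"])
        for p in pl.peaks:
            w.writerow([repr(p.mz), repr(p.intensity),
                        "inf" if math.isinf(p.sn) else repr(p.sn)])


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLS = ["sample_id", "strain_id", "fraction", "site", "age_class", "path"]


def read_manifest(path: str | Path) -> list[SampleDescriptor]:
    """Read a sample manifest CSV into descriptors.

    Enforces the fraction/site/age vocabularies, uniqueness of
    (strain, fraction) pairs, and a non-empty peak-list path per row.
    """
    path = Path(path)
    out: list[SampleDescriptor] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PeakListError(f"{path}: empty manifest")
        missing = [c for c in _MANIFEST_COLS if c not in reader.fieldnames]
        if missing:
            raise PeakListError(f"{path}: manifest missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if not row["path"] or not row["path"].strip():
                raise PeakListError(
                    f"{path}: sample {sid!r} (line {lineno}) has no peak-list path")
            desc = SampleDescriptor(
                sample_id=sid, strain_id=row["strain_id"].strip(),
                fraction=row["fraction"].strip(), site=row["site"].strip(),
                age_class=row["age_class"].strip(), path=row["path"].strip())
            key = (desc.strain_id, desc.fraction)
            if key in seen:
                raise PeakListError(
                    f"{path}: duplicate (strain, fraction) pair {key} at line {lineno}")
            seen.add(key)
            out.append(desc)
    return out


def write_manifest(descriptors: Iterable[SampleDescriptor], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MANIFEST_COLS)
        for d in descriptors:
            w.writerow([d.sample_id, d.strain_id, d.fraction, d.site,
                        d.age_class, d.path or ""])


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

_REFERENCE_COLS = ["formula", "metabolite", "pathway", "metabolic_class"]


def read_reference_table(path: str | Path) -> ReferenceTable:
    """Read the 4-column annotation CSV; formula strings are canonicalized."""
    path = Path(path)
    records: list[ReferenceRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PeakListError(f"{path}: empty reference table")
        missing = [c for c in _REFERENCE_COLS if c not in reader.fieldnames]
        if missing:
            raise PeakListError(f"{path}: reference table missing columns {missing}")
        for row in reader:
            counts = parse_formula(row["formula"])
            records.append(ReferenceRecord(
                formula=formula_to_string(counts), counts=counts,
                metabolite=row["metabolite"].strip(),
                pathway=row["pathway"].strip(),
                metabolic_class=row["metabolic_class"].strip()))
    return ReferenceTable(records=records)


def write_reference_table(table: ReferenceTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_REFERENCE_COLS)
        for rec in table.records:
            w.writerow([rec.formula, rec.metabolite, rec.pathway,
                        rec.metabolic_class])
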