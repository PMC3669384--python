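"""Annotation against the local reference table and discrimination reports.

Assigned formulas are matched to a local formula -> metabolite/pathway/class
table on exact element counts (isomers cannot be separated by exact mass, so
every isomer match is retained and flagged).  Tallies of discriminative /
annotable / pathway-assigned metabolites are formatted in the two reporting
styles used for strain-discrimination summaries: integer percentages
(old-vs-new tables) and one-decimal percentages (cluster-discrimination
tables), both rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .peaklist_io import ReferenceTable

__all__ = [
    "DiscriminationReport", "annotate", "class_distribution",
    "format_pct", "build_report",
]


def annotate(assignments: pd.DataFrame, reference: ReferenceTable) -> pd.DataFrame:
    """Match assigned features to the reference table on exact element counts.

    Returns one row per (feature, matching record); features with several
    isomeric matches appear multiple times with ``isomeric=True``.
    Unassigned or unmatched features are absent from the result.
    """
    lookup = reference.by_counts()
    rows = []
    for i, row in assignments.iterrows():
        if not row["formula"]:
            continue
        counts = (int(row["C"]), int(row["H"]), int(row["N"]),
                  int(row["O"]), int(row["S"]))
        matches = lookup.get(counts, [])
        for rec in matches:
            rows.append({"feature": i, "mz": row["mz"], "formula": rec.formula,
                         "metabolite": rec.metabolite, "pathway": rec.pathway,
                         "metabolic_class": rec.metabolic_class,
                         "isomeric": len(matches) > 1})
    return pd.DataFrame(rows, columns=["feature", "mz", "formula", "metabolite",
                                       "pathway", "metabolic_class", "isomeric"])


def class_distribution(annotations: pd.DataFrame,
                       selected_features=None) -> dict[str, pd.Series]:
    """Counts of annotated features per metabolic class and per pathway.

    A feature annotated in k pathways contributes to each of the k tallies
    (deliberate multi-counting, documented).  ``selected_features`` restricts
    to a feature subset (e.g. the discriminative set).
    """
    ann = annotations
    if selected_features is not None:
        ann = ann[ann["feature"].isin(set(selected_features))]
    by_class = (ann.drop_duplicates(["feature", "metabolic_class"])
                ["metabolic_class"].value_counts())
    by_pathway = (ann.drop_duplicates(["feature", "pathway"])
                  ["pathway"].value_counts())
    return {"by_class": by_class, "by_pathway": by_pathway}


def format_pct(numerator: int, denominator: int, style: str = "integer_pct") -> str:
    """Percentage string: 'integer_pct' -> '7%', 'one_decimal_pct' -> '34.7%'.

    Rounding is half away from zero at the printed precision.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    if style == "integer_pct":
        return f"{pct.quantize(Decimal('1'), rounding=ROUND_HALF_UP)}%"
    if style == "one_decimal_pct":
        return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"
    raise ValueError(f"unknown style {style!r}")


@dataclass
class DiscriminationReport:
    """One row of a discrimination summary table."""

    fraction: str
    design: str                       # 'old-vs-new' | 'm-OTU clusters'
    total_metabolome: int
    per_sample_range: tuple[int, int] | None
    discriminative: int
    annotable: int
    with_pathway: int
    style: str = "integer_pct"
    per_group_discriminative: dict[str, int] | None = None
    per_group_annotable: dict[str, int] | None = None

    @property
    def discriminative_pct(self) -> str:
        return format_pct(self.discriminative, self.total_metabolome, self.style)

    @property
    def annotable_pct(self) -> str:
        """Annotable as a share of the discriminative set."""
        if self.discriminative == 0:
            return format_pct(0, 1, self.style)
        return format_pct(self.annotable, self.discriminative, self.style)

    @property
    def with_pathway_pct(self) -> str:
        if self.discriminative == 0:
            return format_pct(0, 1, self.style)
        return format_pct(self.with_pathway, self.discriminative, self.style)

    def to_row(self) -> dict:
        rng = (f"({self.per_sample_range[0]}–{self.per_sample_range[1]})"
               if self.per_sample_range else "")
        return {
            "fraction": self.fraction,
            "total_metabolome": self.total_metabolome,
            "per_sample_range": rng,
            "discriminative": f"{self.discriminative} ({self.discriminative_pct})",
            "annotable": f"{self.annotable} ({self.annotable_pct})",
            "with_pathway": f"{self.with_pathway} ({self.with_pathway_pct})",
        }


def build_report(fraction: str, design: str, total_metabolome: int,
                 discriminative: int, annotable: int, with_pathway: int,
                 per_sample_range: tuple[int, int] | None = None,
                 style: str = "integer_pct",
                 per_group_discriminative: dict[str, int] | None = None,
                 per_group_annotable: dict[str, int] | None = None,
                 ) -> DiscriminationReport:
    """Validated discrimination summary with printed-style percentages."""
    if style not in ("integer_pct", "one_decimal_pct"):
        raise ValueError(f"unknown style {style!r}")
    if not 0 <= annotable <= discriminative <= total_metabolome:
        raise ValueError(
            f"need annotable <= discriminative <= total, got "
            f"{annotable} / {discriminative} / {total_metabolome}")
    if with_pathway > discriminative:
        raise ValueError("with_pathway cannot exceed discriminative")
    return DiscriminationReport(
        fraction=fraction, design=design, total_metabolome=total_metabolome,
        per_sample_range=per_sample_range, discriminative=discriminative,
        annotable=annotable, with_pathway=with_pathway, style=style,
        per_group_discriminative=per_group_discriminative,
        per_group_annotable=per_group_annotable)


def report_table(reports: list[DiscriminationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def report_markdown(reports: list[DiscriminationReport]) -> str:
    df = report_table(reports)
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)
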