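"""Intersectional reporter logic for mapping co-transmitting neurons.

A neuron's transmitter identity is operationally defined by the vesicular
transporter (or synthesis/uptake) loci it expresses: ``eat-4``/VGLUT for
glutamate, ``unc-17``/VAChT for acetylcholine, ``unc-47``/VGAT for GABA,
``cat-1``/VMAT for monoamines, plus the ``tph-1`` (serotonin) and ``dat-1``
(dopamine) synthesis/uptake drivers.  An intersectional cross pairs a
Flippase driver under one locus's promoter with a conditional reporter at a
second locus: fluorescence appears only in cells expressing BOTH, i.e. an
AND gate on the two expression sets.  Split-GFP intersections follow the
same gate.

Co-expression of two transmitter loci is a molecular signature of
co-transmission potential, not proof of co-release — e.g. the pharyngeal I2
neurons express VGAT but lack the GABA synthesis enzyme, so their transmitter
pairing remains a hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "NeuronRecord",
    "ReporterCross",
    "CoTxSummary",
    "labeled_neurons",
    "tally_summary",
    "percentage",
    "load_expression_table",
    "write_expression_table",
    "reference_expression_table",
    "reference_crosses",
]

CATEGORIES = ("sensory", "interneuron", "motor")
REGIONS = ("head", "midbody", "tail", "pharynx")


@dataclass(frozen=True)
class NeuronRecord:
    """One neuron with anatomical labels and its expressed transmitter loci."""

    name: str
    neuron_class: str
    category: str
    region: str
    expressed_loci: frozenset

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r} for {self.name}")
        object.__setattr__(self, "expressed_loci", frozenset(self.expressed_loci))


@dataclass(frozen=True)
class ReporterCross:
    """One intersectional cross: a Flippase driver locus paired with a
    conditional reporter locus (order is immaterial to the AND gate)."""

    driver_locus: str
    reporter_locus: str

    def __post_init__(self) -> None:
        if self.driver_locus == self.reporter_locus:
            raise ValueError("driver and reporter loci must differ")


@dataclass(frozen=True)
class CoTxSummary:
    """Co-transmission tallies: per-category and per-region counts, totals
    and integer percentages (None where a total is zero), plus the overall
    fraction of the nervous system."""

    neurons: frozenset
    by_category: dict
    by_region: dict
    n_cotransmitting: int
    n_total: int
    overall_percent: int | None


def labeled_neurons(cross: ReporterCross, table: list[NeuronRecord]) -> set[str]:
    """Neurons fluorescent under a cross: those expressing both loci."""
    vocabulary = set()
    for rec in table:
        vocabulary |= rec.expressed_loci
    if table:
        for locus in (cross.driver_locus, cross.reporter_locus):
            if locus not in vocabulary:
                raise ValueError(f"locus {locus!r} not present in the table's locus vocabulary")
    wanted = {cross.driver_locus, cross.reporter_locus}
    return {rec.name for rec in table if wanted <= rec.expressed_loci}


def percentage(count: int, total: int) -> int:
    """Integer percentage 100*count/total, rounded half away from zero to
    match printed table precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(count * 100 / total + 0.5)


def tally_summary(table: list[NeuronRecord], crosses: list[ReporterCross]) -> CoTxSummary:
    """Tally co-transmitting neurons over a set of crosses.

    A neuron is co-transmitting if at least one cross labels it; the union
    is taken so a neuron hit by several crosses counts once.  Percentages
    are per-category/per-region counts over the table's own totals.
    """
    cotx: set[str] = set()
    for cross in crosses:
        cotx |= labeled_neurons(cross, table)

    def breakdown(key):
        out = {}
        values = CATEGORIES if key == "category" else REGIONS
        for value in values:
            members = [r for r in table if getattr(r, key) == value]
            total = len(members)
            count = sum(1 for r in members if r.name in cotx)
            out[value] = {
                "count": count,
                "total": total,
                "percent": percentage(count, total) if total else None,
            }
        return out

    n_total = len(table)
    return CoTxSummary(
        neurons=frozenset(cotx),
        by_category=breakdown("category"),
        by_region=breakdown("region"),
        n_cotransmitting=len(cotx),
        n_total=n_total,
        overall_percent=percentage(len(cotx), n_total) if n_total else None,
    )


def load_expression_table(path: str | Path) -> list[NeuronRecord]:
    """Read a TSV expression table (neuron, class, category, region, loci;
    loci semicolon-separated)."""
    df = pd.read_csv(path, sep="\t")
    required = {"neuron", "class", "category", "region", "loci"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[NeuronRecord]:
    records = []
    for row in df.to_dict("records"):
        loci = str(row["loci"]) if pd.notna(row["loci"]) else ""
        records.append(
            NeuronRecord(
                name=row["neuron"],
                neuron_class=row["class"],
                category=row["category"],
                region=row["region"],
                expressed_loci=frozenset(t for t in loci.split(";") if t),
            )
        )
    return records


def write_expression_table(records: list[NeuronRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "neuron": r.name,
                "class": r.neuron_class,
                "category": r.category,
                "region": r.region,
                "loci": ";".join(sorted(r.expressed_loci)),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def _rec(name, cls, category, region, loci) -> NeuronRecord:
    return NeuronRecord(name, cls, category, region, frozenset(loci))


def reference_expression_table() -> list[NeuronRecord]:
    """Expression table transcribed from the published intersectional-cross
    identifications, padded with representative single-transmitter neurons.

    Only neurons named in the main results are included, so genome-wide
    totals (the full 35-neuron co-transmission roster) are NOT reproducible
    from this fixture; supply an atlas-derived table for that.
    """
    return [
        # cholinergic x glutamatergic cross (VAChT driver, VGLUT reporter)
        _rec("AFDL", "AFD", "sensory", "head", {"unc-17", "eat-4"}),
        _rec("AFDR", "AFD", "sensory", "head", {"unc-17", "eat-4"}),
        _rec("M5", "M5", "motor", "pharynx", {"unc-17", "eat-4"}),
        _rec("DVA", "DVA", "interneuron", "tail", {"unc-17", "eat-4"}),
        _rec("PVN", "PVN", "interneuron", "tail", {"unc-17", "eat-4"}),
        # GABAergic x glutamatergic cross
        _rec("I2L", "I2", "interneuron", "pharynx", {"unc-47", "eat-4"}),
        # dopaminergic x glutamatergic cross
        _rec("PDE", "PDE", "sensory", "midbody", {"dat-1", "eat-4"}),
        # GABAergic x cholinergic cross
        _rec("M4", "M4", "motor", "pharynx", {"unc-47", "unc-17"}),
        _rec("SDQR", "SDQ", "interneuron", "head", {"unc-47", "unc-17"}),
        _rec("SMD", "SMD", "motor", "head", {"unc-47", "unc-17"}),
        # serotonergic x cholinergic cross
        _rec("ADF", "ADF", "sensory", "head", {"tph-1", "unc-17"}),
        _rec("HSN", "HSN", "motor", "midbody", {"tph-1", "unc-17"}),
        _rec("VC4", "VC", "motor", "midbody", {"tph-1", "unc-17"}),
        _rec("VC5", "VC", "motor", "midbody", {"tph-1", "unc-17"}),
        # single-transmitter padding so the AND gate has negatives to reject
        _rec("ASEL", "ASE", "sensory", "head", {"eat-4"}),
        _rec("ASER", "ASE", "sensory", "head", {"eat-4"}),
        _rec("AVAL", "AVA", "interneuron", "head", {"unc-17"}),
        _rec("AVAR", "AVA", "interneuron", "head", {"unc-17"}),
        _rec("DA1", "DA", "motor", "midbody", {"unc-17"}),
        _rec("DD1", "DD", "motor", "midbody", {"unc-47"}),
        _rec("RIS", "RIS", "interneuron", "head", {"unc-47"}),
        _rec("NSML", "NSM", "motor", "pharynx", {"tph-1", "cat-1"}),
        _rec("CEPDL", "CEP", "sensory", "head", {"dat-1", "cat-1"}),
        _rec("PVQL", "PVQ", "interneuron", "tail", {"eat-4"}),
    ]


def reference_crosses() -> list[ReporterCross]:
    """The published driver x reporter panel: glutamate and acetylcholine
    reporters intersected with the four major transmitter drivers."""
    return [
        ReporterCross("unc-17", "eat-4"),
        ReporterCross("unc-47", "eat-4"),
        ReporterCross("dat-1", "eat-4"),
        ReporterCross("tph-1", "eat-4"),
        ReporterCross("unc-47", "unc-17"),
        ReporterCross("tph-1", "unc-17"),
        ReporterCross("dat-1", "unc-17"),
    ]
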