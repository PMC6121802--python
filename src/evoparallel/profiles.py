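"""Inclusion filters and the populations x genes mutation-frequency matrix.

Only mutations whose effect can be attributed to a single gene enter the
similarity analysis: synonymous changes, events spanning several genes, and
intergenic mutations outside the upstream promoter window are excluded, as
is anything below the detection/frequency floor.  The surviving calls are
summed per gene to give n_ig, the total mutation frequency in gene g in
population i — the central object of the whole analysis.  n_ig can exceed
1: competing lineages within one population may carry different mutations
in the same gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .mutation_io import (
    Assignment,
    CodingClass,
    GeneAnnotation,
    MutationRecord,
)


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the inclusion filter: every input lands in exactly one bucket."""

    n_input: int
    n_below_frequency_excluded: int
    n_synonymous_excluded: int
    n_multi_gene_excluded: int
    n_ambiguous_excluded: int
    n_distal_intergenic_excluded: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_below_frequency_excluded
            + self.n_synonymous_excluded
            + self.n_multi_gene_excluded
            + self.n_ambiguous_excluded
            + self.n_distal_intergenic_excluded
        )
        if total != self.n_input:
            raise ValueError(
                f"filter accounting broken: buckets sum to {total}, input {self.n_input}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_below_frequency_excluded": self.n_below_frequency_excluded,
            "n_synonymous_excluded": self.n_synonymous_excluded,
            "n_multi_gene_excluded": self.n_multi_gene_excluded,
            "n_ambiguous_excluded": self.n_ambiguous_excluded,
            "n_distal_intergenic_excluded": self.n_distal_intergenic_excluded,
            "n_retained": self.n_retained,
        }


@dataclass
class ProfileMatrix:
    """Populations x genes matrix of summed mutation frequencies (n_ig).

    ``level`` is "gene" or "operon".  Columns are sorted lexicographically;
    all-zero columns are dropped (a gene nobody mutated carries no signal),
    but all-zero *rows* are kept: a population with no retained mutations is
    still a population.
    """

    values: pd.DataFrame
    level: str = "gene"

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def to_wide_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="population")

    def to_long_tsv(self, path: str | Path) -> None:
        long = (
            self.values.stack()
            .rename("frequency")
            .rename_axis(["population", self.level])
            .reset_index()
        )
        long = long[long["frequency"] > 0]
        long.to_csv(path, sep="\t", index=False)


def filter_mutations(
    records: Sequence[MutationRecord],
    min_frequency: float = 0.05,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the single-gene-assignability and frequency filters.

    Retains records that are non-synonymous in the broad sense (anything but
    ``synonymous``), assigned ``within_gene`` or ``upstream_of_gene``, and at
    frequency >= ``min_frequency``.  Exclusion reasons are attributed in a
    fixed precedence order — frequency, synonymous, multi_gene, ambiguous,
    distal_intergenic — so the report is unambiguous even when a record
    fails several filters at once.
    """
    missing = [i for i, r in enumerate(records) if r.context is None]
    if missing:
        raise ValueError(f"records without gene context at indices {missing[:10]}")
    retained: list[MutationRecord] = []
    n_freq = n_syn = n_multi = n_ambig = n_distal = 0
    for rec in records:
        assert rec.context is not None
        if rec.frequency < min_frequency:
            n_freq += 1
        elif rec.coding_class is CodingClass.SYNONYMOUS:
            n_syn += 1
        elif rec.context.assignment is Assignment.MULTI_GENE:
            n_multi += 1
        elif rec.context.assignment is Assignment.AMBIGUOUS:
            n_ambig += 1
        elif rec.context.assignment is Assignment.DISTAL_INTERGENIC:
            n_distal += 1
        else:
            retained.append(rec)
    report = FilterReport(
        n_input=len(records),
        n_below_frequency_excluded=n_freq,
        n_synonymous_excluded=n_syn,
        n_multi_gene_excluded=n_multi,
        n_ambiguous_excluded=n_ambig,
        n_distal_intergenic_excluded=n_distal,
        n_retained=len(retained),
    )
    return retained, report


def build_profiles(
    records: Sequence[MutationRecord],
    populations: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Sum retained mutation frequencies per (population, gene) into n_ig.

    Mutations at different sites in one gene (including its upstream window)
    add up.  ``populations`` fixes the row set and order; populations with
    no retained mutations then appear as all-zero rows.  Column order is
    lexicographic by gene id.
    """
    rows = []
    for rec in records:
        if rec.context is None or not rec.context.locus_tag:
            raise ValueError(f"record lacks a gene assignment: {rec}")
        rows.append((rec.population_id, rec.context.locus_tag, rec.frequency))
    df = pd.DataFrame(rows, columns=["population", "gene", "frequency"])
    if df.empty:
        wide = pd.DataFrame(index=pd.Index(populations or [], name="population"))
    else:
        wide = df.pivot_table(
            index="population", columns="gene", values="frequency",
            aggfunc="sum", fill_value=0.0,
        )
    if populations is not None:
        wide = wide.reindex(list(populations), fill_value=0.0)
    wide = wide.reindex(sorted(wide.columns), axis=1).astype(float)
    wide.index.name = "population"
    wide.columns.name = "gene"
    return ProfileMatrix(values=wide, level="gene")


def collapse_operons(
    matrix: ProfileMatrix, genes: Sequence[GeneAnnotation]
) -> ProfileMatrix:
    """Sum gene columns sharing an operon_id into one operon-level column.

    Genes without an operon annotation keep their own column.  The total
    matrix sum is conserved; the input must be gene-level.
    """
    if matrix.level != "gene":
        raise ValueError("collapse_operons requires a gene-level matrix")
    operon_of = {g.locus_tag: g.operon_id for g in genes if g.operon_id}
    grouping = {c: operon_of.get(c, c) for c in matrix.values.columns}
    collapsed = matrix.values.T.groupby(grouping.get).sum().T
    collapsed = collapsed.reindex(sorted(collapsed.columns), axis=1)
    collapsed.columns.name = "operon"
    return ProfileMatrix(values=collapsed, level="operon")


def count_fixed(
    records: Sequence[MutationRecord], fixation_threshold: float = 1.0
) -> tuple[int, int]:
    """Split retained mutations into fixed (frequency >= threshold) and intermediate."""
    if not (0.0 < fixation_threshold <= 1.0):
        raise ValueError(f"fixation_threshold must be in (0, 1], got {fixation_threshold}")
    n_fixed = sum(1 for r in records if r.frequency >= fixation_threshold)
    return n_fixed, len(records) - n_fixed
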