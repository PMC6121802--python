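"""End-to-end convenience wrappers chaining the pipeline stages.

These functions wire together curation (read, consolidate, assign gene
context), filtering, profile building, similarity, and the randomization
tests, so the CLI and batch scripts stay thin.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from . import inference, similarity
from .mutation_io import (
    GeneAnnotation,
    MutationRecord,
    TreatmentDesign,
    assign_all_contexts,
    consolidate_indels,
    read_design_table,
    read_gene_annotation,
    read_mutation_table,
)
from .profiles import FilterReport, ProfileMatrix, build_profiles, filter_mutations


def curate(
    mutation_path: str | Path,
    annotation_path: str | Path,
    operon_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
    window: int = 150,
    consolidate: bool = True,
) -> tuple[list[MutationRecord], list[GeneAnnotation]]:
    """Read, consolidate, and context-assign a mutation table."""
    records = read_mutation_table(mutation_path, schema)
    if consolidate:
        records = consolidate_indels(records)
    genes = read_gene_annotation(annotation_path, operon_path)
    return assign_all_contexts(records, genes, window), genes


def profiles_from_records(
    records: Sequence[MutationRecord],
    populations: Sequence[str] | None = None,
    min_frequency: float = 0.05,
) -> tuple[list[MutationRecord], FilterReport, ProfileMatrix]:
    """Filter context-assigned records and build the n_ig matrix."""
    retained, report = filter_mutations(records, min_frequency)
    matrix = build_profiles(retained, populations)
    return retained, report, matrix


def headline_statistics(
    mutation_path: str | Path,
    annotation_path: str | Path,
    design_path: str | Path,
    min_frequency: float = 0.05,
    metric: str = "bray_curtis",
    n_permutations: int = 100_000,
    seed: int = 0,
    low_carbon_pair: tuple[str, str] | None = None,
) -> dict:
    """The study's headline numbers from raw input files.

    Returns BC_within, BC_between, the within-vs-between randomization
    p-value, and (if the design names two low-carbon treatments or
    ``low_carbon_pair`` is given) the mean cross-environment similarity
    between the two low-carbon treatments.
    """
    design = read_design_table(design_path)
    records, _ = curate(mutation_path, annotation_path)
    _, report, matrix = profiles_from_records(
        records, design.populations, min_frequency
    )
    sim = similarity.pairwise_matrix(matrix, metric)
    summary = similarity.treatment_summary(sim, design)
    test = inference.test_within_vs_between(sim, design, n_permutations, seed)
    out = {
        "bc_within": summary.bc_within,
        "bc_between": summary.bc_between,
        "within_vs_between_p": test.p_value,
        "filter_report": report.to_dict(),
    }
    if low_carbon_pair is None:
        low = [
            t for t in design.treatments
            if design.factors_of.get(t, {}).get("carbon") == "low"
        ]
        low_carbon_pair = tuple(low[:2]) if len(low) == 2 else None
    if low_carbon_pair:
        key = tuple(sorted(low_carbon_pair))
        out["low_carbon_cross_similarity"] = summary.per_pair_between.get(key)
    return out
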