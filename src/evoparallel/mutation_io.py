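"""Input handling for curated mutation tables, annotation, designs, and competition counts.

The pipeline starts downstream of variant calling: its input is a curated
table of polymorphic mutation calls (one row per mutation per population,
with a population frequency), such as the table a breseq polymorphism-mode
run produces after manual curation.  This module parses and validates those
tables, reads gene annotation from GFF3, and assigns each mutation an
unambiguous gene context (inside a gene, within the 150 bp putative promoter
window upstream of a gene, or neither).

Coordinates are 1-based inclusive throughout, following GFF3 convention.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils


class MutationType(str, Enum):
    SNP = "snp"
    INSERTION = "insertion"
    DELETION = "deletion"
    MOBILE_ELEMENT = "mobile_element"
    OTHER = "other"


class CodingClass(str, Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    NONCODING_IN_GENE = "noncoding_in_gene"
    INTERGENIC = "intergenic"
    MULTI_GENE = "multi_gene"


class Assignment(str, Enum):
    WITHIN_GENE = "within_gene"
    UPSTREAM_OF_GENE = "upstream_of_gene"
    AMBIGUOUS = "ambiguous"
    DISTAL_INTERGENIC = "distal_intergenic"
    MULTI_GENE = "multi_gene"


@dataclass(frozen=True)
class GeneContext:
    """Resolved gene assignment of one mutation.

    ``upstream_distance`` is the distance in bp from the gene's 5' boundary
    (strand-aware), defined only for upstream assignments.
    """

    assignment: Assignment
    locus_tag: str = ""
    upstream_distance: int | None = None

    def __post_init__(self) -> None:
        if self.assignment in (Assignment.WITHIN_GENE, Assignment.UPSTREAM_OF_GENE):
            if not self.locus_tag:
                raise ValueError(f"{self.assignment.value} context requires a locus_tag")
        if self.assignment is Assignment.UPSTREAM_OF_GENE:
            if self.upstream_distance is None or self.upstream_distance < 1:
                raise ValueError("upstream_of_gene requires upstream_distance >= 1")


@dataclass(frozen=True)
class MutationRecord:
    """One curated mutation call in one population.

    ``frequency`` is the fraction of the population carrying the mutation,
    in (0, 1]; 1.0 denotes fixation.
    """

    population_id: str
    replicon: str
    position: int
    mutation_type: MutationType
    coding_class: CodingClass
    locus_tag: str = ""
    frequency: float = 1.0
    context: GeneContext | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency must be in (0, 1], got {self.frequency}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def with_context(self, context: GeneContext) -> "MutationRecord":
        return replace(self, context=context)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene feature: 1-based inclusive span on a replicon, plus optional operon."""

    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str
    operon_id: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"require 1 <= start <= end, got [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class TreatmentDesign:
    """Population -> treatment mapping with the factorial levels of each treatment."""

    populations: list[str]
    treatment_of: dict[str, str]
    factors_of: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in self.populations if p not in self.treatment_of]
        if missing:
            raise ValueError(f"populations without treatment assignment: {missing}")

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.treatment_of[p], None)
        return list(seen)

    def members(self, treatment: str) -> list[str]:
        return [p for p in self.populations if self.treatment_of[p] == treatment]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """One or more rows of an input table failed validation."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


DEFAULT_SCHEMA: Mapping[str, str] = {
    "population": "population",
    "replicon": "replicon",
    "position": "position",
    "mutation_type": "mutation_type",
    "coding_class": "coding_class",
    "locus_tag": "locus_tag",
    "frequency": "frequency",
}


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_mutation_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[MutationRecord]:
    """Read a curated mutation table (TSV or CSV, header required).

    ``schema`` maps canonical field names (keys of :data:`DEFAULT_SCHEMA`)
    to the column names actually present in the file.  Rows with a frequency
    outside (0, 1] or an unparseable value raise :class:`RowError` naming
    the offending line numbers; a missing column raises :class:`SchemaError`.
    """
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    records: list[MutationRecord] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        header = reader.fieldnames or []
        required = ["population", "replicon", "position", "mutation_type",
                    "coding_class", "frequency"]
        for canon in required:
            if colmap[canon] not in header:
                raise SchemaError(
                    f"{path}: missing required column {colmap[canon]!r} (for {canon})"
                )
        for lineno, row in enumerate(reader, start=2):
            try:
                freq = float(row[colmap["frequency"]])
                rec = MutationRecord(
                    population_id=row[colmap["population"]].strip(),
                    replicon=row[colmap["replicon"]].strip(),
                    position=int(row[colmap["position"]]),
                    mutation_type=MutationType(row[colmap["mutation_type"]].strip()),
                    coding_class=CodingClass(row[colmap["coding_class"]].strip()),
                    locus_tag=(row.get(colmap["locus_tag"]) or "").strip(),
                    frequency=freq,
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"{path}:{lineno}: {exc}")
                continue
            records.append(rec)
    if errors:
        raise RowError(errors)
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a TSV readable by :func:`read_mutation_table`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(DEFAULT_SCHEMA))
        for r in records:
            writer.writerow([
                r.population_id, r.replicon, r.position,
                r.mutation_type.value, r.coding_class.value,
                r.locus_tag, repr(r.frequency),
            ])


def read_gene_annotation(
    path: str | Path, operon_table: str | Path | None = None
) -> list[GeneAnnotation]:
    """Read gene features with locus_tag attributes from a GFF3 file.

    Features of type ``gene`` are used when present; if the file carries
    only ``CDS`` features those are used instead.  Features lacking a
    locus_tag are skipped with a single summary warning.  An optional
    operon sidecar TSV (columns locus_tag, operon_id) populates operon_id.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []  # directives-only file: no features
    featuretypes = set(db.featuretypes())
    ftype = "gene" if "gene" in featuretypes else "CDS"
    operons: dict[str, str] = {}
    if operon_table is not None:
        with open(operon_table, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                operons[row["locus_tag"].strip()] = row["operon_id"].strip()
    genes: list[GeneAnnotation] = []
    n_skipped = 0
    if ftype in featuretypes:
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            tags = feat.attributes.get("locus_tag")
            if not tags:
                n_skipped += 1
                continue
            product = feat.attributes.get("product", [""])[0]
            genes.append(GeneAnnotation(
                locus_tag=tags[0], replicon=feat.seqid,
                start=feat.start, end=feat.end, strand=feat.strand,
                operon_id=operons.get(tags[0], ""), product=product,
            ))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} {ftype} feature(s) without locus_tag")
    return genes


def read_design_table(path: str | Path) -> TreatmentDesign:
    """Read a treatment design TSV (population, treatment, carbon, mode, bead)."""
    populations: list[str] = []
    treatment_of: dict[str, str] = {}
    factors_of: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pop = row["population"].strip()
            trt = row["treatment"].strip()
            populations.append(pop)
            treatment_of[pop] = trt
            factors_of[trt] = {
                "carbon": row.get("carbon", "").strip(),
                "mode": row.get("mode", "").strip(),
                "bead": row.get("bead", "").strip(),
            }
    return TreatmentDesign(populations, treatment_of, factors_of)


def consolidate_indels(
    records: Sequence[MutationRecord], frequency_tolerance: float = 0.01
) -> list[MutationRecord]:
    """Merge runs of sequential 1-bp indels into single multi-bp events.

    Adjacent single-base insertions (or deletions) called at consecutive
    positions in the same population and replicon, at effectively equal
    frequency (within ``frequency_tolerance`` of the run's first call), are
    artifacts of calling one multi-base event base-by-base; each such run is
    replaced by one record at the run's first position, at the mean
    frequency of the run.  All other records pass through unchanged.
    Idempotent: a second application changes nothing.
    """
    indel_types = (MutationType.INSERTION, MutationType.DELETION)
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].population_id, records[i].replicon,
                       records[i].mutation_type.value, records[i].position),
    )
    out: list[MutationRecord] = []
    run: list[MutationRecord] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            mean_freq = sum(r.frequency for r in run) / len(run)
            out.append(replace(run[0], frequency=mean_freq))
        run.clear()

    for idx in order:
        rec = records[idx]
        if rec.mutation_type not in indel_types:
            flush()
            out.append(rec)
            continue
        if run and (
            rec.population_id == run[-1].population_id
            and rec.replicon == run[-1].replicon
            and rec.mutation_type == run[-1].mutation_type
            and rec.position == run[-1].position + 1
            and abs(rec.frequency - run[0].frequency) <= frequency_tolerance
        ):
            run.append(rec)
        else:
            flush()
            run.append(rec)
    flush()
    return out


def _upstream_window(gene: GeneAnnotation, window: int) -> tuple[int, int]:
    """1-based inclusive span of the strand-aware upstream window."""
    if gene.strand == "+":
        return max(1, gene.start - window), gene.start - 1
    return gene.end + 1, gene.end + window


def upstream_distance(gene: GeneAnnotation, position: int) -> int:
    """Distance in bp from ``position`` to the gene's 5' boundary (positive upstream)."""
    if gene.strand == "+":
        return gene.start - position
    return position - gene.end


def assign_gene_context(
    record: MutationRecord,
    genes: Sequence[GeneAnnotation],
    window: int = 150,
) -> GeneContext:
    """Assign one mutation to a gene context using the promoter-window rule.

    A position inside exactly one gene span is ``within_gene``; inside two or
    more overlapping genes, ``multi_gene``.  An intergenic position inside
    the strand-aware upstream window (``window`` bp 5' of the start codon)
    of exactly one gene is ``upstream_of_gene``; inside the windows of two
    or more genes, ``ambiguous`` (its effect cannot be attributed to a
    single gene); otherwise ``distal_intergenic``.
    """
    same_rep = [g for g in genes if g.replicon == record.replicon]
    if not same_rep:
        known = sorted({g.replicon for g in genes})
        raise ValueError(
            f"unknown replicon {record.replicon!r}; annotation covers {known}"
        )
    pos = record.position
    containing = [g for g in same_rep if g.start <= pos <= g.end]
    if len(containing) == 1:
        return GeneContext(Assignment.WITHIN_GENE, containing[0].locus_tag)
    if len(containing) >= 2:
        return GeneContext(Assignment.MULTI_GENE)
    upstream_of = []
    for g in same_rep:
        lo, hi = _upstream_window(g, window)
        if lo <= pos <= hi:
            upstream_of.append(g)
    if len(upstream_of) == 1:
        g = upstream_of[0]
        return GeneContext(
            Assignment.UPSTREAM_OF_GENE, g.locus_tag, upstream_distance(g, pos)
        )
    if len(upstream_of) >= 2:
        return GeneContext(Assignment.AMBIGUOUS)
    return GeneContext(Assignment.DISTAL_INTERGENIC)


def assign_all_contexts(
    records: Sequence[MutationRecord],
    genes: Sequence[GeneAnnotation],
    window: int = 150,
) -> list[MutationRecord]:
    """Attach a :class:`GeneContext` to every record.

    Records whose coding class is ``multi_gene`` are assigned multi_gene
    context directly (the upstream curation already established that they
    span several genes).
    """
    out = []
    for rec in records:
        if rec.coding_class is CodingClass.MULTI_GENE:
            out.append(rec.with_context(GeneContext(Assignment.MULTI_GENE)))
        else:
            out.append(rec.with_context(assign_gene_context(rec, genes, window)))
    return out
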