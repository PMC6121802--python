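"""Synthetic experiments with the statistical structure of the bead-transfer study.

The generator emulates a factorial evolution experiment: five treatments
(high/low carbon x biofilm/planktonic growth, plus a high-carbon biofilm
population-size control run with small beads), six replicate populations
each, with one contaminated large-bead replicate dropped so 29 populations
are usable.  Each population accumulates a Poisson number of curated
mutation calls (mean 14.9); a minority fix (probability 51/352) and the
rest segregate at intermediate frequencies uniform on [0.05, 0.95].
Decoy synonymous and distal-intergenic calls are injected at the observed
study fractions (55/432 and 25/432) to exercise the inclusion filters.

Adaptive mutations hit genes drawn from a mixture of gene pools — a global
pool (beneficial everywhere), per-factor-level pools (beneficial under one
carbon level or one growth mode), and treatment-private pools.  The
``divergence`` parameter d interpolates the mixture weights smoothly:
w_private = d^2, w_factor = 2d(1-d) (split equally between the carbon and
mode pools), w_global = (1-d)^2, so d = 0 gives a single shared pool (an
exchangeable null) and d = 1 gives fully treatment-private evolution.  A
``low_carbon_tradeoff`` switch splits the low-carbon factor pool into
disjoint biofilm and planktonic halves, reproducing the scenario in which
the two low-carbon environments share a selection pressure but not its
genetic solutions.

True fitness couples to gene content: a population's selection rate in an
environment rises linearly with the (frequency-weighted) fraction of its
adaptive mutations that fall in that environment's beneficial pools, and
competition colony counts are Poisson-perturbed around the trajectories
those rates imply.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .mutation_io import (
    CodingClass,
    GeneAnnotation,
    MutationRecord,
    MutationType,
    TreatmentDesign,
    write_mutation_table,
)
from .fitness import CompetitionAssay

GENE_LENGTH = 900
INTERGENIC_GAP = 600
UPSTREAM_WINDOW = 150

TREATMENTS = {
    # name: (carbon, mode, bead)
    "HC-planktonic": ("high", "planktonic", "none"),
    "HC-biofilm-L": ("high", "biofilm", "large"),
    "HC-biofilm-S": ("high", "biofilm", "small"),
    "LC-planktonic": ("low", "planktonic", "none"),
    "LC-biofilm": ("low", "biofilm", "large"),
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study's conditions."""

    replicates: int = 6
    include_bead_control: bool = True
    exclude_contaminated: bool = True  # drop one large-bead replicate -> 29 usable
    n_genes: int = 120
    operon_fraction: float = 0.3
    operon_size: int = 3
    global_pool_size: int = 12
    factor_pool_size: int = 10
    treatment_pool_size: int = 8
    divergence: float = 0.6
    pool_concentration: float = 1.5  # Zipf exponent for gene choice within a pool
    bead_control_shares_pool: bool = True  # small-bead control = same environment
    low_carbon_tradeoff: bool = True
    promoter_hotspot: bool = True  # one global-pool gene mutates at a fixed -61 site
    mutations_per_population: float = 14.9
    fixation_probability: float = 51 / 352
    min_frequency: float = 0.05
    max_frequency: float = 0.95
    synonymous_fraction: float = 55 / 432
    distal_intergenic_fraction: float = 25 / 432
    upstream_fraction: float = 0.25
    fitness_intercept: float = 0.5
    fitness_slope: float = 2.5
    fitness_noise: float = 0.15
    ancestral_malthusian: float = 1.0
    initial_density: float = 1e5
    colony_target: float = 200.0
    count_noise: bool = True
    assay_replicates: int = 3
    duration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutations_per_population <= 0:
            raise ValueError("mutations_per_population must be > 0")
        for name in ("divergence", "fixation_probability", "synonymous_fraction",
                     "distal_intergenic_fraction", "upstream_fraction",
                     "operon_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        needed = (
            self.global_pool_size
            + 4 * self.factor_pool_size
            + len(TREATMENTS) * self.treatment_pool_size
        )
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the configured pools ({needed})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one generated experiment, for recovery tests."""

    pool_of_gene: dict[str, str]
    adaptive_content: dict[str, list[tuple[str, float]]]  # pop -> [(gene, freq)]
    content_score: dict[str, dict[str, float]]  # pop -> env -> weighted overlap
    true_selection_rate: dict[str, dict[str, float]]  # pop -> env -> rate/day

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def generate_design(config: SyntheticConfig) -> TreatmentDesign:
    """Factorial design table: treatments x replicate populations."""
    if config.replicates < 1:
        raise ValueError("replicates must be >= 1")
    treatments = {
        name: fac for name, fac in TREATMENTS.items()
        if config.include_bead_control or fac[2] != "small"
    }
    populations: list[str] = []
    treatment_of: dict[str, str] = {}
    for name in treatments:
        for i in range(1, config.replicates + 1):
            if (
                config.exclude_contaminated
                and name == "HC-biofilm-L"
                and i == config.replicates
            ):
                continue  # the cross-contaminated replicate is unusable
            pop = f"{name}_{i}"
            populations.append(pop)
            treatment_of[pop] = name
    factors_of = {
        name: {"carbon": c, "mode": m, "bead": b}
        for name, (c, m, b) in treatments.items()
    }
    return TreatmentDesign(populations, treatment_of, factors_of)


def synthetic_genome(config: SyntheticConfig) -> list[GeneAnnotation]:
    """Evenly spaced forward-strand genes on one replicon, some in operons.

    Genes of 900 bp separated by 600 bp gaps leave room for both the 150 bp
    upstream window and a distal intergenic zone, so every context class is
    reachable.
    """
    genes = []
    n_operon_genes = int(config.operon_fraction * config.n_genes)
    for k in range(config.n_genes):
        start = INTERGENIC_GAP + 1 + k * (GENE_LENGTH + INTERGENIC_GAP)
        operon = (
            f"OPN{k // config.operon_size:03d}" if k < n_operon_genes else ""
        )
        genes.append(GeneAnnotation(
            locus_tag=f"G{k:04d}", replicon="chr1",
            start=start, end=start + GENE_LENGTH - 1, strand="+",
            operon_id=operon, product=f"synthetic protein {k}",
        ))
    return genes


class _PoolModel:
    """Gene pools and the mixture rule mapping a treatment to gene draws."""

    def __init__(self, config: SyntheticConfig, genes: Sequence[GeneAnnotation],
                 rng: np.random.Generator):
        self.config = config
        self.genes = list(genes)
        tags = [g.locus_tag for g in genes]
        order = rng.permutation(len(tags))
        cursor = 0

        def take(n: int) -> list[str]:
            nonlocal cursor
            chunk = [tags[i] for i in order[cursor:cursor + n]]
            cursor += n
            return chunk

        self.global_pool = take(config.global_pool_size)
        self.factor_pools = {
            ("carbon", "high"): take(config.factor_pool_size),
            ("carbon", "low"): take(config.factor_pool_size),
            ("mode", "biofilm"): take(config.factor_pool_size),
            ("mode", "planktonic"): take(config.factor_pool_size),
        }
        self.treatment_pools = {}
        for name, (_, _, bead) in TREATMENTS.items():
            if bead == "small" and config.bead_control_shares_pool:
                continue  # filled below from the large-bead pool
            self.treatment_pools[name] = take(config.treatment_pool_size)
        for name, (carbon, mode, bead) in TREATMENTS.items():
            if name not in self.treatment_pools:
                twin = next(
                    n for n, (c, m, b) in TREATMENTS.items()
                    if (c, m) == (carbon, mode) and b != "small"
                )
                self.treatment_pools[name] = self.treatment_pools[twin]
        self.hotspot_gene = self.global_pool[0] if config.promoter_hotspot else None

    def _pick(self, pool: Sequence[str], rng: np.random.Generator) -> str:
        """Zipf-weighted choice: a few genes in each pool dominate, as in real data."""
        s = self.config.pool_concentration
        if s <= 0:
            return pool[rng.integers(len(pool))]
        w = 1.0 / np.arange(1, len(pool) + 1) ** s
        return pool[rng.choice(len(pool), p=w / w.sum())]

    def pool_label(self, gene: str) -> str:
        if gene in self.global_pool:
            return "global"
        for (fac, level), pool in self.factor_pools.items():
            if gene in pool:
                return f"{fac}:{level}"
        for name, pool in self.treatment_pools.items():
            if gene in pool:
                return f"treatment:{name}"
        return "none"

    def _carbon_pool(self, carbon: str, mode: str) -> list[str]:
        pool = self.factor_pools[("carbon", carbon)]
        if carbon == "low" and self.config.low_carbon_tradeoff:
            half = len(pool) // 2
            return pool[:half] if mode == "biofilm" else pool[half:]
        return pool

    def draw_gene(self, treatment: str, rng: np.random.Generator) -> str:
        d = self.config.divergence
        carbon, mode, _ = TREATMENTS[treatment]
        weights = np.array([(1 - d) ** 2, d * (1 - d), d * (1 - d), d * d])
        weights = weights / weights.sum()
        choice = rng.choice(4, p=weights)
        if choice == 0:
            pool = self.global_pool
        elif choice == 1:
            pool = self._carbon_pool(carbon, mode)
        elif choice == 2:
            pool = self.factor_pools[("mode", mode)]
        else:
            pool = self.treatment_pools[treatment]
        return self._pick(pool, rng)

    def environment_pool(self, treatment: str) -> set[str]:
        """Genes beneficial in ``treatment``'s environment."""
        carbon, mode, _ = TREATMENTS[treatment]
        return (
            set(self.global_pool)
            | set(self._carbon_pool(carbon, mode))
            | set(self.factor_pools[("mode", mode)])
            | set(self.treatment_pools[treatment])
        )


def _draw_frequency(config: SyntheticConfig, rng: np.random.Generator) -> float:
    if rng.random() < config.fixation_probability:
        return 1.0
    return float(rng.uniform(config.min_frequency, config.max_frequency))


_MUTATION_TYPE_WEIGHTS = {
    MutationType.SNP: 0.80,
    MutationType.INSERTION: 0.08,
    MutationType.DELETION: 0.08,
    MutationType.MOBILE_ELEMENT: 0.04,
}


def _draw_mutation_type(rng: np.random.Generator) -> MutationType:
    types = list(_MUTATION_TYPE_WEIGHTS)
    probs = np.array(list(_MUTATION_TYPE_WEIGHTS.values()))
    return types[rng.choice(len(types), p=probs)]


def _adaptive_record(
    pop: str, gene: GeneAnnotation, config: SyntheticConfig,
    rng: np.random.Generator, hotspot: bool,
) -> MutationRecord:
    freq = _draw_frequency(config, rng)
    upstream = rng.random() < config.upstream_fraction
    if upstream:
        offset = 61 if hotspot else int(rng.integers(1, UPSTREAM_WINDOW + 1))
        return MutationRecord(
            pop, gene.replicon, gene.start - offset, MutationType.SNP,
            CodingClass.INTERGENIC, locus_tag="", frequency=freq,
        )
    pos = int(rng.integers(gene.start, gene.end + 1))
    roll = rng.random()
    coding = (
        CodingClass.NONSENSE if roll < 0.05
        else CodingClass.NONCODING_IN_GENE if roll < 0.10
        else CodingClass.NONSYNONYMOUS
    )
    mtype = _draw_mutation_type(rng)
    if mtype is not MutationType.SNP:
        coding = CodingClass.NONCODING_IN_GENE
    return MutationRecord(
        pop, gene.replicon, pos, mtype, coding, gene.locus_tag, freq
    )


def _synonymous_record(
    pop: str, genes: Sequence[GeneAnnotation], config: SyntheticConfig,
    rng: np.random.Generator,
) -> MutationRecord:
    gene = genes[rng.integers(len(genes))]
    pos = int(rng.integers(gene.start, gene.end + 1))
    return MutationRecord(
        pop, gene.replicon, pos, MutationType.SNP, CodingClass.SYNONYMOUS,
        gene.locus_tag, _draw_frequency(config, rng),
    )


def _distal_record(
    pop: str, genes: Sequence[GeneAnnotation], config: SyntheticConfig,
    rng: np.random.Generator,
) -> MutationRecord:
    # land in the gap upstream of a gene but beyond the 150 bp window
    gene = genes[rng.integers(len(genes))]
    offset = int(rng.integers(UPSTREAM_WINDOW + 1, INTERGENIC_GAP - UPSTREAM_WINDOW))
    return MutationRecord(
        pop, gene.replicon, gene.start - offset, MutationType.SNP,
        CodingClass.INTERGENIC, "", _draw_frequency(config, rng),
    )


def generate_mutation_table(
    config: SyntheticConfig,
    design: TreatmentDesign,
    genes: Sequence[GeneAnnotation] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[MutationRecord], SyntheticTruth]:
    """Draw one full mutation table plus its ground truth.

    Per population the number of curated calls is Poisson; each call is a
    synonymous decoy, a distal-intergenic decoy, or an adaptive mutation in
    a pool-drawn gene, with frequencies from the fixed/intermediate law.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = synthetic_genome(config) if genes is None else list(genes)
    pools = _PoolModel(config, genes, rng)
    gene_by_tag = {g.locus_tag: g for g in genes}
    records: list[MutationRecord] = []
    adaptive_content: dict[str, list[tuple[str, float]]] = {}
    for pop in design.populations:
        treatment = design.treatment_of[pop]
        n_calls = int(rng.poisson(config.mutations_per_population))
        content: list[tuple[str, float]] = []
        for _ in range(n_calls):
            roll = rng.random()
            if roll < config.synonymous_fraction:
                records.append(_synonymous_record(pop, genes, config, rng))
            elif roll < config.synonymous_fraction + config.distal_intergenic_fraction:
                records.append(_distal_record(pop, genes, config, rng))
            else:
                tag = pools.draw_gene(treatment, rng)
                rec = _adaptive_record(
                    pop, gene_by_tag[tag], config, rng,
                    hotspot=(tag == pools.hotspot_gene),
                )
                records.append(rec)
                content.append((tag, rec.frequency))
        adaptive_content[pop] = content

    content_score: dict[str, dict[str, float]] = {}
    true_rate: dict[str, dict[str, float]] = {}
    for pop in design.populations:
        content = adaptive_content[pop]
        total = sum(f for _, f in content)
        content_score[pop] = {}
        true_rate[pop] = {}
        for env in design.treatments:
            env_pool = pools.environment_pool(env)
            overlap = sum(f for g, f in content if g in env_pool)
            score = overlap / total if total > 0 else 0.0
            content_score[pop][env] = score
            true_rate[pop][env] = float(
                config.fitness_intercept
                + config.fitness_slope * score
                + rng.normal(0.0, config.fitness_noise)
            )
    truth = SyntheticTruth(
        pool_of_gene={g.locus_tag: pools.pool_label(g.locus_tag) for g in genes},
        adaptive_content=adaptive_content,
        content_score=content_score,
        true_selection_rate=true_rate,
    )
    return records, truth


def generate_competition_counts(
    config: SyntheticConfig,
    design: TreatmentDesign,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> list[CompetitionAssay]:
    """Colony-count assays whose noise-free selection rates equal the truth.

    The ancestor grows at a fixed Malthusian rate per environment; the
    evolved competitor's final density is set so the exact selection rate
    matches ``truth.true_selection_rate``.  With ``count_noise`` on, each
    plated density is replaced by a Poisson colony count at the target
    plating density, rescaled back (zero counts are redrawn).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng

    def observe(density: float) -> float:
        if not config.count_noise:
            return density
        colonies = 0
        while colonies == 0:
            colonies = int(rng.poisson(config.colony_target))
        return colonies * density / config.colony_target

    assays = []
    d0 = config.initial_density
    anc_d2 = d0 * float(np.exp(config.ancestral_malthusian * config.duration))
    for pop in design.populations:
        for env in design.treatments:
            rate = truth.true_selection_rate[pop][env]
            ev_d2 = d0 * float(
                np.exp((config.ancestral_malthusian + rate) * config.duration)
            )
            for rep in range(1, config.assay_replicates + 1):
                assays.append(CompetitionAssay(
                    population_id=pop, environment=env, replicate=rep,
                    evolved_d0=observe(d0), evolved_d2=observe(ev_d2),
                    ancestral_d0=observe(d0), ancestral_d2=observe(anc_d2),
                    duration=config.duration,
                ))
    return assays


def generate_reference_composition_table(
    seed: int = 0,
) -> tuple[list[MutationRecord], TreatmentDesign, list[GeneAnnotation]]:
    """A table with the study's exact accounting, for desk checks.

    432 curated calls over the 29 usable populations: 55 synonymous, 25
    distal intergenic, and 352 single-gene-assignable calls of which
    exactly 51 sit at frequency 1.0.  Gene identities and positions are
    drawn with the usual pool machinery; only the class/frequency counts
    are pinned.
    """
    config = SyntheticConfig(seed=seed)
    rng = np.random.default_rng(seed)
    design = generate_design(config)
    assert len(design.populations) == 29
    genes = synthetic_genome(config)
    pools = _PoolModel(config, genes, rng)
    gene_by_tag = {g.locus_tag: g for g in genes}

    kinds = ["synonymous"] * 55 + ["distal"] * 25 + ["adaptive"] * 352
    rng.shuffle(kinds)
    fixed_flags = np.zeros(352, dtype=bool)
    fixed_flags[rng.choice(352, size=51, replace=False)] = True

    records: list[MutationRecord] = []
    adaptive_i = 0
    for i, kind in enumerate(kinds):
        pop = design.populations[i % len(design.populations)]
        treatment = design.treatment_of[pop]
        if kind == "synonymous":
            records.append(_synonymous_record(pop, genes, config, rng))
        elif kind == "distal":
            records.append(_distal_record(pop, genes, config, rng))
        else:
            tag = pools.draw_gene(treatment, rng)
            gene = gene_by_tag[tag]
            freq = (
                1.0 if fixed_flags[adaptive_i]
                else float(rng.uniform(config.min_frequency, config.max_frequency))
            )
            upstream = rng.random() < config.upstream_fraction
            if upstream:
                offset = 61 if tag == pools.hotspot_gene else int(
                    rng.integers(1, UPSTREAM_WINDOW + 1)
                )
                records.append(MutationRecord(
                    pop, gene.replicon, gene.start - offset, MutationType.SNP,
                    CodingClass.INTERGENIC, "", freq,
                ))
            else:
                pos = int(rng.integers(gene.start, gene.end + 1))
                records.append(MutationRecord(
                    pop, gene.replicon, pos, MutationType.SNP,
                    CodingClass.NONSYNONYMOUS, tag, freq,
                ))
            adaptive_i += 1
    return records, design, genes


# ---------------------------------------------------------------------------
# file emission, matching the formats mutation_io consumes


def write_design_table(design: TreatmentDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("population\ttreatment\tcarbon\tmode\tbead\n")
        for pop in design.populations:
            trt = design.treatment_of[pop]
            fac = design.factors_of.get(trt, {})
            fh.write(
                f"{pop}\t{trt}\t{fac.get('carbon', '')}\t"
                f"{fac.get('mode', '')}\t{fac.get('bead', '')}\n"
            )


def write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=gene-{g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.replicon}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_operon_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_tag\toperon_id\n")
        for g in genes:
            if g.operon_id:
                fh.write(f"{g.locus_tag}\t{g.operon_id}\n")


def write_competition_counts(
    assays: Sequence[CompetitionAssay], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("population\tenvironment\tcompetitor\tday\tcfu_per_ml\treplicate\n")
        for a in assays:
            for competitor, day, dens in (
                ("evolved", 0, a.evolved_d0), ("evolved", 2, a.evolved_d2),
                ("ancestral", 0, a.ancestral_d0), ("ancestral", 2, a.ancestral_d2),
            ):
                fh.write(
                    f"{a.population_id}\t{a.environment}\t{competitor}\t{day}\t"
                    f"{dens!r}\t{a.replicate}\n"
                )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    design: TreatmentDesign
    genes: list[GeneAnnotation]
    records: list[MutationRecord]
    truth: SyntheticTruth
    assays: list[CompetitionAssay] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": outdir / "mutations.tsv",
            "design": outdir / "design.tsv",
            "annotation": outdir / "genome.gff3",
            "operons": outdir / "operons.tsv",
            "counts": outdir / "competition_counts.tsv",
            "truth": outdir / "truth.json",
        }
        write_mutation_table(self.records, paths["mutations"])
        write_design_table(self.design, paths["design"])
        write_gff3(self.genes, paths["annotation"])
        write_operon_table(self.genes, paths["operons"])
        write_competition_counts(self.assays, paths["counts"])
        self.truth.to_json(paths["truth"])
        return paths


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """One complete experiment: design, genome, mutations, truth, assays."""
    config = SyntheticConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    design = generate_design(config)
    genes = synthetic_genome(config)
    records, truth = generate_mutation_table(config, design, genes, rng)
    assays = generate_competition_counts(config, design, truth, rng)
    return SyntheticDataset(config, design, genes, records, truth, assays)
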