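"""Competition-assay fitness and its correlation with genetic similarity.

Fitness of an evolved population against the ancestor is the difference of
the two competitors' Malthusian parameters over a head-to-head competition:

    selection rate (day^-1) = [ln(evolved_d2 / evolved_d0)
                               - ln(ancestral_d2 / ancestral_d0)] / duration

A rate of zero means the competitors are equally fit; positive means the
evolved population is fitter.  (Written with d0/d2 ratios instead, the same
expression flips sign; ``printed_orientation=True`` reproduces that form
for comparison with legacy spreadsheets.)

The downstream question: does a population's mean genetic similarity to the
populations evolved in an environment predict its fitness there?  Because
no linear relationship is assumed, the association is measured with
Kendall's rank correlation (tau-b, tie-corrected).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .mutation_io import TreatmentDesign
from .similarity import SimilarityMatrix, mean_similarity_to_environment


@dataclass(frozen=True)
class CompetitionAssay:
    """Colony-count densities for one evolved-vs-ancestor competition."""

    population_id: str
    environment: str
    evolved_d0: float
    evolved_d2: float
    ancestral_d0: float
    ancestral_d2: float
    duration: float = 2.0
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("evolved_d0", "evolved_d2", "ancestral_d0", "ancestral_d2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class FitnessEstimate:
    population_id: str
    environment: str
    selection_rate: float


@dataclass(frozen=True)
class CorrelationResult:
    environment: str
    tau: float
    p_value: float
    n_points: int
    native_included: bool


def selection_rate(
    assay: CompetitionAssay, printed_orientation: bool = False
) -> FitnessEstimate:
    """Difference of Malthusian parameters, per day.

    Default orientation uses growth ratios ln(d2/d0), so a positive rate
    means the evolved competitor grew faster.  ``printed_orientation``
    swaps to ln(d0/d2) differences (the sign-flipped variant).
    """
    rate = (
        math.log(assay.evolved_d2 / assay.evolved_d0)
        - math.log(assay.ancestral_d2 / assay.ancestral_d0)
    ) / assay.duration
    if printed_orientation:
        rate = -rate
    return FitnessEstimate(assay.population_id, assay.environment, rate)


def read_competition_counts(path: str | Path) -> list[CompetitionAssay]:
    """Read a long-format competition-count TSV into assays.

    Expected columns: population, environment, competitor (evolved |
    ancestral), day (0 | 2), cfu_per_ml, replicate (optional, default 1).
    The four measurements of each (population, environment, replicate) are
    assembled into one :class:`CompetitionAssay`; incomplete quartets raise.
    """
    cells: dict[tuple[str, str, int], dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (
                row["population"].strip(),
                row["environment"].strip(),
                int(row.get("replicate", 1) or 1),
            )
            slot = f"{row['competitor'].strip()}_d{int(float(row['day']))}"
            cells.setdefault(key, {})[slot] = float(row["cfu_per_ml"])
    assays = []
    for (pop, env, rep), slots in sorted(cells.items()):
        needed = {"evolved_d0", "evolved_d2", "ancestral_d0", "ancestral_d2"}
        if set(slots) < needed:
            raise ValueError(
                f"incomplete assay for ({pop}, {env}, replicate {rep}): "
                f"missing {sorted(needed - set(slots))}"
            )
        assays.append(CompetitionAssay(
            population_id=pop, environment=env, replicate=rep,
            evolved_d0=slots["evolved_d0"], evolved_d2=slots["evolved_d2"],
            ancestral_d0=slots["ancestral_d0"], ancestral_d2=slots["ancestral_d2"],
        ))
    return assays


def mean_selection_rates(
    assays: Sequence[CompetitionAssay], printed_orientation: bool = False
) -> list[FitnessEstimate]:
    """Average replicate assays into one selection rate per (population, environment)."""
    acc: dict[tuple[str, str], list[float]] = {}
    for assay in assays:
        est = selection_rate(assay, printed_orientation)
        acc.setdefault((assay.population_id, assay.environment), []).append(
            est.selection_rate
        )
    return [
        FitnessEstimate(pop, env, float(np.mean(rates)))
        for (pop, env), rates in sorted(acc.items())
    ]


def kendall_tau(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Kendall's tau-b with tie correction.

    Exact p-value for small untied samples, normal approximation otherwise
    (scipy's automatic choice).  All-tied input has no defined tau and
    returns (nan, nan).
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return math.nan, math.nan
    res = stats.kendalltau(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def similarity_fitness_correlation(
    sim: SimilarityMatrix,
    fitness: Sequence[FitnessEstimate],
    design: TreatmentDesign,
    environment: str,
    include_native: bool = True,
    alternative: str = "two-sided",
) -> CorrelationResult:
    """Correlate mean similarity-to-environment with fitness in that environment.

    For each population with a fitness measurement in ``environment``, x is
    its mean pairwise similarity to the populations evolved there (its own
    self-similarity excluded if native) and y is its selection rate there.
    ``include_native=False`` restricts to populations whose home treatment
    is not ``environment``.
    """
    rate_of = {
        f.population_id: f.selection_rate
        for f in fitness if f.environment == environment
    }
    xs, ys = [], []
    for pop in sim.populations:
        if pop not in rate_of:
            continue
        if not include_native and design.treatment_of.get(pop) == environment:
            continue
        x = mean_similarity_to_environment(pop, environment, sim, design)
        if math.isnan(x):
            continue
        xs.append(x)
        ys.append(rate_of[pop])
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} usable populations for environment {environment!r}"
        )
    tau, p = kendall_tau(xs, ys, alternative=alternative)
    return CorrelationResult(environment, tau, p, len(xs), include_native)
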