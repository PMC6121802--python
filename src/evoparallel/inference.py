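"""Randomization tests for treatment structure in genetic similarity.

The central question — are replicate populations from the same treatment
more genetically alike than populations from different treatments? — is
answered by a label-permutation test on the precomputed similarity matrix:
the population -> treatment assignment is shuffled (preserving group
sizes), the statistic BC_within - BC_between is recomputed from the fixed
pairwise similarities, and the one-sided p-value is the fraction of
permuted statistics at least as large as the observed one.  When the
number of distinct assignments is small the null is enumerated exhaustively
(the observed assignment is then one member of the null multiset, so p is
never 0); otherwise assignments are sampled and the add-one estimator
p = (1 + #{null >= obs}) / (1 + n_permutations) is used.

A second test asks whether treatments sharing one environmental factor
(carbon level or growth mode) are more alike than treatments sharing
neither: restricted to the four factorial treatments, the statistic is the
difference between the mean per-treatment-pair similarity over "edge"
pairs (one shared factor) and "diagonal" pairs (no shared factor), and the
null again permutes population -> treatment labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mutation_io import MutationRecord, TreatmentDesign
from .profiles import ProfileMatrix
from .similarity import SimilarityMatrix

_TIE_TOL = 1e-12  # permuted stats equal to the observed one count as >= (conservative)


@dataclass
class RandomizationResult:
    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_permutations: int
    p_value: float
    seed: int | None
    exhaustive: bool

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
        }


@dataclass
class MultipleTestResult:
    raw_p: list[float]
    alpha: float
    decisions: list[bool]
    procedure: str = "holm"


def _pair_arrays(sim: SimilarityMatrix, pops: Sequence[str]):
    """Upper-triangle pair index arrays and values, restricted to ``pops``."""
    sub = sim.values.loc[list(pops), list(pops)].to_numpy(dtype=float)
    n = len(pops)
    iu, ju = np.triu_indices(n, k=1)
    vals = sub[iu, ju]
    valid = ~np.isnan(vals)
    return iu, ju, vals, valid


def _within_between_stat(labels: np.ndarray, iu, ju, vals, valid) -> float:
    within = labels[iu] == labels[ju]
    w = vals[within & valid]
    b = vals[~within & valid]
    if w.size == 0 or b.size == 0:
        return math.nan
    return float(w.mean() - b.mean())


def _count_distinct_assignments(counts: Sequence[int]) -> float:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def _permutation_test(
    labels: np.ndarray,
    iu, ju, vals, valid,
    n_permutations: int,
    seed: int | None,
    statistic_name: str,
) -> RandomizationResult:
    observed = _within_between_stat(labels, iu, ju, vals, valid)
    _, counts = np.unique(labels, return_counts=True)
    n_distinct = _count_distinct_assignments(counts)
    if n_distinct <= n_permutations:
        from sympy.utilities.iterables import multiset_permutations

        null = np.array([
            _within_between_stat(np.array(perm), iu, ju, vals, valid)
            for perm in multiset_permutations(list(labels))
        ])
        p = float(np.sum(null >= observed - _TIE_TOL) / null.size)
        return RandomizationResult(
            statistic_name, observed, null, int(null.size), p, seed, True
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = _within_between_stat(rng.permutation(labels), iu, ju, vals, valid)
    p = float((1 + np.sum(null >= observed - _TIE_TOL)) / (1 + n_permutations))
    return RandomizationResult(
        statistic_name, observed, null, n_permutations, p, seed, False
    )


def test_within_vs_between(
    sim: SimilarityMatrix,
    design: TreatmentDesign,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> RandomizationResult:
    """One-sided test of BC_within > BC_between over all treatments."""
    pops = [p for p in sim.populations if p in design.treatment_of]
    labels = np.array([design.treatment_of[p] for p in pops])
    _, counts = np.unique(labels, return_counts=True)
    if np.sum(counts >= 2) < 2:
        raise ValueError("need at least two treatments with >=2 populations each")
    iu, ju, vals, valid = _pair_arrays(sim, pops)
    return _permutation_test(
        labels, iu, ju, vals, valid, n_permutations, seed,
        "bc_within_minus_bc_between",
    )


def test_treatment_pair(
    sim: SimilarityMatrix,
    design: TreatmentDesign,
    treatment_a: str,
    treatment_b: str,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> RandomizationResult:
    """Within-vs-between test restricted to two treatments' populations."""
    pops = [
        p for p in sim.populations
        if design.treatment_of.get(p) in (treatment_a, treatment_b)
    ]
    labels = np.array([design.treatment_of[p] for p in pops])
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or np.any(counts < 2):
        raise ValueError(
            f"both {treatment_a!r} and {treatment_b!r} need >=2 populations"
        )
    iu, ju, vals, valid = _pair_arrays(sim, pops)
    return _permutation_test(
        labels, iu, ju, vals, valid, n_permutations, seed,
        f"bc_within_minus_bc_between[{treatment_a} vs {treatment_b}]",
    )


def _factorial_cells(
    sim: SimilarityMatrix, design: TreatmentDesign
) -> dict[tuple[str, str], str]:
    """Map (carbon, mode) cells to treatments, dropping the bead-size control.

    When two treatments occupy one cell, the one run with small beads is the
    population-size control and is excluded from the factorial contrast.
    """
    cells: dict[tuple[str, str], str] = {}
    for trt in design.treatments:
        if not any(p in sim.populations for p in design.members(trt)):
            continue
        fac = design.factors_of.get(trt, {})
        cell = (fac.get("carbon", ""), fac.get("mode", ""))
        if cell in cells:
            incumbent = cells[cell]
            inc_bead = design.factors_of[incumbent].get("bead", "")
            new_bead = fac.get("bead", "")
            if new_bead == "small" and inc_bead != "small":
                continue
            if inc_bead == "small" and new_bead != "small":
                cells[cell] = trt
                continue
            raise ValueError(
                f"cannot disambiguate treatments {incumbent!r} and {trt!r} "
                f"sharing factorial cell {cell}"
            )
        cells[cell] = trt
    carbons = sorted({c for c, _ in cells})
    modes = sorted({m for _, m in cells})
    if len(cells) != 4 or len(carbons) != 2 or len(modes) != 2:
        wanted = list(itertools.product(carbons or ["?"], modes or ["?"]))
        missing = [c for c in wanted if c not in cells]
        raise ValueError(f"factorial design incomplete; missing cells {missing}")
    return cells


def test_shared_trait(
    sim: SimilarityMatrix,
    design: TreatmentDesign,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> RandomizationResult:
    """Test whether treatments sharing one factor are more alike than those sharing none.

    Restricted to the four (carbon, mode) factorial treatments (the
    bead-size control is excluded).  The statistic is the mean
    per-treatment-pair similarity over "edge" pairs (treatments sharing
    exactly one factor) minus the mean over "diagonal" pairs (sharing
    neither).  The null permutes the population -> treatment labels of the
    factorial populations, preserving group sizes; a permutation scheme
    coarser than this (shuffling whole groups over cells) admits only three
    distinct statistic values and cannot resolve small p-values.
    """
    cells = _factorial_cells(sim, design)
    cell_of_treatment = {trt: cell for cell, trt in cells.items()}
    pops = [
        p for p in sim.populations
        if design.treatment_of.get(p) in cell_of_treatment
    ]
    labels = np.array([design.treatment_of[p] for p in pops])
    treatments = sorted(cell_of_treatment)
    label_idx = np.array([treatments.index(t) for t in labels])
    k = len(treatments)
    # edge/diagonal classification of treatment pairs from cell geometry
    edge_mask = np.zeros((k, k), dtype=bool)
    diag_mask = np.zeros((k, k), dtype=bool)
    for a, b in itertools.combinations(range(k), 2):
        shared = sum(
            x == y for x, y in zip(
                cell_of_treatment[treatments[a]], cell_of_treatment[treatments[b]]
            )
        )
        if shared == 1:
            edge_mask[a, b] = edge_mask[b, a] = True
        elif shared == 0:
            diag_mask[a, b] = diag_mask[b, a] = True

    iu, ju, vals, valid = _pair_arrays(sim, pops)

    def stat(lab: np.ndarray) -> float:
        ga, gb = lab[iu], lab[ju]
        cross = (ga != gb) & valid
        sums = np.zeros((k, k))
        counts = np.zeros((k, k))
        np.add.at(sums, (ga[cross], gb[cross]), vals[cross])
        np.add.at(counts, (ga[cross], gb[cross]), 1.0)
        sums = sums + sums.T
        counts = counts + counts.T
        with np.errstate(invalid="ignore"):
            pair_mean = sums / counts
        iu4 = np.triu_indices(k, 1)
        edges = pair_mean[iu4][edge_mask[iu4]]
        diags = pair_mean[iu4][diag_mask[iu4]]
        if np.any(np.isnan(edges)) or np.any(np.isnan(diags)):
            return math.nan
        return float(edges.mean() - diags.mean())

    observed = stat(label_idx)
    _, counts_per_group = np.unique(label_idx, return_counts=True)
    n_distinct = _count_distinct_assignments(counts_per_group)
    if n_distinct <= n_permutations:
        from sympy.utilities.iterables import multiset_permutations

        null = np.array([
            stat(np.array(perm)) for perm in multiset_permutations(list(label_idx))
        ])
        p = float(np.sum(null >= observed - _TIE_TOL) / null.size)
        return RandomizationResult(
            "edge_minus_diagonal_similarity", observed, null,
            int(null.size), p, seed, True,
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stat(rng.permutation(label_idx))
    p = float((1 + np.sum(null >= observed - _TIE_TOL)) / (1 + n_permutations))
    return RandomizationResult(
        "edge_minus_diagonal_similarity", observed, null,
        n_permutations, p, seed, False,
    )


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> MultipleTestResult:
    """Sequential Bonferroni (Holm) step-down control of family-wise error.

    Sorted ascending, p_(k) is rejected iff p_(j) <= alpha / (m - j + 1) for
    every j <= k; decisions are reported in the input order.
    """
    p = list(p_values)
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    decisions = [False] * m
    order = sorted(range(m), key=lambda i: p[i])
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            decisions[idx] = True
        else:
            break  # step-down: first acceptance stops all later rejections
    return MultipleTestResult(raw_p=p, alpha=alpha, decisions=decisions)


def all_pairwise_tests(
    sim: SimilarityMatrix,
    design: TreatmentDesign,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run test_treatment_pair for every unordered treatment pair, Holm-adjusted."""
    pairs = list(itertools.combinations(design.treatments, 2))
    results = []
    for i, (ta, tb) in enumerate(pairs):
        sub_seed = None if seed is None else seed + i
        results.append(test_treatment_pair(sim, design, ta, tb, n_permutations, sub_seed))
    holm = holm_bonferroni([r.p_value for r in results], alpha)
    return pd.DataFrame({
        "treatment_a": [a for a, _ in pairs],
        "treatment_b": [b for _, b in pairs],
        "observed": [r.observed for r in results],
        "p_value": [r.p_value for r in results],
        "n_permutations": [r.n_permutations for r in results],
        "exhaustive": [r.exhaustive for r in results],
        "holm_reject": holm.decisions,
    })


def gene_parallelism_summary(
    matrix: ProfileMatrix, min_populations: int = 2
) -> pd.DataFrame:
    """Genes mutated in at least ``min_populations`` populations.

    Returns one row per parallel gene with the number of populations hit
    and the per-population summed frequencies (the heat-map values), sorted
    by population count (descending) then gene id.
    """
    counts = (matrix.values > 0).sum(axis=0)
    keep = counts[counts >= min_populations]
    out = matrix.values.loc[:, keep.index].T
    out.insert(0, "n_populations", keep.astype(int))
    out = out.loc[sorted(out.index)]
    out = out.sort_values("n_populations", ascending=False, kind="stable")
    out.index.name = matrix.level
    return out


def nucleotide_parallelism_summary(
    records: Sequence[MutationRecord], min_populations: int = 2
) -> pd.DataFrame:
    """Sites mutated in at least ``min_populations`` distinct populations."""
    rows = [(r.replicon, r.position, r.population_id) for r in records]
    df = pd.DataFrame(rows, columns=["replicon", "position", "population"])
    if df.empty:
        return pd.DataFrame(columns=["replicon", "position", "n_populations", "populations"])
    grouped = (
        df.drop_duplicates()
        .groupby(["replicon", "position"])["population"]
        .agg(
            n_populations="nunique",
            populations=lambda s: ",".join(sorted(s)),
        )
        .reset_index()
    )
    out = grouped[grouped["n_populations"] >= min_populations]
    return out.sort_values(
        ["n_populations", "replicon", "position"], ascending=[False, True, True]
    ).reset_index(drop=True)
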