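"""Pairwise genetic similarity between population mutation profiles.

The headline metric is Bray-Curtis similarity applied to gene-level
mutation-frequency profiles:

    BC_ij = 1 - sum_g |n_ig - n_jg| / sum_g (n_ig + n_jg)

where n_ig is the summed frequency of mutations in gene g in population i.
BC is 0 when two populations share no mutated genes and 1 when they carry
mutations in the same genes at identical frequencies, so it weighs both
which genes were hit and how far the mutations rose.  Jaccard (presence/
absence of mutated genes) and Euclidean distance on the frequency vectors
are provided as alternates for sensitivity analysis.

Populations with an all-zero profile have no defined Bray-Curtis similarity
(the denominator vanishes); such pairs are reported as NaN and excluded
from downstream means, never coerced to 0 or 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mutation_io import TreatmentDesign
from .profiles import ProfileMatrix

METRICS = ("bray_curtis", "jaccard", "euclidean_distance")


def bray_curtis(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Bray-Curtis similarity between two gene-frequency vectors.

    Genes at zero in both vectors do not affect the value.  Returns NaN if
    both vectors are all-zero (undefined, not zero similarity).
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    denom = float(np.sum(p_i + p_j))
    if denom == 0.0:
        return math.nan
    return 1.0 - float(np.sum(np.abs(p_i - p_j))) / denom


def jaccard(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Jaccard similarity of the sets of mutated genes (presence = n_ig > 0)."""
    a = np.asarray(p_i) > 0
    b = np.asarray(p_j) > 0
    union = int(np.sum(a | b))
    if union == 0:
        return math.nan
    return int(np.sum(a & b)) / union


def euclidean_distance(p_i: np.ndarray, p_j: np.ndarray) -> float:
    """Euclidean distance between gene-frequency vectors (a distance, not similarity)."""
    diff = np.asarray(p_i, dtype=float) - np.asarray(p_j, dtype=float)
    return float(np.sqrt(np.sum(diff * diff)))


_METRIC_FUNCS = {
    "bray_curtis": bray_curtis,
    "jaccard": jaccard,
    "euclidean_distance": euclidean_distance,
}


@dataclass
class SimilarityMatrix:
    """Symmetric population x population matrix of one metric.

    ``orientation`` records whether larger values mean more alike
    ("similarity": Bray-Curtis, Jaccard) or less ("distance": Euclidean).
    """

    values: pd.DataFrame
    metric: str
    orientation: str

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    def pair(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def to_square_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="population")

    def to_long_tsv(self, path: str | Path) -> None:
        rows = [
            (a, b, self.metric, self.values.loc[a, b])
            for a, b in itertools.combinations(self.populations, 2)
        ]
        pd.DataFrame(rows, columns=["pop_i", "pop_j", "metric", "value"]).to_csv(
            path, sep="\t", index=False
        )


def pairwise_matrix(matrix: ProfileMatrix, metric: str = "bray_curtis") -> SimilarityMatrix:
    """Compute the chosen metric for every unordered pair of populations.

    All-zero profiles make similarity metrics undefined; pairs involving
    such a population are NaN and a warning names it.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    pops = matrix.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    X = matrix.values.to_numpy(dtype=float)
    empty = [p for p, row in zip(pops, X) if not np.any(row > 0)]
    if empty and metric != "euclidean_distance":
        warnings.warn(
            f"populations with all-zero profiles, similarity undefined: {empty}"
        )
    func = _METRIC_FUNCS[metric]
    n = len(pops)
    out = np.empty((n, n))
    diag = 0.0 if metric == "euclidean_distance" else 1.0
    np.fill_diagonal(out, diag)
    empty_set = set(empty)
    for i in range(n):
        for j in range(i + 1, n):
            if metric != "euclidean_distance" and (
                pops[i] in empty_set or pops[j] in empty_set
            ):
                out[i, j] = out[j, i] = math.nan
            else:
                out[i, j] = out[j, i] = func(X[i], X[j])
    df = pd.DataFrame(out, index=pd.Index(pops, name="population"), columns=pops)
    orientation = "distance" if metric == "euclidean_distance" else "similarity"
    return SimilarityMatrix(values=df, metric=metric, orientation=orientation)


@dataclass
class TreatmentSimilaritySummary:
    """Within- and between-treatment means of a pairwise similarity matrix.

    ``bc_within`` pools every within-treatment pair with equal weight across
    treatments (a single overall number, not a mean of treatment means);
    ``bc_between`` likewise pools every cross-treatment pair.
    """

    bc_within: float
    bc_between: float
    per_treatment_within: dict[str, float] = field(default_factory=dict)
    per_pair_between: dict[tuple[str, str], float] = field(default_factory=dict)


def _pair_values(
    sim: SimilarityMatrix, pairs: Sequence[tuple[str, str]]
) -> list[float]:
    vals = [sim.pair(a, b) for a, b in pairs]
    return [v for v in vals if not math.isnan(v)]


def treatment_summary(
    sim: SimilarityMatrix, design: TreatmentDesign
) -> TreatmentSimilaritySummary:
    """Mean similarity within and between treatments.

    Treatments with fewer than two populations contribute no within pairs
    (warned).  NaN pairs (undefined similarity) are skipped.
    """
    unknown = [p for p in sim.populations if p not in design.treatment_of]
    if unknown:
        raise ValueError(f"populations absent from design: {unknown}")
    pops = sim.populations
    within_pairs: list[tuple[str, str]] = []
    per_treatment: dict[str, float] = {}
    for trt in design.treatments:
        members = [p for p in design.members(trt) if p in pops]
        if len(members) < 2:
            warnings.warn(f"treatment {trt!r} has <2 populations; no within pairs")
            continue
        pairs = list(itertools.combinations(members, 2))
        within_pairs.extend(pairs)
        vals = _pair_values(sim, pairs)
        per_treatment[trt] = float(np.mean(vals)) if vals else math.nan
    between_pairs = [
        (a, b)
        for a, b in itertools.combinations(pops, 2)
        if design.treatment_of[a] != design.treatment_of[b]
    ]
    per_pair: dict[tuple[str, str], float] = {}
    for ta, tb in itertools.combinations(design.treatments, 2):
        key = tuple(sorted((ta, tb)))
        pairs = [
            (a, b) for a, b in between_pairs
            if {design.treatment_of[a], design.treatment_of[b]} == {ta, tb}
        ]
        vals = _pair_values(sim, pairs)
        per_pair[key] = float(np.mean(vals)) if vals else math.nan
    wvals = _pair_values(sim, within_pairs)
    bvals = _pair_values(sim, between_pairs)
    return TreatmentSimilaritySummary(
        bc_within=float(np.mean(wvals)) if wvals else math.nan,
        bc_between=float(np.mean(bvals)) if bvals else math.nan,
        per_treatment_within=per_treatment,
        per_pair_between=per_pair,
    )


def mean_similarity_to_environment(
    focal: str,
    env: str,
    sim: SimilarityMatrix,
    design: TreatmentDesign,
) -> float:
    """Mean similarity between one population and the populations evolved in ``env``.

    For a population native to ``env`` its self-similarity (1 by definition)
    is excluded, so the mean covers only the *other* replicates.
    """
    members = [p for p in design.members(env) if p in sim.populations and p != focal]
    if not members:
        raise ValueError(
            f"environment {env!r} has no populations other than {focal!r}"
        )
    vals = [sim.pair(focal, q) for q in members]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return math.nan
    return float(np.mean(vals))
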