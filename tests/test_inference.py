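"""Randomization tests, Holm step-down, and parallelism summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import evoparallel as ep
from evoparallel.profiles import ProfileMatrix
from evoparallel.inference import (
    all_pairwise_tests,
    gene_parallelism_summary,
    holm_bonferroni,
    nucleotide_parallelism_summary,
)
from evoparallel.inference import test_shared_trait as shared_trait_test
from evoparallel.inference import test_treatment_pair as treatment_pair_test
from evoparallel.inference import test_within_vs_between as within_vs_between_test
from conftest import make_record


def sim_from(vals, pops):
    df = pd.DataFrame(np.asarray(vals, dtype=float), index=pops, columns=pops)
    return ep.SimilarityMatrix(df, "bray_curtis", "similarity")


def design_of(assignment, factors=None):
    pops = list(assignment)
    return ep.TreatmentDesign(pops, dict(assignment), factors or {})


SEPARATED_4 = sim_from(
    [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
    ["A1", "A2", "B1", "B2"],
)
DESIGN_4 = design_of({"A1": "TA", "A2": "TA", "B1": "TB", "B2": "TB"})


class TestWithinVsBetween:
    def test_constant_similarity_gives_p_one(self):
        vals = np.full((4, 4), 0.3)
        np.fill_diagonal(vals, 1.0)
        res = within_vs_between_test(sim_from(vals, DESIGN_4.populations), DESIGN_4)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_separated_toy_exhaustive_p_one_third(self):
        """Hand enumeration: of the 3 distinct 2+2 groupings only the true one
        separates the blocks, so the one-sided p is 1/3."""
        res = within_vs_between_test(SEPARATED_4, DESIGN_4, n_permutations=100)
        assert res.exhaustive
        assert res.observed == 1.0
        assert math.isclose(res.p_value, 1 / 3)

    def test_observed_is_member_of_exhaustive_null(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        res = within_vs_between_test(sim_from(vals, DESIGN_4.populations), DESIGN_4)
        assert res.exhaustive
        assert np.any(np.isclose(res.null_values, res.observed))

    def test_sampled_p_reproducible_given_seed(self, default_analysis):
        sim = default_analysis["sim"]
        design = default_analysis["dataset"].design
        r1 = within_vs_between_test(sim, design, 300, seed=42)
        r2 = within_vs_between_test(sim, design, 300, seed=42)
        assert not r1.exhaustive
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_values, r2.null_values)

    def test_degenerate_single_treatment_rejected(self):
        design = design_of({"A1": "TA", "A2": "TA"})
        with pytest.raises(ValueError, match="two treatments"):
            within_vs_between_test(SEPARATED_4, design)


class TestTreatmentPair:
    def test_identical_profiles_give_p_one(self):
        vals = np.ones((4, 4))
        res = treatment_pair_test(
            sim_from(vals, DESIGN_4.populations), DESIGN_4, "TA", "TB"
        )
        assert res.p_value == 1.0

    def test_separated_toy_exhaustive(self):
        res = treatment_pair_test(SEPARATED_4, DESIGN_4, "TA", "TB",
                                  n_permutations=100)
        assert res.exhaustive
        assert math.isclose(res.p_value, 1 / 3)

    def test_restricts_to_named_treatments(self, default_analysis):
        sim = default_analysis["sim"]
        design = default_analysis["dataset"].design
        res = treatment_pair_test(sim, design, "HC-planktonic", "LC-planktonic",
                                  n_permutations=500, seed=1)
        n_pops = len(design.members("HC-planktonic")) + len(
            design.members("LC-planktonic")
        )
        # exhaustive count for 6+6 is C(12,6) = 924 > 500, so sampling
        assert n_pops == 12 and not res.exhaustive

    def test_undersized_treatment_rejected(self):
        design = design_of({"A1": "TA", "A2": "TA", "B1": "TB", "B2": "TC"})
        with pytest.raises(ValueError, match=">=2"):
            treatment_pair_test(SEPARATED_4, design, "TA", "TB")


def factorial_design(reps=2):
    cells = {
        "T-HB": ("high", "biofilm", "large"),
        "T-HP": ("high", "planktonic", "none"),
        "T-LB": ("low", "biofilm", "large"),
        "T-LP": ("low", "planktonic", "none"),
    }
    assignment, factors = {}, {}
    for trt, (c, m, b) in cells.items():
        factors[trt] = {"carbon": c, "mode": m, "bead": b}
        for i in range(reps):
            assignment[f"{trt}_{i}"] = trt
    return design_of(assignment, factors)


class TestSharedTrait:
    def test_constant_per_pair_similarity_gives_p_one(self):
        design = factorial_design()
        vals = np.full((8, 8), 0.4)
        np.fill_diagonal(vals, 1.0)
        res = shared_trait_test(sim_from(vals, design.populations), design)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_edges_above_diagonals_detected(self):
        design = factorial_design()
        pops = design.populations
        trt = design.treatment_of
        fac = design.factors_of

        def shared(a, b):
            fa, fb = fac[trt[a]], fac[trt[b]]
            return (fa["carbon"] == fb["carbon"]) + (fa["mode"] == fb["mode"])

        vals = np.eye(8)
        for i, j in itertools.combinations(range(8), 2):
            a, b = pops[i], pops[j]
            if trt[a] == trt[b]:
                v = 0.9
            else:
                v = 0.5 if shared(a, b) == 1 else 0.0
            vals[i, j] = vals[j, i] = v
        res = shared_trait_test(sim_from(vals, pops), design)
        assert math.isclose(res.observed, 0.5)
        assert res.exhaustive
        assert res.p_value < 0.05

    def test_exhaustive_p_matches_independent_enumeration(self):
        """Brute-force the label-permutation null with a naive recomputation."""
        design = factorial_design()
        pops = design.populations
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, (8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        sim = sim_from(vals, pops)
        res = shared_trait_test(sim, design)
        assert res.exhaustive

        treatments = sorted(design.treatments)
        cell = {t: (design.factors_of[t]["carbon"], design.factors_of[t]["mode"])
                for t in treatments}

        def naive_stat(labels):
            per_pair = {}
            for ta, tb in itertools.combinations(treatments, 2):
                vs = [vals[i, j]
                      for i, j in itertools.combinations(range(8), 2)
                      if {labels[i], labels[j]} == {ta, tb}]
                per_pair[(ta, tb)] = np.mean(vs)
            edges, diags = [], []
            for (ta, tb), v in per_pair.items():
                n_shared = sum(x == y for x, y in zip(cell[ta], cell[tb]))
                (edges if n_shared == 1 else diags).append(v)
            return np.mean(edges) - np.mean(diags)

        base = [design.treatment_of[p] for p in pops]
        from sympy.utilities.iterables import multiset_permutations

        null = [naive_stat(perm) for perm in multiset_permutations(base)]
        obs = naive_stat(base)
        p_oracle = np.mean([v >= obs - 1e-12 for v in null])
        assert math.isclose(res.observed, obs)
        assert math.isclose(res.p_value, p_oracle)

    def test_missing_cell_named(self):
        design = design_of(
            {"A1": "TA", "A2": "TA", "B1": "TB", "B2": "TB"},
            {"TA": {"carbon": "high", "mode": "biofilm", "bead": "large"},
             "TB": {"carbon": "low", "mode": "biofilm", "bead": "large"}},
        )
        with pytest.raises(ValueError, match="missing cells"):
            shared_trait_test(SEPARATED_4, design)

    def test_bead_control_excluded(self, default_analysis):
        """The small-bead treatment occupies the same factorial cell as the
        large-bead one and must not enter the shared-trait contrast."""
        sim = default_analysis["sim"]
        design = default_analysis["dataset"].design
        res = shared_trait_test(sim, design)
        n_factorial = sum(
            len(design.members(t)) for t in design.treatments
            if design.factors_of[t]["bead"] != "small"
        )
        # the permuted label vector covers only the factorial populations
        assert res.statistic_name == "edge_minus_diagonal_similarity"
        assert res.n_permutations > 0
        assert n_factorial == 23  # 29 usable minus the 6 small-bead controls


class TestHolmBonferroni:
    def test_all_rejected_when_under_stepwise_thresholds(self):
        res = holm_bonferroni([0.001, 0.02, 0.04], alpha=0.05)
        assert res.decisions == [True, True, True]

    def test_none_rejected_when_smallest_fails(self):
        res = holm_bonferroni([0.04, 0.04, 0.04], alpha=0.05)
        assert res.decisions == [False, False, False]

    def test_empty(self):
        assert holm_bonferroni([]).decisions == []

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])

    def test_matches_statsmodels_on_random_inputs(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            p = rng.uniform(0, 1, size=rng.integers(1, 12)).round(4).tolist()
            ours = holm_bonferroni(p, alpha=0.05).decisions
            theirs = multipletests(p, alpha=0.05, method="holm")[0].tolist()
            assert ours == theirs

    def test_never_more_rejections_than_unadjusted(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            p = rng.uniform(0, 1, size=10).tolist()
            holm = sum(holm_bonferroni(p, 0.05).decisions)
            raw = sum(x <= 0.05 for x in p)
            assert holm <= raw


class TestAllPairwiseTests:
    def test_runs_every_unordered_pair_with_holm_column(self, default_analysis):
        sim = default_analysis["sim"]
        design = default_analysis["dataset"].design
        table = all_pairwise_tests(sim, design, n_permutations=200, seed=3)
        assert len(table) == 10  # C(5, 2) treatment pairs
        assert set(table.columns) >= {"p_value", "holm_reject"}
        assert table["holm_reject"].sum() <= (table["p_value"] <= 0.05).sum()


class TestParallelismSummaries:
    def test_gene_in_one_population_absent(self):
        m = ProfileMatrix(pd.DataFrame(
            [[0.5, 0.2], [0.0, 0.1], [0.0, 0.9]],
            index=["P1", "P2", "P3"], columns=["gA", "gB"],
        ))
        summary = gene_parallelism_summary(m)
        assert list(summary.index) == ["gB"]
        assert summary.loc["gB", "n_populations"] == 3

    def test_empty_matrix_gives_empty_summary(self):
        m = ProfileMatrix(pd.DataFrame(index=["P1"], columns=[], dtype=float))
        assert gene_parallelism_summary(m).empty

    def test_distinct_positions_give_empty_site_summary(self):
        records = [make_record(position=p, pop=f"P{p}") for p in (10, 20, 30)]
        assert nucleotide_parallelism_summary(records).empty

    def test_shared_site_counted_once_per_population(self):
        records = [make_record(position=61, pop=p) for p in ("P1", "P2", "P3")]
        records.append(make_record(position=61, pop="P1"))  # duplicate call
        out = nucleotide_parallelism_summary(records)
        assert len(out) == 1
        assert out.loc[0, "n_populations"] == 3
        assert out.loc[0, "populations"] == "P1,P2,P3"

    def test_promoter_hotspot_recovered_from_default_dataset(self, default_analysis):
        """The generator plants a shared promoter site; the site-level summary
        must rediscover it as the top parallel nucleotide."""
        retained = default_analysis["retained"]
        out = nucleotide_parallelism_summary(retained)
        assert not out.empty
        ds = default_analysis["dataset"]
        hot_genes = [g for g in ds.genes
                     if ds.truth.pool_of_gene[g.locus_tag] == "global"]
        top = out.iloc[0]
        assert top["n_populations"] >= 3
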