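"""Cohort analyses: neutrality, parity, regressions, CA, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from cubkit import (
    codon_clustering,
    correlation_battery,
    correspondence_analysis,
    linkage_to_newick,
    mutational_force_regressions,
    neutrality_analysis,
    parity_summary,
    representation_tally,
    rscu_gc3_regression,
)
from cubkit.composition import ParityCoordinates, PositionalComposition


def _comp(gc1, gc2, gc3, pct=None, pct3=None):
    """Hand-built PositionalComposition for cohort-level tests."""
    pct = pct or {b: 25.0 for b in "ATGC"}
    pct_pos = {b: {1: 25.0, 2: 25.0, 3: (pct3 or {}).get(b, 25.0)} for b in "ATGC"}
    return PositionalComposition(
        pct=pct, pct_pos=pct_pos, gc=(gc1 + gc2 + gc3) / 3,
        gc1=gc1, gc2=gc2, gc3=gc3, gc3s=gc3,
    )


class TestNeutrality:
    def test_noiseless_construction(self):
        gc3 = np.linspace(30, 80, 20)
        cohort = [_comp(g12, g12, g3) for g3, g12 in zip(gc3, 0.4 * gc3 + 20)]
        s = neutrality_analysis(cohort)
        assert s.regression.slope == pytest.approx(0.4)
        assert s.relative_neutrality_pct == pytest.approx(40.0)
        assert s.relative_constraint_pct == pytest.approx(60.0)
        assert s.relative_neutrality_pct + s.relative_constraint_pct == 100.0

    def test_pure_mutation_slope_one(self):
        gc3 = np.linspace(30, 80, 10)
        cohort = [_comp(g, g, g) for g in gc3]
        s = neutrality_analysis(cohort)
        assert s.regression.slope == pytest.approx(1.0)
        assert s.relative_constraint_pct == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(17)
        gc3 = rng.uniform(30, 87, size=200)
        gc12 = 0.25 * gc3 + 30 + rng.normal(0, 2, size=200)
        cohort = [_comp(g12, g12, g3) for g3, g12 in zip(gc3, gc12)]
        s = neutrality_analysis(cohort)
        assert 0.20 <= s.regression.slope <= 0.30

    def test_mutation_selection_ratio(self):
        gc3 = np.linspace(30, 80, 10)
        cohort = [_comp(g12, g12, g3) for g3, g12 in zip(gc3, 0.2 * gc3 + 10)]
        s = neutrality_analysis(cohort)
        assert s.mutation_selection_ratio == pytest.approx(0.25)

    def test_constant_gc3_errors(self):
        with pytest.raises(ValueError, match="constant"):
            neutrality_analysis([_comp(40, 40, 50)] * 5)


class TestParity:
    def test_identical_genes_zero_sd(self):
        out = parity_summary([ParityCoordinates(0.4, 0.6)] * 5)
        assert out["at_bias3"] == (pytest.approx(0.4), 0.0)

    def test_two_gene_mean(self):
        out = parity_summary(
            [ParityCoordinates(0.4, 0.5), ParityCoordinates(0.6, 0.5)]
        )
        assert out["at_bias3"][0] == pytest.approx(0.5)

    def test_nan_excluded(self):
        out = parity_summary(
            [ParityCoordinates(0.4, float("nan")),
             ParityCoordinates(0.6, 0.5), ParityCoordinates(0.5, 0.7)]
        )
        assert out["at_bias3"][0] == pytest.approx(0.5)
        assert out["gc_bias3"][0] == pytest.approx(0.6)


class TestMutationalForces:
    def test_identity_relation_r2_one(self):
        rng = np.random.default_rng(2)
        cohort = []
        for _ in range(10):
            vals = dict(zip("ATGC", rng.dirichlet(np.ones(4)) * 100))
            cohort.append(_comp(50, 50, 50, pct=vals, pct3=vals))
        for base, reg in mutational_force_regressions(cohort).items():
            assert reg.r2 == pytest.approx(1.0)
            assert reg.slope == pytest.approx(1.0)

    def test_shuffled_independence_r2_near_zero(self):
        rng = np.random.default_rng(9)
        overall = rng.uniform(10, 40, size=100)
        third = rng.permutation(overall)
        cohort = [
            _comp(50, 50, 50,
                  pct={"A": o, "T": 50 - o / 2, "G": 25 + o / 4, "C": 25 + o / 4},
                  pct3={"A": t, "T": 50 - t / 2, "G": 25 + t / 4, "C": 25 + t / 4})
            for o, t in zip(overall, third)
        ]
        reg = mutational_force_regressions(cohort)["A"]
        assert reg.r2 < 0.05

    def test_affine_relation(self):
        xs = np.linspace(10, 40, 10)
        cohort = [
            _comp(50, 50, 50,
                  pct={"A": 0.5 * x + 10, "T": 40 - 0.3 * x,
                       "G": 25 - 0.1 * x, "C": 25 - 0.1 * x},
                  pct3={"A": x, "T": 50 - x / 2, "G": 25 - x / 4, "C": 25 - x / 4})
            for x in xs
        ]
        reg = mutational_force_regressions(cohort)["A"]
        assert reg.r2 == pytest.approx(1.0)
        assert reg.slope == pytest.approx(0.5)


class TestRscuGc3Regression:
    def _matrix(self, rng, n=200):
        gc3 = rng.uniform(30, 87, size=n)
        ctg = 0.05 * gc3 + rng.normal(0, 0.3, size=n)
        indep = rng.normal(1.0, 0.3, size=n)
        mat = pd.DataFrame({"CTG": ctg, "CGT": indep})
        return mat, gc3

    def test_at3_mirror_of_gc3(self):
        rng = np.random.default_rng(4)
        mat, gc3 = self._matrix(rng)
        a = rscu_gc3_regression("CTG", mat, gc3)
        b = rscu_gc3_regression("CTG", mat, gc3, predictor="at3")
        assert b.slope == pytest.approx(-a.slope)
        assert b.r == pytest.approx(-a.r)
        assert b.r2 == pytest.approx(a.r2)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        mat, gc3 = self._matrix(rng)
        reg = rscu_gc3_regression("CTG", mat, gc3)
        se = 0.3 / (np.std(gc3) * np.sqrt(len(gc3)))
        assert abs(reg.slope - 0.05) < 2 * se

    def test_independent_codon_small_r2(self):
        rng = np.random.default_rng(15)
        mat, gc3 = self._matrix(rng)
        assert rscu_gc3_regression("CGT", mat, gc3).r2 < 0.05


class TestCorrelationBattery:
    def test_exact_lines(self):
        x = np.linspace(0, 10, 20)
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        res = correlation_battery(df, [("x", "up"), ("x", "down")])
        assert res[0].r == pytest.approx(1.0)
        assert res[1].r == pytest.approx(-1.0)
        assert res[0].stars == "***"

    def test_null_distribution_of_r(self):
        rng = np.random.default_rng(21)
        small = 0
        for _ in range(100):
            df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["x", "y"])
            (res,) = correlation_battery(df, [("x", "y")])
            small += abs(res.r) < 0.08
        assert small >= 95

    def test_stars_thresholds(self):
        from cubkit.evo_analyses import CorrelationResult

        assert CorrelationResult("x", "y", 0.5, 0.0005, 47).stars == "***"
        assert CorrelationResult("x", "y", 0.5, 0.005, 47).stars == "**"
        assert CorrelationResult("x", "y", 0.5, 0.04, 47).stars == "*"
        assert CorrelationResult("x", "y", 0.5, 0.5, 47).stars == "NS"

    def test_pairwise_deletion(self):
        df = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan], "y": [2, 4, 6, 8, 100]}
        )
        (res,) = correlation_battery(df, [("x", "y")])
        assert res.n == 4 and res.r == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        (res,) = correlation_battery(df, [("x", "y")])
        assert math.isnan(res.r)


class TestRepresentationTally:
    def test_single_gene_over(self):
        mat = pd.DataFrame({"CTG": [2.0]}, index=["g1"])
        tally = representation_tally(mat)
        assert tally.loc["CTG", "pct_genes_over"] == 100.0

    def test_all_under(self):
        mat = pd.DataFrame({"TCG": [0.1, 0.2, 0.5]})
        tally = representation_tally(mat)
        assert tally.loc["TCG", "pct_genes_under"] == 100.0

    def test_counting_47_genes(self):
        vals = [2.0] * 35 + [1.0] * 12
        tally = representation_tally(pd.DataFrame({"CTG": vals}))
        assert tally.loc["CTG", "pct_genes_over"] == pytest.approx(100 * 35 / 47)

    def test_classes_sum_to_100_and_order_invariant(self):
        rng = np.random.default_rng(30)
        mat = pd.DataFrame({"GCG": rng.uniform(0, 2.5, size=47)})
        t1 = representation_tally(mat)
        t2 = representation_tally(mat.sample(frac=1, random_state=1))
        row = t1.loc["GCG"]
        assert (
            row["pct_genes_over"] + row["pct_genes_under"] + row["pct_genes_random"]
        ) == pytest.approx(100.0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_family_excluded_from_denominator(self):
        mat = pd.DataFrame({"CTG": [2.0, np.nan]})
        tally = representation_tally(mat)
        assert tally.loc["CTG", "n_genes"] == 1
        assert tally.loc["CTG", "pct_genes_over"] == 100.0


class TestCorrespondenceAnalysis:
    def test_inertia_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.uniform(0, 3, size=(10, 8)))
        ca = correspondence_analysis(mat)
        assert ca.inertia_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ca.inertia_fraction) <= 1e-12)

    def test_identical_rows_identical_coords(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0.1, 2, size=6)
        mat = pd.DataFrame([base, base * 2, rng.uniform(0.1, 2, size=6)],
                           index=["a", "b", "c"])
        ca = correspondence_analysis(mat)
        # identical row *profiles* (b = 2a) coincide in chi-square geometry
        np.testing.assert_allclose(
            ca.row_coords.loc["a"], ca.row_coords.loc["b"], atol=1e-10
        )

    def test_rank_one_table_zero_inertia(self):
        r = np.array([1.0, 2.0, 3.0])
        c = np.array([0.5, 1.0, 1.5, 2.0])
        ca = correspondence_analysis(pd.DataFrame(np.outer(r, c)))
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_toy_table_against_eigendecomposition_oracle(self):
        """Axis inertias must match a brute-force eigendecomposition of the
        standardized residual cross-product matrix."""
        x = np.array(
            [
                [10, 5, 3, 2, 1],
                [4, 8, 6, 2, 2],
                [1, 3, 9, 7, 3],
                [2, 2, 5, 9, 4],
                [1, 1, 2, 5, 11],
            ],
            dtype=float,
        )
        ca = correspondence_analysis(pd.DataFrame(x))
        # independent route: explicit residual matrix, eigh of S^T S
        p = x / x.sum()
        r, c = p.sum(1), p.sum(0)
        s = np.zeros_like(p)
        for i in range(5):
            for j in range(5):
                s[i, j] = (p[i, j] - r[i] * c[j]) / math.sqrt(r[i] * c[j])
        eig = np.sort(np.linalg.eigvalsh(s.T @ s))[::-1]
        np.testing.assert_allclose(ca.inertia, eig[: len(ca.inertia)], atol=1e-8)
        assert ca.total_inertia == pytest.approx(eig.sum(), abs=1e-8)


class TestCodonClustering:
    def _planted(self, seed=13, n_genes=40):
        rng = np.random.default_rng(seed)
        factor = rng.normal(size=n_genes)
        cols = {}
        for i in range(5):
            cols[f"GC{i}"] = 1.2 + 0.5 * factor + rng.normal(0, 0.1, n_genes)
        for i in range(5):
            cols[f"AT{i}"] = 0.8 - 0.5 * factor + rng.normal(0, 0.1, n_genes)
        return pd.DataFrame(cols)

    def test_identical_profiles_merge_at_zero(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(0, 2, size=20)
        mat = pd.DataFrame({"a": col, "b": col, "c": rng.uniform(0, 2, 20)})
        link, labels = codon_clustering(mat)
        first = link[0]
        assert {labels[int(first[0])], labels[int(first[1])]} == {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_block_recovery(self):
        mat = self._planted()
        link, labels = codon_clustering(mat)
        assignment = hierarchy.fcluster(link, 2, criterion="maxclust")
        groups = {}
        for lab, grp in zip(labels, assignment):
            groups.setdefault(grp, set()).add(lab)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"GC{i}" for i in range(5)),
            frozenset(f"AT{i}" for i in range(5)),
        }

    def test_merge_heights_monotone(self):
        link, _ = codon_clustering(self._planted(seed=23))
        assert np.all(np.diff(link[:, 2]) >= -1e-12)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(
            {"a": rng.uniform(size=10), "b": rng.uniform(size=10),
             "flat": np.ones(10)}
        )
        _, labels = codon_clustering(mat)
        assert "flat" not in labels

    def test_newick_export_parses(self):
        link, labels = codon_clustering(self._planted())
        nwk = linkage_to_newick(link, labels)
        assert nwk.endswith(";") and nwk.count(",") == len(labels) - 1
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)
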