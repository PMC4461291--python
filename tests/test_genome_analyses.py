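import math

import numpy as np
import pandas as pd
import pytest

from cubkit import (
    call_optimal_codons,
    cluster_species,
    correlation_matrix,
    group_comparison,
    linkage_to_newick,
    neutrality_fit,
    optimal_codon_summary,
    select_expression_tails,
)
from cubkit.cds_io import pool_counts
from cubkit.genome import _chi2_2x2
from tests.conftest import counts_from


def chi2_oracle(a, b, c, d):
    """Explicit expected-count chi-squared on a 2x2 table."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def idx_frame(cai_values):
    return pd.DataFrame(
        {"cai": cai_values},
        index=[f"g{i:04d}" for i in range(len(cai_values))],
    )


class TestExpressionTails:
    def test_five_percent_of_100(self):
        high, low = select_expression_tails(idx_frame(np.linspace(0, 1, 100)))
        assert len(high) == len(low) == 5

    def test_ceil_rule_at_101(self):
        high, low = select_expression_tails(idx_frame(np.linspace(0, 1, 101)))
        assert len(high) == len(low) == 6

    def test_ties_broken_by_gene_id(self):
        vals = np.concatenate([np.zeros(50), np.ones(50)])
        high, low = select_expression_tails(idx_frame(vals))
        assert high == [f"g{i:04d}" for i in range(50, 55)]
        assert low == [f"g{i:04d}" for i in range(5)]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="40"):
            select_expression_tails(idx_frame(np.linspace(0, 1, 30)))

    def test_planted_tier_dominates_high_tail(self, tiered_genome):
        """High-CAI tail recovers the generator's high-expression tier."""
        high, _ = select_expression_tails(tiered_genome["indices"], 0.05)
        truth = tiered_genome["truth"]
        tier = set(truth[truth.tier].index)
        assert len(tier & set(high)) / len(tier) >= 0.7


class TestOptimalCodons:
    def test_hand_computed_chi2(self):
        """2x2 chi-squared on UUU 80/20 vs 50/50, computed by hand."""
        stat, p = _chi2_2x2(80, 20, 50, 50)
        assert stat == pytest.approx(200 * (80 * 50 - 20 * 50) ** 2
                                     / (100 * 100 * 130 * 70))
        assert stat == pytest.approx(19.78, abs=0.005)
        assert p < 0.01

    def test_example_codon_called_strictly_optimal(self):
        high = counts_from({"TTT": 80, "TTC": 20}, "high")
        low = counts_from({"TTT": 50, "TTC": 50}, "low")
        pooled = pool_counts([high, low], "genome")
        table = call_optimal_codons(high, low, pooled)
        assert table.loc["TTT", "optimal_class"] == "*"
        assert not table.loc["TTC", "optimal"]

    def test_identical_pools_nothing_optimal(self):
        pool = counts_from({"TTT": 60, "TTC": 40, "GAA": 30, "GAG": 10})
        table = call_optimal_codons(pool, pool, pool)
        assert not table["optimal"].any()
        assert table.loc["TTT", "chi2"] == pytest.approx(0.0)

    def test_direction_requirement_under_pool_swap(self):
        high = counts_from({"TTT": 80, "TTC": 20, "GAA": 10, "GAG": 40}, "h")
        low = counts_from({"TTT": 50, "TTC": 50, "GAA": 30, "GAG": 20}, "l")
        pooled = pool_counts([high, low], "genome")
        fwd = call_optimal_codons(high, low, pooled)
        rev = call_optimal_codons(low, high, pooled)
        assert not (fwd["optimal"] & rev["optimal"]).any()

    def test_rare_flag_from_genome_rscu(self):
        pool = counts_from({"TTT": 995, "TTC": 5})
        table = call_optimal_codons(pool, pool, pool)
        # RSCU(TTC) = 2*5/1000 = 0.01 < 0.1
        assert table.loc["TTC", "rare"]
        assert not table.loc["TTT", "rare"]

    def test_chi2_matches_oracle_on_random_tables(self, rng):
        for _ in range(500):
            a, b, c, d = rng.integers(1, 200, size=4)
            stat, _ = _chi2_2x2(a, b, c, d)
            assert stat == pytest.approx(chi2_oracle(a, b, c, d), abs=1e-9)

    def test_summary_counts_sum(self, tiered_genome):
        idx = tiered_genome["indices"]
        high, low = select_expression_tails(idx)
        by_id = {c.gene_id: c for c in tiered_genome["counts"]}
        table = call_optimal_codons(
            pool_counts([by_id[g] for g in high], "h"),
            pool_counts([by_id[g] for g in low], "l"),
            tiered_genome["pooled"],
        )
        summary = optimal_codon_summary(table)
        for kind in ("preferred", "optimal", "rare"):
            row = summary.loc[kind]
            assert row["total"] == row["AU"] + row["GC"]
            assert row["AU"] == row["A"] + row["U"]
            assert row["GC"] == row["G"] + row["C"]
            assert row["total"] == int(table[kind].sum())


class TestNeutralityFit:
    def test_identity_line(self):
        df = pd.DataFrame({"p3": [0.1, 0.3, 0.5, 0.7], "p12": [0.1, 0.3, 0.5, 0.7]})
        fit = neutrality_fit(df)
        assert fit.slope == pytest.approx(1.0)
        assert fit.spearman_rho == pytest.approx(1.0)

    def test_constant_p12_slope_zero(self):
        df = pd.DataFrame({"p3": [0.1, 0.3, 0.5], "p12": [0.4, 0.4, 0.4]})
        assert neutrality_fit(df).slope == pytest.approx(0.0)

    def test_closed_form_ols_on_four_points(self):
        df = pd.DataFrame(
            {"p3": [0.1, 0.2, 0.3, 0.4], "p12": [0.2, 0.25, 0.3, 0.35]}
        )
        fit = neutrality_fit(df)
        assert fit.slope == pytest.approx(0.5)
        assert fit.relative_neutrality == pytest.approx(50.0)

    def test_zero_variance_p3_missing_slope(self):
        df = pd.DataFrame({"p3": [0.3, 0.3, 0.3], "p12": [0.1, 0.2, 0.3]})
        assert math.isnan(neutrality_fit(df).slope)

    def test_incomplete_pairs_dropped(self):
        df = pd.DataFrame(
            {
                "p3": [0.1, np.nan, 0.3, 0.4, 0.5],
                "p12": [0.2, 0.25, np.nan, 0.35, 0.4],
            }
        )
        # only rows 0, 3 and 4 are complete
        assert neutrality_fit(df).n_genes == 3


class TestCorrelationMatrix:
    def test_diagonal_and_antisymmetry(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame(
            {"gc_cds": x, "p1": -x, "p2": x**2, "p12": x, "p3": x, "enc": -x}
        )
        rho, p = correlation_matrix(df)
        assert np.allclose(np.diag(rho), 1.0)
        assert rho.loc["gc_cds", "p1"] == pytest.approx(-1.0)
        assert rho.equals(rho.T)

    def test_constant_column_undefined(self):
        df = pd.DataFrame(
            {
                "gc_cds": np.linspace(0, 1, 10),
                "p1": np.ones(10),
                "p2": np.linspace(1, 0, 10),
                "p12": np.linspace(0, 1, 10),
                "p3": np.linspace(0, 1, 10),
                "enc": np.linspace(0, 1, 10),
            }
        )
        rho, _ = correlation_matrix(df)
        assert math.isnan(rho.loc["gc_cds", "p1"])

    def test_p12_tracks_its_inputs(self, small_composition):
        rho, _ = correlation_matrix(small_composition.assign(enc=1.0),
                                    columns=["p1", "p2", "p12"])
        assert rho.loc["p12", "p1"] > 0


class TestGroupComparison:
    @staticmethod
    def species(vals):
        return pd.DataFrame({"cai": vals, "enc": vals})

    def test_identical_groups_null(self):
        grp = self.species([1.0, 2.0, 3.0])
        out = group_comparison({"a": grp, "b": grp.copy()}, group_a=["a"])
        assert out.loc["cai", "anova_F"] == pytest.approx(0.0)
        assert out.loc["cai", "anova_p"] == pytest.approx(1.0)

    def test_planted_difference_significant(self, rng):
        sp = {
            "a": self.species(rng.normal(0, 1, 50)),
            "b": self.species(rng.normal(10, 1, 50)),
        }
        out = group_comparison(sp, group_a=["a"])
        assert out.loc["cai", "anova_p"] < 0.01
        assert out.loc["cai", "t_p"] < 0.01

    def test_label_permutation_destroys_significance(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(10, 1, 60)
        mixed = np.concatenate([a, b])
        rng.shuffle(mixed)
        sp = {
            "a": self.species(mixed[:60]),
            "b": self.species(mixed[60:]),
        }
        out = group_comparison(sp, group_a=["a"])
        assert out.loc["cai", "anova_p"] > 0.05


class TestClusterSpecies:
    def test_identical_vectors_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                           index=["a", "b", "c"])
        linkage, labels = cluster_species(mat)
        assert linkage[0, 2] == pytest.approx(0.0)

    def test_hand_run_average_linkage(self):
        """d(A,B)=1, d(A,C)=d(B,C)=10: {A,B} first, C joins at height 10."""
        mat = pd.DataFrame({"x": [0.0, 1.0, 0.0], "y": [0.0, 0.0, 10.0]},
                           index=["A", "B", "C"])
        linkage, labels = cluster_species(mat)
        assert labels == ["A", "B", "C"]
        assert linkage[0, 2] == pytest.approx(1.0)
        # average of d(A,C)=10 and d(B,C)=sqrt(101)
        assert linkage[1, 2] == pytest.approx((10 + math.sqrt(101)) / 2)

    def test_newick_contains_all_labels(self):
        mat = pd.DataFrame(np.eye(3), index=["sp1", "sp2", "sp3"])
        newick = linkage_to_newick(*cluster_species(mat))
        for label in ("sp1", "sp2", "sp3"):
            assert label in newick
        assert newick.endswith(";")
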