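import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clonoscope.stats import (
    compare_layer_counts,
    excitatory_fraction,
    laminar_contribution,
    mann_whitney,
    pair_distances,
    sidak_adjust,
    subsample_pairs,
    summarize_dispersion,
)


def _cells(rows):
    cols = ["cell_id", "x_um", "y_um", "layer", "clone_id"]
    df = pd.DataFrame(rows, columns=cols)
    df["clone_id"] = df["clone_id"].astype("Int64")
    return df


class TestPairDistances:
    def test_single_related_pair_distance(self):
        cells = _cells([[0, 0.0, 0.0, "L4", 1], [1, 3.0, 4.0, "L4", 1]])
        pairs = pair_distances(cells)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["relatedness"] == "related"
        assert row["layer_class"] == "same"
        assert row["distance_um"] == pytest.approx(5.0)

    def test_no_self_pairs(self):
        cells = _cells(
            [[0, 0.0, 0.0, "L4", 1], [1, 1.0, 0.0, "L4", 1], [2, 2.0, 0.0, "L5", 2]]
        )
        pairs = pair_distances(cells)
        assert len(pairs) == 3
        assert (pairs["distance_um"] > 0).all()
        assert (pairs["cell_id_a"] != pairs["cell_id_b"]).all()

    def test_fewer_than_two_cells_gives_empty_table(self):
        assert len(pair_distances(_cells([[0, 0.0, 0.0, "L4", 1]]))) == 0

    def test_unlabeled_cells_excluded(self):
        cells = _cells(
            [[0, 0.0, 0.0, "L4", 1], [1, 1.0, 0.0, "L4", 1],
             [2, 2.0, 0.0, "L4", pd.NA]]
        )
        pairs = pair_distances(cells)
        assert set(pairs["cell_id_a"]) | set(pairs["cell_id_b"]) == {0, 1}

    def test_match_related_policy_balances_counts(self):
        rows = [[i, float(i), 0.0, "L4", i // 2] for i in range(20)]
        pairs = pair_distances(_cells(rows), sampling_policy="match-related", seed=0)
        counts = pairs["relatedness"].value_counts()
        assert counts["related"] == counts["unrelated"] == 10

    def test_sections_are_not_mixed(self):
        cells = _cells([[0, 0.0, 0.0, "L4", 1], [1, 1.0, 0.0, "L4", 2]])
        cells["section"] = ["s1", "s2"]
        assert len(pair_distances(cells)) == 0

    def test_subsample_caps_each_category(self):
        rows = [[i, float(i), 0.0, "L4", i // 2] for i in range(30)]
        pairs = pair_distances(_cells(rows))
        capped = subsample_pairs(pairs, 5, seed=1)
        for _, sub in capped.groupby(["relatedness", "layer_class"]):
            assert len(sub) <= 5


class TestSummarizeDispersion:
    def test_identical_distances_have_zero_sd(self):
        cells = _cells(
            [[0, 0.0, 0.0, "L4", 1], [1, 5.0, 0.0, "L4", 1],
             [2, 0.0, 10.0, "L5", 2], [3, 5.0, 10.0, "L5", 2]]
        )
        summary = summarize_dispersion(pair_distances(cells))
        row = summary.table.loc[("related", "same")]
        assert row["n"] == 2 and row["sd_um"] == 0.0

    def test_hand_built_five_pair_table(self):
        pairs = pd.DataFrame(
            {
                "cell_id_a": [0, 0, 0, 1, 1],
                "cell_id_b": [1, 2, 3, 2, 3],
                "relatedness": ["related", "related", "unrelated",
                                "unrelated", "unrelated"],
                "layer_class": ["same", "different", "same", "same", "different"],
                "distance_um": [10.0, 30.0, 50.0, 70.0, 90.0],
            }
        )
        summary = summarize_dispersion(pairs)
        t = summary.table
        assert t.loc[("related", "same"), "mean_um"] == 10.0
        assert t.loc[("related", "total"), "mean_um"] == 20.0
        assert t.loc[("unrelated", "same"), "mean_um"] == 60.0
        assert t.loc[("unrelated", "same"), "sd_um"] == pytest.approx(
            np.std([50, 70], ddof=1)
        )
        assert t.loc[("unrelated", "different"), "n"] == 1

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        rows = [[i, *rng.uniform(0, 100, 2), "L4", i // 2] for i in range(12)]
        cells = _cells(rows)
        base = summarize_dispersion(pair_distances(cells)).table
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        moved = cells.copy()
        xy = moved[["x_um", "y_um"]].to_numpy() @ rot.T + [123.0, -45.0]
        moved[["x_um", "y_um"]] = xy
        other = summarize_dispersion(pair_distances(moved)).table
        pd.testing.assert_frame_equal(base, other)

    def test_empty_pair_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_dispersion(pd.DataFrame(columns=["distance_um"]))


class TestMannWhitney:
    def test_small_two_sided_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_well_separated_large_samples(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 80)
        b = rng.normal(5, 1, 80)
        _, p = mann_whitney(a, b)
        assert p < 1e-4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 3), (2, 5), (4, 4), (3, 5)])
    def test_exact_matches_full_permutation_enumeration(self, na, nb):
        """Oracle: enumerate every permutation of the pooled sample, take the
        first na values as group a, and count U values at least as extreme."""
        rng = np.random.default_rng(na * 10 + nb)
        a = np.round(rng.uniform(0, 5, na), 0)  # ties likely
        b = np.round(rng.uniform(0, 5, nb), 0)
        u_mine, p_mine = mann_whitney(a, b, method="exact")

        pooled = np.concatenate([a, b])
        mean_u = na * nb / 2

        def u_of(x, y):
            return sum(
                1.0 if xi > yi else 0.5 if xi == yi else 0.0
                for xi in x for yi in y
            )

        u_obs = u_of(a, b)
        assert u_mine == pytest.approx(u_obs)
        extreme = total = 0
        for perm in itertools.permutations(pooled):
            u = u_of(perm[:na], perm[na:])
            total += 1
            extreme += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
        assert p_mine == pytest.approx(extreme / total)

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        a = rng.normal(size=6)
        b = rng.normal(0.5, 1, size=5)
        u_mine, p_mine = mann_whitney(a, b, method="exact")
        res = mannwhitneyu(a, b, method="exact")
        assert u_mine == pytest.approx(res.statistic)
        assert p_mine == pytest.approx(res.pvalue)

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    def test_one_sided_alternatives(self, alternative):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        a = rng.normal(size=5)
        b = rng.normal(1, 1, size=6)
        u_mine, p_mine = mann_whitney(a, b, alternative=alternative, method="exact")
        res = mannwhitneyu(a, b, alternative=alternative, method="exact")
        assert p_mine == pytest.approx(res.pvalue)


class TestSidak:
    def test_m_one_is_identity(self):
        assert sidak_adjust(0.04, 1) == pytest.approx(0.04)

    def test_zero_stays_zero(self):
        assert sidak_adjust(0.0, 10) == 0.0

    def test_closed_form(self):
        assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3, abs=1e-15)

    def test_adjusted_at_least_raw_and_monotone_in_m(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        a1 = sidak_adjust(p, 2)
        a2 = sidak_adjust(p, 5)
        assert np.all(a1 >= p) and np.all(a2 >= a1)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.003, 0.04, 0.2, 0.77]
        mine = sidak_adjust(p)
        _, theirs, _, _ = multipletests(p, method="sidak")
        assert np.allclose(mine, theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust([0.5, 1.2])


class TestCompareLayerCounts:
    G1 = {"L2/3": [120.0, 118, 125], "L4": [100.0, 95, 105], "L5": [80.0, 82, 78]}

    def test_identical_groups(self):
        out = compare_layer_counts(self.G1, self.G1)
        assert np.allclose(out["percent_change"], 0.0)
        assert np.allclose(out["p_sidak"], 1.0)

    def test_exact_proportional_reduction(self):
        g2 = {k: [0.57 * v for v in vals] for k, vals in self.G1.items()}
        out = compare_layer_counts(self.G1, g2).set_index("layer")
        assert out.loc["L4", "percent_change"] == pytest.approx(-43.0)

    def test_scale_invariance_of_t_and_p(self):
        g2 = {k: [v * 1.1 + 3 for v in vals] for k, vals in self.G1.items()}
        a = compare_layer_counts(self.G1, g2)
        b = compare_layer_counts(
            {k: [2 * v for v in vals] for k, vals in self.G1.items()},
            {k: [2 * v for v in vals] for k, vals in g2.items()},
        )
        assert np.allclose(a["t"], b["t"]) and np.allclose(a["p_raw"], b["p_raw"])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_layer_counts({"L4": [1.0]}, {"L4": [2.0, 3.0]})


class TestLaminarContribution:
    def test_full_labeling_gives_fraction_one(self):
        out = laminar_contribution({"L4": 50, "L5": 30}, {"L4": 50, "L5": 30})
        assert np.allclose(out["fraction"], 1.0)

    def test_two_layer_arithmetic(self):
        out = laminar_contribution(
            {"L4": 40, "L5": 30}, {"L4": 100, "L5": 100},
            layer_groups={"both": ("L4", "L5")},
        ).set_index("layer")
        assert out.loc["L4", "fraction"] == pytest.approx(0.40)
        assert out.loc["L5", "fraction"] == pytest.approx(0.30)
        assert out.loc["both", "fraction"] == pytest.approx(0.35)

    def test_aggregate_is_count_weighted_mean(self):
        labeled = {"L2/3": 60, "L4": 10}
        total = {"L2/3": 100, "L4": 400}
        out = laminar_contribution(
            labeled, total, layer_groups={"supra": ("L2/3", "L4")}
        ).set_index("layer")
        weighted = (60 + 10) / (100 + 400)
        assert out.loc["supra", "fraction"] == pytest.approx(weighted)

    def test_labeled_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            laminar_contribution({"L4": 10}, {"L4": 5})


class TestExcitatoryFraction:
    def test_identity_when_all_cells_are_excitatory_neurons(self):
        assert excitatory_fraction(0.2, 1.0, 0.0) == pytest.approx(0.2)

    def test_worked_arithmetic(self):
        assert excitatory_fraction(0.20, 0.50, 0.20) == pytest.approx(0.50)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            excitatory_fraction(0.2, 0.0, 0.5)

    def test_inconsistent_inputs_warn(self):
        with pytest.warns(UserWarning):
            excitatory_fraction(0.9, 0.5, 0.5)
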