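"""Trait-proportion permutation tests and species-area scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from specrich import (
    IncidenceMatrix,
    area_controlled_richness,
    permutation_test,
    proportion_by_group,
    species_area_exponent,
)


def incidence(presence: np.ndarray, n_prefix="t", s_prefix="s") -> IncidenceMatrix:
    n, s = presence.shape
    return IncidenceMatrix(
        pd.DataFrame(
            presence.astype(bool),
            index=[f"{n_prefix}{i}" for i in range(n)],
            columns=[f"{s_prefix}{j}" for j in range(s)],
        )
    )


class TestProportions:
    def test_single_group_all_focal(self):
        mat = incidence(np.ones((3, 4)))
        traits = {f"s{j}": "Diptera" for j in range(4)}
        groups = {f"t{i}": "g1" for i in range(3)}
        assert proportion_by_group(mat, traits, groups, "Diptera") == {"g1": 1.0}

    def test_disjoint_groups_hand_count(self):
        # group1 sites see species {0,1,2} labelled D,D,H; group2 sees {3,4,5} = D,H,H
        presence = np.zeros((4, 6), dtype=bool)
        presence[0, [0, 1]] = True
        presence[1, [1, 2]] = True
        presence[2, [3, 4]] = True
        presence[3, [4, 5]] = True
        mat = incidence(presence)
        traits = dict(zip([f"s{j}" for j in range(6)], ["D", "D", "H", "D", "H", "H"]))
        groups = {"t0": "g1", "t1": "g1", "t2": "g2", "t3": "g2"}
        props = proportion_by_group(mat, traits, groups, "D")
        assert props == {"g1": pytest.approx(2 / 3), "g2": pytest.approx(1 / 3)}

    def test_unlabelled_species_excluded_with_warning(self):
        mat = incidence(np.ones((2, 3)))
        traits = {"s0": "D", "s1": "H"}  # s2 unlabelled
        groups = {"t0": "g1", "t1": "g1"}
        with pytest.warns(UserWarning, match="lack a trait"):
            props = proportion_by_group(mat, traits, groups, "D")
        assert props["g1"] == pytest.approx(0.5)

    def test_group_without_labelled_species_is_error(self):
        presence = np.array([[True, False], [False, True]])
        mat = incidence(presence)
        traits = {"s0": "D"}
        groups = {"t0": "g1", "t1": "g2"}
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="g2"):
                proportion_by_group(mat, traits, groups, "D")


class TestPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        mat = incidence(np.ones((4, 5)))
        traits = {f"s{j}": "D" for j in range(5)}
        groups = {f"t{i}": ("g1" if i < 2 else "g2") for i in range(4)}
        res = permutation_test(mat, traits, groups, "D", n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_exact_enumeration_four_traps(self):
        """2+2 grouping of 4 traps: exact p equals hand enumeration over the
        6 distinct assignments."""
        presence = np.array(
            [
                [1, 1, 0, 0, 0],
                [1, 1, 1, 0, 0],
                [0, 0, 1, 1, 1],
                [0, 0, 0, 1, 1],
            ],
            dtype=bool,
        )
        mat = incidence(presence)
        traits = dict(zip([f"s{j}" for j in range(5)], ["D", "D", "D", "H", "H"]))
        groups = {"t0": "g1", "t1": "g1", "t2": "g2", "t3": "g2"}
        res = permutation_test(
            mat, traits, groups, "D", method="exact", alternative="less"
        )

        # independent brute-force enumeration over distinct site->group splits
        sites = list(range(4))
        stats = []
        for combo in itertools.combinations(sites, 2):
            g1 = set(combo)
            pooled1 = presence[list(g1)].any(axis=0)
            pooled2 = presence[[s for s in sites if s not in g1]].any(axis=0)
            is_d = np.array([t == "D" for t in ["D", "D", "D", "H", "H"]])
            stats.append(
                (pooled2 & is_d).sum() / pooled2.sum()
                - (pooled1 & is_d).sum() / pooled1.sum()
            )
        observed = stats[0]  # combo (0,1) is the actual grouping
        expected_p = np.mean([s <= observed for s in stats])
        assert res.observed_statistic == pytest.approx(observed)
        assert res.p_value == pytest.approx(expected_p)

    def test_random_agrees_with_exact(self):
        rng = np.random.default_rng(5)
        presence = rng.random((5, 12)) < 0.5
        presence[:, ~presence.any(axis=0)] = True
        mat = incidence(presence)
        traits = {f"s{j}": ("A" if j % 3 else "B") for j in range(12)}
        groups = {f"t{i}": ("g1" if i < 2 else "g2") for i in range(5)}
        exact = permutation_test(
            mat, traits, groups, "A", method="exact", alternative="greater"
        )
        rand = permutation_test(
            mat, traits, groups, "A", n_permutations=4000, seed=9,
            alternative="greater",
        )
        assert rand.p_value == pytest.approx(exact.p_value, abs=0.03)

    def test_p_uniform_under_null(self):
        """With traits independent of trap groups, one-sided p-values are
        approximately uniform (Kolmogorov-Smirnov over seeded replicates)."""
        rng = np.random.default_rng(2026)
        pvals = []
        for _ in range(500):
            presence = rng.random((8, 40)) < 0.4
            presence[:, ~presence.any(axis=0)] = True
            mat = incidence(presence)
            traits = {
                f"s{j}": ("A" if rng.random() < 0.5 else "B") for j in range(40)
            }
            groups = {f"t{i}": ["g1", "g2", "g3"][i % 3] for i in range(8)}
            res = permutation_test(
                mat, traits, groups, "A", n_permutations=199,
                seed=int(rng.integers(2**31)), alternative="greater",
            )
            pvals.append(res.p_value)
        assert min(pvals) >= 1 / 200
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_group_rejected(self):
        mat = incidence(np.ones((3, 4)))
        traits = {f"s{j}": "D" for j in range(4)}
        groups = {f"t{i}": "only" for i in range(3)}
        with pytest.raises(ValueError, match="2 groups"):
            permutation_test(mat, traits, groups, "D", n_permutations=9, seed=0)

    def test_trend_statistic_on_planted_gradient(self):
        # proportions rise monotonically across ordered groups
        presence = np.eye(6, dtype=bool).repeat(4, axis=1)
        mat = incidence(presence)
        labels = ["B"] * 4 + ["B"] * 3 + ["A"] + ["B"] * 2 + ["A"] * 2
        labels += ["A"] * 12
        traits = dict(zip([f"s{j}" for j in range(24)], labels))
        groups = {f"t{i}": f"g{i // 2}" for i in range(6)}
        res = permutation_test(
            mat, traits, groups, "A", statistic="trend",
            group_order=["g0", "g1", "g2"], n_permutations=499, seed=3,
        )
        assert res.observed_statistic > 0
        assert res.p_value < 0.2  # small design; direction is what matters


class TestSpeciesArea:
    def test_closed_forms(self):
        assert species_area_exponent(100, 10_000) == pytest.approx(0.5)
        assert species_area_exponent(250, 250) == pytest.approx(1.0)
        assert species_area_exponent(1, 50) == 0.0

    def test_invalid_area(self):
        with pytest.raises(ValueError):
            species_area_exponent(10, 1.0)
        with pytest.raises(ValueError):
            species_area_exponent(0, 10)


class TestAreaControlledRichness:
    @staticmethod
    def power_law_table(
        n=12, z=0.3, c=50.0, noise=0.0, lat_effect=0.0, seed=0, lat_range=(35, 70)
    ):
        rng = np.random.default_rng(seed)
        area = np.exp(rng.uniform(8, 14, size=n))
        latitude = rng.uniform(*lat_range, size=n)
        log_s = (
            np.log(c) + z * np.log(area) + lat_effect * latitude
            + noise * rng.normal(size=n)
        )
        return pd.DataFrame(
            {"richness": np.exp(log_s), "area": area, "latitude": latitude},
            index=[f"C{i}" for i in range(n)],
        )

    def test_exact_power_law_leaves_no_latitude_signal(self):
        table = self.power_law_table(noise=0.0)
        res = area_controlled_richness(table)
        assert res.area_slope == pytest.approx(0.3, abs=1e-9)
        assert np.allclose(res.residuals, 0.0, atol=1e-9)
        assert abs(res.latitude_slope) < 1e-9

    def test_planted_latitude_effect_recovered(self):
        table = self.power_law_table(noise=0.02, lat_effect=-0.03, seed=1)
        res = area_controlled_richness(table)
        assert res.latitude_slope < 0
        assert res.latitude_pvalue < 0.01

    def test_outlier_exclusion_flips_significance(self):
        # 11 countries on a clean power law at mid latitudes, plus one
        # high-latitude island with a species deficit
        table = self.power_law_table(n=11, noise=0.05, seed=2, lat_range=(40, 55))
        outlier = pd.DataFrame(
            {
                "richness": [np.exp(np.log(50.0) + 0.3 * 11.0 - 1.0)],
                "area": [np.exp(11.0)],
                "latitude": [68.0],
            },
            index=["ICE"],
        )
        full = pd.concat([table, outlier])
        with_outlier = area_controlled_richness(full)
        without = area_controlled_richness(full, exclude=["ICE"])
        assert with_outlier.latitude_pvalue < 0.05
        assert without.latitude_pvalue > 0.05
        assert without.excluded == ("ICE",)

    def test_too_few_countries_rejected(self):
        table = self.power_law_table(n=3)
        with pytest.raises(ValueError, match="3 countries"):
            area_controlled_richness(table, exclude=["C0"])
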