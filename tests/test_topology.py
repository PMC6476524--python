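"""Accessible paths, unfit-genotype clustering and intra/inter epistasis."""

import itertools
from math import factorial

import numpy as np
import pytest

from fitscape.topology import (
    accessible_path_fraction,
    hamming,
    intermediates,
    intra_vs_inter,
    max_shortest_paths,
    random_null_paths,
    unfit_connectivity,
)


def exhaustive_path_oracle(g1, g2, fit_set):
    """Count site orderings whose every intermediate is present and fit."""
    sites = [i for i, (a, b) in enumerate(zip(g1, g2)) if a != b]
    count = 0
    for order in itertools.permutations(sites):
        g = list(g1)
        ok = True
        for site in order[:-1]:  # the last step lands on g2 itself
            g[site] = g2[site]
            if "".join(g) not in fit_set:
                ok = False
                break
        count += ok
    return count


class TestIntermediates:
    def test_distance_three_has_six_intermediates(self):
        allg, _ = intermediates("AAA", "VVV")
        assert len(allg) == 2**3 - 2 == 6

    def test_distance_one_has_none(self):
        allg, _ = intermediates("AAA", "VAA")
        assert allg == []

    def test_distance_four_matches_enumeration_oracle(self):
        g1, g2 = "AAAA", "VVVV"
        allg, _ = intermediates(g1, g2)
        oracle = {
            "".join(c)
            for c in itertools.product(*zip(g1, g2))
        } - {g1, g2}
        assert set(allg) == oracle
        assert len(allg) == 14

    def test_identical_parents_rejected(self):
        with pytest.raises(ValueError):
            intermediates("AAA", "AAA")


class TestAccessiblePaths:
    def test_all_fit_distance_three_has_six_paths(self):
        fitness = {g: 1.0 for g, _ in [("AAA", 0), ("VVV", 0)]}
        allg, _ = intermediates("AAA", "VVV")
        fitness.update({g: 1.0 for g in allg})
        stats = accessible_path_fraction("AAA", "VVV", fitness)
        assert stats.n_paths_total == 6
        assert stats.fraction_accessible == 1.0

    def test_worked_case_six_paths_reduced_to_three(self):
        # an unfit single mutant kills the 2 orderings starting at its site;
        # an unfit double mutant kills the 2 orderings visiting it second;
        # choosing them to share one ordering removes 3 of the 6 paths
        fitness = {"AAA": 1.0, "VVV": 1.0}
        allg, _ = intermediates("AAA", "VVV")
        fitness.update({g: 1.0 for g in allg})
        fitness["VAA"] = 0.0   # kills orderings (0,1,2) and (0,2,1)
        fitness["VVA"] = 0.0   # kills orderings (0,1,2) and (1,0,2)
        stats = accessible_path_fraction("AAA", "VVV", fitness)
        assert stats.n_paths_total == 6
        assert stats.n_paths_accessible == 3
        oracle = exhaustive_path_oracle(
            "AAA", "VVV", {g for g, f in fitness.items() if f > 0}
        )
        assert stats.n_paths_accessible == oracle

    @pytest.mark.parametrize("d", [3, 4, 5])
    def test_random_fitness_matches_exhaustive_ordering_oracle(self, d, rng):
        g1, g2 = "A" * d, "V" * d
        allg, _ = intermediates(g1, g2)
        for _ in range(10):
            fitness = {g1: 1.0, g2: 1.0}
            for g in allg:
                if rng.random() < 0.85:  # some intermediates unmeasured
                    fitness[g] = float(rng.random() < 0.6)
            stats = accessible_path_fraction(g1, g2, fitness)
            fit_set = {g for g, f in fitness.items() if f > 0}
            measured_oracle = exhaustive_path_oracle(g1, g2, set(fitness))
            assert stats.n_paths_total == measured_oracle
            assert stats.n_paths_accessible == exhaustive_path_oracle(g1, g2, fit_set)
            assert stats.n_paths_total <= max_shortest_paths(d) == factorial(d)

    def test_accessible_fraction_monotone_in_unfit_set(self, rng):
        d = 5
        g1, g2 = "A" * d, "V" * d
        allg, _ = intermediates(g1, g2)
        fitness = {g: 1.0 for g in allg + [g1, g2]}
        last = 1.0
        for g in rng.permutation(allg):
            fitness[str(g)] = 0.0
            frac = accessible_path_fraction(g1, g2, fitness).fraction_accessible
            assert frac <= last + 1e-12
            last = frac

    def test_unfit_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            accessible_path_fraction("AAA", "VVV", {"AAA": 1.0, "VVV": 0.1})


class TestNullPaths:
    def test_zero_unfit_is_fully_accessible(self):
        allg, _ = intermediates("AAAA", "VVVV")
        mean, sd = random_null_paths("AAAA", "VVVV", allg, n_unfit=0, draws=50)
        assert mean == 1.0 and sd == 0.0

    def test_all_unfit_blocks_everything(self):
        allg, _ = intermediates("AAA", "VVV")
        mean, sd = random_null_paths("AAA", "VVV", allg, n_unfit=len(allg), draws=20)
        assert mean == 0.0

    def test_clustered_unfit_leaves_more_paths_than_random(self, rng):
        # unfit genotypes clustered in one "corner" of the d=6 cube block
        # fewer orderings than the same number scattered at random
        d = 6
        g1, g2 = "A" * d, "V" * d
        allg, _ = intermediates(g1, g2)
        cluster = [g for g in allg if g[:3].count("V") >= 2][:12]
        fitness = {g: 1.0 for g in allg + [g1, g2]}
        for g in cluster:
            fitness[g] = 0.0
        observed = accessible_path_fraction(g1, g2, fitness).fraction_accessible
        null_mean, null_sd = random_null_paths(
            g1, g2, allg, n_unfit=len(cluster), draws=300, seed=rng
        )
        assert observed > null_mean


class TestConnectivity:
    def test_unfit_equals_all_when_everything_unfit(self, rng):
        genos = ["".join(c) for c in itertools.product("AV", repeat=6)]
        stats = unfit_connectivity(genos, genos, draws=10, seed=rng)
        assert stats.mean_degree_unfit == stats.mean_degree_all == 6.0

    def test_hamming_ball_is_more_connected_than_random(self, rng):
        genos = ["".join(c) for c in itertools.product("AV", repeat=8)]
        ball = [g for g in genos if g.count("V") <= 2]
        stats = unfit_connectivity(genos, ball, draws=200, seed=rng)
        assert stats.mean_degree_unfit > stats.random_mean + 3 * stats.random_sd

    def test_isolated_unfit_pair_has_zero_degree(self):
        genos = ["AAAA", "AVVA", "VVVV", "AAVA"]
        stats = unfit_connectivity(genos, ["AAAA", "VVVV"], draws=10)
        assert stats.mean_degree_unfit == 0.0

    def test_unfit_must_be_measured(self):
        with pytest.raises(ValueError):
            unfit_connectivity(["AAAA"], ["VVVV"])


class TestIntraVsInter:
    def test_all_fit_gives_zero_intra_curve(self):
        genos = ["".join(c) for c in itertools.product("AV", repeat=6)]
        fitness = {g: 1.0 for g in genos}
        curves = intra_vs_inter(fitness, "A" * 6, max_pairs=500, seed=0)
        assert (curves.intra == 0).all()

    def test_symmetric_random_unfitness_gives_ratio_near_one(self, rng):
        # unfitness independent of the reference: the proportion of unfit
        # genotypes is the same between fit pairs and around the reference
        genos = ["".join(c) for c in itertools.product("AV", repeat=10)]
        fitness = {g: float(rng.random() > 0.3) for g in genos}
        fitness["A" * 10] = 1.0
        curves = intra_vs_inter(fitness, "A" * 10, max_pairs=400, seed=1)
        mid = [d for d in curves.ratio.index if 3 <= d <= 7]
        assert mid
        for d in mid:
            assert curves.ratio[d] == pytest.approx(1.0, abs=0.25)

    def test_reference_distance_unfitness_inflates_ratio(self, rng):
        # unfitness driven by distance from the reference: pairs of fit
        # (reference-near) genotypes see few unfit intermediates while the
        # overall unfit fraction explodes with distance
        genos = ["".join(c) for c in itertools.product("AV", repeat=10)]
        fitness = {g: 1.0 if g.count("V") <= 4 else 0.0 for g in genos}
        curves = intra_vs_inter(fitness, "A" * 10, max_pairs=400, seed=1)
        far = [d for d in curves.ratio.index if d >= 5]
        assert far and all(curves.ratio[d] > 1.5 for d in far)
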