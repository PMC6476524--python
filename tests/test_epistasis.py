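"""Replacement effects across backgrounds and sign-epistasis detection."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from fitscape.epistasis import (
    build_epistasis_graph,
    detect_sign_epistasis,
    extant_replacements,
    neutral_fraction,
    overlap_coefficient,
    replacement_effects,
)
from fitscape.presets import (
    RECIPROCAL_SITES,
    SIGN_VOCAB,
    UNIDIRECTIONAL_SITES,
    additive_fitness_table,
    planted_sign_fitness_table,
)


def fitness_table(vocab, fn):
    genos = ["".join(c) for c in itertools.product(*vocab)]
    return pd.Series([fn(g) for g in genos], index=genos)


class TestReplacementEffects:
    def test_additive_landscape_gives_constant_effect(self, two_state_vocab):
        tab = fitness_table(
            two_state_vocab, lambda g: 1.0 - 0.1 * (g[0] == "V") - 0.02 * (g[1] == "I")
        )
        prof = replacement_effects(tab, 0, "A", "V")
        assert len(prof.deltas) == 16  # all backgrounds shared
        assert np.allclose(prof.deltas, -0.1)

    def test_cliff_landscape_spreads_effects_across_backgrounds(
        self, two_state_vocab, additive_cliff_landscape
    ):
        sites = list(range(1, len(two_state_vocab) + 1))
        tab = fitness_table(
            two_state_vocab, lambda g: additive_cliff_landscape.fitness(g, sites)
        )
        prof = replacement_effects(tab, 0, "A", "V")
        # near the plateau the replacement is nearly neutral; near the
        # threshold it is close to lethal
        assert prof.deltas.max() > -0.1
        assert prof.deltas.min() < -0.9

    def test_absent_state_yields_empty_profile(self, two_state_vocab):
        tab = fitness_table(two_state_vocab, lambda g: 1.0)
        prof = replacement_effects(tab, 0, "A", "W")
        assert prof.empty


class TestNeutralFraction:
    def test_identical_distributions_fully_neutral(self, rng):
        prof = replacement_effects(
            pd.Series({"A" + s: 1.0 for s in "LIVM"}), 0, "X", "Y"
        )
        deltas = rng.normal(0, 0.05, 4000)
        prof.deltas = deltas
        prof.backgrounds = ["b"] * len(deltas)
        out = neutral_fraction(prof, deltas.copy())
        assert out.neutral == pytest.approx(1.0)
        assert out.beneficial == 0.0 and out.deleterious == 0.0

    def test_disjoint_distributions_fully_deleterious(self, rng):
        prof = replacement_effects(pd.Series({"AL": 1.0}), 0, "X", "Y")
        prof.deltas = rng.normal(-0.9, 0.02, 2000)
        out = neutral_fraction(prof, rng.normal(0.0, 0.02, 2000))
        assert out.neutral == pytest.approx(0.0, abs=1e-6)
        assert out.deleterious == pytest.approx(1.0)

    def test_planted_mixture_recovers_components(self, rng):
        null = rng.normal(0.0, 0.05, 5000)
        prof = replacement_effects(pd.Series({"AL": 1.0}), 0, "X", "Y")
        prof.deltas = np.concatenate(
            [rng.normal(0.0, 0.05, 2500), rng.normal(-0.8, 0.05, 2500)]
        )
        out = neutral_fraction(prof, null)
        assert out.neutral == pytest.approx(0.5, abs=0.05)
        assert out.deleterious == pytest.approx(0.5, abs=0.05)

    def test_invariant_under_common_affine_rescaling(self, rng):
        deltas = rng.normal(-0.2, 0.3, 3000)
        null = rng.normal(0.0, 0.1, 3000)
        a, b = 2.5, 0.0  # common scale applied to both samples
        assert overlap_coefficient(deltas, null, 0.05) == pytest.approx(
            overlap_coefficient(a * deltas + b, a * null + b, a * 0.05), abs=0.02
        )

    def test_empty_profile_flagged(self, two_state_vocab):
        tab = fitness_table(two_state_vocab, lambda g: 1.0)
        prof = replacement_effects(tab, 0, "A", "W")
        with pytest.raises(ValueError):
            neutral_fraction(prof, np.zeros(10))


def fisher_two_sided_oracle(table):
    """Exhaustive conditional-probability two-sided Fisher test."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    probs = {
        x: comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_pvalues_match_hypergeometric_oracle():
    # exhaustive over all 2x2 tables with total N <= 14 plus the larger
    # margins used elsewhere in the suite
    tables = [
        ((a, b), (c, d))
        for a in range(8) for b in range(8) for c in range(8) for d in range(8)
        if 0 < a + b + c + d <= 14 and (a + b) > 0 and (c + d) > 0
        and (a + c) > 0 and (b + d) > 0
    ]
    tables += [((30, 2), (3, 25)), ((10, 10), (10, 10)), ((28, 1), (2, 30))]
    for t in tables:
        _, p = fisher_exact(np.array(t), alternative="two-sided")
        assert p == pytest.approx(fisher_two_sided_oracle(t), rel=1e-8), t


class TestDetectSignEpistasis:
    def _table_with_counts(self, n_up_x, n_dn_x, n_up_y, n_dn_y):
        """Fitness table making the focal replacement's 2x2 table explicit.

        Site 0 is the focal site (C/S), site 1 the secondary (T/I), and two
        filler sites enumerate distinct backgrounds.
        """
        filler = "ACDEFGHK"
        genos = {}
        cells = (
            [("T", +1)] * n_up_x + [("T", -1)] * n_dn_x
            + [("I", +1)] * n_up_y + [("I", -1)] * n_dn_y
        )
        assert len(cells) <= len(filler) ** 2
        for idx, (sec, sign) in enumerate(cells):
            bg = filler[idx // len(filler)] + filler[idx % len(filler)]
            genos["C" + sec + bg] = 0.5
            genos["S" + sec + bg] = 0.5 + 0.5 * sign
        return pd.Series(genos)

    def test_strong_association_creates_edge(self):
        tab = self._table_with_counts(30, 2, 3, 25)
        tests = detect_sign_epistasis(tab, (0, "C", "S"))
        by_secondary = {t.secondary: t for t in tests}
        t = by_secondary[(1, "I", "T")]
        assert t.p_raw == pytest.approx(
            fisher_two_sided_oracle(((30, 2), (3, 25))), rel=1e-8
        )
        assert t.p_raw < 1e-8
        assert t.significant

    def test_independent_secondary_not_significant(self):
        tab = self._table_with_counts(10, 10, 10, 10)
        tests = detect_sign_epistasis(tab, (0, "C", "S"), secondary_sites=[1])
        assert all(not t.significant for t in tests)
        t = [t for t in tests if t.secondary[0] == 1][0]
        assert t.p_raw == pytest.approx(1.0)

    def test_single_direction_of_large_effects_gives_no_test(self):
        tab = self._table_with_counts(5, 0, 5, 0)
        assert detect_sign_epistasis(tab, (0, "C", "S")) == []


class TestEpistasisGraph:
    def _run(self, table):
        vocab_map = {i + 1: v for i, v in enumerate(SIGN_VOCAB)}
        reps = extant_replacements(vocab_map, sorted(vocab_map))
        return build_epistasis_graph(table, reps, n_sites=len(SIGN_VOCAB))

    def test_planted_reciprocal_and_unidirectional_edges_recovered(self):
        g = self._run(planted_sign_fitness_table(seed=5))
        i, j = RECIPROCAL_SITES
        u, v = UNIDIRECTIONAL_SITES
        edges = {(a[0], b[0]) for a, b in g.directed.edges}
        assert edges == {(i, j), (j, i), (u, v)}
        assert len(g.reciprocal_pairs) == 1
        # sites under sign epistasis are the focal (source) sites: i, j, u
        assert g.summary["sites_with_sign_epistasis"] == 3
        assert g.summary["sites_with_reciprocal"] == 2

    def test_purely_additive_landscape_gives_empty_graph(self):
        genos = ["".join(c) for c in itertools.product(*SIGN_VOCAB)]
        tab = pd.Series(
            [1.0 - 0.05 * sum(a != w[0] for a, w in zip(g, SIGN_VOCAB)) for g in genos],
            index=genos,
        )
        g = self._run(tab)
        assert g.directed.number_of_edges() == 0

    def test_additive_noisy_calibration_below_bonferroni_level(self):
        g = self._run(additive_fitness_table(seed=5))
        assert g.summary["fraction_sites_sign"] <= 0.05
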