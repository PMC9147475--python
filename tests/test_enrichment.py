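"""Signed drug vectors, cosine enrichment, empirical p-values, combinations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from balfrepo import (
    build_graph,
    classify_drug_effects,
    cosine_enrichment,
    drug_vector,
    empirical_p,
    enrich_combinations,
    idealized_vector,
    net_effect,
    null_distribution,
)
from balfrepo.enrichment import DESIRED, UNDESIRED, UNKNOWN
from balfrepo.network import IdealizedVector
from oracles import brute_force_enrichment


def _fx(rows):
    return pd.DataFrame(rows, columns=["drug", "protein", "effect"])


ENTITIES = ["h1", "h2", "e3", "e4"]


class TestDrugVector:
    def test_single_promotion_gives_unit_vector(self):
        fx = _fx([("d", "h1", "promote")])
        np.testing.assert_array_equal(
            drug_vector("d", fx, ENTITIES), [1, 0, 0, 0]
        )

    def test_conflicting_effects_cancel_with_warning(self):
        fx = _fx([("d", "h1", "promote"), ("d", "h1", "inhibit")])
        with pytest.warns(UserWarning, match="conflicting"):
            vec = drug_vector("d", fx, ENTITIES)
        assert vec[0] == 0

    def test_unknown_entity_skipped_with_warning(self):
        fx = _fx([("d", "nowhere", "inhibit"), ("d", "h2", "inhibit")])
        with pytest.warns(UserWarning, match="unknown entity"):
            vec = drug_vector("d", fx, ENTITIES)
        np.testing.assert_array_equal(vec, [0, -1, 0, 0])

    def test_no_documented_effects_gives_zero_vector(self):
        vec = drug_vector("d", _fx([]), ENTITIES)
        assert np.abs(vec).sum() == 0


class TestCosineEnrichment:
    def test_identical_vector_scores_exactly_one(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        assert cosine_enrichment(m.copy(), m) == 1.0

    def test_opposed_vector_scores_exactly_minus_one(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        assert cosine_enrichment(-m, m) == -1.0

    def test_partial_overlap_closed_form(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        d = np.array([1, 0, 0, 0], dtype=float)
        assert cosine_enrichment(d, m) == pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_enrichment(np.zeros(4), np.array([1.0, 0, 0, 0]))


class TestNetEffect:
    def test_single_drug_is_identity(self):
        v = np.array([1, -1, 0, 1], dtype=np.int8)
        np.testing.assert_array_equal(net_effect([v]), v)

    def test_opposite_signs_cancel_and_agreement_keeps_sign(self):
        a = np.array([1, 1, 0], dtype=np.int8)
        b = np.array([-1, 1, 0], dtype=np.int8)
        np.testing.assert_array_equal(net_effect([a, b]), [0, 1, 0])


class TestNullDistribution:
    def test_background_of_m_alone_gives_unit_null(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        null = null_distribution(m[None, :], m, combo_size=1)
        np.testing.assert_allclose(null, [1.0])

    def test_exhaustive_pair_null_has_choose_2_values(self):
        rng = np.random.default_rng(1)
        bg = rng.choice([-1, 0, 1], size=(5, 6)).astype(float)
        bg[np.abs(bg).sum(axis=1) == 0, 0] = 1
        m = np.array([1, -1, 1, 0, 0, 0], dtype=float)
        null = null_distribution(bg, m, combo_size=2, n_samples=1000)
        assert null.size <= math.comb(5, 2)  # zero-net pairs dropped
        assert null.size >= math.comb(5, 2) - 2

    def test_sampled_null_tracks_exhaustive_mean(self):
        rng = np.random.default_rng(2)
        bg = rng.choice([-1, 0, 1], size=(12, 8), p=[0.25, 0.5, 0.25]).astype(float)
        bg[np.abs(bg).sum(axis=1) == 0, 0] = 1
        m = np.zeros(8)
        m[:3] = [1, -1, 1]
        exhaustive = null_distribution(bg, m, 2, n_samples=10**6)
        sampled = null_distribution(bg, m, 2, n_samples=4000, seed=5)
        assert sampled.mean() == pytest.approx(exhaustive.mean(), abs=0.05)

    def test_reproducible_by_seed(self):
        rng = np.random.default_rng(3)
        bg = rng.choice([-1, 1], size=(30, 6)).astype(float)
        m = np.array([1, -1, 0, 0, 1, 0], dtype=float)
        a = null_distribution(bg, m, 3, n_samples=500, seed=9)
        b = null_distribution(bg, m, 3, n_samples=500, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            null_distribution(np.zeros((0, 4)), np.ones(4), 1)


class TestEmpiricalP:
    @pytest.mark.parametrize(
        "r, n, expect",
        [(0, 99, 0.01), (9, 9, 1.0), (4, 19, 0.25)],
    )
    def test_formula_on_constructed_nulls(self, r, n, expect):
        # null with exactly r values above the observed score 0.5
        null = np.concatenate([np.full(r, 0.9), np.full(n - r, 0.1)])
        assert empirical_p(0.5, null) == pytest.approx(expect)

    def test_ties_are_not_counted_as_greater(self):
        null = np.array([0.5, 0.5, 0.9])
        assert empirical_p(0.5, null) == pytest.approx((1 + 1) / 4)

    def test_minimum_attainable_p(self):
        null = np.linspace(-1, 0.9, 49)
        assert empirical_p(1.0, null) == pytest.approx(1 / 50)

    def test_super_uniform_under_resampled_null(self):
        """Scoring background drugs against their own null keeps p <= alpha
        at rate <= alpha (+ Monte-Carlo slack)."""
        rng = np.random.default_rng(17)
        hits = trials = 0
        for _ in range(30):
            bg = rng.choice([-1, 0, 1], size=(40, 10), p=[0.2, 0.6, 0.2]).astype(float)
            bg[np.abs(bg).sum(axis=1) == 0, 0] = 1
            m = np.zeros(10)
            m[rng.choice(10, 3, replace=False)] = rng.choice([-1, 1], 3)
            null = null_distribution(bg, m, 1, n_samples=10**6)
            for row in bg:
                p = empirical_p(cosine_enrichment(row, m), null)
                hits += p <= 0.05
                trials += 1
        assert hits / trials <= 0.05 + 0.02


class TestEnrichCombinations:
    def _vectors(self):
        return {
            "dA": np.array([1, -1, 0, 0], dtype=np.int8),   # = M
            "dB": np.array([-1, 1, 0, 0], dtype=np.int8),   # = -M
            "dC": np.array([1, 0, 0, 0], dtype=np.int8),
            "dD": np.array([0, 0, 1, 0], dtype=np.int8),
            "dE": np.array([0, -1, 0, 1], dtype=np.int8),
        }

    def test_report_matches_exhaustive_hand_enumeration(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        vectors = self._vectors()
        report = enrich_combinations(vectors, m, alpha=0.25, seed=0)
        oracle = brute_force_enrichment(vectors, m, max_size=2, alpha=0.25)
        assert len(report.table) == 5 + 10
        for row in report.table.itertuples(index=False):
            sc, p, sig = oracle[row.members]
            if sc is None:
                assert np.isnan(row.Sc)
            else:
                assert row.Sc == pytest.approx(sc)
                assert row.p_hat == pytest.approx(p)
                assert bool(row.significant) == sig

    def test_frequencies_count_each_pair_member_once(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        report = enrich_combinations(self._vectors(), m, alpha=0.4, seed=0)
        n_pairs = len(report.significant_pairs())
        assert report.frequencies["count"].sum() == 2 * n_pairs
        if n_pairs:
            assert report.frequencies["fraction"].max() <= 1.0

    def test_zero_net_combination_gets_nan_and_sorts_last(self):
        m = np.array([1, -1, 0, 0], dtype=float)
        report = enrich_combinations(self._vectors(), m, seed=0)
        row = report.table[report.table["members"] == ("dA", "dB")].iloc[0]
        assert np.isnan(row["Sc"]) and not row["significant"]
        assert report.table.index[-1] == report.table.index[
            report.table["Sc"].isna()
        ][-1]

    def test_zero_vector_candidate_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            enrich_combinations(
                {"bad": np.zeros(4, dtype=np.int8)}, np.array([1.0, 0, 0, 0])
            )

    def test_planted_ideal_tops_and_anti_ideal_never_significant(self, study):
        truth = study.truth
        rg = build_graph(study.edges, truth["de_directions"])
        m = idealized_vector(truth["hubs"], truth["de_directions"], rg.nodes)
        vectors = {}
        for drug in sorted(set(study.effects["drug"])):
            vec = drug_vector(drug, study.effects, m.entities)
            if np.abs(vec).sum():
                vectors[drug] = vec
        report = enrich_combinations(vectors, m, seed=1)
        first = report.table.iloc[0]
        assert first["members"] == (truth["ideal_drug"],)
        assert first["Sc"] == 1.0
        singles = report.table[report.table["size"] == 1]
        assert first["p_hat"] == singles["p_hat"].min()
        anti = report.table[
            report.table["members"].map(lambda ms: truth["anti_ideal_drug"] in ms)
        ]
        anti_single = anti[anti["size"] == 1].iloc[0]
        assert anti_single["Sc"] == -1.0
        assert not anti_single["significant"]

    def test_ideal_partner_combination_never_hurts_on_hubs(self):
        """Adding the ideal drug to a partner with no conflicting hub effect
        cannot lower the enrichment score."""
        m = np.array([1, -1, 1, 0, 0], dtype=float)
        ideal = np.array([1, -1, 1, 0, 0], dtype=np.int8)
        partner = np.array([1, 0, 0, 0, 0], dtype=np.int8)  # aligned subset
        combo = net_effect([ideal, partner])
        assert cosine_enrichment(combo, m) >= cosine_enrichment(partner, m)


class TestClassification:
    def test_desired_undesired_unknown_labels(self):
        m = IdealizedVector(pd.Series({"h1": 1, "h2": -1, "e3": 0}, dtype=np.int8))
        fx = _fx(
            [
                ("d1", "h1", "promote"),   # matches +1 -> desired
                ("d1", "h2", "promote"),   # opposes -1 -> undesired
                ("d2", "h2", "inhibit"),   # matches -> desired
            ]
        )
        out = classify_drug_effects(["d1", "d2"], m, fx)
        labels = {(r.drug, r.hub): r.label for r in out.itertuples()}
        assert labels[("d1", "h1")] == DESIRED
        assert labels[("d1", "h2")] == UNDESIRED
        assert labels[("d2", "h1")] == UNKNOWN
        assert labels[("d2", "h2")] == DESIRED
        flags = dict(zip(out["drug"], out["any_undesired"]))
        assert flags["d1"] is True or flags["d1"] == True  # noqa: E712
        assert not flags["d2"]
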