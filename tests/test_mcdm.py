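"""VIKOR, SAW and Spearman concordance against reference values and oracles."""

import numpy as np
import pandas as pd
import pytest

from phytorank.mcdm import (
    DecisionMatrix,
    WeightVector,
    ideal_solutions,
    saw_normalize,
    saw_rank,
    spearman_rho,
    vikor_normalize,
    vikor_rank,
)
from phytorank.synthetic import synth_decision_matrix

# Reference per-compound values from the published eleven-compound study,
# kept as printed strings so each comparison can use the tolerance matching
# its printed precision (5e-4 for <=4 decimals, 5e-5 for 5 decimals).
VIKOR_EXPECTED = {
    # compound: (S, R, Omega, rank)
    "azadirone": ("0.4147", "0.12027", "0.40782", 5),
    "azadirachtin": ("0", "0", "0", 1),
    "stigmasterol": ("0.4773", "0.1316", "0.45812", 7),
    "tiglic_acid": ("1", "0.3", "1", 11),
    "catechin": ("0.6662", "0.16668", "0.61089", 8),
    "scopoletin": ("0.8425", "0.24340", "0.82695", 10),
    "odoratone": ("0.326", "0.09370", "0.31917", 3),
    "tirucallol": ("0.4404", "0.13958", "0.45284", 6),
    "nimbin": ("0.3045", "0.08608", "0.29573", 2),
    "nimbolide": ("0.3876", "0.09333", "0.34933", 4),
    "sugiol": ("0.65", "0.19367", "0.64779", 9),
}


def printed(value: str) -> tuple[float, float]:
    """A printed table entry and the tolerance matching its precision."""
    decimals = len(value.split(".")[1]) if "." in value else 0
    return float(value), 5e-5 if decimals >= 5 else 5e-4
SAW_EXPECTED = {
    # compound: (total, rank)
    "azadirone": (0.6209, 5),
    "azadirachtin": (1.0000, 1),
    "stigmasterol": (0.5638, 7),
    "tiglic_acid": (0.0853, 11),
    "catechin": (0.3932, 9),
    "scopoletin": (0.2300, 10),
    "odoratone": (0.7017, 3),
    "tirucallol": (0.5966, 6),
    "nimbin": (0.7216, 2),
    "nimbolide": (0.6471, 4),
    "sugiol": (0.4054, 8),
}


def brute_vikor(values, w, lam=0.5):
    """First-principles VIKOR with plain loops (independent oracle)."""
    m, n = values.shape
    best = [max(values[:, j]) for j in range(n)]
    worst = [min(values[:, j]) for j in range(n)]
    s, r = [], []
    for i in range(m):
        terms = [
            w[j] * (best[j] - values[i, j]) / (best[j] - worst[j]) for j in range(n)
        ]
        s.append(sum(terms))
        r.append(max(terms))
    omega = [
        lam * (si - min(s)) / (max(s) - min(s))
        + (1 - lam) * (ri - min(r)) / (max(r) - min(r))
        for si, ri in zip(s, r)
    ]
    ranks = [1 + sum(1 for o2 in omega if o2 < o) for o in omega]
    return s, r, omega, ranks


def brute_saw(values, w):
    m, n = values.shape
    col_max = [max(values[:, j]) for j in range(n)]
    totals = [
        sum(w[j] * values[i, j] / col_max[j] for j in range(n)) for i in range(m)
    ]
    ranks = [1 + sum(1 for t2 in totals if t2 > t) for t in totals]
    return totals, ranks


class TestIdealSolutions:
    def test_study_matrix_extremes(self, decision_matrix):
        ideals = ideal_solutions(decision_matrix)
        assert ideals.best.to_list() == pytest.approx(
            [40.875, 542.53, 44.4979, 99.675, 68, 35.887]
        )
        assert ideals.worst.to_list() == pytest.approx(
            [4.53, 37.516, 1.6684, 7.9502, 8, 4.8263]
        )

    def test_constant_column_collapses_extremes(self):
        d = DecisionMatrix(
            pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 5.0]}, index=["x", "y"])
        )
        ideals = ideal_solutions(d)
        assert ideals.best["a"] == ideals.worst["a"] == 1.0

    def test_non_beneficial_orientation_swaps_extremes(self):
        d = DecisionMatrix(
            pd.DataFrame({"cost": [1.0, 9.0]}, index=["x", "y"]),
            orientation={"cost": "non_beneficial"},
        )
        ideals = ideal_solutions(d)
        assert ideals.best["cost"] == 1.0
        assert ideals.worst["cost"] == 9.0


class TestVikor:
    def test_normalized_matrix_spot_values(self, decision_matrix, weights):
        norm = vikor_normalize(decision_matrix, weights)
        assert norm.loc["azadirone"].to_list() == pytest.approx(
            [0.0819, 0.0477, 0.1203, 0.0387, 0.0800, 0.0462], abs=5e-4
        )
        assert (norm.loc["azadirachtin"] == 0).all()
        assert norm.loc["tiglic_acid"].to_list() == pytest.approx(
            [0.2, 0.1, 0.3, 0.1, 0.2, 0.1], abs=1e-12
        )

    def test_study_scores_and_ranks(self, decision_matrix, weights):
        res = vikor_rank(decision_matrix, weights)
        for compound, (s, r, omega, rank) in VIKOR_EXPECTED.items():
            row = res.table.loc[compound]
            for col, entry in (("S", s), ("R", r), ("Omega", omega)):
                value, tol = printed(entry)
                assert row[col] == pytest.approx(value, abs=tol), (compound, col)
            assert row["rank"] == rank, compound

    def test_internal_consistency_s_r_from_normalized(self, decision_matrix, weights):
        res = vikor_rank(decision_matrix, weights)
        assert np.allclose(res.table["S"], res.normalized.sum(axis=1))
        assert np.allclose(res.table["R"], res.normalized.max(axis=1))

    def test_lambda_zero_ranks_by_regret_alone(self, decision_matrix, weights):
        from scipy.stats import rankdata

        res = vikor_rank(decision_matrix, weights, lam=0.0)
        regret_order = rankdata(res.table["R"].to_numpy(), method="min")
        assert (res.table["rank"].to_numpy() == regret_order).all()

    def test_dominant_and_dominated_extremes(self):
        matrix, weights = synth_decision_matrix(8, 5, dominance="one_dominant", seed=3)
        res = vikor_rank(matrix, weights)
        top = res.table.loc["alt1"]
        assert top["S"] == top["R"] == top["Omega"] == 0.0
        assert top["rank"] == 1

    def test_two_alternatives_give_omega_zero_and_one(self):
        matrix, weights = synth_decision_matrix(2, 4, seed=8)
        res = vikor_rank(matrix, weights)
        assert sorted(res.table["Omega"]) == pytest.approx([0.0, 1.0])

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            matrix, weights = synth_decision_matrix(8, 5, seed=rng)
            res = vikor_rank(matrix, weights)
            s, r, omega, ranks = brute_vikor(
                matrix.values.to_numpy(), weights.aligned(matrix.criteria)
            )
            assert res.table["S"].to_list() == pytest.approx(s, rel=1e-12)
            assert res.table["R"].to_list() == pytest.approx(r, rel=1e-12)
            assert res.table["Omega"].to_list() == pytest.approx(omega, rel=1e-10)
            assert res.table["rank"].to_list() == ranks

    def test_constant_criterion_rejected(self, weights):
        df = pd.DataFrame(
            {c: [1.0, 2.0] for c in ["ABC", "AUZ", "RLI", "SLI", "MDI", "ISLI"]},
            index=["x", "y"],
        )
        df["RLI"] = 3.0
        with pytest.raises(ValueError, match="RLI"):
            vikor_normalize(DecisionMatrix(df), weights)

    def test_identical_alternatives_rejected(self, weights):
        df = pd.DataFrame(
            [[1.0, 2, 3, 4, 5, 6]] * 2,
            columns=["ABC", "AUZ", "RLI", "SLI", "MDI", "ISLI"],
            index=["x", "y"],
        )
        with pytest.raises(ValueError):
            vikor_rank(DecisionMatrix(df), weights)

    def test_invalid_lambda_rejected(self, decision_matrix, weights):
        with pytest.raises(ValueError, match="lambda"):
            vikor_rank(decision_matrix, weights, lam=1.5)


class TestSaw:
    def test_max_normalization_spot_values(self, decision_matrix):
        norm = saw_normalize(decision_matrix)
        assert norm.loc["stigmasterol"].to_list() == pytest.approx(
            [0.5791, 0.4999, 0.5775, 0.5065, 0.5882, 0.5649], abs=5e-4
        )
        assert (norm.loc["azadirachtin"] == 1.0).all()
        assert ((norm > 0) & (norm <= 1)).all().all()

    def test_vector_normalization(self):
        d = DecisionMatrix(
            pd.DataFrame({"c": [1.0, 2.0, 2.0]}, index=["x", "y", "z"])
        )
        norm = saw_normalize(d, scheme="vector")
        assert norm["c"].to_list() == pytest.approx([1 / 3, 2 / 3, 2 / 3])

    def test_study_totals_and_ranks(self, decision_matrix, weights):
        res = saw_rank(decision_matrix, weights)
        for compound, (total, rank) in SAW_EXPECTED.items():
            assert res.totals[compound] == pytest.approx(total, abs=5e-4), compound
            assert res.ranks[compound] == rank, compound

    def test_totals_invariant_under_column_rescaling(self, decision_matrix, weights):
        res = saw_rank(decision_matrix, weights)
        scaled = DecisionMatrix(
            decision_matrix.values * [3.0, 0.1, 7.0, 1.0, 100.0, 0.5]
        )
        res2 = saw_rank(scaled, weights)
        assert np.allclose(res.totals, res2.totals)

    def test_dominant_alternative_scores_unit_total(self):
        matrix, weights = synth_decision_matrix(8, 5, dominance="one_dominant", seed=4)
        res = saw_rank(matrix, weights)
        assert res.totals["alt1"] == pytest.approx(1.0)
        assert res.ranks["alt1"] == 1

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            matrix, weights = synth_decision_matrix(8, 5, seed=rng)
            res = saw_rank(matrix, weights)
            totals, ranks = brute_saw(
                matrix.values.to_numpy(), weights.aligned(matrix.criteria)
            )
            assert res.totals.to_list() == pytest.approx(totals, rel=1e-12)
            assert res.ranks.to_list() == ranks

    def test_nonpositive_column_rejected_under_max_scheme(self):
        d = DecisionMatrix(pd.DataFrame({"c": [-1.0, -2.0]}, index=["x", "y"]))
        with pytest.raises(ValueError, match="non-positive"):
            saw_normalize(d)


class TestSpearman:
    def test_identical_rankings(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_reversed_rankings_length_11(self):
        a = list(range(1, 12))
        assert spearman_rho(a, a[::-1]) == pytest.approx(-1.0)

    def test_symmetric(self):
        a, b = [1, 3, 2, 4], [2, 1, 4, 3]
        assert spearman_rho(a, b) == spearman_rho(b, a)

    def test_study_rankings_concordance(self, decision_matrix, weights):
        v = vikor_rank(decision_matrix, weights).ranking
        s = saw_rank(decision_matrix, weights).ranks
        rho = spearman_rho(v.to_numpy(), s.to_numpy())
        assert rho == pytest.approx(1 - 12 / 1320, rel=1e-12)
        assert rho >= 0.98

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            spearman_rho([1, 2], [1, 2, 3])


class TestInputs:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WeightVector(pd.Series({"a": 0.5, "b": 0.6}))

    def test_weights_must_be_non_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            WeightVector(pd.Series({"a": -0.2, "b": 1.2}))

    def test_matrix_needs_two_alternatives(self):
        with pytest.raises(ValueError, match="2 alternatives"):
            DecisionMatrix(pd.DataFrame({"c": [1.0]}, index=["only"]))

    def test_matrix_must_be_complete(self):
        with pytest.raises(ValueError, match="complete"):
            DecisionMatrix(
                pd.DataFrame({"c": [1.0, np.nan]}, index=["x", "y"])
            )
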