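"""Signature scoring, sparsemax/sparsegen-lin, and the mapping matrix P."""

import numpy as np
import pytest

from spatmap.expression_model import ExpressionMatrix, OnOffModel, OnOffModelSet
from spatmap.mapping import (
    SignatureDistribution,
    build_mapping,
    likelihood_tensor,
    log_density,
    signature_params,
    sparsegen_lin,
    sparsemax,
)


def qp_simplex_projection(z):
    """Independent oracle: argmin ||p - z||^2 s.t. p >= 0, sum p = 1.

    Solved by brute-force enumeration of KKT-feasible support sets, which
    is exact to machine precision for the short vectors used here.
    """
    import itertools

    n = len(z)
    for r in range(n, 0, -1):  # prefer larger support on ties
        for S in itertools.combinations(range(n), r):
            S = list(S)
            tau = (z[S].sum() - 1.0) / r
            p = np.zeros(n)
            p[S] = z[S] - tau
            rest = np.setdiff1d(np.arange(n), S)
            if np.all(p[S] >= -1e-14) and np.all(z[rest] <= tau + 1e-14):
                return p
    raise RuntimeError(f"no KKT-feasible support found for {z}")


def toy_models():
    return OnOffModelSet(
        {
            "A": OnOffModel("A", 5.0, 1.0, 0.0, 1.0, 2, 0.0),
            "B": OnOffModel("B", 4.0, 2.0, 1.0, 0.5, 2, 0.0),
        },
        ["A", "B"],
    )


class TestSignatureParams:
    def test_all_zero_signature_uses_off_params(self):
        sd = signature_params(np.array([0, 0]), toy_models())
        assert np.allclose(sd.mean, [0.0, 1.0])
        assert np.allclose(sd.var, [1.0, 0.5])

    def test_all_one_signature_uses_on_params(self):
        sd = signature_params(np.array([1, 1]), toy_models())
        assert np.allclose(sd.mean, [5.0, 4.0])

    def test_mixed_signature_lookup(self):
        sd = signature_params(np.array([1, 0]), toy_models())
        assert np.allclose(sd.mean, [5.0, 1.0])
        assert np.allclose(sd.var, [1.0, 0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            signature_params(np.array([1, 0, 1]), toy_models())


class TestLogDensity:
    def test_closed_form_zero(self):
        # var = 1/(2 pi) makes the normalizing constant exactly 1 at the mode
        sd = SignatureDistribution(0, np.array([2.0]), np.array([1 / (2 * np.pi)]))
        assert log_density(np.array([2.0]), sd) == pytest.approx(0.0, abs=1e-12)

    def test_mode_is_maximal(self, rng):
        sd = SignatureDistribution(0, np.array([1.0, -2.0]), np.array([0.5, 2.0]))
        at_mode = log_density(sd.mean, sd)
        for _ in range(50):
            assert log_density(sd.mean + rng.normal(size=2), sd) <= at_mode

    def test_diagonal_factorizes(self):
        sd2 = SignatureDistribution(0, np.array([1.0, 3.0]), np.array([0.5, 2.0]))
        x = np.array([0.3, 2.2])
        parts = [
            log_density(x[[i]], SignatureDistribution(0, sd2.mean[[i]], sd2.var[[i]]))
            for i in range(2)
        ]
        assert log_density(x, sd2) == pytest.approx(sum(parts))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            SignatureDistribution(0, np.array([0.0]), np.array([0.0]))


class TestLikelihoodTensor:
    def test_matches_scalar_normal_formula(self):
        models = toy_models()
        expr = ExpressionMatrix(
            np.array([[5.0, 4.0], [0.0, 1.0]]), ["c0", "c1"], ["A", "B"]
        )
        sig_table = np.array([[1, 1], [0, 0]], dtype=bool)
        L = likelihood_tensor(expr, sig_table, models)
        for c in range(2):
            for s in range(2):
                sd = signature_params(sig_table[s], models, s)
                assert L[c, s] == pytest.approx(log_density(expr.values[c], sd))

    def test_identical_cells_identical_rows(self):
        models = toy_models()
        expr = ExpressionMatrix(
            np.array([[2.0, 2.0], [2.0, 2.0]]), ["c0", "c1"], ["A", "B"]
        )
        L = likelihood_tensor(expr, np.array([[1, 0]], dtype=bool), models)
        assert np.allclose(L[0], L[1])


class TestSparsemax:
    def test_already_on_simplex_unchanged(self):
        z = np.array([1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(sparsemax(z), z)

    def test_saturating_vector(self):
        assert np.allclose(sparsemax(np.array([2.0, 0.0, 0.0])), [1, 0, 0])

    def test_partial_support(self):
        assert np.allclose(
            sparsemax(np.array([0.6, 0.4, 0.0])), [0.6, 0.4, 0.0]
        )

    def test_matches_qp_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(1, 9)
            z = rng.normal(scale=rng.uniform(0.1, 5), size=n)
            assert np.allclose(
                sparsemax(z), qp_simplex_projection(z), atol=1e-7
            )

    def test_shift_invariance(self, rng):
        z = rng.normal(size=6)
        assert np.allclose(sparsemax(z), sparsemax(z + 13.7))

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            sparsemax(np.array([]))


class TestSparsegenLin:
    def test_lam_zero_recovers_sparsemax(self, rng):
        z = rng.normal(size=7)
        assert np.allclose(sparsegen_lin(z, 0.0), sparsemax(z))

    def test_hand_computed_example(self):
        # sparsemax((1.2, 0.8, 0)) has support 2, tau = 0.5
        out = sparsegen_lin(np.array([0.6, 0.4, 0.0]), lam=0.5)
        assert np.allclose(out, [0.7, 0.3, 0.0])

    def test_support_nonincreasing_in_lam(self, rng):
        for _ in range(300):
            z = rng.normal(size=rng.integers(2, 8))
            prev = np.inf
            for lam in (0.0, 0.5, 0.9):
                supp = int((sparsegen_lin(z, lam) > 0).sum())
                assert supp <= prev
                prev = supp

    def test_lam_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            sparsegen_lin(np.array([1.0, 2.0]), lam=1.0)


class TestBuildMapping:
    def test_columns_sum_to_one(self, rng):
        logdens = rng.normal(scale=20, size=(30, 5))
        sig_index = rng.integers(0, 5, size=(4, 6))
        P = build_mapping(logdens, sig_index, lam=0.9)
        assert np.allclose(P.weights.sum(axis=0), 1.0, atol=1e-9)

    def test_dominant_cell_yields_one_hot(self, rng):
        logdens = rng.normal(size=(10, 2))
        logdens[3, 0] += 1e4
        P = build_mapping(logdens, np.array([[0, 1]]), lam=0.5)
        assert P.weights[3, 0] == pytest.approx(1.0)
        assert (P.weights[:, 0] > 0).sum() == 1

    def test_bins_sharing_signature_have_identical_columns(self, rng):
        logdens = rng.normal(size=(8, 3))
        sig_index = np.array([[0, 1, 0], [2, 1, 0]])
        P = build_mapping(logdens, sig_index, lam=0.9)
        assert np.array_equal(P.column(0, 0), P.column(0, 2))
        assert np.array_equal(P.column(0, 0), P.column(1, 2))

    def test_mapping_is_column_stochastic_on_tissue(self, mapping):
        assert np.allclose(mapping.weights.sum(axis=0), 1.0, atol=1e-9)
        assert (mapping.weights >= 0).all()
        assert mapping.weights.shape[1] <= mapping.n_bins


def test_zone_mass_enrichment_beats_chance(mapping, tissue):
    """Cells place their mapping mass in the true zone >= 3x chance level."""
    from spatmap.synthetic_data import mapping_accuracy

    acc = mapping_accuracy(mapping, tissue)
    assert acc["mean_enrichment"] >= 3.0
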