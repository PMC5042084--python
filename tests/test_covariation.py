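import numpy as np
import pytest

from metacontact.covariation import (
    ScoreMatrix,
    apc,
    compute_frequencies,
    coupling_scores,
    mfdca,
    mutual_information,
    plm_couplings,
    plm_objective,
    psicov_glasso,
    sparse_inverse_covariance,
    _onehot_sparse,
)
from metacontact.msa_io import Q, STATE_INDEX
from metacontact.weighting import WeightedAlignment

from conftest import make_alignment, uniform_weighted


class TestFrequencies:
    def test_single_sequence_point_mass(self):
        wa = uniform_weighted(make_alignment(["AC"]))
        f = compute_frequencies(wa, pseudocount=0.0)
        A, C = STATE_INDEX["A"], STATE_INDEX["C"]
        assert f.f1[0, A] == 1.0 and f.f1[1, C] == 1.0
        assert f.f2[0, 1, A, C] == 1.0

    def test_large_pseudocount_limit(self):
        wa = uniform_weighted(make_alignment(["AC", "AC"]))
        f = compute_frequencies(wa, pseudocount=1e9)
        assert np.allclose(f.f1, 1.0 / Q, atol=1e-7)

    def test_pair_frequencies_split(self):
        wa = uniform_weighted(make_alignment(["AA", "CC"]))
        f = compute_frequencies(wa, pseudocount=0.0)
        A, C = STATE_INDEX["A"], STATE_INDEX["C"]
        assert f.f2[0, 1, A, A] == pytest.approx(0.5)
        assert f.f2[0, 1, C, C] == pytest.approx(0.5)
        assert f.f2[0, 1, A, C] == 0.0

    @pytest.mark.parametrize("lam", [0.0, 0.5, 3.0])
    def test_normalization_and_marginalization(self, lam):
        rng = np.random.default_rng(3)
        rows = ["".join("ACDEG"[k] for k in rng.integers(0, 5, 6)) for _ in range(9)]
        wa = WeightedAlignment.from_alignment(make_alignment(rows))
        f = compute_frequencies(wa, pseudocount=lam)
        assert np.allclose(f.f1.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(f.f2.sum(axis=(2, 3)), 1.0, atol=1e-9)
        assert np.allclose(f.f2.sum(axis=3), np.broadcast_to(f.f1[:, None, :], f.f2.shape[:3]), atol=1e-9)


class TestMutualInformation:
    def test_perfect_correlation_ln2(self, correlated_two_column):
        f = compute_frequencies(uniform_weighted(correlated_two_column), 0.0)
        mi = mutual_information(f, min_separation=1)
        assert mi.scores[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_independent_columns_zero(self):
        # joint = product of marginals: {AA, AC, CA, CC} uniformly
        aln = make_alignment(["AA", "AC", "CA", "CC"])
        f = compute_frequencies(uniform_weighted(aln), 0.0)
        mi = mutual_information(f, min_separation=1)
        assert mi.scores[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_four_sequence_toy_against_brute_force(self):
        aln = make_alignment(["AA", "AA", "AC", "CC"])
        f = compute_frequencies(uniform_weighted(aln), 0.0)
        mi = mutual_information(f, min_separation=1)
        # independent oracle: direct summation over the 21x21 joint table
        joint = np.zeros((Q, Q))
        for row in aln.rows:
            joint[STATE_INDEX[row[0]], STATE_INDEX[row[1]]] += 0.25
        p1, p2 = joint.sum(axis=1), joint.sum(axis=0)
        expected = sum(
            joint[a, b] * np.log(joint[a, b] / (p1[a] * p2[b]))
            for a in range(Q)
            for b in range(Q)
            if joint[a, b] > 0
        )
        assert mi.scores[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_mi_nonnegative_on_random_alignments(self):
        rng = np.random.default_rng(11)
        rows = ["".join("ACDEG"[k] for k in rng.integers(0, 5, 8)) for _ in range(20)]
        f = compute_frequencies(uniform_weighted(make_alignment(rows)), 0.0)
        mi = mutual_information(f, min_separation=1)
        vals = mi.scores[np.isfinite(mi.scores)]
        assert (vals >= -1e-12).all()


class TestAPC:
    def test_constant_matrix_zeroed(self):
        S = ScoreMatrix(np.full((6, 6), 3.5), "MI", min_separation=1)
        out = apc(S)
        vals = out.scores[np.isfinite(out.scores)]
        assert np.allclose(vals, 0.0, atol=1e-12)
        # idempotent on the constant matrix
        vals2 = apc(out).scores[np.isfinite(out.scores)]
        assert np.allclose(vals2, 0.0, atol=1e-12)

    def test_four_by_four_toy_against_direct_formula(self):
        raw = np.array(
            [
                [0.0, 0.0, 1.0, 2.0],
                [0.0, 0.0, 0.0, 3.0],
                [1.0, 0.0, 0.0, 0.0],
                [2.0, 3.0, 0.0, 0.0],
            ]
        )
        sm = ScoreMatrix(raw, "MI", min_separation=2)
        out = apc(sm)
        # spreadsheet-style oracle over unmasked entries (|i-j| >= 2)
        unmasked = [(0, 2), (0, 3), (1, 3), (2, 0), (3, 0), (3, 1)]
        col_means = {}
        for i in range(4):
            vals = [raw[i, j] for (a, j) in [(i, j) for j in range(4)] if abs(i - j) >= 2]
            col_means[i] = np.mean(vals)
        grand = np.mean([raw[i, j] for i, j in unmasked])
        for i, j in [(0, 2), (0, 3), (1, 3)]:
            expected = raw[i, j] - col_means[i] * col_means[j] / grand
            assert out.scores[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(out.scores[np.isfinite(out.scores)],
                           out.scores.T[np.isfinite(out.scores)])

    def test_all_masked_rejected(self):
        S = ScoreMatrix(np.ones((3, 3)), "MI", min_separation=5)
        with pytest.raises(ValueError):
            apc(S)


def _sample_from_joint(joint, states, n, seed):
    """Draw aligned rows from an explicit per-pair joint distribution."""
    rng = np.random.default_rng(seed)
    flat = joint.ravel()
    idx = rng.choice(len(flat), size=n, p=flat / flat.sum())
    rows = []
    for k in idx:
        a, b = divmod(k, joint.shape[1])
        rows.append(states[a] + states[b])
    return make_alignment(rows)


class TestMfDCA:
    def test_independent_columns_scores_vanish(self):
        rng = np.random.default_rng(5)
        rows = ["".join("ACDEG"[k] for k in rng.integers(0, 5, 6)) for _ in range(4000)]
        wa = uniform_weighted(make_alignment(rows))
        f = compute_frequencies(wa, pseudocount=wa.weighted_n)
        sm = mfdca(f, min_separation=1)
        vals = np.abs(sm.scores[np.isfinite(sm.scores)])
        assert vals.max() < 0.05

    def test_requires_pseudocount(self):
        wa = uniform_weighted(make_alignment(["ACDEG", "ACDEG"]))
        with pytest.raises(ValueError):
            mfdca(compute_frequencies(wa, 0.0))

    def test_chain_dependency_decoupled(self):
        # columns 0-1 and 1-2 directly coupled, 0-2 only transitively;
        # mfDCA must score the direct pairs above the indirect one even
        # though raw MI(0,2) is substantial.
        rng = np.random.default_rng(17)
        n = 6000
        c0 = rng.integers(0, 2, n)
        flip1 = rng.random(n) < 0.1
        c1 = np.where(flip1, 1 - c0, c0)
        flip2 = rng.random(n) < 0.1
        c2 = np.where(flip2, 1 - c1, c1)
        rows = ["".join("AC"[v] for v in triple) for triple in zip(c0, c1, c2)]
        wa = uniform_weighted(make_alignment(rows))
        f = compute_frequencies(wa, pseudocount=1.0)
        sm = mfdca(f, min_separation=1)
        assert sm.scores[0, 1] > sm.scores[0, 2]
        assert sm.scores[1, 2] > sm.scores[0, 2]

    def test_gaussian_precision_support_recovery(self):
        # the inversion step itself: samples from a known sparse-precision
        # Gaussian; support of the inverse sample covariance (thresholded)
        # must match the generating precision pattern (direct-inverse oracle).
        rng = np.random.default_rng(23)
        P = np.eye(5)
        P[0, 1] = P[1, 0] = 0.45
        P[2, 3] = P[3, 2] = -0.4
        cov = np.linalg.inv(P)
        X = rng.multivariate_normal(np.zeros(5), cov, size=20000)
        S = np.cov(X.T)
        Pest = np.linalg.inv(S)
        off = np.abs(Pest - np.diag(np.diag(Pest)))
        support = off > 0.1
        expected = np.abs(P - np.diag(np.diag(P))) > 0
        assert (support == expected).all()


class TestSparseInverseCovariance:
    def test_rho_zero_equals_direct_inverse(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((6, 40))
        S = A @ A.T / 40 + 0.5 * np.eye(6)
        prec, trace, ok = sparse_inverse_covariance(S, rho=0.0)
        assert np.allclose(prec, np.linalg.inv(S), atol=1e-10)
        assert ok

    def test_two_by_two_closed_form(self):
        # p=2 graphical lasso: W = S with off-diagonal soft-thresholded by
        # rho (diagonal unpenalized), Theta = inv(W)
        S = np.array([[1.2, 0.5], [0.5, 1.0]])
        for rho in (0.1, 0.3):
            prec, _, _ = sparse_inverse_covariance(S, rho=rho, tol=1e-10, max_iter=500)
            W = S.copy()
            W[0, 1] = W[1, 0] = np.sign(S[0, 1]) * max(abs(S[0, 1]) - rho, 0.0)
            assert np.allclose(prec, np.linalg.inv(W), atol=1e-4)

    def test_full_shrinkage_gives_diagonal_precision(self):
        S = np.array([[1.2, 0.5], [0.5, 1.0]])
        prec, _, _ = sparse_inverse_covariance(S, rho=10.0)
        assert prec[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((12, 60))
        S = A @ A.T / 60 + 0.3 * np.eye(12)
        _, trace, _ = sparse_inverse_covariance(S, rho=0.05, tol=1e-12, max_iter=50)
        assert len(trace) >= 2
        diffs = np.diff(trace)
        assert (diffs <= 1e-7).all()


class TestPsicov:
    def test_large_rho_kills_all_pair_scores(self):
        rng = np.random.default_rng(9)
        rows = ["".join("ACDEG"[k] for k in rng.integers(0, 5, 6)) for _ in range(200)]
        wa = uniform_weighted(make_alignment(rows))
        f = compute_frequencies(wa, pseudocount=1.0)
        sm = psicov_glasso(f, rho=50.0, min_separation=1)
        vals = sm.scores[np.isfinite(sm.scores)]
        assert np.allclose(vals, 0.0, atol=1e-10)

    def test_invalid_shrinkage(self):
        wa = uniform_weighted(make_alignment(["ACDEG", "GEDCA"]))
        f = compute_frequencies(wa, pseudocount=1.0)
        with pytest.raises(ValueError):
            psicov_glasso(f, shrinkage=1.0)


class TestPLM:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(31)
        rows = ["".join("ACDEG"[k] for k in rng.integers(0, 5, 4)) for _ in range(6)]
        wa = uniform_weighted(make_alignment(rows))
        X = wa.alignment.to_indices()
        Xs = _onehot_sparse(X)
        L, q = 4, Q
        n_params = L * q + (L * (L - 1) // 2) * q * q
        theta = 0.1 * rng.standard_normal(n_params)
        args = (Xs, wa.weights, L, q, 0.01, 0.05)
        f0, g = plm_objective(theta, *args)
        eps = 1e-6
        coords = rng.choice(n_params, size=60, replace=False)
        for c in coords:
            tp, tm = theta.copy(), theta.copy()
            tp[c] += eps
            tm[c] -= eps
            fd = (plm_objective(tp, *args)[0] - plm_objective(tm, *args)[0]) / (2 * eps)
            assert abs(fd - g[c]) < 1e-5

    def test_strong_regularization_suppresses_couplings(self):
        wa = uniform_weighted(make_alignment(["ACDEG"]))
        model, sm = plm_couplings(wa, l2_field=0.01, l2_coupling=100.0, max_iter=200)
        assert np.abs(model.J).max() < 1e-3

    def test_two_site_signs_match_exact_maxent_fit(self):
        # L=2 binary alignment strongly favouring AA/CC; for two sites the
        # exact maximum-entropy couplings are the doubly centred log joint
        # (brute-force fit over all 2-site models reduces to moment
        # matching). PLM must agree in sign and in the ranking of states.
        aln = make_alignment(["AA"] * 40 + ["CC"] * 40 + ["AC"] * 10 + ["CA"] * 10)
        wa = uniform_weighted(aln)
        model, _ = plm_couplings(
            wa, l2_field=0.01, l2_coupling=0.01, max_iter=300, min_separation=1
        )
        A, C = STATE_INDEX["A"], STATE_INDEX["C"]
        joint = np.array([[0.4, 0.1], [0.1, 0.4]])
        lg = np.log(joint)
        exact = lg - lg.mean(axis=0) - lg.mean(axis=1)[:, None] + lg.mean()
        sub = model.J[0, 1][np.ix_([A, C], [A, C])]
        sub = sub - sub.mean(axis=0) - sub.mean(axis=1)[:, None] + sub.mean()
        assert np.all(np.sign(sub) == np.sign(exact))
        assert sub[0, 0] > sub[0, 1]

    def test_invalid_regularization(self):
        wa = uniform_weighted(make_alignment(["ACDEG"]))
        with pytest.raises(ValueError):
            plm_couplings(wa, l2_field=0.0)


class TestScoreMatrixProperties:
    @pytest.mark.parametrize("method", ["mi", "mip", "mfdca", "psicov", "plm"])
    def test_outputs_symmetric_and_masked(self, method):
        rng = np.random.default_rng(41)
        rows = ["".join("ACDEGKL"[k] for k in rng.integers(0, 7, 10)) for _ in range(60)]
        wa = WeightedAlignment.from_alignment(make_alignment(rows))
        sm = coupling_scores(wa, method)
        finite = np.isfinite(sm.scores)
        assert np.allclose(sm.scores[finite], sm.scores.T[finite])
        idx = np.arange(sm.L)
        near = np.abs(idx[:, None] - idx[None, :]) < sm.min_separation
        assert np.isnan(sm.scores[near]).all()

    def test_ranked_pairs_tie_break_lexicographic(self):
        S = np.full((6, 6), np.nan)
        for i in range(6):
            for j in range(i + 1, 6):
                S[i, j] = S[j, i] = 1.0
        sm = ScoreMatrix(S, "MI", min_separation=1)
        ranked = sm.ranked_pairs()
        assert ranked[:3] == [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]

    def test_unknown_method_rejected(self, toy_alignment):
        wa = uniform_weighted(toy_alignment)
        with pytest.raises(ValueError):
            coupling_scores(wa, "nope")
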