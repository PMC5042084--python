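"""Covariation engines: mutual information, mean-field DCA, sparse inverse
covariance (PSICOV-style) and pseudolikelihood Potts inference (GREMLIN/
CCMpred-style), each yielding an L x L coupling score matrix.

The three model-based engines attack the same statistical decoupling
problem — separating direct residue-residue couplings from transitive
correlations — with different approximations, and consequently rank
partially non-overlapping sets of pairs:

* mfDCA inverts the connected-correlation matrix of the alignment
  (mean-field approximation of the inverse Potts problem),
* the PSICOV-style engine estimates a sparse precision matrix by
  L1-penalized maximum likelihood (graphical lasso),
* the pseudolikelihood engine maximizes the per-site conditional
  likelihoods of a full Potts model with L2 regularization.

All raw scores are average-product corrected (APC) before use: the APC
subtracts the background score expected from each residue's overall
coupling propensity (row mean times column mean over the global mean),
which removes phylogenetic and composition bias.

Frequencies are kept over the full 21-state alphabet; mfDCA and PSICOV drop
the gap state per column before matrix inversion to remove the simplex
degeneracy, as is standard.  Masked near-diagonal entries (sequence
separation below ``min_separation``) are NaN throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.special import logsumexp
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .msa_io import Q
from .potts import PottsModel, zero_sum_gauge_block
from .weighting import WeightedAlignment

DEFAULT_MIN_SEPARATION = 4  # pairs at least four residues apart


# ---------------------------------------------------------------------------
# score matrices
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """Symmetric L x L pairwise coupling scores; near-diagonal is NaN."""

    scores: np.ndarray
    method: str
    min_separation: int = DEFAULT_MIN_SEPARATION
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("scores must be square")

    @property
    def L(self) -> int:
        return self.scores.shape[0]

    def mask(self) -> np.ndarray:
        """Boolean matrix of scoreable entries (separation >= min_separation)."""
        idx = np.arange(self.L)
        return np.abs(idx[:, None] - idx[None, :]) >= self.min_separation

    def ranked_pairs(self) -> List[Tuple[int, int, float]]:
        """Unmasked pairs (i < j, 0-based) sorted by score descending.

        Ties break lexicographically on (i, j).
        """
        out = []
        for i in range(self.L):
            for j in range(i + self.min_separation, self.L):
                s = self.scores[i, j]
                if np.isfinite(s):
                    out.append((i, j, float(s)))
        out.sort(key=lambda t: (-t[2], t[0], t[1]))
        return out


def _apply_mask(scores: np.ndarray, min_separation: int) -> np.ndarray:
    L = scores.shape[0]
    idx = np.arange(L)
    masked = scores.copy().astype(float)
    masked[np.abs(idx[:, None] - idx[None, :]) < min_separation] = np.nan
    return masked


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyModel:
    """Weighted single- and pair-column state frequencies with pseudocount.

    ``f1[i, a]`` and ``f2[i, j, a, b]`` are probability tables over the
    21-state alphabet; the pseudocount ``lam`` is expressed in effective
    observation counts and is split uniformly over states (``lam/q`` per
    single state, ``lam/q**2`` per state pair), which keeps marginalization
    exact: sum_b f2[i, j, a, b] == f1[i, a].
    """

    f1: np.ndarray
    f2: np.ndarray
    pseudocount: float
    weighted_n: float

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


def _onehot_sparse(X: np.ndarray, q: int = Q) -> csr_matrix:
    """Sparse (N, L*q) one-hot encoding of an integer-coded alignment."""
    N, L = X.shape
    cols = (np.arange(L) * q)[None, :] + X
    rows = np.repeat(np.arange(N), L)
    data = np.ones(N * L)
    return csr_matrix((data, (rows, cols.ravel())), shape=(N, L * q))


def compute_frequencies(
    walign: WeightedAlignment, pseudocount: float = 0.0
) -> FrequencyModel:
    """Weighted column and column-pair frequencies with uniform pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    X = walign.alignment.to_indices()
    w = walign.weights
    N, L = X.shape
    W = float(w.sum())
    lam = float(pseudocount)

    S = _onehot_sparse(X)
    c1 = np.asarray(S.multiply(w[:, None]).sum(axis=0)).reshape(L, Q)
    f1 = (lam / Q + c1) / (lam + W)

    Sw = S.multiply(w[:, None]).tocsr()
    C2 = np.asarray((S.T @ Sw).todense()).reshape(L, Q, L, Q).transpose(0, 2, 1, 3)
    f2 = (lam / Q**2 + C2) / (lam + W)
    # diagonal blocks: joint of a column with itself is its own marginal
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return FrequencyModel(f1=f1, f2=f2, pseudocount=lam, weighted_n=W)


# ---------------------------------------------------------------------------
# mutual information + APC
# ---------------------------------------------------------------------------

def mutual_information(
    freq: FrequencyModel, min_separation: int = DEFAULT_MIN_SEPARATION
) -> ScoreMatrix:
    """MI(i, j) in nats from the (possibly pseudocounted) joint tables."""
    f1, f2 = freq.f1, freq.f2
    L = freq.L
    outer = f1[:, None, :, None] * f1[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f2 > 0, f2 / np.where(outer > 0, outer, 1.0), 1.0)
        terms = np.where(f2 > 0, f2 * np.log(ratio), 0.0)
    mi = terms.sum(axis=(2, 3))
    mi = (mi + mi.T) / 2.0
    return ScoreMatrix(_apply_mask(mi, min_separation), "MI", min_separation)


def apc(scores: ScoreMatrix) -> ScoreMatrix:
    """Average product correction over the unmasked entries.

    S'(i,j) = S(i,j) - mean_i * mean_j / grand_mean, where the means run
    over each residue's unmasked partners.
    """
    S = scores.scores
    finite = np.isfinite(S) & scores.mask()
    if not finite.any():
        raise ValueError("cannot APC-correct an all-masked matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(np.where(finite, S, np.nan), axis=1)
        grand = np.nanmean(S[finite])
    corrected = S - np.outer(row_mean, row_mean) / grand if grand != 0 else S.copy()
    corrected = np.where(finite, corrected, np.nan)
    corrected = (corrected + corrected.T) / 2.0
    tag = scores.method + "p" if scores.method == "MI" else scores.method
    return ScoreMatrix(corrected, tag, scores.min_separation, dict(scores.meta))


# ---------------------------------------------------------------------------
# mean-field DCA
# ---------------------------------------------------------------------------

def _connected_correlation(freq: FrequencyModel, drop_state: int = Q - 1):
    """Connected-correlation matrix over q-1 states per column.

    Returns ``C`` with shape (L*(q-1), L*(q-1)); the dropped state (the gap
    by default) removes the per-column simplex degeneracy.
    """
    keep = [a for a in range(Q) if a != drop_state]
    f1 = freq.f1[:, keep]
    f2 = freq.f2[:, :, keep][:, :, :, keep]
    L, qk = f1.shape
    C = f2 - f1[:, None, :, None] * f1[None, :, None, :]
    return C.transpose(0, 2, 1, 3).reshape(L * qk, L * qk), qk


def mfdca(
    freq: FrequencyModel, min_separation: int = DEFAULT_MIN_SEPARATION
) -> ScoreMatrix:
    """Mean-field DCA: couplings as the negative inverse correlation matrix.

    Requires a positive pseudocount in ``freq`` for invertibility; in
    practice a pseudocount comparable to the weighted sequence count
    (relative weight ~0.5) is used, as is standard for mean-field DCA.
    """
    if freq.pseudocount <= 0:
        raise ValueError("mfDCA requires a positive pseudocount")
    if freq.L < 2:
        raise ValueError("mfDCA needs at least two columns")
    C, qk = _connected_correlation(freq)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; increase the pseudocount"
        ) from e
    L = freq.L
    raw = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            e_ij = -Cinv[i * qk : (i + 1) * qk, j * qk : (j + 1) * qk]
            g = zero_sum_gauge_block(e_ij)
            raw[i, j] = raw[j, i] = np.linalg.norm(g)
    sm = ScoreMatrix(_apply_mask(raw, min_separation), "mfDCA", min_separation)
    return apc(sm)


# ---------------------------------------------------------------------------
# PSICOV-style sparse inverse covariance
# ---------------------------------------------------------------------------

def sparse_inverse_covariance(
    S: np.ndarray, rho: float, tol: float = 1e-4, max_iter: int = 30
) -> Tuple[np.ndarray, List[float], bool]:
    """L1-penalized precision-matrix estimate of a covariance matrix.

    Solves  max_Theta  log det Theta - tr(S Theta) - rho * ||Theta||_1
    (off-diagonal penalty) by coordinate-descent graphical lasso; at
    rho = 0 the estimate is the plain inverse.  Returns (precision,
    objective trace per outer sweep, converged flag).
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho == 0.0:
        return np.linalg.inv(S), [], True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _, precision, costs = _sk_graphical_lasso(
            S, alpha=rho, tol=tol, max_iter=max_iter, return_costs=True
        )
        converged = not any("did not converge" in str(w.message) for w in caught)
    return precision, [float(c[0]) for c in costs], converged


def psicov_glasso(
    freq: FrequencyModel,
    rho: float = 0.005,
    shrinkage: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 30,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ScoreMatrix:
    """Sparse inverse covariance contact scores via the graphical lasso.

    The sample covariance of the one-hot encoded columns (gap state
    dropped) is shrunk toward its diagonal, Theta is estimated by
    L1-penalized maximum likelihood (coordinate-descent graphical lasso),
    and the score for pair (i, j) is the L1 norm of the corresponding
    20 x 20 precision block, followed by APC.

    Non-convergence is flagged in ``meta['converged']`` but a result is
    still returned.  ``meta['objective_trace']`` holds the penalized
    negative log-likelihood per outer sweep.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if not (0.0 <= shrinkage < 1.0):
        raise ValueError("shrinkage must be in [0, 1)")
    S, qk = _connected_correlation(freq)
    S = (S + S.T) / 2.0
    # escalate shrinkage toward the diagonal until the solver accepts the
    # matrix (shallow, redundant alignments give near-singular covariances)
    precision = trace = None
    level = shrinkage
    while True:
        S_sh = (1.0 - level) * S + level * np.diag(np.diag(S))
        eigmin = float(np.linalg.eigvalsh(S_sh).min())
        if eigmin < 1e-10:
            S_sh = S_sh + (1e-10 - eigmin) * np.eye(S_sh.shape[0])
        try:
            precision, trace, converged = sparse_inverse_covariance(
                S_sh, rho, tol, max_iter
            )
            break
        except FloatingPointError:
            level = 0.2 if level == 0 else 2.0 * level
            if level > 0.91:
                raise ValueError(
                    "covariance too ill-conditioned for sparse inverse "
                    "estimation even at maximum diagonal shrinkage"
                ) from None
    L = freq.L
    raw = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            blk = precision[i * qk : (i + 1) * qk, j * qk : (j + 1) * qk]
            raw[i, j] = raw[j, i] = np.abs(blk).sum()
    sm = ScoreMatrix(
        _apply_mask(raw, min_separation),
        "PSICOV",
        min_separation,
        {"converged": converged, "objective_trace": trace, "shrinkage_used": level},
    )
    return apc(sm)


# ---------------------------------------------------------------------------
# pseudolikelihood Potts inference
# ---------------------------------------------------------------------------

def _plm_unpack(theta: np.ndarray, L: int, q: int):
    n_h = L * q
    h = theta[:n_h].reshape(L, q)
    Jp = theta[n_h:].reshape(-1, q, q)  # upper-triangle blocks, (i<j) order
    return h, Jp


def _plm_jflat(h: np.ndarray, Jp: np.ndarray, L: int, q: int) -> np.ndarray:
    """Symmetric (L*q, L*q) coupling matrix from the upper-triangle blocks."""
    Jflat = np.zeros((L * q, L * q))
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            Jflat[i * q : (i + 1) * q, j * q : (j + 1) * q] = Jp[k]
            Jflat[j * q : (j + 1) * q, i * q : (i + 1) * q] = Jp[k].T
            k += 1
    return Jflat


def plm_objective(
    theta: np.ndarray,
    Xs: csr_matrix,
    w: np.ndarray,
    L: int,
    q: int,
    l2_field: float,
    l2_coupling: float,
) -> Tuple[float, np.ndarray]:
    """Weighted negative log-pseudolikelihood and its analytic gradient.

    The pseudolikelihood replaces the intractable Potts likelihood with the
    product over sites of P(x_i | x_{-i}; h, J); its negative log is convex
    in (h, J) and the L2 penalties make the optimum unique.
    """
    h, Jp = _plm_unpack(theta, L, q)
    Jflat = _plm_jflat(h, Jp, L, q)
    logits = (Xs @ Jflat) + h.ravel()[None, :]  # (N, L*q)
    logits3 = logits.reshape(-1, L, q)
    lse = logsumexp(logits3, axis=2)  # (N, L)
    X_dense_logit = np.asarray(Xs.multiply(logits).sum(axis=1)).ravel()
    nll = -float(w @ (X_dense_logit - lse.sum(axis=1)))

    P = np.exp(logits3 - lse[:, :, None]).reshape(-1, L * q)
    R = (P - Xs.toarray()) * w[:, None]
    dh = R.sum(axis=0).reshape(L, q)
    G = Xs.T @ R  # G[jb, ia] = sum_s X[s,jb] R[s,ia]
    Gsym = G + G.T
    dJp = np.empty_like(Jp)
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            dJp[k] = Gsym[i * q : (i + 1) * q, j * q : (j + 1) * q]
            k += 1

    nll += l2_field * float((h ** 2).sum()) + l2_coupling * float((Jp ** 2).sum())
    dh += 2.0 * l2_field * h
    dJp += 2.0 * l2_coupling * Jp
    grad = np.concatenate([dh.ravel(), dJp.ravel()])
    if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite pseudolikelihood objective")
    return nll, grad


def plm_couplings(
    walign: WeightedAlignment,
    l2_field: float = 0.01,
    l2_coupling: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-5,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> Tuple[PottsModel, ScoreMatrix]:
    """Potts couplings by weighted L2-regularized pseudolikelihood maximization.

    Deterministic: parameters start at zero and L-BFGS with an analytic
    gradient is seed-free.  Scores are Frobenius norms of zero-sum-gauged
    coupling blocks, APC-corrected.  ``meta['converged']`` flags whether the
    optimizer hit the iteration cap.
    """
    if l2_field <= 0 or l2_coupling <= 0:
        raise ValueError("regularization strengths must be > 0")
    X = walign.alignment.to_indices()
    N, L = X.shape
    q = Q
    Xs = _onehot_sparse(X)
    w = walign.weights
    n_params = L * q + (L * (L - 1) // 2) * q * q
    theta0 = np.zeros(n_params)
    res = minimize(
        plm_objective,
        theta0,
        args=(Xs, w, L, q, l2_field, l2_coupling),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12},
    )
    h, Jp = _plm_unpack(res.x, L, q)
    J = np.zeros((L, L, q, q))
    k = 0
    raw = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            J[i, j] = Jp[k]
            J[j, i] = Jp[k].T
            g = zero_sum_gauge_block(Jp[k])
            raw[i, j] = raw[j, i] = np.linalg.norm(g)
            k += 1
    model = PottsModel(h=h, J=J, gauge="plm")
    sm = ScoreMatrix(
        _apply_mask(raw, min_separation),
        "PLM",
        min_separation,
        {"converged": bool(res.success) or res.status == 0, "n_iter": int(res.nit)},
    )
    return model, apc(sm)


# ---------------------------------------------------------------------------
# convenience dispatcher
# ---------------------------------------------------------------------------

def coupling_scores(
    walign: WeightedAlignment,
    method: str,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    **kwargs,
) -> ScoreMatrix:
    """Compute one method's score matrix with field-standard defaults.

    ``method`` is one of ``mi``, ``mip``, ``mfdca``, ``psicov``, ``plm``.
    MI uses raw weighted frequencies; mfDCA uses a pseudocount equal to the
    weighted sequence count (relative weight 0.5); PSICOV uses a unit
    pseudocount plus diagonal shrinkage.
    """
    method = method.lower()
    if method in ("mi", "mip"):
        freq = compute_frequencies(walign, pseudocount=0.0)
        sm = mutual_information(freq, min_separation)
        return apc(sm) if method == "mip" else sm
    if method == "mfdca":
        freq = compute_frequencies(walign, pseudocount=walign.weighted_n)
        return mfdca(freq, min_separation)
    if method == "psicov":
        freq = compute_frequencies(walign, pseudocount=1.0)
        return psicov_glasso(freq, min_separation=min_separation, **kwargs)
    if method == "plm":
        _, sm = plm_couplings(walign, min_separation=min_separation, **kwargs)
        return sm
    raise ValueError(f"unknown covariation method {method!r}")
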