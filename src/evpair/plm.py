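"""Potts-model inference by pseudo-likelihood maximization (PLM).

The concatenated alignment is modeled as a pairwise Markov random field
over q letters (20 amino acids plus gap by default): per-site fields
h_i(a) and per-pair couplings J_ij(a, b).  The intractable joint
likelihood is replaced by the product of per-site conditionals

    P(x_i | x_{-i}) = softmax_a( h_i(a) + sum_{j != i} J_ij(a, x_j) ),

maximized with L2 penalties lambda_h ||h||^2 + lambda_J sum_{i<j}
||J_ij||^2, where lambda_J = lambda_base * (q - 1) * (L - 1).  A single
symmetric J is shared between the site-i and site-j conditionals, and the
optimization starts from zero, so the fit is deterministic.

Coupling strengths are summarized by the Frobenius norm of each J_ij
after a zero-sum gauge over the amino-acid states (the gap state, when
present, carries no structural signal and is excluded), then de-biased by
the average product correction (APC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import ConvergenceError, ParameterError
from .msa import DEFAULT_ALPHABET, MSA, compute_weights
from .pairing import PairedMSA


@dataclass
class PottsModel:
    """Fitted fields and couplings.

    ``J`` is the full (L, L, q, q) array with J[i, j] == J[j, i].T and
    zero diagonal blocks; the independent parameters are the i < j blocks.
    """

    h: np.ndarray  # (L, q)
    J: np.ndarray  # (L, L, q, q), symmetric
    alphabet: str
    lambda_h: float
    lambda_J: float
    lambda_base: float = 0.01

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]


def encode_msa(msa: MSA, alphabet: str = DEFAULT_ALPHABET) -> np.ndarray:
    """Integer-encode an alignment; letters outside the alphabet map to
    the gap state if present, else raise."""
    lut = np.zeros(128, dtype=np.int64)
    known = np.zeros(128, dtype=bool)
    for idx, ch in enumerate(alphabet):
        lut[ord(ch)] = idx
        known[ord(ch)] = True
    X = msa.char_matrix()
    enc = lut[X]
    unknown = ~known[X]
    if unknown.any():
        if "-" in alphabet:
            enc[unknown] = alphabet.index("-")
        else:
            bad = sorted({chr(c) for c in X[unknown]})
            raise ParameterError(f"letters {bad} outside alphabet and no gap state")
    return enc


def _onehot(encoded: np.ndarray, q: int) -> np.ndarray:
    n, L = encoded.shape
    X = np.zeros((n, L * q))
    rows = np.repeat(np.arange(n), L)
    cols = (np.arange(L) * q)[None, :] + encoded
    X[rows, cols.ravel()] = 1.0
    return X


def _unpack(x: np.ndarray, L: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat parameter vector -> (h, full symmetric Jmat (Lq, Lq))."""
    h = x[: L * q].reshape(L, q)
    iu, ju = np.triu_indices(L, k=1)
    blocks = x[L * q :].reshape(len(iu), q, q)
    J4 = np.zeros((L, q, L, q))
    J4[iu, :, ju, :] = blocks
    J4[ju, :, iu, :] = blocks.transpose(0, 2, 1)
    return h, J4.reshape(L * q, L * q)


def _objective_flat(
    x: np.ndarray,
    X1h: np.ndarray,
    encoded: np.ndarray,
    weights: np.ndarray,
    L: int,
    q: int,
    lambda_h: float,
    lambda_J: float,
) -> tuple[float, np.ndarray]:
    n = encoded.shape[0]
    h, Jmat = _unpack(x, L, q)

    logits = (X1h @ Jmat).reshape(n, L, q) + h[None]
    m = logits.max(axis=2, keepdims=True)
    ex = np.exp(logits - m)
    Z = ex.sum(axis=2)
    logZ = np.log(Z) + m[:, :, 0]
    obs = np.take_along_axis(logits, encoded[:, :, None], axis=2)[:, :, 0]
    nll = float(np.sum(weights[:, None] * (logZ - obs)))

    # D = (P - onehot) * w, reusing the softmax buffer
    D = ex / Z[:, :, None]
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    D[rows, cols, encoded] -= 1.0
    D *= weights[:, None, None]

    gh = D.sum(axis=0) + 2.0 * lambda_h * h
    D2 = D.reshape(n, L * q)
    M = X1h.T @ D2  # (Lq, Lq)
    Gfull = (M + M.T).reshape(L, q, L, q)
    iu, ju = np.triu_indices(L, k=1)
    gJ = Gfull[iu, :, ju, :]
    Jup = x[L * q :]
    penalty = lambda_h * float(np.sum(h * h)) + lambda_J * float(np.sum(Jup * Jup))
    grad = np.concatenate([gh.ravel(), (gJ.reshape(-1) + 2.0 * lambda_J * Jup)])
    return nll + penalty, grad


def plm_objective(
    model: PottsModel, encoded_msa: np.ndarray, weights: np.ndarray
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Penalized negative log pseudo-likelihood and its exact gradient.

    Returns ``(value, (grad_h, grad_J_upper))`` where ``grad_J_upper`` has
    shape (n_pairs, q, q) over the i < j blocks in ``np.triu_indices``
    order (the tied J[j, i] blocks are not independent parameters).
    """
    L, q = model.L, model.q
    if encoded_msa.ndim != 2 or encoded_msa.shape[1] != L:
        raise ParameterError("encoded alignment does not match model sites")
    if encoded_msa.min() < 0 or encoded_msa.max() >= q:
        raise ParameterError("encoded values outside [0, q)")
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != encoded_msa.shape[0] or np.any(weights <= 0):
        raise ParameterError("weights must be positive, one per sequence")

    iu, ju = np.triu_indices(L, k=1)
    Jup = model.J[iu, ju]
    x = np.concatenate([model.h.ravel(), Jup.ravel()])
    X1h = _onehot(encoded_msa, q)
    val, grad = _objective_flat(
        x, X1h, encoded_msa, weights, L, q, model.lambda_h, model.lambda_J
    )
    gh = grad[: L * q].reshape(L, q)
    gJ = grad[L * q :].reshape(len(iu), q, q)
    return val, (gh, gJ)


def fit_plm(
    paired: PairedMSA | MSA,
    lambda_h: float = 0.01,
    lambda_base: float = 0.01,
    alphabet: str = DEFAULT_ALPHABET,
    theta: float = 0.8,
    maxiter: int = 500,
    grad_tol: float = 1e-4,
) -> PottsModel:
    """Fit the Potts model to a (concatenated) alignment.

    Sequence weights are computed on the full concatenated alignment when
    absent.  Optimization is L-BFGS from zero initialization; the stopping
    tolerance scales with the total sequence weight so that deep and
    shallow alignments converge to comparable per-sequence accuracy.
    Raises :class:`ConvergenceError` if the iteration cap is reached with
    the gradient still large.
    """
    msa = paired.msa if isinstance(paired, PairedMSA) else paired
    if msa.weights is None:
        msa = compute_weights(msa, theta=theta)
    L, q = msa.L, len(alphabet)
    lambda_J = lambda_base * (q - 1) * (L - 1)

    encoded = encode_msa(msa, alphabet)
    X1h = _onehot(encoded, q)
    weights = msa.weights
    scale = max(1.0, float(weights.sum()))

    n_pairs = L * (L - 1) // 2
    x0 = np.zeros(L * q + n_pairs * q * q)
    res = scipy.optimize.minimize(
        _objective_flat,
        x0,
        args=(X1h, encoded, weights, L, q, lambda_h, lambda_J),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 10 * maxiter, "gtol": grad_tol * scale, "ftol": 1e-12},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > 10 * grad_tol * scale:
        raise ConvergenceError(
            f"PLM did not converge in {maxiter} iterations (max|grad| = {gnorm:.3g})",
            grad_norm=gnorm,
        )
    h, Jmat = _unpack(res.x, L, q)
    J = Jmat.reshape(L, q, L, q).transpose(0, 2, 1, 3)
    return PottsModel(
        h=h, J=np.ascontiguousarray(J), alphabet=alphabet,
        lambda_h=lambda_h, lambda_J=lambda_J, lambda_base=lambda_base,
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Double-center a coupling block: subtract row and column means, add
    the grand mean."""
    return (
        block
        - block.mean(axis=0, keepdims=True)
        - block.mean(axis=1, keepdims=True)
        + block.mean()
    )


def frobenius_scores(model: PottsModel) -> np.ndarray:
    """Frobenius norm of every gauge-fixed coupling block (L x L).

    The gauge and the norm run over the amino-acid states only; the gap
    state, when the alphabet has one, is excluded.
    """
    res_idx = [k for k, ch in enumerate(model.alphabet) if ch != "-"]
    sub = model.J[np.ix_(range(model.L), range(model.L), res_idx, res_idx)]
    sub = (
        sub
        - sub.mean(axis=2, keepdims=True)
        - sub.mean(axis=3, keepdims=True)
        + sub.mean(axis=(2, 3), keepdims=True)
    )
    fn = np.sqrt((sub ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(fn, 0.0)
    return fn


def apc(scores: np.ndarray) -> np.ndarray:
    """Average product correction: subtract the rank-one background
    (row mean x column mean / grand mean), means over off-diagonal
    entries.  The diagonal of the result is zero."""
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ParameterError("APC input must be square")
    if not np.allclose(S, S.T):
        raise ParameterError("APC input must be symmetric")
    L = S.shape[0]
    off = ~np.eye(L, dtype=bool)
    grand = S[off].mean()
    if grand == 0:
        return np.zeros_like(S)
    row = (S.sum(axis=1) - np.diag(S)) / (L - 1)
    corrected = S - np.outer(row, row) / grand
    np.fill_diagonal(corrected, 0.0)
    return corrected


def build_ec_table(
    cn_matrix: np.ndarray,
    L1: int,
    L2: int,
    n_eff: float,
    fn_matrix: np.ndarray | None = None,
    min_sequence_separation: int = 5,
) -> pd.DataFrame:
    """Rank residue pairs by corrected coupling score.

    Intra-segment pairs closer than ``min_sequence_separation`` + 1 in
    sequence are dropped (|i - j| <= 5 by default); cross-segment pairs
    are never distance-excluded.  Positions ``i``/``j`` are 1-based in the
    concatenated coordinate, ``pos_i``/``pos_j`` 1-based within their
    segment.  Ties in score break by (i, j) ascending.
    """
    L = L1 + L2
    if cn_matrix.shape != (L, L):
        raise ParameterError(f"score matrix shape {cn_matrix.shape} != ({L}, {L})")
    iu, ju = np.triu_indices(L, k=1)
    seg_i = np.where(iu < L1, "A", "B")
    seg_j = np.where(ju < L1, "A", "B")
    same_seg = seg_i == seg_j
    keep = ~(same_seg & (ju - iu <= min_sequence_separation))
    iu, ju, seg_i, seg_j = iu[keep], ju[keep], seg_i[keep], seg_j[keep]

    df = pd.DataFrame(
        {
            "i": iu + 1,
            "j": ju + 1,
            "segment_i": seg_i,
            "segment_j": seg_j,
            "pos_i": np.where(iu < L1, iu + 1, iu - L1 + 1),
            "pos_j": np.where(ju < L1, ju + 1, ju - L1 + 1),
            "cn": cn_matrix[iu, ju],
            "is_inter": seg_i != seg_j,
        }
    )
    if fn_matrix is not None:
        df["fn"] = fn_matrix[iu, ju]
    df = df.sort_values(["cn", "i", "j"], ascending=[False, True, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs.update({"n_eff": float(n_eff), "L1": int(L1), "L2": int(L2)})
    return df


def inter_zscores(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score of each inter-protein EC against the distribution of all
    inter-protein ECs.  Zero spread yields NaN z-scores."""
    inter = table["is_inter"].to_numpy()
    if inter.sum() < 2:
        raise ParameterError("need at least two inter-protein ECs for z-scores")
    out = table.copy()
    attrs = dict(table.attrs)
    cn = out.loc[out["is_inter"], "cn"]
    sd = float(cn.std(ddof=0))
    out["z"] = np.nan
    if sd > 0:
        out.loc[out["is_inter"], "z"] = (cn - float(cn.mean())) / sd
    out.attrs.update(attrs)
    return out
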