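"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here with its truth
attached: paired alignments sampled by Gibbs sampling from a Potts model
with planted intra- and inter-segment couplings, species-labeled ortholog
fixtures with paralog decoys for the pairing logic, and Gaussian feature
tables whose Bayes-optimal AUC is known in closed form.  All generators
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ParameterError
from .msa import AMINO_ACIDS, MSA
from .plm import PottsModel

#: default Gibbs settings; generous burn-in because residual
#: autocorrelation inflates apparent N_eff
DEFAULT_BURN_IN = 500
DEFAULT_THIN = 10


@dataclass
class PlantedTruth:
    """A Potts model with known planted couplings."""

    potts: PottsModel
    intra_pairs: list[tuple[int, int]]  # 0-based concatenated positions
    inter_pairs: list[tuple[int, int]]
    L1: int
    L2: int
    seed: int
    burn_in: int = DEFAULT_BURN_IN
    thin: int = DEFAULT_THIN

    @property
    def planted_pairs(self) -> set[tuple[int, int]]:
        return set(self.intra_pairs) | set(self.inter_pairs)


def synthetic_alphabet(q: int) -> str:
    """First q canonical amino-acid letters (no gap state)."""
    if not 2 <= q <= 20:
        raise ParameterError("q must be in [2, 20] for the synthetic alphabet")
    return AMINO_ACIDS[:q]


def make_planted_potts(
    L1: int,
    L2: int,
    n_intra: int,
    n_inter: int,
    coupling_strength: float = 1.0,
    q: int = 8,
    seed: int = 0,
    field_sigma: float = 0.3,
    min_separation: int = 5,
    inter_diagonal_band: int = 2,
) -> PlantedTruth:
    """Plant couplings into an otherwise independent-site Potts model.

    Fields are small Gaussians; each planted pair receives a rank-one
    +/- ``coupling_strength`` block (outer product of random sign
    vectors), so its pre-gauge Frobenius norm is exactly strength * q.
    Intra pairs respect the |i - j| > ``min_separation`` band that EC
    ranking excludes, and inter pairs avoid the homology diagonal.
    """
    rng = np.random.default_rng(seed)
    L = L1 + L2
    alphabet = synthetic_alphabet(q)

    intra_cands = [
        (i, j)
        for seg_lo, seg_hi in ((0, L1), (L1, L))
        for i in range(seg_lo, seg_hi)
        for j in range(i + min_separation + 1, seg_hi)
    ]
    inter_cands = [
        (i, L1 + j)
        for i in range(L1)
        for j in range(L2)
        if abs(i - j) > inter_diagonal_band
    ]
    if n_intra > len(intra_cands) or n_inter > len(inter_cands):
        raise ParameterError("requested more planted pairs than the geometry allows")

    intra_idx = rng.choice(len(intra_cands), size=n_intra, replace=False)
    inter_idx = rng.choice(len(inter_cands), size=n_inter, replace=False)
    intra_pairs = sorted(intra_cands[k] for k in intra_idx)
    inter_pairs = sorted(inter_cands[k] for k in inter_idx)

    h = rng.normal(0.0, field_sigma, size=(L, q))
    J = np.zeros((L, L, q, q))
    for i, j in intra_pairs + inter_pairs:
        u = rng.choice([-1.0, 1.0], size=q)
        v = rng.choice([-1.0, 1.0], size=q)
        block = coupling_strength * np.outer(u, v)
        J[i, j] = block
        J[j, i] = block.T
    potts = PottsModel(h=h, J=J, alphabet=alphabet, lambda_h=0.0, lambda_J=0.0)
    return PlantedTruth(
        potts=potts, intra_pairs=intra_pairs, inter_pairs=inter_pairs,
        L1=L1, L2=L2, seed=seed,
    )


def gibbs_sample(
    truth: PlantedTruth,
    n_sequences: int,
    seed: int = 0,
    n_chains: int = 100,
    burn_in: int | None = None,
    thin: int | None = None,
) -> MSA:
    """Sample sequences from the planted model by single-site Gibbs sweeps.

    ``n_chains`` chains run in parallel from random starts; after
    ``burn_in`` full sweeps each chain emits one sequence every ``thin``
    sweeps until ``n_sequences`` are collected.
    """
    if n_sequences < 1:
        raise ParameterError("n_sequences must be >= 1")
    burn_in = truth.burn_in if burn_in is None else burn_in
    thin = truth.thin if thin is None else thin
    model = truth.potts
    L, q = model.L, model.q
    m = min(n_chains, n_sequences)
    rng = np.random.default_rng(seed)

    Jmat = model.J.transpose(0, 2, 1, 3).reshape(L * q, L * q)
    state = rng.integers(0, q, size=(m, L))
    X1h = np.zeros((m, L * q))
    X1h[np.repeat(np.arange(m), L), (np.arange(L) * q)[None, :].repeat(m, 0).ravel() + state.ravel()] = 1.0

    def sweep() -> None:
        for i in range(L):
            logits = model.h[i][None, :] + X1h @ Jmat[:, i * q : (i + 1) * q]
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(m)
            new = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
            X1h[np.arange(m), i * q + state[:, i]] = 0.0
            X1h[np.arange(m), i * q + new] = 1.0
            state[:, i] = new

    for _ in range(burn_in):
        sweep()
    samples = [state.copy()]
    n_rounds = int(np.ceil(n_sequences / m))
    for _ in range(n_rounds - 1):
        for _ in range(thin):
            sweep()
        samples.append(state.copy())
    seqs_int = np.vstack(samples)[:n_sequences]

    letters = np.array(list(model.alphabet))
    seqs = ["".join(letters[row]) for row in seqs_int]
    ids = [f"synth_{k}" for k in range(n_sequences)]
    return MSA(ids=ids, seqs=seqs, query_index=0)


def independent_site_marginals(truth: PlantedTruth) -> np.ndarray:
    """Closed-form per-site letter frequencies when no couplings are
    planted: softmax of the fields."""
    h = truth.potts.h
    e = np.exp(h - h.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Species / pairing fixtures
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute a fixed fraction of positions with different letters."""
    seq = list(seq)
    n_mut = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [c for c in AMINO_ACIDS if c != seq[p]]
        seq[p] = rng.choice(choices)
    return "".join(seq)


def make_species_fixture(
    n_species: int = 20,
    paralog_rate: float = 2.0,
    decoy_divergence: float = 0.3,
    seed: int = 0,
    L_a: int = 60,
    L_b: int = 50,
    ortholog_divergence: tuple[float, float] = (0.05, 0.5),
    query_species: str = "ECOLI",
) -> tuple[MSA, MSA, list[tuple[str, str, str]]]:
    """Two species-labeled monomer alignments with planted ortholog pairs.

    Per species, the true ortholog of each query is a bounded mutation of
    the query; ``int(paralog_rate)`` decoy paralogs per species are
    further mutations of the ortholog by at least ``decoy_divergence``,
    so the ortholog always has the highest identity to the query.
    Headers carry UniProt-style species mnemonics.  Returns
    (msa_a, msa_b, true pairs as (species, id_a, id_b)).
    """
    if decoy_divergence <= 0:
        raise ParameterError("decoy_divergence must be positive")
    rng = np.random.default_rng(seed)
    n_decoys = int(paralog_rate)
    query_a = _random_protein(rng, L_a)
    query_b = _random_protein(rng, L_b)

    ids_a, seqs_a = [f"QA_{query_species}"], [query_a]
    ids_b, seqs_b = [f"QB_{query_species}"], [query_b]
    truth = []
    for s in range(n_species):
        sp = f"SP{s:03d}"
        d_a = rng.uniform(*ortholog_divergence)
        d_b = rng.uniform(*ortholog_divergence)
        orth_a = _mutate(rng, query_a, d_a)
        orth_b = _mutate(rng, query_b, d_b)
        id_a, id_b = f"O{s}A_{sp}", f"O{s}B_{sp}"
        ids_a.append(id_a)
        seqs_a.append(orth_a)
        ids_b.append(id_b)
        seqs_b.append(orth_b)
        truth.append((sp, id_a, id_b))
        for k in range(n_decoys):
            extra = decoy_divergence + rng.uniform(0.0, 0.1)
            ids_a.append(f"P{s}A{k}_{sp}")
            seqs_a.append(_mutate(rng, orth_a, extra))
            ids_b.append(f"P{s}B{k}_{sp}")
            seqs_b.append(_mutate(rng, orth_b, extra))

    msa_a = MSA(ids=ids_a, seqs=seqs_a, query_index=0)
    msa_b = MSA(ids=ids_b, seqs=seqs_b, query_index=0)
    msa_a.species = [h.rsplit("_", 1)[1] for h in ids_a]
    msa_b.species = [h.rsplit("_", 1)[1] for h in ids_b]
    return msa_a, msa_b, truth


# ---------------------------------------------------------------------------
# Classifier fixtures
# ---------------------------------------------------------------------------

def bayes_auc(class_separation: float) -> float:
    """Bayes-optimal AUC of two unit-variance Gaussian classes whose
    means differ by ``class_separation``: Phi(d / sqrt(2))."""
    return float(norm.cdf(class_separation / np.sqrt(2.0)))


def make_feature_fixture(
    n_pos: int,
    n_neg: int,
    class_separation: float = 1.0,
    seed: int = 0,
    n_features: int = 5,
) -> pd.DataFrame:
    """Two spherical Gaussian classes separated along the first feature.

    The optimal classifier reads only feature ``f0``; its AUC is
    :func:`bayes_auc`\\ (class_separation).  Returns a DataFrame with
    feature columns ``f0..f{n-1}`` and a ``label`` column.
    """
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("class counts must be >= 1")
    rng = np.random.default_rng(seed)
    Xp = rng.normal(0.0, 1.0, size=(n_pos, n_features))
    Xp[:, 0] += class_separation
    Xn = rng.normal(0.0, 1.0, size=(n_neg, n_features))
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    df = pd.DataFrame(X, columns=[f"f{k}" for k in range(n_features)])
    df["label"] = y
    return df


def make_logistic_fixture(
    n: int,
    weights: np.ndarray,
    bias: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Features ~ N(0, 1), labels ~ Bernoulli(sigmoid(Xw + b)); for
    weight-recovery tests of the logistic trainers."""
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    X = rng.normal(0.0, 1.0, size=(n, len(w)))
    p = 1.0 / (1.0 + np.exp(-(X @ w + bias)))
    y = (rng.random(n) < p).astype(float)
    df = pd.DataFrame(X, columns=[f"f{k}" for k in range(len(w))])
    df["label"] = y
    return df
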