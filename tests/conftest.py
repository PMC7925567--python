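import numpy as np
import pytest

from evpair import msa as msa_mod
from evpair import plm, synth


@pytest.fixture(scope="session")
def small_planted():
    """A small paired Potts fixture: truth, sampled alignment."""
    truth = synth.make_planted_potts(12, 12, 8, 4, coupling_strength=1.2, q=6, seed=3)
    m = synth.gibbs_sample(truth, 500, seed=4, burn_in=150, thin=5)
    return truth, m


@pytest.fixture(scope="session")
def small_ec_table(small_planted):
    """EC table fitted on the small planted fixture."""
    truth, m = small_planted
    m = msa_mod.compute_weights(m)
    model = plm.fit_plm(m, alphabet=truth.potts.alphabet, maxiter=400)
    fn = plm.frobenius_scores(model)
    cn = plm.apc(fn)
    table = plm.build_ec_table(cn, truth.L1, truth.L2, m.n_eff, fn_matrix=fn)
    return truth, m, table


def random_msa(rng, n, L, alphabet=msa_mod.AMINO_ACIDS, gap_prob=0.0):
    letters = list(alphabet)
    seqs = []
    for _ in range(n):
        chars = rng.choice(letters, size=L)
        if gap_prob:
            mask = rng.random(L) < gap_prob
            chars = np.where(mask, "-", chars)
        seqs.append("".join(chars))
    # ensure the query row has no gaps
    seqs[0] = "".join(rng.choice(letters, size=L))
    return msa_mod.MSA(ids=[f"s{i}" for i in range(n)], seqs=seqs, query_index=0)
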