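import numpy as np
import pytest

import finecomp as fc


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_sparse_matrix(n, density, seed, bin_size=500, max_count=20):
    """Random symmetric integer contact matrix (upper-triangle density)."""
    rng = np.random.default_rng(seed)
    bins = fc.BinTable("chr1", bin_size, n)
    iu = np.triu_indices(n)
    mask = rng.random(iu[0].size) < density
    counts = rng.integers(1, max_count, mask.sum())
    return fc.ContactMatrix.from_coo(bins, iu[0][mask], iu[1][mask], counts)


def dense_corr_oracle(m):
    """Dense correlation eigendecomposition with the same variance filter.

    Returns (kept indices, eigenvalues descending, eigenvectors as columns).
    """
    D = m.dense()
    kept = np.arange(m.n_bins)
    while True:
        sub = D[np.ix_(kept, kept)]
        var = sub.var(axis=0)
        meansq = (sub**2).mean(axis=0)
        ok = var > 1e-12 * np.maximum(meansq, 1e-300)
        if ok.all():
            break
        kept = kept[ok]
    sub = D[np.ix_(kept, kept)]
    Y = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    w, V = np.linalg.eigh(Y.T @ Y)
    return kept, w[::-1], V[:, ::-1]


def planted_runs(labels, min_bins=2):
    runs = []
    s = 0
    for i in range(1, len(labels) + 1):
        if i < len(labels) and labels[i] == labels[s]:
            continue
        if i - s >= min_bins:
            runs.append((s, i, labels[s]))
        s = i
    return runs


@pytest.fixture(scope="session")
def plaid_default():
    """One plaid map at the standard study conditions (shared across tests)."""
    spec = fc.PlaidSpec(seed=2)
    m, labels = fc.generate_plaid_map(spec)
    return m, labels, spec
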