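"""Top-k eigenpairs of the implicit correlation matrix of a sparse contact map.

Given a sparse symmetric matrix ``X`` (a Hi-C contact map), the correlation
matrix ``A = Y^T Y`` — where each column of ``Y`` is the standardized column
``(X^(i) - c_i) / sigma_i`` — is dense and is never formed. Instead the
matrix-vector product ``A x`` is evaluated through the sparse factorization

    Y = Z - 1 r^T,   Z = X S,   S = diag(1 / sigma_i),   r_i = c_i / sigma_i

so that ``Y x = Z x - (r . x) 1`` and ``A x = Z^T w - (sum w) r`` for
``w = Y x``. Each product costs O(nnz(X)). The leading eigenpair is found by
power iteration; subsequent pairs by deflation, re-orthogonalizing the iterate
against all previously found eigenvectors at every step. The eigenvector error
bound ``||v - v_1|| <= ||A v - lambda_1 v|| / |lambda_1 - lambda_2|`` is
reported when the top of the spectrum is non-degenerate.

Normalization modes. ``X`` may be analysed raw, as observed/expected (each
count divided by the mean count at its separation), or as Pearson residuals
``(obs - expected) / sqrt(expected)``. The residual mode subtracts a term that
depends only on genomic separation, i.e. a symmetric Toeplitz matrix; its
matrix-vector product is evaluated by FFT in O(n log n), so the effective
matrix "sparse minus Toeplitz" never has to be materialized and auxiliary
storage stays O(n + nnz).

The population (divide-by-n) standard deviation is used for standardization
and ``A`` carries no 1/n factor, so the eigenvalues of a perfectly correlated
pair of columns scale with the row dimension n; eigenvectors are unaffected by
either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import matmul_toeplitz

from .errors import DegenerateMatrixError, DegenerateSpectrumError
from .io import ContactMatrix

__all__ = [
    "ColumnStats",
    "CorrelationOperator",
    "EigenResult",
    "PowerResult",
    "filter_zero_variance",
    "implicit_corr_matvec",
    "power_top",
    "deflate_next",
    "error_bound",
    "possumm",
]

# relative variance below this is treated as exactly zero (constant column)
_VAR_RTOL = 1e-12

MODES = ("raw", "oe", "pearson")


@dataclass
class ColumnStats:
    """Per-column statistics of the retained square submatrix.

    ``kept`` holds the original column indices surviving the zero-variance
    filter; ``mean`` and ``sigma`` (population convention) are computed over
    the ``n_rows`` rows of the retained submatrix.
    """

    kept: np.ndarray
    mean: np.ndarray
    sigma: np.ndarray
    n_rows: int

    @property
    def inv_sigma(self) -> np.ndarray:
        """Diagonal of the scaling matrix S."""
        return 1.0 / self.sigma

    @property
    def ratio(self) -> np.ndarray:
        """The vector r with r_i = c_i / sigma_i."""
        return self.mean / self.sigma


def _filter_sparse(sym: sparse.csr_array) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed point of removing zero-variance columns (symmetrically).

    Returns (kept original indices, column means, column variances) of the
    final retained square submatrix.
    """
    kept = np.arange(sym.shape[0])
    while True:
        sub = sym[np.ix_(kept, kept)].tocsr()
        n = sub.shape[0]
        colsum = np.asarray(sub.sum(axis=0)).ravel()
        sumsq = np.asarray(sub.power(2).sum(axis=0)).ravel()
        mean = colsum / max(n, 1)
        meansq = sumsq / max(n, 1)
        var = meansq - mean**2
        ok = var > _VAR_RTOL * np.maximum(meansq, 1e-300)
        if ok.all() or kept.size == 0:
            return kept, mean, var
        kept = kept[ok]


def filter_zero_variance(m: ContactMatrix) -> ColumnStats:
    """Remove rows/columns with zero variance; return stats of the remainder.

    Removal is symmetric (the matrix stays square) and repeated to a fixed
    point, since deleting a row can render another column constant. A column
    is "constant" when its variance is zero up to floating-point rounding.
    """
    kept, mean, var = _filter_sparse(m.symmetric())
    if kept.size < 2:
        raise DegenerateMatrixError(
            f"only {kept.size} columns with nonzero variance; need >= 2"
        )
    return ColumnStats(kept=kept, mean=mean, sigma=np.sqrt(var),
                       n_rows=int(kept.size))


def _normalized_parts(
    m: ContactMatrix, mode: str
) -> tuple[sparse.csr_array, np.ndarray | None]:
    """(sparse symmetric part X0, per-distance Toeplitz offsets t or None).

    The effective analysed matrix is ``X0 - T`` with ``T_ij = t[|i - j|]``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "raw":
        return m.symmetric(), None
    expected = m.distance_means()
    i, j, c = m.entries()
    exp = expected[j - i]
    ok = exp > 0
    if mode == "oe":
        scaled = ContactMatrix.from_coo(m.bins, i[ok], j[ok], c[ok] / exp[ok])
        return scaled.symmetric(), None
    root = np.sqrt(expected)
    scaled = ContactMatrix.from_coo(m.bins, i[ok], j[ok], c[ok] / root[j - i][ok])
    return scaled.symmetric(), root


class CorrelationOperator:
    """Implicit ``A = Y^T Y`` on the kept-column space of a contact matrix.

    ``mode`` selects the normalization of X before standardization: "raw",
    "oe" (observed/expected) or "pearson" (variance-stabilized residuals,
    whose distance-only offset term is applied as an FFT Toeplitz product).
    The zero-variance filter always acts on the sparse part, so bins with no
    informative signal stay excluded in every mode.
    """

    def __init__(self, m: ContactMatrix, mode: str = "raw"):
        x0, toep = _normalized_parts(m, mode)
        self.mode = mode
        self.n_full = m.n_bins
        kept, mean0, var0 = _filter_sparse(x0)
        if kept.size < 2:
            raise DegenerateMatrixError(
                f"only {kept.size} columns with nonzero variance; need >= 2"
            )
        self.kept = kept
        sub = x0[np.ix_(kept, kept)].tocsr()
        nk = kept.size

        self._t = toep
        if toep is None:
            mean, var = mean0, var0
        else:
            # column stats of B = X0 - T over the kept rows
            chi = np.zeros(self.n_full)
            chi[kept] = 1.0
            t_sum = matmul_toeplitz((toep, toep), chi)[kept]
            t2_sum = matmul_toeplitz((toep**2, toep**2), chi)[kept]
            coo = sub.tocoo()
            d = np.abs(kept[coo.row] - kept[coo.col])
            cross = np.bincount(coo.col, weights=coo.data * toep[d], minlength=nk)
            colsum = np.asarray(sub.sum(axis=0)).ravel()
            sumsq = np.asarray(sub.power(2).sum(axis=0)).ravel()
            mean = (colsum - t_sum) / nk
            meansq = (sumsq - 2.0 * cross + t2_sum) / nk
            var = meansq - mean**2
            if np.any(var <= 0):
                raise DegenerateMatrixError("zero-variance column after normalization")
        self.stats = ColumnStats(kept=kept, mean=mean, sigma=np.sqrt(var),
                                 n_rows=int(nk))
        self._sub = sub
        self._subt = sub.T.tocsr()
        self._r = self.stats.ratio
        self._s = self.stats.inv_sigma
        self.dim = nk

    @classmethod
    def from_stats(cls, m: ContactMatrix, stats: ColumnStats) -> "CorrelationOperator":
        """Raw-mode operator reusing precomputed column statistics."""
        op = cls.__new__(cls)
        op.mode = "raw"
        op.n_full = m.n_bins
        op.kept = stats.kept
        op.stats = stats
        op._t = None
        op._sub = m.symmetric()[np.ix_(stats.kept, stats.kept)].tocsr()
        op._subt = op._sub.T.tocsr()
        op._r = stats.ratio
        op._s = stats.inv_sigma
        op.dim = stats.kept.size
        return op

    @property
    def shape(self) -> tuple[int, int]:
        return (self.dim, self.dim)

    def _toeplitz_apply(self, x: np.ndarray) -> np.ndarray:
        xf = np.zeros(self.n_full)
        xf[self.kept] = x
        yf = matmul_toeplitz((self._t, self._t), xf)
        return yf[self.kept]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """One product ``A x`` touching only stored nonzeros (+ FFT term)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(f"expected vector of length {self.dim}, got {x.shape}")
        u = self._s * x
        w = self._sub @ u - (self.stats.mean @ u)  # (X0 S) x - (c . u) 1
        if self._t is not None:
            w -= self._toeplitz_apply(u)
        y = self._subt @ w
        if self._t is not None:
            y -= self._toeplitz_apply(w)
        return self._s * y - (self.stats.mean * self._s) * w.sum()

    __call__ = matvec


def implicit_corr_matvec(
    stats: ColumnStats, m: ContactMatrix, x: np.ndarray
) -> np.ndarray:
    """One product ``A x`` of the implicit (raw-mode) correlation matrix."""
    return CorrelationOperator.from_stats(m, stats).matvec(x)


@dataclass
class PowerResult:
    """One eigenpair estimate from (deflated) power iteration."""

    value: float
    vector: np.ndarray
    residual: float
    converged: bool          # the vector's own residual passed tolerance
    value_converged: bool    # the eigenvalue estimate stabilized
    iterations: int


def _iterate(
    matvec,
    dim: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    v_prev: np.ndarray | None,
) -> PowerResult:
    x = rng.standard_normal(dim)
    x /= np.linalg.norm(x)
    lam_prev = np.inf
    lam = 0.0
    residual = np.inf
    for k in range(1, max_iter + 1):
        if v_prev is not None and v_prev.size:
            x = x - v_prev @ (v_prev.T @ x)
            nx = np.linalg.norm(x)
            if nx < 1e-300:  # start vector lay in the found subspace
                x = rng.standard_normal(dim)
                x -= v_prev @ (v_prev.T @ x)
                nx = np.linalg.norm(x)
            x /= nx
        y = matvec(x)
        lam = float(np.linalg.norm(y))
        if lam < 1e-300:
            # x is annihilated: eigenvalue 0, x itself is a null vector
            return PowerResult(0.0, x, 0.0, True, True, k)
        residual = float(np.linalg.norm(y - lam * x))
        value_ok = abs(lam - lam_prev) <= tol * max(lam, 1.0)
        if residual / lam < tol:
            return PowerResult(lam, x, residual, True, value_ok, k)
        lam_prev = lam
        x = y / lam
    return PowerResult(lam, x, residual, False,
                       abs(lam - lam_prev) <= tol * max(lam, 1.0), max_iter)


def power_top(
    matvec, dim: int, tol: float = 1e-8, max_iter: int = 10_000, seed: int = 0
) -> PowerResult:
    """Leading eigenpair of a symmetric PSD operator by power iteration.

    Starts from a seeded standard-normal vector, renormalizes every step, and
    stops when the relative residual ``||A x - lambda x|| / lambda`` falls
    below ``tol``. A result that exhausts ``max_iter`` is returned with
    ``converged=False``, never silently.
    """
    if dim < 2:
        raise ValueError("operator dimension must be >= 2")
    rng = np.random.default_rng(seed)
    return _iterate(matvec, dim, tol, max_iter, rng, None)


def deflate_next(
    matvec,
    v_prev: np.ndarray,
    dim: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int = 0,
) -> PowerResult:
    """Next eigenpair below an orthonormal set ``v_prev`` (dim x m array).

    The iterate is re-orthogonalized against every previously found
    eigenvector before each product, a numerically robust superset of the
    single-projection deflation recurrence. The eigenvalue estimate converges
    even when the eigenvector direction does not (degenerate trailing
    spectrum); ``value_converged`` tracks the former, ``converged`` the
    latter.
    """
    v_prev = np.atleast_2d(np.asarray(v_prev, dtype=float))
    if v_prev.shape[0] != dim:
        v_prev = v_prev.T
    gram = v_prev.T @ v_prev
    if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-6):
        raise ValueError("v_prev must be orthonormal")
    rng = np.random.default_rng(seed)
    return _iterate(matvec, dim, tol, max_iter, rng, v_prev)


def error_bound(lambda1: float, lambda2: float, v: np.ndarray, matvec) -> float:
    """Bound on ``||v - v_1||``: residual norm over the spectral gap.

    Undefined (raises :class:`DegenerateSpectrumError`) when
    ``lambda_1 == lambda_2``.
    """
    gap = abs(lambda1 - lambda2)
    if gap <= 1e-12 * max(abs(lambda1), 1.0):
        raise DegenerateSpectrumError(
            "lambda_1 == lambda_2: eigenvector error bound undefined"
        )
    res = np.linalg.norm(matvec(v) - lambda1 * np.asarray(v))
    return float(res / gap)


@dataclass
class EigenResult:
    """Top-k eigenpairs of the implicit correlation matrix.

    Eigenvectors are re-expanded onto the full bin space with NaN at bins
    removed by the zero-variance filter.
    """

    values: np.ndarray          # lambda_1 >= ... >= lambda_k
    vectors: np.ndarray         # (n_bins, k), NaN at filtered bins
    residuals: np.ndarray
    converged: np.ndarray       # per-pair vector convergence
    value_converged: np.ndarray
    iterations: np.ndarray
    kept: np.ndarray            # bin indices surviving the variance filter
    n_bins: int
    v1_error_bound: float | None = field(default=None)

    @property
    def k(self) -> int:
        return int(self.values.size)


def possumm(
    m: ContactMatrix,
    k: int = 1,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int = 0,
    mode: str = "raw",
) -> EigenResult:
    """Top-k eigenpairs of the correlation matrix of a sparse contact map.

    ``k`` between 1 and 4 (the compartment analyses use at most the first
    four principal components). ``mode`` selects the normalization applied to
    the matrix before column standardization (see module docstring). The
    dense correlation matrix is never materialized; peak auxiliary storage is
    O(n + nnz).
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be between 1 and 4")
    op = CorrelationOperator(m, mode=mode)
    dim = op.dim
    results: list[PowerResult] = []
    basis = np.empty((dim, 0))
    for comp in range(k):
        if comp == 0:
            res = power_top(op, dim, tol=tol, max_iter=max_iter, seed=seed)
        else:
            res = deflate_next(op, basis, dim, tol=tol, max_iter=max_iter,
                               seed=seed + comp)
        results.append(res)
        if np.linalg.norm(res.vector) > 0:
            v = res.vector - basis @ (basis.T @ res.vector)
            nv = np.linalg.norm(v)
            if nv > 1e-12:
                basis = np.column_stack([basis, v / nv])

    vectors = np.full((m.n_bins, k), np.nan)
    for idx, res in enumerate(results):
        vectors[op.kept, idx] = res.vector

    bound: float | None = None
    if k >= 2:
        try:
            bound = error_bound(results[0].value, results[1].value,
                                results[0].vector, op)
        except DegenerateSpectrumError:
            bound = None

    return EigenResult(
        values=np.array([r.value for r in results]),
        vectors=vectors,
        residuals=np.array([r.residual for r in results]),
        converged=np.array([r.converged for r in results]),
        value_converged=np.array([r.value_converged for r in results]),
        iterations=np.array([r.iterations for r in results]),
        kept=op.kept,
        n_bins=m.n_bins,
        v1_error_bound=bound,
    )
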