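"""Binned sparse contact matrices, signal tracks, and their plain-text formats.

The canonical on-disk formats are deliberately simple text:

* contacts — 4-column triplet text ``chrom<TAB>start1<TAB>start2<TAB>count``
  where ``start1``/``start2`` are 0-based bin start coordinates;
* signal tracks — 4-column bedGraph (0-based, half-open);
* intervals — BED; paired anchors — 6-column BEDPE.

All coordinates are 0-based half-open throughout the package: bin ``i`` spans
``[i * bin_size, (i + 1) * bin_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import CoordinateError, EmptyDomainError, ParseError

__all__ = [
    "BinTable",
    "ContactMatrix",
    "SignalTrack",
    "read_contacts",
    "write_contacts",
    "subsample_contacts",
    "coverage_fraction",
    "write_track",
    "read_bedgraph",
    "read_bed",
    "read_bedpe",
]


@dataclass(frozen=True)
class BinTable:
    """Uniform binning of one chromosome.

    Bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``; bins tile the
    chromosome contiguously.
    """

    chrom: str
    bin_size: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")

    @property
    def length(self) -> int:
        return self.bin_size * self.n_bins

    def bin_of(self, pos: int) -> int:
        """Index of the bin containing base-pair position ``pos``."""
        if not 0 <= pos < self.length:
            raise CoordinateError(
                f"position {pos} outside [0, {self.length}) on {self.chrom}"
            )
        return int(pos) // self.bin_size

    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size


class ContactMatrix:
    """Sparse symmetric intra-chromosomal contact matrix.

    Only the upper triangle (i <= j) is stored; queries and exports treat the
    matrix as symmetric. Counts are strictly positive; raw maps hold integers,
    normalized (e.g. observed/expected) maps hold reals.
    """

    def __init__(self, bins: BinTable, upper: sparse.csr_array):
        self.bins = bins
        upper = upper.tocsr()
        upper.eliminate_zeros()
        self._upper = upper

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_coo(
        cls,
        bins: BinTable,
        row: np.ndarray,
        col: np.ndarray,
        count: np.ndarray,
    ) -> "ContactMatrix":
        """Build from triplets; (j, i) is folded onto (i, j), duplicates summed."""
        row = np.asarray(row, dtype=np.int64)
        col = np.asarray(col, dtype=np.int64)
        count = np.asarray(count)
        if row.size and (row.min() < 0 or col.min() < 0 or
                         max(row.max(), col.max()) >= bins.n_bins):
            raise CoordinateError("bin index outside bin table")
        i = np.minimum(row, col)
        j = np.maximum(row, col)
        n = bins.n_bins
        mat = sparse.coo_array((count, (i, j)), shape=(n, n)).tocsr()
        mat.sum_duplicates()
        return cls(bins, mat)

    @classmethod
    def empty(cls, bins: BinTable) -> "ContactMatrix":
        n = bins.n_bins
        return cls(bins, sparse.csr_array((n, n)))

    # -- basic views --------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def nnz(self) -> int:
        return self._upper.nnz

    @property
    def total_contacts(self) -> float:
        return float(self._upper.sum())

    @property
    def is_integer(self) -> bool:
        data = self._upper.data
        return bool(np.all(data == np.round(data)))

    def entries(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle triplets (i, j, count) with i <= j, count > 0."""
        coo = self._upper.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order], coo.data[order]

    def upper(self) -> sparse.csr_array:
        return self._upper

    def symmetric(self) -> sparse.csr_array:
        """Full symmetric sparse matrix (diagonal not double-counted)."""
        up = self._upper
        diag = sparse.dia_array((up.diagonal()[None, :], [0]), shape=up.shape)
        return (up + up.T - diag).tocsr()

    def dense(self) -> np.ndarray:
        return self.symmetric().toarray()

    def distance_means(self) -> np.ndarray:
        """Mean count at each genomic separation d (zeros included in the mean)."""
        n = self.n_bins
        coo = self._upper.tocoo()
        sums = np.bincount(coo.col - coo.row, weights=coo.data, minlength=n)
        return sums / (n - np.arange(n))

    def scaled(self, factor: float) -> "ContactMatrix":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ContactMatrix(self.bins, self._upper * factor)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        if self.bins != other.bins:
            return False
        a, b = self._upper.tocoo(), other._upper.tocoo()
        if a.nnz != b.nnz:
            return False
        sa = self.entries()
        sb = other.entries()
        return all(np.array_equal(x, y) for x, y in zip(sa, sb))


@dataclass
class SignalTrack:
    """Piecewise-constant genomic signal over sorted, non-overlapping intervals."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.starts.size == self.ends.size == self.values.size):
            raise ValueError("starts, ends, values must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must be non-empty")
        if self.starts.size > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("intervals must be sorted and non-overlapping")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    @classmethod
    def from_binned(cls, bins: BinTable, values: np.ndarray) -> "SignalTrack":
        """One interval per bin; NaN bins are omitted (missing)."""
        values = np.asarray(values, dtype=float)
        keep = np.isfinite(values)
        starts = bins.starts()[keep]
        return cls(bins.chrom, starts, starts + bins.bin_size, values[keep])

    def sum_over(self, start: int, end: int) -> float:
        """Integral of the signal over [start, end): sum of value * overlap_bp."""
        if end <= start:
            return 0.0
        lo = np.searchsorted(self.ends, start, side="right")
        hi = np.searchsorted(self.starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(self.starts[lo:hi], start)
        e = np.minimum(self.ends[lo:hi], end)
        return float(np.sum(self.values[lo:hi] * (e - s)))

    def bin_means(self, bins: BinTable) -> np.ndarray:
        """Mean signal per bin (zero where the track has no coverage)."""
        out = np.empty(bins.n_bins)
        for b in range(bins.n_bins):
            out[b] = self.sum_over(b * bins.bin_size, (b + 1) * bins.bin_size)
        return out / bins.bin_size

    @property
    def total(self) -> float:
        return float(np.sum(self.values * (self.ends - self.starts)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "value": self.values,
            }
        )


# -- contact text I/O -------------------------------------------------------


def read_contacts(
    path: str | Path,
    bin_size: int,
    chromosome: str | None = None,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Read triplet contact text into a :class:`ContactMatrix`.

    Lines are ``chrom<TAB>start1<TAB>start2<TAB>count``; starts must be
    multiples of ``bin_size``. Duplicate and transposed pairs are summed.
    ``n_bins`` is inferred from the largest coordinate when not given.
    """
    rows: list[int] = []
    cols: list[int] = []
    counts: list[float] = []
    chrom_seen: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 tab-separated fields")
            chrom, s1, s2, c = parts
            if chromosome is not None and chrom != chromosome:
                continue
            if chrom_seen is None:
                chrom_seen = chrom
            elif chrom != chrom_seen:
                raise ParseError(
                    f"line {lineno}: multiple chromosomes ({chrom_seen}, {chrom}); "
                    "pass chromosome= to select one"
                )
            try:
                p1, p2, cnt = int(s1), int(s2), float(c)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if p1 % bin_size or p2 % bin_size:
                raise CoordinateError(
                    f"line {lineno}: start not a multiple of bin_size {bin_size}"
                )
            if cnt <= 0:
                raise ParseError(f"line {lineno}: count must be positive")
            rows.append(p1 // bin_size)
            cols.append(p2 // bin_size)
            counts.append(cnt)
    if chrom_seen is None:
        chrom_seen = chromosome or "chr?"
    if n_bins is None:
        n_bins = (max(max(rows), max(cols)) + 1) if rows else 1
    bins = BinTable(chrom_seen, bin_size, n_bins)
    return ContactMatrix.from_coo(
        bins, np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64),
        np.array(counts),
    )


def write_contacts(m: ContactMatrix, path: str | Path) -> None:
    """Write upper-triangle triplet text (inverse of :func:`read_contacts`)."""
    i, j, c = m.entries()
    bs = m.bins.bin_size
    with open(path, "w") as fh:
        for a, b, cnt in zip(i, j, c):
            val = int(cnt) if cnt == int(cnt) else cnt
            fh.write(f"{m.bins.chrom}\t{a * bs}\t{b * bs}\t{val}\n")


# -- subsampling ------------------------------------------------------------


def subsample_contacts(m: ContactMatrix, n_target: int, seed: int) -> ContactMatrix:
    """Uniform without-replacement subsample of the contact multiset.

    Draws ``n_target`` read-pairs uniformly from the multiset of recorded
    contacts (multivariate hypergeometric over entries), so the returned total
    equals ``n_target`` exactly. Deterministic given ``seed``.
    """
    if not m.is_integer:
        raise TypeError("subsampling requires integer contact counts")
    total = int(round(m.total_contacts))
    if not 0 <= n_target <= total:
        raise ValueError(f"n_target {n_target} outside [0, {total}]")
    if n_target == total:
        return ContactMatrix(m.bins, m.upper().copy())
    i, j, c = m.entries()
    if n_target == 0 or c.size == 0:
        return ContactMatrix.empty(m.bins)
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(
        c.astype(np.int64), n_target, method="marginals"
    )
    keep = kept > 0
    return ContactMatrix.from_coo(m.bins, i[keep], j[keep], kept[keep])


# -- coverage ---------------------------------------------------------------


def coverage_fraction(
    m: ContactMatrix,
    max_distance: int | None = None,
    unmappable_bins: set[int] | frozenset[int] = frozenset(),
) -> float:
    """Fraction of eligible bin pairs touched by at least one read.

    Eligible pairs are intra-chromosomal (i <= j, diagonal included) between
    mappable bins, restricted to ``|i - j| * bin_size <= max_distance`` when
    given. Unmappable bins are excluded from numerator and denominator.
    """
    n = m.n_bins
    mappable = np.setdiff1d(np.arange(n), np.fromiter(unmappable_bins, dtype=np.int64,
                                                      count=len(unmappable_bins)))
    if mappable.size == 0:
        raise EmptyDomainError("all bins unmappable: coverage undefined")
    if max_distance is None:
        d_bins = n  # no restriction
    else:
        d_bins = max_distance // m.bins.bin_size
    upper_idx = np.searchsorted(mappable, mappable + d_bins, side="right")
    denom = int(np.sum(upper_idx - np.arange(mappable.size)))
    i, j, _ = m.entries()
    ok = np.isin(i, mappable) & np.isin(j, mappable) & ((j - i) <= d_bins)
    return int(np.count_nonzero(ok)) / denom


# -- track / interval text I/O ----------------------------------------------


def write_track(track, path: str | Path) -> None:
    """Write a track as 4-column bedGraph; missing (NaN) bins are omitted.

    Accepts anything with a ``to_frame()`` returning chrom/start/end/value.
    """
    frame = track.to_frame()
    frame = frame[np.isfinite(frame["value"].to_numpy())]
    if not frame["start"].is_monotonic_increasing:
        raise ValueError("track intervals must be sorted")
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_bedgraph(path: str | Path, chromosome: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if chromosome is not None:
        df = df[df["chrom"] == chromosome]
    if df.empty:
        raise ParseError(f"no bedGraph records in {path}")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ParseError("multiple chromosomes; pass chromosome= to select one")
    df = df.sort_values("start", kind="stable")
    return SignalTrack(chroms[0], df["start"].to_numpy(), df["end"].to_numpy(),
                       df["value"].to_numpy())


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    return df


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read 6-column BEDPE (two anchor intervals per line)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 6:
        raise ParseError("BEDPE requires at least 6 columns")
    df = df.iloc[:, :6]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    return df
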