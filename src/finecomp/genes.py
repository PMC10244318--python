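"""Gene-level compartment concordance, eigenvector profiles, and pausing.

A gene whose transcription start site (TSS) sits in the A compartment but
whose termination site (TTS) sits in B is *discordant* (labelled A/B);
concordant genes are A/A. Discordance is analysed against gene size, against
the TSS-anchored average eigenvector profile (whose first zero crossing
measures how far the A compartment extends into gene bodies), and against
RNA-polymerase pausing estimated from nascent-transcription (GRO-seq-like)
signal.

Pausing index: signal density within +/-250 bp of the TSS divided by the
density over the gene body, the body starting 500 bp downstream of the TSS
(strand-aware). Densities are length-normalized, so any global library-size
factor cancels in the ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compartments import EigenTrack, assign_elements
from .errors import EmptyDomainError
from .io import SignalTrack

__all__ = [
    "classify_gene_compartments",
    "discordance_by_size",
    "tss_anchored_profile",
    "pausing_index",
    "pausing_tertiles",
]

TSS_HALF_WINDOW = 250   # bp each side of the TSS for the promoter window
BODY_EXCLUSION = 500    # bp excluded from the 5' end of the gene body
PAUSING_MIN_SIZE = 20_000  # genes below this are excluded from tertiles


def _gene_ends(genes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(TSS, TTS) positions per gene; '-' strand genes start at their end."""
    plus = genes["strand"].to_numpy() == "+"
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    tss = np.where(plus, start, end - 1)
    tts = np.where(plus, end - 1, start)
    return tss, tts


def classify_gene_compartments(genes: pd.DataFrame, track: EigenTrack) -> pd.DataFrame:
    """Label genes concordant (A/A) or discordant (A/B) by TSS/TTS compartments.

    TSS and TTS bins are assigned by plain eigenvector sign. Genes whose TSS
    is not in A are excluded from the concordance classification (class
    ``excluded``, with the reason recorded), following the convention that
    discordance is conditioned on an active (A) start.
    """
    tss, tts = _gene_ends(genes)
    point = lambda p: pd.DataFrame({"chrom": genes["chrom"], "start": p, "end": p + 1})
    tss_lab = assign_elements(point(tss), track)["compartment"].to_numpy()
    tts_lab = assign_elements(point(tts), track)["compartment"].to_numpy()

    out = genes.copy()
    out["tss"] = tss
    out["tts"] = tts
    out["length"] = np.abs(out["end"] - out["start"])
    out["tss_label"] = tss_lab
    out["tts_label"] = tts_lab
    klass = np.full(len(out), "excluded", dtype=object)
    reason = np.full(len(out), "", dtype=object)
    in_a = tss_lab == "A"
    klass[in_a & (tts_lab == "A")] = "A/A"
    klass[in_a & (tts_lab == "B")] = "A/B"
    klass[in_a & (tts_lab == "unassigned")] = "excluded"
    reason[~in_a] = "TSS not in A"
    reason[in_a & (tts_lab == "unassigned")] = "TTS unassigned"
    out["class"] = klass
    out["exclusion_reason"] = reason
    return out


def discordance_by_size(
    records: pd.DataFrame,
    size_bins: tuple[int, ...] = (0, 20_000, 50_000, 100_000, 200_000, 750_000,
                                  10_000_000),
) -> pd.Series:
    """Fraction of TSS-in-A genes with the TTS in B, per gene-size class.

    Size classes with no eligible gene are NaN (undefined), never 0.
    """
    if records.empty:
        raise EmptyDomainError("no gene records")
    eligible = records[records["class"].isin(["A/A", "A/B"])]
    cats = pd.cut(eligible["length"], bins=list(size_bins))
    frac = eligible.groupby(cats, observed=False)["class"].apply(
        lambda s: np.nan if len(s) == 0 else float(np.mean(s == "A/B"))
    )
    return frac


def tss_anchored_profile(
    records: pd.DataFrame,
    track: EigenTrack,
    max_dist: int = 100_000,
) -> tuple[pd.DataFrame, float | None]:
    """Mean eigenvector vs distance downstream of the TSS, and its zero crossing.

    Strand-aware: distance runs in the direction of transcription. Each gene
    contributes only up to its own TTS, so post-gene chromatin never enters
    the average. The crossing distance is the first linearly interpolated zero
    of the mean profile (None when the profile never crosses).
    """
    bs = track.bins.bin_size
    dists = np.arange(0, max_dist + 1, bs)
    sums = np.zeros(dists.size)
    counts = np.zeros(dists.size, dtype=int)
    for row in records.itertuples(index=False):
        sign = 1 if row.strand == "+" else -1
        span = abs(row.tts - row.tss)
        for di, d in enumerate(dists):
            if d > span:
                break
            pos = row.tss + sign * d
            if not 0 <= pos < track.bins.length:
                break
            val = track.values[track.bins.bin_of(pos)]
            if np.isfinite(val):
                sums[di] += val
                counts[di] += 1
    have = counts > 0
    profile = pd.DataFrame(
        {
            "distance": dists[have],
            "mean_value": sums[have] / counts[have],
            "n_genes": counts[have],
        }
    )
    crossing = _zero_crossing(profile["distance"].to_numpy(),
                              profile["mean_value"].to_numpy())
    return profile, crossing


def _zero_crossing(x: np.ndarray, y: np.ndarray) -> float | None:
    """First positive-to-negative zero of a piecewise-linear curve."""
    for a in range(1, x.size):
        if y[a - 1] > 0 >= y[a]:
            if y[a] == y[a - 1]:
                return float(x[a])
            frac = y[a - 1] / (y[a - 1] - y[a])
            return float(x[a - 1] + frac * (x[a] - x[a - 1]))
    return None


def _densities(gro: SignalTrack, tss: int, tts: int, strand: str) -> tuple[float, float]:
    """(promoter, body) signal densities in units per kb."""
    p_lo, p_hi = tss - TSS_HALF_WINDOW, tss + TSS_HALF_WINDOW
    if strand == "+":
        b_lo, b_hi = tss + BODY_EXCLUSION, tts + 1
    else:
        b_lo, b_hi = tts, tss - BODY_EXCLUSION + 1
    prom = gro.sum_over(p_lo, p_hi) / ((p_hi - p_lo) / 1000.0)
    body_len = max(b_hi - b_lo, 0)
    body = gro.sum_over(b_lo, b_hi) / (body_len / 1000.0) if body_len else 0.0
    return prom, body


def pausing_index(gro: SignalTrack, gene) -> float:
    """Promoter-proximal over gene-body signal density ratio.

    Returns ``inf`` when the body is silent but the promoter is not, and NaN
    when both are silent (undefined).
    """
    tss, tts, strand = int(gene.tss), int(gene.tts), gene.strand
    prom, body = _densities(gro, tss, tts, strand)
    if body == 0.0:
        return float("inf") if prom > 0 else float("nan")
    return prom / body


def pausing_tertiles(
    records: pd.DataFrame,
    gro: SignalTrack,
    min_size: int = PAUSING_MIN_SIZE,
) -> pd.DataFrame:
    """Rank genes by promoter-minus-body density and split into three classes.

    Only genes of at least ``min_size`` bp are eligible. The lowest-difference
    third is ``elongating``, the middle ``mid``, the highest ``paused``. Ties
    at tertile boundaries are broken by stable input order.
    """
    eligible = records[records["length"] >= min_size].copy()
    if len(eligible) < 3:
        raise EmptyDomainError("need at least 3 genes of sufficient size")
    diffs = np.empty(len(eligible))
    pis = np.empty(len(eligible))
    for pos, row in enumerate(eligible.itertuples(index=False)):
        prom, body = _densities(gro, int(row.tss), int(row.tts), row.strand)
        diffs[pos] = prom - body
        pis[pos] = pausing_index(gro, row)
    order = np.argsort(diffs, kind="stable")
    groups = np.array_split(order, 3)
    labels = np.empty(len(eligible), dtype=object)
    for name, grp in zip(("elongating", "mid", "paused"), groups):
        labels[grp] = name
    eligible["pausing_diff"] = diffs
    eligible["pausing_index"] = pis
    eligible["pausing_class"] = labels
    return eligible
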