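"""Synthetic contact maps, tracks, genes, and loops with planted ground truth.

Every downstream analysis in this package is testable without external data
through these generators:

* plaid contact maps — a polymer-like distance decay ``(d + 1)^-alpha``
  multiplied by a same-compartment enrichment factor on planted A/B interval
  labels (intervals down to 2 kb at 500 bp bins), Poisson-sampled to a target
  contact total;
* loop maps — center intensity decaying as a compounding percentage per kb of
  Manhattan distance, added to a base map before Poisson sampling;
* gene sets — an eigenvector-like track that is positive from each TSS until
  a planted A-to-B transition distance, plus a nascent-transcription track
  with class-specific promoter/body densities (paused, mid, elongating).

What these fixtures emulate — and what they do not (no balancing biases, no
TAD structure, no replication timing) — is discussed in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import EigenTrack
from .io import BinTable, ContactMatrix, SignalTrack
from .loops import LoopAnchorPair

__all__ = [
    "PlaidSpec",
    "LoopSpec",
    "GeneSetSpec",
    "GeneSet",
    "generate_plaid_map",
    "generate_loop_map",
    "generate_gene_set",
    "place_loops",
]


@dataclass(frozen=True)
class PlaidSpec:
    """Plaid (checkerboard) contact-map specification.

    Expected counts are ``lambda_ij ∝ (|i - j| + 1)^-decay_exponent`` times
    ``enrichment`` when bins i and j share a compartment label, scaled so the
    expectation sums to ``total_contacts``. Interval run lengths are drawn
    uniformly in ``[min_run_bins, max_run_bins]`` — 4 to 100 bins at 500 bp
    gives intervals of 2-50 kb.
    """

    bin_size: int = 500
    n_bins: int = 2_000
    min_run_bins: int = 4
    max_run_bins: int = 100
    enrichment: float = 1.5
    decay_exponent: float = 1.0
    total_contacts: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment <= 1.0:
            raise ValueError("enrichment factor must exceed 1")
        if self.min_run_bins < 1 or self.max_run_bins < self.min_run_bins:
            raise ValueError("invalid run-length range")


def _planted_labels(spec: PlaidSpec, rng: np.random.Generator) -> np.ndarray:
    labels = np.empty(spec.n_bins, dtype=int)
    pos = 0
    current = 1
    while pos < spec.n_bins:
        run = int(rng.integers(spec.min_run_bins, spec.max_run_bins + 1))
        labels[pos : pos + run] = current
        pos += run
        current = -current
    return labels


def generate_plaid_map(spec: PlaidSpec) -> tuple[ContactMatrix, np.ndarray]:
    """Poisson-sampled plaid contact map and its planted +1/-1 labels."""
    rng = np.random.default_rng(spec.seed)
    labels = _planted_labels(spec, rng)
    n = spec.n_bins
    iu, ju = np.triu_indices(n)
    base = (ju - iu + 1.0) ** (-spec.decay_exponent)
    base *= np.where(labels[iu] == labels[ju], spec.enrichment, 1.0)
    mass = base.sum()
    if mass <= 0:
        raise ValueError("expected contact mass is zero; infeasible total")
    lam = base * (spec.total_contacts / mass)
    counts = rng.poisson(lam)
    keep = counts > 0
    bins = BinTable("chrSim", spec.bin_size, n)
    m = ContactMatrix.from_coo(bins, iu[keep], ju[keep], counts[keep])
    return m, labels


@dataclass(frozen=True)
class LoopSpec:
    """Loop-signal specification: anchors plus a radial compounding decay.

    Expected added counts at Manhattan distance ``d`` (in kb) from a loop's
    central cell are ``center_intensity * (1 - decay_pct_per_kb / 100)^d``.
    Diffuse CTCF-like loops decay around 6 %/kb; punctate (Polycomb-like)
    loops around 20-28 %/kb.
    """

    anchors: tuple[tuple[int, int], ...]
    center_intensity: float = 50.0
    decay_pct_per_kb: float = 6.0
    window_radius: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_pct_per_kb <= 0:
            raise ValueError("decay rate must be positive")
        if not 0 < self.decay_pct_per_kb < 100:
            raise ValueError("decay rate must be a percentage in (0, 100)")


def generate_loop_map(base: ContactMatrix, spec: LoopSpec) -> ContactMatrix:
    """Add Poisson-sampled loop signal to a base map.

    Each loop contributes over its ``(2R+1)^2`` window; the expected added
    signal follows the spec's compounding radial decay. With zero intensity
    the base map is returned unchanged in expectation (and exactly, since a
    Poisson(0) draw is 0).
    """
    rng = np.random.default_rng(spec.seed)
    n = base.n_bins
    bs_kb = base.bins.bin_size / 1000.0
    retain = 1.0 - spec.decay_pct_per_kb / 100.0
    R = spec.window_radius
    offs = np.arange(-R, R + 1)
    oi, oj = np.meshgrid(offs, offs, indexing="ij")
    lam_cell = spec.center_intensity * retain ** ((np.abs(oi) + np.abs(oj)) * bs_kb)

    add_i, add_j, add_c = [], [], []
    for a1, a2 in spec.anchors:
        if a1 >= a2:
            raise ValueError("anchor1 must precede anchor2")
        counts = rng.poisson(lam_cell)
        ii = a1 + oi
        jj = a2 + oj
        ok = (counts > 0) & (ii >= 0) & (jj >= 0) & (ii < n) & (jj < n) & (ii <= jj)
        add_i.append(ii[ok])
        add_j.append(jj[ok])
        add_c.append(counts[ok])
    if not add_i or all(a.size == 0 for a in add_i):
        return ContactMatrix(base.bins, base.upper().copy())
    bi, bj, bc = base.entries()
    return ContactMatrix.from_coo(
        base.bins,
        np.concatenate([bi] + add_i),
        np.concatenate([bj] + add_j),
        np.concatenate([bc] + add_c),
    )


def place_loops(
    n_loops: int,
    n_bins: int,
    min_span_bins: int,
    window_radius: int,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Random anchor pairs whose windows fit inside the matrix, off-diagonal."""
    rng = np.random.default_rng(seed)
    out = []
    lo = window_radius
    hi = n_bins - window_radius - 1
    for _ in range(n_loops):
        a1 = int(rng.integers(lo, hi - min_span_bins))
        a2 = a1 + min_span_bins + int(rng.integers(0, max(hi - a1 - min_span_bins, 1)))
        out.append((a1, min(a2, hi)))
    return out


def ladder_loops(
    n_loops: int, window_radius: int, span_bins: int, gap_bins: int = 2
) -> tuple[list[tuple[int, int]], int]:
    """Anchor pairs on a diagonal ladder with pairwise disjoint windows.

    Successive anchors advance by ``2 * window_radius + gap_bins`` so the
    ``(2R+1)^2`` analysis windows never overlap — the clean condition for
    radial-decay recovery tests. Returns (anchors, n_bins required).
    """
    step = 2 * window_radius + gap_bins
    anchors = []
    for k in range(n_loops):
        a1 = window_radius + k * step
        anchors.append((a1, a1 + span_bins))
    n_bins = anchors[-1][1] + window_radius + 1
    return anchors, n_bins


@dataclass(frozen=True)
class GeneSetSpec:
    """Synthetic gene set with planted compartment transitions and pausing.

    Each gene's eigenvector-like value is ``+amplitude`` from the TSS until
    the planted transition distance and ``-amplitude`` beyond it (within the
    gene); intergenic background is weakly negative. Transition distances are
    normal around ``transition_mean_bp``; when ``couple_pausing`` is set the
    mean differs by pausing class (paused genes keep a shorter A extent).
    Nascent-signal densities (promoter, body; arbitrary units per bp) per
    class make promoter-minus-body differences strictly ordered:
    paused > mid > elongating.
    """

    n_genes: int = 120
    min_size_bp: int = 25_000
    max_size_bp: int = 250_000
    transition_mean_bp: float = 42_000.0
    transition_sd_bp: float = 8_000.0
    couple_pausing: bool = False
    transition_shift_bp: float = 15_000.0  # +/- shift for elongating/paused
    bin_size: int = 500
    gap_bp: int = 10_000
    amplitude: float = 0.1
    track_noise_sd: float = 0.01
    promoter_density: dict = field(
        default_factory=lambda: {"paused": 0.08, "mid": 0.02, "elongating": 0.004}
    )
    body_density: dict = field(
        default_factory=lambda: {"paused": 0.0005, "mid": 0.002, "elongating": 0.008}
    )
    seed: int = 0


@dataclass
class GeneSet:
    """Generated genes plus the tracks and ground truth that describe them."""

    genes: pd.DataFrame       # BED-like: chrom start end name score strand
    track: EigenTrack         # eigenvector-like, oriented (A positive)
    gro: SignalTrack          # nascent-transcription-like signal
    truth: pd.DataFrame       # planted transition, class, expected labels


def generate_gene_set(spec: GeneSetSpec) -> GeneSet:
    """Lay out genes end to end with planted transitions and pausing classes."""
    rng = np.random.default_rng(spec.seed)
    classes = np.array(["paused", "mid", "elongating"])[
        np.arange(spec.n_genes) % 3
    ]
    rng.shuffle(classes)

    sizes = np.exp(
        rng.uniform(np.log(spec.min_size_bp), np.log(spec.max_size_bp), spec.n_genes)
    ).astype(int)
    shift = {"paused": -spec.transition_shift_bp, "mid": 0.0,
             "elongating": +spec.transition_shift_bp}
    means = np.full(spec.n_genes, spec.transition_mean_bp)
    if spec.couple_pausing:
        means += np.array([shift[c] for c in classes])
    transitions = np.maximum(
        rng.normal(means, spec.transition_sd_bp, spec.n_genes), 2_000.0
    ).astype(int)
    strands = np.where(rng.random(spec.n_genes) < 0.5, "+", "-")

    starts = np.empty(spec.n_genes, dtype=np.int64)
    pos = spec.gap_bp
    for g in range(spec.n_genes):
        starts[g] = pos
        pos += sizes[g] + spec.gap_bp
    total_len = pos + spec.gap_bp
    n_bins = -(-total_len // spec.bin_size)
    bins = BinTable("chrSim", spec.bin_size, n_bins)

    # eigenvector-like track: weak B background, planted A extent per gene
    values = np.full(n_bins, -0.05)
    gro_iv: list[tuple[int, int, float]] = []
    rows, truth_rows = [], []
    for g in range(spec.n_genes):
        s, e = int(starts[g]), int(starts[g] + sizes[g])
        strand = strands[g]
        tss = s if strand == "+" else e - 1
        tts = e - 1 if strand == "+" else s
        t = int(transitions[g])
        if strand == "+":
            a_lo, a_hi = s, min(s + t, e)
            b_lo, b_hi = min(s + t, e), e
        else:
            a_lo, a_hi = max(e - t, s), e
            b_lo, b_hi = s, max(e - t, s)
        values[a_lo // spec.bin_size : -(-a_hi // spec.bin_size)] = spec.amplitude
        if b_hi > b_lo:
            values[b_lo // spec.bin_size : -(-b_hi // spec.bin_size)] = -spec.amplitude

        jitter = rng.uniform(0.9, 1.1)
        p_val = spec.promoter_density[classes[g]] * jitter
        b_val = spec.body_density[classes[g]] * jitter
        p_lo, p_hi = tss - 250, tss + 250
        gro_iv.append((p_lo, p_hi, p_val))
        if strand == "+":
            gro_iv.append((p_hi, e, b_val))
        else:
            gro_iv.append((s, p_lo, b_val))

        rows.append((bins.chrom, s, e, f"gene{g}", 0, strand))
        truth_rows.append(
            {
                "name": f"gene{g}",
                "length": sizes[g],
                "strand": strand,
                "transition_bp": t,
                "pausing_class": classes[g],
                "expected_class": "A/B" if t < sizes[g] else "A/A",
            }
        )
    values += rng.normal(0.0, spec.track_noise_sd, n_bins)

    gro_iv.sort()
    gro = SignalTrack(
        bins.chrom,
        np.array([iv[0] for iv in gro_iv]),
        np.array([iv[1] for iv in gro_iv]),
        np.array([iv[2] for iv in gro_iv]),
    )
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                        "strand"])
    track = EigenTrack(bins, values, component=1, oriented=True)
    return GeneSet(genes=genes, track=track, gro=gro, truth=pd.DataFrame(truth_rows))
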