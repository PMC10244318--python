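import numpy as np
import pandas as pd
import pytest

import finecomp as fc
from finecomp.errors import EmptyDomainError


def make_track(values, bin_size=500):
    bins = fc.BinTable("chr1", bin_size, len(values))
    return fc.EigenTrack(bins, np.asarray(values, dtype=float), oriented=True)


def gene_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                       "strand"])


class TestConcordanceClasses:
    def test_tss_a_tts_b_is_discordant(self):
        track = make_track([0.5, 0.5, -0.2, -0.2])
        genes = gene_frame([("chr1", 100, 1900, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        assert rec["class"].iloc[0] == "A/B"

    def test_tss_a_tts_a_is_concordant(self):
        track = make_track([0.5, 0.1, 0.1, 0.1])
        genes = gene_frame([("chr1", 100, 1900, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        assert rec["class"].iloc[0] == "A/A"

    def test_tss_in_b_excluded(self):
        track = make_track([-0.3, 0.5, 0.5, 0.5])
        genes = gene_frame([("chr1", 100, 1900, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        assert rec["class"].iloc[0] == "excluded"
        assert rec["exclusion_reason"].iloc[0] == "TSS not in A"

    def test_strand_symmetry(self):
        """Mirroring coordinates and flipping strands leaves classes unchanged."""
        gs = fc.generate_gene_set(fc.GeneSetSpec(n_genes=30, seed=4))
        rec = fc.classify_gene_compartments(gs.genes, gs.track)
        L = gs.track.bins.length
        mirrored = gs.genes.copy()
        mirrored["start"] = L - gs.genes["end"]
        mirrored["end"] = L - gs.genes["start"]
        mirrored["strand"] = np.where(gs.genes["strand"] == "+", "-", "+")
        mtrack = fc.EigenTrack(gs.track.bins, gs.track.values[::-1].copy(),
                               oriented=True)
        mrec = fc.classify_gene_compartments(mirrored, mtrack)
        assert (rec["class"].to_numpy() == mrec["class"].to_numpy()).all()

    def test_rescaling_invariance(self):
        gs = fc.generate_gene_set(fc.GeneSetSpec(n_genes=30, seed=4))
        rec = fc.classify_gene_compartments(gs.genes, gs.track)
        scaled = fc.EigenTrack(gs.track.bins, gs.track.values * 17.3, oriented=True)
        rec2 = fc.classify_gene_compartments(gs.genes, scaled)
        assert (rec["class"].to_numpy() == rec2["class"].to_numpy()).all()


class TestDiscordanceBySize:
    def test_extremes(self):
        track = make_track([0.5] * 10)
        genes = gene_frame([("chr1", 100, 4000, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        frac = fc.discordance_by_size(rec, size_bins=(0, 10_000))
        assert frac.iloc[0] == 0.0

    def test_empty_class_is_nan_not_zero(self):
        track = make_track([0.5] * 10)
        genes = gene_frame([("chr1", 100, 4000, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        frac = fc.discordance_by_size(rec, size_bins=(0, 1000, 10_000))
        assert np.isnan(frac.iloc[0]) and frac.iloc[1] == 0.0

    def test_monotone_with_fixed_transition(self):
        """Longer genes are more often discordant for a fixed A extent."""
        gs = fc.generate_gene_set(fc.GeneSetSpec(n_genes=300, seed=8))
        rec = fc.classify_gene_compartments(gs.genes, gs.track)
        frac = fc.discordance_by_size(
            rec, size_bins=(0, 40_000, 80_000, 160_000, 320_000)
        ).to_numpy()
        vals = frac[np.isfinite(frac)]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))


class TestProfileCrossing:
    def test_all_positive_never_crosses(self):
        track = make_track([0.5] * 20)
        genes = gene_frame([("chr1", 0, 10_000, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        _, crossing = fc.tss_anchored_profile(rec, track, max_dist=5000)
        assert crossing is None

    def test_linear_profile_crosses_midway(self):
        # values fall linearly from +1 to -1 over 100 kb => crossing at 50 kb
        nbins = 201
        vals = np.linspace(1.0, -1.0, nbins)
        track = make_track(vals)
        genes = gene_frame([("chr1", 0, nbins * 500, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        _, crossing = fc.tss_anchored_profile(rec, track, max_dist=100_000)
        assert crossing == pytest.approx(50_000, abs=500)

    def test_contributions_truncate_at_tts(self):
        # gene of 2 kb: distances past the TTS get no contribution
        track = make_track([0.5] * 20)
        genes = gene_frame([("chr1", 0, 2000, "g", 0, "+")])
        rec = fc.classify_gene_compartments(genes, track)
        profile, _ = fc.tss_anchored_profile(rec, track, max_dist=10_000)
        assert profile["distance"].max() <= 2000


class TestPausingIndex:
    def test_uniform_signal_gives_unit_pi(self):
        gro = fc.SignalTrack("chr1", [0], [100_000], [1.0])
        gene = pd.Series({"tss": 10_000, "tts": 40_000, "strand": "+"})
        assert fc.pausing_index(gro, gene) == pytest.approx(1.0)

    def test_promoter_only_signal_is_infinite(self):
        gro = fc.SignalTrack("chr1", [9_800], [10_200], [5.0])
        gene = pd.Series({"tss": 10_000, "tts": 40_000, "strand": "+"})
        assert np.isinf(fc.pausing_index(gro, gene))

    def test_silent_gene_is_undefined(self):
        gro = fc.SignalTrack("chr1", [90_000], [90_100], [5.0])
        gene = pd.Series({"tss": 10_000, "tts": 40_000, "strand": "+"})
        assert np.isnan(fc.pausing_index(gro, gene))

    def test_crafted_densities(self):
        # 100 units over the 500 bp promoter window, 100 over a 10 kb body
        # (body begins 500 bp past the TSS): PI = (100/0.5)/(100/10) = 20
        tss = 10_000
        gro = fc.SignalTrack(
            "chr1",
            [tss - 250, tss + 500],
            [tss + 250, tss + 10_500],
            [100 / 500, 100 / 10_000],
        )
        gene = pd.Series({"tss": tss, "tts": tss + 10_499, "strand": "+"})
        assert fc.pausing_index(gro, gene) == pytest.approx(20.0, rel=1e-3)


class TestPausingTertiles:
    def records(self, lengths, strand="+"):
        rows = []
        pos = 10_000
        for k, L in enumerate(lengths):
            rows.append(("chr1", pos, pos + L, f"g{k}", 0, strand))
            pos += L + 10_000
        genes = gene_frame(rows)
        genes["tss"] = genes["start"]
        genes["tts"] = genes["end"] - 1
        genes["length"] = genes["end"] - genes["start"]
        return genes

    def test_six_genes_split_two_two_two(self):
        rec = self.records([30_000] * 6)
        # increasing promoter signal -> increasing promoter-minus-body diff
        starts, ends, vals = [], [], []
        for k, row in enumerate(rec.itertuples(index=False)):
            starts.append(row.tss - 250)
            ends.append(row.tss + 250)
            vals.append(0.01 * (k + 1))
        gro = fc.SignalTrack("chr1", starts, ends, vals)
        out = fc.pausing_tertiles(rec, gro)
        assert out["pausing_class"].tolist() == [
            "elongating", "elongating", "mid", "mid", "paused", "paused"
        ]

    def test_short_genes_excluded(self):
        rec = self.records([15_000, 30_000, 30_000, 30_000])
        gro = fc.SignalTrack("chr1", [0], [200_000], [1.0])
        out = fc.pausing_tertiles(rec, gro)
        assert "g0" not in out["name"].tolist()

    def test_too_few_genes_raise(self):
        rec = self.records([30_000, 30_000])
        gro = fc.SignalTrack("chr1", [0], [100_000], [1.0])
        with pytest.raises(EmptyDomainError):
            fc.pausing_tertiles(rec, gro)

    def test_planted_classes_recovered(self):
        gs = fc.generate_gene_set(fc.GeneSetSpec(n_genes=90, seed=3))
        rec = fc.classify_gene_compartments(gs.genes, gs.track)
        out = fc.pausing_tertiles(rec, gs.gro)
        merged = out.merge(gs.truth[["name", "pausing_class"]], on="name",
                           suffixes=("", "_true"))
        acc = np.mean(merged["pausing_class"] == merged["pausing_class_true"])
        assert acc >= 0.95

    def test_paused_genes_more_discordant_when_coupled(self):
        """With the A extent coupled to elongation, paused genes show more
        discordance than elongating genes."""
        gs = fc.generate_gene_set(
            fc.GeneSetSpec(n_genes=150, seed=5, couple_pausing=True)
        )
        rec = fc.classify_gene_compartments(gs.genes, gs.track)
        out = fc.pausing_tertiles(rec, gs.gro)

        def disc_rate(cls):
            sub = out[out["pausing_class"] == cls]
            sub = sub[sub["class"].isin(["A/A", "A/B"])]
            return np.mean(sub["class"] == "A/B")

        assert disc_rate("paused") >= disc_rate("elongating")
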