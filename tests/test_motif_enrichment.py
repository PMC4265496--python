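"""Boundary peak strata, 6-mer tables, obs/exp ratios and ROC/AUC."""

import numpy as np
import pytest

import hmrnuc as h
from hmrnuc.boundary_profiles import Anchor
from hmrnuc.genomic_io import GenomeSequence, ValidationError
from hmrnuc.motif_enrichment import (
    boundary_kmer_table,
    boundary_peak_scores,
    cg_positions,
    genome_pattern_rate,
    kmer_enrichment,
    obs_exp_positional,
    roc_auc,
)
from hmrnuc.nucleosome_map import OccupancyTrack


def make_track(values):
    return OccupancyTrack("chr1", 0, np.asarray(values, dtype=float), 0.0, 0)


class TestPeakScores:
    def test_constant_track_strata_sizes(self):
        track = make_track(np.ones(10_000))
        anchors = [Anchor("chr1", 100 + 90 * i) for i in range(100)]
        scores = boundary_peak_scores(track, anchors)
        sizes = {s: sum(1 for x in scores if x.stratum == s) for s in ("bottom20", "mid", "top20")}
        assert abs(sizes["bottom20"] - 20) <= 1
        assert abs(sizes["top20"] - 20) <= 1
        assert len({x.score for x in scores}) == 1

    def test_window_mean_matches_hand_computation(self, rng):
        vals = rng.random(2000)
        track = make_track(vals)
        (score,) = boundary_peak_scores(track, [Anchor("chr1", 700)])
        assert abs(score.score - vals[700 - 73 : 700 + 74].mean()) < 1e-9

    def test_edge_boundary_masked_mean(self):
        vals = np.arange(200, dtype=float)
        track = make_track(vals)
        (score,) = boundary_peak_scores(track, [Anchor("chr1", 10)])
        assert score.score == pytest.approx(vals[0:84].mean())

    def test_percentile_cut_matches_sorting_oracle(self, rng):
        vals = rng.random(120_000)
        track = make_track(vals)
        anchors = [Anchor("chr1", int(p)) for p in rng.integers(100, 119_000, 100)]
        scores = boundary_peak_scores(track, anchors)
        raw = np.array([s.score for s in scores])
        order = np.argsort(raw, kind="stable")
        n_cut = round(0.2 * len(raw))
        for rank, idx in enumerate(order):
            expected = (
                "bottom20" if rank < n_cut
                else "top20" if rank >= len(raw) - n_cut
                else "mid"
            )
            assert scores[idx].stratum == expected


class TestKmerTable:
    def test_windowing_around_cg(self):
        genome = GenomeSequence("chr1", "TTTACACGTGATTT")
        # CG at positions 6-7; 6-mer = bases 4..9
        report = boundary_kmer_table(genome, [Anchor("chr1", 6, "5prime")])
        assert report.kmers == ["CACGTG"]

    def test_non_cg_boundary_skipped(self):
        genome = GenomeSequence("chr1", "A" * 30)
        report = boundary_kmer_table(genome, [Anchor("chr1", 10)])
        assert report.kmers == [] and report.n_skipped_not_cg == 1

    def test_palindromic_ebox_same_on_3prime(self):
        genome = GenomeSequence("chr1", "TTTACACGTGATTT")
        r5 = boundary_kmer_table(genome, [Anchor("chr1", 6, "5prime")])
        r3 = boundary_kmer_table(genome, [Anchor("chr1", 6, "3prime")])
        assert r5.kmers == r3.kmers == ["CACGTG"]

    def test_edge_window_skipped(self):
        genome = GenomeSequence("chr1", "CGAAAA")
        report = boundary_kmer_table(genome, [Anchor("chr1", 0)])
        assert report.kmers == [] and report.n_skipped_edge == 1


class TestEnrichment:
    def test_identical_sets_zero_ratio(self):
        kmers = ["CACGTG", "AACGTT", "CACGTG"]
        df = kmer_enrichment(kmers, list(kmers))
        assert np.allclose(df["log2_ratio"], 0.0)

    def test_frequencies_sum_to_one(self, rng):
        top = [f"{a}ACGTG" for a in rng.choice(list("ACGT"), 500)]
        bot = [f"{a}ACGTT" for a in rng.choice(list("ACGT"), 400)]
        df = kmer_enrichment(top, bot)
        assert df["freq_top"].sum() == pytest.approx(1.0, abs=1e-9)
        assert df["freq_bottom"].sum() == pytest.approx(1.0, abs=1e-9)
        assert df["count_top"].sum() == 500 and df["count_bottom"].sum() == 400

    def test_planted_enrichment_ranks_first(self, rng):
        other = ["TTCGAA", "AACGTT", "GTCGAC", "CTCGAG"]
        top = ["CACGTG" if rng.random() < 0.2 else other[rng.integers(4)] for _ in range(2000)]
        bot = ["CACGTG" if rng.random() < 0.02 else other[rng.integers(4)] for _ in range(2000)]
        df = kmer_enrichment(top, bot)
        assert df.iloc[0]["kmer"] == "CACGTG"

    def test_recount_oracle(self, rng):
        top = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(300)]
        bot = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(200)]
        df = kmer_enrichment(top, bot)
        for _, row in df.head(20).iterrows():
            assert row["freq_top"] == pytest.approx(top.count(row["kmer"]) / 300, abs=1e-12)
            assert row["freq_bottom"] == pytest.approx(bot.count(row["kmer"]) / 200, abs=1e-12)


class TestObsExp:
    def test_expected_matches_direct_enumeration(self):
        genome, _ = h.simulate_genome(length=50_000, cgi_spec={"count": 2, "length": 500}, seed=13)
        rate = genome_pattern_rate(genome, "CACGTG")
        seq = genome.seq
        n_match = n_tot = 0
        for p in range(2, len(seq) - 3):
            if seq[p : p + 2] == "CG":
                n_tot += 1
                if seq[p - 2 : p + 4] == "CACGTG":
                    n_match += 1
        assert rate == pytest.approx(n_match / n_tot, abs=1e-12)

    def test_pattern_without_central_cg_rejected(self):
        genome = GenomeSequence("chr1", "ACGT" * 100)
        with pytest.raises(ValidationError):
            obs_exp_positional(genome, [], pattern="AAATTT")

    def test_null_genome_ratios_near_one(self, analysis):
        # with boundary planting on, only index 0 deviates from unity
        ds = analysis["dataset"]
        df = obs_exp_positional(ds.genome, analysis["hmrs"])
        flank = df[df["cg_index"].abs() == 5]["ratio"]
        assert np.all((flank > 0.7) & (flank < 1.3))

    def test_planted_twofold_signal(self, analysis):
        ds = analysis["dataset"]
        df = obs_exp_positional(ds.genome, analysis["hmrs"]).set_index("cg_index")
        assert 1.7 <= df.loc[0, "ratio"] <= 2.3


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, size=10_000)
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.02

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.normal(size=30), 1)  # ties likely
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = 0.0
        for p in pos:
            for n in neg:
                wins += 1.0 if p > n else 0.5 if p == n else 0.0
        assert abs(res.auc - wins / (len(pos) * len(neg))) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=200)
        labels = (scores + rng.normal(size=200) > 0).astype(int)
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.exp(3 * scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_matches_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        scores = np.round(rng.normal(size=500), 1)
        labels = rng.integers(0, 2, size=500)
        assert roc_auc(scores, labels).auc == pytest.approx(
            metrics.roc_auc_score(labels, scores), abs=1e-12
        )


def test_cg_positions_and_indicator():
    genome = GenomeSequence("chr1", "ACGTCGA")
    assert list(cg_positions(genome)) == [1, 4]
    ind = h.cg_indicator(genome, [0, 1, 4, 6])
    assert list(ind) == [0.0, 1.0, 1.0, 0.0]
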