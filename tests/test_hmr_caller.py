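"""Two-state beta-binomial HMM: fitting, decoding, boundaries, gaps."""

import numpy as np
import pytest
from scipy.stats import betabinom

import hmrnuc as h
from hmrnuc.genomic_io import CpGRecord, GenomicInterval
from hmrnuc.hmr_caller import HMRInterval, HmmParams, extract_boundary, posterior_hypo
from hmrnuc.synthetic_data import simulate_hmm_counts

TOY_PARAMS = HmmParams(
    pi=np.array([0.4, 0.6]),
    trans=np.array([[0.8, 0.2], [0.1, 0.9]]),
    alpha=np.array([0.5, 8.0]),
    beta=np.array([8.0, 1.5]),
)


def brute_force_posteriors(meth, total, params):
    """Exhaustive sum over all state paths (oracle for small chains)."""
    n = len(meth)
    post = np.zeros((n, 2))
    z = 0.0
    for mask in range(2**n):
        states = [(mask >> i) & 1 for i in range(n)]
        p = params.pi[states[0]]
        for i in range(1, n):
            p *= params.trans[states[i - 1], states[i]]
        for i, s in enumerate(states):
            p *= betabinom.pmf(meth[i], total[i], params.alpha[s], params.beta[s])
        z += p
        for i, s in enumerate(states):
            post[i, s] += p
    return post / z


class TestPosterior:
    def test_three_site_posterior_matches_path_enumeration(self):
        meth = np.array([0, 1, 9])
        total = np.array([10, 12, 10])
        cpgs = [CpGRecord("chr1", 100 * i, int(m), int(t)) for i, (m, t) in enumerate(zip(meth, total))]
        gamma_hypo = posterior_hypo(cpgs, TOY_PARAMS)["chr1"]
        oracle = brute_force_posteriors(meth, total, TOY_PARAMS)
        assert np.max(np.abs(gamma_hypo - oracle[:, 0])) < 1e-9

    def test_posterior_rows_sum_to_one(self):
        records, _ = simulate_hmm_counts(n_cpgs=500, seed=3)
        gamma_hypo = posterior_hypo(records, TOY_PARAMS)["chr1"]
        # posterior_hypo returns P(HYPO); complement is P(METH) by construction
        assert np.all((gamma_hypo >= 0) & (gamma_hypo <= 1))


class TestFit:
    def test_loglik_nondecreasing_on_random_datasets(self):
        for seed in range(50):
            records, _ = simulate_hmm_counts(
                n_cpgs=120, coverage_mean=8.0, seed=seed
            )
            fit = h.fit_hmm(records, max_iter=25, tol=0.0, seed=seed)
            ll = np.array(fit.log_likelihoods)
            assert np.all(np.diff(ll) >= -1e-8), f"seed {seed}"

    def test_fully_methylated_data_gives_no_hypo_occupancy(self):
        cpgs = [CpGRecord("chr1", 50 * i, 10, 10) for i in range(400)]
        fit = h.fit_hmm(cpgs, seed=0)
        t = fit.params.trans
        stationary_hypo = t[1, 0] / (t[0, 1] + t[1, 0])
        assert stationary_hypo < 0.01

    def test_recovers_planted_state_levels(self):
        records, _ = simulate_hmm_counts(
            n_cpgs=10_000, hypo_level=0.05, meth_level=0.85, mean_block=20.0,
            coverage_mean=10.0, seed=11,
        )
        fit = h.fit_hmm(records, seed=11)
        levels = fit.params.expected_levels
        assert abs(levels[0] - 0.05) <= 0.05
        assert abs(levels[1] - 0.85) <= 0.05

    def test_too_few_cpgs_rejected(self):
        with pytest.raises(Exception):
            h.fit_hmm([CpGRecord("chr1", 0, 1, 10)])


class TestDecode:
    def test_planted_block_recovered(self):
        rng = np.random.default_rng(5)
        pos = np.arange(1000) * 40
        hypo = np.zeros(1000, dtype=bool)
        hypo[400:430] = True  # planted 30-CpG unmethylated block
        levels = np.where(hypo, 0.02, 0.9)
        meth = rng.binomial(20, levels)
        cpgs = [CpGRecord("chr1", int(p), int(m), 20) for p, m in zip(pos, meth)]
        hmrs, _ = h.call_hmrs(cpgs, seed=2)
        assert len(hmrs) == 1
        called = set(hmrs[0].cpg_positions)
        planted = set(int(p) for p in pos[hypo])
        jaccard = len(called & planted) / len(called | planted)
        assert jaccard >= 0.9

    def test_all_methylated_yields_empty(self):
        cpgs = [CpGRecord("chr1", 50 * i, 19, 20) for i in range(300)]
        hmrs, _ = h.call_hmrs(cpgs, seed=0)
        assert hmrs == []

    def test_output_disjoint_and_sorted(self, analysis):
        hmrs = analysis["hmrs"]
        for a, b in zip(hmrs[:-1], hmrs[1:]):
            assert a.interval.end <= b.interval.start

    def test_level_flip_maps_hmrs_onto_methylated_blocks(self):
        records, states = simulate_hmm_counts(
            n_cpgs=2000, hypo_level=0.03, meth_level=0.97, coverage_mean=30.0, seed=9
        )
        flipped = [
            CpGRecord(r.chrom, r.pos, r.total_count - r.meth_count, r.total_count)
            for r in records
        ]
        fit = h.fit_hmm(records, seed=1)
        fit_f = h.fit_hmm(flipped, seed=1)
        hmrs = h.decode_hmrs(records, fit.params, min_cpgs=1, max_gap=10**9)
        hmrs_f = h.decode_hmrs(flipped, fit_f.params, min_cpgs=1, max_gap=10**9)
        hypo_pos = {p for hm in hmrs for p in hm.cpg_positions}
        flip_pos = {p for hm in hmrs_f for p in hm.cpg_positions}
        all_pos = {r.pos for r in records}
        assert flip_pos == all_pos - hypo_pos


def make_toy_hmr():
    hmr = HMRInterval(
        interval=GenomicInterval("chr1", 200, 301),
        cpg_positions=(200, 240, 300),
        mean_level=0.03,
    )
    all_pos = np.array([120, 200, 240, 300, 410])
    return hmr, all_pos


class TestBoundaries:
    @pytest.mark.parametrize(
        "mode,side,expected",
        [
            ("first_unmeth", "5prime", 200),
            ("second_unmeth", "5prime", 240),
            ("adjacent_meth", "5prime", 120),
            ("first_unmeth", "3prime", 300),
            ("second_unmeth", "3prime", 240),
            ("adjacent_meth", "3prime", 410),
        ],
    )
    def test_boundary_conventions(self, mode, side, expected):
        hmr, all_pos = make_toy_hmr()
        assert extract_boundary(hmr, all_pos, mode, side) == expected

    def test_single_cpg_hmr_has_no_second_unmeth(self):
        hmr = HMRInterval(GenomicInterval("chr1", 100, 101), (100,), 0.0)
        assert extract_boundary(hmr, np.array([100]), "second_unmeth", "5prime") is None

    def test_chromosome_start_has_no_adjacent(self):
        hmr = HMRInterval(GenomicInterval("chr1", 100, 151), (100, 150), 0.0)
        assert extract_boundary(hmr, np.array([100, 150]), "adjacent_meth", "5prime") is None

    def test_invalid_mode_rejected(self):
        hmr, all_pos = make_toy_hmr()
        with pytest.raises(ValueError):
            extract_boundary(hmr, all_pos, "nearest", "5prime")


class TestGapStats:
    def test_toy_gaps(self):
        hmr, all_pos = make_toy_hmr()
        for side in ("5prime", "3prime"):
            tab = hmr.boundary_5 if side == "5prime" else hmr.boundary_3
            for mode in ("first_unmeth", "second_unmeth", "adjacent_meth"):
                tab[mode] = extract_boundary(hmr, all_pos, mode, side)
        stats = h.boundary_gap_stats([hmr])
        assert list(stats.gaps_5prime) == [80]
        assert list(stats.gaps_3prime) == [110]
        assert stats.mean == 95

    def test_empty_input(self):
        stats = h.boundary_gap_stats([])
        assert stats.n == 0 and np.isnan(stats.mean)

    def test_planted_gap_distribution_recovered(self):
        genome, truth = h.simulate_genome(length=600_000, cgi_spec={"count": 6}, seed=21)
        sim = h.simulate_methylome(
            genome, truth,
            plan=h.HmrPlan(n_common=60, n_specific_a=0, n_specific_b=0, n_extended=0,
                           cgi_fraction_common=0.0),
            boundary_gap=(100, 200), seed=22,
        )
        hmrs, _ = h.call_hmrs(sim.records["a"], seed=23)
        stats = h.boundary_gap_stats(hmrs)
        assert abs(stats.mean - 150) <= 10
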