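"""k-mer featurization, coordinate-descent Lasso, and genome scoring."""

import numpy as np
import pytest

import hmrnuc as h
from hmrnuc.genomic_io import ValidationError
from hmrnuc.inos_model import (
    FEATURE_NAMES,
    N_FEATURES,
    WINDOW,
    HALF,
    LassoModel,
    featurize_window,
    fit_lasso,
    lambda_max,
    revcomp,
    score_inos,
    train_on_track,
)
from hmrnuc.nucleosome_map import OccupancyTrack


def random_window(rng):
    return "".join(rng.choice(list("ACGT"), size=WINDOW))


class TestFeaturize:
    def test_homopolymer(self):
        x = featurize_window("A" * WINDOW)
        names = dict(zip(FEATURE_NAMES, x))
        assert names["4mer_AAAA"] == pytest.approx(144 / 144)
        assert names["gc_fraction"] == 0.0

    def test_alternating_cg(self):
        seq = ("CG" * 74)[:WINDOW]
        names = dict(zip(FEATURE_NAMES, featurize_window(seq)))
        assert names["2mer_CG"] == pytest.approx(73 / 146)
        assert names["gc_fraction"] == pytest.approx(1.0)

    def test_reverse_complement_collapsing_exact(self, rng):
        for _ in range(100):
            s = random_window(rng)
            assert np.array_equal(featurize_window(s), featurize_window(revcomp(s)))

    def test_normalized_counts_in_unit_interval(self, rng):
        x = featurize_window(random_window(rng))
        assert np.all(x >= 0) and np.all(x <= 1)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            featurize_window("ACGT")

    def test_n_rejected(self):
        with pytest.raises(ValidationError):
            featurize_window("N" * WINDOW)


class TestLasso:
    def test_lambda_zero_matches_normal_equations(self, rng):
        X = rng.normal(size=(50, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + 0.1 * rng.normal(size=50)
        model = fit_lasso(X, y, lam=0.0, max_iter=20_000, tol=1e-13)
        X1 = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
        assert np.max(np.abs(model.weights - beta[1:])) < 1e-6
        assert abs(model.intercept - beta[0]) < 1e-6

    def test_above_lambda_max_all_weights_zero(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        lam = lambda_max(X, y) * 1.001
        model = fit_lasso(X, y, lam=lam)
        assert np.all(model.weights == 0.0)
        assert model.intercept == pytest.approx(y.mean())

    def test_single_feature_soft_threshold_closed_form(self, rng):
        x = rng.normal(size=(60, 1))
        y = 2.0 * x[:, 0] + rng.normal(size=60)
        lam = 0.3
        model = fit_lasso(x, y, lam=lam, max_iter=10_000, tol=1e-13)
        xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        yc = y - y.mean()
        rho = xs @ yc / len(y)
        csq = xs @ xs / len(y)
        expected_std = np.sign(rho) * max(abs(rho) - lam, 0.0) / csq
        assert model.weights[0] * x[:, 0].std() == pytest.approx(expected_std, abs=1e-8)

    def test_path_nonzeros_nonincreasing(self, rng):
        X = rng.normal(size=(80, 20))
        y = X[:, 0] - X[:, 3] + 0.5 * rng.normal(size=80)
        lams = [0.0, 0.01, 0.05, 0.1, 0.3, 1.0]
        nnz = [fit_lasso(X, y, lam=l).n_nonzero() for l in lams]
        assert all(a >= b for a, b in zip(nnz[:-1], nnz[1:]))

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        m1 = fit_lasso(X, y, lam=0.05, seed=7)
        m2 = fit_lasso(X, y, lam=0.05, seed=7)
        assert np.array_equal(m1.weights, m2.weights)

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(100, 10))
        y = X[:, 0] - 0.5 * X[:, 2] + 0.2 * rng.normal(size=100)
        lam = 0.05
        mine = fit_lasso(X, y, lam=lam, max_iter=20_000, tol=1e-13)
        ref = sklearn.Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-12)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        ref.fit((X - mu) / sd, y)
        assert np.max(np.abs(mine.weights * sd - ref.coef_)) < 1e-5

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            fit_lasso(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]), lam=0.1)

    def test_json_round_trip(self, tmp_path, rng):
        model = LassoModel(FEATURE_NAMES, rng.normal(size=N_FEATURES), 0.4, 0.01)
        p = tmp_path / "m.json"
        model.to_json(p)
        back = LassoModel.from_json(p)
        assert np.array_equal(back.weights, model.weights)
        assert back.feature_names == model.feature_names


class TestScoring:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(3)
        return LassoModel(FEATURE_NAMES, 0.1 * rng.normal(size=N_FEATURES), 0.25, 0.01)

    def test_matches_per_window_featurization(self, model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        scores = score_inos(seq, model)
        for pos in rng.integers(HALF, len(seq) - HALF, size=50):
            x = featurize_window(seq[pos - HALF : pos + HALF + 1])
            assert abs(scores[pos] - (x @ model.weights + model.intercept)) < 1e-9

    def test_reverse_complement_reverses_track_exactly(self, model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        s0 = score_inos(seq, model)
        s1 = score_inos(revcomp(seq), model)[::-1]
        assert np.array_equal(np.isnan(s0), np.isnan(s1))
        assert np.array_equal(s0[~np.isnan(s0)], s1[~np.isnan(s1)])

    def test_periodic_sequence_constant_score(self, model):
        seq = "CG" * 300
        scores = score_inos(seq, model)
        defined = scores[~np.isnan(scores)]
        assert np.ptp(defined) < 1e-9

    def test_edges_and_n_windows_undefined(self, model):
        seq = "ACGT" * 100 + "N" + "ACGT" * 100
        scores = score_inos(seq, model)
        assert np.all(np.isnan(scores[:HALF])) and np.all(np.isnan(scores[-HALF:]))
        n_pos = 400
        assert np.all(np.isnan(scores[n_pos - HALF : n_pos + HALF + 1]))


class TestTrainOnTrack:
    def test_recovers_planted_gc_signal(self, rng):
        genome, _ = h.simulate_genome(length=200_000, cgi_spec={"count": 4}, seed=31)
        from hmrnuc.inos_model import _sliding_sum, encode

        gc = ((encode(genome.seq) == 1) | (encode(genome.seq) == 2)).astype(float)
        occ = _sliding_sum(gc, WINDOW) / WINDOW
        vals = np.zeros(len(genome.seq))
        vals[HALF : HALF + len(occ)] = 4 * occ + 0.05 * rng.normal(size=len(occ)) + 1
        track = OccupancyTrack(genome.chrom, 0, np.clip(vals, 0, None), 0.0, 0)
        model = train_on_track(genome, track, sample_n=5000, lam=1e-3, seed=5)
        # GC fraction and the collapsed C/G mononucleotide feature are the
        # same quantity; the planted positive signal must land on them
        gc_like = [i for i, nm in enumerate(FEATURE_NAMES) if nm in ("1mer_C", "gc_fraction")]
        assert model.weights[gc_like].sum() > 0
        scores = score_inos(genome, model)
        held = rng.choice(np.arange(HALF, len(genome.seq) - HALF), 3000, replace=False)
        yp, yt = scores[held], track.values[held]
        ok = ~np.isnan(yp)
        r2 = 1 - np.sum((yp[ok] - yt[ok]) ** 2) / np.sum((yt[ok] - yt[ok].mean()) ** 2)
        assert r2 >= 0.5

    def test_retraining_same_seed_identical(self, small_genome):
        genome, _ = small_genome
        vals = np.ones(len(genome.seq))
        track = OccupancyTrack(genome.chrom, 0, vals, 0.0, 0)
        m1 = train_on_track(genome, track, sample_n=500, lam=0.01, seed=3)
        m2 = train_on_track(genome, track, sample_n=500, lam=0.01, seed=3)
        assert np.array_equal(m1.weights, m2.weights)

    def test_oversampling_rejected(self, small_genome):
        genome, _ = small_genome
        track = OccupancyTrack(genome.chrom, 0, np.ones(len(genome.seq)), 0.0, 0)
        with pytest.raises(ValidationError):
            train_on_track(genome, track, sample_n=10**7)


def test_default_model_loads_and_scores():
    model = h.default_model()
    assert model.metadata.get("synthetic") is True
    scores = score_inos("ACGTAC" * 50, model)
    assert np.sum(~np.isnan(scores)) > 0
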