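"""Methylome stage: QC gates, beta-binomial normalization, HVF, clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest

from crossct import (
    ResolutionCriteria,
    beta_from_moments,
    consensus_cluster,
    filter_cells,
    filter_features,
    finalize_clusters,
    fit_beta_prior,
    normalize_rates,
    pca_reduce,
    select_hvf,
    select_resolution,
)
from crossct.methylome import ClusterEvaluation


def metrics_row(**overrides):
    row = {
        "mccc_rate": 0.02,
        "mcg_rate": 0.7,
        "mch_rate": 0.1,
        "final_reads": 600_000,
        "mapping_rate": 0.6,
    }
    row.update(overrides)
    return row


class TestFilterCells:
    def test_passing_cell_kept(self):
        keep = filter_cells(pd.DataFrame([metrics_row()]))
        assert keep.all()

    @pytest.mark.parametrize(
        "override",
        [
            {"mccc_rate": 0.03},  # boundary is not strict-less
            {"mcg_rate": 0.5},
            {"mch_rate": 0.2},
            {"final_reads": 500_000},
            {"mapping_rate": 0.5},
        ],
    )
    def test_boundary_values_rejected(self, override):
        keep = filter_cells(pd.DataFrame([metrics_row(**override)]))
        assert not keep.any()

    def test_one_violation_each_rejects_all(self):
        # ten cells, each violating exactly one threshold; independent
        # re-evaluation of each rule must agree with the mask
        violations = [
            {"mccc_rate": 0.05},
            {"mcg_rate": 0.4},
            {"mch_rate": 0.25},
            {"final_reads": 100_000},
            {"mapping_rate": 0.3},
        ] * 2
        frame = pd.DataFrame([metrics_row(**v) for v in violations])
        keep, reasons = filter_cells(frame, return_reasons=True)
        assert (~keep).all()
        for v, reason in zip(violations, reasons):
            assert reason == next(iter(v))

    def test_missing_metric_rejected_incomplete(self):
        frame = pd.DataFrame([metrics_row(mcg_rate=np.nan)])
        keep, reasons = filter_cells(frame, return_reasons=True)
        assert not keep.any() and reasons[0] == "incomplete"


class TestFilterFeatures:
    def test_coverage_bounds(self):
        means = np.array([100.0, 250.0, 1000.0, 3000.0, 3500.0])
        cov = np.tile(means, (4, 1))
        mask = filter_features(cov)
        assert mask.tolist() == [False, True, True, True, False]

    def test_boundary_249_removed_250_kept(self):
        cov = np.tile([249.0, 250.0], (3, 1))
        assert filter_features(cov).tolist() == [False, True]

    def test_blacklist_intersection(self):
        cov = np.full((2, 3), 500.0)
        features = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [0, 100_000, 0],
                "end": [100_000, 200_000, 100_000],
            }
        )
        mask = filter_features(
            cov, features=features, blacklist=[("chr1", 150_000, 160_000)]
        )
        assert mask.tolist() == [True, False, True]


class TestBetaPrior:
    def test_moment_plugin_example(self):
        a, b = beta_from_moments(0.5, 0.05)
        assert a == pytest.approx(2.0) and b == pytest.approx(2.0)
        # beta moment identities close the loop
        assert a / (a + b) == pytest.approx(0.5)
        assert 0.5 * 0.5 / (a + b + 1) == pytest.approx(0.05)

    def test_exact_round_trip_on_grid(self):
        # method of moments on exact Beta moments is the identity
        grid = [(a, b) for a in (0.5, 1, 2, 5, 20) for b in (0.5, 1, 2, 5, 20)]
        for a, b in grid:
            m = a / (a + b)
            v = a * b / ((a + b) ** 2 * (a + b + 1))
            ar, br = beta_from_moments(m, v)
            assert ar == pytest.approx(a, rel=1e-10)
            assert br == pytest.approx(b, rel=1e-10)

    def test_weak_prior_limit(self):
        m = 0.5
        v = m * (1 - m) * (1 - 1e-9)
        a, b = beta_from_moments(m, v)
        assert 0 < a < 1e-6 and 0 < b < 1e-6

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(0)
        rates = rng.beta(5, 15, size=100_000)
        m, v = rates.mean(), rates.var(ddof=1)
        a, b = beta_from_moments(m, v)
        assert a == pytest.approx(5, rel=0.05)
        assert b == pytest.approx(15, rel=0.05)

    def test_overdispersion_errors(self):
        with pytest.raises(ValueError, match="bound"):
            beta_from_moments(0.5, 0.3)
        with pytest.raises(ValueError, match="mean"):
            beta_from_moments(1.0, 0.01)

    def test_weaker_priors_for_larger_variance(self):
        a1, b1 = beta_from_moments(0.5, 0.01)
        a2, b2 = beta_from_moments(0.5, 0.1)
        assert a2 + b2 < a1 + b1

    def test_fit_from_counts(self):
        rng = np.random.default_rng(1)
        levels = rng.beta(2, 2, size=(3, 500))
        cov = rng.poisson(200, size=(3, 500))
        mc = rng.binomial(cov, levels)
        prior = fit_beta_prior(mc, cov)
        assert prior.alpha.shape == (3,)
        assert np.allclose(prior.mean, prior.sample_mean)


class TestNormalizeRates:
    @staticmethod
    def prior():
        return fit_beta_prior(
            np.random.default_rng(0).binomial(20, 0.5, (1, 200)),
            np.full((1, 200), 20),
        )

    def test_zero_coverage_is_exactly_one(self):
        prior = self.prior()
        out = normalize_rates(np.zeros((1, 3)), np.zeros((1, 3)), prior)
        assert (out == 1.0).all()

    def test_hand_example(self):
        from crossct.methylome import BetaPrior

        prior = BetaPrior(
            alpha=np.array([2.0]), beta=np.array([2.0]),
            sample_mean=np.array([0.5]), sample_var=np.array([0.05]),
        )
        out = normalize_rates(np.array([[5]]), np.array([[10]]), prior)
        assert out[0, 0] == pytest.approx(1.0)  # posterior 0.5 / mean 0.5

    def test_large_coverage_limit(self):
        from crossct.methylome import BetaPrior

        prior = BetaPrior(
            alpha=np.array([2.0]), beta=np.array([2.0]),
            sample_mean=np.array([0.5]), sample_var=np.array([0.05]),
        )
        r = 0.8
        cov = 10_000_000
        out = normalize_rates(
            np.array([[int(cov * r)]]), np.array([[cov]]), prior
        )
        assert out[0, 0] == pytest.approx(r / 0.5, rel=1e-4)

    def test_posterior_convex_combination_and_no_nan(self):
        rng = np.random.default_rng(2)
        cov = rng.poisson(5, (4, 300))
        mc = rng.binomial(cov, 0.3)
        prior = fit_beta_prior(mc, cov)
        out = normalize_rates(mc, cov, prior)
        assert np.isfinite(out).all() and (out >= 0).all()
        posterior = out * prior.mean[:, None]
        covered = cov > 0
        raw = np.where(covered, mc / np.where(covered, cov, 1), 0.0)
        lo = np.minimum(prior.mean[:, None], raw)
        hi = np.maximum(prior.mean[:, None], raw)
        assert (posterior[covered] >= lo[covered] - 1e-12).all()
        assert (posterior[covered] <= hi[covered] + 1e-12).all()


class TestSelectHVF:
    def test_tie_breaking_by_index(self):
        # exactly identical columns: every dispersion is exactly equal, so
        # the contract selects the first n_select features by index
        X = np.ones((30, 50))
        cov = np.full((30, 50), 300.0)
        idx = select_hvf(X, cov, n_select=10)
        assert idx.tolist() == list(range(10))

    def test_outlier_feature_ranks_first(self):
        rng = np.random.default_rng(1)
        X = 1 + 0.01 * rng.standard_normal((100, 40))
        X[:, 7] = 1 + 2.0 * rng.standard_normal(100)
        cov = np.full((100, 40), 300.0)
        # one bin: the high-dispersion feature towers over its bin peers
        idx = select_hvf(X, cov, n_select=1, mean_bins=1, cov_bins=1)
        assert idx.tolist() == [7]

    def test_planted_high_variance_recovered(self):
        rng = np.random.default_rng(2)
        n_feat = 2000
        X = 1 + 0.05 * rng.standard_normal((150, n_feat))
        planted = rng.choice(n_feat, 100, replace=False)
        X[:, planted] += 0.8 * rng.standard_normal((150, 100))
        cov = rng.poisson(300, (150, n_feat)).astype(float)
        idx = select_hvf(X, cov, n_select=1000)
        assert len(np.intersect1d(idx, planted)) >= 95

    def test_too_few_features_warns_and_returns_all(self):
        X = np.random.default_rng(0).uniform(0.5, 1.5, (10, 20))
        with pytest.warns(UserWarning, match="returning all"):
            idx = select_hvf(X, np.full((10, 20), 300.0), n_select=100)
        assert len(idx) == 20


def two_blob_pcs(n=120, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n // 2, 4)) + np.array([6, 0, 0, 0])
    b = rng.standard_normal((n // 2, 4)) - np.array([6, 0, 0, 0])
    return np.vstack([a, b]), np.repeat([0, 1], n // 2)


class TestConsensusCluster:
    def test_two_blobs_clean_bipartition(self):
        pcs, truth = two_blob_pcs()
        res = consensus_cluster(pcs, resolution=0.2, n_runs=25, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert (res.labels >= 0).all()
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_single_run_equals_that_run(self):
        pcs, _ = two_blob_pcs(seed=1)
        res = consensus_cluster(pcs, resolution=0.2, n_runs=1, seed=1)
        run = res.ensemble[:, 0]
        core = res.labels >= 0
        assert core.all()
        # same partition up to label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(run, res.labels) == 1.0

    def test_permutation_invariance_of_runs(self):
        pcs, _ = two_blob_pcs(seed=2)
        res = consensus_cluster(pcs, resolution=0.2, n_runs=20, seed=2)
        rng = np.random.default_rng(0)
        shuffled = res.ensemble[:, rng.permutation(20)]
        # relabel clusters within each run
        relabeled = shuffled.copy()
        for c in range(relabeled.shape[1]):
            relabeled[:, c] = 7 - relabeled[:, c]
        from scipy.spatial.distance import pdist

        assert np.allclose(
            pdist(res.ensemble, "hamming"), pdist(relabeled, "hamming")
        )

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            consensus_cluster(np.zeros((5, 2)), k_neighbors=15)


class TestFinalizeAndSelect:
    def test_separated_clusters_perfect_accuracy(self):
        pcs, _ = two_blob_pcs(n=200, seed=3)
        res = consensus_cluster(pcs, resolution=0.2, n_runs=25, seed=3)
        res = finalize_clusters(res, pcs, seed=3)
        assert res.accuracy == 1.0

    def test_shuffled_labels_chance_accuracy(self):
        # 4 balanced random labels on structureless data: balanced
        # accuracy sits at chance (1/4) and fails the 0.95 criterion
        rng = np.random.default_rng(4)
        pcs = rng.standard_normal((400, 5))
        labels = np.tile(np.arange(4), 100)
        from crossct.methylome import _evaluate_version

        _, acc, _cv = _evaluate_version(labels, pcs, ResolutionCriteria(), seed=0)
        assert acc == pytest.approx(0.25, abs=0.15)
        assert acc < 0.95

    def test_rescue_requires_strictly_above_threshold(self):
        pcs, _ = two_blob_pcs(n=200, seed=5)
        res = consensus_cluster(pcs, resolution=0.2, n_runs=25, seed=5)
        # plant an outlier and finalize
        res.versions = [
            (res.versions[0][0],
             np.where(np.arange(200) == 0, -1, res.versions[0][1]),
             res.versions[0][2])
        ]
        res = finalize_clusters(res, pcs, seed=5)
        # the planted outlier sits inside blob 1: confidently rescued
        assert res.rescued[0] and res.labels[0] >= 0

    def test_select_resolution_rules(self):
        def ev(res, acc, out_frac, size):
            e = ClusterEvaluation(
                resolution=res, accuracy=acc, outlier_fraction=out_frac,
                mean_cluster_size=size, result=None,
            )
            return e

        # all qualifying: the maximum resolution wins
        evs = [ev(0.5, 0.99, 0.0, 100), ev(1.0, 0.99, 0.0, 80), ev(2.0, 0.99, 0.0, 50)]
        assert select_resolution(evs).resolution == 2.0
        # mean cluster size 29 disqualifies
        evs = [ev(0.5, 0.99, 0.0, 100), ev(1.0, 0.99, 0.0, 29)]
        assert select_resolution(evs).resolution == 0.5
        # nothing qualifies: highest accuracy, flagged non-conforming
        with pytest.warns(UserWarning, match="non-conforming"):
            chosen = select_resolution(
                [ev(0.5, 0.8, 0.2, 100), ev(1.0, 0.9, 0.2, 100)]
            )
        assert chosen.resolution == 1.0 and not chosen.conforming
        with pytest.raises(ValueError):
            select_resolution([])
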