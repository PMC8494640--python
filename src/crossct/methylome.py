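"""Single-cell methylome stage: QC, beta-binomial normalization, highly
variable features, and ensemble consensus clustering.

Raw methylation rates mc/cov are noisy at low coverage, so each cell's
rates per cytosine context are shrunk toward the cell's global mean with a
beta-binomial posterior. The beta prior (alpha, beta) is fitted per cell
by the method of moments from the sample mean m and variance v of the raw
rates::

    alpha = m (m(1 - m)/v - 1)
    beta  = (1 - m)(m(1 - m)/v - 1)

so cells with more information (larger raw variance) get weaker priors.
The posterior rate (alpha + mc) / (alpha + beta + cov) is divided by the
cell's global mean alpha/(alpha + beta); a feature with zero coverage is
therefore exactly 1 after normalization and the matrix holds no missing
values.

Clustering runs Leiden many times on a KNN graph of concatenated CH+CG
principal components, treats the runs as a cells x runs label matrix, and
extracts consensus clusters with outlier-aware DBSCAN under Hamming
distance. A class-balanced classifier trained on the principal components
scores each consensus version by held-out balanced accuracy, rescues
outliers whose predicted-class probability clears a threshold, and a grid
search over Leiden resolutions keeps the largest resolution meeting the
outlier-fraction / accuracy / cluster-size criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import kneighbors_graph
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CELL_QC_THRESHOLDS",
    "ResolutionCriteria",
    "BetaPrior",
    "ConsensusClusterResult",
    "ClusterEvaluation",
    "filter_cells",
    "filter_features",
    "beta_from_moments",
    "fit_beta_prior",
    "normalize_rates",
    "select_hvf",
    "pca_reduce",
    "consensus_cluster",
    "finalize_clusters",
    "select_resolution",
    "run_methylome_pipeline",
]


# mCCC rate bounds the bisulfite non-conversion rate from above, hence the
# strict upper threshold; all five comparisons are strict.
CELL_QC_THRESHOLDS = {
    "mccc_rate": ("<", 0.03),
    "mcg_rate": (">", 0.5),
    "mch_rate": ("<", 0.2),
    "final_reads": (">", 500_000),
    "mapping_rate": (">", 0.5),
}


def filter_cells(metrics: pd.DataFrame, return_reasons: bool = False):
    """Keep cells passing all five mapping-metric thresholds.

    A cell with any missing metric is rejected with reason ``incomplete``.
    """
    missing = [c for c in CELL_QC_THRESHOLDS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    n = len(metrics)
    keep = np.ones(n, dtype=bool)
    reasons = [[] for _ in range(n)]
    incomplete = metrics[list(CELL_QC_THRESHOLDS)].isna().any(axis=1).to_numpy()
    for i in np.flatnonzero(incomplete):
        reasons[i].append("incomplete")
    keep &= ~incomplete
    for col, (op, thr) in CELL_QC_THRESHOLDS.items():
        vals = metrics[col].to_numpy(dtype=float)
        ok = (vals < thr) if op == "<" else (vals > thr)
        fail = ~ok & ~incomplete
        for i in np.flatnonzero(fail):
            reasons[i].append(col)
        keep &= ok | incomplete  # incomplete already rejected with its reason
    keep &= ~incomplete
    if return_reasons:
        return keep, [";".join(r) for r in reasons]
    return keep


def filter_features(
    cov: np.ndarray,
    features: pd.DataFrame | None = None,
    blacklist: Sequence[tuple[str, int, int]] = (),
    min_mean: float = 250.0,
    max_mean: float = 3000.0,
) -> np.ndarray:
    """Keep features with mean coverage in [min_mean, max_mean] that do not
    intersect any blacklist region (half-open, 0-based intervals).

    ``cov`` must already be restricted to retained cells. ``features``
    needs chrom/start/end columns when a blacklist is given.
    """
    mean_cov = np.asarray(cov, dtype=float).mean(axis=0)
    keep = (mean_cov >= min_mean) & (mean_cov <= max_mean)
    if len(blacklist) > 0:
        if features is None:
            raise ValueError("a feature table is required to apply a blacklist")
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in blacklist:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        hits = np.array(
            [
                bool(trees.get(c) and trees[c].overlap(s, e))
                for c, s, e in zip(
                    features["chrom"], features["start"], features["end"]
                )
            ]
        )
        keep &= ~hits
    return keep


@dataclass
class BetaPrior:
    """Per-cell beta prior and the moments it came from.

    ``mean`` is the cell's global mean methylation alpha/(alpha+beta),
    which by the method-of-moments construction equals the sample mean of
    the raw rates.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sample_mean: np.ndarray
    sample_var: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


def beta_from_moments(m, v) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments beta shape parameters from mean m and variance v."""
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        bad = np.flatnonzero((m <= 0) | (m >= 1))
        raise ValueError(
            f"sample mean must lie strictly in (0, 1); offending index {bad[0]}"
        )
    if np.any(v <= 0):
        bad = np.flatnonzero(v <= 0)
        raise ValueError(f"sample variance must be positive; offending index {bad[0]}")
    limit = m * (1 - m)
    if np.any(v >= limit):
        bad = np.flatnonzero(v >= limit)
        raise ValueError(
            "variance exceeds the beta-distribution bound m(1-m): "
            f"v={np.atleast_1d(v)[bad[0]]:.4g} >= "
            f"{np.atleast_1d(limit)[bad[0]]:.4g} at index {bad[0]}"
        )
    scale = limit / v - 1.0
    return m * scale, (1.0 - m) * scale


def fit_beta_prior(mc: np.ndarray, cov: np.ndarray) -> BetaPrior:
    """Fit the per-cell beta prior from raw rates of covered features."""
    mc = np.asarray(mc)
    cov = np.asarray(cov)
    if mc.shape != cov.shape:
        raise ValueError("mc and cov must have the same shape")
    if np.any(mc > cov):
        raise ValueError("mc must be <= cov elementwise")
    n_cells = mc.shape[0]
    m = np.empty(n_cells)
    v = np.empty(n_cells)
    for i in range(n_cells):
        covered = cov[i] > 0
        if covered.sum() < 2:
            raise ValueError(f"cell {i} has fewer than 2 covered features")
        rates = mc[i, covered] / cov[i, covered]
        m[i] = rates.mean()
        v[i] = rates.var(ddof=1)
    alpha, beta = beta_from_moments(m, v)
    return BetaPrior(alpha=alpha, beta=beta, sample_mean=m, sample_var=v)


def normalize_rates(
    mc: np.ndarray, cov: np.ndarray, prior: BetaPrior
) -> np.ndarray:
    """Posterior methylation rate normalized by the cell's global mean.

    posterior = (alpha + mc) / (alpha + beta + cov); normalized =
    posterior / (alpha/(alpha+beta)). Zero-coverage entries are exactly 1;
    the output contains no missing values.
    """
    a = prior.alpha[:, None]
    b = prior.beta[:, None]
    posterior = (a + mc) / (a + b + cov)
    normalized = posterior / prior.mean[:, None]
    assert np.isfinite(normalized).all()
    return normalized


def select_hvf(
    normalized: np.ndarray,
    cov: np.ndarray,
    n_select: int = 3000,
    mean_bins: int = 20,
    cov_bins: int = 5,
) -> np.ndarray:
    """Top features by mean/coverage-binned normalized dispersion.

    Dispersion is the variance-to-mean ratio of the normalized rates.
    Features are grouped on a mean x mean-coverage quantile grid and the
    dispersion is z-scored within each group (groups of one get 0); the
    ``n_select`` features with the largest normalized dispersion win, ties
    broken by feature index. Returns sorted feature indices.
    """
    normalized = np.asarray(normalized, dtype=float)
    n_features = normalized.shape[1]
    mean = normalized.mean(axis=0)
    var = normalized.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    mean_cov = np.asarray(cov, dtype=float).mean(axis=0)

    if n_features <= n_select:
        warnings.warn(
            f"only {n_features} features available; returning all of them"
        )
        return np.arange(n_features)

    def quantile_bins(x: np.ndarray, k: int) -> np.ndarray:
        edges = np.unique(np.quantile(x, np.linspace(0, 1, k + 1)[1:-1]))
        return np.digitize(x, edges)

    grid = quantile_bins(mean, mean_bins) * (cov_bins + 1) + quantile_bins(
        mean_cov, cov_bins
    )
    z = np.zeros(n_features)
    for g in np.unique(grid):
        sel = grid == g
        if sel.sum() < 2:
            continue  # singleton bin: normalized dispersion stays 0
        d = dispersion[sel]
        sd = d.std()
        z[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    order = np.lexsort((np.arange(n_features), -z))
    return np.sort(order[:n_select])


def pca_reduce(
    matrix: np.ndarray,
    n_components: int | None = None,
    max_components: int = 50,
    random_state: int = 0,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Scale to zero mean / unit variance, PCA, elbow-select components.

    When ``n_components`` is not given, the kept dimensionality is the
    position of the largest drop in the explained-variance-ratio curve
    (at least 2 components).
    """
    X = StandardScaler().fit_transform(np.asarray(matrix, dtype=float))
    k_max = min(max_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k_max, random_state=random_state)
    pcs = pca.fit_transform(X)
    vr = pca.explained_variance_ratio_
    if n_components is None:
        drops = vr[:-1] - vr[1:]
        n_components = max(2, int(np.argmax(drops)) + 1)
    n_components = min(n_components, k_max)
    return pcs[:, :n_components], n_components, vr


@dataclass(frozen=True)
class ResolutionCriteria:
    """Acceptance gates for a finalized clustering version."""

    max_outlier_fraction: float = 0.05
    min_accuracy: float = 0.95
    min_mean_cluster_size: int = 30
    rescue_probability: float = 0.3


@dataclass
class ConsensusClusterResult:
    """Ensemble of Leiden runs plus DBSCAN consensus versions.

    ``versions`` holds (epsilon, labels, n_clusters) for each distinct
    DBSCAN consensus over the run-label matrix (label -1 marks outliers);
    ``labels`` / ``outlier`` / ``rescued`` describe the finalized choice
    after supervised evaluation.
    """

    ensemble: np.ndarray  # cells x runs label matrix
    versions: list[tuple[float, np.ndarray, int]]
    resolution: float
    labels: np.ndarray | None = None
    outlier: np.ndarray | None = None
    rescued: np.ndarray | None = None
    chosen_eps: float | None = None
    accuracy: float | None = None
    cv_accuracy: float | None = None

    @property
    def n_cells(self) -> int:
        return self.ensemble.shape[0]


def consensus_cluster(
    pcs: np.ndarray,
    resolution: float = 1.0,
    n_runs: int = 300,
    k_neighbors: int = 15,
    seed: int = 0,
    eps_grid_size: int = 20,
    min_samples: int = 5,
) -> ConsensusClusterResult:
    """Leiden ensemble on a KNN graph, consensus via DBSCAN over runs.

    Each of ``n_runs`` Leiden restarts contributes one column to a label
    matrix; DBSCAN with Hamming distance groups cells that co-cluster
    consistently. Epsilon traverses a grid between the 1st and 99th
    percentile of pairwise Hamming distances, keeping versions whose
    cluster count lies between the minimum and maximum observed across
    runs. Co-membership within a run is invariant to that run's label
    names, so no cross-run label alignment is needed.
    """
    import igraph as ig
    import leidenalg

    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if n <= k_neighbors:
        raise ValueError(
            f"need more cells ({n}) than k_neighbors ({k_neighbors})"
        )
    adj = kneighbors_graph(pcs, k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=n, edges=edges)

    rng = np.random.default_rng(seed)
    runs = np.empty((n, n_runs), dtype=np.int32)
    counts = np.empty(n_runs, dtype=int)
    for r in range(n_runs):
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=int(rng.integers(2**31 - 1)),
        )
        runs[:, r] = part.membership
        counts[r] = len(part)

    k_min, k_max = counts.min(), counts.max()
    dists = pdist(runs, metric="hamming")
    lo, hi = np.percentile(dists, [1, 99])
    eps_grid = np.unique(np.linspace(max(lo, 1e-9), max(hi, 2e-9), eps_grid_size))

    versions: list[tuple[float, np.ndarray, int]] = []
    seen: set[bytes] = set()
    fallback = None
    sq = squareform(dists)
    for eps in eps_grid:
        db = DBSCAN(eps=float(eps), min_samples=min_samples, metric="precomputed")
        labels = db.fit_predict(sq)
        k = len(set(labels[labels >= 0]))
        if k == 0:
            continue
        key = labels.tobytes()
        if key in seen:
            continue
        seen.add(key)
        if fallback is None or k > fallback[2]:
            fallback = (float(eps), labels, k)
        if k_min <= k <= k_max:
            versions.append((float(eps), labels.copy(), k))
    if not versions:
        if fallback is None:
            raise ValueError("DBSCAN produced no clusters at any epsilon")
        warnings.warn(
            "no consensus version matched the observed cluster-count range; "
            "keeping the version with the most clusters"
        )
        versions = [fallback]

    result = ConsensusClusterResult(
        ensemble=runs, versions=versions, resolution=resolution
    )
    # provisional choice (refined by finalize_clusters): most clusters,
    # then smallest epsilon
    eps0, labels0, _ = max(versions, key=lambda v: (v[2], -v[0]))
    result.labels = labels0.copy()
    result.outlier = labels0 < 0
    result.chosen_eps = eps0
    return result


def _evaluate_version(
    labels: np.ndarray,
    pcs: np.ndarray,
    criteria: ResolutionCriteria,
    seed: int,
    cv_folds: int = 10,
):
    """Train/evaluate the class-balanced classifier for one version."""
    core = labels >= 0
    y = labels[core]
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("fewer than 2 clusters among non-outliers")
    if class_counts.min() < cv_folds:
        raise ValueError(
            f"cluster of size {class_counts.min()} is smaller than the "
            f"fold count ({cv_folds}); stratification impossible"
        )
    X = pcs[core]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.1, stratify=y, random_state=seed
    )
    model = RandomForestClassifier(
        n_estimators=100,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(
        model, X_tr, y_tr, cv=cv, scoring="balanced_accuracy"
    )
    model.fit(X_tr, y_tr)
    acc = balanced_accuracy_score(y_te, model.predict(X_te))
    return model, float(acc), float(cv_scores.mean())


def finalize_clusters(
    result: ConsensusClusterResult,
    pcs: np.ndarray,
    criteria: ResolutionCriteria = ResolutionCriteria(),
    seed: int = 0,
    cv_folds: int = 10,
) -> ConsensusClusterResult:
    """Supervised evaluation: choose the best consensus version and rescue
    outliers.

    For each consensus version, 10% of non-outlier cells are held out, a
    class-balanced random-forest is cross-validated (``cv_folds``) and
    trained on the rest, and the version with the best held-out balanced
    accuracy wins. Outliers whose predicted-class probability exceeds
    ``criteria.rescue_probability`` are rescued into that class; the rest
    stay flagged.
    """
    pcs = np.asarray(pcs, dtype=float)
    best = None
    for eps, labels, k in result.versions:
        try:
            model, acc, cv_acc = _evaluate_version(
                labels, pcs, criteria, seed, cv_folds
            )
        except ValueError as err:
            if len(result.versions) == 1:
                raise
            warnings.warn(f"version eps={eps:.3g} skipped: {err}")
            continue
        if best is None or (acc, k) > (best[3], best[2]):
            best = (eps, labels, k, acc, cv_acc, model)
    if best is None:
        raise ValueError("no consensus version could be evaluated")
    eps, labels, _k, acc, cv_acc, model = best

    final = labels.copy()
    outlier = labels < 0
    rescued = np.zeros_like(outlier)
    if outlier.any():
        proba = model.predict_proba(pcs[outlier])
        max_p = proba.max(axis=1)
        pred = model.classes_[proba.argmax(axis=1)]
        ok = max_p > criteria.rescue_probability
        idx = np.flatnonzero(outlier)
        final[idx[ok]] = pred[ok]
        rescued[idx[ok]] = True
        outlier = final < 0
    result.labels = final
    result.outlier = outlier
    result.rescued = rescued
    result.chosen_eps = eps
    result.accuracy = acc
    result.cv_accuracy = cv_acc
    return result


@dataclass
class ClusterEvaluation:
    """Summary of one finalized clustering at one Leiden resolution."""

    resolution: float
    accuracy: float
    outlier_fraction: float
    mean_cluster_size: float
    result: ConsensusClusterResult
    conforming: bool = False

    @classmethod
    def from_result(cls, result: ConsensusClusterResult) -> "ClusterEvaluation":
        if result.labels is None or result.accuracy is None:
            raise ValueError("result must be finalized first")
        labels = result.labels
        core = labels >= 0
        k = len(np.unique(labels[core])) if core.any() else 0
        return cls(
            resolution=result.resolution,
            accuracy=result.accuracy,
            outlier_fraction=float((~core).mean()),
            mean_cluster_size=float(core.sum() / k) if k else 0.0,
            result=result,
        )


def select_resolution(
    evaluations: Sequence[ClusterEvaluation],
    criteria: ResolutionCriteria = ResolutionCriteria(),
) -> ClusterEvaluation:
    """Largest Leiden resolution meeting all three acceptance criteria.

    Qualifying versions have outlier fraction below
    ``max_outlier_fraction``, held-out balanced accuracy above
    ``min_accuracy`` and mean cells per cluster of at least
    ``min_mean_cluster_size``. If none qualify, the highest-accuracy
    candidate is returned flagged as non-conforming.
    """
    if not evaluations:
        raise ValueError("no candidate resolutions were evaluated")
    qualifying = [
        e
        for e in evaluations
        if e.outlier_fraction < criteria.max_outlier_fraction
        and e.accuracy > criteria.min_accuracy
        and e.mean_cluster_size >= criteria.min_mean_cluster_size
    ]
    if qualifying:
        chosen = max(qualifying, key=lambda e: e.resolution)
        chosen.conforming = True
        return chosen
    chosen = max(evaluations, key=lambda e: e.accuracy)
    chosen.conforming = False
    warnings.warn(
        "no resolution met all criteria; returning the highest-accuracy "
        "candidate flagged as non-conforming"
    )
    return chosen


def run_methylome_pipeline(
    mc: Mapping[str, np.ndarray],
    cov: Mapping[str, np.ndarray],
    qc: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
    blacklist: Sequence[tuple[str, int, int]] = (),
    n_select: int = 3000,
    n_components: int | None = None,
    resolution: float = 1.0,
    n_runs: int = 300,
    k_neighbors: int = 15,
    criteria: ResolutionCriteria = ResolutionCriteria(),
    feature_cov_bounds: tuple[float, float] = (250.0, 3000.0),
    seed: int = 0,
) -> dict:
    """QC -> normalize -> HVF -> PCA per context -> concatenate -> cluster.

    Returns a dict with the cell mask, per-context feature masks and
    normalized matrices, concatenated principal components, and the
    finalized :class:`ConsensusClusterResult`.
    """
    contexts = list(mc)
    n_cells = next(iter(mc.values())).shape[0]
    cell_mask = (
        filter_cells(qc) if qc is not None else np.ones(n_cells, dtype=bool)
    )
    out: dict = {"cell_mask": cell_mask, "contexts": contexts}

    pcs_blocks = []
    feature_masks = {}
    normalized = {}
    for ctx in contexts:
        mc_c = mc[ctx][cell_mask]
        cov_c = cov[ctx][cell_mask]
        fmask = filter_features(
            cov_c,
            features=features,
            blacklist=blacklist,
            min_mean=feature_cov_bounds[0],
            max_mean=feature_cov_bounds[1],
        )
        if not fmask.any():
            raise ValueError(
                f"no {ctx} features remain after coverage filtering "
                f"(bounds {feature_cov_bounds}); check the coverage scale"
            )
        mc_c, cov_c = mc_c[:, fmask], cov_c[:, fmask]
        prior = fit_beta_prior(mc_c, cov_c)
        norm = normalize_rates(mc_c, cov_c, prior)
        hvf = select_hvf(norm, cov_c, n_select=n_select)
        pcs, k, _ = pca_reduce(
            norm[:, hvf], n_components=n_components, random_state=seed
        )
        feature_masks[ctx] = fmask
        normalized[ctx] = norm
        pcs_blocks.append(pcs)
        out[f"n_components_{ctx}"] = k
    pcs_all = np.hstack(pcs_blocks)
    out.update(feature_masks=feature_masks, normalized=normalized, pcs=pcs_all)

    result = consensus_cluster(
        pcs_all,
        resolution=resolution,
        n_runs=n_runs,
        k_neighbors=k_neighbors,
        seed=seed,
    )
    result = finalize_clusters(result, pcs_all, criteria=criteria, seed=seed)
    out["result"] = result
    out["evaluation"] = ClusterEvaluation.from_result(result)
    return out
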