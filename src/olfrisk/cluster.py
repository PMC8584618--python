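"""High-dimensional subgroup discovery: correlation-PCA → Ward → k-means.

The metabolomics panel is projected by PCA on scaled, centered data
(correlation-matrix PCA); components with eigenvalue > 1 are retained (Kaiser
rule).  On the retained scores, hierarchical clustering with Ward's criterion
is cut at k and the partition is consolidated by a single k-means run seeded
at the cut's centroids — consolidation can only decrease the within-cluster
sum of squares.  The cluster count is chosen by majority vote over a panel of
cluster-number indices, and solution quality is summarized by the average
silhouette width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
)

__all__ = [
    "PCAResult",
    "ClusterSolution",
    "pca_project",
    "ward_kmeans",
    "choose_k",
    "avg_silhouette",
    "within_ss",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    scores: np.ndarray  # subjects x components (all components)
    loadings: np.ndarray  # variables x components (unit eigenvectors)
    contributions: np.ndarray  # squared-loading share per retained component
    retained: int
    columns: list[str] = field(default_factory=list)

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained]


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1..k
    wss: float
    silhouette: float | None = None
    index_votes: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_project(X: np.ndarray, columns: list[str] | None = None) -> PCAResult:
    """Correlation-matrix PCA with Kaiser (eigenvalue > 1) retention.

    Scores are the standardized data projected on the unit eigenvectors, so
    score variances equal the eigenvalues and the eigenvalue sum equals the
    number of variables.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("pca_project needs a matrix with >= 2 columns")
    if np.isnan(X).any():
        raise ValueError("pca_project requires complete data")
    sd = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = [columns[j] if columns else f"col{j}" for j in const]
        raise ValueError(f"constant columns cannot be standardized: {names}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest-|loading| entry positive, for reproducibility
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    scores = Z @ eigvec
    retained = int(np.sum(eigval > 1.0))
    # correlation loadings: eigvec * sqrt(lambda); contribution = squared share
    sq = eigvec**2
    contributions = sq[:, :retained] / sq[:, :retained].sum(axis=0, keepdims=True)
    return PCAResult(
        eigenvalues=eigval, scores=scores, loadings=eigvec,
        contributions=contributions, retained=retained,
        columns=list(columns) if columns else [],
    )


# ---------------------------------------------------------------------------
# Ward + k-means
# ---------------------------------------------------------------------------


def within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared Euclidean distances to centroids."""
    X = np.asarray(X, dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return total


def ward_kmeans(scores: np.ndarray, k: int) -> ClusterSolution:
    """Ward tree cut at k, consolidated by one centroid-seeded k-means run."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == 1:
        labels = np.ones(n, dtype=int)
        return ClusterSolution(k=1, labels=labels, wss=within_ss(scores, labels))

    # Ward on Euclidean distances (Lance-Williams "ward" = Ward.D2 criterion)
    Zlink = linkage(scores, method="ward")
    cut = fcluster(Zlink, t=k, criterion="maxclust")
    centroids = np.stack(
        [scores[cut == lab].mean(axis=0) for lab in np.unique(cut)]
    )
    km = KMeans(n_clusters=centroids.shape[0], init=centroids, n_init=1,
                max_iter=100, tol=1e-6)
    labels = km.fit_predict(scores) + 1
    wss_cut = within_ss(scores, cut)
    wss_km = within_ss(scores, labels)
    if wss_km > wss_cut + 1e-9:  # Lloyd never increases WSS from its init
        labels, wss_km = cut, wss_cut
    sil = avg_silhouette(labels, scores) if len(np.unique(labels)) >= 2 else None
    return ClusterSolution(k=k, labels=labels, wss=wss_km, silhouette=sil)


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------


def avg_silhouette(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average silhouette width s(i) = (b−a)/max(a,b); singletons contribute 0."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = squareform(pdist(scores))
    s = np.zeros(len(labels))
    for i in range(len(labels)):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


# ---------------------------------------------------------------------------
# Cluster-count index panel and majority vote
# ---------------------------------------------------------------------------


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for a in range(len(uniq)):
        ia = labels == uniq[a]
        da = D[np.ix_(ia, ia)]
        if da.size > 1:
            max_within = max(max_within, da.max())
        for b in range(a + 1, len(uniq)):
            ib = labels == uniq[b]
            min_between = min(min_between, D[np.ix_(ia, ib)].min())
    return min_between / max_within if max_within > 0 else np.inf


def _c_index(D: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(len(labels), k=1)
    within_mask = labels[iu[0]] == labels[iu[1]]
    d = D[iu]
    sw = d[within_mask].sum()
    nw = int(within_mask.sum())
    if nw == 0:
        return np.nan
    ds = np.sort(d)
    smin, smax = ds[:nw].sum(), ds[-nw:].sum()
    return (sw - smin) / (smax - smin) if smax > smin else 0.0


def _mcclain_rao(D: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(len(labels), k=1)
    within_mask = labels[iu[0]] == labels[iu[1]]
    d = D[iu]
    nw, nb = within_mask.sum(), (~within_mask).sum()
    if nw == 0 or nb == 0:
        return np.nan
    return (d[within_mask].mean()) / (d[~within_mask].mean())


def _ball_hall(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    return within_ss(X, labels) / k


def _gap_statistic(
    X: np.ndarray, solutions: dict[int, ClusterSolution], ks: list[int],
    rng: np.random.Generator, n_ref: int = 10,
) -> int | None:
    """Tibshirani gap statistic; reference = uniform over the PCA-aligned box."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = {k: np.log(max(solutions[k].wss, 1e-300)) for k in ks}
    ref_logs = {k: [] for k in ks}
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        Zlink = linkage(ref, method="ward")
        for k in ks:
            cut = fcluster(Zlink, t=k, criterion="maxclust")
            ref_logs[k].append(np.log(max(within_ss(ref, cut), 1e-300)))
    gap = {k: np.mean(ref_logs[k]) - log_w[k] for k in ks}
    sk = {
        k: np.std(ref_logs[k], ddof=0) * np.sqrt(1 + 1.0 / n_ref) for k in ks
    }
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - sk[ks[i + 1]]:
            return k
    return ks[-1]


def choose_k(
    scores: np.ndarray,
    k_range: range | list[int] = range(2, 9),
    seed: int = 0,
) -> tuple[int, dict[str, int], dict[int, ClusterSolution]]:
    """Majority vote of cluster-number indices over Ward+k-means solutions.

    Panel (a documented subset of the classical index catalogue): average
    silhouette, Calinski–Harabasz, Davies–Bouldin, Hartigan, Krzanowski–Lai,
    Dunn, C-index, McClain–Rao, gap statistic, Ball–Hall.  Each index proposes
    one k by its own rule; the modal proposal wins; ties break toward the
    smaller k.  Returns (k, per-index votes, per-k solutions).
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")

    sols = {k: ward_kmeans(X, k) for k in ks}
    # WSS at flanking k (for Hartigan / KL / Ball-Hall differences)
    w_ext = {k: sols[k].wss for k in ks}
    for k in (ks[0] - 1, ks[-1] + 1):
        if 1 <= k <= n:
            w_ext[k] = ward_kmeans(X, k).wss

    D = squareform(pdist(X))
    rng = np.random.default_rng(seed)
    votes: dict[str, int] = {}

    votes["silhouette"] = max(ks, key=lambda k: (sols[k].silhouette, -k))
    votes["calinski_harabasz"] = max(
        ks, key=lambda k: (calinski_harabasz_score(X, sols[k].labels), -k)
    )
    votes["davies_bouldin"] = min(
        ks, key=lambda k: (davies_bouldin_score(X, sols[k].labels), k)
    )
    votes["dunn"] = max(ks, key=lambda k: (_dunn(D, sols[k].labels), -k))
    votes["c_index"] = min(ks, key=lambda k: (_c_index(D, sols[k].labels), k))
    votes["mcclain_rao"] = min(
        ks, key=lambda k: (_mcclain_rao(D, sols[k].labels), k)
    )

    # Hartigan: smallest k with H(k) <= 10, else largest drop in H
    hart = {}
    for k in ks:
        if k + 1 in w_ext and w_ext[k + 1] > 0:
            hart[k] = (w_ext[k] / w_ext[k + 1] - 1.0) * (n - k - 1)
    small = [k for k, h in hart.items() if h <= 10]
    if small:
        votes["hartigan"] = min(small)
    elif len(hart) >= 2:
        hk = sorted(hart)
        drops = {hk[i + 1]: hart[hk[i]] - hart[hk[i + 1]] for i in range(len(hk) - 1)}
        votes["hartigan"] = max(drops, key=lambda k: (drops[k], -k))
    # Krzanowski-Lai: maximize |DIFF_k| / |DIFF_{k+1}|
    diff = {}
    for k in ks + [ks[-1] + 1]:
        if k - 1 in w_ext and k in w_ext:
            diff[k] = (k - 1) ** (2.0 / p) * w_ext[k - 1] - k ** (2.0 / p) * w_ext[k]
    kl = {}
    for k in ks:
        if k in diff and k + 1 in diff and abs(diff[k + 1]) > 1e-12:
            kl[k] = abs(diff[k]) / abs(diff[k + 1])
    if kl:
        votes["krzanowski_lai"] = max(kl, key=lambda k: (kl[k], -k))
    # Ball-Hall: largest successive difference of W_k / k
    bh = {k: _ball_hall(X, sols[k].labels, k) for k in ks}
    bh_all = dict(bh)
    if ks[0] - 1 in w_ext:
        bh_all[ks[0] - 1] = w_ext[ks[0] - 1] / (ks[0] - 1)
    bh_keys = sorted(bh_all)
    bh_diff = {
        bh_keys[i + 1]: bh_all[bh_keys[i]] - bh_all[bh_keys[i + 1]]
        for i in range(len(bh_keys) - 1)
        if bh_keys[i + 1] in ks
    }
    if bh_diff:
        votes["ball_hall"] = max(bh_diff, key=lambda k: (bh_diff[k], -k))
    gap_k = _gap_statistic(X, sols, ks, rng)
    if gap_k is not None:
        votes["gap"] = gap_k

    best = majority_vote(votes)
    sols[best].index_votes = votes
    return best, votes, sols


def majority_vote(votes: dict[str, int]) -> int:
    """Modal proposed k; exact ties break toward the smaller k."""
    if not votes:
        raise ValueError("no index votes")
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    return max(sorted(tally), key=lambda k: (tally[k], -k))
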