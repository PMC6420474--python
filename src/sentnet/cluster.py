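"""Intrinsic-connectivity matrices, network clustering and cluster support.

The mean intrinsic connectivity matrix is the Fisher-z average of the
per-subject Pearson correlation matrices.  Networks are extracted by
agglomerative hierarchical clustering with Ward linkage on the distance
d = (1 - r) / 2 of the back-transformed mean matrix; the number of
clusters is chosen by a plurality vote over a battery of ten classical
internal validity indices.  Cluster reliability is quantified by
multiscale bootstrap resampling of subjects with approximately unbiased
(AU) p values, and robustness by comparing the Ward partition with
average linkage, a diagonal Gaussian mixture and k-means through the
adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.mixture import GaussianMixture

from .config import AnalysisConfig
from .data import DataError, MergeTree, TimeSeriesPanel

_R_CAP = 1.0 - 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity with an explicit scale.

    ``scale`` is "pearson_r" or "fisher_z"; the diagonal is zero by
    convention (self-connectivity is undefined).
    """

    values: np.ndarray
    region_names: list[str]
    scale: str = "pearson_r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.region_names)
        if self.values.shape != (n, n):
            raise DataError(
                f"matrix shape {self.values.shape} != ({n}, {n})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("connectivity matrix is not symmetric")
        if np.abs(np.diag(self.values)).max() > 1e-12:
            raise DataError("connectivity diagonal must be zero")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "pearson_r":
            off = self.values[~np.eye(n, dtype=bool)]
            if off.size and np.abs(off).max() >= 1.0:
                raise DataError("pearson_r entries must lie in (-1, 1)")

    def to_pearson(self) -> "ConnectivityMatrix":
        if self.scale == "pearson_r":
            return self
        vals = np.tanh(self.values)
        np.fill_diagonal(vals, 0.0)
        return ConnectivityMatrix(vals, list(self.region_names), "pearson_r")

    def subset(self, names) -> "ConnectivityMatrix":
        idx = [self.region_names.index(n) for n in names]
        return ConnectivityMatrix(
            self.values[np.ix_(idx, idx)], list(names), self.scale
        )


@dataclass
class Partition:
    """Region -> cluster labels, contiguous 1..k, covering all regions."""

    labels: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if len(self.labels) != len(self.region_names):
            raise DataError("labels and region names differ in length")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise DataError("labels must be contiguous 1..k")

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def members(self, label: int) -> list[str]:
        return [
            n for n, l in zip(self.region_names, self.labels) if l == label
        ]

    def as_dict(self) -> dict:
        return dict(zip(self.region_names, (int(l) for l in self.labels)))


@dataclass
class ClusterSupport:
    """Multiscale-bootstrap support for each reference cluster."""

    table: pd.DataFrame  # cluster, au, bp, v, c, degenerate
    per_scale_counts: pd.DataFrame  # cluster x scale counts
    scales: list[float]
    replicates: int


def subject_connectivity(
    series: np.ndarray, region_names: list[str]
) -> ConnectivityMatrix:
    """Pearson correlation matrix of one subject's T x N series.

    Off-diagonals are capped at +/-(1 - 1e-12) so the Fisher transform
    stays finite; the diagonal is set to zero.
    """
    series = np.asarray(series, float)
    if series.shape[0] < 3:
        raise DataError("need at least 3 time points")
    sd = series.std(axis=0)
    if (sd == 0).any():
        bad = [n for n, s in zip(region_names, sd) if s == 0]
        raise DataError(f"constant time series for region(s) {bad}")
    r = np.corrcoef(series, rowvar=False)
    r = np.clip(r, -_R_CAP, _R_CAP)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, list(region_names), "pearson_r")


def connectivity_panel(ts: TimeSeriesPanel) -> list[ConnectivityMatrix]:
    return [
        subject_connectivity(mat, ts.region_names) for mat in ts.series
    ]


def mean_connectivity(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Fisher-z average of per-subject correlation matrices (fisher_z scale)."""
    if not matrices:
        raise DataError("need at least one connectivity matrix")
    names = matrices[0].region_names
    for m in matrices[1:]:
        if m.region_names != names:
            raise DataError("mixed region orders in mean_connectivity")
    z = np.mean(
        [np.arctanh(np.clip(m.to_pearson().values, -_R_CAP, _R_CAP))
         for m in matrices],
        axis=0,
    )
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, list(names), "fisher_z")


def correlation_to_distance(mat: ConnectivityMatrix) -> np.ndarray:
    """d = (1 - r) / 2 on the correlation scale; entries in [0, 1]."""
    r = mat.to_pearson().values
    d = (1.0 - r) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def ward_cluster(dist: np.ndarray, leaf_names: list[str]) -> MergeTree:
    """Ward agglomeration (Lance-Williams recurrence) of a distance matrix.

    Ties are broken toward the smallest condensed index, i.e. the
    lowest-numbered leaf pair merges first.
    """
    dist = np.asarray(dist, float)
    if not np.isfinite(dist).all():
        raise DataError("distance matrix contains non-finite entries")
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="ward")
    return MergeTree(link, list(leaf_names))


def cut_tree(tree: MergeTree, k: int) -> Partition:
    """Partition from removing the k-1 highest merges.

    Cluster labels are assigned by decreasing cluster size, ties broken
    by the smallest leaf index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise DataError(f"k={k} outside [1, {n}]")
    raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # ties in merge heights can make maxclust overshoot; cut by height
        heights = np.sort(tree.linkage[:, 2])
        thresh = heights[n - 1 - k] if k < n else -1.0
        raw = hierarchy.fcluster(tree.linkage, t=thresh, criterion="distance")
    order = {}
    sizes = {lab: (raw == lab).sum() for lab in np.unique(raw)}
    first_leaf = {lab: int(np.argmax(raw == lab)) for lab in sizes}
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], first_leaf[lab]))
    order = {lab: i + 1 for i, lab in enumerate(ranked)}
    labels = np.array([order[lab] for lab in raw])
    return Partition(labels, list(tree.leaf_names))


# ---------------------------------------------------------------------------
# Cluster-number vote
# ---------------------------------------------------------------------------


def _within_between_masks(labels: np.ndarray):
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    return same[iu], iu


def _index_battery(
    dist: np.ndarray, profiles: np.ndarray, labels: np.ndarray
) -> dict:
    """Ten classical internal validity indices for one partition.

    Distance-based indices use the correlation distance directly;
    centroid-based indices (Calinski-Harabasz, Davies-Bouldin,
    Ball-Hall) use the connectivity-profile row vectors.
    """
    within_mask, iu = _within_between_masks(labels)
    dvec = dist[iu]
    dw = dvec[within_mask]
    db = dvec[~within_mask]
    out = {}
    out["silhouette"] = silhouette_score(dist, labels, metric="precomputed")
    out["calinski_harabasz"] = calinski_harabasz_score(profiles, labels)
    out["davies_bouldin"] = davies_bouldin_score(profiles, labels)
    # Dunn: min between-cluster distance / max within-cluster diameter
    out["dunn"] = db.min() / dw.max() if len(dw) and len(db) else np.nan
    # C-index: (S_w - S_min) / (S_max - S_min) over n_w smallest/largest
    nw = len(dw)
    s_sorted = np.sort(dvec)
    s_min, s_max = s_sorted[:nw].sum(), s_sorted[-nw:].sum()
    out["c_index"] = (
        (dw.sum() - s_min) / (s_max - s_min) if s_max > s_min else np.nan
    )
    out["mcclain"] = (dw.mean() / db.mean()) if len(db) else np.nan
    # point-biserial correlation between distance and between-indicator
    out["point_biserial"] = stats.pointbiserialr(
        (~within_mask).astype(float), dvec
    ).statistic
    # Baker-Hubert gamma: concordant vs discordant (within, between) pairs
    order = np.argsort(dvec, kind="mergesort")
    w_sorted = within_mask[order]
    n_between_seen = np.cumsum(~w_sorted)
    concordant = n_between_seen[-1] * w_sorted.sum() - (
        n_between_seen[w_sorted].sum()
    )
    discordant = n_between_seen[w_sorted].sum()
    # concordant: within < between; discordant: between < within
    total = concordant + discordant
    out["gamma"] = (concordant - discordant) / total if total else np.nan
    # Ball-Hall: mean within-cluster dispersion around profile centroids
    bh = 0.0
    for lab in np.unique(labels):
        pts = profiles[labels == lab]
        bh += ((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()
    out["ball_hall"] = bh / len(np.unique(labels))
    # Xie-Beni analogue on distances, with medoids as prototypes
    medoids = []
    compact = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        sub = dist[np.ix_(idx, idx)]
        med = idx[np.argmin(sub.sum(axis=0))]
        medoids.append(med)
        compact += (dist[idx, med] ** 2).sum()
    seps = [
        dist[a, b] for i, a in enumerate(medoids) for b in medoids[i + 1 :]
    ]
    min_sep = min(seps) if seps else np.nan
    out["xie_beni"] = (
        compact / (len(labels) * min_sep**2) if min_sep else np.nan
    )
    return out


_MAXIMIZE = {
    "silhouette",
    "calinski_harabasz",
    "dunn",
    "point_biserial",
    "gamma",
}
_MINIMIZE = {"davies_bouldin", "c_index", "mcclain", "xie_beni"}


def choose_k(
    dist: np.ndarray,
    tree: MergeTree,
    k_range: tuple = (2, 8),
    profiles: np.ndarray | None = None,
):
    """Plurality vote over the index battery; ties go to the smaller k.

    ``profiles`` are the feature rows for centroid-based indices; by
    default the rows of (1 - 2*dist), i.e. the correlation profile each
    region has with all others.

    Returns (k, votes table) where the table holds every index value per
    candidate k and the per-index winner.
    """
    kmin, kmax = k_range
    n = tree.n_leaves
    kmax = min(kmax, n - 1)
    if kmin > kmax:
        raise DataError(f"empty k range after clipping: ({kmin}, {kmax})")
    if profiles is None:
        profiles = 1.0 - 2.0 * np.asarray(dist, float)
    ks = list(range(kmin, kmax + 1))
    rows = {}
    for k in ks:
        labels = cut_tree(tree, k).labels
        rows[k] = _index_battery(dist, profiles, labels)
    table = pd.DataFrame(rows).T  # k x index
    # Ball-Hall votes on the largest drop between consecutive k
    bh = table["ball_hall"]
    votes = {}
    for name in table.columns:
        col = table[name].astype(float)
        if name == "ball_hall":
            if len(ks) < 2:
                continue
            drops = -(col.diff())
            votes[name] = int(drops.idxmax())
        elif name in _MAXIMIZE:
            votes[name] = int(col.idxmax())
        elif name in _MINIMIZE:
            votes[name] = int(col.idxmin())
    counts = pd.Series(votes).value_counts()
    best = counts.max()
    k_star = int(min(k for k in counts.index if counts[k] == best))
    table["vote"] = [
        sum(1 for v in votes.values() if v == k) for k in table.index
    ]
    return k_star, table


# ---------------------------------------------------------------------------
# Multiscale bootstrap support
# ---------------------------------------------------------------------------


def _clades_of_linkage(link: np.ndarray, n: int) -> set:
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = set()
    for k in range(n - 1):
        a, b = int(link[k, 0]), int(link[k, 1])
        merged = sets[a] | sets[b]
        sets[n + k] = merged
        out.add(merged)
    return out


def bootstrap_support(
    subject_z: np.ndarray,
    reference: Partition,
    config: AnalysisConfig,
    seed: int | None = None,
) -> ClusterSupport:
    """Multiscale bootstrap AU/BP support for each reference cluster.

    ``subject_z`` is the (n_subjects, N, N) stack of per-subject
    Fisher-z matrices.  For each relative scale rho, subjects are
    resampled with replacement (round(rho * n) of them), the mean matrix
    rebuilt, transformed to the correlation distance and re-clustered
    with Ward linkage; a cluster scores when its exact leaf set appears
    as a clade.  Per cluster the probit-transformed counts are fitted by
    weighted least squares to z(sigma) = v * sigma + c / sigma with
    sigma = sqrt(1 / rho), and AU = 1 - Phi(v - c); BP is the count
    fraction at the scale closest to rho = 1.
    """
    scales = list(config.bootstrap_scales)
    if len(scales) < 2:
        raise DataError("need at least 2 bootstrap scales")
    reps = config.bootstrap_reps
    n_sub, n_reg, _ = subject_z.shape
    rng = np.random.default_rng(
        config.seed if seed is None else seed
    )
    ref_sets = []
    for lab in range(1, reference.k + 1):
        members = frozenset(
            i for i, l in enumerate(reference.labels) if l == lab
        )
        if 1 < len(members) < n_reg:
            ref_sets.append((lab, members))
    counts = np.zeros((len(ref_sets), len(scales)), dtype=int)
    for si, rho in enumerate(scales):
        m = int(round(rho * n_sub))
        if m < 3:
            raise DataError(f"scale {rho} gives {m} < 3 subjects")
        for _ in range(reps):
            idx = rng.integers(0, n_sub, size=m)
            z_mean = subject_z[idx].mean(axis=0)
            r = np.tanh(z_mean)
            d = (1.0 - r) / 2.0
            np.fill_diagonal(d, 0.0)
            link = hierarchy.linkage(
                squareform(d, checks=False), method="ward"
            )
            clades = _clades_of_linkage(link, n_reg)
            for ci, (_lab, members) in enumerate(ref_sets):
                if members in clades:
                    counts[ci, si] += 1
    sigma = np.sqrt(1.0 / np.asarray(scales))
    rows = []
    bp_scale = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    for ci, (lab, members) in enumerate(ref_sets):
        c_row = counts[ci].astype(float)
        degenerate = False
        if c_row.sum() == 0:
            au, bp, v, c = 0.0, 0.0, np.nan, np.nan
            degenerate = True
        elif (c_row == reps).all():
            au, bp, v, c = 1.0, 1.0, np.nan, np.nan
            degenerate = True
        elif np.ptp(c_row) == 0:
            # flat BP across scales: the model z = v*sigma + c/sigma can
            # only represent it with c = 0, whence AU = BP at rho = 1
            bp = float(c_row[bp_scale] / reps)
            frac = np.clip(bp, 0.5 / reps, 1 - 0.5 / reps)
            v, c = float(stats.norm.ppf(1.0 - frac)), 0.0
            au = float(1.0 - stats.norm.cdf(v))
        else:
            bp_frac = np.clip(c_row / reps, 0.5 / reps, 1 - 0.5 / reps)
            zvals = stats.norm.ppf(1.0 - bp_frac)
            # weights: inverse delta-method variance of the probit counts
            weights = (
                reps
                * stats.norm.pdf(zvals) ** 2
                / (bp_frac * (1 - bp_frac))
            )
            # counts pinned at 0 or at the replicate ceiling carry a
            # censored, not binomial, probit value: exclude them from
            # the two-parameter fit when enough scales remain
            informative = (c_row > 0) & (c_row < reps)
            if informative.sum() >= 2:
                sw = np.sqrt(weights[informative])
                X = np.column_stack(
                    [sigma[informative], 1.0 / sigma[informative]]
                )
                beta, *_ = np.linalg.lstsq(
                    sw[:, None] * X, sw * zvals[informative], rcond=None
                )
                v, c = float(beta[0]), float(beta[1])
            else:
                # curvature-free fallback on all (clipped) scales
                num = float((weights * sigma * zvals).sum())
                den = float((weights * sigma**2).sum())
                v, c = num / den, 0.0
            au = float(1.0 - stats.norm.cdf(v - c))
            bp = float(c_row[bp_scale] / reps)
        rows.append(
            {
                "cluster": lab,
                "members": sorted(
                    reference.region_names[i] for i in members
                ),
                "au": au,
                "bp": bp,
                "v": v,
                "c": c,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)
    per_scale = pd.DataFrame(
        counts,
        index=[lab for lab, _ in ref_sets],
        columns=[f"{s:g}" for s in scales],
    )
    return ClusterSupport(table, per_scale, scales, reps)


def fit_au(bp_fracs, scales, replicates: int):
    """Fit (v, c, AU) from bootstrap proportions at the given scales.

    Exposed separately so the signed-distance/curvature model can be
    checked against closed-form cases (flat BP across scales gives
    AU = BP at rho = 1).
    """
    bp = np.clip(
        np.asarray(bp_fracs, float), 0.5 / replicates, 1 - 0.5 / replicates
    )
    sigma = np.sqrt(1.0 / np.asarray(scales, float))
    zvals = stats.norm.ppf(1.0 - bp)
    if np.ptp(bp) == 0:
        v = float(zvals[0])
        return v, 0.0, float(1.0 - stats.norm.cdf(v))
    weights = replicates * stats.norm.pdf(zvals) ** 2 / (bp * (1 - bp))
    X = np.column_stack([sigma, 1.0 / sigma])
    beta, *_ = np.linalg.lstsq(
        np.sqrt(weights)[:, None] * X, np.sqrt(weights) * zvals, rcond=None
    )
    v, c = float(beta[0]), float(beta[1])
    return v, c, float(1.0 - stats.norm.cdf(v - c))


# ---------------------------------------------------------------------------
# Robustness across clustering methods
# ---------------------------------------------------------------------------


def alternative_partitions(
    dist: np.ndarray,
    mean_mat: ConnectivityMatrix,
    k: int,
    seed: int = 0,
) -> dict:
    """Average-linkage, diagonal Gaussian-mixture and k-means partitions.

    The mixture and k-means operate on the mean-connectivity row
    profiles (each region described by its correlation with all
    others).  Mixture: best of 20 restarts by likelihood; k-means: 100
    restarts by inertia.  Deterministic given the seed.
    """
    names = list(mean_mat.region_names)
    n = len(names)
    if k == 1:
        triv = Partition(np.ones(n, int), names)
        return {"average": triv, "gmm": triv, "kmeans": triv}
    profiles = mean_mat.to_pearson().values
    link = hierarchy.linkage(
        squareform(np.asarray(dist, float), checks=False), method="average"
    )
    avg = cut_tree(MergeTree(link, names), k)
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        n_init=20,
        random_state=seed % (2**31),
        reg_covar=1e-6,
    ).fit(profiles)
    gmm_labels = gmm.predict(profiles) + 1
    km = KMeans(
        n_clusters=k, n_init=100, random_state=seed % (2**31)
    ).fit(profiles)
    km_labels = km.labels_ + 1

    def _canon(labels):
        labels = np.asarray(labels, int)
        uniq = {lab: i + 1 for i, lab in enumerate(
            sorted(set(labels), key=lambda l: (
                -(labels == l).sum(), int(np.argmax(labels == l))
            ))
        )}
        return Partition(np.array([uniq[l] for l in labels]), names)

    return {"average": avg, "gmm": _canon(gmm_labels), "kmeans": _canon(km_labels)}


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Chance-corrected agreement between two partitions (1 = identical)."""
    if p1.region_names != p2.region_names:
        raise DataError("partitions defined on different leaf sets")
    return float(adjusted_rand_score(p1.labels, p2.labels))
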