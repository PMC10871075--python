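"""Build the genomic-wave reference model.

Autosomes are tiled with fixed-size bins (default 1 Mb); the per-bin mean LRR
of each reference sample is the clustering feature.  Bins that are empty in
any sample, or whose across-sample SD of bin means is <= ``sd_threshold``
(default 0.05, inclusive), are excluded as uninformative.  The number of wave
clusters is chosen by the elbow method on the k-means curve of total
(unsquared) point-to-centroid distance, operationalized as the k maximizing
the discrete second difference of that curve.  The frozen model stores, per
cluster and per marker, the mean and SD of LRR across member samples -- the
statistics that later turn a test sample's raw LRR into Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .signal_io import MarkerMap, SignalSample, is_autosome

__all__ = [
    "ReferenceError",
    "BinScheme",
    "KSelectionCurve",
    "ReferenceModel",
    "bin_genome",
    "extract_bin_features",
    "select_informative_bins",
    "fit_kmeans",
    "select_k_elbow",
    "elbow_from_scores",
    "build_reference",
]

BIN_SIZE_DEFAULT = 1_000_000
BIN_SD_THRESHOLD_DEFAULT = 0.05
SD_FLOOR_DEFAULT = 1e-4
KMEANS_RESTARTS_DEFAULT = 10
MODEL_VERSION = "wavecnv-ref-1"


class ReferenceError(ValueError):
    """The reference cohort cannot support a valid model."""


@dataclass
class BinScheme:
    """Fixed-size tiling of the autosomes, plus the informative-bin mask."""

    bin_size: int
    chrom: np.ndarray  # per-bin chromosome label
    start: np.ndarray  # 1-based inclusive
    end: np.ndarray
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def n_informative(self) -> int:
        if self.informative_mask is None:
            raise ValueError("informative mask not set")
        return int(self.informative_mask.sum())

    def assign_markers(self, markers: MarkerMap) -> np.ndarray:
        """Per-marker bin index; -1 for markers outside the scheme (sex chroms)."""
        offsets: dict[str, tuple[int, int]] = {}
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            offsets[c] = (int(idx[0]), len(idx))
        out = np.full(len(markers), -1, dtype=np.int64)
        for i, (c, p) in enumerate(zip(markers.chrom, markers.position)):
            if c in offsets:
                first, count = offsets[c]
                j = (int(p) - 1) // self.bin_size
                if 0 <= j < count:
                    out[i] = first + j
        return out


@dataclass(frozen=True)
class KSelectionCurve:
    k_values: np.ndarray
    scores: np.ndarray


@dataclass
class ReferenceModel:
    """Frozen wave-cluster reference.

    ``marker_mean``/``marker_sd`` are (k, n_markers) arrays of per-cluster
    LRR statistics; ``reference_features``/``reference_labels`` are retained
    so new samples can be classified by k-NN against the fitting cohort.
    """

    k: int
    bin_scheme: BinScheme
    markers: MarkerMap
    centroids: np.ndarray
    cluster_sizes: np.ndarray
    marker_mean: np.ndarray
    marker_sd: np.ndarray
    sd_floor: float
    seed: int
    version: str = MODEL_VERSION
    reference_features: np.ndarray | None = None
    reference_labels: np.ndarray | None = None
    reference_sample_ids: list[str] = field(default_factory=list)
    selection_curve: KSelectionCurve | None = None

    @property
    def feature_means(self) -> np.ndarray:
        """Column means of the reference feature matrix (imputation values)."""
        if self.reference_features is not None:
            return self.reference_features.mean(axis=0)
        return self.centroids.mean(axis=0)


def bin_genome(markers: MarkerMap, bin_size: int = BIN_SIZE_DEFAULT) -> BinScheme:
    """Tile each autosome from position 1 to the last marker's position.

    The final partial bin is kept at full nominal width.  Sex chromosomes are
    excluded.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for c, sl in markers.chrom_slices():
        if not is_autosome(c):
            continue
        last = int(markers.position[sl].max())
        n_bins = (last + bin_size - 1) // bin_size
        for j in range(n_bins):
            chroms.append(c)
            starts.append(j * bin_size + 1)
            ends.append((j + 1) * bin_size)
    return BinScheme(bin_size=bin_size, chrom=np.array(chroms, dtype=object),
                     start=np.array(starts), end=np.array(ends))


def extract_bin_features(sample: SignalSample, scheme: BinScheme,
                         markers: MarkerMap) -> np.ndarray:
    """Per-bin mean of non-missing LRR; bins with no observations are NaN."""
    idx = scheme.assign_markers(markers)
    ok = (idx >= 0) & np.isfinite(sample.lrr)
    sums = np.bincount(idx[ok], weights=sample.lrr[ok], minlength=scheme.n_bins)
    counts = np.bincount(idx[ok], minlength=scheme.n_bins)
    out = np.full(scheme.n_bins, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def select_informative_bins(features: np.ndarray,
                            sd_threshold: float = BIN_SD_THRESHOLD_DEFAULT) -> np.ndarray:
    """Mask of informative bins over a (n_samples, n_bins) feature matrix.

    A bin is excluded if it is empty (NaN) in any sample or if the
    across-sample SD of its bin means is <= ``sd_threshold`` (inclusive).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a (n_samples >= 2, n_bins) feature matrix")
    complete = np.isfinite(features).all(axis=0)
    sd = np.zeros(features.shape[1])
    sd[complete] = np.std(features[:, complete], axis=0, ddof=1)
    return complete & (sd > sd_threshold)


def _spawn_ints(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def fit_kmeans(features: np.ndarray, k: int, seed: int,
               n_init: int = KMEANS_RESTARTS_DEFAULT) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's k-means, Euclidean, best of ``n_init`` restarts.

    The selection score -- and the returned score -- is the total *unsquared*
    point-to-centroid distance, matching the elbow curve used for k
    selection.
    """
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features contain missing values; impute first")
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for child in _spawn_ints(seed, n_init):
        km = KMeans(n_clusters=k, n_init=1, init="k-means++", random_state=child)
        labels = km.fit_predict(X)
        dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
        score = float(dists.sum())
        if best is None or score < best[0]:
            best = (score, labels, km.cluster_centers_.copy())
    assert best is not None
    score, labels, centroids = best
    return labels, centroids, score


def elbow_from_scores(k_values: Sequence[int], scores: Sequence[float]) -> int:
    """Elbow of a k-selection curve: interior k maximizing the second
    difference score(k-1) - 2*score(k) + score(k+1); ties to the smallest k."""
    ks = list(k_values)
    sc = list(scores)
    if len(ks) < 3:
        return ks[-1]
    best_k, best_d2 = None, -np.inf
    for i in range(1, len(ks) - 1):
        d2 = sc[i - 1] - 2.0 * sc[i] + sc[i + 1]
        if d2 > best_d2:
            best_k, best_d2 = ks[i], d2
    assert best_k is not None
    return best_k


def select_k_elbow(features: np.ndarray, k_min: int = 2, k_max: int = 20,
                   seed: int = 0, n_init: int = KMEANS_RESTARTS_DEFAULT
                   ) -> tuple[int, KSelectionCurve]:
    """Choose the cluster count by the elbow method over k = k_min..k_max.

    The curve is padded on the left with the k = k_min - 1 fit (down to k=1)
    so the second difference is defined at k_min.
    """
    if k_max < k_min:
        raise ValueError("k_max < k_min")
    X = np.asarray(features, dtype=float)
    if k_max > X.shape[0]:
        raise ValueError("k_max exceeds sample count")
    lo = max(1, k_min - 1)
    ks = list(range(lo, k_max + 1))
    scores = [fit_kmeans(X, k, seed=seed, n_init=n_init)[2] for k in ks]
    curve = KSelectionCurve(np.array(ks), np.array(scores))
    if k_min == k_max:
        return k_min, curve
    # restrict candidates to [k_min, k_max - 1]
    cand = [(k, s) for k, s in zip(ks, scores)]
    best_k, best_d2 = k_min, -np.inf
    for i in range(1, len(cand) - 1):
        k = cand[i][0]
        if not (k_min <= k <= k_max - 1):
            continue
        d2 = cand[i - 1][1] - 2.0 * cand[i][1] + cand[i + 1][1]
        if d2 > best_d2:
            best_k, best_d2 = k, d2
    return best_k, curve


def _impute_column_means(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return X


def build_reference(
    samples: Sequence[SignalSample],
    markers: MarkerMap,
    bin_size: int = BIN_SIZE_DEFAULT,
    k_range: tuple[int, int] = (2, 20),
    sd_floor: float = SD_FLOOR_DEFAULT,
    seed: int = 0,
    sd_threshold: float = BIN_SD_THRESHOLD_DEFAULT,
    n_init: int = KMEANS_RESTARTS_DEFAULT,
) -> ReferenceModel:
    """Full reference construction: bin, select bins, pick k, cluster, freeze stats.

    Every cluster must end up with at least 2 members (the per-marker SD uses
    ddof=1); otherwise a :class:`ReferenceError` is raised.
    """
    if len(samples) < 2:
        raise ReferenceError("need at least 2 reference samples")
    scheme = bin_genome(markers, bin_size)
    raw = np.vstack([extract_bin_features(s, scheme, markers) for s in samples])
    mask = select_informative_bins(raw, sd_threshold=sd_threshold)
    if mask.sum() == 0:
        raise ReferenceError("no informative bins")
    scheme.informative_mask = mask
    X = _impute_column_means(raw[:, mask])

    k_min, k_max = k_range
    k_max = min(k_max, len(samples))
    k, curve = select_k_elbow(X, k_min=k_min, k_max=k_max, seed=seed, n_init=n_init)
    labels, centroids, _ = fit_kmeans(X, k, seed=seed, n_init=n_init)

    sizes = np.bincount(labels, minlength=k)
    if (sizes < 2).any():
        raise ReferenceError(f"cluster sizes {sizes.tolist()} include a cluster < 2")

    n_markers = len(markers)
    marker_mean = np.zeros((k, n_markers))
    marker_sd = np.zeros((k, n_markers))
    lrr_matrix = np.vstack([s.lrr for s in samples])
    for c in range(k):
        member = lrr_matrix[labels == c]
        with np.errstate(invalid="ignore"):
            marker_mean[c] = np.nanmean(member, axis=0)
            marker_sd[c] = np.nanstd(member, axis=0, ddof=1)
    marker_mean = np.nan_to_num(marker_mean, nan=0.0)
    marker_sd = np.nan_to_num(marker_sd, nan=0.0)
    marker_sd = np.maximum(marker_sd, sd_floor)

    return ReferenceModel(
        k=k,
        bin_scheme=scheme,
        markers=markers,
        centroids=centroids,
        cluster_sizes=sizes,
        marker_mean=marker_mean,
        marker_sd=marker_sd,
        sd_floor=sd_floor,
        seed=seed,
        reference_features=X,
        reference_labels=labels,
        reference_sample_ids=[s.sample_id for s in samples],
        selection_curve=curve,
    )
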