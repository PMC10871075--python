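"""Wave-cluster assignment and the raw LRR -> modified LRR (mLRR) transform.

A test sample is assigned to the wave cluster of the majority of its k
nearest reference samples (Euclidean distance in informative-bin feature
space; ties broken toward the cluster whose centroid is nearest, then the
smaller cluster index).  Its raw LRR is then normalized per marker against
the cluster's frozen statistics, z_i = (x_i - mean_i) / sd_i, and the
Z-scores are rescaled affinely so the corrected signal keeps the sample's
original LRR mean and SD:

    mlrr_i = (z_i - mean(z)) * SD(lrr)/SD(z) + mean(lrr)

Subtracting the per-marker cluster mean is what cancels the genomic wave;
the rescale only restores the familiar LRR units so downstream callers can
consume the corrected signal unchanged.  Test samples never update the
reference model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import MarkerMap, SignalSample
from .wave_reference import ReferenceModel, extract_bin_features

__all__ = [
    "CorrectedSignal",
    "assign_cluster",
    "zscore_normalize",
    "rescale_to_mlrr",
    "correct_sample",
]

KNN_K_DEFAULT = 5
DEGENERATE_SD = 1e-12


@dataclass
class CorrectedSignal:
    """Wave-corrected signal for one sample; BAF passes through unchanged."""

    sample_id: str
    cluster_id: int
    z: np.ndarray
    mlrr: np.ndarray
    scale: float
    center: float
    baf: np.ndarray | None = None
    genotype: np.ndarray | None = None

    def as_sample(self) -> SignalSample:
        """Repackage with mLRR in the LRR slot (drop-in for external callers)."""
        baf = self.baf if self.baf is not None else np.full_like(self.mlrr, np.nan)
        return SignalSample(self.sample_id, self.mlrr, baf, self.genotype)


def assign_cluster(
    sample: SignalSample,
    model: ReferenceModel,
    reference_features: np.ndarray | None = None,
    reference_labels: np.ndarray | None = None,
    knn_k: int = KNN_K_DEFAULT,
) -> int:
    """k-NN cluster assignment in informative-bin feature space.

    Missing bins in the query are imputed with the reference feature means.
    """
    if reference_features is None:
        reference_features = model.reference_features
        reference_labels = model.reference_labels
    if reference_features is None or reference_labels is None:
        raise ValueError("model carries no reference features for k-NN")
    q = extract_bin_features(sample, model.bin_scheme, model.markers)
    q = q[model.bin_scheme.informative_mask]
    if q.shape[0] != reference_features.shape[1]:
        raise ValueError("feature dimension mismatch between query and reference")
    missing = ~np.isfinite(q)
    if missing.any():
        q = q.copy()
        q[missing] = model.feature_means[missing]

    dists = np.linalg.norm(reference_features - q, axis=1)
    k = min(knn_k, len(dists))
    nearest = np.argsort(dists, kind="stable")[:k]
    votes = np.bincount(reference_labels[nearest], minlength=model.k)
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if len(tied) == 1:
        return int(tied[0])
    centroid_d = np.linalg.norm(model.centroids[tied] - q, axis=1)
    # nearest centroid among tied labels; remaining ties -> smaller index
    return int(tied[np.argmin(centroid_d)])


def zscore_normalize(sample: SignalSample, model: ReferenceModel, cluster_id: int) -> np.ndarray:
    """Per-marker Z-score against the cluster's frozen mean/SD; missing LRR -> NaN."""
    if not 0 <= cluster_id < model.k:
        raise ValueError(f"cluster_id {cluster_id} outside [0, {model.k})")
    return (sample.lrr - model.marker_mean[cluster_id]) / model.marker_sd[cluster_id]


def rescale_to_mlrr(
    z: np.ndarray,
    raw_lrr: np.ndarray,
    stat_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Affine rescale of Z-scores back to the sample's raw LRR moments.

    Statistics (ddof=1) are taken over markers where both vectors are present
    (optionally restricted by ``stat_mask``, e.g. to autosomes).  If SD(z) is
    numerically zero the guard fires: every present marker gets the raw mean
    and the recorded scale is 0.
    """
    z = np.asarray(z, dtype=float)
    raw_lrr = np.asarray(raw_lrr, dtype=float)
    both = np.isfinite(z) & np.isfinite(raw_lrr)
    stat = both if stat_mask is None else (both & np.asarray(stat_mask, bool))
    if stat.sum() < 2:
        raise ValueError("need at least 2 jointly non-missing values")
    mean_z = float(np.mean(z[stat]))
    sd_z = float(np.std(z[stat], ddof=1))
    center = float(np.mean(raw_lrr[stat]))
    sd_raw = float(np.std(raw_lrr[stat], ddof=1))

    mlrr = np.full_like(z, np.nan)
    if sd_z < DEGENERATE_SD:
        mlrr[np.isfinite(z)] = center
        return mlrr, 0.0, center
    scale = sd_raw / sd_z
    present = np.isfinite(z)
    mlrr[present] = (z[present] - mean_z) * scale + center
    return mlrr, scale, center


def correct_sample(
    sample: SignalSample,
    model: ReferenceModel,
    reference_features: np.ndarray | None = None,
    reference_labels: np.ndarray | None = None,
    knn_k: int = KNN_K_DEFAULT,
) -> CorrectedSignal:
    """assign_cluster -> zscore_normalize -> rescale_to_mlrr, BAF untouched.

    Moment-matching statistics are restricted to autosomal markers (the
    clusters are built on autosomes only); sex-chromosome markers still
    receive Z-scores and mLRR from the cluster statistics.
    """
    cluster = assign_cluster(sample, model, reference_features, reference_labels, knn_k)
    z = zscore_normalize(sample, model, cluster)
    auto = model.markers.autosome_mask
    stat_mask = auto if not auto.all() else None
    mlrr, scale, center = rescale_to_mlrr(z, sample.lrr, stat_mask=stat_mask)
    return CorrectedSignal(
        sample_id=sample.sample_id,
        cluster_id=cluster,
        z=z,
        mlrr=mlrr,
        scale=scale,
        center=center,
        baf=sample.baf,
        genotype=sample.genotype,
    )
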