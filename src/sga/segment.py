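"""Membrane-stain based 3D cell segmentation.

The route mirrors an interactive pixel-classification workflow: multiscale
intensity/gradient/Laplacian features feed a random-forest classifier trained
on sparse voxel annotations; thresholding its interior-probability map and
size-filtering the connected components yields seeds; a seeded watershed on
(1 − probability) grows the seeds into full 3D cell territories; finally cells
whose volumes fall outside a robust Gaussian band are flagged out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import relabel_sequential, watershed
from sklearn.ensemble import RandomForestClassifier

from .geometry import VoxelGeometry


def extract_features(
    membrane_stack: np.ndarray,
    scales: tuple[float, ...] = (1.0, 2.0, 4.0),
    standardize: bool = True,
) -> np.ndarray:
    """Per-voxel multiscale feature volume, shape ``stack.shape + (3*len(scales),)``.

    Per scale: Gaussian-smoothed intensity, gradient magnitude, Laplacian.
    By default each feature is standardized over the volume (zero mean, unit
    SD) so tree splits see comparable ranges across acquisitions;
    ``standardize=False`` returns the raw filter responses.
    """
    if len(scales) == 0:
        raise ValueError("at least one scale is required")
    stack = np.asarray(membrane_stack, dtype=np.float32)
    feats = []
    for s in scales:
        if s < 1.0:
            warnings.warn(f"feature scale {s} below voxel size; under-resolved", stacklevel=2)
        smooth = ndimage.gaussian_filter(stack, sigma=s)
        grad = ndimage.gaussian_gradient_magnitude(stack, sigma=s)
        lap = ndimage.gaussian_laplace(stack, sigma=s)
        feats.extend([smooth, grad, lap])
    out = np.stack(feats, axis=-1).astype(np.float32)
    if not standardize:
        return out
    flat = out.reshape(-1, out.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    return ((out - mean) / sd).astype(np.float32)


def train_pixel_classifier(
    features: np.ndarray,
    sparse_labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
) -> RandomForestClassifier:
    """Train an interior-vs-rest random forest on sparsely annotated voxels.

    ``sparse_labels``: same spatial shape as the feature volume, −1 for
    unlabeled voxels, 0 for not-interior (membrane/outside), 1 for interior.
    Out-of-bag accuracy is stored on the returned classifier
    (``oob_score_``).
    """
    mask = sparse_labels >= 0
    y = sparse_labels[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("sparse labels must contain both interior (1) and not-interior (0) voxels")
    X = features[mask]
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def predict_interior(clf: RandomForestClassifier, features: np.ndarray) -> np.ndarray:
    """Per-voxel interior probability map in [0, 1]."""
    if features.shape[-1] != clf.n_features_in_:
        raise ValueError(
            f"feature dimensionality {features.shape[-1]} != training {clf.n_features_in_}"
        )
    shape = features.shape[:-1]
    flat = features.reshape(-1, features.shape[-1])
    proba = clf.predict_proba(flat)[:, list(clf.classes_).index(1)]
    return proba.reshape(shape).astype(np.float32)


class NoSeedsError(ValueError):
    """No connected component survived thresholding + size filtering."""


def seeds_from_probability(
    prob: np.ndarray, threshold: float = 0.5, min_seed_voxels: int = 240
) -> np.ndarray:
    """Connected components of ``prob >= threshold`` with size >= min_seed_voxels.

    The default minimum corresponds to 30 µm³ at the simulator's 0.125 µm³
    voxel. Returns a label volume with seeds labeled 1..K.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly between 0 and 1")
    binary = prob >= threshold
    # 6-connectivity: diagonal contact across a thin membrane must not merge seeds
    labeled, n = ndimage.label(binary, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        raise NoSeedsError(
            "no voxel reached the probability threshold; lower `threshold` or retrain"
        )
    counts = np.bincount(labeled.ravel())
    keep = np.flatnonzero(counts >= min_seed_voxels)
    keep = keep[keep > 0]
    if len(keep) == 0:
        raise NoSeedsError(
            f"all {n} components are smaller than min_seed_voxels={min_seed_voxels}; "
            "lower the threshold or the size cutoff"
        )
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, len(keep) + 1)
    return mapping[labeled]


def watershed_3d(
    elevation: np.ndarray, seeds: np.ndarray, barrier_mask: np.ndarray | None = None
) -> np.ndarray:
    """Seeded watershed; each foreground voxel joins exactly one seed's catchment.

    ``elevation`` is typically ``1 − interior probability``; voxels in
    ``barrier_mask`` (e.g. interior probability < 0.2: membrane or outside
    tissue) stay label 0. Output labels are relabeled to a contiguous 1..K.
    """
    if elevation.shape != seeds.shape:
        raise ValueError("elevation and seeds must share a shape")
    mask = None if barrier_mask is None else ~barrier_mask
    labels = watershed(elevation, markers=seeds, mask=mask)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_membrane_stack(
    membrane_stack: np.ndarray,
    sparse_labels: np.ndarray,
    geometry: VoxelGeometry,
    scales: tuple[float, ...] = (1.0, 2.0, 4.0),
    threshold: float = 0.5,
    min_seed_voxels: int = 240,
    barrier_probability: float = 0.2,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, RandomForestClassifier]:
    """Full classify → seed → watershed route on one membrane stack.

    Returns ``(label_volume, cell_table, classifier)``.
    """
    feats = extract_features(membrane_stack, scales)
    clf = train_pixel_classifier(feats, sparse_labels, n_trees=n_trees, seed=seed)
    prob = predict_interior(clf, feats)
    seeds = seeds_from_probability(prob, threshold, min_seed_voxels)
    labels = watershed_3d(1.0 - prob, seeds, barrier_mask=prob < barrier_probability)
    table = cell_table_from_labels(labels, geometry)
    table, _ = filter_cells_by_volume(table)
    return labels, table, clf


def cell_table_from_labels(labels: np.ndarray, geometry: VoxelGeometry) -> pd.DataFrame:
    """Per-cell volume, centroid and boundary-contact flag from a label volume."""
    from .simulate import cell_stats  # shared implementation

    table = cell_stats(labels, geometry)
    table["kept"] = True
    return table


def filter_cells_by_volume(
    cell_table: pd.DataFrame, z_cut: float = 3.0, min_cells: int = 10
) -> tuple[pd.DataFrame, float]:
    """Robust Gaussian volume filter: flag cells with |robust z| > z_cut.

    Watershed fragments and merged cells land in the tails of the otherwise
    Gaussian-looking cell-volume distribution; the filter removes them via a
    median/MAD z-score. Returns the table with ``kept`` updated and the
    excluded fraction. Fewer than ``min_cells`` cells, or MAD = 0: all kept,
    with a diagnostic.
    """
    out = cell_table.copy()
    if len(out) == 0:
        return out, 0.0
    vols = out["volume_um3"].to_numpy(dtype=float)
    if len(vols) < min_cells:
        warnings.warn(f"only {len(vols)} cells (<{min_cells}); volume filter skipped", stacklevel=2)
        return out, 0.0
    med = np.median(vols)
    mad = 1.4826 * np.median(np.abs(vols - med))
    if mad == 0:
        warnings.warn("volume filter: MAD is zero; keeping all cells", stacklevel=2)
        return out, 0.0
    z = (vols - med) / mad
    excluded = np.abs(z) > z_cut
    out["kept"] = out.get("kept", True) & ~excluded
    return out, float(excluded.mean())


@dataclass
class SegmentationMatch:
    """1:1 greedy IoU matching of predicted to true labels (evaluation aid)."""

    pairs: pd.DataFrame  # true_id, pred_id, iou
    matched_fraction: float  # fraction of true cells matched at the IoU cutoff


def match_segmentation(
    true_labels: np.ndarray, pred_labels: np.ndarray, iou_threshold: float = 0.5
) -> SegmentationMatch:
    """Greedy best-IoU matching between ground-truth and predicted cells."""
    true_ids = np.unique(true_labels)
    true_ids = true_ids[true_ids > 0]
    overlap: dict[tuple[int, int], int] = {}
    flat_t = true_labels.ravel()
    flat_p = pred_labels.ravel()
    both = (flat_t > 0) & (flat_p > 0)
    pair_codes, counts = np.unique(
        flat_t[both].astype(np.int64) << 32 | flat_p[both].astype(np.int64), return_counts=True
    )
    sizes_t = np.bincount(flat_t)
    sizes_p = np.bincount(flat_p)
    records = []
    for code, inter in zip(pair_codes, counts):
        t, p = int(code >> 32), int(code & 0xFFFFFFFF)
        union = sizes_t[t] + sizes_p[p] - inter
        records.append((t, p, inter / union))
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for t, p, iou in records:
        if iou < iou_threshold or t in used_t or p in used_p:
            continue
        used_t.add(t)
        used_p.add(p)
        pairs.append((t, p, iou))
    df = pd.DataFrame(pairs, columns=["true_id", "pred_id", "iou"])
    frac = len(df) / max(len(true_ids), 1)
    return SegmentationMatch(pairs=df, matched_fraction=float(frac))
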