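"""Round-to-round registration and the two dot-level QC statistics.

Samples are remounted between hybridization rounds, so every round is rigidly
shifted relative to the first. The shift is estimated from the morphological
reference channel (the membrane stain) by phase cross-correlation, spot
coordinates — not images — are resampled into the reference frame, and two QC
rates are computed by one-to-one spot matching: two-channel colocalization and
first-round rehybridization recovery. Both are expected to exceed ~80% on an
intact sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation


@dataclass(frozen=True)
class RigidShift:
    """Translation mapping a moving round into the reference frame."""

    round_index: int
    dz: float
    dy: float
    dx: float
    score: float  # normalized correlation after alignment, in [-1, 1]

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dz, self.dy, self.dx])


class LowConfidenceShift(RuntimeError):
    """Correlation peak too weak to trust; manual correction required."""


def _aligned_correlation(reference: np.ndarray, moving: np.ndarray, shift: np.ndarray) -> float:
    """Pearson correlation of the overlapping region after integer alignment."""
    s = np.round(shift).astype(int)
    slices_ref, slices_mov = [], []
    for axis, d in enumerate(s):
        n = reference.shape[axis]
        if abs(d) >= n:
            return 0.0
        if d >= 0:
            slices_ref.append(slice(d, n))
            slices_mov.append(slice(0, n - d))
        else:
            slices_ref.append(slice(0, n + d))
            slices_mov.append(slice(-d, n))
    a = reference[tuple(slices_ref)].ravel().astype(float)
    b = moving[tuple(slices_mov)].ravel().astype(float)
    if a.size < 8 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def estimate_translation(
    reference_stack: np.ndarray,
    moving_stack: np.ndarray,
    max_drift: float = 10.0,
    round_index: int = 0,
    min_score: float = 0.2,
    upsample_factor: int = 20,
) -> RigidShift:
    """Estimate the rigid translation of ``moving_stack`` relative to the reference.

    Phase cross-correlation with upsampled-DFT subvoxel refinement; the
    returned shift, *added* to moving-round coordinates, maps them into the
    reference frame. A normalized correlation score of the aligned overlap is
    attached; below ``min_score`` a :class:`LowConfidenceShift` is raised
    (the hook for manual correction).
    """
    if reference_stack.shape != moving_stack.shape:
        raise ValueError("stacks must share a shape")
    detected, _, _ = phase_cross_correlation(
        reference_stack, moving_stack, upsample_factor=upsample_factor, normalization=None
    )
    shift = np.asarray(detected, dtype=float)
    if np.any(np.abs(shift) > max_drift):
        raise LowConfidenceShift(
            f"estimated shift {tuple(shift)} exceeds max_drift={max_drift}"
        )
    score = _aligned_correlation(reference_stack, moving_stack, shift)
    if score < min_score:
        raise LowConfidenceShift(
            f"alignment score {score:.3f} below {min_score}; correct manually"
        )
    return RigidShift(round_index=round_index, dz=shift[0], dy=shift[1], dx=shift[2], score=score)


def apply_shift_to_spots(
    table: pd.DataFrame, shift: RigidShift, volume_shape: tuple[int, int, int]
) -> pd.DataFrame:
    """Translate spot coordinates into the reference frame.

    Dots landing outside the volume are flagged ``kept=False`` (they cannot
    be assigned to any cell).
    """
    out = table.copy()
    if "kept" not in out.columns:
        out["kept"] = True
    coords = out[["z", "y", "x"]].to_numpy(dtype=float) + shift.vector
    out[["z", "y", "x"]] = coords
    inside = np.all((coords >= -0.5) & (coords <= np.asarray(volume_shape) - 0.5), axis=1)
    out["kept"] = out["kept"].to_numpy() & inside
    return out


@dataclass
class SpotMatching:
    """One-to-one matching between two dot sets within a radius."""

    pairs: pd.DataFrame  # index_a, index_b, distance
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray
    rate_a: float  # matched / |A|

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_spots(
    a: pd.DataFrame,
    b: pd.DataFrame,
    radius: float = 1.0,
    z_aspect: float = 1.0,
) -> SpotMatching:
    """Greedy globally-nearest-first one-to-one matching within ``radius``.

    Distances are lateral-equivalent: z-differences are multiplied by
    ``z_aspect`` (axial/lateral voxel-size ratio) before the Euclidean norm,
    so the radius means the same physical distance on every axis. Candidate
    pairs are accepted nearest-first; ties break on (distance, index in A,
    index in B), making the matching deterministic.
    """
    pa = a[["z", "y", "x"]].to_numpy(dtype=float).copy()
    pb = b[["z", "y", "x"]].to_numpy(dtype=float).copy()
    pa[:, 0] *= z_aspect
    pb[:, 0] *= z_aspect
    if len(pa) == 0 or len(pb) == 0:
        return SpotMatching(
            pairs=pd.DataFrame(columns=["index_a", "index_b", "distance"]),
            unmatched_a=np.arange(len(pa)),
            unmatched_b=np.arange(len(pb)),
            rate_a=0.0,
        )
    from scipy.spatial import cKDTree

    tree = cKDTree(pb)
    candidates = tree.query_ball_point(pa, r=radius)
    edges = []
    for ia, nbrs in enumerate(candidates):
        for ib in nbrs:
            edges.append((float(np.linalg.norm(pa[ia] - pb[ib])), ia, ib))
    edges.sort()
    used_a = np.zeros(len(pa), dtype=bool)
    used_b = np.zeros(len(pb), dtype=bool)
    pairs = []
    for d, ia, ib in edges:
        if used_a[ia] or used_b[ib]:
            continue
        used_a[ia] = used_b[ib] = True
        pairs.append((ia, ib, d))
    df = pd.DataFrame(pairs, columns=["index_a", "index_b", "distance"])
    return SpotMatching(
        pairs=df,
        unmatched_a=np.flatnonzero(~used_a),
        unmatched_b=np.flatnonzero(~used_b),
        rate_a=len(df) / len(pa),
    )


def colocalization_rate(
    channel_a: pd.DataFrame, channel_b: pd.DataFrame, radius: float = 1.0, z_aspect: float = 1.0
) -> float:
    """Fraction of channel-A dots re-found in channel B (two-color QC)."""
    return match_spots(channel_a, channel_b, radius=radius, z_aspect=z_aspect).rate_a


def recovery_rate(
    round_first: pd.DataFrame,
    round_repeat: pd.DataFrame,
    radius: float = 1.0,
    z_aspect: float = 1.0,
    per_gene: bool = False,
) -> float | tuple[float, pd.Series]:
    """Fraction of first-round dots recovered in the end-of-experiment repeat.

    Both tables must already be in the reference frame. With
    ``per_gene=True`` additionally returns a per-gene rate Series.
    """
    if len(round_first) == 0:
        raise ValueError("first round has no dots; recovery rate undefined")
    overall = match_spots(round_first, round_repeat, radius=radius, z_aspect=z_aspect).rate_a
    if not per_gene:
        return overall
    rates = {}
    for gene, sub_a in round_first.groupby("gene"):
        sub_b = round_repeat[round_repeat["gene"] == gene]
        rates[gene] = (
            match_spots(sub_a, sub_b, radius=radius, z_aspect=z_aspect).rate_a
            if len(sub_a)
            else np.nan
        )
    return overall, pd.Series(rates, name="recovery_rate")
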