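"""Diffraction-limited dot detection and the weakest-intensity background filter.

Each transcript appears as one anisotropic PSF-shaped dot in a 3D stack.
Detection runs an anisotropic Laplacian-of-Gaussian filter, takes local maxima
above a permissive floor, and refines each peak to subvoxel precision with a
separable 3-point parabolic fit. Nonspecific probe binding produces a small
population of dim dots; these are removed per round/channel by a one-sided
robust z-score on log-intensity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

SPOT_COLUMNS = ["round", "channel", "gene", "z", "y", "x", "intensity", "kept", "cell_id"]


def empty_spot_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "round": pd.Series(dtype=int),
            "channel": pd.Series(dtype=int),
            "gene": pd.Series(dtype=object),
            "z": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "intensity": pd.Series(dtype=float),
            "kept": pd.Series(dtype=bool),
            "cell_id": pd.Series(dtype=int),
        }
    )


def _parabolic_offset(fm: np.ndarray, f0: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Vertex offset of the parabola through (-1, fm), (0, f0), (1, fp)."""
    denom = fm - 2.0 * f0 + fp
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (fm - fp) / denom
    off = np.where(np.abs(denom) < 1e-12, 0.0, off)
    return np.clip(off, -0.5, 0.5)


def detect_spots(
    stack: np.ndarray,
    psf_sigma_voxels: tuple[float, float, float],
    min_separation: float = 1.0,
    floor: float | None = None,
    round_index: int = 0,
    channel: int = 0,
    gene: str = "",
) -> pd.DataFrame:
    """Detect diffraction-limited dots in one 3D stack.

    Parameters
    ----------
    stack
        3D intensity volume (z, y, x).
    psf_sigma_voxels
        Anisotropic PSF sigma in voxels, (z, y, x) order.
    min_separation
        Minimum lateral distance between reported maxima, voxels.
    floor
        Minimum LoG response, as a multiple of the robust noise level of the
        response volume. ``None`` uses 5 (a deliberately permissive floor —
        the statistical background cut is done later on intensities).

    Returns a SpotTable with one row per detection: subvoxel (z, y, x) from a
    separable parabolic fit and the raw peak intensity of the smoothed stack.
    """
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ValueError(f"stack must be 3D, got shape {stack.shape}")
    sigma = np.asarray(psf_sigma_voxels, dtype=float)
    if np.any(sigma[1:] < 0.5):
        warnings.warn(
            "lateral PSF sigma below 0.5 voxel: the dot is under-sampled and "
            "localization will degrade",
            stacklevel=2,
        )
    # scale-normalized LoG response (bright blobs -> positive peaks)
    log = -ndimage.gaussian_laplace(stack, sigma=sigma) * float(np.mean(sigma[1:]) ** 2)
    noise = 1.4826 * np.median(np.abs(log - np.median(log)))
    threshold = (5.0 if floor is None else floor) * max(noise, 1e-12)

    size = np.maximum(3, (2 * np.ceil(np.array([1.0, min_separation, min_separation])) + 1).astype(int))
    local_max = (log == ndimage.maximum_filter(log, size=tuple(size))) & (log > threshold)
    coords = np.argwhere(local_max)
    if len(coords) == 0:
        return empty_spot_table()

    # separable 3-point parabolic refinement on the LoG response
    refined = coords.astype(float)
    valid = np.all((coords >= 1) & (coords < np.array(stack.shape) - 1), axis=1)
    for axis in range(3):
        step = np.zeros(3, dtype=int)
        step[axis] = 1
        c = coords[valid]
        fm = log[tuple((c - step).T)]
        f0 = log[tuple(c.T)]
        fp = log[tuple((c + step).T)]
        refined[valid, axis] += _parabolic_offset(fm, f0, fp)

    smoothed = ndimage.gaussian_filter(stack, sigma=sigma / 2.0)
    intensity = smoothed[tuple(coords.T)]
    table = pd.DataFrame(
        {
            "round": round_index,
            "channel": channel,
            "gene": gene,
            "z": refined[:, 0],
            "y": refined[:, 1],
            "x": refined[:, 2],
            "intensity": intensity.astype(float),
            "kept": True,
            "cell_id": 0,
        }
    )
    return table.sort_values(["z", "y", "x"], kind="stable").reset_index(drop=True)


def filter_spot_intensities(
    table: pd.DataFrame, z_cut: float = -3.0, min_group: int = 20
) -> tuple[pd.DataFrame, float]:
    """Flag nonspecific dim dots per (round, channel) group.

    True single-molecule dots have log-intensities that follow a roughly
    Gaussian distribution; nonspecific binding shows up as a dim tail. Per
    round/channel group a robust Gaussian is fit to log-intensity (median and
    1.4826×MAD) and dots with robust z below ``z_cut`` get ``kept=False``.

    Returns the table with updated ``kept`` flags and the overall excluded
    fraction. Groups smaller than ``min_group`` or with MAD = 0 are kept
    wholesale (with a diagnostic warning): there is no distribution to fit.
    """
    out = table.copy()
    if len(out) == 0:
        return out, 0.0
    if (out["intensity"] <= 0).any():
        raise ValueError("spot intensities must be positive for the log-domain filter")
    excluded = np.zeros(len(out), dtype=bool)
    for (_, _), idx in out.groupby(["round", "channel"]).groups.items():
        vals = np.log(out.loc[idx, "intensity"].to_numpy(dtype=float))
        if len(vals) < min_group:
            warnings.warn(
                f"intensity filter: group of {len(vals)} dots (<{min_group}); keeping all",
                stacklevel=2,
            )
            continue
        med = np.median(vals)
        mad = 1.4826 * np.median(np.abs(vals - med))
        if mad == 0:
            warnings.warn("intensity filter: zero MAD in a group; keeping all", stacklevel=2)
            continue
        z = (vals - med) / mad
        excluded[out.index.get_indexer(idx)] = z < z_cut
    # never drop the globally brightest dot
    excluded[int(np.argmax(out["intensity"].to_numpy()))] = False
    out["kept"] = out["kept"].to_numpy() & ~excluded
    return out, float(excluded.mean())
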