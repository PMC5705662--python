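"""Synthetic 3D seqFISH tissue scenes with complete ground truth.

The simulator emulates the statistical structure a sequential-smFISH pipeline
assumes: a tightly packed epithelial sheet of ~250 cells whose membranes are
visible in a dedicated stain channel, population-structured transcript counts
for 35 genes read out over 7 hybridization rounds × 5 channels, diffraction-
limited dots with a small nonspecific dim background fraction, rigid round-to-
round drift, and per-spot recapture loss on rehybridization. Every quantity a
downstream stage estimates (cell labels, spot positions, counts, population
memberships, drifts) is emitted as ground truth so the whole pipeline is
testable without any real acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .codebook import Codebook
from .geometry import VoxelGeometry

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_mean_counts",
    "place_cells",
    "sample_expression",
    "simulate_scene",
    "render_round",
    "render_membrane",
    "zero_fraction",
]

#: Simulator imaging geometry: 13 µm camera pixels at 39x (1/3 µm lateral) and
#: 0.5 µm z-steps — a whole cell spans ~20-25 voxels laterally, and single-
#: molecule dots stay well separated, as they are at acquisition resolution.
SIM_GEOMETRY = VoxelGeometry(camera_pixel_um=13.0, magnification=39.0, z_step_um=0.5)


class PackingError(ValueError):
    """Raised when the requested cells cannot fit in the configured volume."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic tissue scene.

    The defaults describe the study-scale scene: 250 cells in 5 spatially
    contiguous populations, 35 genes over 7 rounds × 5 channels.
    """

    n_cells: int = 250
    n_populations: int = 5
    n_genes: int = 35
    rounds: int = 7
    channels_per_round: int = 5
    volume_shape: tuple[int, int, int] = (28, 400, 400)
    voxel_geometry: VoxelGeometry = SIM_GEOMETRY
    edge_margin: tuple[int, int, int] = (3, 4, 4)  # keep tissue off the stack faces
    mean_cell_volume_voxels: float = 9000.0
    cell_volume_cv: float = 0.2
    mean_counts: np.ndarray | None = None  # (n_populations, n_genes); None → default panel
    count_dispersion: float | None = 20.0  # NB dispersion theta; None → Poisson limit
    module_genes: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    module_factor_sd: float = 0.35  # log-sd of the shared per-cell factor on module genes
    background_dot_fraction: float = 0.04
    background_intensity_factor: float = 0.3
    recapture_probability: float = 0.98
    drift_magnitude: float = 3.0  # voxels, lateral; axial drift is 1/4 of this
    psf_sigma_um: tuple[float, float] = (0.25, 0.5)  # (lateral, axial)
    true_intensity_mean: float = 1000.0
    intensity_log_sd: float = 0.2
    membrane_intensity: float = 900.0
    autofluorescence_intensity: float = 180.0  # dim glow of cell interiors vs dark outside
    noise_sd: float = 100.0
    spatial_layout: str = "blocks"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("n_populations", "n_genes", "rounds", "channels_per_round"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.background_dot_fraction < 1):
            raise ValueError("background_dot_fraction must be in [0, 1)")
        if not (0 < self.recapture_probability <= 1):
            raise ValueError("recapture_probability must be in (0, 1]")
        if self.n_genes > self.rounds * self.channels_per_round:
            raise ValueError("n_genes exceeds rounds × channels_per_round")

    def resolved_mean_counts(self) -> np.ndarray:
        if self.mean_counts is not None:
            m = np.asarray(self.mean_counts, dtype=float)
            if m.shape != (self.n_populations, self.n_genes):
                raise ValueError(
                    f"mean_counts shape {m.shape} != (n_populations, n_genes) = "
                    f"({self.n_populations}, {self.n_genes})"
                )
            return m
        return default_mean_counts(self.n_populations, self.n_genes)

    def psf_sigma_voxels(self) -> tuple[float, float, float]:
        lat, ax = self.psf_sigma_um
        return self.voxel_geometry.sigma_um_to_voxels(lat, ax)


def default_mean_counts(
    n_populations: int,
    n_genes: int,
    baseline: float = 2.0,
    marker: float = 12.0,
    housekeeping: float = 20.0,  # the high-copy housekeeping gene stays the brightest
) -> np.ndarray:
    """Population × gene expected counts with block marker structure.

    Genes are split into ``n_populations`` contiguous blocks; block ``p`` is
    the marker set of population ``p`` (mean ``marker`` there, ``baseline``
    elsewhere). The last gene plays the high-copy housekeeping role and is
    expressed at ``housekeeping`` in every population.
    """
    means = np.full((n_populations, n_genes), baseline, dtype=float)
    block = n_genes // n_populations
    for p in range(n_populations):
        lo = p * block
        hi = n_genes if p == n_populations - 1 else lo + block
        means[p, lo:hi] = marker
    means[:, -1] = housekeeping
    return means


@dataclass
class GroundTruth:
    """Everything the simulator knows about a scene."""

    config: SimulationConfig
    labels: np.ndarray  # (z, y, x) int32; 0 = membrane/background
    cell_table: pd.DataFrame  # cell_id, voxel_count, volume_um3, cz, cy, cx, touches_boundary
    population_of_cell: pd.Series  # index cell_id → population
    true_expression: pd.DataFrame  # index cell_id × columns gene
    spots: pd.DataFrame  # gene, round, channel, z, y, x, intensity, cell_id, is_background
    per_round_shift: dict[int, tuple[float, float, float]]
    codebook: Codebook


def _lattice_seeds(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice seed points, densest-possible regular packing."""
    margin = np.asarray(config.edge_margin, dtype=float)
    shape = np.asarray(config.volume_shape, dtype=float) - 2 * margin
    if np.any(shape <= 0):
        raise PackingError(f"volume {config.volume_shape} smaller than twice the edge margin")
    spacing = (config.mean_cell_volume_voxels * 1.35) ** (1.0 / 3.0)
    dims = np.maximum(1, np.round(shape / spacing).astype(int))
    # grow the grid along the least-squeezed axis until it holds n_cells,
    # refusing once cells would be squeezed below ~60% of their nominal pitch
    while int(np.prod(dims)) < config.n_cells:
        steps = shape / (dims + 1)
        axis = int(np.argmax(steps))
        if steps[axis] < 0.6 * spacing:
            raise PackingError(
                f"volume {config.volume_shape} fits at most {int(np.prod(dims))} cells "
                f"of mean volume {config.mean_cell_volume_voxels:.0f} voxels; "
                f"{config.n_cells} requested"
            )
        dims[axis] += 1
    step = shape / dims
    grid = np.stack(
        np.meshgrid(*[(np.arange(d) + 0.5) * s for d, s in zip(dims, step)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    # choose the most central sites first so the tissue stays one block
    center = shape / 2
    order = np.argsort(np.linalg.norm((grid - center) / shape, axis=1), kind="stable")
    seeds = grid[order[: config.n_cells]]
    jitter = rng.uniform(-0.25, 0.25, size=seeds.shape) * step
    return seeds + jitter + margin


def _assign_voxels(
    shape: tuple[int, int, int], seeds: np.ndarray, radii: np.ndarray, reach: float = 1.25
) -> np.ndarray:
    """Radius-capped multiplicatively weighted Voronoi labeling (1-based)."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
    voxels = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    tree = cKDTree(seeds)
    k = min(8, len(seeds))
    dist, idx = tree.query(voxels, k=k, workers=-1)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    score = dist / radii[idx]
    best = np.argmin(score, axis=1)
    rows = np.arange(len(voxels))
    labels = idx[rows, best] + 1
    labels[score[rows, best] > reach] = 0
    return labels.reshape(shape).astype(np.int32)


def _carve_membrane(labels: np.ndarray) -> np.ndarray:
    """Two-voxel membrane wall between adjacent labels (one voxel per side).

    At the simulator's 1/3 µm lateral voxel this matches the apparent width
    of a cortical membrane stain and keeps neighboring interiors disconnected
    even under 26-connectivity.
    """
    out = labels.copy()
    wall = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        for direction in (1, -1):
            shifted = np.roll(labels, direction, axis=axis)
            diff = (labels != shifted) & (labels > 0)
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 1) if direction == 1 else slice(-1, None)
            diff[tuple(sl)] = False  # roll wrap-around is not a real neighbor
            wall |= diff
    out[wall] = 0
    return out


def cell_stats(labels: np.ndarray, geometry: VoxelGeometry) -> pd.DataFrame:
    """Per-label voxel count, physical volume, centroid and boundary flag."""
    ids = np.arange(1, labels.max() + 1) if labels.size else np.array([], dtype=int)
    if len(ids) == 0:
        return pd.DataFrame(
            columns=["cell_id", "voxel_count", "volume_um3", "cz", "cy", "cx", "touches_boundary"]
        )
    counts = np.bincount(labels.ravel(), minlength=len(ids) + 1)[1:]
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    centroids = np.array([c if np.all(np.isfinite(c)) else (np.nan,) * 3 for c in centroids])
    border = np.zeros(len(ids) + 1, dtype=bool)
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border[np.unique(face)] = True
    return pd.DataFrame(
        {
            "cell_id": ids,
            "voxel_count": counts,
            "volume_um3": counts * geometry.voxel_volume_um3,
            "cz": centroids[:, 0],
            "cy": centroids[:, 1],
            "cx": centroids[:, 2],
            "touches_boundary": border[1:],
        }
    )


def place_cells(
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    """Pack ``n_cells`` space-filling cells into the volume.

    Cells are radius-capped weighted Voronoi regions of jittered lattice
    seeds, separated by 1-2 voxel membrane walls. Per-cell target volumes are
    drawn from a Gaussian with the configured CV, and seed radii are
    calibrated over a few assignment passes so realized volumes track the
    targets. Populations are assigned by ``spatial_layout``: contiguous
    blocks along the longest lateral axis (default) or uniformly at random.

    Returns ``(labels, cell_table, population_of_cell)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    if config.n_cells == 0:
        labels = np.zeros(config.volume_shape, dtype=np.int32)
        return labels, cell_stats(labels, config.voxel_geometry), pd.Series(dtype=int)

    seeds = _lattice_seeds(config, rng)
    m = config.mean_cell_volume_voxels
    targets = np.clip(
        rng.normal(m, config.cell_volume_cv * m, size=config.n_cells), 0.2 * m, 3.0 * m
    )
    radii = (3.0 * targets / (4.0 * np.pi)) ** (1.0 / 3.0)
    labels = np.zeros(config.volume_shape, dtype=np.int32)
    for _ in range(3):
        labels = _carve_membrane(_assign_voxels(config.volume_shape, seeds, radii))
        realized = np.bincount(labels.ravel(), minlength=config.n_cells + 1)[1:].astype(float)
        if np.all(realized > 0):
            radii = radii * np.clip((targets / realized) ** (1.0 / 3.0), 0.8, 1.25)
    table = cell_stats(labels, config.voxel_geometry)
    if (table["voxel_count"] == 0).any():
        raise PackingError("a placed cell ended up with zero voxels; volume too tight")

    if config.spatial_layout == "random":
        pops = rng.integers(0, config.n_populations, size=config.n_cells)
    else:  # contiguous blocks along x
        order = np.argsort(seeds[:, 2], kind="stable")
        pops = np.empty(config.n_cells, dtype=int)
        splits = np.array_split(order, config.n_populations)
        for p, block in enumerate(splits):
            pops[block] = p
    population_of_cell = pd.Series(pops, index=table["cell_id"].to_numpy(), name="population")
    return labels, table, population_of_cell


def sample_expression(
    config: SimulationConfig,
    population_of_cell: pd.Series,
    cell_volumes: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-cell transcript counts.

    Counts are negative-binomial with mean ``population mean × v_c / v̄``
    (larger cells hold proportionally more transcripts) and dispersion
    ``count_dispersion``; ``count_dispersion=None`` is the Poisson limit.
    Genes listed in ``module_genes`` additionally share a per-cell lognormal
    factor, planting a correlated synexpression module.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 23])
    )
    means = config.resolved_mean_counts()
    pops = population_of_cell.to_numpy()
    vols = np.asarray(cell_volumes, dtype=float)
    n_cells = len(pops)
    if n_cells == 0:
        return pd.DataFrame(np.zeros((0, config.n_genes), dtype=int))
    scale = vols / vols.mean() if vols.mean() > 0 else np.ones_like(vols)
    mu = means[pops] * scale[:, None]  # (cells, genes)
    module = [g for g in config.module_genes if g < config.n_genes]
    if module and config.module_factor_sd > 0:
        factor = rng.lognormal(
            mean=-0.5 * config.module_factor_sd**2, sigma=config.module_factor_sd, size=n_cells
        )
        mu[:, module] *= factor[:, None]
    theta = config.count_dispersion
    if theta is None or not np.isfinite(theta):
        counts = rng.poisson(mu)
    else:
        lam = np.where(mu > 0, rng.gamma(theta, np.maximum(mu, 1e-300) / theta), 0.0)
        counts = rng.poisson(lam)
    genes = Codebook.default(config.rounds, config.channels_per_round).genes[: config.n_genes]
    return pd.DataFrame(counts, index=population_of_cell.index, columns=genes)


def _sample_positions_in_cell(
    labels: np.ndarray, cell_voxels: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    pick = rng.integers(0, len(cell_voxels), size=n)
    return cell_voxels[pick] + rng.uniform(-0.5, 0.5, size=(n, 3))


def _draw_shifts(config: SimulationConfig, rng: np.random.Generator) -> dict[int, tuple[float, float, float]]:
    shifts = {0: (0.0, 0.0, 0.0)}
    for r in range(1, config.rounds + 1):  # +1: an extra repeat-QC round may be rendered
        lateral = rng.uniform(-config.drift_magnitude, config.drift_magnitude, size=2)
        axial = rng.uniform(-config.drift_magnitude / 4, config.drift_magnitude / 4)
        shifts[r] = (float(axial), float(lateral[0]), float(lateral[1]))
    return shifts


def simulate_scene(config: SimulationConfig) -> GroundTruth:
    """Build the full ground truth for one scene (no image rendering yet)."""
    labels, cell_table, population_of_cell = place_cells(config)
    expression = sample_expression(
        config, population_of_cell, cell_table["voxel_count"].to_numpy()
    )
    codebook = Codebook.default(config.rounds, config.channels_per_round)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    shifts = _draw_shifts(config, rng)

    voxels_of_cell = {
        cid: np.argwhere(labels == cid) for cid in cell_table["cell_id"].to_numpy()
    }
    records: list[pd.DataFrame] = []
    for gene in expression.columns:
        rnd, ch = codebook.location(gene)
        counts = expression[gene]
        total = int(counts.sum())
        pos_blocks, cell_ids = [], []
        for cid, c in counts.items():
            c = int(c)
            if c == 0:
                continue
            pos_blocks.append(_sample_positions_in_cell(labels, voxels_of_cell[cid], c, rng))
            cell_ids.extend([cid] * c)
        pos = np.concatenate(pos_blocks, axis=0) if pos_blocks else np.zeros((0, 3))
        n_bg = 0
        f = config.background_dot_fraction
        if f > 0:
            n_bg = rng.binomial(max(total, 1), f / (1 - f)) if total > 0 else 0
        bg_pos = rng.uniform(0, 1, size=(n_bg, 3)) * np.asarray(labels.shape)
        intensity = rng.lognormal(
            np.log(config.true_intensity_mean), config.intensity_log_sd, size=total
        )
        bg_intensity = rng.lognormal(
            np.log(config.true_intensity_mean * config.background_intensity_factor),
            config.intensity_log_sd,
            size=n_bg,
        )
        all_pos = np.concatenate([pos, bg_pos], axis=0)
        records.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "round": rnd,
                    "channel": ch,
                    "z": all_pos[:, 0],
                    "y": all_pos[:, 1],
                    "x": all_pos[:, 2],
                    "intensity": np.concatenate([intensity, bg_intensity]),
                    "cell_id": cell_ids + [0] * n_bg,
                    "is_background": [False] * total + [True] * n_bg,
                }
            )
        )
    spots = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(
            columns=["gene", "round", "channel", "z", "y", "x", "intensity", "cell_id", "is_background"]
        )
    )
    return GroundTruth(
        config=config,
        labels=labels,
        cell_table=cell_table,
        population_of_cell=population_of_cell,
        true_expression=expression,
        spots=spots,
        per_round_shift=shifts,
        codebook=codebook,
    )


def _stamp_gaussians(
    shape: tuple[int, int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma: tuple[float, float, float],
) -> np.ndarray:
    """Render point emitters as anisotropic Gaussians (additive, float32)."""
    img = np.zeros(shape, dtype=np.float32)
    if len(positions) == 0:
        return img
    half = np.ceil(4.0 * np.asarray(sigma)).astype(int)
    axes = [np.arange(-h, h + 1) for h in half]
    for (z, y, x), a in zip(positions, amplitudes):
        c = np.array([z, y, x])
        lo = np.floor(c).astype(int) - half
        hi = lo + 2 * half + 1
        if np.any(hi <= 0) or np.any(lo >= shape):
            continue
        prof = [
            np.exp(-0.5 * ((ax + np.floor(ci) - ci) / s) ** 2)
            for ax, ci, s in zip(axes, c, sigma)
        ]
        kernel = a * prof[0][:, None, None] * prof[1][None, :, None] * prof[2][None, None, :]
        dst, src = [], []
        for l, h_stop, s in zip(lo, hi, shape):
            d0, d1 = max(0, l), min(s, h_stop)
            dst.append(slice(d0, d1))
            src.append(slice(d0 - l, d1 - l))
        img[tuple(dst)] += kernel[tuple(src)].astype(np.float32)
    return img


def render_round(
    truth: GroundTruth,
    round_index: int,
    repeat_of: int | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render one hybridization round as per-channel 3D stacks.

    The round's genes (or, for a repeat-QC round, the genes of ``repeat_of``)
    are drawn from the ground-truth spot list; for rounds after the first each
    spot survives with ``recapture_probability``, modeling rehybridization
    loss. Surviving spots are shifted by the round's rigid drift, rendered as
    anisotropic Gaussian dots, and Gaussian read noise is added.

    Returns ``(stacks, rendered_spots)`` where ``rendered_spots`` carries the
    post-drift positions actually drawn into the images.
    """
    config = truth.config
    gene_round = repeat_of if repeat_of is not None else round_index
    if gene_round >= config.rounds:
        raise ValueError(f"round_index {gene_round} out of range (rounds={config.rounds})")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53, round_index]))
    shift = np.asarray(truth.per_round_shift.get(round_index, (0.0, 0.0, 0.0)))
    sigma = config.psf_sigma_voxels()
    shape = config.volume_shape

    round_spots = truth.spots[truth.spots["round"] == gene_round]
    stacks: list[np.ndarray] = []
    rendered: list[pd.DataFrame] = []
    sub = truth.codebook.genes_in_round(gene_round)
    for ch in range(config.channels_per_round):
        genes = sub.loc[sub["channel"] == ch, "gene"].tolist()
        ch_spots = round_spots[round_spots["gene"].isin(genes)].reset_index(drop=True)
        if round_index > 0 and config.recapture_probability < 1 and len(ch_spots):
            keep = rng.uniform(size=len(ch_spots)) < config.recapture_probability
            ch_spots = ch_spots[keep].reset_index(drop=True)
        pos = ch_spots[["z", "y", "x"]].to_numpy(dtype=float) + shift
        img = _stamp_gaussians(shape, pos, ch_spots["intensity"].to_numpy(dtype=float), sigma)
        if config.noise_sd > 0:
            img += rng.normal(0, config.noise_sd, size=shape).astype(np.float32)
        stacks.append(img)
        out = ch_spots.copy()
        out[["z", "y", "x"]] = pos
        out["round"] = round_index
        rendered.append(out)
    spot_table = (
        pd.concat(rendered, ignore_index=True) if rendered else round_spots.iloc[0:0].copy()
    )
    return stacks, spot_table


def render_membrane(truth: GroundTruth, round_index: int = 0) -> np.ndarray:
    """Membrane-stain stack: bright 1-2 voxel walls between cells, plus noise.

    Rendered for every round (the stain is re-imaged each time) so it can
    serve as the morphological reference for round-to-round registration.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71, round_index]))
    tissue = ndimage.binary_dilation(truth.labels > 0, iterations=2)
    wall = tissue & (truth.labels == 0)
    base = (
        wall.astype(np.float32) * config.membrane_intensity
        + (truth.labels > 0).astype(np.float32) * config.autofluorescence_intensity
    )
    img = ndimage.gaussian_filter(base, sigma=0.7)
    shift = truth.per_round_shift.get(round_index, (0.0, 0.0, 0.0))
    if any(s != 0 for s in shift):
        img = ndimage.shift(img, shift, order=1, mode="constant", cval=0.0)
    if config.noise_sd > 0:
        img = img + rng.normal(0, config.noise_sd / 2, size=img.shape).astype(np.float32)
    return img


def zero_fraction(labels: np.ndarray) -> float:
    """Fraction of membrane/background (zero-labeled) voxels."""
    return float(np.mean(labels == 0))
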