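"""Shared fixtures: small simulated scenes reused across test modules.

Scenes are deliberately smaller than the study-scale default (fewer cells,
genes and rounds in a smaller volume) so the whole suite stays fast; they
keep the same voxel geometry and statistical structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sga.quantify import volume_normalize, zscore_per_sample
from sga.simulate import SimulationConfig, simulate_scene, sample_expression


SMALL_SCENE = dict(
    n_cells=40,
    n_populations=2,
    n_genes=6,
    rounds=2,
    channels_per_round=3,
    volume_shape=(24, 192, 192),
    seed=3,
)


@pytest.fixture(scope="session")
def study_scale_placements():
    """Cell placements for two seeds of the full 250-cell default scene."""
    from sga.simulate import place_cells

    out = {}
    for seed in (1, 2):
        labels, table, _ = place_cells(SimulationConfig(seed=seed))
        out[seed] = (labels, table)
    return out


@pytest.fixture(scope="session")
def small_truth():
    """A 40-cell, 2-population, 6-gene scene with full ground truth."""
    return simulate_scene(SimulationConfig(**SMALL_SCENE))


@pytest.fixture(scope="session")
def pop5_zscore():
    """Study-scale expression matrix (250 cells, 5 populations, 35 genes).

    Built at the matrix level (no image rendering): per-cell volumes are
    drawn directly and counts sampled from the population model, then volume-
    normalized and z-scored — the layer the clustering operates on.
    Returns ``(zscore DataFrame, population Series)``.
    """
    cfg = SimulationConfig(seed=5)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    pops = pd.Series(
        np.repeat(np.arange(cfg.n_populations), cfg.n_cells // cfg.n_populations),
        index=pd.RangeIndex(1, cfg.n_cells + 1),
        name="population",
    )
    volumes = rng.normal(
        cfg.mean_cell_volume_voxels, cfg.cell_volume_cv * cfg.mean_cell_volume_voxels,
        size=cfg.n_cells,
    ).clip(min=1.0)
    counts = sample_expression(cfg, pops, volumes)
    vol_um3 = pd.Series(volumes * cfg.voxel_geometry.voxel_volume_um3, index=counts.index)
    density = volume_normalize(counts, vol_um3)
    zscore = zscore_per_sample(density, pd.Series("s0", index=counts.index))
    return zscore, pops


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on a compact scene, shared by downstream tests."""
    from sga.pipeline import RunConfig, run

    cfg = RunConfig(
        out_dir=str(tmp_path_factory.mktemp("run") / "out"),
        seed=11,
        simulation=SimulationConfig(**{**SMALL_SCENE, "seed": 11, "recapture_probability": 0.9}),
        k_range=(2, 6),
    )
    out = run(cfg)
    return cfg, out
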