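"""Self-contained QC benchmark scenarios.

Each function simulates one of the pipeline's control experiments under
stated conditions and reports the statistic the control is judged on:

* two-channel colocalization of a split probe set,
* first-round dot recovery after the full rehybridization routine,
* the weakest-intensity background-dot filter's excluded fraction,
* the Gaussian cell-size filter's excluded fraction.

They are used both by the test suite and by the reproduction script; on an
intact sample the two rate statistics are expected to exceed 80% and the two
excluded fractions to stay below 5%.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .register import apply_shift_to_spots, estimate_translation, match_spots, recovery_rate
from .segment import filter_cells_by_volume
from .simulate import SimulationConfig, render_membrane, render_round, simulate_scene
from .spots import filter_spot_intensities


def _spot_frame(pos: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"z": pos[:, 0], "y": pos[:, 1], "x": pos[:, 2], "gene": "", "kept": True}
    )


def colocalization_qc(
    seed: int,
    n_spots: int = 2000,
    detection_probability: float = 0.92,
    jitter_rms: float = 0.3,
    radius: float = 1.0,
    volume_shape: tuple[int, int, int] = (24, 256, 256),
) -> float:
    """Two-channel colocalization rate on a simulated split probe set.

    One set of true dot positions is imaged twice (every other probe carries
    a different amplifier, read on two channels); each channel detects each
    dot independently with ``detection_probability`` and localizes it with an
    isotropic Gaussian error of ``jitter_rms`` voxels RMS displacement
    magnitude. Channels are matched one-to-one within ``radius`` and the
    matched fraction of channel-1 dots is returned.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4001]))
    margin = 2.0
    span = np.asarray(volume_shape) - 2 * margin
    truth = rng.uniform(0, 1, size=(n_spots, 3)) * span + margin
    sigma = jitter_rms / np.sqrt(3.0)  # per-axis sigma giving the stated RMS magnitude

    def observe() -> np.ndarray:
        kept = rng.uniform(size=n_spots) < detection_probability
        return truth[kept] + rng.normal(0, sigma, size=(int(kept.sum()), 3))

    a, b = observe(), observe()
    return match_spots(_spot_frame(a), _spot_frame(b), radius=radius).rate_a


def recovery_qc(
    seed: int,
    recapture_probability: float = 0.9,
    drift: tuple[float, float, float] = (3.2, -2.6, 0.4),
    radius: float = 1.0,
    min_spots: int = 1500,
) -> tuple[float, int]:
    """End-to-end rehybridization recovery under recapture loss and drift.

    A first hybridization round is rendered, then re-rendered at the end of
    the experiment with per-spot ``recapture_probability`` and a rigid
    ``drift``. The repeat round is registered back to the first from the
    membrane reference channel, its dots are shifted into the reference
    frame, and the matched fraction of first-round dots is returned along
    with the number of first-round dots.
    """
    # marker-heavy first round so the scene clears `min_spots`
    mean_counts = np.full((2, 6), 14.0)
    config = SimulationConfig(
        n_cells=60,
        n_populations=2,
        n_genes=6,
        rounds=2,
        channels_per_round=3,
        volume_shape=(24, 256, 256),
        mean_counts=mean_counts,
        recapture_probability=recapture_probability,
        background_dot_fraction=0.0,
        seed=seed,
    )
    truth = simulate_scene(config)
    repeat_index = config.rounds  # extra QC round after the routine
    truth.per_round_shift[repeat_index] = tuple(float(d) for d in drift)
    _, first = render_round(truth, 0)
    if len(first) < min_spots:
        raise RuntimeError(f"scene produced only {len(first)} first-round dots")
    _, repeat = render_round(truth, repeat_index, repeat_of=0)
    reference = render_membrane(truth, 0)
    moving = render_membrane(truth, repeat_index)
    shift = estimate_translation(reference, moving, round_index=repeat_index)
    repeat_aligned = apply_shift_to_spots(repeat, shift, config.volume_shape)
    rate = recovery_rate(
        first, repeat_aligned, radius=radius, z_aspect=config.voxel_geometry.z_aspect
    )
    return rate, len(first)


def intensity_filter_qc(
    seed: int,
    n_dots: int = 1000,
    background_fraction: float = 0.04,
    true_mean: float = 1000.0,
    true_sd: float = 100.0,
    background_mean: float = 300.0,
    background_sd: float = 50.0,
) -> float:
    """Excluded fraction of the weakest-intensity filter on a dot mixture.

    ``1 − background_fraction`` of the dots are true single-molecule signals
    (Gaussian intensity around ``true_mean``); the rest are dim nonspecific
    dots. Returns the overall excluded fraction after the robust one-sided
    log-intensity cut.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4003]))
    n_bg = int(round(n_dots * background_fraction))
    intensities = np.concatenate(
        [
            rng.normal(true_mean, true_sd, size=n_dots - n_bg),
            rng.normal(background_mean, background_sd, size=n_bg),
        ]
    )
    intensities = np.clip(intensities, 1.0, None)
    table = pd.DataFrame(
        {
            "round": 0,
            "channel": 0,
            "gene": "",
            "z": 0.0,
            "y": 0.0,
            "x": 0.0,
            "intensity": intensities,
            "kept": True,
            "cell_id": 0,
        }
    )
    _, excluded = filter_spot_intensities(table)
    return excluded


def volume_filter_qc(
    seed: int,
    n_cells: int = 300,
    mean_volume_um3: float = 500.0,
    cv: float = 0.2,
) -> float:
    """Excluded fraction of the Gaussian cell-size filter on outlier-free cells."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4004]))
    volumes = rng.normal(mean_volume_um3, cv * mean_volume_um3, size=n_cells)
    volumes = np.clip(volumes, 1.0, None)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "volume_um3": volumes,
            "kept": True,
        }
    )
    _, excluded = filter_cells_by_volume(table)
    return excluded
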