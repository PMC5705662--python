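"""Register a drifted repeat round and compute the two dot-level QC rates.

A first hybridization round is repeated at the end of the experiment with
90% per-spot recapture and a rigid drift; the example estimates the drift
from the membrane channel, shifts the repeat-round dots into the reference
frame and reports the recovery rate, plus a two-channel colocalization run.
"""

from sga import SimulationConfig, simulate_scene
from sga.qc_scenarios import colocalization_qc
from sga.register import apply_shift_to_spots, estimate_translation, recovery_rate
from sga.simulate import render_membrane, render_round

config = SimulationConfig(
    n_cells=60, n_populations=2, n_genes=6, rounds=2, channels_per_round=3,
    volume_shape=(24, 224, 224), recapture_probability=0.9, seed=13,
)
truth = simulate_scene(config)
repeat_index = config.rounds
truth.per_round_shift[repeat_index] = (0.6, 3.1, -2.4)

_, first = render_round(truth, 0)
_, repeat = render_round(truth, repeat_index, repeat_of=0)
shift = estimate_translation(
    render_membrane(truth, 0), render_membrane(truth, repeat_index)
)
print(f"estimated drift (dz,dy,dx): ({shift.dz:.2f}, {shift.dy:.2f}, {shift.dx:.2f}), "
      f"score {shift.score:.2f}")

aligned = apply_shift_to_spots(repeat, shift, config.volume_shape)
rate = recovery_rate(first, aligned, radius=1.0, z_aspect=config.voxel_geometry.z_aspect)
print(f"rehybridization recovery:   {rate:.1%} of {len(first)} first-round dots")

coloc = colocalization_qc(seed=13)
print(f"two-channel colocalization: {coloc:.1%}")

# Both rates sit near their generative values (90% recapture, 0.92^2-ish
# joint detection) and comfortably above the 80% RNA-integrity bar.
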