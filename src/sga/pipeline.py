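"""End-to-end orchestration: simulate → detect → segment → register → quantify → cluster.

One :class:`RunConfig` drives a full reproducible run into an output
directory; every stage writes its artifacts (TIFF stacks, CSV tables, JSON
metadata) and a final ``qc_report.json`` aggregates the control statistics a
bench scientist checks first: per-round spot counts, excluded fractions,
registration shifts and scores, rehybridization recovery, the unassigned-dot
fraction, cells kept, cluster sizes and PCA variance explained.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cluster import cluster_cells, cluster_genes, pca_biplot, spatial_map
from .geometry import VoxelGeometry
from .quantify import assign_spots_to_cells, build_expression_matrix
from .register import apply_shift_to_spots, estimate_translation, recovery_rate
from .segment import (
    cell_table_from_labels,
    extract_features,
    filter_cells_by_volume,
    predict_interior,
    seeds_from_probability,
    train_pixel_classifier,
    watershed_3d,
)
from .simulate import GroundTruth, SimulationConfig, render_membrane, render_round, simulate_scene
from .spots import detect_spots, filter_spot_intensities

logger = logging.getLogger("sga")

ALL_STAGES = ("simulate", "spots", "segment", "register", "quantify", "cluster")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    out_dir: str = "sga_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # spots
    detection_floor: float = 5.0
    intensity_z_cut: float = -3.0
    # segment
    feature_scales: tuple[float, ...] = (1.0, 2.0, 4.0)
    annotation_fraction: float = 0.01
    seed_threshold: float = 0.5
    min_seed_voxels: int | None = None  # None → 30 µm³ at the scene's voxel volume
    barrier_probability: float = 0.2
    n_trees: int = 100
    volume_z_cut: float = 3.0
    # register
    max_drift: float = 10.0
    match_radius: float = 1.0
    run_recovery_qc: bool = True
    # cluster
    n_cell_clusters: int | None = None  # None → silhouette selection
    n_gene_clusters: int | None = None
    k_range: tuple[int, int] = (2, 10)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)} (valid: {ALL_STAGES})")

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"]["voxel_geometry"] = dataclasses.asdict(
            self.simulation.voxel_geometry
        )
        Path(path).write_text(yaml.safe_dump(_plain(payload), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = raw.pop("simulation", {})
        geom_raw = sim_raw.pop("voxel_geometry", None)
        if geom_raw is not None:
            sim_raw["voxel_geometry"] = VoxelGeometry(**geom_raw)
        for key in ("volume_shape", "psf_sigma_um", "module_genes", "edge_margin"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        if "mean_counts" in sim_raw and sim_raw["mean_counts"] is not None:
            sim_raw["mean_counts"] = np.asarray(sim_raw["mean_counts"], dtype=float)
        sim = SimulationConfig(**sim_raw)
        for key in ("stages", "feature_scales", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _plain(obj):
    """Recursively convert numpy / tuples for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained in the run dir."""


def run(config: RunConfig) -> Path:
    """Execute the configured stages into ``config.out_dir``; returns the dir.

    Every random operation derives its stream from the run seed through a
    fixed per-stage counter, so disabling one stage never shifts another
    stage's randomness, and identical configs give byte-identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    qc: dict = {"seed": config.seed}
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.time()
            try:
                _STAGE_FUNCS[stage](config, out, state, qc)
            except Exception as exc:  # noqa: BLE001 - name the failing stage
                raise StageError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
        sio.write_json(out / "qc_report.json", qc)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _stage_simulate(config: RunConfig, out: Path, state: dict, qc: dict) -> None:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    truth = simulate_scene(sim)
    state["truth"] = truth
    sio.write_labels(out / "true_labels.tif", truth.labels)
    truth.cell_table.assign(population=truth.population_of_cell.to_numpy()).to_csv(
        out / "true_cells.csv", index=False
    )
    truth.spots.to_csv(out / "true_spots.csv", index=False)
    truth.true_expression.to_csv(out / "true_expression.csv")
    truth.codebook.write_csv(out / "codebook.csv")
    sio.write_json(
        out / "true_shifts.json", {str(r): list(s) for r, s in truth.per_round_shift.items()}
    )
    qc["simulate"] = {
        "n_cells": int(len(truth.cell_table)),
        "n_true_spots": int((~truth.spots["is_background"]).sum()),
        "n_background_spots": int(truth.spots["is_background"].sum()),
        "zero_voxel_fraction": float(np.mean(truth.labels == 0)),
    }


def _require(state: dict, key: str, producer: str):
    if key not in state:
        raise StageError(f"missing upstream output {key!r}; enable the {producer!r} stage")
    return state[key]


def _stage_spots(config: RunConfig, out: Path, state: dict, qc: dict) -> None:
    truth: GroundTruth = _require(state, "truth", "simulate")
    sim = truth.config
    sigma = sim.psf_sigma_voxels()
    detected = []
    counts_per_round_channel = {}
    for r in range(sim.rounds):
        stacks, rendered = render_round(truth, r)
        state.setdefault("rendered_spots", {})[r] = rendered
        for ch, stack in enumerate(stacks):
            sub = truth.codebook.genes_in_round(r)
            genes = sub.loc[sub["channel"] == ch, "gene"].tolist()
            gene = genes[0] if genes else ""
            table = detect_spots(
                stack, sigma, floor=config.detection_floor, round_index=r, channel=ch, gene=gene
            )
            counts_per_round_channel[f"r{r}c{ch}"] = int(len(table))
            detected.append(table)
    spots = pd.concat(detected, ignore_index=True)
    spots, excluded = filter_spot_intensities(spots, z_cut=config.intensity_z_cut)
    state["spots"] = spots
    sio.write_spot_table(out / "spots.csv", spots)
    qc["spots"] = {
        "detections_per_round_channel": counts_per_round_channel,
        "n_detected": int(len(spots)),
        "excluded_fraction": excluded,
    }


def _stage_segment(config: RunConfig, out: Path, state: dict, qc: dict) -> None:
    truth: GroundTruth = _require(state, "truth", "simulate")
    membrane = render_membrane(truth, round_index=0)
    state["membrane_0"] = membrane
    sio.write_stack(out / "membrane_r0.tif", membrane)
    feats = extract_features(membrane, config.feature_scales)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    sparse = np.full(truth.labels.shape, -1, dtype=np.int8)
    pick = rng.random(truth.labels.shape) < config.annotation_fraction
    sparse[pick] = (truth.labels[pick] > 0).astype(np.int8)
    clf = train_pixel_classifier(feats, sparse, n_trees=config.n_trees, seed=config.seed)
    prob = predict_interior(clf, feats)
    min_seed = config.min_seed_voxels
    if min_seed is None:
        min_seed = int(round(30.0 / truth.config.voxel_geometry.voxel_volume_um3))
    seeds = seeds_from_probability(prob, config.seed_threshold, min_seed)
    labels = watershed_3d(1.0 - prob, seeds, barrier_mask=prob < config.barrier_probability)
    table = cell_table_from_labels(labels, truth.config.voxel_geometry)
    table, excluded = filter_cells_by_volume(table, z_cut=config.volume_z_cut)
    state["labels"] = labels
    state["cell_table"] = table
    sio.write_labels(out / "labels.tif", labels)
    sio.write_cell_table(out / "cells.csv", table)
    qc["segment"] = {
        "oob_accuracy": float(clf.oob_score_),
        "n_cells": int(len(table)),
        "n_cells_kept": int(table["kept"].sum()),
        "excluded_fraction": excluded,
    }


def _stage_register(config: RunConfig, out: Path, state: dict, qc: dict) -> None:
    truth: GroundTruth = _require(state, "truth", "simulate")
    spots: pd.DataFrame = _require(state, "spots", "spots")
    sim = truth.config
    reference = state.get("membrane_0")
    if reference is None:
        reference = render_membrane(truth, round_index=0)
        state["membrane_0"] = reference
    shifts_out = {}
    aligned = [spots[spots["round"] == 0]]
    z_aspect = sim.voxel_geometry.z_aspect
    for r in range(1, sim.rounds):
        moving = render_membrane(truth, round_index=r)
        shift = estimate_translation(reference, moving, max_drift=config.max_drift, round_index=r)
        shifts_out[str(r)] = {"shift": [shift.dz, shift.dy, shift.dx], "score": shift.score}
        aligned.append(
            apply_shift_to_spots(spots[spots["round"] == r], shift, sim.volume_shape)
        )
    registered = pd.concat(aligned, ignore_index=True)
    state["spots"] = registered
    sio.write_spot_table(out / "spots_registered.csv", registered)
    qc["register"] = {"shifts": shifts_out}
    if config.run_recovery_qc:
        repeat_index = sim.rounds  # extra repeat of round 0 at the end of the experiment
        _, repeat_spots = render_round(truth, repeat_index, repeat_of=0)
        moving = render_membrane(truth, round_index=repeat_index)
        shift = estimate_translation(
            reference, moving, max_drift=config.max_drift, round_index=repeat_index
        )
        repeat_aligned = apply_shift_to_spots(repeat_spots, shift, sim.volume_shape)
        first = state["rendered_spots"][0] if "rendered_spots" in state else spots[spots["round"] == 0]
        rate = recovery_rate(
            first, repeat_aligned, radius=config.match_radius, z_aspect=z_aspect
        )
        qc["register"]["recovery_rate"] = float(rate)


def _stage_quantify(config: RunConfig, out: Path, state: dict, qc: dict) -> None:
    truth: GroundTruth = _require(state, "truth", "simulate")
    spots = _require(state, "spots", "spots")
    cell_table = _require(state, "cell_table", "segment")
    labels = _require(state, "labels", "segment")
    assigned, unassigned = assign_spots_to_cells(spots, labels)
    matrix = build_expression_matrix(
        assigned,
        cell_table,
        genes=list(truth.true_expression.columns),
        sample_id=f"sample{config.seed}",
        gene_meta=truth.codebook.table.set_index("gene"),
    )
    state["matrix"] = matrix
    matrix.counts.to_csv(out / "counts.csv")
    matrix.density.to_csv(out / "density.csv")
    matrix.zscore.to_csv(out / "zscore.csv")
    matrix.cell_meta.to_csv(out / "cell_meta.csv")
    qc["quantify"] = {
        "unassigned_fraction": unassigned,
        "matrix_total": int(matrix.counts.to_numpy().sum()),
        "n_cells": matrix.n_cells,
    }


def _stage_cluster(config: RunConfig, out: Path, state: dict, qc: dict) -> None:
    matrix = _require(state, "matrix", "quantify")
    k_range = range(config.k_range[0], config.k_range[1] + 1)
    cells = cluster_cells(matrix.zscore, k=config.n_cell_clusters, k_range=k_range)
    genes = cluster_genes(matrix.zscore, k=config.n_gene_clusters, k_range=k_range)
    pca = pca_biplot(matrix.zscore)
    smap = spatial_map(cells, matrix.cell_meta)
    cells.assignment.rename("cluster").to_csv(out / "cell_clusters.csv")
    genes.assignment.rename("cluster").to_csv(out / "gene_clusters.csv")
    pd.DataFrame(cells.linkage_matrix, columns=["child_a", "child_b", "height", "size"]).to_csv(
        out / "cell_linkage.csv", index=False
    )
    smap.to_csv(out / "spatial_map.csv")
    pca.scores.iloc[:, :10].to_csv(out / "pca_scores.csv")
    pca.loadings.iloc[:, :10].to_csv(out / "pca_loadings.csv")
    pd.Series(pca.variance_explained, name="variance_explained").to_csv(
        out / "pca_variance.csv", index_label="component"
    )
    qc["cluster"] = {
        "n_cell_clusters": cells.k,
        "cell_cluster_sizes": cells.assignment.value_counts().sort_index().tolist(),
        "n_gene_clusters": genes.k,
        "pca_variance_explained_first2": float(pca.variance_explained[:2].sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "spots": _stage_spots,
    "segment": _stage_segment,
    "register": _stage_register,
    "quantify": _stage_quantify,
    "cluster": _stage_cluster,
}


def qc_report(run_dir: str | Path) -> dict:
    """Re-read a run directory's ``qc_report.json`` (validating it exists)."""
    path = Path(run_dir) / "qc_report.json"
    if not path.exists():
        missing = [
            name
            for name in ("config.yaml", "qc_report.json")
            if not (Path(run_dir) / name).exists()
        ]
        raise FileNotFoundError(f"run dir {run_dir} is missing outputs: {missing}")
    return sio.read_json(path)
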