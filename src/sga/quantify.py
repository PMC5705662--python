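"""Per-cell transcript quantification: counts → density → z-scores → pooling.

Kept dots are assigned to segmented cells by the label under their voxel,
counted into a cells × genes matrix, divided by each cell's volume (partial
cells in a physical section hold proportionally fewer transcripts), z-scored
per gene *within each sample* to absorb embryo-to-embryo level differences,
and only then pooled across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Cells × genes expression with three layers and per-axis metadata.

    Layers: ``counts`` (integer transcript counts), ``density`` (counts per
    µm³ of cell volume), ``zscore`` (per-sample per-gene standardized
    density). Rows are indexed by a unique cell key; ``cell_meta`` carries
    sample_id, centroid, volume and (after clustering) cluster labels;
    ``gene_meta`` carries round/channel/functional class.
    """

    counts: pd.DataFrame
    density: pd.DataFrame
    zscore: pd.DataFrame
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    def to_anndata(self):
        """Optional AnnData export (imported lazily)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.zscore.to_numpy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.reindex(self.genes).copy(),
            layers={"counts": self.counts.to_numpy(), "density": self.density.to_numpy()},
        )
        adata.obs_names = [str(i) for i in self.counts.index]
        adata.var_names = self.genes
        return adata


def assign_spots_to_cells(spots: pd.DataFrame, label_volume: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Assign each dot the label of the voxel containing it.

    Coordinates are rounded to the nearest voxel; label 0 (membrane or
    outside tissue) and out-of-volume dots stay unassigned (``cell_id=0``).
    Returns the table plus the unassigned fraction among kept dots (a QC
    metric worth logging: high values indicate registration or segmentation
    trouble).
    """
    out = spots.copy()
    coords = np.round(out[["z", "y", "x"]].to_numpy(dtype=float)).astype(int)
    shape = np.asarray(label_volume.shape)
    inside = np.all((coords >= 0) & (coords < shape), axis=1)
    cell_id = np.zeros(len(out), dtype=np.int64)
    cell_id[inside] = label_volume[tuple(coords[inside].T)]
    out["cell_id"] = cell_id
    kept = out["kept"].to_numpy(dtype=bool)
    unassigned = float(np.mean(cell_id[kept] == 0)) if kept.any() else 0.0
    return out, unassigned


def count_matrix(spots: pd.DataFrame, cell_table: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Counts[c, g] = number of kept dots of gene g assigned to kept cell c."""
    unknown = set(spots["gene"].unique()) - set(genes) - {""}
    if unknown:
        raise ValueError(f"spots reference genes not in the panel: {sorted(unknown)}")
    kept_cells = cell_table.loc[cell_table["kept"], "cell_id"].to_numpy()
    counts = pd.DataFrame(0, index=pd.Index(kept_cells, name="cell_id"), columns=genes, dtype=int)
    usable = spots[(spots["kept"]) & (spots["cell_id"].isin(kept_cells))]
    grouped = usable.groupby(["cell_id", "gene"]).size()
    for (cid, gene), n in grouped.items():
        counts.at[cid, gene] = int(n)
    return counts


def volume_normalize(counts: pd.DataFrame, volumes_um3: pd.Series) -> pd.DataFrame:
    """Density layer: counts divided by each cell's volume in µm³."""
    vols = volumes_um3.reindex(counts.index)
    if vols.isna().any():
        missing = counts.index[vols.isna()].tolist()
        raise ValueError(f"no volume for cells {missing[:5]}...")
    if (vols <= 0).any():
        raise ValueError("cell volumes must be positive")
    return counts.div(vols, axis=0)


def zscore_per_sample(density: pd.DataFrame, sample_ids: pd.Series) -> pd.DataFrame:
    """Standardize each gene within each sample: (x − mean) / SD, SD with n−1.

    Genes with zero variance inside a sample are set to 0 there, with a
    diagnostic — a constant gene carries no contrast to standardize.
    """
    sample_ids = sample_ids.reindex(density.index)
    out = density.copy().astype(float)
    for sample, idx in density.groupby(sample_ids).groups.items():
        block = density.loc[idx]
        if len(block) < 2:
            raise ValueError(f"sample {sample!r} has fewer than 2 cells; cannot z-score")
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn(
                f"sample {sample!r}: zero-variance genes set to 0: "
                f"{list(block.columns[degenerate])}",
                stacklevel=2,
            )
        sd = sd.replace(0, np.inf)
        out.loc[idx] = (block - mean) / sd
    return out


def pool_samples(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Row-concatenate per-sample matrices (already z-scored within sample).

    All inputs must share the gene set and order; cell indices are made
    globally unique as ``{sample_id}:{cell_id}``.
    """
    if not matrices:
        raise ValueError("nothing to pool")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            extra = set(m.genes) ^ set(genes)
            raise ValueError(f"gene sets differ between samples: {sorted(extra)}")

    def _rekey(m: ExpressionMatrix, layer: pd.DataFrame) -> pd.DataFrame:
        sample = m.cell_meta["sample_id"].iloc[0] if len(m.cell_meta) else "s"
        renamed = layer.copy()
        renamed.index = [f"{sample}:{i}" for i in layer.index]
        return renamed

    counts = pd.concat([_rekey(m, m.counts) for m in matrices])
    density = pd.concat([_rekey(m, m.density) for m in matrices])
    zscore = pd.concat([_rekey(m, m.zscore) for m in matrices])
    meta = pd.concat([_rekey(m, m.cell_meta) for m in matrices])
    return ExpressionMatrix(
        counts=counts,
        density=density,
        zscore=zscore,
        cell_meta=meta,
        gene_meta=matrices[0].gene_meta,
    )


def build_expression_matrix(
    spots: pd.DataFrame,
    cell_table: pd.DataFrame,
    genes: list[str],
    sample_id: str = "s0",
    gene_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Counts → density → within-sample z-score for one sample."""
    counts = count_matrix(spots, cell_table, genes)
    volumes = cell_table.set_index("cell_id")["volume_um3"]
    density = volume_normalize(counts, volumes)
    sample_ids = pd.Series(sample_id, index=counts.index)
    zscore = zscore_per_sample(density, sample_ids)
    meta = (
        cell_table.set_index("cell_id")
        .loc[counts.index, ["volume_um3", "cz", "cy", "cx", "touches_boundary"]]
        .copy()
    )
    meta["sample_id"] = sample_id
    return ExpressionMatrix(
        counts=counts,
        density=density,
        zscore=zscore,
        cell_meta=meta,
        gene_meta=gene_meta if gene_meta is not None else pd.DataFrame(index=genes),
    )
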