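"""Disk formats: multi-page TIFF stacks, CSV tables, JSON metadata.

Stacks are written as z-paged TIFF (float32 for intensity images, uint16 for
label volumes); tables as plain CSV with stable column order so runs diff
cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spots import SPOT_COLUMNS

CELL_COLUMNS = ["cell_id", "volume_um3", "cz", "cy", "cx", "touches_boundary", "kept"]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; uint16 TIFF cannot hold them")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_spot_table(path: str | Path, table: pd.DataFrame) -> None:
    cols = [c for c in SPOT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cell_table(path: str | Path, table: pd.DataFrame) -> None:
    cols = [c for c in CELL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {record name: sequence}."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
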