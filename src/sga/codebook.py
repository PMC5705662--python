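"""Gene ↔ (round, channel) codebook for sequential hybridization.

In seqFISH-style multiplexing each hybridization round images a handful of
genes on orthogonal fluorescence channels; the codebook records which gene is
read out where, plus a coarse functional class used for downstream annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

# Synthetic 35-gene developmental panel (neural crest / neural tube flavored);
# names are real developmental genes, the panel itself is a simulation default.
_PANEL = [
    # neural crest
    ("FoxD3", "neural_crest"),
    ("Sox9", "neural_crest"),
    ("Snai2", "neural_crest"),
    ("Ets1", "neural_crest"),
    ("TfAP2A", "neural_crest"),
    ("TfAP2B", "neural_crest"),
    ("Axud1", "neural_crest"),
    ("Sox10", "neural_crest"),
    ("Sox8", "neural_crest"),
    ("Sip1", "neural_crest"),
    ("Msx1", "neural_crest"),
    ("Msx2", "neural_crest"),
    ("Pax7", "neural_crest"),
    ("MycC", "neural_crest"),
    # neural
    ("Sox2", "neural"),
    ("Msi1", "neural"),
    ("Pax6", "neural"),
    ("MycN", "neural"),
    ("Fabp7", "neural"),
    ("Sox3", "neural"),
    ("Sox21", "neural"),
    ("Zic1", "neural"),
    # pluripotency
    ("Nanog", "pluripotency"),
    ("PouV", "pluripotency"),
    ("Klf4", "pluripotency"),
    ("Lin28A", "pluripotency"),
    ("Sall4", "pluripotency"),
    # differentiation / lineage
    ("Krt19", "lineage"),
    ("Col2a1", "lineage"),
    ("Mitf", "lineage"),
    ("Plp1", "lineage"),
    ("Tubb3", "lineage"),
    # proliferation / cell death / housekeeping
    ("Ccnd1", "proliferation"),
    ("E2f1", "proliferation"),
    ("Actb", "housekeeping"),
]


@dataclass
class Codebook:
    """Maps each gene to the (round, channel) it is imaged in."""

    table: pd.DataFrame = field(repr=False)  # columns: gene, round, channel, functional_class

    def __post_init__(self) -> None:
        required = {"gene", "round", "channel"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"codebook missing columns: {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            dups = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in codebook: {dups}")
        pairs = list(zip(self.table["round"], self.table["channel"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (round, channel) assignment in codebook")

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def n_rounds(self) -> int:
        return int(self.table["round"].max()) + 1

    @property
    def n_channels(self) -> int:
        return int(self.table["channel"].max()) + 1

    def genes_in_round(self, round_index: int) -> pd.DataFrame:
        """Sub-table (gene, channel) for one hybridization round, channel-ordered."""
        sub = self.table[self.table["round"] == round_index]
        return sub.sort_values("channel").reset_index(drop=True)

    def location(self, gene: str) -> tuple[int, int]:
        row = self.table[self.table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in codebook")
        return int(row["round"].iloc[0]), int(row["channel"].iloc[0])

    @classmethod
    def default(cls, rounds: int = 7, channels_per_round: int = 5) -> "Codebook":
        """The default 35-gene panel laid out row-major over rounds × channels."""
        n = rounds * channels_per_round
        if n > len(_PANEL):
            raise ValueError(f"default panel has {len(_PANEL)} genes; {n} requested")
        rows = [
            {"gene": g, "round": i // channels_per_round, "channel": i % channels_per_round, "functional_class": c}
            for i, (g, c) in enumerate(_PANEL[:n])
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Codebook":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
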