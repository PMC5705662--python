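"""HCR probe design over coding sequences.

Each probe carries an 18-20 nt mRNA-binding sequence — the reverse complement
of a CDS window with GC content in [40%, 60%] — plus a 4-base linker and an
amplifier initiator appended at the 3′ end. Consecutive windows keep at least
5 nt of separation; at most 24 probes are emitted per gene. Window selection
is a deterministic greedy scan (longest window first, earliest start first);
specificity screening against the transcriptome is an external step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DEFAULT_LINKER = "TATA"


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N stays N)."""
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length; N counts in the denominator only."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class Probe:
    start: int  # 0-based on the CDS
    length: int
    binding_seq: str  # reverse complement of the CDS window
    gc: float
    full_seq: str  # binding + linker + initiator


@dataclass
class ProbeSet:
    gene: str
    probes: list[Probe] = field(default_factory=list)
    diagnostic: str = ""

    def __len__(self) -> int:
        return len(self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": self.gene,
                    "start": p.start,
                    "length": p.length,
                    "binding_seq": p.binding_seq,
                    "gc": p.gc,
                    "full_seq": p.full_seq,
                }
                for p in self.probes
            ],
            columns=["gene", "start", "length", "binding_seq", "gc", "full_seq"],
        )


def design_probes(
    cds: str,
    gene: str = "",
    max_probes: int = 24,
    lengths: tuple[int, ...] = (20, 19, 18),
    gc_bounds: tuple[float, float] = (0.40, 0.60),
    min_gap: int = 5,
    linker: str = DEFAULT_LINKER,
    initiator: str = "",
) -> ProbeSet:
    """Greedy left-to-right probe tiling of one coding sequence.

    At each candidate start the longest admissible window is tried first; a
    window is accepted if it is N-free and its GC fraction lies inside
    ``gc_bounds`` (inclusive). After an acceptance the scan jumps past the
    window plus ``min_gap`` bases. Pure function of its inputs — rerunning
    reproduces the same set. Too-short or constraint-violating input yields
    an empty set with a diagnostic, not an error.
    """
    s = cds.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"CDS contains non-ACGTN characters: {sorted(bad)}")
    lengths = tuple(sorted(lengths, reverse=True))
    result = ProbeSet(gene=gene)
    if len(s) < min(lengths):
        result.diagnostic = f"CDS of {len(s)} nt shorter than minimum window {min(lengths)}"
        return result
    lo, hi = gc_bounds
    pos = 0
    while pos <= len(s) - min(lengths) and len(result.probes) < max_probes:
        accepted = False
        for L in lengths:
            if pos + L > len(s):
                continue
            window = s[pos : pos + L]
            if "N" in window:
                continue
            gc = gc_fraction(window)
            if lo <= gc <= hi:
                result.probes.append(
                    Probe(
                        start=pos,
                        length=L,
                        binding_seq=reverse_complement(window),
                        gc=gc,
                        full_seq=reverse_complement(window) + linker + initiator,
                    )
                )
                pos += L + min_gap
                accepted = True
                break
        if not accepted:
            pos += 1
    if not result.probes:
        result.diagnostic = "no window satisfied the GC and alphabet constraints"
    _check_invariants(result, min_gap)
    return result


def _check_invariants(probe_set: ProbeSet, min_gap: int) -> None:
    """Window separation and reverse-complement consistency, asserted on output."""
    prev_end = None
    for p in sorted(probe_set.probes, key=lambda p: p.start):
        if prev_end is not None and p.start - prev_end < min_gap:
            raise AssertionError(
                f"windows closer than min_gap={min_gap}: gap {p.start - prev_end}"
            )
        prev_end = p.start + p.length


def design_probes_for_fasta(
    records: dict[str, str],
    **kwargs,
) -> pd.DataFrame:
    """Design probes for a dict of gene → CDS; returns one concatenated table."""
    frames = [design_probes(seq, gene=name, **kwargs).to_frame() for name, seq in records.items()]
    return (
        pd.concat(frames, ignore_index=True)
        if frames
        else ProbeSet(gene="").to_frame()
    )
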