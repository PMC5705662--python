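"""Design HCR probes for a coding sequence.

Each probe binds an 18-20 nt window of the CDS (reverse complement), with
GC between 40% and 60%, at least 5 nt between windows, and at most 24
probes per gene; a 4-base linker plus the amplifier initiator are appended
at the 3' end.
"""

import numpy as np

from sga.probes import design_probes

rng = np.random.default_rng(2024)
cds = "".join(rng.choice(list("ACGT"), p=[0.28, 0.22, 0.22, 0.28], size=900))

result = design_probes(cds, gene="ExampleGene", initiator="GCATTCTTTCTTGAGGAGGG")
frame = result.to_frame()
print(f"CDS length: {len(cds)} nt -> {len(result)} probes")
print(frame[["start", "length", "gc"]].head(8).to_string(index=False))
gaps = frame["start"].to_numpy()[1:] - (frame["start"] + frame["length"]).to_numpy()[:-1]
print(f"min inter-probe gap: {gaps.min()} nt (constraint: >= 5)")
print(f"GC range: {frame['gc'].min():.2f} - {frame['gc'].max():.2f} (constraint: 0.40-0.60)")

# A ~900 nt CDS typically yields the full 24-probe set; genes where fewer
# windows pass the GC screen end up with fewer probes, which the bench
# protocol tolerates down to about 12.
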