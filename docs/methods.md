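# Methods

This note documents the models behind `sga`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where more than one reasonable option existed.

## The measurement model

Sequential smFISH encodes genes by (hybridization round, channel): each
round hybridizes one probe set per channel, HCR amplification makes every
transcript a diffraction-limited dot, probes are stripped, and the cycle
repeats. Seven rounds × five channels read 35 genes on one section. The
pipeline's job is to (1) count dots per gene, (2) attribute them to cells
segmented from a membrane immunostain, and (3) normalize so that cells of
different size — and partial cells cut by the physical section — are
comparable. All image-space computation uses 0-based (z, y, x) voxel
coordinates; physical µm enter only through `VoxelGeometry`
(lateral = camera pixel / magnification; voxel volume = lateral² × z-step).

## The synthetic scene

The simulator is first-class, tested code: it defines the study conditions
every downstream stage is validated under.

**Geometry.** Cells are radius-capped, multiplicatively weighted Voronoi
regions of jittered-lattice seeds inside an edge margin. Per-cell target
volumes are Gaussian (default mean 9000 voxels ≈ 500 µm³, CV 0.2); seed
radii are recalibrated over three assignment passes so realized volumes
track the targets — this is what makes the generator's configured mean a
contract (realized mean within 5%) rather than an aspiration. Adjacent
labels are separated by a two-voxel membrane wall, matching the apparent
width of a cortical stain at the simulator's 1/3 µm lateral voxel. The
default volume, 28 × 400 × 400 voxels (14 µm section), holds 250 cells in
roughly one cell layer, as a real 12–16 µm cross section does.

**Populations and counts.** Populations (default 5) occupy contiguous
blocks along x. Counts are negative-binomial — mean = population mean ×
v_c/v̄ (bigger cells hold more transcripts), dispersion θ = 20, Poisson as
the θ→∞ limit — with a default mean structure of 7 marker genes per
population at 12 copies/cell, a 2-copy baseline, and one housekeeping gene
at 20 copies everywhere. The first seven genes additionally share a
per-cell lognormal factor (σ = 0.35), planting a correlated synexpression
module that gene-level clustering must recover as one cluster. Copy numbers
are deliberately modest: at the simulator's voxel scale they keep dots
non-overlapping, which is the regime the counting model assumes (real
acquisitions at higher magnification are sparser still).

**Optics and rounds.** Dots render as anisotropic Gaussians (σ = 0.25 µm
lateral, 0.5 µm axial), amplitudes lognormal around 1000 counts over
Gaussian read noise (σ = 100; SNR ≈ 10). A fraction (4%) of dots are
nonspecific background at 0.3× intensity. Each round is rigidly shifted
(uniform up to 3 voxels laterally, a quarter of that axially); rounds after
the first keep each spot with the recapture probability (default 0.98; QC
scenarios use 0.9). The membrane channel adds a dim interior
autofluorescence (180 counts) over a dark outside — exactly the cue the
pixel classifier needs to tell "inside tissue" from "outside", as in real
stained sections.

**What it does not emulate** (and what passing tests therefore do not
show): optical aberrations and depth-dependent PSFs, photobleaching,
autofluorescence spectra and spectral bleed-through, EMCCD noise
statistics, tissue deformation between rounds (drift is translation-only),
cell-shape irregularity beyond weighted Voronoi, and background dots that
persist across rehybridizations at new positions (the simulator reuses the
same background dots per gene). Results on real data depend on these
factors; the simulator validates the pipeline's logic and statistics, not
its robustness to every imaging artifact.

## Stage-by-stage choices

**Detection.** Scale-normalized LoG with the PSF's anisotropic σ; local
maxima in a 3×3×3 neighborhood above a deliberately permissive floor
(5 × robust MAD of the response) — background dots are meant to be culled
statistically later, not at the detection floor. Subvoxel refinement is a
separable 3-point parabolic fit per axis: counting, not nanometer
localization, is the goal, so no Gaussian MLE. Dots merging closer than
~2σ are counted once; the default scene keeps that loss under ~5%.

**Intensity filter.** "Weakest intensity" is formalized as robust z < −3 on
log-intensity per round/channel (median, 1.4826 × MAD). One-sided by
design: bright outliers are real transcripts. Degenerate groups (MAD = 0 or
fewer than 20 dots) are kept wholesale with a diagnostic. The globally
brightest dot is never removed.

**Segmentation.** Features are Gaussian-smoothed intensity, gradient
magnitude and Laplacian at scales (1, 2, 4) voxels, standardized per
volume. The classifier is a 100-tree random forest (√d feature subsampling,
fixed seed, OOB accuracy reported) over a two-class scheme — interior vs
everything else; a three-class scheme (adding membrane) was considered and
rejected as unnecessary given the barrier mask. Seeds are 6-connected
components of p ≥ 0.5 with at least 30 µm³; the watershed runs on 1 − p
with voxels at p < 0.2 held out as membrane/background barrier. Cell-volume
filtering is the same robust-z machinery as the intensity filter, two-sided
at |z| > 3. Manual "intactness" curation is replaced by a
`touches_boundary` flag.

**Registration.** Translation-only, estimated by phase cross-correlation
with upsampled-DFT subvoxel refinement on the membrane channel; re-mounted
sections show negligible rotation at field scale, a documented limitation.
A Pearson score of the aligned overlap gates acceptance (score < 0.2 raises
a low-confidence error — the manual-correction hook). Spots, not images,
are resampled. Matching is greedy globally-nearest-first one-to-one with
ties broken by (distance, index, index); z-distances are multiplied by the
axial/lateral voxel ratio so the radius (default 1.0 voxel) is isotropic in
physical units.

**Quantification.** Dot→cell assignment is the label under the rounded
voxel; no dilation rescue of membrane-adjacent dots by default (a 1-voxel
dilation hook exists but changes counts and is off). The unassigned
fraction is a logged QC metric. z-scores use the n−1 SD so they are
bit-reproducible; zero-variance genes become 0 with a diagnostic. Densities
(counts/µm³), not raw counts, are what get z-scored — the normalization is
explicitly a cell-size correction, and using counts instead would re-import
the size variation just removed.

**Clustering.** Cosine distance with average linkage on both axes. Average
linkage was chosen over complete/Ward because it is the conventional
pairing with cosine dissimilarity and is reproducible without an embedding;
both alternatives remain available. The cluster count is either fixed or
selected by mean silhouette width over k = 2..10 (ties to the smallest k) —
the selection rule is this package's choice, exposed so a fixed k can
override it. PCA is the exact eigendecomposition of the covariance; biplot
scaling divides scores by max |score| and loadings by the max loading norm
so both live in [−1, 1]. KDE uses the Silverman (normal-reference)
bandwidth.

**Probe design.** The constraints (18–20 nt, GC 40–60%, ≥ 5 nt gaps, ≤ 24
probes, reverse complement of the CDS) admit many tilings; the greedy
longest-first earliest-start scan is one deterministic maximizer, and the
emitted probe count is a QC output rather than a guarantee. Initiator
sequences are opaque configurable strings; BLAST specificity screening is
an external step by design.

**Pipeline.** One run seed fans out to every stage through fixed
`SeedSequence([seed, stage-constant])` streams, so toggling one stage never
shifts another's randomness and identical configs give byte-identical
outputs. A stage failure halts the run naming the stage; partial outputs
are kept.

## Numerical details

- Robust scale is always 1.4826 × MAD (consistent for a Gaussian).
- The parabolic-fit offset is clipped to ±0.5 voxel; degenerate curvature
  (|denominator| < 1e-12) yields offset 0.
- Cosine similarities are clipped to [−1, 1] before forming distances; the
  distance matrix is symmetrized to remove float round-off.
- Eigenvector signs are fixed by making each loading's largest-magnitude
  coefficient positive.
- Zero-norm rows/columns make cosine distance undefined and raise with the
  offending names; zero-variance genes are excluded from correlation with a
  warning rather than an error.
- Label volumes are uint16 on disk (≤ 65535 cells per field).

## Test-scene sizes

The test and example suites run on scaled scenes — typically 40 cells, 2
populations, 6 genes over 2 rounds × 3 channels in 24 × 192 × 192 voxels,
with matrix-level (image-free) scenes at the full 250 cells × 35 genes —
chosen so the whole suite completes in about two minutes while preserving
the statistical structure of the study-scale default. The QC benchmark
scenarios (`sga.qc_scenarios`) state their own sizes: 2000 dots for
colocalization, ≥ 1500 first-round dots for recovery, 1000 dots for the
intensity filter, 300 cells for the volume filter.

## Known limitations

- Translation-only registration; no deformable model.
- No dense-spot deconvolution: overlapping dots undercount at high copy
  number (the default scene keeps dots separable; very high expressors
  would need finer sampling).
- The silhouette criterion can merge genuinely hierarchical populations;
  fixed-k override is the escape hatch.
- Per-sample z-scoring removes sample-level biology along with batch level
  differences; that trade-off is inherent to the normalization.
- The random-forest classifier is trained per acquisition from sparse
  annotations; no transfer across staining conditions is attempted.
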