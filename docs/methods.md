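# Methods

This note records the models, parameter choices and numerical conventions
behind `cycliq`, and what the synthetic benchmarks do and do not establish
about real microscopy data.

## Image model and coordinate conventions

All images are 2-D grayscale arrays in (row, col) order, 0-based, origin at
the top-left pixel centre. Intensities are normalised to [0, 1] at load
time using the recorded dtype range (integer images divide by the dtype
maximum; float images are taken as-is), so thresholds such as the 0.2 spot
peak rule have a single meaning everywhere. Ellipse orientations are
radians in [0, π), measured from the +row axis towards the +col axis.

## Synthetic experiment generator

The generator (`cycliq.synth`) emulates a fixed-cell cyclic
immunofluorescence run plus sequential smFISH:

- **Nuclei** are non-overlapping filled ellipses placed by rejection
  sampling with a 2 px clearance (bounded retries, then a hard failure with
  a clear message). Default semi-axes 22–34 px give areas of roughly
  1500–3600 px, inside the detector's [1200, 12000] px envelope; a scenario
  can deliberately choose axes outside it.
- **Reference channel** (nuclear stain): per-cell brightness drawn once
  from U(0.55, 0.9) and held constant across cycles, as for a fixed sample.
- **Marker channels**: per-cell per-marker mean intensities from
  U(0.2, 0.8), rendered inside the nucleus mask. The clean erased image of
  cycle c is the uniform residual background `base + rate·(c−1)`
  (defaults 0.05 + 0.01/cycle, a slight accumulation over cycles); the
  clean stained image adds the marker signal. On noise-free data the
  background-subtracted nucleus mean therefore recovers the true intensity
  exactly, which the tests assert.
- **Drift** is an integer (dy, dx) per cycle, drawn uniformly within
  ±drift_max and applied to every channel of the cycle by zero-filled
  shifting; cycle 1 is (0, 0). Placement keeps nuclei at least
  drift_max + margin from the border so drift never clips a nucleus.
- **Noise** is additive Gaussian (default sd 0.05 of the dynamic range),
  clipped to [0, 1]. The real camera's noise statistics are not modelled;
  the Gaussian is a stand-in sufficient for recovery tests.
- **RNA spots**: per cell per gene counts are Poisson (default mean 3);
  spots are isotropic Gaussian blobs (default σ = 2 px, peak 0.6) on a
  0.05 background. Spots of one gene keep a minimum separation (default
  16 px ≈ 8σ) so neighbouring blobs cannot merge into one connected
  component through noise at the saddle between them; a spot that cannot
  be placed within the retry budget is dropped so the recorded truth always
  matches the separated-spot contract. Setting
  `enforce_spot_separation=False` yields coincident-spot scenarios where
  detection may undercount. Spots are placed inside nuclei; this is a
  simplification (real transcripts are largely cytoplasmic) that does not
  affect the counting logic under test.

One integer seed fully determines every draw; sub-streams for placement,
spots and noise derive deterministically from it.

What passing tests on these synthetics show: the algorithms recover the
quantities they are defined to recover under the stated noise, drift and
spacing conditions. What they do not show: robustness to optical artefacts
absent from the model — uneven illumination, tile-stitching seams, focus
drift, overlapping nuclei in tissue, autofluorescence structure, or
non-Gaussian camera noise.

## Registration

Alignment is pure integer translation of each cycle to cycle 1 via the
nuclear-stain reference, reflecting a stage that returns near, but not
exactly to, a stored position; channels within one cycle share one shift
because they are acquired without stage motion. The similarity is ZNCC on
the overlapping pixels (out-of-frame pixels are excluded, avoiding edge
bias); ZNCC is invariant to the intensity scaling and offset that differ
between cycles. The exhaustive search over [−max_shift, max_shift]² is
evaluated in closed form — one FFT cross-correlation for the cross term,
2-D prefix sums for per-shift window statistics — which is algebraically
identical to a per-shift loop (tests compare against a literal loop
oracle). Scores within 1e-9 (relative) of the maximum are treated as tied
and resolved deterministically: smallest |dy| + |dx| first, then
lexicographic (dy, dx). Constant images raise an error since their
similarity is undefined. `max_shift` defaults to 20 px; the appropriate
search radius depends on stage repeatability and is exposed in the
configuration. No sub-pixel interpolation is attempted: quantification is
region-mean based, and the acquisition offsets are integer-pixel to good
approximation.

## Nucleus and spot detection

Candidate regions are connected components (8-connected) of the image
binarised at a ladder of threshold levels, linked parent→child by
containment into a component forest. Threshold levels are evenly spaced
*intensity* values between the minimum and maximum of the nonzero pixels
(default 32 levels). Evenly spaced intensities rather than quantiles keep
levels between the background and the peaks even when foreground pixels
are a tiny fraction of the image — on smFISH images, quantile levels all
land in the background and every blob would stay merged with the
background component. On dense nucleus images the two choices behave
equivalently. A constant image yields an empty forest; a binary image
yields its single foreground level.

Selection is rule-based: among candidates with area within
[min_area, max_area], peak intensity above the brightness threshold and
(for nuclei) circularity 4πA/P² ≥ 0.8, the largest candidate per nesting
chain wins. This is implemented greedily by descending area with
pixel-overlap suppression — regions of a component forest are either
nested or disjoint, so overlap suppression is exactly ancestor/descendant
conflict removal. Ties break by higher peak intensity, then lexicographic
centroid, for determinism. Defaults are the published constants: nucleus
area 1200–12000 px, circularity ≥ 0.8, automatic brightness threshold;
spot area 30–500 px and absolute peak threshold 0.2, with no circularity
rule for spots (diffraction-limited spots are small enough that discrete
circularity is uninformative).

Numerical conventions: the perimeter in the circularity score is the
8-connected boundary contour length as computed by scikit-image; a
degenerate region with zero perimeter scores circularity 1. The
"automatic" brightness threshold is Otsu's threshold on the image,
overridable with an explicit value — Otsu is the most common automatic
choice; nothing in the selection logic depends on that particular choice.

Ellipse fitting uses the moment-equivalent ellipse: centroid from the mask
mean, semi-axes 2√λ of the second central moment matrix eigenvalues with
the 1/12 unit-pixel variance added (so a single pixel has positive axes),
orientation from the leading eigenvector, with orientation 0 as the
tie-break for rotationally symmetric regions. Cytosol rings are the fitted
ellipse grown by +25 px (major) and +15 px (minor) minus the nucleus and
minus other cells' pixels; pixels contested between neighbouring cells go
to the nearer nucleus centroid (exact ties to the lower cell id), and
rings are clipped at the image border. The growth is applied to the
ellipse axes rather than by anisotropic mask dilation — "expansion along
the major/minor axis direction" reads most naturally on the fitted
ellipse, and the ellipse form keeps rings smooth for arbitrary mask
boundaries.

## Quantification

Foreground = stained − erased, clipped at 0. Clipping prevents
negative-mean artefacts from dominating later scaling; the residual
background in the erased image is the per-cycle baseline, so the
difference isolates the current round's specific signal. Segmentation is
computed once on the cycle-1 reference and reused for all aligned cycles
(cells are fixed). Per cell, the mean over N_i and over C_i is recorded;
an empty compartment yields a missing value, never a silent zero. Cells
whose nucleus or cytosol touches the image border are retained but
flagged in a `border_flag` column, preserving auditability without
discarding data. Spot metrics count detected spot centroids inside N_i
and C_i; spots outside every region accumulate in an unassigned tally so
totals always reconcile.

## Spatial statistic and grid smoothing

The spatial correlation coefficient is v_iᵀ W v_j with W the globally
normalised inverse-square-distance matrix (zero diagonal, normalised by
the grand sum so ΣW = 1). v_i is the per-protein z-score across cells —
plain z-scores, not the arcsinh-compressed features, so each protein
enters with unit variance. Distances are in whatever unit the coordinates
carry; because W is normalised by its total, the statistic is invariant
to global rescaling of the coordinate units. Duplicate cell coordinates
raise an error naming the offending pair (the weight would be infinite).
Global (grand-sum) normalisation is used rather than row normalisation;
the matrix then stays symmetric and the two-cell case gives off-diagonal
weights of exactly ½ regardless of distance.

Grid smoothing averages per-cell values on a 50 × 50 grid over the
coordinate bounding box, then applies three passes of a 5 × 5 moving
average. Grid cells containing no cells are missing, not zero, and are
excluded from the kernel normalisation (zero-padding would bleed
artificial signal into tissue margins); at the field border the kernel is
renormalised over in-bounds entries. Missing cells stay missing through
all passes.

## Feature scaling, PCA and silhouettes

Features are z-transformed per column (population sd; zero-variance
columns map to zero with a warning) and then arcsinh-transformed, in that
order. The order is unusual — arcsinh-then-z is the common convention —
but it is the pipeline's defining transform; the conventional order is
available behind `arcsinh_first=True` for comparison runs. PCA drops
component 1: with cyclic staining the dominant variance direction tracks
per-cell total signal (staining efficiency and residual background), which
the implementation verifies by reporting |corr(PC1, row totals)|.
Component signs are fixed by making each component's largest-magnitude
loading positive.

Silhouettes use Euclidean distance (the classical definition; the
distance metric is not otherwise specified) with s = 0 for singleton
clusters. The subsampling analysis draws feature panels of 25/50/100
without replacement, rescales, re-runs PCA and scores silhouettes on
components 2–20 (fewer when the panel limits the rank, which is recorded),
100 repetitions per size, with per-repetition RNG substreams derived from
one seed. The spatial variant scores the same labels on 2-D tissue
coordinates.

## Probe design

Primary probes are 28-mer windows of each gene's representative transcript
(the longest isoform; length ties break by transcript id). A window
survives if it occurs exactly once across the entire representative set
(exact match on the sense strand — the aligner settings being emulated map
sense-strand k-mers with zero mismatches; antisense collisions are handled
by the complementarity screen), has GC in [45 %, 65 %] inclusive
(boundaries checked on the integer G+C count with an epsilon against
binary rounding of the percentage limits), and genes keep ≥ 24 survivors.
Cross-hybridising pairs — one probe containing an exact ≥ 10 nt match to
the reverse complement of another — are resolved by removing the
most-conflicted probe first (lazy max-heap; ties by gene then position)
until the set is conflict-free, which retains more probes than discarding
both members of each pair; the ≥ 24 rule is then re-applied.

Readout probes are seeded random 15-mers filtered to GC ∈ [40 %, 60 %],
5′ base A or T, and no ≥ 10 nt complementary stretch against any accepted
probe or against themselves, generated until the requested count or an
attempt cap (partial sets are returned with a warning). An optional screen
against a user-supplied FASTA stands in for genome-scale off-target
databases, default off. The published pool of 243 readout sequences
depended on an unstated random pool size and a remote database and is not
reproducible at desk scale; the count is therefore a parameter
(`n_readouts`). Secondary probes concatenate the reverse complement of the
primary target with two identical readout-binding units; the
antibody-conjugated oligo layout is leader `A` + unit + `AAA` spacer +
unit + trailer `A`, 35 nt for a 15-nt readout. Every emitted probe is
re-checked by an independent validator that shares no code with the
design path. No thermodynamic (Tm/ΔG) modelling is attempted.

## Problem sizes in the benchmark suite

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to exercise every code path with comfortable statistics:
registration recovery on 50 (tests) or 20 (script) stacks of 288² px with
drifts up to ±20 px, clean and at 5 % noise; segmentation-oracle
equivalence on 30 random 64² images with proportionally scaled area
bounds; parameter recovery on 720² px fields of 50 cells with 6 markers at
5 % noise (20 seeds in the tests, 5 in the script); spot recovery on 384²
fields; and probe design on random transcriptomes up to 50 kb. These sizes
are the package's benchmark conditions, not limits of the implementation.

## Known limitations

- Registration is translation-only; rotation, scaling and deformation are
  out of scope, as is tile stitching (assumed done upstream).
- Segmentation assumes roughly elliptical, non-overlapping nuclei; it is
  a rule-based selector, not a learned model, and inherits the printed
  area/circularity envelope.
- The chromatin-subdomain layering metric, UMAP/graph clustering/
  pseudotime embeddings and RNA-seq processing are deliberately not
  implemented; the scaled matrix and PCs are exported for external tools.
- The synthetic generator's noise and background models are simple
  stand-ins (see above), so quantitative performance on real data may
  differ from the benchmark numbers.
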