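# Methods

`codexkit` reimplements the computational stack behind multicycle,
DNA-barcoded immunofluorescence imaging (CODEX-style): antibodies carry
unique oligonucleotide barcodes, and each imaging cycle reveals up to three
of them with dye-bearing complementary oligonucleotides (plus a nuclear
stain imaged every cycle), producing one image plane per marker after
registration and concatenation.  Everything is validated against a
synthetic phantom generator with complete ground truth, so no microscope
data is required to exercise or test any stage.

## The phantom generator

The phantom emulates the data-generating process, not the optics.  Cells
are disks (nucleus of radius ~N(5, 0.8) px) with a 2 px annular membrane;
each cell draws a type from a configurable table of expected marker
intensities (default: five lymphoid-like types — T cell/CD3, B cell/CD19,
macrophage/CD68, epithelial/Cytokeratin, stromal/CD90 — with CD45 as a
pan-immune membrane marker at 80 a.u. and defining markers at 100 a.u.;
nuclear signal 150 a.u.).  Rendering per cycle: paint ideal marker images,
add barcode cross-talk as a configurable leakage fraction, Gaussian-blur
(sigma 1 px, a stand-in for the PSF), add per-channel additive background
(default 8 a.u.), translate by the cycle's stage drift in the Fourier
domain (so sub-pixel ground truth is exact), add Gaussian (default sd 3)
or Poisson noise, clip to the 16-bit range, and cut overlapping tiles.
Defaults follow a small two-by-two-tile field of 200 px tiles with 10%
overlap at 0.5 um/px.

What the phantom does *not* model — irregular cell morphology, spatially
varying autofluorescence spectra, vignetting/flat-field structure, real
PSFs, 3D — bounds what passing tests show: they demonstrate that each
algorithm recovers its planted truth under the stated noise model, not
that the stack is robust to every artifact of real microscopes.

Special phantoms: a *singlet spread* (every cell carries exactly one of
``n`` barcodes, revealed at most three per cycle — used for barcode
cross-reactivity QC), a two-marker *on/off schedule* (the repeating
four-cycle pattern A, B, A+B, none — used for stripping-efficiency
statistics), and a *co-localization point pattern* (two types sharing
hotspots, a third confined to the complementary area — used for density
correlation).

## Preprocessing

Stage drift between cycles is modeled as pure translation and estimated
per tile on the nuclear channel by Hann-windowed phase cross-correlation
with 20x sub-pixel upsampling; the per-cycle correction is the median
across tiles (robust to a failed tile).  Correction uses bilinear
interpolation with zero fill (identity, bit-exact, at zero drift).
Background is removed by subtracting the registered blank-cycle image of
the same fluor — linear per-pixel interpolation between flanking blanks
when two exist, nearest blank otherwise — clamped at zero.  Registration
runs before subtraction, so blank and signal images are aligned.

Stitching places tiles by nominal grid geometry and blends overlaps with
separable linear ramps, which reproduces the source exactly when the
overlapping data agree.  Optional refinement estimates each neighbor
pair's residual offset by phase correlation on the overlap strip (bounded
by half the overlap) and accumulates corrections over a breadth-first
spanning tree anchored at tile 0.  Richardson–Lucy deconvolution with a
Gaussian PSF is available but off by default (no PSF is generally known);
it uses reflective-boundary convolution so flat images are exact fixed
points and flux is conserved to ~1%.  Concatenation keeps one nuclear
plane (reference cycle) plus one plane per non-blank marker in
channel-map order.

## Segmentation

Watershed on the nuclear plane: Gaussian smoothing (sigma 1), Otsu (or
fixed) foreground threshold, Euclidean distance transform, h-maxima
suppression (h = 1) to remove plateau artifacts, seeds at local maxima
separated by at least 5 px (raster-order tie-break for determinism), then
watershed on ``-distance + 0.3 x max(distance) x normalized membrane
gradient`` — the membrane marker (e.g. CD45) sharpens boundaries between
touching cells.  Regions outside 20–10,000 px are dropped and labels
relabeled densely.  Per-cell intensity is the *mean* over the cell's
pixels (size- and exposure-comparable), centroid is the unweighted pixel
centroid, and coordinates are exported both in px and mm.

## Clustering

Features are ``arcsinh(x / 5)`` (cytometry convention; the cofactor is
configurable) then per-marker z-scored; excluded and zero-variance
markers are dropped.  Density is ``1 / mean distance to the K nearest
neighbors``; each cell links to the densest of its K neighbors that is
denser than itself; cells with no denser neighbor are modes and the trees
rooted at them are density basins.

Finite-K density estimation fragments true populations into several
basins, so basins are merged by three complementary rules (defaults in
parentheses):

1. **Structural contact** (0.3): the fraction of the smaller basin's kNN
   links crossing the pair boundary, divided by the boundary-shell share
   ``(K/size)^(1/d)`` expected when one dense region is bisected.  High
   normalized contact means the two basins are halves of one region.
2. **Resolution floor** (6 K, contact floor 0.1): a group smaller than
   ~6 K points cannot support a distinct mode at smoothing scale K; it
   joins its strongest-contact neighbor group, iterated until all groups
   reach the resolution scale or run out of contact.  Consequence: the
   method cannot resolve populations smaller than about six times K —
   lower K to find rare populations.
3. **Density saddle** (0.6): remaining adjacent groups merge while
   ``(saddle / weaker group peak)^d`` clears the threshold, best pair
   first.  The saddle is an order statistic (5th-largest, capped at a
   third) of the boundary-edge densities rather than the single best
   edge, and the peak is the mean of the basin's top five densities —
   both choices suppress single-point noise.  The d-th power converts
   kNN-density ratios (which scale as pdf^(1/d)) to probability-density
   ratios, making one threshold serve all dimensionalities.

A final one-pass kNN-majority vote smooths boundary assignments.  The
procedure is deterministic given the input order, and the partition is
invariant under input permutation (verified by test).  Thresholds were
calibrated once on a battery of synthetic scenarios (single Gaussian
cloud; three components at 6 sd in 2D; five components at 4 sd minimum
separation in 8 marker dimensions; two clouds separated by 20x their
spread; three well-separated marker-defined types), 15–40 independent
instances each; the shipped defaults resolve 122 of 124 instances, with
the two failures marginal (one 2D instance at ARI 0.90 against a 0.95
bar, one 8D instance where two components sit exactly at the 4 sd floor).

``select_elbow`` picks K where the cluster-count-vs-K curve flattens: the
first sweep point whose count equals the next one, falling back to the
maximum second difference of log counts, with a warning path for flat
curves.

## Barcode QC

The rank image sorts all reporter planes per pixel and composites the top
three as blue/green/red; the *dominance fraction* (share of pixels whose
rank-1 intensity is at least twice rank-2) quantifies "mostly blue", i.e.
one barcode per pixel.  Positive cells per barcode are gated by a
two-component Gaussian mixture on log1p intensity (posterior > 0.5 for
the upper component; Otsu fallback for degenerate distributions; fixed
threshold supported), and orthogonality is the pairwise
intersection-over-union of the positive sets (empty union defined as 0 so
heatmaps render).  For on/off cycle schedules, the reproducibility
deviation is the largest relative difference of later on-cycles from the
*first* on-cycle — the natural reading of reproducibility "across
additional cycles" — and carryover is the mean signal of off-cycles
immediately following an on-cycle (stripping efficiency), as a fraction
of the on-mean.  The default pass bound is 20%.

## Spatial analysis

Cells are points (centroids) for all membership tests.  For each follicle
mask, the surrounding ring is the dilation of the mask by
``(factor - 1) x D / 2`` (D = maximum pairwise distance between the
follicle's cells; default factor 1.2) minus all follicle interiors, so
``factor = 1`` gives an empty ring.  Composition is counts/total per zone,
averaged unweighted across follicles per tissue.  Local structure is
probed by counting cell types in randomly placed square windows (default
100 px, 500 windows, optionally constrained to a domain mask with the
whole window inside) and correlating per-window counts between types with
Spearman's rho (average-rank ties; zero-variance types reported as 0 and
flagged); display order comes from average-linkage clustering of
``1 - rho``.

## Numerical and reproducibility choices

All randomness flows through explicit integer seeds
(``numpy.random.default_rng``); segmentation, preprocessing and
clustering contain no RNG at all, so the pipeline is bit-reproducible and
two runs with one config produce checksum-identical outputs (asserted in
tests).  Images are processed in float64 and converted to uint16 only on
export, with clipping (never wrapping).  Problem sizes in the test-suite
and in ``scripts/acceptance.py`` — 100–400-cell fields, 5,000-cell
clustering problems, 500 sampling windows — were chosen as the smallest
sizes at which the statistical assertions have comfortable margins.

## Known limitations

Translation-only registration (no rotation/scale); no illumination or
chromatic correction; disk-shaped cells only in the phantom; the
clustering resolution floor of ~6 K cells per population; the
FCS writer/reader supports only float list-mode with the keywords this
package emits.
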