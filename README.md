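# codexkit

Processing and single-cell analysis for **multicycle DNA-barcoded
fluorescence imaging** (CODEX-style experiments), where antibodies carry
unique oligonucleotide barcodes that are revealed a few at a time over many
hybridize–image–strip cycles.  The package covers the full computational
chain from raw tiles to spatial statistics:

- **phantom** — seeded synthetic multicycle datasets with complete ground
  truth (cell positions, types, expression, drift, background, cross-talk),
  so every stage can be developed and tested without a microscope;
- **stack_io** — TIFF tile stacks, channel-map YAML, cell tables as CSV and
  FCS 3.1;
- **preprocess** — nuclear-channel drift compensation (sub-pixel phase
  correlation), blank-cycle background subtraction, optional
  Richardson–Lucy deconvolution, overlap-blended tile stitching, cycle
  concatenation into one plane-per-marker mosaic;
- **segmentation** — watershed single-cell segmentation seeded from the
  nuclear distance transform with a membrane-gradient term, plus per-cell
  marker quantification and intensity gating;
- **clustering** — kNN-density mode-seeking (X-shift-style) unsupervised
  clustering on arcsinh/z-scored intensities, with an elbow rule for K;
- **barcode_qc** — top-3 rank images, mixture-model barcode gating,
  cross-reactivity intersection-over-union matrices, on/off cycle
  reproducibility and carryover statistics;
- **spatial** — follicle inner/ring cell-type composition and windowed
  cell-density Spearman correlation;
- **pipeline** / `codex` CLI — one-config orchestration with seeds,
  checksums and a machine-readable run report.

## The core algorithms

*Registration*: per-cycle stage drift is a translation estimated on the
nuclear channel (imaged every cycle) by windowed phase cross-correlation
with 20x sub-pixel upsampling; recovery is accurate to <0.25 px at
single-digit SNR.

*Segmentation*: smooth the nuclear plane, threshold (Otsu), distance
transform, h-maxima-suppressed seeds, then watershed on
`-distance + w * membrane gradient` so a membrane marker (e.g. CD45)
shapes the boundary between touching cells.

*Clustering*: density of cell *i* is `1 / mean distance to its K nearest
neighbors` in marker space; each cell links to its densest denser
neighbor; cells with no denser neighbor are modes.  Basins are merged by
boundary-contact and density-saddle tests that are normalized to be
dimension-free (see `docs/methods.md`), yielding a deterministic,
permutation-invariant partition.

*Barcode QC*: for barcodes *i*, *j* with positive cell sets `A_i`, `A_j`,
cross-reactivity is `IoU = |A_i ∩ A_j| / |A_i ∪ A_j|`; an orthogonal
library has near-zero off-diagonal IoU.

*Spatial*: cell-type composition inside follicle masks and in a
surrounding ring scaled to 1.2x the follicle's cell spread; co-location
of cell types as the Spearman correlation of per-window counts over
randomly sampled 100 px squares.

## Worked example

Generate a phantom, process it, segment, cluster and correlate densities,
all from the shell:

```bash
codex phantom --output-dir exp --n-cells 120 --seed 5
codex process --input-dir exp --output-dir proc
codex segment --mosaic proc/mosaic.tif --channel-map exp/experiment.yaml \
              --membrane-channel CD45 --out cells.csv --fcs cells.fcs
codex cluster --cells cells.csv --k 15 --out clusters.csv --profiles-out profiles.csv
codex density --cells clusters.csv --shape 380x380 --window 50 --n 100 --seed 0 --out rho.csv
```

which prints

```
wrote 12 tiles, 120 cells -> exp
mosaic (7, 380, 380) -> proc/mosaic.tif
120 cells -> cells.csv
K=15: 5 clusters -> clusters.csv
rho matrix (5, 5) -> rho.csv
```

The phantom plants five cell types (CD3, CD19, CD68, Cytokeratin, CD90
defining markers) in a 2x2-tile, 3-cycle experiment; all 120 cells are
recovered and the clustering finds exactly the five planted types — the
first rows of `profiles.csv` show one cluster with CD3 mean ~99 a.u. (T
cells) and the others each dominated by a different defining marker.  The
same chain is available in one step via `codex run --config run.yaml`.

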