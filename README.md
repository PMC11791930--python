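# prism_ms

Mass-guided two-pass MALDI mass spectrometry imaging (MSI) for
single-cell metabolomics of low-mass, hydrophilic metabolites.

Whole-slide MSI at single-cell resolution is slow and produces enormous
files, while optical pre-scanning exposes unfixed cells to light and
heat that alter their metabolome. This package implements the MSI-only
alternative: a fast, coarse **PreScan** (typically 200 µm pixels)
locates cell-containing spots from a single marker ion image; only
those spots are re-acquired in a fine **DeepScan** (typically 20 µm).
The DeepScan pixels are reduced to single-cell objects, cell
subpopulations are detected by Monte Carlo reference-based consensus
clustering, and group differences are scored as effect-size volcano
statistics. A synthetic field generator with exact ground truth —
emulating composition-known giant unilamellar vesicles (GUVs) and
activation experiments — makes every stage testable without instrument
data.

## The computations at the core

**Targeting.** For a marker m/z (e.g. the ubiquitous fatty acid 18:1,
[M−H]⁻ at *m/z* 281.2485) the PreScan ion image *I* is thresholded at

    κ = Ī + α·σ,       (α = 1 by default)

with mean and population standard deviation taken over all grid cells.
Cells strictly above κ are binarized, resized to the fine raster,
optionally dilated, split into 8-connected components, and emitted as
measurement regions for the DeepScan.

**Single cells.** Each DeepScan spectrum is normalized by the
internal-standard channel (Trp-d5, [M−H]⁻ at *m/z* 208.1140),
M′ᵢⱼ = Mᵢⱼ / Mᵢ,IS (total-ion-current normalization for vesicle data),
then each feature column is z-standardized to mean 0, sd 1. Pixels with
standardized marker intensity ≤ 3 are removed, the survivors are grouped
into 8-connected components, and components of ≤ 7 pixels count as
single cells (larger ones are aggregates, excluded from statistics).
Each cell's mean spectrum forms one row of the cell-level matrix.

**Subpopulations (M3C).** For each candidate k = 2…8, the cell values
are repeatedly subsampled and hierarchically clustered; the consensus
matrix records how often each pair co-clusters. Stability is the PAC
(proportion of ambiguous clustering) and is compared against reference
datasets simulated from a structure-free normal null:

    RCSI_k = ln( mean reference PAC_k / real PAC_k ),
    p_k    = (1 + #{reference PAC ≤ real PAC}) / (B + 1).

The selected k maximizes RCSI among k with p < 0.01; if none qualifies
the feature is homogeneous (no subpopulations). k = 2 markers label each
cell +/− per axis (e.g. itaconate⁺/taurine⁻ for activated microglia).

**Statistics.** Per feature, Cohen's D = μ₁ − μ₂ (the pooled sd is 1 on
standardized data) with Welch-test p-values, Benjamini-Hochberg
adjusted; features with |D| > 0.2 and adjusted p < 0.05 are classified
up/down. Tissue comparisons subsample 1000 pixels per condition, 10
times, and average, to break the dependence of adjacent pixels.

## Worked example

```python
import numpy as np
from prism_ms import synth, prescan, cells, m3c, msio, ppm

spec = synth.FieldSpec(field_um=(4000., 4000.), n_objects=160, seed=42)
pre, deep, truth = synth.generate_field(spec)     # two GUV classes, 1:1

# PreScan -> union mask of the two lipid channels -> DeepScan regions
grids = []
for mz in (synth.DOPC_MZ, synth.DMPC_MZ):
    image = prescan.ion_image(pre, mz, ppm(10))
    grids.append(prescan.binarize(image, prescan.compute_threshold(image, 1.0)).grid)
mask = prescan.resize_mask(prescan.BinaryMask(np.logical_or.reduce(grids), 200.0), 10)
regions = prescan.extract_rois(mask)
document = msio.emit_mis(synth.prescan_template(spec), regions, 20.0, "DeepScan")

# DeepScan -> single cells -> consensus clustering per lipid
sub = msio.restrict_to_regions(deep, document)
matrix = cells.z_standardize(cells.normalize_tic(
    cells.feature_matrix(sub, sub.common_axis(ppm(10)), ppm(10))))
keep = cells.select_union_pixels(matrix, [synth.DOPC_MZ, synth.DMPC_MZ], ppm(10), 3.0)
objects = cells.cluster_cells(matrix.coords[keep], 20.0)
table = cells.cell_mean_spectra(objects, matrix)
cell_level = cells.z_standardize(
    cells.FeatureMatrix(table.values, table.feature_mz, table.ids))

dopc = cell_level.values[:, cell_level.column_index(synth.DOPC_MZ, ppm(10))]
result = m3c.M3C(dopc, m3c.M3CConfig(real_iterations=100,
                                     reference_iterations=100)).fit()
print(len(regions), "regions,", table.n_objects, "cells")
print(result.summary().round(3))
```

prints

```
35 regions, 74 cells
   pac_real  pac_reference_mean    rcsi  p_value  significant  selected
k
2     0.000               0.607  13.316     0.01         True      True
3     0.099               0.519   1.654     0.02        False     False
4     0.080               0.408   1.624     0.01         True     False
5     0.015               0.320   3.048     0.01         True     False
6     0.016               0.260   2.792     0.01         True     False
7     0.024               0.212   2.159     0.01         True     False
8     0.022               0.172   2.063     0.01         True     False
```

i.e. the DOPC channel splits the recovered cells into k = 2
subpopulations (the DOPC⁺ and DOPC⁻ vesicles) with perfect consensus
stability (PAC 0), and no higher k is more stable.

The same stages are scriptable from the shell (`prism synth-guv`,
`prism synth-activation`, `prism prescan`, `prism cells`, `prism m3c`,
`prism volcano`, `prism volcano-tissue`, `prism mz`,
`prism run <config.yaml>`); every invocation writes a run manifest
with its configuration, seed, input digests and headline numbers.

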