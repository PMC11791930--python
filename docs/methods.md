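# Methods

This note records the model choices, parameter conventions and known
limitations of the package; the README describes the workflow itself.

## Targeting (PreScan → regions)

The PreScan ion image for a target m/z sums, per pixel, all peak
intensities within tolerance of the target. Two tolerance semantics
coexist and are never converted silently: relative (ppm, default 10)
for read-time alignment and ion images, absolute (Da, default ±0.005)
for annotation-based peak reduction. Both carry their kind explicitly
(`prism_ms.tolerance.Tolerance`).

The threshold is κ = Ī + α·σ with α = 1 by default. Conventions chosen
here, because the rule itself does not pin them down:

* **σ is the population standard deviation over all grid cells,
  including zero cells.** This makes κ a function of the ion image
  alone, reproducible without knowledge of which pixels were measured.
  The same population-σ convention is used for z-standardization, so
  one definition of "standard deviation" runs through the package.
  At small n this yields slightly smaller σ than the sample convention,
  i.e. marginally more permissive masks and stricter z-cuts.
* **Strict inequality at the threshold** (intensity > κ): ties at κ are
  vanishingly rare in float data; fixing strictness makes the mask
  deterministic. A corollary: an all-zero image yields an empty mask.
* Some acquisition protocols call the region-widening parameter the
  "dilution factor"; the package names it `dilation_factor` (default 1
  = no change; factor d uses a square structuring element of side
  2(d−1)+1).

Region extraction uses **8-connectivity** (diagonal touching merges):
a cell body sampled at a coarse raster should not be split by a
diagonal adjacency. The same convention is reused for single-cell
clustering. Region polygons are the counter-clockwise outer boundary
of the union of the component's pixel squares; holes are filled (a
measurement region is a solid area), and components connected only
through a corner are bridged by a sliver two orders of magnitude below
the pixel size so every polygon is simple. Region names are generated
sequentially (`ROI_001`, …) in row-major order of first occurrence.

Mask evaluation against a ground-truth mask reports FPR = FP/(FP+TN)
and FNR = FN/(FN+TP) plus the raw counts. In published uses of this
threshold rule a "threshold index T_N" appears alongside the dilation
factor; the package reads it as the α of the κ rule — the two are
treated as the same parameter.

## Region documents (".mis" dialect)

The vendor region-file schema is proprietary and cannot be verified
without instrument files, so the package defines a minimal documented
XML dialect carrying exactly what the workflow needs: root
`PrismRegionDocument` with a `method` attribute, one `Raster size_um`
element, an optional `Transform matrix="a b c d e f"` element (the 2×3
affine taking grid indices (col, row) to stage µm), and ordered
`Region name` elements each holding a closed `Point x_um/y_um` list.
Adapting real vendor files means writing one translator to and from
this dialect. Grid coordinates are 0-based, (x = column, y = row),
origin top-left — the convention of most imaging toolchains. Intensity
is written to disk as 32-bit float (m/z at 64-bit) and held at full
precision in memory.

## Single-cell extraction

Processing order is fixed as: normalize → z-standardize →
marker-select → cluster → mean spectra → re-standardize the cell-level
matrix. Pixels without internal-standard signal are dropped *before*
standardization so they cannot distort column moments; they are never
zero-filled. The marker cut keeps pixels with standardized intensity
strictly above the cut (default 3), i.e. values ≤ 3 are removed. For
two-population vesicle fields the union of per-lipid selections is
used because the two classes share no peak.

Cell-size rules: components of ≤ 7 pixels are single cells (in
low-density cultures a cell spans at most about seven fine-raster
pixels); larger components are aggregates. Aggregates are retained in
outputs with their classification for audit but excluded from all
downstream statistics; the hard bound of 20 pixels is kept as
configuration for callers who want an intermediate class.

The cell-level matrix is re-standardized before effect-size statistics
so the unit-variance assumption of Cohen's D holds at the cell level —
pixel-level standardization does not survive averaging over cells.
Both matrices are kept.

## Monte Carlo consensus clustering

The procedure names only the stability index (RCSI) and the Monte
Carlo reference scheme; the formulas implemented here follow the
established consensus-clustering literature:

* **PAC** — fraction of off-diagonal consensus entries strictly inside
  the window (0.1, 0.9) (configurable).
* **Reference null** — multivariate normal with the data's mean and
  covariance, sampled in the principal-component frame; univariate
  input reduces to a fitted normal. A singular covariance falls back
  to its diagonal with a logged warning. An independent column
  permutation null is available behind `reference_method="permute"`.
* **RCSI** = ln(mean reference PAC / real PAC), with a PAC floor
  (1e−6) so perfectly stable clusterings (PAC 0) do not divide by
  zero.
* **p-value** — add-one-corrected empirical tail,
  (1 + #{reference PAC ≤ real PAC})/(B + 1), never zero; reaching
  p < 0.01 therefore needs at least 100 reference iterations.

Defaults mirror the study conditions: maxK 8, 200 real and 200
reference iterations, seed 42, p-threshold 0.01. The subsample
fraction (0.8) and linkage (complete, Euclidean) are standard
consensus-clustering practice and configurable. Selection takes the
highest RCSI among significant k, ties broken toward smaller k; no
significant k means "homogeneous". An ambiguous phrase in the source
protocol ("five iterations per dataset") is exposed as the optional
`repeats` parameter: repeats > 1 reruns the whole procedure with
derived seeds and takes a majority vote on the selected k (votes are
logged and returned); the default is a single run.

Determinism: the seed fully determines the result, and it is applied
after a canonical (lexicographic) ordering of objects, so the selected
k and assignments are invariant to input order. Final assignments for
the selected k cluster the consensus dissimilarity (1 − consensus).

For marker labeling only k ∈ {homogeneous, 2} is meaningful: the
cluster with the higher mean marker value is "+", a homogeneous marker
labels all cells "−", and labels are the cross-product over axes.
Cells negative on every axis are flagged and omitted from population
statistics.

Implementation notes: one dendrogram per subsample is cut at every k
by replaying the merge sequence through a union-find (equivalent in
co-membership to cutting the tree per k), and pairwise counts are
formed as sparse incidence products. Per-pixel clustering of whole
images is out of scope — the object count would make the Monte Carlo
loop prohibitively expensive — the unit of clustering is the cell.

## Statistics

Cohen's D uses the group1 − group2 sign convention (pass treatment
first so activation markers come out positive; every written table
header states this). On standardized data the denominator is 1; the
pooled-sd path exists for unstandardized input. The underlying
two-sample test is Welch's t — the source protocol does not name its
test, and Welch is robust to the unequal variances typical of
activation data; Mann-Whitney is available. BH adjustment is the
standard step-up (delegated to statsmodels; verified in tests against
a hand-rolled step-up oracle). Features constant in both groups have
no defined test: p is set to 1, the class to ns, and a `degenerate`
flag raised.

Tissue subsampling averages raw and adjusted p separately across
repeats (the protocol says only "mean p-values"); classification uses
the averaged adjusted p. Conditions with fewer pixels than the
subsample size contribute all their pixels, with a warning.

## Synthetic fields

The generator emulates the study conditions: a 200-µm coarse grid over
a field of disc-shaped objects (diameters uniform 5–50 µm) rescanned
at 20 µm; two object classes carrying disjoint single-lipid signatures
(1:1 by default); log-normal multiplicative intensity noise (σ = 0.3
in ln units — MSI intensities are positive and right-skewed); a matrix
background peak and an internal-standard channel in every pixel; and a
chemical/detector noise floor (median 0.5 intensity units) on every
channel, because real spectra are never exactly zero — without it,
absent-channel values are bit-identical across cells and consensus
clustering finds spuriously "stable" splits inside the positive group.

Rasterization rule: a fine pixel belongs to an object iff the pixel
center lies inside the object's disc; a pixel claimed by two discs
goes to the nearer center (mirroring how unresolved adjacent vesicles
produce apparent double-positives). Objects are placed uniformly
without overlap by rejection sampling (default minimum gap 40 µm = two
fine pixels, so distinct objects never merge into one component);
overcrowded specifications are refused with the achieved count. The
coarse scan is the exact sum of each pixel's 10×10 fine children, with
optional multiplicative acquisition noise (σ = 0.05) on top — with
both noises off the conservation is exact and is tested as such.

Objects much smaller than the pixel pitch may cover no pixel center
and are invisible by construction — as in real acquisitions, where
most small vesicles occupy at most one fine pixel. Recovery statistics
are therefore reported over objects covering at least one pixel.

What the generator does *not* model: ionization suppression and
matrix effects, isotope envelopes, peak-shape/centroiding artifacts,
spatial intensity gradients, and optical co-registration error.
Passing end-to-end tests demonstrates the correctness of the data
flow and the statistical machinery under the stated noise model, not
instrument-level robustness.

The activation-experiment generator plants an exact
round(fraction·n) activated cells with the activation marker shifted
up and the quiescence marker shifted down by the stated effect size
(in pre-standardization sd units) against N(0,1) null features, then
z-standardizes columns.

## Problem sizes in tests

The test suite and the acceptance script run the full procedures at
desk scale: consensus clustering with 100 real/100 reference
iterations (the smallest reference count at which p < 0.01 is
attainable), fields of 160 objects on 4 mm², activation tables of 500
cells, and 100-seed repetition loops for error-rate checks. All seeds
are fixed; stochastic assertions use 3σ binomial bounds.

## Pipeline configuration (`prism run`)

YAML with sections `synth` (field spec overrides and `mix`), `prescan`
(`alpha`, `dilation`, `tol_ppm`), `cells` (`z_min`), `m3c` (`max_k`,
`iters`, `ref_iters`), plus top-level `seed` and `out_dir`;
command-line flags override file values. Unknown keys are rejected by
name. Every CLI invocation writes one JSON run manifest (timestamp,
command, configuration, seed, SHA-256 input digests, headline
numbers). No CLI path mutates its inputs.

## Known limitations

* The .mis dialect is this package's own; vendor files need a
  translator.
* Supported adducts are [M+H]⁺, [M−H]⁻, [M+Na]⁺, singly charged;
  isotope labels support deuteration only.
* Marker labeling is defined for binary (k = 2) axes only; markers
  selecting k > 2 are refused rather than silently binarized.
* Consensus clustering at small cell counts (≲ 40) has limited power:
  reference draws occasionally reach perfect stability, inflating
  empirical p-values — expect "homogeneous" calls on small fields.
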