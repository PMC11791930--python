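"""Single-cell extraction from the fine-raster scan.

The fine scan delivers one spectrum per 20-µm pixel.  This module turns
those pixels into a table of cell-sized objects:

1. build a pixel × feature intensity matrix (``feature_matrix``);
2. normalize each spectrum — by the internal-standard channel
   (Trp-d5, m/z 208.1140) for cell experiments, or by total ion current
   for vesicle experiments;
3. z-standardize each feature column (population sd) so intensities are
   comparable across features and experiments;
4. keep pixels whose standardized marker intensity strictly exceeds a
   z cut-off (default 3); for two-population vesicle fields the union of
   per-lipid selections is used, as the two vesicle classes share no peak;
5. group the surviving pixels into 8-connected components: components of
   up to 7 pixels count as single cells, larger ones as aggregates that
   are kept for audit but excluded from downstream statistics;
6. average the member-pixel spectra into one mean spectrum per cell.

For group statistics the cell-level matrix is re-standardized so the
unit-variance assumption of the effect-size computation holds at the
cell level (both matrices are kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import label as sk_label

from ._errors import WorkflowError
from .msio import MsiDataset
from .tolerance import Tolerance

log = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"
STANDARDIZED = "standardized"

#: default single-cell size limit (pixels) and hard aggregate cut-off
MAX_SINGLE_CELL_PIXELS = 7
MAX_CLUSTER_PIXELS = 20

SINGLE_CELL = "single_cell"
AGGREGATE = "aggregate_excluded"


@dataclass
class FeatureMatrix:
    """Objects × features intensity matrix with processing-stage tag.

    ``ids`` identifies each row (pixel coordinates or cell ids);
    ``coords`` optionally carries the (x, y) grid position of pixel rows.
    After standardization, columns that were constant are all-zero and
    flagged in ``constant_columns``.
    """

    values: np.ndarray
    feature_mz: np.ndarray
    ids: list
    stage: str = RAW
    coords: np.ndarray | None = None
    is_index: int | None = None
    constant_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if self.values.ndim != 2:
            raise WorkflowError("feature matrix must be 2-D (objects x features)")
        if self.values.shape[1] != len(self.feature_mz):
            raise WorkflowError("feature_mz length must match the number of columns")
        if len(self.ids) != self.values.shape[0]:
            raise WorkflowError("ids length must match the number of rows")

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, mz: float, tol: Tolerance) -> int:
        """Index of the feature column matching an m/z within tolerance."""
        delta = np.abs(self.feature_mz - mz)
        j = int(np.argmin(delta))
        if delta[j] > tol.half_width(mz):
            raise WorkflowError(f"no feature column within {tol} of m/z {mz}")
        return j

    def subset_rows(self, keep: np.ndarray) -> "FeatureMatrix":
        keep = np.asarray(keep)
        return replace(
            self,
            values=self.values[keep],
            ids=[self.ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
                else [self.ids[i] for i in keep],
            coords=None if self.coords is None else self.coords[keep],
        )


def feature_matrix(dataset: MsiDataset, feature_mzs, tol: Tolerance) -> FeatureMatrix:
    """Pixel × feature matrix: per pixel, summed intensity within
    tolerance of each feature m/z."""
    feature_mzs = np.asarray(feature_mzs, dtype=float)
    values = np.zeros((dataset.n_pixels, len(feature_mzs)))
    for i, (mz, inten) in enumerate(zip(dataset.mzs, dataset.intensities)):
        for j, target in enumerate(feature_mzs):
            lo, hi = tol.window(target)
            a, b = np.searchsorted(mz, lo), np.searchsorted(mz, hi, side="right")
            if b > a:
                values[i, j] = np.sum(inten[a:b])
    ids = [tuple(c) for c in dataset.coords]
    return FeatureMatrix(values, feature_mzs, ids, stage=RAW,
                         coords=dataset.coords.copy())


def normalize_is(matrix: FeatureMatrix, is_mz: float, tol: Tolerance) -> FeatureMatrix:
    """Divide each row by its internal-standard intensity.

    Rows whose IS intensity is not strictly positive have no valid
    normalization and are dropped (never silently zero-filled); the count
    is logged.  The IS column becomes identically 1.
    """
    if matrix.stage != RAW:
        raise WorkflowError(f"normalize_is expects a raw matrix, got {matrix.stage!r}")
    j = matrix.column_index(is_mz, tol)
    is_values = matrix.values[:, j]
    keep = is_values > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("normalize_is: dropped %d pixel(s) without internal-standard signal",
                    dropped)
    sub = matrix.subset_rows(keep)
    values = sub.values / sub.values[:, j][:, None]
    return replace(sub, values=values, stage=NORMALIZED, is_index=j)


def normalize_tic(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each row by its total ion current (row sum).

    Zero-sum rows are dropped with a logged count.
    """
    if matrix.stage != RAW:
        raise WorkflowError(f"normalize_tic expects a raw matrix, got {matrix.stage!r}")
    totals = matrix.values.sum(axis=1)
    keep = totals > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("normalize_tic: dropped %d pixel(s) with zero total ion current", dropped)
    sub = matrix.subset_rows(keep)
    return replace(sub, values=sub.values / sub.values.sum(axis=1, keepdims=True),
                   stage=NORMALIZED)


def z_standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Center and scale each feature column to mean 0, population sd 1.

    Constant columns cannot be scaled; they map to all-zero and are
    flagged in ``constant_columns``.
    """
    if matrix.n_objects < 2:
        raise WorkflowError("standardization needs at least 2 rows (sd undefined)")
    mu = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0)  # population sd, consistent with the threshold rule
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    values = (matrix.values - mu) / safe_sd
    values[:, constant] = 0.0
    if constant.any():
        log.warning("z_standardize: %d constant column(s) set to zero", int(constant.sum()))
    return replace(matrix, values=values, stage=STANDARDIZED, constant_columns=constant)


def select_marker_pixels(matrix: FeatureMatrix, marker_mz: float, tol: Tolerance,
                         z_min: float = 3.0) -> np.ndarray:
    """Boolean row mask of pixels whose standardized marker intensity
    strictly exceeds ``z_min`` (values <= z_min are removed)."""
    if matrix.stage != STANDARDIZED:
        raise WorkflowError("marker selection runs on the standardized matrix")
    j = matrix.column_index(marker_mz, tol)
    keep = matrix.values[:, j] > z_min
    if not keep.any():
        log.warning("select_marker_pixels: no pixel exceeds z=%g for m/z %g", z_min, marker_mz)
    return keep


def select_union_pixels(matrix: FeatureMatrix, marker_mzs, tol: Tolerance,
                        z_min: float = 3.0) -> np.ndarray:
    """Union of per-marker selections — used when populations share no
    common peak (e.g. two single-lipid vesicle classes)."""
    if not len(marker_mzs):
        raise WorkflowError("need at least one marker m/z")
    keep = np.zeros(matrix.n_objects, dtype=bool)
    for mz in marker_mzs:
        keep |= select_marker_pixels(matrix, mz, tol, z_min)
    return keep


@dataclass
class CellObject:
    """An 8-connected component of selected pixels."""

    pixel_set: np.ndarray  # (k, 2) int, (x, y)
    classification: str
    centroid: tuple  # stage µm
    cell_id: int
    mean_spectrum: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)


def cluster_cells(coords: np.ndarray, pixel_size: float = 1.0,
                  max_single_cell_pixels: int = MAX_SINGLE_CELL_PIXELS,
                  max_cluster_pixels: int = MAX_CLUSTER_PIXELS) -> list:
    """Group selected pixels into 8-connected components.

    Components of at most ``max_single_cell_pixels`` pixels are single
    cells; anything larger is an aggregate, retained in the output with
    its label for audit but excluded from downstream statistics.  In
    low-density cultures a cell spans up to seven fine-raster pixels, so
    7 is the default single-cell limit and 20 the hard aggregate bound.
    """
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    if len(coords) == 0:
        return []
    if len(np.unique(coords, axis=0)) != len(coords):
        raise WorkflowError("pixel coordinates must be unique")
    x0, y0 = coords[:, 0].min(), coords[:, 1].min()
    w = coords[:, 0].max() - x0 + 1
    h = coords[:, 1].max() - y0 + 1
    grid = np.zeros((h, w), dtype=bool)
    grid[coords[:, 1] - y0, coords[:, 0] - x0] = True
    labels = sk_label(grid, connectivity=2)
    cells = []
    order = sorted(set(labels[labels > 0].tolist()),
                   key=lambda l: int(np.argmax(labels.ravel() == l)))
    for cid, lab in enumerate(order, start=1):
        ys, xs = np.nonzero(labels == lab)
        pixels = np.column_stack([xs + x0, ys + y0])
        n = len(pixels)
        cls = SINGLE_CELL if n <= max_single_cell_pixels else AGGREGATE
        centroid = (
            float((pixels[:, 0].mean() + 0.5) * pixel_size),
            float((pixels[:, 1].mean() + 0.5) * pixel_size),
        )
        cells.append(CellObject(pixels, cls, centroid, cell_id=cid))
    n_single = sum(c.classification == SINGLE_CELL for c in cells)
    log.info("cluster_cells: %d component(s), %d single cell(s), %d aggregate(s)",
             len(cells), n_single, len(cells) - n_single)
    return cells


def cell_mean_spectra(cells: list, matrix: FeatureMatrix,
                      only_single_cells: bool = True) -> FeatureMatrix:
    """Per-feature arithmetic mean over each cell's member pixels.

    Returns a cell-level matrix (one row per cell, in cell order) at the
    same processing stage as the input pixel matrix.  Aggregates are
    omitted unless ``only_single_cells`` is False.
    """
    if matrix.coords is None:
        raise WorkflowError("cell_mean_spectra needs a pixel-level matrix with coords")
    index = {tuple(c): i for i, c in enumerate(matrix.coords)}
    selected = [c for c in cells
                if not only_single_cells or c.classification == SINGLE_CELL]
    rows, ids = [], []
    for cell in selected:
        try:
            idx = [index[tuple(p)] for p in cell.pixel_set]
        except KeyError as exc:
            raise WorkflowError(f"cell pixel {exc} missing from the feature matrix") from exc
        mean = matrix.values[idx].mean(axis=0)
        cell.mean_spectrum = mean
        rows.append(mean)
        ids.append(cell.cell_id)
    values = np.array(rows).reshape(len(rows), matrix.n_features)
    return FeatureMatrix(values, matrix.feature_mz, ids, stage=matrix.stage,
                         is_index=matrix.is_index)
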