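"""Coarse-scan targeting: from an ion image to fine-scan regions.

The first pass acquires a fast, coarse raster (typically 200 µm) over
the whole slide.  A single marker m/z (e.g. the ubiquitous fatty-acid
18:1 peak at 281.2485 in negative mode) is pulled as an ion image and
thresholded at

    kappa = mean + alpha * sd

where the mean and the *population* standard deviation are taken over
all grid cells of the ion image, zeros included, and alpha defaults
to 1.  Cells strictly above kappa form a binary mask that is resized to
the fine raster, optionally dilated, decomposed into 8-connected
components, and emitted as one measurement region per component for the
second acquisition pass.

A predicted mask can be scored against a ground-truth mask (e.g. from
fluorescence) as false-positive / false-negative rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label
from skimage.morphology import dilation as sk_dilation, footprint_rectangle

from ._errors import WorkflowError
from .msio import GridTransform, MsiDataset, Region
from .tolerance import Tolerance

log = logging.getLogger(__name__)


@dataclass
class IonImage:
    """Summed intensity of one target m/z per grid cell, (row, col) indexed."""

    grid: np.ndarray
    target_mz: float
    tol: Tolerance
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise WorkflowError("ion image grid must be 2-D and non-empty")
        if not np.all(np.isfinite(self.grid)) or (self.grid < 0).any():
            raise WorkflowError("ion image values must be finite and non-negative")


@dataclass(frozen=True)
class ThresholdSpec:
    """The threshold kappa = mean + alpha*sd of an ion image."""

    alpha: float
    mean: float
    sd: float

    @property
    def kappa(self) -> float:
        return self.mean + self.alpha * self.sd


@dataclass
class BinaryMask:
    """Boolean presence mask derived from a thresholded ion image."""

    grid: np.ndarray
    pixel_size: float
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise WorkflowError("mask grid must be 2-D")

    @property
    def n_true(self) -> int:
        return int(self.grid.sum())


def ion_image(dataset: MsiDataset, target_mz: float, tol: Tolerance) -> IonImage:
    """Sum, per pixel, all peak intensities within tolerance of target_mz.

    Pixels absent from the dataset hold 0.  If the target lies outside
    the dataset's global m/z range a warning is issued and the image is
    all-zero.
    """
    rows, cols = dataset.grid_shape()
    grid = np.zeros((rows, cols), dtype=float)
    lo, hi = tol.window(target_mz)
    glo, ghi = dataset.mz_range()
    if not (np.isnan(glo) or (lo <= ghi and hi >= glo)):
        warnings.warn(
            f"target m/z {target_mz} outside dataset range [{glo:.4f}, {ghi:.4f}]"
        )
    for (x, y), mz, inten in zip(dataset.coords, dataset.mzs, dataset.intensities):
        i, j = np.searchsorted(mz, lo), np.searchsorted(mz, hi, side="right")
        if j > i:
            grid[y, x] = np.sum(inten[i:j])
    if not grid.any():
        warnings.warn(f"ion image for m/z {target_mz} ({tol}) is all zero")
    return IonImage(grid, target_mz, tol, dataset.pixel_size)


def compute_threshold(image: IonImage, alpha: float = 1.0) -> ThresholdSpec:
    """Mean + alpha*sd over ALL grid cells (zeros included, population sd)."""
    values = image.grid.ravel()
    spec = ThresholdSpec(alpha=alpha, mean=float(values.mean()), sd=float(values.std()))
    log.info("threshold: mean=%.6g sd=%.6g alpha=%g kappa=%.6g",
             spec.mean, spec.sd, alpha, spec.kappa)
    return spec


def binarize(image: IonImage, spec: ThresholdSpec) -> BinaryMask:
    """Cell true iff intensity strictly exceeds kappa."""
    return BinaryMask(
        image.grid > spec.kappa,
        pixel_size=image.pixel_size,
        provenance={"threshold": spec, "dilation_factor": 1},
    )


def resize_mask(mask: BinaryMask, factor: int) -> BinaryMask:
    """Refine a coarse mask to the fine raster: each cell becomes a
    factor x factor block; the pixel size shrinks by the same factor.

    The coarse/fine raster ratio must divide evenly (e.g. 200 µm → 20 µm
    gives factor 10)."""
    if not float(factor).is_integer() or factor < 1:
        raise WorkflowError(
            f"resize factor must be a positive integer (raster ratio must divide evenly), got {factor}"
        )
    factor = int(factor)
    grid = np.kron(mask.grid, np.ones((factor, factor), dtype=bool))
    return BinaryMask(grid, pixel_size=mask.pixel_size / factor, provenance=mask.provenance)


def dilate_mask(mask: BinaryMask, dilation_factor: int = 1) -> BinaryMask:
    """Morphological dilation with a square element of side 2*(d-1)+1.

    Factor 1 (the default) means no change; the parameter widens emitted
    regions so cells on a coarse-pixel border are not clipped by the fine
    scan.  (Some acquisition notes call this the "dilution factor"; it is
    the same parameter.)
    """
    if dilation_factor < 1:
        raise WorkflowError("dilation_factor must be >= 1")
    if dilation_factor == 1:
        return mask
    side = 2 * (int(dilation_factor) - 1) + 1
    grid = sk_dilation(mask.grid, footprint_rectangle((side, side)))
    prov = dict(mask.provenance or {})
    prov["dilation_factor"] = int(dilation_factor)
    return BinaryMask(grid, pixel_size=mask.pixel_size, provenance=prov)


def _component_polygon(component: np.ndarray, transform: GridTransform) -> np.ndarray:
    """Outer boundary polygon (stage µm) of one connected component.

    The polygon is the boundary of the union of the component's pixel
    squares; holes are filled (a measurement region is a solid area) and
    diagonal-only connections are bridged by a sliver two orders of
    magnitude below the pixel size so the polygon stays simple.
    """
    from shapely.geometry import MultiPolygon, box
    from shapely.geometry.polygon import orient
    from shapely.ops import unary_union

    ys, xs = np.nonzero(component)
    boxes = [box(x, y, x + 1, y + 1) for x, y in zip(xs, ys)]
    geom = unary_union(boxes)
    if isinstance(geom, MultiPolygon) or not geom.geom_type == "Polygon":
        # 8-connected through corners only: close the corner gaps.
        eps = 5e-3
        geom = unary_union([b.buffer(eps, join_style="mitre") for b in boxes])
        geom = geom.buffer(-eps, join_style="mitre")
    if geom.geom_type == "MultiPolygon":  # pragma: no cover - defensive
        geom = max(geom.geoms, key=lambda g: g.area)
    geom = orient(geom, sign=1.0)  # counter-clockwise outer boundary
    verts = np.asarray(geom.exterior.coords, dtype=float)
    return transform.apply(verts)


def extract_rois(mask: BinaryMask, transform: GridTransform | None = None,
                 name_format: str = "ROI_{:03d}") -> list:
    """One region per 8-connected component of true mask cells.

    Components are ordered by first (row-major) occurrence and named
    sequentially.  ``transform`` maps fine-grid indices to stage µm and
    defaults to pure scaling by the mask's pixel size.
    """
    if mask.n_true == 0:
        raise WorkflowError(
            "no cells found: the thresholded mask is empty (this is a workflow "
            "condition, not an I/O failure)"
        )
    if transform is None:
        transform = GridTransform.scaling(mask.pixel_size)
    labels = sk_label(mask.grid, connectivity=2)
    regions = []
    for i, lab in enumerate(
        sorted(set(labels[labels > 0].tolist()),
               key=lambda l: int(np.argmax(labels.ravel() == l))),
        start=1,
    ):
        poly = _component_polygon(labels == lab, transform)
        regions.append(Region(name_format.format(i), poly))
    log.info("extract_rois: %d region(s) from %d true cell(s)", len(regions), mask.n_true)
    return regions


@dataclass(frozen=True)
class MaskEvaluation:
    """Confusion counts and rates of a predicted versus ground-truth mask."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def false_positive_rate(self) -> float | None:
        neg = self.fp + self.tn
        return self.fp / neg if neg else None

    @property
    def false_negative_rate(self) -> float | None:
        pos = self.fn + self.tp
        return self.fn / pos if pos else None


def evaluate_mask(predicted: BinaryMask, truth: BinaryMask) -> MaskEvaluation:
    """FPR and FNR of a predicted mask against a ground-truth mask.

    FPR = FP / (FP + TN) over truth-negative cells, FNR = FN / (FN + TP)
    over truth-positive cells; raw counts are returned for transparency.
    An all-negative truth leaves the FNR undefined (None, with warning).
    """
    if predicted.grid.shape != truth.grid.shape:
        raise WorkflowError("predicted and truth masks must have equal shapes")
    p, t = predicted.grid, truth.grid
    ev = MaskEvaluation(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )
    if ev.fn + ev.tp == 0:
        warnings.warn("truth mask is all-negative: false-negative rate undefined")
    return ev
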