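"""File formats touched by the two-pass workflow.

Three carriers move data between acquisition and analysis:

* **imzML 1.1** (XML + .ibd binary pair, continuous or processed mode)
  for the PreScan and DeepScan images themselves — read and written
  through :mod:`pyimzml`;
* a **measurement-region document** (".mis") holding the method name,
  raster size and region polygons in stage coordinates.  The vendor
  schema is proprietary, so the package defines a minimal documented XML
  dialect (see docs/methods.md) carrying exactly the fields the workflow
  needs; adapting real vendor files means writing one translator.
* **annotation tables** — delimited text with header
  ``formula,adduct,mz,fdr`` emulating FDR-controlled database exports.

Conventions fixed here and used everywhere downstream: pixel indices are
0-based ``(x=column, y=row)`` with the origin top-left; intensities are
stored as 32-bit floats on disk and full precision in memory; stage
coordinates are µm, obtained from grid indices via the region document's
affine transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree

from ._errors import FormatError, IntegrityError, WorkflowError
from .tolerance import Tolerance

log = logging.getLogger(__name__)

CONTINUOUS = "continuous"
PROCESSED = "processed"


# ---------------------------------------------------------------------------
# In-memory carriers


@dataclass
class MsiDataset:
    """Pixel-indexed mass spectra on a regular grid.

    ``coords`` is an (n, 2) integer array of (x=column, y=row) indices;
    ``mzs``/``intensities`` are per-pixel peak arrays (m/z strictly
    increasing within each spectrum).  ``region_ids`` optionally labels
    each pixel with the measurement region it came from.
    """

    coords: np.ndarray
    mzs: list
    intensities: list
    pixel_size: float
    mode: str = CONTINUOUS
    region_ids: list | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise IntegrityError("coords must be an (n, 2) array of (x, y)")
        n = len(self.coords)
        if not (len(self.mzs) == len(self.intensities) == n):
            raise IntegrityError("every pixel needs exactly one spectrum")
        if self.pixel_size <= 0:
            raise IntegrityError("pixel_size must be positive")
        if self.mode not in (CONTINUOUS, PROCESSED):
            raise IntegrityError(f"unknown mode {self.mode!r}")
        keys = self._dedup_keys()
        if len(set(keys)) != n:
            raise IntegrityError("duplicate pixel coordinates within a region")
        for mz in self.mzs:
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise IntegrityError("m/z arrays must be strictly increasing")

    def _dedup_keys(self):
        if self.region_ids is None:
            return [tuple(c) for c in self.coords]
        return [(r, *c) for r, c in zip(self.region_ids, self.coords)]

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the smallest grid containing all pixels."""
        if self.n_pixels == 0:
            return (0, 0)
        return int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1

    def mz_range(self) -> tuple[float, float]:
        lo = min((mz[0] for mz in self.mzs if len(mz)), default=np.nan)
        hi = max((mz[-1] for mz in self.mzs if len(mz)), default=np.nan)
        return lo, hi

    def common_axis(self, tol: Tolerance) -> np.ndarray:
        """Merge all per-pixel peaks into one m/z axis.

        Peaks across pixels closer than the tolerance collapse into one
        bin (intensity-weighted mean position).  For continuous-mode data
        this returns the shared axis unchanged.
        """
        if self.mode == CONTINUOUS and self.n_pixels:
            return np.asarray(self.mzs[0], dtype=float)
        allmz = np.sort(np.concatenate([np.asarray(m, float) for m in self.mzs]))
        if allmz.size == 0:
            return allmz
        bins = [[allmz[0]]]
        for v in allmz[1:]:
            if v - bins[-1][-1] <= tol.half_width(v) * 2:
                bins[-1].append(v)
            else:
                bins.append([v])
        return np.array([float(np.mean(b)) for b in bins])


@dataclass(frozen=True)
class Region:
    """A named measurement region: a closed polygon in stage µm."""

    name: str
    polygon: np.ndarray  # (k, 2) float, closed (first == last vertex)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise IntegrityError("polygon must be a (k, 2) array")
        if not np.allclose(poly[0], poly[-1]):
            poly = np.vstack([poly, poly[0]])
        if len(np.unique(np.round(poly[:-1], 9), axis=0)) < 3:
            raise IntegrityError(f"region {self.name!r}: polygon needs >=3 distinct vertices")
        object.__setattr__(self, "polygon", poly)

    def area(self) -> float:
        """Shoelace area in µm²."""
        x, y = self.polygon[:-1, 0], self.polygon[:-1, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class GridTransform:
    """Affine map from grid indices (col, row) to stage coordinates (µm).

    ``matrix`` is the 2×3 array [[a, b, tx], [c, d, ty]]; grid point
    (u, v) maps to (a·u + b·v + tx, c·u + d·v + ty).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise IntegrityError("transform matrix must be 2x3")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def scaling(cls, pixel_size: float, origin=(0.0, 0.0)) -> "GridTransform":
        return cls(np.array([[pixel_size, 0.0, origin[0]], [0.0, pixel_size, origin[1]]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


@dataclass
class RegionDocument:
    """The measurement-region document: ordered regions, raster size,
    method name and the grid→stage transform."""

    method_name: str
    raster_size: float
    regions: list
    transform: GridTransform = field(
        default_factory=lambda: GridTransform.scaling(1.0)
    )

    def __post_init__(self) -> None:
        if self.raster_size <= 0:
            raise IntegrityError("raster_size must be positive")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise IntegrityError("region names must be unique")


@dataclass
class AnnotationTable:
    """Rows of {formula, adduct, mz, fdr} from an FDR-controlled export."""

    frame: pd.DataFrame

    REQUIRED = ("formula", "adduct", "mz", "fdr")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"annotation table missing columns {missing}")
        if (self.frame["mz"] <= 0).any():
            raise IntegrityError("annotation m/z values must be positive")
        if ((self.frame["fdr"] < 0) | (self.frame["fdr"] > 1)).any():
            raise IntegrityError("FDR values must lie in [0, 1]")

    @classmethod
    def read(cls, path, sep=",") -> "AnnotationTable":
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path, sep=",") -> None:
        self.frame.to_csv(path, index=False, sep=sep)

    def filter_fdr(self, max_fdr: float) -> "AnnotationTable":
        return AnnotationTable(self.frame[self.frame["fdr"] <= max_fdr].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# imzML


def read_imzml(path, mz_tolerance_ppm: float = 10.0, pixel_size: float | None = None) -> MsiDataset:
    """Load an imzML/ibd pair into an :class:`MsiDataset`.

    Coordinates are converted from the format's 1-based convention to the
    package's 0-based one.  ``mz_tolerance_ppm`` is recorded for on-demand
    peak alignment of processed-mode data (``MsiDataset.common_axis``).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message path
        raise FormatError(f"malformed imzML XML: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"cannot parse imzML file {path}: {exc}") from exc

    fd = parser.metadata.file_description.param_by_name
    mode = PROCESSED if fd.get("processed") else CONTINUOUS

    if pixel_size is None:
        px = parser.imzmldict.get("pixel size x") or parser.imzmldict.get("pixel size y")
        pixel_size = float(px) if px else 1.0

    coords, mzs, intens = [], [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        coords.append((int(x) - 1, int(y) - 1))
        mzs.append(np.asarray(mz, dtype=float))
        intens.append(np.asarray(inten, dtype=float))
    dataset = MsiDataset(
        np.array(coords, dtype=int).reshape(-1, 2),
        mzs,
        intens,
        pixel_size=pixel_size,
        mode=mode,
    )
    dataset.mz_tolerance_ppm = mz_tolerance_ppm
    return dataset


def write_imzml(dataset: MsiDataset, path) -> tuple[str, str]:
    """Write a dataset as an imzML 1.1 file pair (XML + ibd).

    m/z values are stored at 64-bit and intensities at 32-bit precision;
    continuous-mode datasets store the shared m/z axis once.  Returns the
    (imzML, ibd) paths.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if dataset.n_pixels == 0:
        raise WorkflowError("refusing to write an empty dataset (no pixels)")
    path = str(path)
    with ImzMLWriter(
        path,
        mode=dataset.mode,
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        for (x, y), mz, inten in zip(dataset.coords, dataset.mzs, dataset.intensities):
            writer.addSpectrum(np.asarray(mz, float), np.asarray(inten, float),
                               (int(x) + 1, int(y) + 1, 1))
    return path, path[:-5] + "ibd" if path.endswith("imzML") else path + ".ibd"


# ---------------------------------------------------------------------------
# Region documents (".mis" dialect)

_ROOT_TAG = "PrismRegionDocument"


def write_mis(document: RegionDocument, path) -> None:
    """Serialize a region document in the package's XML dialect."""
    root = etree.Element(_ROOT_TAG, method=document.method_name)
    etree.SubElement(root, "Raster", size_um=repr(float(document.raster_size)))
    mat = " ".join(repr(float(v)) for v in document.transform.matrix.ravel())
    etree.SubElement(root, "Transform", matrix=mat)
    for region in document.regions:
        el = etree.SubElement(root, "Region", name=region.name)
        for x, y in region.polygon:
            etree.SubElement(el, "Point", x_um=repr(float(x)), y_um=repr(float(y)))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def parse_mis(path) -> RegionDocument:
    """Parse a region document written in the documented dialect."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed region document XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != _ROOT_TAG:
        raise FormatError(f"unexpected root element {root.tag!r}, expected {_ROOT_TAG!r}")
    raster = root.find("Raster")
    if raster is None or "size_um" not in raster.attrib:
        raise FormatError("missing <Raster size_um=...> element")
    transform_el = root.find("Transform")
    if transform_el is None:
        transform = GridTransform.scaling(float(raster.get("size_um")))
    else:
        vals = [float(v) for v in transform_el.get("matrix").split()]
        if len(vals) != 6:
            raise FormatError("Transform matrix must hold 6 numbers")
        transform = GridTransform(np.array(vals).reshape(2, 3))
    regions = []
    for el in root.findall("Region"):
        pts = [(float(p.get("x_um")), float(p.get("y_um"))) for p in el.findall("Point")]
        if len({tuple(np.round(p, 9)) for p in pts[:-1] or pts}) < 3:
            raise IntegrityError(f"region {el.get('name')!r} has fewer than 3 distinct vertices")
        regions.append(Region(el.get("name", ""), np.array(pts)))
    return RegionDocument(
        method_name=root.get("method", ""),
        raster_size=float(raster.get("size_um")),
        regions=regions,
        transform=transform,
    )


def emit_mis(template: RegionDocument, new_regions: list, raster_size: float,
             method_name: str, path=None) -> RegionDocument:
    """Derive the fine-raster acquisition document from a coarse template.

    All template fields not explicitly replaced (currently the grid→stage
    transform) are preserved; the regions appear in input order.  When
    ``path`` is given the document is also written to disk.
    """
    if not new_regions:
        raise WorkflowError(
            "no target regions: a fine scan with no targets is a workflow error, not a file"
        )
    if raster_size <= 0:
        raise WorkflowError("raster_size must be positive")
    document = RegionDocument(
        method_name=method_name,
        raster_size=raster_size,
        regions=list(new_regions),
        transform=template.transform,
    )
    if path is not None:
        write_mis(document, path)
    return document


# ---------------------------------------------------------------------------
# Annotation-based peak reduction


def reduce_to_annotated(dataset: MsiDataset, annotations: AnnotationTable,
                        tol_da: float = 0.005, max_fdr: float = 0.10) -> MsiDataset:
    """Keep only peaks within ±tol_da of an annotation with fdr <= max_fdr.

    The pixel set is unchanged; spectra may become empty.  Idempotent and
    never increases the peak count.
    """
    if tol_da <= 0:
        raise WorkflowError("tol_da must be positive")
    kept = annotations.filter_fdr(max_fdr)
    if len(kept) == 0:
        raise WorkflowError(
            f"no annotations remain at FDR <= {max_fdr}; nothing to reduce to"
        )
    targets = np.sort(kept.frame["mz"].to_numpy(dtype=float))
    new_mzs, new_int = [], []
    for mz, inten in zip(dataset.mzs, dataset.intensities):
        mz = np.asarray(mz, float)
        if mz.size == 0:
            new_mzs.append(mz)
            new_int.append(np.asarray(inten, float))
            continue
        idx = np.clip(np.searchsorted(targets, mz), 1, len(targets)) - 1
        nearest = np.minimum(
            np.abs(mz - targets[idx]),
            np.abs(mz - targets[np.minimum(idx + 1, len(targets) - 1)]),
        )
        keep = nearest <= tol_da
        new_mzs.append(mz[keep])
        new_int.append(np.asarray(inten, float)[keep])
    mode = PROCESSED if dataset.mode == PROCESSED else dataset.mode
    out = replace(dataset, mzs=new_mzs, intensities=new_int, mode=mode)
    n_before = sum(len(m) for m in dataset.mzs)
    n_after = sum(len(m) for m in new_mzs)
    log.info("reduce_to_annotated: kept %d of %d peaks", n_after, n_before)
    return out


def restrict_to_regions(dataset: MsiDataset, document: RegionDocument) -> MsiDataset:
    """Subset a dataset to the pixels whose centers fall inside any region.

    Emulates acquiring the fine scan only inside the emitted regions:
    pixel (x, y) is kept iff its center, mapped to stage µm through the
    document transform, lies in some region polygon.
    """
    from shapely.geometry import Point, Polygon
    from shapely.prepared import prep

    polys = [prep(Polygon(r.polygon)) for r in document.regions]
    centers = document.transform.apply(dataset.coords + 0.5)
    keep = np.array(
        [any(p.intersects(Point(c)) for p in polys) for c in centers], dtype=bool
    )
    if not keep.any():
        warnings.warn("no pixels fall inside the given regions")
    return replace(
        dataset,
        coords=dataset.coords[keep],
        mzs=[m for m, k in zip(dataset.mzs, keep) if k],
        intensities=[i for i, k in zip(dataset.intensities, keep) if k],
        region_ids=None,
    )
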