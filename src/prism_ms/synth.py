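"""Synthetic ground-truth fields for end-to-end pipeline testing.

Real acquisitions cannot ship with the package, so every pipeline stage
is exercised on synthetic data with a known ground truth:

* :func:`generate_field` emulates a slide carrying cell-sized disc
  objects (5–50 µm, e.g. two single-lipid vesicle classes), rasterized
  at the fine pixel size (default 20 µm) with the coarse scan (default
  200 µm) formed by summing each coarse pixel's fine children.  Object
  and background peak intensities carry multiplicative log-normal noise
  (positive and right-skewed, like real ion counts); an
  internal-standard channel is present in every pixel.
* :func:`generate_activation_experiment` emulates a cell-level table of
  an activation experiment: a planted fraction of cells has an
  activation marker shifted up and a quiescence marker shifted down by a
  chosen effect size, against null features.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._errors import WorkflowError
from .cells import STANDARDIZED, FeatureMatrix, z_standardize, RAW
from .masses import Formula, adduct_mz
from .msio import CONTINUOUS, GridTransform, MsiDataset, Region, RegionDocument

log = logging.getLogger(__name__)

# exact adduct m/z of the stock fixtures
DOPC_MZ = adduct_mz("C44H84NO8P", "[M+H]+")      # 786.60
DMPC_MZ = adduct_mz("C36H72NO8P", "[M+H]+")      # 678.51
DAN_MZ = adduct_mz("C10H10N2", "[M-H]-")         # 157.0771 matrix peak
TRP_D5_MZ = adduct_mz(
    Formula.parse("C11H12N2O2").labeled("2H", 5), "[M-H]-"
)                                                # 208.1140 internal standard
ITACONATE_MZ = adduct_mz("C5H6O4", "[M-H]-")     # 129.0193
TAURINE_MZ = adduct_mz("C2H7NO3S", "[M-H]-")     # 124.0074


@dataclass(frozen=True)
class Population:
    """One object class with its feature signature (m/z -> median intensity)."""

    name: str
    fraction: float
    signature: dict


def guv_populations(mix: float = 0.5, intensity: float = 50.0) -> list:
    """The stock two-class vesicle field: each class carries only its own
    lipid peak, mixed ``mix`` : 1-mix."""
    return [
        Population("DOPC", mix, {DOPC_MZ: intensity}),
        Population("DMPC", 1.0 - mix, {DMPC_MZ: intensity}),
    ]


@dataclass
class FieldSpec:
    """Geometry, populations and noise of a synthetic object field.

    Defaults emulate the study conditions: a 200-µm coarse grid over a
    field of 5–50 µm objects rescanned at 20 µm, log-normal intensity
    noise (sigma 0.3 in ln units), a matrix background peak in every
    pixel and an internal-standard channel in every pixel.
    """

    field_um: tuple = (2000.0, 2000.0)
    n_objects: int = 60
    diameter_um: tuple = (5.0, 50.0)
    populations: list = field(default_factory=guv_populations)
    noise_sigma: float = 0.3
    background: list = field(default_factory=lambda: [(DAN_MZ, 2.0)])
    is_mz: float = TRP_D5_MZ
    is_intensity: float = 20.0
    baseline_intensity: float = 0.5  # chemical/detector noise floor, every channel
    prescan_pixel: float = 200.0
    deepscan_pixel: float = 20.0
    acquisition_noise_sigma: float = 0.05
    min_gap_um: float = 40.0
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(p.fraction for p in self.populations) - 1.0) > 1e-9:
            raise WorkflowError("population fractions must sum to 1")
        if self.diameter_um[0] <= 0:
            raise WorkflowError("diameters must be positive")
        ratio = self.prescan_pixel / self.deepscan_pixel
        if abs(ratio - round(ratio)) > 1e-9:
            raise WorkflowError("deepscan pixel must divide the prescan pixel evenly")
        for dim in self.field_um:
            if (dim / self.prescan_pixel) % 1 > 1e-9:
                raise WorkflowError("field size must be a multiple of the prescan pixel")

    @property
    def resize_factor(self) -> int:
        return int(round(self.prescan_pixel / self.deepscan_pixel))


@dataclass
class PlantedObject:
    center: tuple
    diameter: float
    population: str
    pixels: np.ndarray  # (k, 2) fine-grid (x, y); may be empty for tiny objects


@dataclass
class GroundTruth:
    """Planted objects and the fine-pixel → object map."""

    objects: list
    pixel_map: dict  # (x, y) -> object index

    def population_of_pixel(self, xy) -> str | None:
        i = self.pixel_map.get(tuple(xy))
        return None if i is None else self.objects[i].population

    def detectable_objects(self) -> list:
        """Objects that cover at least one fine pixel center (objects much
        smaller than the pixel pitch may cover none and are invisible)."""
        return [o for o in self.objects if len(o.pixels)]


def _place_objects(spec: FieldSpec, diameters: np.ndarray, rng) -> np.ndarray:
    """Uniform non-overlapping placement by rejection sampling."""
    centers = np.empty((spec.n_objects, 2))
    w, h = spec.field_um
    max_tries = 2000
    for i, d in enumerate(diameters):
        r = d / 2.0
        for _ in range(max_tries):
            c = rng.uniform([r, r], [w - r, h - r])
            if i == 0:
                centers[i] = c
                break
            dist = np.linalg.norm(centers[:i] - c, axis=1)
            if np.all(dist > (diameters[:i] + d) / 2.0 + spec.min_gap_um):
                centers[i] = c
                break
        else:
            raise WorkflowError(
                f"object density too high: placed {i} of {spec.n_objects} "
                f"objects without overlap after {max_tries} tries each"
            )
    return centers


def generate_field(spec: FieldSpec):
    """Generate (coarse MsiDataset, fine MsiDataset, GroundTruth).

    A fine pixel belongs to an object iff the pixel center lies inside
    the object's disc; a pixel covered by two discs goes to the nearer
    center.  Every coarse pixel is the sum of its fine children, with
    optional multiplicative acquisition noise on top.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.field_um
    nxf, nyf = int(round(w / spec.deepscan_pixel)), int(round(h / spec.deepscan_pixel))
    factor = spec.resize_factor

    pop_idx = rng.choice(
        len(spec.populations),
        size=spec.n_objects,
        p=[p.fraction for p in spec.populations],
    )
    diameters = rng.uniform(*spec.diameter_um, size=spec.n_objects)
    centers = (
        _place_objects(spec, diameters, rng)
        if spec.n_objects
        else np.empty((0, 2))
    )

    # rasterize: pixel centers inside each disc; ties to the nearer center
    pixel_map: dict = {}
    obj_pixels: list = [[] for _ in range(spec.n_objects)]
    xs = (np.arange(nxf) + 0.5) * spec.deepscan_pixel
    ys = (np.arange(nyf) + 0.5) * spec.deepscan_pixel
    for i, (c, d) in enumerate(zip(centers, diameters)):
        r = d / 2.0
        for ix in np.flatnonzero(np.abs(xs - c[0]) <= r):
            for iy in np.flatnonzero(np.abs(ys - c[1]) <= r):
                dist = float(np.hypot(xs[ix] - c[0], ys[iy] - c[1]))
                if dist > r:
                    continue
                key = (int(ix), int(iy))
                prev = pixel_map.get(key)
                if prev is not None:
                    prev_d = float(np.hypot(xs[ix] - centers[prev][0],
                                            ys[iy] - centers[prev][1]))
                    if prev_d <= dist:
                        continue
                    obj_pixels[prev] = [p for p in obj_pixels[prev] if p != key]
                pixel_map[key] = i
                obj_pixels[i].append(key)

    objects = [
        PlantedObject(tuple(c), float(d), spec.populations[p].name,
                      np.array(sorted(px), dtype=int).reshape(-1, 2))
        for c, d, p, px in zip(centers, diameters, pop_idx, obj_pixels)
    ]
    truth = GroundTruth(objects, pixel_map)

    # shared m/z axis: background + internal standard + population signatures
    axis = sorted(
        {mz for mz, _ in spec.background}
        | {spec.is_mz}
        | {mz for p in spec.populations for mz in p.signature}
    )
    axis = np.array(axis, dtype=float)
    col = {mz: j for j, mz in enumerate(axis)}
    npix = nxf * nyf
    values = np.zeros((npix, len(axis)))

    def noisy(level: float, size) -> np.ndarray:
        if spec.noise_sigma == 0:
            return np.full(size, level)
        return level * np.exp(spec.noise_sigma * rng.standard_normal(size))

    if spec.baseline_intensity > 0:
        # chemical/detector noise floor: no channel is ever exactly zero
        for j in range(len(axis)):
            values[:, j] += noisy(spec.baseline_intensity, npix)
    for mz, level in spec.background:
        values[:, col[mz]] += noisy(level, npix)
    values[:, col[spec.is_mz]] += noisy(spec.is_intensity, npix)
    for i, obj in enumerate(objects):
        sig = spec.populations[pop_idx[i]].signature
        for (x, y) in obj.pixels:
            flat = y * nxf + x
            for mz, level in sig.items():
                values[flat, col[mz]] += float(noisy(level, 1)[0])

    coords = np.array([(x, y) for y in range(nyf) for x in range(nxf)], dtype=int)
    deep = MsiDataset(
        coords,
        [axis] * npix,
        [values[i] for i in range(npix)],
        pixel_size=spec.deepscan_pixel,
        mode=CONTINUOUS,
    )

    # coarse scan: block sums of fine children (+ acquisition noise)
    cube = values.reshape(nyf, nxf, len(axis))
    nxp, nyp = nxf // factor, nyf // factor
    block = cube.reshape(nyp, factor, nxp, factor, len(axis)).sum(axis=(1, 3))
    if spec.acquisition_noise_sigma > 0:
        block = block * np.exp(
            spec.acquisition_noise_sigma * rng.standard_normal(block.shape)
        )
    pcoords = np.array([(x, y) for y in range(nyp) for x in range(nxp)], dtype=int)
    pvalues = block.reshape(nxp * nyp, len(axis))
    pre = MsiDataset(
        pcoords,
        [axis] * (nxp * nyp),
        [pvalues[i] for i in range(nxp * nyp)],
        pixel_size=spec.prescan_pixel,
        mode=CONTINUOUS,
    )
    log.info("generate_field: %d objects, %d with >=1 covered pixel, %d fine pixels",
             spec.n_objects, len(truth.detectable_objects()), npix)
    return pre, deep, truth


def prescan_template(spec: FieldSpec, method_name: str = "PreScan_200um") -> RegionDocument:
    """The coarse-scan region document covering the whole field."""
    w, h = spec.field_um
    outline = Region("Field", np.array([[0, 0], [w, 0], [w, h], [0, h], [0, 0]], float))
    return RegionDocument(
        method_name=method_name,
        raster_size=spec.prescan_pixel,
        regions=[outline],
        transform=GridTransform.scaling(spec.deepscan_pixel),
    )


def generate_activation_experiment(
    n_cells: int,
    activated_fraction: float,
    marker_up=(ITACONATE_MZ,),
    marker_down=(TAURINE_MZ,),
    effect_size: float = 2.0,
    seed: int = 42,
    n_null_features: int = 20,
):
    """Cell-level table of a planted activation experiment.

    An exact ``round(activated_fraction * n_cells)`` cells (in shuffled
    position) are activated: their ``marker_up`` features are shifted by
    +effect_size and ``marker_down`` by −effect_size standard deviations
    before the final column standardization; all other features are
    null N(0, 1).  Returns ``(FeatureMatrix@standardized, activated)``
    with the planted boolean labels.
    """
    if not (0 <= activated_fraction <= 1):
        raise WorkflowError("activated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_act = int(round(activated_fraction * n_cells))
    activated = np.zeros(n_cells, dtype=bool)
    activated[rng.permutation(n_cells)[:n_act]] = True

    marker_up = list(marker_up)
    marker_down = list(marker_down)
    null_mzs = [150.0 + 7.0 * j for j in range(n_null_features)]
    feature_mz = np.array(marker_up + marker_down + null_mzs)

    values = rng.standard_normal((n_cells, len(feature_mz)))
    for j in range(len(marker_up)):
        values[activated, j] += effect_size
    for j in range(len(marker_up), len(marker_up) + len(marker_down)):
        values[activated, j] -= effect_size

    matrix = FeatureMatrix(values, feature_mz, ids=list(range(n_cells)), stage=RAW)
    return z_standardize(matrix), activated
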