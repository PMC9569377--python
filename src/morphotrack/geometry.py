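"""Extracellular-space geometries: representation, synthesis, morphing.

The tissue of an early embryo is a loose packing of cells separated by a
thin extracellular film.  Two classes of extracellular space matter for
morphogen transport: *interfaces*, the narrow gaps where exactly two cells
are aligned, and *cavities*, the larger voids where more than two cells
meet.  Geometries are binary rasters (1 = extracellular) at a fine pitch —
simulation-grade masks use 10 nm pixels — plus labeled polygons in physical
units (µm) for region assignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from shapely.geometry import Polygon
from skimage import measure, morphology

__all__ = [
    "TissueGeometry",
    "ReceptorSet",
    "GeometryStats",
    "Region",
    "compute_extracellular_fraction",
    "morph_extracellular_width",
    "place_receptors",
    "synthesize_tissue",
    "classify_regions",
    "boundary_contours",
    "total_boundary_length",
    "geometry_stats",
    "load_mask",
    "save_mask",
    "load_regions",
    "save_regions",
]

#: Simulation-grade pixel pitch (µm): 10 nm pixels.
SIM_PIXEL_PITCH_UM = 0.01

# raster codes used by classify_regions and synthesize_tissue label maps
LABEL_NONE = 0
LABEL_INTERFACE = 1
LABEL_CAVITY = 2


@dataclass
class Region:
    """A labeled region polygon with vertices in µm."""

    label: str  # "interface" | "cavity"
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.label not in ("interface", "cavity"):
            raise ValueError(f"unknown region label {self.label!r}")
        if not self.polygon.is_valid:
            raise ValueError("region polygon must be simple (non-self-intersecting)")


@dataclass
class TissueGeometry:
    """Binary extracellular raster plus labeled region polygons.

    ``mask[i, j] == 1`` marks extracellular space at row i (y), column j (x).
    Physical coordinates put pixel centers at ``(j + 0.5, i + 0.5) * pitch``.
    """

    mask: np.ndarray
    pixel_pitch_um: float = SIM_PIXEL_PITCH_UM
    regions: list[Region] = field(default_factory=list)
    label_map: np.ndarray | None = None  # optional per-pixel region codes

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        vals = np.unique(self.mask)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.mask = self.mask.astype(np.uint8)
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        return (
            self.mask.shape[1] * self.pixel_pitch_um,
            self.mask.shape[0] * self.pixel_pitch_um,
        )

    def pixel_centers_um(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(x, y) µm coordinates of pixel centers."""
        return np.column_stack(
            [
                (np.asarray(cols) + 0.5) * self.pixel_pitch_um,
                (np.asarray(rows) + 0.5) * self.pixel_pitch_um,
            ]
        )


@dataclass
class ReceptorSet:
    """Receptor positions (µm) on the extracellular boundary."""

    positions: np.ndarray  # (n, 2) x,y in µm
    density_sigma: float  # receptors per µm of membrane length

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass
class GeometryStats:
    eta: float  # extracellular fraction, percent
    boundary_length_um: float
    cavity_area_um2: float
    interface_area_um2: float


def compute_extracellular_fraction(geometry: TissueGeometry) -> float:
    """Extracellular fraction η = 100 × extracellular pixels / total pixels."""
    mask = geometry.mask
    n_extra = int(mask.sum())
    if n_extra == 0:
        raise ValueError("degenerate geometry: no extracellular pixels")
    return 100.0 * n_extra / mask.size


def _n_components(mask: np.ndarray) -> int:
    return int(measure.label(mask, connectivity=2).max())


def morph_extracellular_width(
    geometry: TissueGeometry, target_eta: float, max_iter: int = 500
) -> TissueGeometry:
    """Widen or narrow the extracellular space to reach a target η.

    Each iteration dilates (or erodes) the extracellular set by one pixel on
    both sides of every boundary, changing the local width by 2 pixels
    (20 nm at simulation pitch).  Iteration stops at the mask whose η is
    closest to the target; the result is within one iteration step of it.

    Raises if the target cannot be approached (erosion exhausts the space or
    stalls) or if erosion disconnects the extracellular network.
    """
    eta0 = compute_extracellular_fraction(geometry)
    selem = morphology.disk(1)
    mask = geometry.mask.astype(bool)
    if abs(target_eta - eta0) < 1e-12:
        return TissueGeometry(
            geometry.mask.copy(), geometry.pixel_pitch_um, list(geometry.regions)
        )
    growing = target_eta > eta0
    n_comp0 = _n_components(mask)
    best_mask, best_err = mask, abs(eta0 - target_eta)
    prev_eta = eta0
    for _ in range(max_iter):
        mask = (
            morphology.dilation(mask, selem)
            if growing
            else morphology.erosion(mask, selem)
        )
        if not mask.any():
            raise ValueError("target eta unreachable: extracellular space vanished")
        eta = 100.0 * mask.sum() / mask.size
        if not growing and _n_components(mask) > n_comp0:
            raise ValueError(
                "erosion disconnected the extracellular network before "
                "reaching the target eta"
            )
        err = abs(eta - target_eta)
        if err < best_err:
            best_mask, best_err = mask, err
        crossed = (eta >= target_eta) if growing else (eta <= target_eta)
        if crossed:
            break
        if abs(eta - prev_eta) < 1e-12:
            raise ValueError("target eta unreachable: morphing stalled")
        prev_eta = eta
    else:
        raise ValueError("target eta not reached within the iteration limit")
    return TissueGeometry(
        best_mask.astype(np.uint8), geometry.pixel_pitch_um, list(geometry.regions)
    )


def boundary_contours(geometry: TissueGeometry) -> list[np.ndarray]:
    """Extracellular/intracellular boundary polylines in µm (x, y columns).

    Contours are extracted at the 0/1 transition by marching squares; each
    is an (n, 2) array of x, y coordinates.  Closed contours repeat their
    first vertex at the end.  Image-edge pixels do not generate boundary
    (the field of view is not a membrane).
    """
    contours = measure.find_contours(geometry.mask.astype(float), 0.5)
    out = []
    for c in contours:
        # find_contours yields (row, col); pixel centers sit at +0.5
        xy = np.column_stack([c[:, 1] + 0.5, c[:, 0] + 0.5]) * geometry.pixel_pitch_um
        out.append(xy)
    return out


def _contour_length(xy: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())


def total_boundary_length(geometry: TissueGeometry) -> float:
    """Total membrane (boundary) length in µm."""
    return sum(_contour_length(c) for c in boundary_contours(geometry))


def place_receptors(geometry: TissueGeometry, sigma: float) -> ReceptorSet:
    """Place receptors with uniform arc-length spacing along every boundary.

    Spacing is ``1/sigma`` µm.  On closed contours the count is
    ``round(length * sigma)`` distributed evenly; open contours (touching
    the mask edge) get receptors at odd multiples of half the spacing so
    the pattern is symmetric.  If the requested spacing falls below the
    pixel pitch a warning is issued and receptors are placed one pitch
    apart (one per boundary pixel).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    spacing = 1.0 / sigma
    if spacing < geometry.pixel_pitch_um:
        warnings.warn(
            "receptor spacing below pixel pitch; placing one receptor per "
            "boundary pixel",
            stacklevel=2,
        )
        spacing = geometry.pixel_pitch_um
    points = []
    for xy in boundary_contours(geometry):
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        total = arclen[-1]
        if total <= 0:
            continue
        closed = np.allclose(xy[0], xy[-1])
        if closed:
            n = max(int(round(total / spacing)), 1)
            targets = np.arange(n) * (total / n)
        else:
            n = int(round(total / spacing))
            if n == 0:
                continue
            targets = (np.arange(n) + 0.5) * (total / n)
        x = np.interp(targets, arclen, xy[:, 0])
        y = np.interp(targets, arclen, xy[:, 1])
        points.append(np.column_stack([x, y]))
    positions = np.vstack(points) if points else np.empty((0, 2))
    return ReceptorSet(positions=positions, density_sigma=sigma)


def _mask_polygons(mask: np.ndarray, pitch: float, min_area_px: int = 25):
    """Simple polygons (µm) around connected true regions of ``mask``."""
    polys = []
    padded = np.pad(mask.astype(float), 1)
    for c in measure.find_contours(padded, 0.5):
        xy = np.column_stack([c[:, 1] - 0.5, c[:, 0] - 0.5]) * pitch
        if len(xy) < 4:
            continue
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.geom_type != "Polygon" or not poly.is_valid:
                continue
        if poly.area < min_area_px * pitch * pitch:
            continue
        polys.append(poly)
    # drop holes (contours traced inside larger ones)
    return [
        p
        for i, p in enumerate(polys)
        if not any(j != i and q.contains(p) for j, q in enumerate(polys))
    ]


def synthesize_tissue(
    n_cells: int,
    target_eta: float = 10.0,
    cavity_fraction: float = 0.4,
    seed: int = 0,
    field_um: float | None = None,
    pixel_pitch_um: float = SIM_PIXEL_PITCH_UM,
    cell_area_um2: float = 100.0,
    cavity_site_fraction: float = 0.5,
) -> TissueGeometry:
    """Generate a tissue-like mask: cells separated by narrow interfaces
    with cavity bulges at multi-cell junctions.

    Cells are seeded as a blue-noise point set; the extracellular network
    is the generalized Voronoi channel (pixels whose two nearest seeds are
    nearly equidistant) whose half-width is tuned by bisection to reach the
    target η after cavities — disks around points where three influence
    zones meet — are added.  ``cavity_fraction`` sets the share of
    extracellular area allotted to cavities.  Deterministic under ``seed``.

    The returned geometry carries both labeled polygons and a per-pixel
    ``label_map`` recording the generator's own interface/cavity assignment.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if not 0 < target_eta < 100:
        raise ValueError("target_eta must be in (0, 100)")
    rng = np.random.default_rng(seed)
    if field_um is None:
        field_um = float(np.sqrt(n_cells * cell_area_um2))
    n_px = int(round(field_um / pixel_pitch_um))
    field_um = n_px * pixel_pitch_um

    # blue-noise cell seeds by dart throwing
    min_sep = 0.7 * np.sqrt(cell_area_um2)
    seeds: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform(0, field_um, 2)
        if all(np.linalg.norm(cand - s) >= min_sep for s in seeds):
            seeds.append(cand)
            if len(seeds) == n_cells:
                break
    if len(seeds) < n_cells:
        raise ValueError("could not place the requested number of cells")
    seed_pts = np.array(seeds)

    # three nearest seed distances per pixel, chunked row blocks
    xs = (np.arange(n_px) + 0.5) * pixel_pitch_um
    gap21 = np.empty((n_px, n_px))
    gap31 = np.empty((n_px, n_px))
    k = min(3, n_cells)
    for start in range(0, n_px, 256):
        stop = min(start + 256, n_px)
        yy = xs[start:stop, None, None]
        xx = xs[None, :, None]
        d = np.sqrt(
            (xx - seed_pts[None, None, :, 0]) ** 2
            + (yy - seed_pts[None, None, :, 1]) ** 2
        )
        part = np.partition(d, k - 1, axis=2)[:, :, :k]
        part.sort(axis=2)
        gap21[start:stop] = part[:, :, 1] - part[:, :, 0]
        gap31[start:stop] = (
            part[:, :, 2] - part[:, :, 0] if k >= 3 else np.inf
        )

    total_px = n_px * n_px
    target_px = target_eta / 100.0 * total_px

    # cavity disks at triple junctions sized for the requested area share;
    # only the larger half of the junctions seeds a cavity — tissue shows a
    # few large cavities rather than one per junction
    junction = gap31 <= 2 * pixel_pitch_um
    cavity = np.zeros((n_px, n_px), dtype=bool)
    if junction.any() and cavity_fraction > 0:
        blob_labels = measure.label(junction, connectivity=2)
        sizes = np.bincount(blob_labels.ravel())[1:]
        n_keep = max(int(round(cavity_site_fraction * len(sizes))), 1)
        keep_ids = np.argsort(sizes)[::-1][:n_keep] + 1
        junction_kept = np.isin(blob_labels, keep_ids)
        cavity_area_target = cavity_fraction * target_px * pixel_pitch_um**2
        r_cav = float(np.sqrt(cavity_area_target / (np.pi * n_keep)))
        if r_cav > 0:
            dist_to_junction = distance_transform_edt(~junction_kept) * pixel_pitch_um
            cavity = dist_to_junction <= r_cav

    # bisection on interface half-width to reach target eta
    lo, hi = 0.0, field_um / 2
    for _ in range(60):
        w = 0.5 * (lo + hi)
        mask = (gap21 <= w) | cavity
        if mask.sum() > target_px:
            hi = w
        else:
            lo = w
    w = 0.5 * (lo + hi)
    mask = (gap21 <= w) | cavity
    interface_mask = (gap21 <= w) & ~cavity

    label_map = np.zeros((n_px, n_px), dtype=np.uint8)
    label_map[interface_mask] = LABEL_INTERFACE
    label_map[cavity & mask] = LABEL_CAVITY

    regions = [
        Region("cavity", p) for p in _mask_polygons(cavity & mask, pixel_pitch_um)
    ]
    regions += [
        Region("interface", p)
        for p in _mask_polygons(interface_mask, pixel_pitch_um)
    ]
    return TissueGeometry(
        mask.astype(np.uint8),
        pixel_pitch_um,
        regions,
        label_map=label_map,
    )


def classify_regions(
    geometry: TissueGeometry, width_threshold_um: float = 1.0
) -> np.ndarray:
    """Partition extracellular pixels into interface and cavity classes.

    A pixel is a *cavity* pixel if the local width of the extracellular
    space around it exceeds the threshold, or if a junction where more than
    two cells meet lies within its free-space disk; otherwise it is an
    *interface* pixel (bounded by exactly two cells).  Local width is
    estimated as twice the Euclidean distance to the nearest intracellular
    pixel.  Returns a raster with 0 = intracellular, 1 = interface,
    2 = cavity.
    """
    mask = geometry.mask.astype(bool)
    pitch = geometry.pixel_pitch_um
    if not mask.any():
        raise ValueError("no extracellular pixels")
    if mask.all():
        # no cells at all: everything is one large void
        return np.full(mask.shape, LABEL_CAVITY, dtype=np.uint8)

    cells = measure.label(~mask, connectivity=1)
    edt, inds = distance_transform_edt(mask, return_indices=True)
    nearest_cell = cells[inds[0], inds[1]]
    nearest_cell[~mask] = 0
    local_width = 2.0 * edt * pitch

    # junction pixels: >2 distinct nearest-cell zones meet within a 3x3 patch
    padded = np.pad(nearest_cell, 1, mode="edge")
    shifts = [
        padded[di : di + mask.shape[0], dj : dj + mask.shape[1]]
        for di in (0, 1, 2)
        for dj in (0, 1, 2)
    ]
    stack = np.stack(shifts)
    stack.sort(axis=0)
    distinct = (np.diff(stack, axis=0) > 0).sum(axis=0) + 1
    junction = (distinct > 2) & mask

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask] = LABEL_INTERFACE
    if junction.any():
        # the cavity around a junction extends over the junction's own
        # free-space (inscribed) disk: paint a ball of radius edt(q) + 2 px
        # around every junction pixel q
        cavity_zone = np.zeros(mask.shape, dtype=bool)
        jr, jc = np.nonzero(junction)
        radii_px = edt[jr, jc] + 2.0
        h, w_px = mask.shape
        for r0, c0, rad in zip(jr, jc, radii_px):
            ir = int(np.ceil(rad))
            r_lo, r_hi = max(r0 - ir, 0), min(r0 + ir + 1, h)
            c_lo, c_hi = max(c0 - ir, 0), min(c0 + ir + 1, w_px)
            yy, xx = np.ogrid[r_lo - r0 : r_hi - r0, c_lo - c0 : c_hi - c0]
            cavity_zone[r_lo:r_hi, c_lo:c_hi] |= yy * yy + xx * xx <= rad * rad
        labels[mask & cavity_zone] = LABEL_CAVITY
    labels[mask & (local_width > width_threshold_um)] = LABEL_CAVITY
    return labels


def geometry_stats(geometry: TissueGeometry) -> GeometryStats:
    """Summary statistics: η, boundary length, per-class region areas."""
    eta = compute_extracellular_fraction(geometry)
    boundary = total_boundary_length(geometry)
    cavity_area = sum(r.polygon.area for r in geometry.regions if r.label == "cavity")
    interface_area = sum(
        r.polygon.area for r in geometry.regions if r.label == "interface"
    )
    return GeometryStats(
        eta=eta,
        boundary_length_um=boundary,
        cavity_area_um2=cavity_area,
        interface_area_um2=interface_area,
    )


# ---------------------------------------------------------------------------
# I/O


def save_mask(geometry: TissueGeometry, path: str | Path) -> None:
    """Write the mask as an 8-bit TIFF/PNG (0/255) with a pitch sidecar."""
    import tifffile
    from PIL import Image

    path = Path(path)
    img = (geometry.mask * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_pitch_um": geometry.pixel_pitch_um}))


def load_mask(path: str | Path, pixel_pitch_um: float | None = None) -> TissueGeometry:
    """Read an 8-bit mask (0/255 or 0/1); pitch from sidecar JSON if present.

    A ``pixel_pitch_um`` argument overrides the sidecar.  Values above 1 are
    interpreted as nm and converted (no real mask has >1 µm pixels).
    """
    import tifffile
    from PIL import Image

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path).convert("L"))
    mask = (img > 0).astype(np.uint8)
    if pixel_pitch_um is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            pixel_pitch_um = json.loads(sidecar.read_text())["pixel_pitch_um"]
        else:
            pixel_pitch_um = SIM_PIXEL_PITCH_UM
    if pixel_pitch_um > 1.0:  # given in nm
        pixel_pitch_um = pixel_pitch_um / 1000.0
    return TissueGeometry(mask, pixel_pitch_um)


def save_regions(regions: list[Region], path: str | Path) -> None:
    payload = [
        {
            "label": r.label,
            "vertices_um": np.asarray(r.polygon.exterior.coords).tolist(),
        }
        for r in regions
    ]
    Path(path).write_text(json.dumps(payload))


def load_regions(path: str | Path) -> list[Region]:
    payload = json.loads(Path(path).read_text())
    return [Region(item["label"], Polygon(item["vertices_um"])) for item in payload]
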