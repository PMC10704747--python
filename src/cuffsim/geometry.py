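"""Nerve cross-section geometry, cuff electrode layout, and voxel volumes.

The cross-section is a labeled 2-D pixel grid distinguishing saline,
endoneurium (fascicle interior), perineurium (fascicle sheath), epineurium
(outer connective tissue) and the cuff electrode material.  A synthetic
generator emulates an oblong human median-nerve slice (~9 x 4 mm epineurium
containing 17 quasi-elliptical fascicles) held in a rectangular
flat-interface nerve electrode (FINE) carrying 56 contacts, surrounded by a
saline cylinder.  The cross-section is extruded axially into a 3-D labeled
voxel volume for the volume-conductor forward problem.

Coordinate convention: pixel-centered, 0-based indices; physical
coordinates in mm with the origin at the image center; x along the cuff's
long side, y along the short side, z along the nerve axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import filters, measure, morphology

# Label codes, in precedence order (later codes overwrite earlier ones when
# masks overlap during rendering): saline < epineurium < perineurium <
# endoneurium < electrode.  OUTSIDE marks voxels beyond the saline cylinder
# in 3-D volumes; they take no part in the electrical problem.
LABEL_SALINE = 0
LABEL_ENDONEURIUM = 1
LABEL_PERINEURIUM = 2
LABEL_EPINEURIUM = 3
LABEL_ELECTRODE = 4
LABEL_OUTSIDE = 5

LABEL_NAMES = {
    LABEL_SALINE: "saline",
    LABEL_ENDONEURIUM: "endoneurium",
    LABEL_PERINEURIUM: "perineurium",
    LABEL_EPINEURIUM: "epineurium",
    LABEL_ELECTRODE: "electrode",
    LABEL_OUTSIDE: "outside",
}

# Grayscale rendering intensities.  Endoneurium is rendered far brighter
# than every other material so that a bimodal threshold isolates fascicles,
# mimicking the appearance of fascicles in an IHC slice.
_GRAY_LEVELS = {
    LABEL_SALINE: 30,
    LABEL_EPINEURIUM: 60,
    LABEL_PERINEURIUM: 50,
    LABEL_ELECTRODE: 45,
    LABEL_ENDONEURIUM: 220,
    LABEL_OUTSIDE: 30,
}


class GeometryError(ValueError):
    """Inconsistent or infeasible geometry."""


class NoThresholdError(GeometryError):
    """Degenerate image: no intensity threshold separates foreground."""


class NoFasciclesError(GeometryError):
    """Segmentation produced zero fascicles."""


class PackingError(GeometryError):
    """Fascicle packing failed within the retry budget."""


class ResolutionError(GeometryError):
    """Voxel pitch too coarse to resolve a tissue layer."""


@dataclasses.dataclass(frozen=True)
class ElectrodeLayout:
    """FINE-style cuff: 7 axial layers x 8 contacts on the two long faces.

    Contacts are ordered canonically as
    ``channel = layer * 8 + edge * 4 + within_edge`` with ``edge`` 0 for the
    y < 0 face and 1 for the y > 0 face; this order is the reference for
    every downstream channel arrangement.
    """

    contact_positions: np.ndarray  # (n, 3) mm
    layer_index: np.ndarray  # (n,) 0-based axial layer
    edge_index: np.ndarray  # (n,) 0 or 1
    within_edge_index: np.ndarray  # (n,) 0..contacts_per_edge-1
    inner_long: float = 9.0  # mm, cuff inner long side (x)
    inner_short: float = 4.9  # mm, cuff inner short side (y)
    thickness: float = 0.65  # mm cuff wall
    height: float = 20.0  # mm axial extent of the cuff
    contact_pitch: float = 2.25  # mm within an edge
    layer_pitch: float = 2.86  # mm between layers
    n_layers: int = 7
    contacts_per_edge: int = 4

    @property
    def n_contacts(self) -> int:
        return self.contact_positions.shape[0]

    @property
    def outer_ring_layers(self) -> tuple[int, int]:
        """The two end layers whose contacts form the tripolar reference."""
        return (0, self.n_layers - 1)

    @property
    def outer_ring_channels(self) -> np.ndarray:
        first, last = self.outer_ring_layers
        return np.flatnonzero(
            (self.layer_index == first) | (self.layer_index == last)
        )


@dataclasses.dataclass
class CrossSectionModel:
    """Labeled 2-D tissue map of the nerve slice plus electrode and saline."""

    label_image: np.ndarray  # (ny, nx) uint8 label codes
    fascicle_ids: np.ndarray  # (ny, nx) int32, 0 = not endoneurium
    pixel_pitch: float  # mm per pixel
    fascicle_centroids: list[tuple[float, float]]  # (x, y) mm

    def __post_init__(self) -> None:
        if self.label_image.shape != self.fascicle_ids.shape:
            raise GeometryError("label image and fascicle id image differ in shape")
        endo = self.label_image == LABEL_ENDONEURIUM
        if np.any(endo & (self.fascicle_ids <= 0)):
            raise GeometryError("endoneurium pixel without a fascicle id")

    @property
    def n_fascicles(self) -> int:
        return int(self.fascicle_ids.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate arrays of pixel centers, origin at center."""
        ny, nx = self.label_image.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_pitch
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_pitch
        return x, y

    def to_grayscale(self) -> np.ndarray:
        """Render the slice as a single-channel uint8 image.

        Fascicles are bright against the connective-tissue background, so the
        endoneurium segmentation pipeline can be exercised on synthetic
        slices exactly as it would be on a histology image.
        """
        img = np.zeros(self.label_image.shape, dtype=np.uint8)
        for code, level in _GRAY_LEVELS.items():
            img[self.label_image == code] = level
        return img


@dataclasses.dataclass
class NerveVolume:
    """Extruded 3-D labeled voxel grid, indexed ``[iy, ix, iz]``."""

    label_grid: np.ndarray  # (ny, nx, nz) uint8
    voxel_pitch: tuple[float, float, float]  # (dx, dy, dz) mm
    layout: ElectrodeLayout
    cross_section: CrossSectionModel
    saline_diameter: float = 11.0  # mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def z_coords(self) -> np.ndarray:
        nz = self.label_grid.shape[2]
        return (np.arange(nz) - (nz - 1) / 2.0) * self.voxel_pitch[2]

    def xy_coords(self) -> tuple[np.ndarray, np.ndarray]:
        return self.cross_section.pixel_coords_mm()


# ---------------------------------------------------------------------------
# Mask pipeline (image -> tissue masks)
# ---------------------------------------------------------------------------

def segment_endoneurium(
    image: np.ndarray,
    pixel_pitch: float,
    min_area: float = 0.01,
    smoothing_sigma: float = 1.0,
) -> list[np.ndarray]:
    """Segment fascicle (endoneurium) masks from a grayscale cross-section.

    Otsu's threshold isolates the bright fascicle interiors; light
    morphological smoothing and hole filling regularize the boundaries, and
    connected components smaller than ``min_area`` (mm^2) are discarded as
    artifacts (blood vessels, stain speckle).

    Returns one filled boolean mask per fascicle, ordered by component
    centroid (row-major).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise GeometryError("expected a single-channel 2-D image")
    if min_area <= 0:
        raise GeometryError("min_area must be positive")
    if np.ptp(image) == 0:
        raise NoThresholdError("no threshold found: image has a single intensity")
    smoothed = filters.gaussian(image.astype(float), sigma=smoothing_sigma)
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    fg = morphology.closing(fg, morphology.disk(2))
    fg = ndimage.binary_fill_holes(fg)
    min_px = max(1, int(round(min_area / pixel_pitch**2)))
    labels = measure.label(fg, connectivity=1)
    props = [p for p in measure.regionprops(labels) if p.area >= min_px]
    if not props:
        raise NoFasciclesError("no fascicles after size filtering")
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    return [labels == p.label for p in props]


def grow_perineurium(
    fascicle_masks: list[np.ndarray],
    dilation_fraction: float = 0.03,
) -> np.ndarray:
    """Perineurium mask: each fascicle dilated by a fraction of its size.

    The dilation radius for a fascicle is ``dilation_fraction`` times its
    equivalent diameter ``2 * sqrt(area / pi)`` (at least one pixel), so
    larger fascicles get proportionally thicker sheaths.  Overlapping
    dilations merge; the original endoneurium is subtracted, leaving an
    annular sheath per fascicle (possibly fused between close neighbors).
    """
    if not 0 < dilation_fraction <= 0.5:
        raise GeometryError("dilation_fraction must be in (0, 0.5]")
    if not fascicle_masks:
        return np.zeros((0, 0), dtype=bool)
    shape = fascicle_masks[0].shape
    dilated_union = np.zeros(shape, dtype=bool)
    endo_union = np.zeros(shape, dtype=bool)
    for mask in fascicle_masks:
        area = int(mask.sum())
        if area == 0:
            continue
        eq_diam = 2.0 * np.sqrt(area / np.pi)
        radius = max(1.0, dilation_fraction * eq_diam)
        dist = ndimage.distance_transform_edt(~mask)
        dilated_union |= dist <= radius
        endo_union |= mask
    return dilated_union & ~endo_union


def fill_epineurium(
    perineurium_mask: np.ndarray,
    fascicle_masks: list[np.ndarray],
    target_outline: np.ndarray,
) -> np.ndarray:
    """Epineurium mask: interior of the nerve outline minus inner tissues.

    ``target_outline`` is either a boolean mask of the nerve interior or an
    (n, 2) array of closed-contour vertices in (row, col) pixel coordinates.
    """
    outline = np.asarray(target_outline)
    if outline.dtype == bool:
        interior = outline
    else:
        interior = skdraw.polygon2mask(perineurium_mask.shape, outline)
    endo_union = np.zeros(perineurium_mask.shape, dtype=bool)
    for mask in fascicle_masks:
        endo_union |= mask
    if np.any(endo_union & ~interior):
        raise GeometryError("nerve outline does not enclose every fascicle")
    return interior & ~perineurium_mask & ~endo_union


# ---------------------------------------------------------------------------
# Electrode
# ---------------------------------------------------------------------------

def build_fine_electrode(
    nerve_bbox_mm: tuple[float, float] | None = None,
    inner_long: float = 9.0,
    inner_short: float = 4.9,
    thickness: float = 0.65,
    height: float = 20.0,
    contact_pitch: float = 2.25,
    layer_pitch: float = 2.86,
    n_layers: int = 7,
    contacts_per_edge: int = 4,
) -> ElectrodeLayout:
    """Construct the FINE cuff contact layout.

    Contacts sit on the two long inner faces (y = +/- inner_short / 2), four
    per face per layer at 2.25 mm pitch, with 7 layers at 2.86 mm axial
    pitch, all centered on the cuff.  ``nerve_bbox_mm`` — the (width,
    height) of the nerve's bounding box — is validated against the inner
    opening when given.
    """
    if nerve_bbox_mm is not None:
        w, h = nerve_bbox_mm
        if w > inner_long or h > inner_short:
            raise GeometryError("nerve too large for cuff")
    span = (n_layers - 1) * layer_pitch
    if span > height:
        raise GeometryError("layer stack taller than the cuff")
    xs = (np.arange(contacts_per_edge) - (contacts_per_edge - 1) / 2.0) * contact_pitch
    zs = (np.arange(n_layers) - (n_layers - 1) / 2.0) * layer_pitch
    ys = np.array([-inner_short / 2.0, inner_short / 2.0])
    positions, layer_idx, edge_idx, within_idx = [], [], [], []
    for k, z in enumerate(zs):
        for e, y in enumerate(ys):
            for w, x in enumerate(xs):
                positions.append((x, y, z))
                layer_idx.append(k)
                edge_idx.append(e)
                within_idx.append(w)
    return ElectrodeLayout(
        contact_positions=np.array(positions, dtype=float),
        layer_index=np.array(layer_idx, dtype=int),
        edge_index=np.array(edge_idx, dtype=int),
        within_edge_index=np.array(within_idx, dtype=int),
        inner_long=inner_long,
        inner_short=inner_short,
        thickness=thickness,
        height=height,
        contact_pitch=contact_pitch,
        layer_pitch=layer_pitch,
        n_layers=n_layers,
        contacts_per_edge=contacts_per_edge,
    )


def electrode_mask(
    shape: tuple[int, int], pixel_pitch: float, layout: ElectrodeLayout
) -> np.ndarray:
    """Rasterize the hollow rectangular cuff wall onto a pixel grid."""
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_pitch
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_pitch
    xx, yy = np.meshgrid(x, y)
    hx_in, hy_in = layout.inner_long / 2.0, layout.inner_short / 2.0
    hx_out, hy_out = hx_in + layout.thickness, hy_in + layout.thickness
    inside_outer = (np.abs(xx) <= hx_out) & (np.abs(yy) <= hy_out)
    inside_inner = (np.abs(xx) < hx_in) & (np.abs(yy) < hy_in)
    return inside_outer & ~inside_inner


# ---------------------------------------------------------------------------
# Synthetic cross-section generator
# ---------------------------------------------------------------------------

def _ellipse_mask(xx, yy, cx, cy, a, b, theta):
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def synthesize_cross_section(
    seed: int = 0,
    n_fascicles: int = 17,
    epineurium_semi_axes: tuple[float, float] = (4.5, 2.0),
    fascicle_radius_range: tuple[float, float] = (0.15, 0.45),
    min_centroid_separation: float = 1.0,
    pixel_pitch: float = 0.02,
    perineurium_fraction: float = 0.03,
    field_of_view: float | None = None,
    layout: ElectrodeLayout | None = None,
) -> CrossSectionModel:
    """Generate a synthetic oblong median-nerve slice inside a FINE cuff.

    Deterministic given ``seed``.  Centroids sit on a jittered hexagonal
    lattice clipped to the epineurium ellipse — 17 fascicles at a >= 1 mm
    separation floor inside a 9 x 4 mm oblong is close to the hexagonal
    packing limit, so independent rejection sampling cannot place them;
    the lattice spacing and jitter bound guarantee the floor by
    construction.  Fascicles are quasi-elliptical with seeded radii,
    aspect and orientation; radii are capped by the distance to the
    epineurium boundary and to lattice neighbors so that endoneurium plus
    grown perineurium never collide.  Each perineurium annulus is rendered
    with thickness ``perineurium_fraction`` x the fascicle's equivalent
    diameter, never thinner than one pixel so the sheath survives
    rasterization.
    """
    if n_fascicles < 1:
        raise GeometryError("need at least one fascicle")
    rng = np.random.default_rng(seed)
    layout = layout or build_fine_electrode()
    ex, ey = epineurium_semi_axes
    rmin, rmax = fascicle_radius_range
    if field_of_view is None:
        field_of_view = 2 * (max(ex, ey) + layout.thickness) + 3.4
    n_px = int(round(field_of_view / pixel_pitch))

    # Perineurium thickness upper bound (used for clearances).
    peri_max = max(perineurium_fraction * 2.0 * rmax, pixel_pitch)

    # Jittered hexagonal candidate lattice.
    jitter = 0.015
    spacing = min_centroid_separation + 0.05 + 2 * np.sqrt(2) * jitter
    row_step = spacing * np.sqrt(3.0) / 2.0
    boundary_margin = rmin + peri_max + 0.05
    bx, by = ex - boundary_margin, ey - boundary_margin
    if bx <= 0 or by <= 0:
        raise PackingError("packing failed: epineurium too small")
    sites = []
    n_rows = int(np.floor(by / row_step))
    for k in range(-n_rows, n_rows + 1):
        y = k * row_step
        half_width = bx * np.sqrt(max(0.0, 1.0 - (y / by) ** 2))
        offset = 0.0 if k % 2 == 0 else spacing / 2.0
        m = 0
        while True:
            x = offset + m * spacing
            placed_any = False
            for xs in ([x, -x] if x > 0 else [x]):
                if abs(xs) <= half_width:
                    sites.append((xs, y))
                    placed_any = True
            if not placed_any:
                break
            m += 1
    if len(sites) < n_fascicles:
        raise PackingError(
            f"packing failed: {len(sites)} lattice sites for "
            f"{n_fascicles} fascicles"
        )
    sites = np.array(sorted(sites))
    chosen = sites[rng.choice(len(sites), size=n_fascicles, replace=False)]
    chosen = chosen + rng.uniform(-jitter, jitter, size=chosen.shape)

    # Per-site radius caps from boundary and nearest selected neighbor.
    placed: list[tuple[float, float, float, float, float, float]] = []
    diffs = chosen[:, None, :] - chosen[None, :, :]
    dists = np.hypot(diffs[..., 0], diffs[..., 1])
    np.fill_diagonal(dists, np.inf)
    def _inside_with_margin(cx: float, cy: float, q: float) -> bool:
        if q >= min(ex, ey):
            return False
        return (cx / (ex - q)) ** 2 + (cy / (ey - q)) ** 2 <= 1.0

    for i, (cx, cy) in enumerate(chosen):
        # largest radius keeping fascicle + sheath inside the epineurium
        lo, hi = rmin, rmax
        if _inside_with_margin(cx, cy, hi + peri_max + 0.05):
            a_boundary = hi
        else:
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if _inside_with_margin(cx, cy, mid + peri_max + 0.05):
                    lo = mid
                else:
                    hi = mid
            a_boundary = lo
        a_pair = dists[i].min() / 2.0 - peri_max - 0.025
        a_cap = min(rmax, a_boundary, a_pair)
        if a_cap < rmin:
            raise PackingError("packing failed: radius cap below minimum")
        a = rng.uniform(rmin, a_cap)
        b = a * rng.uniform(0.65, 1.0)
        theta = rng.uniform(0.0, np.pi)
        peri = max(perineurium_fraction * 2.0 * np.sqrt(a * b), pixel_pitch)
        placed.append((cx, cy, a, b, peri, theta))

    x = (np.arange(n_px) - (n_px - 1) / 2.0) * pixel_pitch
    xx, yy = np.meshgrid(x, x)
    labels = np.full((n_px, n_px), LABEL_SALINE, dtype=np.uint8)
    fasc_ids = np.zeros((n_px, n_px), dtype=np.int32)

    epi = _ellipse_mask(xx, yy, 0.0, 0.0, ex, ey, 0.0)
    labels[epi] = LABEL_EPINEURIUM
    centroids = []
    for fid, (cx, cy, a, b, peri, theta) in enumerate(placed, start=1):
        outer = _ellipse_mask(xx, yy, cx, cy, a + peri, b + peri, theta)
        inner = _ellipse_mask(xx, yy, cx, cy, a, b, theta)
        labels[outer & ~inner] = LABEL_PERINEURIUM
        labels[inner] = LABEL_ENDONEURIUM
        fasc_ids[inner] = fid
        if not inner.any():  # sub-pixel fascicle: keep at least its center
            iy = int(np.argmin(np.abs(x - cy)))
            ix = int(np.argmin(np.abs(x - cx)))
            labels[iy, ix] = LABEL_ENDONEURIUM
            fasc_ids[iy, ix] = fid
        centroids.append((cx, cy))
    # guarantee a closed >= 1 px sheath regardless of rasterization
    endo_all = labels == LABEL_ENDONEURIUM
    ring = (
        ndimage.binary_dilation(
            endo_all, structure=ndimage.generate_binary_structure(2, 2)
        )
        & ~endo_all
    )
    labels[ring] = LABEL_PERINEURIUM
    emask = electrode_mask(labels.shape, pixel_pitch, layout)
    labels[emask] = LABEL_ELECTRODE
    fasc_ids[emask] = 0
    return CrossSectionModel(
        label_image=labels,
        fascicle_ids=fasc_ids,
        pixel_pitch=pixel_pitch,
        fascicle_centroids=centroids,
    )


# ---------------------------------------------------------------------------
# Extrusion to 3-D
# ---------------------------------------------------------------------------

def extrude_volume(
    cross_section: CrossSectionModel,
    layout: ElectrodeLayout,
    axial_length: float = 30.0,
    axial_pitch: float = 0.5,
    saline_diameter: float = 11.0,
) -> NerveVolume:
    """Extrude the cross-section into a 3-D labeled voxel volume.

    The in-plane voxel pitch equals the cross-section pixel pitch.  Cuff
    material is present only within the cuff's axial span; elsewhere those
    voxels revert to saline.  Voxels beyond the saline cylinder (including
    any cuff corner that the cylinder truncates) are marked OUTSIDE and take
    no part in the electrical problem — electrically indistinguishable from
    cuff insulation.
    """
    if axial_length < layout.height:
        raise GeometryError("axial extent shorter than the cuff")
    _check_perineurium_resolved(cross_section)
    dx = cross_section.pixel_pitch
    nz = int(round(axial_length / axial_pitch))
    x, y = cross_section.pixel_coords_mm()
    xx, yy = np.meshgrid(x, y)
    rr = np.hypot(xx, yy)
    base = cross_section.label_image.copy()
    no_cuff = base.copy()
    no_cuff[no_cuff == LABEL_ELECTRODE] = LABEL_SALINE
    outside = rr > saline_diameter / 2.0

    z = (np.arange(nz) - (nz - 1) / 2.0) * axial_pitch
    in_cuff = np.abs(z) <= layout.height / 2.0
    grid = np.empty(base.shape + (nz,), dtype=np.uint8)
    grid[..., in_cuff] = np.where(outside, LABEL_OUTSIDE, base)[..., None]
    grid[..., ~in_cuff] = np.where(outside, LABEL_OUTSIDE, no_cuff)[..., None]
    return NerveVolume(
        label_grid=grid,
        voxel_pitch=(dx, dx, axial_pitch),
        layout=layout,
        cross_section=cross_section,
        saline_diameter=saline_diameter,
    )


def _check_perineurium_resolved(cs: CrossSectionModel) -> None:
    """Every fascicle must keep a closed >= 1-pixel perineurium sheath."""
    endo = cs.label_image == LABEL_ENDONEURIUM
    # 4-neighbors of endoneurium must be endoneurium or perineurium only
    grown = ndimage.binary_dilation(endo, structure=ndimage.generate_binary_structure(2, 1))
    ring = grown & ~endo
    bad = ring & (cs.label_image != LABEL_PERINEURIUM)
    if np.any(bad):
        raise ResolutionError(
            "perineurium thinner than one voxel somewhere; use a finer pitch"
        )
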