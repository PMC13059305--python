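"""Seeded synthetic OCTA slab generator with pixel-level ground truth.

Emulates a 3 x 3 mm en-face scan centered on the fovea: bright curvilinear
large vessels (arterioles/venules, ~30-60 um caliber) drawn as constant-width
tubes along smooth random paths, a capillary mesh built from a jittered
Voronoi diagram (controllable coverage), and a dark central foveal avascular
zone bounded by an ellipse with a low-order sinusoidal radial perturbation so
area, perimeter and circularity are independently controllable.  The
choriocapillaris slab is a bright noisy background with dark flow voids of
requested pixel-exact areas.

The generator is artifact plumbing, not biophysics: its job is to provide
images whose true masks, areas and lengths are known exactly, so every
downstream measurement can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from skimage.draw import line as draw_line

from .image import EnFaceImage

_TWO_PI = 2.0 * np.pi


@dataclass
class FAZShape:
    """Parametric FAZ boundary: ellipse plus sinusoidal radial perturbation.

    r(theta) = r_ellipse(theta) * (1 + amp * cos(order * theta + phase))
    """

    semi_axes_mm: tuple[float, float] = (0.36, 0.31)
    perturb_amp: float = 0.06
    perturb_order: int = 3
    phase: float = 0.0


@dataclass
class SlabSimParams:
    """Parameters of the synthetic retinal (superficial/deep) slab."""

    grid_size: int = 512
    field_mm: float = 3.0
    n_large_vessels: int = 5
    lv_caliber_um: tuple[float, float] = (30.0, 60.0)
    cap_density_target: float = 0.20
    cap_width_um: float = 15.0
    faz_shape: FAZShape = field(default_factory=FAZShape)
    noise_sd: float = 0.05
    slab: str = "superficial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64")
        if not self.field_mm > 0:
            raise ValueError("field_mm must be positive")
        lo, hi = self.lv_caliber_um
        if not (0 < lo <= hi < self.field_mm * 1000):
            raise ValueError("large-vessel caliber range must lie within (0, field width)")
        if not 0 <= self.cap_density_target < 1:
            raise ValueError("cap_density_target must lie in [0, 1)")
        a, b = self.faz_shape.semi_axes_mm
        if max(a, b) * (1 + self.faz_shape.perturb_amp) >= self.field_mm / 2:
            raise ValueError("FAZ extends beyond the scan field")

    @property
    def scale_um_per_px(self) -> float:
        return self.field_mm * 1000.0 / self.grid_size


@dataclass
class CCSimParams:
    """Parameters of the synthetic choriocapillaris slab."""

    grid_size: int = 512
    field_mm: float = 3.0
    background_mean: float = 0.62
    background_sd: float = 0.07
    void_spec: list[tuple[float, int]] = field(default_factory=list)
    lv_shadow_mask: np.ndarray | None = None
    seed: int = 0
    max_placement_retries: int = 400

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64")
        field_um2 = (self.field_mm * 1000.0) ** 2
        total = 0.0
        for area, count in self.void_spec:
            if not area > 0:
                raise ValueError("void areas must be positive")
            if count < 0:
                raise ValueError("void counts must be non-negative")
            total += area * count
        if total >= field_um2:
            raise ValueError("total requested void area exceeds the field")

    @property
    def scale_um_per_px(self) -> float:
        return self.field_mm * 1000.0 / self.grid_size


@dataclass
class GroundTruth:
    """Exact pixel-level truth accompanying a generated slab."""

    vessel_mask_true: np.ndarray | None = None
    lv_mask_true: np.ndarray | None = None
    faz_mask_true: np.ndarray | None = None
    void_mask_true: np.ndarray | None = None
    faz_area_true: float | None = None  # mm^2, from the parametric boundary
    faz_perimeter_true: float | None = None  # mm
    void_sizes_true: np.ndarray | None = None  # um^2 per component


# ---------------------------------------------------------------------------
# FAZ geometry
# ---------------------------------------------------------------------------

def faz_boundary_radius(shape: FAZShape, theta: np.ndarray) -> np.ndarray:
    """Polar radius (mm) of the FAZ boundary at the given angles."""
    a, b = shape.semi_axes_mm
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return r_ell * (1.0 + shape.perturb_amp * np.cos(shape.perturb_order * theta + shape.phase))


def faz_true_geometry(shape: FAZShape, n_theta: int = 8192) -> tuple[float, float]:
    """(area mm^2, perimeter mm) of the parametric FAZ boundary by quadrature."""
    theta = np.linspace(0.0, _TWO_PI, n_theta, endpoint=False)
    r = faz_boundary_radius(shape, theta)
    dr = np.gradient(r, theta, edge_order=2)
    dtheta = _TWO_PI / n_theta
    area = 0.5 * float(np.sum(r**2)) * dtheta
    perimeter = float(np.sum(np.sqrt(r**2 + dr**2))) * dtheta
    return area, perimeter


def _rasterize_faz(shape: FAZShape, grid: int, scale_mm: float) -> np.ndarray:
    c = (grid - 1) / 2.0
    rr, cc = np.mgrid[0:grid, 0:grid]
    dy = (rr - c) * scale_mm
    dx = (cc - c) * scale_mm
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return dist < faz_boundary_radius(shape, theta)


# ---------------------------------------------------------------------------
# vessel geometry
# ---------------------------------------------------------------------------

def _smooth_path_px(rng, grid: int, scale_mm: float, clear_radius_mm: float) -> np.ndarray:
    """Dense polyline (px coords) crossing the field, avoiding the center.

    The path is a straight chord at perpendicular distance > clear_radius
    from the field center, with a smooth sinusoidal wiggle along its normal.
    """
    c = (grid - 1) / 2.0
    half_mm = grid * scale_mm / 2.0
    for _ in range(100):
        phi = rng.uniform(0, np.pi)
        u = np.array([np.cos(phi), np.sin(phi)])  # chord direction
        nvec = np.array([-u[1], u[0]])
        max_wiggle = 0.12
        d = rng.uniform(clear_radius_mm + max_wiggle + 0.08, 0.92 * half_mm)
        d *= rng.choice([-1.0, 1.0])
        t = np.linspace(-1.6 * half_mm, 1.6 * half_mm, 600)
        amp1, amp2 = rng.uniform(0.02, max_wiggle / 2, 2)
        ph1, ph2 = rng.uniform(0, _TWO_PI, 2)
        wiggle = amp1 * np.sin(_TWO_PI * t / (2.1 * half_mm) + ph1)
        wiggle += amp2 * np.sin(_TWO_PI * t / (0.9 * half_mm) + ph2)
        pts_mm = np.outer(t, u) + np.outer(d + wiggle, nvec)
        if np.min(np.hypot(pts_mm[:, 0], pts_mm[:, 1])) <= clear_radius_mm + 0.05:
            continue
        pts_px = pts_mm / scale_mm + c
        inside = (pts_px >= 0).all(axis=1) & (pts_px <= grid - 1).all(axis=1)
        if inside.sum() < 20:
            continue
        return pts_px[inside]
    raise RuntimeError("could not place a large vessel avoiding the FAZ")


def _rasterize_polyline(points_px: np.ndarray, grid: int) -> np.ndarray:
    canvas = np.zeros((grid, grid), bool)
    pts = np.clip(np.round(points_px), 0, grid - 1).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        canvas[rr, cc] = True
    return canvas


def _tube_from_centerline(centerline: np.ndarray, radius_px: float) -> np.ndarray:
    if not centerline.any():
        return centerline.copy()
    return ndi.distance_transform_edt(~centerline) <= radius_px


def _capillary_mesh(rng, params: SlabSimParams) -> np.ndarray:
    """Jittered Voronoi mesh with edge-length density matched to the target.

    For a homogeneous Poisson point process of intensity lambda, the Voronoi
    edge length per unit area is 2*sqrt(lambda); lambda is chosen so that
    length density x drawn width hits ``cap_density_target``.
    """
    grid = params.grid_size
    scale_mm = params.field_mm / grid
    w_mm = params.cap_width_um / 1000.0
    if params.cap_density_target <= 0:
        return np.zeros((grid, grid), bool)
    length_density = params.cap_density_target / w_mm  # mm per mm^2
    lam = (length_density / 2.0) ** 2  # points per mm^2
    pad = 0.25 * grid
    ext_area_mm2 = ((grid + 2 * pad) * scale_mm) ** 2
    n_pts = max(8, int(round(lam * ext_area_mm2)))
    pts = rng.uniform(-pad, grid + pad, size=(n_pts, 2))
    vor = Voronoi(pts)
    centerline = np.zeros((grid, grid), bool)
    for v0, v1 in vor.ridge_vertices:
        if v0 < 0 or v1 < 0:
            continue
        p0, p1 = vor.vertices[v0], vor.vertices[v1]
        if max(p0.max(), p1.max()) < -2 or min(p0.min(), p1.min()) > grid + 1:
            continue
        seg_len = float(np.hypot(*(p1 - p0)))
        if seg_len < 1e-6 or seg_len > grid:
            continue
        n_sub = max(2, int(seg_len / 5.0))
        t = np.linspace(0, 1, n_sub + 1)
        base = np.outer(1 - t, p0) + np.outer(t, p1)
        normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]]) / seg_len
        jitter = rng.normal(0, 1.1, size=n_sub + 1)
        jitter[0] = jitter[-1] = 0.0
        pts_j = base + np.outer(jitter, normal)
        keep = ((pts_j >= 0) & (pts_j <= grid - 1)).all(axis=1)
        if keep.sum() >= 2:
            centerline |= _rasterize_polyline(pts_j[keep], grid)
    radius_px = params.cap_width_um / 2.0 / params.scale_um_per_px
    return _tube_from_centerline(centerline, radius_px)


def generate_vascular_slab(params: SlabSimParams) -> tuple[EnFaceImage, GroundTruth]:
    """Simulate a retinal en-face slab and its exact ground truth.

    Returns an image with bright vessels on a dark background (decorrelation
    convention), plus true whole-vessel / large-vessel / FAZ masks and the
    analytic FAZ area and perimeter.  Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    grid = params.grid_size
    scale_mm = params.field_mm / grid
    scale_um = params.scale_um_per_px

    faz_mask = _rasterize_faz(params.faz_shape, grid, scale_mm)
    faz_area, faz_perim = faz_true_geometry(params.faz_shape)
    faz_clear_mm = max(params.faz_shape.semi_axes_mm) * (1 + params.faz_shape.perturb_amp)

    lv_mask = np.zeros((grid, grid), bool)
    for _ in range(params.n_large_vessels):
        path = _smooth_path_px(rng, grid, scale_mm, faz_clear_mm)
        caliber = rng.uniform(*params.lv_caliber_um)
        centerline = _rasterize_polyline(path, grid)
        lv_mask |= _tube_from_centerline(centerline, caliber / 2.0 / scale_um)

    cap_mask = _capillary_mesh(rng, params)

    lv_mask &= ~faz_mask
    cap_mask &= ~faz_mask
    vessel_mask = lv_mask | cap_mask
    cap_only = vessel_mask & ~lv_mask

    img = np.full((grid, grid), 0.12)
    img[cap_only] = 0.58 * (1.0 + 0.08 * rng.standard_normal(int(cap_only.sum())))
    img[lv_mask] = 0.88 * (1.0 + 0.05 * rng.standard_normal(int(lv_mask.sum())))
    # slowly varying illumination field
    illum = ndi.gaussian_filter(rng.standard_normal((grid, grid)), grid / 8.0)
    if illum.std() > 0:
        illum = 1.0 + 0.04 * illum / illum.std()
        img *= illum
    img = ndi.gaussian_filter(img, 0.7)  # lateral point-spread blur
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = GroundTruth(
        vessel_mask_true=vessel_mask,
        lv_mask_true=lv_mask,
        faz_mask_true=faz_mask,
        faz_area_true=faz_area,
        faz_perimeter_true=faz_perim,
    )
    return EnFaceImage(img, scale_um, params.slab), truth


# ---------------------------------------------------------------------------
# choriocapillaris slab
# ---------------------------------------------------------------------------

def _void_offsets(n_px: int, rng) -> np.ndarray:
    """Pixel offsets of a compact, slightly irregular blob of exactly n_px."""
    radius = int(np.ceil(np.sqrt(n_px / np.pi))) + 3
    dy, dx = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    dist = np.hypot(dy, dx).ravel()
    jitter = rng.uniform(0, 0.6, size=dist.shape)
    order = np.argsort(dist + jitter, kind="stable")
    offs = np.column_stack([dy.ravel(), dx.ravel()])[order[:n_px]]
    return offs


def default_void_spec(
    field_mm: float = 3.0,
    target_fraction: float = 0.17,
    mean_size_um2: float = 450.0,
    sigma_log: float = 1.2,
    seed: int = 0,
) -> list[tuple[float, int]]:
    """Lognormal flow-void size list hitting a target area fraction.

    Defaults emulate clinically realistic choriocapillaris statistics:
    ~17% deficit fraction with mean void size ~450 um^2.
    """
    rng = np.random.default_rng(seed)
    field_um2 = (field_mm * 1000.0) ** 2
    target_um2 = target_fraction * field_um2
    mu = np.log(mean_size_um2) - sigma_log**2 / 2.0
    sizes: list[float] = []
    total = 0.0
    while total < target_um2:
        s = float(np.round(rng.lognormal(mu, sigma_log) / 25.0) * 25.0)
        s = max(s, 50.0)
        sizes.append(s)
        total += s
    return [(s, c) for s, c in zip(*np.unique(sizes, return_counts=True))]


def generate_cc_slab(params: CCSimParams) -> tuple[EnFaceImage, GroundTruth]:
    """Simulate a choriocapillaris slab: bright noisy background, dark voids.

    Voids are placed as non-touching connected components whose pixel areas
    match the requested areas exactly (to one pixel's rasterization); the
    true void mask and per-component sizes are returned.  Raises
    ``RuntimeError`` if a void cannot be placed within the retry budget.
    """
    rng = np.random.default_rng(params.seed)
    grid = params.grid_size
    px_area = params.scale_um_per_px**2

    img = rng.normal(params.background_mean, params.background_sd, size=(grid, grid))
    void_mask = np.zeros((grid, grid), bool)
    blocked = np.zeros((grid, grid), bool)  # voids + 1-px moat, keeps components separate
    if params.lv_shadow_mask is not None:
        shadow = np.asarray(params.lv_shadow_mask, bool)
        if shadow.shape != (grid, grid):
            raise ValueError("lv_shadow_mask shape differs from the grid")
        blocked |= shadow
        img[shadow] -= 0.15  # large-vessel shadow artifact

    sizes: list[float] = []
    requested = [
        float(area) for area, count in params.void_spec for _ in range(int(count))
    ]
    requested.sort(reverse=True)  # largest first: small voids fill leftover space
    for area_um2 in requested:
        n_px = max(1, int(round(area_um2 / px_area)))
        offs = _void_offsets(n_px, rng)
        placed = False
        for _ in range(params.max_placement_retries):
            cy, cx = rng.integers(2, grid - 2, size=2)
            ys, xs = offs[:, 0] + cy, offs[:, 1] + cx
            if ys.min() < 1 or xs.min() < 1 or ys.max() >= grid - 1 or xs.max() >= grid - 1:
                continue
            if blocked[ys, xs].any():
                continue
            void_mask[ys, xs] = True
            blocked[ys, xs] = True
            blocked[np.clip(ys + 1, 0, grid - 1), xs] = True
            blocked[np.clip(ys - 1, 0, grid - 1), xs] = True
            blocked[ys, np.clip(xs + 1, 0, grid - 1)] = True
            blocked[ys, np.clip(xs - 1, 0, grid - 1)] = True
            blocked[np.clip(ys + 1, 0, grid - 1), np.clip(xs + 1, 0, grid - 1)] = True
            blocked[np.clip(ys + 1, 0, grid - 1), np.clip(xs - 1, 0, grid - 1)] = True
            blocked[np.clip(ys - 1, 0, grid - 1), np.clip(xs + 1, 0, grid - 1)] = True
            blocked[np.clip(ys - 1, 0, grid - 1), np.clip(xs - 1, 0, grid - 1)] = True
            img[ys, xs] = rng.normal(0.35 * params.background_mean, 0.03, size=n_px)
            sizes.append(n_px * px_area)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {area_um2} um^2 void after "
                f"{params.max_placement_retries} retries"
            )
    img = np.clip(img, 0.0, 1.0)
    truth = GroundTruth(
        void_mask_true=void_mask,
        void_sizes_true=np.array(sizes, float),
    )
    return EnFaceImage(img, params.scale_um_per_px, "choriocapillaris"), truth
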