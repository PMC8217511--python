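"""AFM ring height-profile analysis and a synthetic height-map renderer.

Mirrors the high-speed AFM procedure used for SAS-6 self-assembly on mica:
rings are detected and circle-fitted, 40 radial profiles are drawn across the
ring circumference, each profile's height is maximum minus baseline (the
profile's own minimum), and the ring's *height difference* is the spread
(max - min) of the 40 per-profile heights.  Line scans across helical
assemblies report peak-to-peak spoke spacings on baseline-subtracted
("relative height") profiles.

Height maps are plain 2D float arrays in nm with a pixel size in nm/px
(:class:`HeightMap`); they can be written/read as 32-bit TIFF with a JSON
sidecar carrying the pixel size.

The renderer draws an assembly from :mod:`cartwheel.geometry` as
Gaussian-broadened ridges: closed rings and arcs as the circular hub through
the unit vertices plus radial spokes, helices as their landing projection
(axial backbone with lateral spokes), emulating how the molecules present to
the tip once adsorbed flat on mica.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from . import geometry
from .geometry import PolymerAssembly

__all__ = [
    "HeightMap",
    "RingMeasurement",
    "DEFAULT_PIXEL_NM",
    "CREST_HEIGHT_NM",
    "render_heightmap",
    "add_noise",
    "fit_circle",
    "detect_rings",
    "radial_profiles",
    "profile_height",
    "ring_height_difference",
    "measure_ring",
    "line_scan_spacings",
]

#: Default synthetic pixel size: a 1200 nm field over 1024 pixels.
DEFAULT_PIXEL_NM = 1200.0 / 1024.0

#: Default crest height of rendered ridges (nm), the scale of a SAS-6
#: homodimer lying on mica.
CREST_HEIGHT_NM = 4.5

#: Intrinsic ridge half-width before tip broadening (nm).
RIDGE_SIGMA_NM = 1.0

#: Spoke ridges are drawn at this fraction of the hub crest height: the
#: coiled-coil spoke is a thinner feature than the globular-head hub.
SPOKE_CREST_FRACTION = 0.7

N_PROFILES = 40
PROFILE_HALF_WIDTH_NM = 8.0


@dataclass
class HeightMap:
    """2D height grid (nm) with its pixel size (nm/px).

    ``origin`` locates grid index (0, 0) in the physical (x, y) frame; x maps
    to columns and y to rows."""

    heights: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def to_pixels(self, xy: np.ndarray) -> np.ndarray:
        """Physical (x, y) nm -> fractional (row, col)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        col = (xy[:, 0] - self.origin[0]) / self.pixel_size
        row = (xy[:, 1] - self.origin[1]) / self.pixel_size
        return np.column_stack([row, col])

    def sample(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear height at physical coordinates (nm)."""
        rc = self.to_pixels(xy)
        return ndimage.map_coordinates(
            self.heights, rc.T, order=1, mode="nearest"
        )

    def write_tiff(self, path: str) -> None:
        import tifffile

        tifffile.imwrite(path, self.heights.astype(np.float32))
        with open(str(path) + ".json", "w") as fh:
            json.dump({"pixel_size_nm": self.pixel_size, "origin": list(self.origin)}, fh)

    @classmethod
    def read_tiff(cls, path: str) -> "HeightMap":
        import tifffile

        heights = tifffile.imread(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(heights, meta["pixel_size_nm"], tuple(meta.get("origin", (0.0, 0.0))))


@dataclass
class RingMeasurement:
    """Circle fit plus the 40-profile height analysis of one ring."""

    center: tuple[float, float]
    radius: float
    profile_heights: np.ndarray
    height_difference: float

    def __post_init__(self):
        self.profile_heights = np.asarray(self.profile_heights, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.profile_heights.size != N_PROFILES:
            raise ValueError(f"expected {N_PROFILES} profile heights")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _segment_distance(px, py, a, b):
    """Distance from grid points to segment a-b (2D)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-18:
        return np.hypot(px - a[0], py - a[1])
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def render_heightmap(
    assembly: PolymerAssembly | None,
    tip_sigma: float = 2.0,
    pixel_size: float = DEFAULT_PIXEL_NM,
    spoke_length: float | None = None,
    field_nm: float = 100.0,
    crest: float = CREST_HEIGHT_NM,
    center: tuple[float, float] | None = None,
    heightmap: HeightMap | None = None,
) -> HeightMap:
    """Render an assembly as a synthetic AFM height map.

    Rings/arcs are drawn as a circular hub ridge through the unit vertex
    circle with radial spokes pointing outward; helices as their mica-landing
    projection: a backbone along the helix axis plus lateral spokes at the
    axial positions given by :func:`cartwheel.geometry.landing_spoke_pattern`.
    Ridges have a Gaussian cross-section (sigma ``RIDGE_SIGMA_NM``) with the
    given crest height; the map is then blurred by ``tip_sigma`` (tip
    broadening) with crest height preserved.  Pass ``heightmap`` to draw onto
    an existing map (used by the dataset generator); overlapping ridges take
    the maximum, not the sum.
    """
    if tip_sigma < 0:
        raise ValueError("tip_sigma must be >= 0")
    if heightmap is None:
        npx = int(round(field_nm / pixel_size))
        heightmap = HeightMap(np.zeros((npx, npx)), pixel_size)
    if assembly is None or not assembly.units:
        return heightmap

    segments = _assembly_segments(assembly, spoke_length, center, heightmap)
    h = heightmap.heights
    nrow, ncol = h.shape
    ys = heightmap.origin[1] + np.arange(nrow) * heightmap.pixel_size
    xs = heightmap.origin[0] + np.arange(ncol) * heightmap.pixel_size
    px, py = np.meshgrid(xs, ys)

    lo_x, lo_y = xs[0], ys[0]
    hi_x, hi_y = xs[-1], ys[-1]
    clipped = False
    canvas = np.zeros_like(h)
    margin = 4.0 * (RIDGE_SIGMA_NM + tip_sigma)
    for kind, a, b, scale in segments:
        if kind == "arc":
            radius = b[0]
            box = [(a[0] - radius, a[1] - radius), (a[0] + radius, a[1] + radius)]
        else:
            box = [a, b]
        for p in box:
            if not (lo_x <= p[0] <= hi_x and lo_y <= p[1] <= hi_y):
                clipped = True
        bx = [p[0] for p in box]
        by = [p[1] for p in box]
        r0 = max(0, int((min(by) - margin - ys[0]) / heightmap.pixel_size))
        r1 = min(nrow, int((max(by) + margin - ys[0]) / heightmap.pixel_size) + 2)
        c0 = max(0, int((min(bx) - margin - xs[0]) / heightmap.pixel_size))
        c1 = min(ncol, int((max(bx) + margin - xs[0]) / heightmap.pixel_size) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        if kind == "arc":
            # a = centre, b = (radius, theta0, theta1) packed
            d = _arc_distance(px[r0:r1, c0:c1], py[r0:r1, c0:c1], a, b)
        else:
            d = _segment_distance(px[r0:r1, c0:c1], py[r0:r1, c0:c1], a, b)
        ridge = scale * crest * np.exp(-(d**2) / (2.0 * RIDGE_SIGMA_NM**2))
        np.maximum(canvas[r0:r1, c0:c1], ridge, out=canvas[r0:r1, c0:c1])
    if clipped:
        warnings.warn("assembly extends beyond the field of view; ridges clipped",
                      RuntimeWarning, stacklevel=2)
    if tip_sigma > 0:
        blurred = ndimage.gaussian_filter(canvas, tip_sigma / heightmap.pixel_size)
        peak = blurred.max()
        if peak > 0:
            blurred *= canvas.max() / peak  # tip broadening widens, crest kept
        canvas = blurred
    np.maximum(h, canvas, out=h)
    return heightmap


def _arc_distance(px, py, centre, packed):
    radius, th0, th1 = packed
    ang = np.arctan2(py - centre[1], px - centre[0])
    rel = (ang - th0) % (2 * math.pi)
    span = (th1 - th0) % (2 * math.pi)
    if span == 0:
        span = 2 * math.pi
    on_arc = rel <= span
    r = np.hypot(px - centre[0], py - centre[1])
    d_arc = np.abs(r - radius)
    # distance to arc endpoints for points outside the angular span
    e0 = centre + radius * np.array([math.cos(th0), math.sin(th0)])
    e1 = centre + radius * np.array([math.cos(th0 + span), math.sin(th0 + span)])
    d_end = np.minimum(np.hypot(px - e0[0], py - e0[1]),
                       np.hypot(px - e1[0], py - e1[1]))
    return np.where(on_arc, d_arc, d_end)


def _assembly_segments(assembly, spoke_length, center, hmap):
    """Flatten an assembly into 2D ridge primitives ('seg' or 'arc')."""
    cls = assembly.classification
    if center is None:
        mid = (np.array(hmap.shape[::-1]) - 1) * hmap.pixel_size / 2.0
        center = (hmap.origin[0] + mid[0], hmap.origin[1] + mid[1])
    center = np.asarray(center, dtype=float)

    segments: list[tuple[str, np.ndarray, object, float]] = []
    if cls.kind == "helix":
        pattern = geometry.landing_spoke_pattern(assembly, visible_sector=30.0)
        length = assembly.units[0].spoke_length if spoke_length is None else spoke_length
        axials = [p for p, _ in pattern]
        lo = min(axials, default=0.0)
        hi = max(axials, default=0.0)
        half = (hi - lo) / 2.0
        a = center + np.array([-half, 0.0])
        segments.append(("seg", a, center + np.array([half, 0.0]), 1.0))
        for axial, side in pattern:
            base = center + np.array([axial - lo - half, 0.0])
            dy = length if side == "left" else -length
            segments.append(("seg", base, base + np.array([0.0, dy]), SPOKE_CREST_FRACTION))
        return segments

    # ring or arc: hub drawn as circle/arc through the unit vertex circle
    origins = assembly.origins()[:, :2]
    if len(origins) == 1:
        p = center
        segments.append(("seg", p, p, 1.0))
        return segments
    if cls.kind == "closed_ring":
        radius = geometry.ring_diameter(
            float(np.linalg.norm(origins[1] - origins[0])), cls.n_units
        ) / 2.0
        hub_centre = origins.mean(axis=0)
        shift = center - hub_centre
        segments.append(("arc", center, (radius, 0.0, 2 * math.pi), 1.0))
    else:
        # open arc: circle through first/mid/last vertex, spanning the units
        hub_centre, radius = fit_circle(origins)
        hub_centre = np.asarray(hub_centre)
        shift = center - _centroid_on_map(origins)
        th = np.unwrap(np.arctan2(*(origins - hub_centre).T[::-1]))
        segments.append(
            ("arc", hub_centre + shift, (radius, float(th.min()), float(th.max())), 1.0)
        )
    for unit in assembly.units:
        length = unit.spoke_length if spoke_length is None else spoke_length
        base = unit.frame_origin[:2] + shift
        tip = base + length * _unit2(unit.spoke_direction[:2])
        segments.append(("seg", base, tip, SPOKE_CREST_FRACTION))
    return segments


def _centroid_on_map(origins):
    return origins.mean(axis=0)


def _unit2(v):
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0])


def add_noise(hmap: HeightMap, sigma: float, seed: int) -> HeightMap:
    """Add i.i.d. Gaussian height noise (nm); deterministic for a fixed seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return HeightMap(hmap.heights.copy(), hmap.pixel_size, hmap.origin)
    rng = np.random.default_rng(seed)
    noisy = hmap.heights + rng.normal(0.0, sigma, size=hmap.heights.shape)
    return HeightMap(noisy, hmap.pixel_size, hmap.origin)


# ---------------------------------------------------------------------------
# circle fitting and ring detection
# ---------------------------------------------------------------------------

def fit_circle(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Taubin algebraic circle fit; returns ((cx, cy), radius).

    Preferred over the Kasa fit for its much smaller radius bias on partial
    arcs.  Raises for fewer than 3 points or (near-)collinear input."""
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3 or P.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) points")
    c = P.mean(axis=0)
    X = P - c
    x, y = X[:, 0], X[:, 1]
    z = x * x + y * y
    Mxx, Myy, Mxy = (x * x).mean(), (y * y).mean(), (x * y).mean()
    Mxz, Myz, Mzz, Mz = (x * z).mean(), (y * z).mean(), (z * z).mean(), z.mean()
    cov_xy = Mxx * Myy - Mxy * Mxy
    var_z = Mzz - Mz * Mz
    # Newton iteration on the Taubin characteristic polynomial (Chernov)
    a3 = 4.0 * Mz
    a2 = -3.0 * Mz * Mz - Mzz
    a1 = var_z * Mz + 4.0 * cov_xy * Mz - Mxz * Mxz - Myz * Myz
    a0 = (Mxz * (Mxz * Myy - Myz * Mxy)
          + Myz * (Myz * Mxx - Mxz * Mxy) - var_z * cov_xy)
    eta = 0.0
    y_new = 1e30
    for _ in range(30):
        y_old = y_new
        y_new = a0 + eta * (a1 + eta * (a2 + eta * a3))
        if abs(y_new) > abs(y_old):
            eta = 0.0
            break
        dy = a1 + eta * (2.0 * a2 + eta * 3.0 * a3)
        if dy == 0:
            break
        eta_old = eta
        eta = eta_old - y_new / dy
        if eta < 0:
            eta = 0.0
        if abs(eta - eta_old) <= 1e-14 * (1.0 + abs(eta)):
            break
    det = eta * eta - eta * Mz + cov_xy
    if abs(det) < 1e-14:
        raise ValueError("collinear points: circle fit is degenerate")
    bx = (Mxz * (Myy - eta) - Myz * Mxy) / det / 2.0
    by = (Myz * (Mxx - eta) - Mxz * Mxy) / det / 2.0
    r2 = bx * bx + by * by + Mz
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return (float(c[0] + bx), float(c[1] + by)), float(math.sqrt(r2))


def detect_rings(
    hmap: HeightMap,
    threshold: float = 2.0,
    min_radius: float = 6.0,
    max_radius: float = 20.0,
    min_coverage: float = 0.70,
    max_residual: float = 1.5,
) -> list[RingMeasurement]:
    """Detect ring particles: above-threshold components with annular topology.

    A connected component qualifies when its crest points cover >= 70% of the
    angular range about their circle-fit centre, the fit residual is small,
    and the fitted radius lies in [min_radius, max_radius].  Arcs (and the
    linear assemblies formed when ring closure is blocked) fail the coverage
    or residual filter.  Each accepted ring is measured with the 40-profile
    height analysis.
    """
    if threshold <= 0 or min_radius <= 0 or min_radius >= max_radius:
        raise ValueError("thresholds must be positive with min_radius < max_radius")
    mask = hmap.heights > threshold
    labels, n = ndimage.label(mask)
    out = []
    for lbl in range(1, n + 1):
        rows, cols = np.nonzero(labels == lbl)
        if len(rows) < 12:
            continue
        xs = hmap.origin[0] + cols * hmap.pixel_size
        ys = hmap.origin[1] + rows * hmap.pixel_size
        pts = np.column_stack([xs, ys])
        crest = _crest_points(pts, hmap.heights[rows, cols])
        if len(crest) < 8:
            continue
        try:
            centre, radius = fit_circle(crest)
        except ValueError:
            continue
        if not (min_radius <= radius <= max_radius):
            continue
        resid = np.abs(np.hypot(*(crest - centre).T) - radius)
        if resid.mean() > max_residual:
            continue
        ang = np.arctan2(crest[:, 1] - centre[1], crest[:, 0] - centre[0])
        bins = np.unique(((ang + math.pi) / (2 * math.pi) * 36).astype(int) % 36)
        if len(bins) / 36.0 < min_coverage:
            continue
        centre, radius = refine_ring_fit(hmap, centre, radius)
        out.append(measure_ring(hmap, centre, radius))
    return out


def refine_ring_fit(
    hmap: HeightMap,
    center: tuple[float, float],
    radius: float,
    half_width: float = 5.0,
    k: int = N_PROFILES,
    n_iter: int = 2,
) -> tuple[tuple[float, float], float]:
    """Refine a candidate circle by relocating the crest along radial rays.

    The per-ray crest is the peak of the (lightly smoothed) height profile
    within ``half_width`` of the candidate radius; rays whose crest is pulled
    off the ring (e.g. along a spoke ridge, whose crest height matches the
    hub's) are rejected by a median-absolute-deviation filter before the
    Taubin refit."""
    smooth = HeightMap(
        ndimage.gaussian_filter(hmap.heights, 1.0), hmap.pixel_size, hmap.origin
    )
    for _ in range(n_iter):
        cx, cy = center
        rr = np.linspace(max(radius - half_width, 0.5), radius + half_width, 64)
        crest = []
        for j in range(k):
            th = 2.0 * math.pi * j / k
            direction = np.array([math.cos(th), math.sin(th)])
            xy = np.array([cx, cy]) + rr[:, None] * direction
            prof = smooth.sample(xy)
            span = prof.max() - prof.min()
            peaks, _ = signal.find_peaks(prof, prominence=0.2 * span)
            # spokes project outward, so the hub crest is the innermost
            # strong peak along the ray, not necessarily the global max
            strong = [p for p in peaks if prof[p] >= prof.max() - 0.3 * span]
            idx = strong[0] if strong else int(np.argmax(prof))
            crest.append(np.array([cx, cy]) + rr[idx] * direction)
        crest = np.array(crest)
        resid = np.abs(np.hypot(*(crest - center).T) - radius)
        mad = np.median(np.abs(resid - np.median(resid)))
        keep = resid <= np.median(resid) + 3.0 * max(mad, 0.1)
        if keep.sum() >= 8:
            crest = crest[keep]
        try:
            center, radius = fit_circle(crest)
        except ValueError:
            break
    return center, radius


def _crest_points(pts: np.ndarray, heights: np.ndarray) -> np.ndarray:
    """Per-angular-bin highest point of a blob, about its centroid."""
    centre = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    bins = ((ang + math.pi) / (2 * math.pi) * 36).astype(int) % 36
    crest = []
    for b in range(36):
        sel = bins == b
        if sel.any():
            crest.append(pts[sel][np.argmax(heights[sel])])
    return np.array(crest)


# ---------------------------------------------------------------------------
# profiles and heights
# ---------------------------------------------------------------------------

def radial_profiles(
    hmap: HeightMap,
    center: tuple[float, float],
    radius: float,
    k: int = N_PROFILES,
    half_width: float = PROFILE_HALF_WIDTH_NM,
    samples: int = 64,
) -> np.ndarray:
    """k radial height profiles across the ring circumference.

    Profile j runs along the ray at angle 360*j/k (from +x, counterclockwise)
    from ``radius - half_width`` to ``radius + half_width``, sampled with
    bilinear interpolation.  Returns shape (k, samples)."""
    if k < 4:
        raise ValueError("need at least 4 profiles")
    cx, cy = center
    r_in = max(radius - half_width, 0.0)
    rr = np.linspace(r_in, radius + half_width, samples)
    profs = np.empty((k, samples))
    hi_x = hmap.origin[0] + (hmap.shape[1] - 1) * hmap.pixel_size
    hi_y = hmap.origin[1] + (hmap.shape[0] - 1) * hmap.pixel_size
    truncated = False
    for j in range(k):
        th = 2.0 * math.pi * j / k
        xy = np.column_stack([cx + rr * math.cos(th), cy + rr * math.sin(th)])
        if (xy[:, 0].min() < hmap.origin[0] or xy[:, 0].max() > hi_x
                or xy[:, 1].min() < hmap.origin[1] or xy[:, 1].max() > hi_y):
            truncated = True
        profs[j] = hmap.sample(xy)
    if truncated:
        warnings.warn("some radial profiles extend beyond the map and were "
                      "sampled with edge padding", RuntimeWarning, stacklevel=2)
    return profs


def profile_height(profile: np.ndarray) -> float:
    """Height of one radial profile: maximum minus baseline, where the
    baseline is the profile's own lowest value.  Invariant to any constant
    offset of the whole map."""
    p = np.asarray(profile, dtype=float)
    if p.size == 0:
        raise ValueError("empty profile")
    return float(p.max() - p.min())


def ring_height_difference(profile_heights: np.ndarray) -> float:
    """Spread of the per-profile heights around one ring (max - min); the
    quantity reported per ring by the AFM assay."""
    h = np.asarray(profile_heights, dtype=float)
    return float(h.max() - h.min())


def measure_ring(
    hmap: HeightMap,
    center: tuple[float, float],
    radius: float,
    half_width: float = PROFILE_HALF_WIDTH_NM,
) -> RingMeasurement:
    """Full per-ring analysis: 40 radial profiles -> heights -> difference."""
    profs = radial_profiles(hmap, center, radius, k=N_PROFILES, half_width=half_width)
    heights = np.array([profile_height(p) for p in profs])
    return RingMeasurement(
        center=(float(center[0]), float(center[1])),
        radius=float(radius),
        profile_heights=heights,
        height_difference=ring_height_difference(heights),
    )


# ---------------------------------------------------------------------------
# line scans
# ---------------------------------------------------------------------------

def line_scan_spacings(
    hmap: HeightMap,
    start: tuple[float, float],
    end: tuple[float, float],
    min_prominence: float = 0.5,
    samples_per_nm: float = 4.0,
) -> list[float]:
    """Consecutive peak-to-peak distances (nm) along a line scan.

    The scan is baseline-subtracted to *relative height* (minimum set to
    zero); peaks are local maxima with at least ``min_prominence`` nm
    prominence.  Fewer than two peaks yields an empty list.  Used to read
    spoke-to-spoke spacings off helical assemblies (26 nm same-side for the
    fourfold helix; 13 nm between opposite sides)."""
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    length = float(np.linalg.norm(b - a))
    n = max(int(length * samples_per_nm), 2)
    ts = np.linspace(0.0, 1.0, n)
    xy = a + ts[:, None] * (b - a)
    prof = hmap.sample(xy)
    rel = prof - prof.min()
    peaks, _ = signal.find_peaks(rel, prominence=min_prominence)
    if len(peaks) < 2:
        return []
    pos = ts[peaks] * length
    return list(np.diff(pos))
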