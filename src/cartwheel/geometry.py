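"""Rigid-body propagation model of SAS-6 oligomer architecture.

SAS-6 homodimers associate head-to-head through a weak N-terminal interface.
Treating each homodimer as a rigid unit, the whole higher-order oligomer is
generated by repeated application of a single inter-unit rigid motion (the
*step*).  Decomposing that step as a screw transform — a rotation by angle
theta about an axis plus a rise d along it — predicts the architecture:

* rise ~ 0 and 360/theta integer n  ->  closed ring of n units
  (the native ~40 degree bend gives the ninefold, ~23 nm cartwheel ring);
* rise appreciably non-zero        ->  helix with pitch = rise * 360/theta
  (a 90 degree twist with 6.5 nm rise gives the fourfold, 26 nm-pitch helix);
* otherwise                        ->  open arc.

Lengths are nanometres and angles degrees throughout the public contract;
frames are right-handed, helix handedness is the sign of the rise along the
(canonically oriented) axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CHORD_NM",
    "SPOKE_LENGTH_NM",
    "ScrewTransform",
    "HomodimerUnit",
    "Classification",
    "PolymerAssembly",
    "InvalidTransformError",
    "DegenerateStepError",
    "compose",
    "make_transform",
    "screw_transform_matrix",
    "screw_decompose",
    "interface_step",
    "default_seed_unit",
    "propagate",
    "classify_step",
    "ring_diameter",
    "helix_parameters",
    "landing_spoke_pattern",
    "max_same_side_spacing",
]

#: Inter-vertex chord of neighbouring homodimer head interfaces, chosen so a
#: ninefold ring has a 23 nm vertex-circle diameter: 23 * sin(pi/9) = 7.87 nm.
CHORD_NM = 7.87

#: Coiled-coil spoke length used for rendering/export (the ring and pitch
#: scales are constrained by the data; the spoke length is a drawing choice).
SPOKE_LENGTH_NM = 10.0

#: A ring is declared closed when the frame one-past-last returns to the seed
#: within this gap (nm) and orientation mismatch (degrees).
CLOSURE_GAP_NM = 0.5
CLOSURE_ANGLE_DEG = 5.0

MAX_UNITS = 200
N_MIN, N_MAX = 3, 48

_ANGLE_TOL_DEG = 1e-7  # below this the rotation part is treated as identity


class InvalidTransformError(ValueError):
    """Raised when a 4x4 matrix is not a proper rigid motion."""


class DegenerateStepError(ValueError):
    """Raised when a step has neither rotation nor translation."""


# ---------------------------------------------------------------------------
# rigid motions as 4x4 homogeneous matrices
# ---------------------------------------------------------------------------

def make_transform(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Assemble a 4x4 rigid motion from a 3x3 rotation and a translation."""
    T = np.eye(4)
    T[:3, :3] = np.asarray(rotation, dtype=float)
    T[:3, 3] = np.asarray(translation, dtype=float)
    _check_rigid(T)
    return T


def _check_rigid(T: np.ndarray) -> None:
    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4):
        raise InvalidTransformError(f"expected 4x4 matrix, got {T.shape}")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise InvalidTransformError("rotation part is not orthonormal")
    if np.linalg.det(R) < 0:
        raise InvalidTransformError("rotation part is improper (det < 0)")
    if not np.allclose(T[3], [0.0, 0.0, 0.0, 1.0]):
        raise InvalidTransformError("bottom row must be [0, 0, 0, 1]")


def compose(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Rigid motion equal to applying ``t2`` after ``t1``."""
    _check_rigid(t1)
    _check_rigid(t2)
    return t2 @ t1


def apply_transform(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a rigid motion to an (n, 3) array (or single 3-vector)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    out = p @ T[:3, :3].T + T[:3, 3]
    return out[0] if np.asarray(points).ndim == 1 else out


# ---------------------------------------------------------------------------
# screw decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScrewTransform:
    """A rigid motion as rotation about an axis plus rise along it.

    Attributes
    ----------
    rotation_angle : float
        Rotation in degrees, in [0, 180].
    axis : ndarray
        Unit 3-vector of the screw axis.
    axis_point : ndarray
        A point (nm) on the axis, chosen perpendicular to ``axis`` from the
        origin (so it is unique).
    rise : float
        Signed translation (nm) along ``axis`` per application.
    residual_translation : float
        Norm of any translation component that could not be folded into the
        screw (zero for a true rigid motion; kept as a diagnostic).
    """

    rotation_angle: float
    axis: np.ndarray
    axis_point: np.ndarray
    rise: float
    residual_translation: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise InvalidTransformError("screw axis must be a unit vector")

    def matrix(self) -> np.ndarray:
        """Reconstruct the 4x4 rigid motion this screw describes."""
        return screw_transform_matrix(
            self.rotation_angle, self.axis, self.axis_point, self.rise
        )


def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = math.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def screw_transform_matrix(
    angle_deg: float,
    axis: np.ndarray,
    axis_point: np.ndarray,
    rise: float,
) -> np.ndarray:
    """4x4 matrix of a screw: rotate about the axis through ``axis_point``,
    then translate by ``rise`` along the axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    c = np.asarray(axis_point, dtype=float)
    R = _axis_angle_matrix(a, angle_deg)
    t = c - R @ c + rise * a
    return make_transform(R, t)


def screw_decompose(T: np.ndarray) -> ScrewTransform:
    """Decompose a rigid motion into screw parameters.

    The rotation angle is reported in [0, 180] degrees.  A pure translation
    (angle ~ 0) is handled as the special case with the axis along the
    translation.  At angle ~ 180 the axis sign is ambiguous; it is chosen so
    the rise is non-negative, with a warning.
    """
    _check_rigid(T)
    R = T[:3, :3]
    t = T[:3, 3]

    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = math.degrees(math.acos(cos_th))

    if angle < _ANGLE_TOL_DEG:
        # pure translation
        norm = np.linalg.norm(t)
        if norm < 1e-15:
            axis = np.array([0.0, 0.0, 1.0])
            return ScrewTransform(0.0, axis, np.zeros(3), 0.0)
        axis = t / norm
        return ScrewTransform(0.0, axis, np.zeros(3), float(norm))

    if angle > 180.0 - 1e-9 * 180.0 / math.pi:
        warnings.warn(
            "rotation angle within tolerance of 180 degrees: axis sign is "
            "ambiguous; choosing the sign that makes the rise non-negative",
            RuntimeWarning,
            stacklevel=2,
        )
        # R is symmetric; axis from the +1 eigenvector
        w, v = np.linalg.eigh(R)
        axis = v[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
        if float(axis @ t) < 0:
            axis = -axis
    else:
        skew = (R - R.T) / (2.0 * math.sin(math.radians(angle)))
        axis = np.array([skew[2, 1], skew[0, 2], skew[1, 0]])
        axis = axis / np.linalg.norm(axis)

    rise = float(axis @ t)
    t_perp = t - rise * axis
    # axis point c solves (I - R) c = t_perp in the plane normal to the axis
    th = math.radians(angle)
    c = 0.5 * (t_perp + np.cross(axis, t_perp) / math.tan(th / 2.0))
    residual = float(np.linalg.norm((np.eye(3) - R) @ c - t_perp))
    return ScrewTransform(float(angle), axis, c, rise, residual)


# ---------------------------------------------------------------------------
# homodimer units and assemblies
# ---------------------------------------------------------------------------

@dataclass
class HomodimerUnit:
    """One rigid SAS-6 homodimer: a frame at the head-to-head vertex plus the
    direction and length of its coiled-coil spoke."""

    frame_origin: np.ndarray
    frame_orientation: np.ndarray
    spoke_direction: np.ndarray
    spoke_length: float = SPOKE_LENGTH_NM

    def __post_init__(self):
        self.frame_origin = np.asarray(self.frame_origin, dtype=float)
        self.frame_orientation = np.asarray(self.frame_orientation, dtype=float)
        self.spoke_direction = np.asarray(self.spoke_direction, dtype=float)
        R = self.frame_orientation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise InvalidTransformError("frame_orientation must be a proper rotation")
        n = np.linalg.norm(self.spoke_direction)
        if n == 0:
            raise ValueError("spoke_direction must be non-zero")
        self.spoke_direction = self.spoke_direction / n
        if self.spoke_length <= 0:
            raise ValueError("spoke_length must be positive")

    def spoke_tip(self) -> np.ndarray:
        return self.frame_origin + self.spoke_length * self.spoke_direction

    def transformed(self, T: np.ndarray) -> "HomodimerUnit":
        R = T[:3, :3]
        return HomodimerUnit(
            frame_origin=apply_transform(T, self.frame_origin),
            frame_orientation=R @ self.frame_orientation,
            spoke_direction=R @ self.spoke_direction,
            spoke_length=self.spoke_length,
        )


@dataclass(frozen=True)
class Classification:
    """Architecture label of an assembly.

    kind is one of ``closed_ring`` (with ``n_units``), ``open_arc`` (with
    ``arc_angle`` in degrees) or ``helix`` (with ``pitch`` nm,
    ``units_per_turn`` and ``helix_radius`` nm).
    """

    kind: Literal["closed_ring", "open_arc", "helix"]
    n_units: int | None = None
    arc_angle: float | None = None
    pitch: float | None = None
    units_per_turn: float | None = None
    helix_radius: float | None = None


@dataclass
class PolymerAssembly:
    units: list[HomodimerUnit]
    classification: Classification
    closure_gap: float
    step: ScrewTransform | None = None

    def origins(self) -> np.ndarray:
        return np.array([u.frame_origin for u in self.units])


def interface_step(
    rotation_deg: float,
    rise_nm: float = 0.0,
    chord_nm: float = CHORD_NM,
) -> np.ndarray:
    """Build the inter-unit step for a given per-interface geometry.

    The step is the screw about the assembly super-axis (z): rotation by
    ``rotation_deg`` (the inter-unit bend for rings, the twist for helices)
    plus ``rise_nm`` along the axis, positioned so that consecutive unit
    origins are ``chord_nm`` apart.  The seed unit is expected at the origin
    (see :func:`default_seed_unit`).

    With rotation 40 and rise 0 this closes into the ninefold ring; with
    rotation 90 and rise 6.5 it generates the fourfold helix of 26 nm pitch.
    """
    if chord_nm <= 0:
        raise ValueError("chord_nm must be positive")
    if abs(rise_nm) > chord_nm:
        raise ValueError("rise cannot exceed the inter-unit chord")
    if abs(rotation_deg) < _ANGLE_TOL_DEG:
        # straight filament: pure translation, chord in-plane plus rise
        dx = math.sqrt(chord_nm**2 - rise_nm**2)
        return make_transform(np.eye(3), [dx, 0.0, rise_nm])
    half = math.radians(abs(rotation_deg)) / 2.0
    in_plane = math.sqrt(chord_nm**2 - rise_nm**2)
    radius = in_plane / (2.0 * math.sin(half))
    axis = np.array([0.0, 0.0, 1.0])
    axis_point = np.array([0.0, radius, 0.0])  # axis offset so seed sits on the helix
    return screw_transform_matrix(rotation_deg, axis, axis_point, rise_nm)


def default_seed_unit(
    spoke_length: float = SPOKE_LENGTH_NM,
    step: np.ndarray | None = None,
) -> HomodimerUnit:
    """Seed homodimer at the origin with its spoke pointing radially outward
    from the assembly axis implied by ``step`` (or along -y by default)."""
    direction = np.array([0.0, -1.0, 0.0])
    if step is not None:
        screw = screw_decompose(step)
        if screw.rotation_angle >= _ANGLE_TOL_DEG:
            radial = -screw.axis_point  # from axis toward the seed origin
            n = np.linalg.norm(radial)
            if n > 1e-12:
                direction = radial / n
    return HomodimerUnit(
        frame_origin=np.zeros(3),
        frame_orientation=np.eye(3),
        spoke_direction=direction,
        spoke_length=spoke_length,
    )


def classify_step(
    step: np.ndarray | ScrewTransform,
    tol_gap: float = CLOSURE_GAP_NM,
    tol_angle: float = CLOSURE_ANGLE_DEG,
    chord_nm: float = CHORD_NM,
) -> Classification:
    """Classify the architecture generated by repeating ``step``.

    A closed ring of n units is declared when the rise is below the closure
    gap tolerance and n applications of the step return the seed frame within
    ``tol_gap`` nm and ``tol_angle`` degrees, for some integer n in [3, 48]
    (ties between neighbouring n broken toward the smaller closure gap).
    A step with appreciable rise is a helix; anything else is an open arc.
    A step with neither rotation nor translation is degenerate.
    """
    if tol_gap <= 0 or tol_angle <= 0:
        raise ValueError("tolerances must be positive")
    if isinstance(step, ScrewTransform):
        screw = step
        T = step.matrix()
    else:
        T = np.asarray(step, dtype=float)
        screw = screw_decompose(T)

    angle = screw.rotation_angle
    if angle < _ANGLE_TOL_DEG:
        if np.linalg.norm(T[:3, 3]) < 1e-12:
            raise DegenerateStepError("step has neither rotation nor translation")
        # straight filament (bend 0): an open arc of zero curvature
        return Classification(kind="open_arc", arc_angle=0.0)

    if abs(screw.rise) >= tol_gap:
        pitch, upt, radius = helix_parameters(screw)
        return Classification(
            kind="helix", pitch=pitch, units_per_turn=upt, helix_radius=radius
        )

    # candidate ring orders: nearest integers to 360/angle
    ratio = 360.0 / angle
    candidates = sorted(
        {n for n in (math.floor(ratio), math.ceil(ratio)) if N_MIN <= n <= N_MAX}
    )
    best: tuple[float, int] | None = None
    for n in candidates:
        Tn = np.linalg.matrix_power(T, n)
        gap = float(np.linalg.norm(apply_transform(Tn, np.zeros(3))))
        mis = screw_decompose_angle_only(Tn)
        if gap <= tol_gap and mis <= tol_angle:
            if best is None or gap < best[0]:
                best = (gap, n)
    if best is not None:
        return Classification(kind="closed_ring", n_units=best[1])
    # ring-plane step that does not close: open arc spanning n_app * angle
    return Classification(kind="open_arc", arc_angle=angle)


def screw_decompose_angle_only(T: np.ndarray) -> float:
    """Rotation angle (degrees) of the rotation part of a rigid motion."""
    cos_th = np.clip((np.trace(T[:3, :3]) - 1.0) / 2.0, -1.0, 1.0)
    return math.degrees(math.acos(cos_th))


def propagate(
    seed: HomodimerUnit,
    step: np.ndarray | ScrewTransform,
    n_units: int,
    tol_gap: float = CLOSURE_GAP_NM,
    tol_angle: float = CLOSURE_ANGLE_DEG,
    max_units: int = MAX_UNITS,
) -> PolymerAssembly:
    """Propagate a seed homodimer ``n_units`` times by the step transform.

    Unit k carries the frame ``step^k`` applied to the seed.  The assembly is
    labelled by :func:`classify_step`; the closure gap is the distance between
    the seed origin and the frame one past the last unit.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if n_units > max_units:
        raise ValueError(f"n_units {n_units} exceeds maximum {max_units}")
    T = step.matrix() if isinstance(step, ScrewTransform) else np.asarray(step, float)
    _check_rigid(T)

    units = [seed]
    current = np.eye(4)
    for _ in range(1, n_units):
        current = T @ current
        units.append(seed.transformed(current))
    one_past = T @ current
    closure_gap = float(
        np.linalg.norm(apply_transform(one_past, seed.frame_origin) - seed.frame_origin)
    )
    screw = screw_decompose(T)
    classification = classify_step(T, tol_gap=tol_gap, tol_angle=tol_angle)
    if classification.kind == "closed_ring" and n_units != classification.n_units:
        # the step would close at n, but this finite assembly stops short
        # (or overshoots): it is an open arc spanning the units present
        classification = Classification(
            kind="open_arc", arc_angle=screw.rotation_angle * (n_units - 1)
        )
    elif classification.kind == "open_arc" and classification.arc_angle not in (0.0, None):
        # arc actually spanned by this finite assembly
        classification = Classification(
            kind="open_arc", arc_angle=screw.rotation_angle * (n_units - 1)
        )
    return PolymerAssembly(
        units=units, classification=classification, closure_gap=closure_gap, step=screw
    )


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def ring_diameter(chord: float, n_units: int) -> float:
    """Diameter of the circle through the n interface vertices of a closed
    ring whose neighbouring vertices are ``chord`` nm apart:
    D = chord / sin(pi / n).  The ninefold ring with the 7.87 nm chord gives
    the cartwheel's 23 nm."""
    if n_units < 3:
        raise ValueError("a ring needs at least 3 units")
    if chord <= 0:
        raise ValueError("chord must be positive")
    return chord / math.sin(math.pi / n_units)


def helix_parameters(step: ScrewTransform | np.ndarray) -> tuple[float, float, float]:
    """(pitch nm, units per turn, helix radius nm) of the helix generated by
    a screw step: units_per_turn = 360/angle, pitch = rise * units_per_turn,
    radius = perpendicular offset of the seed origin from the screw axis."""
    screw = step if isinstance(step, ScrewTransform) else screw_decompose(step)
    if screw.rotation_angle < _ANGLE_TOL_DEG:
        raise ValueError("pitch undefined for a non-rotating step")
    upt = 360.0 / screw.rotation_angle
    pitch = screw.rise * upt
    # radius: distance from the origin (seed) to the screw axis line
    rel = -screw.axis_point
    radius = float(np.linalg.norm(rel - (rel @ screw.axis) * screw.axis))
    return pitch, upt, radius


# ---------------------------------------------------------------------------
# landing-spoke geometry
# ---------------------------------------------------------------------------

def landing_spoke_pattern(
    assembly: PolymerAssembly,
    visible_sector: float = 30.0,
) -> list[tuple[float, str]]:
    """Axial spoke positions visible when a helix lands on a flat surface.

    When the helix lies on mica with its axis in the surface plane, spokes
    pointing sideways (azimuth near +/-90 degrees from the surface normal
    plane) project clear of the backbone and are observable.  Returns
    ``(axial_position_nm, side)`` for spokes whose azimuth is strictly within
    ``visible_sector`` degrees of either lateral direction, ordered along the
    axis.  For the fourfold helix (90 degree twist, 6.5 nm rise) the maximal
    same-side spacing is one pitch, 26 nm; opposite sides interleave at 13 nm.
    """
    if assembly.classification.kind != "helix":
        raise ValueError("landing_spoke_pattern requires a helix assembly")
    if not 0 <= visible_sector <= 90:
        raise ValueError("visible_sector must be in [0, 90] degrees")
    screw = assembly.step
    axis = screw.axis
    # lateral directions: perpendicular to the axis and to the surface normal.
    # Use the seed spoke azimuth as phase reference.
    out: list[tuple[float, str]] = []
    left = _azimuth_reference(assembly, axis)
    for unit in assembly.units:
        axial = float((unit.frame_origin - screw.axis_point) @ axis)
        az = _spoke_azimuth(unit, screw, left)
        for side, centre in (("left", 0.0), ("right", 180.0)):
            d = abs((az - centre + 180.0) % 360.0 - 180.0)
            if d < visible_sector:
                out.append((axial, side))
    out.sort(key=lambda t: t[0])
    return out


def _azimuth_reference(assembly: PolymerAssembly, axis: np.ndarray) -> np.ndarray:
    u0 = assembly.units[0]
    ref = u0.spoke_direction - (u0.spoke_direction @ axis) * axis
    n = np.linalg.norm(ref)
    if n < 1e-12:
        ref = np.array([1.0, 0.0, 0.0])
        ref = ref - (ref @ axis) * axis
        n = np.linalg.norm(ref)
    return ref / n


def _spoke_azimuth(unit: HomodimerUnit, screw: ScrewTransform, ref: np.ndarray) -> float:
    axis = screw.axis
    v = unit.spoke_direction - (unit.spoke_direction @ axis) * axis
    n = np.linalg.norm(v)
    if n < 1e-12:
        return float("nan")
    v = v / n
    cosang = np.clip(v @ ref, -1.0, 1.0)
    sinang = float(np.cross(ref, v) @ axis)
    return math.degrees(math.atan2(sinang, cosang)) % 360.0


def max_same_side_spacing(pattern: list[tuple[float, str]]) -> float:
    """Largest gap between consecutive same-side spokes in a landing pattern."""
    best = 0.0
    for side in ("left", "right"):
        xs = sorted(p for p, s in pattern if s == side)
        if len(xs) >= 2:
            best = max(best, max(b - a for a, b in zip(xs, xs[1:])))
    return best
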