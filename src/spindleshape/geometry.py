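"""Planar and mesh geometry for blastomere shape analysis.

Contours are closed simple polygons in micrometres describing the apical
plane of a single blastomere; meshes are closed triangulated cell surfaces
whose faces are labelled apical (contact-free) or basolateral
(cell-contact).  All angles are axial: defined modulo 180 degrees,
measured counter-clockwise from the +x axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import trimesh
from shapely.geometry import Point, Polygon

APICAL = "apical"
BASOLATERAL = "basolateral"

#: eigenvalue-ratio tolerance below which a shape is treated as isotropic
ISOTROPY_TOL = 0.02


class InvalidShapeError(ValueError):
    """A contour or mesh violates its geometric invariants."""


class MeshLabelError(ValueError):
    """Face labels are missing or inconsistent with the mesh."""


# --------------------------------------------------------------------------
# axial-angle helpers
# --------------------------------------------------------------------------

def wrap_axial(angle_deg: float | np.ndarray) -> float | np.ndarray:
    """Map an angle to the axial range [0, 180)."""
    return np.mod(angle_deg, 180.0)


def axial_difference(a_deg: float, b_deg: float) -> float:
    """Acute angle in [0, 90] between two axial (undirected) directions."""
    d = abs(float(a_deg) - float(b_deg)) % 180.0
    return min(d, 180.0 - d)


def unit_vector(angle_deg: float) -> np.ndarray:
    rad = math.radians(angle_deg)
    return np.array([math.cos(rad), math.sin(rad)])


# --------------------------------------------------------------------------
# Contour2D
# --------------------------------------------------------------------------

@dataclass
class Contour2D:
    """Closed simple polygon (µm) outlining a cell's apical plane.

    Vertices are normalized at construction: an explicit duplicate closing
    vertex is dropped and the orientation is made counter-clockwise.
    """

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidShapeError("contour vertices must be an (n, 2) array")
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 4:
            raise InvalidShapeError(
                f"contour needs >= 4 distinct vertices, got {len(v)}"
            )
        poly = Polygon(v)
        if (not poly.is_valid) or poly.area <= 0.0:
            raise InvalidShapeError(
                f"contour '{self.label}' is degenerate or self-intersecting"
            )
        # shoelace sign: normalize to CCW
        x, y = v[:, 0], v[:, 1]
        cross = x * np.roll(y, -1) - np.roll(x, -1) * y
        if cross.sum() < 0.0:
            v = v[::-1].copy()
        self.vertices = v
        self._polygon = Polygon(v)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized strict-interior test for an (n, 2) array of points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return shapely.contains_xy(self._polygon, pts[:, 0], pts[:, 1])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "Contour2D":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(), label=label)


@dataclass(frozen=True)
class PrincipalAxes:
    """Equivalent-ellipse axes of a filled polygon.

    Lengths are full axis lengths of the ellipse with the same second area
    moments as the polygon; the angle is axial ([0, 180) degrees, CCW from
    +x).  ``degenerate`` marks isotropic shapes whose major-axis direction
    is not meaningful.
    """

    angle_major: float
    length_major: float
    length_minor: float
    aspect_ratio: float
    centroid: tuple[float, float]
    degenerate: bool = False


def area_centroid(contour: Contour2D) -> tuple[float, tuple[float, float]]:
    """Area (µm²) and centroid (µm) of the filled contour."""
    poly = contour.polygon
    c = poly.centroid
    return float(poly.area), (float(c.x), float(c.y))


def _second_central_moments(contour: Contour2D) -> tuple[float, float, float]:
    """Normalized central second moments (covariance of the filled polygon)."""
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central, normalized by area -> covariance of the uniform lamina
    mxx = ixx / area - cx * cx
    myy = iyy / area - cy * cy
    mxy = ixy / area - cx * cy
    return mxx, myy, mxy


def principal_axes(contour: Contour2D, isotropy_tol: float = ISOTROPY_TOL) -> PrincipalAxes:
    """Principal axes of the filled polygon via second area moments.

    Area moments (rather than vertex PCA) make the result robust to uneven
    vertex spacing from manual tracing.  For an ellipse the recovered
    lengths equal the true axis lengths.
    """
    area, centroid = area_centroid(contour)
    mxx, myy, mxy = _second_central_moments(contour)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    eigval, eigvec = np.linalg.eigh(cov)
    lam_minor, lam_major = float(eigval[0]), float(eigval[1])
    if lam_minor <= 0.0:
        raise InvalidShapeError("contour has a degenerate (zero-width) axis")
    vx, vy = eigvec[:, 1]
    angle = wrap_axial(math.degrees(math.atan2(vy, vx)))
    degenerate = (lam_major / lam_minor) < (1.0 + isotropy_tol)
    # ellipse with semi-axis a has second moment a^2/4 -> full length 4*sqrt(lam)
    return PrincipalAxes(
        angle_major=float(angle),
        length_major=4.0 * math.sqrt(lam_major),
        length_minor=4.0 * math.sqrt(lam_minor),
        aspect_ratio=math.sqrt(lam_major / lam_minor),
        centroid=centroid,
        degenerate=degenerate,
    )


def ray_to_boundary(
    contour: Contour2D,
    origin: np.ndarray,
    direction: np.ndarray,
) -> float:
    """Distance from an interior point to the first boundary hit.

    This is the length of an astral microtubule reaching the cortex from
    ``origin`` along ``direction``.  Safe for non-convex contours: the
    nearest of all edge intersections is returned.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise ValueError("direction must be non-zero")
    d = d / nd
    if not contour.contains(o[None, :])[0]:
        raise InvalidShapeError("ray origin must lie strictly inside the contour")
    v = contour.vertices
    p0 = v
    e = np.roll(v, -1, axis=0) - v
    # o + t d = p0 + u e ;  denom = d x e
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    w = p0 - o
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        u = (w[:, 0] * d[1] - w[:, 1] * d[0]) / denom
    # u-window slightly widened so rays through a vertex cannot miss both
    # adjacent edges (duplicate hits are harmless under the min)
    valid = (np.abs(denom) > 1e-300) & (t > 1e-12) & (u >= -1e-9) & (u <= 1.0 + 1e-9)
    if not valid.any():
        raise InvalidShapeError("ray found no boundary intersection")
    return float(t[valid].min())


# --------------------------------------------------------------------------
# SpindleAxis (shared by observed and predicted spindles)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpindleAxis:
    """Undirected axis defined by two spindle-pole positions (µm)."""

    pole_a: tuple[float, float]
    pole_b: tuple[float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.pole_a, dtype=float)
        b = np.asarray(self.pole_b, dtype=float)
        if np.allclose(a, b):
            raise InvalidShapeError("spindle poles must be distinct")
        object.__setattr__(self, "pole_a", (float(a[0]), float(a[1])))
        object.__setattr__(self, "pole_b", (float(b[0]), float(b[1])))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.pole_a) + np.asarray(self.pole_b))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.pole_b) - np.asarray(self.pole_a)))

    @property
    def angle(self) -> float:
        """Axial orientation in [0, 180) degrees."""
        d = np.asarray(self.pole_b) - np.asarray(self.pole_a)
        return float(wrap_axial(math.degrees(math.atan2(d[1], d[0]))))

    @classmethod
    def from_center_angle(
        cls, center: np.ndarray, angle_deg: float, length: float
    ) -> "SpindleAxis":
        c = np.asarray(center, dtype=float)
        half = 0.5 * length * unit_vector(angle_deg)
        return cls(tuple(c - half), tuple(c + half))


# --------------------------------------------------------------------------
# Labeled meshes
# --------------------------------------------------------------------------

@dataclass
class LabeledMesh:
    """Watertight triangulated blastomere surface with per-face labels.

    ``face_label`` holds one of ``"apical"`` / ``"basolateral"`` per face.
    """

    mesh: trimesh.Trimesh
    face_label: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.face_label, dtype=object)
        if len(labels) != len(self.mesh.faces):
            raise MeshLabelError(
                f"{len(labels)} labels for {len(self.mesh.faces)} faces"
            )
        bad = set(np.unique(labels)) - {APICAL, BASOLATERAL}
        if bad:
            raise MeshLabelError(f"unknown face labels: {sorted(map(str, bad))}")
        self.face_label = labels
        if self.mesh.is_watertight and self.mesh.volume < 0:
            self.mesh.invert()  # enforce outward winding; face order preserved

    @property
    def apical_mask(self) -> np.ndarray:
        return self.face_label == APICAL


def _require_watertight(mesh: trimesh.Trimesh) -> None:
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int((counts == 1).sum())
        raise InvalidShapeError(
            f"mesh is not watertight ({n_open} open edges)"
        )


def mesh_volume_area(lm: LabeledMesh) -> tuple[float, float]:
    """Enclosed volume (µm³) and total surface area (µm²)."""
    _require_watertight(lm.mesh)
    return float(abs(lm.mesh.volume)), float(lm.mesh.area)


def sphericity(lm: LabeledMesh) -> float:
    """Sphericity Psi = pi^(1/3) (6V)^(2/3) / A.

    1 for a sphere, lower for flatter or more polyhedral shapes; invariant
    to uniform scaling.
    """
    vol, area = mesh_volume_area(lm)
    return float(math.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area)


def apical_surface_ratio(lm: LabeledMesh) -> float:
    """Apical surface area divided by total surface area, in [0, 1]."""
    areas = lm.mesh.area_faces
    total = float(areas.sum())
    if total <= 0:
        raise InvalidShapeError("mesh has zero surface area")
    return float(areas[lm.apical_mask].sum() / total)


# --------------------------------------------------------------------------
# Apical-plane extraction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneFit:
    """Plane through the spindle poles separating apical from basolateral.

    ``separation_score`` is the area fraction of faces on the correct side
    of the plane (apical on the +normal side), in [0.5, 1] after the normal
    orientation is fixed.
    """

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    separation_score: float


def points_inside_mesh(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Interior test via the generalized winding number.

    Sums the signed solid angle subtended by every face at each query
    point; the total is ~4*pi inside a watertight mesh and ~0 outside.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (F, 3, 3)
    winding = np.empty(len(pts))
    for i, p in enumerate(pts):
        a = tri[:, 0, :] - p
        b = tri[:, 1, :] - p
        c = tri[:, 2, :] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", c, a) * lb
        )
        winding[i] = np.arctan2(num, den).sum() / (2.0 * math.pi)
    return winding > 0.5


def _separation_score(
    signed: np.ndarray, areas: np.ndarray, apical: np.ndarray
) -> float:
    total = areas.sum()
    correct = areas[(signed > 0) & apical].sum() + areas[(signed <= 0) & ~apical].sum()
    return float(correct / total)


def extract_apical_plane(
    lm: LabeledMesh,
    poles3d: np.ndarray,
    phi_step_deg: float = 1.0,
) -> tuple[PlaneFit, Contour2D, SpindleAxis]:
    """Extract the apical plane and its cross-section contour.

    Among the one-parameter family of planes containing the pole-pole
    axis, finds the rotation angle phi maximizing the area-weighted
    separation of apical from basolateral faces (each face assigned by the
    side of its centroid), scanning phi on a grid and refining by
    golden-section search.  Returns the plane, the cross-section polygon in
    plane coordinates, and the poles projected into those coordinates.

    Plane coordinates: origin at the pole midpoint, x-axis along the pole
    axis, y-axis = normal x pole-axis.
    """
    _require_watertight(lm.mesh)
    poles = np.asarray(poles3d, dtype=float).reshape(2, 3)
    a3, b3 = poles
    if np.allclose(a3, b3):
        raise InvalidShapeError("spindle poles are coincident")
    inside = points_inside_mesh(lm.mesh, poles)
    if not inside.all():
        raise InvalidShapeError("both spindle poles must lie inside the mesh")
    mid = 0.5 * (a3 + b3)
    u = (b3 - a3) / np.linalg.norm(b3 - a3)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    v = ref - np.dot(ref, u) * u
    v /= np.linalg.norm(v)
    w = np.cross(u, v)

    centroids = lm.mesh.triangles_center - mid
    areas = lm.mesh.area_faces
    apical = lm.apical_mask
    cv = centroids @ v
    cw = centroids @ w

    def score(phi_deg: float) -> float:
        phi = math.radians(phi_deg)
        signed = math.cos(phi) * cv + math.sin(phi) * cw
        s = _separation_score(signed, areas, apical)
        return max(s, 1.0 - s)

    grid = np.arange(0.0, 180.0, phi_step_deg)
    scores = np.array([score(p) for p in grid])
    best = int(np.argmax(scores))
    # golden-section refinement in the bracket around the grid maximum
    lo = grid[best] - phi_step_deg
    hi = grid[best] + phi_step_deg
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1, x2 = hi - invphi * (hi - lo), lo + invphi * (hi - lo)
    f1, f2 = score(x1), score(x2)
    while hi - lo > 0.05:
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = score(x2)
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = score(x1)
    phi_best = 0.5 * (lo + hi)
    if score(phi_best) < scores[best]:
        phi_best = float(grid[best])  # refinement left the score plateau
    phi = math.radians(phi_best)
    normal = math.cos(phi) * v + math.sin(phi) * w
    signed = math.cos(phi) * cv + math.sin(phi) * cw
    s = _separation_score(signed, areas, apical)
    if s < 0.5:  # orient normal so the apical side is positive
        normal = -normal
        s = 1.0 - s
    if s < 0.6:
        warnings.warn(
            f"apical/basolateral separation is weak (score {s:.2f}); "
            "the labeling carries little planar signal",
            stacklevel=2,
        )

    section = lm.mesh.section(plane_origin=mid, plane_normal=normal)
    if section is None:
        raise InvalidShapeError("plane does not intersect the mesh")
    e1, e2 = u, np.cross(normal, u)
    poles2d = SpindleAxis(
        (float((a3 - mid) @ e1), float((a3 - mid) @ e2)),
        (float((b3 - mid) @ e1), float((b3 - mid) @ e2)),
    )
    loops = section.discrete
    contour = None
    for loop in loops:
        pts = np.asarray(loop, dtype=float)
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        xy = np.column_stack(((pts - mid) @ e1, (pts - mid) @ e2))
        # drop near-duplicate consecutive points from the section chain
        keep = np.ones(len(xy), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) > 1e-9
        xy = xy[keep]
        if len(xy) < 4:
            continue
        try:
            cand = Contour2D(xy, label=lm.name)
        except InvalidShapeError:
            continue
        if cand.contains(np.array([poles2d.pole_a, poles2d.pole_b])).all():
            contour = cand
            break
    if contour is None:
        raise InvalidShapeError(
            "no cross-section loop contains both spindle poles"
        )
    if len(loops) > 1:
        warnings.warn(
            f"cross-section has {len(loops)} loops; kept the loop containing "
            "the spindle poles",
            stacklevel=2,
        )
    plane = PlaneFit(
        point=tuple(float(x) for x in mid),
        normal=tuple(float(x) for x in normal),
        separation_score=float(s),
    )
    return plane, contour, poles2d


# --------------------------------------------------------------------------
# Mesh I/O: OFF / PLY geometry, labels from a PLY face property or sidecar CSV
# --------------------------------------------------------------------------

_LABEL_CODE = {0: BASOLATERAL, 1: APICAL}
_CODE_LABEL = {v: k for k, v in _LABEL_CODE.items()}


def load_labeled_mesh(
    path: str | Path, labels: str | Path | None = None, name: str = ""
) -> LabeledMesh:
    """Load an OFF/PLY mesh plus per-face apical/basolateral labels.

    Labels come from a sidecar CSV with columns (face_index, label), or —
    for PLY files — from an integer face property named ``label``
    (0 = basolateral, 1 = apical).
    """
    path = Path(path)
    mesh = trimesh.load(path, process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise InvalidShapeError(f"{path} did not load as a triangle mesh")
    if labels is not None:
        df = pd.read_csv(labels)
        lab = np.empty(len(mesh.faces), dtype=object)
        lab[:] = None
        lab[df["face_index"].to_numpy()] = df["label"].to_numpy()
        if any(l is None for l in lab):
            raise MeshLabelError(f"label file {labels} does not cover every face")
        return LabeledMesh(mesh, lab, name=name or path.stem)
    raw = mesh.metadata.get("_ply_raw", {}).get("face", {}).get("data")
    if raw is not None and "label" in getattr(raw, "dtype", np.dtype([])).names:
        codes = np.asarray(raw["label"]).ravel()
        lab = np.array([_LABEL_CODE[int(c)] for c in codes], dtype=object)
        return LabeledMesh(mesh, lab, name=name or path.stem)
    raise MeshLabelError(
        f"no labels for {path}: provide a sidecar CSV or a PLY 'label' property"
    )


def save_labeled_mesh(lm: LabeledMesh, path: str | Path) -> Path:
    """Write mesh geometry (format from the extension) plus a label CSV.

    Returns the path of the sidecar label file (``<stem>.labels.csv``).
    """
    path = Path(path)
    lm.mesh.export(path)
    label_path = path.with_suffix("").with_suffix(".labels.csv")
    pd.DataFrame(
        {"face_index": np.arange(len(lm.face_label)), "label": lm.face_label}
    ).to_csv(label_path, index=False)
    return label_path
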