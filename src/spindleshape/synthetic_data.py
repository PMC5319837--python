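"""Seeded generators for every input the pipeline consumes.

Emulates the inputs of an early-ascidian spindle-orientation study
without imaging data: blastomere-like apical contours (anisotropic,
convex-ish polygons), noisy spindle observations whose metaphase axes
follow the model prediction with axial angular noise, a planted
sub-population of spindle-rotating (OCD-like) cells whose prophase axes
sit 45-90 degrees off, labeled surface meshes, and two-hemisphere
mitotic-entry timing data.  Every generator is a pure function of
(params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .geometry import (
    APICAL,
    BASOLATERAL,
    Contour2D,
    InvalidShapeError,
    LabeledMesh,
    PlaneFit,
    SpindleAxis,
    unit_vector,
    wrap_axial,
)
from .pipeline import CellRecord
from .spindle_model import ModelParams, predict_spindle

#: 32-cell-stage blastomere names cycled over synthetic records
_LINEAGES = (
    "a6.5", "a6.6", "a6.7", "a6.8",
    "b6.5", "b6.6", "b6.7", "b6.8",
    "A6.1", "A6.2", "A6.4",
    "B6.1", "B6.2", "B6.4",
)


@dataclass(frozen=True)
class ShapeFamilyParams:
    """Parameters of the apical-contour generator.

    ``size_range`` is the major-axis length in µm (apical planes of
    cleavage-stage blastomeres are a few tens of µm across);
    ``aspect_range`` covers near-round to strongly elongated outlines;
    ``fourier_noise`` is the amplitude scale of low-order radial
    harmonics added by the fourier_blob family.
    """

    family: str = "fourier_blob"  # ellipse | superellipse | fourier_blob | flattened
    aspect_range: tuple[float, float] = (1.1, 3.0)
    size_range: tuple[float, float] = (20.0, 40.0)
    fourier_noise: float = 0.05
    n_points: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aspect_range[0] < 1.0:
            raise ValueError("aspect ratios must be >= 1")
        if self.family not in ("ellipse", "superellipse", "fourier_blob", "flattened"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class ObservationParams:
    """Noise model for synthetic spindle observations.

    ``angular_noise_sd`` is axial Gaussian noise (degrees) applied to the
    predicted orientation, wrapped on the 180-degree circle;
    ``rotating_fraction`` is the proportion of cells whose prophase axis
    is planted 45-90 degrees off the metaphase axis, mimicking
    spindle-rotating (OCD) cells; ``center_noise_sd`` is isotropic
    positional noise (µm) on the spindle center.
    """

    angular_noise_sd: float = 15.0
    rotating_fraction: float = 0.0
    center_noise_sd: float = 1.0
    n_cells: int = 149
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be >= 0")
        if not 0.0 <= self.rotating_fraction <= 1.0:
            raise ValueError("rotating_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneratedShape:
    """A synthetic contour with its ground-truth construction."""

    contour: Contour2D
    true_angle: float
    true_aspect: float
    family: str


def _base_contour(
    family: str,
    a: float,
    b: float,
    n_points: int,
    fourier_noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    if family in ("ellipse", "flattened"):
        return np.column_stack((a * np.cos(t), b * np.sin(t)))
    if family == "superellipse":
        p = rng.uniform(2.2, 3.0)
        c, s = np.cos(t), np.sin(t)
        return np.column_stack(
            (a * np.sign(c) * np.abs(c) ** (2.0 / p),
             b * np.sign(s) * np.abs(s) ** (2.0 / p))
        )
    # fourier_blob: ellipse radius modulated by low-order harmonics
    r_e = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    mod = np.ones_like(t)
    for k in (2, 3, 4):
        amp = rng.normal(0.0, fourier_noise / k)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        mod += amp * np.cos(k * t + phase)
    r = r_e * mod
    return np.column_stack((r * np.cos(t), r * np.sin(t)))


def make_contours(params: ShapeFamilyParams, n: int) -> list[GeneratedShape]:
    """Generate ``n`` blastomere-like contours, rejection-resampling any
    that fail the contour invariants (at most 100 attempts each)."""
    rng = np.random.default_rng(params.seed)
    lo_a, hi_a = params.aspect_range
    shapes = []
    for _ in range(n):
        for attempt in range(100):
            if params.family == "flattened":
                aspect = rng.uniform(0.5 * (lo_a + hi_a), hi_a)
            else:
                aspect = rng.uniform(lo_a, hi_a)
            length = rng.uniform(*params.size_range)
            a = 0.5 * length
            b = a / aspect
            angle = rng.uniform(0.0, 180.0)
            offset = rng.uniform(-20.0, 20.0, size=2)
            base = _base_contour(
                params.family, a, b, params.n_points, params.fourier_noise, rng
            )
            rad = math.radians(angle)
            rot = np.array(
                [[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]]
            )
            pts = base @ rot.T + offset
            try:
                contour = Contour2D(pts, label=params.family)
            except InvalidShapeError:
                continue
            shapes.append(
                GeneratedShape(
                    contour=contour,
                    true_angle=float(angle % 180.0),
                    true_aspect=float(aspect),
                    family=params.family,
                )
            )
            break
        else:
            raise RuntimeError("could not generate a simple contour in 100 tries")
    return shapes


def _place_poles(
    contour: Contour2D,
    center: np.ndarray,
    angle: float,
    length: float,
) -> SpindleAxis | None:
    """Spindle poles at center/angle, shrinking until both are interior."""
    for _ in range(12):
        half = 0.5 * length * unit_vector(angle)
        poles = np.vstack([center - half, center + half])
        if contour.contains(poles).all():
            return SpindleAxis(tuple(poles[0]), tuple(poles[1]))
        length *= 0.85
    return None


def synthesize_observations(
    shapes: list[GeneratedShape] | list[Contour2D],
    model_params: ModelParams = ModelParams(),
    obs: ObservationParams = ObservationParams(),
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Noisy prophase + metaphase spindle observations per contour.

    The metaphase axis is the model prediction perturbed by wrapped axial
    Gaussian noise, with isotropic noise on the center.  A planted subset
    of exactly round(rotating_fraction * n) cells gets a prophase axis
    offset by Uniform(45, 90) degrees (random sign) from its metaphase
    axis — cells that will visibly rotate into alignment during mitosis.
    Returns (records, ground truth); records carry phase-suffixed unique
    ids (``c0003-metaphase``), ground truth one row per cell.
    """
    rng = np.random.default_rng(obs.seed)
    contours = [
        s.contour if isinstance(s, GeneratedShape) else s for s in shapes
    ]
    n = len(contours)
    if n == 0:
        raise ValueError("no contours supplied")
    gen_params = replace(model_params, spindle_length_mode="fraction")
    n_rot = int(round(obs.rotating_fraction * n))
    rotating = np.zeros(n, dtype=bool)
    rotating[rng.choice(n, size=n_rot, replace=False)] = True

    records, truth = [], []
    for i, contour in enumerate(contours):
        pred = predict_spindle(contour, None, gen_params)
        p_angle, p_center, p_len = (
            pred.axis.angle,
            pred.axis.center,
            pred.axis.length,
        )
        base_id = f"c{i:04d}"
        lineage = _LINEAGES[i % len(_LINEAGES)]

        meta_axis = None
        for _ in range(100):
            noise = rng.normal(0.0, obs.angular_noise_sd)
            m_angle = float(wrap_axial(p_angle + noise))
            m_center = p_center + rng.normal(0.0, obs.center_noise_sd, size=2)
            meta_axis = _place_poles(contour, m_center, m_angle, p_len)
            if meta_axis is not None:
                break
        if meta_axis is None:
            raise RuntimeError(
                f"cell {base_id}: could not place a noisy metaphase spindle"
            )

        offset = 0.0
        if rotating[i]:
            offset = float(rng.uniform(45.0, 90.0) * rng.choice([-1.0, 1.0]))
        pro_angle = float(wrap_axial(m_angle + offset))
        pro_axis = _place_poles(contour, meta_axis.center, pro_angle, p_len)
        if pro_axis is None:
            raise RuntimeError(
                f"cell {base_id}: could not place the prophase spindle"
            )

        for phase, axis in (("prophase", pro_axis), ("metaphase", meta_axis)):
            records.append(
                CellRecord(
                    cell_id=f"{base_id}-{phase}",
                    lineage=lineage,
                    stage=32,
                    phase=phase,
                    group="control",
                    contour=contour,
                    observed=axis,
                )
            )
        truth.append(
            {
                "cell_id": base_id,
                "lineage": lineage,
                "predicted_angle_deg": p_angle,
                "predicted_center_x": float(p_center[0]),
                "predicted_center_y": float(p_center[1]),
                "spindle_length_um": p_len,
                "metaphase_noise_deg": float(noise),
                "metaphase_angle_deg": m_angle,
                "is_rotating": bool(rotating[i]),
                "prophase_offset_deg": offset,
                "model_degenerate": bool(pred.degenerate),
            }
        )
    return records, pd.DataFrame(truth)


def simulate_dataset(
    shape_params: ShapeFamilyParams = ShapeFamilyParams(),
    model_params: ModelParams = ModelParams(),
    obs: ObservationParams = ObservationParams(),
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Contours plus observations in one call (``obs.n_cells`` cells)."""
    shapes = make_contours(shape_params, obs.n_cells)
    return synthesize_observations(shapes, model_params, obs)


# --------------------------------------------------------------------------
# Labeled meshes
# --------------------------------------------------------------------------

def make_labeled_mesh(
    kind: str = "icosphere",
    label_rule: str = "hemisphere",
    seed: int = 0,
    radius: float = 15.0,
    subdivisions: int = 4,
    cap_fraction: float = 0.2,
) -> tuple[LabeledMesh, PlaneFit | None]:
    """Watertight labeled test mesh plus its ground-truth plane.

    Kinds: ``icosphere``, ``box``, ``ellipsoid`` (2:1:1) and
    ``flattened`` (2:2:1 oblate).  Label rules: ``hemisphere`` (apical =
    faces with centroid above the equator), ``cap_fraction`` (apical
    spherical cap of the given area fraction; quantile-based for
    non-spherical kinds) and ``random``.  The returned plane (normal +z)
    is the exact separator for hemisphere/cap labelings, None for random.
    """
    rng = np.random.default_rng(seed)
    if kind == "icosphere":
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    elif kind == "box":
        mesh = trimesh.creation.box(extents=(2 * radius,) * 3)
    elif kind == "ellipsoid":
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        mesh.apply_scale((2.0, 1.0, 1.0))
    elif kind == "flattened":
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        mesh.apply_scale((2.0, 2.0, 1.0))
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")

    z = mesh.triangles_center[:, 2]
    plane: PlaneFit | None = None
    if label_rule == "hemisphere":
        apical = z > 0.0
        z_cut = 0.0
    elif label_rule == "cap_fraction":
        if kind == "icosphere":
            # spherical cap of height h has area fraction h / (2 r)
            z_cut = radius * (1.0 - 2.0 * cap_fraction)
        else:
            areas = mesh.area_faces
            order = np.argsort(-z)
            cum = np.cumsum(areas[order]) / areas.sum()
            z_cut = float(z[order][np.searchsorted(cum, cap_fraction)])
        apical = z > z_cut
    elif label_rule == "random":
        apical = rng.random(len(mesh.faces)) < 0.5
        z_cut = None
    else:
        raise ValueError(f"unknown label rule {label_rule!r}")

    if z_cut is not None:
        plane = PlaneFit(
            point=(0.0, 0.0, float(z_cut)),
            normal=(0.0, 0.0, 1.0),
            separation_score=1.0,
        )
    labels = np.where(apical, APICAL, BASOLATERAL).astype(object)
    return LabeledMesh(mesh, labels, name=f"{kind}-{label_rule}"), plane


def make_timing_data(
    dt: float,
    jitter_sd: float,
    n_per_group: int,
    seed: int = 0,
    t0: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mitotic-entry times for the two hemispheres.

    Vegetal cells enter at ~N(t0, jitter), animal cells ``dt`` minutes
    later; positive dt = animal later, matching the asynchrony sign
    convention.  Returns (animal, vegetal) entry times in minutes.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    vegetal = rng.normal(t0, jitter_sd, size=n_per_group)
    animal = rng.normal(t0 + dt, jitter_sd, size=n_per_group)
    return animal, vegetal
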