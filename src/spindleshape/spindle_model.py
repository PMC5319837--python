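"""2D cortical-pulling model of spindle positioning.

Astral microtubules radiate from each spindle pole to the cell cortex
(n_rays equally spaced directions per pole) and pull with a force that
scales with microtubule length, f(L) = L^beta.  The energy of a spindle
placement is the exact potential of those forces,

    E(center, theta) = sum_poles sum_rays phi_beta(L_i),

    phi_beta(L) = beta / ((beta - 1)(beta + 1)) * L^(beta+1)   (beta != 1)
    phi_1(L)    = L^2 (2 ln L - 1) / 4                         (beta = 1)

so that the pulling force on a pole is -grad E and -dE/dtheta is the
mechanical torque on the spindle; the global energy minimum over all
candidate placements inside the cell outline is the predicted spindle.
(phi_beta is the ray-sum form of the area integral
integral |x - p|^(beta-1) dA over the cell, whose gradient reproduces
the summed pull of a uniform astral fan; the log kernel is the beta -> 1
limit.)

For 0 < beta < 3 the energy minimum sits at a centered spindle aligned
with the cell's long axis — the long-axis (Hertwig) rule.  beta = 3 is
the critical exponent of this model family: sum L^4 over a uniform fan
is proportional to the polar second moment of the cell area about the
pole, which depends only on the pole's distance from the centroid, so
the landscape carries no orientation information and is flagged
degenerate.  Above beta = 3 the preference inverts to the short axis.
The default beta = 1 (force proportional to length) is the regime the
long-axis rule is built on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .geometry import (
    Contour2D,
    SpindleAxis,
    principal_axes,
    unit_vector,
    wrap_axial,
)


class InfeasiblePlacementError(ValueError):
    """A spindle pole lies on or outside the cell boundary."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the pulling-force model and of the placement search.

    beta
        Force-length exponent, f(L) = L^beta (dimensionless, >= 0).
        Default 1: force proportional to microtubule length.  Values at
        or above 3 yield orientation-free (degenerate) landscapes, see
        the module docstring.
    n_rays
        Astral rays per pole, equally spaced over 360 degrees.
    dtheta
        Orientation grid step in degrees.
    spindle_length_mode
        "observed" uses the observed pole separation; "fraction" uses
        ``spindle_fraction`` of the contour's major-axis length.
    center_mode
        "optimize" searches the spindle center per orientation by local
        descent from the centroid; "centroid" pins it at the centroid.
    relief_tol
        Minimum relative energy relief (max-min)/|min| below which the
        landscape is flagged degenerate (isotropic shape).
    """

    beta: float = 1.0
    n_rays: int = 180
    dtheta: float = 1.0
    spindle_length_mode: str = "observed"
    spindle_fraction: float = 0.4
    center_mode: str = "optimize"
    relief_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_rays < 16:
            raise ValueError("n_rays must be >= 16")
        if not 0 < self.dtheta <= 10:
            raise ValueError("dtheta must be in (0, 10] degrees")
        if not 0 < self.spindle_fraction < 1:
            raise ValueError("spindle_fraction must be in (0, 1)")
        if self.spindle_length_mode not in ("observed", "fraction"):
            raise ValueError("spindle_length_mode must be 'observed' or 'fraction'")
        if self.center_mode not in ("optimize", "centroid"):
            raise ValueError("center_mode must be 'optimize' or 'centroid'")


@dataclass
class EnergyLandscape:
    """Energy over the axial orientation grid, with per-angle centers.

    ``relief`` is (max - min)/|min| of the energy; landscapes with relief
    below the model's ``relief_tol`` are flagged degenerate (no reliable
    preferred orientation, e.g. a circular cell).
    """

    angles: np.ndarray
    energies: np.ndarray
    centers: np.ndarray
    relief: float
    degenerate: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_deg": self.angles,
                "energy": self.energies,
                "center_x": self.centers[:, 0],
                "center_y": self.centers[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SpindlePrediction:
    """Model-predicted spindle with its full energy landscape."""

    axis: SpindleAxis
    landscape: EnergyLandscape
    params: ModelParams

    @property
    def degenerate(self) -> bool:
        return self.landscape.degenerate


# --------------------------------------------------------------------------
# Batched pole-energy kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _pole_energy_sums(px, py, ex, ey, ox, oy, dx, dy, beta1, log_mode):  # pragma: no cover
    """sum_j phi(L_j) for each origin over all ray directions.

    phi(L) = L^beta1, or L^2 (2 ln L - 1) / 4 when ``log_mode`` (the
    beta = 1 potential).  (px, py) are edge start points, (ex, ey) edge
    vectors of the closed polygon; (ox, oy) ray origins assumed strictly
    inside; (dx, dy) unit ray directions.  Compiled hot path: the model
    evaluates millions of ray casts per cell.
    """
    n_o = ox.size
    n_d = dx.size
    n_e = px.size
    out = np.empty(n_o)
    ib = int(beta1)
    is_int = (not log_mode) and (beta1 == ib) and ib >= 1 and ib <= 6
    for i in range(n_o):
        acc = 0.0
        oxi = ox[i]
        oyi = oy[i]
        for j in range(n_d):
            dxj = dx[j]
            dyj = dy[j]
            tmin = 1.0e300
            for k in range(n_e):
                denom = dxj * ey[k] - dyj * ex[k]
                if denom == 0.0:
                    continue
                wx = px[k] - oxi
                wy = py[k] - oyi
                t = (wx * ey[k] - wy * ex[k]) / denom
                if t <= 1e-12 or t >= tmin:
                    continue
                u = (wx * dyj - wy * dxj) / denom
                # slightly widened so rays through a vertex cannot miss both
                # adjacent edges; duplicates are harmless under the min
                if -1e-9 <= u <= 1.0 + 1e-9:
                    tmin = t
            if log_mode:
                acc += tmin * tmin * (2.0 * np.log(tmin) - 1.0) * 0.25
            elif is_int:
                p = tmin
                for _ in range(ib - 1):
                    p *= tmin
                acc += p
            else:
                acc += tmin ** beta1
        out[i] = acc
    return out


def _ray_directions(n_rays: int) -> tuple[np.ndarray, np.ndarray]:
    ang = np.arange(n_rays) * (2.0 * math.pi / n_rays)
    return np.cos(ang), np.sin(ang)


def pole_energies(
    contour: Contour2D, origins: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Single-pole potential sum_rays phi_beta(L) at each origin.

    phi_beta is the per-ray potential of a pulling force f = L^beta (see
    module docstring); lower values mean a more stable pole position.
    Origins outside the contour get +inf (infeasible).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    v = contour.vertices
    ex, ey = (np.roll(v, -1, axis=0) - v).T.copy()
    dx, dy = _ray_directions(params.n_rays)
    inside = contour.contains(origins)
    out = np.full(len(origins), np.inf)
    if inside.any():
        beta = float(params.beta)
        log_mode = beta == 1.0
        sums = _pole_energy_sums(
            np.ascontiguousarray(v[:, 0]),
            np.ascontiguousarray(v[:, 1]),
            np.ascontiguousarray(ex),
            np.ascontiguousarray(ey),
            np.ascontiguousarray(origins[inside, 0]),
            np.ascontiguousarray(origins[inside, 1]),
            dx,
            dy,
            float(beta + 1.0),
            log_mode,
        )
        if log_mode:
            out[inside] = sums
        else:
            out[inside] = sums * (beta / ((beta - 1.0) * (beta + 1.0)))
    return out


def placement_energy(
    contour: Contour2D,
    center: np.ndarray,
    angle: float,
    length: float,
    params: ModelParams,
) -> float:
    """Energy of one spindle placement; lower is more stable.

    Raises :class:`InfeasiblePlacementError` if either pole is on or
    outside the boundary.
    """
    c = np.asarray(center, dtype=float)
    half = 0.5 * length * unit_vector(angle)
    poles = np.vstack([c - half, c + half])
    if not contour.contains(poles).all():
        raise InfeasiblePlacementError(
            "spindle pole on or outside the contour boundary"
        )
    e = pole_energies(contour, poles, params)
    return float(e.sum())


def torque(landscape: EnergyLandscape) -> np.ndarray:
    """Torque tau(theta) = -dE/dtheta by periodic central differences."""
    e = landscape.energies
    dtheta = float(landscape.angles[1] - landscape.angles[0])
    return -(np.roll(e, -1) - np.roll(e, 1)) / (2.0 * dtheta)


# --------------------------------------------------------------------------
# Placement search
# --------------------------------------------------------------------------

def _batched_energy(
    contour: Contour2D,
    centers: np.ndarray,
    offsets: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """E for placements pairing centers[i] with pole offsets offsets[i]."""
    poles = np.concatenate([centers + offsets, centers - offsets])
    e = pole_energies(contour, poles, params)
    n = len(centers)
    return e[:n] + e[n:]


def _optimize_centers(
    contour: Contour2D,
    seed_centers: np.ndarray,
    offsets: np.ndarray,
    params: ModelParams,
    length_scale: float,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-orientation pattern-search descent of the spindle center.

    All orientations descend in lockstep so every energy evaluation is one
    batched kernel call.  Returns (centers, energies).
    """
    n = len(seed_centers)
    centers = seed_centers.copy()
    energies = _batched_energy(contour, centers, offsets, params)
    step = np.full(n, 0.05 * length_scale)
    moves = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    tol = 5e-3 * length_scale
    for _ in range(max_iter):
        active = step > tol
        if not active.any():
            break
        cand = centers[:, None, :] + step[:, None, None] * moves[None, :, :]
        flat = cand.reshape(-1, 2)
        off4 = np.repeat(offsets, 4, axis=0)
        e_cand = _batched_energy(contour, flat, off4, params).reshape(n, 4)
        best = np.argmin(e_cand, axis=1)
        e_best = e_cand[np.arange(n), best]
        improved = active & (e_best < energies)
        centers[improved] = cand[np.arange(n), best][improved]
        energies[improved] = e_best[improved]
        step[active & ~improved] *= 0.5
    return centers, energies


def _build_landscape(
    contour: Contour2D,
    length: float,
    params: ModelParams,
) -> EnergyLandscape:
    axes = principal_axes(contour)
    centroid = np.asarray(axes.centroid)
    angles = np.arange(0.0, 180.0, params.dtheta)
    offsets = 0.5 * length * np.column_stack(
        (np.cos(np.radians(angles)), np.sin(np.radians(angles)))
    )
    seeds = np.tile(centroid, (len(angles), 1))
    if params.center_mode == "optimize":
        centers, energies = _optimize_centers(
            contour, seeds, offsets, params, axes.length_major
        )
    else:
        centers = seeds
        energies = _batched_energy(contour, centers, offsets, params)
    finite = np.isfinite(energies)
    if not finite.any():
        raise InfeasiblePlacementError(
            f"no feasible placement for spindle length {length:.3g} um"
        )
    emin = energies[finite].min()
    emax = energies[finite].max()
    relief = float((emax - emin) / abs(emin)) if emin != 0 else 0.0
    degenerate = relief < params.relief_tol
    return EnergyLandscape(
        angles=angles,
        energies=energies,
        centers=centers,
        relief=relief,
        degenerate=degenerate,
    )


def _refine_angle(landscape: EnergyLandscape) -> float:
    """Quadratic interpolation of the grid minimum (periodic)."""
    e = landscape.energies
    n = len(e)
    i = int(np.nanargmin(np.where(np.isfinite(e), e, np.nan)))
    em, e0, ep = e[(i - 1) % n], e[i], e[(i + 1) % n]
    if not (np.isfinite(em) and np.isfinite(ep)):
        return float(landscape.angles[i])
    denom = em - 2.0 * e0 + ep
    if denom <= 0:
        return float(landscape.angles[i])
    delta = 0.5 * (em - ep) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    dtheta = float(landscape.angles[1] - landscape.angles[0])
    return float(wrap_axial(landscape.angles[i] + delta * dtheta))


def predict_spindle(
    contour: Contour2D,
    observed: SpindleAxis | None = None,
    params: ModelParams = ModelParams(),
) -> SpindlePrediction:
    """Predicted spindle = global energy minimum over placements.

    The orientation grid covers [0, 180) in ``dtheta`` steps; per
    orientation the center is either descended from the centroid
    ("optimize") or pinned there ("centroid").  The winning orientation is
    refined by quadratic interpolation around the grid minimum.  If the
    requested spindle does not fit anywhere it is shrunk geometrically
    until a feasible placement exists.  Deterministic for fixed params.
    """
    if params.spindle_length_mode == "observed":
        if observed is None:
            raise ValueError(
                "spindle_length_mode='observed' requires an observed axis"
            )
        length = observed.length
    else:
        length = params.spindle_fraction * principal_axes(contour).length_major

    landscape = None
    for _ in range(20):
        try:
            landscape = _build_landscape(contour, length, params)
            break
        except InfeasiblePlacementError:
            length *= 0.85
    if landscape is None:
        raise InfeasiblePlacementError(
            "no feasible placement even after shrinking the spindle"
        )

    finite = np.isfinite(landscape.energies)
    i_min = int(np.argmin(np.where(finite, landscape.energies, np.inf)))
    angle = _refine_angle(landscape)
    center = landscape.centers[i_min].copy()
    if params.center_mode == "optimize":
        # joint local polish of (center, angle): the energy trough couples
        # the two, so refining them together lands at the true minimum.
        # Near-tied local minima are resolved below the per-orientation
        # descent's energy noise by polishing each candidate basin.
        from scipy.optimize import minimize

        def objective(x):
            off = 0.5 * length * unit_vector(x[2])[None, :]
            e = _batched_energy(contour, x[:2][None, :], off, params)[0]
            return e if np.isfinite(e) else 1e30

        e_grid = np.where(finite, landscape.energies, np.inf)
        is_min = finite & (e_grid <= np.roll(e_grid, 1)) & (
            e_grid <= np.roll(e_grid, -1)
        )
        idx = np.nonzero(is_min)[0]
        idx = idx[np.argsort(e_grid[idx])][:5]
        seeds = [
            np.array([*landscape.centers[j], float(landscape.angles[j])])
            for j in idx
        ]
        seeds.append(np.array([center[0], center[1], angle]))
        best_fun = np.inf
        for seed in seeds:
            res = minimize(
                objective,
                seed,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 0.0, "maxfev": 400},
            )
            if np.isfinite(res.fun) and res.fun < best_fun:
                best_fun = res.fun
                center = res.x[:2]
                angle = float(wrap_axial(res.x[2]))
    else:
        offset = 0.5 * length * unit_vector(angle)[None, :]
        if not np.isfinite(
            _batched_energy(contour, center[None, :], offset, params)[0]
        ):
            angle = float(landscape.angles[i_min])  # off-grid refinement infeasible
    axis = SpindleAxis.from_center_angle(center, angle, length)
    return SpindlePrediction(axis=axis, landscape=landscape, params=params)


def exhaustive_scan(
    contour: Contour2D,
    length: float,
    params: ModelParams,
    lattice_step: float = 0.5,
    dtheta: float = 0.25,
    refine: bool = False,
) -> tuple[np.ndarray, float, float]:
    """Dense reference scan of the placement energy.

    Evaluates E on the full product of a square center lattice
    (``lattice_step`` µm) and an orientation grid (``dtheta`` degrees) and
    returns (center, angle, energy) of the global minimum.  Slow;
    intended as an exhaustive check of the local-descent search in
    :func:`predict_spindle`.

    With ``refine=True`` the global lattice optimum is polished by a
    shrinking local grid (pure grid descent, no gradient or simplex
    steps), removing the lattice-quantization bias so the result can be
    compared with a continuum optimizer at sub-degree resolution.
    """
    v = contour.vertices
    xmin, ymin = v.min(axis=0)
    xmax, ymax = v.max(axis=0)
    xs = np.arange(xmin, xmax + lattice_step, lattice_step)
    ys = np.arange(ymin, ymax + lattice_step, lattice_step)
    grid = np.array([(x, y) for x in xs for y in ys])
    grid = grid[contour.contains(grid)]
    angles = np.arange(0.0, 180.0, dtheta)
    n_t = len(angles)
    # pole offset directions: theta and theta+180 for the two poles
    phis = np.radians(np.concatenate([angles, angles + 180.0]))
    offs = 0.5 * length * np.column_stack((np.cos(phis), np.sin(phis)))
    best = (None, None, np.inf)
    e_theta = np.full(n_t, np.inf)  # best energy per orientation column
    c_theta = np.zeros((n_t, 2))
    chunk = max(1, 200_000 // (2 * n_t))
    for lo in range(0, len(grid), chunk):
        centers = grid[lo : lo + chunk]
        pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        u = pole_energies(contour, pts, params).reshape(len(centers), 2 * n_t)
        e = u[:, :n_t] + u[:, n_t:]
        col_best = np.argmin(e, axis=0)
        col_e = e[col_best, np.arange(n_t)]
        better = col_e < e_theta
        e_theta[better] = col_e[better]
        c_theta[better] = centers[col_best[better]]
        i, j = np.unravel_index(np.argmin(e), e.shape)
        if e[i, j] < best[2]:
            best = (centers[i].copy(), float(angles[j]), float(e[i, j]))
    if best[0] is None or not np.isfinite(best[2]):
        raise InfeasiblePlacementError("no feasible placement on the lattice")
    if not refine:
        return best
    # the lattice's center quantization can misrank near-tied basins, so
    # polish the lowest local minima of the per-orientation profile, not
    # just the global lattice argmin, and keep the overall best

    def polish(center, angle, energy):
        # pattern descent on a local (center, angle) grid: recenter while
        # the neighborhood improves (walks along flat troughs), shrink on
        # stall
        center = np.asarray(center, dtype=float).copy()
        step, dstep = 0.5 * lattice_step, 0.5 * dtheta
        moves = np.array(
            [(x, y, t) for x in (-2, -1, 0, 1, 2) for y in (-2, -1, 0, 1, 2)
             for t in (-2, -1, 0, 1, 2)],
            dtype=float,
        )
        for _ in range(300):
            cand_c = center[None, :] + step * moves[:, :2]
            cand_a = angle + dstep * moves[:, 2]
            offs = 0.5 * length * np.column_stack(
                (np.cos(np.radians(cand_a)), np.sin(np.radians(cand_a)))
            )
            e = _batched_energy(contour, cand_c, offs, params)
            j = int(np.argmin(e))
            if e[j] < energy:
                center, angle, energy = (
                    cand_c[j].copy(), float(cand_a[j] % 180.0), float(e[j])
                )
            else:
                step *= 0.5
                dstep *= 0.5
                if step < 0.01 and dstep < 0.01:
                    break
        return center, angle, energy

    finite = np.isfinite(e_theta)
    is_local_min = finite & (e_theta <= np.roll(e_theta, 1)) & (
        e_theta <= np.roll(e_theta, -1)
    )
    idx = np.nonzero(is_local_min)[0]
    idx = idx[np.argsort(e_theta[idx])][:12]
    seeds = [(c_theta[j], float(angles[j]), float(e_theta[j])) for j in idx]
    seeds.append(best)
    result = min((polish(*s) for s in seeds), key=lambda r: r[2])
    return result
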