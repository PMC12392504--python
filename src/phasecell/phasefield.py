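"""Phase-field representation of the cell and its relaxational dynamics.

The cell shape is a smooth field ϕ(r, t) ∈ [0, 1] whose ϕ=1/2 level set is
the cell boundary.  Its evolution combines energy minimization (an
interfacial double-well energy plus a soft area constraint) with advection
by the velocity field obtained from local force balance:

    ∂ϕ/∂t + v·∇ϕ = −ℳ δF/δϕ,          η v = (δF/δϕ)∇ϕ + f_motility,

with f_motility = α P ϕ²(1−ϕ)² (1−χ) n̂ and n̂ = −∇ϕ/|∇ϕ|.  Both force
densities act along ∇ϕ, so the advection term is evaluated scalar-wise,
v·∇ϕ = (1/η)[μ|∇ϕ|² − α P ϕ²(1−ϕ)²(1−χ)|∇ϕ|], which avoids forming vector
fields in the inner loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .fields import Grid, ScalarField2D, gradient, laplacian
from .params import ModelParams, ParameterError


class NumericalFailure(RuntimeError):
    """The explicit update produced non-finite values."""


class EmptyCellError(ValueError):
    """No ϕ=1/2 level set exists in the field."""


class PhiOvershootWarning(UserWarning):
    """ϕ left the tolerated band [−ε_ϕ, 1+ε_ϕ]."""


@dataclass
class Contour:
    """Closed ϕ=1/2 polyline with outward normals (all lengths in μm)."""

    points: np.ndarray        # (n, 2) ordered closed sequence, first != last
    normals: np.ndarray       # (n, 2) outward unit vectors
    arclengths: np.ndarray    # (n,) cumulative arc length from point 0
    perimeter: float
    ruptured: bool = False    # more than one connected ϕ>1/2 component

    def __len__(self) -> int:
        return len(self.points)


def double_well(phi: np.ndarray) -> np.ndarray:
    """G(ϕ) = ϕ²(1−ϕ)², minimal at the two bulk phases."""
    return phi ** 2 * (1.0 - phi) ** 2


def double_well_prime(phi: np.ndarray) -> np.ndarray:
    """G'(ϕ) = 2ϕ(1−ϕ)(1−2ϕ)."""
    return 2.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def functional_derivative_CH(phi: ScalarField2D,
                             params: ModelParams) -> ScalarField2D:
    """δF_CH/δϕ = γ[(c/λ)G'(ϕ) − λ∇²ϕ] for the interfacial energy.

    Vanishes identically on uniform bulk fields (ϕ≡0 or ϕ≡1) and, up to
    discretization error, on the equilibrium 1D front
    ϕ(x) = 1/(1+e^{−√(2c)x/λ}).
    """
    if params.lam <= 0 or params.gamma <= 0:
        raise ParameterError("lam and gamma must be positive")
    g = params.gamma * params.gamma0
    mu = g * ((params.c_well / params.lam) * double_well_prime(phi.values)
              - params.lam * laplacian(phi.values, phi.dx))
    return phi.like(mu)


def cell_area(phi: ScalarField2D) -> float:
    """A = ∫ϕ² dr by grid quadrature, μm²."""
    return float(np.sum(phi.values ** 2) * phi.dx ** 2)


def functional_derivative_area(phi: ScalarField2D,
                               params: ModelParams) -> ScalarField2D:
    """δF_area/δϕ = −(4κ/πR0²)(1 − A/πR0²)ϕ with A = ∫ϕ² dr."""
    params.validate()
    A0 = params.target_area
    A = cell_area(phi)
    coef = -(4.0 * params.kappa * params.gamma0 / A0) * (1.0 - A / A0)
    return phi.like(coef * phi.values)


def functional_derivative(phi: ScalarField2D,
                          params: ModelParams) -> ScalarField2D:
    """Total δF/δϕ = δF_CH/δϕ + δF_area/δϕ."""
    mu = functional_derivative_CH(phi, params).values
    mu += functional_derivative_area(phi, params).values
    return phi.like(mu)


def free_energy(phi: ScalarField2D, params: ModelParams) -> float:
    """F_CH + F_area (γ0 energy units); non-increasing under relaxation."""
    gx, gy = gradient(phi.values, phi.dx)
    g = params.gamma * params.gamma0
    f_ch = g * ((params.c_well / params.lam) * double_well(phi.values)
                + (params.lam / 2.0) * (gx ** 2 + gy ** 2))
    A0 = params.target_area
    f_area = params.kappa * params.gamma0 * (1.0 - cell_area(phi) / A0) ** 2
    return float(np.sum(f_ch) * phi.dx ** 2 + f_area)


def motility_prefactor(phi_values: np.ndarray, P_values: np.ndarray,
                       chi_values: np.ndarray, params: ModelParams
                       ) -> np.ndarray:
    """Scalar magnitude α P ϕ²(1−ϕ)²(1−χ) of the motility force density."""
    return (params.alpha * params.gamma0 * P_values
            * double_well(phi_values) * (1.0 - chi_values))


def velocity_field(phi: ScalarField2D, P: ScalarField2D, chi: ScalarField2D,
                   params: ModelParams
                   ) -> tuple[ScalarField2D, ScalarField2D]:
    """Force-balance velocity v = (1/η)[(δF/δϕ)∇ϕ + f_motility].

    Returns (vx, vy) as fields on the same grid.  The outward normal
    n̂ = −∇ϕ/|∇ϕ| is set to zero where |∇ϕ| falls below the gradient floor;
    the motility force is negligible there anyway since ϕ²(1−ϕ)² ≈ 0.
    """
    if not (phi.grid == P.grid and phi.grid == chi.grid):
        raise ValueError("phi, P and chi must share one grid")
    gx, gy = gradient(phi.values, phi.dx)
    gnorm = np.hypot(gx, gy)
    mu = functional_derivative(phi, params).values
    eta = params.eta * params.gamma0
    fmag = motility_prefactor(phi.values, P.values, chi.values, params)
    floor = params.numerics.grad_floor / phi.dx
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat_x = np.where(gnorm > floor, -gx / gnorm, 0.0)
        nhat_y = np.where(gnorm > floor, -gy / gnorm, 0.0)
    vx = (mu * gx + fmag * nhat_x) / eta
    vy = (mu * gy + fmag * nhat_y) / eta
    return phi.like(vx), phi.like(vy)


def _one_sided_differences(values: np.ndarray, dx: float):
    """Backward/forward differences with replicated (Neumann) edges."""
    p = np.empty((values.shape[0] + 2, values.shape[1] + 2))
    p[1:-1, 1:-1] = values
    p[0, 1:-1] = values[0]
    p[-1, 1:-1] = values[-1]
    p[:, 0] = p[:, 1]
    p[:, -1] = p[:, -2]
    c = p[1:-1, 1:-1]
    dxm = (c - p[1:-1, :-2]) / dx
    dxp = (p[1:-1, 2:] - c) / dx
    dym = (c - p[:-2, 1:-1]) / dx
    dyp = (p[2:, 1:-1] - c) / dx
    return dxm, dxp, dym, dyp


def upwind_gradient_norm(values: np.ndarray, speed: np.ndarray,
                         dx: float) -> np.ndarray:
    """Godunov-upwind |∇ϕ| for the normal-motion term ϕ_t = −w|∇ϕ|.

    Central differencing of the advection term oscillates when the local
    motility speed is large compared with the diffusive regularization
    (cell Péclet ≫ 1); the standard level-set upwinding cures this.
    """
    dxm, dxp, dym, dyp = _one_sided_differences(values, dx)
    plus = np.sqrt(np.maximum(dxm, 0.0) ** 2 + np.minimum(dxp, 0.0) ** 2
                   + np.maximum(dym, 0.0) ** 2 + np.minimum(dyp, 0.0) ** 2)
    minus = np.sqrt(np.minimum(dxm, 0.0) ** 2 + np.maximum(dxp, 0.0) ** 2
                    + np.minimum(dym, 0.0) ** 2 + np.maximum(dyp, 0.0) ** 2)
    return np.where(speed > 0.0, plus, minus)


def phase_field_rhs(phi_values: np.ndarray, P_values: np.ndarray,
                    chi_values: np.ndarray, dx: float, params: ModelParams
                    ) -> np.ndarray:
    """∂ϕ/∂t = −v·∇ϕ − ℳ δF/δϕ evaluated scalar-wise (see module docs).

    Both force densities act along the interface normal, so the advection
    reduces to normal motion with speed w = (μ|∇ϕ| − f_mot)/η (measured
    along +∇ϕ, i.e. w < 0 pushes the front outward); the transported
    gradient is discretized with Godunov upwinding.
    """
    g = params.gamma * params.gamma0
    mu = g * ((params.c_well / params.lam) * double_well_prime(phi_values)
              - params.lam * laplacian(phi_values, dx))
    A0 = params.target_area
    A = float(np.sum(phi_values ** 2) * dx * dx)
    mu += (-(4.0 * params.kappa * params.gamma0 / A0) * (1.0 - A / A0)
           * phi_values)
    gx, gy = gradient(phi_values, dx)
    gnorm = np.sqrt(gx * gx + gy * gy)
    fmag = motility_prefactor(phi_values, P_values, chi_values, params)
    eta = params.eta * params.gamma0
    w = (mu * gnorm - fmag) / eta
    grad_up = upwind_gradient_norm(phi_values, w, dx)
    return -w * grad_up - params.M * mu


def step_phase_field(phi: ScalarField2D, P: ScalarField2D,
                     chi: ScalarField2D, dt: float,
                     params: ModelParams) -> ScalarField2D:
    """One explicit Euler step of the ϕ dynamics.

    Raises a configuration error when dt exceeds the diffusive stability
    bound, and a :class:`NumericalFailure` (with diagnostics) if the update
    produces non-finite values.  ϕ is not clipped; overshoots beyond the
    tolerance ε_ϕ raise a :class:`PhiOvershootWarning`.
    """
    if dt > params.dt_stability_bound():
        raise ParameterError(
            f"dt={dt} exceeds the diffusive stability bound "
            f"{params.dt_stability_bound():.4g} min at dx={phi.dx}")
    new = phi.values + dt * phase_field_rhs(
        phi.values, P.values, chi.values, phi.dx, params)
    if not np.all(np.isfinite(new)):
        bad = int(np.sum(~np.isfinite(new)))
        raise NumericalFailure(
            f"phase-field update produced {bad} non-finite nodes "
            f"(dt={dt}, max|phi|={np.nanmax(np.abs(phi.values)):.3g})")
    eps = params.numerics.eps_phi
    lo, hi = float(new.min()), float(new.max())
    if lo < -eps or hi > 1.0 + eps:
        warnings.warn(
            f"phi overshoot beyond tolerance: range [{lo:.3g}, {hi:.3g}]",
            PhiOvershootWarning, stacklevel=2)
    return phi.like(new)


def center_of_mass(phi: ScalarField2D) -> tuple[float, float]:
    """ϕ-weighted centroid ∫rϕ / ∫ϕ, μm."""
    total = float(np.sum(phi.values))
    if total <= 0:
        raise EmptyCellError("center of mass of an empty field")
    x, y = phi.grid.x, phi.grid.y
    cx = float(np.sum(phi.values.sum(axis=0) * x)) / total
    cy = float(np.sum(phi.values.sum(axis=1) * y)) / total
    return cx, cy


def interface_perimeter(phi: ScalarField2D) -> float:
    """Perimeter estimate s = ∫|∇ϕ| dr (exact for a unit-height front).

    Cheap enough to evaluate every time step; agrees with the contour
    perimeter to discretization error for a relaxed interface.
    """
    gx, gy = gradient(phi.values, phi.dx)
    return float(np.sum(np.hypot(gx, gy)) * phi.dx ** 2)


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def extract_contour(phi: ScalarField2D, level: float = 0.5) -> Contour:
    """Ordered closed ϕ=1/2 polyline with outward normals.

    When several closed components exist (cell rupture), the largest by
    enclosed area is returned and the ``ruptured`` flag is set.
    """
    if float(phi.values.max()) <= level:
        raise EmptyCellError("no phi level set above the contour level")
    raw = measure.find_contours(phi.values, level)
    closed = [c for c in raw
              if np.allclose(c[0], c[-1]) and len(c) > 3]
    if not closed:
        # a level set truncated by the domain edge (escaping cell): fall
        # back to the longest open component, treated as closed
        open_ = [c for c in raw if len(c) > 3]
        if not open_:
            raise EmptyCellError("no closed level-set component found")
        closed = [max(open_, key=len)]
    # convert (row, col) to physical (x, y), dropping the duplicate endpoint
    polys = []
    for c in closed:
        pts = np.column_stack([
            phi.origin[0] + c[:-1, 1] * phi.dx,
            phi.origin[1] + c[:-1, 0] * phi.dx,
        ])
        polys.append(pts)
    areas = [abs(_polygon_area(p)) for p in polys]
    order = int(np.argmax(areas))
    ruptured = sum(a > 1e-9 for a in areas) > 1
    pts = polys[order]

    gx, gy = gradient(phi.values, phi.dx)
    fgx = phi.like(gx).sample(pts[:, 0], pts[:, 1])
    fgy = phi.like(gy).sample(pts[:, 0], pts[:, 1])
    norm = np.hypot(fgx, fgy)
    norm[norm == 0] = 1.0
    normals = np.column_stack([-fgx / norm, -fgy / norm])

    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return Contour(points=pts, normals=normals, arclengths=arc,
                   perimeter=float(seg.sum()), ruptured=ruptured)


def count_components(phi: ScalarField2D, level: float = 0.5,
                     min_area: float = 0.0) -> int:
    """Number of connected ϕ>level components larger than min_area (μm²)."""
    from scipy import ndimage

    labels, n = ndimage.label(phi.values > level)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1)) * phi.dx ** 2
    return int(np.sum(sizes > min_area))


def make_disk(grid: Grid, center: tuple[float, float], R: float,
              lam: float, c_well: float = 16.0,
              area_corrected: bool = False) -> ScalarField2D:
    """Logistic-profile disk matching the equilibrium 1D front shape.

    With ``area_corrected`` the level-set radius is inflated by 1/k
    (k = √(2c)/λ, the interface decay rate) so that the quadratic area
    ∫ϕ² dr matches πR² to leading order in 1/(kR): the smooth interface
    removes ∫(H(−u)−ϕ²(u))du = 1/k of area per unit of circumference.
    """
    X, Y = grid.meshgrid()
    r = np.hypot(X - center[0], Y - center[1])
    k = np.sqrt(2.0 * c_well) / lam
    R_level = R + (1.0 / k if area_corrected else 0.0)
    return ScalarField2D(
        1.0 / (1.0 + np.exp(np.clip(k * (r - R_level), -60, 60))), grid)
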