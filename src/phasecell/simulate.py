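"""Full cell simulations: the coupled ϕ/P/patch loop and seeded ensembles.

A run couples three ingredients per time step: (1) the deterministic decay
and inhibition of the polarity field, (2) an activity-patch impulse whenever
the simulation clock crosses a multiple of τf, and (3) one explicit Euler
step of the phase field driven by energy relaxation and the polarity-derived
motility force.  The center of mass, area and perimeter are recorded on a
fixed sampling interval.  Runs are bit-reproducible for a fixed
(params, pattern, duration, seed) tuple.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage

from .fields import Grid, ScalarField2D, gradient
from .micropattern import PatternSpec, build_pattern, default_grid
from .params import ModelParams, ParameterError
from .phasefield import (NumericalFailure, extract_contour, make_disk,
                         phase_field_rhs)
from .polarity import PatchScheduler, apply_activity_patch, draw_patch

#: a second ϕ>1/2 component larger than this fraction of πR0² marks rupture
RUPTURE_AREA_FRACTION = 0.05


@dataclass
class CellState:
    """Complete state of one simulated cell."""

    phi: ScalarField2D
    P: ScalarField2D
    t: float
    rng: np.random.Generator

    def __post_init__(self) -> None:
        if not (self.phi.grid == self.P.grid):
            raise ValueError("phi and P must share one grid")


@dataclass
class Trajectory:
    """Recorded time series of one run (times in min, lengths in μm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: np.ndarray
    perimeter: np.ndarray
    seed: int | None = None
    ruptured: bool = False
    escaped: bool = False
    failed: bool = False
    patch_log: np.ndarray | None = None   # columns (t, theta_x, theta_y, beta)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("x", "y", "area", "perimeter"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory series lengths differ")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def ok(self) -> bool:
        return not (self.ruptured or self.failed)


@dataclass
class TrajectorySet:
    """An ensemble of runs sharing parameters and pattern."""

    runs: list
    params_hash: str = ""
    pattern_kind: str = ""
    meta: dict = dataclass_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.runs)

    def valid_runs(self) -> list:
        return [r for r in self.runs if r.ok]

    def n_excluded(self) -> int:
        return len(self.runs) - len(self.valid_runs())


def initialize_cell(pattern: PatternSpec, mode: str, params: ModelParams,
                    seed: int, grid: Grid | None = None) -> CellState:
    """Place a logistic-profile disk of radius R0 on the pattern.

    ``basin_random`` picks one of the two basins uniformly and jitters the
    center uniformly over positions that keep the disk inside the basin;
    ``uniform_x`` draws x uniformly over positions keeping the disk inside
    the rectangle (used for rectangular patterns); ``center`` places the
    disk at the origin.  P starts at zero everywhere.
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = default_grid(pattern, params.numerics.dx, params.numerics.pad)
    R0 = params.R0
    if mode == "center":
        center = (0.0, 0.0)
    elif mode == "basin_random":
        b = pattern.basin_size
        margin = b / 2.0 - R0
        if margin < 0:
            raise ParameterError(
                f"R0={R0} does not fit in a {b}x{b} basin")
        basin_cx = pattern.bridge_length / 2.0 + b / 2.0
        side = 1.0 if rng.random() < 0.5 else -1.0
        jx = rng.uniform(-margin, margin)
        jy = rng.uniform(-margin, margin)
        center = (side * basin_cx + jx, jy)
    elif mode == "uniform_x":
        half = pattern.rect_width / 2.0 - R0
        if half < 0:
            raise ParameterError("R0 too large for the rectangle")
        center = (rng.uniform(-half, half), 0.0)
    else:
        raise ParameterError(f"unknown initialization mode {mode!r}")
    phi = make_disk(grid, center, R0, params.lam, params.c_well,
                    area_corrected=True)
    P = ScalarField2D(np.zeros(grid.shape), grid)
    return CellState(phi=phi, P=P, t=0.0, rng=rng)


#: largest per-step change of ϕ tolerated before the step is subdivided
MAX_PHI_STEP = 0.15


def _coupled_step(phi: np.ndarray, P: np.ndarray, chi: np.ndarray,
                  dx: float, dt: float, params: ModelParams,
                  freeze_shape: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """One fused explicit step of (ϕ, P); returns (ϕ', P', perimeter).

    The ϕ update is adaptively subdivided whenever the advective speed
    (driven by polarity spikes) would move ϕ by more than MAX_PHI_STEP in
    a single step; the subdivision is deterministic, so runs stay
    bit-reproducible.
    """
    gx, gy = gradient(phi, dx)
    grad_sq = gx * gx + gy * gy
    s = float(np.sum(np.sqrt(grad_sq)) * dx * dx)

    # deterministic polarity terms
    rhs_P = -P / params.tau
    if not params.no_chi_coupling:
        rhs_P = rhs_P - (chi * phi) / params.tau_chi
    if not params.no_perimeter_inhibition and s > params.s0:
        rhs_P = rhs_P - (s / params.s0) ** 2 / params.tau_s * phi
    P_new = P + dt * rhs_P

    if freeze_shape:
        return phi, P_new, s

    f = phi
    remaining = dt
    for _ in range(400):
        r = phase_field_rhs(f, P, chi, dx, params)
        peak = float(np.max(np.abs(r)))
        if not np.isfinite(peak):
            raise NumericalFailure(
                "non-finite phase-field rate of change")
        h = remaining if peak * remaining <= MAX_PHI_STEP \
            else MAX_PHI_STEP / peak
        f = f + h * r
        remaining -= h
        if remaining <= 1e-12:
            return f, P_new, s
    raise NumericalFailure(
        f"phase-field step did not complete: residual dt {remaining:.3g} "
        f"of {dt} min after 400 substeps (peak rate {peak:.3g}/min)")


def run_simulation(params: ModelParams, pattern: PatternSpec,
                   duration: float, seed: int, *,
                   init_mode: str | None = None,
                   freeze_shape: bool = False,
                   record_fields: bool = False,
                   log_patches: bool = False,
                   chi: ScalarField2D | None = None,
                   state: CellState | None = None,
                   ) -> Trajectory:
    """Simulate one cell for ``duration`` minutes and record its trajectory.

    ``freeze_shape`` holds ϕ fixed and evolves only the polarity (used to
    study the polarity model decoupled from boundary motion).  When
    ``record_fields`` is set, per-sample snapshots of ϕ and P are attached
    to the returned trajectory as ``traj.fields`` (a list of arrays).
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    dt = params.numerics.dt
    if dt > params.dt_stability_bound():
        raise ParameterError("dt exceeds the diffusive stability bound")
    if init_mode is None:
        init_mode = ("basin_random" if pattern.kind == "two_state"
                     else "uniform_x" if pattern.kind == "rectangle"
                     else "center")
    if state is None:
        grid = None if chi is None else chi.grid
        state = initialize_cell(pattern, init_mode, params, seed, grid=grid)
    if chi is None:
        chi = build_pattern(pattern, state.phi.grid)
    elif not (chi.grid == state.phi.grid):
        raise ValueError("chi grid does not match the cell grid")

    grid = state.phi.grid
    dx = grid.dx
    phi = state.phi.values.copy()
    P = state.P.values.copy()
    rng = state.rng
    scheduler = PatchScheduler(params.tau_f, t0=state.t)

    xmin, ymin, xmax, ymax = pattern.bounding_box()
    escape_margin = params.R0 / 2.0
    x_sum = grid.x
    y_sum = grid.y
    A0 = params.target_area

    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(params.numerics.sample_interval / dt)))
    times, xs, ys, areas, perims = [], [], [], [], []
    snapshots = [] if record_fields else None
    patch_rows = [] if log_patches else None
    ruptured = False
    escaped = False
    failed = False
    t = state.t

    def record(s_now: float) -> None:
        total = float(phi.sum())
        cx = float((phi.sum(axis=0) * x_sum).sum()) / total
        cy = float((phi.sum(axis=1) * y_sum).sum()) / total
        times.append(t)
        xs.append(cx)
        ys.append(cy)
        areas.append(float(np.sum(phi * phi)) * dx * dx)
        perims.append(s_now)
        if snapshots is not None:
            snapshots.append((phi.copy(), P.copy()))

    gx0, gy0 = gradient(phi, dx)
    record(float(np.sum(np.hypot(gx0, gy0)) * dx * dx))

    sustained = params.patch_mode == "sustained"
    patch_rate = np.zeros(grid.shape) if sustained else None
    X_mesh, Y_mesh = grid.meshgrid() if sustained else (None, None)

    for k in range(1, n_steps + 1):
        if sustained:
            # the active patch acts as a polarity source over its window
            P = P + dt * patch_rate * phi
        try:
            phi, P, s = _coupled_step(phi, P, chi.values, dx, dt, params,
                                      freeze_shape)
        except (FloatingPointError, NumericalFailure):
            failed = True
            break
        if not np.isfinite(phi).all() or not np.isfinite(P).all():
            failed = True
            break
        t = state.t + k * dt

        if scheduler.due(t):
            phi_f = ScalarField2D(phi, grid)
            P_f = ScalarField2D(P, grid)
            try:
                contour = extract_contour(phi_f)
            except Exception:
                failed = True
                break
            while scheduler.due(t):
                theta, beta = draw_patch(rng, contour, P_f, chi, params)
                if not sustained:
                    P_f = apply_activity_patch(P_f, theta, beta,
                                               params.sigma, phi_f)
                if patch_rows is not None:
                    patch_rows.append((t, theta[0], theta[1], beta))
                scheduler.advance()
            if sustained:
                r2 = ((X_mesh - theta[0]) ** 2 + (Y_mesh - theta[1]) ** 2)
                patch_rate = beta * np.exp(-r2 / (2.0 * params.sigma ** 2))
            else:
                P = P_f.values

        if k % rec_every == 0:
            record(s)
            # rupture: a second ϕ>1/2 component above the area cutoff
            labels, ncomp = ndimage.label(phi > 0.5)
            if ncomp > 1:
                sizes = np.sort(ndimage.sum_labels(
                    np.ones_like(labels), labels,
                    index=np.arange(1, ncomp + 1)))[::-1] * dx * dx
                if sizes[1] > RUPTURE_AREA_FRACTION * A0:
                    ruptured = True
            if np.isfinite(xmin):
                cx, cy = xs[-1], ys[-1]
                if (cx < xmin - escape_margin or cx > xmax + escape_margin
                        or cy < ymin - escape_margin
                        or cy > ymax + escape_margin):
                    escaped = True

    state.phi = ScalarField2D(phi, grid)
    state.P = ScalarField2D(P, grid)
    state.t = t

    traj = Trajectory(
        times=np.asarray(times), x=np.asarray(xs), y=np.asarray(ys),
        area=np.asarray(areas), perimeter=np.asarray(perims),
        seed=seed, ruptured=ruptured, escaped=escaped, failed=failed,
        patch_log=(np.asarray(patch_rows) if patch_rows else None))
    if snapshots is not None:
        traj.fields = snapshots
    traj.final_state = state
    return traj


def run_ensemble(params: ModelParams, pattern: PatternSpec, N: int,
                 duration: float, base_seed: int, **kwargs) -> TrajectorySet:
    """N independent seeded runs (seeds base_seed … base_seed+N−1).

    Ruptured or failed runs stay in ``runs`` with their flags set and are
    excluded from downstream inference via :meth:`TrajectorySet.valid_runs`.
    """
    if N < 1:
        raise ParameterError("ensemble size must be at least 1")
    grid = default_grid(pattern, params.numerics.dx, params.numerics.pad)
    chi = build_pattern(pattern, grid)
    runs = []
    for i in range(N):
        runs.append(run_simulation(params, pattern, duration,
                                   seed=base_seed + i, chi=chi, **kwargs))
    from .io import params_digest

    return TrajectorySet(runs=runs, params_hash=params_digest(params),
                         pattern_kind=pattern.kind,
                         meta={"base_seed": base_seed, "N": N,
                               "duration": duration,
                               "n_excluded": sum(not r.ok for r in runs)})
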