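"""Data-driven reconstruction of the cell's equation of motion.

The center-of-mass dynamics are represented by the underdamped stochastic
model  v̇ = F(x, v) + σ(x, v)η(t),  and the deterministic part is estimated
nonparametrically as the conditional mean acceleration,
F(x, v) = ⟨v̇ | x, v⟩, on a rectangular (x, v) lattice.  Velocities and
accelerations are forward finite differences of the sampled position at an
interval Δt_sample, and a_k is conditioned on (x_k, v_k).

The estimated field is summarized by its streamlines: Euler iterates
(x, v) ← (x + v·dt, v + F·dt) seeded on a lattice.  Streamlines that reach
a point with both speed and acceleration near zero terminate; terminal
points are clustered and the portrait is labeled limit_cycle, bistable,
stationary, or other.  Bootstrap resampling of whole trajectories
quantifies the sampling variability of the labels, terminal points, and
separatrices.

Note on discretization bias: for coarsely sampled underdamped dynamics the
finite-difference velocity shares noise with the acceleration it is
conditioned on, so the apparent linear friction slope of F(0, v) is
(ρ(ξΔ)−1)/Δ rather than −ξ, where ρ is the lag-one correlation of position
increments of an Ornstein–Uhlenbeck velocity.  The helper
:func:`implied_friction_coefficient` inverts this exact relation to recover
the continuous-time friction coefficient from the measured slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import optimize, stats


@dataclass
class KinematicsSamples:
    """(x, v, a) triples in μm, μm/min, μm/min², tagged by source run."""

    x: np.ndarray
    v: np.ndarray
    a: np.ndarray
    run_id: np.ndarray
    dt_sample: float

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.v) == len(self.a) == len(self.run_id) == n):
            raise ValueError("kinematics arrays must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class DriftField:
    """Binned conditional-mean acceleration F(x, v) with sample counts."""

    x_edges: np.ndarray
    v_edges: np.ndarray
    F: np.ndarray          # (n_xbins, n_vbins); NaN on masked bins
    counts: np.ndarray
    noise: np.ndarray | None = None   # per-bin std of a (σ(x,v) estimate)
    min_count: int = 20

    def __post_init__(self) -> None:
        for e in (self.x_edges, self.v_edges):
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def v_centers(self) -> np.ndarray:
        return 0.5 * (self.v_edges[:-1] + self.v_edges[1:])

    @property
    def mask(self) -> np.ndarray:
        """True on bins with enough samples to trust F."""
        return self.counts >= self.min_count

    def interpolator(self) -> "MaskedBilinear":
        return MaskedBilinear(self)


@dataclass
class PhasePortrait:
    """Streamlines, terminal structure and the categorical motility label."""

    streamlines: list
    terminal_points: np.ndarray         # (n, 2), possibly empty
    terminal_group: np.ndarray          # group index per terminated line
    cycling: np.ndarray                 # bool per streamline
    separatrices: list = dataclass_field(default_factory=list)
    label: str = "other"
    diagnostics: dict = dataclass_field(default_factory=dict)


def finite_difference_kinematics(times: np.ndarray, x: np.ndarray,
                                 dt_sample: float,
                                 run_id: int = 0) -> KinematicsSamples:
    """Forward-difference (x, v, a) samples from one recorded trajectory.

    The series is first downsampled to the interval Δt_sample (which must
    be a multiple of the recording interval), then
    v_k = (x_{k+1} − x_k)/Δt and a_k = (v_{k+1} − v_k)/Δt, with a_k paired
    with (x_k, v_k).
    """
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples")
    rec = times[1] - times[0]
    stride = int(round(dt_sample / rec))
    if stride < 1 or abs(stride * rec - dt_sample) > 1e-9 * dt_sample:
        raise ValueError(
            f"dt_sample={dt_sample} is not a multiple of the recording "
            f"interval {rec}")
    xs = x[::stride]
    if len(xs) < 3:
        raise ValueError("trajectory too short for this dt_sample")
    v = np.diff(xs) / dt_sample
    a = np.diff(v) / dt_sample
    return KinematicsSamples(x=xs[:-2], v=v[:-1], a=a,
                             run_id=np.full(len(a), run_id, dtype=int),
                             dt_sample=dt_sample)


def kinematics_from_runs(runs, dt_sample: float) -> KinematicsSamples:
    """Pool finite-difference samples over an iterable of trajectories."""
    parts = []
    for i, r in enumerate(runs):
        times, x = (r.times, r.x) if hasattr(r, "times") else r
        parts.append(finite_difference_kinematics(times, x, dt_sample, i))
    if not parts:
        raise ValueError("no trajectories supplied")
    return KinematicsSamples(
        x=np.concatenate([p.x for p in parts]),
        v=np.concatenate([p.v for p in parts]),
        a=np.concatenate([p.a for p in parts]),
        run_id=np.concatenate([p.run_id for p in parts]),
        dt_sample=dt_sample)


def default_edges(samples: KinematicsSamples, n_x: int = 36, n_v: int = 30,
                  x_extent: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Default lattice: n_x bins over the x extent (the pattern extent if
    given, else the central 98% of the data), n_v bins over the central
    98% of v."""
    if x_extent is None:
        xlo, xhi = np.percentile(samples.x, [1.0, 99.0])
        if xhi <= xlo:
            xlo, xhi = float(samples.x.min()), float(samples.x.max() + 1e-9)
        x_extent = (float(xlo), float(xhi))
    vlo, vhi = np.percentile(samples.v, [1.0, 99.0])
    if vhi <= vlo:
        vlo, vhi = float(samples.v.min()), float(samples.v.max() + 1e-9)
    return (np.linspace(x_extent[0], x_extent[1], n_x + 1),
            np.linspace(vlo, vhi, n_v + 1))


def estimate_drift_field(samples: KinematicsSamples,
                         x_edges: np.ndarray, v_edges: np.ndarray,
                         min_count: int = 20) -> DriftField:
    """Binned conditional mean of the acceleration, F = ⟨a | x, v⟩.

    Bins with fewer than ``min_count`` samples are masked (NaN).  The
    per-bin standard deviation of a is returned as a σ(x, v) estimate; it
    is reported but not used by the downstream phase-portrait analysis.
    """
    if len(samples) == 0:
        raise ValueError("no kinematics samples")
    mean, _, _, _ = stats.binned_statistic_2d(
        samples.x, samples.v, samples.a, statistic="mean",
        bins=[x_edges, v_edges])
    count, _, _, _ = stats.binned_statistic_2d(
        samples.x, samples.v, samples.a, statistic="count",
        bins=[x_edges, v_edges])
    sd, _, _, _ = stats.binned_statistic_2d(
        samples.x, samples.v, samples.a, statistic="std",
        bins=[x_edges, v_edges])
    count = count.astype(int)
    if not np.any(count >= min_count):
        raise ValueError(
            f"no (x, v) bin reaches min_count={min_count}; "
            "supply more data or coarser bins")
    F = np.where(count >= min_count, mean, np.nan)
    noise = np.where(count >= min_count, sd, np.nan)
    return DriftField(x_edges=np.asarray(x_edges, float),
                      v_edges=np.asarray(v_edges, float),
                      F=F, counts=count, noise=noise, min_count=min_count)


def drift_field_from_function(func, x_edges: np.ndarray,
                              v_edges: np.ndarray) -> DriftField:
    """Evaluate an analytic drift F*(x, v) on the bin-center lattice."""
    xe, ve = np.asarray(x_edges, float), np.asarray(v_edges, float)
    xc = 0.5 * (xe[:-1] + xe[1:])
    vc = 0.5 * (ve[:-1] + ve[1:])
    X, V = np.meshgrid(xc, vc, indexing="ij")
    F = np.asarray(func(X, V), float)
    counts = np.full(F.shape, np.iinfo(np.int32).max, dtype=int)
    return DriftField(x_edges=xe, v_edges=ve, F=F, counts=counts,
                      min_count=1)


class MaskedBilinear:
    """Bilinear interpolation of F over bin centers, honoring the mask.

    A query point is supported only if the four surrounding bin centers all
    carry unmasked values; outside the supported region ``None`` is
    returned, so streamline integration never reads masked bins.
    """

    def __init__(self, field: DriftField):
        self.xc = field.x_centers
        self.vc = field.v_centers
        self.F = field.F
        self.valid = field.mask & np.isfinite(field.F)

    def __call__(self, x: float, v: float) -> float | None:
        xc, vc = self.xc, self.vc
        if not (xc[0] <= x <= xc[-1] and vc[0] <= v <= vc[-1]):
            return None
        i = min(int(np.searchsorted(xc, x) - 1), len(xc) - 2)
        j = min(int(np.searchsorted(vc, v) - 1), len(vc) - 2)
        i = max(i, 0)
        j = max(j, 0)
        if not (self.valid[i, j] and self.valid[i + 1, j]
                and self.valid[i, j + 1] and self.valid[i + 1, j + 1]):
            return None
        tx = (x - xc[i]) / (xc[i + 1] - xc[i])
        tv = (v - vc[j]) / (vc[j + 1] - vc[j])
        f = self.F
        return float(
            f[i, j] * (1 - tx) * (1 - tv) + f[i + 1, j] * tx * (1 - tv)
            + f[i, j + 1] * (1 - tx) * tv + f[i + 1, j + 1] * tx * tv)


@dataclass
class StreamlineSettings:
    """Numerical settings for streamline tracing and termination."""

    dt: float = 0.1            # min per Euler step
    max_steps: int = 100_000
    eps_v: float | None = None   # default: 5% of RMS |v| over the lattice
    eps_F: float | None = None   # default: 5% of RMS |F|
    n_seed_x: int = 12
    n_seed_v: int = 12
    tail_fraction: float = 0.25  # late-orbit window for the recurrence test


def _terminal_tolerances(field: DriftField,
                         settings: StreamlineSettings) -> tuple[float, float]:
    vc = field.v_centers
    v_rms = float(np.sqrt(np.mean(vc ** 2)))
    f_vals = field.F[field.mask & np.isfinite(field.F)]
    f_rms = float(np.sqrt(np.mean(f_vals ** 2))) if len(f_vals) else 1.0
    eps_v = settings.eps_v if settings.eps_v is not None else 0.05 * v_rms
    eps_F = settings.eps_F if settings.eps_F is not None else 0.05 * f_rms
    return eps_v, eps_F


def _is_recurrent(path: np.ndarray, r_c: float, tail_fraction: float) -> bool:
    """Late-time loop-closure test for a non-terminating orbit.

    The tail of the orbit must revisit the neighborhood of an earlier tail
    point while winding around the tail centroid.
    """
    n = len(path)
    if n < 100:
        return False
    tail = path[int((1.0 - tail_fraction) * n):]
    center = tail.mean(axis=0)
    rel = tail - center
    scale = np.array([np.ptp(tail[:, 0]) + 1e-12, np.ptp(tail[:, 1]) + 1e-12])
    if min(scale) < 1e-9:
        return False
    ang = np.unwrap(np.arctan2(rel[:, 1] / scale[1], rel[:, 0] / scale[0]))
    winding = abs(ang[-1] - ang[0]) / (2.0 * np.pi)
    if winding < 1.0:
        return False
    # revisit: the last point comes back near a much earlier tail point
    d = np.linalg.norm(tail[: len(tail) // 2] - tail[-1], axis=1)
    return bool(np.min(d) < r_c)


try:
    from numba import njit

    @njit(cache=True)
    def _trace_kernel(F, valid, xc, vc, x0, v0, dt, eps_v, eps_F,
                      max_steps):
        """Euler-integrate one streamline; returns (path, n, status).

        status: 0 terminated, 1 left the supported region, 2 hit
        max_steps (cycling candidate).
        """
        path = np.empty((max_steps + 1, 2))
        nx = len(xc)
        nv = len(vc)
        x = x0
        v = v0
        path[0, 0] = x
        path[0, 1] = v
        n = 1
        status = 2
        for _ in range(max_steps):
            if x < xc[0] or x > xc[-1] or v < vc[0] or v > vc[-1]:
                status = 1
                break
            i = np.searchsorted(xc, x) - 1
            j = np.searchsorted(vc, v) - 1
            if i < 0:
                i = 0
            if i > nx - 2:
                i = nx - 2
            if j < 0:
                j = 0
            if j > nv - 2:
                j = nv - 2
            if not (valid[i, j] and valid[i + 1, j] and valid[i, j + 1]
                    and valid[i + 1, j + 1]):
                status = 1
                break
            tx = (x - xc[i]) / (xc[i + 1] - xc[i])
            tv = (v - vc[j]) / (vc[j + 1] - vc[j])
            f = (F[i, j] * (1 - tx) * (1 - tv)
                 + F[i + 1, j] * tx * (1 - tv)
                 + F[i, j + 1] * (1 - tx) * tv
                 + F[i + 1, j + 1] * tx * tv)
            if abs(v) < eps_v and abs(f) < eps_F:
                status = 0
                break
            x = x + v * dt
            v = v + f * dt
            path[n, 0] = x
            path[n, 1] = v
            n += 1
        return path, n, status

except ImportError:     # pragma: no cover - numba is a hard dependency
    _trace_kernel = None


def integrate_streamlines(field: DriftField,
                          settings: StreamlineSettings | None = None,
                          seeds: np.ndarray | None = None) -> PhasePortrait:
    """Trace streamlines of F from a lattice of seeds.

    Each streamline is iterated with x ← x + v·dt, v ← v + F(x, v)·dt and
    bilinearly interpolated F.  It terminates at a point where |v| < ε_v
    and |F| < ε_F (recorded as a terminal point), when it leaves the
    supported region, or at max_steps — in which case it is flagged a
    cycling candidate if its late orbit closes on itself.
    """
    settings = settings or StreamlineSettings()
    interp = field.interpolator()
    eps_v, eps_F = _terminal_tolerances(field, settings)
    dx_bin = field.x_edges[1] - field.x_edges[0]
    dv_bin = field.v_edges[1] - field.v_edges[0]
    r_c = float(np.hypot(dx_bin, dv_bin))

    if seeds is None:
        xs = np.linspace(field.x_centers[0], field.x_centers[-1],
                         settings.n_seed_x)
        vs = np.linspace(field.v_centers[0], field.v_centers[-1],
                         settings.n_seed_v)
        seeds = np.array([(x, v) for x in xs for v in vs])

    Fgrid = np.where(np.isfinite(field.F), field.F, 0.0)
    valid = np.ascontiguousarray(interp.valid)
    xc = field.x_centers
    vc = field.v_centers

    streamlines = []
    terminals = []
    cycling = []
    used_seeds = []
    for x0, v0 in seeds:
        if interp(x0, v0) is None:
            continue   # seed outside the supported region
        used_seeds.append((x0, v0))
        path, n, status = _trace_kernel(
            Fgrid, valid, xc, vc, float(x0), float(v0), settings.dt,
            eps_v, eps_F, settings.max_steps)
        path = path[:n].copy()
        terminal = (float(path[-1, 0]), float(path[-1, 1])) \
            if status == 0 else None
        cyc = (status == 2
               and _is_recurrent(path, r_c, settings.tail_fraction))
        streamlines.append(path)
        terminals.append(terminal)
        cycling.append(cyc)

    term_pts = np.array([t for t in terminals if t is not None]
                        ).reshape(-1, 2)
    return PhasePortrait(
        streamlines=streamlines,
        terminal_points=term_pts,
        terminal_group=np.full(len(term_pts), -1, dtype=int),
        cycling=np.asarray(cycling, dtype=bool),
        diagnostics={"eps_v": eps_v, "eps_F": eps_F, "r_c": r_c,
                     "seeds": np.asarray(used_seeds).reshape(-1, 2),
                     "terminals_per_seed": terminals})


def _cluster_points(points: np.ndarray, r_c: float) -> np.ndarray:
    """Single-linkage clustering with linking radius r_c."""
    n = len(points)
    labels = -np.ones(n, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = nxt
        while stack:
            j = stack.pop()
            d = np.hypot(points[:, 0] - points[j, 0],
                         points[:, 1] - points[j, 1])
            near = np.where((d < r_c) & (labels < 0))[0]
            for k in near:
                labels[k] = nxt
                stack.append(int(k))
        nxt += 1
    return labels


def classify_phase_portrait(portrait: PhasePortrait, field: DriftField,
                            geometry_hints: dict | None = None,
                            f_cyc: float = 0.25) -> PhasePortrait:
    """Attach terminal groups, separatrices, and the motility label.

    Labels:

    * ``limit_cycle`` — at least a fraction f_cyc of streamlines are
      non-terminating with recurrent (loop-closing) orbits;
    * ``bistable``    — two dominant terminal clusters at v≈0 whose x
      separation exceeds the hint ``x_sep_min`` (default: a quarter of the
      lattice x-range);
    * ``stationary``  — terminals lie along v≈0 spread over a wide x-range
      without two dominant clusters;
    * ``other``       — anything else.
    """
    hints = dict(geometry_hints or {})
    # x-extent of the populated (trustworthy) part of the lattice
    pop = field.mask.any(axis=1) & np.isfinite(field.F).any(axis=1)
    if pop.any():
        x_range = float(field.x_centers[pop][-1] - field.x_centers[pop][0])
    else:
        x_range = field.x_centers[-1] - field.x_centers[0]
    x_sep_min = hints.get("x_sep_min", 0.25 * x_range)
    dx_bin = field.x_edges[1] - field.x_edges[0]
    dv_bin = field.v_edges[1] - field.v_edges[0]
    r_c = hints.get("r_c", float(np.hypot(dx_bin, dv_bin)))
    eps_v = portrait.diagnostics.get("eps_v", 0.05)

    n_lines = len(portrait.streamlines)
    n_cycling = int(portrait.cycling.sum())
    pts = portrait.terminal_points
    n_term = len(pts)

    label = "other"
    groups = np.full(n_term, -1, dtype=int)
    diag = dict(portrait.diagnostics)
    diag.update({"n_streamlines": n_lines, "n_cycling": n_cycling,
                 "n_terminated": n_term})

    if n_lines and n_cycling / n_lines >= f_cyc:
        label = "limit_cycle"
    if n_term:
        # cluster in a metric where one v-bin counts like one x-bin
        scaled = np.column_stack([pts[:, 0], pts[:, 1] * dx_bin / dv_bin])
        groups = _cluster_points(scaled, r_c)
        sizes = np.bincount(groups)
        order = np.argsort(sizes)[::-1]
        diag["cluster_sizes"] = sizes[order].tolist()
        # "two point attractors": the two largest clusters hold most
        # terminals, each is substantial, and each is tight (point-like,
        # unlike chains of terminals along a stationary v≈0 line)
        two_point_attractors = False
        if len(sizes) >= 2:
            g1, g2 = order[0], order[1]
            p1 = pts[groups == g1]
            p2 = pts[groups == g2]
            c1 = p1.mean(axis=0)
            c2 = p2.mean(axis=0)
            sep = abs(c1[0] - c2[0])
            pair_near_v0 = (abs(c1[1]) < 3 * eps_v
                            and abs(c2[1]) < 3 * eps_v)
            dominant = (sizes[g1] + sizes[g2] >= 0.8 * n_term
                        and sizes[g2] >= 0.2 * n_term)
            tight = (np.ptp(p1[:, 0]) <= 2 * dx_bin
                     and np.ptp(p2[:, 0]) <= 2 * dx_bin)
            two_point_attractors = dominant and tight and pair_near_v0
            if (label == "other" and two_point_attractors
                    and sep > x_sep_min):
                label = "bistable"
                diag["fixed_points"] = [c1.tolist(), c2.tolist()]
        if label == "other":
            spread = np.ptp(pts[:, 0]) if n_term > 1 else 0.0
            near_v0 = bool(np.mean(np.abs(pts[:, 1]) < 3 * eps_v) > 0.8)
            if near_v0 and spread > 4 * dx_bin and not two_point_attractors:
                label = "stationary"

    # separatrices: boundaries between basins of attraction on the seed grid
    separatrices = _separatrices(portrait, groups, r_c)

    return PhasePortrait(streamlines=portrait.streamlines,
                         terminal_points=pts, terminal_group=groups,
                         cycling=portrait.cycling,
                         separatrices=separatrices, label=label,
                         diagnostics=diag)


def _separatrices(portrait: PhasePortrait, groups: np.ndarray,
                  r_c: float) -> list:
    """Boundaries, in the seed lattice, between basins of attraction."""
    seeds = portrait.diagnostics.get("seeds")
    terminals = portrait.diagnostics.get("terminals_per_seed")
    if seeds is None or terminals is None or len(groups) == 0:
        return []
    pts = portrait.terminal_points
    seed_label = []
    ti = 0
    for t in terminals:
        if t is None:
            seed_label.append(-1)
        else:
            seed_label.append(int(groups[ti]))
            ti += 1
    seed_label = np.asarray(seed_label)
    xs = np.unique(seeds[:, 0])
    vs = np.unique(seeds[:, 1])
    if len(xs) * len(vs) != len(seeds):
        return []
    lab = seed_label.reshape(len(xs), len(vs))
    out = []
    for g in np.unique(groups):
        ind = (lab == g).astype(float)
        if ind.sum() in (0, ind.size):
            continue
        from skimage import measure as _measure

        for c in _measure.find_contours(ind, 0.5):
            ix, iv = c[:, 0], c[:, 1]
            out.append(np.column_stack([np.interp(ix, np.arange(len(xs)), xs),
                                        np.interp(iv, np.arange(len(vs)), vs)]))
    return out


def infer_portrait(runs, dt_sample: float = 10.0, n_x: int = 36,
                   n_v: int = 30, min_count: int = 20,
                   x_extent: tuple[float, float] | None = None,
                   settings: StreamlineSettings | None = None,
                   geometry_hints: dict | None = None
                   ) -> tuple[DriftField, PhasePortrait]:
    """Convenience pipeline: trajectories → drift field → labeled portrait."""
    samples = kinematics_from_runs(runs, dt_sample)
    xe, ve = default_edges(samples, n_x, n_v, x_extent)
    field = estimate_drift_field(samples, xe, ve, min_count)
    portrait = integrate_streamlines(field, settings)
    portrait = classify_phase_portrait(portrait, field, geometry_hints)
    return field, portrait


def increment_autocorrelation(u: float) -> float:
    """Lag-one correlation ρ of position increments for an OU velocity.

    For v̇ = −ξv + noise sampled at interval Δ with u = ξΔ:
    ρ(u) = (1−e^{−u})² / [2(u − 1 + e^{−u})], decreasing from 1 − 2u/3 at
    small u to 0 as u → ∞.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if u < 1e-6:
        return 1.0 - 2.0 * u / 3.0
    return float((1.0 - np.exp(-u)) ** 2
                 / (2.0 * (u - 1.0 + np.exp(-u))))


def implied_friction_coefficient(slope: float, dt_sample: float) -> float:
    """Continuous-time friction ξ implied by a measured F(0, v) slope.

    The finite-difference estimator makes the apparent slope of the
    conditional mean equal to (ρ(ξΔ)−1)/Δ (see module docstring); this
    inverts that relation, assuming locally linear (OU-like) friction.
    Raises for slopes outside the attainable range (slope·Δ ≤ −1 or ≥ 0).
    """
    m = slope * dt_sample
    if m >= 0 or m <= -1.0:
        raise ValueError(
            f"slope*dt={m:.3g} outside (−1, 0); no OU friction matches")
    target = 1.0 + m

    def f(u):
        return increment_autocorrelation(u) - target

    u = optimize.brentq(f, 1e-9, 1e6)
    return u / dt_sample


def bootstrap_inference(runs, B: int, base_seed: int,
                        dt_sample: float = 10.0, n_x: int = 36,
                        n_v: int = 30, min_count: int = 20,
                        x_extent: tuple[float, float] | None = None,
                        settings: StreamlineSettings | None = None,
                        geometry_hints: dict | None = None) -> dict:
    """Whole-trajectory bootstrap of the inference pipeline.

    Resamples the runs with replacement B times, re-runs
    estimate → integrate → classify on each resample, and summarizes label
    frequencies, the scatter of terminal points, and the separatrix
    envelope.  B=0 returns an empty summary.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    summary = {"B": B, "labels": {}, "terminal_points": [],
               "separatrices": []}
    if B == 0:
        return summary
    rng = np.random.default_rng(base_seed)
    for _ in range(B):
        idx = rng.integers(0, len(runs), size=len(runs))
        sample = [runs[i] for i in idx]
        try:
            _, portrait = infer_portrait(
                sample, dt_sample, n_x, n_v, min_count, x_extent,
                settings, geometry_hints)
        except ValueError:
            label = "undetermined"
            summary["labels"][label] = summary["labels"].get(label, 0) + 1
            continue
        summary["labels"][portrait.label] = (
            summary["labels"].get(portrait.label, 0) + 1)
        if len(portrait.terminal_points):
            summary["terminal_points"].append(portrait.terminal_points)
        summary["separatrices"].append(portrait.separatrices)
    summary["label_frequency"] = {
        k: v / B for k, v in summary["labels"].items()}
    if summary["terminal_points"]:
        summary["terminal_scatter"] = np.vstack(summary["terminal_points"])
    return summary
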