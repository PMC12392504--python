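"""Synthetic underdamped SDE trajectories with analytically known drift.

These generators validate the drift-inference pipeline without the cell
simulator in the loop.  Each model integrates

    ẋ = v,    v̇ = F*(x, v) + σ_n η(t)

by Euler–Maruyama and exposes the exact F* for oracle comparisons:

* ``ou``          — F* = −ξ v                        (stationary portrait)
* ``van_der_pol`` — F* = μ(1 − (x/x_s)²) v − ω² x    (limit cycle)
* ``double_well`` — F* = −4k x(x² − x₀²) − ξ v       (bistable)

Default scales mimic the cell problem (x of order tens of μm, v of order
1 μm/min) so the inference defaults transfer unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Trajectory, TrajectorySet

MODEL_NAMES = ("ou", "van_der_pol", "double_well")


@dataclass
class SDEModelSpec:
    """Specification of one synthetic model."""

    name: str = "ou"
    xi: float | None = None    # friction, 1/min (ou, double_well)
    mu: float = 0.025          # limit-cycle gain, 1/min (van_der_pol)
    omega: float = 0.0125      # restoring frequency, 1/min (van_der_pol)
    x_scale: float = 20.0      # μm; vdP nonlinearity scale
    x0: float = 20.0           # μm; double-well minima at ±x0
    stiffness: float = 5e-7    # k, double-well quartic coefficient
    noise: float | None = None  # σ_n, μm/min^{3/2}; per-model default
    x_init: float = 0.0
    v_init: float = 0.0
    init_spread: float = 25.0  # μm; uniform jitter of initial x

    # The default scales mimic the cell problem: positions of order tens
    # of μm, velocities of order 1 μm/min or less, oscillation periods of
    # hours.  Slow dynamics relative to the 10-min inference sampling
    # matter: a portrait whose state moves several lattice bins per
    # sample is smeared beyond recognition by the finite-difference
    # conditioning, no matter how much data is pooled.
    _DEFAULT_XI = {"ou": 0.2, "van_der_pol": 0.0, "double_well": 0.1}
    _DEFAULT_NOISE = {"ou": 0.4, "van_der_pol": 0.05, "double_well": 0.1}

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown SDE model {self.name!r}; "
                             f"choose from {MODEL_NAMES}")
        if self.xi is None:
            self.xi = self._DEFAULT_XI[self.name]
        if self.noise is None:
            self.noise = self._DEFAULT_NOISE[self.name]

    def drift(self):
        """Return the exact drift evaluator F*(x, v) (vectorized)."""
        if self.name == "ou":
            xi = self.xi

            def F(x, v):
                return -xi * np.asarray(v, float) + 0.0 * np.asarray(x)
        elif self.name == "van_der_pol":
            mu, om, xs = self.mu, self.omega, self.x_scale

            def F(x, v):
                x = np.asarray(x, float)
                return mu * (1.0 - (x / xs) ** 2) * v - om ** 2 * x
        else:
            k, x0, xi = self.stiffness, self.x0, self.xi

            def F(x, v):
                x = np.asarray(x, float)
                return -4.0 * k * x * (x ** 2 - x0 ** 2) - xi * v
        return F

    def fastest_timescale(self) -> float:
        """Heuristic fastest relaxation time (min), for the dt check."""
        rates = [1e-12]
        if self.name in ("ou", "double_well"):
            rates.append(self.xi)
        if self.name == "double_well":
            rates.append(np.sqrt(8.0 * self.stiffness * self.x0 ** 2))
        if self.name == "van_der_pol":
            rates.append(self.omega)
            rates.append(self.mu)
        return 1.0 / max(rates)


def analytic_drift(spec: SDEModelSpec):
    """The exact F*(x, v) used by :func:`simulate_sde`."""
    return spec.drift()


def simulate_sde(spec: SDEModelSpec, n_traj: int, T: float, dt: float,
                 seed: int, record_interval: float = 1.0) -> TrajectorySet:
    """Euler–Maruyama ensemble of the chosen model.

    All ``n_traj`` trajectories are advanced in lockstep (vectorized over
    the ensemble) with one seeded generator, recording x every
    ``record_interval`` minutes.  The output reuses the simulator's
    :class:`Trajectory` container so the inference stage is agnostic to
    the data source.
    """
    if dt <= 0 or T <= 0 or n_traj < 1:
        raise ValueError("need positive dt, T and n_traj >= 1")
    tmin = spec.fastest_timescale()
    if dt > 0.1 * tmin:
        raise ValueError(
            f"dt={dt} too coarse for model timescale {tmin:.3g} min; "
            f"use dt <= {0.1 * tmin:.3g}")
    rng = np.random.default_rng(seed)
    F = spec.drift()
    x = np.full(n_traj, spec.x_init, dtype=float)
    if spec.init_spread > 0:
        x = x + rng.uniform(-spec.init_spread, spec.init_spread, n_traj)
    v = np.full(n_traj, spec.v_init, dtype=float)

    n_steps = int(round(T / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    n_rec = n_steps // rec_every + 1
    X = np.empty((n_rec, n_traj))
    times = np.empty(n_rec)
    X[0] = x
    times[0] = 0.0
    r = 1
    sq = np.sqrt(dt) * spec.noise
    for k in range(1, n_steps + 1):
        a = F(x, v)
        x = x + v * dt
        v = v + a * dt + sq * rng.standard_normal(n_traj)
        if k % rec_every == 0:
            X[r] = x
            times[r] = k * dt
            r += 1
    runs = [Trajectory(times=times.copy(), x=X[:, i].copy(),
                       y=np.zeros(n_rec), area=np.zeros(n_rec),
                       perimeter=np.zeros(n_rec), seed=seed)
            for i in range(n_traj)]
    return TrajectorySet(runs=runs, params_hash=f"sde:{spec.name}",
                         pattern_kind="synthetic",
                         meta={"model": spec.name, "seed": seed, "T": T,
                               "dt": dt, "n_traj": n_traj})
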