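"""Stochastic polarity field P(r, t).

P summarizes the cell's front/rear chemical asymmetry: the boundary
protrudes where P > 0 and retracts where P < 0.  The field obeys

    ∂P/∂t = β f(|r−θ|; σ) δ(t mod τf) ϕ  −  (1/τχ) χ ϕ
            − (1/τs)(s/s0)² H(s−s0) ϕ  −  P/τ,

i.e. Gaussian activity patches of random amplitude β ~ N(μβ, σβ) delivered
once per period τf at a contour location θ, inhibition where the cell
overlaps non-adhesive substrate (χϕ > 0), a global perimeter-triggered
inhibition, and basal exponential decay.  Patch locations are drawn from
the "filopodial" probability p(θ) ∝ (1 − χ(θ + ℓn̂)) · max(P(θ), 0): points
with adhesive substrate a probe distance ℓ ahead and existing polarity are
favored.
"""

from __future__ import annotations

import numpy as np

from .fields import ScalarField2D
from .params import ModelParams
from .phasefield import Contour


def filopodial_weights(contour: Contour, P: ScalarField2D,
                       chi: ScalarField2D, ell: float,
                       no_filopodia: bool = False) -> np.ndarray:
    """Patch-placement probabilities over the contour points.

    Weights are ∝ (1 − χ(θ'))·max(P(θ), 0) with θ' = θ + ℓn̂ (the filopodial
    probe point); with ``no_filopodia`` the substrate factor is dropped and
    weights are ∝ max(P(θ), 0).  Negative polarity carries zero weight so
    that p(θ) remains a valid distribution.  If every weight vanishes
    (e.g. a fully depolarized cell) the uniform distribution is returned.
    """
    pts = contour.points
    p_here = np.maximum(P.sample(pts[:, 0], pts[:, 1]), 0.0)
    if no_filopodia:
        w = p_here
    else:
        probes = pts + ell * contour.normals
        chi_ahead = np.clip(chi.sample(probes[:, 0], probes[:, 1]), 0.0, 1.0)
        w = (1.0 - chi_ahead) * p_here
    total = w.sum()
    if total <= 0.0:
        return np.full(len(pts), 1.0 / len(pts))
    return w / total


def apply_activity_patch(P: ScalarField2D, theta: tuple[float, float],
                         beta: float, sigma: float,
                         phi: ScalarField2D) -> ScalarField2D:
    """Instantaneous impulse P ← P + β e^{−|r−θ|²/2σ²} ϕ.

    The ϕ factor confines the patch to the cell interior; one such additive
    impulse is delivered per period τf (the Dirac comb in the dynamics).
    """
    X, Y = P.grid.meshgrid()
    r2 = (X - theta[0]) ** 2 + (Y - theta[1]) ** 2
    bump = beta * np.exp(-r2 / (2.0 * sigma ** 2)) * phi.values
    return P.like(P.values + bump)


def polarity_rhs(P_values: np.ndarray, phi_values: np.ndarray,
                 chi_values: np.ndarray, s: float,
                 params: ModelParams) -> np.ndarray:
    """Deterministic part of ∂P/∂t (patches are applied separately).

    The perimeter inhibition −(1/τs)(s/s0)²H(s−s0) is spatially uniform
    within the cell (localized by ϕ).
    """
    rhs = -P_values / params.tau
    if not params.no_chi_coupling:
        rhs = rhs - (chi_values * phi_values) / params.tau_chi
    if not params.no_perimeter_inhibition and s > params.s0:
        rhs = rhs - (s / params.s0) ** 2 / params.tau_s * phi_values
    return rhs


def step_polarity(P: ScalarField2D, phi: ScalarField2D, chi: ScalarField2D,
                  s: float, dt: float, params: ModelParams) -> ScalarField2D:
    """Advance the deterministic P dynamics by one explicit Euler step."""
    return P.like(P.values + dt * polarity_rhs(
        P.values, phi.values, chi.values, s, params))


class PatchScheduler:
    """Fires one activity patch per τf of simulated time.

    τf need not be a multiple of dt: the scheduler fires at the first step
    whose end time reaches the next multiple of τf, so that exactly
    ⌊T/τf⌋ patches occur over a duration T starting at t=0.
    """

    def __init__(self, tau_f: float, t0: float = 0.0):
        self.tau_f = tau_f
        self.next_fire = (np.floor(t0 / tau_f + 1e-12) + 1.0) * tau_f

    def due(self, t_new: float) -> bool:
        return t_new >= self.next_fire - 1e-12

    def advance(self) -> None:
        self.next_fire += self.tau_f


def draw_patch(rng: np.random.Generator, contour: Contour,
               P: ScalarField2D, chi: ScalarField2D,
               params: ModelParams) -> tuple[tuple[float, float], float]:
    """Sample a patch location θ (a contour point) and amplitude β.

    β ~ Normal(μβ, σβ); negative amplitudes are allowed and transiently
    depolarize the region they hit.
    """
    weights = filopodial_weights(contour, P, chi, params.ell,
                                 no_filopodia=params.no_filopodia)
    idx = int(rng.choice(len(weights), p=weights))
    beta = float(rng.normal(params.mu_beta, params.sigma_beta))
    theta = (float(contour.points[idx, 0]), float(contour.points[idx, 1]))
    return theta, beta
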