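"""Model parameters for the default simulated cell.

Internal units are micrometers and minutes throughout; tensions are measured
in an arbitrary scale γ0 (results depend only on ratios to γ0).  The two fast
polarity timescales ``tau_f`` and ``tau_chi`` are conventionally quoted in
seconds and are converted on construction via :func:`ModelParams.from_units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

SECONDS_PER_MINUTE = 60.0

#: Coefficient of the double-well term in the interface free energy,
#: γ[(C_WELL/λ)ϕ²(1−ϕ)² + (λ/2)|∇ϕ|²].  With this choice the relaxed 1D
#: front is the logistic profile ϕ(x) = 1/(1+exp(−√(2·C_WELL)·x/λ)).
C_WELL_DEFAULT = 16.0


class ParameterError(ValueError):
    """A model parameter violates its physical constraint."""


@dataclass
class Numerics:
    """Discretization settings for the phase-field solver.

    dx resolves the interface width λ=4.8 μm with ~5 nodes by default; dt
    sits well below both the diffusive limit dx²/(4ℳγλ) and the advective
    (CFL) limit for the speeds reached by the default cell.
    """

    dx: float = 1.0
    dt: float = 0.01           # min
    pad: float = 20.0          # μm of domain beyond the pattern bounding box
    sample_interval: float = 1.0   # min between trajectory records
    eps_phi: float = 0.02      # tolerated overshoot of ϕ outside [0, 1]
    grad_floor: float = 1e-6   # |∇ϕ| floor (per μm) below which n̂ := 0

    def validate(self) -> None:
        for name in ("dx", "dt", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.pad < 0:
            raise ParameterError("pad must be nonnegative")


@dataclass
class ModelParams:
    """Default parameter set of the simulated cell (μm / min / γ0 units)."""

    gamma: float = 0.8          # line tension, γ0
    lam: float = 4.8            # interface width, μm
    kappa: float = 6000.0       # area-constraint strength, γ0·μm
    R0: float = 18.0            # target radius, μm
    eta: float = 0.67           # friction, γ0·min·μm⁻³
    M: float = 0.75             # transport coefficient, μm·γ0⁻¹·min⁻¹
    alpha: float = 1.4          # motility force magnitude, γ0·μm⁻²
    mu_beta: float = 7.5        # patch-amplitude mean (unitless)
    sigma_beta: float = 37.5    # patch-amplitude s.d. (unitless)
    sigma: float = 6.7          # patch spatial extent, μm
    s0: float = 2.0 * np.pi * (1.5 * 18.0)   # perimeter threshold, μm
    tau_f: float = 2.2 / SECONDS_PER_MINUTE  # patch period, min
    tau_chi: float = 9.6 / SECONDS_PER_MINUTE  # off-pattern inhibition, min
    tau_s: float = 8.0          # perimeter-inhibition timescale, min
    tau: float = 4.0            # basal polarity decay, min
    ell: float = 6.0            # filopodial probe distance, μm
    gamma0: float = 1.0         # arbitrary tension scale
    c_well: float = C_WELL_DEFAULT
    # knockouts (§ model simplifications)
    no_filopodia: bool = False        # p(θ) ∝ P(θ) only
    no_chi_coupling: bool = False     # τχ → ∞
    no_perimeter_inhibition: bool = False  # s0 → ∞
    #: how the δ(t mod τf) pulse train is realized: "impulse" adds the
    #: full patch β·f·ϕ instantaneously once per τf; "sustained" applies
    #: β·f·ϕ as a rate over the following τf window (an alternative
    #: reading of the pulse-train notation; see the methods note)
    patch_mode: str = "impulse"
    numerics: Numerics = field(default_factory=Numerics)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ("gamma", "lam", "kappa", "R0", "eta", "M", "sigma",
                    "s0", "tau_f", "tau_chi", "tau_s", "tau", "ell",
                    "gamma0", "c_well")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.sigma_beta < 0:
            raise ParameterError("sigma_beta must be nonnegative")
        if self.alpha < 0:
            raise ParameterError("alpha must be nonnegative")
        if self.patch_mode not in ("impulse", "sustained"):
            raise ParameterError("patch_mode must be impulse or sustained")
        self.numerics.validate()

    @property
    def target_area(self) -> float:
        """πR0², μm²."""
        return float(np.pi * self.R0 ** 2)

    def dt_stability_bound(self) -> float:
        """Explicit-Euler stability bound from the ℳγλ diffusive term."""
        D = self.M * self.gamma * self.lam
        return self.numerics.dx ** 2 / (4.0 * D)

    @classmethod
    def from_units(cls, *, tau_f_s: float | None = None,
                   tau_chi_s: float | None = None, **kwargs) -> "ModelParams":
        """Construct with the fast timescales given in seconds."""
        if tau_f_s is not None:
            kwargs["tau_f"] = tau_f_s / SECONDS_PER_MINUTE
        if tau_chi_s is not None:
            kwargs["tau_chi"] = tau_chi_s / SECONDS_PER_MINUTE
        return cls(**kwargs)

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
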