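"""Reduced kinetic model of MeIQx metabolism in human hepatocytes.

The model tracks eight species (concentrations in molar, time in hours):
the parent compound MeIQx, five terminal products (C-Hydroxy-MeIQx,
MeIQx-N2-Gl, MeIQx-N2-SO3H, oxo-MeIQx, HON-MeIQx-N2-Gl), the labile
N-hydroxylamine intermediate HONH-MeIQx, and the Potential-Genotoxic-Compound
pool that closes the mass balance.

Two enzyme pools are shared between competing reactions: CYP1A2 splits
between C8-hydroxylation (detoxifying) and N-hydroxylation (bioactivating)
of MeIQx, and UGT splits between direct N2-glucuronidation of MeIQx and
glucuronidation of HONH-MeIQx.  The split is expressed by distribution
coefficients alpha (CYP1A2) and beta (UGT): either fixed constants
("saturation" hypothesis) or decreasing sigmoid functions of the
instantaneous MeIQx concentration ("dose-dependent" hypothesis),

    phi(a, b, theta, n, S) = a * theta^n / (theta^n + S^n) + b.

Each enzymatic step follows Michaelis-Menten kinetics; the Vmax of a
competing branch is k_i * (partition fraction) * (total enzyme).  Three
further reactions (sulfamate formation, oxo formation, esterification into
the genotoxic pool) are lumped Vm/Km Michaelis-Menten terms.  The system is
closed: the stoichiometry conserves total mass, so the eight concentrations
always sum to the initial dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels

__all__ = [
    "SPECIES",
    "FLUXES",
    "SigmoidSpec",
    "DistributionCoefficientSpec",
    "ParameterSet",
    "Trajectory",
    "SimulationError",
    "sigmoid_phi",
    "distribution_coefficients",
    "reaction_rates",
    "ode_rhs",
    "simulate",
]

#: species names, in state-vector order
SPECIES = (
    "meiqx",
    "c_hydroxy_meiqx",
    "meiqx_n2_gl",
    "meiqx_n2_so3h",
    "oxo_meiqx",
    "honh_meiqx",
    "hon_meiqx_n2_gl",
    "potential_genotoxic",
)

#: reaction names, in flux-vector order
FLUXES = (
    "meiqx_to_c_hydroxy",      # v1, CYP1A2, fraction alpha
    "meiqx_to_honh",           # v2, CYP1A2, fraction 1-alpha
    "meiqx_to_n2_gl",          # v3, UGT, fraction beta
    "honh_to_hon_gl",          # v4, UGT, fraction 1-beta
    "meiqx_to_so3h",           # v5, lumped
    "meiqx_to_oxo",            # v6, lumped
    "honh_to_genotoxic",       # v7, lumped (NAT/SULT esterification)
)

#: names of the 16 fixed kinetic parameters
FIXED_PARAM_NAMES = (
    "k1", "k2", "k3", "k4",
    "km1", "km2", "km3", "km4",
    "vm_so3h", "vm_oxo", "vm_pgc",
    "km_so3h", "km_oxo", "km_pgc",
    "e_cyp1a2_total", "e_ugt_total",
)

#: default dense output grid size over [0, t_end]
DEFAULT_GRID_POINTS = 241

#: solver tolerances; atol applies to dose-normalised concentrations
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL_SCALED = 1e-10


class SimulationError(RuntimeError):
    """Raised when the stiff solver fails; carries parameters and dose."""


@dataclass(frozen=True)
class SigmoidSpec:
    """Decreasing sigmoid phi(S) = a*theta^n/(theta^n + S^n) + b.

    Parameters
    ----------
    a : float
        Amplitude; phi falls from ``a + b`` at S=0 to ``b`` at high S.
    b : float
        Baseline (high-concentration asymptote).
    theta : float
        Inflection concentration (M); phi(theta) = a/2 + b.
    n : float
        Slope exponent, fixed at 5 throughout the analysis.
    """

    a: float
    b: float
    theta: float
    n: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.b <= 1.0):
            raise ValueError(f"sigmoid a, b must lie in [0, 1]: a={self.a}, b={self.b}")
        if self.a + self.b > 1.0 + 1e-12:
            raise ValueError(f"sigmoid requires a + b <= 1, got {self.a + self.b}")
        if self.theta <= 0.0 or self.n <= 0.0:
            raise ValueError("sigmoid theta and n must be positive")


@dataclass(frozen=True)
class DistributionCoefficientSpec:
    """How the CYP1A2/UGT pools are split between their competing reactions.

    ``saturation`` mode holds (alpha, beta) fixed; ``dose_dependent`` mode
    evaluates each coefficient from a sigmoid of the current MeIQx
    concentration.
    """

    mode: str
    alpha_fixed: float | None = None
    beta_fixed: float | None = None
    alpha_sigmoid: SigmoidSpec | None = None
    beta_sigmoid: SigmoidSpec | None = None

    def __post_init__(self) -> None:
        if self.mode == "saturation":
            if self.alpha_fixed is None or self.beta_fixed is None:
                raise ValueError("saturation mode requires alpha_fixed and beta_fixed")
            if self.alpha_sigmoid is not None or self.beta_sigmoid is not None:
                raise ValueError("saturation mode must not carry sigmoid specs")
            for name, v in (("alpha", self.alpha_fixed), ("beta", self.beta_fixed)):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}_fixed must lie in [0, 1], got {v}")
        elif self.mode == "dose_dependent":
            if self.alpha_sigmoid is None or self.beta_sigmoid is None:
                raise ValueError("dose_dependent mode requires both sigmoid specs")
            if self.alpha_fixed is not None or self.beta_fixed is not None:
                raise ValueError("dose_dependent mode must not carry fixed coefficients")
        else:
            raise ValueError(f"unknown mode {self.mode!r}; use 'saturation' or 'dose_dependent'")

    @classmethod
    def saturation(cls, alpha: float, beta: float) -> "DistributionCoefficientSpec":
        return cls(mode="saturation", alpha_fixed=alpha, beta_fixed=beta)

    @classmethod
    def dose_dependent(
        cls, alpha_sigmoid: SigmoidSpec, beta_sigmoid: SigmoidSpec
    ) -> "DistributionCoefficientSpec":
        return cls(mode="dose_dependent", alpha_sigmoid=alpha_sigmoid, beta_sigmoid=beta_sigmoid)


@dataclass(frozen=True)
class ParameterSet:
    """The 16 fixed kinetic parameters plus the distribution-coefficient law.

    Units: catalytic constants ``k*`` in 1/h, Michaelis constants ``km*`` in
    M, maximal rates ``vm*`` in M/h, enzyme totals in M.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    km1: float
    km2: float
    km3: float
    km4: float
    vm_so3h: float
    vm_oxo: float
    vm_pgc: float
    km_so3h: float
    km_oxo: float
    km_pgc: float
    e_cyp1a2_total: float
    e_ugt_total: float
    dist: DistributionCoefficientSpec = field(
        default_factory=lambda: DistributionCoefficientSpec.saturation(0.5, 0.5)
    )

    def __post_init__(self) -> None:
        for name in FIXED_PARAM_NAMES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0.0):
                raise ValueError(f"kinetic parameter {name} must be finite and >= 0, got {v}")

    # -- flat-vector packing used by the compiled kernels ------------------

    def to_vector(self) -> np.ndarray:
        p = np.empty(_kernels.N_PARAMS)
        for i, name in enumerate(FIXED_PARAM_NAMES):
            p[i] = getattr(self, name)
        d = self.dist
        if d.mode == "saturation":
            p[16:20] = (0.0, d.alpha_fixed, 1.0, 1.0)
            p[20:24] = (0.0, d.beta_fixed, 1.0, 1.0)
        else:
            sa, sb = d.alpha_sigmoid, d.beta_sigmoid
            p[16:20] = (sa.a, sa.b, sa.theta, sa.n)
            p[20:24] = (sb.a, sb.b, sb.theta, sb.n)
        return p

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {name: float(getattr(self, name)) for name in FIXED_PARAM_NAMES}
        d = self.dist
        if d.mode == "saturation":
            out["distribution"] = {
                "mode": "saturation",
                "alpha": float(d.alpha_fixed),
                "beta": float(d.beta_fixed),
            }
        else:
            out["distribution"] = {
                "mode": "dose_dependent",
                "alpha_sigmoid": {
                    "a": d.alpha_sigmoid.a, "b": d.alpha_sigmoid.b,
                    "theta": d.alpha_sigmoid.theta, "n": d.alpha_sigmoid.n,
                },
                "beta_sigmoid": {
                    "a": d.beta_sigmoid.a, "b": d.beta_sigmoid.b,
                    "theta": d.beta_sigmoid.theta, "n": d.beta_sigmoid.n,
                },
            }
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ParameterSet":
        kw = {name: float(mapping[name]) for name in FIXED_PARAM_NAMES}
        dist = mapping["distribution"]
        if dist["mode"] == "saturation":
            kw["dist"] = DistributionCoefficientSpec.saturation(
                float(dist["alpha"]), float(dist["beta"])
            )
        else:
            kw["dist"] = DistributionCoefficientSpec.dose_dependent(
                SigmoidSpec(**{k: float(v) for k, v in dist["alpha_sigmoid"].items()}),
                SigmoidSpec(**{k: float(v) for k, v in dist["beta_sigmoid"].items()}),
            )
        return cls(**kw)

    def with_cyp1a2_scaled(self, factor: float) -> "ParameterSet":
        if factor <= 0:
            raise ValueError("scaling factor must be positive")
        return replace(self, e_cyp1a2_total=self.e_cyp1a2_total * factor)


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: ``states[i]`` is the 8-species state (M) at
    ``times[i]`` (h); row 0 is the initial condition (dose, 0, ..., 0)."""

    times: np.ndarray
    states: np.ndarray
    dose: float
    params: ParameterSet

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def state_at(self, t: float) -> np.ndarray:
        """State at time t by linear interpolation on the output grid."""
        return np.array([np.interp(t, self.times, self.states[:, i]) for i in range(8)])

    def to_frame(self, model_id: str = "model-0"):
        """Tidy table: time_h, species, concentration_M, dose_M, model_id."""
        import pandas as pd

        n = len(self.times)
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, 8),
                "species": np.tile(np.array(SPECIES), n),
                "concentration_M": self.states.ravel(),
                "dose_M": self.dose,
                "model_id": model_id,
            }
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sigmoid_phi(spec: SigmoidSpec, s: float) -> float:
    """Evaluate the partition sigmoid at MeIQx concentration ``s`` (M)."""
    if s < 0.0:
        raise ValueError(f"concentration must be >= 0, got {s}")
    return float(_kernels.phi_kernel(spec.a, spec.b, spec.theta, spec.n, s))


def distribution_coefficients(
    dist: DistributionCoefficientSpec, meiqx_conc: float
) -> tuple[float, float]:
    """(alpha, beta) enzyme-pool fractions at the given MeIQx concentration."""
    if meiqx_conc < 0.0:
        raise ValueError(f"concentration must be >= 0, got {meiqx_conc}")
    if dist.mode == "saturation":
        return float(dist.alpha_fixed), float(dist.beta_fixed)
    return (
        sigmoid_phi(dist.alpha_sigmoid, meiqx_conc),
        sigmoid_phi(dist.beta_sigmoid, meiqx_conc),
    )


def reaction_rates(state: Sequence[float], params: ParameterSet) -> np.ndarray:
    """The 7 reaction fluxes (M/h) at a state, ordered as :data:`FLUXES`."""
    x = np.asarray(state, dtype=float)
    if x.shape != (8,):
        raise ValueError("state must have 8 entries")
    if np.any(x < 0.0):
        raise ValueError("state entries must be >= 0")
    v = np.empty(7)
    _kernels.fluxes_kernel(x, params.to_vector(), v)
    return v


def ode_rhs(t: float, state: Sequence[float], params: ParameterSet) -> np.ndarray:
    """Time derivative of the state (M/h).  Components sum to zero."""
    x = np.asarray(state, dtype=float)
    if x.shape != (8,):
        raise ValueError("state must have 8 entries")
    dx = np.empty(8)
    _kernels.rhs_kernel(x, params.to_vector(), dx)
    return dx


def simulate(
    params: ParameterSet,
    dose: float,
    t_end: float = 24.0,
    t_grid: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol_scaled: float = DEFAULT_ATOL_SCALED,
) -> Trajectory:
    """Integrate the model from (dose, 0, ..., 0) with an implicit stiff
    (Radau IIA) scheme.

    Parameters
    ----------
    dose : float
        Initial MeIQx concentration (M).
    t_grid : ndarray, optional
        Output grid (h); defaults to 241 evenly spaced points on [0, t_end].
    rtol, atol_scaled : float
        Solver tolerances; the absolute tolerance is ``atol_scaled * dose``
        so that it acts on dose-normalised concentrations.

    Raises
    ------
    SimulationError
        If the solver does not converge; the message carries dose and
        parameters, the result is never silently truncated.
    """
    if dose < 0.0:
        raise ValueError("dose must be >= 0")
    if t_grid is None:
        if t_end <= 0.0:
            raise ValueError("t_end must be > 0")
        t_grid = np.linspace(0.0, t_end, DEFAULT_GRID_POINTS)
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0.0):
            raise ValueError("t_grid must start at 0 and be strictly increasing")
        t_end = float(t_grid[-1])

    if dose == 0.0:
        return Trajectory(times=t_grid, states=np.zeros((len(t_grid), 8)), dose=0.0, params=params)

    p = params.to_vector()
    y0 = np.zeros(8)
    y0[0] = dose
    atol = atol_scaled * dose

    sol = solve_ivp(
        lambda t, y: _rhs_wrap(y, p),
        (0.0, t_end),
        y0,
        method="Radau",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: _kernels.jac_full_kernel(y, p),
    )
    if not sol.success:
        raise SimulationError(
            f"stiff solver failed at dose {dose:g} M: {sol.message}; params={params.to_dict()}"
        )
    states = sol.y.T.copy()
    if states.min() < -100.0 * atol:
        raise SimulationError(
            f"solution went negative beyond tolerance ({states.min():.3e} M) "
            f"at dose {dose:g} M; params={params.to_dict()}"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=t_grid, states=states, dose=dose, params=params)


def _rhs_wrap(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    dx = np.empty(8)
    _kernels.rhs_kernel(y, p, dx)
    return dx
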