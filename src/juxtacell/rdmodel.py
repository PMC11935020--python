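"""Radial reaction-diffusion model of light-switched membrane recruitment.

Models cytosolic SspB diffusing inside a vesicle cross-section (a disk of
radius ``R``) and binding membrane-anchored iLID at the rim.  iLID is an
optogenetic switch: under blue light its affinity for SspB is high
(``Kd_lit``), in the dark low (``Kd_dark``).  Free SspB obeys the radially
symmetric diffusion equation

    dc/dt = D * (1/r) d/dr ( r dc/dr ),      0 <= r <= R,

with a reactive boundary at ``r = R`` where the bound surface density ``b``
(mol per unit membrane length, per unit depth of the disk) evolves by mass
action against a finite number of iLID sites:

    db/dt = k_on * c(R) * (sigma_max - b) - k_off * b,   k_off = k_on * Kd.

``sigma_max`` is the encapsulated iLID redistributed onto the rim:
``I_tot * (disk area)/(perimeter) = I_tot * R / 2``.

The solver is an explicit-Euler finite-volume scheme on a uniform radial
grid.  Fluxes are exchanged through annular faces, so total molecule count
(lumen integral plus membrane pool) is conserved to rounding error by
construction, and the discrete steady state coincides with the well-mixed
binding equilibrium with depletion — the closed-form oracle
:func:`equilibrium_ratio` solves it directly via the quadratic

    B^2 - (I_tot + S_tot + Kd) * B + I_tot * S_tot = 0   (smaller root),

whose bound/free read-out ``B / (S_tot - B)`` is the model's
membrane:lumen molecule ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "RDParams",
    "RDState",
    "RDResult",
    "StabilityError",
    "SaturationError",
    "sigma_max",
    "equilibrium_ratio",
    "new_state",
    "step",
    "run_to_steady_state",
    "simulate_conditions",
]

#: Explicit-Euler stability safety factor: dt <= CFL_SAFETY * dr^2 / D.
CFL_SAFETY = 0.2

_M_TO_MOL_M3 = 1e3  # mol/L -> mol/m^3


class StabilityError(RuntimeError):
    """The explicit scheme violated its stability bound (negative/NaN state)."""


class SaturationError(ValueError):
    """Irreversible binding with S_tot <= I_tot: all SspB bound, ratio unbounded."""


@dataclass(frozen=True)
class RDParams:
    """Model parameters (SI units; concentrations in molar).

    Attributes
    ----------
    R : float
        Vesicle radius (m).  Default 10 um — a 20 um diameter disk.
    D : float
        SspB diffusion coefficient (m^2/s).  Default 20 um^2/s, a typical
        cytosolic value for a small fluorescent fusion protein.
    S_tot : float
        Total SspB concentration (M).  Default 100 nM.
    I_tot : float
        Total iLID, as the equivalent volumetric concentration of the
        encapsulated protein (M).  Default 450 nM.  Zero models the
        no-iLID control.
    k_on : float
        Association rate constant (M^-1 s^-1).
    Kd_lit, Kd_dark : float
        Dissociation constants in the lit / dark photoswitch states (M).
    lit : bool
        Light state; selects which Kd applies.
    n_r : int
        Radial grid points (node 0 at the center, node n_r-1 on the rim).
    dt : float or None
        Time step (s); ``None`` selects the stability-bound default.
    """

    R: float = 10e-6
    D: float = 20e-12
    S_tot: float = 100e-9
    I_tot: float = 450e-9
    k_on: float = 1e6
    Kd_lit: float = 132e-9
    Kd_dark: float = 4.7e-6
    lit: bool = False
    n_r: int = 64
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("R", "D", "S_tot", "k_on", "Kd_lit", "Kd_dark"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.I_tot < 0:
            raise ValueError("I_tot must be >= 0")
        if self.Kd_dark <= self.Kd_lit:
            raise ValueError("Kd_dark must exceed Kd_lit")
        if self.n_r < 10:
            raise ValueError("n_r must be >= 10")
        if self.dt is not None and not (0 < self.dt <= self.dt_max):
            raise ValueError(
                f"dt must satisfy 0 < dt <= {self.dt_max:.3e} s "
                f"(= {CFL_SAFETY} * dr^2 / D)"
            )

    @property
    def dr(self) -> float:
        """Radial grid spacing (m)."""
        return self.R / (self.n_r - 1)

    @property
    def dt_max(self) -> float:
        """Explicit-Euler stability bound on the time step (s)."""
        return CFL_SAFETY * self.dr**2 / self.D

    @property
    def dt_eff(self) -> float:
        return self.dt if self.dt is not None else self.dt_max

    @property
    def Kd(self) -> float:
        """Dissociation constant of the current light state (M)."""
        return self.Kd_lit if self.lit else self.Kd_dark


@dataclass
class RDState:
    """Free-SspB radial profile plus the bound membrane pool."""

    c: np.ndarray  # mol/m^3 on the radial grid
    b: float  # mol/m^2 (per unit rim length, per unit depth)
    t: float  # s


@dataclass
class RDResult:
    """Steady-state summary of one model run."""

    r: np.ndarray  # m, radial nodes
    profile: np.ndarray  # M, free SspB c(r)
    bound_count: float  # mol per unit depth on the membrane
    free_count: float  # mol per unit depth in the lumen
    ratio: float  # bound_count / free_count
    shell_intensity_ratio: float  # imaging analogue: rim shell / center
    converged: bool
    mass_error: float  # relative drift of total count
    t_end: float  # s of simulated time
    history: Optional[np.ndarray] = None  # (t, bound_count) rows if recorded


def sigma_max(params: RDParams) -> float:
    """Saturating iLID surface density (mol/m^2 of rim, per unit depth).

    The encapsulated iLID, expressed as a volumetric concentration, is
    anchored uniformly on the rim: ``I_tot * pi R^2 / (2 pi R) = I_tot R/2``.
    """
    return params.I_tot * _M_TO_MOL_M3 * params.R / 2.0


def equilibrium_ratio(params: RDParams) -> float:
    """Closed-form membrane:lumen ratio at binding equilibrium with depletion.

    Solves ``B^2 - (I + S + Kd) B + I S = 0`` for the bound concentration B
    (smaller root; the larger root exceeds min(I, S) and is unphysical) and
    returns ``B / (S - B)``.  Uses the light state's Kd.
    """
    I, S, Kd = params.I_tot, params.S_tot, params.Kd
    if Kd == 0 and S <= I:
        raise SaturationError(
            "irreversible binding with S_tot <= I_tot leaves no free SspB"
        )
    q = I + S + Kd
    disc = q * q - 4.0 * I * S
    # Numerically stable smaller root: 2IS / (q + sqrt(disc)).
    B = 2.0 * I * S / (q + np.sqrt(disc))
    free = S - B
    if free <= 0:
        raise SaturationError("no free SspB at equilibrium")
    return float(B / free)


def new_state(params: RDParams) -> RDState:
    """Default initial condition: uniform free SspB, empty membrane."""
    c = np.full(params.n_r, params.S_tot * _M_TO_MOL_M3)
    return RDState(c=c, b=0.0, t=0.0)


class _Grid:
    """Precomputed finite-volume geometry and coefficients for one params set."""

    def __init__(self, params: RDParams):
        n, dr, R = params.n_r, params.dr, params.R
        r = np.linspace(0.0, R, n)
        faces = 0.5 * (r[:-1] + r[1:])  # interior annular faces
        edges = np.concatenate(([0.0], faces, [R]))  # cell boundaries
        self.r = r
        self.V = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)  # cell areas
        self.face_coef = params.D * 2.0 * np.pi * faces / dr
        self.perimeter = 2.0 * np.pi * R
        self.sigma_max = sigma_max(params)
        self.k_on = params.k_on / _M_TO_MOL_M3  # m^3 mol^-1 s^-1
        self.k_off = self.k_on * params.Kd * _M_TO_MOL_M3  # s^-1
        self.dt = params.dt_eff

    def total_count(self, state: RDState) -> float:
        """Total SspB (mol per unit depth): lumen integral + membrane pool."""
        return float(self.V @ state.c + state.b * self.perimeter)

    def advance(self, c: np.ndarray, b: float) -> tuple[np.ndarray, float]:
        dt = self.dt
        flux = self.face_coef * np.diff(c)  # mol/s into the inner cell
        dc = np.empty_like(c)
        dc[0] = flux[0]
        dc[1:-1] = flux[1:] - flux[:-1]
        dc[-1] = -flux[-1]
        # Membrane exchange: the rim cell loses exactly what b gains.
        J = self.k_on * c[-1] * (self.sigma_max - b) - self.k_off * b
        dc[-1] -= J * self.perimeter
        c = c + dt * dc / self.V
        b = b + dt * J
        return c, b


def step(state: RDState, params: RDParams, _grid: Optional[_Grid] = None) -> RDState:
    """Advance the state by one explicit time step (count-conserving)."""
    grid = _grid if _grid is not None else _Grid(params)
    c, b = grid.advance(state.c, state.b)
    if np.any(~np.isfinite(c)) or np.any(c < 0) or not np.isfinite(b) or b < 0:
        raise StabilityError(
            f"state left the physical domain; dt={grid.dt:.3e} s violates the "
            f"bound dt <= {CFL_SAFETY}*dr^2/D = {params.dt_max:.3e} s"
        )
    return RDState(c=c, b=float(b), t=state.t + grid.dt)


def _summarize(
    grid: _Grid,
    params: RDParams,
    state: RDState,
    converged: bool,
    count0: float,
    history: Optional[list[tuple[float, float]]],
) -> RDResult:
    bound = state.b * grid.perimeter
    free = float(grid.V @ state.c)
    ratio = bound / free if free > 0 else np.inf
    c_center = state.c[0]
    shell = state.b / params.dr + state.c[-1]
    shell_ratio = shell / c_center if c_center > 0 else np.inf
    mass_err = abs(grid.total_count(state) - count0) / count0
    return RDResult(
        r=grid.r.copy(),
        profile=state.c / _M_TO_MOL_M3,
        bound_count=bound,
        free_count=free,
        ratio=float(ratio),
        shell_intensity_ratio=float(shell_ratio),
        converged=converged,
        mass_error=float(mass_err),
        t_end=state.t,
        history=np.array(history) if history is not None else None,
    )


def run_to_steady_state(
    params: RDParams,
    init: Optional[RDState] = None,
    tol: float = 1e-6,
    t_max: float = 3600.0,
    record_every: Optional[float] = None,
) -> RDResult:
    """Iterate the scheme until the profile stops changing.

    Convergence: the maximum relative change of the free profile per second
    of simulated time, ``max_i |dc_i| / (dt * max c)``, drops below ``tol``
    (checked on blocks of steps).  If ``t_max`` elapses first the result is
    returned with ``converged=False`` rather than raising.

    ``record_every`` (s) optionally samples ``(t, bound_count)`` into
    ``RDResult.history`` for relaxation-time analysis.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    grid = _Grid(params)
    state = init if init is not None else new_state(params)
    c, b, t = state.c.astype(float).copy(), float(state.b), float(state.t)
    count0 = grid.total_count(RDState(c=c, b=b, t=t))
    dt = grid.dt
    block = max(1, int(round(0.25 / dt)))  # check convergence ~4x per sim-second
    history: Optional[list[tuple[float, float]]] = (
        [(t, b * grid.perimeter)] if record_every is not None else None
    )
    next_record = record_every if record_every is not None else np.inf
    converged = False
    while t < t_max:
        c_prev, b_prev = c, b
        for _ in range(block):
            c, b = grid.advance(c, b)
        t += block * dt
        if np.any(~np.isfinite(c)) or np.any(c < 0) or b < 0:
            raise StabilityError(
                f"state left the physical domain at t={t:.3g} s; "
                f"dt={dt:.3e} s vs bound {params.dt_max:.3e} s"
            )
        if history is not None and t >= next_record:
            history.append((t, b * grid.perimeter))
            next_record += record_every
        scale = max(c.max(), 1e-300)
        rate = max(
            np.max(np.abs(c - c_prev)) / scale, abs(b - b_prev) / max(b, 1e-300)
        ) / (block * dt)
        if rate < tol:
            converged = True
            break
    state = RDState(c=c, b=b, t=t)
    if history is not None:
        history.append((t, b * grid.perimeter))
    return _summarize(grid, params, state, converged, count0, history)


def simulate_conditions(
    params: RDParams, tol: float = 1e-6, t_max: float = 3600.0
) -> dict[str, RDResult]:
    """Run the three study conditions: no iLID, iLID in the dark, iLID lit.

    Returns a dict keyed ``no_ilid`` / ``dark`` / ``lit``.  The no-iLID
    control sets ``I_tot = 0`` (flat profile, ratio 0); the other two differ
    only in the photoswitch state.
    """
    conditions = {
        "no_ilid": replace(params, I_tot=0.0, lit=False),
        "dark": replace(params, lit=False),
        "lit": replace(params, lit=True),
    }
    return {
        name: run_to_steady_state(p, tol=tol, t_max=t_max)
        for name, p in conditions.items()
    }
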