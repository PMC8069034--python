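"""Structural PK-PD binding model for a single subject.

The model couples a two-compartment drug disposition with first-order
subcutaneous absorption to an indirect-response (turnover) model of the
soluble target IL13, and a drug:target complex with its own apparent central
volume plus a peripheral complex compartment.

States (amounts in nmol except free IL13, a concentration in nM):

====  =========  ==================================================
idx   symbol     meaning
====  =========  ==================================================
0     A_depot    drug amount in the SC depot
1     A_c        drug amount, central compartment (volume V2/F)
2     A_p        drug amount, peripheral compartment (volume V3/F)
3     C_il13     free IL13 concentration, central
4     A_cx       complex amount, central (volume Vcx/F)
5     A_cxp      complex amount, peripheral (volume V3/F)
====  =========  ==================================================

Free IL13 follows zero-order production ``Kin`` and first-order loss
``Kout`` (baseline Kin/Kout).  Drug in the central compartment captures
free IL13 by a second-order mass-transfer flux ``Kon * C * C_il13``; the
captured material joins the complex pool, which is cleared with the drug's
apparent clearance referenced to its own volume Vcx/F and exchanges with a
peripheral space using the drug's Q/F and V3/F.

By default the capture is treated as irreversible on the system's
timescales: the complex does not return target to the degradable free pool.
This is the formulation under which the published parameter set reproduces
the published simulation behaviour (deep free-IL13 suppression below
0.01 pM and a total-complex excursion approaching Kin*V2/CL ~ 0.1 nM); a
fully reversible mass-action variant with the dissociation flux
``Koff * A_cx`` returned to the free pool is available via
``dissociation=True`` and is used for equilibrium-limit checks.  See the
methods note for the quantitative comparison of the two.

Drug disposition is linear and unaffected by the binding (the target is in
vast molar deficit), so the PK subsystem is also available in closed form
(:func:`pk_concentration`) and the PD subsystem can be integrated against
that analytic forcing (:func:`pd_response_basis`), which the estimation
module relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .units import UnitConventions, mg_to_nmol

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "Trajectory",
    "dissociation_constant",
    "baseline_il13",
    "detected_il13",
    "rhs",
    "simulate_subject",
    "pk_concentration",
    "pd_response_basis",
]

# state indices
A_DEPOT, A_CENTRAL, A_PERIPH, C_IL13, A_CX, A_CXP = range(6)

_POSITIVE_FIELDS = (
    "ka", "cl_f", "v2_f", "v3_f", "q_f", "kin", "kout", "kon", "koff", "vcx_f",
)


@dataclass(frozen=True)
class StructuralParams:
    """Typical or individual structural parameters.

    Rates are 1/day, clearances L/day, volumes L (all apparent, i.e. /F),
    ``kin`` nM/day in the central reference space, ``kon`` 1/(nM day),
    ``fr`` the fraction of complex the PD assay detects (dimensionless in
    [0, 1]) and ``ada_cl_effect`` the fractional clearance increase for
    ADA-positive subjects.
    """

    ka: float
    cl_f: float
    v2_f: float
    v3_f: float
    q_f: float
    kin: float
    kout: float
    kon: float
    koff: float
    vcx_f: float
    fr: float
    ada_cl_effect: float = 0.0

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not (v > 0) and not (name in ("kin", "koff") and v == 0.0):
                raise ValueError(f"parameter {name}={v!r} must be strictly positive")
        if not 0.0 <= self.fr <= 1.0:
            raise ValueError(f"fr={self.fr!r} must lie in [0, 1]")
        if self.ada_cl_effect <= -1.0:
            raise ValueError("ada_cl_effect must keep clearance positive")
        if not math.isfinite(self.koff / self.kon):
            raise ValueError("KD = koff/kon must be finite")

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    @property
    def baseline(self) -> float:
        return self.kin / self.kout

    def with_(self, **kwargs) -> "StructuralParams":
        return replace(self, **kwargs)


def dissociation_constant(p: StructuralParams) -> float:
    """Equilibrium dissociation constant KD = Koff/Kon in nM."""
    if p.kon <= 0:
        raise ValueError("kon must be strictly positive to define KD")
    return p.koff / p.kon


def baseline_il13(p: StructuralParams) -> float:
    """Pre-treatment free IL13 concentration Kin/Kout in nM."""
    if p.kout <= 0:
        raise ValueError("kout must be strictly positive to define the baseline")
    return p.kin / p.kout


def detected_il13(c_free, c_cx, fr: float):
    """Assay-detected IL13: free plus the detected fraction of complex (nM)."""
    c_free = np.asarray(c_free, dtype=float)
    c_cx = np.asarray(c_cx, dtype=float)
    if np.any(c_free < 0) or np.any(c_cx < 0):
        raise ValueError("concentrations must be non-negative")
    if not 0.0 <= fr <= 1.0:
        raise ValueError(f"fr={fr!r} must lie in [0, 1]")
    out = c_free + fr * c_cx
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseEvent:
    """A subcutaneous dose: time in days, amount in nmol."""

    time: float
    amount: float
    route: str = "sc"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose at t={self.time} has negative amount {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time {self.time} must be non-negative")
        if self.route != "sc":
            raise ValueError("only the subcutaneous depot route is modelled")

    @classmethod
    def from_mg(cls, time: float, dose_mg: float,
                units: UnitConventions = UnitConventions()) -> "DoseEvent":
        return cls(time=time, amount=mg_to_nmol(dose_mg, units))


def rhs(t: float, s: np.ndarray, p: StructuralParams,
        cl_multiplier: float = 1.0, dissociation: bool = False) -> np.ndarray:
    """Time derivative of the six-state system.

    ``cl_multiplier`` encodes the ADA covariate on clearance (1 for
    ADA-negative).  With ``dissociation=True`` the complex returns target to
    the free pool at ``Koff * A_cx`` (fully reversible mass action).
    """
    if not np.all(np.isfinite(s)):
        raise FloatingPointError(f"non-finite state at t={t}: {s}")
    cl = p.cl_f * cl_multiplier
    a_dep, a_c, a_p, c_f, a_cx, a_cxp = s
    conc = a_c / p.v2_f
    ccx = a_cx / p.vcx_f
    bind = p.kon * conc * c_f          # nM/day in the central reference space
    diss = p.koff * a_cx if dissociation else 0.0   # nmol/day
    d = np.empty(6)
    d[A_DEPOT] = -p.ka * a_dep
    d[A_CENTRAL] = (p.ka * a_dep - (cl / p.v2_f) * a_c
                    - (p.q_f / p.v2_f) * a_c + (p.q_f / p.v3_f) * a_p)
    d[A_PERIPH] = (p.q_f / p.v2_f) * a_c - (p.q_f / p.v3_f) * a_p
    d[C_IL13] = p.kin - p.kout * c_f - bind + diss / p.v2_f
    d[A_CX] = (bind * p.v2_f - diss - cl * ccx
               - p.q_f * ccx + p.q_f * (a_cxp / p.v3_f))
    d[A_CXP] = p.q_f * ccx - p.q_f * (a_cxp / p.v3_f)
    return d


@dataclass
class Trajectory:
    """Dense single-subject solution with derived observables.

    ``states`` is (n_times, 6); derived series are nM.
    """

    t: np.ndarray
    states: np.ndarray
    params: StructuralParams
    cl_multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.t.size, 6):
            raise ValueError("states must be (len(t), 6)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def drug_conc(self) -> np.ndarray:
        """Free drug concentration A_c/V2 in nM."""
        return self.states[:, A_CENTRAL] / self.params.v2_f

    @property
    def complex_conc(self) -> np.ndarray:
        """Central complex concentration A_cx/Vcx in nM."""
        return self.states[:, A_CX] / self.params.vcx_f

    @property
    def free_il13(self) -> np.ndarray:
        return self.states[:, C_IL13]

    @property
    def total_il13(self) -> np.ndarray:
        """What a fully total assay would report: free + all central complex."""
        return self.free_il13 + self.complex_conc

    @property
    def detected(self) -> np.ndarray:
        """What the mixed assay reports: free + FR * complex."""
        return self.detected_with(self.params.fr)

    def detected_with(self, fr: float) -> np.ndarray:
        return detected_il13(np.maximum(self.free_il13, 0.0),
                             np.maximum(self.complex_conc, 0.0), fr)


class SolverError(RuntimeError):
    """ODE integration failure; carries the last successful time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


def simulate_subject(p: StructuralParams,
                     doses: Sequence[DoseEvent],
                     grid: np.ndarray,
                     cl_multiplier: float = 1.0,
                     dissociation: bool = False,
                     rtol: float = 1e-8,
                     atol: float = 1e-12,
                     initial_state: np.ndarray | None = None) -> Trajectory:
    """Integrate the six-state system over ``grid`` with SC doses.

    Doses are instantaneous additions to the depot; the solver restarts at
    each dose time.  The initial condition is the drug-free steady state
    (free IL13 at Kin/Kout, everything else zero).  The system is stiff
    (Kout ~ 1e2/day against complex turnover ~ 1e-2/day), hence LSODA with
    tight tolerances.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    doses = sorted(doses, key=lambda d: d.time)
    for d in doses:
        if not grid[0] <= d.time <= grid[-1]:
            raise ValueError(f"dose at t={d.time} outside the simulation grid")

    if initial_state is None:
        y = np.array([0.0, 0.0, 0.0, p.kin / p.kout, 0.0, 0.0])
    else:
        y = np.asarray(initial_state, dtype=float).copy()
        if y.shape != (6,):
            raise ValueError("initial_state must have six components")
    out = np.empty((grid.size, 6))
    t_now = grid[0]
    di = 0
    while di < len(doses) and doses[di].time <= t_now:
        y[A_DEPOT] += doses[di].amount
        di += 1
    out[0] = y
    filled = 1
    while filled < grid.size or di < len(doses):
        t_stop = doses[di].time if di < len(doses) else grid[-1]
        mask = (grid > t_now) & (grid <= t_stop)
        t_eval = np.unique(np.append(grid[mask], t_stop))
        sol = solve_ivp(rhs, (t_now, t_stop), y, t_eval=t_eval,
                        method="LSODA", rtol=rtol, atol=atol,
                        args=(p, cl_multiplier, dissociation))
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else t_now
            raise SolverError(f"ODE solver failed: {sol.message}", last_time=last)
        n_grid = int(mask.sum())
        out[filled:filled + n_grid] = sol.y.T[:n_grid]
        filled += n_grid
        y = sol.y[:, -1].copy()
        t_now = t_stop
        while di < len(doses) and doses[di].time <= t_now:
            y[A_DEPOT] += doses[di].amount
            di += 1
        if t_now >= grid[-1]:
            break
    return Trajectory(t=grid, states=out, params=p, cl_multiplier=cl_multiplier)


# ---------------------------------------------------------------------------
# analytic linear PK and the fast forced PD path


def _pk_coeffs(ka: float, cl: float, v2: float, v3: float, q: float):
    """Macro-constants of the triexponential SC two-compartment solution."""
    k10 = cl / v2
    k12 = q / v2
    k21 = q / v3
    b = k10 + k12 + k21
    disc = math.sqrt(max(b * b - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (b + disc)
    beta = 0.5 * (b - disc)
    # guard the degenerate ka == alpha/beta case with a tiny perturbation
    eps = 1e-9 * max(ka, 1e-12)
    if abs(ka - alpha) < eps or abs(ka - beta) < eps:
        ka = ka * (1.0 + 1e-7) + 1e-15
    c_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    c_b = (k21 - beta) / ((ka - beta) * (alpha - beta))
    c_k = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return alpha, beta, ka, c_a, c_b, c_k


def pk_concentration(t, dose_nmol: float, ka: float, cl: float, v2: float,
                     v3: float, q: float, t_dose: float = 0.0):
    """Closed-form central drug concentration (nM) after one SC dose.

    Exact solution of the linear depot + two-compartment system; zero before
    the dose time.  Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    alpha, beta, ka_, c_a, c_b, c_k = _pk_coeffs(ka, cl, v2, v3, q)
    tau = np.maximum(t - t_dose, 0.0)
    c = (dose_nmol * ka_ / v2) * (c_a * np.exp(-alpha * tau)
                                  + c_b * np.exp(-beta * tau)
                                  + c_k * np.exp(-ka_ * tau))
    c = np.where(t >= t_dose, np.maximum(c, 0.0), 0.0)
    return c if c.ndim else float(c)


def pk_forcing(doses: Sequence[tuple], ka: float, cl: float, v2: float,
               v3: float, q: float) -> Callable:
    """Superposed analytic drug concentration for a (time, nmol) dose list."""
    coef = _pk_coeffs(ka, cl, v2, v3, q)
    alpha, beta, ka_, c_a, c_b, c_k = coef

    def conc(t):
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t, dtype=float)
        for t_d, amt in doses:
            tau = t - t_d
            live = tau >= 0
            tau = np.where(live, tau, 0.0)
            total += np.where(
                live,
                (amt * ka_ / v2) * (c_a * np.exp(-alpha * tau)
                                    + c_b * np.exp(-beta * tau)
                                    + c_k * np.exp(-ka_ * tau)),
                0.0,
            )
        out = np.maximum(total, 0.0)
        return out if out.ndim else float(out)

    return conc


def pd_response_basis(times: np.ndarray,
                      doses: Sequence[tuple],
                      ka: float, cl: float, v2: float, v3: float, q: float,
                      kout: float, vcx: float, kon: float,
                      koff: float = 0.0, dissociation: bool = False,
                      rtol: float = 1e-6, atol: float = 1e-12) -> tuple:
    """Unit-production PD response against the analytic drug forcing.

    Because the PD subsystem is linear in the production rate Kin (the
    initial condition Kin/Kout and the source term both scale with it), one
    integration with Kin = 1 yields basis series ``(u, w)`` such that for
    any Kin::

        free_il13(t)        = Kin * u(t)
        complex_amount(t)   = Kin * w(t)      [nmol]

    and the detected series is ``Kin * (u + fr * w / vcx)``.  Returns
    ``(u, w)`` evaluated at ``times`` (which must start at a time at or
    before the first dose; 0 is prepended internally if needed).
    """
    times = np.asarray(times, dtype=float)
    t0 = 0.0 if times[0] > 0 else times[0]
    tt = times
    prepend = times[0] > t0
    if prepend:
        tt = np.concatenate(([t0], times))

    # scalar-math forcing: precompute the macro-constants per dose
    alpha, beta, ka_, c_a, c_b, c_k = _pk_coeffs(ka, cl, v2, v3, q)
    dose_terms = [(float(t_d), amt * ka_ / v2) for t_d, amt in doses]
    exp = math.exp
    k_off = koff if dissociation else 0.0

    def f(y, t):
        u, w, wp = y
        c = 0.0
        for t_d, scale in dose_terms:
            if t >= t_d:
                tau = t - t_d
                c += scale * (c_a * exp(-alpha * tau) + c_b * exp(-beta * tau)
                              + c_k * exp(-ka_ * tau))
        if c < 0.0:
            c = 0.0
        ccx = w / vcx
        bind = kon * c * u
        diss = k_off * w
        return (
            1.0 - kout * u - bind + diss / v2,
            bind * v2 - diss - cl * ccx - q * ccx + q * wp / v3,
            q * ccx - q * wp / v3,
        )

    out = odeint(f, [1.0 / kout, 0.0, 0.0], tt, rtol=rtol, atol=atol,
                 mxstep=100_000)
    if prepend:
        out = out[1:]
    return out[:, 0], out[:, 1]
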