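"""Structural pharmacokinetic model.

Two-compartment disposition with first-order absorption from a subcutaneous
depot and a cumulative milk-excretion compartment:

    dAa/dt    = -Ka * Aa
    dA1/dt    =  Ka * Aa - Cl*C - Cl2*(C - C2) - CLmilk*C
    dA2/dt    =  Cl2 * (C - C2)
    dAmilk/dt =  CLmilk * C
    C = A1/V,  C2 = A2/V2

The milk compartment is purely cumulative (no back-flow), so disposition in
plasma is a standard two-compartment system with total central elimination
clearance ``Cl + CLmilk``.  Both an analytic (tri-exponential) solution and a
high-accuracy ODE integration are provided; the ODE path serves as the
independent numerical oracle for the closed forms.  Multi-dose profiles use
superposition (the system is linear and time-invariant).

One- and three-compartment variants share the same conventions: the
one-compartment model is the ``Cl2 = 0`` reduction, the three-compartment
model adds a second peripheral pair ``(V3, Cl3)`` and is solved by
eigendecomposition of the linear system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp


@dataclass(frozen=True)
class DoseEvent:
    """A subcutaneous bolus into the absorption depot.

    time_h is hours since the first injection; amount_ng is the full dose
    (dose_mg_per_kg x body weight kg x 1e6).
    """
    time_h: float
    amount_ng: float
    route: str = "SC"

    def __post_init__(self):
        if self.amount_ng <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount_ng}")
        if self.time_h < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time_h}")


@dataclass(frozen=True)
class PKParams:
    """Individual structural parameters (mL, mL/h, 1/h)."""
    V: float
    Cl: float
    V2: float = 1.0
    Cl2: float = 0.0
    CLmilk: float = 0.0
    Ka: float = 1.0
    V3: Optional[float] = None
    Cl3: Optional[float] = None

    def __post_init__(self):
        for name in ("V", "Cl", "Ka", "V2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("Cl2", "CLmilk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.V3 is None) != (self.Cl3 is None):
            raise ValueError("V3 and Cl3 must be given together")
        if self.V3 is not None and (self.V3 <= 0 or self.Cl3 < 0):
            raise ValueError("V3 must be positive and Cl3 non-negative")

    @property
    def n_compartments(self) -> int:
        if self.V3 is not None:
            return 3
        return 2 if self.Cl2 > 0 else 1

    def as_array(self) -> np.ndarray:
        base = [self.V, self.Cl, self.V2, self.Cl2, self.CLmilk, self.Ka]
        if self.V3 is not None:
            base += [self.V3, self.Cl3]
        return np.asarray(base, dtype=float)


@dataclass(frozen=True)
class MicroConstants:
    """Hybrid rate constants of the two-compartment disposition system.

    k10 = (Cl + CLmilk)/V is total elimination from central (milk excretion
    is elimination as far as plasma kinetics are concerned); alpha >= beta
    are the roots of s^2 - (k10+k12+k21) s + k10 k21 = 0.
    """
    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


def micro_constants(params: PKParams) -> MicroConstants:
    k10 = (params.Cl + params.CLmilk) / params.V
    k12 = params.Cl2 / params.V
    k21 = params.Cl2 / params.V2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(max(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return MicroConstants(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


def _resolve_ka(ka: float, alpha: float, beta: float) -> float:
    # Ka exactly coincident with a disposition exponent makes the partial
    # fractions singular; nudge Ka relatively rather than switching to the
    # confluent solution (measure-zero case, ODE oracle unaffected).
    for lam in (alpha, beta):
        if abs(ka - lam) < 1e-9 * ka:
            return ka * (1.0 + 1e-8)
    return ka


def _biexp_coefficients(params: PKParams):
    mc = micro_constants(params)
    ka = _resolve_ka(params.Ka, mc.alpha, mc.beta)
    al, be = mc.alpha, mc.beta
    A = (mc.k21 - al) / ((ka - al) * (be - al))
    B = (mc.k21 - be) / ((ka - be) * (al - be)) if be > 0 else 0.0
    G = (mc.k21 - ka) / ((al - ka) * (be - ka))
    return mc, ka, A, B, G


def plasma_conc_closed(params: PKParams, doses: Sequence[DoseEvent], t) -> np.ndarray:
    """Plasma concentration (ng/mL) at times ``t`` (h) by superposition.

    For each dose, C(tau) = (D*Ka/V) * [A e^{-alpha tau} + B e^{-beta tau}
    + G e^{-Ka tau}] with the standard partial-fraction coefficients.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if params.n_compartments == 3:
        return _conc_eigen(params, doses, t)
    mc, ka, A, B, G = _biexp_coefficients(params)
    out = np.zeros(t.shape)
    for d in doses:
        tau = t - d.time_h
        m = tau >= 0
        tau = tau[m]
        out[m] += (d.amount_ng * ka / params.V) * (
            A * np.exp(-mc.alpha * tau)
            + B * np.exp(-mc.beta * tau)
            + G * np.exp(-ka * tau)
        )
    return out


def milk_cumulative_closed(params: PKParams, doses: Sequence[DoseEvent], t) -> np.ndarray:
    """Cumulative amount excreted into milk (ng) at times ``t``.

    Termwise integral of CLmilk * C; the t -> inf limit per dose is
    D * CLmilk / (Cl + CLmilk).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if params.CLmilk == 0:
        return np.zeros(t.shape)
    if params.n_compartments == 3:
        return _milk_eigen(params, doses, t)
    mc, ka, A, B, G = _biexp_coefficients(params)
    out = np.zeros(t.shape)
    for d in doses:
        tau = t - d.time_h
        m = tau >= 0
        tau = tau[m]
        terms = A * (-np.expm1(-mc.alpha * tau)) / mc.alpha
        if mc.beta > 0:
            terms = terms + B * (-np.expm1(-mc.beta * tau)) / mc.beta
        terms = terms + G * (-np.expm1(-ka * tau)) / ka
        out[m] += params.CLmilk * (d.amount_ng * ka / params.V) * terms
    return out


def milk_fraction_of_dose(params: PKParams) -> float:
    """Fraction of the dose ultimately excreted in milk: CLmilk/(Cl+CLmilk)."""
    return params.CLmilk / (params.Cl + params.CLmilk)


# ---------------------------------------------------------------------------
# generic linear solution (used for the 3-compartment variant)

def _rate_matrix(params: PKParams) -> np.ndarray:
    """State order: Aa, A1, A2[, A3]. Milk is handled by quadrature of A1."""
    k10 = (params.Cl + params.CLmilk) / params.V
    k12 = params.Cl2 / params.V
    k21 = params.Cl2 / params.V2
    n = 3 if params.V3 is None else 4
    M = np.zeros((n, n))
    M[0, 0] = -params.Ka
    M[1, 0] = params.Ka
    M[1, 1] = -(k10 + k12)
    M[1, 2] = k21
    M[2, 1] = k12
    M[2, 2] = -k21
    if n == 4:
        k13 = params.Cl3 / params.V
        k31 = params.Cl3 / params.V3
        M[1, 1] -= k13
        M[1, 3] = k31
        M[3, 1] = k13
        M[3, 3] = -k31
    return M


def _unit_depot_exponents(params: PKParams):
    """A1(t) for a unit depot dose as sum_i c_i exp(-lam_i t)."""
    M = _rate_matrix(params)
    lam, W = np.linalg.eig(M)
    x0 = np.zeros(M.shape[0])
    x0[0] = 1.0
    coef = np.linalg.solve(W, x0)
    c1 = W[1] * coef  # component of A1
    return -lam.real, c1.real


def _conc_eigen(params: PKParams, doses, t):
    rates, c1 = _unit_depot_exponents(params)
    out = np.zeros(np.shape(t))
    for d in doses:
        tau = np.asarray(t) - d.time_h
        m = tau >= 0
        tau = tau[m]
        a1 = np.zeros(tau.shape)
        for lam, c in zip(rates, c1):
            a1 += c * np.exp(-lam * tau)
        out[m] += d.amount_ng * a1 / params.V
    return out


def _milk_eigen(params: PKParams, doses, t):
    rates, c1 = _unit_depot_exponents(params)
    out = np.zeros(np.shape(t))
    for d in doses:
        tau = np.asarray(t) - d.time_h
        m = tau >= 0
        tau = tau[m]
        integ = np.zeros(tau.shape)
        for lam, c in zip(rates, c1):
            if lam > 0:
                integ += c * (-np.expm1(-lam * tau)) / lam
            else:
                integ += c * tau
        out[m] += d.amount_ng * params.CLmilk * integ / params.V
    return out


# ---------------------------------------------------------------------------
# ODE oracle

def solve_ode(params: PKParams, doses: Sequence[DoseEvent], time_grid,
              rtol: float = 1e-10, atol: float = 1e-8):
    """Integrate the model numerically on ``time_grid``.

    Returns a dict of trajectories (``Aa``, ``A1``, ``A2``, ``Amilk``,
    ``Aelim``, ``C_plasma``); ``Aelim`` is the running integral of Cl*C so
    that mass balance Aa+A1+A2(+A3)+Amilk+Aelim = total dose can be checked
    at every grid point.  Dose events reset the depot (Aa += D).
    """
    grid = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("time grid must be sorted, unique and non-negative")
    three = params.V3 is not None
    k10m = params.Cl / params.V       # non-milk elimination
    kmilk = params.CLmilk / params.V

    def rhs(_t, y):
        if three:
            aa, a1, a2, a3, _amilk, _ael = y
        else:
            aa, a1, a2, _amilk, _ael = y
        c = a1 / params.V
        c2 = a2 / params.V2
        da1 = aa * params.Ka - params.Cl * c - params.Cl2 * (c - c2) - params.CLmilk * c
        out = [-aa * params.Ka, da1, params.Cl2 * (c - c2)]
        if three:
            c3 = a3 / params.V3
            out[1] -= params.Cl3 * (c - c3)
            out.append(params.Cl3 * (c - c3))
        out.append(params.CLmilk * c)
        out.append(params.Cl * c)
        return out

    nstate = 6 if three else 5
    y = np.zeros(nstate)
    dose_times = sorted({d.time_h for d in doses})
    doses_by_time = {tt: sum(d.amount_ng for d in doses if d.time_h == tt) for tt in dose_times}
    # integrate from t=0 (hours since first dose) with dose resets at events
    bounds = sorted({0.0, grid[-1]} | {tt for tt in dose_times if 0.0 < tt < grid[-1]})
    traj = np.zeros((nstate, grid.size))
    for tt in dose_times:
        if tt <= 0.0:
            y[0] += doses_by_time[tt]
    if grid[0] == 0.0:
        traj[:, 0] = y
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = (grid > a) & (grid <= b)
        t_eval = np.append(grid[sel], b) if not (sel.any() and grid[sel][-1] == b) \
            else grid[sel]
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
        traj[:, sel] = sol.y[:, :sel.sum()]
        y = np.array(sol.y[:, -1])
        if b in doses_by_time:
            y[0] += doses_by_time[b]
            # a grid point exactly at a dose time reports the post-dose state
            at = np.isclose(grid, b)
            if at.any():
                traj[:, at] = y[:, None]
    names = (["Aa", "A1", "A2", "A3", "Amilk", "Aelim"] if three
             else ["Aa", "A1", "A2", "Amilk", "Aelim"])
    out = {n: traj[i] for i, n in enumerate(names)}
    out["C_plasma"] = out["A1"] / params.V
    out["time_h"] = grid
    return out


def terminal_halflife(params: PKParams) -> float:
    """ln 2 over the slowest exponential (flip-flop aware).

    With slow absorption (Ka < beta) the terminal slope reflects absorption,
    not disposition.
    """
    mc = micro_constants(params)
    rates = [r for r in (mc.alpha, mc.beta, params.Ka) if r > 0]
    return float(np.log(2.0) / min(rates))


def trajectory_frame(params: PKParams, doses, time_grid, rtol: float = 1e-10):
    """Trajectory as a pandas DataFrame (time_h, C_plasma, Aa, A1, A2, Amilk)."""
    import pandas as pd
    sol = solve_ode(params, doses, time_grid, rtol=rtol)
    cols = ["time_h", "C_plasma", "Aa", "A1", "A2", "Amilk"]
    return pd.DataFrame({c: sol[c] for c in cols})
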