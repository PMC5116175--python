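"""Noncompartmental analysis: Cmax/Tmax, terminal slope (lambda-z) by
best-fit log-linear regression, trapezoidal AUC (linear or linear-up /
log-down) and extrapolation to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .dataset import AssayLimits

__all__ = ["NCAResult", "TerminalPhaseError", "select_terminal_phase",
           "auc_trapezoidal", "nca_summary"]


class TerminalPhaseError(ValueError):
    """Raised when no acceptable log-linear terminal window exists."""


@dataclass(frozen=True)
class NCAResult:
    cmax_obs: float
    tmax_obs: float          # relative to the dose time
    lambda_z: Optional[float]
    t_half: Optional[float]
    auc_last: float
    auc_inf: Optional[float]
    n_terminal_points: Optional[int]
    adjusted_r2: Optional[float]
    auc_extrapolated_fraction: Optional[float] = None


def _clean_profile(times, concs) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size != c.size or t.size == 0:
        raise ValueError("profile must be non-empty with matching times and concentrations")
    order = np.argsort(t)
    t, c = t[order], c[order]
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate sampling times in profile")
    return t, c


def select_terminal_phase(times, concs, dose_time: float = 0.0,
                          min_points: int = 3, tie_tol: float = 1e-4):
    """Pick the terminal log-linear window by the best-fit rule.

    Among all contiguous windows ending at the last positive sample with at
    least ``min_points`` points and excluding Tmax, the window with the
    largest adjusted R^2 of the log-linear regression wins; adjusted R^2
    ties within ``tie_tol`` go to the window with more points.  Returns
    ``(indices, lambda_z, adjusted_r2)``.
    """
    t, c = _clean_profile(times, concs)
    pos = c > 0
    if pos.sum() < min_points:
        raise TerminalPhaseError("terminal phase undeterminable: fewer than "
                                 f"{min_points} positive concentrations")
    imax = int(np.argmax(c))
    last_pos = int(np.max(np.nonzero(pos)[0]))
    best = None
    for start in range(imax + 1, last_pos - min_points + 2):
        idx = np.arange(start, last_pos + 1)
        idx = idx[c[idx] > 0]
        if idx.size < min_points:
            continue
        x, y = t[idx], np.log(c[idx])
        n = idx.size
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0 or slope >= 0:
            continue
        r2 = 1.0 - np.sum((y - yhat) ** 2) / sst
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if (best is None or adj > best[2] + tie_tol
                or (adj > best[2] - tie_tol and n > best[0].size)):
            best = (idx, -slope, adj)
    if best is None:
        raise TerminalPhaseError("terminal phase undeterminable: no window with negative slope")
    return best


def _segment_auc(t1, t2, c1, c2, method):
    dt = t2 - t1
    if method == "linup_logdown" and c2 < c1 and c1 > 0 and c2 > 0:
        return dt * (c1 - c2) / np.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def auc_trapezoidal(times, concs, dose_time: float = 0.0,
                    method: str = "linear") -> float:
    """AUC to the last sample (h*ng/mL).

    A zero-concentration anchor is inserted at ``dose_time`` when the profile
    starts later (extravascular dosing).  ``method="linup_logdown"`` uses the
    logarithmic rule on strictly decreasing positive segments and falls back
    to the linear rule elsewhere.
    """
    if method not in ("linear", "linup_logdown"):
        raise ValueError(f"unknown AUC method {method!r}")
    t, c = _clean_profile(times, concs)
    if dose_time > t[0]:
        raise ValueError("dose_time must not be after the first sample")
    if dose_time < t[0]:
        t = np.insert(t, 0, dose_time)
        c = np.insert(c, 0, 0.0)
    return float(sum(_segment_auc(t[i], t[i + 1], c[i], c[i + 1], method)
                     for i in range(t.size - 1)))


def nca_summary(times, concs, dose_time: float = 0.0,
                assay: Optional[AssayLimits] = None,
                method: str = "linear") -> NCAResult:
    """Full NCA for one profile; Tmax is reported relative to ``dose_time``."""
    t, c = _clean_profile(times, concs)
    imax = int(np.argmax(c))
    auc_last = auc_trapezoidal(t, c, dose_time=dose_time, method=method)
    lam = thalf = auc_inf = adj = extrap = None
    npts = None
    try:
        idx, lam, adj = select_terminal_phase(t, c, dose_time=dose_time)
        npts = int(idx.size)
        thalf = float(np.log(2.0) / lam)
        c_last = c[c > 0][-1] if np.any(c > 0) else 0.0
        auc_inf = auc_last + c_last / lam
        extrap = (auc_inf - auc_last) / auc_inf if auc_inf > 0 else None
    except TerminalPhaseError:
        pass
    return NCAResult(cmax_obs=float(c[imax]), tmax_obs=float(t[imax] - dose_time),
                     lambda_z=lam, t_half=thalf, auc_last=auc_last,
                     auc_inf=auc_inf, n_terminal_points=npts, adjusted_r2=adj,
                     auc_extrapolated_fraction=extrap)


def nca_table(dataset, method: str = "linear"):
    """Per-subject NCA mirroring the published summary layout.

    Three profiles are analysed where the data allow: plasma after the
    second injection (dose at 168 h), milk after the first injection
    (samples truncated at 168 h) and milk after the second injection.
    Single-dose subjects contribute plasma and milk for the single
    injection instead.  Returns a long DataFrame.
    """
    import pandas as pd
    rows = []

    def add(subject, profile, kind, label, dose_time, lo=None, hi=None):
        t = np.array([o.time_h for o in profile])
        c = np.array([o.value for o in profile])
        m = np.ones(t.size, dtype=bool)
        if lo is not None:
            m &= t >= lo
        if hi is not None:
            m &= t <= hi
        if m.sum() < 2:
            return
        res = nca_summary(t[m], c[m], dose_time=dose_time, method=method)
        for fieldname in ("cmax_obs", "tmax_obs", "lambda_z", "t_half",
                          "auc_last", "auc_inf"):
            rows.append(dict(subject_id=subject.id, profile=label,
                             parameter=fieldname, value=getattr(res, fieldname)))

    for s in dataset.subjects:
        plasma = s.observations_of("plasma_conc")
        milk = s.observations_of("milk_conc")
        two = len(s.doses) >= 2
        second = s.doses[1].time_h if two else None
        if plasma:
            if two:
                add(s, plasma, "plasma_conc", "plasma_inj2", second, lo=second)
            else:
                add(s, plasma, "plasma_conc", "plasma_inj1", s.doses[0].time_h)
        if milk:
            first = s.doses[0].time_h
            add(s, milk, "milk_conc", "milk_inj1", first,
                hi=second if two else None)
            if two:
                add(s, milk, "milk_conc", "milk_inj2", second, lo=second)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    wide = (df.groupby(["profile", "parameter"])["value"]
              .agg(["mean", "std", "count"]).reset_index())
    return wide
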