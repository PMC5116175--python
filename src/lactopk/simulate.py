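"""Monte Carlo population simulation and withdrawal-time estimation.

Replicate individuals are drawn from the population model (log-normal
inter-individual variability), plasma and cumulative-milk trajectories are
evaluated with the closed-form structural model, milk concentrations are
reconstructed by dividing interval excreted amounts by the milk volume
produced over the interval, and the withdrawal time is the first whole day
after the last dose from which the chosen percentile band stays below the
tolerance (here the assay LOD, the conservative de-facto tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model import DoseEvent, PKParams, milk_cumulative_closed, plasma_conc_closed
from .nlme import PopulationModel
from .units import dose_ng, volume_from_weight

__all__ = ["SimulationResult", "WithdrawalEstimate", "draw_individuals",
           "simulate_replicates", "milk_conc_from_amounts", "withdrawal_time",
           "standard_regimen"]


@dataclass
class SimulationResult:
    time_h: np.ndarray
    plasma: np.ndarray          # replicates x time, ng/mL
    milk_cum: np.ndarray        # replicates x time, ng
    milk_times_h: np.ndarray    # milking grid
    milk_conc: np.ndarray       # replicates x milkings, ng/mL
    regimen: str
    last_dose_h: float
    seed: Optional[int]

    def percentile(self, q: float, matrix: str = "plasma"):
        arr = {"plasma": self.plasma, "milk_cum": self.milk_cum,
               "milk": self.milk_conc}[matrix]
        return np.percentile(arr, q, axis=0)

    def band_frame(self, matrix: str = "plasma", percentiles=(50, 95)):
        import pandas as pd
        t = self.milk_times_h if matrix == "milk" else self.time_h
        data = {"time_h": t}
        for q in percentiles:
            data[f"p{q:g}"] = self.percentile(q, matrix)
        return pd.DataFrame(data)


@dataclass
class WithdrawalEstimate:
    matrix: str
    tolerance_ngml: float
    percentile: float
    days: Optional[float]       # whole days after the LAST dose; None if never
    defined: bool
    definitive: bool = True     # milk estimates are flagged non-definitive
    regimen: str = ""
    note: str = ""


def draw_individuals(pop: PopulationModel, n: int, seed=None) -> List[PKParams]:
    """n individuals with P_i = theta * exp(eta_i), eta ~ N(0, omega)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = pop.param_names
    theta = pop.theta_array()
    sd = np.sqrt(pop.omega_array())
    eta = rng.standard_normal((n, len(names))) * sd
    out = []
    for i in range(n):
        kw = dict(zip(names, theta * np.exp(eta[i])))
        out.append(PKParams(**kw))
    return out


def standard_regimen(n_doses: int = 1, interval_h: float = 168.0,
                     dose_mg_per_kg: float = 2.5,
                     body_weight_kg: float = 88.0) -> List[DoseEvent]:
    amt = dose_ng(dose_mg_per_kg, body_weight_kg)
    return [DoseEvent(i * interval_h, amt) for i in range(n_doses)]


def _default_milkings(grid_end_h: float, last_dose_h: float) -> np.ndarray:
    # twice-daily milkings anchored 12 h after the first dose
    return np.arange(12.0, grid_end_h + 1e-9, 12.0)


def simulate_replicates(pop: PopulationModel, doses: Sequence[DoseEvent],
                        grid_end_h: float = 4800.0, grid_step_h: float = 12.0,
                        n_reps: int = 100, seed=None,
                        milking_times_h: Optional[np.ndarray] = None,
                        daily_milk_yield_lbs: float = 10.8,
                        residual: bool = False,
                        regimen_label: str = "") -> SimulationResult:
    """Simulate ``n_reps`` population replicates of the dosing regimen.

    One individual is drawn per replicate; the band therefore reflects
    inter-individual variability only unless ``residual=True`` adds the
    proportional assay-error layer on top.  Deterministic given ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    last_dose = max(d.time_h for d in doses)
    if grid_end_h <= last_dose:
        raise ValueError("simulation grid must extend beyond the last dose")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.arange(0.0, grid_end_h + 1e-9, grid_step_h)
    if milking_times_h is None:
        milking_times_h = _default_milkings(grid_end_h, last_dose)
    milking_times_h = np.asarray(milking_times_h, dtype=float)
    per_milking_ml = np.empty(milking_times_h.size)
    prev = 0.0
    for i, t in enumerate(milking_times_h):
        per_milking_ml[i] = volume_from_weight(
            daily_milk_yield_lbs * (t - prev) / 24.0, "lbs")
        prev = t

    individuals = draw_individuals(pop, n_reps, seed=rng)
    plasma = np.zeros((n_reps, grid.size))
    milk_cum = np.zeros((n_reps, grid.size))
    milk_conc = np.zeros((n_reps, milking_times_h.size))
    for i, ind in enumerate(individuals):
        plasma[i] = plasma_conc_closed(ind, doses, grid)
        milk_cum[i] = milk_cumulative_closed(ind, doses, grid)
        cum_at_milkings = milk_cumulative_closed(ind, doses, milking_times_h)
        milk_conc[i] = milk_conc_from_amounts(milking_times_h, cum_at_milkings,
                                              per_milking_ml)
    if residual:
        sig_p = pop.sigma.get("plasma_conc", 0.0)
        sig_m = pop.sigma.get("milk_cumamount", 0.0)
        plasma = np.clip(plasma * (1.0 + sig_p * rng.standard_normal(plasma.shape)), 0.0, None)
        milk_conc = np.clip(milk_conc * (1.0 + sig_m * rng.standard_normal(milk_conc.shape)), 0.0, None)
    return SimulationResult(time_h=grid, plasma=plasma, milk_cum=milk_cum,
                            milk_times_h=milking_times_h, milk_conc=milk_conc,
                            regimen=regimen_label or f"{len(doses)}x dose",
                            last_dose_h=last_dose,
                            seed=seed if isinstance(seed, int) else None)


def milk_conc_from_amounts(milking_times_h, cum_amounts_ng, volumes_ml) -> np.ndarray:
    """Per-milking concentration from a cumulative excreted-amount series.

    conc_k = (Amilk(t_k) - Amilk(t_{k-1})) / V_k with the first interval
    starting at t = 0; conserves total mass exactly:
    sum_k conc_k * V_k = Amilk(t_last).
    """
    v = np.asarray(volumes_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("milking volumes must be positive")
    cum = np.asarray(cum_amounts_ng, dtype=float)
    inc = np.diff(np.concatenate([[0.0], cum]))
    return inc / v


def withdrawal_time(sim: SimulationResult, matrix: str = "plasma",
                    tolerance_ngml: float = 1.2, percentile: float = 95.0,
                    granularity_days: float = 1.0) -> WithdrawalEstimate:
    """First whole day after the last dose from which the percentile band
    stays below the tolerance at every later grid time."""
    band = sim.percentile(percentile, matrix)
    t = sim.milk_times_h if matrix == "milk" else sim.time_h
    above = band >= tolerance_ngml
    definitive = matrix != "milk"
    note = ("terminal milk concentrations fluctuate with milking volume; "
            "estimate is indicative only" if matrix == "milk" else "")
    if not above.any():
        return WithdrawalEstimate(matrix=matrix, tolerance_ngml=tolerance_ngml,
                                  percentile=percentile, days=0.0, defined=True,
                                  definitive=definitive, regimen=sim.regimen, note=note)
    t_last_above = t[np.nonzero(above)[0][-1]]
    if t_last_above >= t[-1]:
        return WithdrawalEstimate(matrix=matrix, tolerance_ngml=tolerance_ngml,
                                  percentile=percentile, days=None, defined=False,
                                  definitive=definitive, regimen=sim.regimen,
                                  note="band never stays below tolerance within the grid")
    days = np.ceil((t_last_above - sim.last_dose_h) / (24.0 * granularity_days) + 1e-12)
    days = max(days * granularity_days, 0.0)
    return WithdrawalEstimate(matrix=matrix, tolerance_ngml=tolerance_ngml,
                              percentile=percentile, days=float(days), defined=True,
                              definitive=definitive, regimen=sim.regimen, note=note)
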