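"""Synthetic study generator.

Emulates the three source designs that the population analysis pools:

* ``twodose_lactating`` — 8 lactating does, 2.5 mg/kg SC at 0 h and 168 h;
  plasma sampled twice daily for the 7 days after the second injection;
  milk collected twice daily through day 21, every 48 h days 22-36 and
  every 72 h days 37-64.
* ``singledose_lactating`` — 8 lactating does, one 2.5 mg/kg SC dose;
  plasma twice daily for 7 days; milk twice daily days 1-14, every 48 h
  days 14-28, every 72 h days 28-45.
* ``market`` — 10 market-age goats, one 2.5 mg/kg SC dose, dense plasma-only
  schedule from 1 min to 360 h.

Individual parameters are drawn log-normally around the population means,
plasma observations get proportional assay noise, milk is recorded as
per-milking concentrations derived from interval excreted amounts (with
proportional noise on the cumulative amounts) and per-milking volumes from
the animal's daily yield.  Body weights and milk yields are uniform over the
published ranges.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .dataset import (DEFAULT_LIMITS, Observation, StudyDataset, Subject)
from .model import DoseEvent, milk_cumulative_closed, plasma_conc_closed
from .nlme import PopulationModel
from .simulate import draw_individuals, milk_conc_from_amounts
from .units import dose_ng, volume_from_weight

__all__ = ["SamplingDesign", "study_design", "generate_study", "generate_pooled"]


@dataclass(frozen=True)
class SamplingDesign:
    name: str
    n_subjects: int
    body_weight_range_kg: Tuple[float, float]
    dose_times_h: Tuple[float, ...]
    dose_mg_per_kg: float
    plasma_times_h: Tuple[float, ...]
    milk_times_h: Tuple[float, ...] = ()
    milk_yield_range_lbs: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        for seq in (self.plasma_times_h, self.milk_times_h, self.dose_times_h):
            arr = np.asarray(seq)
            if arr.size and (np.any(np.diff(arr) <= 0) or np.any(arr < 0)):
                raise ValueError("times must be sorted, unique and non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _steps(start, stop, step):
    return tuple(np.arange(start, stop + 1e-9, step))


_DESIGNS = {
    # plasma twice daily during the 7 days after the SECOND injection;
    # milk twice daily d1-21, every 48 h d22-36, every 72 h d37-64
    "twodose_lactating": SamplingDesign(
        name="twodose_lactating", n_subjects=8,
        body_weight_range_kg=(73.0, 109.0),
        dose_times_h=(0.0, 168.0), dose_mg_per_kg=2.5,
        plasma_times_h=_steps(180.0, 348.0, 12.0),
        milk_times_h=_steps(12.0, 504.0, 12.0) + _steps(540.0, 876.0, 48.0)
                     + _steps(948.0, 1524.0, 72.0),
        milk_yield_range_lbs=(7.0, 14.0)),
    # plasma twice daily for 7 days; milk twice daily d1-14, 48 h d14-28,
    # 72 h d28-45
    "singledose_lactating": SamplingDesign(
        name="singledose_lactating", n_subjects=8,
        body_weight_range_kg=(72.5, 89.0),
        dose_times_h=(0.0,), dose_mg_per_kg=2.5,
        plasma_times_h=_steps(12.0, 168.0, 12.0),
        milk_times_h=_steps(12.0, 336.0, 12.0) + _steps(384.0, 672.0, 48.0)
                     + _steps(720.0, 1080.0, 72.0),
        milk_yield_range_lbs=(7.0, 14.0)),
    # dense early plasma-only sampling; market body weight is not published,
    # 30 kg is a configurable stand-in typical of 6-month meat goats
    "market": SamplingDesign(
        name="market", n_subjects=10,
        body_weight_range_kg=(25.0, 35.0),
        dose_times_h=(0.0,), dose_mg_per_kg=2.5,
        plasma_times_h=tuple(np.array([1, 2, 4, 6, 8, 10]) / 60.0)
                       + (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0)
                       + _steps(24.0, 360.0, 24.0)),
}


def study_design(name: str) -> SamplingDesign:
    try:
        return _DESIGNS[name]
    except KeyError:
        raise ValueError(f"unknown design {name!r}; valid designs: "
                         f"{sorted(_DESIGNS)}") from None


def generate_study(design, pop: PopulationModel, seed=None,
                   residual: bool = True) -> StudyDataset:
    """Simulate one study under ``design`` from the population model."""
    if isinstance(design, str):
        design = study_design(design)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lod_p = DEFAULT_LIMITS["plasma"].lod
    lod_m = DEFAULT_LIMITS["milk"].lod
    sig_p = pop.sigma.get("plasma_conc", 0.0) if residual else 0.0
    sig_m = pop.sigma.get("milk_cumamount", 0.0) if residual else 0.0
    subjects = []
    for i in range(design.n_subjects):
        bw = rng.uniform(*design.body_weight_range_kg)
        ind = draw_individuals(pop, 1, seed=rng)[0]
        doses = [DoseEvent(t, dose_ng(design.dose_mg_per_kg, bw))
                 for t in design.dose_times_h]
        obs = []
        tp = np.asarray(design.plasma_times_h)
        if tp.size:
            f = plasma_conc_closed(ind, doses, tp)
            y = np.clip(f * (1.0 + sig_p * rng.standard_normal(tp.size)), 0.0, None)
            for t, v in zip(tp, y):
                obs.append(Observation(time_h=float(t), kind="plasma_conc",
                                       value=float(v), bloq=bool(v < lod_p)))
        yld = None
        tm = np.asarray(design.milk_times_h)
        if tm.size:
            yld = rng.uniform(*design.milk_yield_range_lbs)
            vols = np.empty(tm.size)
            prev = 0.0
            for k, t in enumerate(tm):
                vols[k] = volume_from_weight(yld * (t - prev) / 24.0, "lbs")
                prev = t
            cum = milk_cumulative_closed(ind, doses, tm)
            if sig_m > 0:
                cum = cum * (1.0 + sig_m * rng.standard_normal(tm.size))
                cum = np.maximum.accumulate(np.clip(cum, 0.0, None))
            conc = milk_conc_from_amounts(tm, cum, vols)
            for t, v, vol in zip(tm, conc, vols):
                obs.append(Observation(time_h=float(t), kind="milk_conc",
                                       value=float(max(v, 0.0)),
                                       milk_volume_ml=float(vol),
                                       bloq=bool(v < lod_m)))
        subjects.append(Subject(id=f"{design.name}_{i + 1:02d}",
                                study=design.name, body_weight_kg=float(bw),
                                doses=doses, observations=obs,
                                daily_milk_yield_lbs=yld))
    return StudyDataset(subjects=subjects,
                        note=f"synthetic {design.name} study")


def generate_pooled(pop: PopulationModel, seed=None, residual: bool = True,
                    designs: Sequence[str] = ("twodose_lactating",
                                              "singledose_lactating",
                                              "market")) -> StudyDataset:
    """The pooled 26-subject analysis dataset (all three designs)."""
    rng = np.random.default_rng(seed)
    subjects = []
    for name in designs:
        ds = generate_study(name, pop, seed=rng, residual=residual)
        subjects.extend(ds.subjects)
    return StudyDataset(subjects=subjects, note="synthetic pooled dataset")
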