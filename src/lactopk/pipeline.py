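"""End-to-end orchestration: data -> NCA -> candidate fits -> bootstrap ->
Monte Carlo simulation -> withdrawal report, from one configuration."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import fixtures
from .bootstrap import bootstrap_ci
from .dataset import DEFAULT_LIMITS, StudyDataset, apply_bloq_policy, load_dataset, save_dataset
from .generate import generate_pooled
from .nca import nca_table
from .nlme import STRUCTURES, compare_models, fit_population
from .simulate import simulate_replicates, standard_regimen, withdrawal_time

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    input_path: Optional[str] = None     # or generate synthetically:
    seed: int = 1
    bloq_policy: str = "exclude"
    structures: List[str] = field(default_factory=lambda: ["2cpt"])
    error_models: List[str] = field(default_factory=lambda: ["proportional"])
    n_boot: int = 100
    n_reps: int = 100
    tolerance_plasma: float = DEFAULT_LIMITS["plasma"].lod
    tolerance_milk: float = DEFAULT_LIMITS["milk"].lod
    percentile: float = 95.0
    out_dir: str = "lactopk_run"
    fit_maxiter: int = 200
    sim_doses: int = 2
    sim_interval_days: float = 7.0
    sim_dose_mg_per_kg: float = 2.5
    sim_body_weight_kg: float = 88.0
    use_table3_for_sim: bool = False     # simulate from the new fit by default

    def validate(self):
        for s in self.structures:
            if s not in STRUCTURES:
                raise ValueError(f"unknown structure {s!r} in config")
        for em in self.error_models:
            if em not in ("additive", "proportional", "combined"):
                raise ValueError(f"unknown error model {em!r} in config")
        if self.bloq_policy not in ("exclude", "zero", "half_lod"):
            raise ValueError(f"unknown BLOQ policy {self.bloq_policy!r}")


def load_config(path) -> RunConfig:
    """Parse a plain ``key: value`` config file."""
    cfg = RunConfig()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition(":")
        key, raw = key.strip(), raw.strip()
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        cur = getattr(cfg, key)
        if isinstance(cur, list):
            val = [x.strip() for x in raw.split(",") if x.strip()]
        elif isinstance(cur, bool):
            val = raw.lower() in ("1", "true", "yes")
        elif isinstance(cur, int):
            val = int(raw)
        elif isinstance(cur, float):
            val = float(raw)
        else:
            val = raw or None
        setattr(cfg, key, val)
    return cfg


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Execute all stages; returns a dict of artifact paths.

    Stages: load/generate data, NCA table, candidate fits with AIC ranking,
    bootstrap of the selected model, Monte Carlo simulation and the
    withdrawal report.  Reruns with the same config are reproducible.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []
    artifacts: Dict[str, str] = {}

    def log(stage, msg):
        line = f"[{time.strftime('%H:%M:%S')}] {stage}: {msg}"
        log_lines.append(line)

    def stage(name):
        log(name, "start")

    # provenance copy of the configuration
    cfg_path = out / "config.txt"
    cfg_path.write_text("".join(f"{k}: {v if not isinstance(v, list) else ','.join(map(str, v))}\n"
                                for k, v in asdict(config).items()))
    artifacts["config"] = str(cfg_path)

    stage("data")
    if config.input_path:
        ds = load_dataset(config.input_path)
        log("data", f"loaded {config.input_path}: {ds.n_observations} observations")
    else:
        pop0 = fixtures.table3_population()
        ds = generate_pooled(pop0, seed=config.seed, residual=True)
        gen_path = out / "synthetic_data.csv"
        save_dataset(ds, gen_path)
        artifacts["data"] = str(gen_path)
        log("data", f"generated pooled synthetic dataset (seed={config.seed}): "
                    f"{ds.n_observations} observations")
    ds_fit = apply_bloq_policy(ds, config.bloq_policy)
    log("data", f"BLOQ policy {config.bloq_policy}: "
                f"{ds_fit.n_observations}/{ds.n_observations} observations retained")

    stage("nca")
    nca = nca_table(ds)
    nca_path = out / "nca.csv"
    nca.to_csv(nca_path, index=False)
    artifacts["nca"] = str(nca_path)
    log("nca", f"{len(nca)} summary rows")

    stage("fit")
    fits = []
    for s in config.structures:
        for em in config.error_models:
            fit = fit_population(ds_fit, structure=s,
                                 error_models={"plasma_conc": em,
                                               "milk_cumamount": em},
                                 maxiter=config.fit_maxiter,
                                 dataset_tag="pipeline")
            fits.append(fit)
            log("fit", f"{s}/{em}: -2LL={fit.neg2ll:.2f} AIC={fit.aic:.2f} "
                       f"converged={fit.converged} ({fit.wall_time_s:.1f}s)")
    ranking = compare_models(fits)
    fits_path = out / "fits.csv"
    ranking.to_csv(fits_path, index=False)
    artifacts["fits"] = str(fits_path)
    selected = fits[int(np.argmin([f.aic for f in fits]))]
    est = selected.estimates
    est_rows = [dict(parameter=n, estimate=getattr(est.theta, n),
                     iiv_variance=est.omega.get(n, 0.0)) for n in est.param_names]
    est_rows += [dict(parameter=f"sigma_{k}", estimate=v, iiv_variance=np.nan)
                 for k, v in est.sigma.items()]
    import pandas as pd
    est_path = out / "estimates.csv"
    pd.DataFrame(est_rows).to_csv(est_path, index=False)
    artifacts["estimates"] = str(est_path)

    stage("bootstrap")
    boot = bootstrap_ci(ds_fit, n_reps=config.n_boot, seed=config.seed,
                        structure=est.structure, maxiter=config.fit_maxiter,
                        strict_convergence=False)
    boot_path = out / "bootstrap.csv"
    boot.ci.to_csv(boot_path, index=False)
    artifacts["bootstrap"] = str(boot_path)
    log("bootstrap", f"{config.n_boot} replicates, {boot.n_nonconverged} non-converged")

    stage("simulate")
    sim_pop = fixtures.table3_population() if config.use_table3_for_sim else est
    doses = standard_regimen(n_doses=config.sim_doses,
                             interval_h=config.sim_interval_days * 24.0,
                             dose_mg_per_kg=config.sim_dose_mg_per_kg,
                             body_weight_kg=config.sim_body_weight_kg)
    sim = simulate_replicates(sim_pop, doses, n_reps=config.n_reps,
                              seed=config.seed,
                              regimen_label=f"{config.sim_doses}x "
                                            f"{config.sim_dose_mg_per_kg} mg/kg SC")
    bands_path = out / "bands.csv"
    bands = sim.band_frame("plasma").rename(columns=lambda c: c if c == "time_h"
                                            else f"plasma_{c}_ngml")
    milk_bands = sim.band_frame("milk").rename(columns=lambda c: c if c == "time_h"
                                               else f"milk_{c}_ngml")
    bands.merge(milk_bands, on="time_h", how="outer").to_csv(bands_path, index=False)
    artifacts["bands"] = str(bands_path)
    log("simulate", f"{config.n_reps} replicates (seed={config.seed})")

    stage("withdrawal")
    wd_plasma = withdrawal_time(sim, "plasma", config.tolerance_plasma,
                                config.percentile)
    wd_milk = withdrawal_time(sim, "milk", config.tolerance_milk,
                              config.percentile)
    report = {
        "regimen": sim.regimen, "seed": config.seed,
        "percentile": config.percentile,
        "plasma": {"tolerance_ngml": wd_plasma.tolerance_ngml,
                   "days_after_last_dose": wd_plasma.days,
                   "defined": wd_plasma.defined},
        "milk": {"tolerance_ngml": wd_milk.tolerance_ngml,
                 "days_after_last_dose": wd_milk.days,
                 "defined": wd_milk.defined,
                 "definitive": wd_milk.definitive,
                 "note": wd_milk.note},
    }
    wd_path = out / "withdrawal.json"
    wd_path.write_text(json.dumps(report, indent=2) + "\n")
    artifacts["withdrawal"] = str(wd_path)
    log("withdrawal", f"plasma {wd_plasma.days} d, milk {wd_milk.days} d "
                      f"(non-definitive)")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = str(out / "run.log")
    return artifacts
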