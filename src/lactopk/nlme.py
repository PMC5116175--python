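"""Population (nonlinear mixed-effects) estimation.

The model: individual parameters are log-normally distributed around the
population means, ``P_i = theta * exp(eta_i)`` with ``eta_i ~ N(0, Omega)``
(diagonal Omega, one variance per structural parameter).  Residual error is
additive, proportional or combined, with one block per observation kind
(plasma concentrations; cumulative milk amounts), and the proportional
variance is evaluated at the conditional prediction ("with interaction").

The marginal likelihood is approximated subject-by-subject by the Laplace /
FOCE method: the joint -2 log-likelihood is minimised over each subject's
eta (the empirical-Bayes mode) and the Gaussian integral over eta is
replaced by the curvature correction at the mode,

    -2 log L_i  ~=  joint(-2LL)(eta_hat) + log det H - d log(2 pi)

with H the Gauss-Newton Hessian ``Omega^-1 + J' W J`` of the joint
objective.  When all omegas are zero this reduces exactly to the pooled
(naive) -2 log-likelihood.  Lactating subjects contribute both plasma and
milk likelihood terms; market subjects plasma only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .dataset import StudyDataset, build_milk_cumulative
from .model import PKParams

__all__ = ["PopulationModel", "FitResult", "STRUCTURES", "subject_data",
           "individual_neg2ll", "laplace_neg2ll", "foce_objective",
           "fit_population", "compare_models", "default_initials"]

STRUCTURES: Dict[str, tuple] = {
    "1cpt": ("V", "Cl", "CLmilk", "Ka"),
    "2cpt": ("V", "Cl", "V2", "Cl2", "CLmilk", "Ka"),
    "3cpt": ("V", "Cl", "V2", "Cl2", "V3", "Cl3", "CLmilk", "Ka"),
}

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class PopulationModel:
    theta: PKParams
    omega: Dict[str, float]            # log-scale random-effect VARIANCES
    sigma: Dict[str, float]            # per observation kind
    error_model: Dict[str, str] = field(default_factory=lambda: {
        "plasma_conc": "proportional", "milk_cumamount": "proportional"})
    sigma_add: Dict[str, float] = field(default_factory=dict)  # for "combined"
    structure: str = "2cpt"

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; "
                             f"expected one of {sorted(STRUCTURES)}")
        names = STRUCTURES[self.structure]
        for k, v in self.omega.items():
            if k not in names:
                raise ValueError(f"omega entry {k!r} not a {self.structure} parameter")
            if v < 0:
                raise ValueError("omega entries must be non-negative")
        for k, v in self.sigma.items():
            if v <= 0:
                raise ValueError("sigma must be positive")
        for em in self.error_model.values():
            if em not in ("additive", "proportional", "combined"):
                raise ValueError(f"unknown error model {em!r}")

    @property
    def param_names(self):
        return STRUCTURES[self.structure]

    def theta_array(self) -> np.ndarray:
        return np.array([getattr(self.theta, n) for n in self.param_names])

    def omega_array(self) -> np.ndarray:
        return np.array([self.omega.get(n, 0.0) for n in self.param_names])

    def n_free_params(self, fit_omega: bool = True, fit_sigma: bool = True) -> int:
        n = len(self.param_names)
        if fit_omega:
            n += sum(1 for v in self.omega.values() if v > 0)
        if fit_sigma:
            n += len(self.sigma) + sum(1 for k in self.sigma
                                       if self.error_model.get(k) == "combined")
        return n


@dataclass
class FitResult:
    estimates: PopulationModel
    neg2ll: float
    n_obs: int
    n_params: int
    etas: Dict[str, np.ndarray]
    converged: bool
    n_outer_iter: int
    message: str = ""
    wall_time_s: float = 0.0
    dataset_tag: Optional[str] = None

    @property
    def aic(self) -> float:
        return self.neg2ll + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return self.neg2ll + self.n_params * np.log(self.n_obs)


# ---------------------------------------------------------------------------
# packed per-subject data and fast structural predictions

@dataclass
class _SubjectData:
    sid: str
    study: str
    dose_times: np.ndarray
    dose_amts: np.ndarray
    t_plasma: np.ndarray
    y_plasma: np.ndarray
    t_milk: np.ndarray
    y_milk: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.t_plasma.size + self.t_milk.size


def subject_data(ds: StudyDataset) -> List[_SubjectData]:
    """Pack a dataset for fitting: plasma concentrations plus the cumulative
    milk amount series (built from per-milking records where needed)."""
    out = []
    for s in ds.subjects:
        plasma = s.observations_of("plasma_conc")
        tp = np.array([o.time_h for o in plasma])
        yp = np.array([o.value for o in plasma])
        if s.observations_of("milk_conc") or s.observations_of("milk_cumamount"):
            cum = build_milk_cumulative(s)
            tm, ym = cum[:, 0], cum[:, 1]
        else:
            tm = ym = np.empty(0)
        if tp.size + tm.size == 0:
            continue
        out.append(_SubjectData(
            sid=s.id, study=s.study,
            dose_times=np.array([d.time_h for d in s.doses]),
            dose_amts=np.array([d.amount_ng for d in s.doses]),
            t_plasma=tp, y_plasma=yp, t_milk=tm, y_milk=ym))
    return out


def _exponents_2cpt(V, Cl, V2, Cl2, CLmilk, Ka):
    k10 = (Cl + CLmilk) / V
    k12 = Cl2 / V
    k21 = Cl2 / V2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    al = 0.5 * (s + disc)
    be = 0.5 * (s - disc)
    if abs(Ka - al) < 1e-9 * Ka or (be > 0 and abs(Ka - be) < 1e-9 * Ka):
        Ka = Ka * (1.0 + 1e-8)
    A = (k21 - al) / ((Ka - al) * (be - al))
    B = (k21 - be) / ((Ka - be) * (al - be)) if be > 0 else 0.0
    G = (k21 - Ka) / ((al - Ka) * (be - Ka))
    return np.array([al, be, Ka]), np.array([A, B, G])


def _predict(structure: str, p: np.ndarray, sd: _SubjectData):
    """(plasma conc at t_plasma, cumulative milk amount at t_milk)."""
    if structure == "2cpt":
        V, Cl, V2, Cl2, CLmilk, Ka = p
    elif structure == "1cpt":
        V, Cl, CLmilk, Ka = p
        V2, Cl2 = 1.0, 0.0
    else:  # 3cpt via the generic eigen solution
        from .model import DoseEvent, PKParams, _conc_eigen, _milk_eigen
        V, Cl, V2, Cl2, V3, Cl3, CLmilk, Ka = p
        params = PKParams(V=V, Cl=Cl, V2=V2, Cl2=Cl2, CLmilk=CLmilk, Ka=Ka,
                          V3=V3, Cl3=Cl3)
        doses = [DoseEvent(t, a) for t, a in zip(sd.dose_times, sd.dose_amts)]
        fp = _conc_eigen(params, doses, sd.t_plasma) if sd.t_plasma.size else np.empty(0)
        fm = _milk_eigen(params, doses, sd.t_milk) if sd.t_milk.size else np.empty(0)
        return fp, fm
    # extreme parameter probes during optimisation can overflow; the
    # resulting non-finite predictions are rejected by the likelihood
    with np.errstate(all="ignore"):
        rates, coefs = _exponents_2cpt(V, Cl, V2, Cl2, CLmilk, Ka)
        scale = sd.dose_amts * Ka / V
        fp = np.zeros(sd.t_plasma.size)
        fm = np.zeros(sd.t_milk.size)
        for td, sc in zip(sd.dose_times, scale):
            if fp.size:
                tau = sd.t_plasma - td
                m = tau >= 0
                e = np.exp(-np.outer(tau[m], rates))
                fp[m] += sc * (e @ coefs)
            if fm.size:
                tau = sd.t_milk - td
                m = tau >= 0
                inv = np.where(rates > 0, 1.0 / np.where(rates > 0, rates, 1.0), 0.0)
                e = -np.expm1(-np.outer(tau[m], rates))
                fm[m] += CLmilk * sc * (e @ (coefs * inv))
    return fp, fm


def _predict_batch(structure: str, P: np.ndarray, sd: _SubjectData):
    """Predictions for a batch of parameter vectors, shape (k, npar).

    Returns (fp, fm) with shapes (k, n_plasma) and (k, n_milk).  The
    two-compartment exponents vectorise over the batch; the rare 3cpt
    path falls back to a row loop.
    """
    k = P.shape[0]
    if structure != "3cpt":
        with np.errstate(all="ignore"):
            return _predict_batch_2cpt(structure, P, sd)
    fp = np.zeros((k, sd.t_plasma.size))
    fm = np.zeros((k, sd.t_milk.size))
    for i in range(k):
        fp[i], fm[i] = _predict(structure, P[i], sd)
    return fp, fm


def _predict_batch_2cpt(structure: str, P: np.ndarray, sd: _SubjectData):
    k = P.shape[0]
    if structure == "2cpt":
        V, Cl, V2, Cl2, CLmilk, Ka = (P[:, i] for i in range(6))
    else:
        V, Cl, CLmilk, Ka = (P[:, i] for i in range(4))
        V2 = np.ones(k)
        Cl2 = np.zeros(k)
    k10 = (Cl + CLmilk) / V
    k12 = Cl2 / V
    k21 = Cl2 / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    al = 0.5 * (s + disc)
    be = 0.5 * (s - disc)
    Ka = np.where((np.abs(Ka - al) < 1e-9 * Ka)
                  | ((be > 0) & (np.abs(Ka - be) < 1e-9 * Ka)),
                  Ka * (1.0 + 1e-8), Ka)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (k21 - al) / ((Ka - al) * (be - al))
        B = np.where(be > 0, (k21 - be) / ((Ka - be) * (al - be)), 0.0)
    G = (k21 - Ka) / ((al - Ka) * (be - Ka))
    rates = np.stack([al, be, Ka], axis=1)           # (k, 3)
    coefs = np.stack([A, B, G], axis=1)              # (k, 3)
    with np.errstate(divide="ignore"):
        inv_rates = np.where(rates > 0, 1.0 / np.where(rates > 0, rates, 1.0), 0.0)
    fp = np.zeros((k, sd.t_plasma.size))
    fm = np.zeros((k, sd.t_milk.size))
    for td, da in zip(sd.dose_times, sd.dose_amts):
        sc = da * Ka / V                              # (k,)
        if fp.shape[1]:
            tau = sd.t_plasma - td
            m = tau >= 0
            e = np.exp(-tau[m][None, :, None] * rates[:, None, :])
            fp[:, m] += sc[:, None] * np.einsum("knr,kr->kn", e, coefs)
        if fm.shape[1]:
            tau = sd.t_milk - td
            m = tau >= 0
            e = -np.expm1(-tau[m][None, :, None] * rates[:, None, :])
            fm[:, m] += (CLmilk * sc)[:, None] * np.einsum(
                "knr,kr->kn", e, coefs * inv_rates)
    return fp, fm


def _residual_neg2ll(y, f, err_model, sig, sig_add):
    if err_model == "proportional":
        var = (sig * f) ** 2
        if np.any(f <= 0):
            raise FloatingPointError("non-positive prediction under proportional error")
    elif err_model == "additive":
        var = np.full(y.shape, sig ** 2)
    else:  # combined
        var = (sig * f) ** 2 + sig_add ** 2
    return float(np.sum(np.log(2.0 * np.pi * var) + (y - f) ** 2 / var)), var


def individual_neg2ll(pop: PopulationModel, sd: _SubjectData,
                      eta: np.ndarray) -> float:
    """Joint -2 log-likelihood of (y, eta) for one subject.

    Dimensions with zero omega are fixed at eta = 0 and contribute no prior
    term (the degenerate limit), so with all omegas zero this is the pooled
    -2LL of the subject.
    """
    names = pop.param_names
    theta = pop.theta_array()
    om = pop.omega_array()
    eta = np.asarray(eta, dtype=float)
    if eta.size != len(names):
        full = np.zeros(len(names))
        full[om > 0] = eta
        eta = full
    p = theta * np.exp(eta)
    fp, fm = _predict(pop.structure, p, sd)
    total = 0.0
    for kind, y, f in (("plasma_conc", sd.y_plasma, fp),
                       ("milk_cumamount", sd.y_milk, fm)):
        if y.size == 0:
            continue
        ll, _ = _residual_neg2ll(y, f, pop.error_model.get(kind, "proportional"),
                                 pop.sigma[kind], pop.sigma_add.get(kind, 0.0))
        total += ll
    free = om > 0
    if free.any():
        total += float(np.sum(eta[free] ** 2 / om[free]))
        total += float(np.sum(np.log(2.0 * np.pi * om[free])))
    return total


def _joint_from_predictions(pop, sd, fp, fm, eta_full, om, free):
    total = 0.0
    for kind, y, f in (("plasma_conc", sd.y_plasma, fp),
                       ("milk_cumamount", sd.y_milk, fm)):
        if y.size == 0:
            continue
        em = pop.error_model.get(kind, "proportional")
        sig = pop.sigma[kind]
        if em == "proportional":
            if np.any(f <= 0):
                return np.inf
            var = (sig * f) ** 2
        elif em == "additive":
            var = np.full(y.shape, sig ** 2)
        else:
            var = (sig * f) ** 2 + pop.sigma_add.get(kind, 0.0) ** 2
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            contrib = float(np.sum(np.log(2.0 * np.pi * var) + (y - f) ** 2 / var))
        if not np.isfinite(contrib):
            return np.inf
        total += contrib
    if free.any():
        total += float(np.sum(eta_full[free] ** 2 / om[free]))
        total += float(np.sum(np.log(2.0 * np.pi * om[free])))
    return total


def _obs_weights(pop, sd, fp, fm):
    """Inverse residual variances at the conditional predictions."""
    out = []
    for kind, f in (("plasma_conc", fp), ("milk_cumamount", fm)):
        if f.size == 0:
            out.append(np.empty(0))
            continue
        em = pop.error_model.get(kind, "proportional")
        sig = pop.sigma[kind]
        if em == "proportional":
            var = (sig * f) ** 2
        elif em == "additive":
            var = np.full(f.shape, sig ** 2)
        else:
            var = (sig * f) ** 2 + pop.sigma_add.get(kind, 0.0) ** 2
        out.append(1.0 / var)
    return out


def laplace_neg2ll(pop: PopulationModel, sd: _SubjectData,
                   eta0: Optional[np.ndarray] = None,
                   inner_gtol: float = 1e-6, max_inner: int = 60):
    """FOCE/Laplace -2 log marginal likelihood for one subject.

    The conditional mode is found by a damped Newton iteration whose
    curvature matrix is the Gauss-Newton Hessian ``Omega^-1 + J' W J`` (W
    the inverse residual variances at the conditional prediction, i.e. the
    interaction form); the same matrix supplies the Laplace log-determinant.
    Returns ``(value, eta_hat)`` with eta_hat over the free (omega > 0)
    dimensions.
    """
    om = pop.omega_array()
    theta = pop.theta_array()
    free = om > 0
    d = int(free.sum())
    if d == 0:
        return individual_neg2ll(pop, sd, np.zeros(om.size)), np.empty(0)
    cols = np.nonzero(free)[0]
    eta_full = np.zeros(om.size)
    if eta0 is not None and eta0.size == d:
        eta_full[cols] = eta0
    fd_h = 1e-4
    om_inv_free = 1.0 / om[free]

    j0 = None
    H = np.eye(d)
    for _ in range(max_inner):
        E = np.tile(eta_full, (d + 1, 1))
        E[np.arange(1, d + 1), cols] += fd_h
        fp, fm = _predict_batch(pop.structure, theta * np.exp(E), sd)
        j0 = _joint_from_predictions(pop, sd, fp[0], fm[0], eta_full, om, free)
        if not np.isfinite(j0):
            raise RuntimeError(f"inner eta optimisation failed for subject {sd.sid}: "
                               "non-finite joint likelihood at the current eta")
        jpert = np.array([_joint_from_predictions(pop, sd, fp[1 + j], fm[1 + j],
                                                  E[1 + j], om, free)
                          for j in range(d)])
        grad = (jpert - j0) / fd_h
        Jp = (fp[1:] - fp[0]).T / fd_h
        Jm = (fm[1:] - fm[0]).T / fd_h
        wp, wm = _obs_weights(pop, sd, fp[0], fm[0])
        H = np.diag(om_inv_free)
        if Jp.size:
            H = H + (Jp.T * wp) @ Jp
        if Jm.size:
            H = H + (Jm.T * wm) @ Jm
        step = -np.linalg.solve(2.0 * H, grad)
        decrement = -float(grad @ step)          # expected decrease scale
        if decrement < inner_gtol * (1.0 + abs(j0)) * 1e-3 or np.max(np.abs(step)) < 1e-9:
            break
        # |eta| beyond ~15 on the log scale is physically meaningless and
        # only risks overflow during the search
        lam = 1.0
        while lam > 1e-10:
            trial = eta_full.copy()
            trial[cols] = np.clip(trial[cols] + lam * step, -15.0, 15.0)
            fpt, fmt = _predict_batch(pop.structure,
                                      (theta * np.exp(trial))[None, :], sd)
            jt = _joint_from_predictions(pop, sd, fpt[0], fmt[0], trial, om, free)
            if jt < j0 - 1e-4 * lam * decrement:
                eta_full = trial
                break
            lam *= 0.5
        else:
            break
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise RuntimeError(f"non-positive-definite curvature for subject {sd.sid}")
    value = j0 - d * _LN2PI + logdet
    return value, eta_full[cols]


def foce_objective(pop: PopulationModel, data, warm: Optional[Dict[str, np.ndarray]] = None,
                   inner_gtol: float = 1e-6) -> float:
    """Approximate marginal -2 log-likelihood over all subjects."""
    sds = data if isinstance(data, list) else subject_data(data)
    total = 0.0
    for sd in sds:
        eta0 = warm.get(sd.sid) if warm is not None else None
        v, eta = laplace_neg2ll(pop, sd, eta0=eta0, inner_gtol=inner_gtol)
        if warm is not None:
            warm[sd.sid] = eta
        total += v
    return total


# ---------------------------------------------------------------------------
# population fit

def default_initials(data: StudyDataset, structure: str = "2cpt") -> PopulationModel:
    """Crude NCA-flavoured starting values.

    Clearance from dose/AUCinf on plasma profiles, volume from clearance and
    the terminal slope, milk clearance from the excreted fraction; absorption
    and the peripheral compartment start at generic values.
    """
    from .nca import nca_summary

    sds = subject_data(data)
    cls, vzs, fracs = [], [], []
    for sd in sds:
        if sd.t_plasma.size >= 4:
            try:
                res = nca_summary(sd.t_plasma, sd.y_plasma,
                                  dose_time=float(sd.dose_times[0]))
                if res.auc_inf and res.lambda_z:
                    cl = sd.dose_amts.sum() / res.auc_inf
                    cls.append(cl)
                    vzs.append(cl / res.lambda_z)
            except ValueError:
                pass
        if sd.t_milk.size:
            fracs.append(sd.y_milk[-1] / sd.dose_amts.sum())
    cl = float(np.median(cls)) if cls else 2e4
    vz = float(np.median(vzs)) if vzs else 2e6
    frac = float(np.clip(np.median(fracs), 1e-4, 0.5)) if fracs else 0.04
    clmilk = cl * frac / (1.0 - frac)
    V = vz / 5.0
    kw = dict(V=V, Cl=cl, CLmilk=clmilk, Ka=0.5)
    if structure in ("2cpt", "3cpt"):
        kw.update(V2=2.0 * V, Cl2=cl / 2.0)
    if structure == "3cpt":
        kw.update(V3=V, Cl3=cl / 4.0)
    names = STRUCTURES[structure]
    theta = PKParams(**kw)
    return PopulationModel(theta=theta,
                           omega={n: 0.1 for n in names},
                           sigma={"plasma_conc": 0.3, "milk_cumamount": 0.1},
                           structure=structure)


def _pack(pop: PopulationModel, fit_omega: bool, fit_sigma: bool):
    names = pop.param_names
    x = list(np.log(pop.theta_array()))
    layout = [("theta", n) for n in names]
    if fit_omega:
        for n in names:
            if pop.omega.get(n, 0.0) > 0:
                x.append(np.log(pop.omega[n]))
                layout.append(("omega", n))
    if fit_sigma:
        for k in sorted(pop.sigma):
            x.append(np.log(pop.sigma[k]))
            layout.append(("sigma", k))
            if pop.error_model.get(k) == "combined":
                x.append(np.log(max(pop.sigma_add.get(k, 1.0), 1e-6)))
                layout.append(("sigma_add", k))
    return np.array(x), layout


def _unpack(x: np.ndarray, layout, template: PopulationModel) -> PopulationModel:
    theta_kw = {n: getattr(template.theta, n) for n in template.param_names}
    omega = dict(template.omega)
    sigma = dict(template.sigma)
    sigma_add = dict(template.sigma_add)
    for v, (group, name) in zip(x, layout):
        val = float(np.exp(np.clip(v, -700.0, 700.0)))
        if group == "theta":
            theta_kw[name] = val
        elif group == "omega":
            omega[name] = val
        elif group == "sigma":
            sigma[name] = val
        else:
            sigma_add[name] = val
    if template.structure == "1cpt":
        theta = PKParams(V=theta_kw["V"], Cl=theta_kw["Cl"], V2=1.0, Cl2=0.0,
                         CLmilk=theta_kw["CLmilk"], Ka=theta_kw["Ka"])
    elif template.structure == "3cpt":
        theta = PKParams(**theta_kw)
    else:
        theta = PKParams(**{k: theta_kw[k] for k in STRUCTURES["2cpt"]})
    return replace(template, theta=theta, omega=omega, sigma=sigma,
                   sigma_add=sigma_add)


def fit_population(data: StudyDataset, structure: str = "2cpt",
                   error_models: Optional[Dict[str, str]] = None,
                   init: Optional[PopulationModel] = None,
                   fit_omega: bool = True, fit_sigma: bool = True,
                   maxiter: int = 200, outer_tol: float = 1e-6,
                   inner_gtol: float = 1e-6, fd_step: float = 1e-4,
                   dataset_tag: Optional[str] = None) -> FitResult:
    """Maximise the FOCE approximate marginal likelihood.

    Population means, IIV variances and residual parameters are optimised on
    the log scale with L-BFGS-B (finite-difference gradients, step
    ``fd_step``); each objective evaluation re-solves every subject's inner
    eta problem, warm-started from the previous evaluation.  Deterministic
    given the data and starting values.
    """
    sds = subject_data(data)
    if not sds:
        raise ValueError("dataset has no fittable subjects")
    if init is None:
        init = default_initials(data, structure)
    if init.structure != structure:
        raise ValueError("init structure does not match requested structure")
    if error_models:
        init = replace(init, error_model={**init.error_model, **error_models})
    kinds_present = set()
    for sd in sds:
        if sd.t_plasma.size:
            kinds_present.add("plasma_conc")
        if sd.t_milk.size:
            kinds_present.add("milk_cumamount")
    init = replace(init, sigma={k: v for k, v in init.sigma.items() if k in kinds_present})

    x0, layout = _pack(init, fit_omega, fit_sigma)
    warm: Dict[str, np.ndarray] = {}
    n_eval = [0]

    def objective(x):
        pop = _unpack(x, layout, init)
        n_eval[0] += 1
        try:
            val = foce_objective(pop, sds, warm=warm, inner_gtol=inner_gtol)
        except (RuntimeError, np.linalg.LinAlgError, FloatingPointError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    bounds = []
    for _, (group, _n) in zip(x0, layout):
        if group == "theta":
            bounds.append((None, None))
        elif group == "omega":
            bounds.append((np.log(1e-4), np.log(100.0)))
        else:
            bounds.append((np.log(1e-5), np.log(100.0)))

    t0 = time.perf_counter()
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": outer_tol,
                            "eps": fd_step, "maxcor": 20})
    wall = time.perf_counter() - t0
    pop = _unpack(res.x, layout, init)
    # final pass for the converged etas and objective
    warm2: Dict[str, np.ndarray] = {}
    final = foce_objective(pop, sds, warm=warm2, inner_gtol=inner_gtol)
    n_obs = sum(sd.n_obs for sd in sds)
    n_params = len(layout)
    return FitResult(estimates=pop, neg2ll=float(final), n_obs=n_obs,
                     n_params=n_params, etas=warm2,
                     converged=bool(res.success), n_outer_iter=int(res.nit),
                     message=str(res.message), wall_time_s=wall,
                     dataset_tag=dataset_tag)


def compare_models(fits: Sequence[FitResult]):
    """Rank candidate fits of the SAME dataset by AIC (ascending)."""
    import pandas as pd
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    tags = {f.dataset_tag for f in fits}
    if len(n_obs) > 1 or len(tags) > 1:
        raise ValueError("fits do not share a dataset (n_obs or tag mismatch)")
    rows = [dict(structure=f.estimates.structure,
                 error_model="/".join(f.estimates.error_model[k]
                                      for k in sorted(f.estimates.sigma)),
                 neg2ll=f.neg2ll, aic=f.aic, bic=f.bic,
                 n_params=f.n_params, converged=f.converged)
            for f in fits]
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["selected"] = False
    df.loc[0, "selected"] = True
    return df
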