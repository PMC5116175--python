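"""Study datasets: domain types, CSV I/O, BLOQ handling and the
per-milking concentration -> cumulative excreted amount conversion.

The CSV schema is NONMEM-flavoured long format::

    subject_id,study,time_h,kind,value,milk_volume_ml,amt_ng,evid,bloq

``evid=1`` rows are dose events and carry ``amt_ng``; ``evid=0`` rows are
observations of ``kind`` plasma_conc (ng/mL), milk_conc (ng/mL, requires
``milk_volume_ml``) or milk_cumamount (ng).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import DoseEvent
from .units import volume_from_weight  # re-exported for convenience

__all__ = [
    "AssayLimits", "Observation", "Subject", "StudyDataset",
    "PLASMA_LIMITS", "MILK_LIMITS", "SchemaError", "ValidationError",
    "load_dataset", "save_dataset", "build_milk_cumulative",
    "apply_bloq_policy", "volume_from_weight",
]

OBS_KINDS = ("plasma_conc", "milk_conc", "milk_cumamount")
STUDY_LABELS = ("twodose_lactating", "singledose_lactating", "market")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A row violates a dataset invariant."""


@dataclass(frozen=True)
class AssayLimits:
    """LC-MS assay limits for one matrix (ng/mL)."""
    matrix: str
    lod: float
    loq: float

    def __post_init__(self):
        if not (0 < self.lod <= self.loq):
            raise ValueError(f"need 0 < lod <= loq, got lod={self.lod}, loq={self.loq}")


#: study assay limits: tulathromycin in plasma, marker residue CP-60,300 in milk
PLASMA_LIMITS = AssayLimits("plasma", lod=1.2, loq=4.0)
MILK_LIMITS = AssayLimits("milk", lod=1.8, loq=5.0)
DEFAULT_LIMITS = {"plasma": PLASMA_LIMITS, "milk": MILK_LIMITS}


@dataclass(frozen=True)
class Observation:
    time_h: float
    kind: str
    value: float
    milk_volume_ml: Optional[float] = None
    bloq: bool = False

    def __post_init__(self):
        if self.kind not in OBS_KINDS:
            raise ValidationError(f"unknown observation kind {self.kind!r}")
        if self.time_h < 0:
            raise ValidationError(f"negative observation time {self.time_h}")
        if self.value < 0:
            raise ValidationError(f"negative observation value {self.value}")
        if self.kind == "milk_conc":
            if self.milk_volume_ml is None or not self.milk_volume_ml > 0:
                raise ValidationError("milk_conc observations require a positive milk_volume_ml")


@dataclass
class Subject:
    id: str
    study: str
    body_weight_kg: float
    doses: List[DoseEvent] = field(default_factory=list)
    observations: List[Observation] = field(default_factory=list)
    daily_milk_yield_lbs: Optional[float] = None

    def __post_init__(self):
        if self.study not in STUDY_LABELS:
            raise ValidationError(f"unknown study label {self.study!r}")
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight must be positive")
        times = [d.time_h for d in self.doses]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(f"dose times must be strictly increasing for subject {self.id}")
        self.observations = sorted(self.observations, key=lambda o: (o.time_h, o.kind))
        if self.study == "market" and any(o.kind.startswith("milk") for o in self.observations):
            raise ValidationError("market subjects have no milk observations")

    def observations_of(self, kind: str) -> List[Observation]:
        return [o for o in self.observations if o.kind == kind]


@dataclass
class StudyDataset:
    subjects: List[Subject]
    assay_limits: Dict[str, AssayLimits] = field(default_factory=lambda: dict(DEFAULT_LIMITS))
    note: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {k: 0 for k in OBS_KINDS}
        for s in self.subjects:
            for o in s.observations:
                out[o.kind] += 1
        return out


# ---------------------------------------------------------------------------
# CSV I/O

_REQUIRED = ["subject_id", "study", "time_h", "kind", "value"]


def load_dataset(path, schema: Optional[Dict[str, str]] = None) -> StudyDataset:
    """Read a study CSV into a validated :class:`StudyDataset`.

    ``schema`` optionally maps the canonical column names to the file's
    actual column names.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    for opt in ("milk_volume_ml", "amt_ng", "evid", "bloq", "body_weight_kg", "daily_milk_yield_lbs"):
        if opt not in df.columns:
            df[opt] = np.nan
    df["evid"] = df["evid"].fillna(0).astype(int)
    df["bloq"] = df["bloq"].fillna(0).astype(bool)

    subjects = []
    for sid, g in df.groupby("subject_id", sort=False):
        study = str(g["study"].iloc[0])
        bw = g["body_weight_kg"].dropna()
        bw = float(bw.iloc[0]) if len(bw) else 88.0
        yld = g["daily_milk_yield_lbs"].dropna()
        yld = float(yld.iloc[0]) if len(yld) else None
        doses, obs = [], []
        for idx, row in g.iterrows():
            t = float(row["time_h"])
            if t < 0:
                raise ValidationError(f"negative time at row {idx}")
            if row["evid"] == 1:
                if not np.isfinite(row["amt_ng"]):
                    raise ValidationError(f"dose row {idx} lacks amt_ng")
                doses.append(DoseEvent(time_h=t, amount_ng=float(row["amt_ng"])))
                continue
            kind = str(row["kind"])
            if kind not in OBS_KINDS:
                raise ValidationError(f"unknown observation kind {kind!r} at row {idx}")
            value = float(row["value"])
            if value < 0:
                raise ValidationError(f"negative value at row {idx}")
            vol = row["milk_volume_ml"]
            vol = float(vol) if np.isfinite(vol) else None
            if kind == "milk_conc" and vol is None:
                raise ValidationError(f"milk_conc row {idx} lacks milk_volume_ml")
            obs.append(Observation(time_h=t, kind=kind, value=value,
                                   milk_volume_ml=vol, bloq=bool(row["bloq"])))
        subjects.append(Subject(id=str(sid), study=study, body_weight_kg=bw,
                                doses=sorted(doses, key=lambda d: d.time_h),
                                observations=obs, daily_milk_yield_lbs=yld))
    return StudyDataset(subjects=subjects)


def to_frame(ds: StudyDataset) -> pd.DataFrame:
    rows = []
    for s in ds.subjects:
        for d in s.doses:
            rows.append(dict(subject_id=s.id, study=s.study, time_h=d.time_h,
                             kind="dose", value=np.nan, milk_volume_ml=np.nan,
                             amt_ng=d.amount_ng, evid=1, bloq=0,
                             body_weight_kg=s.body_weight_kg,
                             daily_milk_yield_lbs=s.daily_milk_yield_lbs))
        for o in s.observations:
            rows.append(dict(subject_id=s.id, study=s.study, time_h=o.time_h,
                             kind=o.kind, value=o.value,
                             milk_volume_ml=o.milk_volume_ml, amt_ng=np.nan,
                             evid=0, bloq=int(o.bloq),
                             body_weight_kg=s.body_weight_kg,
                             daily_milk_yield_lbs=s.daily_milk_yield_lbs))
    return pd.DataFrame(rows)


def save_dataset(ds: StudyDataset, path) -> None:
    to_frame(ds).to_csv(path, index=False)


def dataset_csv_bytes(ds: StudyDataset) -> bytes:
    buf = io.StringIO()
    to_frame(ds).to_csv(buf, index=False)
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# BLOQ policy and the cumulative milk series

def apply_bloq_policy(ds: StudyDataset, policy: str = "exclude") -> StudyDataset:
    """Return a copy of the dataset with BLOQ observations handled.

    exclude  drop BLOQ rows from fitting (M1, the default),
    zero     keep them with value 0,
    half_lod replace the value with LOD/2 for the matrix.
    """
    if policy not in ("exclude", "zero", "half_lod"):
        raise ValueError(f"unknown BLOQ policy {policy!r}")
    subjects = []
    for s in ds.subjects:
        obs = []
        for o in s.observations:
            if not o.bloq:
                obs.append(o)
                continue
            if policy == "exclude":
                continue
            if policy == "zero":
                obs.append(replace(o, value=0.0))
            else:
                matrix = "plasma" if o.kind == "plasma_conc" else "milk"
                obs.append(replace(o, value=ds.assay_limits[matrix].lod / 2.0))
        subjects.append(Subject(id=s.id, study=s.study, body_weight_kg=s.body_weight_kg,
                                doses=list(s.doses), observations=obs,
                                daily_milk_yield_lbs=s.daily_milk_yield_lbs))
    return StudyDataset(subjects=subjects, assay_limits=dict(ds.assay_limits), note=ds.note)


def build_milk_cumulative(subject: Subject) -> np.ndarray:
    """Running cumulative excreted amount (ng) from per-milking records.

    Each milking contributes concentration x volume; the series is the
    running sum in time order and is non-decreasing for non-negative input.
    Returns an array of shape (n, 2): time_h, cumulative ng.  Subjects that
    already carry milk_cumamount observations get those passed through.
    """
    direct = subject.observations_of("milk_cumamount")
    if direct:
        return np.array([[o.time_h, o.value] for o in direct])
    milkings = subject.observations_of("milk_conc")
    if not milkings:
        raise ValidationError(f"subject {subject.id} has no milk observations")
    times = [o.time_h for o in milkings]
    if len(set(times)) != len(times):
        raise ValidationError(f"duplicate milking times for subject {subject.id}")
    amounts = np.array([o.value * o.milk_volume_ml for o in milkings])
    return np.column_stack([times, np.cumsum(amounts)])
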