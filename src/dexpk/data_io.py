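"""Dataset and result I/O with NONMEM-style column conventions.

One row per dose event (EVID 1, AMT µg, RATE µg/min, MDV 1) or observation
(EVID 0, DV µg/L, MDV 0); covariates repeated on every row; −99 marks a
missing PMA or FFM. Times are minutes from the subject's first event.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import CovariateRecord, DoseEvent, impute_pma
from .synthetic_data import PopulationDataset, Subject

__all__ = ["COLUMNS", "MISSING", "RunConfig", "read_dataset", "write_dataset"]

COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV",
    "AGE", "PMA", "WT", "HT", "SEX", "FFM", "STUDY",
]

#: Missing-value sentinel for PMA and FFM.
MISSING = -99.0


@dataclass
class RunConfig:
    """Run settings recorded alongside every output artifact."""

    seed: int = 0
    xtol_rel: float = 1e-3
    ftol_abs: float = 0.01
    bootstrap_reps: int = 1000
    vpc_n_sim: int = 200
    vpc_bins: int = 8
    time_unit: str = "min"  # "min" | "h" (CLI input conversion)
    output_dir: str = "."

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: type(f.default) for f in cls.__dataclass_fields__.values()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = types[key](val)
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(repr(sorted(asdict(self).items())).encode()).hexdigest()[:12]


def write_dataset(dataset: PopulationDataset, path: str | Path) -> None:
    """Write subjects as a NONMEM-style CSV (dose rows then observation rows)."""
    rows = []
    for s in dataset.subjects:
        cov = s.covariates
        base = {
            "AGE": cov.age,
            "PMA": cov.pma if cov.pma is not None else MISSING,
            "WT": cov.weight_tbw,
            "HT": cov.height,
            "SEX": 1 if cov.sex == "male" else 0,
            "FFM": cov.ffm_measured if cov.ffm_measured is not None else MISSING,
            "STUDY": s.study,
        }
        recs = []
        for ev in s.events:
            recs.append(
                {"ID": s.id, "TIME": ev.start, "EVID": 1, "AMT": ev.amount,
                 "RATE": ev.rate if ev.duration > 0 else 0.0, "DV": 0.0, "MDV": 1, **base}
            )
        for t, dv in zip(s.obs_times, s.dv):
            recs.append(
                {"ID": s.id, "TIME": float(t), "EVID": 0, "AMT": 0.0,
                 "RATE": 0.0, "DV": float(dv), "MDV": 0, **base}
            )
        recs.sort(key=lambda r: (r["TIME"], -r["EVID"]))
        rows.extend(recs)
    # %.17g guarantees float64 values survive the text round-trip exactly
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False, float_format="%.17g")


def _row_error(path, i, msg):
    raise ValueError(f"{path}: row {i + 2}: {msg}")  # +2: header and 1-based


def read_dataset(path: str | Path) -> PopulationDataset:
    """Read and validate a NONMEM-style CSV into a PopulationDataset.

    Missing PMA is imputed from age (term birth assumed) and missing FFM is
    left for the covariate model to predict; both are flagged with warnings.
    Violations of the row invariants raise with the offending row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")

    n_imputed_pma = 0
    subjects: list[Subject] = []
    for sid, grp in df.groupby("ID", sort=True):
        grp = grp.reset_index(drop=False)
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            _row_error(path, int(grp["index"].iloc[int(np.argmin(np.diff(times) >= 0))]),
                       f"TIME must be non-decreasing within subject {sid}")
        events: list[DoseEvent] = []
        obs_t: list[float] = []
        dv: list[float] = []
        for _, row in grp.iterrows():
            i = int(row["index"])
            evid = int(row["EVID"])
            if evid == 1:
                if row["AMT"] <= 0:
                    _row_error(path, i, "dose row requires AMT > 0")
                if int(row["MDV"]) != 1:
                    _row_error(path, i, "dose row requires MDV = 1")
                if row["RATE"] > 0:
                    events.append(
                        DoseEvent(start=row["TIME"], duration=row["AMT"] / row["RATE"], rate=row["RATE"])
                    )
                else:
                    events.append(DoseEvent.bolus(row["TIME"], row["AMT"]))
            elif evid == 0:
                if row["AMT"] > 0:
                    _row_error(path, i, "observation row must have AMT = 0")
                if int(row["MDV"]) == 0 and row["DV"] <= 0:
                    _row_error(path, i, "observed DV must be positive when MDV = 0")
                if int(row["MDV"]) == 0:
                    obs_t.append(float(row["TIME"]))
                    dv.append(float(row["DV"]))
            else:
                _row_error(path, i, f"unsupported EVID {evid}")
        if not events:
            _row_error(path, int(grp["index"].iloc[0]), f"subject {sid} has no dose events")
        if obs_t and min(obs_t) < min(ev.start for ev in events):
            _row_error(path, int(grp["index"].iloc[0]),
                       f"subject {sid} has observations before the first dose")
        first = grp.iloc[0]
        pma = float(first["PMA"])
        if pma == MISSING:
            pma = impute_pma(float(first["AGE"]))
            n_imputed_pma += 1
        ffm = float(first["FFM"])
        cov = CovariateRecord(
            age=float(first["AGE"]),
            weight_tbw=float(first["WT"]),
            height=float(first["HT"]),
            sex="male" if int(first["SEX"]) == 1 else "female",
            pma=pma,
            ffm_measured=None if ffm == MISSING else ffm,
        )
        subjects.append(
            Subject(
                id=int(sid),
                covariates=cov,
                events=events,
                obs_times=np.asarray(obs_t),
                dv=np.asarray(dv),
                study=str(first["STUDY"]),
            )
        )
    if n_imputed_pma:
        warnings.warn(f"{path}: imputed PMA from age for {n_imputed_pma} subjects", stacklevel=2)
    return PopulationDataset(subjects=subjects)
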