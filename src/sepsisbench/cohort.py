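"""Cohort container and the CSV schemas it round-trips through.

A cohort is five tables:

``admissions``    one row per admission (demographics, stay, disposition)
``observations``  time-stamped vitals/labs (``element``/``value`` long form)
``orders``        time-stamped clinician actions (antimicrobials, blood
                  cultures, vasopressors, mechanical ventilation)
``dx_codes``      ICD-10 codes; negative ``time_min`` = historical (pre-admit)
``truth``         generator ground truth (absent for real extracts)

Event times are integer minutes from admission start; each admission is
taken to begin at midnight of its calendar day 0, so the calendar day of an
event is ``time_min // 1440``. ``admit_min``/``discharge_min`` sit on a
shared absolute axis and are used only for inter-admission spacing
(readmission exclusion); ``discharge_min - admit_min`` is the length of stay.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import SchemaError

SCHEMAS: dict[str, dict[str, str]] = {
    "admissions": {
        "admission_id": "str", "patient_id": "str",
        "admit_min": "int", "discharge_min": "int", "age": "int",
        "sex": "str", "race_ethnicity": "str", "site": "str",
        "service": "str", "source": "str", "disposition": "str",
    },
    "observations": {
        "admission_id": "str", "time_min": "int",
        "element": "str", "value": "float",
    },
    "orders": {
        "admission_id": "str", "time_min": "int",
        "kind": "str", "detail": "str",
    },
    "dx_codes": {
        "admission_id": "str", "code": "str", "time_min": "int",
    },
    "truth": {
        "admission_id": "str", "label": "str", "onset_min": "float",
    },
}

ORDER_KINDS = ("antimicrobial", "blood_culture", "vasopressor", "mech_vent")

LABELS = ("ASE_SEPSIS", "COVID_SEPSIS", "NONSEPSIS")


def empty_table(name: str) -> pd.DataFrame:
    spec = SCHEMAS[name]
    mapping = {"str": "object", "int": "int64", "float": "float64"}
    return pd.DataFrame({c: pd.Series(dtype=mapping[t])
                         for c, t in spec.items()})


@dataclass
class Cohort:
    admissions: pd.DataFrame = field(default_factory=lambda: empty_table("admissions"))
    observations: pd.DataFrame = field(default_factory=lambda: empty_table("observations"))
    orders: pd.DataFrame = field(default_factory=lambda: empty_table("orders"))
    dx_codes: pd.DataFrame = field(default_factory=lambda: empty_table("dx_codes"))
    truth: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        if self.truth is None:
            out.pop("truth")
        return out

    def admission_ids(self) -> list[str]:
        return list(self.admissions["admission_id"])

    def subset(self, admission_ids) -> "Cohort":
        keep = set(admission_ids)

        def _f(df: pd.DataFrame) -> pd.DataFrame:
            return df[df["admission_id"].isin(keep)].reset_index(drop=True)

        return Cohort(
            admissions=_f(self.admissions),
            observations=_f(self.observations),
            orders=_f(self.orders),
            dx_codes=_f(self.dx_codes),
            truth=None if self.truth is None else _f(self.truth),
        )

    def events_for(self, admission_id: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        obs = self.observations[self.observations["admission_id"] == admission_id]
        orders = self.orders[self.orders["admission_id"] == admission_id]
        return (obs.sort_values("time_min", kind="stable").reset_index(drop=True),
                orders.sort_values("time_min", kind="stable").reset_index(drop=True))


def _coerce(df: pd.DataFrame, name: str, path: str) -> pd.DataFrame:
    spec = SCHEMAS[name]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(spec)].copy()
    for col, typ in spec.items():
        if typ == "str":
            df[col] = df[col].astype("object").where(df[col].notna(), "")
            df[col] = df[col].astype(str)
        else:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if name == "truth" and col == "onset_min":
                blank = df[col].astype(str).str.strip().isin(("", "nan"))
                bad &= ~blank
            if bad.any():
                # +2: header row and 1-based numbering
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise SchemaError(
                    f"{path}: line {line}: cannot parse {col!r} value "
                    f"{df[col].iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} as {typ}")
            if typ == "int":
                if coerced.isna().any():
                    line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
                    raise SchemaError(f"{path}: line {line}: missing value in {col!r}")
                df[col] = coerced.astype("int64")
            else:
                df[col] = coerced.astype("float64")
    return df


def write_cohort(cohort: Cohort, directory: str) -> dict[str, str]:
    """Write the cohort tables as UTF-8 CSV files; returns name -> path."""
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for name, df in cohort.tables().items():
        path = os.path.join(directory, f"{name}.csv")
        out = df.copy()
        for col, typ in SCHEMAS[name].items():
            if typ == "float":
                out[col] = out[col].map(
                    lambda v: "" if pd.isna(v) else format(float(v), ".10g"))
        out.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def read_cohort(directory: str) -> Cohort:
    """Read the CSV schemas back; inverse of :func:`write_cohort`."""
    kwargs: dict[str, pd.DataFrame] = {}
    for name in SCHEMAS:
        path = os.path.join(directory, f"{name}.csv")
        if not os.path.exists(path):
            if name == "truth":
                continue
            raise SchemaError(f"missing required file: {path}")
        try:
            raw = pd.read_csv(path, dtype="object", keep_default_na=False,
                              na_values=[""])
        except pd.errors.ParserError as exc:  # malformed row
            raise SchemaError(f"{path}: {exc}") from exc
        kwargs[name] = _coerce(raw, name, path)
    return Cohort(**kwargs)
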