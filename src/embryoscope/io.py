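"""CSV dialects shared by the CLI and the tests.

All files are UTF-8, header required, '.' decimal separator.
"""

from __future__ import annotations

import pandas as pd

from .errors import DomainError
from .respirometry import OxygenTrace

TRACE_COLUMNS = ["vial_id", "time_s", "o2_mg_per_l", "temp_c", "volume_ul",
                 "is_blank", "embryo_id"]
COHORT_COLUMNS = ["embryo_id", "stage", "phase", "egg_ww_mg", "embryo_ww_mg"]
BIOMARKER_COLUMNS = ["sample_id", "tissue", "stage", "analyte", "value",
                     "unit", "protein_mg"]
DILUTION_COLUMNS = ["gene", "log10_input", "rep", "cq"]
CQ_COLUMNS = ["sample_id", "stage", "phase", "gene", "rep", "cq", "is_reference"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DomainError(f"{what} file missing columns: {missing}")


def traces_to_frame(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "vial_id": tr.vial_id,
            "time_s": tr.times,
            "o2_mg_per_l": tr.o2,
            "temp_c": tr.temperature,
            "volume_ul": tr.chamber_volume_l * 1e6,
            "is_blank": tr.is_blank,
            "embryo_id": tr.embryo_id if tr.embryo_id is not None else "",
        }))
    return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]


def frame_to_traces(df: pd.DataFrame) -> list[OxygenTrace]:
    _require(df, TRACE_COLUMNS, "trace")
    traces = []
    for vial_id, sub in df.groupby("vial_id", sort=False):
        sub = sub.sort_values("time_s")
        embryo_id = sub["embryo_id"].iloc[0]
        if pd.isna(embryo_id) or embryo_id == "":
            embryo_id = None
        is_blank = sub["is_blank"].iloc[0]
        if isinstance(is_blank, str):
            is_blank = is_blank.strip().lower() in ("true", "1", "yes")
        traces.append(OxygenTrace(
            vial_id=str(vial_id),
            times=sub["time_s"].to_numpy(float),
            o2=sub["o2_mg_per_l"].to_numpy(float),
            temperature=float(sub["temp_c"].iloc[0]),
            chamber_volume_l=float(sub["volume_ul"].iloc[0]) * 1e-6,
            is_blank=bool(is_blank),
            embryo_id=None if embryo_id is None else str(embryo_id),
        ))
    return traces


def write_traces(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[OxygenTrace]:
    return frame_to_traces(pd.read_csv(path))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    _require(cohort, COHORT_COLUMNS, "cohort")
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, COHORT_COLUMNS, "cohort")
    df["stage"] = df["stage"].astype(int)
    return df


def write_biomarkers(table: pd.DataFrame, path) -> None:
    _require(table, BIOMARKER_COLUMNS, "biomarker")
    table[BIOMARKER_COLUMNS].to_csv(path, index=False)


def read_biomarkers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, BIOMARKER_COLUMNS, "biomarker")
    df["stage"] = df["stage"].astype("Int64")
    return df


def write_dilution(table: pd.DataFrame, path) -> None:
    _require(table, DILUTION_COLUMNS, "dilution")
    table[DILUTION_COLUMNS].to_csv(path, index=False)


def read_dilution(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DILUTION_COLUMNS, "dilution")
    return df


def write_cq(table: pd.DataFrame, path) -> None:
    _require(table, CQ_COLUMNS, "Cq")
    table[CQ_COLUMNS].to_csv(path, index=False)


def read_cq(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, CQ_COLUMNS, "Cq")
    df["stage"] = df["stage"].astype(int)
    return df
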