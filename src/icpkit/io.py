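"""CSV interchange formats.

Trend recordings travel as plain CSV with the fixed header
``time_s,icp_mmhg,map_mmhg,amp_mmhg,valid`` (valid in {0,1}; the amp column
may be entirely empty, in which case the series loads without an AMP
channel). Parsing is strict: a malformed header, non-uniform or
non-monotone time axis, or a non-numeric cell is rejected with the
offending line number. Missing index values are serialised as empty fields,
never as 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .indices import HourlyIndices, PatientIndices, TrendSeries
from .signal_model import PatientRecord

__all__ = [
    "ParseError",
    "TREND_HEADER",
    "COVARIATE_HEADER",
    "write_trend_csv",
    "read_trend_csv",
    "write_covariates_csv",
    "read_covariates_csv",
    "hourly_frame",
    "patient_frame",
    "write_hourly_csv",
    "write_patient_csv",
    "read_patient_csv",
]

TREND_HEADER = "time_s,icp_mmhg,map_mmhg,amp_mmhg,valid"
COVARIATE_HEADER = "patient_id,age,sex,gcs,hematoma_ml,gos,group"

TIME_TOLERANCE_S = 1e-6


class ParseError(ValueError):
    """Malformed input file; the message carries path and line number."""


def write_trend_csv(series: TrendSeries, path) -> None:
    path = Path(path)
    n = len(series)
    t = series.time
    amp = series.amp
    with path.open("w") as fh:
        fh.write(TREND_HEADER + "\n")
        for i in range(n):
            amp_s = "" if amp is None else repr(float(amp[i]))
            fh.write(
                f"{float(t[i])!r},{float(series.icp[i])!r},{float(series.map[i])!r},"
                f"{amp_s},{int(series.valid[i])}\n"
            )


def _numeric_column(raw: pd.Series, path, name: str) -> np.ndarray:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & (raw.astype(str).str.strip() != "")
    empty = raw.astype(str).str.strip() == ""
    problem = bad | empty
    if problem.any():
        line = int(problem.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}:{line}: non-numeric value in column '{name}'")
    # numpy's parser is correctly rounded, so full-precision round-trips hold
    return raw.to_numpy(dtype="U32").astype(np.float64)


def read_trend_csv(path) -> TrendSeries:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    if header != TREND_HEADER:
        raise ParseError(f"{path}:1: expected header '{TREND_HEADER}', got '{header}'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ParseError(f"{path}:2: file contains no samples")
    df = df.reset_index(drop=True)

    t = _numeric_column(df["time_s"], path, "time_s")
    icp = _numeric_column(df["icp_mmhg"], path, "icp_mmhg")
    map_ = _numeric_column(df["map_mmhg"], path, "map_mmhg")

    amp_raw = df["amp_mmhg"].astype(str).str.strip()
    if (amp_raw == "").all():
        amp: Optional[np.ndarray] = None
    elif (amp_raw == "").any():
        line = int((amp_raw == "").idxmax()) + 2
        raise ParseError(
            f"{path}:{line}: amp_mmhg must be either fully populated or fully empty"
        )
    else:
        amp = _numeric_column(df["amp_mmhg"], path, "amp_mmhg")

    valid_raw = df["valid"].astype(str).str.strip()
    bad_valid = ~valid_raw.isin(["0", "1"])
    if bad_valid.any():
        line = int(bad_valid.idxmax()) + 2
        raise ParseError(f"{path}:{line}: 'valid' must be 0 or 1")
    valid = valid_raw.to_numpy() == "1"

    if len(t) > 1:
        dts = np.diff(t)
        if (dts <= 0).any():
            line = int(np.argmax(dts <= 0)) + 3  # offending (second) sample row
            raise ParseError(f"{path}:{line}: time axis is not strictly increasing")
        dt = dts[0]
        off = np.abs(dts - dt) > TIME_TOLERANCE_S
        if off.any():
            line = int(np.argmax(off)) + 3
            raise ParseError(
                f"{path}:{line}: non-uniform sampling (expected interval {dt:g} s)"
            )
    else:
        dt = 1.0
    return TrendSeries(
        sample_interval_s=float(dt), icp=icp, map=map_, amp=amp, valid=valid, t0=float(t[0])
    )


def write_covariates_csv(records: Sequence[PatientRecord], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(COVARIATE_HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.patient_id},{r.age},{r.sex},{r.gcs},{r.hematoma_ml!r},{r.gos},{r.group}\n"
            )


def read_covariates_csv(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    if header != COVARIATE_HEADER:
        raise ParseError(f"{path}:1: expected header '{COVARIATE_HEADER}', got '{header}'")
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str, "group": str})
    return df


def _fmt(v) -> str:
    """Full-precision serialisation; missing values become empty fields."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def hourly_frame(per_patient: dict[str, Sequence[HourlyIndices]]) -> pd.DataFrame:
    rows = []
    for pid, hourly in per_patient.items():
        for h in hourly:
            rows.append(
                {
                    "patient_id": pid,
                    "segment": h.segment_index,
                    "mean_icp": h.mean_icp,
                    "mean_cpp": h.mean_cpp,
                    "prx": h.prx,
                    "rap": h.rap,
                    "dicp": h.dicp,
                    "valid_fraction": h.valid_fraction,
                }
            )
    return pd.DataFrame(rows)


def write_hourly_csv(per_patient: dict[str, Sequence[HourlyIndices]], path) -> None:
    path = Path(path)
    cols = ["patient_id", "segment", "mean_icp", "mean_cpp", "prx", "rap", "dicp", "valid_fraction"]
    with path.open("w") as fh:
        fh.write(",".join(cols) + "\n")
        for pid, hourly in per_patient.items():
            for h in hourly:
                vals = [pid, str(h.segment_index)] + [
                    _fmt(v) for v in (h.mean_icp, h.mean_cpp, h.prx, h.rap, h.dicp, h.valid_fraction)
                ]
                fh.write(",".join(vals) + "\n")


PATIENT_COLUMNS = [
    "patient_id",
    "mean_icp",
    "mean_cpp",
    "mean_prx",
    "mean_rap",
    "total_dicp",
    "n_segments",
]


def patient_frame(per_patient: dict[str, PatientIndices]) -> pd.DataFrame:
    if not per_patient:
        return pd.DataFrame(columns=PATIENT_COLUMNS)
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "mean_icp": pi.mean_icp,
                "mean_cpp": pi.mean_cpp,
                "mean_prx": pi.mean_prx,
                "mean_rap": pi.mean_rap,
                "total_dicp": pi.total_dicp,
                "n_segments": pi.n_segments,
            }
            for pid, pi in per_patient.items()
        ]
    )


PATIENT_HEADER = "patient_id,mean_icp,mean_cpp,mean_prx,mean_rap,total_dicp,n_segments"


def write_patient_csv(per_patient: dict[str, PatientIndices], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(PATIENT_HEADER + "\n")
        for pid, pi in per_patient.items():
            vals = [pid] + [
                _fmt(v)
                for v in (pi.mean_icp, pi.mean_cpp, pi.mean_prx, pi.mean_rap, pi.total_dicp)
            ] + [str(pi.n_segments)]
            fh.write(",".join(vals) + "\n")


def read_patient_csv(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    if header != PATIENT_HEADER:
        raise ParseError(f"{path}:1: expected header '{PATIENT_HEADER}', got '{header}'")
    return pd.read_csv(path, dtype={"patient_id": str})
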