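"""CSV readers/writers for the measurement formats.

All dialects are plain UTF-8 CSV with a header row, decimal points
and ``#``-prefixed comment lines.  Readers validate the required
columns and report malformed rows with their line numbers; writers
round-trip bit-exactly through the matching reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import IrradiationSeries, ReleaseCurve, SurfaceProfile
from .retention import retention_signed

__all__ = [
    "read_release_csv", "write_release_csv",
    "read_irradiation_csv", "write_irradiation_csv",
    "read_profile_csv", "write_profile_csv",
    "read_plate_csv", "read_retention_csv",
    "write_fit_report",
]


class CsvFormatError(ValueError):
    """Malformed input CSV (missing columns or unparseable rows)."""


def _read_table(path, required, numeric) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CsvFormatError(f"{path}: file is empty (no header row)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering (comment lines shift
            # this for hand-audit purposes; the row index is still exact)
            lines = [int(i) + 2 for i in df.index[bad][:5]]
            raise CsvFormatError(
                f"{path}: non-numeric value(s) in column {col!r} near "
                f"line(s) {lines}"
            )
        df[col] = parsed
    return df


def read_release_csv(path) -> ReleaseCurve:
    """Read a release curve from ``time_h,q_pct[,medium,replicate]``."""
    df = _read_table(path, ("time_h", "q_pct"), ("time_h", "q_pct"))
    if df.empty:
        warnings.warn(f"{path}: no data rows, returning an empty curve",
                      stacklevel=2)
        return ReleaseCurve(np.array([]), np.array([]))
    medium = str(df["medium"].iloc[0]) if "medium" in df.columns else ""
    replicate = (int(df["replicate"].iloc[0])
                 if "replicate" in df.columns and df["replicate"].notna().all()
                 else None)
    return ReleaseCurve(df["time_h"].to_numpy(), df["q_pct"].to_numpy(),
                        medium_label=medium, replicate_id=replicate)


def write_release_csv(curve: ReleaseCurve, path) -> None:
    df = pd.DataFrame({"time_h": curve.time_h, "q_pct": curve.q_pct})
    if curve.medium_label:
        df["medium"] = curve.medium_label
    if curve.replicate_id is not None:
        df["replicate"] = curve.replicate_id
    df.to_csv(path, index=False, float_format="%.17g")


def read_irradiation_csv(path) -> IrradiationSeries:
    """Read an irradiation series from ``t_irr_h,q24_pct``."""
    df = _read_table(path, ("t_irr_h", "q24_pct"), ("t_irr_h", "q24_pct"))
    return IrradiationSeries(df["t_irr_h"].to_numpy(),
                             df["q24_pct"].to_numpy())


def write_irradiation_csv(series: IrradiationSeries, path) -> None:
    pd.DataFrame({"t_irr_h": series.t_irr_h,
                  "q24_pct": series.q24_pct}).to_csv(path, index=False,
                                                  float_format="%.17g")


def read_profile_csv(path) -> SurfaceProfile:
    """Read a surface profile from ``x,z``."""
    df = _read_table(path, ("x", "z"), ("x", "z"))
    return SurfaceProfile(df["x"].to_numpy(), df["z"].to_numpy())


def write_profile_csv(profile: SurfaceProfile, path) -> None:
    pd.DataFrame({"x": profile.x, "z": profile.z}).to_csv(
        path, index=False, float_format="%.17g")


def read_plate_csv(path) -> pd.DataFrame:
    """Read MTT plate records ``well_id,group,timepoint_h,a595,a655``."""
    return _read_table(path, ("well_id", "group", "timepoint_h",
                              "a595", "a655"),
                       ("timepoint_h", "a595", "a655"))


def read_retention_csv(path) -> pd.DataFrame:
    """Read retention records ``sample,medium,m0_g,meq_g``.

    Adds the derived signed retention column ``q_signed_pct``.
    """
    df = _read_table(path, ("sample", "medium", "m0_g", "meq_g"),
                     ("m0_g", "meq_g"))
    df["q_signed_pct"] = [retention_signed(m0, meq)
                          for m0, meq in zip(df["m0_g"], df["meq_g"])]
    return df


def write_fit_report(comparisons: dict, path_prefix) -> dict:
    """Write a kinetic-fit report as CSV and JSON.

    ``comparisons`` maps a medium label to a
    :class:`~releasekit.kinetics.ModelComparison`.  The CSV uses the
    long layout ``model,parameter,value,medium`` (one row per fitted
    parameter plus an R² row per model); the JSON mirrors the full
    diagnostics.  Returns the paths written.
    """
    path_prefix = Path(path_prefix)
    rows, blob = [], {}
    for medium, comp in comparisons.items():
        blob[medium] = {
            "fits": [res.to_dict() for res in comp.fits],
            "failures": dict(comp.failures),
        }
        for res in comp.fits:
            for pname, value in res.params.items():
                rows.append({"medium": medium, "model": res.model.name,
                             "parameter": pname, "value": value})
            rows.append({"medium": medium, "model": res.model.name,
                         "parameter": "R2", "value": res.rsquared})
        for name in comp.failures:
            rows.append({"medium": medium, "model": name,
                         "parameter": "error", "value": float("nan")})
    csv_path = path_prefix.with_suffix(".csv")
    json_path = path_prefix.with_suffix(".json")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(blob, indent=2, sort_keys=True))
    return {"csv": csv_path, "json": json_path}
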