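"""Reading and writing the pipeline's file formats.

Melt data travels as long-format CSV (well, temperature, fluorescence, plus
optional identity columns), sample metadata as a sample-sheet CSV
(sample_id, species, sex, age_years, health, marker, well, replicate,
standard_level[, plate_id]), and marker sequences as standard FASTA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .melt import MeltCurve

__all__ = [
    "read_melt_csv",
    "write_melt_csv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_marker_fasta",
    "write_marker_fasta",
    "MELT_COLUMNS",
    "SHEET_COLUMNS",
]

MELT_COLUMNS = ("well", "temperature", "fluorescence")
SHEET_COLUMNS = (
    "sample_id", "species", "sex", "age_years", "health",
    "marker", "well", "replicate", "standard_level",
)


def read_melt_csv(path) -> list[MeltCurve]:
    """Parse a long-format melt CSV (comma or tab) into one curve per well.

    Rows are sorted by temperature within each well, so shuffled exports
    parse to identical curves.  Malformed (non-numeric) rows are reported
    with their 1-based line numbers.
    """
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = set(MELT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing melt columns {sorted(missing)}")
    temp = pd.to_numeric(table["temperature"], errors="coerce")
    fluor = pd.to_numeric(table["fluorescence"], errors="coerce")
    bad = table.index[temp.isna() | fluor.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric temperature/fluorescence at lines {lines}")
    table = table.assign(temperature=temp, fluorescence=fluor)
    curves = []
    for well, group in table.groupby("well", sort=True):
        group = group.sort_values("temperature")
        curves.append(
            MeltCurve(
                sample_id=group["sample_id"].iloc[0] if "sample_id" in group else None,
                marker_id=group["marker"].iloc[0] if "marker" in group else None,
                replicate_index=int(group["replicate"].iloc[0]) if "replicate" in group else 0,
                well_id=str(well),
                plate_id=str(group["plate_id"].iloc[0]) if "plate_id" in group else "plate1",
                temperatures=group["temperature"].to_numpy(),
                fluorescence=group["fluorescence"].to_numpy(),
            )
        )
    return curves


def write_melt_csv(curves: list[MeltCurve], path) -> None:
    """Write curves as instrument-style long CSV (full float precision)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well": c.well_id,
                    "temperature": c.temperatures,
                    "fluorescence": c.fluorescence,
                    "plate_id": c.plate_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_sample_sheet(path) -> pd.DataFrame:
    """Load and validate the sample sheet; standards flagged by standard_level.

    Checks the documented schema: sex in {F, M}, health in {healthy, CKD}
    (both may be blank on standard wells), no duplicate well assignments,
    numeric ages and standard levels.  Errors name the offending rows.
    """
    sheet = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    dup = sheet["well"][sheet["well"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate well assignments {sorted(set(dup))[:10]}")
    std_level = pd.to_numeric(
        sheet["standard_level"].where(sheet["standard_level"] != "", np.nan), errors="coerce"
    )
    bad_std = sheet.index[(sheet["standard_level"] != "") & std_level.isna()]
    if len(bad_std):
        raise ValueError(f"{path}: non-numeric standard_level at rows {list(bad_std[:10])}")
    is_sample = sheet["standard_level"] == ""
    for col, allowed in (("sex", {"F", "M"}), ("health", {"healthy", "CKD"})):
        bad = sheet.index[is_sample & ~sheet[col].isin(allowed)]
        if len(bad):
            vals = sorted(set(sheet.loc[bad, col]))
            raise ValueError(
                f"{path}: invalid {col} value(s) {vals} at rows {list(bad[:10])} "
                f"(allowed: {sorted(allowed)})"
            )
    age = pd.to_numeric(
        sheet["age_years"].where(sheet["age_years"] != "", np.nan), errors="coerce"
    )
    bad_age = sheet.index[is_sample & age.isna()]
    if len(bad_age):
        raise ValueError(f"{path}: missing/non-numeric age_years at rows {list(bad_age[:10])}")
    sheet = sheet.copy()
    sheet["age_years"] = age
    sheet["standard_level"] = std_level
    sheet["replicate"] = pd.to_numeric(sheet["replicate"], errors="coerce").fillna(0).astype(int)
    if "plate_id" not in sheet.columns:
        sheet["plate_id"] = "plate1"
    else:
        sheet["plate_id"] = sheet["plate_id"].where(sheet["plate_id"] != "", "plate1")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False, float_format="%.10g")


def read_marker_fasta(path) -> dict[str, str]:
    """Marker id -> sequence from a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_marker_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
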