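"""CSV input/output for the pipeline's tabular formats.

Canonical dialects (all plain CSV, written/read with pandas):

* feature table: ``sample_id, role, ref, polarity, mz, rt_min, intensity``
* plate (long):  ``plate_id, well, sample_id, conc_ngL, response, replicate``
* spike table:   ``level_ugL, replicate, response``
* kinetics:      ``pH, replicate, time_h, area_reduced, area_oxidized, is_area``
* library:       ``name, formula, polarity, rt_min, ms2`` with MS2 peaks
  encoded as ``mz:relint;mz:relint``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import SpeciesSeries, normalize_to_is
from .nts import Formula, LibraryEntry, adduct_mz
from .types import Feature, FeatureTable, PlateSeries, Polarity, SampleRole

__all__ = [
    "FEATURE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_plate_series",
    "write_plate_series",
    "read_spike_table",
    "write_spike_table",
    "read_kinetics",
    "write_kinetics",
    "read_library",
]

FEATURE_COLUMNS = ["sample_id", "role", "ref", "polarity", "mz", "rt_min", "intensity"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_feature_table(path: str | Path,
                       schema: dict[str, str] | None = None) -> FeatureTable:
    """Read one feature table from CSV.

    ``schema`` optionally maps canonical column names to the file's
    column names.  Rows are validated (positive m/z and intensity,
    non-negative RT); a validation error names the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, FEATURE_COLUMNS, path)
    features: list[Feature] = []
    for i, row in df.iterrows():
        try:
            features.append(
                Feature(
                    mz=float(row["mz"]),
                    rt=float(row["rt_min"]),
                    intensity=float(row["intensity"]),
                    polarity=Polarity(row["polarity"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid feature in row {i}: {exc}") from exc
    if len(df):
        sample_id = str(df["sample_id"].iloc[0])
        role = SampleRole(df["role"].iloc[0])
        ref = float(df["ref"].iloc[0])
    else:
        sample_id, role, ref = str(path), SampleRole.EXTRACT, 1.0
    return FeatureTable(sample_id=sample_id, role=role, ref=ref, features=features)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": table.sample_id,
            "role": table.role.value,
            "ref": table.ref,
            "polarity": [f.polarity.value for f in table.features],
            "mz": [f.mz for f in table.features],
            "rt_min": [f.rt for f in table.features],
            "intensity": [f.intensity for f in table.features],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_plate_series(path: str | Path, conc_col: str = "conc_ngL") -> list[PlateSeries]:
    """Read a long-format plate CSV into one PlateSeries per replicate."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, [conc_col, "response", "replicate"], path)
    out = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values(conc_col)
        out.append(
            PlateSeries(
                concentrations=grp[conc_col].to_numpy(float),
                responses=grp["response"].to_numpy(float),
                replicate_id=str(rep),
            )
        )
    return out


def write_plate_series(series: list[PlateSeries], path: str | Path,
                       plate_id: str = "plate1", conc_col: str = "conc_ngL") -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well": [f"{s.replicate_id}_{i}" for i in range(len(s))],
                    "sample_id": s.replicate_id,
                    conc_col: s.concentrations,
                    "response": s.responses,
                    "replicate": s.replicate_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_spike_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["level_ugL", "replicate", "response"], path)
    return df["level_ugL"].to_numpy(float), df["response"].to_numpy(float)


def write_spike_table(spikes: np.ndarray, responses: np.ndarray,
                      path: str | Path) -> None:
    pd.DataFrame(
        {
            "level_ugL": np.asarray(spikes, float),
            "replicate": np.arange(len(spikes)) + 1,
            "response": np.asarray(responses, float),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_kinetics(path: str | Path) -> list[SpeciesSeries]:
    """Read a kinetics CSV; areas are normalized against is_area on read.

    Returns one series per (pH, replicate) group, sorted by pH then
    replicate.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["pH", "replicate", "time_h", "area_reduced", "area_oxidized", "is_area"], path
    )
    out: list[SpeciesSeries] = []
    for (pH, rep), grp in df.groupby(["pH", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(SpeciesSeries(
            pH=float(pH),
            times=grp["time_h"].to_numpy(float),
            area_reduced=normalize_to_is(
                grp["area_reduced"].to_numpy(float), grp["is_area"].to_numpy(float)
            ),
            area_oxidized=normalize_to_is(
                grp["area_oxidized"].to_numpy(float), grp["is_area"].to_numpy(float)
            ),
            replicate_id=str(rep),
        ))
    return out


def write_kinetics(series: list[SpeciesSeries], path: str | Path,
                   is_area: float = 1.0) -> None:
    frames = []
    for s in sorted(series, key=lambda s: (s.pH, s.replicate_id)):
        frames.append(
            pd.DataFrame(
                {
                    "pH": s.pH,
                    "replicate": s.replicate_id,
                    "time_h": s.times,
                    "area_reduced": s.area_reduced * is_area,
                    "area_oxidized": s.area_oxidized * is_area,
                    "is_area": is_area,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _parse_ms2(encoded: str) -> list[tuple[float, float]]:
    if not isinstance(encoded, str) or not encoded.strip():
        return []
    peaks = []
    for token in encoded.split(";"):
        mz_s, rel_s = token.split(":")
        peaks.append((float(mz_s), float(rel_s)))
    return peaks


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a spectral library CSV into LibraryEntry records."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["name", "formula", "polarity", "rt_min"], path)
    entries = []
    for _, row in df.iterrows():
        formula = Formula.parse(str(row["formula"]))
        pol = Polarity(row["polarity"])
        adduct = "[M+H]+" if pol is Polarity.POSITIVE else "[M-H]-"
        entries.append(
            LibraryEntry(
                name=str(row["name"]),
                formula=formula,
                expected_rt=float(row["rt_min"]),
                ms2_peaks=_parse_ms2(row.get("ms2", "")),
                adduct_mz_by_polarity={pol: adduct_mz(formula, adduct)},
                is_reference=bool(row.get("is_reference", False)),
            )
        )
    return entries
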