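"""File readers/writers and run configuration.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row.  Schemas:

* NFI matrix CSV — columns ``protein,pathway,<sample...>``, one row per
  protein, linear NFI values.
* plate table CSV — columns ``model,drug,dose_uM,time_h,replicate,rfu,
  is_vehicle`` (long format, vehicle rows flagged).
* killing table CSV — columns ``arm,well,pdm_id,fi_total_dead,fi_dead_til,
  fi_viable_pdm``.

Invariants are validated on load and violations reported with row numbers
(1-based, counting the header as row 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cytotox import GRADE_P_CUTS, MODIFIED_Z_CUTOFF, PLATE_COLUMNS
from .killing import KillingRecord
from .rppa import BLANK_NFI, NFIMatrix, RAW_LINEAR
from .signatures import SIGNATURE_MIN_RATIO
from .timecourse import TR_THRESHOLD_FRACTION

KILLING_COLUMNS = [
    "arm", "well", "pdm_id", "fi_total_dead", "fi_dead_til", "fi_viable_pdm",
]


class LoadError(ValueError):
    """A file violates its documented schema or an invariant."""


# ---------------------------------------------------------------- NFI matrix

def write_nfi_csv(m: NFIMatrix, path) -> None:
    out = m.values.copy()
    out.insert(0, "pathway", m.pathway_of)
    out.index.name = "protein"
    out.to_csv(path)


def read_nfi_csv(path, scale_tag: str = RAW_LINEAR) -> NFIMatrix:
    df = pd.read_csv(path)
    for col in ("protein", "pathway"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing required column {col!r}")
    if df["protein"].duplicated().any():
        dupes = df.loc[df["protein"].duplicated(), "protein"].tolist()
        raise LoadError(f"{path}: duplicate protein ids {dupes}")
    df = df.set_index("protein")
    df.index.name = None
    pathway = df.pop("pathway")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).to_numpy().argmax()) + 2
        raise LoadError(f"{path}: non-numeric NFI value at row {row}")
    if scale_tag == RAW_LINEAR and (values.to_numpy() < 0).any():
        row = int((values < 0).any(axis=1).to_numpy().argmax()) + 2
        raise LoadError(f"{path}: negative NFI value at row {row}")
    return NFIMatrix(values, pathway, scale_tag)


# ---------------------------------------------------------------- plate table

def write_plate_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_plate_csv(path, min_replicates: int = 3) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    if (df["rfu"] < 0).any():
        row = int((df["rfu"] < 0).to_numpy().argmax()) + 2
        raise LoadError(f"{path}: negative RFU at row {row}")
    treated = df[~df["is_vehicle"]]
    counts = treated.groupby(["model", "drug", "dose_uM", "time_h"]).size()
    thin = counts[counts < min_replicates]
    if not thin.empty:
        model, drug, dose, time_h = thin.index[0]
        raise LoadError(
            f"{path}: stratum model={model!r} drug={drug!r} dose={dose} "
            f"time={time_h} h has {thin.iloc[0]} replicates; at least "
            f"{min_replicates} are required"
        )
    vehicle_keys = set(
        map(tuple, df.loc[df["is_vehicle"], ["model", "time_h"]].drop_duplicates().values)
    )
    treated_keys = set(map(tuple, treated[["model", "time_h"]].drop_duplicates().values))
    unmatched = sorted(treated_keys - vehicle_keys)
    if unmatched:
        model, time_h = unmatched[0]
        raise LoadError(
            f"{path}: no vehicle stratum for model={model!r} at {time_h} h"
        )
    return df


# ---------------------------------------------------------------- killing table

def write_killing_csv(records: list[KillingRecord], path) -> None:
    pd.DataFrame(
        [dataclasses.astuple(r) for r in records], columns=KILLING_COLUMNS
    ).to_csv(path, index=False, float_format="%.17g")


def read_killing_csv(path) -> list[KillingRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(KILLING_COLUMNS) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        rec = KillingRecord(
            arm=str(row["arm"]),
            well=str(row["well"]),
            pdm_id=str(row["pdm_id"]),
            fi_total_dead=float(row["fi_total_dead"]),
            fi_dead_til=float(row["fi_dead_til"]),
            fi_viable_pdm=float(row["fi_viable_pdm"]),
        )
        try:
            rec.validate()
        except ValueError as exc:
            raise LoadError(f"{path}: row {i + 2}: {exc}") from exc
        records.append(rec)
    return records


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Thresholds default to the assay-standard values: blank level 0.02 NFI,
    signature filter ratio 1.2 (>20% difference), TR threshold 0.5 (50%
    change), outlier cutoff |M| >= 3.5, grade p-cuts 0.05/0.01/0.001.
    """

    out_dir: str = "pdmkit-out"
    seed: int = 0
    drug: str = "carboplatin"
    nfi_csv: str | None = None
    plate_csv: str | None = None
    tr_treated_csv: str | None = None
    tr_vehicle_csv: str | None = None
    killing_csv: str | None = None
    blank_nfi: float = BLANK_NFI
    signature_min_ratio: float = SIGNATURE_MIN_RATIO
    tr_threshold_fraction: float = TR_THRESHOLD_FRACTION
    outlier_z: float = MODIFIED_Z_CUTOFF
    grade_p_cuts: tuple = GRADE_P_CUTS
    final_time_h: float = 72
    hcl_k: int = 3
    hcl_metric: str = "pearson"
    hcl_linkage: str = "average"
    write_figures: bool = True

    def __post_init__(self) -> None:
        for name in ("blank_nfi", "signature_min_ratio", "tr_threshold_fraction",
                     "outlier_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        cuts = tuple(self.grade_p_cuts)
        if list(cuts) != sorted(cuts, reverse=True) or len(set(cuts)) != len(cuts):
            raise ValueError("grade_p_cuts must be strictly decreasing")
        self.grade_p_cuts = cuts

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["grade_p_cuts"] = list(self.grade_p_cuts)
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def write_json(payload: dict, path) -> None:
    """Deterministic JSON dump (sorted keys, trailing newline)."""
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
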