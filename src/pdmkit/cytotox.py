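"""Functional drug-sensitivity grading from plate cytotoxicity assays.

A real-time cytotoxicity assay reads out cell death as relative fluorescence
units (RFU) at 24/48/72 h for each PDM model x drug x dose stratum, with
3-8 replicates plus matched DMSO vehicle controls.  The analysis chain is:

1. flag outlier replicates within each stratum with the Iglewicz-Hoaglin
   modified Z-score (M_i = 0.6745 (x_i - median) / MAD, cutoff |M| >= 3.5);
2. express treatment effects as fold change (FC) of the outlier-cleaned
   treated mean over the outlier-cleaned vehicle mean, separately per time
   point;
3. test each dose-time cell against vehicle (two-way dose x time ANOVA as
   omnibus; Dunnett-style per-cell comparisons vs the matched-time vehicle
   using the ANOVA-pooled residual error, Holm-adjusted within the
   model x drug family);
4. map the minimum adjusted p across doses at the final time point onto an
   ordinal 0-3 sensitivity grade (p > 0.05 / < 0.05 / < 0.01 / < 0.001);
   a model is a responder for the drug iff its grade is >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .stats import holm_adjust

#: Recommended modified Z-score cutoff for flagging outliers.
MODIFIED_Z_CUTOFF = 3.5

#: 1 / (sqrt(2/pi)) — relates the mean absolute deviation of a normal to
#: its standard deviation; used in the MAD=0 fallback.
_MEANAD_SCALE = 1.253314

#: Significance cuts for the ordinal sensitivity grade (grades 1, 2, 3).
GRADE_P_CUTS = (0.05, 0.01, 0.001)

PLATE_COLUMNS = ["model", "drug", "dose_uM", "time_h", "replicate", "rfu", "is_vehicle"]


class PairingError(ValueError):
    """A treated stratum has no matched vehicle stratum."""


class TestingError(ValueError):
    """Replication is insufficient for the requested test."""


class GradingError(ValueError):
    """Required p-values for grading are missing."""


class ZScore(NamedTuple):
    value: float
    mscore: float
    is_outlier: bool


def modified_zscores(x, cutoff: float = MODIFIED_Z_CUTOFF) -> list[ZScore]:
    """Iglewicz-Hoaglin modified Z-scores with outlier flags.

    M_i = 0.6745 (x_i - median) / MAD with MAD the median absolute deviation
    from the median; |M_i| >= ``cutoff`` flags an outlier.  All points are
    scored in a single pass against the cutoff (the test is designed for
    multiple outliers).  When MAD is zero the mean absolute deviation is
    substituted (M_i = (x_i - median) / (1.253314 meanAD)); when that is
    also zero the vector is constant and nothing is flagged.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("modified_zscores requires a 1-D vector of >= 3 values")
    dev = arr - np.median(arr)
    mad = np.median(np.abs(dev))
    if mad > 0:
        m = 0.6745 * dev / mad
    else:
        meanad = np.mean(np.abs(dev))
        m = np.zeros_like(dev) if meanad == 0 else dev / (_MEANAD_SCALE * meanad)
    return [
        ZScore(float(v), float(mi), bool(abs(mi) >= cutoff))
        for v, mi in zip(arr, m)
    ]


@dataclass
class FoldChangeTable:
    """DMSO-normalized fold changes with outlier bookkeeping.

    ``strata`` holds one row per treated stratum with the stratum-level FC
    (mean treated / mean vehicle, both after outlier removal).
    ``replicate_fc`` holds each surviving treated replicate divided by the
    cleaned vehicle stratum mean (preserving replicate error structure for
    testing), and ``vehicle_fc`` the analogous vehicle replicate FCs.
    ``outliers`` lists the removed records with their modified Z-scores.
    """

    strata: pd.DataFrame
    replicate_fc: pd.DataFrame
    vehicle_fc: pd.DataFrame
    outliers: pd.DataFrame


def _clean(values: np.ndarray, cutoff: float) -> tuple[np.ndarray, list]:
    scored = modified_zscores(values, cutoff=cutoff)
    kept = np.array([z.value for z in scored if not z.is_outlier])
    removed = [(z.value, z.mscore) for z in scored if z.is_outlier]
    return kept, removed


def compute_fold_changes(
    table: pd.DataFrame, z_cutoff: float = MODIFIED_Z_CUTOFF
) -> FoldChangeTable:
    """Fold changes to DMSO vehicle, separately for each time point.

    Outlier replicates are flagged within every stratum (treated and vehicle
    independently) and removed before averaging; the replicate-level FCs
    retained for testing keep all replicates.  Raises :class:`PairingError`
    when a treated stratum has no vehicle records at the same model and
    time, and a domain error when a vehicle mean is non-positive.
    """
    missing = set(PLATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    vehicle_means: dict = {}
    veh_rows, out_rows = [], []
    vehicles = table[table["is_vehicle"]]
    for (model, time_h), grp in vehicles.groupby(["model", "time_h"], sort=False):
        kept, removed = _clean(grp["rfu"].to_numpy(), z_cutoff)
        vmean = kept.mean()
        if vmean <= 0:
            raise ValueError(
                f"vehicle mean RFU <= 0 for model {model!r} at {time_h} h"
            )
        vehicle_means[(model, time_h)] = vmean
        for value, mscore in removed:
            out_rows.append((model, "DMSO", 0.0, time_h, value, mscore, True))
        for value in kept:
            veh_rows.append((model, time_h, value / vmean))

    strat_rows, rep_rows = [], []
    treated = table[~table["is_vehicle"]]
    for (model, drug, dose, time_h), grp in treated.groupby(
        ["model", "drug", "dose_uM", "time_h"], sort=False
    ):
        if (model, time_h) not in vehicle_means:
            raise PairingError(
                f"no vehicle stratum for model {model!r} at {time_h} h"
            )
        vmean = vehicle_means[(model, time_h)]
        kept, removed = _clean(grp["rfu"].to_numpy(), z_cutoff)
        for value, mscore in removed:
            out_rows.append((model, drug, dose, time_h, value, mscore, False))
        fc = kept.mean() / vmean
        strat_rows.append((model, drug, dose, time_h, len(kept), fc))
        for value in kept:
            rep_rows.append((model, drug, dose, time_h, value / vmean))

    return FoldChangeTable(
        strata=pd.DataFrame(
            strat_rows, columns=["model", "drug", "dose_uM", "time_h", "n", "fc"]
        ),
        replicate_fc=pd.DataFrame(
            rep_rows, columns=["model", "drug", "dose_uM", "time_h", "fc"]
        ),
        vehicle_fc=pd.DataFrame(veh_rows, columns=["model", "time_h", "fc"]),
        outliers=pd.DataFrame(
            out_rows,
            columns=["model", "drug", "dose_uM", "time_h", "rfu", "mscore", "is_vehicle"],
        ),
    )


@dataclass
class TreatmentTestResult:
    """Per-cell adjusted p-values with the two-way ANOVA omnibus table."""

    model: str
    drug: str
    cells: pd.DataFrame  # dose_uM, time_h, n, mean_fc, p_raw, p_adj
    anova: pd.DataFrame


def test_treatment_effects(
    fct: FoldChangeTable, model: str, drug: str
) -> TreatmentTestResult:
    """Two-way ANOVA with Dunnett-style per-cell comparisons against vehicle.

    Fits a dose x time ANOVA on treated replicate-level FCs as the omnibus.
    Each dose-time cell is then compared against the matched-time vehicle
    replicate FCs with a t statistic whose error term is the residual mean
    square pooled over every cell (treated and vehicle), as in a classical
    Dunnett comparison against a control; Holm adjusts across all cells of
    the model x drug family.
    """
    rep = fct.replicate_fc.query("model == @model and drug == @drug")
    veh = fct.vehicle_fc.query("model == @model")
    if rep.empty:
        raise TestingError(f"no replicate FCs for model {model!r}, drug {drug!r}")
    if rep["dose_uM"].nunique() < 2 or rep["time_h"].nunique() < 2:
        raise TestingError(
            f"two-way ANOVA needs >= 2 doses and >= 2 time points "
            f"(model {model!r}, drug {drug!r})"
        )
    counts = rep.groupby(["dose_uM", "time_h"]).size()
    thin = counts[counts < 2]
    if not thin.empty:
        dose, time_h = thin.index[0]
        raise TestingError(
            f"insufficient replication at dose {dose}, time {time_h} h "
            f"(model {model!r}, drug {drug!r})"
        )

    fit = smf.ols("fc ~ C(dose_uM) * C(time_h)", data=rep).fit()
    anova = sm.stats.anova_lm(fit, typ=2)

    # residual mean square pooled over all treated cells and vehicle strata
    groups = [grp["fc"].to_numpy() for _, grp in
              rep.groupby(["dose_uM", "time_h"], sort=True)]
    groups += [grp["fc"].to_numpy() for _, grp in veh.groupby("time_h", sort=True)]
    ss_res = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_res = sum(len(g) - 1 for g in groups)
    if df_res <= 0:
        raise TestingError(
            f"no residual degrees of freedom (model {model!r}, drug {drug!r})"
        )
    mse = ss_res / df_res

    rows = []
    for (dose, time_h), grp in rep.groupby(["dose_uM", "time_h"], sort=True):
        control = veh.loc[veh["time_h"] == time_h, "fc"].to_numpy()
        se = np.sqrt(mse * (1.0 / len(grp) + 1.0 / len(control)))
        tstat = (grp["fc"].mean() - control.mean()) / se
        p = 2.0 * sps.t.sf(abs(tstat), df_res)
        rows.append((dose, time_h, len(grp), grp["fc"].mean(), float(p)))
    cells = pd.DataFrame(rows, columns=["dose_uM", "time_h", "n", "mean_fc", "p_raw"])
    cells["p_adj"] = holm_adjust(cells["p_raw"])
    return TreatmentTestResult(model, drug, cells, anova)


@dataclass
class SensitivityGrade:
    """Ordinal 0-3 drug-sensitivity grade for one model x drug."""

    model: str
    drug: str
    grade: int
    responder: bool
    p_min: float
    cells: pd.DataFrame = field(repr=False, default=None)


def map_p_to_grade(p: float, p_cuts: tuple = GRADE_P_CUTS) -> int:
    """Map a p-value to the ordinal grade: >0.05 -> 0, <0.05/<0.01/<0.001 -> 1/2/3."""
    grade = 0
    for cut in sorted(p_cuts, reverse=True):
        if p < cut:
            grade += 1
    return grade


def grade_sensitivity(
    result: TreatmentTestResult,
    final_time: float = 72,
    p_cuts: tuple = GRADE_P_CUTS,
) -> SensitivityGrade:
    """Grade a model's sensitivity to a drug from its per-cell p-values.

    The grade is the significance level of the minimum Holm-adjusted p
    across doses at the final (72 h) time point: models responding only at
    higher dose still count as responders.
    """
    final = result.cells[result.cells["time_h"] == final_time]
    if final.empty:
        raise GradingError(
            f"no adjusted p-values at {final_time} h for model "
            f"{result.model!r}, drug {result.drug!r}"
        )
    p_min = float(final["p_adj"].min())
    grade = map_p_to_grade(p_min, p_cuts)
    return SensitivityGrade(
        model=result.model,
        drug=result.drug,
        grade=grade,
        responder=grade >= 1,
        p_min=p_min,
        cells=result.cells,
    )


def grade_all(
    table: pd.DataFrame,
    drug: str,
    z_cutoff: float = MODIFIED_Z_CUTOFF,
    final_time: float = 72,
    p_cuts: tuple = GRADE_P_CUTS,
) -> tuple[list[SensitivityGrade], FoldChangeTable]:
    """Convenience chain: fold changes, tests and grades for every model."""
    fct = compute_fold_changes(table, z_cutoff=z_cutoff)
    grades = []
    for model in fct.replicate_fc["model"].unique():
        result = test_treatment_effects(fct, model, drug)
        grades.append(grade_sensitivity(result, final_time=final_time, p_cuts=p_cuts))
    return grades, fct
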