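"""Drug mode-of-action time-course analysis of treated/vehicle NFI ratios.

On- and off-target pathway effects of a compound are read out by treating a
PDM model at one concentration and profiling proteins at three treatment
times — immediate (0.5 h), early (4 h) and late (72 h) — against matched
DMSO vehicle controls.  The readout per protein and time is the
treated-to-vehicle NFI ratio TR = log2(treated / vehicle).

A treatment-specific change threshold focuses the analysis on the strongest
effects (for carboplatin: a minimum 50% difference, i.e. linear ratio >= 1.5
or <= 1/1.5 at at least one time point).  Retained proteins are grouped by
pathway panel and their trajectories tested with two-sided Wilcoxon
signed-rank tests: paired by protein between each pair of time points, and
one-sample against zero (i.e. against vehicle) at each time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rppa import NFIMatrix, PATHWAY_PANELS, RAW_LINEAR

#: Default treatment-specific change threshold (carboplatin: 50%).
TR_THRESHOLD_FRACTION = 0.5


@dataclass
class TRProfile:
    """Protein x time matrix of log2 treated/vehicle NFI ratios."""

    values: pd.DataFrame  # index proteins, columns times (h)
    pathway_of: pd.Series
    drug: str = ""
    model: str = ""
    threshold_fraction: float = TR_THRESHOLD_FRACTION

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("TR profile contains non-finite values")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        self.pathway_of = (
            pd.Series(self.pathway_of, dtype=object)
            .reindex(self.values.index)
            .fillna("unassigned")
        )

    @property
    def times(self) -> list:
        return list(self.values.columns)


@dataclass
class TimecoursePathwayResult:
    pathway: str
    n_proteins: int
    pairwise: pd.DataFrame  # time_a, time_b, p_value (paired by protein)
    vs_control: pd.DataFrame  # time, p_value (TR vs 0)


def average_technical_replicates(matrices: list[NFIMatrix]) -> NFIMatrix:
    """Average technical replicate matrices on the log2 scale.

    Returns the geometric mean of the linear NFI values, the appropriate
    summary before ratio computation.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    stack = []
    for m in matrices:
        if m.scale_tag != RAW_LINEAR:
            raise ValueError("technical replicates must be raw linear NFI")
        if list(m.values.index) != list(first.values.index) or list(
            m.values.columns
        ) != list(first.values.columns):
            raise ValueError("technical replicates must share proteins and samples")
        stack.append(np.log2(m.values.to_numpy(dtype=float)))
    mean_log2 = np.mean(stack, axis=0)
    values = pd.DataFrame(
        np.power(2.0, mean_log2), index=first.values.index, columns=first.values.columns
    )
    return NFIMatrix(values, first.pathway_of, RAW_LINEAR)


def compute_tr(
    treated: NFIMatrix,
    vehicle: NFIMatrix,
    drug: str = "",
    model: str = "",
    threshold_fraction: float = TR_THRESHOLD_FRACTION,
) -> TRProfile:
    """Element-wise log2 treated/vehicle NFI ratio per time point.

    Treated and vehicle matrices must be raw linear, strictly positive, and
    share protein ids and time columns.
    """
    for name, m in (("treated", treated), ("vehicle", vehicle)):
        if m.scale_tag != RAW_LINEAR:
            raise ValueError(f"{name} matrix must be raw linear NFI")
        if (m.values.to_numpy(dtype=float) <= 0).any():
            raise ValueError(f"{name} matrix contains non-positive NFI values")
    if list(treated.values.index) != list(vehicle.values.index):
        raise ValueError("treated and vehicle matrices have mismatched proteins")
    if list(treated.values.columns) != list(vehicle.values.columns):
        raise ValueError("treated and vehicle matrices have mismatched time points")
    tr = np.log2(treated.values / vehicle.values)
    return TRProfile(
        tr, treated.pathway_of, drug=drug, model=model,
        threshold_fraction=threshold_fraction,
    )


def threshold_tr(
    profile: TRProfile, threshold_fraction: float | None = None
) -> tuple[TRProfile, pd.DataFrame]:
    """Apply the treatment-specific change threshold.

    A protein is retained (with its full trajectory) iff at at least one
    time point its linear ratio differs from 1 by at least the threshold
    fraction in either direction: |log2 TR| >= log2(1 + fraction), boundary
    inclusive.  Returns the filtered profile and a per-protein report.
    """
    fraction = (
        profile.threshold_fraction if threshold_fraction is None else threshold_fraction
    )
    if not 0 < fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    cut = np.log2(1.0 + fraction)
    max_abs = profile.values.abs().max(axis=1)
    retained = max_abs >= cut - 1e-12
    report = pd.DataFrame(
        {"max_abs_log2_tr": max_abs, "threshold_log2": cut, "retained": retained}
    )
    report.index.name = "protein"
    filtered = TRProfile(
        profile.values.loc[retained],
        profile.pathway_of.loc[retained],
        drug=profile.drug,
        model=profile.model,
        threshold_fraction=fraction,
    )
    return filtered, report


def _wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; degenerate all-zero input gives 1."""
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    return float(sps.wilcoxon(nonzero, alternative="two-sided", method="auto").pvalue)


def test_timecourse(
    profile: TRProfile,
    panels: tuple = PATHWAY_PANELS,
    min_proteins: int = 2,
) -> list[TimecoursePathwayResult]:
    """Pathway-level trajectory tests on a (thresholded) TR profile.

    Per panel: (a) Wilcoxon signed-rank paired by protein between every
    pair of time points; (b) one-sample Wilcoxon of TR against zero (vs
    vehicle) at each time point.  Panels with fewer than ``min_proteins``
    retained members are skipped with a warning.
    """
    results = []
    for panel in panels:
        members = profile.pathway_of.index[profile.pathway_of == panel]
        if len(members) < min_proteins:
            warnings.warn(
                f"pathway panel {panel!r} has {len(members)} retained proteins "
                f"(< {min_proteins}); skipped"
            )
            continue
        sub = profile.values.loc[members]
        pair_rows = [
            (ta, tb, _wilcoxon_p((sub[tb] - sub[ta]).to_numpy(dtype=float)))
            for ta, tb in combinations(profile.times, 2)
        ]
        ctrl_rows = [
            (t, _wilcoxon_p(sub[t].to_numpy(dtype=float))) for t in profile.times
        ]
        results.append(
            TimecoursePathwayResult(
                pathway=panel,
                n_proteins=len(members),
                pairwise=pd.DataFrame(pair_rows, columns=["time_a", "time_b", "p_value"]),
                vs_control=pd.DataFrame(ctrl_rows, columns=["time", "p_value"]),
            )
        )
    return results
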