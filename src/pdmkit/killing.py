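"""TIL-mediated PDM killing quantification from image-mask fluorescence sums.

An endpoint co-culture killing assay images z-stacks of microtumors (PDM)
co-cultured with autologous tumor-infiltrating lymphocytes (TILs).  Three
masks are segmented per imaged PDM — all dead cells, dead TILs, and viable
PDM — and the total fluorescence intensity (FI) summed over each mask.  The
killing readout per PDM is the dead:viable ratio

    R = (FI_total_dead - FI_dead_TIL) / FI_viable_PDM

i.e. dead PDM cell signal relative to viable PDM signal, rendered as a
percentage.  Treatment arms (untreated, isotype control, checkpoint
inhibitors) are summarized per arm and compared pairwise with a two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


class InvariantError(ValueError):
    """A killing record violates a mask-sum invariant."""


@dataclass(frozen=True)
class KillingRecord:
    """Mask-level fluorescence sums for one imaged PDM."""

    arm: str
    well: str
    pdm_id: str
    fi_total_dead: float
    fi_dead_til: float
    fi_viable_pdm: float

    def validate(self) -> None:
        if self.fi_total_dead < 0 or self.fi_dead_til < 0:
            raise InvariantError(
                f"{self.pdm_id}: mask fluorescence sums must be non-negative"
            )
        if self.fi_viable_pdm <= 0:
            raise InvariantError(
                f"{self.pdm_id}: viable-PDM fluorescence sum must be positive"
            )
        if self.fi_dead_til > self.fi_total_dead:
            raise InvariantError(
                f"{self.pdm_id}: dead-TIL sum {self.fi_dead_til} exceeds "
                f"total-dead sum {self.fi_total_dead}"
            )


@dataclass
class KillingResult:
    """Per-arm summary and pairwise comparisons of dead:viable PDM ratios."""

    ratios: pd.DataFrame  # per record: arm, well, pdm_id, ratio, percent
    per_arm: pd.DataFrame  # arm, n, mean_ratio, sd_ratio, mean_percent
    comparisons: pd.DataFrame  # arm_a, arm_b, u_stat, p_value


@dataclass(frozen=True)
class ViabilityMeasure:
    """Dead/viable cell volumes with the derived dead-cell fraction."""

    dead_volume: float
    viable_volume: float
    dead_fraction: float
    qc_flagged: bool


def killing_ratio(record: KillingRecord) -> float:
    """Dead:viable PDM ratio for one imaged PDM, as a fraction.

    Multiply by 100 for the percent rendering used in reports.
    """
    record.validate()
    return (record.fi_total_dead - record.fi_dead_til) / record.fi_viable_pdm


def summarize_arms(records: list[KillingRecord], min_n: int = 3) -> KillingResult:
    """Summarize treatment arms and compare them pairwise.

    Arms with fewer than ``min_n`` imaged PDM are excluded with a warning.
    Pairwise comparisons use the two-sided Mann-Whitney U test (exact where
    sample sizes permit and no ties are present).
    """
    rows = [
        (r.arm, r.well, r.pdm_id, killing_ratio(r)) for r in records
    ]
    ratios = pd.DataFrame(rows, columns=["arm", "well", "pdm_id", "ratio"])
    ratios["percent"] = 100.0 * ratios["ratio"]

    kept_arms = []
    for arm, grp in ratios.groupby("arm", sort=False):
        if len(grp) < min_n:
            warnings.warn(f"arm {arm!r} has only {len(grp)} records; excluded")
        else:
            kept_arms.append(arm)
    if len(kept_arms) < 2:
        raise ValueError("arm comparison requires at least 2 arms with enough records")
    ratios = ratios[ratios["arm"].isin(kept_arms)].reset_index(drop=True)

    summary = (
        ratios.groupby("arm", sort=False)["ratio"]
        .agg(n="size", mean_ratio="mean", sd_ratio="std")
        .reset_index()
    )
    summary["mean_percent"] = 100.0 * summary["mean_ratio"]

    comps = []
    for arm_a, arm_b in combinations(kept_arms, 2):
        x = ratios.loc[ratios["arm"] == arm_a, "ratio"]
        y = ratios.loc[ratios["arm"] == arm_b, "ratio"]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        comps.append((arm_a, arm_b, float(res.statistic), float(res.pvalue)))
    comparisons = pd.DataFrame(comps, columns=["arm_a", "arm_b", "u_stat", "p_value"])
    return KillingResult(ratios, summary, comparisons)


def viability_fraction(
    dead_volume: float, viable_volume: float, qc_threshold: float = 0.07
) -> ViabilityMeasure:
    """Dead-cell fraction of the total PDM cell mass from 3D volumes.

    Robustly viable PDM preparations show at most ~7% dead cell mass, the
    default QC threshold; fractions above it are flagged.
    """
    if dead_volume < 0 or viable_volume < 0:
        raise ValueError("cell volumes must be non-negative")
    total = dead_volume + viable_volume
    if total == 0:
        raise ValueError("dead and viable volumes are both zero; fraction undefined")
    fraction = dead_volume / total
    return ViabilityMeasure(
        dead_volume, viable_volume, fraction, qc_flagged=fraction > qc_threshold
    )
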