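"""Responder vs non-responder protein signatures.

Given sensitivity grades for a drug of interest, PDM models are split into
responders (grade >= 1) and non-responders.  Per protein, group means of
the centered log2 NFI values are compared: only proteins with a >20%
difference between the (geometric, i.e. linear-scale) group means enter the
signature.  Signature proteins are sorted by pathway panel and the pooled
per-protein-per-sample values compared between groups with an unpaired
two-sided Mann-Whitney U test.  Individual protein abundances can also be
correlated with the ordinal 0-3 grade by Spearman rank correlation, with an
exact permutation p-value at the small cohort sizes typical of PDM studies.

Note that p-values computed on proteins pre-selected by the 20% filter are
descriptive: the selection conditions on large group differences, and the
pooling of protein x sample values within a panel pseudo-replicates samples.
Calibration holds for the unfiltered test (``min_ratio=1``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cytotox import SensitivityGrade
from .rppa import CENTERED_LOG2, NFIMatrix, PATHWAY_PANELS
from .stats import spearman_with_p

#: Minimum linear-scale ratio between group means for the signature filter
#: (a >20% difference between the means).
SIGNATURE_MIN_RATIO = 1.2


class AnalysisError(ValueError):
    """The requested analysis is undefined for the given grouping."""


@dataclass
class GroupSplit:
    """Responder / non-responder sample ids for one drug."""

    responders: tuple
    non_responders: tuple
    drug: str = ""

    def __post_init__(self) -> None:
        self.responders = tuple(self.responders)
        self.non_responders = tuple(self.non_responders)
        if set(self.responders) & set(self.non_responders):
            raise AnalysisError("responder and non-responder groups overlap")
        if not self.responders or not self.non_responders:
            raise AnalysisError(
                "both responder and non-responder groups must be non-empty; "
                "a signature is undefined otherwise"
            )


@dataclass
class PathwayTestResult:
    pathway: str
    n_proteins: int
    responder_values: np.ndarray
    nonresponder_values: np.ndarray
    u_stat: float
    p_value: float


@dataclass
class SensitivityCorrelation:
    protein: str
    r: float
    p_value: float
    n: int
    method: str
    undefined: bool = False


def split_groups(grades: list[SensitivityGrade], m: NFIMatrix) -> GroupSplit:
    """Split the matrix samples by responder call (grade >= 1)."""
    by_model = {g.model: g for g in grades}
    missing = [s for s in m.sample_ids if s not in by_model]
    if missing:
        raise AnalysisError(f"no sensitivity grade for samples: {missing}")
    drug = grades[0].drug if grades else ""
    resp = [s for s in m.sample_ids if by_model[s].responder]
    nonresp = [s for s in m.sample_ids if not by_model[s].responder]
    return GroupSplit(resp, nonresp, drug=drug)


def filter_20pct(
    m: NFIMatrix, split: GroupSplit, min_ratio: float = SIGNATURE_MIN_RATIO
) -> pd.DataFrame:
    """Per-protein signature table with the >20% mean-difference filter.

    Group means are computed on the log2 scale and back-transformed, so the
    linear-scale ratio compared against ``min_ratio`` is a ratio of
    geometric means (NFI is a relative-abundance measure; a percentage on
    centered log2 values near zero would be ill-defined).  The boundary is
    inclusive.  Columns: mean_responder, mean_nonresponder (log2),
    linear_ratio, passes, direction (up/down in responders).
    """
    if m.scale_tag != CENTERED_LOG2:
        raise ValueError("signature filter expects a centered log2 matrix")
    mr = m.values[list(split.responders)].mean(axis=1)
    mn = m.values[list(split.non_responders)].mean(axis=1)
    diff = mr - mn
    ratio = np.power(2.0, diff.abs())
    table = pd.DataFrame(
        {
            "pathway": m.pathway_of,
            "mean_responder": mr,
            "mean_nonresponder": mn,
            "linear_ratio": ratio,
            "passes": ratio >= min_ratio - 1e-12,
            "direction": np.where(diff > 0, "up", np.where(diff < 0, "down", "none")),
        }
    )
    table.index.name = "protein"
    return table


def test_pathways(
    signature: pd.DataFrame,
    m: NFIMatrix,
    split: GroupSplit,
    panels: tuple = PATHWAY_PANELS,
    passing_only: bool = True,
) -> list[PathwayTestResult]:
    """Mann-Whitney U per pathway panel on pooled protein x sample values.

    For each panel, the centered log2 values of its (signature-passing)
    member proteins are pooled across responder samples and compared with
    the pooled non-responder values by a two-sided Mann-Whitney U test
    (exact where sample sizes permit and there are no ties).  Panels without
    eligible proteins are skipped with a warning.
    """
    eligible = signature.index[signature["passes"]] if passing_only else signature.index
    results = []
    for panel in panels:
        members = [p for p in eligible if m.pathway_of.get(p) == panel]
        if not members:
            warnings.warn(f"pathway panel {panel!r} has no eligible proteins; skipped")
            continue
        pooled_r = m.values.loc[members, list(split.responders)].to_numpy().ravel()
        pooled_n = m.values.loc[members, list(split.non_responders)].to_numpy().ravel()
        res = sps.mannwhitneyu(pooled_r, pooled_n, alternative="two-sided", method="auto")
        results.append(
            PathwayTestResult(
                pathway=panel,
                n_proteins=len(members),
                responder_values=pooled_r,
                nonresponder_values=pooled_n,
                u_stat=float(res.statistic),
                p_value=float(res.pvalue),
            )
        )
    return results


def correlate_with_grade(
    m: NFIMatrix,
    grades: list[SensitivityGrade],
    protein: str,
    exact_max_n: int = 8,
) -> SensitivityCorrelation:
    """Spearman correlation of one protein's abundance with the 0-3 grade.

    Uses average-rank tie handling; the two-sided p-value is an exact
    permutation enumeration for n <= ``exact_max_n`` models and the usual
    t-approximation beyond.  Zero variance in either vector is flagged as
    an undefined correlation rather than silently reported as 0.
    """
    by_model = {g.model: g.grade for g in grades}
    samples = [s for s in m.sample_ids if s in by_model]
    if len(samples) < 4:
        raise AnalysisError("grade correlation requires >= 4 graded models")
    if protein not in m.values.index:
        raise KeyError(f"unknown protein {protein!r}")
    values = m.values.loc[protein, samples].to_numpy(dtype=float)
    grade_vec = np.array([by_model[s] for s in samples], dtype=float)
    if np.ptp(values) == 0 or np.ptp(grade_vec) == 0:
        return SensitivityCorrelation(
            protein, float("nan"), float("nan"), len(samples), "undefined", True
        )
    r, p, method = spearman_with_p(values, grade_vec, exact_max_n=exact_max_n)
    return SensitivityCorrelation(protein, r, p, len(samples), method, False)
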