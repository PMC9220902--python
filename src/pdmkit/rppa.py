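"""Core RPPA (reverse-phase protein array) matrix processing.

The abundance readout of an RPPA experiment is the protein-normalized,
background-corrected mean fluorescence intensity (NFI), a dimensionless
linear ratio measured per protein per sample.  Analysis happens on the
relative-abundance scale: each protein row is divided by its median across
all measured samples and log2-transformed, so a value of +1 means twofold
above the cohort-median abundance of that protein.

This module provides the quality filter against blank-level signals, the
median-centering/log2 transform, agglomerative sample clustering, and the
aggregation of proteins into signaling-pathway panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

RAW_LINEAR = "raw_linear"
CENTERED_LOG2 = "centered_log2"

#: The eight signaling-pathway panels used to sort proteins.
PATHWAY_PANELS = (
    "cell cycle",
    "DNA damage response",
    "apoptosis",
    "chromatin regulation",
    "MAPK/RTK",
    "PI3K/AKT-mTOR-Wnt-NFkB",
    "tumor/stem cell markers",
    "other",
)

UNASSIGNED = "unassigned"

#: Default blank assay level on the linear NFI scale.
BLANK_NFI = 0.02


class EmptyMatrixError(ValueError):
    """All proteins were removed by a filter."""


class DomainError(ValueError):
    """A value lies outside the domain an operation requires."""


@dataclass
class NFIMatrix:
    """Proteins x samples relative-abundance matrix with pathway annotation.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample.  On the
        ``raw_linear`` scale values are non-negative NFI ratios; on the
        ``centered_log2`` scale they are finite log2 relative abundances.
    pathway_of
        Series mapping protein id to one of :data:`PATHWAY_PANELS` (or
        ``"unassigned"``).  Missing proteins are filled with unassigned.
    scale_tag
        Either ``"raw_linear"`` or ``"centered_log2"``.
    """

    values: pd.DataFrame
    pathway_of: pd.Series
    scale_tag: str = RAW_LINEAR

    def __post_init__(self) -> None:
        if self.scale_tag not in (RAW_LINEAR, CENTERED_LOG2):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("NFI matrix contains non-finite values")
        if self.scale_tag == RAW_LINEAR and (vals < 0).any():
            raise ValueError("raw linear NFI values must be non-negative")
        self.pathway_of = (
            pd.Series(self.pathway_of, dtype=object)
            .reindex(self.values.index)
            .fillna(UNASSIGNED)
        )

    @property
    def protein_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples.

    ``linkage`` is a SciPy linkage matrix with ``n_samples - 1`` merges;
    ``order`` is the dendrogram leaf order; ``labels`` maps each sample id
    to its flat cluster (1..k) at the requested partition size.
    """

    linkage: np.ndarray
    sample_ids: list
    order: list
    labels: pd.Series
    k: int
    metric: str = "pearson"
    method: str = "average"

    def partition(self) -> dict:
        """Clusters as a mapping label -> sorted list of sample ids."""
        out: dict = {}
        for sample, lab in self.labels.items():
            out.setdefault(int(lab), []).append(sample)
        return {lab: sorted(members) for lab, members in sorted(out.items())}


def apply_blank_filter(
    m: NFIMatrix, blank: float = BLANK_NFI
) -> tuple[NFIMatrix, list]:
    """Drop proteins whose median NFI is at or below blank assay level.

    Small NFI signals around the blank level of the assay (0.02 NFI) are a
    limiting quality criterion: such proteins are excluded wholesale so that
    downstream analyses operate on complete rows.  Retained values are passed
    through unchanged.

    Returns the filtered matrix and the list of excluded protein ids.
    """
    if m.scale_tag != RAW_LINEAR:
        raise ValueError("blank filter applies to raw linear NFI matrices")
    medians = m.values.median(axis=1)
    excluded = list(m.values.index[medians <= blank])
    kept = m.values.drop(index=excluded)
    if kept.empty:
        raise EmptyMatrixError(
            f"all {m.n_proteins} proteins fall at or below blank level {blank}"
        )
    return NFIMatrix(kept, m.pathway_of.loc[kept.index], RAW_LINEAR), excluded


def center_log2(m: NFIMatrix) -> NFIMatrix:
    """Median-center each protein across all samples and log2-transform.

    Centering is performed on the log2 scale (each row's log2 median is
    subtracted, i.e. each value is divided by the row's geometric median),
    which guarantees every output row has median exactly 0 regardless of
    whether the sample count is odd or even.  For odd sample counts this
    coincides with dividing by the linear-scale row median before log2.
    """
    if m.scale_tag != RAW_LINEAR:
        raise ValueError("center_log2 expects a raw linear NFI matrix")
    vals = m.values
    nonpos = vals <= 0
    if nonpos.to_numpy().any():
        stacked = nonpos.stack()
        protein, sample = stacked[stacked].index[0]
        raise DomainError(
            f"non-positive NFI for protein {protein!r}, sample {sample!r}; "
            "apply the blank filter first"
        )
    log2_vals = np.log2(vals)
    centered = log2_vals.sub(log2_vals.median(axis=1), axis=0)
    return NFIMatrix(centered, m.pathway_of, CENTERED_LOG2)


def _sample_distance(m: NFIMatrix, metric: str) -> np.ndarray:
    X = m.values.to_numpy(dtype=float).T  # samples x proteins
    if metric == "pearson":
        r = np.corrcoef(X)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
        return squareform(d, checks=False)
    return pdist(X, metric=metric)


def hcl_cluster(
    m: NFIMatrix, k: int, metric: str = "pearson", method: str = "average"
) -> ClusterResult:
    """Hierarchical (HCL) clustering of samples on the centered log2 matrix.

    Samples are grouped by similarity of their relative protein signal
    intensities using Pearson-correlation distance (1 - r) and average
    linkage by default; both are configurable.  Returns the merge tree,
    dendrogram leaf order and the flat partition at ``k`` clusters.
    """
    n = m.n_samples
    if n < 2:
        raise ValueError("clustering requires at least 2 samples")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}] for {n} samples")
    condensed = _sample_distance(m, metric)
    Z = hierarchy.linkage(condensed, method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = [m.sample_ids[i] for i in hierarchy.leaves_list(Z)]
    labels = pd.Series(flat, index=m.sample_ids, name="cluster")
    return ClusterResult(Z, m.sample_ids, order, labels, k, metric, method)


def pathway_summarize(
    m: NFIMatrix, panels: tuple = PATHWAY_PANELS
) -> tuple[pd.DataFrame, dict]:
    """Aggregate proteins into pathway panels.

    For each panel and sample, returns the median log2 NFI of the member
    proteins, together with the full member-value sub-matrices (those value
    sets feed rank-based group tests downstream).  Panels without member
    proteins are skipped with a warning.
    """
    medians: dict = {}
    value_sets: dict = {}
    for panel in panels:
        members = m.pathway_of.index[m.pathway_of == panel]
        if len(members) == 0:
            warnings.warn(f"pathway panel {panel!r} has no member proteins; skipped")
            continue
        sub = m.values.loc[members]
        value_sets[panel] = sub
        medians[panel] = sub.median(axis=0)
    table = pd.DataFrame(medians).T
    table.index.name = "pathway"
    return table, value_sets
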