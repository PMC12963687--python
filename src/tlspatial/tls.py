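"""TLS region calling, maturity classification, and the IHC composite score.

A spot belongs to a TLS region iff its TLS signature score is high (strictly
above a quantile threshold) AND it is a hotspot; contiguous qualifying spots
(connected through the spatial KNN graph) are merged into numbered regions.

Regions are classified as mature when every evaluated criterion holds:
(1) mean expression of the canonical TLS cytokine panel (CXCL9, CXCL13,
TNFSF13, RORA) and of the germinal-center panel (AICDA, CD38, IGHG1 — IgG
operationalized as IGHG1) both exceed the cohort reference medians;
(2) germinal-center-like B cells / plasmablasts are present; and
(3, optional) histology confirms organized T/B zones — evaluated only when
the flag is provided. Otherwise the region is immature.

The IHC composite score is the product of a 0-4 proportion score
(0 = none; 1 = 1-25%; 2 = 26-50%; 3 = 51-75%; 4 = 76-100%) and a 0-3
staining intensity score (negative/weak/moderate/strong).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .data import SpatialDataset
from .hotspot import HotspotResult, NeighborGraph
from .scoring import ScoreVector

__all__ = [
    "CYTOKINE_PANEL",
    "GC_PANEL",
    "RegionFeatures",
    "MaturityCall",
    "PanelReference",
    "IhcScore",
    "call_tls_regions",
    "region_features",
    "panel_reference",
    "classify_maturity",
    "ihc_proportion_score",
    "ihc_intensity_score",
    "ihc_final_score",
]

CYTOKINE_PANEL = ("CXCL9", "CXCL13", "TNFSF13", "RORA")
GC_PANEL = ("AICDA", "CD38", "IGHG1")

INTENSITY_LEVELS = {"negative": 0, "weak": 1, "moderate": 2, "strong": 3}


def call_tls_regions(
    tls_scores: ScoreVector,
    hotspots: HotspotResult,
    graph: NeighborGraph,
    quantile: float = 0.75,
) -> np.ndarray:
    """Per-spot TLS region labels: -1 outside, else 0-based region id.

    A spot qualifies iff its score is strictly above the ``quantile``
    threshold AND its hotspot flag is set; qualifying spots connected through
    the (symmetrized) KNN graph form one region. Region ids are ordered by
    the first member spot index. No qualifying spot yields an all ``-1``
    labelling, not an error.
    """
    scores = tls_scores.scores
    if len(scores) != graph.n or len(hotspots.flag) != graph.n:
        raise ValueError("scores, hotspot flags and graph must cover the same spots")
    threshold = float(np.quantile(scores, quantile))
    member = (scores > threshold) & hotspots.flag
    labels = np.full(graph.n, -1, dtype=int)
    if not member.any():
        return labels

    idx = np.flatnonzero(member)
    pos = {spot: j for j, spot in enumerate(idx)}
    rows, cols = [], []
    for j, spot in enumerate(idx):
        for nbr in graph.indices[spot]:
            if nbr in pos:
                rows.append(j)
                cols.append(pos[nbr])
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(idx), len(idx))
    )
    n_comp, comp = connected_components(adj, directed=False)
    # renumber components by first appearance so ids follow spot order
    order = {}
    for c in comp:
        if c not in order:
            order[c] = len(order)
    labels[idx] = [order[c] for c in comp]
    return labels


@dataclass
class RegionFeatures:
    """Panel summaries for one TLS region."""

    region_id: int
    cytokine_mean: float
    gc_mean: float
    gc_like_presence: float  # proportion in [0, 1] or a 0/1 flag
    histology_confirmed: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_like_presence <= 1.0:
            raise ValueError("gc_like_presence must lie in [0, 1]")


@dataclass
class MaturityCall:
    """Region maturity call with the per-criterion booleans that produced it."""

    region_id: int
    call: str
    criterion_molecular: bool
    criterion_gc_cells: bool
    criterion_histology: bool | None = None


@dataclass
class PanelReference:
    """Cohort reference levels for 'elevated' panel expression."""

    cytokine_median: float
    gc_median: float


def region_features(
    dataset: SpatialDataset,
    region_labels: np.ndarray,
    gc_like_presence=None,
    histology_confirmed=None,
    cytokine_panel=CYTOKINE_PANEL,
    gc_panel=GC_PANEL,
) -> list[RegionFeatures]:
    """Mean panel expression per region, with optional external flags.

    ``gc_like_presence`` / ``histology_confirmed`` may be None, a scalar for
    all regions, or a mapping ``region_id -> value``. Panel genes absent from
    the dataset are ignored; a panel with no gene present raises.
    """
    region_labels = np.asarray(region_labels, dtype=int)
    if region_labels.shape != (dataset.n_spots,):
        raise ValueError("one region label per spot required")

    def panel_rows(panel):
        present = [g for g in panel if g in dataset.genes]
        if not present:
            raise ValueError(f"no gene of panel {panel} in the dataset")
        return np.array([dataset.gene_index(g) for g in present])

    def lookup(value, rid, default):
        if value is None:
            return default
        if isinstance(value, dict):
            return value.get(rid, default)
        return value

    cyt_rows, gc_rows = panel_rows(cytokine_panel), panel_rows(gc_panel)
    matrix = np.asarray(dataset.matrix, dtype=float)
    out = []
    for rid in sorted(set(region_labels[region_labels >= 0])):
        cols = region_labels == rid
        out.append(
            RegionFeatures(
                region_id=int(rid),
                cytokine_mean=float(matrix[np.ix_(cyt_rows, np.flatnonzero(cols))].mean()),
                gc_mean=float(matrix[np.ix_(gc_rows, np.flatnonzero(cols))].mean()),
                gc_like_presence=float(lookup(gc_like_presence, int(rid), 0.0)),
                histology_confirmed=lookup(histology_confirmed, int(rid), None),
            )
        )
    return out


def panel_reference(features: list[RegionFeatures]) -> PanelReference:
    """Cohort medians of region-level panel means ('elevated' reference)."""
    if not features:
        raise ValueError("empty region set")
    return PanelReference(
        cytokine_median=float(np.median([f.cytokine_mean for f in features])),
        gc_median=float(np.median([f.gc_mean for f in features])),
    )


def classify_maturity(
    features: RegionFeatures, cohort_reference: PanelReference
) -> MaturityCall:
    """Mature iff all evaluated criteria hold, else immature.

    Criterion 1 (molecular): cytokine AND germinal-center panel means both
    strictly above the cohort reference medians. Criterion 2: GC-like B
    cells / plasmablasts present. Criterion 3 (histology): evaluated only
    when the region carries a histology flag. Monotone: switching any
    criterion from false to true never flips mature -> immature.
    """
    if cohort_reference is None:
        raise ValueError("empty cohort reference")
    crit1 = (
        features.cytokine_mean > cohort_reference.cytokine_median
        and features.gc_mean > cohort_reference.gc_median
    )
    crit2 = features.gc_like_presence > 0
    crit3 = features.histology_confirmed
    evaluated = [crit1, crit2] + ([bool(crit3)] if crit3 is not None else [])
    return MaturityCall(
        region_id=features.region_id,
        call="mature" if all(evaluated) else "immature",
        criterion_molecular=crit1,
        criterion_gc_cells=crit2,
        criterion_histology=None if crit3 is None else bool(crit3),
    )


@dataclass
class IhcScore:
    """Composite immunohistochemistry score: proportion x intensity."""

    proportion_score: int
    intensity_score: int

    def __post_init__(self) -> None:
        if self.proportion_score not in range(5):
            raise ValueError("proportion score must be 0-4")
        if self.intensity_score not in range(4):
            raise ValueError("intensity score must be 0-3")

    @property
    def final(self) -> int:
        return self.proportion_score * self.intensity_score


def ihc_proportion_score(pct_positive: float) -> int:
    """Proportion score: 0 = none; 1 = 1-25%; 2 = 26-50%; 3 = 51-75%; 4 = 76-100%.

    Non-integer percentages fall into half-open bins (0, 25] -> 1,
    (25, 50] -> 2, (50, 75] -> 3, (75, 100] -> 4; exactly 0 -> 0.
    """
    if not 0.0 <= pct_positive <= 100.0:
        raise ValueError("percentage must lie in [0, 100]")
    if pct_positive == 0:
        return 0
    return int(np.ceil(pct_positive / 25.0))


def ihc_intensity_score(level: str) -> int:
    """Intensity score: 0 = negative; 1 = weak; 2 = moderate; 3 = strong."""
    try:
        return INTENSITY_LEVELS[level]
    except KeyError:
        raise ValueError(
            f"unknown intensity level {level!r}; expected one of {tuple(INTENSITY_LEVELS)}"
        ) from None


def ihc_final_score(proportion_score: int, intensity_score: int) -> int:
    """Final composite score: proportion score times intensity score (0-12)."""
    score = IhcScore(proportion_score=proportion_score, intensity_score=intensity_score)
    return score.final
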