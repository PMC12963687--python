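"""Marker-pair spot classification, distance-conditional co-occurrence, and
permutation inference.

Spots are binarized on two marker scores A and B and partitioned into the four
joint classes ``A+B+ / A+B- / A-B+ / A-B-``. For a condition class C and a
target class T, the co-occurrence curve reports, per cumulative radius r,

    ratio(r) = P(spot k in T | exists spot i in C with d(i, k) <= r, k != i)
               / P(spot in T)

i.e. the conditional probability of the target class among all ordered pairs
(i, k) with i in C and d(i, k) <= r, divided by the unconditional (global)
target fraction. Under spatial independence the ratio is 1 at every radius.

Significance is assessed with a label-permutation null: the joint four-class
label vector is shuffled as a unit across spot positions (conserving the
marker contingency table exactly, so only the spatial arrangement is
randomized), the curve is reduced to a scalar (by default the mean of
``ratio - 1`` over defined bins up to an evaluation radius), and an empirical
p-value with add-one correction plus null percentile bounds are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .scoring import ScoreVector

__all__ = [
    "CLASS_NAMES",
    "PairClassLabels",
    "RadialBins",
    "CooccurrenceCurve",
    "PermutationTestResult",
    "CoLocalization",
    "EmptyClassError",
    "binarize_scores",
    "pair_classes",
    "cooccurrence_curve",
    "centroid_proximity",
    "permute_pair_labels",
    "cooccurrence_permutation_test",
    "adjust_bh",
]

CLASS_NAMES = ("A+B+", "A+B-", "A-B+", "A-B-")

DEFAULT_MAX_DISTANCE_UM = 6000.0
DEFAULT_N_BINS = 30


class EmptyClassError(ValueError):
    """A required spot class is empty."""


@dataclass
class PairClassLabels:
    """Joint two-marker classification of spots into the four +/- classes."""

    spot_ids: np.ndarray
    labels: np.ndarray
    marker_a: str = "A"
    marker_b: str = "B"

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.labels.shape != self.spot_ids.shape:
            raise ValueError("one label per spot required")
        if not set(np.unique(self.labels)) <= set(CLASS_NAMES):
            raise ValueError(f"labels must be among {CLASS_NAMES}")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict:
        """Class -> spot count, over all four classes (zeros included)."""
        return {c: int(np.sum(self.labels == c)) for c in CLASS_NAMES}

    def mask(self, class_name: str) -> np.ndarray:
        if class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {class_name!r}")
        return self.labels == class_name


@dataclass
class RadialBins:
    """Strictly increasing distance edges in um, starting at 0.

    Cumulative bin j collects all pairs with distance <= edges[j + 1].
    """

    edges: np.ndarray = field(
        default_factory=lambda: np.linspace(
            0.0, DEFAULT_MAX_DISTANCE_UM, DEFAULT_N_BINS + 1
        )
    )

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 2 or self.edges[0] != 0.0:
            raise ValueError("need >= 2 edges starting at 0")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def regular(
        cls, max_um: float = DEFAULT_MAX_DISTANCE_UM, n_bins: int = DEFAULT_N_BINS
    ) -> "RadialBins":
        return cls(np.linspace(0.0, max_um, n_bins + 1))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def upper(self) -> np.ndarray:
        return self.edges[1:]


@dataclass
class CooccurrenceCurve:
    """Conditional-probability ratio per cumulative radius bin.

    ``ratio`` is NaN where a bin holds no conditioning pair; ``pair_counts``
    is the number of ordered conditioning pairs per bin.
    """

    condition_class: str
    target_class: str
    edges: np.ndarray
    ratio: np.ndarray
    pair_counts: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return self.pair_counts > 0


@dataclass
class PermutationTestResult:
    """Observed co-occurrence summary, permutation null, and empirical p."""

    observed: float
    null: np.ndarray
    pvalue: float
    ci_low: float
    ci_high: float
    alternative: str
    seed: int
    condition_class: str
    target_class: str
    statistic: str = "mean_deviation"

    @property
    def n_perm(self) -> int:
        return len(self.null)


@dataclass
class CoLocalization:
    """Result of the centroid proximity rule: per-A-point flags and pairs."""

    flags_a: np.ndarray
    pairs: np.ndarray  # (m, 2) indices (ia, ib) within the radius
    radius_um: float


def binarize_scores(
    scores, rule: str = "median", q: float | None = None
) -> np.ndarray:
    """Boolean +/- call per spot: + iff score strictly above the threshold.

    ``rule`` is ``"median"`` or ``"quantile"`` (the latter requires
    ``q`` in (0, 1)).
    """
    values = scores.scores if isinstance(scores, ScoreVector) else np.asarray(
        scores, dtype=float
    )
    if values.size < 2:
        raise ValueError("binarization requires at least 2 spots")
    if rule == "median":
        threshold = float(np.median(values))
    elif rule == "quantile":
        if q is None or not 0.0 < q < 1.0:
            raise ValueError("quantile rule requires q in (0, 1)")
        threshold = float(np.quantile(values, q))
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    return values > threshold


def pair_classes(
    a_positive,
    b_positive,
    spot_ids=None,
    marker_a: str = "A",
    marker_b: str = "B",
) -> PairClassLabels:
    """Cross two binary marker calls into the four joint classes.

    Accepts boolean arrays or :class:`ScoreVector`-aligned calls; when both
    inputs carry spot ids they must agree.
    """
    a = np.asarray(a_positive, dtype=bool)
    b = np.asarray(b_positive, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("marker calls must cover the same spots")
    if spot_ids is None:
        spot_ids = np.array([f"spot{i}" for i in range(a.size)])
    spot_ids = np.asarray(spot_ids, dtype=str)
    if spot_ids.shape != a.shape:
        raise ValueError("spot_ids length mismatch")
    labels = np.where(
        a,
        np.where(b, "A+B+", "A+B-"),
        np.where(b, "A-B+", "A-B-"),
    )
    return PairClassLabels(
        spot_ids=spot_ids, labels=labels, marker_a=marker_a, marker_b=marker_b
    )


class BinnedPairDistances:
    """Cumulative radial bin index for every ordered spot pair.

    Precomputes, for ``n`` spots, an ``n x n`` matrix of bin indices (the
    first cumulative bin containing each pair); self-pairs and pairs beyond
    the last edge carry a sentinel so they never count. Reused across label
    permutations, which only re-aggregate counts.
    """

    def __init__(self, coords: np.ndarray, bins: RadialBins):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        self.bins = bins
        self.n = len(coords)
        dist = cdist(coords, coords)
        idx = np.searchsorted(bins.upper, dist, side="left")
        idx[dist > bins.upper[-1]] = bins.n_bins  # sentinel: never counted
        np.fill_diagonal(idx, bins.n_bins)
        dtype = np.int16 if bins.n_bins < np.iinfo(np.int16).max else np.int64
        self.idx = idx.astype(dtype)

    def pair_counts(
        self, cond_mask: np.ndarray, targ_mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative (condition->target, condition->any) pair counts per bin."""
        nb = self.bins.n_bins
        rows = np.flatnonzero(cond_mask)
        cols = np.flatnonzero(targ_mask)
        num = np.bincount(
            self.idx[np.ix_(rows, cols)].ravel().astype(np.int64), minlength=nb + 1
        )[:nb].cumsum()
        den = np.bincount(
            self.idx[rows].ravel().astype(np.int64), minlength=nb + 1
        )[:nb].cumsum()
        return num, den

    def ratios(
        self, cond_mask: np.ndarray, targ_mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Co-occurrence ratio per bin (NaN where undefined) and pair counts."""
        num, den = self.pair_counts(cond_mask, targ_mask)
        p_target = targ_mask.sum() / self.n
        ratio = np.full(self.bins.n_bins, np.nan)
        ok = den > 0
        ratio[ok] = (num[ok] / den[ok]) / p_target
        return ratio, den


def cooccurrence_curve(
    coords,
    labels: PairClassLabels,
    condition_class: str,
    target_class: str,
    bins: RadialBins | None = None,
    _binned: BinnedPairDistances | None = None,
) -> CooccurrenceCurve:
    """Distance-conditional co-occurrence curve for one (condition, target) pair.

    Raises :class:`EmptyClassError` if the condition class is empty or the
    target class is absent from the dataset (global fraction zero).
    """
    bins = bins or RadialBins()
    cond = labels.mask(condition_class)
    targ = labels.mask(target_class)
    if not cond.any():
        raise EmptyClassError(f"condition class {condition_class!r} is empty")
    if not targ.any():
        raise EmptyClassError(f"target class {target_class!r} absent from the data")
    binned = _binned or BinnedPairDistances(np.asarray(coords, dtype=float), bins)
    ratio, den = binned.ratios(cond, targ)
    return CooccurrenceCurve(
        condition_class=condition_class,
        target_class=target_class,
        edges=bins.edges.copy(),
        ratio=ratio,
        pair_counts=den,
    )


def centroid_proximity(points_a, points_b, radius_um: float = 50.0) -> CoLocalization:
    """Flag A-points with some B-point centroid within ``radius_um`` (inclusive).

    Empty point sets give empty results, not errors.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(a)) or not np.all(np.isfinite(b)):
        raise ValueError("coordinates must be finite")
    if a.size == 0 or b.size == 0:
        return CoLocalization(
            flags_a=np.zeros(len(a), dtype=bool),
            pairs=np.empty((0, 2), dtype=int),
            radius_um=radius_um,
        )
    tree = cKDTree(b)
    neighbor_lists = tree.query_ball_point(a, r=radius_um)
    pairs = [
        (ia, ib) for ia, hits in enumerate(neighbor_lists) for ib in sorted(hits)
    ]
    flags = np.array([len(hits) > 0 for hits in neighbor_lists], dtype=bool)
    return CoLocalization(
        flags_a=flags,
        pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        radius_um=radius_um,
    )


def permute_pair_labels(labels: PairClassLabels, seed: int) -> PairClassLabels:
    """Shuffle the joint label vector as a unit across spot positions.

    Class counts (the full marker contingency table) are conserved exactly;
    only the spatial arrangement changes.
    """
    rng = np.random.default_rng(seed)
    return PairClassLabels(
        spot_ids=labels.spot_ids,
        labels=labels.labels[rng.permutation(len(labels))],
        marker_a=labels.marker_a,
        marker_b=labels.marker_b,
    )


def _summarize(
    ratio: np.ndarray, den: np.ndarray, eligible: np.ndarray, statistic: str
) -> float:
    use = eligible & (den > 0)
    if not use.any():
        return np.nan
    dev = ratio[use] - 1.0
    if statistic == "mean_deviation":
        return float(np.mean(dev))
    if statistic == "max_deviation":
        return float(np.max(dev))
    raise ValueError(f"unknown statistic {statistic!r}")


def cooccurrence_permutation_test(
    coords,
    labels: PairClassLabels,
    condition_class: str,
    target_class: str,
    bins: RadialBins | None = None,
    n_perm: int = 1000,
    alternative: str = "greater",
    max_eval_radius: float = DEFAULT_MAX_DISTANCE_UM,
    statistic: str = "mean_deviation",
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of the co-occurrence curve against spatial randomness.

    The curve is reduced to a scalar over defined bins whose upper edge is at
    most ``max_eval_radius`` — by default the mean of ``ratio - 1``
    (``statistic="max_deviation"`` uses the largest deviation instead). The
    null is built from ``n_perm`` joint-label permutations; the empirical
    p-value uses the add-one formula, e.g. for ``alternative="greater"``:

        p = (1 + #{null >= observed}) / (1 + n_perm)

    so p is never below ``1 / (n_perm + 1)``. ``ci_low``/``ci_high`` are the
    2.5th/97.5th percentiles of the null sample.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    bins = bins or RadialBins()
    cond = labels.mask(condition_class)
    targ = labels.mask(target_class)
    if not cond.any():
        raise EmptyClassError(f"condition class {condition_class!r} is empty")
    if not targ.any():
        raise EmptyClassError(f"target class {target_class!r} absent from the data")

    binned = BinnedPairDistances(np.asarray(coords, dtype=float), bins)
    eligible = bins.upper <= max_eval_radius + 1e-9
    obs_ratio, obs_den = binned.ratios(cond, targ)
    observed = _summarize(obs_ratio, obs_den, eligible, statistic)
    if np.isnan(observed):
        raise EmptyClassError("all bins undefined for the observed labels")

    rng = np.random.default_rng(seed)
    lab = labels.labels
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(lab))
        ratio, den = binned.ratios(cond[perm], targ[perm])
        null[b] = _summarize(ratio, den, eligible, statistic)

    finite_null = null[np.isfinite(null)]
    n_eff = len(finite_null)
    ge = int(np.sum(finite_null >= observed))
    le = int(np.sum(finite_null <= observed))
    if alternative == "greater":
        p = (1 + ge) / (1 + n_eff)
    elif alternative == "less":
        p = (1 + le) / (1 + n_eff)
    else:
        p = min(1.0, 2.0 * min((1 + ge) / (1 + n_eff), (1 + le) / (1 + n_eff)))
    ci_low, ci_high = np.percentile(finite_null, [2.5, 97.5])
    return PermutationTestResult(
        observed=observed,
        null=null,
        pvalue=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        alternative=alternative,
        seed=seed,
        condition_class=condition_class,
        target_class=target_class,
        statistic=statistic,
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
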