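"""Synthetic Visium-like sections and cohorts with planted ground truth.

The spatial generator emulates the statistical structure the downstream
analysis assumes: a hexagonal (or square) spot lattice at ~100 um pitch,
negative-binomial transcript counts, disk-shaped TLS niches over-expressing
the canonical TLS signature genes, metabolic regions over-expressing the
tryptophan-catabolism enzymes, and a tunable co-localization/avoidance
parameter rho between the two niche systems:

* rho = +1: metabolic regions are co-centered with TLS niches;
* rho = 0: centers placed independently, uniform over the capture area;
* rho < 0: rejection sampling enforces a minimum cross-type center distance
  of ``|rho| * 2 * niche_radius_um``, so at rho = -1 the two niche systems
  are disjoint (maximal avoidance).

The cohort generator draws Beta-distributed per-sample germinal-center-like
B cell frequencies with a mean shift between High and Low metabolism groups,
and ``simulate_null_labels`` draws spot class labels independent of any
coordinates for permutation-test calibration.

All randomness flows from the config seed; identical configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import CohortTable
from .cooccurrence import CLASS_NAMES, PairClassLabels
from .data import GeneSignature, SpatialDataset

__all__ = [
    "TLS_SIGNATURE",
    "METABOLIC_SIGNATURE",
    "SyntheticSpatialConfig",
    "SyntheticTruth",
    "NichePlacementError",
    "simulate_spatial",
    "simulate_cohort",
    "simulate_null_labels",
]

#: Canonical TLS signature used by the generator (chemokines, GC markers,
#: class-switch machinery, B-cell lineage).
TLS_SIGNATURE = GeneSignature(
    name="TLS_signature",
    genes=("CXCL9", "CXCL13", "TNFSF13", "RORA", "AICDA", "CD38", "IGHG1", "MS4A1"),
    role="TLS",
)

#: Tryptophan-catabolism (kynurenine pathway) signature.
METABOLIC_SIGNATURE = GeneSignature(
    name="tryptophan_metabolism",
    genes=("TDO2", "IDO1", "KMO", "KYNU"),
    role="metabolic",
)


class NichePlacementError(RuntimeError):
    """Niche centers could not be placed under the distance constraints."""


@dataclass
class SyntheticSpatialConfig:
    """Parameters of the planted-niche spatial generator.

    Defaults describe a 50 x 50 hex lattice at 100 um pitch (2500 spots),
    200 genes with negative-binomial counts (mean 5, dispersion 2), and three
    TLS plus three metabolic niches of radius 180 um (about a dozen spots
    each, ~1.5% tissue coverage per system — compact lymphoid-aggregate-sized
    structures) whose signature genes are elevated four-fold.
    """

    lattice: str = "hex"
    n_rows: int = 50
    n_cols: int = 50
    pitch_um: float = 100.0
    n_genes: int = 200
    baseline_mean: float = 5.0  # scalar or per-gene array
    dispersion: float = 2.0
    n_tls_niches: int = 3
    n_met_regions: int = 3
    niche_radius_um: float = 180.0
    fold_tls: float = 4.0
    fold_met: float = 4.0
    overlap: float = 0.0  # rho in [-1, 1]
    seed: int = 0
    max_placement_tries: int = 10000

    def __post_init__(self) -> None:
        if self.lattice not in ("hex", "square"):
            raise ValueError("lattice must be 'hex' or 'square'")
        if not -1.0 <= self.overlap <= 1.0:
            raise ValueError("overlap rho must lie in [-1, 1]")
        if self.fold_tls < 1.0 or self.fold_met < 1.0:
            raise ValueError("fold changes must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        extent = min(self.n_rows, self.n_cols) * self.pitch_um
        if self.niche_radius_um >= extent:
            raise ValueError("niche radius must be smaller than the lattice extent")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated section."""

    tls_mask: np.ndarray
    met_mask: np.ndarray
    tls_centers: np.ndarray
    met_centers: np.ndarray
    realized_center_distances: np.ndarray  # cross distances, (n_tls, n_met)


def lattice_coords(
    lattice: str, n_rows: int, n_cols: int, pitch_um: float
) -> np.ndarray:
    """Spot centroid coordinates in um for a square or hex lattice."""
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rows, cols = rows.ravel(), cols.ravel()
    if lattice == "square":
        x = cols * pitch_um
        y = rows * pitch_um
    else:  # hex: odd rows shifted half a pitch, rows sqrt(3)/2 pitch apart
        x = (cols + 0.5 * (rows % 2)) * pitch_um
        y = rows * pitch_um * np.sqrt(3.0) / 2.0
    return np.column_stack([x, y]).astype(float)


def _place_centers(coords: np.ndarray, config: SyntheticSpatialConfig, rng) -> tuple:
    r = config.niche_radius_um
    rho = config.overlap
    lo = coords.min(axis=0) + r
    hi = coords.max(axis=0) - r
    if np.any(hi <= lo):
        raise NichePlacementError("niche radius leaves no room for centers")
    same_type_min = 2.0 * r  # keep same-type niches disjoint
    cross_min = abs(rho) * 2.0 * r if rho < 0 else 0.0

    def draw() -> np.ndarray:
        return rng.uniform(lo, hi)

    def far_enough(c, others, dmin) -> bool:
        return len(others) == 0 or all(
            np.linalg.norm(c - o) >= dmin for o in others
        )

    tls = []
    tries = 0
    while len(tls) < config.n_tls_niches:
        c = draw()
        if far_enough(c, tls, same_type_min):
            tls.append(c)
        tries += 1
        if tries > config.max_placement_tries:
            raise NichePlacementError("could not place TLS niche centers")

    met = []
    tries = 0
    while len(met) < config.n_met_regions:
        if rho >= 0:
            anchor = tls[len(met) % len(tls)] if tls else draw()
            u = draw()
            c = anchor + (1.0 - rho) * (u - anchor)  # rho=1 co-centered, rho=0 uniform
        else:
            c = draw()
        ok = far_enough(c, met, same_type_min)
        if ok and rho < 0:
            ok = far_enough(c, tls, cross_min)
        if ok:
            met.append(c)
        tries += 1
        if tries > config.max_placement_tries:
            raise NichePlacementError("could not place metabolic region centers")
    return np.array(tls).reshape(-1, 2), np.array(met).reshape(-1, 2)


def _disk_mask(coords: np.ndarray, centers: np.ndarray, radius: float) -> np.ndarray:
    if len(centers) == 0:
        return np.zeros(len(coords), dtype=bool)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= radius**2).any(axis=1)


def simulate_spatial(
    config: SyntheticSpatialConfig,
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Simulate one spatial section with planted TLS and metabolic niches.

    Counts are drawn gene-wise from a negative binomial with mean ``mu_g``
    (multiplied by ``fold_tls`` on TLS signature genes within TLS niches and
    by ``fold_met`` on metabolic genes within metabolic regions) and
    dispersion theta, parameterised so the variance is
    ``mu + mu**2 / theta``.
    """
    rng = np.random.default_rng(config.seed)
    coords = lattice_coords(
        config.lattice, config.n_rows, config.n_cols, config.pitch_um
    )
    n_spots = len(coords)

    sig_genes = list(TLS_SIGNATURE.genes) + list(METABOLIC_SIGNATURE.genes)
    if config.n_genes < len(sig_genes):
        raise ValueError(f"need at least {len(sig_genes)} genes")
    background = [
        f"GENE{i:04d}" for i in range(1, config.n_genes - len(sig_genes) + 1)
    ]
    genes = np.array(sig_genes + background)

    tls_centers, met_centers = _place_centers(coords, config, rng)
    tls_mask = _disk_mask(coords, tls_centers, config.niche_radius_um)
    met_mask = _disk_mask(coords, met_centers, config.niche_radius_um)

    mu = np.broadcast_to(
        np.atleast_1d(np.asarray(config.baseline_mean, dtype=float))[:, None]
        if np.ndim(config.baseline_mean)
        else np.full((config.n_genes, 1), float(config.baseline_mean)),
        (config.n_genes, n_spots),
    ).copy()
    tls_rows = np.isin(genes, TLS_SIGNATURE.genes)
    met_rows = np.isin(genes, METABOLIC_SIGNATURE.genes)
    mu[np.ix_(tls_rows, tls_mask)] *= config.fold_tls
    mu[np.ix_(met_rows, met_mask)] *= config.fold_met

    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    spot_ids = np.array([f"SPOT-{i:05d}" for i in range(n_spots)])
    dataset = SpatialDataset(
        spot_ids=spot_ids, coords=coords, genes=genes, matrix=counts, units="counts"
    )
    cross = np.linalg.norm(
        tls_centers[:, None, :] - met_centers[None, :, :], axis=2
    ) if len(tls_centers) and len(met_centers) else np.empty((len(tls_centers), len(met_centers)))
    truth = SyntheticTruth(
        tls_mask=tls_mask,
        met_mask=met_mask,
        tls_centers=tls_centers,
        met_centers=met_centers,
        realized_center_distances=cross,
    )
    return dataset, truth


def simulate_cohort(
    n_samples: int = 26,
    n_high: int = 13,
    effect_delta: float = -0.08,
    seed: int = 0,
    base_mean: float = 0.18,
    concentration: float = 30.0,
) -> CohortTable:
    """Beta-distributed per-sample GC-like B cell frequencies with a group shift.

    Low-group frequencies have mean ``base_mean``; High-group frequencies
    have mean ``base_mean + effect_delta`` (negative by default: high
    metabolic activity depresses germinal-center-like B cell frequency).
    Both means must lie strictly inside (0, 1).
    """
    if not 0 < n_high < n_samples:
        raise ValueError("need 0 < n_high < n_samples")
    high_mean = base_mean + effect_delta
    for m in (base_mean, high_mean):
        if not 0.0 < m < 1.0:
            raise ValueError("group means must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    groups = np.array(["High"] * n_high + ["Low"] * (n_samples - n_high))
    means = np.where(groups == "High", high_mean, base_mean)
    freqs = rng.beta(means * concentration, (1.0 - means) * concentration)
    sample_ids = np.array([f"S{i:03d}" for i in range(1, n_samples + 1)])
    return CohortTable(sample_ids=sample_ids, groups=groups, frequencies=freqs)


def simulate_null_labels(
    n_spots: int, class_probs=(0.25, 0.25, 0.25, 0.25), seed: int = 0
) -> PairClassLabels:
    """i.i.d. four-class spot labels, independent of any coordinates."""
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_probs must be four proportions summing to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(np.array(CLASS_NAMES), size=n_spots, p=probs)
    spot_ids = np.array([f"SPOT-{i:05d}" for i in range(n_spots)])
    return PairClassLabels(spot_ids=spot_ids, labels=labels)


def config_record(config: SyntheticSpatialConfig) -> dict:
    """JSON-serialisable provenance record of a generator config."""
    rec = asdict(config)
    if np.ndim(rec["baseline_mean"]):
        rec["baseline_mean"] = np.asarray(rec["baseline_mean"]).tolist()
    return rec
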