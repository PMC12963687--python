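"""Core containers, Visium-style bundle I/O, GMT parsing, and expression preprocessing.

The central objects are :class:`SpatialDataset` (a gene x spot matrix with
centroid coordinates in micrometres), :class:`ExpressionTable` (a bulk
gene x sample matrix in TPM or log2(TPM+1)), and :class:`GeneSignature`
(a named gene set, optionally tagged with a biological role).

Coordinate convention: spot coordinates are centroid positions in um, origin at
the top-left of the capture area with y increasing downward (pixel-space
convention). All distances downstream are Euclidean in um.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import pdist

__all__ = [
    "SpatialDataset",
    "ExpressionTable",
    "GeneSignature",
    "BundleError",
    "DimensionMismatchError",
    "DuplicateBarcodeError",
    "MissingPositionsError",
    "GmtFormatError",
    "UnitsError",
    "read_visium_like",
    "write_visium_like",
    "read_gmt",
    "filter_low_abundance",
    "log_normalize",
    "qc_filter_cells",
]

#: Recognised units tags for expression matrices.
UNITS = ("counts", "tpm", "log2_tpm1", "zscore")

#: Recognised role tags for gene signatures.
SIGNATURE_ROLES = ("TLS", "HEV", "metabolic", "GC-marker", "other")

DEFAULT_SPOT_PITCH_UM = 100.0


class BundleError(ValueError):
    """Malformed spatial bundle."""


class DimensionMismatchError(BundleError):
    """Matrix dimensions disagree with the features/barcodes tables."""


class DuplicateBarcodeError(BundleError):
    """A barcode appears more than once."""


class MissingPositionsError(BundleError):
    """A barcode present in the matrix has no row in the positions table."""


class GmtFormatError(ValueError):
    """A GMT line has fewer than three tab-separated fields."""


class UnitsError(ValueError):
    """An operation was applied to a matrix with the wrong units tag."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=str)


@dataclass
class SpatialDataset:
    """Gene x spot expression matrix with spot centroid coordinates in um.

    Parameters
    ----------
    spot_ids:
        Unique spot barcodes, length ``n_spots``.
    coords:
        ``(n_spots, 2)`` array of (x, y) centroids in um.
    genes:
        Unique gene symbols, length ``n_genes``.
    matrix:
        ``(n_genes, n_spots)`` matrix of expression values.
    units:
        One of ``counts | tpm | log2_tpm1 | zscore``. In counts mode all
        values must be nonnegative integers.
    """

    spot_ids: np.ndarray
    coords: np.ndarray
    genes: np.ndarray
    matrix: np.ndarray
    units: str = "counts"

    def __post_init__(self) -> None:
        self.spot_ids = _as_str_array(self.spot_ids)
        self.genes = _as_str_array(self.genes)
        self.coords = np.asarray(self.coords, dtype=float)
        self.matrix = np.asarray(self.matrix)
        if self.units not in UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}")
        n_genes, n_spots = len(self.genes), len(self.spot_ids)
        if self.coords.shape != (n_spots, 2):
            raise DimensionMismatchError(
                f"coords shape {self.coords.shape} != ({n_spots}, 2)"
            )
        if self.matrix.shape != (n_genes, n_spots):
            raise DimensionMismatchError(
                f"matrix shape {self.matrix.shape} != ({n_genes}, {n_spots})"
            )
        if len(np.unique(self.spot_ids)) != n_spots:
            raise DuplicateBarcodeError("spot_ids are not unique")
        if len(np.unique(self.genes)) != n_genes:
            raise BundleError("gene symbols are not unique")
        if not np.all(np.isfinite(self.coords)):
            raise BundleError("coordinates must be finite")
        if not np.all(np.isfinite(self.matrix.astype(float))):
            raise BundleError("matrix values must be finite")
        if self.units == "counts":
            m = np.asarray(self.matrix, dtype=float)
            if (m < 0).any() or not np.allclose(m, np.round(m)):
                raise BundleError("counts-mode values must be nonnegative integers")
        elif self.units in ("tpm", "log2_tpm1") and (
            np.asarray(self.matrix, dtype=float) < 0
        ).any():
            raise BundleError(f"{self.units} values must be nonnegative")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in dataset")
        return int(idx[0])

    def expression(self, gene: str) -> np.ndarray:
        """Per-spot expression vector of one gene."""
        return np.asarray(self.matrix[self.gene_index(gene)], dtype=float)


@dataclass
class ExpressionTable:
    """Bulk gene x sample matrix with a units tag (TPM or log2(TPM+1))."""

    sample_ids: np.ndarray
    genes: np.ndarray
    matrix: np.ndarray
    units: str = "tpm"

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.genes = _as_str_array(self.genes)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.units not in UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}")
        shape = (len(self.genes), len(self.sample_ids))
        if self.matrix.shape != shape:
            raise DimensionMismatchError(f"matrix shape {self.matrix.shape} != {shape}")
        if self.units in ("tpm", "log2_tpm1") and (self.matrix < 0).any():
            raise ValueError("TPM-scale values cannot be negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GeneSignature:
    """A named, duplicate-free gene set with an optional role tag."""

    name: str
    genes: tuple
    role: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")
        if self.role is not None and self.role not in SIGNATURE_ROLES:
            raise ValueError(f"unknown signature role {self.role!r}")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Visium-dialect bundle I/O
# ---------------------------------------------------------------------------

_POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _read_positions(spatial_dir: Path) -> pd.DataFrame:
    """Read a tissue-positions table, headered or header-less (older dialect)."""
    for name in ("tissue_positions.csv", "tissue_positions_list.csv"):
        path = spatial_dir / name
        if path.exists():
            with open(path) as fh:
                first = fh.readline()
            has_header = first.split(",")[0].strip() == "barcode"
            df = pd.read_csv(
                path,
                header=0 if has_header else None,
                names=None if has_header else _POSITIONS_COLUMNS,
            )
            df.columns = _POSITIONS_COLUMNS[: len(df.columns)]
            return df
    raise BundleError(f"no tissue-positions table under {spatial_dir}")


def _microns_per_pixel(spatial_dir: Path, positions: pd.DataFrame, pitch_um: float) -> float:
    """Scale factor for pixel -> um conversion.

    Prefers an explicit scale-factors file; otherwise calibrates the stated
    spot pitch against the smallest center-to-center pixel distance.
    """
    sf_path = spatial_dir / "scalefactors_json.json"
    if sf_path.exists():
        with open(sf_path) as fh:
            sf = json.load(fh)
        if "microns_per_pixel" in sf:
            return float(sf["microns_per_pixel"])
        if "spot_diameter_fullres" in sf:
            # 10x convention: 65 um spot diameter in a standard Visium assay.
            return 65.0 / float(sf["spot_diameter_fullres"])
    pix = positions[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(float)
    if len(pix) < 2:
        return 1.0
    return pitch_um / float(pdist(pix).min())


def read_visium_like(
    bundle_dir, *, spot_pitch_um: float = DEFAULT_SPOT_PITCH_UM
) -> SpatialDataset:
    """Read a Visium-dialect bundle into a :class:`SpatialDataset`.

    The bundle directory must contain ``matrix.mtx`` (gene x spot triplets),
    ``features.tsv``, ``barcodes.tsv`` and a ``spatial/`` folder with a
    tissue-positions table. Only in-tissue spots are retained; pixel
    coordinates are converted to um using ``spatial/scalefactors_json.json``
    when present, else by calibrating ``spot_pitch_um`` against the smallest
    inter-spot pixel distance.
    """
    bundle_dir = Path(bundle_dir)
    matrix = np.asarray(spio.mmread(bundle_dir / "matrix.mtx").todense())
    features = pd.read_csv(bundle_dir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(bundle_dir / "barcodes.tsv", sep="\t", header=None)
    genes = features.iloc[:, 0].astype(str).to_numpy()
    codes = barcodes.iloc[:, 0].astype(str).to_numpy()
    if matrix.shape != (len(genes), len(codes)):
        raise DimensionMismatchError(
            f"matrix is {matrix.shape} but bundle lists "
            f"{len(genes)} features x {len(codes)} barcodes"
        )
    if len(np.unique(codes)) != len(codes):
        raise DuplicateBarcodeError("duplicate barcodes in barcodes.tsv")

    positions = _read_positions(bundle_dir / "spatial")
    if positions["barcode"].duplicated().any():
        raise DuplicateBarcodeError("duplicate barcodes in tissue positions")
    pos = positions.set_index("barcode")
    missing = [b for b in codes if b not in pos.index]
    if missing:
        raise MissingPositionsError(
            f"{len(missing)} barcode(s) lack tissue positions, e.g. {missing[0]!r}"
        )
    pos = pos.loc[codes]

    scale = _microns_per_pixel(bundle_dir / "spatial", positions, spot_pitch_um)
    keep = pos["in_tissue"].to_numpy(int) == 1
    coords = np.column_stack(
        [
            pos["pxl_col_in_fullres"].to_numpy(float) * scale,  # x
            pos["pxl_row_in_fullres"].to_numpy(float) * scale,  # y
        ]
    )
    units = "counts"
    meta_path = bundle_dir / "units.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            units = json.load(fh).get("units", "counts")
    return SpatialDataset(
        spot_ids=codes[keep],
        coords=coords[keep],
        genes=genes,
        matrix=matrix[:, keep],
        units=units,
    )


def write_visium_like(dataset: SpatialDataset, out_dir) -> Path:
    """Write a :class:`SpatialDataset` as a Visium-dialect bundle.

    Emits ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and
    ``spatial/tissue_positions.csv`` plus a scale-factors file with
    ``microns_per_pixel = 1`` (pixel coordinates are written in um), so the
    bundle round-trips losslessly through :func:`read_visium_like`. Row order
    is deterministic (dataset order).
    """
    if dataset.n_genes == 0:
        raise ValueError("refusing to write a dataset with no genes")
    out_dir = Path(out_dir)
    (out_dir / "spatial").mkdir(parents=True, exist_ok=True)

    mat = sparse.coo_matrix(np.asarray(dataset.matrix, dtype=float))
    field_kind = "integer" if dataset.units == "counts" else "real"
    if field_kind == "integer":
        mat = mat.astype(np.int64)
    spio.mmwrite(out_dir / "matrix.mtx", mat, field=field_kind)

    pd.DataFrame(
        {"id": dataset.genes, "name": dataset.genes, "type": "Gene Expression"}
    ).to_csv(out_dir / "features.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": dataset.spot_ids}).to_csv(
        out_dir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    positions = pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "in_tissue": 1,
            "array_row": 0,
            "array_col": np.arange(dataset.n_spots),
            "pxl_row_in_fullres": dataset.coords[:, 1],
            "pxl_col_in_fullres": dataset.coords[:, 0],
        }
    )
    positions.to_csv(out_dir / "spatial" / "tissue_positions.csv", index=False)
    with open(out_dir / "spatial" / "scalefactors_json.json", "w") as fh:
        json.dump({"microns_per_pixel": 1.0}, fh)
    with open(out_dir / "units.json", "w") as fh:
        json.dump({"units": dataset.units}, fh)
    return out_dir


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file: one signature per line, ``name<TAB>description<TAB>genes...``.

    The description column is discarded. Duplicate genes within a line are
    removed (first occurrence wins) with a warning. An empty file yields an
    empty list; a line with fewer than three fields raises
    :class:`GmtFormatError`.
    """
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"signature {name!r} contains duplicate genes; deduplicated",
                    stacklevel=2,
                )
            signatures.append(GeneSignature(name=name, genes=tuple(unique)))
    return signatures


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

def filter_low_abundance(
    expr: ExpressionTable, tpm_floor: float = 1.0, sample_fraction: float = 0.90
) -> ExpressionTable:
    """Drop low-abundance genes from a TPM table.

    A gene is removed iff the fraction of samples with TPM strictly below
    ``tpm_floor`` is strictly greater than ``sample_fraction`` ("below 1 in
    more than 90% of samples"); all other genes are retained in their
    original order. Idempotent.
    """
    if expr.units != "tpm":
        raise UnitsError("filter_low_abundance requires a TPM table")
    frac_below = np.mean(expr.matrix < tpm_floor, axis=1)
    keep = frac_below <= sample_fraction
    return ExpressionTable(
        sample_ids=expr.sample_ids,
        genes=expr.genes[keep],
        matrix=expr.matrix[keep],
        units="tpm",
    )


def log_normalize(expr: ExpressionTable) -> ExpressionTable:
    """Replace every TPM value v by log2(v + 1) and update the units tag."""
    if expr.units != "tpm":
        raise UnitsError("log_normalize requires a TPM table")
    if (expr.matrix < 0).any():
        raise ValueError("negative TPM value")
    return ExpressionTable(
        sample_ids=expr.sample_ids,
        genes=expr.genes,
        matrix=np.log2(expr.matrix + 1.0),
        units="log2_tpm1",
    )


def qc_filter_cells(
    counts: np.ndarray,
    genes,
    mito_genes,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito: float = 0.10,
) -> np.ndarray:
    """Indices of cells passing standard count-based quality control.

    A cell is kept iff its detected-gene count (genes with count > 0) lies in
    ``[min_genes, max_genes]`` and its mitochondrial count fraction is at most
    ``max_mito`` — "fewer than 200", "more than 2500" and "over 10%" are all
    strict exclusions, so the stated bounds themselves are kept.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    genes = _as_str_array(genes)
    mito_mask = np.isin(genes, _as_str_array(list(mito_genes)))
    if not mito_mask.any():
        warnings.warn("no mitochondrial genes found in the matrix", stacklevel=2)
    detected = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0).astype(float)
    mito_frac = np.divide(
        counts[mito_mask].sum(axis=0),
        totals,
        out=np.zeros_like(totals),
        where=totals > 0,
    )
    keep = (detected >= min_genes) & (detected <= max_genes) & (mito_frac <= max_mito)
    return np.flatnonzero(keep)
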