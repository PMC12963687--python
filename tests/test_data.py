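"""Containers, bundle I/O round-trips, GMT parsing, and preprocessing filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlspatial.data import (
    DimensionMismatchError,
    DuplicateBarcodeError,
    ExpressionTable,
    GeneSignature,
    GmtFormatError,
    MissingPositionsError,
    SpatialDataset,
    UnitsError,
    filter_low_abundance,
    log_normalize,
    qc_filter_cells,
    read_gmt,
    read_visium_like,
    write_visium_like,
)
from tlspatial.simulate import SyntheticSpatialConfig, simulate_spatial


# --------------------------------------------------------------------------
# bundle round-trip and error paths
# --------------------------------------------------------------------------

def test_bundle_round_trip_is_lossless(tmp_path):
    dataset, _ = simulate_spatial(
        SyntheticSpatialConfig(
            n_rows=10, n_cols=10, niche_radius_um=120,
            n_tls_niches=2, n_met_regions=2, seed=3,
        )
    )
    write_visium_like(dataset, tmp_path / "bundle")
    back = read_visium_like(tmp_path / "bundle")
    assert np.array_equal(back.spot_ids, dataset.spot_ids)
    assert np.array_equal(back.genes, dataset.genes)
    np.testing.assert_allclose(back.coords, dataset.coords, atol=1e-6)
    assert np.array_equal(np.asarray(back.matrix), np.asarray(dataset.matrix))
    assert back.units == dataset.units


def test_not_in_tissue_spot_is_dropped(tmp_path, small_dataset):
    write_visium_like(small_dataset, tmp_path / "b")
    pos_path = tmp_path / "b" / "spatial" / "tissue_positions.csv"
    pos = pd.read_csv(pos_path)
    pos.loc[pos["barcode"] == "S05", "in_tissue"] = 0
    pos.to_csv(pos_path, index=False)
    back = read_visium_like(tmp_path / "b")
    assert back.n_spots == small_dataset.n_spots - 1
    assert "S05" not in back.spot_ids


def test_headerless_positions_dialect(tmp_path, small_dataset):
    write_visium_like(small_dataset, tmp_path / "b")
    pos_path = tmp_path / "b" / "spatial" / "tissue_positions.csv"
    pos = pd.read_csv(pos_path)
    pos_path.unlink()
    pos.to_csv(
        tmp_path / "b" / "spatial" / "tissue_positions_list.csv",
        index=False,
        header=False,
    )
    back = read_visium_like(tmp_path / "b")
    assert np.array_equal(back.spot_ids, small_dataset.spot_ids)


@pytest.mark.parametrize(
    "corruption, error",
    [
        ("truncate_barcodes", DimensionMismatchError),
        ("duplicate_barcode", DuplicateBarcodeError),
        ("drop_position", MissingPositionsError),
    ],
)
def test_malformed_bundles_raise_named_errors(tmp_path, small_dataset, corruption, error):
    write_visium_like(small_dataset, tmp_path / "b")
    barcodes_path = tmp_path / "b" / "barcodes.tsv"
    barcodes = barcodes_path.read_text().splitlines()
    if corruption == "truncate_barcodes":
        barcodes_path.write_text("\n".join(barcodes[:-1]) + "\n")
    elif corruption == "duplicate_barcode":
        barcodes[1] = barcodes[0]
        barcodes_path.write_text("\n".join(barcodes) + "\n")
    else:
        pos_path = tmp_path / "b" / "spatial" / "tissue_positions.csv"
        pos = pd.read_csv(pos_path)
        pos.iloc[:-1].to_csv(pos_path, index=False)
    with pytest.raises(error):
        read_visium_like(tmp_path / "b")


def test_write_refuses_empty_gene_set(tmp_path, square_coords):
    dataset = SpatialDataset(
        spot_ids=[f"s{i}" for i in range(36)],
        coords=square_coords,
        genes=[],
        matrix=np.zeros((0, 36)),
    )
    with pytest.raises(ValueError):
        write_visium_like(dataset, tmp_path / "b")


def test_counts_mode_rejects_negative_and_fractional():
    with pytest.raises(ValueError):
        SpatialDataset(
            spot_ids=["a", "b"],
            coords=[[0, 0], [100, 0]],
            genes=["G1"],
            matrix=[[1.5, 2.0]],
            units="counts",
        )


# --------------------------------------------------------------------------
# GMT parsing
# --------------------------------------------------------------------------

def test_read_gmt_basic_and_dedup(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("TLS\tdesc\tCXCL9\tCXCL13\nMET\tdesc\tTDO2\tTDO2\tIDO1\n")
    with pytest.warns(UserWarning, match="duplicate"):
        sigs = read_gmt(path)
    assert [s.name for s in sigs] == ["TLS", "MET"]
    assert sigs[0].genes == ("CXCL9", "CXCL13")
    assert sigs[1].genes == ("TDO2", "IDO1")


def test_read_gmt_empty_file_and_short_line(tmp_path):
    empty = tmp_path / "empty.gmt"
    empty.write_text("")
    assert read_gmt(empty) == []
    bad = tmp_path / "bad.gmt"
    bad.write_text("NAME\tdesc-only\n")
    with pytest.raises(GmtFormatError):
        read_gmt(bad)


def test_gene_signature_invariants():
    with pytest.raises(ValueError):
        GeneSignature(name="empty", genes=())
    with pytest.raises(ValueError):
        GeneSignature(name="dup", genes=("A", "A"))


# --------------------------------------------------------------------------
# preprocessing filters
# --------------------------------------------------------------------------

def _tpm_table(matrix, n_samples=None):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionTable(
        sample_ids=[f"P{j}" for j in range(matrix.shape[1])],
        genes=[f"G{i}" for i in range(matrix.shape[0])],
        matrix=matrix,
        units="tpm",
    )


def test_low_abundance_boundary_is_strict():
    # 9 of 10 samples below floor = exactly 90%: retained (not "more than")
    row_at_boundary = [0.5] * 9 + [2.0]
    row_above = [0.5] * 10
    row_kept = [5.0] * 10
    table = _tpm_table([row_at_boundary, row_above, row_kept])
    out = filter_low_abundance(table)
    assert list(out.genes) == ["G0", "G2"]


def test_low_abundance_matches_brute_force_oracle(rng):
    matrix = rng.choice([0.2, 0.9, 1.5, 8.0], size=(20, 10), p=[0.4, 0.2, 0.2, 0.2])
    table = _tpm_table(matrix)
    out = filter_low_abundance(table)
    kept_oracle = [
        g
        for g, row in zip(table.genes, matrix)
        if sum(v < 1.0 for v in row) / len(row) <= 0.90
    ]
    assert list(out.genes) == kept_oracle
    # idempotent
    again = filter_low_abundance(out)
    assert np.array_equal(again.matrix, out.matrix)


def test_filters_require_tpm_units():
    table = _tpm_table([[1.0, 2.0]])
    logged = log_normalize(table)
    assert logged.units == "log2_tpm1"
    with pytest.raises(UnitsError):
        filter_low_abundance(logged)
    with pytest.raises(UnitsError):
        log_normalize(logged)


def test_log_normalize_values():
    table = _tpm_table([[0.0, 1.0, 3.0]])
    np.testing.assert_allclose(log_normalize(table).matrix, [[0.0, 1.0, 2.0]])


@settings(deadline=None, max_examples=30)
@given(
    st.lists(st.integers(min_value=0, max_value=10**9), min_size=2, max_size=20, unique=True)
)
def test_log_normalize_is_strictly_monotone(values):
    table = _tpm_table(np.array(values, dtype=float)[None, :])
    out = log_normalize(table).matrix[0]
    order_in = np.argsort(values)
    assert np.all(np.diff(out[order_in]) > 0)


def test_qc_filter_boundary_cells():
    n_genes = 3000
    genes = [f"G{i}" for i in range(n_genes - 1)] + ["MT-CO1"]
    counts = np.zeros((n_genes, 3), dtype=int)
    counts[:200, 0] = 1  # exactly 200 detected genes -> kept
    counts[:150, 1] = 1  # 150 detected -> removed
    counts[:250, 2] = 1
    counts[-1, 2] = 100  # heavy mitochondrial load -> removed
    kept = qc_filter_cells(counts, genes, ["MT-CO1"])
    assert list(kept) == [0]


def test_qc_filter_matches_per_cell_oracle(rng):
    n_genes, n_cells = 400, 50
    genes = [f"G{i}" for i in range(n_genes - 4)] + [f"MT-{i}" for i in range(4)]
    mito = [g for g in genes if g.startswith("MT-")]
    counts = rng.poisson(rng.uniform(0.1, 3.0, size=(1, n_cells)), size=(n_genes, n_cells))
    kept = qc_filter_cells(counts, genes, mito, min_genes=100, max_genes=320, max_mito=0.05)
    oracle = []
    mito_idx = [genes.index(g) for g in mito]
    for c in range(n_cells):
        col = counts[:, c]
        detected = int((col > 0).sum())
        total = col.sum()
        frac = col[mito_idx].sum() / total if total else 0.0
        if 100 <= detected <= 320 and frac <= 0.05:
            oracle.append(c)
    assert list(kept) == oracle


def test_qc_filter_warns_on_disjoint_mito_genes():
    with pytest.warns(UserWarning, match="mitochondrial"):
        qc_filter_cells(np.ones((5, 2), dtype=int), [f"G{i}" for i in range(5)], ["MT-X"])
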