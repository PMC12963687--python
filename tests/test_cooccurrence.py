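"""Spot classification, co-occurrence curves vs the O(n^2) oracle,
permutation inference, proximity rule, and BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlspatial.cooccurrence import (
    CLASS_NAMES,
    EmptyClassError,
    PairClassLabels,
    RadialBins,
    adjust_bh,
    binarize_scores,
    centroid_proximity,
    cooccurrence_curve,
    cooccurrence_permutation_test,
    pair_classes,
    permute_pair_labels,
)
from tlspatial.scoring import ScoreVector
from tlspatial.simulate import lattice_coords, simulate_null_labels


def brute_force_curve(coords, labels, condition, target, edges):
    """Literal double loop over all ordered pairs, per cumulative bin."""
    coords = np.asarray(coords, dtype=float)
    lab = np.asarray(labels)
    n = len(lab)
    p_target = np.sum(lab == target) / n
    ratios, counts = [], []
    for r in edges[1:]:
        cond_pairs = 0
        hits = 0
        for i in range(n):
            if lab[i] != condition:
                continue
            for k in range(n):
                if k == i:
                    continue
                if np.hypot(*(coords[i] - coords[k])) <= r:
                    cond_pairs += 1
                    hits += lab[k] == target
        counts.append(cond_pairs)
        ratios.append((hits / cond_pairs) / p_target if cond_pairs else np.nan)
    return np.array(ratios), np.array(counts)


def _labels(lab):
    return PairClassLabels(
        spot_ids=[f"s{i}" for i in range(len(lab))], labels=np.asarray(lab)
    )


# --------------------------------------------------------------------------
# binarization and pairing
# --------------------------------------------------------------------------

def _scores(values):
    return ScoreVector(
        unit_ids=[f"s{i}" for i in range(len(values))],
        scores=values,
        signature_name="x",
        method="mean_z",
    )


def test_binarize_rules():
    assert not binarize_scores(_scores([3.0, 3.0, 3.0])).any()
    assert list(binarize_scores(_scores([1, 2, 3, 4]))) == [False, False, True, True]
    values = np.random.default_rng(0).permutation(100).astype(float)
    assert binarize_scores(_scores(values), rule="quantile", q=0.75).sum() == 25
    with pytest.raises(ValueError):
        binarize_scores(_scores([1, 2]), rule="quantile", q=1.5)


def test_pair_classes_cross_product():
    out = pair_classes([True] * 3, [False] * 3)
    assert list(out.labels) == ["A+B-"] * 3
    a = [True, True, False, False, True, False]
    b = [True, False, True, False, False, True]
    out = pair_classes(a, b)
    assert list(out.labels) == ["A+B+", "A+B-", "A-B+", "A-B-", "A+B-", "A-B+"]
    counts = out.counts()
    assert counts == {"A+B+": 1, "A+B-": 2, "A-B+": 2, "A-B-": 1}


# --------------------------------------------------------------------------
# co-occurrence curves
# --------------------------------------------------------------------------

def test_uniform_target_class_gives_unit_ratio(square_coords):
    lab = ["A+B+"] * 18 + ["A-B+"] * 18  # every spot is B+... use full target class
    labels = _labels(["A+B+"] * 36)
    curve = cooccurrence_curve(
        square_coords, labels, "A+B+", "A+B+", RadialBins.regular(800, 8)
    )
    defined = curve.pair_counts > 0
    np.testing.assert_allclose(curve.ratio[defined], 1.0)


def test_five_spot_hand_layout_matches_oracle():
    coords = np.array([[0, 0], [100, 0], [0, 100], [300, 0], [500, 500]], dtype=float)
    lab = ["A+B+", "A-B+", "A+B+", "A-B-", "A-B+"]
    edges = np.array([0.0, 150.0, 350.0, 800.0])
    curve = cooccurrence_curve(
        coords, _labels(lab), "A+B+", "A-B+", RadialBins(edges)
    )
    oracle_ratio, oracle_counts = brute_force_curve(coords, lab, "A+B+", "A-B+", edges)
    np.testing.assert_array_equal(curve.pair_counts, oracle_counts)
    np.testing.assert_allclose(curve.ratio, oracle_ratio)


def test_all_class_pairs_match_oracle_exactly(rng):
    coords = rng.uniform(0, 2000, size=(60, 2))
    lab = rng.choice(np.array(CLASS_NAMES), size=60)
    labels = _labels(lab)
    bins = RadialBins.regular(3000, 6)
    for cond in CLASS_NAMES:
        for targ in CLASS_NAMES:
            if not (lab == cond).any() or not (lab == targ).any():
                continue
            curve = cooccurrence_curve(coords, labels, cond, targ, bins)
            oracle_ratio, oracle_counts = brute_force_curve(
                coords, lab, cond, targ, bins.edges
            )
            np.testing.assert_array_equal(curve.pair_counts, oracle_counts)
            np.testing.assert_allclose(curve.ratio, oracle_ratio, rtol=1e-12)


def test_empty_or_absent_classes_raise(square_coords):
    labels = _labels(["A+B+"] * 36)
    with pytest.raises(EmptyClassError):
        cooccurrence_curve(square_coords, labels, "A-B-", "A+B+")
    with pytest.raises(EmptyClassError):
        cooccurrence_curve(square_coords, labels, "A+B+", "A-B-")


# --------------------------------------------------------------------------
# centroid proximity
# --------------------------------------------------------------------------

def test_proximity_boundary_is_inclusive():
    res = centroid_proximity([[0.0, 0.0]], [[49.0, 0.0]])
    assert res.flags_a[0]
    res = centroid_proximity([[0.0, 0.0]], [[50.0, 0.0]])
    assert res.flags_a[0]  # "within 50 um" includes the boundary
    res = centroid_proximity([[0.0, 0.0]], [[50.001, 0.0]])
    assert not res.flags_a[0]


def test_proximity_matches_all_pairs_oracle(rng):
    a = rng.uniform(0, 400, size=(40, 2))
    b = rng.uniform(0, 400, size=(40, 2))
    res = centroid_proximity(a, b, radius_um=50)
    d = np.linalg.norm(a[:, None] - b[None], axis=2)
    np.testing.assert_array_equal(res.flags_a, (d <= 50).any(axis=1))
    oracle_pairs = sorted(zip(*np.nonzero(d <= 50)))
    assert sorted(map(tuple, res.pairs)) == [tuple(map(int, p)) for p in oracle_pairs]


def test_proximity_empty_sets():
    res = centroid_proximity(np.empty((0, 2)), [[1.0, 1.0]])
    assert res.flags_a.size == 0 and res.pairs.size == 0
    res = centroid_proximity([[1.0, 1.0]], np.empty((0, 2)))
    assert not res.flags_a[0]


# --------------------------------------------------------------------------
# permutation machinery
# --------------------------------------------------------------------------

def test_permutation_conserves_contingency_and_is_seeded():
    labels = simulate_null_labels(200, (0.1, 0.2, 0.3, 0.4), seed=1)
    shuffled = permute_pair_labels(labels, seed=9)
    assert shuffled.counts() == labels.counts()
    assert np.array_equal(
        shuffled.labels, permute_pair_labels(labels, seed=9).labels
    )
    single = _labels(["A+B+"])
    assert np.array_equal(permute_pair_labels(single, seed=0).labels, single.labels)


def test_permtest_addone_floor_on_extreme_clustering():
    """A tight corner block of double-positive spots exceeds every one of 19
    null values, so p hits the add-one floor 1/20 = 0.05."""
    coords = lattice_coords("square", 10, 10, 100.0)
    lab = np.array(["A-B-"] * 100)
    lab[[0, 1, 2, 10, 11]] = "A+B+"
    res = cooccurrence_permutation_test(
        coords, _labels(lab), "A+B+", "A+B+",
        bins=RadialBins.regular(1000, 10), n_perm=19, seed=5,
    )
    assert res.pvalue == pytest.approx(0.05)
    assert res.observed > res.null.max()


def test_permtest_result_invariants(rng):
    coords = rng.uniform(0, 1500, size=(80, 2))
    labels = simulate_null_labels(80, seed=3)
    res = cooccurrence_permutation_test(
        coords, labels, "A+B-", "A-B+", n_perm=49, seed=11
    )
    assert res.pvalue >= 1 / 50
    assert res.ci_low <= np.median(res.null) <= res.ci_high
    assert res.n_perm == 49
    # the alternative flips consistently
    res_less = cooccurrence_permutation_test(
        coords, labels, "A+B-", "A-B+", n_perm=49, alternative="less", seed=11
    )
    ge = np.sum(res.null >= res.observed)
    le = np.sum(res_less.null <= res_less.observed)
    assert res.pvalue == pytest.approx((1 + ge) / 50)
    assert res_less.pvalue == pytest.approx((1 + le) / 50)


# --------------------------------------------------------------------------
# BH adjustment
# --------------------------------------------------------------------------

def bh_oracle(p):
    """Step-up formula, written directly."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def test_bh_matches_step_up_oracle():
    np.testing.assert_allclose(adjust_bh([0.2]), [0.2])
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), rtol=1e-12)
    rng = np.random.default_rng(8)
    for _ in range(5):
        p = rng.uniform(size=12)
        np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), rtol=1e-12)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_never_decreases_p(p):
    q = adjust_bh(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)
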