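"""Co-expression machinery: PCC pairing, soft power, TOM (against a
brute-force oracle), module detection and module significance."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tadscope import (
    adjacency,
    detect_modules,
    module_eigengenes,
    module_significance,
    pcc_pairs,
    pick_soft_power,
    tom,
)
from tests.conftest import random_symmetric_adjacency


def tom_brute_force(a):
    """Triple-loop topological overlap, straight from the definition."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


# ----------------------------------------------------------------------
# pcc pairs


def _expr(rows, ids, cols=6):
    return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(cols)])


def test_pcc_identical_vectors_retained_anticorrelated_not():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    lnc = _expr([x, [-v for v in x]], ["lnc_pos", "lnc_neg"])
    mrna = _expr([x], ["m1"])
    pairs = pcc_pairs(lnc, mrna, r_min=0.9)
    assert set(pairs["lnc_id"]) == {"lnc_pos"}  # r = -1 fails one-sided r > 0.9
    pairs_abs = pcc_pairs(lnc, mrna, r_min=0.9, use_abs=True)
    assert set(pairs_abs["lnc_id"]) == {"lnc_pos", "lnc_neg"}
    assert pairs_abs.set_index("lnc_id").loc["lnc_neg", "r"] == pytest.approx(-1.0)


def test_pcc_value_matches_hand_formula():
    lnc = _expr([[1, 2, 3, 4, 5, 6]], ["l"])
    mrna = _expr([[2, 4, 6, 8, 10, 12]], ["m"])
    pairs = pcc_pairs(lnc, mrna, r_min=0.5)
    assert pairs["r"].iloc[0] == pytest.approx(1.0)


def test_pcc_affine_invariance_and_zero_variance_skip():
    rng = np.random.default_rng(0)
    base = rng.normal(size=6)
    lnc = _expr([base, np.full(6, 3.0)], ["l", "flat"])
    mrna = _expr([2.5 * base + 7.0], ["m"])
    pairs = pcc_pairs(lnc, mrna, r_min=0.9)
    assert list(pairs["lnc_id"]) == ["l"]
    assert pairs["r"].iloc[0] == pytest.approx(1.0)


def test_pcc_needs_three_samples():
    with pytest.raises(ValueError, match="3 samples"):
        pcc_pairs(_expr([[1, 2]], ["l"], cols=2), _expr([[1, 2]], ["m"], cols=2))


# ----------------------------------------------------------------------
# TOM


def test_tom_two_node_closed_form():
    for x in (0.0, 0.3, 0.9):
        t = tom(np.array([[0.0, x], [x, 0.0]]))
        assert t[0, 1] == pytest.approx(x)
        assert t[0, 0] == 1.0


def test_tom_disconnected_cliques():
    a = np.zeros((6, 6))
    for block in (slice(0, 3), slice(3, 6)):
        a[block, block] = 1.0
    np.fill_diagonal(a, 0.0)
    t = tom(a)
    assert np.allclose(t[:3, :3], 1.0)
    assert np.allclose(t[:3, 3:], 0.0)


def test_tom_zero_adjacency():
    t = tom(np.zeros((5, 5)))
    assert np.allclose(t - np.eye(5), 0.0)


def test_tom_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        a = random_symmetric_adjacency(rng, 20)
        assert np.abs(tom(a) - tom_brute_force(a)).max() < 1e-10


def test_tom_rejects_invalid_adjacency():
    with pytest.raises(ValueError):
        tom(np.array([[0.0, 1.5], [1.5, 0.0]]))
    with pytest.raises(ValueError):
        tom(np.array([[0.0, 0.1], [0.9, 0.0]]))


# ----------------------------------------------------------------------
# soft power


def _module_expr(rng, n_modules=3, size=40, n_noise=40, n_samples=6):
    # factors orthogonal after centering (QR against the ones vector):
    # with a handful of samples, independently drawn factors are collinear
    # often enough to merge planted blocks by chance
    raw = np.hstack([np.ones((n_samples, 1)), rng.normal(size=(n_samples, n_modules))])
    q, _ = np.linalg.qr(raw)
    rows, ids = [], []
    for m in range(n_modules):
        f = q[:, m + 1] * np.sqrt(n_samples)
        for g in range(size):
            rows.append(rng.uniform(0.5, 1.0) * f + rng.normal(scale=0.2, size=n_samples))
            ids.append(f"M{m}_{g}")
    for g in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        ids.append(f"bg_{g}")
    return pd.DataFrame(rows, index=ids)


def test_pick_soft_power_contracts():
    rng = np.random.default_rng(1)
    expr = _module_expr(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, table = pick_soft_power(expr)
    assert beta in set(table["power"])
    # singleton candidate set is returned regardless of fit quality
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta6, _ = pick_soft_power(expr, candidate_powers=[6])
    assert beta6 == 6
    with pytest.raises(ValueError, match="30 features"):
        pick_soft_power(expr.head(10))


def test_pick_soft_power_degenerate_identical_features_warns():
    expr = pd.DataFrame(np.tile(np.arange(6.0), (40, 1)),
                        index=[f"g{i}" for i in range(40)])
    with pytest.warns(UserWarning):
        pick_soft_power(expr)


# ----------------------------------------------------------------------
# module detection


def test_detect_modules_recovers_planted_blocks_and_is_permutation_invariant():
    rng = np.random.default_rng(3)
    expr = _module_expr(rng)
    ids = list(expr.index)
    t = tom(adjacency(expr, beta=6).to_numpy())
    ms = detect_modules(t, ids, min_size=30)
    truth = pd.Series([i.split("_")[0] for i in ids], index=ids)
    from sklearn.metrics import adjusted_rand_score

    members = truth.index[truth.str.startswith("M")]
    assert adjusted_rand_score(truth[members], ms.labels[members]) >= 0.8
    assert set(ms.labels) - {"grey"} == {"turquoise", "blue", "brown"}
    # permutation invariance of the partition
    perm = rng.permutation(len(ids))
    ids_p = [ids[i] for i in perm]
    t_p = t[np.ix_(perm, perm)]
    ms_p = detect_modules(t_p, ids_p, min_size=30)
    assert (ms_p.labels.reindex(ids) == ms.labels).all()


def test_detect_modules_min_size_larger_than_n_makes_everything_grey():
    rng = np.random.default_rng(0)
    t = tom(random_symmetric_adjacency(rng, 10))
    with pytest.warns(UserWarning, match="grey"):
        ms = detect_modules(t, [f"g{i}" for i in range(10)], min_size=11)
    assert set(ms.labels) == {"grey"}


def test_single_planted_module_yields_one_label():
    rng = np.random.default_rng(5)
    expr = _module_expr(rng, n_modules=1, size=40, n_noise=20)
    t = tom(adjacency(expr, beta=6).to_numpy())
    ms = detect_modules(t, list(expr.index), min_size=30)
    assert set(ms.labels) - {"grey"} == {"turquoise"}


# ----------------------------------------------------------------------
# eigengenes & significance


def test_module_eigengene_tracks_shared_factor():
    rng = np.random.default_rng(9)
    f = rng.normal(size=6)
    expr = pd.DataFrame(
        [w * f + rng.normal(scale=0.1, size=6) for w in rng.uniform(0.5, 1, 35)],
        index=[f"g{i}" for i in range(35)],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series("turquoise", index=expr.index)
    eig = module_eigengenes(expr, labels)
    r = np.corrcoef(eig.loc["turquoise"], f)[0, 1]
    assert abs(r) > 0.95
    # sign orientation: positive mean loading
    loadings = expr.sub(expr.mean(axis=1), axis=0).to_numpy() @ eig.loc["turquoise"].to_numpy()
    assert loadings.mean() > 0


def test_module_significance_definitions():
    de = pd.DataFrame({"p": [1.0, 1.0, 1e-4, 1e-2]}, index=["a", "b", "c", "d"])
    labels = pd.Series(
        {"a": "blue", "b": "blue", "c": "red", "d": "grey"}, name="module"
    )
    sig, selected = module_significance(labels, de, top_k=1)
    assert sig["blue"] == pytest.approx(0.0)
    assert sig["red"] == pytest.approx(4.0)  # single member: its own -log10 p
    assert selected == ["red"]


def test_module_significance_ranks_de_module_first():
    de = pd.DataFrame(
        {"p": [1e-6] * 30 + [0.5] * 30}, index=[f"g{i}" for i in range(60)]
    )
    labels = pd.Series(
        ["turquoise"] * 30 + ["blue"] * 30, index=de.index, name="module"
    )
    sig, selected = module_significance(labels, de, top_k=2)
    assert selected[0] == "turquoise"
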