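"""Differential-expression chain: size factors, detection, the paired NB
Wald test, BH adjustment, class filters and heatmap ordering."""

import numpy as np
import pandas as pd
import pytest

from tadscope import (
    CountMatrix,
    adjust_bh,
    detection_filter,
    filter_de,
    heatmap_order,
    log2_normalized,
    paired_nb_test,
    run_de,
    simulate_study,
    size_factors_median_of_ratios,
)
from tadscope.config import SimulationConfig


def _cm(counts, design=None):
    if design is None:
        n = counts.shape[1] // 2
        design = pd.DataFrame(
            {
                "sample": counts.columns,
                "patient": [f"P{i // 2 + 1}" for i in range(counts.shape[1])],
                "condition": ["normal", "lesion"] * n,
            }
        )
    return CountMatrix(counts, design, pd.Series("mRNA", index=counts.index))


# ----------------------------------------------------------------------
# size factors


def test_identical_columns_give_unit_size_factors(toy_count_matrix):
    counts = toy_count_matrix.counts.copy()
    for c in counts.columns:
        counts[c] = counts.iloc[:, 0]
    sf = size_factors_median_of_ratios(_cm(counts))
    assert np.allclose(sf, 1.0)


def test_doubled_column_has_twice_the_size_factor():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(5, 200, size=(5, 3)),
        columns=["P1_normal", "P1_lesion", "P2_normal"],
        index=[f"g{i}" for i in range(5)],
    )
    counts["P2_lesion"] = counts["P1_normal"] * 2
    sf = size_factors_median_of_ratios(_cm(counts))
    assert sf["P2_lesion"] == pytest.approx(2.0 * sf["P1_normal"], rel=1e-9)


def test_single_sample_size_factor_is_one():
    # a single sample cannot satisfy the paired-design invariant, so build
    # the container without validation: normalization of one is trivially 1
    from tadscope.diffexpr import CountMatrix as CM

    cm = object.__new__(CM)
    cm.counts = pd.DataFrame({"P1_normal": [5, 10, 20]}, index=["a", "b", "c"])
    cm.design = pd.DataFrame(
        {"patient": ["P1"], "condition": ["normal"]}, index=["P1_normal"]
    )
    cm.class_of = pd.Series("mRNA", index=cm.counts.index)
    assert np.allclose(size_factors_median_of_ratios(cm), 1.0)


def test_size_factor_invariances(toy_count_matrix):
    sf = size_factors_median_of_ratios(toy_count_matrix)
    assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-9)
    # feature-order invariance
    shuffled = toy_count_matrix.counts.sample(frac=1, random_state=1)
    sf2 = size_factors_median_of_ratios(_cm(shuffled))
    assert np.allclose(sf, sf2)
    # global count rescaling leaves (geomean-1) factors unchanged
    sf3 = size_factors_median_of_ratios(_cm(toy_count_matrix.counts * 5))
    assert np.allclose(sf, sf3)


def test_no_all_positive_feature_errors_and_pseudo_reference_fallback():
    counts = pd.DataFrame(
        {
            "P1_normal": [0, 4],
            "P1_lesion": [3, 0],
            "P2_normal": [5, 6],
            "P2_lesion": [2, 8],
        },
        index=["a", "b"],
    )
    cm = _cm(counts)
    with pytest.raises(ValueError, match="pseudo_reference"):
        size_factors_median_of_ratios(cm)
    sf = size_factors_median_of_ratios(cm, pseudo_reference=True)
    assert (sf > 0).all()


# ----------------------------------------------------------------------
# detection


def test_detection_requires_positive_counts_in_every_sample(toy_count_matrix):
    detected = detection_filter(toy_count_matrix)
    assert not detected["g4"]  # zero in one sample
    assert detected[["g0", "g1", "g2", "g3"]].all()


def test_detection_single_patient_degenerates_to_two_samples():
    counts = pd.DataFrame(
        {"P1_normal": [1, 0], "P1_lesion": [2, 5]}, index=["a", "b"]
    )
    detected = detection_filter(_cm(counts))
    assert detected["a"] and not detected["b"]


def test_design_validation_rejects_unpaired_samples():
    counts = pd.DataFrame(
        {"s1": [1], "s2": [2], "s3": [3]}, index=["g"]
    )
    design = pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3"],
            "patient": ["P1", "P1", "P2"],
            "condition": ["normal", "lesion", "lesion"],
        }
    )
    with pytest.raises(ValueError, match="exactly one sample"):
        CountMatrix(counts, design, pd.Series("mRNA", index=counts.index))


# ----------------------------------------------------------------------
# the paired NB test


def test_null_by_symmetry_gives_zero_lfc_and_p_one():
    counts = pd.DataFrame(
        {
            "P1_normal": [50, 200, 7],
            "P1_lesion": [50, 200, 7],
            "P2_normal": [60, 180, 9],
            "P2_lesion": [60, 180, 9],
            "P3_normal": [55, 210, 8],
            "P3_lesion": [55, 210, 8],
        },
        index=["a", "b", "c"],
    )
    cm = _cm(counts)
    res = paired_nb_test(cm, size_factors_median_of_ratios(cm))
    assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
    assert np.allclose(res["p"], 1.0, atol=1e-6)


def test_large_count_fold_change_matches_moment_estimate():
    """Poisson-like counts in the thousands at a 4x fold: the fitted log2FC
    lands within 0.05 of the log2 ratio of normalized means."""
    rng = np.random.default_rng(5)
    base = rng.integers(2_000, 8_000, size=50)
    cols = {}
    for p in (1, 2, 3):
        cols[f"P{p}_normal"] = rng.poisson(base)
        cols[f"P{p}_lesion"] = rng.poisson(base * 4)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(50)])
    cm = _cm(counts)
    sf = size_factors_median_of_ratios(cm)
    res = paired_nb_test(cm, sf)
    norm = counts.div(sf, axis=1)
    lesion = [c for c in counts.columns if c.endswith("lesion")]
    normal = [c for c in counts.columns if c.endswith("normal")]
    moment = np.log2(norm[lesion].mean(axis=1) / norm[normal].mean(axis=1))
    assert (res["log2fc"] - moment).abs().max() < 0.05


def test_all_zero_condition_uses_pseudo_count_and_flags():
    counts = pd.DataFrame(
        {
            "P1_normal": [0, 10],
            "P1_lesion": [40, 12],
            "P2_normal": [0, 9],
            "P2_lesion": [35, 11],
            "P3_normal": [0, 10],
            "P3_lesion": [42, 10],
        },
        index=["onoff", "flat"],
    )
    cm = _cm(counts)
    res = paired_nb_test(cm, size_factors_median_of_ratios(cm, pseudo_reference=True))
    assert res.loc["onoff", "flag"] == "pseudo_count"
    assert res.loc["onoff", "log2fc"] > 3
    assert res.loc["flat", "flag"] == "ok"


def test_simulated_null_type_one_error_in_band(flat_sim_config):
    """Global null: the fraction of raw p < 0.05 stays near nominal."""
    cfg = SimulationConfig(**{**flat_sim_config.__dict__, "de_fraction_per_class": 0.0,
                              "n_mrna": 2000, "seed": 13})
    study = simulate_study(cfg)
    cm = CountMatrix(
        study.counts, study.design, study.annotation.set_index("feature_id")["rna_class"]
    )
    res = run_de(cm)
    frac = float((res.loc[res["detected"], "p"] < 0.05).mean())
    assert 0.03 <= frac <= 0.08


# ----------------------------------------------------------------------
# BH


def bh_step_up_oracle(p):
    """Textbook BH step-up, evaluated directly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_known_values(p, expected):
    assert np.allclose(adjust_bh(p), expected)


def test_bh_matches_direct_step_up_formula_and_handles_nan():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    assert np.allclose(adjust_bh(p), bh_step_up_oracle(p), atol=1e-12)
    # reordering stability
    perm = rng.permutation(200)
    assert np.allclose(adjust_bh(p[perm]), bh_step_up_oracle(p)[perm], atol=1e-12)
    withnan = np.array([0.01, np.nan, 0.5])
    q = adjust_bh(withnan)
    assert np.isnan(q[1]) and np.allclose(q[[0, 2]], bh_step_up_oracle([0.01, 0.5]))


# ----------------------------------------------------------------------
# filters


def _de_frame(rows):
    df = pd.DataFrame(rows).set_index("feature_id")
    df["detected"] = df.get("detected", True)
    return df


def test_filter_de_published_thresholds():
    de = _de_frame(
        [
            {"feature_id": "m_up", "rna_class": "mRNA", "log2fc": 2.5, "p": 1e-4, "q": 0.01},
            {"feature_id": "m_edge", "rna_class": "mRNA", "log2fc": 2.0, "p": 1e-4, "q": 0.01},
            {"feature_id": "m_weak", "rna_class": "mRNA", "log2fc": 1.5, "p": 1e-4, "q": 0.01},
            {"feature_id": "mi_small", "rna_class": "miRNA", "log2fc": 0.5, "p": 1e-4, "q": 0.01},
            {"feature_id": "mi_ok", "rna_class": "miRNA", "log2fc": -0.67, "p": 1e-4, "q": 0.01},
        ]
    )
    up, down = filter_de(de, "mRNA")
    assert up == ["m_edge", "m_up"] and down == []  # >= is inclusive at the cut
    up_mi, down_mi = filter_de(de, "miRNA")
    assert up_mi == [] and down_mi == ["mi_ok"]  # 0.5 < 0.67 dropped


def test_filter_de_unknown_class_errors():
    with pytest.raises(ValueError, match="thresholds"):
        filter_de(_de_frame([{"feature_id": "x", "rna_class": "mRNA",
                              "log2fc": 3.0, "p": 0.1, "q": 0.2}]), "circRNA")


def test_undetected_features_never_pass(toy_count_matrix):
    res = run_de(toy_count_matrix)
    assert not res.loc["g4", "detected"]
    up, down = filter_de(res, "mRNA", {"mRNA": ("raw", 1.0, 0.0)})
    assert "g4" not in up + down


# ----------------------------------------------------------------------
# heatmap ordering


def test_heatmap_order_identical_rows_adjacent_and_closest_pair_merges_first():
    expr = pd.DataFrame(
        [[0.0, 0.0], [10.0, 10.0], [0.0, 0.0], [10.5, 10.2]],
        index=["a", "b", "a2", "b2"],
        columns=["s1", "s2"],
    )
    rows, cols = heatmap_order(expr)
    order = list(expr.index[rows])
    assert abs(order.index("a") - order.index("a2")) == 1
    assert abs(order.index("b") - order.index("b2")) == 1


def test_heatmap_order_permutation_invariant_topology():
    """Leaf orders may flip branches, but the nearest pair stays adjacent
    and the leaf multiset is preserved under input permutation."""
    rng = np.random.default_rng(8)
    expr = pd.DataFrame(rng.normal(size=(12, 6)), index=[f"g{i}" for i in range(12)])
    d = ((expr.to_numpy()[:, None, :] - expr.to_numpy()[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    nearest = {expr.index[i], expr.index[j]}
    for permuted in (expr, expr.iloc[rng.permutation(12)]):
        rows, _ = heatmap_order(permuted)
        order = list(permuted.index[rows])
        assert sorted(order) == sorted(expr.index)
        pos = {g: k for k, g in enumerate(order)}
        a, b = sorted(nearest)
        assert abs(pos[a] - pos[b]) == 1


def test_log2_normalized_scale(toy_count_matrix):
    sf = size_factors_median_of_ratios(toy_count_matrix)
    expr = log2_normalized(toy_count_matrix.counts, sf)
    manual = np.log2(toy_count_matrix.counts["P1_normal"] / sf["P1_normal"] + 1)
    assert np.allclose(expr["P1_normal"], manual)
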