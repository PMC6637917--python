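"""Normalization, fold change, significance and SSG classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from topoclust import diffexpr, simulate
from topoclust.io import ExpressionMatrix, ParameterError

from conftest import make_count_matrix


def brute_force_uq(values):
    """Independent oracle: sort nonzero values, take the element at
    0-based index floor(0.75 * n)."""
    nz = sorted(v for v in values if v > 0)
    return nz[int(math.floor(0.75 * len(nz)))]


def expr_from(data: dict, conditions: dict) -> ExpressionMatrix:
    df = pd.DataFrame(data).T.astype(float)
    samples = pd.DataFrame(
        [{"sample": s, "condition": c, "replicate": i + 1}
         for i, (s, c) in enumerate(conditions.items())]
    ).set_index("sample")
    return ExpressionMatrix(df, samples)


# -------------------------------------------------------------- upper quartile


def test_upper_quartile_matches_spec_example():
    assert diffexpr.upper_quartile([10, 20, 30, 40]) == 40


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=1,
                max_size=60).filter(lambda xs: any(x > 0 for x in xs)))
def test_upper_quartile_matches_brute_force(xs):
    assert diffexpr.upper_quartile(xs) == brute_force_uq(xs)


def test_normalize_identical_samples_are_scaled_copies():
    cm = make_count_matrix(
        {"g1": {"a": 10, "b": 10}, "g2": {"a": 40, "b": 40}},
        {"a": "x", "b": "x"},
    )
    expr = diffexpr.normalize_upper_quartile(cm, reference_scale=100.0)
    assert (expr.values["a"] == expr.values["b"]).all()
    assert expr.values.at["g2", "a"] == pytest.approx(40 / 40 * 100)


def test_normalize_scale_invariance():
    """Doubling one sample's counts leaves its normalized column unchanged."""
    cm = make_count_matrix(
        {"g1": {"a": 10, "b": 20}, "g2": {"a": 40, "b": 80}, "g3": {"a": 7, "b": 14}},
        {"a": "x", "b": "x"},
    )
    expr = diffexpr.normalize_upper_quartile(cm)
    pd.testing.assert_series_equal(
        expr.values["a"], expr.values["b"], check_names=False
    )


def test_normalize_zeros_stay_zero_and_uq_equalized():
    cm = make_count_matrix(
        {"g1": {"a": 0, "b": 5}, "g2": {"a": 9, "b": 30}, "g3": {"a": 18, "b": 90}},
        {"a": "x", "b": "x"},
    )
    expr = diffexpr.normalize_upper_quartile(cm)
    assert expr.values.at["g1", "a"] == 0
    uqs = [diffexpr.upper_quartile(expr.values[c]) for c in expr.values.columns]
    assert uqs[0] == pytest.approx(uqs[1])


def test_normalize_all_zero_sample_errors_with_name():
    cm = make_count_matrix(
        {"g1": {"a": 0, "b": 5}, "g2": {"a": 0, "b": 3}},
        {"a": "x", "b": "x"},
    )
    with pytest.raises(ParameterError, match="'a'"):
        diffexpr.normalize_upper_quartile(cm)


# ----------------------------------------------------------------- fold change


def test_log2fc_identity_and_powers_of_two():
    expr = expr_from(
        {"eq": {"t1": 5, "t2": 5, "c1": 5, "c2": 5},
         "oct": {"t1": 8, "t2": 8, "c1": 1, "c2": 1}},
        {"t1": "T", "t2": "T", "c1": "C", "c2": "C"},
    )
    fc = diffexpr.log2_fold_change(expr, ("T", "C"))
    assert fc.at["eq", "log2fc"] == 0.0
    assert fc.at["oct", "log2fc"] == pytest.approx(3.0)


def test_log2fc_of_gyrase_operon_like_induction():
    """A 2.71-fold induction corresponds to log2FC ~ 1.44."""
    expr = expr_from(
        {"gyr": {"t1": 271, "t2": 271, "c1": 100, "c2": 100}},
        {"t1": "T", "t2": "T", "c1": "C", "c2": "C"},
    )
    fc = diffexpr.log2_fold_change(expr, ("T", "C"))
    assert fc.at["gyr", "log2fc"] == pytest.approx(math.log2(2.71))
    assert fc.at["gyr", "log2fc"] == pytest.approx(1.44, abs=0.005)


def test_log2fc_antisymmetric_under_contrast_swap():
    expr = expr_from(
        {"g": {"t1": 30, "t2": 34, "c1": 9, "c2": 11}},
        {"t1": "T", "t2": "T", "c1": "C", "c2": "C"},
    )
    a = diffexpr.log2_fold_change(expr, ("T", "C")).at["g", "log2fc"]
    b = diffexpr.log2_fold_change(expr, ("C", "T")).at["g", "log2fc"]
    assert a == pytest.approx(-b)


def test_log2fc_zero_mean_handling():
    expr = expr_from(
        {"one_zero": {"t1": 8, "t2": 8, "c1": 0, "c2": 0},
         "both_zero": {"t1": 0, "t2": 0, "c1": 0, "c2": 0}},
        {"t1": "T", "t2": "T", "c1": "C", "c2": "C"},
    )
    fc = diffexpr.log2_fold_change(expr, ("T", "C"))
    assert fc.at["one_zero", "fc_flag"] == "zero_mean_pseudocount"
    assert fc.at["one_zero", "log2fc"] == pytest.approx(math.log2(9))
    assert fc.at["both_zero", "fc_flag"] == "both_zero"
    assert np.isnan(fc.at["both_zero", "log2fc"])


# ---------------------------------------------------------------- significance


def welch_p(a, b):
    """Closed-form Welch t with Welch-Satterthwaite df, on log2(x+1)."""
    a = np.log2(np.asarray(a, float) + 1)
    b = np.log2(np.asarray(b, float) + 1)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


def test_significance_identical_groups_p_one():
    expr = expr_from(
        {"g": {"t1": 5, "t2": 5, "c1": 5, "c2": 5}},
        {"t1": "T", "t2": "T", "c1": "C", "c2": "C"},
    )
    sig = diffexpr.test_significance(expr, ("T", "C"))
    assert sig.at["g", "p_value"] == 1.0


def test_significance_matches_closed_form_welch():
    a, b = [5, 6, 7], [500, 520, 480]
    expr = expr_from(
        {"g": dict(zip(["t1", "t2", "t3", "c1", "c2", "c3"], a + b))},
        {"t1": "T", "t2": "T", "t3": "T", "c1": "C", "c2": "C", "c3": "C"},
    )
    sig = diffexpr.test_significance(expr, ("T", "C"))
    assert sig.at["g", "p_value"] == pytest.approx(welch_p(a, b), rel=1e-9)
    assert sig.at["g", "p_value"] < 0.05


def test_bh_step_up_by_hand():
    """BH on [0.01, 0.02, 0.03, 0.04] gives q = 0.04 everywhere."""
    from statsmodels.stats.multitest import multipletests
    q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    # independent hand computation of the step-up procedure
    p = [0.01, 0.02, 0.03, 0.04]
    m = len(p)
    raw = [p[i] * m / (i + 1) for i in range(m)]
    hand = [min(raw[i:]) for i in range(m)]
    assert list(q) == pytest.approx(hand)
    assert list(q) == pytest.approx([0.04] * 4)


# -------------------------------------------------------------- classification


@pytest.mark.parametrize(
    "log2fc,p,exempt,expected",
    [
        (9.75, 0.001, False, "up"),          # strongly induced SHC-type gene
        (1.22, 0.001, False, "not_significant"),  # inside the eliminated band
        (-0.40, 0.01, True, "down"),         # exempted NAP-like gene, p alone
        (-0.40, 0.01, False, "not_significant"),
        (-2.0, 0.2, False, "not_significant"),
        (-2.0, 0.01, False, "down"),
    ],
)
def test_classify_ssg_rules(log2fc, p, exempt, expected):
    diff = pd.DataFrame({"log2fc": [log2fc], "p_value": [p]}, index=["g"])
    out = diffexpr.classify_ssg(diff, exemption_list=["g"] if exempt else [])
    assert out.at["g", "ssg_class"] == expected


def test_classify_threshold_is_strict():
    diff = pd.DataFrame({"log2fc": [1.5, np.nextafter(1.5, 2)],
                         "p_value": [0.001, 0.001]}, index=["at", "above"])
    out = diffexpr.classify_ssg(diff)
    assert out.at["at", "ssg_class"] == "not_significant"
    assert out.at["above", "ssg_class"] == "up"


# --------------------------------------------------------------------- summary


def test_summarize_specificity_percentages():
    """408 specific of 552, and 70 of 214, reproduce the printed 73.9% / 32%."""
    down = [f"d{i}" for i in range(552)]
    up_shared = down[408:]  # 144 shared
    up = up_shared + [f"u{i}" for i in range(70)]
    mk = lambda tags: pd.DataFrame(
        {"log2fc": 2.0, "p_value": 0.01, "ssg_class": "up"}, index=tags
    )
    summary = diffexpr.summarize_affected(
        {"topA_down": mk(down), "topA_up": mk(up)}, total_genes=7900
    )
    s = summary.set_index("contrast")
    assert s.at["topA_down", "n_affected"] == 552
    assert s.at["topA_down", "pct_of_genome"] == pytest.approx(7.0, abs=0.05)
    assert s.at["topA_down", "n_specific"] == 408
    assert s.at["topA_down", "pct_specific"] == pytest.approx(73.9, abs=0.05)
    assert s.at["topA_up", "n_affected"] == 214
    assert s.at["topA_up", "pct_of_genome"] == pytest.approx(2.7, abs=0.05)
    assert s.at["topA_up", "pct_specific_floor"] == 32


def test_summarize_empty_results_all_zero():
    empty = pd.DataFrame({"log2fc": [], "p_value": [], "ssg_class": []})
    summary = diffexpr.summarize_affected({"c": empty}, total_genes=100)
    row = summary.iloc[0]
    assert row["n_affected"] == 0 and row["pct_of_genome"] == 0.0


# -------------------------------------------------------------------- recovery


def test_recovery_on_planted_effects_seed_pinned():
    """Planted |log2 effect| 3 at baseline 200, dispersion 0.05, 3 replicates:
    classification recovers >=90% of planted genes with <=5% false positives."""
    d = simulate.SyntheticDesign(
        seed=11, genome_length=300_000, n_genes=270,
        conditions=(("control", 3), ("treated", 3)),
        baseline_mean=200.0, nb_dispersion=0.05,
        planted_clusters=(
            simulate.PlantedCluster(20_000, 60_000, "up", log2_effect=3.0,
                                    fraction=0.5, condition="treated"),
            simulate.PlantedCluster(180_000, 220_000, "down", log2_effect=-3.0,
                                    fraction=0.5, condition="treated"),
        ),
    )
    g = simulate.simulate_genome(d)
    genes, _ = simulate.simulate_annotation(d, g)
    cm, truth = simulate.simulate_counts(d, genes)
    diff = diffexpr.run_contrast(cm, ("treated", "control"))
    planted = set(truth["locus_tag"])
    called = set(diff.index[diff["ssg_class"].isin(["up", "down"])])
    sensitivity = len(called & planted) / len(planted)
    unaffected = set(diff.index) - planted
    fpr = len(called & unaffected) / len(unaffected)
    assert sensitivity >= 0.9
    assert fpr <= 0.05
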