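"""ROC construction, AUC equivalences, DeLong inference, Youden selection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metscreen.errors import DegenerateLabelsError, InsufficientDataError
from metscreen.experiments import (
    exhaustive_youden_scan,
    pairwise_concordance_auc,
)
from metscreen.roc import (
    auc_ci_bootstrap,
    auc_ci_delong,
    auc_trapezoid,
    build_roc,
    cutoff_report,
    derive_cutoffs_stratified,
    format_cutoff_table,
    youden_optimal_cutoff,
)


def _random_instance(rng, n_max=200):
    n = int(rng.integers(8, n_max + 1))
    scores = rng.normal(size=n)
    if rng.random() < 0.3:  # force ties sometimes
        scores = np.round(scores, 1)
    labels = rng.random(size=n) < rng.uniform(0.2, 0.8)
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels


def test_perfect_separation_has_unit_sens_and_spec():
    curve = build_roc([1, 2, 3, 4], [False, False, True, True])
    i = np.where(curve.thresholds == 2.5)[0][0]
    assert curve.sensitivity[i] == 1.0 and curve.specificity[i] == 1.0
    assert auc_trapezoid(curve) == 1.0


def test_curve_endpoints_and_monotonicity(rng):
    scores, labels = _random_instance(rng)
    curve = build_roc(scores, labels)
    assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
    assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0
    assert np.all(np.diff(curve.sensitivity) <= 0)
    assert np.all(np.diff(curve.specificity) >= 0)


def test_three_point_curve_matches_hand_count():
    curve = build_roc([1.0, 2.0, 3.0], [False, True, False])
    # thresholds -inf, 1.5, 2.5, +inf; single positive at 2, negatives 1 and 3
    np.testing.assert_array_equal(curve.thresholds, [-np.inf, 1.5, 2.5, np.inf])
    np.testing.assert_array_equal(curve.sensitivity, [1.0, 1.0, 0.0, 0.0])
    np.testing.assert_array_equal(curve.specificity, [0.0, 0.5, 0.5, 1.0])


def test_all_equal_scores_are_degenerate():
    curve = build_roc([2.0] * 6, [True, False, True, False, False, True])
    cutoff, sens, spec, j, degenerate = youden_optimal_cutoff(
        curve, scores=[2.0] * 6
    )
    assert degenerate and j == 0.0 and cutoff == 2.0


def test_single_class_labels_raise():
    with pytest.raises(DegenerateLabelsError):
        build_roc([1.0, 2.0], [True, True])


def test_auc_equals_pairwise_concordance(rng):
    for _ in range(200):
        scores, labels = _random_instance(rng)
        auc = auc_trapezoid(build_roc(scores, labels))
        assert auc == pytest.approx(
            pairwise_concordance_auc(scores, labels), abs=1e-12
        )


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(50):
        scores, labels = _random_instance(rng)
        auc = auc_trapezoid(build_roc(scores, labels))
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_auc_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    scores, labels = _random_instance(rng, n_max=60)
    auc = auc_trapezoid(build_roc(scores, labels))
    for f in (np.exp, lambda x: x**3, lambda x: 1 / (1 + np.exp(-x))):
        assert auc_trapezoid(build_roc(f(scores), labels)) == pytest.approx(
            auc, abs=1e-12
        )


def test_label_swap_mirrors_auc(rng):
    scores, labels = _random_instance(rng)
    auc = auc_trapezoid(build_roc(scores, labels))
    swapped = auc_trapezoid(build_roc(scores, ~labels))
    assert auc + swapped == pytest.approx(1.0, abs=1e-12)


def test_delong_null_pvalue_near_one():
    # symmetric construction with AUC exactly 0.5
    scores = np.array([1.0, 2.0, 3.0, 4.0] * 10)
    labels = np.array([True, False, False, True] * 10)
    lo, hi, p = auc_ci_delong(scores, labels)
    assert p == pytest.approx(1.0, abs=1e-9)
    assert lo < 0.5 < hi


def test_delong_ci_width_shrinks_like_root_n(rng):
    widths = []
    for n in (100, 400, 1600):
        w = []
        for _ in range(10):
            labels = np.arange(n) < n // 2
            scores = rng.normal(size=n) + labels
            lo, hi, _ = auc_ci_delong(scores, labels)
            w.append(hi - lo)
        widths.append(np.mean(w))
    assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)
    assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.25)


def test_bootstrap_ci_overlaps_delong(rng):
    labels = np.arange(200) < 80
    scores = rng.normal(size=200) + 0.9 * labels
    d_lo, d_hi, _ = auc_ci_delong(scores, labels)
    b_lo, b_hi, _ = auc_ci_bootstrap(scores, labels, n_boot=2000, seed=5)
    assert max(d_lo, b_lo) < min(d_hi, b_hi)  # intervals overlap
    assert abs(d_lo - b_lo) < 0.05 and abs(d_hi - b_hi) < 0.05


def test_delong_requires_two_per_class():
    with pytest.raises(InsufficientDataError):
        auc_ci_delong([1.0, 2.0, 3.0], [True, False, False])


def test_youden_matches_exhaustive_scan(rng):
    for _ in range(200):
        scores, labels = _random_instance(rng)
        curve = build_roc(scores, labels)
        _, sens, spec, j, _ = youden_optimal_cutoff(curve, scores=scores)
        j_star, _ = exhaustive_youden_scan(scores, labels)
        assert j == pytest.approx(j_star, abs=1e-12)


def test_youden_tie_break_prefers_sensitivity():
    # J ties at 0.5 for thresholds 1.5 (sens 1.0) and 3.5 (sens 0.5)
    cutoff, sens, spec, j, _ = youden_optimal_cutoff(
        build_roc([1.0, 2.0, 3.0, 4.0], [False, True, False, True])
    )
    assert cutoff == 1.5 and sens == 1.0 and j == pytest.approx(0.5)


def test_report_likelihood_ratio_identities(rng):
    for _ in range(50):
        scores, labels = _random_instance(rng)
        rep = cutoff_report(scores, labels)
        sens = rep.sensitivity / 100.0
        spec = rep.specificity / 100.0
        if spec < 1.0:
            assert rep.lr_pos == pytest.approx(sens / (1 - spec), abs=1e-12)
        if spec > 0.0:
            assert rep.lr_neg == pytest.approx((1 - sens) / spec, abs=1e-12)
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]


def test_stratified_cutoffs_cardinality_and_skips(analysis_df):
    table, skipped = derive_cutoffs_stratified(analysis_df)
    assert len(table) + len(skipped) == 12  # 6 strata x 2 indices
    assert len(table) >= 10  # default cohort has cases in every stratum

    # a stratum with no positive labels is skipped with a reason, not fatal
    df = analysis_df.copy()
    mask = (df["sex"] == "female") & (df["age_group"] == "children")
    df.loc[mask, "mets"] = False
    table2, skipped2 = derive_cutoffs_stratified(df)
    assert ("female/children" == skipped2["stratum"]).sum() == 2
    assert len(table2) + len(skipped2) == 12


def test_stratified_output_is_deterministic(analysis_df):
    a, _ = derive_cutoffs_stratified(analysis_df)
    b, _ = derive_cutoffs_stratified(analysis_df)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_format_rounds_only_presentation_columns(analysis_df):
    table, _ = derive_cutoffs_stratified(analysis_df)
    shown = format_cutoff_table(table)
    assert (shown["sensitivity_pct"] == shown["sensitivity_pct"].astype(int)).all()
    assert np.all(np.abs(shown["auc"] - table["auc"]) <= 5e-4)
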