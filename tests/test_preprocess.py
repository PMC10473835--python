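import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npxcc import preprocess
from npxcc.exceptions import ConfigError, IntegrityError
from npxcc.preprocess import (
    PreprocessConfig,
    apply_bridge,
    below_lod_fraction,
    compute_bridge_offsets,
    flag_outliers,
    lod_filter,
    pca_scores,
    preprocess_pipeline,
)
from npxcc.simulate import SimConfig, simulate_cohorts

from conftest import make_npx


def _bridge_pair(vals_a, vals_b, protein="p1"):
    """Two single-protein cohorts whose bridge samples are the given lists."""
    a = make_npx(
        pd.DataFrame({protein: vals_a}, index=[f"a{i}" for i in range(len(vals_a))]),
        cohort="A", bridge_rows=[f"a{i}" for i in range(len(vals_a))],
    )
    b = make_npx(
        pd.DataFrame({protein: vals_b}, index=[f"b{i}" for i in range(len(vals_b))]),
        cohort="B", bridge_rows=[f"b{i}" for i in range(len(vals_b))],
    )
    return a, b


def test_bridge_offset_explicit_medians():
    a, b = _bridge_pair([5, 5, 5, 5, 5, 5, 5, 7], [4, 4, 4, 4, 4, 4, 4, 6])
    off = compute_bridge_offsets(a, b)
    assert off.offset_x["p1"] == 1.0
    assert off.n_bridge_a == 8 and off.n_bridge_b == 8


def test_bridge_offset_identical_pools_is_zero():
    a, b = _bridge_pair([3.0, 4.0, 5.0, 6.0], [3.0, 4.0, 5.0, 6.0])
    assert compute_bridge_offsets(a, b).offset_x["p1"] == 0.0


@settings(max_examples=50, deadline=None)
@given(
    va=st.lists(st.floats(-10, 10, allow_nan=False), min_size=8, max_size=8),
    vb=st.lists(st.floats(-10, 10, allow_nan=False), min_size=8, max_size=8),
)
def test_bridge_offset_matches_sort_and_middle_oracle(va, vb):
    """X equals the brute-force midpoint-of-central-order-statistics median."""
    def naive_median(vals):
        s = sorted(vals)
        n = len(s)
        return (s[n // 2 - 1] + s[n // 2]) / 2 if n % 2 == 0 else s[n // 2]

    a, b = _bridge_pair(va, vb)
    off = compute_bridge_offsets(a, b)
    assert off.offset_x["p1"] == pytest.approx(naive_median(va) - naive_median(vb), abs=1e-12)


def test_bridge_undefined_offset_flagged():
    a, b = _bridge_pair([5.0], [4.0, 4.5])
    off = compute_bridge_offsets(a, b)
    assert off.undefined == ["p1"]
    assert np.isnan(off.offset_x["p1"])


def test_apply_bridge_equalizes_bridge_medians(small_pair):
    a, b, _, _ = small_pair
    off = compute_bridge_offsets(a, b)
    bridged = apply_bridge(a, off)
    diff = bridged.bridge_values().median() - b.bridge_values().median()
    assert diff.abs().max() <= 1e-9


def test_apply_bridge_zero_offsets_is_identity(small_pair):
    a, _, _, _ = small_pair
    off = compute_bridge_offsets(a, a)  # A against itself: X = 0 everywhere
    assert (off.offset_x == 0).all()
    bridged = apply_bridge(a, off)
    pd.testing.assert_frame_equal(bridged.values, a.values)


def test_bridging_translation_equivariance(small_pair):
    """Adding c to every cohort-A value shifts X by c and leaves the bridged
    matrix unchanged."""
    a, b, _, _ = small_pair
    c = 2.75
    shifted = a.copy()
    shifted.values = shifted.values + c
    off0 = compute_bridge_offsets(a, b)
    off1 = compute_bridge_offsets(shifted, b)
    assert np.allclose(off1.offset_x - off0.offset_x, c)
    pd.testing.assert_frame_equal(
        apply_bridge(shifted, off1).values, apply_bridge(a, off0).values
    )


def test_below_lod_counts_study_samples_only():
    vals = pd.DataFrame({"p1": [0.5] * 3 + [2.0] * 7 + [0.0, 0.0]},
                        index=[str(i) for i in range(12)])
    m = make_npx(vals, lod={"p1": 1.0}, bridge_rows=["10", "11"])  # 2 bridge rows below LOD
    frac = below_lod_fraction(m)
    assert frac["p1"] == pytest.approx(0.3)


def test_value_equal_to_lod_counts_as_detected():
    m = make_npx(pd.DataFrame({"p1": [1.0, 1.0, 2.0, 0.9]}), lod={"p1": 1.0})
    assert below_lod_fraction(m)["p1"] == pytest.approx(0.25)


@pytest.mark.parametrize(
    "fa, fb, mode, excl_a, excl_b",
    [
        (0.30, 0.30, "both", True, True),
        (0.30, 0.30, "either", True, True),
        (0.30, 0.20, "both", False, False),
        (0.30, 0.20, "per_cohort", True, False),
        (0.25, 0.25, "both", False, False),  # rule is strictly "more than"
        (0.25, 0.30, "per_cohort", False, True),
    ],
)
def test_lod_filter_rule_application(fa, fb, mode, excl_a, excl_b):
    frac_a = pd.Series({"p1": fa})
    frac_b = pd.Series({"p1": fb})
    res = lod_filter(frac_a, frac_b, threshold=0.25, mode=mode)
    assert (("p1" in res["excluded_a"]) == excl_a)
    assert (("p1" in res["excluded_b"]) == excl_b)


def test_lod_filter_threshold_range_checked():
    s = pd.Series({"p1": 0.1})
    with pytest.raises(ConfigError):
        lod_filter(s, s, threshold=1.5)


@settings(max_examples=30, deadline=None)
@given(st.floats(0.05, 0.45), st.floats(0.05, 0.45))
def test_lod_filter_monotone_in_threshold(t1, t2):
    """Raising the threshold never excludes more proteins."""
    lo, hi = sorted((t1, t2))
    rng = np.random.default_rng(5)
    frac_a = pd.Series(rng.uniform(0, 0.6, 30), index=[f"p{i}" for i in range(30)])
    frac_b = pd.Series(rng.uniform(0, 0.6, 30), index=frac_a.index)
    for mode in ("both", "either", "per_cohort"):
        n_lo = len(lod_filter(frac_a, frac_b, lo, mode)["excluded_a"])
        n_hi = len(lod_filter(frac_a, frac_b, hi, mode)["excluded_a"])
        assert n_hi <= n_lo


def test_pca_matches_covariance_eigendecomposition():
    """Scores on a 5x4 fixture reproduce the covariance-matrix eigenstructure."""
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.normal(size=(5, 4)))
    pcs = pca_scores(x, center=True, scale=False)
    xc = x.to_numpy() - x.to_numpy().mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(xc, rowvar=False))
    evals, evecs = evals[::-1], evecs[:, ::-1]
    # explained-variance fractions agree
    assert np.allclose(pcs.explained_variance, evals / evals.sum(), atol=1e-10)
    # scores agree with projections up to component sign
    proj = xc @ evecs
    for j in range(4 - 1):
        r = np.corrcoef(pcs.scores.iloc[:, j], proj[:, j])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)


def test_pca_collinear_data_one_component():
    t = np.linspace(0, 1, 10)
    x = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
    pcs = pca_scores(x, center=True, scale=False)
    assert pcs.explained_variance[0] == pytest.approx(1.0)


def test_pca_duplicated_rows_same_directions():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"s{i}" for i in range(20)])
    dup = pd.concat([x, x.set_index(x.index + "_dup")])
    p1 = pca_scores(x, center=True, scale=False)
    p2 = pca_scores(dup, center=True, scale=False)
    # duplicates land on identical scores; directions match the originals
    assert np.allclose(p2.scores.iloc[:20].to_numpy(), p2.scores.iloc[20:].to_numpy())
    for j in range(3):
        r = np.corrcoef(p1.scores.iloc[:, j], p2.scores.iloc[:20, j])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)


def test_pca_zero_variance_feature_dropped_when_scaling():
    x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 1.0, 1.0, 1.0],
                      "c": [0.0, 1.0, 0.0, 1.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        pcs = pca_scores(x, center=True, scale=True)
    assert pcs.dropped_features == ["b"]


def test_flag_outliers_catches_single_extreme_point():
    rng = np.random.default_rng(2)
    x = pd.DataFrame(rng.normal(0, 0.1, size=(100, 3)), index=[f"s{i}" for i in range(100)])
    x.iloc[0] = 10.0  # far along every axis
    pcs = pca_scores(x, center=True, scale=False)
    flags = flag_outliers(pcs, k_sd=3.0, components=2)
    assert flags["sample_id"].tolist() == ["s0"]


def test_flag_outliers_degenerate_zero_sd():
    scores = pd.DataFrame({"PC1": [1.0] * 5, "PC2": [2.0] * 5},
                          index=[f"s{i}" for i in range(5)])
    pcs = preprocess.PCScores(scores, np.array([1.0, 0.0]), True, False)
    assert len(flag_outliers(pcs)) == 0


def test_flag_outliers_affine_invariant_when_scaled():
    rng = np.random.default_rng(3)
    x = pd.DataFrame(rng.normal(size=(80, 6)), index=[f"s{i}" for i in range(80)])
    x.iloc[5] += 8.0
    f1 = flag_outliers(pca_scores(x, center=True, scale=True))
    f2 = flag_outliers(pca_scores(x * 3.5 + 11.0, center=True, scale=True))
    assert f1["sample_id"].tolist() == f2["sample_id"].tolist()


def test_pipeline_excludes_constructed_censored_proteins(default_pair):
    """Default conditions censor proteins 1-18 above the 25% rule in both
    cohorts (plus 2 more in cohort A only); mode=both excludes exactly 18."""
    a, b, _, truth = default_pair
    cfg = PreprocessConfig(lod_mode="both")
    clean_a, clean_b, qc = preprocess_pipeline(a, b, cfg)
    expected = {f"prot{i:03d}" for i in range(1, 19)}
    assert {e["protein"] for e in qc.excluded_proteins} == expected
    assert clean_a.n_proteins == clean_b.n_proteins == 92 - 18


def test_pipeline_per_cohort_mode_distinct_retained_counts(default_pair):
    a, b, _, _ = default_pair
    clean_a, clean_b, qc = preprocess_pipeline(a, b, PreprocessConfig())
    assert clean_a.n_proteins == 72  # cohort A censors 20
    assert clean_b.n_proteins == 74  # cohort B censors 18


def test_pipeline_output_contains_no_flagged_samples(default_pair):
    a, b, _, _ = default_pair
    clean_a, clean_b, qc = preprocess_pipeline(a, b, PreprocessConfig())
    flagged = set(qc.outlier_samples["sample_id"])
    assert not flagged & set(clean_a.samples)
    assert not flagged & set(clean_b.samples)
    counts = qc.counts
    for c in counts["samples_in"]:
        assert counts["samples_in"][c] == counts["samples_out"][c] + counts["samples_excluded"][c]


def test_pipeline_idempotent_on_bounded_data():
    """Re-running at fixed thresholds is a no-op: bounded (uniform) noise can
    never reach 3 SD on a 2-feature panel, so the second pass flags nothing."""
    rng = np.random.default_rng(8)

    def cohort(label):
        n = 40
        idx = [f"{label}{i}" for i in range(n)] + [f"{label}b{i}" for i in range(4)]
        vals = pd.DataFrame(
            rng.uniform(-1, 1, size=(n + 4, 2)) + 5.0, index=idx, columns=["p1", "p2"]
        )
        return make_npx(vals, cohort=label, bridge_rows=[f"{label}b{i}" for i in range(4)])

    a, b = cohort("A"), cohort("B")
    cfg = PreprocessConfig()
    a1, b1, _ = preprocess_pipeline(a, b, cfg)
    a2, b2, qc2 = preprocess_pipeline(a1, b1, cfg)
    assert len(qc2.outlier_samples) == 0
    assert list(a2.samples) == list(a1.samples)
    assert np.allclose(a2.values, a1.values, atol=1e-12)
    pd.testing.assert_frame_equal(b2.values, b1.values)
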