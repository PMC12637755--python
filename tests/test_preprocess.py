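"""QC chain: filters, PQN, imputation, outliers, extreme-value flagging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_matrix
from metabomwas import (
    PreprocessConfig,
    SynthConfig,
    derive_diagnosis,
    detect_sample_outliers,
    filter_missing,
    flag_extreme_values,
    generate_cohort,
    harmonize_cohort,
    knn_impute,
    log2_transform,
    pqn_normalize,
    preprocess_pipeline,
)
from metabomwas.preprocess import extreme_value_cutoff


# --- diagnosis rule -----------------------------------------------------

@pytest.mark.parametrize(
    "braak,cerad,expected",
    [
        (4, 2, "case"),
        (6, 1, "case"),
        (3, 3, "control"),
        (1, 4, "control"),
        (5, 4, "other"),  # severe tangles but no plaques: neither rule
        (3, 2, "other"),
        (np.nan, 2, "missing"),
    ],
)
def test_derive_diagnosis_rule(braak, cerad, expected):
    assert derive_diagnosis([braak], [cerad]).iloc[0] == expected


def test_derive_diagnosis_rejects_out_of_range():
    with pytest.raises(ValueError):
        derive_diagnosis([7], [2])


# --- cohort harmonization ----------------------------------------------

def _toy_metadata():
    meta = pd.DataFrame(
        {
            "region": ["DLPFC"] * 8 + ["TCX"] * 2,
            "group": ["A"] * 5 + ["B"] * 4 + [None],
            "sex": ["F"] * 10,
            "age_at_death": [80.0] * 9 + [np.nan],
            "pmi": [8.0] * 10,
            "apoe4_count": [0] * 10,
        },
        index=[f"s{i}" for i in range(10)],
    )
    return meta


def test_harmonize_region_filter_first():
    meta, log = harmonize_cohort(_toy_metadata(), min_group_size=2)
    assert (log.loc[["s8", "s9"], "reason"] == "region").all()
    assert len(meta) == 8


def test_harmonize_small_group_excluded():
    meta = _toy_metadata().iloc[:8]  # all DLPFC; groups A=5, B=3
    kept, log = harmonize_cohort(meta, min_group_size=4)
    assert set(kept["group"]) == {"A"}
    assert (log["reason"] == "small_group").sum() == 3


def test_harmonize_missing_covariate_excluded():
    meta = _toy_metadata()
    meta.loc["s3", "pmi"] = np.nan
    kept, log = harmonize_cohort(meta, min_group_size=2)
    assert log.loc["s3", "reason"] == "covariate"
    assert "s3" not in kept.index


def test_harmonize_empty_result_raises():
    meta = _toy_metadata()
    with pytest.raises(ValueError):
        harmonize_cohort(meta, region_keep="cerebellum")


# --- missingness filter -------------------------------------------------

def test_filter_missing_boundary_is_strictly_greater():
    vals = np.ones((20, 4))
    vals[:0, 0] = np.nan
    vals[:4, 1] = np.nan  # 20%
    vals[:5, 2] = np.nan  # 25% — retained ("more than" is strict)
    vals[:6, 3] = np.nan  # 30% — removed
    m = make_matrix(vals, scale_tag="raw")
    kept = filter_missing(m, 0.25)
    assert list(kept.metabolite_ids) == ["m0", "m1", "m2"]
    assert kept.n_samples == 20


def test_filter_missing_complete_matrix_identity(clean_cohort):
    _, matrix, *_ = clean_cohort
    complete = filter_missing(matrix, 0.25)
    assert complete.n_metabolites <= matrix.n_metabolites


def test_filter_missing_removes_exactly_planted_victims():
    cfg = SynthConfig(n_per_group={"NHAA": 40, "HA": 30, "NHW": 30},
                      n_metabolites=100, missing_frac=0.0, outlier_rate=0.0, seed=21)
    matrix, *_ = generate_cohort(cfg)
    rng = np.random.default_rng(0)
    victims = rng.choice(matrix.metabolite_ids, size=17, replace=False)
    vals = matrix.values.copy()
    for v in victims:
        rows = rng.choice(vals.index, size=31, replace=False)  # 31% of 100 samples
        vals.loc[rows, v] = np.nan
    holed = matrix.with_values(vals)
    kept = filter_missing(holed, 0.25)
    assert set(matrix.metabolite_ids) - set(kept.metabolite_ids) == set(victims)


# --- PQN ----------------------------------------------------------------

def test_pqn_identical_samples_unchanged():
    vals = np.tile(np.array([1.0, 2.0, 4.0, 8.0]), (2, 1))
    m = make_matrix(vals, scale_tag="raw")
    out, quotients = pqn_normalize(m)
    np.testing.assert_allclose(out.values.to_numpy(), vals)
    np.testing.assert_allclose(quotients.to_numpy(), [1.0, 1.0])


def test_pqn_undoes_constant_dilution_two_samples():
    base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    vals = np.vstack([base, 3.0 * base])
    m = make_matrix(vals, scale_tag="raw")
    out, quotients = pqn_normalize(m)
    # direct median-quotient oracle: reference = elementwise median = 2*base
    reference = np.median(vals, axis=0)
    expected_q = [np.median(base / reference), np.median(3 * base / reference)]
    np.testing.assert_allclose(quotients.to_numpy(), expected_q)
    np.testing.assert_allclose(out.values.to_numpy()[0] * expected_q[0], base)
    # after normalization both rows are proportional to the same profile
    ratio = out.values.to_numpy()[1] / out.values.to_numpy()[0]
    np.testing.assert_allclose(ratio, ratio[0])


def test_pqn_recovers_planted_dilution():
    cfg = SynthConfig(n_per_group={"NHAA": 80, "HA": 60, "NHW": 60}, n_metabolites=900,
                      missing_frac=0.0, outlier_rate=0.0, dilution_sd=0.4, seed=31)
    matrix, _, _, truth = generate_cohort(cfg)
    _, quotients = pqn_normalize(matrix)
    rho = spearmanr(quotients.to_numpy(), truth.dilution.to_numpy()).statistic
    assert rho > 0.95


def test_pqn_errors_on_disjoint_sample():
    vals = np.array([[np.nan, np.nan], [1.0, 2.0], [2.0, 3.0]])
    m = make_matrix(vals, scale_tag="raw")
    with pytest.raises(ValueError, match="reference"):
        pqn_normalize(m)


# --- log2 ---------------------------------------------------------------

def test_log2_values_and_roundtrip_of_site_shifts(clean_cohort):
    m = make_matrix([[8.0, 1.0], [2.0, 16.0]], scale_tag="raw")
    out = log2_transform(m)
    np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 0.0], [1.0, 4.0]])
    assert out.scale_tag == "log2"

    # planted additive site shifts are recovered on the log2 scale
    cfg, matrix, metadata, _, truth = clean_cohort
    cfg2 = SynthConfig(**{**cfg.__dict__, "dilution_sd": 0.0, "site_scale_sd": 0.0,
                          "site_shift_sd": 1.0, "seed": 77})
    matrix, metadata, _, truth = __import__("metabomwas").generate_cohort(cfg2)
    log2m = log2_transform(matrix)
    est = log2m.values.groupby(metadata["site"]).mean()
    est = est - est.mean(axis=0)
    planted = truth.true_site_shift.loc[est.index] - truth.true_site_shift.loc[est.index].mean(axis=0)
    r = np.corrcoef(est.to_numpy().ravel(), planted.to_numpy().ravel())[0, 1]
    assert r > 0.95


def test_log2_rejects_nonpositive():
    with pytest.raises(ValueError):
        log2_transform(make_matrix([[1.0, 0.5]], scale_tag="raw").with_values(
            pd.DataFrame([[1.0, -2.0]], index=["s0"], columns=["m0", "m1"]), "normalized"))


# --- kNN imputation -----------------------------------------------------

def test_knn_impute_twin_sample():
    vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [5.0, 9.0, 7.0]])
    m = make_matrix(vals)
    out = knn_impute(m, k=1)
    assert out.values.iloc[1, 2] == 3.0  # copied from the identical twin
    # observed cells untouched
    obs = ~np.isnan(vals)
    np.testing.assert_array_equal(out.values.to_numpy()[obs], vals[obs])


def test_knn_impute_complete_is_identity(clean_log2):
    matrix, *_ = clean_log2
    out = knn_impute(matrix, k=5)
    pd.testing.assert_frame_equal(out.values, matrix.values)


def test_knn_beats_metabolite_mean_imputation():
    # smooth structure: samples vary along a latent gradient
    rng = np.random.default_rng(8)
    t = np.sort(rng.uniform(0, 1, size=120))
    loadings = rng.normal(size=(1, 60))
    truth_vals = 10 + t[:, None] * 3 * loadings + 0.2 * rng.normal(size=(120, 60))
    holes = rng.random(truth_vals.shape) < 0.10
    holed = truth_vals.copy()
    holed[holes] = np.nan
    m = make_matrix(holed)
    knn = knn_impute(m, k=10).values.to_numpy()
    col_means = np.nanmean(holed, axis=0)
    mean_imp = np.where(holes, col_means[None, :], holed)
    rmse_knn = np.sqrt(((knn[holes] - truth_vals[holes]) ** 2).mean())
    rmse_mean = np.sqrt(((mean_imp[holes] - truth_vals[holes]) ** 2).mean())
    assert rmse_knn < rmse_mean


# --- LOF ----------------------------------------------------------------

def test_lof_clean_gaussian_rarely_flags():
    flags = 0
    for seed in range(10):
        rng = np.random.default_rng(900 + seed)
        m = make_matrix(rng.normal(size=(150, 30)))
        flags += int(len(detect_sample_outliers(m, 20, 1.5)) == 0)
    assert flags >= 9


def test_lof_flags_displaced_sample():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(100, 50))
    vals[17] += 10.0  # 10 SD displacement in every dimension
    flagged = detect_sample_outliers(make_matrix(vals), 20, 1.5)
    assert "s17" in flagged


def test_lof_finds_exactly_two_planted_outliers():
    cfg = SynthConfig(n_per_group={"NHAA": 220, "HA": 160, "NHW": 170},
                      n_metabolites=200, missing_frac=0.0, outlier_rate=0.0, seed=55)
    matrix, *_ = generate_cohort(cfg)
    log2m = log2_transform(matrix)
    vals = log2m.values.copy()
    planted = ["S0100", "S0400"]
    vals.loc[planted] += 8.0 * np.sign(np.random.default_rng(1).normal(size=vals.shape[1]))
    flagged = detect_sample_outliers(log2m.with_values(vals), 20, 1.5)
    assert set(flagged) == set(planted)


def test_lof_rejects_too_many_neighbors():
    with pytest.raises(ValueError):
        detect_sample_outliers(make_matrix(np.zeros((5, 3))), 5, 1.5)


# --- extreme-value flagging --------------------------------------------

def _bisect_norm_quantile(prob: float) -> float:
    """Independent inverse-normal via bisection on the erfc-based CDF."""
    lo, hi = 0.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if 0.5 * math.erfc(mid / math.sqrt(2)) > prob:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def test_cutoff_matches_independent_inversion():
    q = extreme_value_cutoff(0.0125, 547)
    assert abs(q - _bisect_norm_quantile(0.0125 / 547)) < 1e-9
    assert abs(q - 4.08) < 0.01


def test_extreme_flag_rate_matches_analytic_expectation():
    n, m = 400, 2000
    rng = np.random.default_rng(12)
    matrix = make_matrix(rng.normal(size=(n, m)))
    _, flags = flag_extreme_values(matrix, alpha=0.0125)
    total = flags.to_numpy().sum()
    expected = 2 * 0.0125 * m  # n cells/metabolite x 2*(alpha/n) per cell
    assert abs(total - expected) < 4 * np.sqrt(expected) + 1


def test_extreme_flag_never_hits_the_mean_and_skips_constant():
    vals = np.random.default_rng(3).normal(size=(50, 3))
    vals[:, 2] = 7.0  # constant metabolite: skipped with warning
    vals[10, 0] = vals[:, 0].mean()
    m = make_matrix(vals)
    with pytest.warns(UserWarning, match="zero-variance"):
        masked, flags = flag_extreme_values(m, alpha=0.0125)
    assert not flags.iloc[10, 0]
    assert not flags["m2"].any()


# --- full chain ---------------------------------------------------------

def test_pipeline_order_and_bookkeeping(small_cohort):
    _, matrix, metadata, _, truth = small_cohort
    out, report = preprocess_pipeline(matrix, PreprocessConfig(knn_k=5, lof_n_neighbors=10))
    stages = [s["stage"] for s in report["stages"]]
    assert stages == ["input", "filter_missing", "pqn", "log2", "knn_impute",
                      "lof", "flag_extremes", "knn_impute_2"]
    assert out.is_complete()
    assert out.scale_tag == "log2"
    # dimensions: input minus missingness-filter victims and LOF outliers
    frac = truth.missing_mask.mean(axis=0)
    expected_mets = int((frac <= 0.25).sum())
    assert report["stages"][1]["n_metabolites"] == expected_mets
    assert out.n_samples == matrix.n_samples - len(report["stages"][5]["outliers"])


def test_pipeline_platform_scale_filter_arithmetic():
    """A 1,388-metabolite panel with 481 planted high-missingness metabolites
    retains exactly 907 after the 25% filter."""
    rng = np.random.default_rng(99)
    n, m_total, m_bad = 60, 1388, 481
    vals = np.exp(rng.normal(size=(n, m_total)))
    bad = rng.choice(m_total, size=m_bad, replace=False)
    for j in bad:
        rows = rng.choice(n, size=int(0.30 * n), replace=False)
        vals[rows, j] = np.nan
    kept = filter_missing(make_matrix(vals, scale_tag="raw"), 0.25)
    assert kept.n_metabolites == m_total - m_bad == 907


def test_observed_cells_never_altered(small_cohort):
    _, matrix, *_ = small_cohort
    filtered = filter_missing(matrix, 0.25)
    normalized, q = pqn_normalize(filtered)
    log2m = log2_transform(normalized)
    imputed = knn_impute(log2m, 10)
    obs = ~log2m.mask.to_numpy()
    np.testing.assert_array_equal(imputed.values.to_numpy()[obs], log2m.values.to_numpy()[obs])
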