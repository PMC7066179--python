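"""TMT normalization, volcano statistics, complex summaries, CS activity."""

import numpy as np
import pandas as pd
import pytest

from mitosep.proteomics import (cs_activity, metabolite_fold,
                                mito_renormalize, ocr_per_cs,
                                summarize_by_complex, tmt_normalize, volcano)
from mitosep.simulate import CHANNELS, gen_proteomics_matrix

GROUPS = pd.Series(["control"] * 3 + ["ko"] * 3, index=list(CHANNELS))


def small_matrix():
    rng = np.random.default_rng(0)
    log2 = rng.normal(20, 1, size=(8, 6))
    df = pd.DataFrame(2.0 ** log2, index=[f"P{i}" for i in range(8)],
                      columns=list(CHANNELS))
    peptides = pd.Series([5, 6, 7, 8, 2, 3, 4, 9], index=df.index)
    return df, peptides


def test_column_medians_are_exactly_zero():
    df, peptides = small_matrix()
    norm, _ = tmt_normalize(df, peptides)
    assert (norm.median(axis=0) == 0).all()


def test_row_with_missing_value_dropped():
    df, peptides = small_matrix()
    df.iloc[0, 2] = np.nan
    norm, dropped = tmt_normalize(df, peptides)
    assert "P0" not in norm.index
    assert dropped.set_index("protein").loc["P0", "rules"] == "missing_values"


def test_exactly_two_unique_peptides_dropped():
    df, peptides = small_matrix()   # P4 has exactly 2 peptides
    norm, dropped = tmt_normalize(df, peptides)
    assert "P4" not in norm.index
    assert "unique_peptides<=2" in dropped.set_index("protein").loc["P4", "rules"]


def test_nonpositive_raw_intensity_rejected():
    df, peptides = small_matrix()
    df.iloc[1, 1] = 0.0
    with pytest.raises(ValueError, match="positive"):
        tmt_normalize(df, peptides)


def test_centering_is_idempotent():
    df, peptides = small_matrix()
    once, _ = tmt_normalize(df, peptides)
    twice, _ = tmt_normalize(once, pd.Series(9, index=once.index),
                             already_log2=True)
    pd.testing.assert_frame_equal(once, twice)


def test_mito_mean_zero_after_renormalization():
    df, peptides = small_matrix()
    norm, _ = tmt_normalize(df, peptides)
    flags = pd.Series(False, index=norm.index)
    flags.iloc[:3] = True
    renorm = mito_renormalize(norm, flags)
    assert np.allclose(renorm.loc[flags].mean(axis=0), 0.0)


def test_non_mito_rows_shift_by_exactly_the_mito_mean():
    values = pd.DataFrame(
        [[1, 2, 3, 4, 5, 6],
         [3, 4, 5, 6, 7, 8],
         [10, 10, 10, 10, 10, 10],
         [0, 1, 0, 1, 0, 1]],
        index=list("abcd"), columns=list(CHANNELS), dtype=float)
    flags = pd.Series([True, True, False, False], index=list("abcd"))
    renorm = mito_renormalize(values, flags)
    mito_mean = values.loc[["a", "b"]].mean(axis=0)   # (2,3,4,5,6,7)
    assert np.allclose(renorm.loc["c"], values.loc["c"] - mito_mean)


def test_all_rows_mito_equals_column_centering():
    values = pd.DataFrame(np.arange(12, dtype=float).reshape(2, 6),
                          index=["a", "b"], columns=list(CHANNELS))
    flags = pd.Series(True, index=["a", "b"])
    renorm = mito_renormalize(values, flags)
    assert np.allclose(renorm, values - values.mean(axis=0))


def test_no_mito_rows_is_an_error():
    values = pd.DataFrame(np.ones((2, 6)), index=["a", "b"],
                          columns=list(CHANNELS))
    with pytest.raises(ValueError, match="no mitochondrial"):
        mito_renormalize(values, pd.Series(False, index=["a", "b"]))


# ---------------------------------------------------------------------------
# volcano
# ---------------------------------------------------------------------------

def test_volcano_t_statistic_matches_hand_formula():
    # 3v3 integer fixture; pooled-variance Student's t computed explicitly
    row = pd.DataFrame([[1.0, 2.0, 3.0, 5.0, 6.0, 7.0]],
                       index=["P"], columns=list(CHANNELS))
    res = volcano(row, GROUPS)
    a, b = np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0])
    sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    from scipy import stats
    p_hand = 2 * stats.t.sf(abs(t), df=4)
    assert res.loc["P", "log2fc"] == pytest.approx(4.0)
    assert res.loc["P", "p_value"] == pytest.approx(p_hand)


def test_identical_groups_give_zero_fc_p_one():
    row = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
                       index=["P"], columns=list(CHANNELS))
    res = volcano(row, GROUPS)
    assert res.loc["P", "log2fc"] == 0.0
    assert res.loc["P", "p_value"] == pytest.approx(1.0)


def test_zero_variance_nonzero_difference_flagged():
    row = pd.DataFrame([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]],
                       index=["P"], columns=list(CHANNELS))
    res = volcano(row, GROUPS)
    assert bool(res.loc["P", "flagged"])
    assert np.isnan(res.loc["P", "p_value"])


def test_planted_depletion_detected_on_ciii_rows():
    intens, ann, groups, truth = gen_proteomics_matrix(
        n_proteins=300, seed=2, depletion_log2fc=-2.0, sigma=0.3, n_ciii=12)
    norm, _ = tmt_normalize(intens, ann["n_unique_peptides"])
    renorm = mito_renormalize(norm, ann["mito"])
    res = volcano(renorm, groups)
    ciii = [p for p in renorm.index if ann.loc[p, "complex"] == "CIII"]
    sig = (res.loc[ciii, "p_value"] < 0.05) & (res.loc[ciii, "log2fc"] < 0)
    assert sig.mean() >= 0.95


# ---------------------------------------------------------------------------
# per-complex summaries
# ---------------------------------------------------------------------------

def test_complex_median_of_three_ratios():
    mat = pd.DataFrame(
        [[0, 0, 0, -1, -1, -1],
         [0, 0, 0, -2, -2, -2],
         [0, 0, 0, -3, -3, -3]],
        index=["a", "b", "c"], columns=list(CHANNELS), dtype=float)
    # add tiny within-group spread so the SD filter keeps the rows
    mat += np.arange(6) * 1e-3
    membership = pd.Series("CIII", index=mat.index)
    per_complex, _ = summarize_by_complex(mat, GROUPS, membership,
                                          sd_threshold=2.0)
    assert per_complex.loc["CIII", "median_log2_ratio"] == pytest.approx(-2.0,
                                                                         abs=0.01)


def test_most_altered_isoform_represents_subunit():
    mat = pd.DataFrame(
        [[0, 0.01, -0.01, -0.1, -0.11, -0.09],
         [0, 0.01, -0.01, -1.4, -1.41, -1.39]],
        index=["iso_a", "iso_b"], columns=list(CHANNELS), dtype=float)
    membership = pd.Series("CIII", index=mat.index)
    subunit = pd.Series("uqcrc1", index=mat.index)
    per_complex, _ = summarize_by_complex(mat, GROUPS, membership,
                                          sd_threshold=2.0, subunit=subunit)
    assert per_complex.loc["CIII", "median_log2_ratio"] == pytest.approx(-1.4,
                                                                         abs=0.02)


def test_zero_sd_threshold_excludes_everything():
    mat = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 6)),
                       index=list("abcd"), columns=list(CHANNELS))
    membership = pd.Series(["CI", "CI", "CIII", "CIII"], index=mat.index)
    per_complex, per_protein = summarize_by_complex(mat, GROUPS, membership,
                                                    sd_threshold=0.0)
    assert not per_protein["retained"].any()
    assert per_complex["median_log2_ratio"].isna().all()


# ---------------------------------------------------------------------------
# metabolite fold changes
# ---------------------------------------------------------------------------

def test_identical_concentrations_fold_one_p_one():
    wt = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["lactate"])
    res = metabolite_fold(wt, wt.copy())
    assert res.loc["lactate", "fold_change"] == pytest.approx(1.0)
    assert res.loc["lactate", "p_bonferroni"] == pytest.approx(1.0)


def test_bonferroni_factor_is_number_of_metabolites():
    rng = np.random.default_rng(1)
    wt = pd.DataFrame(rng.uniform(1, 2, size=(3, 4)),
                      index=["lactate", "succinate", "malate"])
    ko = wt * 1.8 + rng.normal(0, 0.05, size=wt.shape)
    res = metabolite_fold(wt, ko)
    expected = np.minimum(1.0, res["p_value"] * 3)
    assert np.allclose(res["p_bonferroni"], expected)


def test_paired_t_matches_hand_computation():
    wt = pd.DataFrame([[10.0, 12.0, 9.0, 11.0]], index=["succ"])
    ko = pd.DataFrame([[31.0, 33.0, 28.0, 35.0]], index=["succ"])
    res = metabolite_fold(wt, ko)
    diff = ko.loc["succ"].to_numpy() - wt.loc["succ"].to_numpy()
    t = diff.mean() / (diff.std(ddof=1) / np.sqrt(4))
    from scipy import stats
    assert res.loc["succ", "p_value"] == pytest.approx(2 * stats.t.sf(t, df=3))
    assert res.loc["succ", "fold_change"] == pytest.approx(
        ko.loc["succ"].mean() / wt.loc["succ"].mean())


def test_unpaired_lengths_rejected():
    wt = pd.DataFrame([[1.0, 2.0]], index=["m"])
    ko = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"])
    with pytest.raises(ValueError, match="paired"):
        metabolite_fold(wt, ko)


# ---------------------------------------------------------------------------
# citrate synthase activity
# ---------------------------------------------------------------------------

def test_linear_series_recovers_slope_exactly():
    t = np.array([0.0, 0.7, 1.3, 2.9, 4.1])
    a = 0.2 + 0.05 * t
    assert cs_activity(t, a) == pytest.approx(0.05)


def test_two_points_single_slope():
    assert cs_activity([0.0, 2.0], [0.1, 0.5]) == pytest.approx(0.2)


def test_noisy_linear_series_within_tolerance():
    rng = np.random.default_rng(6)
    t = np.arange(16, dtype=float)
    a = 0.1 + 0.02 * t + rng.normal(0, 0.001, size=16)
    assert 0.018 <= cs_activity(t, a) <= 0.022


def test_nonincreasing_times_rejected():
    with pytest.raises(ValueError, match="increasing"):
        cs_activity([0.0, 1.0, 1.0], [0.1, 0.2, 0.3])


def test_ocr_normalization_is_a_ratio():
    assert ocr_per_cs(120.0, 0.05) == pytest.approx(2400.0)
    with pytest.raises(ValueError):
        ocr_per_cs(120.0, 0.0)
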