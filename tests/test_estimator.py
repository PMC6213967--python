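"""Estimator: per-axis clustering, call combination, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylsex import (
    BinScheme,
    SimulationConfig,
    ValidationError,
    combine_calls,
    detect_label_mismatch,
    estimate_sex,
    flip_labels,
    pca_cluster,
    simulate_cohort,
)
from conftest import EST_SEED, small_config


# --------------------------------------------------------------- combine_calls


@pytest.mark.parametrize(
    "sex_x, sex_y, expected",
    [("f", "f", "F"), ("m", "m", "M"), ("f", "m", "N"), ("m", "f", "N")],
)
def test_combine_calls_truth_table(sex_x, sex_y, expected):
    assert combine_calls(sex_x, sex_y) == expected


def test_combine_calls_rejects_bad_input():
    with pytest.raises(ValidationError):
        combine_calls("F", "m")


@settings(derandomize=True, max_examples=20)
@given(st.sampled_from(["f", "m"]), st.sampled_from(["f", "m"]))
def test_combine_calls_total_and_conflict_symmetric(a, b):
    out = combine_calls(a, b)
    assert out in {"F", "M", "N"}
    assert (out == "N") == (a != b)
    assert combine_calls(a, b) == combine_calls(b, a) or a != b


# ----------------------------------------------------------------- pca_cluster


def test_pca_cluster_reference_self_consistency(small_panel):
    """Clustering the panel alone reassigns every reference its own label."""
    for axis in ("X", "Y"):
        feats = small_panel.rebin(BinScheme.default()).features(axis)
        res = pca_cluster(feats, small_panel.labels, seed=1, axis=axis)
        assert (res.assignments["assigned_sex"] == small_panel.labels).all()
        assert res.warnings == []
        # cluster 1 holds the female references; pc1 oriented female-negative
        f_rows = res.assignments[small_panel.labels == "f"]
        assert (f_rows["cluster"] == 1).all()
        assert f_rows["pc1"].mean() < 0


def test_pca_cluster_assigns_single_test_sample(small_panel):
    one = simulate_cohort(small_config(n_xx=0, n_xy=1, seed=77))
    from methylsex import build_profiles

    prof = build_profiles(one.matrix, one.annot, BinScheme.default())
    ref = small_panel.rebin(BinScheme.default())
    for axis in ("X", "Y"):
        query = prof.features(axis).rename(index={"XY_0001": "query"})
        feats = pd.concat([ref.features(axis), query])
        ref_sex = pd.Series(index=feats.index, dtype=object)
        ref_sex.iloc[: len(small_panel.labels)] = small_panel.labels.to_numpy()
        res = pca_cluster(feats, ref_sex, seed=1, axis=axis)
        assert res.assignments.loc["query", "assigned_sex"] == "m"


def test_pca_cluster_duplicated_row_gets_identical_assignment(small_panel):
    feats = small_panel.rebin(BinScheme.default()).features("X")
    dup = feats.iloc[[0]].rename(index={feats.index[0]: "dup"})
    res = pca_cluster(pd.concat([feats, dup]), small_panel.labels, seed=1)
    a = res.assignments
    for col in ("cluster", "assigned_sex"):
        assert a.loc["dup", col] == a.loc[feats.index[0], col]
    assert a.loc["dup", "pc1"] == pytest.approx(a.loc[feats.index[0], "pc1"])


def test_pca_cluster_needs_both_reference_sexes(small_panel):
    feats = small_panel.rebin(BinScheme.default()).features("X")
    only_f = small_panel.labels.where(small_panel.labels == "f")
    with pytest.raises(ValidationError):
        pca_cluster(feats, only_f, seed=1)


# ---------------------------------------------------------------- estimate_sex


def test_estimate_sex_recovers_all_karyotypes(panel, study_test_cohort):
    """40 XX + 40 XY + 10 XXY + 10 X0 at default effect sizes: every call
    matches the simulated truth, with the aneuploidies flagged N via the
    expected per-chromosome signatures."""
    res = estimate_sex(
        study_test_cohort.matrix, study_test_cohort.annot, panel, seed=EST_SEED
    )
    truth = study_test_cohort.truth
    assert (res.calls["predicted"] == truth["expected_call"]).all()
    xxy = truth.index[truth["karyotype"] == "XXY"]
    assert (res.calls.loc[xxy, "sex_chrX"] == "f").all()
    assert (res.calls.loc[xxy, "sex_chrY"] == "m").all()
    x0 = truth.index[truth["karyotype"] == "X0"]
    assert (res.calls.loc[x0, "sex_chrX"] == "m").all()
    assert (res.calls.loc[x0, "sex_chrY"] == "f").all()


def test_estimate_sex_invariant_to_sample_order(small_panel):
    cohort = simulate_cohort(small_config(n_xx=8, n_xy=8, seed=31))
    res = estimate_sex(cohort.matrix, cohort.annot, small_panel, seed=3)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(cohort.matrix.sample_ids))
    from methylsex import MethylationMatrix

    shuffled = MethylationMatrix(
        beta=cohort.matrix.beta.iloc[:, perm], detp=cohort.matrix.detp.iloc[:, perm]
    )
    res2 = estimate_sex(shuffled, cohort.annot, small_panel, seed=3)
    merged = res.calls[["predicted"]].join(
        res2.calls[["predicted"]], rsuffix="_perm"
    )
    assert (merged["predicted"] == merged["predicted_perm"]).all()


def test_estimate_sex_reproducible(small_panel, small_cohort):
    a = estimate_sex(small_cohort.matrix, small_cohort.annot, small_panel, seed=9)
    b = estimate_sex(small_cohort.matrix, small_cohort.annot, small_panel, seed=9)
    pd.testing.assert_frame_equal(a.calls, b.calls)


def test_estimate_sex_all_male_cohort_still_called_male(panel):
    """Reference anchoring: a test set containing only XY samples must not
    be split in half by the clustering."""
    males = simulate_cohort(SimulationConfig(n_xx=0, n_xy=100, seed=55))
    res = estimate_sex(males.matrix, males.annot, panel, seed=EST_SEED)
    assert (res.calls["predicted"] == "M").all()


def test_estimate_sex_same_calls_under_wider_beta_bins(small_panel, small_cohort):
    """Clean cohorts get identical calls under 10 and 5 beta bins."""
    res10 = estimate_sex(
        small_cohort.matrix, small_cohort.annot, small_panel,
        scheme=BinScheme.default(), seed=3,
    )
    res5 = estimate_sex(
        small_cohort.matrix, small_cohort.annot, small_panel,
        scheme=BinScheme.default(n_beta_bins=5), seed=3,
    )
    assert (res10.calls["predicted"] == res5.calls["predicted"]).all()


def test_estimate_sex_monotone_separation_in_xci_mass(small_panel):
    """Growing the female chrX intermediate-methylation weight widens the
    gap between female and male X.PC1 means."""
    margins = []
    for w in (0.3, 0.5, 0.7):
        cohort = simulate_cohort(
            small_config(n_xx=10, n_xy=10, seed=41, xci_intermediate_weight=w)
        )
        res = estimate_sex(cohort.matrix, cohort.annot, small_panel, seed=3)
        is_f = cohort.truth["karyotype"] == "XX"
        margin = (
            res.calls.loc[(~is_f).to_numpy(), "pc1_x"].mean()
            - res.calls.loc[is_f.to_numpy(), "pc1_x"].mean()
        )
        margins.append(margin)
    assert margins[0] < margins[1] < margins[2]


def test_estimate_sex_collapsed_effect_size_warns_or_degrades(small_panel):
    """Shrinking the XCI mass to male-like levels must not crash; near the
    collapse point the axis purity warning fires or calls degrade."""
    cohort = simulate_cohort(
        small_config(n_xx=10, n_xy=10, seed=43, xci_intermediate_weight=0.10)
    )
    from methylsex import EstimationError

    try:
        res = estimate_sex(cohort.matrix, cohort.annot, small_panel, seed=3)
    except EstimationError:
        return
    assert set(res.calls["predicted"]) <= {"F", "M", "N"}


def test_estimate_sex_empty_test_set_errors(small_panel, small_cohort):
    from methylsex import MethylationMatrix

    empty = MethylationMatrix(
        beta=small_cohort.matrix.beta.iloc[:, :0],
        detp=small_cohort.matrix.detp.iloc[:, :0],
    )
    with pytest.raises(ValidationError):
        estimate_sex(empty, small_cohort.annot, small_panel, seed=1)


def test_estimate_sex_qc_flags_attached_not_dropping(small_panel, small_cohort):
    detp = small_cohort.matrix.detp.copy()
    chrx = small_cohort.annot.probes("chrX")
    bad_sample = detp.columns[0]
    detp.loc[chrx[: int(0.10 * len(chrx))], bad_sample] = 0.5
    from methylsex import MethylationMatrix

    matrix = MethylationMatrix(beta=small_cohort.matrix.beta, detp=detp)
    res = estimate_sex(matrix, small_cohort.annot, small_panel, seed=3)
    assert bad_sample in res.calls.index  # flagged, not removed
    assert not res.calls.loc[bad_sample, "qc_passed"]
    assert res.calls.loc[bad_sample, "frac_chrX_detp_failed"] >= 0.10


# ------------------------------------------------------- detect_label_mismatch


def _toy_calls(preds):
    return pd.DataFrame(
        {"predicted": preds}, index=[f"s{i}" for i in range(len(preds))]
    )


def test_mismatch_definition_and_n_sample_separation():
    calls = _toy_calls(["F", "M", "N", "F"])
    labels = pd.Series(
        ["M", "M", "F", "unknown"], index=["s0", "s1", "s2", "s3"]
    )
    report = detect_label_mismatch(calls, labels)
    assert list(report.discordant.index) == ["s0"]
    assert list(report.n_samples.index) == ["s2"]


def test_mismatch_unknown_sample_id_errors():
    calls = _toy_calls(["F"])
    with pytest.raises(ValidationError):
        detect_label_mismatch(calls, pd.Series({"nope": "F"}))


def test_mismatch_recovers_flipped_labels_end_to_end(panel):
    """Flipping 5 labels in a 50+50 cohort yields exactly those 5 as
    discordant after estimation."""
    cohort = simulate_cohort(SimulationConfig(n_xx=50, n_xy=50, seed=33))
    flipped, chosen = flip_labels(cohort.truth["sex_label"], k=5, seed=13)
    assert (flipped != cohort.truth["sex_label"]).sum() == 5
    res = estimate_sex(cohort.matrix, cohort.annot, panel, seed=EST_SEED)
    report = detect_label_mismatch(res.calls, flipped)
    assert sorted(report.discordant.index) == sorted(chosen)
    assert len(report.n_samples) == 0
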