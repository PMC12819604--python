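import numpy as np
import pandas as pd
import pytest

from scngraph import (
    CohortConfig,
    aal90,
    auc,
    auc_table,
    density_sweep,
    fdr_correct,
    generate_cohort,
    identify_hubs,
    metric_curves,
    normalized_bc_profile,
    permutation_test,
)

import oracles


# -- AUC ----------------------------------------------------------------


def test_auc_of_constant_and_ramp_curves():
    d = density_sweep()
    assert auc(np.full(21, 1.0), d) == pytest.approx(0.40, abs=1e-12)
    assert auc(np.full(21, 2.5), d) == pytest.approx(1.00, abs=1e-12)
    ramp = np.linspace(0.0, 1.0, 21)
    assert auc(ramp, d) == pytest.approx(0.20, abs=1e-12)


def test_auc_matches_trapezoid_oracle(rng):
    d = density_sweep()
    for _ in range(10):
        y = rng.normal(size=21)
        assert auc(y, d) == pytest.approx(oracles.oracle_auc(y, d), abs=1e-12)


def test_auc_requires_two_points():
    with pytest.raises(ValueError):
        auc(np.array([1.0]), np.array([0.1]))


# -- FDR ----------------------------------------------------------------


def test_bh_equal_pvalues_unchanged():
    p = np.full(90, 0.01)
    np.testing.assert_allclose(fdr_correct(p), 0.01)


def test_bh_stepup_hand_example():
    q = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_textbook_oracle_and_dominates_p(rng):
    for _ in range(10):
        p = rng.uniform(0.001, 1.0, 40)
        q = fdr_correct(p)
        np.testing.assert_allclose(q, oracles.oracle_bh(p), atol=1e-12)
        assert (q >= p - 1e-12).all()


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        fdr_correct(np.array([0.0, 0.5]))


# -- hubs ---------------------------------------------------------------


def test_hub_rule_hand_example():
    values = np.array([8.0, 1.0, 1.0, 1.0, 1.0])
    table = identify_hubs(values)
    # mean 2.4, sample SD sqrt(9.8) ~ 3.1305, threshold ~ 5.5305
    assert table["threshold"].iloc[0] == pytest.approx(2.4 + np.sqrt(9.8), abs=1e-9)
    assert list(table["is_hub"]) == [True, False, False, False, False]


def test_constant_profile_has_no_hubs():
    with pytest.warns(UserWarning, match="zero variance"):
        table = identify_hubs(np.full(6, 1.0))
    assert not table["is_hub"].any()


def test_hub_set_invariant_to_shift_and_scale(rng):
    values = rng.uniform(0, 3, 30)
    base = identify_hubs(values)["is_hub"]
    shifted = identify_hubs(values + 17.0)["is_hub"]
    scaled = identify_hubs(values * 4.2)["is_hub"]
    assert (base == shifted).all() and (base == scaled).all()


def test_hub_table_carries_atlas_lobes():
    atlas = aal90()
    values = pd.Series(np.ones(90), index=atlas.names)
    values.iloc[0] = 30.0
    table = identify_hubs(values, atlas, group="patient")
    row = table[table["region"] == "PreCG.L"].iloc[0]
    assert row["lobe"] == "frontal" and bool(row["is_hub"])
    assert (table["group"] == "patient").all()


# -- metric curves ------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_curves(small_residuals_module):
    return metric_curves(
        small_residuals_module,
        metrics=("degree", "betweenness"),
        n_refs=0,
        seed=0,
    )


@pytest.fixture(scope="module")
def small_residuals_module():
    from scngraph import residualize

    cohort = generate_cohort(CohortConfig(n_patients=25, n_controls=20, seed=42))
    return residualize(cohort)


def test_curves_have_one_value_per_density(tiny_curves):
    sub = tiny_curves[
        (tiny_curves.group == "patient") & (tiny_curves.metric == "degree")
    ]
    assert sub["node"].nunique() == 90
    assert sub.groupby("node")["density"].count().eq(21).all()


def test_degree_curves_monotone_in_density(tiny_curves):
    sub = tiny_curves[tiny_curves.metric == "degree"]
    for _, g in sub.groupby(["group", "node"]):
        vals = g.sort_values("density")["value"].to_numpy()
        assert (np.diff(vals) >= 0).all()


def test_identical_groups_give_identical_curves():
    cohort = generate_cohort(CohortConfig(n_patients=12, n_controls=12, seed=6))
    regions = list(cohort.columns[9:])
    # feed the same residual rows under both labels
    pat = cohort[cohort["group"] == "patient"].copy()
    twin = pat.copy()
    twin["group"] = "control"
    both = pd.concat([pat, twin], ignore_index=True)
    curves = metric_curves(both, metrics=("degree",), n_refs=0, region_columns=regions)
    wide = curves.pivot_table(
        index=["metric", "node", "density"], columns="group", values="value"
    )
    np.testing.assert_array_equal(wide["patient"], wide["control"])


def test_normalized_bc_profile_mean_one(tiny_curves):
    prof = normalized_bc_profile(tiny_curves, "patient")
    assert len(prof) == 90
    assert prof.mean() == pytest.approx(1.0, abs=1e-9)


def test_auc_table_layout(tiny_curves):
    table = auc_table(tiny_curves)
    assert set(table.columns) == {"group", "metric", "node", "auc"}
    assert len(table) == 2 * 2 * 90  # groups x metrics x nodes


# -- permutation test ---------------------------------------------------


@pytest.fixture(scope="module")
def perm_cohort():
    return generate_cohort(CohortConfig(n_patients=16, n_controls=14, seed=33))


def test_permutation_reproducible_and_bounded(perm_cohort):
    kwargs = dict(metrics=("degree",), n_perm=60, seed=5)
    a = permutation_test(perm_cohort, **kwargs)
    b = permutation_test(perm_cohort, **kwargs)
    pd.testing.assert_frame_equal(a, b)
    assert (a["p_value"] >= 1 / 61 - 1e-12).all()
    assert (a["p_value"] <= 1.0).all()
    assert (a["q_value"] >= a["p_value"] - 1e-12).all()


def test_total_degree_difference_is_structurally_zero(perm_cohort):
    """Fixed sparsity forces equal edge counts, so summed degree AUCs cancel."""
    result, null = permutation_test(
        perm_cohort, metrics=("degree",), n_perm=30, seed=2, return_null=True
    )
    assert result["observed_diff"].sum() == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(null["degree"].sum(axis=1), 0.0, atol=1e-9)


def test_small_nperm_warns(perm_cohort):
    with pytest.warns(UserWarning, match="n_perm"):
        permutation_test(perm_cohort, metrics=("degree",), n_perm=5, seed=0)


def test_global_metrics_reported_without_fdr(perm_cohort):
    res = permutation_test(
        perm_cohort, metrics=("degree", "clustering"), n_perm=30, seed=1
    )
    glob = res[res["metric"] == "clustering"]
    assert list(glob["node"]) == ["global"]
    assert np.isnan(glob["q_value"]).all()
    nodal = res[res["metric"] == "degree"]
    assert len(nodal) == 90 and not nodal["q_value"].isna().any()
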