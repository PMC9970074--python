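"""Rating I/O, the >2-missing exclusion rule, EM imputation, rescaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sdmnet import (
    GeneratorConfig,
    filter_missing,
    impute_em,
    inject_missingness,
    load_ratings,
    rescale_score,
    aggregate_observer,
    sample_true_model,
    simulate_ratings,
)
from sdmnet.preprocessing import EmError, save_ratings
from sdmnet.skills import SKILL_COLUMNS


def _table(rows):
    return pd.DataFrame(
        rows, columns=["physician_id", "consultation_id", *SKILL_COLUMNS]
    )


def test_load_ratings_well_formed(tmp_path):
    df = _table(
        [
            ["a", "c1", *([3] * 9)],
            ["a", "c2", *([2] * 9)],
            ["b", "c1", *([5] * 9)],
        ]
    )
    path = tmp_path / "r.csv"
    save_ratings(df, path)
    out = load_ratings(path)
    assert len(out) == 3
    assert out[SKILL_COLUMNS].notna().all().all()


def test_load_ratings_rejects_out_of_range(tmp_path):
    df = _table([["a", "c1", 1, 2, 7, 3, 3, 3, 3, 3, 3]])
    path = tmp_path / "r.csv"
    save_ratings(df, path)
    with pytest.raises(ValueError, match="skill_3.*row 0"):
        load_ratings(path)


def test_load_ratings_empty_cell_is_missing_not_zero(tmp_path):
    path = tmp_path / "r.csv"
    path.write_text(
        "physician_id,consultation_id," + ",".join(SKILL_COLUMNS) + "\n"
        "a,c1,1,2,,3,3,3,3,3,3\n"
    )
    out = load_ratings(path)
    assert np.isnan(out.loc[0, "skill_3"])
    assert out.loc[0, "skill_2"] == 2


def test_load_ratings_rejects_duplicates_and_bad_header(tmp_path):
    df = _table([["a", "c1", *([3] * 9)], ["a", "c1", *([2] * 9)]])
    path = tmp_path / "r.csv"
    save_ratings(df, path)
    with pytest.raises(ValueError, match="duplicate"):
        load_ratings(path)
    bad = tmp_path / "bad.csv"
    bad.write_text("physician_id,consultation_id,skill_1\n" "a,c1,3\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_ratings(bad)


def test_filter_missing_rule():
    row = lambda pid, cid, miss: [
        pid, cid, *[np.nan if i < miss else 3.0 for i in range(9)]
    ]
    df = _table(
        [row("a", "c0", 0), row("a", "c2", 2), row("a", "c3", 3), row("b", "c5", 5)]
    )
    kept, report = filter_missing(df)
    assert set(kept["consultation_id"]) == {"c0", "c2"}  # <=2 missing retained
    assert report.n_excluded == 2
    assert set(report.excluded["consultation_id"]) == {"c3", "c5"}
    # idempotent
    kept2, report2 = filter_missing(kept)
    pd.testing.assert_frame_equal(kept2, kept)
    assert report2.n_excluded == 0


def test_filter_missing_fully_observed_identity():
    df = _table([["a", "c1", *([4] * 9)]])
    kept, report = filter_missing(df)
    pd.testing.assert_frame_equal(kept, df, check_dtype=False)
    assert report.n_excluded == 0 and len(report.excluded) == 0


def test_impute_em_no_missing_is_identity():
    m = sample_true_model(GeneratorConfig(n_physicians=3), seed=1)
    r = simulate_ratings(m, 10, seed=2)
    res = impute_em(r)
    pd.testing.assert_frame_equal(res.ratings, r.astype({c: float for c in SKILL_COLUMNS}))
    assert res.n_iter == 0 and res.converged


def _conditional_mean_oracle(mu, sigma, obs_idx, miss_idx, x_obs):
    """Schur-complement conditional mean, computed independently."""
    S_oo = sigma[np.ix_(obs_idx, obs_idx)]
    S_mo = sigma[np.ix_(miss_idx, obs_idx)]
    return mu[miss_idx] + S_mo @ np.linalg.solve(S_oo, x_obs - mu[obs_idx])


def test_impute_em_matches_closed_form_conditional_mean():
    # Continuous 9-variate data from a known MVN; hide one and two cells in
    # two rows and compare against the Schur-complement oracle evaluated at
    # the EM-converged parameters.
    m = sample_true_model(
        GeneratorConfig(n_physicians=1, n_recorded=1, heterogeneity=0.0), seed=5
    )
    r = simulate_ratings(m, 400, discretize=False, seed=6)
    X = r[SKILL_COLUMNS].to_numpy().copy()
    r.loc[0, "skill_2"] = np.nan
    r.loc[1, "skill_4"] = np.nan
    r.loc[1, "skill_7"] = np.nan
    res = impute_em(r, tol=1e-10)

    mu, sigma = res.mean, res.cov
    x0 = res.ratings.loc[0, SKILL_COLUMNS].to_numpy(dtype=float)
    obs = [i for i in range(9) if i != 1]
    expected = _conditional_mean_oracle(mu, sigma, obs, [1], x0[obs])
    assert abs(x0[1] - expected[0]) < 1e-4

    x1 = res.ratings.loc[1, SKILL_COLUMNS].to_numpy(dtype=float)
    obs = [i for i in range(9) if i not in (3, 6)]
    expected = _conditional_mean_oracle(mu, sigma, obs, [3, 6], x1[obs])
    assert np.abs(x1[[3, 6]] - expected).max() < 1e-4

    # observed cells bit-identical
    mask = ~np.isnan(r[SKILL_COLUMNS].to_numpy())
    assert np.array_equal(
        res.ratings[SKILL_COLUMNS].to_numpy()[mask], r[SKILL_COLUMNS].to_numpy()[mask]
    )


def test_impute_em_bivariate_closed_form():
    # Two observed skills carry the signal; impute one from the other and
    # check mu_1 + s_12/s_22 (x_2 - mu_2) directly.
    rng = np.random.default_rng(8)
    n = 500
    z2 = rng.normal(3.0, 0.7, n)
    z1 = 1.0 + 0.6 * z2 + rng.normal(0, 0.3, n)
    rest = rng.uniform(1.0, 4.0, (n, 7))  # independent filler skills
    df = _table(
        [["a", f"c{i}", z1[i], z2[i], *rest[i]] for i in range(n)]
    )
    df[SKILL_COLUMNS] = df[SKILL_COLUMNS].clip(0.0, 5.0)
    df.loc[0, "skill_1"] = np.nan
    res = impute_em(df, tol=1e-10)
    mu, sigma = res.mean, res.cov
    x2 = df.loc[0, "skill_2"]
    expected = mu[0] + sigma[0, 1] / sigma[1, 1] * (x2 - mu[1])
    # degenerate constant columns make the full Schur solve ill-posed;
    # the pairwise formula on the informative block must still hold
    got = res.ratings.loc[0, "skill_1"]
    oracle = _conditional_mean_oracle(
        mu, sigma, [i for i in range(9) if i != 0], [0],
        df.loc[0, SKILL_COLUMNS].to_numpy(dtype=float)[1:],
    )
    assert abs(got - oracle[0]) < 1e-4
    assert abs(got - expected) < 0.05  # pairwise approximation


def test_impute_em_loglik_monotone():
    m = sample_true_model(GeneratorConfig(n_physicians=6), seed=9)
    r = simulate_ratings(m, 20, seed=10)
    r = inject_missingness(r, 0.05, seed=11)
    kept, _ = filter_missing(r)
    res = impute_em(kept, tol=1e-8)
    diffs = np.diff(res.loglik_trace)
    assert np.all(diffs > -1e-6)


def test_impute_em_nonconvergence_raises_with_trace():
    m = sample_true_model(GeneratorConfig(n_physicians=6), seed=12)
    r = simulate_ratings(m, 20, seed=13)
    r = inject_missingness(r, 0.05, seed=14)
    kept, _ = filter_missing(r)
    with pytest.raises(EmError) as err:
        impute_em(kept, tol=0.0, max_iter=3)
    assert len(err.value.trace) == 4  # initial + 3 iterations


def test_impute_em_requires_filtering_first():
    row = ["a", "c1", np.nan, np.nan, np.nan, 3, 3, 3, 3, 3, 3]
    with pytest.raises(ValueError, match="filter_missing"):
        impute_em(_table([row, ["a", "c2", *([3] * 9)]]))


def test_rescale_score_endpoints_and_midpoint():
    assert rescale_score(4.0, 0.0, 4.0) == 100.0
    assert rescale_score(0.0, 0.0, 4.0) == 0.0
    assert rescale_score(2.0, 0.0, 4.0) == 50.0
    with pytest.raises(ValueError):
        rescale_score(5.0, 0.0, 4.0)
    with pytest.raises(ValueError):
        rescale_score(1.0, 2.0, 2.0)


@settings(deadline=None, max_examples=50)
@given(
    lo=st.floats(-10, 10),
    width=st.floats(0.5, 50),
    f1=st.floats(0, 1),
    f2=st.floats(0, 1),
)
def test_rescale_score_affine_order_preserving(lo, width, f1, f2):
    hi = lo + width
    x1, x2 = lo + f1 * width, lo + f2 * width
    y1, y2 = rescale_score(x1, lo, hi), rescale_score(x2, lo, hi)
    assert 0 <= y1 <= 100
    if x1 < x2:
        assert y1 < y2 or np.isclose(y1, y2)
    # invertible: map back
    assert np.isclose(lo + y1 / 100 * width, x1, atol=1e-9)


def test_aggregate_observer_means_and_counts():
    obs = pd.DataFrame(
        {
            "physician_id": ["a", "a", "a", "b"],
            "consultation_id": ["1", "2", "3", "1"],
            "instrument": ["OPTION-5"] * 3 + ["4HCS"],
            "score": [20.0, 40.0, 60.0, 80.0],
        }
    )
    agg = aggregate_observer(obs)
    assert agg.loc["a", "OPTION-5"] == 40.0
    assert agg.loc["a", "n_OPTION-5"] == 3
    # physician b absent (NaN) for OPTION-5, never zero-filled
    assert np.isnan(agg.loc["b", "OPTION-5"])
    assert agg.loc["b", "4HCS"] == 80.0


def test_aggregate_observer_study_like_coverage():
    cfg = GeneratorConfig(n_physicians=28)
    m = sample_true_model(cfg, seed=50)
    from sdmnet import simulate_observer_scores

    obs = simulate_observer_scores(m, seed=51)
    agg = aggregate_observer(obs)
    # per-instrument n follows the configured coverage (22 / 24 / 22)
    assert agg["OPTION-12"].notna().sum() == 22
    assert agg["OPTION-5"].notna().sum() == 24
    assert agg["4HCS"].notna().sum() == 22
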