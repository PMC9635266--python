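"""Long-table assembly, factorial OLS fits, and Tukey cell contrasts."""

import numpy as np
import pandas as pd
import pytest

from recurlang.models import (LEVEL_CODES, TYPE_CODES, build_long_table,
                              fit_metric_model, posthoc_cell_contrasts,
                              predictor_correlations)
from recurlang.rqa import RQAResult


def make_profiles(n_children, rng, det_missing_every=None):
    profiles, meta_rows = {}, []
    for i in range(n_children):
        cid = f"c{i:03d}"
        prof = {}
        for ty in ("noun", "verb"):
            for lv in ("lexical", "grammar"):
                det = float(rng.uniform(5, 40))
                if det_missing_every and i % det_missing_every == 0 \
                        and (ty, lv) == ("noun", "lexical"):
                    det = None
                prof[(ty, lv)] = RQAResult(cid, ty, lv, 100,
                                           float(rng.uniform(0.5, 8)), det,
                                           50, 25)
        profiles[cid] = prof
        meta_rows.append({"child_id": cid,
                          "mlu": float(rng.uniform(2, 9)),
                          "total_utterances": int(rng.integers(20, 260)),
                          "ados_severity": float(rng.uniform(2, 10))})
    return profiles, pd.DataFrame(meta_rows)


DESIGN_COLS = ["type_code", "level_code", "mlu", "total_utterances",
               "ados_severity"]


def design_matrix(rows):
    """Design matrix in the model's own term order (returns X, term names)."""
    probe = fit_metric_model(rows.assign(rr=np.arange(len(rows)) % 7), "rr")
    names = list(probe.coefficients.index)
    cols = []
    for name in names:
        col = np.ones(len(rows))
        if name != "Intercept":
            for factor in name.split(":"):
                col = col * rows[factor].to_numpy()
        cols.append(col)
    return np.column_stack(cols), names


def test_long_table_shape_and_coding():
    rng = np.random.default_rng(0)
    profiles, meta = make_profiles(51, rng)
    rows = build_long_table(profiles, meta)
    assert len(rows) == 204
    assert set(rows["type_code"]) == set(TYPE_CODES.values())
    assert set(rows["level_code"]) == set(LEVEL_CODES.values())
    assert rows.groupby("child_id").size().eq(4).all()


def test_single_child_four_rows():
    rng = np.random.default_rng(1)
    profiles, meta = make_profiles(1, rng)
    assert len(build_long_table(profiles, meta)) == 4


def test_missing_metadata_names_child():
    rng = np.random.default_rng(2)
    profiles, meta = make_profiles(3, rng)
    with pytest.raises(KeyError, match="c002"):
        build_long_table(profiles, meta[meta.child_id != "c002"])


def test_balanced_design_orthogonal_to_covariates():
    rng = np.random.default_rng(3)
    profiles, meta = make_profiles(30, rng)
    corr = predictor_correlations(build_long_table(profiles, meta))
    for cov in ("mlu", "total_utterances", "ados_severity"):
        assert corr.loc["type_code", cov] == pytest.approx(0.0, abs=1e-12)
        assert corr.loc["level_code", cov] == pytest.approx(0.0, abs=1e-12)
    assert corr.loc["type_code", "level_code"] == pytest.approx(0.0,
                                                                abs=1e-12)


def test_rr_model_df_matches_design():
    rng = np.random.default_rng(4)
    profiles, meta = make_profiles(51, rng)
    fit = fit_metric_model(build_long_table(profiles, meta), "rr")
    assert len(fit.coefficients) == 16
    assert fit.df_model == 15
    assert fit.df_resid == 188


def test_missing_det_rows_dropped_listwise():
    rng = np.random.default_rng(5)
    profiles, meta = make_profiles(40, rng, det_missing_every=4)
    rows = build_long_table(profiles, meta)
    n_missing = int(rows["det"].isna().sum())
    assert n_missing == 10
    fit_rr = fit_metric_model(rows, "rr")
    fit_det = fit_metric_model(rows, "det")
    assert fit_rr.df_resid - fit_det.df_resid == n_missing


def test_planted_coefficients_recovered():
    rng = np.random.default_rng(6)
    profiles, meta = make_profiles(51, rng)
    rows = build_long_table(profiles, meta)
    X, _ = design_matrix(rows)
    beta = rng.normal(0, 1, size=16)
    rows = rows.assign(rr=X @ beta + rng.normal(0, 1, size=len(rows)))
    fit = fit_metric_model(rows, "rr")
    inside = ((fit.coefficients["ci_low"].to_numpy() <= beta)
              & (beta <= fit.coefficients["ci_high"].to_numpy()))
    assert inside.sum() >= 13  # ~95% coverage per term; allow a few misses


def test_type_code_sign_flip_symmetry():
    rng = np.random.default_rng(7)
    profiles, meta = make_profiles(30, rng)
    rows = build_long_table(profiles, meta)
    flipped = rows.assign(type_code=-rows["type_code"])
    a = fit_metric_model(rows, "rr").coefficients["B"]
    b = fit_metric_model(flipped, "rr").coefficients["B"]
    for term in a.index:
        sign = -1.0 if "type_code" in term else 1.0
        assert b[term] == pytest.approx(sign * a[term], rel=1e-8, abs=1e-8)


def test_f_and_r2_invariant_to_covariate_rescaling():
    rng = np.random.default_rng(8)
    profiles, meta = make_profiles(40, rng)
    rows = build_long_table(profiles, meta)
    scaled = rows.assign(mlu=10 * rows["mlu"] + 3)
    a = fit_metric_model(rows, "rr")
    b = fit_metric_model(scaled, "rr")
    assert b.r_squared == pytest.approx(a.r_squared, rel=1e-9)
    assert b.f_statistic == pytest.approx(a.f_statistic, rel=1e-9)


def test_constant_response_handled():
    rng = np.random.default_rng(9)
    profiles, meta = make_profiles(20, rng)
    rows = build_long_table(profiles, meta).assign(rr=0.0)
    fit = fit_metric_model(rows, "rr")
    assert np.allclose(fit.coefficients["B"], 0.0, atol=1e-10)
    assert fit.r_squared == pytest.approx(0.0, abs=1e-10)


def test_too_few_rows_rejected():
    rng = np.random.default_rng(10)
    profiles, meta = make_profiles(4, rng)  # 16 rows < 17 required
    with pytest.raises(ValueError):
        fit_metric_model(build_long_table(profiles, meta), "rr")


def test_contrasts_identical_cells_nonsignificant():
    rng = np.random.default_rng(11)
    profiles, meta = make_profiles(20, rng)
    rows = build_long_table(profiles, meta)
    rows = rows.assign(rr=rng.normal(10, 1, size=len(rows)))
    contrasts = posthoc_cell_contrasts(rows, "rr")
    assert len(contrasts) == 6
    assert all(c.p_adjusted > 0.05 for c in contrasts)


def test_contrasts_detect_shifted_cell():
    rng = np.random.default_rng(12)
    profiles, meta = make_profiles(25, rng)
    rows = build_long_table(profiles, meta)
    rr = rng.normal(10, 1, size=len(rows))
    shift = (rows["cell"] == "noun:grammar").to_numpy() * 8.0
    rows = rows.assign(rr=rr + shift)
    contrasts = posthoc_cell_contrasts(rows, "rr")
    involving = [c for c in contrasts if "noun:grammar" in c.pair]
    others = [c for c in contrasts if "noun:grammar" not in c.pair]
    assert all(c.p_adjusted < 0.01 for c in involving)
    assert all(c.p_adjusted > 0.05 for c in others)
    # the shifted cell's mean is higher in every comparison
    for c in involving:
        higher_second = c.pair[1] == "noun:grammar"
        assert (c.estimate > 0) == higher_second


def test_mixed_model_variant_runs():
    rng = np.random.default_rng(13)
    profiles, meta = make_profiles(30, rng)
    rows = build_long_table(profiles, meta)
    fit = fit_metric_model(rows, "rr", random_intercept=True)
    assert len(fit.coefficients) == 16
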