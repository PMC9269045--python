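"""Collinearity diagnostics and bidirectional stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from gaitsynergy.determinants import StepwiseOLS, collinearity_diagnostics

PREDICTORS = ("x1", "x2", "x3", "x4", "x5", "x6")


def _table(X, y):
    tab = pd.DataFrame(X, columns=list(PREDICTORS)[: X.shape[1]])
    tab["y"] = y
    return tab


def test_vif_is_one_for_orthogonal_predictors():
    n = 64
    t = np.arange(n)
    X = np.column_stack(
        [np.sin(2 * np.pi * k * t / n) for k in (1, 2, 3)]
    )  # exactly orthogonal columns
    tab = _table(X, np.zeros(n))
    rep = collinearity_diagnostics(tab, ("x1", "x2", "x3"))
    assert np.allclose(rep.vif.to_numpy(), 1.0, atol=1e-6)


def test_duplicated_column_flags_infinite_vif():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 2))
    tab = _table(np.column_stack([X, X[:, 0]]), rng.normal(size=40))
    rep = collinearity_diagnostics(tab, ("x1", "x2", "x3"))
    assert np.isinf(rep.vif["x1"]) and np.isinf(rep.vif["x3"])
    assert "x3" in rep.flagged


def test_near_collinear_pair_exceeds_vif_ten():
    rng = np.random.default_rng(1)
    x1 = rng.normal(size=60)
    x2 = x1 + rng.normal(0, 0.01 * x1.std(), 60)
    tab = _table(np.column_stack([x1, x2, rng.normal(size=60)]), rng.normal(size=60))
    rep = collinearity_diagnostics(tab, ("x1", "x2", "x3"))
    assert rep.vif["x1"] > 10 and rep.vif["x2"] > 10


def test_exact_single_predictor_selected_with_unit_r2():
    rng = np.random.default_rng(2)
    x1 = rng.normal(size=30)
    tab = _table(x1[:, None], x1.copy())
    res = StepwiseOLS(tab, "y", ("x1",), screen_collinearity=False).fit()
    assert res.selected == ["x1"]
    assert res.rsquared == pytest.approx(1.0)


def test_power_construction_always_includes_true_predictor():
    included = 0
    exact = 0
    n_rep = 200
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        X = rng.normal(size=(40, 6))
        y = 3 * X[:, 0] + rng.normal(0, 0.1 * np.std(3 * X[:, 0]), 40)
        sel = StepwiseOLS(_table(X, y), "y", PREDICTORS).fit().selected
        included += "x1" in sel
        exact += sel == ["x1"]
    assert included == n_rep
    # with five noise candidates each tested at alpha 0.1, the exact-
    # selection rate has expectation ~0.9^5 ~= 0.59; check the binomial band
    assert 0.45 <= exact / n_rep <= 0.72


def test_pure_noise_often_selects_nothing():
    empty = 0
    for rep in range(500):
        rng = np.random.default_rng(5000 + rep)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        empty += StepwiseOLS(_table(X, y), "y", PREDICTORS).fit().selected == []
    assert empty >= 200  # >= 40% of 500


def test_selection_is_invariant_to_predictor_rescaling():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 6))
    y = 3 * X[:, 0] + rng.normal(0, 0.3, 40)
    tab = _table(X, y)
    res1 = StepwiseOLS(tab, "y", PREDICTORS).fit()
    tab2 = tab.copy()
    tab2["x1"] *= 1e3
    tab2["x4"] *= 1e-4
    res2 = StepwiseOLS(tab2, "y", PREDICTORS).fit()
    assert res1.selected == res2.selected
    assert res1.rsquared == pytest.approx(res2.rsquared)


def test_final_model_is_internally_consistent():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    X = rng.normal(size=(50, 6))
    y = 2 * X[:, 0] - X[:, 2] + rng.normal(0, 0.2, 50)
    tab = _table(X, y)
    res = StepwiseOLS(tab, "y", PREDICTORS).fit()
    refit = sm.OLS(y, sm.add_constant(tab[res.selected].to_numpy())).fit()
    assert np.allclose(res.params.to_numpy(), refit.params)
    assert res.rsquared == pytest.approx(refit.rsquared)


def test_rom_knee_recovered_on_stroke_like_cohort():
    # response constructed from knee range of motion + noise across a
    # jittered stroke cohort; the selection should find it reliably
    from gaitsynergy.profiles import jitter_profile, make_profile

    base = make_profile("stroke")
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(900 + rep)
        rows = []
        for subj in range(12):
            prof = jitter_profile(base, int(rng.integers(2**31)), sd=0.12)
            for side in ("left", "right"):
                rows.append(
                    {
                        "di_stance": rng.uniform(0.1, 0.5),
                        "di_swing": rng.uniform(0.05, 0.35),
                        "rom_hip": prof.rom_hip[side],
                        "rom_knee": prof.rom_knee[side],
                        "swing_percentage": prof.swing_percentage[side],
                        "speed": prof.speed,
                    }
                )
        tab = pd.DataFrame(rows)
        tab["y"] = -2.0 * tab["rom_knee"] + rng.normal(0, 0.2 * tab["rom_knee"].std(), len(tab))
        res = StepwiseOLS(
            tab,
            "y",
            ("di_stance", "di_swing", "rom_hip", "rom_knee", "swing_percentage", "speed"),
        ).fit()
        hits += "rom_knee" in res.selected
    assert hits >= 18


def test_too_few_rows_rejected():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(5, 6))
    with pytest.raises(ValueError):
        StepwiseOLS(_table(X, rng.normal(size=5)), "y", PREDICTORS)
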