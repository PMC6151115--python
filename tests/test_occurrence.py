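"""Logistic occurrence modelling, AIC selection and group comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from cholosc.occurrence import (LogisticFit, candidate_formulas,
                                collapse_areas, compare_groups, fit_logistic,
                                predicted_probability_by_div, rank_fits,
                                select_model)


def _area_table():
    rows = []
    presence = {"c1": {"DG": 0, "CA3": 1, "CA1": 0},
                "c2": {"DG": 0, "CA3": 0, "CA1": 0},
                "c3": {"DG": 1, "CA3": 1, "CA1": 1}}
    for cid, areas in presence.items():
        for area, p in areas.items():
            rows.append({"culture_id": cid, "genotype": "WT", "div": 7,
                         "area": area, "band": "gamma", "present": p})
    return pd.DataFrame(rows)


def _simulate_table(rng, n_per_cell, beta_div13=0.0, beta_div26=0.0,
                    beta_ko=0.0, intercept=0.0):
    rows = []
    for g in ("WT", "KO"):
        for d in (7, 13, 26):
            eta = intercept + (beta_div13 if d == 13 else 0.0) \
                + (beta_div26 if d == 26 else 0.0) + (beta_ko if g == "KO" else 0.0)
            p = expit(eta)
            y = rng.random(n_per_cell) < p
            for i, yi in enumerate(y):
                rows.append({"culture_id": f"{g}{d}-{i}", "genotype": g,
                             "div": d, "band": "gamma", "present": int(yi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- collapse

def test_collapse_is_logical_or_over_areas():
    out = collapse_areas(_area_table()).set_index("culture_id")["present"]
    assert out["c1"] == 1  # (0, 1, 0) -> 1
    assert out["c2"] == 0  # (0, 0, 0) -> 0
    assert out["c3"] == 1


def test_collapsed_rate_no_less_than_any_area_rate():
    tab = _area_table()
    collapsed_rate = collapse_areas(tab)["present"].mean()
    for area, grp in tab.groupby("area"):
        assert collapsed_rate >= grp["present"].mean()


def test_collapse_rejects_duplicate_rows():
    tab = pd.concat([_area_table()] * 2, ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        collapse_areas(tab)


# ------------------------------------------------------------------- fitting

def test_intercept_only_fit_recovers_half_probability(rng):
    tab = pd.DataFrame({"present": [0, 1] * 100, "genotype": "WT", "div": 7,
                        "culture_id": range(200)})
    fit = fit_logistic(tab, ())
    assert fit.coefficients["Intercept"] == pytest.approx(0.0, abs=1e-8)
    assert fit.converged
    assert fit.k == 1
    # AIC identity for the intercept-only model: 2 - 2 lnL
    assert fit.aic == pytest.approx(2.0 - 2.0 * fit.log_likelihood)


def test_parameter_recovery_within_three_standard_errors(rng):
    """Estimates from n = 2000 recover known log-odds coefficients."""
    truth = {"b13": 1.2, "b26": 0.8, "ko": -0.5, "icpt": -0.4}
    tab = _simulate_table(rng, 2000 // 6 * 3, beta_div13=truth["b13"],
                          beta_div26=truth["b26"], beta_ko=truth["ko"],
                          intercept=truth["icpt"])
    fit = fit_logistic(tab, ("genotype", "div"))
    res = fit.result
    se = res.bse
    params = res.params
    expected = {
        # KO sorts first, so it is the reference level of the intercept
        "Intercept": truth["icpt"] + truth["ko"],
        "C(genotype)[T.WT]": -truth["ko"],  # WT relative to KO baseline
        "C(div)[T.13]": truth["b13"],
        "C(div)[T.26]": truth["b26"],
    }
    for name, val in expected.items():
        assert abs(params[name] - val) <= 3 * se[name], name


def test_aic_identity_holds_for_every_fit(rng):
    tab = _simulate_table(rng, 80, beta_div13=0.7)
    for terms in [(), ("genotype",), ("div",), ("genotype", "div"),
                  ("genotype", "div", "genotype:div")]:
        fit = fit_logistic(tab, terms)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood,
                                        abs=1e-10)


def test_saturated_model_reproduces_cell_proportions(rng):
    tab = _simulate_table(rng, 150, beta_div13=0.9, beta_ko=0.6)
    fit = fit_logistic(tab, ("genotype", "div", "genotype:div"))
    pred = fit.predict(tab)
    for (g, d), grp in tab.groupby(["genotype", "div"]):
        cell_pred = pred[(tab["genotype"] == g) & (tab["div"] == d)]
        assert np.allclose(cell_pred, grp["present"].mean(), atol=1e-6)


def test_perfect_separation_is_flagged():
    tab = pd.DataFrame({
        "present": [0] * 20 + [1] * 20,
        "genotype": ["WT"] * 20 + ["KO"] * 20,
        "div": [7, 13] * 20,
        "culture_id": range(40),
    })
    fit = fit_logistic(tab, ("genotype",))
    assert not fit.converged


def test_empty_table_and_nonbinary_rejected():
    with pytest.raises(ValueError):
        fit_logistic(pd.DataFrame(columns=["present"]), ())
    tab = pd.DataFrame({"present": [0, 2], "genotype": ["WT", "KO"]})
    with pytest.raises(ValueError, match="binary"):
        fit_logistic(tab, ())


# ----------------------------------------------------------- model selection

def test_candidate_lattice_respects_marginality():
    two = candidate_formulas(("genotype", "div"))
    assert len(two) == 5
    assert () in two
    assert ("genotype", "div", "genotype:div") in two
    three = candidate_formulas(("genotype", "div", "area"))
    assert len(three) == 19
    for model in three:
        for term in model:
            for f in term.split(":"):
                if ":" in term:
                    assert f in model  # interaction implies its main effects
    assert ("genotype", "div", "area", "genotype:div", "genotype:area",
            "div:area", "genotype:div:area") in three


def test_aic_tie_prefers_fewer_parameters():
    small = LogisticFit((), {}, -10.0, 22.0, 50, 1, True)
    big = LogisticFit(("div",), {}, -8.0, 22.0, 50, 3, True)
    assert rank_fits([big, small])[0] is small


def test_selection_retains_strong_div_effect(rng):
    """With a large DIV effect (n=600), the lowest-AIC model contains DIV in
    nearly every replicate."""
    kept = 0
    for _ in range(10):
        tab = _simulate_table(rng, 100, beta_div13=1.5, beta_div26=1.6)
        sel = select_model(tab)
        kept += any("div" in t for t in sel.best.formula)
    assert kept >= 9


def test_null_model_competitive_without_effects(rng):
    hits = 0
    for _ in range(10):
        tab = _simulate_table(rng, 100)
        sel = select_model(tab)
        null_delta = float(sel.ranking.loc[sel.ranking["formula"] == "null",
                                           "delta_aic"].iloc[0])
        hits += null_delta <= 2.0
    assert hits >= 6


def test_likelihood_ratio_type_one_error_at_nominal_rate(rng):
    """Full model vs null on no-effect data rejects at the nominal 5% rate
    (within 2 SE over 500 simulated cohorts)."""
    from scipy import stats as spstats

    alpha, n_sim = 0.05, 500
    rejections = 0
    for _ in range(n_sim):
        tab = _simulate_table(rng, 20)
        null = fit_logistic(tab, ())
        full = fit_logistic(tab, ("genotype", "div", "genotype:div"))
        lr = 2 * (full.log_likelihood - null.log_likelihood)
        p = spstats.chi2.sf(lr, full.k - null.k)
        rejections += p < alpha
    se = np.sqrt(alpha * (1 - alpha) / n_sim)
    assert abs(rejections / n_sim - alpha) <= 2 * se


def test_predicted_probability_by_div(rng):
    tab = _simulate_table(rng, 400, beta_div13=logit(0.62) - logit(0.27),
                          beta_div26=logit(0.65) - logit(0.27),
                          intercept=logit(0.27))
    fit = fit_logistic(tab, ("div",))
    est = predicted_probability_by_div(fit, tab)
    for d, p in {7: 0.27, 13: 0.62, 26: 0.65}.items():
        assert est[d] == pytest.approx(p, abs=0.07)


# -------------------------------------------------------------------- ANOVA

def _value_table(rng, shift_ko=0.0, n=10):
    rows = []
    for g in ("WT", "KO"):
        for d in (7, 13, 26):
            vals = rng.normal(40.0 + (shift_ko if g == "KO" else 0.0), 1.0, n)
            for v in vals:
                rows.append({"genotype": g, "div": d, "value": v})
    return pd.DataFrame(rows)


def test_anova_flags_identical_values_nonsignificant(rng):
    tab = _value_table(rng)
    tab["value"] = 40.0
    out = compare_groups(tab)
    assert not out["significant"].any()
    assert out["note"].str.contains("identical").all()


def test_anova_detects_large_known_shift(rng):
    out = compare_groups(_value_table(rng, shift_ko=5.0))
    geno = out[out["effect"] == "genotype"].iloc[0]
    assert geno["p_value"] < 0.0125
    assert geno["significant"]
    assert geno["alpha"] == 0.0125


def test_anova_controls_family_wise_alpha(rng):
    """A p-value between 0.0125 and 0.05 is not significant at the
    family-wise level used for the four-band families."""
    out = compare_groups(_value_table(rng, shift_ko=0.0))
    assert (out.loc[out["p_value"] > 0.0125, "significant"] == False).all()


def test_anova_drops_interaction_on_empty_cell(rng):
    tab = _value_table(rng)
    tab = tab[~((tab["genotype"] == "KO") & (tab["div"] == 26))]
    with pytest.warns(UserWarning, match="interaction"):
        out = compare_groups(tab)
    assert "genotype:div" not in set(out["effect"])
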