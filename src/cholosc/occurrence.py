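"""Occurrence modelling: binomial logistic regression with AIC model
selection, the area-collapse rule, and two-way group comparisons.

Per band, presence/absence of an oscillation per culture (after collapsing
areas with a logical OR) is modelled by logistic regression in genotype and
DIV (and area, pre-collapse).  All hierarchical term subsets from the null
model to the full factorial are fitted and ranked by AIC; the lowest-AIC
model is assessed against the null with a likelihood-ratio test.  Peak
frequency and relative peak power are compared across genotype x DIV with
two-way fixed-effects ANOVA (Type II sums of squares) at a family-wise
alpha of 0.0125 (four bands per family).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as spstats

DEFAULT_ALPHA = 0.0125  # family-wise alpha for a family of four tests

def collapse_areas(tab: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-area rows to one row per culture x band.

    A culture has an oscillation in a band if at least one of its areas does
    (logical OR over areas).
    """
    required = {"culture_id", "area", "band", "present"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"occurrence table lacks columns: {sorted(missing)}")
    if tab.duplicated(subset=["culture_id", "area", "band"]).any():
        raise ValueError("duplicate culture x area x band rows")
    keys = ["culture_id", "band"]
    carried = [c for c in ("genotype", "div") if c in tab.columns]
    agg = {c: "first" for c in carried}
    agg["present"] = "max"
    out = tab.groupby(keys, as_index=False, sort=False).agg(agg)
    return out[keys[:1] + carried + ["band", "present"]]


def _patsy_term(term: str) -> str:
    return ":".join(f"C({f})" for f in term.split(":"))


@dataclass
class LogisticFit:
    """One fitted binomial logistic model."""

    formula: Tuple[str, ...]
    coefficients: Dict[str, float]
    log_likelihood: float
    aic: float
    n: int
    k: int
    converged: bool
    result: object = field(default=None, repr=False)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        if self.result is None:
            raise ValueError("fit carries no underlying model result")
        return np.asarray(self.result.predict(data))


def fit_logistic(tab: pd.DataFrame, terms: Sequence[str] = ()) -> LogisticFit:
    """Maximum-likelihood binomial logistic fit of ``present`` on ``terms``.

    ``terms`` are factor names and ':'-joined interactions, e.g.
    ``("genotype", "div", "genotype:div")``; the empty tuple is the
    intercept-only null model.  Genotype, DIV and area enter categorically.
    Perfect separation or non-convergence is flagged (``converged=False``),
    never silently returned as a clean fit.
    """
    if len(tab) == 0:
        raise ValueError("empty occurrence table")
    if not set(np.unique(tab["present"])) <= {0, 1}:
        raise ValueError("present must be binary 0/1")
    terms = tuple(terms)
    for t in terms:
        for f in t.split(":"):
            if f not in tab.columns:
                raise ValueError(f"term factor {f!r} not in table")
            if tab[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than two levels")
    rhs = " + ".join(_patsy_term(t) for t in terms) if terms else "1"
    formula = f"present ~ {rhs}"
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = smf.glm(formula, data=tab, family=sm.families.Binomial()).fit()
        except Exception as err:  # e.g. PerfectSeparationError
            if "separation" not in str(err).lower():
                raise
            return LogisticFit(formula=terms, coefficients={},
                               log_likelihood=float("nan"), aic=float("inf"),
                               n=len(tab), k=0, converged=False)
    if any("separation" in str(w.message).lower() for w in caught):
        converged = False
    if not getattr(res, "converged", True):
        converged = False
    params = res.params.to_dict()
    # quasi-separation shows as runaway log-odds
    if params and max(abs(v) for v in params.values()) > 15:
        converged = False
    return LogisticFit(formula=terms, coefficients=params,
                       log_likelihood=float(res.llf), aic=float(res.aic),
                       n=int(res.nobs), k=len(params), converged=converged,
                       result=res)


def candidate_formulas(factors: Sequence[str] = ("genotype", "div", "area")
                       ) -> List[Tuple[str, ...]]:
    """All term sets respecting marginality, from the null model up to the
    full factorial (interactions included only with all their main effects)."""
    factors = tuple(factors)
    models: List[Tuple[str, ...]] = []
    for r in range(len(factors) + 1):
        for mains in itertools.combinations(factors, r):
            pairs = list(itertools.combinations(mains, 2))
            for s in range(len(pairs) + 1):
                for inter in itertools.combinations(pairs, s):
                    terms = tuple(mains) + tuple(":".join(p) for p in inter)
                    models.append(terms)
                    if len(mains) == 3 and len(inter) == 3:
                        models.append(terms + (":".join(mains),))
    seen, out = set(), []
    for m in models:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out


@dataclass
class ModelSelection:
    best: LogisticFit
    fits: List[LogisticFit]
    ranking: pd.DataFrame
    lr_stat: float
    lr_df: int
    lr_pvalue: float


def rank_fits(fits: Sequence[LogisticFit]) -> List[LogisticFit]:
    """Sort by AIC ascending; exact AIC ties prefer the smaller model."""
    return sorted(fits, key=lambda f: (f.aic, f.k))


def select_model(tab: pd.DataFrame,
                 candidates: Optional[Sequence[Sequence[str]]] = None,
                 factors: Optional[Sequence[str]] = None) -> ModelSelection:
    """Fit every candidate model, pick the lowest AIC, test it against null.

    Candidates default to all marginality-respecting subsets of the factors
    present in the table (among genotype, div, area).  A candidate whose fit
    fails outright is excluded with a warning; flagged (non-converged) fits
    stay in the ranking but carry ``converged=False``.
    """
    if factors is None:
        factors = [f for f in ("genotype", "div", "area")
                   if f in tab.columns and tab[f].nunique() > 1]
    if candidates is None:
        candidates = candidate_formulas(factors)
    candidates = [tuple(c) for c in candidates]
    if () not in candidates:
        candidates = [()] + candidates
    if len(candidates) < 2:
        raise ValueError("model selection needs at least two candidates (incl. null)")
    fits = []
    for terms in candidates:
        try:
            fits.append(fit_logistic(tab, terms))
        except Exception as err:
            warnings.warn(f"candidate {terms} failed and was excluded: {err}")
    ranked = rank_fits(fits)
    best = ranked[0]
    null = next(f for f in fits if f.formula == ())
    lr_stat = max(0.0, 2.0 * (best.log_likelihood - null.log_likelihood))
    lr_df = max(0, best.k - null.k)
    lr_p = float(spstats.chi2.sf(lr_stat, lr_df)) if lr_df > 0 else 1.0
    ranking = pd.DataFrame({
        "formula": ["+".join(f.formula) if f.formula else "null" for f in ranked],
        "k": [f.k for f in ranked],
        "log_likelihood": [f.log_likelihood for f in ranked],
        "aic": [f.aic for f in ranked],
        "delta_aic": [f.aic - best.aic for f in ranked],
        "converged": [f.converged for f in ranked],
    })
    return ModelSelection(best=best, fits=ranked, ranking=ranking,
                          lr_stat=lr_stat, lr_df=lr_df, lr_pvalue=lr_p)


def predicted_probability_by_div(fit: LogisticFit, tab: pd.DataFrame) -> Dict[int, float]:
    """Model-predicted occurrence probability per DIV, averaged over the
    observed covariate rows of that DIV."""
    probs = fit.predict(tab)
    out = {}
    for d, grp in tab.groupby("div"):
        out[int(d)] = float(np.mean(probs[tab["div"].values == d]))
    return out


def compare_groups(values: pd.DataFrame, value_col: str = "value",
                   factors: Tuple[str, str] = ("genotype", "div"),
                   alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (Type II) on per-culture values.

    Returns one row per effect with F, degrees of freedom, p-value and a
    significance flag at the family-wise alpha.  If any factor-combination
    cell is empty the interaction is dropped (with a warning); degenerate
    inputs (no residual variance) yield flagged, non-significant rows.
    """
    f1, f2 = factors
    for f in factors:
        if f not in values.columns:
            raise ValueError(f"missing factor column {f!r}")
    if len(values) < 2:
        raise ValueError("need at least two observations")
    cells = values.groupby([f1, f2], observed=True).size()
    full_grid = values[f1].nunique() * values[f2].nunique()
    with_interaction = len(cells) == full_grid and (cells >= 1).all()
    if not with_interaction:
        warnings.warn("empty genotype x div cells: interaction term dropped")
    effects = [f1, f2] + ([f"{f1}:{f2}"] if with_interaction else [])

    def flagged(reason: str) -> pd.DataFrame:
        return pd.DataFrame({
            "effect": effects,
            "F": np.nan, "df_num": np.nan, "df_den": np.nan, "p_value": np.nan,
            "significant": False, "alpha": alpha, "note": reason,
        })

    if values[value_col].nunique() <= 1:
        return flagged("all values identical; F undefined")
    rhs = f"C({f1}) + C({f2})"
    if with_interaction:
        rhs += f" + C({f1}):C({f2})"
    model = smf.ols(f"{value_col} ~ {rhs}", data=values).fit()
    if model.df_resid <= 0 or model.ssr <= 0:
        return flagged("no residual degrees of freedom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    rows = []
    for eff, patsy_eff in zip(effects, [_patsy_term(e) for e in effects]):
        if patsy_eff not in table.index:
            continue
        r = table.loc[patsy_eff]
        p = float(r["PR(>F)"])
        rows.append({"effect": eff, "F": float(r["F"]),
                     "df_num": float(r["df"]),
                     "df_den": float(model.df_resid),
                     "p_value": p, "significant": bool(p < alpha),
                     "alpha": alpha, "note": ""})
    return pd.DataFrame(rows)
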