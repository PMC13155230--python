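"""Confounder identification for the TSLB-biomarker models.

A two-stage procedure: (1) univariable screen — each candidate covariate is
regressed against continuous time since last birth (TSLB) on its own, keeping
candidates with p at or below a screening level; (2) joint backward stepwise
elimination run in parallel on a linear model for continuous TSLB and a
polytomous (unordered multinomial) model for the four-level ordinal TSLB. A
covariate is retained if it survives in EITHER model; covariates with strong
prior reasons (for example BMI, an established breast cancer risk factor) can
be forced into the set and bypass elimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["ConfounderSet", "univariable_screen", "joint_stepwise",
           "DEFAULT_CONFOUNDERS"]

logger = logging.getLogger(__name__)

#: The confounder set used by pipeline presets: the six covariates retained by
#: this procedure in the reference cohort (BMI forced on prior grounds).
DEFAULT_CONFOUNDERS = ["age_dx", "n_children", "breastfed", "menopause",
                       "fam_hx", "bmi"]


@dataclass
class ConfounderSet:
    selected: list[str]
    forced: list[str] = field(default_factory=list)
    screen_pvalues: dict[str, float] = field(default_factory=dict)
    criterion_trace: list[dict] = field(default_factory=list)

    def __post_init__(self):
        missing = set(self.forced) - set(self.selected)
        if missing:
            raise ValueError(f"forced covariates not in selected: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "forced": self.forced,
            "screen_pvalues": {k: (None if v is None or np.isnan(v) else float(v))
                               for k, v in self.screen_pvalues.items()},
            "criterion_trace": self.criterion_trace,
        }


def _is_categorical(s: pd.Series) -> bool:
    return (isinstance(s.dtype, pd.CategoricalDtype)
            or s.dtype == object or s.dtype == bool)


def _term(cohort: pd.DataFrame, name: str) -> str:
    return f"C({name})" if _is_categorical(cohort[name]) else name


def univariable_screen(cohort: pd.DataFrame, candidates: list[str]
                       ) -> dict[str, float]:
    """Per-candidate p-value from a single-covariate linear model for TSLB.

    Restricted to parous women with non-missing TSLB; complete cases per
    candidate. Categorical candidates enter as full factor blocks and are
    tested jointly (model F-test). Constant candidates are flagged with an
    absent (NaN) p-value.
    """
    parous = cohort[cohort["parous"] & cohort["tslb"].notna()]
    out: dict[str, float] = {}
    for cand in candidates:
        sub = parous[["tslb", cand]].dropna()
        if sub[cand].nunique() < 2:
            logger.warning("candidate %s is constant; p reported as absent", cand)
            out[cand] = float("nan")
            continue
        fit = smf.ols(f"tslb ~ {_term(cohort, cand)}", data=sub).fit()
        out[cand] = float(fit.f_pvalue)
    return out


def _linear_term_pvalues(parous: pd.DataFrame, terms: list[str],
                         term_of: dict[str, str]) -> tuple[dict[str, float], float]:
    formula = "tslb ~ " + (" + ".join(term_of[t] for t in terms) if terms else "1")
    fit = smf.ols(formula, data=parous).fit()
    wt = fit.wald_test_terms(scalar=True)
    table = wt.table
    pvals = {}
    for t in terms:
        pvals[t] = float(table.loc[term_of[t], "P>F" if "P>F" in table.columns
                                   else table.columns[-1]])
    return pvals, float(fit.aic)


def _multinomial_term_pvalues(parous: pd.DataFrame, terms: list[str],
                              term_of: dict[str, str]
                              ) -> tuple[dict[str, float], float, list[str]]:
    """Per-term likelihood-ratio p-values from an unordered multinomial logit
    of the 4-level ordinal TSLB. Returns (pvalues, aic, failed_terms)."""
    endog = parous["tslb_cat"].cat.remove_unused_categories().cat.codes.to_numpy()
    failures: list[str] = []

    def fit_terms(ts: list[str]):
        rhs = " + ".join(term_of[t] for t in ts) if ts else "1"
        exog = patsy.dmatrix(rhs, parous, return_type="dataframe")
        model = sm.MNLogit(endog, exog)
        res = model.fit(method="newton", maxiter=200, disp=0)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("multinomial fit did not converge")
        return res

    try:
        full = fit_terms(terms)
    except Exception as exc:  # separation / non-convergence
        logger.warning("multinomial full fit failed (%s); all terms retained "
                       "conservatively on this side", exc)
        return {t: 0.0 for t in terms}, float("inf"), list(terms)

    k_cat = len(np.unique(endog))
    pvals = {}
    for t in terms:
        reduced_terms = [u for u in terms if u != t]
        try:
            reduced = fit_terms(reduced_terms)
            lr = 2.0 * (full.llf - reduced.llf)
            df = (full.df_model - reduced.df_model) or (k_cat - 1)
            from scipy.stats import chi2
            pvals[t] = float(chi2.sf(max(lr, 0.0), df))
        except Exception as exc:
            logger.warning("multinomial reduced fit without %s failed (%s); "
                           "term retained conservatively", t, exc)
            failures.append(t)
            pvals[t] = 0.0
    return pvals, float(full.aic), failures


def joint_stepwise(cohort: pd.DataFrame, marginal_hits: list[str],
                   forced: list[str] | None = None, alpha: float = 0.05,
                   criterion: str = "pvalue",
                   screen_pvalues: dict[str, float] | None = None
                   ) -> ConfounderSet:
    """Backward elimination on parallel linear and polytomous TSLB models.

    At each step, every non-forced candidate's criterion is the smaller of its
    p-values in the two models (a covariate survives if either model wants
    it). The candidate with the largest criterion is dropped if it exceeds
    ``alpha``; ties are broken lexicographically and logged. ``criterion="aic"``
    instead drops the covariate whose removal most improves AIC in both
    models. Forced covariates bypass elimination. A multinomial fit failure
    (for example quasi-separation) retains the affected covariate
    conservatively and is recorded in the trace.
    """
    if criterion not in ("pvalue", "aic"):
        raise ValueError("criterion must be 'pvalue' or 'aic'")
    forced = list(forced or [])
    parous = cohort[cohort["parous"] & cohort["tslb"].notna()]
    candidates = sorted(set(marginal_hits) | set(forced))
    parous = parous[["tslb", "tslb_cat"] + candidates].dropna()
    term_of = {c: _term(cohort, c) for c in candidates}

    current = list(candidates)
    trace: list[dict] = []
    while True:
        droppable = sorted(c for c in current if c not in forced)
        if not droppable:
            break
        lin_p, lin_aic = _linear_term_pvalues(parous, current, term_of)
        mul_p, mul_aic, failed = _multinomial_term_pvalues(parous, current, term_of)
        if criterion == "pvalue":
            crit = {c: min(lin_p[c], mul_p[c]) for c in droppable}
            worst = max(droppable, key=lambda c: (crit[c], [-ord(ch) for ch in c]))
            # lexicographic tie-break: among equal criteria pick smallest name
            ties = [c for c in droppable if crit[c] == crit[worst]]
            worst = sorted(ties)[0]
            if crit[worst] <= alpha:
                break
            record = {"dropped": worst, "criterion": "min_pvalue",
                      "value": crit[worst],
                      "linear_p": lin_p[worst], "multinomial_p": mul_p[worst]}
        else:
            scores = {}
            for c in droppable:
                reduced = [u for u in current if u != c]
                _, lin_aic_r = _linear_term_pvalues(parous, reduced, term_of)
                _, mul_aic_r, _ = _multinomial_term_pvalues(parous, reduced, term_of)
                # positive score: dropping c worsens at least one model
                scores[c] = max(lin_aic_r - lin_aic, mul_aic_r - mul_aic)
            worst = sorted([c for c in droppable
                            if scores[c] == min(scores.values())])[0]
            if scores[worst] >= 0:
                break
            record = {"dropped": worst, "criterion": "delta_aic",
                      "value": scores[worst]}
        if failed:
            record["multinomial_failures"] = failed
        trace.append(record)
        current.remove(worst)

    selected = sorted(set(current) | set(forced))
    return ConfounderSet(
        selected=selected, forced=sorted(forced),
        screen_pvalues=dict(screen_pvalues or {}),
        criterion_trace=trace,
    )


def select_confounders(cohort: pd.DataFrame, candidates: list[str],
                       forced: list[str] | None = None,
                       screen_alpha: float = 0.05, alpha: float = 0.05,
                       criterion: str = "pvalue") -> ConfounderSet:
    """Convenience wrapper: univariable screen then joint stepwise."""
    screen = univariable_screen(cohort, candidates)
    hits = [c for c, p in screen.items()
            if p is not None and not np.isnan(p) and p <= screen_alpha]
    result = joint_stepwise(cohort, hits, forced=forced, alpha=alpha,
                            criterion=criterion, screen_pvalues=screen)
    return result
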