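"""General linear models for egg volume with competing age parameterizations.

Fits Gaussian identity-link linear models of mean (VM) or total (VT) egg
volume per nest against age — as a linear term, a quadratic, a logarithm, or
one of the four class pooling schemes — plus clutch size and optional annual
covariates, and ranks the candidates by AIC.

Two-stage candidate enumeration: an *age-only* stage compares the seven age
forms (plus a no-age null), each with clutch size; an *environmental* stage
fixes the winning age form and adds combinations of Year, z-scored food per
capita and one NAO index (winter or annual, never both), optionally with
age x annual-variable interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .features import SCHEMES, age_to_class

__all__ = [
    "AGE_FORMS",
    "ModelSpec",
    "FittedModel",
    "candidate_specs",
    "fit_glm",
    "aic_rank",
    "select_best",
]

AGE_FORMS = ("NONE", "LINEAR", "QUADRATIC", "LOG", "AGE14", "AGE6", "AGE3", "AGE2")

_AGE_TERMS = {
    "NONE": None,
    "LINEAR": "age",
    "QUADRATIC": "age + I(age**2)",
    "LOG": "np.log(age)",
    "AGE14": "C(ac_AGE14)",
    "AGE6": "C(ac_AGE6)",
    "AGE3": "C(ac_AGE3)",
    "AGE2": "C(ac_AGE2)",
}

# the single term usable on the right of an `age x variable` interaction
_AGE_INTERACT = {
    "LINEAR": "age",
    "QUADRATIC": "age",
    "LOG": "np.log(age)",
    "AGE14": "C(ac_AGE14)",
    "AGE6": "C(ac_AGE6)",
    "AGE3": "C(ac_AGE3)",
    "AGE2": "C(ac_AGE2)",
}

_COVARIATE_TERMS = {
    "Clutch": "C(Clutch)",
    "Year": "C(Year)",
    "Foodpc": "Foodpc",
    "WNAO": "WNAO",
    "ANAO": "ANAO",
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, age form, covariates, interactions.

    Clutch size is always included; WNAO and ANAO never co-occur; interaction
    terms always appear alongside both main effects (hierarchy convention).
    """

    response: str = "VM"
    age_form: str = "QUADRATIC"
    covariates: tuple[str, ...] = ("Clutch",)
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.response not in ("VM", "VT"):
            raise ValueError("response must be VM or VT")
        if self.age_form not in AGE_FORMS:
            raise ValueError(f"unknown age form {self.age_form!r}")
        if "Clutch" not in self.covariates:
            raise ValueError("Clutch must be included in every model")
        if "WNAO" in self.covariates and "ANAO" in self.covariates:
            raise ValueError("WNAO and ANAO may not co-occur in one model")
        unknown = set(self.covariates) - set(_COVARIATE_TERMS)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")
        for age_form, var in self.interactions:
            if age_form != self.age_form:
                raise ValueError("interaction age form must match the model's age form")
            if var not in ("Year", "Foodpc", "WNAO", "ANAO"):
                raise ValueError(f"interactions only with annual variables, not {var!r}")
            if var not in self.covariates:
                raise ValueError(f"interaction with {var} requires its main effect")
            if self.age_form == "NONE":
                raise ValueError("no age x variable interaction without an age term")

    def formula(self) -> str:
        terms = []
        age_term = _AGE_TERMS[self.age_form]
        if age_term:
            terms.append(age_term)
        for cov in self.covariates:
            terms.append(_COVARIATE_TERMS[cov])
        for age_form, var in self.interactions:
            terms.append(f"{_AGE_INTERACT[age_form]}:{_COVARIATE_TERMS[var]}")
        return f"{self.response} ~ " + " + ".join(terms)

    def label(self) -> str:
        parts = [self.age_form] + [c for c in self.covariates]
        parts += [f"{a}x{v}" for a, v in self.interactions]
        return f"{self.response} ~ " + " + ".join(parts)


@dataclass(frozen=True)
class FittedModel:
    spec: ModelSpec
    n_params: int  # includes the residual-variance parameter
    loglik: float
    aic: float
    params: pd.Series = field(repr=False, compare=False)
    bse: pd.Series = field(repr=False, compare=False)


def candidate_specs(
    stage: str,
    response: str = "VM",
    age_form: str = "QUADRATIC",
    include_interactions: bool = True,
) -> list[ModelSpec]:
    """Enumerate the candidate model set for one selection stage.

    ``stage='age-only'``: the 7 age forms plus a no-age null, each with
    clutch size.  ``stage='environmental'``: fixes ``age_form`` and crosses
    {Year or not} x {Foodpc or not} x {no NAO, WNAO, ANAO}, optionally adding
    one age x annual-covariate interaction per numeric annual variable present.
    """
    if stage == "age-only":
        return [
            ModelSpec(response=response, age_form=form, covariates=("Clutch",))
            for form in AGE_FORMS
        ]
    if stage != "environmental":
        raise ValueError("stage must be 'age-only' or 'environmental'")
    if age_form == "NONE":
        raise ValueError("environmental stage needs a winning age form")
    specs: list[ModelSpec] = []
    # The year factor spans every annual covariate (they are constant within a
    # year), so Year never co-occurs with annual numeric main effects: the
    # combination would be perfectly aliased.
    for use_food in (False, True):
        for nao in (None, "WNAO", "ANAO"):
            covs: tuple[str, ...] = ("Clutch",)
            if use_food:
                covs += ("Foodpc",)
            if nao:
                covs += (nao,)
            specs.append(
                ModelSpec(response=response, age_form=age_form, covariates=covs)
            )
            if include_interactions:
                for var in covs:
                    if var in ("Foodpc", "WNAO", "ANAO"):
                        specs.append(
                            ModelSpec(
                                response=response,
                                age_form=age_form,
                                covariates=covs,
                                interactions=((age_form, var),),
                            )
                        )
    specs.append(
        ModelSpec(response=response, age_form=age_form, covariates=("Clutch", "Year"))
    )
    return specs


def _with_class_columns(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    data = table.copy()
    if spec.age_form.startswith("AGE") or any(
        a.startswith("AGE") for a, _ in spec.interactions
    ):
        scheme = SCHEMES[spec.age_form]
        data[f"ac_{spec.age_form}"] = [
            age_to_class(int(a), scheme) for a in data["age"]
        ]
    return data


def fit_glm(spec: ModelSpec, table: pd.DataFrame) -> FittedModel:
    """Fit one candidate by Gaussian least squares.

    AIC is 2k - 2 lnL with k counting every mean parameter plus the residual
    variance, and lnL the Gaussian maximum likelihood (variance at its MLE).
    """
    needed = {spec.response, "Clutch"}
    if spec.age_form != "NONE":
        needed.add("age")
    needed.update(c for c in spec.covariates if c != "Clutch")
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    data = _with_class_columns(table, spec)
    model = smf.ols(spec.formula(), data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {model.exog.shape[1]}) for "
            f"{spec.label()}: aliased terms among {list(model.exog_names)}"
        )
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("fewer observations than parameters")
    res = model.fit()
    k = len(res.params) + 1  # + residual variance
    loglik = float(res.llf)
    return FittedModel(
        spec=spec,
        n_params=k,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        params=res.params,
        bse=res.bse,
    )


def aic_rank(fits: list[FittedModel]) -> pd.DataFrame:
    """Rank fitted candidates by AIC (ascending), with delta-AIC column."""
    if not fits:
        raise ValueError("no fitted models to rank")
    rows = [
        {
            "model": f.spec.label(),
            "age_form": f.spec.age_form,
            "k": f.n_params,
            "logLik": f.loglik,
            "AIC": f.aic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("AIC", kind="mergesort").reset_index(drop=True)
    table["dAIC"] = table["AIC"] - table["AIC"].iloc[0]
    return table


def select_best(
    table: pd.DataFrame, stage: str, response: str = "VM", **kwargs
) -> tuple[pd.DataFrame, FittedModel]:
    """Fit a whole candidate stage and return (ranking table, best fit)."""
    specs = candidate_specs(stage, response=response, **kwargs)
    fits = [fit_glm(s, table) for s in specs]
    ranking = aic_rank(fits)
    best = min(fits, key=lambda f: f.aic)
    return ranking, best
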