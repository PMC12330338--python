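"""Deterministic regression imputation and imputation-scope strategies.

Each partially missing covariate gets its own generalized linear model,
fit on the rows where that covariate is observed, with the fully observed
covariates as predictors — the survival outcome is never included, which is
the condition for unbiased deterministic imputation in a prediction model.
Links: logit for binary targets, identity for continuous ones.  A missing
entry is replaced by the model's predicted response (a probability for a
binary target — no thresholding by default); observed entries pass through
bit-exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .missingness import MaskedCohort
from .simulate import Cohort

__all__ = [
    "Strategy",
    "ImputationModel",
    "ImputationModelSet",
    "ImputationError",
    "fit_imputation_models",
    "apply_imputation",
    "apply_strategy",
    "complete_cases",
]


class ImputationError(RuntimeError):
    """An imputation model could not be fit (too few rows, singular design)."""

    def __init__(self, covariate: str, reason: str):
        super().__init__(f"imputation model for {covariate} failed: {reason}")
        self.covariate = covariate


class Strategy(str, enum.Enum):
    """Imputation-scope strategies compared in the simulation study."""

    IMPUTE_ALL = "impute_all"          # impute every missing value
    IMPUTE_GT10 = "impute_gt10"        # only covariates missing in >10% of rows
    IMPUTE_LE2 = "impute_le2"          # only rows missing <= 2 covariates
    COMPLETE_CASE = "complete_case"    # drop all incomplete rows, no imputation


@dataclass(frozen=True)
class ImputationModel:
    target: str
    link: str                    # "logit" or "identity"
    intercept: float
    coefficients: np.ndarray     # one per predictor
    predictors: tuple[str, ...]
    n_fit: int

    def predict(self, Xpred: np.ndarray) -> np.ndarray:
        lp = self.intercept + Xpred @ self.coefficients
        return expit(lp) if self.link == "logit" else lp


@dataclass(frozen=True)
class ImputationModelSet:
    models: dict[str, ImputationModel]

    def __len__(self):
        return len(self.models)

    def __getitem__(self, target: str) -> ImputationModel:
        return self.models[target]

    def __contains__(self, target: str) -> bool:
        return target in self.models


def _is_binary(values: np.ndarray) -> bool:
    return bool(np.isin(values, (0.0, 1.0)).all())


def fit_imputation_models(
    masked: MaskedCohort, targets: list[str] | None = None
) -> ImputationModelSet:
    """Fit one GLM per partially missing covariate.

    Predictors are the covariates with zero missing entries in *this*
    dataset; independent per-variable models cannot use partially missing
    covariates.  ``targets`` restricts which missing covariates get a model
    (used by the scope-restricted strategies); default is all of them.
    """
    frac = masked.mask.mean(axis=0)
    missing_cols = [c for c, f in zip(masked.columns, frac) if f > 0]
    complete_cols = [c for c, f in zip(masked.columns, frac) if f == 0]
    if targets is None:
        targets = missing_cols
    colindex = {c: i for i, c in enumerate(masked.columns)}
    if missing_cols and not complete_cols:
        raise ImputationError(missing_cols[0],
                              "no fully observed covariate to predict from")
    Xc = masked.X[:, [colindex[c] for c in complete_cols]]
    models: dict[str, ImputationModel] = {}
    for target in targets:
        j = colindex[target]
        obs = ~masked.mask[:, j]
        n_fit = int(obs.sum())
        if n_fit <= len(complete_cols) + 1:
            raise ImputationError(
                target, f"only {n_fit} observed rows for "
                f"{len(complete_cols)} predictors")
        y = masked.X[obs, j]
        design = sm.add_constant(Xc[obs], has_constant="add")
        binary = _is_binary(y)
        try:
            if binary:
                res = sm.GLM(y, design, family=sm.families.Binomial()).fit()
            else:
                res = sm.OLS(y, design).fit()
            params = np.asarray(res.params, dtype=float)
        except Exception as exc:  # singular design, separation, ...
            raise ImputationError(target, str(exc)) from exc
        if not np.isfinite(params).all():
            raise ImputationError(target, "non-finite coefficients")
        models[target] = ImputationModel(
            target=target,
            link="logit" if binary else "identity",
            intercept=float(params[0]),
            coefficients=params[1:],
            predictors=tuple(complete_cols),
            n_fit=n_fit,
        )
    return ImputationModelSet(models=models)


def _filled_matrix(
    masked: MaskedCohort, models: ImputationModelSet,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """X with modelled targets' missing entries replaced by predictions.

    ``rows`` optionally restricts which rows are filled (strategy 3).
    Observed entries are passed through untouched.
    """
    colindex = {c: i for i, c in enumerate(masked.columns)}
    X = masked.X.copy()
    fill_rows = np.ones(masked.n, dtype=bool) if rows is None else rows
    for target, model in models.models.items():
        j = colindex[target]
        need = masked.mask[:, j] & fill_rows
        if not need.any():
            continue
        Xpred = masked.X[np.ix_(need, [colindex[c] for c in model.predictors])]
        X[need, j] = model.predict(Xpred)
    return X


def apply_imputation(
    masked: MaskedCohort, models: ImputationModelSet,
    threshold_binary: bool = False,
) -> Cohort:
    """Fill every missing entry with its model-predicted response.

    Every partially missing covariate must have a model; the result is a
    complete cohort.  Binary targets are imputed as predicted probabilities
    (the conditional mean); ``threshold_binary`` rounds them to {0, 1} at
    0.5 instead, for sensitivity analyses.
    """
    frac = masked.mask.mean(axis=0)
    uncovered = [c for c, f in zip(masked.columns, frac)
                 if f > 0 and c not in models]
    if uncovered:
        raise ImputationError(uncovered[0], "missing covariate has no model")
    X = _filled_matrix(masked, models)
    if threshold_binary:
        colindex = {c: i for i, c in enumerate(masked.columns)}
        for target, model in models.models.items():
            if model.link == "logit":
                j = colindex[target]
                X[masked.mask[:, j], j] = (
                    X[masked.mask[:, j], j] >= 0.5).astype(float)
    return Cohort(X=X, time=masked.time.copy(), event=masked.event.copy(),
                  columns=list(masked.columns), index=masked.index.copy())


def apply_strategy(
    masked: MaskedCohort, strategy: Strategy | str
) -> tuple[Cohort, int]:
    """Produce a complete, model-ready cohort under the chosen scope.

    impute_all
        impute every missing value; no rows dropped.
    impute_gt10
        impute only covariates missing in more than 10% of rows of this
        dataset; rows still incomplete afterwards are dropped.
    impute_le2
        impute only rows missing two or fewer covariates; rows missing
        three or more are dropped.
    complete_case
        drop every incomplete row, impute nothing.

    Returns the cohort and the number of dropped rows.  Thresholds are
    evaluated on the dataset at hand (original or bootstrap resample).
    """
    strategy = Strategy(strategy)
    if strategy is Strategy.COMPLETE_CASE:
        keep = ~masked.mask.any(axis=1)
        cohort = Cohort(
            X=masked.X[keep], time=masked.time[keep],
            event=masked.event[keep], columns=list(masked.columns),
            index=masked.index[keep],
        )
        return cohort, int((~keep).sum())

    frac = masked.mask.mean(axis=0)
    if strategy is Strategy.IMPUTE_ALL:
        targets = [c for c, f in zip(masked.columns, frac) if f > 0]
        rows = None
    elif strategy is Strategy.IMPUTE_GT10:
        targets = [c for c, f in zip(masked.columns, frac) if f > 0.10]
        rows = None
    else:  # IMPUTE_LE2
        targets = [c for c, f in zip(masked.columns, frac) if f > 0]
        rows = masked.mask.sum(axis=1) <= 2
    models = (fit_imputation_models(masked, targets=targets)
              if targets else ImputationModelSet(models={}))
    X = _filled_matrix(masked, models, rows=rows)
    keep = ~np.isnan(X).any(axis=1)
    cohort = Cohort(
        X=X[keep], time=masked.time[keep], event=masked.event[keep],
        columns=list(masked.columns), index=masked.index[keep],
    )
    return cohort, int((~keep).sum())


def complete_cases(masked: MaskedCohort) -> Cohort:
    """Complete-case filter: the rows with no missing covariate."""
    cohort, _ = apply_strategy(masked, Strategy.COMPLETE_CASE)
    return cohort
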