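"""Proportional-hazards fitting and horizon-specific performance metrics.

The outcome model is a Cox proportional-hazards fit (partial likelihood,
Breslow baseline).  Discrimination is measured with the cumulative-case /
dynamic-control time-dependent AUC and overall accuracy with the
time-dependent Brier score, both corrected for right censoring by inverse
probability of censoring weighting (IPCW): the censoring survival G is
estimated by a reverse Kaplan-Meier, subjects with an event before the
horizon tau contribute with weight 1/G(s-), subjects still at risk past tau
with weight 1/G(tau), and subjects censored before tau with weight 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import ConvergenceWarning

from .simulate import Cohort

__all__ = [
    "CoxFit",
    "CoxFitError",
    "UndefinedMetricError",
    "PerformancePair",
    "fit_cox",
    "predict_risk",
    "censoring_weights",
    "td_auc",
    "td_brier",
    "score_cohort",
]


class CoxFitError(RuntimeError):
    """The outcome model cannot be fit (sparse data, singularity, ...).

    Consumed by the validation and simulation layers as a fit-failure
    signal rather than a hard abort.
    """


class UndefinedMetricError(RuntimeError):
    """A metric has no value (no cases/controls, degenerate IPCW weights)."""


@dataclass
class CoxFit:
    """A converged proportional-hazards fit with a Breslow baseline."""

    model: CoxPHFitter
    columns: list[str]
    n_events: int
    converged: bool = True

    @property
    def coefficients(self) -> pd.Series:
        return self.model.params_

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.model.params_)

    def baseline_cumhaz(self, t: float) -> float:
        """Breslow cumulative baseline hazard at time t (0 at t = 0)."""
        bch = self.model.baseline_cumulative_hazard_
        times = bch.index.to_numpy(dtype=float)
        vals = bch.iloc[:, 0].to_numpy(dtype=float)
        i = np.searchsorted(times, t, side="right") - 1
        return float(vals[i]) if i >= 0 else 0.0


def fit_cox(cohort: Cohort, min_rows_margin: int = 2) -> CoxFit:
    """Fit the multivariable Cox model; signal failure instead of guessing.

    Failure conditions: fewer than p + ``min_rows_margin`` rows, no events,
    a raised optimizer error, non-finite coefficients, a genuine
    non-convergence report, or a quasi-singular design (a covariate with
    near-zero variance conditional on event status — the monotone-likelihood
    situation in which a coefficient diverges).  Precautionary notes the
    optimizer attaches to successful completions do not count.  Sparse
    complete-case subsets with few events relative to the covariate count
    fail through these diagnostics rather than a hard events-per-covariate
    cutoff.
    """
    p = cohort.p
    n_events = int(cohort.event.sum())
    if cohort.n < p + min_rows_margin:
        raise CoxFitError(
            f"only {cohort.n} rows for {p} covariates: under-determined fit")
    if n_events < 1:
        raise CoxFitError("no events observed")
    if np.isnan(cohort.X).any():
        raise CoxFitError("covariate matrix contains missing values")
    df = cohort.to_frame()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            # order matters: ConvergenceWarning subclasses RuntimeWarning,
            # and later inserts take precedence
            warnings.simplefilter("ignore", category=RuntimeWarning)
            warnings.simplefilter("always", category=ConvergenceWarning)
            cph.fit(df, duration_col="time", event_col="event")
        complaints = [
            w for w in caught
            if issubclass(w.category, ConvergenceWarning)
            and "completed successfully" not in str(w.message)
        ]
        if complaints:
            raise CoxFitError(
                "optimizer reported convergence problems: "
                + "; ".join(str(w.message)[:70] for w in complaints[:3]))
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise CoxFitError(f"partial-likelihood fit failed: {exc}") from exc
    params = cph.params_.to_numpy()
    if not np.isfinite(params).all():
        raise CoxFitError("non-finite coefficients")
    return CoxFit(model=cph, columns=list(cohort.columns), n_events=n_events)


def predict_risk(fit: CoxFit, X: np.ndarray, tau: float) -> np.ndarray:
    """Predicted event probability by tau: 1 - S0(tau)**exp(lp)."""
    Xdf = pd.DataFrame(np.asarray(X, dtype=float), columns=fit.columns)
    last = float(fit.model.baseline_cumulative_hazard_.index.max())
    if tau > last:
        warnings.warn(
            f"horizon {tau} beyond last observed time {last:.3g}; using the "
            "last baseline-hazard step", RuntimeWarning, stacklevel=2)
    surv = fit.model.predict_survival_function(Xdf, times=[min(tau, last)])
    return 1.0 - surv.iloc[0].to_numpy(dtype=float)


def _reverse_km(time: np.ndarray, event: np.ndarray):
    """Censoring-survival step function from a reverse Kaplan-Meier."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - np.asarray(event))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def censoring_weights(
    time: np.ndarray, event: np.ndarray, tau: float
) -> np.ndarray:
    """IPCW weights at horizon tau from the reverse Kaplan-Meier.

    weight_i = 1/G(s_i-) for events before tau, 1/G(tau) for subjects at
    risk past tau, and 0 for subjects censored before tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ts, gs = _reverse_km(time, event)

    def g_at(t: np.ndarray, left_limit: bool) -> np.ndarray:
        side = "left" if left_limit else "right"
        i = np.searchsorted(ts, t, side=side) - 1
        out = np.where(i >= 0, gs[np.clip(i, 0, None)], 1.0)
        return out

    w = np.zeros_like(time)
    is_case = (time <= tau) & (event == 1)
    at_risk = time > tau
    g_case = g_at(time[is_case], left_limit=True)
    g_tau = g_at(np.array([tau]), left_limit=False)[0]
    if (g_case <= 0).any() or (at_risk.any() and g_tau <= 0):
        raise UndefinedMetricError(
            "censoring survival reaches 0 before the horizon; IPCW weights "
            "are degenerate")
    w[is_case] = 1.0 / g_case
    w[at_risk] = 1.0 / g_tau
    return w


def td_auc(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray, tau: float
) -> float:
    """IPCW cumulative/dynamic time-dependent AUC at horizon tau.

    Weighted proportion of (case, control) pairs in which the case has the
    higher predicted risk; ties count one half.  Cases (event by tau) carry
    their IPCW weights; the common control weight 1/G(tau) cancels.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    is_case = (time <= tau) & (event == 1)
    is_control = time > tau
    if not is_case.any() or not is_control.any():
        raise UndefinedMetricError(
            "time-dependent AUC needs at least one case and one control")
    w = censoring_weights(time, event, tau)
    wc = w[is_case]
    r_case = risk[is_case]
    r_ctrl = np.sort(risk[is_control])
    n_ctrl = r_ctrl.size
    # for each case: #controls strictly below + half the ties
    lo = np.searchsorted(r_ctrl, r_case, side="left")
    hi = np.searchsorted(r_ctrl, r_case, side="right")
    conc = lo + 0.5 * (hi - lo)
    return float((wc * conc).sum() / (wc.sum() * n_ctrl))


def td_brier(
    surv_pred: np.ndarray, time: np.ndarray, event: np.ndarray, tau: float
) -> float:
    """IPCW time-dependent Brier score at horizon tau.

    (1/n) * sum_i w_i * (1{s_i > tau} - surv_pred_i)^2 with w from
    :func:`censoring_weights`; lower is better, 0.25 is the value of the
    non-informative constant-half prediction on uncensored data.
    """
    surv_pred = np.asarray(surv_pred, dtype=float)
    time = np.asarray(time, dtype=float)
    if np.nanmin(surv_pred) < 0 or np.nanmax(surv_pred) > 1:
        raise ValueError("predicted survival probabilities must be in [0, 1]")
    w = censoring_weights(time, event, tau)
    alive = (time > tau).astype(float)
    return float(np.mean(w * (alive - surv_pred) ** 2))


@dataclass(frozen=True)
class PerformancePair:
    """Time-dependent AUC and Brier score at a common horizon."""

    auc: float
    brier: float
    horizon: float


def score_cohort(fit: CoxFit, cohort: Cohort, tau: float) -> PerformancePair:
    """Predict risks for a cohort and score both metrics at tau."""
    risk = predict_risk(fit, cohort.X, tau)
    return PerformancePair(
        auc=td_auc(risk, cohort.time, cohort.event, tau),
        brier=td_brier(1.0 - risk, cohort.time, cohort.event, tau),
        horizon=tau,
    )
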