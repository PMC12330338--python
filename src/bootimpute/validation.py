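"""Bootstrap-then-impute internal validation.

The recommended order of operations when a single incomplete dataset must
serve for both model development and validation: resample the *incomplete*
data with replacement, repeat the entire pipeline (imputation-model fitting,
imputation, outcome-model fitting) inside every resample, and combine the
in-resample, original-data and out-of-bag performances into four estimators:

apparent
    performance of the original-data model on the original (imputed) data.
Harrell bootstrap-corrected
    apparent minus the average optimism, where optimism is the in-resample
    performance minus the same model's performance on the original imputed
    data.
0.632
    0.368 * apparent + 0.632 * mean out-of-bag performance (out-of-bag =
    rows of the original imputed data absent from the resample).
0.632+
    like 0.632 but with a weight adapted to the relative overfitting rate
    R = (mean_test - apparent) / (no_info - apparent), w = 0.632 /
    (1 - 0.368 R); no-information values are 0.5 for the AUC and 0.25 for
    the Brier score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imputation import ImputationError, Strategy, apply_strategy
from .metrics import (
    CoxFitError,
    PerformancePair,
    UndefinedMetricError,
    fit_cox,
    predict_risk,
    score_cohort,
)
from .missingness import MaskedCohort

__all__ = [
    "NO_INFORMATION",
    "ValidationError",
    "MetricReport",
    "ValidationReport",
    "draw_bootstrap",
    "apparent_performance",
    "harrell_corrected",
    "est_632",
    "est_632_plus",
    "validate",
]

#: Benchmark performance of a non-informative model.
NO_INFORMATION = {"auc": 0.5, "brier": 0.25}


class ValidationError(RuntimeError):
    """The validation run cannot produce a report."""


def draw_bootstrap(
    n: int, B: int, rng=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """B resamples of n indices with replacement, each with its out-of-bag
    complement (rows never drawn)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    out = []
    all_rows = np.arange(n)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_rows, idx, assume_unique=False)
        out.append((idx, oob))
    return out


def harrell_corrected(
    apparent: float, in_sample, on_original
) -> float:
    """Apparent performance minus the mean optimism over resamples."""
    in_sample = np.asarray(in_sample, dtype=float)
    on_original = np.asarray(on_original, dtype=float)
    if in_sample.size == 0 or in_sample.shape != on_original.shape:
        raise ValueError("need equal-length, non-empty performance vectors")
    return float(apparent - np.mean(in_sample - on_original))


def est_632(apparent: float, mean_test: float) -> float:
    """The 0.632 estimator: 0.368 * apparent + 0.632 * mean_test."""
    return 0.368 * apparent + 0.632 * mean_test


def est_632_plus(
    apparent: float, mean_test: float, no_info: float
) -> tuple[float, float, float]:
    """The 0.632+ estimator.

    Returns ``(estimate, R, w)`` where R is the relative overfitting rate
    clamped to [0, 1] and w = 0.632 / (1 - 0.368 R) the resulting weight in
    [0.632, 1].
    """
    if no_info == apparent:
        raise ValueError(
            "no-information value equals apparent performance; the relative "
            "overfitting rate is undefined")
    R = (mean_test - apparent) / (no_info - apparent)
    R = float(np.clip(R, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * R)
    return float((1.0 - w) * apparent + w * mean_test), R, w


@dataclass(frozen=True)
class MetricReport:
    """All four estimators of one performance metric, plus diagnostics."""

    apparent: float
    harrell: float
    e632: float
    e632plus: float
    optimism: float
    mean_test: float
    overfit_rate: float
    weight: float

    def as_dict(self) -> dict[str, float]:
        return {
            "apparent": self.apparent, "harrell": self.harrell,
            "e632": self.e632, "e632plus": self.e632plus,
        }


@dataclass
class ValidationReport:
    """Outcome of one bootstrap-then-impute internal validation run."""

    B: int
    horizon: float
    strategy: Strategy
    auc: MetricReport
    brier: MetricReport
    records: pd.DataFrame = field(repr=False)
    n_failed: int = 0
    n_original: int = 0
    n_dropped_original: int = 0
    surv_pred: np.ndarray | None = field(default=None, repr=False)

    def metric(self, name: str) -> MetricReport:
        return {"auc": self.auc, "brier": self.brier}[name]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for m in ("auc", "brier"):
            r = self.metric(m)
            for est, v in r.as_dict().items():
                rows.append({"metric": m, "estimator": est, "value": v})
        return pd.DataFrame(rows)


def apparent_performance(
    masked0: MaskedCohort, strategy: Strategy | str, tau: float
) -> PerformancePair:
    """Impute/filter the original data, fit, and score on the same data."""
    dat, _ = apply_strategy(masked0, strategy)
    fit = fit_cox(dat)
    return score_cohort(fit, dat, tau)


def _metric_report(
    apparent: float, in_sample: np.ndarray, on_original: np.ndarray,
    oob: np.ndarray, no_info: float,
) -> MetricReport:
    optimism = float(np.mean(in_sample - on_original))
    mean_test = float(np.mean(oob))
    e632p, R, w = est_632_plus(apparent, mean_test, no_info)
    return MetricReport(
        apparent=apparent,
        harrell=harrell_corrected(apparent, in_sample, on_original),
        e632=est_632(apparent, mean_test),
        e632plus=e632p,
        optimism=optimism,
        mean_test=mean_test,
        overfit_rate=R,
        weight=w,
    )


def validate(
    masked0: MaskedCohort,
    strategy: Strategy | str = Strategy.IMPUTE_ALL,
    B: int = 500,
    tau: float = 5.0,
    rng=None,
) -> ValidationReport:
    """Run the full bootstrap-then-impute internal validation.

    1. Impute/filter the original incomplete data once (the "original
       imputed dataset"); fit and score for the apparent performance.
    2. For each of B resamples of the *incomplete* data: impute/filter the
       resample independently, fit, and score the resample's model on (a)
       the resample's own imputed data, (b) the original imputed dataset,
       and (c) the out-of-bag rows of the original imputed dataset.
    3. Combine into the apparent, Harrell-corrected, 0.632 and 0.632+
       estimators for both metrics.

    Resamples whose imputation or outcome fit fails are counted in
    ``n_failed`` and excluded from the averages.
    """
    strategy = Strategy(strategy)
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    try:
        dat, n_dropped = apply_strategy(masked0, strategy)
        fit0 = fit_cox(dat)
    except (ImputationError, CoxFitError) as exc:
        raise ValidationError(
            f"original-data fit failed under {strategy.value}: {exc}"
        ) from exc
    apparent = score_cohort(fit0, dat, tau)
    risk0 = predict_risk(fit0, dat.X, tau)

    # rows of the original imputed dataset, keyed by original row position
    pos_in_dat = {row: i for i, row in enumerate(dat.index)}
    rows = []
    for b, (idx, oob) in enumerate(draw_bootstrap(masked0.n, B, rng)):
        rec = {"b": b, "oob_size": len(oob), "failed": False, "reason": ""}
        try:
            dat_b, _ = apply_strategy(masked0.take(idx), strategy)
            fit_b = fit_cox(dat_b)
            in_perf = score_cohort(fit_b, dat_b, tau)
            orig_perf = score_cohort(fit_b, dat, tau)
            keep = [pos_in_dat[r] for r in oob if r in pos_in_dat]
            oob_perf = score_cohort(fit_b, dat.take(np.asarray(keep)), tau)
        except (ImputationError, CoxFitError, UndefinedMetricError) as exc:
            rec["failed"] = True
            rec["reason"] = str(exc)
            rows.append(rec)
            continue
        rec.update({
            "auc_in": in_perf.auc, "auc_orig": orig_perf.auc,
            "auc_oob": oob_perf.auc,
            "brier_in": in_perf.brier, "brier_orig": orig_perf.brier,
            "brier_oob": oob_perf.brier,
        })
        rows.append(rec)
    records = pd.DataFrame(rows)
    ok = records[~records["failed"]]
    if ok.empty:
        raise ValidationError("every bootstrap resample failed to fit")
    reports = {}
    for m in ("auc", "brier"):
        reports[m] = _metric_report(
            getattr(apparent, m),
            ok[f"{m}_in"].to_numpy(),
            ok[f"{m}_orig"].to_numpy(),
            ok[f"{m}_oob"].to_numpy(),
            NO_INFORMATION[m],
        )
    return ValidationReport(
        B=B, horizon=tau, strategy=strategy,
        auc=reports["auc"], brier=reports["brier"],
        records=records,
        n_failed=int(records["failed"].sum()),
        n_original=dat.n,
        n_dropped_original=n_dropped,
        surv_pred=1.0 - risk0,
    )
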