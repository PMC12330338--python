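"""Missing-at-random masking of a complete cohort.

Each target covariate j acquires missingness through a logistic model

    P(M_ij = 1) = logistic(g0_j + g1_j * M_ik + g2_j * X_il),

where M_ik is the missingness indicator of a driver covariate k and X_il the
value of another covariate l (k != l).  g1_j = log(OR) where the odds ratio
comes from the 2x2 cross-tabulation implied by the target marginal and joint
missingness proportions; the intercept g0_j is solved by the plug-in

    g0_j = logit(pi_j) - g1_j * P(M_ik = 1) - g2_j * mean(X_il).

Missingness never depends on the outcome or on any masked value, so the
mechanism is MAR by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import presets
from .simulate import Cohort

__all__ = [
    "MissingnessSpec",
    "MissingnessEntry",
    "MaskedCohort",
    "cross_tab_or",
    "solve_intercept",
    "build_spec",
    "impose_missingness",
    "guided_example_spec",
    "pattern_spec",
]


class SpecError(ValueError):
    """Missingness specification cannot be built or applied."""


class DegenerateTableError(SpecError):
    """A 2x2 missingness cross-tabulation has a zero cell where it may not."""


@dataclass(frozen=True)
class MissingnessEntry:
    """Resolved logistic-missingness model for one target covariate."""

    target: str              # covariate acquiring missingness
    pi: float                # target marginal missingness proportion
    driver_mask: str | None  # covariate whose missingness enters (k)
    driver_value: str        # covariate whose value enters (l)
    gamma0: float
    gamma1: float
    gamma2: float
    p_driver_missing: float  # plug-in P(M_ik = 1) used to solve gamma0


@dataclass(frozen=True)
class MissingnessSpec:
    entries: tuple[MissingnessEntry, ...]

    @property
    def targets(self) -> list[str]:
        return [e.target for e in self.entries]


@dataclass
class MaskedCohort:
    """Covariates with an explicit missingness mask.

    ``X`` holds NaN where masked; ``mask`` is True exactly there.  Follow-up
    time and the event indicator are never missing.
    """

    X: np.ndarray
    mask: np.ndarray
    time: np.ndarray
    event: np.ndarray
    columns: list[str] = field(default_factory=list)
    index: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.mask.shape != self.X.shape:
            raise ValueError("mask must match X in shape")
        if not self.columns:
            self.columns = [f"x{j}" for j in range(1, self.X.shape[1] + 1)]
        if self.index is None:
            self.index = np.arange(self.n)
        else:
            self.index = np.asarray(self.index)
        if np.isnan(self.X[~self.mask]).any():
            raise ValueError("NaN present outside the mask")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "MaskedCohort":
        """Wrap a complete cohort with an all-zero mask."""
        return cls(
            X=cohort.X.copy(),
            mask=np.zeros_like(cohort.X, dtype=bool),
            time=cohort.time.copy(),
            event=cohort.event.copy(),
            columns=list(cohort.columns),
            index=cohort.index.copy(),
        )

    def take(self, idx: np.ndarray) -> "MaskedCohort":
        idx = np.asarray(idx)
        return MaskedCohort(
            X=self.X[idx],
            mask=self.mask[idx],
            time=self.time[idx],
            event=self.event[idx],
            columns=list(self.columns),
            index=self.index[idx],
        )

    def missing_fraction(self) -> pd.Series:
        return pd.Series(self.mask.mean(axis=0), index=self.columns)

    def to_frame(self) -> pd.DataFrame:
        X = self.X.copy()
        X[self.mask] = np.nan
        df = pd.DataFrame(X, columns=self.columns)
        df["time"] = self.time
        df["event"] = self.event
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MaskedCohort":
        cols = [c for c in df.columns if c not in ("time", "event")]
        X = df[cols].to_numpy(dtype=float)
        return cls(
            X=X,
            mask=np.isnan(X),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
            columns=list(cols),
        )


def cross_tab_or(pA: float, pB: float, pJoint: float) -> float:
    """Odds ratio implied by two marginal proportions and their joint.

    Cells: p11 = joint, p10 = pA - joint, p01 = pB - joint,
    p00 = 1 - pA - pB + joint; returns (p00 * p11) / (p10 * p01).
    """
    p11 = pJoint
    p10 = pA - pJoint
    p01 = pB - pJoint
    p00 = 1.0 - pA - pB + pJoint
    if min(p11, p10, p01, p00) < -1e-12:
        raise SpecError(
            f"inconsistent proportions: cells ({p00:.4g}, {p01:.4g}, "
            f"{p10:.4g}, {p11:.4g}) must be nonnegative"
        )
    if p10 * p01 == 0.0:
        raise DegenerateTableError(
            "cross-tabulation denominator cell is zero; the odds ratio is "
            "undefined for these marginal/joint proportions"
        )
    return (p00 * p11) / (p10 * p01)


def solve_intercept(
    pi_j: float, gamma1: float, p_Mk: float, xbar_l: float, gamma2: float
) -> float:
    """Plug-in intercept: logit(pi_j) - gamma1 * P(M_ik=1) - gamma2 * xbar_l."""
    if not 0.0 < pi_j < 1.0:
        raise SpecError("target marginal proportion must lie in (0, 1)")
    return float(logit(pi_j) - gamma1 * p_Mk - gamma2 * xbar_l)


def _joint_lookup(
    pi_a: float, pi_b: float,
    table: dict[tuple[float, float], float],
    overrides: dict[tuple[float, float], float] | None,
) -> float:
    key = tuple(sorted((round(pi_a, 6), round(pi_b, 6))))
    if overrides and key in overrides:
        return overrides[key]
    if key not in table:
        raise SpecError(f"no joint missingness target for marginal pair {key}")
    return table[key]


def build_spec(
    pattern: dict[str, float],
    cohort: Cohort,
    drivers: dict[str, tuple[str | None, str, float]] | None = None,
    joint_targets: dict[tuple[float, float], float] | None = None,
    joint_overrides: dict[tuple[float, float], float] | None = None,
) -> MissingnessSpec:
    """Resolve a marginal-target pattern into a full missingness spec.

    ``pattern`` maps covariate name -> marginal missingness proportion.  Each
    covariate's driver indices and gamma2 come from ``drivers``; gamma1 is 0
    for x1 (it has no missingness driver) and for any target whose driver has
    no imposed missingness in the pattern, otherwise log(OR) from the joint
    target looked up by the unordered pair of marginals.
    """
    drivers = drivers if drivers is not None else presets.MISSINGNESS_DRIVERS
    joint_targets = (joint_targets if joint_targets is not None
                     else presets.JOINT_MISSINGNESS)
    colindex = {c: i for i, c in enumerate(cohort.columns)}
    entries = []
    order = [t for t in presets.IMPOSITION_ORDER if t in pattern]
    order += [t for t in pattern if t not in order]
    for target in order:
        pi = pattern[target]
        if target not in drivers:
            raise SpecError(f"no missingness drivers defined for {target}")
        k, l, gamma2 = drivers[target]
        if k is not None and k not in colindex or l not in colindex:
            raise SpecError(f"driver covariate missing from cohort for {target}")
        if k is None or k not in pattern:
            # driver never missing: M_ik is identically 0, the term is inert
            gamma1, p_mk = 0.0, 0.0
        else:
            joint = _joint_lookup(pi, pattern[k], joint_targets,
                                  joint_overrides)
            gamma1 = float(np.log(cross_tab_or(pi, pattern[k], joint)))
            p_mk = pattern[k]
        xbar_l = float(cohort.X[:, colindex[l]].mean())
        gamma0 = solve_intercept(pi, gamma1, p_mk, xbar_l, gamma2)
        entries.append(
            MissingnessEntry(
                target=target, pi=pi,
                driver_mask=k if (k is not None and k in pattern) else None,
                driver_value=l, gamma0=gamma0, gamma1=gamma1, gamma2=gamma2,
                p_driver_missing=p_mk,
            )
        )
    return MissingnessSpec(entries=tuple(entries))


def pattern_spec(letter: str, cohort: Cohort) -> MissingnessSpec:
    """Spec for one of the simulation study's patterns A-I."""
    if letter not in presets.PATTERNS:
        raise SpecError(f"unknown pattern {letter!r}")
    return build_spec(presets.PATTERNS[letter], cohort)


def guided_example_spec(cohort: Cohort) -> MissingnessSpec:
    """The worked example's mechanism: marginals 5/15/30% on x1/x3/x4 with
    joint targets 0.02 for (x1, x3) and 0.075 for (x3, x4)."""
    return build_spec(
        presets.PATTERNS["E"], cohort,
        joint_overrides=presets.GUIDED_JOINT_OVERRIDES,
    )


def impose_missingness(
    cohort: Cohort, spec: MissingnessSpec, rng=None
) -> MaskedCohort:
    """Draw the missingness mask and return the masked cohort.

    Entries are processed in dependency order so every driver's missingness
    indicator exists when referenced.  Only covariates named in the spec
    acquire missingness; time and event are untouched.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    colindex = {c: i for i, c in enumerate(cohort.columns)}
    done: set[str] = set()
    for e in spec.entries:
        if e.driver_mask is not None and e.driver_mask not in done:
            raise SpecError(
                f"driver {e.driver_mask} of {e.target} not yet imposed; "
                "entry order must follow the (acyclic) driver graph"
            )
        done.add(e.target)
    mask = np.zeros_like(cohort.X, dtype=bool)
    for e in spec.entries:
        m_k = (mask[:, colindex[e.driver_mask]].astype(float)
               if e.driver_mask is not None else 0.0)
        x_l = cohort.X[:, colindex[e.driver_value]]
        prob = expit(e.gamma0 + e.gamma1 * m_k + e.gamma2 * x_l)
        mask[:, colindex[e.target]] = rng.uniform(size=cohort.n) < prob
    X = cohort.X.copy()
    X[mask] = np.nan
    return MaskedCohort(
        X=X, mask=mask, time=cohort.time.copy(), event=cohort.event.copy(),
        columns=list(cohort.columns), index=cohort.index.copy(),
    )
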