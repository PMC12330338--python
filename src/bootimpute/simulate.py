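"""Synthetic survival cohort generation.

Covariates come from a multivariate normal with selected columns
dichotomised at a threshold; death times follow a Weibull
proportional-hazards model via the inverse-transform

    t_i = b * ((-log u_i) / exp(beta' x_i)) ** (1 / a),   u_i ~ U(0, 1),

with the Weibull parameterised through its survival function
S(t) = exp(-(t / scale) ** shape); censoring times are drawn from an
independent Weibull.  Observed time is s_i = min(t_i, c_i) and the event
indicator is 1 when t_i <= c_i (a tie counts as a death).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets

__all__ = [
    "GenerationConfig",
    "Cohort",
    "draw_covariates",
    "simulate_event_times",
    "simulate_censoring",
    "assemble_cohort",
    "generate_cohort",
]


class ConfigError(ValueError):
    """Invalid generation configuration."""


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n : int
        Number of participants.
    mu, sigma : ndarray
        Mean vector and covariance matrix of the latent multivariate normal.
    binary_flags : ndarray of bool
        Columns to dichotomise at ``dichot_threshold``.
    beta : ndarray
        Log hazard ratios entering the death-time model.
    event_shape, event_scale : float
        Weibull shape/scale of baseline death times (scale in years).
    cens_shape, cens_scale : float
        Weibull shape/scale of censoring times (years).
    horizon : float
        Prediction horizon tau in years.
    """

    n: int
    mu: np.ndarray
    sigma: np.ndarray
    binary_flags: np.ndarray
    beta: np.ndarray
    dichot_threshold: float = 0.5
    event_shape: float = presets.EVENT_SHAPE
    event_scale: float = presets.EVENT_SCALE
    cens_shape: float = presets.CENS_SHAPE
    cens_scale: float = presets.CENS_SCALE
    horizon: float = presets.HORIZON

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(
            self, "binary_flags", np.asarray(self.binary_flags, dtype=bool)
        )
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        p = self.mu.shape[0]
        if self.sigma.shape != (p, p):
            raise ConfigError("sigma must be p x p with p = len(mu)")
        if self.beta.shape[0] != p or self.binary_flags.shape[0] != p:
            raise ConfigError("mu, beta and binary_flags must share length")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ConfigError("sigma must be symmetric")
        eigvals = np.linalg.eigvalsh(self.sigma)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise ConfigError("sigma must be positive semi-definite")
        for name in ("event_shape", "event_scale", "cens_shape", "cens_scale",
                     "horizon"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @classmethod
    def default(cls, n: int = 3500) -> "GenerationConfig":
        """The 11-covariate breast-cancer-cohort configuration."""
        return cls(
            n=n,
            mu=presets.MU,
            sigma=presets.SIGMA,
            binary_flags=presets.BINARY_FLAGS,
            beta=presets.BETA,
        )

    def with_n(self, n: int) -> "GenerationConfig":
        return replace(self, n=n)


@dataclass
class Cohort:
    """A fully observed survival cohort.

    ``X`` is the n x p covariate matrix, ``time`` the observed follow-up in
    years, ``event`` the death indicator (1 = died, 0 = censored).  Latent
    death/censoring times are retained only when requested, for diagnostics.
    ``index`` tracks original row positions through resampling/filtering.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    columns: list[str] = field(default_factory=list)
    death_time: np.ndarray | None = None
    cens_time: np.ndarray | None = None
    index: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not self.columns:
            self.columns = [f"x{j}" for j in range(1, self.X.shape[1] + 1)]
        if self.index is None:
            self.index = np.arange(self.n)
        else:
            self.index = np.asarray(self.index)
        if not (len(self.time) == len(self.event) == self.n):
            raise ValueError("X, time and event must be row-aligned")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def take(self, idx: np.ndarray) -> "Cohort":
        """Row subset / resample; keeps track of original row identity."""
        idx = np.asarray(idx)
        return Cohort(
            X=self.X[idx],
            time=self.time[idx],
            event=self.event[idx],
            columns=list(self.columns),
            index=self.index[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df["time"] = self.time
        df["event"] = self.event
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        cols = [c for c in df.columns if c not in ("time", "event")]
        return cls(
            X=df[cols].to_numpy(dtype=float),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
            columns=list(cols),
        )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None or isinstance(rng, (int, np.integer, np.random.SeedSequence)):
        return np.random.default_rng(rng)
    return rng  # duck-typed random stream (e.g. a fixed-uniform stub)


def _open_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draws on the open interval (0, 1): log(u) must be finite."""
    u = rng.uniform(size=n)
    tiny = np.finfo(float).tiny
    return np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)


def draw_covariates(config: GenerationConfig, rng=None) -> np.ndarray:
    """Draw the n x p covariate matrix.

    Latent values come from N(mu, sigma); columns flagged binary are
    thresholded (latent > ``dichot_threshold`` maps to 1), the rest are kept
    as raw draws.
    """
    rng = _as_rng(rng)
    latent = rng.multivariate_normal(
        config.mu, config.sigma, size=config.n, method="cholesky"
    )
    X = latent.copy()
    flags = config.binary_flags
    X[:, flags] = (latent[:, flags] > config.dichot_threshold).astype(float)
    return X


def simulate_event_times(
    X: np.ndarray, config: GenerationConfig, rng=None
) -> np.ndarray:
    """Inverse-transform Weibull proportional-hazards death times."""
    rng = _as_rng(rng)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != config.beta.shape[0]:
        raise ConfigError("X column count must match beta length")
    u = _open_uniform(rng, X.shape[0])
    lp = X @ config.beta
    return config.event_scale * ((-np.log(u)) / np.exp(lp)) ** (
        1.0 / config.event_shape
    )


def simulate_censoring(config: GenerationConfig, rng=None) -> np.ndarray:
    """Weibull censoring times with S(t) = exp(-(t/scale)**shape)."""
    rng = _as_rng(rng)
    u = _open_uniform(rng, config.n)
    return config.cens_scale * (-np.log(u)) ** (1.0 / config.cens_shape)


def assemble_cohort(
    t: np.ndarray,
    c: np.ndarray,
    X: np.ndarray,
    columns: list[str] | None = None,
    keep_latent: bool = False,
) -> Cohort:
    """Combine death and censoring times: s = min(t, c), event = 1{t <= c}."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (len(t) == len(c) == X.shape[0]):
        raise ValueError("t, c and X must be row-aligned")
    cohort = Cohort(
        X=X,
        time=np.minimum(t, c),
        event=(t <= c).astype(int),
        columns=columns or [],
    )
    if keep_latent:
        cohort.death_time = t
        cohort.cens_time = c
    return cohort


def generate_cohort(
    config: GenerationConfig, rng=None, keep_latent: bool = False
) -> Cohort:
    """Full generation pipeline: covariates, death times, censoring."""
    rng = _as_rng(rng)
    X = draw_covariates(config, rng)
    t = simulate_event_times(X, config, rng)
    c = simulate_censoring(config, rng)
    return assemble_cohort(t, c, X, columns=list(presets.COVARIATES)
                           if config.p == 11 else None,
                           keep_latent=keep_latent)
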