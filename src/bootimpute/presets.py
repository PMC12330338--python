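"""Default parameter sets for the synthetic breast-cancer survival cohort.

The defaults emulate a post-mastectomy cohort of 3532 patients with eleven
prognostic covariates and overall survival as the outcome: covariates are
drawn from a multivariate normal (binary ones dichotomised at 0.5), death
times follow a Weibull proportional-hazards model, and censoring times an
independent Weibull.  The missingness tables parameterise a missing-at-random
mechanism in which each covariate's missingness depends on the value of one
other covariate and the missingness status of another.
"""

from __future__ import annotations

import numpy as np

#: Covariate column names, in generation order.
COVARIATES = [f"x{j}" for j in range(1, 12)]

#: Mean vector of the latent multivariate normal for (x1, ..., x11).
MU = np.array(
    [0.6145, 57.6495, 2.3665, 0.4225, 0.1538, 0.2421, 0.4142, 0.8680,
     0.1695, 0.1636, 0.8891]
)

# Covariance of the latent normal (lower triangle as estimated; symmetrised).
_SIGMA_LOWER = [
    [0.2370],
    [-1.3349, 196.2990],
    [0.0812, 0.6471, 1.0967],
    [0.0247, -0.6314, 0.0680, 0.2441],
    [0.0298, -0.0759, 0.0452, 0.0063, 0.1302],
    [0.0134, 0.3167, 0.0063, -0.0089, 0.0070, 0.0558],
    [0.0280, -0.7944, 0.0740, 0.0468, 0.0214, -0.0015, 0.2427],
    [-0.0069, 0.0156, -0.0190, -0.0581, -0.0026, 0.0050, -0.0119, 0.1146],
    [0.0039, -0.1261, -0.0080, 0.0484, 0.0016, -0.0026, 0.0131, -0.0318,
     0.1408],
    [0.0002, 0.0294, -0.0147, 0.0003, -0.0001, 0.0003, 0.0017, 0.0001,
     0.0050, 0.1369],
    [0.0223, -0.8057, -0.0075, -0.0139, 0.0043, -0.0000, 0.0012, 0.0086,
     -0.0267, 0.0014, 0.0986],
]


def _symmetrise(lower: list[list[float]]) -> np.ndarray:
    p = len(lower)
    out = np.zeros((p, p))
    for i, row in enumerate(lower):
        out[i, : len(row)] = row
    return out + np.tril(out, -1).T


#: Covariance matrix of the latent multivariate normal.
SIGMA = _symmetrise(_SIGMA_LOWER)

#: True hazard ratio per covariate.
HAZARD_RATIOS = np.array(
    [0.80, 1.05, 1.25, 1.54, 1.18, 1.45, 1.10, 0.76, 0.64, 1.25, 0.48]
)

#: Log hazard ratios (Cox coefficients) used to generate death times.
BETA = np.log(HAZARD_RATIOS)

#: Which covariates are binary (dichotomised) rather than continuous.
BINARY_FLAGS = np.array(
    [True, False, False, True, True, False, True, True, True, True, True]
)

#: Weibull parameters: death times (shape, scale in years) and censoring.
EVENT_SHAPE, EVENT_SCALE = 1.6, 122.0
CENS_SHAPE, CENS_SCALE = 2.6, 8.2

#: Prediction horizon in years.
HORIZON = 5.0

# --- Missing-at-random mechanism ------------------------------------------

#: Per missing covariate j: (k_j, l_j, gamma2_j).  k_j is the covariate whose
#: *missingness status* enters the logistic model (None when absent), l_j the
#: covariate whose *value* enters with coefficient gamma2_j (log odds per
#: unit).
MISSINGNESS_DRIVERS: dict[str, tuple[str | None, str, float]] = {
    "x1": (None, "x2", np.log(1.05)),
    "x3": ("x1", "x5", np.log(0.80)),
    "x4": ("x3", "x6", np.log(0.70)),
    "x7": ("x4", "x8", np.log(0.90)),
    "x10": ("x5", "x9", np.log(0.60)),
    "x11": ("x10", "x2", np.log(1.05)),
}

#: Target joint missingness proportion keyed by the unordered pair of
#: marginal missingness proportions.
JOINT_MISSINGNESS: dict[tuple[float, float], float] = {
    (0.05, 0.05): 0.01,
    (0.05, 0.15): 0.02,
    (0.15, 0.15): 0.05,
    (0.15, 0.30): 0.07,
    (0.30, 0.30): 0.10,
    (0.30, 0.60): 0.20,
    (0.60, 0.60): 0.40,
}

#: The nine missing-data patterns of the simulation study: marginal
#: missingness targets per covariate.
PATTERNS: dict[str, dict[str, float]] = {
    "A": {"x1": 0.05},
    "B": {"x1": 0.15},
    "C": {"x1": 0.60},
    "D": {"x1": 0.05, "x3": 0.05, "x4": 0.05},
    "E": {"x1": 0.05, "x3": 0.15, "x4": 0.30},
    "F": {"x1": 0.15, "x3": 0.30, "x4": 0.60},
    "G": {"x1": 0.05, "x3": 0.05, "x4": 0.05, "x7": 0.05, "x10": 0.05,
          "x11": 0.05},
    "H": {"x1": 0.05, "x3": 0.05, "x4": 0.15, "x7": 0.15, "x10": 0.30,
          "x11": 0.30},
    "I": {"x1": 0.15, "x3": 0.15, "x4": 0.30, "x7": 0.30, "x10": 0.60,
          "x11": 0.60},
}

#: The guided worked example uses pattern E's marginals but pins the joint
#: missingness of the (0.15, 0.30) pair at 0.075 rather than the grid's 0.07.
GUIDED_JOINT_OVERRIDES: dict[tuple[float, float], float] = {
    (0.15, 0.30): 0.075,
}

#: Order in which missingness is imposed, so that every driver's missingness
#: indicator is defined before it is needed (the driver graph is acyclic:
#: x1 -> x3 -> x4 -> x7 and x10 -> x11).
IMPOSITION_ORDER = ["x1", "x3", "x4", "x7", "x10", "x11"]
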