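"""Random correlation matrices (C-vine, LKJ) and multivariate-normal endpoint data.

The correlation generator draws partial correlations layer by layer on a
canonical vine, each as a Beta(b, b) variate rescaled to (-1, 1) with the
shape b decaying by half per tree level, then composes them recursively into
full correlations.  With concentration ``alphad = 1`` (LKJ eta = 1) the draw
is uniform over the space of positive-definite correlation matrices — the
reference ensemble used throughout the simulation studies.  In dimension 2
this reduces to a single off-diagonal correlation uniform on (-1, 1), which
is the closed-form check used in the tests.

Endpoint data are multivariate normal with unit variances, so per-endpoint
mean shifts ``delta`` are standardized effect sizes in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_correlation

__all__ = [
    "SCENARIO_LABELS",
    "CorrGenConfig",
    "EffectScenario",
    "effect_scenario",
    "random_correlation",
    "make_dataset",
]

SCENARIO_LABELS = (
    "const",
    "bidirectional-const",
    "stagger",
    "bidirectional-stagger",
    "spike",
    "null",
)


def as_rng(seed) -> np.random.Generator:
    """Coerce None / int / SeedSequence / Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CorrGenConfig:
    """Configuration for the vine correlation generator."""

    m: int
    alphad: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least 2 endpoints")
        if self.alphad <= 0:
            raise ValueError("alphad must be positive")


@dataclass(frozen=True)
class EffectScenario:
    """Named per-endpoint standardized effect pattern (SD units)."""

    label: str
    delta: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "delta", np.atleast_1d(np.asarray(self.delta, dtype=float))
        )

    @property
    def m(self) -> int:
        return len(self.delta)


def effect_scenario(
    label: str,
    m: int,
    *,
    effect_size: float = 0.5,
    spike_size: float = 1.0,
    spike_background: float = 0.1,
) -> EffectScenario:
    """Build one of the named effect-size patterns on m endpoints.

    const                : +effect_size on every endpoint.
    bidirectional-const  : -effect_size on the first half, + on the rest.
    stagger              : effect_size * k/m for endpoint k = 1..m.
    bidirectional-stagger: stagger magnitudes with the first (smallest) half
                           negated.
    spike                : spike_size on endpoint 1, spike_background on the
                           others.
    null                 : all zeros.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if label == "const":
        delta = np.full(m, effect_size)
    elif label == "bidirectional-const":
        delta = np.full(m, effect_size)
        delta[: m // 2] *= -1.0
    elif label == "stagger":
        delta = effect_size * np.arange(1, m + 1) / m
    elif label == "bidirectional-stagger":
        delta = effect_size * np.arange(1, m + 1) / m
        delta[: m // 2] *= -1.0
    elif label == "spike":
        delta = np.full(m, spike_background)
        delta[0] = spike_size
    elif label == "null":
        delta = np.zeros(m)
    else:
        raise ValueError(
            f"unknown scenario {label!r}; choose from {SCENARIO_LABELS}"
        )
    return EffectScenario(label=label, delta=delta)


def random_correlation(m, *, alphad: float = 1.0, rng=None) -> np.ndarray:
    """Draw a random m x m positive-definite correlation matrix (C-vine).

    Partial correlations on tree level k (1-based) are
    ``2*Beta(b_k, b_k) - 1`` with ``b_k = alphad + (m - 1 - k)/2``; with
    ``alphad = 1`` the resulting matrix is uniform over positive-definite
    correlation matrices.  Accepts a :class:`CorrGenConfig` in place of m.
    """
    if isinstance(m, CorrGenConfig):
        cfg = m
        m, alphad = cfg.m, cfg.alphad
        rng = as_rng(cfg.seed if rng is None else rng)
    else:
        rng = as_rng(rng)
    m = int(m)
    if m < 2:
        raise ValueError("need at least 2 endpoints")
    if alphad <= 0:
        raise ValueError("alphad must be positive")
    beta = alphad + (m - 1) / 2.0
    P = np.zeros((m, m))  # partial correlations
    R = np.eye(m)
    for k in range(m - 1):
        beta -= 0.5
        for i in range(k + 1, m):
            P[k, i] = 2.0 * rng.beta(beta, beta) - 1.0
            rho = P[k, i]
            for l in range(k - 1, -1, -1):
                rho = (
                    rho * np.sqrt((1.0 - P[l, i] ** 2) * (1.0 - P[l, k] ** 2))
                    + P[l, i] * P[l, k]
                )
            R[k, i] = R[i, k] = rho
    return R


def cholesky_factor(C: np.ndarray) -> np.ndarray:
    """Lower-triangular factor of a validated correlation matrix.

    Falls back to an eigenvalue factorization when the matrix is positive
    semi-definite but numerically singular.
    """
    C = validate_correlation(C)
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        lam, V = np.linalg.eigh(C)
        return V * np.sqrt(np.clip(lam, 0.0, None))


def make_dataset(
    C,
    scenario,
    n: int,
    *,
    design: str = "two-group",
    rng=None,
    endpoint_labels=None,
) -> pd.DataFrame:
    """Simulate an endpoint data table from MVN(delta, C) with unit variances.

    two-group: group 1 ~ MVN(0, C), group 2 ~ MVN(delta, C), n rows per group,
    with a leading ``group`` column (levels 1 and 2).  paired: n rows of
    within-subject differences ~ MVN(delta, C).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = as_rng(rng)
    C = validate_correlation(C)
    m = C.shape[0]
    if isinstance(scenario, EffectScenario):
        delta = scenario.delta
    elif isinstance(scenario, str):
        delta = effect_scenario(scenario, m).delta
    else:
        delta = np.atleast_1d(np.asarray(scenario, dtype=float))
    if len(delta) != m:
        raise ValueError(f"{len(delta)} effect sizes for {m} endpoints")
    L = cholesky_factor(C)
    labels = (
        [str(x) for x in endpoint_labels]
        if endpoint_labels is not None
        else [f"e{i + 1}" for i in range(m)]
    )
    if len(labels) != m:
        raise ValueError(f"{len(labels)} labels for {m} endpoints")
    if design == "two-group":
        g1 = rng.standard_normal((n, m)) @ L.T
        g2 = rng.standard_normal((n, m)) @ L.T + delta
        df = pd.DataFrame(np.vstack([g1, g2]), columns=labels)
        df.insert(0, "group", np.repeat([1, 2], n))
        return df
    if design == "paired":
        X = rng.standard_normal((n, m)) @ L.T + delta
        return pd.DataFrame(X, columns=labels)
    raise ValueError(f"unknown design {design!r}; use 'paired' or 'two-group'")
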