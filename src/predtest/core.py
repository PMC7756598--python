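"""Prediction-based global test for multiple correlated endpoints.

A study measures ``m`` endpoints on each experimental unit and the researcher
states, a priori, the direction (increase or decrease) each endpoint will move.
Each endpoint ``i`` receives a weight

    w_i = 1 / sum_j r_ij**2

(the sum over row ``i`` of the squared sample correlation matrix, including the
diagonal term ``r_ii = 1``), so ``w_i = 1`` when the endpoint is uncorrelated
with every other endpoint and ``w_i = 1/m`` under perfect pairwise association.
``W = sum_i w_i`` acts as the effective number of independent endpoints.

The test statistic is the weighted count of correct directional predictions,

    T_m = sum_i p_i * w_i,   p_i = 1 iff the observed sample effect on
                             endpoint i has the predicted sign,

and the hypotheses concern phi, the researcher's predictive ability
(H0: phi <= phi0 vs H1: phi > phi0).  Under H0 the p_i are iid
Bernoulli(phi0), so T_m is a weighted Bernoulli sum whose null distribution is
enumerated exactly over all 2**m prediction vectors, or approximated by
Normal(phi0*W, sqrt(phi0*(1-phi0)*sum(w_i**2))) when m is large.  The null is
rejected when the upper-tail p-value is at most alpha and, by default, when
T_m >= 1 (at least one effective endpoint correctly predicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ENUMERATION_CAP",
    "DEFAULT_EXACT_LIMIT",
    "TIE_TOLERANCE",
    "CorrelationMatrix",
    "WeightVector",
    "DirectionPredictions",
    "PredictionOutcomes",
    "ExactNullDistribution",
    "TestResult",
    "validate_correlation",
    "compute_weights",
    "evaluate_predictions",
    "test_statistic",
    "exact_null_distribution",
    "exact_pvalue",
    "exact_tail_probability",
    "normal_pvalue",
    "prediction_test",
    "run_prediction_test",
    "minimum_required_m",
    "observed_effects",
    "sample_correlation",
]

#: hard cap on full enumeration of the 2**m prediction vectors
ENUMERATION_CAP = 25
#: method="auto" uses the exact distribution up to this many endpoints
DEFAULT_EXACT_LIMIT = 20
#: absolute tolerance for merging / comparing enumerated statistic values
TIE_TOLERANCE = 1e-9

_PSD_TOL = 1e-8


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def validate_correlation(C, *, name: str = "correlation matrix") -> np.ndarray:
    """Validate and return an m x m correlation matrix as a float array.

    Requires a square symmetric matrix with unit diagonal, off-diagonal
    entries in [-1, 1] and smallest eigenvalue >= -1e-8.  Raises
    ``ValueError`` naming the offending entry otherwise.
    """
    if isinstance(C, CorrelationMatrix):
        return C.values
    if isinstance(C, pd.DataFrame):
        C = C.to_numpy()
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"{name} must be square, got shape {C.shape}")
    m = C.shape[0]
    if m < 2:
        raise ValueError(
            "not a multiple-endpoint problem: need at least 2 endpoints"
        )
    if not np.isfinite(C).all():
        i, j = map(int, np.argwhere(~np.isfinite(C))[0])
        raise ValueError(f"{name} has non-finite entry at ({i}, {j})")
    asym = np.abs(C - C.T)
    if asym.max() > 1e-8:
        i, j = map(int, np.unravel_index(np.argmax(asym), C.shape))
        raise ValueError(
            f"{name} is not symmetric at ({i}, {j}): "
            f"{C[i, j]!r} vs {C[j, i]!r}"
        )
    ddev = np.abs(np.diag(C) - 1.0)
    if ddev.max() > 1e-8:
        i = int(np.argmax(ddev))
        raise ValueError(f"{name} diagonal entry ({i}, {i}) = {C[i, i]!r} is not 1")
    over = np.abs(C) - 1.0
    if over.max() > 1e-8:
        i, j = map(int, np.unravel_index(np.argmax(over), C.shape))
        raise ValueError(f"{name} entry ({i}, {j}) = {C[i, j]!r} is outside [-1, 1]")
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    lam_min = float(np.linalg.eigvalsh(C)[0])
    if lam_min < -_PSD_TOL:
        raise ValueError(
            f"{name} is not positive semi-definite "
            f"(smallest eigenvalue {lam_min:.3g})"
        )
    return C


def _check_phi0(phi0: float) -> float:
    phi0 = float(phi0)
    if not 0.0 < phi0 < 1.0:
        raise ValueError(f"phi0 must be in (0, 1), got {phi0}")
    return phi0


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    """Validated m x m endpoint correlation matrix with optional labels."""

    values: np.ndarray
    endpoint_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        vals = validate_correlation(self.values)
        object.__setattr__(self, "values", vals)
        if self.endpoint_labels is not None:
            labels = tuple(str(x) for x in self.endpoint_labels)
            if len(labels) != vals.shape[0]:
                raise ValueError(
                    f"{len(labels)} labels for {vals.shape[0]} endpoints"
                )
            object.__setattr__(self, "endpoint_labels", labels)

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """Per-endpoint weights w_i with W = sum(w) the effective endpoint count."""

    w: np.ndarray

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a 1-d vector")
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("weights must be finite and positive")
        object.__setattr__(self, "w", w)

    def __len__(self) -> int:
        return len(self.w)

    @property
    def m(self) -> int:
        return len(self.w)

    @property
    def W(self) -> float:
        """Sum of weights: the effective number of independent endpoints."""
        return float(self.w.sum())

    @property
    def sumsq(self) -> float:
        return float((self.w ** 2).sum())


@dataclass(frozen=True)
class DirectionPredictions:
    """A priori +1 / -1 directional predictions, one per endpoint."""

    signs: np.ndarray
    endpoint_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.signs))
        if s.dtype.kind in "UO":  # allow "up"/"down" style tokens
            s = np.array([parse_direction(x) for x in s], dtype=int)
        s = s.astype(int)
        if not np.isin(s, (-1, 1)).all():
            bad = s[~np.isin(s, (-1, 1))][0]
            raise ValueError(f"predictions must be +1 or -1, got {bad!r}")
        object.__setattr__(self, "signs", s)
        if self.endpoint_labels is not None:
            labels = tuple(str(x) for x in self.endpoint_labels)
            if len(labels) != len(s):
                raise ValueError("label / prediction length mismatch")
            object.__setattr__(self, "endpoint_labels", labels)

    def __len__(self) -> int:
        return len(self.signs)


_DIRECTION_TOKENS = {
    "+1": 1, "1": 1, "up": 1, "increase": 1, "pos": 1, "positive": 1,
    "-1": -1, "down": -1, "decrease": -1, "neg": -1, "negative": -1,
}


def parse_direction(token) -> int:
    """Map a direction token (+1/-1/up/down/...) to an integer sign."""
    key = str(token).strip().lower()
    if key not in _DIRECTION_TOKENS:
        raise ValueError(f"unrecognised direction {token!r}; use +1/-1/up/down")
    return _DIRECTION_TOKENS[key]


@dataclass(frozen=True)
class PredictionOutcomes:
    """Binary indicators: p_i = 1 iff the prediction on endpoint i was correct."""

    p: np.ndarray

    def __post_init__(self):
        p = np.atleast_1d(np.asarray(self.p)).astype(int)
        if not np.isin(p, (0, 1)).all():
            bad = p[~np.isin(p, (0, 1))][0]
            raise ValueError(f"outcomes must be 0 or 1, got {bad!r}")
        object.__setattr__(self, "p", p)

    def __len__(self) -> int:
        return len(self.p)

    @property
    def n_correct(self) -> int:
        return int(self.p.sum())


@dataclass(frozen=True)
class ExactNullDistribution:
    """Enumerated null pmf of T_m for given weights and phi0.

    ``support`` holds the distinct achievable statistic values (sorted,
    merged within ``tie_tolerance``) and ``probs`` their probabilities
    phi0**k * (1-phi0)**(m-k) accumulated over the 2**m prediction vectors.
    """

    support: np.ndarray
    probs: np.ndarray
    phi0: float
    tie_tolerance: float = TIE_TOLERANCE

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)

    @property
    def var(self) -> float:
        mu = self.mean
        return float(((self.support - mu) ** 2) @ self.probs)

    def cdf(self, t):
        """P(T <= t), with t + tie_tolerance inclusion."""
        t = np.asarray(t, dtype=float)
        cs = np.concatenate([[0.0], np.cumsum(self.probs)])
        idx = np.searchsorted(self.support, t + self.tie_tolerance, side="right")
        out = cs[idx]
        return float(out) if out.ndim == 0 else out

    def sf(self, t):
        """Upper tail P(T >= t), observed value included (within tolerance)."""
        t = np.asarray(t, dtype=float)
        tail = np.concatenate([np.cumsum(self.probs[::-1])[::-1], [0.0]])
        idx = np.searchsorted(self.support, t - self.tie_tolerance, side="left")
        out = tail[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.support, "probability": self.probs})


@dataclass(frozen=True)
class TestResult:
    """Outcome of the prediction-based global test."""

    statistic: float
    p_value: float
    method: str
    phi0: float
    alpha: float
    reject: bool
    W: float
    require_T_ge_1: bool
    weights: np.ndarray
    n_correct: int
    m: int
    endpoint_labels: tuple[str, ...] | None = None

    def __str__(self) -> str:  # 6 significant digits, human readable
        lines = [
            "Prediction-based global test",
            f"  endpoints (m)        : {self.m}",
            f"  effective endpoints W: {self.W:.6g}",
            f"  correct predictions  : {self.n_correct}",
            f"  statistic T_m        : {self.statistic:.6g}",
            f"  null phi0            : {self.phi0:.6g}",
            f"  p-value ({self.method:>6s})     : {self.p_value:.6g}",
            f"  alpha                : {self.alpha:.6g}",
            f"  T_m >= 1 gate        : {'on' if self.require_T_ge_1 else 'off'}",
            f"  decision             : "
            f"{'reject H0' if self.reject else 'fail to reject H0'}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# weights and outcomes
# ---------------------------------------------------------------------------

def compute_weights(C, endpoint_labels=None) -> WeightVector:
    """Correlation-derived endpoint weights w_i = 1 / sum_j r_ij**2.

    The row sum of squared correlations includes the diagonal r_ii = 1, so
    w_i = 1 for an endpoint uncorrelated with all others and w_i = 1/m when
    every |r_ij| = 1.
    """
    vals = validate_correlation(C)
    w = 1.0 / (vals ** 2).sum(axis=1)
    return WeightVector(w)


def evaluate_predictions(effects, predictions) -> PredictionOutcomes:
    """Score directional predictions against observed effect estimates.

    ``p_i = 1`` iff ``sign(effects[i]) == predictions[i]``.  An exactly-zero
    observed effect counts as an incorrect prediction (conservative tie rule).
    """
    effects = np.atleast_1d(np.asarray(effects, dtype=float))
    if not np.isfinite(effects).all():
        i = int(np.flatnonzero(~np.isfinite(effects))[0])
        raise ValueError(f"effect estimate for endpoint {i} is not finite")
    if not isinstance(predictions, DirectionPredictions):
        predictions = DirectionPredictions(predictions)
    if len(predictions) != len(effects):
        raise ValueError(
            f"{len(effects)} effects but {len(predictions)} predictions"
        )
    p = (np.sign(effects) == predictions.signs).astype(int)
    return PredictionOutcomes(p)


def _as_outcomes(p) -> PredictionOutcomes:
    return p if isinstance(p, PredictionOutcomes) else PredictionOutcomes(p)


def _as_weights(w) -> WeightVector:
    return w if isinstance(w, WeightVector) else WeightVector(w)


def test_statistic(p, w) -> float:
    """Weighted count of correct predictions, T_m = sum_i p_i * w_i."""
    p = _as_outcomes(p)
    w = _as_weights(w)
    if len(p) != len(w):
        raise ValueError(f"{len(p)} outcomes but {len(w)} weights")
    return float(p.p @ w.w)


# ---------------------------------------------------------------------------
# null distribution
# ---------------------------------------------------------------------------

def _subset_sums(w: np.ndarray):
    """All 2**m subset sums of w and the matching subset sizes (by doubling)."""
    m = len(w)
    vals = np.zeros(2 ** m)
    k = np.zeros(2 ** m, dtype=np.int16)
    size = 1
    for wi in w:
        vals[size:2 * size] = vals[:size] + wi
        k[size:2 * size] = k[:size] + 1
        size *= 2
    return vals, k


def _check_enumeration(m: int):
    if m > ENUMERATION_CAP:
        raise ValueError(
            f"exact enumeration over 2**{m} prediction vectors exceeds the "
            f"cap of m = {ENUMERATION_CAP}; use the normal approximation "
            "(method='normal') or a Monte-Carlo estimate"
        )


def exact_null_distribution(
    w, phi0: float, tie_tolerance: float = TIE_TOLERANCE
) -> ExactNullDistribution:
    """Enumerate the exact null pmf of T_m over all 2**m prediction vectors.

    Each prediction vector p contributes probability
    phi0**sum(p) * (1-phi0)**(m-sum(p)) to the statistic value p @ w.
    Values equal within ``tie_tolerance`` are merged (probability-weighted
    representative value).
    """
    w = _as_weights(w)
    phi0 = _check_phi0(phi0)
    m = len(w)
    _check_enumeration(m)
    vals, k = _subset_sums(w.w)
    pk = phi0 ** np.arange(m + 1)
    qk = (1.0 - phi0) ** np.arange(m + 1)
    probs = pk[k] * qk[m - k]
    order = np.argsort(vals, kind="stable")
    vals = vals[order]
    probs = probs[order]
    starts = np.flatnonzero(
        np.concatenate([[True], np.diff(vals) > tie_tolerance])
    )
    grouped_probs = np.add.reduceat(probs, starts)
    grouped_vals = np.add.reduceat(vals * probs, starts) / grouped_probs
    return ExactNullDistribution(
        support=grouped_vals,
        probs=grouped_probs,
        phi0=phi0,
        tie_tolerance=tie_tolerance,
    )


def exact_pvalue(t_obs: float, dist: ExactNullDistribution) -> float:
    """Upper-tail exact p-value P(T >= t_obs), observed value included."""
    t_obs = float(t_obs)
    if not np.isfinite(t_obs):
        raise ValueError("observed statistic must be finite")
    return dist.sf(t_obs)


def exact_tail_probability(
    t_obs: float,
    w,
    phi0: float,
    tie_tolerance: float = TIE_TOLERANCE,
) -> float:
    """P(T >= t_obs) by direct enumeration, without building the full pmf.

    Equivalent to ``exact_pvalue(t_obs, exact_null_distribution(w, phi0))``
    but avoids the sort, which matters inside simulation loops.
    """
    w = _as_weights(w)
    phi0 = _check_phi0(phi0)
    m = len(w)
    _check_enumeration(m)
    t_obs = float(t_obs)
    vals, k = _subset_sums(w.w)
    mask = vals >= t_obs - tie_tolerance
    if phi0 == 0.5:  # all 2**m vectors equiprobable
        return float(mask.mean())
    pk = phi0 ** np.arange(m + 1)
    qk = (1.0 - phi0) ** np.arange(m + 1)
    return float((pk[k[mask]] * qk[m - k[mask]]).sum())


def normal_pvalue(t_obs: float, w, phi0: float) -> float:
    """Upper-tail p-value from the large-m normal approximation.

    T_m ~ Normal(mu, sigma) with mu = phi0*W and
    sigma = sqrt(phi0*(1-phi0)*sum(w_i**2)); no continuity correction is
    applied (the support is irregular, so a half-width correction is
    ill-defined).
    """
    w = _as_weights(w)
    phi0 = _check_phi0(phi0)
    mu = phi0 * w.W
    var = phi0 * (1.0 - phi0) * w.sumsq
    if var <= 0.0:
        raise ValueError("degenerate null distribution: sigma = 0")
    return float(sps.norm.sf((float(t_obs) - mu) / np.sqrt(var)))


def minimum_required_m(phi0: float, alpha: float = 0.05) -> int:
    """Smallest endpoint count m at which H0 can ever be rejected.

    The most extreme achievable record is all-correct, with null probability
    phi0**m; rejection at level alpha is feasible only once phi0**m <= alpha.
    """
    phi0 = _check_phi0(phi0)
    alpha = _check_alpha(alpha)
    m = 1
    p = phi0
    while p > alpha:
        m += 1
        p *= phi0
        if m > 10_000_000:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("minimum m search did not terminate")
    return m


# ---------------------------------------------------------------------------
# data handling: observed effects and sample correlation
# ---------------------------------------------------------------------------

def _split_two_group(data: pd.DataFrame, group_col: str):
    if group_col not in data.columns:
        raise ValueError(f"two-group design requires a {group_col!r} column")
    levels = sorted(data[group_col].unique(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"two-group design requires exactly 2 group levels, "
            f"got {len(levels)}: {levels!r}"
        )
    endpoints = [c for c in data.columns if c != group_col]
    if not endpoints:
        raise ValueError("no endpoint columns found")
    g1 = data.loc[data[group_col] == levels[0], endpoints].to_numpy(float)
    g2 = data.loc[data[group_col] == levels[1], endpoints].to_numpy(float)
    return g1, g2, endpoints


def observed_effects(data: pd.DataFrame, design: str = "paired",
                     group_col: str = "group"):
    """Per-endpoint observed effect estimates from a study data table.

    paired: column means of the within-subject differences.
    two-group: mean of the second group level minus the first (levels sorted).
    Returns ``(effects, endpoint_labels)``.
    """
    if design == "paired":
        X = data.to_numpy(float)
        return X.mean(axis=0), [str(c) for c in data.columns]
    if design == "two-group":
        g1, g2, endpoints = _split_two_group(data, group_col)
        return g2.mean(axis=0) - g1.mean(axis=0), [str(c) for c in endpoints]
    raise ValueError(f"unknown design {design!r}; use 'paired' or 'two-group'")


def _corr_matrix(X: np.ndarray, estimator: str, labels) -> np.ndarray:
    sd = X.std(axis=0)
    if (sd == 0).any():
        i = int(np.argmax(sd == 0))
        raise ValueError(f"endpoint {labels[i]!r} has zero variance")
    if estimator == "pearson":
        return np.corrcoef(X, rowvar=False)
    if estimator == "spearman":
        rho = sps.spearmanr(X).statistic
        return np.array([[1.0, rho], [rho, 1.0]]) if np.isscalar(rho) else rho
    if estimator == "kendall":
        m = X.shape[1]
        R = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                R[i, j] = R[j, i] = sps.kendalltau(X[:, i], X[:, j]).statistic
        return R
    raise ValueError(
        f"unknown correlation estimator {estimator!r}; "
        "use pearson, spearman or kendall"
    )


def sample_correlation(data: pd.DataFrame, design: str = "paired",
                       estimator: str = "pearson",
                       group_col: str = "group") -> np.ndarray:
    """Endpoint correlation matrix on the analysis scale.

    paired: correlation of the within-subject differences.  two-group: pooled
    within-group correlation (each group de-meaned before pooling), so that
    between-group mean shifts do not contaminate the correlations.
    """
    if design == "paired":
        X = data.to_numpy(float)
        labels = list(data.columns)
    elif design == "two-group":
        g1, g2, labels = _split_two_group(data, group_col)
        X = np.vstack([g1 - g1.mean(axis=0), g2 - g2.mean(axis=0)])
    else:
        raise ValueError(f"unknown design {design!r}; use 'paired' or 'two-group'")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    return _corr_matrix(X, estimator, labels)


# ---------------------------------------------------------------------------
# the test itself
# ---------------------------------------------------------------------------

def prediction_test(
    outcomes,
    weights,
    *,
    phi0: float = 0.5,
    alpha: float = 0.05,
    method: str = "auto",
    require_T_ge_1: bool = True,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    endpoint_labels=None,
) -> TestResult:
    """Run the global test from prediction outcomes and endpoint weights.

    This is the computational kernel behind :func:`run_prediction_test`; use
    it directly when weights and outcomes are already available (e.g. from a
    published summary).
    """
    p = _as_outcomes(outcomes)
    w = _as_weights(weights)
    if len(p) != len(w):
        raise ValueError(f"{len(p)} outcomes but {len(w)} weights")
    m = len(w)
    if m < 2:
        raise ValueError("not a multiple-endpoint problem: need at least 2 endpoints")
    phi0 = _check_phi0(phi0)
    alpha = _check_alpha(alpha)
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    resolved = method
    if method == "auto":
        resolved = "exact" if m <= exact_limit else "normal"
    t = float(p.p @ w.w)
    if resolved == "exact":
        p_value = exact_tail_probability(t, w, phi0)
    else:
        p_value = normal_pvalue(t, w, phi0)
    reject = p_value <= alpha and (not require_T_ge_1 or t >= 1.0 - TIE_TOLERANCE)
    return TestResult(
        statistic=t,
        p_value=p_value,
        method=resolved,
        phi0=phi0,
        alpha=alpha,
        reject=bool(reject),
        W=w.W,
        require_T_ge_1=require_T_ge_1,
        weights=w.w,
        n_correct=p.n_correct,
        m=m,
        endpoint_labels=tuple(endpoint_labels) if endpoint_labels else None,
    )


def run_prediction_test(
    data: pd.DataFrame | None = None,
    predictions=None,
    design: str = "paired",
    *,
    correlation=None,
    outcomes=None,
    phi0: float = 0.5,
    alpha: float = 0.05,
    method: str = "auto",
    require_T_ge_1: bool = True,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    correlation_estimator: str = "pearson",
    group_col: str = "group",
) -> TestResult:
    """Full pipeline: weights, outcomes, statistic, p-value and decision.

    Either pass a raw ``data`` table plus directional ``predictions`` (the
    correlation matrix and observed effect signs are computed per ``design``),
    or a precomputed ``correlation`` matrix plus binary ``outcomes``.
    """
    if data is not None:
        if predictions is None:
            raise ValueError("predictions are required when data is given")
        effects, labels = observed_effects(data, design, group_col)
        if len(effects) < 2:
            raise ValueError(
                "not a multiple-endpoint problem: need at least 2 endpoints"
            )
        C = sample_correlation(data, design, correlation_estimator, group_col)
        out = evaluate_predictions(effects, predictions)
    elif correlation is not None and outcomes is not None:
        C = validate_correlation(correlation)
        labels = None
        out = _as_outcomes(outcomes)
    else:
        raise ValueError(
            "pass either (data, predictions) or (correlation=, outcomes=)"
        )
    w = compute_weights(C)
    return prediction_test(
        out,
        w,
        phi0=phi0,
        alpha=alpha,
        method=method,
        require_T_ge_1=require_T_ge_1,
        exact_limit=exact_limit,
        endpoint_labels=labels,
    )
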