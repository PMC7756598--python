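"""Monte-Carlo studies: power, type-I error, weight sensitivity and the
accuracy of the normal approximation (GMAE).

All studies share the same layered design: draw ``n_matrices`` random
correlation matrices from the uniform (vine, alphad = 1) ensemble, then for
each matrix run ``n_reps_per_matrix`` replicates.  One master seed spawns an
independent child stream per (matrix, replicate) cell, so any cell can be
re-run in isolation.

Predictions are simulated per the constant-predictive-ability model: each
endpoint's prediction equals the true sign of its effect with probability
``phi_true`` (against a fixed +1 reference direction where the true effect is
zero), and a prediction scores as correct only when it matches the true
direction *and* the observed sample effect falls on that side of zero.
Sampling error can therefore put the observed effect on the wrong side of
zero even for a correct prediction, which drives the per-endpoint success
rate below ``phi_true`` — and the test below its nominal level — for small
effect sizes and small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    DEFAULT_EXACT_LIMIT,
    TIE_TOLERANCE,
    WeightVector,
    compute_weights,
    exact_null_distribution,
    exact_tail_probability,
    normal_pvalue,
)
from .corrsim import as_rng, cholesky_factor, effect_scenario, random_correlation

__all__ = [
    "SimConfig",
    "SimResult",
    "SensitivityResult",
    "simulate_power",
    "simulate_type1",
    "simulate_sensitivity",
    "gmae_study",
]


@dataclass(frozen=True)
class SimConfig:
    """One power / type-I simulation cell."""

    n_per_group: int = 50
    m: int = 6
    phi_true: float = 0.8
    phi0: float = 0.5
    alpha: float = 0.05
    scenario: str = "const"
    effect_size: float = 0.5
    n_matrices: int = 50
    n_reps_per_matrix: int = 100
    design: str = "two-group"
    method: str = "auto"
    exact_limit: int = DEFAULT_EXACT_LIMIT
    require_T_ge_1: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_matrices < 1 or self.n_reps_per_matrix < 1:
            raise ValueError("simulation counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.phi_true <= 1.0:
            raise ValueError("phi_true must be in [0, 1]")


@dataclass(frozen=True)
class SimResult:
    """Rejection-rate estimate with its Monte-Carlo standard error."""

    rejection_rate: float
    mc_se: float
    per_matrix_rates: np.ndarray
    config: SimConfig
    n_total: int
    ols_rejection_rate: float | None = None
    ols_mc_se: float | None = None
    ols_per_matrix_rates: np.ndarray | None = None

    @property
    def cluster_se(self) -> float:
        """Between-matrix standard error of the overall rate."""
        r = self.per_matrix_rates
        if len(r) < 2:
            return self.mc_se
        return float(r.std(ddof=1) / np.sqrt(len(r)))


def _binomial_se(rate: float, n: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / n))


def _resolve_method(method: str, m: int, exact_limit: int) -> str:
    if method == "auto":
        return "exact" if m <= exact_limit else "normal"
    return method


def _tail_prob(t: float, w: WeightVector, phi0: float, method: str) -> float:
    if method == "exact":
        return exact_tail_probability(t, w, phi0)
    return normal_pvalue(t, w, phi0)


def _simulate_effects(rng, L, delta, n, design):
    """Observed per-endpoint effects plus the rows used for correlation."""
    m = L.shape[0]
    if design == "two-group":
        g1 = rng.standard_normal((n, m)) @ L.T
        g2 = rng.standard_normal((n, m)) @ L.T + delta
        effects = g2.mean(axis=0) - g1.mean(axis=0)
        pooled = np.vstack([g1 - g1.mean(axis=0), g2 - g2.mean(axis=0)])
        return effects, pooled, (g1, g2)
    if design == "paired":
        X = rng.standard_normal((n, m)) @ L.T + delta
        return X.mean(axis=0), X - X.mean(axis=0), (X,)
    raise ValueError(f"unknown design {design!r}")


def _ols_reject(t_stats, R, df, alpha):
    denom_sq = float(R.sum())
    if denom_sq <= 0:
        return False
    t_ols = t_stats.sum() / np.sqrt(denom_sq)
    return bool(sps.t.sf(t_ols, df) <= alpha)


def simulate_power(cfg: SimConfig, *, include_ols: bool = False) -> SimResult:
    """Empirical rejection rate of the proposed test (optionally OLS too).

    Per replicate: draw directional predictions with per-endpoint accuracy
    ``phi_true`` against the true signs, simulate the dataset, score a
    prediction as correct when it matches the true direction and the observed
    sample effect confirms it, weight by the sample correlation matrix, and
    test at ``phi0`` / ``alpha``.
    """
    method = _resolve_method(cfg.method, cfg.m, cfg.exact_limit)
    if method == "exact" and cfg.m > 25:
        raise ValueError("exact method infeasible for m > 25; use normal")
    delta = effect_scenario(
        cfg.scenario, cfg.m, effect_size=cfg.effect_size
    ).delta
    true_dir = np.where(delta < 0, -1, 1)  # +1 reference where delta == 0
    ss = np.random.SeedSequence(cfg.seed)
    matrix_seeds = ss.spawn(cfg.n_matrices)
    rates = np.empty(cfg.n_matrices)
    ols_rates = np.empty(cfg.n_matrices) if include_ols else None
    n1 = n2 = cfg.n_per_group
    ols_df = (
        2 * cfg.n_per_group - 2 if cfg.design == "two-group"
        else cfg.n_per_group - 1
    )
    for j, mseed in enumerate(matrix_seeds):
        children = mseed.spawn(cfg.n_reps_per_matrix + 1)
        C = random_correlation(cfg.m, rng=as_rng(children[0]))
        L = cholesky_factor(C)
        rejected = 0
        ols_rejected = 0
        for rep_seed in children[1:]:
            rng = as_rng(rep_seed)
            predicted_true_dir = rng.random(cfg.m) < cfg.phi_true
            effects, centered, groups = _simulate_effects(
                rng, L, delta, cfg.n_per_group, cfg.design
            )
            R = np.corrcoef(centered, rowvar=False)
            w = WeightVector(1.0 / (R ** 2).sum(axis=1))
            p = (predicted_true_dir & (np.sign(effects) == true_dir)).astype(int)
            t = float(p @ w.w)
            pv = _tail_prob(t, w, cfg.phi0, method)
            if pv <= cfg.alpha and (
                not cfg.require_T_ge_1 or t >= 1.0 - TIE_TOLERANCE
            ):
                rejected += 1
            if include_ols:
                if cfg.design == "two-group":
                    g1, g2 = groups
                    s1 = g1.var(axis=0, ddof=1)
                    s2 = g2.var(axis=0, ddof=1)
                    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
                    t_stats = effects / np.sqrt(sp2 * (1 / n1 + 1 / n2))
                else:
                    (X,) = groups
                    sd = X.std(axis=0, ddof=1)
                    t_stats = effects / (sd / np.sqrt(cfg.n_per_group))
                if _ols_reject(t_stats, R, ols_df, cfg.alpha):
                    ols_rejected += 1
        rates[j] = rejected / cfg.n_reps_per_matrix
        if include_ols:
            ols_rates[j] = ols_rejected / cfg.n_reps_per_matrix
    n_total = cfg.n_matrices * cfg.n_reps_per_matrix
    rate = float(rates.mean())
    result = SimResult(
        rejection_rate=rate,
        mc_se=_binomial_se(rate, n_total),
        per_matrix_rates=rates,
        config=cfg,
        n_total=n_total,
    )
    if include_ols:
        ols_rate = float(ols_rates.mean())
        result = replace(
            result,
            ols_rejection_rate=ols_rate,
            ols_mc_se=_binomial_se(ols_rate, n_total),
            ols_per_matrix_rates=ols_rates,
        )
    return result


def simulate_type1(cfg: SimConfig, *, include_ols: bool = False) -> SimResult:
    """Type-I error study: same engine with phi_true pinned to phi0."""
    return simulate_power(replace(cfg, phi_true=cfg.phi0), include_ols=include_ols)


# ---------------------------------------------------------------------------
# sensitivity of conclusions to sample vs true correlation weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    """Decision agreement between true-correlation and sample-correlation weights."""

    table: pd.DataFrame
    average_agreement: float
    seed: int | None = None


def simulate_sensitivity(
    *,
    m_grid,
    phi_grid,
    phi0: float = 0.5,
    alpha: float = 0.05,
    n: int = 20,
    n_matrices: int = 25,
    n_reps_per_matrix: int = 20,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    require_T_ge_1: bool = True,
    seed: int | None = None,
) -> SensitivityResult:
    """How often do sample-correlation weights change the test conclusion?

    For each (m, phi) cell: draw a true correlation matrix, estimate a sample
    correlation matrix from n MVN observations, draw Bernoulli(phi) prediction
    outcomes, run the test once with each weight set (exact for
    m <= exact_limit, normal above) and record whether the reject/fail
    decisions agree.  Returns per-cell and overall average agreement.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for m in m_grid:
        method = _resolve_method("auto", m, exact_limit)
        for phi in phi_grid:
            cell_seed = ss.spawn(1)[0]
            matrix_seeds = cell_seed.spawn(n_matrices)
            agree = 0
            total = 0
            for mseed in matrix_seeds:
                children = mseed.spawn(n_reps_per_matrix + 1)
                C_true = random_correlation(m, rng=as_rng(children[0]))
                L = cholesky_factor(C_true)
                w_true = compute_weights(C_true)
                for rep_seed in children[1:]:
                    rng = as_rng(rep_seed)
                    X = rng.standard_normal((n, m)) @ L.T
                    R = np.corrcoef(X, rowvar=False)
                    w_samp = WeightVector(1.0 / (R ** 2).sum(axis=1))
                    p = (rng.random(m) < phi).astype(int)
                    decisions = []
                    for w in (w_true, w_samp):
                        t = float(p @ w.w)
                        pv = _tail_prob(t, w, phi0, method)
                        decisions.append(
                            pv <= alpha
                            and (not require_T_ge_1 or t >= 1.0 - TIE_TOLERANCE)
                        )
                    agree += decisions[0] == decisions[1]
                    total += 1
            rows.append(
                {
                    "m": m,
                    "phi": phi,
                    "phi0": phi0,
                    "n": n,
                    "method": method,
                    "agreement": agree / total,
                    "n_reps": total,
                }
            )
    table = pd.DataFrame(rows)
    return SensitivityResult(
        table=table,
        average_agreement=float(table["agreement"].mean()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# normal-approximation accuracy (GMAE)
# ---------------------------------------------------------------------------

def gmae_study(
    m_grid,
    phi_grid=(0.5,),
    *,
    n_matrices: int = 20,
    n_pred_sets: int = 1000,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Grand mean absolute error between the exact and normal CDFs of T_m.

    Per correlation matrix: draw ``n_pred_sets`` Bernoulli(phi0) prediction
    vectors, compute their statistics, and average |F_exact - F_normal| over
    those points; F_exact is the enumerated CDF for m <= exact_limit and the
    empirical CDF of the sampled statistics above it.  The GMAE for a grid
    cell is the mean over matrices.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for m in m_grid:
        for phi0 in phi_grid:
            cell_seed = ss.spawn(1)[0]
            maes = np.empty(n_matrices)
            for j, mseed in enumerate(cell_seed.spawn(n_matrices)):
                rng = as_rng(mseed)
                C = random_correlation(m, rng=rng)
                w = compute_weights(C)
                P = (rng.random((n_pred_sets, m)) < phi0).astype(float)
                stats = P @ w.w
                mu = phi0 * w.W
                sigma = np.sqrt(phi0 * (1.0 - phi0) * w.sumsq)
                f_norm = sps.norm.cdf((stats - mu) / sigma)
                if m <= exact_limit:
                    dist = exact_null_distribution(w, phi0)
                    f_exact = dist.cdf(stats)
                else:
                    order = np.sort(stats)
                    f_exact = (
                        np.searchsorted(order, stats + TIE_TOLERANCE, side="right")
                        / n_pred_sets
                    )
                maes[j] = np.abs(f_exact - f_norm).mean()
            rows.append(
                {
                    "m": m,
                    "phi0": phi0,
                    "gmae": float(maes.mean()),
                    "n_matrices": n_matrices,
                    "n_pred_sets": n_pred_sets,
                }
            )
    return pd.DataFrame(rows)
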