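"""Per-gene expression weight training from eQTL summary statistics.

The model is penalized least squares on the standardized scale.  Writing
``r`` for the vector of standardized marginal SNP-expression correlations
and ``R`` for the SNP LD matrix, the quantity minimized by coordinate
descent is

    F(w) = 1/2 (w' R w + theta w' w) - w' r + J_lambda(w),

whose coordinate update for the LASSO penalty is the soft threshold
``S(z_j, lambda) / (1 + theta)`` with partial residual
``z_j = r_j - sum_{l != j} R_jl w_l``.  The ridge term ``theta w' w``
guarantees a unique minimizer when R is rank-deficient.  Five penalty
families are supported: LASSO, elastic net, MCP, SCAD and MNet; their
coordinate updates are the canonical univariate thresholding operators
with the (1 + theta) ridge folded into the denominator.

Neither r nor R requires individual-level training data: r is estimated
from eQTL z-scores as ``r_j = Z_j / sqrt(N_j - 1 + Z_j^2)`` (per-SNP
sample sizes N_j) and R from a reference panel, optionally with
genetic-distance shrinkage (see :mod:`sumtwas.ld`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

from .datatypes import EqtlSummaryTable
from .ld import LdMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "PenaltySpec",
    "TrainingConfig",
    "WeightModel",
    "MarginalEffects",
    "standardized_marginal_effects",
    "objective",
    "descent_objective",
    "coordinate_descent",
    "CdResult",
    "lambda_path",
    "fit_gene",
    "validate_models",
    "cramer_r2_threshold",
    "squared_correlation",
]

FAMILIES = ("lasso", "elastic_net", "mcp", "scad", "mnet")
_FAMILY_CODE = {f: i for i, f in enumerate(FAMILIES)}


@dataclass(frozen=True)
class PenaltySpec:
    """One penalty-family configuration point.

    ``gamma`` is the concavity parameter (MCP/MNet need gamma > 1, SCAD
    gamma > 2); ``alpha`` the L1 mixing fraction for elastic net / MNet;
    ``theta`` the ridge coefficient shared by all families.
    """

    family: str
    lam: float
    gamma: float = 0.0
    alpha: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.family == "scad" and self.gamma <= 2:
            raise ValueError("SCAD requires gamma > 2")
        if self.family in ("mcp", "mnet") and self.gamma <= 1:
            raise ValueError(f"{self.family} requires gamma > 1")
        if self.family in ("elastic_net", "mnet") and not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class TrainingConfig:
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    theta_grid: tuple = (0.0, 0.1, 0.2, 0.4, 0.8)
    alpha_grid: tuple = (0.5,)
    gamma_mcp: float = 3.0
    gamma_scad: float = 3.7
    tol: float = 1e-5
    max_iter: int = 1000
    r2_min: float = 0.005
    families: tuple = FAMILIES

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if not self.theta_grid or not self.alpha_grid or self.n_lambda < 1:
            raise ValueError("grids must be non-empty")


@dataclass
class WeightModel:
    gene_id: str
    snp_ids: list[str]
    w_hat: np.ndarray
    penalty: PenaltySpec
    r2_tuning: float
    r2_testing: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.w_hat = np.asarray(self.w_hat, dtype=float)
        if self.w_hat.shape[0] != len(self.snp_ids):
            raise ValueError("weight vector length does not match SNP ids")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.w_hat))


MarginalEffects = np.ndarray  # alias: vector of standardized marginal correlations


def standardized_marginal_effects(table: EqtlSummaryTable) -> np.ndarray:
    """Estimate standardized marginal correlations from z-scores.

    ``r_j = Z_j / sqrt(N_j - 1 + Z_j^2)``; strictly inside (-1, 1) for any
    finite z and N >= 2.
    """
    z, n = table.z, table.n
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    return z / np.sqrt(n - 1.0 + z**2)


# ---------------------------------------------------------------------------
# Penalty values and coordinate updates
# ---------------------------------------------------------------------------


@njit(cache=True)
def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def _mcp_pen(t: float, lam: float, gam: float) -> float:
    if t <= gam * lam:
        return lam * t - t * t / (2.0 * gam)
    return 0.5 * gam * lam * lam


@njit(cache=True)
def _penalty_value(w: np.ndarray, fam: int, lam: float, gam: float, alp: float) -> float:
    """J_lambda(w) for one family (theta ridge handled separately)."""
    s = 0.0
    for j in range(w.shape[0]):
        t = abs(w[j])
        if fam == 0:  # lasso
            s += lam * t
        elif fam == 1:  # elastic net
            s += lam * (alp * t + 0.5 * (1.0 - alp) * t * t)
        elif fam == 2:  # mcp
            s += _mcp_pen(t, lam, gam)
        elif fam == 3:  # scad
            if t <= lam:
                s += lam * t
            elif t <= gam * lam:
                s += (2.0 * gam * lam * t - t * t - lam * lam) / (2.0 * (gam - 1.0))
            else:
                s += 0.5 * lam * lam * (gam + 1.0)
        else:  # mnet: MCP part at alpha*lambda plus elastic-net style ridge
            s += _mcp_pen(t, lam * alp, gam) + 0.5 * lam * (1.0 - alp) * t * t
    return s


@njit(cache=True)
def _update(z: float, fam: int, lam: float, gam: float, alp: float, theta: float) -> float:
    """Coordinate-wise minimizer of 0.5*(1+theta)*w^2 - z*w + J(w)."""
    d0 = 1.0 + theta
    if fam == 0:  # lasso
        return _soft(z, lam) / d0
    if fam == 1:  # elastic net
        return _soft(z, lam * alp) / (d0 + lam * (1.0 - alp))
    if fam == 2:  # mcp (firm threshold)
        if abs(z) <= gam * lam * d0:
            return _soft(z, lam) / (d0 - 1.0 / gam)
        return z / d0
    if fam == 3:  # scad (three-piece rule)
        if abs(z) <= lam * (d0 + 1.0):
            return _soft(z, lam) / d0
        if abs(z) <= gam * lam * d0:
            return _soft(z, gam * lam / (gam - 1.0)) / (d0 - 1.0 / (gam - 1.0))
        return z / d0
    # mnet: firm threshold with the elastic-net ridge in the denominator
    dd = d0 + lam * (1.0 - alp)
    l1 = lam * alp
    if abs(z) <= gam * l1 * dd:
        return _soft(z, l1) / (dd - 1.0 / gam)
    return z / dd


@njit(cache=True)
def _cd_kernel(R, r, fam, lam, gam, alp, theta, w, tol, max_iter, fvals):
    """Cyclic coordinate descent; w is updated in place.

    Maintains s = R @ w so each unchanged coordinate costs O(1) and each
    changed one O(p).  Stores the half-quadratic objective after each full
    sweep in fvals.  Returns (n_sweeps, converged, nan_flag).
    """
    p = r.shape[0]
    s = np.zeros(p)
    for j in range(p):
        if w[j] != 0.0:
            row = R[j]  # symmetric: column j equals row j (contiguous)
            wj = w[j]
            for i in range(p):
                s[i] += row[i] * wj
    for it in range(max_iter):
        maxd = 0.0
        for j in range(p):
            zj = r[j] - s[j] + w[j]  # R has unit diagonal
            wj = _update(zj, fam, lam, gam, alp, theta)
            d = wj - w[j]
            if d != 0.0:
                w[j] = wj
                row = R[j]
                for i in range(p):
                    s[i] += row[i] * d
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        quad = 0.0
        for j in range(p):
            quad += w[j] * (0.5 * s[j] + 0.5 * theta * w[j] - r[j])
        fvals[it] = quad + _penalty_value(w, fam, lam, gam, alp)
        if not np.isfinite(fvals[it]):
            return it + 1, False, True
        if maxd < tol:
            return it + 1, True, False
    return max_iter, False, False


@dataclass
class CdResult:
    w: np.ndarray
    converged: bool
    n_sweeps: int
    objective_path: np.ndarray  # half-quadratic objective after each sweep


def _as_matrix(R) -> np.ndarray:
    return R.values if isinstance(R, LdMatrix) else np.asarray(R, dtype=float)


def objective(w: np.ndarray, r_tilde: np.ndarray, R_tilde, penalty: PenaltySpec) -> float:
    """Summary-level training objective w'Rw - 2 w'r + theta w'w + J_lambda(w)."""
    w = np.asarray(w, dtype=float)
    r = np.asarray(r_tilde, dtype=float)
    R = _as_matrix(R_tilde)
    quad = float(w @ R @ w - 2.0 * w @ r + penalty.theta * w @ w)
    pen = _penalty_value(
        w, _FAMILY_CODE[penalty.family], penalty.lam, penalty.gamma, penalty.alpha
    )
    return quad + pen


def descent_objective(w: np.ndarray, r_tilde: np.ndarray, R_tilde, penalty: PenaltySpec) -> float:
    """The half-quadratic form F(w) that coordinate descent minimizes."""
    w = np.asarray(w, dtype=float)
    r = np.asarray(r_tilde, dtype=float)
    R = _as_matrix(R_tilde)
    quad = float(0.5 * (w @ R @ w + penalty.theta * w @ w) - w @ r)
    pen = _penalty_value(
        w, _FAMILY_CODE[penalty.family], penalty.lam, penalty.gamma, penalty.alpha
    )
    return quad + pen


def coordinate_descent(
    r_tilde: np.ndarray,
    R_tilde,
    penalty: PenaltySpec,
    config: Optional[TrainingConfig] = None,
    w0: Optional[np.ndarray] = None,
) -> CdResult:
    """Solve the penalized summary-level regression for one penalty point.

    Iterates coordinates cyclically from ``w0`` (default all zero) until the
    largest absolute coordinate change in a sweep is below ``config.tol``.
    Non-convergence sets ``converged=False`` (a warning, not an error); a
    NaN in the iterates raises.
    """
    config = config or TrainingConfig()
    r = np.ascontiguousarray(r_tilde, dtype=np.float64)
    R = np.ascontiguousarray(_as_matrix(R_tilde), dtype=np.float64)
    p = r.shape[0]
    if R.shape != (p, p):
        raise ValueError("LD matrix shape does not match r")
    w = np.zeros(p) if w0 is None else np.array(w0, dtype=np.float64)
    fvals = np.empty(config.max_iter)
    n_sweeps, converged, nan_flag = _cd_kernel(
        R,
        r,
        _FAMILY_CODE[penalty.family],
        penalty.lam,
        penalty.gamma,
        penalty.alpha,
        penalty.theta,
        w,
        config.tol,
        config.max_iter,
        fvals,
    )
    if nan_flag:
        raise FloatingPointError("coordinate descent produced non-finite iterates")
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {config.max_iter} sweeps "
            f"({penalty.family}, lambda={penalty.lam:g})",
            RuntimeWarning,
        )
    return CdResult(w=w, converged=converged, n_sweeps=n_sweeps, objective_path=fvals[:n_sweeps])


def lambda_path(r_tilde: np.ndarray, config: Optional[TrainingConfig] = None) -> np.ndarray:
    """Log-spaced lambda grid from lambda_max = max |r| down to its ratio."""
    config = config or TrainingConfig()
    r = np.asarray(r_tilde, dtype=float)
    if r.shape[0] == 0:
        raise ValueError("empty marginal-effect vector")
    lam_max = float(np.max(np.abs(r)))
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def squared_correlation(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either side has zero variance."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.std() == 0.0 or obs.std() == 0.0:
        return 0.0
    c = np.corrcoef(pred, obs)[0, 1]
    return float(c * c)


def _standardize_genotypes(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns contribute nothing to prediction
    return (x - mu) / sd


def _grid_specs(family: str, lams: np.ndarray, config: TrainingConfig):
    thetas = config.theta_grid
    if family == "lasso":
        combos = [(0.0, 1.0)]
    elif family == "mcp":
        combos = [(config.gamma_mcp, 1.0)]
    elif family == "scad":
        combos = [(config.gamma_scad, 1.0)]
    elif family == "elastic_net":
        combos = [(0.0, a) for a in config.alpha_grid]
    else:  # mnet
        combos = [(config.gamma_mcp, a) for a in config.alpha_grid]
    for gam, alp in combos:
        for theta in thetas:
            yield gam, alp, theta


def fit_family(
    family: str,
    r_tilde: np.ndarray,
    R_tilde,
    config: TrainingConfig,
) -> list[tuple[PenaltySpec, np.ndarray, bool]]:
    """Fit the full (lambda, theta[, gamma, alpha]) grid for one family.

    Lambda paths are traversed from lambda_max downward with warm starts.
    Returns (spec, weights, converged) per grid point.
    """
    lams = lambda_path(r_tilde, config)
    out = []
    for gam, alp, theta in _grid_specs(family, lams, config):
        w = np.zeros(r_tilde.shape[0])
        for lam in lams:
            spec = PenaltySpec(family=family, lam=float(lam), gamma=gam, alpha=alp, theta=theta)
            res = coordinate_descent(r_tilde, R_tilde, spec, config, w0=w)
            w = res.w
            out.append((spec, w.copy(), res.converged))
    return out


def fit_gene(
    table: EqtlSummaryTable,
    R_tilde,
    tuning_panel: tuple[np.ndarray, np.ndarray],
    config: Optional[TrainingConfig] = None,
    r_tilde: Optional[np.ndarray] = None,
) -> list[WeightModel]:
    """Fit all penalty families and pick the best grid point per family.

    ``tuning_panel`` is ``(genotypes, expression)`` for an individual-level
    tuning cohort; expression is assumed covariate-residualized.  Selection
    maximizes the squared correlation between predicted and observed tuning
    expression; ties prefer the sparsest model, then the largest lambda.
    ``r_tilde`` overrides the z-score-based marginal effects (used for
    individual-level oracle fits).
    """
    config = config or TrainingConfig()
    x_tune, e_tune = tuning_panel
    x_tune = np.asarray(x_tune, dtype=float)
    e_tune = np.asarray(e_tune, dtype=float)
    if x_tune.shape[0] < 10:
        raise ValueError(f"tuning set has {x_tune.shape[0]} samples; need >= 10")
    if x_tune.shape[1] != len(table):
        raise ValueError("tuning genotype SNP count does not match summary table")
    if r_tilde is None:
        r_tilde = standardized_marginal_effects(table)
    xs = _standardize_genotypes(x_tune)
    models = []
    for family in config.families:
        fits = fit_family(family, r_tilde, R_tilde, config)
        W = np.stack([w for _, w, _ in fits], axis=1)  # p x n_grid
        preds = xs @ W
        best = None  # (r2, -nnz, lam, idx)
        for k, (spec, w, conv) in enumerate(fits):
            r2 = squared_correlation(preds[:, k], e_tune) if np.any(w) else 0.0
            key = (r2, -int(np.count_nonzero(w)), spec.lam)
            if best is None or key > best[0]:
                best = (key, k)
        k = best[1]
        spec, w, conv = fits[k]
        models.append(
            WeightModel(
                gene_id=table.gene_id,
                snp_ids=table.snp_ids,
                w_hat=w,
                penalty=spec,
                r2_tuning=best[0][0],
                converged=conv,
            )
        )
    return models


def validate_models(
    models: Sequence[WeightModel],
    testing_panel: tuple[np.ndarray, np.ndarray],
    r2_min: float = 0.005,
) -> list[WeightModel]:
    """Score models on a held-out cohort and keep those with R^2 >= r2_min.

    The boundary is inclusive: a model at exactly ``r2_min`` is retained.
    """
    x_test, e_test = testing_panel
    xs = _standardize_genotypes(np.asarray(x_test, dtype=float))
    e_test = np.asarray(e_test, dtype=float)
    kept = []
    for m in models:
        r2 = squared_correlation(xs @ m.w_hat, e_test)
        m.r2_testing = r2
        if r2 >= r2_min:
            kept.append(m)
    return kept


def cramer_r2_threshold(p_nonzero: int, n: int, alpha: float) -> float:
    """Null rejection boundary for multiple-regression R^2.

    Under H0 of no association, R^2 from an ordinary regression of n
    observations on p predictors follows Beta((p-1)/2, (n-p)/2); the
    returned value is that distribution's (1 - alpha) quantile, i.e. the
    lower edge of the rejection region for R^2.
    """
    if not (n > p_nonzero >= 2):
        raise ValueError(f"need n > p >= 2, got p={p_nonzero}, n={n}")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    a = (p_nonzero - 1) / 2.0
    b = (n - p_nonzero) / 2.0
    return float(stats.beta.ppf(1.0 - alpha, a, b))
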