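"""Single-season site-occupancy models with imperfect detection.

Maximum-likelihood estimation of occupancy probability (psi) and
per-occasion detection probability (p), both on logit links, with
covariates on either.  The per-site likelihood is the standard two-term
mixture over the latent occupied/unoccupied state:

    L_i = psi_i * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi_i) * I[all observed y_ij = 0]

with missing occasions dropped from the product.  A detection-only
variant fixes psi to one (used for "occupied sites" analyses where the
species is known present), leaving a product-Bernoulli likelihood for p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)
from statsmodels.tools.numdiff import approx_hess1

from .data import CovariateBundle, DetectionHistory

__all__ = ["OccupancySpec", "OccupancyFit", "occupancy_negloglik",
           "fit_occupancy", "predict_occupancy", "predict_detection"]

_BOUNDARY_ETA = 10.0  # |logit| beyond this is effectively 0/1


@dataclass(frozen=True)
class OccupancySpec:
    """Which covariates act on occupancy (psi) and detection (p).

    Empty lists mean intercept-only.  ``fix_psi_to_one`` switches to the
    detection-only model (no psi parameters at all).
    """

    psi_covariates: tuple = ()
    p_covariates: tuple = ()
    fix_psi_to_one: bool = False

    def __post_init__(self) -> None:
        for group in (self.psi_covariates, self.p_covariates):
            if len(set(group)) != len(group):
                raise ValueError("duplicate covariate in model specification")
        if self.fix_psi_to_one and self.psi_covariates:
            raise ValueError("psi covariates are meaningless with psi fixed to 1")

    @property
    def n_beta(self) -> int:
        return 0 if self.fix_psi_to_one else 1 + len(self.psi_covariates)

    @property
    def n_alpha(self) -> int:
        return 1 + len(self.p_covariates)

    @property
    def n_params(self) -> int:
        return self.n_beta + self.n_alpha

    def name(self) -> str:
        psi = "1" if self.fix_psi_to_one else " + ".join(self.psi_covariates) or "."
        p = " + ".join(self.p_covariates) or "."
        return f"psi({psi}), p({p})"


def _designs(spec: OccupancySpec, history: DetectionHistory,
             bundle: CovariateBundle):
    """Build (X_psi: n x n_beta, X_p: n x J x n_alpha) design arrays."""
    n, J = history.n_sites, history.n_occasions
    if spec.fix_psi_to_one:
        X_psi = np.zeros((n, 0))
    else:
        cols = [np.ones(n)]
        for name in spec.psi_covariates:
            if not bundle.is_site_covariate(name):
                raise KeyError(f"occupancy covariate {name!r} must be site-level")
            cols.append(bundle.site_table[name].to_numpy(dtype=float))
        X_psi = np.column_stack(cols)
    layers = [np.ones((n, J))]
    for name in spec.p_covariates:
        layers.append(bundle.obs_matrix(name, J))
    X_p = np.stack(layers, axis=2)
    for X in (X_psi, X_p):
        if X.size and not np.isfinite(np.nan_to_num(X, nan=0.0)).all():
            raise ValueError("non-finite covariate values in design")
    return X_psi, X_p


def _site_logliks(params, spec, history, bundle, designs=None):
    X_psi, X_p = designs if designs is not None else _designs(spec, history, bundle)
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(f"expected {spec.n_params} parameters, got {params.size}")
    beta, alpha = params[:spec.n_beta], params[spec.n_beta:]
    y = history.y
    obs = ~np.isnan(y)
    eta_p = X_p @ alpha
    # Bernoulli log-pmf per occasion, 0 where missing
    with np.errstate(over="ignore"):
        logp = -np.logaddexp(0.0, -eta_p)
        log1mp = -np.logaddexp(0.0, eta_p)
    occ_ll = np.where(obs, np.where(np.nan_to_num(y) > 0, logp, log1mp), 0.0)
    cond_ll = occ_ll.sum(axis=1)  # log P(history | occupied)
    if spec.fix_psi_to_one:
        return cond_ll
    eta_psi = X_psi @ beta
    log_psi = -np.logaddexp(0.0, -eta_psi)
    log_1mpsi = -np.logaddexp(0.0, eta_psi)
    all_zero = (np.nan_to_num(y) * obs).sum(axis=1) == 0
    ll = np.where(
        all_zero,
        np.logaddexp(log_psi + cond_ll, log_1mpsi),
        log_psi + cond_ll,
    )
    return ll


def occupancy_negloglik(params, spec: OccupancySpec, history: DetectionHistory,
                        bundle: CovariateBundle) -> float:
    """Negative log-likelihood of the occupancy model at ``params``.

    ``params`` stacks the occupancy coefficients (logit scale, intercept
    first; absent when psi is fixed to one) followed by the detection
    coefficients.
    """
    return float(-_site_logliks(params, spec, history, bundle).sum())


@dataclass
class OccupancyFit:
    """A fitted occupancy model: coefficients, likelihood and curvature."""

    spec: OccupancySpec
    beta: np.ndarray
    alpha: np.ndarray
    loglik: float
    K: int
    n_sites: int
    vcov: np.ndarray | None
    converged: bool
    boundary: bool = False
    _bundle_means: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])

    def summary(self) -> dict:
        """JSON-serializable fit report."""
        se = (np.sqrt(np.diag(self.vcov)).tolist()
              if self.vcov is not None else None)
        return {
            "model": self.spec.name(),
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "se": se,
            "loglik": self.loglik,
            "K": self.K,
            "n_sites": self.n_sites,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _multistart_points(n_params: int, n_beta: int):
    """Deterministic starts: zeros, then +/-1 on each block intercept."""
    pts = [np.zeros(n_params)]
    intercept_idx = ([0] if n_beta else []) + [n_beta]
    for idx in intercept_idx:
        for delta in (1.0, -1.0):
            p = np.zeros(n_params)
            p[idx] = delta
            pts.append(p)
    return pts[:5]


def _minimize_multistart(nll, n_params, n_beta, gtol=1e-8, n_starts=5):
    best = None
    for x0 in _multistart_points(n_params, n_beta)[:max(1, n_starts)]:
        res = optimize.minimize(nll, x0, method="BFGS",
                                options={"gtol": gtol, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return best


def fit_occupancy(spec: OccupancySpec, history: DetectionHistory,
                  bundle: CovariateBundle, gtol: float = 1e-8,
                  n_starts: int = 5) -> OccupancyFit:
    """Maximum-likelihood fit with deterministic multistart BFGS.

    The coefficient covariance is the inverse of the numerically
    differentiated observed information; when that matrix is singular
    (typically at boundary estimates) ``vcov`` is None and intervals are
    reported as unavailable rather than fabricated.
    """
    designs = _designs(spec, history, bundle)

    def nll(params):
        return float(-_site_logliks(params, spec, history, bundle, designs).sum())

    res = _minimize_multistart(nll, spec.n_params, spec.n_beta, gtol, n_starts)
    params = res.x
    beta, alpha = params[:spec.n_beta], params[spec.n_beta:]
    boundary = bool((np.abs(params) > _BOUNDARY_ETA).any())
    vcov = None
    if not boundary:
        try:
            hess = approx_hess1(params, nll)
            vcov = np.linalg.inv(hess)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
                vcov = None
        except np.linalg.LinAlgError:
            vcov = None
    means = {c: 0.0 for c in spec.psi_covariates + spec.p_covariates}
    return OccupancyFit(
        spec=spec, beta=beta, alpha=alpha, loglik=float(-res.fun),
        K=spec.n_params, n_sites=history.n_sites, vcov=vcov,
        converged=bool(res.success or np.linalg.norm(res.jac) < 1e-4),
        boundary=boundary, _bundle_means=means,
    )


def _linear_ci(eta: float, var: float | None, z: float):
    if var is None or not np.isfinite(var):
        return expit(eta), (np.nan, np.nan)
    half = z * np.sqrt(max(var, 0.0))
    return expit(eta), (float(expit(eta - half)), float(expit(eta + half)))


def predict_occupancy(fit: OccupancyFit, covariate_values: dict | None = None,
                      z: float = 1.96):
    """Occupancy probability at given (standardized) covariate values.

    Defaults to covariate means, i.e. zeros on the standardized scale.
    The interval is delta-method on the logit scale, back-transformed, so
    its endpoints always lie in (0, 1); ``z = 0`` collapses it to the
    point estimate.
    """
    if fit.spec.fix_psi_to_one:
        return 1.0, (1.0, 1.0)
    covariate_values = covariate_values or {}
    x = np.ones(fit.spec.n_beta)
    for i, name in enumerate(fit.spec.psi_covariates, start=1):
        x[i] = covariate_values.get(name, 0.0)
    eta = float(x @ fit.beta)
    var = None
    if fit.vcov is not None:
        V = fit.vcov[:fit.spec.n_beta, :fit.spec.n_beta]
        var = float(x @ V @ x)
    est, ci = _linear_ci(eta, var, z)
    return float(est), ci


def predict_detection(fit: OccupancyFit, covariate_grid=None, z: float = 1.96):
    """Detection probability over a covariate grid (others at their means).

    ``covariate_grid`` is a mapping name -> array (or a DataFrame); with
    None, returns the single estimate at covariate means.  Returns arrays
    ``(p, lower, upper)``.
    """
    import pandas as pd

    if covariate_grid is None:
        covariate_grid = pd.DataFrame(index=[0])
    grid = pd.DataFrame(covariate_grid)
    m = len(grid)
    X = np.ones((m, fit.spec.n_alpha))
    for i, name in enumerate(fit.spec.p_covariates, start=1):
        if name in grid.columns:
            X[:, i] = grid[name].to_numpy(dtype=float)
        else:
            X[:, i] = 0.0
    eta = X @ fit.alpha
    p = expit(eta)
    if fit.vcov is not None:
        Va = fit.vcov[fit.spec.n_beta:, fit.spec.n_beta:]
        var = np.einsum("ij,jk,ik->i", X, Va, X)
        half = z * np.sqrt(np.clip(var, 0.0, None))
        lower, upper = expit(eta - half), expit(eta + half)
    else:
        lower = upper = np.full(m, np.nan)
    return p, lower, upper
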