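"""AICc model selection: candidate enumeration, ranking, weights, averaging.

The two-stage protocol first screens observation (detection) covariates
with the state model held constant (occupancy fixed to one, or abundance
intercept-only), then crosses the influential observation set with site
covariates.  Candidate sets enumerate every covariate subset up to a
size cap (3 observation covariates, 2 site covariates).  Models are
ranked by AICc; Akaike weights are computed over the full candidate set,
and model-averaged predictions combine per-model estimates on the link
scale with the Burnham-Anderson unconditional variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["CandidateSet", "RankedModels", "enumerate_candidates", "aicc",
           "akaike_weights", "rank_models", "top_set", "model_average"]

MAX_OBS_COVS = 3
MAX_SITE_COVS = 2


def aicc(loglik: float, K: int, n: int) -> float:
    """Akaike information criterion corrected for small samples:
    AICc = -2 LL + 2K + 2K(K+1)/(n - K - 1).  Requires n > K + 1."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(-delta/2), normalized; invariant to adding a constant to all values."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass(frozen=True)
class CandidateSet:
    """Enumerated model specifications for one selection stage."""

    stage: str  # "observation_stage" | "full_stage"
    specs: tuple

    def __len__(self) -> int:
        return len(self.specs)


def enumerate_candidates(site_covs, obs_covs, stage: str, base_spec_factory,
                         max_obs: int = MAX_OBS_COVS,
                         max_site: int = MAX_SITE_COVS) -> CandidateSet:
    """Enumerate covariate subsets for one stage of the two-stage protocol.

    ``base_spec_factory(psi_covs, p_covs)`` builds a model spec from the
    chosen subsets.  Observation stage: all subsets of ``obs_covs`` of
    size 0..max_obs with the state structure held constant (empty site
    set).  Full stage: all subsets of ``site_covs`` of size 0..max_site
    crossed with the fixed observation set ``obs_covs``.
    """
    specs = []
    if stage == "observation_stage":
        for k in range(min(max_obs, len(obs_covs)) + 1):
            for combo in combinations(obs_covs, k):
                specs.append(base_spec_factory((), combo))
    elif stage == "full_stage":
        for k in range(min(max_site, len(site_covs)) + 1):
            for combo in combinations(site_covs, k):
                specs.append(base_spec_factory(combo, tuple(obs_covs)))
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return CandidateSet(stage, tuple(specs))


@dataclass
class RankedModels:
    """AICc-ranked candidate models with weights over the full set.

    Rows are sorted ascending by AICc, ties broken by smaller K then
    model name; the best model has delta 0 and weights sum to 1.
    """

    table: pd.DataFrame  # columns: model, K, AICc, delta, weight, loglik
    fits: list           # aligned with table rows

    @classmethod
    def from_fits(cls, fits, n: int | None = None) -> "RankedModels":
        import warnings

        rows = []
        small_n = False
        for f in fits:
            n_eff = n if n is not None else f.n_sites
            if n_eff > f.K + 1:
                crit = aicc(f.loglik, f.K, n_eff)
            else:  # AICc undefined: fall back to plain AIC, flagged
                crit = -2.0 * f.loglik + 2.0 * f.K
                small_n = True
            rows.append((f.spec.name(), f.K, crit, f.loglik))
        if small_n:
            warnings.warn("sample size too small for AICc on some models; "
                          "those rows carry plain AIC")
        df = pd.DataFrame(rows, columns=["model", "K", "AICc", "loglik"])
        df["weight"] = akaike_weights(df["AICc"].to_numpy())
        df["delta"] = df["AICc"] - df["AICc"].min()
        order = np.lexsort((df["model"].to_numpy(), df["K"].to_numpy(),
                            df["AICc"].to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
        df = df[["model", "K", "AICc", "delta", "weight", "loglik"]]
        return cls(df, [fits[i] for i in order])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def best(self):
        return self.fits[0]

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={
            "delta": "dAICc", "weight": "AICc_wt", "loglik": "LL"})
        out.to_csv(path, index=False)


def rank_models(fits, n: int | None = None) -> RankedModels:
    """Rank fitted models by AICc with effective sample size ``n``
    (default: each fit's site count)."""
    return RankedModels.from_fits(fits, n=n)


def top_set(ranked: RankedModels, delta_threshold: float = 4.0) -> RankedModels:
    """Models within ``delta_threshold`` AICc of the best (never empty)."""
    keep = ranked.table["delta"] <= delta_threshold
    idx = np.flatnonzero(keep.to_numpy())
    return RankedModels(ranked.table.loc[keep].reset_index(drop=True),
                        [ranked.fits[i] for i in idx])


def model_average(ranked: RankedModels, predict_fn, link: str = "logit",
                  z: float = 1.96):
    """Model-averaged prediction with unconditional variance.

    ``predict_fn(fit)`` returns ``(eta, var)`` on the link scale for one
    model.  Unconverged models are dropped with weight renormalization
    and a warning.  The average and the Burnham-Anderson variance

        var_u = [ sum_m w_m sqrt(var_m + (eta_m - eta_bar)^2) ]^2

    are combined on the link scale, then back-transformed (logit -> to
    probability, log -> exponential, identity -> unchanged).
    """
    import warnings

    etas, variances, weights = [], [], []
    for fit, w in zip(ranked.fits, ranked.table["weight"].to_numpy()):
        if not getattr(fit, "converged", True):
            warnings.warn(f"excluding unconverged model {fit.spec.name()}")
            continue
        eta, var = predict_fn(fit)
        etas.append(eta)
        variances.append(var if var is not None else np.nan)
        weights.append(w)
    if not etas:
        raise ValueError("no converged models to average")
    etas = np.asarray(etas, dtype=float)
    variances = np.asarray(variances, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    eta_bar = float(w @ etas)
    if np.isnan(variances).any():
        half = np.nan
    else:
        se_u = float(w @ np.sqrt(variances + (etas - eta_bar) ** 2))
        half = z * se_u
    back = {"logit": expit, "log": np.exp, "identity": lambda x: x}[link]
    point = float(back(eta_bar))
    if np.isnan(half):
        return point, (np.nan, np.nan)
    return point, (float(back(eta_bar - half)), float(back(eta_bar + half)))
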