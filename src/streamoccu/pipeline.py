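"""End-to-end chained analysis for a paired VES / eDNA study.

Stages mirror the analysis protocol:

1. VES occupancy — observation covariates screened on known-occupied
   sites with occupancy fixed to one, then site covariates crossed with
   the influential observation set over all sites.
2. Abundance — zero-inflated N-mixture on counts at VES-occupied sites,
   same two-stage screen; model-averaged expected abundances divided by
   stream volume give per-site turtle densities.
3. eDNA occupancy — all-sites model with the influential VES site
   covariates held fixed while eDNA observation covariates are screened;
   plus an occupied-sites (OS) detection-only model (psi = 1) on the
   union of VES- and eDNA-positive sites, with estimated density as an
   extra observation covariate.
4. Summary — naive and model-averaged occupancy/detection per method,
   a g-test of method agreement, and replicate-planning numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountHistory, CovariateBundle, DetectionHistory, \
    naive_occupancy
from .nmixture import NMixtureSpec, density_table as _density_frame, \
    fit_nmixture, site_density
from .occupancy import OccupancySpec, fit_occupancy
from .planning import cumulative_detection, min_replicates
from .selection import enumerate_candidates, model_average, rank_models, \
    top_set
from .stats import ContingencyTable, g_test, proportion_interval

__all__ = ["PipelineConfig", "PipelineResult", "run_ves_stage",
           "run_abundance_stage", "run_edna_stage", "summarize", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """Covariate roles and knobs for the chained analysis."""

    ves_site_covariates: tuple = ("embed", "mf", "pavement", "ag", "forest")
    ves_obs_covariates: tuple = ("surveyor", "time", "depth", "temp", "clarity")
    edna_obs_covariates: tuple = ("drain", "arain", "temp_edna", "mf")
    edna_site_covariates: tuple | None = None  # None -> take from VES best model
    max_obs_covariates: int = 3
    max_site_covariates: int = 2
    delta_threshold: float = 4.0
    z: float = 1.96
    n_starts: int = 5
    gtol: float = 1e-8
    target_confidence: float = 0.95
    compute_vcov: bool = True


@dataclass
class StageResult:
    ranked: object
    averaged_psi: tuple | None
    averaged_p: tuple
    influential_obs: tuple
    stage1_ranked: object | None = None


@dataclass
class PipelineResult:
    ves: StageResult
    abundance: object
    density: pd.DataFrame
    edna_all: StageResult
    edna_os: StageResult
    summary: dict


def _psi_prediction(fit):
    eta = float(fit.beta[0])
    var = float(fit.vcov[0, 0]) if fit.vcov is not None else None
    return eta, var


def _p_prediction(fit):
    i = fit.spec.n_beta
    eta = float(fit.alpha[0])
    var = float(fit.vcov[i, i]) if fit.vcov is not None else None
    return eta, var


def run_ves_stage(config: PipelineConfig, detections: DetectionHistory,
                  bundle: CovariateBundle) -> StageResult:
    """Two-stage VES occupancy selection with model-averaged estimates."""
    occupied = detections.detected_sites()
    sub_hist = detections.subset(occupied)
    sub_bundle = bundle.subset(occupied)

    def os_spec(site_covs, obs_covs):
        return OccupancySpec((), obs_covs, fix_psi_to_one=True)

    stage1 = enumerate_candidates((), config.ves_obs_covariates,
                                  "observation_stage", os_spec,
                                  max_obs=config.max_obs_covariates)
    fits1 = [fit_occupancy(s, sub_hist, sub_bundle, gtol=config.gtol, n_starts=config.n_starts) for s in stage1.specs]
    ranked1 = rank_models(fits1)
    influential = ranked1.best.spec.p_covariates

    def full_spec(site_covs, obs_covs):
        return OccupancySpec(site_covs, obs_covs)

    stage2 = enumerate_candidates(config.ves_site_covariates, influential,
                                  "full_stage", full_spec,
                                  max_site=config.max_site_covariates)
    fits2 = [fit_occupancy(s, detections, bundle, gtol=config.gtol, n_starts=config.n_starts) for s in stage2.specs]
    ranked2 = rank_models(fits2)
    psi = model_average(ranked2, _psi_prediction, z=config.z)
    p = model_average(ranked2, _p_prediction, z=config.z)
    return StageResult(ranked2, psi, p, influential, ranked1)


def run_abundance_stage(config: PipelineConfig, counts: CountHistory,
                        bundle: CovariateBundle, occupied_mask: np.ndarray,
                        volumes: dict):
    """Two-stage N-mixture selection on occupied-site counts, then
    model-averaged per-site density over *all* sites in ``bundle``
    (density at sites outside the fitted subset is a covariate-based
    prediction).  Returns ``(RankedModels, density DataFrame)``."""
    occupied_mask = np.asarray(occupied_mask, bool)
    if not occupied_mask.any():
        raise ValueError("no occupied sites for the abundance stage")
    sub_counts = counts.subset(occupied_mask)
    sub_bundle = bundle.subset(occupied_mask)

    def obs_spec(site_covs, obs_covs):
        return NMixtureSpec((), obs_covs)

    stage1 = enumerate_candidates((), config.ves_obs_covariates,
                                  "observation_stage", obs_spec,
                                  max_obs=config.max_obs_covariates)
    fits1 = [fit_nmixture(s, sub_counts, sub_bundle, gtol=config.gtol, n_starts=config.n_starts) for s in stage1.specs]
    ranked1 = rank_models(fits1)
    influential = ranked1.best.spec.p_covariates

    def full_spec(site_covs, obs_covs):
        return NMixtureSpec(site_covs, obs_covs)

    stage2 = enumerate_candidates(config.ves_site_covariates, influential,
                                  "full_stage", full_spec,
                                  max_site=config.max_site_covariates)
    fits2 = [fit_nmixture(s, sub_counts, sub_bundle, gtol=config.gtol, n_starts=config.n_starts) for s in stage2.specs]
    ranked2 = rank_models(fits2)

    estimates = site_density(ranked2.fits, ranked2.table["weight"].to_numpy(),
                             bundle, volumes)
    dens = _density_frame(estimates)
    dens["fitted"] = [s in set(sub_counts.site_ids) for s in dens["site"]]
    ranked2.stage1 = ranked1
    return ranked2, dens


def run_edna_stage(config: PipelineConfig, detections: DetectionHistory,
                   bundle: CovariateBundle, ves_site_covariates: tuple,
                   density: pd.DataFrame, occupied_mask: np.ndarray):
    """All-sites eDNA occupancy plus the occupied-sites detection model.

    The all-sites candidates share the VES-derived site covariates and
    screen eDNA observation covariates; the OS model fixes psi = 1 on
    the occupied subset (VES- or eDNA-positive) and adds estimated
    turtle density — standardized within that subset — as an
    observation covariate.  Returns ``(all-sites StageResult,
    OS StageResult)``.
    """
    site_covs = (config.edna_site_covariates
                 if config.edna_site_covariates is not None
                 else tuple(ves_site_covariates))

    def all_spec(site_covs_, obs_covs):
        return OccupancySpec(tuple(site_covs), obs_covs)

    cands = enumerate_candidates((), config.edna_obs_covariates,
                                 "observation_stage", all_spec,
                                 max_obs=config.max_obs_covariates)
    fits = [fit_occupancy(s, detections, bundle, gtol=config.gtol, n_starts=config.n_starts) for s in cands.specs]
    ranked_all = rank_models(fits)
    psi_all = model_average(ranked_all, _psi_prediction, z=config.z)
    p_all = model_average(ranked_all, _p_prediction, z=config.z)
    all_result = StageResult(ranked_all, psi_all, p_all,
                             ranked_all.best.spec.p_covariates)

    occupied_mask = np.asarray(occupied_mask, bool)
    sub_hist = detections.subset(occupied_mask)
    sub_bundle = bundle.subset(occupied_mask)
    dens = density.set_index("site").loc[sub_bundle.site_ids, "density"]
    vals = dens.to_numpy(dtype=float)
    sd = vals.std(ddof=1)
    vals_std = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
    R = sub_hist.n_occasions
    sub_bundle.obs_tables["density"] = pd.DataFrame(
        np.repeat(vals_std[:, None], R, axis=1),
        index=pd.Index(sub_bundle.site_ids, name="site"),
        columns=[f"occ{j + 1}" for j in range(R)])

    def os_spec(site_covs_, obs_covs):
        return OccupancySpec((), obs_covs, fix_psi_to_one=True)

    os_covs = tuple(config.edna_obs_covariates) + ("density",)
    cands_os = enumerate_candidates((), os_covs, "observation_stage", os_spec,
                                    max_obs=config.max_obs_covariates)
    fits_os = [fit_occupancy(s, sub_hist, sub_bundle, gtol=config.gtol, n_starts=config.n_starts) for s in cands_os.specs]
    ranked_os = rank_models(fits_os)
    p_os = model_average(ranked_os, _p_prediction, z=config.z)
    os_result = StageResult(ranked_os, None, p_os,
                            ranked_os.best.spec.p_covariates)
    return all_result, os_result


def summarize(config: PipelineConfig, ves_hist: DetectionHistory,
              edna_hist: DetectionHistory, ves_stage: StageResult,
              edna_all: StageResult, edna_os: StageResult) -> dict:
    """Cross-method summary: naive and model-averaged estimates, the
    agreement g-test on the 2x2 site cross-classification, and the
    replicate counts needed for the target cumulative confidence."""
    k_ves, n, naive_ves = naive_occupancy(ves_hist)
    k_edna, _, naive_edna = naive_occupancy(edna_hist)
    ves_pos = ves_hist.detected_sites()
    edna_pos = edna_hist.detected_sites()
    table = ContingencyTable(np.array([
        [int((ves_pos & edna_pos).sum()), int((ves_pos & ~edna_pos).sum())],
        [int((~ves_pos & edna_pos).sum()), int((~ves_pos & ~edna_pos).sum())],
    ]), ("ves+", "ves-"), ("edna+", "edna-"))
    try:
        G, df, pval = g_test(table)
        gres = {"G": G, "df": df, "p_value": pval}
    except ValueError:
        gres = None

    def planning(p):
        if not 0 < p < 1:
            return None
        return {"min_replicates": min_replicates(p, config.target_confidence),
                "p_star_3": cumulative_detection(p, 3)}

    p_os_point = edna_os.averaged_p[0]
    return {
        "ves": {
            "naive_occupancy": proportion_interval(k_ves, n, z=1.0),
            "occupancy": ves_stage.averaged_psi,
            "detection": ves_stage.averaged_p,
        },
        "edna": {
            "naive_occupancy": proportion_interval(k_edna, n, z=1.0),
            "occupancy": edna_all.averaged_psi,
            "detection": edna_all.averaged_p,
            "detection_os": edna_os.averaged_p,
        },
        "agreement_g_test": gres,
        "planning": {"ves": planning(ves_stage.averaged_p[0]),
                     "edna": planning(p_os_point)},
    }


def run_all(config: PipelineConfig, ves_hist: DetectionHistory,
            counts: CountHistory, edna_hist: DetectionHistory,
            bundle: CovariateBundle, volumes: dict) -> PipelineResult:
    """Run the full chained analysis; deterministic given its inputs.

    All covariates not yet carrying a recorded scaling are standardized
    first, so coefficients and predictions refer to covariate means.
    """
    from .data import standardize

    bundle = standardize(bundle)
    ves_stage = run_ves_stage(config, ves_hist, bundle)
    ves_occupied = ves_hist.detected_sites()
    abundance_ranked, density = run_abundance_stage(
        config, counts, bundle, ves_occupied, volumes)
    best_site_covs = ves_stage.ranked.best.spec.psi_covariates
    occupied_union = ves_occupied | edna_hist.detected_sites()
    edna_all, edna_os = run_edna_stage(
        config, edna_hist, bundle, best_site_covs, density, occupied_union)
    summary = summarize(config, ves_hist, edna_hist, ves_stage,
                        edna_all, edna_os)
    return PipelineResult(ves_stage, abundance_ranked, density,
                          edna_all, edna_os, summary)
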