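"""Core data containers and delimited-file I/O for repeated-survey data.

The containers hold site-by-occasion detection/nondetection matrices
(visual-encounter surveys or eDNA filter replicates), repeated counts,
and site- and observation-level covariates.  Missing surveys are carried
as NaN internally — never 0, which is a valid observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "DetectionHistory",
    "CountHistory",
    "CovariateBundle",
    "SurveyDesign",
    "read_survey_tables",
    "write_survey_tables",
    "standardize",
    "spearman_screen",
    "naive_occupancy",
]

_NA_TOKENS = {"", "NA", "NaN", "nan", "na"}


@dataclass(frozen=True)
class SurveyDesign:
    """Shape of a repeated survey: sites x occasions, and what a replicate is."""

    n_sites: int
    n_occasions: int
    replicate_kind: str = "ves_survey"  # or "edna_filter"

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_occasions < 1:
            raise ValueError("n_sites and n_occasions must be >= 1")
        if self.replicate_kind not in ("ves_survey", "edna_filter"):
            raise ValueError(f"unknown replicate_kind {self.replicate_kind!r}")


@dataclass
class DetectionHistory:
    """Site x occasion binary detection matrix with missing-value support.

    ``y`` is a float array with entries in {0.0, 1.0, NaN}; NaN marks an
    occasion that was not surveyed.  Every site must have at least one
    non-missing occasion.
    """

    site_ids: list
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-dimensional (sites x occasions)")
        if len(self.site_ids) != self.y.shape[0]:
            raise ValueError("site_ids length must match number of rows of y")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site_ids must be unique")
        obs = self.y[~np.isnan(self.y)]
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("non-missing detection entries must be 0 or 1")
        if np.isnan(self.y).all(axis=1).any():
            raise ValueError("every site needs at least one non-missing occasion")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    def detected_sites(self) -> np.ndarray:
        """Boolean mask of sites with >= 1 detection on a non-missing occasion."""
        return np.nansum(self.y, axis=1) > 0

    def subset(self, mask: np.ndarray) -> "DetectionHistory":
        ids = [s for s, m in zip(self.site_ids, mask) if m]
        return DetectionHistory(ids, self.y[np.asarray(mask, bool)])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"occ{j + 1}" for j in range(self.n_occasions)]
        df = pd.DataFrame(self.y, columns=cols)
        df.insert(0, "site", self.site_ids)
        return df


@dataclass
class CountHistory:
    """Site x occasion matrix of individuals counted (nonnegative ints or NaN)."""

    site_ids: list
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 2:
            raise ValueError("c must be 2-dimensional")
        if len(self.site_ids) != self.c.shape[0]:
            raise ValueError("site_ids length must match rows of c")
        obs = self.c[~np.isnan(self.c)]
        if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
            raise ValueError("counts must be nonnegative integers")

    @property
    def n_sites(self) -> int:
        return self.c.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.c.shape[1]

    def subset(self, mask: np.ndarray) -> "CountHistory":
        ids = [s for s, m in zip(self.site_ids, mask) if m]
        return CountHistory(ids, self.c[np.asarray(mask, bool)])

    def to_detections(self) -> DetectionHistory:
        y = np.where(np.isnan(self.c), np.nan, (self.c > 0).astype(float))
        return DetectionHistory(list(self.site_ids), y)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"occ{j + 1}" for j in range(self.n_occasions)]
        df = pd.DataFrame(self.c, columns=cols)
        df.insert(0, "site", self.site_ids)
        return df


@dataclass
class CovariateBundle:
    """Site-level and observation-level covariates with standardization state.

    ``site_table`` is indexed by site id; ``obs_tables`` maps a covariate
    name to a site x occasion DataFrame (same site index).  ``scaling``
    records (mean, sd) per column iff :func:`standardize` was applied, so
    the transform is invertible.
    """

    site_table: pd.DataFrame
    obs_tables: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)

    @property
    def site_ids(self) -> list:
        return list(self.site_table.index)

    def covariate_names(self) -> list:
        return list(self.site_table.columns) + list(self.obs_tables)

    def is_site_covariate(self, name: str) -> bool:
        return name in self.site_table.columns

    def obs_matrix(self, name: str, n_occasions: int) -> np.ndarray:
        """Covariate as a site x occasion array; site-level columns broadcast."""
        if name in self.obs_tables:
            m = self.obs_tables[name].to_numpy(dtype=float)
            if m.shape[1] != n_occasions:
                raise ValueError(
                    f"obs covariate {name!r} has {m.shape[1]} occasions, "
                    f"expected {n_occasions}"
                )
            return m
        if name in self.site_table.columns:
            col = self.site_table[name].to_numpy(dtype=float)
            return np.repeat(col[:, None], n_occasions, axis=1)
        raise KeyError(f"unknown covariate {name!r}")

    def subset(self, mask: np.ndarray) -> "CovariateBundle":
        mask = np.asarray(mask, bool)
        return CovariateBundle(
            self.site_table.loc[mask],
            {k: v.loc[mask] for k, v in self.obs_tables.items()},
            dict(self.scaling),
        )


def _parse_matrix_csv(path, value_check) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path, dtype={0: str}, na_values=list(_NA_TOKENS), keep_default_na=False)
    site_col = df.columns[0]
    sites = df[site_col].tolist()
    mat = df.drop(columns=[site_col]).to_numpy(dtype=float)
    value_check(mat)
    return sites, mat


def read_survey_tables(detection_path, covariates_path, counts_path=None,
                       obs_covariate_paths=None, obs_long_path=None):
    """Read aligned detection, (optional) count and covariate CSV tables.

    All files carry a header row with the site identifier in the first
    column.  Sites are aligned by identifier; the detection file's order
    wins.  Observation covariates come either as ``obs_covariate_paths``
    (covariate name -> wide site x occasion CSV) or as ``obs_long_path``,
    a single long-format CSV with columns (site, occasion, covariate,
    value).  Returns ``(DetectionHistory, CountHistory | None,
    CovariateBundle)``.
    """

    def check_binary(mat):
        obs = mat[~np.isnan(mat)]
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError(f"non-binary detection value in {detection_path}")

    sites, y = _parse_matrix_csv(detection_path, check_binary)
    hist = DetectionHistory(sites, y)

    cov_df = pd.read_csv(covariates_path, dtype={0: str},
                         na_values=list(_NA_TOKENS), keep_default_na=False)
    cov_df = cov_df.set_index(cov_df.columns[0])
    if set(cov_df.index) != set(sites):
        missing = set(sites) ^ set(cov_df.index)
        raise ValueError(f"site sets differ between detections and covariates: {missing}")
    cov_df = cov_df.loc[sites]

    counts = None
    if counts_path is not None:
        def check_counts(mat):
            obs = mat[~np.isnan(mat)]
            if (obs < 0).any():
                raise ValueError(f"negative count in {counts_path}")

        csites, c = _parse_matrix_csv(counts_path, check_counts)
        if set(csites) != set(sites):
            raise ValueError("site sets differ between detections and counts")
        order = [csites.index(s) for s in sites]
        counts = CountHistory(sites, c[order])

    obs_tables = {}
    for name, p in (obs_covariate_paths or {}).items():
        osites, m = _parse_matrix_csv(p, lambda _: None)
        if set(osites) != set(sites):
            raise ValueError(f"site sets differ for obs covariate {name!r}")
        order = [osites.index(s) for s in sites]
        obs_tables[name] = pd.DataFrame(
            m[order], index=pd.Index(sites, name="site"),
            columns=[f"occ{j + 1}" for j in range(m.shape[1])])

    if obs_long_path is not None:
        long = pd.read_csv(obs_long_path, dtype={"site": str},
                           na_values=list(_NA_TOKENS), keep_default_na=False)
        need = {"site", "occasion", "covariate", "value"}
        if not need <= set(long.columns):
            raise ValueError(f"long-format table must have columns {need}")
        if set(long["site"]) - set(sites):
            raise ValueError("long-format table names unknown sites")
        for name, grp in long.groupby("covariate"):
            wide = grp.pivot(index="site", columns="occasion", values="value")
            wide = wide.reindex(sites)
            wide.columns = [f"occ{int(j)}" for j in wide.columns]
            wide.index = pd.Index(sites, name="site")
            obs_tables[str(name)] = wide

    bundle = CovariateBundle(cov_df, obs_tables)
    return hist, counts, bundle


def write_survey_tables(outdir, detections: DetectionHistory,
                        bundle: CovariateBundle,
                        counts: CountHistory | None = None,
                        prefix: str = "survey") -> dict:
    """Write the standard CSV trio (plus per-covariate obs tables); returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    dpath = os.path.join(outdir, f"{prefix}_detections.csv")
    detections.to_frame().to_csv(dpath, index=False)
    paths["detections"] = dpath
    cpath = os.path.join(outdir, f"{prefix}_covariates.csv")
    bundle.site_table.rename_axis("site").to_csv(cpath)
    paths["covariates"] = cpath
    if counts is not None:
        kpath = os.path.join(outdir, f"{prefix}_counts.csv")
        counts.to_frame().to_csv(kpath, index=False)
        paths["counts"] = kpath
    obs_paths = {}
    for name, tab in bundle.obs_tables.items():
        p = os.path.join(outdir, f"{prefix}_obs_{name}.csv")
        tab.rename_axis("site").to_csv(p)
        obs_paths[name] = p
    paths["obs_covariates"] = obs_paths
    return paths


def standardize(bundle: CovariateBundle, columns=None) -> CovariateBundle:
    """Center on the mean and scale by standard deviation (ddof=1).

    Applies to the named site- or observation-level columns (default: all
    numeric columns not yet standardized).  The (mean, sd) pair is stored
    so the transform can be inverted.  Zero-variance columns raise.
    """
    if columns is None:
        columns = [c for c in bundle.covariate_names() if c not in bundle.scaling]
    site = bundle.site_table.copy()
    obs = {k: v.copy() for k, v in bundle.obs_tables.items()}
    scaling = dict(bundle.scaling)
    for name in columns:
        if name in site.columns:
            vals = site[name].to_numpy(dtype=float)
            mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))
            if not sd > 0:
                raise ValueError(f"zero-variance covariate {name!r}")
            site[name] = (vals - mu) / sd
        elif name in obs:
            vals = obs[name].to_numpy(dtype=float)
            mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))
            if not sd > 0:
                raise ValueError(f"zero-variance covariate {name!r}")
            obs[name] = (obs[name] - mu) / sd
        else:
            raise KeyError(f"unknown covariate {name!r}")
        scaling[name] = (mu, sd)
    return CovariateBundle(site, obs, scaling)


def unstandardize(bundle: CovariateBundle, columns=None) -> CovariateBundle:
    """Invert :func:`standardize` using the stored (mean, sd) pairs."""
    if columns is None:
        columns = list(bundle.scaling)
    site = bundle.site_table.copy()
    obs = {k: v.copy() for k, v in bundle.obs_tables.items()}
    scaling = dict(bundle.scaling)
    for name in columns:
        mu, sd = scaling.pop(name)
        if name in site.columns:
            site[name] = site[name] * sd + mu
        else:
            obs[name] = obs[name] * sd + mu
    return CovariateBundle(site, obs, scaling)


def spearman_screen(bundle: CovariateBundle, threshold: float = 0.7):
    """Flag covariate pairs with |Spearman rho| >= threshold.

    Observation-level covariates enter as their site means so all columns
    share the site index.  Returns a list of ``(name_a, name_b, rho)``
    with name_a < name_b; the screen warns the analyst, it never drops.
    """
    cols = {}
    for name in bundle.site_table.columns:
        cols[name] = bundle.site_table[name].to_numpy(dtype=float)
    for name, tab in bundle.obs_tables.items():
        cols[name] = np.nanmean(tab.to_numpy(dtype=float), axis=1)
    names = sorted(cols)
    if len(next(iter(cols.values()), [])) < 3:
        raise ValueError("need at least 3 sites for a rank correlation")
    flagged = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = _sps.spearmanr(cols[a], cols[b], nan_policy="omit").statistic
            if np.isfinite(rho) and abs(rho) >= threshold:
                flagged.append((a, b, float(rho)))
    return flagged


def naive_occupancy(history: DetectionHistory):
    """Fraction of sites with at least one detection, uncorrected for
    imperfect detection.  Returns ``(n_detected, n_sites, proportion)``."""
    det = history.detected_sites()
    k = int(det.sum())
    n = history.n_sites
    return k, n, k / n
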