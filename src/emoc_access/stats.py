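"""Remoteness index and the mortality regression.

The remoteness index of an administrative zone is the proportion of its
population whose modelled travel time to the nearest EmOC facility is
strictly greater than a threshold (two hours by default).  The maternal
mortality ratio (MMR, deaths per 100,000 live births) is regressed on the
remoteness index and a season indicator (dry = 1, wet = 0) with a Poisson
log-link GLM; the remoteness index is standardised by two standard
deviations so its coefficient is directly comparable with the binary
season coefficient.

Two response parameterisations are exposed.  ``mmr`` regresses the ratio
itself — the variance assumption is quasi-likelihood, the score equations
are the Poisson ones and tolerate a non-integer response.  ``deaths_offset``
fits the death counts with a fixed offset log(births / 100,000); it is the
statistically cleaner form and its coefficients live on the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GLMResult",
    "remoteness_index", "fertile_women_remote", "standardize_2sd",
    "fit_poisson_glm", "build_glm_dataset", "scenario_report",
]

_ZONE_LABEL_ORDER = ["0-30", "30-60", "60-90", "90-120", ">120"]


def remoteness_index(pat: pd.DataFrame, threshold: float = 120.0,
                     zones=None) -> pd.DataFrame:
    """Per-zone remoteness: share of persons strictly beyond ``threshold`` minutes.

    ``pat`` is a population-at-travel-time table (columns zone, minutes,
    persons).  Zones with zero population get a NaN index and
    ``defined=False``; they are excluded from any downstream regression.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive minutes")
    g = pat.groupby("zone")
    total = g["persons"].sum()
    remote = pat.loc[pat["minutes"] > threshold].groupby("zone")["persons"].sum()
    out = pd.DataFrame({"persons_total": total})
    out["persons_remote"] = remote.reindex(total.index).fillna(0.0)
    if zones is not None:
        out = out.reindex(pd.Index(zones, name="zone")).fillna(0.0)
    defined = out["persons_total"] > 0
    out["remoteness"] = np.where(defined, out["persons_remote"] / out["persons_total"].where(defined, 1.0), np.nan)
    out["defined"] = defined
    return out.reset_index()


def fertile_women_remote(rt: pd.DataFrame, census: pd.DataFrame) -> pd.DataFrame:
    """Add the count of fertile-aged women (15-45) among the remote population.

    persons_remote x female fraction x fertile fraction, per zone.
    """
    fr = census.set_index("zone")[["female_fraction", "fertile_fraction"]]
    out = rt.merge(fr, on="zone", how="left")
    out["fertile_women_remote"] = (
        out["persons_remote"] * out["female_fraction"] * out["fertile_fraction"])
    return out


def standardize_2sd(x) -> tuple[np.ndarray, float, float]:
    """Centre and scale by twice the (n-1) standard deviation.

    Returns (z, mean, sd); the standardised vector has sd 0.5, which puts a
    continuous covariate's coefficient on the footing of a binary one.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot 2-SD standardize a constant covariate")
    return (x - mean) / (2.0 * sd), float(mean), float(sd)


@dataclass
class GLMResult:
    """Fit summary of the Poisson log-link model."""

    names: list[str]
    beta: np.ndarray            # on the (possibly standardized) fitting scale
    se: np.ndarray
    beta_raw: np.ndarray        # remoteness effect per unit of the raw index
    deviance: float
    iterations: int
    converged: bool
    response_mode: str
    standardized: bool
    r_mean: float = float("nan")
    r_sd: float = float("nan")
    dispersion: float = 1.0
    extra: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "beta_raw": [float(b) for b in self.beta_raw],
            "deviance": float(self.deviance),
            "iterations": self.iterations,
            "converged": bool(self.converged),
            "response_mode": self.response_mode,
            "standardized": bool(self.standardized),
            "r_mean": float(self.r_mean),
            "r_sd": float(self.r_sd),
            "dispersion": float(self.dispersion),
        }


def _irls(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
          tol: float = 1e-10, max_iter: int = 100):
    """Poisson log-link scoring iterations; returns (beta, cov, dev, it, ok)."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"design matrix is rank deficient (n={n}, p={p})")
    mu = np.maximum((y + y.mean()) / 2.0, 1e-8)
    eta = np.log(mu)
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu
        z = eta - offset + (y - mu) / mu
        wx = X * w[:, None]
        xtwx = X.T @ wx
        beta_new = np.linalg.solve(xtwx, wx.T @ z)
        step = np.max(np.abs(beta_new - beta)) if it > 1 else np.inf
        beta = beta_new
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -700, 700))
        if step < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last max coefficient step {step:.3e})")
    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = float(2.0 * dev_terms.sum())
    return beta, cov, deviance, it, mu


def fit_poisson_glm(data: pd.DataFrame, response_mode: str = "mmr",
                    covariates: tuple[str, ...] = ("remoteness", "season"),
                    standardize: bool = True,
                    quasi_dispersion: bool = False) -> GLMResult:
    """Fit MMR ~ remoteness + season with a Poisson log link (IRLS).

    ``data`` needs one row per zone-season with columns ``remoteness``,
    ``season`` (dry = 1, wet = 0) and, depending on the mode, ``mmr`` or
    ``deaths``/``births``.  The continuous remoteness covariate is 2-SD
    standardised by default (binary season passes through).  Standard
    errors come from the inverse Fisher information at convergence, with
    dispersion fixed at 1 unless ``quasi_dispersion`` is set.
    """
    if response_mode not in ("mmr", "deaths_offset"):
        raise ValueError(f"unknown response_mode {response_mode!r}")
    if len(data) < max(4, len(covariates) + 1):
        raise ValueError(f"need at least 4 rows to fit, got {len(data)}")
    cols = [np.ones(len(data))]
    names = ["intercept"]
    r_mean = r_sd = float("nan")
    shifts, scales = [], []  # raw x = scale * z + shift per covariate
    for cov_name in covariates:
        x = np.asarray(data[cov_name], dtype=float)
        is_binary = set(np.unique(x)) <= {0.0, 1.0}
        if standardize and not is_binary:
            x, mean, sd = standardize_2sd(x)
            r_mean, r_sd = mean, sd
            shifts.append(mean)
            scales.append(2.0 * sd)
        else:
            shifts.append(0.0)
            scales.append(1.0)
        cols.append(x)
        names.append(cov_name)
    X = np.column_stack(cols)
    if response_mode == "mmr":
        y = np.asarray(data["mmr"], dtype=float)
        offset = np.zeros(len(data))
    else:
        y = np.asarray(data["deaths"], dtype=float)
        births = np.asarray(data["births"], dtype=float)
        if np.any(births <= 0):
            raise ValueError("deaths_offset mode needs positive births in every row")
        offset = np.log(births / 100_000.0)
    beta, cov, deviance, it, mu = _irls(X, y, offset)
    se = np.sqrt(np.diag(cov))
    dispersion = 1.0
    if quasi_dispersion:
        pearson = float(np.sum((y - mu) ** 2 / mu))
        dispersion = pearson / (len(y) - X.shape[1])
        se = se * np.sqrt(dispersion)
    # undo the 2-SD scaling: z = (x - mean)/(2 sd) => beta_std = beta_raw * 2 sd
    beta_raw = beta.copy()
    for k, (shift, scale) in enumerate(zip(shifts, scales), start=1):
        beta_raw[k] = beta[k] / scale
        beta_raw[0] -= beta[k] * shift / scale
    return GLMResult(
        names=names, beta=beta, se=se, beta_raw=beta_raw, deviance=deviance,
        iterations=it, converged=True, response_mode=response_mode,
        standardized=standardize, r_mean=r_mean, r_sd=r_sd, dispersion=dispersion)


def build_glm_dataset(remoteness_by_season: pd.DataFrame,
                      mortality: pd.DataFrame,
                      pool_years: bool = False) -> pd.DataFrame:
    """Assemble the two-rows-per-zone regression table.

    ``remoteness_by_season``: columns zone, season (dry=1/wet=0), remoteness.
    ``mortality``: columns zone, year, deaths, births, optionally season —
    without a season column the zone's MMR series is shared across both
    season rows.  MMR is the mean of yearly ratios 100000 * deaths/births
    (years with zero births are dropped with a warning); ``pool_years``
    switches to pooled total deaths / total births instead.
    """
    mort = mortality.copy()
    zero = mort["births"] == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zone-year(s) with zero births from MMR")
        mort = mort.loc[~zero]
    keys = ["zone"] + (["season"] if "season" in mort.columns else [])
    if pool_years:
        agg = mort.groupby(keys).agg(deaths=("deaths", "sum"), births=("births", "sum"))
        agg["mmr"] = 100_000.0 * agg["deaths"] / agg["births"]
    else:
        mort["ratio"] = 100_000.0 * mort["deaths"] / mort["births"]
        agg = mort.groupby(keys).agg(
            mmr=("ratio", "mean"), deaths=("deaths", "sum"), births=("births", "sum"))
    agg = agg.reset_index()
    rt = remoteness_by_season.loc[remoteness_by_season.get("defined", True).astype(bool)] \
        if "defined" in remoteness_by_season.columns else remoteness_by_season
    rows = rt[["zone", "season", "remoteness"]].copy()
    out = rows.merge(agg, on=keys, how="inner")
    return out.sort_values(["zone", "season"]).reset_index(drop=True)


def scenario_report(pats: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Population share per travel-time class for each scenario.

    Rows are scenarios, columns the five classes ("0-30" ... ">120");
    shares sum to 1 within each scenario.
    """
    rows = {}
    for name, pat in pats.items():
        shares = pat.groupby("zone_label")["persons"].sum()
        total = shares.sum()
        rows[name] = [float(shares.get(lbl, 0.0)) / total for lbl in _ZONE_LABEL_ORDER]
    return pd.DataFrame.from_dict(rows, orient="index", columns=_ZONE_LABEL_ORDER)
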