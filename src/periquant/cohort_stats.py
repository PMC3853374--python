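"""Survival and regression pipeline for compartment-metric cohorts.

Mirrors a conventional retrospective outcome analysis around the imaging
metrics: Kaplan-Meier overall survival with median and 95 % CI, two-sample
t-tests between residual-disease groups, a univariate Cox screen feeding a
multivariate Cox model (compartment volume and surface area always enter;
other covariates enter when univariate p < 0.1), hazard ratios expressed per
standard deviation, and an interaction-retention linear model for
posttreatment GFR.  A seeded cohort simulator with known coefficients
provides ground truth for validating the whole pipeline.

Cox models use the Breslow tie approximation by default (Efron available);
survival-function confidence bands use the log-minus-log transform; t-tests
are Welch by default.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
import statsmodels.api as sm

__all__ = [
    "KMEstimate",
    "CovariateEffect",
    "CoxFit",
    "ScreenResult",
    "GfrRegressionFit",
    "CohortParams",
    "km_estimate",
    "group_ttest",
    "cox_fit",
    "screen_then_multivariate",
    "per_sd_hazard_ratio",
    "gfr_regression",
    "predict_post_gfr",
    "bsa_auc_regression",
    "simulate_cohort",
]

Z95 = 1.959963984540054  # two-sided 95 % normal quantile


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int
    median_defined: bool
    ci_method: str = "log-minus-log (Brookmeyer-Crowley style)"


def km_estimate(records: pd.DataFrame, duration_col: str = "time", event_col: str = "event") -> KMEstimate:
    """Product-limit survival estimate with median and 95 % CI.

    The median is the earliest time at which S(t) <= 0.5.  With no events the
    curve is flat at 1 and the median is flagged undefined rather than
    raising.
    """
    t = np.asarray(records[duration_col], dtype=float)
    e = np.asarray(records[event_col], dtype=bool)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    median = kmf.median_survival_time_
    defined = np.isfinite(median)
    lo = hi = None
    if e.any():
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = (float(v) if np.isfinite(v) else None for v in ci.iloc[0].to_numpy())
    return KMEstimate(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median=float(median) if defined else None,
        median_ci=(lo, hi),
        n=len(t),
        n_events=int(e.sum()),
        median_defined=bool(defined),
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def group_ttest(
    records: pd.DataFrame,
    variable: str,
    group_col: str = "residual_gt_0_5cm",
    equal_var: bool = False,
):
    """Two-sample t-test (Welch by default) of ``variable`` between the two
    groups defined by ``group_col``.  Returns ``(t, p)``."""
    g = records[group_col].astype(bool)
    a = records.loc[g, variable].to_numpy(dtype=float)
    b = records.loc[~g, variable].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateEffect:
    coef: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    covariates: dict[str, CovariateEffect]
    log_likelihood: float
    null_log_likelihood: float
    lr_statistic: float
    lr_df: int
    global_p: float
    ties: str
    n: int
    n_events: int

    def __getitem__(self, name: str) -> CovariateEffect:
        return self.covariates[name]


def cox_fit(
    records: pd.DataFrame,
    covariates,
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxFit:
    """Maximize the Cox partial likelihood and report Wald statistics.

    Hazard ratios are exp(coef) with 95 % Wald CIs; the global p-value is a
    likelihood-ratio test against the null (all-zero) model.  Constant
    covariates and event-free data are rejected.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    t = np.asarray(records[duration_col], dtype=float)
    e = np.asarray(records[event_col], dtype=float)
    if e.sum() < 1:
        raise ValueError("need at least one event")
    X = records[covariates].to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    model = PHReg(t, X, status=e, ties=ties)
    res = model.fit(disp=False)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        raise RuntimeError("Cox fit did not converge (possible complete separation)")
    effects = {}
    for name, b, se in zip(covariates, params, bse):
        z = b / se
        effects[name] = CovariateEffect(
            coef=float(b),
            se=float(se),
            hazard_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)),
            p=float(2.0 * stats.norm.sf(abs(z))),
        )
    ll = float(model.loglike(params))
    ll0 = float(model.loglike(np.zeros_like(params)))
    lr = 2.0 * (ll - ll0)
    df = len(covariates)
    return CoxFit(
        covariates=effects,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        lr_statistic=float(lr),
        lr_df=df,
        global_p=float(stats.chi2.sf(lr, df)),
        ties=ties,
        n=len(t),
        n_events=int(e.sum()),
    )


@dataclass
class ScreenResult:
    univariate_p: dict[str, float]
    selected: list[str]
    forced: list[str]
    fit: CoxFit


def screen_then_multivariate(
    records: pd.DataFrame,
    candidates,
    screen_alpha: float = 0.1,
    force_include=("volume", "surface_area"),
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> ScreenResult:
    """Univariate Cox screen followed by a multivariate model.

    Compartment volume and surface area always enter the multivariate model
    (set ``force_include=()`` to disable); every other candidate enters iff
    its univariate p-value is below ``screen_alpha``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    forced = [c for c in force_include]
    uni_p = {}
    for cov in candidates:
        fit = cox_fit(records, [cov], duration_col, event_col, ties)
        uni_p[cov] = fit[cov].p
    selected = [c for c in candidates if c not in forced and uni_p[c] < screen_alpha]
    final_covs = forced + selected
    if not final_covs:
        raise ValueError("no covariate passed the screen and none are forced")
    fit = cox_fit(records, final_covs, duration_col, event_col, ties)
    return ScreenResult(univariate_p=uni_p, selected=selected, forced=forced, fit=fit)


def per_sd_hazard_ratio(fit: CoxFit, covariate: str, sd: float):
    """Hazard ratio for a one-standard-deviation covariate increase.

    HR = exp(beta * sd) with CI exp((beta ± 1.96 se) * sd).  Returns
    ``(hr, (lo, hi))``.
    """
    if covariate not in fit.covariates:
        raise KeyError(f"covariate {covariate!r} not in the fit")
    eff = fit.covariates[covariate]
    hr = float(np.exp(eff.coef * sd))
    lo = float(np.exp((eff.coef - Z95 * eff.se) * sd))
    hi = float(np.exp((eff.coef + Z95 * eff.se) * sd))
    return hr, (min(lo, hi), max(lo, hi))


# ---------------------------------------------------------------------------
# posttreatment-GFR linear model
# ---------------------------------------------------------------------------

_GFR_MAIN = ["pre_gfr", "bsa", "volume", "surface_area"]
_GFR_INTERACTIONS = {"bsa_x_volume": ("bsa", "volume"), "bsa_x_surface_area": ("bsa", "surface_area")}


@dataclass
class GfrRegressionFit:
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    retained_interactions: list[str]
    model_p: float
    n: int


def _gfr_design(records: pd.DataFrame, interactions) -> pd.DataFrame:
    X = records[_GFR_MAIN].astype(float).copy()
    for name in interactions:
        a, b = _GFR_INTERACTIONS[name]
        X[name] = records[a].astype(float) * records[b].astype(float)
    return sm.add_constant(X, has_constant="add")


def gfr_regression(records: pd.DataFrame, alpha: float = 0.05) -> GfrRegressionFit:
    """OLS of posttreatment GFR with interaction retention.

    Main effects: pretreatment GFR, BSA, compartment volume and surface
    area.  Candidate two-way interactions BSA x volume and BSA x surface
    area are kept only when significant at ``alpha`` in the full model; the
    model is then refit with the retained interactions only.
    """
    y = records["post_gfr"].astype(float)
    full = sm.OLS(y, _gfr_design(records, _GFR_INTERACTIONS)).fit()
    retained = [name for name in _GFR_INTERACTIONS if full.pvalues[name] < alpha]
    final = sm.OLS(y, _gfr_design(records, retained)).fit()
    return GfrRegressionFit(
        params={k: float(v) for k, v in final.params.items()},
        bse={k: float(v) for k, v in final.bse.items()},
        pvalues={k: float(v) for k, v in final.pvalues.items()},
        retained_interactions=retained,
        model_p=float(final.f_pvalue),
        n=int(final.nobs),
    )


def predict_post_gfr(
    fit: GfrRegressionFit, pre_gfr: float, bsa: float, volume: float, surface_area: float
) -> float:
    """Evaluate the fitted linear predictor for one covariate pattern."""
    vals = {"pre_gfr": pre_gfr, "bsa": bsa, "volume": volume, "surface_area": surface_area}
    out = fit.params.get("const", 0.0)
    for name in _GFR_MAIN:
        out += fit.params[name] * vals[name]
    for name in fit.retained_interactions:
        a, b = _GFR_INTERACTIONS[name]
        out += fit.params[name] * vals[a] * vals[b]
    return float(out)


def bsa_auc_regression(records: pd.DataFrame, auc_col: str = "auc", bsa_col: str = "bsa"):
    """Simple OLS of plasma AUC on BSA; returns ``(slope, p)``.

    The slope is in mg.min/L per m^2.
    """
    X = sm.add_constant(records[[bsa_col]].astype(float))
    res = sm.OLS(records[auc_col].astype(float), X).fit()
    return float(res.params[bsa_col]), float(res.pvalues[bsa_col])


# ---------------------------------------------------------------------------
# cohort simulator
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a target mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


@dataclass
class CohortParams:
    """Generative description of a synthetic IP-chemotherapy cohort.

    Covariate marginals default to the study population this pipeline was
    designed around: mean compartment volume 558.4 cm^3 (SD 532), surface
    area 1261.7 cm^2 (SD 1158.5), BSA 1.92 m^2 (SD 0.25), pretreatment GFR
    96 cc/min (SD 35.5), half female, ~11 % biphasic histology, ~26 %
    residual disease > 0.5 cm, and a baseline median survival of 48 months.
    Volume and surface area are lognormal (positivity) with a Gaussian-copula
    correlation of ``vol_sa_corr``.

    ``cox_betas`` are log-hazard coefficients applied to the named covariate
    columns on their raw scales; survival is exponential with hazard
    ``log(2)/baseline_median_months * exp(sum beta x)`` and independent
    exponential censoring calibrated to ``censor_frac``.  ``gfr_coefs``
    generate posttreatment GFR from the linear model (keys: const, pre_gfr,
    bsa, volume, surface_area, bsa_x_volume, bsa_x_surface_area) plus
    N(0, gfr_noise_sd) noise.
    """

    n: int = 38
    age_mean: float = 60.0
    age_sd: float = 13.0
    age_range: tuple[float, float] = (21.0, 83.0)
    p_female: float = 0.5
    p_biphasic: float = 4.0 / 38.0
    p_residual: float = 10.0 / 38.0
    bsa_mean: float = 1.92
    bsa_sd: float = 0.25
    pre_gfr_mean: float = 96.0
    pre_gfr_sd: float = 35.5
    volume_mean: float = 558.4
    volume_sd: float = 532.0
    surface_area_mean: float = 1261.7
    surface_area_sd: float = 1158.5
    vol_sa_corr: float = 0.7
    baseline_median_months: float = 48.0
    cox_betas: dict = field(default_factory=dict)
    censor_frac: float = 0.3
    gfr_coefs: dict = field(
        default_factory=lambda: {
            "const": 0.0,
            "pre_gfr": 0.802,
            "bsa": 69.969,
            "volume": 0.154,
            "surface_area": -0.003,
            "bsa_x_volume": -0.07,
            "bsa_x_surface_area": 0.0,
        }
    )
    gfr_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.censor_frac < 1.0:
            raise ValueError("censor_frac must lie in [0, 1)")
        for name in ("age_sd", "bsa_sd", "pre_gfr_sd", "volume_sd", "surface_area_sd", "gfr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_median_months <= 0:
            raise ValueError("baseline_median_months must be positive")
        if not -1.0 < self.vol_sa_corr < 1.0:
            raise ValueError("vol_sa_corr must lie in (-1, 1)")


def simulate_cohort(params: CohortParams, seed: int) -> pd.DataFrame:
    """Draw a synthetic cohort with known generative coefficients.

    Deterministic given ``seed``.  Columns: id, age, sex, female, histology,
    biphasic, residual_gt_0_5cm, bsa, pre_gfr, volume, surface_area,
    post_gfr, time (months), event.
    """
    rng = np.random.default_rng(seed)
    n = params.n
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), *params.age_range)
    female = rng.random(n) < params.p_female
    biphasic = rng.random(n) < params.p_biphasic
    residual = rng.random(n) < params.p_residual
    bsa = np.clip(rng.normal(params.bsa_mean, params.bsa_sd, n), 1.0, None)
    pre_gfr = np.clip(rng.normal(params.pre_gfr_mean, params.pre_gfr_sd, n), 5.0, None)

    # correlated lognormal volume / surface area via a Gaussian copula
    mu_v, s_v = _lognormal_params(params.volume_mean, params.volume_sd)
    mu_a, s_a = _lognormal_params(params.surface_area_mean, params.surface_area_sd)
    rho = params.vol_sa_corr
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    volume = np.exp(mu_v + s_v * z[:, 0])
    surface_area = np.exp(mu_a + s_a * z[:, 1])

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age,
            "sex": np.where(female, "female", "male"),
            "female": female.astype(int),
            "histology": np.where(biphasic, "biphasic", "epithelioid"),
            "biphasic": biphasic.astype(int),
            "residual_gt_0_5cm": residual.astype(int),
            "bsa": bsa,
            "pre_gfr": pre_gfr,
            "volume": volume,
            "surface_area": surface_area,
        }
    )

    lam0 = np.log(2.0) / params.baseline_median_months
    eta = np.zeros(n)
    for col, beta in params.cox_betas.items():
        eta += beta * df[col].to_numpy(dtype=float)
    lam = lam0 * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    if params.censor_frac > 0:
        lam_c = lam.mean() * params.censor_frac / (1.0 - params.censor_frac)
        t_cens = rng.exponential(1.0 / lam_c, n)
    else:
        t_cens = np.full(n, np.inf)
    df["time"] = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    df["event"] = (t_event <= t_cens).astype(int)

    g = params.gfr_coefs
    post = (
        g.get("const", 0.0)
        + g.get("pre_gfr", 0.0) * pre_gfr
        + g.get("bsa", 0.0) * bsa
        + g.get("volume", 0.0) * volume
        + g.get("surface_area", 0.0) * surface_area
        + g.get("bsa_x_volume", 0.0) * bsa * volume
        + g.get("bsa_x_surface_area", 0.0) * bsa * surface_area
    )
    df["post_gfr"] = post + rng.normal(0.0, params.gfr_noise_sd, n)
    return df
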