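"""Vital-rate regressions.

Each demographic rate is fit by a small scikit-learn style estimator
(``fit`` on arrays, fitted attributes with trailing underscores,
``get_params``/``set_params`` for composition with sklearn tooling), and a
module-level ``fit_*`` function adapts a :class:`~rametipm.dataset.RametDataset`
to the estimator and returns a :class:`VitalRateFit` record.

Models
------
survival, flowering : logistic regression of a binary fate on log-size
growth              : Gaussian regression of size at t+1 on size at t with
                      residual SD σ(z) = σ0·exp(βσ·z), fit jointly by
                      maximum likelihood
flower_count        : Poisson log-link regression on flowering ramets only,
                      with a quasi-Poisson dispersion (Pearson χ²/df) used
                      to scale the standard errors
recruit_size        : truncated-normal maximum likelihood on recruit sizes
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .dataset import RametDataset
from .errors import ConvergenceError, DegenerateDataError, SeparationError

__all__ = [
    "VitalRateFit",
    "ModelSelectionTable",
    "SizeLogisticRegression",
    "GrowthRegression",
    "FlowerCountRegression",
    "TruncatedNormalFit",
    "fit_survival",
    "fit_growth",
    "fit_flowering",
    "fit_flower_count",
    "fit_recruit_size",
    "estimate_recruitment_rate",
    "select_by_aic",
    "select_from_candidates",
]

_SEP_PARAM_LIMIT = 30.0  # |logit coefficient| beyond this is numerically separated


@dataclass
class VitalRateFit:
    """A fitted vital-rate model in coefficient form."""

    rate_name: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    aic: float
    n: int
    formula: str = "linear"
    dispersion: float | None = None
    converged: bool = True
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "rate_name": self.rate_name,
            "formula": self.formula,
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
            "dispersion": self.dispersion,
            "converged": self.converged,
        }


@dataclass
class ModelSelectionTable:
    """AIC comparison of candidate formulas for one vital rate."""

    rate_name: str
    candidates: list[dict] = field(default_factory=list)
    selected: str | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.candidates)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

_FORMULA_DEGREE = {"intercept": 0, "linear": 1, "quadratic": 2}


def _design(z: np.ndarray, formula: str) -> np.ndarray:
    if formula not in _FORMULA_DEGREE:
        raise ValueError(f"unknown formula {formula!r}")
    deg = _FORMULA_DEGREE[formula]
    return np.vander(z, deg + 1, increasing=True)


def _coef_names(prefix: str, formula: str) -> list[str]:
    deg = _FORMULA_DEGREE[formula]
    return [f"beta{i}_{prefix}" for i in range(deg + 1)]


def _as_1d(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("expected a single size column")
        X = X[:, 0]
    return X


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class SizeLogisticRegression(BaseEstimator):
    """Maximum-likelihood logistic regression of a binary fate on log-size.

    Parameters
    ----------
    formula : {"intercept", "linear", "quadratic"}
        Polynomial degree of log-size in the linear predictor.
    """

    def __init__(self, formula: str = "linear"):
        self.formula = formula

    def fit(self, X, y):
        z = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if z.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if len(z) < 2:
            raise DegenerateDataError("need at least 2 records for a logistic fit")
        if len(np.unique(y)) < 2:
            raise SeparationError(
                "response is constant; both outcomes must be represented"
            )
        design = _design(z, self.formula)
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = sm.Logit(y, design).fit(disp=0)
            except (PerfectSeparationError, PerfectSeparationWarning) as exc:
                raise SeparationError(f"complete separation detected: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError("logistic fit did not converge", res.mle_retvals)
        if np.any(np.abs(res.params) > _SEP_PARAM_LIMIT):
            raise SeparationError(
                f"coefficients diverged (|beta| > {_SEP_PARAM_LIMIT}); "
                "data are separated"
            )
        self.coef_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.llf_ = float(res.llf)
        self.aic_ = float(res.aic)
        self.n_ = len(z)
        self.n_params_ = design.shape[1]
        return self

    def predict_proba_1d(self, X):
        from scipy.special import expit

        z = _as_1d(X)
        return expit(_design(z, self.formula) @ self.coef_)


class GrowthRegression(BaseEstimator):
    """Gaussian growth model with an exponential variance function.

    size_t1 ~ Normal(m(z), σ(z)) with polynomial mean m(z) and
    σ(z) = σ0·exp(βσ·z).  With ``variance="constant"`` the SD exponent is
    fixed at 0 and the fit coincides with ordinary least squares.
    All parameters are estimated jointly by maximum likelihood; standard
    errors come from the inverse observed information.
    """

    def __init__(self, formula: str = "linear", variance: str = "exponential"):
        self.formula = formula
        self.variance = variance

    def _nll_and_grad(self, theta, design, z, y):
        k = design.shape[1]
        beta = theta[:k]
        log_s0 = theta[k]
        bsig = theta[k + 1] if self.variance == "exponential" else 0.0
        s = np.exp(log_s0 + bsig * z)
        r = (y - design @ beta) / s
        nll = np.sum(np.log(s) + 0.5 * r * r) + 0.5 * len(y) * np.log(2 * np.pi)
        g_beta = -design.T @ (r / s)
        g_ls0 = np.sum(1.0 - r * r)
        grad = np.concatenate([g_beta, [g_ls0]])
        if self.variance == "exponential":
            grad = np.concatenate([grad, [np.sum(z * (1.0 - r * r))]])
        return nll, grad

    def fit(self, X, y):
        z = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(z) < 3:
            raise DegenerateDataError("need at least 3 survivor records for growth")
        design = _design(z, self.formula)
        beta0, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta0
        s_hat = float(np.std(resid))
        if s_hat <= 1e-10 * max(1.0, float(np.std(y))):
            raise DegenerateDataError("zero residual variance in growth data")
        theta0 = np.concatenate([beta0, [np.log(s_hat)]])
        if self.variance == "exponential":
            theta0 = np.concatenate([theta0, [0.0]])
        res = optimize.minimize(
            self._nll_and_grad,
            theta0,
            args=(design, z, y),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        if not res.success and res.status != 2:  # 2: precision loss near optimum
            raise ConvergenceError(
                f"growth ML fit failed: {res.message}",
                {"status": res.status, "nit": res.nit, "grad_norm": float(np.max(np.abs(res.jac)))},
            )
        theta = res.x
        k = design.shape[1]
        hess = approx_hess(theta, lambda t: self._nll_and_grad(t, design, z, y)[0])
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))

        self.coef_ = theta[:k]
        self.sigma0_ = float(np.exp(theta[k]))
        self.sigma_slope_ = float(theta[k + 1]) if self.variance == "exponential" else 0.0
        # delta method: SE(sigma0) = sigma0 * SE(log sigma0)
        self.bse_ = np.concatenate(
            [
                se[:k],
                [self.sigma0_ * se[k]],
                [se[k + 1]] if self.variance == "exponential" else [],
            ]
        )
        self.llf_ = -float(res.fun)
        self.n_params_ = len(theta)
        self.aic_ = 2.0 * float(res.fun) + 2.0 * self.n_params_
        self.n_ = len(z)
        self.converged_ = True
        return self

    def predict(self, X):
        z = _as_1d(X)
        return _design(z, self.formula) @ self.coef_

    def predict_sd(self, X):
        z = _as_1d(X)
        return self.sigma0_ * np.exp(self.sigma_slope_ * z)


class FlowerCountRegression(BaseEstimator):
    """Poisson log-link count regression with quasi-Poisson dispersion.

    The mean structure is fit by Poisson maximum likelihood; the dispersion
    φ = Pearson χ²/(n−p) is then estimated on the fitted model and standard
    errors are scaled by √φ, the standard quasi-likelihood correction for
    overdispersed counts.
    """

    def __init__(self, formula: str = "linear"):
        self.formula = formula

    def fit(self, X, y):
        z = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(z) < 2:
            raise DegenerateDataError("need at least 2 flowering records")
        if np.all(y == y[0]):
            raise DegenerateDataError(
                "all counts equal; dispersion is undefined"
            )
        design = _design(z, self.formula)
        res = sm.GLM(y, design, family=sm.families.Poisson()).fit()
        df_resid = len(z) - design.shape[1]
        if df_resid <= 0:
            raise DegenerateDataError("no residual degrees of freedom for dispersion")
        self.dispersion_ = float(res.pearson_chi2 / df_resid)
        self.coef_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse) * np.sqrt(self.dispersion_)
        self.llf_ = float(res.llf)
        self.aic_ = float(res.aic)
        self.n_ = len(z)
        self.n_params_ = design.shape[1]
        return self

    def predict(self, X):
        z = _as_1d(X)
        return np.exp(_design(z, self.formula) @ self.coef_)


class TruncatedNormalFit(BaseEstimator):
    """Maximum-likelihood normal fit on an interval-truncated support.

    Estimates the location and scale of a normal distribution truncated to
    ``bounds``; used for the recruit-size distribution, whose support is the
    IPM domain.
    """

    _MIN_LOG_SIGMA = np.log(1e-8)

    def __init__(self, bounds: tuple[float, float] = (-np.inf, np.inf)):
        self.bounds = bounds

    def _nll(self, theta, x, lo, hi):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        with np.errstate(all="ignore"):
            lp = stats.truncnorm.logpdf(x, a, b, loc=mu, scale=sigma)
        if not np.all(np.isfinite(lp)):
            return 1e12
        return -float(np.sum(lp))

    def fit(self, X, y=None):
        x = _as_1d(X)
        lo, hi = float(self.bounds[0]), float(self.bounds[1])
        if len(x) < 2:
            raise DegenerateDataError("need at least 2 recruit sizes")
        outside = (x < lo) | (x > hi)
        if outside.any():
            raise DegenerateDataError(
                f"sizes outside bounds [{lo}, {hi}]: values {x[outside].tolist()}"
            )
        s0 = float(np.std(x))
        self.degenerate_ = False
        if s0 <= 0:
            self.mu_ = float(np.mean(x))
            self.sigma_ = float(np.exp(self._MIN_LOG_SIGMA))
            self.degenerate_ = True
            self.se_ = np.array([np.nan, np.nan])
            self.llf_ = np.nan
            self.aic_ = np.nan
            self.n_ = len(x)
            self.n_params_ = 2
            return self
        theta0 = np.array([float(np.mean(x)), np.log(s0)])
        res = optimize.minimize(
            self._nll,
            theta0,
            args=(x, lo, hi),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if not res.success:
            raise ConvergenceError(f"truncated-normal fit failed: {res.message}")
        mu, log_sigma = res.x
        if log_sigma <= self._MIN_LOG_SIGMA:
            self.degenerate_ = True
        hess = approx_hess(res.x, self._nll, args=(x, lo, hi))
        with np.errstate(all="ignore"):
            try:
                cov = np.linalg.inv(hess)
                se = np.sqrt(np.abs(np.diag(cov)))
            except np.linalg.LinAlgError:
                se = np.array([np.nan, np.nan])
        self.mu_ = float(mu)
        self.sigma_ = float(np.exp(log_sigma))
        self.se_ = np.array([se[0], self.sigma_ * se[1]])
        self.llf_ = -float(res.fun)
        self.n_params_ = 2
        self.aic_ = 2.0 * float(res.fun) + 4.0
        self.n_ = len(x)
        return self


# ---------------------------------------------------------------------------
# dataset-facing wrappers
# ---------------------------------------------------------------------------


def _year_t_frame(dataset: RametDataset) -> pd.DataFrame:
    df = dataset.year_t_records
    return df[df["size_t"].notna()]


def _fit_record(est, names, rate_name, formula, dispersion=None) -> VitalRateFit:
    return VitalRateFit(
        rate_name=rate_name,
        coefficients=dict(zip(names, [float(c) for c in est.coef_]))
        if not isinstance(est, TruncatedNormalFit)
        else {"mu_rd": est.mu_, "sigma_rd": est.sigma_},
        standard_errors=dict(zip(names, [float(s) for s in est.bse_]))
        if not isinstance(est, TruncatedNormalFit)
        else {"mu_rd": float(est.se_[0]), "sigma_rd": float(est.se_[1])},
        log_likelihood=float(est.llf_),
        aic=float(est.aic_),
        n=int(est.n_),
        formula=formula,
        dispersion=dispersion,
        degenerate=bool(getattr(est, "degenerate_", False)),
    )


def fit_survival(dataset: RametDataset, formula: str = "linear") -> VitalRateFit:
    """Logistic regression of survival on log-size over all year-t ramets."""
    df = _year_t_frame(dataset)
    df = df[df["survived"].notna()]
    est = SizeLogisticRegression(formula).fit(
        df["size_t"].to_numpy(), df["survived"].to_numpy()
    )
    return _fit_record(est, _coef_names("s", formula), "survival", formula)


def fit_growth(
    dataset: RametDataset, formula: str = "linear", variance: str = "exponential"
) -> VitalRateFit:
    """Joint ML fit of the size transition of survivors (mean and SD)."""
    df = _year_t_frame(dataset)
    df = df[(df["survived"] == 1) & df["size_t1"].notna()]
    est = GrowthRegression(formula, variance).fit(
        df["size_t"].to_numpy(), df["size_t1"].to_numpy()
    )
    names = _coef_names("g", formula) + ["sigma0_g"]
    if variance == "exponential":
        names += ["betasigma_g"]
    coefs = list(est.coef_) + [est.sigma0_]
    if variance == "exponential":
        coefs += [est.sigma_slope_]
    fit = VitalRateFit(
        rate_name="growth",
        coefficients=dict(zip(names, [float(c) for c in coefs])),
        standard_errors=dict(zip(names, [float(s) for s in est.bse_])),
        log_likelihood=float(est.llf_),
        aic=float(est.aic_),
        n=int(est.n_),
        formula=f"{formula}+{variance}_sd",
        converged=bool(est.converged_),
    )
    return fit


def fit_flowering(dataset: RametDataset, formula: str = "linear") -> VitalRateFit:
    """Logistic regression of flowering probability on log-size (all year-t ramets)."""
    df = _year_t_frame(dataset)
    df = df[df["flowered"].notna()]
    est = SizeLogisticRegression(formula).fit(
        df["size_t"].to_numpy(), df["flowered"].to_numpy()
    )
    return _fit_record(est, _coef_names("pr", formula), "flowering", formula)


def fit_flower_count(dataset: RametDataset, formula: str = "linear") -> VitalRateFit:
    """Quasi-Poisson flower-count regression on flowering ramets only."""
    df = _year_t_frame(dataset)
    df = df[df["flowered"] == 1]
    est = FlowerCountRegression(formula).fit(
        df["size_t"].to_numpy(), df["n_flowers"].to_numpy()
    )
    return _fit_record(
        est, _coef_names("rs", formula), "flower_count", formula, est.dispersion_
    )


def fit_recruit_size(recruit_sizes, bounds) -> VitalRateFit:
    """Truncated-normal ML fit of recruit log-sizes on the IPM domain."""
    est = TruncatedNormalFit(bounds).fit(np.asarray(recruit_sizes, dtype=float))
    return _fit_record(est, ["mu_rd", "sigma_rd"], "recruit_size", "truncnorm")


def estimate_recruitment_rate(n_recruits: int, total_flowers: int) -> float:
    """Recruits at t+1 per flower at t."""
    if total_flowers < 1:
        raise DegenerateDataError("total_flowers must be >= 1 to define a rate")
    if n_recruits < 0:
        raise ValueError("n_recruits must be >= 0")
    return n_recruits / total_flowers


# ---------------------------------------------------------------------------
# AIC model selection
# ---------------------------------------------------------------------------

_RATE_FITTERS = {
    "survival": fit_survival,
    "growth": fit_growth,
    "flowering": fit_flowering,
    "flower_count": fit_flower_count,
}

# candidate formulas mirror the study design: binomial rates and growth get
# the full intercept/linear/quadratic ladder (growth additionally compares
# constant-SD vs exponential-SD errors); flower counts compare intercept vs
# linear only
_DEFAULT_CANDIDATES = {
    "survival": ["intercept", "linear", "quadratic"],
    "growth": ["intercept", "linear", "quadratic"],
    "flowering": ["intercept", "linear"],
    "flower_count": ["intercept", "linear"],
}

_AIC_TIE_WINDOW = 2.0


def select_by_aic(
    dataset: RametDataset, rate_name: str, candidates: list[str] | None = None
) -> ModelSelectionTable:
    """Fit candidate formulas for one rate and select by AIC.

    Candidates within 2 AIC units of the minimum are treated as ties and
    resolved toward the formula with fewer parameters (the most
    parsimonious adequate model).  For flower counts the Poisson AIC is
    used; dispersion is estimated afterwards on the selected model.
    """
    if rate_name not in _RATE_FITTERS:
        raise ValueError(f"unknown rate {rate_name!r}")
    fitter = _RATE_FITTERS[rate_name]
    labels = candidates or _DEFAULT_CANDIDATES[rate_name]
    table = ModelSelectionTable(rate_name=rate_name)
    fits: dict[str, VitalRateFit] = {}
    for label in labels:
        variants = [("", {})]
        if rate_name == "growth":
            variants = [
                ("+constant_sd", {"variance": "constant"}),
                ("+exponential_sd", {"variance": "exponential"}),
            ]
        for suffix, kw in variants:
            name = label + suffix
            try:
                fit = fitter(dataset, formula=label, **kw)
            except Exception as exc:  # per-candidate failures are recorded
                table.candidates.append(
                    {"formula": name, "aic": np.nan, "n_params": np.nan,
                     "error": f"{type(exc).__name__}: {exc}"}
                )
                continue
            n_params = len(fit.coefficients)
            table.candidates.append(
                {"formula": name, "aic": fit.aic, "n_params": n_params, "error": None}
            )
            fits[name] = fit
    table.selected = select_from_candidates(table.candidates)
    return table


def select_from_candidates(candidates: list[dict]) -> str | None:
    """Apply the parsimony tie-break to an AIC candidate table (in place).

    Fills ``delta_aic`` and returns the selected formula: among candidates
    within 2 AIC units of the minimum, the one with the fewest parameters
    (lowest AIC breaking remaining ties).  Returns None if every candidate
    failed.
    """
    ok = [c for c in candidates if c.get("error") is None]
    if not ok:
        return None
    best_aic = min(c["aic"] for c in ok)
    for c in candidates:
        c["delta_aic"] = (c["aic"] - best_aic) if c.get("error") is None else np.nan
    near = [c for c in ok if c["aic"] - best_aic < _AIC_TIE_WINDOW]
    near.sort(key=lambda c: (c["n_params"], c["aic"]))
    return near[0]["formula"]
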