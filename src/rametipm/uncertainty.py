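"""Uncertainty quantification for the IPM.

Two procedures:

* a nonparametric bootstrap of the whole inferential chain — resample the
  census with replacement (year-t records and recruits as separate strata,
  since the recruit-size fit and the recruits-per-flower rate use a
  different sample), refit every vital rate with the originally selected
  formulas, rebuild the kernel and re-analyze; percentile 95% intervals for
  λ and the sub-kernel elasticities;

* a parameter-perturbation analysis of the flower-count regression — draw
  its coefficients independently from Normal(estimate, quasi-scaled SE),
  rebuild only the fecundity sub-kernel per draw, and track the induced
  spread in λ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import vital_rates as vr
from .dataset import RametDataset
from .errors import DegenerateDataError, RametIPMError
from .ipm import IPMGrid, analyze_kernels, build_kernels
from .params import VitalRateParams

__all__ = ["BootstrapResult", "PerturbationResult", "bootstrap_pipeline", "perturb_flower_model"]


def _percentile_ci(draws, level=95.0):
    lo, hi = np.percentile(draws, [(100 - level) / 2, 100 - (100 - level) / 2])
    return float(lo), float(hi)


@dataclass
class BootstrapResult:
    n_reps: int
    lambda_draws: np.ndarray
    e_P_draws: np.ndarray
    e_F_draws: np.ndarray
    ci_lambda: tuple[float, float]
    ci_e_P: tuple[float, float]
    ci_e_F: tuple[float, float]
    n_failed: int


@dataclass
class PerturbationResult:
    n_draws: int
    lambda_draws: np.ndarray
    ci: tuple[float, float]


def _params_from_fits(surv, grow, flow, count, rec, r_r) -> VitalRateParams:
    c = {}
    for f in (surv, grow, flow, count, rec):
        c.update(f.coefficients)
    return VitalRateParams(
        beta0_s=c["beta0_s"],
        beta1_s=c.get("beta1_s", 0.0),
        beta0_g=c["beta0_g"],
        beta1_g=c.get("beta1_g", 0.0),
        sigma0_g=c["sigma0_g"],
        betasigma_g=c.get("betasigma_g", 0.0),
        beta0_pr=c["beta0_pr"],
        beta1_pr=c.get("beta1_pr", 0.0),
        beta0_rs=c["beta0_rs"],
        beta1_rs=c.get("beta1_rs", 0.0),
        mu_rd=c["mu_rd"],
        sigma_rd=c["sigma_rd"],
        r_r=r_r,
        phi=count.dispersion if count.dispersion is not None else 1.0,
    ).validate()


def bootstrap_pipeline(
    dataset: RametDataset,
    n_reps: int,
    grid: IPMGrid,
    seed: int | None = None,
    formulas: dict | None = None,
    growth_variance: str = "exponential",
) -> BootstrapResult:
    """Case-resampling bootstrap of λ and the sub-kernel elasticities.

    Year-t records and recruit records are resampled with replacement within
    their own strata (original sizes), all vital rates are refit with the
    frozen ``formulas`` (default: linear throughout), the recruits-per-flower
    rate is recomputed from the resampled totals, and the IPM is rebuilt on
    the fixed ``grid``.  Degenerate resamples (e.g. no deaths) are counted
    in ``n_failed`` and excluded.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dataset.validate()
    formulas = formulas or {
        "survival": "linear",
        "growth": "linear",
        "flowering": "linear",
        "flower_count": "linear",
    }
    rng = np.random.default_rng(seed)
    year_t = dataset.year_t_records.reset_index(drop=True)
    recruits = dataset.recruit_records.reset_index(drop=True)
    n_t, n_rec = len(year_t), len(recruits)
    if n_t == 0:
        raise DegenerateDataError("no year-t records to resample")

    lams, ePs, eFs = [], [], []
    n_failed = 0
    for _ in range(n_reps):
        idx_t = rng.integers(0, n_t, size=n_t)
        parts = [year_t.iloc[idx_t]]
        if n_rec > 0:
            idx_r = rng.integers(0, n_rec, size=n_rec)
            parts.append(recruits.iloc[idx_r])
        boot = pd.concat(parts, ignore_index=True)
        # resampling duplicates IDs by construction; make them unique again
        boot = boot.assign(ramet_id=[f"B{i:06d}" for i in range(len(boot))])
        bset = RametDataset(boot, dataset.year_t, dataset.year_t1)
        try:
            surv = vr.fit_survival(bset, formulas["survival"])
            grow = vr.fit_growth(bset, formulas["growth"], growth_variance)
            flow = vr.fit_flowering(bset, formulas["flowering"])
            count = vr.fit_flower_count(bset, formulas["flower_count"])
            rec = vr.fit_recruit_size(bset.recruit_sizes, (grid.L, grid.U))
            r_r = vr.estimate_recruitment_rate(bset.n_recruits, bset.total_flowers)
            params = _params_from_fits(surv, grow, flow, count, rec, r_r)
            res = analyze_kernels(build_kernels(params, grid))
        except RametIPMError:
            n_failed += 1
            continue
        lams.append(res.lam)
        ePs.append(res.e_P)
        eFs.append(res.e_F)

    if not lams:
        raise DegenerateDataError("every bootstrap replicate failed")
    lams = np.asarray(lams)
    ePs = np.asarray(ePs)
    eFs = np.asarray(eFs)
    return BootstrapResult(
        n_reps=n_reps,
        lambda_draws=lams,
        e_P_draws=ePs,
        e_F_draws=eFs,
        ci_lambda=_percentile_ci(lams),
        ci_e_P=_percentile_ci(ePs),
        ci_e_F=_percentile_ci(eFs),
        n_failed=n_failed,
    )


def perturb_flower_model(
    fit: vr.VitalRateFit,
    base_params: VitalRateParams,
    n_draws: int,
    grid: IPMGrid,
    seed: int | None = None,
) -> PerturbationResult:
    """Propagate flower-count coefficient uncertainty into λ.

    Each draw replaces (beta0_rs, beta1_rs) by independent Gaussians centred
    on the estimates with the fit's (quasi-scaled) standard errors, rebuilds
    the fecundity sub-kernel, and records λ.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    se = fit.standard_errors
    if not se or any(not np.isfinite(s) for s in se.values()):
        raise DegenerateDataError("flower-count fit carries no usable standard errors")
    rng = np.random.default_rng(seed)
    lams = np.empty(n_draws)
    for i in range(n_draws):
        b0 = rng.normal(fit.coefficients["beta0_rs"], se["beta0_rs"])
        b1 = rng.normal(fit.coefficients.get("beta1_rs", 0.0), se.get("beta1_rs", 0.0))
        params = replace(base_params, beta0_rs=b0, beta1_rs=b1)
        res = analyze_kernels(build_kernels(params, grid))
        lams[i] = res.lam
    return PerturbationResult(n_draws=n_draws, lambda_draws=lams, ci=_percentile_ci(lams))
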