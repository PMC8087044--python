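"""Synthetic ramet census generator.

Produces one-year transition tables with the same statistical structure the
demographic analysis assumes: uniform initial sizes over the observed range,
logistic size-dependent survival and flowering, Gaussian growth whose
residual SD decays exponentially with size, overdispersed (negative
binomial, Var = φ·mean) flower counts conditioned on at least one flower
for flowering ramets, and truncated-normal recruit sizes with a Poisson
number of recruits proportional to total flower production.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import COLUMNS, RametDataset
from .errors import DegenerateDataError, InvalidParameterError
from .params import VitalRateParams

__all__ = [
    "generate_population",
    "generate_groundtruth_fixture",
    "sample_conditional_flower_counts",
]

DEFAULT_SIZE_RANGE = (-6.04, 3.31)


def sample_conditional_flower_counts(mean, phi, rng):
    """Draw flower counts with Var = phi*mean, conditioned >= 1.

    For phi > 1 the draws are negative binomial with shape r = mean/(phi-1)
    and success probability 1/phi (which gives exactly the quasi-Poisson
    mean/variance relation); for phi = 1 they are Poisson.  Zeros are
    redrawn until every count is positive.
    """
    mean = np.asarray(mean, dtype=float)
    counts = np.zeros(mean.shape, dtype=np.int64)
    todo = np.ones(mean.shape, dtype=bool)
    # mean > 0 guarantees P(X>=1) > 0, so this terminates a.s.
    while todo.any():
        m = mean[todo]
        if phi == 1.0:
            draw = rng.poisson(m)
        else:
            r = m / (phi - 1.0)
            draw = rng.negative_binomial(r, 1.0 / phi)
        counts[np.flatnonzero(todo)] = draw
        todo = counts < 1
    return counts


def generate_population(
    params: VitalRateParams,
    n_ramets: int,
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE,
    seed: int | None = None,
    year_t: int = 2018,
) -> RametDataset:
    """Simulate one annual transition of a ramet population.

    Initial log-sizes are uniform on ``size_range``; each downstream fate is
    drawn from the corresponding vital-rate model in ``params``.  The number
    of recruits is Poisson(r_r × total flowers) and recruit sizes follow the
    truncated-normal recruit distribution restricted to ``size_range``.
    Deterministic given ``seed``.
    """
    params.validate()
    if n_ramets < 1:
        raise DegenerateDataError("n_ramets must be >= 1")
    lo, hi = float(size_range[0]), float(size_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise InvalidParameterError(f"size_range must be finite with lo < hi, got {size_range}")

    rng = np.random.default_rng(seed)
    z = rng.uniform(lo, hi, size=n_ramets)

    survived = rng.binomial(1, params.survival_prob(z)).astype(float)
    size_t1 = np.full(n_ramets, np.nan)
    alive = survived == 1
    size_t1[alive] = rng.normal(params.growth_mean(z[alive]), params.growth_sd(z[alive]))

    flowered = rng.binomial(1, params.flowering_prob(z)).astype(float)
    n_flowers = np.zeros(n_ramets, dtype=float)
    fl = flowered == 1
    if fl.any():
        n_flowers[fl] = sample_conditional_flower_counts(
            params.flower_count_mean(z[fl]), params.phi, rng
        )

    total_flowers = float(n_flowers.sum())
    n_rec = int(rng.poisson(params.r_r * total_flowers))
    if n_rec > 0:
        a = (lo - params.mu_rd) / params.sigma_rd
        b = (hi - params.mu_rd) / params.sigma_rd
        rec_sizes = stats.truncnorm.rvs(
            a, b, loc=params.mu_rd, scale=params.sigma_rd, size=n_rec, random_state=rng
        )
    else:
        rec_sizes = np.empty(0)

    frame = pd.DataFrame(
        {
            "ramet_id": [f"R{i:05d}" for i in range(n_ramets)],
            "size_t": z,
            "survived": survived,
            "size_t1": size_t1,
            "flowered": flowered,
            "n_flowers": n_flowers,
            "is_recruit": np.zeros(n_ramets),
        }
    )
    if n_rec > 0:
        recruits = pd.DataFrame(
            {
                "ramet_id": [f"N{i:05d}" for i in range(n_rec)],
                "size_t": np.nan,
                "survived": np.nan,
                "size_t1": rec_sizes,
                "flowered": np.nan,
                "n_flowers": np.nan,
                "is_recruit": 1.0,
            }
        )
        frame = pd.concat([frame, recruits], ignore_index=True)
    return RametDataset(frame[COLUMNS], year_t=year_t, year_t1=year_t + 1).validate()


def generate_groundtruth_fixture(
    true_areas,
    bias_ratio: float,
    noise_sd: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic ground-truth calibration table.

    Emulates measuring targets of known area from an aerial mosaic with a
    multiplicative bias: measured = true · bias_ratio · (1 + ε),
    ε ~ Normal(0, noise_sd).  Returns a DataFrame with columns
    ``measured_m2`` and ``true_m2``.
    """
    true_areas = np.asarray(true_areas, dtype=float)
    if true_areas.size == 0:
        raise DegenerateDataError("true_areas must be non-empty")
    if np.any(true_areas <= 0):
        raise InvalidParameterError("all true_areas must be > 0")
    if bias_ratio <= 0:
        raise InvalidParameterError("bias_ratio must be > 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=true_areas.shape) if noise_sd > 0 else 0.0
    measured = true_areas * bias_ratio * (1.0 + eps)
    return pd.DataFrame({"measured_m2": measured, "true_m2": true_areas})
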