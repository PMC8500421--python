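"""Seeded generators of synthetic mortality / index data.

The generators emulate the statistical structure of a pastoral-region
livestock panel: a small number of sub-locations observed over two herding
seasons per year, with seasonal mortality rates averaging around 13%,
driven by a standardized forage index through a piecewise-linear (hinge)
response — mortality rises steeply as the index drops below about one
standard deviation under normal, and is flat above — plus occasional
index-independent shocks (e.g. disease outbreaks) that produce high
mortality even in good forage seasons.

All outputs are deterministic functions of the scenario seed.  The noise
model is additive on the mortality scale with truncation to [0, 1]; it is a
stand-in for survey sampling error, not a claim about any real survey.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OutcomeDistribution, validate_season_frame
from .loss_models import fit_segmented, goodness_of_fit

__all__ = [
    "ScenarioConfig",
    "gen_mortality_index",
    "gen_matched_r2_pair",
    "gen_outcome_distribution",
]

_SEASONS = ("LRLD", "SRSD")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic mortality/index scenario.

    Defaults follow the structure of the motivating panel: 15 sub-locations
    x 2 seasons/year x 8 years (240 records), hinge breakpoint at z = -1
    with slope -0.25 mortality per z-unit below it and flat above, base
    (good-season) mortality 0.10, homoskedastic noise sd 0.05, and
    index-independent disease shocks with probability 0.03 and magnitude
    uniform on [0.2, 0.4].  Together these put overall mean mortality near
    0.13.
    """

    n_locations: int = 15
    years: int = 8
    start_year: int = 2008
    psi: float = -1.0
    slope_below: float = -0.25
    slope_above: float = 0.0
    base_mortality: float = 0.10
    noise_sd: float = 0.05
    noise_placement: str = "homoskedastic"
    #: mortality level above which noise is considered "high-mortality";
    #: also the default contract trigger
    high_mortality_level: float = 0.23
    shock_prob: float = 0.03
    shock_range: tuple[float, float] = (0.2, 0.4)
    index_name: str = "NDVI"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_locations < 1 or self.years < 1:
            raise ValueError("need at least one location and one year")
        if self.noise_sd < 0 or self.shock_prob < 0 or self.shock_prob > 1:
            raise ValueError("invalid noise or shock parameters")
        if self.noise_placement not in (
            "homoskedastic",
            "high_mortality_heavy",
            "low_mortality_heavy",
        ):
            raise ValueError(f"unknown noise placement {self.noise_placement!r}")

    @property
    def n_records(self) -> int:
        return self.n_locations * self.years * len(_SEASONS)


def _hinge_mean(z: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    dz = z - cfg.psi
    return cfg.base_mortality + np.where(
        z < cfg.psi, cfg.slope_below * dz, cfg.slope_above * dz
    )


def _noise_sd_per_obs(mean_m: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    """Per-observation noise sd under the chosen placement mode.

    Heteroskedastic modes reallocate variance between high- and
    low-mortality states at fixed average variance (heavy group gets 10x
    the variance of the light group), so total noise energy is comparable
    across modes.
    """
    n = mean_m.size
    if cfg.noise_placement == "homoskedastic":
        return np.full(n, cfg.noise_sd)
    high = mean_m > cfg.high_mortality_level
    if cfg.noise_placement == "high_mortality_heavy":
        heavy = high
    else:
        heavy = ~high
    w = np.where(heavy, 10.0, 1.0)
    # normalize so the mean variance equals noise_sd^2
    var = w * (n * cfg.noise_sd**2 / w.sum())
    return np.sqrt(var)


def gen_mortality_index(config: ScenarioConfig = ScenarioConfig()) -> pd.DataFrame:
    """Generate one synthetic location-season panel.

    Returns the canonical long table with columns (location, year, season,
    mortality, <index_name>, z_latent).  ``z_latent`` is the generator's
    true standardized forage score; the raw index column is a per-location
    affine transform of it, so the standard pipeline (z-scoring the raw
    index per location) approximately recovers ``z_latent``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    locs = [f"L{i:02d}" for i in range(1, cfg.n_locations + 1)]
    keys = [
        (loc, cfg.start_year + y, s)
        for loc in locs
        for y in range(cfg.years)
        for s in _SEASONS
    ]
    n = len(keys)

    z = rng.standard_normal(n)
    mean_m = _hinge_mean(z, cfg)
    noise = rng.standard_normal(n) * _noise_sd_per_obs(mean_m, cfg)
    shock = (rng.random(n) < cfg.shock_prob) * rng.uniform(
        cfg.shock_range[0], cfg.shock_range[1], n
    )
    mortality = np.clip(mean_m + noise + shock, 0.0, 1.0)

    # raw index: location-specific level and scale, NDVI-like magnitudes
    loc_mu = rng.uniform(0.2, 0.5, cfg.n_locations)
    loc_sigma = 0.15 * loc_mu
    loc_of = np.repeat(np.arange(cfg.n_locations), cfg.years * len(_SEASONS))
    raw = loc_mu[loc_of] + loc_sigma[loc_of] * z

    df = pd.DataFrame(
        {
            "location": [k[0] for k in keys],
            "year": [k[1] for k in keys],
            "season": [k[2] for k in keys],
            "mortality": mortality,
            cfg.index_name: raw,
            "z_latent": z,
        }
    )
    return validate_season_frame(df)


def gen_matched_r2_pair(
    config: ScenarioConfig = ScenarioConfig(),
    *,
    r2_tol: float = 0.03,
    heavy_share: float = 1.0,
    error_sd: float = 0.06,
    max_retries: int = 50,
) -> pd.DataFrame:
    """Two candidate indices with matched R-squared but different error placement.

    Shares one mortality series (linear in a latent score, so both indices
    face the same signal) and builds two noisy index columns at fixed total
    error variance: ``err_high_mortality`` concentrates its prediction
    errors in payout-relevant high-mortality seasons (producing severe
    false negatives), ``err_low_mortality`` concentrates them where losses
    are small.  With the default ``heavy_share`` of 1 the whole error
    budget sits in the targeted group and the other group is error-free,
    the sharpest version of the contrast.  Noise draws are rescaled within
    each group to hit the variance budget, and draws are retried (new
    noise only) until the
    segmented-model R-squared of the two indices differs by less than
    ``r2_tol``.

    Welfare metrics should prefer the second index even though generic
    goodness of fit cannot tell them apart.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    locs = [f"L{i:02d}" for i in range(1, cfg.n_locations + 1)]
    keys = [
        (loc, cfg.start_year + y, s)
        for loc in locs
        for y in range(cfg.years)
        for s in _SEASONS
    ]
    n = len(keys)

    beta0, beta1 = 0.13, -0.10
    z = rng.standard_normal(n)
    mortality = np.clip(beta0 + beta1 * z + 0.02 * rng.standard_normal(n), 0.0, 1.0)
    if error_sd == 0:
        df = pd.DataFrame(
            {
                "location": [k[0] for k in keys],
                "year": [k[1] for k in keys],
                "season": [k[2] for k in keys],
                "mortality": mortality,
                "err_high_mortality": z,
                "err_low_mortality": z,
            }
        )
        return validate_season_frame(df)

    high = mortality > cfg.high_mortality_level
    if high.sum() < 4 or (~high).sum() < 4:
        raise ValueError(
            "too few high- (or low-) mortality seasons to place errors; "
            "increase the sample size"
        )

    budget = n * error_sd**2

    def _index_with_errors(heavy_mask: np.ndarray) -> np.ndarray:
        eta = rng.standard_normal(n)
        out = np.empty(n)
        for mask, share in ((heavy_mask, heavy_share), (~heavy_mask, 1 - heavy_share)):
            target_var = share * budget / mask.sum()
            g = eta[mask]
            rms = np.sqrt(np.mean(g**2))
            out[mask] = g / rms * np.sqrt(target_var)
        # error on the mortality scale, mapped to the index scale
        return z + out / abs(beta1)

    for _ in range(max_retries):
        idx_a = _index_with_errors(high)  # errors at high mortality
        idx_b = _index_with_errors(~high)  # errors at low mortality
        r2_a = goodness_of_fit(fit_segmented(idx_a, mortality), idx_a, mortality)[
            "r_squared"
        ]
        r2_b = goodness_of_fit(fit_segmented(idx_b, mortality), idx_b, mortality)[
            "r_squared"
        ]
        if abs(r2_a - r2_b) < r2_tol:
            df = pd.DataFrame(
                {
                    "location": [k[0] for k in keys],
                    "year": [k[1] for k in keys],
                    "season": [k[2] for k in keys],
                    "mortality": mortality,
                    "err_high_mortality": idx_a,
                    "err_low_mortality": idx_b,
                }
            )
            out = validate_season_frame(df)
            out.attrs["r2"] = {"err_high_mortality": r2_a, "err_low_mortality": r2_b}
            return out
    raise RuntimeError(
        f"could not match R^2 within {r2_tol} after {max_retries} draws; "
        "try a larger sample size"
    )


def gen_outcome_distribution(n_bins: int = 25) -> OutcomeDistribution:
    """Stylized discrete mortality-risk distribution.

    ``n_bins`` mortality states spread over [0, 0.65] with right-skewed,
    exponentially decaying probabilities (gamma with shape 1, mean 0.13),
    renormalized over the support.  The exponential tail is heavy enough
    that the perfect contract with a 23% trigger has an actuarially fair
    price around 2% of insured value (about $20 per $1000-TLU).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    from scipy import stats

    m = np.linspace(0.0, 0.65, n_bins)
    shape, scale = 1.0, 0.13
    # bin edges midway between states; mass from the gamma CDF
    edges = np.concatenate([[0.0], (m[1:] + m[:-1]) / 2, [np.inf]])
    pi = np.diff(stats.gamma.cdf(edges, a=shape, scale=scale))
    pi = pi / pi.sum()
    return OutcomeDistribution(mortality=m, probability=pi)
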