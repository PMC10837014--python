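"""Synthetic populations, phenotypes and weather with the structure the
pipeline assumes.

The generator emulates a biparental inbred mapping population (RIL or BIL)
with markers in linkage along chromosomes, sparse additive marker effects on
both reaction-norm parameters, environments on an environmental-mean
gradient, phenotypes built generatively from the linear reaction-norm model
``Y_ij = mu_i + beta_i I_j + noise``, and sinusoidal-seasonal daily weather
whose amplitude grows with latitude.  Defaults are shaped like a sorghum
flowering-time study (trait in GDD, 9 environments spanning ~950 GDD of
environmental mean) at a reduced population size for fast tests; the
full-scale shape (237 lines x 1462 markers) sits behind a flag.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enviro_index import DailyWeather
from .errors import InvalidArgumentError
from .genomic_prediction import MarkerMatrix
from .reaction_norm import PhenotypeMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_biparental_genotypes",
    "simulate_study",
    "simulate_weather",
    "default_scenario",
]


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated study, sufficient to regenerate it."""

    genotype_ids: list[str]
    intercepts: np.ndarray
    slopes: np.ndarray
    intercept_effects: np.ndarray
    slope_effects: np.ndarray
    intercept_qtl: np.ndarray
    slope_qtl: np.ndarray
    noise_sd: float
    env_index: np.ndarray
    seed: int


def _haldane_recomb(distance_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * distance_cm / 100.0))


def simulate_biparental_genotypes(
    n_lines: int,
    n_markers: int,
    n_chromosomes: int = 10,
    population_type: str = "RIL",
    seed: int = 0,
    chrom_length_cm: float = 150.0,
) -> MarkerMatrix:
    """Markers in linkage blocks along evenly spaced chromosome maps.

    RIL: fully homozygous lines, codes in {-1, +1}, simulated as a Markov
    chain along each chromosome with switch probability 2r/(1+2r) (the extra
    recombination accumulated over selfing generations) where r is Haldane's
    recombination fraction at the inter-marker distance.  BIL: two gamete
    chains per line with the donor allele held at 25% frequency, so codes in
    {-1, 0, +1} skewed 3:1 toward the recurrent parent.
    """
    if population_type not in ("RIL", "BIL"):
        raise InvalidArgumentError(f"unknown population_type {population_type!r}")
    if n_lines < 2:
        raise InvalidArgumentError("need >=2 lines")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_chromosomes, n_markers // n_chromosomes)
    sizes[: n_markers % n_chromosomes] += 1

    chrom_codes = []
    for size in sizes:
        if size == 0:
            continue
        spacing = chrom_length_cm / max(size - 1, 1)
        r = _haldane_recomb(np.full(size - 1, spacing))
        if population_type == "RIL":
            switch = 2.0 * r / (1.0 + 2.0 * r)
            first = rng.choice([-1.0, 1.0], size=n_lines)
            cols = [first]
            for p in switch:
                flip = rng.random(n_lines) < p
                cols.append(np.where(flip, -cols[-1], cols[-1]))
            chrom_codes.append(np.column_stack(cols))
        else:
            # per-gamete chain with stationary donor frequency 0.25
            pi_d = 0.25
            geno = np.zeros((n_lines, size))
            for _ in range(2):
                state = (rng.random(n_lines) < pi_d).astype(float)  # 1 = donor
                cols = [state]
                for p in r:
                    # switching kernel preserving the 75/25 stationary mix
                    to_d = np.minimum(2.0 * p * pi_d, 1.0)
                    to_r = np.minimum(2.0 * p * (1 - pi_d), 1.0)
                    u = rng.random(n_lines)
                    prev = cols[-1]
                    nxt = np.where(prev == 1.0, np.where(u < to_r, 0.0, 1.0),
                                   np.where(u < to_d, 1.0, 0.0))
                    cols.append(nxt)
                geno += np.column_stack(cols)
            chrom_codes.append(geno - 1.0)  # dosage 0/1/2 -> -1/0/+1
    codes = np.hstack(chrom_codes)
    return MarkerMatrix(
        genotype_ids=[f"L{i:04d}" for i in range(n_lines)],
        marker_ids=[f"M{j:04d}" for j in range(n_markers)],
        codes=codes,
    )


def simulate_study(
    pop: MarkerMatrix,
    n_env: int = 9,
    index_range: float = 950.0,
    n_qtl: int = 10,
    effect_sd_intercept: float = 80.0,
    effect_sd_slope: float = 0.15,
    noise_sd: float = 30.0,
    baseline_intercept: float = 2000.0,
    baseline_slope: float = 1.0,
    index_jitter: float = 0.0,
    qtl_overlap: bool = False,
    seed: int = 0,
) -> tuple[PhenotypeMatrix, SyntheticTruth]:
    """Phenotypes from the linear reaction-norm model with marker-based truth.

    True intercepts and slopes are baseline + marker codes . sparse effect
    vectors (disjoint QTL for the two parameters unless ``qtl_overlap``);
    effect sizes are scaled so the genetic standard deviations of intercept
    and slope roughly match ``effect_sd_intercept`` / ``effect_sd_slope``.
    Environment index values are evenly spaced over ``index_range`` (plus
    optional jitter) and centred.
    """
    if n_env < 2:
        raise InvalidArgumentError("need >=2 environments")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    n_markers = len(pop.marker_ids)
    if n_qtl > n_markers:
        raise InvalidArgumentError("n_qtl exceeds marker count")
    if not qtl_overlap and 2 * n_qtl > n_markers:
        raise InvalidArgumentError("disjoint QTL need 2*n_qtl <= n_markers")
    rng = np.random.default_rng(seed)
    Z = pop.imputed()
    n_lines = Z.shape[0]

    perm = rng.permutation(n_markers)
    qtl_mu = np.sort(perm[:n_qtl])
    qtl_beta = np.sort(perm[:n_qtl]) if qtl_overlap else np.sort(perm[n_qtl: 2 * n_qtl])

    def genetic_values(qtl: np.ndarray, target_sd: float) -> np.ndarray:
        eff = np.zeros(n_markers)
        eff[qtl] = rng.normal(0.0, 1.0, size=len(qtl))
        g = Z @ eff
        sd = g.std()
        if sd > 0:
            eff *= target_sd / sd
            g = Z @ eff
        # centre over the population so baselines are exact population means
        # (joint regression identifies slopes only up to their mean, fixed at 1)
        return eff, g - g.mean()

    a_mu, g_mu = genetic_values(qtl_mu, effect_sd_intercept)
    a_beta, g_beta = genetic_values(qtl_beta, effect_sd_slope)
    mu = baseline_intercept + g_mu
    beta = baseline_slope + g_beta

    I = np.linspace(-index_range / 2.0, index_range / 2.0, n_env)
    if index_jitter > 0:
        I = I + rng.normal(0.0, index_jitter, size=n_env)
    I = I - I.mean()
    Y = mu[:, None] + np.outer(beta, I) + rng.normal(0.0, noise_sd, (n_lines, n_env))

    pheno = PhenotypeMatrix(
        genotype_ids=list(pop.genotype_ids),
        environment_ids=[f"E{j:02d}" for j in range(n_env)],
        values=Y,
    )
    truth = SyntheticTruth(
        genotype_ids=list(pop.genotype_ids), intercepts=mu, slopes=beta,
        intercept_effects=a_mu, slope_effects=a_beta,
        intercept_qtl=qtl_mu, slope_qtl=qtl_beta,
        noise_sd=noise_sd, env_index=I, seed=seed,
    )
    return pheno, truth


def default_scenario(seed: int = 0, full_scale: bool = False, **overrides):
    """The default synthetic study: markers, phenotypes and truth in one call.

    CI scale is 64 lines x 200 markers; ``full_scale`` switches to the
    237 x 1462 sorghum-study shape.
    """
    n_lines, n_markers = (237, 1462) if full_scale else (64, 200)
    pop = simulate_biparental_genotypes(n_lines, n_markers, seed=seed)
    pheno, truth = simulate_study(pop, seed=seed + 1, **overrides)
    return pop, pheno, truth


def simulate_weather(
    sites: dict[str, float],
    years: list[int],
    seed: int = 0,
    seasonal_amplitude_ref: float = 15.0,
    year_effect_sd: float = 1.5,
    daily_noise_sd: float = 1.5,
    diurnal_half_range: float = 5.0,
    tropical_mean: float = 27.0,
    lapse_per_degree: float = 0.6,
) -> dict[str, DailyWeather]:
    """Sinusoidal-seasonal daily weather per site spanning the given years.

    Daily mean temperature = site mean + seasonal sinusoid + an annual year
    effect + daily noise; tmax/tmin sit a fixed half-range above/below.
    The site mean holds at ``tropical_mean`` inside the tropics and declines
    by ``lapse_per_degree`` per degree beyond |latitude| 20; the seasonal
    half-amplitude is ``seasonal_amplitude_ref`` at the 45-degree reference
    latitude and scales with (latitude/45)^2, so tropical sites barely cycle
    while temperate sites swing widely (the sinusoid peaks ~20 July in the
    northern hemisphere, flipped in the southern).  Interannual (year-effect)
    variability likewise grows away from the equator: ``year_effect_sd`` is
    the 45-degree value, scaled by 0.2 + (latitude/45)^2 so tropical years
    resemble each other while temperate years differ.  One extra trailing year
    of records is generated so windows planted late in the final year stay
    covered.
    """
    if seasonal_amplitude_ref < 0 or year_effect_sd < 0 or daily_noise_sd < 0:
        raise InvalidArgumentError("amplitude and sds must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    all_years = sorted(years) + [max(years) + 1]
    for site, lat in sorted(sites.items()):
        dates = pd.date_range(dt.date(all_years[0], 1, 1),
                              dt.date(all_years[-1], 12, 31), freq="D")
        doy = dates.dayofyear.to_numpy()
        amplitude = seasonal_amplitude_ref * (lat / 45.0) ** 2
        phase = np.sign(lat) if lat != 0 else 1.0
        seasonal = amplitude * phase * np.cos(2.0 * np.pi * (doy - 201) / 365.25)
        year_sd = year_effect_sd * (0.2 + (lat / 45.0) ** 2)
        year_effects = dict(zip(all_years, rng.normal(0.0, year_sd,
                                                      len(all_years))))
        yr = np.array([year_effects[y] for y in dates.year])
        site_mean = tropical_mean - lapse_per_degree * max(0.0, abs(lat) - 20.0)
        tmean = (site_mean + seasonal + yr
                 + rng.normal(0.0, daily_noise_sd, len(dates)))
        frame = pd.DataFrame({"tmax": tmean + diurnal_half_range,
                              "tmin": tmean - diurnal_half_range}, index=dates)
        out[site] = DailyWeather(site=site, latitude=lat, longitude=0.0, frame=frame)
    return out
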