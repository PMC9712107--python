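"""Synthetic fixtures with known ground truth.

Generates idealized but realistically shaped inputs for every analysis in
the package: an oligotrophic subtropical water column (exponentially
attenuated PAR, sigmoidal nutriclines, a deep chlorophyll-maximum-like
cell distribution), sparse observed-growth profiles that stay at
0.1-0.25 day^-1 down to 150 m, a seasonal mixed-layer cycle with
depth-structured ecotype niches, and single-cell isotope enrichments
drawn around known true uptake rates.  Every generator is a pure function
of its spec and seed, and ground truth is returned alongside the data so
downstream tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .isotopes import NATURAL_13C, NATURAL_15N, SingleCellMeasurement
from .lightscape import EcotypeTimeSeries, photic_depth
from .profiles import EnvironmentProfile

__all__ = [
    "SyntheticSpec",
    "make_environment",
    "make_observed_growth",
    "make_timeseries",
    "make_single_cells",
    "ObservedGrowth",
    "TimeseriesTruth",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults describe a stratified subtropical oligotrophic column:
    noon surface PAR 600 umol photons m^-2 s^-1 attenuating at
    0.045 m^-1, nutriclines near 110 m, observed growth declining from
    ~0.5 day^-1 at the surface to a deep plateau of ~0.17 day^-1, a
    winter-deep/summer-shallow mixed layer, ecotype depth niches ordered
    HL above LL, and single-cell truth at the field rates
    mu_C = 0.024 day^-1, mu_N = 0.16 day^-1.
    """

    # light
    surface_noon_par: float = 600.0
    k_d: float = 0.045
    latitude: float = 22.75
    day_of_year: int = 190
    # depth grid
    depth_max: float = 200.0
    dz: float = 5.0
    # nutriclines (sigmoid from surface to deep value)
    din_surface: float = 1.0e-5   # mol N m^-3 (10 nmol l^-1)
    din_deep: float = 3.0e-3
    po4_surface: float = 5.0e-6   # mol P m^-3
    po4_deep: float = 2.0e-4
    nutricline_mid: float = 110.0
    nutricline_width: float = 12.0
    include_fe: bool = False
    fe_surface: float = 0.02      # nmol l^-1, below typical detection
    fe_deep: float = 0.6
    # cell density
    cells_surface: float = 1.2e11  # cells m^-3
    cells_background: float = 1.0e10
    dcm_depth: float = 110.0
    dcm_width: float = 15.0
    dcm_amplitude: float = 1.0e11
    # observed growth template
    mu_obs_surface: float = 0.5
    mu_obs_deep: float = 0.17
    mu_obs_transition: float = 60.0
    mu_obs_width: float = 20.0
    obs_spacing: float = 15.0
    obs_gap_fraction: float = 0.2
    # seasonal cycle / ecotypes
    mld_winter_max: float = 180.0
    mld_summer_min: float = 30.0
    mld_peak_doy: float = 45.0
    par_seasonal_amplitude: float = 150.0
    n_years: int = 5
    # single cells
    mu_c_true: float = 0.024
    mu_n_true: float = 0.16
    incubation_days: float = 3.5 / 24.0
    source_c: float = 0.45
    source_n: float = 0.95
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("surface_noon_par", "k_d", "dz", "depth_max",
                     "nutricline_width", "mu_obs_width", "dcm_width",
                     "incubation_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _sigmoid_increase(depth, surface, deep, midpoint, width):
    """Surface-depleted, deep-replete sigmoid with value (surface+deep)/2
    at the midpoint."""
    return surface + (deep - surface) / (1.0 + np.exp(-(depth - midpoint) / width))


def growth_template(spec: SyntheticSpec, depth) -> np.ndarray:
    """Smooth observed-growth template: surface maximum, deep plateau."""
    depth = np.asarray(depth, dtype=float)
    return spec.mu_obs_deep + (spec.mu_obs_surface - spec.mu_obs_deep) / (
        1.0 + np.exp((depth - spec.mu_obs_transition) / spec.mu_obs_width)
    )


def make_environment(spec: SyntheticSpec,
                     with_observed_growth: bool = True) -> EnvironmentProfile:
    """Synthetic depth profile: exponential PAR, sigmoidal nutriclines.

    Deterministic given the spec (gap placement in the observed-growth
    column uses the spec's seed).
    """
    depth = np.arange(0.0, spec.depth_max + spec.dz / 2, spec.dz)
    par = spec.surface_noon_par * np.exp(-spec.k_d * depth)
    din = _sigmoid_increase(depth, spec.din_surface, spec.din_deep,
                            spec.nutricline_mid, spec.nutricline_width)
    po4 = _sigmoid_increase(depth, spec.po4_surface, spec.po4_deep,
                            spec.nutricline_mid, spec.nutricline_width)
    fe = None
    if spec.include_fe:
        fe = _sigmoid_increase(depth, spec.fe_surface, spec.fe_deep,
                               spec.nutricline_mid, spec.nutricline_width)
    cells = (spec.cells_background
             + (spec.cells_surface - spec.cells_background)
             / (1.0 + np.exp((depth - spec.nutricline_mid) / spec.dcm_width))
             + spec.dcm_amplitude
             * np.exp(-0.5 * ((depth - spec.dcm_depth) / spec.dcm_width) ** 2))
    mu_obs = None
    if with_observed_growth:
        obs = make_observed_growth(spec)
        mu_obs = np.full_like(depth, np.nan)
        inside = (depth >= obs.depth[0]) & (depth <= obs.depth[-1])
        mu_obs[inside] = np.interp(depth[inside], obs.depth, obs.mu_obs)
    return EnvironmentProfile(depth=depth, noon_par=par, din=din, po4=po4,
                              fe=fe, cell_density=cells, mu_obs=mu_obs,
                              latitude=spec.latitude,
                              day_of_year=spec.day_of_year)


@dataclass(frozen=True)
class ObservedGrowth:
    """Sparse observed-growth samples plus the underlying smooth template."""

    depth: np.ndarray
    mu_obs: np.ndarray
    gap_depths: np.ndarray
    template_depth: np.ndarray
    template_mu: np.ndarray


def make_observed_growth(spec: SyntheticSpec) -> ObservedGrowth:
    """Sample the growth template at sparse depths with seeded gaps.

    The deep plateau stays at or above 0.1 day^-1 down to 150 m by
    construction; gap positions are reproducible from the spec seed and
    never remove the two endpoint samples (interpolation, not
    extrapolation, fills them).
    """
    rng = np.random.default_rng(spec.seed)
    candidates = np.arange(0.0, min(spec.depth_max, 160.0) + 1e-9,
                           spec.obs_spacing)
    interior = np.arange(1, len(candidates) - 1)
    n_gaps = int(round(spec.obs_gap_fraction * len(interior)))
    gaps = rng.choice(interior, size=n_gaps, replace=False) if n_gaps else \
        np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(len(candidates)), gaps)
    dense = np.arange(0.0, spec.depth_max + 1e-9, 1.0)
    return ObservedGrowth(
        depth=candidates[keep],
        mu_obs=growth_template(spec, candidates[keep]),
        gap_depths=candidates[gaps],
        template_depth=dense,
        template_mu=growth_template(spec, dense),
    )


#: Ecotype depth niches (centre m, sigma m, peak cells m^-3): HL clades
#: shallow, LL clades successively deeper.
ECOTYPE_NICHES: dict[str, tuple[float, float, float]] = {
    "HLI": (30.0, 25.0, 1.0e11),
    "HLII": (60.0, 25.0, 1.5e11),
    "LLI": (90.0, 20.0, 2.5e10),
    "LLII-III": (110.0, 18.0, 8.0e9),
    "LLIV": (130.0, 20.0, 4.0e9),
}


@dataclass(frozen=True)
class TimeseriesTruth:
    """Analytic ground truth stored beside the seasonal fixture."""

    photic_depth_hl: np.ndarray
    stratified: np.ndarray
    below_photic_total_pct: np.ndarray
    below_photic_by_ecotype: dict[str, np.ndarray]
    stratified_mean_total_pct: float
    stratified_max_total_pct: float


def _gaussian_fraction_below(centre, sigma, z_split, z_min, z_max) -> float:
    """Analytic below-split mass fraction of a truncated Gaussian niche."""
    lo = ndtr((z_min - centre) / sigma)
    hi = ndtr((z_max - centre) / sigma)
    split = ndtr((z_split - centre) / sigma)
    return float((hi - split) / (hi - lo))


def make_timeseries(spec: SyntheticSpec) -> tuple[EcotypeTimeSeries, TimeseriesTruth]:
    """Seasonal MLD cycle with depth-structured ecotype profiles.

    Monthly dates over ``n_years``; the sinusoidal mixed layer crosses the
    HL photic depth twice a year, separating stratified summers from
    deep-mixing winters.  Ground truth below-photic fractions come from
    the analytic Gaussian niche integrals.
    """
    n = 12 * spec.n_years
    dates = pd.date_range("2015-01-15", periods=n, freq="MS") + pd.Timedelta(days=14)
    doy = dates.dayofyear.to_numpy(dtype=float)
    mean_mld = 0.5 * (spec.mld_winter_max + spec.mld_summer_min)
    amp_mld = 0.5 * (spec.mld_winter_max - spec.mld_summer_min)
    mld = mean_mld + amp_mld * np.cos(2 * np.pi * (doy - spec.mld_peak_doy) / 365.0)
    par0 = spec.surface_noon_par \
        - spec.par_seasonal_amplitude * np.cos(2 * np.pi * (doy - 200.0) / 365.0)
    k_d = np.full(n, spec.k_d)
    depth_grid = np.arange(0.0, spec.depth_max + spec.dz / 2, spec.dz)

    profiles = {}
    for name, (centre, sigma, peak) in ECOTYPE_NICHES.items():
        prof = peak * np.exp(-0.5 * ((depth_grid - centre) / sigma) ** 2)
        profiles[name] = np.tile(prof, (n, 1))

    series = EcotypeTimeSeries(dates=dates, mld=mld, surface_par=par0,
                               k_d=k_d, depth_grid=depth_grid,
                               profiles=profiles)

    pd_hl = photic_depth(par0, k_d, 10.0)
    stratified = mld < pd_hl
    z_min, z_max = depth_grid[0], depth_grid[-1]
    by_ecotype: dict[str, np.ndarray] = {}
    # Column-integrated Gaussian masses for the total-population fractions
    masses = {name: peak * sigma * np.sqrt(2 * np.pi)
              * (ndtr((z_max - c) / sigma) - ndtr((z_min - c) / sigma))
              for name, (c, sigma, peak) in ECOTYPE_NICHES.items()}
    total_pct = np.zeros(n)
    for name, (centre, sigma, peak) in ECOTYPE_NICHES.items():
        thr = series.threshold_for(name)
        pd_eco = photic_depth(par0, k_d, thr)
        by_ecotype[name] = 100.0 * np.array([
            _gaussian_fraction_below(centre, sigma, z, z_min, z_max)
            for z in pd_eco
        ])
        below_hl = np.array([
            _gaussian_fraction_below(centre, sigma, z, z_min, z_max)
            for z in pd_hl
        ])
        total_pct += 100.0 * below_hl * masses[name]
    total_pct /= sum(masses.values())
    truth = TimeseriesTruth(
        photic_depth_hl=pd_hl,
        stratified=stratified,
        below_photic_total_pct=total_pct,
        below_photic_by_ecotype=by_ecotype,
        stratified_mean_total_pct=float(np.mean(total_pct[stratified])),
        stratified_max_total_pct=float(np.max(total_pct[stratified])),
    )
    return series, truth


def make_single_cells(spec: SyntheticSpec, n_cells: int,
                      seed: Optional[int] = None) -> tuple[list[SingleCellMeasurement], dict]:
    """Single-cell isotope enrichments around known true uptake rates.

    Enrichments invert the linear-dilution rate formula at the true
    (mu_C, mu_N) and incubation duration, then apply multiplicative
    log-normal noise with median 1 (so the generated rate medians sit at
    the truth).  Returns the cells and a ground-truth dict.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = spec.incubation_days
    excess_c = spec.mu_c_true * t * (spec.source_c - NATURAL_13C)
    excess_n = spec.mu_n_true * t * (spec.source_n - NATURAL_15N)
    noise_c = np.exp(rng.normal(0.0, spec.noise_sigma, n_cells))
    noise_n = np.exp(rng.normal(0.0, spec.noise_sigma, n_cells))
    cells = [
        SingleCellMeasurement(
            atom_fraction_c=NATURAL_13C + excess_c * noise_c[i],
            atom_fraction_n=NATURAL_15N + excess_n * noise_n[i],
            source_c=spec.source_c,
            source_n=spec.source_n,
            incubation_duration=t,
            label=f"synthetic cell {i}",
        )
        for i in range(n_cells)
    ]
    truth = {
        "mu_c_true": spec.mu_c_true,
        "mu_n_true": spec.mu_n_true,
        "ratio_true": spec.mu_c_true / spec.mu_n_true,
        "noise_sigma": spec.noise_sigma,
        "incubation_days": t,
    }
    return cells, truth
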