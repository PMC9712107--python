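"""Photo-autotrophic growth from photosynthesis-irradiance physiology.

Carbon fixation follows the Platt photosynthesis-irradiance (P-I) curve:
chlorophyll-specific fixation rises with the initial slope ``alpha_chl``,
saturates at ``ps_chl`` and, with a positive photo-inhibition coefficient
``beta_chl``, declines again at high photon flux.  The carbon-specific,
daily-averaged fixation rate is the time average of the instantaneous
chlorophyll-specific rate scaled by the cellular chlorophyll-to-carbon
ratio, driven by noon PAR modulated over the diel cycle by solar geometry.

Because the chlorophyll-to-carbon ratio is itself a photo-acclimation state
that depends on growth rate and irradiance, the light-limited autotrophic
growth rate is obtained as a fixed point: the ratio sets the fixation rate,
the fixation rate (less maintenance respiration, capped by the
allocation-based maximum growth rate) sets the growth rate, and the growth
rate feeds back into the ratio.  :func:`solve_autotrophic_rate` iterates
this map to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotoPhysParams",
    "AllocationParams",
    "DielIrradiance",
    "FixedPointResult",
    "chl_specific_fixation",
    "diel_irradiance_factors",
    "daily_mean_fixation",
    "chl_to_carbon_ratio",
    "max_growth_rate",
    "solve_autotrophic_rate",
    "PHOTOPHYS_PRESETS",
    "SECONDS_PER_DAY",
]

SECONDS_PER_DAY = 86400.0

#: Irradiance floor used where the acclimation ratio would otherwise be
#: evaluated at I = 0 (dark water); the contracted form is undefined there.
IRRADIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class PhotoPhysParams:
    """Platt P-I curve coefficients for one ecotype/acclimation scenario.

    Parameters
    ----------
    ps_chl : float
        Chlorophyll-specific maximum fixation rate, mol C (mol Chl)^-1 s^-1.
    alpha_chl : float
        Initial slope of the P-I curve, mol C (mol Chl)^-1 s^-1 per
        (umol photons m^-2 s^-1).
    beta_chl : float
        Photo-inhibition coefficient, same units as ``alpha_chl``.
        Zero encodes the "without photo-inhibition" scenario.
    label : str
        Free-text ecotype/acclimation tag.
    """

    ps_chl: float
    alpha_chl: float
    beta_chl: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.ps_chl <= 0:
            raise ValueError("ps_chl must be > 0")
        if self.alpha_chl <= 0:
            raise ValueError("alpha_chl must be > 0")
        if self.beta_chl < 0:
            raise ValueError("beta_chl must be >= 0")

    def with_beta(self, beta_chl: float) -> "PhotoPhysParams":
        """Return a copy with a different photo-inhibition coefficient."""
        return PhotoPhysParams(self.ps_chl, self.alpha_chl, beta_chl, self.label)


@dataclass(frozen=True)
class AllocationParams:
    """Contracted macromolecular-allocation model.

    The chlorophyll-to-carbon ratio and the allocation-limited maximum
    growth rate are represented by compact functional forms that preserve
    the documented photo-acclimation monotonicities:

    * ``qChl/qC = (a0 + a1 * mu) / (1 + a2 * I)`` -- more chlorophyll per
      carbon at low light and at high growth rate;
    * ``mu_max(I) = mu_hat * I / (I + k_i)`` -- saturating in irradiance.

    ``k_r`` is the fixed maintenance respiration rate (day^-1) subtracted
    from gross daily fixation.  Coefficients are swappable for the full
    published allocation model by users who have it.
    """

    a0: float = 6.0e-4
    a1: float = 2.0e-4
    a2: float = 8.0e-4
    mu_hat: float = 0.8
    k_i: float = 20.0
    k_r: float = 0.05

    def __post_init__(self) -> None:
        if self.k_r < 0:
            raise ValueError("k_r must be >= 0")
        if min(self.a0, self.a1, self.a2, self.mu_hat, self.k_i) <= 0:
            raise ValueError("allocation coefficients must be > 0")


#: Named photo-physiology presets for a high-light-adapted ecotype
#: acclimated at 70 umol photons m^-2 s^-1 and a low-light-adapted ecotype
#: acclimated at 9 umol photons m^-2 s^-1.  The numerical values are this
#: package's calibrated defaults (editable via the YAML config), chosen so
#: that HL surface growth over a 600 umol photons noon profile falls around
#: 0.4-0.6 day^-1 and light-limited growth vanishes near 1-2% of surface
#: PAR; they are placeholders for laboratory-derived coefficients.
PHOTOPHYS_PRESETS: dict[str, PhotoPhysParams] = {
    "HL": PhotoPhysParams(ps_chl=0.030, alpha_chl=3.0e-4, beta_chl=3.0e-6,
                          label="HL MIT9215 @70"),
    "LL": PhotoPhysParams(ps_chl=0.015, alpha_chl=6.0e-4, beta_chl=3.0e-5,
                          label="LL MIT9211 @9"),
}


@dataclass(frozen=True)
class DielIrradiance:
    """Relative diel modulation of noon PAR over a 24 h cycle.

    ``factors`` are non-negative multipliers applied to the observed noon
    value; they are zero between astronomical sunset and sunrise and reach
    their maximum (1 at exact noon) around midday.
    """

    latitude: float
    day_of_year: int
    factors: np.ndarray = field(repr=False)

    @property
    def polar_night(self) -> bool:
        """True when the sun never rises (all factors zero)."""
        return bool(np.all(self.factors == 0.0))

    @property
    def daylength_hours(self) -> float:
        """Approximate daylength implied by the positive factors."""
        n = len(self.factors)
        return 24.0 * float(np.count_nonzero(self.factors > 0)) / n


def _solar_declination(day_of_year: int) -> float:
    """Solar declination (radians) from a standard cosine approximation."""
    return np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (day_of_year + 10) / 365.0)


def chl_specific_fixation(irradiance, params: PhotoPhysParams):
    """Chlorophyll-specific carbon fixation rate on the Platt P-I curve.

    ``ps_chl * (1 - exp(-alpha*I/ps_chl)) * exp(-beta*I/ps_chl)``, in
    mol C (mol Chl)^-1 s^-1.  Accepts scalars or arrays; irradiance must be
    non-negative.
    """
    irradiance = np.asarray(irradiance, dtype=float)
    if np.any(irradiance < 0):
        raise ValueError("irradiance must be >= 0")
    ps = params.ps_chl
    rate = ps * (-np.expm1(-params.alpha_chl * irradiance / ps)) \
        * np.exp(-params.beta_chl * irradiance / ps)
    return rate if rate.ndim else float(rate)


def diel_irradiance_factors(latitude: float, day_of_year: int,
                            n_steps_per_day: int = 24) -> DielIrradiance:
    """Relative PAR factors over one day from solar geometry.

    Factors are proportional to max(0, cos(solar zenith angle)) evaluated at
    the centre of each of ``n_steps_per_day`` equal intervals, normalized by
    the noon zenith cosine so that the exact-noon value is 1.  A polar-night
    input yields an all-zero, flagged result rather than an error.
    """
    if abs(latitude) > 90:
        raise ValueError("latitude must be within [-90, 90]")
    if not 1 <= int(day_of_year) <= 365:
        raise ValueError("day_of_year must be in 1..365")
    phi = np.deg2rad(latitude)
    delta = _solar_declination(int(day_of_year))
    hours = (np.arange(n_steps_per_day) + 0.5) * 24.0 / n_steps_per_day
    hour_angle = np.pi * (hours - 12.0) / 12.0
    cosz = np.sin(phi) * np.sin(delta) \
        + np.cos(phi) * np.cos(delta) * np.cos(hour_angle)
    noon_cosz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta)
    if noon_cosz <= 0:  # sun below horizon even at noon
        factors = np.zeros(n_steps_per_day)
    else:
        factors = np.clip(cosz, 0.0, None) / noon_cosz
    return DielIrradiance(latitude=latitude, day_of_year=int(day_of_year),
                          factors=factors)


def daily_mean_fixation(noon_irradiance: float, diel: DielIrradiance,
                        chl_to_c_ratio: float,
                        params: PhotoPhysParams) -> float:
    """Carbon-specific, daily-averaged carbon fixation rate (day^-1).

    Time average over the diel cycle of ``(qChl/qC) * P_chl(noon * factor)``
    converted from s^-1 to day^-1.
    """
    if chl_to_c_ratio <= 0:
        raise ValueError("chl_to_c_ratio must be > 0")
    if noon_irradiance < 0:
        raise ValueError("noon_irradiance must be >= 0")
    rates = chl_specific_fixation(noon_irradiance * diel.factors, params)
    return chl_to_c_ratio * float(np.mean(rates)) * SECONDS_PER_DAY


def chl_to_carbon_ratio(growth_rate: float, irradiance: float,
                        alloc: AllocationParams) -> float:
    """Photo-acclimated chlorophyll-to-carbon ratio (mol Chl (mol C)^-1).

    Decreasing in irradiance (cells shed antenna pigment in bright water)
    and non-decreasing in growth rate (faster-growing cells carry more
    photosynthetic machinery).  Undefined at zero irradiance; callers
    evaluating dark water should apply an irradiance floor.
    """
    if growth_rate < 0:
        raise ValueError("growth_rate must be >= 0")
    if irradiance <= 0:
        raise ValueError("irradiance must be > 0 (apply a floor for dark water)")
    return (alloc.a0 + alloc.a1 * growth_rate) / (1.0 + alloc.a2 * irradiance)


def max_growth_rate(irradiance: float, alloc: AllocationParams) -> float:
    """Allocation-limited maximum growth rate (day^-1), saturating in light."""
    irradiance = float(irradiance)
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    return alloc.mu_hat * irradiance / (irradiance + alloc.k_i)


@dataclass(frozen=True)
class FixedPointResult:
    """Converged light-limited growth solution.

    ``rate`` is the non-negative rate used in limitation profiles;
    ``raw_rate`` retains a possible negative value (respiration exceeding
    fixation in dark water), needed to diagnose respiration-driven decline.
    """

    rate: float
    raw_rate: float
    chl_to_c: float
    n_iterations: int


class FixedPointError(RuntimeError):
    """Raised when the growth/acclimation iteration fails to converge."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


def solve_autotrophic_rate(noon_irradiance: float, diel: DielIrradiance,
                           params: PhotoPhysParams, alloc: AllocationParams,
                           initial_guess: float = 0.1, tol: float = 1e-6,
                           max_iter: int = 200,
                           relaxation: float = 0.5) -> FixedPointResult:
    """Solve the coupled growth-rate / chl:C fixed point.

    Iterates ``ratio <- chl_to_carbon_ratio(rate, I_noon)`` and
    ``rate <- min(daily_mean_fixation(...) - k_r, mu_max(I_noon))`` with
    under-relaxation until successive rate iterates differ by less than
    ``tol`` (day^-1).  The acclimation state responds to the noon
    irradiance at the depth considered.
    """
    i_acclim = max(noon_irradiance, IRRADIANCE_FLOOR)
    rate = float(initial_guess)
    for iteration in range(1, max_iter + 1):
        ratio = chl_to_carbon_ratio(max(rate, 0.0), i_acclim, alloc)
        fixation = daily_mean_fixation(noon_irradiance, diel, ratio, params)
        new_raw = min(fixation - alloc.k_r, max_growth_rate(noon_irradiance, alloc))
        new_rate = (1.0 - relaxation) * rate + relaxation * new_raw
        if abs(new_rate - rate) < tol:
            ratio = chl_to_carbon_ratio(max(new_rate, 0.0), i_acclim, alloc)
            return FixedPointResult(rate=max(new_raw, 0.0), raw_rate=new_raw,
                                    chl_to_c=ratio, n_iterations=iteration)
        rate = new_rate
    raise FixedPointError(
        f"growth/acclimation iteration did not converge in {max_iter} steps",
        last_iterate=rate,
    )
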