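"""Depth-resolved autotrophic growth limitation and mixotrophy inference.

At each depth the light-, nitrogen-, phosphorus- and (when measured)
iron-limited specific growth rates are evaluated and the minimum taken as
the modelled purely photo-autotrophic growth rate (Liebig minimum law).
Where observed growth rates exceed this autotrophic ceiling, the shortfall
is interpreted as heterotrophically supported growth -- the signature of
mixotrophy.  Vertical integration with cell densities and a carbon quota
converts the rate profiles into areal production and the heterotrophic
fraction of total production.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .nutrients import NutrientUptakeParams, iron_specific_rate, michaelis_specific_rate
from .photo import (
    AllocationParams,
    PhotoPhysParams,
    diel_irradiance_factors,
    solve_autotrophic_rate,
)

__all__ = [
    "EnvironmentProfile",
    "GrowthProfileResult",
    "autotrophic_profile",
    "infer_heterotrophic_rate",
    "integrate_production",
    "mixotrophy_onset_depth",
    "scenario_envelope",
]

logger = logging.getLogger(__name__)

#: Default cellular carbon quota, g C cell^-1 (configurable; literature
#: placeholder for small Prochlorococcus cells).
DEFAULT_CARBON_QUOTA = 50e-15


@dataclass(frozen=True)
class EnvironmentProfile:
    """Co-registered water-column profile on a strictly increasing depth grid.

    Depths are positive-down metres.  ``noon_par`` is the observed noon PAR
    (umol photons m^-2 s^-1), ``din``/``po4`` are mol m^-3, ``fe`` is
    nmol l^-1 (optional), ``cell_density`` cells m^-3 (optional) and
    ``mu_obs`` observed growth rates in day^-1 (optional, NaN for gaps).
    """

    depth: np.ndarray
    noon_par: np.ndarray
    din: np.ndarray
    po4: np.ndarray
    fe: Optional[np.ndarray] = None
    cell_density: Optional[np.ndarray] = None
    mu_obs: Optional[np.ndarray] = None
    latitude: float = 22.75
    day_of_year: int = 190

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        if depth.size == 0:
            raise ValueError("profile is empty")
        if np.any(np.diff(depth) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        for name in ("depth", "noon_par", "din", "po4", "fe",
                     "cell_density", "mu_obs"):
            value = getattr(self, name)
            if value is None:
                continue
            value = np.asarray(value, dtype=float)
            if value.shape != depth.shape:
                raise ValueError(f"column '{name}' does not match the depth grid")
            object.__setattr__(self, name, value)
        for name in ("noon_par", "din", "po4", "fe"):
            value = getattr(self, name)
            if value is not None and np.any(value < 0):
                raise ValueError(f"column '{name}' has negative values")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class GrowthProfileResult:
    """Per-depth limitation diagnosis and inferred heterotrophic growth.

    ``table`` holds one row per depth with columns ``depth_m``, the
    component rates ``v_c_auto``, ``v_c_auto_raw``, ``v_n``, ``v_p``,
    ``v_fe`` (NaN when iron was not measured), the minimum-law rate
    ``mu_auto`` and its ``limiter``, and after heterotrophic inference
    ``mu_obs`` (linearly interpolated) and ``mu_het``.
    """

    table: pd.DataFrame
    scenario: str
    environment: EnvironmentProfile = field(repr=False)

    @property
    def mu_auto(self) -> np.ndarray:
        return self.table["mu_auto"].to_numpy()

    @property
    def mu_het(self) -> np.ndarray:
        return self.table["mu_het"].to_numpy()


def autotrophic_profile(env: EnvironmentProfile, photophys: PhotoPhysParams,
                        alloc: AllocationParams | None = None,
                        nutrients: NutrientUptakeParams | None = None,
                        scenario: str | None = None) -> GrowthProfileResult:
    """Evaluate component rates and the minimum-law autotrophic rate.

    One photo-physiology scenario per call; the four canonical scenarios
    are the HL and LL parameterizations each with and without
    photo-inhibition.  The iron component enters the minimum only when the
    profile carries iron data.
    """
    alloc = alloc or AllocationParams()
    nutrients = nutrients or NutrientUptakeParams()
    diel = diel_irradiance_factors(env.latitude, env.day_of_year)

    v_c, v_c_raw, chl2c = [], [], []
    for par in env.noon_par:
        sol = solve_autotrophic_rate(float(par), diel, photophys, alloc)
        v_c.append(sol.rate)
        v_c_raw.append(sol.raw_rate)
        chl2c.append(sol.chl_to_c)
    v_c = np.array(v_c)

    v_n = michaelis_specific_rate(env.din, nutrients.vmax_n, nutrients.k_n,
                                  nutrients.q_n)
    v_p = michaelis_specific_rate(env.po4, nutrients.vmax_p, nutrients.k_p,
                                  nutrients.q_p)
    components = {"light": v_c, "N": v_n, "P": v_p}
    if env.fe is not None:
        fe = np.where(env.fe < nutrients.fe_detection_limit,
                      nutrients.fe_detection_limit, env.fe)
        components["Fe"] = iron_specific_rate(fe, nutrients)
    else:
        logger.warning("profile lacks iron data; Fe omitted from the minimum law")

    names = list(components)
    stacked = np.vstack([components[k] for k in names])
    idx = np.argmin(stacked, axis=0)
    mu_auto = stacked[idx, np.arange(stacked.shape[1])]
    limiter = np.array(names, dtype=object)[idx]

    table = pd.DataFrame({
        "depth_m": env.depth,
        "v_c_auto": v_c,
        "v_c_auto_raw": np.array(v_c_raw),
        "chl_to_c": np.array(chl2c),
        "v_n": v_n,
        "v_p": v_p,
        "v_fe": components.get("Fe", np.full(len(env), np.nan)),
        "mu_auto": mu_auto,
        "limiter": limiter,
    })
    label = scenario or (photophys.label +
                         (" no-inhibition" if photophys.beta_chl == 0 else ""))
    return GrowthProfileResult(table=table, scenario=label, environment=env)


def _interpolate_observed(env: EnvironmentProfile) -> np.ndarray:
    """Linearly interpolate observed growth over gaps, never extrapolating."""
    if env.mu_obs is None or np.all(np.isnan(env.mu_obs)):
        raise ValueError("profile has no observed growth rates")
    obs = env.mu_obs
    valid = ~np.isnan(obs)
    mu = np.full_like(env.depth, np.nan, dtype=float)
    inside = (env.depth >= env.depth[valid].min()) & \
             (env.depth <= env.depth[valid].max())
    mu[inside] = np.interp(env.depth[inside], env.depth[valid], obs[valid])
    return mu


def infer_heterotrophic_rate(result: GrowthProfileResult) -> GrowthProfileResult:
    """Add observed growth and the inferred heterotrophic rate.

    ``mu_het = max(0, mu_obs - mu_auto)`` at each depth: growth beyond what
    photosynthesis alone can supply is attributed to organic-carbon
    assimilation.  Outside the observed depth span ``mu_obs`` (and hence
    ``mu_het``) is left undefined rather than extrapolated.
    """
    mu_obs = _interpolate_observed(result.environment)
    table = result.table.copy()
    table["mu_obs"] = mu_obs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN outside obs span
        table["mu_het"] = np.where(np.isnan(mu_obs), np.nan,
                                   np.maximum(0.0, mu_obs - table["mu_auto"]))
    return replace(result, table=table)


@dataclass(frozen=True)
class ProductionSummary:
    """Vertically integrated production split by carbon source."""

    autotrophic_g_c_m2_day: float
    heterotrophic_g_c_m2_day: float
    heterotrophic_fraction_pct: float
    below_onset_heterotrophic_fraction_pct: float
    onset_depth_m: Optional[float]


def integrate_production(result: GrowthProfileResult,
                         cell_density: np.ndarray | None = None,
                         carbon_quota: float = DEFAULT_CARBON_QUOTA) -> ProductionSummary:
    """Trapezoidal areal production (g C m^-2 day^-1) and heterotrophic shares.

    Integrates ``rate * density * quota`` over depth for the autotrophic
    and heterotrophic rate profiles; fractions are heterotrophic over total
    production, both for the whole column and restricted to depths below
    the mixotrophy onset depth (where heterotrophy exceeds photosynthesis).
    """
    env = result.environment
    if cell_density is None:
        cell_density = env.cell_density
    if cell_density is None:
        raise ValueError("cell density required to integrate production")
    cell_density = np.asarray(cell_density, dtype=float)
    if np.any(cell_density < 0):
        raise ValueError("cell densities must be >= 0")
    if "mu_het" not in result.table:
        raise ValueError("run infer_heterotrophic_rate first")

    depth = env.depth
    mu_auto = result.mu_auto
    mu_het = np.nan_to_num(result.mu_het, nan=0.0)
    auto_rate = mu_auto * cell_density * carbon_quota
    het_rate = mu_het * cell_density * carbon_quota
    auto_areal = float(np.trapezoid(auto_rate, depth))
    het_areal = float(np.trapezoid(het_rate, depth))
    total = auto_areal + het_areal
    frac = 100.0 * het_areal / total if total > 0 else np.nan

    onset, _ = mixotrophy_onset_depth(result)
    if onset is None:
        below_frac = 0.0 if het_areal == 0 else np.nan
    else:
        fine = np.union1d(depth, [onset])
        fine = fine[fine >= onset]
        a = float(np.trapezoid(np.interp(fine, depth, auto_rate), fine))
        h = float(np.trapezoid(np.interp(fine, depth, het_rate), fine))
        below_frac = 100.0 * h / (a + h) if (a + h) > 0 else np.nan
    return ProductionSummary(auto_areal, het_areal, frac, below_frac, onset)


def _first_crossing(depth: np.ndarray, signal: np.ndarray) -> Optional[float]:
    """Shallowest linearly interpolated zero up-crossing of ``signal``."""
    valid = ~np.isnan(signal)
    d, s = depth[valid], signal[valid]
    if len(d) == 0 or not np.any(s > 0):
        return None
    if s[0] > 0:
        return float(d[0])
    i = int(np.argmax(s > 0))
    d0, d1, s0, s1 = d[i - 1], d[i], s[i - 1], s[i]
    if s1 == s0:
        return float(d1)
    return float(d0 + (0.0 - s0) * (d1 - d0) / (s1 - s0))


def mixotrophy_onset_depth(result: GrowthProfileResult,
                           k_d: float | None = None) -> tuple[Optional[float], Optional[float]]:
    """Depth where heterotrophy first exceeds photosynthesis, and PAR there.

    Returns ``(onset_depth_m, par_at_onset)``; both ``None`` when
    heterotrophy never dominates.  The first depth with any positive
    ``mu_het`` is available via :func:`mixotrophy_first_positive`.
    """
    if "mu_het" not in result.table:
        raise ValueError("run infer_heterotrophic_rate first")
    env = result.environment
    onset = _first_crossing(env.depth, result.mu_het - result.mu_auto)
    if onset is None:
        return None, None
    par = float(np.interp(onset, env.depth, env.noon_par))
    return onset, par


def mixotrophy_first_positive(result: GrowthProfileResult) -> Optional[float]:
    """Shallowest depth at which any heterotrophic support is inferred."""
    if "mu_het" not in result.table:
        raise ValueError("run infer_heterotrophic_rate first")
    return _first_crossing(result.environment.depth, result.mu_het)


def scenario_envelope(results: list[GrowthProfileResult]) -> pd.DataFrame:
    """Per-depth min/max of ``mu_auto`` across scenarios (extreme-range band)."""
    if not results:
        raise ValueError("no scenarios given")
    depth = results[0].environment.depth
    stacked = np.vstack([r.mu_auto for r in results])
    return pd.DataFrame({
        "depth_m": depth,
        "mu_auto_min": stacked.min(axis=0),
        "mu_auto_max": stacked.max(axis=0),
    })
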