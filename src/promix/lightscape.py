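"""Ecotype light thresholds, photic depths and below-photic cell fractions.

High-light (HL) and low-light (LL) adapted *Prochlorococcus* strains have
experimentally determined minimal light requirements for active growth
(defaults 10 and 2.8 umol photons m^-2 s^-1).  With exponentially
attenuated PAR, the photic depth for a threshold ``I_th`` is the closed
form ``ln(I_0 / I_th) / K_d``.  Over a seasonal time series, the analysis
is restricted to stratified dates -- mixed layer shallower than the photic
depth -- because during deep mixing cells below the photic depth can still
be carried up into the light.  The headline statistic is the stratified-
period mean (and maximum) percentage of cells living below their photic
depth, i.e. without enough light for purely photo-autotrophic growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "HL_THRESHOLD",
    "LL_THRESHOLD",
    "EcotypeTimeSeries",
    "photic_depth",
    "stratified_mask",
    "fraction_below_photic",
    "stratified_mean_fraction",
    "timeseries_fractions",
]

#: Minimal light supporting growth of HL-adapted strains, umol photons m^-2 s^-1.
HL_THRESHOLD = 10.0
#: Minimal light supporting growth of LL-adapted strains.
LL_THRESHOLD = 2.8


@dataclass
class EcotypeTimeSeries:
    """Seasonal series of MLD, surface PAR, attenuation and ecotype profiles.

    ``profiles`` maps ecotype name -> array of shape (n_dates, n_depths)
    with cell concentrations (cells m^-3) on the shared ``depth_grid``.
    ``thresholds`` maps ecotype name -> light threshold; names absent from
    the map fall back to the HL/LL defaults by prefix.
    """

    dates: pd.DatetimeIndex
    mld: np.ndarray
    surface_par: np.ndarray
    k_d: np.ndarray
    depth_grid: np.ndarray
    profiles: Mapping[str, np.ndarray] = field(default_factory=dict)
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.dates)
        for name in ("mld", "surface_par", "k_d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            if len(arr) != n:
                raise ValueError(f"'{name}' does not match the date index")
            setattr(self, name, arr)
        if np.any(self.mld <= 0):
            raise ValueError("mixed layer depths must be > 0")
        for name, prof in self.profiles.items():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (n, len(self.depth_grid)):
                raise ValueError(f"profile '{name}' has wrong shape")
            if np.any(prof < 0):
                raise ValueError(f"profile '{name}' has negative cells")

    def threshold_for(self, ecotype: str) -> float:
        if ecotype in self.thresholds:
            return float(self.thresholds[ecotype])
        return LL_THRESHOLD if ecotype.upper().startswith("LL") else HL_THRESHOLD


def photic_depth(surface_par, k_d, threshold):
    """Depth (m) where attenuated PAR falls to the ecotype's threshold.

    ``ln(surface_par / threshold) / k_d``; zero when the surface is already
    at or below the threshold.
    """
    surface_par = np.asarray(surface_par, dtype=float)
    k_d = np.asarray(k_d, dtype=float)
    if np.any(k_d <= 0):
        raise ValueError("k_d must be > 0")
    if np.any(np.asarray(threshold) <= 0) or np.any(surface_par <= 0):
        raise ValueError("surface_par and threshold must be > 0")
    depth = np.log(surface_par / threshold) / k_d
    depth = np.maximum(depth, 0.0)
    return depth if depth.ndim else float(depth)


def stratified_mask(mld_series, photic_depth_series) -> np.ndarray:
    """True where the mixed layer is shallower than the photic depth."""
    mld = np.asarray(mld_series, dtype=float)
    pd_ = np.asarray(photic_depth_series, dtype=float)
    if mld.shape != pd_.shape:
        raise ValueError("series lengths differ")
    return mld < pd_


def fraction_below_photic(profile, depth_grid, photic_depth_m) -> float:
    """Percentage of column-integrated cells below the photic depth.

    Trapezoidal integration on the native grid; the layer straddling the
    photic depth is split linearly.  Undefined (NaN) for an empty column.
    """
    profile = np.asarray(profile, dtype=float)
    depth_grid = np.asarray(depth_grid, dtype=float)
    total = float(np.trapezoid(profile, depth_grid))
    if total <= 0:
        return float("nan")
    if photic_depth_m <= depth_grid[0]:
        return 100.0
    if photic_depth_m >= depth_grid[-1]:
        return 0.0
    split = np.union1d(depth_grid, [photic_depth_m])
    values = np.interp(split, depth_grid, profile)
    below = split >= photic_depth_m
    below_integral = float(np.trapezoid(values[below], split[below]))
    return 100.0 * below_integral / total


def stratified_mean_fraction(fractions, mask) -> tuple[float, float]:
    """Mean and max below-photic percentage over stratified dates only.

    Dates are weighted equally.  Non-stratified dates never contribute.
    """
    fractions = np.asarray(fractions, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if fractions.shape != mask.shape:
        raise ValueError("series lengths differ")
    if not np.any(mask):
        raise ValueError("no stratified dates in the series")
    sel = fractions[mask]
    sel = sel[~np.isnan(sel)]
    if sel.size == 0:
        raise ValueError("no defined fractions on stratified dates")
    return float(np.mean(sel)), float(np.max(sel))


def timeseries_fractions(series: EcotypeTimeSeries,
                         ecotype: Optional[str] = None) -> pd.DataFrame:
    """Per-date photic depth, stratification flag and below-photic fraction.

    With ``ecotype=None`` the total cell profile (sum over ecotypes) is
    used with the HL threshold, mirroring the whole-population statistic;
    otherwise the named ecotype's own threshold applies.
    """
    if ecotype is None:
        profile = sum(np.asarray(p, dtype=float) for p in series.profiles.values())
        threshold = HL_THRESHOLD
        name = "total"
    else:
        profile = np.asarray(series.profiles[ecotype], dtype=float)
        threshold = series.threshold_for(ecotype)
        name = ecotype
    pd_series = photic_depth(series.surface_par, series.k_d, threshold)
    mask = stratified_mask(series.mld, pd_series)
    fracs = np.array([
        fraction_below_photic(profile[i], series.depth_grid, pd_series[i])
        for i in range(len(series.dates))
    ])
    return pd.DataFrame({
        "date": series.dates,
        "ecotype": name,
        "photic_depth_m": pd_series,
        "stratified": mask,
        "below_photic_pct": fracs,
    })
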