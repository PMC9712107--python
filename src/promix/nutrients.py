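"""Nutrient-specific growth rates for fixed nitrogen, phosphate and iron.

Nitrogen and phosphorus follow Michaelis-Menten uptake kinetics normalized
by the cell quota, giving a quota-specific rate in day^-1.  Dissolved-iron
uptake is a linear function of cell surface area.  Default constants are
configuration entries standing in for empirical allometric scalings; they
are set so that a surface DIN of ~10 nmol l^-1 yields N-limited rates in
the 0.3-0.5 day^-1 range typical of oligotrophic surface waters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutrientUptakeParams", "michaelis_specific_rate", "iron_specific_rate"]


@dataclass(frozen=True)
class NutrientUptakeParams:
    """Uptake constants for one cell type.

    Units: ``vmax_n`` mol N cell^-1 day^-1, ``k_n`` mol N m^-3, ``q_n``
    mol N cell^-1 (analogous for P); ``k_fe_sa`` mol Fe um^-2 day^-1 per
    (nmol Fe l^-1), ``surface_area`` um^2, ``q_fe`` mol Fe cell^-1.
    ``fe_detection_limit`` (nmol l^-1) replaces below-detection iron
    values upstream.
    """

    vmax_n: float = 6.0e-17      # ~1.0 day^-1 specific at saturation
    k_n: float = 1.5e-5          # 15 nmol l^-1
    q_n: float = 6.0e-17
    vmax_p: float = 4.8e-18      # ~1.2 day^-1 specific at saturation
    k_p: float = 1.0e-5
    q_p: float = 4.0e-18
    k_fe_sa: float = 2.65e-20
    surface_area: float = 1.13   # 0.6 um diameter sphere
    q_fe: float = 1.0e-20
    fe_detection_limit: float = 0.03

    def __post_init__(self) -> None:
        for name in ("vmax_n", "k_n", "q_n", "vmax_p", "k_p", "q_p",
                     "k_fe_sa", "surface_area", "q_fe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def michaelis_specific_rate(concentration, vmax: float, half_sat: float,
                            quota: float):
    """Quota-specific Michaelis-Menten uptake rate (day^-1).

    ``(vmax / quota) * conc / (conc + half_sat)``; saturating and concave
    in the ambient concentration.
    """
    concentration = np.asarray(concentration, dtype=float)
    if np.any(concentration < 0):
        raise ValueError("concentration must be >= 0")
    if min(vmax, half_sat, quota) <= 0:
        raise ValueError("vmax, half_sat and quota must be > 0")
    rate = (vmax / quota) * concentration / (concentration + half_sat)
    return rate if rate.ndim else float(rate)


def iron_specific_rate(fe_concentration, params: NutrientUptakeParams):
    """Iron-specific uptake rate (day^-1), linear in ambient iron.

    ``k_fe_sa * surface_area * Fe / q_fe`` with Fe in nmol l^-1.
    Below-detection values are expected to have been replaced by the
    detection limit upstream (profile loading).
    """
    fe_concentration = np.asarray(fe_concentration, dtype=float)
    if np.any(fe_concentration < 0):
        raise ValueError("fe_concentration must be >= 0")
    rate = params.k_fe_sa * params.surface_area * fe_concentration / params.q_fe
    return rate if rate.ndim else float(rate)
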