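"""Individual-based model of *Prochlorococcus* in a 1-D water column.

Super-agents, each representing many identical cells, carry carbon,
nitrogen and phosphorus reserve quotas and a structural size.  They fix
carbon by photosynthesis (Platt P-I response to exponentially attenuated,
diel-modulated surface PAR), take up dissolved inorganic nitrogen and
phosphate with quota-regulated Michaelis-Menten kinetics, and -- when the
mixotrophy flag is on -- assimilate a DOC-like tracer:

    V_DOC = V_DOC_max * clamp((qC_max - qC)/(qC_max - qC_min), 0, 1)
                      * DOC / (DOC + K_DOC_sat)
    f_PS  = P_S / (P_S + V_DOC)        (1 when both vanish)
    V_DOC = 0  when f_PS < f_PS_min    (photosynthesis-obligate gate)

so a cell can never acquire more than (1 - f_PS_min) of its carbon
heterotrophically.  Reserves fuel biosynthesis of structure; cells divide
probabilistically once they approach twice the reference size, and die by
quadratic (density-dependent) grazing whose N and P content is
remineralized locally and whose carbon returns to the DOC pool.  Agents
random-walk vertically with a two-layer eddy-diffusivity profile; tracers
diffuse implicitly on an Eulerian grid with optional deep restoring.

Paired autotroph/mixotroph scenario ensembles expose how DOC assimilation
extends the viable depth range, sustains division below the autotrophic
light floor, and deepens the nutricline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from .photo import PhotoPhysParams, chl_specific_fixation, diel_irradiance_factors

__all__ = [
    "IBMConfig",
    "AgentPopulation",
    "TracerFields",
    "doc_uptake",
    "photosynthesis_fraction_gate",
    "step_population",
    "ColumnModel",
    "run_scenario",
    "ScenarioResult",
    "EnsembleResult",
    "division_rate_profile",
    "nutricline_depth",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class IBMConfig:
    """Configuration of the column simulator.

    Quota bounds and the structural stoichiometry are expressed per unit
    structural size, so they scale through growth and halve consistently
    at division.  Defaults are the desk-scale study conditions: a 200 m
    column on a 2 m grid, 10-minute timestep, 120 simulated days with the
    final quarter recorded, and ~2000 super-agents.
    """

    # --- column & physics ---
    depth_max: float = 200.0
    dz: float = 2.0
    mixed_layer_depth: float = 50.0
    k_mixed: float = 1.0e-2          # m^2 s^-1
    k_deep: float = 1.0e-5
    k_transition_width: float = 5.0  # m
    surface_noon_par: float = 600.0
    attenuation: float = 0.052       # m^-1
    latitude: float = 22.75
    day_of_year: int = 190
    # --- photosynthesis (fixed acclimation in the IBM) ---
    photophys: PhotoPhysParams = field(
        default=PhotoPhysParams(ps_chl=0.030, alpha_chl=1.0e-3,
                                beta_chl=3.0e-6, label="HL column"))
    chl_to_c: float = 2.4e-3         # mol Chl (mol C)^-1, fixed
    k_r: float = 0.3                 # maintenance respiration, day^-1
    # --- structure & quotas (per unit size) ---
    n_c: float = 4.0e-15             # structural mol C per unit size
    n_n: float = 6.04e-16            # Redfield 16/106
    n_p: float = 3.77e-17            # Redfield 1/106
    q_c_min: float = 4.0e-16
    q_c_max: float = 1.64e-14
    q_n_min: float = 6.0e-17
    q_n_max: float = 3.0e-16
    q_p_min: float = 4.0e-18
    q_p_max: float = 2.0e-17
    # --- uptake ---
    vmax_n: float = 1.2e-20          # mol N cell^-1 s^-1 per unit size
    k_n: float = 1.0e-5              # mol N m^-3
    vmax_p: float = 8.0e-22
    k_p: float = 1.0e-6
    v_doc_max: float = 3.5e-19       # mol C cell^-1 s^-1 per unit size
    k_doc_sat: float = 1.5e-3        # mol C m^-3
    f_ps_min: float = 0.01
    mixotrophy: bool = True
    # --- synthesis, division, grazing ---
    mu_syn_max: float = 0.45         # day^-1
    div_rate_max: float = 5.0        # day^-1 at large size
    div_size_mid: float = 2.0
    div_size_slope: float = 0.15
    grazing_coeff: float = 2.2e-12   # m^3 cell^-1 day^-1
    # --- tracers ---
    din_surface: float = 1.0e-5      # mol N m^-3
    din_deep: float = 2.6e-4
    po4_surface: float = 6.0e-7
    po4_deep: float = 1.63e-5
    nutricline_mid: float = 60.0
    nutricline_width: float = 10.0
    doc_background: float = 4.6e-3   # mol C m^-3 at the surface
    doc_depth_scale: float = 55.0    # e-folding depth of the DOC background, m
    doc_restore_days: Optional[float] = 0.7
    nutrient_restore_below: Optional[float] = 150.0
    nutrient_restore_days: float = 10.0
    # --- agents & run control ---
    n_super_agents: int = 2000
    init_cells_ml: float = 1.35e11   # cells m^-3 in the mixed layer
    init_cells_deep: float = 1.0e10  # cells m^-3 below, down to init_depth
    init_depth: float = 150.0
    timestep: float = 600.0          # s
    duration_days: float = 120.0
    record_fraction: float = 0.25    # final fraction of the run averaged
    bin_dz: float = 5.0              # output depth bins
    seed: int = 0
    check_conservation: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.f_ps_min < 1:
            raise ValueError("f_ps_min must be in (0, 1)")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.q_c_max <= self.q_c_min:
            raise ValueError("q_c_max must exceed q_c_min")

    @property
    def closed(self) -> bool:
        """True when no restoring terms exchange mass with the outside."""
        return self.doc_restore_days is None and self.nutrient_restore_below is None


@dataclass
class AgentPopulation:
    """Arrays of super-agent state (one entry per agent)."""

    depth: np.ndarray
    size: np.ndarray
    q_c: np.ndarray
    q_n: np.ndarray
    q_p: np.ndarray
    multiplicity: np.ndarray

    def __len__(self) -> int:
        return len(self.depth)

    def total_cells(self) -> float:
        return float(self.multiplicity.sum())


@dataclass
class TracerFields:
    """Eulerian tracer concentrations on the column grid (mol m^-3)."""

    din: np.ndarray
    po4: np.ndarray
    doc: np.ndarray
    dz: float
    depth_max: float

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(len(self.din)) + 0.5) * self.dz

    def __post_init__(self) -> None:
        if self.dz <= 0:
            raise ValueError("grid spacing must be > 0")
        for name in ("din", "po4", "doc"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"tracer '{name}' has negative values")


def doc_uptake(agent, doc_concentration, config: IBMConfig):
    """Cell-specific DOC uptake rate before gating (mol C cell^-1 s^-1).

    Quota regulation scales uptake by the remaining carbon-reserve
    headroom; a Michaelis-Menten factor scales it by ambient DOC.  Zero
    when the mixotrophy flag is off.  Works on single agents or on the
    whole population (arrays).
    """
    if config.q_c_max <= config.q_c_min:
        raise ValueError("q_c_max must exceed q_c_min")
    if not config.mixotrophy:
        return np.zeros_like(np.asarray(agent.q_c, dtype=float))
    size = np.asarray(agent.size, dtype=float)
    q_c = np.asarray(agent.q_c, dtype=float)
    headroom = np.clip((config.q_c_max * size - q_c)
                       / ((config.q_c_max - config.q_c_min) * size), 0.0, 1.0)
    doc = np.asarray(doc_concentration, dtype=float)
    return config.v_doc_max * size * headroom * doc / (doc + config.k_doc_sat)


def photosynthesis_fraction_gate(photosynthesis_rate, v_doc,
                                 config: IBMConfig):
    """Fraction of fixed C from photosynthesis, and the gated DOC uptake.

    ``f_PS = P_S / (P_S + V_DOC)`` (1 when both are zero); DOC uptake is
    shut off wherever ``f_PS`` falls below the obligate-photosynthesis
    floor ``f_ps_min``.  Returns ``(f_ps, gated_v_doc)``.
    """
    ps = np.asarray(photosynthesis_rate, dtype=float)
    vd = np.asarray(v_doc, dtype=float)
    total = ps + vd
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ps = np.where(total > 0, ps / np.where(total > 0, total, 1.0), 1.0)
    gated = np.where(f_ps < config.f_ps_min, 0.0, vd)
    if ps.ndim == 0 and vd.ndim == 0:
        return float(f_ps), float(gated)
    return f_ps, gated


def doc_background_profile(z, config: IBMConfig):
    """Labile-DOC background (mol C m^-3): surface-produced, decaying with depth."""
    return config.doc_background * np.exp(-np.asarray(z, dtype=float)
                                          / config.doc_depth_scale)


def _diffusivity(z, config: IBMConfig):
    """Two-layer eddy diffusivity (m^2 s^-1) with a smooth transition."""
    t = np.tanh((np.asarray(z, dtype=float) - config.mixed_layer_depth)
                / config.k_transition_width)
    return config.k_deep + (config.k_mixed - config.k_deep) * 0.5 * (1.0 - t)


def _diffusivity_gradient(z, config: IBMConfig):
    s = 1.0 / np.cosh((np.asarray(z, dtype=float) - config.mixed_layer_depth)
                      / config.k_transition_width) ** 2
    return -(config.k_mixed - config.k_deep) * 0.5 * s / config.k_transition_width


class _Recorder:
    """Accumulates depth-binned diagnostics over the recording window."""

    def __init__(self, config: IBMConfig):
        self.edges = np.arange(0.0, config.depth_max + config.bin_dz / 2,
                               config.bin_dz)
        n = len(self.edges) - 1
        self.cell_days = np.zeros(n)
        self.division_cells = np.zeros(n)
        self.ps_mol = np.zeros(n)
        self.doc_mol = np.zeros(n)
        self.doc_contrib_days = np.zeros(n)
        self.c_limited_days = np.zeros(n)
        self.n_tracer_samples = 0
        self.din_sum = None
        self.po4_sum = None
        self.doc_sum = None
        self.days = 0.0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_of(self, depth: np.ndarray) -> np.ndarray:
        idx = np.floor(depth / (self.edges[1] - self.edges[0])).astype(int)
        return np.clip(idx, 0, len(self.edges) - 2)


@dataclass
class ScenarioResult:
    """Depth-binned quasi-steady-state diagnostics of one member run.

    Profiles are averages over the recording window: ``cell_density``
    (cells m^-3), ``division_rate`` (day^-1; NaN in bins never occupied),
    tracer concentrations, and ``doc_share`` -- the fraction of total
    carbon acquisition taken from DOC, the recorded (1 - f_PS)
    contribution.  ``c_limited_fraction`` is the occupancy-weighted
    fraction of cells whose biosynthesis was carbon- (light/DOC-) rather
    than nutrient-limited.
    """

    depth: np.ndarray
    cell_density: np.ndarray
    division_rate: np.ndarray
    din: np.ndarray
    po4: np.ndarray
    doc: np.ndarray
    doc_share: np.ndarray
    doc_contribution: np.ndarray
    c_limited_fraction: np.ndarray
    ps_mol: np.ndarray
    doc_mol: np.ndarray
    tracer_depth: np.ndarray
    extinct: bool
    seed: int

    @property
    def total_doc_share_pct(self) -> float:
        """DOC share of vertically integrated carbon acquisition (%)."""
        total = self.ps_mol.sum() + self.doc_mol.sum()
        return 100.0 * self.doc_mol.sum() / total if total > 0 else float("nan")


def _initial_state(config: IBMConfig, rng: np.random.Generator
                   ) -> tuple[AgentPopulation, TracerFields]:
    nz = int(round(config.depth_max / config.dz))
    z = (np.arange(nz) + 0.5) * config.dz
    sig = lambda zz: 1.0 / (1.0 + np.exp(-(zz - config.nutricline_mid)
                                         / config.nutricline_width))
    din = config.din_surface + (config.din_deep - config.din_surface) * sig(z)
    po4 = config.po4_surface + (config.po4_deep - config.po4_surface) * sig(z)
    doc = doc_background_profile(z, config)
    tracers = TracerFields(din=din, po4=po4, doc=doc, dz=config.dz,
                           depth_max=config.depth_max)

    # agents: allocated proportionally to the target density profile
    n_agents = config.n_super_agents
    ml, zdeep = config.mixed_layer_depth, config.init_depth
    total_cells = config.init_cells_ml * ml \
        + config.init_cells_deep * max(zdeep - ml, 0.0)
    mult = total_cells / n_agents
    n_ml = int(round(n_agents * config.init_cells_ml * ml / total_cells))
    depth = np.concatenate([
        rng.uniform(0.0, ml, n_ml),
        rng.uniform(ml, zdeep, n_agents - n_ml),
    ])
    size = rng.uniform(1.0, 2.0, n_agents)
    agents = AgentPopulation(
        depth=depth,
        size=size,
        q_c=0.5 * (config.q_c_min + config.q_c_max) * size,
        q_n=0.5 * (config.q_n_min + config.q_n_max) * size,
        q_p=0.5 * (config.q_p_min + config.q_p_max) * size,
        multiplicity=np.full(n_agents, mult),
    )
    return agents, tracers


def _limited_tracer_draw(demand_per_agent: np.ndarray, mult: np.ndarray,
                         bins: np.ndarray, tracer: np.ndarray, dz: float,
                         dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Scale per-agent uptake so no grid cell is driven negative.

    Returns the realized per-agent uptake (mol cell^-1 over the step) and
    the per-grid-cell concentration decrement.
    """
    nz = len(tracer)
    demand = np.zeros(nz)
    np.add.at(demand, bins, demand_per_agent * mult * dt)
    demand /= dz  # mol m^-3 requested
    avail = 0.99 * tracer
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(demand > avail,
                         avail / np.where(demand > 0, demand, 1.0), 1.0)
    realized = demand_per_agent * dt * scale[bins]
    decrement = np.minimum(demand * scale, tracer)
    return realized, decrement


def step_population(agents: AgentPopulation, tracers: TracerFields,
                    time_of_day: float, config: IBMConfig,
                    rng: np.random.Generator,
                    diel_factor: Optional[float] = None,
                    recorder: Optional[_Recorder] = None,
                    ) -> tuple[AgentPopulation, TracerFields]:
    """Advance the population and tracers by one timestep.

    ``time_of_day`` is in hours (0-24); the diel light factor is derived
    from it unless given explicitly.  Random draws are consumed in a fixed
    order (division, grazing, random walk) for reproducibility.  Mutates
    and returns the inputs.
    """
    dt = config.timestep
    dt_day = dt / SECONDS_PER_DAY
    nz = len(tracers.din)
    dz = tracers.dz

    if diel_factor is None:
        diel = diel_irradiance_factors(config.latitude, config.day_of_year,
                                       n_steps_per_day=int(SECONDS_PER_DAY / dt))
        idx = int(time_of_day / 24.0 * len(diel.factors)) % len(diel.factors)
        diel_factor = float(diel.factors[idx])

    n = len(agents)
    if n > 0:
        bins = np.clip((agents.depth / dz).astype(int), 0, nz - 1)
        size = agents.size
        mult = agents.multiplicity

        # (1)-(2) light and photosynthesis (mol C cell^-1 s^-1); fixation
        # fills the carbon reserve up to its cap (excess is implicitly
        # exuded) -- the quota-regulation factor applies to DOC uptake only
        irr = config.surface_noon_par * diel_factor \
            * np.exp(-config.attenuation * agents.depth)
        ps = config.chl_to_c * chl_specific_fixation(irr, config.photophys) \
            * config.n_c * size

        # (3) quota-regulated N and P uptake, depleting tracers
        headroom_n = np.clip((config.q_n_max * size - agents.q_n)
                             / ((config.q_n_max - config.q_n_min) * size),
                             0.0, 1.0)
        v_n = config.vmax_n * size * headroom_n \
            * tracers.din[bins] / (tracers.din[bins] + config.k_n)
        got_n, dec = _limited_tracer_draw(v_n, mult, bins, tracers.din, dz, dt)
        tracers.din -= dec
        agents.q_n += got_n

        headroom_p = np.clip((config.q_p_max * size - agents.q_p)
                             / ((config.q_p_max - config.q_p_min) * size),
                             0.0, 1.0)
        v_p = config.vmax_p * size * headroom_p \
            * tracers.po4[bins] / (tracers.po4[bins] + config.k_p)
        got_p, dec = _limited_tracer_draw(v_p, mult, bins, tracers.po4, dz, dt)
        tracers.po4 -= dec
        agents.q_p += got_p

        # (4) DOC uptake with the obligate-photosynthesis gate; DOC enters
        # the reserve first (its draw already left the tracer), then
        # fixation fills whatever headroom remains below the cap
        v_doc = doc_uptake(agents, tracers.doc[bins], config)
        f_ps, v_doc = photosynthesis_fraction_gate(ps, v_doc, config)
        cap = np.maximum(config.q_c_max * size - agents.q_c, 0.0)
        v_doc = np.minimum(v_doc, cap / dt)
        got_doc, dec = _limited_tracer_draw(v_doc, mult, bins, tracers.doc,
                                            dz, dt)
        tracers.doc -= dec
        ps_stored = np.minimum(ps * dt, cap - got_doc)
        agents.q_c += ps_stored + got_doc

        # (5) biosynthesis from reserves, with maintenance respiration
        fill_c = np.clip((agents.q_c - config.q_c_min * size)
                         / ((config.q_c_max - config.q_c_min) * size), 0.0, 1.0)
        fill_n = np.clip((agents.q_n - config.q_n_min * size)
                         / ((config.q_n_max - config.q_n_min) * size), 0.0, 1.0)
        fill_p = np.clip((agents.q_p - config.q_p_min * size)
                         / ((config.q_p_max - config.q_p_min) * size), 0.0, 1.0)
        mu = config.mu_syn_max * np.minimum(np.minimum(fill_c, fill_n), fill_p)
        growth = size * mu * dt_day
        for q, qmin, nx in ((agents.q_c, config.q_c_min, config.n_c),
                            (agents.q_n, config.q_n_min, config.n_n),
                            (agents.q_p, config.q_p_min, config.n_p)):
            growth = np.minimum(growth, np.maximum(q - qmin * size, 0.0)
                                / (nx + qmin))
        agents.size = size = size + growth
        agents.q_c -= growth * config.n_c
        agents.q_n -= growth * config.n_n
        agents.q_p -= growth * config.n_p
        resp = config.k_r * dt_day * config.n_c * size
        agents.q_c = np.maximum(agents.q_c - resp, config.q_c_min * size)

        if recorder is not None:
            recorder.days += dt_day
            np.add.at(recorder.cell_days, recorder.bin_of(agents.depth),
                      mult * dt_day)
            np.add.at(recorder.ps_mol, recorder.bin_of(agents.depth),
                      ps_stored * mult)
            np.add.at(recorder.doc_mol, recorder.bin_of(agents.depth),
                      got_doc * mult)
            # time-mean DOC contribution (1 - f_PS) from the gross
            # photosynthesis rate and the realized (gated, tracer-limited)
            # DOC uptake rate; zero at night when both rates vanish
            total_rate = ps * dt + got_doc
            with np.errstate(invalid="ignore", divide="ignore"):
                contrib = np.where(total_rate > 0,
                                   got_doc / np.where(total_rate > 0,
                                                      total_rate, 1.0),
                                   0.0)
            np.add.at(recorder.doc_contrib_days, recorder.bin_of(agents.depth),
                      contrib * mult * dt_day)
            c_lim = fill_c < np.minimum(fill_n, fill_p)
            np.add.at(recorder.c_limited_days, recorder.bin_of(agents.depth),
                      np.where(c_lim, mult * dt_day, 0.0))

        # (6) division: probability rises sigmoidally past twice the
        # reference size; daughters halve size and quotas
        p_div = dt_day * config.div_rate_max / (
            1.0 + np.exp(-(agents.size - config.div_size_mid)
                         / config.div_size_slope))
        dividing = rng.random(n) < p_div
        if np.any(dividing):
            if recorder is not None:
                np.add.at(recorder.division_cells,
                          recorder.bin_of(agents.depth[dividing]),
                          mult[dividing])
            for arr in (agents.size, agents.q_c, agents.q_n, agents.q_p):
                arr[dividing] *= 0.5
            agents.depth = np.concatenate([agents.depth,
                                           agents.depth[dividing]])
            agents.size = np.concatenate([agents.size, agents.size[dividing]])
            agents.q_c = np.concatenate([agents.q_c, agents.q_c[dividing]])
            agents.q_n = np.concatenate([agents.q_n, agents.q_n[dividing]])
            agents.q_p = np.concatenate([agents.q_p, agents.q_p[dividing]])
            agents.multiplicity = np.concatenate([agents.multiplicity,
                                                  mult[dividing]])
            n = len(agents)
            bins = np.clip((agents.depth / dz).astype(int), 0, nz - 1)
            mult = agents.multiplicity

        # (7) quadratic grazing: per-cell probability proportional to the
        # local cell concentration; grazed N/P remineralize, C joins DOC
        conc = np.zeros(nz)
        np.add.at(conc, bins, mult)
        conc /= dz
        p_graze = np.clip(dt_day * config.grazing_coeff * conc[bins], 0.0, 1.0)
        grazed = rng.random(n) < p_graze
        if np.any(grazed):
            gb = bins[grazed]
            gm = mult[grazed]
            n_ret = (agents.q_n[grazed] + config.n_n * agents.size[grazed]) * gm
            p_ret = (agents.q_p[grazed] + config.n_p * agents.size[grazed]) * gm
            c_ret = (agents.q_c[grazed] + config.n_c * agents.size[grazed]) * gm
            np.add.at(tracers.din, gb, n_ret / dz)
            np.add.at(tracers.po4, gb, p_ret / dz)
            np.add.at(tracers.doc, gb, c_ret / dz)
            keep = ~grazed
            agents.depth = agents.depth[keep]
            agents.size = agents.size[keep]
            agents.q_c = agents.q_c[keep]
            agents.q_n = agents.q_n[keep]
            agents.q_p = agents.q_p[keep]
            agents.multiplicity = agents.multiplicity[keep]
            n = len(agents)

        # (8) vertical random walk consistent with the diffusivity profile
        if n > 0:
            k_here = _diffusivity(agents.depth, config)
            drift = _diffusivity_gradient(agents.depth, config) * dt
            agents.depth = agents.depth + drift \
                + np.sqrt(2.0 * k_here * dt) * rng.standard_normal(n)
            agents.depth = np.abs(agents.depth)
            over = agents.depth > config.depth_max
            agents.depth[over] = 2.0 * config.depth_max - agents.depth[over]
            np.clip(agents.depth, 0.0, config.depth_max - 1e-9,
                    out=agents.depth)

    # (9) implicit tracer diffusion and restoring
    _diffuse_tracers(tracers, config)
    z = tracers.z_centers
    if config.nutrient_restore_below is not None:
        mask = z >= config.nutrient_restore_below
        w = dt_day / config.nutrient_restore_days
        sig = 1.0 / (1.0 + np.exp(-(z[mask] - config.nutricline_mid)
                                  / config.nutricline_width))
        din_target = config.din_surface + (config.din_deep - config.din_surface) * sig
        po4_target = config.po4_surface + (config.po4_deep - config.po4_surface) * sig
        tracers.din[mask] += w * (din_target - tracers.din[mask])
        tracers.po4[mask] += w * (po4_target - tracers.po4[mask])
    if config.doc_restore_days is not None:
        tracers.doc += (dt_day / config.doc_restore_days) \
            * (doc_background_profile(z, config) - tracers.doc)

    if recorder is not None:
        recorder.n_tracer_samples += 1
        if recorder.din_sum is None:
            recorder.din_sum = tracers.din.copy()
            recorder.po4_sum = tracers.po4.copy()
            recorder.doc_sum = tracers.doc.copy()
        else:
            recorder.din_sum += tracers.din
            recorder.po4_sum += tracers.po4
            recorder.doc_sum += tracers.doc
    return agents, tracers


def _diffusion_matrix(config: IBMConfig, nz: int) -> np.ndarray:
    """Banded backward-Euler matrix for the variable-K diffusion solve."""
    z_if = np.arange(1, nz) * config.dz
    k_if = _diffusivity(z_if, config)
    r = config.timestep / config.dz ** 2
    lower = np.zeros(nz)
    upper = np.zeros(nz)
    diag = np.ones(nz)
    diag[:-1] += r * k_if
    diag[1:] += r * k_if
    upper[1:] = -r * k_if
    lower[:-1] = -r * k_if
    return np.vstack([upper, diag, lower])


_MATRIX_CACHE: dict[tuple, np.ndarray] = {}


def _diffuse_tracers(tracers: TracerFields, config: IBMConfig) -> None:
    nz = len(tracers.din)
    key = (config.dz, config.depth_max, config.timestep, config.k_mixed,
           config.k_deep, config.mixed_layer_depth,
           config.k_transition_width, nz)
    ab = _MATRIX_CACHE.get(key)
    if ab is None:
        ab = _diffusion_matrix(config, nz)
        _MATRIX_CACHE[key] = ab
    rhs = np.column_stack([tracers.din, tracers.po4, tracers.doc])
    out = solve_banded((1, 1), ab, rhs)
    tracers.din = np.maximum(out[:, 0], 0.0)
    tracers.po4 = np.maximum(out[:, 1], 0.0)
    tracers.doc = np.maximum(out[:, 2], 0.0)


class ColumnModel:
    """One member simulation: state, clock and recording."""

    def __init__(self, config: IBMConfig, seed: Optional[int] = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)
        self.agents, self.tracers = _initial_state(config, self.rng)
        steps_per_day = int(round(SECONDS_PER_DAY / config.timestep))
        self.diel = diel_irradiance_factors(config.latitude,
                                            config.day_of_year,
                                            n_steps_per_day=steps_per_day)
        self.steps_per_day = steps_per_day
        self.step_index = 0

    def total_nitrogen(self) -> float:
        """Column inventory of N (mol m^-2): tracer plus agent biomass."""
        a, t, c = self.agents, self.tracers, self.config
        biomass = float(np.sum((a.q_n + c.n_n * a.size) * a.multiplicity))
        return float(t.din.sum() * t.dz) + biomass

    def total_phosphorus(self) -> float:
        a, t, c = self.agents, self.tracers, self.config
        biomass = float(np.sum((a.q_p + c.n_p * a.size) * a.multiplicity))
        return float(t.po4.sum() * t.dz) + biomass

    def step(self, recorder: Optional[_Recorder] = None) -> None:
        factor = float(self.diel.factors[self.step_index % self.steps_per_day])
        hours = 24.0 * (self.step_index % self.steps_per_day) / self.steps_per_day
        step_population(self.agents, self.tracers, hours, self.config,
                        self.rng, diel_factor=factor, recorder=recorder)
        if self.config.check_conservation and not self.config.closed:
            raise ValueError("conservation checking requires a closed config")
        self.step_index += 1
        self._enforce_agent_cap()

    def _enforce_agent_cap(self) -> None:
        # merge depth-adjacent pairs when the population of super-agents
        # outgrows memory bounds; totals of cells, N and P are conserved
        a = self.agents
        cap = 3 * self.config.n_super_agents
        if len(a) <= cap:
            return
        order = np.argsort(a.depth)
        even = order[0:2 * (len(order) // 2):2]
        odd = order[1:2 * (len(order) // 2):2]
        m = a.multiplicity[even] + a.multiplicity[odd]
        w1 = a.multiplicity[even] / m
        w2 = a.multiplicity[odd] / m
        merged = AgentPopulation(
            depth=w1 * a.depth[even] + w2 * a.depth[odd],
            size=w1 * a.size[even] + w2 * a.size[odd],
            q_c=w1 * a.q_c[even] + w2 * a.q_c[odd],
            q_n=w1 * a.q_n[even] + w2 * a.q_n[odd],
            q_p=w1 * a.q_p[even] + w2 * a.q_p[odd],
            multiplicity=m,
        )
        if len(order) % 2:
            last = order[-1:]
            for name in ("depth", "size", "q_c", "q_n", "q_p", "multiplicity"):
                setattr(merged, name, np.concatenate([getattr(merged, name),
                                                      getattr(a, name)[last]]))
        self.agents = merged

    def run(self) -> ScenarioResult:
        """Integrate to the end of the run, recording the final fraction."""
        cfg = self.config
        n_steps = int(round(cfg.duration_days * self.steps_per_day))
        record_from = int(round((1.0 - cfg.record_fraction) * n_steps))
        recorder = _Recorder(cfg)
        extinct = False
        for i in range(n_steps):
            self.step(recorder if i >= record_from else None)
            if len(self.agents) == 0:
                extinct = True
                break
        return self._result(recorder, extinct)

    def _result(self, rec: _Recorder, extinct: bool) -> ScenarioResult:
        days = max(rec.days, 1e-12)
        bin_dz = rec.edges[1] - rec.edges[0]
        density = rec.cell_days / days / bin_dz
        with np.errstate(invalid="ignore", divide="ignore"):
            division = np.where(rec.cell_days > 0,
                                rec.division_cells / np.where(
                                    rec.cell_days > 0, rec.cell_days, 1.0),
                                np.nan)
            total_c = rec.ps_mol + rec.doc_mol
            share = np.where(total_c > 0,
                             rec.doc_mol / np.where(total_c > 0, total_c, 1.0),
                             np.nan)
            contrib = np.where(rec.cell_days > 0,
                               rec.doc_contrib_days / np.where(
                                   rec.cell_days > 0, rec.cell_days, 1.0),
                               np.nan)
            climf = np.where(rec.cell_days > 0,
                             rec.c_limited_days / np.where(
                                 rec.cell_days > 0, rec.cell_days, 1.0),
                             np.nan)
        ns = max(rec.n_tracer_samples, 1)
        zeros = np.zeros(int(round(self.config.depth_max / self.config.dz)))
        return ScenarioResult(
            depth=rec.centers,
            cell_density=density,
            division_rate=division,
            din=(rec.din_sum / ns) if rec.din_sum is not None else zeros,
            po4=(rec.po4_sum / ns) if rec.po4_sum is not None else zeros,
            doc=(rec.doc_sum / ns) if rec.doc_sum is not None else zeros,
            doc_share=share,
            doc_contribution=contrib,
            c_limited_fraction=climf,
            ps_mol=rec.ps_mol,
            doc_mol=rec.doc_mol,
            tracer_depth=self.tracers.z_centers,
            extinct=extinct,
            seed=self.seed,
        )


@dataclass
class EnsembleResult:
    """Ensemble of member results with per-depth min/max bands."""

    members: list[ScenarioResult]
    config: IBMConfig

    @property
    def depth(self) -> np.ndarray:
        return self.members[0].depth

    def _stack(self, name: str) -> np.ndarray:
        return np.vstack([getattr(m, name) for m in self.members])

    def mean(self, name: str) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            return np.nanmean(self._stack(name), axis=0)

    def band(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-depth (min, max) across ensemble members."""
        import warnings

        stack = self._stack(name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmin(stack, axis=0), np.nanmax(stack, axis=0)

    @property
    def any_extinct(self) -> bool:
        return any(m.extinct for m in self.members)

    def _contribution_pct(self, sel: np.ndarray) -> float:
        """Production-weighted mean DOC contribution (1 - f_PS), %.

        The per-depth time-mean DOC contribution is weighted by total
        carbon acquisition and integrated over the selected depth bins.
        """
        contrib = self.mean("doc_contribution")
        prod = np.zeros_like(contrib)
        for m in self.members:
            prod += m.ps_mol + m.doc_mol
        ok = sel & ~np.isnan(contrib)
        total = prod[ok].sum()
        if total <= 0:
            return float("nan")
        return 100.0 * float(np.sum(contrib[ok] * prod[ok]) / total)

    def total_doc_share_pct(self) -> float:
        """DOC contribution to vertically integrated production (%)."""
        return self._contribution_pct(np.ones_like(self.depth, dtype=bool))

    def doc_share_below_pct(self, depth_m: float) -> float:
        """DOC contribution to production integrated below ``depth_m`` (%)."""
        return self._contribution_pct(self.depth >= depth_m)

    def doc_uptake_mass_share_pct(self) -> float:
        """DOC share of integrated carbon-acquisition mass (%), pooled."""
        ps = sum(m.ps_mol.sum() for m in self.members)
        doc = sum(m.doc_mol.sum() for m in self.members)
        total = ps + doc
        return 100.0 * doc / total if total > 0 else float("nan")

    def limitation_transition_depth(self) -> Optional[float]:
        """Depth where limitation shifts from nutrients to carbon/light.

        Shallowest crossing, below the surface bin, of the ensemble-mean
        carbon-limited occupancy fraction through one half.
        """
        frac = self.mean("c_limited_fraction")
        depth = self.depth
        valid = ~np.isnan(frac)
        d, f = depth[valid], frac[valid]
        above = f < 0.5
        for i in range(1, len(d)):
            if above[i - 1] and not above[i]:
                return float(np.interp(0.5, [f[i - 1], f[i]],
                                       [d[i - 1], d[i]]))
        return None

    def division_extinction_depth(self, cutoff: float = 0.02) -> Optional[float]:
        """Shallowest depth below which division effectively ceases.

        The bottom edge of the deepest bin whose ensemble-mean division
        rate still exceeds ``cutoff`` (day^-1).
        """
        rate = self.mean("division_rate")
        alive = ~np.isnan(rate) & (rate > cutoff)
        if not alive[0]:
            return None
        # bottom of the contiguous actively dividing region from the
        # surface; isolated deep bins with rare division events are noise
        end = int(np.argmin(alive)) if not alive.all() else len(alive)
        half = 0.5 * (self.depth[1] - self.depth[0])
        return float(self.depth[end - 1] + half)

    def division_rate_at(self, depth_m: float) -> float:
        """Ensemble-mean division rate in the bin containing ``depth_m``."""
        idx = int(np.argmin(np.abs(self.depth - depth_m)))
        return float(self.mean("division_rate")[idx])

    def mixed_layer_division_rate(self) -> float:
        """Occupancy-weighted mean division rate over the mixed layer."""
        sel = self.depth <= self.config.mixed_layer_depth
        rate = self.mean("division_rate")[sel]
        dens = self.mean("cell_density")[sel]
        ok = ~np.isnan(rate)
        return float(np.sum(rate[ok] * dens[ok]) / np.sum(dens[ok]))


def run_scenario(config: IBMConfig, n_ensemble: int = 5) -> EnsembleResult:
    """Run an ensemble of member simulations with distinct seeds.

    Member seeds are derived deterministically from ``config.seed``;
    an extinct member is flagged on its result, not raised.
    """
    if n_ensemble < 1:
        raise ValueError("n_ensemble must be >= 1")
    members = []
    for k in range(n_ensemble):
        member_seed = (config.seed * 1000 + k) % (2 ** 31)
        members.append(ColumnModel(config, seed=member_seed).run())
    return EnsembleResult(members=members, config=config)


def division_rate_profile(division_event_log, cell_density_profile=None,
                          *, cell_days=None, bin_edges=None):
    """Per-depth daily division rate (day^-1) from an event log.

    ``division_event_log`` is a sequence of (depth, cells) division events;
    ``cell_days`` the matching per-bin occupancy (cell-days).  Bins with no
    occupancy are reported as NaN (missing), not zero.
    """
    if bin_edges is None or cell_days is None:
        raise ValueError("bin_edges and cell_days are required")
    events = np.zeros(len(bin_edges) - 1)
    for depth, cells in division_event_log:
        idx = min(int(depth / (bin_edges[1] - bin_edges[0])),
                  len(events) - 1)
        events[idx] += cells
    cell_days = np.asarray(cell_days, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cell_days > 0,
                        events / np.where(cell_days > 0, cell_days, 1.0),
                        np.nan)


def nutricline_depth(nutrient_profile, depth, threshold_concentration
                     ) -> Optional[float]:
    """Shallowest depth where the profile crosses the threshold (m).

    Linear interpolation between grid points; ``None`` when the profile
    never reaches the threshold.
    """
    profile = np.asarray(nutrient_profile, dtype=float)
    depth = np.asarray(depth, dtype=float)
    above = profile >= threshold_concentration
    if not np.any(above):
        return None
    if above[0]:
        return float(depth[0])
    i = int(np.argmax(above))
    c0, c1 = profile[i - 1], profile[i]
    if c1 == c0:
        return float(depth[i])
    return float(depth[i - 1] + (threshold_concentration - c0)
                 * (depth[i] - depth[i - 1]) / (c1 - c0))
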