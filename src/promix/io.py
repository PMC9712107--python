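"""Table readers/writers, YAML configuration and run manifests.

Depth profiles travel as plain CSV with one row per depth (columns
``depth_m, par_noon, din, po4`` plus optional ``fe, cells_per_m3,
mu_obs``).  Iron values below the detection limit -- either numeric or
tokens like ``<0.03`` -- are substituted with the detection limit and
logged.  Results are written as CSV (tables), JSON (summaries) and
NetCDF via xarray (gridded IBM ensembles); every CLI invocation records a
manifest with the command, config hash, seeds and output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .ibm import EnsembleResult, IBMConfig
from .nutrients import NutrientUptakeParams
from .photo import AllocationParams, PHOTOPHYS_PRESETS, PhotoPhysParams
from .profiles import EnvironmentProfile, GrowthProfileResult

__all__ = [
    "read_profile_table",
    "write_growth_result",
    "write_ensemble",
    "load_config",
    "RunManifest",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("depth_m", "par_noon", "din", "po4")
OPTIONAL_COLUMNS = ("fe", "cells_per_m3", "mu_obs")


def _parse_detection_limited(series: pd.Series, limit: float) -> np.ndarray:
    """Parse a column that may contain '<x' below-detection tokens."""
    values = np.empty(len(series))
    n_sub = 0
    for i, raw in enumerate(series):
        if isinstance(raw, str) and raw.strip().startswith("<"):
            values[i] = limit
            n_sub += 1
        else:
            v = float(raw) if not pd.isna(raw) else np.nan
            if v < limit:
                v = limit
                n_sub += 1
            values[i] = v
    if n_sub:
        logger.info("substituted %d below-detection iron values with %.3g",
                    n_sub, limit)
    return values


def read_profile_table(path, fe_detection_limit: float = 0.03,
                       latitude: float = 22.75,
                       day_of_year: int = 190) -> EnvironmentProfile:
    """Read a depth-profile CSV into an :class:`EnvironmentProfile`.

    Requires a header row with ``depth_m, par_noon, din, po4``; optional
    ``fe`` (nmol l^-1; ``<limit`` tokens allowed), ``cells_per_m3`` and
    ``mu_obs`` (blank cells become gaps for interpolation).  Rows are
    sorted by depth; duplicate depths are an error.
    """
    table = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"profile table {path} is missing column '{col}'")
    dup = table["depth_m"].duplicated()
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise ValueError(f"duplicate depth {table['depth_m'][row]} m in {path} "
                         f"(row {row})")
    table = table.sort_values("depth_m").reset_index(drop=True)
    fe = None
    if "fe" in table.columns and not table["fe"].isna().all():
        fe = _parse_detection_limited(table["fe"], fe_detection_limit)
    cells = table["cells_per_m3"].to_numpy(dtype=float) \
        if "cells_per_m3" in table.columns else None
    mu_obs = table["mu_obs"].to_numpy(dtype=float) \
        if "mu_obs" in table.columns else None
    return EnvironmentProfile(
        depth=table["depth_m"].to_numpy(dtype=float),
        noon_par=table["par_noon"].to_numpy(dtype=float),
        din=table["din"].to_numpy(dtype=float),
        po4=table["po4"].to_numpy(dtype=float),
        fe=fe, cell_density=cells, mu_obs=mu_obs,
        latitude=latitude, day_of_year=day_of_year,
    )


def write_growth_result(result: GrowthProfileResult, path) -> Path:
    """Write a growth-profile result table to CSV."""
    path = Path(path)
    table = result.table.copy()
    table.insert(0, "scenario", result.scenario)
    table.to_csv(path, index=False)
    return path


def read_growth_result(path, environment: EnvironmentProfile
                       ) -> GrowthProfileResult:
    """Round-trip reader for :func:`write_growth_result` output."""
    table = pd.read_csv(path)
    scenario = str(table.pop("scenario").iloc[0])
    return GrowthProfileResult(table=table, scenario=scenario,
                               environment=environment)


def write_json_summary(summary: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return path


def _json_default(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def ensemble_to_dataset(result: EnsembleResult) -> xr.Dataset:
    """Pack an IBM ensemble into an xarray Dataset (depth x member)."""
    members = result.members
    depth = result.depth
    data = {}
    for name in ("cell_density", "division_rate", "doc_share",
                 "doc_contribution", "c_limited_fraction"):
        data[name] = (("member", "depth"),
                      np.vstack([getattr(m, name) for m in members]))
    for name in ("din", "po4", "doc"):
        data[name] = (("member", "tracer_depth"),
                      np.vstack([getattr(m, name) for m in members]))
    ds = xr.Dataset(
        data,
        coords={"depth": depth,
                "tracer_depth": members[0].tracer_depth,
                "member": np.array([m.seed for m in members])},
        attrs={"mixotrophy": int(result.config.mixotrophy),
               "timestep_s": result.config.timestep,
               "duration_days": result.config.duration_days},
    )
    return ds


def write_ensemble(result: EnsembleResult, path) -> Path:
    """Write an IBM ensemble as NetCDF plus a CSV profile summary."""
    path = Path(path)
    ds = ensemble_to_dataset(result)
    ds.to_netcdf(path, engine="scipy")
    lo_d, hi_d = result.band("cell_density")
    lo_r, hi_r = result.band("division_rate")
    summary = pd.DataFrame({
        "depth_m": result.depth,
        "cell_density_mean": result.mean("cell_density"),
        "cell_density_min": lo_d, "cell_density_max": hi_d,
        "division_rate_mean": result.mean("division_rate"),
        "division_rate_min": lo_r, "division_rate_max": hi_r,
        "doc_contribution_mean": result.mean("doc_contribution"),
    })
    summary.to_csv(path.with_suffix(".csv"), index=False)
    return path


def _photophys_from_dict(d: dict, label: str) -> PhotoPhysParams:
    return PhotoPhysParams(ps_chl=float(d["ps_chl"]),
                           alpha_chl=float(d["alpha_chl"]),
                           beta_chl=float(d.get("beta_chl", 0.0)),
                           label=d.get("label", label))


def load_config(path: Optional[str] = None) -> dict:
    """Load the YAML configuration into parameter objects.

    Recognized blocks: ``photophys`` (named P-I presets), ``allocation``,
    ``nutrients`` and ``ibm``; anything omitted falls back to package
    defaults.  Returns a dict with keys ``photophys`` (dict of presets),
    ``allocation``, ``nutrients`` and ``ibm``.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    presets = dict(PHOTOPHYS_PRESETS)
    for name, block in (raw.get("photophys") or {}).items():
        presets[name] = _photophys_from_dict(block, name)
    alloc = AllocationParams(**(raw.get("allocation") or {}))
    nutrients = NutrientUptakeParams(**(raw.get("nutrients") or {}))
    ibm_block = dict(raw.get("ibm") or {})
    if "photophys" in ibm_block:
        ibm_block["photophys"] = _photophys_from_dict(
            ibm_block["photophys"], "ibm")
    ibm = IBMConfig(**ibm_block)
    return {"photophys": presets, "allocation": alloc,
            "nutrients": nutrients, "ibm": ibm}


@dataclasses.dataclass
class RunManifest:
    """Provenance record written once per CLI invocation."""

    command: str
    config_hash: str
    seeds: list[int]
    started: str = ""
    finished: str = ""
    outputs: list[str] = dataclasses.field(default_factory=list)
    version: str = "promix 0.1.0"

    @classmethod
    def start(cls, command: str, config_obj: Any, seeds: list[int]
              ) -> "RunManifest":
        blob = repr(config_obj).encode()
        return cls(command=command,
                   config_hash=hashlib.sha256(blob).hexdigest()[:16],
                   seeds=list(map(int, seeds)),
                   started=datetime.now(timezone.utc).isoformat())

    def record(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, directory) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        out = Path(directory) / "run_manifest.json"
        with open(out, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return out
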