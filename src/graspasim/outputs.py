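"""File output: CF-style NetCDF for gridded annual fields, CSV for tables,
and JSON run manifests sufficient to reproduce a run."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .synthetic_forcing import DailyMeteo, ForcingGrid

#: units recorded in file metadata
UNITS = {
    "y_cut": "kg DM ha-1 yr-1",
    "y_graze": "kg DM ha-1 yr-1",
    "npp": "g C m-2 yr-1",
    "d_opt": "LSU ha-1",
    "s_opt": "LSU ha-1",
    "f_opt": "1",
    "t_farm": "days",
    "temp": "degC",
    "precip": "mm d-1",
    "swdown": "W m-2",
    "rh": "1",
    "co2": "ppm",
    "nitrogen": "kg N ha-1 yr-1",
}


def annual_fields_to_dataset(fields: dict[str, np.ndarray],
                             grid: ForcingGrid,
                             years: np.ndarray) -> xr.Dataset:
    """Reshape (n_years, n_cells) arrays onto (year, lat, lon)."""
    n_lat, n_lon = grid.lat.size, grid.lon.size
    data = {}
    for name, arr in fields.items():
        cube = np.asarray(arr).reshape(len(years), n_lat, n_lon)
        attrs = {"units": UNITS.get(name, "1"), "long_name": name}
        data[name] = xr.DataArray(cube, dims=("year", "lat", "lon"),
                                  attrs=attrs)
    ds = xr.Dataset(data, coords={"year": np.asarray(years),
                                  "lat": grid.lat, "lon": grid.lon})
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    return ds


def write_annual_netcdf(path: str | Path, fields: dict[str, np.ndarray],
                        grid: ForcingGrid, years: np.ndarray) -> Path:
    path = Path(path)
    annual_fields_to_dataset(fields, grid, years).to_netcdf(
        path, engine="scipy")
    return path


def meteo_to_dataset(meteo: DailyMeteo, grid: ForcingGrid) -> xr.Dataset:
    """Daily meteorology on (time, lat, lon) with a day index coordinate."""
    n_lat, n_lon = grid.lat.size, grid.lon.size
    n_time = meteo.n_years * 365
    data = {}
    for name in ("temp", "precip", "swdown", "rh"):
        cube = getattr(meteo, name).reshape(n_time, n_lat, n_lon)
        data[name] = xr.DataArray(cube, dims=("time", "lat", "lon"),
                                  attrs={"units": UNITS[name]})
    return xr.Dataset(data, coords={"time": np.arange(n_time),
                                    "lat": grid.lat, "lon": grid.lon})


def write_outputs(results, path: str | Path, fmt: str, **kwargs) -> Path:
    """Write ``results`` in the requested format.

    ``fmt="netcdf"`` expects an xarray Dataset (or a dict of annual fields
    with ``grid=`` and ``years=`` keyword arguments); ``fmt="csv"`` expects
    a pandas DataFrame.  Unknown formats raise."""
    path = Path(path)
    if fmt == "netcdf":
        if isinstance(results, xr.Dataset):
            results.to_netcdf(path, engine="scipy")
        else:
            write_annual_netcdf(path, results, kwargs["grid"], kwargs["years"])
        return path
    if fmt == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, index=False)
        return path
    raise ValueError(f"unknown output format {fmt!r}")


def read_annual_netcdf(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(Path(path), engine="scipy")


@dataclass
class RunManifest:
    """Reproducibility record emitted next to every CLI output."""

    command: str
    seed: int
    config: dict
    outputs: list[str]
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str))
        return path


def start_manifest(command: str, seed: int, config: dict) -> RunManifest:
    return RunManifest(command=command, seed=seed, config=config, outputs=[],
                       started=_dt.datetime.now().isoformat())


def finish_manifest(manifest: RunManifest, outputs: list[Path],
                    out_dir: str | Path) -> Path:
    manifest.outputs = [str(p) for p in outputs]
    manifest.finished = _dt.datetime.now().isoformat()
    return manifest.write(Path(out_dir) / f"manifest_{manifest.command}.json")
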