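"""File bundles: float32 TIFF maps with JSON sidecars, CSV tables.

A "phantom bundle" is a directory with mu_a.tif / mu_s_prime.tif (float32),
labels.tif (uint16), marker.tif (uint8 mask) and meta.json (grid spec,
refractive indices, legend, marker absorption). Forward and inversion
results follow the same pattern. Multi-wavelength quantities carry a
``_w<k>`` suffix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fem import GridSpec, OpticalMap
from .forward import AbsorbedEnergyMap
from .inversion import InversionResult
from .phantoms import MarkerPrior, RegionLabelMap

CSV_FLOAT_FORMAT = "%.10g"


def _grid_meta(grid: GridSpec) -> dict:
    return {"nx": grid.nx, "ny": grid.ny, "h": grid.h}


def _grid_from_meta(meta: dict) -> GridSpec:
    return GridSpec(int(meta["nx"]), int(meta["ny"]), float(meta["h"]))


def write_map(path: Path, values: np.ndarray, dtype=np.float32) -> None:
    tifffile.imwrite(str(path), np.asarray(values).astype(dtype))


def read_map(path: Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_phantom(outdir: str | Path, optics: OpticalMap, labels: RegionLabelMap,
                  marker: MarkerPrior, suffix: str = "") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(outdir / f"mu_a{suffix}.tif", optics.mu_a)
    write_map(outdir / f"mu_s_prime{suffix}.tif", optics.mu_s_prime)
    write_map(outdir / f"labels{suffix}.tif", labels.labels, dtype=np.uint16)
    write_map(outdir / f"marker{suffix}.tif", marker.mask, dtype=np.uint8)
    meta = {
        "grid": _grid_meta(optics.grid),
        "n_in": optics.n_in,
        "n_out": optics.n_out,
        "legend": {str(k): {"name": name,
                            "mu_a": list(v) if np.ndim(v) else float(v)}
                   for k, (name, v) in labels.legend.items()},
        "mu_a_marker": float(marker.mu_a_marker),
    }
    (outdir / f"meta{suffix}.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir


def read_phantom(indir: str | Path, suffix: str = ""
                 ) -> tuple[OpticalMap, RegionLabelMap, MarkerPrior]:
    indir = Path(indir)
    meta = json.loads((indir / f"meta{suffix}.json").read_text())
    grid = _grid_from_meta(meta["grid"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        optics = OpticalMap(grid,
                            read_map(indir / f"mu_a{suffix}.tif").astype(float),
                            read_map(indir / f"mu_s_prime{suffix}.tif").astype(float),
                            n_in=float(meta["n_in"]), n_out=float(meta["n_out"]))
    legend = {int(k): (v["name"],
                       tuple(v["mu_a"]) if isinstance(v["mu_a"], list) else v["mu_a"])
              for k, v in meta["legend"].items()}
    labels = RegionLabelMap(read_map(indir / f"labels{suffix}.tif").astype(np.int16),
                            legend)
    marker = MarkerPrior(read_map(indir / f"marker{suffix}.tif").astype(bool),
                         float(meta["mu_a_marker"]))
    return optics, labels, marker


def write_energy(outdir: str | Path, h: AbsorbedEnergyMap, name: str,
                 extra_meta: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(outdir / f"{name}.tif", h.values)
    meta = {"grid": _grid_meta(h.grid), "role": h.role,
            "snr_db": h.snr_db, "seed": h.seed}
    meta.update(extra_meta or {})
    (outdir / f"{name}.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return outdir / f"{name}.tif"


def read_energy(path: str | Path) -> AbsorbedEnergyMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = read_map(path).astype(float)
    snr = meta.get("snr_db")
    return AbsorbedEnergyMap(_grid_from_meta(meta["grid"]), values,
                             role=meta.get("role", "H"),
                             snr_db=float(snr) if snr is not None else None,
                             seed=meta.get("seed"))


def write_result(outdir: str | Path, name: str, result: InversionResult,
                 grid: GridSpec, config_echo: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(outdir / f"mu_a_hat_{name}.tif", result.mu_a_hat)
    trace = pd.DataFrame({"iteration": np.arange(1, result.iterations_used + 1),
                          "log_sse": result.error_trace})
    for label, values in result.region_traces.items():
        trace[f"region_{label}_mean_mu_a"] = values
    trace.to_csv(outdir / f"trace_{name}.csv", index=False,
                 float_format=CSV_FLOAT_FORMAT)
    meta = {
        "grid": _grid_meta(grid),
        "iterations_used": result.iterations_used,
        "converged": bool(result.converged),
        "reason": result.reason,
        "config": config_echo or {},
    }
    (outdir / f"result_{name}.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))
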