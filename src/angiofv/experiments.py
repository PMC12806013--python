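"""Named experiment presets and file output.

Each preset perturbs exactly one benchmark value, mirroring the
one-factor-at-a-time parameter study: ``chi_half`` halves the maximum
chemotactic response, ``dv_x10`` raises the TAF diffusivity tenfold,
``mu_5`` raises the tumor's Robin influx coefficient to 5, and
``mu_sweep`` runs μ = 0, 0.5, …, 5 and tabulates terminal diagnostics.

A run writes: the diagnostics time series as CSV, the requested snapshot
fields as a self-describing NetCDF array container (u, v, cell-center
coordinates, time and parameter attributes), a JSON manifest of the
effective configuration, and (optionally) heatmap images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import xarray as xr

from . import __version__
from .config import ConfigError, SimulationConfig, load_config
from .diagnostics import mu_sweep_summary
from .integrate import Trajectory, run

__all__ = ["ExperimentSpec", "PRESETS", "MU_SWEEP_VALUES", "run_experiment"]

PRESETS: dict[str, dict[str, float]] = {
    "baseline": {},
    "chi_half": {"params.chi": 0.5},
    "dv_x10": {"params.Dv": 0.1},
    "mu_5": {"params.mu": 5.0},
}

#: μ grid of the sweep experiment: 0, 0.5, ..., 5.
MU_SWEEP_VALUES: tuple[float, ...] = tuple(np.arange(0.0, 5.01, 0.5))

#: Boundary closure used by the replication experiments: the literal
#: reading of the no-flux condition — zero *diffusive* EC flux on every
#: edge, with the chemotactic drift through the Robin tumor face left
#: open.  Under the alternative total-flux closure ECs pile up against
#: the tumor wall instead of exiting, which contradicts the terminal
#: EC readouts at the tumor interface the study reports (the μ=5 run in
#: particular shows suppressed, not accumulated, EC there).  A config
#: file or ``--set bc.u_leak=false`` restores the conservative closure.
STUDY_CLOSURE: dict[str, Any] = {"bc.u_leak": True}


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment: a preset plus optional extra overrides."""

    name: str = "baseline"
    overrides: Mapping[str, Any] = field(default_factory=dict)
    config_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.name not in set(PRESETS) | {"mu_sweep", "custom"}:
            raise ConfigError(
                f"unknown preset {self.name!r}; expected one of "
                f"{sorted(set(PRESETS) | {'mu_sweep', 'custom'})}"
            )

    def build_config(self) -> SimulationConfig:
        base = SimulationConfig().with_overrides(**STUDY_CLOSURE)
        cfg = load_config(self.config_path, base=base)
        cfg = cfg.with_overrides(**PRESETS.get(self.name, {}))
        return cfg.with_overrides(**dict(self.overrides))


def snapshots_to_dataset(traj: Trajectory) -> xr.Dataset:
    """Pack trajectory snapshots into a self-describing xarray Dataset."""
    grid = traj.grid
    times = [s.t for s in traj.snapshots]
    u = np.stack([s.u.values for s in traj.snapshots]) if traj.snapshots else np.empty((0, *grid.shape))
    v = np.stack([s.v.values for s in traj.snapshots]) if traj.snapshots else np.empty((0, *grid.shape))
    ds = xr.Dataset(
        {
            "u": (("time", "x", "y"), u),
            "v": (("time", "x", "y"), v),
        },
        coords={"time": times, "x": grid.x, "y": grid.y},
    )
    ds["u"].attrs["long_name"] = "endothelial cell density"
    ds["v"].attrs["long_name"] = "TAF concentration"
    if traj.config is not None:
        for key, val in traj.config.as_flat_dict().items():
            if key == "time.snapshots":
                val = list(map(float, val))
            ds.attrs[key.replace(".", "_")] = val
    ds.attrs["tumor_edge"] = traj.partition.tumor_edge
    return ds


def _write_plots(traj: Trajectory, outdir: Path, created: list[Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for snap in traj.snapshots:
        for name, fld in (("u", snap.u), ("v", snap.v)):
            fig, ax = plt.subplots(figsize=(4, 3.4))
            im = ax.imshow(
                fld.values.T,
                origin="lower",
                extent=(0, 1, 0, 1),
                cmap="viridis",
                aspect="equal",
            )
            fig.colorbar(im, ax=ax, shrink=0.85)
            ax.set_xlabel("x")
            ax.set_ylabel("y")
            ax.set_title(f"{name} at t={snap.t:g}")
            path = outdir / f"{name}_t{snap.t:g}.png"
            fig.savefig(path, dpi=110, bbox_inches="tight")
            plt.close(fig)
            created.append(path)


def run_experiment(
    spec: ExperimentSpec, outdir: str | Path, plots: bool = False
) -> dict[str, Path]:
    """Run an experiment and write its artifact set into ``outdir``.

    Returns a mapping of artifact names to paths.  On failure any
    partially written outputs are removed before the error propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    artifacts: dict[str, Path] = {}
    config = spec.build_config()

    def add(name: str, path: Path) -> Path:
        created.append(path)
        artifacts[name] = path
        return path

    try:
        manifest = {
            "experiment": spec.name,
            "config": config.as_flat_dict(),
            "code_version": __version__,
        }
        if spec.name == "mu_sweep":
            table = mu_sweep_summary(list(MU_SWEEP_VALUES), config)
            table.to_csv(add("mu_sweep", outdir / "mu_sweep.csv"), index=False)
            manifest["mu_values"] = list(MU_SWEEP_VALUES)
        else:
            traj = run(config)
            traj.to_frame().to_csv(add("diagnostics", outdir / "diagnostics.csv"), index=False)
            ds = snapshots_to_dataset(traj)
            ds.to_netcdf(add("snapshots", outdir / "snapshots.nc"), engine="scipy")
            manifest["n_steps"] = traj.n_steps
            first, last = traj.diagnostics[0], traj.diagnostics[-1]
            manifest["u_mass_relative_drift"] = (
                abs(last.mass_u - first.mass_u) / first.mass_u if first.mass_u else 0.0
            )
            if plots:
                _write_plots(traj, outdir, created)
        path = add("manifest", outdir / "manifest.json")
        path.write_text(json.dumps(manifest, indent=2, default=float) + "\n")
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise
    return artifacts
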