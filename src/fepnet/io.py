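"""Deterministic serialisation of simulation results, run manifests and
small test fixtures.

All outputs are plain text: comma-separated tables with a header row (time
recorded in integer steps; millisecond conversion is left to reporting so
that written files are exactly reproducible), adjacency snapshots as edge
lists, and a JSON manifest holding the configuration, seeds, and a SHA-256
checksum for every file written.  Re-running with the manifest's
configuration reproduces checksum-identical rasters.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import SimulationConfig
from .engine import Network, SimulationResult

__all__ = ["write_results", "read_results", "make_fixtures", "RunManifest"]


class RunManifest(dict):
    """Manifest of one simulation run (a thin dict with typed access)."""

    @property
    def files(self) -> dict[str, str]:
        return self["files"]

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_wide(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def write_results(
    result: SimulationResult, outdir: str | Path, plots: bool = False
) -> RunManifest:
    """Serialise a :class:`SimulationResult` into a directory of text files.

    Files written: ``raster.csv`` (long format: time_step, neuron_id,
    spike), ``fired.csv``, ``firing_prob.csv``, ``potential.csv``,
    ``free_energy.csv`` (wide format, one column per neuron),
    ``zeta_period_<t>.csv`` per plasticity snapshot and
    ``adjacency_epoch_<t>.csv`` per pruning snapshot (edge lists
    ``pre,post``), ``config.json`` and ``manifest.json``.  With
    ``plots=True`` a raster image and the sliding free-energy curves are
    rendered as well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    n_steps, n = result.raster.shape
    files: list[Path] = []

    steps = np.arange(1, n_steps + 1)
    t_idx, n_idx = np.nonzero(np.ones_like(result.raster))
    raster_long = pd.DataFrame(
        {
            "time_step": t_idx + 1,
            "neuron_id": n_idx,
            "spike": result.raster[t_idx, n_idx],
        }
    )
    p = outdir / "raster.csv"
    _write_wide(raster_long, p)
    files.append(p)

    cols = [f"n{i}" for i in range(n)]
    for name, arr in (
        ("fired", result.fired),
        ("firing_prob", result.firing_prob),
        ("potential", result.potential),
        ("free_energy", result.free_energy),
    ):
        df = pd.DataFrame(arr, columns=cols)
        df.insert(0, "time_step", steps)
        p = outdir / f"{name}.csv"
        _write_wide(df, p)
        files.append(p)

    for t, z in zip(result.zeta_times, result.zeta_traj):
        pre, post = np.nonzero(z.T)
        df = pd.DataFrame(
            {"pre": pre, "post": post, "zeta": z.T[pre, post]}
        )
        p = outdir / f"zeta_period_{int(t):05d}.csv"
        _write_wide(df, p)
        files.append(p)

    for t, adj in zip(result.adjacency_times, result.adjacency):
        pre, post = np.nonzero(adj.T)
        df = pd.DataFrame({"pre": pre, "post": post})
        p = outdir / f"adjacency_epoch_{int(t):05d}.csv"
        _write_wide(df, p)
        files.append(p)

    p = outdir / "config.json"
    p.write_text(json.dumps(result.config.to_dict(), indent=2, sort_keys=True)
                 + "\n", encoding="utf-8")
    files.append(p)

    if plots:
        files += _render_plots(result, outdir)

    manifest = RunManifest(
        version=_pkg_version,
        config=result.config.to_dict(),
        seeds={
            "structure_seed": result.config.structure_seed,
            "action_seed": result.config.action_seed,
        },
        n_steps=n_steps,
        n_neurons=n,
        elapsed_s=round(time.perf_counter() - t_start, 4),
        files={f.name: _sha256(f) for f in files},
    )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return manifest


def _render_plots(result: SimulationResult, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.imshow(result.raster.T, aspect="auto", cmap="gray_r",
              interpolation="nearest")
    ax.set_xlabel("time step")
    ax.set_ylabel("neuron")
    p = outdir / "raster.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(10, 4))
    sliding = result.free_energy_trace().sliding_mean(result.config.fe_window)
    ax.plot(sliding, lw=0.6, alpha=0.5)
    ax.plot(sliding.mean(axis=1), lw=2.0, color="k", label="ensemble mean")
    ax.set_xlabel("time step")
    ax.set_ylabel("sliding free energy")
    ax.legend()
    p = outdir / "free_energy.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written


def read_results(outdir: str | Path) -> SimulationResult:
    """Reconstruct a :class:`SimulationResult` from :func:`write_results`
    output (trace arrays, adjacency and precision snapshots, config)."""
    outdir = Path(outdir)
    with open(outdir / "config.json", "r", encoding="utf-8") as fh:
        config = SimulationConfig.from_dict(json.load(fh))
    n = config.n_neurons

    raster_long = pd.read_csv(outdir / "raster.csv")
    n_steps = int(raster_long["time_step"].max())
    raster = np.zeros((n_steps, n), dtype=np.int8)
    raster[raster_long["time_step"] - 1, raster_long["neuron_id"]] = (
        raster_long["spike"]
    )

    def wide(name: str, dtype=float) -> np.ndarray:
        df = pd.read_csv(outdir / f"{name}.csv")
        return df.drop(columns="time_step").to_numpy(dtype=dtype)

    zeta_paths = sorted(outdir.glob("zeta_period_*.csv"))
    zeta_times = [int(p.stem.split("_")[-1]) for p in zeta_paths]
    zeta_traj = []
    for p in zeta_paths:
        df = pd.read_csv(p)
        z = np.zeros((n, n))
        z[df["post"], df["pre"]] = df["zeta"]
        zeta_traj.append(z)

    adj_paths = sorted(outdir.glob("adjacency_epoch_*.csv"))
    adj_times = [int(p.stem.split("_")[-1]) for p in adj_paths]
    adjacency = []
    for p in adj_paths:
        df = pd.read_csv(p)
        a = np.zeros((n, n), dtype=bool)
        a[df["post"], df["pre"]] = True
        adjacency.append(a)

    final_active = (adjacency[-1] if adjacency
                    else ~np.eye(n, dtype=bool))
    final_zeta = (zeta_traj[-1] if zeta_traj
                  else np.where(final_active, config.initial_zeta, 0.0))

    return SimulationResult(
        config=config,
        raster=raster,
        fired=wide("fired", np.int8),
        firing_prob=wide("firing_prob"),
        potential=wide("potential"),
        free_energy=wide("free_energy"),
        zeta_traj=(np.array(zeta_traj) if zeta_traj
                   else np.zeros((0, n, n))),
        zeta_times=np.array(zeta_times, dtype=int),
        adjacency=(np.array(adjacency) if adjacency
                   else np.zeros((0, n, n), dtype=bool)),
        adjacency_times=np.array(adj_times, dtype=int),
        reduction_traces=np.zeros((0, n, n)),
        final_zeta=final_zeta,
        final_active=final_active,
        windows=np.zeros(n, dtype=int),
    )


def make_fixtures(seed: int = 0) -> dict[str, Any]:
    """Small deterministic inputs for unit tests.

    Returns a bundle with a two-neuron configuration, the observation
    sequence and belief traces of a short run of that network, and
    precomputed message values for the hand-checkable inference examples.
    Identical seeds give byte-identical bundles.
    """
    config = SimulationConfig(
        n_neurons=2,
        n_steps=100,
        phase_spread=10,
        structure_seed=seed,
        action_seed=seed,
    )
    net = Network(config)
    result = net.run()
    # observation sequence as seen by neuron 0 (spikes of neuron 1, lagged)
    obs_seq = np.concatenate(([0], result.raster[:-1, 1])).astype(int)

    abar = np.array([[0.75, 0.25], [0.25, 0.75]])
    messages = {
        "abar": abar.tolist(),
        "zeta": 0.5,
        "obs": [1, 1],
        "message": (
            2 * 0.5 * np.log(abar[1, :])
        ).tolist(),
    }
    return {
        "config": config,
        "raster": result.raster.copy(),
        "fired": result.fired.copy(),
        "beliefs": result.firing_prob.copy(),
        "observation_sequence": obs_seq,
        "messages": messages,
    }
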