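"""Run artifacts: CSV time series, JSON metrics, manifest, optional plots.

Outputs are fully deterministic: field ordering is fixed and two identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import config_hash, dump_config
from .simulate import Metrics, SimulationResult

_CSV_COLUMNS = ("t", "e", "v", "F1", "F2", "u1", "u2")
_UNITS_LINE = "# units: t[s] e[m] v[m/s] F1[N] F2[N] u1[N] u2[N]\n"


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record: same manifest => bit-identical outputs."""

    config_hash: str
    preset: str
    version: str
    gains: list[list[float]]
    outputs: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "preset": self.preset,
            "version": self.version,
            "gains": self.gains,
            "outputs": self.outputs,
        }


def result_frame(res: SimulationResult) -> pd.DataFrame:
    """Time series as a DataFrame on the post-step time grid (forces and
    controls exist per step, not at t=0, so the initial sample is dropped)."""
    return pd.DataFrame({
        "t": res.t[1:],
        "e": res.e[1:],
        "v": res.v[1:],
        "F1": res.F1,
        "F2": res.F2,
        "u1": res.u1,
        "u2": res.u2,
    })[list(_CSV_COLUMNS)]


def write_outputs(
    res: SimulationResult, metrics: Metrics, out_dir: str | Path,
    plots: bool = False,
) -> RunManifest:
    """Write ``timeseries.csv``, ``metrics.json``, ``manifest.json`` (and
    optional PNG plots) into ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = res.config

    csv_path = out / "timeseries.csv"
    frame = result_frame(res)
    with open(csv_path, "w", newline="") as fh:
        fh.write(_UNITS_LINE)
        frame.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")

    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=False) + "\n")

    config_path = out / "config.json"
    config_path.write_text(json.dumps(dump_config(cfg), indent=2) + "\n")

    outputs = {"timeseries": csv_path.name, "metrics": metrics_path.name,
               "config": config_path.name}
    if plots:
        outputs["plot"] = _write_plot(res, out)

    manifest = RunManifest(
        config_hash=config_hash(cfg),
        preset=cfg.name,
        version=__version__,
        gains=[k.ravel().tolist() for k in res.gains],
        outputs=outputs,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2) + "\n")
    return manifest


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a ``timeseries.csv`` back (units comment line skipped)."""
    return pd.read_csv(path, comment="#")


def _write_plot(res: SimulationResult, out: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(res.t, res.e, color="k")
    ax1.set_xlabel("t [s]"); ax1.set_ylabel("object error [m]")
    a1, a2 = res.config.agent1.label, res.config.agent2.label
    ax2.plot(res.t[1:], res.F1, label=a1)
    ax2.plot(res.t[1:], res.F2, label=a2, linestyle="--")
    ax2.set_xlabel("t [s]"); ax2.set_ylabel("force [N]"); ax2.legend()
    fig.suptitle(res.config.name)
    fig.tight_layout()
    name = "trajectory.png"
    fig.savefig(out / name, dpi=120)
    plt.close(fig)
    return name
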