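"""TSV / JSON serialization for populations, spikes, positions and results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Geometry, PlaceFieldParams, TrialRateMatrix

__all__ = [
    "write_population", "read_population",
    "write_spikes", "write_positions", "write_manifest",
]

PARAM_COLUMNS = ["neuron_id", "A", "mu", "sigma", "B0", "noise_sd",
                 "jitter_max", "presence", "seed"]


def write_population(
    population: Sequence[tuple[PlaceFieldParams, TrialRateMatrix]],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write params.tsv (one row per neuron) and rates.tsv (long format)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    param_rows, rate_rows = [], []
    for i, (p, m) in enumerate(population):
        mu = np.atleast_1d(np.asarray(p.mu, dtype=float))
        param_rows.append({
            "neuron_id": i, "A": p.a, "mu": ",".join(f"{v:g}" for v in mu),
            "sigma": p.sigma, "B0": p.b0, "noise_sd": p.noise_sd,
            "jitter_max": p.jitter_max, "presence": p.presence,
            "seed": str(m.provenance.get("seed", "")),
        })
        trials, bins = np.nonzero(np.ones_like(m.rates))
        rate_rows.append(pd.DataFrame({
            "neuron_id": i, "trial": trials, "bin": bins,
            "rate_hz": m.rates.ravel(),
        }))
    params_path = out / "params.tsv"
    rates_path = out / "rates.tsv"
    pd.DataFrame(param_rows, columns=PARAM_COLUMNS).to_csv(
        params_path, sep="\t", index=False)
    pd.concat(rate_rows, ignore_index=True).to_csv(
        rates_path, sep="\t", index=False, float_format="%.10g")
    return params_path, rates_path


def read_population(rates_path: str | Path,
                    geometry: Geometry | None = None) -> list[TrialRateMatrix]:
    """Rebuild trial rate matrices from a long-format rates.tsv."""
    df = pd.read_csv(rates_path, sep="\t")
    matrices = []
    for neuron_id, g in df.groupby("neuron_id", sort=True):
        wide = g.pivot(index="trial", columns="bin", values="rate_hz")
        wide = wide.sort_index().sort_index(axis=1)
        rates = wide.to_numpy(dtype=float)
        geom = geometry or Geometry.linear(rates.shape[1])
        matrices.append(TrialRateMatrix(
            rates, geom, {"kind": "file", "neuron_id": int(neuron_id)}))
    return matrices


def write_spikes(spikes_by_neuron: dict[int, np.ndarray],
                 path: str | Path) -> Path:
    rows = [pd.DataFrame({"neuron_id": nid, "spike_time_s": times})
            for nid, times in spikes_by_neuron.items()]
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["neuron_id", "spike_time_s"]))
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_positions(positions: dict[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": positions["time_s"],
        "position": positions["position"],
        "trial": positions["trial"],
    }).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def write_manifest(out_dir: str | Path, **entries) -> Path:
    """JSON run manifest: config, seeds, package version, row counts."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "placecells", "version": __version__}
    manifest.update(entries)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
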