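"""Parameter-sweep and sensitivity experiments on simulated populations."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, estimate_features
from .metrics import anova_f, spatial_information
from .ratemaps import rebin, smooth_map
from .simulate import Geometry, SweepSpec, TrialRateMatrix, sample_population

logger = logging.getLogger(__name__)

__all__ = ["SweepResult", "run_sweep", "run_sensitivity"]


@dataclass
class SweepResult:
    """Per-neuron long table, per-value summary, and argmax records."""

    spec: SweepSpec
    long: pd.DataFrame      # parameter, swept_value, neuron_id, si, f_stat, ...
    summary: pd.DataFrame   # per swept value: mean and SD of each metric
    argmax: dict            # swept value maximising each metric's mean


def _stage(name: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info("stage=%s n_in=%d n_out=%d seconds=%.2f",
                name, n_in, n_out, time.time() - t0)


def run_sweep(
    spec: SweepSpec,
    geometry: Geometry | None = None,
    compute_features: bool = False,
    smooth_sd: float = 0.0,
) -> SweepResult:
    """Simulate a one-parameter population sweep and score every neuron.

    SI is computed on the (optionally smoothed) trial-averaged map, the
    ANOVA F on the trial x bin matrix; smoothing is never implicit
    (``smooth_sd=0`` by default).
    """
    t0 = time.time()
    population = sample_population(spec, geometry=geometry)
    _stage("simulate", spec.n_samples, len(population), t0)

    t0 = time.time()
    rows = []
    for i, (params, matrix) in enumerate(population):
        rates = (smooth_map(matrix.rates, smooth_sd, matrix.geometry)
                 if smooth_sd > 0 else matrix.rates)
        scored = TrialRateMatrix(rates, matrix.geometry, matrix.provenance)
        row = {
            "parameter": spec.parameter,
            "swept_value": matrix.provenance["swept_value"],
            "neuron_id": i,
            "si": spatial_information(scored.mean_map()),
            "f_stat": anova_f(scored).f_stat,
            "seed": str(matrix.provenance["seed"]),
        }
        if compute_features and matrix.geometry.ndim == 1:
            fv = estimate_features(scored)
            row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        rows.append(row)
    long = pd.DataFrame(rows)
    metric_cols = [c for c in long.columns
                   if c not in ("parameter", "swept_value", "neuron_id", "seed")]
    summary = long.groupby("swept_value")[metric_cols].agg(["mean", "std"])
    argmax = {c: float(summary[(c, "mean")].idxmax()) for c in ("si", "f_stat")}
    _stage("score", len(population), len(long), t0)
    return SweepResult(spec=spec, long=long, summary=summary, argmax=argmax)


def width_sweep_study(
    seed: int = 0,
    neurons_per_sigma: int = 200,
    sigmas=tuple(range(1, 21)),
    n_trials: int = 30,
    geometry: Geometry | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Field-width sweep at fixed conditions: which sigma maximises each metric.

    Simulates ``neurons_per_sigma`` neurons at every width in ``sigmas``
    (peak 10 Hz, baseline 1 Hz, noise SD 1 Hz, presence 1, no jitter, 30
    trials on the 50-bin track), scores each neuron with both statistics,
    and reports per-sigma population means plus the argmax sigma of each
    mean curve.  Both curves are non-monotonic: spatial information peaks at
    narrow fields, the ANOVA F at intermediate ones.
    """
    from .metrics import f_batch, si_batch

    t0 = time.time()
    rows = []
    for sigma in sigmas:
        sub_seed = int(np.random.SeedSequence((seed, int(sigma))
                                              ).generate_state(1)[0] % 2**31)
        spec = SweepSpec("width", float(sigma), float(sigma),
                         neurons_per_sigma, n_trials=n_trials, seed=sub_seed)
        stack = np.stack([m.rates for _, m in
                          sample_population(spec, geometry=geometry)])
        rows.append({
            "sigma": float(sigma),
            "mean_si": float(np.mean(si_batch(stack.mean(axis=1)))),
            "mean_f": float(np.mean(f_batch(stack))),
            "n_neurons": neurons_per_sigma,
        })
    summary = pd.DataFrame(rows)
    argmax = {
        "si": float(summary.loc[summary.mean_si.idxmax(), "sigma"]),
        "f_stat": float(summary.loc[summary.mean_f.idxmax(), "sigma"]),
    }
    _stage("width_sweep_study", len(summary) * neurons_per_sigma,
           len(summary), t0)
    return summary, argmax


def run_sensitivity(
    population: list[tuple[object, TrialRateMatrix]],
    variants: list[dict],
) -> pd.DataFrame:
    """Re-score the same neurons under re-binning / smoothing variants.

    ``variants`` is a list of dicts with optional keys ``n_bins`` (must
    divide the source bin count in every dimension) and ``smooth_sd``
    (Gaussian kernel SD in bins, applied per trial row after re-binning).
    Returns a long table with paired per-neuron metrics for sign tests;
    the identity variant (source bins, no smoothing) reproduces the
    baseline metrics exactly.
    """
    rows = []
    for v_id, variant in enumerate(variants):
        unknown = set(variant) - {"n_bins", "smooth_sd", "label"}
        if unknown:
            raise ValueError(f"unknown variant keys: {sorted(unknown)}")
        n_bins = variant.get("n_bins")
        smooth_sd = float(variant.get("smooth_sd", 0.0))
        label = variant.get("label", f"variant_{v_id}")
        for i, (_, matrix) in enumerate(population):
            m = rebin(matrix, n_bins) if n_bins is not None else matrix
            if smooth_sd > 0:
                m = TrialRateMatrix(
                    smooth_map(m.rates, smooth_sd, m.geometry),
                    m.geometry, m.provenance)
            rows.append({
                "variant": label,
                "n_bins": m.n_bins,
                "smooth_sd": smooth_sd,
                "neuron_id": i,
                "si": spatial_information(m.mean_map()),
                "f_stat": anova_f(m).f_stat,
            })
    return pd.DataFrame(rows)
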