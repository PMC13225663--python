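"""Spatial tuning statistics: spatial information and the one-way ANOVA F.

Spatial information (Skaggs-style, bits/spike) is computed on the
trial-averaged rate map::

    SI = sum_x p(x) * (g(x) / gbar) * log2(g(x) / gbar)

where p(x) is the occupancy probability of bin x, g(x) the mean rate in bin
x, and gbar the overall mean rate.  It rewards contrast between a neuron's
peak and average firing and is insensitive to trial-to-trial variability
because averaging precedes the computation.

The ANOVA F-statistic treats spatial bins as groups and per-trial rates as
observations: F = MS_between / MS_within.  It rewards spatial structure that
is consistent across trials, and penalises trial-level variance.  Both
statistics treat bins as unordered categories, so 2D arenas are analysed on
the flattened bin set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .simulate import TrialRateMatrix

__all__ = ["TuningCurve", "MetricResult", "spatial_information", "anova_f"]


@dataclass
class TuningCurve:
    """Trial-averaged rate map plus the occupancy used to weight it."""

    rates: np.ndarray
    occupancy_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.occupancy_p is None:
            n = self.rates.size
            self.occupancy_p = np.full(n, 1.0 / n)
        else:
            self.occupancy_p = np.asarray(self.occupancy_p, dtype=float)

    @property
    def overall_mean(self) -> float:
        return float(np.sum(self.occupancy_p * self.rates))


@dataclass
class MetricResult:
    """One computed statistic with its degrees of freedom and flags."""

    si: float | None = None
    f_stat: float | None = None
    df_between: int | None = None
    df_within: int | None = None
    flags: list[str] = field(default_factory=list)


def spatial_information(
    rates: np.ndarray | TuningCurve,
    occupancy_p: np.ndarray | None = None,
    mean: Literal["weighted", "unweighted"] = "weighted",
) -> float:
    """Spatial information in bits/spike of a trial-averaged rate map.

    Parameters
    ----------
    rates : mean rate per bin (Hz), or a :class:`TuningCurve`.
    occupancy_p : occupancy probability per bin; uniform if omitted.
        Must sum to 1 over the included (non-NaN) bins.
    mean : whether the overall mean rate gbar is occupancy-weighted
        (consistent with the definition above) or a plain bin average.

    Bins with zero rate contribute 0 (the x*log x -> 0 limit).  A silent
    neuron (gbar == 0) yields NaN.  NaN bins (missing occupancy) are
    excluded, with occupancy renormalised over the remainder.
    """
    if isinstance(rates, TuningCurve):
        curve = rates
    else:
        curve = TuningCurve(np.asarray(rates, dtype=float), occupancy_p)
    g = curve.rates
    p = curve.occupancy_p
    valid = ~np.isnan(g)
    g = g[valid]
    p = p[valid]
    if g.size == 0:
        return float("nan")
    if np.any(g < 0):
        raise ValueError("firing rates must be non-negative")
    total_p = p.sum()
    if total_p <= 0:
        raise ValueError("occupancy must have positive mass")
    p = p / total_p
    gbar = float(np.sum(p * g)) if mean == "weighted" else float(np.mean(g))
    if gbar == 0.0:
        return float("nan")
    ratio = g / gbar
    active = ratio > 0
    return float(np.sum(p[active] * ratio[active] * np.log2(ratio[active])))


def anova_f(matrix: TrialRateMatrix | np.ndarray) -> MetricResult:
    """One-way between-groups ANOVA with spatial bins as groups.

    Observations are per-trial rates within each bin; NaN entries (bins
    without occupancy on a trial) are treated as missing, giving unbalanced
    group sizes.  Degenerate cases are flagged: zero within-variance with
    remaining between-bin structure yields +inf, a constant matrix yields
    NaN.
    """
    rates = matrix.rates if isinstance(matrix, TrialRateMatrix) else np.asarray(
        matrix, dtype=float)
    if rates.ndim != 2:
        raise ValueError("expected a trials x bins matrix")
    counts = np.sum(~np.isnan(rates), axis=0)
    keep = counts > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 bins with data")
    rates = rates[:, keep]
    counts = counts[keep]
    n_total = int(counts.sum())
    k = rates.shape[1]
    if n_total - k < 1:
        raise ValueError("need at least 2 trials of data overall")
    group_means = np.nanmean(rates, axis=0)
    grand_mean = np.nansum(rates) / n_total
    ss_between = float(np.sum(counts * (group_means - grand_mean) ** 2))
    ss_within = float(np.nansum((rates - group_means[None, :]) ** 2))
    df_between = k - 1
    df_within = n_total - k
    result = MetricResult(df_between=df_between, df_within=df_within)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    # tolerance scaled to the data magnitude: pure float round-off must not
    # masquerade as real variance
    scale = max(abs(grand_mean), 1.0)
    tiny = (scale * 1e-12) ** 2
    if ms_within <= tiny:
        if ms_between <= tiny:
            result.f_stat = float("nan")
            result.flags.append("constant matrix")
        else:
            result.f_stat = float("inf")
            result.flags.append("degenerate: zero within-variance")
        return result
    result.f_stat = ms_between / ms_within
    return result


# ---------------------------------------------------------------------------
# vectorised batch helpers (used by the permutation machinery, where the same
# statistic is evaluated over hundreds of surrogate matrices at once)

def si_batch(mean_maps: np.ndarray, occupancy_p: np.ndarray | None = None) -> np.ndarray:
    """Spatial information for each row of a (n_sets, n_bins) mean-map stack."""
    g = np.asarray(mean_maps, dtype=float)
    n = g.shape[1]
    p = (np.full(n, 1.0 / n) if occupancy_p is None
         else np.asarray(occupancy_p, dtype=float) / np.sum(occupancy_p))
    gbar = g @ p
    out = np.full(g.shape[0], np.nan)
    ok = gbar > 0
    ratio = g[ok] / gbar[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ratio > 0, ratio * np.log2(ratio), 0.0)
    out[ok] = terms @ p
    return out


def f_batch(stack: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each (trials x bins) matrix in a 3D stack.

    Assumes complete (non-NaN) balanced data, as produced by the simulator.
    Degenerate matrices yield inf or NaN as in :func:`anova_f`.
    """
    x = np.asarray(stack, dtype=float)
    n_trials, n_bins = x.shape[1], x.shape[2]
    group_means = x.mean(axis=1)
    grand = group_means.mean(axis=1)
    ss_between = n_trials * np.sum((group_means - grand[:, None]) ** 2, axis=1)
    ss_within = np.sum((x - group_means[:, None, :]) ** 2, axis=(1, 2))
    ms_between = ss_between / (n_bins - 1)
    ms_within = ss_within / (n_bins * (n_trials - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    return f
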