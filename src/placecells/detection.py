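"""Permutation nulls, significance rules, and classification curves.

Two surrogate generators break the spike-position (or rate-position)
relationship while preserving everything else about a neuron's firing:

* ``circular_surrogates`` rotates all spike times by a random offset modulo
  the session length, preserving spike count, rate and autocorrelation.
* ``rate_row_surrogates`` circularly shifts every trial row of a rate
  matrix by an independent bin offset — the rate-level analogue, used for
  simulated matrices that have no underlying spike train.

A neuron is significant when its observed statistic strictly exceeds the
95th percentile of its own null distribution (per-neuron alpha = 0.05, no
correction across neurons).  A fixed spatial-information threshold
(default 0.25 bits/spike) is provided as the alternative criterion used in
much of the rodent literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .metrics import f_batch, si_batch
from .simulate import TrialRateMatrix

__all__ = [
    "NullDistribution",
    "DetectionResult",
    "circular_surrogates",
    "rate_row_surrogates",
    "null_distributions",
    "permutation_test",
    "classify_cells",
    "binned_proportion_curve",
    "CATEGORIES",
]

CATEGORIES = ("both", "si_only", "anova_only", "neither")

DEFAULT_N_SURROGATES = 1000
DEFAULT_SI_THRESHOLD = 0.25


@dataclass
class NullDistribution:
    """Surrogate statistic values for one neuron and one metric."""

    values: np.ndarray
    method: Literal["spike_circular_shift", "rate_row_shift"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("null distribution must be non-empty")

    @property
    def n_surrogates(self) -> int:
        return self.values.size

    def percentile(self, q: float = 95.0) -> float:
        return float(np.percentile(self.values, q))

    @property
    def percentile_95(self) -> float:
        return self.percentile(95.0)


@dataclass
class DetectionResult:
    """Per-neuron detection outcome under both metrics and both criteria."""

    si: float
    f_stat: float
    p_si: float
    p_f: float
    sig_si_perm: bool
    sig_f_perm: bool
    sig_si_thresh: bool
    category: str
    method: str
    si_threshold: float = DEFAULT_SI_THRESHOLD
    flags: list[str] = field(default_factory=list)


def apply_circular_shift(spike_times: np.ndarray,
                         session_bounds: tuple[float, float],
                         offset: float) -> np.ndarray:
    """One circular time shift: rotate all spikes by ``offset`` modulo the
    session length.  Offsets of 0 or the full session length are identities."""
    spikes = np.asarray(spike_times, dtype=float)
    t0, t1 = session_bounds
    return np.sort(np.mod(spikes - t0 + offset, t1 - t0) + t0)


def circular_surrogates(
    spike_times: np.ndarray,
    session_bounds: tuple[float, float],
    n: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.SeedSequence | None = None,
    min_shift_s: float = 1.0,
) -> np.ndarray:
    """``n`` circularly time-shifted copies of a spike train.

    Each surrogate shifts every spike by one uniform offset drawn from
    [min_shift, T - min_shift] and wraps modulo the session length T,
    excluding near-zero shifts that would trivially reproduce the observed
    statistic.  Returns an (n, n_spikes) array of sorted spike times.
    """
    spikes = np.asarray(spike_times, dtype=float)
    t0, t1 = session_bounds
    T = t1 - t0
    if T <= 2 * min_shift_s:
        raise ValueError("session shorter than twice the minimum shift")
    if spikes.size and (spikes.min() < t0 or spikes.max() > t1):
        raise ValueError("spikes must lie within the session bounds")
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(min_shift_s, T - min_shift_s, size=n)
    shifted = np.mod(spikes[None, :] - t0 + offsets[:, None], T) + t0
    return np.sort(shifted, axis=1)


def rate_row_surrogates(
    matrix: TrialRateMatrix | np.ndarray,
    n: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """``n`` surrogate matrices with every trial row circularly bin-shifted.

    Each surrogate draws an independent offset per trial row, preserving
    each row's multiset of values (and hence row sums) exactly while
    scrambling the across-trial spatial alignment.  Returns an
    (n, n_trials, n_bins) array.
    """
    rates = matrix.rates if isinstance(matrix, TrialRateMatrix) else np.asarray(
        matrix, dtype=float)
    n_trials, n_bins = rates.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins to shift")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, n_bins, size=(n, n_trials))
    cols = (np.arange(n_bins)[None, None, :] + offsets[:, :, None]) % n_bins
    return rates[np.arange(n_trials)[None, :, None], cols]


def null_distributions(
    matrix: TrialRateMatrix,
    n: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[NullDistribution, NullDistribution]:
    """(SI null, F null) from one shared set of row-shift surrogates."""
    surrogates = rate_row_surrogates(matrix, n=n, seed=seed)
    si_null = si_batch(surrogates.mean(axis=1))
    f_null = f_batch(surrogates)
    return (NullDistribution(si_null, "rate_row_shift"),
            NullDistribution(f_null, "rate_row_shift"))


def permutation_test(
    observed: float,
    null: NullDistribution,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Permutation p-value and the percentile significance decision.

    Significant iff the observed value strictly exceeds the
    100*(1-alpha) percentile of the null (ties lose).  The reported
    p-value uses the standard add-one counting formula
    p = (1 + #{null >= observed}) / (1 + n).  A NaN observed statistic is
    never significant.
    """
    values = null.values
    if np.isnan(observed):
        return float("nan"), False
    p = (1.0 + np.sum(values >= observed)) / (1.0 + values.size)
    significant = bool(observed > null.percentile(100.0 * (1.0 - alpha)))
    return float(p), significant


def classify_cells(
    sig_si: Sequence[bool],
    sig_f: Sequence[bool],
) -> tuple[np.ndarray, dict[str, int]]:
    """Four-way partition by the two significance flags.

    Returns per-neuron categories plus counts over
    {both, si_only, anova_only, neither}; counts sum to n.
    """
    si = np.asarray(sig_si)
    f = np.asarray(sig_f)
    if si.shape != f.shape:
        raise ValueError("flag vectors must align")
    if si.dtype != bool or f.dtype != bool:
        raise ValueError("flags must be boolean (no missing values)")
    cats = np.where(si & f, "both",
                    np.where(si, "si_only",
                             np.where(f, "anova_only", "neither")))
    counts = {c: int(np.sum(cats == c)) for c in CATEGORIES}
    return cats, counts


def binned_proportion_curve(
    scores: np.ndarray,
    flags: np.ndarray,
    n_score_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of flagged neurons per score bin (equal-count bins).

    Serves both the score-vs-significance curves (flags = one criterion's
    outcome) and the criterion-agreement curves (flags = the two criteria
    agreeing), as a function of the underlying score.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=float)
    if scores.shape != flags.shape:
        raise ValueError("scores and flags must align")
    if scores.size < n_score_bins:
        raise ValueError("fewer neurons than score bins")
    order = np.argsort(scores, kind="stable")
    chunks = np.array_split(order, n_score_bins)
    centers = np.array([scores[c].mean() for c in chunks])
    proportions = np.array([flags[c].mean() for c in chunks])
    return centers, proportions
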