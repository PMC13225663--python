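"""Occupancy-normalised rate maps from spikes and positions, plus QC.

Rates are spike counts per spatial bin divided by the time spent in that
bin.  Bins are half-open intervals [edge_i, edge_{i+1}) with 0-based
indices; a position exactly at the track end falls in the last bin.  Bins a
subject never occupied on a trial are missing data (NaN), not zero — they
are excluded from spatial information's sum and from the ANOVA's groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .simulate import Geometry, TrialRateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PositionTrace",
    "Occupancy",
    "QCCriteria",
    "NeuronSummary",
    "SessionSummary",
    "compute_occupancy",
    "trial_rate_matrix",
    "smooth_map",
    "qc_filter",
    "rebin",
    "mask_edge_bins",
]


@dataclass
class PositionTrace:
    """Timestamped 1D positions, optionally with per-sample trial id and speed.

    Speed (cm/s or track-units/s) is derived by central differences when not
    supplied.
    """

    times: np.ndarray
    positions: np.ndarray
    trial_ids: np.ndarray | None = None
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1D array")
        if self.positions.shape != self.times.shape:
            raise ValueError("positions must align with times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.speed is None:
            if self.times.size > 1:
                self.speed = np.abs(np.gradient(self.positions, self.times))
            else:
                self.speed = np.zeros_like(self.positions)
        else:
            self.speed = np.asarray(self.speed, dtype=float)

    def sample_durations(self) -> np.ndarray:
        """Seconds attributed to each sample (central differences of time)."""
        if self.times.size == 1:
            return np.zeros(1)
        return np.gradient(self.times)


@dataclass
class Occupancy:
    """Time per bin (s) and the occupancy probability p(x)."""

    seconds_per_bin: np.ndarray
    p_x: np.ndarray

    @classmethod
    def from_seconds(cls, seconds: np.ndarray) -> "Occupancy":
        seconds = np.asarray(seconds, dtype=float)
        total = seconds.sum()
        if total <= 0:
            raise ValueError("empty occupancy")
        return cls(seconds, seconds / total)


def _bin_index(positions: np.ndarray, geometry: Geometry) -> np.ndarray:
    n = geometry.n_bins_total
    track_len = n * geometry.bin_width
    idx = np.floor(positions / geometry.bin_width).astype(int)
    # position exactly at the track end belongs to the last bin
    idx[positions >= track_len] = n - 1
    idx = np.clip(idx, 0, n - 1)
    return idx


def compute_occupancy(trace: PositionTrace, geometry: Geometry,
                      min_speed: float = 0.0) -> Occupancy:
    """Time spent per bin, counting only samples at or above ``min_speed``."""
    if geometry.ndim != 1:
        raise ValueError("occupancy from traces is supported for 1D tracks")
    dt = trace.sample_durations()
    keep = trace.speed >= min_speed
    if not np.any(keep) or dt[keep].sum() <= 0:
        raise ValueError("empty occupancy")
    idx = _bin_index(trace.positions[keep], geometry)
    seconds = np.bincount(idx, weights=dt[keep],
                          minlength=geometry.n_bins_total).astype(float)
    return Occupancy.from_seconds(seconds)


def trial_rate_matrix(
    spikes: np.ndarray,
    trace: PositionTrace,
    geometry: Geometry,
    trial_windows: np.ndarray,
    min_speed: float = 0.0,
) -> tuple[TrialRateMatrix, np.ndarray]:
    """Trials x bins rate matrix plus the per-trial occupancy seconds.

    rate[t, x] = spikes of trial t landing in bin x, divided by the seconds
    bin x was occupied during trial t.  Spike positions are interpolated
    from the trace; spikes outside every window are ignored (their count is
    logged).  Zero-occupancy bins are NaN.
    """
    spikes = np.asarray(spikes, dtype=float)
    windows = np.asarray(trial_windows, dtype=float)
    if windows.ndim != 2 or windows.shape[1] != 2:
        raise ValueError("trial_windows must be (n_trials, 2)")
    order = np.argsort(windows[:, 0])
    if np.any(windows[order][:-1, 1] > windows[order][1:, 0]):
        raise ValueError("trial windows must not overlap")
    n_bins = geometry.n_bins_total
    n_trials = windows.shape[0]
    rates = np.full((n_trials, n_bins), np.nan)
    occ_seconds = np.zeros((n_trials, n_bins))
    dt = trace.sample_durations()
    spike_pos = np.interp(spikes, trace.times, trace.positions)
    spike_speed = np.interp(spikes, trace.times, trace.speed)
    assigned = np.zeros(spikes.shape, dtype=bool)
    for t, (t0, t1) in enumerate(windows):
        in_win = (trace.times >= t0) & (trace.times < t1)
        keep = in_win & (trace.speed >= min_speed)
        if np.any(keep):
            idx = _bin_index(trace.positions[keep], geometry)
            occ_seconds[t] = np.bincount(idx, weights=dt[keep],
                                         minlength=n_bins)
        s_in = (spikes >= t0) & (spikes < t1)
        assigned |= s_in
        s_keep = s_in & (spike_speed >= min_speed)
        counts = np.bincount(_bin_index(spike_pos[s_keep], geometry),
                             minlength=n_bins).astype(float)
        occupied = occ_seconds[t] > 0
        rates[t, occupied] = counts[occupied] / occ_seconds[t, occupied]
        n_orphan = int(np.sum(counts[~occupied]))
        if n_orphan:
            logger.info("trial %d: %d spikes in unoccupied bins ignored",
                        t, n_orphan)
    n_outside = int(np.sum(~assigned & (spikes >= 0)))
    if n_outside:
        logger.info("%d spikes outside all trial windows ignored", n_outside)
    matrix = TrialRateMatrix(rates=rates, geometry=geometry,
                             provenance={"kind": "empirical",
                                         "min_speed": min_speed})
    return matrix, occ_seconds


def smooth_map(rate_map: np.ndarray, kernel_sd_bins: float,
               geometry: Geometry | None = None) -> np.ndarray:
    """Gaussian smoothing along the spatial axis with edge renormalisation.

    The kernel is truncated at 3 SD; near the edges the remaining weights
    are renormalised to sum to 1 at every bin, so a flat map is invariant.
    Accepts a single map or a trials x bins matrix (each row smoothed
    independently).  For 2D geometries each row is reshaped to the grid and
    smoothed with an isotropic 2D kernel.  NaN bins are held out and
    restored afterwards.
    """
    m = np.asarray(rate_map, dtype=float)
    if kernel_sd_bins < 0:
        raise ValueError("kernel SD must be >= 0")
    if kernel_sd_bins == 0:
        return m.copy()

    def _smooth_1d(row: np.ndarray) -> np.ndarray:
        nan = np.isnan(row)
        filled = np.where(nan, 0.0, row)
        weights = (~nan).astype(float)
        num = ndimage.gaussian_filter1d(filled, kernel_sd_bins,
                                        mode="constant", truncate=3.0)
        den = ndimage.gaussian_filter1d(weights, kernel_sd_bins,
                                        mode="constant", truncate=3.0)
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[nan] = np.nan
        return out

    def _smooth_2d(row: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        grid = row.reshape(shape)
        nan = np.isnan(grid)
        filled = np.where(nan, 0.0, grid)
        weights = (~nan).astype(float)
        num = ndimage.gaussian_filter(filled, kernel_sd_bins,
                                      mode="constant", truncate=3.0)
        den = ndimage.gaussian_filter(weights, kernel_sd_bins,
                                      mode="constant", truncate=3.0)
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[nan] = np.nan
        return out.ravel()

    two_d = geometry is not None and geometry.ndim == 2
    if m.ndim == 1:
        return _smooth_2d(m, geometry.shape) if two_d else _smooth_1d(m)
    if m.ndim == 2:
        rows = [(_smooth_2d(r, geometry.shape) if two_d else _smooth_1d(r))
                for r in m]
        return np.vstack(rows)
    raise ValueError("rate_map must be 1D or 2D")


@dataclass(frozen=True)
class QCCriteria:
    """Session/neuron inclusion rules for empirical recordings.

    Defaults follow common practice for linear-track pyramidal-cell
    screening: a 0.2-20 Hz mean-rate window, at least 50 spikes, at least 15
    trials (after dropping traversals whose duration deviates more than
    ``max_duration_sd`` SDs from the session mean), a 5 cm/s running-speed
    floor for occupancy, and a 50% spike presence ratio.
    """

    min_rate_hz: float = 0.2
    max_rate_hz: float = 20.0
    min_spikes: int = 50
    min_trials: int = 15
    min_speed_cms: float = 5.0
    max_duration_sd: float = 2.0
    min_presence: float = 0.5

    def __post_init__(self) -> None:
        if self.min_rate_hz >= self.max_rate_hz:
            raise ValueError("min_rate_hz must be < max_rate_hz")


@dataclass
class NeuronSummary:
    mean_rate_hz: float
    n_spikes: int
    presence_ratio: float


@dataclass
class SessionSummary:
    trial_durations_s: np.ndarray

    def __post_init__(self) -> None:
        self.trial_durations_s = np.asarray(self.trial_durations_s, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.trial_durations_s.size


def valid_trials(session: SessionSummary, max_duration_sd: float) -> np.ndarray:
    """Boolean mask of traversals within ``max_duration_sd`` SDs of the mean."""
    d = session.trial_durations_s
    if d.size < 2:
        return np.ones(d.size, dtype=bool)
    sd = d.std(ddof=0)
    if sd == 0:
        return np.ones(d.size, dtype=bool)
    return np.abs(d - d.mean()) <= max_duration_sd * sd


def qc_filter(neuron: NeuronSummary, session: SessionSummary,
              criteria: QCCriteria | None = None) -> tuple[bool, list[str]]:
    """Keep flag plus the list of violated rules (empty when kept)."""
    c = criteria or QCCriteria()
    violations = []
    if neuron.mean_rate_hz < c.min_rate_hz:
        violations.append("min_rate")
    if neuron.mean_rate_hz > c.max_rate_hz:
        violations.append("max_rate")
    if neuron.n_spikes < c.min_spikes:
        violations.append("min_spikes")
    n_ok = int(valid_trials(session, c.max_duration_sd).sum())
    if n_ok < c.min_trials:
        violations.append("min_trials")
    if neuron.presence_ratio < c.min_presence:
        violations.append("min_presence")
    return (len(violations) == 0), violations


def rebin(matrix: TrialRateMatrix, n_bins: int | tuple[int, ...]) -> TrialRateMatrix:
    """Aggregate to a coarser resolution by averaging groups of bins.

    The target bin count must divide the source count in every dimension
    (clean aggregation only).  With equal occupancy per source bin the
    average conserves rate x occupancy totals exactly.
    """
    target = (n_bins,) if isinstance(n_bins, int) else tuple(n_bins)
    src = matrix.geometry.shape
    if len(target) != len(src):
        raise ValueError("target dimensionality must match the source")
    factors = []
    for s, t in zip(src, target):
        if t < 1 or s % t:
            raise ValueError(
                f"target bin count {t} does not divide source {s}")
        factors.append(s // t)
    rates = matrix.rates.reshape(matrix.n_trials, *src)
    for axis, f in enumerate(factors):
        # collapse axis+1 into (target, factor) and average the factor axis
        shp = list(rates.shape)
        shp[axis + 1] = shp[axis + 1] // f
        shp.insert(axis + 2, f)
        rates = rates.reshape(shp).mean(axis=axis + 2)
    rates = rates.reshape(matrix.n_trials, -1)
    geom = Geometry(target, matrix.geometry.bin_width * factors[0])
    prov = dict(matrix.provenance)
    prov["rebinned_from"] = src
    return TrialRateMatrix(rates=rates, geometry=geom, provenance=prov)


def mask_edge_bins(matrix: TrialRateMatrix, n_edge: int = 3) -> TrialRateMatrix:
    """Mark the first and last ``n_edge`` bins of a 1D track as missing.

    Post-hoc mask for reward-site edge effects; off by default in every
    pipeline.
    """
    if matrix.geometry.ndim != 1:
        raise ValueError("edge masking applies to 1D tracks")
    rates = matrix.rates.copy()
    if n_edge > 0:
        rates[:, :n_edge] = np.nan
        rates[:, -n_edge:] = np.nan
    prov = dict(matrix.provenance)
    prov["edge_bins_masked"] = n_edge
    return TrialRateMatrix(rates=rates, geometry=matrix.geometry,
                           provenance=prov)
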