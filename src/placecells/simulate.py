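"""Synthetic place-field generator.

Each simulated neuron is a Gaussian tuning curve over spatial bins::

    F(x) = A * exp(-(x - mu)^2 / (2 sigma^2))

plus a constant baseline B0 and i.i.d. Gaussian noise N(0, noise_sd^2) added
per bin on every trial.  Trial-to-trial variability is introduced through
per-trial jitter of the field centre and a presence ratio: on "absent" trials
the rate is baseline plus noise only.  Supports 1D linear tracks (default
50 bins) and square 2D arenas (default 10 x 10), with the 2D grid stored
flattened row-major so every downstream statistic sees an unordered bin set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Geometry",
    "PlaceFieldParams",
    "TrialRateMatrix",
    "SweepSpec",
    "SWEEP_PARAMETERS",
    "DEFAULT_SWEEP_FIXED",
    "tuning_profile",
    "simulate_trials",
    "sweep_values",
    "sample_population",
    "synthesize_spikes",
]


@dataclass(frozen=True)
class Geometry:
    """Discretisation of the environment into equal-width spatial bins.

    ``shape`` is the bin count per dimension: ``(50,)`` for a linear track,
    ``(10, 10)`` for a square arena.  Bin coordinates are the 0-based bin
    indices; ``bin_width`` converts them to track units when needed.
    """

    shape: tuple[int, ...]
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if len(self.shape) not in (1, 2):
            raise ValueError("only 1D and 2D geometries are supported")
        if any(int(n) != n or n < 1 for n in self.shape):
            raise ValueError("bin counts must be positive integers")
        if self.n_bins_total < 2:
            raise ValueError("total bin count must be >= 2")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_bins_total(self) -> int:
        return int(np.prod(self.shape))

    def coordinates(self) -> np.ndarray:
        """Bin-centre coordinates, shape (n_bins_total, ndim), row-major."""
        grids = np.meshgrid(*(np.arange(n, dtype=float) for n in self.shape),
                            indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    @classmethod
    def linear(cls, n_bins: int = 50, bin_width: float = 1.0) -> "Geometry":
        return cls((n_bins,), bin_width)

    @classmethod
    def grid(cls, nx: int = 10, ny: int = 10, bin_width: float = 1.0) -> "Geometry":
        return cls((nx, ny), bin_width)


@dataclass(frozen=True)
class PlaceFieldParams:
    """Ground-truth generative parameters of one simulated neuron.

    a : peak firing-rate amplitude A (Hz)
    mu : field centre in bin coordinates (scalar for 1D, pair for 2D)
    sigma : field width SD (bins), shared across dimensions in 2D
    b0 : constant baseline rate (Hz)
    noise_sd : per-bin Gaussian noise SD (Hz)
    jitter_max : maximum per-trial centre offset (bins)
    presence : probability the field is expressed on a trial
    """

    a: float
    mu: float | tuple[float, ...]
    sigma: float
    b0: float = 0.0
    noise_sd: float = 0.0
    jitter_max: float = 0.0
    presence: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("peak amplitude A must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.b0 < 0:
            raise ValueError("baseline B0 must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")
        if not 0.0 <= self.presence <= 1.0:
            raise ValueError("presence must be in [0, 1]")

    def mu_array(self, geometry: Geometry) -> np.ndarray:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if mu.size != geometry.ndim:
            raise ValueError(
                f"mu has {mu.size} coordinate(s) for a {geometry.ndim}D geometry")
        return mu


@dataclass
class TrialRateMatrix:
    """Trials x bins firing-rate matrix G (Hz) with geometry metadata.

    2D arenas are stored with bins flattened row-major; ``geometry`` retains
    the original shape.  ``provenance`` records how the matrix was produced
    (simulation seed and parameters, or an empirical session id).
    """

    rates: np.ndarray
    geometry: Geometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise ValueError("rates must be a 2D (trials x bins) array")
        if self.rates.shape[0] < 1:
            raise ValueError("need at least one trial")
        if self.rates.shape[1] != self.geometry.n_bins_total:
            raise ValueError("column count must equal the total bin count")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def mean_map(self) -> np.ndarray:
        """Trial-averaged rate map (NaN-aware for missing-occupancy bins)."""
        return np.nanmean(self.rates, axis=0)


def tuning_profile(params: PlaceFieldParams, geometry: Geometry) -> np.ndarray:
    """Noiseless expected rate per bin: Gaussian field plus baseline.

    Raises if the field centre lies outside the bin range.
    """
    mu = params.mu_array(geometry)
    upper = np.asarray(geometry.shape, dtype=float) - 1.0
    if np.any(mu < 0.0) or np.any(mu > upper):
        raise ValueError("center out of range")
    return _field_term(params.a, mu, params.sigma, geometry) + params.b0


def _field_term(a: float, mu: np.ndarray, sigma: float,
                geometry: Geometry) -> np.ndarray:
    coords = geometry.coordinates()
    sq = np.sum((coords - mu[None, :]) ** 2, axis=1)
    return a * np.exp(-sq / (2.0 * sigma ** 2))


def simulate_trials(
    params: PlaceFieldParams,
    geometry: Geometry,
    n_trials: int,
    seed: int | np.random.SeedSequence | None = None,
    jitter_mode: Literal["positive", "symmetric"] = "positive",
    clip: bool = True,
) -> TrialRateMatrix:
    """Simulate a trials x bins rate matrix for one neuron.

    Per trial: a Bernoulli(presence) draw decides whether the field is
    expressed; if so the centre is offset by a uniform jitter (``positive``:
    U[0, jitter_max], as described for the consistency manipulation;
    ``symmetric``: U[-jitter_max, jitter_max]).  Baseline and per-bin
    Gaussian noise are added on every trial.  Shifted fields are evaluated
    on the fixed bin grid, so mass pushed past a track edge is truncated
    rather than wrapped.  Negative rates are clipped to zero unless
    ``clip=False`` (rates are physical; the flag exists for oracle tests).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mu = params.mu_array(geometry)
    # validate centre up front (same rule as tuning_profile)
    tuning_profile(params, geometry)
    rng = np.random.default_rng(seed)
    n_bins = geometry.n_bins_total
    rates = np.empty((n_trials, n_bins), dtype=float)
    for t in range(n_trials):
        present = rng.random() < params.presence if params.presence < 1.0 else True
        if params.jitter_max > 0:
            if jitter_mode == "symmetric":
                offset = rng.uniform(-params.jitter_max, params.jitter_max,
                                     size=geometry.ndim)
            else:
                offset = rng.uniform(0.0, params.jitter_max, size=geometry.ndim)
        else:
            offset = np.zeros(geometry.ndim)
        row = np.full(n_bins, params.b0, dtype=float)
        if present and params.a > 0:
            row += _field_term(params.a, mu + offset, params.sigma, geometry)
        if params.noise_sd > 0:
            row += rng.normal(0.0, params.noise_sd, size=n_bins)
        rates[t] = row
    if clip:
        np.clip(rates, 0.0, None, out=rates)
    return TrialRateMatrix(
        rates=rates,
        geometry=geometry,
        provenance={
            "kind": "simulation",
            "params": params,
            "seed": seed,
            "jitter_mode": jitter_mode,
            "clip": clip,
        },
    )


SWEEP_PARAMETERS = {
    "peak": "a",
    "width": "sigma",
    "baseline": "b0",
    "noise": "noise_sd",
    "jitter": "jitter_max",
    "presence": "presence",
}

#: Fixed values for the non-swept parameters of a population sweep on the
#: 50-bin track (centre field, strong single field, unit noise).
DEFAULT_SWEEP_FIXED = PlaceFieldParams(
    a=10.0, mu=24.5, sigma=5.0, b0=1.0, noise_sd=1.0,
    jitter_max=0.0, presence=1.0,
)


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter population sweep: which knob to turn and how."""

    parameter: str
    low: float
    high: float
    n_samples: int
    sampling: Literal["evenly_spaced", "uniform_random"] = "evenly_spaced"
    fixed: PlaceFieldParams = DEFAULT_SWEEP_FIXED
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; "
                f"expected one of {sorted(SWEEP_PARAMETERS)}")
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def sweep_values(spec: SweepSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """The swept parameter values (endpoints included for evenly_spaced).

    With ``n_samples=1`` and evenly spaced sampling the single value is the
    low endpoint.
    """
    if spec.sampling == "evenly_spaced":
        if spec.n_samples == 1:
            return np.array([spec.low])
        return np.linspace(spec.low, spec.high, spec.n_samples)
    if spec.sampling == "uniform_random":
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
        return rng.uniform(spec.low, spec.high, size=spec.n_samples)
    raise ValueError(f"unknown sampling mode {spec.sampling!r}")


def neuron_seed(seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based sub-seed: neuron ``index`` of population ``seed``.

    Any single neuron is reproducible in isolation from (seed, index).
    """
    return np.random.SeedSequence((seed, 1 + index))


def sample_population(
    spec: SweepSpec,
    geometry: Geometry | None = None,
    jitter_mode: Literal["positive", "symmetric"] = "positive",
    clip: bool = True,
) -> list[tuple[PlaceFieldParams, TrialRateMatrix]]:
    """Simulate ``spec.n_samples`` neurons along a one-parameter sweep.

    The swept parameter follows ``spec.sampling`` over [low, high]; all other
    parameters come from ``spec.fixed``.  Each neuron gets an independent
    counter-based sub-seed (see :func:`neuron_seed`); value draws for
    uniform_random sampling use the sub-stream (seed, 0).
    """
    if geometry is None:
        geometry = Geometry.linear(50)
    values = sweep_values(spec)
    attr = SWEEP_PARAMETERS[spec.parameter]
    out = []
    for i, v in enumerate(values):
        params = replace(spec.fixed, **{attr: float(v)})
        matrix = simulate_trials(
            params, geometry, spec.n_trials,
            seed=neuron_seed(spec.seed, i),
            jitter_mode=jitter_mode, clip=clip,
        )
        matrix.provenance["seed"] = (spec.seed, 1 + i)
        matrix.provenance["swept_parameter"] = spec.parameter
        matrix.provenance["swept_value"] = float(v)
        out.append((params, matrix))
    return out


def synthesize_spikes(
    rates_per_trial: np.ndarray,
    trial_duration_s: float,
    seed: int | np.random.SeedSequence | None = None,
    position_samples_per_bin: int = 4,
):
    """Poisson spikes along a constant-speed traversal of a 1D track.

    Converts a trials x bins expected-rate matrix into spike times plus a
    synthetic position trace, so the spike-level pipeline (occupancy,
    rate-map reconstruction, circular-shift surrogates) can be exercised
    end to end.  Each trial traverses the track at constant speed, spending
    ``trial_duration_s / n_bins`` seconds in each bin; spike counts per bin
    dwell are Poisson with the bin's rate, spike times uniform within the
    dwell.

    Returns
    -------
    spikes : 1D array of strictly sorted spike times (s)
    positions : record array-like dict of arrays with keys
        ``time_s``, ``position``, ``trial``
    trial_windows : (n_trials, 2) array of [t_start, t_end) per trial
    """
    rates = np.asarray(rates_per_trial, dtype=float)
    if rates.ndim != 2:
        raise ValueError("rates_per_trial must be 2D (trials x bins)")
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if trial_duration_s <= 0:
        raise ValueError("trial duration must be > 0")
    rng = np.random.default_rng(seed)
    n_trials, n_bins = rates.shape
    dwell = trial_duration_s / n_bins
    spikes = []
    for t in range(n_trials):
        t0 = t * trial_duration_s
        counts = rng.poisson(rates[t] * dwell)
        for b in range(n_bins):
            if counts[b]:
                start = t0 + b * dwell
                spikes.append(np.sort(rng.uniform(start, start + dwell,
                                                  size=counts[b])))
    spike_times = (np.sort(np.concatenate(spikes))
                   if spikes else np.empty(0, dtype=float))
    # position trace: several samples per bin, constant speed, every bin
    # covered on every trial
    n_samp = n_bins * position_samples_per_bin
    rel = (np.arange(n_samp) + 0.5) / n_samp  # fraction of trial elapsed
    times = np.concatenate(
        [t * trial_duration_s + rel * trial_duration_s for t in range(n_trials)])
    pos = np.concatenate([rel * n_bins for _ in range(n_trials)])
    trial_ids = np.repeat(np.arange(n_trials), n_samp)
    positions = {"time_s": times, "position": pos, "trial": trial_ids}
    windows = np.array([[t * trial_duration_s, (t + 1) * trial_duration_s]
                        for t in range(n_trials)], dtype=float)
    return spike_times, positions, windows
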