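"""The eight per-neuron place-field features.

All features are estimated from a trials x bins rate matrix on a 1D track:

peak_rate, avg_rate, peak_to_avg  - tuning-contrast measures from the
    trial-averaged map;
field_width, n_fields             - structure of the supra-threshold region
    (bins above a fraction of the peak, default 20%);
field_consistency                 - fraction of trials whose per-trial peak
    bin lies within +/-3 bins of the overall peak bin;
presence_ratio                    - fraction of trials with non-zero firing
    in at least one bin of the detected field region;
even_odd_r                        - Pearson correlation between mean maps
    built from odd- and even-numbered trials (trial 1 is odd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import TrialRateMatrix

__all__ = ["FieldInterval", "FeatureVector", "FEATURE_NAMES",
           "detect_fields", "estimate_features", "features_dataframe"]

FEATURE_NAMES = (
    "peak_rate", "avg_rate", "peak_to_avg", "field_width",
    "n_fields", "field_consistency", "presence_ratio", "even_odd_r",
)


@dataclass(frozen=True)
class FieldInterval:
    """One contiguous supra-threshold run of bins (inclusive endpoints)."""

    start_bin: int
    end_bin: int
    peak_bin: int
    peak_rate_hz: float

    def __post_init__(self) -> None:
        if not self.start_bin <= self.peak_bin <= self.end_bin:
            raise ValueError("peak bin must lie inside the interval")

    @property
    def width_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class FeatureVector:
    """The eight estimated features of one neuron (NaN where undefined)."""

    peak_rate: float
    avg_rate: float
    peak_to_avg: float
    field_width: float
    n_fields: float
    field_consistency: float
    presence_ratio: float
    even_odd_r: float
    flags: list[str] = field(default_factory=list)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES],
                        dtype=float)


def detect_fields(
    mean_map: np.ndarray,
    rel_threshold: float = 0.2,
    min_width_bins: int = 2,
) -> list[FieldInterval]:
    """Contiguous runs of bins with rate above ``rel_threshold`` * peak.

    The threshold is relative to the raw trial-averaged peak (baseline not
    subtracted); runs shorter than ``min_width_bins`` are discarded.  An
    all-zero (or all-NaN) map has no fields.
    """
    m = np.asarray(mean_map, dtype=float)
    if m.size == 0:
        raise ValueError("map must be non-empty")
    finite = np.nan_to_num(m, nan=-np.inf)
    peak = finite.max()
    if not np.isfinite(peak) or peak <= 0:
        return []
    above = finite > rel_threshold * peak
    fields_out: list[FieldInterval] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            end = i - 1
            if end - start + 1 >= min_width_bins:
                seg = finite[start:end + 1]
                peak_bin = start + int(np.argmax(seg))  # lowest index on ties
                fields_out.append(FieldInterval(start, end, peak_bin,
                                                float(finite[peak_bin])))
            start = None
    return fields_out


def estimate_features(
    matrix: TrialRateMatrix,
    rel_threshold: float = 0.2,
    min_width_bins: int = 2,
    consistency_window_bins: int = 3,
) -> FeatureVector:
    """Estimate the eight features from a 1D trials x bins rate matrix."""
    if matrix.geometry.ndim != 1:
        raise ValueError("feature extraction is defined for 1D tracks")
    rates = matrix.rates
    if rates.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    flags: list[str] = []
    mean_map = np.nanmean(rates, axis=0)
    peak_rate = float(np.nanmax(mean_map))
    avg_rate = float(np.nanmean(rates))
    peak_to_avg = peak_rate / avg_rate if avg_rate > 0 else float("nan")
    if avg_rate <= 0:
        flags.append("silent neuron")

    field_list = detect_fields(mean_map, rel_threshold, min_width_bins)
    n_fields = float(len(field_list))
    finite = np.nan_to_num(mean_map, nan=-np.inf)
    peak_for_thr = finite.max()
    field_width = (float(np.sum(finite > rel_threshold * peak_for_thr))
                   if peak_for_thr > 0 else 0.0)

    # per-trial peak bin within +/- window of the overall peak bin;
    # ties broken toward the lowest bin index (np.argmax / nanargmax)
    overall_peak_bin = int(np.nanargmax(mean_map))
    trial_peaks = np.array([
        int(np.nanargmax(row)) if np.any(~np.isnan(row)) else -10 ** 6
        for row in rates
    ])
    field_consistency = float(np.mean(
        np.abs(trial_peaks - overall_peak_bin) <= consistency_window_bins))

    if field_list:
        region = np.concatenate([
            np.arange(f.start_bin, f.end_bin + 1) for f in field_list])
        in_field = rates[:, region]
        with np.errstate(invalid="ignore"):
            presence_ratio = float(np.mean(np.nansum(in_field > 0, axis=1) > 0))
    else:
        presence_ratio = float("nan")
        flags.append("no detected field")

    odd = np.nanmean(rates[0::2], axis=0)   # trial 1 (index 0) is odd
    even_rows = rates[1::2]
    if even_rows.shape[0] == 0:
        even_odd_r = float("nan")
        flags.append("no even trials")
    else:
        even = np.nanmean(even_rows, axis=0)
        ok = ~np.isnan(odd) & ~np.isnan(even)
        if ok.sum() < 2 or np.std(odd[ok]) == 0 or np.std(even[ok]) == 0:
            even_odd_r = float("nan")
            flags.append("constant even/odd map")
        else:
            even_odd_r = float(stats.pearsonr(odd[ok], even[ok])[0])

    return FeatureVector(
        peak_rate=peak_rate, avg_rate=avg_rate, peak_to_avg=peak_to_avg,
        field_width=field_width, n_fields=n_fields,
        field_consistency=field_consistency, presence_ratio=presence_ratio,
        even_odd_r=even_odd_r, flags=flags,
    )


def features_dataframe(vectors: Sequence[FeatureVector]):
    """Stack feature vectors into a neurons x features DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [v.to_array() for v in vectors], columns=list(FEATURE_NAMES))
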