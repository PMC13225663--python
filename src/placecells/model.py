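"""Model/Results interface for per-neuron spatial-tuning analysis.

``SpatialTuningModel`` wraps one neuron's trials x bins firing-rate matrix;
``fit()`` computes both tuning statistics (spatial information on the
trial-averaged map, one-way ANOVA F on the full matrix), their circular
row-shift permutation nulls, the fixed-threshold criterion, the four-way
classification, and the eight place-field features, returning a
``SpatialTuningResults`` with a ``summary()`` table.

>>> from placecells import SpatialTuningModel, simulate
>>> m = simulate.simulate_trials(simulate.DEFAULT_SWEEP_FIXED,
...                              simulate.Geometry.linear(50), 30, seed=0)
>>> res = SpatialTuningModel(m).fit(seed=0)
>>> res.sig_f_perm
True
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import detection as _det
from .features import FEATURE_NAMES, FeatureVector, estimate_features
from .metrics import anova_f, spatial_information
from .simulate import Geometry, PlaceFieldParams, TrialRateMatrix, simulate_trials

__all__ = ["SpatialTuningModel", "SpatialTuningResults", "fit_population"]


class SpatialTuningModel:
    """Spatial-tuning analysis of one neuron's trial-by-bin rate matrix."""

    def __init__(self, matrix: TrialRateMatrix | np.ndarray,
                 geometry: Geometry | None = None,
                 occupancy_p: np.ndarray | None = None):
        if isinstance(matrix, TrialRateMatrix):
            self.matrix = matrix
        else:
            rates = np.asarray(matrix, dtype=float)
            geom = geometry or Geometry.linear(rates.shape[1])
            self.matrix = TrialRateMatrix(rates=rates, geometry=geom)
        self.occupancy_p = occupancy_p

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trial_col: str = "trial",
                       bin_col: str = "bin", rate_col: str = "rate_hz",
                       geometry: Geometry | None = None) -> "SpatialTuningModel":
        """Build from a long-format (trial, bin, rate) table."""
        wide = df.pivot(index=trial_col, columns=bin_col, values=rate_col)
        wide = wide.sort_index().sort_index(axis=1)
        return cls(wide.to_numpy(dtype=float), geometry=geometry)

    @classmethod
    def from_simulation(cls, params: PlaceFieldParams, geometry: Geometry,
                        n_trials: int, seed=None, **kwargs) -> "SpatialTuningModel":
        return cls(simulate_trials(params, geometry, n_trials, seed=seed,
                                   **kwargs))

    def fit(self,
            n_surrogates: int = _det.DEFAULT_N_SURROGATES,
            seed: int | np.random.SeedSequence | None = None,
            alpha: float = 0.05,
            si_threshold: float = _det.DEFAULT_SI_THRESHOLD,
            compute_features: bool = True) -> "SpatialTuningResults":
        m = self.matrix
        si = spatial_information(m.mean_map(), self.occupancy_p)
        f_res = anova_f(m)
        si_null, f_null = _det.null_distributions(m, n=n_surrogates, seed=seed)
        p_si, sig_si = _det.permutation_test(si, si_null, alpha)
        p_f, sig_f = _det.permutation_test(f_res.f_stat, f_null, alpha)
        sig_si_thresh = bool(not np.isnan(si) and si > si_threshold)
        category = _det.classify_cells([sig_si], [sig_f])[0][0]
        features = None
        if compute_features and m.geometry.ndim == 1:
            features = estimate_features(m)
        return SpatialTuningResults(
            model=self, si=si, f_stat=f_res.f_stat,
            df_between=f_res.df_between, df_within=f_res.df_within,
            p_si=p_si, p_f=p_f,
            sig_si_perm=sig_si, sig_f_perm=sig_f,
            sig_si_thresh=sig_si_thresh, category=str(category),
            si_null=si_null, f_null=f_null,
            alpha=alpha, si_threshold=si_threshold,
            features=features, flags=list(f_res.flags),
        )


@dataclass
class SpatialTuningResults:
    """Estimates, permutation uncertainty and classification of one neuron."""

    model: SpatialTuningModel
    si: float
    f_stat: float
    df_between: int
    df_within: int
    p_si: float
    p_f: float
    sig_si_perm: bool
    sig_f_perm: bool
    sig_si_thresh: bool
    category: str
    si_null: _det.NullDistribution
    f_null: _det.NullDistribution
    alpha: float
    si_threshold: float
    features: FeatureVector | None = None
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "si": self.si, "f_stat": self.f_stat,
            "p_si": self.p_si, "p_f": self.p_f,
            "sig_si_perm": self.sig_si_perm, "sig_f_perm": self.sig_f_perm,
            "sig_si_thresh": self.sig_si_thresh, "category": self.category,
        }
        if self.features is not None:
            row.update({name: getattr(self.features, name)
                        for name in FEATURE_NAMES})
        return row

    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "Spatial Tuning Results",
            "=" * 54,
            f"{'trials':<28}{m.n_trials:>10d}",
            f"{'bins':<28}{m.n_bins:>10d}  {m.geometry.shape}",
            f"{'surrogates':<28}{self.si_null.n_surrogates:>10d}"
            f"  ({self.si_null.method})",
            "-" * 54,
            f"{'spatial information':<28}{self.si:>10.4f}  bits/spike",
            f"{'  perm p':<28}{self.p_si:>10.4f}"
            f"  {'significant' if self.sig_si_perm else 'n.s.'}",
            f"{'  > ' + format(self.si_threshold, 'g') + ' bits/spike':<28}"
            f"{'yes' if self.sig_si_thresh else 'no':>10}",
            f"{'ANOVA F':<28}{self.f_stat:>10.4f}"
            f"  df=({self.df_between}, {self.df_within})",
            f"{'  perm p':<28}{self.p_f:>10.4f}"
            f"  {'significant' if self.sig_f_perm else 'n.s.'}",
            f"{'category':<28}{self.category:>10}",
        ]
        if self.features is not None:
            lines.append("-" * 54)
            for name in FEATURE_NAMES:
                lines.append(f"{name:<28}{getattr(self.features, name):>10.4f}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def fit_population(
    matrices: Sequence[TrialRateMatrix],
    n_surrogates: int = _det.DEFAULT_N_SURROGATES,
    seed: int = 0,
    alpha: float = 0.05,
    si_threshold: float = _det.DEFAULT_SI_THRESHOLD,
    compute_features: bool = True,
) -> pd.DataFrame:
    """Fit every neuron; one row per neuron, counter-based sub-seeds."""
    rows = []
    for i, matrix in enumerate(matrices):
        res = SpatialTuningModel(matrix).fit(
            n_surrogates=n_surrogates,
            seed=np.random.SeedSequence((seed, 7, i)),
            alpha=alpha, si_threshold=si_threshold,
            compute_features=compute_features,
        )
        row = {"neuron_id": i}
        row.update(res.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
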