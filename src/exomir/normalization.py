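"""Median-reference regression normalization.

A common set of sequences (detected in every sample) defines a reference
vector of log2 per-sequence medians.  For each sample, sequences within a
4-fold band of the reference (|delta log2| < 2) form a regression subset;
ordinary least squares of the sample's log2 copies on the reference gives a
line, and the offset of that line from the identity at the midpoint of the
reference range yields a per-sample arithmetic correction factor
``f = 2**(x_mid - y_mid)``.  Corrected copies are ``f * raw``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DELTA_LOG2_LIMIT = 2.0


class NormalizationError(ValueError):
    pass


@dataclass
class SampleFit:
    sample: str
    subset: list[str]
    slope: float
    intercept: float
    x_mid: float
    y_mid: float
    delta_y: float
    factor: float


@dataclass
class NormalizationModel:
    common: list[str]
    reference: pd.Series  # log2 of per-sequence median copies
    fits: dict[str, SampleFit]

    def factor(self, sample: str) -> float:
        if sample not in self.fits:
            raise NormalizationError(f"no fitted factor for sample {sample!r}")
        return self.fits[sample].factor


def build_reference(matrix: pd.DataFrame, min_copy: float = 1.0):
    """Common sequence set and log2-median reference vector.

    The common set holds sequences with copies >= ``min_copy`` in every
    sample; the reference value is the across-sample median (mean-of-middle
    convention for even sample counts, the numpy default).
    """
    if matrix.shape[1] < 2:
        raise NormalizationError("need at least 2 samples")
    common_mask = (matrix >= min_copy).all(axis=1)
    common = matrix.index[common_mask]
    if len(common) < 3:
        raise NormalizationError(
            f"only {len(common)} common sequences (need >= 3); cannot normalize"
        )
    reference = np.log2(matrix.loc[common].median(axis=1))
    return list(common), reference


def fit_sample(y: pd.Series, x: pd.Series, sample: str = "",
               delta_limit: float = DELTA_LOG2_LIMIT,
               mid_mode: str = "midpoint") -> SampleFit:
    """OLS of sample log2 copies on the reference over the |dy| < limit subset.

    ``mid_mode`` selects the reference mid value: ``midpoint`` uses
    (max+min)/2 (default); ``half_range`` uses (max-min)/2 (flagged
    alternative reading).
    """
    mask = (y - x).abs() < delta_limit
    subset = x.index[mask]
    if len(subset) < 3:
        raise NormalizationError(
            f"sample {sample!r}: regression subset has {len(subset)} sequences (need >= 3)"
        )
    xs, ys = x[subset].to_numpy(float), y[subset].to_numpy(float)
    if np.allclose(xs, xs[0]):
        raise NormalizationError(f"sample {sample!r}: degenerate subset (all x equal)")
    slope, intercept = np.polyfit(xs, ys, 1)
    if mid_mode == "midpoint":
        x_mid = (xs.max() + xs.min()) / 2.0
    elif mid_mode == "half_range":
        x_mid = (xs.max() - xs.min()) / 2.0
    else:
        raise NormalizationError(f"unknown mid_mode {mid_mode!r}")
    y_mid = slope * x_mid + intercept
    delta_y = x_mid - y_mid
    return SampleFit(sample, list(subset), float(slope), float(intercept),
                     float(x_mid), float(y_mid), float(delta_y), float(2.0 ** delta_y))


def fit_model(matrix: pd.DataFrame, min_copy: float = 1.0,
              delta_limit: float = DELTA_LOG2_LIMIT,
              mid_mode: str = "midpoint") -> NormalizationModel:
    common, reference = build_reference(matrix, min_copy)
    fits = {}
    for sample in matrix.columns:
        y = np.log2(matrix.loc[common, sample])
        fits[sample] = fit_sample(y, reference, sample, delta_limit, mid_mode)
    return NormalizationModel(common, reference, fits)


def apply_model(matrix: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Entrywise multiplication by each sample's correction factor."""
    factors = pd.Series({sample: model.factor(sample) for sample in matrix.columns})
    return matrix * factors


def normalize(matrix: pd.DataFrame, min_copy: float = 1.0,
              delta_limit: float = DELTA_LOG2_LIMIT, mid_mode: str = "midpoint"):
    """Fit and apply in one step; returns ``(corrected, model)``."""
    model = fit_model(matrix, min_copy, delta_limit, mid_mode)
    return apply_model(matrix, model), model


def model_rows(model: NormalizationModel) -> list[dict]:
    return [{"sample": fit.sample, "slope": fit.slope, "intercept": fit.intercept,
             "x_mid": fit.x_mid, "delta_y": fit.delta_y, "factor": fit.factor,
             "subset_size": len(fit.subset)}
            for fit in model.fits.values()]
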