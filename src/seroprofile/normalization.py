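"""The two array-normalization transforms.

Planar-array data are standardized array-wise into nSD units — the number
of standard deviations a spot's intensity lies from the array mean:

    nSD_i = (x_i - mean(x)) / SD(x)

Bead-array data are normalized sample-wise into nMAD units — the number of
(unscaled) median absolute deviations from the sample median:

    nMAD_i = (x_i - median(x)) / MAD(x),   MAD(x) = median(|x - median(x)|)

The MAD carries no 1.4826 consistency factor: the statistic is used as a
robust scale unit, not as a normal-sd estimator.  Sample-wise centering and
scaling removes per-sample multiplicative/additive background shifts, which
is exactly the artifact a pooled-assay background introduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DegenerateInputError", "NormalizedMatrix", "nsd_transform", "nmad_transform"]


class DegenerateInputError(ValueError):
    """Zero scale (SD or MAD) makes the transform undefined."""


@dataclass
class NormalizedMatrix:
    """Samples x antigens matrix of unitless deviations.

    ``center`` and ``scale`` record the per-row statistics that were
    removed, so the transform is auditable and invertible.
    """

    values: pd.DataFrame
    mode: str  # "nSD" or "nMAD"
    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        if self.mode not in ("nSD", "nMAD"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if (self.scale <= 0).any():
            bad = list(self.scale.index[self.scale <= 0])
            raise DegenerateInputError(f"non-positive scale for row(s): {bad}")


def nsd_transform(raw: pd.Series | Sequence[float], ddof: int = 0) -> pd.Series:
    """Standardize one array's intensities to nSD units.

    ``ddof=0`` (population SD) by default; at array sizes in the tens of
    thousands the choice is numerically immaterial but it is fixed for
    reproducibility.
    """
    series = pd.Series(raw, dtype=float) if not isinstance(raw, pd.Series) else raw.astype(float)
    if len(series) < 2:
        raise DegenerateInputError("nSD needs at least 2 values")
    sd = float(series.std(ddof=ddof))
    if sd == 0:
        raise DegenerateInputError("zero standard deviation: constant array")
    return (series - series.mean()) / sd


def _row_mad(row: np.ndarray) -> tuple[float, float]:
    med = float(np.median(row))
    mad = float(np.median(np.abs(row - med)))
    return med, mad


def nmad_transform(
    raw: pd.DataFrame, exclude: Sequence[str] = ()
) -> NormalizedMatrix:
    """Normalize each sample row to nMAD units.

    ``exclude`` lists antigen columns (e.g. assay controls) left out of the
    per-row median/MAD computation; the transform is still applied to them.
    Raises :class:`DegenerateInputError`, naming the sample, for any row
    whose MAD is zero.
    """
    stat_cols = [c for c in raw.columns if c not in set(exclude)]
    if not stat_cols:
        raise DegenerateInputError("no columns left to compute row statistics")
    centers, scales = {}, {}
    for sid in raw.index:
        med, mad = _row_mad(raw.loc[sid, stat_cols].to_numpy(dtype=float))
        if mad == 0:
            raise DegenerateInputError(f"zero MAD for sample {sid!r}")
        centers[sid], scales[sid] = med, mad
    center = pd.Series(centers, name="median")
    scale = pd.Series(scales, name="mad")
    values = raw.sub(center, axis=0).div(scale, axis=0)
    return NormalizedMatrix(values=values, mode="nMAD", center=center, scale=scale)
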