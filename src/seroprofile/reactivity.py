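"""Binary reactivity calling from normalized bead-array signals.

A per-antigen cutoff is set from the distribution of that antigen's
normalized signal across all samples; samples strictly above the cutoff
are called reactive (1), all others negative (0).  The default rule is
robust and monotone:

    cutoff_a = max(floor, median_a + c * MAD_a)

with ``c = 5`` and a floor of 5 nMAD.  An antigen whose across-sample MAD
is zero (reactivity so sparse that most samples sit at the same value)
falls back to the floor-only cutoff, which is logged.  Antigen-level calls
aggregate to protein level by logical OR over the protein's fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core_io import AntigenRecord, BinaryReactivityMatrix, ValidationError, logger, pct_half_up
from .normalization import NormalizedMatrix

__all__ = [
    "CutoffRule",
    "call_reactivity",
    "protein_level_calls",
    "reactivity_summary",
]


@dataclass
class CutoffRule:
    """Cutoff strategy for reactivity calling.

    strategy 'antigen_mad': per-antigen cutoff max(floor, median + c*MAD)
    across samples; strategy 'fixed': the same cutoff ``c`` for every
    antigen (for sensitivity analysis).  ``realized`` holds the per-antigen
    cutoffs after fitting.
    """

    strategy: str = "antigen_mad"
    c: float = 5.0
    floor: float = 5.0
    realized: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("antigen_mad", "fixed"):
            raise ValueError(f"unknown cutoff strategy {self.strategy!r}")


def call_reactivity(
    normalized: NormalizedMatrix | pd.DataFrame,
    rule: CutoffRule | None = None,
    allow_raw: bool = False,
) -> BinaryReactivityMatrix:
    """Threshold a normalized matrix into 0/1 reactivity calls.

    Expects nMAD-normalized input; pass ``allow_raw=True`` to threshold an
    arbitrary matrix (e.g. raw intensities) instead.  Ties at the cutoff
    are negative (strict inequality).
    """
    rule = rule or CutoffRule()
    if isinstance(normalized, NormalizedMatrix):
        if normalized.mode != "nMAD":
            raise ValidationError(
                f"reactivity calling expects nMAD input, got {normalized.mode}"
            )
        values = normalized.values
    else:
        if not allow_raw:
            raise ValidationError(
                "raw matrix passed without allow_raw=True; normalize first"
            )
        values = normalized

    cutoffs = {}
    mad_fallbacks = []
    for aid in values.columns:
        col = values[aid].to_numpy(dtype=float)
        if rule.strategy == "fixed":
            cutoffs[aid] = float(rule.c)
            continue
        med = float(np.median(col))
        mad = float(np.median(np.abs(col - med)))
        if mad == 0:
            cutoffs[aid] = float(rule.floor)
            mad_fallbacks.append(aid)
        else:
            cutoffs[aid] = max(float(rule.floor), med + rule.c * mad)
    if mad_fallbacks:
        logger.info(
            "antigen_mad cutoff: %d antigen(s) with zero MAD fell back to floor %.3g",
            len(mad_fallbacks),
            rule.floor,
        )
    cutoff_series = pd.Series(cutoffs).reindex(values.columns)
    calls = (values.gt(cutoff_series, axis=1)).astype("int8")
    rule.realized = {k: float(v) for k, v in cutoff_series.items()}
    provenance = {
        "strategy": rule.strategy,
        "c": rule.c,
        "floor": rule.floor,
        "cutoffs": rule.realized,
        "mad_fallback_antigens": mad_fallbacks,
    }
    return BinaryReactivityMatrix(calls=calls, provenance=provenance)


def protein_level_calls(
    calls: BinaryReactivityMatrix, panel: Iterable[AntigenRecord]
) -> BinaryReactivityMatrix:
    """Aggregate antigen calls to proteins: positive iff any fragment is.

    Protein column order follows first appearance in the panel.
    """
    mapping = {}
    proteins: list[str] = []
    for rec in panel:
        mapping[rec.antigen_id] = rec.protein_id
        if rec.protein_id not in proteins:
            proteins.append(rec.protein_id)
    unmapped = [a for a in calls.calls.columns if a not in mapping]
    if unmapped:
        raise ValidationError(f"antigen(s) without protein mapping: {unmapped}")

    grouped = calls.calls.T.groupby(
        calls.calls.columns.map(mapping.get)
    ).max().T
    grouped = grouped[[p for p in proteins if p in grouped.columns]]
    provenance = dict(calls.provenance)
    provenance["level"] = "protein"
    provenance["aggregation"] = "any-fragment OR"
    return BinaryReactivityMatrix(calls=grouped.astype("int8"), provenance=provenance)


def reactivity_summary(calls: BinaryReactivityMatrix) -> dict:
    """Headline counts of a binary call matrix.

    Reports the number (and half-up-rounded percentage) of targets with at
    least one positive sample, per-target positive counts, and the range
    of per-sample loads.
    """
    df = calls.calls
    per_target = df.sum(axis=0).astype(int)
    per_sample = df.sum(axis=1).astype(int)
    n_targets = int(df.shape[1])
    n_reactive = int((per_target > 0).sum())
    return {
        "n_targets": n_targets,
        "n_reactive_targets": n_reactive,
        "pct_reactive_targets": pct_half_up(n_reactive, n_targets) if n_targets else 0,
        "per_target_positive_counts": per_target.to_dict(),
        "detected_in_range": (
            (int(per_target[per_target > 0].min()), int(per_target.max()))
            if n_reactive
            else (0, 0)
        ),
        "load_range": (int(per_sample.min()), int(per_sample.max())) if len(df) else (0, 0),
    }
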