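"""Untargeted planar-screen candidate selection.

Two pooled plasma samples (one from diffuse-disease patients, one from
limited-disease patients) are screened over a near proteome-wide antigen
array.  After array-wise nSD standardization, antigens whose signal in the
diffuse pool reaches a cutoff (default 4 SD) and exceeds the limited pool
are kept and ranked by a composite of signal strength and pool difference.
The ranked candidates, complemented with literature-reported antigens,
form the targeted bead-array panel.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import AntigenRecord, ValidationError, logger

__all__ = ["select_planar_candidates", "candidates_to_panel"]

RANK_ORDERS = ("composite", "intensity", "difference")


def select_planar_candidates(
    dc_pool: pd.Series,
    lc_pool: pd.Series,
    cutoff: float = 4.0,
    min_difference: float = 0.0,
    order: str = "composite",
) -> pd.DataFrame:
    """Select and rank diffuse-pool-elevated antigens from nSD vectors.

    An antigen is a candidate when its diffuse-pool nSD reaches ``cutoff``
    and its diffuse-minus-limited difference exceeds ``min_difference``.
    The default composite ranking averages the descending rank by
    diffuse-pool nSD with the descending rank by pool difference, breaking
    ties by antigen id, so both the signal strength and the width of the
    pool difference contribute without arbitrary weights.  Single-key
    orderings are available via ``order='intensity'`` / ``'difference'``.

    Returns a DataFrame with columns ``antigen_id, nsd_dc, nsd_lc,
    difference, composite_rank``, sorted by rank.
    """
    if order not in RANK_ORDERS:
        raise ValueError(f"order must be one of {RANK_ORDERS}")
    if set(dc_pool.index) != set(lc_pool.index):
        raise ValidationError("pool vectors cover different antigen ids")
    lc_pool = lc_pool.reindex(dc_pool.index)

    df = pd.DataFrame(
        {
            "antigen_id": dc_pool.index,
            "nsd_dc": dc_pool.to_numpy(dtype=float),
            "nsd_lc": lc_pool.to_numpy(dtype=float),
        }
    )
    df["difference"] = df["nsd_dc"] - df["nsd_lc"]
    kept = df[(df["nsd_dc"] >= cutoff) & (df["difference"] > min_difference)].copy()
    if kept.empty:
        kept["composite_rank"] = pd.Series(dtype=int)
        logger.info("planar selection: 0 candidates at cutoff %.3g", cutoff)
        return kept.reset_index(drop=True)

    rank_intensity = kept["nsd_dc"].rank(ascending=False, method="average")
    rank_difference = kept["difference"].rank(ascending=False, method="average")
    if order == "composite":
        score = (rank_intensity + rank_difference) / 2.0
    elif order == "intensity":
        score = rank_intensity
    else:
        score = rank_difference
    kept = kept.assign(_score=score).sort_values(
        ["_score", "antigen_id"], kind="mergesort"
    )
    kept["composite_rank"] = range(1, len(kept) + 1)
    kept = kept.drop(columns="_score").reset_index(drop=True)
    logger.info(
        "planar selection: %d candidates at cutoff %.3g (order=%s)",
        len(kept),
        cutoff,
        order,
    )
    return kept


def candidates_to_panel(
    candidates: pd.DataFrame | Sequence[str],
    literature: Iterable[AntigenRecord] = (),
    protein_map: Mapping[str, str] | None = None,
    fibrosis_related: Mapping[str, bool] | None = None,
) -> list[AntigenRecord]:
    """Union of planar-selected candidates and literature antigens.

    Duplicated antigen ids collapse with the planar record winning.
    ``protein_map`` supplies protein ids for planar candidates (defaults to
    the antigen id itself when unknown); ``fibrosis_related`` optionally
    flags candidate antigens.
    """
    if isinstance(candidates, pd.DataFrame):
        candidate_ids = list(candidates["antigen_id"])
    else:
        candidate_ids = list(candidates)
    protein_map = protein_map or {}
    fibrosis_related = fibrosis_related or {}

    panel: dict[str, AntigenRecord] = {}
    for aid in candidate_ids:
        panel[aid] = AntigenRecord(
            antigen_id=aid,
            protein_id=protein_map.get(aid, aid),
            source="planar_selected",
            fibrosis_related=bool(fibrosis_related.get(aid, False)),
        )
    for rec in literature:
        panel.setdefault(rec.antigen_id, rec)
    result = list(panel.values())
    logger.info(
        "panel assembly: %d planar + literature -> %d antigens",
        len(candidate_ids),
        len(result),
    )
    return result
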