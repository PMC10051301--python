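"""Case-control and subgroup statistics on binary reactivity calls.

All tests are nonparametric, matching the discrete/ordinal nature of the
data: Mann-Whitney-Wilcoxon for two-group autoantibody-load comparisons,
Kruskal-Wallis for three or more groups, Spearman rank correlation for
load vs age, and the two-sided Fisher exact test (point-probability
convention) for prevalence.  Raw p-values are reported by default;
Benjamini-Hochberg adjustment is available but clearly labelled.

The candidate-selection rule keeps a target when its case-vs-control
Fisher p is below alpha, or when its case prevalence strictly exceeds the
control prevalence and the target binds a fibrosis-related protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AntigenRecord, BinaryReactivityMatrix, ValidationError, logger, pct_half_up

__all__ = [
    "LoadResult",
    "PrevalenceResult",
    "SelectionDecision",
    "AugmentationResult",
    "autoantibody_load",
    "compare_load",
    "compare_load_multi",
    "load_age_correlation",
    "fisher_exact_p",
    "prevalence_test",
    "prevalence_table",
    "select_candidates",
    "panel_augmentation",
]


@dataclass
class LoadResult:
    """Group comparison of per-sample autoantibody loads."""

    test: str
    statistic: float
    p_value: float
    group_medians: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValidationError(f"p-value out of range: {self.p_value}")


@dataclass
class PrevalenceResult:
    """2x2 prevalence comparison for one target.

    a/b: positive/negative cases, c/d: positive/negative controls (or the
    two compared subgroups).
    """

    target_id: str
    a: int
    b: int
    c: int
    d: int
    p_value: float

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def prevalence_case(self) -> float:
        return self.a / self.n_cases

    @property
    def prevalence_control(self) -> float:
        return self.c / self.n_controls

    @property
    def prevalence_case_pct(self) -> int:
        return pct_half_up(self.a, self.n_cases)

    @property
    def prevalence_control_pct(self) -> int:
        return pct_half_up(self.c, self.n_controls)


@dataclass
class SelectionDecision:
    """Outcome of the two-branch candidate-selection rule for one target."""

    target_id: str
    significant: bool
    fibrosis_rescued: bool
    p_value: float
    selected: bool = field(init=False)

    def __post_init__(self) -> None:
        self.selected = self.significant or self.fibrosis_rescued


@dataclass
class AugmentationResult:
    """Clinical-panel positivity before and after adding array markers."""

    n_cases: int
    n_clinical_positive: int
    n_augmented_positive: int
    baseline_pct: int
    augmented_pct: int


def autoantibody_load(calls: BinaryReactivityMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample count of positive calls (row sums of the binary matrix)."""
    df = calls.calls if isinstance(calls, BinaryReactivityMatrix) else calls
    return df.sum(axis=1).astype(int).rename("load")


def _split_groups(values: pd.Series, labels: pd.Series) -> dict[str, np.ndarray]:
    labels = labels.reindex(values.index)
    groups = {}
    for g in pd.unique(labels.dropna()):
        groups[str(g)] = values[labels == g].to_numpy(dtype=float)
    return groups


def compare_load(load: pd.Series, labels: pd.Series) -> LoadResult:
    """Two-sided Mann-Whitney-Wilcoxon comparison of loads between two groups.

    Exact p-value for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy).
    """
    groups = _split_groups(load, labels)
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {sorted(groups)}")
    (name_x, x), (name_y, y) = groups.items()
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty group in load comparison")
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    result = LoadResult(
        test="mann-whitney-wilcoxon",
        statistic=float(stat),
        p_value=float(p),
        group_medians={name_x: float(np.median(x)), name_y: float(np.median(y))},
    )
    logger.info(
        "load comparison %s (n=%d) vs %s (n=%d): p=%.4g",
        name_x, len(x), name_y, len(y), p,
    )
    return result


def compare_load_multi(load: pd.Series, labels: pd.Series) -> LoadResult:
    """Kruskal-Wallis comparison of loads across k >= 3 groups.

    Tie-corrected H statistic with a chi-square p-value on k-1 degrees of
    freedom.  A fully constant sample (no variation at all) yields H = 0,
    p = 1 by convention.
    """
    groups = _split_groups(load, labels)
    if len(groups) < 3:
        raise ValidationError(f"need >= 3 groups, got {sorted(groups)}")
    arrays = list(groups.values())
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("empty group in multi-group comparison")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*arrays)
    result = LoadResult(
        test="kruskal-wallis",
        statistic=float(stat),
        p_value=float(p),
        group_medians={g: float(np.median(a)) for g, a in groups.items()},
    )
    logger.info(
        "multi-group load comparison over %d groups: H=%.4g p=%.4g",
        len(groups), stat, p,
    )
    return result


def load_age_correlation(
    load: pd.Series,
    age: pd.Series,
    mask: pd.Series | None = None,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation between autoantibody load and age within one group.

    Spearman rank correlation by default (Pearson via ``method``); returns
    ``(r, two-sided p)``.
    """
    if mask is not None:
        load = load[mask.reindex(load.index).fillna(False).astype(bool)]
    age = age.reindex(load.index)
    if len(load) < 3:
        raise ValidationError("need at least 3 paired observations")
    x, y = load.to_numpy(dtype=float), age.to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant vector: correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability convention: the sum, under fixed margins, of the
    probabilities of all tables no more probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count")
    if a + b == 0 or c + d == 0:
        raise ValidationError("empty margin in 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def prevalence_test(
    calls_column: pd.Series,
    labels: pd.Series,
    subgroup_mask: pd.Series | None = None,
    target_id: str = "",
    positive_label: str = "case",
) -> PrevalenceResult:
    """Two-sided Fisher exact test on one target's 0/1 calls.

    ``labels`` assigns each sample to one of two groups; samples whose
    label (or subgroup mask) is missing are dropped from this test only.
    The two-sided p-value follows the point-probability convention: the
    sum of probabilities, under fixed margins, of all tables no more
    probable than the observed one.
    """
    labels = labels.reindex(calls_column.index)
    keep = labels.notna()
    if subgroup_mask is not None:
        keep &= subgroup_mask.reindex(calls_column.index).notna() & subgroup_mask.reindex(
            calls_column.index
        ).fillna(False).astype(bool)
    calls_column, labels = calls_column[keep], labels[keep]
    level_names = list(pd.unique(labels))
    if len(level_names) != 2:
        raise ValidationError(f"need exactly 2 groups, got {level_names}")
    if positive_label in level_names:
        level_names = [positive_label] + [g for g in level_names if g != positive_label]
    g1 = calls_column[labels == level_names[0]]
    g2 = calls_column[labels == level_names[1]]
    a, b = int(g1.sum()), int((1 - g1).sum())
    c, d = int(g2.sum()), int((1 - g2).sum())
    return PrevalenceResult(
        target_id=target_id, a=a, b=b, c=c, d=d, p_value=fisher_exact_p(a, b, c, d)
    )


def prevalence_table(
    calls: BinaryReactivityMatrix | pd.DataFrame,
    labels: pd.Series,
    subgroup_mask: pd.Series | None = None,
) -> list[PrevalenceResult]:
    """Fisher prevalence test for every target column."""
    df = calls.calls if isinstance(calls, BinaryReactivityMatrix) else calls
    return [
        prevalence_test(df[t], labels, subgroup_mask=subgroup_mask, target_id=str(t))
        for t in df.columns
    ]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-FDR adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adjusted[i] = running
    return adjusted


def select_candidates(
    results: Iterable[PrevalenceResult],
    panel: Iterable[AntigenRecord],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list[SelectionDecision]:
    """Apply the two-branch selection rule to prevalence results.

    A target is selected when (i) its p-value is below ``alpha``, or
    (ii) its case prevalence strictly exceeds the control prevalence and
    it maps to a fibrosis-related protein.  ``panel`` supplies the
    fibrosis flags, looked up by antigen id or by protein id (a protein is
    fibrosis-related when any of its fragments is).  ``adjust='bh'``
    switches branch (i) to BH-adjusted p-values.
    """
    results = list(results)
    fibrosis: dict[str, bool] = {}
    for rec in panel:
        fibrosis[rec.antigen_id] = fibrosis.get(rec.antigen_id, False) or rec.fibrosis_related
        fibrosis[rec.protein_id] = fibrosis.get(rec.protein_id, False) or rec.fibrosis_related
    p_values = [r.p_value for r in results]
    if adjust == "bh":
        p_values = list(benjamini_hochberg(p_values))
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    decisions = []
    for r, p in zip(results, p_values):
        significant = p < alpha
        rescued = (
            r.prevalence_case > r.prevalence_control
            and fibrosis.get(r.target_id, False)
        )
        decisions.append(
            SelectionDecision(
                target_id=r.target_id,
                significant=bool(significant),
                fibrosis_rescued=bool(rescued),
                p_value=float(p),
            )
        )
    logger.info(
        "selection rule: %d/%d targets selected (alpha=%.3g, adjust=%s)",
        sum(d.selected for d in decisions), len(decisions), alpha, adjust,
    )
    return decisions


def panel_augmentation(
    clinical_positive: pd.Series | Sequence[bool],
    marker_positive: pd.Series | Sequence[bool],
) -> AugmentationResult:
    """Cohort positivity before/after adding an array marker to the
    clinical antibody panel (cases only).

    Baseline is the percentage of cases positive on the clinical panel;
    augmented counts a case positive when either the clinical panel or the
    array marker is positive.  Percentages are rounded half-up.
    """
    clinical = np.asarray(clinical_positive, dtype=bool)
    marker = np.asarray(marker_positive, dtype=bool)
    if clinical.shape != marker.shape:
        raise ValidationError("clinical and marker vectors differ in length")
    n = len(clinical)
    if n == 0:
        raise ValidationError("no cases supplied")
    n_clin = int(clinical.sum())
    n_aug = int((clinical | marker).sum())
    return AugmentationResult(
        n_cases=n,
        n_clinical_positive=n_clin,
        n_augmented_positive=n_aug,
        baseline_pct=pct_half_up(n_clin, n),
        augmented_pct=pct_half_up(n_aug, n),
    )
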