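"""Synthetic cohorts with known ground truth.

Two layers of simulated data mirror the two phases of an antigen-array
autoantibody study:

* :func:`simulate_planar_pools` — an untargeted planar-array screen of two
  pooled plasma samples over many antigens, with a heavy-tailed background
  and a small minority of strongly elevated antigens in the first
  (diffuse-disease-like) pool.
* :func:`simulate_bead_cohort` — a targeted bead-array cohort of ~55 cases
  and ~52 controls over a few hundred antigens, with per-sample
  multiplicative background shifts, sparse antigen-specific reactivity and
  clinical metadata whose marginal frequencies follow the study-group
  table of a typical systemic-sclerosis cohort (84% female cases, median
  case age ~61, 14/55 lung fibrosis, 13/55 with skin score above 15, and
  8 patients with both).

The background is log-normal with a per-sample multiplicative shift: a
sample-wise robust normalization (median/MAD) is designed to remove exactly
such shifts, which makes the purpose of normalization directly testable.
A truly reactive sample-antigen pair has its signal multiplied by
``exp(reactive_effect)``.  All draws flow from a single seeded generator,
so identical configurations produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CLINICAL_ANTIBODIES,
    CLINICAL_FLAGS,
    AntigenRecord,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_bead_cohort",
    "simulate_planar_pools",
]

#: Study-group marginal counts (out of 55 cases) used for simulated metadata.
CASE_MARGINALS = {
    "calcinosis": 16,
    "digital_ulcers": 12,
    "dysphagia": 29,
    "pah": 20,
    "raynaud": 47,
    "reflux": 30,
    "sicca": 16,
}
ANTIBODY_MARGINALS = {"scl70": 18, "centromere": 19, "ssa": 4, "rnp_sm": 3}
#: joint frequencies of lung fibrosis x active skin fibrosis (mRSS > 15)
#: among 55 cases: 8 both, 6 fibrosis only, 5 high-mRSS only.
FIBROSIS_JOINT = {"both": 8, "lf_only": 6, "mrss_only": 5}
SUBTYPE_COUNTS = {"limited": 42, "diffuse": 11, "no_sclerosis": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the bead-cohort generator.

    Defaults emulate the targeted-screening conditions: 55 cases vs 52
    controls over 246 antigens, 132 of which carry genuine reactivity;
    per-antigen positivity probabilities of 0.08 (cases) vs 0.04 (controls)
    put each reactive antigen's positive count in the single-digit range
    and per-sample autoantibody loads roughly between one and fifteen.
    ``load_boost_fibrosis`` is added to a case's per-antigen positivity
    probability once per fibrosis feature present (lung fibrosis, skin
    score above 15), so the both-features subgroup has the highest expected
    load by construction.
    """

    n_cases: int = 55
    n_controls: int = 52
    n_antigens: int = 246
    n_reactive_antigens: int = 132
    background_location: float = 6.0  # log-MFI, exp(6) ~ 400 MFI
    background_scale: float = 0.35
    sample_shift_scale: float = 0.3  # sd of log multiplicative shift
    reactive_effect: float = 3.5  # log-space elevation of true reactivity
    prevalence_case: float = 0.08
    prevalence_control: float = 0.04
    load_boost_fibrosis: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_antigens) <= 0:
            raise ValidationError("cohort dimensions must be positive")
        if not 0 <= self.n_reactive_antigens <= self.n_antigens:
            raise ValidationError("n_reactive_antigens must be in [0, n_antigens]")
        for name in ("prevalence_case", "prevalence_control", "load_boost_fibrosis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.background_scale <= 0 or self.sample_shift_scale < 0:
            raise ValidationError("scales must be positive")


@dataclass
class GroundTruth:
    """Which sample-antigen pairs are truly reactive, and which antigens
    are case-enriched by construction."""

    reactive_pairs: set[tuple[str, str]] = field(default_factory=set)
    antigen_labels: dict[str, bool] = field(default_factory=dict)

    def reactive_antigens(self) -> set[str]:
        return {a for _, a in self.reactive_pairs}


def _allocate(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Boolean vector of length n with exactly `count` True at random positions."""
    out = np.zeros(n, dtype=bool)
    out[rng.choice(n, size=min(count, n), replace=False)] = True
    return out


def _case_metadata(rng: np.random.Generator, n_cases: int) -> list[SampleRecord]:
    scale = n_cases / 55.0

    def scaled(c: int) -> int:
        return min(n_cases, int(round(c * scale)))

    # joint fibrosis structure first, so the load-boost subgroups exist
    lf = np.zeros(n_cases, dtype=bool)
    high_mrss = np.zeros(n_cases, dtype=bool)
    order = rng.permutation(n_cases)
    n_both = scaled(FIBROSIS_JOINT["both"])
    n_lf_only = scaled(FIBROSIS_JOINT["lf_only"])
    n_mrss_only = scaled(FIBROSIS_JOINT["mrss_only"])
    idx = 0
    lf[order[idx : idx + n_both]] = True
    high_mrss[order[idx : idx + n_both]] = True
    idx += n_both
    lf[order[idx : idx + n_lf_only]] = True
    idx += n_lf_only
    high_mrss[order[idx : idx + n_mrss_only]] = True

    subtype_pool: list[str] = []
    for name, count in SUBTYPE_COUNTS.items():
        subtype_pool += [name] * scaled(count)
    while len(subtype_pool) < n_cases:
        subtype_pool.append("limited")
    subtypes = list(rng.permutation(subtype_pool[:n_cases]))

    sex = np.where(rng.random(n_cases) < 0.84, "F", "M")
    ages = np.clip(np.round(rng.normal(61, 13, n_cases)), 25, 85).astype(int)

    flags_matrix = {
        name: _allocate(rng, n_cases, scaled(count))
        for name, count in CASE_MARGINALS.items()
    }
    ab_matrix = {
        name: _allocate(rng, n_cases, scaled(count))
        for name, count in ANTIBODY_MARGINALS.items()
    }

    records = []
    for i in range(n_cases):
        if high_mrss[i]:
            mrss = int(rng.integers(16, 47))
        else:
            mrss = int(rng.integers(0, 16))
        flags = {name: bool(flags_matrix[name][i]) for name in CASE_MARGINALS}
        flags["lung_fibrosis"] = bool(lf[i])
        antibodies = {name: bool(ab_matrix[name][i]) for name in CLINICAL_ANTIBODIES}
        records.append(
            SampleRecord(
                sample_id=f"case_{i + 1:03d}",
                group="case",
                subtype=subtypes[i],
                age=int(ages[i]),
                sex=str(sex[i]),
                mrss=mrss,
                clinical_flags={k: flags.get(k) for k in CLINICAL_FLAGS},
                clinical_antibodies=antibodies,
            )
        )
    return records


def _control_metadata(rng: np.random.Generator, n_controls: int) -> list[SampleRecord]:
    sex = np.where(rng.random(n_controls) < 0.75, "F", "M")
    ages = np.clip(np.round(rng.normal(53, 14, n_controls)), 21, 79).astype(int)
    return [
        SampleRecord(
            sample_id=f"ctrl_{i + 1:03d}",
            group="control",
            subtype="not_applicable",
            age=int(ages[i]),
            sex=str(sex[i]),
            mrss=None,
            clinical_flags={k: None for k in CLINICAL_FLAGS},
            clinical_antibodies={k: None for k in CLINICAL_ANTIBODIES},
        )
        for i in range(n_controls)
    ]


def default_panel(
    n_antigens: int, rng: np.random.Generator, fibrosis_fraction: float = 0.3
) -> list[AntigenRecord]:
    """A panel mimicking a planar-selected + literature antigen mix.

    The first ~30% of antigens are planar-selected; proteins are shared by
    pairs of antigens at roughly the rate seen in multi-fragment panels, so
    protein-level aggregation is exercised.
    """
    n_planar = int(round(n_antigens * 73 / 246))
    records = []
    protein_idx = 0
    i = 0
    while i < n_antigens:
        protein_idx += 1
        pid = f"PROT{protein_idx:04d}"
        n_frag = 2 if rng.random() < 0.25 and i + 1 < n_antigens else 1
        for _ in range(n_frag):
            if i >= n_antigens:
                break
            records.append(
                AntigenRecord(
                    antigen_id=f"AG{i + 1:04d}",
                    protein_id=pid,
                    source="planar_selected" if i < n_planar else "literature",
                    fibrosis_related=bool(rng.random() < fibrosis_fraction),
                )
            )
            i += 1
    return records


def simulate_bead_cohort(
    config: SimulationConfig | None = None, **overrides
) -> tuple[pd.DataFrame, list[SampleRecord], list[AntigenRecord], GroundTruth]:
    """Simulate a bead-array cohort with known reactive pairs.

    Returns ``(matrix, metadata, panel, truth)`` where ``matrix`` is the
    raw MFI DataFrame (samples x antigens).  A cell's MFI is

        exp(N(background_location, background_scale)) * sample_shift
            * (exp(reactive_effect) if the pair is truly reactive else 1)

    with ``sample_shift = exp(N(0, sample_shift_scale))`` drawn once per
    sample.  Reactivity indicators are Bernoulli per (sample, reactive
    antigen) with group-specific prevalence plus the fibrosis load boost.
    """
    config = replace(config or SimulationConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    cases = _case_metadata(rng, config.n_cases)
    controls = _control_metadata(rng, config.n_controls)
    metadata = cases + controls
    sample_ids = [r.sample_id for r in metadata]
    panel = default_panel(config.n_antigens, rng)
    antigen_ids = [a.antigen_id for a in panel]

    reactive_cols = np.sort(
        rng.choice(config.n_antigens, size=config.n_reactive_antigens, replace=False)
    )
    n_samples = len(sample_ids)

    # per-sample positivity probability for reactive antigens
    probs = np.empty(n_samples)
    for i, rec in enumerate(metadata):
        if rec.group == "control":
            probs[i] = config.prevalence_control
        else:
            p = config.prevalence_case
            if rec.flag("lung_fibrosis"):
                p += config.load_boost_fibrosis
            if rec.mrss is not None and rec.mrss > 15:
                p += config.load_boost_fibrosis
            probs[i] = min(p, 1.0)

    reactive = np.zeros((n_samples, config.n_antigens), dtype=bool)
    if config.n_reactive_antigens:
        draws = rng.random((n_samples, config.n_reactive_antigens))
        reactive[:, reactive_cols] = draws < probs[:, None]

    log_bg = rng.normal(
        config.background_location, config.background_scale, (n_samples, config.n_antigens)
    )
    shift = np.exp(rng.normal(0.0, config.sample_shift_scale, n_samples))
    values = np.exp(log_bg) * shift[:, None]
    values[reactive] *= np.exp(config.reactive_effect)

    matrix = pd.DataFrame(values, index=sample_ids, columns=antigen_ids)

    truth = GroundTruth()
    case_enriched = config.prevalence_case > config.prevalence_control
    for j in reactive_cols:
        truth.antigen_labels[antigen_ids[j]] = case_enriched
    rows, cols = np.nonzero(reactive)
    truth.reactive_pairs = {
        (sample_ids[i], antigen_ids[j]) for i, j in zip(rows, cols)
    }
    return matrix, metadata, panel, truth


def simulate_planar_pools(
    n_antigens: int,
    n_elevated: int,
    elevation_sd_units: float = 8.0,
    seed: int = 0,
    background_location: float = 7.0,
    background_scale: float = 0.5,
) -> tuple[pd.Series, pd.Series, GroundTruth]:
    """Simulate the two pooled-plasma vectors of a planar-array screen.

    Both pools share a log-normal background; ``n_elevated`` antigens in
    the first (diffuse-disease-like) pool are raised by
    ``elevation_sd_units`` background standard deviations.
    """
    if n_elevated > n_antigens:
        raise ValidationError("n_elevated must not exceed n_antigens")
    rng = np.random.default_rng(seed)
    ids = [f"AG{i + 1:05d}" for i in range(n_antigens)]
    dc = np.exp(rng.normal(background_location, background_scale, n_antigens))
    lc = np.exp(rng.normal(background_location, background_scale, n_antigens))
    truth = GroundTruth()
    if n_elevated:
        elevated = rng.choice(n_antigens, size=n_elevated, replace=False)
        dc[elevated] += elevation_sd_units * dc.std()
        pool_id = "dc_pool"
        for j in elevated:
            truth.reactive_pairs.add((pool_id, ids[j]))
            truth.antigen_labels[ids[j]] = True
    return (
        pd.Series(dc, index=ids, name="dc_pool"),
        pd.Series(lc, index=ids, name="lc_pool"),
        truth,
    )
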