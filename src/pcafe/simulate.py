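"""Seeded synthetic-data generators with known ground truth.

Two generators back the test and acceptance machinery:

* :func:`gen_expression` builds a two-group probe-by-sample matrix on a
  Gaussian noise background, with a chosen number of "signal" probes
  carrying an additive group-mean shift in the case samples.  The default
  design mirrors the motivating study: 10 control and 9 case samples and
  ~10^4 probes.  Signal probes are placed first and named predictably
  (``sig_0001`` ...) so truth recovery is trivially checkable.

* :func:`gen_survival` builds a single-gene survival cohort in which the
  hazard is multiplied by a known ratio for the upper expression half,
  with exact-fraction independent uniform censoring.

Both are pure functions of their config (the seed included): repeated
calls agree bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleGroups
from .survival import SurvivalCohort

__all__ = [
    "ExpressionSimConfig",
    "SurvivalSimConfig",
    "ExpressionSim",
    "SurvivalSim",
    "gen_expression",
    "gen_survival",
]


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Two-group expression simulation parameters.

    ``effect`` is the additive case-group mean shift in units of the
    pre-normalization noise standard deviation.
    """

    n_probes: int = 10_000
    n_controls: int = 10
    n_cases: int = 9
    n_signal_probes: int = 100
    effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 2 or self.n_controls < 2 or self.n_cases < 2:
            raise ValueError("need >= 2 probes and >= 2 samples per group")
        if not 0 <= self.n_signal_probes <= self.n_probes:
            raise ValueError("n_signal_probes must lie in [0, n_probes]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Survival cohort simulation parameters.

    Survival times are exponential with rate ``baseline_hazard`` (per
    day), multiplied by ``hazard_ratio`` for patients in the upper
    expression half.  ``censor_fraction`` of the cohort (rounded) is
    censored at a uniform fraction of its event time.
    """

    n_patients: int = 360
    hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 1000.0
    censor_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("need >= 4 patients")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")


@dataclass
class ExpressionSim:
    matrix: ExpressionMatrix
    groups: SampleGroups
    signal_probes: set
    config: ExpressionSimConfig


@dataclass
class SurvivalSim:
    cohort: SurvivalCohort
    high_patients: set  # patients whose hazard is multiplied
    config: SurvivalSimConfig


def gen_expression(cfg: ExpressionSimConfig) -> ExpressionSim:
    """Simulate a two-group expression matrix with known signal probes."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_controls + cfg.n_cases
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probes, n))
    values[: cfg.n_signal_probes, cfg.n_controls :] += cfg.effect * cfg.noise_sd
    probe_ids = [f"sig_{i + 1:04d}" for i in range(cfg.n_signal_probes)] + [
        f"probe_{i + 1:06d}" for i in range(cfg.n_probes - cfg.n_signal_probes)
    ]
    sample_ids = [f"ctrl_{j + 1:02d}" for j in range(cfg.n_controls)] + [
        f"case_{j + 1:02d}" for j in range(cfg.n_cases)
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        meta={"seed": cfg.seed, "config": cfg},
    )
    groups = SampleGroups(
        {s: ("control" if s.startswith("ctrl") else "case") for s in sample_ids}
    )
    return ExpressionSim(matrix, groups, set(probe_ids[: cfg.n_signal_probes]), cfg)


def gen_survival(cfg: SurvivalSimConfig) -> SurvivalSim:
    """Simulate a survival cohort with expression-dependent hazard."""
    rng = np.random.default_rng(cfg.seed)
    expr = rng.standard_normal(cfg.n_patients)
    high = expr > np.median(expr)
    hazard = np.where(high, cfg.baseline_hazard * cfg.hazard_ratio, cfg.baseline_hazard)
    times = rng.exponential(1.0 / hazard)
    event = np.ones(cfg.n_patients, dtype=int)
    n_censor = round(cfg.censor_fraction * cfg.n_patients)
    if n_censor:
        who = rng.choice(cfg.n_patients, size=n_censor, replace=False)
        event[who] = 0
        times[who] *= rng.uniform(0.0, 1.0, size=n_censor)
    times = np.maximum(times, np.finfo(float).tiny)
    patient_ids = [f"pt_{i + 1:04d}" for i in range(cfg.n_patients)]
    cohort = SurvivalCohort(
        pd.DataFrame(
            {"time": times, "event": event, "expression": expr},
            index=pd.Index(patient_ids, name="patient_id"),
        )
    )
    high_ids = {patient_ids[i] for i in np.flatnonzero(high)}
    return SurvivalSim(cohort, high_ids, cfg)
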