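"""Analysis configuration and seed derivation.

One :class:`AnalysisConfig` plus one integer seed reproduces every
stochastic stage of the pipeline; per-stage seeds are derived by hashing
the stage name into the master seed so that adding a stage never shifts
the streams of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across the pipeline stages.

    alpha_per_task
        Per-task significance level for the activation and asymmetry
        tests; the conjunction threshold is its cube and the overall
        (activation AND asymmetry) threshold the square of that.
    k_range
        Inclusive (kmin, kmax) interval searched by the cluster-number
        vote.
    bootstrap_reps, bootstrap_scales
        Multiscale bootstrap replicates per scale, and the relative
        resample-size grid (fractions of the subject count).
    opsahl_alpha
        Tuning exponent of the weighted shortest-path cost w**(-alpha)
        used by betweenness centrality.
    hub_sd_multiplier
        Hubs exceed mean + multiplier * SD on both centralities.
    connector_top_fraction
        Fraction of the full selected-region set whose highest
        participation indices are flagged connector hubs.
    """

    alpha_per_task: float = 0.05
    k_range: tuple = (2, 8)
    bootstrap_reps: int = 10_000
    bootstrap_scales: tuple = (
        0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4,
    )
    opsahl_alpha: float = 1.0
    hub_sd_multiplier: float = 1.0
    connector_top_fraction: float = 0.15
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    filter_order: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_per_task < 1:
            raise ValueError("alpha_per_task must lie in (0, 1)")
        if any(not 0 < s <= 2 for s in self.bootstrap_scales):
            raise ValueError("bootstrap scales must lie in (0, 2]")
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100")
        if self.opsahl_alpha < 0:
            raise ValueError("opsahl_alpha must be non-negative")
        kmin, kmax = self.k_range
        if kmin < 2 or kmax < kmin:
            raise ValueError("k_range must satisfy 2 <= kmin <= kmax")

    @property
    def conjunction_alpha(self) -> float:
        return self.alpha_per_task**3

    @property
    def overall_alpha(self) -> float:
        return self.conjunction_alpha**2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["bootstrap_scales"] = list(self.bootstrap_scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        if "bootstrap_scales" in d:
            d["bootstrap_scales"] = tuple(d["bootstrap_scales"])
        return cls(**d)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from a master seed."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stage))
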