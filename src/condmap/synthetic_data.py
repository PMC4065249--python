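"""Synthetic conditional screens with known ground truth.

The generative model mirrors what the differential analysis is built to
detect: each gene pair has a condition-independent baseline interaction
(zero for most pairs), a planted condition-specific shift for a small set of
(query, array, drug) triples, and independent replicate noise:

    score(q, a, cond, rep) = mu(q, a) + delta(q, a, drug)*[cond is drug] + eps
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import DRUGS, SCORE_COLUMNS, UNTREATED, InteractionCall, ScreenTensor


@dataclass
class SimulationConfig:
    """Parameters of a simulated conditional screen.

    Defaults mimic a triplicate screen at two concentrations per drug with
    two untreated control blocks.
    """

    n_queries: int = 3
    n_arrays: int = 200
    drugs: Sequence[str] = DRUGS
    concentrations_per_drug: int = 2
    replicates: int = 3
    baseline_sd: float = 2.0
    baseline_interaction_fraction: float = 0.2
    noise_sd: float = 1.0
    planted_fraction: float = 0.01
    effect_size: float = 6.0
    heavy_tail: bool = False
    heavy_tail_fraction: float = 0.05
    heavy_tail_sd_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_queries", "n_arrays", "concentrations_per_drug", "replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("baseline_interaction_fraction", "planted_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("baseline_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        bad = [d for d in self.drugs if d not in DRUGS]
        if bad:
            raise ConfigurationError(f"unknown drug(s) in config: {bad}")


@dataclass
class SyntheticTruth:
    """Planted condition-specific effects: (query, array, drug) -> signed delta."""

    planted: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.planted)

    @property
    def triples(self) -> set[tuple[str, str, str]]:
        return set(self.planted)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"query": q, "array": a, "drug": d, "delta": v}
            for (q, a, d), v in sorted(self.planted.items())
        ]
        return pd.DataFrame(rows, columns=["query", "array", "drug", "delta"])


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0


def generate_screen(config: SimulationConfig) -> tuple[ScreenTensor, SyntheticTruth]:
    """Simulate a replicate-level screen; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    queries = [f"Q{i + 1:02d}" for i in range(config.n_queries)]
    arrays = [f"A{i + 1:04d}" for i in range(config.n_arrays)]
    nq, na = len(queries), len(arrays)

    # condition-independent baselines, sparse
    mu = np.zeros((nq, na))
    has_baseline = rng.random((nq, na)) < config.baseline_interaction_fraction
    n_base = int(has_baseline.sum())
    if config.heavy_tail:
        wide = rng.random(n_base) < config.heavy_tail_fraction
        sds = np.where(wide, config.baseline_sd * config.heavy_tail_sd_factor, config.baseline_sd)
        mu[has_baseline] = rng.normal(0.0, sds)
    else:
        mu[has_baseline] = rng.normal(0.0, config.baseline_sd, size=n_base)

    # planted condition-specific shifts
    truth = SyntheticTruth()
    n_triples = nq * na * len(config.drugs)
    expected_planted = config.planted_fraction * n_triples
    if 0 < expected_planted < 1:
        warnings.warn(
            "planted_fraction too small for the screen size; no effects planted",
            stacklevel=2,
        )
    delta = np.zeros((nq, na, len(config.drugs)))
    if config.planted_fraction > 0 and expected_planted >= 1:
        planted_mask = rng.random((nq, na, len(config.drugs))) < config.planted_fraction
        n_planted = int(planted_mask.sum())
        mags = rng.normal(config.effect_size, config.effect_size / 4.0, size=n_planted)
        mags = np.abs(mags)  # truncate to positive magnitudes
        mags[mags == 0] = config.effect_size
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        delta[planted_mask] = signs * mags
        for (qi, ai, di), v in zip(np.argwhere(planted_mask), delta[planted_mask]):
            truth.planted[(queries[qi], arrays[ai], config.drugs[di])] = float(v)

    # untreated control blocks share the concentration slot structure
    conditions: list[tuple[str, Optional[str], int]] = []  # (drug, conc, drug_index)
    for c in range(config.concentrations_per_drug):
        conditions.append((UNTREATED, f"ctrl{c + 1}", -1))
    for di, drug in enumerate(config.drugs):
        for c in range(config.concentrations_per_drug):
            conditions.append((drug, f"c{c + 1}", di))

    n_cond = len(conditions)
    n_rep = config.replicates
    noise = rng.normal(0.0, config.noise_sd, size=(nq, na, n_cond, n_rep))

    frames = []
    for ci, (drug, conc, di) in enumerate(conditions):
        eff = mu if di < 0 else mu + delta[:, :, di]
        for rep in range(n_rep):
            frames.append(
                pd.DataFrame(
                    {
                        "query": np.repeat(queries, na),
                        "array": np.tile(arrays, nq),
                        "drug": drug,
                        "concentration": conc,
                        "replicate": rep + 1,
                        "score": (eff + noise[:, :, ci, rep]).ravel(),
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]
    return ScreenTensor(df), truth


def truth_confusion(
    calls: Sequence[InteractionCall],
    truth: SyntheticTruth,
    n_triples_tested: int,
) -> ConfusionCounts:
    """Score calls against planted truth over (query, array, drug) triples.

    A call counts as a true positive only if its direction matches the sign
    of the planted delta; a wrong-direction call at a planted triple counts
    as both a false positive and a false negative.
    """
    called = {c.key: c.direction for c in calls}
    tp = fp = fn = 0
    for triple, delta in truth.planted.items():
        want = "positive" if delta > 0 else "negative"
        if called.get(triple) == want:
            tp += 1
        else:
            fn += 1
            if triple in called:
                fp += 1  # wrong direction: also a false discovery
    fp += sum(1 for key in called if key not in truth.planted)
    tn = n_triples_tested - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=max(tn, 0))
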