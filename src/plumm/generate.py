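"""Constrained stochastic generation of rhythm sets.

Generates five-onset, downbeat-anchored rhythm patterns whose delta
surprisal or syncopation index lands within a buffer of requested target
values.  Candidate patterns are drawn from a probabilistic template — a
uniformly weighted mixture of the metered and flat (unmetered) templates,
with a fresh mixture weight per attempt — so that both very regular and
very irregular rhythms arise, then rejection-sampled against the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, TemplatePair, delta_surprisal_batch
from .rhythm import GRID, RhythmPattern, syncopation_index

log = logging.getLogger(__name__)

Metric = Literal["delta_surprisal", "syncopation"]

#: default buffers per metric: a pattern is accepted when its achieved
#: value lies within this distance of the target
DEFAULT_BUFFERS = {"delta_surprisal": 0.01, "syncopation": 1.0}


class GenerationError(RuntimeError):
    """A target could not be reached within the attempt budget."""


@dataclass(frozen=True)
class GenerationSpec:
    """Targets and constraints for one generation run.

    The constraints mirror the reference stimuli: exactly ``n_onsets``
    onsets per measure, an onset forced on the first beat, and no onsets on
    adjacent grid steps (the strict reading of "no consecutive 32nd-note
    onsets").
    """

    metric: Metric = "delta_surprisal"
    targets: tuple[float, ...] = ()
    buffer: float | None = None
    n_onsets: int = 5
    require_first_beat: bool = True
    forbid_consecutive_32nds: bool = True
    max_attempts: int = 10_000
    repeats: int = 4

    def __post_init__(self) -> None:
        if self.metric not in DEFAULT_BUFFERS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not 1 <= self.n_onsets <= GRID:
            raise ValueError("n_onsets outside the grid")
        if self.buffer is not None and self.buffer <= 0:
            raise ValueError("buffer must be positive")

    @property
    def effective_buffer(self) -> float:
        return self.buffer if self.buffer is not None else DEFAULT_BUFFERS[self.metric]


def mixture_template(weight: float, templates: TemplatePair) -> np.ndarray:
    """Convex combination of the metered and flat templates.

    ``weight = 1`` reproduces the metered template, ``weight = 0`` the flat
    unmetered one.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"mixture weight must lie in [0, 1], got {weight}")
    return weight * templates.metered + (1.0 - weight) * templates.unmetered


def _satisfies_constraints(positions: np.ndarray, spec: GenerationSpec) -> bool:
    if spec.forbid_consecutive_32nds:
        onsets = np.zeros(GRID, dtype=bool)
        onsets[positions] = True
        # adjacency is cyclic: position 31 next to 0
        if np.any(onsets & np.roll(onsets, -1)):
            return False
    return True


def sample_pattern(
    template: Sequence[float],
    spec: GenerationSpec,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> RhythmPattern:
    """Draw one constraint-satisfying pattern from a probabilistic template.

    The first beat is forced on (when required); the remaining onsets are
    drawn without replacement with selection probability proportional to
    the template, resampling until the adjacency constraint holds.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != (GRID,):
        raise ValueError(f"template must have {GRID} positions")
    budget = max_attempts if max_attempts is not None else spec.max_attempts
    fixed = [0] if spec.require_first_beat else []
    free_positions = np.array([p for p in range(GRID) if p not in fixed])
    probs = template[free_positions]
    probs = probs / probs.sum()
    n_free = spec.n_onsets - len(fixed)
    for _ in range(budget):
        chosen = rng.choice(free_positions, size=n_free, replace=False, p=probs)
        positions = np.sort(np.concatenate([fixed, chosen]).astype(int))
        if _satisfies_constraints(positions, spec):
            return RhythmPattern.from_positions(positions, repeats=spec.repeats)
    raise GenerationError(f"no constraint-satisfying pattern in {budget} attempts")


def _batch_metric(
    patterns: list[RhythmPattern],
    spec: GenerationSpec,
    templates: TemplatePair,
    params: ModelParams,
) -> np.ndarray:
    if spec.metric == "delta_surprisal":
        return delta_surprisal_batch(patterns, templates, params)
    return np.array([syncopation_index(p) for p in patterns], dtype=float)


def generate_set(
    spec: GenerationSpec,
    templates: TemplatePair,
    params: ModelParams | None = None,
    rng: np.random.Generator | int | None = None,
    batch_size: int = 128,
) -> tuple[list[RhythmPattern], pd.DataFrame]:
    """Generate one accepted pattern per target value.

    For each target, candidate patterns are sampled — each from a mixture
    template with a fresh uniform weight — and the first whose metric value
    lies within the buffer of the target is accepted.  Delta surprisal is
    evaluated at ``params`` (defaults: p_switch 0.01, contrast 1.0).
    Unreachable targets are skipped with a warning, and the run continues.

    Returns the accepted patterns and a manifest frame with one row per
    target (id, target, achieved, mixture weight, attempts, reached).
    """
    if not spec.targets:
        raise ValueError("targets must be non-empty")
    params = params or ModelParams()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    accepted: list[RhythmPattern] = []
    manifest_rows = []
    for k, target in enumerate(spec.targets):
        attempts = 0
        found = None
        while attempts < spec.max_attempts and found is None:
            n = min(batch_size, spec.max_attempts - attempts)
            cands, weights = [], []
            for _ in range(n):
                w = rng.uniform()
                cands.append(sample_pattern(mixture_template(w, templates), spec, rng))
                weights.append(w)
            values = _batch_metric(cands, spec, templates, params)
            attempts += n
            hits = np.flatnonzero(np.abs(values - target) <= spec.effective_buffer)
            if hits.size:
                i = int(hits[0])
                attempts -= n - (i + 1)  # only the first hit's attempts count
                found = (cands[i], float(values[i]), weights[i])
        row = {
            "id": f"gen{k:02d}",
            "metric": spec.metric,
            "target": target,
            "reached": found is not None,
            "attempts": attempts,
        }
        if found is None:
            log.warning(
                "target %s=%.4g unreachable within %d attempts",
                spec.metric, target, spec.max_attempts,
            )
            row.update({"achieved": np.nan, "mixture_weight": np.nan})
        else:
            pattern, achieved, weight = found
            pattern = RhythmPattern(
                pattern.onsets, repeats=pattern.repeats, id=row["id"], label=None
            )
            accepted.append(pattern)
            row.update({"achieved": achieved, "mixture_weight": weight})
        manifest_rows.append(row)
    return accepted, pd.DataFrame(manifest_rows)
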