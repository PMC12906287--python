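"""Participant-level QC, normalization, model fitting, and synthetic raters.

Ratings tables hold one row per (participant, stimulus) with a 0-100
slider rating.  Per participant, four parameters are fitted by bounded
local optimization with random restarts: the two model parameters
(``p_switch``, ``contrast``) and a slope/intercept mapping delta surprisal
(in nats) onto the rating scale.  A synthetic-rater simulator generates
ratings as a noisy linear function of delta surprisal for parameter
recovery studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    DEFAULT_LEVEL_PROBS,
    ModelParams,
    build_templates,
    delta_surprisal_batch,
)
from .rhythm import RhythmPattern

log = logging.getLogger(__name__)

RATING_COLUMNS = ["participant_id", "stimulus_id", "rating", "age", "gmsi", "attention_fail"]

#: bounds for the four fitted parameters: p_switch, contrast, slope
#: (rating units per nat of delta surprisal), intercept (rating units)
DEFAULT_BOUNDS = ((0.0, 1.0), (0.0, 1.0), (-2000.0, 2000.0), (0.0, 100.0))


class FitError(RuntimeError):
    """No optimizer restart converged for a participant."""


# ---------------------------------------------------------------------------
# ratings table I/O and QC
# ---------------------------------------------------------------------------

def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read a ratings CSV and validate ranges (ratings within 0-100)."""
    df = pd.read_csv(path)
    missing = {"participant_id", "stimulus_id", "rating"} - set(df.columns)
    if missing:
        raise ValueError(f"ratings file missing columns: {sorted(missing)}")
    if df["rating"].lt(0).any() or df["rating"].gt(100).any():
        raise ValueError("ratings must lie within the 0-100 slider bounds")
    if "attention_fail" not in df.columns:
        df["attention_fail"] = False
    df["participant_id"] = df["participant_id"].astype(str)
    df["stimulus_id"] = df["stimulus_id"].astype(str)
    return df


def write_ratings(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def qc_filter(
    records: pd.DataFrame, variability_floor: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude participants failing the pre-registered quality checks.

    A participant is dropped for (in order of precedence) failing any
    attention check, rating every stimulus 100 or every stimulus 1
    ("extreme-constant"), or showing near-zero rating variability
    (within-participant SD below ``variability_floor`` slider units).

    Returns the retained rows and an exclusion report with one row per
    excluded participant and the triggering reason.
    """
    if records.empty:
        raise ValueError("empty ratings table")
    reasons: dict[str, str] = {}
    for pid, grp in records.groupby("participant_id", sort=False):
        ratings = grp["rating"].to_numpy(dtype=float)
        if "attention_fail" in grp.columns and grp["attention_fail"].any():
            reasons[pid] = "attention-check"
        elif np.all(ratings == 100.0) or np.all(ratings == 1.0):
            reasons[pid] = "extreme-constant"
        else:
            sd = np.std(ratings, ddof=1) if len(ratings) > 1 else 0.0
            if sd < variability_floor:
                reasons[pid] = "low-variability"
    report = pd.DataFrame(
        {"participant_id": list(reasons), "reason": list(reasons.values())}
    )
    kept = records[~records["participant_id"].isin(reasons)].copy()
    return kept, report


def zscore_within(records: pd.DataFrame) -> pd.Series:
    """Z-score ratings within participant (sample-SD convention, ddof=1).

    Provided for rating-scale normalization; the parameter fit itself uses
    raw 0-100 ratings.
    """
    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError("zero within-participant variance; run QC first")
        return (x - x.mean()) / sd

    return records.groupby("participant_id")["rating"].transform(_z)


# ---------------------------------------------------------------------------
# per-participant model fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Best-of-restarts parameter estimate for one participant."""

    participant_id: str
    p_switch: float
    contrast: float
    slope: float
    intercept: float
    rmse: float
    n_restarts: int
    seed: int | None = None


class _DeltaCache:
    """Memoized delta-surprisal vectors over a fixed stimulus list.

    The optimizer perturbs one parameter at a time when estimating
    gradients, so slope/intercept steps re-use the cached model pass.
    """

    def __init__(
        self,
        rhythms: Sequence[RhythmPattern],
        level_probs: Sequence[float],
        initial_prior: float = 0.5,
    ):
        self.rhythms = list(rhythms)
        self.level_probs = tuple(level_probs)
        self.initial_prior = initial_prior
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def __call__(self, p_switch: float, contrast: float) -> np.ndarray:
        key = (float(p_switch), float(contrast))
        if key not in self._cache:
            templates = build_templates(self.level_probs, contrast)
            params = ModelParams(
                p_switch=min(max(p_switch, 0.0), 1.0),
                contrast=contrast,
                initial_prior=self.initial_prior,
            )
            self._cache[key] = delta_surprisal_batch(self.rhythms, templates, params)
        return self._cache[key]


def predict_ratings(
    fit: FitResult,
    rhythms: Sequence[RhythmPattern],
    level_probs: Sequence[float] = DEFAULT_LEVEL_PROBS,
) -> np.ndarray:
    """Predicted ratings ``slope * delta_surprisal + intercept`` per rhythm."""
    delta = _DeltaCache(rhythms, level_probs)(fit.p_switch, fit.contrast)
    return fit.slope * delta + fit.intercept


def fit_participant(
    records: pd.DataFrame,
    rhythms: dict[str, RhythmPattern],
    level_probs: Sequence[float] = DEFAULT_LEVEL_PROBS,
    n_restarts: int = 5,
    rng: np.random.Generator | int | None = None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
) -> FitResult:
    """Fit (p_switch, contrast, slope, intercept) to one participant's ratings.

    Minimizes the RMSE between raw ratings and the linear-in-delta-surprisal
    prediction, using bounded sequential quadratic programming started from
    ``n_restarts`` random points drawn uniformly within the bounds; the
    restart with the lowest achieved RMSE wins.  Deterministic given the rng
    seed and the input table (records are sorted by stimulus id internally).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    missing = set(records["stimulus_id"]) - set(rhythms)
    if missing:
        raise KeyError(f"ratings reference unknown stimuli: {sorted(missing)[:5]}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pid = str(records["participant_id"].iloc[0])
    records = records.sort_values("stimulus_id", kind="stable")
    stim_ids = records["stimulus_id"].tolist()
    ratings = records["rating"].to_numpy(dtype=float)
    stim_list = sorted(set(stim_ids))
    stim_index = {s: i for i, s in enumerate(stim_list)}
    row_of = np.array([stim_index[s] for s in stim_ids])
    delta_of = _DeltaCache([rhythms[s] for s in stim_list], level_probs)
    bounds = tuple(bounds)

    def objective(theta: np.ndarray) -> float:
        p_switch, contrast, slope, intercept = theta
        delta = delta_of(p_switch, contrast)
        pred = slope * delta[row_of] + intercept
        return float(np.sqrt(np.mean((pred - ratings) ** 2)))

    best = None
    failures = []
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(objective, x0, method="SLSQP", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-8})
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts failed for {pid}: {failures}")
    p_switch, contrast, slope, intercept = best.x
    return FitResult(
        participant_id=pid,
        p_switch=float(p_switch),
        contrast=float(contrast),
        slope=float(slope),
        intercept=float(intercept),
        rmse=float(best.fun),
        n_restarts=n_restarts,
    )


def fit_cohort(
    records: pd.DataFrame,
    rhythms: dict[str, RhythmPattern],
    fixture_rhythms: Sequence[RhythmPattern] | None = None,
    level_probs: Sequence[float] = DEFAULT_LEVEL_PROBS,
    n_restarts: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict[str, float], pd.DataFrame]:
    """Fit every participant; report medians and a predicted-delta table.

    Returns ``(fits, medians, predicted_delta)`` where ``fits`` has one row
    per successfully fitted participant, ``medians`` holds the cohort
    median ``p_switch`` and ``contrast``, and ``predicted_delta`` tabulates
    each participant's delta surprisal for ``fixture_rhythms`` (default:
    the nine reference rhythms) at their fitted parameters.  Individual fit
    failures are logged and skipped; the cohort run continues.
    """
    from .rhythm import fixtures as _fixtures

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    fixture_rhythms = list(fixture_rhythms) if fixture_rhythms is not None else _fixtures()
    fit_rows, delta_rows = [], []
    for pid, grp in records.groupby("participant_id", sort=True):
        try:
            fit = fit_participant(
                grp, rhythms, level_probs=level_probs, n_restarts=n_restarts, rng=rng
            )
        except (FitError, KeyError) as exc:
            log.warning("skipping participant %s: %s", pid, exc)
            continue
        fit_rows.append(asdict(fit))
        delta = _DeltaCache(fixture_rhythms, level_probs)(fit.p_switch, fit.contrast)
        delta_rows.append(
            {"participant_id": fit.participant_id}
            | {r.id: d for r, d in zip(fixture_rhythms, delta)}
        )
    if not fit_rows:
        raise FitError("no participant could be fitted")
    fits = pd.DataFrame(fit_rows)
    medians = {
        "p_switch": float(fits["p_switch"].median()),
        "contrast": float(fits["contrast"].median()),
    }
    return fits, medians, pd.DataFrame(delta_rows)


# ---------------------------------------------------------------------------
# synthetic raters
# ---------------------------------------------------------------------------

#: simulation-default rater parameters: model defaults plus a slope and
#: intercept placing ratings comfortably inside the 0-100 slider range
DEFAULT_TRUE_PARAMS = (0.01, 1.0, 400.0, 30.0)

ParamSampler = Callable[[np.random.Generator], tuple[float, float, float, float]]


def simulate_raters(
    n: int,
    rhythms: Sequence[RhythmPattern],
    param_sampler: ParamSampler | tuple[float, float, float, float] = DEFAULT_TRUE_PARAMS,
    noise_sd: float = 5.0,
    level_probs: Sequence[float] = DEFAULT_LEVEL_PROBS,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate a synthetic ratings table for parameter-recovery studies.

    Each simulated participant gets parameters from ``param_sampler`` (a
    callable drawing ``(p_switch, contrast, slope, intercept)`` per
    participant, or a fixed tuple applied to everyone), rates each rhythm
    as ``slope * delta_surprisal + intercept`` plus Gaussian noise of SD
    ``noise_sd`` slider units, clipped to [0, 100].

    The generator emulates ratings driven purely by delta surprisal with
    independent homoscedastic noise; it deliberately omits the sequence,
    fatigue, and anchoring effects of real slider data.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sampler: ParamSampler
    if callable(param_sampler):
        sampler = param_sampler
    else:
        fixed = tuple(param_sampler)
        sampler = lambda _rng: fixed  # noqa: E731
    cache = _DeltaCache(rhythms, level_probs)
    rows = []
    for i in range(n):
        p_switch, contrast, slope, intercept = sampler(rng)
        delta = cache(p_switch, contrast)
        ratings = slope * delta + intercept + rng.normal(0.0, noise_sd, size=len(delta))
        ratings = np.clip(ratings, 0.0, 100.0)
        for r, rating in zip(rhythms, ratings):
            rows.append(
                {
                    "participant_id": f"sim{i:03d}",
                    "stimulus_id": r.id,
                    "rating": float(rating),
                    "age": np.nan,
                    "gmsi": np.nan,
                    "attention_fail": False,
                }
            )
    return pd.DataFrame(rows, columns=RATING_COLUMNS)
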