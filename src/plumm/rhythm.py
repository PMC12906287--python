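"""Rhythm patterns on a 32-step metrical grid.

A rhythm is a binary onset indicator over one 4/4 measure quantized at
32nd-note resolution (32 grid positions), optionally repeated several times
to form the observation stream fed to the inference model.  This module
provides the pattern container, the Longuet-Higgins & Lee (LHL) metric
weight grid, the quarter-note metronome overlay, the summed LHL syncopation
index, and the nine reference stimuli (three per complexity level) used in
the simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

GRID = 32
#: grid positions carrying the quarter-note beat within one measure
QUARTER_POSITIONS = (0, 8, 16, 24)

#: grid positions per metric level (whole, half, quarter, eighth, sixteenth,
#: thirty-second), obtained by recursive binary subdivision of the measure
LEVEL_POSITIONS: tuple[tuple[int, ...], ...] = (
    (0,),
    (16,),
    (8, 24),
    (4, 12, 20, 28),
    tuple(p for p in range(2, GRID, 2) if p % 4 != 0),
    tuple(range(1, GRID, 2)),
)

#: LHL metric weight per level: the longer the note value whose position a
#: grid point marks, the stronger (less negative) its weight
LEVEL_WEIGHTS = (0, -1, -2, -3, -4, -5)

SyncopationRule = Literal["per_rest", "strongest_rest"]


def lhl_weight_grid() -> np.ndarray:
    """Longuet-Higgins & Lee metric weights for the 32-position grid.

    Position 0 (the downbeat / whole-note position) carries the unique
    maximum weight 0; the 16 odd (32nd-note) positions carry the minimum -5.
    """
    weights = np.empty(GRID, dtype=int)
    for level, positions in enumerate(LEVEL_POSITIONS):
        weights[list(positions)] = LEVEL_WEIGHTS[level]
    return weights


@dataclass(frozen=True)
class RhythmPattern:
    """A binary onset pattern over one 32-step measure.

    Parameters
    ----------
    onsets
        Length-32 binary indicator (1 = onset, 0 = rest).
    repeats
        How many times the measure is tiled to build the observation
        stream (default 4, matching a ~10 s presentation at 96 BPM).
    id
        Identifier used in file I/O and result tables.
    label
        Optional complexity tag ("low", "medium", "high").
    """

    onsets: tuple[int, ...]
    repeats: int = 4
    id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.onsets) != GRID:
            raise ValueError(f"pattern must have {GRID} positions, got {len(self.onsets)}")
        if any(o not in (0, 1) for o in self.onsets):
            raise ValueError("onsets must be binary (0/1)")
        if self.repeats < 1:
            raise ValueError("repeats must be a positive integer")

    @property
    def n_onsets(self) -> int:
        return int(sum(self.onsets))

    @property
    def onset_positions(self) -> tuple[int, ...]:
        return tuple(i for i, o in enumerate(self.onsets) if o)

    @classmethod
    def from_positions(
        cls,
        positions: Iterable[int],
        repeats: int = 4,
        id: str = "",
        label: str | None = None,
    ) -> "RhythmPattern":
        onsets = [0] * GRID
        for p in positions:
            if not 0 <= p < GRID:
                raise ValueError(f"onset position {p} outside grid 0..{GRID - 1}")
            onsets[p] = 1
        return cls(tuple(onsets), repeats=repeats, id=id, label=label)

    @classmethod
    def from_string(
        cls, text: str, repeats: int = 4, id: str = "", label: str | None = None
    ) -> "RhythmPattern":
        """Parse an 'x'/'.' string, one character per grid position."""
        if len(text) != GRID:
            raise ValueError(f"pattern string must have {GRID} characters, got {len(text)}")
        if set(text) - {"x", "."}:
            raise ValueError("pattern string may contain only 'x' and '.'")
        return cls(tuple(1 if c == "x" else 0 for c in text), repeats=repeats, id=id, label=label)

    def to_string(self) -> str:
        return "".join("x" if o else "." for o in self.onsets)

    def to_stream(self) -> np.ndarray:
        """Tile the measure ``repeats`` times into a binary observation stream."""
        return to_stream(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.id or 'rhythm'}[{self.to_string()}]x{self.repeats}"


def to_stream(pattern: RhythmPattern) -> np.ndarray:
    """Concatenate ``pattern.repeats`` copies of the measure.

    The returned array has length ``32 * repeats`` and satisfies
    ``stream[t] == onsets[t % 32]``.
    """
    return np.tile(np.asarray(pattern.onsets, dtype=np.int8), pattern.repeats)


def add_metronome(stream: np.ndarray) -> np.ndarray:
    """Overlay quarter-note onsets on an observation stream.

    Forces an onset at every position congruent to 0, 8, 16, 24 (mod 32);
    positions that already carry an onset are unaffected, so the operation
    is idempotent.  The overlay is the model's proxy for the sensory
    feedback of moving along with the beat.
    """
    stream = np.asarray(stream, dtype=np.int8)
    if stream.ndim != 1 or len(stream) % GRID != 0:
        raise ValueError("stream length must be a positive multiple of 32")
    out = stream.copy()
    idx = np.arange(len(out))
    out[np.isin(idx % GRID, QUARTER_POSITIONS)] = 1
    return out


def syncopation_index(
    pattern: RhythmPattern, rule: SyncopationRule = "per_rest"
) -> int:
    """Summed LHL syncopation index of one cyclic measure.

    A syncopation occurs when a note precedes a rest whose metric weight is
    strictly stronger than the note's; its strength is the weight
    difference.  Only rests on eighth-note positions or stronger (weights
    >= -3, i.e. positions divisible by 4) enter the count: a rest on a 16th
    or 32nd position never scores, although notes may sit anywhere.

    The measure is treated as cyclic: rests after the last onset wrap
    around toward position 0.  Two scoring rules are provided:

    - ``per_rest`` (default): every qualifying rest between a note and the
      next note contributes its own weight difference.  This is the
      classical reading in which each strong-position rest marks one
      syncopation, and it is the rule under which the nine reference
      stimuli span indices 0..18.
    - ``strongest_rest``: each note->rest run contributes at most once,
      scored against the strongest qualifying rest in the run.
    """
    positions = pattern.onset_positions
    if not positions:
        raise ValueError("syncopation index undefined for an all-rest pattern")
    weights = lhl_weight_grid()
    total = 0
    n = len(positions)
    for i, p in enumerate(positions):
        q = positions[(i + 1) % n]
        gap = (q - p) % GRID
        rests = [(p + d) % GRID for d in range(1, gap)]
        qualifying = [r for r in rests if weights[r] >= -3 and weights[r] > weights[p]]
        if not qualifying:
            continue
        if rule == "per_rest":
            total += int(sum(weights[r] - weights[p] for r in qualifying))
        elif rule == "strongest_rest":
            total += int(max(weights[r] for r in qualifying) - weights[p])
        else:
            raise ValueError(f"unknown syncopation rule: {rule!r}")
    return total


# The nine reference stimuli: five onsets each, always an onset on the
# downbeat, four repeats.  Low-complexity patterns keep every onset on
# quarter/eighth positions (zero syncopation); medium-complexity patterns
# are clave-type timelines (son, bossa, rumba); high-complexity patterns
# shift every onset but the first onto 32nd-note positions.  Stored as
# editable data rather than code.
_FIXTURE_SPECS: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("low1", "low", (0, 4, 8, 16, 24)),
    ("low2", "low", (0, 8, 12, 16, 24)),
    ("low3", "low", (0, 8, 16, 20, 24)),
    ("med1", "medium", (0, 6, 12, 20, 24)),   # son clave
    ("med2", "medium", (0, 6, 12, 20, 26)),   # bossa clave
    ("med3", "medium", (0, 6, 14, 20, 24)),   # rumba clave
    ("high1", "high", (0, 9, 15, 23, 31)),
    ("high2", "high", (0, 7, 15, 23, 31)),
    ("high3", "high", (0, 3, 15, 19, 31)),
)


def fixtures(repeats: int = 4) -> list[RhythmPattern]:
    """The nine reference rhythms, ordered low -> medium -> high complexity."""
    return [
        RhythmPattern.from_positions(pos, repeats=repeats, id=fid, label=lab)
        for fid, lab, pos in _FIXTURE_SPECS
    ]


# ---------------------------------------------------------------------------
# plain-text rhythm file format: one JSON record per rhythm
# ---------------------------------------------------------------------------

def write_rhythms(patterns: Sequence[RhythmPattern], path: str | Path) -> None:
    """Write rhythms as a JSON list of {id, label, repeats, pattern} records."""
    records = [
        {
            "id": p.id,
            "label": p.label,
            "repeats": p.repeats,
            "pattern": p.to_string(),
        }
        for p in patterns
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_rhythms(path: str | Path) -> list[RhythmPattern]:
    """Read rhythms written by :func:`write_rhythms` (bit-exact round trip)."""
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed rhythm file {path}: {exc}") from exc
    patterns = []
    for i, rec in enumerate(records):
        try:
            patterns.append(
                RhythmPattern.from_string(
                    rec["pattern"],
                    repeats=int(rec.get("repeats", 4)),
                    id=str(rec.get("id", f"r{i}")),
                    label=rec.get("label"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed rhythm record {i} in {path}: {exc}") from exc
    return patterns
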