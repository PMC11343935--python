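"""Reading, validating, relabelling and writing ordinal stress sequences.

A stress sequence is one user's daily self-reported stress, an integer per
calendar day in ``{0,1,2,3,4,5}`` where 0 means *unknown* (no report that day)
and 1..5 run from *no stress at all* to *a great deal of stress*.  Days missing
from the input are gap-filled with 0 so that positional (phase-space) indexing
stays aligned with calendar days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

#: sentinel used for unknown labels after a LabelScheme is applied
UNKNOWN = -1

VALID_LEVELS = frozenset(range(6))


@dataclass(frozen=True)
class StressSequence:
    """One user's daily ordinal stress levels with a missing-day mask.

    Attributes
    ----------
    user_id : str
        Opaque identifier.
    levels : tuple of int
        One level per calendar day, each in {0..5}; 0 marks an unknown day.
    """

    user_id: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = [lv for lv in self.levels if lv not in VALID_LEVELS]
        if bad:
            raise DomainError(
                f"user {self.user_id!r}: stress level(s) {sorted(set(bad))} "
                "outside the domain {0..5}"
            )
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))

    @property
    def n(self) -> int:
        return len(self.levels)

    @property
    def missing_mask(self) -> tuple[bool, ...]:
        """True where the day's level is unknown (stored as 0)."""
        return tuple(lv == 0 for lv in self.levels)

    @property
    def missing_ratio(self) -> float:
        return sum(self.missing_mask) / self.n if self.n else 0.0

    def values(self) -> np.ndarray:
        """Levels as a float array (unknown days literally 0)."""
        return np.asarray(self.levels, dtype=float)

    def prefix(self, n: int) -> "StressSequence":
        return StressSequence(self.user_id, self.levels[:n])

    def with_levels(self, levels: Sequence[int]) -> "StressSequence":
        return StressSequence(self.user_id, tuple(int(v) for v in levels))


def _default_mapping(cuts: tuple[int, ...]) -> Callable[[int], int]:
    def mapping(level: int) -> int:
        return int(sum(level > c for c in cuts))

    return mapping


@dataclass(frozen=True)
class LabelScheme:
    """Maps raw levels 1..5 onto 2 or 3 ordinal classes.

    The defaults place the cut points so that, on data with the class balance
    this package's synthetic benchmark emulates, the two-class split is roughly
    1 (unstressed) : 2 (stressed) and the three-class split roughly
    5 (unstressed) : 10 (weak stressed) : 1 (heavy stressed).

    ``cuts`` are the highest raw level of each class but the last, e.g.
    ``(2,)`` puts {1,2} in class 0 and {3,4,5} in class 1.
    """

    num_class: int
    cuts: tuple[int, ...]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.cuts) != self.num_class - 1:
            raise DomainError("need num_class-1 cut points")
        if list(self.cuts) != sorted(set(self.cuts)):
            raise DomainError("cut points must be strictly increasing")
        if not all(1 <= c <= 4 for c in self.cuts):
            raise DomainError("cut points must lie in 1..4")
        if len(self.class_names) != self.num_class:
            raise DomainError("need one name per class")

    def class_of(self, level: int) -> int:
        """Class index of a raw level in 1..5; unknown (0) maps to UNKNOWN."""
        if level == 0:
            return UNKNOWN
        if level not in VALID_LEVELS:
            raise DomainError(f"level {level} outside domain")
        return int(sum(level > c for c in self.cuts))

    def members(self, cls: int) -> tuple[int, ...]:
        """Raw levels belonging to a class."""
        return tuple(lv for lv in range(1, 6) if self.class_of(lv) == cls)

    def representative_level(self, cls: int) -> int:
        """Midpoint of the class's raw-level set, rounded half-up.

        Used to re-embed a class prediction as a raw level during recursive
        forecasting.
        """
        m = self.members(cls)
        mid = (m[0] + m[-1]) / 2.0
        return int(np.floor(mid + 0.5))


def two_label_scheme() -> LabelScheme:
    return LabelScheme(2, (2,), ("unstressed", "stressed"))


def three_label_scheme() -> LabelScheme:
    return LabelScheme(3, (2, 4), ("unstressed", "weak stressed", "heavy stressed"))


def apply_label_scheme(seq: StressSequence, scheme: LabelScheme) -> np.ndarray:
    """Class index per day; unknown days become the UNKNOWN (-1) sentinel."""
    return np.array([scheme.class_of(lv) for lv in seq.levels], dtype=int)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("user_id", "day_index", "stress_level")


def read_sequences(path: str | Path, format: str | None = None) -> list[StressSequence]:
    """Read per-user sequences from CSV or JSON.

    CSV carries ``user_id,day_index,stress_level`` rows; day indices are
    1-based and gaps are filled with level 0 (unknown).  JSON is a list of
    ``{"user_id": ..., "levels": [...]}`` objects.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ParseError(f"unknown format {fmt!r}")


def _read_json(path: Path) -> list[StressSequence]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for i, rec in enumerate(payload):
        try:
            out.append(StressSequence(str(rec["user_id"]), tuple(rec["levels"])))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: record {i}: {exc}") from exc
    return out


def _read_csv(path: Path) -> list[StressSequence]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("day_index", "stress_level"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: 1-based data rows below the header line
            raise ParseError(f"{path}: line {bad[0] + 2}: non-numeric {col!r}")
        df[col] = coerced.astype(int)
    bad = df.index[~df["stress_level"].isin(range(6))]
    if len(bad):
        raise DomainError(
            f"{path}: line {bad[0] + 2}: stress_level "
            f"{df.loc[bad[0], 'stress_level']} outside the domain 0..5"
        )
    out = []
    for user_id, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("day_index")
        if grp["day_index"].min() < 1:
            raise ParseError(f"{path}: user {user_id}: day_index must be >= 1")
        if grp["day_index"].duplicated().any():
            raise ParseError(f"{path}: user {user_id}: duplicate day_index")
        levels = np.zeros(int(grp["day_index"].max()), dtype=int)
        levels[grp["day_index"].to_numpy() - 1] = grp["stress_level"].to_numpy()
        out.append(StressSequence(str(user_id), tuple(levels)))
    return out


def write_sequences(seqs: Sequence[StressSequence], path: str | Path) -> None:
    """Write sequences in the CSV schema (known days only; gaps encode 0)."""
    rows = [
        (s.user_id, day + 1, lv)
        for s in seqs
        for day, lv in enumerate(s.levels)
    ]
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# forecast results
# ---------------------------------------------------------------------------


@dataclass
class ForecastResult:
    """Per-day class predictions (and probabilities) over an m-day horizon."""

    user_id: str
    classes: list[int]
    probabilities: np.ndarray  # shape (m, num_class)
    levels: list[int] = field(default_factory=list)  # re-embedded raw levels
    method: str = ""

    @property
    def horizon(self) -> int:
        return len(self.classes)


def write_forecast(results: Sequence[ForecastResult], path: str | Path) -> None:
    """Write forecasts as ``user_id,day_offset,predicted_class,prob_*`` CSV."""
    if not results:
        raise ValueError("nothing to write")
    k = results[0].probabilities.shape[1]
    cols = ["user_id", "day_offset", "predicted_class"] + [f"prob_{j}" for j in range(k)]
    rows = []
    for r in results:
        for off, (cls, probs) in enumerate(zip(r.classes, r.probabilities), start=1):
            rows.append([r.user_id, off, int(cls)] + [float(p) for p in probs])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_forecast(path: str | Path) -> list[ForecastResult]:
    df = pd.read_csv(path)
    prob_cols = sorted(
        (c for c in df.columns if c.startswith("prob_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = []
    for user_id, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("day_offset")
        out.append(
            ForecastResult(
                user_id=str(user_id),
                classes=[int(c) for c in grp["predicted_class"]],
                probabilities=grp[prob_cols].to_numpy(dtype=float),
            )
        )
    return out
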