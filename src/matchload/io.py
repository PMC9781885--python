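"""Domain types and readers/writers for the package's tabular dialects.

All CSV files are UTF-8, comma separated, with a header row and ``.`` as
the decimal mark. Game metadata (half boundaries, goals, lineups) travels
as JSON. Readers validate invariants row by row and raise
:class:`ValidationError` naming the offending line; writers round-trip all
fields losslessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: tolerance (s) between duration_s and end_s - start_s, absorbing vendor rounding
DURATION_TOL_S = 0.5

POSITIONS = ("CB", "WB", "MF", "WF", "FW")


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(ValueError):
    """A row violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MpeEvent:
    """One detected metabolic-power event (a short high-intensity phase).

    ``energy_jkg`` is the product of average power and duration; it is
    derived on construction when not supplied.
    """

    game_id: str
    player_id: str
    start_s: float
    end_s: float
    duration_s: float
    max_speed_kmh: float
    avg_power_wkg: float
    energy_jkg: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValidationError(
                f"MpeEvent {self.game_id}/{self.player_id}: end_s {self.end_s} <= start_s {self.start_s}"
            )
        if self.start_s < 0:
            raise ValidationError(f"MpeEvent {self.game_id}/{self.player_id}: negative start_s")
        if abs(self.duration_s - (self.end_s - self.start_s)) > DURATION_TOL_S:
            raise ValidationError(
                f"MpeEvent {self.game_id}/{self.player_id}: duration_s {self.duration_s} "
                f"inconsistent with end-start {self.end_s - self.start_s}"
            )
        if self.avg_power_wkg < 0:
            raise ValidationError(f"MpeEvent {self.game_id}/{self.player_id}: negative avg_power_wkg")
        if self.energy_jkg is None or (isinstance(self.energy_jkg, float) and math.isnan(self.energy_jkg)):
            object.__setattr__(self, "energy_jkg", self.avg_power_wkg * self.duration_s)


@dataclass(frozen=True)
class FiveMinWindow:
    """Provider aggregate for one player over one fixed 5-minute window."""

    game_id: str
    player_id: str
    window_start_s: float
    time_played_s: float
    distance_m: float
    mpe_count: float
    anaerobic_energy_jkg: float
    avg_metabolic_power_wkg: float
    avg_mpe_time_s: float
    avg_mpe_recovery_time_s: float
    avg_mpe_recovery_power_wkg: float
    walk_distance_m: float
    running_distance_m: float
    walk_energy_jkg: float
    running_energy_jkg: float
    general_energy_jkg: float

    #: slack (J/kg) allowed in general >= walk + running energy
    _ENERGY_TOL = 1e-6

    def __post_init__(self) -> None:
        key = f"FiveMinWindow {self.game_id}/{self.player_id}@{self.window_start_s}"
        if self.window_start_s % 300 != 0:
            raise ValidationError(f"{key}: window_start_s not a multiple of 300")
        for name in (
            "window_start_s",
            "time_played_s",
            "distance_m",
            "mpe_count",
            "anaerobic_energy_jkg",
            "avg_metabolic_power_wkg",
            "avg_mpe_time_s",
            "avg_mpe_recovery_time_s",
            "avg_mpe_recovery_power_wkg",
            "walk_distance_m",
            "running_distance_m",
            "walk_energy_jkg",
            "running_energy_jkg",
            "general_energy_jkg",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{key}: negative {name}")
        if self.walk_distance_m + self.running_distance_m > self.distance_m + 1e-6:
            raise ValidationError(f"{key}: walk + running distance exceeds total distance")
        if self.general_energy_jkg < self.walk_energy_jkg + self.running_energy_jkg - self._ENERGY_TOL:
            raise ValidationError(f"{key}: general energy below walk + running energy")


@dataclass(frozen=True)
class PlayerStint:
    """A player's on-pitch interval and position within one game."""

    position: str
    on_s: float
    off_s: float

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValidationError(f"unknown position {self.position!r}; expected one of {POSITIONS}")
        if self.off_s <= self.on_s:
            raise ValidationError(f"stint off_s {self.off_s} <= on_s {self.on_s}")


@dataclass(frozen=True)
class GameMeta:
    """Game-level metadata: half boundaries, goals and lineup.

    Time is seconds since first-half kickoff and runs continuously through
    halftime; minutes inside the halftime gap are simply not played.
    """

    game_id: str
    kickoff_utc: str
    half1_end_s: float
    half2_start_s: float
    game_end_s: float
    goals: tuple = field(default_factory=tuple)  # of (minute:int, "for"|"against")
    lineups: dict = field(default_factory=dict)  # player_id -> PlayerStint

    def __post_init__(self) -> None:
        if not (0 < self.half1_end_s < self.half2_start_s < self.game_end_s):
            raise ValidationError(
                f"GameMeta {self.game_id}: half boundaries must satisfy 0 < half1_end < half2_start < game_end"
            )
        for minute, side in self.goals:
            if side not in ("for", "against"):
                raise ValidationError(f"GameMeta {self.game_id}: goal side {side!r} invalid")
            if not 0 <= minute < self.game_end_s / 60:
                raise ValidationError(f"GameMeta {self.game_id}: goal minute {minute} outside play")

    def played_intervals(self, player_id: str) -> list:
        """Seconds actually played by ``player_id``: stint clipped to the two halves."""
        stint = self.lineups[player_id]
        out = []
        for lo, hi in ((0.0, self.half1_end_s), (self.half2_start_s, self.game_end_s)):
            a, b = max(lo, stint.on_s), min(hi, stint.off_s)
            if b > a:
                out.append((a, b))
        return out

    def n_minutes(self) -> int:
        return int(math.ceil(self.game_end_s / 60.0))


@dataclass(frozen=True)
class GameTotals:
    """Whole-game speed-band distances for one player (the conventional view)."""

    game_id: str
    player_id: str
    total_distance_m: float
    walk_distance_m: float
    run_below20_m: float
    above20_m: float

    def __post_init__(self) -> None:
        key = f"GameTotals {self.game_id}/{self.player_id}"
        for name in ("total_distance_m", "walk_distance_m", "run_below20_m", "above20_m"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{key}: negative {name}")
        if self.walk_distance_m + self.run_below20_m + self.above20_m > self.total_distance_m + 1e-6:
            raise ValidationError(f"{key}: band distances exceed total distance")


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

_MPE_COLUMNS = ["game_id", "player_id", "start_s", "end_s", "duration_s", "max_speed_kmh", "avg_power_wkg"]
_GM5_COLUMNS = [f.name for f in dc_fields(FiveMinWindow)]
_TOTALS_COLUMNS = [f.name for f in dc_fields(GameTotals)]


def _read_csv(path, required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"game_id": str, "player_id": str}, float_precision="round_trip")
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _build_rows(df: pd.DataFrame, cls, path, extra_cols: Sequence[str] = ()):
    rows = []
    names = [f.name for f in dc_fields(cls)]
    for i, rec in enumerate(df.itertuples(index=False)):
        kwargs = {n: getattr(rec, n) for n in names if hasattr(rec, n)}
        try:
            rows.append(cls(**kwargs))
        except (ValidationError, TypeError, ValueError) as exc:
            # +2: header line plus 1-based numbering
            raise ValidationError(f"{path}, line {i + 2}: {exc}") from exc
    return rows


def read_mpe(path) -> list:
    """Read an MPE event stream; ``energy_jkg`` is computed when absent."""
    df = _read_csv(path, _MPE_COLUMNS)
    if "energy_jkg" not in df.columns:
        df["energy_jkg"] = float("nan")
    events = _build_rows(df, MpeEvent, path)
    events.sort(key=lambda e: (e.game_id, e.player_id, e.start_s))
    return events


def write_mpe(events: Iterable[MpeEvent], path) -> None:
    df = pd.DataFrame([vars(e) if not hasattr(e, "__dataclass_fields__") else e.__dict__ for e in events],
                      columns=_MPE_COLUMNS + ["energy_jkg"])
    df.to_csv(path, index=False)


def read_five_min(path) -> list:
    """Read GM-5MIN aggregates, validating 300 s window alignment."""
    df = _read_csv(path, _GM5_COLUMNS)
    windows = _build_rows(df, FiveMinWindow, path)
    windows.sort(key=lambda w: (w.game_id, w.player_id, w.window_start_s))
    return windows


def write_five_min(windows: Iterable[FiveMinWindow], path) -> None:
    df = pd.DataFrame([w.__dict__ for w in windows], columns=_GM5_COLUMNS)
    df.to_csv(path, index=False)


def read_game_totals(path) -> list:
    df = _read_csv(path, _TOTALS_COLUMNS)
    totals = _build_rows(df, GameTotals, path)
    totals.sort(key=lambda t: (t.game_id, t.player_id))
    return totals


def write_game_totals(totals: Iterable[GameTotals], path) -> None:
    df = pd.DataFrame([t.__dict__ for t in totals], columns=_TOTALS_COLUMNS)
    df.to_csv(path, index=False)


def read_game_meta(path) -> list:
    """Read game metadata JSON: a list of games (or a single game object)."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    metas = []
    for obj in payload:
        lineups = {
            pid: PlayerStint(position=st["position"], on_s=st["on_s"], off_s=st["off_s"])
            for pid, st in obj.get("lineups", {}).items()
        }
        goals = tuple((int(m), s) for m, s in obj.get("goals", []))
        metas.append(
            GameMeta(
                game_id=obj["game_id"],
                kickoff_utc=obj["kickoff_utc"],
                half1_end_s=obj["half1_end_s"],
                half2_start_s=obj["half2_start_s"],
                game_end_s=obj["game_end_s"],
                goals=goals,
                lineups=lineups,
            )
        )
    return metas


def write_game_meta(metas: Iterable[GameMeta], path) -> None:
    payload = []
    for m in metas:
        payload.append(
            {
                "game_id": m.game_id,
                "kickoff_utc": m.kickoff_utc,
                "half1_end_s": m.half1_end_s,
                "half2_start_s": m.half2_start_s,
                "game_end_s": m.game_end_s,
                "goals": [[minute, side] for minute, side in m.goals],
                "lineups": {
                    pid: {"position": st.position, "on_s": st.on_s, "off_s": st.off_s}
                    for pid, st in m.lineups.items()
                },
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False), encoding="utf-8")


def write_minute_features(table: pd.DataFrame, path) -> None:
    """Write a per-minute feature table (column order preserved)."""
    table.to_csv(path, index=False)


def read_minute_features(path) -> pd.DataFrame:
    from matchload.features import FEATURE_ORDER  # cycle-safe late import

    required = ["game_id", "player_id", "minute", *FEATURE_ORDER, "excluded"]
    df = _read_csv(path, required)
    df["excluded"] = df["excluded"].astype(bool)
    return df
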