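"""Game-load analytics on top of intensity assignments.

Covers per-player minute timelines with goal annotations, pooled 5-minute
interval distributions, per-game zone fractions vs the conventional
whole-game speed-band proxies, and the coefficient-of-variation report
that quantifies between-game variability of both descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from matchload.cluster import LABELS, UNCLASSIFIED
from matchload.io import GameMeta, GameTotals

#: proxy mapping: high ~ distance above 20 km/h, middle ~ running below
#: 20 km/h (walking excluded), low ~ walking distance
PROXY_FIELDS = {"high": "above20_m", "middle": "run_below20_m", "low": "walk_distance_m"}


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class GameLoadSummary:
    """Per-game zone fractions from clustering and from speed-band proxies."""

    game_id: str
    cluster_fractions: dict  # label -> fraction of classified minutes
    proxy_fractions: dict  # label -> share of summed team distance
    n_classified: int


@dataclass(frozen=True)
class CvReport:
    """Coefficient of variation (percent) per zone and method over games."""

    cv_percent: dict  # (method, label) -> CV% or None when mean == 0
    n_games: int


@dataclass(frozen=True)
class Timeline:
    """One player's minute-by-minute labels with goal annotations."""

    game_id: str
    player_id: str
    minutes: list
    labels: list
    goals: list  # (minute, side) within the played span
    halftime_minutes: tuple  # (first, last+1) halftime minute range


def timeline(assignments: pd.DataFrame, meta: GameMeta, player_id: str) -> Timeline:
    """Ordered label sequence for one player in one game."""
    if player_id not in meta.lineups:
        raise AnalysisError(f"player {player_id!r} did not play in game {meta.game_id}")
    sub = assignments[
        (assignments["game_id"] == meta.game_id) & (assignments["player_id"] == player_id)
    ].sort_values("minute")
    ht = (int(meta.half1_end_s // 60), int(np.ceil(meta.half2_start_s / 60)))
    played = sub[(sub["minute"] < ht[0]) | (sub["minute"] >= ht[1])]
    minutes = played["minute"].astype(int).tolist()
    return Timeline(
        game_id=meta.game_id,
        player_id=player_id,
        minutes=minutes,
        labels=played["label"].tolist(),
        goals=[(m, s) for m, s in meta.goals if m in set(minutes) or m < (minutes[-1] if minutes else 0)],
        halftime_minutes=ht,
    )


def interval_distribution(assignments: pd.DataFrame, bin_min: int = 5) -> pd.DataFrame:
    """Counts of each zone per game-time bin, pooled over players and games.

    Returns one row per bin with columns ``bin_start_min``, the three zone
    labels, and ``unclassified``.
    """
    if assignments.empty:
        raise AnalysisError("interval_distribution: empty assignments")
    df = assignments.copy()
    df["bin_start_min"] = (df["minute"] // bin_min) * bin_min
    counts = (
        df.groupby(["bin_start_min", "label"]).size().unstack(fill_value=0).reset_index()
    )
    for lbl in (*LABELS, UNCLASSIFIED):
        if lbl not in counts.columns:
            counts[lbl] = 0
    return counts[["bin_start_min", *LABELS, UNCLASSIFIED]].sort_values("bin_start_min").reset_index(drop=True)


def summarize_game(assignments: pd.DataFrame, totals: list, game_id: str) -> GameLoadSummary:
    """Zone fractions of classified team minutes vs pooled speed-band shares."""
    sub = assignments[(assignments["game_id"] == game_id) & (assignments["label"] != UNCLASSIFIED)]
    if sub.empty:
        raise AnalysisError(f"no classified minutes for game {game_id}")
    n = len(sub)
    cluster_fractions = {lbl: float((sub["label"] == lbl).sum()) / n for lbl in LABELS}

    game_totals = [t for t in totals if t.game_id == game_id]
    if not game_totals:
        raise AnalysisError(f"no GameTotals for game {game_id}")
    sums = {lbl: sum(getattr(t, fieldname) for t in game_totals) for lbl, fieldname in PROXY_FIELDS.items()}
    denom = sum(sums.values())
    if denom <= 0:
        raise AnalysisError(f"zero total band distance for game {game_id}")
    proxy_fractions = {lbl: v / denom for lbl, v in sums.items()}
    return GameLoadSummary(
        game_id=game_id,
        cluster_fractions=cluster_fractions,
        proxy_fractions=proxy_fractions,
        n_classified=n,
    )


def cv_report(summaries: list) -> CvReport:
    """Population CV (100*sigma/mu) per zone and method across games."""
    if len(summaries) < 2:
        raise AnalysisError("cv_report needs at least 2 games")
    cv = {}
    for method, attr in (("cluster", "cluster_fractions"), ("proxy", "proxy_fractions")):
        for lbl in LABELS:
            vals = np.array([getattr(s, attr)[lbl] for s in summaries], dtype=float)
            mu = vals.mean()
            cv[(method, lbl)] = None if mu == 0 else float(100.0 * vals.std() / mu)
    return CvReport(cv_percent=cv, n_games=len(summaries))


def report_dict(summaries: list, report: CvReport) -> dict:
    """JSON-ready view of per-game summaries plus the CV comparison."""
    return {
        "games": [
            {
                "game_id": s.game_id,
                "cluster_fractions": s.cluster_fractions,
                "proxy_fractions": s.proxy_fractions,
                "n_classified": s.n_classified,
            }
            for s in summaries
        ],
        "cv_percent": {f"{method}_{lbl}": v for (method, lbl), v in report.cv_percent.items()},
        "n_games": report.n_games,
    }


def plot_timeline(tl: Timeline, path) -> None:
    """Render a timeline as a colored minute strip (PNG or any mpl format)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"high": "#a63603", "middle": "#fd8d3c", "low": "#3182bd", UNCLASSIFIED: "#dddddd"}
    fig, ax = plt.subplots(figsize=(12, 1.8))
    for m, lbl in zip(tl.minutes, tl.labels):
        ax.axvspan(m, m + 1, color=colors.get(lbl, "#dddddd"))
    for m, side in tl.goals:
        ax.axvline(m + 0.5, color="green" if side == "for" else "red", ls="--", lw=1.2)
    ax.axvspan(*tl.halftime_minutes, color="white")
    ax.set_xlim(0, max(tl.minutes) + 1 if tl.minutes else 1)
    ax.set_yticks([])
    ax.set_xlabel("minute")
    ax.set_title(f"{tl.game_id} / {tl.player_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
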