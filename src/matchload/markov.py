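"""Markov-chain analysis of intensity-state sequences.

Transition matrices are estimated from consecutive classified minutes
(chains break across halftime, substitutions, unclassified minutes and
game boundaries), smoothed, and condensed into a bounded per-player
fitness score that tracks the propensity to reach and sustain the
high-intensity state across training cycles.

The fitness score here is a documented proxy: the stationary probability
of the high state plus half the middle-to-high transition probability,
clipped to [0, 1]. It is isolated behind :func:`mfit_index` (accepting a
custom ``score_fn``) so an alternative definition can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from matchload.cluster import LABELS, UNCLASSIFIED

STATE_INDEX = {lbl: i for i, lbl in enumerate(LABELS)}  # low=0, middle=1, high=2


class MarkovError(ValueError):
    pass


class ReducibleChainError(MarkovError):
    """The chain has an unreachable/absorbing class; no unique stationary law."""


@dataclass(frozen=True)
class TransitionModel:
    player_id: str
    window: str
    counts: np.ndarray  # 3x3 raw transition counts
    probs: np.ndarray  # 3x3 row-stochastic, smoothed
    n_transitions: int
    alpha: float


@dataclass(frozen=True)
class MFitPoint:
    player_id: str
    window: str
    mfit: float


def _chains(assignments: pd.DataFrame, player_id: str):
    """Maximal runs of consecutive classified minutes for one player."""
    sub = assignments[assignments["player_id"] == player_id]
    for _, game in sub.groupby("game_id", sort=True):
        game = game.sort_values("minute")
        run = []
        prev_minute = None
        for minute, label in zip(game["minute"].astype(int), game["label"]):
            # anything that is not a proper intensity state breaks the chain
            known = label in STATE_INDEX
            broken = not known or (prev_minute is not None and minute != prev_minute + 1)
            if broken:
                if len(run) >= 2:
                    yield run
                run = []
            if known:
                run.append(label)
            prev_minute = minute
        if len(run) >= 2:
            yield run


def fit_transitions(
    assignments: pd.DataFrame, player_id: str, alpha: float = 0.5, window: str = "all"
) -> TransitionModel:
    """Count transitions between temporally adjacent classified minutes and
    Laplace-smooth each row into a stochastic matrix."""
    counts = np.zeros((3, 3), dtype=float)
    for run in _chains(assignments, player_id):
        idx = [STATE_INDEX[lbl] for lbl in run]
        for a, b in zip(idx[:-1], idx[1:]):
            counts[a, b] += 1
    n = int(counts.sum())
    if n == 0:
        raise MarkovError(f"no valid transitions for player {player_id!r}")
    smoothed = counts + alpha
    row_sums = smoothed.sum(axis=1, keepdims=True)
    # a state never observed (possible at alpha=0) gets a uniform row
    probs = np.where(row_sums > 0, smoothed / np.where(row_sums == 0, 1, row_sums), 1.0 / 3.0)
    return TransitionModel(
        player_id=player_id, window=window, counts=counts, probs=probs, n_transitions=n, alpha=alpha
    )


def _communicating(P: np.ndarray) -> bool:
    """Irreducibility via reachability on the positive-entry digraph."""
    n = P.shape[0]
    adj = P > 0
    reach = np.eye(n, dtype=bool) | adj
    for _ in range(n):
        reach = reach | ((reach.astype(int) @ reach.astype(int)) > 0)
    return bool(reach.all())


def stationary_distribution(probs: np.ndarray) -> np.ndarray:
    """Left eigenvector of a row-stochastic matrix for eigenvalue 1."""
    P = np.asarray(probs, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise MarkovError("rows must sum to 1")
    if not _communicating(P):
        closed = [LABELS[i] for i in range(3) if P[i].max() == P[i, i]]
        raise ReducibleChainError(f"chain is reducible (closed class near {closed or 'unknown'})")
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def default_score(probs: np.ndarray) -> float:
    """Proxy fitness score: pi_high + 0.5 * P(middle -> high), clipped to [0, 1]."""
    pi = stationary_distribution(probs)
    hi = STATE_INDEX["high"]
    mid = STATE_INDEX["middle"]
    return float(np.clip(pi[hi] + 0.5 * probs[mid, hi], 0.0, 1.0))


def mfit_index(model: TransitionModel, score_fn=default_score) -> MFitPoint:
    """Condense a transition model into a bounded fitness score.

    On a reducible chain the score falls back to the observed fraction of
    transitions that *enter* the high state.
    """
    try:
        score = score_fn(model.probs)
    except ReducibleChainError:
        warnings.warn(f"player {model.player_id}: reducible chain, using count-based fallback")
        hi = STATE_INDEX["high"]
        score = float(model.counts[:, hi].sum() / model.counts.sum())
    return MFitPoint(player_id=model.player_id, window=model.window, mfit=score)


def track(
    assignments: pd.DataFrame, windows: dict, alpha: float = 0.5, score_fn=default_score
) -> list:
    """One fitness point per (player, window).

    ``windows`` maps a window id to the list of game_ids it contains;
    windows are processed in sorted order so the series is chronological
    when ids sort chronologically.
    """
    points = []
    for window_id in sorted(windows):
        game_ids = set(windows[window_id])
        sub = assignments[assignments["game_id"].isin(game_ids)]
        for player_id in sorted(sub["player_id"].unique()):
            try:
                model = fit_transitions(sub, player_id, alpha=alpha, window=str(window_id))
            except MarkovError:
                continue
            points.append(mfit_index(model, score_fn=score_fn))
    return points
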