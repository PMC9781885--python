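"""Build the 25-feature per-minute table from event and 5-minute streams.

Each player-minute record merges three views of the data:

* ``GM-5MIN-PRIOR`` — provider aggregates over the 5 minutes preceding the
  minute (time-weighted across the <=2 fixed provider windows they straddle),
  plus cumulative totals since kickoff;
* ``MPE-PRIOR`` — event-derived work/recovery over the preceding 3 and 5
  minutes;
* ``MPE-CURRENT`` — event-derived work/recovery inside the minute itself.

Minutes are half-open ``[60*m, 60*(m+1))``; an event belongs to the minute
containing its start, while its *work* seconds are attributed by overlap.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from matchload.io import FiveMinWindow, GameMeta, MpeEvent, ValidationError

logger = logging.getLogger(__name__)

#: the 25 clustering features, in canonical column order
FEATURE_ORDER = [
    # GM-5MIN-PRIOR (12)
    "distance_m",
    "mpe_count",
    "anaerobic_energy_jkg",
    "avg_metabolic_power_wkg",
    "avg_mpe_time_s",
    "avg_mpe_recovery_time_s",
    "avg_mpe_recovery_power_wkg",
    "walk_energy_jkg",
    "running_energy_jkg",
    "general_energy_jkg",
    "total_mpe_count",
    "total_energy_jkg",
    # MPE-PRIOR (9)
    "mpe_energy_3min",
    "mpe_energy_5min",
    "mpe_count_3min",
    "mpe_count_5min",
    "recovery_time_3min",
    "recovery_time_5min",
    "avg_recovery_time_3min",
    "avg_recovery_time_5min",
    "total_recovery_time_s",
    # MPE-CURRENT (4)
    "mpe_energy_jkg",
    "event_count",
    "avg_recovery_time_s",
    "recovery_time_s",
]

_GM5_EXTENSIVE = {
    "distance_m": "distance_m",
    "mpe_count": "mpe_count",
    "anaerobic_energy_jkg": "anaerobic_energy_jkg",
    "walk_energy_jkg": "walk_energy_jkg",
    "running_energy_jkg": "running_energy_jkg",
    "general_energy_jkg": "general_energy_jkg",
}
_GM5_INTENSIVE = {
    "avg_metabolic_power_wkg": "avg_metabolic_power_wkg",
    "avg_mpe_time_s": "avg_mpe_time_s",
    "avg_mpe_recovery_time_s": "avg_mpe_recovery_time_s",
    "avg_mpe_recovery_power_wkg": "avg_mpe_recovery_power_wkg",
}


def mpe_energy(avg_power_wkg: float, duration_s: float) -> float:
    """Energy of one event (J/kg): average power times duration."""
    if avg_power_wkg < 0 or duration_s < 0:
        raise ValidationError("mpe_energy requires nonnegative power and duration")
    return avg_power_wkg * duration_s


def avg_recovery_time(recovery_s: float, n_events: int) -> float:
    """Average recovery time: total recovery divided by (event count + 1).

    With N events in a window there are N+1 recovery stretches, so a window
    with zero events returns the full recovery time unchanged.
    """
    if recovery_s < 0 or n_events < 0:
        raise ValidationError("avg_recovery_time requires nonnegative inputs")
    return recovery_s / (n_events + 1)


def _overlap(a: float, b: float, lo: float, hi: float) -> float:
    return max(0.0, min(b, hi) - max(a, lo))


def window_recovery(
    events: Sequence, win_start_s: float, win_len_s: float, played_s: float
) -> tuple:
    """Recovery seconds and event count for a time window.

    ``events`` may be :class:`MpeEvent` objects or ``(start_s, end_s)``
    pairs. Events are *counted* at their start; their *work* contributes
    only the seconds overlapping the window. Recovery is the played time
    (capped at the window length) minus work, floored at zero.
    """
    win_end = win_start_s + win_len_s
    n = 0
    work = 0.0
    for ev in events:
        start, end = (ev.start_s, ev.end_s) if isinstance(ev, MpeEvent) else (ev[0], ev[1])
        if win_start_s <= start < win_end:
            n += 1
        work += _overlap(start, end, win_start_s, win_end)
    recovery = max(0.0, min(played_s, win_len_s) - work)
    return recovery, n


def _window_energy(events: Sequence[MpeEvent], win_start_s: float, win_end_s: float) -> float:
    """Event energy attributed to a window, proportional to time overlap."""
    total = 0.0
    for ev in events:
        ov = _overlap(ev.start_s, ev.end_s, win_start_s, win_end_s)
        if ov > 0:
            total += ev.avg_power_wkg * ov
    return total


def _gm5_prior(windows: dict, lo: float, hi: float) -> tuple:
    """Time-weighted GM-5MIN reconstruction over [lo, hi).

    Returns (field dict, covered seconds). Extensive fields are fractional
    sums, intensive fields overlap-weighted averages.
    """
    out = {k: 0.0 for k in list(_GM5_EXTENSIVE) + list(_GM5_INTENSIVE)}
    covered = 0.0
    weight = 0.0
    acc_int = {k: 0.0 for k in _GM5_INTENSIVE}
    first = int(np.floor(lo / 300.0)) * 300
    for ws in range(first, int(hi) + 1, 300):
        w = windows.get(float(ws))
        if w is None:
            continue
        ov = _overlap(ws, ws + 300.0, lo, hi)
        if ov <= 0:
            continue
        covered += ov
        frac = ov / 300.0
        for feat, src in _GM5_EXTENSIVE.items():
            out[feat] += getattr(w, src) * frac
        for feat, src in _GM5_INTENSIVE.items():
            acc_int[feat] += getattr(w, src) * ov
        weight += ov
    if weight > 0:
        for feat in _GM5_INTENSIVE:
            out[feat] = acc_int[feat] / weight
    return out, covered


def build_minute_table(
    events: Iterable[MpeEvent],
    windows: Iterable[FiveMinWindow],
    meta,
    prior_coverage_tol_s: float = 1.0,
) -> pd.DataFrame:
    """Merge the three streams into one record per player-minute.

    ``meta`` is a :class:`GameMeta` or a list of them. A record is emitted
    for every minute a player is in the game (halftime minutes included,
    flagged unplayed). ``excluded`` is set for minutes not fully played or
    lacking full GM-5MIN coverage of the preceding 5 minutes.
    """
    metas = meta if isinstance(meta, (list, tuple)) else [meta]
    ev_by_key: dict = {}
    for ev in events:
        ev_by_key.setdefault((ev.game_id, ev.player_id), []).append(ev)
    for lst in ev_by_key.values():
        lst.sort(key=lambda e: e.start_s)
    win_by_key: dict = {}
    for w in windows:
        win_by_key.setdefault((w.game_id, w.player_id), {})[float(w.window_start_s)] = w

    records = []
    for gm in metas:
        for player_id, stint in sorted(gm.lineups.items()):
            key = (gm.game_id, player_id)
            p_events = ev_by_key.get(key, [])
            p_windows = win_by_key.get(key, {})
            played = gm.played_intervals(player_id)
            ev_starts = np.array([e.start_s for e in p_events]) if p_events else np.empty(0)

            total_recovery = 0.0
            n_uncovered = 0
            for m in range(gm.n_minutes()):
                m_lo, m_hi = 60.0 * m, 60.0 * (m + 1)
                if _overlap(stint.on_s, stint.off_s, m_lo, m_hi) <= 0:
                    continue
                played_s = sum(_overlap(a, b, m_lo, m_hi) for a, b in played)

                # current minute
                cur_rec, cur_n = window_recovery(p_events, m_lo, 60.0, played_s)
                cur_energy = _window_energy(p_events, m_lo, m_hi)
                total_recovery += cur_rec

                rec = {
                    "game_id": gm.game_id,
                    "player_id": player_id,
                    "minute": m,
                    "played_s": played_s,
                }

                # event-derived prior windows (3 and 5 min)
                for span, tag in ((3, "3min"), (5, "5min")):
                    w_lo = m_lo - 60.0 * span
                    played_in = sum(_overlap(a, b, max(0.0, w_lo), m_lo) for a, b in played)
                    r, n = window_recovery(p_events, w_lo, 60.0 * span, played_in)
                    rec[f"mpe_energy_{tag}"] = _window_energy(p_events, w_lo, m_lo)
                    rec[f"mpe_count_{tag}"] = n
                    rec[f"recovery_time_{tag}"] = r
                    rec[f"avg_recovery_time_{tag}"] = avg_recovery_time(r, n)

                # provider aggregates over the preceding 5 minutes; a minute
                # only has full context when those 5 minutes were both
                # reported by the provider and actually played (rules out
                # the first 5 minutes of each half)
                gm5, covered = _gm5_prior(p_windows, m_lo - 300.0, m_lo)
                rec.update(gm5)
                played_cov = sum(_overlap(a, b, m_lo - 300.0, m_lo) for a, b in played)
                coverage_ok = min(covered, played_cov) >= 300.0 - prior_coverage_tol_s
                if not coverage_ok:
                    n_uncovered += 1

                # cumulative (kickoff through the end of the current minute)
                rec["total_mpe_count"] = int((ev_starts < m_hi).sum()) if ev_starts.size else 0
                cum, _ = _gm5_prior(p_windows, 0.0, m_hi)
                rec["total_energy_jkg"] = cum["general_energy_jkg"]
                rec["total_recovery_time_s"] = total_recovery

                rec["mpe_energy_jkg"] = cur_energy
                rec["event_count"] = cur_n
                rec["recovery_time_s"] = cur_rec
                rec["avg_recovery_time_s"] = avg_recovery_time(cur_rec, cur_n)

                rec["excluded"] = (played_s < 60.0 - 1e-6) or not coverage_ok
                records.append(rec)
            if n_uncovered:
                logger.warning(
                    "%s/%s: %d minute(s) lacked full 5-min prior coverage and were excluded",
                    gm.game_id,
                    player_id,
                    n_uncovered,
                )

    cols = ["game_id", "player_id", "minute", "played_s", *FEATURE_ORDER, "excluded"]
    df = pd.DataFrame.from_records(records, columns=cols)
    return df.sort_values(["game_id", "player_id", "minute"], kind="stable").reset_index(drop=True)


def apply_ceiling(table: pd.DataFrame, quantile: float = 0.995) -> pd.DataFrame:
    """Clip each feature at its corpus-level upper quantile (denoising).

    Idempotent; non-feature columns and flags pass through untouched.
    """
    if table.empty:
        raise ValidationError("apply_ceiling: empty table")
    if not 0 < quantile <= 1:
        raise ValidationError(f"apply_ceiling: quantile {quantile} outside (0, 1]")
    out = table.copy()
    for col in FEATURE_ORDER:
        # 'lower' picks an order statistic, which makes the clip idempotent
        cap = float(np.quantile(out[col].to_numpy(dtype=float), quantile, method="lower"))
        out[col] = out[col].clip(upper=cap)
    return out
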