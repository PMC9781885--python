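"""Synthetic match corpus generator with known hidden intensity regimes.

Each player-minute is governed by a 3-state first-order Markov regime
(0 = low, 1 = middle, 2 = high). Regimes drive the rate of short
high-intensity events (a per-minute Poisson count with truncated
log-normal durations), the background (non-event) energy flow, and the
speed-band split of the distance covered. Provider-style 5-minute windows
and whole-game totals are aggregated *exactly* from the simulated minute
stream, so every downstream computation has a ground truth to recover.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from matchload import features as F
from matchload.io import (
    FiveMinWindow,
    GameMeta,
    GameTotals,
    MpeEvent,
    PlayerStint,
    ValidationError,
    write_five_min,
    write_game_meta,
    write_game_totals,
    write_mpe,
)

REGIMES = (0, 1, 2)
_DURATION_CAP_S = 20.0  # events are short; longer ones are not observed


class ConfigError(ValueError):
    """Simulator configuration is invalid."""


@dataclass(frozen=True)
class RegimeParams:
    """Per-regime generating parameters for one hidden intensity state."""

    mpe_rate_per_min: float
    power_mean_wkg: float
    power_sd_wkg: float
    background_power_wkg: float
    distance_per_min_m: float
    walk_share: float
    run_share: float
    hsr_share: float


@dataclass(frozen=True)
class SimConfig:
    """Corpus-level simulator configuration.

    ``duration_median_s`` / ``duration_mean_s`` calibrate the truncated
    log-normal event-duration distribution; ``mpe_energy_share_target``
    sets the expected fraction of total energy spent inside events;
    ``game_mix_concentration`` controls how strongly the regime mix varies
    between games (smaller = stronger variation).
    """

    n_games: int = 20
    players_per_game: int = 14
    regime_transition: tuple = (
        (0.970, 0.020, 0.010),
        (0.015, 0.970, 0.015),
        (0.010, 0.020, 0.970),
    )
    # background power proportional to each regime's event-energy rate keeps
    # the event-energy share near its target for any realized regime mix
    regime_params: tuple = (
        RegimeParams(0.05, 6.0, 1.0, 0.076, 45.0, 0.38, 0.52, 0.10),
        RegimeParams(3.20, 11.0, 1.0, 8.898, 105.0, 0.33, 0.55, 0.12),
        RegimeParams(7.00, 17.0, 1.0, 30.08, 165.0, 0.30, 0.56, 0.14),
    )
    duration_median_s: float = 5.8
    duration_mean_s: float = 6.5
    mpe_energy_share_target: float = 0.30
    game_mix_concentration: float = 12.0
    half_len_s: float = 2700.0
    halftime_len_s: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.regime_transition, dtype=float)
        if T.shape != (3, 3):
            raise ConfigError("regime_transition must be 3x3")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("regime_transition rows must sum to 1")
        if (T < 0).any():
            raise ConfigError("regime_transition entries must be nonnegative")
        if not 0 < self.mpe_energy_share_target < 1:
            raise ConfigError("mpe_energy_share_target must lie in (0, 1)")
        for rp in self.regime_params:
            if rp.mpe_rate_per_min < 0 or rp.power_sd_wkg < 0:
                raise ConfigError("regime rates and spreads must be nonnegative")
            if rp.walk_share + rp.run_share + rp.hsr_share > 1.0 + 1e-9:
                raise ConfigError("speed-band shares must sum to <= 1")
        if not 0 < self.duration_median_s < self.duration_mean_s < _DURATION_CAP_S:
            raise ConfigError("need 0 < duration median < mean < 20 s")

    @property
    def game_end_s(self) -> float:
        return 2 * self.half_len_s + self.halftime_len_s

    def transition_matrix(self) -> np.ndarray:
        return np.asarray(self.regime_transition, dtype=float)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the base regime chain."""
        return _stationary_of(self.transition_matrix())


@dataclass
class SimGame:
    """One simulated game plus its hidden regime truth table."""

    events: list
    windows: list
    totals: list
    meta: GameMeta
    truth: pd.DataFrame  # game_id, player_id, minute, regime


# ---------------------------------------------------------------------------
# event-duration distribution
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _lognormal_params(median: float, mean: float, cap: float) -> tuple:
    """Solve (mu, sigma) of a log-normal truncated at ``cap`` hitting the
    requested truncated median and mean."""

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        z_cap = (math.log(cap) - mu) / sigma
        phi_cap = stats.norm.cdf(z_cap)
        med = math.exp(mu + sigma * stats.norm.ppf(0.5 * phi_cap))
        mn = (
            math.exp(mu + 0.5 * sigma**2)
            * stats.norm.cdf(z_cap - sigma)
            / phi_cap
        )
        return [med - median, mn - mean]

    # untruncated solution as the starting point
    mu0 = math.log(median)
    sigma0 = math.sqrt(max(2.0 * math.log(mean / median), 1e-4))
    sol = optimize.root(moments, [mu0, math.log(sigma0)], tol=1e-12)
    if not sol.success:
        raise ConfigError(f"duration calibration failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def sample_mpe_duration(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. event durations from the calibrated distribution."""
    if n < 1:
        raise ConfigError("sample_mpe_duration: n must be >= 1")
    mu, sigma = _lognormal_params(cfg.duration_median_s, cfg.duration_mean_s, _DURATION_CAP_S)
    z_cap = (math.log(_DURATION_CAP_S) - mu) / sigma
    u = rng.uniform(0.0, stats.norm.cdf(z_cap), size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _expected_duration(cfg: SimConfig) -> float:
    return cfg.duration_mean_s


def _stationary_of(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, i]))
    return pi / pi.sum()


def _background_scale(cfg: SimConfig, pi: np.ndarray | None = None) -> float:
    """Multiplier on regime background power so that, at the given regime
    mix (default: the base chain's stationary mix), event energy is the
    target share of total energy."""
    if pi is None:
        pi = cfg.stationary()
    mean_dur = _expected_duration(cfg)
    e_mpe = sum(
        pi[r] * cfg.regime_params[r].mpe_rate_per_min * cfg.regime_params[r].power_mean_wkg * mean_dur
        for r in REGIMES
    )
    s = cfg.mpe_energy_share_target
    e_bg_target = e_mpe * (1.0 - s) / s
    base = sum(pi[r] * cfg.regime_params[r].background_power_wkg * 60.0 for r in REGIMES)
    return e_bg_target / base


# ---------------------------------------------------------------------------
# game simulation
# ---------------------------------------------------------------------------


def _game_transition(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-game tilt of the base chain toward a Dirichlet-sampled mix."""
    pi = cfg.stationary()
    w = rng.dirichlet(cfg.game_mix_concentration * pi)
    T = cfg.transition_matrix() * (w / pi)[None, :]
    return T / T.sum(axis=1, keepdims=True)


def _simulate_minute_events(
    game_id: str,
    player_id: str,
    minute: int,
    regime: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list:
    """Events for one played minute: Poisson count, calibrated durations,
    Dirichlet-spread recovery gaps. Events never straddle the minute edge,
    and total work is capped at 55 s so every minute has some recovery."""
    rp = cfg.regime_params[regime]
    n = int(rng.poisson(rp.mpe_rate_per_min))
    if n == 0:
        return []
    durations = list(sample_mpe_duration(n, cfg, rng))
    while durations and sum(durations) > 55.0:
        durations.pop()
    if not durations:
        return []
    n = len(durations)
    slack = 60.0 - sum(durations)
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    events = []
    t = 60.0 * minute
    for i, d in enumerate(durations):
        t += gaps[i]
        power = max(3.0, rng.normal(rp.power_mean_wkg, rp.power_sd_wkg))
        events.append(
            MpeEvent(
                game_id=game_id,
                player_id=player_id,
                start_s=round(t, 3),
                end_s=round(t + d, 3),
                duration_s=round(d, 3),
                max_speed_kmh=round(18.0 + 0.6 * power + rng.normal(0, 1.5), 2),
                avg_power_wkg=round(power, 3),
            )
        )
        t += d
    return events


def simulate_game(cfg: SimConfig, rng: np.random.Generator, game_id: str = "g001") -> SimGame:
    """Simulate one game for ``cfg.players_per_game`` players.

    Aggregates (5-min windows, game totals) are computed from the minute
    stream itself, so they are consistent with the event stream by
    construction.
    """
    T_game = _game_transition(cfg, rng)
    pi_game = _stationary_of(T_game)
    bg_scale = _background_scale(cfg, pi_game)
    n_min = int(cfg.game_end_s // 60)
    half1_end = cfg.half_len_s
    half2_start = cfg.half_len_s + cfg.halftime_len_s

    goals = []
    for _ in range(int(rng.poisson(2.5))):
        minute = int(rng.integers(0, n_min))
        if not (half1_end / 60 <= minute < half2_start / 60):
            goals.append((minute, "for" if rng.random() < 0.5 else "against"))

    positions = ["CB", "CB", "WB", "WB", "MF", "MF", "MF", "WF", "FW", "FW"]
    lineups = {}
    events: list = []
    windows: list = []
    totals: list = []
    truth_rows = []

    for p in range(cfg.players_per_game):
        player_id = f"p{p + 1:02d}"  # stable squad ids across games
        position = positions[p % len(positions)]
        lineups[player_id] = PlayerStint(position=position, on_s=0.0, off_s=cfg.game_end_s)

        regime = int(rng.choice(3, p=pi_game))
        minute_rows = []
        for m in range(n_min):
            m_lo = 60.0 * m
            played = m_lo >= half2_start or m_lo + 60.0 <= half1_end
            if played:
                regime = int(rng.choice(3, p=T_game[regime]))
                rp = cfg.regime_params[regime]
                evs = _simulate_minute_events(game_id, player_id, m, regime, cfg, rng)
                work = sum(e.duration_s for e in evs)
                e_mpe = sum(e.energy_jkg for e in evs)
                bg = bg_scale * rp.background_power_wkg * 60.0 * max(0.1, rng.normal(1.0, 0.05))
                dist = max(10.0, rng.normal(rp.distance_per_min_m, 4.0))
                shares = np.array([rp.walk_share, rp.run_share, rp.hsr_share])
                shares = shares * np.maximum(0.05, rng.normal(1.0, 0.03, size=3))
                shares = shares / shares.sum() * (rp.walk_share + rp.run_share + rp.hsr_share)
                durs = [e.duration_s for e in evs]
                truth_rows.append(
                    {"game_id": game_id, "player_id": player_id, "minute": m, "regime": regime}
                )
                minute_rows.append(
                    {
                        "minute": m,
                        "played_s": 60.0,
                        "regime": regime,
                        "n_events": len(evs),
                        "work_s": work,
                        "durations": durs,
                        "mpe_energy": e_mpe,
                        "bg_energy": bg,
                        "anaerobic": 0.5 * e_mpe + 0.08 * bg,
                        "distance": dist,
                        "walk_m": dist * shares[0],
                        "run_m": dist * shares[1],
                        "hsr_m": dist * shares[2],
                    }
                )
                events.extend(evs)
            else:
                # halftime: device keeps recording a near-idle player
                dist = float(rng.uniform(5.0, 15.0))
                bg = bg_scale * 1.5 * 60.0 * max(0.1, rng.normal(1.0, 0.2))
                minute_rows.append(
                    {
                        "minute": m,
                        "played_s": 0.0,
                        "regime": -1,
                        "n_events": 0,
                        "work_s": 0.0,
                        "durations": [],
                        "mpe_energy": 0.0,
                        "bg_energy": bg,
                        "anaerobic": 0.0,
                        "distance": dist,
                        "walk_m": dist,
                        "run_m": 0.0,
                        "hsr_m": 0.0,
                    }
                )

        windows.extend(_aggregate_windows(game_id, player_id, minute_rows))
        played_rows = [r for r in minute_rows if r["played_s"] > 0]
        ht_rows = [r for r in minute_rows if r["played_s"] == 0]
        totals.append(
            GameTotals(
                game_id=game_id,
                player_id=player_id,
                total_distance_m=sum(r["distance"] for r in minute_rows),
                walk_distance_m=sum(r["walk_m"] for r in played_rows) + sum(r["walk_m"] for r in ht_rows),
                run_below20_m=sum(r["run_m"] for r in played_rows),
                above20_m=sum(r["hsr_m"] for r in played_rows),
            )
        )

    meta = GameMeta(
        game_id=game_id,
        kickoff_utc="2021-01-01T15:00:00Z",
        half1_end_s=half1_end,
        half2_start_s=half2_start,
        game_end_s=cfg.game_end_s,
        goals=tuple(sorted(set(goals))),
        lineups=lineups,
    )
    events.sort(key=lambda e: (e.game_id, e.player_id, e.start_s))
    truth = pd.DataFrame(truth_rows, columns=["game_id", "player_id", "minute", "regime"])
    return SimGame(events=events, windows=windows, totals=totals, meta=meta, truth=truth)


def _aggregate_windows(game_id: str, player_id: str, minute_rows: list) -> list:
    """Fold the minute stream into provider-style 5-minute windows."""
    out = []
    for w0 in range(0, len(minute_rows), 5):
        chunk = minute_rows[w0 : w0 + 5]
        if not chunk:
            continue
        win_start = 60.0 * chunk[0]["minute"]
        time_played = 300.0  # device records through halftime
        n_events = sum(r["n_events"] for r in chunk)
        work = sum(r["work_s"] for r in chunk)
        durs = [d for r in chunk for d in r["durations"]]
        recovery = max(0.0, min(time_played, 300.0) - work)
        e_mpe = sum(r["mpe_energy"] for r in chunk)
        e_bg = sum(r["bg_energy"] for r in chunk)
        general = e_mpe + e_bg
        out.append(
            FiveMinWindow(
                game_id=game_id,
                player_id=player_id,
                window_start_s=win_start,
                time_played_s=time_played,
                distance_m=sum(r["distance"] for r in chunk),
                mpe_count=n_events,
                anaerobic_energy_jkg=sum(r["anaerobic"] for r in chunk),
                avg_metabolic_power_wkg=general / time_played,
                avg_mpe_time_s=float(np.mean(durs)) if durs else 0.0,
                avg_mpe_recovery_time_s=F.avg_recovery_time(recovery, n_events),
                avg_mpe_recovery_power_wkg=e_bg / recovery if recovery > 0 else 0.0,
                walk_distance_m=sum(r["walk_m"] for r in chunk),
                running_distance_m=sum(r["run_m"] for r in chunk),
                walk_energy_jkg=0.30 * e_bg,
                running_energy_jkg=0.62 * e_bg,
                general_energy_jkg=general,
            )
        )
    return out


def simulate_corpus(cfg: SimConfig, out_dir=None) -> list:
    """Simulate ``cfg.n_games`` independent games with derived per-game seeds.

    When ``out_dir`` is given the combined corpus is written there as
    ``mpe.csv``, ``gm5.csv``, ``game_totals.csv``, ``game_meta.json`` and
    ``truth.csv``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    games = []
    for i, child in enumerate(ss.spawn(cfg.n_games)):
        rng = np.random.default_rng(child)
        games.append(simulate_game(cfg, rng, game_id=f"g{i + 1:03d}"))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mpe([e for g in games for e in g.events], out / "mpe.csv")
        write_five_min([w for g in games for w in g.windows], out / "gm5.csv")
        write_game_totals([t for g in games for t in g.totals], out / "game_totals.csv")
        write_game_meta([g.meta for g in games], out / "game_meta.json")
        pd.concat([g.truth for g in games], ignore_index=True).to_csv(out / "truth.csv", index=False)
    return games
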