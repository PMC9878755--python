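"""Derivation of nest-related traits from an electronic-nest visit stream.

Nine whole-period traits per hen, plus per-28-day-period duration traits:

LRN   laying rate in the nests: nest eggs / days alive x 100 (kept only
      when >= 50%)
CN    clutch number: pauses + 1, where a 1-4 day no-nest-egg gap is a pause
      when the 24-h entry time resets backwards by more than the
      line-specific threshold (3 h / 3 h 15 min), and a floor-egg episode
      otherwise
MOT   mean time of entry for oviposition visits, minutes after lights-on
      (entry times are more reliable than egg-sensor times, which fail when
      an egg stays stuck behind the nest); an auxiliary sensor-based MOT
      over accurately-timed visits and the mean time of entry (MTE) are
      stored alongside
MDN   mean horizontal distance (in nests) between the nests used on
      consecutive laying days; top and bottom rows share the horizontal code
PNL   percentage of the pen's nests used for laying (rows distinct);
      only for hens with >= 100 nest eggs
MLD   mean nest-visit duration on oviposition visits (entry to exit)
MDB   mean duration before oviposition (accurate sensor times only)
MDA   mean duration after oviposition (accurate sensor times only)
NAL   nest acceptance for laying: 1 if LRN >= 50%, else 0

Every exclusion is logged as ``filter rule=... n_before=... n_after=...``
so each missing cell is attributable to exactly one rule.  Visits without
an egg never influence any trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PERIOD_TRAIT_COLUMNS, TRAIT_COLUMNS, log_filter

logger = logging.getLogger("hennest")


@dataclass
class DerivationConfig:
    """Filter thresholds; defaults are the study's published rules."""

    clock_decrease_threshold: float = 180.0   # minutes (195 for WL-like)
    lrn_floor: float = 50.0                   # percent
    pnl_min_eggs: int = 100
    min_records: int = 10
    max_gap_days: int = 4
    period_length: int = 28
    n_periods: int = 10
    survival_fraction: float = 0.5
    total_nests: int = 100
    recording_days: int = 280
    drop_last_period: bool = False            # RIR-like: 10th period unusable

    def validate(self) -> "DerivationConfig":
        for name in ("clock_decrease_threshold", "lrn_floor", "pnl_min_eggs",
                     "min_records", "max_gap_days", "period_length",
                     "n_periods", "survival_fraction", "total_nests",
                     "recording_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_periods > 10:
            raise ValueError("n_periods must be <= 10")
        return self

    def replace(self, **kw) -> "DerivationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# per-hen operations
# ---------------------------------------------------------------------------

def filter_survivors(days_alive: pd.Series, cfg: DerivationConfig) -> pd.Index:
    """Hens alive for at least half (``survival_fraction``) of the window.

    The boundary is inclusive: alive-days >= ceil(fraction * window) counts
    as surviving.
    """
    need = math.ceil(cfg.survival_fraction * cfg.recording_days)
    keep = days_alive.index[days_alive >= need]
    log_filter("survival>=half", len(days_alive), len(keep))
    return keep


def compute_lrn(n_nest_eggs: int, days_alive: int,
                cfg: DerivationConfig) -> tuple[float, float]:
    """Return ``(lrn_raw, lrn_phenotype)``; the phenotype is NaN below the
    50% floor (the raw value still feeds NAL)."""
    if days_alive < 1:
        raise ValueError("days_alive must be >= 1")
    raw = 100.0 * n_nest_eggs / days_alive
    return raw, (raw if raw >= cfg.lrn_floor else np.nan)


def compute_nal(lrn_raw: float, cfg: DerivationConfig) -> int:
    return int(lrn_raw >= cfg.lrn_floor)


def find_gaps(days: np.ndarray, entries: np.ndarray) -> list[tuple]:
    """No-laying gaps between consecutive nest-laying days.

    ``days``/``entries`` are the sorted laying days and their entry times.
    Returns ``(gap_start_day, gap_len, t_before, t_after)`` tuples; spells
    at the window edges are not gaps because they are not bounded by laying
    days on both sides.
    """
    out = []
    for k in range(len(days) - 1):
        gap = int(days[k + 1] - days[k]) - 1
        if gap >= 1:
            out.append((int(days[k]) + 1, gap,
                        float(entries[k]), float(entries[k + 1])))
    return out


def classify_gap(gap: tuple, cfg: DerivationConfig) -> str:
    """``pause`` when the entry time resets backwards by strictly more than
    the threshold; otherwise (smaller backward shift, or any forward shift)
    the hen was laying floor eggs."""
    _, _, t_before, t_after = gap
    return "pause" if (t_before - t_after) > cfg.clock_decrease_threshold \
        else "floor"


def compute_cn(days: np.ndarray, entries: np.ndarray, lrn_raw: float,
               cfg: DerivationConfig) -> float:
    """Clutch number = pauses + 1; missing for hens below the LRN floor or
    with any gap longer than ``max_gap_days`` (activity indeterminable)."""
    if lrn_raw < cfg.lrn_floor or len(days) == 0:
        return np.nan
    gaps = find_gaps(days, entries)
    if any(g[1] > cfg.max_gap_days for g in gaps):
        return np.nan
    return 1.0 + sum(classify_gap(g, cfg) == "pause" for g in gaps)


def _mean_if(x: np.ndarray, min_n: int) -> float:
    return float(np.mean(x)) if len(x) >= min_n else np.nan


def compute_mot(entries: np.ndarray, cfg: DerivationConfig) -> float:
    """Mean entry time over oviposition visits (>= min_records of them)."""
    return _mean_if(entries, cfg.min_records)


def compute_mdn(days: np.ndarray, positions: np.ndarray,
                cfg: DerivationConfig) -> float:
    """Mean |horizontal distance| over strictly consecutive laying-day
    pairs; same nest contributes distance 0."""
    if len(days) < 2:
        return np.nan
    consec = np.diff(days) == 1
    dist = np.abs(np.diff(positions))[consec]
    return _mean_if(dist, cfg.min_records)


def compute_pnl(positions: np.ndarray, rows: np.ndarray,
                cfg: DerivationConfig) -> float:
    """Distinct physical nests (row-sensitive) / total nests x 100; only
    for hens with >= pnl_min_eggs nest eggs."""
    if len(positions) < cfg.pnl_min_eggs:
        return np.nan
    distinct = len(set(zip(positions.tolist(), rows.tolist())))
    return 100.0 * distinct / cfg.total_nests


def compute_durations(entries, exits, ovi, accurate,
                      cfg: DerivationConfig) -> tuple[float, float, float]:
    """(MLD, MDB, MDA); MDB/MDA restricted to accurate sensor times, each
    missing below its own record count."""
    mld = _mean_if(exits - entries, cfg.min_records)
    acc = accurate.astype(bool)
    mdb = _mean_if((ovi - entries)[acc], cfg.min_records)
    mda = _mean_if((exits - ovi)[acc], cfg.min_records)
    return mld, mdb, mda


# ---------------------------------------------------------------------------
# table-level derivation
# ---------------------------------------------------------------------------

def _egg_visits(events: pd.DataFrame) -> pd.DataFrame:
    """Oviposition visits only, at most one per hen-day (first kept)."""
    eggs = events[events["egg"] == 1]
    log_filter("oviposition_visits_only", len(events), len(eggs))
    dup = eggs.duplicated(["hen_id", "day_index"])
    if dup.any():
        logger.warning("multiple same-day ovipositions for %d hen-days; "
                       "keeping the first", int(dup.sum()))
        eggs = eggs[~dup]
    return eggs


def derive_all(events: pd.DataFrame, cfg: DerivationConfig,
               days_alive: pd.Series | None = None,
               with_periods: bool = True):
    """Apply the survival filter, then every trait rule, to a visit stream.

    ``days_alive`` maps hen_id -> days alive during the recording window
    (from barn mortality records / simulation truth).  Hens absent from it
    are assumed alive for the whole window.  Returns ``(traits, periods)``
    (``periods`` is None when ``with_periods`` is false).
    """
    cfg.validate()
    eggs = _egg_visits(events)

    all_hens = pd.Index(sorted(set(events["hen_id"].tolist())
                               | (set(days_alive.index.tolist())
                                  if days_alive is not None else set())),
                        name="hen_id")
    if days_alive is None:
        days_alive = pd.Series(cfg.recording_days, index=all_hens)
    else:
        days_alive = days_alive.reindex(all_hens,
                                        fill_value=cfg.recording_days)
        days_alive = days_alive.clip(upper=cfg.recording_days)
    survivors = filter_survivors(days_alive, cfg)

    grouped = dict(list(eggs.groupby("hen_id", sort=True)))
    rows = []
    n_lrn_dropped = n_cn_gap = 0
    for hen in survivors:
        g = grouped.get(hen)
        if g is None:
            g = eggs.iloc[0:0]
        g = g.sort_values("day_index")
        days = g["day_index"].to_numpy()
        entries = g["entry_min"].to_numpy(float)
        exits = g["exit_min"].to_numpy(float)
        ovi = g["ovi_min"].to_numpy(float)
        acc = g["ovi_accurate"].to_numpy() == 1
        pos = g["nest_pos"].to_numpy()
        rowlab = g["nest_row"].to_numpy()

        lrn_raw, lrn = compute_lrn(len(days), int(days_alive.loc[hen]), cfg)
        nal = compute_nal(lrn_raw, cfg)
        if np.isnan(lrn):
            n_lrn_dropped += 1
        cn = compute_cn(days, entries, lrn_raw, cfg)
        if lrn_raw >= cfg.lrn_floor and np.isnan(cn):
            n_cn_gap += 1
        mot = compute_mot(entries, cfg)
        mot_ovi = _mean_if(ovi[acc], cfg.min_records)
        mte = compute_mot(entries, cfg)
        mdn = compute_mdn(days, pos, cfg)
        pnl = compute_pnl(pos, rowlab, cfg)
        mld, mdb, mda = compute_durations(entries, exits, ovi, acc, cfg)
        rows.append((hen, lrn, cn, mot, mot_ovi, mte, mdn, pnl,
                     mld, mdb, mda, nal))

    traits = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    log_filter("LRN>=floor", len(traits), len(traits) - n_lrn_dropped)
    log_filter("CN_gap<=max", len(traits) - n_lrn_dropped,
               len(traits) - n_lrn_dropped - n_cn_gap)
    for col in ("MOT", "MDN", "PNL", "MLD", "MDB", "MDA"):
        log_filter(f"{col}_records>=min", len(traits),
                   int(traits[col].notna().sum()))

    periods = None
    if with_periods:
        periods = compute_period_traits(eggs, survivors, cfg)
    return traits, periods


def compute_period_traits(eggs: pd.DataFrame, hens: pd.Index,
                          cfg: DerivationConfig) -> pd.DataFrame:
    """Duration traits recomputed within each 28-day period.

    The same record-count rule applies per (hen, period); the last period is
    dropped when the config says it is unusable (infection-truncated line).
    """
    n_periods = min(cfg.n_periods, cfg.recording_days // cfg.period_length)
    kept = list(range(n_periods - 1 if cfg.drop_last_period else n_periods))
    eggs = eggs[eggs["day_index"] < n_periods * cfg.period_length]
    pidx = (eggs["day_index"] // cfg.period_length).rename("period")
    rows = []
    for (hen, p), g in eggs.groupby(["hen_id", pidx], sort=True):
        if p not in kept or hen not in hens:
            continue
        acc = g["ovi_accurate"].to_numpy() == 1
        mld, mdb, mda = compute_durations(
            g["entry_min"].to_numpy(float), g["exit_min"].to_numpy(float),
            g["ovi_min"].to_numpy(float), acc, cfg)
        rows.append((hen, int(p), mld, mdb, mda))
    out = pd.DataFrame(rows, columns=PERIOD_TRAIT_COLUMNS)
    for col in ("MLD", "MDB", "MDA"):
        log_filter(f"period_{col}_records>=min", len(out),
                   int(out[col].notna().sum()))
    return out


def days_alive_from_truth(truth, cfg: DerivationConfig) -> pd.Series:
    """Per-hen days alive during the window, from simulation truth."""
    alive = np.where(truth.death_day >= 0, truth.death_day,
                     truth.window_days)
    return pd.Series(alive, index=pd.Index(truth.hen_ids, name="hen_id"))


def cn_detector_eligible(truth, cfg: DerivationConfig) -> np.ndarray:
    """Hens on which exact clutch-count agreement is a fair test.

    A detector working from nest records can only see pauses that are
    bracketed by nest-laying days and shorter than the gap window: hens
    with a pause or floor spell touching the window edges, or any no-egg
    gap longer than ``max_gap_days``, are excluded (their CN is missing or
    their truth is invisible by construction).
    """
    ok = np.ones(len(truth.hen_ids), dtype=bool)
    for i in range(len(truth.hen_ids)):
        end = truth.death_day[i] if truth.death_day[i] >= 0 \
            else truth.window_days[i]
        offdays = np.union1d(truth.true_pause_days[i],
                             truth.true_floor_days[i])
        laying = np.setdiff1d(np.arange(end), offdays)
        if len(laying) == 0:
            ok[i] = False
            continue
        pause_inner = ((truth.true_pause_days[i] > laying[0])
                       & (truth.true_pause_days[i] < laying[-1]))
        if not pause_inner.all():
            ok[i] = False
            continue
        # floor spells at the edges are invisible but do not shift CN
        if len(laying) >= 2 and np.max(np.diff(laying)) - 1 > cfg.max_gap_days:
            ok[i] = False
    return ok
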