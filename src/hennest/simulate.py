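"""Synthetic pedigreed flock and electronic-nest event-log generator.

The generator produces what a breeding-company barn would record with RFID
electronic nests: a shallow pedigree (ancestors, sires/dams, one recorded
generation of hens), and a 40-week stream of per-visit records (entry/exit
times, nest location, egg sensor output).  Its point is that the genetic
architecture is *known*: every behavioural parameter of a hen is a latent
variable latent = mu + a + pe with a drawn jointly MVN(0, A x G) over the
pedigree and pe ~ MVN(0, P), so pipeline estimates can be compared against
construction-time truth.

Latent behavioural parameters (one Gaussian scale each, monotone link to
the behavioural scale):

========================  =====================================================
latent                    behavioural meaning (link)
========================  =====================================================
pause_logit               daily probability of starting a laying pause
                          (sigmoid), only active late in a clutch
floor_logit               daily probability of laying on the floor (sigmoid)
clock_start               oviposition clock at the start of a clutch
                          (identity, minutes after lights-on)
log_clock_lag             daily forward drift of the clock within a clutch
                          (exp, minutes/day)
log_window                width of the hen's home range of nest columns (exp)
log_favorites             number of favourite nest columns, evenly spaced in
                          the home range (exp, rounded, >= 1)
log_dur_total             mean total nest-visit duration on an oviposition
                          visit (exp, minutes)
logit_dur_frac            fraction of the visit spent before oviposition
                          (sigmoid)
========================  =====================================================

Clutch mechanics: within a clutch the clock advances ``lag`` minutes per day.
When it passes ``clock_ceiling`` the hen is forced into a pause; before that
a spontaneous pause can fire, but only once the clock has drifted more than
``classification_threshold + 4*lag + pause_gate_margin`` past
``clock_start``.  A pause resets the clock to ``clock_start``.  Floor-egg
days produce no nest record but the clock keeps advancing.  The gate
guarantees that every true pause shows a backward entry-time reset strictly
greater than the classification threshold even when up to three floor days
sit inside the same no-nest-egg gap and entry times carry bounded jitter,
while pure floor gaps of <= 4 days always show a small or forward shift.
This is what makes the clutch-number detector exactly testable.

Nest choice: a hen owns ``F`` favourite columns evenly spaced across a home
range of width ``W`` centred on her (uniformly placed) home position.  Each
laying day she reuses the previous nest with probability ``reuse_prob``,
otherwise picks a favourite column uniformly and a row at random
(``row_mix_prob`` of switching rows).  Mean consecutive-day distance is
monotone in ``W``; the number of distinct nests used is monotone in ``F``;
the additive covariance between the two latents therefore *is* the true
genetic correlation between the derived nest-preference traits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EVENT_COLUMNS

logger = logging.getLogger("hennest")

#: order of latent behavioural parameters in mu, G and P
LATENT_NAMES = [
    "pause_logit", "floor_logit", "clock_start", "log_clock_lag",
    "log_window", "log_favorites", "log_dur_total", "logit_dur_frac",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture parameters of a simulated flock.

    ``G`` and ``P`` are the additive-genetic and permanent-environment
    covariance matrices over :data:`LATENT_NAMES`; ``mu`` the latent means.
    """

    n_sires: int = 99
    n_dams: int = 348
    hens_per_dam: int = 3
    base_generations: int = 1
    n_nests: int = 100
    n_rows: int = 2
    recording_days: int = 280
    lights_on: int = 240          # minutes after midnight; metadata only
    hatch_dates: tuple = (("batch1", 0.47), ("batch2", 0.53))
    #: per-batch additive shifts on latent means, {latent: (shift per batch)}
    hatch_shifts: dict = field(default_factory=lambda: {
        "clock_start": (6.0, -6.0), "log_dur_total": (0.02, -0.02)})
    #: optional per-batch truncation of the recording window (days)
    batch_recording_days: tuple | None = None
    G: np.ndarray = None
    P: np.ndarray = None
    mu: np.ndarray = None
    clock_span: float = 360.0     # clock_ceiling - clock_start, minutes
    classification_threshold: float = 180.0
    pause_gate_margin: float = 25.0
    multi_day_pause_prob: float = 0.2
    sensor_failure_rate: float = 0.043
    nonlaying_visit_rate: float = 0.3
    daily_mortality_hazard: float = 0.00025
    reuse_prob: float = 0.10
    row_mix_prob: float = 0.5
    entry_jitter: float = 10.0    # uniform +/- bound, minutes
    #: clutch phase at the window start, as a fraction of the clock span
    #: (hens begin lay shortly before recording starts, so phases are low)
    initial_clock_phase: float = 0.30
    visit_noise_sd: float = 0.22  # lognormal day-to-day noise on durations
    period_shock_sd: float = 0.12  # per hen x 28-day-period duration shock
    period_length: int = 28
    age_curve: tuple = (0.90, 0.97, 1.03, 1.05, 1.05, 1.05, 1.04, 1.03,
                        1.01, 1.00)
    seed: int = 0

    @property
    def n_cols(self) -> int:
        return self.n_nests // self.n_rows

    def validate(self) -> "SimulationConfig":
        for name in ("n_sires", "n_dams", "hens_per_dam", "n_nests", "n_rows"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.base_generations < 0:
            raise ValueError("base_generations must be >= 0")
        if self.n_cols * self.n_rows != self.n_nests:
            raise ValueError("n_nests must be divisible by n_rows")
        if self.recording_days < 56:
            raise ValueError("recording_days must be >= 56 (two periods)")
        for name in ("sensor_failure_rate", "daily_mortality_hazard",
                     "multi_day_pause_prob", "reuse_prob", "row_mix_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nonlaying_visit_rate < 0:
            raise ValueError("nonlaying_visit_rate must be >= 0")
        L = len(LATENT_NAMES)
        for name in ("G", "P"):
            M = getattr(self, name)
            if M is None or np.asarray(M).shape != (L, L):
                raise ValueError(f"{name} must be a {L}x{L} matrix")
            M = np.asarray(M, float)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            w = np.linalg.eigvalsh(M)
            if w.min() < -1e-8:
                raise ValueError(
                    f"{name} is not positive semi-definite "
                    f"(min eigenvalue {w.min():.3g})")
        if self.mu is None or len(self.mu) != L:
            raise ValueError(f"mu must have length {L}")
        props = np.array([p for _, p in self.hatch_dates], float)
        if props.min() <= 0 or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("hatch_date proportions must be positive and sum to 1")
        if self.clock_span <= self.classification_threshold + self.pause_gate_margin:
            raise ValueError("clock_span leaves no room for the pause gate")
        return self

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def latent_covariances(h2: dict, total_var: dict,
                       ra_window_favorites: float,
                       rpe_window_favorites: float = 0.684):
    """Build (G, P) from per-latent heritability targets and total variances.

    Each latent gets sigma2_a = h2 * total and sigma2_pe = (1 - h2) * total;
    derived traits are (near-)monotone functions of single latents averaged
    over >= ~150 daily records, so the observable-scale heritability equals
    the latent target up to negligible sampling attenuation.  The only
    cross-covariance is between ``log_window`` and ``log_favorites``, which
    sets the true genetic correlation between the nest-preference traits.
    """
    L = len(LATENT_NAMES)
    G = np.zeros((L, L))
    P = np.zeros((L, L))
    for i, name in enumerate(LATENT_NAMES):
        v = float(total_var[name])
        h = float(h2[name])
        if not 0.0 <= h <= 1.0:
            raise ValueError(f"heritability target for {name} outside [0, 1]")
        G[i, i] = h * v
        P[i, i] = (1.0 - h) * v
    iw = LATENT_NAMES.index("log_window")
    jf = LATENT_NAMES.index("log_favorites")
    G[iw, jf] = G[jf, iw] = ra_window_favorites * np.sqrt(G[iw, iw] * G[jf, jf])
    P[iw, jf] = P[jf, iw] = rpe_window_favorites * np.sqrt(P[iw, iw] * P[jf, jf])
    return G, P


# Preset latent means / variances / heritabilities.  Calibrated by
# simulation against the published per-line trait summaries (laying rate,
# clutch number, nest-acceptance fraction, duration means); heritability
# targets are the published per-line estimates (the percentage-of-nests
# trait uses the rounded common-line value for the red-line preset).
_PRESETS = {
    "RIR-like": dict(
        n_sires=99, n_dams=348, hens_per_dam=3, n_nests=100,
        classification_threshold=180.0, sensor_failure_rate=0.043,
        mu={"pause_logit": -5.3, "floor_logit": -3.55,
            "clock_start": 45.0, "log_clock_lag": np.log(4.3),
            "log_window": np.log(26.0) - 0.5 * 0.137,
            "log_favorites": np.log(15.0) - 0.5 * 0.09,
            "log_dur_total": np.log(41.0) - 0.5 * 0.159,
            "logit_dur_frac": 0.66},
        total_var={"pause_logit": 0.49, "floor_logit": 7.3,
                   "clock_start": 100.0, "log_clock_lag": 0.0625,
                   "log_window": 0.137, "log_favorites": 0.09,
                   "log_dur_total": 0.159, "logit_dur_frac": 0.25},
        h2={"pause_logit": 0.37, "floor_logit": 0.13, "clock_start": 0.30,
            "log_clock_lag": 0.65, "log_window": 0.30, "log_favorites": 0.20,
            "log_dur_total": 0.54, "logit_dur_frac": 0.60},
        ra_wf=0.85,
    ),
    "WL-like": dict(
        n_sires=99, n_dams=352, hens_per_dam=3, n_nests=120,
        classification_threshold=195.0, sensor_failure_rate=0.112,
        mu={"pause_logit": -4.7, "floor_logit": -3.05,
            "clock_start": 60.0, "log_clock_lag": np.log(9.8),
            "log_window": np.log(31.0) - 0.5 * 0.137,
            "log_favorites": np.log(18.0) - 0.5 * 0.09,
            "log_dur_total": np.log(64.0) - 0.5 * 0.122,
            "logit_dur_frac": -0.12},
        total_var={"pause_logit": 0.49, "floor_logit": 7.3,
                   "clock_start": 100.0, "log_clock_lag": 0.0625,
                   "log_window": 0.137, "log_favorites": 0.09,
                   "log_dur_total": 0.122, "logit_dur_frac": 0.25},
        h2={"pause_logit": 0.52, "floor_logit": 0.23, "clock_start": 0.30,
            "log_clock_lag": 0.55, "log_window": 0.37, "log_favorites": 0.18,
            "log_dur_total": 0.68, "logit_dur_frac": 0.68},
        ra_wf=0.71,
    ),
}


def preset_configs(line_label: str, seed: int = 0) -> SimulationConfig:
    """Return a validated line-like configuration (``RIR-like``/``WL-like``)."""
    if line_label not in _PRESETS:
        raise ValueError(
            f"unknown preset {line_label!r}; choose from {sorted(_PRESETS)}")
    p = _PRESETS[line_label]
    G, P = latent_covariances(p["h2"], p["total_var"], p["ra_wf"])
    mu = np.array([p["mu"][name] for name in LATENT_NAMES])
    cfg = SimulationConfig(
        n_sires=p["n_sires"], n_dams=p["n_dams"], hens_per_dam=p["hens_per_dam"],
        n_nests=p["n_nests"],
        classification_threshold=p["classification_threshold"],
        sensor_failure_rate=p["sensor_failure_rate"],
        G=G, P=P, mu=mu, seed=seed)
    return cfg.validate()


def preset_true_values(line_label: str) -> dict:
    """Construction-time truth of a preset: per-trait heritabilities and the
    genetic correlation between the nest-preference traits."""
    p = _PRESETS[line_label]
    return {"h2_MDN": p["h2"]["log_window"], "h2_PNL": p["h2"]["log_favorites"],
            "h2_MLD": p["h2"]["log_dur_total"], "h2_CN": p["h2"]["pause_logit"],
            "h2_MOT": p["h2"]["log_clock_lag"], "ra_MDN_PNL": p["ra_wf"]}


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def generate_pedigree(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Simulate the breeding structure: ancestor generations, one sire/dam
    generation, and the recorded hens (n_dams * hens_per_dam of them).

    Sires descend from one founder pool and dams from a disjoint, unrelated
    pool, so every sire x dam mating is between non-inbred, unrelated
    parents and the pedigree is inbreeding-free.  Returns a frame with
    columns id, sire, dam, generation, is_recorded (parents precede
    offspring; unknown parent = 0).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids, sires, dams, gens = [], [], [], []
    next_id = 1

    def _new_generation(pool, size, gen):
        nonlocal next_id
        out = []
        if pool is None:                       # founders
            for _ in range(size):
                ids.append(next_id); sires.append(0); dams.append(0)
                gens.append(gen); out.append(next_id); next_id += 1
            return out
        half = max(1, len(pool) // 2)
        males, females = pool[:half], pool[half:] or pool[:half]
        for _ in range(size):
            ids.append(next_id)
            sires.append(int(rng.choice(males)))
            dams.append(int(rng.choice(females)))
            gens.append(gen); out.append(next_id); next_id += 1
        return out

    side_sizes = {"sire": cfg.n_sires, "dam": cfg.n_dams}
    parents = {}
    for side, size in side_sizes.items():
        pool = None
        if cfg.base_generations > 0:
            pool = _new_generation(None, max(4, size), 0)
            for g in range(1, cfg.base_generations):
                pool = _new_generation(pool, max(4, size), g)
        parents[side] = _new_generation(pool, size, cfg.base_generations)

    gen_rec = cfg.base_generations + 1
    first_recorded = next_id
    for j, dam in enumerate(parents["dam"]):
        sire = parents["sire"][j % cfg.n_sires]
        for _ in range(cfg.hens_per_dam):
            ids.append(next_id); sires.append(sire); dams.append(dam)
            gens.append(gen_rec); next_id += 1

    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams,
                        "generation": gens})
    ped["is_recorded"] = ped["id"] >= first_recorded
    logger.info("generate_pedigree n_total=%d n_recorded=%d",
                len(ped), int(ped["is_recorded"].sum()))
    return ped


def sample_breeding_values(ped: pd.DataFrame, G: np.ndarray,
                           rng=None) -> np.ndarray:
    """Draw additive genetic values over the pedigree.

    Founders ~ MVN(0, G); non-founders = midparent + Mendelian sampling
    MVN(0, G/2) (no-inbreeding simplification).  Returns an array of shape
    (n_individuals, n_latents) in pedigree order.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if np.isscalar(rng):
        rng = np.random.default_rng(rng)
    G = np.asarray(G, float)
    w, V = np.linalg.eigh((G + G.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(
            f"G is not positive semi-definite (min eigenvalue {w.min():.3g})")
    F = V * np.sqrt(np.clip(w, 0.0, None))        # G = F F'
    L = G.shape[0]
    n = len(ped)
    idx = {int(i): k for k, i in enumerate(ped["id"].to_numpy())}
    z = rng.standard_normal((n, L))
    a = np.empty((n, L))
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    for k in range(n):
        s, d = int(sire[k]), int(dam[k])
        mid = np.zeros(L)
        scale = 1.0
        if s != 0 and d != 0:
            mid = 0.5 * (a[idx[s]] + a[idx[d]])
            scale = np.sqrt(0.5)
        elif s != 0 or d != 0:
            p = idx[s if s != 0 else d]
            mid = 0.5 * a[p]
            scale = np.sqrt(0.75)
        a[k] = mid + scale * (F @ z[k])
    return a


# ---------------------------------------------------------------------------
# latent realisation
# ---------------------------------------------------------------------------

@dataclass
class LatentHenParams:
    """Realised behavioural parameters of the recorded hens (arrays)."""

    hen_ids: np.ndarray
    hatch_batch: np.ndarray          # batch index per hen
    pause_prob: np.ndarray
    floor_prob: np.ndarray
    clock_start: np.ndarray
    clock_lag: np.ndarray
    clock_ceiling: np.ndarray
    home_nest: np.ndarray            # horizontal column of the range centre
    home_row: np.ndarray             # 0 = bottom, 1 = top
    nest_spread: np.ndarray          # home-range width W, in nest columns
    n_favorites: np.ndarray
    dur_before_mean: np.ndarray
    dur_after_mean: np.ndarray
    latent: np.ndarray               # (n, n_latents) realised latent values

    def __len__(self):
        return len(self.hen_ids)


def realize_latents(ped: pd.DataFrame, bv: np.ndarray,
                    cfg: SimulationConfig, rng=None) -> LatentHenParams:
    """Map breeding values + permanent environment + batch shifts to the
    behavioural scale for the recorded hens."""
    if rng is None:
        rng = np.random.default_rng(0)
    rec = ped["is_recorded"].to_numpy()
    hen_ids = ped.loc[rec, "id"].to_numpy()
    n = len(hen_ids)
    L = len(LATENT_NAMES)

    w, V = np.linalg.eigh((cfg.P + cfg.P.T) / 2.0)
    Fp = V * np.sqrt(np.clip(w, 0.0, None))
    pe = rng.standard_normal((n, L)) @ Fp.T

    props = np.array([p for _, p in cfg.hatch_dates])
    batch = rng.choice(len(props), size=n, p=props)
    shift = np.zeros((n, L))
    for name, per_batch in cfg.hatch_shifts.items():
        j = LATENT_NAMES.index(name)
        shift[:, j] = np.asarray(per_batch)[batch]

    lat = np.asarray(cfg.mu, float)[None, :] + shift + bv[rec] + pe
    col = {name: lat[:, j] for j, name in enumerate(LATENT_NAMES)}

    start = np.clip(col["clock_start"], 5.0, None)
    # keep the forced-pause reset detectable: lag small enough that the
    # clock span exceeds threshold + 4*lag + margin (see module docstring)
    lag_cap = (cfg.clock_span - cfg.classification_threshold
               - cfg.pause_gate_margin - 1.0) / 4.0
    lag = np.clip(np.exp(col["log_clock_lag"]), 0.5, lag_cap)
    W = np.clip(np.exp(col["log_window"]), 0.0, cfg.n_cols - 1.0)
    nfav = np.maximum(1, np.rint(np.exp(col["log_favorites"])).astype(int))
    lo = 1.0 + W / 2.0
    hi = cfg.n_cols - W / 2.0
    home = lo + (hi - lo) * rng.random(n)
    total = np.exp(col["log_dur_total"])
    frac = np.clip(_sigmoid(col["logit_dur_frac"]), 0.05, 0.95)

    return LatentHenParams(
        hen_ids=hen_ids, hatch_batch=batch,
        pause_prob=_sigmoid(col["pause_logit"]),
        floor_prob=_sigmoid(col["floor_logit"]),
        clock_start=start, clock_lag=lag,
        clock_ceiling=start + cfg.clock_span,
        home_nest=home, home_row=rng.integers(0, 2, size=n),
        nest_spread=W, n_favorites=nfav,
        dur_before_mean=total * frac, dur_after_mean=total * (1.0 - frac),
        latent=lat)


# ---------------------------------------------------------------------------
# event simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Generator ground truth for recovery tests."""

    hen_ids: np.ndarray
    breeding_values: np.ndarray      # (n_hens, n_latents), LATENT_NAMES order
    true_pause_days: list            # list of int arrays, one per hen
    true_floor_days: list
    true_clutch_count: np.ndarray    # pause events + 1
    death_day: np.ndarray            # -1 if the hen survived the window
    window_days: np.ndarray          # per-hen recording window length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hen_id": self.hen_ids,
            "death_day": self.death_day,
            "window_days": self.window_days,
            "true_clutch_count": self.true_clutch_count,
            "pause_days": [";".join(map(str, d)) for d in self.true_pause_days],
            "floor_days": [";".join(map(str, d)) for d in self.true_floor_days],
        })


def _favorite_columns(lp: LatentHenParams, n_cols: int) -> np.ndarray:
    """(n_hens, max_F) matrix of favourite columns, evenly spaced across
    each hen's home range (unused slots repeat the last favourite)."""
    n = len(lp)
    fmax = int(lp.n_favorites.max())
    k = np.arange(fmax)[None, :]
    Fh = lp.n_favorites[:, None].astype(float)
    pos = (lp.home_nest[:, None] - lp.nest_spread[:, None] / 2.0
           + lp.nest_spread[:, None] * (np.minimum(k, Fh - 1) + 0.5) / Fh)
    return np.clip(np.rint(pos), 1, n_cols).astype(int)


def simulate_events(ped: pd.DataFrame, lp: LatentHenParams,
                    cfg: SimulationConfig, rng=None):
    """Run the daily clutch/nest-choice state machine.

    Returns ``(events, truth)`` where ``events`` is a visit table in the
    event-file schema (validated ordering) and ``truth`` the bookkeeping of
    true pauses, floor days, clutch counts and deaths.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(lp)
    D = cfg.recording_days
    n_periods = max(1, D // cfg.period_length)
    age = np.asarray(cfg.age_curve, float)
    if len(age) < n_periods + 1:
        age = np.concatenate([age, np.full(n_periods + 1 - len(age), age[-1])])

    # per-hen recording window (batch truncation) and death day
    window = np.full(n, D)
    if cfg.batch_recording_days is not None:
        window = np.asarray(cfg.batch_recording_days)[lp.hatch_batch]
        window = np.minimum(window, D)
    u = rng.random(n)
    h = cfg.daily_mortality_hazard
    if h > 0:
        dd = np.floor(np.log(u) / np.log1p(-h)).astype(int)
    else:
        dd = np.full(n, np.iinfo(np.int32).max)
    death = np.where(dd < window, dd, -1)
    last_day = np.where(death >= 0, death, window)   # exclusive

    fav = _favorite_columns(lp, cfg.n_cols)
    shock = np.exp(rng.normal(0.0, cfg.period_shock_sd, size=(n, n_periods + 1)))

    clock = lp.clock_start + cfg.clock_span * cfg.initial_clock_phase \
        * rng.random(n)
    pause_rem = np.zeros(n, dtype=int)
    prev_col = np.zeros(n, dtype=int)
    prev_row = lp.home_row.copy()
    has_prev = np.zeros(n, dtype=bool)
    n_pauses = np.zeros(n, dtype=int)
    pause_days: list[list] = [[] for _ in range(n)]
    floor_days: list[list] = [[] for _ in range(n)]

    rows_out = {k: [] for k in EVENT_COLUMNS}
    gate = (cfg.classification_threshold + 4.0 * lp.clock_lag
            + cfg.pause_gate_margin)

    for d in range(D):
        alive = d < last_day
        period = min(d // cfg.period_length, n_periods)

        in_pause = alive & (pause_rem > 0)
        pause_rem[in_pause] -= 1

        active = alive & ~in_pause
        forced = active & (clock > lp.clock_ceiling)
        u_p = rng.random(n)
        spont = (active & ~forced & (clock - lp.clock_start > gate)
                 & (u_p < lp.pause_prob))
        new_pause = forced | spont
        if new_pause.any():
            extra = rng.geometric(0.6, size=n) - 1
            extra = np.where(rng.random(n) < cfg.multi_day_pause_prob,
                             np.minimum(extra + 1, 2), 0)
            pause_rem[new_pause] = extra[new_pause]
            clock[new_pause] = lp.clock_start[new_pause]
            n_pauses[new_pause] += 1

        egg_day = active & ~new_pause
        u_f = rng.random(n)
        floor = egg_day & (u_f < lp.floor_prob)
        nest = egg_day & ~floor
        clock[egg_day] += lp.clock_lag[egg_day]

        for i in np.nonzero(in_pause | new_pause)[0]:
            pause_days[i].append(d)
        for i in np.nonzero(floor)[0]:
            floor_days[i].append(d)

        if nest.any():
            u_reuse = rng.random(n)
            reuse = nest & has_prev & (u_reuse < cfg.reuse_prob)
            fresh = nest & ~reuse
            pick = rng.integers(0, np.maximum(lp.n_favorites, 1))
            col = np.where(fresh, fav[np.arange(n), np.minimum(pick, fav.shape[1] - 1)],
                           prev_col)
            flip = rng.random(n) < cfg.row_mix_prob
            row = np.where(fresh, np.where(flip, 1 - prev_row, prev_row), prev_row)

            jit = rng.uniform(-cfg.entry_jitter, cfg.entry_jitter, size=n)
            entry = np.maximum(1, np.rint(clock - lp.clock_lag + jit)).astype(int)
            scale = age[period] * shock[:, period]
            noise_b = np.exp(rng.normal(0.0, cfg.visit_noise_sd, size=n))
            noise_a = np.exp(rng.normal(0.0, cfg.visit_noise_sd, size=n))
            dur_b = np.maximum(1, np.rint(lp.dur_before_mean * scale * noise_b))
            dur_a = np.maximum(1, np.rint(lp.dur_after_mean * scale * noise_a))
            ovi = entry + dur_b.astype(int)
            exit_ = ovi + dur_a.astype(int)
            accurate = (rng.random(n) >= cfg.sensor_failure_rate).astype(int)
            ovi_rec = np.where(accurate == 1, ovi, exit_)   # stuck egg

            idx = np.nonzero(nest)[0]
            rows_out["hen_id"].extend(lp.hen_ids[idx])
            rows_out["day_index"].extend([d] * len(idx))
            rows_out["nest_pos"].extend(col[idx])
            rows_out["nest_row"].extend(
                np.where(row[idx] == 1, "top", "bottom"))
            rows_out["entry_min"].extend(entry[idx])
            rows_out["exit_min"].extend(exit_[idx])
            rows_out["egg"].extend([1] * len(idx))
            rows_out["ovi_min"].extend(ovi_rec[idx])
            rows_out["ovi_accurate"].extend(accurate[idx])

            prev_col = np.where(nest, col, prev_col)
            prev_row = np.where(nest, row, prev_row)
            has_prev = has_prev | nest

    events = pd.DataFrame(rows_out)

    # non-laying visits: egg-less records that every trait must ignore
    if cfg.nonlaying_visit_rate > 0:
        counts = rng.poisson(cfg.nonlaying_visit_rate * last_day)
        tot = int(counts.sum())
        if tot > 0:
            hen_idx = np.repeat(np.arange(n), counts)
            days = (rng.random(tot) * last_day[hen_idx]).astype(int)
            pick = rng.integers(0, lp.n_favorites[hen_idx])
            colv = fav[hen_idx, np.minimum(pick, fav.shape[1] - 1)]
            entry = rng.integers(300, 540, size=tot)
            exit_ = entry + rng.integers(2, 30, size=tot)
            extra = pd.DataFrame({
                "hen_id": lp.hen_ids[hen_idx], "day_index": days,
                "nest_pos": colv,
                "nest_row": np.where(rng.random(tot) < 0.5, "top", "bottom"),
                "entry_min": entry, "exit_min": exit_,
                "egg": 0, "ovi_min": np.nan, "ovi_accurate": 0})
            events = pd.concat([events, extra], ignore_index=True)

    events["ovi_min"] = events["ovi_min"].astype(float)
    events = events.sort_values(["hen_id", "day_index", "entry_min"],
                                kind="mergesort").reset_index(drop=True)

    rec = ped["is_recorded"].to_numpy()
    truth = SimulationTruth(
        hen_ids=lp.hen_ids,
        breeding_values=None,        # filled in by run_simulation
        true_pause_days=[np.array(p, dtype=int) for p in pause_days],
        true_floor_days=[np.array(f, dtype=int) for f in floor_days],
        true_clutch_count=n_pauses + 1,
        death_day=death, window_days=window if np.ndim(window) else
        np.full(n, D))
    logger.info("simulate_events n_hens=%d n_visits=%d n_dead=%d",
                n, len(events), int((death >= 0).sum()))
    return events, truth


def run_simulation(cfg: SimulationConfig):
    """Generate a full flock: pedigree, breeding values, latents, events.

    The config seed is fanned out to one child stream per stage (pedigree,
    breeding values, permanent environment, events) via ``SeedSequence``.

    Returns ``(ped, latents, events, truth)``.
    """
    cfg.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(cfg.seed).spawn(4)]
    ped = generate_pedigree(cfg, streams[0])
    bv = sample_breeding_values(ped, cfg.G, streams[1])
    lp = realize_latents(ped, bv, cfg, streams[2])
    events, truth = simulate_events(ped, lp, cfg, streams[3])
    truth.breeding_values = bv[ped["is_recorded"].to_numpy()]
    return ped, lp, events, truth
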