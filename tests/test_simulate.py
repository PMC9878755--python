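import numpy as np
import pandas as pd
import pytest

from hennest import (LATENT_NAMES, build_A, generate_pedigree,
                     preset_configs, run_simulation, sample_breeding_values)
from hennest.simulate import SimulationConfig, latent_covariances


def test_pedigree_reproduces_study_structure():
    cfg = preset_configs("WL-like").replace(n_sires=99, n_dams=352,
                                            hens_per_dam=3)
    ped = generate_pedigree(cfg, np.random.default_rng(0))
    rec = ped[ped["is_recorded"]]
    assert len(rec) == 352 * 3 == 1056
    hens_per_sire = rec.groupby("sire").size()
    assert 9 <= hens_per_sire.mean() <= 12        # about ten hens per sire
    assert rec.groupby("dam").size().eq(3).all()  # three hens per dam
    # parents precede offspring
    order = {i: k for k, i in enumerate(ped["id"])}
    for _, r in ped.iterrows():
        for p in (r["sire"], r["dam"]):
            assert p == 0 or order[p] < order[r["id"]]


def test_zero_base_generations_gives_founder_parents():
    cfg = preset_configs("RIR-like").replace(base_generations=0, n_sires=3,
                                             n_dams=6, hens_per_dam=2)
    ped = generate_pedigree(cfg, np.random.default_rng(0))
    parents = ped[~ped["is_recorded"]]
    assert (parents[["sire", "dam"]] == 0).all().all()


def test_single_sire_two_dams_forces_sib_structure():
    cfg = preset_configs("RIR-like").replace(base_generations=0, n_sires=1,
                                             n_dams=2, hens_per_dam=2)
    ped = generate_pedigree(cfg, np.random.default_rng(0))
    rel = build_A(ped)
    rec_ids = ped.loc[ped["is_recorded"], "id"].to_numpy()
    K = rel.subset(rec_ids)
    dams = ped.set_index("id").loc[rec_ids, "dam"].to_numpy()
    for i in range(4):
        for j in range(i + 1, 4):
            expect = 0.5 if dams[i] == dams[j] else 0.25
            assert K[i, j] == pytest.approx(expect)


def test_breeding_values_zero_when_G_zero(small_flock):
    ped = small_flock[0]
    a = sample_breeding_values(ped, np.zeros((2, 2)),
                               np.random.default_rng(1))
    assert np.all(a == 0.0)


def test_non_psd_G_rejected(small_flock):
    ped = small_flock[0]
    G = np.array([[1.0, 2.0], [2.0, 1.0]])       # eigenvalues -1, 3
    with pytest.raises(ValueError, match="positive semi-definite"):
        sample_breeding_values(ped, G, np.random.default_rng(1))


def test_founder_breeding_values_recover_G_correlation():
    ped = pd.DataFrame({"id": np.arange(1, 10001), "sire": 0, "dam": 0})
    G = np.array([[1.0, 0.8], [0.8, 1.0]])
    a = sample_breeding_values(ped, G, np.random.default_rng(3))
    r = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
    assert r == pytest.approx(0.8, abs=0.03)


def test_full_sib_covariance_is_half_G():
    n_fam = 4000
    rows = []
    for f in range(n_fam):
        s, d = 3 * f + 1, 3 * f + 2
        rows += [(s, 0, 0), (d, 0, 0), (3 * f + 3, s, d)]
    ped = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    # one extra sib per family to measure the sib-sib covariance
    extra = pd.DataFrame([(3 * n_fam + f + 1, 3 * f + 1, 3 * f + 2)
                          for f in range(n_fam)],
                         columns=["id", "sire", "dam"])
    ped = pd.concat([ped, extra], ignore_index=True)
    a = sample_breeding_values(ped, np.eye(1), np.random.default_rng(4))[:, 0]
    sib1 = a[ped["id"].between(1, 3 * n_fam) & (ped["sire"] != 0)]
    sib2 = a[ped["id"] > 3 * n_fam]
    cov = np.mean(sib1 * sib2)
    assert cov == pytest.approx(0.5, abs=0.05)


def test_event_stream_deterministic_given_seed(small_cfg):
    e1 = run_simulation(small_cfg)[2]
    e2 = run_simulation(small_cfg)[2]
    pd.testing.assert_frame_equal(e1, e2)


def test_day_partition_conservation(small_flock, small_cfg):
    """Visit days, floor days, pause days and post-death days partition the
    recording window for every hen."""
    ped, lp, events, truth = small_flock
    eggs = events[events["egg"] == 1]
    by_hen = eggs.groupby("hen_id")["day_index"].apply(set)
    D = small_cfg.recording_days
    for i, hen in enumerate(truth.hen_ids):
        end = truth.death_day[i] if truth.death_day[i] >= 0 else \
            truth.window_days[i]
        visit = by_hen.get(hen, set())
        floor = set(truth.true_floor_days[i].tolist())
        pause = set(truth.true_pause_days[i].tolist())
        assert visit | floor | pause == set(range(int(end)))
        assert not (visit & floor or visit & pause or floor & pause)
        assert truth.true_clutch_count[i] == len(_pause_events(
            truth.true_pause_days[i])) + 1


def _pause_events(days):
    """Contiguous runs of pause days = pause events."""
    if len(days) == 0:
        return []
    breaks = np.nonzero(np.diff(days) > 1)[0]
    return np.split(days, breaks + 1)


def test_clock_property_of_generated_gaps(small_flock, small_cfg, small_dcfg):
    """Across every truth pause the entry time resets backwards by more
    than the classification threshold; across pure floor gaps of <= 4 days
    it moves forward or backwards by less than the threshold."""
    ped, lp, events, truth = small_flock
    thr = small_dcfg.clock_decrease_threshold
    eggs = events[events["egg"] == 1]
    checked_pause = checked_floor = 0
    for i, hen in enumerate(truth.hen_ids):
        g = eggs[eggs["hen_id"] == hen]
        days = g["day_index"].to_numpy()
        entry = g["entry_min"].to_numpy(float)
        pauses = set(truth.true_pause_days[i].tolist())
        floors = set(truth.true_floor_days[i].tolist())
        for k in range(len(days) - 1):
            gap = days[k + 1] - days[k] - 1
            if gap < 1 or gap > small_dcfg.max_gap_days:
                continue
            gap_days = set(range(days[k] + 1, days[k + 1]))
            decrease = entry[k] - entry[k + 1]
            if gap_days & pauses:
                assert decrease > thr
                checked_pause += 1
            else:
                assert gap_days <= floors
                assert decrease < thr
                checked_floor += 1
    assert checked_pause > 100 and checked_floor > 50


def test_no_pause_regime_lays_every_day_single_clutch(small_cfg):
    mu = np.array(small_cfg.mu, float).copy()
    mu[LATENT_NAMES.index("pause_logit")] = -30.0
    mu[LATENT_NAMES.index("floor_logit")] = -30.0
    mu[LATENT_NAMES.index("log_clock_lag")] = np.log(0.5)
    cfg = small_cfg.replace(mu=mu, recording_days=56,
                            daily_mortality_hazard=0.0,
                            initial_clock_phase=0.0, n_dams=20)
    ped, lp, events, truth = run_simulation(cfg)
    assert np.all(truth.true_clutch_count == 1)
    eggs = events[events["egg"] == 1]
    assert eggs.groupby("hen_id").size().eq(56).all()


def test_zero_spread_fixed_row_uses_one_physical_nest(small_cfg):
    G, P = latent_covariances(
        {n: 0.0 for n in LATENT_NAMES}, {n: 1e-12 for n in LATENT_NAMES},
        ra_window_favorites=0.0, rpe_window_favorites=0.0)
    mu = np.array(small_cfg.mu, float).copy()
    mu[LATENT_NAMES.index("log_window")] = -30.0     # spread -> 0
    mu[LATENT_NAMES.index("log_favorites")] = -30.0  # one favourite
    cfg = small_cfg.replace(mu=mu, G=G, P=P, row_mix_prob=0.0,
                            reuse_prob=0.0, n_dams=15, recording_days=56,
                            daily_mortality_hazard=0.0)
    ped, lp, events, truth = run_simulation(cfg)
    eggs = events[events["egg"] == 1]
    nests = eggs.groupby("hen_id").apply(
        lambda g: len(set(zip(g["nest_pos"], g["nest_row"]))),
        include_groups=False)
    assert nests.eq(1).all()


def test_forced_pause_clutch_length_matches_span_over_lag():
    """With no spontaneous pauses the clutch ends when the oviposition
    clock crosses the ceiling: length = span/lag + 1 days."""
    cfg = preset_configs("RIR-like", seed=2)
    mu = np.array(cfg.mu, float).copy()
    mu[LATENT_NAMES.index("pause_logit")] = -30.0
    mu[LATENT_NAMES.index("floor_logit")] = -30.0
    mu[LATENT_NAMES.index("log_clock_lag")] = np.log(30.0)
    G, P = latent_covariances(
        {n: 0.0 for n in LATENT_NAMES}, {n: 1e-12 for n in LATENT_NAMES},
        ra_window_favorites=0.0, rpe_window_favorites=0.0)
    cfg = cfg.replace(mu=mu, G=G, P=P, clock_span=300.0, n_dams=15,
                      recording_days=112, daily_mortality_hazard=0.0,
                      initial_clock_phase=0.0, multi_day_pause_prob=0.0,
                      classification_threshold=60.0)  # allow a 30 min lag
    ped, lp, events, truth = run_simulation(cfg)
    # expected clutch length ~ span/lag + 1 = 11
    lengths = []
    for p in truth.true_pause_days:
        if len(p) >= 2:
            lengths.append(np.mean(np.diff(p) - 1))
    assert np.mean(lengths) == pytest.approx(11, abs=1)


@pytest.mark.parametrize("label", ["RIR-like", "WL-like"])
def test_presets_validate_with_psd_covariances(label):
    cfg = preset_configs(label)
    assert np.linalg.eigvalsh(cfg.G).min() >= -1e-12
    assert np.linalg.eigvalsh(cfg.P).min() >= -1e-12
    cfg.validate()


def test_preset_line_specific_values():
    rir = preset_configs("RIR-like")
    wl = preset_configs("WL-like")
    assert rir.sensor_failure_rate == pytest.approx(0.043)
    assert wl.sensor_failure_rate == pytest.approx(0.112)
    assert wl.n_nests == 120 and wl.n_rows == 2
    assert rir.classification_threshold == 180.0
    assert wl.classification_threshold == 195.0


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        preset_configs("leghorn")


def test_config_validation_catches_bad_values():
    cfg = preset_configs("RIR-like")
    with pytest.raises(ValueError, match="recording_days"):
        cfg.replace(recording_days=30).validate()
    with pytest.raises(ValueError, match="sensor_failure_rate"):
        cfg.replace(sensor_failure_rate=1.4).validate()
    bad_g = np.array(cfg.G).copy()
    bad_g[0, 1] = 5.0
    with pytest.raises(ValueError, match="symmetric"):
        cfg.replace(G=bad_g).validate()
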