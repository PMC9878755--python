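import numpy as np
import pandas as pd
import pytest

from hennest import (DerivationConfig, build_A, days_alive_from_truth,
                     derive_all, preset_configs, run_simulation)
from hennest.pipeline import derivation_config_for, hatch_date_frame


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down red-line flock: 150 hens, 24 weeks of recording."""
    cfg = preset_configs("RIR-like", seed=11)
    return cfg.replace(n_sires=15, n_dams=50, recording_days=168)


@pytest.fixture(scope="session")
def small_flock(small_cfg):
    return run_simulation(small_cfg)


@pytest.fixture(scope="session")
def small_dcfg(small_cfg):
    return derivation_config_for(small_cfg, "RIR-like")


@pytest.fixture(scope="session")
def small_traits(small_cfg, small_flock, small_dcfg):
    ped, lp, events, truth = small_flock
    da = days_alive_from_truth(truth, small_dcfg)
    traits, periods = derive_all(events, small_dcfg, da)
    traits = traits.merge(hatch_date_frame(lp, small_cfg), on="hen_id")
    periods = periods.merge(hatch_date_frame(lp, small_cfg), on="hen_id")
    return traits, periods


@pytest.fixture(scope="session")
def small_rel(small_flock):
    ped = small_flock[0]
    return build_A(ped)


@pytest.fixture()
def dcfg_loose():
    """Thresholds relaxed so tiny hand-built examples are not filtered."""
    return DerivationConfig(min_records=1, pnl_min_eggs=1, total_nests=100)


def halfsib_data(n_sires=40, progeny=8, h2=0.4, seed=5, n_traits=1,
                 r_a=0.6, r_e=0.2):
    """Balanced paternal half-sib families with known variance components.

    Returns (pedigree frame, phenotype frame); dams unknown, so the only
    covariance is 0.25 * sigma2_a within sire families.
    """
    rng = np.random.default_rng(seed)
    sires = np.arange(1, n_sires + 1)
    off = np.arange(n_sires + 1, n_sires + 1 + n_sires * progeny)
    ped = pd.DataFrame({
        "id": np.concatenate([sires, off]),
        "sire": np.concatenate([np.zeros(n_sires, int),
                                np.repeat(sires, progeny)]),
        "dam": 0})
    t = n_traits
    if t == 1:
        G0 = np.array([[h2]])
        R0 = np.array([[1 - h2]])
    else:
        G0 = np.array([[h2, r_a * h2], [r_a * h2, h2]])
        R0 = np.array([[1 - h2, r_e * (1 - h2)], [r_e * (1 - h2), 1 - h2]])
    cg = np.linalg.cholesky(G0)
    cr = np.linalg.cholesky(R0)
    a_sire = rng.standard_normal((n_sires, t)) @ cg.T
    # offspring additive value: sire/2 + (3/4) Mendelian+dam part
    a_off = (np.repeat(a_sire, progeny, axis=0) / 2
             + np.sqrt(0.75) * rng.standard_normal((len(off), t)) @ cg.T)
    y = a_off + rng.standard_normal((len(off), t)) @ cr.T
    data = pd.DataFrame({"hen_id": off})
    for j in range(t):
        data[f"y{j + 1}"] = y[:, j]
    return ped, data
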