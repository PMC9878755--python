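"""End-to-end orchestration: simulate -> derive -> normalize -> estimate
-> periods, with one config, one seed, and a run manifest.

A single global seed is fanned out per stage inside the generator
(``SeedSequence`` children, documented in :mod:`hennest.simulate`); every
other stage is deterministic, so re-running with the same manifest
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from . import __version__
from .genetics import ModelSpec, build_A, reml_fit, summarize_estimates
from .normalize import normalize_traits
from .periods import (DURATION_TRAITS, fit_period_models, fit_repeatability,
                      lsmeans_and_ztests)
from .simulate import SimulationConfig, preset_configs, run_simulation
from .traits import DerivationConfig, days_alive_from_truth, derive_all

logger = logging.getLogger("hennest")

#: the nine whole-period traits entering the genetic analysis
ANALYSIS_TRAITS = ["LRN", "CN", "MOT", "MDN", "PNL", "MLD", "MDB", "MDA",
                   "NAL"]


@dataclass
class RunManifest:
    """What a run did: config digest, seed, versions, per-stage record
    counts and output paths."""

    seed: int
    config_hash: str
    version: str = ""
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def config_hash(cfg: SimulationConfig) -> str:
    payload = repr(dataclasses.asdict(cfg)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def derivation_config_for(cfg: SimulationConfig,
                          line_label: str | None = None) -> DerivationConfig:
    """Derivation thresholds matched to a simulation config (pen size,
    line-specific clock threshold, last-period usability)."""
    return DerivationConfig(
        clock_decrease_threshold=cfg.classification_threshold,
        total_nests=cfg.n_nests,
        recording_days=cfg.recording_days,
        drop_last_period=bool(line_label and line_label.startswith("RIR")),
    ).validate()


def hatch_date_frame(lp, cfg: SimulationConfig) -> pd.DataFrame:
    labels = np.array([lab for lab, _ in cfg.hatch_dates])
    return pd.DataFrame({"hen_id": lp.hen_ids,
                         "hatch_date": labels[lp.hatch_batch]})


def run_all(config: SimulationConfig | str, out_dir, seed: int | None = None,
            pairs: str | list = "all", with_periods: bool = True,
            line_label: str | None = None) -> RunManifest:
    """Run the whole pipeline and leave all artifacts in ``out_dir``.

    ``config`` may be a preset label (``RIR-like``/``WL-like``) or a full
    :class:`SimulationConfig`.  ``pairs`` selects the bivariate fits:
    ``"all"`` (every pair of analysis traits), a list of ``(i, j)`` trait
    name tuples, or ``"none"``.
    """
    if isinstance(config, str):
        line_label = line_label or config
        config = preset_configs(config, seed=seed or 0)
    elif seed is not None:
        config = config.replace(seed=seed)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(seed=config.seed, config_hash=config_hash(config),
                      version=__version__)

    # --- simulate ----------------------------------------------------------
    ped, lp, events, truth = run_simulation(config)
    hio.write_events(events, out / "events.csv")
    hio.write_pedigree(ped, out / "pedigree.csv")
    truth.to_frame().to_csv(out / "truth.csv", index=False)
    hatch = hatch_date_frame(lp, config)
    hatch.to_csv(out / "hens.csv", index=False)
    man.stages["simulate"] = {"hens": len(lp), "visits": len(events),
                              "pedigree": len(ped)}

    # --- derive ------------------------------------------------------------
    dcfg = derivation_config_for(config, line_label)
    da = days_alive_from_truth(truth, dcfg)
    traits_df, periods_df = derive_all(events, dcfg, da,
                                       with_periods=with_periods)
    hio.write_traits(traits_df, out / "traits.csv")
    if periods_df is not None:
        hio.write_traits(periods_df, out / "traits_periods.csv")
    man.stages["derive"] = {"hens_analyzed": len(traits_df),
                            "period_rows": 0 if periods_df is None
                            else len(periods_df)}

    # --- normalize ---------------------------------------------------------
    merged = traits_df.merge(hatch, on="hen_id")
    normed = normalize_traits(merged, ANALYSIS_TRAITS)
    hio.write_traits(normed.reindex(columns=hio.TRAIT_COLUMNS),
                     out / "traits_normalized.csv")
    man.stages["normalize"] = {
        "traits_kept": sum(c in normed.columns for c in ANALYSIS_TRAITS)}

    # --- estimate ----------------------------------------------------------
    rel = build_A(ped)
    kept = [c for c in ANALYSIS_TRAITS if c in normed.columns]
    fits = []
    for trait in kept:
        try:
            fits.append(reml_fit(normed, ModelSpec(traits=[trait]), rel))
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("univariate fit %s failed: %s", trait, err)
    if pairs == "all":
        pair_list = list(itertools.combinations(kept, 2))
    elif pairs == "none":
        pair_list = []
    else:
        pair_list = [tuple(p) for p in pairs]
    for ti, tj in pair_list:
        try:
            fits.append(reml_fit(normed, ModelSpec(traits=[ti, tj]), rel))
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("bivariate fit %s-%s failed: %s", ti, tj, err)
    est_df = pd.concat([f.to_frame() for f in fits], ignore_index=True) \
        if fits else pd.DataFrame(columns=hio.ESTIMATE_COLUMNS)
    hio.write_estimates(est_df, out / "estimates.csv")
    man.stages["estimate"] = {"fits": len(fits)}

    # --- periods -----------------------------------------------------------
    if with_periods and periods_df is not None and len(periods_df):
        pmerged = periods_df.merge(hatch, on="hen_id")
        pmodels = fit_period_models(pmerged, rel)
        rows = []
        for trait in DURATION_TRAITS:
            try:
                fit = fit_repeatability(pmerged, trait, rel)
            except ValueError as err:
                logger.warning("repeatability fit %s failed: %s", trait, err)
                continue
            res = lsmeans_and_ztests(fit, pmodels)
            df = res.to_frame()
            df.insert(0, "trait", trait)
            rows.append(df)
        per_df = pd.concat(rows, ignore_index=True) if rows else \
            pd.DataFrame()
        per_df.to_csv(out / "periods.csv", index=False)
        man.stages["periods"] = {"rows": len(per_df)}

    man.outputs = {p.name: str(p) for p in sorted(out.glob("*.csv"))}
    man.save(out / "manifest.json")
    logger.info("run_all complete out_dir=%s", out)
    return man


# ---------------------------------------------------------------------------
# validation protocols: calibration summaries and parameter recovery
# ---------------------------------------------------------------------------

def simulate_and_derive(line_label: str, seed: int):
    """One preset flock taken through simulation and trait derivation.

    Returns ``(traits+hatch frame, relationship matrix, truth, config)``.
    """
    cfg = preset_configs(line_label, seed=seed)
    ped, lp, events, truth = run_simulation(cfg)
    dcfg = derivation_config_for(cfg, line_label)
    da = days_alive_from_truth(truth, dcfg)
    traits_df, _ = derive_all(events, dcfg, da, with_periods=False)
    traits_df = traits_df.merge(hatch_date_frame(lp, cfg), on="hen_id")
    return traits_df, build_A(ped), truth, cfg


def calibration_summary(line_label: str, seed: int) -> dict:
    """Whole-flock trait summaries of one preset run, on the scales the
    field reports them: NAL as a percentage of analysed hens, LRN as the
    mean over qualifying hens, CN as mean clutches."""
    traits_df, _, _, _ = simulate_and_derive(line_label, seed)
    return {
        "n_analyzed": len(traits_df),
        "nal_percent": 100.0 * traits_df["NAL"].mean(),
        "lrn_mean": traits_df["LRN"].mean(),
        "cn_mean": traits_df["CN"].mean(),
        "n_lrn": int(traits_df["LRN"].notna().sum()),
        "n_cn": int(traits_df["CN"].notna().sum()),
    }


def heritability_recovery(seeds, line_label: str = "RIR-like",
                          traits=("MDN", "MLD", "PNL"),
                          pair=("MDN", "PNL")) -> dict:
    """Simulate replicate flocks and re-estimate the preset's true genetic
    parameters through the full pipeline (derive -> rank-normalise ->
    REML animal model with hatch-date fixed effect).

    Returns per-trait heritability estimates across replicates, the
    bivariate genetic correlation of ``pair``, and replicate sizes.
    """
    out = {t: [] for t in traits}
    out["r_a"] = []
    out["n"] = []
    for seed in seeds:
        traits_df, rel, _, _ = simulate_and_derive(line_label, seed)
        normed = normalize_traits(traits_df, list(dict.fromkeys(
            list(traits) + list(pair))))
        for t in traits:
            est = reml_fit(normed, ModelSpec(traits=[t]), rel)
            out[t].append(float(est.h2[0]))
        biv = reml_fit(normed, ModelSpec(traits=list(pair)), rel)
        out["r_a"].append(float(biv.r_a[0, 1]))
        out["n"].append(int(biv.n_records))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _summary_block(traits_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for c in ANALYSIS_TRAITS:
        if c not in traits_df.columns:
            continue
        v = traits_df[c].dropna()
        rows.append((c, len(v), v.mean(), v.std(), v.min(), v.max()))
    return pd.DataFrame(rows,
                        columns=["trait", "n", "mean", "SD", "min", "max"])


def report(manifest: RunManifest) -> str:
    """Human-readable run summary: per-trait summary statistics, the
    heritability/correlation triangle, and period LS-means."""
    lines = [f"hennest run (seed={manifest.seed}, "
             f"config={manifest.config_hash}, v{manifest.version})", ""]
    for stage, counts in manifest.stages.items():
        kv = " ".join(f"{k}={v}" for k, v in counts.items())
        lines.append(f"stage {stage}: {kv}")
    lines.append("")

    tpath = manifest.outputs.get("traits.csv")
    if tpath and Path(tpath).exists():
        tdf = hio.read_traits(tpath)
        lines.append("trait summaries (n / mean / SD / min / max):")
        lines.append(_summary_block(tdf).round(2).to_string(index=False))
        lines.append("")

    epath = manifest.outputs.get("estimates.csv")
    if epath and Path(epath).exists():
        est = hio.read_estimates(epath)
        if len(est):
            traits = [t for t in ANALYSIS_TRAITS
                      if t in set(est["trait_i"]) | set(est["trait_j"])]
            val = pd.DataFrame(np.nan, index=traits, columns=traits)
            for _, r in est.iterrows():
                if r["parameter"] == "h2":
                    val.loc[r["trait_i"], r["trait_i"]] = r["value"]
                elif r["parameter"] == "r_a":
                    val.loc[r["trait_i"], r["trait_j"]] = r["value"]
                elif r["parameter"] == "r_p":
                    val.loc[r["trait_j"], r["trait_i"]] = r["value"]
            lines.append("h2 (diagonal), genetic correlations (above), "
                         "phenotypic correlations (below):")
            lines.append(val.round(2).to_string())
            lines.append("")

    ppath = manifest.outputs.get("periods.csv")
    if ppath and Path(ppath).exists():
        pdf = pd.read_csv(ppath)
        if len(pdf):
            lines.append("period least-square means "
                         "(deviation from final period):")
            lines.append(pdf.round(3).to_string(index=False))
    return "\n".join(lines) + "\n"
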