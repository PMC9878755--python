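"""Per-28-day-period genetic analysis of the laying-duration traits.

Two complementary analyses, both on the raw (unnormalised) scale because
within-period duration means are close to normal:

* per-period three-trait animal-model fits (MLD, MDB, MDA) via
  :func:`hennest.genetics.reml_fit`, giving age trajectories of additive
  and residual variances and heritabilities;
* a repeatability animal model per trait across all (hen, period) records
  — fixed hatch date and period effects, random additive and permanent
  environment effects — whose period solutions are the least-square means,
  expressed as deviations from the final period (set to 0).

Period least-square means and variance components are compared across
periods with two-tailed z-tests, significant when |z| > 2.58 (alpha=0.01),
and summarised with a compact-letter display.

The repeatability fit uses balanced complete cases (hens with a record in
every analysed period).  The pedigree eigendecomposition combined with a
within-hen orthonormal rotation (first direction = the period mean) then
diagonalises all three covariance structures, so EM-REML iterations are
closed-form scalar updates and the restricted likelihood is monotone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import GeneticEstimate, ModelSpec, RelationshipMatrix, reml_fit

logger = logging.getLogger("hennest")

Z_CRITICAL = 2.58          # two-tailed, alpha = 0.01

DURATION_TRAITS = ["MLD", "MDB", "MDA"]


# ---------------------------------------------------------------------------
# per-period multi-trait fits
# ---------------------------------------------------------------------------

def fit_period_models(period_traits: pd.DataFrame, rel: RelationshipMatrix,
                      fixed: str | None = "hatch_date",
                      traits: list[str] = None,
                      min_hens: int = 50) -> dict[int, GeneticEstimate]:
    """Three-trait animal-model REML separately for each period.

    Periods with fewer than ``min_hens`` complete-case hens are skipped
    with a log line.  Returns {period: GeneticEstimate}.
    """
    traits = traits or DURATION_TRAITS
    out = {}
    for p, g in period_traits.groupby("period", sort=True):
        cc = g.dropna(subset=traits)
        if len(cc) < min_hens:
            logger.warning("period %d skipped: %d complete hens < %d",
                           p, len(cc), min_hens)
            continue
        spec = ModelSpec(traits=traits, fixed=fixed)
        out[int(p)] = reml_fit(cc, spec, rel)
    return out


# ---------------------------------------------------------------------------
# repeatability model
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityFit:
    """Univariate repeatability animal-model fit across periods."""

    trait: str
    periods: list
    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float
    repeatability: float            # (sigma2_a + sigma2_pe) / total
    h2: float
    lsmeans: np.ndarray             # deviation from the final period
    lsmean_se: np.ndarray           # final period: deviation 0, SE 0
    fixed_effects: pd.DataFrame = None
    loglik: float = np.nan
    converged: bool = False
    n_hens: int = 0


def fit_repeatability(period_traits: pd.DataFrame, trait: str,
                      rel: RelationshipMatrix,
                      fixed: str | None = "hatch_date",
                      tol: float = 1e-8, max_iter: int = 2000,
                      min_hens: int = 30) -> RepeatabilityFit:
    """Fit ``y_hp = hatch + period + a_h + pe_h + e_hp`` by EM-REML.

    Complete cases: hens with a record for ``trait`` in every period
    present in the table.  The last period is the reference level, so the
    period fixed-effect solutions are directly the least-square-mean
    deviations from the final period.
    """
    wide = period_traits.pivot_table(index="hen_id", columns="period",
                                     values=trait)
    n_all = len(wide)
    wide = wide.dropna()
    periods = [int(p) for p in wide.columns]
    m = len(periods)
    H = len(wide)
    logger.info("fit_repeatability trait=%s n_hens=%d of %d periods=%d",
                trait, H, n_all, m)
    if H < min_hens or m < 2:
        raise ValueError(f"too few complete hens ({H}) or periods ({m})")
    hens = wide.index.to_numpy()
    Y = wide.to_numpy(float)                      # H x m

    # fixed-effect design per (hen, period) record: intercept, hatch
    # dummies (hen-level), period dummies (last absorbed)
    names = ["intercept"]
    Xcols = [np.ones((H, m))]
    if fixed is not None and fixed in period_traits.columns:
        hb = period_traits.drop_duplicates("hen_id").set_index("hen_id")[fixed]
        hb = hb.reindex(hens).astype(str)
        levels = sorted(hb.unique())
        for lev in levels[1:]:
            Xcols.append(np.tile((hb == lev).to_numpy(float)[:, None], (1, m)))
            names.append(f"{fixed}={lev}")
    for j, p in enumerate(periods[:-1]):
        col = np.zeros((H, m))
        col[:, j] = 1.0
        Xcols.append(col)
        names.append(f"period={p}")
    X = np.stack(Xcols, axis=-1)                  # H x m x p
    p_fix = X.shape[-1]

    # rotate: pedigree eigenvectors between hens, mean/contrast within hen
    K = rel.subset(hens)
    dk, U = np.linalg.eigh(K)
    dk = np.clip(dk, 1e-10, None)
    Qm, _ = np.linalg.qr(np.hstack([np.ones((m, 1)) / np.sqrt(m),
                                    np.eye(m)[:, :-1]]))
    Qm[:, 0] *= np.sign(Qm[0, 0])                 # first column = 1/sqrt(m)
    Z = U.T @ Y @ Qm
    Xr = np.einsum("hi,hmp,mj->ijp", U, X, Qm)    # rotated design

    # flatten: component records c = (i, j); random part only at j = 0
    z = Z.reshape(-1)
    Xf = Xr.reshape(-1, p_fix)
    j0 = (np.tile(np.arange(m), (H, 1)).reshape(-1) == 0)
    dvec = np.repeat(dk, m)                       # pedigree eigenvalue per record

    vy = float(np.var(Y, ddof=1))
    sa, spe, se_ = 0.4 * vy, 0.2 * vy, 0.4 * vy
    ll_prev, converged = -np.inf, False
    for it in range(max_iter):
        g_a = np.where(j0, m * dvec * sa, 0.0)    # prior var of sqrt(m)*a part
        g_pe = np.where(j0, m * spe, 0.0)
        v = g_a + g_pe + se_
        Minf = Xf.T @ (Xf / v[:, None])
        rhs = Xf.T @ (z / v)
        beta = np.linalg.solve(Minf, rhs)
        r = z - Xf @ beta
        ll = -0.5 * (np.sum(np.log(v)) + np.linalg.slogdet(Minf)[1]
                     + np.sum(r * r / v))
        if ll < ll_prev - 1e-6 * (1.0 + abs(ll_prev)):
            raise AssertionError(
                f"restricted log-likelihood decreased at iteration {it}")
        ll_prev = ll

        Minv = np.linalg.inv(Minf)
        q_c = np.einsum("cp,pq,cq->c", Xf, Minv, Xf)
        wa, wpe = g_a / v, g_pe / v
        ahat, pehat = wa * r, wpe * r
        # joint posterior second moments incl. fixed-effect uncertainty
        pev_a = g_a - wa * g_a + wa * wa * q_c
        pev_pe = g_pe - wpe * g_pe + wpe * wpe * q_c
        wtot = wa + wpe
        ehat = (1.0 - wtot) * r
        var_e = wtot * se_ + (1.0 - wtot) ** 2 * q_c

        mask = j0
        sa_new = float(np.mean(((ahat ** 2 + pev_a) / (m * dvec))[mask]))
        spe_new = float(np.mean(((pehat ** 2 + pev_pe) / m)[mask]))
        se_new = float(np.mean(ehat ** 2 + var_e))
        sa_new = max(sa_new, 1e-10)
        spe_new = max(spe_new, 1e-10)
        delta = max(abs(sa_new - sa) / (sa + 1e-10),
                    abs(spe_new - spe) / (spe + 1e-10),
                    abs(se_new - se_) / (se_ + 1e-10))
        sa, spe, se_ = sa_new, spe_new, se_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_repeatability trait=%s not converged "
                       "(last change %.2e)", trait, delta)

    # final GLS pass for fixed effects and their covariance
    g_a = np.where(j0, m * dvec * sa, 0.0)
    g_pe = np.where(j0, m * spe, 0.0)
    v = g_a + g_pe + se_
    Minf = Xf.T @ (Xf / v[:, None])
    beta = np.linalg.solve(Minf, Xf.T @ (z / v))
    Minv = np.linalg.inv(Minf)

    idx_period = [names.index(f"period={p}") for p in periods[:-1]]
    ls = np.zeros(m)
    ls_se = np.zeros(m)
    ls[:-1] = beta[idx_period]
    ls_se[:-1] = np.sqrt(np.diag(Minv)[idx_period])
    total = sa + spe + se_
    fit = RepeatabilityFit(
        trait=trait, periods=periods, sigma2_a=sa, sigma2_pe=spe,
        sigma2_e=se_, repeatability=(sa + spe) / total, h2=sa / total,
        lsmeans=ls, lsmean_se=ls_se,
        fixed_effects=pd.DataFrame({"effect": names, "estimate": beta,
                                    "se": np.sqrt(np.diag(Minv))}),
        loglik=float(ll_prev), converged=converged, n_hens=H)
    return fit


# ---------------------------------------------------------------------------
# z-tests and compact-letter display
# ---------------------------------------------------------------------------

def z_matrix(values: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Pairwise two-sample z statistics, z_pq = (v_p - v_q)/sqrt(se_p^2+se_q^2)."""
    v = np.asarray(values, float)
    s = np.asarray(ses, float)
    denom = np.sqrt(s[:, None] ** 2 + s[None, :] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (v[:, None] - v[None, :]) / denom
    z[denom == 0] = 0.0
    return z


def compact_letters(values: np.ndarray, significant: np.ndarray) -> list[str]:
    """Compact-letter display by insert-and-absorb.

    Start with one letter covering every group; for each significantly
    different pair split any letter containing both; absorb letters that
    became subsets of others.  Groups sharing no letter differ
    significantly; groups sharing a letter do not.
    """
    k = len(values)
    letters = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for L in [L for L in letters if i in L and j in L]:
                letters.remove(L)
                letters.extend([L - {i}, L - {j}])
            letters = [L for L in letters
                       if not any(L < M for M in letters)]
    letters = [L for L in letters if L]
    letters.sort(key=lambda L: (min(values[list(L)]), sorted(L)))
    label = {}
    for pos, L in enumerate(letters):
        ch = chr(ord("a") + pos)
        for g in L:
            label.setdefault(g, []).append(ch)
    return ["".join(sorted(label.get(g, []))) for g in range(k)]


@dataclass
class PeriodResult:
    """Period-wise summary: variance-component trajectories, LS-mean
    deviations from the final period, z statistics and letters."""

    trait: str
    periods: list
    lsmeans: np.ndarray
    lsmean_se: np.ndarray
    z: np.ndarray
    letters: list
    sigma2_a: np.ndarray = None      # from the per-period models, if given
    sigma2_e: np.ndarray = None
    h2: np.ndarray = None
    h2_se: np.ndarray = None
    repeatability: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        d = {"period": self.periods, "lsmean": self.lsmeans,
             "lsmean_se": self.lsmean_se, "letters": self.letters}
        for name in ("sigma2_a", "sigma2_e", "h2", "h2_se"):
            val = getattr(self, name)
            if val is not None:
                d[name] = val
        return pd.DataFrame(d)


def lsmeans_and_ztests(fit: RepeatabilityFit,
                       period_models: dict[int, GeneticEstimate] | None = None,
                       ) -> PeriodResult:
    """Assemble the period summary: z-tests on LS-mean deviations and, when
    per-period fits are supplied, the variance-component trajectories."""
    z = z_matrix(fit.lsmeans, fit.lsmean_se)
    sig = np.abs(z) > Z_CRITICAL
    letters = compact_letters(fit.lsmeans, sig)
    res = PeriodResult(trait=fit.trait, periods=fit.periods,
                       lsmeans=fit.lsmeans, lsmean_se=fit.lsmean_se,
                       z=z, letters=letters,
                       repeatability=fit.repeatability)
    if period_models:
        ti = None
        sa, se_, h2, h2se = [], [], [], []
        for p in fit.periods:
            est = period_models.get(p)
            if est is None:
                sa.append(np.nan); se_.append(np.nan)
                h2.append(np.nan); h2se.append(np.nan)
                continue
            if ti is None:
                ti = est.traits.index(fit.trait)
            sa.append(est.G0[ti, ti]); se_.append(est.R0[ti, ti])
            h2.append(est.h2[ti]); h2se.append(est.se["h2"][ti])
        res.sigma2_a = np.array(sa)
        res.sigma2_e = np.array(se_)
        res.h2 = np.array(h2)
        res.h2_se = np.array(h2se)
    return res
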