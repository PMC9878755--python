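"""Pedigree relationship matrices and REML for the multi-trait animal model.

The model is the standard animal model: for hen ``i`` and trait vector
``y_i`` (t traits), ``y_i = X_i b + a_i + e_i`` with ``var(a) = A (x) G0``
over the pedigree (A the numerator relationship matrix, G0 the t x t
additive covariance) and ``var(e_i) = R0``.  The hen's hatch date enters as
a fixed effect; analyses use complete cases for the requested trait subset,
so the published nine-trait analysis is reproduced as univariate fits (for
heritabilities) plus all bivariate fits (for correlations).

Estimation is EM-REML iterated to convergence.  Internally the phenotyped
block of the relationship matrix is eigendecomposed once
(``K = U D U'``); rotating phenotypes and design by ``U`` makes every EM
step a set of independent t x t operations with the *same* restricted
likelihood as mixed-model-equation EM, so the restricted log-likelihood is
monotone by construction (asserted every iteration).  A single
average-information (AI) iteration at the optimum supplies the information
matrix; standard errors of heritabilities and correlations follow by the
delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ESTIMATE_COLUMNS

logger = logging.getLogger("hennest")


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A over a pedigree order."""

    ids: np.ndarray
    A: np.ndarray

    def index_of(self, ids) -> np.ndarray:
        pos = {int(i): k for k, i in enumerate(self.ids)}
        try:
            return np.array([pos[int(i)] for i in ids])
        except KeyError as err:
            raise KeyError(f"individual {err} not in pedigree") from err

    def subset(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.A[np.ix_(idx, idx)]


def build_A(ped: pd.DataFrame) -> RelationshipMatrix:
    """Tabular (recursive) construction of A.

    ``A_ii = 1 + A_{sire,dam}/2``; ``A_ij = (A_{j,sire(i)} + A_{j,dam(i)})/2``
    for j earlier in the (parents-first) order; unknown parents contribute 0.
    """
    ids = ped["id"].to_numpy()
    q = len(ids)
    pos = {int(i): k for k, i in enumerate(ids)}
    # index q acts as a zero-contribution virtual parent
    sp = np.array([pos.get(int(s), q) for s in ped["sire"]])
    dp = np.array([pos.get(int(d), q) for d in ped["dam"]])
    idx = np.arange(q)
    if (((sp < q) & (sp >= idx)) | ((dp < q) & (dp >= idx))).any():
        raise ValueError("pedigree is not ordered parents-before-offspring")
    A = np.zeros((q + 1, q + 1))
    for i in range(q):
        s, d = sp[i], dp[i]
        A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
        A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + 0.5 * A[s, d]
    return RelationshipMatrix(ids=ids, A=A[:q, :q])


def build_A_inverse(ped: pd.DataFrame) -> np.ndarray:
    """A-inverse by Henderson's rules (no-inbreeding variant).

    If the pedigree turns out to be inbred (A diagonal above 1) the rules
    are inexact, so the function falls back to dense inversion with a
    warning.
    """
    rel = build_A(ped)
    if np.any(np.diag(rel.A) > 1.0 + 1e-8):
        logger.warning("inbred pedigree detected; using dense inversion "
                       "instead of Henderson's rules")
        return np.linalg.inv(rel.A)
    ids = ped["id"].to_numpy()
    q = len(ids)
    pos = {int(i): k for k, i in enumerate(ids)}
    Ainv = np.zeros((q, q))
    for i in range(q):
        parents = [pos[p] for p in
                   (int(ped["sire"].iat[i]), int(ped["dam"].iat[i])) if p != 0]
        b = {0: 1.0, 1: 4.0 / 3.0, 2: 2.0}[len(parents)]
        Ainv[i, i] += b
        for p in parents:
            Ainv[i, p] -= b / 2.0
            Ainv[p, i] -= b / 2.0
            for p2 in parents:
                Ainv[p, p2] += b / 4.0
    return Ainv


# ---------------------------------------------------------------------------
# model specification and results
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to fit: traits, fixed effect, convergence control."""

    traits: list
    fixed: str | None = "hatch_date"
    tol: float = 1e-8
    max_iter: int = 2000
    min_joint_hens: int = 50


@dataclass
class GeneticEstimate:
    """Variance components and derived genetic parameters with SEs."""

    traits: list
    G0: np.ndarray                 # additive covariance (t x t)
    R0: np.ndarray                 # residual covariance (t x t)
    h2: np.ndarray                 # per-trait heritability
    r_a: np.ndarray                # genetic correlations (t x t, diag 1)
    r_e: np.ndarray
    r_p: np.ndarray                # phenotypic correlations via r_p identity
    se: dict = field(default_factory=dict)   # {"h2":…, "r_a":…, "G0":…, …}
    loglik: float = np.nan
    loglik_trace: np.ndarray = None
    converged: bool = False
    bended: bool = False
    n_records: int = 0
    fixed_effects: pd.DataFrame | None = None
    sigma2_pe: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        t = len(self.traits)
        for i, tr in enumerate(self.traits):
            rows.append((tr, tr, "h2", self.h2[i], self.se["h2"][i]))
            rows.append((tr, tr, "sigma2_a", self.G0[i, i],
                         self.se["G0"][i, i]))
            rows.append((tr, tr, "sigma2_e", self.R0[i, i],
                         self.se["R0"][i, i]))
        for i in range(t):
            for j in range(i + 1, t):
                a, b = self.traits[i], self.traits[j]
                rows.append((a, b, "r_a", self.r_a[i, j], self.se["r_a"][i, j]))
                rows.append((a, b, "r_e", self.r_e[i, j], self.se["r_e"][i, j]))
                rows.append((a, b, "r_p", self.r_p[i, j], self.se["r_p"][i, j]))
        return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def phenotypic_correlation(h2_i: float, h2_j: float, r_a: float,
                           r_e: float, e2_i: float, e2_j: float) -> float:
    """Phenotypic correlation from its genetic and residual parts:
    ``r_p = h_i h_j r_a + e_i e_j r_e`` with h, e the square roots of the
    heritability and of the residual variance fraction."""
    r_p = (np.sqrt(h2_i * h2_j) * r_a + np.sqrt(e2_i * e2_j) * r_e)
    if abs(r_p) > 1.0 + 1e-9:
        raise ValueError(f"|r_p| = {abs(r_p):.6f} > 1; inconsistent inputs")
    return float(np.clip(r_p, -1.0, 1.0))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _design(data: pd.DataFrame, fixed: str | None):
    """Intercept + treatment-coded fixed effect (first level absorbed);
    redundant columns dropped with a warning."""
    n = len(data)
    X = np.ones((n, 1))
    names = ["intercept"]
    if fixed is not None and fixed in data.columns:
        levels = sorted(data[fixed].astype(str).unique())
        if len(levels) < 2:
            logger.warning("fixed effect %r has < 2 levels; dropped", fixed)
        else:
            for lev in levels[1:]:
                X = np.hstack([X, (data[fixed].astype(str) == lev)
                               .to_numpy(float)[:, None]])
                names.append(f"{fixed}={lev}")
    # drop columns that do not add rank (singular design)
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping redundant fixed-effect column %r",
                           names[j])
    return X[:, keep], [names[j] for j in keep]


# ---------------------------------------------------------------------------
# EM-REML in the eigenrotated space
# ---------------------------------------------------------------------------

def _sym(M):
    return (M + M.swapaxes(-1, -2)) / 2.0


def _bend(M, floor=1e-6):
    w, V = np.linalg.eigh(_sym(M))
    if w.min() >= floor:
        return M, False
    w = np.clip(w, floor, None)
    return (V * w) @ V.T, True


def _gls(dk, Xs, Ys, G0, R0):
    """GLS solve in the rotated space; returns per-record inverses,
    residuals and the fixed-effect information matrix."""
    n, p = Xs.shape
    t = Ys.shape[1]
    Vi = dk[:, None, None] * G0[None] + R0[None]
    Viinv = np.linalg.inv(Vi)
    M = np.einsum("ij,ik,its->jtks", Xs, Xs, Viinv).reshape(p * t, p * t)
    rhs = np.einsum("ij,its,is->jt", Xs, Viinv, Ys).reshape(p * t)
    B = np.linalg.solve(M, rhs).reshape(p, t)
    r = Ys - Xs @ B
    return Vi, Viinv, M, B, r


def _restricted_ll(Vi, Viinv, M, r):
    sign, ld_v = np.linalg.slogdet(Vi)
    if np.any(sign <= 0):
        return -np.inf
    _, ld_m = np.linalg.slogdet(M)
    quad = np.einsum("ia,iab,ib->", r, Viinv, r)
    return -0.5 * (ld_v.sum() + ld_m + quad)


def reml_fit(data: pd.DataFrame, spec: ModelSpec,
             rel: RelationshipMatrix) -> GeneticEstimate:
    """EM-REML fit of the (multi-)trait animal model on complete cases.

    ``data`` holds ``hen_id``, the trait columns and (optionally) the fixed
    effect column.  Hens must be in the pedigree behind ``rel``.
    """
    traits = list(spec.traits)
    t = len(traits)
    cols = ["hen_id"] + traits + ([spec.fixed] if spec.fixed and
                                  spec.fixed in data.columns else [])
    cc = data[cols].dropna(subset=traits)
    logger.info("reml_fit traits=%s n_complete=%d of %d",
                traits, len(cc), len(data))
    if t >= 2 and len(cc) < spec.min_joint_hens:
        raise ValueError(
            f"only {len(cc)} jointly phenotyped hens for {traits}; "
            f"need >= {spec.min_joint_hens}")
    if len(cc) < 3:
        raise ValueError("too few records to fit")

    Y = cc[traits].to_numpy(float)
    X, xnames = _design(cc, spec.fixed)
    K = rel.subset(cc["hen_id"].to_numpy())
    dk, U = np.linalg.eigh(K)
    dk = np.clip(dk, 1e-10, None)
    Ys, Xs = U.T @ Y, U.T @ X
    n, p = Xs.shape

    vp = np.var(Y, axis=0, ddof=1)
    G0 = np.diag(0.5 * vp)
    R0 = np.diag(0.5 * vp)
    It = np.eye(t)

    ll_trace = []
    ll_prev = -np.inf
    converged = False
    bended_any = False
    for it in range(spec.max_iter):
        Vi, Viinv, M, B, r = _gls(dk, Xs, Ys, G0, R0)
        ll = _restricted_ll(Vi, Viinv, M, r)
        if ll < ll_prev - 1e-6 * (1.0 + abs(ll_prev)):
            raise AssertionError(
                f"restricted log-likelihood decreased at iteration {it}: "
                f"{ll_prev:.8f} -> {ll:.8f}")
        ll_trace.append(ll)
        ll_prev = ll

        Minv4 = np.linalg.inv(M).reshape(p, t, p, t)
        W = dk[:, None, None] * np.einsum("ab,ibc->iac", G0, Viinv)
        ghat = np.einsum("iab,ib->ia", W, r)
        S = np.einsum("iab,bc->iac", W, R0)
        Q = np.einsum("ij,ik,jtks->its", Xs, Xs, Minv4)
        PEV = S + np.einsum("iab,ibc,idc->iad", W, Q, W)
        ImW = It[None] - W
        Var = S + np.einsum("iab,ibc,idc->iad", ImW, Q, ImW)
        ehat = r - ghat

        G0_new = _sym(np.mean(
            (np.einsum("ia,ib->iab", ghat, ghat) + PEV)
            / dk[:, None, None], axis=0))
        R0_new = _sym(np.mean(
            np.einsum("ia,ib->iab", ehat, ehat) + Var, axis=0))
        G0_new, b1 = _bend(G0_new)
        R0_new, b2 = _bend(R0_new)
        bended_any |= (b1 or b2)

        delta = max(
            np.max(np.abs(G0_new - G0) / (np.abs(G0) + 1e-10)),
            np.max(np.abs(R0_new - R0) / (np.abs(R0) + 1e-10)))
        G0, R0 = G0_new, R0_new
        if delta < spec.tol:
            converged = True
            break
    if not converged:
        logger.warning("reml_fit did not converge in %d iterations "
                       "(last relative change %.2e)", spec.max_iter, delta)
    if bended_any:
        logger.info("reml_fit PSD bending applied during iteration")

    Vi, Viinv, M, B, r = _gls(dk, Xs, Ys, G0, R0)
    ll = _restricted_ll(Vi, Viinv, M, r)
    se = _ai_standard_errors(dk, Xs, Viinv, M, r, G0, R0)

    h2 = np.diag(G0) / (np.diag(G0) + np.diag(R0))
    r_a = _cov2corr(G0)
    r_e = _cov2corr(R0)
    r_p = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            r_p[i, j] = r_p[j, i] = phenotypic_correlation(
                h2[i], h2[j], r_a[i, j], r_e[i, j], 1 - h2[i], 1 - h2[j])

    fixed_df = pd.DataFrame(
        {"effect": [f"{nm}:{tr}" for nm in xnames for tr in traits],
         "estimate": B.reshape(-1)})
    est = GeneticEstimate(
        traits=traits, G0=G0, R0=R0, h2=h2, r_a=r_a, r_e=r_e, r_p=r_p,
        se=se, loglik=float(ll), loglik_trace=np.array(ll_trace),
        converged=converged, bended=bended_any, n_records=n,
        fixed_effects=fixed_df)
    return est


def _cov2corr(C):
    d = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    return C / np.outer(d, d)


def _param_list(t):
    """vech index pairs for (G0, R0)."""
    return [("G", a, b) for a in range(t) for b in range(a, t)] + \
           [("R", a, b) for a in range(t) for b in range(a, t)]


def _ai_standard_errors(dk, Xs, Viinv, M, r, G0, R0):
    """One average-information iteration at the optimum -> SEs.

    AI_kl = y'P V_k P V_l P y / 2 evaluated via the rotated representation;
    SEs of heritabilities and correlations follow by a (numerical) delta
    method on the inverse AI matrix.
    """
    n, p = Xs.shape
    t = r.shape[1]
    params = _param_list(t)
    Py = np.einsum("iab,ib->ia", Viinv, r)

    def _project(wv):
        # P w = Vinv w - Vinv X (X'Vinv X)^-1 X'Vinv w
        q = np.einsum("iab,ib->ia", Viinv, wv)
        xt = np.einsum("ij,it->jt", Xs, q).reshape(p * t)
        delta = np.linalg.solve(M, xt).reshape(p, t)
        return np.einsum("iab,ib->ia", Viinv, wv - Xs @ delta)

    w_list, pw_list = [], []
    for comp, a, b in params:
        E = np.zeros((t, t))
        E[a, b] = E[b, a] = 1.0
        coef = dk if comp == "G" else np.ones_like(dk)
        wv = coef[:, None] * (Py @ E.T)
        w_list.append(wv)
        pw_list.append(_project(wv))
    m = len(params)
    AI = np.empty((m, m))
    for k in range(m):
        for l in range(k, m):
            AI[k, l] = AI[l, k] = 0.5 * np.sum(w_list[k] * pw_list[l])
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        logger.warning("AI matrix singular; using pseudo-inverse for SEs")
        cov = np.linalg.pinv(AI)

    def _unpack(theta):
        Gm = np.zeros((t, t))
        Rm = np.zeros((t, t))
        for val, (comp, a, b) in zip(theta, params):
            Mref = Gm if comp == "G" else Rm
            Mref[a, b] = Mref[b, a] = val
        return Gm, Rm

    def _summaries(theta):
        Gm, Rm = _unpack(theta)
        h2 = np.diag(Gm) / (np.diag(Gm) + np.diag(Rm))
        out = list(h2)
        for i in range(t):
            for j in range(i + 1, t):
                ra = Gm[i, j] / np.sqrt(abs(Gm[i, i] * Gm[j, j]) + 1e-300)
                re = Rm[i, j] / np.sqrt(abs(Rm[i, i] * Rm[j, j]) + 1e-300)
                rp = (np.sqrt(abs(h2[i] * h2[j])) * ra
                      + np.sqrt(abs((1 - h2[i]) * (1 - h2[j]))) * re)
                out.extend([ra, re, rp])
        return np.array(out)

    theta0 = np.array([(G0 if c == "G" else R0)[a, b] for c, a, b in params])
    scale = np.maximum(np.abs(theta0), 1e-8)
    J = np.empty((len(_summaries(theta0)), m))
    for k in range(m):
        hstep = 1e-6 * scale[k]
        tp, tm = theta0.copy(), theta0.copy()
        tp[k] += hstep
        tm[k] -= hstep
        J[:, k] = (_summaries(tp) - _summaries(tm)) / (2 * hstep)
    var_sum = np.einsum("ik,kl,il->i", J, cov, J)
    se_sum = np.sqrt(np.clip(var_sum, 0.0, None))

    se_h2 = se_sum[:t]
    se_ra = np.zeros((t, t))
    se_re = np.zeros((t, t))
    se_rp = np.zeros((t, t))
    pos = t
    for i in range(t):
        for j in range(i + 1, t):
            se_ra[i, j] = se_ra[j, i] = se_sum[pos]
            se_re[i, j] = se_re[j, i] = se_sum[pos + 1]
            se_rp[i, j] = se_rp[j, i] = se_sum[pos + 2]
            pos += 3
    se_G0 = np.zeros((t, t))
    se_R0 = np.zeros((t, t))
    for k, (comp, a, b) in enumerate(params):
        target = se_G0 if comp == "G" else se_R0
        target[a, b] = target[b, a] = np.sqrt(max(cov[k, k], 0.0))
    return {"h2": se_h2, "r_a": se_ra, "r_e": se_re, "r_p": se_rp,
            "G0": se_G0, "R0": se_R0}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def summarize_estimates(estimates: list[GeneticEstimate],
                        traits: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the published correlation-table layout from univariate and
    bivariate fits: heritabilities on the diagonal, genetic correlations
    above, phenotypic correlations below.  Returns (values, standard
    errors); the SE table leaves the lower triangle empty as in print.
    """
    t = len(traits)
    val = pd.DataFrame(np.full((t, t), np.nan), index=traits, columns=traits)
    sev = pd.DataFrame(np.full((t, t), np.nan), index=traits, columns=traits)
    for est in estimates:
        if len(est.traits) == 1 and est.traits[0] in traits:
            i = traits.index(est.traits[0])
            val.iat[i, i] = est.h2[0]
            sev.iat[i, i] = est.se["h2"][0]
        elif len(est.traits) == 2:
            try:
                i, j = (traits.index(est.traits[0]),
                        traits.index(est.traits[1]))
            except ValueError:
                continue
            i, j = min(i, j), max(i, j)
            val.iat[i, j] = est.r_a[0, 1]
            sev.iat[i, j] = est.se["r_a"][0, 1]
            val.iat[j, i] = est.r_p[0, 1]
    return val, sev
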