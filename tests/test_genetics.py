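import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from hennest import (ModelSpec, build_A, build_A_inverse,
                     phenotypic_correlation, reml_fit, summarize_estimates,
                     write_estimates, read_estimates)
from tests.conftest import halfsib_data


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def _trio_ped():
    return pd.DataFrame({"id": [1, 2, 3], "sire": [0, 0, 1],
                         "dam": [0, 0, 2]})


def test_A_basic_relationships():
    rel = build_A(_trio_ped())
    assert rel.A[0, 2] == 0.5 and rel.A[1, 2] == 0.5   # parent-offspring
    assert np.allclose(np.diag(rel.A), 1.0)            # non-inbred
    ped = pd.DataFrame({"id": [1, 2, 3, 4, 5],
                        "sire": [0, 0, 1, 1, 1],
                        "dam": [0, 0, 2, 2, 0]})
    A = build_A(ped).A
    assert A[2, 3] == 0.5                              # full sibs
    assert A[2, 4] == 0.25                             # half sibs


def random_pedigree(q, n_founders, rng):
    rows = []
    for i in range(1, q + 1):
        if i <= n_founders:
            rows.append((i, 0, 0))
        else:
            s, d = rng.choice(np.arange(1, i), size=2, replace=False)
            rows.append((i, int(s), int(d)))
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


def gene_drop_kinship(ped, n_drops, rng):
    """Independent oracle: simulate allele descent; A = 2 x kinship with
    the diagonal handled as 0.5 (1 + F)."""
    q = len(ped)
    pos = {int(i): k for k, i in enumerate(ped["id"])}
    alleles = np.empty((q, 2, n_drops), dtype=np.int32)
    for k in range(q):
        s, d = int(ped["sire"].iat[k]), int(ped["dam"].iat[k])
        for slot, parent in enumerate((s, d)):
            if parent == 0:
                alleles[k, slot] = 2 * k + slot
            else:
                pick = rng.integers(0, 2, n_drops)
                alleles[k, slot] = alleles[pos[parent], pick,
                                           np.arange(n_drops)]
    A = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            if i == j:
                f_self = 0.5 * (1 + np.mean(alleles[i, 0] == alleles[i, 1]))
            else:
                f_self = 0.25 * sum(
                    np.mean(alleles[i, si] == alleles[j, sj])
                    for si in range(2) for sj in range(2))
            A[i, j] = A[j, i] = 2 * f_self
    return A


def test_A_matches_gene_dropping_small():
    rng = np.random.default_rng(7)
    ped = random_pedigree(25, 8, rng)
    A = build_A(ped).A
    A_mc = gene_drop_kinship(ped, 20000, rng)
    assert np.max(np.abs(A - A_mc)) < 0.03


def test_A_inverse_trio_closed_form():
    Ainv = build_A_inverse(_trio_ped())
    expect = np.array([[1.5, 0.5, -1.0],
                       [0.5, 1.5, -1.0],
                       [-1.0, -1.0, 2.0]])
    assert np.allclose(Ainv, expect)


def test_A_inverse_founders_identity():
    ped = pd.DataFrame({"id": [1, 2, 3], "sire": 0, "dam": 0})
    assert np.allclose(build_A_inverse(ped), np.eye(3))


def test_A_inverse_henderson_on_flock(small_flock):
    ped = small_flock[0]
    rel = build_A(ped)
    Ainv = build_A_inverse(ped)
    assert np.max(np.abs(rel.A @ Ainv - np.eye(len(ped)))) < 1e-8


def test_A_inverse_inbred_fallback(caplog):
    # sire mated to his own daughter -> inbred offspring
    ped = pd.DataFrame({"id": [1, 2, 3, 4], "sire": [0, 0, 1, 1],
                        "dam": [0, 0, 2, 3]})
    rel = build_A(ped)
    assert rel.A[3, 3] > 1.0
    with caplog.at_level("WARNING", logger="hennest"):
        Ainv = build_A_inverse(ped)
    assert "inbred" in caplog.text
    assert np.allclose(rel.A @ Ainv, np.eye(4), atol=1e-10)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def anova_halfsib(y, sire, k):
    """Closed-form balanced half-sib ANOVA mapped to animal-model
    components: between-sire = sigma2_a/4."""
    fam_means = pd.Series(y).groupby(sire).mean()
    grand = y.mean()
    s = len(fam_means)
    msb = k * np.sum((fam_means - grand) ** 2) / (s - 1)
    msw = sum(np.sum((y[sire == f] - fam_means[f]) ** 2)
              for f in fam_means.index) / (s * (k - 1))
    sigma_b = (msb - msw) / k
    return 4 * sigma_b, msw - 3 * sigma_b     # sigma2_a, sigma2_e


def test_reml_matches_halfsib_anova_closed_form():
    ped, data = halfsib_data(n_sires=40, progeny=8, h2=0.4, seed=5)
    rel = build_A(ped)
    est = reml_fit(data.rename(columns={"y1": "y"}),
                   ModelSpec(traits=["y"], fixed=None, tol=1e-12), rel)
    sire = ped.set_index("id").loc[data["hen_id"], "sire"].to_numpy()
    sa, se = anova_halfsib(data["y1"].to_numpy(), sire, 8)
    assert est.G0[0, 0] == pytest.approx(sa, abs=1e-4)
    assert est.R0[0, 0] == pytest.approx(se, abs=1e-4)


def test_null_heritability_estimated_near_zero(small_rel, small_flock):
    ped = small_flock[0]
    ids = ped.loc[ped["is_recorded"], "id"].to_numpy()
    rng = np.random.default_rng(9)
    data = pd.DataFrame({"hen_id": ids, "y": rng.standard_normal(len(ids))})
    est = reml_fit(data, ModelSpec(traits=["y"], fixed=None), small_rel)
    assert est.h2[0] < 0.12    # pure-noise phenotype on 150 hens


def dense_restricted_ll(theta, Y, X, K, t):
    """Independent likelihood oracle: fully dense REML log-likelihood with
    V = K (x) G0 + I (x) R0, no eigenrotation."""
    n, p = X.shape
    Lg = np.zeros((t, t))
    Lr = np.zeros((t, t))
    idx = np.tril_indices(t)
    m = len(idx[0])
    Lg[idx] = theta[:m]
    Lr[idx] = theta[m:]
    G0 = Lg @ Lg.T
    R0 = Lr @ Lr.T
    V = np.kron(K, G0) + np.kron(np.eye(n), R0)
    Xf = np.kron(X, np.eye(t))
    y = Y.reshape(-1)
    sign, ldv = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vi = np.linalg.inv(V)
    M = Xf.T @ Vi @ Xf
    beta = np.linalg.solve(M, Xf.T @ Vi @ y)
    r = y - Xf @ beta
    _, ldm = np.linalg.slogdet(M)
    return 0.5 * (ldv + ldm + r @ Vi @ r)


@pytest.mark.parametrize("n_traits", [1, 2])
def test_reml_agrees_with_direct_likelihood_maximization(n_traits):
    ped, data = halfsib_data(n_sires=40, progeny=7, h2=0.5, seed=1,
                             n_traits=n_traits, r_a=0.5, r_e=0.2)
    rel = build_A(ped)
    traits = [f"y{j + 1}" for j in range(n_traits)]
    est = reml_fit(data, ModelSpec(traits=traits, fixed=None, tol=1e-12),
                   rel)
    K = rel.subset(data["hen_id"].to_numpy())
    Y = data[traits].to_numpy()
    X = np.ones((len(Y), 1))
    m = n_traits * (n_traits + 1) // 2
    x0 = np.concatenate([np.linalg.cholesky(
        est.G0 + 0.05 * np.eye(n_traits))[np.tril_indices(n_traits)],
        np.linalg.cholesky(est.R0)[np.tril_indices(n_traits)]])
    x0 = x0 + 0.05    # start the oracle away from the EM solution
    opt = optimize.minimize(
        dense_restricted_ll, x0, args=(Y, X, K, n_traits),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000,
                 "maxfev": 20000})
    Lg = np.zeros((n_traits, n_traits))
    Lg[np.tril_indices(n_traits)] = opt.x[:m]
    G0_opt = Lg @ Lg.T
    Lr = np.zeros((n_traits, n_traits))
    Lr[np.tril_indices(n_traits)] = opt.x[m:]
    R0_opt = Lr @ Lr.T
    assert np.allclose(est.G0, G0_opt, atol=1e-3)
    assert np.allclose(est.R0, R0_opt, atol=1e-3)


def test_loglik_at_estimate_not_below_truth():
    ped, data = halfsib_data(n_sires=30, progeny=7, h2=0.5, seed=13,
                             n_traits=2, r_a=0.6, r_e=0.2)
    rel = build_A(ped)
    est = reml_fit(data, ModelSpec(traits=["y1", "y2"], fixed=None), rel)
    K = rel.subset(data["hen_id"].to_numpy())
    Y = data[["y1", "y2"]].to_numpy()
    X = np.ones((len(Y), 1))

    def nll(G0, R0):
        th = np.concatenate([np.linalg.cholesky(G0)[np.tril_indices(2)],
                             np.linalg.cholesky(R0)[np.tril_indices(2)]])
        return dense_restricted_ll(th, Y, X, K, 2)

    G_true = np.array([[0.5, 0.3], [0.3, 0.5]])
    R_true = np.array([[0.5, 0.1], [0.1, 0.5]])
    assert nll(est.G0, est.R0) <= nll(G_true, R_true) + 1e-6


def test_em_loglik_monotone_and_permutation_invariant(small_rel,
                                                      small_traits):
    traits, _ = small_traits
    from hennest import normalize_traits
    normed = normalize_traits(traits, ["MLD"])
    est = reml_fit(normed, ModelSpec(traits=["MLD"]), small_rel)
    diffs = np.diff(est.loglik_trace)
    assert np.all(diffs >= -1e-7 * (1 + np.abs(est.loglik)))
    # hen reordering must not change the estimates
    perm = normed.sample(frac=1.0, random_state=4)
    est2 = reml_fit(perm, ModelSpec(traits=["MLD"]), small_rel)
    assert est.h2[0] == pytest.approx(est2.h2[0], abs=1e-8)
    assert est.G0[0, 0] == pytest.approx(est2.G0[0, 0], abs=1e-8)


def test_ai_standard_errors_are_plausible(small_rel, small_traits):
    traits, _ = small_traits
    from hennest import normalize_traits
    normed = normalize_traits(traits, ["MLD"])
    est = reml_fit(normed, ModelSpec(traits=["MLD"]), small_rel)
    assert 0.02 < est.se["h2"][0] < 0.5    # 150 hens: broad but finite


def test_too_few_joint_hens_rejected(small_rel):
    data = pd.DataFrame({"hen_id": [1, 2, 3], "a": [1.0, 2.0, 3.0],
                         "b": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="jointly phenotyped"):
        reml_fit(data, ModelSpec(traits=["a", "b"]), small_rel)


# ---------------------------------------------------------------------------
# the phenotypic-correlation identity
# ---------------------------------------------------------------------------

def test_phenotypic_correlation_identities():
    assert phenotypic_correlation(0.5, 0.5, 0.0, 0.0, 0.5, 0.5) == 0.0
    assert phenotypic_correlation(1.0, 1.0, 0.42, 0.0, 0.0, 0.0) == \
        pytest.approx(0.42)
    with pytest.raises(ValueError, match="r_p"):
        phenotypic_correlation(1.0, 1.0, 0.9, 0.9, 1.0, 1.0)


def test_phenotypic_correlation_matches_published_lrn_cn():
    """With the published heritabilities (0.13, 0.37) and genetic
    correlation (-0.55), the residual correlation back-solved from the
    published r_p = -0.37 reproduces it through the forward identity."""
    h2_i, h2_j, r_a, r_p_published = 0.13, 0.37, -0.55, -0.37
    e2_i, e2_j = 1 - h2_i, 1 - h2_j
    r_e = (r_p_published - np.sqrt(h2_i * h2_j) * r_a) / np.sqrt(e2_i * e2_j)
    assert r_e == pytest.approx(-0.337, abs=0.002)
    r_p = phenotypic_correlation(h2_i, h2_j, r_a, r_e, e2_i, e2_j)
    assert r_p == pytest.approx(-0.37, abs=1e-12)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def test_summarize_estimates_triangle_layout():
    ped, data = halfsib_data(n_sires=20, progeny=6, h2=0.5, seed=2,
                             n_traits=2)
    rel = build_A(ped)
    uni1 = reml_fit(data, ModelSpec(traits=["y1"], fixed=None), rel)
    uni2 = reml_fit(data, ModelSpec(traits=["y2"], fixed=None), rel)
    biv = reml_fit(data, ModelSpec(traits=["y1", "y2"], fixed=None), rel)
    val, se = summarize_estimates([uni1, uni2, biv], ["y1", "y2"])
    assert val.loc["y1", "y1"] == pytest.approx(uni1.h2[0])
    assert val.loc["y1", "y2"] == pytest.approx(biv.r_a[0, 1])
    assert val.loc["y2", "y1"] == pytest.approx(biv.r_p[0, 1])
    assert val.loc["y1", "y2"] != val.loc["y2", "y1"]  # asymmetric by design


def test_estimate_frame_round_trip(tmp_path):
    ped, data = halfsib_data(n_sires=20, progeny=6, h2=0.5, seed=3,
                             n_traits=2)
    rel = build_A(ped)
    est = reml_fit(data, ModelSpec(traits=["y1", "y2"], fixed=None), rel)
    path = tmp_path / "est.csv"
    write_estimates(est.to_frame(), path)
    back = read_estimates(path)
    ra = back.query("parameter == 'r_a'")["value"].iloc[0]
    assert ra == pytest.approx(est.r_a[0, 1])
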