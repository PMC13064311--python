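"""PCA on LD-pruned genotypes and a binomial-likelihood admixture model.

PCA standardises each SNP as (g - 2p)/sqrt(2p(1-p)) with missing entries
zeroed after centring, eigendecomposes the sample-by-sample covariance, and
reports explained variance as each eigenvalue's share of the positive
spectrum.

The admixture model maximises the binomial log-likelihood
LL = sum_ij [ g_ij ln theta_ij + (2 - g_ij) ln(1 - theta_ij) ],
theta_ij = sum_k q_ik f_kj, by EM with guaranteed monotone LL.  Model
choice uses entry-masking cross-validation scored by binomial deviance,
mirroring the usual --cv workflow.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .gio import MISSING, GenotypeMatrix

_EPS = 1e-6


@dataclass
class PCAResult:
    coordinates: pd.DataFrame      # samples x components
    explained_variance: np.ndarray  # fraction per component, non-increasing


@dataclass
class AdmixtureFit:
    k: int
    Q: np.ndarray  # (n_samples, k), rows sum to 1
    F: np.ndarray  # (k, n_snps) ancestral allele frequencies
    log_likelihood: float
    ll_trace: np.ndarray
    iterations: int
    converged: bool


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Principal components of the standardised genotype matrix.

    Component sign is fixed so each component's largest-magnitude sample
    loading is positive.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    calls = gm.calls.astype(float)
    called = gm.calls != MISSING
    n_allele = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, calls, 0.0).sum(axis=0) / n_allele
        scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = (p > 0) & (p < 1) & np.isfinite(scale) & (scale > 0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs")
    X = (calls[:, poly] - 2.0 * p[poly]) / scale[poly]
    X[~called[:, poly]] = 0.0
    m = X.shape[1]
    cov = X @ X.T / m
    evals, evecs = eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos_sum = evals[evals > 0].sum()
    n_components = min(n_components, len(evals))
    coords = evecs[:, :n_components] * np.sqrt(np.maximum(evals[:n_components], 0))
    for j in range(n_components):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    frac = np.maximum(evals[:n_components], 0) / pos_sum if pos_sum > 0 else \
        np.zeros(n_components)
    df = pd.DataFrame(coords, index=gm.samples,
                      columns=[f"PC{j + 1}" for j in range(n_components)])
    return PCAResult(coordinates=df, explained_variance=frac)


def _em_iterate(G, mask, Q, F, max_iter, tol):
    """EM updates; returns (Q, F, ll_trace).  G is (n, m) float with
    missing entries arbitrary but excluded via ``mask``."""
    n, m = G.shape
    two_minus = np.where(mask, 2.0 - G, 0.0)
    Gm = np.where(mask, G, 0.0)
    M_i = mask.sum(axis=1, keepdims=True) * 2.0
    trace = []
    ll_prev = -np.inf
    for it in range(max_iter):
        theta = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        ll = float((Gm * np.log(theta) + two_minus * np.log1p(-theta))[mask].sum())
        trace.append(ll)
        if ll - ll_prev < tol and it > 0:
            return Q, F, np.array(trace), True
        ll_prev = ll
        # responsibilities folded into closed-form updates
        A = Gm / theta        # (n, m)
        B = two_minus / (1.0 - theta)
        # a_ijk = A_ij q_ik f_kj ; b_ijk = B_ij q_ik (1 - f_kj)
        AF = A @ F.T          # (n, k): sum_j A_ij f_kj
        BF = B @ (1.0 - F).T  # (n, k)
        Q_new = Q * (AF + BF) / M_i
        num = (A.T @ Q) * F.T          # (m, k): sum_i a_ijk
        den = num + (B.T @ Q) * (1.0 - F.T)
        with np.errstate(invalid="ignore", divide="ignore"):
            F_new = np.where(den.T > 0, num.T / den.T, F)
        Q = Q_new / Q_new.sum(axis=1, keepdims=True)
        F = np.clip(F_new, _EPS, 1.0 - _EPS)
    return Q, F, np.array(trace), False


def admixture_fit(
    gm: GenotypeMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_init: int = 5,
) -> AdmixtureFit:
    """Maximum-likelihood admixture proportions by EM.

    Runs ``n_init`` seeded restarts and keeps the best log-likelihood.
    For k = 1 the closed form (F = observed frequencies) is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > gm.n_samples:
        raise ValueError("k larger than the number of samples")
    G = gm.calls.astype(float)
    mask = gm.calls != MISSING
    return _admixture_fit_arrays(G, mask, k, seed, max_iter, tol, n_init)


def _admixture_fit_arrays(G, mask, k, seed, max_iter, tol, n_init):
    n, m = G.shape
    rng = np.random.default_rng(seed)
    if k == 1:
        with np.errstate(invalid="ignore"):
            freq = np.where(mask, G, 0.0).sum(axis=0) / (2.0 * mask.sum(axis=0))
        F = np.clip(freq[None, :], _EPS, 1.0 - _EPS)
        Q = np.ones((n, 1))
        theta = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        Gm = np.where(mask, G, 0.0)
        two_minus = np.where(mask, 2.0 - G, 0.0)
        ll = float((Gm * np.log(theta) + two_minus * np.log1p(-theta))[mask].sum())
        return AdmixtureFit(k=1, Q=Q, F=F, log_likelihood=ll,
                            ll_trace=np.array([ll]), iterations=0, converged=True)
    best = None
    for _ in range(max(1, n_init)):
        Q0 = rng.dirichlet(np.ones(k), size=n)
        F0 = np.clip(rng.uniform(0.05, 0.95, size=(k, m)), _EPS, 1 - _EPS)
        Q, F, trace, conv = _em_iterate(G, mask, Q0, F0, max_iter, tol)
        if best is None or trace[-1] > best.log_likelihood:
            best = AdmixtureFit(k=k, Q=Q, F=F, log_likelihood=float(trace[-1]),
                                ll_trace=trace, iterations=len(trace),
                                converged=conv)
    return best


def _deviance(g, theta):
    """Binomial deviance between observed dosage g and fitted 2*theta."""
    theta = np.clip(theta, _EPS, 1.0 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(g > 0, g * np.log(g / (2.0 * theta)), 0.0)
        t2 = np.where(g < 2, (2.0 - g) * np.log((2.0 - g) / (2.0 - 2.0 * theta)),
                      0.0)
    return 2.0 * (t1 + t2)


def admixture_cv(
    gm: GenotypeMatrix,
    k_range=range(1, 11),
    folds: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_init: int = 2,
) -> pd.DataFrame:
    """Entry-masking cross-validation over k.

    Non-missing genotype entries are partitioned into ``folds`` random
    folds; each fold is masked in turn, the model refit, and the masked
    entries scored by binomial deviance against 2·theta-hat.  Returns a
    DataFrame (k, cv_error) sorted by k; the best k minimises cv_error.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds to hold data out")
    G = gm.calls.astype(float)
    mask = gm.calls != MISSING
    rng = np.random.default_rng(seed)
    obs = np.argwhere(mask)
    fold_id = rng.integers(0, folds, size=len(obs))
    rows = []
    for k in k_range:
        errs = []
        for f in range(folds):
            hold = obs[fold_id == f]
            if len(hold) == 0:
                continue
            m2 = mask.copy()
            m2[hold[:, 0], hold[:, 1]] = False
            fit = _admixture_fit_arrays(G, m2, k, seed + 1000 * k + f,
                                        max_iter, tol, n_init)
            theta = fit.Q @ fit.F
            dev = _deviance(G[hold[:, 0], hold[:, 1]],
                            theta[hold[:, 0], hold[:, 1]])
            errs.append(float(np.mean(dev)))
        rows.append((int(k), float(np.mean(errs))))
    return pd.DataFrame(rows, columns=["k", "cv_error"])


def best_k(cv_table: pd.DataFrame) -> int:
    return int(cv_table.loc[cv_table["cv_error"].idxmin(), "k"])
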