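"""Bayesian sparse linear mixed model: PVE and posterior inclusion
probabilities, plus GRM / PCA utilities for covariate construction.

Model
-----
    y = W a + X b + u + e,      b_j ~ pi N(0, s_a^2) + (1 - pi) d_0,
    u ~ N(0, s_b^2 K),          e ~ N(0, s_e^2 I),

with K the centered genomic relatedness matrix.  Hyperpriors follow the
conventional sparse-LMM parameterization: h (approximate genetic variance
fraction) and rho (share of it carried by the sparse effects) uniform on
(0, 1), log pi uniform on [log(1/p), 0].  The sparse and polygenic scales are
tied to (h, rho) so that the *expected* genetic variance fraction equals h:

    s_a^2 = h rho s_e^2 / ((1 - h) max(|gamma|, 1) vbar)
    s_b^2 = h (1 - rho) s_e^2 / ((1 - h) kbar)

where vbar is the mean genotype-column variance and kbar = tr(K)/n.  Scaling
the slab by the current inclusion count |gamma| (rather than pi p) keeps the
pi update conjugate.

Sampling is Gibbs-within-Metropolis: single-site spike-and-slab updates for
(gamma_j, b_j) with the effect integrated inside each inclusion draw (the
tight inner loop is numba-compiled), an exact multivariate draw of u in the
eigenbasis of K, a conjugate inverse-gamma draw for s_e^2, a random-walk
Metropolis step on (logit h, logit rho), and a truncated-Beta draw for pi.
One "iteration" is a full sweep over all p SNPs.  Covariates are removed by
projecting y and X onto the orthogonal complement of W (flat prior on a).

PVE is reported per retained sample as the realized var(Xb + u) /
(var(Xb + u) + s_e^2) on the analyzed individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "compute_grm",
    "genotype_pca",
    "BslmmPosterior",
    "fit_bslmm",
    "summarize_pve",
    "pip_candidates",
]


# ---------------------------------------------------------------------------
# GRM and PCA
# ---------------------------------------------------------------------------

def compute_grm(X: np.ndarray) -> np.ndarray:
    """Centered genomic relatedness matrix K = X_c X_c^T / p.

    ``X`` is the complete (no missing) n × p dosage matrix.  K is symmetric
    and positive semi-definite up to numerical tolerance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need an n x p dosage matrix with p >= 1 variants")
    if np.isnan(X).any():
        raise ValueError("genotype matrix must be complete (impute first)")
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T / X.shape[1]
    return (K + K.T) / 2.0


def genotype_pca(X: np.ndarray, n_pcs: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of genetic variation via the GRM eigendecomposition.

    Returns (scores, explained variance fractions).  Scores are eigenvectors
    scaled by sqrt(eigenvalue); the sign of each PC is fixed so its
    largest-magnitude loading is positive.  Explained-variance fractions are
    over the non-negative spectrum and sum to 1.
    """
    K = compute_grm(X)
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    n_pcs = min(n_pcs, len(evals))
    scores = evecs[:, :n_pcs] * np.sqrt(evals[:n_pcs])
    for j in range(n_pcs):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    total = evals.sum()
    frac = evals / total if total > 0 else evals
    return scores, frac


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sweep(
    Xt,  # (p, n) C-contiguous: rows are SNP columns
    xx,  # (p,) column squared norms
    r,  # (n,) residual y* - X b - u, updated in place
    beta,  # (p,)
    gamma,  # (p,) uint8
    order,  # (p,) visit order
    sigma_e2,
    sigma_a2,
    log_prior_odds,
    unif,  # (p,) uniforms
    norm,  # (p,) standard normals
):
    n_incl = 0
    for t in range(order.shape[0]):
        j = order[t]
        xj = Xt[j]
        if gamma[j] == 1:
            for i in range(r.shape[0]):
                r[i] += xj[i] * beta[j]
        xr = 0.0
        for i in range(r.shape[0]):
            xr += xj[i] * r[i]
        v = sigma_a2
        denom = sigma_e2 + v * xx[j]
        log_bf = 0.5 * np.log(sigma_e2 / denom) + 0.5 * v * xr * xr / (
            sigma_e2 * denom
        )
        logit = log_prior_odds + log_bf
        if logit > 35.0:
            p_incl = 1.0
        elif logit < -35.0:
            p_incl = 0.0
        else:
            p_incl = 1.0 / (1.0 + np.exp(-logit))
        if unif[t] < p_incl:
            var_b = v * sigma_e2 / denom
            mean_b = var_b * xr / sigma_e2
            beta[j] = mean_b + np.sqrt(var_b) * norm[t]
            gamma[j] = 1
            for i in range(r.shape[0]):
                r[i] -= xj[i] * beta[j]
            n_incl += 1
        else:
            beta[j] = 0.0
            gamma[j] = 0
    return n_incl


@dataclass
class BslmmPosterior:
    """Retained MCMC samples and per-SNP inclusion probabilities."""

    pve_samples: np.ndarray
    h_samples: np.ndarray
    rho_samples: np.ndarray
    log_pi_samples: np.ndarray
    n_gamma_samples: np.ndarray
    pip: np.ndarray
    n_retained: int
    rhat_pve: float
    meta: dict = field(default_factory=dict)


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _scales(h, rho, pi_, sigma_e2, p_eff, vbar, kbar):
    base = h / (1.0 - h) * sigma_e2
    sigma_a2 = base * rho / (max(pi_ * p_eff, 1.0) * vbar)
    sigma_b2 = base * (1.0 - rho) / kbar
    return sigma_a2, sigma_b2


def fit_bslmm(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray | None = None,
    n_iter: int = 10000,
    burn_in: int = 2000,
    thin: int = 8,
    seed: int = 0,
    mh_step: float = 0.6,
    max_sparse: int = 300,
) -> BslmmPosterior:
    """Fit the BSLMM by MCMC; see the module docstring for the model.

    ``n_iter`` counts full sweeps over all p SNPs; retained samples number
    (n_iter - burn_in) / thin.  Chains are fully reproducible from ``seed``.
    A split-chain convergence statistic on the PVE samples is reported in
    ``rhat_pve`` (values far above 1 indicate non-convergence).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("inputs must be complete; impute genotypes first")
    if W is None:
        W = np.ones((n, 1))
    W = np.asarray(W, dtype=float)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    # project out covariates (flat prior on their coefficients)
    Q, _ = np.linalg.qr(W)
    ystar = y - Q @ (Q.T @ y)
    Xs = X - Q @ (Q.T @ X)

    xx = (Xs**2).sum(axis=0)
    keep = xx > 1e-12  # monomorphic-after-projection SNPs never enter
    vbar = float(xx[keep].mean() / n) if keep.any() else 1.0
    K = compute_grm(X)
    evals, evecs = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    kbar = float(evals.sum() / n) if evals.sum() > 0 else 1.0

    Xt = np.ascontiguousarray(Xs.T)
    rng = np.random.default_rng(seed)

    # state
    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.uint8)
    u = np.zeros(n)
    sigma_e2 = float(ystar.var()) or 1.0
    h, rho = 0.5, 0.5
    log_pi_min = np.log(1.0 / p)
    # cap the expected number of sparse SNPs (conventional desk-scale bound;
    # also suppresses the degenerate many-tiny-effects mode of the sampler)
    log_pi_max = np.log(min(1.0, max_sparse / p))
    pi_ = min(10.0 / p, 1.0)
    n_incl = 0

    n_keep = max((n_iter - burn_in) // thin, 0)
    if n_keep < 1:
        raise ValueError("chain settings leave no retained samples")
    pve_s = np.empty(n_keep)
    h_s = np.empty(n_keep)
    rho_s = np.empty(n_keep)
    lpi_s = np.empty(n_keep)
    ng_s = np.empty(n_keep, dtype=int)
    incl_counts = np.zeros(p)

    r = ystar - u  # beta starts at 0
    kept = 0
    active = np.flatnonzero(keep)
    p_eff = active.size
    d = evals[pos]
    n_pos = int(pos.sum())

    for it in range(n_iter):
        sigma_a2, sigma_b2 = _scales(h, rho, pi_, sigma_e2, p_eff, vbar, kbar)
        log_prior_odds = float(_logit(pi_))

        order = active[rng.permutation(active.size)]
        unif = rng.random(active.size)
        norm = rng.standard_normal(active.size)
        n_incl = _sweep(
            Xt, xx, r, beta, gamma, order, sigma_e2, sigma_a2,
            log_prior_odds, unif, norm,
        )

        # (h, rho, pi) Metropolis with the polygenic term integrated out:
        # rotated residual t = y* - X b has diagonal covariance
        # sigma_b2 * D + sigma_e2 * I in the eigenbasis of K.
        t_vec = r + u
        tt = evecs.T @ t_vec
        tt_pos2 = tt[pos] ** 2
        tt_null2 = float((tt[~pos] ** 2).sum())
        bb = float(beta @ beta)

        def log_target(h_, rho_, lpi_):
            sa, sb = _scales(h_, rho_, np.exp(lpi_), sigma_e2, p_eff, vbar, kbar)
            var_t = sb * d + sigma_e2
            lp = -0.5 * float(np.log(var_t).sum() + (tt_pos2 / var_t).sum())
            lp += -0.5 * (n - n_pos) * np.log(sigma_e2) - tt_null2 / (2 * sigma_e2)
            if n_incl > 0:
                lp += -0.5 * n_incl * np.log(sa) - bb / (2 * sa)
            # binomial likelihood of the inclusion pattern given pi
            pi_v = np.exp(lpi_)
            lp += n_incl * lpi_ + (p_eff - n_incl) * np.log1p(-min(pi_v, 1 - 1e-12))
            return lp

        cur = log_target(h, rho, np.log(pi_))
        for _ in range(4):
            lh_p = _logit(h) + mh_step * rng.standard_normal()
            lr_p = _logit(rho) + mh_step * rng.standard_normal()
            lpi_p = np.log(pi_) + mh_step * rng.standard_normal()
            if not log_pi_min <= lpi_p <= log_pi_max:
                continue  # uniform prior on log pi: reject outside bounds
            h_p, rho_p = _expit(lh_p), _expit(lr_p)
            prop = log_target(h_p, rho_p, lpi_p)
            # Jacobian of the logit transform: log|dh/dlogit| = log h(1-h)
            log_acc = (
                prop - cur
                + np.log(h_p * (1 - h_p)) + np.log(rho_p * (1 - rho_p))
                - np.log(h * (1 - h)) - np.log(rho * (1 - rho))
            )
            if np.log(rng.random()) < log_acc:
                h, rho, pi_ = h_p, rho_p, float(np.exp(lpi_p))
                cur = prop

        # polygenic term: exact conditional draw in the eigenbasis of K
        sigma_a2, sigma_b2 = _scales(h, rho, pi_, sigma_e2, p_eff, vbar, kbar)
        w = np.zeros(n)
        prec = sigma_b2 * d / (sigma_b2 * d + sigma_e2)
        w[pos] = prec * tt[pos] + rng.standard_normal(n_pos) * np.sqrt(
            prec * sigma_e2
        )
        u = evecs @ w
        r = t_vec - u

        # residual variance (Jeffreys prior), conditioning on scaled priors
        s_a = sigma_a2 / sigma_e2
        s_b = sigma_b2 / sigma_e2
        quad = float(r @ r)
        dof = n
        if n_incl > 0:
            quad += bb / s_a
            dof += n_incl
        wp = w[pos]
        quad += float((wp**2 / d).sum()) / s_b
        dof += n_pos
        sigma_e2 = quad / (2.0 * rng.gamma(dof / 2.0, 1.0))

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            g = ystar - r  # = X beta + u
            vg = float(g.var())
            pve_s[kept] = vg / (vg + sigma_e2)
            h_s[kept] = h
            rho_s[kept] = rho
            lpi_s[kept] = np.log(pi_)
            ng_s[kept] = n_incl
            incl_counts += gamma
            kept += 1

    pip = incl_counts / kept
    rhat = _split_rhat(pve_s[:kept])
    return BslmmPosterior(
        pve_samples=pve_s[:kept],
        h_samples=h_s[:kept],
        rho_samples=rho_s[:kept],
        log_pi_samples=lpi_s[:kept],
        n_gamma_samples=ng_s[:kept],
        pip=pip,
        n_retained=kept,
        rhat_pve=rhat,
        meta={"n": n, "p": p, "n_iter": n_iter, "burn_in": burn_in, "thin": thin,
              "seed": seed},
    )


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction on one chain's retained draws."""
    m = len(x) // 2
    if m < 2:
        return float("nan")
    halves = np.stack([x[:m], x[m : 2 * m]])
    within = halves.var(axis=1, ddof=1).mean()
    between = m * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (m - 1) / m * within + between / m
    return float(np.sqrt(var_plus / within))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_pve(post: BslmmPosterior, interval: float = 0.89) -> tuple[float, tuple[float, float]]:
    """Posterior median of PVE and the equal-tailed credible interval
    (89% by default: the 5.5% and 94.5% quantiles)."""
    s = np.asarray(post.pve_samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty posterior")
    alpha = (1.0 - interval) / 2.0
    lo, med, hi = np.quantile(s, [alpha, 0.5, 1.0 - alpha])
    return float(med), (float(lo), float(hi))


def pip_candidates(post: BslmmPosterior, threshold: float = 0.1) -> np.ndarray:
    """Indices of SNPs with PIP strictly above ``threshold``, sorted by
    descending PIP (an empty result is a perfectly valid outcome)."""
    pip = np.asarray(post.pip)
    hits = np.flatnonzero(pip > threshold)
    return hits[np.argsort(-pip[hits], kind="stable")]
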