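"""Polygenic scores by clumping + thresholding with jackknife cross-validation.

The pipeline is the standard C+T recipe: covariate-adjusted per-SNP
regression → greedy p-value-ordered LD clumping → a grid of p-value
thresholds, with the threshold chosen on an internal split of the training
fold (never on the evaluation fold).  Accuracy is summarized as incremental
R²: the squared Pearson correlation between the predicted score and the
covariate-residualized phenotype of the held-out individuals.  Cross-
validation uses 100 random 85/15 partitions; per-individual predictions are
averaged over the repetitions in which they were held out and summarized by
decile (1 = lowest PGS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "marginal_gwas",
    "ld_clump",
    "PgsModel",
    "build_pgs_model",
    "CvResult",
    "jackknife_cv",
    "decile_summary",
]

DEFAULT_THRESHOLDS = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


def _residualize(W: np.ndarray, *arrays: np.ndarray) -> list[np.ndarray]:
    Q, _ = np.linalg.qr(W)
    return [a - Q @ (Q.T @ a) for a in arrays]


def marginal_gwas(
    y: np.ndarray, X: np.ndarray, W: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-SNP regression of y on dosage with covariates W (plus intercept).

    Returns a frame with beta, se, p (two-sided), and an ``excluded`` flag
    for monomorphic (zero-variance after covariate projection) variants.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if W is None:
        W = np.ones((n, 1))
    W = np.asarray(W, dtype=float)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    yr, Xr = _residualize(W, y, X)
    xx = (Xr**2).sum(axis=0)
    excluded = xx < 1e-10
    xx_safe = np.where(excluded, 1.0, xx)
    beta = (Xr * yr[:, None]).sum(axis=0) / xx_safe
    dof = n - W.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough samples for per-SNP regression")
    sse = (yr @ yr) - beta**2 * xx_safe
    sigma2 = np.clip(sse, 0.0, None) / dof
    se = np.sqrt(sigma2 / xx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({"beta": beta, "se": se, "p": pval, "excluded": excluded})
    out.loc[excluded, ["beta", "se"]] = np.nan
    out.loc[excluded, "p"] = 1.0
    return out


def ld_clump(
    stats_df: pd.DataFrame,
    X: np.ndarray,
    var: pd.DataFrame,
    r2_cutoff: float = 0.1,
    window_kb: float = 250.0,
) -> np.ndarray:
    """Greedy p-value-ordered clumping; returns sorted index-variant indices.

    Variants are visited in ascending p-value (ties: scaffold, position,
    index); a variant becomes an index unless an existing index on the same
    scaffold within ``window_kb`` has squared genotype correlation strictly
    greater than ``r2_cutoff``.  Excluded (monomorphic) variants never index.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    scaf = var["scaffold"].to_numpy()
    pos = var["pos"].to_numpy(dtype=float)
    pvals = stats_df["p"].to_numpy(dtype=float)
    excluded = stats_df["excluded"].to_numpy(dtype=bool)

    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    ok = sd > 0
    Z[:, ok] = Z[:, ok] / sd[ok]

    order = sorted(
        np.flatnonzero(~excluded), key=lambda j: (pvals[j], scaf[j], pos[j], j)
    )
    window_bp = window_kb * 1000.0
    n = X.shape[0]
    # per-scaffold growable buffers of accepted index variants (amortized
    # appends; a fresh array per candidate would make the loop quadratic)
    idx_buf: dict[str, np.ndarray] = {}
    pos_buf: dict[str, np.ndarray] = {}
    cnt: dict[str, int] = {}
    for j in order:
        s = scaf[j]
        k = cnt.get(s, 0)
        clumped = False
        if k:
            members = idx_buf[s][:k]
            near = members[np.abs(pos_buf[s][:k] - pos[j]) <= window_bp]
            if near.size:
                r = (Z[:, near].T @ Z[:, j]) / n
                clumped = bool((r * r > r2_cutoff).any())
        if not clumped:
            if s not in idx_buf:
                idx_buf[s] = np.empty(16, dtype=int)
                pos_buf[s] = np.empty(16, dtype=float)
            elif k == len(idx_buf[s]):
                idx_buf[s] = np.concatenate([idx_buf[s], np.empty_like(idx_buf[s])])
                pos_buf[s] = np.concatenate([pos_buf[s], np.empty_like(pos_buf[s])])
            idx_buf[s][k] = j
            pos_buf[s][k] = pos[j]
            cnt[s] = k + 1
    out = np.array(
        sorted(int(i) for s, k in cnt.items() for i in idx_buf[s][:k]), dtype=int
    )
    return out


@dataclass
class PgsModel:
    """Index variants, effect-allele weights and the chosen threshold."""

    variant_indices: np.ndarray
    weights: np.ndarray
    threshold: float
    r2_cutoff: float
    window_kb: float
    empty: bool = False

    def score(self, X: np.ndarray) -> np.ndarray:
        if self.empty or len(self.variant_indices) == 0:
            return np.zeros(np.asarray(X).shape[0])
        return np.asarray(X)[:, self.variant_indices] @ self.weights


def _incremental_r2(score: np.ndarray, y: np.ndarray, W: np.ndarray) -> float:
    """Squared Pearson correlation of score with the covariate-residualized
    phenotype (0 when either side is constant)."""
    yr = _residualize(W, np.asarray(y, dtype=float))[0]
    s = np.asarray(score, dtype=float)
    if s.std() == 0 or yr.std() == 0:
        return 0.0
    r = np.corrcoef(s, yr)[0, 1]
    return float(r * r)


def build_pgs_model(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    var: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    r2_cutoff: float = 0.1,
    window_kb: float = 250.0,
    inner_frac: float = 0.8,
    rng: np.random.Generator | None = None,
) -> PgsModel:
    """Fit a clumping + thresholding PGS on training data only.

    The p-value threshold is selected by incremental R² on an internal
    ``1 - inner_frac`` holdout of the training fold; the returned weights are
    refit on the full training fold at the winning threshold.  Ties prefer
    the smaller (sparser) threshold.
    """
    rng = rng or np.random.default_rng(0)
    n = len(y)
    perm = rng.permutation(n)
    n_inner = max(int(round(inner_frac * n)), 2)
    tr, va = perm[:n_inner], perm[n_inner:]
    if len(va) < 2:
        tr, va = perm[:-2], perm[-2:]

    stats_in = marginal_gwas(y[tr], X[tr], W[tr])
    idx_in = ld_clump(stats_in, X[tr], var, r2_cutoff, window_kb)
    p_in = stats_in["p"].to_numpy()

    best_thr, best_r2 = None, -np.inf
    for thr in sorted(thresholds):
        sel = idx_in[p_in[idx_in] <= thr]
        if len(sel) == 0:
            continue
        score = X[va][:, sel] @ stats_in["beta"].to_numpy()[sel]
        r2 = _incremental_r2(score, y[va], W[va])
        if r2 > best_r2 + 1e-12:
            best_thr, best_r2 = thr, r2
    if best_thr is None:
        return PgsModel(np.array([], dtype=int), np.array([]), np.nan,
                        r2_cutoff, window_kb, empty=True)

    stats_full = marginal_gwas(y, X, W)
    idx_full = ld_clump(stats_full, X, var, r2_cutoff, window_kb)
    sel = idx_full[stats_full["p"].to_numpy()[idx_full] <= best_thr]
    if len(sel) == 0:
        return PgsModel(np.array([], dtype=int), np.array([]), best_thr,
                        r2_cutoff, window_kb, empty=True)
    return PgsModel(sel, stats_full["beta"].to_numpy()[sel], best_thr,
                    r2_cutoff, window_kb)


@dataclass
class CvResult:
    """Jackknife cross-validation output."""

    reps: pd.DataFrame  # per repetition: rep, n_train, n_test, threshold, r2
    predictions: pd.DataFrame  # per individual: sample_id, mean_pgs, n_heldout
    never_heldout: list = field(default_factory=list)
    test_sets: list = field(default_factory=list)  # held-out index array per rep
    models: list = field(default_factory=list)  # fitted PgsModel per rep


def jackknife_cv(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    sample_ids,
    reps: int = 100,
    train_frac: float = 0.85,
    seed: int = 0,
    thresholds=DEFAULT_THRESHOLDS,
    r2_cutoff: float = 0.1,
    window_kb: float = 250.0,
    var: pd.DataFrame | None = None,
) -> CvResult:
    """Repeated random-partition ("jackknife") cross-validation of the PGS.

    Each repetition draws a random train fraction (85% default), runs the
    full pipeline (per-SNP GWAS → clump → threshold selection) on the
    training fold only, and evaluates incremental R² on the held-out fold.
    Held-out scores are standardized by the training-fold score distribution
    so they are comparable across repetitions, then averaged per individual.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need n >= 20 for jackknife cross-validation")
    if var is None:
        var = pd.DataFrame({"scaffold": ["scaf_1"] * X.shape[1],
                            "pos": np.arange(1, X.shape[1] + 1)})
    sample_ids = list(sample_ids)
    rng = np.random.default_rng(seed)

    rows = []
    test_sets = []
    models = []
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=int)
    n_train = int(round(train_frac * n))
    for rep in range(reps):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = build_pgs_model(
            y[tr], X[tr], W[tr], var, thresholds, r2_cutoff, window_kb,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        score_tr = model.score(X[tr])
        score_te = model.score(X[te])
        sd = score_tr.std()
        if sd > 0:
            z_te = (score_te - score_tr.mean()) / sd
        else:
            z_te = np.zeros_like(score_te)
        r2 = _incremental_r2(score_te, y[te], W[te]) if len(te) >= 3 else np.nan
        rows.append((rep, len(tr), len(te), model.threshold, r2))
        test_sets.append(te.copy())
        models.append(model)
        pred_sum[te] += z_te
        pred_cnt[te] += 1

    with np.errstate(invalid="ignore"):
        mean_pred = np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)
    never = [sample_ids[i] for i in np.flatnonzero(pred_cnt == 0)]
    preds = pd.DataFrame(
        {"sample_id": sample_ids, "mean_pgs": mean_pred, "n_heldout": pred_cnt}
    )
    reps_df = pd.DataFrame(
        rows, columns=["rep", "n_train", "n_test", "threshold", "r2"]
    )
    return CvResult(
        reps=reps_df,
        predictions=preds,
        never_heldout=never,
        test_sets=test_sets,
        models=models,
    )


def decile_summary(cv: CvResult, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-decile arrival summary of the cross-validated predictions.

    Individuals with a prediction are ranked by mean predicted PGS (ties by
    sample id) and cut into 10 contiguous groups; with n not divisible by 10
    the first n mod 10 deciles take the extra individual.  Decile 1 = lowest
    predicted score.
    """
    merged = cv.predictions.dropna(subset=["mean_pgs"]).merge(
        phenotypes[["sample_id", "arrival_date_ordinal"]], on="sample_id"
    )
    n = len(merged)
    if n < 10:
        raise ValueError("need at least 10 predicted individuals for deciles")
    merged = merged.sort_values(["mean_pgs", "sample_id"], kind="stable").reset_index(
        drop=True
    )
    sizes = [len(c) for c in np.array_split(np.arange(n), 10)]
    merged["decile"] = np.repeat(np.arange(1, 11), sizes)
    out = (
        merged.groupby("decile")
        .agg(
            n=("sample_id", "size"),
            mean_pgs=("mean_pgs", "mean"),
            mean_arrival=("arrival_date_ordinal", "mean"),
            median_arrival=("arrival_date_ordinal", "median"),
        )
        .reset_index()
    )
    out.attrs["assignments"] = merged[["sample_id", "decile", "mean_pgs",
                                       "arrival_date_ordinal"]]
    return out
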