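"""Genomic prediction: RR-BLUP/GBLUP, Bayesian LASSO, Bayesian ridge, CV.

RR-BLUP fits y = μ1 + Zg + ε with g ~ N(0, G σ²g), G the VanRaden genomic
relationship matrix; variance components come from the spectral REML engine
and marker effects are recovered as β̂ = (σ²g/denom)·Wᵀ V⁻¹(y − μ̂1), which
makes the marker-effect and kinship prediction routes algebraically
identical (the RR-BLUP ≡ GBLUP equivalence).

The Bayesian LASSO uses the scale-mixture-of-normals representation of the
double-exponential prior (per-marker variances τ²_j with exponential mixing
rate λ²/2 and a gamma hyperprior on λ²); Bayesian ridge regression places a
common Gaussian prior on all marker effects with scaled-inverse-χ² priors on
both variances.  Both are Gibbs samplers, deterministic given a seed.

Predictive ability is the Pearson correlation between predicted and observed
values of held-out genotypes in a k-fold × r-repeat cross-validation; the
marker-subsetting experiment re-runs the GWAS scan per training fold
(``within_fold``, unbiased) or once on all data (``full_data``, the
optimistically biased variant some analyses use; a warning is logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, logger
from .gwas import bonferroni_threshold, emma_reml, mlm_scan
from .popgen import vanraden_kinship

# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


@dataclass
class PredictionFit:
    """A fitted whole-genome regression model."""

    model: str                     # RRBLUP | BL | BRR | MEAN
    mu: float
    beta: np.ndarray               # marker effects (centred-dose scale)
    ghat: np.ndarray               # fitted genetic values of training genotypes
    col_means: np.ndarray          # training column means used for centring
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    extras: dict = field(default_factory=dict)
    _W_train: np.ndarray | None = None
    _Vinv_resid: np.ndarray | None = None
    _denom: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and np.all(np.isfinite(self.beta))):
            raise ValueError("non-finite estimates in prediction fit")

    def predict(self, M_new: np.ndarray, via: str = "markers") -> np.ndarray:
        """Predict new genotypes from their dose matrix.

        ``via='markers'`` uses μ̂ + (M−m̄)β̂; ``via='kinship'`` (RR-BLUP only)
        goes through the genomic relationships with the training set.  The
        two routes agree to numerical precision.
        """
        W_new = np.asarray(M_new, dtype=float) - self.col_means
        if via == "markers":
            return self.mu + W_new @ self.beta
        if via == "kinship":
            if self._W_train is None or self._Vinv_resid is None:
                raise ValueError("kinship route only available for RR-BLUP fits")
            G_nt = (W_new @ self._W_train.T) / self._denom
            return self.mu + self.sigma2_g * (G_nt @ self._Vinv_resid)
        raise ValueError("via must be 'markers' or 'kinship'")


def fit_rrblup(y: np.ndarray, M: np.ndarray) -> PredictionFit:
    """RR-BLUP via its GBLUP equivalent: REML on G, then a BLUP back-solve."""
    y = np.asarray(y, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    if n != y.size:
        raise ValueError("y and M are misaligned")
    if n < 10:
        raise ValueError("fewer than 10 training genotypes")
    col_means = M.mean(axis=0)
    W = M - col_means
    p = col_means / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic")
    G = (W @ W.T) / denom
    if np.ptp(y) == 0:
        # degenerate flat phenotype: predictions are the constant mean
        beta = np.zeros(m)
        return PredictionFit(
            model="RRBLUP", mu=float(y[0]), beta=beta, ghat=np.zeros(n),
            col_means=col_means, sigma2_g=0.0, sigma2_e=0.0,
            _W_train=W, _Vinv_resid=np.zeros(n), _denom=denom,
        )
    res = emma_reml(y, np.ones((n, 1)), G)
    mu = float(res.beta[0])
    resid = y - mu
    # V⁻¹ r through the eigendecomposition: V = σ²g (G + δ I)
    rt = res.U.T @ resid
    Vinv_resid = res.U @ (rt / (res.sigma2_g * (res.S + res.delta)))
    beta = (res.sigma2_g / denom) * (W.T @ Vinv_resid)
    ghat = W @ beta
    return PredictionFit(
        model="RRBLUP", mu=mu, beta=beta, ghat=ghat, col_means=col_means,
        sigma2_g=res.sigma2_g, sigma2_e=res.sigma2_e,
        extras={"delta": res.delta, "loglik": res.loglik},
        _W_train=W, _Vinv_resid=Vinv_resid, _denom=denom,
    )


def ridge_solution(y: np.ndarray, M: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Closed-form ridge on centred doses with an unpenalised intercept."""
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(M, dtype=float)
    W = W - W.mean(axis=0)
    mu = float(y.mean())
    m = W.shape[1]
    beta = np.linalg.solve(W.T @ W + lam * np.eye(m), W.T @ (y - mu))
    return mu, beta


def _chain_params(chain: tuple[int, int, int] | dict | None) -> tuple[int, int, int]:
    if chain is None:
        return 10_000, 2_000, 5
    if isinstance(chain, dict):
        return chain.get("n_iter", 10_000), chain.get("burn_in", 2_000), chain.get("thin", 5)
    n_iter, burn_in, thin = chain
    if n_iter <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    return n_iter, burn_in, thin


def _check_finite(arrs, it: int) -> None:
    for a in arrs:
        if not np.all(np.isfinite(a)):
            raise RuntimeError(f"non-finite Gibbs draw at iteration {it}")


def fit_bayesian_lasso(
    y: np.ndarray,
    M: np.ndarray,
    chain: tuple[int, int, int] | dict | None = None,
    seed: int = 0,
    lambda2_fixed: float | None = None,
    tau2_fixed: float | None = None,
    lambda_shape: float = 0.55,
    lambda_rate: float = 1e-4,
    store_samples: bool = False,
) -> PredictionFit:
    """Bayesian LASSO Gibbs sampler (double-exponential prior on effects).

    ``lambda2_fixed`` pins the regularisation; ``tau2_fixed`` degenerates the
    prior to equal fixed variances (the Gibbs sampler then matches ridge
    regression in posterior mean, a useful closed-form check).
    """
    n_iter, burn_in, thin = _chain_params(chain)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(M, dtype=float)
    col_means = W.mean(axis=0)
    W = W - col_means
    n, m = W.shape
    xtx = (W**2).sum(axis=0)
    mu = float(y.mean())
    beta = np.zeros(m)
    tau2 = np.full(m, tau2_fixed if tau2_fixed is not None else 1.0)
    sigma2 = float(y.var()) / 2.0 or 1.0
    lambda2 = lambda2_fixed if lambda2_fixed is not None else 1.0
    resid = y - mu

    keep_mu, keep_beta, keep_s2, keep_l2 = [], [], [], []
    kept_sum = np.zeros(m)
    kept_sq = np.zeros(m)
    n_kept = 0
    for it in range(1, n_iter + 1):
        # marker effects, single-site updates with running residual
        for j in range(m):
            if xtx[j] == 0:
                continue
            rj = resid + W[:, j] * beta[j]
            a = xtx[j] + 1.0 / tau2[j]
            mean_j = (W[:, j] @ rj) / a
            beta_j = rng.normal(mean_j, np.sqrt(sigma2 / a))
            resid = rj - W[:, j] * beta_j
            beta[j] = beta_j
        # intercept
        r0 = resid + mu
        mu = rng.normal(r0.mean(), np.sqrt(sigma2 / n))
        resid = r0 - mu
        # residual variance (prior ∝ 1/σ²)
        scale = (resid @ resid + np.sum(beta**2 / tau2)) / 2.0
        sigma2 = scale / rng.gamma((n - 1 + m) / 2.0, 1.0)
        if tau2_fixed is None:
            # 1/τ² | rest ~ InverseGaussian(√(λ²σ²/β²), λ²)
            mu_ig = np.sqrt(lambda2 * sigma2 / np.maximum(beta**2, 1e-30))
            mu_ig = np.minimum(mu_ig, 1e8)
            inv_tau2 = rng.wald(mu_ig, lambda2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            if lambda2_fixed is None:
                rate = tau2.sum() / 2.0 + lambda_rate
                lambda2 = rng.gamma(m + lambda_shape, 1.0 / rate)
        _check_finite((beta, [mu, sigma2, lambda2]), it)
        if it > burn_in and (it - burn_in) % thin == 0:
            keep_mu.append(mu)
            keep_s2.append(sigma2)
            keep_l2.append(lambda2)
            kept_sum += beta
            kept_sq += beta**2
            n_kept += 1
            if store_samples:
                keep_beta.append(beta.copy())
    if n_kept == 0:
        raise ValueError("no post-burn-in samples kept; lengthen the chain")
    beta_mean = kept_sum / n_kept
    beta_sd = np.sqrt(np.maximum(kept_sq / n_kept - beta_mean**2, 0.0))
    fit = PredictionFit(
        model="BL",
        mu=float(np.mean(keep_mu)),
        beta=beta_mean,
        ghat=W @ beta_mean,
        col_means=col_means,
        sigma2_e=float(np.mean(keep_s2)),
        extras={
            "lambda2": float(np.mean(keep_l2)),
            "n_kept": n_kept,
            "beta_sd": beta_sd,
            "chain": (n_iter, burn_in, thin),
            "seed": seed,
        },
    )
    if store_samples:
        fit.extras["beta_samples"] = np.array(keep_beta)
    return fit


def fit_brr(
    y: np.ndarray,
    M: np.ndarray,
    chain: tuple[int, int, int] | dict | None = None,
    seed: int = 0,
    sigma2_beta_fixed: float | None = None,
    df_prior: float = 5.0,
    r2_prior: float = 0.5,
    store_samples: bool = False,
) -> PredictionFit:
    """Bayesian ridge regression Gibbs sampler (common Gaussian prior).

    Scaled-inverse-χ² priors on the marker-effect variance σ²β and the
    residual σ²; scales follow the usual variance-partition heuristic
    (``r2_prior`` of var(y) assigned to markers a priori).
    """
    n_iter, burn_in, thin = _chain_params(chain)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    W = np.asarray(M, dtype=float)
    col_means = W.mean(axis=0)
    W = W - col_means
    n, m = W.shape
    xtx = (W**2).sum(axis=0)
    vy = float(y.var()) or 1.0
    sum_var_x = float(np.sum(W.var(axis=0))) or 1.0
    S_b = vy * r2_prior * (df_prior + 2.0) / sum_var_x
    S_e = vy * (1.0 - r2_prior) * (df_prior + 2.0)
    mu = float(y.mean())
    beta = np.zeros(m)
    sigma2 = vy / 2.0
    sigma2_b = sigma2_beta_fixed if sigma2_beta_fixed is not None else S_b / (df_prior + 2.0)
    resid = y - mu

    keep_mu, keep_beta, keep_s2, keep_sb = [], [], [], []
    kept_sum = np.zeros(m)
    kept_sq = np.zeros(m)
    n_kept = 0
    for it in range(1, n_iter + 1):
        for j in range(m):
            if xtx[j] == 0:
                continue
            rj = resid + W[:, j] * beta[j]
            prec = xtx[j] / sigma2 + 1.0 / sigma2_b
            mean_j = (W[:, j] @ rj) / sigma2 / prec
            beta_j = rng.normal(mean_j, np.sqrt(1.0 / prec))
            resid = rj - W[:, j] * beta_j
            beta[j] = beta_j
        r0 = resid + mu
        mu = rng.normal(r0.mean(), np.sqrt(sigma2 / n))
        resid = r0 - mu
        if sigma2_beta_fixed is None:
            sigma2_b = (beta @ beta + df_prior * S_b) / rng.chisquare(m + df_prior)
        sigma2 = (resid @ resid + df_prior * S_e) / rng.chisquare(n + df_prior)
        _check_finite((beta, [mu, sigma2, sigma2_b]), it)
        if it > burn_in and (it - burn_in) % thin == 0:
            keep_mu.append(mu)
            keep_s2.append(sigma2)
            keep_sb.append(sigma2_b)
            kept_sum += beta
            kept_sq += beta**2
            n_kept += 1
            if store_samples:
                keep_beta.append(beta.copy())
    if n_kept == 0:
        raise ValueError("no post-burn-in samples kept; lengthen the chain")
    beta_mean = kept_sum / n_kept
    beta_sd = np.sqrt(np.maximum(kept_sq / n_kept - beta_mean**2, 0.0))
    fit = PredictionFit(
        model="BRR",
        mu=float(np.mean(keep_mu)),
        beta=beta_mean,
        ghat=W @ beta_mean,
        col_means=col_means,
        sigma2_e=float(np.mean(keep_s2)),
        extras={
            "sigma2_beta": float(np.mean(keep_sb)),
            "n_kept": n_kept,
            "beta_sd": beta_sd,
            "chain": (n_iter, burn_in, thin),
            "seed": seed,
        },
    )
    if store_samples:
        fit.extras["beta_samples"] = np.array(keep_beta)
    return fit


def _fit_mean(y: np.ndarray, M: np.ndarray) -> PredictionFit:
    """Training-mean baseline (null model for calibration checks)."""
    M = np.asarray(M, dtype=float)
    return PredictionFit(
        model="MEAN", mu=float(np.mean(y)), beta=np.zeros(M.shape[1]),
        ghat=np.zeros(M.shape[0]), col_means=M.mean(axis=0),
    )


MODEL_REGISTRY: dict[str, Callable] = {
    "rrblup": lambda y, M, seed: fit_rrblup(y, M),
    "bl": lambda y, M, seed: fit_bayesian_lasso(y, M, chain=(1500, 500, 5), seed=seed),
    "brr": lambda y, M, seed: fit_brr(y, M, chain=(1500, 500, 5), seed=seed),
    "mean": lambda y, M, seed: _fit_mean(y, M),
}


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Fold bookkeeping and per-evaluation predictive abilities."""

    fold_assignment: np.ndarray    # (n_repeats, n) fold index per genotype
    abilities: np.ndarray          # (n_repeats * n_folds,) Pearson r
    mean_ability: float
    n_folds: int
    n_repeats: int
    seed: int

    def __post_init__(self) -> None:
        for rep in self.fold_assignment:
            counts = np.bincount(rep, minlength=self.n_folds)
            if counts.sum() != self.fold_assignment.shape[1] or (counts == 0).any():
                raise ValueError("folds must partition the genotypes")
        if len(self.abilities) != self.n_folds * self.n_repeats:
            raise ValueError("evaluation count must be n_folds × n_repeats")


def _ability(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson predictive ability; 0.0 when either side is constant."""
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0
    r = float(stats.pearsonr(pred, obs).statistic)
    return 0.0 if not np.isfinite(r) else r


def make_folds(n: int, n_folds: int, n_repeats: int, seed: int) -> np.ndarray:
    """Seeded fold assignments, sizes differing by at most one."""
    rng = np.random.default_rng(seed)
    assign = np.empty((n_repeats, n), dtype=int)
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        for k, chunk in enumerate(np.array_split(perm, n_folds)):
            assign[rep, chunk] = k
    return assign


def cross_validate(
    model: str | Callable,
    y: np.ndarray,
    M: np.ndarray,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    marker_subset: np.ndarray | None = None,
) -> CVResult:
    """k-fold × r-repeat cross-validation of a whole-genome model.

    Per repeat the genotypes are randomly partitioned into ``n_folds``
    near-equal disjoint subsets; the model is refit on each training
    complement (marker columns re-centred within the fold) and scored by the
    Pearson correlation between predictions and observations on the held-out
    fold.  Deterministic given ``seed``.
    """
    if n_folds < 2 or n_repeats < 1:
        raise ValueError("need n_folds >= 2 and n_repeats >= 1")
    y = np.asarray(y, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    n = y.size
    if marker_subset is not None:
        M = M[:, marker_subset]
    fit_fn = MODEL_REGISTRY[model] if isinstance(model, str) else model
    assign = make_folds(n, n_folds, n_repeats, seed)
    abilities = []
    for rep in range(n_repeats):
        for k in range(n_folds):
            test = assign[rep] == k
            if test.sum() < 3:
                raise ValueError("a fold has < 3 test genotypes; correlation unstable")
            train = ~test
            fit = fit_fn(y[train], M[train], seed + 7919 * rep + k)
            pred = fit.predict(M[test])
            abilities.append(_ability(pred, y[test]))
    abilities = np.asarray(abilities)
    return CVResult(
        fold_assignment=assign,
        abilities=abilities,
        mean_ability=float(abilities.mean()),
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GWAS-informed marker subsetting
# ---------------------------------------------------------------------------


@dataclass
class SubsetExperimentResult:
    """Mean predictive ability per (p-value threshold, model)."""

    table: pd.DataFrame    # threshold_label, threshold, model, n_markers, ability
    scheme: str

    def __post_init__(self) -> None:
        for model, grp in self.table.groupby("model"):
            nm = grp.sort_values("threshold", ascending=False, na_position="first")
            vals = nm["n_markers"].dropna().to_numpy()
            if (np.diff(vals) > 0).any():
                raise ValueError("n_markers must be non-increasing as thresholds tighten")


def _resolve_thresholds(thresholds: Sequence, m: int, alpha: float = 0.05):
    out = []
    for t in thresholds:
        if isinstance(t, str) and t.lower() == "all":
            out.append(("all", np.nan))
        elif isinstance(t, str) and t.lower() == "bonferroni":
            out.append(("bonferroni", bonferroni_threshold(alpha, m)))
        else:
            out.append((f"{float(t):g}", float(t)))
    return out


def subset_prediction_experiment(
    blues: pd.Series,
    geno: GenotypeMatrix,
    thresholds: Sequence = ("all", 0.05, 0.01, 1e-3, 1e-4, 1e-5, "bonferroni"),
    models: Sequence[str] = ("rrblup",),
    scheme: str = "within_fold",
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> SubsetExperimentResult:
    """Predictive ability of GWAS-p-value marker subsets (threshold ladder).

    ``within_fold`` (default, unbiased): the mixed-model scan is run on each
    training fold only, and the subset selected from those p-values.
    ``full_data``: one scan on the complete data defines the subsets reused
    across folds — an optimistically biased variant some analyses use; its
    use is logged prominently.  A threshold yielding zero
    markers in any training fold is recorded as undefined (NaN), not raised.
    """
    if scheme not in ("within_fold", "full_data"):
        raise ValueError("scheme must be within_fold or full_data")
    ids = [g for g in blues.index if not pd.isna(blues[g])]
    sub = geno.subset_samples(ids)
    y = blues.loc[ids].to_numpy(dtype=float)
    M = sub.dosages(impute=True)
    n, m = M.shape
    specs = _resolve_thresholds(thresholds, m)
    assign = make_folds(n, n_folds, n_repeats, seed)

    if scheme == "full_data":
        logger.warning(
            "subset_prediction_experiment: full_data scheme selects markers on "
            "the complete data set; reported abilities are optimistically biased"
        )
        K = vanraden_kinship(sub)
        scan = mlm_scan(pd.Series(y, index=ids), sub, K, p3d=True)
        pfull = scan.table["p"].to_numpy()

    rows = []
    for label, thr in specs:
        for model in models:
            fit_fn = MODEL_REGISTRY[model]
            abilities = []
            n_markers_used = []
            undefined = False
            for rep in range(assign.shape[0]):
                for k in range(n_folds):
                    test = assign[rep] == k
                    train = ~test
                    if label == "all":
                        cols = np.arange(m)
                    elif scheme == "full_data":
                        cols = np.where(np.nan_to_num(pfull, nan=np.inf) <= thr)[0]
                    else:
                        tr_ids = [ids[i] for i in np.where(train)[0]]
                        tr_geno = sub.subset_samples(tr_ids)
                        Ktr = vanraden_kinship(tr_geno)
                        tr_scan = mlm_scan(
                            pd.Series(y[train], index=tr_ids), tr_geno, Ktr, p3d=True
                        )
                        ptr = tr_scan.table["p"].to_numpy()
                        cols = np.where(np.nan_to_num(ptr, nan=np.inf) <= thr)[0]
                    if cols.size == 0:
                        undefined = True
                        break
                    n_markers_used.append(cols.size)
                    fit = fit_fn(y[train], M[np.ix_(train, cols)], seed + 7919 * rep + k)
                    pred = fit.predict(M[np.ix_(test, cols)])
                    abilities.append(_ability(pred, y[test]))
                if undefined:
                    break
            rows.append(
                {
                    "threshold_label": label,
                    "threshold": thr,
                    "model": model,
                    "n_markers": np.nan if undefined else float(np.mean(n_markers_used)),
                    "ability": np.nan if undefined else float(np.mean(abilities)),
                    "n_evaluations": 0 if undefined else len(abilities),
                }
            )
    return SubsetExperimentResult(table=pd.DataFrame(rows), scheme=scheme)
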