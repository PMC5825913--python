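"""Kinship, linkage disequilibrium and population-structure estimation.

The genomic relationship matrix follows VanRaden: allele-dose columns are
centred at twice the sample allele frequency and G = WWᵀ / 2Σp(1−p).  For the
compressed mixed model the panel is clustered (average linkage on max(G)−G)
and kinship averaged within group blocks.  LD is the squared Pearson
correlation r² of dose vectors; its decay with physical distance is fitted
with the drift–mutation (Hill–Weir) expectation

    E[r²](C) = [(10+C)/((2+C)(11+C))] ·
               [1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))],   C = c·d,

and the LD extent is the distance where the fitted curve crosses a chosen
threshold (0.2 by default).  Ancestry is estimated under the binomial
admixture model (genotype dose g_ij ~ Binomial(2, Σ_k q_ik p_jk)) by an EM
algorithm, with the number of groups K chosen by masked-entry
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import MISSING, GenotypeMatrix, logger

_P_EPS = 1e-6  # allele-frequency clamp keeping the likelihood finite


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """VanRaden genomic relationship matrix, optionally compressed to groups."""

    G: np.ndarray
    samples: list[str]
    denominator: float
    groups: pd.Series | None = None          # sample -> group id
    G_compressed: np.ndarray | None = None   # group-level kinship

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.shape[0] != G.shape[1] or G.shape[0] != len(self.samples):
            raise ValueError("G must be square and match samples")
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        self.G = G
        if self.G_compressed is not None and self.groups is not None:
            if self.G_compressed.shape[0] != self.groups.nunique():
                raise ValueError("compressed matrix dimension != number of groups")

    @property
    def n(self) -> int:
        return len(self.samples)

    def expanded(self) -> np.ndarray:
        """Individual-level kinship implied by the group compression."""
        if self.G_compressed is None or self.groups is None:
            return self.G
        idx = self.groups.to_numpy()
        return self.G_compressed[np.ix_(idx, idx)]


def vanraden_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """G = WWᵀ / 2Σp(1−p), W the 0/1/2 doses centred at 2p (sample p).

    Missing calls are imputed to the marker mean before centring.
    """
    X = geno.dosages(impute=True)
    p = X.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    return KinshipMatrix(G=G, samples=list(geno.samples), denominator=denom)


def compress_kinship(km: KinshipMatrix, n_groups: int) -> KinshipMatrix:
    """Average-linkage clustering of genotypes and block-mean kinship.

    Distance is max(G) − G.  Group labels are renumbered by first occurrence
    so that ``n_groups == n`` reproduces the original matrix exactly.
    """
    n = km.n
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [1, {n}]")
    if n_groups == n:
        groups = pd.Series(np.arange(n), index=km.samples)
        return KinshipMatrix(
            G=km.G, samples=km.samples, denominator=km.denominator,
            groups=groups, G_compressed=km.G.copy(),
        )
    D = km.G.max() - km.G
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    labels = fcluster(linkage(squareform(D, checks=False), method="average"),
                      t=n_groups, criterion="maxclust")
    # renumber by first occurrence for deterministic ordering
    order: dict[int, int] = {}
    idx = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        idx[i] = order[lab]
    k = len(order)
    Gc = np.zeros((k, k))
    for a in range(k):
        ia = idx == a
        for b in range(a, k):
            ib = idx == b
            Gc[a, b] = Gc[b, a] = km.G[np.ix_(ia, ib)].mean()
    groups = pd.Series(idx, index=km.samples)
    return KinshipMatrix(
        G=km.G, samples=km.samples, denominator=km.denominator,
        groups=groups, G_compressed=Gc,
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(geno: GenotypeMatrix, j: int, k: int) -> float:
    """Squared Pearson correlation between dose vectors of markers j and k.

    Genotypes missing at either marker, or failing the depth mask at either
    marker, are excluded.
    """
    x = geno.calls[:, j].astype(float)
    y = geno.calls[:, k].astype(float)
    ok = (geno.calls[:, j] != MISSING) & (geno.calls[:, k] != MISSING)
    if geno.depth_mask is not None:
        ok &= geno.depth_mask[:, j] & geno.depth_mask[:, k]
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete observations: r² undefined")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("marker monomorphic among complete observations")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(min(r * r, 1.0))


def pairwise_r2(X: np.ndarray, obs: np.ndarray | None = None) -> np.ndarray:
    """All-pairs r² for the columns of X, pairwise-complete over ``obs``.

    ``obs`` is a boolean observed-mask of the same shape; when omitted all
    entries are used.  Computed with cross-product sums so missing data need
    no per-pair loop.  Pairs with < 2 joint observations or a constant
    marker are NaN.
    """
    X = np.asarray(X, dtype=float)
    if obs is None:
        obs = np.ones(X.shape, dtype=bool)
    B = obs.astype(float)
    Xo = np.where(obs, X, 0.0)
    N = B.T @ B
    Sx = Xo.T @ B          # Σ x_j over joint observations (rows j, cols k)
    Sxx = (Xo * Xo).T @ B
    Sxy = Xo.T @ Xo
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        varx = N * Sxx - Sx**2
        r2 = cov**2 / (varx * varx.T)
    r2[N < 2] = np.nan
    return np.clip(r2, 0.0, 1.0)


def hill_weir_expected_r2(d: np.ndarray, c: float, n: int) -> np.ndarray:
    """Drift–mutation equilibrium expectation of r² at distance d (bp)."""
    C = c * np.asarray(d, dtype=float)
    f1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    f2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return f1 * f2


@dataclass
class LDDecayFit:
    """Fitted LD-decay curve and the implied LD extent."""

    c: float                     # population recombination coefficient per bp
    n: int                       # sample size used in the expectation
    bin_centers: np.ndarray
    bin_means: np.ndarray
    extent_bp: float
    extent_is_finite: bool
    threshold: float = 0.2
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.c < 0 or (self.extent_is_finite and self.extent_bp < 0):
            raise ValueError("coefficient and extent must be >= 0")

    def predict(self, d: np.ndarray) -> np.ndarray:
        return hill_weir_expected_r2(d, self.c, self.n)


def ld_decay_fit(
    geno: GenotypeMatrix,
    max_dist: float = 1_000_000.0,
    n_bins: int = 100,
    threshold: float = 0.2,
    use_bins: bool = True,
    max_pairs: int = 500_000,
    exclude_chroms: tuple = (),
    seed: int = 0,
) -> LDDecayFit:
    """Fit the r² decay curve on intra-chromosomal pairs within ``max_dist``.

    Pairs are binned by distance (``n_bins`` equal-width bins) and the bin
    means fitted by nonlinear least squares; ``use_bins=False`` fits raw
    pairs.  The extent is the smallest distance where the fitted curve
    crosses ``threshold`` (linear interpolation on a fine grid), flagged
    infinite when the curve never falls below it.
    """
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    obs_all = geno.calls != MISSING
    if geno.depth_mask is not None:
        obs_all &= geno.depth_mask
    for chrom, grp in geno.markers.groupby("chrom", sort=False):
        if chrom in exclude_chroms:
            continue
        idx = grp.index.to_numpy()
        if idx.size < 2:
            continue
        pos = grp["pos"].to_numpy(dtype=float)
        R2 = pairwise_r2(geno.calls[:, idx].astype(float), obs_all[:, idx])
        iu, ju = np.triu_indices(idx.size, k=1)
        d = pos[ju] - pos[iu]
        keep = (d <= max_dist) & np.isfinite(R2[iu, ju])
        dists.append(d[keep])
        r2s.append(R2[iu, ju][keep])
    if not dists:
        raise ValueError("no intra-chromosomal pairs available")
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    if d.size < 100:
        raise ValueError(f"only {d.size} pairs within max_dist; need >= 100")
    if d.size > max_pairs:
        sel = np.random.default_rng(seed).choice(d.size, size=max_pairs, replace=False)
        d, r2 = d[sel], r2[sel]

    n = geno.n_samples
    if use_bins:
        edges = np.linspace(0, max_dist, n_bins + 1)
        which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                xs.append(d[sel].mean())
                ys.append(r2[sel].mean())
        xd, yd = np.asarray(xs), np.asarray(ys)
    else:
        xd, yd = d, r2

    # coarse grid start, then nonlinear least squares
    grid = np.concatenate([[0.0], np.logspace(-9, -1, 33)])
    sse = [np.sum((hill_weir_expected_r2(xd, c0, n) - yd) ** 2) for c0 in grid]
    c_start = max(grid[int(np.argmin(sse))], 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            lambda dd, c: hill_weir_expected_r2(dd, c, n),
            xd, yd, p0=[c_start], bounds=(0.0, np.inf), maxfev=10_000,
        )
        c_hat = float(popt[0])
    except RuntimeError as exc:
        raise RuntimeError(f"LD-decay fit did not converge (last c={c_start:g})") from exc

    grid_d = np.linspace(1.0, max(max_dist * 10.0, 1.0), 20_000)
    curve = hill_weir_expected_r2(grid_d, c_hat, n)
    below = np.where(curve < threshold)[0]
    if below.size == 0:
        extent, finite = float("inf"), False
    else:
        i = below[0]
        if i == 0:
            extent = float(grid_d[0])
        else:
            d0, d1 = grid_d[i - 1], grid_d[i]
            y0, y1 = curve[i - 1], curve[i]
            extent = float(d0 + (y0 - threshold) / (y0 - y1) * (d1 - d0))
        finite = True
    return LDDecayFit(
        c=c_hat, n=n, bin_centers=xd, bin_means=yd,
        extent_bp=extent, extent_is_finite=finite,
        threshold=threshold, n_pairs=int(d.size),
    )


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureFit:
    """Binomial admixture-model fit: Q ancestry fractions, P allele freqs."""

    Q: np.ndarray
    P: np.ndarray
    loglik: float
    n_iter: int
    K: int
    cv_errors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-9).any() or (self.Q > 1 + 1e-9).any():
            raise ValueError("Q entries must be in [0, 1]")
        if (self.P < _P_EPS / 2).any() or (self.P > 1 - _P_EPS / 2).any():
            raise ValueError("P entries must be in [eps, 1-eps]")


def _admixture_loglik(g0, obs, Q, P):
    F = np.clip(Q @ P.T, _P_EPS, 1.0 - _P_EPS)
    ll = np.where(obs, g0 * np.log(F) + (2.0 - g0) * np.log(1.0 - F), 0.0)
    return float(ll.sum()), F


def admixture_em(
    geno: GenotypeMatrix,
    K: int,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit by EM (multiplicative updates).

    Maximises Σ_ij over observed calls of g·log(q_i·p_j) + (2−g)·log(1−q_i·p_j)
    with multiple restarts; the best log-likelihood is kept.  Deterministic
    given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    obs = geno.calls != MISSING
    g0 = np.where(obs, geno.calls, 0).astype(float)
    n, m = g0.shape
    m_i = obs.sum(axis=1).astype(float)
    if (m_i == 0).any():
        raise ValueError("a genotype has no observed calls")
    freqs = np.clip(g0.sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)), _P_EPS, 1 - _P_EPS)
    if K == 1:
        Q = np.ones((n, 1))
        P = freqs[:, None].copy()
        ll, _ = _admixture_loglik(g0, obs, Q, P)
        return AdmixtureFit(Q=Q, P=P, loglik=ll, n_iter=0, K=1)

    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(n_restarts, 1)):
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(freqs[:, None] + rng.normal(0, 0.1, size=(m, K)), _P_EPS, 1 - _P_EPS)
        ll_prev = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            F = np.clip(Q @ P.T, _P_EPS, 1.0 - _P_EPS)
            R1 = np.where(obs, g0 / F, 0.0)            # g / f
            R0 = np.where(obs, (2.0 - g0) / (1.0 - F), 0.0)
            # Q update
            numQ = Q * (R1 @ P) + Q * (R0 @ (1.0 - P))
            Q = numQ / numQ.sum(axis=1, keepdims=True)
            # P update
            n1 = (R1.T @ Q) * P
            n0 = (R0.T @ Q) * (1.0 - P)
            P = np.clip(n1 / np.maximum(n1 + n0, 1e-300), _P_EPS, 1.0 - _P_EPS)
            ll, _ = _admixture_loglik(g0, obs, Q, P)
            if ll < ll_prev - 1e-6 * max(abs(ll_prev), 1.0):
                raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
            if ll - ll_prev < tol * max(abs(ll), 1.0) * 1e-3 or abs(ll - ll_prev) < tol:
                ll_prev = ll
                break
            ll_prev = ll
        cand = AdmixtureFit(Q=Q, P=P, loglik=ll_prev, n_iter=it, K=K)
        if best is None or cand.loglik > best.loglik:
            best = cand
    assert best is not None
    return best


def align_q_columns(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match a reference (label switching)."""
    from itertools import permutations

    K = Q.shape[1]
    best_perm, best_err = None, np.inf
    for perm in permutations(range(K)):
        err = np.abs(Q[:, list(perm)] - Q_ref).mean()
        if err < best_err:
            best_err, best_perm = err, perm
    return Q[:, list(best_perm)]


def choose_k_cv(
    geno: GenotypeMatrix,
    k_max: int,
    n_folds: int = 5,
    seed: int = 0,
    n_restarts: int = 1,
    max_iter: int = 300,
) -> dict:
    """Masked-entry cross-validation over K = 1..k_max.

    Observed genotype entries are partitioned into ``n_folds`` folds; each
    fold is masked in turn, the admixture model fitted on the remainder, and
    the masked entries scored by binomial deviance −2[g·log f̂ + (2−g)·log(1−f̂)]
    (mean per masked entry).  Returns {"cv_error": {K: err}, "best_k": argmin}.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(geno.calls != MISSING)
    n_obs = len(obs_idx)

    for attempt in range(20):
        perm = rng.permutation(n_obs)
        folds = np.array_split(perm, n_folds)
        ok = True
        for f in folds:
            masked = np.zeros(geno.calls.shape, dtype=bool)
            masked[tuple(obs_idx[f].T)] = True
            remaining = (geno.calls != MISSING) & ~masked
            if (remaining.sum(axis=0) == 0).any() or (remaining.sum(axis=1) == 0).any():
                ok = False
                break
        if ok:
            break
        logger.info("choose_k_cv: re-drawing mask (fold emptied a marker)")
    else:
        raise RuntimeError("could not draw a valid cross-validation mask")

    errors: dict[int, float] = {}
    for K in range(1, k_max + 1):
        devs = []
        for fi, f in enumerate(folds):
            masked = np.zeros(geno.calls.shape, dtype=bool)
            masked[tuple(obs_idx[f].T)] = True
            train_calls = geno.calls.copy()
            train_calls[masked] = MISSING
            train = GenotypeMatrix(
                samples=geno.samples, markers=geno.markers, calls=train_calls
            )
            fit = admixture_em(
                train, K, seed=seed + 1000 * K + fi,
                n_restarts=n_restarts, max_iter=max_iter,
            )
            F = np.clip(fit.Q @ fit.P.T, _P_EPS, 1.0 - _P_EPS)
            g = geno.calls[masked].astype(float)
            fm = F[masked]
            dev = -2.0 * (g * np.log(fm) + (2.0 - g) * np.log(1.0 - fm))
            devs.append(dev.mean())
        errors[K] = float(np.mean(devs))
    best_k = min(errors, key=errors.get)
    return {"cv_error": errors, "best_k": best_k}
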