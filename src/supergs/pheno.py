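"""Two-stage linear mixed-model phenotype analysis for multi-environment trials.

Stage 1 fits, per site and trait, a spatial LMM with genotype fixed and
independent random row and column intercepts; the genotype estimates are the
site BLUEs.  Stage 2 combines sites: with genotype fixed and environment
random it yields cross-environment BLUEs; with genotype random (on replicated
plot-level data) it yields REML estimates of the genotypic (σ²g),
genotype×environment (σ²ge) and residual (σ²e) variances, from which the
entry-mean broad-sense heritability

    h² = σ²g / (σ²g + σ²ge/t + σ²e/(r·t))

is computed for t environments and r replicates.  Fixed effects are tested
with Wald chi-square statistics; variance components with a likelihood-ratio
test against the boundary mixture ½χ²₀ + ½χ²₁.

REML machinery
--------------
Variance components are parameterised as ratios γ_k = σ²_k / σ²e and the
restricted likelihood is profiled over σ²e.  Writing W for the concatenated
random-effect design and Γ for the diagonal of ratios, V/σ²e = I + WΓWᵀ is
handled through the Woodbury identity, so each likelihood evaluation costs a
Cholesky of the q×q matrix I + Γ^{1/2}WᵀWΓ^{1/2} (q = total random levels).
The ratios are optimised on the log scale with L-BFGS-B; for fully balanced
random models the classical expected-mean-squares (ANOVA) estimators — which
coincide with REML in the interior of the parameter space — are used as a
closed-form fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .io import PhenotypeTable

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Core REML
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    """A fitted linear mixed model (REML)."""

    beta: pd.Series
    cov_beta: np.ndarray
    varcomps: dict[str, float]
    sigma2_e: float
    loglik: float
    n_obs: int
    terms: list[str]
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < -1e-10 for v in self.varcomps.values()) or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")


def _dummy(codes: pd.Series | np.ndarray) -> tuple[np.ndarray, list]:
    levels, inv = np.unique(np.asarray(codes), return_inverse=True)
    Z = np.zeros((len(inv), len(levels)))
    Z[np.arange(len(inv)), inv] = 1.0
    return Z, list(levels)


class VarCompModel:
    """REML for y = Xβ + Σ_k Z_k u_k + ε with u_k ~ N(0, σ²_k I)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray], names: list[str]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Z_list = [np.asarray(Z, dtype=float) for Z in Z_list]
        self.names = list(names)
        n, p = self.X.shape
        if n != self.y.size:
            raise ValueError("y/X shape mismatch")
        if np.linalg.matrix_rank(self.X) < p:
            raise np.linalg.LinAlgError("fixed-effect design is rank deficient")
        if n <= p:
            raise ValueError("no residual degrees of freedom (singular design)")
        self.n, self.p = n, p
        self.W = np.hstack(self.Z_list) if self.Z_list else np.zeros((n, 0))
        self.block = np.concatenate(
            [np.full(Z.shape[1], k) for k, Z in enumerate(self.Z_list)]
        ) if self.Z_list else np.zeros(0, dtype=int)
        self.q = self.W.shape[1]
        # fixed cross-products reused at every likelihood evaluation
        self.WtW = self.W.T @ self.W
        self.XtW = self.X.T @ self.W
        self.ytW = self.y @ self.W
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _core(self, gammas: np.ndarray):
        gvec = gammas[self.block] if self.q else np.zeros(0)
        gs = np.sqrt(gvec)
        if self.q:
            M = np.eye(self.q) + (gs[:, None] * self.WtW) * gs[None, :]
            cf = cho_factor(M, lower=True)
            logdetH = 2.0 * np.log(np.diag(cf[0])).sum()
            TX = self.XtW * gs  # p×q
            ty = self.ytW * gs
            sX = cho_solve(cf, TX.T)  # q×p
            sy = cho_solve(cf, ty)
            A = self.XtX - TX @ sX
            b = self.Xty - TX @ sy
            yHy = self.yty - float(ty @ sy)
        else:
            logdetH = 0.0
            A, b, yHy = self.XtX, self.Xty, self.yty
        cA = cho_factor(A, lower=True)
        beta = cho_solve(cA, b)
        rss = max(yHy - float(b @ beta), 1e-300)
        logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
        return beta, cA, rss, logdetH, logdetA

    def neg2_reml(self, log_gammas: np.ndarray) -> float:
        try:
            _, _, rss, logdetH, logdetA = self._core(np.exp(log_gammas))
        except np.linalg.LinAlgError:
            return 1e30
        nmp = self.n - self.p
        sigma2 = rss / nmp
        return nmp * (np.log(sigma2) + _LOG2PI + 1.0) + logdetH + logdetA

    def fit(self, fixed_names: list | None = None, x0: np.ndarray | None = None) -> LmmFit:
        k = len(self.Z_list)
        if k:
            x0 = np.zeros(k) if x0 is None else np.asarray(x0, dtype=float)
            res = optimize.minimize(
                self.neg2_reml,
                x0,
                method="L-BFGS-B",
                bounds=[(-16.0, 12.0)] * k,
                options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
            )
            # derivative-free polish guards against flat-likelihood stalls
            res2 = optimize.minimize(
                self.neg2_reml, res.x, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000},
            )
            if res2.fun < res.fun:
                res = res2
            gammas = np.exp(res.x)
            neg2 = res.fun
            converged = bool(np.isfinite(neg2))
        else:
            gammas = np.zeros(0)
            neg2 = self.neg2_reml(np.zeros(0))
            converged = True
        beta, cA, rss, _, _ = self._core(gammas)
        sigma2_e = rss / (self.n - self.p)
        cov_beta = sigma2_e * cho_solve(cA, np.eye(self.p))
        # ratios below the optimiser floor are reported as exactly zero
        sig = {
            name: (0.0 if g < 2e-7 else float(g * sigma2_e))
            for name, g in zip(self.names, gammas)
        }
        names = fixed_names if fixed_names is not None else list(range(self.p))
        return LmmFit(
            beta=pd.Series(beta, index=names),
            cov_beta=cov_beta,
            varcomps=sig,
            sigma2_e=float(sigma2_e),
            loglik=-0.5 * float(neg2),
            n_obs=self.n,
            terms=self.names,
            converged=converged,
        )


def reml_loglik(y, X, Z_list, varcomps: list[float], sigma2_e: float) -> float:
    """Restricted log-likelihood at fixed variance components."""
    model = VarCompModel(y, X, Z_list, [str(i) for i in range(len(Z_list))])
    se = max(sigma2_e, 1e-12)
    log_g = np.log(np.maximum(np.asarray(varcomps, dtype=float), 1e-14) / se)
    # profiled form: recompute with the implied ratios (profile σ²e is exact
    # only at the optimum, so evaluate the unprofiled likelihood directly)
    gammas = np.exp(log_g)
    _, _, rss, logdetH, logdetA = model._core(gammas)
    nmp = model.n - model.p
    return -0.5 * (nmp * (_LOG2PI + np.log(se)) + rss / se + logdetH + logdetA)


# ---------------------------------------------------------------------------
# Stage 1: per-site spatial model
# ---------------------------------------------------------------------------


def fit_site_lmm(pheno: PhenotypeTable, site, trait) -> tuple[LmmFit, pd.DataFrame]:
    """Spatial LMM at one site: genotype fixed, row and column random.

    Returns the fit and a BLUE table (genotype, blue, se).
    """
    df = pheno.site_trait(site, trait)
    if df["genotype"].nunique() < 2:
        raise ValueError(f"site {site!r}: fewer than 2 genotypes observed")
    if len(df) < 3:
        raise ValueError(f"site {site!r}: too few observations for a mixed model")
    X, geno_levels = _dummy(df["genotype"])
    Z_list, names = [], []
    for term in ("row", "col"):
        Z, levels = _dummy(df[term])
        if Z.shape[1] > 1:
            Z_list.append(Z)
            names.append(term)
    model = VarCompModel(df["value"].to_numpy(), X, Z_list, names)
    fit = model.fit(fixed_names=geno_levels)
    blues = pd.DataFrame(
        {
            "genotype": geno_levels,
            "blue": fit.beta.to_numpy(),
            "se": np.sqrt(np.diag(fit.cov_beta)),
        }
    )
    return fit, blues


# ---------------------------------------------------------------------------
# Stage 2: multi-environment model
# ---------------------------------------------------------------------------


def _is_balanced(df: pd.DataFrame) -> tuple[bool, int, int, int]:
    counts = df.groupby(["genotype", "env"], sort=False).size()
    n_g = df["genotype"].nunique()
    n_e = df["env"].nunique()
    r = int(counts.iloc[0])
    balanced = len(counts) == n_g * n_e and (counts == r).all()
    return bool(balanced), n_g, n_e, r


def _anova_varcomps(df: pd.DataFrame, n_g: int, n_e: int, r: int):
    y = df["value"].to_numpy()
    grand = y.mean()
    cell = df.groupby(["genotype", "env"], sort=False)["value"].mean()
    gm = df.groupby("genotype", sort=False)["value"].mean()
    em = df.groupby("env", sort=False)["value"].mean()
    ss_g = r * n_e * ((gm - grand) ** 2).sum()
    ss_e = r * n_g * ((em - grand) ** 2).sum()
    cell_dev = cell - gm.reindex(cell.index.get_level_values(0)).to_numpy() \
        - em.reindex(cell.index.get_level_values(1)).to_numpy() + grand
    ss_ge = r * (cell_dev**2).sum()
    fitted = cell.reindex(pd.MultiIndex.from_frame(df[["genotype", "env"]])).to_numpy()
    ss_err = ((y - fitted) ** 2).sum()
    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (n_e - 1))
    ms_err = ss_err / (n_g * n_e * (r - 1)) if r > 1 else np.nan
    ms_env = ss_e / (n_e - 1)
    s2e = float(ms_err)
    s2ge = float(max((ms_ge - ms_err) / r, 0.0))
    s2g = float(max((ms_g - ms_ge) / (r * n_e), 0.0))
    s2env = float(max((ms_env - ms_ge) / (r * n_g), 0.0))
    return s2g, s2ge, s2e, s2env


def fit_multienv_lmm(
    data: PhenotypeTable | pd.DataFrame,
    mode: str = "genotype_fixed",
    trait: str | None = None,
) -> LmmFit:
    """Combine environments: BLUEs (genotype fixed) or variance components.

    ``data`` is either a :class:`PhenotypeTable` (its ``site`` column becomes
    the environment) or a long DataFrame with columns ``genotype, env, value``
    and, for ``genotype_random``, replicated records per (genotype, env) cell
    so that σ²ge and σ²e are separable.

    ``genotype_fixed`` returns cross-environment BLUEs in ``fit.beta`` with
    environment (and, when replicated, genotype×environment) random.
    ``genotype_random`` returns REML estimates of σ²g, σ²ge and σ²e in
    ``fit.varcomps`` / ``fit.sigma2_e``.
    """
    if isinstance(data, PhenotypeTable):
        df = data.data.dropna(subset=["value"]).rename(columns={"site": "env"})
        if trait is not None:
            df = df[df["trait"] == trait]
    else:
        df = data.dropna(subset=["value"]).copy()
        if "env" not in df.columns and "site" in df.columns:
            df = df.rename(columns={"site": "env"})
    if mode not in ("genotype_fixed", "genotype_random"):
        raise ValueError("mode must be genotype_fixed or genotype_random")
    n_env = df["env"].nunique()
    if n_env < 2:
        if mode == "genotype_random":
            raise ValueError("σ²ge is unidentifiable with a single environment")
        if mode == "genotype_fixed" and n_env < 1:
            raise ValueError("no environments present")
    y = df["value"].to_numpy(dtype=float)
    replicated = (df.groupby(["genotype", "env"], sort=False).size() > 1).any()

    if mode == "genotype_fixed":
        X, geno_levels = _dummy(df["genotype"])
        Z_list, names = [], []
        if n_env > 1:
            Ze, _ = _dummy(df["env"])
            Z_list.append(Ze)
            names.append("env")
        if replicated and n_env > 1:
            Zge, _ = _dummy(df["genotype"].astype(str) + "\x00" + df["env"].astype(str))
            Z_list.append(Zge)
            names.append("gxe")
        fit = VarCompModel(y, X, Z_list, names).fit(fixed_names=geno_levels)
        fit.meta["t"] = n_env
        return fit

    # genotype_random
    if not replicated:
        raise ValueError(
            "genotype_random requires replicated (genotype, env) records to "
            "separate σ²ge from σ²e"
        )
    balanced, n_g, n_e, r = _is_balanced(df)
    Zg, geno_levels = _dummy(df["genotype"])
    Ze, _ = _dummy(df["env"])
    Zge, _ = _dummy(df["genotype"].astype(str) + "\x00" + df["env"].astype(str))
    X = np.ones((len(df), 1))
    names = ["genotype", "env", "gxe"]
    if balanced and r > 1:
        s2g, s2ge, s2e, s2env = _anova_varcomps(df, n_g, n_e, r)
        ll = reml_loglik(y, X, [Zg, Ze, Zge], [s2g, s2env, s2ge], s2e)
        mu = float(y.mean())
        fit = LmmFit(
            beta=pd.Series([mu], index=["mu"]),
            cov_beta=np.array([[s2e / len(y)]]),
            varcomps={"genotype": s2g, "env": s2env, "gxe": s2ge},
            sigma2_e=s2e,
            loglik=float(ll),
            n_obs=len(df),
            terms=names,
            meta={"method": "anova_balanced"},
        )
    else:
        fit = VarCompModel(y, X, [Zg, Ze, Zge], names).fit(fixed_names=["mu"])
        fit.meta["method"] = "reml_iterative"
    rep_counts = df.groupby(["genotype", "env"], sort=False).size().to_numpy()
    fit.meta["t"] = n_e if balanced else n_env
    fit.meta["r"] = float(len(rep_counts) / (1.0 / rep_counts).sum())  # harmonic mean
    return fit


@dataclass
class VarianceComponents:
    """σ²g, σ²ge, σ²e plus the design constants of the h² formula."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    t: int
    r: float

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variances must be >= 0")
        if self.t < 1 or self.r < 1:
            raise ValueError("t and r must be >= 1")

    @classmethod
    def from_fit(cls, fit: LmmFit) -> "VarianceComponents":
        return cls(
            sigma2_g=fit.varcomps["genotype"],
            sigma2_ge=fit.varcomps["gxe"],
            sigma2_e=fit.sigma2_e,
            t=int(fit.meta["t"]),
            r=float(fit.meta["r"]),
        )


def broad_sense_h2(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability σ²g/(σ²g + σ²ge/t + σ²e/(r·t))."""
    denom = vc.sigma2_g + vc.sigma2_ge / vc.t + vc.sigma2_e / (vc.r * vc.t)
    if denom <= 0:
        raise ValueError("all variance components are zero; h² undefined")
    return float(vc.sigma2_g / denom)


# ---------------------------------------------------------------------------
# Tests on fitted models
# ---------------------------------------------------------------------------


def wald_test_genotype(fit: LmmFit) -> tuple[float, int, float]:
    """Wald chi-square for equality of all genotype (fixed) effects."""
    k = len(fit.beta)
    if k < 2:
        raise ValueError("fit has fewer than 2 genotype levels")
    C = np.zeros((k - 1, k))
    C[:, 0] = 1.0
    C[np.arange(k - 1), np.arange(1, k)] = -1.0
    d = C @ fit.beta.to_numpy()
    S = C @ fit.cov_beta @ C.T
    try:
        stat = float(d @ np.linalg.solve(S, d))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("contrast covariance is singular") from exc
    df = k - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def lrt_random_term(fit_full: LmmFit, fit_reduced: LmmFit, tol: float = 1e-6) -> tuple[float, float]:
    """Boundary LRT (½χ²₀ + ½χ²₁) for dropping one variance component."""
    delta = fit_full.loglik - fit_reduced.loglik
    if delta < -tol:
        raise RuntimeError(
            f"full-model logL ({fit_full.loglik:.6f}) below reduced "
            f"({fit_reduced.loglik:.6f}): optimiser failure"
        )
    stat = max(0.0, 2.0 * delta)
    p = 1.0 if stat <= 0 else 0.5 * float(stats.chi2.sf(stat, 1))
    return stat, p


# ---------------------------------------------------------------------------
# Trait correlations
# ---------------------------------------------------------------------------


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def trait_correlations(blues: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between trait BLUEs.

    ``blues`` is a genotype×trait DataFrame.  Returns (r, p, stars) matrices;
    pairs with < 3 complete genotypes or a zero-variance trait are NaN.
    """
    traits = list(blues.columns)
    k = len(traits)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x = blues[traits[i]]
            y = blues[traits[j]]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            xs, ys = x[ok].to_numpy(), y[ok].to_numpy()
            if xs.std() == 0 or ys.std() == 0:
                continue
            if i == j:
                r_mat[i, j], p_mat[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(xs, ys)
            r_mat[i, j] = r_mat[j, i] = res.statistic
            p_mat[i, j] = p_mat[j, i] = res.pvalue
    r_df = pd.DataFrame(r_mat, index=traits, columns=traits)
    p_df = pd.DataFrame(p_mat, index=traits, columns=traits)
    star_df = p_df.map(_stars)
    return r_df, p_df, star_df


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------


def stage1_blues(pheno: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Per-site BLUEs for one trait: long DataFrame (genotype, env, value)."""
    frames = []
    for site in pheno.sites:
        if pheno.site_trait(site, trait).empty:
            continue
        _, blues = fit_site_lmm(pheno, site, trait)
        frames.append(
            pd.DataFrame({"genotype": blues["genotype"], "env": site, "value": blues["blue"]})
        )
    if not frames:
        raise ValueError(f"trait {trait!r} has no observations")
    return pd.concat(frames, ignore_index=True)


def combined_blues(pheno: PhenotypeTable, trait: str) -> pd.Series:
    """Two-stage cross-environment BLUEs for one trait, indexed by genotype."""
    long = stage1_blues(pheno, trait)
    if long["env"].nunique() == 1:
        return long.set_index("genotype")["value"]
    fit = fit_multienv_lmm(long, mode="genotype_fixed")
    return fit.beta
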