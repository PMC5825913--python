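"""Mixed-model association scans: EMMA REML, P3D, and the SUPER method.

The model for one trait is y = Xβ + Zu + ε with u ~ N(0, K σ²g) for a
genomic relationship matrix K.  After a spectral decomposition K = U S Uᵀ,
REML reduces to a one-dimensional optimisation over the variance ratio
δ = σ²e/σ²g.  Marker tests are generalised least squares in the rotated
space; under P3D ("population parameters previously determined") the null
variance components are reused for every marker.

SUPER raises power by building the kinship from a small set of pseudo-QTNs
(bin-wise best hits, greedily retained while the null REML likelihood
improves) and, for every test marker, excluding pseudo-QTNs in LD with it
(r² above a threshold, 0.1 by default) from that marker's kinship.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix, GeneModel, MISSING, logger
from .popgen import KinshipMatrix, vanraden_kinship

# ---------------------------------------------------------------------------
# EMMA-style REML on a kinship matrix
# ---------------------------------------------------------------------------


@dataclass
class EmmaResult:
    sigma2_g: float
    sigma2_e: float
    loglik: float
    delta: float           # σ²e / σ²g
    beta: np.ndarray
    U: np.ndarray          # eigenvectors of K
    S: np.ndarray          # eigenvalues of K


def emma_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    log_delta_bounds: tuple[float, float] = (-12.0, 12.0),
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> EmmaResult:
    """REML for y = Xβ + u + ε, u ~ N(0, Kσ²g), by spectral decomposition.

    The restricted likelihood is profiled down to the ratio δ = σ²e/σ²g and
    maximised by bounded scalar optimisation on log δ (grid endpoints are
    also checked).  ``eig`` allows reusing a precomputed eigendecomposition.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("y is constant; variance components undefined")
    if eig is None:
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        S, U = np.linalg.eigh(K)
        if S.min() < -1e-6 * max(S.max(), 1.0):
            raise ValueError("K is not positive semidefinite")
        S = np.clip(S, 0.0, None)
    else:
        S, U = eig
    yt = U.T @ y
    Xt = U.T @ X

    def neg2(log_delta: float) -> float:
        delta = np.exp(log_delta)
        D = S + delta
        w = 1.0 / D
        A = (Xt * w[:, None]).T @ Xt
        b = (Xt * w[:, None]).T @ yt
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return 1e30
        rss = float(yt @ (w * yt) - b @ beta)
        if rss <= 0:
            return 1e30
        nmp = n - p
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e30
        return nmp * np.log(rss / nmp) + np.log(D).sum() + logdetA

    lo, hi = log_delta_bounds
    res = optimize.minimize_scalar(neg2, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    cands = [(neg2(lo), lo), (neg2(hi), hi), (res.fun, float(res.x))]
    # coarse grid guards against local minima of the profiled likelihood
    for g in np.linspace(lo, hi, 25):
        cands.append((neg2(g), g))
    fbest, xbest = min(cands, key=lambda t: t[0])
    if fbest < res.fun - 1e-8:
        res = optimize.minimize_scalar(
            neg2, bounds=(max(lo, xbest - 1.5), min(hi, xbest + 1.5)),
            method="bounded", options={"xatol": 1e-8},
        )
    delta = float(np.exp(res.x))
    D = S + delta
    w = 1.0 / D
    A = (Xt * w[:, None]).T @ Xt
    b = (Xt * w[:, None]).T @ yt
    beta = np.linalg.solve(A, b)
    rss = float(yt @ (w * yt) - b @ beta)
    nmp = n - p
    sigma2_g = rss / nmp
    neg2_final = float(res.fun) + nmp * (np.log(2.0 * np.pi) + 1.0)
    return EmmaResult(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(delta * sigma2_g),
        loglik=-0.5 * neg2_final,
        delta=delta,
        beta=beta,
        U=U,
        S=S,
    )


# ---------------------------------------------------------------------------
# Mixed-model scan
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Per-marker scan results plus scan metadata."""

    table: pd.DataFrame        # chrom, pos, snp_id, effect, se, p, maf, tested
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        tested = t["tested"].to_numpy(dtype=bool)
        p = t["p"].to_numpy(dtype=float)
        if tested.any():
            pv = p[tested]
            if np.nanmin(pv) <= 0 or np.nanmax(pv) > 1:
                raise ValueError("p-values must be in (0, 1]")

    def significant(self, p_cut: float) -> pd.DataFrame:
        t = self.table
        return t[(t["tested"]) & (t["p"] <= p_cut)].copy()


def _align_y(blues: pd.Series, geno: GenotypeMatrix) -> tuple[np.ndarray, GenotypeMatrix]:
    ids = [g for g in blues.index if not pd.isna(blues[g])]
    missing = set(ids) - set(geno.samples)
    if missing:
        raise KeyError(f"genotypes absent from the marker data: {sorted(missing)[:5]}")
    sub = geno.subset_samples(ids)
    return blues.loc[ids].to_numpy(dtype=float), sub


def _gls_tests(yt, ones_t, Xt_markers, w, nmp):
    """Vectorised 2-parameter GLS (intercept + marker) in rotated space."""
    a11 = float(ones_t @ (w * ones_t))
    b1 = float(ones_t @ (w * yt))
    yWy = float(yt @ (w * yt))
    a12 = (w * ones_t) @ Xt_markers
    a22 = np.einsum("i,ij,ij->j", w, Xt_markers, Xt_markers)
    b2 = (w * yt) @ Xt_markers
    det = a11 * a22 - a12**2
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    beta = (a11 * b2 - a12 * b1) / det
    beta0 = (a22 * b1 - a12 * b2) / det
    rss = yWy - (beta0 * b1 + beta * b2)
    sigma2 = np.maximum(rss, 0.0) / nmp
    var_beta = sigma2 * a11 / det
    se = np.sqrt(np.maximum(var_beta, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=nmp)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def mlm_scan(
    blues: pd.Series,
    geno: GenotypeMatrix,
    K_matrix: KinshipMatrix | np.ndarray | None = None,
    p3d: bool = True,
    min_obs: int = 5,
) -> AssociationResult:
    """Mixed linear model scan: each marker tested by GLS in rotated space.

    ``K_matrix`` may be a :class:`KinshipMatrix` (a compressed one is
    expanded to individuals), a plain array, or ``None`` for ordinary least
    squares.  ``p3d=True`` reuses the null-model variance ratio for every
    marker; ``p3d=False`` re-estimates it per marker.  Markers with fewer
    than ``min_obs`` non-missing calls, or monomorphic ones, are flagged
    untested.
    """
    y, sub = _align_y(blues, geno)
    n = len(y)
    if isinstance(K_matrix, KinshipMatrix):
        order = [K_matrix.samples.index(s) for s in sub.samples]
        K = K_matrix.expanded()[np.ix_(order, order)]
    elif K_matrix is None:
        K = np.zeros((n, n))
    else:
        K = np.asarray(K_matrix, dtype=float)
    X0 = np.ones((n, 1))
    null = emma_reml(y, X0, K)
    U, S = null.U, null.S
    yt = U.T @ y
    ones_t = U.T @ X0.ravel()

    Xm = sub.dosages(impute=True)
    Xm = Xm - Xm.mean(axis=0)
    n_obs = (sub.calls != MISSING).sum(axis=0)
    poly = Xm.std(axis=0) > 0
    tested = (n_obs >= min_obs) & poly

    effect = np.full(sub.n_markers, np.nan)
    se = np.full(sub.n_markers, np.nan)
    pval = np.full(sub.n_markers, np.nan)
    nmp = n - 2
    if p3d:
        w = 1.0 / (S + null.delta)
        Xt = U.T @ Xm[:, tested]
        b, s, p = _gls_tests(yt, ones_t, Xt, w, nmp)
        effect[tested], se[tested], pval[tested] = b, s, p
    else:
        idx = np.where(tested)[0]
        for j in idx:
            Xj = np.column_stack([np.ones(n), Xm[:, j]])
            fit_j = emma_reml(y, Xj, K, eig=(S, U))
            w = 1.0 / (S + fit_j.delta)
            b, s, p = _gls_tests(yt, ones_t, (U.T @ Xm[:, j])[:, None], w, nmp)
            effect[j], se[j], pval[j] = b[0], s[0], p[0]

    table = sub.markers[["chrom", "pos", "id"]].rename(columns={"id": "snp_id"}).copy()
    table["effect"] = effect
    table["se"] = se
    table["p"] = pval
    table["maf"] = sub.maf()
    table["tested"] = tested
    return AssociationResult(
        table=table,
        meta={
            "kinship": "none" if K_matrix is None else "supplied",
            "p3d": p3d,
            "sigma2_g": null.sigma2_g,
            "sigma2_e": null.sigma2_e,
            "delta": null.delta,
            "n": n,
        },
    )


def genomic_inflation(pvals: np.ndarray) -> float:
    """λ_GC: median association chi-square over its null median."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# SUPER: pseudo-QTN selection and LD-excluded kinship
# ---------------------------------------------------------------------------


@dataclass
class PseudoQTNSet:
    """Markers chosen as surrogate causal loci for kinship construction."""

    indices: np.ndarray        # positions-sorted marker indices into geno
    n_bins: int
    bin_count: int
    loglik: float

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError("pseudo-QTN set is empty")


def select_pseudo_qtns(
    initial_scan: AssociationResult,
    geno: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    n_bins: int = 100,
    n_qtn_max: int = 20,
) -> PseudoQTNSet:
    """Bin-wise best hits, greedily kept while the null REML logL improves.

    The genome (concatenated chromosomes) is divided into ``n_bins`` equal-bp
    bins; the smallest-p tested marker of each bin is a candidate.  Candidates
    are added in increasing-p order (ties: smaller position) while the REML
    log-likelihood of the null model under a VanRaden kinship built from the
    selected markers improves.
    """
    if isinstance(y, pd.Series):
        yv, sub = _align_y(y, geno)
    else:
        yv, sub = np.asarray(y, dtype=float), geno
    t = initial_scan.table
    if len(t) != sub.n_markers:
        raise ValueError("scan does not cover the marker set")
    # global coordinates: chromosome offsets in order of appearance
    offsets: dict = {}
    off = 0
    for chrom, grp in sub.markers.groupby("chrom", sort=False):
        offsets[chrom] = off
        off += int(grp["pos"].max()) + 1
    gpos = t["pos"].to_numpy() + np.array([offsets[c] for c in t["chrom"]])
    span = off
    width = span / n_bins
    bin_id = np.minimum((gpos / width).astype(int), n_bins - 1)

    p = t["p"].to_numpy(dtype=float)
    tested = t["tested"].to_numpy(dtype=bool)
    candidates: list[int] = []
    for b in np.unique(bin_id):
        sel = np.where((bin_id == b) & tested & np.isfinite(p))[0]
        if sel.size == 0:
            continue
        order = sel[np.lexsort((t["pos"].to_numpy()[sel], p[sel]))]
        candidates.append(int(order[0]))
    if not candidates:
        raise ValueError("no tested markers available as pseudo-QTN candidates")
    candidates.sort(key=lambda j: (p[j], int(t["pos"].iloc[j])))

    selected: list[int] = []
    best_ll = -np.inf
    for cand in candidates[: max(n_qtn_max * 3, n_qtn_max)]:
        trial = selected + [cand]
        try:
            Ktrial = vanraden_kinship(sub.subset(marker_idx=trial)).G
        except ValueError:
            continue
        ll = emma_reml(yv, np.ones((len(yv), 1)), Ktrial).loglik
        if not selected or ll > best_ll + 1e-9:
            selected = trial
            best_ll = ll
        else:
            break
        if len(selected) >= n_qtn_max:
            break
    pos = t["pos"].to_numpy()
    selected_sorted = np.array(sorted(selected, key=lambda j: (t["chrom"].iloc[j], pos[j])))
    return PseudoQTNSet(
        indices=selected_sorted, n_bins=n_bins,
        bin_count=len(candidates), loglik=float(best_ll),
    )


def super_scan(
    blues: pd.Series,
    geno: GenotypeMatrix,
    pseudo_qtns: PseudoQTNSet,
    ld_exclude_r2: float = 0.1,
    min_obs: int = 5,
) -> AssociationResult:
    """SUPER scan: per-marker kinship from pseudo-QTNs not in LD with it.

    For each test marker, pseudo-QTNs with r² above ``ld_exclude_r2`` are
    dropped and the VanRaden kinship rebuilt from the remainder; markers
    sharing an exclusion pattern share the null REML fit.  If every
    pseudo-QTN is excluded the scan falls back to identity kinship (logged).
    """
    if not 0.0 < ld_exclude_r2 <= 1.0:
        raise ValueError("ld_exclude_r2 must be in (0, 1]")
    y, sub = _align_y(blues, geno)
    n = len(y)
    Xm = sub.dosages(impute=True)
    Xc = Xm - Xm.mean(axis=0)
    n_obs = (sub.calls != MISSING).sum(axis=0)
    poly = Xc.std(axis=0) > 0
    tested = (n_obs >= min_obs) & poly

    qidx = pseudo_qtns.indices
    Q = Xc[:, qidx]
    # r² between every marker and every pseudo-QTN (mean-imputed doses)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (Xc.T @ Q) ** 2
        den = np.outer((Xc**2).sum(axis=0), (Q**2).sum(axis=0))
        r2 = np.where(den > 0, num / den, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    keep_mat = r2 <= ld_exclude_r2   # marker × QTN retained flags

    patterns, inverse = np.unique(keep_mat, axis=0, return_inverse=True)
    effect = np.full(sub.n_markers, np.nan)
    se = np.full(sub.n_markers, np.nan)
    pval = np.full(sub.n_markers, np.nan)
    nmp = n - 2
    n_fallback = 0
    for pi, pat in enumerate(patterns):
        members = np.where((inverse == pi) & tested)[0]
        if members.size == 0:
            continue
        kept = qidx[pat]
        if kept.size == 0:
            K = np.eye(n)
            n_fallback += members.size
        else:
            try:
                K = vanraden_kinship(sub.subset(marker_idx=kept)).G
            except ValueError:
                K = np.eye(n)
                n_fallback += members.size
        null = emma_reml(y, np.ones((n, 1)), K)
        w = 1.0 / (null.S + null.delta)
        yt = null.U.T @ y
        ones_t = null.U.T @ np.ones(n)
        Xt = null.U.T @ Xc[:, members]
        b, s, p = _gls_tests(yt, ones_t, Xt, w, nmp)
        effect[members], se[members], pval[members] = b, s, p
    if n_fallback:
        logger.warning("super_scan: identity-kinship fallback for %d markers", n_fallback)

    table = sub.markers[["chrom", "pos", "id"]].rename(columns={"id": "snp_id"}).copy()
    table["effect"] = effect
    table["se"] = se
    table["p"] = pval
    table["maf"] = sub.maf()
    table["tested"] = tested
    return AssociationResult(
        table=table,
        meta={
            "kinship": "super",
            "n_pseudo_qtns": int(qidx.size),
            "ld_exclude_r2": ld_exclude_r2,
            "n_patterns": int(len(patterns)),
            "n_fallback": int(n_fallback),
            "n": n,
        },
    )


# ---------------------------------------------------------------------------
# Thresholds, genes, regions
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise p-value cut-off α/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class FlankingGenes:
    """Nearest genes left/right of a SNP, plus any gene containing it."""

    left: GeneModel | None
    right: GeneModel | None
    containing: GeneModel | None
    left_dist: int | None
    right_dist: int | None


def flanking_genes(snp: tuple[str, int], genes: list[GeneModel]) -> FlankingGenes:
    """Nearest gene ending before and starting after the SNP position.

    ``snp`` is (chrom, 1-based pos).  A gene overlapping the position is
    reported as ``containing``; an absent side is ``None``.
    """
    chrom, pos = snp
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        raise KeyError(f"chromosome {chrom!r} absent from the annotation")
    left = None
    for g in on_chrom:
        if g.end < pos and (left is None or g.end > left.end):
            left = g
    starts = [g.start for g in on_chrom]
    i = bisect.bisect_right(starts, pos)
    right = on_chrom[i] if i < len(on_chrom) else None
    containing = None
    for g in on_chrom:
        if g.start <= pos <= g.end:
            containing = g
            break
    return FlankingGenes(
        left=left,
        right=right,
        containing=containing,
        left_dist=(pos - left.end) if left else None,
        right_dist=(right.start - pos) if right else None,
    )


@dataclass
class SignificantRegion:
    """A run of significant SNPs merged across traits on one chromosome."""

    chrom: str
    start: int
    end: int
    snps: pd.DataFrame          # pos, trait, p (one row per member SNP hit)
    traits: list[str]
    pleiotropic: bool

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end < start")
        if len(self.snps) < 1 or not self.traits:
            raise ValueError("region needs >= 1 SNP and >= 1 trait")

    @property
    def width_bp(self) -> int:
        return self.end - self.start


def pleiotropic_regions(
    per_trait_significant: pd.DataFrame, merge_dist_bp: int
) -> list[SignificantRegion]:
    """Single-linkage merge of significant SNPs (pooled across traits).

    ``per_trait_significant`` needs columns ``chrom, pos, trait, p``.  SNPs on
    the same chromosome within ``merge_dist_bp`` of each other join one
    region; regions carrying >= 2 distinct traits are flagged pleiotropic.
    """
    req = {"chrom", "pos", "trait", "p"}
    if not req.issubset(per_trait_significant.columns):
        raise ValueError(f"input needs columns {sorted(req)}")
    regions: list[SignificantRegion] = []
    for chrom, grp in per_trait_significant.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > merge_dist_bp)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            block = grp.iloc[a:b]
            traits = sorted(block["trait"].unique())
            regions.append(
                SignificantRegion(
                    chrom=str(chrom),
                    start=int(block["pos"].min()),
                    end=int(block["pos"].max()),
                    snps=block.reset_index(drop=True),
                    traits=traits,
                    pleiotropic=len(traits) >= 2,
                )
            )
    return regions


def manhattan_table(result: AssociationResult, alpha: float = 0.05,
                    suggestive: float = 1e-4) -> pd.DataFrame:
    """Manhattan-ready table: chrom, pos, −log₁₀p and threshold lines."""
    t = result.table
    m = int(t["tested"].sum())
    out = t.loc[t["tested"], ["chrom", "pos", "snp_id", "p"]].copy()
    out["neg_log10_p"] = -np.log10(out["p"])
    out["bonferroni_line"] = -np.log10(bonferroni_threshold(alpha, m))
    out["suggestive_line"] = -np.log10(suggestive)
    return out.reset_index(drop=True)
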