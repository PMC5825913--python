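"""Synthetic genotypes and multi-environment phenotypes with known truth.

The generator emulates a resequenced panel of inbred crop lines: a two-group
(or K-group) admixed population of near-homozygous genotypes, per-chromosome
linkage disequilibrium decaying with physical distance, and replicated field
trials at several sites with row/column spatial trends, genotype×environment
deviations and traits of chosen plot-level heritability — including ordinal
1–9 scores obtained by binning a latent Gaussian value.

LD is produced by first-order Markov haplotype copying: walking along a
chromosome, the next allele equals the previous one with probability
exp(-rho_ld * distance) and is otherwise redrawn from the ancestral
population's allele frequency.  This gives a closed-form, tunable decay rate
without coalescent machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import MARKER_COLUMNS, GenotypeMatrix, PhenotypeTable


@dataclass
class SimulationTruth:
    """Ground truth of a simulated trait, for downstream validation."""

    causal_indices: np.ndarray
    effects: np.ndarray
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    spatial_sd: float
    h2_plot: float
    h2_entry: float
    n_sites: int
    n_reps: int
    genetic_values: np.ndarray
    mu: float = 0.0

    def __post_init__(self) -> None:
        for h in (self.h2_plot, self.h2_entry):
            if not 0.0 <= h <= 1.0:
                raise ValueError("heritability must be in [0, 1]")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")


def _default_chrom_lengths(m: int) -> dict[str, int]:
    # Two chromosomes at ~4 kb mean marker spacing, matching the 2.4–4.3
    # SNPs / 10 kb densities typical of a resequenced chickpea-sized genome.
    per = max(m // 2, 1)
    length = max(per * 4000, 10_000)
    return {"chr1": length, "chr2": length}


def _sample_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """k distinct sorted positions in [1, length]."""
    if k > length:
        raise ValueError("more markers than base pairs on a chromosome")
    pos = np.unique(rng.integers(1, length + 1, size=int(k * 1.2) + 8))
    while pos.size < k:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=k)]))
    return np.sort(rng.choice(pos, size=k, replace=False))


def simulate_genotypes(
    n: int,
    m: int,
    K: int = 2,
    alpha_admix: float = 0.2,
    chrom_lengths: Mapping[str, int] | None = None,
    rho_ld: float = 5e-6,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    fst: float = 0.15,
    het_rate: float = 0.005,
    ensure_polymorphic: bool = True,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Simulate an admixed panel of near-inbred genotypes with LD.

    Parameters
    ----------
    n, m
        Number of genotypes and markers (each >= 2).
    K
        Number of ancestral populations; individual ancestry proportions are
        Dirichlet(``alpha_admix``) draws (K=1 gives a single population).
    rho_ld
        Per-bp decay rate of the haplotype-copying probability; larger values
        mean faster LD decay.
    maf_range
        Range of ancestral allele frequencies, a sub-interval of (0, 0.5].
    fst
        Balding–Nichols divergence of the K populations from the ancestral
        frequency.
    het_rate
        Per-call probability of residual heterozygosity (inbred lines are
        near-homozygous by default).

    Returns
    -------
    (GenotypeMatrix, Q_true, P) where Q_true is n×K ancestry and P is the m×K
    matrix of population allele frequencies.
    """
    if n < 2 or m < 2:
        raise ValueError("need n >= 2 and m >= 2")
    if K < 1:
        raise ValueError("K must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if rho_ld <= 0:
        raise ValueError("rho_ld must be > 0")
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = _default_chrom_lengths(m)

    # allocate markers to chromosomes proportionally to length
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(m * lengths / lengths.sum()).astype(int)
    while counts.sum() < m:
        counts[int(np.argmax(lengths - counts))] += 1

    # ancestral and population allele frequencies
    p_anc = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)
    if fst > 0 and K > 1:
        shape = (1.0 - fst) / fst
        P = rng.beta(p_anc[:, None] * shape, (1.0 - p_anc[:, None]) * shape, size=(m, K))
    else:
        P = np.repeat(p_anc[:, None], K, axis=1)
    P = np.clip(P, 1e-3, 1.0 - 1e-3)

    if K == 1:
        Q = np.ones((n, 1))
    else:
        Q = rng.dirichlet(np.full(K, alpha_admix), size=n)

    calls = np.empty((n, m), dtype=np.int16)
    marker_rows: list[tuple] = []
    col0 = 0
    for ci, chrom in enumerate(chroms):
        mc = counts[ci]
        if mc == 0:
            continue
        pos = _sample_positions(rng, int(chrom_lengths[chrom]), mc)
        cols = slice(col0, col0 + mc)
        Pc = P[cols]
        copy_prob = np.exp(-rho_ld * np.diff(pos).astype(float))

        def _haplotypes() -> np.ndarray:
            # per-individual ancestral population for this chromosome copy
            z = (rng.random(n)[:, None] > np.cumsum(Q, axis=1)).sum(axis=1)
            freqs = Pc[:, z]  # (mc, n)
            # Markov chain on the latent uniform: kept with prob
            # exp(-rho_ld * d), else redrawn.  Thresholding the shared
            # uniform at each marker's population frequency preserves the
            # marginal Bernoulli(p) exactly while correlation decays with
            # distance.
            fresh = rng.random((mc, n))
            keep = rng.random((mc - 1, n)) < copy_prob[:, None]
            u = np.empty((mc, n))
            u[0] = fresh[0]
            for j in range(1, mc):
                u[j] = np.where(keep[j - 1], u[j - 1], fresh[j])
            return u < freqs

        h1 = _haplotypes()
        h2 = _haplotypes()
        het_mask = rng.random((mc, n)) < het_rate
        second = np.where(het_mask, h2, h1)
        calls[:, cols] = (h1.astype(np.int16) + second.astype(np.int16)).T
        for p in pos:
            marker_rows.append((chrom, int(p), f"snp_{chrom}_{p}", "A", "G"))
        col0 += mc

    if ensure_polymorphic:
        for _ in range(20):
            mono = np.where(calls.min(axis=0) == calls.max(axis=0))[0]
            if mono.size == 0:
                break
            for j in mono:
                f = float(P[j].mean())
                draws = rng.random((n, 2)) < f
                calls[:, j] = draws.sum(axis=1).astype(np.int16)

    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    gm = GenotypeMatrix(
        samples=[f"g{i:04d}" for i in range(n)], markers=markers, calls=calls
    )
    return gm, Q, P


def simulate_trait(
    geno: GenotypeMatrix,
    n_qtl: int,
    h2_plot: float,
    n_sites: int = 3,
    n_reps: int = 3,
    prop_ge: float = 0.0,
    spatial_sd: float = 0.0,
    ordinal: bool = False,
    seed: int = 0,
    trait: str = "trait",
    mu: float = 5.0,
    randomize_layout: bool = True,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Simulate a replicated multi-site field trial on a genotype panel.

    The additive genetic value is a sum of ``n_qtl`` standard-normal marker
    effects, rescaled so the genetic variance is exactly 1; G×E deviations
    (variance ``prop_ge``·σ²g, independent per site), independent row and
    column effects (sd ``spatial_sd``) and a residual solved so the expected
    plot-level heritability equals ``h2_plot`` complete the phenotype.
    Ordinal traits are the latent values quantile-binned to 1–9.
    """
    n, m = geno.n_samples, geno.n_markers
    if not 0.0 < h2_plot <= 1.0:
        raise ValueError("h2_plot must be in (0, 1]")
    if n_qtl == 0 and h2_plot > 0:
        raise ValueError("n_qtl = 0 cannot produce a heritable trait")
    if n_qtl > m:
        raise ValueError("n_qtl exceeds the number of markers")
    if n_reps < 1 or n_sites < 1:
        raise ValueError("need n_sites >= 1 and n_reps >= 1")
    rng = np.random.default_rng(seed)

    causal = np.sort(rng.choice(m, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    X = geno.dosages(impute=True)[:, causal]
    X = X - X.mean(axis=0)
    g_raw = X @ effects
    sd = g_raw.std()
    if sd <= 0:
        raise ValueError("causal markers carry no variation")
    g = (g_raw - g_raw.mean()) / sd  # genetic variance exactly 1
    effects = effects / sd

    sigma2_g = 1.0
    sigma2_ge = prop_ge * sigma2_g
    sigma2_spatial = 2.0 * spatial_sd**2
    sigma2_e = sigma2_g / h2_plot - sigma2_g - sigma2_ge - sigma2_spatial
    if sigma2_e < -1e-12:
        raise ValueError(
            "h2_plot incompatible with prop_ge/spatial_sd (residual variance < 0)"
        )
    sigma2_e = max(sigma2_e, 0.0)

    records: list[tuple] = []
    ge = rng.normal(0.0, np.sqrt(sigma2_ge), size=(n, n_sites)) if sigma2_ge > 0 else np.zeros((n, n_sites))
    for s in range(n_sites):
        site = f"site{s + 1}"
        row_eff = rng.normal(0.0, spatial_sd, size=n_reps) if spatial_sd > 0 else np.zeros(n_reps)
        col_eff = rng.normal(0.0, spatial_sd, size=n) if spatial_sd > 0 else np.zeros(n)
        for r in range(n_reps):
            order = rng.permutation(n) if randomize_layout else np.arange(n)
            noise = rng.normal(0.0, np.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)
            for c, i in enumerate(order):
                y = mu + g[i] + ge[i, s] + row_eff[r] + col_eff[c] + noise[c]
                records.append((geno.samples[i], site, r + 1, r + 1, c + 1, trait, y))

    data = pd.DataFrame(
        records, columns=["genotype", "site", "rep", "row", "col", "trait", "value"]
    )
    ordinal_traits: frozenset = frozenset()
    if ordinal:
        ranks = data["value"].rank(method="first")
        data["value"] = np.ceil(ranks / len(ranks) * 9).clip(1, 9)
        ordinal_traits = frozenset([trait])

    t, r = n_sites, n_reps
    h2_entry = sigma2_g / (sigma2_g + sigma2_ge / t + sigma2_e / (r * t))
    truth = SimulationTruth(
        causal_indices=causal,
        effects=effects,
        sigma2_g=sigma2_g,
        sigma2_ge=sigma2_ge,
        sigma2_e=sigma2_e,
        spatial_sd=spatial_sd,
        h2_plot=h2_plot,
        h2_entry=h2_entry,
        n_sites=n_sites,
        n_reps=n_reps,
        genetic_values=g,
        mu=mu,
    )
    return PhenotypeTable(data=data, ordinal_traits=ordinal_traits), truth
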