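"""Data containers and file I/O for the GWAS / genomic-selection pipeline.

The pipeline starts from a VCF of biallelic SNPs (0/1/2 allele dosages on a
panel of mostly inbred lines), plot-level multi-environment phenotype tables,
and a GFF3 gene annotation used for flanking-gene reports.  Coordinates are
1-based inclusive throughout, following the VCF/GFF convention.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("supergs")

#: Sentinel for a missing genotype call.
MISSING: int = -1

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
PHENO_KEY_COLUMNS = ["genotype", "site", "rep", "row", "col"]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


class EmptyResultError(ValueError):
    """Raised when filtering leaves no usable markers."""


def setup_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    """Log to stderr, and additionally to ``logfile`` when given."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = "%(asctime)s %(levelname)s %(name)s: %(message)s"
    logging.basicConfig(level=level, format=fmt, handlers=handlers, force=True)


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """An n×m matrix of 0/1/2 allele dosages with a marker map.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``calls``.
    markers
        DataFrame with columns ``chrom, pos, id, ref, alt`` (1-based ``pos``,
        strictly increasing within each chromosome).
    calls
        Integer matrix in {0, 1, 2, MISSING} of shape (n_samples, n_markers).
    depth_mask
        Optional boolean matrix marking calls supported by at least the read
        depth threshold used at import time; ``None`` means all calls trusted.
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    depth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        n, m = self.calls.shape
        if n != len(self.samples):
            raise ValueError(f"calls has {n} rows but {len(self.samples)} samples")
        if m != len(self.markers):
            raise ValueError(f"calls has {m} columns but {len(self.markers)} markers")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        self.markers = self.markers.reset_index(drop=True)
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        pos = self.markers["pos"].to_numpy()
        if (pos < 1).any():
            raise ValueError("positions must be >= 1")
        for _, grp in self.markers.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if not (np.diff(p) > 0).all():
                raise ValueError("positions must be strictly increasing per chromosome")
        if self.depth_mask is not None and self.depth_mask.shape != self.calls.shape:
            raise ValueError("depth_mask shape mismatch")

    # -- basic descriptors --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        tot = np.where(self.calls == MISSING, 0, self.calls).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, tot / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def het_rate(self) -> float:
        obs = self.calls != MISSING
        return float((self.calls == 1).sum() / max(obs.sum(), 1))

    def dosages(self, impute: bool = True) -> np.ndarray:
        """Float dosage matrix; missing calls become NaN or the marker mean."""
        X = self.calls.astype(float)
        X[self.calls == MISSING] = np.nan
        if impute:
            means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(np.isnan(X))
            X[idx] = means[idx[1]]
        return X

    # -- subsetting ---------------------------------------------------------

    def subset(
        self,
        sample_idx: Sequence[int] | None = None,
        marker_idx: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        dm = self.depth_mask[np.ix_(si, mi)] if self.depth_mask is not None else None
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            markers=self.markers.iloc[mi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, mi)],
            depth_mask=dm,
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing[:5]}")
        return self.subset(sample_idx=[lookup[s] for s in ids])

    def filter_maf(self, maf_min: float) -> "GenotypeMatrix":
        """Keep markers whose sample MAF exceeds ``maf_min`` (strict)."""
        keep = np.where(self.maf() > maf_min)[0]
        if keep.size == 0:
            raise EmptyResultError(f"no markers with MAF > {maf_min}")
        return self.subset(marker_idx=keep)


def read_vcf(path: str, maf_min: float = 0.0, depth_min: int | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; markers are then filtered to sample
    MAF > ``maf_min`` (computed on non-missing calls).  Heterozygous calls are
    retained as dosage 1.  When FORMAT/DP is present and ``depth_min`` is
    given, ``depth_mask`` marks calls with DP >= ``depth_min``; otherwise the
    mask is all-true.
    """
    from cyvcf2 import VCF

    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises various types on bad headers
        raise VcfParseError(f"{path}: cannot open VCF ({exc})") from exc
    samples = list(vcf.samples)
    rows: list[tuple] = []
    calls: list[np.ndarray] = []
    depths: list[np.ndarray | None] = []
    n_skipped = 0
    record_no = 0
    try:
        for record_no, var in enumerate(vcf, start=1):
            if not var.is_snp or len(var.ALT) != 1:
                n_skipped += 1
                continue
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            dp = None
            if depth_min is not None:
                try:
                    dp_arr = var.format("DP")
                except Exception:
                    dp_arr = None
                if dp_arr is not None:
                    dp = np.asarray(dp_arr).reshape(-1) >= depth_min
            rows.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}_{var.POS}", var.REF, var.ALT[0]))
            calls.append(dose.astype(np.int16))
            depths.append(dp)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF near record {record_no}: {exc}") from exc
    if not rows:
        raise EmptyResultError(f"{path}: no biallelic SNP records found")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    call_mat = np.vstack(calls).T  # (n_samples, n_markers)
    if depth_min is not None:
        mask = np.ones_like(call_mat, dtype=bool)
        for j, dp in enumerate(depths):
            if dp is not None:
                mask[:, j] = dp
    else:
        mask = None
    gm = GenotypeMatrix(samples=samples, markers=markers, calls=call_mat, depth_mask=mask)
    het = gm.het_rate()
    if het > 0:
        logger.info("read_vcf: %.3f%% heterozygous calls retained as dosage 1", 100 * het)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if maf_min > 0:
        gm = gm.filter_maf(maf_min)
    logger.info("read_vcf: %d samples × %d markers from %s", gm.n_samples, gm.n_markers, path)
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT fields from a genotype matrix."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=supergs\n")
        for chrom, grp in gm.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, rec in gm.markers.iterrows():
            gts = "\t".join(gt_map[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['id']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Long-format plot-level phenotype records.

    ``data`` has columns ``genotype, site, rep, row, col, trait, value``;
    ``ordinal_traits`` flags 1–9 scored traits (their non-missing values must
    lie in [1, 9]).
    """

    data: pd.DataFrame
    ordinal_traits: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        required = PHENO_KEY_COLUMNS + ["trait", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        self.ordinal_traits = frozenset(self.ordinal_traits)
        dup = self.data.duplicated(subset=["genotype", "site", "rep", "trait"])
        if dup.any():
            bad = self.data.loc[dup, ["genotype", "site", "rep", "trait"]]
            raise ValueError(
                "duplicate (genotype, site, rep, trait) records:\n"
                + bad.head(10).to_string(index=False)
            )
        for t in self.ordinal_traits:
            v = self.data.loc[self.data["trait"] == t, "value"].dropna()
            if len(v) and not ((v >= 1) & (v <= 9)).all():
                raise ValueError(f"ordinal trait {t!r} has values outside [1, 9]")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))

    @property
    def sites(self) -> list:
        return list(pd.unique(self.data["site"]))

    @property
    def genotypes(self) -> list:
        return list(pd.unique(self.data["genotype"]))

    def site_trait(self, site, trait) -> pd.DataFrame:
        sel = (self.data["site"] == site) & (self.data["trait"] == trait)
        return self.data.loc[sel].dropna(subset=["value"])

    def to_wide(self) -> pd.DataFrame:
        wide = self.data.pivot_table(
            index=PHENO_KEY_COLUMNS, columns="trait", values="value", aggfunc="first"
        ).reset_index()
        wide.columns.name = None
        return wide[PHENO_KEY_COLUMNS + self.traits]


def read_phenotypes(path: str, sep: str | None = None, ordinal_traits: Iterable[str] = ()) -> PhenotypeTable:
    """Read a delimited plot-level phenotype file into long format.

    The header must name ``genotype, site, rep, row, col`` plus one column per
    trait.  Non-numeric trait cells become missing values and are counted in
    the log.  Duplicate (genotype, site, rep) rows are an error.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    wide = pd.read_csv(path, sep=sep)
    missing = [c for c in PHENO_KEY_COLUMNS if c not in wide.columns]
    if missing:
        raise ValueError(f"{path}: header lacks columns {missing}")
    dup = wide.duplicated(subset=["genotype", "site", "rep"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicated (genotype, site, rep) rows:\n"
            + wide.loc[dup, ["genotype", "site", "rep"]].to_string(index=False)
        )
    trait_cols = [c for c in wide.columns if c not in PHENO_KEY_COLUMNS]
    if not trait_cols:
        raise ValueError(f"{path}: no trait columns found")
    n_coerced = 0
    for c in trait_cols:
        before = wide[c].notna().sum()
        wide[c] = pd.to_numeric(wide[c], errors="coerce")
        n_coerced += before - wide[c].notna().sum()
    if n_coerced:
        logger.info("read_phenotypes: %d non-numeric cells set to missing", n_coerced)
    long = wide.melt(id_vars=PHENO_KEY_COLUMNS, value_vars=trait_cols, var_name="trait", value_name="value")
    long = long.sort_values(["trait", "site", "rep", "genotype"], kind="stable").reset_index(drop=True)
    return PhenotypeTable(data=long, ordinal_traits=frozenset(ordinal_traits))


def write_phenotypes(pheno: PhenotypeTable, path: str, sep: str | None = None) -> None:
    """Write the table back to wide delimited text (stable formatting)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    wide = pheno.to_wide()
    wide = wide.sort_values(["site", "rep", "genotype"], kind="stable").reset_index(drop=True)
    wide.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (1-based inclusive) used for flanking-gene reports."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")


def read_gff(path: str) -> list[GeneModel]:
    """Read gene-type features from a GFF3 file, sorted by (chrom, start).

    Non-gene features are ignored; records with end < start are rejected with
    a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            logger.warning("read_gff: rejecting %s (end < start)", feat.id)
            continue
        desc = ""
        for key in ("description", "Note", "product", "Name"):
            if key in feat.attributes:
                desc = feat.attributes[key][0]
                break
        genes.append(
            GeneModel(
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                gene_id=feat.id,
                description=desc,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    logger.info("read_gff: %d genes from %s", len(genes), path)
    return genes


def write_association(table: pd.DataFrame, path: str) -> None:
    """Write an association scan as TSV (chrom, pos, snp_id, effect, se, p, maf)."""
    cols = ["chrom", "pos", "snp_id", "effect", "se", "p", "maf"]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")
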