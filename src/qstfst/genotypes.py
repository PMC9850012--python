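"""Genotype matrices: VCF input, QC filters, and genotype PCA.

The central container is :class:`GenotypeMatrix`, a dense matrix of allele
dosages (0/1/2, -1 for missing) for maternal trees, with a cluster label per
sample.  Filters mirror common SNP-array QC practice for open-pollinated
progeny trials: a per-genotype-class carrier count (an alternative to a MAF
cutoff that guards against leverage points in downstream regressions) and
loose per-sample / per-locus missingness cutoffs applied sample-first.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_genotype_class_count",
    "filter_missingness",
    "GenotypePCA",
    "pca_genotypes",
]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosages for a set of samples.

    Parameters
    ----------
    samples : array of sample identifiers, in matrix row order.
    loci : DataFrame with columns ``chrom, pos, ref, alt`` in column order.
    calls : int8 array, shape (n_samples, n_loci); values in {0, 1, 2, -1}.
    populations : Series mapping sample id -> cluster label.
    noncoding_mask : optional boolean array per locus.
    """

    samples: np.ndarray
    loci: pd.DataFrame
    calls: np.ndarray
    populations: pd.Series
    noncoding_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")
        missing_labels = set(self.samples) - set(self.populations.index)
        if missing_labels:
            raise ValueError(
                "samples without population label: " + ", ".join(sorted(missing_labels))
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_labels(self) -> np.ndarray:
        """Cluster label per sample, in matrix row order."""
        return self.populations.loc[self.samples].to_numpy()

    def missing_fraction(self, axis: str) -> np.ndarray:
        """Fraction of missing calls per 'sample' or per 'locus'."""
        m = self.calls == MISSING
        if axis == "sample":
            return m.mean(axis=1) if self.n_loci else np.zeros(self.n_samples)
        if axis == "locus":
            return m.mean(axis=0) if self.n_samples else np.zeros(self.n_loci)
        raise ValueError("axis must be 'sample' or 'locus'")

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        locus_idx = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        mask = self.noncoding_mask[locus_idx] if self.noncoding_mask is not None else None
        return GenotypeMatrix(
            samples=self.samples[sample_idx],
            loci=self.loci.iloc[locus_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(sample_idx, locus_idx)],
            populations=self.populations,
            noncoding_mask=mask,
        )


@dataclass
class FilterReport:
    """Bookkeeping for one QC filter pass."""

    filter_name: str
    n_samples_in: int
    n_samples_out: int
    n_loci_in: int
    n_loci_out: int
    removal_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_samples_in - sum(
            v for k, v in self.removal_counts.items() if k.startswith("sample")
        ) == self.n_samples_out
        assert self.n_loci_in - sum(
            v for k, v in self.removal_counts.items() if k.startswith("locus")
        ) == self.n_loci_out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": self.filter_name, "axis": "sample",
             "n_in": self.n_samples_in, "n_out": self.n_samples_out},
            {"filter": self.filter_name, "axis": "locus",
             "n_in": self.n_loci_in, "n_out": self.n_loci_out},
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

def read_popfile(popfile) -> pd.Series:
    pop = pd.read_csv(popfile, sep="\t", header=None, names=["sample", "cluster"],
                      dtype=str, comment="#")
    return pop.set_index("sample")["cluster"]


def read_vcf(path, popfile, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Load a biallelic VCF plus a two-column (sample, cluster) TSV.

    GT fields are converted to alternate-allele dosage; half calls and
    ``./.`` become missing.  Multi-allelic records raise unless
    ``split_multiallelic`` is set, in which case the first ALT allele is kept
    and other alternate alleles are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    pops = read_popfile(popfile)
    orphans = sorted(set(samples) - set(pops.index))
    if orphans:
        raise ValueError("VCF samples missing from population file: " + ", ".join(orphans))

    rows, columns = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            if not split_multiallelic:
                raise ValueError(
                    f"multi-allelic record at {v.CHROM}:{v.POS}; "
                    "rerun with split_multiallelic=True to keep the first ALT"
                )
        alt = v.ALT[0] if v.ALT else "."
        geno = np.array([g[:2] for g in v.genotypes], dtype=np.int32)
        dosage = np.where(
            (geno < 0).any(axis=1), MISSING, (geno == 1).sum(axis=1)
        ).astype(np.int8)
        # extra alternate alleles (allele index >= 2) are not interpretable
        # as a biallelic dosage -> missing
        dosage[(geno >= 2).any(axis=1)] = MISSING
        rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": alt})
        columns.append(dosage)
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, populations=pops)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path, popfile=None) -> None:
    """Write a minimal VCF v4.2 (GT only) and optionally the population TSV."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.samples)) + "\n")
        buf = io.StringIO()
        for j in range(G.n_loci):
            loc = G.loci.iloc[j]
            gts = "\t".join(_GT_CODE[int(d)] for d in G.calls[:, j])
            buf.write(f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\tGT\t{gts}\n")
        fh.write(buf.getvalue())
    if popfile is not None:
        G.populations.loc[G.samples].rename_axis("sample").rename("cluster").to_csv(
            popfile, sep="\t", header=False
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_genotype_class_count(
    G: GenotypeMatrix, min_per_class: int = 5
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci where each genotype class (0, 1, 2) has enough carriers.

    A locus survives only if hom-ref, het and hom-alt each have at least
    ``min_per_class`` non-missing individuals; this removes rare-genotype
    loci whose few carriers would act as leverage points.
    """
    counts = np.stack([(G.calls == d).sum(axis=0) for d in (0, 1, 2)], axis=0)
    keep = (counts >= min_per_class).all(axis=0)
    out = G.subset(locus_idx=np.flatnonzero(keep))
    report = FilterReport(
        filter_name=f"genotype_class_count(min={min_per_class})",
        n_samples_in=G.n_samples, n_samples_out=out.n_samples,
        n_loci_in=G.n_loci, n_loci_out=out.n_loci,
        removal_counts={"locus_class_count": int((~keep).sum())},
    )
    return out, report


def filter_missingness(
    G: GenotypeMatrix,
    max_sample_missing: float = 0.7,
    max_locus_missing: float = 0.7,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Two-pass missingness filter: samples first, then loci.

    Removal is strict (fraction strictly greater than the threshold is
    removed), and the locus pass recomputes missingness on the surviving
    samples only.
    """
    if not (0 <= max_sample_missing <= 1 and 0 <= max_locus_missing <= 1):
        raise ValueError("missingness thresholds must be in [0, 1]")
    keep_s = G.missing_fraction("sample") <= max_sample_missing
    G1 = G.subset(sample_idx=np.flatnonzero(keep_s))
    keep_l = G1.missing_fraction("locus") <= max_locus_missing
    out = G1.subset(locus_idx=np.flatnonzero(keep_l))
    report = FilterReport(
        filter_name=f"missingness(sample>{max_sample_missing}, locus>{max_locus_missing})",
        n_samples_in=G.n_samples, n_samples_out=out.n_samples,
        n_loci_in=G.n_loci, n_loci_out=out.n_loci,
        removal_counts={
            "sample_missingness": int((~keep_s).sum()),
            "locus_missingness": int((~keep_l).sum()),
        },
    )
    return out, report


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class GenotypePCA(BaseEstimator):
    """PCA of a genotype matrix with per-locus mean imputation.

    Missing dosages are imputed by the locus mean, loci are centred, and by
    default no variance scaling is applied (EIGENSTRAT-like convention;
    set ``scale=True`` for unit-variance loci).

    Attributes
    ----------
    scores_ : (n_samples, n_components) array of PC scores.
    explained_variance_ : eigenvalues of the sample covariance.
    percent_variance_ : percent of total variance per component.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, G: GenotypeMatrix):
        if G.n_samples < 2 or G.n_loci < 2:
            raise ValueError("PCA needs at least 2 samples and 2 loci")
        X = G.calls.astype(float)
        X[X == MISSING] = np.nan
        mu = np.nanmean(X, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)  # all-missing locus -> constant 0
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[1]]
        X -= mu
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            nz = sd > 0
            X[:, nz] /= sd[nz]
        if not np.any(X.std(axis=0) > 0):
            raise ValueError("genotype matrix has zero variance; PCA undefined")
        k = min(self.n_components, G.n_samples - 1, G.n_loci)
        pca = PCA(n_components=k, svd_solver="full")
        self.scores_ = pca.fit_transform(X)
        self.explained_variance_ = pca.explained_variance_
        self.percent_variance_ = 100.0 * pca.explained_variance_ratio_
        self.samples_ = G.samples.copy()
        return self

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores_.shape[1])]
        return pd.DataFrame(self.scores_, index=self.samples_, columns=cols)


def pca_genotypes(G: GenotypeMatrix, n_components: int = 2, scale: bool = False):
    """Functional wrapper: returns (scores DataFrame, percent variance)."""
    est = GenotypePCA(n_components=n_components, scale=scale).fit(G)
    return est.scores_frame(), est.percent_variance_
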