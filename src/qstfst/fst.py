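"""Per-SNP Weir & Cockerham FST and the pairwise-averaged empirical distribution.

The estimator is the classic variance-components theta-hat = a / (a + b + c),
with a the among-population, b the among-individual-within-population and c
the within-individual component, computed per locus from sample sizes, allele
frequencies and observed heterozygosity.  For more than two clusters the
default summary averages, per SNP, the estimates over all cluster pairs with
a defined value; a multi-population theta is available as an option.

Negative per-SNP estimates (small true differentiation plus sampling noise)
are kept in the raw distribution; the "positive part" used as the neutral
reference for trait-divergence tests discards them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "FstDistribution",
    "wc_fst_pair",
    "wc_fst_multi",
    "pairwise_fst_distribution",
    "multi_fst_distribution",
    "fst_quantile",
    "WeirCockerhamFst",
]


def _pop_stats(calls: np.ndarray):
    """Per-locus (n, p, h) for one population's dosage rows."""
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
        h = ((calls == 1) & obs).sum(axis=0) / n
    return n, p, h


def _wc_components(ns, ps, hs):
    """Weir & Cockerham (1984) a, b, c for r populations, vectorised over loci.

    ``ns, ps, hs`` are (r, L) arrays of sample sizes, allele frequencies and
    observed heterozygote frequencies.  Loci where any population has < 2
    genotyped individuals are returned as NaN.
    """
    ns = np.asarray(ns, float)
    ps = np.asarray(ps, float)
    hs = np.asarray(hs, float)
    r = ns.shape[0]
    valid = (ns >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = ns.sum(axis=0)
        nbar = S / r
        nc = (S - (ns**2).sum(axis=0) / S) / (r - 1)
        pbar = (ns * ps).sum(axis=0) / S
        s2 = (ns * (ps - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ns * hs).sum(axis=0) / S
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def _theta(a, b, c):
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta


def _pop_rows(G: GenotypeMatrix, label) -> np.ndarray:
    rows = np.flatnonzero(G.pop_labels == label)
    if rows.size == 0:
        raise ValueError(f"unknown population label: {label!r}")
    return rows


def wc_fst_pair(G: GenotypeMatrix, popA, popB, return_components: bool = False):
    """Per-SNP Weir-Cockerham FST between two clusters.

    Returns an array of length ``n_loci`` with NaN where the locus is not
    evaluable (fewer than two genotyped individuals in either cluster, or a
    zero total variance a + b + c).
    """
    ra, rb = _pop_rows(G, popA), _pop_rows(G, popB)
    na, pa, ha = _pop_stats(G.calls[ra])
    nb, pb, hb = _pop_stats(G.calls[rb])
    a, b, c = _wc_components(np.stack([na, nb]), np.stack([pa, pb]), np.stack([ha, hb]))
    theta = _theta(a, b, c)
    if np.all(np.isnan(theta)):
        raise ValueError(
            f"no locus evaluable for pair ({popA}, {popB}); "
            "each cluster needs >=2 genotyped samples at some locus"
        )
    if return_components:
        return theta, (a, b, c)
    return theta


def wc_fst_multi(G: GenotypeMatrix, labels=None) -> np.ndarray:
    """Multi-population Weir-Cockerham theta per SNP (all clusters jointly)."""
    labels = list(labels) if labels is not None else sorted(set(G.pop_labels))
    stats = [_pop_stats(G.calls[_pop_rows(G, lab)]) for lab in labels]
    ns = np.stack([s[0] for s in stats])
    ps = np.stack([s[1] for s in stats])
    hs = np.stack([s[2] for s in stats])
    return _theta(*_wc_components(ns, ps, hs))


@dataclass
class FstDistribution:
    """Empirical genome-wide FST distribution (pair-averaged per SNP)."""

    per_snp: np.ndarray            # pair-averaged theta per locus (NaN undefined)
    n_pairs_used: np.ndarray       # defined pairs entering each locus average
    mean_method: str               # convention behind `mean_fst`
    mean_fst: float
    ratio_of_sums: float           # sum(a)/sum(a+b+c) pooled over loci & pairs
    positive_part: np.ndarray = field(repr=False)
    q95: float = np.nan

    def quantile(self, q: float) -> float:
        return fst_quantile(self, q)

    def summary(self) -> dict:
        return {
            "n_loci": int(np.sum(~np.isnan(self.per_snp))),
            "n_positive": int(self.positive_part.size),
            "mean_fst": float(self.mean_fst),
            "mean_method": self.mean_method,
            "ratio_of_sums": float(self.ratio_of_sums),
            "q95": float(self.q95),
        }


def pairwise_fst_distribution(G: GenotypeMatrix, clusters=None) -> FstDistribution:
    """Per-SNP FST averaged over all cluster pairs, with positive-part summary.

    For each locus the pair estimates with a defined value are averaged;
    pairs that are undefined at that locus are dropped from the average
    rather than zero-filled.
    """
    labels = list(clusters) if clusters is not None else sorted(set(G.pop_labels))
    if len(labels) < 2:
        raise ValueError("need at least two clusters for FST")
    thetas, num, den = [], 0.0, 0.0
    for la, lb in combinations(labels, 2):
        theta, (a, b, c) = wc_fst_pair(G, la, lb, return_components=True)
        thetas.append(theta)
        num += np.nansum(a)
        den += np.nansum(a + b + c)
    T = np.stack(thetas)  # (n_pairs, L)
    defined = ~np.isnan(T)
    n_pairs_used = defined.sum(axis=0)
    if not np.any(n_pairs_used > 0):
        raise ValueError("FST undefined at every locus")
    sums = np.where(defined, T, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(n_pairs_used > 0, sums / n_pairs_used, np.nan)
    return _make_distribution(
        per_snp, n_pairs_used, "mean_of_ratios",
        ratio_of_sums=float(num / den) if den != 0 else np.nan,
    )


def _make_distribution(per_snp, n_pairs_used, method, ratio_of_sums=np.nan):
    vals = per_snp[~np.isnan(per_snp)]
    positive = np.sort(vals[vals > 0])
    q95 = float(np.quantile(positive, 0.95)) if positive.size else np.nan
    return FstDistribution(
        per_snp=per_snp,
        n_pairs_used=n_pairs_used,
        mean_method=method,
        mean_fst=float(vals.mean()),
        ratio_of_sums=ratio_of_sums,
        positive_part=positive,
        q95=q95,
    )


def multi_fst_distribution(G: GenotypeMatrix, clusters=None) -> FstDistribution:
    """Per-SNP multi-population theta distribution over all clusters jointly.

    The per-SNP drift noise of this estimator matches that of a neutral
    polygenic trait among the same clusters (both have r - 1 degrees of
    freedom of drift), which makes its positive-part q95 the calibrated
    reference for the trait-divergence rule; the pair-averaged distribution
    is narrower and anti-conservative for that purpose.
    """
    labels = list(clusters) if clusters is not None else sorted(set(G.pop_labels))
    if len(labels) < 2:
        raise ValueError("need at least two clusters for FST")
    stats = [_pop_stats(G.calls[_pop_rows(G, lab)]) for lab in labels]
    ns = np.stack([s[0] for s in stats])
    ps = np.stack([s[1] for s in stats])
    hs = np.stack([s[2] for s in stats])
    a, b, c = _wc_components(ns, ps, hs)
    per_snp = _theta(a, b, c)
    if np.all(np.isnan(per_snp)):
        raise ValueError("FST undefined at every locus")
    den = np.nansum(a + b + c)
    n_used = np.where(np.isnan(per_snp), 0, len(labels) * (len(labels) - 1) // 2)
    return _make_distribution(
        per_snp, n_used, "multi_population",
        ratio_of_sums=float(np.nansum(a) / den) if den != 0 else np.nan,
    )


def fst_quantile(dist: FstDistribution, q: float) -> float:
    """Empirical quantile (type-7 linear interpolation) of the positive part."""
    if dist.positive_part.size == 0:
        raise ValueError("positive part of the FST distribution is empty")
    return float(np.quantile(dist.positive_part, q))


class WeirCockerhamFst(BaseEstimator):
    """Estimator wrapper around :func:`pairwise_fst_distribution`.

    Attributes after ``fit``: ``distribution_``, ``per_snp_``, ``mean_``,
    ``q95_``.
    """

    def __init__(self, clusters=None):
        self.clusters = clusters

    def fit(self, G: GenotypeMatrix, y=None):
        self.distribution_ = pairwise_fst_distribution(G, self.clusters)
        self.per_snp_ = self.distribution_.per_snp
        self.mean_ = self.distribution_.mean_fst
        self.q95_ = self.distribution_.q95
        return self

    def per_snp_frame(self, G: GenotypeMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": G.loci["chrom"], "pos": G.loci["pos"], "fst": self.per_snp_}
        )
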