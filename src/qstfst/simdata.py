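"""Synthetic genotypes and phenotypes with the structure of a two-site
open-pollinated progeny trial.

Genetic clusters diverge by drift under the Balding-Nichols model: cluster
allele frequencies are Beta-distributed around an ancestral frequency with a
single parameter mapping directly to the expected fixation index.  Maternal
trees (one per half-sib family) are genotyped; offspring phenotypes are drawn
from the variance-component structure the downstream mixed models assume:
cluster, block-in-site and family random effects plus a residual, a fixed
per-cluster mean offset ordered by latitude rank, and a linear ontogenetic
trend over cambial rings.

Trait values are produced on the mean-normalised scale times a nominal trait
mean, i.e. value = mean * (1 + offset + trend + cluster + block + family +
residual), so the configured variance components are the components of the
mean-normalised trait regardless of measurement units.  Age at breast height
(ABH) is generated per tree on its raw scale in years.

An explicit-locus mode is provided for neutrality checks: a polygenic trait
is built as a weighted sum of genotypes, and offspring records inherit the
maternal genetic value wholesale, so the family variance estimates the full
within-cluster genetic variance (the convention the trait-divergence ratio
sigmaA^2 / (sigmaA^2 + 2 sigmaF^2) assumes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, write_vcf

__all__ = [
    "SimConfig",
    "SimOutput",
    "TRAITS",
    "draw_cluster_frequencies",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "simulate_neutral_polygenic_trait",
    "offspring_phenotypes_from_breeding_values",
]

TRAITS = ("dbh", "rw", "wd", "trw", "ttw", "twt")

#: cluster labels ordered by decreasing latitude, as in the trial material
DEFAULT_CLUSTERS = ("CSE", "RBA", "NPL", "CEU", "ALP", "CSE-ALP")


def _default_ontogeny():
    # DBH roughly quadruples over rings 3-13; the other traits vary far less
    return {"dbh": 0.12, "rw": 0.04, "wd": 0.04, "trw": 0.04, "ttw": 0.04, "twt": 0.04}


def _default_trait_means():
    return {"dbh": 60.0, "rw": 3.0, "wd": 400.0, "trw": 30.0, "ttw": 25.0, "twt": 2.5}


@dataclass
class SimConfig:
    """Generating parameters for one synthetic trial.

    Variance components are on the mean-normalised trait scale and apply to
    each of the six ring traits; ABH has its own components on the scale of
    years.  Defaults emulate the real trial: 6 clusters, 396 families over
    two sites with 20/23 incomplete blocks, components matching the fitted
    values for stem diameter, and a drift divergence matching the observed
    genome-wide average fixation index.
    """

    n_clusters: int = 6
    families_per_cluster: int = 66
    offspring_per_family_per_site: int = 6
    n_sites: int = 2
    blocks_per_site: tuple = (20, 23)
    n_snps: int = 20000
    ancestral_freq_law: tuple = (0.05, 0.95)   # uniform bounds
    fst_target: float = 0.0488
    var_cluster: float = 2.37e-2               # sigmaA^2
    var_family: float = 3.03e-2                # sigmaF^2
    var_block: float = 4.3e-2                  # sigmaB^2
    var_resid: float = 1.72e-1                 # sigma^2
    cluster_means: tuple | None = None         # per-cluster offsets, latitude order
    ring_range: tuple = (3, 13)
    ontogeny_slopes: dict = field(default_factory=_default_ontogeny)
    trait_means: dict = field(default_factory=_default_trait_means)
    abh_mean: float = 5.0
    abh_var_cluster: float = 1.05e-2
    abh_var_family: float = 7.44e-2
    abh_var_block: float = 0.33
    abh_var_resid: float = 1.32
    missing_rate_geno: float = 0.2
    seed: int = 0
    exact_component_variance: bool = False     # standardise realised effect draws
    balanced_blocks: bool = False              # round-robin instead of random blocks

    def __post_init__(self):
        for name in ("var_cluster", "var_family", "var_block", "var_resid",
                     "abh_var_cluster", "abh_var_family", "abh_var_block",
                     "abh_var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 <= self.missing_rate_geno < 1:
            raise ValueError("missing_rate_geno must be in [0, 1)")
        if self.families_per_cluster < 3:
            raise ValueError("families_per_cluster must be >= 3")
        lo, hi = self.ring_range
        if not (1 <= lo <= hi <= 13):
            raise ValueError("ring_range must be within [1, 13]")
        if self.cluster_means is None:
            self.cluster_means = tuple(np.linspace(-0.05, 0.05, self.n_clusters))
        if len(self.cluster_means) != self.n_clusters:
            raise ValueError("cluster_means length must equal n_clusters")
        if len(self.blocks_per_site) != self.n_sites:
            raise ValueError("blocks_per_site length must equal n_sites")

    @property
    def cluster_labels(self):
        if self.n_clusters == len(DEFAULT_CLUSTERS):
            return list(DEFAULT_CLUSTERS)
        return [f"P{k + 1}" for k in range(self.n_clusters)]

    @property
    def site_labels(self):
        base = ["FF1146", "FF1147"]
        if self.n_sites <= 2:
            return base[: self.n_sites]
        return base + [f"S{i + 1}" for i in range(2, self.n_sites)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_means"] = list(self.cluster_means)
        d["blocks_per_site"] = list(self.blocks_per_site)
        return d


@dataclass
class SimOutput:
    """One simulated dataset plus the generating truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "popfile": outdir / "populations.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
            "truth": outdir / "truth.json",
        }
        write_vcf(self.genotypes, paths["vcf"], popfile=paths["popfile"])
        self.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def draw_cluster_frequencies(p_anc, fst_target: float, n_clusters: int, seed):
    """Balding-Nichols cluster allele frequencies.

    Each cluster's frequency at each SNP is drawn independently from
    Beta(p (1-F)/F, (1-p) (1-F)/F) around the ancestral frequency ``p``,
    which has mean p and variance F p (1-p).  F = 0 degenerates to the
    ancestral frequencies.  Boundary draws (loss or fixation) are allowed.
    """
    p_anc = np.atleast_1d(np.asarray(p_anc, float))
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    if not 0 <= fst_target < 1:
        raise ValueError("fst_target must be in [0, 1)")
    if fst_target == 0:
        return np.tile(p_anc, (n_clusters, 1))
    rng = np.random.default_rng(seed)
    scale = (1.0 - fst_target) / fst_target
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(n_clusters, p_anc.size))


def simulate_genotypes(freqs, mothers_per_cluster: int, missing_rate: float, seed,
                       cluster_labels=None, sample_ids=None) -> GenotypeMatrix:
    """Diploid maternal genotypes Binomial(2, p) with injected missingness."""
    freqs = np.asarray(freqs, float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("cluster frequencies must be in [0, 1]")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    n_clusters, n_snps = freqs.shape
    if cluster_labels is None:
        cluster_labels = (
            list(DEFAULT_CLUSTERS) if n_clusters == len(DEFAULT_CLUSTERS)
            else [f"P{k + 1}" for k in range(n_clusters)]
        )
    rng = np.random.default_rng(seed)
    calls = np.concatenate(
        [
            rng.binomial(2, freqs[k], size=(mothers_per_cluster, n_snps))
            for k in range(n_clusters)
        ]
    ).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    if sample_ids is None:
        sample_ids = [
            f"{cluster_labels[k]}_fam{j + 1:03d}"
            for k in range(n_clusters)
            for j in range(mothers_per_cluster)
        ]
    pops = pd.Series(
        np.repeat(cluster_labels, mothers_per_cluster), index=sample_ids, name="cluster"
    )
    loci = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 100,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(
        samples=np.asarray(sample_ids, dtype=object),
        loci=loci,
        calls=calls,
        populations=pops,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _draw_effects(rng, n, sd, exact):
    x = rng.normal(0.0, 1.0, n)
    if exact and n > 1 and sd > 0:
        x = (x - x.mean()) / x.std(ddof=1)
    return sd * x


def simulate_phenotypes(config: SimConfig, seed=None) -> pd.DataFrame:
    """Long-format offspring phenotype table for the configured trial.

    One row per tree x ring, with design factors (site, block, family,
    cluster), ABH per tree, a calendar formation year per ring, and the six
    ring traits.  Family effects are shared by a family's offspring at both
    sites; block membership is randomised within site (incomplete blocks).
    """
    lo, hi = config.ring_range
    rings = np.arange(lo, hi + 1)
    if rings.size == 0:
        raise ValueError("empty ring_range")
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_design = np.random.default_rng(streams[0])
    rng_abh = np.random.default_rng(streams[1])
    rng_eff = np.random.default_rng(streams[2])
    rng_resid = np.random.default_rng(streams[3])

    clusters = config.cluster_labels
    sites = config.site_labels
    fams = [
        (f"{clusters[k]}_fam{j + 1:03d}", clusters[k], k)
        for k in range(config.n_clusters)
        for j in range(config.families_per_cluster)
    ]

    rows = []
    for fam_id, cl, k in fams:
        for s_i, site in enumerate(sites):
            for o in range(config.offspring_per_family_per_site):
                rows.append((f"{fam_id}_{site}_t{o + 1}", fam_id, cl, k, site, s_i))
    trees = pd.DataFrame(
        rows, columns=["tree_id", "family", "cluster", "k", "site", "s_i"]
    )
    n_trees = len(trees)

    # incomplete blocks: random assignment within site (or round robin)
    blocks = np.empty(n_trees, dtype=object)
    for s_i, site in enumerate(sites):
        idx = np.flatnonzero(trees["s_i"].to_numpy() == s_i)
        nb = config.blocks_per_site[s_i]
        if config.balanced_blocks:
            b = np.tile(np.arange(nb), int(np.ceil(idx.size / nb)))[: idx.size]
        else:
            b = rng_design.integers(0, nb, size=idx.size)
        blocks[idx] = [f"b{j + 1:02d}" for j in b]
    trees["block"] = blocks

    exact = config.exact_component_variance
    fam_ids = [f[0] for f in fams]
    site_block = sorted(set(zip(trees["site"], trees["block"])))

    def component_effects(v_cl, v_fam, v_blk, rng):
        cl_eff = _draw_effects(rng, config.n_clusters, np.sqrt(v_cl), exact)
        fam_eff = pd.Series(
            _draw_effects(rng, len(fam_ids), np.sqrt(v_fam), exact), index=fam_ids
        )
        blk_eff = pd.Series(
            _draw_effects(rng, len(site_block), np.sqrt(v_blk), exact),
            index=pd.MultiIndex.from_tuples(site_block),
        )
        return cl_eff, fam_eff, blk_eff

    k_arr = trees["k"].to_numpy()
    fam_arr = trees["family"].to_numpy()
    sb_index = pd.MultiIndex.from_arrays([trees["site"], trees["block"]])

    # ABH: per tree, raw scale (years); southern clusters reach 1.3 m earlier
    cl_eff, fam_eff, blk_eff = component_effects(
        config.abh_var_cluster, config.abh_var_family, config.abh_var_block, rng_abh
    )
    abh_offsets = -np.asarray(config.cluster_means) * config.abh_mean
    abh = (
        config.abh_mean
        + abh_offsets[k_arr]
        + cl_eff[k_arr]
        + fam_eff.loc[fam_arr].to_numpy()
        + blk_eff.loc[sb_index].to_numpy()
        + _draw_effects(rng_abh, n_trees, np.sqrt(config.abh_var_resid), exact)
    )
    trees["abh"] = abh

    table = trees.loc[trees.index.repeat(rings.size)].reset_index(drop=True)
    table["ring"] = np.tile(rings, n_trees)
    # ring r at breast height forms ~r years after the tree reaches 1.3 m;
    # trials planted 1990, so formation year ~ 1989 + ABH + ring
    table["year"] = (1989 + np.round(table["abh"]).astype(int) + table["ring"]).astype(int)

    mid = rings.mean()
    ring_dev = (table["ring"] - mid).to_numpy()
    k_long = table["k"].to_numpy()
    fam_long = table["family"].to_numpy()
    sb_long = pd.MultiIndex.from_arrays([table["site"], table["block"]])
    offsets = np.asarray(config.cluster_means)

    for trait in TRAITS:
        cl_eff, fam_eff, blk_eff = component_effects(
            config.var_cluster, config.var_family, config.var_block, rng_eff
        )
        resid = _draw_effects(rng_resid, len(table), np.sqrt(config.var_resid), exact)
        rel = (
            1.0
            + offsets[k_long]
            + config.ontogeny_slopes[trait] * ring_dev
            + cl_eff[k_long]
            + fam_eff.loc[fam_long].to_numpy()
            + blk_eff.loc[sb_long].to_numpy()
            + resid
        )
        table[trait] = config.trait_means[trait] * rel

    cols = ["tree_id", "family", "cluster", "site", "block", "abh", "ring", "year"]
    return table[cols + list(TRAITS)].copy()


def simulate_dataset(config: SimConfig, seed=None) -> SimOutput:
    """Full trial: maternal genotypes + offspring phenotypes + truth record."""
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_anc = np.random.default_rng(streams[0])
    lo, hi = config.ancestral_freq_law
    p_anc = rng_anc.uniform(lo, hi, config.n_snps)
    freqs = draw_cluster_frequencies(
        p_anc, config.fst_target, config.n_clusters, streams[1]
    )
    genotypes = simulate_genotypes(
        freqs,
        config.families_per_cluster,
        config.missing_rate_geno,
        streams[2],
        cluster_labels=config.cluster_labels,
    )
    phenotypes = simulate_phenotypes(config, seed=seed)
    truth = {"config": config.to_dict(), "seed": int(seed)}
    return SimOutput(genotypes=genotypes, phenotypes=phenotypes, truth=truth)


# ---------------------------------------------------------------------------
# Explicit-locus neutral traits
# ---------------------------------------------------------------------------

def simulate_neutral_polygenic_trait(G: GenotypeMatrix, n_causal: int,
                                     effect_sd: float, seed) -> pd.Series:
    """Additive breeding values from randomly chosen causal loci.

    Effects are i.i.d. N(0, effect_sd^2); the trait is the dosage-weighted
    sum over the causal loci.  Missing dosages are imputed by the locus mean
    so every individual gets a value.
    """
    if n_causal <= 0:
        raise ValueError("n_causal must be >= 1")
    if n_causal > G.n_loci:
        raise ValueError("n_causal exceeds the number of loci")
    rng = np.random.default_rng(seed)
    loci = rng.choice(G.n_loci, size=n_causal, replace=False)
    effects = rng.normal(0.0, effect_sd, n_causal)
    X = G.calls[:, loci].astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    return pd.Series(X @ effects, index=G.samples, name="breeding_value")


def offspring_phenotypes_from_breeding_values(
    G: GenotypeMatrix, breeding_values: pd.Series, offspring_per_family: int,
    resid_sd: float, seed,
) -> pd.DataFrame:
    """Offspring records for the explicit-locus neutrality check.

    Each maternal genotype founds one family; offspring inherit the maternal
    genetic value wholesale plus an independent residual.  The family
    variance of the resulting table therefore estimates the full
    within-cluster genetic variance, which is what the divergence ratio
    sigmaA^2 / (sigmaA^2 + 2 sigmaF^2) divides by.
    """
    rng = np.random.default_rng(seed)
    fam = np.repeat(G.samples, offspring_per_family)
    cl = np.repeat(G.pop_labels, offspring_per_family)
    bv = np.repeat(breeding_values.loc[G.samples].to_numpy(), offspring_per_family)
    y = bv + rng.normal(0.0, resid_sd, bv.size)
    return pd.DataFrame({"y": y, "family": fam, "cluster": cl})
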