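"""Quantitative-genetic analyses per cambial ring: trait preparation,
heritability, trait divergence (QST), trend tests, family-effect PCA and the
label-shuffling variance test.

Traits are analysed on a mean-normalised scale, ring by ring.  Heritability
uses the half-sib intraclass correlation h2 = 4 sigmaF^2 / (sigmaF^2 +
sigmaB^2 + sigma^2); trait divergence uses QST = sigmaA^2 / (sigmaA^2 +
2 sigmaF^2) with the cluster variance from a model treating the genetic
cluster as a random effect.  With ideal half-sib families the family
variance is a quarter of the additive variance, in which case Spitze's
definition would read sigmaA^2 / (sigmaA^2 + 8 sigmaF^2); both denominators
are exposed (``family_var_scale``), the 2-sigmaF^2 form being the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .lmm import LmmFit, MixedModelREML, VarianceComponents, model_spec
from .simdata import TRAITS

__all__ = [
    "prepare_rings",
    "filter_families",
    "normalize_traits",
    "heritability",
    "qst",
    "QstResult",
    "per_ring_battery",
    "qst_per_trait",
    "trend_test",
    "family_effect_matrix",
    "family_effect_pca",
    "shuffle_variance_test",
    "cv_per_ring",
]


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def prepare_rings(raw: pd.DataFrame, max_ring: int = 13, drop_innermost: int = 2,
                  last_calendar_year: int | None = 2008):
    """Apply the ring filters: innermost rings, a maximum cambial age, and
    (when a ``year`` column is present) rings formed after a cutoff year.

    Returns the filtered table and a dict of per-filter removal counts.
    """
    n0 = len(raw)
    out = raw[raw["ring"] > drop_innermost]
    n_inner = n0 - len(out)
    out = out[out["ring"] <= max_ring]
    n_old = n0 - n_inner - len(out)
    n_year = 0
    if last_calendar_year is not None and "year" in out.columns:
        kept = out[out["year"] <= last_calendar_year]
        n_year = len(out) - len(kept)
        out = kept
    if len(out) == 0:
        raise ValueError("no rings left after preparation")
    report = {
        "rows_in": n0,
        "removed_innermost": int(n_inner),
        "removed_beyond_max_ring": int(n_old),
        "removed_after_cutoff_year": int(n_year),
        "rows_out": len(out),
    }
    return out.reset_index(drop=True), report


def filter_families(table: pd.DataFrame, min_offspring_per_site: int = 4,
                    min_families_per_stand: int = 3):
    """Drop families with too few offspring at either site, then (when a
    ``stand`` column is present) stands with too few surviving families."""
    counts = (
        table.groupby(["family", "site"], observed=True)["tree_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    ok = counts.ge(min_offspring_per_site).all(axis=1)
    keep_fams = set(counts.index[ok])
    out = table[table["family"].isin(keep_fams)]
    n_stand = 0
    if "stand" in table.columns:
        fams_per_stand = out.groupby("stand", observed=True)["family"].nunique()
        keep_stands = set(fams_per_stand.index[fams_per_stand >= min_families_per_stand])
        before = out["family"].nunique()
        out = out[out["stand"].isin(keep_stands)]
        n_stand = before - out["family"].nunique()
    report = {
        "families_in": int(counts.shape[0]),
        "families_removed_offspring": int((~ok).sum()),
        "families_removed_stand": int(n_stand),
        "families_out": int(out["family"].nunique()),
    }
    return out.reset_index(drop=True), report


def normalize_traits(table: pd.DataFrame, traits=TRAITS):
    """Divide each trait by its grand mean over all retained rows.

    ABH is left on its raw scale (years).  The normalised grand mean of each
    trait is exactly 1.
    """
    out = table.copy()
    for trait in traits:
        mu = out[trait].mean()
        if mu == 0:
            raise ValueError(f"grand mean of {trait!r} is zero; cannot normalise")
        out[trait] = out[trait] / mu
    out.attrs["normalized"] = True
    return out


# ---------------------------------------------------------------------------
# Heritability and trait divergence
# ---------------------------------------------------------------------------

def heritability(vc: VarianceComponents) -> float:
    """Half-sib intraclass-correlation heritability 4 sF2/(sF2 + sB2 + s2).

    Values above 1 are possible with noisy components and are returned as-is.
    """
    sF = vc.sigma2_F
    if sF is None:
        raise ValueError("no family variance component in this fit")
    sB = vc.sigma2_B or 0.0
    denom = sF + sB + vc.sigma2_resid
    if denom <= 0:
        raise ValueError("zero phenotypic variance; heritability undefined")
    return 4.0 * sF / denom


def qst(vc: VarianceComponents, family_var_scale: float = 2.0) -> float:
    """Trait divergence sigmaA^2 / (sigmaA^2 + scale * sigmaF^2).

    ``family_var_scale=2`` is the printed convention; 8 corresponds to
    Spitze's definition with ideal half-sib families (sigmaF^2 = VA/4).
    """
    sA, sF = vc.sigma2_A, vc.sigma2_F
    if sA is None or sF is None:
        raise ValueError("fit lacks cluster and/or family variance components")
    if sA == 0 and sF == 0:
        raise ValueError("both components zero; QST undefined")
    return sA / (sA + family_var_scale * sF)


@dataclass
class QstResult:
    """Per-ring and ring-averaged trait divergence for one trait."""

    trait: str
    per_ring_qst: pd.Series
    mean_qst: float
    p_empirical: float = np.nan
    significant_q95: bool | None = None


# ---------------------------------------------------------------------------
# Per-ring model battery
# ---------------------------------------------------------------------------

def per_ring_battery(table: pd.DataFrame, model_id: int, traits=TRAITS,
                     split_by_site: bool | None = None, alpha: float = 0.05):
    """Fit one mixed model per trait x ring.

    Returns ``(fits, summary)`` where ``fits`` maps (trait, ring[, site]) to
    an :class:`LmmFit` (or an error record) and ``summary`` is a tidy frame
    of Wald tests with the Bonferroni cutoff alpha / n_tests over the
    battery attached in ``summary.attrs['bonferroni']``.

    The joint ABH+cluster model is split per site by default, its ABH x site
    interaction being consistently significant in data of this design.
    """
    if split_by_site is None:
        split_by_site = model_id == 2
    rings = sorted(table["ring"].unique())
    fits, rows = {}, []
    for trait in traits:
        for ring in rings:
            sub = table[table["ring"] == ring]
            groups = (
                [(site, sub[sub["site"] == site]) for site in sorted(sub["site"].unique())]
                if split_by_site else [(None, sub)]
            )
            for site, df in groups:
                spec = model_spec(model_id, trait)
                if split_by_site:
                    fixed = tuple(t for t in spec.fixed if "site" not in t.split(":"))
                    random = tuple(
                        t.replace("site:", "") if t.startswith("site:") else t
                        for t in spec.random
                    )
                    spec = type(spec)(trait, fixed=fixed, random=random)
                key = (trait, ring) if site is None else (trait, ring, site)
                try:
                    fit = MixedModelREML(
                        response=spec.response, fixed=spec.fixed, random=spec.random
                    ).fit(df).result_
                    fits[key] = fit
                    for _, w in fit.wald.iterrows():
                        rows.append({
                            "trait": trait, "ring": ring, "site": site,
                            "term": w["term"], "chisq": w["chisq"],
                            "df": w["df"], "p": w["p"],
                        })
                except Exception as exc:  # noqa: BLE001 - battery must continue
                    fits[key] = {"error": str(exc)}
    summary = pd.DataFrame(rows)
    n_tests = len(traits) * len(rings)
    if not summary.empty:
        summary["bonferroni_significant"] = summary["p"] < alpha / n_tests
    summary.attrs["bonferroni"] = alpha / n_tests
    summary.attrs["n_tests"] = n_tests
    return fits, summary


def qst_per_trait(table: pd.DataFrame, traits=TRAITS,
                  family_var_scale: float = 2.0) -> dict:
    """Ring-by-ring divergence-model fits and ring-averaged QST per trait."""
    rings = sorted(table["ring"].unique())
    results = {}
    for trait in traits:
        per_ring = {}
        for ring in rings:
            sub = table[table["ring"] == ring]
            fit = MixedModelREML(
                response=trait, fixed=("abh",),
                random=("cluster", "site:block", "family"),
                compute_wald=False,
            ).fit(sub)
            per_ring[ring] = qst(fit.varcomp_, family_var_scale)
        s = pd.Series(per_ring, name=trait)
        results[trait] = QstResult(trait=trait, per_ring_qst=s, mean_qst=float(s.mean()))
    return results


# ---------------------------------------------------------------------------
# Trends, PCA, permutation
# ---------------------------------------------------------------------------

def trend_test(per_ring_stats) -> dict:
    """OLS slope of a per-ring statistic against cambial age, with its t-test.

    Accepts a Series indexed by ring (or a sequence, taken at ages 1..n).
    A constant series has an undefined t and is reported with NaN.
    """
    s = pd.Series(per_ring_stats).astype(float).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 cambial ages for a trend test")
    x = s.index.to_numpy(float) if s.index.is_unique else np.arange(1, len(s) + 1.0)
    res = stats.linregress(x, s.to_numpy())
    if res.stderr == 0:
        if res.slope == 0:  # constant series
            return {"slope": 0.0, "t": np.nan, "p": np.nan,
                    "note": "constant series; t undefined"}
        return {"slope": float(res.slope),  # exact line: infinite evidence
                "t": float(np.sign(res.slope) * np.inf), "p": 0.0}
    return {"slope": float(res.slope), "t": float(res.slope / res.stderr),
            "p": float(res.pvalue)}


def cv_per_ring(table: pd.DataFrame, trait: str) -> pd.Series:
    """Coefficient of variation (sd/mean over trees) of a trait per ring."""
    g = table.groupby("ring", observed=True)[trait]
    return g.std(ddof=1) / g.mean()


def family_effect_matrix(fits: dict, traits=TRAITS) -> pd.DataFrame:
    """Family x trait matrix of predicted family effects (BLUPs).

    ``fits`` maps (trait, ring[, site]) keys to fits; BLUPs are averaged
    across rings (and sites) per trait.
    """
    per_trait = {}
    for trait in traits:
        series = [
            f.ranef["family"] for k, f in fits.items()
            if k[0] == trait and isinstance(f, LmmFit) and "family" in f.ranef
        ]
        if series:
            per_trait[trait] = pd.concat(series, axis=1).mean(axis=1)
    if not per_trait:
        raise ValueError("no family effects available")
    return pd.DataFrame(per_trait).dropna()


def family_effect_pca(effects: pd.DataFrame, n_components: int = 2):
    """PCA of the family x trait effect matrix.

    Returns (scores DataFrame indexed by family, percent variance array).
    """
    import warnings

    if effects.shape[0] < effects.shape[1]:
        warnings.warn("fewer families than traits; PCA is rank-limited")
    X = effects.to_numpy(float)
    X = X - X.mean(axis=0)
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("family effects are degenerate (zero variance)")
    k = max(1, min(n_components, X.shape[1], X.shape[0] - 1))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=effects.index, columns=cols),
        100.0 * pca.explained_variance_ratio_,
    )


def shuffle_variance_test(table: pd.DataFrame, trait: str, level: str,
                          n_perm: int = 1000, seed=0) -> dict:
    """Is within-group variance smaller than under shuffled group labels?

    The statistic is the mean within-group variance of the trait over groups
    with at least two members ('family' or 'cluster' level); the null is
    built by permuting group labels across trees and the one-sided p-value
    is (1 + #{perm <= observed}) / (n_perm + 1).
    """
    if level not in ("family", "cluster"):
        raise ValueError("level must be 'family' or 'cluster'")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    df = table[[trait, level]].dropna()
    y = df[trait].to_numpy(float)
    labels = df[level].to_numpy()

    def stat(lab):
        s = pd.Series(y).groupby(pd.Series(lab), observed=True)
        var = s.var(ddof=1)
        cnt = s.count()
        return float(var[cnt >= 2].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for i in range(n_perm):
        perms[i] = stat(rng.permutation(labels))
    p = (1.0 + np.sum(perms <= observed)) / (n_perm + 1.0)
    return {"observed": observed, "perm_mean": float(perms.mean()), "p": float(p),
            "n_perm": n_perm}
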