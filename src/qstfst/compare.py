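"""The QST-vs-FST decision layer.

A trait's ring-averaged divergence (QST) is referred to the positive part of
the genome-wide per-SNP FST distribution, which serves as the empirical null
for neutral divergence: the empirical p-value is the fraction of positive
per-SNP FST values at least as large as the QST, and the trait is called
divergent when its QST exceeds the 95th percentile of that positive part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst import FstDistribution

__all__ = ["DivergenceVerdict", "qst_fst_test", "bonferroni_threshold", "verdict_table"]


@dataclass
class DivergenceVerdict:
    trait: str
    qst: float
    fst_q95: float
    p_empirical: float
    verdict: str  # 'divergent' | 'not-distinguishable'

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "qst": self.qst,
            "fst_q95": self.fst_q95,
            "p_empirical": self.p_empirical,
            "verdict": self.verdict,
        }


def qst_fst_test(qst_value: float, dist: FstDistribution, trait: str = "",
                 include_nonpositive: bool = False) -> DivergenceVerdict:
    """Refer a trait's QST to the empirical FST null.

    p = #{FST >= QST} / #{FST} over the positive part of the distribution
    (or over all defined values with ``include_nonpositive``); the verdict
    is 'divergent' iff QST exceeds the 95th percentile of the positive part.
    """
    if not 0 <= qst_value <= 1:
        raise ValueError("QST must be in [0, 1]")
    if dist.positive_part.size == 0:
        raise ValueError("positive part of the FST distribution is empty")
    if include_nonpositive:
        vals = dist.per_snp[~np.isnan(dist.per_snp)]
    else:
        vals = dist.positive_part
    p = float(np.mean(vals >= qst_value))
    q95 = dist.quantile(0.95)
    return DivergenceVerdict(
        trait=trait,
        qst=float(qst_value),
        fst_q95=float(q95),
        p_empirical=p,
        verdict="divergent" if qst_value > q95 else "not-distinguishable",
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise cutoff alpha / n_tests (e.g. 0.05/66 ~ 7.6e-4)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def verdict_table(qst_results: dict, dist: FstDistribution) -> pd.DataFrame:
    """One verdict row per trait from ring-averaged QST results."""
    rows = [
        qst_fst_test(res.mean_qst, dist, trait=trait).to_dict()
        for trait, res in qst_results.items()
    ]
    return pd.DataFrame(rows)
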