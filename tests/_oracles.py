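"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-locus / per-row loops, directly
transcribing textbook formulas, deliberately sharing no code with the
package implementations it checks.
"""

import numpy as np


def wc_fst_brute(pops):
    """Weir & Cockerham (1984) theta for one locus, looped transcription.

    ``pops`` is a list of per-population dosage arrays (0/1/2, -1 missing).
    Returns (a, b, c, theta); theta is NaN when undefined.
    """
    r = len(pops)
    ns, ps, hs = [], [], []
    for dos in pops:
        dos = np.asarray(dos)
        obs = dos[dos >= 0]
        n_i = len(obs)
        if n_i < 2:
            return np.nan, np.nan, np.nan, np.nan
        ns.append(n_i)
        ps.append(obs.sum() / (2.0 * n_i))
        hs.append(np.sum(obs == 1) / n_i)
    nbar = sum(ns) / r
    S = sum(ns)
    nc = (S - sum(n**2 for n in ns) / S) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / S
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / S
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else np.nan
    return a, b, c, theta


def balanced_oneway_anova(y, groups):
    """Method-of-moments variance components for a balanced one-way layout."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    n = len(y) // len(levels)
    means = np.array([y[groups == g].mean() for g in levels])
    msb = n * means.var(ddof=1)
    msw = np.mean([y[groups == g].var(ddof=1) for g in levels])
    return max((msb - msw) / n, 0.0), msw


def class_count_keep(calls, min_per_class):
    """Brute-force per-locus genotype-class-count predicate."""
    keep = []
    for j in range(calls.shape[1]):
        col = calls[:, j]
        ok = all(np.sum(col == d) >= min_per_class for d in (0, 1, 2))
        keep.append(ok)
    return np.array(keep)


def missingness_survivors(calls, max_sample, max_locus):
    """Brute-force two-pass (samples first) missingness filter."""
    n_s, n_l = calls.shape
    keep_s = [i for i in range(n_s) if np.mean(calls[i] < 0) <= max_sample]
    sub = calls[keep_s]
    keep_l = [j for j in range(n_l) if np.mean(sub[:, j] < 0) <= max_locus]
    return keep_s, keep_l
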