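"""Gaussian linear mixed models by REML for half-sib progeny-trial designs.

Models are variance-component models with crossed/nested categorical random
effects (block-in-site, half-sib family, genetic cluster) and a small fixed
part (site, age at breast height, cluster, and their interactions).  The
restricted likelihood is profiled over the fixed effects and the residual
variance, leaving only the variance ratios gamma_i = sigma_i^2 / sigma^2 to
optimise, constrained to gamma_i >= 0 so that boundary (singular) solutions
are attainable exactly.

With V = I + sum_i gamma_i Z_i Z_i' and q total random-effect levels, all
matrix work is reduced via the Woodbury identity to q x q operations on
K = I + L Z'Z L (L = diag(sqrt gamma)), so each objective/gradient
evaluation costs O(q^3) regardless of the number of observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import chi2
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "LmmFit",
    "MixedModelREML",
    "fit_reml",
    "wald_type2",
    "MODEL_SPECS",
    "model_spec",
]


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random term lists for one response.

    Terms are column names, with ``a:b`` denoting an interaction (fixed) or
    a composite grouping label (random, e.g. block nested in site).
    """

    response: str
    fixed: tuple = ()
    random: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))


def model_spec(model_id: int, response: str) -> ModelSpec:
    """The three trial models for a given response trait.

    1: site fixed; block-in-site and family random (heritability model).
    2: ABH, site, cluster and ABH interactions fixed; block, family random.
    3: ABH fixed; cluster, block and family random (trait-divergence model).
    """
    if model_id == 1:
        return ModelSpec(response, fixed=("site",), random=("site:block", "family"))
    if model_id == 2:
        return ModelSpec(
            response,
            fixed=("abh", "site", "cluster", "abh:cluster", "abh:site"),
            random=("site:block", "family"),
        )
    if model_id == 3:
        return ModelSpec(
            response, fixed=("abh",), random=("cluster", "site:block", "family")
        )
    raise ValueError(f"unknown model id: {model_id}")


MODEL_SPECS = {i: model_spec(i, "y") for i in (1, 2, 3)}


def _is_factor(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s)


def _component_design(data: pd.DataFrame, name: str):
    """Design columns for a single term component (factor -> treatment coding)."""
    s = data[name]
    if _is_factor(s):
        levels = sorted(pd.unique(s.astype(str)))
        cols = [(f"{name}[{lev}]", (s.astype(str) == lev).to_numpy(float))
                for lev in levels[1:]]  # first level is the reference
        return cols
    return [(name, s.to_numpy(float))]


def _term_design(data: pd.DataFrame, term: str):
    """Columns for a fixed term, products over ':'-separated components."""
    parts = term.split(":")
    cols = [("", np.ones(len(data)))]
    for part in parts:
        comp = _component_design(data, part)
        cols = [
            (f"{n1}:{n2}" if n1 else n2, x1 * x2) for n1, x1 in cols for n2, x2 in comp
        ]
    return cols


def _random_labels(data: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    lab = data[parts[0]].astype(str)
    for part in parts[1:]:
        lab = lab + ":" + data[part].astype(str)
    return lab


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Response vector, fixed design with term slices, and random indicators.

    Rows with a missing value in any used column are dropped (listwise
    deletion).  Returns ``y, X, names, term_cols, Zs, z_levels, kept_index``.
    """
    used = {spec.response}
    for t in spec.fixed + spec.random:
        used.update(t.split(":"))
    sub = data[sorted(used)].copy()
    keep = sub.notna().all(axis=1)
    sub = sub.loc[keep]
    if len(sub) == 0:
        raise ValueError("no complete observations for this model")

    y = sub[spec.response].to_numpy(float)
    names, arrays, term_cols = ["(Intercept)"], [np.ones(len(sub))], {}
    for term in spec.fixed:
        cols = _term_design(sub, term)
        term_cols[term] = list(range(len(names), len(names) + len(cols)))
        for n, x in cols:
            names.append(n)
            arrays.append(x)
    X = np.column_stack(arrays)

    Zs, z_levels = [], {}
    for term in spec.random:
        lab = _random_labels(sub, term)
        levels = sorted(pd.unique(lab))
        if len(levels) < 2:
            raise ValueError(f"random term {term!r} has fewer than 2 levels")
        idx = pd.Categorical(lab, categories=levels).codes
        Z = np.zeros((len(sub), len(levels)))
        Z[np.arange(len(sub)), idx] = 1.0
        Zs.append(Z)
        z_levels[term] = levels
    return y, X, names, term_cols, Zs, z_levels, sub.index


# ---------------------------------------------------------------------------
# Profiled REML core
# ---------------------------------------------------------------------------

class _RemlCore:
    """Profiled REML criterion and analytic gradient in the variance ratios."""

    def __init__(self, y, X, Zs):
        self.n, self.p = X.shape
        self.m = len(Zs)
        Z = np.concatenate(Zs, axis=1) if Zs else np.zeros((self.n, 0))
        self.q = Z.shape[1]
        sizes = [Zi.shape[1] for Zi in Zs]
        edges = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        self.slices = [slice(edges[i], edges[i + 1]) for i in range(self.m)]
        self.Czz = Z.T @ Z
        self.Czx = Z.T @ X
        self.Czy = Z.T @ y
        self.Cxx = X.T @ X
        self.Cxy = X.T @ y
        self.yty = float(y @ y)

    def _expand(self, gamma):
        lam = np.empty(self.q)
        for g, sl in zip(gamma, self.slices):
            lam[sl] = np.sqrt(max(g, 0.0))
        return lam

    def evaluate(self, gamma, need_grad=True, need_effects=False):
        n, p = self.n, self.p
        lam = self._expand(gamma)
        K = np.eye(self.q) + (lam[:, None] * self.Czz) * lam[None, :]
        cK = cho_factor(K, lower=True)
        logdetK = 2.0 * np.log(np.diag(cK[0])).sum()

        Lx = lam[:, None] * self.Czx          # q x p
        Ly = lam * self.Czy                   # q
        KiLx = cho_solve(cK, Lx)
        KiLy = cho_solve(cK, Ly)
        A = self.Cxx - Lx.T @ KiLx            # X'V^-1 X
        bvec = self.Cxy - Lx.T @ KiLy         # X'V^-1 y
        c0 = self.yty - Ly @ KiLy             # y'V^-1 y
        cA = cho_factor(A, lower=True)
        logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
        beta = cho_solve(cA, bvec)
        yPy = max(c0 - bvec @ beta, 1e-300)
        f = logdetK + logdetA + (n - p) * np.log(yPy)

        out = {"f": f, "beta": beta, "yPy": yPy, "A_chol": cA,
               "logdetK": logdetK, "logdetA": logdetA}
        if need_grad or need_effects:
            Mz = lam[:, None] * self.Czz      # Lambda Z'Z
            T = self.Czx - Mz.T @ KiLx        # Z'V^-1 X
            w = self.Czy - Mz.T @ KiLy        # Z'V^-1 y
            u = w - T @ beta                  # Z'P y
        if need_effects:
            out["zt_py"] = u
        if need_grad:
            S = self.Czz - Mz.T @ cho_solve(cK, Mz)   # Z'V^-1 Z
            # tr(A^-1 T_i' T_i) via triangular solve against chol(A)
            R = solve_triangular(cA[0], T.T, lower=True)  # p x q
            grad = np.empty(self.m)
            for i, sl in enumerate(self.slices):
                tr_v = np.trace(S[sl, sl])
                tr_a = float((R[:, sl] ** 2).sum())
                grad[i] = tr_v - tr_a - (n - p) * float(u[sl] @ u[sl]) / yPy
            out["grad"] = grad
        return out

    def optimize(self, tol=1e-10, starts=((0.1,), (1.0,), (0.01,))):
        if self.m == 0:
            return np.zeros(0), self.evaluate(np.zeros(0), need_grad=False), True
        best = None
        success = False

        def fun(g):
            st = self.evaluate(g)
            return st["f"], st["grad"]

        for s in starts:
            x0 = np.full(self.m, s[0]) if len(s) == 1 else np.asarray(s, float)
            res = optimize.minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, 1e8)] * self.m,
                options={"ftol": tol * 1e-2, "gtol": 1e-9, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            success = success or res.success
        gamma = np.maximum(best.x, 0.0)
        return gamma, self.evaluate(gamma, need_grad=True, need_effects=True), success


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Estimated variance components on the response scale.

    ``by_term`` maps each random term to its variance; named accessors pick
    out the conventional roles (family, block, cluster) by term name.
    """

    by_term: dict
    resid: float

    def _find(self, key: str):
        for term, v in self.by_term.items():
            if key in term:
                return v
        return None

    @property
    def sigma2_F(self):
        return self._find("family")

    @property
    def sigma2_B(self):
        return self._find("block")

    @property
    def sigma2_A(self):
        return self._find("cluster")

    @property
    def sigma2_resid(self):
        return self.resid

    def as_dict(self) -> dict:
        d = {f"sigma2[{k}]": float(v) for k, v in self.by_term.items()}
        d["sigma2[resid]"] = float(self.resid)
        return d


@dataclass
class LmmFit:
    """One converged (or flagged) REML fit."""

    spec: ModelSpec
    vc: VarianceComponents
    fixed: pd.DataFrame                 # term, name, estimate, se
    fixed_cov: np.ndarray
    wald: pd.DataFrame                  # term, chisq, df, p
    reml_loglik: float
    n_obs: int
    n_groups: dict
    converged: bool
    singular: bool
    ranef: dict = field(default_factory=dict)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "vc": self.vc.as_dict(),
            "fixed": self.fixed.to_dict(orient="records"),
            "wald": self.wald.to_dict(orient="records"),
            "reml_loglik": self.reml_loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "singular": self.singular,
        }


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class MixedModelREML(BaseEstimator):
    """REML variance-components estimator over a long-format data frame.

    Parameters mirror :class:`ModelSpec`; ``fit`` expects a DataFrame with
    the response, factor and covariate columns.  Fitted attributes:
    ``varcomp_``, ``fixef_``, ``fixef_cov_``, ``wald_``, ``ranef_``,
    ``reml_loglik_``, ``converged_``, ``singular_``.
    """

    SINGULAR_TOL = 1e-6

    def __init__(self, response="y", fixed=(), random=(), tol=1e-10,
                 compute_wald=True):
        self.response = response
        self.fixed = tuple(fixed)
        self.random = tuple(random)
        self.tol = tol
        self.compute_wald = compute_wald

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.response, self.fixed, self.random)

    def fit(self, data: pd.DataFrame, y=None):
        spec = self.spec
        y_, X, names, term_cols, Zs, z_levels, _ = build_design(data, spec)
        n, p = X.shape

        # drop linearly dependent fixed columns (pivoted QR rank detection)
        Rdiag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        if p > 0 and np.any(Rdiag < 1e-10 * max(Rdiag.max(), 1.0)):
            keep = self._independent_columns(X)
            dropped = [names[j] for j in range(p) if j not in keep]
            warnings.warn(
                "rank-deficient fixed design; dropping: " + ", ".join(dropped)
            )
            remap = {old: new for new, old in enumerate(keep)}
            term_cols = {
                t: [remap[j] for j in js if j in remap] for t, js in term_cols.items()
            }
            names = [names[j] for j in keep]
            X = X[:, keep]
            p = X.shape[1]

        core = _RemlCore(y_, X, Zs)
        gamma, state, success = core.optimize(tol=self.tol)
        sigma2 = state["yPy"] / (n - p)
        beta = state["beta"]
        cov = sigma2 * cho_solve(state["A_chol"], np.eye(p))

        self.gamma_ = gamma
        self.sigma2_ = float(sigma2)
        self.varcomp_ = VarianceComponents(
            by_term={t: float(g * sigma2) for t, g in zip(spec.random, gamma)},
            resid=float(sigma2),
        )
        self.fixef_ = pd.DataFrame(
            {
                "term": self._col_terms(names, term_cols),
                "name": names,
                "estimate": beta,
                "se": np.sqrt(np.diag(cov)),
            }
        )
        self.fixef_cov_ = cov
        self.term_cols_ = term_cols
        self.reml_loglik_ = -0.5 * (
            state["logdetK"] + state["logdetA"] + (n - p) * np.log(sigma2)
            + (n - p) * (1.0 + np.log(2.0 * np.pi))
        )
        self.converged_ = bool(success)
        self.singular_ = bool(np.any(gamma <= self.SINGULAR_TOL))
        self.n_obs_ = n
        self.n_groups_ = {t: len(z_levels[t]) for t in spec.random}
        if not success:
            warnings.warn(f"REML did not converge for response {spec.response!r}")

        # BLUPs: u_i = gamma_i * Z_i' P y (on the response scale)
        self.ranef_ = {}
        zt_py = state.get("zt_py")
        if zt_py is not None:
            for term, g, sl in zip(spec.random, gamma, core.slices):
                self.ranef_[term] = pd.Series(
                    g * zt_py[sl], index=z_levels[term], name=term
                )

        self.wald_ = (
            self._wald_type2(data) if (self.compute_wald and self.fixed)
            else pd.DataFrame(columns=["term", "chisq", "df", "p"])
        )
        self.result_ = LmmFit(
            spec=spec, vc=self.varcomp_, fixed=self.fixef_, fixed_cov=cov,
            wald=self.wald_, reml_loglik=float(self.reml_loglik_),
            n_obs=n, n_groups=self.n_groups_, converged=self.converged_,
            singular=self.singular_, ranef=self.ranef_,
        )
        return self

    @staticmethod
    def _independent_columns(X):
        # greedy left-to-right selection keeps earlier (lower-order) terms
        keep = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial, tol=1e-8 * max(np.abs(trial).max(), 1)) > len(keep):
                keep.append(j)
        return keep

    @staticmethod
    def _col_terms(names, term_cols):
        terms = ["(Intercept)"] * len(names)
        for t, js in term_cols.items():
            for j in js:
                terms[j] = t
        return terms

    def _marginal_wald(self, term):
        js = self.term_cols_.get(term, [])
        if not js:
            return np.nan, 0, np.nan
        b = self.fixef_["estimate"].to_numpy()[js]
        C = self.fixef_cov_[np.ix_(js, js)]
        stat = float(b @ np.linalg.solve(C, b))
        df = len(js)
        return stat, df, float(chi2.sf(stat, df))

    def _wald_type2(self, data: pd.DataFrame) -> pd.DataFrame:
        """Type-II Wald chi-square tests of the fixed terms.

        Each term is tested after every other term except its higher-order
        relatives (terms whose component set strictly contains it); when
        relatives are present the model is refitted without them and the
        term's coefficients are tested in that submodel.
        """
        rows = []
        comp = {t: set(t.split(":")) for t in self.fixed}
        for term in self.fixed:
            relatives = [u for u in self.fixed if u != term and comp[term] < comp[u]]
            if not relatives:
                stat, df, p = self._marginal_wald(term)
            else:
                sub = MixedModelREML(
                    response=self.response,
                    fixed=tuple(t for t in self.fixed if t not in relatives),
                    random=self.random,
                    tol=self.tol,
                    compute_wald=False,
                ).fit(data)
                stat, df, p = sub._marginal_wald(term)
            rows.append({"term": term, "chisq": stat, "df": df, "p": p})
        return pd.DataFrame(rows)


def fit_reml(spec: ModelSpec, data: pd.DataFrame, tol=1e-10,
             compute_wald=True) -> LmmFit:
    """Fit one model by REML; functional wrapper over :class:`MixedModelREML`."""
    est = MixedModelREML(
        response=spec.response, fixed=spec.fixed, random=spec.random,
        tol=tol, compute_wald=compute_wald,
    ).fit(data)
    return est.result_


def wald_type2(fit: LmmFit) -> pd.DataFrame:
    """Type-II Wald table of an existing fit."""
    return fit.wald
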