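"""Longitudinal statistical designs with a uniform result contract.

The workhorse is a linear mixed model with a by-participant random
intercept, fitted by REML:

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

Estimation profiles the variance ratio theta = tau^2/sigma^2 (the marginal
covariance per subject is sigma^2 (I + theta J), inverted analytically via
Sherman-Morrison), so the REML criterion is a 1-D optimisation.  Fixed
effects get 95% confidence intervals and Type II/III Wald F-tests with
Satterthwaite-approximated denominator degrees of freedom, computed from
the covariance of the REML variance estimates (inverse observed
information) by the delta method.

This module owns design-matrix construction (0/1 sex indicator, treatment
coding for Type II, sum-to-zero contrasts for Type III) and result
extraction.  statsmodels' MixedLM is used as an independent cross-check in
the test suite, never as the implementation, because it does not expose
Satterthwaite F-tests.

Also here: penalized-spline smooths of ranked diagnostic groups (GCV
smoothing selection, mgcv-style effective degrees of freedom, basis
dimension k = 6), baseline ANCOVA with estimated-marginal-mean pairwise
t-tests, the Holm-Bonferroni step-down procedure, and the declarative
analysis suite combining them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "ModelFit", "fit_lmm", "fit_gam_ranked", "rank_groups",
    "ancova_pairwise", "holm", "run_analysis_suite", "SuiteConfig",
    "GROUP_RANKS",
]

GROUP_RANKS = {
    "CU-young": 1, "CU-middle": 2, "CU-oldneg": 3,
    "CU-oldpos": 4, "MCI": 5, "AD": 6,
}


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def expand_terms(terms: Sequence[str]) -> List[str]:
    """Expand 'a*b' into 'a', 'b', 'a:b' preserving order."""
    out: List[str] = []
    for t in terms:
        if "*" in t:
            a, b = [s.strip() for s in t.split("*", 1)]
            for piece in (a, b, f"{a}:{b}"):
                if piece not in out:
                    out.append(piece)
        elif t not in out:
            out.append(t)
    return out


def _is_categorical(table: pd.DataFrame, name: str) -> bool:
    if name.startswith("C(") and name.endswith(")"):
        return True
    col = table[name]
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)


def _base_name(term: str) -> str:
    return term[2:-1] if term.startswith("C(") and term.endswith(")") else term


def _encode_factor(values: pd.Series, coding: str) -> Tuple[np.ndarray, List[str]]:
    levels = sorted(values.dropna().unique().tolist())
    if len(levels) < 2:
        return np.zeros((len(values), 0)), []
    cols = []
    names = []
    if coding == "treatment":
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(float))
            names.append(f"[{lev}]")
    elif coding == "sum":
        last = levels[-1]
        for lev in levels[:-1]:
            c = (values == lev).to_numpy(float) - (values == last).to_numpy(float)
            cols.append(c)
            names.append(f"[S.{lev}]")
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return np.column_stack(cols), names


def build_design(
    table: pd.DataFrame, terms: Sequence[str], coding: str = "treatment"
) -> Tuple[np.ndarray, List[str], Dict[str, List[int]]]:
    """Intercept-first design matrix with per-term column bookkeeping."""
    n = len(table)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    term_cols: Dict[str, List[int]] = {}
    col = 1

    def term_block(t: str) -> Tuple[np.ndarray, List[str]]:
        if ":" in t:
            a, b = [s.strip() for s in t.split(":", 1)]
            Ba, na = term_block(a)
            Bb, nb = term_block(b)
            cols, cnames = [], []
            for i in range(Ba.shape[1]):
                for j in range(Bb.shape[1]):
                    cols.append(Ba[:, i] * Bb[:, j])
                    cnames.append(f"{na[i]}:{nb[j]}")
            return np.column_stack(cols) if cols else np.zeros((n, 0)), cnames
        base = _base_name(t)
        if base not in table.columns:
            raise KeyError(base)
        if _is_categorical(table, t):
            block, suffixes = _encode_factor(table[base], coding)
            return block, [f"{base}{s}" for s in suffixes]
        return table[base].to_numpy(float).reshape(-1, 1), [base]

    for t in terms:
        block, cnames = term_block(t)
        if block.shape[1] == 0:
            term_cols[t] = []
            continue
        blocks.append(block)
        names.extend(cnames)
        term_cols[t] = list(range(col, col + block.shape[1]))
        col += block.shape[1]
    return np.column_stack(blocks), names, term_cols


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model
# ---------------------------------------------------------------------------

class _RandomInterceptREML:
    """Profiled REML for y = X beta + Z b + e with scalar random intercept."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g = groups[order]
        _, starts, counts = np.unique(g, return_index=True, return_counts=True)
        self.starts = starts
        self.counts = counts
        self.n, self.p = X.shape
        self.n_groups = len(counts)
        # per-group sums reused at every theta
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.sx = np.add.reduceat(self.X, starts, axis=0)      # (G, p)
        self.sy = np.add.reduceat(self.y, starts)              # (G,)

    def parts(self, theta: float):
        """X'(I+theta J)^-1 X etc. via Sherman-Morrison per group."""
        c = theta / (1.0 + theta * self.counts)                # (G,)
        XtViX = self.XtX - (self.sx * c[:, None]).T @ self.sx
        XtViy = self.Xty - (self.sx * c[:, None]).T @ self.sy
        ytViy = self.yty - float((c * self.sy) @ self.sy)
        logdet = float(np.log1p(theta * self.counts).sum())
        return XtViX, XtViy, ytViy, logdet

    def profile_criterion(self, theta: float) -> float:
        XtViX, XtViy, ytViy, logdet = self.parts(theta)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        rvr = max(ytViy - float(XtViy @ beta), 1e-300)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return logdet + logdet_xvx + (self.n - self.p) * np.log(rvr)

    def fit(self):
        if self.counts.max() == 1:
            # one observation per subject: only sigma2 (1 + theta) is
            # identified, so resolve the flat ridge to the OLS corner
            theta = 0.0
            XtViX, XtViy, ytViy, _ = self.parts(theta)
            beta = np.linalg.solve(XtViX, XtViy)
            rvr = max(ytViy - float(XtViy @ beta), 0.0)
            sigma2 = rvr / (self.n - self.p)
            return beta, sigma2, 0.0, 0.0
        res = optimize.minimize_scalar(
            lambda lt: self.profile_criterion(np.exp(lt)),
            bounds=(-14.0, 10.0), method="bounded",
            options={"xatol": 1e-8},
        )
        theta = float(np.exp(res.x))
        if self.profile_criterion(0.0) <= res.fun:
            theta = 0.0
        XtViX, XtViy, ytViy, _ = self.parts(theta)
        beta = np.linalg.solve(XtViX, XtViy)
        rvr = max(ytViy - float(XtViy @ beta), 0.0)
        sigma2 = rvr / (self.n - self.p)
        tau2 = theta * sigma2
        return beta, sigma2, tau2, theta

    # --- quantities as functions of gamma = (sigma2, tau2) ---------------

    def neg_reml_loglik(self, sigma2: float, tau2: float) -> float:
        if sigma2 <= 0 or tau2 < 0:
            return np.inf
        theta = tau2 / sigma2
        XtViX, XtViy, ytViy, logdet_theta = self.parts(theta)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        rvr = ytViy - float(XtViy @ beta)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return 0.5 * (
            self.n * np.log(sigma2) + logdet_theta
            + logdet_xvx - self.p * np.log(sigma2)
            + rvr / sigma2
        )

    def beta_cov(self, sigma2: float, tau2: float) -> np.ndarray:
        theta = tau2 / sigma2
        XtViX, *_ = self.parts(theta)
        return sigma2 * np.linalg.inv(XtViX)

    def varpar_cov(self, sigma2: float, tau2: float) -> Optional[np.ndarray]:
        """Covariance of (sigma2, tau2) = inverse observed REML information."""
        h = np.array([max(1e-7, 1e-4 * sigma2), max(1e-7, 1e-4 * max(tau2, sigma2))])
        def f(s, t):
            return self.neg_reml_loglik(s, max(t, 0.0))
        H = np.empty((2, 2))
        g0 = np.array([sigma2, tau2])
        for i in range(2):
            for j in range(2):
                if i == j:
                    fp = f(*(g0 + _e(i, h[i])))
                    fm = f(*(g0 - _e(i, h[i]))) if g0[i] - h[i] > 0 or i == 1 and tau2 - h[1] >= 0 else None
                    if fm is None or not np.isfinite(fm):
                        # one-sided second difference at a boundary
                        f0 = f(*g0)
                        fpp = f(*(g0 + _e(i, 2 * h[i])))
                        H[i, i] = (fpp - 2 * fp + f0) / h[i] ** 2
                    else:
                        H[i, i] = (fp - 2 * f(*g0) + fm) / h[i] ** 2
                elif j > i:
                    shift_i = h[i]
                    shift_j = h[j]
                    lo_ok = (g0[i] - shift_i > 0 if i == 0 else g0[i] - shift_i >= 0) and \
                            (g0[j] - shift_j > 0 if j == 0 else g0[j] - shift_j >= 0)
                    if lo_ok:
                        H[i, j] = (
                            f(*(g0 + _e(i, shift_i) + _e(j, shift_j)))
                            - f(*(g0 + _e(i, shift_i) - _e(j, shift_j)))
                            - f(*(g0 - _e(i, shift_i) + _e(j, shift_j)))
                            + f(*(g0 - _e(i, shift_i) - _e(j, shift_j)))
                        ) / (4 * shift_i * shift_j)
                    else:
                        H[i, j] = (
                            f(*(g0 + _e(i, shift_i) + _e(j, shift_j)))
                            - f(*(g0 + _e(i, shift_i)))
                            - f(*(g0 + _e(j, shift_j)))
                            + f(*g0)
                        ) / (shift_i * shift_j)
                    H[j, i] = H[i, j]
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(A)):
            return None
        return A

    def satterthwaite_df(self, l: np.ndarray, sigma2: float, tau2: float,
                         A: Optional[np.ndarray]) -> float:
        """Satterthwaite df for the scalar contrast l' beta."""
        resid_df = float(self.n - self.p)
        if A is None or tau2 / max(sigma2, 1e-300) < 1e-8:
            return resid_df
        h = np.array([max(1e-7, 1e-4 * sigma2), max(1e-7, 1e-4 * max(tau2, sigma2))])
        def fval(s, t):
            return float(l @ self.beta_cov(s, max(t, 0.0)) @ l)
        g = np.empty(2)
        g[0] = (fval(sigma2 + h[0], tau2) - fval(max(sigma2 - h[0], 1e-12), tau2)) \
            / (sigma2 + h[0] - max(sigma2 - h[0], 1e-12))
        if tau2 - h[1] >= 0:
            g[1] = (fval(sigma2, tau2 + h[1]) - fval(sigma2, tau2 - h[1])) / (2 * h[1])
        else:
            g[1] = (fval(sigma2, tau2 + h[1]) - fval(sigma2, tau2)) / h[1]
        denom = float(g @ A @ g)
        f0 = fval(sigma2, tau2)
        if denom <= 0 or f0 <= 0:
            return resid_df
        df = 2.0 * f0 ** 2 / denom
        return float(np.clip(df, 1.0, 1e7))


def _e(i: int, v: float) -> np.ndarray:
    out = np.zeros(2)
    out[i] = v
    return out


# ---------------------------------------------------------------------------
# Model spec / fit containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed_terms`` is an ordered list of term strings (continuous columns,
    ``C(col)`` factors, ``a:b`` / ``a*b`` interactions).  ``ftest_type``
    defaults to III when any interaction is present and II otherwise
    (Type III uses sum-to-zero contrasts).
    """

    outcome: str
    fixed_terms: List[str]
    random_intercept_by: str = "subject_id"
    estimation: str = "REML"
    ftest_type: Optional[str] = None
    smooth: Optional[Tuple[str, int]] = None

    def resolved_type(self) -> str:
        has_ix = any(":" in t or "*" in t for t in self.fixed_terms)
        if self.ftest_type is None:
            return "III" if has_ix else "II"
        if has_ix and self.ftest_type != "III":
            raise ValueError("Type III F-tests are required when an "
                             "interaction term is present")
        return self.ftest_type


@dataclass
class ModelFit:
    coefficients: pd.DataFrame
    f_tests: pd.DataFrame
    sigma2: float
    tau2: float
    n_subjects: int
    n_observations: int
    converged: bool = True
    degenerate: bool = False
    edf: Optional[float] = None
    extra: Dict = field(default_factory=dict)

    def coef(self, name: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[name]


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML random-intercept LMM with Satterthwaite t/F inference."""
    if spec.estimation != "REML":
        raise ValueError("only REML estimation is supported")
    ftype = spec.resolved_type()
    terms = expand_terms(spec.fixed_terms)
    used_cols = {spec.outcome, spec.random_intercept_by}
    for t in terms:
        for piece in t.split(":"):
            used_cols.add(_base_name(piece.strip()))
    missing = [c for c in used_cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing column(s) {missing} for outcome {spec.outcome!r}")
    data = table.dropna(subset=[c for c in used_cols]).copy()
    subjects = data[spec.random_intercept_by].to_numpy()
    n_subjects = len(pd.unique(subjects))
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    coding = "sum" if ftype == "III" else "treatment"
    X, names, term_cols = build_design(data, terms, coding=coding)
    # drop aliased (exactly collinear) columns, e.g. a factor constant in
    # the analysed subset; the intercept is always kept
    keep: List[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        log.warning("dropping aliased design column(s): %s", dropped)
        remap = {old: new for new, old in enumerate(keep)}
        X = X[:, keep]
        names = [names[j] for j in keep]
        term_cols = {t: [remap[j] for j in idx if j in remap]
                     for t, idx in term_cols.items()}
    y = data[spec.outcome].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few observations ({n}) for {p} fixed effects")

    codes = pd.factorize(subjects)[0]
    engine = _RandomInterceptREML(X, y, codes)

    degenerate = float(np.var(y)) < 1e-28
    if degenerate:
        beta = np.zeros(p)
        sigma2 = tau2 = 0.0
        cov = np.zeros((p, p))
        A = None
    else:
        beta, sigma2, tau2, _theta = engine.fit()
        cov = engine.beta_cov(sigma2, tau2)
        A = engine.varpar_cov(sigma2, tau2) if tau2 > 0 else None

    rows = []
    for j, name in enumerate(names):
        se = float(np.sqrt(max(cov[j, j], 0.0)))
        if degenerate or se == 0:
            rows.append(dict(term=name, beta=float(beta[j]), se=se, df=np.nan,
                             t=np.nan, p=np.nan, ci_lo=float(beta[j]),
                             ci_hi=float(beta[j])))
            continue
        l = np.zeros(p)
        l[j] = 1.0
        df = engine.satterthwaite_df(l, sigma2, tau2, A)
        tval = beta[j] / se
        pval = 2.0 * sps.t.sf(abs(tval), df)
        crit = sps.t.ppf(0.975, df)
        rows.append(dict(term=name, beta=float(beta[j]), se=se, df=df,
                         t=float(tval), p=float(pval),
                         ci_lo=float(beta[j] - crit * se),
                         ci_hi=float(beta[j] + crit * se)))
    coef_df = pd.DataFrame(rows)

    frows = []
    for t in terms:
        idx = term_cols.get(t, [])
        if not idx or degenerate:
            frows.append(dict(term=t, F=np.nan, df_num=len(idx),
                              df_den=np.nan, p=np.nan))
            continue
        L = np.zeros((len(idx), p))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        M = L @ cov @ L.T
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            frows.append(dict(term=t, F=np.nan, df_num=len(idx),
                              df_den=np.nan, p=np.nan))
            continue
        q = len(idx)
        Fval = float((L @ beta) @ Minv @ (L @ beta)) / q
        # Satterthwaite denominator df via per-eigencontrast dfs
        evals, evecs = np.linalg.eigh(M)
        dfs = []
        for k in range(q):
            if evals[k] <= 1e-14 * evals.max():
                continue
            lk = L.T @ evecs[:, k]
            dfs.append(engine.satterthwaite_df(lk, sigma2, tau2, A))
        if not dfs:
            df_den = float(n - p)
        else:
            ecap = [d / (d - 2.0) for d in dfs if d > 2.0]
            E = float(np.sum(ecap)) if ecap else 0.0
            df_den = 2.0 * E / (E - q) if E > q else float(np.mean(dfs))
        pval = float(sps.f.sf(Fval, q, df_den))
        frows.append(dict(term=t, F=Fval, df_num=q, df_den=df_den, p=pval))
    f_df = pd.DataFrame(frows)

    return ModelFit(coefficients=coef_df, f_tests=f_df, sigma2=float(sigma2),
                    tau2=float(tau2), n_subjects=int(n_subjects),
                    n_observations=int(n), converged=True,
                    degenerate=degenerate,
                    extra={"ftest_type": ftype, "names": names})


# ---------------------------------------------------------------------------
# Ranked groups and penalized-spline smooths
# ---------------------------------------------------------------------------

def rank_groups(labels: Sequence[str]) -> pd.Series:
    """Ordinal coding of the six diagnostic groups (1 = youngest controls)."""
    s = pd.Series(labels)
    unknown = sorted(set(s.dropna()) - set(GROUP_RANKS))
    if unknown:
        raise ValueError(f"unknown group label(s): {unknown}")
    out = s.map(GROUP_RANKS)
    if out.nunique() == 1:
        warnings.warn("all group labels identical; rank column is constant")
    return out.astype(float)


def _bspline_knots(x: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("smooth variable is constant")
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis dimension k={k} too small for degree {degree}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _bspline_basis(x: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    knots = _bspline_knots(x, k, degree)
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _curvature_penalty(knots: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """S_ij = int B_i''(x) B_j''(x) dx (null space = linear functions).

    For cubic splines the integrand is piecewise quadratic, so two-point
    Gauss quadrature per knot span is exact.
    """
    spans = np.unique(knots)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    S = np.zeros((k, k))
    eye = np.eye(k)
    d2 = [BSpline(knots, eye[:, j], degree).derivative(2) for j in range(k)]
    for a, b in zip(spans[:-1], spans[1:]):
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gauss
        B2 = np.array([[float(d2[j](p)) for j in range(k)] for p in pts])
        S += half * (B2.T @ B2)
    return S


def fit_gam_ranked(
    table: pd.DataFrame,
    outcome: str,
    rank_column: str = "group_rank",
    k: int = 6,
    covariates: Sequence[str] = (),
) -> ModelFit:
    """Penalized regression spline of ``outcome`` on a group-rank ordinal.

    Cubic B-spline basis of dimension ``k`` with an integrated-squared-
    curvature penalty; the smoothing parameter is selected by REML (the penalized
    block is treated as a random effect — the stable choice when the
    smooth variable has few distinct values, where GCV undersmooths).
    The reported ``edf`` is the effective degrees of freedom of the smooth
    term (1 = linear, as the penalty null space is exactly the linear
    trend).
    """
    data = table.dropna(subset=[outcome, rank_column, *covariates]).copy()
    x = data[rank_column].to_numpy(float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct rank values for a smooth")
    if len(np.unique(x)) < k:
        log.info("smooth of %s: only %d distinct ranks for k=%d basis "
                 "functions (penalty handles the deficiency)",
                 rank_column, len(np.unique(x)), k)
    y = data[outcome].to_numpy(float)
    n = len(y)

    knots = _bspline_knots(x, k)
    B = _bspline_basis(x, k)
    # sum-to-zero constraint: project out the dimension aligned with the
    # column means so the smooth is identifiable next to the intercept
    cmean = B.mean(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(cmean, full_matrices=True)
    Q = Vt[1:].T                                # (k, k-1) null space of cmean
    Bz = B @ Q
    S = _curvature_penalty(knots, k)            # integrated squared curvature
    Pz = Q.T @ S @ Q

    cov_block = np.column_stack(
        [data[c].to_numpy(float) for c in covariates]
    ) if covariates else np.zeros((n, 0))
    M = np.column_stack([np.ones(n), cov_block, Bz])
    n_fixed = 1 + cov_block.shape[1]
    P = np.zeros((M.shape[1], M.shape[1]))
    P[n_fixed:, n_fixed:] = Pz

    # mixed-model form: eigenvectors of the penalty with zero eigenvalue
    # stay fixed effects, the rest become i.i.d. random effects with
    # variance sigma^2 / lambda
    omega, U = np.linalg.eigh(Pz)
    tol = max(float(omega.max()), 1e-30) * 1e-10
    null_cols = omega <= tol
    X_fix = np.column_stack([np.ones(n), cov_block, Bz @ U[:, null_cols]])
    Z = (Bz @ U[:, ~null_cols]) / np.sqrt(omega[~null_cols])
    p_fix = X_fix.shape[1]
    r = Z.shape[1]
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    ZtX = Z.T @ X_fix
    XtX = X_fix.T @ X_fix
    Xty = X_fix.T @ y
    yty = float(y @ y)

    def reml_criterion(lam: float) -> float:
        # V = I + ZZ'/lam inverted by Woodbury
        G = lam * np.eye(r) + ZtZ
        try:
            Ginv_Zty = np.linalg.solve(G, Zty)
            Ginv_ZtX = np.linalg.solve(G, ZtX)
        except np.linalg.LinAlgError:
            return np.inf
        a = XtX - ZtX.T @ Ginv_ZtX
        b = Xty - ZtX.T @ Ginv_Zty
        c = yty - float(Zty @ Ginv_Zty)
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return np.inf
        rvr = max(c - float(b @ beta), 1e-300)
        sign_a, logdet_a = np.linalg.slogdet(a)
        sign_g, logdet_g = np.linalg.slogdet(G)
        if sign_a <= 0 or sign_g <= 0:
            return np.inf
        logdet_v = logdet_g - r * np.log(lam)
        return logdet_v + logdet_a + (n - p_fix) * np.log(rvr)

    lam_grid = np.logspace(-6, 12, 73)
    crits = [reml_criterion(l) for l in lam_grid]
    lam = float(lam_grid[int(np.argmin(crits))])

    MtM = M.T @ M
    Mty = M.T @ y
    coef = np.linalg.solve(MtM + lam * P, Mty)
    Ainv = np.linalg.inv(MtM + lam * P)
    fitted = M @ coef
    rss = float(((y - fitted) ** 2).sum())
    edf_total = float(np.trace(Ainv @ MtM))
    # smooth edf excludes intercept/covariates; the penalty null space
    # inside Bz is the centred linear trend, so a linear truth gives edf 1
    edf_smooth = max(edf_total - n_fixed, 0.0)

    coef_df = pd.DataFrame([
        dict(term="Intercept", beta=float(coef[0]), se=np.nan, df=np.nan,
             t=np.nan, p=np.nan, ci_lo=np.nan, ci_hi=np.nan)
    ])
    f_df = pd.DataFrame([dict(term=f"s({rank_column}, k={k})", F=np.nan,
                              df_num=np.nan, df_den=np.nan, p=np.nan)])
    return ModelFit(coefficients=coef_df, f_tests=f_df,
                    sigma2=rss / max(n - edf_total, 1.0), tau2=0.0,
                    n_subjects=n, n_observations=n, edf=float(edf_smooth),
                    extra={"lambda": float(lam),
                           "reml_criterion": float(min(crits)),
                           "fitted": fitted})


# ---------------------------------------------------------------------------
# ANCOVA with estimated marginal means
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    f_tests: pd.DataFrame
    emmeans: pd.DataFrame
    contrasts: pd.DataFrame
    n_observations: int
    residual_df: float


def ancova_pairwise(
    table: pd.DataFrame,
    outcome: str,
    group: str = "group",
    covariates: Sequence[str] = (),
) -> AncovaResult:
    """Cross-sectional ANCOVA with all pairwise EMM t-contrasts.

    Group means are evaluated at the covariate means; pairwise p-values
    are unadjusted (post hoc convention).
    """
    cols = [outcome, group, *covariates]
    data = table.dropna(subset=cols).copy()
    levels = sorted(data[group].dropna().unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = data[group].value_counts()
    small = [g for g in levels if sizes.get(g, 0) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    terms = [f"C({group})"] + list(covariates)
    X, names, term_cols = build_design(data, terms, coding="treatment")
    y = data[outcome].to_numpy(float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"singular ANCOVA design (rank {rank} < {p}); aliased columns "
            f"among {names}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_res = n - p
    sigma2 = float(resid @ resid) / df_res
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv

    cov_means = {c: float(data[c].mean()) for c in covariates}

    def emm_row(level: str) -> np.ndarray:
        row = np.zeros(p)
        row[0] = 1.0
        for j, nm in zip(term_cols[f"C({group})"],
                         [f"{group}[{lev}]" for lev in levels[1:]]):
            row[j] = 1.0 if nm == f"{group}[{level}]" else 0.0
        for c in covariates:
            row[term_cols[c][0]] = cov_means[c]
        return row

    em_rows = []
    for lev in levels:
        r = emm_row(lev)
        est = float(r @ beta)
        se = float(np.sqrt(r @ cov @ r))
        em_rows.append(dict(group=lev, emmean=est, se=se,
                            ci_lo=est - sps.t.ppf(0.975, df_res) * se,
                            ci_hi=est + sps.t.ppf(0.975, df_res) * se))
    emmeans = pd.DataFrame(em_rows)

    c_rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = emm_row(levels[i]) - emm_row(levels[j])
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            tval = est / se if se > 0 else np.nan
            c_rows.append(dict(contrast=f"{levels[i]} - {levels[j]}",
                               estimate=est, se=se, t=tval,
                               df=df_res,
                               p=2 * sps.t.sf(abs(tval), df_res) if se > 0 else np.nan))
    contrasts = pd.DataFrame(c_rows)

    f_rows = []
    for t in terms:
        idx = term_cols[t]
        L = np.zeros((len(idx), p))
        for r_i, jj in enumerate(idx):
            L[r_i, jj] = 1.0
        M = L @ cov @ L.T
        q = len(idx)
        Fv = float((L @ beta) @ np.linalg.inv(M) @ (L @ beta)) / q
        f_rows.append(dict(term=t, F=Fv, df_num=q, df_den=float(df_res),
                           p=float(sps.f.sf(Fv, q, df_res))))
    return AncovaResult(f_tests=pd.DataFrame(f_rows), emmeans=emmeans,
                        contrasts=contrasts, n_observations=n,
                        residual_df=float(df_res))


# ---------------------------------------------------------------------------
# Holm-Bonferroni
# ---------------------------------------------------------------------------

def holm(pvals: Sequence[float], alpha: float = 0.05):
    """Step-down Holm-Bonferroni adjustment.

    Returns ``(adjusted, reject)`` in the input order, with
    ``adjusted_(i) = max_{j<=i} min(1, (m-j+1) p_(j))`` over the sorted
    p-values and rejection while adjusted < alpha.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


# ---------------------------------------------------------------------------
# The full analysis suite
# ---------------------------------------------------------------------------

@dataclass
class SuiteConfig:
    """Which designs to run and with which replication variants."""

    age_models: bool = True
    stage_models: bool = True
    association_models: bool = True
    converter_models: bool = True
    ranked_models: bool = True
    fd_adjusted: bool = False
    both_networks: bool = False
    alpha: float = 0.05
    older_age_cutoff: float = 60.0


_NETWORK_OUTCOMES = {"AT": "at_index", "PM": "pm_index"}
_ASSOC_FEATURES = ["amyloid_suvr", "fdg_suvr", "hippo_z", "mmse", "mdrs"]
_BASE_COVARIATES = ["age_c", "sex_male", "education_years"]


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    from .synthgen import hippo_standardized

    out = table.copy()
    out["sex_male"] = (out["sex"] == "M").astype(float)
    out["age_c"] = out["age_years"] - out["age_years"].mean()
    out["hippo_z"] = hippo_standardized(out)
    return out


def _require(data: pd.DataFrame, design: str, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"design {design!r} requires missing column(s) {missing}")


def run_analysis_suite(table: pd.DataFrame, config: Optional[SuiteConfig] = None):
    """Run the full set of statistical designs on a cohort table.

    Returns ``(fits, results)``: a dict of fitted models keyed by design
    name and a tidy results DataFrame (design, family, term, beta, CI, F,
    df, p, p_holm).  The association family (2 networks x 5 features = 10
    tests) is Holm-corrected as one family.
    """
    config = config or SuiteConfig()
    base_cols = ["subject_id", "visit_index", "group", "age_years", "sex",
                 "education_years", "months_from_baseline", "at_index",
                 "pm_index"]
    _require(table, "suite", base_cols)
    data = _prepare(table)
    fd_term = ["mean_fd"] if config.fd_adjusted else []
    if config.fd_adjusted:
        _require(data, "fd_adjusted variants", ["mean_fd"])

    fits: Dict[str, object] = {}
    rows: List[dict] = []

    def record(design, family, term, *, beta=np.nan, se=np.nan, ci_lo=np.nan,
               ci_hi=np.nan, F=np.nan, df_num=np.nan, df_den=np.nan, p=np.nan):
        rows.append(dict(design=design, family=family, term=term, beta=beta,
                         se=se, ci_lo=ci_lo, ci_hi=ci_hi, F=F, df_num=df_num,
                         df_den=df_den, p=p, p_holm=np.nan))

    def record_term(design, family, fit: ModelFit, term: str,
                    coef_name: Optional[str] = None):
        frow = fit.f_tests.set_index("term").loc[term]
        beta = se = ci_lo = ci_hi = np.nan
        cname = coef_name or term
        ctab = fit.coefficients.set_index("term")
        if cname in ctab.index:
            c = ctab.loc[cname]
            beta, se, ci_lo, ci_hi = c["beta"], c["se"], c["ci_lo"], c["ci_hi"]
        record(design, family, term, beta=beta, se=se, ci_lo=ci_lo,
               ci_hi=ci_hi, F=frow["F"], df_num=frow["df_num"],
               df_den=frow["df_den"], p=frow["p"])

    # --- age trajectories (unimpaired, excluding amyloid-positive CU) ----
    if config.age_models:
        cu = data[data["group"].isin(["CU-young", "CU-middle", "CU-oldneg"])]
        for net, outcome in _NETWORK_OUTCOMES.items():
            spec = ModelSpec(outcome=outcome, fixed_terms=[
                "age_years", "sex_male", "education_years",
                "C(sequence_variant)", *fd_term,
            ])
            _require(cu, f"age_{net}", ["sequence_variant"])
            fit = fit_lmm(cu, spec)
            fits[f"age_{net}"] = fit
            record_term(f"age_{net}", "age", fit, "age_years")

    older = data[(data["age_years"] >= config.older_age_cutoff)
                 | data["group"].isin(["MCI", "AD"])]

    # --- Alzheimer stage: baseline ANCOVA + longitudinal time x group ----
    if config.stage_models:
        stage = older[older["group"].isin(
            ["CU-oldneg", "CU-oldpos", "MCI", "AD"])]
        base = stage[stage["visit_index"] == 1]
        for net, outcome in _NETWORK_OUTCOMES.items():
            anc = ancova_pairwise(base, outcome, group="group",
                                  covariates=_BASE_COVARIATES + fd_term)
            fits[f"stage_baseline_{net}"] = anc
            frow = anc.f_tests.set_index("term").loc["C(group)"]
            record(f"stage_baseline_{net}", "stage", "C(group)", F=frow["F"],
                   df_num=frow["df_num"], df_den=frow["df_den"], p=frow["p"])
            spec = ModelSpec(outcome=outcome, fixed_terms=[
                "months_from_baseline*C(group)", "age_c", "sex_male",
                "education_years", *fd_term,
            ], ftest_type="III")
            fit = fit_lmm(stage, spec)
            fits[f"stage_long_{net}"] = fit
            record_term(f"stage_long_{net}", "stage", fit,
                        "months_from_baseline:C(group)")

    # --- associations with biomarkers/cognition (10-test Holm family) ----
    assoc_keys = []
    if config.association_models:
        for net, outcome in _NETWORK_OUTCOMES.items():
            for feat in _ASSOC_FEATURES:
                design = f"assoc_{net}_{feat}"
                _require(older, design, [feat])
                spec = ModelSpec(outcome=outcome, fixed_terms=[
                    feat, *_BASE_COVARIATES, "months_from_baseline", *fd_term,
                ])
                fit = fit_lmm(older, spec)
                fits[design] = fit
                record_term(design, "associations", fit, feat)
                assoc_keys.append(design)

    # --- delay to dementia onset in MCI converters ----------------------
    if config.converter_models:
        conv = data[data["months_to_dementia"].notna()]
        if len(conv) >= 8:
            for net, outcome in _NETWORK_OUTCOMES.items():
                spec = ModelSpec(outcome=outcome, fixed_terms=[
                    "months_to_dementia", *_BASE_COVARIATES, *fd_term,
                ])
                fit = fit_lmm(conv, spec)
                fits[f"converter_{net}"] = fit
                record_term(f"converter_{net}", "converter", fit,
                            "months_to_dementia")

    # --- ranked-group smooths and time x rank interactions ---------------
    if config.ranked_models:
        ranked = data.copy()
        ranked["group_rank"] = rank_groups(ranked["group"]).to_numpy()
        base = ranked[ranked["visit_index"] == 1]
        for net, outcome in _NETWORK_OUTCOMES.items():
            gam = fit_gam_ranked(base, outcome, "group_rank", k=6,
                                 covariates=["sex_male", "education_years",
                                             *fd_term])
            fits[f"ranked_gam_{net}"] = gam
            # the edf of the smooth is the quantity of interest here
            record(f"ranked_gam_{net}", "ranked", "s(group_rank)",
                   beta=gam.edf)
            spec = ModelSpec(outcome=outcome, fixed_terms=[
                "months_from_baseline*group_rank", "sex_male",
                "education_years", *fd_term,
            ], ftest_type="III")
            fit = fit_lmm(ranked, spec)
            fits[f"ranked_time_{net}"] = fit
            record_term(f"ranked_time_{net}", "ranked", fit,
                        "months_from_baseline:group_rank")

    # --- both-network replication models ---------------------------------
    if config.both_networks:
        long = pd.concat([
            data.assign(network="AT", index_value=data["at_index"]),
            data.assign(network="PM", index_value=data["pm_index"]),
        ], ignore_index=True)
        cu_long = long[long["group"].isin(["CU-young", "CU-middle", "CU-oldneg"])]
        spec = ModelSpec(outcome="index_value", fixed_terms=[
            "C(network)*age_years", "sex_male", "education_years", *fd_term,
        ], ftest_type="III")
        fit = fit_lmm(cu_long, spec)
        fits["both_networks_age"] = fit
        record_term("both_networks_age", "both_networks", fit,
                    "C(network):age_years")

    results = pd.DataFrame(rows)
    if assoc_keys:
        fam = results["family"] == "associations"
        adj, _rej = holm(results.loc[fam, "p"].to_numpy(), alpha=config.alpha)
        results.loc[fam, "p_holm"] = adj
    return fits, results
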