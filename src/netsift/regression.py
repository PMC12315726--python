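"""Mass-univariate edge-wise regression and the weighted inference matrix.

Every edge value is regressed, with an identity link, on age (optionally
plus a quadratic age term), sex and five imaging confounds:

    E[Y_e] = b0 + b1*age + [b2*age^2] + b3*sex + b4..b8*confounds

All edges share one design matrix, so the whole stack is fit with a single
pseudoinverse (hat-matrix reuse); per-edge coefficients, t and p for the age
term agree with an ordinary per-edge least-squares fit to numerical
precision.  The age t-statistics and two-sided p-values are assembled into a
symmetric inference matrix ``W = {-log10(p_ij)}``, optionally masked to one
effect direction, which is the weighted graph that subnetwork extraction
consumes.

Age is mean-centered before entering the design (and the quadratic term is
the square of centered age); this leaves the age slope, its t and p
unchanged while keeping the design well conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ConnectomeStack, SubjectTable, matrixize_vector

#: residual-variance floor below which an edge is declared degenerate
_RSS_TOL = 1e-12


class DesignError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class EdgeFitTable:
    """Per-edge OLS results for a shared design.

    ``beta`` is ``(n_edges, p)`` in the column order of ``columns``; ``t_age``
    and ``p_age`` refer to the linear age coefficient.  ``rss`` and
    ``df_resid`` support nested-model comparison; ``partial_r2_agesq`` and
    ``p_agesq`` are populated only when the quadratic term was evaluated.
    """

    n_nodes: int
    columns: list
    beta: np.ndarray
    t_age: np.ndarray
    p_age: np.ndarray
    rss: np.ndarray
    df_resid: int
    used_quadratic: bool = False
    partial_r2_agesq: np.ndarray = None
    p_agesq: np.ndarray = None

    @property
    def n_edges(self) -> int:
        return self.beta.shape[0]

    @property
    def sign_age(self) -> np.ndarray:
        return np.sign(self.beta[:, self.columns.index("age_c")]).astype(int)


@dataclass
class InferenceMatrix:
    """Symmetric ``N x N`` edge-weight matrix ``w_ij = -log10(p_ij)``.

    ``sign`` holds the sign of the age coefficient and ``t`` the signed age
    t-statistic; both are retained regardless of the direction mask applied
    to ``w``.  Diagonals are zero.
    """

    w: np.ndarray
    sign: np.ndarray
    t: np.ndarray
    direction: str = "both"

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


def build_design(subjects: SubjectTable, include_quadratic: bool):
    """Design matrix ``[1, age_c, (age_c^2), sex, confounds]`` and column names."""
    age = subjects.age
    age_c = age - age.mean()
    cols = [np.ones(len(subjects)), age_c]
    names = ["const", "age_c"]
    if include_quadratic:
        cols.append(age_c**2)
        names.append("age_c_sq")
    cols.append(subjects.sex)
    names.append("sex")
    conf = subjects.confounds
    for k, cname in enumerate(SubjectTable.CONFOUNDS):
        cols.append(conf[:, k])
        names.append(cname)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the R factor's diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[k] for k in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols_shared_design(X: np.ndarray, Y: np.ndarray, term: int):
    """OLS of every column of ``Y`` on the shared design ``X``.

    Returns ``(beta, t, p, rss, df_resid)`` where ``t`` and ``p`` are for the
    ``term``-th design column.  Degenerate columns (zero residual variance)
    get ``t = 0``, ``p = 1``.
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise DesignError(f"not enough subjects ({n}) for {p} parameters")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    xtx_inv_kk = float((pinv @ pinv.T)[term, term])
    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv_kk)
    degenerate = rss <= _RSS_TOL * max(1.0, float(np.abs(Y).max()) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[term] / np.where(se > 0, se, 1.0), 0.0)
    t = np.where(degenerate, 0.0, t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(degenerate, 1.0, pvals)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) have zero residual variance; "
            "their p is set to 1 and t to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return beta.T, t, pvals, rss, df


def fit_edges(
    stack: ConnectomeStack,
    subjects: SubjectTable,
    include_quadratic: str = "never",
    alpha: float = 0.05,
    r2_min: float = 0.01,
    scope: str = "global",
) -> EdgeFitTable:
    """Fit the edge-wise age model to every edge of an imputed stack.

    ``include_quadratic`` is ``"never"``, ``"always"`` or ``"auto"``; under
    ``"auto"`` both nested models are fit and :func:`quadratic_rule` decides
    (globally by default) whether the quadratic age term is kept.
    """
    subjects.check_aligned(stack)
    if stack.missing.any():
        raise ValueError("stack has missing edges; run impute_missing first")
    if include_quadratic not in ("never", "always", "auto"):
        raise ValueError("include_quadratic must be never, always or auto")

    fit_lin = _fit_with_design(stack, subjects, quadratic=False)
    if include_quadratic == "never":
        return fit_lin
    fit_quad = _fit_with_design(stack, subjects, quadratic=True)
    # nested-model comparison for the quadratic term
    with np.errstate(divide="ignore", invalid="ignore"):
        partial_r2 = np.where(
            fit_lin.rss > 0, (fit_lin.rss - fit_quad.rss) / fit_lin.rss, 0.0
        )
    partial_r2 = np.clip(partial_r2, 0.0, 1.0)
    fit_quad.partial_r2_agesq = partial_r2
    fit_lin.partial_r2_agesq = partial_r2
    fit_lin.p_agesq = fit_quad.p_agesq
    if include_quadratic == "always":
        fit_quad.used_quadratic = True
        return fit_quad
    keep = quadratic_rule(fit_quad, fit_lin, alpha=alpha, r2_min=r2_min, scope=scope)
    if scope == "global":
        chosen = fit_quad if keep else fit_lin
        chosen.used_quadratic = bool(keep)
        return chosen
    # per-edge: splice quadratic results into the linear table where kept
    out = fit_lin
    out.t_age = np.where(keep, fit_quad.t_age, fit_lin.t_age)
    out.p_age = np.where(keep, fit_quad.p_age, fit_lin.p_age)
    out.used_quadratic = keep
    return out


def _fit_with_design(stack, subjects, quadratic: bool) -> EdgeFitTable:
    X, names = build_design(subjects, include_quadratic=quadratic)
    _check_full_rank(X, names)
    term = names.index("age_c")
    beta, t, p, rss, df = ols_shared_design(X, stack.values, term)
    table = EdgeFitTable(
        n_nodes=stack.n_nodes,
        columns=names,
        beta=beta,
        t_age=t,
        p_age=p,
        rss=rss,
        df_resid=df,
        used_quadratic=quadratic,
    )
    if quadratic:
        qterm = names.index("age_c_sq")
        # t/p of the quadratic coefficient from the same shared fit
        pinv = np.linalg.pinv(X)
        xtx_inv_qq = float((pinv @ pinv.T)[qterm, qterm])
        se_q = np.sqrt(np.maximum(rss, 0.0) / df * xtx_inv_qq)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_q = np.where(se_q > 0, beta[:, qterm] / np.where(se_q > 0, se_q, 1.0), 0.0)
        table.p_agesq = 2.0 * stats.t.sf(np.abs(t_q), df)
    return table


def quadratic_rule(
    fit_with: EdgeFitTable,
    fit_without: EdgeFitTable,
    alpha: float = 0.05,
    r2_min: float = 0.01,
    scope: str = "global",
):
    """Decide whether the quadratic age term earns its place.

    The term is retained only when it is statistically significant at
    ``alpha`` *and* its partial r-squared reaches ``r2_min`` (a non-trivial
    effect size; default 1%).  ``scope="global"`` applies one decision to all
    edges, using the median partial r-squared and median quadratic p-value
    across edges; ``scope="per_edge"`` returns a boolean per edge.
    """
    if fit_with.df_resid + 1 != fit_without.df_resid:
        raise ValueError("fits do not look like nested models on the same data")
    with np.errstate(divide="ignore", invalid="ignore"):
        partial_r2 = np.where(
            fit_without.rss > 0,
            (fit_without.rss - fit_with.rss) / fit_without.rss,
            0.0,
        )
    partial_r2 = np.clip(partial_r2, 0.0, 1.0)
    p_q = fit_with.p_agesq
    if p_q is None:
        raise ValueError("fit_with carries no quadratic-term p-values")
    if scope == "global":
        return bool(np.median(p_q) < alpha and np.median(partial_r2) >= r2_min)
    if scope == "per_edge":
        return (p_q < alpha) & (partial_r2 >= r2_min)
    raise ValueError("scope must be 'global' or 'per_edge'")


def build_inference_matrix(
    fits: EdgeFitTable,
    direction: str = "negative",
    w_max: float = 50.0,
) -> InferenceMatrix:
    """Assemble ``W = -log10(p)`` (and sign/t companions) from edge fits.

    ``direction="negative"`` zeroes entries whose age coefficient is >= 0
    (the aging-decline analysis); ``"positive"`` mirrors it; ``"both"``
    keeps all.  Zero p-values (numerical underflow) are capped at ``w_max``.
    """
    if direction not in ("negative", "positive", "both"):
        raise ValueError("direction must be negative, positive or both")
    p = np.asarray(fits.p_age, dtype=float)
    underflow = p <= 10.0 ** (-w_max)
    if underflow.any():
        warnings.warn(
            f"{int(underflow.sum())} p-value(s) underflow; w capped at {w_max}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        w = np.where(underflow, w_max, -np.log10(np.maximum(p, 1e-300)))
    w = np.minimum(w, w_max)
    sign = fits.sign_age
    if direction == "negative":
        w = np.where(sign >= 0, 0.0, w)
    elif direction == "positive":
        w = np.where(sign <= 0, 0.0, w)
    n = fits.n_nodes
    return InferenceMatrix(
        w=matrixize_vector(w, n, diagonal=0.0),
        sign=matrixize_vector(sign, n, diagonal=0.0).astype(int),
        t=matrixize_vector(fits.t_age, n, diagonal=0.0),
        direction=direction,
    )


def fit_single_edge_reference(
    stack: ConnectomeStack,
    subjects: SubjectTable,
    edge: int,
    include_quadratic: bool = False,
):
    """Independent per-edge OLS via statsmodels, for cross-checking.

    Returns ``(params, t_age, p_age)`` for one edge column.  This routine is
    deliberately separate from the vectorized path.
    """
    import statsmodels.api as sm

    X, names = build_design(subjects, include_quadratic=include_quadratic)
    res = sm.OLS(stack.values[:, edge], X).fit()
    k = names.index("age_c")
    return res.params, float(res.tvalues[k]), float(res.pvalues[k])
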