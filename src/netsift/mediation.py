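"""Linear path analysis: age -> white-matter mediator -> subnetwork rsFC.

The mediation model is the classic just-identified linear path system,

    mediator = a * age + (sex) + e1
    outcome  = c' * age + b * mediator + (sex) + e2

fit as two ordinary least-squares regressions, which is exactly equivalent
to the saturated linear structural-equation model.  The indirect effect is
``a*b``, the total effect ``a*b + c'`` (an exact identity for nested linear
fits with shared covariates), and the proportion mediated
``a*b / (a*b + c')``.  Uncertainty comes from a nonparametric
subject-resampling bootstrap (percentile intervals); a delta-method interval
for the indirect effect is reported alongside.

The module also builds the general cognitive score — the first principal
component of a standardized nine-assessment battery, with missing entries
imputed by predictive mean matching — and the age-adjusted association
between subnetwork rsFC and that score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConnectomeStack


class DegenerateInputError(ValueError):
    pass


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    prop_mediated: float
    ci_indirect: tuple
    ci_prop: tuple
    p_indirect: float
    n_boot: int
    seed: int
    unstable: bool = False
    ci_indirect_delta: tuple = None

    @property
    def prop_mediated_pct(self) -> float:
        """Proportion mediated on the percent scale."""
        return 100.0 * self.prop_mediated


def mean_subnetwork_rsfc(stack: ConnectomeStack, S) -> np.ndarray:
    """Per-subject mean of the intra-subnetwork edge values."""
    nodes = sorted(set(int(v) for v in S))
    if len(nodes) < 2:
        raise ValueError("subnetwork needs at least 2 nodes")
    if stack.missing.any():
        raise ValueError("stack has missing edges; run impute_missing first")
    idx = stack.edge_index
    cols = [idx.index_of(i, j) for k, i in enumerate(nodes) for j in nodes[k + 1 :]]
    return stack.values[:, cols].mean(axis=1)


def _ols_beta(X, y):
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _paths(age, mediator, outcome, sex):
    n = len(age)
    if sex is None:
        Xm = np.column_stack([np.ones(n), age])
        Xo = np.column_stack([np.ones(n), age, mediator])
    else:
        Xm = np.column_stack([np.ones(n), age, sex])
        Xo = np.column_stack([np.ones(n), age, mediator, sex])
    bm = _ols_beta(Xm, mediator)
    bo = _ols_beta(Xo, outcome)
    return float(bm[1]), float(bo[2]), float(bo[1])  # a, b, c'


def fit_mediation(
    age,
    mediator,
    outcome,
    sex=None,
    n_boot: int = 1000,
    seed: int = 0,
    total_tol: float = 1e-8,
) -> MediationResult:
    """Two-regression linear mediation with bootstrap intervals.

    ``a`` comes from ``mediator ~ age (+ sex)``; ``b`` and ``c'`` from
    ``outcome ~ age + mediator (+ sex)``.  The bootstrap resamples subjects
    with replacement ``n_boot`` times (deterministic given ``seed``) and
    reports 95% percentile intervals for the indirect effect and the
    proportion mediated, plus a two-sided bootstrap p-value for the indirect
    effect.  When the total effect is near zero the proportion is flagged
    ``unstable`` (its point estimate and CI are still reported).
    """
    age = np.asarray(age, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
    n = len(age)
    if not (len(mediator) == len(outcome) == n) or (sex is not None and len(sex) != n):
        raise ValueError("age, mediator, outcome (and sex) must align")
    if n < 10:
        raise ValueError("mediation needs at least 10 subjects")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    for name, v in (("age", age), ("mediator", mediator), ("outcome", outcome)):
        if np.std(v) == 0:
            raise DegenerateInputError(f"{name} has zero variance")

    a, b, c_prime = _paths(age, mediator, outcome, sex)
    indirect = a * b
    total = indirect + c_prime
    unstable = abs(total) < total_tol * max(1.0, abs(indirect))
    if unstable:
        warnings.warn(
            "total effect is near zero; proportion mediated is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    prop = indirect / total if total != 0 else np.nan

    rng = np.random.default_rng(seed)
    boot_ind = np.empty(n_boot)
    boot_prop = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ab, bb, cb = _paths(
            age[idx], mediator[idx], outcome[idx], None if sex is None else sex[idx]
        )
        boot_ind[k] = ab * bb
        tot = ab * bb + cb
        boot_prop[k] = ab * bb / tot if tot != 0 else np.nan
    ci_ind = tuple(np.percentile(boot_ind, [2.5, 97.5]))
    ci_prop = tuple(np.nanpercentile(boot_prop, [2.5, 97.5]))
    # two-sided bootstrap p for the indirect effect (sign-crossing rate)
    frac_le = (1 + np.sum(boot_ind <= 0)) / (n_boot + 1)
    frac_ge = (1 + np.sum(boot_ind >= 0)) / (n_boot + 1)
    p_ind = min(1.0, 2 * min(frac_le, frac_ge))

    ci_delta = _sobel_ci(age, mediator, outcome, sex, a, b)
    return MediationResult(
        a=a,
        b=b,
        c_prime=c_prime,
        indirect=indirect,
        total=total,
        prop_mediated=prop,
        ci_indirect=ci_ind,
        ci_prop=ci_prop,
        p_indirect=p_ind,
        n_boot=n_boot,
        seed=seed,
        unstable=unstable,
        ci_indirect_delta=ci_delta,
    )


def _sobel_ci(age, mediator, outcome, sex, a, b, level=0.95):
    """First-order delta-method (Sobel) interval for the indirect effect."""
    import statsmodels.api as sm

    n = len(age)
    if sex is None:
        Xm = np.column_stack([np.ones(n), age])
        Xo = np.column_stack([np.ones(n), age, mediator])
    else:
        Xm = np.column_stack([np.ones(n), age, sex])
        Xo = np.column_stack([np.ones(n), age, mediator, sex])
    se_a = sm.OLS(mediator, Xm).fit().bse[1]
    se_b = sm.OLS(outcome, Xo).fit().bse[2]
    se = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    zq = stats.norm.ppf(0.5 + level / 2)
    return (a * b - zq * se, a * b + zq * se)


# ---------------------------------------------------------------------------
# general cognitive score


def _pmm_impute(battery: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Predictive-mean-matching imputation, single draw, deterministic.

    For each column with missing entries, a linear predictor on the other
    (mean-filled) columns is fit on that column's observed rows; each missing
    row borrows the observed value of one of its ``k`` nearest donors in
    predicted-value space.
    """
    rng = np.random.default_rng(seed)
    X = battery.copy()
    col_means = np.nanmean(X, axis=0)
    filled = np.where(np.isnan(X), col_means[None, :], X)
    out = X.copy()
    for c in range(X.shape[1]):
        miss = np.isnan(X[:, c])
        if not miss.any():
            continue
        obs = ~miss
        others = [j for j in range(X.shape[1]) if j != c]
        D = np.column_stack([np.ones(X.shape[0]), filled[:, others]])
        coef = np.linalg.lstsq(D[obs], X[obs, c], rcond=None)[0]
        pred = D @ coef
        pred_obs = pred[obs]
        vals_obs = X[obs, c]
        for r in np.flatnonzero(miss):
            d = np.abs(pred_obs - pred[r])
            donors = np.argsort(d, kind="stable")[: min(k, len(d))]
            out[r, c] = vals_obs[rng.choice(donors)]
    return out


def cognitive_score(battery, k_donors: int = 5, seed: int = 0):
    """General cognitive score: PC1 of the standardized assessment battery.

    Missing entries are imputed by predictive mean matching (``k_donors``
    nearest donors, deterministic given ``seed``).  Columns that are entirely
    missing are dropped with a warning; subjects missing every assessment get
    a NaN score.  The score is oriented so that higher is better (positive
    mean loading) and standardized to unit variance.

    Returns ``(scores, explained_variance_fraction)``.
    """
    df = pd.DataFrame(battery)
    arr = df.to_numpy(dtype=float)
    all_missing_cols = np.isnan(arr).all(axis=0)
    if all_missing_cols.any():
        warnings.warn(
            f"dropping {int(all_missing_cols.sum())} entirely missing column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
        arr = arr[:, ~all_missing_cols]
    if arr.shape[1] < 2:
        raise ValueError("cognitive score needs at least 2 assessment columns")
    row_all_missing = np.isnan(arr).all(axis=1)
    work = arr[~row_all_missing]
    if np.isnan(work).any():
        work = _pmm_impute(work, k=k_donors, seed=seed)
    sd = work.std(axis=0, ddof=1)
    if (sd == 0).any():
        sd = np.where(sd == 0, 1.0, sd)
    zs = (work - work.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    loadings = vt[0]
    if loadings.mean() < 0:
        loadings = -loadings
        u = u.copy()
        u[:, 0] = -u[:, 0]
    explained = float(s[0] ** 2 / np.sum(s**2))
    raw = zs @ loadings
    score_vals = (raw - raw.mean()) / raw.std(ddof=1)
    scores = np.full(arr.shape[0], np.nan)
    scores[~row_all_missing] = score_vals
    return scores, explained


def cognitive_association(score, mean_rsfc, age):
    """OLS of cognition on subnetwork rsFC controlling for age.

    Returns a dict with the rsFC coefficient, its standard error and 95% CI,
    and the fitted-model p-value for the coefficient.
    """
    import statsmodels.api as sm

    score = np.asarray(score, dtype=float)
    mean_rsfc = np.asarray(mean_rsfc, dtype=float)
    age = np.asarray(age, dtype=float)
    ok = np.isfinite(score) & np.isfinite(mean_rsfc) & np.isfinite(age)
    X = np.column_stack([np.ones(ok.sum()), mean_rsfc[ok], age[ok]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design is collinear: rsFC cannot be separated from age/intercept"
        )
    res = sm.OLS(score[ok], X).fit()
    lo, hi = res.conf_int()[1]
    return {
        "coef": float(res.params[1]),
        "se": float(res.bse[1]),
        "ci": (float(lo), float(hi)),
        "p": float(res.pvalues[1]),
        "n": int(ok.sum()),
    }
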