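"""Max-statistic permutation inference for extracted subnetworks.

The observed pipeline (edge regression -> inference matrix -> extraction) is
re-run on data in which the subjects' ages have been shuffled while every
other covariate and the connectomes stay attached to their subjects.  For
permutation ``k`` the test statistic ``T_k`` is the maximum score over all
subnetworks extracted from the permuted inference matrix (0 when none is
found).  Comparing every observed subnetwork's score against this single
max-null controls the family-wise error rate.

p-values use the add-one estimator ``(1 + #{T_k >= T_obs}) / (M + 1)``, so
the smallest attainable p with ``M`` permutations is ``1/(M+1)``.

Two shuffling schemes are available: permuting the age column directly
(Draper-Stoneman style, the default, matching an age-randomization design)
and Freedman-Lane residual permutation, in which reduced-model residuals are
shuffled and re-added to the reduced-model fit before the full model is
refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConnectomeStack, SubjectTable
from .extract import DEFAULT_LAMBDA, extract_subnetworks
from .regression import (
    build_design,
    build_inference_matrix,
    fit_edges,
    ols_shared_design,
    _check_full_rank,
)
from .core import matrixize_vector
from .regression import InferenceMatrix


@dataclass
class PermutationNull:
    """Null distribution of per-permutation maximum subnetwork scores."""

    T_values: np.ndarray
    M: int
    seed: int
    scheme: str = "draper-stoneman"

    def __post_init__(self):
        self.T_values = np.asarray(self.T_values, dtype=float)
        if len(self.T_values) != self.M:
            raise ValueError("T_values length must equal M")


def _matrix_from_tp(t, p, n_nodes, direction, w_max=50.0):
    with np.errstate(divide="ignore"):
        w = np.minimum(-np.log10(np.maximum(p, 1e-300)), w_max)
    sign = np.sign(t).astype(int)
    if direction == "negative":
        w = np.where(sign >= 0, 0.0, w)
    elif direction == "positive":
        w = np.where(sign <= 0, 0.0, w)
    return InferenceMatrix(
        w=matrixize_vector(w, n_nodes, diagonal=0.0),
        sign=matrixize_vector(sign, n_nodes, diagonal=0.0).astype(int),
        t=matrixize_vector(t, n_nodes, diagonal=0.0),
        direction=direction,
    )


def build_null(
    stack: ConnectomeStack,
    subjects: SubjectTable,
    M: int = 1000,
    seed: int = 0,
    direction: str = "negative",
    lam: float = DEFAULT_LAMBDA,
    min_size: int = 5,
    max_subnetworks: int = 10,
    include_quadratic: bool = False,
    scheme: str = "draper-stoneman",
    extraction_kwargs: dict | None = None,
) -> PermutationNull:
    """Build the max-statistic null by re-running the pipeline on shuffled age.

    The regression/extraction configuration must match the observed-data run;
    pass the same ``lam``, ``min_size``, ``direction`` (and any extra
    extraction options) used there.  Deterministic for a fixed ``seed``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if scheme not in ("draper-stoneman", "freedman-lane"):
        raise ValueError("scheme must be draper-stoneman or freedman-lane")
    subjects.check_aligned(stack)
    if stack.missing.any():
        raise ValueError("stack has missing edges; run impute_missing first")
    rng = np.random.default_rng(seed)
    X, names = build_design(subjects, include_quadratic=include_quadratic)
    _check_full_rank(X, names)
    term = names.index("age_c")
    age_cols = [names.index(c) for c in ("age_c", "age_c_sq") if c in names]
    Y = stack.values
    n = X.shape[0]
    kwargs = dict(extraction_kwargs or {})
    kwargs.setdefault("min_size", min_size)
    kwargs.setdefault("max_subnetworks", max_subnetworks)

    if scheme == "freedman-lane":
        # reduced model: everything but the age terms
        keep = [k for k in range(X.shape[1]) if k not in age_cols]
        Xr = X[:, keep]
        beta_r = np.linalg.pinv(Xr) @ Y
        fitted_r = Xr @ beta_r
        resid_r = Y - fitted_r

    T = np.empty(M)
    for k in range(M):
        perm = rng.permutation(n)
        if scheme == "draper-stoneman":
            Xp = X.copy()
            # shuffle age (and its square, consistently) across subjects
            Xp[:, age_cols] = X[perm][:, age_cols]
            Yp = Y
        else:
            Xp = X
            Yp = fitted_r + resid_r[perm]
        _, t, p, _, _ = ols_shared_design(Xp, Yp, term)
        Wp = _matrix_from_tp(t, p, stack.n_nodes, direction)
        res = extract_subnetworks(Wp, lam=lam, **kwargs)
        T[k] = max((s.score for s in res.subnetworks), default=0.0)
    return PermutationNull(T_values=T, M=M, seed=seed, scheme=scheme)


def subnetwork_pvalue(T_obs: float, null: PermutationNull) -> float:
    """Add-one percentile p-value of an observed score against the max-null."""
    if not np.isfinite(T_obs):
        raise ValueError("observed score must be finite")
    if null.M < 1 or len(null.T_values) == 0:
        raise ValueError("permutation null is empty")
    count = int((null.T_values >= T_obs).sum())
    return (1 + count) / (null.M + 1)


def attach_pvalues(result, null: PermutationNull):
    """Set ``p_value`` on every subnetwork of an ExtractionResult (in place)."""
    for s in result.subnetworks:
        s.p_value = subnetwork_pvalue(s.score, null)
    return result
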