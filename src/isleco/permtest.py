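"""Permutation inference for the compositional-similarity models.

The pairwise comparisons entering the similarity models are heavily
pseudo-replicated (every site appears in many pairs), so chi-square
reference distributions are invalid.  Significance is instead assessed
by permutation: the response column is shuffled among rows within each
study — explanatory variables, weights and the grouping structure stay
fixed — and the observed likelihood ratio (or coefficient) is compared
against the statistics recomputed on permuted data.

The Monte-Carlo p-value includes the observed statistic in the
reference set, ``p = (1 + #{null as or more extreme}) / (1 + n_perm)``,
so with 199 permutations the smallest attainable p is 1/200 = 0.005.

Randomness flows through a seed tree (one spawned stream per
permutation index, and one branch per test during stepwise
simplification), so results are bit-reproducible and independent of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modelfit import (FitResult, ModelSpec, backward_simplify, fit_mixed,
                       loglik_nested_pair)

__all__ = [
    "PermutationResult",
    "permute_within_study",
    "permutation_lr_test",
    "permutation_coef_test",
    "stepwise_with_permutation",
]


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and Monte-Carlo p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    tails: str  # "upper" or "two"
    n_perm: int
    seed: int

    def __post_init__(self):
        assert 0.0 < self.p_value <= 1.0


def _mc_p(observed: float, null_values: np.ndarray, tails: str) -> float:
    null_values = np.asarray(null_values, dtype=float)
    if tails == "upper":
        extreme = int(np.sum(null_values >= observed))
    elif tails == "two":
        extreme = int(np.sum(np.abs(null_values) >= abs(observed)))
    else:
        raise ValueError("tails must be 'upper' or 'two'")
    return (1 + extreme) / (1 + null_values.size)


def permute_within_study(
    data: pd.DataFrame,
    response: str,
    seed: int,
    study_col: str = "study_id",
) -> pd.DataFrame:
    """Shuffle one response column among rows within each study.

    All other columns are untouched; a single-row study is returned
    unchanged; the same seed always produces the same permutation.
    """
    rng = np.random.default_rng(seed)
    out = data.copy()
    values = out[response].to_numpy().copy()
    for _, idx in out.groupby(study_col, sort=True).indices.items():
        values[idx] = values[rng.permutation(idx)]
    out[response] = values
    return out


# --------------------------------------------------------------------------
# Internal machinery working directly on fitted designs
# --------------------------------------------------------------------------


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    order = pd.Series(range(len(groups))).groupby(pd.Series(groups), sort=True).indices
    return [np.asarray(v) for _, v in sorted(order.items(), key=lambda kv: str(kv[0]))]


def _permuted_response(y: np.ndarray, idx_groups, rng) -> np.ndarray:
    yp = y.copy()
    for idx in idx_groups:
        yp[idx] = y[rng.permutation(idx)]
    return yp


def _null_lrs(full_fit: FitResult, reduced_fit: FitResult,
              n_perm: int, seed) -> np.ndarray:
    """Null LR statistics from within-study permutations of the shared
    response.  Raises when >= 5% of permutation fits fail."""
    ef, er = full_fit._engine, reduced_fit._engine
    if ef.d.n != er.d.n or not np.allclose(ef.d.y, er.d.y):
        raise ValueError("full and reduced models must share response rows")
    y = ef.d.y
    idx_groups = _group_indices(ef.d.groups)
    seeds = (seed.spawn(n_perm) if isinstance(seed, np.random.SeedSequence)
             else np.random.SeedSequence(seed).spawn(n_perm))
    nulls, failures = [], 0
    for child in seeds:
        rng = np.random.default_rng(child)
        yp = _permuted_response(y, idx_groups, rng)
        rf = ef.fit(yp, theta0=full_fit._theta)
        rr = er.fit(yp, theta0=reduced_fit._theta)
        if not (rf.converged and rr.converged):
            failures += 1
            continue
        nulls.append(max(2.0 * (rf.loglik - rr.loglik), 0.0))
    if failures > 0.05 * n_perm:
        raise RuntimeError(
            f"{failures} of {n_perm} permutation fits failed to converge")
    return np.asarray(nulls)


def permutation_lr_test(
    full: ModelSpec | FitResult,
    reduced: ModelSpec | FitResult,
    data: pd.DataFrame | None = None,
    n_perm: int = 199,
    seed: int = 0,
) -> PermutationResult:
    """Upper-tailed permutation test of a nested model comparison.

    The observed likelihood ratio ``2 (l_full - l_reduced)`` is
    compared against ratios from ``n_perm`` within-study permutations
    of the response.  Accepts either model specs (fitted here by ML on
    ``data``) or already-fitted results.
    """
    full_fit = full if isinstance(full, FitResult) else fit_mixed(full, data, reml=False)
    reduced_fit = (reduced if isinstance(reduced, FitResult)
                   else fit_mixed(reduced, data, reml=False))
    if not (full_fit.converged and reduced_fit.converged):
        raise RuntimeError("observed-data fits did not converge")
    lf, lr_ = loglik_nested_pair(full_fit, reduced_fit)
    observed = max(2.0 * (lf - lr_), 0.0)
    nulls = _null_lrs(full_fit, reduced_fit, n_perm, seed)
    seed_val = seed if isinstance(seed, int) else -1
    return PermutationResult(
        observed=observed,
        null_values=nulls,
        p_value=_mc_p(observed, nulls, "upper"),
        tails="upper",
        n_perm=n_perm,
        seed=seed_val,
    )


def permutation_coef_test(
    fit: FitResult,
    term: str,
    data: pd.DataFrame | None = None,
    n_perm: int = 199,
    seed: int = 0,
) -> PermutationResult:
    """Two-tailed permutation test of one model coefficient.

    The observed coefficient is compared in absolute value against the
    coefficients refitted on within-study permutations of the response.
    """
    if term not in fit.coefficients.index:
        raise KeyError(f"coefficient {term!r} not in model")
    j = list(fit.coefficients.index).index(term)
    engine = fit._engine
    y = engine.d.y
    idx_groups = _group_indices(engine.d.groups)
    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    nulls, failures = [], 0
    for child in seeds:
        rng = np.random.default_rng(child)
        yp = _permuted_response(y, idx_groups, rng)
        r = engine.fit(yp, theta0=fit._theta)
        if not r.converged:
            failures += 1
            continue
        nulls.append(float(r.beta[j]))
    if failures > 0.05 * n_perm:
        raise RuntimeError(
            f"{failures} of {n_perm} permutation fits failed to converge")
    nulls = np.asarray(nulls)
    observed = float(fit.coefficients.iloc[j])
    return PermutationResult(
        observed=observed,
        null_values=nulls,
        p_value=_mc_p(observed, nulls, "two"),
        tails="two",
        n_perm=n_perm,
        seed=seed,
    )


def stepwise_with_permutation(
    full: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[FitResult, pd.DataFrame]:
    """Backwards stepwise simplification with permutation LR p-values.

    Identical control flow to :func:`isleco.modelfit.backward_simplify`
    but every likelihood-ratio p-value comes from a within-study
    permutation null.  Each term test draws a fresh branch of the seed
    tree, so the procedure is reproducible end to end.
    """
    root = np.random.SeedSequence(seed)

    def perm_lrt(full_fit: FitResult, reduced_fit: FitResult, term: str):
        # each test takes the next branch of the seed tree
        branch = root.spawn(1)[0]
        lf, lr_ = loglik_nested_pair(full_fit, reduced_fit)
        observed = max(2.0 * (lf - lr_), 0.0)
        nulls = _null_lrs(full_fit, reduced_fit, n_perm, branch)
        df = len(full_fit.coefficients) - len(reduced_fit.coefficients)
        return observed, df, _mc_p(observed, nulls, "upper")

    return backward_simplify(full, data, alpha=alpha, lrt=perm_lrt)
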