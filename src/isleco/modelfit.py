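"""Mixed-effects model engine for the diversity and similarity analyses.

Three model families share one engine:

* gaussian linear mixed models of square-root rescaled abundance and of
  logit compositional similarity, with per-observation precision
  weights (the proportion of classified species);
* Poisson log-link mixed models of species richness, with an optional
  observation-level random effect (OLRE) absorbing overdispersion,
  fitted by penalised IRLS with a Laplace approximation to the
  marginal likelihood;
* the island-trait models (land use x island characteristic
  interactions) which are the same two families with different fixed
  effects.

Random-effect structures are variance components: every term is a
grouping factor (study, block nested in study, island, or land use
within study for random slopes) with one variance.  Random slopes are
therefore independent per-(study, land-use) deviations sharing a
single variance — the diagonal analogue of a full slope covariance,
which is rarely identifiable at these sample sizes.

For the gaussian family the fixed effects and the residual variance
are profiled out analytically, leaving a low-dimensional optimisation
over log variance ratios; all matrix work runs through the Woodbury
identity on the (small) random-effect scale, and the sufficient
statistics that involve the response are isolated so that refitting
the same design to a permuted response (the permutation tests' inner
loop) costs almost nothing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelSpec",
    "FitResult",
    "RANDOM_STRUCTURES",
    "fit_mixed",
    "select_random_structure",
    "backward_simplify",
    "gvif",
    "posthoc_slopes",
]

# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

#: Candidate random-effect structures.  ``slopes`` means land-use
#: deviations within study; ``block`` is nested within study by keying
#: on the (study, block) combination.
RANDOM_STRUCTURES: dict[str, tuple[tuple[str, ...], ...]] = {
    "slopes+study+block+island": (
        ("study_id", "land_use"), ("study_id",), ("study_id", "block_id"), ("island_id",)),
    "slopes+study+block": (
        ("study_id", "land_use"), ("study_id",), ("study_id", "block_id")),
    "study+block+island": (("study_id",), ("study_id", "block_id"), ("island_id",)),
    "study+block": (("study_id",), ("study_id", "block_id")),
    "study+island": (("study_id",), ("island_id",)),
    "study": (("study_id",),),
    "none": (),
}

_SLOPE_TERM = ("study_id", "land_use")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed_terms`` lists individual model terms (main effects and
    explicit interactions written with ``:``); an intercept is always
    included.  ``random_structure`` is either a key of
    :data:`RANDOM_STRUCTURES` or an explicit tuple of grouping-column
    tuples.  ``weights`` names a column of per-observation weights in
    [0, 1] (precision multipliers for the gaussian family,
    log-likelihood multipliers for the Poisson family).
    """

    response: str
    fixed_terms: tuple = ()
    random_structure: str | tuple = "study"
    family: str = "gaussian"
    olre: bool = False
    weights: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        if self.family not in ("gaussian", "poisson_log"):
            raise ValueError("family must be 'gaussian' or 'poisson_log'")
        if self.olre and self.family != "poisson_log":
            raise ValueError("an observation-level random effect requires the "
                             "poisson_log family")
        for term in self.resolve_random():
            if len(term) > 1 and "block_id" not in term and term != _SLOPE_TERM:
                raise ValueError("random slopes are only supported for land use "
                                 f"within study, got {term}")

    def resolve_random(self) -> tuple:
        if isinstance(self.random_structure, str):
            try:
                return RANDOM_STRUCTURES[self.random_structure]
            except KeyError:
                raise KeyError(
                    f"unknown random structure {self.random_structure!r}; "
                    f"known: {sorted(RANDOM_STRUCTURES)}") from None
        return tuple(tuple(t) for t in self.random_structure)

    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        return f"{self.response} ~ {rhs}"

    def drop_term(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise KeyError(f"term {term!r} not in model")
        return dataclasses.replace(
            self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))


@dataclass
class FitResult:
    """A fitted mixed model.

    ``coefficients`` and ``vcov`` are indexed by design-column name;
    ``varcomps`` maps random-term labels to variances (on the response
    scale for gaussian fits, on the linear-predictor scale for Poisson
    fits).  ``loglik`` is the maximised (restricted) log-likelihood of
    the chosen estimation method.
    """

    spec: ModelSpec
    coefficients: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    estimation: str
    varcomps: dict
    sigma2: float | None
    aic: float
    # implementation handles (design + response) used by refits,
    # post-hoc contrasts and diagnostics
    design_info: object = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)
    _engine: object = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)

    @property
    def term_slices(self) -> dict:
        return {name: self.design_info.term_name_slices[name]
                for name in self.design_info.term_names}

    def predict_row(self, values: Mapping) -> np.ndarray:
        """Design row for one combination of predictor values.

        Numeric variables missing from ``values`` default to 0,
        categorical ones to their first (baseline) level.
        """
        row = {}
        for name, fi in self.design_info.factor_infos.items():
            var = name.name()
            if var in values:
                row[var] = [values[var]]
            elif fi.type == "categorical":
                row[var] = [list(fi.categories)[0]]
            else:
                row[var] = [0.0]
        frame = pd.DataFrame(row) if row else pd.DataFrame(index=[0])
        (m,) = patsy.build_design_matrices([self.design_info], frame)
        return np.asarray(m)[0]


# --------------------------------------------------------------------------
# Design assembly
# --------------------------------------------------------------------------


def _random_codes(data: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray | None:
    """Integer group codes for one variance-component term; None when
    the term is vacuous for these data (e.g. no blocks recorded)."""
    cols = []
    for c in term:
        if c not in data.columns:
            return None
        col = data[c]
        if c == "block_id" and col.isna().all():
            return None
        cols.append(col.astype(object).where(col.notna(), "_none").astype(str))
    key = cols[0] if len(cols) == 1 else cols[0].str.cat(cols[1:], sep="\x1f")
    return pd.factorize(key)[0]


class _Design:
    """Aligned response, fixed-effect matrix, RE indicator blocks and
    weights for one model on one dataset."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        cols = {spec.response} | ({spec.weights} if spec.weights else set())
        usable = data.dropna(subset=[c for c in cols if c in data.columns])
        if spec.weights:
            usable = usable[usable[spec.weights] > 0]
        y_df, x_df = patsy.dmatrices(spec.formula(), usable, return_type="dataframe")
        usable = usable.loc[x_df.index]
        self.design_info = x_df.design_info
        self.colnames = list(x_df.columns)
        self.X = np.asarray(x_df, dtype=float)
        self.y = np.asarray(y_df, dtype=float).ravel()
        self.w = (np.asarray(usable[spec.weights], dtype=float)
                  if spec.weights else np.ones(len(usable)))
        self.n = len(self.y)
        self.groups = (usable["study_id"].astype(str).to_numpy()
                       if "study_id" in usable.columns else np.zeros(self.n))
        self.n_groups = len(pd.unique(self.groups))

        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            _, r = np.linalg.qr(self.X)
            diag = np.abs(np.diag(r))
            aliased = [self.colnames[j] for j in range(len(diag))
                       if diag[j] < 1e-8 * diag.max()]
            raise np.linalg.LinAlgError(
                f"rank-deficient fixed effects; aliased columns: {aliased}")

        self.re_names: list[str] = []
        blocks = []
        for term in spec.resolve_random():
            codes = _random_codes(usable, term)
            if codes is None:
                continue
            blocks.append(codes)
            self.re_names.append(":".join(term))
        if spec.olre:
            blocks.append(np.arange(self.n))
            self.re_names.append("olre")
        self.Z = None
        self.block_sizes = []
        if blocks:
            zs = []
            for codes in blocks:
                q_k = int(codes.max()) + 1
                z = np.zeros((self.n, q_k))
                z[np.arange(self.n), codes] = 1.0
                zs.append(z)
                self.block_sizes.append(q_k)
            self.Z = np.hstack(zs)
        self.k = len(self.block_sizes)
        self._ginv_index = np.repeat(np.arange(self.k), self.block_sizes) if self.k else None


# --------------------------------------------------------------------------
# Gaussian family: profiled ML/REML
# --------------------------------------------------------------------------


class GaussianLMM:
    """Weighted gaussian LMM with variance components.

    Fixed effects and the residual variance are profiled out; the
    remaining objective over log variance ratios is minimised
    numerically.  Cross-products not involving the response are
    precomputed once, so :meth:`fit` is cheap to call repeatedly with
    new responses on the same design.
    """

    _BOUND = (-20.0, 12.0)

    def __init__(self, design: _Design, reml: bool = False):
        self.d = design
        self.reml = reml
        w = design.w
        self.Xw = design.X * w[:, None]
        self.XtWX = design.X.T @ self.Xw
        self.logdetW = float(np.sum(np.log(w)))
        self.p = design.X.shape[1]
        if design.Z is not None:
            self.Zw = design.Z * w[:, None]
            self.ZtWZ = design.Z.T @ self.Zw
            self.ZtWX = design.Z.T @ self.Xw
        else:
            self.Zw = None

    # -- response-dependent statistics ----------------------------------
    def _stats(self, y):
        XtWy = self.Xw.T @ y
        ytWy = float(y @ (self.d.w * y))
        ZtWy = self.Zw.T @ y if self.Zw is not None else None
        return XtWy, ytWy, ZtWy

    def _profile(self, theta, XtWy, ytWy, ZtWy):
        d = self.d
        n, p = d.n, self.p
        if d.k == 0:
            XtVX, XtVy, ytVy = self.XtWX, XtWy, ytWy
            logdetV = -self.logdetW
        else:
            gamma = np.exp(theta)
            ginv = 1.0 / gamma[d._ginv_index]
            A = self.ZtWZ + np.diag(ginv)
            cf = cho_factor(A, lower=True)
            AiZtWX = cho_solve(cf, self.ZtWX)
            AiZtWy = cho_solve(cf, ZtWy)
            XtVX = self.XtWX - self.ZtWX.T @ AiZtWX
            XtVy = XtWy - self.ZtWX.T @ AiZtWy
            ytVy = ytWy - float(ZtWy @ AiZtWy)
            logdetV = (2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                       + float(np.sum(np.log(gamma[d._ginv_index])))
                       - self.logdetW)
        cfx = cho_factor(XtVX)
        beta = cho_solve(cfx, XtVy)
        rss = max(ytVy - float(beta @ XtVy), 1e-12)
        if self.reml:
            dof = n - p
            sigma2 = rss / dof
            logdetXVX = 2.0 * float(np.sum(np.log(np.abs(np.diag(cfx[0])))))
            m2ll = dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV + logdetXVX
        else:
            sigma2 = rss / n
            m2ll = n * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV
        return m2ll, beta, sigma2, XtVX

    def fit(self, y, theta0=None):
        XtWy, ytWy, ZtWy = self._stats(y)
        d = self.d
        if d.k == 0:
            m2ll, beta, sigma2, XtVX = self._profile(None, XtWy, ytWy, ZtWy)
            return _GaussFit(beta, np.array([]), sigma2, -0.5 * m2ll, True, False, XtVX)
        lo, hi = self._BOUND

        def objective(theta):
            theta = np.clip(theta, lo, hi)
            return self._profile(theta, XtWy, ytWy, ZtWy)[0]

        if d.k == 1:
            res = optimize.minimize_scalar(
                lambda t: objective(np.array([t])),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-7})
            theta = np.clip(np.atleast_1d(res.x), lo, hi)
            ok = bool(res.success)
        else:
            starts = ([np.zeros(d.k), np.full(d.k, -4.0)]
                      if theta0 is None else [np.asarray(theta0, float)])
            best = None
            ok = False
            for s in starts:
                res = optimize.minimize(objective, s, method="Nelder-Mead",
                                        options={"xatol": 1e-8, "fatol": 1e-10,
                                                 "maxiter": 2000})
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
                ok = ok or bool(res.success)
            theta = np.clip(best.x, lo, hi)
        m2ll, beta, sigma2, XtVX = self._profile(theta, XtWy, ytWy, ZtWy)
        singular = bool((np.exp(theta) < 1e-6).any())
        return _GaussFit(beta, theta, sigma2, -0.5 * m2ll, ok, singular, XtVX)


@dataclass
class _GaussFit:
    beta: np.ndarray
    theta: np.ndarray
    sigma2: float
    loglik: float
    converged: bool
    singular: bool
    XtVX: np.ndarray


# --------------------------------------------------------------------------
# Poisson family: PIRLS + Laplace
# --------------------------------------------------------------------------


class PoissonGLMM:
    """Poisson log-link mixed model via penalised IRLS and a Laplace
    approximation, with observation weights multiplying the
    log-likelihood contributions."""

    def __init__(self, design: _Design):
        self.d = design
        self._warm = None

    def _pirls(self, lnsig2, start=None):
        d = self.d
        X, Z, y, w = d.X, d.Z, d.y, d.w
        n, p = d.n, X.shape[1]
        q = Z.shape[1] if Z is not None else 0
        ginv = (1.0 / np.exp(lnsig2)[d._ginv_index]) if q else np.array([])
        if start is None:
            beta = np.zeros(p)
            beta[0] = np.log(max(np.average(y, weights=w), 0.1))
            u = np.zeros(q)
        else:
            beta, u = start[0].copy(), start[1].copy()

        def penalised(beta, u):
            eta = X @ beta + (Z @ u if q else 0.0)
            eta = np.clip(eta, -30.0, 30.0)
            mu = np.exp(eta)
            ll = float(np.sum(w * (y * eta - mu - special.gammaln(y + 1.0))))
            return ll - 0.5 * float(u @ (ginv * u)) if q else ll, eta, mu

        f, eta, mu = penalised(beta, u)
        H_uu = None
        for _ in range(80):
            m = w * mu
            grad_b = X.T @ (w * (y - mu))
            if q:
                grad_u = Z.T @ (w * (y - mu)) - ginv * u
                XtMX = X.T @ (X * m[:, None])
                XtMZ = X.T @ (Z * m[:, None])
                ZtMZ = Z.T @ (Z * m[:, None]) + np.diag(ginv)
                H = np.block([[XtMX, XtMZ], [XtMZ.T, ZtMZ]])
                g = np.concatenate([grad_b, grad_u])
            else:
                H = X.T @ (X * m[:, None])
                g = grad_b
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), g)
            except np.linalg.LinAlgError:
                return None
            scale = 1.0
            for _ in range(30):
                nb = beta + scale * step[:p]
                nu = u + scale * step[p:] if q else u
                nf, neta, nmu = penalised(nb, nu)
                if nf >= f - 1e-12:
                    break
                scale *= 0.5
            improved = nf - f
            beta, u, f, eta, mu = nb, nu, nf, neta, nmu
            if abs(improved) < 1e-10 and float(np.max(np.abs(g))) < 1e-6:
                break
        m = w * mu
        if q:
            H_uu = Z.T @ (Z * m[:, None]) + np.diag(ginv)
        return beta, u, f, mu, H_uu

    def laplace_loglik(self, lnsig2, start=None):
        out = self._pirls(lnsig2, start)
        if out is None:
            return -np.inf, None
        beta, u, f, mu, H_uu = out
        d = self.d
        if d.k:
            sign, logdet_h = np.linalg.slogdet(H_uu)
            if sign <= 0:
                return -np.inf, None
            logdet_g = float(np.sum(lnsig2[d._ginv_index]))
            ll = f - 0.5 * logdet_h - 0.5 * logdet_g
        else:
            ll = f
        return ll, (beta, u, mu)

    def fit(self, theta0=None):
        d = self.d
        if d.k == 0:
            ll, sol = self.laplace_loglik(np.array([]))
            beta, _, mu = sol
            vcov = np.linalg.inv(d.X.T @ (d.X * (d.w * mu)[:, None]))
            return _PoisFit(beta, np.array([]), ll, True, False, vcov)
        warm = {"sol": None}

        def objective(theta):
            theta = np.clip(theta, -15.0, 8.0)
            start = warm["sol"]
            ll, sol = self.laplace_loglik(theta, start)
            if sol is not None:
                warm["sol"] = (sol[0], sol[1])
            return -ll

        start = np.full(d.k, -1.0) if theta0 is None else np.asarray(theta0, float)
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8,
                                         "maxiter": 1500})
        theta = np.clip(res.x, -15.0, 8.0)
        ll, sol = self.laplace_loglik(theta, warm["sol"])
        if sol is None:
            return _PoisFit(np.full(d.X.shape[1], np.nan), theta, -np.inf,
                            False, True, np.full((d.X.shape[1],) * 2, np.nan))
        beta, u, mu = sol
        m = d.w * mu
        XtMX = d.X.T @ (d.X * m[:, None])
        XtMZ = d.X.T @ (d.Z * m[:, None])
        ZtMZ = d.Z.T @ (d.Z * m[:, None]) + np.diag(
            1.0 / np.exp(theta)[d._ginv_index])
        vcov = np.linalg.inv(XtMX - XtMZ @ np.linalg.solve(ZtMZ, XtMZ.T))
        singular = bool((np.exp(theta) < 1e-6).any())
        return _PoisFit(beta, theta, ll, bool(res.success), singular, vcov)


@dataclass
class _PoisFit:
    beta: np.ndarray
    theta: np.ndarray
    loglik: float
    converged: bool
    singular: bool
    vcov: np.ndarray


# --------------------------------------------------------------------------
# Public fitting interface
# --------------------------------------------------------------------------


def fit_mixed(spec: ModelSpec, data: pd.DataFrame, reml: bool = False) -> FitResult:
    """Fit one mixed model and return a :class:`FitResult`.

    Gaussian models use profiled ML (or REML when ``reml=True``);
    Poisson models always use the Laplace approximation to ML.
    Non-convergence is reported through ``converged``, never silently;
    rank-deficient fixed effects raise with the aliased columns named.
    """
    design = _Design(spec, data)
    names = design.colnames
    if spec.family == "gaussian":
        engine = GaussianLMM(design, reml=reml)
        raw = engine.fit(design.y)
        sigma2 = raw.sigma2
        vc = {name: float(np.exp(t) * sigma2)
              for name, t in zip(design.re_names, raw.theta)}
        n_par = len(names) + design.k + 1
        vcov = sigma2 * np.linalg.inv(raw.XtVX)
        estimation = "REML" if reml else "ML"
        theta = raw.theta
    else:
        engine = PoissonGLMM(design)
        raw = engine.fit()
        sigma2 = None
        vc = {name: float(np.exp(t))
              for name, t in zip(design.re_names, raw.theta)}
        n_par = len(names) + design.k
        vcov = raw.vcov
        estimation = "Laplace"
        theta = raw.theta
    return FitResult(
        spec=spec,
        coefficients=pd.Series(raw.beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=float(raw.loglik),
        n_obs=design.n,
        n_groups=design.n_groups,
        converged=bool(raw.converged),
        singular=bool(raw.singular),
        estimation=estimation,
        varcomps=vc,
        sigma2=sigma2,
        aic=float(-2.0 * raw.loglik + 2.0 * n_par),
        design_info=design.design_info,
        _X=design.X,
        _y=design.y,
        _w=design.w,
        _engine=engine,
        _theta=theta,
    )


def refit_response(fit: FitResult, new_y: np.ndarray) -> float:
    """Log-likelihood of the same gaussian design refitted to a new
    response (the permutation tests' fast path)."""
    if not isinstance(fit._engine, GaussianLMM):
        raise TypeError("refit_response supports gaussian fits only")
    return float(fit._engine.fit(np.asarray(new_y, float), theta0=fit._theta).loglik)


def select_random_structure(specs: Sequence[ModelSpec], data: pd.DataFrame):
    """Choose among candidate random-effect structures by AIC.

    Gaussian candidates are compared on REML fits, Poisson candidates
    on Laplace ML fits.  Candidates that fail to converge are dropped
    (the fallback path is recorded in the returned trail); if none
    converge a ``RuntimeError`` is raised.

    Returns ``(best_spec, trail)`` where ``trail`` is a DataFrame with
    one row per candidate (structure, converged, singular, AIC).
    """
    if not specs:
        raise ValueError("need at least one candidate")
    rows, fits = [], {}
    for spec in specs:
        reml = spec.family == "gaussian"
        try:
            fr = fit_mixed(spec, data, reml=reml)
            ok = fr.converged and np.isfinite(fr.aic)
        except np.linalg.LinAlgError:
            fr, ok = None, False
        rows.append({
            "random_structure": str(spec.random_structure),
            "converged": ok,
            "singular": bool(fr.singular) if fr else True,
            "aic": fr.aic if fr else np.nan,
        })
        if ok:
            fits[str(spec.random_structure)] = (spec, fr.aic)
    trail = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("no candidate random-effects structure converged")
    best = min(fits.values(), key=lambda t: t[1])[0]
    return best, trail


# --------------------------------------------------------------------------
# Fixed-effect simplification
# --------------------------------------------------------------------------


def _factors(term: str) -> frozenset:
    return frozenset(f.strip() for f in term.split(":"))


def droppable_terms(terms: Sequence[str]) -> list[str]:
    """Terms removable while respecting marginality: a term is droppable
    only when its factors are not a proper subset of another term's."""
    out = []
    for t in terms:
        ft = _factors(t)
        if not any(ft < _factors(o) for o in terms if o != t):
            out.append(t)
    return out


def loglik_nested_pair(full_fit: FitResult, reduced_fit: FitResult) -> tuple[float, float]:
    """Log-likelihoods of a nested pair, polished for comparability.

    With identical random structures the full model nests the reduced
    one at any fixed variance ratios, so if the reduced optimiser found
    a better ratio point the full model is re-optimised from there;
    this makes the ML likelihood-ratio non-negative up to numerical
    noise.
    """
    lf, lr_ = full_fit.loglik, reduced_fit.loglik
    if lr_ > lf and reduced_fit._theta is not None and len(reduced_fit._theta):
        eng = full_fit._engine
        if isinstance(eng, GaussianLMM):
            lf = max(lf, eng.fit(eng.d.y, theta0=reduced_fit._theta).loglik)
        elif isinstance(eng, PoissonGLMM):
            lf = max(lf, eng.fit(theta0=reduced_fit._theta).loglik)
    return lf, lr_


def _chi2_lrt(full_fit: FitResult, reduced_fit: FitResult) -> tuple[float, int, float]:
    lf, lr_ = loglik_nested_pair(full_fit, reduced_fit)
    lr = 2.0 * (lf - lr_)
    assert lr >= -1e-4, "dropping a term increased the ML log-likelihood"
    lr = max(lr, 0.0)
    df = len(full_fit.coefficients) - len(reduced_fit.coefficients)
    p = float(stats.chi2.sf(lr, max(df, 1)))
    return lr, df, p


def backward_simplify(
    full: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    lrt: Callable | None = None,
) -> tuple[FitResult, pd.DataFrame]:
    """Backwards stepwise simplification by likelihood-ratio tests.

    Models are compared under maximum likelihood.  At each step every
    droppable term (marginality respected) is tested; the least
    significant with p >= alpha is removed and the process repeats.
    ``lrt`` may replace the chi-square reference with another test of
    ``(full_fit, reduced_fit, term)`` returning ``(stat, df, p)`` —
    the permutation machinery hooks in here.

    Returns the final ML fit and the full testing trail.
    """
    current = full
    fit = fit_mixed(current, data, reml=False)
    if not fit.converged:
        raise RuntimeError("full model did not converge under ML")
    if alpha <= 0:
        # a significance level of zero can never declare a term
        # non-significant: the full model stands
        return fit, pd.DataFrame(columns=["step", "term", "lr", "df", "p", "action"])
    test = lrt or (lambda f, r, term: _chi2_lrt(f, r))
    trail = []
    step = 0
    while True:
        step += 1
        candidates = []
        for term in droppable_terms(current.fixed_terms):
            reduced_fit = fit_mixed(current.drop_term(term), data, reml=False)
            stat, df, p = test(fit, reduced_fit, term)
            candidates.append((p, term, stat, df, reduced_fit))
            trail.append({"step": step, "term": term, "lr": stat, "df": df,
                          "p": p, "action": "tested"})
        drops = [c for c in candidates if c[0] >= alpha]
        if not drops:
            break
        p, term, stat, df, reduced_fit = max(drops, key=lambda c: c[0])
        trail.append({"step": step, "term": term, "lr": stat, "df": df,
                      "p": p, "action": "dropped"})
        current = current.drop_term(term)
        fit = reduced_fit
        if not current.fixed_terms:
            break
    return fit, pd.DataFrame(trail)


# --------------------------------------------------------------------------
# Diagnostics and post-hoc tests
# --------------------------------------------------------------------------


def gvif(fit: FitResult) -> dict:
    """Generalised variance inflation factors per fixed-effect term.

    Computed from the correlation matrix R of the non-intercept design
    columns: for a term with column set g,
    ``GVIF = det(R_gg) det(R_-g-g) / det(R)``.  The returned mapping
    holds ``(gvif, gvif ** (1 / (2 df)))`` per term.
    """
    info = fit.design_info
    names = [t for t in info.term_names if t != "Intercept"]
    if len(names) < 2:
        raise ValueError("need at least two non-intercept terms for GVIF")
    cols, groups = [], {}
    for t in names:
        sl = info.term_name_slices[t]
        groups[t] = list(range(len(cols), len(cols) + (sl.stop - sl.start)))
        cols.extend(range(sl.start, sl.stop))
    x = fit._X[:, cols]
    r = np.corrcoef(x, rowvar=False)
    sign, logdet_all = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular correlation matrix among fixed effects")
    out = {}
    for t, idx in groups.items():
        other = [i for i in range(r.shape[0]) if i not in idx]
        s1, d1 = np.linalg.slogdet(r[np.ix_(idx, idx)])
        s2, d2 = np.linalg.slogdet(r[np.ix_(other, other)])
        if s1 <= 0 or s2 <= 0:
            raise np.linalg.LinAlgError(f"singular sub-correlation matrix for {t}")
        g = float(np.exp(d1 + d2 - logdet_all))
        out[t] = (g, g ** (1.0 / (2.0 * len(idx))))
    return out


def posthoc_slopes(
    fit: FitResult,
    focal: str,
    by: str = "land_use",
    levels: Sequence[str] | None = None,
    at: Mapping | None = None,
) -> pd.DataFrame:
    """Per-level slopes of a covariate interacting with a factor.

    For each level of ``by``, the slope of ``focal`` is the contrast
    between design rows at focal = 1 and focal = 0 with the factor held
    at that level; its Wald chi-square (1 df) tests whether the slope
    differs from zero.  Raises when the model lacks a
    ``by`` x ``focal`` interaction.
    """
    has_int = any(
        {f.name() for f in term.factors} >= {focal, by}
        for term in fit.design_info.terms)
    if not has_int:
        raise ValueError(f"model has no {by} x {focal} interaction")
    if levels is None:
        fi = next(info for factor, info in fit.design_info.factor_infos.items()
                  if factor.name() == by)
        levels = list(fi.categories)
    beta = fit.coefficients.to_numpy()
    V = fit.vcov.to_numpy()
    rows = []
    base = dict(at or {})
    for level in levels:
        x1 = fit.predict_row({**base, by: level, focal: 1.0})
        x0 = fit.predict_row({**base, by: level, focal: 0.0})
        c = x1 - x0
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        chisq = (est / se) ** 2 if se > 0 else np.inf
        rows.append({by: level, "estimate": est, "se": se,
                     "chisq": chisq, "p": float(stats.chi2.sf(chisq, 1))})
    return pd.DataFrame(rows)
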