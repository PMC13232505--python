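"""Gibbs-sampling engine for Gaussian and binary-probit mixed models.

The engine fits latent-Gaussian mixed models in a "long" data layout where
every observation carries a *component* index.  A component is one slice of
the character-state dimension: one transplant elevation when the same trait
expressed at different elevations is treated as distinct, genetically
correlated traits, or one trait in a bivariate development-time x survival
model.  Random terms may have

* ``scalar`` structure      -- one variance, i.i.d. effects per level;
* ``diagonal`` structure    -- one effect per (level, component) with a
  separate variance per component and no cross-component covariance;
* ``unstructured`` structure -- one effect vector per level drawn from a
  full, unstructured covariance matrix across components (the sire term of
  a character-state genetic model).

Binary responses are handled by probit latent-liability augmentation
(truncated-normal draws of the liability given the observed 0/1), after
which the Gaussian conjugate updates apply with the residual liability
variance pinned at 1 — the usual threshold-model identifiability
convention.  Covariance updates are conjugate inverse-Wishart
(inverse-gamma in one dimension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "fit_mixed",
    "fit_gaussian_mixed",
    "fit_probit_mixed",
    "fit_bivariate_mixed",
    "cov2cor",
]

GAUSSIAN = "gaussian"
PROBIT = "binary_probit"

#: linear predictors are clamped to +/- this value before sampling the
#: truncated-normal liability, which keeps the inverse-CDF draw finite at
#: extreme fitted probabilities.
LIABILITY_CLAMP = 8.0

_TAIL_EPS = 1e-12


@dataclass(frozen=True)
class RandomTerm:
    """One random term of a mixed model.

    Parameters
    ----------
    factor
        Column of the data frame whose values label the grouping levels
        (e.g. ``"sire"``, ``"family"``, ``"block"``).
    structure
        ``"scalar"``, ``"diagonal"`` or ``"unstructured"`` (see module
        docstring).  Non-scalar structures are indexed by the model's
        component dimension.
    """

    factor: str
    structure: str = "scalar"

    def __post_init__(self) -> None:
        if self.structure not in ("scalar", "diagonal", "unstructured"):
            raise ValueError(f"unknown random-term structure {self.structure!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a model for the data-frame front ends.

    ``response`` names the response column, ``family`` its distribution
    (``gaussian`` or ``binary_probit``), ``fixed_terms`` the fixed-effect
    factor columns (crossed into a cell-means design), ``random_terms`` the
    random structure and ``environment_factor`` the column indexing the
    character-state dimension (``None`` for single-component models).
    """

    response: str
    family: str
    fixed_terms: Sequence[str] = ()
    random_terms: Sequence[RandomTerm] = ()
    environment_factor: str | None = None

    def __post_init__(self) -> None:
        if self.family not in (GAUSSIAN, PROBIT):
            raise ValueError(f"unknown family {self.family!r}")
        n_unstr = sum(t.structure == "unstructured" for t in self.random_terms)
        if self.environment_factor is None and n_unstr:
            raise ValueError(
                "unstructured random terms need an environment_factor"
            )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults are desk-scale (a complete chain in seconds to minutes);
    production-scale settings (e.g. burn-in 200,000 / thin 2,000 / 1,000
    saved) can be requested explicitly for final runs.
    """

    n_burnin: int = 5_000
    thin: int = 10
    n_saved: int = 1_000
    prior_scale: float = 1.0
    #: extra inverse-Wishart degrees of freedom beyond the term dimension;
    #: the default df = dim + 1 is proper but heavy-tailed.
    prior_df_extra: int = 1
    parameter_expansion: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_saved < 1:
            raise ValueError("n_saved must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")

    def with_(self, **kw) -> "MCMCConfig":
        d = self.__dict__ | kw
        return MCMCConfig(**d)


@dataclass
class PosteriorSamples:
    """Saved draws from one fitted model.

    ``fixed`` is (n_saved, p); ``random_cov[name]`` is (n_saved,) for scalar
    terms, (n_saved, C) for diagonal terms and (n_saved, C, C) for
    unstructured terms; ``resid_var`` is (n_saved, C) with probit components
    pinned at 1.  ``random_effects[name]`` holds the posterior *mean* effect
    per level (BLUP analogue), not per-draw effects.
    """

    fixed: np.ndarray
    fixed_names: list[str]
    random_cov: dict[str, np.ndarray]
    random_structure: dict[str, str]
    resid_var: np.ndarray
    component_labels: list
    component_family: list[str]
    random_effects: dict[str, np.ndarray]
    random_levels: dict[str, list]
    n_obs: int
    n_dropped: int = 0
    log: list[str] = field(default_factory=list)

    @property
    def n_saved(self) -> int:
        return self.fixed.shape[0]

    def fixed_draws(self, name: str) -> np.ndarray:
        return self.fixed[:, self.fixed_names.index(name)]

    def total_random_variance(self, component_idx: int = 0) -> np.ndarray:
        """Per-draw sum of all random-term variances acting on a component."""
        out = np.zeros(self.n_saved)
        for name, draws in self.random_cov.items():
            s = self.random_structure[name]
            if s == "scalar":
                out += draws
            elif s == "diagonal":
                out += draws[:, component_idx]
            else:
                out += draws[:, component_idx, component_idx]
        return out

    def diagnostics(self) -> dict[str, dict[str, float]]:
        """Lag-1 autocorrelation and crude effective size per variance chain."""
        out = {}
        for name, draws in self.random_cov.items():
            chain = draws.reshape(self.n_saved, -1)[:, 0]
            rho = _lag1_autocorr(chain)
            ess = self.n_saved * max(1.0 - rho, 1e-3) / (1.0 + abs(rho))
            out[name] = {"lag1_autocorr": rho, "ess": ess}
        return out


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size < 3 or np.var(x) < 1e-300:
        return 0.0
    a, b = x[:-1], x[1:]
    return float(np.corrcoef(a, b)[0, 1])


def cov2cor(cov: np.ndarray) -> np.ndarray:
    """Covariance matrix -> correlation matrix (unit diagonal)."""
    cov = np.asarray(cov, float)
    d = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# core sampler
# ---------------------------------------------------------------------------


def _check_fixed_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer observations than fixed-effect columns")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify aliased columns by incremental QR rank
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient fixed design; aliased terms: {aliased}")


def _sample_truncnorm_std(eta: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Liability draws: N(eta,1) truncated to >0 where y=1, <=0 where y=0."""
    eta = np.clip(eta, -LIABILITY_CLAMP, LIABILITY_CLAMP)
    u = rng.random(eta.shape)
    p_neg = ndtr(-eta)  # P(liability <= 0)
    # inverse-CDF sampling of the standardized residual e = liab - eta
    q = np.where(y > 0, p_neg + u * (1.0 - p_neg), u * p_neg)
    q = np.clip(q, _TAIL_EPS, 1.0 - _TAIL_EPS)
    return eta + ndtri(q)


class _TermState:
    """Mutable per-term sampler state."""

    __slots__ = ("name", "structure", "codes", "n_levels", "u", "cov", "codes2")

    def __init__(self, name, structure, codes, n_levels, n_comp):
        self.name = name
        self.structure = structure
        self.codes = codes
        self.n_levels = n_levels
        if structure == "scalar":
            self.u = np.zeros(n_levels)
            self.cov = 1.0
            self.codes2 = None
        else:
            self.u = np.zeros((n_levels, n_comp))
            self.cov = np.eye(n_comp) if structure == "unstructured" else np.ones(n_comp)
            self.codes2 = None  # set once component codes are known

    def contribution(self, comp: np.ndarray) -> np.ndarray:
        if self.structure == "scalar":
            return self.u[self.codes]
        return self.u[self.codes, comp]


def fit_mixed(
    y: np.ndarray,
    component: np.ndarray,
    component_family: Sequence[str],
    component_labels: Sequence,
    X: np.ndarray,
    fixed_names: Sequence[str],
    terms: Sequence[tuple[str, str, np.ndarray, int, Sequence]],
    cfg: MCMCConfig,
    n_dropped: int = 0,
) -> PosteriorSamples:
    """Run the Gibbs sampler on pre-built numeric inputs.

    ``terms`` is a sequence of ``(name, structure, level_codes, n_levels,
    level_labels)``.  ``component`` indexes ``component_family`` /
    ``component_labels`` per observation.  Binary components must be coded
    0/1 and are augmented with latent liabilities.
    """
    y = np.asarray(y, float)
    component = np.asarray(component, int)
    X = np.asarray(X, float)
    n, p = X.shape
    n_comp = len(component_family)
    fixed_names = list(fixed_names)
    log: list[str] = []

    if y.shape[0] != n or component.shape[0] != n:
        raise ValueError("y, component and X must have matching lengths")
    for fam in component_family:
        if fam not in (GAUSSIAN, PROBIT):
            raise ValueError(f"unknown family {fam!r}")
    _check_fixed_rank(X, fixed_names)

    is_probit_comp = np.array([f == PROBIT for f in component_family])
    probit_rows = is_probit_comp[component]
    for c in range(n_comp):
        rows = component == c
        if not rows.any():
            raise ValueError(f"component {component_labels[c]!r} has no observations")
        if is_probit_comp[c]:
            vals = np.unique(y[rows])
            if not np.isin(vals, [0.0, 1.0]).all():
                raise ValueError("binary_probit responses must be coded 0/1")
            if vals.size < 2:
                raise ValueError(
                    f"component {component_labels[c]!r} has a single observed "
                    "class; the liability scale is unidentified"
                )

    rng = np.random.default_rng(cfg.rng_seed)

    states = []
    for name, structure, codes, n_levels, _labels in terms:
        codes = np.asarray(codes, int)
        st = _TermState(name, structure, codes, n_levels, n_comp)
        if structure != "scalar":
            st.codes2 = codes * n_comp + component
            present = np.zeros((n_levels, n_comp), bool)
            present[codes, component] = True
            n_empty = int((~present).sum())
            if n_empty:
                log.append(
                    f"term {name!r}: {n_empty} (level, component) cells with no "
                    "observations; effects there are imputed from the covariance"
                )
        states.append(st)

    # priors
    nu0 = {"scalar": 1 + cfg.prior_df_extra, "diagonal": 1 + cfg.prior_df_extra,
           "unstructured": n_comp + cfg.prior_df_extra}
    S0_scalar = cfg.prior_scale
    S0_mat = cfg.prior_scale * np.eye(n_comp)
    beta_prior_prec = 1e-8  # effectively flat fixed-effect prior

    # state
    beta = np.zeros(p)
    resid_var = np.ones(n_comp)
    ystar = y.copy()

    comp_counts = np.bincount(component, minlength=n_comp)

    saved_fixed = np.empty((cfg.n_saved, p))
    saved_resid = np.empty((cfg.n_saved, n_comp))
    saved_cov = {
        st.name: np.empty((cfg.n_saved,) + np.shape(st.cov)) for st in states
    }
    u_mean = {st.name: np.zeros_like(st.u) for st in states}

    n_iter = cfg.n_burnin + cfg.thin * cfg.n_saved
    fitted_random = np.zeros(n)
    for st in states:
        fitted_random += st.contribution(component)

    for it in range(n_iter):
        eta = X @ beta + fitted_random

        # 1) latent liabilities for probit rows
        if probit_rows.any():
            ystar[probit_rows] = _sample_truncnorm_std(
                eta[probit_rows], y[probit_rows], rng
            )

        w = 1.0 / resid_var[component]

        # 2) fixed effects
        r = ystar - fitted_random
        Xw = X * w[:, None]
        A = X.T @ Xw + beta_prior_prec * np.eye(p)
        b = Xw.T @ r
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        fitted_fixed = X @ beta

        # 3) random terms
        for st in states:
            contrib = st.contribution(component)
            r_t = ystar - fitted_fixed - (fitted_random - contrib)
            if st.structure == "scalar":
                s0 = np.bincount(st.codes, weights=w, minlength=st.n_levels)
                s1 = np.bincount(st.codes, weights=w * r_t, minlength=st.n_levels)
                prec = s0 + 1.0 / st.cov
                mu = s1 / prec
                st.u = mu + rng.standard_normal(st.n_levels) / np.sqrt(prec)
                if cfg.parameter_expansion:
                    _px_rescale(st, r_t, w, rng)
                ss = float(st.u @ st.u)
                df = nu0["scalar"] + st.n_levels
                st.cov = (S0_scalar + ss) / rng.chisquare(df)
            elif st.structure == "diagonal":
                m = st.n_levels * n_comp
                s0 = np.bincount(st.codes2, weights=w, minlength=m).reshape(
                    st.n_levels, n_comp
                )
                s1 = np.bincount(st.codes2, weights=w * r_t, minlength=m).reshape(
                    st.n_levels, n_comp
                )
                prec = s0 + 1.0 / st.cov[None, :]
                mu = s1 / prec
                st.u = mu + rng.standard_normal(mu.shape) / np.sqrt(prec)
                ss = (st.u**2).sum(axis=0)
                df = nu0["diagonal"] + st.n_levels
                st.cov = (S0_scalar + ss) / rng.chisquare(df, size=n_comp)
            else:  # unstructured
                m = st.n_levels * n_comp
                s0 = np.bincount(st.codes2, weights=w, minlength=m).reshape(
                    st.n_levels, n_comp
                )
                s1 = np.bincount(st.codes2, weights=w * r_t, minlength=m).reshape(
                    st.n_levels, n_comp
                )
                prec0 = np.linalg.inv(st.cov)
                lam = np.broadcast_to(prec0, (st.n_levels, n_comp, n_comp)).copy()
                idx = np.arange(n_comp)
                lam[:, idx, idx] += s0
                cov_post = np.linalg.inv(lam)
                mu = np.einsum("lij,lj->li", cov_post, s1)
                Lc = np.linalg.cholesky(cov_post)
                z = rng.standard_normal((st.n_levels, n_comp))
                st.u = mu + np.einsum("lij,lj->li", Lc, z)
                scale = S0_mat + st.u.T @ st.u
                df = nu0["unstructured"] + st.n_levels
                st.cov = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
                if n_comp == 1:
                    st.cov = np.atleast_2d(st.cov)
            fitted_random = fitted_random - contrib + st.contribution(component)

        # 4) residual variances (gaussian components only)
        resid = ystar - fitted_fixed - fitted_random
        ss_comp = np.bincount(component, weights=resid**2, minlength=n_comp)
        for c in range(n_comp):
            if is_probit_comp[c]:
                resid_var[c] = 1.0
            else:
                df = nu0["scalar"] + comp_counts[c]
                resid_var[c] = (S0_scalar + ss_comp[c]) / rng.chisquare(df)

        # 5) save
        k = it - cfg.n_burnin
        if k >= 0 and (k + 1) % cfg.thin == 0:
            s = k // cfg.thin
            saved_fixed[s] = beta
            saved_resid[s] = resid_var
            for st in states:
                saved_cov[st.name][s] = st.cov
                u_mean[st.name] += st.u

    for name in u_mean:
        u_mean[name] /= cfg.n_saved

    return PosteriorSamples(
        fixed=saved_fixed,
        fixed_names=fixed_names,
        random_cov=saved_cov,
        random_structure={t[0]: t[1] for t in terms},
        resid_var=saved_resid,
        component_labels=list(component_labels),
        component_family=list(component_family),
        random_effects=u_mean,
        random_levels={t[0]: list(t[4]) for t in terms},
        n_obs=n,
        n_dropped=n_dropped,
        log=log,
    )


def _px_rescale(st: _TermState, r_t: np.ndarray, w: np.ndarray, rng) -> None:
    """Parameter-expansion move for a scalar term.

    Samples a redundant multiplicative working parameter alpha (diffuse
    Gaussian prior) from its conditional given the current effects, then
    absorbs it into the effects and their variance.  Improves mixing when
    the variance is near zero.
    """
    zu = st.u[st.codes]
    denom = float(np.sum(w * zu * zu)) + 1e-4
    num = float(np.sum(w * zu * r_t))
    mu = num / denom
    alpha = mu + rng.standard_normal() / np.sqrt(denom)
    st.u = st.u * alpha
    st.cov = max(st.cov * alpha * alpha, 1e-12)


# ---------------------------------------------------------------------------
# data-frame front ends
# ---------------------------------------------------------------------------


def _codes(values) -> tuple[np.ndarray, list]:
    import pandas as pd

    cat = pd.Categorical(values)
    return np.asarray(cat.codes, int), list(cat.categories)


def build_cell_means_design(df, factors: Sequence[str]):
    """Indicator (cell-means) design for crossed categorical factors.

    Returns ``(X, names, cell_index)`` where each column is the indicator
    of one observed factor combination; no reference level, no intercept.
    """
    import pandas as pd

    if not factors:
        n = len(df)
        return np.ones((n, 1)), ["(intercept)"], np.zeros(n, int)
    key = df[list(factors)].astype(str).agg(":".join, axis=1)
    codes, labels = _codes(key)
    X = np.zeros((len(df), len(labels)))
    X[np.arange(len(df)), codes] = 1.0
    return X, list(labels), codes


def _prepare(df, spec: ModelSpec):
    import pandas as pd

    data = df.loc[df[spec.response].notna()].reset_index(drop=True)
    n_dropped = len(df) - len(data)
    if len(data) == 0:
        raise ValueError(f"no non-missing observations of {spec.response!r}")

    if spec.environment_factor is not None:
        comp, comp_labels = _codes(data[spec.environment_factor])
    else:
        comp = np.zeros(len(data), int)
        comp_labels = ["(all)"]
    fams = [spec.family] * len(comp_labels)

    X, names, _ = build_cell_means_design(data, list(spec.fixed_terms))

    terms = []
    for t in spec.random_terms:
        codes, labels = _codes(data[t.factor])
        terms.append((t.factor, t.structure, codes, len(labels), labels))

    y = data[spec.response].to_numpy(float)
    return y, comp, fams, comp_labels, X, names, terms, n_dropped


def fit_gaussian_mixed(df, spec: ModelSpec, cfg: MCMCConfig) -> PosteriorSamples:
    """Fit a Gaussian mixed model described by ``spec`` to a data frame.

    Rows with a missing response are dropped and counted in
    ``PosteriorSamples.n_dropped``.
    """
    if spec.family != GAUSSIAN:
        raise ValueError("spec.family must be 'gaussian'")
    y, comp, fams, labels, X, names, terms, nd = _prepare(df, spec)
    return fit_mixed(y, comp, fams, labels, X, names, terms, cfg, n_dropped=nd)


def fit_probit_mixed(df, spec: ModelSpec, cfg: MCMCConfig) -> PosteriorSamples:
    """Fit a binary-probit mixed model (latent-liability augmentation)."""
    if spec.family != PROBIT:
        raise ValueError("spec.family must be 'binary_probit'")
    y, comp, fams, labels, X, names, terms, nd = _prepare(df, spec)
    return fit_mixed(y, comp, fams, labels, X, names, terms, cfg, n_dropped=nd)


def fit_bivariate_mixed(
    df,
    gaussian_response: str,
    binary_response: str,
    random_terms: Sequence[RandomTerm],
    cfg: MCMCConfig,
    fixed_terms: Sequence[str] = (),
) -> PosteriorSamples:
    """Joint model of a Gaussian and a binary-probit trait.

    The two traits are stacked as the two components of the engine's
    character-state dimension: every individual contributes one row per
    observed trait, sharing its grouping-factor levels, and non-scalar
    random terms carry a full 2x2 covariance linking the traits.  An
    individual missing the Gaussian trait (e.g. died before the trait could
    be expressed) contributes to the binary component only; because trait
    residuals are independent given the random effects, dropping the
    missing rows integrates the missing response out of its conditional
    distribution exactly.
    """
    import pandas as pd

    has_g = df[gaussian_response].notna()
    has_b = df[binary_response].notna()
    if not (has_g & has_b).any():
        raise ValueError(
            "no individual with both responses observed; the trait "
            "covariance is unidentified"
        )

    rows = []
    for resp, mask, comp in ((gaussian_response, has_g, 0), (binary_response, has_b, 1)):
        sub = df.loc[mask].copy()
        sub["_y"] = sub[resp].astype(float)
        sub["_comp"] = comp
        rows.append(sub)
    long = pd.concat(rows, ignore_index=True)

    comp = long["_comp"].to_numpy(int)
    fams = [GAUSSIAN, PROBIT]
    labels = [gaussian_response, binary_response]

    # per-component cell-means fixed design
    fix_key = long["_comp"].astype(str)
    for f in fixed_terms:
        fix_key = fix_key + ":" + long[f].astype(str)
    codes, cell_labels = _codes(fix_key)
    X = np.zeros((len(long), len(cell_labels)))
    X[np.arange(len(long)), codes] = 1.0

    terms = []
    for t in random_terms:
        tcodes, tlabels = _codes(long[t.factor])
        terms.append((t.factor, t.structure, tcodes, len(tlabels), tlabels))

    nd = int((~has_g).sum())  # informational: binary-only individuals
    return fit_mixed(
        long["_y"].to_numpy(float), comp, fams, labels, X, list(cell_labels),
        terms, cfg, n_dropped=nd,
    )
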