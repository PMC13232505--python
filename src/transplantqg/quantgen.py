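"""Character-state genetic (co)variance estimation and derived quantities.

The central model treats the same trait expressed at each transplant
elevation as distinct, genetically correlated character states: elevation
is the only fixed effect, the sire term carries an unstructured covariance
matrix across elevations, dam-within-sire (the family term of the nested
paternal half-sib design) has a separate variance per elevation, and field
blocks within elevation have a common variance.  With paternal half-sibs,
additive genetic variance is V_A = 4 x V_sire.

For the binary survival trait, latent-scale variances are mapped to the
data (probability) scale with the exact probit closed forms

    pbar  = Phi(mu / sqrt(1 + V_tot))
    Psi   = phi(mu / sqrt(1 + V_tot)) / sqrt(1 + V_tot)
    V_obs = Psi^2 * V_A_latent

where V_tot is the total latent variance above the unit probit residual
(additive plus dam and block components).  Relative (mean-standardized)
variance, V / mean^2, gives the evolvability of a Gaussian trait and — for
survival — the additive genetic variance in relative fitness, the quantity
that bounds the rate of adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from . import glmm_engine as ge
from .util import elevation_order, posterior_summary

__all__ = [
    "GMatrixSummary",
    "BivariateGeneticSummary",
    "estimate_G_character_state",
    "backtransform_binary",
    "backtransform_binary_mc",
    "relative_variance",
    "cross_environment_correlations",
    "fit_bivariate_devtime_survival",
]

TRAIT_CONDITIONING = {"dev_time": ("established", ge.GAUSSIAN),
                      "survived": ("emerged", ge.PROBIT)}


@dataclass
class GMatrixSummary:
    """Posterior of the cross-elevation sire covariance and its derivatives.

    ``sire_cov_draws`` is (S, E, E) on the model (latent for binary) scale;
    ``va_draws`` = 4 x its diagonal; binary traits additionally carry the
    data-scale mean, additive variance and relative variance per elevation,
    Gaussian traits the mean and V_A / mean^2.
    """

    trait: str
    family: str
    elevations: list[str]
    sire_cov_draws: np.ndarray
    va_draws: np.ndarray
    corr_draws: np.ndarray
    mean_draws: np.ndarray            # data-scale mean per elevation per draw
    va_obs_draws: np.ndarray          # data-scale additive variance
    relative_va_draws: np.ndarray     # va_obs / mean^2
    posterior: ge.PosteriorSamples | None = None

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for j, el in enumerate(self.elevations):
            for label, draws in (
                ("V_A_latent", self.va_draws[:, j]),
                ("mean", self.mean_draws[:, j]),
                ("V_A_data", self.va_obs_draws[:, j]),
                ("relative_V_A", self.relative_va_draws[:, j]),
            ):
                m, lo, hi = posterior_summary(draws)
                rows.append({"trait": self.trait, "elevation": el,
                             "quantity": label, "mean": m,
                             "lower": lo, "upper": hi})
        return pd.DataFrame(rows)


@dataclass
class BivariateGeneticSummary:
    """Sire- and family-level covariance between development time and
    survival liability, within or across elevations."""

    devtime_elevation: str
    survival_elevation: str
    sire_cov_draws: np.ndarray        # (S, 2, 2)
    family_cov_draws: np.ndarray      # (S, 2, 2)
    posterior: ge.PosteriorSamples | None = None

    def _corr(self, draws: np.ndarray) -> np.ndarray:
        v1 = draws[:, 0, 0]
        v2 = draws[:, 1, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            return draws[:, 0, 1] / np.sqrt(v1 * v2)

    @property
    def sire_corr_draws(self) -> np.ndarray:
        return self._corr(self.sire_cov_draws)

    @property
    def family_corr_draws(self) -> np.ndarray:
        return self._corr(self.family_cov_draws)

    def summary(self) -> dict:
        out = {}
        for level, draws in (("sire", self.sire_corr_draws),
                             ("family", self.family_corr_draws)):
            ok = np.isfinite(draws)
            d = draws[ok]
            m, lo, hi = posterior_summary(d)
            out[level] = {
                "corr_mean": float(m), "lower": float(lo), "upper": float(hi),
                "prop_negative": float(np.mean(d < 0)),
                "n_excluded_draws": int((~ok).sum()),
            }
        return out


def estimate_G_character_state(
    data: pd.DataFrame,
    trait: str,
    cfg: ge.MCMCConfig,
    family: str | None = None,
) -> GMatrixSummary:
    """Fit the character-state sire model for one trait and one species.

    Requires the trait observed at >= 2 elevations with sires represented
    across them (the reciprocal design plants every family everywhere).
    """
    cond, default_family = TRAIT_CONDITIONING.get(trait, (None, ge.GAUSSIAN))
    family = family or default_family
    df = data.copy()
    if cond is not None:
        df = df[df[cond] == 1]
    df = df[df[trait].notna()].reset_index(drop=True)
    if df["species"].nunique() > 1:
        raise ValueError("character-state model is fitted per species; "
                         "filter the data to one species first")
    elevs = elevation_order(df["elevation"])
    if len(elevs) < 2:
        raise ValueError(
            f"trait {trait!r} observed at a single elevation; use a "
            "univariate (single-environment) model instead"
        )
    df[trait] = df[trait].astype(float)
    df["elevation"] = pd.Categorical(df["elevation"].astype(str),
                                     categories=elevs, ordered=True)

    spec = ge.ModelSpec(
        response=trait, family=family, fixed_terms=["elevation"],
        random_terms=[
            ge.RandomTerm("sire", "unstructured"),
            ge.RandomTerm("family", "diagonal"),
            ge.RandomTerm("block", "scalar"),
        ],
        environment_factor="elevation",
    )
    fit = ge.fit_probit_mixed if family == ge.PROBIT else ge.fit_gaussian_mixed
    post = fit(df, spec, cfg)

    order = [post.component_labels.index(e) for e in elevs]
    S = post.random_cov["sire"][:, order][:, :, order]
    va = 4.0 * np.diagonal(S, axis1=1, axis2=2)
    corr = np.stack([ge.cov2cor(s) for s in S])

    # fixed effects are elevation cell means, one per component
    mu = np.stack([post.fixed_draws(e) for e in elevs], axis=1)
    dam = post.random_cov["family"][:, order]
    blk = post.random_cov["block"][:, None]

    if family == ge.PROBIT:
        # V_A on the liability scale plus the dam and block components make
        # up the latent variance entering the data-scale conversion
        v_other = dam + blk
        mean_draws, va_obs = backtransform_binary(mu, va, v_other)
    else:
        mean_draws = mu
        va_obs = va
    rel = relative_variance(va_obs, mean_draws)

    return GMatrixSummary(
        trait=trait, family=family, elevations=elevs,
        sire_cov_draws=S, va_draws=va, corr_draws=corr,
        mean_draws=mean_draws, va_obs_draws=va_obs,
        relative_va_draws=rel, posterior=post,
    )


def backtransform_binary(mu_latent, V_A_latent, V_other_latent):
    """Latent probit (liability) scale -> data (probability) scale.

    With total latent variance ``V_tot = V_A_latent + V_other_latent``
    above the unit probit residual:

        pbar  = Phi(mu / sqrt(1 + V_tot))
        Psi   = phi(mu / sqrt(1 + V_tot)) / sqrt(1 + V_tot)
        V_A_obs = Psi^2 * V_A_latent

    All inputs broadcast; applied per posterior draw by the callers.
    Returns ``(pbar, V_A_obs)``.
    """
    mu = np.asarray(mu_latent, float)
    va = np.asarray(V_A_latent, float)
    vo = np.asarray(V_other_latent, float)
    if np.any(va < 0) or np.any(vo < 0):
        raise ValueError("latent variances must be >= 0")
    v_tot = va + vo
    t = np.sqrt(1.0 + v_tot)
    pbar = ndtr(mu / t)
    psi = norm.pdf(mu / t) / t
    return pbar, psi**2 * va


def backtransform_binary_mc(
    mu_latent: float, V_A_latent: float, V_other_latent: float,
    n: int = 1_000_000, seed: int = 0,
):
    """Monte-Carlo oracle for :func:`backtransform_binary`.

    Integrates the probit mean and the average derivative over ``n`` draws
    of the total latent deviation; used to validate the closed forms.
    Returns ``(pbar, Psi)``.
    """
    rng = np.random.default_rng(seed)
    v_tot = V_A_latent + V_other_latent
    l = rng.normal(0.0, np.sqrt(v_tot), n) if v_tot > 0 else np.zeros(n)
    eta = mu_latent + l
    return float(ndtr(eta).mean()), float(norm.pdf(eta).mean())


def relative_variance(V_obs, mean):
    """Mean-standardized variance V / mean^2 (evolvability; for survival,
    the additive genetic variance in relative fitness)."""
    V_obs = np.asarray(V_obs, float)
    mean = np.asarray(mean, float)
    if np.any(mean == 0):
        raise ValueError("relative variance undefined at mean = 0")
    return V_obs / mean**2


def cross_environment_correlations(g: GMatrixSummary, level: float = 0.95) -> pd.DataFrame:
    """Posterior summaries of the cross-elevation genetic correlations.

    Draws where either variance is numerically zero are excluded and
    counted.  Intervals overlapping zero are flagged, echoing the caution
    such correlations deserve when weakly identified.
    """
    E = len(g.elevations)
    rows = []
    for i in range(E):
        for j in range(i + 1, E):
            vi = g.sire_cov_draws[:, i, i]
            vj = g.sire_cov_draws[:, j, j]
            ok = (vi > 1e-12) & (vj > 1e-12)
            r = g.sire_cov_draws[ok, i, j] / np.sqrt(vi[ok] * vj[ok])
            m, lo, hi = posterior_summary(r, level)
            rows.append({
                "trait": g.trait,
                "elev_a": g.elevations[i], "elev_b": g.elevations[j],
                "corr_mean": float(m), "lower": float(lo), "upper": float(hi),
                "overlaps_zero": bool(lo <= 0.0 <= hi),
                "n_excluded_draws": int((~ok).sum()),
            })
    return pd.DataFrame(rows)


def fit_bivariate_devtime_survival(
    data: pd.DataFrame,
    cfg: ge.MCMCConfig,
    mode: str = "within",
    devtime_elevation: str | None = None,
    survival_elevation: str | None = None,
) -> BivariateGeneticSummary:
    """Sire and family covariance between development time and survival.

    ``mode="within"`` uses both traits from one elevation (the two traits
    of the same individuals, survival also from siblings that never
    established).  ``mode="cross"`` takes development time from
    ``devtime_elevation`` and survival from ``survival_elevation`` —
    disjoint individual sets linked through the shared sires — to estimate
    the genetic association between native-range development and
    novel-environment fitness.
    """
    if mode not in ("within", "cross"):
        raise ValueError(f"unknown mode {mode!r}")
    df = data.copy()
    df["elevation"] = df["elevation"].astype(str)

    if mode == "within":
        el = devtime_elevation or survival_elevation
        if el is None:
            raise ValueError("within-elevation mode needs an elevation")
        sub = df[df["elevation"] == str(el)].copy()
        dev_el = surv_el = str(el)
    else:
        if devtime_elevation is None or survival_elevation is None:
            raise ValueError("cross-elevation mode needs both elevations")
        dev_el, surv_el = str(devtime_elevation), str(survival_elevation)
        a = df[df["elevation"] == dev_el].copy()
        b = df[df["elevation"] == surv_el].copy()
        sub = pd.concat([a, b], ignore_index=True)
        # development-time side contributes that trait only, survival side
        # the other, so the two slices stay disjoint in the likelihood
        sub.loc[: len(a) - 1, "survived"] = np.nan
        sub.loc[len(a):, "dev_time"] = np.nan

    sub.loc[sub["established"] != 1, "dev_time"] = np.nan
    sub.loc[sub["emerged"] != 1, "survived"] = np.nan
    sub["survived"] = sub["survived"].astype(float)

    dev_sires = set(sub.loc[sub["dev_time"].notna(), "sire"])
    surv_sires = set(sub.loc[sub["survived"].notna(), "sire"])
    shared = dev_sires & surv_sires
    if len(shared) < 2:
        raise ValueError(
            "fewer than 2 sires shared between the development-time and "
            "survival slices; the sire covariance is unidentified"
        )

    if mode == "cross":
        # disjoint individual sets: bypass the both-observed precondition
        # of the generic bivariate fitter, which targets same-individual
        # designs, by fitting the stacked model directly
        post = _fit_bivariate_stacked(sub, cfg)
    else:
        post = ge.fit_bivariate_mixed(
            sub, "dev_time", "survived",
            random_terms=[ge.RandomTerm("sire", "unstructured"),
                          ge.RandomTerm("family", "unstructured"),
                          ge.RandomTerm("block", "scalar")],
            cfg=cfg,
        )
    return BivariateGeneticSummary(
        devtime_elevation=dev_el, survival_elevation=surv_el,
        sire_cov_draws=post.random_cov["sire"],
        family_cov_draws=post.random_cov["family"],
        posterior=post,
    )


def _fit_bivariate_stacked(sub: pd.DataFrame, cfg: ge.MCMCConfig):
    import pandas as pd

    rows = []
    for resp, comp in (("dev_time", 0), ("survived", 1)):
        s = sub[sub[resp].notna()].copy()
        s["_y"] = s[resp].astype(float)
        s["_comp"] = comp
        rows.append(s)
    long = pd.concat(rows, ignore_index=True)
    comp = long["_comp"].to_numpy(int)
    codes, cells = pd.factorize(long["_comp"].astype(str) + ":" + long["elevation"])
    X = np.zeros((len(long), len(cells)))
    X[np.arange(len(long)), codes] = 1.0
    terms = []
    for t in (ge.RandomTerm("sire", "unstructured"),
              ge.RandomTerm("family", "unstructured"),
              ge.RandomTerm("block", "scalar")):
        c = pd.Categorical(long[t.factor])
        terms.append((t.factor, t.structure, np.asarray(c.codes, int),
                      len(c.categories), list(c.categories)))
    return ge.fit_mixed(
        long["_y"].to_numpy(float), comp, [ge.GAUSSIAN, ge.PROBIT],
        ["dev_time", "survived"], X, list(cells), terms, cfg,
    )
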