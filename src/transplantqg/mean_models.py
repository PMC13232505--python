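"""Species x elevation marginal means for seedling traits.

Fits, for each trait (emergence, establishment, survival as binary traits;
development time as Gaussian), a mixed model with species x elevation
cell-means fixed effects and random field-block and family terms, then
reports data-scale marginal means averaged over the random effects:
for a probit trait the marginal mean of a cell is Phi(eta / sqrt(1 + V_rand))
per posterior draw, where V_rand is the summed random-term variance.

Conditioning follows the trial-record rules: establishment and survival are
defined only for emerged seedlings, development time only for established
seedlings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import glmm_engine as ge
from .util import elevation_order, posterior_summary, tail_prob_two_sided

__all__ = ["MarginalMeans", "fit_trait_means", "pairwise_contrasts"]

#: trait -> (conditioning column, family)
TRAIT_RULES = {
    "emerged": (None, ge.PROBIT),
    "established": ("emerged", ge.PROBIT),
    "survived": ("emerged", ge.PROBIT),
    "dev_time": ("established", ge.GAUSSIAN),
}


@dataclass
class MarginalMeans:
    """Posterior marginal means per species x elevation cell.

    ``mean_draws[(species, elevation)]`` holds data-scale draws (probability
    for binary traits, days for development time).  Cells absent from the
    data are reported in ``missing_cells`` rather than extrapolated.
    ``interaction_tail_prob`` is the smallest Bonferroni-adjusted two-sided
    posterior tail probability over all species-difference-by-elevation-pair
    interaction contrasts (small values: strong evidence the species
    respond differently to elevation).
    """

    trait: str
    family: str
    species: list[str]
    elevations: list[str]
    mean_draws: dict[tuple[str, str], np.ndarray]
    missing_cells: list[tuple[str, str]] = field(default_factory=list)
    interaction_tail_prob: float = 1.0
    posterior: ge.PosteriorSamples | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for (sp, el), draws in self.mean_draws.items():
            m, lo, hi = posterior_summary(draws)
            rows.append({"species": sp, "elevation": el, "mean": m,
                         "lower": lo, "upper": hi})
        return pd.DataFrame(rows).sort_values(["species", "elevation"],
                                              key=_elev_key).reset_index(drop=True)


def _elev_key(col: pd.Series) -> pd.Series:
    try:
        return col.astype(float)
    except ValueError:
        return col


def fit_trait_means(
    data: pd.DataFrame,
    trait: str,
    cfg: ge.MCMCConfig,
    family: str | None = None,
) -> MarginalMeans:
    """Fit the species x elevation mean model for one trait.

    ``family`` defaults from the trait name (binary probit for emergence /
    establishment / survival, Gaussian for development time).
    """
    if trait not in data.columns:
        raise ValueError(f"trait column {trait!r} not in data")
    cond, default_family = TRAIT_RULES.get(trait, (None, ge.GAUSSIAN))
    family = family or default_family

    df = data.copy()
    if cond is not None:
        df = df[df[cond] == 1]
    df = df[df[trait].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no observations of {trait!r} after conditioning")
    df[trait] = df[trait].astype(float)
    df["elevation"] = df["elevation"].astype(str)

    species = sorted(df["species"].astype(str).unique())
    elevations = elevation_order(df["elevation"])
    all_cells = [(sp, el) for sp in species for el in elevations]
    present = set(map(tuple, df[["species", "elevation"]].astype(str).itertuples(index=False)))
    missing = [c for c in all_cells if c not in present]

    spec = ge.ModelSpec(
        response=trait,
        family=family,
        fixed_terms=["species", "elevation"],
        random_terms=[ge.RandomTerm("block"), ge.RandomTerm("family")],
    )
    fit = ge.fit_probit_mixed if family == ge.PROBIT else ge.fit_gaussian_mixed
    post = fit(df, spec, cfg)

    v_rand = post.total_random_variance()
    mean_draws: dict[tuple[str, str], np.ndarray] = {}
    link_draws: dict[tuple[str, str], np.ndarray] = {}
    for sp, el in all_cells:
        name = f"{sp}:{el}"
        if (sp, el) in missing:
            continue
        eta = post.fixed_draws(name)
        link_draws[(sp, el)] = eta
        if family == ge.PROBIT:
            mean_draws[(sp, el)] = ndtr(eta / np.sqrt(1.0 + v_rand))
        else:
            mean_draws[(sp, el)] = eta

    interaction_p = _interaction_tail_prob(link_draws, species, elevations)

    return MarginalMeans(
        trait=trait, family=family, species=species, elevations=elevations,
        mean_draws=mean_draws, missing_cells=missing,
        interaction_tail_prob=interaction_p, posterior=post,
    )


def _interaction_tail_prob(link_draws, species, elevations) -> float:
    """Bonferroni-adjusted minimum tail probability over all
    difference-in-differences contrasts (link scale)."""
    if len(species) < 2 or len(elevations) < 2:
        return 1.0
    ps = []
    pairs_sp = [(a, b) for i, a in enumerate(species) for b in species[i + 1:]]
    pairs_el = [(a, b) for i, a in enumerate(elevations) for b in elevations[i + 1:]]
    for sa, sb in pairs_sp:
        for ea, eb in pairs_el:
            keys = [(sa, ea), (sa, eb), (sb, ea), (sb, eb)]
            if any(k not in link_draws for k in keys):
                continue
            d = (link_draws[(sa, ea)] - link_draws[(sa, eb)]) - (
                link_draws[(sb, ea)] - link_draws[(sb, eb)]
            )
            ps.append(tail_prob_two_sided(d))
    if not ps:
        return 1.0
    return float(min(1.0, min(ps) * len(ps)))


def pairwise_contrasts(
    means: MarginalMeans, adjust: str = "bonferroni", alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise elevation contrasts per species, with letter groupings.

    Each pair is tested by the two-sided posterior tail probability of the
    data-scale difference; with ``adjust="bonferroni"`` the probability is
    multiplied by the number of pairs per species.  Letters are assigned by
    greedy grouping in ascending elevation order: elevations sharing a
    letter are not significantly different.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    rows = []
    letter_rows = []
    for sp in means.species:
        elevs = [e for e in means.elevations if (sp, e) in means.mean_draws]
        if len(elevs) < 2:
            raise ValueError(f"species {sp!r} has < 2 elevations with estimates")
        pairs = [(a, b) for i, a in enumerate(elevs) for b in elevs[i + 1:]]
        m = len(pairs)
        differ: dict[tuple[str, str], bool] = {}
        for a, b in pairs:
            d = means.mean_draws[(sp, a)] - means.mean_draws[(sp, b)]
            p = tail_prob_two_sided(d)
            if adjust == "bonferroni":
                p = min(1.0, p * m)
            sig = p < alpha
            differ[(a, b)] = differ[(b, a)] = sig
            rows.append({"species": sp, "elev_a": a, "elev_b": b,
                         "difference": float(np.mean(d)), "p": p,
                         "significant": sig})
        letters = _letter_groups(elevs, differ)
        for e in elevs:
            letter_rows.append({"species": sp, "elevation": e,
                                "letters": letters[e]})
    out = pd.DataFrame(rows)
    out.attrs["letters"] = pd.DataFrame(letter_rows)
    return out


def _letter_groups(elevs, differ) -> dict[str, str]:
    """Greedy compact-letter assignment, ascending elevation order.

    Each elevation joins every existing group whose members it does not
    differ from; if none accepts it, a new group (next letter) is opened.
    """
    groups: list[list[str]] = []
    for e in elevs:
        placed = False
        for g in groups:
            if all(not differ[(e, other)] for other in g):
                g.append(e)
                placed = True
        if not placed:
            groups.append([e])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {e: "" for e in elevs}
    for i, g in enumerate(groups):
        for e in g:
            out[e] += alphabet[i]
    return out
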