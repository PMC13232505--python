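"""Synthetic breeding-design pedigrees, planting layouts and trait data.

Emulates a factorial sire x dam breeding design reciprocally planted across
an elevational gradient: sires and dams are crossed in small factorial
mating blocks (three sires to three dams by default), each resulting family
contributes a fixed number of seeds per transplant elevation, and seeds are
randomized into field blocks within each elevation.  Trait data are
generated under the latent-Gaussian model the inference modules assume:

* development time (days to seedling establishment) = elevation mean +
  sire effect + dam effect + block effect + Gaussian residual;
* survival is a probit threshold trait: a latent liability (intercept +
  optional development-time coupling + sire + dam + block + standard-normal
  residual) crossing zero;
* sire effects for the two traits at every elevation are drawn jointly from
  a single (2 x n_elevations) x (2 x n_elevations) covariance matrix, so
  cross-trait, cross-environment genetic structure (e.g. fast native
  development covarying with novel-environment survival) is expressible
  directly.

Emergence and establishment are genetics-free Bernoulli events by default
(an optional family-level variance hook exists for robustness studies);
the mean-model module only consumes their means.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "GroundTruthParams",
    "CSV_COLUMNS",
    "generate_pedigree",
    "allocate_seeds",
    "simulate_traits",
    "simulate_dataset",
    "write_trials_csv",
    "read_trials_csv",
    "write_params_sidecar",
]

CSV_COLUMNS = [
    "species", "sire", "dam", "family", "elevation", "block",
    "emerged", "established", "dev_time", "survived",
]

DEFAULT_ELEVATIONS = ("500", "1000", "1500", "2000")


@dataclass(frozen=True)
class DesignSpec:
    """Breeding-design and planting-layout parameters for one species."""

    species_label: str = "sp"
    n_sires: int = 36
    n_dams: int = 36
    mating_block_size: int = 3
    n_families: int | None = None
    seeds_per_family_per_elevation: int = 25
    #: overrides: (number of families, seeds per elevation) for families
    #: whose seed yield fell short of the default
    family_shortfalls: tuple[tuple[int, int], ...] = ()
    elevations: tuple[str, ...] = DEFAULT_ELEVATIONS
    n_field_blocks: int = 5

    def __post_init__(self) -> None:
        if self.mating_block_size < 1:
            raise ValueError("mating_block_size must be >= 1")
        if self.n_sires < 1 or self.n_dams < 1:
            raise ValueError("need at least one sire and one dam")
        if self.n_field_blocks < 1:
            raise ValueError("n_field_blocks must be >= 1")
        for n_fam, seeds in self.family_shortfalls:
            if seeds > self.seeds_per_family_per_elevation:
                raise ValueError(
                    f"shortfall of {seeds} seeds exceeds the default "
                    f"{self.seeds_per_family_per_elevation}"
                )


@dataclass(frozen=True)
class GroundTruthParams:
    """Full simulator parameter set (the quantities recovery tests target).

    ``sire_cov`` is the (2E x 2E) sire covariance over (development time at
    each of E elevations, survival liability at each of E elevations), on
    the latent scale.  The survival residual liability variance is fixed at
    1 (probit convention).  ``survival_devtime_slope`` couples the latent
    development-time deviation into the survival liability (liability units
    per day), emulating directional selection on development time.
    """

    elevations: tuple[str, ...] = DEFAULT_ELEVATIONS
    elevation_means_devtime: tuple[float, ...] = (25.0, 35.0, 45.0, 55.0)
    devtime_sd_residual: float = 6.0
    emergence_prob: tuple[float, ...] = (0.75, 0.75, 0.75, 0.75)
    establishment_prob: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8)
    survival_liability_intercepts: tuple[float, ...] = (0.5, 0.3, 0.0, -0.5)
    sire_cov: np.ndarray | None = None
    dam_var_devtime: float = 4.0
    dam_var_survival: float = 0.1
    block_var_devtime: float = 2.0
    block_var_survival: float = 0.05
    survival_devtime_slope: float | tuple[float, ...] = 0.0
    #: if True, dams transmit genetic (gametic) effects drawn from the same
    #: covariance as sires, so full sibs share twice the half-sib
    #: covariance plus the environmental dam variance — the structure of a
    #: nested paternal half-sib design.  The sire variance component the
    #: inference targets equals the sire_cov diagonal either way.
    dam_genetic: bool = True
    #: optional family-level Bernoulli-probability jitter (logit-normal sd)
    #: for emergence/establishment; 0 disables the hook
    family_emergence_sd: float = 0.0

    def __post_init__(self) -> None:
        E = len(self.elevations)
        for name in ("elevation_means_devtime", "emergence_prob",
                     "establishment_prob", "survival_liability_intercepts"):
            if len(getattr(self, name)) != E:
                raise ValueError(f"{name} must have one entry per elevation")
        for p in (*self.emergence_prob, *self.establishment_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for v in (self.dam_var_devtime, self.dam_var_survival,
                  self.block_var_devtime, self.block_var_survival,
                  self.devtime_sd_residual):
            if v < 0:
                raise ValueError("variances must be >= 0")
        slope = np.asarray(self.survival_devtime_slope, float)
        if slope.ndim not in (0, 1) or (slope.ndim == 1 and slope.size != E):
            raise ValueError(
                "survival_devtime_slope must be a scalar or one value per "
                "elevation"
            )
        cov = self.sire_cov
        if cov is None:
            cov = np.zeros((2 * E, 2 * E))
            object.__setattr__(self, "sire_cov", cov)
        cov = np.asarray(cov, float)
        if cov.shape != (2 * E, 2 * E):
            raise ValueError(f"sire_cov must be {2*E}x{2*E}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("sire_cov must be symmetric")
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("sire_cov must be positive semi-definite")
        object.__setattr__(self, "sire_cov", cov)

    @property
    def n_elevations(self) -> int:
        return len(self.elevations)

    def devtime_block(self) -> np.ndarray:
        E = self.n_elevations
        return self.sire_cov[:E, :E]

    def survival_block(self) -> np.ndarray:
        E = self.n_elevations
        return self.sire_cov[E:, E:]


def sire_cov_from_blocks(
    dev_cov: np.ndarray,
    surv_cov: np.ndarray,
    cross_cov: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the joint sire covariance from per-trait blocks.

    ``cross_cov[i, j]`` is the covariance between development time at
    elevation ``i`` and survival liability at elevation ``j``.
    """
    dev_cov = np.asarray(dev_cov, float)
    surv_cov = np.asarray(surv_cov, float)
    E = dev_cov.shape[0]
    if cross_cov is None:
        cross_cov = np.zeros((E, E))
    cross_cov = np.asarray(cross_cov, float)
    top = np.hstack([dev_cov, cross_cov])
    bottom = np.hstack([cross_cov.T, surv_cov])
    return np.vstack([top, bottom])


def exchangeable_cov(variance: float, correlation: float, dim: int) -> np.ndarray:
    """Equicorrelated covariance matrix (single variance, single correlation)."""
    m = np.full((dim, dim), variance * correlation)
    np.fill_diagonal(m, variance)
    return m


# ---------------------------------------------------------------------------
# pedigree and planting layout
# ---------------------------------------------------------------------------


def generate_pedigree(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Factorial-block pedigree: families as (sire, dam) crosses.

    Sires and dams are partitioned into consecutive mating blocks of
    ``mating_block_size``; within a block every sire is crossed to every
    dam.  A partial final block is permitted (filled left-to-right) so
    realistic, non-multiple-of-three parent counts are reproducible.  If
    ``design.n_families`` asks for fewer families than the candidate
    crosses, a random subset (under ``seed``) is retained, emulating
    crosses that failed to yield seed.
    """
    b = design.mating_block_size
    if design.n_sires < min(b, design.n_sires) or design.n_dams < 1:
        raise ValueError("invalid parent counts")
    n_blocks_s = -(-design.n_sires // b)
    n_blocks_d = -(-design.n_dams // b)
    if n_blocks_s != n_blocks_d:
        rem = abs(design.n_sires - design.n_dams)
        raise ValueError(
            f"cannot partition {design.n_sires} sires and {design.n_dams} dams "
            f"into aligned {b}x{b} mating blocks (even allowing a partial last "
            f"block); parent counts differ by {rem} across "
            f"{n_blocks_s} vs {n_blocks_d} blocks"
        )
    sp = design.species_label
    sires = [f"{sp}_s{i+1:03d}" for i in range(design.n_sires)]
    dams = [f"{sp}_d{i+1:03d}" for i in range(design.n_dams)]
    crosses = []
    for blk in range(n_blocks_s):
        for s in sires[blk * b:(blk + 1) * b]:
            for d in dams[blk * b:(blk + 1) * b]:
                crosses.append((blk + 1, s, d))
    rng = np.random.default_rng(seed)
    if design.n_families is not None:
        if design.n_families > len(crosses):
            raise ValueError(
                f"requested {design.n_families} families but the factorial "
                f"design yields only {len(crosses)} candidate crosses"
            )
        keep = np.sort(rng.choice(len(crosses), design.n_families, replace=False))
        crosses = [crosses[i] for i in keep]
    ped = pd.DataFrame(crosses, columns=["mating_block", "sire", "dam"])
    ped.insert(0, "family", [f"{sp}_f{i+1:03d}" for i in range(len(ped))])
    ped.insert(0, "species", sp)
    return ped


def _seeds_per_family(ped: pd.DataFrame, design: DesignSpec, rng) -> pd.Series:
    """Per-family seed number per elevation, applying shortfall overrides
    to disjoint, randomly chosen family subsets."""
    counts = pd.Series(design.seeds_per_family_per_elevation, index=ped["family"])
    total_short = sum(n for n, _ in design.family_shortfalls)
    if total_short > len(ped):
        raise ValueError(
            f"shortfall overrides cover {total_short} families but the "
            f"pedigree has only {len(ped)}"
        )
    if total_short:
        chosen = rng.choice(len(ped), total_short, replace=False)
        pos = 0
        for n_fam, seeds in design.family_shortfalls:
            for i in chosen[pos:pos + n_fam]:
                counts.iloc[i] = seeds
            pos += n_fam
    return counts


def allocate_seeds(ped: pd.DataFrame, design: DesignSpec, seed: int) -> pd.DataFrame:
    """Assign every seed to a field block within each elevation.

    Each family contributes its per-elevation seed number (default or
    shortfall override), split as evenly as possible across field blocks;
    when the number does not divide evenly, the blocks receiving an extra
    seed are chosen at random under ``seed``.
    """
    rng = np.random.default_rng(seed)
    counts = _seeds_per_family(ped, design, rng)
    nb = design.n_field_blocks
    rows = []
    for _, fam in ped.iterrows():
        n = int(counts[fam["family"]])
        base, rem = divmod(n, nb)
        per_block = np.full(nb, base)
        if rem:
            per_block[rng.choice(nb, rem, replace=False)] += 1
        for elev in design.elevations:
            for blk in range(nb):
                for _ in range(per_block[blk]):
                    rows.append((fam["species"], fam["sire"], fam["dam"],
                                 fam["family"], elev, f"{elev}_b{blk+1}"))
    table = pd.DataFrame(rows, columns=["species", "sire", "dam", "family",
                                        "elevation", "block"])
    # randomized position within block
    perm = rng.permutation(len(table))
    table = table.iloc[np.argsort(perm, kind="stable")].reset_index(drop=True)
    return table.sort_values(["elevation", "block"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------


def simulate_traits(
    seed_table: pd.DataFrame,
    params: GroundTruthParams,
    seed: int,
) -> pd.DataFrame:
    """Generate trait data for every planted seed.

    Sire effects are drawn once per sire from the joint sire covariance;
    dam and block effects are drawn independently per (dam, elevation) and
    per block, matching the diagonal (no cross-environment covariance)
    structure the inference model assumes for those terms.  Development
    time deviations are realized (latently) for every emerged seedling so
    the survival coupling acts on all of them, but recorded only for
    established seedlings.
    """
    E = params.n_elevations
    elev_index = {e: i for i, e in enumerate(params.elevations)}
    missing = set(seed_table["elevation"].astype(str)) - set(params.elevations)
    if missing:
        raise ValueError(f"elevations {sorted(missing)} not covered by params")

    rng = np.random.default_rng(seed)
    n = len(seed_table)
    elev = seed_table["elevation"].astype(str).map(elev_index).to_numpy()

    sires = pd.Categorical(seed_table["sire"])
    dams = pd.Categorical(seed_table["dam"])
    blocks = pd.Categorical(seed_table["block"])
    fams = pd.Categorical(seed_table["family"])

    # sire effect vectors: (n_sires, 2E), columns = dev@elevs then surv@elevs
    cov = params.sire_cov
    L = _psd_cholesky(cov)
    sire_fx = rng.standard_normal((len(sires.categories), 2 * E)) @ L.T

    n_dam_levels = len(dams.categories)
    if params.dam_genetic:
        dam_gen = rng.standard_normal((n_dam_levels, 2 * E)) @ L.T
    else:
        dam_gen = np.zeros((n_dam_levels, 2 * E))
    dam_dev = dam_gen[:, :E] + rng.normal(
        0, np.sqrt(params.dam_var_devtime), (n_dam_levels, E))
    dam_surv = dam_gen[:, E:] + rng.normal(
        0, np.sqrt(params.dam_var_survival), (n_dam_levels, E))
    blk_dev = rng.normal(0, np.sqrt(params.block_var_devtime),
                         len(blocks.categories))
    blk_surv = rng.normal(0, np.sqrt(params.block_var_survival),
                          len(blocks.categories))

    sc, dc, bc = sires.codes, dams.codes, blocks.codes

    p_em = np.asarray(params.emergence_prob)[elev]
    p_est = np.asarray(params.establishment_prob)[elev]
    if params.family_emergence_sd > 0:
        from scipy.special import expit, logit
        jit = rng.normal(0, params.family_emergence_sd, len(fams.categories))
        p_em = expit(logit(np.clip(p_em, 1e-6, 1 - 1e-6)) + jit[fams.codes])
    emerged = (rng.random(n) < p_em).astype(int)
    established = np.where(
        emerged == 1, (rng.random(n) < p_est).astype(int), 0
    )

    dev_mean = np.asarray(params.elevation_means_devtime)[elev]
    dev_dev = (
        sire_fx[sc, elev]
        + dam_dev[dc, elev]
        + blk_dev[bc]
        + rng.normal(0, params.devtime_sd_residual, n)
    )
    dev_time_latent = dev_mean + dev_dev

    gam = np.broadcast_to(
        np.asarray(params.survival_devtime_slope, float), (E,)
    )
    liab = (
        np.asarray(params.survival_liability_intercepts)[elev]
        + gam[elev] * dev_dev
        + sire_fx[sc, E + elev]
        + dam_surv[dc, elev]
        + blk_surv[bc]
        + rng.standard_normal(n)
    )
    survived_all = (liab > 0).astype(int)

    out = seed_table.copy()
    out["emerged"] = emerged
    out["established"] = established
    out["dev_time"] = np.where(established == 1, np.round(dev_time_latent, 2),
                               np.nan)
    out["survived"] = np.where(emerged == 1, survived_all, np.nan)
    out["survived"] = out["survived"].astype("Int64")
    return out[CSV_COLUMNS]


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of semi-definite matrices."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_dataset(
    design: DesignSpec, params: GroundTruthParams, seed: int
) -> pd.DataFrame:
    """Pedigree -> planting layout -> traits, with sub-seeds split off the
    master seed so each stage is independently reproducible."""
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    ped = generate_pedigree(design, sub[0])
    table = allocate_seeds(ped, design, sub[1])
    return simulate_traits(table, params, sub[2])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_trials_csv(df: pd.DataFrame, path) -> None:
    """Fixed-header CSV, one row per planted seed; missing values empty."""
    out = df[CSV_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species": str, "sire": str, "dam": str,
                                  "family": str, "elevation": str, "block": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    df["survived"] = df["survived"].astype("Int64")
    return df


def write_params_sidecar(params: GroundTruthParams, design: DesignSpec, path) -> None:
    """Echo the generating parameters to a key: value sidecar for recovery
    tests and provenance."""
    buf = io.StringIO()
    buf.write("# ground-truth parameters\n")
    for name, val in (
        ("species", design.species_label),
        ("n_sires", design.n_sires),
        ("n_dams", design.n_dams),
        ("n_families", design.n_families),
        ("seeds_per_family_per_elevation", design.seeds_per_family_per_elevation),
        ("family_shortfalls", list(design.family_shortfalls)),
        ("n_field_blocks", design.n_field_blocks),
        ("elevations", list(params.elevations)),
        ("elevation_means_devtime", list(params.elevation_means_devtime)),
        ("devtime_sd_residual", params.devtime_sd_residual),
        ("emergence_prob", list(params.emergence_prob)),
        ("establishment_prob", list(params.establishment_prob)),
        ("survival_liability_intercepts",
         list(params.survival_liability_intercepts)),
        ("dam_var_devtime", params.dam_var_devtime),
        ("dam_var_survival", params.dam_var_survival),
        ("block_var_devtime", params.block_var_devtime),
        ("block_var_survival", params.block_var_survival),
        ("survival_devtime_slope", params.survival_devtime_slope),
        ("dam_genetic", params.dam_genetic),
    ):
        buf.write(f"{name}: {val}\n")
    buf.write("sire_cov:\n")
    for row in params.sire_cov:
        buf.write("  - [" + ", ".join(f"{x:.6g}" for x in row) + "]\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
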