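"""End-to-end pipeline: simulate -> fit -> transform -> permute -> report.

A YAML config drives every stage; all randomness flows from one global
seed, every output directory gets a run log with seeds and settings, and
outputs are plain CSV/JSON so runs can be diffed.  The CLI is a thin layer
over the library: ``simulate``, ``analyze``, ``permute`` and ``report``
subcommands with ``--config``, ``--seed``, ``--outdir`` and ``--fast``
(reduced MCMC) flags.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import glmm_engine as ge
from . import mean_models, permutation, quantgen, selection
from . import synthetic_data as sd

__all__ = ["load_config", "default_config", "cmd_simulate", "cmd_analyze",
           "cmd_permute", "cmd_report", "cli"]

_MCMC_KEYS = {"n_burnin", "thin", "n_saved", "prior_scale", "prior_df_extra",
              "parameter_expansion", "rng_seed"}
_SPECIES_KEYS = {"species_label", "n_sires", "n_dams", "mating_block_size",
                 "n_families", "seeds_per_family_per_elevation",
                 "family_shortfalls", "n_field_blocks", "params"}
_PARAM_KEYS = {"elevations", "elevation_means_devtime", "devtime_sd_residual",
               "emergence_prob", "establishment_prob",
               "survival_liability_intercepts", "dam_var_devtime",
               "dam_var_survival", "block_var_devtime", "block_var_survival",
               "survival_devtime_slope", "family_emergence_sd", "sire_cov",
               "dam_genetic"}
_TOP_KEYS = {"seed", "outdir", "trials_csv", "simulate", "analyze", "permute"}
_SIM_KEYS = {"species", "params"}
_ANALYZE_KEYS = {"mcmc", "traits", "bivariate"}
_PERMUTE_KEYS = {"n_perm", "trait", "species", "mcmc", "joint"}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} in {where}")


def _species_truth(reverse: bool) -> dict:
    """Direction-dependent ground truth for one species.

    ``reverse=False`` is the low-elevation native (novel end at the top of
    the gradient); ``reverse=True`` mirrors every elevation-indexed vector
    for the high-elevation native.  The regime encoded: survival genetic
    variance rising toward the novel end, development-time genetic
    variance concentrated in the native range, and a -0.6 sire correlation
    between native-range development time and novel-end survival.
    """
    E = 4
    dev_v = np.array([9.0, 7.0, 4.0, 2.0])      # native -> novel
    surv_v = np.array([0.02, 0.05, 0.12, 0.25])
    intercepts = np.array([0.6, 0.3, 0.0, -0.4])
    emergence = np.array([0.75, 0.7, 0.7, 0.65])
    establishment = np.array([0.8, 0.75, 0.7, 0.6])
    gamma = np.array([-0.05, -0.02, 0.0, 0.03])
    native, novel = 0, 3
    if reverse:
        # selection on development time keeps its direction (it tracks the
        # elevation gradient, not the species); everything else mirrors
        dev_v, surv_v = dev_v[::-1], surv_v[::-1]
        intercepts = intercepts[::-1]
        emergence, establishment = emergence[::-1], establishment[::-1]
        native, novel = 3, 0
    dev = np.sqrt(np.outer(dev_v, dev_v)) * 0.6
    np.fill_diagonal(dev, dev_v)
    surv = np.sqrt(np.outer(surv_v, surv_v)) * 0.5
    np.fill_diagonal(surv, surv_v)
    cross = np.zeros((E, E))
    cross[native, novel] = -0.6 * np.sqrt(dev_v[native] * surv_v[novel])
    cov = sd.sire_cov_from_blocks(dev, surv, cross)
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    cov = (v * np.clip(w, 1e-9, None)) @ v.T
    return {
        "emergence_prob": [float(x) for x in emergence],
        "establishment_prob": [float(x) for x in establishment],
        "survival_liability_intercepts": [float(x) for x in intercepts],
        "survival_devtime_slope": [float(x) for x in gamma],
        "sire_cov": [[float(x) for x in row] for row in cov],
    }


def default_config() -> dict:
    """Two-species configuration emulating the transplant experiment.

    Design counts follow the field layout (94 families from 36 sires x 35
    dams with seed shortfalls; 108 families from 38 sires x 38 dams; 25
    seeds per family per elevation in 5 blocks at 4 elevations).  Each
    species carries the ground-truth regime oriented toward its own novel
    end of the gradient (see :func:`_species_truth`).
    """
    return {
        "seed": 20260401,
        "outdir": "results/run",
        "simulate": {
            "species": [
                {"species_label": "highland", "n_sires": 36, "n_dams": 35,
                 "n_families": 94,
                 "family_shortfalls": [[4, 10], [8, 15], [10, 20]],
                 "params": _species_truth(reverse=True)},
                {"species_label": "lowland", "n_sires": 38, "n_dams": 38,
                 "n_families": 108,
                 "params": _species_truth(reverse=False)},
            ],
            "params": {
                "elevation_means_devtime": [28.0, 36.0, 44.0, 52.0],
                "devtime_sd_residual": 6.0,
                "dam_var_devtime": 3.0,
                "dam_var_survival": 0.05,
                "block_var_devtime": 2.0,
                "block_var_survival": 0.05,
            },
        },
        "analyze": {
            "mcmc": {"n_burnin": 1000, "thin": 3, "n_saved": 500},
            "traits": ["emerged", "established", "survived", "dev_time"],
            "bivariate": {"mode": "cross", "devtime_elevation": "500",
                          "survival_elevation": "2000"},
        },
        "permute": {"n_perm": 200, "trait": "survived",
                    "mcmc": {"n_burnin": 200, "thin": 1, "n_saved": 150}},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "simulate" in cfg:
        _check_keys(cfg["simulate"], _SIM_KEYS, "simulate")
        for i, spb in enumerate(cfg["simulate"].get("species", [])):
            _check_keys(spb, _SPECIES_KEYS, f"simulate.species[{i}]")
            _check_keys(spb.get("params", {}), _PARAM_KEYS,
                        f"simulate.species[{i}].params")
        if "params" in cfg["simulate"]:
            _check_keys(cfg["simulate"]["params"], _PARAM_KEYS,
                        "simulate.params")
    if "analyze" in cfg:
        _check_keys(cfg["analyze"], _ANALYZE_KEYS, "analyze")
        _check_keys(cfg["analyze"].get("mcmc", {}), _MCMC_KEYS, "analyze.mcmc")
    if "permute" in cfg:
        _check_keys(cfg["permute"], _PERMUTE_KEYS, "permute")
        _check_keys(cfg["permute"].get("mcmc", {}), _MCMC_KEYS, "permute.mcmc")


def _design_from_config(block: dict) -> sd.DesignSpec:
    kw = dict(block)
    if "family_shortfalls" in kw:
        kw["family_shortfalls"] = tuple(tuple(x) for x in kw["family_shortfalls"])
    try:
        return sd.DesignSpec(**kw)
    except TypeError as exc:
        raise ConfigError(f"malformed species block: {exc}") from exc


def _params_from_config(block: dict) -> sd.GroundTruthParams:
    kw = dict(block)
    for key in ("elevations", "elevation_means_devtime", "emergence_prob",
                "establishment_prob", "survival_liability_intercepts"):
        if key in kw:
            kw[key] = tuple(str(x) for x in kw[key]) if key == "elevations" \
                else tuple(float(x) for x in kw[key])
    if "sire_cov" in kw and kw["sire_cov"] is not None:
        kw["sire_cov"] = np.asarray(kw["sire_cov"], float)
    try:
        return sd.GroundTruthParams(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"malformed params block: {exc}") from exc


def _mcmc_from_config(block: dict, seed: int, fast: bool) -> ge.MCMCConfig:
    cfg = ge.MCMCConfig(**block).with_(rng_seed=seed)
    if fast:
        cfg = cfg.with_(n_burnin=min(cfg.n_burnin, 200), thin=1,
                        n_saved=min(cfg.n_saved, 200))
    return cfg


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]


def _log(outdir: Path, lines: list[str]) -> None:
    with open(outdir / "run_log.txt", "a") as fh:
        for line in lines:
            fh.write(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {line}\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def cmd_simulate(cfg: dict, outdir: Path) -> pd.DataFrame:
    """Generate the trial CSV and the ground-truth sidecar."""
    if "simulate" not in cfg:
        raise ConfigError("config has no 'simulate' block")
    outdir.mkdir(parents=True, exist_ok=True)
    shared_params = cfg["simulate"].get("params", {})
    seed = int(cfg.get("seed", 0))
    species_blocks = cfg["simulate"].get("species", [{}])
    seeds = _sub_seeds(seed, len(species_blocks))
    frames, lines = [], []
    for spb, s in zip(species_blocks, seeds):
        spb = dict(spb)
        # a species block may override parts of the shared ground truth
        # (the two species face opposite native/novel directions)
        params = _params_from_config(shared_params | spb.pop("params", {}))
        design = _design_from_config(spb)
        df = sd.simulate_dataset(design, params, s)
        frames.append(df)
        per_elev = len(df) // len(params.elevations)
        lines.append(f"simulate: species={design.species_label} seed={s} "
                     f"families={df['family'].nunique()} seeds/elevation={per_elev}")
        sd.write_params_sidecar(params, design,
                                outdir / f"truth_{design.species_label}.yaml")
    trials = pd.concat(frames, ignore_index=True)
    sd.write_trials_csv(trials, outdir / "trials.csv")
    lines.append(f"simulate: total rows={len(trials)}")
    _log(outdir, lines)
    return trials


def _load_trials(cfg: dict, outdir: Path) -> pd.DataFrame:
    path = cfg.get("trials_csv") or (outdir / "trials.csv")
    df = sd.read_trials_csv(path)
    if len(df) == 0:
        raise ValueError(f"trial table {path} is empty")
    return df


def cmd_analyze(cfg: dict, outdir: Path, fast: bool = False) -> dict:
    """Run mean models, selection, G estimation and the bivariate model.

    Writes one machine-readable summary file per analysis plus a run log.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    trials = _load_trials(cfg, outdir)
    ablock = cfg.get("analyze", {})
    seed = int(cfg.get("seed", 0))
    seeds = _sub_seeds(seed + 1, 64)
    mc = lambda i: _mcmc_from_config(ablock.get("mcmc", {}), seeds[i], fast)
    lines = [f"analyze: seed={seed} fast={fast} rows={len(trials)}"]
    out: dict = {}

    # trait means and contrasts
    mean_tabs, letter_tabs = [], []
    for i, trait in enumerate(ablock.get("traits",
                                         ["emerged", "established",
                                          "survived", "dev_time"])):
        mm = mean_models.fit_trait_means(trials, trait, mc(i))
        tab = mm.table()
        tab.insert(0, "trait", trait)
        tab["interaction_tail_prob"] = mm.interaction_tail_prob
        mean_tabs.append(tab)
        contrasts = mean_models.pairwise_contrasts(mm)
        letters = contrasts.attrs["letters"].copy()
        letters.insert(0, "trait", trait)
        letter_tabs.append(letters)
        lines.append(f"analyze: trait means {trait} "
                     f"interaction_p={mm.interaction_tail_prob:.4f}")
    out["trait_means"] = pd.concat(mean_tabs, ignore_index=True)
    out["trait_means"].to_csv(outdir / "trait_means.csv", index=False)
    out["letters"] = pd.concat(letter_tabs, ignore_index=True)
    out["letters"].to_csv(outdir / "elevation_letters.csv", index=False)

    # selection gradients
    sel_tabs = []
    for j, sp in enumerate(sorted(trials["species"].unique())):
        fit = selection.fit_selection_model(
            trials[trials["species"] == sp], mc(8 + j)
        )
        sel_tabs.append(selection.selection_table(fit))
    out["selection"] = pd.concat(sel_tabs, ignore_index=True)
    out["selection"].to_csv(outdir / "selection_gradients.csv", index=False)
    lines.append(f"analyze: selection gradients for "
                 f"{out['selection']['species'].nunique()} species")

    # character-state G per species x trait
    g_tabs, corr_tabs = [], []
    k = 16
    for sp in sorted(trials["species"].unique()):
        sub = trials[trials["species"] == sp]
        for trait in ("survived", "dev_time"):
            g = quantgen.estimate_G_character_state(sub, trait, mc(k)); k += 1
            tab = g.summary_table()
            tab.insert(0, "species", sp)
            g_tabs.append(tab)
            ctab = quantgen.cross_environment_correlations(g)
            ctab.insert(0, "species", sp)
            corr_tabs.append(ctab)
            diag = g.posterior.diagnostics()["sire"]
            lines.append(f"analyze: G {sp}/{trait} sire lag1="
                         f"{diag['lag1_autocorr']:.3f} ess={diag['ess']:.0f}")
    out["genetic_variance"] = pd.concat(g_tabs, ignore_index=True)
    out["genetic_variance"].to_csv(outdir / "genetic_variance.csv", index=False)
    out["cross_env_correlations"] = pd.concat(corr_tabs, ignore_index=True)
    out["cross_env_correlations"].to_csv(
        outdir / "cross_env_correlations.csv", index=False)

    # bivariate development time x survival
    bconf = ablock.get("bivariate")
    if bconf:
        rows = []
        for sp in sorted(trials["species"].unique()):
            biv = quantgen.fit_bivariate_devtime_survival(
                trials[trials["species"] == sp], mc(k),
                mode={"cross": "cross", "within": "within"}[bconf.get("mode", "cross")],
                devtime_elevation=bconf.get("devtime_elevation"),
                survival_elevation=bconf.get("survival_elevation"),
            ); k += 1
            s = biv.summary()
            for level in ("sire", "family"):
                rows.append({"species": sp, "level": level,
                             "devtime_elevation": biv.devtime_elevation,
                             "survival_elevation": biv.survival_elevation,
                             **s[level]})
        out["bivariate"] = pd.DataFrame(rows)
        out["bivariate"].to_csv(outdir / "bivariate_correlations.csv",
                                index=False)
        lines.append("analyze: bivariate dev_time x survival done")

    _log(outdir, lines)
    return out


def cmd_permute(cfg: dict, outdir: Path, fast: bool = False) -> dict:
    """Permutation null for genetic variance, per species."""
    outdir.mkdir(parents=True, exist_ok=True)
    trials = _load_trials(cfg, outdir)
    pblock = cfg.get("permute", {})
    n_perm = int(pblock.get("n_perm", 200))
    trait = pblock.get("trait", "survived")
    seed = int(cfg.get("seed", 0))
    mcmc = _mcmc_from_config(pblock.get("mcmc", {}), seed, fast)
    species = pblock.get("species") or sorted(trials["species"].unique())
    rows = []
    for j, sp in enumerate(species):
        res = permutation.null_distribution(
            trials[trials["species"] == sp], trait, n_perm, mcmc,
            seed=seed + 7919 * (j + 1), joint=bool(pblock.get("joint", True)),
        )
        for el, r in res.items():
            rows.append({"species": sp, "trait": trait, "elevation": el,
                         "observed_VA": r.observed,
                         "null_mean_VA": float(np.mean(r.null_values)),
                         "n_permutations": r.n_permutations,
                         "n_failed": r.n_failed,
                         "exceedance_p": r.exceedance_p})
    tab = pd.DataFrame(rows)
    tab.to_csv(outdir / "permutation_null.csv", index=False)
    _log(outdir, [f"permute: trait={trait} n_perm={n_perm} seed={seed}"])
    return {"permutation": tab}


def cmd_report(outdir: Path) -> dict:
    """Aggregate stage outputs into one JSON report."""
    report = {}
    for name in ("trait_means", "elevation_letters", "selection_gradients",
                 "genetic_variance", "cross_env_correlations",
                 "bivariate_correlations", "permutation_null"):
        path = outdir / f"{name}.csv"
        if path.exists():
            report[name] = pd.read_csv(path).to_dict(orient="records")
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def cli():
    """Quantitative-genetic analysis of elevational transplant experiments."""


def _common(config, seed, outdir):
    cfg = load_config(config) if config else default_config()
    if seed is not None:
        cfg["seed"] = seed
    out = Path(outdir or cfg.get("outdir", "results/run"))
    return cfg, out


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
def simulate(config, seed, outdir):
    """Generate a synthetic trial table and ground-truth sidecars."""
    cfg, out = _common(config, seed, outdir)
    trials = cmd_simulate(cfg, out)
    click.echo(f"wrote {len(trials)} rows to {out/'trials.csv'}")


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
@click.option("--fast", is_flag=True, help="reduced MCMC settings")
def analyze(config, seed, outdir, fast):
    """Fit mean, selection, genetic-variance and bivariate models."""
    cfg, out = _common(config, seed, outdir)
    res = cmd_analyze(cfg, out, fast=fast)
    click.echo(f"wrote {len(res)} summary tables to {out}")


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
@click.option("--fast", is_flag=True, help="reduced MCMC settings")
def permute(config, seed, outdir, fast):
    """Permutation null distribution for genetic variance."""
    cfg, out = _common(config, seed, outdir)
    res = cmd_permute(cfg, out, fast=fast)
    click.echo(res["permutation"].to_string(index=False))


@cli.command()
@click.option("--outdir", type=click.Path(), default="results/run")
def report(outdir):
    """Aggregate stage outputs into report.json."""
    rep = cmd_report(Path(outdir))
    click.echo(f"report.json written with sections: {sorted(rep)}")


if __name__ == "__main__":
    cli()
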