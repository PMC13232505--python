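"""Shared setup for the analysis drivers: one config, one output folder.

Every driver takes ``--seed`` and ``--outdir`` and operates on the trial
table written by ``01_simulate.py``.
"""

import argparse
from pathlib import Path

from transplantqg import pipeline
from transplantqg import synthetic_data as sd


def parse_args(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=20260401)
    ap.add_argument("--outdir", type=Path, default=Path("results/study"))
    ap.add_argument("--fast", action="store_true",
                    help="reduced MCMC settings")
    return ap.parse_args()


def study_config(seed):
    cfg = pipeline.default_config()
    cfg["seed"] = seed
    return cfg


def load_trials(outdir):
    path = outdir / "trials.csv"
    if not path.exists():
        raise SystemExit(f"{path} not found - run analysis/01_simulate.py first")
    return sd.read_trials_csv(path)
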