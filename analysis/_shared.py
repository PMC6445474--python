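"""Shared setup for the numbered analysis scripts.

Every script regenerates the same seeded synthetic survey through the
library (generation is fast and a pure function of the seed), so the
scripts can be run independently and in any order.
"""

import os

import pandas as pd

from stagedist.io_core import RunConfig

SEED = 1
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def default_config(out_subdir: str = "pipeline") -> RunConfig:
    return RunConfig(seed=SEED, out_dir=os.path.join(RESULTS, out_subdir))


def build_inputs(seed: int = SEED):
    """Environment, truth, hauls, SMALKs and catches for the default run."""
    from stagedist import synthetic as syn

    cfg = default_config()
    env = syn.generate_environment(seed, (cfg.nrows, cfg.ncols),
                                   years_autumn=cfg.years_autumn,
                                   years_spring=cfg.years_spring)
    truth = syn.default_truth(seed, env, years_autumn=cfg.years_autumn,
                              years_spring=cfg.years_spring)
    n = {"SWC_IBTS": cfg.hauls_swc_per_year, "NIGFS": cfg.hauls_nigfs_per_year}
    hauls_aut = syn.generate_hauls(env, n, cfg.years_autumn, "OCT_NOV", seed + 1)
    hauls_spr = syn.generate_hauls(env, n, cfg.years_spring, "FEB_MAR", seed + 2)
    smalks_aut = syn.generate_smalks(truth, cfg.smalks_per_region_year,
                                     cfg.years_autumn, "OCT_NOV", seed + 3)
    smalks_spr = syn.generate_smalks(truth, cfg.smalks_per_region_year,
                                     cfg.years_spring, "FEB_MAR", seed + 4)
    catches = pd.concat(
        [syn.generate_catches(env, hauls_aut, truth, seed + 5),
         syn.generate_catches(env, hauls_spr, truth, seed + 6)],
        ignore_index=True)
    return dict(config=cfg, env=env, truth=truth,
                hauls_aut=hauls_aut, hauls_spr=hauls_spr,
                hauls=pd.concat([hauls_aut, hauls_spr], ignore_index=True),
                smalks_aut=smalks_aut, smalks_spr=smalks_spr, catches=catches)


def outdir(name: str) -> str:
    path = os.path.join(RESULTS, name)
    os.makedirs(path, exist_ok=True)
    return path
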