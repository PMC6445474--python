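"""Simulate the synthetic trawl survey and export it with its ground truth.

Writes the haul/length-frequency/SMALK tables, the environmental grid
layers, and the truth tables/grids every later script is checked against.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _shared import SEED, build_inputs, outdir  # noqa: E402

from stagedist import synthetic as syn  # noqa: E402
from stagedist.io_core import write_grid, write_survey_tables  # noqa: E402


def main() -> None:
    inp = build_inputs()
    out = outdir("survey")
    write_survey_tables(out, inp["hauls"], inp["catches"],
                        __import__("pandas").concat(
                            [inp["smalks_aut"], inp["smalks_spr"]],
                            ignore_index=True))
    inp["smalks_aut"].to_csv(os.path.join(out, "smalks_autumn.csv"), index=False)
    inp["smalks_spr"].to_csv(os.path.join(out, "smalks_spring.csv"), index=False)
    gdir = outdir("survey/grids")
    for name in ("depth", "slope", "aspect", "prox_shore", "sediment", "land"):
        write_grid(os.path.join(gdir, f"{name}.asc"), inp["env"].layers[name])
    tdir = outdir("survey/truth")
    l50, grids = syn.export_truth(inp["truth"], inp["env"])
    l50.to_csv(os.path.join(tdir, "l50_true.csv"), index=False,
               float_format="%.6g")
    for (stage, year, kind), layer in grids.items():
        write_grid(os.path.join(tdir, f"{kind}_{stage}_{year}.asc"), layer)

    env = inp["env"]
    print(f"seed {SEED}: grid {env.shape[0]}x{env.shape[1]}, "
          f"{int(env.sea_mask().sum())} sea cells")
    print(f"hauls: {len(inp['hauls'])} "
          f"({inp['hauls']['survey'].value_counts().to_dict()})")
    n_zero = len(inp["hauls"]) - inp["catches"]["haul_id"].nunique()
    print(f"catch rows: {len(inp['catches'])}; empty hauls: {n_zero} "
          f"({100 * n_zero / len(inp['hauls']):.0f}% zero-inflation)")
    print(f"SMALK records: {len(inp['smalks_aut']) + len(inp['smalks_spr'])}")
    print(f"wrote survey tables, grids and truth under {out}")


if __name__ == "__main__":
    main()
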