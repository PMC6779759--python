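"""Colour-space constraint simulation.

Monte-Carlo RGB variation over a grid of brightness ceilings and saturation
floors; writes results/colourspace_surface.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from elevcolour.colourspace import constraint_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("-n", "--samples", type=int, default=20_000)
    args = parser.parse_args()

    table = constraint_experiment(
        v_ceilings=np.linspace(0.1, 1.0, 10),
        s_floors=np.linspace(0.0, 0.8, 5),
        n=args.samples,
        seed=args.seed,
    )
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "colourspace_surface.csv"
    table.to_csv(out, index=False)
    full = table.query("v_ceiling == 1.0 and s_floor == 0.0")["rgb_variation"].iloc[0]
    dark = table.query("v_ceiling == 0.1 and s_floor == 0.8")["rgb_variation"].iloc[0]
    print(f"variation ratio darkest/full = {dark / full:.3f} -> {out}")


if __name__ == "__main__":
    main()
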